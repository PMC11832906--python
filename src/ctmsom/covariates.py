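"""Site- and occasion-level covariate preparation.

Continuous covariates are standardized to mean 0, sample (n-1) standard
deviation 1 before model fitting; binary indicators (on/off trail, human,
hunting) and categorical codes are left untouched.  Collinearity among the
numeric site covariates is screened pairwise with a |Pearson r| threshold
(0.6 by default); the lower-priority member of each offending pair is
dropped, and variance inflation factors of the retained set are reported as
a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = ["standardize", "standardize_table", "screen_collinearity", "ScreeningReport"]


def standardize(values) -> "tuple[np.ndarray, tuple[float, float]]":
    """Center and scale to mean 0, sample (n-1) sd 1.

    Returns the standardized vector and the ``(mean, sd)`` pair needed to
    back-transform (``x = z * sd + mean``).  Constant vectors are rejected.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D vector")
    if np.unique(x).size < 2:
        raise ValueError("cannot standardize a constant vector (sd = 0)")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    return (x - mean) / sd, (mean, sd)


def standardize_table(
    table: pd.DataFrame, columns: "list[str] | None" = None
) -> "tuple[pd.DataFrame, dict[str, tuple[float, float]]]":
    """Standardize the named columns of a covariate table (others pass through).

    By default all float/int columns with more than two distinct values are
    standardized; 0/1 indicators are deliberately skipped.
    """
    out = table.copy()
    if columns is None:
        columns = [
            c for c in table.columns
            if pd.api.types.is_numeric_dtype(table[c]) and table[c].nunique() > 2
        ]
    stats: dict[str, tuple[float, float]] = {}
    for c in columns:
        out[c], stats[c] = standardize(table[c].to_numpy())
    return out, stats


@dataclass
class ScreeningReport:
    """Outcome of pairwise collinearity screening."""

    retained: list
    dropped: list = field(default_factory=list)
    # (kept, dropped, r) for every pair that tripped the threshold
    decisions: list = field(default_factory=list)
    correlation: pd.DataFrame | None = None
    vif: pd.Series | None = None

    def to_dict(self) -> dict:
        return {
            "retained": list(self.retained),
            "dropped": list(self.dropped),
            "decisions": [
                {"kept": k, "dropped": d, "r": float(r)} for k, d, r in self.decisions
            ],
            "correlation": None if self.correlation is None
            else self.correlation.round(6).to_dict(),
            "vif": None if self.vif is None else self.vif.round(6).to_dict(),
        }


def screen_collinearity(
    table: pd.DataFrame,
    columns: "list[str] | None" = None,
    r_threshold: float = 0.6,
    priority: "list[str] | None" = None,
) -> ScreeningReport:
    """Drop one member of every covariate pair with |Pearson r| >= threshold.

    ``priority`` lists covariates from most to least important; when a pair
    exceeds the threshold the lower-priority member is dropped.  Without an
    explicit priority the column order of the table is used (earlier wins),
    which makes the user's ordering the decision -- the choice of which
    member to keep is a modelling judgement, not a statistic.

    VIFs of the retained set are computed diagnostically (with an intercept);
    the drop rule itself is the pairwise correlation threshold.
    """
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    if not columns:
        return ScreeningReport(retained=[])
    rank = {c: i for i, c in enumerate(priority)} if priority else \
        {c: i for i, c in enumerate(columns)}
    unknown = [c for c in columns if c not in rank]
    if unknown:
        raise ValueError(f"no priority given for covariates: {unknown}")

    X = table[columns].astype(float)
    corr = X.corr()
    ordered = sorted(columns, key=rank.__getitem__)
    retained: list = []
    dropped: list = []
    decisions: list = []
    for c in ordered:
        clash = None
        for kept in retained:
            r = corr.loc[c, kept]
            if abs(r) >= r_threshold:
                clash = (kept, r)
                break
        if clash is None:
            retained.append(c)
        else:
            dropped.append(c)
            decisions.append((clash[0], c, clash[1]))

    vif = None
    if retained:
        Xr = np.column_stack([np.ones(len(X))] + [X[c].to_numpy() for c in retained])
        vals = [variance_inflation_factor(Xr, i + 1) for i in range(len(retained))] \
            if len(X) > len(retained) + 1 else [np.nan] * len(retained)
        vif = pd.Series(vals, index=retained, name="VIF")

    return ScreeningReport(
        retained=retained, dropped=dropped, decisions=decisions,
        correlation=corr, vif=vif,
    )
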