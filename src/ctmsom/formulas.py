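"""Minimal additive formula strings for occupancy / detection linear predictors.

A formula is a string of the form ``"~ forest + tri + roads"`` (intercept
implicit), ``"~ 1"`` (intercept only), or ``"absent"`` (the linear predictor is
identically zero and carries no free coefficients -- used for pairwise
occupancy terms that are switched off).  Only additive main effects of named
columns are supported; that is all the candidate model sets require.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Formula", "parse_formula"]


@dataclass(frozen=True)
class Formula:
    """An additive linear-predictor formula: intercept plus named covariates."""

    terms: tuple[str, ...] = ()
    absent: bool = False
    intercept: bool = True

    @property
    def n_params(self) -> int:
        if self.absent:
            return 0
        return int(self.intercept) + len(self.terms)

    @property
    def names(self) -> tuple[str, ...]:
        """Coefficient names, intercept first."""
        if self.absent:
            return ()
        head = ("(Intercept)",) if self.intercept else ()
        return head + self.terms

    def design(self, table: pd.DataFrame | dict[str, np.ndarray]) -> np.ndarray:
        """Build the design matrix from a table of covariate columns.

        Columns may be 1-D (one row per site) or 2-D (site x occasion); all
        referenced columns must share a shape.  Returns an array of shape
        ``base_shape + (n_params,)``.
        """
        if self.absent:
            raise ValueError("an 'absent' formula has no design matrix")
        cols = []
        for name in self.terms:
            try:
                col = np.asarray(table[name], dtype=float)
            except KeyError:
                raise KeyError(f"covariate {name!r} not found in table") from None
            cols.append(col)
        if cols:
            base_shape = cols[0].shape
            for name, col in zip(self.terms, cols):
                if col.shape != base_shape:
                    raise ValueError(
                        f"covariate {name!r} has shape {col.shape}, expected {base_shape}"
                    )
        else:
            base_shape = (len(table),) if hasattr(table, "__len__") else ()
        if self.intercept:
            cols = [np.ones(base_shape)] + cols
        return np.stack(cols, axis=-1)

    def __str__(self) -> str:
        if self.absent:
            return "absent"
        rhs = " + ".join(("1",) + self.terms if self.intercept else self.terms)
        return f"~ {rhs or '0'}"


def parse_formula(spec: "str | Formula | None") -> Formula:
    """Parse ``"~ a + b"``, ``"~ 1"``, ``"a + b"``, ``"absent"`` or ``None``."""
    if isinstance(spec, Formula):
        return spec
    if spec is None:
        return Formula(absent=True)
    text = spec.strip()
    if text.lower() in {"absent", "0", "~ 0", "~0"}:
        return Formula(absent=True)
    if text.startswith("~"):
        text = text[1:]
    terms: list[str] = []
    for part in text.split("+"):
        part = part.strip()
        if not part or part == "1":
            continue
        if not part.replace("_", "").isalnum():
            raise ValueError(f"unsupported formula term {part!r}: only additive "
                             "main effects of named columns are supported")
        terms.append(part)
    # deduplicate, preserving order
    seen: dict[str, None] = dict.fromkeys(terms)
    return Formula(terms=tuple(seen))
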