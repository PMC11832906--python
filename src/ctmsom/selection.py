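"""Candidate model sets and AIC ranking.

The canonical candidate set crosses three co-occurrence structures
(independence; constant pairwise dependence; covariate-linked pairwise
dependence) with three detection hypotheses (baseline camera-performance
covariates; + day-level human presence; + hunting-season days), giving nine
models M1-M9 for a roe deer / red deer / wolf community.  Marginal occupancy
formulas are held fixed across the set so that AIC differences isolate the
dependence and detection hypotheses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .msom import FitResult, ModelSpec

__all__ = ["build_candidate_set", "rank", "DEFAULT_SPECIES"]

DEFAULT_SPECIES = ("roe", "red", "wolf")

# marginal occupancy, fixed across all nine candidates
_OCC = {
    "roe": "~ forest + tri + roads",
    "red": "~ tri + buildings",
    "wolf": "~ tri + hum_passage",
}
# covariate-linked pairwise dependence (the third structure)
_INTER_COV = {
    ("roe", "red"): "~ open + roads",
    ("roe", "wolf"): "~ forest + buildings",
    ("red", "wolf"): "~ buildings",
}
_DET_BASE = "~ visual + tri + trail"

_REQUIRED = ("forest", "open", "tri", "roads", "buildings", "hum_passage",
             "visual", "trail")


def build_candidate_set(
    available_covariates,
    species: tuple = DEFAULT_SPECIES,
    occasion_covariates=("human", "hunting"),
) -> "list[ModelSpec]":
    """The nine-model candidate set (M1-M9) for a three-species community.

    ``available_covariates`` lists the covariate names present in the
    prepared tables; a missing requirement is rejected by name.  A species
    subset degrades gracefully (interactions only among the retained
    species; one species yields three single-species specs).
    """
    have = set(available_covariates) | set(occasion_covariates)
    missing = [c for c in _REQUIRED if c not in have]
    if missing:
        raise ValueError(f"covariates required by the candidate set are "
                         f"missing: {missing}")
    for extra in ("human", "hunting"):
        if extra not in have:
            raise ValueError(f"occasion covariate {extra!r} is required")
    species = tuple(species)
    unknown = [sp for sp in species if sp not in _OCC]
    if unknown:
        raise ValueError(f"no canonical formulas for species: {unknown}")

    det_variants = [
        ("", _DET_BASE),
        ("+Human", _DET_BASE + " + human"),
        ("+Hunting", _DET_BASE + " + hunting"),
    ]
    inter_variants = [
        ("independent", None),
        ("constant", "const"),
        ("covariate", "cov"),
    ]
    out = []
    m = 0
    for det_label, det_formula in det_variants:
        for inter_label, inter_mode in inter_variants:
            m += 1
            interactions = {}
            if inter_mode == "const":
                interactions = {
                    (a, b): "~ 1"
                    for (a, b) in _INTER_COV if a in species and b in species
                }
            elif inter_mode == "cov":
                interactions = {
                    (a, b): f
                    for (a, b), f in _INTER_COV.items()
                    if a in species and b in species
                }
            out.append(ModelSpec(
                species=species,
                occupancy={sp: _OCC[sp] for sp in species},
                detection={sp: det_formula for sp in species},
                interactions=interactions,
                name=f"M{m}",
            ))
    return out


def rank(fits: "list[FitResult]", tie_tol: float = 1e-6) -> pd.DataFrame:
    """AIC ranking table: ascending AIC, delta vs the best model.

    Non-converged fits are listed last and flagged rather than dropped;
    the AIC reference (delta = 0) is the best converged model when one
    exists.  Ties within ``tie_tol`` are broken toward fewer parameters.
    """
    if not fits:
        raise ValueError("no fits to rank")
    rows = []
    for f in fits:
        inter = [f"{a}:{b}" for (a, b) in f.spec.pairs
                 if not f.spec.interactions[(a, b)].absent]
        rows.append({
            "model": f.spec.name or "(unnamed)",
            "AIC": f.aic,
            "logLik": f.loglik,
            "n_params": f.n_params,
            "converged": bool(f.converged),
            "interactions": ", ".join(inter) if inter else "none",
        })
    table = pd.DataFrame(rows)
    # quantize AIC so near-ties sort by parsimony
    q = np.round(table["AIC"] / tie_tol) * tie_tol
    table = (
        table.assign(_q=q)
        .sort_values(["converged", "_q", "n_params"],
                     ascending=[False, True, True], kind="mergesort")
        .drop(columns="_q")
        .reset_index(drop=True)
    )
    ref_pool = table.loc[table["converged"], "AIC"]
    ref = ref_pool.min() if not ref_pool.empty else table["AIC"].min()
    table.insert(2, "dAIC", table["AIC"] - ref)
    return table
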