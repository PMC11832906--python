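"""Post-fit quantities: marginal, conditional and co-occurrence probabilities,
averaged occupancy/detection summaries, and detection prediction curves.

All occupancy-side quantities are derived from the fitted state distribution
at each site's observed covariates; summary tables report the mean of the
per-site (or per-site-occasion) predictions, with a delta-method standard
error propagated through the fitted coefficient covariance.  Detection
prediction curves for covariate grids carry delta-method confidence
intervals computed on the logit scale and back-transformed, which keeps the
bands inside [0, 1].
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .msom import FitResult, ModelData, _Packed

__all__ = [
    "marginal_occupancy",
    "conditional_occupancy",
    "cooccurrence_probability",
    "predict_detection",
    "derived_summary",
]


def _state_distribution(fitres: FitResult, data: ModelData, theta=None):
    packed = _Packed(fitres.spec, data)
    eta = packed._eta(fitres.theta if theta is None else theta)  # (M, J)
    w = np.exp(eta - eta.max(axis=0, keepdims=True))
    return packed, w / w.sum(axis=0, keepdims=True)


def _delta_se_mean(fitres: FitResult, data: ModelData, mean_fn) -> float:
    """Delta-method SE of a scalar summary of the fitted parameters."""
    if fitres.vcov is None:
        return float("nan")
    theta = fitres.theta
    g = np.empty_like(theta)
    for l in range(theta.size):
        h = 1e-5 * max(1.0, abs(theta[l]))
        tp, tm = theta.copy(), theta.copy()
        tp[l] += h
        tm[l] -= h
        g[l] = (mean_fn(tp) - mean_fn(tm)) / (2.0 * h)
    var = float(g @ fitres.vcov @ g)
    return float(np.sqrt(max(var, 0.0)))


def marginal_occupancy(fitres: FitResult, data: ModelData) -> pd.DataFrame:
    """Per-site marginal occupancy psi_i = P(z_i = 1) for every species.

    With all pairwise terms at zero this reduces exactly to
    logistic(f_i(site)); otherwise co-occurring species shift the marginal
    through the state distribution.
    """
    packed, probs = _state_distribution(fitres, data)
    psi = packed.states.T @ probs                          # (S, J)
    out = pd.DataFrame(psi.T, columns=list(fitres.spec.species))
    out.insert(0, "site", data.array.site_ids)
    return out


def conditional_occupancy(
    fitres: FitResult, data: ModelData, species: str,
    given: str, present: bool = True,
) -> np.ndarray:
    """Per-site P(z_species = 1 | z_given = present).

    When the pairwise natural parameter linking the two species is zero the
    conditional equals the marginal.
    """
    sp_list = list(fitres.spec.species)
    if species not in sp_list or given not in sp_list or species == given:
        raise ValueError(f"need two distinct model species, got "
                         f"{species!r} given {given!r} (model: {sp_list})")
    packed, probs = _state_distribution(fitres, data)
    i, j = sp_list.index(species), sp_list.index(given)
    cond_mask = packed.states[:, j] == (1.0 if present else 0.0)
    denom = probs[cond_mask].sum(axis=0)
    num = probs[cond_mask & (packed.states[:, i] == 1.0)].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / denom


def cooccurrence_probability(
    fitres: FitResult, data: ModelData, species_a: str, species_b: str
) -> np.ndarray:
    """Per-site P(z_a = 1, z_b = 1)."""
    sp_list = list(fitres.spec.species)
    i, j = sp_list.index(species_a), sp_list.index(species_b)
    packed, probs = _state_distribution(fitres, data)
    both = (packed.states[:, i] == 1.0) & (packed.states[:, j] == 1.0)
    return probs[both].sum(axis=0)


def predict_detection(
    fitres: FitResult, species: str, grid: pd.DataFrame, level: float = 0.95
) -> pd.DataFrame:
    """Detection probability over a covariate grid with delta-method CIs.

    ``grid`` must provide every covariate in the species' detection formula
    (e.g. a trail x hunting factorial at mean values of the continuous
    covariates).  CIs are computed on the logit scale and back-transformed.
    """
    formula = fitres.spec.detection[species]
    missing = [t for t in formula.terms if t not in grid.columns]
    if missing:
        raise KeyError(f"grid is missing detection covariates: {missing}")
    V = formula.design(grid)                               # (G, P)
    names = [f"p[{species}] {t}" for t in formula.names]
    idx = [fitres.coef_names.index(n) for n in names]
    alpha = fitres.theta[idx]
    lin = V @ alpha
    out = grid.copy()
    out["p"] = expit(lin)
    if fitres.vcov is not None:
        sub = fitres.vcov[np.ix_(idx, idx)]
        se_lin = np.sqrt(np.maximum(np.einsum("gp,pq,gq->g", V, sub, V), 0.0))
        zq = norm.ppf(0.5 + level / 2.0)
        out["p_low"] = expit(lin - zq * se_lin)
        out["p_high"] = expit(lin + zq * se_lin)
        out["se_logit"] = se_lin
    return out


def derived_summary(fitres: FitResult, data: ModelData) -> pd.DataFrame:
    """Species-level summary: mean marginal psi and mean daily detection p.

    The single psi (p) per species is the mean of per-site (per-deployed
    site-occasion) predictions at the observed covariates; standard errors
    are delta-method SEs of that mean.  Pairwise co-occurrence means and
    conditionals are reported in companion columns of the pair rows.
    """
    packed, probs = _state_distribution(fitres, data)
    sp_list = list(fitres.spec.species)
    rows = []
    for sp in sp_list:
        i = sp_list.index(sp)

        def mean_psi(theta, i=i):
            _, pr = _state_distribution(fitres, data, theta)
            return float((packed.states[:, i] @ pr).mean())

        formula = fitres.spec.detection[sp]
        V = data.detection_design(formula)
        names = [f"p[{sp}] {t}" for t in formula.names]
        idx = [fitres.coef_names.index(n) for n in names]
        obs = packed.mask[:, :, i]

        def mean_p(theta, V=V, idx=idx, obs=obs):
            pmat = expit(V @ theta[idx])
            return float(pmat[obs].mean())

        rows.append({
            "species": sp,
            "psi": mean_psi(fitres.theta),
            "psi_se": _delta_se_mean(fitres, data, mean_psi),
            "p": mean_p(fitres.theta),
            "p_se": _delta_se_mean(fitres, data, mean_p),
        })
    out = pd.DataFrame(rows)
    pair_rows = []
    for a, b in fitres.spec.pairs:
        both = cooccurrence_probability(fitres, data, a, b)
        pair_rows.append({
            "pair": f"{a}:{b}",
            "cooccurrence": float(both.mean()),
            f"psi_{a}_given_{b}": float(np.nanmean(
                conditional_occupancy(fitres, data, a, given=b, present=True))),
            f"psi_{a}_given_not_{b}": float(np.nanmean(
                conditional_occupancy(fitres, data, a, given=b, present=False))),
        })
    out.attrs["pairs"] = pd.DataFrame(pair_rows)
    return out
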