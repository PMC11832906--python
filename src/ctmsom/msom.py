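"""Multi-species occupancy models with pairwise co-occurrence (MSOM).

The community state at a site is a binary vector z in {0,1}^S distributed as
a multivariate Bernoulli in natural-parameter form:

    P(z) ∝ exp( Σ_i f_i z_i + Σ_{i<j} f_ij z_i z_j ),

where each first-order natural parameter f_i and each pairwise parameter
f_ij is a linear function of site covariates.  f_ij = 0 recovers conditional
independence of species i and j; third- and higher-order terms are fixed at
zero (a deliberate model restriction -- only pairwise dependence is
estimated).  Conditional on presence (z_i = 1), daily detections are
independent Bernoulli draws with logit(p) linear in site- and occasion-level
covariates; conditional on absence the species is never detected.  Missing
occasions (camera not deployed) drop out of the likelihood.

The marginal likelihood sums the 2^S latent states per site; everything is
accumulated in log space with log-sum-exp.  The gradient is computed
analytically (posterior-minus-prior moments for the occupancy natural
parameters; posterior presence probability times the Bernoulli score for
detection), which is what makes repeated fitting in simulation studies
affordable.  Standard errors come from the inverse observed Hessian
(central finite differences of the analytic gradient) and p-values are
two-sided Wald.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, log_expit, logsumexp
from scipy.stats import norm

from .events import DetectionArray
from .formulas import Formula, parse_formula

__all__ = [
    "ModelSpec",
    "ModelData",
    "FitResult",
    "state_probabilities",
    "detection_probability",
    "site_log_likelihood",
    "fit",
    "aic",
]

_NEG = -1e30  # log-probability of an impossible state; exp(_NEG) == 0.0 exactly


# --------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class ModelSpec:
    """Formulas for a multi-species occupancy model.

    ``occupancy[sp]`` models the first-order natural parameter of species
    ``sp``; ``interactions[(a, b)]`` models the pairwise natural parameter
    (an ``absent`` formula pins it at zero, ``~ 1`` makes it a free constant);
    ``detection[sp]`` models daily detection on the logit scale.
    """

    species: tuple
    occupancy: dict
    detection: dict
    interactions: dict = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        occ = {sp: parse_formula(self.occupancy[sp]) for sp in self.species}
        det = {sp: parse_formula(self.detection[sp]) for sp in self.species}
        for sp, f in occ.items():
            if f.absent:
                raise ValueError(f"occupancy formula for {sp!r} cannot be absent")
        for sp, f in det.items():
            if f.absent:
                raise ValueError(f"detection formula for {sp!r} cannot be absent")
        inter = {}
        for key, val in self.interactions.items():
            a, b = key
            if a not in self.species or b not in self.species or a == b:
                raise ValueError(f"interaction {key!r} does not name two distinct "
                                 f"species from {self.species}")
            ia, ib = self.species.index(a), self.species.index(b)
            pair = (self.species[min(ia, ib)], self.species[max(ia, ib)])
            inter[pair] = parse_formula(val)
        full = {p: inter.get(p, Formula(absent=True)) for p in self.pairs}
        object.__setattr__(self, "occupancy", occ)
        object.__setattr__(self, "detection", det)
        object.__setattr__(self, "interactions", full)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def pairs(self) -> list:
        return [(a, b) for a, b in itertools.combinations(self.species, 2)]

    @property
    def n_params(self) -> int:
        return (
            sum(f.n_params for f in self.occupancy.values())
            + sum(f.n_params for f in self.interactions.values())
            + sum(f.n_params for f in self.detection.values())
        )

    def blocks(self) -> list:
        """Ordered coefficient blocks: psi singles, psi pairs, then detection."""
        out = []
        for sp in self.species:
            out.append(("psi", sp, self.occupancy[sp]))
        for pair in self.pairs:
            f = self.interactions[pair]
            if not f.absent:
                out.append(("psi", f"{pair[0]}:{pair[1]}", f))
        for sp in self.species:
            out.append(("p", sp, self.detection[sp]))
        return out

    def coef_names(self) -> list:
        names = []
        for kind, label, f in self.blocks():
            names.extend(f"{kind}[{label}] {term}" for term in f.names)
        return names

    @classmethod
    def from_dict(cls, mapping: dict, name: str = "") -> "ModelSpec":
        """Build from flat keys ``f[roe]``, ``f[roe:red]``, ``p[roe]``.

        ``species`` may be given explicitly; otherwise it is inferred from
        the order of the ``f[...]`` single-species keys.
        """
        species = list(mapping.get("species", []))
        occ, det, inter = {}, {}, {}
        for key, val in mapping.items():
            if key in ("species", "name"):
                continue
            head, _, rest = key.partition("[")
            label = rest.rstrip("]")
            if head == "f" and ":" in label:
                a, _, b = label.partition(":")
                inter[(a.strip(), b.strip())] = val
            elif head == "f":
                occ[label] = val
                if label not in species:
                    species.append(label)
            elif head == "p":
                det[label] = val
            else:
                raise ValueError(f"unrecognized model key {key!r}")
        return cls(species=tuple(species), occupancy=occ, detection=det,
                   interactions=inter, name=name or mapping.get("name", ""))


@dataclass
class ModelData:
    """Detection histories plus the covariate tables the formulas reference.

    ``site_covariates`` has one row per site (aligned to ``array.site_ids``;
    reindexed if its index contains them).  ``occasion_covariates`` maps a
    name to a (J, K) array, or (K,) for day-level covariates shared by all
    sites (e.g. the hunting calendar).
    """

    array: DetectionArray
    site_covariates: pd.DataFrame
    occasion_covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = self.array.site_ids
        df = self.site_covariates
        if list(df.index) != list(ids):
            if set(ids).issubset(set(df.index)):
                df = df.loc[ids]
            elif len(df) == len(ids):
                df = df.set_axis(ids, axis=0)
            else:
                raise ValueError("site_covariates cannot be aligned to array sites")
        self.site_covariates = df
        J, K = self.array.n_sites, self.array.n_occasions
        norm_occ = {}
        for name, arr in self.occasion_covariates.items():
            a = np.asarray(arr, dtype=float)
            if a.shape == (K,):
                a = np.broadcast_to(a, (J, K))
            if a.shape != (J, K):
                raise ValueError(f"occasion covariate {name!r} has shape {a.shape}, "
                                 f"expected {(J, K)} or {(K,)}")
            norm_occ[name] = a
        self.occasion_covariates = norm_occ

    def detection_design(self, formula: Formula) -> np.ndarray:
        """(J, K, P) design for a detection formula; site columns broadcast."""
        J, K = self.array.n_sites, self.array.n_occasions
        cols = [np.ones((J, K))] if formula.intercept else []
        for name in formula.terms:
            if name in self.occasion_covariates:
                cols.append(self.occasion_covariates[name])
            elif name in self.site_covariates.columns:
                col = self.site_covariates[name].to_numpy(dtype=float)
                cols.append(np.broadcast_to(col[:, None], (J, K)))
            else:
                raise KeyError(f"detection covariate {name!r} not found")
        return np.stack(cols, axis=-1)


# --------------------------------------------------------------------------
# elementary probability operations


def _enumerate_states(S: int) -> np.ndarray:
    """All 2^S community states, lexicographic in the fixed species order."""
    return np.array(list(itertools.product((0, 1), repeat=S)), dtype=float)


def state_probabilities(f_single, f_pair=None) -> "tuple[np.ndarray, np.ndarray]":
    """Distribution over the 2^S community states at one site.

    Parameters
    ----------
    f_single : (S,) first-order natural parameters.
    f_pair : optional (S, S) matrix of pairwise natural parameters (only the
        upper triangle is read), or dict {(i, j): value} of index pairs.

    Returns ``(states, probs)`` where ``states`` is (2^S, S).
    """
    f = np.asarray(f_single, dtype=float)
    S = f.size
    if not np.all(np.isfinite(f)):
        raise ValueError("natural parameters must be finite")
    G = np.zeros((S, S))
    if f_pair is not None:
        if isinstance(f_pair, dict):
            for (i, j), val in f_pair.items():
                G[min(i, j), max(i, j)] = val
        else:
            G = np.triu(np.asarray(f_pair, dtype=float), k=1)
    states = _enumerate_states(S)
    eta = states @ f
    for i in range(S):
        for j in range(i + 1, S):
            eta += G[i, j] * states[:, i] * states[:, j]
    eta -= eta.max()
    w = np.exp(eta)
    return states, w / w.sum()


def detection_probability(alpha, v) -> float:
    """Logistic detection probability for one design row."""
    alpha = np.asarray(alpha, dtype=float)
    v = np.asarray(v, dtype=float)
    if alpha.shape[-1] != v.shape[-1]:
        raise ValueError(f"coefficient length {alpha.shape[-1]} != "
                         f"design row length {v.shape[-1]}")
    return expit(v @ alpha)


def site_log_likelihood(history, f_single, f_pair, p) -> float:
    """Log-likelihood contribution of one site, marginalized over 2^S states.

    Parameters
    ----------
    history : (K, S) array in {0, 1, NaN}; NaN occasions contribute factor 1.
    f_single : (S,) natural parameters at this site.
    f_pair : (S, S) upper-triangular pairwise natural parameters (or dict).
    p : (K, S) daily detection probabilities given presence.
    """
    y = np.asarray(history, dtype=float)
    p = np.broadcast_to(np.asarray(p, dtype=float), y.shape)
    K, S = y.shape
    mask = np.isfinite(y)
    if not mask.any():
        raise ValueError("history is entirely missing")
    states, probs = state_probabilities(f_single, f_pair)
    with np.errstate(divide="ignore"):
        logp, log1mp = np.log(p), np.log1p(-p)
    term = np.where(mask, np.where(y == 1, logp, log1mp), 0.0)
    logD1 = term.sum(axis=0)                              # (S,)
    detected = np.nansum(y, axis=0) > 0
    logD0 = np.where(detected, _NEG, 0.0)
    logB = states @ logD1 + (1.0 - states) @ logD0        # (2^S,)
    with np.errstate(divide="ignore"):
        return float(logsumexp(np.log(probs) + logB))


# --------------------------------------------------------------------------
# packed likelihood over all sites


class _Packed:
    """Design matrices and index bookkeeping for one (spec, data) pair."""

    def __init__(self, spec: ModelSpec, data: ModelData):
        self.spec = spec
        arr = data.array
        self.species = list(spec.species)
        sp_idx = [arr.species_index(sp) for sp in self.species]
        self.Y = arr.values[:, :, sp_idx]                 # (J, K, S)
        self.J, self.K, self.S = self.Y.shape
        self.mask = np.isfinite(self.Y)
        if not self.mask.any():
            raise ValueError("detection array has no non-missing occasions")
        self.site_ok = self.mask.any(axis=(1, 2))
        self.detected = np.nansum(self.Y, axis=1) > 0     # (J, S)
        self.states = _enumerate_states(self.S)           # (M, S)
        self.n_pairs = self.S * (self.S - 1) // 2
        pair_cols = []
        pidx = 0
        self.pair_index = {}
        for i in range(self.S):
            for j in range(i + 1, self.S):
                pair_cols.append(self.states[:, i] * self.states[:, j])
                self.pair_index[(i, j)] = pidx
                pidx += 1
        self.pair_states = np.stack(pair_cols, axis=1) if pair_cols else \
            np.zeros((self.states.shape[0], 0))

        # coefficient slices, in ModelSpec.blocks() order
        self.slices = []
        self.single_designs = []                          # (i, X (J,P), slice)
        self.pair_designs = []                            # (pair_col, X, slice)
        self.det_designs = []                             # (i, V (J,K,P), slice)
        pos = 0
        for sp in spec.species:
            f = spec.occupancy[sp]
            X = f.design(data.site_covariates)
            sl = slice(pos, pos + f.n_params)
            pos += f.n_params
            self.single_designs.append((self.species.index(sp), X, sl))
            self.slices.append(("psi", sp, sl))
        for pair in spec.pairs:
            f = spec.interactions[pair]
            if f.absent:
                continue
            X = f.design(data.site_covariates)
            sl = slice(pos, pos + f.n_params)
            pos += f.n_params
            i = self.species.index(pair[0])
            j = self.species.index(pair[1])
            col = self.pair_index[(min(i, j), max(i, j))]
            self.pair_designs.append((col, X, sl))
            self.slices.append(("psi", f"{pair[0]}:{pair[1]}", sl))
        for sp in spec.species:
            f = spec.detection[sp]
            V = data.detection_design(f)
            sl = slice(pos, pos + f.n_params)
            pos += f.n_params
            self.det_designs.append((self.species.index(sp), V, sl))
            self.slices.append(("p", sp, sl))
        self.n_params = pos
        self.coef_names = spec.coef_names()
        self.Y0 = np.where(self.mask, self.Y, 0.0)

    # ---- likelihood -----------------------------------------------------

    def _eta(self, theta: np.ndarray) -> np.ndarray:
        """(M, J) unnormalized state log-weights."""
        F1 = np.zeros((self.J, self.S))
        for i, X, sl in self.single_designs:
            F1[:, i] = X @ theta[sl]
        eta = self.states @ F1.T
        for col, X, sl in self.pair_designs:
            eta += np.outer(self.pair_states[:, col], X @ theta[sl])
        return eta

    def _log_detection(self, theta: np.ndarray):
        """Per-species (J,) log-lik of the observed history given presence,
        plus linear predictors for the gradient."""
        logD1 = np.zeros((self.J, self.S))
        lins = []
        for i, V, sl in self.det_designs:
            lin = V @ theta[sl]                           # (J, K)
            term = self.Y0[:, :, i] * log_expit(lin) \
                + (1.0 - self.Y0[:, :, i]) * log_expit(-lin)
            logD1[:, i] = np.where(self.mask[:, :, i], term, 0.0).sum(axis=1)
            lins.append(lin)
        return logD1, lins

    def nll_grad(self, theta: np.ndarray):
        eta = self._eta(theta)                            # (M, J)
        logD1, lins = self._log_detection(theta)
        logD0 = np.where(self.detected, _NEG, 0.0)        # (J, S)
        logB = self.states @ logD1.T + (1.0 - self.states) @ logD0.T
        a = eta + logB
        logZ = logsumexp(eta, axis=0)
        logL_site = logsumexp(a, axis=0) - logZ
        nll = -float(logL_site[self.site_ok].sum())

        # posterior / prior state weights
        W = np.exp(a - a.max(axis=0, keepdims=True))
        W /= W.sum(axis=0, keepdims=True)
        P = np.exp(eta - eta.max(axis=0, keepdims=True))
        P /= P.sum(axis=0, keepdims=True)
        W[:, ~self.site_ok] = 0.0
        P[:, ~self.site_ok] = 0.0

        grad = np.zeros_like(theta)
        post1 = self.states.T @ W                         # (S, J) E_post[z_i]
        prior1 = self.states.T @ P
        for i, X, sl in self.single_designs:
            grad[sl] = -(X.T @ (post1[i] - prior1[i]))
        if self.pair_designs:
            post2 = self.pair_states.T @ W
            prior2 = self.pair_states.T @ P
            for col, X, sl in self.pair_designs:
                grad[sl] = -(X.T @ (post2[col] - prior2[col]))
        for (i, V, sl), lin in zip(self.det_designs, lins):
            resid = np.where(self.mask[:, :, i],
                             self.Y0[:, :, i] - expit(lin), 0.0)
            grad[sl] = -np.einsum("j,jk,jkq->q", post1[i], resid, V)
        return nll, grad

    def nll(self, theta: np.ndarray) -> float:
        return self.nll_grad(theta)[0]

    def hessian(self, theta: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
        """Observed-information Hessian via central differences of the gradient."""
        P = theta.size
        H = np.empty((P, P))
        for l in range(P):
            h = rel_step * max(1.0, abs(theta[l]))
            tp, tm = theta.copy(), theta.copy()
            tp[l] += h
            tm[l] -= h
            _, gp = self.nll_grad(tp)
            _, gm = self.nll_grad(tm)
            H[:, l] = (gp - gm) / (2.0 * h)
        return 0.5 * (H + H.T)


# --------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """Maximum-likelihood fit of a ModelSpec."""

    spec: ModelSpec
    theta: np.ndarray
    loglik: float
    n_params: int
    converged: bool
    grad_norm: float
    se: np.ndarray
    vcov: np.ndarray | None
    coef_names: list
    n_sites: int
    n_starts: int = 1
    se_ok: bool = True
    message: str = ""

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table: estimate, SE, Wald z, two-sided p."""
        est = self.theta
        se = self.se
        with np.errstate(divide="ignore", invalid="ignore"):
            z = est / se
        p = 2.0 * (1.0 - norm.cdf(np.abs(z)))
        return pd.DataFrame({
            "coefficient": self.coef_names,
            "estimate": est,
            "se": se,
            "z": z,
            "p": p,
        })

    def to_json(self) -> str:
        frame = self.to_frame()
        payload = {
            "model": self.spec.name,
            "logLik": self.loglik,
            "n_params": self.n_params,
            "AIC": self.aic,
            "converged": bool(self.converged),
            "grad_norm": self.grad_norm,
            "n_starts": self.n_starts,
            "se_defined": bool(self.se_ok),
            "coefficients": frame.replace({np.nan: None}).to_dict(orient="records"),
        }
        return json.dumps(payload, indent=2, default=float)

    def coef(self, name: str) -> float:
        return float(self.theta[self.coef_names.index(name)])

    def coef_se(self, name: str) -> float:
        return float(self.se[self.coef_names.index(name)])


def _initial_theta(packed: _Packed) -> np.ndarray:
    """Occupancy intercepts at logit(naive psi), detection at logit(0.1)."""
    theta = np.zeros(packed.n_params)
    naive = []
    surveyed = packed.mask.any(axis=1)                    # (J, S)
    for i in range(packed.S):
        occ = packed.detected[:, i][surveyed[:, i]]
        frac = occ.mean() if occ.size else 0.5
        naive.append(np.clip(frac, 0.05, 0.95))
    for i, X, sl in packed.single_designs:
        theta[sl.start] = math.log(naive[i] / (1.0 - naive[i]))
    for i, V, sl in packed.det_designs:
        theta[sl.start] = math.log(0.1 / 0.9)
    return theta


def _newton_polish(packed: _Packed, theta: np.ndarray, fval: float,
                   gtol: float, max_steps: int = 10):
    """Drive the gradient below tolerance with damped Newton steps.

    Quasi-Newton optimizers routinely stop with a small but not tiny
    gradient; a few Newton iterations from there sharpen the optimum so the
    convergence flag (gradient infinity-norm < gtol) is meaningful.  Falls
    back to the incoming point whenever a step fails to decrease the
    objective or the Hessian is not usable.
    """
    H = None  # one Hessian is reused while steps keep shrinking the gradient
    prev_gnorm = np.inf
    for _ in range(max_steps):
        _, grad = packed.nll_grad(theta)
        gnorm = np.abs(grad).max()
        if gnorm < gtol * 0.5:
            break
        if H is None or gnorm > 0.5 * prev_gnorm:
            H = packed.hessian(theta)
        prev_gnorm = gnorm
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        scale, improved = 1.0, False
        for _ in range(8):
            cand = theta - scale * step
            fc = packed.nll(cand)
            if fc <= fval + 1e-12:
                theta, fval, improved = cand, fc, True
                break
            scale *= 0.5
        if not improved:
            break
    return theta, fval


def fit(
    spec: ModelSpec,
    data: ModelData,
    n_starts: int = 5,
    seed: "int | np.random.Generator | None" = 0,
    jitter_sd: float = 0.5,
    gtol: float = 1e-6,
    maxiter: int = 1000,
    compute_se: bool = True,
) -> FitResult:
    """Maximize the marginal likelihood by multi-start quasi-Newton.

    The default 5 random starts (initial point plus N(0, jitter_sd^2)
    perturbations) guard against the multimodality MSOM likelihoods show in
    small samples; the best optimum is kept.  Convergence is declared only
    when the gradient infinity-norm at the optimum is below ``gtol``.
    Non-convergence yields a flagged result, not an exception; a singular or
    indefinite Hessian yields NaN standard errors with ``se_ok=False``.
    """
    packed = _Packed(spec, data)
    if not packed.detected.any(axis=0).all():
        missing = [sp for i, sp in enumerate(packed.species)
                   if not packed.detected[:, i].any()]
        raise ValueError(f"no detections at all for species: {missing}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    theta0 = _initial_theta(packed)

    best = None
    for s in range(max(1, n_starts)):
        start = theta0 if s == 0 else theta0 + rng.normal(0.0, jitter_sd, theta0.size)
        # the quasi-Newton stage only needs to land near the optimum; the
        # Newton polish below drives the gradient under the strict tolerance
        res = optimize.minimize(
            packed.nll_grad, start, jac=True, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-12, "maxcor": 25,
                     "gtol": max(gtol * 10.0, 1e-5)},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta, fval = _newton_polish(packed, best.x, float(best.fun), gtol)
    _, grad = packed.nll_grad(theta)
    grad_norm = float(np.abs(grad).max())
    converged = grad_norm < gtol

    se = np.full(packed.n_params, np.nan)
    vcov = None
    se_ok = False
    if compute_se:
        H = packed.hessian(theta)
        try:
            eig = np.linalg.eigvalsh(H)
            if eig.min() > 0:
                vcov = np.linalg.inv(H)
                se = np.sqrt(np.diag(vcov))
                se_ok = True
        except np.linalg.LinAlgError:
            pass

    return FitResult(
        spec=spec, theta=theta, loglik=-fval,
        n_params=packed.n_params, converged=converged, grad_norm=grad_norm,
        se=se, vcov=vcov, coef_names=packed.coef_names,
        n_sites=packed.J, n_starts=max(1, n_starts), se_ok=se_ok,
        message=str(best.message),
    )


def aic(fit_result: FitResult) -> float:
    """Akaike information criterion: -2 logL + 2 K."""
    return fit_result.aic
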