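"""Synthetic camera-trap worlds with known occupancy and detection truth.

The default configuration emulates the structure of a winter Alpine
camera-trap study: 56 sites on one deployment each, staggered starts giving
a mean of about 112 +/- 38 trap days per camera within a November-April
window, three focal species (roe deer, red deer, wolf) whose community
states follow a multivariate Bernoulli with covariate-linked pairwise
dependence, daily Bernoulli detection driven by camera performance (visual
clarity, terrain ruggedness, on/off-trail placement) and day-level
covariates (hunting-season days, human presence), and image records
fabricated per detected site-day so the 5-minute event-grouping rule is
exercised nontrivially.

Everything downstream of the seed is deterministic: the same config and
seed reproduce the tables byte for byte.  Truth files (latent states, true
coefficients, the directly simulated detection array) are carried alongside
the observable tables so estimator recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .events import DetectionArray
from .msom import FitResult, ModelData, ModelSpec, _Packed

__all__ = ["SimConfig", "SimOutput", "simulate", "roundtrip_score"]


def _default_occupancy_coefs() -> dict:
    # standardized-covariate scale; signs follow the field expectations
    # (ungulates avoid rugged terrain, wolves tolerate it and human passage)
    return {
        "roe": {"(Intercept)": 1.2, "forest": 0.8, "tri": -0.9, "roads": 0.5},
        "red": {"(Intercept)": -0.6, "tri": -0.6, "buildings": -0.5},
        "wolf": {"(Intercept)": -0.3, "tri": 0.5, "hum_passage": 0.6},
    }


def _default_interaction_coefs() -> dict:
    return {
        ("roe", "red"): {"(Intercept)": 0.4, "open": -0.6, "roads": 0.4},
        ("roe", "wolf"): {"(Intercept)": 0.3, "forest": -0.3, "buildings": 0.3},
        ("red", "wolf"): {"(Intercept)": 0.5, "buildings": -0.2},
    }


def _default_detection_coefs() -> dict:
    return {
        "roe": {"(Intercept)": -1.4, "visual": 0.4, "trail": -0.35,
                "tri": -0.6, "hunting": -0.15},
        "red": {"(Intercept)": -2.2, "visual": 0.1, "trail": -1.0,
                "tri": 0.2, "hunting": -0.05},
        "wolf": {"(Intercept)": -2.0, "visual": 0.25, "trail": 0.5,
                 "tri": 0.1, "hunting": 0.1},
    }


@dataclass
class SimConfig:
    """Generative world for a synthetic camera-trap study.

    Coefficients are on the standardized-covariate scale (continuous site
    covariates standardized across sites; binary trail/hunting/human left
    as 0/1).  ``interaction_coefs={}`` turns the truth into an
    independence world.
    """

    n_sites: int = 56
    species: tuple = ("roe", "red", "wolf")
    study_start: str = "2021-11-01"
    study_end: str = "2022-04-30"
    deployment: str = "staggered"          # "staggered" or "full"
    mean_trap_days: float = 112.0
    sd_trap_days: float = 38.0
    min_trap_days: int = 14
    trail_categories: tuple = (
        ("forest road", 0.15), ("hiking trail", 0.15),
        ("animal path", 0.20), ("off trail", 0.50),
    )
    human_presence_mean: float = 0.15      # mean of the per-site daily rate
    hunting_weekdays: tuple = (3, 6)       # Thu, Sun (Monday = 0)
    hunting_season_end: str = "2022-01-31"
    occupancy_coefs: dict = field(default_factory=_default_occupancy_coefs)
    interaction_coefs: dict = field(default_factory=_default_interaction_coefs)
    detection_coefs: dict = field(default_factory=_default_detection_coefs)
    simulate_images: bool = True           # fabricate image records at all
    simulate_human_images: bool = True
    events_per_day: float = 1.2            # Poisson mean, floored at 1
    images_per_event: int = 3
    intra_event_gap_s: float = 0.1
    gap_minutes: float = 5.0
    seed: int = 0

    def spec(self, name: str = "truth") -> ModelSpec:
        """The ModelSpec whose coefficient layout matches the truth."""
        def form(coefs: dict) -> str:
            terms = [k for k in coefs if k != "(Intercept)"]
            return "~ " + " + ".join(["1"] + terms)
        return ModelSpec(
            species=self.species,
            occupancy={sp: form(self.occupancy_coefs[sp]) for sp in self.species},
            detection={sp: form(self.detection_coefs[sp]) for sp in self.species},
            interactions={pair: form(c)
                          for pair, c in self.interaction_coefs.items()},
            name=name,
        )

    def theta_true(self) -> np.ndarray:
        """True coefficients packed in the spec's block order."""
        spec = self.spec()
        vals = []
        lookup = {**{(("psi", sp)): self.occupancy_coefs[sp] for sp in self.species},
                  **{(("p", sp)): self.detection_coefs[sp] for sp in self.species}}
        for a, b in self.interaction_coefs:
            lookup[("psi", f"{a}:{b}")] = self.interaction_coefs[(a, b)]
        for kind, label, formula in spec.blocks():
            coefs = lookup[(kind, label)]
            for term in formula.names:
                vals.append(float(coefs[term]))
        return np.array(vals)


@dataclass
class SimOutput:
    """Observable tables plus the generating truth."""

    config: SimConfig
    records: pd.DataFrame
    deployments: pd.DataFrame
    site_covariates_raw: pd.DataFrame
    site_covariates: pd.DataFrame          # standardized continuous columns
    human: pd.DataFrame                    # long: site, date, human 0/1
    hunting: pd.DataFrame                  # long: date, hunting 0/1
    array: DetectionArray                  # directly simulated truth histories
    z: np.ndarray                          # (J, S) latent states
    theta_true: np.ndarray
    spec: ModelSpec

    def model_data(self) -> ModelData:
        """Bundle the truth array and covariates for direct fitting."""
        J, K = self.array.n_sites, self.array.n_occasions
        human = self.human.pivot(index="site", columns="date", values="human") \
            .reindex(self.array.site_ids).to_numpy(dtype=float)
        hunting = self.hunting.set_index("date")["hunting"] \
            .reindex(self.array.occasion_dates).to_numpy(dtype=float)
        return ModelData(
            array=self.array,
            site_covariates=self.site_covariates,
            occasion_covariates={"human": human, "hunting": hunting},
        )

    def write(self, outdir) -> None:
        """Write the CSV dialects the pipeline consumes; truth namespaced."""
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "image_records.csv", index=False)
        self.deployments.to_csv(out / "deployments.csv", index=False)
        self.site_covariates_raw.to_csv(out / "site_covariates.csv")
        self.site_covariates.to_csv(out / "site_covariates_standardized.csv")
        self.human.to_csv(out / "occasion_human.csv", index=False)
        self.hunting.to_csv(out / "occasion_hunting.csv", index=False)
        z = pd.DataFrame(self.z, columns=list(self.spec.species))
        z.insert(0, "site", self.array.site_ids)
        z.to_csv(out / "truth_latent_states.csv", index=False)
        pd.DataFrame({
            "coefficient": self.spec.coef_names(),
            "value": self.theta_true,
        }).to_csv(out / "truth_parameters.csv", index=False)
        self.array.to_long().to_csv(out / "truth_detections.csv", index=False)


def _draw_site_covariates(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    J = cfg.n_sites
    forest = np.clip(rng.normal(65.0, 20.0, J), 5.0, 100.0)
    open_ = np.clip(55.0 - 0.4 * forest + rng.normal(0.0, 12.0, J), 0.0, 100.0)
    tri = rng.gamma(4.0, 2.0, J)
    roads = rng.exponential(400.0, J)
    buildings = rng.exponential(700.0, J)
    visual = rng.uniform(10.0, 100.0, J)
    cats = [c for c, _ in cfg.trail_categories]
    probs = np.array([p for _, p in cfg.trail_categories], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("trail category probabilities must sum to 1")
    trail_cat = rng.choice(cats, size=J, p=probs)
    return pd.DataFrame({
        "forest": forest, "open": open_, "tri": tri, "roads": roads,
        "buildings": buildings, "visual": visual,
        "trail_category": trail_cat,
        "trail": (trail_cat != "off trail").astype(float),
    })


def simulate(config: SimConfig | None = None, **overrides) -> SimOutput:
    """Generate one synthetic dataset from the configured world."""
    cfg = config or SimConfig()
    if overrides:
        cfg = replace(cfg, **overrides)
    rng = np.random.default_rng(cfg.seed)
    J, S = cfg.n_sites, len(cfg.species)
    start = pd.Timestamp(cfg.study_start)
    end = pd.Timestamp(cfg.study_end)
    dates = pd.date_range(start, end, freq="D")
    K = len(dates)
    if cfg.deployment == "staggered" and (cfg.mean_trap_days > K
                                          or cfg.min_trap_days > K):
        raise ValueError(f"trap-day schedule (mean {cfg.mean_trap_days}, "
                         f"min {cfg.min_trap_days}) exceeds the "
                         f"{K}-day study window")

    # deployments: staggered starts, cameras run to the end of the window
    site_ids = [f"S{j + 1:03d}" for j in range(J)]
    camera_ids = [f"CT{j + 1:03d}" for j in range(J)]
    if cfg.deployment == "full":
        td = np.full(J, K)
    elif cfg.deployment == "staggered":
        td = np.clip(np.round(rng.normal(cfg.mean_trap_days, cfg.sd_trap_days, J)),
                     cfg.min_trap_days, K).astype(int)
    else:
        raise ValueError(f"unknown deployment mode {cfg.deployment!r}")
    start_k = K - td
    deployments = pd.DataFrame({
        "camera_id": camera_ids,
        "site_id": site_ids,
        "start_date": dates[start_k].normalize(),
        "end_date": [dates[-1].normalize()] * J,
    })
    deployed = np.zeros((J, K), dtype=bool)
    for j in range(J):
        deployed[j, start_k[j]:] = True

    # covariates
    raw = _draw_site_covariates(cfg, rng)
    raw.index = pd.Index(site_ids, name="site_id")

    hunting_season = (dates <= pd.Timestamp(cfg.hunting_season_end))
    hunting = (np.isin(dates.weekday, cfg.hunting_weekdays) & hunting_season) \
        .astype(float)
    site_rate = rng.beta(1.5, 1.5 * (1.0 - cfg.human_presence_mean)
                         / cfg.human_presence_mean, J)
    human = (rng.random((J, K)) < site_rate[:, None]) & deployed
    human = human.astype(float)

    with np.errstate(invalid="ignore"):
        hum_passage = 100.0 * human.sum(axis=1) / deployed.sum(axis=1)
    raw["hum_passage"] = hum_passage

    std = raw.copy()
    for col in ("forest", "open", "tri", "roads", "buildings", "visual",
                "hum_passage"):
        x = raw[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        # a covariate can degenerate in tiny worlds (e.g. 1-day windows);
        # center it and let the slope coefficient act on a zero column
        std[col] = (x - x.mean()) / sd if sd > 0 else x - x.mean()

    # latent community states from the multivariate Bernoulli
    spec = cfg.spec()
    dummy = DetectionArray(np.zeros((J, 1, S)), site_ids,
                           pd.date_range(start, periods=1), list(cfg.species))
    data0 = ModelData(array=dummy, site_covariates=std,
                      occasion_covariates={"human": np.zeros((J, 1)),
                                           "hunting": np.zeros(1)})
    packed = _Packed(spec, data0)
    theta = cfg.theta_true()
    eta = packed._eta(theta)                              # (2^S, J)
    probs = np.exp(eta - eta.max(axis=0, keepdims=True))
    probs /= probs.sum(axis=0, keepdims=True)
    u = rng.random(J)
    state_idx = (u[None, :] < probs.cumsum(axis=0)).argmax(axis=0)
    z = packed.states[state_idx].astype(int)              # (J, S)

    # daily detections given presence
    det_cov = {
        "visual": np.broadcast_to(std["visual"].to_numpy()[:, None], (J, K)),
        "tri": np.broadcast_to(std["tri"].to_numpy()[:, None], (J, K)),
        "trail": np.broadcast_to(std["trail"].to_numpy()[:, None], (J, K)),
        "hunting": np.broadcast_to(hunting[None, :], (J, K)),
        "human": human,
    }
    Y = np.full((J, K, S), np.nan)
    for s, sp in enumerate(cfg.species):
        coefs = cfg.detection_coefs[sp]
        lin = np.full((J, K), coefs.get("(Intercept)", 0.0))
        for term, val in coefs.items():
            if term == "(Intercept)":
                continue
            lin = lin + val * det_cov[term]
        p = expit(lin)
        y = (rng.random((J, K)) < p) & (z[:, s] == 1)[:, None] & deployed
        Y[:, :, s] = np.where(deployed, y.astype(float), np.nan)

    array = DetectionArray(Y, site_ids, dates, list(cfg.species))

    # fabricate image records per detected site-day
    if cfg.simulate_images:
        records = _fabricate_records(cfg, rng, array, camera_ids, human, dates)
    else:
        records = pd.DataFrame(columns=["camera_id", "timestamp", "species",
                                        "n_individuals"])

    human_long = pd.DataFrame({
        "site": np.repeat(site_ids, K),
        "date": np.tile(dates, J),
        "human": human.ravel(),
    })
    hunting_long = pd.DataFrame({"date": dates, "hunting": hunting})

    return SimOutput(
        config=cfg, records=records, deployments=deployments,
        site_covariates_raw=raw, site_covariates=std,
        human=human_long, hunting=hunting_long,
        array=array, z=z, theta_true=theta, spec=spec,
    )


def _fabricate_records(cfg, rng, array, camera_ids, human, dates):
    """Image records per detected site-day, spaced so that the event-grouping
    rule recovers them exactly: event starts sit on a minute grid coarser than
    the gap threshold, and the photo burst inside an event spans well under it.
    """
    slot_min = int(np.ceil(cfg.gap_minutes)) + 1
    n_slots = (24 * 60 - slot_min) // slot_min            # keep bursts inside the day
    rows = []
    J, K, S = array.values.shape
    for j in range(J):
        cam = camera_ids[j]
        for s, sp in enumerate(array.species_ids):
            days = np.nonzero(array.values[j, :, s] == 1.0)[0]
            for k in days:
                n_ev = max(1, int(rng.poisson(cfg.events_per_day)))
                n_ev = min(n_ev, n_slots)
                slots = rng.choice(n_slots, size=n_ev, replace=False)
                slots.sort()
                for slot in slots:
                    t0 = dates[k] + pd.Timedelta(minutes=int(slot) * slot_min)
                    for m in range(cfg.images_per_event):
                        rows.append((cam, t0 + pd.Timedelta(
                            seconds=m * cfg.intra_event_gap_s), sp, 1))
        if cfg.simulate_human_images:
            for k in np.nonzero(human[j] > 0)[0]:
                slot = int(rng.integers(n_slots))
                t0 = dates[k] + pd.Timedelta(minutes=slot * slot_min)
                rows.append((cam, t0, "human", 1))
    records = pd.DataFrame(rows, columns=["camera_id", "timestamp", "species",
                                          "n_individuals"])
    return records.sort_values(["camera_id", "species", "timestamp"],
                               kind="mergesort").reset_index(drop=True)


def roundtrip_score(
    theta_true: np.ndarray,
    fits: "list[FitResult]",
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-coefficient recovery report across replicate fits.

    Columns: true value, mean estimate, bias, RMSE, and Wald CI coverage at
    the requested level.  An empty fit list yields an empty report.
    """
    if not fits:
        return pd.DataFrame(columns=["coefficient", "true", "mean_estimate",
                                     "bias", "rmse", "coverage", "n"])
    names = fits[0].coef_names
    theta_true = np.asarray(theta_true, dtype=float)
    if theta_true.size != len(names):
        raise ValueError(f"truth has {theta_true.size} coefficients, fits "
                         f"have {len(names)}")
    for f in fits:
        if f.coef_names != names:
            raise ValueError("fits have mismatched coefficient layouts")
    est = np.stack([f.theta for f in fits])               # (R, P)
    se = np.stack([f.se for f in fits])
    zq = norm.ppf(0.5 + level / 2.0)
    with np.errstate(invalid="ignore"):
        covered = np.abs(est - theta_true[None, :]) <= zq * se
        coverage = np.nanmean(np.where(np.isfinite(se), covered, np.nan), axis=0)
    return pd.DataFrame({
        "coefficient": names,
        "true": theta_true,
        "mean_estimate": est.mean(axis=0),
        "bias": est.mean(axis=0) - theta_true,
        "rmse": np.sqrt(((est - theta_true[None, :]) ** 2).mean(axis=0)),
        "coverage": coverage,
        "n": len(fits),
    })
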