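"""From classified camera-trap images to independent events and daily histories.

The input currency is pandas DataFrames with documented columns:

* image records -- one row per classified photo:
  ``camera_id``, ``timestamp`` (datetime, second or finer resolution),
  ``species``, ``n_individuals``.  Multi-species photos are assumed to have
  been duplicated upstream, one row per species.
* deployments -- one row per camera/site (one deployment per site):
  ``camera_id``, ``site_id``, ``start_date``, ``end_date``.  The interval is
  closed on both ends, so ``trap_days = end_date - start_date + 1``.
* events -- output of :func:`group_events`:
  ``camera_id``, ``species``, ``start_time``, ``end_time``, ``n_images``.

Consecutive photos of the same species at the same camera are collapsed into
one independent event whenever each photo follows its predecessor by less
than the gap threshold (5 minutes by default).  Daily detection histories are
binary site x day x species arrays on a calendar-aligned study window; days
outside a site's deployment are missing (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DetectionArray",
    "group_events",
    "capture_rate",
    "naive_occupancy",
    "build_detection_array",
    "trap_days",
    "summary_table",
]

RECORD_COLUMNS = ("camera_id", "timestamp", "species")
EVENT_COLUMNS = ("camera_id", "species", "start_time", "end_time", "n_images")


@dataclass
class DetectionArray:
    """Daily detection histories: sites x occasions x species in {0, 1, NaN}.

    ``values[j, k, s]`` is 1 if species ``s`` produced at least one event at
    site ``j`` on calendar day ``k``, 0 if the site was deployed that day with
    no event, and NaN if the site was not deployed (missing occasion).
    Occasion dates are globally aligned calendar days.
    """

    values: np.ndarray
    site_ids: list
    occasion_dates: pd.DatetimeIndex
    species_ids: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.site_ids), len(self.occasion_dates), len(self.species_ids))
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.values.shape[1]

    @property
    def n_species(self) -> int:
        return self.values.shape[2]

    def species_index(self, species: str) -> int:
        try:
            return self.species_ids.index(species)
        except ValueError:
            raise KeyError(f"species {species!r} not in array "
                           f"(have {self.species_ids})") from None

    def non_missing_site_days(self) -> int:
        """Total deployed site-days (identical across species by construction)."""
        return int(np.isfinite(self.values[:, :, 0]).sum())

    def to_long(self) -> pd.DataFrame:
        """Long-format export: columns site, date, species, value (NA = missing)."""
        j, k, s = np.meshgrid(
            np.arange(self.n_sites), np.arange(self.n_occasions),
            np.arange(self.n_species), indexing="ij",
        )
        return pd.DataFrame({
            "site": np.asarray(self.site_ids, dtype=object)[j.ravel()],
            "date": self.occasion_dates[k.ravel()],
            "species": np.asarray(self.species_ids, dtype=object)[s.ravel()],
            "value": self.values.ravel(),
        })


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"image records missing columns: {missing}")
    out = records.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"])
    return out


def group_events(records: pd.DataFrame, gap_minutes: float = 5.0) -> pd.DataFrame:
    """Collapse ordered image records into independent detection events.

    Within each (camera, species) stream, a record opens a new event iff its
    timestamp is at least ``gap_minutes`` after the previous record; closer
    records extend the current event (the gap is measured from the previous
    image, not from the event's first image, so a animal lingering in the
    field of view keeps one event alive indefinitely).

    Parameters
    ----------
    records : DataFrame
        Image records sorted by (camera_id, species, timestamp).  Unsorted
        input is rejected rather than silently re-sorted.
    gap_minutes : float
        Independence threshold in minutes; must be positive.

    Returns
    -------
    DataFrame with columns camera_id, species, start_time, end_time, n_images.
    """
    if gap_minutes <= 0:
        raise ValueError(f"gap_minutes must be positive, got {gap_minutes}")
    records = _check_records(records)
    if records.empty:
        return pd.DataFrame(columns=list(EVENT_COLUMNS))

    grouped = records.groupby(["camera_id", "species"], sort=False, observed=True)
    if (grouped["timestamp"].diff().dropna() < pd.Timedelta(0)).any():
        raise ValueError("image records are not sorted by timestamp within "
                         "(camera_id, species); sort the input first")

    gap = pd.Timedelta(minutes=gap_minutes)
    delta = grouped["timestamp"].diff()
    new_event = delta.isna() | (delta >= gap)
    event_id = new_event.cumsum()

    events = (
        records.assign(_event=event_id)
        .groupby("_event", sort=True)
        .agg(
            camera_id=("camera_id", "first"),
            species=("species", "first"),
            start_time=("timestamp", "first"),
            end_time=("timestamp", "last"),
            n_images=("timestamp", "size"),
        )
        .reset_index(drop=True)
    )
    return events


def capture_rate(n_events: int, trap_days: int) -> float:
    """Independent events per 100 trap days (relative activity index)."""
    if trap_days <= 0:
        raise ValueError(f"trap_days must be positive, got {trap_days}")
    return n_events / trap_days * 100.0


def naive_occupancy(array: DetectionArray, species: str) -> float:
    """Proportion of surveyed sites where the species was detected at least once.

    Uncorrected for imperfect detection: the denominator is the number of
    sites with at least one non-missing occasion.
    """
    s = array.species_index(species)
    vals = array.values[:, :, s]
    surveyed = np.isfinite(vals).any(axis=1)
    if not surveyed.any():
        raise ValueError("no site has a non-missing occasion")
    detected = np.nansum(vals, axis=1) > 0
    return float(detected.sum() / surveyed.sum())


def trap_days(deployments: pd.DataFrame) -> pd.Series:
    """Trap days per deployment row; both first and last day count."""
    start = pd.to_datetime(deployments["start_date"])
    end = pd.to_datetime(deployments["end_date"])
    if (end < start).any():
        bad = deployments.loc[end < start, "camera_id"].tolist()
        raise ValueError(f"deployment end before start for cameras: {bad}")
    days = (end - start).dt.days + 1
    return pd.Series(days.to_numpy(), index=deployments.index, name="trap_days")


def build_detection_array(
    events: pd.DataFrame,
    deployments: pd.DataFrame,
    species_set: "list[str]",
    study_start=None,
    study_end=None,
) -> DetectionArray:
    """Build the calendar-day detection/non-detection array from events.

    Occasions are calendar days on a global study window (default: the span
    of all deployments).  Events spanning midnight count toward the day of
    each contributing image's start; here the event start day is used for the
    event as a whole, with multi-day events contributing to every day they
    overlap via their start/end range.

    Raises if any event falls outside its camera's deployment window, listing
    the offending events.
    """
    dep = deployments.copy()
    dep["start_date"] = pd.to_datetime(dep["start_date"]).dt.normalize()
    dep["end_date"] = pd.to_datetime(dep["end_date"]).dt.normalize()
    if dep["camera_id"].duplicated().any():
        raise ValueError("multiple deployments per camera are not supported")

    start = pd.to_datetime(study_start).normalize() if study_start is not None \
        else dep["start_date"].min()
    end = pd.to_datetime(study_end).normalize() if study_end is not None \
        else dep["end_date"].max()
    dates = pd.date_range(start, end, freq="D")

    site_of_camera = dict(zip(dep["camera_id"], dep["site_id"]))
    site_ids = list(dep["site_id"])
    site_pos = {s: i for i, s in enumerate(site_ids)}
    species_ids = list(species_set)
    sp_pos = {s: i for i, s in enumerate(species_ids)}

    values = np.full((len(site_ids), len(dates), len(species_ids)), np.nan)
    day0 = dates[0]
    dep_start_k = ((dep["start_date"] - day0).dt.days).to_numpy()
    dep_end_k = ((dep["end_date"] - day0).dt.days).to_numpy()
    for j, (k0, k1) in enumerate(zip(dep_start_k, dep_end_k)):
        lo, hi = max(k0, 0), min(k1, len(dates) - 1)
        if lo <= hi:
            values[j, lo:hi + 1, :] = 0.0

    if not events.empty:
        ev = events.copy()
        ev["start_day"] = pd.to_datetime(ev["start_time"]).dt.normalize()
        ev["end_day"] = pd.to_datetime(ev["end_time"]).dt.normalize()
        bounds = dep.set_index("camera_id")[["start_date", "end_date"]]
        ev = ev.join(bounds, on="camera_id")
        outside = (
            ev["start_date"].isna()
            | (ev["start_day"] < ev["start_date"])
            | (ev["end_day"] > ev["end_date"])
        )
        if outside.any():
            bad = ev.loc[outside, ["camera_id", "species", "start_time", "end_time"]]
            raise ValueError(
                "events outside their camera's deployment window:\n"
                + bad.to_string(index=False)
            )
        for row in ev.itertuples(index=False):
            sp = sp_pos.get(row.species)
            if sp is None:
                continue
            j = site_pos[site_of_camera[row.camera_id]]
            k_lo = (row.start_day - day0).days
            k_hi = (row.end_day - day0).days
            for k in range(max(k_lo, 0), min(k_hi, len(dates) - 1) + 1):
                values[j, k, sp] = 1.0

    return DetectionArray(values, site_ids, dates, species_ids)


def summary_table(
    events: pd.DataFrame,
    deployments: pd.DataFrame,
    array: DetectionArray,
) -> pd.DataFrame:
    """Per-species events, capture rate and naive occupancy (activity summary)."""
    total_days = int(trap_days(deployments).sum())
    counts = events.groupby("species").size() if not events.empty else pd.Series(dtype=int)
    rows = []
    for sp in array.species_ids:
        n = int(counts.get(sp, 0))
        rows.append({
            "species": sp,
            "events": n,
            "capture_rate": capture_rate(n, total_days),
            "naive_occupancy": naive_occupancy(array, sp),
        })
    return pd.DataFrame(rows).sort_values("events", ascending=False).reset_index(drop=True)
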