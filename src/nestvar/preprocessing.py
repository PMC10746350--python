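"""Event-log -> analysis-ready IVI table.

Construction and exclusion rules:

* an IVI is the minutes between the start times of consecutive provisioning
  visits within a nest; any interval whose left or right endpoint row is a
  camera ``fail`` is dropped;
* the interval's nestling age is the age (days since hatch of the
  first-hatched nestling) at its *start* visit; day-0 intervals and ages
  beyond 12 days are dropped;
* in years whose cameras had no time-lapse backstop, intervals above
  4000 min are biologically impossible and are removed (the outlier rule);
* covariates are transformed for modelling: nestling age is left-zeroed
  (day 1 -> 0) and SD-scaled, brood size is centered and SD-scaled.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import MAX_IVI_MINUTES, MAX_NESTLING_AGE

__all__ = ["compute_ivis", "apply_outlier_rule", "build_model_frame", "ModelFrame"]

logger = logging.getLogger(__name__)

IVI_COLUMNS = [
    "pair_id",
    "site_id",
    "year",
    "nestling_age_days",
    "brood_size",
    "ivi_minutes",
    "log_ivi",
]


def compute_ivis(events: pd.DataFrame, exclude_nests: set[str] | None = None) -> pd.DataFrame:
    """Build IVI records from a time-stamped event log.

    Parameters
    ----------
    events
        Columns ``nest_id, site_id, year, timestamp, status, brood_size,
        hatch_date``; timestamps strictly increasing within each nest.
    exclude_nests
        Nest ids to drop wholesale (e.g. food-supplemented nests).

    Returns
    -------
    DataFrame of IVI records; ``.attrs["drop_counts"]`` holds the number of
    intervals dropped by each rule (``fail``, ``day0``, ``age_gt_12``) so
    that exclusion accounting is conserved.
    """
    ev = events.copy()
    ev["timestamp"] = pd.to_datetime(ev["timestamp"])
    ev["hatch_date"] = pd.to_datetime(ev["hatch_date"]).dt.date
    if exclude_nests:
        ev = ev[~ev["nest_id"].isin(exclude_nests)]

    rows = []
    drops = {"fail": 0, "day0": 0, "age_gt_12": 0}
    for nest, sub in ev.groupby("nest_id", sort=True):
        sub = sub.sort_index()  # preserve given order; verify monotone below
        ts = sub["timestamp"].to_numpy()
        if len(ts) > 1 and not (np.diff(ts) > np.timedelta64(0, "s")).all():
            raise ValueError(f"timestamps are not strictly increasing within nest {nest!r}")
        hatch = sub["hatch_date"].iloc[0]
        if pd.isna(hatch):
            logger.warning("nest %r has no hatch date; skipping its records", nest)
            continue
        status = sub["status"].to_numpy()
        left, right = status[:-1], status[1:]
        t_left, t_right = ts[:-1], ts[1:]
        site = sub["site_id"].iloc[0]
        year = int(sub["year"].iloc[0])
        brood = int(sub["brood_size"].iloc[0])
        hatch64 = np.datetime64(hatch)
        for i in range(len(left)):
            if left[i] != "visit" or right[i] != "visit":
                drops["fail"] += 1
                continue
            age = int((t_left[i] - hatch64) / np.timedelta64(1, "D"))
            if age == 0:
                drops["day0"] += 1
                continue
            if age > MAX_NESTLING_AGE:
                drops["age_gt_12"] += 1
                continue
            ivi = (t_right[i] - t_left[i]) / np.timedelta64(1, "m")
            rows.append((f"s{site:02d}-{year}", site, year, age, brood, float(ivi)))

    out = pd.DataFrame(rows, columns=IVI_COLUMNS[:-1])
    out["log_ivi"] = np.log(out["ivi_minutes"])
    out.attrs["drop_counts"] = drops
    return out


def apply_outlier_rule(
    records: pd.DataFrame, timelapse_years: set[int]
) -> tuple[pd.DataFrame, int]:
    """Remove impossible IVIs (> 4000 min) from years without time-lapse.

    Years with a time-lapse setting already expose camera failures as
    ``fail`` rows, so their long intervals are genuine and retained.
    Returns the filtered records and the removal count.
    """
    bad = (records["ivi_minutes"] > MAX_IVI_MINUTES) & ~records["year"].isin(
        list(timelapse_years)
    )
    n_removed = int(bad.sum())
    out = records[~bad].reset_index(drop=True)
    out.attrs["drop_counts"] = {**records.attrs.get("drop_counts", {}), "outlier": n_removed}
    logger.info("outlier rule removed %d record(s)", n_removed)
    return out, n_removed


@dataclass
class ModelFrame:
    """Analysis-ready response, standardized covariates and grouping labels.

    ``age_s`` is left-zeroed nestling age divided by its sample SD (day 1
    maps to exactly 0); ``brood_s`` is brood size centered at its mean and
    divided by its sample SD.  The scaling constants are stored so effects
    can be mapped back to days/nestlings.
    """

    log_ivi: np.ndarray
    age_s: np.ndarray
    brood_s: np.ndarray
    year: np.ndarray  # integer codes
    site: np.ndarray
    pair: np.ndarray
    year_labels: list
    site_labels: list
    pair_labels: list
    scaling: dict[str, float] = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return len(self.log_ivi)

    def unscale_age(self, age_s: np.ndarray) -> np.ndarray:
        """Map standardized age back to nestling age in days."""
        return age_s * self.scaling["age_sd"] + 1.0

    def unscale_brood(self, brood_s: np.ndarray) -> np.ndarray:
        return brood_s * self.scaling["brood_sd"] + self.scaling["brood_mean"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "log_ivi": self.log_ivi,
                "age_s": self.age_s,
                "brood_s": self.brood_s,
                "year": [self.year_labels[i] for i in self.year],
                "site": [self.site_labels[i] for i in self.site],
                "pair": [self.pair_labels[i] for i in self.pair],
            }
        )

    def save(self, csv_path) -> None:
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False)
        csv_path.with_suffix(".scaling.json").write_text(json.dumps(self.scaling, indent=2))

    @classmethod
    def load(cls, csv_path) -> "ModelFrame":
        csv_path = Path(csv_path)
        df = pd.read_csv(csv_path)
        scaling = json.loads(csv_path.with_suffix(".scaling.json").read_text())
        codes = {}
        labels = {}
        for col in ("year", "site", "pair"):
            cat = pd.Categorical(df[col])
            codes[col] = np.asarray(cat.codes)
            labels[col] = list(cat.categories)
        return cls(
            log_ivi=df["log_ivi"].to_numpy(float),
            age_s=df["age_s"].to_numpy(float),
            brood_s=df["brood_s"].to_numpy(float),
            year=codes["year"],
            site=codes["site"],
            pair=codes["pair"],
            year_labels=labels["year"],
            site_labels=labels["site"],
            pair_labels=labels["pair"],
            scaling=scaling,
        )


def build_model_frame(records: pd.DataFrame, ddof: int = 1) -> ModelFrame:
    """Standardize covariates and encode grouping factors for model fitting.

    Transformations, in order: ``age' = age - 1`` (left-zeroing, so the
    intercept sits at the first analyzed day), ``age_s = age'/SD(age')``,
    ``brood_s = (brood - mean)/SD(brood)``.  SDs are sample SDs (``ddof=1``)
    computed on the post-exclusion table.
    """
    age = records["nestling_age_days"].to_numpy(float) - 1.0
    brood = records["brood_size"].to_numpy(float)
    if records["nestling_age_days"].nunique() < 2 or records["brood_size"].nunique() < 2:
        raise ValueError("need >= 2 distinct nestling ages and brood sizes (zero-SD covariate)")
    age_sd = float(np.std(age, ddof=ddof))
    brood_mean = float(brood.mean())
    brood_sd = float(np.std(brood, ddof=ddof))

    def codes(col):
        cat = pd.Categorical(records[col])
        return np.asarray(cat.codes), list(cat.categories)

    year_c, year_l = codes("year")
    site_c, site_l = codes("site_id")
    pair_c, pair_l = codes("pair_id")
    return ModelFrame(
        log_ivi=records["log_ivi"].to_numpy(float),
        age_s=age / age_sd,
        brood_s=(brood - brood_mean) / brood_sd,
        year=year_c,
        site=site_c,
        pair=pair_c,
        year_labels=year_l,
        site_labels=site_l,
        pair_labels=pair_l,
        scaling={"age_sd": age_sd, "brood_mean": brood_mean, "brood_sd": brood_sd},
    )
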