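"""Synthetic provisioning data with the statistical structure the analysis assumes.

The generator emulates a multi-year nest-camera study of Arctic peregrine
falcons: each active nest (a site x year "pair") is watched over nestling
ages 1-12 days, and the response is the inter-visit interval (IVI, minutes)
between consecutive prey deliveries.  Log IVIs are drawn from a normal
location-scale model in which both the mean and the log residual SD are
linear in standardized nestling age and centered/standardized brood size,
with site and pair random intercepts and correlated year-level effects on
the intercept, the age slope and the log residual SD.

Every dataset is returned together with the :class:`GeneratorTruth` actually
used (including realized year effects and the covariate scaling constants),
so that simulate-and-refit experiments can score parameter recovery.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "StudyDesign",
    "GeneratorTruth",
    "draw_year_effects",
    "generate_ivi_table",
    "generate_event_log",
]

MINUTES_PER_DAY = 1440.0
MAX_NESTLING_AGE = 12
MAX_IVI_MINUTES = 4000.0  # biological plausibility cutoff applied downstream


# ---------------------------------------------------------------------------
# study design and generating truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyDesign:
    """Shape of the study: years, sites, occupancy, broods, observed ages.

    ``mean_visits_per_day`` caps the number of intervals a nest-day can
    contribute (the expected count of a Poisson draw); together with the
    24-h day boundary it bounds simulation length and sets the realized
    dataset size (~5,000 records at the defaults).
    """

    n_years: int = 7
    n_sites: int = 51
    occupancy: float = 99.0 / (7 * 51)
    brood_size_support: dict[int, float] = field(
        default_factory=lambda: {1: 0.10, 2: 0.25, 3: 0.40, 4: 0.25}
    )
    age_range: tuple[int, int] = (1, 12)
    mean_visits_per_day: float = 4.5
    first_year: int = 2013

    def __post_init__(self) -> None:
        lo, hi = self.age_range
        if not (1 <= lo <= hi <= MAX_NESTLING_AGE):
            raise ValueError(f"age_range must lie within [1, {MAX_NESTLING_AGE}]")
        if not set(self.brood_size_support) <= {1, 2, 3, 4}:
            raise ValueError("brood sizes must be in {1, 2, 3, 4}")
        probs = np.array(list(self.brood_size_support.values()), dtype=float)
        if probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
            raise ValueError("brood_size_support probabilities must sum to 1")
        if self.mean_visits_per_day <= 0:
            raise ValueError("mean_visits_per_day must be positive")

    @property
    def years(self) -> list[int]:
        return [self.first_year + k for k in range(self.n_years)]

    @property
    def ages(self) -> np.ndarray:
        lo, hi = self.age_range
        return np.arange(lo, hi + 1)

    # Design-wide covariate moments; the generator standardizes with these so
    # that the generating coefficients live on the same per-SD scale the
    # analysis uses.
    @property
    def age_sd(self) -> float:
        # population SD of the uniform age distribution: what the sample SD of
        # a large balanced analysis table converges to
        a = self.ages - 1.0  # left-zeroed
        return float(np.std(a))

    @property
    def brood_mean(self) -> float:
        ks = np.array(list(self.brood_size_support), dtype=float)
        ps = np.array(list(self.brood_size_support.values()))
        return float(ks @ ps)

    @property
    def brood_sd(self) -> float:
        ks = np.array(list(self.brood_size_support), dtype=float)
        ps = np.array(list(self.brood_size_support.values()))
        m = ks @ ps
        return float(np.sqrt(ps @ (ks - m) ** 2))


def _check_corr(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (3, 3) or not np.allclose(corr, corr.T):
        raise ValueError(f"corr_year must be a symmetric 3x3 matrix, got\n{corr}")
    if not np.allclose(np.diag(corr), 1.0):
        raise ValueError(f"corr_year must have unit diagonal, got\n{corr}")
    eig = np.linalg.eigvalsh(corr)
    if eig.min() < -1e-10:
        raise ValueError(
            f"corr_year is not positive semi-definite (eigenvalues {eig}):\n{corr}"
        )
    return corr


@dataclass
class GeneratorTruth:
    """Generating parameters recorded alongside every synthetic dataset.

    ``beta_mu``/``beta_sigma`` are (intercept, age effect, brood effect) on
    the natural-log-minute and log-SD scales; covariates are standardized so
    the slopes are per covariate SD.  Year effects are per-year triples
    (mean-intercept deviation u0, age-slope deviation u1, log-sigma
    deviation v): either supplied via ``year_effects`` or drawn from the
    covariance implied by ``sd_year`` and ``corr_year``.
    """

    beta_mu: tuple[float, float, float] = (5.40, -0.18, -0.12)
    beta_sigma: tuple[float, float, float] = (float(np.log(0.72)), 0.08, -0.01)
    sd_site: float = 0.14
    sd_pair: float = 0.19
    sd_year: tuple[float, float, float] = (0.10, 0.12, 0.12)
    corr_year: np.ndarray = field(default_factory=lambda: np.eye(3))
    year_effects: np.ndarray | None = None  # (n_years, 3) when fixed by the user
    year_effects_fixed: bool = False
    failure_rate: float = 0.003
    outlier_rate: float = 0.0005
    outlier_min_minutes: float = 4200.0
    seed: int = 0
    scaling: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.corr_year = _check_corr(self.corr_year)
        if min(self.sd_site, self.sd_pair, *self.sd_year) < 0:
            raise ValueError("random-effect SDs must be non-negative")
        if not (0.0 <= self.failure_rate <= 0.005):
            raise ValueError("failure_rate must lie in [0, 0.005] (<0.5% error rate)")
        if self.outlier_min_minutes <= MAX_IVI_MINUTES:
            raise ValueError("outlier_min_minutes must exceed 4000 min")
        if self.year_effects is not None:
            self.year_effects = np.asarray(self.year_effects, dtype=float)
            if self.year_effects.ndim != 2 or self.year_effects.shape[1] != 3:
                raise ValueError("year_effects must have shape (n_years, 3)")
            self.year_effects_fixed = True

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorTruth":
        d = json.loads(text)
        scaling = d.pop("scaling", {})
        fixed = d.pop("year_effects_fixed", False)
        if d.get("corr_year") is not None:
            d["corr_year"] = np.asarray(d["corr_year"])
        if d.get("year_effects") is not None:
            d["year_effects"] = np.asarray(d["year_effects"])
        for k in ("beta_mu", "beta_sigma", "sd_year"):
            d[k] = tuple(d[k])
        out = cls(**d)
        out.scaling = scaling
        out.year_effects_fixed = fixed or out.year_effects is not None
        return out


def draw_year_effects(truth: GeneratorTruth, n_years: int, rng: np.random.Generator) -> np.ndarray:
    """Draw per-year (u0, u1, v) triples from the truth's year covariance."""
    sd = np.asarray(truth.sd_year, dtype=float)
    cov = truth.corr_year * np.outer(sd, sd)
    # eigen-decomposition handles semi-definite corr (e.g. a zero SD)
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    root = v @ np.diag(np.sqrt(w))
    z = rng.standard_normal((n_years, 3))
    return z @ root.T


# ---------------------------------------------------------------------------
# IVI table generation
# ---------------------------------------------------------------------------

def _active_pairs(design: StudyDesign, rng: np.random.Generator) -> list[tuple[int, int]]:
    """(year, site) combinations active in the study, by Bernoulli occupancy."""
    pairs = []
    for year in design.years:
        active = rng.random(design.n_sites) < design.occupancy
        pairs.extend((year, s) for s in np.flatnonzero(active))
    return pairs


def _simulate_streams(design: StudyDesign, truth: GeneratorTruth):
    """Continuous per-nest renewal streams plus the realized truth.

    Each interval is drawn from the log-normal of the day on which it starts
    (days 0 through the last analyzed age), so an interval spanning midnight
    carries its start day's parameters — exactly what the fitted likelihood
    and the preprocessing rules assume.  Intervals are recorded while a
    per-day Poisson(``mean_visits_per_day``) cap allows; the cap is drawn
    independently of the interval values, so recorded intervals remain an
    unbiased i.i.d. sample.  Only the single stream-terminating interval per
    nest is discarded.  Interval lengths are whole minutes (>= 1): event
    timestamps have minute resolution.
    """
    rng = np.random.default_rng(truth.seed)
    pairs = _active_pairs(design, rng)
    years = design.years
    year_index = {y: i for i, y in enumerate(years)}

    if truth.year_effects is not None:
        ye = np.asarray(truth.year_effects, dtype=float)
        if ye.shape[0] != design.n_years:
            raise ValueError(
                f"year_effects has {ye.shape[0]} rows but design has {design.n_years} years"
            )
        rng.standard_normal((design.n_years, 3))  # keep the stream aligned
    else:
        ye = draw_year_effects(truth, design.n_years, rng)

    site_eff = truth.sd_site * rng.standard_normal(design.n_sites)
    pair_eff = truth.sd_pair * rng.standard_normal(len(pairs))

    brood_sizes = np.array(list(design.brood_size_support))
    brood_probs = np.array(list(design.brood_size_support.values()))
    age_sd, brood_mean, brood_sd = design.age_sd, design.brood_mean, design.brood_sd
    lo, hi = design.age_range

    b0, b_age, b_brood = truth.beta_mu
    g0, g_age, g_brood = truth.beta_sigma
    streams = []
    for p_idx, (year, site) in enumerate(pairs):
        brood = int(rng.choice(brood_sizes, p=brood_probs))
        brood_s = (brood - brood_mean) / brood_sd
        u0, u1, v = ye[year_index[year]]
        base = b0 + b_brood * brood_s + site_eff[site] + pair_eff[p_idx] + u0
        days = np.arange(0, hi + 1)
        age_s = (np.clip(days, lo, hi) - 1.0) / age_sd
        mu_day = base + (b_age + u1) * age_s
        sig_day = np.exp(g0 + g_age * age_s + g_brood * brood_s + v)
        caps = rng.poisson(design.mean_visits_per_day, size=hi + 1)

        t = 0.0
        counts = np.zeros(hi + 1, dtype=int)
        intervals = []  # (day, start_minute, length, kept)
        while True:
            day = int(t // MINUTES_PER_DAY)
            if day > hi:
                break
            x = max(1.0, np.round(np.exp(mu_day[day] + sig_day[day] * rng.standard_normal())))
            kept = day == 0 or counts[day] < caps[day]  # day 0 is plumbing only
            counts[day] += 1
            intervals.append((day, t, x, kept))
            t += x
        streams.append(
            {"pair": f"s{site:02d}-{year}", "site": site, "year": year, "brood": brood,
             "intervals": intervals}
        )

    realized = dataclasses.replace(truth, year_effects=ye.copy(), corr_year=truth.corr_year.copy())
    realized.year_effects_fixed = truth.year_effects_fixed
    realized.scaling = {"age_sd": age_sd, "brood_mean": brood_mean, "brood_sd": brood_sd}
    return streams, realized


def generate_ivi_table(
    design: StudyDesign, truth: GeneratorTruth
) -> tuple[pd.DataFrame, GeneratorTruth]:
    """Simulate an analysis-ready IVI table plus the realized truth.

    Log IVIs are i.i.d. Normal given the linear predictors: log-mean
    ``mu = beta_mu . x + site + pair + u0_year + u1_year * age_s`` and log-SD
    ``sigma = exp(beta_sigma . x + v_year)`` with ``x = (1, age_s, brood_s)``
    standardized by the design-wide covariate SDs (reported in the returned
    truth).  Records per nest-day follow the renewal stream described in
    :func:`_simulate_streams`: however many the day holds, capped by a
    Poisson(``mean_visits_per_day``) draw.
    """
    streams, realized = _simulate_streams(design, truth)
    lo, hi = design.age_range
    rows = [
        (s["pair"], s["site"], s["year"], day, s["brood"], float(x))
        for s in streams
        for (day, start, x, kept) in s["intervals"]
        if kept and lo <= day <= hi
    ]
    table = pd.DataFrame(
        rows,
        columns=["pair_id", "site_id", "year", "nestling_age_days", "brood_size", "ivi_minutes"],
    )
    table["log_ivi"] = np.log(table["ivi_minutes"])
    return table, realized


# ---------------------------------------------------------------------------
# event-log generation
# ---------------------------------------------------------------------------

def generate_event_log(design: StudyDesign, truth: GeneratorTruth) -> pd.DataFrame:
    """Emit a time-stamped provisioning event log realizing the IVI table.

    Visits start at a per-nest hatch datetime (uniform over the first two
    weeks of July) and include day-0 visits that preprocessing must drop.
    Whenever the per-day cap leaves a span of the stream unrecorded, one
    camera-off ``fail`` row is written inside the gap, so preprocessing
    drops exactly the unrecorded intervals and the round trip is exact.
    Random camera failures are injected at ``truth.failure_rate`` per
    recorded interval, and biologically impossible gaps
    (> ``outlier_min_minutes``) at ``truth.outlier_rate`` per nest-day.
    """
    streams, realized = _simulate_streams(design, truth)
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed & 0x7FFFFFFF, 9151]))
    lo, hi = design.age_range

    events: list[tuple] = []
    for s in sorted(streams, key=lambda s: s["pair"]):
        pair_id, site, year, brood = s["pair"], s["site"], s["year"], s["brood"]
        hatch = date(int(year), 7, int(rng.integers(1, 15)))
        hatch_dt = datetime.combine(hatch, datetime.min.time())

        def emit(minute_offset: float, status: str) -> None:
            ts = hatch_dt + timedelta(minutes=float(minute_offset))
            events.append((pair_id, site, year, ts, status, brood, hatch))

        kept = [(d, t0, x) for (d, t0, x, k) in s["intervals"] if k]

        # outlier injection: a too-long gap replacing a day's recorded activity
        outlier_days = {d for d in range(lo, hi + 1) if rng.random() < truth.outlier_rate}
        for d in sorted(outlier_days):
            day_ivs = [iv for iv in kept if iv[0] == d]
            if not day_ivs:
                continue
            start = day_ivs[0][1]
            gap = float(np.round(truth.outlier_min_minutes + rng.exponential(400.0)))
            kept = [iv for iv in kept if iv[1] + iv[2] <= start or iv[1] >= start + gap]
            kept.append((d, start, gap))
            kept.sort(key=lambda iv: iv[1])

        # contiguous runs of recorded intervals; one fail row inside each gap
        prev_end = None
        for day, t0, x in kept:
            if prev_end is None:
                emit(t0, "visit")
            elif t0 > prev_end:
                emit(prev_end + (t0 - prev_end) * rng.uniform(0.05, 0.95), "fail")
                emit(t0, "visit")
            if rng.random() < truth.failure_rate:
                emit(t0 + x * rng.uniform(0.05, 0.95), "fail")
            emit(t0 + x, "visit")
            prev_end = t0 + x

    log = pd.DataFrame(
        events,
        columns=["nest_id", "site_id", "year", "timestamp", "status", "brood_size", "hatch_date"],
    )
    log = log.sort_values(["nest_id", "timestamp"], kind="stable").reset_index(drop=True)
    log.attrs["truth"] = realized
    return log


def write_dataset(outdir, design: StudyDesign, truth: GeneratorTruth) -> None:
    """Write event log CSV, IVI table CSV and the truth JSON side by side."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, realized = generate_ivi_table(design, truth)
    log = generate_event_log(design, truth)
    table.to_csv(outdir / "ivi_table.csv", index=False)
    log.to_csv(outdir / "event_log.csv", index=False)
    (outdir / "truth.json").write_text(realized.to_json())
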