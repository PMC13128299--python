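"""Respiration-rate pathway to daily field metabolic rate (FMR).

Post-dive surfacings are split into three behavioural periods with distinct
respiratory physiology:

* period 1 — initial 80% of a post-dive surfacing (<=9 min): rapid recovery
  breathing, large tidal volumes, high O2 extraction;
* period 2 — final 20% of the surfacing: pre-dive settling;
* period 3 — any surface time beyond the 9-min threshold: non-foraging
  behaviour (resting, socializing, travelling).

Per Monte Carlo iteration a whale is drawn (length -> mass -> vital
capacity), then for each period a respiration rate f_R (lognormal), a mean
tidal-volume proportion of vital capacity (uniform) and an oxygen extraction
fraction E_O2 (beta) are drawn.  Oxygen per breath is
``VO2 = 0.21 * Vt * EO2`` (litres; 0.21 = O2 fraction of inspired air) and
the period's daily energy is ``f_R * minutes/day * VO2 * 20.1`` kJ
(20.1 kJ per litre O2).  The daily FMR is the within-iteration sum over the
three periods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .morphometrics import (
    DEFAULT_BETA_ADMR,
    DEFAULT_LENGTH_MEAN_M,
    DEFAULT_LENGTH_SD_M,
    MorphometrySample,
    as_rng,
    percentile_ci,
    sample_morphometry,
)

__all__ = [
    "SurfacePeriodSpec",
    "FmrDistribution",
    "RespirationFmrResult",
    "DEFAULT_SURFACE_PERIODS",
    "segment_surface",
    "segment_surface_table",
    "fit_lognormal_from_mean_ci",
    "sample_vt",
    "sample_eo2",
    "vo2_per_breath",
    "breath_energy_kj",
    "closed_form_period_mean",
    "fmr_respiration_mc",
]

O2_FRACTION_INSPIRED = 0.21   # fraction of O2 in inspired air
KJ_PER_L_O2 = 20.1            # oxidative energy yield, kJ per litre O2
SURFACE_SPLIT = 0.8           # period-1 share of a post-dive surfacing
SURFACE_THRESHOLD_MIN = 9.0   # post-dive surfacing standardized length, min
_Z95 = 1.959963984540054      # normal 97.5% quantile


@dataclass(frozen=True)
class SurfacePeriodSpec:
    """Respiratory parameters of one surface period.

    Parameters
    ----------
    period_id : 1, 2 or 3.
    fr_mean, fr_ci : mean respiration rate (breaths/min) and its 95% CI,
        modelled as a lognormal matched to the mean.
    vt_prop_range : (low, high) mean tidal volume as a proportion of vital
        capacity; the per-iteration mean proportion is uniform on this range.
    vt_sd_frac : per-breath tidal-volume SD as a fraction of vital capacity
        (only enters the optional per-breath jitter mode; it integrates out
        of the mean).
    eo2_mean : mean oxygen extraction fraction, in (0, 1).
    eo2_concentration : beta pseudo-count kappa; E_O2 ~ Beta(mean*kappa,
        (1-mean)*kappa).  ``math.inf`` collapses to a point mass (used for
        fixed-E_O2 sensitivity scenarios).
    daily_minutes : time spent in this period per day, min.
    daily_prop_ci : optional (low, high) 95% CI of the daily time
        *proportion*, used when daily time is sampled rather than fixed.
    """

    period_id: int
    fr_mean: float
    fr_ci: tuple[float, float]
    vt_prop_range: tuple[float, float]
    eo2_mean: float
    daily_minutes: float
    vt_sd_frac: float = 0.1
    eo2_concentration: float = 50.0
    daily_prop_ci: tuple[float, float] | None = None

    def __post_init__(self):
        lo, hi = self.vt_prop_range
        if not 0 < lo <= hi <= 1:
            raise ValueError(f"invalid Vt proportion range {self.vt_prop_range}")
        if not 0 < self.eo2_mean < 1:
            raise ValueError(f"E_O2 mean must be in (0,1), got {self.eo2_mean}")
        if self.daily_minutes < 0:
            raise ValueError("daily_minutes must be >= 0")
        if self.fr_mean <= 0:
            raise ValueError("fr_mean must be positive")
        if self.eo2_concentration <= 0:
            raise ValueError("eo2_concentration must be positive")


#: Default per-period parameters: measured respiration rates with 95% CIs,
#: tidal-volume proportion ranges, mean oxygen extraction and daily minutes.
DEFAULT_SURFACE_PERIODS: tuple[SurfacePeriodSpec, ...] = (
    SurfacePeriodSpec(1, 5.06, (3.78, 6.10), (0.60, 0.80), 0.80, 135.83,
                      daily_prop_ci=(0.0552, 0.1334)),
    SurfacePeriodSpec(2, 3.50, (3.20, 3.80), (0.40, 0.50), 0.50, 33.96,
                      daily_prop_ci=(0.0138, 0.0334)),
    SurfacePeriodSpec(3, 1.37, (0.81, 1.93), (0.30, 0.40), 0.35, 422.09,
                      daily_prop_ci=(0.0536, 0.5327)),
)


@dataclass(frozen=True)
class FmrDistribution:
    """Monte Carlo draws of a daily energy quantity, MJ/day, with summaries."""

    draws: np.ndarray
    seed: int | None = None

    @property
    def n_iter(self) -> int:
        return self.draws.size

    @property
    def mean(self) -> float:
        return float(np.mean(self.draws))

    @property
    def sd(self) -> float:
        return float(np.std(self.draws, ddof=1)) if self.draws.size > 1 else 0.0

    @property
    def ci(self) -> tuple[float, float]:
        return percentile_ci(self.draws)

    def summary(self) -> dict:
        lo, hi = self.ci
        return {"mean": self.mean, "sd": self.sd, "ci_low": lo, "ci_high": hi,
                "n_iter": self.n_iter}


@dataclass(frozen=True)
class RespirationFmrResult:
    """Per-period and total daily FMR distributions plus the morphometry draws."""

    per_period: dict[int, FmrDistribution]
    total: FmrDistribution
    morphometry: MorphometrySample
    seed: int | None = None


def segment_surface(
    surface_duration: float,
    threshold: float = SURFACE_THRESHOLD_MIN,
    split: float = SURFACE_SPLIT,
) -> tuple[float, float, float]:
    """Split one surfacing (min) into period-1/2/3 minutes.

    Surfacings up to ``threshold`` are split ``split``/(1-``split``) into
    periods 1 and 2; anything beyond the threshold is period 3 (non-foraging
    surface time).  The three parts always sum to the input duration.
    """
    if surface_duration < 0:
        raise ValueError("surface duration must be >= 0")
    recovery = min(surface_duration, threshold)
    p1 = split * recovery
    p2 = recovery - p1
    p3 = surface_duration - recovery
    return p1, p2, p3


def segment_surface_table(surfacings, threshold: float = SURFACE_THRESHOLD_MIN,
                          split: float = SURFACE_SPLIT):
    """Segment a table of surfacings into per-period segments.

    Parameters
    ----------
    surfacings : DataFrame with ``start_s`` and ``end_s`` columns (seconds).

    Returns
    -------
    DataFrame with columns ``start_s``, ``end_s``, ``period_id`` — one row
    per non-empty period segment, chronological within each surfacing
    (period 1, then 2, then 3).
    """
    import pandas as pd

    rows = []
    for r in surfacings.itertuples(index=False):
        dur_min = (r.end_s - r.start_s) / 60.0
        p1, p2, p3 = segment_surface(dur_min, threshold, split)
        t = r.start_s
        for pid, dur in ((1, p1), (2, p2), (3, p3)):
            if dur > 0:
                rows.append({"start_s": t, "end_s": t + dur * 60.0,
                             "period_id": pid})
                t += dur * 60.0
    return pd.DataFrame(rows, columns=["start_s", "end_s", "period_id"])


def fit_lognormal_from_mean_ci(mean: float, ci_low: float, ci_high: float
                               ) -> tuple[float, float]:
    """Lognormal (mu, sigma) whose mean equals ``mean`` and whose quantile
    spread matches the 95% CI ratio.

    ``sigma = ln(hi/lo) / (2 * 1.96)`` matches the CI width on the log scale;
    ``mu = ln(mean) - sigma^2 / 2`` then pins the distribution mean exactly.
    The slight asymmetry of the printed CIs cannot be matched exactly by any
    lognormal; the mean is prioritised because downstream results are means.
    """
    if not 0 < ci_low < mean < ci_high:
        raise ValueError(
            f"need 0 < ci_low < mean < ci_high, got ({mean}, {ci_low}, {ci_high})")
    sigma = math.log(ci_high / ci_low) / (2.0 * _Z95)
    mu = math.log(mean) - sigma**2 / 2.0
    return mu, sigma


def sample_vt(vc: float, prop_range: tuple[float, float], sd_frac: float,
              rng=None, n_breaths: int = 1) -> np.ndarray:
    """Sample per-breath tidal volumes (L) for one surface-period visit.

    A mean proportion of vital capacity is drawn once from
    Uniform(``prop_range``); each breath is then Normal(mean_prop * Vc,
    sd_frac * Vc), truncated into (0, Vc].
    """
    lo, hi = prop_range
    if not 0 < lo <= hi <= 1:
        raise ValueError(f"invalid proportion range {prop_range}")
    if sd_frac < 0:
        raise ValueError("sd_frac must be >= 0")
    rng = as_rng(rng)
    mean_prop = rng.uniform(lo, hi)
    if sd_frac == 0:
        return np.full(n_breaths, mean_prop * vc)
    out = rng.normal(mean_prop * vc, sd_frac * vc, size=n_breaths)
    bad = (out <= 0) | (out > vc)
    while bad.any():
        out[bad] = rng.normal(mean_prop * vc, sd_frac * vc, size=int(bad.sum()))
        bad = (out <= 0) | (out > vc)
    return out


def sample_eo2(mean: float, concentration: float = 50.0, rng=None,
               size=None) -> np.ndarray | float:
    """Sample oxygen extraction fractions from Beta(mean*k, (1-mean)*k).

    The beta is parameterized by its mean and a concentration pseudo-count
    ``k``, so the long-run mean equals ``mean`` for any ``k``; infinite
    concentration degenerates to a point mass at the mean.
    """
    if not 0 < mean < 1:
        raise ValueError(f"mean must be in (0,1), got {mean}")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if math.isinf(concentration):
        return mean if size is None else np.full(size, mean)
    rng = as_rng(rng)
    return rng.beta(mean * concentration, (1.0 - mean) * concentration, size=size)


def vo2_per_breath(vt, eo2):
    """Oxygen consumed per breath, L O2: ``0.21 * Vt * EO2``."""
    vt = np.asarray(vt, dtype=float)
    eo2 = np.asarray(eo2, dtype=float)
    if np.any(vt <= 0):
        raise ValueError("tidal volume must be positive")
    if np.any((eo2 <= 0) | (eo2 > 1)):
        raise ValueError("E_O2 must be in (0, 1]")
    return O2_FRACTION_INSPIRED * vt * eo2


def breath_energy_kj(vo2):
    """Energy per breath, kJ: 20.1 kJ per litre O2."""
    return KJ_PER_L_O2 * np.asarray(vo2, dtype=float)


def closed_form_period_mean(spec: SurfacePeriodSpec, vc_mean: float) -> float:
    """Expected period FMR, MJ/day, from independence of the sampled factors.

    E[FMR] = f_R_mean * minutes * 0.21 * mid(Vt range) * E[Vc] * EO2_mean
    * 20.1 / 1000.  Serves as an analytic oracle for the Monte Carlo mean.
    """
    mid_prop = 0.5 * (spec.vt_prop_range[0] + spec.vt_prop_range[1])
    kj = (spec.fr_mean * spec.daily_minutes * O2_FRACTION_INSPIRED
          * mid_prop * vc_mean * spec.eo2_mean * KJ_PER_L_O2)
    return kj / 1000.0


def _sample_daily_minutes(spec: SurfacePeriodSpec, n: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Daily minutes from a truncated normal on the daily time proportion."""
    if spec.daily_prop_ci is None:
        return np.full(n, spec.daily_minutes)
    lo, hi = spec.daily_prop_ci
    mean = spec.daily_minutes / 1440.0
    sd = (hi - lo) / (2.0 * _Z95)
    out = rng.normal(mean, sd, size=n)
    bad = (out <= 0) | (out > 1)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out <= 0) | (out > 1)
    return out * 1440.0


def fmr_respiration_mc(
    periods=DEFAULT_SURFACE_PERIODS,
    n_iter: int = 10_000,
    seed: int | None = None,
    length_mean: float = DEFAULT_LENGTH_MEAN_M,
    length_sd: float = DEFAULT_LENGTH_SD_M,
    beta: float = DEFAULT_BETA_ADMR,
    per_breath_jitter: bool = False,
    sample_daily_minutes: bool = False,
) -> RespirationFmrResult:
    """Monte Carlo daily FMR from respiration rates.

    Per iteration: draw one whale (length -> mass -> vital capacity), then
    per period an f_R, a mean Vt proportion and an E_O2; the period FMR is
    ``f_R * minutes * 0.21 * Vt * EO2 * 20.1`` kJ -> MJ, and the total is
    the within-iteration sum.

    Parameters
    ----------
    per_breath_jitter : if True, the period's representative tidal volume is
        the average of its ~f_R*minutes jittered breaths (Normal per-breath
        SD of 0.1 Vc), i.e. Normal noise of SD ``0.1 Vc / sqrt(N_breaths)``
        is added to the mean Vt.  Off by default: the jitter integrates out
        of the mean.
    sample_daily_minutes : if True, per-period daily minutes are sampled
        from a truncated normal on the daily time proportion (matching the
        reported proportion CIs) instead of held at their point values.
    """
    periods = list(periods)
    if not periods:
        raise ValueError("need at least one surface period")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    ids = [p.period_id for p in periods]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate period ids {ids}")
    if sum(p.daily_minutes for p in periods) > 1440.0 + 1e-9:
        raise ValueError("total daily minutes exceed 1440")

    rng = as_rng(seed)
    morph = sample_morphometry(n_iter, length_mean, length_sd, beta, rng=rng)

    per_period: dict[int, FmrDistribution] = {}
    total = np.zeros(n_iter)
    for spec in periods:
        mu, sig = fit_lognormal_from_mean_ci(spec.fr_mean, *spec.fr_ci)
        fr = rng.lognormal(mu, sig, size=n_iter)
        lo, hi = spec.vt_prop_range
        vt = rng.uniform(lo, hi, size=n_iter) * morph.vc
        minutes = (_sample_daily_minutes(spec, n_iter, rng)
                   if sample_daily_minutes
                   else np.full(n_iter, spec.daily_minutes))
        if per_breath_jitter and spec.vt_sd_frac > 0:
            n_breaths = np.maximum(fr * minutes, 1.0)
            vt = vt + rng.normal(0.0, 1.0, size=n_iter) * (
                spec.vt_sd_frac * morph.vc / np.sqrt(n_breaths))
            vt = np.clip(vt, 1e-9, morph.vc)
        eo2 = sample_eo2(spec.eo2_mean, spec.eo2_concentration, rng, size=n_iter)
        fmr_mj = (fr * minutes * O2_FRACTION_INSPIRED * vt * eo2
                  * KJ_PER_L_O2) / 1000.0
        per_period[spec.period_id] = FmrDistribution(fmr_mj, seed=seed)
        total = total + fmr_mj

    return RespirationFmrResult(
        per_period=per_period,
        total=FmrDistribution(total, seed=seed),
        morphometry=morph,
        seed=seed,
    )
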