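"""Orchestration: run both FMR pathways, compare them, and write a summary.

``run_all`` executes morphometrics, the respiration Monte Carlo, the
ODBA/dive-simulation Monte Carlo and the sensitivity scenarios under one
seed, then writes a summary CSV (one row per reported quantity with mean,
percentile CI and both Kleiber/ADMR multiple conventions), the raw draws,
an overlap figure of the two FMR distributions and a reproducibility
manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .divesim import DailyBudget, FmrOdbaResult, fmr_odba_mc
from .morphometrics import percentile_ci
from .respiration import (
    DEFAULT_SURFACE_PERIODS,
    RespirationFmrResult,
    fmr_respiration_mc,
)
from .sensitivity import default_scenarios, run_scenarios

__all__ = ["RunManifest", "distribution_overlap", "summary_table", "run_all"]


def distribution_overlap(draws_a, draws_b, bins: int = 100) -> float:
    """Overlap coefficient of two sampled distributions, in [0, 1].

    Both samples are binned on a shared grid spanning their pooled range
    (default 100 bins) and the overlap is the integral of the pointwise
    minimum of the two histogram densities.  Symmetric; 1 for identical
    samples, 0 for disjoint supports.
    """
    a = np.asarray(draws_a, dtype=float)
    b = np.asarray(draws_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:
        return 1.0
    edges = np.linspace(lo, hi, bins + 1)
    pa, _ = np.histogram(a, bins=edges, density=True)
    pb, _ = np.histogram(b, bins=edges, density=True)
    width = edges[1] - edges[0]
    return float(np.minimum(pa, pb).sum() * width)


@dataclass
class RunManifest:
    """Reproducibility record of one full run."""

    seed: int
    config_hash: str
    version: str
    n_iter_resp: int
    n_iter_odba: int
    outputs: dict
    metrics: dict


def _multiples(fmr_draws, bmr_mj_draws, beta: float) -> dict:
    """Kleiber and ADMR multiples under both ratio conventions.

    ``ratio_of_means`` divides the mean FMR by the mean BMR; ``mean_of_
    ratios`` averages the per-iteration FMR/BMR ratio.  The two differ for
    skewed distributions, so both are always reported.
    """
    fmr = np.asarray(fmr_draws, dtype=float)
    bmr = np.asarray(bmr_mj_draws, dtype=float)
    out = {"kleiber_ratio_of_means": float(fmr.mean() / bmr.mean()),
           "admr_ratio_of_means": float(fmr.mean() / (beta * bmr.mean()))}
    if fmr.shape == bmr.shape:
        r = fmr / bmr
        out["kleiber_mean_of_ratios"] = float(r.mean())
        out["admr_mean_of_ratios"] = float((r / beta).mean())
    return out


def summary_table(resp: RespirationFmrResult, odba: FmrOdbaResult,
                  beta: float) -> pd.DataFrame:
    """Summary rows for both pathways: value, CI and multiple conventions."""
    bmr_mj = resp.morphometry.bmr_kj / 1000.0
    admr_mj = resp.morphometry.admr_kj / 1000.0
    p = resp.per_period

    def row(name, draws, with_multiples=True, bmr_ref=bmr_mj):
        draws = np.asarray(draws, dtype=float)
        lo, hi = percentile_ci(draws)
        r = {"quantity": name, "mean_mj_day": draws.mean(),
             "ci_low": lo, "ci_high": hi}
        if with_multiples:
            m = _multiples(draws, bmr_ref, beta)
            r["x_kleiber"] = m["kleiber_ratio_of_means"]
            r["x_admr"] = m["admr_ratio_of_means"]
            r["x_kleiber_mean_of_ratios"] = m.get("kleiber_mean_of_ratios", np.nan)
            r["x_admr_mean_of_ratios"] = m.get("admr_mean_of_ratios", np.nan)
        else:
            r["x_kleiber"] = r["x_admr"] = np.nan
            r["x_kleiber_mean_of_ratios"] = r["x_admr_mean_of_ratios"] = np.nan
        return r

    p12 = p[1].draws + p[2].draws
    odba_bmr_mj = odba.bmr.draws
    rows = [
        row("BMR", bmr_mj, with_multiples=False),
        row("ADMR", admr_mj, with_multiples=False),
        row("FMR_resp_period_1", p[1].draws),
        row("FMR_resp_period_2", p[2].draws),
        row("FMR_resp_periods_1_2", p12),
        row("FMR_resp_period_3", p[3].draws),
        row("FMR_resp_total", resp.total.draws),
        row("COL", odba.col.draws, bmr_ref=odba_bmr_mj),
        row("FMR_ODBA", odba.fmr.draws, bmr_ref=odba_bmr_mj),
    ]
    return pd.DataFrame(rows)


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_all(config: dict | None = None, seed: int = 0,
            outdir=None, make_figure: bool = True) -> RunManifest:
    """Run the full analysis deterministically under one seed.

    ``config`` accepts the keys of :func:`whalefmr.config.default_config`
    (missing keys fall back to defaults).  If ``outdir`` is given, writes
    ``summary.csv``, per-pathway draws CSVs, ``sensitivity.csv``,
    ``overlap.png`` and ``manifest.json`` there.  Identical config + seed
    give byte-identical summary outputs.
    """
    from .config import default_config, periods_from_config

    cfg = default_config()
    if config:
        for k, v in config.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k] = cfg[k] | v
            else:
                cfg[k] = v

    morph = cfg["morphometrics"]
    periods = periods_from_config(cfg)
    n_resp = int(cfg["respiration"]["n_iter"])
    n_odba = int(cfg["odba_sim"]["n_iter"])
    beta = float(morph["beta_admr"])

    resp = fmr_respiration_mc(
        periods, n_iter=n_resp, seed=seed,
        length_mean=morph["length_mean_m"], length_sd=morph["length_sd_m"],
        beta=beta)
    odba = fmr_odba_mc(
        n_individuals=int(cfg["odba_sim"]["n_individuals"]),
        n_dives=int(cfg["odba_sim"]["n_dives"]),
        n_iter=n_odba, seed=seed,
        length_mean=morph["length_mean_m"], length_sd=morph["length_sd_m"],
        budget=DailyBudget())
    sens = run_scenarios(default_scenarios(), periods, seed=seed,
                         length_mean=morph["length_mean_m"],
                         length_sd=morph["length_sd_m"])
    summary = summary_table(resp, odba, beta)
    overlap = distribution_overlap(resp.total.draws, odba.fmr.draws)

    metrics = {
        "fmr_resp_mean": resp.total.mean,
        "fmr_resp_ci": list(resp.total.ci),
        "fmr_odba_mean": odba.fmr.mean,
        "fmr_odba_ci": list(odba.fmr.ci),
        "bmr_mean": float(resp.morphometry.bmr_kj.mean() / 1000.0),
        "admr_mean": float(resp.morphometry.admr_kj.mean() / 1000.0),
        "col_mean": odba.col.mean,
        "overlap_fraction": overlap,
        "multiples_resp": _multiples(resp.total.draws,
                                     resp.morphometry.bmr_kj / 1000.0, beta),
        "multiples_odba": _multiples(odba.fmr.draws, odba.bmr.draws, beta),
    }

    outputs = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(outdir / "summary.csv", index=False,
                       float_format="%.6f")
        pd.DataFrame({"fmr_resp_total": resp.total.draws}
                     | {f"fmr_resp_period_{k}": v.draws
                        for k, v in resp.per_period.items()}).to_csv(
            outdir / "fmr_resp_draws.csv", index=False, float_format="%.6f")
        pd.DataFrame({"fmr_odba": odba.fmr.draws,
                      "col": odba.col.draws}).to_csv(
            outdir / "fmr_odba_draws.csv", index=False, float_format="%.6f")
        sens.to_csv(outdir / "sensitivity.csv", index=False,
                    float_format="%.6f")
        outputs = {"summary": "summary.csv",
                   "resp_draws": "fmr_resp_draws.csv",
                   "odba_draws": "fmr_odba_draws.csv",
                   "sensitivity": "sensitivity.csv"}
        if make_figure:
            _overlap_figure(resp.total.draws, odba.fmr.draws,
                            outdir / "overlap.png")
            outputs["figure"] = "overlap.png"

    manifest = RunManifest(
        seed=seed, config_hash=_config_hash(cfg), version=__version__,
        n_iter_resp=n_resp, n_iter_odba=n_odba,
        outputs=outputs, metrics=metrics)
    if outdir is not None:
        (Path(outdir) / "manifest.json").write_text(
            json.dumps(asdict(manifest), indent=2, sort_keys=True))
    return manifest


def _overlap_figure(draws_a, draws_b, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    lo = min(np.min(draws_a), np.min(draws_b))
    hi = max(np.max(draws_a), np.max(draws_b))
    edges = np.linspace(lo, hi, 101)
    pa, _ = np.histogram(draws_a, bins=edges, density=True)
    pb, _ = np.histogram(draws_b, bins=edges, density=True)
    mid = 0.5 * (edges[:-1] + edges[1:])
    ax.fill_between(mid, pa, alpha=0.4, label="FMR respiration", step="mid")
    ax.fill_between(mid, pb, alpha=0.4, label="FMR ODBA", step="mid")
    ax.fill_between(mid, np.minimum(pa, pb), color="green", alpha=0.6,
                    label="overlap", step="mid")
    ax.set_xlabel("daily FMR (MJ/day)")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
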