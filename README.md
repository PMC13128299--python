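# whalefmr

Daily field metabolic rate (FMR) estimation for sperm whales
(*Physeter macrocephalus*) in social units, by two independent proxy
methods with full Monte Carlo uncertainty propagation:

1. **Respiration rates** — breath counts during post-dive surfacings,
   combined with tidal volume and oxygen-extraction physiology, give the
   daily oxygen budget and hence energy expenditure.
2. **ODBA / locomotion cost** — overall dynamic body acceleration from
   tri-axial biologging tags, mapped to locomotion power through an
   activity–energetics calibration and combined with allometric basal
   metabolism.

The package is aimed at physiological ecologists and bioenergetic
modellers (e.g. Population Consequences of Disturbance applications) who
need daily energy-expenditure distributions, not just point estimates,
for large deep-diving cetaceans where direct respirometry is impossible.

## The models

**Allometric chain.** Body length `L ~ Normal(8.61, 0.89)` m
(photogrammetry-derived); mass `M = 1.25 × 0.0196 L^2.74` tonnes → kg;
total lung capacity `TLC = 0.026 M` L; vital capacity `V_c = 0.85 TLC`;
Kleiber basal rate `BMR = 293.1 M^0.75` kJ/day; average daily metabolic
requirement `ADMR = β·BMR` with `β = 2` for a slow-swimming squid feeder.

**Respiration pathway.** Each post-dive surfacing splits into period 1
(initial 80%, rapid recovery breathing), period 2 (final 20%) and — for
surfacings beyond the 9-min standard — period 3 (non-foraging surface
time). Per period: respiration rate `f_R` is lognormal (mean-matched to
the measured rate), tidal volume `V_t` is a uniform proportion of `V_c`,
oxygen extraction `E_O2` is beta-distributed. Then

    VO2 = 0.21 · V_t · E_O2          (L O2 per breath)
    FMR_resp = VO2 · 20.1 · N_breaths/day   (kJ/day)

summed over the three periods within each Monte Carlo iteration.

**ODBA pathway.** Tag acceleration is high-pass filtered at 0.068 Hz
(0.4× the 0.17-Hz fluking frequency), body-rotation components are
removed using the magnetometer (25° gating where the field aligns with
the rotation axis), and ODBA is the minute-mean L1 norm of the specific
acceleration, median-normalized across individuals. Simulated days
(60% diving; 100 dives × 10 individuals with correlated phase durations
and lognormal phase ODBA) convert to energy via

    COL = 0.09 + 9.01 · ODBA          (W/kg)
    FMR_ODBA = COL · M · Dur_dive / 1000 + BMR

## Worked example

```python
from whalefmr import fmr_respiration_mc, fmr_odba_mc, distribution_overlap

resp = fmr_respiration_mc(n_iter=10_000, seed=1)
for pid, d in resp.per_period.items():
    lo, hi = d.ci
    print(f"period {pid}: {d.mean:6.2f} MJ/day (95% CI {lo:.2f}-{hi:.2f})")
lo, hi = resp.total.ci
print(f"total FMR_resp: {resp.total.mean:.2f} MJ/day (95% CI {lo:.2f}-{hi:.2f})")

odba = fmr_odba_mc(n_iter=1000, seed=1)
print(f"FMR_ODBA: {odba.fmr.mean:.2f} MJ/day; COL {odba.col.mean:.2f} MJ/day")
print(f"overlap: {distribution_overlap(resp.total.draws, odba.fmr.draws):.3f}")
```

prints

```
period 1: 327.29 MJ/day (95% CI 156.34-577.66)
period 2:  22.69 MJ/day (95% CI 10.94-39.34)
period 3:  60.25 MJ/day (95% CI 23.38-122.77)
total FMR_resp: 410.23 MJ/day (95% CI 202.13-711.39)
FMR_ODBA: 630.10 MJ/day; COL 358.26 MJ/day
overlap: 0.171
```

Period 1 dominates the respiration-side budget (post-dive oxygen-debt
repayment at ~5 breaths/min and high extraction); the ODBA estimate sits
~50% higher, as expected when a dolphin-derived locomotion calibration
is carried to a larger, glide-heavy swimmer. Each distribution is a
`FmrDistribution` whose `.draws` are the raw Monte Carlo samples;
summary CIs are empirical 2.5th/97.5th percentiles.

The same stages are scriptable from the shell:

```sh
whalefmr run-all --seed 1 --out results/        # both pathways + summary CSV
whalefmr simulate-tags --individuals 3 --out tags/   # synthetic DTAG data
whalefmr sensitivity --out sens.csv
```

## Layout

| module | contents |
| --- | --- |
| `whalefmr.morphometrics` | length/mass/lung/BMR allometric chain |
| `whalefmr.respiration` | surface-period segmentation + respiration Monte Carlo |
| `whalefmr.odba` | high-pass, rotation removal, minute ODBA, normalization, trimming |
| `whalefmr.divesim` | dive simulation, locomotion cost, FMR_ODBA Monte Carlo |
| `whalefmr.sensitivity` | one-at-a-time V_t / E_O2 scenario engine |
| `whalefmr.synthetic` | synthetic DTAG generator (dive tables, breaths, sensor streams) |
| `whalefmr.report` | orchestration, summary table, distribution overlap |
| `whalefmr.cli` | `whalefmr` command-line interface |

See `docs/methods.md` for modelling assumptions, parameter provenance
and known limitations.
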