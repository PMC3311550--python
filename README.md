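# serasim

Spatially explicit, individual-based simulation of forest stand growth,
and the stand-height statistics used to ask a remote-sensing question:
*which description of canopy height best predicts stand volume?*

Satellite LiDAR and SAR deliver one height number per resolution cell,
and biomass retrieval then leans on stand-level allometry
`M_forest = β·H^α`. But "the" height of a stand can be defined many
ways — the tallest tree (H_max), the arithmetic mean over all stems
(H_mean), the mean height of the 100 largest-DBH trees per hectare
(H_100), or the basal-area-weighted mean (Lorey's height,
`H_L = Σ H_i A_i / Σ A_i`) — and these differ systematically with
planting density, species and resource level. `serasim` grows whole
stands tree by tree (annual time step; asymmetric competition for light
between canopy discs; carbon-starvation self-thinning; gap-limited
recruitment; juvenile power-law height–diameter growth
`H = c·D^(2/3)` switching irrevocably to a saturating mature curve
`H = h_asym(1 − e^(−kD))`), sweeps density × species × light × area
factorials, and measures how tightly each height classification tracks
stand volume (m³/ha) with "best fitting cubic" r² protocols.

Headline result reproduced by this package: on the pooled all-data
protocol H_mean is the most consistent volume predictor (r² ≈ 0.75),
H_max the worst (r² ≈ 0.5), with H_100 and Lorey's height between —
and Abies alba stem counts converge across planting densities of
1–25 000/ha once stands pass ≈ 300 m³/ha.

## Worked example

Grow one dense silver-fir hectare for 60 years and summarise it:

```python
from serasim import SimConfig, run

res = run(SimConfig(species="abies_alba", planting_density=10_000,
                    years=60, rng_seed=1))
cols = ["year", "stems_per_ha", "volume_m3_per_ha",
        "h_max_m", "h_mean_m", "h100_m", "h_lorey_m"]
print(res.summaries[cols].iloc[::15].round(1).to_string(index=False))
```

```
 year  stems_per_ha  volume_m3_per_ha  h_max_m  h_mean_m  h100_m  h_lorey_m
  0.0       10000.0               0.6      3.0       2.1     2.7        2.2
 15.0        3317.0             233.6     18.1      12.7    18.0       15.1
 30.0        1548.0             514.3     26.3      19.1    26.2       23.4
 45.0        1181.0             779.7     31.4      20.7    31.3       29.0
 60.0        1015.0            1013.9     34.9      20.8    34.8       32.8
```

Ten thousand seedlings close canopy within a decade, self-thin to about
a thousand stems by year 60, and the four height classifications spread
out exactly as inventory practice expects: H_max > H_100 > Lorey >
H_mean, because the larger trees dominate the top-weighted metrics.
Feeding each metric's trajectory into the cubic height–volume fit:

```python
from serasim import analysis
s = res.summaries
for m in ("h_max_m", "h_mean_m", "h100_m", "h_lorey_m"):
    fit = analysis.fit_cubic_height_volume((s.volume_m3_per_ha, s[m]))
    print(m, round(fit.r2, 3))
# h_max_m 0.996 / h_mean_m 0.995 / h100_m 0.996 / h_lorey_m 0.997
```

Within one scenario every metric fits well (r² ≈ 1 above); the
differences appear when
trajectories from *different* densities and species are pooled — that
is the study the numbered scripts under `analysis/` run:

| script | what it does |
|---|---|
| `01_allometry_calibration.py` | pooled stem mass–DBH log–log slopes per species (2.54 / 2.48 / 2.63) |
| `02_default_resource_sweep.py` | 5 compositions × 5 densities × 100 yr factorial |
| `03_height_volume_fits.py` | "all data" cubic r² per height class + cross-application |
| `04_density_convergence.py` | stem-count convergence volume across densities |
| `05_light_and_area.py` | 100/75/50 % light and 1/0.5/0.25 ha experiments |

Each takes an optional seed argument (`python analysis/02_... 1`) and
writes tidy CSVs under `results/`. A `serasim` command-line tool wraps
the same library for single runs, sweeps, stand summaries of stem-table
CSVs, and synthetic fixtures (`serasim --help`).

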