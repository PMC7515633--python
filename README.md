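# epibolykit

Quantitative analysis of zebrafish **epiboly** — the first morphogenetic
movement of teleost development, in which the blastoderm spreads
vegetally over the yolk — from 4D nuclei recordings of the kind produced
by light-sheet (DSLM) imaging of H2A-GFP transgenic embryos.

The package is aimed at developmental biologists and image analysts who
need the downstream quantification, not the microscope: it provides

- **nucleus detection** from anisotropic 3D stacks (multiscale
  Laplacian-of-Gaussian on an isotropically resampled volume), with
  dual-view redundancy fusion, feature-based false-positive rejection
  and per-frame counting;
- **nearest-neighbour tracking** with single-frame gap repair and
  spatio-temporal sub-track fusion, plus a windowed mean-speed
  estimator for migrating deep cells;
- **spherical cartography**: rigid alignment of the embryo onto the
  animal–vegetal (AV) axis, conversion to azimuth/elevation/radius,
  fixed-radius local density (cells per 40 µm bounding sphere) and 2D
  "unwrapped" density maps;
- **phenotype scoring**: unaffected / affected / dead classification
  against stage-matched controls, penetrance percentages from
  `n = x/y` tallies, the adenylate energy charge and the 2^−ΔΔCt
  fold-change; and
- a **synthetic 4D embryo generator** that produces ground-truthed
  control and epiboly-arrested recordings (and rendered image stacks),
  so every stage is testable end to end without microscopy data.

## The quantities computed

With nuclei aligned so the vegetal pole sits on the +y axis, each
position maps to spherical coordinates with azimuth ∈ [−π, π] and
elevation ∈ [−π/2, π/2]; local density of nucleus *i* is
|{*j* : ‖x_j − x_i‖ ≤ 40 µm}| (self included). Epiboly progress is

    Epiboly (%) = 100 · (axial distance animal pole → margin) / (axial AV pole distance)

Mean migration speed is the arithmetic mean of all per-step
displacement lengths of the selected tracks over a fixed window
(e.g. 10 cells × 100 steps ≈ 1000 displacement steps), divided by the
frame interval. Energy charge is ([ATP] + ½[ADP]) / ([ATP] + [ADP] +
[AMP]); expression fold change is 2^−ΔΔCt.

## Worked example

Run the bundled pipeline on a synthetic control embryo (200 nuclei,
30 one-minute frames, margin advancing at 0.5°/min from 75°):

```python
from epibolykit.pipeline import run_pipeline

report = run_pipeline(
    {
        "seed": 7,
        "simulation": {"n_initial_nuclei": 200, "n_frames": 30, "epiboly_speed": 0.5},
        "tracking": {"max_link_distance": 4.0},
    },
    "demo_out",
)
print(report["stages"])
```

prints (abridged):

```
simulate: {'n_records': 6000, 'n_frames': 30, 'final_margin_deg': 89.5}
track:    {'n_tracks': 200, 'n_records': 6000}
density:  {'n_records': 200, 'mean_count': 11.87, 'radius_um': 40.0}
epiboly:  {'epiboly_pct': 49.14}
```

All 200 simulated nuclei are recovered as single tracks; the margin has
advanced from 75° to 89.5° of polar angle, i.e. the vegetal-most
nucleus sits at 49.1% epiboly (a margin at 90° is exactly 50%); the
mean local density is ~12 cells per 40 µm sphere. Re-running with the
same seed reproduces every output byte for byte. The same stages are
available as CLI subcommands (`epibolykit simulate|render|detect|track|
speed|density|unwrap|epiboly|score|penetrance|energy-charge|ddct|run`).

Scoring and penetrance:

```python
import epibolykit as ek

counts = ek.PhenotypeCounts("morphant 2 mM", n_unaffected=1, n_affected=39,
                            n_dead=1, denominator=41)
ek.penetrance(counts)["affected_pct"]   # 95.1
ek.energy_charge(ek.AdenylatePool(atp=6.3, adp=1.1, amp=0.4))  # 0.878
```

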