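# Methods

This note documents the models, conventions and numerical choices
behind `epibolykit`, in the spirit of a methods appendix: what each
stage assumes, which knobs matter, and what the synthetic benchmark
does and does not establish about real data.

Units are µm and minutes everywhere; no pixel-unit quantity crosses a
module boundary. Polar angle is measured from the animal pole, so a
margin at 90° corresponds to 50% epiboly and 180° to completion.

## Synthetic embryo model

The generator treats the blastoderm as a point process on a thin
spherical shell (default radius 120 µm, shell thickness 15 µm) centred
on the origin with the vegetal pole on +y. It is a kinematic model of
nucleus positions, not a mechanical model of tissue: the analysis
operates on positions, so forces, adhesion and yolk mechanics are
deliberately out of scope.

- **Spreading.** The blastoderm margin's polar angle advances at
  `epiboly_speed` (default 0.3°/min, the rate that carries a margin
  from 90° to 180° in about five hours) from an initial 75°
  (≈37% coverage). Each nucleus keeps the latitude fraction
  u = θ/θ_margin it had at birth, so the cap stretches self-similarly:
  margin-adjacent nuclei (u ≈ 1) move vegetally at exactly the
  configured rate (arc speed = rate × radius), nuclei near the animal
  pole barely move. This is the property the drift-calibration test
  asserts.
- **Arrest.** `arrest_time` freezes the margin (and therefore all
  directed motion) while divisions continue — the morphant-like
  condition. Because the control and arrested runs share a division
  schedule under the same seed, the two conditions can be compared at
  exactly matched nucleus counts, which is how the density-contrast
  property is tested.
- **Divisions.** A nucleus divides when its age reaches
  `division_interval` (default 30 min, a blastula-stage cycle time);
  both daughters get fresh ids and track ids, inherit the parent's
  layer and intensity, and are placed ±2.5 µm along a random tangent
  (5 µm separation keeps daughters resolvable at the default rendering
  scale). Lineage reconstruction across divisions is a non-goal of the
  tracker, so ground-truth track ids terminate at division.
- **Layers.** EVL/DEL/YSL labels (default fractions 0.2/0.7/0.1)
  affect only radial placement (surface / shell interior / yolk
  interface). They exist as simulator ground truth; no analysis stage
  infers layers.
- **Motility noise** is a tangential Gaussian random walk
  (default 0.3 µm/step). `min_separation` optionally enforces a
  minimum initial inter-nucleus distance by rejection sampling; the
  well-separated benchmark regime uses 6 µm ≥ 3× the per-step
  displacement.
- **Scale.** Default geometry (120 µm radius, ≤ a few hundred nuclei,
  ≤ 40 one-minute frames) is a reduced-scale stand-in for a ~350 µm
  embryo imaged over 10–15 h; the kinematics scale linearly and the
  analyses are scale-free, so nothing in the pipeline depends on the
  reduction.

The renderer adds an anisotropic Gaussian blob per nucleus (σ 1.8 µm
lateral / 2.6 µm axial) on a constant background, sampled at
1.5 µm lateral / 2.0 µm axial voxel spacing, with optional
Poisson and Gaussian read noise. It does not emulate yolk
autofluorescence, photobleaching, scattering depth-dependence, or the
dual-rotation acquisition itself — detection performance on real
stacks will be worse than on these benchmarks, and the passing tests
establish correctness of the pipeline contracts, not detector
performance on real microscopy.

## Detection

A multiscale Laplacian-of-Gaussian blob detector runs on the volume
linearly resampled to isotropic voxels at the finest spacing present
(anisotropy must never distort distances, so every threshold
downstream is in µm). The volume is normalised by (peak − median
background); a stack whose peak does not clear 6× the robust noise sd
(MAD-based) is declared signal-free, which keeps background-only
stacks from yielding spurious maxima after normalisation. Candidate
maxima are refined to sub-voxel precision by an intensity-weighted
centroid over a ±2σ window. Features populated per candidate: peak
intensity above background, integrated intensity, radius estimate
(σ√3 at the best-responding scale) and border distance.

Dual-view fusion pairs **mutually nearest** records within
`fusion_radius` (default 5 µm) and merges them at the
intensity-weighted mean position; mutual pairing (rather than one-sided
greedy) makes the operation symmetric in its two arguments, which is
asserted as a property. Rejection rules are user-configurable
(feature, min, max) triples — the defaults gate on intensity and
size — because the exact feature set used historically for object
rejection is not contractual; the rule engine, not a fixed rule set,
is the interface.

## Tracking

Frame-to-frame linking is **sorted-edge greedy**: all candidate pairs
within `max_link_distance` are sorted by ascending distance and
accepted greedily, each record used at most once. This matches plain
nearest-neighbour semantics, is independent of record order, and costs
O(E log E); a brute-force enumeration of the same rule serves as the
test oracle, and globally optimal assignment is intentionally not used
(the matching rule is a documented choice, not an inference about any
prior tool's internals).

Two repair passes follow. (1) Single-frame gap repair joins a track
ending at frame t to one starting at t+2 within `gap_link_distance`,
inserting one interpolated midpoint entry. (2) Sub-track fusion
matches track ends to strictly later track starts within
`fuse_start_end_distance` and up to `fuse_max_frame_gap` frames
(default 5), linearly interpolating any skipped frames. Allowing a
multi-frame gap here is what keeps tracks gap-free (an asserted
invariant) while still absorbing consecutive dropouts; with 5%
independent dropouts, ~10% of 40-frame tracks contain a ≥2-frame
dropout run that single-frame repair alone cannot close. Interpolated
entries are flagged and excluded from speed and density measurements
unless explicitly requested — measured quantities stay
observation-driven.

**Speed.** The estimator averages per-step displacement lengths over a
fixed window and divides by the frame interval. `window` counts
displacement steps (a track must span window+1 frames), so ten cells
tracked over a 100-step window contribute exactly 1000 steps. Every
selected track must span the full window — partial tracks raise rather
than silently biasing the estimate. Note that additive positional
noise biases mean step length upward (the mean norm of a noisy vector
exceeds the true displacement); the benchmark generator therefore
models constant-speed cells with per-step speed jitter and heading
wobble, for which the configured speed is exactly the estimand.

## Cartography

Alignment is the minimal rigid rotation (Rodrigues formula) taking the
centre-to-vegetal-pole direction onto +y after translating the centre
to the origin; roll about the AV axis is left free, so azimuth has an
arbitrary zero — density maps and all distances are roll-invariant.
With the AV axis on y: elevation = arcsin(y/r) (vegetal pole +π/2),
azimuth = atan2(z, x); unwrapped maps plot azimuth on x and elevation
on y.

Local density counts nuclei within a 40 µm bounding sphere, **self
included** (minimum 1; either convention differs by the constant 1,
and the self-inclusive one keeps the cells-per-sphere colour scale
strictly positive). The k-d-tree path used for n > 1000 must agree
with brute force exactly on integers, which is tested, along with the
identity Σ counts = n + 2·(pairs within radius). Gridded maps store
the per-bin **mean** of per-nucleus counts with NaN for empty bins, so
an unobserved bin is distinguishable from a measured zero.

Epiboly percentage uses the **axial projection** of the margin onto
the AV axis (clamped to [0, 100]), matching how the measurement is
performed on 2D lateral-view micrographs, not surface arc length —
the two differ away from the poles. The margin point is an explicit
input (e.g. the vegetal-most blastoderm nucleus) because choosing it
is a segmentation/annotation question, not a geometry one.

## Phenotype scoring and closed forms

Stages live on a declared ordered scale (sphere < 30% < 50% < 60% <
75% < 90% epiboly < bud < 3-somite, extensible in config); an embryo
is *dead* if coagulated, *affected* if alive but at any strictly
earlier stage than its stage-matched control, else *unaffected*. The
default threshold ("strictly earlier") is configurable in spirit: the
scorer takes the ordinal comparison as given and does not attempt to
distinguish mild delay from arrest.

Penetrance takes the tally denominator explicitly because published
`n = x/y` denominators do not always equal the sum of scored
categories; percentages are rounded one decimal, half away from zero,
matching hand-reported values (Python's banker's rounding would differ
on exact halves). Pooled penetrance and clutch-mean ± SEM are separate
outputs: a mean of per-clutch percentages weights clutches equally and
is generally not reproducible from pooled counts.

Energy charge (ATP + ½ADP)/(ATP + ADP + AMP) and 2^−ΔΔCt are exact
closed forms with domain validation (non-negative pools, at least one
positive; finite positive Ct values).

## Pipeline and reproducibility

One global seed is fanned out to named per-stage substreams via
`numpy.random.SeedSequence.spawn`, so a stage re-run standalone with
its substream reproduces its in-pipeline behaviour. Identical config
and seed give byte-identical output tables (asserted). Stacks travel
as multi-page TIFF plus a JSON sidecar carrying spacing and origin;
a missing sidecar is an error because silently assuming isotropy would
corrupt every µm distance downstream. Tables are TSV with schema
validation; unknown columns pass through untouched.

## Benchmark problem sizes

The test and acceptance workloads use desk-scale problems chosen to
exercise every code path at comfortable margins: 20 × 300-point clouds
for the density oracle, 250 nuclei × 40 frames with 5% dropouts for
tracking recovery, 10 × 100-step tracks for speed, 10 rendered stacks
of 50 nuclei (≥8 µm separation, SNR ≥ 10) for detection, and a 5-seed
control/arrested matrix for the density contrast. These establish the
implementation's correctness and calibration on data whose ground
truth is known exactly; they are not performance claims about
full-scale microscopy volumes.

## Known limitations

- The tracker is not a lineage reconstructor: divisions terminate
  ground-truth tracks, and one daughter typically continues the
  parent's recovered track.
- Sorted-greedy matching can differ from globally optimal assignment
  in dense, fast-moving scenes; the benchmark regime (spacing ≥ 3×
  step) is where its behaviour is guaranteed.
- The renderer's noise model (Poisson + Gaussian on a flat
  background) is far simpler than real light-sheet data.
- Spherical unwrapping is not equal-area; bin areas shrink toward the
  poles, which matters if grid means are compared across elevations.
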