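# Methods

## Model

A lung HRCT crop is treated as a lattice of radio-densities. For each
pathological Hounsfield band *b* the in-band pixels form the node set *P* of
an undirected graph; two pixels are adjacent when they are both spatially
close and radiometrically similar:

*E = { {Px, Py} : d(Px, Py) ≤ Rd and |G(Px) − G(Py)| ≤ D }*

where *d* is Euclidean distance on the pixel lattice and *G(P)* the pixel's
HU value. The degree distribution of this graph is the texture signature:
sparse, feedback-free normal parenchyma produces degree-count curves well
described by `a·ln k + b`, whereas proliferative processes (inflammation,
fibrosis) produce clustered structures whose humped histograms are captured
only by a flexible polynomial. Three size metrics complete the description:
the degree sum ("total count"), the mean degree ("average count"), and the
maximum degree.

### Assumptions

- The HU bands are a total, disjoint partition of the attenuation axis;
  band bounds are scanner/protocol-specific and are configurable. All
  intervals are half-open `[low, high)`; the final interstitial-vessel band
  is `[5, ∞)` so that the partition has no gap at exactly 5 HU.
- Pixel spacing is in-plane isotropic; only single-frame slices and 2-D
  (intra-slice) connectivity are considered.
- The gradient tolerance *D* applies to HU differences. *D* = 50 spans the
  entire 47-HU-wide emphysema band (every emphysema pixel pair within reach
  connects) while fragmenting the 335-HU GGO band and the 105-HU
  consolidation band into clusters of similar density, which is the intended
  behaviour. A configuration switch would be required to apply it to raw
  stored values instead; with the common slope = 1 the two are identical.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| crop side | 65 | px | ≈ double the 25 mm / 0.74 mm-px⁻¹ ≈ 33.8 px minimum that spans one secondary lobule |
| Rd (radius) | 4 | px | 2.96 mm at 0.74 mm/px — the scale of the smallest clinically reported lesions; below 3 px networks are too sparse to discriminate, above 5 px node attachment links tissue without anatomical cause |
| D (gradient delta) | 50 | HU | covers the emphysema band; clusters the wider bands |
| distance at Rd | inclusive (≤) | — | the rule is a closed disk; distance exactly 4.0 connects |
| α | 0.05 | — | conventional two-sample test level |
| polynomial degree | chosen in [2, 8] | — | observed range for pathological fits; selection by adjusted R², ties to the lowest degree |

Coordinates are 0-based (row, col); crop windows are origin-inclusive,
size-exclusive. HU values are clamped to the 12-bit CT range [−1024, 3071].

## Numerical choices

- **Graph construction** scans the 24 half-disk lattice offsets within the
  radius (48 neighbours per interior pixel at Rd = 4) and intersects the
  layer mask with its shifted self, one vectorised pass per offset. This is
  provably identical to the all-pairs definition and is tested against a
  brute-force oracle on random layers; isolated in-band pixels are retained
  as degree-0 nodes because the node set is defined as the pixel set.
- **Fitting** is least squares of raw node counts versus degree (counts are
  what the distributions plot, not frequencies). Degree-0 nodes are excluded
  from fitting (ln 0 undefined) but included in all metrics. The power
  family is fitted by log–log linearisation — deterministic, no starting
  values — and its R² is recomputed on the original count scale so the three
  families are comparable. Fits require ≥ 3 distinct positive degrees;
  constant counts make R² undefined, and both conditions raise named errors
  that lot-level sweeps record as missing cells instead of aborting.
- **Welch test**: sample variances use the n−1 denominator; the
  Welch–Satterthwaite df is floored to an integer for reporting but p-values
  and critical values use the unrounded df. Both variances zero is a
  degenerate-sample error.
- **SD separation**: each group's SD divided by the sum of the two SDs,
  × 100, so the two shares total 100; absolute SDs are reported alongside.
- **Determinism**: node ids are row-major crop indices; exports are sorted;
  all randomness flows from one integer seed per phantom spec. Identical
  seed ⇒ byte-identical CSV outputs.

## Synthetic phantoms

The generator emulates exactly two things about real crops: HU-band
occupancy and spatial clustering.

- `normal_like`: a Gaussian-smoothed random field (kernel 2 px, amplitude
  30–50 HU) centred at −850 HU and clipped inside the normal-parenchyma
  band, plus sparse uncorrelated out-of-band speckle — 6% of pixels by
  default (5–8% across a cohort), split 70% GGO / 15% emphysema /
  15% consolidation, emulating small vessels, airway walls and
  reconstruction noise. The speckle level was set so the normal GGO layer
  forms a sparse but fittable network (~150–250 nodes): much below that,
  degree histograms collapse to fewer than three distinct degrees and no
  curve family can be fitted at all.
- `emphysema_bubbles` / `ggo_blobs` / `consolidation_clusters` /
  `mixed_dild`: the same background with seeded compact structures (disks;
  irregularised by a smooth noise field for GGO) whose smooth interior
  textures are clipped inside the intended band, painted in the order
  emphysema → GGO → consolidation. At a matched seed the DILD phantom is the
  normal phantom plus structures, so its GGO and consolidation node counts
  strictly dominate the normal ones by construction.

What passing tests on phantoms do **not** show: performance on real
anatomy. The phantoms contain no septal architecture, no partial-volume
gradients at tissue interfaces, no reconstruction-kernel noise spectrum, and
no observer variability in crop placement. They demonstrate that the
pipeline is correct and that the degree-distribution signature behaves as
designed when the band occupancy and clustering assumptions hold.

## Problem sizes

The cohort-level checks use 30 normal + 30 DILD 65×65 phantoms (a full run
takes on the order of a second); oracle-equivalence checks use 100 random
20×20 layers across radii 1–8 and gradient tolerances {0, 50, ∞}.

## Known limitations

- Per-phenotype inference (UIP, OP, HP subclasses) is out of scope; records
  carry an optional subclass label but no statistics are computed on it.
- No multiple-testing correction is applied across the three metrics.
- Whole-slice tiling, 3-D connectivity, and centrality/community measures
  are not implemented; the degree distribution is the only network
  characterisation, matching what the method actually uses.
- The band table defaults are calibrated to one scanner family; applying
  them to other protocols requires overriding the table.
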