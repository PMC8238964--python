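# Methods

This note describes the algorithms implemented in `rhocta` and how they
were validated. All numbers below come from the seeded synthetic bench
included in the package; the published reference cohort table bundled
in `rhocta.reference` is used only for metric-arithmetic worked
examples and as a shape template for synthetic cohorts.

## Imaging model

En-face images represent maximum-intensity projections of an
angiography volume over the dermal depth range 40–440 µm, sampled at a
6.5 µm transverse pixel pitch (a 6.006 mm field is 924 × 924 px).
Field sizes must be integer multiples of the pitch. Three acquisition
states are modeled:

- **baseline** — perfused vessels only;
- **compressed** — probe pressure suppresses flow; the image should be
  essentially avascular and serves as a flow-suppression quality
  control (a segmented vessel density above 2% raises a QC warning);
- **hyperemia** — post-occlusion reactive hyperemia recruits
  previously unperfused capillaries, so the vascular tree is a strict
  superset of baseline.

## Synthetic networks

`generate_network` grows a planar tree of straight segments from
several trunks, with diameters tapering from 40–60 µm trunks down to
15 µm capillaries (15–65 µm overall), a 39 µm clearance rule between
non-adjacent segments, and geometric rules that keep junctions
resolvable at the working resolution: a minimum sprout angle, a
bifurcation half-angle window, a minimum tip-turn angle, and a
junction degree cap of 4. A configurable fraction of terminal branches
is marked unperfused; these render only in the hyperemia state, which
is what gives a positive ground-truth RCC. The generator books exact
truth per state: rendered area fraction, centerline length per area,
and branch count among rendered segments.

`render_enface` rasterizes segments with their physical widths
(slightly dilated to mimic the point-spread function) and
`add_artifacts` applies multiplicative speckle and additive horizontal
scan stripes, both seeded. `render_histology_stack` slices the network
into evenly spaced depth sections over 40–440 µm with integer
per-section placement jitter and isotropic tissue shrinkage about the
field center.

## Preprocessing

`project_enface` performs a maximum-intensity projection over a
configurable depth slab of a (z, y, x) volume with 3.5 µm axial
spacing. `remove_stripes` implements wavelet–FFT destriping: a
multilevel DWT (db4, 5 levels) isolates the horizontal-detail bands,
whose columnwise FFT is attenuated around the zero frequency with a
Gaussian notch (σ = 2.4), removing coherent stripes while leaving
stripe-free content nearly untouched (< 5% energy change; ≥ 90% of
stripe-band energy removed on striped flats).

## Segmentation and skeleton metrics

`segment_vessels` chains: median filter (radius 1) → Gaussian smoothing
(σ = 1 px, which suppresses speckle filaments that otherwise survive as
false skeleton branches) → multiscale Frangi vesselness with scales
matched to the 13–65 µm diameter range → hysteresis thresholding at the
0.35/0.65 quantiles of above-floor vesselness → an intensity gate at a
fixed fraction between the background and foreground class means of the
raw pixels → small-object removal, morphological closing, and
small-hole filling.

`skeletonize` thins the mask, prunes terminal spurs up to 8 px (long
enough to remove thinning artifacts of wide vessels, short enough to
keep real short terminal arms), and detects branch points by combining
two junction candidates — crossing-number ≥ 3 and 8-neighbor count ≥ 4
(the latter catches 2-px-thick knots left by thinning at wide
orthogonal crossings) — then merging candidate clusters connected
within 8 skeleton-path pixels and keeping clusters with at least three
persistent arms. Network length uses a calibrated step-weighted
estimator (0.948 per axial step, 1.340 per diagonal step).

## Metrics

Per image: VD (% of field area covered by the vessel mask), LVN
(skeleton length in mm per mm² of field), NBP (branch-point count),
and mean vessel diameter 1000·(VD/100)/LVN in µm. Per subject, the
reactive capillary coefficient is

RCC = (VD_h/VD_b) · (LVN_h/LVN_b) · (NBP_h/NBP_b) − 1,

with hyperemia (h) over baseline (b).

## Histology registration

`register_sections` aligns each section to its already-registered
predecessor by integer phase correlation (shift bound 10 px), so the
estimated shift is the full chained correction; flat sections are
passed through with a warning. `max_intensity_project` collapses the
registered stack to an en-face image.

## Statistics

`summarize` reports group mean and sample SD (ddof = 1, degenerate flag
for n = 1), `compare_groups` is Welch's unequal-variance t-test, and
`regress` is ordinary least squares with r².

## Validation

- **Recovery.** On 20 seeded 2.002 mm networks at 25% target density,
  noise-free renders segment to VD within ±3.2% relative, LVN within
  ±1.2%, and NBP exactly on all 40 state images. With default speckle
  and stripes (destriped before segmentation), subject-level RCC is
  within ±15% of truth on all 20 seeds (worst 10.3%).
- **Destriping.** ≥ 90% stripe-band energy removal on striped flats;
  < 5% total-energy change on stripe-free images.
- **Registration.** Jittered offsets up to 5 px recovered to within
  ±1 px across 20 seeds.
- **Statistics.** Null rejection rate at α = 0.05 within ±0.02 over
  1000 replicates; exact lines give r² = 1; independent noise gives
  r² < 0.02 at n = 1000.
- **Determinism.** Two runs of the cohort pipeline on the same
  manifest produce byte-identical CSV outputs; provenance records the
  configuration and package version without timestamps.
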