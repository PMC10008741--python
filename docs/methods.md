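# Methods

This note records the models, conventions, parameter choices and
limitations behind `ulm3d`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is
asserted from memory.

## Conventions

Axis order is `(z axial, x lateral, y elevation)` everywhere; lengths are
millimetres internally (µm at user-facing surfaces), frequencies Hz,
times seconds. Grids use the voxel-center convention with 0-based
indices: voxel `(0,0,0)` sits at the grid origin, and index ↔ physical
mapping is an exact bijection (property-tested). The sound speed defaults
to 1540 m/s, the conventional soft-tissue value and the one under which
7.81 MHz gives λ = 197.18 µm, hence the 98.6 µm (λ/2) beamforming voxel
and 9.86 µm (λ/20) rendering voxel. λ/20 is conventionally *printed* as
9.8 µm; that is a truncation, not a rounding, so the toolkit keeps full
precision and provides a `truncate` display helper.

## Acquisition planner

`plan_acquisition` is pure arithmetic over an `AcquisitionPlan` (5
transmits × 1024 samples × 100 volumes/block × 256 channels × 2
bytes/sample on each of four systems, 500 volumes/s, 100 000 volumes by
default). Block duration, total duration and dataset size follow exactly;
per-system block bytes may be overridden with a measured figure because
vendor buffer layouts pad the naive product (a measured 245 MB/block/
system yields the 980 MB/block and 980 GB totals the defaults target).

## Beamforming

Plane-wave transmit delay uses direction cosines normalized to a unit
vector: `u = (√(1−sin²θ_lat−sin²θ_elev), sin θ_lat, sin θ_elev)` and
`τ_tx = (r·u)/c`, which reduces to `(z cos θ + x sin θ)/c` for single
tilts; receive delay is the element–voxel path over `c`. Channel samples
are linearly interpolated; out-of-range samples contribute zero; receive
apodization is off by default with an optional f-number cone. Envelope
detection is the magnitude of the axial analytic signal for real RF data
and the plain magnitude for complex or already-envelope data; compounding
(coherent mean over angles) precedes envelope detection, matching the
stage order of the chain (compound → filter → envelope).

The bundled RF simulator emits a one-cycle Hann-tapered sinusoid at the
probe center frequency, *centered* on the geometric delay so the envelope
peak encodes the echo time; amplitudes are proportional to scatterer
strength with no spreading loss (the simulator targets localization-grade
geometry, not calibrated echo levels).

## SVD clutter filter

Per non-overlapping block (200 frames by default) the sequence is
reshaped into a space × time Casorati matrix, and the
`K = ⌈removed_fraction · n_t⌉` largest singular values are zeroed —
ceiling rounding so 15 % of 200 frames removes exactly 30. K is counted
against the temporal dimension; for the thin matrices that occur here it
coincides with min(space, time). The filter is an orthogonal projection
(energy never increases; output rank ≤ n_t − K), supports complex input,
and a trailing remainder block of ≥ 2 frames is filtered with K scaled to
its length (a single trailing frame is zeroed — no temporal separation is
possible for it).

A caution established while validating the stage: removal of the top 15 %
implicitly assumes the clutter owns that many strong temporal modes. If
synthetic clutter is a single frozen field (exact rank 1), the remaining
29 removed components are taken from the *bubble* subspace, and slow
sparse bubbles can be annihilated. The scene generator therefore models
clutter the way tissue behaves in vivo — a bright static field plus ~29
smooth spatial modes with slowly varying weights and geometrically
decaying amplitudes (`SceneNoiseModel.clutter_rank`, default 30) — so the
removed fraction matches an actual clutter subspace.

## Localization

Per frame: (1) normalize to the frame maximum and zero voxels below
`noise_threshold_frac` (default 3 %, empirical range 1–7 %); (2) convolve
with a unit-sum anisotropic Gaussian matched to the PSF
(σ = FWHM/2.355 per axis, kernel half-width 3σ, reflective boundaries;
separable, so three 1-D passes); (3) threshold at `mean + k·std` computed
over the whole frame volume and label connected components (26-
connectivity default, blobs under 2 voxels dropped); (4) report the
intensity-weighted centroid of each blob in mm, weights taken from the
convolved volume (raw-envelope weights available via flag). Blobs
touching the volume border are kept but flagged.

The same chain runs twice: `k = 1.5` (low pass — keeps dim bubbles but
merges close bright pairs) and `k = 3.5` (high pass — separates bright
pairs, loses dim bubbles). The passes are fused only at the rendering
stage. Note the blob *count* is deliberately not monotone in `k` — a
higher threshold can split one merged blob into two, which is precisely
the behaviour the dual-pass strategy exploits; what is monotone is the
supra-threshold mask size, and that is what the tests assert.

The PSF defaults are the diffraction-limit figures at 7.81 MHz: FWHM λ/2
axially and 1.5 λ laterally and in elevation (98.6 µm / 295.8 µm).

## Tracking

Frame-to-frame linking solves the gated minimum-total-Euclidean-distance
one-to-one assignment (`scipy.optimize.linear_sum_assignment`); pairs
beyond `max_link_distance` (default 0.2 mm = 100 mm/s at 500 volumes/s)
are forbidden, and the gate directly bounds the fastest recoverable flow.
There is no gap closing — a missed detection splits a track — matching
basic Hungarian trackers. Tracks shorter than 10 positions are discarded
(a 10-point track is kept: "below ten" read strictly). Coordinates are
smoothed with a Savitzky–Golay filter (window 5, order 2 — the filter is
standard, the parameters are this package's defaults); linking uses raw
positions, velocities use smoothed ones. Per-segment speed is
`‖p_{t+1}−p_t‖ × frame_rate` with the signed axial component kept
separately. Angle/acceleration pruning is not implemented: it risks
destroying genuine tortuosity.

## Rendering and measurements

Each track segment is rasterized as the *exact* 3-D digital line between
consecutive smoothed positions (the set of nearest-voxel roundings of the
continuous segment, enumerated from the boundary-crossing parameters —
no sampling-density knob); every visited voxel increments intensity and
density and accumulates the segment's signed axial velocity. Out-of-grid
visits are clipped and counted. Velocity per voxel is `vz_sum/density`
where density > 0, median-filtered (3³ default) to suppress isolated
noisy-track voxels. The low/high-pass volumes are fused voxelwise: mean
where both are non-zero, the lone value otherwise — so vessels seen by
both passes are not doubled in brightness. A σ = 0.8 voxel isotropic
Gaussian is available as a final display smoothing. The directional split
returns positive/negative axial-flow volumes and a color-map saturation
limit at the 99.9th percentile of |vz| over non-zero voxels.

Vessel width is the full width at half maximum of a cubic-spline-
interpolated (×10) cross-section with a single dominant peak;
bifurcation separability returns the valley intensity between two peaks —
the minimum threshold above which they form disjoint supra-threshold
components (verified against an exhaustive threshold sweep) — plus the
peak-to-peak distance. Bubble-count time series report per-volume counts,
means/stds over 200-frame blocks and a 5-point moving average.

## Fourier shell correlation

A single rendered volume is decimated 2×2 along the lateral and
elevation axes into four checkerboard sub-volumes; the FSC
`Re Σ F₁F₂*/√(Σ|F₁|²Σ|F₂|²)` is computed over spherical shells one DFT
bin wide for the two complementary pairs (ee↔oo, eo↔oe) and the curves
averaged. Because the sub-grids are offset by one original voxel, a phase
ramp for the known shift is removed from the second spectrum by default;
identical content then gives FSC ≡ 1 on every shell. Resolution is
1/frequency at the first sustained drop below the 1/2-bit threshold
(asymptote 0.2071/1.2071 ≈ 0.1716); single-shell dips followed by at
least two shells back above the threshold are ignored as spikes.

Two deliberate choices matter. First, shells extend to the Nyquist of the
*finest* axis: the axial axis keeps the λ/20 spacing while the split axes
double, so outer shells are partially supported — but they are exactly
what allows a measured resolution finer than the decimated lateral
Nyquist (39.4 µm). Second, the FSC is computed on the raw λ/20 track
projection, not on the σ = 0.8-smoothed display volume: the smoothing is
cosmetic and, applied before splitting, would correlate the checkerboard
halves and push the curve artificially high.

## The synthetic scene generator

The generator emulates the statistical structure of a rodent-brain
acquisition, not its anatomy:

* **Vessel trees** — binary trees with child radius = parent × 2^(−1/3)
  (Murray's law) and child peak speed scaled so volumetric Poiseuille
  flow (πR²·v_peak/2) is conserved at every bifurcation; branch planes
  rotate pseudo-randomly. Radii span ~15–200 µm, speeds 0–70 mm/s.
* **Bubble transport** — Poisson arrivals calibrated by Monte-Carlo
  estimation of the mean residence time so the expected in-view count hits
  its target (86 ± 3 per volume in the reference acquisition; 20 on the
  desk-scale grids here). Each bubble keeps a fixed fractional radial
  offset ρ (area-uniform, capped at 0.85 so near-wall bubbles do not
  stall forever) and azimuth, advances by `v_peak(1−ρ²)·Δt` per frame,
  and branches with probability ∝ child flow. A `centerline` mode pins
  ρ = 0 for recovery tests that need a single known speed.
* **Rendering** — each bubble adds an anisotropic Gaussian (peak = its
  amplitude, drawn log-uniform over 1–10× to create the dim/bright mix
  that motivates the dual threshold) at its true sub-voxel position;
  clutter (above) ~30 dB over a unit bubble; additive white noise; final
  magnitude returned as the envelope-like sequence.

Packaged configurations:

* `make_demo_scene` — a 5-generation tree (~20 mm of vessel) in the
  32×48×48 λ/2 volume. Five generations keep the ~20 in-view bubbles
  mostly farther apart than a PSF; with fewer generations the same count
  packs the vessels shoulder-to-shoulder, the time-averaged vessel trace
  becomes quasi-static, and the SVD filter eats it — a real dense-ULM
  failure mode, but not the operating point of the method.
* `make_parallel_vessel_scene` — eight straight vessels ≥ 1.2 mm apart,
  all at one centerline speed (20 mm/s), bubbles on the centerline, no
  clutter. This is the reference for localization-error and
  speed-recovery measurements: it isolates the localization/tracking
  stages (the clutter/SVD interaction is validated separately), and the
  single known speed makes "recovered speed vs simulated centerline
  speed" well defined.
* `make_two_vessel_tree` — two parallel vessels 60 µm apart, used with
  ~1.2 bubbles in view over 4 s. Bubbles co-occurring within a PSF across
  the pair localize at the midline and fill the inter-vessel valley; the
  rate of such merges is quadratic in bubble density while coverage is
  linear in density × duration, so the sparse-long regime (the one ULM
  itself relies on) keeps the pair separable robustly across seeds.

What the generator does **not** model: acoustic propagation and
aberration (the PSF is a fixed Gaussian, not a depth- and skull-dependent
response), nonlinear bubble dynamics and amplitude fluctuation over a
track, speckle statistics of the envelope background, motion, and
attenuation. Tests passing on these scenes therefore demonstrate the
correctness and precision of the *processing*, not robustness to every
in-vivo degradation.

## Numerical choices and degenerate inputs

FWHM→σ uses 2√(2 ln 2) ≈ 2.355. All-zero frames pass through the noise
threshold unchanged with a warning and produce no localizations. Zero-
weight blobs are discarded. Tracks shorter than the smoothing window pass
through unsmoothed. Empty FSC shells are skipped; a curve that never
drops below threshold reports an infinite (beyond-Nyquist) resolution
sentinel. Per-frame normalization uses the frame maximum (configurable
choice; a per-block maximum is the alternative). The pipeline derives one
sub-seed per stage from the run seed via `numpy.random.SeedSequence`, so
toggling one stage never shifts another's randomness, and every artifact
directory carries a resolved-config snapshot and a config-hash manifest.

## Problem sizes

The shipped tests and the acceptance script run desk-scale analogues of
the reference acquisition: 500–2000 volumes of 32×48×48 λ/2 voxels
(vs 100 000 volumes of a 9.5×9×10 mm³ field in vivo), ~10⁴–10⁵
localizations (vs 4.02 million), and λ/20 renderings up to 320×310×320
voxels. At these sizes the measured FSC resolution of a full-chain
rendering is ~42 µm — strictly finer than the 98.6 µm diffraction voxel,
qualitatively mirroring the ~31 µm reported at full scale, with the gap
attributable to the thousand-fold difference in track counts. The
99.9th-percentile velocity saturation on these sparse renderings is
dominated by rare mis-linked track segments and is bounded above by
`max_link_distance × frame_rate` (100 mm/s at the defaults); the 3³
median filter that cleans dense in-vivo velocity maps removes almost all
voxels of a one-voxel-wide desk-scale track line, so the saturation
figure is reported on the unfiltered map.

## Known limitations

* Beamforming is CPU-only and loops over elements; it is meant for
  fixture-scale validation, not for 10⁵-volume datasets.
* The Hungarian gate admits occasional cross-bubble links in dense
  regions; no motion model (Kalman/IMM) is applied.
* Segmentation thresholds are global per frame; spatially local
  thresholds would localize dim and bright bubbles in one pass.
* The FSC's outer, partially supported shells average fewer voxels and
  are noisier than the fully supported ones; the 1/2-bit threshold's
  n-dependence partially compensates.
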