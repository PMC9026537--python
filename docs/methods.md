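# Methods

## Image model and conventions

An en-face image is a 2-D grid of intensities in [0, 1] with a physical
lateral pitch in µm/pixel. Intensities are normalized by the bit-depth
maximum of the source file (255 or 65535), never by the per-image
maximum: the Phansalkar threshold has absolute-intensity terms, and
per-image stretching would make thresholds incomparable across eyes.
The pixel pitch is required user metadata. Published px↔µm
conversions for these scans are not always self-consistent (a "4 px =
26.37 µm" and an "8 px = 49.80 µm" statement imply pitches of 6.5925
and 6.225 µm/px for the same device), so the pipeline refuses to guess:
whatever pitch the manifest states is used for all physical
quantities. The synthetic generator uses 6.6 µm/px, the nominal scale
of a 6 × 6 mm scan sampled at ~910 px equivalents.

Row 0 is superior. Nasal/temporal corner labels are resolved from
laterality: for a right eye (OD) the nasal side is the left image
column side, mirrored for OS. The convention is arbitrary but
self-consistent: mirroring an image left↔right while flipping the
laterality flag leaves every corner-labeled metric unchanged (tested).

The depth slab an en-face projection comes from (by convention 15 µm
thick, starting 16 µm below the RPE/Bruch's membrane) is carried as
metadata only; slab segmentation happens upstream in device software.

## Compensation

`compensated = flow × G_σ(1 − structure)`, then division by the global
maximum. Shadowed regions are dark in the structure channel, invert to
bright multipliers, and lift the attenuated flow signal before
thresholding.

* **Blur σ = 2 px (default).** The σ of the structure smoothing is not
  standardized in the literature; 2 px suppresses speckle in the shadow
  estimate while preserving deposit-scale (tens of µm) shadow
  structure. It is exposed in `CompensationParams`. The acceptance
  surface is the efficacy property below, not a particular σ.
* **Rescale by max, not min–max.** Deficit polarity depends on the zero
  level; a min–max stretch would move it. If the product is identically
  zero the image is returned unchanged with a warning.
* **Mirror (symmetric) boundary padding** for every filter in the
  package. Corner ROIs sit flush against the image border, so a
  zero-padded filter would create a dark rim that inflates corner FD%.

## Binarization

Phansalkar threshold `T = m(1 + p·e^(−qm) + k(s/r − 1))` with window
mean `m` and *population* SD `s` over a square window of side 2·radius+1,
constants k = 0.25, r = 0.5, p = 2, q = 10 (the de-facto community
defaults on [0, 1] data), radii 4 and 8 px. A pixel is a deficit iff
intensity ≤ T; the tie rule makes the all-zero image 100% deficit, the
only self-consistent degenerate behavior. The window is square — the
"radius" names its half-side — which admits an exact separable
implementation checked bit-for-bit against a naive sliding-window
oracle; the circular-neighborhood variant is a possible alternative
that is not implemented. The full image is thresholded first and ROIs
are cropped afterwards, so ROI-interior statistics are unaffected by
the crop line.

Note a property of this formula on [0, 1] data: since s ≤ 0.5 = r
always, the k-term is non-positive, so raising k weakly *lowers* T and
shrinks the deficit set.

## Particle metrics

Corner ROI side = round(1000·size_mm / pitch) px; four ROIs flush with
the image corners, rejected if they would overlap. Components use
8-connectivity with no size or circularity exclusion and no border
exclusion (equivalent to particle analysis with size 0–∞, circularity
0–1). Per ROI: FD% = 100·deficit/total pixels; mean FD size =
deficit area / component count (0 when empty); total FD area =
deficit pixels · pitch² · 10⁻⁶ mm². Mean FD size is defined per-ROI and
then averaged per-eye, mirroring the per-eye averaging of the other
three metrics. Two identities hold exactly and are fuzz-tested:
total area = FD%/100 × ROI area, and count × mean size = total area.

## Statistics

Two-sided tests only; mean ± SD (sample SD, n−1) summaries to two
decimals.

* **Wilcoxon signed-rank**: zeros dropped, mid-ranks on |d|. Exact p by
  full enumeration of all 2ⁿ sign assignments for n ≤ 12 (exact even
  under rank ties); standard exact distribution for n ≤ 25 without
  ties; otherwise normal approximation with continuity and tie
  correction.
* **Mann–Whitney U**: exact by enumeration of group assignments for
  m + n ≤ 14; standard exact for m + n ≤ 20 without ties; otherwise
  tie-corrected normal approximation with continuity correction.

Cohort tables apply the signed-rank test to the two groups by pairing
eyes in row order, the convention of the clinical literature this
pipeline serves — statistically questionable for independent cohorts,
so a warning documents the caveat on every such run; with unequal group
sizes the pipeline falls back to the rank-sum test (with a warning).
Both tests' type-I rates at α = 0.05 are verified to lie in
[0.03, 0.07] over 1000 null simulations of 27 + 27 cohorts.

The MNV subgroup contrast (diseased eyes with vs without macular
neovascularization) is a manifest filter plus the Mann–Whitney test,
not special-cased code.

## Synthetic data

The generator emulates a 6 × 6 mm choriocapillaris en-face pair at
512 px (6.6 µm/px) per eye:

* **Void texture**: white noise smoothed with a Gaussian of physical
  scale `correlation_length_um` (default 24 µm, the intercapillary
  distance of the choriocapillaris; recommended thresholding windows
  are 1–2 × this scale, i.e. 4–8 px), thresholded at the empirical
  void-fraction quantile. Quantile thresholding pins the realized void
  fraction exactly (to grid quantization), which is what makes
  parameter-recovery testing possible. Mesh renders at 0.75, voids at
  0.15, plus Gaussian noise (default SD 0.03, a mild speckle residue
  consistent with device-averaged en-face exports), clipped to [0, 1].
* **Shadowing**: a multiplicative field A = 1 − depth·max(blobs) in
  (1 − depth, 1], Gaussian blobs with σ ∈ [80, 250] µm (deposit scale)
  at random centers; default depth 0.5, 4 blobs. The same A multiplies
  the flow image and the structure image (bright base 0.8 plus fine
  texture), exactly the artifact the compensation stage assumes.
  A deliberate limitation: shadowing is purely multiplicative, so the
  mesh/void contrast survives inside shadows and the locally adaptive
  threshold degrades only mildly there; real shadows also collapse the
  flow signal toward an unattenuated noise floor, an effect this model
  excludes because multiplicative compensation could not undo it and
  no stage could then be validated against ground truth.
* **Cohorts**: per-eye seeds derive from (master seed, eye index), so
  any eye regenerates in isolation. Controls draw void fraction from
  N(0.39, 0.06²) truncated to (0.02, 0.98); diseased eyes from
  N(0.48, 0.08²) and additionally use a longer correlation length
  (32 µm vs 24 µm): diseased choriocapillaris shows larger, more
  confluent deficits, and void fraction alone does not reproduce the
  larger-but-fewer deficit signature at a fixed texture scale. 75% of
  diseased eyes are labeled MNV (21/27, the typical prevalence).

What passing tests show — and what they do not: the generator's
bimodal, stationary texture validates the measurement chain
(compensation, thresholding, particle metrics, statistics) against
exact ground truth; it does not model OCTA speckle physics, projection
artifacts, vessel-density gradients with eccentricity, or lobular
choriocapillaris architecture, so absolute FD counts and sizes are not
comparable to device data (the synthetic voids are fewer and larger
than real intercapillary gaps at equal area fraction).

## Problem sizes and numerical choices

Simulation sizes used by the test suite and the acceptance script —
512² images; 27 + 27-eye cohorts; recovery grid of 4 void fractions ×
5 seeds; 20 compensation trials; 1000 null simulations — were chosen to
estimate each property comfortably on a laptop-class single core (the
whole suite runs in well under a minute of simulation time). Variance
is clipped at zero in the local-stats filter to absorb floating-point
cancellation; the sliding-window oracle equivalence is asserted
bit-for-bit on the binary masks and to 10⁻¹⁰ on the statistics.
Degenerate inputs are defined, not special-cased: all-zero images are
all-deficit, empty masks yield zero metrics, all-equal paired samples
report a flagged degenerate test with p = NaN.

## Known limitations

* The pipeline consumes device-exported en-face pairs; it does not
  segment slabs from OCTA volumes or correct segmentation errors.
* Inter-eye correlation (two eyes of one patient) is ignored by the
  row-order-paired signed-rank convention; a mixed-effects treatment is
  out of scope by design.
* Retinal-vessel projection artifacts are not removed.
* Whole-image (6 × 6 mm) FD quantification is not offered; metrics are
  defined on the four peripheral corner ROIs only.
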