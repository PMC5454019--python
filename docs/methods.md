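# Methods

## Signal model

Three-filter sensitized-emission FRET assumes the raw FRET channel is a
linear mixture: a fraction `d` of the donor signal and a fraction `a`
of the acceptor signal leak into it, on top of any genuine sensitized
emission. The corrected image is the pixel-wise residual

    FRETc = rawFRET − d·DF − a·AF

and, because FRETc scales with the local fluorophore amounts, the
normalized value `NFRET = FRETc / √(DF·AF)` is used to compare sites
with different staining intensity. Both are computed on the raw integer
channels promoted to float64; no smoothing or background subtraction is
applied first. Negative FRETc values are preserved in every statistic —
clipping at zero would rectify noise and bias object means toward
false-positive FRET — and are only clipped for pseudo-color rendering.
NFRET is undefined (NaN, excluded from all aggregates, empty in CSV)
where `DF = 0` or `AF = 0`; writing 0 there would masquerade as a
measured null.

## Bleed-through calibration

`d` and `a` are estimated from single-stain controls as the
least-squares slope through the origin of rawFRET against the stained
channel, over thresholded, unsaturated pixels (≥ 50 required; the
built-in controls provide > 10⁴). The through-origin slope is the
direct estimator of the proportionality the correction assumes and is
insensitive to intensity heterogeneity; median per-pixel ratio and
ratio-of-sums estimators are available as cross-checks. Negative fitted
slopes are clipped to 0 with a warning; factors ≥ 1 warn (the control
is probably not single-stained).

No background is subtracted by default. This leaves a small structural
bias: in an acceptor-only control the donor-channel *background* still
bleeds into rawFRET, adding roughly `d·bg/⟨AF⟩` (≈ +0.007 under the
default synthetic conditions) to the estimate of `a`. The bias is
documented rather than hidden because it is exactly what the same
estimator does on real images without background correction; passing
`subtract_background=True` (low-percentile constant) removes it.

## Segmentation

Channels are thresholded with the same automated method (foreground =
strictly above threshold). Implemented methods: moment-preserving
(Tsai) thresholding — implemented from the histogram-moment equations,
as it is absent from scikit-image — plus Otsu, mean, triangle, and a
manual value. Histograms are built over the full native code range.

Touching objects are split by the classic binary watershed: Euclidean
distance transform, regional maxima as seeds (maxima closer than ~2 px
merged before flooding, so plateaus do not oversegment), 8-connected
flooding with a watershed line, leaving a one-pixel background
separation wherever objects touched. Components are labeled with
8-connectivity and numbered in raster-scan order of their first pixel,
making labelings reproducible to the byte. Components below `min_size`
(default 10 px) are discarded as noise specks. Per-channel masks are
split first and then combined (union = combined regions, intersection =
colocalizing regions); the opposite order is available via
`watershed_before_combine=False`.

### Choice of threshold algorithm

The analysis default is the moments method. It is, however, a
moment-matching rule, and on images whose foreground has a large
within-class variance it places the threshold well inside the
foreground distribution (≈ 0.78 of the object mean under the synthetic
defaults). The truncated lower tail then biases within-object intensity
correlations downward (measured: 0.661 vs a ground-truth 0.702).
Threshold choice should match the staining; for the synthetic
validation scenes, whose object histograms are broad by design, the
scenario analyses and the acceptance script therefore use Otsu, which
lands between the classes and recovers the programmed correlation
(0.6999 vs 0.7018 on true masks). This is an analysis-level choice, not
a change to the library default.

## Per-object statistics

All metrics are computed on the raw (uncorrected) DF/AF intensities —
FRET transfers little enough intensity that its effect on the stain
channels is negligible relative to colocalization itself — over the
union ("combined regions") objects by default, with per-channel and
intersection tables also emitted. Pearson is undefined for zero-variance
objects; acceptor:donor is undefined for `mean_DF = 0`; object NFRET
defaults to the mean of defined per-pixel values, with the
ratio-of-means form `mean_FRETc/√(mean_DF·mean_AF)` as an option (the
two coincide on uniform objects). Color-mix is the per-pixel min/max
ratio averaged over the object (ratio-of-object-means optional).
Objects overlapping any saturated pixel in any channel are flagged and
excluded from aggregates by default — object-wise exclusion, the
pixel-wise masks being available for stricter policies.

The whole-image Pearson is reported alongside deliberately: the
contrast between it and the object-restricted values is the
methodological point.

## Classification and tabulation

The conventional visual three-way call is made explicit: an object is
`one_protein` if the weaker channel's mean stays at or below a presence
threshold (default: that channel's own automated threshold value),
otherwise `two_colocalizing` if its color-mix exceeds a threshold
(default 0.5, deliberately explicit because the original call is
visual), else `two_combined`. Percentages in count tables are
**truncated**, not rounded, to one decimal (25/267 → 9.3; 5/13 → 38.4),
matching the convention of the tallies they reproduce. Group summaries
report mean and SEM of defined object Pearson values; strata with fewer
than two defined values are flagged.

## Synthetic scenes

The generator is the test bed for every stage and instantiates the same
forward model the correction assumes:

    rawFRET = d_true·DF + a_true·AF + S_true·(co-located support) + noise

* **Geometry.** Discs with radius uniform in 6–10 px, randomly packed
  without contact on a 512×512 field; a configurable fraction of pairs
  is co-located (shared center and radius). Objects are hard-edged by
  default (`edge_sigma = 0`): a fractional-coverage rim shared by both
  channels of a pair is a common spatial signal that inflates
  within-object correlation by ~+0.1, confounding exactly the statistic
  the correlated scenarios probe. Thresholding stays non-trivial because
  pixel intensities inside objects are heterogeneous.
* **Intensities.** Object mean 600 counts (±20 % per-object jitter per
  channel), per-pixel SD 100, over a background of 30 counts plus a
  smooth shared "autofluorescence" haze (SD 8, correlation length 8 px)
  present in both stain channels — the dim common structure that excess
  gain amplifies in real overexposed acquisitions.
* **Correlation.** Co-located pairs draw pixel values from a bivariate
  normal. Independent per-channel noise attenuates pixel correlations,
  so the latent correlation is pre-compensated analytically
  (`ρ_lat = ρ·√((σ²+ν_d)(σ²+ν_a))/σ²`, capped at ±1 with a warning);
  the realized correlation of emitted pixels then converges to the
  requested ρ (verified to ±0.05 at object areas ≥ 500 px).
* **Noise and quantization.** Optional Poisson shot noise plus Gaussian
  read noise (SD 2–4), rounding to integer counts at the declared bit
  depth (12 by default).
* **Overexposure.** `clip_ceiling` is the intensity at which the
  detector saturates: the gain is effectively raised so the ceiling maps
  to the ADC full scale and every brighter pixel is pinned at
  `2^bit_depth − 1` — precisely the pixels the saturation audit flags.
  The `overexposed` scenario is the `distinct_localization` scene with
  identical random draws and only this ceiling changed (350 vs 4095).

Scenario defaults (`scenario_library()`): `distinct_localization`
(60+60 disjoint objects, Poisson noise), `overexposed` (same, ceiling
350), `true_interaction` (110 co-located pairs, ρ = 0.7, S = 60,
Gaussian noise SD 4), `donor_only`/`acceptor_only` (70 objects,
d = 0.15 / a = 0.05). The interaction scenario uses Gaussian rather
than Poisson noise so the correlation compensation is exact rather than
mean-dependent.

**What the simulator does not emulate:** real point-spread blur and
out-of-focus light, donor quenching by FRET (sensitized emission is a
purely additive rawFRET term — the Youvan/Xia arithmetic never models
quenching either), chromatic mis-registration, spatially varying
illumination, and non-disc morphologies. Passing tests therefore
demonstrate the correctness of the measurement chain on data obeying
the stated model, not robustness to every optical artifact of real
tissue.

## Numerical choices

* Saturation is judged against the declared bit depth (4095 for 12-bit
  data in 16-bit containers), never the container dtype; the default
  saturation tolerance is 0 (correct exposure admits no saturated
  pixel) and is configurable for deliberate-overexposure comparisons.
* The moments threshold guards its plateau search with a 1e-9 epsilon
  so float round-off cannot skip an exact cumulative-histogram step.
* Watershed seeds, flooding and label order are fully deterministic;
  repeated batch runs with the same configuration produce
  byte-identical pooled CSVs.
* FCS export stores float32 little-endian ($DATATYPE F) so negative
  FRETc values and sub-unit coefficients survive; a CSV twin is always
  written. The FCS 3.0 writer/reader is a minimal in-package
  implementation covering list-mode float data.
* Problem sizes in tests and the acceptance script (512×512 fields,
  ~110–160 objects, 20 small oracle scenes) were chosen as the smallest
  sizes at which the 3-SEM recovery criteria are statistically
  meaningful.

## Known limitations

* FRET efficiency (E %), acceptor photobleaching and lifetime methods
  are out of scope; FRETc/NFRET are relative indices, not molecular
  distances.
* Bleed-through factors are treated as per-run constants; drift within
  a session is not modeled.
* 2-D only; no channel registration or flat-field correction — inputs
  are assumed co-registered and shading-corrected upstream.
* The classification thresholds digitize an inherently visual
  convention; they are exposed in the configuration rather than
  inferred from data.
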