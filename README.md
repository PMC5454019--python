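# fretcoloc

Object-based colocalization and sensitized-emission FRET analysis for
three-channel fluorescence microscopy, with built-in synthetic ground
truth.

## The problem

Deciding whether two immunolabeled proteins *colocalize* — or are even
close enough to interact — is notoriously easy to get wrong with merged
two-color images. Whole-image pixel correlations are inflated by shared
background, and detector saturation manufactures convincing yellow
overlap out of strictly disjoint structures. `fretcoloc` implements the
combined remedy used in high-content tissue imaging: segment the stains
into objects, compute colocalization statistics *per object*, and add a
bleed-through-corrected FRET channel as an independent proximity
reporter, all with an explicit saturation audit.

The package is aimed at microscopists analyzing antibody double-stains
(e.g. protein aggregates in neurodegenerative disease tissue), and at
method developers who need a fully synthetic, ground-truthed test bed
for colocalization pipelines.

## The measurements

For a triple of co-registered channels — donor emission `DF`, acceptor
emission `AF`, and the raw FRET channel (acceptor emission under donor
excitation) — the corrected and normalized FRET images are

```
FRETc = rawFRET − d·DF − a·AF          (Youvan correction)
NFRET = FRETc / √(DF·AF)               (Xia normalization)
```

where the bleed-through fractions `d` and `a` are estimated from
donor-only / acceptor-only control images as the least-squares slope
through the origin of rawFRET against the stained channel.

Objects come from an automated histogram threshold (moments, Otsu, mean,
triangle, or manual) followed by a Euclidean-distance-map watershed that
separates touching objects with a one-pixel background line. The donor
and acceptor masks are combined pixel-wise into union ("combined") and
intersection ("colocalizing") regions. Each object is scored with:

* **object Pearson** — product-moment correlation of (DF, AF) pixel
  pairs inside the object;
* **color-mix coefficient** — mean per-pixel `min(DF,AF)/max(DF,AF)`,
  1 = complete two-channel mix, 0 = single marker;
* **acceptor:donor ratio**, **mean NFRET**, and the **colocalization
  area fraction** (intersection as % of union);
* a **saturation flag** for objects touching any clipped pixel.

A classification step reproduces the conventional three-way tally
(`one_protein` / `two_combined` / `two_colocalizing`) with explicit
thresholds, and batch results export as CSV and FCS 3.0 for
cytometry-style gating and density plots.

## Worked example

```python
import fretcoloc as fc

stack, truth = fc.generate_scene(fc.scenario_library()["true_interaction"])
factors = fc.BleedthroughFactors(d=truth.d_true, a=truth.a_true)
result = fc.analyze_triple(stack, factors, threshold_method="otsu")
print(len(result.object_table),
      result.object_table["pearson"].mean(),
      result.object_table["mean_NFRET"].mean())
```

Running `python examples/01_simulate_and_analyze.py` prints:

```
objects found (union of both channel masks): 111
mean object Pearson : 0.700  (pixel correlation of the two stains inside each object; 1 = perfect)
mean object NFRET   : 0.0992  (corrected FRET per unit stain; > 0 indicates molecular proximity)
coloc area fraction : 95.2 %  (overlap of the two masks as % of their combined area)
whole-image Pearson : 0.978  (the classic full-frame statistic, for comparison)
```

The scene was generated with pair correlation ρ = 0.7 and sensitized
emission S = 60 counts on objects of mean intensity 600, so the mean
object Pearson of 0.700 and NFRET of ≈ 0.10 (= 60/600) recover the
ground truth. The complementary negative control
(`examples/03_overexposure_artifact.py`) shows the same pipeline on
spatially disjoint stains:

```
correct exposure  saturated fraction 0.000  whole-image Pearson -0.0394  mean color-mix 0.047
overexposed       saturated fraction 0.044  whole-image Pearson -0.0309  mean color-mix 0.085
```

— overexposing the identical field raises both colocalization scores,
which is exactly the artifact the saturation audit is there to catch.

Each script in `examples/` demonstrates one capability: simulation +
analysis, bleed-through calibration, the overexposure artifact, batch
processing with FCS export, and the conventional count tables. The same
workflow is available from the shell:

```
fretcoloc simulate --scenario donor_only --out sim/
fretcoloc calibrate --donor-control ... --acceptor-control ... --out factors.json
fretcoloc analyze donor.tif acceptor.tif rawfret.tif --factors factors.json --out results/
fretcoloc batch --config run.yaml
```

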