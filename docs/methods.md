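# Methods

## Problem and imaging model

Nile Red is a solvatochromic dye: in one acquisition the phospholipid
signal (membranes, diffuse cytoplasm) is collected in a red channel and
the neutral-lipid signal (intracellular droplets) in a green channel.
Monocytes are imaged as z-stacks at 1,024² × 8 bit and collapsed by
maximum intensity projection, so droplets at any depth appear in one
countable 2-D image. Droplets in non-adipocytes are small (≲ 3 µm) and
near-circular; cells are ellipse-like, ~15–20 µm across.

The quantification is deliberately *semi*-automated: one user click per
cell replaces automatic cell detection, which is unreliable for touching
monocytes. Everything downstream of the clicks is deterministic — fixed
image + seeds + config reproduce outputs bit-identically, and every run
can be replayed from its JSON manifest.

## Pipeline stages and parameters

**Preprocessing.** Grayscale is BT.601 luminance (`0.299R + 0.587G +
0.114B`), the canonical luminance definition for 8-bit RGB. The grayscale
is morphologically opened with a rasterized disk and then contrast
stretched between the 1st and 99th intensity percentiles. The opening
radius is the one preprocessing parameter that matters: it must exceed
the radius of the largest droplet (so droplets and the ~2 px membrane
ring are erased and the cytoplasm plateau dominates the stretch) while
staying far below the cell scale. Default 7 px against droplets of ≤ 6 px.
With a too-small disk, bright droplets capture the upper stretch
percentile and the active contour at high droplet load collapses onto the
droplets instead of the cells.

**Cell segmentation.** Each seed is stamped with a flat-top regular
octagon (circumradius 8 px by default). Rasterization note: a pixel is
included when its center satisfies all eight half-plane constraints pushed
out by half a pixel — with a strict half-plane test an octagon of
circumradius 1 would contain only its center pixel, which contradicts the
intended "mark" semantics (radius 1 covers the full 8-neighborhood).

The stamps initialize a two-phase piecewise-constant active contour
(morphological Chan–Vese): boundary pixels flip toward the phase mean they
are closer to, followed by the alternating sup-inf/inf-sup curvature
smoothing (default strength 1). The smoothing alternation parity is
derived from the iteration index, keeping the evolution a pure function of
its inputs (a library implementation with global operator state was
rejected for breaking determinism). Evolution stops when the region
changes by < 0.1 % of its pixels per iteration (checked every 5
iterations) or at 200 iterations, in which case the result is returned
with a warning flag.

The converged foreground is hole-filled (droplets are brighter than
cytoplasm and must not punch holes), restricted to components containing a
seed, and split between seeds sharing a component by nearest-seed distance
(ties to the lower seed index). A seed whose region ends below 20 px is a
*failed* seed: it is excluded from all denominators rather than counted as
a negative cell, protecting the % positive statistic. Labels touching the
image border are removed — droplet counts there are incomplete — and the
remaining labels are dilated by 3 px so droplets hugging the membrane are
captured; contested pixels go to the nearest pre-dilation label.

**Droplet segmentation.** On the original color image, a pixel is droplet
foreground when its hexcone-HSV coordinates satisfy hue ∈ (60°, 180°)
(green, wraparound windows supported), saturation ≥ 0.25 and value
≥ 0.15. Background correction intersects this mask with the dilated cell
masks; everything extracellular (staining debris, artifacts) is discarded,
and by construction zero droplet pixels remain outside cells. 8-connected
components under 4 px are dropped as speckle.

**Shape measurements and multiplicity.** Per component: area, perimeter,
centroid, circularity `4πA/P²`, eccentricity. The perimeter is estimated
from the crack boundary using the 4-direction Crofton formula. This choice
is load-bearing: a naive 2-direction crack count measures the Manhattan
perimeter, which makes fused droplet pairs look almost as circular as
disks (circ ≈ 0.87 vs 1.0) and defeats the circularity gate, while the
Crofton weighting separates them (pairs ≤ ~0.8, digital disks 0.89–0.94;
rasterized disks of radius ≥ 4 measure within [0.85, 1.1]). Circularity
can exceed 1 for few-pixel blobs; only the ≥ 0.8 gate is interpreted.

Touching droplets merge into one component, so components are assigned a
multiplicity via area quantization: with `ref` the median area of
components with circularity ≥ 0.8 (fallback: median of all, flagged), a
component is 1 droplet if `area ≤ 1.5·ref` *or* circularity ≥ 0.8, else 2
if `area ≤ 2.5·ref`, else 3 (capped — the annotation scheme recognizes at
most triples). All constants are config-exposed. The known limitation:
with droplet radii spanning 2–6 px (a 9-fold area spread), a pair of
large droplets exceeds `2.5·ref` and is counted as a capped triple,
indistinguishable by area/circularity from a true triple of mid-sized
droplets. Errors are near-symmetric (small pairs undercount, large pairs
overcount); per-FOV totals stay within ~10 % and batch totals within ~4 %
at a 30 % merge fraction.

**Quantification.** A component belongs to the cell under its centroid
(centroid on background → largest pixel overlap, ties to the lower
label). A cell is lipid-positive iff its mask overlaps at least one
droplet pixel — equivalent to the subtract-the-inverted-droplet-mask
construction (any "lost area pixels" ⇔ nonempty overlap), which the test
suite asserts pixel-for-pixel. "LDs per positive cell" averages over
positive cells only; sample summaries are unweighted means over FOVs
(weighting by cell count is a defensible alternative; unweighted was
chosen for robustness to FOV-to-FOV seeding density). Fold changes divide
sample means of FOV means, i.e. group-mean normalization rather than
matched-pair normalization.

## Validation statistics

ICC is the single-measurement two-way model from the ANOVA mean squares
(MSR, MSC, MSE): absolute agreement ICC(2,1) =
`(MSR−MSE)/(MSR+(k−1)MSE+k(MSC−MSE)/n)`; consistency ICC(3,1) drops the
rater-variance term. Absolute agreement is the default, the standard
choice for inter-observer agreement on the same images; which form the
original validation used is not recoverable, so no attempt is made to
match published ICC values (they also require the original images). The
paired CV is `100·sd(a−b)/mean(a∪b)` with the sample SD; "mean of the
sample" is read as the pooled mean of both measurement columns.
Regression is plain OLS with r² = squared Pearson correlation; constant-y
input defines r² = 0 with a warning. Estimates are cross-checked in the
tests against a hand-coded ANOVA decomposition, pingouin, and the normal
equations.

## Synthetic world

The generator renders what the pipeline needs to be tested against, not
microscope physics. Defaults (512² FOV, ~0.18 µm/px equivalent):

| parameter | default | rationale |
|---|---|---|
| n_cells | 6 | sparse seeding; dense clusters defeat seeded splitting |
| cell radii | 35–55 px | monocyte radius 7–10 µm at this scale; ellipses, axis ratio ≤ 1.5 |
| droplet radii | 2–6 px | sub-cellular droplet range |
| droplet_rate | 8 per cell (Poisson) | lipid-laden monocytes show ~10 droplets; also keeps the zero-truncation bias of "LDs per positive cell" negligible: at rate λ the measure is λ/(1−e^{-λ}), so a rate doubling reads as ×2.00 at λ=8 but only ×1.46 at λ=1 |
| merge_fraction | 0.1 | fraction of *droplets* placed touching an equal-sized neighbor (pairs, occasionally triples; centers 2r−0.8 apart: connected but minimally fused) |
| artifact_rate | 5 per FOV | extracellular bright spots, kept ≥ 8 px from any cell so even dilated masks exclude them |
| noise | σ=8 Gaussian + Poisson shot noise | stressed 8-bit acquisition; clean renders must switch noise off explicitly |

Intensities: membrane ring 220, cytoplasm 90, droplets 210, artifacts 230;
edges anti-aliased by 4× supersampled coverage. Droplets keep ≥ 1 px
clearance from the cell boundary and ≥ 3 px from other droplet clusters,
so in a clean render no droplet pixel lies outside its owner and no two
planned clusters fuse by accident. Cells are placed by rejection sampling
without overlap; a request that cannot be placed raises rather than
silently thinning the world (an earlier version dropped unplaceable
droplets silently, which truncated dose-response curves).

**What a green test does and does not establish.** The synthetic cells are
high-contrast ellipses on black; real monocytes have texture, uneven
staining, neighbors in contact, and out-of-focus haze. Exactness on clean
synthetics and near-exactness under synthetic noise establish internal
consistency of the chain (segmentation → correction → counting →
statistics), not field performance on patient material. The published
accuracy of this class of tool against human counting (r² ≈ 0.8) is not
reproducible here because it requires the original images; the harness
instead demands a *stronger* bound (r² ≥ 0.95, slope 0.9–1.1) against
perfect ground truth.

## Numerical and degenerate-input choices

* 16-bit inputs are accepted via linear min-max rescale to 8-bit, with a
  warning.
* Contrast stretch of a constant image returns it unchanged with a
  warning; ICC of a table with zero between-subject variance is defined
  as 0 with a warning.
* Percentiles use numpy's linear interpolation; all rounding is
  round-half-even via `np.rint`.
* Ties are always broken toward the lower label/seed index; component
  labels follow seed-file order, making outputs stable under relabeling.
* Batch runs isolate per-image failures by default (`strict=False`),
  reporting a failure count instead of aborting a clinical batch.
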