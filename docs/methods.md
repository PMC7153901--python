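# Methods

This note documents the models implemented in gonadscan, the
parameters that matter, what the synthetic data do and do not emulate,
and the numerical choices made where the procedure left room.

## Cell-diameter coordinates and linescans

The gonad's distal–proximal axis is measured in cell diameters (cd):
one row of germ nuclei per unit, roughly 3 µm (~30 px at the 63×
/ ~0.1 µm-per-pixel imaging scale emulated here). `trace_axis` chains
nucleus centroids greedily by nearest neighbor starting from a
user-supplied distal tip, and places cd boundaries midway between
successive centroids with the first boundary at the tip. The
procedure needs n_cd + 1 chainable nuclei; with exactly n_cd the last
boundary is extrapolated by half the final spacing, and with fewer it
raises. A hand-drawn polyline with markers (e.g. exported from Fiji)
can be supplied verbatim by constructing `AxisTrace` directly; both
routes give identical downstream profiles for identical geometry.

`linescan` samples a perpendicular band (default width 75 px) at 1-px
arc steps with nearest-pixel lookup. Each sample takes the per-pixel
maximum over the selected z-slices — out-of-focus stretches of a
dissected gonad make single-slice reads unreliable, and the maximum
over a small slice set is the standard remedy. Slice choice on real
data was ad hoc; the reproducible default here is the two brightest
slices by band mean, configurable to any explicit slice set. Band
pixels are averaged (not summed) per position so values do not scale
with band width; pixels falling outside the image are excluded with a
warning. `profile_by_cd` averages scan values within each cd interval
(left-closed, right-open, with a 1e-6 px guard against float fuzz in
marker positions); an empty interval indicates mismatched geometry and
raises.

## Background subtraction and internal normalization

Staining of an untagged strain (no epitope) measures non-specific
signal; its per-cd mean is subtracted from every tagged profile.
Negative differences are clipped to 0 but the pre-clip values are kept
(`raw_corrected`) for audit. Profiles co-processed in a batch are then
scaled by a single factor, 100 / (control mean over the peak window),
where the control is the tagged protein in an otherwise wild-type
background — so all genotypes are expressed as "% of control peak" and
ratios between cds are untouched. Peak readout is the window mean for
narrow peaks (LAG-1: cd 4) and the window maximum of the mean profile
for broad peaks (FBF-2: cd 8–13). Note the maximum rule is upward
biased on flat profiles by ~1.27× the per-cd standard error (expected
maximum of six near-equal noisy values); with the shipped noise
settings this is ≲1% and it is a faithful property of the readout, not
corrected for.

Significance of level differences uses a two-tailed Welch t-test when
min(n) < 30 and a two-sample Z-test with per-sample SDs when both
n ≥ 30, with tiers p ≤ 0.0001 (***), ≤ 0.001 (**), ≤ 0.01 (*), else
NS. Welch (rather than pooled-variance Student) is the robust default
since genotype variances need not match; whether the original Z-test
pooled SDs is unknowable from the text, so per-sample SDs are used.

## Percent-contribution decomposition

For a reference peak `P_ref`, a pathway-null peak `P_path` and a
targets-null peak `P_tgt` (all background-subtracted, same batch):
independent = 100·P_path/P_ref, via-targets = 100·(P_ref−P_tgt)/P_ref,
other = the remainder. Percentages are reported to integer precision
by default with raw floats retained. If the targets-null peak falls
below the pathway-null peak, "other" goes negative; it is clipped to
0 and flagged rather than silently redistributed. The LAG-1 panel
encodes the pathway null at 39% and the targets null at 70% of the
reference peak, so the via-targets term computes to 30%; the conventionally quoted
31% is the same split under rounding of the underlying means, so
tests on this decomposition accept a ±1 point difference. The FBF-2 panel encodes the 15%/85% split with
triple- and quadruple-mutant peaks both at 15% of the reference; the
alternative "~4-fold below the double mutant" phrasing (which would
imply 25%) cannot be reconciled with that split from the available
numbers and is documented here rather than resolved.

## smFISH foci

Foci are connected components of voxels strictly above threshold
(26-connectivity by default, matching typical 3D object-counter
behavior; 6 is available), with `min_voxels = 2` suppressing
single-voxel noise. Centroids are intensity weighted. Assignment to
cd uses the in-plane distance to the nearest axis point: imaging
covers a single surface layer of nuclei (to limit bleaching), so depth
carries no axis information. A focus within half the band width
(default 100 px ≈ 10 µm) is counted in the cd interval containing its
arc-length position — a tie exactly on a boundary goes to the distal
bin — otherwise it is excluded; assigned + excluded always equals
detected. Threshold selection on real data was subjective ("include
most foci"); no automatic selector is imposed, the threshold is an
explicit argument.

## Expression pipeline

CPM is plain counts-per-million; TMM scaling is deliberately omitted
and the synthetic libraries are generated at comparable sizes so
composition bias is negligible. `de_table` tests log2(CPM + 0.5) with
a Welch t-test per gene and Benjamini–Hochberg FDR across genes — a
documented substitution for the moderated limma-voom fit used on the
real data, adequate for synthetic data (see limitations). The
regulated-gene filter applies fold ≥ 2 on the linear scale
(2^|log2fc|), FDR < 0.05 and mean CPM > 2 across all samples of the
contrast (whether the original CPM cut applied to one condition is
unstated; the mean across samples is used). Both activated and
repressed lists can be produced via `direction`.

A primary target must be regulated at the earliest analyzed
degradation time point (default 2 h) **and** carry a ChIP peak; a
secondary target is unbound and regulated only later, consistent with
it responding to loss of the primary targets' protein products (their
half-life bound, 2 h, is the default decay lag for planted
secondaries). An optional contrast between signaling-ON and
primary-targets-null conditions sets a per-gene `targets_dependent`
evidence flag. `half_life_bound` returns the earliest sampled time
with a ≥ 2-fold drop — an upper bound on the half-life, since halving
must have occurred by then; it is conservative by construction
(bound ≥ true half-life for exponential decay). ΔΔCt follows the
standard form: ΔCt against the reference gene (*ama-1*) within each
replicate, ΔΔCt against the reference condition, abundance 2^(−ΔΔCt),
so the reference condition is exactly 1.

## Synthetic data: what it emulates, and defaults

Profile panels (percent of control peak; converted to fluorescence
units at 5 AU/% over a flat 100 AU non-specific background):

* **fig3 / figS3 (LAG-1, 25 cd):** wild type peaks at 4 cd, falls to a
  base of 100/7 ≈ 14.3% by 17 cd (~7-fold drop, base ~15% of peak).
  The meiotic-entry double null raises the peak ~25% and the 25-cd
  base 4.5-fold (gld-1 single null: 3-fold; gld-2: none). The pathway
  null is 39% of the double-null peak with a gradual distal-to-proximal
  rise; the targets null is 70% of it.
* **fig6 (FBF-2, 35 cd):** wild type peaks at 8–13 cd, ~4-fold above
  its 35-cd base; the double null peaks at 80% of wild type with a
  flat base from 18 cd; pathway- and targets-null are flat at 15% of
  the double-null peak.
* **figS10 (LST-1/SYGL-1 degradation):** distal peak (cd 1–5) scaled
  to 20%/10% at 2 h/4 h for LST-1 and 33%/10% for SYGL-1.

Replicate noise is additive Gaussian per cd per gonad, SD 2% of the
control peak, with 24 gonads per genotype. Neither value is published;
they were chosen for testability — small enough that single-cd
peak/base readouts (standard error ≈ 0.6% of peak after background
subtraction) sit well inside the ~printed precision of the encoded
relationships — and fixture tests use tolerances of three standard
deviations of each statistic's measured sampling distribution.

Images are tubes (radius 50 px) around a polyline axis: one Gaussian
DAPI nucleus per cd (spacing 30 px), a marker channel equal to
background plus the per-cd signal step at each pixel's cd coordinate,
and Gaussian smFISH foci planted at recorded positions (optionally
with a minimum separation so planted counts are recoverable). Camera
noise is Poisson shot noise plus Gaussian read noise and an offset.
Zero-noise configurations are exactly recoverable by the full
pipeline; with shot/read noise the 20-gonad closed loop recovers the
configured means within 5% at every cd (the per-pixel max over slices
contributes a small upward bias that shrinks with signal level). No
PSF, photobleaching or optical sectioning is modeled beyond this.

The expression design (`paper_like`) plants 2000 genes, 137 bound
genes and 94 dependent genes of which exactly two (the primaries) are
bound; three confirmed secondaries and two trend-level genes decay
with 1 h half-life after a 2 h lag, the remaining dependent genes
respond slowly (10 h), and primaries decay with half-life 0.63 h
(a ~3-fold drop by 1 h). ON/OFF uses 5 replicates, the time course 4,
at {0, 0.5, 1, 2, 4, 48} h. Counts are negative binomial
(var = m + φm²) around a composition normalized so configured values
are true CPM, at 30M reads per library (matching the emulated study's
depth) and dispersion φ = 0.002.

## Limitations

* The dispersion is near-technical by design. With only two early
  true positives among 2000 genes, BH at FDR < 0.05 needs p ≤ 5×10⁻⁵,
  and an unmoderated 4-replicate Welch test (df collapsing toward 3)
  only reaches that reliably when per-replicate log2 scatter is ≲0.08.
  Real biological replicates (BCV ~0.1–0.4) would require the
  moderated model this package deliberately does not reimplement — so
  passing tests here demonstrate the pipeline's logic, not that the
  simple test would succeed on real sequencing data.
* Synthetic images have idealized, well-separated nuclei and foci;
  nucleus segmentation is simple blob detection and would not survive
  real clumped DAPI staining.
* Percentages in the decomposition are point values; no bootstrap CI
  is propagated (the underlying replicate profiles are retained for
  anyone who wants to).
* No longitudinal registration across gonads beyond the cd coordinate;
  no mixed-effects modeling of replicate structure.
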