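# Methods

This note records the models, numerical choices and limitations behind each
stage of the pipeline. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Topoisomer distributions and synthetic lanes

A plasmid population is modelled as a probability mass over integer apparent
linking numbers. The generator discretizes a Gaussian — the standard
physical model for a thermal topoisomer ladder — by sampling its density at
the integers within `half_support` of `round(mean_lk)` and renormalizing;
`sd = 0` degenerates to a point mass. Two consequences of this
discretization are worth knowing:

* the realized discrete mean equals the requested mean exactly only when the
  support is symmetric about it (integer or half-integer means); otherwise
  truncation and the lattice-sampling term leave a residual that shrinks
  rapidly with `sd` and support width (≈1e-4 at the default ±4 sd,
  below 1e-9 for sd ≥ 1.2 with a ±8 support);
* gyrase time courses (`simulate_gyrase_timecourse`) shift the mean linearly
  in time and re-discretize with the spread preserved, so two half-steps
  compose to one full step up to the same residual.

A rendered lane is the sum of Gaussian band profiles (area ∝ topoisomer
probability, common width `band_sigma_px`) placed at
`origin + spacing·k − compression·k²`, on a constant-plus-linear background,
with optional additive Gaussian noise whose SD is a fraction of the tallest
band. Position 0 is the top of the gel (well side); larger Lk indices lie
further down. With zero noise, rendering is deterministic regardless of
seed, and the profile integral equals the requested total intensity to
better than 0.5%.

The default scenario mirrors the normalization design of the in-vivo
experiments: reference lanes `ref0` and `ref1` at mean Lk 2.5 and 3.0
(0.5 Lk apart, so one linking number ≡ 2 RSU), one sample lane a full
linking number below `ref0`, sd 1 Lk (≈5–7 bands above the detection floor,
matching the 7–8 visible bands of real gels), 1% band noise, and a gentle
background (30 + 0.01·px). These defaults are the test conditions
throughout; they are not tuning knobs.

What the generator does **not** emulate: chloroquine–DNA binding physics,
nonlinear electrophoretic mobility, lane curvature/smiling, saturation and
blooming of the imager, and correlated (structured) background. Passing the
recovery tests therefore shows the estimator chain is unbiased and stable
under idealized band shapes and additive noise, not that it is robust to
every artefact of a physical gel.

## Densitometry

The chain is: ROI → profile (per-row mean), background subtraction, peak
detection, ladder indexing, weighted mean.

**Background.** Rolling minimum followed by a rolling mean of the same
window (default 180 px ≈ 3 band spacings), clipped at zero. On noisy
profiles the raw rolling minimum chases the deepest noise trough in each
window and leaves a positive residual after subtraction, so the pipeline
estimates the background on a lightly smoothed copy (`presmooth_sigma_px`,
default 4 px in the pipeline; the signal itself is not smoothed by this
step).

**Peak detection.** Local maxima with topographic prominence of at least
`min_prominence_frac` of the profile maximum and a minimum mutual
separation; ties within the separation window keep the topmost peak. The
library default for the prominence floor is 0.05; the pipeline uses 0.02
because a ladder whose mean sits at a half-integer places an edge band's
relative prominence almost exactly at 0.05 (e^−3 ≈ 0.0498 for a band 2.5 sd
out at sd = 1), where 1% noise flips detection and destabilizes the weighted
mean. At the lower floor two guards keep pixel noise out: Gaussian
pre-smoothing before peak picking (4 px, half the band sigma;
area-preserving and center-neutral for symmetric bands) and a minimum peak
width at half prominence (14 px ≈ the band FWHM after smoothing; noise bumps
are about half that wide).

**Integration dialect.** Each band's intensity is the trapezoidal area over
a window bounded by the midpoints to its neighbouring peaks but never wider
than half the median ladder spacing on either side — a "band box". For a
complete ladder the two rules coincide; the cap matters when a band is
missing (its neighbour would otherwise swallow the gap) and at the lane ends
(hundreds of band-free pixels of residual background would otherwise be
attributed to the faint outermost topoisomers, biasing the weighted mean by
~0.1 Lk). How the original ImageJ-style quantification drew its band boxes
is not documented; this is one defensible dialect and is stated here as the
package's convention.

**Ladder indexing.** The topmost detected band takes index 0; each band's
index is its distance from the top in units of the ladder spacing (median
inter-peak distance, after dividing out the integer multiples a missing band
introduces), so a skipped topoisomer leaves a gap in the indices. Two peaks
rounding to the same index raise an error naming the positions.
`quantify_lanes` additionally anchors all lanes of one gel to a shared
origin (the topmost band detected anywhere on the gel) and a shared spacing,
as when reading aligned bands across lanes of a physical gel — without this,
lanes whose faint topmost topoisomer drops below detection would get
inconsistent origins and between-lane differences (RSU, activity) would be
meaningless. In anchored mode a lane's smallest index may exceed 0.

Under the default scenario conditions the chain recovers a lane's true mean
Lk to <0.02 on zero-noise lanes and ≈0.01–0.02 at 1% noise; the test suite
checks both, plus gyrase-rate recovery to 0.1 ΔLk/h at 2% noise.

## Supercoiling statistics

RSU is the linear coordinate of a lane's weighted Lk on the axis defined by
the two reference lanes (0 and 1 RSU); it is invariant under affine
transforms of the Lk scale, and references are only ever used within their
own gel/batch — cross-gel comparison happens on the RSU scale alone. The
package never asserts which direction is "more negative" supercoiling
(the gel does not resolve the sign); results carry both reference labels.

Gyrase activity is `(⟨Lk⟩_final − ⟨Lk⟩_initial)/hours`, signed, with
relaxation negative; relative activity is the percent variation against the
no-polyamine baseline, which maps to 0% by construction.

Tukey's HSD is implemented from its definition: one-way ANOVA within-group
mean square on N−k degrees of freedom, Tukey–Kramer statistics
`q = |mᵢ−mⱼ| / √(MSE/2·(1/nᵢ+1/nⱼ))`, and p-values from the
studentized-range distribution (evaluated via `scipy.stats.studentized_range`;
the surrounding procedure is this package's). If every observation equals
its group mean (MSE = 0), equal means give p = 1 and unequal means p = 0.
Groups of n = 2 are accepted — tiny designs are common in gel work — with a
low-replication warning. The compact-letter display uses insert-and-absorb:
start from one column holding all groups, split every column containing a
significantly different pair, absorb subsets; letters are assigned to
columns ordered by their best-ranked member, with groups ordered by mean
descending and ties broken lexicographically, so output is deterministic.
The tests validate the p-values against statsmodels and against a
100 000-permutation max-q oracle, and fuzz the letter invariant
(sharing ⇔ non-significance).

## Polyamine quantitation

Calibration is an unweighted ordinary-least-squares line of detector
response against concentration over a 4-fold serial dilution (≥3 distinct
levels required; a nonpositive slope is a calibration failure). Inversion
floors negative extrapolations at zero with a warning. Intracellular
concentration is `amount_mol / (cfu · cell_volume · 1e-15 L)` in mM with a
4 μm³ default cell volume. The free fractions (putrescine 0.40, spermidine
0.05) are configured constants taken from binding-equilibrium estimates in
the literature — the equilibrium partition itself is out of scope — and no
default exists for spermine. Censoring at the 0.2 mM detection limit is
inclusive (a value equal to the limit passes); concentrations are reported
to one decimal in mM.

## Expression arithmetic

Fold change is `log2(FPKM_0.8mM / FPKM_10mM)` — low Mg²⁺ over high Mg²⁺,
a direction the published table's header leaves implicit but several rows
fix unambiguously. Zero FPKM is a hard error unless a pseudocount is
supplied (no packaged row needs one). q-values of the form `<x` are stored
as upper bounds and compared as such; the differential flag is
`q < threshold` (default 0.05). Recomputed fold changes match the printed
column within ±0.01 for ≥80% of rows; the residual rows reflect rounding of
the printed FPKM inputs (mostly low-expression genes), so only four
anchor rows with exact agreement at two decimals are used as exact checks.

## Pipeline and determinism

`run_pipeline` validates the configuration first (missing reference labels
fail before any computation), then renders or loads lanes, quantifies them
on a shared ladder, normalizes to RSU, and writes band tables, a
supercoiling report and a JSON summary carrying the package version and a
SHA-256 configuration hash. Per-lane noise seeds derive deterministically
from the run seed, so identical configuration and seed give identical
summaries; an `INCOMPLETE` marker flags aborted runs. Floating-point output
is 4 significant digits in machine files and 2 decimals in reports.

## Known limitations

* Apparent Lk indices are relative; absolute superhelical density σ and the
  sign of supercoiling are out of reach by design.
* The densitometry assumes an approximately uniform ladder; strong spacing
  compression is only exercised synthetically via the quadratic term.
* Whole-gel images must be cut into per-lane ROIs by the caller; there is no
  automatic lane segmentation.
* The permutation oracle and the studentized-range p-values agree closely
  for near-normal data; for grossly non-normal data only the significance
  pattern is expected to match.
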