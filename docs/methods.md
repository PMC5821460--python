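# Methods

This note documents the models implemented in `l1cycle`, the choices
made where the underlying experimental procedures leave the estimator
unspecified, what the synthetic generators do and do not emulate, and
what a green test therefore does and does not establish.

## Exponential-growth age structure

All cell-cycle sampling and the phase-fraction algebra assume an
asynchronous, exponentially growing culture with doubling time `T`
(default 24 h, HeLa). Cell age `a` (time since last division) has
density

    f(a) = (2 ln 2 / T) · 2^(−a/T),  a ∈ [0, T],

so a phase occupying ages `[a1, a2]` holds a fraction
`2(2^(−a1/T) − 2^(−a2/T))` of the population. The inversion
(`durations_from_fractions`) maps a measured phase distribution to
durations via the boundary age `a(F) = −T log2(1 − F/2)` at cumulative
fraction `F`; the round trip is the identity to 1e-9. Default durations
come from inverting the measured asynchronous PI distribution
(G1/S/G2M = 49.5/34.2/15.2 %, renormalized — the printed triple sums to
98.9 % from rounding) at `T = 24 h`, giving
d(G1) ≈ 9.97 h, d(S) ≈ 9.08 h, d(G2/M) ≈ 4.95 h.

## DNA-content deconvolution

`DNAContentModel` fits a per-event DNA-stain histogram with three
components: a Gaussian at the 2N position `mu` with coefficient of
variation `cv` (sd = cv·mu); a 4N Gaussian constrained to mean `2·mu`
and sd `2·cv·mu` (stain signal proportional to DNA content); and an
S-phase bridge modeled as an equal-weight sum of 8 broadened steps at
`mu·(1 + (j−½)/8)`, each with the shared CV — the classic
broadened-rectangle (Dean–Jett–Fox-style) treatment. Parameters
`(mu, cv, fractions)` maximize the multinomial likelihood of a 256-bin
histogram (L-BFGS-B, multiple starts seeded from the histogram peak and
the 1st percentile; `cv` bounded to [0.005, 0.25]). Degenerate inputs
(zero-variance samples) short-circuit to pure G1. At n = 100 000 and
CV 5 % the fitted fractions recover planted mixtures within ±2
percentage points, including a boundary mixture with zero G1. The
8-step bridge is a modeling approximation of the generator's continuous
uniform bridge; the residual mismatch is well inside the ±2 pp
tolerance and is the dominant systematic (about 0.5 pp on S).

## Proximity analysis

Observed statistic: for every nuclear-ORF1p cell, the Euclidean
distance to the nearest other nuclear-ORF1p cell. Null: 1000 draws of
the same number of cells from a reference population (default:
non-nuclear cells, matching the published description of the null as
random localization of non-nuclear cells; an all-cells mode is
provided). Per-cell p-values use the pooled null with add-one
correction, `p_i = (1 + #{null ≤ obs_i}) / (1 + N_pool)` — pooling is
the only choice that resolves per-cell p at 1000 permutations — and
Benjamini–Hochberg FDR. Selection applies to raw p (threshold 0.1);
q-values are reported alongside. The final comparison is a two-sided
Wilcoxon rank-sum of the selected cells' NN distances against the NN
distances within one random same-size sample of non-nuclear cells
(exact for small tie-free samples, normal approximation with tie
correction otherwise).

Calibration caveat, measured on 500 null fields (random labels): the
plain rank-sum p is anticonservative (~8–9 % rejection at α = 0.05)
even without selection, because NN distances within a sample are
dependent — mutual nearest neighbors contribute duplicated values —
violating the iid assumption behind the rank-sum null; the selection
step conditions on small distances and inflates this further. The
report therefore also carries `ranksum_p_calibrated`: the same U
statistic referred to the resampling null itself (two-sided, add-one).
With an exchangeable all-cells null this calibrated test rejects at
5.2 % under random labels; with the non-nuclear null, 7.0 % (the null
subsets partially overlap the comparison sample). Power is unaffected
in practice: planted daughter-pair fields (80 % of nuclear cells in
pairs ~10 µm apart at background NN ≈ 40 µm) give p < 0.001 in 100/100
seeds. The published real-data p (4.4e−13) is not reproducible at desk
scale — the original cell coordinates are not available — so the
planted-signal simulation substitutes for it.

## Compartmental image quantification

Nuclei are segmented from the nuclear-dye channel by subtracting a
morphological-opening background (disk radius 15 px, larger than any
nucleus) and thresholding with an in-package iterative intermeans
(isodata) implementation — cross-checked against scikit-image — then
discarding components below the area of a radius-3 px disk (29 px).
The "circle" is the nucleus eroded by 4 px (Euclidean distance
transform); the "ring" is the annulus 1 < d ≤ 8 px outside the nuclear
edge, clipped at image borders, excluding all nuclei, with contested
pixels assigned to the nearest nucleus (ties to the lower label id).
The per-cell statistic is the mean marker intensity per compartment
(total intensity is also reported; which statistic the original
instrument thresholds is unspecified — mean is the default). Limits are
the maxima of the negative-control per-cell statistics, so re-scoring
the control yields zero positives; on a fresh negative field the
expected false-positive rate is the order statistic 1/(n_control + 1),
which is why recovery experiments should calibrate on ≳100 control
cells. Quantification is covariant under a constant marker-intensity
shift applied to both the image and the limits.

## Synthetic image generator

Cells are rendered as a bright nuclear disk (radius 6 px default) plus
a cytoplasmic annulus (8 px wide) in the marker channel; nuclear marker
signal is added only for nuclear-positive cells; Gaussian noise is
added to both channels. Non-overlap is enforced at the cell-footprint
level — no cell's cytoplasmic annulus may intersect another cell's
nucleus — by jittering placements with bounded retries. This is
deliberate: annulus-onto-nucleus bleed-through cannot be calibrated
away by a marker-free negative control, and real high-content assays
handle confluent fields with segmentation machinery out of scope here.
Not modeled: point-spread function, vignetting, z-structure, spectral
spillover, cell-shape variation. A green recovery test therefore
establishes that the compartment logic and limit calibration are
correct, not that segmentation is robust to confluent or
optically-degraded fields.

## Fluorescent-timer kinetics

Maturation is first order: a blue pool converts to red at rate `k_mat`,
default `ln 2 / 2.35 h⁻¹` so that the red half-rise of a fixed blue
burst occurs at the measured 2.35 h. The conversion-time estimator is
the first time the red trace reaches half of its plateau. On noisy
traces the crossing is read off an isotonic (monotone) regression with
linear interpolation — raw first crossings are biased early by noise —
and the plateau is the mean of the final 20 % of samples. A trace is
excluded (and counted in diagnostics) unless it has flattened: the mean
red signal of the last quarter of the record must exceed that of the
previous quarter by less than 10 % of the total rise. Estimator bias is
below 5 % across `k_mat` ∈ [0.1, 1.0] h⁻¹ at 5 % noise, provided the
record spans the plateau (~10 half-lives).

Expression onset after induction is lognormal, parameterized by the two
measured quantiles (median 2.71 h, 90th percentile 8.01 h:
μ = ln 2.71, σ = ln(8.01/2.71)/z₀.₉ ≈ 0.846). Onset quantiles of a
measured cumulative-visibility curve are linear-interpolated crossings;
a step discontinuity is encoded with a repeated time value.

Timer FACS gating: blue⁺ means blue above a threshold (the "auto" mode
mirrors the imaging rule — the maximum blue among ground-truth
event-free cells); blue⁺ events split at their median red intensity
into red-low (recent events, mainly S phase in S-restricted simulations)
and red-high (older events, mainly G2/M).

## Time courses and slope analysis

Synchronized cohorts start G1 at t = 0 (mitotic release); each cell
acquires at most one retrotransposition event per cycle (default
probability 0.3 per cycle, a plausible per-cycle reporter rate for an
efficiently induced element; the sources report percentages, not
per-cell rates) at a position uniform in S, becomes GFP⁺ once
`event time + detection delay ≤ t`, and stays GFP⁺. Slopes are forward
finite differences of the cumulative GFP⁺ percentage; the peak interval
is the argmax; intervals are annotated with the phase occupying the
majority of them under supplied phase windows (from the cell-cycle
model for synchronized cohorts). A series is flagged "no peak" when the
maximal slope is below 1.5× the median slope — unsynchronized control
cohorts rise approximately linearly and always raise the flag at the
default simulation size.

## Interactome rules

"Found in an experiment" means ≥1 unique peptide in that experiment's
bait (V5) channel, after a global ≥2-unique-peptide filter (at least
one bait channel with ≥2; a strict per-experiment mode is available —
the original description does not say which applies). Classes: red =
found in both experiments, IgG empty in both; orange = found in both,
IgG hit in ≥1; yellow = found in exactly one, IgG empty in both; gray =
everything else, including the single-experiment-with-IgG case the
published legend leaves undefined. Classification is invariant to row
order and to positive scaling of counts. The published per-experiment
exclusive-interactor counts (279 and 158) require the original
supplementary protein table, which is not redistributed here; the
planted-class construction oracle substitutes.

## Numerical and reproducibility conventions

Distances in µm (pixel measurements convert via the image pixel size);
times in hours; intensities in arbitrary units (DNA 2N ≡ 100). Rasters
are row-major with pixel centers at integer coordinates. Every
generator takes one integer seed and is bit-reproducible; analysis
randomness (permutations, comparison-sample draws) is seeded
separately. Daughter-pair separation defaults to 15 ± 5 µm (truncated
normal at 0) — the imaging observation is only "close proximity", and
this sits within one cell diameter of typical HeLa spreading — and the
DNA-content CV defaults to 5 %, a typical PI histogram width.

## Known limitations

- Nuclear positivity is a static label per snapshot; ORF1p nuclear
  export kinetics after G1 are not modeled (no quantitative model is
  available).
- The DNA-content fit assumes a shared CV and an exactly 2× 4N/2N
  ratio; aneuploid or poorly stained samples violate both.
- The proximity test models fields as homogeneous; real slides have
  density gradients that the within-slide resampling null absorbs only
  partially.
- No flow compensation/spillover, no microscope optics, no spectral
  search or protein inference for MS data.
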