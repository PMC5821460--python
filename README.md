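# l1cycle

Quantitative analysis of LINE-1 (L1) retrotransposon protein dynamics
across the cell cycle — as a tested, reusable Python package exercised
end-to-end on synthetic data with full ground truth.

L1 is the only autonomous human retrotransposon still active today. Its
two proteins, ORF1p (RNA chaperone) and ORF2p
(endonuclease/reverse-transcriptase), must reach the nucleus for a new
insertion; imaging and reporter experiments show that ORF1p enters
during mitosis, is nuclear in G1, and that retrotransposition itself
peaks in S phase. This package implements the statistical machinery
behind those conclusions for anyone analysing similar single-cell
imaging, flow-cytometry or IP-MS data:

- **Proximity testing** (`l1cycle.proximity`) — are cells with nuclear
  ORF1p post-mitotic daughter pairs? Nearest-neighbor (NN) distances of
  labeled cells are compared against a resampling null (1000
  permutations of equal-size random cell subsets), per-cell permutation
  p-values get a Benjamini–Hochberg FDR, and the selected cells
  (p ≤ 0.1) are compared with a random unlabeled sample by a Wilcoxon
  rank-sum test. A permutation-calibrated rank-sum p is reported
  alongside, because NN distances within a sample are dependent and the
  textbook rank-sum null is slightly anticonservative.
- **Compartmental image quantification** (`l1cycle.imgquant`) —
  Arrayscan-style analysis: isodata (intermeans) nucleus segmentation
  after morphological background subtraction, a "circle" eroded 4 px
  inside the nuclear edge and a "ring" 1–8 px outside it, positivity
  limits set from a negative control so that *no* control cell scores
  positive, and
  `percent_nuclear = 100 · n(nuclear⁺) / n(cytoplasmic⁺)`.
- **Cell-cycle quantitation** (`l1cycle.cyclekin`) — closed-form phase
  fractions for an exponentially growing population
  (`f(a) = (2 ln2/T)·2^(−a/T)`), maximum-likelihood DNA-content
  deconvolution (2N/4N Gaussians bridged by a broadened-step S phase,
  Dean–Jett–Fox style) via `DNAContentModel(...).fit()`, slope analysis
  of cumulative GFP⁺ retrotransposition time courses, fast
  fluorescent-timer (blue→red) maturation and expression-onset
  estimation, timer FACS gating, FUCCI contingency counts and
  western-blot loading normalization.
- **Interactor classification** (`l1cycle.interactome`) — ≥2-unique-
  peptide filtering, per-experiment V5/IgG exclusivity, and the
  red/orange/yellow/gray confidence classes for replicated IP-MS.
- **Synthetic data with ground truth** (`l1cycle.synthgen`) — seeded
  generators for every input above: daughter-pair cell fields,
  two-channel microscopy rasters, DNA-content/timer flow tables,
  synchronized-release time courses and planted-class peptide tables.

Defaults are calibrated to the published single-cell measurements:
doubling time 24 h, asynchronous phase distribution
G1/S/G2M = 49.5/34.2/15.2 %, timer conversion time 2.35 h
(`k_mat = ln2/2.35 h⁻¹`), and a lognormal expression-onset delay with
t₅₀ = 2.71 h and t₉₀ = 8.01 h.

## Worked example

```bash
l1cycle demo --seed 7 --out demo_out
```

```
percent nuclear = 22.3%  (truth 22.3%)
Nuclear-ORF1p proximity analysis
================================================
nuclear-positive cells (k):     67
permutations:                   1000 (source: non_nuclear_cells)
median observed NN distance:       15.07 um
median null NN distance:           35.77 um
cells selected at p <= 0.1:    23
rank-sum p (selected vs random sample): 3.156e-08
rank-sum p (all nuclear vs random sample): 5.891e-06
rank-sum p (permutation-calibrated):       0.001998
```

The demo plants daughter pairs of nuclear-positive cells (~15 µm apart)
in a 600×600 µm field, renders it into a two-channel image, recovers the
nuclear fraction through segmentation + compartment scoring (22.3%
measured vs 22.3% planted), and detects the pair clustering: the median
NN distance of nuclear cells (15 µm) is far below the resampled null
(36 µm), giving rank-sum p ≈ 3×10⁻⁸.

The same machinery from Python:

```python
from l1cycle import synthgen, DNAContentModel, defaults

facs = synthgen.gen_facs_snapshot(
    n=100_000, event_rule="fixed_phase_mixture",
    mixture=defaults.BLUE_RED_LOW_FRACTIONS, seed=0)
res = DNAContentModel(facs.events["dna"]).fit()
print(res.summary())      # fitted S fraction ~78% for the blue+/red-low gate
```

Other subcommands: `l1cycle synth {field,image,facs,timecourse,peptides}`,
`quantify`, `proximity`, `deconvolve`, `slopes`, `ft-estimate`, `gate`,
`fucci`, `western`, `interactome`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from freshly generated synthetic data, the package's
headline recovery quantities: the mean timer conversion time estimated
from 500 noisy single-cell traces (t1), the 50%/90% visible-reporter
onset times from 10 000 simulated delays (t2, t3), and the fitted
S / G2-M / G1 percentages from DNA-content deconvolution of
100 000-event samples generated at the measured phase mixtures of the
blue⁺red-low, blue⁺red-high and blue⁻ populations (t4–t6). See
`docs/methods.md` for models, assumptions and limitations.
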