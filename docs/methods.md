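# Methods

## Sequence conventions

The guide (antisense) strand is the canonical sequence for every siRNA
feature. Positions are 1-based 5′→3′ along the guide: 1–19 are the core that
base-pairs with the mRNA, 20–21 the 3′ overhang. The overhang contributes to
the one-hot sequence codes only; k-mer frequencies, the stability profile
and the rule codes use the 19-nt core. Binding sites are found as the
leftmost exact occurrence of the reverse complement of the core on the
target (mismatch-tolerant search is out of scope); an explicit `site_start`
column overrides the search. Internally coordinates are 0-based half-open,
1-based in files and reports.

The binding-site *neighborhood* — the region whose composition enters the
quantitative representation — is the site extended by W nt on each side,
clipped at transcript ends. W defaults to 20 nt. This is a genuinely free
parameter: "near the binding site" has no standard width, and 20 nt keeps
the neighborhood (≤ 59 nt) large enough for stable trinucleotide
frequencies while remaining local. It is configurable everywhere.

## Thermodynamics

Duplex stability uses the classic RNA/RNA nearest-neighbor model: each of
the 18 adjacent dinucleotides of the core, assumed fully Watson–Crick
paired, contributes a stacking free energy ΔG (kcal/mol, 37 °C) read from a
packaged parameter table; ΔG_duplex is their sum (exactly, by construction)
and the terminal asymmetry ΔΔG is the 5′-window stack sum minus the
3′-window stack sum, each window covering the 4 stacks fully inside the
terminal 5-mer. The sign convention makes ΔΔG negative when the 5′ end of
the guide is the more stable end. The shipped default is the Freier et
al. 1986 parameter set (16 stacks, +3.4 kcal/mol duplex initiation); the
table is pluggable (e.g. Turner 2004) but all golden tests pin the shipped
file, since no absolute energies are asserted beyond it.

The siRNA–mRNA interaction is summarized by the RNAup decomposition:
ΔG_s and ΔG_m, the non-negative costs of opening the binding region in the
siRNA and the mRNA, and ΔG_h, the (negative) hybridization gain. Two
backends exist. `"rnaup"` shells out to ViennaRNA's `RNAup -b
--interaction_first` and parses the printed `(total = ΔG_h + ΔG_m [+
ΔG_s])` decomposition, checking the sum to 0.01 kcal/mol; results can be
cached to a TSV sidecar keyed on (guide, target, site) so reruns and test
suites never need the binary. `"fallback"` assumes a perfectly accessible,
perfectly complementary site: ΔG_h from the nearest-neighbor sum plus
initiation, ΔG_s = ΔG_m = 0. The fallback is the default because it is
deterministic, dependency-free and preserves the feature-vector contract;
with it, ΔG_s/ΔG_m are uninformative constants and ΔG_h is collinear with
ΔG_duplex — a documented degeneracy, not a bug. Which of RNAup's two
unpairing terms is "siRNA" vs "mRNA" is configurable in the parser mapping;
the default maps the long-sequence term to the mRNA.

## Feature representations

F_Qt (275 dims, canonical order): guide 1/2/3-mer frequencies (4+16+64,
lexicographic A<C<G<U, overlapping windows, denominators L−k+1 so every
block is a proper distribution), 18 stacks, ΔG_duplex, ΔΔG, ΔG_s, ΔG_m,
ΔG_h, then mRNA-global and neighborhood 1/2/3-mer blocks. The order and
names are frozen so that selection indices are portable across runs.

F_Ql (103 dims): 84 one-hot codes (position-major, channels A,C,G,U,
overhang included) and 19 rule codes from the packaged majority-compiled
positional table. The table is shipped as reviewed data with per-cell
provider provenance; the compilation from the 12 primary rule sets is *not*
re-run (their raw contents are not available here). One known internal
tension in the source material: its prose worked example argues (position 9,
U) resolves to +1 by majority, while its printed compiled table assigns −1.
The shipped table follows the printed table; the data file flags the cell.

## Feature selection

F-scores use the standard two-class form: numerator
(x̄⁺−x̄)² + (x̄⁻−x̄)², denominator the sum of the two unbiased (1/(n−1))
within-class scatters. Zero denominator with separated means yields a +inf
sentinel ranked first; constant features score 0; ties and sentinels break
by original feature index. Classes come from the 70% knockdown threshold
(boundary inclusive — the convention chosen here; nothing downstream is
sensitive to the boundary).

The subset-size scheduler halves from the full dimension while the
evaluation score improves; at the first drop it bisects the bracket
(lo = first failing size, hi = last improving size) with integer midpoints
lo + (hi−lo)//2, moving lo up when the midpoint fails to beat the best score
and hi down when it improves, and stops when at most one untested size
remains strictly inside the bracket. The returned size is the best-scoring
one visited. The evaluation function used by `SirnaEfficacyModel.fit` is the
cross-validated (default 5-fold, seeded) PCC of a linear ε-SVR on the top-k
features; a held-out split can be supplied instead by calling the selection
primitives directly.

## Fusion model

Stage 1: linear-kernel ε-SVR on the selected, standardized quantitative
features (train-set mean/sd stored in the model) and RBF-kernel ε-SVR
(γ = 1/p) on the raw qualitative codes. Stage 2: linear ε-SVR on the score
pair. Defaults C = 1, ε = 0.1 with no grid search; these are the stock
ε-SVR settings and the experiments here are not sensitive to them.

Stage 2 is trained on out-of-fold stage-1 scores (k = 10, seeded shuffled
folds): record i's training score comes from a stage-1 model whose training
fold excluded i. This is a deliberate strengthening over fitting stage 2 on
in-sample scores, which would let it calibrate against optimistic fits. The
stage-1 models actually served at prediction time are refit on all training
rows. Everything is deterministic given data + seed: fold assignment is the
only randomized step and it is seeded, so refits are bit-identical and a
saved bundle (JSON metadata + serialized regressors) predicts identically
after reload.

## Evaluation

PCC via the product-moment formula (errors, not NaN, on zero variance);
sensitivity TP/(TP+FN) and specificity TN/(TN+FP) with absent-class rates
reported as NaN sentinels; ROC by threshold sweep over unique scores with
trapezoidal AUC, which equals the Mann–Whitney pairwise-concordance
statistic with half-credit ties (asserted against an O(n²) oracle in
tests). Operating points pick, for each specificity target, the threshold
with the smallest specificity ≥ target (max-sensitivity tie-break),
reporting the maximum achievable point when the target is unreachable.

## Synthetic data generator

The generator emulates the statistical shape of an siRNA efficacy screen:
a pool of random transcripts (default one per 10 records, i.i.d. nucleotides
at GC 0.5, length 500 nt), guides cut as reverse complements of random
19-nt windows (binding sites exist by construction; explicit `site_start`
recorded) with random overhangs, and efficacy planted as a noisy linear
function of named features from the package's own representations, rescaled
affinely into [0, 100]. By default the scale is anchored so 30% of records
fall at or above the 70% activity threshold, a realistic active fraction for
screens of this kind.

Effect weights apply to z-scored feature columns, so a unit weight is a
unit-variance contribution; `noise_sd = 1` (the default, "moderate") makes
the noise as strong as one unit-weight feature. The default planted model
splits signal across both representations: six stacking energies at
mutually disjoint core positions and two anagram pairs of region
trinucleotides (weight ±2), plus three rule codes and a one-hot channel at
loci the stacks avoid (weight ±1). Two design constraints matter and are
deliberate: planted quantitative features are chosen weakly
inter-correlated — summary features like G% or ΔG_duplex have too many
near-collinear surrogates for ranking-recovery questions to be well-posed —
and each anagram pair cancels in mononucleotide composition so that
aggregate composition features carry no planted signal. The heavier
quantitative weights keep each planted feature's marginal correlation
comfortably above the null tail of the other ~260 features at n = 500.

Because the plant lives in the package's own feature space, recovery
experiments validate the pipeline's statistical machinery — ranking,
selection, fusion, leakage control — not biological truth. Real screens have
chemically biased sequence panels, measurement floors/ceilings, shared-target
pseudo-replication stronger than simulated here, and efficacy mechanisms
outside this feature space; passing these tests says nothing about
prediction accuracy on such data.

## Problem sizes and numerical choices

The packaged end-to-end experiment uses n = 500 records (350 train / 150
held out), a 50-transcript pool, 10-fold fusion CV and 5-fold selection CV —
sizes at which every quantity of interest is stable across seeds while the
whole suite stays desk-scale. Degenerate inputs error loudly rather than
silently: constant features in Pearson, single-class labelings in F-score
and ROC, k-mer blocks on too-short sequences, non-complementary sites in the
fallback hybridization path.

## Known limitations

- The fallback interaction backend makes ΔG_s/ΔG_m constants; accessibility
  effects require the RNAup backend.
- Nearest-neighbor energies exclude dangling ends, terminal mismatches and
  temperature dependence beyond 37 °C.
- The rule table covers core positions 1–19 only; overhang positions get
  sequence codes only.
- Selection operates on the quantitative representation only; the
  qualitative codes are rule-validated by construction and pass through
  unselected.
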