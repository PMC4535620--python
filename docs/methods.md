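# Methods

This note documents the models behind `serosom`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a user auditing results should know
about. Empirical statements below are the ones the test suite and
`scripts/acceptance.py` themselves compute.

## Normalization

RPKM and TPM are computed per cell from raw counts, gene lengths and
column sums; TPM columns sum to 10⁶ by construction. SOM landscapes and
clustering operate on `log10(TPM + 1)` (pseudocount 1, config-exposed;
the log base and pseudocount only shift and scale the landscape, they do
not change spot topology). Between-sample normalization for the NB test
uses median-of-ratios size factors computed over genes with a nonzero
count in every sample — the standard reference-gene convention; a matrix
with no universally expressed gene is rejected with advice to filter.

## Negative-binomial differential expression

Counts are modelled as NB with `Var = μ + αμ²`. The stage is a
deliberately minimal, fully specified NB pipeline (no Cox–Reid
adjustment, no fold-change shrinkage, no independent filtering):

- **Dispersion.** Raw per-gene `α̂ = max(0, (s² − μ̄)/μ̄²)` from pooled
  within-group variance of normalized counts. A log-log OLS trend of
  `α̂` on mean is fitted over genes with positive raw estimates. The
  trend is a *lower bound* on the final dispersion: raw estimates below
  it are replaced by it, estimates above it are kept (optionally shrunk
  geometrically toward it via `trend_weight`, default 0). The bound is
  what calibrates the test: at 3 vs 3 replicates the raw moment
  estimator is so noisy that its low tail, taken at face value, inflates
  the null `p < 0.05` fraction to ~0.10 and the empirical FDP at the
  0.01 threshold to ~0.13; with the bound the acceptance suite measures
  null fractions 0.041–0.050, per-run FDP ≤ 0.043 (20 seeds) and power
  ≥ 0.95 for |log₂FC| ≥ 2 at μ ≥ 100. A control run with oracle
  dispersions confirms the Wald statistic against the standard normal is
  itself near-nominal (4.8%) at these sample sizes.
- **Test.** `log₂FC = log₂((m̄_A + δ)/(m̄_B + δ))` with offset δ = 0.5
  normalized counts (avoids infinities; config-exposed);
  `SE² = [(1/(m̄_A+δ) + α)/n_A + (1/(m̄_B+δ) + α)/n_B]/ln2²`; two-sided
  p from the normal reference; BH step-up FDR; calls at FDR < 0.01 by
  fold-change sign. Genes all-zero in both groups get p = 1 and a flag.
- One test cross-checks fold changes against DESeq2's Python
  implementation on a planted two-group design (rank correlation > 0.9,
  sign agreement > 95% on planted genes); that library is never used in
  the computation itself.

## SOM landscapes and regulated spots

Genes are observations (one feature per sample) mapped onto a
rows × cols = 20 × 20 lattice by classic online Kohonen training:
Gaussian neighbourhood, geometric decay of learning rate (0.5 → 0.01)
and radius (max(rows, cols)/2 → 0.3) over 10 epochs, codebook
initialized from random data rows, deterministic given `random_state`.
The small final radius matters: ending at radius 1 keeps enough
neighbourhood smoothing (weight 0.61 at distance 1) that quantization
error never drops below the initialization; at 0.3 the final assignment
is crisp, quantization error decreases and lattice-adjacent codebooks
remain much closer than random unit pairs (topographic ordering).

**Preprocessing (the key design decision).** Each gene is mean-centered
across samples and then saturated at ±0.35 (`scale="center"`,
`clip=0.35`; z-scoring, raw mode and unclipped variants are retained as
options). The saturation bound exists because of how the extremum-band
rule interacts with dynamic range. The rule classifies a unit
over-expressed only when its expression exceeds 90% of the landscape
maximum — a 10% corridor below the most extreme metagene. On unbounded
centered data, a mutually exclusive surface antigen spans ~3 decades
while a co-regulated module at log₂FC = 2 spans 0.6: the antigen then
owns the maximum and the corridor contains only its own unit, so no
multi-gene spot can form. Per-gene z-scoring fails differently: it
hands every pure-noise gene unit variance, whose most extreme of ~21
samples sits near 2.5, so small noise-dominated units top the landscape;
and the sd estimate at n = 21 carries ~15% jitter, larger than the
corridor. Bounded centering resolves both: every strongly regulated
gene saturates at the ceiling, MaxEXP is pinned there, and the corridor
selects exactly the saturated co-regulated set. The bound (0.35 in
log₁₀ units, ≈ 2.2-fold above a gene's own mean) is chosen below the
centered amplitude of a two-fold-change module expressed in a quarter of
the samples, so such modules saturate; it is config-exposed and should
be lowered if smaller effect sizes are of interest.

**Landscape and classification.** A sample's landscape assigns each
unit the arithmetic mean of its member genes' scaled expression; empty
units carry the codebook value and are excluded from MaxEXP/MinEXP and
from classification. Classification is exactly the printed rule with
strict inequalities: over iff `Δe > MaxEXP·0.9`, under iff
`Δe < MinEXP·0.9`, factor config-exposed. MaxEXP/MinEXP are per-sample
by default (a global mode across samples is available). When
MaxEXP ≤ 0 or MinEXP ≥ 0 the band is ill-posed and everything is
classified none with a warning — generic centered data does not hit
this. Spots are maximal connected components of same-class units under
8-neighbour adjacency by default (4-neighbour available), ordered by
gene count then row-major anchor.

## Serotype co-regulation

The active SAg of a condition is the family member with dominant mean
TPM (a warning fires below a 10× margin over the runner-up). The SAg
spot is the over-class spot containing it; the co-regulation group is
the set of genes whose (sample, class) spot-incidence pattern equals the
SAg's everywhere — an exact-incidence rule, deliberately strict;
persistence between a parent spot and a derived sample is the maximum
Jaccard similarity over the derived sample's over-spots, and heat-shock
spot loss is the fraction of parent spot units no longer over-expressed.
These formalize what is otherwise a visual comparison of landscapes;
the thresholds quoted in tests (persistence ≥ 0.6 for short-term
derivatives, ≤ 0.2 after heat shock) describe the synthetic design, not
a biological constant.

## Transcriptome similarity

Sample-by-sample distances on unscaled log-TPM columns: Euclidean, and
1 − Pearson (range [0, 2]; zero-variance samples rejected by name). The
two are complementary by construction — profiles that are an affine
transform of one another have correlation distance 0 but large Euclidean
distance. Agglomeration is UPGMA via scipy (tie-breaking is scipy's
deterministic order); Newick export uses ultrametric branch lengths
(node depth = merge height/2) and round-trips through standard parsers.

## Telomere position effect scan

Distances to telomeric positions (both scaffold ends plus internal
telomeric sites, toggleable) are measured in bp from the nearest feature
edge and in gene rank (intervening gene count); the test uses gene rank,
which is robust to intergenic-length variation. The spreading statistic
is the pooled regression slope, over genes between each focal SAg and
its nearest telomere, of the ON−OFF mean log-expression difference on
proximity (negated rank): the extra silencing per gene step toward the
telomere. A slope, not a correlation, is essential under the
condition-label permutation null: relabelling attenuates the difference
profile but preserves its rank order, so any correlation statistic
returns ±its observed value for every unbalanced relabelling and the
test would have no power at any effect size. p-values are one-sided
upper-tail with the +1 correction (never exactly 0). Calibration on the
generator: null rejection 2–8% at α = 0.05, power ≥ 80% (in practice
≈ 100%) against the planted spreading model.

## GO enrichment

Annotations propagate to ancestors on load (true-path rule); only is-a
edges are honoured and part-of edges are treated as is-a with a warning.
Term-for-term is the upper-tail hypergeometric against the annotated
population. Parent-child-union restricts population and study to genes
annotated to the union of the term's parents (the root gets p = 1); on a
flat ontology it reduces exactly to term-for-term, which is asserted in
tests. BH correction is applied across terms within each direction;
reporting uses FDR < 0.02.

## The synthetic-data generator

The generator emulates the study design, not its sequences: seven
conditions (four serotype-pure cultures A.31/B.24/D.24/H.14 and three
derivatives B.6 cold, D.starv starved, D.HS heat-shocked) × 3
replicates, 6,000 genes by default.

- **Counts.** NB via gamma–Poisson with gene-wise
  `α ~ lognormal(ln 0.02, 0.5)` — tight, as expected for replicate
  cultures of a clonal line — and per-sample library factors
  `U(0.5, 2)`. The moment identity `Var = μ + αμ²` is verified to 5%
  in tests.
- **SAg family.** 8 genes; the member matching the condition's serotype
  has mean 3 × 10⁴ (among the top-expressed genes), all others 30
  (0.1%, far inside the ≤ 2% mutual-exclusion margin). Starvation keeps
  the active SAg with a slight reduction (×0.8). SAg dispersion is
  fixed at 0.005: mutually exclusive antigen expression is
  epigenetically locked and extremely abundant, so its replicate CV is
  far below the genome-wide draw.
- **Modules.** One disjoint 500-gene module per serotype at
  log₂FC = 2, ON exactly when its serotype is active. Module baselines
  are drawn `lognormal(4.7, 0.6)` — higher and tighter than the
  `lognormal(4, 1)` background — because the co-regulated groups being
  modelled are characteristically highly expressed.
- **Heat shock.** Modelled as geometric interpolation of the serotype
  program toward its silent state: `HS mean = off·(on/off)^ρ` with the
  same residual exponent ρ = 0.6 for the SAg and its module, so their
  log-scale profiles stay proportional and the SAg co-locates with its
  module on the map. ρ is bounded below by the mutual-exclusion
  invariant (the decayed SAg must stay ≥ 50× the silent members) and
  still yields a ~16-fold SAg drop. A single multiplicative decay
  factor cannot do this: applied to a 1000× antigen and a 4× module it
  sends the module below its own silent level while the antigen stays
  far above its own, tearing their shapes apart. Cytosolic HSP70 genes
  (6, baseline 200) activate 32×. Each heat-shock replicate gets a
  shock intensity λ, evenly spaced over (0.75, 1) and randomly
  permuted across replicates: HSPs activate as `32^λ` and the program
  decays with exponent `1 − (1−ρ)λ`, so replicates differ cleanly and
  the HSP-vs-SAg rank correlation is −1 by construction up to counting
  noise. Per-sample intensities are recorded in the truth object; the
  condition-level mean matrix corresponds to the full shock.
- **Condition programs.** Cold adaptation perturbs 15% and starvation
  20% of eligible background genes relative to the parent condition
  (|log₂FC| ~ U(1, 2.5), random sign); module genes are untouched
  (within the < 0.5 log₂FC contract of the parent). Genes placed on
  the subtelomeric scaffolds are excluded from perturbation so their
  expression is independent of SAg state by construction.
- **Subtelomeres.** One scaffold per serotype in the attached map: the
  focal SAg sits 2 genes from the right scaffold end, with an internal
  telomeric site near the left end. The standalone generator
  (`simulate_subtelomere`) controls the spreading model explicitly:
  with spreading, downstream neighbours lose `decay = 0.5` per gene
  step toward the telomere in SAg-OFF conditions; without, neighbour
  expression is independent of SAg state. Log-normal noise
  (σ = 0.15 log₁₀) on top.
- **Ontology.** A flat DAG (root + 30 random terms) plus one planted
  term drawn from the first serotype's module, so a differential set
  from that module is enriched for it by construction.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: multi-mapping reads and paralog
cross-talk from whole-genome duplications (quantification is assumed
solved), isoform structure, GC/length biases, batch effects,
autogamy-related developmental transcription, partially penetrant
serotype switches within a culture, correlated noise between
co-regulated genes beyond their shared mean structure, and realistic GO
topology. Recovery results on the default design demonstrate that the
pipeline's inference machinery is correct under its own model
assumptions at realistic effect sizes, not that real libraries reach
the same margins.

## Problem sizes and determinism

Default analyses run at 6,000 genes × 21 samples with a 20 × 20 map;
calibration simulations use 5,000 genes at 3 vs 3 and 199–999
permutations. These sizes give stable margins while keeping a full run
in seconds and the entire acceptance computation in minutes. All
randomness flows from explicit seeds; the pipeline derives per-stage
seeds from the global seed via `numpy.random.SeedSequence.spawn`, and
rerunning a configuration reproduces output hashes of deterministic
stages byte for byte.

## Known limitations

- The spot corridor (factor 0.9) interacts with the preprocessing
  bound; analyses of subtle modules (log₂FC ≲ 1) need a lower `clip`.
- The NB test's trend lower bound trades a little power below-trend for
  calibration; with many replicates (≥ 20) pure raw estimates are
  fine (`trend_weight` and the bound then barely bind).
- The exact-incidence co-regulation rule is brittle to single-sample
  classification flips by design; persistence (Jaccard) is the robust
  counterpart.
- Newick export encodes an ultrametric tree; it is not meant for
  non-UPGMA linkages.
- `transform` on data other than the training genes is undefined for
  landscape purposes (membership comes from the training assignment);
  use `predict` for new observations.
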