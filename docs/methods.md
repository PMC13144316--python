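# Methods

## Study design the package models

Two tumor cohorts are compared layer by layer: cohort A, small (default 17
samples) and profiled with a targeted gene panel (648 genes) that yields
somatic calls and segment-level copy-number states, and cohort B, much
larger, with gene-level copy-number states and expression from a different
platform. All mutation and CNV analyses are restricted to the panel genes
so the two platforms measure the same gene space; expression comparisons
run on within-sample ranks so that per-platform monotone distortions cancel.

## Statistical conventions

All primitives live in `stratomics.stats` and are written from first
principles so they can be verified against brute-force oracles.

* **Fisher exact test (two-sided).** Probability-mass definition: p is the
  sum of hypergeometric point masses, over tables with the observed
  margins, that do not exceed the observed table's mass (relative tolerance
  10⁻⁷ on the comparison, absorbing floating-point noise). This matches the
  convention of the mainstream implementations. The odds ratio is the
  unconditional cross-product ratio a·d/(b·c); zero cells yield ∞ or an
  undefined (NaN) value rather than silent smoothing.
* **BH adjustment.** Step-up: q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j capped at 1,
  returned in input order. BH is not idempotent and no such claim is made.
* **Mann–Whitney / Wilcoxon rank-sum.** U from joint average ranks. `auto`
  mode enumerates exactly for tie-free samples with n₁+n₂ ≤ 12; otherwise a
  tie-corrected normal approximation with continuity correction is used
  (the cohort sizes here always land in the normal branch; the exact branch
  exists for oracle checks). Zero tie-corrected variance (all values equal)
  gives p = 1.
* **Hypergeometric upper tail** is summed in log space (log-gamma terms
  plus log-sum-exp), exact to ~10⁻¹² against direct summation.
* **NNLS** is Lawson–Hanson active-set on top of `numpy.linalg.lstsq`.

## Mutation layer

The filter cascade removes (1) variants with popmax population AF strictly
greater than 5×10⁻⁴ in any configured reference subpopulation — variants
with no AF annotation are kept, since absence of annotation is not evidence
of commonness, and are counted separately; (2) non-protein-altering classes
(silent, UTRs, introns, flanks, other), keeping missense, nonsense,
frameshift and in-frame indels, splice-site and translation-start changes;
(3) off-panel genes. The three filters commute on the retained set; the
report's per-stage attrition follows the cascade order.

Per-gene 2×2 Fisher tests compare mutated-sample proportions; the BH family
is the panel genes with at least one mutated sample overall (never-mutated
genes carry p = 1 by construction and only dilute rank; an `all`-genes
family is available as a config switch). Discoveries at q < 0.1.

The bootstrap resamples columns with replacement independently within each
cohort, preserving cohort sizes; +0.5 smoothing is applied to all four
cells only when a resample contains a zero cell, so well-populated tables
are untouched. Directional consistency is the fraction of resample log-ORs
sharing the point estimate's sign; for a zero point estimate it is defined
as the fraction of non-negative resamples, which is ~0.5 under a symmetric
null.

## CNV layer

Segments are normalized to 0-based half-open intervals at ingestion; any
≥1 bp intersection with a gene body counts as overlap. The default
conflict mode (`gain_loss_only`) marks a gene invalid only when gain and
loss both overlap it in one sample; an alteration co-occurring with neutral
keeps the alteration. A `strict` mode invalidates any two distinct states —
provided because "conflicting" could be read either way; the choice is
recorded in the table's provenance. Frequencies divide by valid samples
only. Genes map to arms by midpoint (a gene spanning the centromere goes to
the arm containing its midpoint — deterministic and order-free); an arm is
flagged per sample when at least one panel gene on it carries the event.
Arm-level Fisher tests are BH-adjusted within the combined gain+loss
family; burden (count of flagged arms per sample) is compared by two-sided
Wilcoxon. Infinite/zero odds ratios are kept exact in the tables and only
flagged for presentation-time truncation.

## Expression layer

Genes with mean normalized expression strictly below 10 in *both* cohorts
are dropped (the `pooled` alternative is available; the default reads the
filter as "retain if adequately expressed in at least one cohort"). Within
each sample, values are replaced by ascending average ranks (ties share the
mean rank); per-gene Mann–Whitney tests on these ranks are exactly
invariant under strictly monotone per-sample transformations — the property
that makes the comparison platform-robust, and one the suite asserts
bitwise. Fold change is *not* invariant, which is why it is computed on the
original normalized values, as log₂((mean_A + 1)/(mean_B + 1)) — the
pseudocount (configurable) guards zero means; arithmetic cohort means are
used. A DEG must satisfy q < 0.01 and |log₂FC| ≥ 2.

## Signature layer

SNVs are classified into the 96 COSMIC-ordered pyrimidine-centered classes
(purine-reference substitutions reverse-complemented); the context comes
from a MAF context column or a reference FASTA lookup, and the context's
middle base must equal the reference allele. The catalog pools both
cohorts. Indels and multi-nucleotide records are skipped with counts.

Extraction fits NMF with the generalized Kullback–Leibler objective —
the natural likelihood for count catalogs — by multiplicative updates
(convergence when the relative objective change between checks falls below
10⁻⁸, checked every 25 sweeps, or at 10,000 sweeps; factor entries are
floored at 10⁻³⁰ to keep the updates positive and out of the denormal
range, where hardware arithmetic is an order of magnitude slower). For
each candidate k the catalog is Poisson-resampled per replicate (default
20) with distinct seeded initializations; each replicate's signatures are
Hungarian-matched to the running consensus by cosine distance, giving k
clusters of replicate signatures. Stability is the mean cosine silhouette
of the pooled cluster members (for k = 1, the mean pairwise cosine
similarity, since the silhouette is undefined); reconstruction error is the
mean per-sample cosine distance between the catalog and W·H with exposures
refit per sample by NNLS on the original catalog. The consensus signatures
are cluster medoids. Selected k: the largest candidate with stability ≥ 0.8;
if none reaches the floor, the highest-stability candidate wins, ties
toward lower reconstruction error. This operationalizes the
resampling/stability/reconstruction selection scheme of the established
signature-extraction tooling with silhouette and cosine distance as the
concrete metrics.

Decomposition onto reference spectra uses NNLS with coefficients
renormalized to percentage contributions; a signature is named after the
reference with the highest contribution, and the best single-reference
cosine is reported alongside. Exposure comparisons use two-sided
Mann–Whitney on absolute attributed counts by default (raw p at α = 0.05,
matching how such exposure contrasts are usually reported); a proportion
mode is available since catalogs of very different depth can make absolute
counts misleading. Panel-derived catalogs are sparse — nothing assumes row
sums ≫ 96 — and no renormalization from panel to whole-genome trinucleotide
background is applied (an explicit non-feature; spectra are compared in
panel context space).

## Enrichment

One hypergeometric upper-tail engine serves every layer; the universe
defaults to the panel genes for mutation/CNV layers and to the
expression-filter survivors for DEG layers — each layer is conditioned on
what it could have measured. Pathways are intersected with the universe and
only non-empty intersections enter the BH family. The integrative matrix
holds −log₁₀(q) per pathway × layer, leaves zero-overlap cells empty
(absence of overlap is not evidence at q = 1), stars cells at q < 0.05, and
orders rows by the count of significant layers, ties alphabetically.

## Synthetic study generator

The generator emulates the two-cohort design end to end and writes a truth
ledger of every planted effect. Defaults are the study conditions (CI scale
17 vs 60 keeps the imbalance while staying fast; `scale="full"` gives
17 vs 689):

* **Genome scaffold.** 22 autosomes (~100–144 Mb), centromere at 40%,
  648 panel genes placed evenly; two cytoBand rows per arm so the reader's
  band-merging is exercised.
* **Mutations.** Per gene and sample, Bernoulli indicators: baseline rate
  0.02, with 11 planted genes at 0.24 (cohort A) vs 0.02 (cohort B) —
  mirroring the strongest reported gene-level contrast (≈24% vs ≈2%). Each
  mutated gene receives 1–2 (A) or 3–5 (B) variants; ~5% are indels. A
  decoy fraction violates each filter rule (popmax AF 0.01, silent class,
  off-panel gene) to exercise the cascade; retained-variant AFs are below
  the threshold or absent.
* **Signatures.** Three sparse spectra with pairwise cosine ≤ 0.6. Each
  sample's SNV classes are multinomial draws from its signature mixture,
  with mixture weights from gamma draws (shape 2) whose cohort means are
  (2, 2, 4) vs (4.4, 3.4, 2.2). Together with the higher per-gene SNV
  multiplicity in cohort B this yields absolute exposures shifted upward in
  B for the first two signatures while the third stays flat — the pattern
  of two significant and one non-significant exposure contrast. Planting
  the multiplicity rather than extra mutated genes keeps the binary
  mutation matrix unconfounded by the signature layer.
* **CNV.** 32 of 44 arms carry per-sample gain probability 0.63 (B) vs
  0.176 (A), the remaining arms 0.05 — reproducing arm-gain burden means
  near 21 vs 6. Scattered focal losses hit a Poisson number of random arms
  per sample (means 6.2 in A, 9.3 in B; one random gene per hit), and 10
  recurrently lost genes on 2 arms are lost at 0.5 (A) vs 0.03 (B). A focal
  loss landing on a gained arm produces a genuine gain/loss conflict and
  hence an invalid status; after this masking the surviving loss burdens
  are ≈7 (A) vs ≈5 (B) with few significant loss arms while the recurrent
  genes remain detectable at gene level — losses focal and heterogeneous,
  gains broad. Cohort A is emitted as segments (whole-chromosome neutral
  background plus event segments), cohort B as a gene-level status table,
  so both ingestion paths run.
* **Expression.** 3000 genes with log-normal latent means (μ=3.5, σ=1.2 on
  the log scale), 60 planted DEGs up in A and 20 up in B at fold 8,
  multiplicative log-normal noise (σ=0.5), and a mild monotone platform
  distortion on cohort B (scale 1.3, exponent 1.05). The distortion is
  deliberately mild: rank-based p-values are invariant under *any* monotone
  map (asserted separately with strong random distortions), but the
  |log₂FC| ≥ 2 threshold operates on the original scale and is only
  meaningful when the two platforms' normalized scales are comparable, as
  they are after the harmonization the design assumes.
* **Pathways.** A GMT with planted pathways concentrating the planted DEG,
  mutation, and CNV genes plus random pathways.

What the generator does **not** emulate: germline contamination, subclonal
structure, FFPE artifacts, LD between genes, correlated expression modules,
or realistic panel trinucleotide composition. Passing recovery tests
therefore demonstrates that the statistical machinery detects what it
claims to detect under its stated model — not that it is robust to every
artifact of real tumor data.

## Recovery floors and problem sizes

`evaluate_recovery` scores a pipeline run against the ledger;
`check_floors` gates each layer with floors set from design power
calculations at the CI scale (roughly half the expected sensitivity):
mutation 0.09 (median over 25 replicate draws of the layer, because at
17 vs 60 the per-study discovery count is small and discrete), CNV gain
genes 0.5, recurrent loss genes 0.4, arm gains 0.5, DEGs 0.7 with observed
FDR ≤ 0.15, signature k = 3 with matched cosines ≥ 0.85 and the planted
exposure pattern, planted pathways within the top 2 of their layer. The
loss-burden contrast is gated on direction only — it is genuinely marginal
at this scale, as its full-scale counterpart already was.

Problem sizes used by the test suite are the package's own choices: the
signature-recovery study runs 20 seeded extractions on 120 samples × 150
mutations with 20 replicates and candidate k ∈ 1..5 (two above-truth
candidates suffice to exercise the selection rule; the API default remains
1..10); the orchestrated end-to-end run caps candidate k at 5 with 8
replicates. Mutation-recovery simulations at 17 vs 689 reuse a memoized
Fisher lookup since the cohort margins are fixed.

## Known limitations

* The invalid-status rule can mask true focal losses inside broad gains;
  this is faithful to the stated rule but means loss frequencies are
  conditional on not being gain-masked.
* Exposure tests on absolute counts conflate mutation burden with mixture
  shifts; the proportion mode trades that for compositional coupling.
* NMF stability selection is a heuristic; with nearly collinear spectra
  (cosine ≫ 0.6) the silhouette can stay high for merged solutions and the
  selected k can undershoot.
* The normal-approximation Mann–Whitney is used for all production cohort
  sizes; for very small strata (< ~8 per group with ties) its p-values are
  approximate.
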