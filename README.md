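# stratomics

Race-stratified multi-omics comparison of two tumor cohorts of very unequal
size — a small targeted-panel cohort (n ≈ 17) against a large public
comparator (hundreds of samples) — across four molecular layers plus an
integrative pathway view:

1. **Somatic mutations.** A gnomAD-style population-AF filter (popmax AF
   > 5×10⁻⁴ removed), a protein-altering consequence filter, and a panel
   restriction produce a binary gene × sample indicator. Each gene g is
   tested with a two-sided Fisher exact test on the 2×2 table
   (mutated vs not × cohort), Benjamini–Hochberg adjusted; discoveries at
   q < 0.1. Stability of each discovery's log odds ratio is assessed by a
   within-cohort bootstrap (5000 resamples, Haldane–Anscombe +0.5 only on
   zero-cell resamples) reporting directional consistency.
2. **Copy number.** Segment calls are lifted to per-gene states
   {gain, loss, neutral}; a gene overlapped by conflicting segments in one
   sample is *invalid* and leaves that gene's denominator. Per-gene event
   frequencies (gain, loss, gain-or-loss) are Fisher-tested at q < 0.05 over
   valid samples; genes collapse to chromosome arms ("at least one panel
   gene on the arm" rule, midpoint assignment) for arm-level tests and a
   per-sample arm-burden Wilcoxon comparison.
3. **Expression.** Cross-platform differential expression via within-sample
   average ranks: Mann–Whitney U per gene on the ranks (invariant to any
   strictly monotone per-sample platform distortion), BH adjustment, and a
   dual DEG rule — q < 0.01 *and* |log₂FC| ≥ 2, the fold change computed on
   the original normalized values with a pseudocount.
4. **Mutational signatures.** SBS96 catalogs (pyrimidine-centered
   trinucleotide classes), de novo NMF extraction (KL objective) with
   Poisson-resampled replicates, cosine-silhouette stability selection of
   the signature number k, NNLS decomposition onto reference spectra for
   naming, and per-signature Mann–Whitney exposure comparison between
   cohorts.
5. **Enrichment.** Hypergeometric over-representation of any gene layer
   against any GMT collection, and an integrative pathway × layer matrix
   ranked by the number of significantly enriched layers.

Because individual-level data for such studies are typically not shareable,
the package ships a first-class synthetic study generator
(`stratomics.synthetic`) that emits every input format (MAF, SEG, gene-level
CNV TSV, expression TSV, BED, cytoBand, GMT, reference spectra, FASTA) with
planted, parameterized effects and a machine-readable truth ledger, plus
recovery scoring (`evaluate_recovery`) used throughout the test suite.

## Worked example

```python
from stratomics import pipeline, synthetic

cfg = synthetic.default_config(scale="test", seed=1)   # 17 vs 60 samples
paths, ledger = synthetic.simulate_study(cfg, "study")
config = pipeline.default_run_config(paths, "bundle", seed=1)
config["signatures"].update({"k_max": 5, "n_replicates": 8})
bundle = pipeline.run_all(config)
```

The bundle directory then contains one TSV per analysis. The significant
mutation genes (of 11 planted at 24% vs 2%):

```
gene   mutated_A  mutated_B  frequency_A  frequency_B  odds_ratio  q_value
G0093          6          0       0.3529       0.0000         inf   0.0135
G0162          6          1       0.3529       0.0167     32.1818   0.0546
G0610          7          0       0.4118       0.0000         inf   0.0042
G0484          7          3       0.4118       0.0500     13.3000   0.0837
```

all with bootstrap directional consistency ≥ 0.999. The arm-burden table
reproduces the planted asymmetry — broad gains in the large cohort, a
smaller but real loss-burden excess in the small cohort:

```
event  mean_A  mean_B  p_value
gain   6.0000  19.850  3.2e-10
loss   7.3529   4.883  0.0008
```

The signature stage selects k = 3 (stability 0.96 at k = 3, collapsing to
0.53 at k = 4), matches each consensus signature to its generating spectrum
with cosine ≥ 0.98, and the exposure tests flag exactly the two signatures
planted with higher cohort-B exposure (p < 10⁻⁴, the third p = 0.45).
Differential expression calls 74 DEGs (54 up in A, 20 up in B; 80 planted).

The same pipeline runs from the shell:

```bash
stratomics simulate --scale test --seed 1 --out study
stratomics all --config run.yaml
stratomics evaluate-recovery --truth study/truth.json --bundle bundle
```

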