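# tcrtrace

Longitudinal single-cell TCR clonotype tracking for paired pre/post-treatment
blood samples (plus baseline tumor biopsies) from checkpoint-blockade
cohorts. `tcrtrace` groups T cells into clonotypes by CDR3 amino-acid
identity, follows them across timepoints and compartments, classifies
treatment-driven clonal expansion, quantifies repertoire clonality, scores a
weighted memory-precursor gene signature per clonotype, and flags putative
viral-reactive clonotypes — with a fully ground-truthed synthetic cohort
generator so every stage is testable without access to patient data.

It is written for computational immunologists analyzing paired
scRNA-seq + scTCR-seq data (10x-style contig annotation tables, MatrixMarket
count matrices, VDJdb-style reference TSVs).

## The model

**Clonotypes.** Cells sharing the same TCR are grouped by the amino-acid
sequences of the α- and β-chain CDR3s. Per cell, one chain per locus is kept
(highest UMI support). Matching two clonotype sets requires equality of both
CDR3s when both partners carry both chains; when either partner lacks a
chain, equality of the shared chain suffices (single-chain fallback). The
same rule drives blood↔tumor matching and pre↔post identity, so a clonotype
is called *novel* only if no pre-treatment clonotype matches it even under
the fallback — conservative against false novelty from chain dropout.

**Clonal dynamics.** A clonotype is *treatment-expanded* when it has ≥ 2
cells post-treatment and a strictly higher within-sample frequency post than
pre:

    expanded(c)  ⇔  n_post(c) ≥ 2  and  n_post(c)/N_post > n_pre(c)/N_pre

Treatment-expanded clonotypes split into *novel expanded* (NE; undetected
pre-treatment — "clonal replacement") and *pre-existing* (PE). The
comparator group "expanded at baseline but static" is n_pre ≥ 2 without
meeting the rule. Per-sample clonality is the Gini coefficient of the
clone-size vector, G = Σᵢⱼ|xᵢ−xⱼ| / (2n²x̄), plus singleton / expanded /
hyper-expanded category counts.

**Memory signature score.** From a paired memory- vs effector-precursor
dataset, genes with log₂ fold change > 0.25 (memory over effector) and
Bonferroni-adjusted rank-sum p < 0.05 at *both* timepoints — excluding
mitochondrial and ribosomal symbols — form the signature; each gene's weight
is the antilog of its average LFC, w(g) = 2^((LFC_pre + LFC_post)/2). Every
cell gets a z-score per signature gene against the gene's global
log-normalized mean, and a clonotype's score is the weighted sum of its
member cells' average z-scores:

    score(c) = Σ_g w(g) · mean_{cells ∈ c} z[g, cell]

Scores are computed before and after treatment per clonotype; a
random-gene signature serves as the batch-effect control.

## Worked example

```bash
tcrtrace simulate --seed 7 --patients 2 --cells-per-sample 600 --out cohort/
tcrtrace run --in cohort/ --out report/ --seed 7
tcrtrace report --in report/
```

The report prints (seed 7, this exact configuration):

```json
{
  "fraction_increasing_memory": 0.7712031558185405,
  "fraction_increasing_random": 0.45956607495069035,
  "gini_post_blood_mean": 0.4182150735226736,
  "gini_pre_blood_mean": 0.3815539092512075,
  "n_cells_post_qc": 3341,
  "n_cells_pre_qc": 3400,
  "n_clonotypes": 1242,
  "n_novel_expanded": 33,
  "n_scored_clonotypes_memory": 576,
  "n_scored_clonotypes_random": 576,
  "n_signature_genes": 40,
  "n_treatment_expanded": 139,
  "ne_rate_mean": 0.05999418174124617,
  "signature_false_positives": 0,
  "signature_recovered_planted": 40,
  "signed_rank_p_memory": 3.978190512869324e-37,
  "signed_rank_p_random": 0.04565587237482589,
  "tumor_matched_fraction_of_expanded": 0.1079136690647482,
  "viral_fraction": 0.01932367149758454
}
```

Reading it: 59 of 3,400 cells failed mitochondrial QC; the rest carry 1,242
clonotypes, of which 139 expanded under treatment and 33 of those were novel
(mean NE rate 6.0% of post-treatment clonotypes, against the 5% the
generator injects). Repertoire clonality rose slightly post-treatment
(Gini 0.38 → 0.42), and 10.8% of expanded clonotypes were also found in the
tumor sample. The derived signature recovered all 40 planted memory-program
genes with no false positives; 77% of scoreable clonotypes scored higher
post-treatment (the planted memory shift; signed-rank p ≈ 4 × 10⁻³⁷), while
the random-gene control sat near 50% (0.46) — no meaningful timepoint batch
effect. The viral fraction counts flagged clonotypes among *all* clonotypes
including tumor-private ones; every one of the 24 planted viral clones was
flagged and nothing else.

The same analyses are available as library functions
(`tcrtrace.call_clonotypes`, `classify_dynamics`, `derive_signature`,
`score_timecourse`, …) for use on real cohort exports.

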