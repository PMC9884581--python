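# Methods

## Analysis model

### Clonotype identity and matching

A clonotype is the set of cells sharing the same α/β CDR3 amino-acid pair.
Per cell, the highest-UMI chain per locus is retained (ties break to the
lexicographically smallest CDR3); non-productive chains are excluded, since
clonotype identity is a functional-TCR concept. A configuration switch
(`collapse="all_chains"`) instead keys cells on all productive CDR3s per
locus. Matching between two clonotype sets requires equality of both CDR3s
when both partners carry both chains; if either partner lacks a chain,
equality of the chain present in both suffices. This single-chain fallback
can produce one-to-many matches; all pairs are reported, and downstream
"found in tumor" is an existence test, so no arbitrary tie-break is needed.
Matching is exact (no edit-distance tolerance) and CDR3-only; V/J-gene
identity is available as an optional restriction for viral annotation but is
off by default. Matching is within-patient only.

### Quality control and normalization

Blood cells with a mitochondrial count fraction strictly above 0.20 and
tumor cells strictly above 0.30 are discarded ("> cutoff" is read as strict,
matching the rule's wording); mitochondrial genes are identified by the
`MT-` symbol prefix (configurable). Genes with zero counts across the
surviving cells are dropped. Normalization is
`ln(1 + 10⁴ · count / cell_total)` (both the scale and the log base are
configurable); zero-total cells are an error naming the barcode.

### Longitudinal classification

With within-sample frequencies f = n/N, a clonotype is treatment-expanded
iff `n_post ≥ 2` and `f_post > f_pre` (strict; equal frequency does not
qualify; a raw-count comparison is available by flag). Origin is `novel` iff
no pre-treatment clonotype matches under the fallback rule — deliberately
conservative against false novelty caused by chain dropout. The baseline
comparator (`baseline_expanded_static`) is `n_pre ≥ 2` without expansion.
The novel-expansion rate defaults to NE clonotypes over all clonotypes
observed post-treatment; the alternative denominator (treatment-expanded
clonotypes only) is computed alongside, since the figure-level normalization
is a choice the data do not pin down.

Cluster flux restricts to treatment-expanded clonotypes with at least one
pre-treatment cell. Incidence mode credits every (pre-cluster, post-cluster)
pair the clonotype touches; modal mode credits only the modal pair, ties
broken lexicographically.

### Repertoire statistics

Gini clonality uses the sorted closed form of the pairwise-difference
definition, G = (2Σᵢ i·x₍ᵢ₎ − (n+1)Σx) / (nΣx), which is scale-invariant, so
counts and frequencies give the same value. Expansion categories default to
singleton = 1 cell, expanded = 2–9, hyper-expanded ≥ 10 (the three-way split
is conventional; the boundary is configurable because no standard exists).
Detection depth is the number of cells with an assigned clonotype in a
sample.

### Differential expression

Per-gene two-sided Wilcoxon rank-sum tests on log-normalized expression with
Bonferroni correction over the genes actually tested (genes expressed in
neither group are skipped). The fold change is computed on de-logged means
with a 10⁻⁹ pseudocount: `lfc = log₂((mean expm1 x₁ + ε)/(mean expm1 x₂ + ε))`.
A hurdle-model fit would add assumptions the downstream signature logic does
not use — it consumes only (lfc, adjusted p) — so the rank-sum surrogate is
used; externally computed DE tables with those columns can be substituted
directly.

### Memory signature

Genes pass when `lfc > 0.25` (strict) and `p_adj < 0.05` at **both**
timepoints and the symbol does not start with `MT-`, `RPL` or `RPS`
(thresholds and prefixes configurable). The significance filter reflects
that candidate genes come from differential-expression volcanoes; an
LFC-only rule admits dozens of noisy low-expression genes. "Antilog" is
base 2 (fold changes are log₂; the base is configurable and recorded in the
signature file header). z-scores use the global per-gene mean and the
population (divisor n) standard deviation of log-normalized expression over
all cells; zero-variance genes get z ≡ 0; no clipping is applied (a clip
option exists, default off). Clonotype scores are weighted sums of mean
member-cell z-scores; the timecourse restricts to clonotypes with ≥ 2
scoreable blood cells and reports the fraction with strictly positive delta
plus a paired Wilcoxon signed-rank p. The random-signature control draws
detected genes uniformly without replacement with unit weights.

### Viral annotation

Exact, case-sensitive CDR3β equality against a VDJdb-style reference (TRB
rows only). Clonotypes lacking a β chain are never flagged. All matching
species/epitopes are accumulated. Score/species-based reference filtering is
left to the caller via the reader.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline must handle,
with exact ground truth:

- **Repertoire**: clone sizes are zipf(α = 2.5) draws truncated to fill each
  sample budget exactly. Longitudinal classes are enforced by construction:
  NE clones exist only post-treatment with ≥ 2 cells; PE-expanded clones
  receive `post > pre·(N_post/N_pre)` (and ≥ 2); all other clones receive
  `post ≤ pre·(N_post/N_pre)`. Budget deficits are absorbed by extra growth
  of expanded clones or novel post-treatment singletons; surpluses shrink
  non-expanded clones. Classification against truth is therefore exact, not
  probabilistic.
- **TCRs**: unique random CDR3s (length 10–18, C…F convention) per clone,
  collision-free by registry across the whole cohort, so the single-chain
  fallback can never merge distinct clones. A configurable fraction of
  clones (default 10%) drops one chain; viral planting (default 3.4% of
  blood clonotypes, the study-scale fraction) is restricted to clones that
  keep their β chain, so β-matching can recover the planted set exactly.
  Tumor-shared clones (default 10% of tumor clones) reuse blood CDR3s,
  selected with probability proportional to blood clone size (abundant
  circulating clones are the ones re-detected in a shallow tumor sample).
- **Expression**: negative-binomial counts (dispersion 0.3, mid-range for
  UMI data) with log-normal gene base means, per-cell log-normal library
  factors (σ = 0.3), and 25 neutral marker genes at 2-fold per cluster.
  The 40-gene memory program is shifted by `2^0.5` in NE-clone cells and
  `2^0.25` in post-treatment pre-existing cells (log₂ units, so expected
  LFCs are known analytically). Program genes draw base means from a
  moderately expressed range (1–4) and constitute ≈ 9% of the library, so
  the compositional attenuation of an observed LFC is ≈ 0.05; expected
  sequencing depth is equalized across planted classes so detection rates
  carry no depth confound. Cluster identity deliberately rests on neutral
  genes only: zero-shift configurations are genuinely null for the
  signature score. 3% of cells receive a 25× mitochondrial boost, putting
  them above the blood QC cutoff (~26% mitochondrial) but below the tumor
  cutoff.
- **Precursor fixture**: a paired memory- vs effector-precursor dataset
  (500 cells per group per timepoint by default) with the memory program
  up in memory precursors and the effector program up in effector
  precursors at both timepoints (LFC 0.6), plus two deliberately confounded
  excluded-prefix genes (MT-ND1, RPL3) to exercise the symbol-exclusion
  rule.

Default cohort scale is six patients × (2,000 pre-blood + 2,000 post-blood
+ 500 tumor) cells and 1,000 genes — the package's chosen desk-scale stand-in
for a ~20k-gene transcriptome, large enough for all statistics to operate in
their asymptotic regimes.

### What the generator does not emulate

No V(D)J recombination model (no germline segments or generation
probabilities), no doublets or ambient RNA, no batch effects between
samples, no per-cell chain dropout (dropout is per clone), and clusters are
planted labels, not transcriptional states discovered from the expression
itself. Passing tests therefore demonstrate correctness of the bookkeeping,
the matching rules and the statistics under a faithful noise model — not
robustness to artifacts the generator omits (index hopping, batch effects,
clonotype collisions in real repertoires).

## Numerical choices

- Gini uses the exact sorted formula (no binning); single-clone samples give
  0 by the definition.
- Rank-sum tests use the tie-corrected normal approximation, vectorized over
  genes; two-sample comparisons with combined n ≤ 20 and no ties use the
  exact null distribution. Constant genes receive p = 1.
- Weights are `2^((lfc_pre+lfc_post)/2)`; larger average LFC ⇒ strictly
  larger weight.
- Ties in modal flux assignments and in UMI-based chain selection break
  lexicographically; all outputs are sorted so results are independent of
  input order.
- Every random path flows through one `numpy.random.Generator`; a seed
  determines all emitted files byte-for-byte.

## Known limitations

- One-to-many single-chain matches can double-count pre-treatment cells when
  several post clonotypes match the same pre clonotype; the generator's
  collision-free CDR3s avoid this, but real data may not.
- The rank-sum test between clonotype score groups is mildly anti-
  conservative when the two groups have very different clone-size
  distributions (score variance scales as 1/cells-per-clone); comparisons
  between size-matched groups are preferable, which is why the NE-vs-PE
  score comparison uses non-singleton pre-existing clonotypes.
- Bonferroni correction is deliberately strict; with thousands of genes it
  trades power for exactness of the signature's false-positive control.
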