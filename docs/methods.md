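# Methods

`cdsevol` analyses a set of coding sequences (CDSs) for codon-usage bias,
pairwise selective pressure and annotation-based gene-set structure. This
document defines every statistic the package computes, the model behind the
synthetic data generator, and the numerical conventions used throughout.

## 1. Sequence validation and assembly statistics (`seqio`)

A valid CDS has positive length divisible by three, no in-frame internal
stop codon, and at least `min_codons` codons (default 30; optionally an ATG
start). A terminal stop codon is stripped and noted. Validation never
deletes sequences — failures are flagged and reported, and downstream
stages use only the valid subset. IUPAC ambiguity codes are normalised to
`N` on input; codons containing `N` are excluded from all codon statistics.

Assembly statistics follow the standard definitions: sequences are sorted
by descending length; Nx is the length of the first sequence at which the
cumulative length reaches x% of the total, and Lx is that sequence's rank.
GC% counts unambiguous bases only. `longest_orf` scans all six reading
frames for ATG-to-stop open reading frames and returns the longest
(ties: forward strand first, then earliest start).

## 2. Codon usage statistics (`codon_usage`)

**RSCU.** For codon *j* in a synonymous family of degeneracy *d* with
family total *m*, RSCU = count_j · d / m. Codons of amino acids never
observed in a gene are reported as NaN (missing), not zero, so that
unobserved families do not masquerade as maximally biased. Met (ATG) and
Trp (TGG) are excluded from the 59-column RSCU matrix because their RSCU
is identically 1.

**ENC.** Wright's effective number of codons. Per amino acid with family
size > 1 and count n ≥ 2, the codon homozygosity is
F̂ = (n·Σp̂ᵢ² − 1)/(n − 1); class means F̄₂, F̄₃, F̄₄, F̄₆ are taken over the
2-, 3-, 4- and 6-fold degenerate amino acids, and

    ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆.

The 3-fold class (Ile only) is imputed as (F̄₂+F̄₄)/2 when Ile is absent or
its F̂ is non-positive (flagged `f3_imputed`); if any other class is
missing or non-positive the ENC is NaN (flagged `enc_undefined`). Values
are clipped to [20, 61].

**Expected ENC.** The compositional null curve
ENC\* = 2 + s + 29/(s² + (1−s)²), evaluated at **s = GC3s**: the G+C
fraction of third positions of *synonymous* codons only (Met, Trp and
stops excluded). Using raw GC3 here biases the ratio ENC/ENC\* away from 1
even for null data, because ATG/TGG third positions are not free to vary;
with GC3s, null cohorts generated at GC3 targets 0.3–0.7 give median
ENC/ENC\* within 0.05 of 1.0 (asserted in the acceptance suite). Both gc3
and gc3s are reported per gene.

**GC partition.** gc, gc1, gc2, gc3 are G+C fractions over all codon
positions and positions 1–3; gc12 is the mean of gc1 and gc2. The ratios
gc3/gc12 and gc3/gc are exported as neutrality indicators.

## 3. RSCU clustering (`cluster`)

The objects clustered are the 59 informative **codons** (matrix columns),
with genes as features. NaN entries are imputed with the column mean; each
codon row of the transposed matrix is z-scaled (population SD;
zero-variance rows dropped with a warning). K-means (scikit-learn,
`n_init` restarts, seeded) is scanned over k; the silhouette score selects
k (ties → smallest k), with the inertia elbow exported as advisory data.
Concordance with the third-base partition (codons grouped by their ending
nucleotide A/C/G/T) is reported as purity and adjusted Rand index; a
single-cluster solution is assigned ARI 0.

## 4. Homology pairs (`homology`)

Proteins are translated (codons with `N` → `X`) and aligned globally with
Bio.Align.PairwiseAligner (BLOSUM62, gap open −11, extend −1); the
alignment is back-translated onto codons. Alignments are computed in a
canonical argument order so scores are symmetric. Coverage = aligned
columns / length of the shorter protein; identity = identical columns /
aligned columns. Pairs pass the filters only with coverage **strictly
greater than** 0.6 and identity **strictly greater than** 0.75 (boundary
values fail). Paralogs are all within-species pairs passing the filters;
orthologs are reciprocal best hits by alignment score (ties broken
lexicographically by id), forming a matching.

## 5. NG86 dN/dS (`selection`)

The Nei–Gojobori (1986) counting method on the codon alignment:

- **Sites.** Each position of a codon contributes 1/3 of a site per
  possible change; changes to stop codons are excluded from the
  denominator (so e.g. TGG has 7/3 nonsynonymous sites). Site totals are
  averaged between the two sequences of a pair.
- **Differences.** For codons differing at 1–3 positions, all orderings of
  the single-base steps are enumerated; pathways through stop codons are
  discarded; synonymous/nonsynonymous step counts are averaged over the
  remaining pathways.
- Columns containing a gap, an `N`, or a stop codon are skipped entirely
  (both sites and differences), keeping numerator and denominator
  consistent.
- **Correction.** Proportions pS = Sd/S, pN = Nd/N are Jukes–Cantor
  corrected, d = −(3/4)·ln(1 − (4/3)p). p ≥ 3/4 is reported as
  `saturated`; dS = 0 as `ds_zero`; no usable columns as `no_sites`; all
  three yield ω = NaN and class `undefined`.

**Classification.** For `ok` estimates: ω < 0.001 → `ultra_conserved`
(dN = 0 with dS > 0 counts as ω = 0); ω > 1.05 → `positive`;
ω ≥ 0.95 → `neutral`; otherwise `purifying`. The neutral band is
implemented by direct comparison against 1 ± ε rather than |ω − 1| ≤ ε so
that ω exactly equal to a bound classifies consistently under
floating-point arithmetic. A gene is positively selected if any of its
pairs, across all comparisons, is `positive`.

## 6. Species-specific genes and annotation sets (`specificity`)

A gene is species-specific iff it has domain evidence (Pfam **or**
InterPro hit) **and** no NR hit **and** no ortholog passing the filters in
any comparator species. Specific genes are grouped into orthogroups as
connected components of the within-species paralog graph restricted to
specific genes (singletons form their own group). Venn counts partition
the gene set into the 7 NR/Pfam/InterPro regions plus "none".

## 7. GO enrichment (`enrichment`)

For a study set of n genes inside a background of N genes, a term
annotated to K background genes and k study genes has one-sided
p = P[X ≥ k], X ~ Hypergeometric(N, K, n), computed via
`scipy.stats.hypergeom.sf(k−1, N, K, n)`. Terms with K < `min_term_size`
(default 5) are not tested. P-values are Benjamini–Hochberg adjusted
(statsmodels) across tested terms; each term reports rich factor k/K and
score −log₁₀(p_adj). The study set must be a subset of the background.

## 8. Synthetic data generator (`synthetic`)

The generator produces every input the pipeline consumes, with known
truth. Its defaults are the study conditions used by the acceptance suite.

**Cohorts.** Gene lengths are Poisson(`len_codons`), minimum 10. Amino
acids are uniform (after a fixed ATG start); codon choice within a family
is proportional to a third-base weight times exp(s_sel) for one designated
preferred codon per family (alphabetically first). Third-base weights are
either the shared GC3 target ({A,T} ← 1−g, {C,G} ← g; mode `"gc"`) or a
per-gene Dirichlet(α = 0.5) draw over A/C/G/T (mode `"per_gene"`, the
clustering scenario — per-gene compositional variation is what makes
codons cluster by ending base). With s_sel = 0 the cohort is the
mutational null on which ENC tracks the expected curve.

**Diverged pairs.** Two descendants of an ancestor evolve independently
under a continuous-time codon model: the relative rate of each single-base
codon change is κ for transitions (default 1), ×ω for nonsynonymous
changes, 0 into stops. Substitutions are sampled event-by-event
(Gillespie). The branch duration is calibrated so the pair divergence t is
the expected number of synonymous substitutions per NG86 synonymous site:
duration = t·S_anc/(2·R_syn,anc) per branch, where S_anc is the ancestor's
synonymous site count and R_syn,anc its total synonymous flux. Realized
synonymous/nonsynonymous event counts are recorded as truth. κ defaults to
1 because NG86 site counting assumes no transition/transversion bias; κ is
exposed for robustness experiments, with the caveat that κ ≠ 1 biases NG86
estimates by construction.

**Annotations and GO.** Exactly `n_specific` genes are planted to satisfy
the specificity rule; background genes draw NR/Pfam/InterPro flags at
rates 0.848/0.629/0.703 (typical plant transcriptome annotation coverage)
and are forced to violate the rule (a comparator orthogroup is added when
a background gene would otherwise satisfy it). Each GO term has a base
annotation rate U(0.02, 0.10); planted terms multiply that rate by
`enrichment_fold` inside a designated study set.

**Generator fidelity.** At the defaults, and as asserted in
`tests/test_acceptance.py`: null cohorts sit on the ENC null curve (median
ratio within 0.05 of 1); ω̂ medians recover ω ∈ {0.1, 0.5, 1.0, 2.0}
within 25% and increase monotonically (50 pairs, 500 codons, t = 0.2);
silhouette-selected k = 4 with purity ≥ 0.9 on per-gene-mode cohorts;
planted specific genes are recovered exactly and planted enriched terms
rank first in ≥ 95% of replicates.

## 9. Pipeline and determinism (`pipeline`, CLI)

Stages (validate → stats → usage → cluster → pairs → dnds → classify →
specific → enrich) communicate through plain TSV/FASTA files in the output
directory. The run manifest records the configuration, input SHA-256
checksums and per-stage row counts; timings go to the log only, so the
manifest — and every output file — is byte-identical across reruns of the
same configuration and seed. Files are written atomically via `.partial`
temporaries. All randomness (k-means restarts, generators) flows from the
single configured seed through `numpy.random.default_rng`.

## 10. Limitations

- NG86 is a counting method: it ignores transition/transversion bias,
  codon frequencies and rate variation; with κ ≠ 1 or strong composition
  bias its ω̂ is biased relative to maximum-likelihood methods. The 25%
  median tolerance reflects counting-method accuracy at t = 0.2, not a
  general guarantee.
- The Jukes–Cantor correction saturates at p = 3/4; deeply diverged pairs
  are reported as `saturated` rather than extrapolated.
- RBH orthology assumes one-to-one orthologs; lineage-specific
  duplications produce missed or arbitrary pairings.
- The specificity rule is evidence-based, not phylogenetic: it inherits
  the sensitivity of the annotation sources and comparator set supplied.
- The generator's amino-acid composition is uniform and indel-free;
  coverage/identity filters are therefore exercised by substitution
  divergence only.
- Silhouette selection can prefer k = 2 on weakly structured matrices; the
  scan and elbow data are exported so the choice is auditable.
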