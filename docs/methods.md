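# Methods

This note documents the models, algorithms, numerical choices, and known
limitations of `orphanscan`.

## Selection inference

### Model

Each homology cluster is analysed under the Goldman–Yang M0 codon model on
the 61 sense codons of the standard genetic code. The instantaneous rate
from codon *i* to *j* is zero unless the codons differ at exactly one
nucleotide, in which case

q_ij = π_j · κ^δts · ω^δnonsyn,

where κ > 0 is the transition/transversion rate ratio, ω > 0 the
nonsynonymous/synonymous rate ratio shared by all sites and branches, and
π the stationary codon frequencies. The matrix is scaled so that
−Σ π_i q_ii = 1; branch lengths are therefore expected codon substitutions
per codon site. Codon frequencies default to **F3x4** (position-specific
nucleotide frequencies estimated from the cluster's own alignment,
restricted to sense codons and renormalized), with a floor of 1e−10 per
codon so the chain stays irreducible on degenerate alignments.

### Likelihood

Log-likelihoods come from Felsenstein's pruning algorithm over the cluster
tree, with alignment columns compressed to unique site patterns, gap codons
treated as missing data (partial likelihood one), and per-column rescaling
so valid inputs never underflow to −∞. Transition matrices P(t) = exp(Qt)
are obtained by eigendecomposition of the π-symmetrized rate matrix
(reversibility makes D^{1/2} Q D^{−1/2} symmetric); scipy's
scaling-and-squaring `expm` is the fallback if the decomposition fails.
For two-sequence clusters the likelihood reduces to
Σ_ij n_ij log(π_i P_ij(t)) over the codon-pair count matrix, which the
implementation uses as a fast path (verified against the generic pruning
path to ~1e−11).

### Trees

Clusters of two sequences are a single edge (only the total path length is
identifiable and only it is optimized); three sequences form a star; four
or more get a neighbor-joining topology (scikit-bio) built from
Poisson-corrected codon distances d = −(60/61) ln(1 − p·61/60). Saturated
pairs fall back to the largest finite distance in the matrix and are
flagged; NJ branch lengths are clipped below at 1e−8 and re-estimated by
maximum likelihood anyway.

### Optimization

Fitting is cyclic coordinate ascent: each branch length, then κ, then ω
(unless fixed) is optimized with bounded Brent's method, sweeping until the
log-likelihood improves by less than 1e−6. Bounds: ω ∈ [1e−4, 10]
(boundary hits flagged), κ ∈ [0.05, 50], branch lengths ∈ [1e−6, 20]. The
free-ω fit restarts from ω ∈ {0.1, 1, 3}; restarts after the first inherit
the best nuisance parameters found so far (they still explore their own ω
start), which roughly halves the cost without changing the deterministic
result. The null fit re-optimizes κ and branch lengths with ω pinned at 1 —
a proper nested fit — warm-started from the alternative fit.

### Test and FDR

The statistic 2(lnL_HA − lnL_H0), clipped at zero, is referred to χ² with
one degree of freedom; ω = 1 is interior to the parameter space, so no
boundary-mixture correction applies. p-values are Benjamini–Hochberg
adjusted *within* each dataset (ortholog, paralog, clade pair), and a
cluster is significantly negatively selected when ω̂ < 1 and q < 0.05.
Identical-sequence clusters are flagged and reported with p = 1 and ω̂
undefined rather than fitted; pairs with zero synonymous divergence are
flagged (`ds_zero`) via the NG86 counts instead of being reported as huge ω.

### NG86 cross-check

The Nei–Gojobori (1986) counting method is implemented independently of the
likelihood machinery: per-codon synonymous/nonsynonymous site fractions
(mutations to stop codons count as neither), pathway-averaged difference
counts for multi-hit codon pairs (pathways through stops excluded; if all
pathways are blocked, positions are classified one at a time),
Jukes–Cantor correction of both proportions. When the synonymous proportion
exceeds the correctable range but the nonsynonymous divergence is zero, the
ratio is reported as 0 (flagged `ds_saturated`). NG86 serves as the oracle
for the ML engine in the test suite (Spearman ρ > 0.9 across a simulation
grid) and is never used as the primary estimator.

## Homology clustering

All-vs-all protein similarity uses Smith–Waterman local alignment
(Biopython's PairwiseAligner; BLOSUM62, gap open 11, extend 1), normalized
by the smaller self-score; edges at normalized similarity ≥ 0.3 form an
undirected weighted graph. A prescreen skips pairs sharing fewer than 10 %
of the smaller protein's distinct 4-mers (computed for all pairs at once by
a sparse matrix product): homologous pairs below ~20 % divergence share
~0.8⁴ ≈ 41 % of them, unrelated pairs of any length about 1 %, so the
threshold sits in a wide gap. An absolute shared-count threshold does not
work — long unrelated proteins share many 4-mers by chance.

Markov clustering (expansion 2, inflation 2, entries pruned below 1e−5,
self-loops of weight 1, at most 100 iterations) partitions the graph;
clusters are read off attractor rows and overlaps merged by union-find, so
the output is always a partition and fully deterministic. Non-convergence
is reported with the partial result flagged.

Clusters are categorized by their focal-species orphan/conserved
composition: clusters mixing orphan and conserved focal genes (**hybrid**)
and clusters private to the sister species are excluded from both selection
datasets (gene fusion/fission and unequal divergence rates make the mixed
clusters unreliable). The **ortholog** dataset takes clusters with at least
one gene from each species; the **paralog** dataset takes clusters with at
least two focal-species genes, *minus* the sister-species members. The
**clade-pair** dataset covers every focal gene, singletons included: the
fixed differences of each of two intra-species lineages are implanted into
the reference CDS (strand-aware, with allele complementation on
minus-strand genes), giving one two-allele "cluster" per gene.

## Alignments

Cluster proteins are aligned progressively: UPGMA guide tree on 3-mer
cosine distances, profile-profile steps by global affine-gap DP (BLOSUM62,
first gap character 10, extension 0.5; rows vectorized, the horizontal gap
state via a running-max scan). Most clusters are pairs, where this is
simply optimal global pairwise alignment (verified against Biopython's
global aligner). Protein alignments are back-translated codon-by-codon onto
each member's CDS (terminal stop codons stripped first); any translation
mismatch or internal stop rejects the cluster with a recorded reason.
Codon alignments shorter than **150 nt of columns, gap columns included**
are dropped from selection analysis. No alignment trimming/masking is done
beyond this length filter.

## Expression and peptide evidence

Thresholds are inclusive: max FPKM ≥ 1 over samples marks a gene expressed,
≥ 10 robustly expressed, and exactly 0 in every sample "zero-everywhere"
(the stratum from which validation candidates are drawn). Saturation curves
accumulate detected genes over k = 1..n samples for seeded random
permutations of the sample order (default 10), summarized as min/quartiles/
max per k, per threshold, per gene class; DE-set saturation does the same
over permutations of gene-set order. Peptides match only as exact,
full-length substrings of a predicted protein (leucine and isoleucine are
not equated); matching runs one Aho–Corasick pass over the proteome and is
tested for set equality against a naive quadratic scan.

## Classification

Classes are assigned with precedence conserved → coding → ncRNA →
artifact → unassigned. "No sign of strong negative selection" for the
negative classes uses the liberal rule (no dataset with ω̂ < 0.6) by
default; a config switch (`ncrna_rule`) substitutes the conservative rule.
The four named classes are deliberately not exhaustive: orphans whose only
evidence is weak expression (1 ≤ max FPKM < 10) stay `unassigned` rather
than being forced into a class. The ncRNA and artifact classes are
restricted to orphans; conserved genes form their own class regardless of
other evidence. Validation candidates are orphans with significant negative
selection, zero expression everywhere, ω̂ < 0.6 in at least two of the
three datasets, and more than two exons.

Feature contrasts between classes (transcript length, exon count, GC
fraction, contig-size percentile, with ties sharing the minimum rank in the
contig ranking) use two-sided Wilcoxon rank-sum tests — exact enumeration
when n₁·n₂ ≤ 400 and there are no ties, otherwise the tie- and
continuity-corrected normal approximation.

## Synthetic data generator

The generator emulates the study design: a focal genome with conserved and
orphan genes, a sister species, two intra-species clades, 14 RNA-seq
samples, six DE gene sets, and a peptide catalog. Design choices:

* **Divergence calibration.** Config divergences are *nucleotide*
  divergences (defaults 0.10 interspecies, 0.01 intraclade). For each gene
  the generator inverts the M0 expected-divergence curve
  D(t) = Σ_ij π_i P_ij(t)·hamming(i,j)/3 by bisection to get the codon
  branch depth, so realized divergence matches the request irrespective of
  the gene's ω and codon frequencies (tested on ≥ 10 kb).
* **Gene classes.** Orphans are 60 % "coding" (ω lognormal around 0.25),
  20 % ncRNA-like and 20 % artifact-like (both neutral, ω = 1); conserved
  genes have ω around 0.15. Orphans are drawn shorter (median 130–150 vs
  350 codons) with fewer exons (mean ≈ 2.5–3 vs 6), echoing the feature
  contrasts real orphan sets show.
* **Sequences** evolve by substitutions only, restricted to sense codons
  (no indels, no stop codons — matching the model's state space); per-gene
  codon frequencies come from Dirichlet positional nucleotide biases, so
  GC content varies across genes. 12 % of conserved and coding-orphan
  genes carry a paralog copy (duplication halfway down the focal branch),
  populating the paralog dataset at roughly the occupancy real data shows.
* **Expression.** Expressed genes (90 % of conserved, 55 % of coding
  orphans, all ncRNA candidates, no artifacts) get log-normal FPKM in a
  random subset of samples; non-expressed genes are exactly 0, so the
  zero-everywhere stratum exists. A defining floor is enforced per class
  (an "expressed" gene reaches FPKM ≥ 1 somewhere, an ncRNA candidate
  ≥ 10), since a class label contradicted by its own defining observable
  would make truth-scoring meaningless.
* **DE sets** sample expressed genes at per-set rates of 15 % (conserved)
  vs 7.5 % (orphan) — the ~2× enrichment of conserved genes seen in real
  profiling compendia. **Peptides** are random 7–25-residue substrings of
  true proteins covering 25 % of conserved and 7 % of coding-orphan genes,
  plus shuffled decoys verified to be non-substrings.
* **Determinism.** All randomness flows from one `numpy` Generator seeded
  by the config; identical configs produce byte-identical output files.

What the generator does **not** emulate: indel evolution and alignment
uncertainty, codon-usage bias beyond the frequency vector, assembly errors,
read-level noise in FPKM, an orphan-gene origination process, or the
genomic clustering of genes on contigs. Passing the end-to-end tests
therefore shows the pipeline recovers planted signal under the model's own
assumptions — not that it is robust to misalignment or annotation error,
where real orphan analyses meet most of their trouble.

## Problem sizes and numerical defaults

The simulation-based checks use sizes chosen to give stable statistics at
desk scale: 100 random draws for the likelihood oracle; 50 replicates × 500
codons per point of the ω grid {0.1, 0.3, 0.5, 1, 2}; 200 neutral clusters
of 300 codons for LRT calibration; 100 clusters at ω = 0.2 per divergence
scale for power; and a 500-gene genome (300 conserved + 200 orphan) for the
end-to-end class-recovery run. χ² tails, rank-sum tests and BH adjustment
go through scipy/statsmodels; tolerances asserted in the tests are 1e−8
for the likelihood oracle, 15 % relative error for median ω̂ recovery, the
exact-binomial 99 % band for LRT type-I error, and ARI ≥ 0.9 for cluster
recovery.

## Known limitations

* M0 only: no site/branch heterogeneity of ω, no positive-selection site
  inference; κ and π treatments mirror common codeml M0 defaults but exact
  numerical agreement with codeml is not claimed.
* The intra-species clade comparison accepts pre-filtered biallelic fixed
  differences only; genotype-quality filtering is assumed upstream.
* The 150-nt filter is the only alignment-quality gate; badly aligning
  clusters longer than that are not specially detected.
* At ~1 % divergence, ω̂ on short genes is noisy; liberal (ω < 0.6) calls
  from the clade dataset include a substantial random-fluctuation
  component, which is why the conservative (LRT) rule exists.
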