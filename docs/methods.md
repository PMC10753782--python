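# Methods

`nitriscan` re-implements, as a tested library, the comparative-genomics
workflow used in surveys of labile dissolved organic nitrogen (LDON)
metabolism across nitrifier guilds (ammonia-oxidizing archaea and bacteria,
nitrite oxidizers, comammox): homolog screening for a catalog of
LDON-metabolism genes, gene-neighborhood profiling, composition analysis
(GC%, CAI), a composite lateral-gene-transfer screen, cell surface-to-volume
morphometrics, and bootstrapped protein phylogenetics.  A synthetic-genome
generator supplies every input with known ground truth, so the whole
pipeline is exercised without downloading public genomes.

## Homolog screening

An ORF is a homolog of a catalog family if an exact Smith–Waterman local
alignment of its protein against the family's reference reaches **identity ≥
0.40** (identical columns / aligned columns, gaps included in the
denominator — the BLAST convention).  Alignment uses BLOSUM62 with affine
gaps, open 11 / extend 1 (BLAST-style: a gap of length *k* costs 11 + *k*).
Exact dynamic programming (Biopython's `PairwiseAligner`) replaces heuristic
seeding; genomes at this scale are small enough that exhaustive alignment is
cheap, at the cost of occasionally scoring marginal hits a seeded search
would skip.  Two additions the identity rule alone does not determine:

* a **reference-coverage floor** (default 0.50, set 0 to disable) suppresses
  spurious short local hits;
* an ORF passing thresholds for several (often mutually homologous) families
  is assigned to **exactly one** — highest score, ties broken by identity
  then lexicographic family name — so transporter paralogs are not
  double-counted.

Among co-optimal alignments the one ending at the smallest (query, target)
end coordinates is preferred; the choice is made over the aligner's first
eight reported optima rather than an exhaustive enumeration, whose size can
be combinatorial.  Only identity/coverage (not the score) depend on this
choice, and only at exact score ties.

## Gene neighborhoods

The synteny distance between two genes is the number of annotated ORFs
strictly between them on the same replicon (adjacent = 0), using annotation
ordinals, not base pairs.  Pairs are classed adjacent (0), proximal (1–10),
spaced (11–255) or distant (≥256); the class boundaries are configurable and
chosen to echo how gene-organization figures in this literature verbalize
spacing ("contiguous", "a small number of genes", "over 256 interval ORFs").
On replicons flagged circular the shorter arc is counted.  Cluster reports
list consecutive pathway hits in genomic order — the textual analogue of a
gene-order diagram.

## Composition: GC% and CAI

GC content is (G + C + ½·S) / all non-gap characters, case-insensitive;
other ambiguity codes count only in the denominator.  CAI follows Sharp &
Li: per amino acid, relative adaptiveness w = codon frequency / max
synonymous frequency in a reference CDS set; a gene's CAI is the geometric
mean of w over its codons, excluding Met, Trp and stops (no synonymous
choice).  Unobserved codons get the pseudo-weight 0.5 / (count of the most
frequent synonym); amino acids wholly absent from the reference get w = 1.

The reference set defaults to the genome's own ribosomal-protein CDS
(annotation labels containing "ribosomal protein"), the classic highly
expressed set, falling back to all CDS when fewer than 10 are found; the
mode used is recorded in every output.  "Genome CAI" is operationalized as
the median per-CDS CAI.  Self-referenced weights keep the pipeline
download-free but mean absolute CAI values are not comparable to tools that
use a fixed external reference organism.

## LGT screen

Three evidence channels per gene family per strain group:

1. **GC deviation** — two-sided Mann–Whitney of per-strain gene GC against
   the same strains' whole-genome GC (pooled two-sample, matching how such
   comparisons are usually reported);
2. **CAI comparison** — the same test on per-strain gene CAI vs genome
   median CAI; *advisory only*, since elevated CAI can equally mean high
   native expression;
3. **phylogenetic incongruence** — a gene tree contradicts the organismal
   grouping if some labeled leaf's smallest well-supported (bootstrap ≥ 70)
   enclosing clade contains only leaves of a different group; it is
   congruent when every group is monophyletic (unrooted sense), untested
   when supports are absent or neither condition resolves.

Verdict: `LGT_candidate` iff the GC deviation is significant (α = 0.05,
configurable) **and** the phylogeny does not contradict it (flag ≠
congruent); `indeterminate` below 3 strains per side; `vertical` otherwise.
Direction fields (gene_higher/gene_lower) report the median difference
regardless of significance, keeping the evidence channels independent of the
α choice; all channels are retained in the output so users can re-combine
them.  The bootstrap threshold 70 is the community convention for "good"
support.

## Morphometrics

SA/V (μm⁻¹) from literature cell dimensions (means of reported widths and
lengths): sphere of diameter d → 6/d; rod as a flat-capped cylinder of
diameter d, length h → 4/d + 2/h.  The flat-capped form (not a
spherocylinder) is used deliberately: it is the standard simple rod model in
this context, and both forms are unit-tested against surface area and volume
computed separately and divided.

## Statistics

Two-sided throughout.  Mann–Whitney is exact (permutation null) for
tie-free samples with n₁+n₂ ≤ 16, tie-corrected normal approximation
otherwise.  Group comparisons pair a Kruskal–Wallis omnibus with Dunn's
post-hoc z tests (Bonferroni within the family); classical one-way ANOVA is
also provided, since survey papers often name ANOVA while applying Dunn's
method (which follows Kruskal–Wallis) — the rank-based omnibus is the
default.  Correlations: Pearson, and Spearman as Pearson on midranks.
Standard tests are delegated to scipy.stats behind this module's surface;
Dunn's z is implemented here.  The test suite validates the exact rank-sum
path against full enumeration of every tie-free configuration up to 8+8.

## Phylogenetics

* **Models**: Poisson (uniform) and LG amino-acid replacement, optionally
  +Γ (discrete gamma, 5 categories by default, mean-per-quantile-bin rates)
  and +I (invariant sites).  With +I the gamma rates are rescaled by
  1/(1−p_inv) so the site-rate mixture has mean exactly 1 and branch lengths
  stay in substitutions/site.  Equilibrium frequencies default to the
  model's own; empirical (+F) frequencies can be supplied.
* **Likelihood**: Felsenstein pruning with site-pattern compression; gaps
  and unknown residues are missing data (all-ones partials).  Transition
  matrices come from the symmetrized eigendecomposition of the reversible
  rate matrix; the suite checks the pruning result against exhaustive
  internal-state enumeration (with `scipy.linalg.expm` matrices) to 1e-10
  and verifies root-placement invariance.
* **Distances**: pairwise ML distances maximize the two-sequence mixture
  likelihood; the optimum is found by root-finding the analytic likelihood
  gradient (machine precision — a bounded scalar minimizer alone is limited
  to ~1e-8 by objective conditioning).  The plain Poisson model uses its
  closed form −(19/20)·ln(1 − 20p/19).  Saturated pairs are capped at 50
  substitutions/site; pairs with no shared ungapped columns are undefined.
* **Search**: neighbor joining (Saitou–Nei; negative branch estimates
  clamped to 0 with the deficit moved to the sister; deterministic
  lexicographic tie-breaks) followed by optional NNI hill-climbing that
  accepts strict likelihood improvements, re-optimizing the central edge per
  candidate and the local neighborhood after acceptance.  This NJ+NNI
  strategy stands in for a full ML tree search; it is adequate and fully
  testable at single-gene scale (tens of leaves).
* **Model choice**: BIC = k·ln(n_sites) − 2·lnL, k counting branch lengths
  plus one per fitted rate parameter (α, p_inv), fitted by coordinate
  descent on a fixed topology.
* **Bootstrap**: column resampling, NJ (optionally NNI) per replicate,
  support = percentage of replicates containing each bipartition of the
  point-estimate tree; 1000 replicates by default, fully seeded.  Supports
  below 50 are still written — filtering is a display choice.

## Synthetic data

The generator's purpose is controlled ground truth, not biological realism:

* **Genomes**: background CDS are random proteins (LG equilibrium amino-acid
  composition, lengths 80–250) back-translated codon-by-codon from a solved
  codon distribution; intergenic spacers 15–60 bp at the genome GC; ~20% of
  ORFs on the minus strand; one linear replicon per strain.
* **Composition control**: synonymous-codon probabilities ∝
  exp(β·GC(codon) + 6·s·[codon = preferred]), with β solved (Brent) so the
  expected coding GC hits the target and s ∈ [0,1] the codon-bias strength
  interpolating toward a single-preferred-codon table (one synonym per
  amino acid, chosen per host).  This realizes GC offsets mostly through
  third positions and gives CAI a controllable gradient.  Coding GC is
  bounded by amino-acid composition (glycine is always ⅔ GC), so achievable
  targets live in roughly [0.28, 0.66]; infeasible specs raise an error.
* **Homolog divergence**: BLOSUM62-weighted substitutions at
  round((1−target)·L) positions, so realized global identity is within 2
  points of the target and diverged members stay alignable like real
  homologs.
* **Alignments**: evolved along a given tree (root from equilibrium, site
  rates sampled from the model's class mixture, per-branch transition
  matrices); empirical substitution flows are checked against P(t).
* **LGT panels**: 6 AT-leaning recipients + 6 GC-rich donors, each with one
  copy of the focal gene; under transfer the recipients' copies carry a +10
  point GC offset and an alien codon table, and the generating gene tree
  attaches each recipient inside the donor clade (reconstruction by
  NJ + bootstrap is part of the exercise); under vertical descent
  composition is native and the gene tree mirrors the grouping.

What the generator does **not** emulate: real nitrifier gene content beyond
family labels, operon structure and regulatory regions, amelioration of
transferred genes over time, multi-replicon architectures, annotation error.
Passing tests therefore demonstrate the machinery is correct under the
stated statistical structure, not that the screen's error rates transfer to
real panels.

## Problem sizes and numerical choices

The validation suite runs the alignment oracle on 200 random pairs,
likelihood enumeration on all 4-taxon fixtures, NJ recovery on 100 additive
matrices, exact rank-sum enumeration on all tie-free configurations up to
8+8 plus 10,000 null simulations, 100 + 100 LGT panels, and 20 phylogeny
replicates at 8 taxa × 500 sites — sizes chosen so each suite completes in
minutes on one CPU while keeping the Monte-Carlo error well inside the
asserted margins.  Branch-length optimization uses bounded Brent with
tolerance 1e-6 on [1e-9, 20]; likelihood enumeration tolerance 1e-10; CAI
oracle tolerance 1e-12.  Degenerate inputs (empty sequences, saturated
distances, all-gap columns, groups below 3 strains) return explicit error
values or `indeterminate` markers rather than silent numbers.

## Known limitations

* The pipeline consumes annotated genomes; it performs no gene calling and
  no multiple alignment (the pipeline's built-in tree stage pads homologs
  with terminal gaps — adequate for collinear 40%+ families, conservative
  otherwise; feed externally aligned FASTA to the phylo API for serious
  trees).
* CAI values are reference-set dependent; only within-genome comparisons
  are meaningful here.
* The LGT verdict is a screen, not donor inference: no reconciliation,
  no dating, no explicit donor identification.
* Exact printed equality with any particular legacy tool's trees
  (heuristics, model grids) is not claimed; the suite validates against
  oracles, not against other software's output.
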