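# Methods

## The coevolution statistic

The screen treats each orthogroup as a binary vector over genomes placed
in a fixed phylogeny-derived order, and scores a gene pair by how often
the two vectors switch state *simultaneously and in the same direction*
at adjacent-genome boundaries.  For N genomes there are N−1 boundaries;
each boundary of each gene carries a signed transition (+1 gain, −1
loss, 0 none).  A pair's boundaries partition into: a (both transition,
same sign), b and c (exactly one transitions), d (neither), and disc
(both transition, opposite signs).  Discordant boundaries are excluded
from the 2×2 table rather than pooled into a: concordance means a shared
gain or a shared loss, and a gain opposite a loss is evidence against
coevolution, not for it.  They are reported in the `disc` column so the
exclusion is visible; penalizing them further is a deliberate non-choice
(no principled weight presents itself, and at realistic noise levels
they are rare).

Significance is one-sided: P(X ≥ a) under the hypergeometric law of the
table's margins.  The screen looks for an *excess* of concordance; a
two-sided test would also flag avoidance, which is not the question
being asked.  The hypergeometric survival function is evaluated with
scipy (stable to well below 1e−12 on tables up to thousands of
boundaries; the test suite verifies equality with an exact rational
enumeration on all tables with total ≤ 12).  An empty table (no
transitions in either gene) is defined as P = 1.

Multiplicity is controlled by Bonferroni: adjusted P = min(1, m·P) with
m the number of pairs actually tested.  Genes with fewer than
`min_transitions` (default 1) transitions are excluded before pairing —
a constant profile cannot reject any null — and excluded genes do not
inflate m; a flag restores the unfiltered family size for a stricter
correction.  The default significance threshold is adjusted P < 0.001.

The statistic is deliberately linear-order-based: transitions are
counted on the leaf sequence, not on tree edges via ancestral-state
reconstruction.  Convergent losses in adjacent clades can therefore
merge, and a single internal-branch event appears at up to two
boundaries (where the affected clade's leaf block begins and ends).
These are accepted properties of the method, not defects of the
implementation.

## Genome ordering

Any linearization of a phylogeny is a convention; what matters is that
it is deterministic and shared by all genes.  The canonical order used
everywhere is the left-to-right leaf sequence after ladderization:
children sorted by descending subtree leaf count, ties broken by the
lexicographically smallest leaf label in the subtree.  The order is a
function of topology alone — rotating children in the input Newick
string does not change it — and an explicit order file can override it
to reproduce someone else's linearization.  Branch lengths are read but
never used: the statistic is order-based, not rate-based.

## Markov clustering

Significant pairs form an undirected graph weighted by
min(300, −log₁₀ adjusted P) (cap so that floating-point underflow of P
still gives a finite weight; `binary` mode sets all weights to 1).  MCL
is implemented directly on a dense column-stochastic matrix: self-loops
with weight equal to each node's maximum incident edge weight (the
standard regularization that damps oscillation), then repeat [expansion:
matrix power 2; inflation: entrywise power 2.0 followed by column
normalization; pruning: zero entries below 1e−5, keeping each column's
maximum, renormalize] until the largest entrywise change is below 1e−8
or 100 iterations elapse (non-convergence sets a flag and returns the
current partition).  Clusters are read from attractor rows (nonzero
diagonal); attractor systems with overlapping supports merge; a node
attracted to several clusters goes to the largest, ties to the cluster
with the lexicographically smallest member.  The worst observed
deviation of any column sum from 1 is carried in the result as a
numerical diagnostic.  The iteration has no randomness, never joins
disconnected components (the matrix stays block-diagonal), and always
returns a partition of the clustered nodes.  Hyperparameter defaults
(inflation 2.0, expansion 2) are the common MCL practice; cluster
granularity rises with inflation, and sensitivity to it is a property
of MCL itself, documented here rather than asserted in tests.

Genes with no significant partner are excluded from clustering by
default (they carry no information for the flow process); a flag retains
them as singletons.

## Start-codon annotation

Coordinates are 0-based, half-open; input sequences are normalized to
uppercase DNA (U→T).  Given a transcript with an annotated ATG at
`cds_start` and an ORF of L codons (stop excluded), the scanner walks
the in-frame upstream codon positions 5′→3′ and reports every codon in
the allowed set (default {CTG}; an extended near-cognate set
{CTG, GTG, TTG, ACG, ATT} is selectable) such that no in-frame stop lies
strictly between candidate and ATG.  Each candidate carries: distance to
the ATG (a multiple of 3 by construction), extension length
distance/3, extended protein length L + extension, and the Kozak context
at the only two positions scored — −3 (match if A or G) and +4 (match if
G) — with `preferred` the conjunction.  A candidate closer than 3 nt to
the 5′ end gets an `unknown` (None) −3 flag rather than an error.  No
filtering on Kozak status is applied: flags are reported, the decision
is the analyst's.  Out-of-frame candidates are out of scope by design —
an out-of-frame start would not extend the annotated protein.

Frame conservation across orthologs takes an alignment and the columns
of the candidate codon and the annotated ATG.  Per sequence, the verdict
is *conserved* iff every gap run between the anchors has length
divisible by 3 and the ungapped sequence from the candidate to the ATG
contains no in-frame stop (frame anchored at the candidate).  A gap at
the candidate's own column means the ortholog lacks the candidate and is
reported not-conserved with that reason.

## The simulator

The generator emulates orthology-database phyletic profiles — hundreds
of genomes, discontinuous presence/absence — without fitting any real
data.  Each gene evolves down a random rooted bifurcating tree
(recursive uniform splits; exponential mean-1 branch lengths, generated
for realism but not coupled to the flip model) as a two-state chain:
root state Bernoulli(ρ₀); on each branch, present→absent with
probability μ and absent→present with probability λ.  A planted module
draws once a set of "event branches" (fraction σ of all branches); on
each event branch one coin per module (probability κ) toggles every
member simultaneously, overriding that branch's independent noise for
the members; the single shared coin is exactly what creates same-sign
co-transitions detectable by the screen.  Per-branch Bernoulli flips
were chosen over continuous-time rates deliberately: they are simpler,
parameterized in the same units the screen sees (events per branch), and
sufficient to produce the discontinuous patterns the method targets.

Defaults are the benchmark condition used throughout the tests: N = 300
genomes, 200 background genes, one 10-gene module with σ = 0.15,
κ = 0.9, μ = λ = 0.05, ρ₀ = 1, seed 20230317.  One `numpy` generator
seeded from the config drives everything in a fixed draw order (root
states for all genes; event-branch choice per module; then per branch in
preorder: independent flips for all genes, then one co-event coin per
module), so identical config and seed give a bit-identical matrix.

What the simulator does *not* model: gene duplication and copy number
(presence is binary by construction), horizontal transfer, lineage
heterogeneity of rates, correlated backgrounds (e.g. genome quality
artifacts that delete many genes at once), and annotation error.
Passing the recovery benchmark therefore shows the pipeline detects the
concordance signal it is built for at realistic noise; it does not show
robustness to systematic artifacts of real genome databases.

A subtlety worth recording: under the null (no modules) the genes of one
replicate are independent, but they share the tree, and the per-boundary
transition propensity varies with the path length between adjacent
leaves in the linearization.  Independent genes therefore co-transition
at long-path boundaries more often than a uniform permutation of
boundaries predicts, so a naive shuffle is a biased independence oracle
for tree-generated data.  The test suite instead compares within-replicate
concordance to concordance across independently seeded replicates on the
same tree — independent by construction, same propensity profile.  The
family-wise error calibration (≤ 0.5% of 1,000 null replicates with any
Bonferroni-adjusted P < 0.001 at 50 genes × 200 genomes) is unaffected
and holds with large margin, Bonferroni being conservative under the
positive dependence this induces.

## Problem sizes and determinism

The benchmark screen (210 genes × 300 genomes, 21,945 pairs) runs in
under a second on one core via vectorized pair counting (the concordant
and discordant counts for all pairs fall out of two integer matrix
products of the signed transition matrix with itself); the 1,000-replicate
null calibration takes well under a minute.  These sizes were chosen as
the smallest at which the planted-module condition is comfortably
detectable while keeping every run interactive.  All pipeline artifacts
are byte-identical across reruns of the same config and inputs
(timestamps live only in the log); every stochastic step routes through
the single configured seed.

## The worked transcript fixture

The packaged transcript (`coevoscreen.fixtures`) is synthetic: only its
documented coordinates are biological — a 171-codon annotated ATG ORF
(the annotated mouse CATSPERθ length) and an in-frame CTG 213 nt
upstream with an open extension and preferred Kozak context, so that
initiation at the CTG yields 171 + 71 = 242 residues.  The filler
sequence is repetitive synthetic DNA, not the GenBank record, and the
fixture is labelled synthetic in code.

## Known limitations

- Linear-order transition counting conflates some tree events (see
  above); a Dollo or ML gain/loss mapping is an explicit non-goal.
- Bonferroni is conservative; with very large gene sets it will miss
  weakly coupled pairs that an FDR procedure would keep.  The threshold
  α = 0.001 on adjusted P follows the screen's published convention.
- MCL granularity depends on the inflation parameter; the default 2.0 is
  not tuned per dataset.
- The Kozak score is the two-position rule (−3 purine, +4 G), not a full
  position-weight matrix — by design, matching what the annotation
  procedure actually claims.
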