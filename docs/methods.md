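# Methods

## Scope and model

`sctfam` re-implements, at desk scale, the comparative workflow used to
characterise the chordate secretin/glucagon peptide family (SCT, VIP,
PACAP, PHI/PHM, PRP, GHRH, GCG, GLP1, GLP2, GIP — ligands of class B1
GPCRs). The working hypothesis encoded throughout is that the family
descends from one ancestral ~27-residue exon that duplicated into two
subfamilies — PACAP-like (PACAP, PRP, VIP, PH, GHRH, SCT) and GCG-like
(GCG, GLP1, GLP2, GIP) — each subsequently duplicating into peptide
groups sampled across taxa. Every stage operates on a fixed aligned
window of the mature peptide: residues 1–27, except GLP1 where residues
5–32 (the single conserved coding exon) are used instead. The lamprey
proglucagon-II GLP2 is excluded from group comparisons by default; it is
too diverged to inform the consensus.

## Mature-peptide extraction

Precursors are globally aligned (Needleman–Wunsch, affine gaps) to a
reference mature peptide and the precursor residues occupying the
reference window columns are read off. Scoring defaults to BLOSUM62 with
gap open 10 and extend 1 (a length-k gap costs `open + (k-1)*extend`;
terminal gaps are penalised). These defaults favour short-peptide
sensitivity; they are deliberately simple and fully specified so that an
exhaustive enumeration of alignments reproduces the optimum exactly,
which is how the implementation is tested. The traceback tie-break is
fixed (diagonal > up > left) so extractions are deterministic. A
precursor whose identity to the reference over the window falls below a
floor (default 25%) is reported as "no homologue" rather than raising —
absence of a family member is itself a result here.

## Consensus, signatures, prototype

Column profiles count residues per column with gaps excluded from the
frequency denominator. A consensus position is defined when the most
frequent residue is a unique maximum with frequency ≥ τ (default τ =
0.5); ties and sub-threshold columns become the wildcard `x`. The
plurality-with-threshold rule is the minimal formalisation that yields
degenerate patterns with wildcards; τ is recorded in every output.

Percent identity counts matches over columns where both operands are
non-gap and non-wildcard; percent similarity additionally counts
residues in the same similarity group. The default scheme is the strong
partition {ILMV} {FWY} {KRH} {DE} {ST} {NQ} {AG} {C} {P}; similarity
computations name the scheme in their outputs because published
similarity figures depend on the (often unstated) grouping used.

Two subfamily consensuses are fused into a prototype by position-wise
union: a position defined in exactly one input, or in both with the same
residue, is kept; conflicting or doubly-undefined positions become
wildcards. The operation is commutative and idempotent. On the published
subfamily residue sets it yields
`HADGTFTSDYSxxLxQxxAKxFxxWLx` — 18 defined positions, agreement at H1
and F6, and a wildcard at position 23 where the subfamilies conflict
(L vs V).

Signature residues of a group are (position, residue) pairs with
within-group frequency ≥ τ_in (default 0.8) and frequency ≤ τ_out
(default 0.2) in every other group — residues that discriminate one
peptide group from the rest.

## Profile search and significance

A PSSM is compiled as background-weighted log-odds in bits:
`score(p, r) = log2((count(p,r) + α·bg(r)) / ((n_p + α)·bg(r)))` with
Laplace-style pseudocount α = 1 and a uniform background by default.
Wildcard and all-gap columns carry zero scores; the neutral characters
X, `*` and `-` contribute zero wherever they occur in a scanned window.
Nucleotide databases are scanned through all six reading frames
(standard genetic code; N codons → X); the nucleotide coordinate of a
hit in frame f at window offset s is `(|f|-1) + 3s` on the reported
strand.

Significance is empirical: residues are permuted within each database
record, the best window score of each shuffled database is recorded, and
`p = (k+1)/(n_shuffles+1)` where k counts shuffled maxima ≥ the hit
score (add-one estimator; n_shuffles = 200 by default, filter p < 0.01).
This permutation-of-the-maximum null controls for database size and
per-record composition. It is not an E-value and no mapping to one is
attempted; the p < 0.01 filter plays the same screening role the
published analysis assigned to E < 0.01.

## Phylogeny

Distances are pairwise-deletion p-distances. Trees are built with
Saitou–Nei neighbor-joining (Q-criterion minimisation, ties broken by
the lowest index pair, negative branch lengths clamped to zero with a
log entry) — NJ is exact on additive matrices, which is the oracle class
used in testing. Nonparametric bootstrap resamples columns with
replacement; support is the percentage of replicate trees containing
each bipartition of the point-estimate tree. Likelihood and Bayesian
machinery is deliberately out of scope: the downstream claim being
tested is topological (a clean PACAP-like/GCG-like bipartition), not a
branch-length or model-fit statement.

The monophyly statistic is the minimum number of label-pure maximal
clades that partition the leaves, minimised over all rootings of the
tree treated as unrooted (equivalently: the minimum number of label-pure
edge-sides partitioning the leaf set, computed by directed-edge dynamic
programming). A value of 2 is the two-clade configuration; rooting is
never assumed.

## Synteny

Gene neighborhoods are ordered, stranded gene lists on one
chromosome/scaffold; coordinates are 0-based half-open internally and
published 1-based intervals are converted on ingest (intervals printed
high-to-low denote minus-strand genes and are normalised with the strand
recorded). Homology is resolved only through an explicit symbol map —
this module tests arrangement, never infers homology. Shared flanking
genes are homology classes with a member in each neighborhood; order
conservation is the longest common subsequence of the shared classes in
each neighborhood's positional order (the LCS statistic is this
package's operationalisation of "gene order is in general maintained",
which was not quantified in the source analysis). The cluster test
reports `span = max(end) − min(start)` for same-chromosome loci and
calls them clustered iff span ≤ max_span (default 1 Mb — "close
proximity" has no published threshold, so the default is explicit and
configurable).

## Synthetic families

The generator emulates the assumed evolutionary scenario, with ground
truth retained for every downstream stage. Defaults (the conditions all
stochastic tests run under): width 27; 2 subfamilies × 5 groups × 8
taxa; anchor columns (1, 3, 6, 7, 23) substituting at 0.02; variable
columns at 0.15 per leaf; subfamily divergence 0.7 and group divergence
0.25 applied once at each duplication on variable columns; 2 signature
columns per group with a forced residue chosen to differ from every
subfamily ancestor's residue at that column. Substitutions replace a
residue by a member of its similarity group with probability 0.7, else
uniformly — this produces the identity > similarity gradient without
rate-matrix machinery. The divergence defaults reproduce the family's
documented conservation gradient (within-group identity ~85%,
between-group ~45%, cross-subfamily ~30%) and, as a consequence, a clean
two-clade topology.

Two modelling choices deserve emphasis:

* **Leaves diverge independently.** Each taxon's sequence is an
  independent draw from the group ancestor at the per-column
  probabilities; the generated ultrametric species tree is recorded as
  truth metadata but does not correlate substitutions across taxa.
  Independence makes realised per-column substitution frequencies
  binomial in the number of leaves, which is what the parameter-recovery
  checks verify; the cost is that within-group phylogenetic structure is
  star-like, so the package's tree stage is validated on the
  subfamily/group signal only.
* **Signature columns are frozen outside their owner group.** Non-owner
  groups keep the subfamily-ancestor residue at another group's
  signature column, so configured signatures are diagnostic by
  construction and exactly recoverable in the zero-noise limit.

Decoy proteomes (40 × 300 aa) and nucleotide records (8 × 600 nt) are
drawn from a uniform background and screened so that no window reaches
45% identity to the ancestral or subfamily motifs — guaranteed
family-free negatives for search calibration. Simulated genomes implant
the flanking-gene block, order-preserved, around the family locus in two
genomes; the decoy genome carries homologues of the same flanking genes
megabases apart on one chromosome with no family gene, mirroring the
protostome situation the synteny test probes.

What the simulator does **not** model: indel-rich alignment error
(indels default off and, when enabled, are single-column deletions),
codon-level evolution, empirical amino-acid exchangeabilities,
rate-across-site distributions, and correlated taxon sampling. Passing
tests therefore demonstrate that the pipeline recovers planted structure
under its own generative assumptions, not performance on real,
alignment-uncertain data.

## Numerical and procedural choices

* Positions are 1-based throughout the public API (matching superscript
  residue numbering); scan offsets are 0-based half-open with the frame
  reported alongside.
* Identity/similarity denominators exclude columns where either operand
  has a gap or wildcard; zero comparable columns yields NaN, flagged by
  callers, never an exception.
* All randomness flows through one seeded `numpy` generator per entry
  point; the pipeline refuses to run stochastic stages without a seed,
  and a re-run with the same seed reproduces every artifact
  byte-for-byte.
* Problem sizes in the test suite (20 seeds for calibration statistics,
  100 random trees for the NJ oracle, 200 permutations per significance
  estimate, bootstrap with 100 replicates) were chosen to keep each
  statistical check's sampling error well inside its decision margin
  while the whole suite stays interactive.

## Known limitations

* The permutation p-value is conditional on per-record composition; it
  is not calibrated against BLAST E-values, and comparisons of absolute
  significance across databases of very different size should use the
  same n_shuffles.
* Published real-data identity/similarity percentages depend on the
  accessioned sequences and on the similarity grouping of the program
  that produced them; with a different scheme the similarity (not
  identity) figures will differ. The scheme is therefore configurable
  and recorded in outputs.
* `extract_mature` assumes the precursor contains at most one copy of
  the mature peptide; tandem repeats would be reported only once, at
  the best-scoring alignment.
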