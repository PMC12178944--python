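# Methods

This note records the models and procedures the package implements, the
parameters that matter, and the choices made where the design was
genuinely open.

## Distances

The Kimura two-parameter (K80) model distinguishes transitions (A↔G,
C↔T) from transversions. With P and Q the transition and transversion
proportions over comparable sites, the distance in substitutions/site is

    d = -1/2 · ln((1 - 2P - Q) · sqrt(1 - 2Q)).

**Pairwise deletion.** A site is comparable only when both sequences
carry an unambiguous A/C/G/T; gaps and IUPAC ambiguity codes exclude the
site for that pair only. Complete deletion would discard most of the
signal when short metabarcoding fragments are compared against
full-length references, so pairwise deletion is the default and only
mode. Each distance therefore carries its own `sites_used` count.

**Saturation.** When `1-2P-Q ≤ 0` or `1-2Q ≤ 0` the logarithm is
undefined. Such pairs are reported as +infinity with a
`SaturationWarning` rather than raised: clustering can still proceed
(an infinite distance simply never links), whereas neighbour joining
refuses matrices containing infinities and advises cluster-wise trees.
A pair with zero comparable sites is an error, not a distance.

**Neighbour joining** uses the Saitou–Nei agglomeration as implemented
in scikit-bio, with negative branch-length estimates clamped to zero.
On additive matrices the reconstruction is exact (verified to 1e-9 in
the tests).

## MOTU delimitation

MOTUs are connected components of the graph linking every pair at
K2P ≤ t (single linkage — the connectivity notion underlying both
RESL/BINs and ASAP-style partitioning). Cluster ids are the smallest
member label, making partitions deterministic.

A sweep over thresholds (default 0.002–0.10, step 0.002, bracketing the
< 3% within-MOTU divergence typical of COI) produces one candidate per
*distinct* partition. Candidates are scored by

    score = rank(-gap_width) + rank(-plateau_length)

where `gap_width` is the smallest between-cluster linkage minus the
largest within-cluster distance and `plateau_length` is the number of
consecutive sweep steps yielding the identical partition; average ranks
on ties; the lowest score wins, ties broken by fewer clusters then
smaller threshold. This is a deliberate surrogate for full automatic
partitioning: it mirrors the "lowest score wins" selection contract and
the top-10 reporting convention without re-implementing
panmixia-probability scoring. Degenerate inputs with no gap (all
distances equal) legitimately return the one-cluster or all-singleton
partition. A single-cluster partition has no between-cluster linkage;
its gap is scored as minus the within-cluster maximum so that degenerate
lumping never wins on gap width. The default single threshold for quick
runs is 0.03 (3% K2P), the conventional COI cut-off.

## Reference-library filtering

Rules run in a fixed order — length, species name, cluster (BIN)
presence, QC flags, tag code, pseudogene screen — and each rejected
record is charged to the *first* rule it fails, so
`kept + Σ rejections = input` always holds and filtering is idempotent.
Length is strictly greater than 300 bp, matching the printed inequality
in the curation convention it encodes.

**Tag codes.** No formal grammar exists for informal lineage suffixes;
the detector flags names containing " sp." followed by a code token, or
a trailing token of ≥2 characters mixing uppercase letters, digits and
hyphens. The pattern is exposed as a configurable regular expression so
users can tighten it per dataset.

**Pseudogene screen.** Sequences are translated in frame 1 (all three
frames with `any_frame`, accepting the record if any frame is stop-free)
under NCBI table 5 (invertebrate mitochondrial). A stop codon before the
final complete codon marks a putative NUMT. An ambiguous codon counts as
a stop only when *every* resolution is a stop (NNN is clean, TAR is a
stop); this is the conservative choice — a record is only discarded on
certain evidence. The screen is verified against a brute-force codon
enumeration oracle in the tests.

**ASV abundance filter.** ASVs with total reads < 10 (strict) are
dropped, the conventional noise floor for COI metabarcoding tables.

## Audit statuses and BAGS grades

Cluster statuses: singleton (one record), discordant (more than one
nominal species), else concordant. A species split across several
clusters is *not* discordant — discordance is a property of clusters,
splitting is a property of species (grade C).

Grades are decided per species in the order E → D → C → A/B. D before C
is deliberate: a species with two specimens in two clusters is
insufficient data, not evidence of a cryptic complex. The order is a
parameter (`grade_order`) because the original grading tool does not
document its internal precedence. Grade percentages are computed over
species (the grading unit), rounded half-up at one decimal; status
shares over clusters, half-up at integer precision — the mixed precision
such reports conventionally print. Ratios like BINs/species are
truncated (not rounded) to two decimals in `truncate2` mode, matching
how they are conventionally quoted; `full` keeps exact arithmetic.

## Checklist gap analysis

Names are canonicalised before comparison: whitespace collapsed,
parenthesised chunks removed (subgenera and bracketed authorships),
bare authorships truncated at the first capitalised token after the
genus (epithets are always lowercase), then mapped through a
user-supplied synonym table. A checklist species is barcoded when its
canonical name or any synonym occurs among library species names. A
genus or family is barcoded when one of its checklist species is, *or*
when the library holds any record of that genus/family — this keyed-on-
rank-value rule is why genus and family coverage typically exceed
species coverage. No name resolution service is consulted; synonymy
must be supplied as data.

## Richness extrapolation

    X = n_query_MOTUs × n_ref_species / n_ref_MOTUs

calibrated on a reference library identified to species level. In
`truncate2` mode the MOTU/species ratio is truncated to two decimals
first and the query count divided by it; in `full` mode the formula is
evaluated exactly. The two modes differ (e.g. 992 vs 987 for
1350/3131/2291): the truncated-ratio arithmetic reproduces how such
estimates are quoted from a two-decimal ratio, the full mode is the
exact formula. Both are exposed; the package does not arbitrate. An
optional bootstrap resamples reference species (given per-species MOTU
counts) and reports a 95% percentile interval.

## Consensus taxonomy

Within a MOTU, labels are walked from phylum down; at each rank the
label holding at least `min_share` (default 0.6; must exceed 0.5) of
the **total** member weight is kept, otherwise the walk stops. Members
lacking a label at a rank count against consensus, which makes strict
unanimity (`min_share = 1`) coincide exactly with the lowest common
ancestor. Members conflicting with the consensus path are flagged as
outliers and, under the default `exclude` rule, removed once with
shares recomputed — a single round keeps the operation
order-independent. Weights default to 1 per ASV: read abundance is not
evidence of identification quality (`weights=` accepts read counts for
sensitivity analysis). A consensus species label recurring in several
MOTUs flags each as `cryptic_candidate`.

Reference matching places queries by single linkage at strictly
< 0.05 K2P; a cluster containing several reference species yields an
ambiguous match listing all names, with species backed by published and
in-region references listed first.

## Synthetic data

The generator is the package's test substrate and defines its study
conditions. Sequences evolve under a K80 process (transition/
transversion ratio 2) from a shared random root, with frame-1 stop
codons repaired so generated barcodes are open reading frames like real
COI; the deliberately planted pseudogenes then carry the only internal
stops. Lineage ancestors receive enough substitutions to sit beyond the
between-species floor (default 0.08 K2P) even after within-lineage noise
(default ≤ 0.02 K2P, i.e. under the conventional 3% threshold) is added;
targets are enforced by verifying the realised distance matrix and
regenerating on violation (bounded retries), so any clustering threshold
inside the (within, between) gap provably recovers the planted
partition. Defaults: 313 bp sequences (the standard COI metabarcoding
fragment), 3–12 records per species, single-lineage species unless a
lineage distribution is given.

Planted faults: misidentifications move one record's name from a donor
species (≥2 records) to a recipient, making both graded E; tag-coded
species get " sp. CODE" suffixes; pseudogenes get a TAA planted at an
internal codon; singleton species are forced to one record. The planted
grade per species follows from the construction and is recorded in the
`Truth` object.

ASV datasets default to a singleton-heavy lineage-size distribution
(~70% of lineages yield one ASV), a low-read fraction of 2931/8306
(≈35%, the fraction a 10-read floor removes from a realistic raw table)
across 135 samples, and classifier-like label depths (55% class-only,
12% order, 20% family, 13% genus). The consensus-recovery tests instead
use family/genus-depth labels and ~8 ASVs per lineage with a 10%
mislabel rate — the regime the consensus operation is specified over;
with mostly class-only labels no majority rule can recover family
assignments, which is a property of the data, not the method.

What the generator does **not** emulate: sequencing error and chimeras
(ASVs are post-denoising), heterogeneous substitution rates across
sites, real taxonomic name distributions, geographic structure, or
NUMTs without stop codons. Passing tests therefore demonstrate
correctness of the audit logic under a clean barcode gap, not robustness
to every artefact of real libraries.

## Problem sizes

The test suite and acceptance script run synthetic libraries of roughly
100–400 records (15–40 species) and ASV sets of up to a few hundred
sequences; summary-arithmetic checks run at the published scale (4047
clusters, 2291 species) since they are O(n) dictionary passes. These
sizes exercise every code path while keeping a full run in tens of
seconds; all operations scale to libraries of tens of thousands of
records, with the O(n²) distance matrix the binding cost.

## Known limitations

* The partition score is a barcode-gap surrogate; it selects the same
  partition as ASAP-style tools when a clean gap exists but is not a
  re-implementation of their panmixia probabilities, and the top-10
  cluster-count ranges of those tools are not reproducible by a
  threshold sweep in general.
* BINs are accepted as input labels; RESL is not re-implemented.
* The pseudogene screen catches stop-codon NUMTs only; translation-
  preserving NUMTs pass.
* Similarity-search hit tables are consumed, not produced; no BLAST
  execution.
* Checklist entries for subspecies and species complexes are kept as
  distinct entries at species rank; aggregation is left to the caller.
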