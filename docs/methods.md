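# Methods

`crypticsv` finds structural variants in the ~20 bp–10 kbp range from exome
alignments using split reads: reads that span an SV junction align with one
end soft-clipped, and the clipped tail samples the sequence on the far side of
the breakpoint. This note describes the model behind each stage, the
parameters that matter, what the bundled simulator does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Pipeline model

**Fetch.** Primary, non-duplicate alignments whose CIGAR starts or ends with a
soft clip yield one `SplitRead` per clipped end. Coordinates are 0-based
half-open internally (1-based in all user-facing tables): a RIGHT clip sits at
the alignment's half-open end, a LEFT clip at its start, so a clean deletion
satisfies `svlen = -(bp2 - bp1)` with no off-by-one. Read-level gates and
defaults:

| gate | default | why |
| --- | --- | --- |
| `min_clip_len` | 10 bp | noise floor for a clip to be locatable; see below |
| `min_mapq` | 20 | exclude ambiguous anchors |
| `min_mean_clip_baseq` | 15 | low-quality tails are sequencing artifacts |
| `min_entropy_bits` | 1.0 | Shannon entropy of the clip; kills homopolymer/adapter junk |
| `max_n_fraction` | 0.1 | uncalled bases carry no junction information |

The clip-length floor deserves its own paragraph because it interacts with
the support threshold. A heterozygous junction at coverage *c* with read
length *r* is crossed by about *c*/2 reads; the read anchors on whichever side
of the junction is longer, so the crossing reads split roughly evenly between
a RIGHT-clip cluster at one breakpoint and a LEFT-clip cluster at the partner
breakpoint. With *c* = 30, *r* = 100 and a clip floor of *f*, each side
expects about `0.15 * (r/2 - f)` usable clips — 4.6 per side at *f* = 20,
which sits *under* the 5-read cluster support minimum, but 6.0 per side at
*f* = 10. Because junction length for realignment is enforced on the cluster
consensus (which extends to the longest member clip), not on individual
reads, the per-read floor can safely sit at 10 bp; the consensus still needs
`min_hit_len = 20` aligned bases to be typed. This is why the default floor
is 10 and not 20.

**Aggregate.** Single-linkage clustering within (chrom, side): consecutive
clip positions at most `cluster_tolerance` (default 2 bp, absorbing aligner
jitter) apart join one cluster. LEFT and RIGHT clips never co-cluster — the
two sides carry distinct breakpoint semantics and are paired later. The
cluster position is the lower median of member positions (deterministic,
robust to one stray clip). Each cluster receives a fixed-order feature
vector: support, support/depth (clamped to [0,1]; depth-query failure flags
the cluster and sets the ratio to 1.0), mean and SD of member MAPQ, mean clip
base quality, maximum clip length, mean clip entropy, side code, and the
standard deviation of member positions.

**Score.** A binary random forest (500 trees, sqrt features per split,
unlimited depth, class-balanced weights, fixed `random_state`, single thread)
separates true-junction clusters from artifact clusters. A cluster is
retained when its score is at least the threshold (default 0.5) *and* its
support is at least `min_support = 5`; the support floor mirrors the
low-support exclusion used for the published cohort analyses. The default
model ships as a deterministic training recipe rather than a weights file:
three singleton exomes are simulated on a reduced design (1.5 Mb reference,
150 targets) with the standard variant menu and artifact model, clusters are
labeled TRUE_VARIANT when within 5 bp of a truth breakpoint, and the forest
is fit on those labels. `train` rebuilds it from any labeled feature table.
Out-of-bag accuracy is logged and stored in the model's JSON sidecar, which
also pins the feature schema; loading refuses a schema mismatch. Model files
are written through a serialize–reload–serialize round trip so that
save → load → save is bit-identical.

**Database.** Retained clusters are merged across samples by single linkage
on (chrom, side, position ± tolerance); each merged record counts distinct
carrier samples against the cohort size (carrier-based call frequency; every
manifest sample, parents included, counts toward the denominator). For each
record a junction consensus is built: clips are anchored at the breakpoint
(LEFT clips reversed so offset 0 abuts the junction), each offset takes the
base with the highest summed base quality (ties broken toward the
lexicographically smaller base), and the consensus extends to the longest
offset any read covers. The consensus is realigned to the genome and to a
repeat-consensus panel with a seeded local aligner: exact 14-mer seeds locate
candidate diagonals, and an affine-gap Smith–Waterman (match +1, mismatch −1,
gap open −2, gap extend −0.5; a length-k gap costs open + k·extend) scores a
window of ±25 bp around each diagonal band. Hits require identity ≥ 0.9 over
≥ 20 aligned columns and are ranked by identity × aligned length. Seeding is
a heuristic: a true hit whose every sampled k-mer is mutated can be missed,
the same trade a seed-and-extend read aligner makes.

**Classification** is a first-match decision tree. (1) Top hit in the repeat
panel → MEI with that repeat family. Otherwise the top same-chromosome genome
hit defines `deleted` (signed reference span between the breakpoint and where
the clipped sequence resumes) and `inserted` (novel junction bases before the
alignment), computed from the hit's query offsets so that a short insertion
whose clip runs through the insert back into reference sequence is typed INS
with its exact length. (2) `deleted ≥ 20` within `max_event_span = 10 kb` →
DEL with `bp2` and exact negative `svlen`. (3) `deleted ≤ −20` (the junction
maps upstream/overlapping, tandem orientation) → DUP, `svlen = bp1 − bp2 > 0`.
(4) Minus-strand hit → COMPLEX (inversion-like). (5) Different chromosome or
beyond the span limit → TRA_SEGDUP. (6) No hits and junction ≥ 20 bp → INS
(non-templated; `svlen` is the junction length, a lower bound, when the
insert is longer than a read). Everything else is UNRESOLVED. A `slack` of 10
columns tolerates maximal-score local alignments that extend a few columns
past the true junction into novel sequence (the overshoot is added back to
INS lengths); DEL/DUP partners are unaffected because their junction-side
query start cannot move. Reciprocal calls — the RIGHT cluster at bp1 and the
LEFT cluster at bp2 of one event resolve to the same normalized
(svtype, bp1, bp2) — are de-duplicated per sample, keeping the
higher-support record.

**Annotate.** Candidates must pass, in order: (1) cohort rarity — call
frequency < 0.04%, with a carve-out that a cluster carried by exactly one
sample always passes (in any cohort smaller than 2,500 samples a singleton
would otherwise be auto-rejected, which defeats the filter's purpose of
removing *recurrent* variation); (2) external panel rarity — a matched panel
site with MAF ≥ 1e-4 rejects, inclusively; (3) gene relation — some
breakpoint EXONIC or within ±10 bp of an exon (NEAR_EXON) in a gene whose
inheritance mode is allowed; (4) split-read support ≥ 5. Each rejection is
attributed to the first failed rule, so retained + rejected always equals the
input and the cascade can be audited. Exon distance is symmetric: a
breakpoint k bp upstream or downstream of an exon gets the same relation.

**denovo.** Parental evidence uses relaxed read filters (clip ≥ 5 bp, no
MAPQ/entropy/quality gates): missing true parental support turns an inherited
variant into a false de novo call, the costlier error, so the parental filter
set strictly contains the discovery set. Evidence is counted
junction-symmetrically — RIGHT clips at one breakpoint plus LEFT clips at the
partner breakpoint (both sides at bp1 for single-breakpoint calls) — because
the same parental junction reads surface on either side depending on which
anchor was longer. Verdicts: PRESENT with ≥ 2 matching clips (one stray clip
is often noise); otherwise ABSENT when point depth ≥ 10, else UNINFORMATIVE.
Positive evidence wins even at thin point depth. DE_NOVO requires both
parents ABSENT; one PRESENT parent gives MATERNAL/PATERNAL; both PRESENT,
BIPARENTAL; anything else UNKNOWN. The inheritance table covers *all* calls
of each trio proband (an inherited variant keeps its classification even when
the rarity filter removes it from the candidate list); the de novo candidate
table is the intersection of filtered candidates and DE_NOVO calls.

## The simulator

The simulator is the package's truth-set factory: a uniform-random reference
(default 5 Mb) with evenly spaced 200 bp capture targets (500 of them;
consecutive groups of five form the exons of a synthetic gene model, all
marked mono-allelic), per-individual haplotypes with implanted heterozygous
DEL/DUP/INS/MEI across size bins 21–50/51–100/101–500/501–10,000 bp, and
single-end 100 bp reads at 30x written directly as sorted, indexed BAMs.
Alignments are synthesized by projecting each read through the known
haplotype→reference block map: the longest reference-contiguous segment
(minimum 20 bp anchor) is aligned and the rest soft-clipped, so junction
reads carry exact clips with no aligner in the loop, and every output is a
pure function of the seed. Haplotype images of the targets are merged before
fragment sampling so coverage stays uniform across junctions (sampling per
target would double-count exactly the loci under study). Tandem duplications
double coverage across the duplicated span on the carrier haplotype, as real
duplications do. Trio probands inherit each parent's carrier haplotype plus
de novo variants; MEI inserts are (possibly 5′-truncated) copies of three
fixed synthetic repeat consensi labeled Alu/L1/SVA, generated once from a
hard-coded seed — licensing-free stand-ins that users replace with real
consensus sequences. DEL/DUP up to ~140 bp are placed entirely inside one
target (the clinically typical exon-disrupting configuration); larger events
place one breakpoint in a target, which is the laboratory reality that
second breakpoints of large events usually fall in intronic or intergenic
sequence.

Two artifact modes give the scorer a two-class problem: scattered junk clips
(random sequence, clip quality drawn from 8–25, rate 0.5% of reads) and ~15
recurrent artifact sites per sample with 3–7 jittered junk clips each,
mimicking systematic clipping loci. What the simulator does **not** emulate:
aligner-specific clip jitter and micro-homology placement ambiguity, GC and
capture-efficiency bias, empirical error profiles, paired-end signal (written
single-end since discordant pairs are deliberately unused in exomes), somatic
mosaicism, and multi-breakpoint complex events (classified but not
simulated). Passing tests therefore demonstrate correctness of the machinery
under clip-exact, uniform-coverage conditions, not performance on real
exomes, where read-level artifact rates and mappability set the practical
floor.

## Study designs used by tests and the acceptance script

* **Discovery study** (defaults): 20 samples — 5 trios plus 5 singletons —
  at 30x, ~270 implanted variants spanning all four classes and size bins.
  Measured: recall with exact SV class (greedy one-to-one matching, ±10 bp),
  precision, exact-breakpoint fraction, and exact-|svlen| fraction over
  matched DEL/DUP. At these settings per-junction-side support is Poisson
  with mean ≈ 6, so ~92% of two-sided events clear the 5-read floor on at
  least one side; expected recall is ~0.94.
* **Trio integrity study**: 5 trios at 60x on a 2.5 Mb/250-target design,
  105 inherited plus 20 de novo variants. 60x represents clinical trio
  sequencing depth and makes per-variant detection near-certain, isolating
  inheritance classification from the detection limit that the discovery
  study already measures. Measured: inherited variants classified DE_NOVO
  (expected 0) and implanted de novo variants recovered in the de novo
  candidate table (expected all).
* **Scorer study**: train on the recipe at one seed, evaluate accuracy on a
  disjoint seed's labeled clusters (expected ≥ 0.95 given the strong
  separation between junction and artifact feature distributions).
* **Determinism study**: one trio on a 1 Mb design, `complete` run twice;
  all table outputs must be byte-identical (gzip members are written with
  mtime 0 for this reason).

Problem sizes were chosen so the whole suite runs in minutes on one CPU.

## Numerical choices and degenerate inputs

Ties in the consensus break toward the higher summed quality, then the
lexicographically smaller base. Cluster and cohort representative positions
use the lower median. Empty inputs are valid everywhere (a sample with zero
split reads produces empty-but-headered tables and exit code 0); an empty
hit list is a legitimate realignment result (candidate non-templated
insertion). Unsorted cluster input, mixed-side consensus groups, duplicate
sample ids, and missing alignment indexes are fatal with descriptive errors.
Scores are probabilities from the forest and live in [0,1]; retention is
monotone in the threshold by construction.

## Known limitations

Single-breakpoint resolution: each cluster is resolved independently and
reciprocal calls de-duplicated; there is no joint assembly of both junction
sides, no genotyping, and no breakend-graph resolution of multi-part events.
INS lengths are exact only when the whole insert fits inside the junction
consensus. The frequency panel is matched positionally (± cluster tolerance),
which is a simplification of allele-level matching. The seeded aligner can
miss heavily diverged junction sources. Performance figures from the
simulator are upper bounds relative to real exome data.
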