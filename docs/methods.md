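# Methods

## Model and assumptions

`hsdfind` detects *highly similar duplicated genes* (HSDs): groups of ≥ 2
gene copies within one genome whose protein products are nearly identical
in sequence and length. The underlying assumption is that such copies are
recent duplicates (or dosage-maintained families such as histones and
rRNA-associated proteins) and likely share a function; the method makes no
attempt to date duplications, to distinguish tandem/proximal/dispersed/
whole-genome/retro duplication mechanisms, or to detect diverged paralogs
— those need synteny, trees or Ka/Ks, all out of scope here.

Detection is purely similarity-based. The unit of evidence is the best
local alignment between two proteins from an all-vs-all search; a pair
qualifies when that alignment passes the E-value, identity and
length-variance thresholds. Grouping is by transitive linkage (connected
components of the qualifying-pair graph), deliberately tolerant of one
copy in a family having drifted slightly below threshold relative to
another: A~B and A~C suffice to group {A, B, C}. The cost of this
tolerance is that one promiscuous protein can chain otherwise unrelated
pairs into a single group; the strict default thresholds are what keeps
that rare.

Domain-profile classification treats a group's members' Pfam accession
*sets* as the arbiter of annotation consistency. Set semantics means
domain order and per-domain copy number are ignored — a deliberate choice,
since signature annotations on near-identical copies routinely differ in
match counts and coordinates without any biological difference. A
configuration switch (`profile="interpro"`) substitutes InterPro
accessions for Pfam ones.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `identity_min` | 90 | % amino-acid identity | strict cut that favours intact recent duplicates; 80 is the standard relaxed setting for recovering more candidates |
| `length_diff_max` | 10 | residues | near-identical full protein lengths; excludes partial/fragmented duplicates |
| `evalue_max` | 1e-5 | — | conventional homology cut-off for protein BLAST |
| sweep identity grid | 60, 70, 80, 90 | % | spans the strict-to-permissive range where the statistics differentiate |
| sweep length grid | 10, 30, 50, 70, 100 | residues | same |

All three pair thresholds are inclusive (≥ identity, ≤ length diff,
≤ E-value), each boundary exercised by an explicit test. The best hit per
unordered pair is the maximum bit score over both orientations, first-seen
winning ties — deterministic and symmetric under query/subject swap. No
reciprocal-best requirement is imposed, and no minimum aligned length is
applied beyond what the E-value implies: the pair filter is exactly the
three thresholds above.

Protein lengths come from the signature table's sequence-length column
when the protein has at least one signature match, else from the optional
FASTA. The 12-column similarity format carries only alignment lengths, so
a pair with no length source cannot be evaluated; such pairs are counted
and reported (`skipped_no_length`), never silently dropped. Conflicting
lengths for one protein are an error, not a warning — they indicate
mismatched input files.

## Evaluation statistics

With `True`, `Space` and `Incomplete` counts per threshold cell
(`Candidate = True + Incomplete`, `Space ⊆ True`):

* capturing value `⌊100·True/(True+Incomplete)⌋` — the fraction of
  candidates whose copies agree on domain content;
* performance score `⌊(2·True + Incomplete − Space)/(Incomplete + 1)⌋` —
  numerator: true groups plus domain-bearing candidates
  (`Candidate − Space`); denominator: incomplete groups offset by one so
  it is never zero.

Both are **truncated** to integers, not rounded (e.g. 8245/8647·100 =
95.35 reports 95; a score of 37.98 reports 37). Truncation was verified
against all 20 rows of the published A. thaliana per-threshold summary,
which the test suite carries as a data-driven expectation table; rounding
would disagree on several rows. Exact floats are available via
`precise=True`. The "space ⊆ true" reading of the counts is forced by the
score's arithmetic: `(True + Incomplete − Space)` must count the
domain-bearing candidates, which it only does if space groups are the
domain-less subset of true groups. The sweep recomputes the full pipeline
per grid cell rather than updating incrementally — correctness over speed
at the scale of a single proteome (seconds for the 20-cell grid on a
50 k-protein input is dominated by parsing, not filtering).

A cell with zero candidates has an undefined capturing value; the library
raises on direct calls and stores `None` in sweep cells.

## KEGG aggregation

KO accessions are assigned per gene by external KEGG tools
(BlastKOALA/GhostKOALA exports); a group's KO is the majority vote of its
annotated members, ties breaking to the lexicographically smallest KO —
the smallest deterministic rule, since intra-group disagreement is rare
and there is no principled better choice without per-gene scores. Groups
with no annotated member land in an `Unassigned` pseudo-category; a KO
missing from the user-supplied KO→category table lands in `Unmapped` with
a warning. A KO mapping to several categories contributes its group to
each, so category totals can exceed the number of assigned groups; heatmap
cells count distinct HSD *groups*, not gene copies. The category map is a
local TSV (KO, category id, category name, optional KO description) — no
network access anywhere in the package.

## Synthetic data generator

`hsdfind.simulate` plants duplicate families with declared scenario
(`true`, `space`, `incomplete`, `near_miss_identity`, `near_miss_length`),
copy count, target identity, base length and length jitter, then emits the
full input bundle — FASTA, 12-column similarity table, 13-column signature
TSV, KO file, category map — plus a JSON manifest of the expected groups,
classifications, tallies and copy-number histograms at every sweep grid
cell. Ground truth in the manifest is computed from the planted edge list
by naive iterated transitive closure, independently of the detection code.

Similarity rows are synthesized from the declared identities rather than
computed by an aligner: each family contributes star-topology edges from
its first copy (so grouping of the other copies genuinely relies on the
transitive link), reciprocal rows with slightly lower bit scores
(exercising best-hit collapsing), and self-hits; decoy inter-family rows
sit at ≤ 50 % identity or E-value 1.0 to exercise every rejection branch.
The default mixture reflects what well-annotated genomes show: roughly
two-thirds two-copy groups, a fifth three-copy, the rest larger; about
18 % of families domain-less (`space`), a small incomplete fraction, and
near-miss families planted just below the identity (80–90 %) or just
beyond the length (11–60 aa) defaults so relaxed-threshold behaviour is
observable. Generation is deterministic: one seed, byte-identical bundle.

What the generator does **not** emulate: real sequence evolution (the
FASTA sequences are random residues of the planted lengths, not mutated
copies), alignment noise (identities and E-values are declared, not
computed), promiscuous multi-family similarity chains, fragmented gene
models, or assembly artefacts. Passing the recovery tests therefore shows
that filtering, grouping, classification and accounting are correct given
well-formed inputs — not that an aligner's output on a messy genome will
be clean.

## Numerical and degenerate-input choices

* Group ids are the lexicographically smallest member id; members and
  groups are sorted, so all outputs are order-stable regardless of input
  row order.
* Empty similarity or signature files parse to empty results with a
  warning; an empty group list writes a header-only table.
* Readers skip `#` comment lines, which the CLI uses for provenance
  headers (version, thresholds, input MD5 checksums); `--no-header`
  suppresses them for byte-identical reruns.
* Machine outputs use plain integers and `repr`-faithful floats (decimal
  point, scientific notation for E-values); parsing is locale-independent.
* InterProScan rows beyond 13 columns (GO/pathway output) are accepted
  with the extras ignored; the `-` missing-value token maps to empty.
* Duplicate gene rows in KO files collapse to the first non-empty KO;
  malformed KO tokens warn and count as unassigned.

## Test-scale choices

The shared test fixture is a 40-family bundle (~100 genes); oracle
equivalence for clustering runs 100 random graph instances up to 500
nodes, and the quadratic brute-force re-analysis oracle runs on 10-family
bundles across 10 seeds — sizes at which the naive oracles are instant
while still covering every scenario and filter branch.

## Known limitations

Beyond the non-goals above: the classifier has no notion of *partial*
domain matches (a truncated copy retaining a domain fragment counts as
carrying the domain); group-level KO assignment ignores functional
heterogeneity inside a group; and the heatmap color scale is linear, which
compresses differences between very large categories.
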