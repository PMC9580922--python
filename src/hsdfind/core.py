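"""Core HSD detection: pair filtering and transitive-link grouping.

An HSD (highly similar duplicated gene) group is a set of >= 2 gene copies
within one genome whose proteins pass three thresholds pairwise: e-value of
the best alignment <= ``evalue_max`` (default 1e-5), percent identity >=
``identity_min`` (default 90) and protein-length difference <=
``length_diff_max`` residues (default 10).  Qualifying pairs are grouped by
simple transitive linkage: if A passes thresholds with B and with C, then
A, B and C belong to one group even when the B-C pair fails them — i.e.
groups are the connected components of the qualifying-pair graph.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from hsdfind.tabular_io import SignatureRecord, SimilarityHit

logger = logging.getLogger(__name__)

#: InterProScan analysis name whose accessions populate the Pfam profile.
PFAM_ANALYSIS = "Pfam"


@dataclass(frozen=True)
class ThresholdConfig:
    """Filter thresholds for qualifying duplicate pairs.

    identity_min
        Minimum percent amino-acid identity of the best alignment,
        inclusive.  Default 90.
    length_diff_max
        Maximum absolute difference of the two full protein lengths, in
        residues, inclusive.  Default 10.
    evalue_max
        Maximum alignment expectation value, inclusive.  Default 1e-5.
    """

    identity_min: float = 90.0
    length_diff_max: int = 10
    evalue_max: float = 1e-5

    def __post_init__(self):
        if not 0.0 < self.identity_min <= 100.0:
            raise ValueError(f"identity_min {self.identity_min} outside (0, 100]")
        if self.length_diff_max < 0:
            raise ValueError(f"length_diff_max {self.length_diff_max} < 0")
        if self.evalue_max <= 0:
            raise ValueError(f"evalue_max {self.evalue_max} <= 0")

    @property
    def label(self) -> str:
        """Compact label, e.g. ``90%_10aa``."""
        ident = (
            f"{self.identity_min:g}" if self.identity_min % 1 else f"{int(self.identity_min)}"
        )
        return f"{ident}%_{self.length_diff_max}aa"


@dataclass
class GeneRecord:
    """Per-gene annotation state: protein length and signature profiles.

    ``length`` may be ``None`` when neither the signature table nor a FASTA
    supplied it; such genes cannot pass the length-variance filter and are
    reported as skipped.  Profiles may be empty — around a third of HSDs in
    real proteomes are hypothetical proteins without any Pfam domain.
    """

    gene_id: str
    length: int | None = None
    pfam_profile: frozenset[str] = frozenset()
    interpro_profile: frozenset[str] = frozenset()
    descriptions: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class QualifiedEdge:
    """An unordered gene pair whose best alignment passed all thresholds."""

    gene_a: str
    gene_b: str
    best_identity: float
    best_evalue: float

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValueError("edge endpoints must differ")


@dataclass
class HsdGroup:
    """A candidate HSD group: one connected component of qualifying pairs.

    ``group_id`` is the lexicographically smallest member id; members are
    sorted.  ``classification`` is ``None`` until the group is classified
    (``"true"`` if all copies share an identical domain profile, else
    ``"incomplete"``); ``space_flag`` marks groups in which no copy carries
    any domain (hypothetical-protein groups, a subset of ``true``).
    """

    group_id: str
    members: tuple[str, ...]
    member_lengths: tuple[int | None, ...] = ()
    classification: str | None = None
    space_flag: bool = False

    @property
    def size(self) -> int:
        return len(self.members)


class EdgeFilterResult(list):
    """Qualifying edges plus bookkeeping on what the filter discarded.

    Behaves as a plain list of :class:`QualifiedEdge`; the extra attributes
    report self-hits dropped, candidate pairs inspected, and pairs skipped
    because a member had no known protein length (never discarded silently).
    """

    def __init__(
        self,
        edges: Iterable[QualifiedEdge],
        *,
        self_hits: int = 0,
        pairs_seen: int = 0,
        skipped_no_length: tuple[tuple[str, str], ...] = (),
    ):
        super().__init__(edges)
        self.self_hits = self_hits
        self.pairs_seen = pairs_seen
        self.skipped_no_length = skipped_no_length


def build_gene_records(
    signatures: Sequence[SignatureRecord],
    fasta_lengths: Mapping[str, int] | None = None,
) -> dict[str, GeneRecord]:
    """Assemble per-gene records from signature rows and optional FASTA lengths.

    Protein lengths come from the signature table's sequence-length column
    when the protein has at least one signature match, falling back to the
    FASTA for unmatched proteins.  Conflicting lengths for one protein
    across signature rows (or between signatures and FASTA) raise
    ``ValueError`` naming the protein.  Pfam profiles collect the
    accessions whose analysis is :data:`PFAM_ANALYSIS`; InterPro profiles
    collect the integrated IPR accessions of all analyses.
    """
    lengths: dict[str, int] = {}
    pfam: dict[str, set[str]] = defaultdict(set)
    interpro: dict[str, set[str]] = defaultdict(set)
    descriptions: dict[str, dict[str, str]] = defaultdict(dict)

    for rec in signatures:
        prior = lengths.get(rec.protein_id)
        if prior is not None and prior != rec.sequence_length:
            raise ValueError(
                f"conflicting sequence lengths for {rec.protein_id!r}: "
                f"{prior} vs {rec.sequence_length}"
            )
        lengths[rec.protein_id] = rec.sequence_length
        if rec.analysis == PFAM_ANALYSIS:
            pfam[rec.protein_id].add(rec.signature_accession)
            if rec.signature_description:
                descriptions[rec.protein_id].setdefault(
                    rec.signature_accession, rec.signature_description
                )
        if rec.interpro_accession:
            interpro[rec.protein_id].add(rec.interpro_accession)
            if rec.interpro_description:
                descriptions[rec.protein_id].setdefault(
                    rec.interpro_accession, rec.interpro_description
                )

    if fasta_lengths:
        for gene_id, flen in fasta_lengths.items():
            if gene_id in lengths:
                if lengths[gene_id] != flen:
                    raise ValueError(
                        f"conflicting sequence lengths for {gene_id!r}: "
                        f"signatures say {lengths[gene_id]}, FASTA says {flen}"
                    )
            else:
                lengths[gene_id] = flen

    return {
        gene_id: GeneRecord(
            gene_id=gene_id,
            length=lengths[gene_id],
            pfam_profile=frozenset(pfam.get(gene_id, ())),
            interpro_profile=frozenset(interpro.get(gene_id, ())),
            descriptions=dict(descriptions.get(gene_id, {})),
        )
        for gene_id in lengths
    }


def filter_edges(
    hits: Sequence[SimilarityHit],
    genes: Mapping[str, GeneRecord],
    cfg: ThresholdConfig = ThresholdConfig(),
) -> EdgeFilterResult:
    """Select unordered gene pairs whose best alignment passes all thresholds.

    Self-hits are removed.  For each unordered pair, the single best hit —
    maximum bit score over both query/subject orientations, first seen on
    ties — represents the pair; the pair qualifies iff that hit satisfies
    ``e_value <= evalue_max``, ``percent_identity >= identity_min``, both
    protein lengths are known, and ``|len_a - len_b| <= length_diff_max``.
    Pairs with an unknown length are tallied in ``skipped_no_length`` on
    the returned :class:`EdgeFilterResult`, not silently dropped.
    """
    best: dict[tuple[str, str], SimilarityHit] = {}
    order: list[tuple[str, str]] = []
    self_hits = 0
    for hit in hits:
        if hit.query_id == hit.subject_id:
            self_hits += 1
            continue
        pair = (
            (hit.query_id, hit.subject_id)
            if hit.query_id < hit.subject_id
            else (hit.subject_id, hit.query_id)
        )
        incumbent = best.get(pair)
        if incumbent is None:
            best[pair] = hit
            order.append(pair)
        elif hit.bit_score > incumbent.bit_score:
            best[pair] = hit

    edges: list[QualifiedEdge] = []
    skipped: list[tuple[str, str]] = []
    for pair in order:
        hit = best[pair]
        if hit.e_value > cfg.evalue_max or hit.percent_identity < cfg.identity_min:
            continue
        len_a = genes[pair[0]].length if pair[0] in genes else None
        len_b = genes[pair[1]].length if pair[1] in genes else None
        if len_a is None or len_b is None:
            skipped.append(pair)
            continue
        if abs(len_a - len_b) > cfg.length_diff_max:
            continue
        edges.append(
            QualifiedEdge(
                gene_a=pair[0],
                gene_b=pair[1],
                best_identity=hit.percent_identity,
                best_evalue=hit.e_value,
            )
        )
    if skipped:
        logger.warning(
            "%d candidate pair(s) skipped: no protein length known (e.g. %s)",
            len(skipped),
            skipped[0],
        )
    return EdgeFilterResult(
        edges,
        self_hits=self_hits,
        pairs_seen=len(order),
        skipped_no_length=tuple(skipped),
    )


def cluster_groups(
    edges: Sequence[QualifiedEdge],
    genes: Mapping[str, GeneRecord] | None = None,
) -> list[HsdGroup]:
    """Group genes by transitive linkage over qualifying pairs.

    Returns the connected components of the undirected qualifying-pair
    graph as unclassified :class:`HsdGroup` objects.  Singletons cannot
    occur (every node is incident to an edge).  Members are sorted
    lexicographically, the group id is the smallest member id, and groups
    are sorted by id, so output is deterministic regardless of edge order.
    """
    graph = nx.Graph()
    for e in edges:
        graph.add_edge(e.gene_a, e.gene_b)
    groups: list[HsdGroup] = []
    for component in nx.connected_components(graph):
        members = tuple(sorted(component))
        lengths = tuple(
            genes[m].length if genes is not None and m in genes else None
            for m in members
        )
        groups.append(
            HsdGroup(group_id=members[0], members=members, member_lengths=lengths)
        )
    groups.sort(key=lambda g: g.group_id)
    return groups


def copy_number_histogram(
    groups: Sequence[HsdGroup],
) -> dict[str, dict[str, int]]:
    """Bin groups by copy number: exactly 2, exactly 3, and >= 4 members.

    Returns ``{"groups": {"2": .., "3": .., "4plus": ..},
    "copies": {...}}`` where ``groups`` counts HSD groups per bin and
    ``copies`` sums their gene copies.  Bin totals add up to the overall
    group and member counts respectively.
    """
    g = {"2": 0, "3": 0, "4plus": 0}
    c = {"2": 0, "3": 0, "4plus": 0}
    for group in groups:
        bin_key = "2" if group.size == 2 else "3" if group.size == 3 else "4plus"
        g[bin_key] += 1
        c[bin_key] += group.size
    return {"groups": g, "copies": c}


@dataclass
class PipelineResult:
    """End-to-end result of one detection run at a fixed threshold pair."""

    cfg: ThresholdConfig
    edges: EdgeFilterResult
    groups: list[HsdGroup]
    classifications: list
    tally: "object"
    histogram: dict[str, dict[str, int]]


def run_pipeline(
    hits: Sequence[SimilarityHit],
    genes: Mapping[str, GeneRecord],
    cfg: ThresholdConfig = ThresholdConfig(),
    profile: str = "pfam",
) -> PipelineResult:
    """Filter -> cluster -> classify -> tally in one call."""
    from hsdfind.classify import classify_groups, tally_classifications

    edges = filter_edges(hits, genes, cfg)
    groups = cluster_groups(edges, genes)
    classifications = classify_groups(groups, genes, profile=profile)
    tally = tally_classifications(classifications)
    return PipelineResult(
        cfg=cfg,
        edges=edges,
        groups=groups,
        classifications=classifications,
        tally=tally,
        histogram=copy_number_histogram(groups),
    )
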