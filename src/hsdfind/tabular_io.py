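"""Readers and writers for every tabular format the HSD pipeline touches.

All formats are plain tab-separated text:

* 12-column all-vs-all protein similarity table (BLAST ``-outfmt 6`` dialect);
* 13-column InterProScan protein-signature TSV (extra trailing columns from
  ``-goterms``/``-pa`` are tolerated and ignored);
* protein FASTA (used only as a source of sequence lengths);
* two-column gene -> KEGG Orthology (KO) assignment file, BlastKOALA style;
* KO -> pathway-category mapping table;
* the 8-column HSD result table this package writes.

Readers validate column counts strictly, preserve row order, skip blank
lines and ``#`` comment lines, and raise :class:`TableFormatError` with the
offending line number on malformed input.  Every writer/reader pair
round-trips: ``read(write(records)) == records`` for valid records.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from hsdfind.core import GeneRecord, HsdGroup

logger = logging.getLogger(__name__)

#: InterProScan prints "-" for a missing value in optional columns.
MISSING_TOKEN = "-"

KO_PATTERN = re.compile(r"^K\d{5}$")


class TableFormatError(ValueError):
    """A tabular input file violates its format contract."""

    def __init__(self, path, line_no: int | None, message: str):
        self.path = str(path)
        self.line_no = line_no
        where = f"{path}" if line_no is None else f"{path}:{line_no}"
        super().__init__(f"{where}: {message}")


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimilarityHit:
    """One row of a 12-column all-vs-all protein similarity search table."""

    query_id: str
    subject_id: str
    percent_identity: float  # 0-100
    alignment_length: int  # residues
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    e_value: float
    bit_score: float

    def __post_init__(self):
        if not self.query_id or not self.subject_id:
            raise ValueError("query_id and subject_id must be non-empty")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent_identity {self.percent_identity} outside [0, 100]"
            )
        if self.alignment_length < 1:
            raise ValueError(f"alignment_length {self.alignment_length} < 1")
        if self.e_value < 0:
            raise ValueError(f"e_value {self.e_value} < 0")


@dataclass(frozen=True)
class SignatureRecord:
    """One protein-signature match from a 13-column InterProScan TSV row.

    A protein with several signature matches appears on several rows, all
    sharing ``protein_id`` and ``sequence_length``.  ``interpro_accession``
    and ``interpro_description`` are empty when the member-database signature
    has no InterPro integration (InterProScan prints ``-``).
    """

    protein_id: str
    sequence_md5: str
    sequence_length: int
    analysis: str  # member database, e.g. "Pfam"
    signature_accession: str  # e.g. PF00504
    signature_description: str
    match_start: int
    match_end: int
    score: str  # e-value-like text; some analyses print "-"
    status: str
    run_date: str
    interpro_accession: str = ""
    interpro_description: str = ""

    def __post_init__(self):
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if self.sequence_length < 1:
            raise ValueError(f"sequence_length {self.sequence_length} < 1")
        if not 1 <= self.match_start <= self.match_end <= self.sequence_length:
            raise ValueError(
                f"match span {self.match_start}..{self.match_end} invalid for "
                f"sequence of length {self.sequence_length}"
            )


@dataclass(frozen=True)
class KoAssignment:
    """A gene-model -> KEGG Orthology accession assignment (KO may be empty)."""

    gene_id: str
    ko_accession: str = ""

    def __post_init__(self):
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")


@dataclass(frozen=True)
class CategoryMapEntry:
    """One KO -> KEGG pathway-category mapping row.

    ``ko_description`` (a fourth, optional column) carries the KO's gene
    product name, e.g. "ferredoxin" for K02639.
    """

    ko_accession: str
    category_id: str  # e.g. "09102"
    category_name: str  # e.g. "Energy metabolism"
    ko_description: str = ""


# ---------------------------------------------------------------------------
# Line plumbing
# ---------------------------------------------------------------------------


def _data_lines(path) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, stripped line), skipping blanks/comments."""
    with open(path, "r", encoding="utf-8", newline=None) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.startswith("#"):
                continue
            yield line_no, line


def _parse_number(token: str, kind, path, line_no: int, col: int):
    try:
        return kind(token)
    except ValueError:
        raise TableFormatError(
            path, line_no, f"column {col}: cannot parse {token!r} as {kind.__name__}"
        ) from None


# ---------------------------------------------------------------------------
# Similarity table (12 columns)
# ---------------------------------------------------------------------------


def read_similarity_table(path) -> list[SimilarityHit]:
    """Read a 12-column tab-delimited all-vs-all similarity table.

    Rows are returned in file order.  An empty file yields an empty list
    (with a warning); a row with a column count other than 12 or an
    unparseable numeric field raises :class:`TableFormatError`.
    """
    hits: list[SimilarityHit] = []
    for line_no, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 12:
            raise TableFormatError(
                path, line_no, f"expected 12 tab-separated columns, got {len(fields)}"
            )
        try:
            hit = SimilarityHit(
                query_id=fields[0],
                subject_id=fields[1],
                percent_identity=_parse_number(fields[2], float, path, line_no, 3),
                alignment_length=_parse_number(fields[3], int, path, line_no, 4),
                mismatches=_parse_number(fields[4], int, path, line_no, 5),
                gap_opens=_parse_number(fields[5], int, path, line_no, 6),
                query_start=_parse_number(fields[6], int, path, line_no, 7),
                query_end=_parse_number(fields[7], int, path, line_no, 8),
                subject_start=_parse_number(fields[8], int, path, line_no, 9),
                subject_end=_parse_number(fields[9], int, path, line_no, 10),
                e_value=_parse_number(fields[10], float, path, line_no, 11),
                bit_score=_parse_number(fields[11], float, path, line_no, 12),
            )
        except ValueError as exc:
            raise TableFormatError(path, line_no, str(exc)) from None
        hits.append(hit)
    if not hits:
        logger.warning("similarity table %s contains no data rows", path)
    return hits


def write_similarity_table(hits: Sequence[SimilarityHit], path) -> None:
    """Write hits as a 12-column tab-delimited table (outfmt-6 dialect)."""
    with open(path, "w", encoding="utf-8") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        _fmt_float(h.percent_identity),
                        str(h.alignment_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.query_start),
                        str(h.query_end),
                        str(h.subject_start),
                        str(h.subject_end),
                        _fmt_float(h.e_value),
                        _fmt_float(h.bit_score),
                    ]
                )
                + "\n"
            )


def _fmt_float(x: float) -> str:
    """Render a float so that float(render) == x, without locale surprises."""
    return repr(float(x))


# ---------------------------------------------------------------------------
# InterProScan signature table (13+ columns)
# ---------------------------------------------------------------------------


def read_signature_table(path) -> list[SignatureRecord]:
    """Read a 13-column InterProScan TSV.

    InterProScan appends GO-term/pathway columns when run with ``-goterms``
    and ``-pa``; any columns beyond the 13th are ignored.  The missing-value
    token ``-`` in the InterPro accession/description columns maps to the
    empty string.
    """
    records: list[SignatureRecord] = []
    for line_no, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 13:
            raise TableFormatError(
                path, line_no, f"expected >= 13 tab-separated columns, got {len(fields)}"
            )
        try:
            rec = SignatureRecord(
                protein_id=fields[0],
                sequence_md5=fields[1],
                sequence_length=_parse_number(fields[2], int, path, line_no, 3),
                analysis=fields[3],
                signature_accession=fields[4],
                signature_description=_clean(fields[5]),
                match_start=_parse_number(fields[6], int, path, line_no, 7),
                match_end=_parse_number(fields[7], int, path, line_no, 8),
                score=fields[8],
                status=fields[9],
                run_date=fields[10],
                interpro_accession=_clean(fields[11]),
                interpro_description=_clean(fields[12]),
            )
        except ValueError as exc:
            raise TableFormatError(path, line_no, str(exc)) from None
        records.append(rec)
    if not records:
        logger.warning("signature table %s contains no data rows", path)
    return records


def _clean(token: str) -> str:
    return "" if token == MISSING_TOKEN else token


def write_signature_table(records: Sequence[SignatureRecord], path) -> None:
    """Write signature records as a 13-column InterProScan-style TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.protein_id,
                        r.sequence_md5,
                        str(r.sequence_length),
                        r.analysis,
                        r.signature_accession,
                        r.signature_description or MISSING_TOKEN,
                        str(r.match_start),
                        str(r.match_end),
                        r.score,
                        r.status,
                        r.run_date,
                        r.interpro_accession or MISSING_TOKEN,
                        r.interpro_description or MISSING_TOKEN,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# KO assignment file (2 columns) and KO -> category map (3-4 columns)
# ---------------------------------------------------------------------------


def read_ko_file(path) -> list[KoAssignment]:
    """Read a two-column gene -> KO file (BlastKOALA/GhostKOALA style).

    The KO column may be empty (gene without an ortholog assignment).
    Duplicate gene rows are collapsed, keeping the first non-empty KO.
    A KO token that is neither empty nor of the form ``K#####`` triggers a
    warning and the row is kept with an empty KO.
    """
    order: list[str] = []
    best: dict[str, str] = {}
    for line_no, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) > 2 or not fields[0]:
            raise TableFormatError(
                path, line_no, f"expected 2 tab-separated columns, got {len(fields)}"
            )
        gene_id = fields[0]
        ko = fields[1].strip() if len(fields) == 2 else ""
        if ko and not KO_PATTERN.match(ko):
            logger.warning(
                "%s:%d: token %r is not a KO accession (K#####); treating %s as unassigned",
                path,
                line_no,
                ko,
                gene_id,
            )
            ko = ""
        if gene_id not in best:
            order.append(gene_id)
            best[gene_id] = ko
        elif not best[gene_id] and ko:
            best[gene_id] = ko
    return [KoAssignment(g, best[g]) for g in order]


def write_ko_file(assignments: Sequence[KoAssignment], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a in assignments:
            fh.write(f"{a.gene_id}\t{a.ko_accession}\n")


def read_category_map(path) -> list[CategoryMapEntry]:
    """Read a KO -> pathway-category table.

    Columns: KO accession, category id, category name, and an optional
    fourth column with the KO description (gene product name).  A KO may
    map to several categories (one row per mapping).
    """
    entries: list[CategoryMapEntry] = []
    seen: set[tuple[str, str, str]] = set()
    for line_no, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) not in (3, 4):
            raise TableFormatError(
                path, line_no, f"expected 3 or 4 tab-separated columns, got {len(fields)}"
            )
        key = (fields[0], fields[1], fields[2])
        if key in seen:
            continue
        seen.add(key)
        entries.append(
            CategoryMapEntry(
                ko_accession=fields[0],
                category_id=fields[1],
                category_name=fields[2],
                ko_description=fields[3] if len(fields) == 4 else "",
            )
        )
    return entries


def write_category_map(entries: Sequence[CategoryMapEntry], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in entries:
            row = [e.ko_accession, e.category_id, e.category_name]
            if e.ko_description:
                row.append(e.ko_description)
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# FASTA lengths
# ---------------------------------------------------------------------------


def read_fasta_lengths(path) -> dict[str, int]:
    """Map each protein FASTA record id to its sequence length in residues.

    Duplicate record ids and empty sequences are errors: both would make
    the downstream length-variance filter ambiguous.
    """
    lengths: dict[str, int] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in lengths:
            raise TableFormatError(path, None, f"duplicate FASTA id {record.id!r}")
        if len(record.seq) == 0:
            raise TableFormatError(path, None, f"empty sequence for {record.id!r}")
        lengths[record.id] = len(record.seq)
    return lengths


# ---------------------------------------------------------------------------
# 8-column HSD result table
# ---------------------------------------------------------------------------

HSD_COLUMNS = (
    "hsd_id",
    "gene_ids",
    "lengths_aa",
    "pfam_accessions",
    "pfam_descriptions",
    "interpro_accessions",
    "interpro_descriptions",
    "classification",
)

_LIST_SEP = ";"


def write_hsd_table(
    groups: Sequence["HsdGroup"],
    path,
    genes: Mapping[str, "GeneRecord"] | None = None,
    header_lines: Sequence[str] = (),
) -> None:
    """Write HSD groups as the 8-column tab-delimited result table.

    Columns: (1) HSD identifier, (2) ``;``-joined member gene ids, (3)
    ``;``-joined member lengths in residues, (4) distinct Pfam accessions,
    (5) their descriptions, (6) distinct InterPro accessions, (7) their
    descriptions, (8) classification label (``true``/``incomplete``, with
    ``;space`` appended for groups whose copies carry no domain at all).
    An empty group list yields a header-only file.  ``header_lines`` are
    extra provenance comments emitted before the column header.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("#" + "\t".join(HSD_COLUMNS) + "\n")
        for g in groups:
            pfam_accs: list[str] = []
            ipr_accs: list[str] = []
            if genes is not None:
                pfam_accs = sorted({a for m in g.members for a in genes[m].pfam_profile})
                ipr_accs = sorted(
                    {a for m in g.members for a in genes[m].interpro_profile}
                )
            descs = _descriptions(genes, g.members)
            label = g.classification or ""
            if g.space_flag:
                label += ";space"
            fh.write(
                "\t".join(
                    [
                        g.group_id,
                        _LIST_SEP.join(g.members),
                        _LIST_SEP.join(
                            "" if l is None else str(l) for l in g.member_lengths
                        ),
                        _LIST_SEP.join(pfam_accs),
                        _LIST_SEP.join(descs.get(a, "") for a in pfam_accs),
                        _LIST_SEP.join(ipr_accs),
                        _LIST_SEP.join(descs.get(a, "") for a in ipr_accs),
                        label,
                    ]
                )
                + "\n"
            )


def _descriptions(genes, members) -> dict[str, str]:
    out: dict[str, str] = {}
    if genes is None:
        return out
    for m in members:
        for acc, desc in genes[m].descriptions.items():
            out.setdefault(acc, desc)
    return out


def read_hsd_table(path) -> list["HsdGroup"]:
    """Re-parse an 8-column HSD table into :class:`~hsdfind.core.HsdGroup`s.

    Annotation columns (4-7) are informational and not reattached to gene
    records; membership, lengths, classification and the space flag are
    reconstructed exactly.
    """
    from hsdfind.core import HsdGroup  # deferred: avoid import cycle

    groups: list[HsdGroup] = []
    for line_no, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 8:
            raise TableFormatError(
                path, line_no, f"expected 8 tab-separated columns, got {len(fields)}"
            )
        members = tuple(fields[1].split(_LIST_SEP)) if fields[1] else ()
        lengths = tuple(
            None if tok == "" else int(tok)
            for tok in (fields[2].split(_LIST_SEP) if fields[2] else ())
        )
        label_tokens = fields[7].split(_LIST_SEP) if fields[7] else []
        classification = label_tokens[0] if label_tokens and label_tokens[0] else None
        space_flag = "space" in label_tokens[1:]
        groups.append(
            HsdGroup(
                group_id=fields[0],
                members=members,
                member_lengths=lengths,
                classification=classification,
                space_flag=space_flag,
            )
        )
    return groups
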