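"""KEGG pathway-category aggregation and the cross-species HSD heatmap.

Each HSD group is assigned one KEGG Orthology (KO) accession by majority
vote over its members' KO assignments (ties break to the lexicographically
smallest KO; groups with no annotated member fall into an ``Unassigned``
pseudo-category).  A user-supplied KO -> pathway-category table then places
each group under its functional categories — a KO mapping to several
categories contributes the group to each — and the per-species category
counts form the matrix behind the cross-species heatmap.  No network access
is ever attempted: KO assignments come from BlastKOALA/GhostKOALA exports
and the category map is a local TSV snapshot.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from hsdfind.core import HsdGroup
from hsdfind.tabular_io import CategoryMapEntry, KoAssignment

logger = logging.getLogger(__name__)

UNASSIGNED = ("NA", "Unassigned")  # no member has a KO
UNMAPPED = ("NA", "Unmapped")  # KO known but absent from the category map


@dataclass(frozen=True)
class CategorizedHsd:
    """One HSD group placed under one KEGG functional category."""

    species: str
    category_id: str
    category_name: str
    ko_accession: str  # empty for unassigned groups
    ko_description: str
    group_id: str
    copy_count: int
    member_ids: tuple[str, ...]

    def __post_init__(self):
        if self.copy_count != len(self.member_ids):
            raise ValueError("copy_count must equal the number of member ids")


@dataclass
class CategoryMatrix:
    """Species x category HSD-group counts backing the heatmap.

    ``counts`` is a DataFrame with category rows (index
    ``"id category_name"``) and species columns; orders are deterministic:
    species in first-seen input order, categories sorted by id then name.
    """

    species_order: list[str]
    category_order: list[str]
    counts: pd.DataFrame


def assign_group_ko(
    group: HsdGroup, ko: Mapping[str, KoAssignment]
) -> str | None:
    """KO shared by the majority of annotated members; ties break smallest.

    Members without an assignment (missing from ``ko`` or with an empty
    accession) do not vote.  Returns ``None`` when no member is annotated.
    """
    votes = Counter()
    for member in group.members:
        assignment = ko.get(member)
        if assignment is not None and assignment.ko_accession:
            votes[assignment.ko_accession] += 1
    if not votes:
        return None
    top = max(votes.values())
    return min(k for k, v in votes.items() if v == top)


def categorize(
    groups_by_species: Mapping[str, Sequence[HsdGroup]],
    ko_by_species: Mapping[str, Mapping[str, KoAssignment]],
    category_map: Sequence[CategoryMapEntry],
) -> tuple[list[CategorizedHsd], CategoryMatrix]:
    """Place every species' HSD groups under KEGG functional categories.

    A group with a KO appears once per category its KO maps to; a KO absent
    from the map counts under ``Unmapped`` (with a warning); groups without
    any annotated member count under ``Unassigned``.  Matrix cell (species,
    category) is the number of distinct HSD groups — a group never counts
    twice in one cell, but may appear in several categories.
    """
    by_ko: dict[str, list[CategoryMapEntry]] = {}
    for entry in category_map:
        by_ko.setdefault(entry.ko_accession, []).append(entry)

    rows: list[CategorizedHsd] = []
    cell_groups: dict[tuple[str, tuple[str, str]], set[str]] = {}
    species_order = list(groups_by_species)
    warned: set[str] = set()

    for species in species_order:
        ko_map = ko_by_species.get(species, {})
        for group in groups_by_species[species]:
            group_ko = assign_group_ko(group, ko_map)
            if group_ko is None:
                targets = [(UNASSIGNED, "", "")]
            elif group_ko not in by_ko:
                if group_ko not in warned:
                    logger.warning(
                        "KO %s not present in the category map; counting under Unmapped",
                        group_ko,
                    )
                    warned.add(group_ko)
                targets = [(UNMAPPED, group_ko, "")]
            else:
                targets = [
                    ((e.category_id, e.category_name), group_ko, e.ko_description)
                    for e in by_ko[group_ko]
                ]
            for (cat_id, cat_name), ko_acc, ko_desc in targets:
                rows.append(
                    CategorizedHsd(
                        species=species,
                        category_id=cat_id,
                        category_name=cat_name,
                        ko_accession=ko_acc,
                        ko_description=ko_desc,
                        group_id=group.group_id,
                        copy_count=group.size,
                        member_ids=group.members,
                    )
                )
                cell_groups.setdefault(
                    (species, (cat_id, cat_name)), set()
                ).add(group.group_id)

    categories = sorted({cat for (_, cat) in cell_groups})
    category_labels = [f"{cid} {cname}".strip() for cid, cname in categories]
    counts = pd.DataFrame(
        [
            [
                len(cell_groups.get((species, cat), ()))
                for species in species_order
            ]
            for cat in categories
        ],
        index=category_labels,
        columns=species_order,
        dtype=int,
    )
    return rows, CategoryMatrix(
        species_order=species_order,
        category_order=category_labels,
        counts=counts,
    )


CATEGORIZED_COLUMNS = (
    "species",
    "category_id",
    "category_name",
    "ko_accession",
    "ko_description",
    "hsd_id",
    "copy_count",
    "gene_ids",
)


def write_categorized_table(
    rows: Sequence[CategorizedHsd], path, header_lines: Sequence[str] = ()
) -> None:
    """Write the 8-column KEGG-categorized HSD table."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("#" + "\t".join(CATEGORIZED_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.species,
                        r.category_id,
                        r.category_name,
                        r.ko_accession,
                        r.ko_description,
                        r.group_id,
                        str(r.copy_count),
                        ";".join(r.member_ids),
                    ]
                )
                + "\n"
            )


def render_heatmap(matrix: CategoryMatrix, path) -> list[str]:
    """Render the species x category heatmap (PNG and SVG).

    Category rows, species columns, linear color scale, each cell annotated
    with its HSD-group count.  Returns the written file names.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    import seaborn as sns

    if matrix.counts.empty:
        raise ValueError("cannot render an empty category matrix")

    n_rows, n_cols = matrix.counts.shape
    fig, ax = plt.subplots(
        figsize=(1.6 + 1.0 * n_cols, 1.2 + 0.45 * n_rows)
    )
    sns.heatmap(
        matrix.counts,
        annot=True,
        fmt="d",
        cmap="YlOrRd",
        linewidths=0.5,
        cbar_kws={"label": "HSD groups"},
        ax=ax,
    )
    ax.set_xlabel("species")
    ax.set_ylabel("KEGG functional category")

    base = str(path)
    for suffix in (".png", ".svg"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
    written = []
    for suffix in (".png", ".svg"):
        out = base + suffix
        fig.savefig(out, bbox_inches="tight", dpi=150)
        written.append(out)
    plt.close(fig)
    return written
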