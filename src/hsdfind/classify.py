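"""Domain-profile classification of candidate HSD groups.

A candidate group is **true** when every member carries an identical set of
domain signatures (Pfam accessions by default), and **incomplete** when the
members' domain sets differ.  A true group in which no member carries any
domain at all — a hypothetical-protein group — additionally gets the
**space** flag; such groups pass the sequence thresholds but offer no
structural evidence of shared function.  By construction space is a subset
of true: empty profiles are trivially identical across members.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from hsdfind.core import GeneRecord, HsdGroup


@dataclass(frozen=True)
class GroupClassification:
    group_id: str
    label: str  # "true" | "incomplete"
    space_flag: bool
    shared_profile: frozenset[str]

    def __post_init__(self):
        if self.label not in ("true", "incomplete"):
            raise ValueError(f"label must be 'true' or 'incomplete', got {self.label!r}")
        if self.space_flag and self.label != "true":
            raise ValueError("space groups are trivially true")


@dataclass(frozen=True)
class ClassificationTally:
    """Candidate / true / space / incomplete counts for one threshold pair."""

    candidate: int
    true_count: int
    space: int
    incomplete: int


def _profile(gene: GeneRecord, profile: str) -> frozenset[str]:
    if profile == "pfam":
        return gene.pfam_profile
    if profile == "interpro":
        return gene.interpro_profile
    raise ValueError(f"profile must be 'pfam' or 'interpro', got {profile!r}")


def classify_group(
    group: HsdGroup,
    genes: Mapping[str, GeneRecord],
    profile: str = "pfam",
) -> GroupClassification:
    """Classify one group by domain-set agreement among its members.

    Comparison is on accession *sets*: domain order and per-domain copy
    number are ignored.  ``profile`` selects Pfam accessions (default) or
    InterPro accessions.  A member without a gene record is an error.
    """
    missing = [m for m in group.members if m not in genes]
    if missing:
        raise KeyError(f"no gene record for group member(s): {missing}")
    profiles = [_profile(genes[m], profile) for m in group.members]
    first = profiles[0]
    all_same = all(p == first for p in profiles[1:])
    if all_same:
        return GroupClassification(
            group_id=group.group_id,
            label="true",
            space_flag=not first,
            shared_profile=first,
        )
    return GroupClassification(
        group_id=group.group_id,
        label="incomplete",
        space_flag=False,
        shared_profile=frozenset(),
    )


def classify_groups(
    groups: Sequence[HsdGroup],
    genes: Mapping[str, GeneRecord],
    profile: str = "pfam",
) -> list[GroupClassification]:
    """Classify every group, writing labels back onto the group objects."""
    out = []
    for group in groups:
        cls = classify_group(group, genes, profile=profile)
        group.classification = cls.label
        group.space_flag = cls.space_flag
        out.append(cls)
    return out


def tally_classifications(
    classifications: Sequence[GroupClassification],
) -> ClassificationTally:
    """Count candidates, true, space and incomplete groups.

    Invariants: ``candidate == true_count + incomplete`` and
    ``space <= true_count``.
    """
    true_count = sum(1 for c in classifications if c.label == "true")
    incomplete = sum(1 for c in classifications if c.label == "incomplete")
    space = sum(1 for c in classifications if c.space_flag)
    return ClassificationTally(
        candidate=true_count + incomplete,
        true_count=true_count,
        space=space,
        incomplete=incomplete,
    )
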