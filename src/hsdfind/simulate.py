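"""Synthetic test-data generator with planted, known HSD structure.

Emits the full input bundle the detection pipeline consumes — proteome
FASTA, 12-column all-vs-all similarity table, 13-column signature TSV, KO
assignment file and KO -> category map — from a declarative list of
:class:`PlantedFamily` specs, together with a machine-readable manifest of
the ground truth (expected groups, classifications and tallies at every
grid cell).  Similarity rows are synthesized directly from each family's
target identity rather than computed by an aligner, so the bundle is fully
self-contained and deterministic for a given seed.

Scenarios
---------
``true``
    copies share a non-empty Pfam profile; identity >= 90, length spread
    <= 10 aa -> one true group at the default thresholds.
``space``
    like ``true`` but no copy carries any domain (hypothetical proteins);
    classified true with the space flag.
``incomplete``
    copies qualify on sequence but carry *different* domain sets.
``near_miss_identity``
    identity planted in [80, 90): invisible at the default >= 90%
    threshold, appears when relaxed to >= 80%.
``near_miss_length``
    identity >= 90 but length spread > 10 aa: invisible at the default
    <= 10 aa variance, appears at looser length thresholds.

Decoy similarity rows (inter-family, <= 50% identity or e-value 1.0) and
self-hits are planted as well so every filter branch is exercised.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from hsdfind.tabular_io import (
    CategoryMapEntry,
    KoAssignment,
    SignatureRecord,
    SimilarityHit,
    read_fasta_lengths,
    read_ko_file,
    read_signature_table,
    read_similarity_table,
    write_category_map,
    write_ko_file,
    write_signature_table,
    write_similarity_table,
)

SCENARIOS = ("true", "space", "incomplete", "near_miss_identity", "near_miss_length")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Pfam accessions (with descriptions) recurrent in green-algal HSD surveys.
PFAM_POOL = {
    "PF00504": "Chlorophyll A-B binding protein",
    "PF01015": "Ribosomal S3Ae family",
    "PF00125": "Core histone H2A/H2B/H3/H4",
    "PF11999": "Ice-binding protein (DUF3494)",
    "PF00078": "Reverse transcriptase",
    "PF01775": "Ribosomal L18ae family",
    "PF00828": "Ribosomal protein L18e/L15P",
}

#: KO pool with pathway categories (a KO may map to several categories).
KO_POOL: tuple[tuple[str, str, tuple[tuple[str, str], ...]], ...] = (
    ("K02639", "ferredoxin", (("09102", "Energy metabolism"),)),
    (
        "K08913",
        "light-harvesting complex II chlorophyll a/b binding protein 2",
        (("09102", "Energy metabolism"),),
    ),
    ("K13979", "alcohol dehydrogenase", (("09101", "Carbohydrate metabolism"),)),
    ("K01054", "acylglycerol lipase", (("09103", "Lipid metabolism"),)),
    ("K02868", "large subunit ribosomal protein L11e", (("09122", "Translation"),)),
    (
        "K00001",
        "alcohol dehydrogenase (NAD+)",
        (("09101", "Carbohydrate metabolism"), ("09102", "Energy metabolism")),
    ),
)


@dataclass(frozen=True)
class PlantedFamily:
    """Declarative spec of one duplicated-gene family to plant.

    ``target_identity`` is the percent identity synthesized into the
    family's similarity rows; ``length_base``/``length_jitter`` control the
    planted protein lengths (member lengths are ``base + offset`` with
    ``|offset| <= length_jitter``, except ``near_miss_length`` where
    offsets exceed 10).  ``pfam_profile`` is the shared domain set (the
    ``incomplete`` scenario perturbs it per member).
    """

    family_id: str
    copy_count: int
    target_identity: float
    length_base: int
    length_jitter: int
    pfam_profile: tuple[str, ...] = ()
    scenario: str = "true"

    def __post_init__(self):
        if self.copy_count < 2:
            raise ValueError(f"{self.family_id}: copy_count must be >= 2")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"{self.family_id}: unknown scenario {self.scenario!r}")
        if self.length_base < 30:
            raise ValueError(f"{self.family_id}: length_base must be >= 30")
        if self.scenario == "space" and self.pfam_profile:
            raise ValueError(
                f"{self.family_id}: space scenario requires an empty pfam_profile"
            )
        if self.scenario in ("true", "incomplete") and not self.pfam_profile:
            raise ValueError(
                f"{self.family_id}: {self.scenario} scenario requires a non-empty "
                "pfam_profile"
            )
        if self.scenario == "near_miss_identity":
            if not 80.0 <= self.target_identity < 90.0:
                raise ValueError(
                    f"{self.family_id}: near_miss_identity requires identity in [80, 90)"
                )
        elif not 90.0 <= self.target_identity <= 100.0:
            raise ValueError(
                f"{self.family_id}: scenario {self.scenario} requires identity >= 90"
            )
        if self.scenario == "near_miss_length":
            if not 11 <= self.length_jitter <= 100:
                raise ValueError(
                    f"{self.family_id}: near_miss_length requires length_jitter in [11, 100]"
                )
        elif self.length_jitter > 10:
            raise ValueError(
                f"{self.family_id}: scenario {self.scenario} requires length_jitter <= 10"
            )


@dataclass
class Bundle:
    """Paths of one generated dataset plus its in-memory ground truth."""

    outdir: Path
    fasta: Path
    similarity: Path
    signatures: Path
    ko: Path
    category_map: Path
    manifest_path: Path
    manifest: dict


# ---------------------------------------------------------------------------
# Spec construction
# ---------------------------------------------------------------------------

_SCENARIO_WEIGHTS = (
    ("true", 0.50),
    ("space", 0.18),
    ("incomplete", 0.12),
    ("near_miss_identity", 0.10),
    ("near_miss_length", 0.10),
)

# Copy-number mixture: roughly two thirds pairs, a fifth triplets, the rest
# larger families, echoing copy-number spectra of well-annotated genomes.
_COPY_WEIGHTS = ((2, 0.67), (3, 0.20), (4, 0.07), (5, 0.04), (6, 0.02))


def default_families(n_families: int, seed: int) -> list[PlantedFamily]:
    """A randomized but reproducible mixture of planting scenarios."""
    rng = random.Random(seed)
    pool = sorted(PFAM_POOL)
    families = []
    for i in range(n_families):
        scenario = _weighted_choice(rng, _SCENARIO_WEIGHTS)
        copies = _weighted_choice(rng, _COPY_WEIGHTS)
        if scenario == "near_miss_identity":
            identity = round(rng.uniform(80.5, 89.0), 1)
        else:
            identity = round(rng.uniform(90.5, 99.5), 1)
        jitter = rng.randint(12, 60) if scenario == "near_miss_length" else rng.randint(0, 8)
        if scenario == "space":
            profile: tuple[str, ...] = ()
        else:
            k = rng.randint(1, 2)
            profile = tuple(sorted(rng.sample(pool, k)))
        families.append(
            PlantedFamily(
                family_id=f"fam{i:03d}",
                copy_count=copies,
                target_identity=identity,
                length_base=rng.randint(120, 700),
                length_jitter=jitter,
                pfam_profile=profile,
                scenario=scenario,
            )
        )
    return families


def _weighted_choice(rng: random.Random, weighted):
    r = rng.random() * sum(w for _, w in weighted)
    acc = 0.0
    for value, w in weighted:
        acc += w
        if r <= acc:
            return value
    return weighted[-1][0]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate_dataset(
    families: Sequence[PlantedFamily],
    seed: int,
    outdir,
    identity_grid: Sequence[float] = (60.0, 70.0, 80.0, 90.0),
    length_grid: Sequence[int] = (10, 30, 50, 70, 100),
    n_decoys: int | None = None,
) -> Bundle:
    """Write the full input bundle plus a ground-truth manifest.

    Deterministic: the same ``families`` and ``seed`` yield byte-identical
    files.  The manifest records, for every (identity, length) grid cell,
    the expected group partition, per-group classification, candidate/
    true/space/incomplete tally and copy-number histogram, computed
    directly from the planted edges by naive transitive closure —
    independently of the detection code under test.
    """
    if not families:
        raise ValueError("at least one family spec is required")
    ids = [f.family_id for f in families]
    if len(set(ids)) != len(ids):
        raise ValueError("family_id values must be unique")

    rng = random.Random(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genes: dict[str, dict] = {}  # gene_id -> {"length", "profile"}
    planted_edges: list[dict] = []
    hits: list[SimilarityHit] = []
    signature_rows: list[SignatureRecord] = []
    ko_rows: list[KoAssignment] = []

    ipr_counter = 0
    ipr_by_pfam: dict[str, tuple[str, str]] = {}

    def ipr_for(pfam_acc: str) -> tuple[str, str]:
        nonlocal ipr_counter
        if pfam_acc not in ipr_by_pfam:
            ipr_counter += 1
            ipr_by_pfam[pfam_acc] = (
                f"IPR{900000 + ipr_counter:06d}",
                PFAM_POOL.get(pfam_acc, "synthetic domain") + " superfamily",
            )
        return ipr_by_pfam[pfam_acc]

    extra_domain_counter = 0

    for fam_index, fam in enumerate(families):
        member_ids = [f"{fam.family_id}_g{i + 1}" for i in range(fam.copy_count)]
        offsets = [0]
        for _ in member_ids[1:]:
            if fam.scenario == "near_miss_length":
                mag = rng.randint(11, fam.length_jitter)
            else:
                mag = rng.randint(0, fam.length_jitter)
            offsets.append(mag if rng.random() < 0.5 else -mag)
        lengths = [max(30, fam.length_base + off) for off in offsets]

        profiles: list[tuple[str, ...]] = []
        for i in range(fam.copy_count):
            if fam.scenario == "incomplete" and i > 0:
                extra_domain_counter += 1
                profiles.append(
                    tuple(sorted(fam.pfam_profile + (f"PF9{extra_domain_counter:04d}",)))
                )
            else:
                profiles.append(fam.pfam_profile)

        for gid, length, profile in zip(member_ids, lengths, profiles):
            genes[gid] = {"length": length, "profile": profile}

        # star topology from the first copy: grouping of B and C relies on
        # the transitive link through A, never on a direct B-C row
        lo, hi = _identity_band(fam.scenario)
        for other_idx in range(1, fam.copy_count):
            identity = round(
                min(hi, max(lo, fam.target_identity + rng.uniform(-0.3, 0.3))), 2
            )
            a, b = member_ids[0], member_ids[other_idx]
            evalue = 10.0 ** -rng.randint(30, 120)
            aln = min(lengths[0], lengths[other_idx])
            bit = round(aln * 1.9 + rng.uniform(0, 5), 1)
            hits.append(
                SimilarityHit(a, b, identity, aln, int(aln * (100 - identity) / 100),
                              rng.randint(0, 2), 1, aln, 1, aln, evalue, bit)
            )
            # reciprocal hit with a slightly lower bit score: exercises
            # best-hit collapsing without changing which hit wins
            hits.append(
                SimilarityHit(b, a, identity, aln, int(aln * (100 - identity) / 100),
                              rng.randint(0, 2), 1, aln, 1, aln, evalue,
                              round(bit - 0.5, 1))
            )
            planted_edges.append(
                {
                    "a": a,
                    "b": b,
                    "identity": identity,
                    "evalue": evalue,
                    "len_diff": abs(lengths[0] - lengths[other_idx]),
                }
            )

        # all-vs-all searches report self-hits; the filter must drop them
        for gid, length in zip(member_ids, lengths):
            hits.append(
                SimilarityHit(gid, gid, 100.0, length, 0, 0, 1, length, 1, length,
                              10.0 ** -rng.randint(100, 180), round(length * 2.0, 1))
            )

        for gid, length, profile in zip(member_ids, lengths, profiles):
            pos = 5
            for acc in profile:
                desc = PFAM_POOL.get(acc, "synthetic domain")
                span = min(60, length - pos - 1)
                ipr_acc, ipr_desc = ipr_for(acc)
                signature_rows.append(
                    SignatureRecord(
                        protein_id=gid,
                        sequence_md5=f"md5{fam_index:03d}{gid[-2:]}",
                        sequence_length=length,
                        analysis="Pfam",
                        signature_accession=acc,
                        signature_description=desc,
                        match_start=pos,
                        match_end=pos + span,
                        score=f"{rng.uniform(1.0, 9.9):.1f}E-{rng.randint(10, 40)}",
                        status="T",
                        run_date="15-03-2021",
                        interpro_accession=ipr_acc,
                        interpro_description=ipr_desc,
                    )
                )
                pos = min(pos + span + 2, length - 2)

        ko_choice = rng.choice(KO_POOL) if rng.random() < 0.7 else None
        for i, gid in enumerate(member_ids):
            if ko_choice is not None and not (i == fam.copy_count - 1 and fam.copy_count > 2):
                ko_rows.append(KoAssignment(gid, ko_choice[0]))
            else:
                ko_rows.append(KoAssignment(gid, ""))

    # decoy rows between members of different families: below the identity
    # grid or failing the e-value cut, so they can never form edges
    gene_ids = sorted(genes)
    n_decoys = n_decoys if n_decoys is not None else max(10, len(families) * 2)
    for _ in range(n_decoys):
        a, b = rng.sample(gene_ids, 2)
        if a.split("_g")[0] == b.split("_g")[0]:
            continue
        if rng.random() < 0.5:
            identity, evalue = round(rng.uniform(20.0, 50.0), 2), 10.0 ** -rng.randint(6, 20)
        else:
            identity, evalue = round(rng.uniform(55.0, 98.0), 2), 1.0
        aln = rng.randint(40, 200)
        hits.append(
            SimilarityHit(a, b, identity, aln, int(aln * (100 - identity) / 100),
                          rng.randint(0, 3), 1, aln, 1, aln, evalue,
                          round(aln * 0.8, 1))
        )

    fasta = outdir / "proteome.faa"
    with open(fasta, "w", encoding="utf-8") as fh:
        for gid in gene_ids:
            seq = "".join(rng.choice(AMINO_ACIDS) for _ in range(genes[gid]["length"]))
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    similarity = outdir / "similarity.tsv"
    write_similarity_table(hits, similarity)
    signatures = outdir / "signatures.tsv"
    write_signature_table(signature_rows, signatures)
    ko_path = outdir / "ko.tsv"
    write_ko_file(ko_rows, ko_path)
    category_map = outdir / "category_map.tsv"
    write_category_map(
        [
            CategoryMapEntry(ko, cat_id, cat_name, desc)
            for ko, desc, cats in KO_POOL
            for cat_id, cat_name in cats
        ],
        category_map,
    )

    manifest = _build_manifest(
        families, genes, planted_edges, identity_grid, length_grid, seed
    )
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return Bundle(
        outdir=outdir,
        fasta=fasta,
        similarity=similarity,
        signatures=signatures,
        ko=ko_path,
        category_map=category_map,
        manifest_path=manifest_path,
        manifest=manifest,
    )


def _identity_band(scenario: str) -> tuple[float, float]:
    if scenario == "near_miss_identity":
        return 80.0, 89.99
    return 90.0, 100.0


# ---------------------------------------------------------------------------
# Ground truth / brute-force oracle
# ---------------------------------------------------------------------------


def _closure_components(edges: Sequence[tuple[str, str]]) -> list[tuple[str, ...]]:
    """Connected components by iterated set merging (naive closure)."""
    comps: list[set[str]] = []
    for a, b in edges:
        hit_sets = [c for c in comps if a in c or b in c]
        merged = {a, b}
        for c in hit_sets:
            merged |= c
            comps.remove(c)
        comps.append(merged)
    return sorted(tuple(sorted(c)) for c in comps)


def _classify_members(
    members: Sequence[str], profiles: Mapping[str, tuple[str, ...]]
) -> tuple[str, bool]:
    sets = [frozenset(profiles.get(m, ())) for m in members]
    if all(s == sets[0] for s in sets):
        return "true", not sets[0]
    return "incomplete", False


def _build_manifest(families, genes, planted_edges, identity_grid, length_grid, seed):
    profiles = {g: tuple(info["profile"]) for g, info in genes.items()}
    cells = {}
    for ident in identity_grid:
        for ldiff in length_grid:
            qualifying = [
                (e["a"], e["b"])
                for e in planted_edges
                if e["identity"] >= ident
                and e["evalue"] <= 1e-5
                and e["len_diff"] <= ldiff
            ]
            components = _closure_components(qualifying)
            group_info = {}
            true_count = space = incomplete = 0
            hist_groups = {"2": 0, "3": 0, "4plus": 0}
            hist_copies = {"2": 0, "3": 0, "4plus": 0}
            for members in components:
                label, is_space = _classify_members(members, profiles)
                group_info[members[0]] = {
                    "members": list(members),
                    "label": label,
                    "space": is_space,
                }
                if label == "true":
                    true_count += 1
                    space += is_space
                else:
                    incomplete += 1
                key = "2" if len(members) == 2 else "3" if len(members) == 3 else "4plus"
                hist_groups[key] += 1
                hist_copies[key] += len(members)
            cells[f"{ident:g}_{ldiff}"] = {
                "groups": group_info,
                "tally": {
                    "candidate": true_count + incomplete,
                    "true": true_count,
                    "space": space,
                    "incomplete": incomplete,
                },
                "histogram": {"groups": hist_groups, "copies": hist_copies},
            }
    return {
        "seed": seed,
        "identity_grid": [float(i) for i in identity_grid],
        "length_grid": [int(l) for l in length_grid],
        "families": [
            {
                "family_id": f.family_id,
                "copy_count": f.copy_count,
                "scenario": f.scenario,
                "target_identity": f.target_identity,
            }
            for f in families
        ],
        "genes": {
            g: {"length": info["length"], "profile": list(info["profile"])}
            for g, info in genes.items()
        },
        "cells": cells,
    }


def brute_force_pipeline(bundle_dir, cfg) -> dict:
    """Independent re-analysis of a bundle by exhaustive scanning.

    Reads the bundle files back, re-derives gene lengths and Pfam profiles
    with plain dictionary passes, selects each unordered pair's best hit by
    scanning the entire hit list, applies the thresholds directly, groups
    by iterated transitive closure and classifies by literal set
    comparison.  Intended as a test oracle on small instances only
    (quadratic in the number of hits).
    """
    bundle_dir = Path(bundle_dir)
    hits = read_similarity_table(bundle_dir / "similarity.tsv")
    signatures = read_signature_table(bundle_dir / "signatures.tsv")
    fasta_lengths = read_fasta_lengths(bundle_dir / "proteome.faa")

    lengths: dict[str, int] = {}
    profiles: dict[str, set[str]] = {}
    for rec in signatures:
        lengths[rec.protein_id] = rec.sequence_length
        if rec.analysis == "Pfam":
            profiles.setdefault(rec.protein_id, set()).add(rec.signature_accession)
    for gid, length in fasta_lengths.items():
        lengths.setdefault(gid, length)

    pairs: list[tuple[str, str]] = []
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        p = tuple(sorted((h.query_id, h.subject_id)))
        if p not in pairs:
            pairs.append(p)

    qualifying: list[tuple[str, str]] = []
    for a, b in pairs:
        best = None
        for h in hits:
            if {h.query_id, h.subject_id} == {a, b}:
                if best is None or h.bit_score > best.bit_score:
                    best = h
        assert best is not None
        if best.e_value > cfg.evalue_max:
            continue
        if best.percent_identity < cfg.identity_min:
            continue
        if a not in lengths or b not in lengths:
            continue
        if abs(lengths[a] - lengths[b]) > cfg.length_diff_max:
            continue
        qualifying.append((a, b))

    components = _closure_components(qualifying)
    true_count = space = incomplete = 0
    groups = {}
    for members in components:
        label, is_space = _classify_members(
            members, {g: tuple(sorted(profiles.get(g, set()))) for g in members}
        )
        groups[members[0]] = {"members": list(members), "label": label, "space": is_space}
        if label == "true":
            true_count += 1
            space += is_space
        else:
            incomplete += 1
    return {
        "groups": groups,
        "tally": {
            "candidate": true_count + incomplete,
            "true": true_count,
            "space": space,
            "incomplete": incomplete,
        },
    }
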