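"""Threshold-sweep evaluation of HSD detection.

Because no labelled benchmark of recent gene duplicates exists, threshold
choices are compared with two summary statistics computed from the
classification tally at each (identity, length-variance) grid point:

* **capturing value** — the percentage of candidate groups whose copies
  share identical domain content::

      capturing = floor(100 * True / (True + Incomplete))

* **performance score** — rewards domain-consistent groups and penalizes
  domain-discordant ones; the numerator is the true groups plus the
  candidate groups that contain functional domains (candidate - space),
  the denominator is the incomplete count offset by one so it can never
  be zero::

      score = floor((2*True + Incomplete - Space) / (Incomplete + 1))

Both are reported as integers (truncated toward minus infinity, matching
the published tables); exact floats are available via ``precise=True``.
The default sweep grid is identities {60, 70, 80, 90} percent by length
differences {10, 30, 50, 70, 100} residues — 20 cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from hsdfind.core import (
    GeneRecord,
    ThresholdConfig,
    run_pipeline,
)
from hsdfind.tabular_io import SimilarityHit

DEFAULT_IDENTITY_GRID: tuple[float, ...] = (60.0, 70.0, 80.0, 90.0)
DEFAULT_LENGTH_GRID: tuple[int, ...] = (10, 30, 50, 70, 100)


def capturing_value(true_count: int, incomplete: int, precise: bool = False):
    """Percentage of candidate HSD groups with identical domain content.

    Integer-truncated by default.  Undefined (raises ``ValueError``) when
    there are no candidates at all.
    """
    total = true_count + incomplete
    if total <= 0:
        raise ValueError("capturing value undefined: no candidate groups")
    if precise:
        return 100.0 * true_count / total
    return 100 * true_count // total


def performance_score(
    true_count: int, incomplete: int, space: int, precise: bool = False
):
    """Score favouring domain-consistent groups over domain-discordant ones.

    ``(2*True + Incomplete - Space) / (Incomplete + 1)``, integer-truncated
    by default.  The denominator is at least one by construction.
    """
    numerator = 2 * true_count + incomplete - space
    denominator = incomplete + 1
    if precise:
        return numerator / denominator
    return numerator // denominator


@dataclass(frozen=True)
class SweepCell:
    """Counts and statistics for one (identity, length-variance) grid point."""

    identity_min: float
    length_diff_max: int
    candidate: int
    true_count: int
    space: int
    incomplete: int
    capturing: int | None  # None when the cell has no candidates
    score: int
    groups_2: int
    groups_3: int
    groups_4plus: int
    copies_2: int
    copies_3: int
    copies_4plus: int

    @property
    def label(self) -> str:
        return ThresholdConfig(self.identity_min, self.length_diff_max).label


def threshold_sweep(
    hits: Sequence[SimilarityHit],
    genes: Mapping[str, GeneRecord],
    identity_grid: Sequence[float] = DEFAULT_IDENTITY_GRID,
    length_grid: Sequence[int] = DEFAULT_LENGTH_GRID,
    evalue_max: float = 1e-5,
    profile: str = "pfam",
) -> list[SweepCell]:
    """Run the full detection pipeline at every grid point.

    Each cell is recomputed from scratch (filter -> cluster -> classify ->
    tally); nothing is shared between cells, so every cell equals a direct
    single-threshold run.  Cells are ordered identity-major, matching the
    grid arguments.
    """
    if not identity_grid or not length_grid:
        raise ValueError("identity_grid and length_grid must be non-empty")
    cells: list[SweepCell] = []
    for ident in identity_grid:
        for ldiff in length_grid:
            cfg = ThresholdConfig(
                identity_min=ident, length_diff_max=ldiff, evalue_max=evalue_max
            )
            res = run_pipeline(hits, genes, cfg, profile=profile)
            t = res.tally
            hist = res.histogram
            cells.append(
                SweepCell(
                    identity_min=ident,
                    length_diff_max=ldiff,
                    candidate=t.candidate,
                    true_count=t.true_count,
                    space=t.space,
                    incomplete=t.incomplete,
                    capturing=(
                        capturing_value(t.true_count, t.incomplete)
                        if t.candidate > 0
                        else None
                    ),
                    score=performance_score(t.true_count, t.incomplete, t.space),
                    groups_2=hist["groups"]["2"],
                    groups_3=hist["groups"]["3"],
                    groups_4plus=hist["groups"]["4plus"],
                    copies_2=hist["copies"]["2"],
                    copies_3=hist["copies"]["3"],
                    copies_4plus=hist["copies"]["4plus"],
                )
            )
    return cells


SWEEP_COLUMNS = (
    "thresholds",
    "candidate_hsds",
    "true_hsds",
    "space",
    "incomplete_hsds",
    "capturing_pct",
    "score",
    "groups_2",
    "groups_3",
    "groups_4plus",
)


def sweep_to_frame(cells: Sequence[SweepCell]) -> pd.DataFrame:
    """Arrange sweep cells as a summary table, one row per threshold pair.

    Columns mirror the per-threshold summary layout: threshold label,
    candidate/true/space/incomplete counts, the two statistics, and group
    counts in the 2 / 3 / >=4 copy-number bins.
    """
    return pd.DataFrame(
        [
            {
                "thresholds": c.label,
                "candidate_hsds": c.candidate,
                "true_hsds": c.true_count,
                "space": c.space,
                "incomplete_hsds": c.incomplete,
                "capturing_pct": c.capturing,
                "score": c.score,
                "groups_2": c.groups_2,
                "groups_3": c.groups_3,
                "groups_4plus": c.groups_4plus,
            }
            for c in cells
        ],
        columns=list(SWEEP_COLUMNS),
    )


def render_sweep_figure(cells: Sequence[SweepCell], path) -> list[str]:
    """Render the sweep as a heatmap of true-HSD counts with marginal bars.

    The central heatmap shows true-HSD counts per (identity row, length
    column) on a blue-to-red linear scale with the count printed in each
    cell.  The top margin bars show the capturing value per identity level
    (averaged over length columns); the left margin bars show the
    performance score per length column (averaged over identity levels).
    Written as both PNG and SVG next to ``path``; returns the file names.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    import numpy as np

    identities = sorted({c.identity_min for c in cells}, reverse=True)
    lengths = sorted({c.length_diff_max for c in cells})
    grid = {(c.identity_min, c.length_diff_max): c for c in cells}
    expected = {(i, l) for i in identities for l in lengths}
    if set(grid) != expected:
        raise ValueError("sweep cells do not form a full rectangular grid")

    true_mat = np.array(
        [[grid[(i, l)].true_count for l in lengths] for i in identities], dtype=float
    )
    capturing_by_identity = [
        float(np.mean([grid[(i, l)].capturing or 0 for l in lengths]))
        for i in identities
    ]
    score_by_length = [
        float(np.mean([grid[(i, l)].score for i in identities])) for l in lengths
    ]

    fig = plt.figure(figsize=(2.2 + 1.1 * len(lengths), 2.2 + 0.9 * len(identities)))
    gs = fig.add_gridspec(
        2,
        2,
        width_ratios=[1.0, len(lengths)],
        height_ratios=[1.0, len(identities)],
        wspace=0.08,
        hspace=0.08,
    )
    ax_top = fig.add_subplot(gs[0, 1])
    ax_left = fig.add_subplot(gs[1, 0])
    ax_heat = fig.add_subplot(gs[1, 1])

    vmin, vmax = float(true_mat.min()), float(true_mat.max())
    if vmin == vmax:  # degenerate all-equal grid: pin to the colormap midpoint
        vmin, vmax = vmin - 1.0, vmax + 1.0
    im = ax_heat.imshow(
        true_mat, cmap="coolwarm", aspect="auto", vmin=vmin, vmax=vmax
    )
    for r, ident in enumerate(identities):
        for c_idx, l in enumerate(lengths):
            ax_heat.text(
                c_idx,
                r,
                str(grid[(ident, l)].true_count),
                ha="center",
                va="center",
                fontsize=8,
            )
    ax_heat.set_xticks(range(len(lengths)), [f"{l} aa" for l in lengths])
    ax_heat.set_yticks(range(len(identities)), [f"{i:g}%" for i in identities])
    ax_heat.set_xlabel("max length difference")
    ax_heat.yaxis.set_visible(False)

    ax_top.bar(range(len(identities)), capturing_by_identity, color="steelblue")
    ax_top.set_xticks(range(len(identities)), [f"{i:g}%" for i in identities])
    ax_top.set_ylabel("capturing %")
    ax_top.set_title("true-HSD counts across thresholds", fontsize=10)

    ax_left.barh(range(len(lengths)), score_by_length, color="indianred")
    ax_left.set_yticks(range(len(lengths)), [f"{l} aa" for l in lengths])
    ax_left.invert_yaxis()
    ax_left.set_xlabel("score")
    ax_left.set_ylabel("min identity (heatmap rows) / length bins (bars)", fontsize=7)

    fig.colorbar(im, ax=ax_heat, shrink=0.8, label="true HSDs")

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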