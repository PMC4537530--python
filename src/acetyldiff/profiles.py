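"""Binned, input-normalised aggregate signal profiles around anchors.

A window of +/- ``flank`` bp around every anchor (stranded TSS or
unstranded enhancer center) is split into ``n_bins`` bins. Read-start
counts are pooled across anchors before the log ("log of ratio of
averages"), each density is normalised by anchor count, bin size and
library depth, and a symmetric pseudocount keeps the identity case at
exactly zero and every bin finite. For minus-strand TSS anchors the bin
order is reversed so bins always run 5' -> 3'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genomic_io import GeneRecord, GenomicInterval
from .peaks import ReadSet

__all__ = [
    "ProfileConfig",
    "AggregateProfile",
    "compute_profile",
    "group_profile",
    "profile_table",
    "plot_profiles",
]

Anchor = Union[GeneRecord, GenomicInterval]


@dataclass(frozen=True)
class ProfileConfig:
    """Binning geometry and normalisation for aggregate profiles.

    flank: bp each side of the anchor (window = 2*flank).
    n_bins x bin_size must equal 2*flank (default 400 x 50 = 20 kb).
    pseudocount: reads-per-bp added to both densities before the ratio.
    """

    flank: int = 10_000
    n_bins: int = 400
    bin_size: int = 50
    pseudocount: float = 1e-4
    log_base: float = 2.0

    def __post_init__(self) -> None:
        if self.n_bins * self.bin_size != 2 * self.flank:
            raise ValueError(
                f"n_bins * bin_size must equal 2 * flank "
                f"({self.n_bins} * {self.bin_size} != {2 * self.flank})"
            )
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


@dataclass
class AggregateProfile:
    """A per-bin log-ratio profile pooled over anchors.

    ``values`` has length n_bins and is finite everywhere; raw pooled
    chip/input bin counts are retained for count-conservation checks.
    """

    anchor_type: str  # "tss" | "enhancer"
    label: str
    values: np.ndarray
    n_anchors: int
    config: ProfileConfig
    chip_counts: Optional[np.ndarray] = None
    input_counts: Optional[np.ndarray] = None
    n_dropped: int = 0


def _anchor_points(anchors: Sequence[Anchor]) -> tuple[str, list[tuple[str, int, str]]]:
    points = []
    kinds = set()
    for a in anchors:
        if isinstance(a, GeneRecord):
            kinds.add("tss")
            points.append((a.chrom, a.tss, a.strand))
        else:
            kinds.add("enhancer")
            points.append((a.chrom, (a.start + a.end) // 2, "."))
    if len(kinds) != 1:
        raise ValueError("anchors must be all TSSs or all enhancer intervals")
    return kinds.pop(), points


def _pooled_bin_counts(
    reads: ReadSet,
    points: Sequence[tuple[str, int, str]],
    cfg: ProfileConfig,
) -> np.ndarray:
    counts = np.zeros(cfg.n_bins, dtype=np.int64)
    offsets = cfg.bin_size * np.arange(cfg.n_bins + 1, dtype=np.int64) - cfg.flank
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos, strand in points:
        if chrom not in by_chrom:
            by_chrom[chrom] = reads.starts(chrom)
        starts = by_chrom[chrom]
        edges = pos + offsets
        c = np.diff(np.searchsorted(starts, edges))
        if strand == "-":
            c = c[::-1]
        counts += c
    return counts


def compute_profile(
    chip: ReadSet,
    input_: ReadSet,
    anchors: Sequence[Anchor],
    cfg: ProfileConfig,
    chrom_sizes: Mapping[str, int],
    label: Optional[str] = None,
) -> AggregateProfile:
    """Aggregate log-ratio (ChIP/input) profile around the given anchors.

    Anchors whose full window would cross a chromosome boundary are
    dropped (and counted in ``n_dropped``); an error is raised if none
    survive. Per bin b:

        D(b) = pooled read starts in b / (n_anchors * bin_size * depth)
        value(b) = log2((D_chip(b) + pc) / (D_input(b) + pc))
    """
    kind, points = _anchor_points(anchors)
    kept = [
        p
        for p in points
        if p[0] in chrom_sizes
        and p[1] - cfg.flank >= 0
        and p[1] + cfg.flank <= chrom_sizes[p[0]]
    ]
    n_dropped = len(points) - len(kept)
    if not kept:
        raise ValueError(
            f"all {len(points)} anchors dropped: every window of +/-{cfg.flank} bp "
            "crosses a chromosome boundary or lies on an unknown chromosome"
        )
    c_chip = _pooled_bin_counts(chip, kept, cfg)
    c_input = _pooled_bin_counts(input_, kept, cfg)
    n = len(kept)
    d_chip = c_chip / (n * cfg.bin_size * chip.depth)
    d_input = c_input / (n * cfg.bin_size * input_.depth)
    values = np.log(
        (d_chip + cfg.pseudocount) / (d_input + cfg.pseudocount)
    ) / np.log(cfg.log_base)
    return AggregateProfile(
        anchor_type=kind,
        label=label if label is not None else chip.subject_id,
        values=values,
        n_anchors=n,
        config=cfg,
        chip_counts=c_chip,
        input_counts=c_input,
        n_dropped=n_dropped,
    )


def group_profile(
    profiles: Sequence[AggregateProfile],
    subject_groups: Mapping[str, str],
) -> dict[str, AggregateProfile]:
    """Per-bin arithmetic mean of subject profiles within each group."""
    if not profiles:
        raise ValueError("no profiles given")
    ref = profiles[0]
    for p in profiles[1:]:
        if p.anchor_type != ref.anchor_type or p.config != ref.config:
            raise ValueError("profiles mix anchor types or configurations")
    out: dict[str, AggregateProfile] = {}
    groups = sorted({subject_groups[p.label] for p in profiles})
    for g in groups:
        members = [p for p in profiles if subject_groups[p.label] == g]
        values = np.mean([p.values for p in members], axis=0)
        out[g] = AggregateProfile(
            anchor_type=ref.anchor_type,
            label=g,
            values=values,
            n_anchors=members[0].n_anchors,
            config=ref.config,
        )
    return out


def profile_table(profile: AggregateProfile) -> pd.DataFrame:
    """Tidy table (bin_index, offset_bp_from_anchor, value) for one profile."""
    cfg = profile.config
    offsets = cfg.bin_size * np.arange(cfg.n_bins) - cfg.flank
    return pd.DataFrame(
        {
            "bin_index": np.arange(cfg.n_bins),
            "offset_bp_from_anchor": offsets,
            "value": profile.values,
        }
    )


def plot_profiles(profiles: Mapping[str, AggregateProfile], path, title: str = "") -> None:
    """Two-curve (high vs low) profile figure; optional convenience export."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    colors = {"high": "crimson", "low": "steelblue"}
    for label, prof in sorted(profiles.items()):
        cfg = prof.config
        x = (cfg.bin_size * np.arange(cfg.n_bins) - cfg.flank) / 1000.0
        ax.plot(x, prof.values, label=label, color=colors.get(label))
    ax.set_xlabel("distance from anchor (kb)")
    ax.set_ylabel("log2 ChIP/input density")
    ax.axvline(0.0, color="grey", lw=0.5)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
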