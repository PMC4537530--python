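"""Read deduplication and ChIP-vs-input peak calling.

The caller is a fixed-width sliding-window local-Poisson procedure: each
window's read-start count in the ChIP sample is tested against a Poisson
expectation derived from the matched input, where the local rate is the
maximum of the genome-wide input rate and input rates measured in spans
of several sizes centred on the window (the classic dynamic-lambda idea,
without model building or read shifting). Unequal library sizes are
handled by scaling the input-derived expectation by chip_depth/input_depth.

Window "coverage" counts read *start* positions, so each read contributes
to exactly one non-overlapping accounting unit and window counts are
unambiguous at boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import BedRecord, BedTable, GenomicInterval, read_bed, write_bed

__all__ = [
    "ReadSet",
    "Peak",
    "CallerConfig",
    "deduplicate",
    "call_peaks",
    "window_scan",
    "peak_count_summary",
    "write_peaks_bed",
    "read_reads_bed",
]

_READ_COLUMNS = ["chrom", "start", "end", "strand"]


@dataclass
class ReadSet:
    """Single-end aligned reads for one sample (ChIP or matched input).

    Reads are held in a DataFrame with columns chrom/start/end/strand for
    speed; ``reads`` materialises them as :class:`GenomicInterval` when an
    object view is wanted. ``depth`` is the retained read count.
    """

    sample_id: str
    subject_id: str
    role: str  # "chip" | "input"
    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.role not in ("chip", "input"):
            raise ValueError(f"role must be 'chip' or 'input', got {self.role!r}")
        missing = [c for c in _READ_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"read table missing columns: {missing}")
        self.df = self.df[_READ_COLUMNS].reset_index(drop=True)

    @property
    def depth(self) -> int:
        return len(self.df)

    @property
    def reads(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand)
            for r in self.df.itertuples(index=False)
        ]

    def starts(self, chrom: str) -> np.ndarray:
        """Sorted array of read start positions on one chromosome."""
        s = self.df.loc[self.df["chrom"] == chrom, "start"].to_numpy(dtype=np.int64)
        return np.sort(s)

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[GenomicInterval], sample_id: str, subject_id: str, role: str
    ) -> "ReadSet":
        rows = [(iv.chrom, iv.start, iv.end, iv.strand) for iv in intervals]
        df = pd.DataFrame(rows, columns=_READ_COLUMNS)
        return cls(sample_id, subject_id, role, df)


def read_reads_bed(path, sample_id: str, subject_id: str, role: str) -> ReadSet:
    """Load a 6-column reads BED into a :class:`ReadSet` (validated)."""
    table = read_bed(path, expected_columns=6)
    return ReadSet.from_intervals(table.intervals, sample_id, subject_id, role)


@dataclass(frozen=True)
class Peak:
    """A merged significant region for one subject."""

    interval: GenomicInterval
    subject_id: str
    p_value: float
    chip_count: int
    expected: float


@dataclass(frozen=True)
class CallerConfig:
    """Sliding-window caller parameters.

    window/step in bp; ``local_scales`` are the span widths over which
    input rates are measured for the local lambda; ``merge_gap`` is the
    largest separation (bp) at which significant windows still merge;
    ``min_count`` guards against calling on a handful of reads.
    """

    window: int = 300
    step: int = 100
    p_threshold: float = 1e-5
    local_scales: tuple[int, ...] = (1_000, 5_000, 10_000)
    merge_gap: int = 200
    min_count: int = 5

    def __post_init__(self) -> None:
        if self.step > self.window:
            raise ValueError("step must be <= window")
        if any(s < self.window for s in self.local_scales):
            raise ValueError("every local scale must be >= window")
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        if self.window <= 0 or self.step <= 0 or self.merge_gap < 0:
            raise ValueError("window/step must be positive, merge_gap >= 0")


def deduplicate(reads: ReadSet) -> ReadSet:
    """Keep exactly one read per (chrom, start, strand); sort by coordinate.

    Retaining only non-redundant reads corrects for amplification bias;
    opposite-strand reads at one position are genuinely distinct.
    """
    df = (
        reads.df.drop_duplicates(subset=["chrom", "start", "strand"])
        .sort_values(["chrom", "start", "strand"], kind="mergesort")
        .reset_index(drop=True)
    )
    return ReadSet(reads.sample_id, reads.subject_id, reads.role, df)


def _local_rate(
    input_starts: np.ndarray,
    centers: np.ndarray,
    chrom_len: int,
    scales: Sequence[int],
    genome_rate: float,
) -> np.ndarray:
    """Max over {genome rate, per-scale local input rates} for each center."""
    rate = np.full(centers.shape, genome_rate, dtype=float)
    for s in scales:
        lo = np.clip(centers - s // 2, 0, chrom_len)
        hi = np.clip(centers + s - s // 2, 0, chrom_len)
        n = np.searchsorted(input_starts, hi) - np.searchsorted(input_starts, lo)
        span = np.maximum(hi - lo, 1)
        rate = np.maximum(rate, n / span)
    return rate


def window_scan(
    chip: ReadSet,
    input_: ReadSet,
    cfg: CallerConfig,
    chrom_sizes: Mapping[str, int],
) -> pd.DataFrame:
    """Scan sliding windows, returning per-window counts, lambda and p-value.

    Columns: chrom, start, end, chip_count, lam, p_value, significant.
    Windows at chromosome ends are clipped, and lambda scales with the
    clipped window length.
    """
    if input_.depth == 0:
        raise ValueError(
            "matched input sample has zero reads; ChIP-vs-input comparison "
            "requires a non-empty input"
        )
    genome_len = sum(chrom_sizes.values())
    genome_rate = input_.depth / genome_len
    ratio = chip.depth / input_.depth
    frames = []
    for chrom in chrom_sizes:
        L = int(chrom_sizes[chrom])
        starts = np.arange(0, L, cfg.step, dtype=np.int64)
        ends = np.minimum(starts + cfg.window, L)
        cs = chip.starts(chrom)
        is_ = input_.starts(chrom)
        counts = np.searchsorted(cs, ends) - np.searchsorted(cs, starts)
        centers = (starts + ends) // 2
        rate = _local_rate(is_, centers, L, cfg.local_scales, genome_rate)
        lam = (ends - starts) * rate * ratio
        p = stats.poisson.sf(counts - 1, lam)
        sig = (counts >= cfg.min_count) & (p < cfg.p_threshold)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "chip_count": counts,
                    "lam": lam,
                    "p_value": p,
                    "significant": sig,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def merge_significant_windows(
    windows: Sequence[tuple[int, int]],
    p_values: Sequence[float],
    merge_gap: int,
) -> list[tuple[int, int, float]]:
    """Merge overlapping or <= merge_gap-separated windows on one chromosome.

    Input must be sorted by start. Returns (start, end, min p) spans.
    """
    merged: list[tuple[int, int, float]] = []
    for (s, e), p in zip(windows, p_values):
        if merged and s - merged[-1][1] <= merge_gap:
            ps, pe, pp = merged[-1]
            merged[-1] = (ps, max(pe, e), min(pp, p))
        else:
            merged.append((s, e, p))
    return merged


def call_peaks(
    chip: ReadSet,
    input_: ReadSet,
    cfg: CallerConfig,
    chrom_sizes: Mapping[str, int],
) -> list[Peak]:
    """Call enriched regions for one subject against the matched input.

    Significant windows (count >= min_count and upper-tail Poisson
    probability < p_threshold) are merged into peaks; each peak carries
    the minimum window p-value and counts/expectation recomputed on the
    merged span. Peaks within one subject never overlap.
    """
    scan = window_scan(chip, input_, cfg, chrom_sizes)
    genome_len = sum(chrom_sizes.values())
    genome_rate = input_.depth / genome_len
    ratio = chip.depth / input_.depth
    peaks: list[Peak] = []
    for chrom, grp in scan[scan["significant"]].groupby("chrom", sort=False):
        L = int(chrom_sizes[chrom])
        spans = merge_significant_windows(
            list(zip(grp["start"], grp["end"])),
            list(grp["p_value"]),
            cfg.merge_gap,
        )
        cs = chip.starts(chrom)
        is_ = input_.starts(chrom)
        for s, e, p in spans:
            count = int(np.searchsorted(cs, e) - np.searchsorted(cs, s))
            center = np.array([(s + e) // 2])
            rate = _local_rate(is_, center, L, cfg.local_scales, genome_rate)[0]
            expected = (e - s) * rate * ratio
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, int(s), int(e)),
                    subject_id=chip.subject_id,
                    p_value=float(p),
                    chip_count=count,
                    expected=float(expected),
                )
            )
    peaks.sort(key=lambda pk: (pk.interval.chrom, pk.interval.start))
    return peaks


def peak_count_summary(peaks_by_subject: Mapping[str, Sequence[Peak]]) -> pd.DataFrame:
    """One row per subject with its peak count (exposure-trend summary)."""
    rows = [(subj, len(pks)) for subj, pks in peaks_by_subject.items()]
    return pd.DataFrame(rows, columns=["subject_id", "n_peaks"])


def write_peaks_bed(peaks: Sequence[Peak], path) -> None:
    """Write peaks as BED6+2 (name=subject:index, score=-log10 p capped at 1000,
    then chip_count and expected as extra columns)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for i, pk in enumerate(peaks):
            score = 1000.0 if pk.p_value <= 0 else min(1000.0, -np.log10(pk.p_value))
            fh.write(
                f"{pk.interval.chrom}\t{pk.interval.start}\t{pk.interval.end}\t"
                f"{pk.subject_id}:{i}\t{score:.3f}\t.\t{pk.chip_count}\t"
                f"{pk.expected:.4f}\n"
            )
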