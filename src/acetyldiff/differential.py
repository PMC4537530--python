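"""Cross-individual peak merging and exposure-group classification.

Peaks from all subjects are merged by transitive single-linkage (any
>= 1 bp overlap) into broad domains; each domain is then classified by
group presence: present only in the high-exposure group -> induced,
only in the low-exposure group -> suppressed, in both -> shared. Two
readings of "detected in one group" are supported: any-vs-none (a
single subject's peak counts as group presence; the default) and
all-vs-none (every subject of the group must contribute; domains that
satisfy neither rule in a group are "group-specific-partial").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import pandas as pd

from .genomic_io import GenomicInterval
from .peaks import Peak

__all__ = [
    "BroadDomain",
    "DifferentialRule",
    "merge_domains",
    "classify_domains",
    "differential_summary",
    "STATUS_INDUCED",
    "STATUS_SUPPRESSED",
    "STATUS_SHARED",
    "STATUS_PARTIAL",
]

STATUS_INDUCED = "induced"
STATUS_SUPPRESSED = "suppressed"
STATUS_SHARED = "shared"
STATUS_PARTIAL = "group-specific-partial"


@dataclass(frozen=True)
class DifferentialRule:
    """How group "presence" is decided: 'any-vs-none' or 'all-vs-none'."""

    mode: str = "any-vs-none"

    def __post_init__(self) -> None:
        if self.mode not in ("any-vs-none", "all-vs-none"):
            raise ValueError(f"unknown differential mode {self.mode!r}")


@dataclass(frozen=True)
class BroadDomain:
    """A merged cross-individual peak span.

    ``contributing`` maps subject id -> tuple of that subject's peak spans
    inside the domain; ``presence`` (set by classification) maps group ->
    number of subjects contributing; ``status`` is one of the module's
    STATUS_* constants once classified.
    """

    interval: GenomicInterval
    contributing: Mapping[str, tuple[GenomicInterval, ...]]
    presence: Mapping[str, int] = field(default_factory=dict)
    status: Optional[str] = None

    @property
    def subjects(self) -> frozenset[str]:
        return frozenset(self.contributing)


def merge_domains(peaks_by_subject: Mapping[str, Sequence[Peak]]) -> list[BroadDomain]:
    """Merge all subjects' peaks into broad domains by >= 1 bp overlap.

    The merge is a transitive single-linkage union: a chain of pairwise
    overlapping peaks (across any subjects) becomes one domain. Book-ended
    peaks (half-open, zero overlap) stay separate. Output is sorted and
    mutually non-overlapping; the per-subject contributing map is complete.
    """
    entries = []
    for subj in sorted(peaks_by_subject):
        for pk in peaks_by_subject[subj]:
            entries.append((pk.interval.chrom, pk.interval.start, pk.interval.end, subj))
    entries.sort()
    domains: list[BroadDomain] = []
    cur: Optional[dict] = None
    for chrom, start, end, subj in entries:
        if cur is not None and chrom == cur["chrom"] and start < cur["end"]:
            cur["end"] = max(cur["end"], end)
            cur["members"].setdefault(subj, []).append(
                GenomicInterval(chrom, start, end)
            )
        else:
            if cur is not None:
                domains.append(_finish(cur))
            cur = {
                "chrom": chrom,
                "start": start,
                "end": end,
                "members": {subj: [GenomicInterval(chrom, start, end)]},
            }
    if cur is not None:
        domains.append(_finish(cur))
    return domains


def _finish(cur: dict) -> BroadDomain:
    contributing = {
        subj: tuple(sorted(ivs, key=lambda iv: (iv.start, iv.end)))
        for subj, ivs in sorted(cur["members"].items())
    }
    return BroadDomain(
        interval=GenomicInterval(cur["chrom"], cur["start"], cur["end"]),
        contributing=contributing,
    )


def classify_domains(
    domains: Sequence[BroadDomain],
    subject_groups: Mapping[str, str],
    rule: DifferentialRule = DifferentialRule(),
    high_group: str = "high",
    low_group: str = "low",
) -> list[BroadDomain]:
    """Assign induced/suppressed/shared status to each domain.

    ``subject_groups`` maps every subject to its exposure group; group
    sizes for the all-vs-none rule are taken from this mapping, so
    subjects with zero peaks still count toward group size.
    """
    for g in (high_group, low_group):
        if g not in set(subject_groups.values()):
            raise ValueError(f"no subjects assigned to group {g!r}")
    group_sizes = {g: sum(1 for v in subject_groups.values() if v == g)
                   for g in set(subject_groups.values())}
    out = []
    for dom in domains:
        presence: dict[str, int] = {high_group: 0, low_group: 0}
        for subj in dom.contributing:
            if subj not in subject_groups:
                raise ValueError(f"subject {subj!r} has no exposure-group assignment")
            g = subject_groups[subj]
            presence[g] = presence.get(g, 0) + 1
        if rule.mode == "any-vs-none":
            hi_present = presence[high_group] >= 1
            lo_present = presence[low_group] >= 1
        else:  # all-vs-none
            hi_present = presence[high_group] == group_sizes[high_group]
            lo_present = presence[low_group] == group_sizes[low_group]
        if hi_present and not lo_present:
            status = STATUS_INDUCED
        elif lo_present and not hi_present:
            status = STATUS_SUPPRESSED
        elif hi_present and lo_present:
            status = STATUS_SHARED
        else:
            # only reachable under all-vs-none: partial presence in group(s)
            status = STATUS_PARTIAL
        out.append(replace(dom, presence=presence, status=status))
    return out


def differential_summary(domains: Sequence[BroadDomain]) -> pd.DataFrame:
    """Counts per (chromosome, status), plus a genome-wide total row."""
    rows = [(d.interval.chrom, d.status) for d in domains]
    df = pd.DataFrame(rows, columns=["chrom", "status"])
    if df.empty:
        return pd.DataFrame(columns=["chrom", "status", "n"])
    summary = df.value_counts(["chrom", "status"]).rename("n").reset_index()
    summary = summary.sort_values(["chrom", "status"]).reset_index(drop=True)
    total = (
        df.value_counts("status").rename("n").reset_index().assign(chrom="ALL")
    )[["chrom", "status", "n"]]
    return pd.concat([summary, total.sort_values("status")], ignore_index=True)
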