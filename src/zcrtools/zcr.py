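"""Zero-coverage-region (ZCR) detection.

A ZCR is a maximal run of reference bases over which a sample has no mapped
reads, after assembly gaps are masked, of at least a minimum length (2 kb by
default). ZCRs are a conservative proxy for homozygous deletions or sequence
too divergent to map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import _intervals
from .io_formats import CoverageTrack, GenomeLayout, write_bed

Interval = tuple[int, int]

DEFAULT_MIN_LENGTH = 2000


@dataclass
class ZCRSet:
    """Per-sample sorted zero-coverage intervals of at least ``min_length``."""

    sample_id: str
    intervals: dict[str, list[Interval]] = field(default_factory=dict)
    min_length: int = DEFAULT_MIN_LENGTH

    def __post_init__(self) -> None:
        for chrom, ivs in self.intervals.items():
            _intervals.validate(ivs)

    def total_bases(self) -> int:
        return sum(_intervals.total_length(ivs) for ivs in self.intervals.values())

    def chrom_intervals(self, chrom: str) -> list[Interval]:
        return self.intervals.get(chrom, [])

    def to_bed(self, path) -> None:
        write_bed(self.intervals, path)


def detect_zcrs(
    track: CoverageTrack,
    layout: GenomeLayout,
    min_length: int = DEFAULT_MIN_LENGTH,
    sample_id: str = "sample",
    *,
    bridge_gaps: bool = False,
) -> ZCRSet:
    """Extract maximal zero-depth, non-gap runs of at least ``min_length``.

    Gap bases are masked. By default a gap terminates a run, so a zero run
    is never called across an assembly gap; with ``bridge_gaps=True`` runs
    separated only by gap bases are merged (the reported interval spans the
    gap, and its qualifying length counts only non-gap zero bases).
    """
    if min_length <= 0:
        raise ValueError("min_length must be positive")
    lengths = layout.lengths
    for chrom in track.chroms():
        if chrom not in lengths:
            raise ValueError(f"chromosome {chrom} in track absent from layout")

    out: dict[str, list[Interval]] = {}
    for chrom, length in layout.chromosomes:
        gaps = layout.chrom_gaps(chrom)
        covered = track.positive_intervals(chrom)
        zero = _intervals.complement(covered, length)
        zero_nongap = _intervals.subtract(zero, gaps)
        if bridge_gaps:
            runs = _bridge_across_gaps(zero_nongap, gaps)
        else:
            runs = [(s, e, e - s) for s, e in zero_nongap]
        kept = [(s, e) for s, e, qual_len in runs if qual_len >= min_length]
        if kept:
            out[chrom] = kept
    return ZCRSet(sample_id=sample_id, intervals=out, min_length=min_length)


def _bridge_across_gaps(
    zero_nongap: list[Interval], gaps: list[Interval]
) -> list[tuple[int, int, int]]:
    """Merge zero runs separated purely by gap bases.

    Returns (start, end, qualifying_length) where qualifying_length counts
    non-gap zero bases only.
    """
    merged_gaps = _intervals.merge(gaps)
    runs: list[tuple[int, int, int]] = []
    for s, e in zero_nongap:
        if runs:
            ps, pe, plen = runs[-1]
            between = _intervals.subtract([(pe, s)], merged_gaps) if pe < s else []
            if pe == s or not between:
                runs[-1] = (ps, e, plen + (e - s))
                continue
        runs.append((s, e, e - s))
    return runs


def genome_zcr_fraction(
    zcrs: ZCRSet, layout: GenomeLayout, denominator: str = "full"
) -> float:
    """Percentage of the genome covered by ZCRs.

    ``denominator="full"`` uses total assembly length (including gaps);
    ``"non_gap"`` uses assembly length minus gap bases.
    """
    if not layout.chromosomes:
        raise ValueError("empty genome layout")
    if denominator not in ("full", "non_gap"):
        raise ValueError(f"unknown denominator {denominator!r}")
    denom = layout.total_length(exclude_gaps=(denominator == "non_gap"))
    return 100.0 * zcrs.total_bases() / denom
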