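"""Soft-clip scanning: find putative ITD breakpoints in an alignment file.

A read that crosses the junction of an internal tandem duplication cannot
be aligned contiguously to the reference, so a soft-clip-capable aligner
anchors the reference-consistent part and clips the rest (CIGAR ``S``).
The clip boundary on the reference is a putative ITD breakpoint.  This
module walks the alignments overlapping the target region and emits one
event per qualifying clipped read end; clips shorter than
``min_clip_len`` (default 10 bp) are discarded as likely alignment noise.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import pysam

from .regions import TargetRegion

__all__ = [
    "ClipSide",
    "AlignedRead",
    "SoftClipEvent",
    "ScanParams",
    "extract_events",
    "scan_reads",
    "scan",
    "fetch_reads",
]

logger = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_QUERY_OPS = frozenset("MIS=X")
_REF_OPS = frozenset("MDN=X")


class ClipSide(Enum):
    """Which end of the read is clipped, in query (5'->3') orientation."""

    FIVE_PRIME = "5p"
    THREE_PRIME = "3p"


def parse_cigar(text: str) -> tuple[tuple[str, int], ...]:
    ops = tuple((m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(text))
    if not ops or "".join(f"{n}{op}" for op, n in ops) != text:
        raise ValueError(f"malformed CIGAR string: {text!r}")
    return ops


@dataclass
class AlignedRead:
    """Minimal view of one aligned read.

    ``cigar`` is a tuple of ``(op, length)`` pairs; ``seq`` is the query
    sequence as stored in SAM (reference-forward orientation).
    """

    name: str
    ref_start: int
    cigar: tuple[tuple[str, int], ...]
    seq: str
    mapq: int = 60
    is_reverse: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False
    is_duplicate: bool = False
    is_unmapped: bool = False

    def __post_init__(self) -> None:
        if not self.is_unmapped:
            qlen = sum(n for op, n in self.cigar if op in _QUERY_OPS)
            if qlen != len(self.seq):
                raise ValueError(
                    f"read {self.name!r}: CIGAR consumes {qlen} query bases "
                    f"but sequence has {len(self.seq)}"
                )
            softclips = [i for i, (op, _) in enumerate(self.cigar) if op == "S"]
            interior = [
                i for i in softclips
                if not self._is_terminal(i)
            ]
            if interior:
                raise ValueError(f"read {self.name!r}: interior soft clip in CIGAR")

    def _is_terminal(self, idx: int) -> bool:
        before = all(op == "H" for op, _ in self.cigar[:idx])
        after = all(op == "H" for op, _ in self.cigar[idx + 1:])
        return before or after

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.cigar if op in _REF_OPS)

    @classmethod
    def from_pysam(cls, aln: pysam.AlignedSegment) -> "AlignedRead":
        # pysam cigartuples use integer opcodes; translate explicitly.
        opmap = "MIDNSHP=XB"
        cigar = tuple((opmap[op], length) for op, length in (aln.cigartuples or ()))
        return cls(
            name=aln.query_name or "",
            ref_start=aln.reference_start,
            cigar=cigar,
            seq=aln.query_sequence or "",
            mapq=aln.mapping_quality,
            is_reverse=aln.is_reverse,
            is_secondary=aln.is_secondary,
            is_supplementary=aln.is_supplementary,
            is_duplicate=aln.is_duplicate,
            is_unmapped=aln.is_unmapped,
        )


@dataclass(frozen=True)
class SoftClipEvent:
    """One clipped read end anchored at a putative ITD breakpoint.

    ``breakpoint`` is the reference coordinate of the clip boundary: for a
    5' clip it equals the anchor start, for a 3' clip the anchor end.
    ``clip_seq`` is the clipped portion of the query, in query orientation.
    """

    read_name: str
    side: ClipSide
    breakpoint: int
    clip_seq: str
    anchor_start: int
    anchor_end: int


@dataclass
class ScanParams:
    min_clip_len: int = 10
    min_mapq: int = 0

    def __post_init__(self) -> None:
        if self.min_clip_len < 1:
            raise ValueError("min_clip_len must be >= 1")
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")


def _passes_filters(read: AlignedRead, params: ScanParams) -> bool:
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_duplicate
        or read.mapq < params.min_mapq
    )


def extract_events(
    read: AlignedRead,
    region: TargetRegion,
    min_clip_len: int = 10,
) -> list[SoftClipEvent]:
    """Emit 0-2 soft-clip events for one read.

    A clipped end qualifies when its clip length is at least
    ``min_clip_len`` and its breakpoint lies inside ``region``.  Reads
    clipped at both ends yield two independent events.
    """
    events: list[SoftClipEvent] = []
    ops = [(op, n) for op, n in read.cigar if op != "H"]
    if not ops:
        return events
    anchor_start = read.ref_start
    anchor_end = read.ref_end

    if ops[0][0] == "S":
        clen = ops[0][1]
        bp = anchor_start
        if clen >= min_clip_len and region.start <= bp < region.end:
            events.append(
                SoftClipEvent(
                    read_name=read.name,
                    side=ClipSide.FIVE_PRIME,
                    breakpoint=bp,
                    clip_seq=read.seq[:clen],
                    anchor_start=anchor_start,
                    anchor_end=anchor_end,
                )
            )
    if len(ops) > 1 and ops[-1][0] == "S":
        clen = ops[-1][1]
        bp = anchor_end
        if clen >= min_clip_len and region.start <= bp < region.end:
            events.append(
                SoftClipEvent(
                    read_name=read.name,
                    side=ClipSide.THREE_PRIME,
                    breakpoint=bp,
                    clip_seq=read.seq[len(read.seq) - clen:],
                    anchor_start=anchor_start,
                    anchor_end=anchor_end,
                )
            )
    return events


def scan_reads(
    reads: Iterable[AlignedRead],
    region: TargetRegion,
    params: ScanParams | None = None,
) -> dict[tuple[int, ClipSide], list[SoftClipEvent]]:
    """Group soft-clip events by ``(breakpoint, side)``.

    Ordering is deterministic: groups sorted by breakpoint then side,
    events within a group by read name.  Malformed records are skipped
    with a logged warning.
    """
    params = params or ScanParams()
    groups: dict[tuple[int, ClipSide], list[SoftClipEvent]] = {}
    for read in reads:
        if not _passes_filters(read, params):
            continue
        try:
            events = extract_events(read, region, params.min_clip_len)
        except ValueError as exc:
            logger.warning("skipping malformed record: %s", exc)
            continue
        for ev in events:
            groups.setdefault((ev.breakpoint, ev.side), []).append(ev)
    ordered: dict[tuple[int, ClipSide], list[SoftClipEvent]] = {}
    for key in sorted(groups, key=lambda k: (k[0], k[1].value)):
        ordered[key] = sorted(groups[key], key=lambda e: e.read_name)
    return ordered


def fetch_reads(
    alignment_path: str,
    region: TargetRegion,
    pad: int = 0,
) -> list[AlignedRead]:
    """Fetch reads overlapping ``region`` (padded by ``pad``) from a BAM/CRAM.

    Requires a coordinate-sorted, indexed file; raises ``ValueError`` with
    remediation advice otherwise.
    """
    mode = "rc" if str(alignment_path).endswith(".cram") else "rb"
    with pysam.AlignmentFile(str(alignment_path), mode) as af:
        if not af.has_index():
            raise ValueError(
                f"{alignment_path} has no index; run 'samtools sort' and "
                "'samtools index' first"
            )
        if region.contig not in af.references:
            raise ValueError(
                f"contig {region.contig!r} absent from {alignment_path}; "
                f"available: {list(af.references)}"
            )
        start = max(0, region.start - pad)
        end = region.end + pad
        return [AlignedRead.from_pysam(a) for a in af.fetch(region.contig, start, end)]


def scan(
    alignment_path: str,
    region: TargetRegion,
    params: ScanParams | None = None,
) -> dict[tuple[int, ClipSide], list[SoftClipEvent]]:
    """Scan an indexed alignment file for soft-clip events in ``region``."""
    return scan_reads(fetch_reads(alignment_path, region), region, params)
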