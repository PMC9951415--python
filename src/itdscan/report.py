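"""Final filtering and emission of ITD calls as TSV and VCF.

When two detection results share a breakpoint position only the one with
the most supporting reads survives (ties: longer duplication, then
lexicographically smaller insertion).  Calls at *different* breakpoints
— including inclusive or overlapping multi-ITD pairs — are all kept.
Output is byte-deterministic for a fixed call set.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

from .regions import ReferenceContig
from .search import ITDCandidate
from .support import ARMethod, ITDCall

__all__ = ["CallSet", "dedup_same_position", "write_tsv", "read_tsv", "write_vcf"]

TSV_COLUMNS = [
    "sample", "contig", "dup_start", "dup_end", "dup_length",
    "insertion_seq", "insertion_length", "alt_reads", "ref_reads",
    "allelic_ratio", "ar_method",
]


def _sort_key(call: ITDCall):
    return (
        call.candidate.dup_start,
        call.dup_length,
        call.insertion_length,
        call.candidate.insertion_seq,
    )


@dataclass
class CallSet:
    """The ordered, deduplicated calls of one sample."""

    sample_name: str
    contig: str
    calls: list[ITDCall] = field(default_factory=list)
    params_fingerprint: str = ""

    def __post_init__(self) -> None:
        self.calls = sorted(self.calls, key=_sort_key)
        keys = [c.candidate.key for c in self.calls]
        if len(keys) != len(set(keys)):
            raise ValueError("call set contains duplicate (interval, insertion) calls")


def dedup_same_position(calls: Sequence[ITDCall]) -> list[ITDCall]:
    """Keep, per breakpoint position, only the best-supported call.

    Idempotent; deterministic tie-breaking by (alt_reads desc, duplication
    length desc, insertion sequence asc).
    """
    by_bp: dict[int, ITDCall] = {}
    for call in calls:
        bp = call.candidate.breakpoint
        cur = by_bp.get(bp)
        if cur is None or _beats(call, cur):
            by_bp[bp] = call
    return sorted(by_bp.values(), key=_sort_key)


def _beats(a: ITDCall, b: ITDCall) -> bool:
    ka = (a.alt_reads, a.dup_length)
    kb = (b.alt_reads, b.dup_length)
    if ka != kb:
        return ka > kb
    return a.candidate.insertion_seq < b.candidate.insertion_seq


def write_tsv(cs: CallSet, sink) -> None:
    """Write the call set as a TSV table (header + one row per call)."""
    own = isinstance(sink, (str, bytes))
    handle = open(sink, "w", newline="") if own else sink
    try:
        handle.write("\t".join(TSV_COLUMNS) + "\n")
        for call in cs.calls:
            c = call.candidate
            row = [
                cs.sample_name,
                cs.contig,
                str(c.dup_start + 1),  # 1-based inclusive at the I/O boundary
                str(c.dup_end),
                str(c.dup_end - c.dup_start),
                c.insertion_seq or ".",
                str(len(c.insertion_seq)),
                str(call.alt_reads),
                str(call.ref_reads),
                f"{call.allelic_ratio:.6f}",
                call.ar_method.value,
            ]
            handle.write("\t".join(row) + "\n")
    finally:
        if own:
            handle.close()


def read_tsv(source) -> CallSet:
    """Read a call-set TSV written by :func:`write_tsv` (round-trip aid)."""
    own = isinstance(source, (str, bytes))
    handle = open(source) if own else source
    try:
        header = handle.readline().rstrip("\n").split("\t")
        if header != TSV_COLUMNS:
            raise ValueError(f"unexpected TSV header: {header}")
        sample = contig = ""
        calls = []
        for line in handle:
            f = line.rstrip("\n").split("\t")
            sample, contig = f[0], f[1]
            ins = "" if f[5] == "." else f[5]
            dup_start = int(f[2]) - 1
            dup_end = int(f[3])
            cand = ITDCandidate(
                dup_start=dup_start, dup_end=dup_end,
                insertion_seq=ins, breakpoint=dup_end,
            )
            calls.append(
                ITDCall(
                    candidate=cand,
                    alt_reads=int(f[7]),
                    ref_reads=int(f[8]),
                    allelic_ratio=float(f[9]),
                    ar_method=ARMethod(f[10]),
                )
            )
        return CallSet(sample_name=sample, contig=contig, calls=calls)
    finally:
        if own:
            handle.close()


def write_vcf(cs: CallSet, ref: ReferenceContig, sink) -> None:
    """Write calls as VCF 4.2 insertion-style records.

    Each ITD is anchored at the base before the duplication-unit start:
    ALT = anchor + unit + insertion, which spells out the tandem-duplicated
    allele explicitly.  INFO carries the duplication geometry, support
    counts and allelic ratio.
    """
    own = isinstance(sink, (str, bytes))
    handle = open(sink, "w", newline="") if own else sink
    try:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write(f"##contig=<ID={cs.contig},length={len(ref)}>\n")
        handle.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">\n')
        handle.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Total inserted length (duplication + insertion)">\n')
        handle.write('##INFO=<ID=DUPSTART,Number=1,Type=Integer,Description="Duplicated unit start (1-based inclusive)">\n')
        handle.write('##INFO=<ID=DUPEND,Number=1,Type=Integer,Description="Duplicated unit end (1-based inclusive)">\n')
        handle.write('##INFO=<ID=INSLEN,Number=1,Type=Integer,Description="Inserted bases between the duplicated copies">\n')
        handle.write('##INFO=<ID=AR,Number=1,Type=Float,Description="Allelic ratio (ITD reads / wild-type reads)">\n')
        handle.write('##INFO=<ID=AltReads,Number=1,Type=Integer,Description="ITD-supporting reads">\n')
        handle.write('##INFO=<ID=RefReads,Number=1,Type=Integer,Description="Wild-type reads">\n')
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        records = []
        for call in cs.calls:
            c = call.candidate
            unit = ref.fetch(c.dup_start, c.dup_end)
            if c.dup_start >= 1:
                pos0 = c.dup_start - 1
                anchor = ref.fetch(pos0, pos0 + 1)
                alt = anchor + unit + c.insertion_seq
            else:
                # junction at contig start: anchor on the first base instead
                pos0 = 0
                anchor = ref.fetch(0, 1)
                alt = unit + c.insertion_seq + anchor
            info = (
                f"SVTYPE=DUP;SVLEN={len(unit) + len(c.insertion_seq)};"
                f"DUPSTART={c.dup_start + 1};DUPEND={c.dup_end};"
                f"INSLEN={len(c.insertion_seq)};AR={call.allelic_ratio:.6f};"
                f"AltReads={call.alt_reads};RefReads={call.ref_reads}"
            )
            records.append((pos0 + 1, alt, f"{cs.contig}\t{pos0 + 1}\t.\t{anchor}\t{alt}\t.\tPASS\t{info}\n"))
        for _, _, line in sorted(records):
            handle.write(line)
    finally:
        if own:
            handle.close()
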