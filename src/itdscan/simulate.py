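"""Synthetic ITD samples with ground truth, for desk-scale validation.

The simulator emulates the inputs the caller consumes in practice:
a reference contig and short reads from a mixture of haplotypes —
a wild-type haplotype plus one haplotype per ITD (short reads cannot
phase ITDs, so each duplication lives on its own haplotype and a sample
is a weighted mixture).  Reads crossing a duplication junction are
rendered with the soft-clipped CIGAR a soft-clip-capable aligner would
assign, so the alignment file is ready for the caller without invoking
an external aligner; a FASTQ escape hatch supports real-aligner
integration when wanted.

The target allelic ratio is operational: haplotype weights are chosen so
that the *expected* junction-spanning ITD/wild-type read ratio equals
``target_ar`` (weights ``w_i = a_i / (1 + sum(a))`` against
``w_ref = 1 / (1 + sum(a))``), which is well defined for any
``a >= 0`` including ratios above 1.

Defaults mirror a targeted-panel protocol: 150 bp paired-end reads at
200-fold coverage with a 0.001 per-base substitution error rate (100 bp
reads reproduce an exome-style protocol).  Everything is deterministic
under a fixed seed, down to the output bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pysam

from .regions import ReferenceContig
from .softclip import AlignedRead

__all__ = [
    "ITDSpec",
    "SimSpec",
    "ReadTruth",
    "ITDTruth",
    "TruthManifest",
    "SimResult",
    "make_reference",
    "build_itd_allele_truth",
    "simulate_reads",
    "write_sam",
    "write_bam",
    "write_fastq",
    "score_against_truth",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ITDSpec:
    """Ground-truth description of one duplication."""

    dup_start: int
    dup_length: int
    insertion_seq: str = ""
    target_ar: float = 0.5

    def __post_init__(self) -> None:
        if self.dup_length < 3:
            raise ValueError("dup_length must be >= 3")
        if self.dup_start < 0:
            raise ValueError("dup_start must be >= 0")
        if self.target_ar < 0:
            raise ValueError("target_ar must be >= 0")

    @property
    def dup_end(self) -> int:
        return self.dup_start + self.dup_length


@dataclass
class SimSpec:
    """Full description of a simulated sample."""

    ref_length: int = 5000
    itds: list[ITDSpec] = field(default_factory=list)
    coverage: float = 200.0
    read_length: int = 150
    paired: bool = True
    fragment_mean: int = 350
    fragment_sd: int = 35
    error_rate: float = 0.001
    seed: int = 0
    contig_name: str = "sim1"

    def __post_init__(self) -> None:
        if self.ref_length < 1000:
            raise ValueError("ref_length must be >= 1000")
        for itd in self.itds:
            if itd.dup_end > self.ref_length:
                raise ValueError(
                    f"ITD [{itd.dup_start}, {itd.dup_end}) outside reference"
                )
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")


@dataclass(frozen=True)
class ITDTruth:
    """Per-ITD truth: allele structure and junction coordinates."""

    dup_start: int
    dup_end: int
    insertion_seq: str
    target_ar: float
    allele_junction_start: int  # allele coord of first-copy end
    allele_junction_end: int    # allele coord of second-copy start
    allele_length: int


@dataclass(frozen=True)
class ReadTruth:
    name: str
    mate: int            # 1 or 2 (0 for single-end)
    haplotype: int       # 0 = wild type, i >= 1 = ITD i
    allele_pos: int      # origin position on the source allele
    crosses_junction: bool


@dataclass
class TruthManifest:
    contig_name: str
    ref_length: int
    itds: list[ITDTruth]
    reads: list[ReadTruth]
    warnings: list[str] = field(default_factory=list)

    def junction_read_counts(self) -> list[int]:
        counts = [0] * len(self.itds)
        for r in self.reads:
            if r.haplotype >= 1 and r.crosses_junction:
                counts[r.haplotype - 1] += 1
        return counts

    def to_json(self, sink) -> None:
        own = isinstance(sink, (str, bytes))
        handle = open(sink, "w") if own else sink
        try:
            json.dump(asdict(self), handle, indent=1, sort_keys=True)
        finally:
            if own:
                handle.close()


@dataclass
class SimResult:
    spec: SimSpec
    reference: ReferenceContig
    reads: list[AlignedRead]
    manifest: TruthManifest


def _has_tandem_repeat(arr: np.ndarray, lo: int, hi: int, k: int = 10) -> bool:
    """True if any exact k-mer tandem (seq[i:i+k] == seq[i+k:i+2k]) starts in [lo, hi)."""
    if len(arr) < 2 * k:
        return False
    eq = arr[:-k] == arr[k:]
    run = np.convolve(eq[lo: min(hi, len(eq))].astype(np.int32), np.ones(k, np.int32), "valid")
    return bool(run.size and (run == k).any())


def make_reference(
    length: int,
    seed: int,
    contig_name: str = "sim1",
    zone: tuple[int, int] | None = None,
) -> ReferenceContig:
    """Random uppercase contig with a repeat-free ITD placement zone.

    Rejection-samples until the zone (by default the contig minus a
    600 bp margin on each side) contains no exact >= 10 bp tandem
    repeat, so simulated junctions are unambiguous.
    """
    if length < 1000:
        raise ValueError("length must be >= 1000")
    margin = min(600, length // 3)
    lo, hi = zone if zone is not None else (margin, length - margin)
    rng = np.random.default_rng(seed)
    while True:
        arr = _BASES[rng.integers(0, 4, size=length)]
        if not _has_tandem_repeat(arr, lo, hi):
            return ReferenceContig(contig_name, arr.tobytes().decode("ascii"))


def random_insertion(
    ref: ReferenceContig,
    dup_start: int,
    dup_end: int,
    length: int,
    seed: int,
) -> str:
    """Novel inserted bases that are separable from the duplication.

    If an inserted base equals the reference base that continues the
    duplicated unit on either side, parses that extend the unit into the
    insertion describe the *identical* allele sequence — no read can
    distinguish them.  To emulate a sample whose duplication and
    insertion sizes are well defined (and reportable separately), every
    generated base differs from both the downstream continuation
    ``ref[dup_end + i]`` and the upstream continuation
    ``ref[dup_start - length + i]``.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(length):
        down = ref.sequence[dup_end + i] if dup_end + i < len(ref) else ""
        up_idx = dup_start - length + i
        up = ref.sequence[up_idx] if up_idx >= 0 else ""
        choices = [b for b in "ACGT" if b != down and b != up]
        out.append(choices[int(rng.integers(0, len(choices)))])
    return "".join(out)


def build_itd_allele_truth(
    ref: ReferenceContig, itd: ITDSpec
) -> tuple[str, ITDTruth]:
    """ITD haplotype sequence and its junction coordinates.

    The allele is the reference with the unit duplicated and the
    insertion placed between the copies:
    ``ref[:e] + ins + ref[s:e] + ref[e:]``.
    """
    s, e = itd.dup_start, itd.dup_end
    if e > len(ref):
        raise ValueError(f"ITD [{s}, {e}) outside contig of length {len(ref)}")
    ins = itd.insertion_seq.upper()
    allele = ref.sequence[:e] + ins + ref.sequence[s:e] + ref.sequence[e:]
    truth = ITDTruth(
        dup_start=s,
        dup_end=e,
        insertion_seq=ins,
        target_ar=itd.target_ar,
        allele_junction_start=e,
        allele_junction_end=e + len(ins),
        allele_length=len(allele),
    )
    return allele, truth


def _hap_weights(itds: Sequence[ITDSpec]) -> np.ndarray:
    total = sum(i.target_ar for i in itds)
    w_ref = 1.0 / (1.0 + total)
    return np.array([w_ref] + [i.target_ar * w_ref for i in itds])


def _aligned_read_from_allele(
    name: str,
    seq: str,
    pos: int,
    truth: ITDTruth | None,
    is_reverse: bool,
) -> tuple[AlignedRead, bool]:
    """Render one allele-origin read as its reference alignment.

    Splits the read at the inserted block, anchors the longer
    reference-contiguous run as M and soft-clips the rest — the
    placement a soft-clip-capable aligner converges to.  Returns the
    read and whether it crosses the duplication junction.
    """
    L = len(seq)
    if truth is None:
        return (
            AlignedRead(name=name, ref_start=pos, cigar=(("M", L),),
                        seq=seq, is_reverse=is_reverse),
            False,
        )
    e = truth.allele_junction_start
    il = truth.allele_junction_end - truth.allele_junction_start
    dl = truth.dup_end - truth.dup_start
    end = pos + L
    len_a = max(0, min(end, e) - pos)                       # bases before the junction
    ins_lo, ins_hi = e, e + il
    len_ins = max(0, min(end, ins_hi) - max(pos, ins_lo))
    len_b = L - len_a - len_ins                              # bases from copy2 onward
    crosses = (pos < ins_hi and end > ins_lo) if il else (pos < e < end)

    if len_a == 0 and len_b == 0:
        read = AlignedRead(name=name, ref_start=0, cigar=(), seq=seq,
                           is_reverse=is_reverse, is_unmapped=True)
        return read, crosses
    if len_a >= len_b:
        cigar = [("M", len_a)]
        if L - len_a:
            cigar.append(("S", L - len_a))
        read = AlignedRead(name=name, ref_start=pos,
                           cigar=tuple(cigar), seq=seq, is_reverse=is_reverse)
    else:
        b_start_allele = max(pos, ins_hi)
        if b_start_allele < ins_hi + dl:  # starts inside copy2
            ref_pos = truth.dup_start + (b_start_allele - ins_hi)
        else:
            ref_pos = b_start_allele - il - dl
        cigar = []
        if L - len_b:
            cigar.append(("S", L - len_b))
        cigar.append(("M", len_b))
        read = AlignedRead(name=name, ref_start=ref_pos,
                           cigar=tuple(cigar), seq=seq, is_reverse=is_reverse)
    return read, crosses


def _apply_errors(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode("ascii")


def simulate_reads(spec: SimSpec) -> SimResult:
    """Draw reads from the haplotype mixture; fully seeded and reproducible."""
    rng = np.random.default_rng(spec.seed)
    ref = make_reference(spec.ref_length, spec.seed, spec.contig_name)
    alleles: list[str] = [ref.sequence]
    truths: list[ITDTruth | None] = [None]
    itd_truths: list[ITDTruth] = []
    for itd in spec.itds:
        allele, truth = build_itd_allele_truth(ref, itd)
        alleles.append(allele)
        truths.append(truth)
        itd_truths.append(truth)
    weights = _hap_weights(spec.itds)

    reads_per_frag = 2 if spec.paired else 1
    n_frags = max(1, round(spec.coverage * spec.ref_length
                           / (spec.read_length * reads_per_frag)))
    L = spec.read_length
    reads: list[AlignedRead] = []
    read_truths: list[ReadTruth] = []

    for i in range(n_frags):
        hap = int(rng.choice(len(weights), p=weights))
        allele = alleles[hap]
        truth = truths[hap]
        if spec.paired:
            flen = int(np.clip(round(rng.normal(spec.fragment_mean, spec.fragment_sd)),
                               L, len(allele)))
            start = int(rng.integers(0, len(allele) - flen + 1))
            mate_pos = [start, start + flen - L]
            for mate, pos in enumerate(mate_pos, start=1):
                seq = _apply_errors(allele[pos: pos + L], rng, spec.error_rate)
                read, crosses = _aligned_read_from_allele(
                    f"frag{i:06d}", seq, pos, truth, is_reverse=(mate == 2),
                )
                reads.append(read)
                read_truths.append(
                    ReadTruth(read.name, mate, hap, pos, crosses)
                )
        else:
            pos = int(rng.integers(0, len(allele) - L + 1))
            seq = _apply_errors(allele[pos: pos + L], rng, spec.error_rate)
            read, crosses = _aligned_read_from_allele(
                f"frag{i:06d}", seq, pos, truth, is_reverse=False,
            )
            reads.append(read)
            read_truths.append(ReadTruth(read.name, 0, hap, pos, crosses))

    manifest = TruthManifest(
        contig_name=spec.contig_name,
        ref_length=spec.ref_length,
        itds=itd_truths,
        reads=read_truths,
    )
    for idx, n in enumerate(manifest.junction_read_counts()):
        if spec.itds and spec.itds[idx].target_ar > 0 and n == 0:
            manifest.warnings.append(
                f"ITD {idx}: coverage too low, no junction-spanning reads placed"
            )
    return SimResult(spec=spec, reference=ref, reads=reads, manifest=manifest)


def _sam_records(result: SimResult):
    """Deterministically ordered (coordinate-sorted) pysam records."""
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": result.reference.name, "LN": len(result.reference)}],
    })
    mapped = [r for r in result.reads if not r.is_unmapped]
    unmapped = [r for r in result.reads if r.is_unmapped]
    mapped.sort(key=lambda r: (r.ref_start, r.name, r.is_reverse))
    records = []
    for r in mapped + unmapped:
        a = pysam.AlignedSegment(header)
        a.query_name = r.name
        a.query_sequence = r.seq
        a.query_qualities = pysam.qualitystring_to_array("I" * len(r.seq))
        a.mapping_quality = 60 if not r.is_unmapped else 0
        if r.is_unmapped:
            a.is_unmapped = True
            a.reference_id = -1
            a.reference_start = -1
        else:
            a.reference_id = 0
            a.reference_start = r.ref_start
            a.cigarstring = "".join(f"{n}{op}" for op, n in r.cigar)
        a.is_reverse = r.is_reverse
        a.is_paired = result.spec.paired
        if result.spec.paired:
            a.is_read2 = r.is_reverse
            a.is_read1 = not r.is_reverse
            a.mate_is_reverse = not r.is_reverse
        records.append(a)
    return header, records


def write_sam(result: SimResult, path: str) -> None:
    """Coordinate-sorted plain-text SAM."""
    header, records = _sam_records(result)
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for rec in records:
            out.write(rec)


def write_bam(result: SimResult, path: str) -> None:
    """Coordinate-sorted, indexed BAM ready for regional fetch."""
    header, records = _sam_records(result)
    with pysam.AlignmentFile(path, "wb", header=header) as out:
        for rec in records:
            out.write(rec)
    pysam.index(str(path))


_COMP = str.maketrans("ACGTN", "TGCAN")


def write_fastq(result: SimResult, prefix: str) -> list[str]:
    """Paired (``_1.fq``/``_2.fq``) or single (``.fq``) FASTQ files.

    Reverse-strand mates are written reverse-complemented, as a
    sequencer would deliver them.
    """
    if result.spec.paired:
        paths = [f"{prefix}_1.fq", f"{prefix}_2.fq"]
        handles = [open(p, "w") for p in paths]
        try:
            for read in result.reads:
                seq = (read.seq.translate(_COMP)[::-1]
                       if read.is_reverse else read.seq)
                h = handles[1] if read.is_reverse else handles[0]
                h.write(f"@{read.name}\n{seq}\n+\n{'I' * len(seq)}\n")
        finally:
            for h in handles:
                h.close()
        return paths
    path = f"{prefix}.fq"
    with open(path, "w") as h:
        for read in result.reads:
            h.write(f"@{read.name}\n{read.seq}\n+\n{'I' * len(read.seq)}\n")
    return [path]


def score_against_truth(callset, manifest: TruthManifest, max_dist: int = 5) -> dict:
    """Score a call set against the simulation truth.

    A call matches a truth ITD when both junction coordinates agree
    within ``max_dist`` bp.  Reports the detected fraction, per-ITD
    duplication-length error, exact insertion recovery, and the absolute
    percentage error of the allelic ratio where truth AR > 0.
    """
    calls = list(callset.calls)
    per_itd = []
    used: set[int] = set()
    for truth in manifest.itds:
        best = None
        for idx, call in enumerate(calls):
            if idx in used:
                continue
            c = call.candidate
            dist = max(abs(c.dup_start - truth.dup_start),
                       abs(c.dup_end - truth.dup_end))
            if dist <= max_dist and (best is None or dist < best[0]):
                best = (dist, idx)
        if best is None:
            per_itd.append({
                "detected": False, "dup_length_error": None,
                "insertion_exact": False, "ar_ape": None,
            })
            continue
        used.add(best[1])
        call = calls[best[1]]
        ape = None
        if truth.target_ar > 0:
            ape = abs(call.allelic_ratio - truth.target_ar) / truth.target_ar
        per_itd.append({
            "detected": True,
            "dup_length_error": call.dup_length - (truth.dup_end - truth.dup_start),
            "insertion_exact": call.candidate.insertion_seq == truth.insertion_seq,
            "ar_ape": ape,
        })
    detected = [p for p in per_itd if p["detected"]]
    apes = [p["ar_ape"] for p in detected if p["ar_ape"] is not None]
    return {
        "n_truth": len(manifest.itds),
        "n_calls": len(calls),
        "detected_fraction": (len(detected) / len(manifest.itds)
                              if manifest.itds else float("nan")),
        "per_itd": per_itd,
        "mean_ar_ape": float(np.mean(apes)) if apes else None,
        "false_calls": len(calls) - len(used),
    }
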