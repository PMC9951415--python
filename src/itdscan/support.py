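"""Supporting-read counting and allelic-ratio estimation.

For each duplication candidate a predicted ITD allele is built — the
reference with one extra copy of the duplicated unit and any inserted
bases placed between the two copies — and every read near the locus is
assigned to the ITD allele or the wild-type allele:

* breakpoint counting (the primary estimator): a read supports the ITD
  when its best gap-free placement on the predicted allele spans the
  duplication junction with at least ``junction_overhang`` bases on each
  side and fits strictly better than any reference placement spanning
  the reference breakpoint; it supports the wild type in the symmetric
  case.  Reads whose sequence is genuinely consistent with both alleles
  (context shorter than the duplication unit) are left unassigned rather
  than miscounted.

* Smith-Waterman re-estimation: candidates whose first-pass allelic
  ratio exceeds ``ar_reestimate_threshold`` (default 1) are re-counted by
  locally aligning every read to the predicted allele and the reference;
  a read is assigned to the ITD allele when its score deficit from a
  perfect self-alignment is below ``max_score_diff`` and fewer than
  ``max_end_nonoverlap`` of its bases are left unaligned at each end,
  with the alignment spanning the junction.  Gapped local alignment is
  more permissive than gap-free placement for reads degraded by errors
  or co-occurring indels, so the recount is more robust exactly where
  the first-pass denominator is smallest.

The allelic ratio itself is ITD reads / wild-type reads — the
fragment-analysis convention (ITD peak height over wild-type peak
height), not a variant allele fraction — so values above 1 are
legitimate.  The ratio of a sample with multiple ITDs is the sum of the
per-ITD ratios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

from Bio import Align

from .regions import ReferenceContig
from .search import ITDCandidate, placement_mismatch_counts
from .softclip import AlignedRead

__all__ = [
    "ARParams",
    "ARMethod",
    "AlleleModel",
    "ITDCall",
    "build_allele",
    "count_support",
    "apply_support_filter",
    "estimate_ar",
    "reestimate_ar_high",
    "sample_ar",
]

logger = logging.getLogger(__name__)


class ARMethod(Enum):
    BREAKPOINT_COUNT = "breakpoint_count"
    SW_REALIGNED = "sw_realigned"


@dataclass
class ARParams:
    """Thresholds for support counting and AR estimation.

    min_support
        Minimum ITD-supporting reads required to emit a call (3).
    ar_reestimate_threshold
        First-pass AR above which the Smith-Waterman re-estimation runs.
    max_score_diff / max_end_nonoverlap
        Read-assignment thresholds of the re-estimation pass (15 score
        units; 16 bp).
    sw_* : Smith-Waterman scores (+2/-2, gap open -3, extend -1).
    junction_overhang
        Required aligned bases on each side of the junction when counting
        breakpoint support (mirrors the 10 bp clip minimum).
    count_mismatch_frac
        Mismatch cap, as a fraction of read length, for a gap-free
        placement to count at all.
    allele_flank
        Reference flank added on each side of the predicted allele.
    """

    min_support: int = 3
    ar_reestimate_threshold: float = 1.0
    max_score_diff: int = 15
    max_end_nonoverlap: int = 16
    sw_match: int = 2
    sw_mismatch: int = -2
    sw_gap_open: int = -3
    sw_gap_extend: int = -1
    junction_overhang: int = 10
    count_mismatch_frac: float = 0.10
    allele_flank: int = 200

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        for name in ("ar_reestimate_threshold", "max_score_diff",
                     "max_end_nonoverlap", "junction_overhang", "allele_flank"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def aligner(self) -> Align.PairwiseAligner:
        al = Align.PairwiseAligner()
        al.mode = "local"
        al.match_score = self.sw_match
        al.mismatch_score = self.sw_mismatch
        al.open_gap_score = self.sw_gap_open
        al.extend_gap_score = self.sw_gap_extend
        return al


@dataclass(frozen=True)
class AlleleModel:
    """Predicted ITD allele: flank + unit + insertion + unit + flank.

    ``seq`` is the predicted allele subsequence; ``offset`` is the contig
    coordinate of its first base.  ``junction_start``/``junction_end``
    delimit, in ``seq`` coordinates, the gap between the first copy's end
    and the second copy's start (the inserted bases; zero-width when the
    duplication is exact).
    """

    seq: str
    offset: int
    junction_start: int
    junction_end: int
    breakpoint: int  # contig coordinate of the junction (duplication-unit end)


@dataclass(frozen=True)
class ITDCall:
    candidate: ITDCandidate
    alt_reads: int
    ref_reads: int
    allelic_ratio: float
    ar_method: ARMethod = ARMethod.BREAKPOINT_COUNT
    no_wildtype: bool = False

    @property
    def dup_length(self) -> int:
        return self.candidate.dup_length

    @property
    def insertion_length(self) -> int:
        return self.candidate.insertion_length


def build_allele(
    candidate: ITDCandidate,
    ref: ReferenceContig,
    flank: int = 200,
) -> AlleleModel:
    """Build the predicted ITD allele around the candidate's junction.

    The allele is the reference with one extra copy of the duplicated
    unit, the insertion placed between the copies.  Flanks that would
    run past the contig are clamped (and logged).
    """
    s, e = candidate.dup_start, candidate.dup_end
    left_start = max(0, s - flank)
    right_end = min(len(ref), e + flank)
    if left_start != s - flank or right_end != e + flank:
        logger.debug(
            "allele flank clamped to contig bounds for candidate at [%d, %d)", s, e
        )
    left = ref.fetch(left_start, e)           # ...flank + first copy (ends at e)
    unit = ref.fetch(s, e)
    right = unit + ref.fetch(e, right_end)    # second copy + flank
    junction_start = e - left_start
    return AlleleModel(
        seq=left + candidate.insertion_seq + right,
        offset=left_start,
        junction_start=junction_start,
        junction_end=junction_start + len(candidate.insertion_seq),
        breakpoint=e,
    )


def _best_spanning_placement(
    read_seq: str,
    target: str,
    span_start: int,
    span_end: int,
) -> int | None:
    """Fewest mismatches over gap-free placements covering [span_start, span_end]."""
    counts = placement_mismatch_counts(read_seq, target)
    if counts.size == 0:
        return None
    # placement at offset o covers [o, o + len(read)); need o <= span_start
    # and o + len(read) >= span_end
    lo = max(0, span_end - len(read_seq))
    hi = min(counts.size - 1, span_start)
    if hi < lo:
        return None
    return int(counts[lo: hi + 1].min())


def count_support(
    candidate: ITDCandidate,
    reads: Sequence[AlignedRead],
    allele: AlleleModel,
    ref: ReferenceContig,
    params: ARParams | None = None,
) -> tuple[int, int]:
    """Count ITD-supporting and wild-type reads for one candidate.

    Each read counts at most once; reads consistent with both alleles or
    with neither are not counted.
    """
    params = params or ARParams()
    oh = params.junction_overhang
    e = allele.breakpoint
    # reference window around the breakpoint, wide enough for any placement
    pad = max(len(r.seq) for r in reads) if reads else 0
    ref_lo = max(0, e - pad - oh)
    ref_hi = min(len(ref), e + pad + oh)
    ref_window = ref.fetch(ref_lo, ref_hi)
    alt = wt = 0
    inf = math.inf
    for read in reads:
        if read.is_secondary or read.is_supplementary or read.is_duplicate:
            continue
        seq = read.seq
        if len(seq) < 2 * oh:
            continue
        cap = int(params.count_mismatch_frac * len(seq))
        m_alt = _best_spanning_placement(
            seq, allele.seq,
            allele.junction_start - oh,
            allele.junction_end + oh,
        )
        m_ref = _best_spanning_placement(
            seq, ref_window,
            (e - ref_lo) - oh,
            (e - ref_lo) + oh,
        )
        a = m_alt if m_alt is not None and m_alt <= cap else inf
        r = m_ref if m_ref is not None and m_ref <= cap else inf
        if a < r:
            alt += 1
        elif r < a:
            # a read that places strictly better somewhere on the ITD
            # allele (e.g. a junction read clipped short of the overhang)
            # is not wild-type evidence, even if it straddles the
            # reference breakpoint with tolerable mismatches
            any_counts = placement_mismatch_counts(seq, allele.seq)
            m_any = int(any_counts.min()) if any_counts.size else r
            if r <= m_any:
                wt += 1
    return alt, wt


def estimate_ar(alt_reads: int, ref_reads: int) -> tuple[float, bool]:
    """Allelic ratio alt/ref; with no wild-type reads, alt/1 plus a flag."""
    if alt_reads == 0:
        return 0.0, ref_reads == 0
    if ref_reads == 0:
        return float(alt_reads), True
    return alt_reads / ref_reads, False


def apply_support_filter(
    calls: Sequence[ITDCall],
    params: ARParams | None = None,
) -> list[ITDCall]:
    """Drop calls below the minimum supporting-read count (default 3)."""
    params = params or ARParams()
    kept = []
    for call in calls:
        if call.alt_reads >= params.min_support:
            kept.append(call)
        else:
            logger.info(
                "dropping candidate at [%d, %d): %d supporting reads < %d",
                call.candidate.dup_start, call.candidate.dup_end,
                call.alt_reads, params.min_support,
            )
    return kept


def _sw_fits(
    aligner: Align.PairwiseAligner,
    seq: str,
    target: str,
    junction: tuple[int, int] | None,
    params: ARParams,
) -> tuple[bool, float]:
    """Assess one read against one allele under the step-4 thresholds.

    The local alignment must reach near-perfect score (deficit below
    ``max_score_diff``), leave fewer than ``max_end_nonoverlap`` read
    bases unaligned at each end, and — when a junction interval is given
    — extend at least ``junction_overhang`` bases beyond the junction on
    both sides, mirroring the breakpoint-count requirement so the two
    estimators count comparable read populations.
    """
    if not seq:
        return False, 0.0
    alns = aligner.align(seq, target)
    if len(alns) == 0:
        return False, 0.0
    aln = alns[0]
    score = aln.score
    perfect = params.sw_match * len(seq)
    if perfect - score >= params.max_score_diff:
        return False, score
    qblocks, tblocks = aln.aligned
    q_start, q_end = int(qblocks[0][0]), int(qblocks[-1][1])
    if q_start >= params.max_end_nonoverlap:
        return False, score
    if len(seq) - q_end >= params.max_end_nonoverlap:
        return False, score
    if junction is not None:
        t_start, t_end = int(tblocks[0][0]), int(tblocks[-1][1])
        j_lo, j_hi = junction
        oh = params.junction_overhang
        if t_start > j_lo - oh or t_end < j_hi + oh:
            return False, score
    return True, score


def reestimate_ar_high(
    call: ITDCall,
    reads: Sequence[AlignedRead],
    allele: AlleleModel,
    ref: ReferenceContig,
    params: ARParams | None = None,
) -> ITDCall:
    """Smith-Waterman re-estimation for high-frequency candidates.

    A no-op (the call is returned unchanged) when the first-pass AR does
    not exceed ``ar_reestimate_threshold``.
    """
    params = params or ARParams()
    if call.allelic_ratio <= params.ar_reestimate_threshold:
        return call
    aligner = params.aligner()
    e = allele.breakpoint
    pad = max((len(r.seq) for r in reads), default=0)
    ref_lo = max(0, e - pad - params.junction_overhang)
    ref_hi = min(len(ref), e + pad + params.junction_overhang)
    ref_window = ref.fetch(ref_lo, ref_hi)
    ref_junction = (e - ref_lo, e - ref_lo)
    alt = wt = 0
    for read in reads:
        if read.is_secondary or read.is_supplementary or read.is_duplicate:
            continue
        fits_alt, s_alt = _sw_fits(
            aligner, read.seq, allele.seq,
            (allele.junction_start, allele.junction_end), params,
        )
        fits_ref, s_ref = _sw_fits(
            aligner, read.seq, ref_window, ref_junction, params,
        )
        # a read aligning strictly better to one allele can only support
        # that allele; equal scores are uninformative and count nowhere
        if s_alt > s_ref:
            if fits_alt:
                alt += 1
        elif s_ref > s_alt:
            if fits_ref:
                wt += 1
    ratio, no_wt = estimate_ar(alt, wt)
    return replace(
        call,
        alt_reads=alt,
        ref_reads=wt,
        allelic_ratio=ratio,
        ar_method=ARMethod.SW_REALIGNED,
        no_wildtype=no_wt,
    )


def sample_ar(calls: Sequence[ITDCall]) -> float:
    """Sample-level allelic ratio: the sum over the sample's ITD calls."""
    return float(sum(call.allelic_ratio for call in calls))
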