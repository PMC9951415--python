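"""Duplication search: locate clipped sequences in the flanking reference.

For each soft-clip event the clipped sequence is searched in the reference
window on the appropriate side of the breakpoint.  The search model is a
gap-free, full-length placement scan that tolerates substitutions —
tandem duplications are copies of nearby reference sequence, possibly
degraded by PCR artifacts or co-occurring point variants, so the best
placement is the one with the fewest mismatching bases.  A placement is
accepted when its mismatch count is at most
``floor(max_mismatch_frac * length)``.

ITDs frequently carry novel inserted bases *between* the two copies of
the duplicated unit.  Those bases sit at the junction end of the clip
(the end abutting the aligned anchor), so the full clip fails to match;
the search therefore iteratively trims one base at a time from the
junction-proximal end and retries, down to ``min_search_len`` (10 bp).
Among trim depths the winning parse is the one maximising the placement
score (matched bases score +1, mismatches -1, trimmed bases 0), ties
going to the smallest trim — so a genuine insertion (which mismatches
the reference continuation) is split out rather than absorbed as
mismatches, while a clip that merely carries a sequencing error keeps
the longest duplication.  Crucially the winning parse depends only on
the junction sequence, not on how long each read's clip happens to be,
so every read crossing one junction votes for the same candidate.
Trimmed-off bases are reported as the insertion sequence.

Directionality follows the ITD read geometry: a 5' clip is anchored at
the duplication-unit start and its clip matches reference *downstream*
(ending at the unit end); a 3' clip is anchored at the unit end and its
clip matches *upstream* (starting at the unit start).  The duplicated
unit is the reference interval between the breakpoint and the far end of
the match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .regions import ReferenceContig
from .softclip import ClipSide, SoftClipEvent

__all__ = [
    "SearchParams",
    "DuplicationMatch",
    "ITDCandidate",
    "placement_mismatch_counts",
    "dp_similarity_search",
    "trim_and_search",
    "derive_duplication",
    "collect_candidates",
]

logger = logging.getLogger(__name__)

_N = ord("N")


@dataclass
class SearchParams:
    """Tunables for the duplication search.

    search_window
        Maximum distance (bp) between breakpoint and the far end of the
        duplicated unit; equivalently the maximum duplication length.
    min_search_len
        Smallest clip remainder still searched while trimming.
    max_mismatch_frac
        Mismatch tolerance as a fraction of the placed length.
    match_score / mismatch_penalty
        Scoring of the placement DP (+1/-1 by default).  With gap-free
        full-length placements, maximising score is identical to
        minimising mismatches whenever match_score > 0 > mismatch_penalty.
    min_dup_len
        Smallest reportable duplication unit (ITDs of 3 bp occur).
    """

    search_window: int = 1000
    min_search_len: int = 10
    max_mismatch_frac: float = 0.10
    match_score: int = 1
    mismatch_penalty: int = -1
    min_dup_len: int = 3

    def __post_init__(self) -> None:
        if not (self.search_window >= self.min_search_len >= 1):
            raise ValueError("require search_window >= min_search_len >= 1")
        if not (0 <= self.max_mismatch_frac < 0.5):
            raise ValueError("require 0 <= max_mismatch_frac < 0.5")
        if self.min_dup_len < 1:
            raise ValueError("min_dup_len must be >= 1")


@dataclass(frozen=True)
class DuplicationMatch:
    """A full-length, gap-free placement of (part of) a clip."""

    ref_start: int
    ref_end: int
    mismatches: int
    matched_len: int
    query_offset: int = 0

    def __post_init__(self) -> None:
        if self.ref_end - self.ref_start != self.matched_len:
            raise ValueError("gap-free match must span exactly matched_len bases")


@dataclass(frozen=True)
class ITDCandidate:
    """A putative internal tandem duplication.

    ``dup_start``/``dup_end`` delimit the duplicated reference unit
    (0-based half-open); ``insertion_seq`` holds novel bases between the
    two copies; ``breakpoint`` is the canonical junction coordinate (the
    duplication-unit end).
    """

    dup_start: int
    dup_end: int
    insertion_seq: str
    breakpoint: int
    sides: tuple[str, ...] = ()
    source_events: tuple[str, ...] = ()

    @property
    def dup_length(self) -> int:
        return self.dup_end - self.dup_start

    @property
    def insertion_length(self) -> int:
        return len(self.insertion_seq)

    @property
    def key(self) -> tuple[int, int, str]:
        return (self.dup_start, self.dup_end, self.insertion_seq)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def placement_mismatch_counts(query: str, target: str) -> np.ndarray:
    """Mismatch count of every full-length gap-free placement of ``query``.

    Returns an array of length ``len(target) - len(query) + 1`` (empty if
    the query does not fit).  An ``N`` on either side never matches.
    """
    q = _encode(query)
    t = _encode(target)
    n_place = len(t) - len(q) + 1
    if n_place <= 0 or len(q) == 0:
        return np.zeros(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(t, len(q))
    mism = (windows != q) | (windows == _N) | (q == _N)
    return mism.sum(axis=1, dtype=np.int64)


def dp_similarity_search(
    query: str,
    target: str,
    params: SearchParams | None = None,
    prefer: str = "leftmost",
    offset_range: tuple[int, int] | None = None,
) -> DuplicationMatch | None:
    """Best tolerated full-length placement of ``query`` in ``target``.

    ``offset_range`` restricts candidate placements to target offsets in
    the closed interval [lo, hi].  Among equal-mismatch placements,
    ``prefer`` selects the leftmost or rightmost one — callers use this
    to favour the placement nearest the anchored read end, i.e. the
    smallest implied duplication.  Returns ``None`` when no placement
    passes the mismatch tolerance.
    """
    params = params or SearchParams()
    if len(query) < params.min_search_len:
        raise ValueError(
            f"query of length {len(query)} below min_search_len "
            f"{params.min_search_len}"
        )
    counts = placement_mismatch_counts(query, target)
    if counts.size == 0:
        return None
    offsets = np.arange(counts.size)
    if offset_range is not None:
        lo, hi = offset_range
        keep = (offsets >= lo) & (offsets <= hi)
        offsets, counts = offsets[keep], counts[keep]
        if counts.size == 0:
            return None
    tol = int(np.floor(params.max_mismatch_frac * len(query)))
    best = int(counts.min())
    if best > tol:
        return None
    ties = offsets[counts == best]
    off = int(ties[0] if prefer == "leftmost" else ties[-1])
    return DuplicationMatch(
        ref_start=off,
        ref_end=off + len(query),
        mismatches=best,
        matched_len=len(query),
    )


def trim_and_search(
    event: SoftClipEvent,
    ref: ReferenceContig,
    params: SearchParams | None = None,
) -> tuple[DuplicationMatch, str] | None:
    """Locate the duplicated unit for one clip, separating inserted bases.

    Returns ``(match, insertion_seq)`` with the match in contig
    coordinates, or ``None`` when no tolerated placement exists at any
    trim depth.  The match is constrained so that the implied duplication
    length lies in [min_dup_len, search_window].
    """
    params = params or SearchParams()
    clip = event.clip_seq
    b = event.breakpoint
    max_trim = len(clip) - params.min_search_len
    if max_trim < 0:
        return None

    best: tuple[int, int, DuplicationMatch, str] | None = None  # (score, -t, ...)
    for t in range(max_trim + 1):
        # upper bound on any deeper parse: a perfect match of the remainder
        if best is not None and params.match_score * (len(clip) - t) <= best[0]:
            break
        if event.side is ClipSide.THREE_PRIME:
            # insertion abuts the anchor end: trim from the clip's 5' end
            sub, ins = clip[t:], clip[:t]
            # match must start in [b - search_window, b - min_dup_len]
            lo_abs = max(0, b - params.search_window)
            hi_abs = b - params.min_dup_len
            if hi_abs < lo_abs:
                continue
            tgt_end = min(len(ref), hi_abs + len(sub))
            target = ref.sequence[lo_abs:tgt_end]
            found = dp_similarity_search(
                sub, target, params,
                prefer="rightmost",
                offset_range=(0, hi_abs - lo_abs),
            )
        else:
            # 5' clip: insertion abuts the anchor start; trim from the 3' end
            sub = clip[: len(clip) - t]
            ins = clip[len(clip) - t:] if t else ""
            # match must end in [b + min_dup_len, b + search_window]
            lo_abs = max(0, b + params.min_dup_len - len(sub))
            hi_abs = min(len(ref), b + params.search_window) - len(sub)
            if hi_abs < lo_abs:
                continue
            target = ref.sequence[lo_abs: hi_abs + len(sub)]
            found = dp_similarity_search(
                sub, target, params,
                prefer="leftmost",
                offset_range=(0, hi_abs - lo_abs),
            )
        if found is None:
            continue
        score = (params.match_score * (found.matched_len - found.mismatches)
                 + params.mismatch_penalty * found.mismatches)
        # mismatches must be paid for by extra matched length: a parse may
        # never score below a minimum-length exact match, otherwise short
        # noisy remainders (true trim depth unreachable in a short clip)
        # seed spurious near-duplicate candidates
        if score < params.match_score * params.min_search_len:
            continue
        if best is None or (score, -t) > best[:2]:
            best = (
                score,
                -t,
                DuplicationMatch(
                    ref_start=lo_abs + found.ref_start,
                    ref_end=lo_abs + found.ref_end,
                    mismatches=found.mismatches,
                    matched_len=found.matched_len,
                    query_offset=t if event.side is ClipSide.THREE_PRIME else 0,
                ),
                ins,
            )
    if best is None:
        return None
    return best[2], best[3]


def derive_duplication(
    event: SoftClipEvent,
    match: DuplicationMatch,
    insertion_seq: str = "",
    params: SearchParams | None = None,
) -> ITDCandidate | None:
    """Turn a clip match into a duplication candidate.

    For a 5' clip the duplicated unit runs from the anchor start (the
    breakpoint) to the end of the match; for a 3' clip from the match
    start to the breakpoint.  Units shorter than ``min_dup_len`` are
    rejected.
    """
    params = params or SearchParams()
    if event.side is ClipSide.FIVE_PRIME:
        dup_start, dup_end = event.breakpoint, match.ref_end
    else:
        dup_start, dup_end = match.ref_start, event.breakpoint
    if dup_end - dup_start < params.min_dup_len:
        logger.debug(
            "rejecting degenerate duplication [%d, %d) from read %s",
            dup_start, dup_end, event.read_name,
        )
        return None
    return ITDCandidate(
        dup_start=dup_start,
        dup_end=dup_end,
        insertion_seq=insertion_seq,
        breakpoint=dup_end,
        sides=(event.side.value,),
        source_events=(event.read_name,),
    )


def collect_candidates(
    groups: dict[tuple[int, ClipSide], list[SoftClipEvent]],
    ref: ReferenceContig,
    params: SearchParams | None = None,
) -> list[ITDCandidate]:
    """Search every event group and deduplicate candidates.

    Candidates are keyed by ``(dup_interval, insertion_seq)``; identical
    candidates discovered from different reads or from opposite clip
    sides merge their supporting read names.  Inclusive or overlapping
    candidates with distinct keys are all retained.  Output order is
    deterministic: by duplication start, end, then insertion sequence.
    """
    params = params or SearchParams()
    merged: dict[tuple[int, int, str], dict] = {}
    cache: dict[tuple[str, int, str], tuple[DuplicationMatch, str] | None] = {}
    for (bp, side), events in groups.items():
        for event in events:
            cache_key = (side.value, bp, event.clip_seq)
            if cache_key in cache:
                result = cache[cache_key]
            else:
                result = trim_and_search(event, ref, params)
                cache[cache_key] = result
            if result is None:
                continue
            match, ins = result
            cand = derive_duplication(event, match, ins, params)
            if cand is None:
                continue
            slot = merged.setdefault(
                cand.key, {"sides": set(), "events": set()}
            )
            slot["sides"].add(side.value)
            slot["events"].add(event.read_name)
    out = []
    for (dup_start, dup_end, ins), slot in sorted(merged.items()):
        out.append(
            ITDCandidate(
                dup_start=dup_start,
                dup_end=dup_end,
                insertion_seq=ins,
                breakpoint=dup_end,
                sides=tuple(sorted(slot["sides"])),
                source_events=tuple(sorted(slot["events"])),
            )
        )
    return _drop_minority_reparses(out)


def _drop_minority_reparses(cands: list[ITDCandidate]) -> list[ITDCandidate]:
    """Remove minority re-parses of one junction event.

    Two artifact classes produce rival parses of one junction, each
    backed by far fewer clips than the true parse:

    - clips too short to reach the true trim depth can chance-match
      elsewhere within tolerance, yielding a wildly different
      duplication *at the same breakpoint*;
    - a sequencing error at the junction-proximal base re-parses the
      event as a duplication one base shorter plus a one-base insertion
      (overlapping unit, same total inserted length, breakpoint off by
      one).

    Rival parses of one event always share its seeding clip position —
    the duplication-unit start for 5'-seeded candidates, the unit end
    for 3'-seeded ones — so candidates connected through a shared
    seeding key are resolved by clip votes first (only one call per
    junction can survive reporting anyway); then overlapping candidates
    with equal total inserted length are clustered the same way.  Ties
    go to the smaller interval key, deterministically.  Distinct
    co-occurring ITDs — inclusive or overlapping pairs — have distinct
    junctions and total lengths and are untouched.
    """

    def seed_keys(c: ITDCandidate) -> list[tuple[int, str]]:
        keys = []
        if "5p" in c.sides:
            keys.append((c.dup_start, "5p"))
        if "3p" in c.sides:
            keys.append((c.dup_end, "3p"))
        return keys or [(c.dup_end, "3p")]

    # connected components over shared seeding keys
    parent = list(range(len(cands)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    key_owner: dict[tuple[int, str], int] = {}
    for idx, cand in enumerate(cands):
        for key in seed_keys(cand):
            if key in key_owner:
                parent[find(idx)] = find(key_owner[key])
            else:
                key_owner[key] = idx
    components: dict[int, list[ITDCandidate]] = {}
    for idx, cand in enumerate(cands):
        components.setdefault(find(idx), []).append(cand)
    survivors: list[ITDCandidate] = []
    for group in components.values():
        survivors.extend(_majority(group))

    by_total: dict[int, list[ITDCandidate]] = {}
    for cand in survivors:
        by_total.setdefault(cand.dup_length + cand.insertion_length, []).append(cand)
    kept: list[ITDCandidate] = []
    for group in by_total.values():
        clusters: list[list[ITDCandidate]] = []
        for cand in sorted(group, key=lambda c: c.key):
            for cluster in clusters:
                if any(c.dup_start < cand.dup_end and cand.dup_start < c.dup_end
                       for c in cluster):
                    cluster.append(cand)
                    break
            else:
                clusters.append([cand])
        for cluster in clusters:
            kept.extend(_majority(cluster))
    return sorted(kept, key=lambda c: c.key)


def _majority(group: list[ITDCandidate],
              min_fraction: float = 0.25) -> list[ITDCandidate]:
    """Keep parses whose clip votes reach ``min_fraction`` of the leader's.

    Artifact re-parses carry a handful of clips against the true parse's
    tens to hundreds; genuinely co-supported events at one junction keep
    comparable vote counts and all survive for Step-5 adjudication.
    """
    if len(group) <= 1:
        return list(group)
    top = max(len(c.source_events) for c in group)
    keep = [c for c in sorted(group, key=lambda c: c.key)
            if len(c.source_events) >= min_fraction * top]
    if len(keep) < len(group):
        lead = min(group, key=lambda c: (-len(c.source_events), c.key))
        logger.info(
            "dropping %d minority parse(s) of the event at [%d, %d)",
            len(group) - len(keep), lead.dup_start, lead.dup_end,
        )
    return keep
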