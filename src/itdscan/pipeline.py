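"""End-to-end detection pipeline: alignments + reference -> ITD calls.

Stage order: soft-clip scan -> duplication search -> allele construction
and support counting -> minimum-support filter -> AR estimation (with
Smith-Waterman re-estimation for first-pass ratios above 1) ->
same-position deduplication -> ordered call set.  Per-stage candidate
counts are collected for the run summary and are monotonically
non-increasing from the candidate stage onward.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

from .regions import (FLT3_REGION_GRCH37, ReferenceContig, TargetRegion,
                      load_reference, resolve_region)
from .report import CallSet, dedup_same_position, write_tsv, write_vcf
from .search import SearchParams, collect_candidates
from .softclip import AlignedRead, ScanParams, fetch_reads, scan_reads
from .support import (ARParams, ITDCall, apply_support_filter, build_allele,
                      count_support, estimate_ar, reestimate_ar_high)

__all__ = ["RunConfig", "ConfigError", "validate_config", "detect_in_reads", "detect"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised with *all* validation problems, not just the first."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n" + "\n".join(f"- {p}" for p in problems))


@dataclass
class RunConfig:
    bam: str
    ref_fasta: str
    region: TargetRegion = FLT3_REGION_GRCH37
    out_tsv: str | None = None
    out_vcf: str | None = None
    sample_name: str = "sample"
    scan_params: ScanParams = field(default_factory=ScanParams)
    search_params: SearchParams = field(default_factory=SearchParams)
    ar_params: ARParams = field(default_factory=ARParams)
    log_level: str = "INFO"

    def fingerprint(self) -> str:
        parts = {
            "scan": dataclasses.asdict(self.scan_params),
            "search": dataclasses.asdict(self.search_params),
            "ar": dataclasses.asdict(self.ar_params),
            "region": self.region.to_text(),
        }
        return json.dumps(parts, sort_keys=True)


_SCAN_KEYS = {"min_clip_len": int, "min_mapq": int}
_SEARCH_KEYS = {
    "search_window": int, "min_search_len": int,
    "max_mismatch_frac": float, "min_dup_len": int,
}
_AR_KEYS = {
    "min_support": int, "ar_reestimate_threshold": float,
    "max_score_diff": int, "max_end_nonoverlap": int,
    "junction_overhang": int, "allele_flank": int,
}
_TOP_KEYS = {"bam", "ref", "region", "bed", "out_tsv", "out_vcf",
             "sample_name", "log_level"}


def validate_config(raw: dict) -> RunConfig:
    """Normalise a flat key-value mapping into a RunConfig.

    Every problem is collected and reported at once.
    """
    problems: list[str] = []
    known = _TOP_KEYS | set(_SCAN_KEYS) | set(_SEARCH_KEYS) | set(_AR_KEYS)
    for key in raw:
        if key not in known:
            problems.append(f"unknown configuration key: {key!r}")
    for required in ("bam", "ref"):
        if not raw.get(required):
            problems.append(f"missing required setting: {required!r}")

    def build(cls, keys):
        kwargs = {}
        for key, typ in keys.items():
            if raw.get(key) is not None:
                try:
                    kwargs[key] = typ(raw[key])
                except (TypeError, ValueError):
                    problems.append(f"{key}: cannot interpret {raw[key]!r} as {typ.__name__}")
        try:
            return cls(**kwargs)
        except ValueError as exc:
            problems.append(str(exc))
            return cls()

    scan = build(ScanParams, _SCAN_KEYS)
    search = build(SearchParams, _SEARCH_KEYS)
    ar = build(ARParams, _AR_KEYS)

    region = FLT3_REGION_GRCH37
    spec = raw.get("bed") or raw.get("region")
    if spec:
        try:
            region = resolve_region(str(spec))
        except ValueError as exc:
            problems.append(str(exc))
    if problems:
        raise ConfigError(problems)
    return RunConfig(
        bam=str(raw["bam"]),
        ref_fasta=str(raw["ref"]),
        region=region,
        out_tsv=raw.get("out_tsv"),
        out_vcf=raw.get("out_vcf"),
        sample_name=str(raw.get("sample_name", "sample")),
        scan_params=scan,
        search_params=search,
        ar_params=ar,
        log_level=str(raw.get("log_level", "INFO")),
    )


def detect_in_reads(
    reads: Sequence[AlignedRead],
    ref: ReferenceContig,
    region: TargetRegion,
    scan_params: ScanParams | None = None,
    search_params: SearchParams | None = None,
    ar_params: ARParams | None = None,
    sample_name: str = "sample",
) -> tuple[CallSet, dict]:
    """Run the full caller on an in-memory read collection."""
    scan_params = scan_params or ScanParams()
    search_params = search_params or SearchParams()
    ar_params = ar_params or ARParams()

    groups = scan_reads(reads, region, scan_params)
    candidates = collect_candidates(groups, ref, search_params)
    logger.info("%d clip groups -> %d candidates", len(groups), len(candidates))

    pad = ar_params.allele_flank + 50
    calls: list[ITDCall] = []
    alleles = {}
    locus_reads = {}
    for cand in candidates:
        allele = build_allele(cand, ref, ar_params.allele_flank)
        near = [
            r for r in reads
            if not r.is_unmapped
            and r.ref_start < cand.dup_end + pad
            and r.ref_end > cand.dup_start - pad
        ]
        alt, wt = count_support(cand, near, allele, ref, ar_params)
        ratio, no_wt = estimate_ar(alt, wt)
        calls.append(ITDCall(cand, alt, wt, ratio, no_wildtype=no_wt))
        alleles[cand.key] = allele
        locus_reads[cand.key] = near

    supported = apply_support_filter(calls, ar_params)
    reestimated = [
        reestimate_ar_high(
            call, locus_reads[call.candidate.key],
            alleles[call.candidate.key], ref, ar_params,
        )
        for call in supported
    ]
    final = dedup_same_position(reestimated)
    stats = {
        "clip_groups": len(groups),
        "candidates": len(candidates),
        "supported": len(supported),
        "final": len(final),
    }
    callset = CallSet(sample_name=sample_name, contig=region.contig, calls=final)
    return callset, stats


def detect(config: RunConfig) -> tuple[CallSet, dict]:
    """Run the caller per a RunConfig and write the configured outputs."""
    ref = load_reference(config.ref_fasta, config.region.contig)
    reads = fetch_reads(config.bam, config.region,
                        pad=config.ar_params.allele_flank + 50)
    callset, stats = detect_in_reads(
        reads, ref, config.region,
        config.scan_params, config.search_params, config.ar_params,
        sample_name=config.sample_name,
    )
    callset.params_fingerprint = config.fingerprint()
    if config.out_tsv:
        write_tsv(callset, config.out_tsv)
    if config.out_vcf:
        write_vcf(callset, ref, config.out_vcf)
    if config.out_tsv:
        summary = {
            "sample": config.sample_name,
            "region": config.region.to_text(),
            "stage_counts": stats,
            "n_calls": len(callset.calls),
            "params": json.loads(config.fingerprint()),
        }
        with open(config.out_tsv + ".run.json", "w") as handle:
            json.dump(summary, handle, indent=1, sort_keys=True)
    return callset, stats
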