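"""Detect a single ITD end-to-end, entirely in memory.

Simulates a 30 bp duplication at allelic ratio 0.5 and runs the full
caller: soft-clip scan, duplication search, support counting, allelic
ratio estimation and reporting.
"""

import io

from itdscan import (ITDSpec, SimSpec, TargetRegion, detect_in_reads,
                     simulate_reads, write_tsv)

spec = SimSpec(
    itds=[ITDSpec(dup_start=2300, dup_length=30, target_ar=0.5)],
    coverage=500,
    error_rate=0.001,
    seed=7,
)
result = simulate_reads(spec)
region = TargetRegion("sim1", 0, spec.ref_length)
callset, stats = detect_in_reads(result.reads, result.reference, region)

print(f"pipeline stages: {stats}")
buf = io.StringIO()
write_tsv(callset, buf)
print(buf.getvalue())

call = callset.calls[0]
print(f"The caller found a {call.dup_length} bp duplication at "
      f"[{call.candidate.dup_start}, {call.candidate.dup_end}) — the exact "
      "simulated interval.")
print(f"{call.alt_reads} reads span the duplication junction and "
      f"{call.ref_reads} span the wild-type breakpoint, giving an allelic")
print(f"ratio (ITD/wild-type, the fragment-analysis convention) of "
      f"{call.allelic_ratio:.3f} against a simulated truth of 0.5.")
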