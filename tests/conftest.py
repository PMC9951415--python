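import pytest

from itdscan import (ITDSpec, SimSpec, TargetRegion, detect_in_reads,
                     simulate_reads)
from itdscan.simulate import make_reference, random_insertion


@pytest.fixture(scope="session")
def small_ref():
    """A deterministic repeat-free 2 kb contig shared across tests."""
    return make_reference(2000, seed=42, contig_name="tiny")


@pytest.fixture(scope="session")
def whole_region():
    return TargetRegion("sim1", 0, 5000)


@pytest.fixture(scope="session")
def run_sim_and_detect():
    """Factory: simulate a sample and run the caller over the whole contig."""

    def _run(itds, coverage=500.0, error_rate=0.0, seed=0, **spec_kwargs):
        spec = SimSpec(itds=list(itds), coverage=coverage,
                       error_rate=error_rate, seed=seed, **spec_kwargs)
        result = simulate_reads(spec)
        region = TargetRegion(spec.contig_name, 0, spec.ref_length)
        callset, stats = detect_in_reads(result.reads, result.reference, region)
        return result, callset, stats

    return _run


@pytest.fixture(scope="session")
def separable_itd():
    """Factory: an ITDSpec whose insertion is distinguishable from the unit."""

    def _make(ref, dup_start, dup_length, ins_length, target_ar=0.5, ins_seed=1):
        ins = (random_insertion(ref, dup_start, dup_start + dup_length,
                                ins_length, ins_seed)
               if ins_length else "")
        return ITDSpec(dup_start=dup_start, dup_length=dup_length,
                       insertion_seq=ins, target_ar=target_ar)

    return _make
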