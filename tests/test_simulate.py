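import math

import pytest

from itdscan import (CallSet, ITDSpec, SimSpec, build_itd_allele_truth,
                     make_reference, simulate_reads, write_bam, write_fastq,
                     write_sam, score_against_truth)
from itdscan.search import ITDCandidate
from itdscan.support import ITDCall


class TestMakeReference:
    def test_deterministic_under_seed(self):
        a = make_reference(2000, seed=1)
        b = make_reference(2000, seed=1)
        assert a.sequence == b.sequence
        assert make_reference(2000, seed=2).sequence != a.sequence

    def test_placement_zone_free_of_tandem_10mers(self):
        # exhaustive 10-mer scan oracle
        ref = make_reference(5000, seed=0)
        seq = ref.sequence
        lo, hi = 600, 5000 - 600
        for i in range(lo, hi):
            assert seq[i: i + 10] != seq[i + 10: i + 20]


class TestAlleleTruth:
    def test_length_grows_by_duplication(self, small_ref):
        allele, truth = build_itd_allele_truth(small_ref, ITDSpec(700, 84))
        assert len(allele) == len(small_ref) + 84
        assert (truth.allele_junction_start, truth.allele_junction_end) == (784, 784)

    def test_length_grows_by_duplication_plus_insertion(self, small_ref):
        allele, _ = build_itd_allele_truth(small_ref,
                                           ITDSpec(700, 52, "TTACG"))
        assert len(allele) == len(small_ref) + 57

    def test_junction_kmer_appears_exactly_twice(self, small_ref):
        dup = 40
        allele, truth = build_itd_allele_truth(small_ref, ITDSpec(700, dup))
        unit = small_ref.sequence[700: 700 + dup]
        # tandem structure: the duplicated unit occurs twice, adjacent
        assert allele.count(unit) == 2
        j = truth.allele_junction_start
        assert allele[j - dup: j + dup] == unit + unit


class TestSimulateReads:
    def test_full_determinism_byte_identical(self, tmp_path):
        spec = SimSpec(itds=[ITDSpec(2300, 30, "TACGT", 0.5)],
                       coverage=50, seed=9)
        outs = []
        for run in ("a", "b"):
            result = simulate_reads(spec)
            sam = tmp_path / f"{run}.sam"
            write_sam(result, str(sam))
            manifest = tmp_path / f"{run}.json"
            result.manifest.to_json(str(manifest))
            fq = write_fastq(result, str(tmp_path / run))
            outs.append((sam.read_bytes(), manifest.read_bytes(),
                         [open(p, "rb").read() for p in fq]))
        assert outs[0] == outs[1]

    def test_zero_ar_yields_no_junction_reads(self):
        spec = SimSpec(itds=[ITDSpec(2300, 30, target_ar=0.0)],
                       coverage=100, seed=1)
        result = simulate_reads(spec)
        assert result.manifest.junction_read_counts() == [0]

    def test_junction_ratio_within_binomial_ci(self):
        spec = SimSpec(itds=[ITDSpec(2300, 30, target_ar=0.5)],
                       coverage=500, error_rate=0.0, seed=13)
        result = simulate_reads(spec)
        e = 2330
        alt = result.manifest.junction_read_counts()[0]
        wt_span = sum(
            1 for truth in result.manifest.reads
            if truth.haplotype == 0
            and truth.allele_pos < e < truth.allele_pos + spec.read_length
        )
        n, p = alt + wt_span, 0.5 / 1.5
        assert abs(alt / n - p) < 1.96 * math.sqrt(p * (1 - p) / n)

    def test_mean_depth_within_ten_percent(self):
        spec = SimSpec(itds=[], coverage=200, seed=2)
        result = simulate_reads(spec)
        total_bases = sum(len(r.seq) for r in result.reads)
        assert total_bases / spec.ref_length == pytest.approx(200, rel=0.10)

    def test_two_itds_give_two_distinct_junction_pairs(self):
        spec = SimSpec(itds=[ITDSpec(2340, 120, target_ar=0.3),
                             ITDSpec(2400, 90, target_ar=0.3)],
                       coverage=100, seed=3)
        result = simulate_reads(spec)
        pairs = {(t.dup_start, t.dup_end) for t in result.manifest.itds}
        assert pairs == {(2340, 2460), (2400, 2490)}

    def test_error_free_cigar_segments_match_reference(self):
        """Every aligned (M) block of a simulated read equals the reference."""
        spec = SimSpec(itds=[ITDSpec(2300, 40, "TGCAT", 0.5)],
                       coverage=80, error_rate=0.0, seed=6)
        result = simulate_reads(spec)
        seq = result.reference.sequence
        checked = 0
        for read in result.reads:
            if read.is_unmapped:
                continue
            qpos, rpos = 0, read.ref_start
            for op, n in read.cigar:
                if op == "M":
                    assert read.seq[qpos: qpos + n] == seq[rpos: rpos + n]
                    checked += 1
                if op in "MIS=X":
                    qpos += n
                if op in "MDN=X":
                    rpos += n
        assert checked > 100

    def test_bam_is_fetchable_and_sorted(self, tmp_path):
        import pysam

        spec = SimSpec(itds=[ITDSpec(2300, 30, target_ar=0.5)],
                       coverage=60, seed=7)
        result = simulate_reads(spec)
        path = tmp_path / "sim.bam"
        write_bam(result, str(path))
        with pysam.AlignmentFile(str(path), "rb") as bam:
            assert bam.has_index()
            fetched = list(bam.fetch("sim1", 2250, 2400))
        assert fetched
        starts = [a.reference_start for a in fetched]
        assert starts == sorted(starts)


class TestScoreAgainstTruth:
    def manifest_for(self, *itds):
        spec = SimSpec(itds=list(itds), coverage=10, seed=1)
        return simulate_reads(spec).manifest

    def call(self, dup_start, dup_end, ins="", ratio=0.5):
        cand = ITDCandidate(dup_start, dup_end, ins, dup_end)
        return ITDCall(cand, 10, 20, ratio)

    def test_perfect_call_scores_clean(self):
        manifest = self.manifest_for(ITDSpec(2300, 30, target_ar=0.5))
        cs = CallSet("s", "sim1", [self.call(2300, 2330)])
        metrics = score_against_truth(cs, manifest)
        assert metrics["detected_fraction"] == 1.0
        per = metrics["per_itd"][0]
        assert per["dup_length_error"] == 0 and per["insertion_exact"]
        assert per["ar_ape"] == pytest.approx(0.0)

    def test_ape_definition(self):
        manifest = self.manifest_for(ITDSpec(2300, 30, target_ar=0.5))
        cs = CallSet("s", "sim1", [self.call(2300, 2330, ratio=0.45)])
        metrics = score_against_truth(cs, manifest)
        assert metrics["per_itd"][0]["ar_ape"] == pytest.approx(0.1)

    def test_matches_hand_computed_oracle_on_toy_callsets(self):
        manifest = self.manifest_for(ITDSpec(2300, 30, target_ar=0.5),
                                     ITDSpec(2600, 84, target_ar=0.2))
        # one exact, one off by 3 bp (within matching distance), one false call
        cs = CallSet("s", "sim1", [
            self.call(2300, 2330, ratio=0.5),
            self.call(2600, 2687, ratio=0.3),
            self.call(1000, 1040, ratio=0.1),
        ])
        metrics = score_against_truth(cs, manifest)
        assert metrics["detected_fraction"] == 1.0
        assert metrics["false_calls"] == 1
        errors = sorted(p["dup_length_error"] for p in metrics["per_itd"])
        assert errors == [0, 3]

    def test_distant_call_is_a_miss(self):
        manifest = self.manifest_for(ITDSpec(2300, 30, target_ar=0.5))
        cs = CallSet("s", "sim1", [self.call(2400, 2430)])
        metrics = score_against_truth(cs, manifest)
        assert metrics["detected_fraction"] == 0.0
        assert metrics["false_calls"] == 1
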