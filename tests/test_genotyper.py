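import numpy as np
import pysam
import pytest

from caml.catalog import MicrosatLocus
from caml.genotyper import (
    AlleleObservation,
    STATUS_CALLED,
    STATUS_LOW_COVERAGE,
    STATUS_MULTI_ALLELIC,
    STATUS_NO_READS,
    call_genotype,
    extract_observations,
    genotype_cohort,
)
from caml.simulate import (
    SimulationConfig,
    make_planted_caml,
    simulate_cohort_genotypes,
    simulate_reads,
    simulate_reference,
)


def obs(locus_id, length, count, motif="AC"):
    reps = -(-length // len(motif))
    return AlleleObservation(locus_id, length, (motif * reps)[:length], count)


class TestCallGenotype:
    def test_single_bin_homozygous(self):
        call = call_genotype([obs("L", 14, 20)], sample_id="s")
        assert call.status == STATUS_CALLED
        assert (call.allele_a, call.allele_b) == (14, 14)
        assert call.depth == 20

    def test_stutter_bin_suppressed(self):
        bins = [obs("L", 12, 10), obs("L", 16, 9), obs("L", 14, 1)]
        call = call_genotype(bins)
        assert call.status == STATUS_CALLED
        assert (call.allele_a, call.allele_b) == (12, 16)
        assert call.depth == 20

    def test_three_supported_alleles_excluded(self):
        bins = [obs("L", 12, 8), obs("L", 14, 8), obs("L", 16, 8)]
        call = call_genotype(bins)
        assert call.status == STATUS_MULTI_ALLELIC
        assert call.genotype is None

    def test_low_coverage(self):
        call = call_genotype([obs("L", 14, 14)], coverage_min=15)
        assert call.status == STATUS_LOW_COVERAGE

    def test_no_reads(self):
        call = call_genotype([], locus_id="L")
        assert call.status == STATUS_NO_READS
        assert call.depth == 0

    def test_snp_within_tract_does_not_split_length_bin(self):
        # two bins, same length, different sequence: one allele
        bins = [
            AlleleObservation("L", 14, "AC" * 7, 12),
            AlleleObservation("L", 14, "AC" * 3 + "AT" + "AC" * 3, 8),
        ]
        call = call_genotype(bins)
        assert call.status == STATUS_CALLED
        assert (call.allele_a, call.allele_b) == (14, 14)
        assert call.depth == 20

    def test_mixed_locus_ids_rejected(self):
        with pytest.raises(ValueError, match="multiple loci"):
            call_genotype([obs("L1", 14, 10), obs("L2", 14, 10)])

    def test_order_invariance(self):
        bins = [obs("L", 12, 10), obs("L", 16, 9), obs("L", 14, 1)]
        forward = call_genotype(bins)
        backward = call_genotype(list(reversed(bins)))
        assert forward == backward

    def test_coverage_min_monotonicity(self):
        bins = [obs("L", 14, 18)]
        assert call_genotype(bins, coverage_min=15).status == STATUS_CALLED
        assert call_genotype(bins, coverage_min=19).status == STATUS_LOW_COVERAGE
        # raising coverage_min never turns low_coverage into called
        for lo in range(1, 40):
            for hi in range(lo, 40):
                s_lo = call_genotype(bins, coverage_min=lo).status
                s_hi = call_genotype(bins, coverage_min=hi).status
                assert not (s_lo == STATUS_LOW_COVERAGE and s_hi == STATUS_CALLED)

    def test_invalid_observation(self):
        with pytest.raises(ValueError):
            AlleleObservation("L", 14, "AC" * 7, 0)
        with pytest.raises(ValueError):
            AlleleObservation("L", 13, "AC" * 7, 5)


REF_CONTEXT = "TGCATGGTCATTCGGATTGCAGTCCGGTAT"


def _write_sam(path, reads, chrom="chr1", length=200):
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": chrom, "LN": length}]}
    )
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for i, (pos, cigar, seq, flag) in enumerate(reads):
            aln = pysam.AlignedSegment(header)
            aln.query_name = f"r{i}"
            aln.query_sequence = seq
            aln.flag = flag
            aln.reference_id = 0
            aln.reference_start = pos
            aln.mapping_quality = 60
            aln.cigarstring = cigar
            out.write(aln)
    return path


@pytest.fixture
def simple_locus():
    # reference: 30 nt context + AC*7 + 30 nt context
    left = "TGCATGGTCATTCGGATTGCAGTCCGGTAT"
    right = "GGTCATTGACGGTACCTGATCCAGCATGCA"
    tract = "AC" * 7
    locus = MicrosatLocus(
        "chr1",
        30,
        44,
        "AC",
        left_flank=left[-10:],
        right_flank=right[:10],
    )
    return left + tract + right, locus


class TestExtractObservations:
    def test_perfect_spanning_reads(self, simple_locus, tmp_path):
        seq, locus = simple_locus
        read = seq[10:74]  # spans tract with >= 5 nt flanks on both sides
        path = _write_sam(
            str(tmp_path / "a.sam"), [(10, "64M", read, 0)] * 20
        )
        result = extract_observations(path, [locus])
        bins = result[locus.locus_id]
        assert len(bins) == 1
        assert bins[0].allele_length == 14
        assert bins[0].read_count == 20
        assert bins[0].repeat_sequence == "AC" * 7

    def test_flank_mismatch_excluded(self, simple_locus, tmp_path):
        seq, locus = simple_locus
        read = list(seq[10:74])
        # read position of the right flank's 3rd base: tract ends at seq
        # index 44 -> read index 34; corrupt index 36 (inside right 5-mer)
        read[36] = "A" if read[36] != "A" else "G"
        path = _write_sam(str(tmp_path / "a.sam"), [(10, "64M", "".join(read), 0)])
        assert extract_observations(path, [locus]) == {}

    def test_one_flank_mismatch_allowed_when_configured(self, simple_locus, tmp_path):
        seq, locus = simple_locus
        read = list(seq[10:74])
        read[36] = "A" if read[36] != "A" else "G"
        path = _write_sam(str(tmp_path / "a.sam"), [(10, "64M", "".join(read), 0)])
        result = extract_observations(path, [locus], max_flank_mismatches=1)
        assert result[locus.locus_id][0].allele_length == 14

    def test_non_spanning_read_excluded(self, simple_locus, tmp_path):
        seq, locus = simple_locus
        # ends 3 bases into the right flank: no full 5 nt right window
        read = seq[10:47]
        path = _write_sam(str(tmp_path / "a.sam"), [(10, "37M", read, 0)])
        assert extract_observations(path, [locus]) == {}

    def test_flagged_reads_skipped(self, simple_locus, tmp_path):
        seq, locus = simple_locus
        read = seq[10:74]
        flags = [4, 256, 1024, 2048]  # unmapped, secondary, duplicate, supplementary
        path = _write_sam(
            str(tmp_path / "a.sam"), [(10, "64M", read, f) for f in flags]
        )
        assert extract_observations(path, [locus]) == {}

    def test_snp_in_tract_binned_separately_same_length(self, simple_locus, tmp_path):
        seq, locus = simple_locus
        clean = seq[10:74]
        mutated = list(clean)
        mutated[26] = "T"  # inside the tract (read idx 20..33)
        path = _write_sam(
            str(tmp_path / "a.sam"),
            [(10, "64M", clean, 0)] * 3 + [(10, "64M", "".join(mutated), 0)] * 2,
        )
        bins = extract_observations(path, [locus])[locus.locus_id]
        assert sorted((b.allele_length, b.read_count) for b in bins) == [(14, 2), (14, 3)]


class TestSimulatedDiploidRecovery:
    def test_planted_het_recovered_against_enumeration(self, tmp_path):
        """Reads from a planted (12,16) diploid: bins match direct enumeration."""
        config = SimulationConfig(seed=5, n_loci=1, n_case=1, n_control=0, depth_mean=30)
        rng = np.random.default_rng(config.seed)
        reference, truth = simulate_reference(config, rng)
        locus = truth[0]
        table = simulate_cohort_genotypes(config, truth, rng)
        # overwrite the drawn genotype with a known heterozygote
        u = locus.unit_size
        a, b = locus.ref_length, locus.ref_length + 2 * u
        table.calls.loc[:, "allele_a"] = a
        table.calls.loc[:, "allele_b"] = b
        manifest = simulate_reads(config, reference, truth, table, str(tmp_path), rng)

        seq = reference[locus.chrom]
        flanked = [
            MicrosatLocus(
                locus.chrom,
                locus.start,
                locus.end,
                locus.motif,
                left_flank=seq[locus.start - 10 : locus.start],
                right_flank=seq[locus.end : locus.end + 10],
            )
        ]
        bins = extract_observations(manifest["path"][0], flanked)[locus.locus_id]
        lengths = sorted(bin_.allele_length for bin_ in bins)
        assert set(lengths) == {a, b}

        # oracle: every SAM read spanning tract+5 on both sides contributes
        n_spanning = 0
        with pysam.AlignmentFile(manifest["path"][0], check_sq=False) as fh:
            for read in fh:
                if (
                    read.reference_start <= locus.start - 5
                    and read.reference_end >= locus.end + 5
                ):
                    n_spanning += 1
        assert sum(bin_.read_count for bin_ in bins) == n_spanning

        call = call_genotype(bins, sample_id="s", locus_id=locus.locus_id)
        assert call.status == STATUS_CALLED
        assert (call.allele_a, call.allele_b) == (a, b)


class TestGenotypeCohort:
    def test_cohort_recovery_error_free(self, small_fixture):
        catalog = small_fixture["truth_catalog"]
        seq = small_fixture["reference"]["chr1"]
        flanked = [
            MicrosatLocus(
                l.chrom, l.start, l.end, l.motif,
                left_flank=seq[l.start - 10 : l.start],
                right_flank=seq[l.end : l.end + 10],
            )
            for l in catalog
        ]
        table = genotype_cohort(small_fixture["manifest"], flanked)
        truth = small_fixture["truth_table"].genotype_lookup()
        called = table.genotype_lookup()
        shared = set(truth) & set(called)
        assert len(shared) >= 0.95 * len(truth)
        agree = sum(1 for key in shared if truth[key] == called[key])
        assert agree >= 0.99 * len(shared)

    def test_depth_bounded_by_spanning_reads(self, small_fixture):
        catalog = small_fixture["truth_catalog"]
        seq = small_fixture["reference"]["chr1"]
        flanked = [
            MicrosatLocus(
                l.chrom, l.start, l.end, l.motif,
                left_flank=seq[l.start - 10 : l.start],
                right_flank=seq[l.end : l.end + 10],
            )
            for l in catalog
        ]
        row = small_fixture["manifest"].iloc[0]
        spans = {l.locus_id: 0 for l in flanked}
        with pysam.AlignmentFile(row["path"], check_sq=False) as fh:
            reads = list(fh)
        for l in flanked:
            for read in reads:
                if (
                    read.reference_start <= l.start - 5
                    and read.reference_end >= l.end + 5
                ):
                    spans[l.locus_id] += 1
        obs_map = extract_observations(row["path"], flanked)
        for locus_id, bins in obs_map.items():
            assert sum(b.read_count for b in bins) <= spans[locus_id]

    def test_manifest_validation(self):
        import pandas as pd

        with pytest.raises(ValueError, match="manifest"):
            genotype_cohort(pd.DataFrame({"sample_id": []}), [])
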