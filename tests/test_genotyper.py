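"""Probe-based genotype caller: trimming, filtering, counting, calling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amplisnp import (
    CallParams,
    call_genotype,
    count_alleles,
    genotype_reads,
    genotype_sample,
    simulate_amplicon_reads,
)
from amplisnp.design import reverse_complement
from amplisnp.genotyper import (
    AlleleCounts,
    Call,
    ProbeMatch,
    ReadRecord,
    calls_to_frame,
    filter_read,
    match_probe,
    read_genotype_table,
    trim_adapter,
    write_genotype_table,
    write_vcf,
)
from amplisnp.simulate import ReadSimConfig, write_fastq


def _read(seq, q=30, rid="r1"):
    return ReadRecord(rid, seq, tuple([q] * len(seq)))


class TestTrimAdapter:
    def test_read_without_adapter_unchanged(self, design):
        read = _read(design.amplicon_seq)
        assert trim_adapter(read, design.adapter) is read

    def test_full_readthrough_trimmed_to_insert(self, design):
        # 150 bp read = 119 bp insert + adapter + downstream bases
        seq = (design.amplicon_seq + design.adapter + "ACGTACGTACGTACGT")[:150]
        read = _read(seq)
        trimmed = trim_adapter(read, design.adapter)
        assert trimmed.seq == design.amplicon_seq
        assert len(trimmed.qual) == 119

    def test_pure_adapter_read_becomes_empty(self, design):
        read = _read(design.adapter)
        assert trim_adapter(read, design.adapter).seq == ""

    def test_partial_adapter_suffix_trimmed_at_8bp(self, design):
        insert = design.amplicon_seq
        read = _read(insert + design.adapter[:8])
        assert trim_adapter(read, design.adapter).seq == insert
        # below the 8 bp floor the suffix is left alone
        short = _read(insert + design.adapter[:7])
        assert trim_adapter(short, design.adapter).seq == insert + design.adapter[:7]

    @settings(max_examples=30, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=160))
    def test_qualities_truncated_in_lockstep(self, design, seq):
        trimmed = trim_adapter(_read(seq), design.adapter)
        assert len(trimmed.seq) == len(trimmed.qual)
        assert seq.startswith(trimmed.seq)


class TestFilterRead:
    def test_good_read_kept(self):
        assert filter_read(_read("A" * 119, q=30))

    def test_short_read_dropped_even_at_high_quality(self):
        assert not filter_read(_read("A" * 99, q=40))

    def test_mean_quality_boundary_is_strict(self):
        assert not filter_read(_read("A" * 119, q=20))
        assert filter_read(_read("A" * 119, q=21))


class TestMatchProbe:
    def test_forward_ref_probe(self, design, snp1):
        assert match_probe(design.amplicon_seq, snp1) is ProbeMatch.REF

    def test_reverse_complement_alt_probe(self, design, snp1):
        alt_seq = design.haplotype_seq(("C", "A"))
        assert match_probe(reverse_complement(alt_seq), snp1) is ProbeMatch.ALT

    def test_error_inside_probe_region_matches_nothing(self, design, snp1):
        seq = list(design.amplicon_seq)
        seq[snp1.offset + 3] = "A" if seq[snp1.offset + 3] != "A" else "C"
        assert match_probe("".join(seq), snp1) is ProbeMatch.NONE

    def test_both_probes_present_is_ambiguous(self, snp1):
        assert match_probe(snp1.probe_ref + "NN" + snp1.probe_alt, snp1) is ProbeMatch.AMBIGUOUS

    def test_mismatch_tolerant_mode_assigns_closer_probe(self, design, snp1):
        seq = list(design.amplicon_seq)
        pos = snp1.offset + 3  # error inside the probe window, off the SNP base
        seq[pos] = "A" if seq[pos] != "A" else "C"
        seq = "".join(seq)
        assert match_probe(seq, snp1) is ProbeMatch.NONE
        assert match_probe(seq, snp1, max_mismatches=1) is ProbeMatch.REF
        # an exact ref read stays ref, not ambiguous, under tolerance
        assert match_probe(design.amplicon_seq, snp1, max_mismatches=1) is ProbeMatch.REF


class TestCountAlleles:
    def test_no_reads_gives_zero_counts(self, design):
        counts = count_alleles([], design)
        assert all(c.depth == 0 and c.n_unassigned == 0 for c in counts.values())

    def test_heterozygote_counts_conserve_depth(self, design):
        reads = simulate_amplicon_reads(
            (1, 1), design, ReadSimConfig(depth=1000, per_base_error=0.0), seed=21
        )
        counts = count_alleles([seq for _, seq, _ in reads], design)
        for c in counts.values():
            assert c.n_ref + c.n_alt == 1000
            assert c.n_unassigned == 0

    def test_both_snps_counted_from_same_single_amplicon_reads(self, design):
        reads = simulate_amplicon_reads(
            (0, 2), design, ReadSimConfig(depth=200, per_base_error=0.0), seed=22
        )
        counts = count_alleles([seq for _, seq, _ in reads], design)
        assert counts[design.snps[0].snp_id].n_ref == 200
        assert counts[design.snps[1].snp_id].n_alt == 200

    def test_strand_symmetry(self, design):
        reads = simulate_amplicon_reads(
            (1, 1), design, ReadSimConfig(depth=300, per_base_error=0.02), seed=23
        )
        fwd = count_alleles([seq for _, seq, _ in reads], design)
        rev = count_alleles([reverse_complement(seq) for _, seq, _ in reads], design)
        assert fwd == rev


class TestCallGenotype:
    @pytest.mark.parametrize(
        "n_ref,n_alt,expected",
        [
            (990, 10, Call.HOM_REF),
            (480, 520, Call.HET),
            (10, 990, Call.HOM_ALT),
            (799, 201, Call.HET),   # alt fraction 0.201 inside the band
            (801, 199, Call.HOM_REF),
        ],
    )
    def test_ratio_thresholds(self, n_ref, n_alt, expected):
        call = call_genotype(AlleleCounts("snp", n_ref, n_alt))
        assert call.call is expected

    def test_depth_gate(self):
        call = call_genotype(AlleleCounts("snp", 20, 10), min_depth=50)
        assert call.call is Call.NO_CALL

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            call_genotype(AlleleCounts("snp", 5, 5), het_low=0.9, het_high=0.1)


class TestGenotypeSample:
    def test_end_to_end_hom_alt(self, design):
        reads = simulate_amplicon_reads(
            (2, 2), design, ReadSimConfig(depth=1000, per_base_error=0.001), seed=24
        )
        calls, qc = genotype_reads(reads, design)
        assert all(c.call is Call.HOM_ALT for c in calls.values())
        assert qc.reads_in == qc.reads_kept + qc.reads_dropped == 1000

    def test_empty_fastq_gives_no_call(self, design, tmp_path):
        path = tmp_path / "empty.fastq"
        path.write_text("")
        calls, qc = genotype_sample(path, design)
        assert all(c.call is Call.NO_CALL for c in calls.values())
        assert qc.reads_in == 0

    def test_malformed_fastq_reported(self, design, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r1\nACGT\n+\nII\n")  # qual shorter than seq
        with pytest.raises(ValueError, match="bad.fastq"):
            genotype_sample(path, design)

    def test_concordance_monotone_in_depth_and_error(self, design):
        """Call accuracy never worsens with more depth or less error."""
        rng = np.random.default_rng(25)
        depths = (80, 200, 600)
        errors = (0.0, 0.05, 0.12)
        n_samples = 30
        truths = rng.integers(0, 3, size=(n_samples, 2))
        conc = np.zeros((3, 3))
        for i, depth in enumerate(depths):
            for j, err in enumerate(errors):
                ok = 0
                for k in range(n_samples):
                    reads = simulate_amplicon_reads(
                        tuple(truths[k]), design,
                        ReadSimConfig(depth=depth, per_base_error=err),
                        seed=rng,
                    )
                    calls, _ = genotype_reads(reads, design)
                    expect = {0: Call.HOM_REF, 1: Call.HET, 2: Call.HOM_ALT}
                    ok += all(
                        calls[snp.snp_id].call is expect[truths[k, s]]
                        for s, snp in enumerate(design.snps)
                    )
                conc[i, j] = ok / n_samples
        assert np.all(np.diff(conc, axis=0) >= 0), conc  # deeper is better
        assert np.all(np.diff(conc, axis=1) <= 0), conc  # noisier is worse


class TestOutputs:
    @pytest.fixture()
    def calls(self, design):
        out = {}
        for sid, genotype in (("s1", (0, 0)), ("s2", (1, 1)), ("s3", (2, 0))):
            reads = simulate_amplicon_reads(
                genotype, design, ReadSimConfig(depth=200, per_base_error=0.0), seed=26
            )
            out[sid], _ = genotype_reads(reads, design)
        # synthesise a no-call for VCF conventions
        out["s4"] = {
            snp.snp_id: call_genotype(AlleleCounts(snp.snp_id, 0, 0))
            for snp in design.snps
        }
        return out

    def test_tsv_round_trip(self, calls, design, tmp_path):
        path = tmp_path / "geno.tsv"
        write_genotype_table(calls, design, path)
        back = read_genotype_table(path)
        assert list(back["sample_id"]) == ["s1", "s2", "s3", "s4"]
        frame = calls_to_frame(calls, design)
        assert back["genotype_rs2234693"].tolist() == frame["genotype_rs2234693"].tolist()

    def test_vcf_two_records_and_nocall_convention(self, calls, design, tmp_path):
        import pysam

        path = tmp_path / "geno.vcf"
        write_vcf(calls, design, path)
        with pysam.VariantFile(str(path)) as vcf:
            records = list(vcf)
        assert len(records) == 2
        assert [r.id for r in records] == [s.snp_id for s in design.snps]
        assert len(records[0].samples) == 4
        assert records[0].samples["s2"]["GT"] == (0, 1)
        assert records[0].samples["s4"]["GT"] == (None, None)
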