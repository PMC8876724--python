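"""Simulator contracts: determinism, truth-label fidelity, error model."""

import numpy as np
import pytest
from scipy import stats

from mitowgs.align import Aligner, DEFAULT_PARAMS, map_reads
from mitowgs.reference import (
    MT_LENGTH,
    VariantSpec,
    apply_variants,
    diff_substitutions,
    reverse_complement,
)
from mitowgs.simulate import (
    BUILTIN_DONORS,
    PHP,
    Contaminant,
    TruthSpec,
    build_numt_donor,
    read_fastq,
    read_truth,
    simulate_sample,
    write_fastq,
    write_truth,
)


class TestBuiltinDonors:
    def test_hvs1_signature_has_six_variants_in_region(self):
        donor = build_numt_donor("HVS1_sig")
        assert len(donor.variants) == 6
        assert (donor.source_region.start, donor.source_region.end) \
            == (16_380, 16_535)
        assert all(donor.source_region.contains(v.position)
                   for v in donor.variants)

    def test_nd5_signature_has_three_variants_in_region(self):
        donor = build_numt_donor("ND5_sig")
        assert len(donor.variants) == 3
        assert (donor.source_region.start, donor.source_region.end) \
            == (13_060, 13_110)

    @pytest.mark.parametrize("name", ["HVS1_sig", "ND5_sig"])
    def test_donor_differs_from_reference_only_inside_region(self, rcrs, name):
        donor = BUILTIN_DONORS[name]
        seq = apply_variants(rcrs, list(donor.variants))
        for v in diff_substitutions(rcrs, seq):
            assert donor.source_region.contains(v.position)

    def test_unknown_donor_rejected(self):
        with pytest.raises(KeyError):
            build_numt_donor("nope")

    def test_copy_fraction_validated(self):
        with pytest.raises(ValueError):
            build_numt_donor("ND5_sig", 1.2)


class TestSimulateSample:
    def test_same_seed_is_byte_identical(self, rcrs, clean_spec, clean_sample):
        reads1, truth1, _res = clean_sample
        reads2, truth2 = simulate_sample(clean_spec, rcrs, "clean")
        assert truth1.equals(truth2)
        assert all(a.sequence == b.sequence and a.qualities == b.qualities
                   for a, b in zip(reads1, reads2))

    def test_noiseless_reads_are_circular_substrings(self, rcrs, clean_sample):
        reads, _truth, _res = clean_sample
        hap = apply_variants(rcrs, [VariantSpec.parse("A263G"),
                                    VariantSpec.parse("T16093C")])
        doubled = hap + hap
        for r in reads[:4000]:
            assert (r.sequence in doubled
                    or reverse_complement(r.sequence) in doubled)

    def test_truth_rows_match_pair_count(self, clean_sample):
        reads, truth, _res = clean_sample
        assert len(reads) == 2 * len(truth)
        assert set(truth.read_id) == {r.id for r in reads}

    def test_php_minor_count_within_binomial_noise(self, rcrs):
        """Planted 20% heteroplasmy at 1000X recovers ~200 minor reads."""
        depth, frac = 1000.0, 0.20
        spec = TruthSpec(phps=(PHP(16_093, "C", frac),), target_depth=depth,
                         error_rate=0.0, seed=9)
        reads, _ = simulate_sample(spec, rcrs)
        mapping = map_reads(reads, Aligner(rcrs), DEFAULT_PARAMS)
        counts = np.zeros(4, dtype=int)
        for rec in mapping.records:
            off = (16_093 - rec.ref_start) % MT_LENGTH
            if off < rec.codes.size:
                counts[rec.codes[off]] += 1
        total = counts.sum()
        minor = counts[1]  # C
        sd = np.sqrt(total * frac * (1 - frac))
        assert abs(minor - frac * total) <= 3 * sd

    def test_donor_local_read_fraction_converges(self, rcrs):
        """Realized donor share over its span matches copy_fraction (3 SD)."""
        f = 0.10
        spec = TruthSpec(donors=(build_numt_donor("HVS1_sig", f),),
                         target_depth=1500.0, error_rate=0.0, seed=13)
        _reads, truth = simulate_sample(spec, rcrs)
        # count fragments covering the middle of the signature span
        probe = 16_450
        cover_mt = cover_d = 0
        rl, L = spec.read_length, MT_LENGTH
        for row in truth.itertuples():
            start = row.truth_start
            # conservative: count fragments whose first read covers the probe
            if (probe - start) % L < rl:
                if row.origin == "mtDNA":
                    cover_mt += 1
                else:
                    cover_d += 1
        total = cover_mt + cover_d
        sd = np.sqrt(total * f * (1 - f))
        assert abs(cover_d - f * total) <= 3 * sd

    def test_coverage_uniform_across_origin(self, rcrs, clean_sample):
        """No coverage dip at the circle origin.

        Fragment starts are uniform on the circle, so start counts over 100
        bins are multinomial and a plain chi-square applies; read depth
        itself is checked at the origin junction (correlated, so no
        chi-square there).
        """
        _reads, truth, res = clean_sample
        starts = truth.loc[truth.origin == "mtDNA", "truth_start"].to_numpy()
        bins = np.histogram(starts, bins=100, range=(1, MT_LENGTH + 1))[0]
        chi2 = ((bins - bins.mean()) ** 2 / bins.mean()).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=99)
        depth = res.workflow.first_pass.depth_per_position()
        assert depth[0] > 0.5 * depth.mean()
        assert depth[-1] > 0.5 * depth.mean()

    def test_post_homopolymer_boost_elevates_miscalls(self, rcrs):
        """Miscall rate within 3 bp after runs >= 4 exceeds background."""
        spec = TruthSpec(target_depth=120.0, error_rate=0.002,
                         post_homopolymer_boost=20.0, seed=21)
        reads, truth = simulate_sample(spec, rcrs)
        seq = rcrs.sequence
        # positions (0-based) within 3 bp 3' of a >=4 run, on the forward strand
        boosted = set()
        i = 0
        while i < MT_LENGTH:
            j = i
            while j < MT_LENGTH and seq[j] == seq[i]:
                j += 1
            if j - i >= 4:
                boosted.update(range(j, min(j + 3, MT_LENGTH)))
            i = j
        err_b = tot_b = err_n = tot_n = 0
        for r, row in zip(reads[::2], truth.itertuples()):
            start = row.truth_start - 1
            for k, base in enumerate(r.sequence):
                p = (start + k) % MT_LENGTH
                hit = base != seq[p]
                if p in boosted:
                    tot_b += 1
                    err_b += hit
                else:
                    tot_n += 1
                    err_n += hit
        assert err_b / tot_b > 3 * (err_n / tot_n)

    def test_error_free_requires_read_shorter_than_insert(self):
        with pytest.raises(ValueError, match="insert"):
            TruthSpec(read_length=400, insert_mean=350).validate()

    def test_donor_fractions_must_sum_below_one(self):
        spec = TruthSpec(donors=(build_numt_donor("ND5_sig", 0.6),
                                 build_numt_donor("HVS1_sig", 0.5)))
        with pytest.raises(ValueError, match="donor fractions"):
            spec.validate()


class TestIO:
    def test_fastq_round_trip(self, tmp_path, rcrs):
        spec = TruthSpec(target_depth=5.0, seed=3)
        reads, truth = simulate_sample(spec, rcrs, "io")
        r1, r2 = tmp_path / "R1.fastq", tmp_path / "R2.fastq"
        write_fastq(reads, r1, r2)
        back = read_fastq(r1, r2)
        assert len(back) == len(reads)
        orig = sorted(reads, key=lambda r: (r.id, r.mate))
        for a, b in zip(orig, back):
            assert (a.id, a.mate, a.sequence, a.qualities,
                    a.truth_origin, a.truth_start) == \
                   (b.id, b.mate, b.sequence, b.qualities,
                    b.truth_origin, b.truth_start)
        # paired files have equal record counts
        assert r1.read_text().count("\n") == r2.read_text().count("\n")
        tpath = tmp_path / "truth.tsv"
        write_truth(truth, tpath)
        assert read_truth(tpath).equals(truth)

    def test_empty_read_set_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_fastq([], tmp_path / "a", tmp_path / "b")
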