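"""Variant detection, quality filtering and forensic haplotype emission."""

import numpy as np
import pytest

from mitowgs.call import (
    ASTRETCH_ZONES,
    CallThresholds,
    MixedPosition,
    PileupProfiles,
    detect_variants,
    filter_astretch_artifacts,
    finalize_haplotype,
    haplotype_string,
    pileup,
    quality_filter,
    resolve_length_heteroplasmy,
    shift_indels_3prime,
)
from mitowgs.reference import MT_LENGTH, VariantSpec, parse_haplotype
from mitowgs.simulate import PHP, TruthSpec, simulate_sample
from mitowgs.pipeline import process_sample
from tests.conftest import make_mapping


def make_profiles(rcrs, counts_by_pos):
    """Profiles with explicit per-position base counts, Q35 throughout."""
    profiles = PileupProfiles(MT_LENGTH)
    for pos, counts in counts_by_pos.items():
        for base, n in counts.items():
            i = 4 if base == "del" else "ACGT".index(base)
            profiles.counts_fwd[pos - 1, i] = n - n // 2
            profiles.counts_rev[pos - 1, i] = n // 2
            if i < 4:
                profiles.qual_sums[pos - 1, i] = 35 * n
    return profiles


def fill_depth(rcrs, profiles, depth=1000):
    """Give every untouched position a clean reference pileup."""
    untouched = profiles.counts.sum(axis=1) == 0
    idx = np.flatnonzero(untouched)
    codes = rcrs.codes[idx]
    profiles.counts_fwd[idx, codes] = depth - depth // 2
    profiles.counts_rev[idx, codes] = depth // 2
    profiles.qual_sums[idx, codes] = 35 * depth
    return profiles


class TestQualityFilter:
    def test_high_quality_base_accepted(self):
        assert quality_filter([40] * 21, 10)

    def test_central_quality_below_minimum_rejected(self):
        quals = [40] * 21
        quals[10] = 29
        assert not quality_filter(quals, 10)

    def test_uniform_q35_read_fully_accepted(self):
        quals = [35] * 150
        assert all(quality_filter(quals, i) for i in range(150))

    def test_low_neighborhood_rejects_even_good_base(self):
        quals = [10] * 21
        quals[10] = 40
        assert not quality_filter(quals, 10)

    def test_window_truncated_at_read_ends(self):
        assert quality_filter([35, 35, 35], 0)


class TestDetectVariants:
    def test_minor_frequency_thresholds(self, rcrs):
        profiles = make_profiles(rcrs, {1000: {"A": 920, "G": 80}})
        t5 = detect_variants(profiles, rcrs, CallThresholds(detect_freq=0.05))
        mixed = [m for m in t5.mixed if m.position == 1000]
        assert len(mixed) == 1 and mixed[0].minor_freq == pytest.approx(0.08)
        t10 = detect_variants(profiles, rcrs, CallThresholds(detect_freq=0.10))
        assert not [m for m in t10.mixed if m.position == 1000]

    def test_one_percent_minor_never_called(self, rcrs):
        profiles = make_profiles(rcrs, {1000: {"A": 990, "G": 10}})
        for freq in (0.02, 0.05, 0.10):
            res = detect_variants(profiles, rcrs,
                                  CallThresholds(detect_freq=freq))
            assert not [m for m in res.mixed if m.position == 1000]

    @pytest.mark.parametrize("bases,code", [
        (("A", "G"), "R"), (("C", "T"), "Y"),
    ])
    def test_iupac_emission(self, rcrs, bases, code):
        major, minor = bases
        profiles = make_profiles(rcrs, {2000: {major: 900, minor: 100}})
        res = detect_variants(profiles, rcrs, CallThresholds(detect_freq=0.05))
        mp = [m for m in res.mixed if m.position == 2000][0]
        assert mp.iupac == code

    def test_three_alleles_routed_to_multiallelic(self, rcrs):
        profiles = make_profiles(rcrs,
                                 {3000: {"A": 800, "G": 120, "C": 80}})
        res = detect_variants(profiles, rcrs, CallThresholds(detect_freq=0.05))
        assert 3000 in res.multi_allelic
        assert not [m for m in res.mixed if m.position == 3000]

    def test_low_depth_positions_flagged_not_called(self, rcrs):
        profiles = make_profiles(rcrs, {4000: {"A": 50, "G": 30}})
        res = detect_variants(profiles, rcrs, CallThresholds())
        assert 4000 in res.below_threshold
        assert not [m for m in res.mixed if m.position == 4000]

    def test_threshold_filter_promotes_major_of_dropped_mixed(self, rcrs):
        # non-reference major with a 7% reference minor: homoplasmic at 10%
        ref_base = rcrs.base(5000)
        alt = "A" if ref_base != "A" else "G"
        profiles = make_profiles(rcrs, {5000: {alt: 930, ref_base: 70}})
        t5 = detect_variants(profiles, rcrs, CallThresholds(detect_freq=0.05))
        assert [m.position for m in t5.mixed] == [5000]
        t10 = t5.filter(0.10)
        assert not t10.mixed
        assert any(v.position == 5000 and v.alt == alt
                   for v in t10.homoplasmic)


class TestPileup:
    def test_depth_conservation(self, rcrs):
        mapping = make_mapping(rcrs, [("a", 1, 10, {}), ("b", 1, 16_500, {}),
                                      ("c", 2, 8000, {})])
        profiles = pileup(mapping)
        assert profiles.depth.sum() == 3 * 150

    def test_empty_mapping_gives_zero_depth(self, rcrs):
        from mitowgs.align import ReadMapping, STRICT_PARAMS
        profiles = pileup(ReadMapping(rcrs, STRICT_PARAMS, []))
        assert profiles.depth.sum() == 0

    def test_simulated_depth_near_target(self, clean_sample):
        _reads, _truth, res = clean_sample
        depth = res.profiles.depth
        target = 200.0
        sd = np.sqrt(target)
        assert abs(depth.mean() - target) < 3 * sd
        # noiseless sample: a single base observed at every position
        assert ((res.profiles.counts > 0).sum(axis=1) == 1).all()

    def test_low_quality_bases_excluded(self, rcrs):
        mapping = make_mapping(rcrs, [("a", 1, 100, {})])
        mapping.records[0].quals[:] = 20  # below Q30 everywhere
        profiles = pileup(mapping)
        assert profiles.depth.sum() == 0


class TestIndelNomenclature:
    def test_insertion_shifts_to_run_end(self, rcrs):
        # C inserted at 311 inside the 311-315 C run -> 315.1C
        calls = [VariantSpec(311, "ins", alt="C", insert_index=1)]
        out = shift_indels_3prime(calls, rcrs)
        assert [v.token() for v in out] == ["315.1C"]

    def test_deletion_shifts_to_run_end(self, rcrs):
        out = shift_indels_3prime([VariantSpec(312, "del")], rcrs)
        assert [v.token() for v in out] == ["315del"]

    def test_indel_outside_run_unchanged(self, rcrs):
        # find a position whose neighbours differ
        pos = next(p for p in range(1000, 2000)
                   if rcrs.base(p - 1) != rcrs.base(p) != rcrs.base(p + 1))
        out = shift_indels_3prime([VariantSpec(pos, "del")], rcrs)
        assert out[0].position == pos


class TestLengthHeteroplasmy:
    def _lhp_mapping(self, rcrs, n_ins, n_ref):
        """Reads spanning the HVS2 C-stretch; n_ins carry one extra C."""
        reads = []
        for i in range(n_ref):
            reads.append((f"ref{i}", 1, 250, {}))
        mapping = make_mapping(rcrs, reads) if reads else None
        from mitowgs.align import AlignmentRecord
        records = mapping.records if mapping else []
        for i in range(n_ins):
            # 150-bp read starting at 250 with a C inserted after 315
            pos = 250 - 1 + np.arange(149)
            codes = rcrs.codes[pos % MT_LENGTH].copy()
            before = 315 - 250 + 1  # read bases up to and incl. position 315
            seq = np.concatenate([codes[:before],
                                  np.array([1], dtype=np.uint8),
                                  codes[before:]])
            records.append(AlignmentRecord(
                read_id=f"ins{i}", mate=1, ref_start=250, strand="+",
                codes=seq, quals=np.full(150, 35, dtype=np.uint8), nm=1,
                length_fraction=1.0, similarity_fraction=149 / 150,
                accepted=True,
                cigar=(("=", before), ("I", 1), ("=", 149 - before)),
            ))
        from mitowgs.align import ReadMapping, STRICT_PARAMS
        return ReadMapping(rcrs, STRICT_PARAMS, records,
                           n_input=len(records))

    def test_majority_molecule_reported(self, rcrs):
        mapping = self._lhp_mapping(rcrs, n_ins=12, n_ref=8)
        calls = resolve_length_heteroplasmy(mapping, rcrs)
        run_311 = [c for c in calls if c.run.start == 311][0]
        assert run_311.major_length == 6
        assert [v.token() for v in run_311.variants()] == ["315.1C"]

    def test_minority_insertion_dropped(self, rcrs):
        mapping = self._lhp_mapping(rcrs, n_ins=8, n_ref=12)
        calls = resolve_length_heteroplasmy(mapping, rcrs)
        run_311 = [c for c in calls if c.run.start == 311][0]
        assert run_311.major_length == 5
        assert run_311.variants() == []

    def test_fifty_fifty_tie_reports_shorter_molecule(self, rcrs):
        mapping = self._lhp_mapping(rcrs, n_ins=10, n_ref=10)
        calls = resolve_length_heteroplasmy(mapping, rcrs)
        run_311 = [c for c in calls if c.run.start == 311][0]
        assert run_311.major_length == 5

    def test_no_spanning_reads_warns(self, rcrs):
        mapping = make_mapping(rcrs, [("far", 1, 5000, {})])
        calls = resolve_length_heteroplasmy(mapping, rcrs)
        assert all(c.warning == "no spanning reads" for c in calls)


class TestAStretchFilter:
    def test_artifacts_removed_and_tagged(self):
        mps = [
            MixedPosition(302, "A", "C", 0.08, 1000, "M"),    # HVS2 A-stretch
            MixedPosition(16_183, "A", "C", 0.07, 1000, "M"),  # HVS1 A-stretch
            MixedPosition(16_093, "T", "C", 0.20, 1000, "Y"),
        ]
        kept, artifacts = filter_astretch_artifacts(mps)
        assert [m.position for m in kept] == [16_093]
        assert {m.position for m in artifacts} == {302, 16_183}
        assert all(m.classification == "artifact" for m in artifacts)


class TestHaplotypeEmission:
    def test_tokens_match_forensic_nomenclature(self, rcrs, clean_sample):
        _reads, _truth, res = clean_sample
        assert haplotype_string(res.haplotype) == "A263G T16093C"
        assert res.haplotype.range_header() == f"1-{MT_LENGTH}"

    def test_mixed_position_rendered_with_iupac(self, rcrs):
        spec = TruthSpec(phps=(PHP(16_093, "C", 0.30),),
                         target_depth=150.0, error_rate=0.0, seed=55)
        reads, _ = simulate_sample(spec, rcrs)
        res = process_sample("php", reads, rcrs)
        assert haplotype_string(res.haplotype) == "T16093Y"

    def test_empty_call_set_gives_empty_haplotype(self, rcrs):
        spec = TruthSpec(target_depth=120.0, error_rate=0.0, seed=56)
        reads, _ = simulate_sample(spec, rcrs)
        res = process_sample("ref", reads, rcrs)
        assert haplotype_string(res.haplotype) == ""

    def test_haplotype_parse_emit_round_trip(self):
        text = "T152Y A263G 315.1C T16093Y"
        variants = parse_haplotype(text)
        from mitowgs.reference import haplotype_tokens
        assert haplotype_tokens(variants) == text

    def test_error_free_sample_reproduces_base_haplotype(self, clean_sample):
        """With zero error rate and no donors the haplotype is exact."""
        _reads, _truth, res = clean_sample
        assert [v.token() for v in res.haplotype.substitutions] == \
            ["A263G", "T16093C"]
        assert not res.haplotype.mixed
        assert not res.haplotype.indels


class TestPHPRecovery:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_recovery_above_threshold_plus_noise(self, rcrs, seed):
        """Minors >= threshold + 3 binomial SD are always recovered; minors
        well below threshold - 3 SD never are."""
        depth = 400.0
        t = 0.05
        sd = np.sqrt(t * (1 - t) / depth)
        hi = t + 3 * sd  # ~8.3%
        spec = TruthSpec(phps=(PHP(6000, "A" if rcrs.base(6000) != "A" else "C", hi),
                               PHP(9000, "A" if rcrs.base(9000) != "A" else "C", 0.01)),
                         target_depth=depth, seed=seed)
        reads, _ = simulate_sample(spec, rcrs)
        res = process_sample(f"rec{seed}", reads, rcrs)
        called = {m.position for m in res.haplotype.mixed}
        assert 6000 in called
        assert 9000 not in called
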