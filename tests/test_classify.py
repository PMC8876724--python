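"""NUMT-vs-PHP rule engine: clustering, phasing, both review stages."""

import itertools

import numpy as np
import pytest

from mitowgs.call import MixedPosition
from mitowgs.classify import (
    NUMTCatalog,
    PHPHotspotList,
    ReviewCriteria,
    SampleCalls,
    classify_dataset,
    classify_sample,
    detect_clusters,
    initial_review,
    phase_check,
    secondary_review,
    strand_balance_ok,
)
from mitowgs.pipeline import classify_cohort
from tests.conftest import make_mapping


def mp(position, major, minor, freq, depth=1000, fwd=None, rev=None):
    total = max(int(round(freq * depth)), 1)
    fwd = total - total // 2 if fwd is None else fwd
    rev = total // 2 if rev is None else rev
    from mitowgs.reference import iupac_code
    return MixedPosition(position=position, major=major, minor=minor,
                         minor_freq=freq, depth=depth,
                         iupac=iupac_code(major, minor),
                         minor_fwd=fwd, minor_rev=rev)


def sample_with_phased_reads(rcrs, mixed, low_band=(), avg_depth=800.0,
                             phased_groups=(), n_pairs=40,
                             sample_id="s"):
    """SampleCalls whose mapping carries in-phase minor reads for each group.

    ``phased_groups``: iterables of (position, minor) whose minors co-occur
    on the same synthetic reads (NUMT-like); every mixed position not in a
    group gets its own independent minor reads (PHP-like).
    """
    reads = []
    grouped = set()
    for g, group in enumerate(phased_groups):
        grouped.update(p for p, _b in group)
        span = [p for p, _b in group]
        start = min(span) - 10
        subs = {p: b for p, b in group}
        for i in range(max(3, n_pairs // 4)):
            reads.append((f"g{g}_{i}", 1, start, subs))
    for m in mixed + list(low_band):
        if m.position in grouped:
            continue
        k = max(3, int(n_pairs * m.minor_freq))
        for i in range(k):
            reads.append((f"m{m.position}_{i}", 1, m.position - 20,
                          {m.position: m.minor}))
    for i in range(n_pairs):
        reads.append((f"bg{i}", 1, (list(grouped) + [mixed[0].position])[0] - 30, {}))
    mapping = make_mapping(rcrs, reads, read_length=300)
    return SampleCalls(sample_id=sample_id, mixed=list(mixed),
                       low_band=list(low_band), mapping=mapping,
                       avg_depth=avg_depth, reference=rcrs)


class TestClusters:
    def test_nd5_trio_forms_one_cluster(self):
        assert detect_clusters([13_062, 13_095, 13_105], 500) == \
            [[13_062, 13_095, 13_105]]

    def test_distant_positions_stay_separate(self):
        assert detect_clusters([263, 13_062], 500) == [[263], [13_062]]

    def test_cluster_wraps_origin(self):
        clusters = detect_clusters([16_500, 100], 500)
        assert clusters == [[16_500, 100]]

    def test_invariant_to_input_order(self):
        pos = [16_444, 13_062, 16_496, 13_095, 263]
        ref = detect_clusters(pos, 500)
        for perm in itertools.permutations(pos):
            assert detect_clusters(list(perm), 500) == ref


class TestPhaseCheck:
    def test_donor_variants_in_phase(self, rcrs, donor_sample):
        """16,444 and 16,496 are 52 bp apart and ride the same donor reads."""
        _reads, _truth, res = donor_sample
        status = phase_check(res.workflow.final, 16_444, 16_496, "T", "A")
        assert status == "in_phase"

    def test_independent_phps_discordant(self, rcrs):
        reads = [(f"a{i}", 1, 1000, {1050: "A" if rcrs.base(1050) != "A" else "C"})
                 for i in range(10)]
        minor2 = "A" if rcrs.base(1100) != "A" else "C"
        reads += [(f"b{i}", 1, 1000, {1100: minor2}) for i in range(10)]
        reads += [(f"c{i}", 1, 1000, {}) for i in range(20)]
        mapping = make_mapping(rcrs, reads)
        minor1 = "A" if rcrs.base(1050) != "A" else "C"
        assert phase_check(mapping, 1050, 1100, minor1, minor2) == "discordant"

    def test_distant_positions_unassessable(self, rcrs, donor_sample):
        """1,000+ bp apart with ~350-bp inserts: no covering pairs."""
        _reads, _truth, res = donor_sample
        assert phase_check(res.workflow.final, 13_062, 16_444,
                           "G", "T") == "unassessable"

    def test_too_few_covering_pairs_unassessable(self, rcrs):
        mapping = make_mapping(rcrs, [("a", 1, 1000, {})] * 3)
        assert phase_check(mapping, 1050, 1100, "A", "A") == "unassessable"


class TestStrandBalance:
    def test_balanced_minor_passes(self):
        assert strand_balance_ok(mp(100, "A", "G", 0.1, fwd=30, rev=28))

    def test_single_strand_minor_fails(self):
        assert not strand_balance_ok(mp(100, "A", "G", 0.1, fwd=58, rev=0))


class TestInitialReview:
    def test_nd5_donor_trio_all_labelled(self, rcrs, donor_sample):
        _reads, _truth, res = donor_sample
        table = classify_cohort([res])
        nd5 = table[table.position.isin([13_062, 13_095, 13_105])]
        assert (nd5.label == "NUMT").all()
        assert (nd5.stage == "initial").all()

    def test_hvs1_donor_six_labelled(self, rcrs, donor_sample):
        _reads, _truth, res = donor_sample
        table = classify_cohort([res])
        hvs1 = table[(table.position >= 16_390) & (table.position <= 16_527)]
        assert len(hvs1) == 6
        assert (hvs1.label == "NUMT").all()

    def test_isolated_hotspot_php_not_labelled(self, rcrs):
        sample = sample_with_phased_reads(
            rcrs, [mp(16_093, "T", "C", 0.20)], avg_depth=900.0)
        labels = initial_review(sample, ReviewCriteria(), NUMTCatalog.builtin())
        assert labels == {}


class TestSecondaryReview:
    def test_high_frequency_high_depth_retained_as_php(self, rcrs):
        """A 15.3% minor at 3287X average depth fails the entry gate on
        both counts and stays a heteroplasmy."""
        sample = sample_with_phased_reads(
            rcrs, [mp(13_105, "A", "G", 0.153, depth=3287)],
            avg_depth=3287.0)
        labels = secondary_review(sample, ReviewCriteria(),
                                  NUMTCatalog.builtin(),
                                  PHPHotspotList.builtin(), {}, {})
        rec = labels[13_105]
        assert rec.label == "PHP"
        assert "fails_entry_gate" in rec.rules_fired

    def test_low_freq_low_depth_with_partners_is_numt(self, rcrs):
        """5.4% minor, low average depth, in phase with an HVS1 catalog
        partner in the 2-5% band: classified as a NUMT variant."""
        g16129a = mp(16_129, "G", "A", 0.054)
        partner = mp(16_390, "G", "A", 0.035)
        sample = sample_with_phased_reads(
            rcrs, [g16129a], low_band=[partner], avg_depth=700.0,
            phased_groups=[[(16_129, "A"), (16_390, "A")]])
        labels = secondary_review(sample, ReviewCriteria(),
                                  NUMTCatalog.builtin(),
                                  PHPHotspotList.builtin(), {}, {})
        rec = labels[16_129]
        assert rec.label == "NUMT"
        assert {"catalog", "low_band_in_phase"} <= set(rec.rules_fired)

    def test_hotspot_above_gate_is_php_despite_catalog(self, rcrs):
        """T146Y at 12%: hotspot and above the gate, stays a PHP."""
        sample = sample_with_phased_reads(
            rcrs, [mp(146, "T", "C", 0.12)], avg_depth=800.0)
        labels = secondary_review(sample, ReviewCriteria(),
                                  NUMTCatalog.builtin(),
                                  PHPHotspotList.builtin(), {}, {})
        assert labels[146].label == "PHP"

    def test_recurrence_vote(self, rcrs):
        pos = 7220
        minor = "A" if rcrs.base(pos) != "A" else "C"
        token = f"{rcrs.base(pos)}{pos}{minor}"
        sample = sample_with_phased_reads(
            rcrs, [mp(pos, rcrs.base(pos), minor, 0.06)], avg_depth=600.0)
        labels = secondary_review(sample, ReviewCriteria(),
                                  NUMTCatalog.empty(),
                                  PHPHotspotList.builtin(),
                                  {token: 5}, {})
        rec = labels[pos]
        assert rec.label == "NUMT"
        assert {"recurrent_numt", "not_php_hotspot"} <= set(rec.rules_fired)


class TestClassifyDataset:
    def test_pure_cohort_has_no_numt_labels(self, rcrs, clean_sample):
        _reads, _truth, res = clean_sample
        table = classify_cohort([res])
        assert not (table.label == "NUMT").any()

    def test_donor_and_php_truthfully_separated(self, rcrs, donor_sample):
        """Donors at 8% and a 20% PHP: classification matches truth."""
        _reads, _truth, res = donor_sample
        table = classify_cohort([res])
        donor_positions = {13_062, 13_095, 13_105, 16_390, 16_399, 16_444,
                           16_496, 16_519, 16_527}
        for row in table.itertuples():
            if row.position in donor_positions:
                assert row.label == "NUMT", row
            elif row.position == 2887:
                assert row.label == "PHP", row

    def test_catalog_ablation_keeps_phase_based_detection(self, rcrs,
                                                          donor_sample):
        """Without any catalog the in-phase cluster rules still catch the
        donor signatures."""
        _reads, _truth, res = donor_sample
        table = classify_cohort([res], catalog=NUMTCatalog.empty())
        nd5 = table[table.position.isin([13_062, 13_095, 13_105])]
        assert (nd5.label == "NUMT").all()

    def test_classification_is_deterministic(self, rcrs, donor_sample):
        _reads, _truth, res = donor_sample
        t1 = classify_cohort([res])
        t2 = classify_cohort([res])
        assert t1.equals(t2)

    def test_every_position_gets_exactly_one_label(self, rcrs, donor_sample):
        _reads, _truth, res = donor_sample
        table = classify_cohort([res])
        assert len(table) == len(res.haplotype.mixed)
        assert table.label.isin(["NUMT", "PHP", "artifact", "ignored"]).all()
        assert not table.duplicated(["sample", "position"]).any()
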