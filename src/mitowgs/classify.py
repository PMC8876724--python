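"""Rule-based classification of mixed positions: NUMT variant vs PHP.

Reproduces, as an explicit deterministic rule engine, the two-stage review
used to separate variants caused by co-aligning nuclear mtDNA segments
(NUMTs) from authentic point heteroplasmies (PHPs):

Initial review — a mixed position is provisionally a NUMT variant if
(a) it lies in a documented NUMT hotspot region (nps 12,612-13,105 or
16,390-16,527) and is in phase with at least one other mixed or
low-band (2-5%) position in that region; or (b) it is in phase with a
catalogued NUMT variant; or (c) it belongs to a positional cluster of
two or more mixed positions of which at least half are catalogued or
hotspot-region members.

Secondary review — remaining mixed positions enter only if the minor
nucleotide frequency is below 10% *and* the sample's average read depth
is at most 1500X (NUMT interference was only ever observed under those
conditions); within the review a position is a NUMT variant when at
least ``min_votes`` (default 2) of four indicators concur: catalogue
membership; the same variant NUMT-labelled in >= ``recurrence_min``
other samples; an in-phase low-band partner; and not being a known PHP
hotspot. Everything else — including every position failing the entry
gate — is a probable PHP.

Phasing is read-pair based: two positions are in phase when at least 90%
of the minor-bearing pairs covering both carry both minor bases; fewer
than five covering pairs is unassessable (short inserts make distant
pairs unassessable by construction). A forward/reverse strand-balance
check tags positions whose minor allele is effectively single-stranded
as artifacts before review.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd

from .align import ReadMapping
from .call import MixedPosition
from .reference import BASES, MT_LENGTH, CircularRegion, ReferenceGenome

__all__ = [
    "NUMTCatalog", "PHPHotspotList", "ReviewCriteria", "ClassificationRecord",
    "SampleCalls", "detect_clusters", "phase_check", "strand_balance_ok",
    "initial_review", "secondary_review", "classify_dataset",
]


@dataclass(frozen=True)
class NUMTCatalog:
    """Catalog of (position, alternate-base) pairs associated with NUMTs."""

    entries: frozenset[tuple[int, str]]
    sources: tuple[str, ...] = ()

    def __contains__(self, item: tuple[int, str]) -> bool:
        return (int(item[0]), str(item[1]).upper()) in self.entries

    def positions(self) -> set[int]:
        return {p for p, _b in self.entries}

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "NUMTCatalog":
        entries = frozenset(
            (int(r.position), str(r.alt).upper())
            for r in frame.itertuples()
        )
        sources = tuple(sorted(set(frame.get("source", pd.Series(dtype=str)))))
        return cls(entries, sources)

    @classmethod
    def from_tsv(cls, path) -> "NUMTCatalog":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    @classmethod
    def builtin(cls) -> "NUMTCatalog":
        with resources.as_file(
            resources.files("mitowgs.data") / "numt_catalog.tsv"
        ) as p:
            return cls.from_tsv(p)

    @classmethod
    def empty(cls) -> "NUMTCatalog":
        return cls(frozenset())


@dataclass(frozen=True)
class PHPHotspotList:
    """Positions at which point heteroplasmy recurs across individuals."""

    positions: frozenset[int]

    def __contains__(self, position: int) -> bool:
        return int(position) in self.positions

    @classmethod
    def from_tsv(cls, path) -> "PHPHotspotList":
        frame = pd.read_csv(path, sep="\t")
        return cls(frozenset(int(p) for p in frame["position"]))

    @classmethod
    def builtin(cls) -> "PHPHotspotList":
        with resources.as_file(
            resources.files("mitowgs.data") / "php_hotspots.tsv"
        ) as p:
            return cls.from_tsv(p)


@dataclass(frozen=True)
class ReviewCriteria:
    """All thresholds of the two-stage review."""

    secondary_max_freq: float = 0.10
    secondary_max_depth: float = 1500.0
    hotspot_regions: tuple[CircularRegion, ...] = (
        CircularRegion(12_612, 13_105),
        CircularRegion(16_390, 16_527),
    )
    low_band: tuple[float, float] = (0.02, 0.05)
    cluster_window: int = 500
    recurrence_min: int = 3
    min_votes: int = 2
    strand_min_fraction: float = 0.10
    phase_min_pairs: int = 5
    phase_min_concordance: float = 0.90
    ignore_16093: bool = False

    def in_hotspot_region(self, position: int) -> Optional[CircularRegion]:
        for region in self.hotspot_regions:
            if region.contains(position):
                return region
        return None


@dataclass
class ClassificationRecord:
    sample_id: str
    position: int
    major: str
    minor: str
    minor_freq: float
    depth: int
    label: str                      # 'NUMT' | 'PHP' | 'artifact' | 'ignored'
    stage: str                      # 'initial' | 'secondary' | 'gate' | 'pre'
    rules_fired: tuple[str, ...]
    variant_token: str
    phase_partners: tuple[int, ...] = ()
    catalog_hit: bool = False
    recurrence: int = 0


@dataclass
class SampleCalls:
    """Classifier-facing view of one called sample."""

    sample_id: str
    mixed: list[MixedPosition]        # at the analysis threshold, post-artifact
    low_band: list[MixedPosition]     # 2-5% band observations
    mapping: Optional[ReadMapping]    # final mapping, for phasing
    avg_depth: float
    reference: ReferenceGenome


# ---------------------------------------------------------------------------
# Primitive checks
# ---------------------------------------------------------------------------

def detect_clusters(positions: Sequence[int], window: int = 500,
                    genome_length: int = MT_LENGTH) -> list[list[int]]:
    """Maximal groups of positions with consecutive circular gaps <= window.

    Invariant to input order; the first and last group merge when the gap
    across the origin is within the window.
    """
    pos = sorted(set(int(p) for p in positions))
    if not pos:
        return []
    clusters: list[list[int]] = [[pos[0]]]
    for p in pos[1:]:
        if p - clusters[-1][-1] <= window:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    if len(clusters) > 1:
        wrap_gap = pos[0] + genome_length - pos[-1]
        if wrap_gap <= window:
            clusters[0] = clusters.pop() + clusters[0]
    return clusters


class _PhaseCache:
    """Memoized pairwise phasing over one sample's mapping."""

    def __init__(self, mapping: Optional[ReadMapping],
                 criteria: ReviewCriteria):
        self.mapping = mapping
        self.criteria = criteria
        self._bases: dict[int, dict[str, int]] = {}
        self._cache: dict[tuple, str] = {}

    def bases(self, position: int) -> dict[str, int]:
        if position not in self._bases:
            self._bases[position] = self.mapping.pair_bases(position)
        return self._bases[position]

    def check(self, pos_a: int, minor_a: str, pos_b: int,
              minor_b: str) -> str:
        key = (pos_a, minor_a, pos_b, minor_b)
        if key[:2] > key[2:]:
            key = (pos_b, minor_b, pos_a, minor_a)
        if key not in self._cache:
            self._cache[key] = phase_check(
                self.mapping, key[0], key[2], key[1], key[3], self.criteria
            )
        return self._cache[key]


def phase_check(mapping: Optional[ReadMapping], pos_a: int, pos_b: int,
                minor_a: str, minor_b: str,
                criteria: ReviewCriteria = ReviewCriteria()) -> str:
    """'in_phase' | 'discordant' | 'unassessable' from read-pair evidence."""
    if mapping is None:
        return "unassessable"
    a = mapping.pair_bases(pos_a)
    b = mapping.pair_bases(pos_b)
    covering = a.keys() & b.keys()
    if len(covering) < criteria.phase_min_pairs:
        return "unassessable"
    code_a, code_b = BASES.index(minor_a), BASES.index(minor_b)
    minor_bearing = both = 0
    for rid in covering:
        has_a = a[rid] == code_a
        has_b = b[rid] == code_b
        if has_a or has_b:
            minor_bearing += 1
            if has_a and has_b:
                both += 1
    if minor_bearing == 0:
        return "unassessable"
    if both / minor_bearing >= criteria.phase_min_concordance:
        return "in_phase"
    return "discordant"


def strand_balance_ok(mixed: MixedPosition,
                      min_fraction: float = 0.10) -> bool:
    """Minor allele must be seen on both strands (>= min_fraction on the
    rarer one); positions without strand information pass."""
    total = mixed.minor_fwd + mixed.minor_rev
    if total == 0:
        return True
    return min(mixed.minor_fwd, mixed.minor_rev) / total >= min_fraction


# ---------------------------------------------------------------------------
# Review stages
# ---------------------------------------------------------------------------

def _universe(sample: SampleCalls) -> list[MixedPosition]:
    """Mixed positions available as partners: analysis-threshold + low band."""
    seen = {mp.position for mp in sample.mixed}
    extra = [mp for mp in sample.low_band if mp.position not in seen]
    return list(sample.mixed) + extra


def initial_review(sample: SampleCalls, criteria: ReviewCriteria,
                   catalog: NUMTCatalog,
                   phase: Optional[_PhaseCache] = None,
                   ) -> dict[int, ClassificationRecord]:
    """Provisional NUMT labels from clustering, catalogs and phasing."""
    phase = phase or _PhaseCache(sample.mapping, criteria)
    universe = _universe(sample)
    clusters = detect_clusters([mp.position for mp in universe],
                               criteria.cluster_window)
    cluster_of = {p: cl for cl in clusters for p in cl}
    by_pos = {mp.position: mp for mp in universe}
    labels: dict[int, ClassificationRecord] = {}

    for mp in sample.mixed:
        rules: list[str] = []
        partners: list[int] = []
        region = criteria.in_hotspot_region(mp.position)
        if region is not None:
            for other in universe:
                if other.position == mp.position:
                    continue
                if not region.contains(other.position):
                    continue
                if phase.check(mp.position, mp.minor, other.position,
                               other.minor) == "in_phase":
                    rules.append("hotspot_region_in_phase")
                    partners.append(other.position)
                    break
        for other in universe:
            if other.position == mp.position:
                continue
            if (other.position, other.minor) in catalog:
                if phase.check(mp.position, mp.minor, other.position,
                               other.minor) == "in_phase":
                    rules.append("in_phase_with_catalog")
                    partners.append(other.position)
                    break
        cl = cluster_of.get(mp.position, [mp.position])
        if len(cl) >= 2:
            strong = sum(
                1 for p in cl
                if (p, by_pos[p].minor) in catalog
                or criteria.in_hotspot_region(p) is not None
            )
            if strong >= math.ceil(len(cl) / 2):
                rules.append("cluster_majority")
        if rules:
            labels[mp.position] = ClassificationRecord(
                sample_id=sample.sample_id, position=mp.position,
                major=mp.major, minor=mp.minor, minor_freq=mp.minor_freq,
                depth=mp.depth, label="NUMT", stage="initial",
                rules_fired=tuple(dict.fromkeys(rules)),
                variant_token=mp.variant_token(sample.reference),
                phase_partners=tuple(partners),
                catalog_hit=(mp.position, mp.minor) in catalog,
            )
    return labels


def secondary_review(sample: SampleCalls, criteria: ReviewCriteria,
                     catalog: NUMTCatalog, hotspots: PHPHotspotList,
                     recurrence: dict[str, int],
                     already: dict[int, ClassificationRecord],
                     phase: Optional[_PhaseCache] = None,
                     ) -> dict[int, ClassificationRecord]:
    """Five-criteria assessment of the positions the initial review left."""
    phase = phase or _PhaseCache(sample.mapping, criteria)
    labels: dict[int, ClassificationRecord] = {}
    low_band = [mp for mp in sample.low_band
                if criteria.low_band[0] <= mp.minor_freq < criteria.low_band[1]]
    for mp in sample.mixed:
        if mp.position in already:
            continue
        token = mp.variant_token(sample.reference)
        gate = (mp.minor_freq < criteria.secondary_max_freq
                and sample.avg_depth <= criteria.secondary_max_depth)
        if not gate:
            labels[mp.position] = ClassificationRecord(
                sample_id=sample.sample_id, position=mp.position,
                major=mp.major, minor=mp.minor, minor_freq=mp.minor_freq,
                depth=mp.depth, label="PHP", stage="gate",
                rules_fired=("fails_entry_gate",), variant_token=token,
                catalog_hit=(mp.position, mp.minor) in catalog,
                recurrence=recurrence.get(token, 0),
            )
            continue
        votes: list[str] = []
        partners: list[int] = []
        if (mp.position, mp.minor) in catalog:
            votes.append("catalog")
        if recurrence.get(token, 0) >= criteria.recurrence_min:
            votes.append("recurrent_numt")
        for other in low_band:
            if other.position == mp.position:
                continue
            if phase.check(mp.position, mp.minor, other.position,
                           other.minor) == "in_phase":
                votes.append("low_band_in_phase")
                partners.append(other.position)
                break
        if mp.position not in hotspots:
            votes.append("not_php_hotspot")
        label = "NUMT" if len(votes) >= criteria.min_votes else "PHP"
        labels[mp.position] = ClassificationRecord(
            sample_id=sample.sample_id, position=mp.position,
            major=mp.major, minor=mp.minor, minor_freq=mp.minor_freq,
            depth=mp.depth, label=label, stage="secondary",
            rules_fired=tuple(votes), variant_token=token,
            phase_partners=tuple(partners),
            catalog_hit=(mp.position, mp.minor) in catalog,
            recurrence=recurrence.get(token, 0),
        )
    return labels


def classify_sample(sample: SampleCalls, criteria: ReviewCriteria,
                    catalog: NUMTCatalog, hotspots: PHPHotspotList,
                    recurrence: Optional[dict[str, int]] = None,
                    ) -> list[ClassificationRecord]:
    """Both review stages for one sample (dataset recurrence optional)."""
    phase = _PhaseCache(sample.mapping, criteria)
    pre = _pre_review(sample, criteria)
    labels = initial_review(sample, criteria, catalog, phase)
    labels.update(secondary_review(sample, criteria, catalog, hotspots,
                                   recurrence or {},
                                   {**pre, **labels}, phase))
    merged = {**labels, **pre}
    return [merged[mp.position] for mp in sample.mixed
            if mp.position in merged]


def _pre_review(sample: SampleCalls, criteria: ReviewCriteria,
                ) -> dict[int, ClassificationRecord]:
    """Strand-balance artifact tagging and optional hotspot ignore list."""
    out: dict[int, ClassificationRecord] = {}
    for mp in sample.mixed:
        token = mp.variant_token(sample.reference)
        if not strand_balance_ok(mp, criteria.strand_min_fraction):
            out[mp.position] = ClassificationRecord(
                sample_id=sample.sample_id, position=mp.position,
                major=mp.major, minor=mp.minor, minor_freq=mp.minor_freq,
                depth=mp.depth, label="artifact", stage="pre",
                rules_fired=("strand_imbalance",), variant_token=token,
            )
        elif criteria.ignore_16093 and mp.position == 16_093:
            out[mp.position] = ClassificationRecord(
                sample_id=sample.sample_id, position=mp.position,
                major=mp.major, minor=mp.minor, minor_freq=mp.minor_freq,
                depth=mp.depth, label="ignored", stage="pre",
                rules_fired=("hotspot_ignore_list",), variant_token=token,
            )
    return out


def classify_dataset(samples: Sequence[SampleCalls],
                     criteria: ReviewCriteria = ReviewCriteria(),
                     catalog: Optional[NUMTCatalog] = None,
                     hotspots: Optional[PHPHotspotList] = None,
                     ) -> pd.DataFrame:
    """Classify every mixed position of every sample.

    Two passes: the initial review of all samples feeds dataset-wide
    recurrence counts (number of samples in which a variant was labelled
    NUMT), which the secondary review then uses. Returns one row per mixed
    position; every position carries exactly one label.
    """
    catalog = catalog if catalog is not None else NUMTCatalog.builtin()
    hotspots = hotspots if hotspots is not None else PHPHotspotList.builtin()

    caches = {s.sample_id: _PhaseCache(s.mapping, criteria) for s in samples}
    pre: dict[str, dict[int, ClassificationRecord]] = {}
    initial: dict[str, dict[int, ClassificationRecord]] = {}
    for s in samples:
        pre[s.sample_id] = _pre_review(s, criteria)
        labels = initial_review(s, criteria, catalog, caches[s.sample_id])
        for p in pre[s.sample_id]:
            labels.pop(p, None)
        initial[s.sample_id] = labels

    recurrence: dict[str, int] = {}
    for s in samples:
        for rec in initial[s.sample_id].values():
            recurrence[rec.variant_token] = recurrence.get(rec.variant_token,
                                                           0) + 1

    rows: list[ClassificationRecord] = []
    for s in samples:
        merged = {**pre[s.sample_id], **initial[s.sample_id]}
        merged.update(secondary_review(
            s, criteria, catalog, hotspots, recurrence, merged,
            caches[s.sample_id],
        ))
        for mp in s.mixed:
            rec = merged[mp.position]
            rec.recurrence = recurrence.get(rec.variant_token, 0)
            mp.classification = rec.label if rec.label in ("NUMT", "PHP",
                                                           "artifact") else mp.classification
            rows.append(rec)

    columns = ["sample", "position", "major", "minor", "minor_freq",
               "depth", "label", "stage", "rules_fired", "variant",
               "phase_partners", "catalog_hit", "recurrence"]
    return pd.DataFrame([{
        "sample": r.sample_id, "position": r.position, "major": r.major,
        "minor": r.minor, "minor_freq": r.minor_freq, "depth": r.depth,
        "label": r.label, "stage": r.stage,
        "rules_fired": ",".join(r.rules_fired),
        "variant": r.variant_token,
        "phase_partners": ",".join(str(p) for p in r.phase_partners),
        "catalog_hit": r.catalog_hit, "recurrence": r.recurrence,
    } for r in rows], columns=columns)
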