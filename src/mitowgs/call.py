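"""Low-frequency variant detection and haplotype emission.

Per-position read profiles are built from the final (reference-anchored)
mapping with quality filtering: a base is counted only if its own quality
is at least ``min_quality`` and the mean quality of the +/- ``quality_radius``
bp window on the read (truncated at the read ends) also reaches
``min_quality``. At positions with qualified depth >= ``min_depth`` the
major base is called; a second base at or above the detection threshold
(2%, 5% or 10% of qualified depth) yields a mixed position reported with
the two-base IUPAC code. Positions where three or more bases reach the
threshold are routed to QC as multi-allelic mixture evidence rather than
force-coded.

Haplotype finalization applies the forensic-nomenclature conventions:
indels are shifted 3' within homopolymer runs and written with decimal
suffixes (insertions) or ``del`` (deletions); within configured C-stretch
regions only the major-length molecule is reported (length heteroplasmy is
dropped, point substitutions retained); and mixed positions inside the
A-stretches immediately 5' of the HVS1/HVS2 C-stretches are removed as
post-homopolymer sequencing artifacts. Positions below the depth threshold
are excluded from the reported range unless the sample is nearly complete
(at most ``nearly_complete_max_below`` such positions), in which case a
position is auto-confirmed when depth >= ``confirm_min_depth`` and the
major base reaches ``confirm_major_freq``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .align import ReadMapping, _walk_gapped
from .reference import (
    BASES,
    CircularRegion,
    ReferenceGenome,
    VariantSpec,
    haplotype_tokens,
    homopolymer_run,
    iupac_code,
)

__all__ = [
    "CallThresholds", "PositionProfile", "PileupProfiles", "MixedPosition",
    "CallResult", "MitoHaplotype", "pileup", "quality_filter",
    "detect_variants", "shift_indels_3prime", "resolve_length_heteroplasmy",
    "filter_astretch_artifacts", "finalize_haplotype", "haplotype_string",
    "CSTRETCH_REGIONS", "ASTRETCH_ZONES",
]

_DEL = 4  # index of the deletion "allele" in count arrays

#: HVS2 and HVS1 C-stretch regions subject to length-heteroplasmy filtering.
CSTRETCH_REGIONS = (CircularRegion(303, 315), CircularRegion(16_184, 16_193))
#: A-stretches immediately 5' of the HVS C-stretches: mixtures here are
#: post-homopolymer sequencing artifacts, never reported.
ASTRETCH_ZONES = (CircularRegion(300, 302), CircularRegion(16_180, 16_183))


@dataclass(frozen=True)
class CallThresholds:
    """Depth/quality/frequency gates for variant detection."""

    min_depth: int = 100
    quality_radius: int = 5
    min_quality: int = 30
    detect_freq: float = 0.05
    nearly_complete_max_below: int = 4
    php_expected_max: int = 3
    confirm_min_depth: int = 20
    confirm_major_freq: float = 0.90

    def __post_init__(self) -> None:
        if not 0 < self.detect_freq < 0.5:
            raise ValueError("detect_freq must be in (0, 0.5)")
        if self.min_depth <= 0:
            raise ValueError("min_depth must be positive")


@dataclass
class PositionProfile:
    """Qualified per-base counts at one position."""

    position: int
    counts: dict[str, int]
    insertions: dict[str, int]
    depth: int
    mean_quality: dict[str, float]

    def frequencies(self) -> dict[str, float]:
        if self.depth == 0:
            return {b: 0.0 for b in self.counts}
        return {b: c / self.depth for b, c in self.counts.items()}


class PileupProfiles:
    """Vectorized container of qualified per-position profiles."""

    def __init__(self, genome_length: int):
        self.L = genome_length
        # A, C, G, T, deletion -- per strand
        self.counts_fwd = np.zeros((genome_length, 5), dtype=np.int64)
        self.counts_rev = np.zeros((genome_length, 5), dtype=np.int64)
        self.qual_sums = np.zeros((genome_length, 5), dtype=np.int64)
        self.insertions: dict[int, Counter] = {}

    @property
    def counts(self) -> np.ndarray:
        return self.counts_fwd + self.counts_rev

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def profile(self, position: int) -> PositionProfile:
        c = self.counts[position - 1]
        qs = self.qual_sums[position - 1]
        mean_q = {
            BASES[i]: (qs[i] / c[i]) if c[i] else 0.0 for i in range(4)
        }
        counts = {BASES[i]: int(c[i]) for i in range(4)}
        counts["del"] = int(c[_DEL])
        return PositionProfile(
            position=position, counts=counts,
            insertions=dict(self.insertions.get(position, {})),
            depth=int(c.sum()), mean_quality=mean_q,
        )

    def minor_strand_counts(self, position: int, base: str) -> tuple[int, int]:
        i = BASES.index(base)
        return (int(self.counts_fwd[position - 1, i]),
                int(self.counts_rev[position - 1, i]))


def quality_filter(qualities: Sequence[int], index: int,
                   radius: int = 5, min_quality: int = 30) -> bool:
    """Accept the base at ``index`` iff its own quality and the mean quality
    of the window (truncated at read ends) both reach ``min_quality``."""
    q = np.asarray(qualities)
    if q[index] < min_quality:
        return False
    lo = max(index - radius, 0)
    hi = min(index + radius + 1, q.size)
    return float(q[lo:hi].mean()) >= min_quality


def _window_means(quals: np.ndarray, radius: int) -> np.ndarray:
    """Per-base mean quality of the truncated +/- radius window (2-D)."""
    n, rl = quals.shape
    cs = np.zeros((n, rl + 1), dtype=np.int64)
    np.cumsum(quals, axis=1, out=cs[:, 1:])
    idx = np.arange(rl)
    lo = np.maximum(idx - radius, 0)
    hi = np.minimum(idx + radius + 1, rl)
    return (cs[:, hi] - cs[:, lo]) / (hi - lo)


def pileup(mapping: ReadMapping,
           thresholds: CallThresholds = CallThresholds()) -> PileupProfiles:
    """Qualified per-position base counts from a reference-anchored mapping."""
    L = len(mapping.reference)
    profiles = PileupProfiles(L)
    radius, minq = thresholds.quality_radius, thresholds.min_quality
    m = mapping.matrices()
    if len(m["starts"]):
        codes, quals = m["codes"], m["quals"]
        n, rl = codes.shape
        ok = (quals >= minq) & (_window_means(quals, radius) >= minq)
        pos = (m["starts"][:, None] - 1 + np.arange(rl)) % L
        fwd = m["fwd"]
        for sel, target in ((fwd, profiles.counts_fwd),
                            (~fwd, profiles.counts_rev)):
            if sel.any():
                mask = ok[sel]
                np.add.at(target,
                          (pos[sel][mask], codes[sel][mask].astype(np.intp)), 1)
        mask = ok
        np.add.at(profiles.qual_sums,
                  (pos[mask], codes[mask].astype(np.intp)),
                  quals[mask].astype(np.int64))
    for rec in m["gapped"]:
        q = rec.quals
        wm_ok = None
        # per-read qualified mask on read coordinates
        wm = _window_means(q[None, :], radius)[0]
        okr = (q >= minq) & (wm >= minq)
        target = profiles.counts_fwd if rec.strand == "+" else profiles.counts_rev
        rpos = rec.ref_start - 1
        qpos = 0
        for op, nn in rec.cigar:
            if op in ("=", "X"):
                for i in range(nn):
                    if okr[qpos + i]:
                        p = (rpos + i) % L
                        c = int(rec.codes[qpos + i])
                        target[p, c] += 1
                        profiles.qual_sums[p, c] += int(q[qpos + i])
                rpos += nn
                qpos += nn
            elif op == "D":
                for i in range(nn):
                    target[(rpos + i) % L, _DEL] += 1
                rpos += nn
            elif op == "I":
                anchor = (rpos - 1) % L + 1
                run = "".join(BASES[c] for c in rec.codes[qpos: qpos + nn])
                profiles.insertions.setdefault(anchor, Counter())[run] += 1
                qpos += nn
    return profiles


@dataclass
class MixedPosition:
    """A detected two-allele mixed position."""

    position: int
    major: str
    minor: str
    minor_freq: float
    depth: int
    iupac: str
    classification: str = "unassigned"  # unassigned | PHP | NUMT | artifact
    minor_fwd: int = 0
    minor_rev: int = 0
    sample_id: str = ""
    ref_base: str = ""

    def variant_token(self, reference: ReferenceGenome) -> str:
        """Minor variant in reporting nomenclature: ``A13062G``, or the bare
        reference token (``A263``) when the minor base *is* the reference."""
        ref_base = reference.base(self.position)
        if self.minor == ref_base:
            return f"{ref_base}{self.position}"
        return f"{ref_base}{self.position}{self.minor}"

    def iupac_token(self, reference: ReferenceGenome) -> str:
        return f"{reference.base(self.position)}{self.position}{self.iupac}"


@dataclass
class CallResult:
    """Variant detection output at one threshold."""

    detect_freq: float
    mixed: list[MixedPosition]
    homoplasmic: list[VariantSpec]
    below_threshold: list[int]
    multi_allelic: list[int]
    deletion_mixed: list[int] = field(default_factory=list)
    insertion_major: list[VariantSpec] = field(default_factory=list)

    def filter(self, detect_freq: float) -> "CallResult":
        """Derive a higher-threshold call set by frequency filtering."""
        if detect_freq < self.detect_freq:
            raise ValueError("can only filter to a higher threshold")
        homoplasmic = list(self.homoplasmic)
        # a mixed position falling below the new threshold reports its major
        # base; if that differs from the reference it becomes a plain variant
        for m in self.mixed:
            if m.minor_freq < detect_freq and m.ref_base and m.major != m.ref_base:
                homoplasmic.append(VariantSpec(m.position, "sub",
                                               ref=m.ref_base, alt=m.major))
        return CallResult(
            detect_freq=detect_freq,
            mixed=[m for m in self.mixed if m.minor_freq >= detect_freq],
            homoplasmic=homoplasmic,
            below_threshold=list(self.below_threshold),
            multi_allelic=list(self.multi_allelic),
            deletion_mixed=list(self.deletion_mixed),
            insertion_major=list(self.insertion_major),
        )


def detect_variants(profiles: PileupProfiles, reference: ReferenceGenome,
                    thresholds: CallThresholds = CallThresholds(),
                    ) -> CallResult:
    """Call major bases, mixed positions and below-threshold positions."""
    L = profiles.L
    counts = profiles.counts
    depth = counts.sum(axis=1)
    t = thresholds.detect_freq
    below = np.flatnonzero(depth < thresholds.min_depth)
    callable_mask = depth >= thresholds.min_depth
    ref_codes = reference.codes

    # rank alleles with the reference base preferred on exact count ties
    adj = counts * 10
    adj[np.arange(L), ref_codes] += 1
    order = np.argsort(-adj, axis=1, kind="stable")
    maj = order[:, 0]
    sec = order[:, 1]
    cmaj = counts[np.arange(L), maj]
    csec = counts[np.arange(L), sec]
    cthird = counts[np.arange(L), order[:, 2]]
    with np.errstate(invalid="ignore", divide="ignore"):
        fsec = np.where(depth > 0, csec / np.maximum(depth, 1), 0.0)
        fthird = np.where(depth > 0, cthird / np.maximum(depth, 1), 0.0)

    mixed: list[MixedPosition] = []
    homoplasmic: list[VariantSpec] = []
    multi: list[int] = []
    del_mixed: list[int] = []
    ins_major: list[VariantSpec] = []

    interesting = np.flatnonzero(
        callable_mask & ((maj != ref_codes) | (fsec >= t))
    )
    for i in interesting:
        pos = int(i) + 1
        if fthird[i] >= t:
            multi.append(pos)
            continue
        major_code, minor_code = int(maj[i]), int(sec[i])
        is_mixed = fsec[i] >= t
        if major_code == _DEL:
            homoplasmic.append(VariantSpec(pos, "del"))
            continue
        if is_mixed and minor_code == _DEL:
            del_mixed.append(pos)
            is_mixed = False
        major = BASES[major_code]
        if is_mixed:
            minor = BASES[minor_code]
            fwd, rev = profiles.minor_strand_counts(pos, minor)
            mixed.append(MixedPosition(
                position=pos, major=major, minor=minor,
                minor_freq=float(fsec[i]), depth=int(depth[i]),
                iupac=iupac_code(major, minor),
                minor_fwd=fwd, minor_rev=rev,
                ref_base=BASES[ref_codes[i]],
            ))
        elif major_code != ref_codes[i]:
            homoplasmic.append(
                VariantSpec(pos, "sub", ref=BASES[ref_codes[i]], alt=major)
            )
    # major-molecule insertions
    for anchor, runs in sorted(profiles.insertions.items()):
        d = depth[anchor - 1]
        if d and callable_mask[anchor - 1]:
            run, cnt = runs.most_common(1)[0]
            if cnt / d > 0.5:
                for j, b in enumerate(run, start=1):
                    ins_major.append(
                        VariantSpec(anchor, "ins", alt=b, insert_index=j)
                    )
    return CallResult(
        detect_freq=t, mixed=mixed, homoplasmic=homoplasmic,
        below_threshold=[int(p) + 1 for p in below],
        multi_allelic=multi, deletion_mixed=del_mixed,
        insertion_major=ins_major,
    )


# ---------------------------------------------------------------------------
# Forensic nomenclature post-processing
# ---------------------------------------------------------------------------

def shift_indels_3prime(calls: Iterable[VariantSpec],
                        reference: ReferenceGenome) -> list[VariantSpec]:
    """Report indels at the 3'-most equivalent position of their run.

    A deletion inside a homopolymer run moves to the run's last position; an
    insertion of the run base anchors after the run's last position with a
    decimal suffix. Indels not inside a run (length >= 2) are unchanged.
    """
    out: list[VariantSpec] = []
    suffix_count: Counter = Counter()
    for v in calls:
        if v.kind == "del":
            run = homopolymer_run(reference, v.position)
            if run.length(len(reference)) >= 2:
                v = replace(v, position=run.end)
            out.append(v)
        elif v.kind == "ins":
            anchor = v.position
            base = v.alt
            nxt = anchor % len(reference) + 1
            if reference.base(anchor) == base:
                run = homopolymer_run(reference, anchor)
                anchor = run.end
            elif reference.base(nxt) == base:
                run = homopolymer_run(reference, nxt)
                anchor = run.end
            suffix_count[anchor] += 1
            out.append(VariantSpec(anchor, "ins", alt=base,
                                   insert_index=suffix_count[anchor]))
        else:
            out.append(v)
    return out


@dataclass
class LengthCall:
    """Major-molecule length determination for one homopolymer run."""

    run: CircularRegion
    base: str
    reference_length: int
    major_length: int
    support: dict[int, int]
    warning: str = ""

    def variants(self) -> list[VariantSpec]:
        d = self.major_length - self.reference_length
        if d > 0:
            return [VariantSpec(self.run.end, "ins", alt=self.base,
                                insert_index=j) for j in range(1, d + 1)]
        if d < 0:
            # delete from the 3' end of the run
            return [VariantSpec(self.run.end - j, "del") for j in range(-d)]
        return []


def resolve_length_heteroplasmy(mapping: ReadMapping,
                                reference: ReferenceGenome,
                                regions: Sequence[CircularRegion] = CSTRETCH_REGIONS,
                                ) -> list[LengthCall]:
    """Read-count analysis of homopolymer runs: report the major molecule.

    For each maximal homopolymer run (length >= 3) inside each configured
    region, reads spanning the run with one anchor base on each side vote
    with their observed run length; the most frequent length wins, ties
    resolve to the shorter molecule. Minor length variants are dropped (the
    caller emits no indel for them); point substitutions inside runs are
    unaffected.
    """
    L = len(reference)
    m = mapping.matrices()
    calls: list[LengthCall] = []
    for region in regions:
        covered: set[int] = set()
        for pos in region.positions(L):
            if pos in covered:
                continue
            run = homopolymer_run(reference, pos)
            run_len = run.length(L)
            covered.update(run.positions(L))
            if run_len < 3:
                continue
            base = reference.base(run.start)
            support: Counter = Counter()
            if len(m["starts"]):
                rl = m["codes"].shape[1]
                starts = m["starts"]
                # span from the base before the run to the base after it
                pre = (run.start - 2) % L + 1
                off_pre = (pre - starts) % L
                span = run_len + 2
                sel = off_pre + span <= rl
                idx = np.flatnonzero(sel)
                if idx.size:
                    offs = off_pre[idx][:, None] + np.arange(span)
                    seg = m["codes"][idx[:, None], offs]
                    base_code = BASES.index(base)
                    # contiguous run of base starting after the anchor
                    is_base = seg[:, 1:] == base_code
                    runlen_obs = np.argmin(is_base, axis=1)
                    runlen_obs[is_base.all(axis=1)] = is_base.shape[1]
                    for v in runlen_obs:
                        support[int(v)] += 1
            for rec in m["gapped"]:
                obs = _gapped_run_length(rec, run, base, L)
                if obs is not None:
                    support[obs] += 1
            if not support:
                calls.append(LengthCall(run, base, run_len, run_len, {},
                                        warning="no spanning reads"))
                continue
            best = max(support.values())
            major = min(l for l, c in support.items() if c == best)
            calls.append(LengthCall(run, base, run_len, major, dict(support)))
    return calls


def _gapped_run_length(rec, run: CircularRegion, base: str,
                       L: int) -> Optional[int]:
    """Observed run length for a gapped record spanning the run, else None."""
    cols = {p: code for p, code, _q in _walk_gapped(rec, L)}
    pre = (run.start - 2) % L
    post = run.end % L
    if pre not in cols or post not in cols:
        return None
    base_code = BASES.index(base)
    n = sum(1 for p in run.positions(L) if cols.get(p - 1) == base_code)
    # insertions of the run base anchored inside the run
    ins = 0
    rpos = rec.ref_start - 1
    qpos = 0
    for op, nn in rec.cigar:
        if op in ("=", "X"):
            rpos += nn
            qpos += nn
        elif op == "D":
            rpos += nn
        elif op == "I":
            anchor = (rpos - 1) % L + 1
            if run.contains(anchor, L):
                ins += sum(1 for c in rec.codes[qpos: qpos + nn]
                           if int(c) == base_code)
            qpos += nn
    return n + ins


def filter_astretch_artifacts(mixed: Iterable[MixedPosition],
                              zones: Sequence[CircularRegion] = ASTRETCH_ZONES,
                              ) -> tuple[list[MixedPosition], list[MixedPosition]]:
    """Split mixed positions into (kept, artifact-tagged) by A-stretch zone."""
    kept: list[MixedPosition] = []
    artifacts: list[MixedPosition] = []
    for mp in mixed:
        if any(z.contains(mp.position) for z in zones):
            mp.classification = "artifact"
            artifacts.append(mp)
        else:
            kept.append(mp)
    return kept, artifacts


# ---------------------------------------------------------------------------
# Haplotype
# ---------------------------------------------------------------------------

@dataclass
class MitoHaplotype:
    """A sample's mitogenome haplotype as differences from the reference."""

    sample_id: str
    substitutions: list[VariantSpec]
    mixed: list[MixedPosition]
    indels: list[VariantSpec]
    below_threshold_positions: list[int]
    excluded_positions: list[int]
    reference: ReferenceGenome

    def tokens(self) -> list[str]:
        items: list[tuple[tuple[int, int, int], str]] = []
        for v in self.substitutions + self.indels:
            kind_rank = {"sub": 0, "del": 1, "ins": 2}[v.kind]
            items.append(((v.position, kind_rank, v.insert_index), v.token()))
        for mp in self.mixed:
            items.append(((mp.position, 0, 0), mp.iupac_token(self.reference)))
        return [tok for _k, tok in sorted(items)]

    def range_header(self) -> str:
        if not self.excluded_positions:
            return f"1-{len(self.reference)}"
        parts = []
        excl = set(self.excluded_positions)
        start = None
        for p in range(1, len(self.reference) + 1):
            if p not in excl:
                if start is None:
                    start = p
            elif start is not None:
                parts.append(f"{start}-{p - 1}")
                start = None
        if start is not None:
            parts.append(f"{start}-{len(self.reference)}")
        return " ".join(parts)


def haplotype_string(haplotype: MitoHaplotype) -> str:
    """Space-separated ordered variant tokens (empty if reference-identical)."""
    return " ".join(haplotype.tokens())


def finalize_haplotype(sample_id: str, result: CallResult,
                       mapping: ReadMapping, reference: ReferenceGenome,
                       thresholds: CallThresholds = CallThresholds(),
                       profiles: PileupProfiles | None = None,
                       ) -> MitoHaplotype:
    """Apply LHP filtering, A-stretch artifact removal, indel shifting and
    below-threshold confirmation to produce the reported haplotype."""
    L = len(reference)
    mixed, _artifacts = filter_astretch_artifacts(list(result.mixed))
    subs = list(result.homoplasmic)

    lhp_calls = resolve_length_heteroplasmy(mapping, reference)
    lhp_positions: set[int] = set()
    indels: list[VariantSpec] = []
    for lc in lhp_calls:
        lhp_positions.update(lc.run.positions(L))
        indels.extend(lc.variants())
    # indel calls outside LHP-managed runs pass through the 3' shift
    passthrough = [v for v in result.insertion_major
                   if v.position not in lhp_positions]
    passthrough += [v for v in subs if v.kind == "del"
                    and v.position not in lhp_positions]
    subs = [v for v in subs if v.kind == "sub"]
    indels.extend(shift_indels_3prime(passthrough, reference))

    below = sorted(result.below_threshold)
    excluded: list[int] = []
    if below and profiles is not None:
        if len(below) <= thresholds.nearly_complete_max_below:
            depth = profiles.depth
            counts = profiles.counts
            for pos in below:
                d = int(depth[pos - 1])
                if d >= thresholds.confirm_min_depth:
                    major_code = int(np.argmax(counts[pos - 1, :4]))
                    if counts[pos - 1, major_code] / d >= thresholds.confirm_major_freq:
                        if major_code != reference.codes[pos - 1]:
                            subs.append(VariantSpec(
                                pos, "sub",
                                ref=reference.base(pos),
                                alt=BASES[major_code],
                            ))
                        continue
                excluded.append(pos)
        else:
            excluded = list(below)
    elif below:
        excluded = list(below)

    subs.sort(key=lambda v: v.position)
    mixed.sort(key=lambda mp: mp.position)
    return MitoHaplotype(
        sample_id=sample_id, substitutions=subs, mixed=mixed,
        indels=sorted(indels, key=lambda v: (v.position, v.insert_index)),
        below_threshold_positions=below, excluded_positions=sorted(excluded),
        reference=reference,
    )
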