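"""End-to-end orchestration: reads -> mapping -> calls -> classification -> QC.

This module is the programmatic surface the command-line interface, the
analysis drivers and the test-suite all share. A sample flows through:

1. ``consensus_workflow`` (permissive map, consensus, stringent remap,
   reference realignment);
2. ``pileup`` + ``detect_variants`` at the low-band (2%) threshold and at
   the analysis threshold (default 5%); the 10% view is derived by
   frequency filtering, so threshold call sets nest exactly;
3. ``finalize_haplotype`` (A-stretch artifact removal, length-heteroplasmy
   major-molecule reporting, 3' indel shifting, below-threshold handling);
4. dataset-level classification of mixed positions (NUMT vs PHP) and QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .align import (
    DEFAULT_PARAMS,
    STRICT_PARAMS,
    AlignmentRecord,
    ConsensusWorkflowResult,
    MappingParams,
    ReadMapping,
    consensus_workflow,
)
from .call import (
    ASTRETCH_ZONES,
    CallResult,
    CallThresholds,
    MitoHaplotype,
    PileupProfiles,
    detect_variants,
    finalize_haplotype,
    pileup,
)
from .classify import (
    NUMTCatalog,
    PHPHotspotList,
    ReviewCriteria,
    SampleCalls,
    classify_dataset,
)
from .qc import (
    CallThresholds as _CT,  # noqa: F401  (re-export convenience)
    KinshipTable,
    SampleCategory,
    SampleMetrics,
    categorize,
    compute_metrics,
    exclude_related,
    mixture_flag,
    shared_haplotypes,
)
from .reference import (
    CODING_REGION,
    CONTROL_REGION,
    ReferenceGenome,
    load_reference,
)
from .simulate import ReadRecord

__all__ = [
    "SampleResult", "process_sample", "classify_cohort", "qc_cohort",
    "threshold_report", "php_region_percentages",
    "write_sam", "read_sam", "write_variant_table", "write_haplotype_file",
    "LOW_BAND_FREQ", "REPORT_THRESHOLDS",
]

LOW_BAND_FREQ = 0.02
REPORT_THRESHOLDS = (0.02, 0.05, 0.10)


@dataclass
class SampleResult:
    """Everything the pipeline derives for one sample."""

    sample_id: str
    workflow: ConsensusWorkflowResult
    profiles: PileupProfiles
    low_band_result: CallResult
    primary_result: CallResult
    haplotype: MitoHaplotype
    metrics: SampleMetrics
    reference: ReferenceGenome

    def sample_calls(self) -> SampleCalls:
        """Classifier-facing view (analysis-threshold mixed + 2-5% band)."""
        t = self.primary_result.detect_freq
        low = [mp for mp in self.low_band_result.mixed
               if mp.minor_freq < t
               and not any(z.contains(mp.position) for z in ASTRETCH_ZONES)]
        for mp in self.haplotype.mixed:
            mp.sample_id = self.sample_id
        return SampleCalls(
            sample_id=self.sample_id,
            mixed=list(self.haplotype.mixed),
            low_band=low,
            mapping=self.workflow.final,
            avg_depth=self.metrics.avg_depth,
            reference=self.reference,
        )


def process_sample(sample_id: str, reads: Sequence[ReadRecord],
                   reference: Optional[ReferenceGenome] = None,
                   thresholds: CallThresholds = CallThresholds(),
                   params_default: MappingParams = DEFAULT_PARAMS,
                   params_strict: MappingParams = STRICT_PARAMS,
                   ) -> SampleResult:
    """Run mapping and variant detection for one sample."""
    ref = reference if reference is not None else load_reference()
    wf = consensus_workflow(reads, ref, params_default, params_strict)
    profiles = pileup(wf.final, thresholds)
    low = detect_variants(profiles, ref, _with_freq(thresholds, LOW_BAND_FREQ))
    primary = detect_variants(profiles, ref, thresholds)
    haplotype = finalize_haplotype(sample_id, primary, wf.final, ref,
                                   thresholds, profiles)
    metrics = compute_metrics(sample_id, profiles,
                              mtdna_reads=len(wf.final),
                              thresholds=thresholds)
    return SampleResult(sample_id, wf, profiles, low, primary, haplotype,
                        metrics, ref)


def _with_freq(t: CallThresholds, freq: float) -> CallThresholds:
    from dataclasses import replace
    return replace(t, detect_freq=freq)


def classify_cohort(results: Sequence[SampleResult],
                    criteria: ReviewCriteria = ReviewCriteria(),
                    catalog: Optional[NUMTCatalog] = None,
                    hotspots: Optional[PHPHotspotList] = None,
                    ) -> pd.DataFrame:
    """Classify all samples' mixed positions; updates metrics in place."""
    samples = [r.sample_calls() for r in results]
    table = classify_dataset(samples, criteria, catalog, hotspots)
    for r in results:
        sub = table[table["sample"] == r.sample_id]
        r.metrics.residual_php_count = int((sub["label"] == "PHP").sum())
        r.metrics.numt_variant_count = int((sub["label"] == "NUMT").sum())
        r.metrics.multi_allelic_count = len(r.primary_result.multi_allelic)
    return table


def qc_cohort(results: Sequence[SampleResult],
              kinship: Optional[KinshipTable] = None,
              thresholds: CallThresholds = CallThresholds(),
              ) -> pd.DataFrame:
    """Categorize samples and resolve maternal relatives."""
    categories: dict[str, SampleCategory] = {}
    for r in results:
        categories[r.sample_id] = categorize(r.metrics, thresholds)
    passing = [r for r in results
               if categories[r.sample_id] in (
                   SampleCategory.passing_complete,
                   SampleCategory.passing_nearly_complete)]
    pairs = shared_haplotypes([r.haplotype for r in passing])
    unresolved: list[tuple[str, str]] = []
    if pairs and kinship is not None:
        metrics = {r.sample_id: r.metrics for r in passing}
        _retained, excluded, unresolved = exclude_related(
            pairs, kinship, metrics)
        for sid in excluded:
            categories[sid] = SampleCategory.related
    elif pairs:
        unresolved = pairs
    rows = []
    for r in results:
        rows.append({
            "sample": r.sample_id,
            "category": categories[r.sample_id].value,
            "avg_depth": round(r.metrics.avg_depth, 1),
            "min_depth": r.metrics.min_depth,
            "positions_below_threshold": r.metrics.positions_below_threshold,
            "residual_phps": r.metrics.residual_php_count,
            "numt_variants": r.metrics.numt_variant_count,
            "pct_mtdna": (round(r.metrics.pct_mtdna, 4)
                          if r.metrics.pct_mtdna is not None else ""),
            "shared_haplotype_unresolved": ";".join(
                f"{a}|{b}" for a, b in unresolved
                if r.sample_id in (a, b)),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Threshold comparison report
# ---------------------------------------------------------------------------

def php_region_percentages(php_positions: Sequence[int],
                           ) -> dict[str, float]:
    """Distinct heteroplasmic positions per mitogenome region, as counts and
    as percentages of the region length (one decimal, as reported)."""
    pos = set(int(p) for p in php_positions)
    cr = {p for p in pos if CONTROL_REGION.contains(p)}
    codr = pos - cr
    cr_len = CONTROL_REGION.length()
    codr_len = CODING_REGION.length()
    return {
        "cr_positions": len(cr),
        "cr_pct": round(100.0 * len(cr) / cr_len, 1),
        "codr_positions": len(codr),
        "codr_pct": round(100.0 * len(codr) / codr_len, 1),
    }


def threshold_report(classification: pd.DataFrame, n_samples: int,
                     thresholds: Sequence[float] = REPORT_THRESHOLDS,
                     ) -> pd.DataFrame:
    """Per-threshold NUMT/PHP summary derived by frequency filtering.

    The call universe is the classified mixed-position table; each
    threshold's call set is exactly the rows with minor frequency at or
    above it, so the sets nest by construction.
    """
    rows = []
    for t in sorted(thresholds):
        sub = classification[classification["minor_freq"] >= t]
        phps = sub[sub["label"] == "PHP"]
        numts = sub[sub["label"] == "NUMT"]
        per_sample = phps.groupby("sample").size() if len(phps) else pd.Series(dtype=int)
        region = php_region_percentages(phps["position"].tolist())
        rows.append({
            "threshold": t,
            "numt_variants": len(numts),
            "php_count": len(phps),
            "samples_with_php": int((per_sample > 0).sum()),
            "samples_with_php_pct": round(
                100.0 * (per_sample > 0).sum() / n_samples, 1)
            if n_samples else 0.0,
            "max_phps_per_sample": int(per_sample.max()) if len(per_sample) else 0,
            **region,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Artifact I/O (SAM, variant tables, haplotype files)
# ---------------------------------------------------------------------------

def _sam_header(reference: ReferenceGenome) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": reference.name, "LN": len(reference)}],
        "PG": [{"ID": "mitowgs", "PN": "mitowgs"}],
    })


def write_sam(mapping: ReadMapping, path) -> None:
    """Write accepted alignments as plain-text SAM (single reference)."""
    header = _sam_header(mapping.reference)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in mapping.records:
            a = pysam.AlignedSegment(header)
            a.query_name = rec.read_id
            a.query_sequence = rec.sequence()
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(int(q) + 33) for q in rec.quals))
            a.reference_id = 0
            a.reference_start = rec.ref_start - 1
            a.mapping_quality = 60
            flag = 0x1 | (0x40 if rec.mate == 1 else 0x80)
            if rec.strand == "-":
                flag |= 0x10
            a.flag = flag
            if rec.gapless:
                a.cigarstring = f"{rec.read_length}M"
            else:
                a.cigarstring = "".join(
                    f"{n}{'M' if op in ('=', 'X') else op}"
                    for op, n in rec.cigar)
            a.set_tag("NM", rec.nm)
            out.write(a)


def read_sam(path, reference: ReferenceGenome,
             params: MappingParams = STRICT_PARAMS) -> ReadMapping:
    """Rebuild a ReadMapping from SAM (mismatch ops recomputed vs reference).

    Alignments that run past the linear end of the SAM reference are not
    expected (the writer reduces coordinates mod L before writing).
    """
    mapping = ReadMapping(reference, params, [])
    L = len(reference)
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for a in sam.fetch(until_eof=True):
            if a.is_unmapped or a.query_sequence is None:
                continue
            from .reference import encode_bases
            codes = encode_bases(a.query_sequence)
            if a.query_qualities is not None:
                quals = np.asarray(a.query_qualities, dtype=np.uint8)
            else:
                quals = np.full(codes.size, 35, dtype=np.uint8)
            cigar = None
            gapless = (len(a.cigartuples) == 1
                       and a.cigartuples[0][0] == 0)
            start = a.reference_start + 1
            if gapless:
                pos = (start - 1 + np.arange(codes.size)) % L
                nm = int((reference.codes[pos] != codes).sum())
                lf, sim = 1.0, (codes.size - nm) / codes.size
            else:
                ops = []
                qpos = 0
                rpos = start - 1
                nm = 0
                for op, n in a.cigartuples:
                    if op == 0:  # M: split into =/X against the reference
                        seg = codes[qpos: qpos + n]
                        refseg = reference.codes[
                            (rpos + np.arange(n)) % L]
                        for m_ok, c in zip(refseg == seg, seg):
                            tag = "=" if m_ok else "X"
                            if ops and ops[-1][0] == tag:
                                ops[-1] = (tag, ops[-1][1] + 1)
                            else:
                                ops.append((tag, 1))
                        nm += int((refseg != seg).sum())
                        qpos += n
                        rpos += n
                    elif op == 1:  # I
                        ops.append(("I", n))
                        nm += n
                        qpos += n
                    elif op == 2:  # D
                        ops.append(("D", n))
                        nm += n
                        rpos += n
                    else:
                        raise ValueError(f"unsupported CIGAR op {op}")
                cigar = tuple(ops)
                from .align import _fractions_from_ops
                lf, sim, _ = _fractions_from_ops(cigar, codes.size)
            mapping.records.append(AlignmentRecord(
                read_id=a.query_name,
                mate=2 if a.is_read2 else 1,
                ref_start=start,
                strand="-" if a.is_reverse else "+",
                codes=codes, quals=quals, nm=nm,
                length_fraction=lf, similarity_fraction=sim,
                accepted=True, cigar=cigar,
            ))
    mapping.n_input = len(mapping.records)
    return mapping


def write_variant_table(result: SampleResult, path) -> None:
    """Per-sample variant TSV: one row per mixed or homoplasmic call."""
    ref = result.reference
    rows = []
    for mp in result.haplotype.mixed:
        rows.append({
            "sample": result.sample_id, "position": mp.position,
            "ref": ref.base(mp.position), "major": mp.major,
            "minor": mp.minor, "minor_freq": round(mp.minor_freq, 4),
            "depth": mp.depth, "call": mp.iupac_token(ref),
            "classification": mp.classification,
        })
    for v in result.haplotype.substitutions + result.haplotype.indels:
        rows.append({
            "sample": result.sample_id, "position": v.position,
            "ref": ref.base(v.position) if v.kind != "ins" else "",
            "major": v.alt, "minor": "", "minor_freq": "",
            "depth": int(result.profiles.depth[v.position - 1]),
            "call": v.token(), "classification": "homoplasmic",
        })
    frame = pd.DataFrame(rows)
    if len(frame):
        frame = frame.sort_values("position", kind="stable")
    frame.to_csv(path, sep="\t", index=False)


def write_haplotype_file(haplotype: MitoHaplotype, path) -> None:
    """EMPOP-style haplotype file: range header line + variant tokens."""
    with open(path, "w") as fh:
        fh.write(f"# sample: {haplotype.sample_id}\n")
        fh.write(f"# range: {haplotype.range_header()}\n")
        fh.write(" ".join(haplotype.tokens()) + "\n")
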