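"""Shared cohort definition for the numbered analysis drivers.

A twelve-sample synthetic cohort spanning the conditions the pipeline has
to separate: clean haplotypes at varying depth, NUMT donor interference at
6-9% local fraction (stronger at low depth), authentic heteroplasmies at
5-35%, one exogenous mixture, one maternally-related duplicate pair and
one low-coverage (incomplete) sample.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from mitowgs.pipeline import process_sample
from mitowgs.reference import VariantSpec, load_reference
from mitowgs.simulate import (
    PHP,
    Contaminant,
    TruthSpec,
    build_numt_donor,
    read_fastq,
    simulate_sample,
    write_fastq,
    write_truth,
)

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

BASE_SEED = 77_000


def _hap(tokens: str):
    return tuple(VariantSpec.parse(t) for t in tokens.split())


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _transitions_at(positions):
    """Transitions at spread-out positions (isolated, non-catalog)."""
    ref = load_reference()
    return tuple(
        VariantSpec(p, "sub", ref=ref.base(p), alt=_TRANSITION[ref.base(p)])
        for p in positions
    )


def cohort_specs() -> dict[str, TruthSpec]:
    """Sample id -> simulation spec. Depths are desk-scale stand-ins for
    the deep WGS mitochondrial coverage the method targets."""
    nd5 = build_numt_donor("ND5_sig", 0.07)
    hvs1 = build_numt_donor("HVS1_sig", 0.08)
    specs = {
        # clean, deep (each sample carries private variants, as real
        # mitogenome haplotypes do)
        "MT001": TruthSpec(base_haplotype=_hap("A263G")
                            + _transitions_at((750, 3100)),
                            target_depth=900),
        "MT002": TruthSpec(base_haplotype=_hap("T152C A263G")
                            + _transitions_at((5300,)),
                            target_depth=700),
        # authentic heteroplasmy
        "MT003": TruthSpec(base_haplotype=_hap("A263G")
                            + _transitions_at((8200,)),
                            phps=(PHP(16_093, "C", 0.22),), target_depth=800),
        "MT004": TruthSpec(base_haplotype=_hap("G16390A")
                            + _transitions_at((1700, 9900)),
                            phps=(PHP(2887, "T", 0.31), PHP(146, "C", 0.12)),
                            target_depth=1200),
        # NUMT interference at low depth
        "MT005": TruthSpec(base_haplotype=_hap("A263G")
                            + _transitions_at((2200,)),
                            donors=(nd5,), target_depth=400),
        "MT006": TruthSpec(base_haplotype=_hap("T16093C")
                            + _transitions_at((6100,)),
                            donors=(hvs1,), target_depth=500),
        "MT007": TruthSpec(base_haplotype=_hap("A263G T152C")
                            + _transitions_at((14_200,)),
                            donors=(nd5, hvs1),
                            phps=(PHP(204, "C", 0.18),), target_depth=450),
        # exogenous mixture: a second haplotype at 12% of reads, with
        # variants spread across the genome away from NUMT signatures
        "MT008": TruthSpec(
            base_haplotype=_hap("A263G") + _transitions_at((3900,)),
            contaminant=Contaminant(
                _transitions_at((1000, 2500, 4200, 6800, 9100, 11_900,
                                 15_500)), 0.12),
            target_depth=600),
        # maternal duplicate pair (identical haplotype, different depth)
        "MT009": TruthSpec(base_haplotype=_hap("A263G C16527T")
                            + _transitions_at((7600,)),
                            target_depth=800),
        "MT010": TruthSpec(base_haplotype=_hap("A263G C16527T")
                            + _transitions_at((7600,)),
                            target_depth=300),
        # incomplete: too shallow for the 100X gate
        "MT011": TruthSpec(base_haplotype=_hap("A263G")
                            + _transitions_at((5800,)),
                            target_depth=60),
        # clean control at moderate depth
        "MT012": TruthSpec(base_haplotype=_hap("G16129A")
                            + _transitions_at((12_300,)),
                            target_depth=650),
    }
    return {
        sid: TruthSpec(**{**spec.__dict__, "seed": BASE_SEED + i})
        for i, (sid, spec) in enumerate(specs.items())
    }


KINSHIP = pd.DataFrame({
    "sample_a": ["MT009"], "sample_b": ["MT010"], "kinship": [0.2898],
})

TRUE_DONOR_POSITIONS = {13_062, 13_095, 13_105,
                        16_390, 16_399, 16_444, 16_496, 16_519, 16_527}


def simulate_cohort() -> pd.DataFrame:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    rows = []
    ref = load_reference()
    for sid, spec in cohort_specs().items():
        reads, truth = simulate_sample(spec, ref, sid)
        write_fastq(reads, SCRATCH / f"{sid}_R1.fastq",
                    SCRATCH / f"{sid}_R2.fastq")
        write_truth(truth, SCRATCH / f"{sid}_truth.tsv")
        rows.append({
            "sample": sid,
            "read_pairs": len(truth),
            "target_depth": spec.target_depth,
            "donors": ";".join(d.name for d in spec.donors),
            "phps": ";".join(f"{p.position}:{p.fraction}" for p in spec.phps),
            "contaminant_fraction": (spec.contaminant.fraction
                                     if spec.contaminant else 0.0),
        })
    KINSHIP.to_csv(SCRATCH / "kinship.tsv", sep="\t", index=False)
    return pd.DataFrame(rows)


def processed_results():
    """Map and call the whole cohort (recomputed by each driver; the full
    per-read state is too large to cache usefully)."""
    ref = load_reference()
    results = []
    for sid in cohort_specs():
        reads = read_fastq(SCRATCH / f"{sid}_R1.fastq",
                           SCRATCH / f"{sid}_R2.fastq")
        results.append(process_sample(sid, reads, ref))
    return results
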