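"""Shared fixtures: the bundled reference and a few processed synthetic samples.

Session-scoped simulations are kept at desk scale (hundreds of X) so the
whole suite stays fast; the acceptance tests build their own deeper sample.
"""

from __future__ import annotations

import numpy as np
import pytest

from mitowgs.align import AlignmentRecord, ReadMapping, STRICT_PARAMS
from mitowgs.pipeline import process_sample
from mitowgs.reference import VariantSpec, load_reference
from mitowgs.simulate import PHP, TruthSpec, build_numt_donor, simulate_sample


@pytest.fixture(scope="session")
def rcrs():
    return load_reference()


@pytest.fixture(scope="session")
def clean_spec():
    """Error-free sample on a two-variant haplotype, no mixtures."""
    return TruthSpec(
        base_haplotype=(VariantSpec.parse("A263G"),
                        VariantSpec.parse("T16093C")),
        target_depth=200.0, error_rate=0.0, seed=101,
    )


@pytest.fixture(scope="session")
def clean_sample(rcrs, clean_spec):
    reads, truth = simulate_sample(clean_spec, rcrs, "clean")
    return reads, truth, process_sample("clean", reads, rcrs)


@pytest.fixture(scope="session")
def donor_sample(rcrs):
    """Both NUMT signatures at 8% plus a 20% heteroplasmy, 800X, with errors."""
    spec = TruthSpec(
        base_haplotype=(VariantSpec.parse("A263G"),),
        phps=(PHP(2887, "T", 0.20),),
        donors=(build_numt_donor("HVS1_sig", 0.08),
                build_numt_donor("ND5_sig", 0.08)),
        target_depth=800.0, seed=202,
    )
    reads, truth = simulate_sample(spec, rcrs, "donor")
    return reads, truth, process_sample("donor", reads, rcrs)


def make_mapping(reference, reads, params=STRICT_PARAMS,
                 read_length: int = 150) -> ReadMapping:
    """Hand-build a gapless mapping from (read_id, mate, start, {pos: base}).

    Each read is the reference substring at ``start`` (1-based, circular)
    with the given substitutions applied, at constant Q35.
    """
    L = len(reference)
    records = []
    for read_id, mate, start, subs in reads:
        pos = (start - 1 + np.arange(read_length)) % L
        codes = reference.codes[pos].copy()
        nm = 0
        for p, base in subs.items():
            off = (p - start) % L
            if off < read_length:
                codes[off] = "ACGT".index(base)
                nm += 1
        records.append(AlignmentRecord(
            read_id=read_id, mate=mate, ref_start=start, strand="+",
            codes=codes, quals=np.full(read_length, 35, dtype=np.uint8),
            nm=nm, length_fraction=1.0,
            similarity_fraction=(read_length - nm) / read_length,
            accepted=True,
        ))
    return ReadMapping(reference, params, records,
                       n_input=len(records))
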