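"""Sample-level quality control and dataset assembly.

A sample passes when its mitogenome is complete (every position at
>= 100X qualified depth) or nearly complete (at most four positions
below), it is single-source (no mixture flag), and it is not the
maternally-related duplicate of another retained sample. Mixture
flagging is an explicit stand-in for analyst judgement: five or more
residual point heteroplasmies (after NUMT variants are removed) or any
multi-allelic position flags the sample — a passing sample may carry up
to four PHPs. Shared-haplotype detection compares substitution-only
haplotypes, ignoring indels and any position heteroplasmic in either
sample; shared pairs with a kinship coefficient above the cutoff keep
only the deeper sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .call import CallThresholds, MitoHaplotype, PileupProfiles
from .reference import VariantSpec

__all__ = [
    "SampleMetrics", "SampleCategory", "KinshipTable", "compute_metrics",
    "categorize", "mixture_flag", "shared_haplotypes", "exclude_related",
    "DEFAULT_KINSHIP_CUTOFF",
]

#: Lower bound of the second-degree-relative kinship range.
DEFAULT_KINSHIP_CUTOFF = 0.0884


class SampleCategory(str, Enum):
    passing_complete = "passing_complete"
    passing_nearly_complete = "passing_nearly_complete"
    incomplete = "incomplete"
    mixed = "mixed"
    related = "related"


@dataclass
class SampleMetrics:
    sample_id: str
    total_reads: Optional[int] = None
    pct_mapped: Optional[float] = None
    pct_mtdna: Optional[float] = None
    avg_depth: float = 0.0
    min_depth: int = 0
    positions_below_threshold: int = 0
    residual_php_count: int = 0
    numt_variant_count: int = 0
    multi_allelic_count: int = 0


def compute_metrics(sample_id: str, profiles: PileupProfiles,
                    mtdna_reads: int | None = None,
                    mapped_reads: int | None = None,
                    total_reads: int | None = None,
                    pct_mapped: float | None = None,
                    thresholds: CallThresholds = CallThresholds(),
                    ) -> SampleMetrics:
    """Depth/coverage metrics over all genome positions.

    ``pct_mtdna`` (mtDNA-aligned reads as a percentage of mapped reads) is
    computed only when nuclear-mapping counts are supplied as metadata;
    shotgun nuclear processing is out of scope here.
    """
    depth = profiles.depth
    pct_mtdna = None
    if mtdna_reads is not None and mapped_reads:
        pct_mtdna = 100.0 * mtdna_reads / mapped_reads
    return SampleMetrics(
        sample_id=sample_id,
        total_reads=total_reads,
        pct_mapped=pct_mapped,
        pct_mtdna=pct_mtdna,
        avg_depth=float(depth.mean()),
        min_depth=int(depth.min()),
        positions_below_threshold=int((depth < thresholds.min_depth).sum()),
    )


def mixture_flag(residual_php_count: int, multi_allelic_count: int = 0,
                 max_passing_phps: int = 4) -> bool:
    """Possible-mixture flag: too many residual PHPs or any multi-allelic
    position. Exactly ``max_passing_phps`` residual PHPs do *not* flag."""
    return residual_php_count > max_passing_phps or multi_allelic_count > 0


def categorize(metrics: SampleMetrics,
               thresholds: CallThresholds = CallThresholds(),
               max_passing_phps: int = 4) -> SampleCategory:
    """Coverage-completeness category with the mixture override.

    Relatedness is resolved at dataset level (`exclude_related`), not here.
    """
    if mixture_flag(metrics.residual_php_count, metrics.multi_allelic_count,
                    max_passing_phps):
        return SampleCategory.mixed
    below = metrics.positions_below_threshold
    if below == 0:
        return SampleCategory.passing_complete
    if below <= thresholds.nearly_complete_max_below:
        return SampleCategory.passing_nearly_complete
    return SampleCategory.incomplete


@dataclass
class KinshipTable:
    """Pairwise kinship coefficients from nuclear data."""

    pairs: dict[frozenset, float] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path) -> "KinshipTable":
        frame = pd.read_csv(path, sep="\t")
        return cls.from_frame(frame)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "KinshipTable":
        pairs = {}
        for r in frame.itertuples():
            coeff = float(r.kinship)
            if not 0 <= coeff <= 0.5:
                raise ValueError(f"kinship coefficient out of [0, 0.5]: {coeff}")
            pairs[frozenset((str(r.sample_a), str(r.sample_b)))] = coeff
        return cls(pairs)

    def get(self, sample_a: str, sample_b: str) -> Optional[float]:
        return self.pairs.get(frozenset((sample_a, sample_b)))


def _comparable_calls(haplotype: MitoHaplotype,
                      mixed_positions: set[int]) -> frozenset[tuple[int, str]]:
    return frozenset(
        (v.position, v.alt) for v in haplotype.substitutions
        if v.kind == "sub" and v.position not in mixed_positions
    )


def shared_haplotypes(haplotypes: Sequence[MitoHaplotype],
                      ) -> list[tuple[str, str]]:
    """Pairs of samples with identical haplotypes, ignoring indels and any
    position heteroplasmic in either member of the pair."""
    matches: list[tuple[str, str]] = []
    for i, ha in enumerate(haplotypes):
        for hb in haplotypes[i + 1:]:
            mixed = ({mp.position for mp in ha.mixed}
                     | {mp.position for mp in hb.mixed})
            if (_comparable_calls(ha, mixed) == _comparable_calls(hb, mixed)):
                matches.append((ha.sample_id, hb.sample_id))
    return matches


def exclude_related(matching_pairs: Iterable[tuple[str, str]],
                    kinship: KinshipTable,
                    metrics: dict[str, SampleMetrics],
                    cutoff: float = DEFAULT_KINSHIP_CUTOFF,
                    ) -> tuple[set[str], set[str], list[tuple[str, str]]]:
    """(retained, excluded-as-related, unresolved pairs).

    For each shared-haplotype pair with kinship above the cutoff the sample
    with the lower average read depth is dropped; pairs without a kinship
    entry are retained and reported for manual follow-up.
    """
    excluded: set[str] = set()
    unresolved: list[tuple[str, str]] = []
    for a, b in matching_pairs:
        coeff = kinship.get(a, b)
        if coeff is None:
            unresolved.append((a, b))
            continue
        if coeff > cutoff:
            da = metrics[a].avg_depth if a in metrics else 0.0
            db = metrics[b].avg_depth if b in metrics else 0.0
            excluded.add(a if da < db else b)
    retained = set(metrics) - excluded
    return retained, excluded, unresolved
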