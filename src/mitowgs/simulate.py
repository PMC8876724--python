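"""Paired-end shotgun mtDNA read simulator with truth labels.

Generates the read mixture seen in the mitochondrial alignment of a
shotgun WGS sample: authentic mtDNA molecules (with optional point
heteroplasmies), reads from nuclear mtDNA segments (NUMTs) whose variant
clusters co-align to the mitochondrial reference, optional exogenous
contamination, and per-base sequencing error with an elevated miscall
rate immediately 3' of homopolymer runs (the post-homopolymer artifact of
HiSeq-class chemistry that produces spurious mixtures in the A-stretches
preceding the HVS C-stretches).

Conventions:

* ``target_depth`` is the expected mtDNA read depth (X) over the circle.
* A point heteroplasmy's ``fraction`` is the expected minor-read fraction
  at its position.
* A NUMT donor's ``copy_fraction`` is the expected *local* fraction of
  reads over the donor's homology span that are donor-derived, i.e. the
  expected minor-nucleotide frequency at the donor's variant positions.
* Fragments are drawn uniformly from the circular mtDNA molecule (they may
  span the origin) and uniformly from each donor's linear homology span.
* All randomness comes from a single ``numpy`` generator seeded from
  ``TruthSpec.seed``; the same spec yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .reference import (
    MT_LENGTH,
    CircularRegion,
    ReferenceGenome,
    VariantSpec,
    apply_variants,
    encode_bases,
    load_reference,
)

__all__ = [
    "PHP", "NUMTDonor", "Contaminant", "TruthSpec", "ReadRecord",
    "BUILTIN_DONORS", "build_numt_donor", "simulate_sample",
    "write_fastq", "read_fastq", "write_truth", "read_truth",
]


@dataclass(frozen=True)
class PHP:
    """A planted point heteroplasmy: minor base at an expected read fraction."""
    position: int
    minor: str
    fraction: float

    def __post_init__(self) -> None:
        if not 0 < self.fraction < 1:
            raise ValueError(f"PHP fraction must be in (0,1): {self.fraction}")


#: Default one-sided extension of a donor's variant span into the flanking
#: homology tract (bp). Real NUMT homology tracts extend well beyond the
#: positions at which the insertion differs from the mitochondrial sequence;
#: the flank lets fragments of realistic insert size be drawn.
DONOR_FLANK = 600


@dataclass(frozen=True)
class NUMTDonor:
    """A nuclear insertion haplotype defined by its variant set vs the reference.

    ``source_region`` is the span of the documented variant cluster;
    ``homology_region`` (derived: source_region +/- DONOR_FLANK) is the
    mtDNA-homologous tract reads are drawn from. Outside the variant set the
    donor matches the reference.
    """

    name: str
    source_region: CircularRegion
    variants: tuple[VariantSpec, ...]
    copy_fraction: float = 0.08
    flank: int = DONOR_FLANK

    def __post_init__(self) -> None:
        if not 0 <= self.copy_fraction < 1:
            raise ValueError("copy_fraction must be in [0,1)")
        for v in self.variants:
            if not self.source_region.contains(v.position):
                raise ValueError(
                    f"donor {self.name}: variant {v.token()} outside "
                    f"source region {self.source_region}"
                )

    @property
    def homology_region(self) -> CircularRegion:
        start = (self.source_region.start - 1 - self.flank) % MT_LENGTH + 1
        end = (self.source_region.end - 1 + self.flank) % MT_LENGTH + 1
        return CircularRegion(start, end)


# Two NUMT signature clusters recurrently observed in population-scale WGS
# mitochondrial alignments: an ND5-region trio consistent with polymorphic
# NUMT HGDP01029 (and archaic mitogenomes), and an HVS1 six-variant in-phase
# signature matching documented NUMTs (e.g. HGDP00856, HSA_NumtS_587).
BUILTIN_DONORS: dict[str, NUMTDonor] = {
    "ND5_sig": NUMTDonor(
        name="ND5_sig",
        source_region=CircularRegion(13_060, 13_110),
        variants=tuple(
            VariantSpec.parse(t) for t in ("A13062G", "T13095C", "A13105G")
        ),
    ),
    "HVS1_sig": NUMTDonor(
        name="HVS1_sig",
        source_region=CircularRegion(16_380, 16_535),
        variants=tuple(
            VariantSpec.parse(t)
            for t in ("G16390A", "A16399G", "C16444T",
                      "G16496A", "T16519C", "C16527T")
        ),
    ),
}


def build_numt_donor(name: str, copy_fraction: float = 0.08) -> NUMTDonor:
    """Return a built-in donor, with the requested local read fraction."""
    try:
        donor = BUILTIN_DONORS[name]
    except KeyError:
        raise KeyError(
            f"unknown donor {name!r}; built-ins: {sorted(BUILTIN_DONORS)}"
        ) from None
    return replace(donor, copy_fraction=copy_fraction)


@dataclass(frozen=True)
class Contaminant:
    """Exogenous mtDNA mixture component (fraction of total reads)."""
    variants: tuple[VariantSpec, ...]
    fraction: float

    def __post_init__(self) -> None:
        if not 0 < self.fraction < 1:
            raise ValueError("contaminant fraction must be in (0,1)")


@dataclass(frozen=True)
class TruthSpec:
    """Full description of one synthetic sample.

    Defaults follow the sequencing design the pipeline targets: 150+150
    paired-end reads, ~350 +/- 50 bp inserts, constant Q35 base quality with
    a 1e-3 per-base miscall rate, and a 20x miscall boost within 3 bp after
    homopolymer runs of length >= 4 (biased toward the run base).
    """

    base_haplotype: tuple[VariantSpec, ...] = ()
    phps: tuple[PHP, ...] = ()
    donors: tuple[NUMTDonor, ...] = ()
    contaminant: Optional[Contaminant] = None
    target_depth: float = 1000.0
    read_length: int = 150
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    error_rate: float = 0.001
    base_quality: int = 35
    post_homopolymer_boost: float = 20.0
    run_bias: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.target_depth <= 0:
            raise ValueError("target_depth must be > 0")
        if self.read_length > self.insert_mean:
            raise ValueError("read_length exceeds mean insert size")
        if sum(d.copy_fraction for d in self.donors) >= 1:
            raise ValueError("donor fractions must sum to < 1")
        for v in self.base_haplotype:
            if v.is_indel:
                raise ValueError(
                    "simulated base haplotypes are substitution-only"
                )


@dataclass
class ReadRecord:
    """One sequenced read with its truth label."""
    id: str
    mate: int
    sequence: str
    qualities: str
    truth_origin: str  # 'mtDNA' | donor name | 'contaminant'
    truth_start: int   # 1-based fragment start on the reference circle

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence/quality length mismatch")


# ---------------------------------------------------------------------------
# Core simulation
# ---------------------------------------------------------------------------

def _post_run_boost(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mask of positions within 3 bp after a run >= 4, and the run's base."""
    n, rl = mat.shape
    boosted = np.zeros((n, rl), dtype=bool)
    runbase = np.zeros((n, rl), dtype=np.uint8)
    runlen = np.ones(n, dtype=np.int32)
    dist = np.full(n, 99, dtype=np.int32)
    rb = np.zeros(n, dtype=np.uint8)
    for j in range(1, rl):
        same = mat[:, j] == mat[:, j - 1]
        ended = (~same) & (runlen >= 4)
        rb = np.where(ended, mat[:, j - 1], rb)
        dist = np.where(ended, 1, np.minimum(dist + 1, 99))
        runlen = np.where(same, runlen + 1, 1)
        boosted[:, j] = dist <= 3
        runbase[:, j] = rb
    return boosted, runbase


def _inject_errors(mat: np.ndarray, spec: TruthSpec,
                   rng: np.random.Generator) -> np.ndarray:
    if spec.error_rate <= 0 or mat.size == 0:
        return mat
    boosted, runbase = _post_run_boost(mat)
    p = np.where(boosted, spec.error_rate * spec.post_homopolymer_boost,
                 spec.error_rate)
    err = rng.random(mat.shape) < p
    other = (mat + rng.integers(1, 4, size=mat.shape, dtype=np.uint8)) % 4
    toward_run = boosted & (runbase != mat) & (
        rng.random(mat.shape) < spec.run_bias
    )
    out = mat.copy()
    out[err] = np.where(toward_run[err], runbase[err], other[err])
    return out


def _fragment_reads(mol: np.ndarray, starts: np.ndarray, flen: np.ndarray,
                    rl: int, circular: bool) -> tuple[np.ndarray, np.ndarray]:
    """Mate-1 (forward) and mate-2 (reverse-complemented) code matrices."""
    M = mol.size
    offs = np.arange(rl)
    p1 = starts[:, None] + offs
    p2 = starts[:, None] + (flen[:, None] - rl) + offs
    if circular:
        p1 %= M
        p2 %= M
    r1 = mol[p1]
    r2 = (3 - mol[p2])[:, ::-1]  # reverse complement in code space
    return r1, r2


def simulate_sample(spec: TruthSpec,
                    reference: ReferenceGenome | None = None,
                    sample_id: str = "sample",
                    ) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Simulate one sample; returns reads and a per-pair truth table.

    The truth table has one row per read pair: ``read_id``, ``origin``
    (mtDNA, donor name, or contaminant) and ``truth_start`` (1-based
    fragment start on the source molecule, in reference coordinates).
    """
    spec.validate()
    ref = reference if reference is not None else load_reference()
    L = len(ref)
    rl = spec.read_length
    rng = np.random.default_rng(spec.seed)

    mt_codes = encode_bases(apply_variants(ref, list(spec.base_haplotype)))

    def draw_flen(n: int, maxlen: int | None = None) -> np.ndarray:
        f = np.rint(rng.normal(spec.insert_mean, spec.insert_sd, n)).astype(int)
        f = np.maximum(f, rl)
        if maxlen is not None:
            f = np.minimum(f, maxlen)
        return f

    groups: list[tuple[np.ndarray, np.ndarray, str, np.ndarray]] = []

    # Authentic mtDNA fragments, uniform on the circle.
    n_mt = int(round(spec.target_depth * L / (2 * rl)))
    starts = rng.integers(0, L, n_mt)
    flen = draw_flen(n_mt)
    r1, r2 = _fragment_reads(mt_codes, starts, flen, rl, circular=True)
    # Plant heteroplasmies: each fragment carries the minor base
    # independently with the PHP's fraction.
    for php in spec.phps:
        minor_code = encode_bases(php.minor)[0]
        carrier = rng.random(n_mt) < php.fraction
        tgt = (php.position - 1 - starts) % L
        hit1 = carrier & (tgt < rl)
        r1[hit1, tgt[hit1]] = minor_code
        off2 = (php.position - 1 - (starts + flen - rl)) % L
        hit2 = carrier & (off2 < rl)
        r2[hit2, rl - 1 - off2[hit2]] = 3 - minor_code
    groups.append((r1, r2, "mtDNA", starts + 1))

    # NUMT donor fragments, uniform over the linear homology span.
    for donor in spec.donors:
        if donor.copy_fraction <= 0:
            continue
        donor_codes = encode_bases(apply_variants(ref, list(donor.variants)))
        hom = donor.homology_region
        hom_pos = np.asarray(hom.positions(L)) - 1
        mol = donor_codes[hom_pos]
        M = mol.size
        f = donor.copy_fraction
        local_depth = spec.target_depth * f / (1 - f)
        span = max(M - int(spec.insert_mean) + 1, 1)
        n_d = int(round(local_depth * span / (2 * rl)))
        if n_d == 0:
            continue
        flen_d = draw_flen(n_d, maxlen=M)
        starts_d = rng.integers(0, np.maximum(M - flen_d + 1, 1))
        r1, r2 = _fragment_reads(mol, starts_d, flen_d, rl, circular=False)
        groups.append((r1, r2, donor.name, hom_pos[starts_d] + 1))

    # Exogenous contamination: a second mtDNA haplotype over the whole circle.
    if spec.contaminant is not None:
        c = spec.contaminant
        n_c = int(round(n_mt * c.fraction / (1 - c.fraction)))
        if n_c > 0:
            cont_codes = encode_bases(apply_variants(ref, list(c.variants)))
            starts_c = rng.integers(0, L, n_c)
            flen_c = draw_flen(n_c)
            r1, r2 = _fragment_reads(cont_codes, starts_c, flen_c, rl,
                                     circular=True)
            groups.append((r1, r2, "contaminant", starts_c + 1))

    mat1 = np.concatenate([g[0] for g in groups])
    mat2 = np.concatenate([g[1] for g in groups])
    origins = np.concatenate(
        [np.repeat(g[2], g[0].shape[0]) for g in groups]
    )
    truth_starts = np.concatenate([g[3] for g in groups])

    mat1 = _inject_errors(mat1, spec, rng)
    mat2 = _inject_errors(mat2, spec, rng)

    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    qual = chr(33 + spec.base_quality) * rl
    n = mat1.shape[0]
    ascii1 = lut[mat1]
    ascii2 = lut[mat2]
    reads: list[ReadRecord] = []
    for i in range(n):
        rid = f"{sample_id}_{i:06d}"
        origin = str(origins[i])
        start = int(truth_starts[i])
        reads.append(ReadRecord(rid, 1, ascii1[i].tobytes().decode("ascii"),
                                qual, origin, start))
        reads.append(ReadRecord(rid, 2, ascii2[i].tobytes().decode("ascii"),
                                qual, origin, start))
    truth = pd.DataFrame({
        "read_id": [f"{sample_id}_{i:06d}" for i in range(n)],
        "origin": origins,
        "truth_start": truth_starts.astype(int),
    })
    return reads, truth


# ---------------------------------------------------------------------------
# FASTQ / truth-table I/O
# ---------------------------------------------------------------------------

def write_fastq(reads: Sequence[ReadRecord], path_r1, path_r2) -> None:
    """Write mate-paired 4-line FASTQ files (records paired by id)."""
    if not reads:
        raise ValueError("empty read set")
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for r in reads:
            fh = f1 if r.mate == 1 else f2
            fh.write(f"@{r.id}/{r.mate} origin={r.truth_origin}"
                     f" start={r.truth_start}\n{r.sequence}\n+\n{r.qualities}\n")


def read_fastq(path_r1, path_r2) -> list[ReadRecord]:
    reads: list[ReadRecord] = []
    for mate, path in ((1, path_r1), (2, path_r2)):
        with open(path) as fh:
            while True:
                header = fh.readline().strip()
                if not header:
                    break
                seq = fh.readline().strip()
                fh.readline()
                qual = fh.readline().strip()
                name = header[1:].split()[0]
                rid = name.rsplit("/", 1)[0]
                origin, start = "unknown", 0
                for tokn in header.split()[1:]:
                    if tokn.startswith("origin="):
                        origin = tokn[7:]
                    elif tokn.startswith("start="):
                        start = int(tokn[6:])
                reads.append(ReadRecord(rid, mate, seq, qual, origin, start))
    reads.sort(key=lambda r: (r.id, r.mate))
    return reads


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
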