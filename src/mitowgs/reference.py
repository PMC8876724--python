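"""Circular mitochondrial reference handling.

The human mitogenome is a 16,569-bp circle. Forensic mtDNA convention is
used throughout: coordinates are 1-based with both ends inclusive, regions
may wrap the origin (position 16,569 is followed by position 1), and
variants are written as differences from the reference (``A263G``,
``315.1C``, ``315del``).

The bundled reference (``data/synthetic_rCRS.fasta``) is a *synthetic*
stand-in for the rCRS: a 16,569-bp sequence whose homopolymer structure
(HVS1/HVS2 A- and C-stretches) and reference bases at every position used
by the built-in NUMT signatures, catalogs and hotspot lists match the real
rCRS, while the remaining filler is generated from a fixed seed. All
coordinate arithmetic and classification logic in this package is
position-based and independent of the filler sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MT_LENGTH = 16_569

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC two-base ambiguity codes, keyed by the sorted base pair.
IUPAC_CODES = {
    "AG": "R", "CT": "Y", "CG": "S", "AT": "W", "GT": "K", "AC": "M",
}
IUPAC_BASES = {code: pair for pair, code in IUPAC_CODES.items()}


def iupac_code(base1: str, base2: str) -> str:
    """Two-base IUPAC ambiguity code (order-insensitive)."""
    key = "".join(sorted((base1.upper(), base2.upper())))
    try:
        return IUPAC_CODES[key]
    except KeyError:
        raise ValueError(f"no two-base IUPAC code for {base1}/{base2}") from None


def encode_bases(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 array (A=0, C=1, G=2, T=3)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.empty(arr.size, dtype=np.uint8)
    lut = np.full(256, 255, dtype=np.uint8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    out[:] = lut[arr]
    if (out == 255).any():
        bad = seq[int(np.argmax(out == 255))]
        raise ValueError(f"non-ACGT base {bad!r} in sequence")
    return out


def decode_bases(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in np.asarray(codes, dtype=np.uint8))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Circular regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CircularRegion:
    """1-based inclusive interval on the mitochondrial circle.

    A region with ``start > end`` wraps the origin (e.g. the control region,
    nps 16,024-576).
    """

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValueError(f"positions must be >= 1: {self}")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def validate(self, genome_length: int = MT_LENGTH) -> None:
        if self.start > genome_length or self.end > genome_length:
            raise ValueError(
                f"region {self.start}-{self.end} outside 1..{genome_length}"
            )

    def length(self, genome_length: int = MT_LENGTH) -> int:
        self.validate(genome_length)
        if self.wraps:
            return (genome_length - self.start + 1) + self.end
        return self.end - self.start + 1

    def positions(self, genome_length: int = MT_LENGTH) -> list[int]:
        """Ordered 1-based positions, wrapping genome_length -> 1."""
        self.validate(genome_length)
        if self.wraps:
            return list(range(self.start, genome_length + 1)) + list(
                range(1, self.end + 1)
            )
        return list(range(self.start, self.end + 1))

    def contains(self, position: int, genome_length: int = MT_LENGTH) -> bool:
        if self.wraps:
            return position >= self.start or position <= self.end
        return self.start <= position <= self.end

    def complement(self, genome_length: int = MT_LENGTH) -> "CircularRegion":
        """The rest of the circle (undefined for a full-circle region)."""
        self.validate(genome_length)
        if self.length(genome_length) >= genome_length:
            raise ValueError("full-circle region has no complement")
        nxt = self.end % genome_length + 1
        prv = (self.start - 2) % genome_length + 1
        return CircularRegion(nxt, prv)

    def __str__(self) -> str:
        return f"{self.start}-{self.end}"

    @classmethod
    def parse(cls, text: str) -> "CircularRegion":
        m = re.fullmatch(r"\s*(\d+)\s*-\s*(\d+)\s*", text)
        if not m:
            raise ValueError(f"cannot parse region {text!r} (expected 'start-end')")
        return cls(int(m.group(1)), int(m.group(2)))


def region_length(region: CircularRegion, genome_length: int = MT_LENGTH) -> int:
    return region.length(genome_length)


def positions_in(region: CircularRegion, genome_length: int = MT_LENGTH) -> list[int]:
    return region.positions(genome_length)


#: Control region (spans the origin) and coding region: a partition of the circle.
CONTROL_REGION = CircularRegion(16_024, 576)
CODING_REGION = CircularRegion(577, 16_023)


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

_SUB_RE = re.compile(r"([ACGT])(\d+)([ACGTRYSWKM]?)")
_INS_RE = re.compile(r"(\d+)\.(\d+)([ACGT]+)")
_DEL_RE = re.compile(r"(\d+)del")


@dataclass(frozen=True)
class VariantSpec:
    """A single difference from the reference, in forensic nomenclature.

    kind='sub':  ``A263G`` (ref A at 263, alternate G). ``alt`` may be a
        two-base IUPAC code when representing a mixed call, or empty when the
        token names the rCRS base itself (the ``A263`` minor-is-reference
        convention).
    kind='ins':  ``315.1C`` — insertion of ``alt`` after anchor position,
        decimal suffix ``insert_index``.
    kind='del':  ``315del`` — deletion of the base at position.
    """

    position: int
    kind: str  # 'sub' | 'ins' | 'del'
    ref: str = ""
    alt: str = ""
    insert_index: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("sub", "ins", "del"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.kind == "sub" and self.alt and self.ref == self.alt:
            raise ValueError(f"substitution with ref == alt at {self.position}")
        if self.kind == "ins" and self.insert_index < 1:
            raise ValueError("insertion requires a decimal suffix >= .1")

    @property
    def is_indel(self) -> bool:
        return self.kind in ("ins", "del")

    def token(self) -> str:
        if self.kind == "sub":
            return f"{self.ref}{self.position}{self.alt}"
        if self.kind == "ins":
            return f"{self.position}.{self.insert_index}{self.alt}"
        return f"{self.position}del"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token()

    @classmethod
    def parse(cls, token: str) -> "VariantSpec":
        token = token.strip()
        m = _DEL_RE.fullmatch(token)
        if m:
            return cls(int(m.group(1)), "del")
        m = _INS_RE.fullmatch(token)
        if m:
            return cls(int(m.group(1)), "ins", alt=m.group(3),
                       insert_index=int(m.group(2)))
        m = _SUB_RE.fullmatch(token)
        if m:
            return cls(int(m.group(2)), "sub", ref=m.group(1), alt=m.group(3))
        raise ValueError(f"cannot parse variant token {token!r}")


def parse_haplotype(text: str) -> list[VariantSpec]:
    """Parse a whitespace-separated haplotype string."""
    return [VariantSpec.parse(tok) for tok in text.split()]


def haplotype_tokens(variants: Iterable[VariantSpec]) -> str:
    return " ".join(v.token() for v in sorted(variants, key=_variant_sort_key))


def _variant_sort_key(v: VariantSpec) -> tuple[int, int, int]:
    kind_rank = {"sub": 0, "del": 1, "ins": 2}[v.kind]
    return (v.position, kind_rank, v.insert_index)


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------

@dataclass
class ReferenceGenome:
    """A single circular (or linear) reference sequence."""

    name: str
    sequence: str
    circular: bool = True
    _codes: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self._codes = encode_bases(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        """uint8 encoding of the sequence (A=0 .. T=3); do not mutate."""
        return self._codes

    def base(self, position: int) -> str:
        """Reference base at a 1-based position."""
        if not 1 <= position <= len(self):
            raise ValueError(f"position {position} outside 1..{len(self)}")
        return self.sequence[position - 1]

    def subsequence(self, region: CircularRegion) -> str:
        if region.wraps and not self.circular:
            raise ValueError("wrapping region on a linear reference")
        return "".join(self.sequence[p - 1] for p in region.positions(len(self)))


def apply_variants(reference: ReferenceGenome | str,
                   variants: Sequence[VariantSpec]) -> str:
    """Build the linear sequence of a haplotype from reference + variants.

    Substitutions replace the base at their position, insertions add bases
    after their anchor (ordered by decimal suffix), deletions remove the
    base. Conflicting variants at one position, or a substitution whose
    stated ref base disagrees with the reference, raise ``ValueError``.
    """
    seq = reference.sequence if isinstance(reference, ReferenceGenome) else reference
    out: list[str] = list(seq)
    inserts: dict[int, list[VariantSpec]] = {}
    seen: dict[int, str] = {}
    for v in variants:
        if not 1 <= v.position <= len(seq):
            raise ValueError(f"variant position {v.position} outside reference")
        if v.kind == "ins":
            inserts.setdefault(v.position, []).append(v)
            continue
        if v.position in seen:
            raise ValueError(
                f"conflicting variants at position {v.position} "
                f"({seen[v.position]} vs {v.token()})"
            )
        seen[v.position] = v.token()
        if v.kind == "sub":
            if v.ref and seq[v.position - 1] != v.ref:
                raise ValueError(
                    f"ref mismatch at {v.position}: reference has "
                    f"{seq[v.position - 1]}, variant says {v.ref}"
                )
            if not v.alt:
                raise ValueError(f"substitution {v.token()} has no alternate base")
            out[v.position - 1] = v.alt
        else:  # deletion
            out[v.position - 1] = ""
    for pos, group in inserts.items():
        group = sorted(group, key=lambda v: v.insert_index)
        out[pos - 1] = out[pos - 1] + "".join(v.alt for v in group)
    return "".join(out)


def diff_substitutions(reference: ReferenceGenome | str, sequence: str,
                       ) -> list[VariantSpec]:
    """Position-wise diff of two equal-length sequences (substitutions only)."""
    ref = reference.sequence if isinstance(reference, ReferenceGenome) else reference
    if len(ref) != len(sequence):
        raise ValueError("diff_substitutions requires equal-length sequences")
    return [
        VariantSpec(i + 1, "sub", ref=r, alt=a)
        for i, (r, a) in enumerate(zip(ref, sequence))
        if r != a
    ]


def homopolymer_run(reference: ReferenceGenome, position: int) -> CircularRegion:
    """Maximal run of identical bases containing ``position``.

    On a circular reference the run may wrap the origin. A position whose
    neighbours differ yields a single-position region.
    """
    L = len(reference)
    seq = reference.sequence
    base = reference.base(position)
    i = position
    steps = 0
    while steps < L - 1:
        prv = (i - 2) % L + 1
        if seq[prv - 1] != base or (not reference.circular and prv > i):
            break
        i = prv
        steps += 1
    j = position
    steps = 0
    while steps < L - 1:
        nxt = j % L + 1
        if seq[nxt - 1] != base or (not reference.circular and nxt < j):
            break
        j = nxt
        steps += 1
    return CircularRegion(i, j)


# ---------------------------------------------------------------------------
# FASTA I/O and the bundled synthetic rCRS stand-in
# ---------------------------------------------------------------------------

def read_fasta(path, circular: bool = True) -> ReferenceGenome:
    record = next(SeqIO.parse(str(path), "fasta"))
    return ReferenceGenome(record.id, str(record.seq), circular=circular)


def write_fasta(reference: ReferenceGenome, path, description: str = "") -> None:
    record = SeqRecord(Seq(reference.sequence), id=reference.name,
                       description=description)
    SeqIO.write([record], str(path), "fasta")


# Reference bases pinned to the real rCRS at every position used by the
# built-in NUMT signatures, catalogs, hotspot lists and homopolymer regions.
_PINNED_BASES: dict[int, str] = {
    146: "T", 152: "T", 204: "T", 263: "A",
    # HVS2: A-stretch 300-302, C-stretch 303-315 interrupted by 310T.
    299: "C", 300: "A", 301: "A", 302: "A",
    **{p: "C" for p in range(303, 310)}, 310: "T",
    **{p: "C" for p in range(311, 316)}, 316: "G",
    # C-stretch at 956-960 (point heteroplasmy context at np 955).
    955: "A", **{p: "C" for p in range(956, 961)}, 961: "A",
    2887: "C", 4155: "C", 4917: "A", 5054: "G", 5147: "G",
    # C-stretch around np 10,946.
    10942: "A", **{p: "C" for p in range(10943, 10949)}, 10949: "T",
    11386: "T", 12285: "T",
    # ND5 NUMT hotspot region.
    12684: "G", 12705: "C", 13062: "A", 13095: "T", 13105: "A",
    14905: "G",
    16093: "T", 16129: "G",
    # HVS1: A-stretch 16,180-16,183, C-stretch 16,184-16,193 with 16,189T.
    16179: "C", **{p: "A" for p in range(16180, 16184)},
    **{p: "C" for p in range(16184, 16189)}, 16189: "T",
    **{p: "C" for p in range(16190, 16194)}, 16194: "A",
    16311: "T", 16354: "C",
    # HVS1 NUMT signature region.
    16390: "G", 16399: "A", 16444: "C", 16496: "G", 16519: "T", 16527: "C",
}


def synthetic_rcrs_sequence(seed: int = 1042) -> str:
    """Generate the synthetic rCRS stand-in (see module docstring).

    Filler bases are drawn with human-mtDNA-like composition from a fixed
    seed; the positions in ``_PINNED_BASES`` are then overwritten with the
    real rCRS bases. The bundled FASTA fixture is this function's output at
    the default seed.
    """
    rng = np.random.default_rng(seed)
    comp = np.array([0.309, 0.313, 0.131, 0.247])
    codes = rng.choice(4, size=MT_LENGTH, p=comp).astype(np.uint8)
    for pos, base in _PINNED_BASES.items():
        codes[pos - 1] = _BASE_INDEX[base]
    return decode_bases(codes)


def load_reference() -> ReferenceGenome:
    """Load the bundled (synthetic stand-in) mitochondrial reference."""
    path = resources.files("mitowgs.data") / "synthetic_rCRS.fasta"
    with resources.as_file(path) as p:
        ref = read_fasta(p, circular=True)
    if len(ref) != MT_LENGTH:
        raise ValueError(f"bundled reference has length {len(ref)}")
    return ref
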