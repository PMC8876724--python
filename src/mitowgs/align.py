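"""Consensus mapping of short reads to the circular mitochondrial reference.

The workflow mirrors the consensus-mapping strategy used to keep reads from
nuclear mtDNA segments (NUMTs) out of the final alignment:

1. map all reads to the circularized reference with permissive acceptance
   parameters (length fraction 0.5, similarity fraction 0.8);
2. build the per-position majority (consensus) sequence of the sample;
3. remap all reads to that consensus with highly stringent parameters
   (length fraction 0.95, similarity fraction 0.95) — reads dissimilar to
   the sample's own haplotype (NUMT reads, contaminants) are preferentially
   lost here;
4. realign the surviving reads to reference coordinates for variant calling.

Acceptance contract: an alignment is accepted iff its length fraction
(aligned read bases / read length) and similarity fraction (matches /
aligned columns, read-insert columns excluded) both reach the configured
parameters. Circularity is handled by aligning against the doubled
reference and reducing coordinates mod L. Reads with equally good
alignments at two or more distinct loci are discarded (conservative
multi-mapping rule), and mates are aligned independently.

The aligner itself is exact 15-mer seeding plus gapless extension for the
common case, with an edlib infix alignment as the gapped fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np

from .reference import (
    BASES,
    MT_LENGTH,
    ReferenceGenome,
    decode_bases,
    encode_bases,
)
from .simulate import ReadRecord

__all__ = [
    "MappingParams", "DEFAULT_PARAMS", "STRICT_PARAMS", "AlignmentRecord",
    "ReadMapping", "Aligner", "align_read", "map_reads", "build_consensus",
    "consensus_workflow", "ConsensusWorkflowResult",
]


@dataclass(frozen=True)
class MappingParams:
    length_fraction: float
    similarity_fraction: float

    def __post_init__(self) -> None:
        for v in (self.length_fraction, self.similarity_fraction):
            if not 0 < v <= 1:
                raise ValueError("mapping fractions must be in (0,1]")


DEFAULT_PARAMS = MappingParams(0.5, 0.8)
STRICT_PARAMS = MappingParams(0.95, 0.95)

_SEED_K = 15
_PAD = 12


@dataclass
class AlignmentRecord:
    """One accepted (or evaluated) read alignment, reference-oriented.

    ``codes``/``quals`` are stored in reference orientation (mate reversed
    where strand is '-'). ``cigar`` is None for a gapless full-length
    alignment (the common case); otherwise a tuple of (op, length) runs
    with ops '=', 'X', 'I' (read insert) and 'D' (read deletion).
    """

    read_id: str
    mate: int
    ref_start: int  # 1-based on the circle
    strand: str     # '+' | '-'
    codes: np.ndarray
    quals: np.ndarray
    nm: int
    length_fraction: float
    similarity_fraction: float
    accepted: bool
    cigar: Optional[tuple[tuple[str, int], ...]] = None

    @property
    def read_length(self) -> int:
        return int(self.codes.size)

    @property
    def gapless(self) -> bool:
        return self.cigar is None

    def sequence(self) -> str:
        return decode_bases(self.codes)

    def ops(self, reference: ReferenceGenome) -> tuple[tuple[str, int], ...]:
        """Explicit =/X/I/D run-length operations for this alignment."""
        if self.cigar is not None:
            return self.cigar
        L = len(reference)
        pos = (self.ref_start - 1 + np.arange(self.codes.size)) % L
        match = reference.codes[pos] == self.codes
        ops: list[tuple[str, int]] = []
        for m in match:
            op = "=" if m else "X"
            if ops and ops[-1][0] == op:
                ops[-1] = (op, ops[-1][1] + 1)
            else:
                ops.append((op, 1))
        return tuple(ops)


def _fractions_from_ops(ops: Iterable[tuple[str, int]],
                        read_length: int) -> tuple[float, float, int]:
    """(length_fraction, similarity_fraction, edit_ops) by column walk.

    Similarity counts matches over aligned columns excluding read-insert
    ('I') columns; length fraction counts read bases consumed ('=', 'X',
    'I') over the read length.
    """
    matches = read_bases = ref_cols = edits = 0
    for op, n in ops:
        if op == "=":
            matches += n
            read_bases += n
            ref_cols += n
        elif op == "X":
            read_bases += n
            ref_cols += n
            edits += n
        elif op == "I":
            read_bases += n
            edits += n
        elif op == "D":
            ref_cols += n
            edits += n
        else:  # pragma: no cover
            raise ValueError(f"unknown op {op!r}")
    lf = read_bases / read_length if read_length else 0.0
    sim = matches / ref_cols if ref_cols else 0.0
    return lf, sim, edits


_EDLIB_OP = {"=": "=", "X": "X", "I": "I", "D": "D"}


def _parse_edlib_cigar(cigar: str) -> tuple[tuple[str, int], ...]:
    ops: list[tuple[str, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((_EDLIB_OP[ch], int(num)))
            num = ""
    return tuple(ops)


class Aligner:
    """Seed-and-extend aligner against a doubled circular reference."""

    def __init__(self, reference: ReferenceGenome, k: int = _SEED_K):
        self.reference = reference
        self.k = k
        self.L = len(reference)
        codes = reference.codes
        if reference.circular:
            self.doubled = np.concatenate([codes, codes])
        else:
            self.doubled = codes
        self.doubled_str = decode_bases(self.doubled)
        self._powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
        n_kmers = self.L if reference.circular else max(self.L - k + 1, 0)
        windows = np.lib.stride_tricks.sliding_window_view(
            self.doubled[: n_kmers + k - 1], k
        )
        hashes = windows.astype(np.int64) @ self._powers
        order = np.argsort(hashes, kind="stable")
        sh = hashes[order]
        starts = np.flatnonzero(np.r_[True, sh[1:] != sh[:-1]])
        self._index: dict[int, np.ndarray] = {
            int(sh[s]): order[s:e]
            for s, e in zip(starts, np.r_[starts[1:], sh.size])
        }

    # -- seeding -----------------------------------------------------------
    def _kmer_hash(self, codes: np.ndarray, offset: int) -> int:
        return int(codes[offset: offset + self.k] @ self._powers)

    def seed_candidates(self, codes: np.ndarray,
                        offsets: Sequence[int]) -> set[int]:
        cands: set[int] = set()
        for off in offsets:
            hits = self._index.get(self._kmer_hash(codes, off))
            if hits is not None:
                for h in hits:
                    cands.add((int(h) - off) % self.L)
        return cands

    def _offsets(self, rl: int, dense: bool = False) -> list[int]:
        if dense:
            return list(range(0, rl - self.k + 1, self.k))
        return sorted({0, (rl - self.k) // 2, rl - self.k})

    # -- single-read alignment --------------------------------------------
    def _evaluate(self, codes: np.ndarray, cand: int,
                  ) -> tuple[int, int, Optional[tuple]]:
        """Best alignment at a candidate locus: (edits, start, cigar|None)."""
        rl = codes.size
        ref_slice = self.doubled[cand: cand + rl]
        if ref_slice.size == rl:
            mm = int((ref_slice != codes).sum())
            if mm <= 2:
                return mm, cand, None
        else:
            mm = rl
        lo = max(cand - _PAD, 0)
        hi = min(cand + rl + _PAD, self.doubled.size)
        res = edlib.align(decode_bases(codes), self.doubled_str[lo:hi],
                          mode="HW", task="path")
        if res["editDistance"] < 0 or res["cigar"] is None:
            return mm, cand, None
        if res["editDistance"] >= mm:
            return mm, cand, None
        start = lo + res["locations"][0][0]
        return res["editDistance"], start, _parse_edlib_cigar(res["cigar"])

    def align_one(self, codes: np.ndarray, quals: np.ndarray,
                  read_id: str, mate: int, params: MappingParams,
                  ) -> Optional[AlignmentRecord]:
        """Best alignment of one read (both strands); None if unplaceable.

        Returns a record with ``accepted`` reflecting the fraction gates;
        multi-mapping ties across distinct loci return None.
        """
        rl = codes.size
        if rl < self.k:
            return None
        best: list[tuple[int, int, Optional[tuple], str, np.ndarray, np.ndarray]] = []
        for strand, c, q in (
            ("+", codes, quals),
            ("-", (3 - codes)[::-1], quals[::-1] if quals is not None else None),
        ):
            cands = self.seed_candidates(c, self._offsets(rl))
            if not cands:
                cands = self.seed_candidates(c, self._offsets(rl, dense=True))
            for cand in sorted(cands):
                edits, start, cigar = self._evaluate(c, cand)
                best.append((edits, start, cigar, strand, c, q))
        if not best:
            return None
        best.sort(key=lambda t: (t[0], t[1]))
        top = best[0]
        # distinct-locus tie -> discard (conservative multi-mapping rule)
        for other in best[1:]:
            if other[0] != top[0]:
                break
            d = abs(other[1] % self.L - top[1] % self.L)
            if min(d, self.L - d) > rl:
                return None
        edits, start, cigar, strand, c, q = top
        if cigar is None:
            lf, sim = 1.0, (rl - edits) / rl
        else:
            lf, sim, edits = _fractions_from_ops(cigar, rl)
        accepted = (lf >= params.length_fraction
                    and sim >= params.similarity_fraction)
        return AlignmentRecord(
            read_id=read_id, mate=mate, ref_start=start % self.L + 1,
            strand=strand, codes=c, quals=q, nm=edits,
            length_fraction=lf, similarity_fraction=sim,
            accepted=accepted, cigar=cigar,
        )


@dataclass
class ReadMapping:
    """Accepted alignments of one sample against one reference."""

    reference: ReferenceGenome
    params: MappingParams
    records: list[AlignmentRecord]
    n_input: int = 0
    n_unplaced: int = 0
    n_multimapped: int = 0
    n_rejected: int = 0
    _mat: dict = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.records)

    # Structure-of-arrays view over the gapless records (the common case),
    # used by the vectorized pileup and phasing code.
    def matrices(self) -> dict:
        if self._mat:
            return self._mat
        gapless = [r for r in self.records if r.gapless]
        gapped = [r for r in self.records if not r.gapless]
        if gapless:
            mat = {
                "starts": np.array([r.ref_start for r in gapless]),
                "codes": np.stack([r.codes for r in gapless]),
                "quals": np.stack([r.quals for r in gapless]),
                "fwd": np.array([r.strand == "+" for r in gapless]),
                "ids": [r.read_id for r in gapless],
                "mates": np.array([r.mate for r in gapless]),
            }
        else:
            mat = {"starts": np.empty(0, dtype=int),
                   "codes": np.empty((0, 0), dtype=np.uint8),
                   "quals": np.empty((0, 0), dtype=np.uint8),
                   "fwd": np.empty(0, dtype=bool), "ids": [],
                   "mates": np.empty(0, dtype=int)}
        mat["gapped"] = gapped
        self._mat = mat
        return mat

    def pair_bases(self, position: int) -> dict[str, int]:
        """Base code observed at a position, per read pair.

        Pairs whose two mates disagree at the position are dropped.
        """
        L = len(self.reference)
        m = self.matrices()
        out: dict[str, int] = {}
        conflict: set[str] = set()
        if len(m["starts"]):
            rl = m["codes"].shape[1]
            off = (position - m["starts"]) % L
            cover = off < rl
            for idx in np.flatnonzero(cover):
                rid = m["ids"][idx]
                base = int(m["codes"][idx, off[idx]])
                if rid in out and out[rid] != base:
                    conflict.add(rid)
                out[rid] = base
        for r in m["gapped"]:
            base = _gapped_base_at(r, position, L)
            if base is None:
                continue
            if r.read_id in out and out[r.read_id] != base:
                conflict.add(r.read_id)
            out[r.read_id] = base
        for rid in conflict:
            out.pop(rid, None)
        return out

    def depth_per_position(self) -> np.ndarray:
        """Raw aligned-base depth (no quality filtering)."""
        L = len(self.reference)
        depth = np.zeros(L, dtype=np.int64)
        m = self.matrices()
        if len(m["starts"]):
            rl = m["codes"].shape[1]
            pos = (m["starts"][:, None] - 1 + np.arange(rl)) % L
            np.add.at(depth, pos.ravel(), 1)
        for r in m["gapped"]:
            for p, _code, _q in _walk_gapped(r, L):
                depth[p] += 1
        return depth


def _walk_gapped(record: AlignmentRecord, L: int):
    """Yield (0-based ref position, read base code, qual) for a gapped record."""
    rpos = record.ref_start - 1
    qpos = 0
    for op, n in record.cigar:
        if op in ("=", "X"):
            for i in range(n):
                yield (rpos + i) % L, int(record.codes[qpos + i]), int(
                    record.quals[qpos + i]
                )
            rpos += n
            qpos += n
        elif op == "I":
            qpos += n
        elif op == "D":
            rpos += n


def _gapped_base_at(record: AlignmentRecord, position: int,
                    L: int) -> Optional[int]:
    for p, code, _q in _walk_gapped(record, L):
        if p == position - 1:
            return code
    return None


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def align_read(read: ReadRecord | str, reference: ReferenceGenome | Aligner,
               params: MappingParams = DEFAULT_PARAMS,
               ) -> Optional[AlignmentRecord]:
    """Align a single read; None when unplaceable or multi-mapped."""
    aligner = (reference if isinstance(reference, Aligner)
               else Aligner(reference))
    if isinstance(read, str):
        codes = encode_bases(read)
        quals = np.full(codes.size, 35, dtype=np.uint8)
        rid, mate = "read", 1
    else:
        codes = encode_bases(read.sequence)
        quals = np.frombuffer(read.qualities.encode("ascii"),
                              dtype=np.uint8).astype(np.uint8) - 33
        rid, mate = read.id, read.mate
    return aligner.align_one(codes, quals, rid, mate, params)


def map_reads(reads: Sequence[ReadRecord],
              reference: ReferenceGenome | Aligner,
              params: MappingParams = DEFAULT_PARAMS) -> ReadMapping:
    """Map a read set; retains accepted alignments only.

    Vectorized fast path for reads whose seeds agree on a single locus and
    that align gaplessly; anything ambiguous falls back to the full
    per-read aligner.
    """
    aligner = (reference if isinstance(reference, Aligner)
               else Aligner(reference))
    ref = aligner.reference
    L = aligner.L
    mapping = ReadMapping(ref, params, [], n_input=len(reads))
    if not reads:
        return mapping
    rl = len(reads[0].sequence)
    uniform = all(len(r.sequence) == rl for r in reads)
    if not uniform or rl < aligner.k:
        for r in reads:
            _classify_record(mapping, align_read(r, aligner, params))
        return mapping

    n = len(reads)
    mat = np.empty((n, rl), dtype=np.uint8)
    for i, r in enumerate(reads):
        mat[i] = encode_bases(r.sequence)
    quals = np.empty((n, rl), dtype=np.uint8)
    for i, r in enumerate(reads):
        quals[i] = np.frombuffer(r.qualities.encode("ascii"),
                                 dtype=np.uint8).astype(np.uint8) - 33

    offsets = aligner._offsets(rl)
    powers = aligner._powers
    k = aligner.k

    def batch_candidates(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Unique agreed candidate per row (or -1) and an ambiguity flag."""
        hashes = [m[:, off: off + k].astype(np.int64) @ powers
                  for off in offsets]
        cand = np.full(n, -1, dtype=np.int64)
        ambiguous = np.zeros(n, dtype=bool)
        index = aligner._index
        for i in range(n):
            seen: set[int] = set()
            for off, hv in zip(offsets, hashes):
                hits = index.get(int(hv[i]))
                if hits is None:
                    continue
                if hits.size > 4:
                    ambiguous[i] = True
                    break
                for h in hits:
                    seen.add((int(h) - off) % L)
            if ambiguous[i]:
                continue
            if len(seen) == 1:
                cand[i] = seen.pop()
            elif len(seen) > 1:
                ambiguous[i] = True
        return cand, ambiguous

    cand_f, amb_f = batch_candidates(mat)
    rc = (3 - mat)[:, ::-1]
    need_rc = (cand_f < 0) & ~amb_f
    cand_r = np.full(n, -1, dtype=np.int64)
    amb_r = np.zeros(n, dtype=bool)
    if need_rc.any():
        cr, ar = batch_candidates(rc)
        cand_r[need_rc] = cr[need_rc]
        amb_r[need_rc] = ar[need_rc]

    use_f = cand_f >= 0
    use_r = (~use_f) & (cand_r >= 0)
    slow = ~(use_f | use_r)

    offs = np.arange(rl)
    mm = np.full(n, rl, dtype=np.int64)
    starts = np.zeros(n, dtype=np.int64)
    for sel, m, cand in ((use_f, mat, cand_f), (use_r, rc, cand_r)):
        if not sel.any():
            continue
        idx = np.flatnonzero(sel)
        for lo in range(0, idx.size, 50_000):  # bound peak memory
            chunk = idx[lo: lo + 50_000]
            pos = cand[chunk][:, None] + offs
            ref_slices = aligner.doubled[pos]
            mm[chunk] = (ref_slices != m[chunk]).sum(axis=1)
        starts[idx] = cand[idx]
    sim = (rl - mm) / rl
    # high-mismatch rows might be gapped alignments: give them the full path
    recheck = (use_f | use_r) & (sim < params.similarity_fraction) & (mm > 4)
    slow |= recheck
    use_f &= ~recheck
    use_r &= ~recheck

    min_sim = params.similarity_fraction
    for i in np.flatnonzero(use_f | use_r):
        s = float(sim[i])
        accepted = s >= min_sim  # length fraction is 1.0 on the fast path
        if not accepted:
            mapping.n_rejected += 1
            continue
        strand = "+" if use_f[i] else "-"
        codes_i = mat[i] if use_f[i] else rc[i]
        quals_i = quals[i] if use_f[i] else quals[i][::-1]
        mapping.records.append(AlignmentRecord(
            read_id=reads[i].id, mate=reads[i].mate,
            ref_start=int(starts[i]) % L + 1, strand=strand,
            codes=codes_i, quals=quals_i, nm=int(mm[i]),
            length_fraction=1.0, similarity_fraction=s, accepted=True,
        ))
    for i in np.flatnonzero(slow):
        rec = aligner.align_one(mat[i], quals[i], reads[i].id,
                                reads[i].mate, params)
        _classify_record(mapping, rec)
    return mapping


def _classify_record(mapping: ReadMapping,
                     rec: Optional[AlignmentRecord]) -> None:
    if rec is None:
        mapping.n_unplaced += 1
    elif not rec.accepted:
        mapping.n_rejected += 1
    else:
        mapping.records.append(rec)


def build_consensus(mapping: ReadMapping,
                    reference: ReferenceGenome) -> str:
    """Per-position majority base; ties and uncovered positions fall back
    to the reference base."""
    if not mapping.records:
        raise ValueError("cannot build a consensus from an empty mapping")
    L = len(reference)
    counts = np.zeros((L, 4), dtype=np.int64)
    m = mapping.matrices()
    if len(m["starts"]):
        rl = m["codes"].shape[1]
        pos = (m["starts"][:, None] - 1 + np.arange(rl)) % L
        np.add.at(counts, (pos.ravel(), m["codes"].ravel()), 1)
    for r in m["gapped"]:
        for p, code, _q in _walk_gapped(r, L):
            counts[p, code] += 1
    ref_codes = reference.codes
    # strict majority over the reference base; ties resolve to the reference
    best = counts.max(axis=1)
    arg = counts.argmax(axis=1)
    ref_count = counts[np.arange(L), ref_codes]
    consensus = np.where(ref_count >= best, ref_codes, arg).astype(np.uint8)
    consensus[best == 0] = ref_codes[best == 0]
    return decode_bases(consensus)


@dataclass
class ConsensusWorkflowResult:
    first_pass: ReadMapping
    consensus: str
    strict: ReadMapping
    final: ReadMapping


def consensus_workflow(reads: Sequence[ReadRecord],
                       reference: ReferenceGenome,
                       params_default: MappingParams = DEFAULT_PARAMS,
                       params_strict: MappingParams = STRICT_PARAMS,
                       ) -> ConsensusWorkflowResult:
    """Permissive map -> consensus -> stringent remap -> reference realign.

    The final mapping contains exactly the reads accepted by the stringent
    consensus remap, expressed in reference coordinates (the consensus is a
    per-position substitution of the reference, so coordinates transfer
    1:1). Realignment applies no acceptance gate.
    """
    first = map_reads(reads, reference, params_default)
    if not first.records:
        raise ValueError("first-pass mapping is empty; no consensus possible")
    consensus = build_consensus(first, reference)
    cons_ref = ReferenceGenome(reference.name + "_consensus", consensus,
                               circular=reference.circular)
    strict = map_reads(reads, cons_ref, params_strict)
    final = ReadMapping(reference, params_strict, [],
                        n_input=strict.n_input,
                        n_unplaced=strict.n_unplaced,
                        n_multimapped=strict.n_multimapped,
                        n_rejected=strict.n_rejected)
    L = len(reference)
    for rec in strict.records:
        if rec.gapless:
            pos = (rec.ref_start - 1 + np.arange(rec.codes.size)) % L
            nm = int((reference.codes[pos] != rec.codes).sum())
            lf, sim = 1.0, (rec.codes.size - nm) / rec.codes.size
            cigar = None
        else:
            cigar = rec.cigar
            nm = rec.nm
            lf, sim, _ = _fractions_from_ops(cigar, rec.read_length)
        final.records.append(AlignmentRecord(
            read_id=rec.read_id, mate=rec.mate, ref_start=rec.ref_start,
            strand=rec.strand, codes=rec.codes, quals=rec.quals, nm=nm,
            length_fraction=lf, similarity_fraction=sim, accepted=True,
            cigar=cigar,
        ))
    return ConsensusWorkflowResult(first, consensus, strict, final)
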