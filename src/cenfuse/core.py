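"""Sequence model, FASTA I/O and pairwise/multiple alignment.

Coordinates are 1-based inclusive throughout this package; BED output
(see :mod:`cenfuse.scan`) is 0-based half-open.

Identity is defined once, here: matching columns divided by *all*
alignment columns, gap columns included in the denominator. ``N`` never
matches anything (scored as a mismatch), which keeps identity estimates
conservative on ambiguous input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from cenfuse import _align

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

# primary alphabet is {A,C,G,T,N}; IUPAC ambiguity codes are tolerated so
# that consensus sequences (which use them at tie columns) remain first-class
# citizens. In alignment any non-ACGT code scores as a mismatch.
_VALID = set("ACGTNRYSWKMBDHV")

# nucleotide encoding shared with the numba kernels: 4-bit base-set masks
# (match = set intersection). N encodes to 0 so it matches nothing, as does
# the monomer scanner's mask sentinel.
_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
IUPAC_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "M": 3, "R": 5, "W": 9, "S": 6, "Y": 10, "K": 12,
    "V": 7, "H": 11, "D": 13, "B": 14,
    "N": 0,  # deliberately match-nothing (conservative identity)
}
_ENCODE = np.zeros(256, dtype=np.uint8)
for _b, _bits in IUPAC_BITS.items():
    _ENCODE[ord(_b)] = _bits


class FastaFormatError(ValueError):
    """Raised for malformed FASTA records."""


@dataclass(frozen=True)
class NucSequence:
    """A named nucleotide sequence over the alphabet {A,C,G,T,N}.

    Input is normalized on construction: lowercase is uppercased and U is
    mapped to T. Any other character is rejected.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        norm = self.seq.upper().replace("U", "T")
        if not norm:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(norm) - _VALID
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters: {sorted(bad)}"
            )
        object.__setattr__(self, "seq", norm)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap scoring. A gap of length L costs open + (L-1)*extend."""

    match_score: int = 1
    mismatch_score: int = -1
    gap_open: int = -2
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.match_score <= 0:
            raise ValueError("match_score must be positive")
        if self.mismatch_score >= self.match_score:
            raise ValueError("mismatch_score must be below match_score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")


DEFAULT_PARAMS = AlignParams()


@dataclass
class Alignment:
    """A pairwise local alignment.

    Coordinates are 1-based inclusive on the *original* (input-orientation)
    sequences. ``strand`` is the orientation of the query relative to the
    target; the gapped texts are given in the orientation that was aligned
    (i.e. the query is reverse-complemented in them when strand is '-').
    """

    query_id: str
    target_id: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str
    aligned_query: str
    aligned_target: str
    score: int
    identity: float

    @property
    def n_columns(self) -> int:
        return len(self.aligned_query)


def read_fasta(path) -> list[NucSequence]:
    """Read a multi-record FASTA file, preserving order.

    Raises :class:`FastaFormatError` naming the offending record for empty
    sequences or headers.
    """
    records: list[NucSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaFormatError(f"{path}: record with empty header")
        if len(rec.seq) == 0:
            raise FastaFormatError(f"{path}: record {rec.id!r} has no sequence")
        try:
            records.append(NucSequence(rec.id, str(rec.seq)))
        except ValueError as exc:
            raise FastaFormatError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[NucSequence], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def revcomp(seq: str) -> str:
    """Reverse complement of a plain string (IUPAC-unaware beyond ACGTN)."""
    return seq.translate(_COMPLEMENT)[::-1]


def reverse_complement(s: NucSequence) -> NucSequence:
    return NucSequence(s.id, revcomp(s.seq))


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string for the alignment kernels."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def _is_match(a: str, b: str) -> bool:
    """Column match rule: IUPAC base sets intersect; N and '-' never match."""
    if a == "-" or b == "-":
        return False
    return (IUPAC_BITS.get(a, 0) & IUPAC_BITS.get(b, 0)) != 0


def _identity_of(aln_q: str, aln_t: str) -> float:
    if not aln_q:
        return 0.0
    matches = sum(1 for a, b in zip(aln_q, aln_t) if _is_match(a, b))
    return matches / len(aln_q)


def _decode_path(q: str, t: str, qs: int, qe: int, ts: int, te: int, ops: np.ndarray):
    """Expand a traceback op-code array into gapped strings."""
    qi, ti = qs - 1, ts - 1
    aq, at = [], []
    for op in ops:
        if op == 0:  # diagonal
            aq.append(q[qi])
            at.append(t[ti])
            qi += 1
            ti += 1
        elif op == 1:  # gap in query, consume target
            aq.append("-")
            at.append(t[ti])
            ti += 1
        else:  # gap in target, consume query
            aq.append(q[qi])
            at.append("-")
            qi += 1
    return "".join(aq), "".join(at)


def _local_align_one(
    query: NucSequence, target: NucSequence, params: AlignParams, enc_q, enc_t
):
    score, qs, qe, ts, te = _align.sw_locate(
        enc_q,
        enc_t,
        params.match_score,
        params.mismatch_score,
        params.gap_open,
        params.gap_extend,
    )
    if score <= 0:
        return None
    ops = _align.nw_traceback(
        enc_q[qs - 1 : qe],
        enc_t[ts - 1 : te],
        params.match_score,
        params.mismatch_score,
        params.gap_open,
        params.gap_extend,
    )
    aq, at = _decode_path(query.seq, target.seq, qs, qe, ts, te, ops)
    return score, qs, qe, ts, te, aq, at


def local_align(
    query: NucSequence,
    target: NucSequence,
    params: AlignParams = DEFAULT_PARAMS,
    both_strands: bool = False,
) -> Alignment:
    """Maximum-scoring affine-gap local alignment (Smith-Waterman-Gotoh).

    With ``both_strands`` the better of the forward and reverse-complement
    query is returned, ties going to the forward strand. An all-mismatch pair
    yields an empty alignment with score 0.
    """
    if len(query) == 0 or len(target) == 0:
        raise ValueError("cannot align empty sequences")
    enc_t = encode(target.seq)
    enc_q = encode(query.seq)
    best = _local_align_one(query, target, params, enc_q, enc_t)
    best_strand = "+"
    if both_strands:
        rc = reverse_complement(query)
        alt = _local_align_one(rc, target, params, encode(rc.seq), enc_t)
        if alt is not None and (best is None or alt[0] > best[0]):
            best, best_strand = alt, "-"
    if best is None:
        return Alignment(
            query.id, target.id, 0, 0, 0, 0, "+", "", "", 0, 0.0
        )
    score, qs, qe, ts, te, aq, at = best
    if best_strand == "-":
        # map coordinates back onto the original query orientation
        m = len(query)
        qs, qe = m - qe + 1, m - qs + 1
        # gapped texts remain in the aligned (revcomp) orientation; rebuild
        # them from the revcomp query text which _local_align_one already used
    return Alignment(
        query.id,
        target.id,
        qs,
        qe,
        ts,
        te,
        best_strand,
        aq,
        at,
        int(score),
        _identity_of(aq, at),
    )


def global_align(
    a: NucSequence, b: NucSequence, params: AlignParams = DEFAULT_PARAMS
) -> Alignment:
    """End-to-end (Needleman-Wunsch) affine-gap alignment of two sequences."""
    ops = _align.nw_traceback(
        encode(a.seq),
        encode(b.seq),
        params.match_score,
        params.mismatch_score,
        params.gap_open,
        params.gap_extend,
    )
    aq, at = _decode_path(a.seq, b.seq, 1, len(a), 1, len(b), ops)
    score = _score_alignment(aq, at, params)
    return Alignment(
        a.id, b.id, 1, len(a), 1, len(b), "+", aq, at, score, _identity_of(aq, at)
    )


def _score_alignment(aq: str, at: str, params: AlignParams) -> int:
    score = 0
    in_gap = False
    for x, y in zip(aq, at):
        if x == "-" or y == "-":
            score += params.gap_extend if in_gap else params.gap_open
            in_gap = True
        else:
            in_gap = False
            score += params.match_score if _is_match(x, y) else params.mismatch_score
    return score


def pairwise_identity(
    a: NucSequence, b: NucSequence, params: AlignParams = DEFAULT_PARAMS
) -> float:
    """Identity of the end-to-end alignment of two sequences."""
    return global_align(a, b, params).identity


def multi_align(
    members: Sequence[NucSequence], params: AlignParams = DEFAULT_PARAMS
) -> list[str]:
    """Center-star multiple alignment.

    The center is the member with the highest mean pairwise (global)
    identity to the others, ties broken by input order. Adequate for the
    >=85%-identical monomer sets this package targets. Ungapping row ``i``
    recovers ``members[i].seq`` exactly.
    """
    if len(members) < 2:
        raise ValueError("multi_align needs at least 2 sequences")
    n = len(members)
    if n == 2:
        aln = global_align(members[0], members[1], params)
        return [aln.aligned_query, aln.aligned_target]

    ident = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident[i, j] = ident[j, i] = pairwise_identity(members[i], members[j], params)
    center = int(np.argmax(ident.sum(axis=1)))

    # merge pairwise alignments onto a master gapped center ("once a gap,
    # always a gap")
    master = list(members[center].seq)
    rows: dict[int, list[str]] = {center: master}
    order = [i for i in range(n) if i != center]
    for idx in order:
        aln = global_align(members[center], members[idx], params)
        ac, am = aln.aligned_query, aln.aligned_target
        # positions of center residues in the current master
        res_pos = [k for k, c in enumerate(master) if c != "-"]
        new_cols: list[int] = []  # master column for each alignment column
        ri = 0
        inserts: list[tuple[int, int]] = []  # (master position, count) of new gaps
        merged_master_len = len(master)
        # First, find where ac introduces gaps in the center -> new master columns
        out_master = []
        out_rows = {k: [] for k in rows}
        out_new = []
        mi = 0  # index into master columns
        ci = 0  # index into alignment columns
        while ci < len(ac) or mi < len(master):
            if mi < len(master) and master[mi] == "-" and (ci >= len(ac) or ac[ci] != "-" or True):
                # existing master gap column not represented in this pairwise
                # alignment: copy it through, new member gets a gap
                out_master.append("-")
                for k in rows:
                    out_rows[k].append(rows[k][mi])
                out_new.append("-")
                mi += 1
                continue
            if ci < len(ac) and ac[ci] == "-":
                # center gap introduced by the new member: insert a column
                out_master.append("-")
                for k in rows:
                    out_rows[k].append("-")
                out_new.append(am[ci])
                ci += 1
                continue
            # center residue column
            out_master.append(master[mi])
            for k in rows:
                out_rows[k].append(rows[k][mi])
            out_new.append(am[ci])
            mi += 1
            ci += 1
        master = out_master
        rows = {k: out_rows[k] for k in out_rows}
        rows[idx] = out_new

    width = len(master)
    result = []
    for i in range(n):
        row = "".join(rows[i])
        assert len(row) == width
        result.append(row)
    return result
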