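"""HOR-like block decomposition and fusion-provenance inference.

A block is a maximal left-to-right run of same-strand monomers in which
every joining monomer matches the block's running consensus at or above the
block identity threshold, with genomic gaps no larger than ``max_intra_gap``.
Larger gaps are reported as insertions and always terminate the block.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from cenfuse.core import (
    DEFAULT_PARAMS,
    AlignParams,
    NucSequence,
    multi_align,
    pairwise_identity,
    revcomp,
)
from cenfuse.scan import Monomer

# IUPAC code for each non-empty base set (used for consensus ties)
IUPAC_FOR_SET = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("AC"): "M",
    frozenset("GT"): "K",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


@dataclass
class Block:
    block_id: int
    member_indices: list[int]
    orientation: str
    consensus: NucSequence
    n_members: int
    mean_pairwise_identity: float
    divergence_range: tuple[float, float]
    start: int = 0  # genomic span of members, 1-based inclusive
    end: int = 0


@dataclass(frozen=True)
class Insertion:
    source_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ProvenanceAssignment:
    fused_block_id: int
    donor_label: str
    donor_block_id: int
    identity: float
    orientation_relation: str
    runner_up_identity: float
    is_tie: bool


def consensus_text(member_seqs: list[str], params: AlignParams = DEFAULT_PARAMS) -> str:
    """Column-wise majority consensus of a multiple alignment.

    Ties between bases take the IUPAC code of the tied set (never an
    arbitrary base, so the result is order-independent); a column where
    gaps hold a strict majority is dropped.
    """
    if len(member_seqs) == 1:
        return member_seqs[0]
    rows = multi_align([NucSequence(f"m{i}", s) for i, s in enumerate(member_seqs)], params)
    out = []
    for col in zip(*rows):
        gaps = col.count("-")
        bases = [c for c in col if c != "-"]
        if not bases:
            continue
        counts: dict[str, int] = {}
        for b in bases:
            counts[b] = counts.get(b, 0) + 1
        top = max(counts.values())
        if gaps > top:
            continue
        tied = frozenset(b for b, c in counts.items() if c == top)
        if "N" in tied:
            out.append("N")
        else:
            out.append(IUPAC_FOR_SET[frozenset("".join(tied))])
    return "".join(out)


def block_consensus(members: list[NucSequence], params: AlignParams = DEFAULT_PARAMS) -> NucSequence:
    if not members:
        raise ValueError("block_consensus needs at least 1 member")
    return NucSequence("consensus", consensus_text([m.seq for m in members], params))


def segment_blocks(
    monomers: list[Monomer],
    min_block_identity: float = 0.85,
    max_intra_gap: int = 100,
    params: AlignParams = DEFAULT_PARAMS,
) -> tuple[list[Block], list[Insertion]]:
    """Greedy left-to-right segmentation of a monomer array into blocks.

    Monomers must be sorted, non-overlapping and from a single source (as
    produced by :func:`cenfuse.scan.find_monomers`). Identity tests are
    against the running consensus of the current block, on the
    reference-oriented monomer sequences, so they are strand-free.
    """
    if not monomers:
        return [], []
    src = {m.source_id for m in monomers}
    if len(src) != 1:
        raise ValueError("segment_blocks expects monomers from a single source")
    source_id = src.pop()

    blocks: list[Block] = []
    insertions: list[Insertion] = []
    cur: list[Monomer] = [monomers[0]]
    cur_cons = monomers[0].seq

    def _finalize() -> None:
        members = list(cur)
        seqs = [m.seq for m in members]
        if len(members) == 1:
            mean_id, dmin, dmax = 1.0, 0.0, 0.0
        else:
            idents = [
                pairwise_identity(NucSequence("a", x), NucSequence("b", y), params)
                for x, y in itertools.combinations(seqs, 2)
            ]
            mean_id = sum(idents) / len(idents)
            dmin = 1.0 - max(idents)
            dmax = 1.0 - min(idents)
        blocks.append(
            Block(
                block_id=len(blocks),
                member_indices=[m.index for m in members],
                orientation=members[0].strand,
                consensus=NucSequence(f"block{len(blocks)}", cur_cons),
                n_members=len(members),
                mean_pairwise_identity=mean_id,
                divergence_range=(dmin, dmax),
                start=members[0].start,
                end=members[-1].end,
            )
        )

    for prev, mon in zip(monomers, monomers[1:]):
        gap = mon.start - prev.end - 1
        joins = (
            mon.strand == cur[0].strand
            and gap <= max_intra_gap
            and pairwise_identity(NucSequence("m", mon.seq), NucSequence("c", cur_cons), params)
            >= min_block_identity
        )
        if joins:
            cur.append(mon)
            cur_cons = consensus_text([m.seq for m in cur], params)
        else:
            _finalize()
            if gap > max_intra_gap:
                insertions.append(Insertion(source_id, prev.end + 1, mon.start - 1))
            cur = [mon]
            cur_cons = mon.seq
    _finalize()
    return blocks, insertions


def block_homology_matrix(
    blocks_x: list[Block],
    blocks_y: list[Block],
    params: AlignParams = DEFAULT_PARAMS,
) -> list[list[tuple[float, str]]]:
    """Pairwise consensus homology: (identity, orientation_relation).

    Consensus sequences are compared as given; the relation records whether
    the forward or reverse-complement comparison scored better ('same' /
    'inverted').
    """
    from cenfuse.core import local_align

    matrix = []
    for bx in blocks_x:
        row = []
        for by in blocks_y:
            aln = local_align(bx.consensus, by.consensus, params, both_strands=True)
            row.append((aln.identity, "same" if aln.strand == "+" else "inverted"))
        matrix.append(row)
    return matrix


def _genomic_consensus(block: Block) -> NucSequence:
    """Block consensus in its genomic orientation."""
    seq = block.consensus.seq
    if block.orientation == "-":
        seq = revcomp(seq)
    return NucSequence(block.consensus.id, seq)


def infer_provenance(
    fused_blocks: list[Block],
    donor_a_blocks: list[Block],
    donor_b_blocks: list[Block],
    params: AlignParams = DEFAULT_PARAMS,
    tie_epsilon: float = 1e-9,
) -> list[ProvenanceAssignment]:
    """Assign each fused block to its most similar donor block.

    Identity is the strand-aware consensus homology; the orientation
    relation is evaluated between genomically oriented consensuses, so an
    inverted fused block matching an inverted donor block reports 'same'.
    Near-exact ties between the best and runner-up candidate are flagged
    rather than silently broken.
    """
    from cenfuse.core import local_align

    if not donor_a_blocks or not donor_b_blocks:
        raise ValueError("both donors must contribute at least one block")
    assignments = []
    for fb in fused_blocks:
        fseq = _genomic_consensus(fb)
        candidates = []
        for label, donor in (("A", donor_a_blocks), ("B", donor_b_blocks)):
            for db in donor:
                aln = local_align(fseq, _genomic_consensus(db), params, both_strands=True)
                relation = "same" if aln.strand == "+" else "inverted"
                candidates.append((aln.identity, label, db.block_id, relation))
        candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
        best = candidates[0]
        runner_up = candidates[1][0] if len(candidates) > 1 else 0.0
        assignments.append(
            ProvenanceAssignment(
                fused_block_id=fb.block_id,
                donor_label=best[1],
                donor_block_id=best[2],
                identity=best[0],
                orientation_relation=best[3],
                runner_up_identity=runner_up,
                is_tie=abs(best[0] - runner_up) < tie_epsilon,
            )
        )
    return assignments


def block_table(blocks: list[Block]) -> "pandas.DataFrame":  # noqa: F821
    import pandas as pd

    return pd.DataFrame(
        {
            "block_id": [b.block_id for b in blocks],
            "start": [b.start for b in blocks],
            "end": [b.end for b in blocks],
            "orientation": [b.orientation for b in blocks],
            "n_members": [b.n_members for b in blocks],
            "mean_identity": [b.mean_pairwise_identity for b in blocks],
            "divergence_min": [b.divergence_range[0] for b in blocks],
            "divergence_max": [b.divergence_range[1] for b in blocks],
        }
    )
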