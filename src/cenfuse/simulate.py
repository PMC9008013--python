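"""Seeded satellite-array, donor and fusion-chromosome simulator.

Arrays are built top-down: one ancestral monomer, a per-block consensus
diverged from it, per-monomer mutation inside each block, orientation
applied per block, and uniform-random insertions between blocks plus
non-satellite flanks. Every planted feature is recorded as ground truth.

The substitution model is i.i.d. per site with two parameters (divergence,
transition:transversion ratio); a substituted site becomes a transition
with probability R/(R+1), otherwise one of the two transversion partners
uniformly. This keeps all expectations closed-form for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cenfuse.core import NucSequence, revcomp

_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS_OF = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class BlockSpec:
    n_monomers: int
    orientation: str = "+"
    divergence_from_ancestor: float = 0.0

    def __post_init__(self) -> None:
        if self.n_monomers < 1:
            raise ValueError("n_monomers must be >= 1")
        if self.orientation not in "+-":
            raise ValueError("orientation must be '+' or '-'")
        if not 0 <= self.divergence_from_ancestor <= 0.75:
            raise ValueError("divergence must be in [0, 0.75]")


@dataclass(frozen=True)
class SimConfig:
    blocks: tuple[BlockSpec, ...]
    monomer_length: int = 1400
    gc_content: float = 0.5
    intra_block_divergence: float = 0.02
    ts_tv_ratio: float = 2.0
    insertion_length_range: tuple[int, int] = (200, 500)
    flank_length: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("at least one block spec required")
        if not 0 <= self.intra_block_divergence <= 0.75:
            raise ValueError("intra_block_divergence must be in [0, 0.75]")
        if self.ts_tv_ratio <= 0:
            raise ValueError("ts_tv_ratio must be positive")
        lo, hi = self.insertion_length_range
        if lo < 0 or hi < lo:
            raise ValueError("bad insertion_length_range")


@dataclass(frozen=True)
class SubRecord:
    position: int  # 1-based
    from_base: str
    to_base: str
    cls: str


@dataclass(frozen=True)
class MonomerTruth:
    start: int
    end: int
    strand: str
    block_id: int
    seq: str  # reference-oriented
    donor_label: str = ""
    n_substitutions: int = 0


@dataclass(frozen=True)
class InsertionTruth:
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class BlockTruth:
    block_id: int
    orientation: str
    start: int
    end: int
    n_monomers: int
    consensus: str  # reference-oriented block ancestor
    donor_label: str = ""


@dataclass
class ArrayTruth:
    ancestor: str
    monomers: list[MonomerTruth]
    insertions: list[InsertionTruth]
    blocks: list[BlockTruth]
    flank_length: int


def simulate_monomer(length: int, gc: float = 0.5, seed=0) -> NucSequence:
    """Random monomer with the requested GC content."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = _rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.array(list("ACGT")), size=length, p=probs)
    return NucSequence("monomer", "".join(bases))


def mutate(seq: str, divergence: float, ts_tv_ratio: float, seed=0) -> tuple[str, list[SubRecord]]:
    """Substitute each site independently with probability ``divergence``."""
    if not 0 <= divergence <= 0.75:
        raise ValueError("divergence must be in [0, 0.75]")
    rng = _rng(seed)
    out = list(seq)
    records: list[SubRecord] = []
    if divergence == 0:
        return seq, records
    hits = rng.random(len(seq)) < divergence
    p_ts = ts_tv_ratio / (ts_tv_ratio + 1.0)
    for pos in np.nonzero(hits)[0]:
        base = out[pos]
        if base not in _TRANSITION_OF:
            continue  # leave N and ambiguity codes untouched
        if rng.random() < p_ts:
            new, cls = _TRANSITION_OF[base], "transition"
        else:
            new = _TRANSVERSIONS_OF[base][rng.integers(2)]
            cls = "transversion"
        out[pos] = new
        records.append(SubRecord(int(pos) + 1, base, new, cls))
    return "".join(out), records


def _random_insert(rng: np.random.Generator, length_range: tuple[int, int]) -> str:
    lo, hi = length_range
    if hi == 0:
        return ""
    length = int(rng.integers(lo, hi + 1))
    if length == 0:
        return ""
    return "".join(rng.choice(np.array(list("ACGT")), size=length))


def _assemble(
    rng: np.random.Generator,
    block_monomers: list[list[str]],  # reference-oriented member sequences
    block_specs_orient: list[str],
    block_ancestors: list[str],
    donor_labels: list[str],
    insertion_length_range: tuple[int, int],
    flank_length: int,
    ancestor: str,
    seq_id: str,
) -> tuple[NucSequence, ArrayTruth]:
    parts: list[str] = []
    pos = 0
    monomers: list[MonomerTruth] = []
    insertions: list[InsertionTruth] = []
    blocks: list[BlockTruth] = []

    def _emit(text: str) -> tuple[int, int]:
        nonlocal pos
        start = pos + 1
        parts.append(text)
        pos += len(text)
        return start, pos

    if flank_length > 0:
        _emit("".join(rng.choice(np.array(list("ACGT")), size=flank_length)))
    for b, (members, orient, anc, label) in enumerate(
        zip(block_monomers, block_specs_orient, block_ancestors, donor_labels)
    ):
        if b > 0:
            ins = _random_insert(rng, insertion_length_range)
            if ins:
                s, e = _emit(ins)
                insertions.append(InsertionTruth(s, e))
        block_start = pos + 1
        for ref_seq in members:
            placed = ref_seq if orient == "+" else revcomp(ref_seq)
            s, e = _emit(placed)
            monomers.append(
                MonomerTruth(s, e, orient, b, ref_seq, donor_label=label)
            )
        blocks.append(
            BlockTruth(b, orient, block_start, pos, len(members), anc, donor_label=label)
        )
    if flank_length > 0:
        _emit("".join(rng.choice(np.array(list("ACGT")), size=flank_length)))
    truth = ArrayTruth(ancestor, monomers, insertions, blocks, flank_length)
    return NucSequence(seq_id, "".join(parts)), truth


def simulate_array(cfg: SimConfig, seq_id: str = "sim_array") -> tuple[NucSequence, ArrayTruth]:
    """Emit one satellite array plus its ground truth."""
    rng = _rng(cfg.seed)
    ancestor = simulate_monomer(cfg.monomer_length, cfg.gc_content, rng).seq
    block_monomers: list[list[str]] = []
    block_ancestors: list[str] = []
    for spec in cfg.blocks:
        cons, _ = mutate(ancestor, spec.divergence_from_ancestor, cfg.ts_tv_ratio, rng)
        members = []
        for _ in range(spec.n_monomers):
            m, _ = mutate(cons, cfg.intra_block_divergence, cfg.ts_tv_ratio, rng)
            members.append(m)
        block_monomers.append(members)
        block_ancestors.append(cons)
    return _assemble(
        rng,
        block_monomers,
        [s.orientation for s in cfg.blocks],
        block_ancestors,
        [""] * len(cfg.blocks),
        cfg.insertion_length_range,
        cfg.flank_length,
        ancestor,
        seq_id,
    )


@dataclass
class FusionResult:
    fused: NucSequence
    donor_a: NucSequence
    donor_b: NucSequence
    fused_truth: ArrayTruth
    truth_a: ArrayTruth
    truth_b: ArrayTruth
    plan: tuple[tuple[str, int], ...]


def default_fusion_plan(donor_b_cfg: SimConfig) -> tuple[tuple[str, int], ...]:
    """Terminal donor-B blocks flanking a forward donor-A block."""
    last_b = len(donor_b_cfg.blocks) - 1
    return (("B", 0), ("A", 0), ("B", last_b))


def simulate_fusion(
    donor_a_cfg: SimConfig,
    donor_b_cfg: SimConfig,
    plan: tuple[tuple[str, int], ...] | None = None,
    post_fusion_divergence: float = 0.05,
    seed: int = 0,
) -> FusionResult:
    """Assemble a fusion chromosome from planned donor blocks.

    Donors are simulated from a shared ancestral monomer (so their blocks
    form one satellite family); each planned block is copied from its donor
    and further mutated by ``post_fusion_divergence``. Orientation of a
    copied block follows its donor block.
    """
    rng = _rng(seed)
    donor_seed_a = int(rng.integers(2**31))
    donor_seed_b = int(rng.integers(2**31))
    # the two donors share an ancestor: reuse donor A's ancestor for donor B
    rng_a = _rng(donor_seed_a)
    ancestor = simulate_monomer(donor_a_cfg.monomer_length, donor_a_cfg.gc_content, rng_a).seq

    def _build_donor(cfg: SimConfig, d_rng, label: str, seq_id: str):
        block_monomers, block_ancestors = [], []
        for spec in cfg.blocks:
            cons, _ = mutate(ancestor, spec.divergence_from_ancestor, cfg.ts_tv_ratio, d_rng)
            members = [
                mutate(cons, cfg.intra_block_divergence, cfg.ts_tv_ratio, d_rng)[0]
                for _ in range(spec.n_monomers)
            ]
            block_monomers.append(members)
            block_ancestors.append(cons)
        seq, truth = _assemble(
            d_rng,
            block_monomers,
            [s.orientation for s in cfg.blocks],
            block_ancestors,
            [label] * len(cfg.blocks),
            cfg.insertion_length_range,
            cfg.flank_length,
            ancestor,
            seq_id,
        )
        return seq, truth, block_monomers, block_ancestors

    seq_a, truth_a, mons_a, anc_a = _build_donor(donor_a_cfg, rng_a, "A", "donor_a")
    seq_b, truth_b, mons_b, anc_b = _build_donor(donor_b_cfg, _rng(donor_seed_b), "B", "donor_b")

    if plan is None:
        plan = default_fusion_plan(donor_b_cfg)
    fused_monomers, fused_orients, fused_ancestors, fused_labels = [], [], [], []
    for label, block_idx in plan:
        cfg = donor_a_cfg if label == "A" else donor_b_cfg
        mons = mons_a if label == "A" else mons_b
        ancs = anc_a if label == "A" else anc_b
        if not 0 <= block_idx < len(cfg.blocks):
            raise ValueError(f"fusion plan references missing block {label}{block_idx}")
        members = [
            mutate(m, post_fusion_divergence, cfg.ts_tv_ratio, rng)[0]
            for m in mons[block_idx]
        ]
        fused_monomers.append(members)
        fused_orients.append(cfg.blocks[block_idx].orientation)
        fused_ancestors.append(ancs[block_idx])
        fused_labels.append(label)
    fused, fused_truth = _assemble(
        rng,
        fused_monomers,
        fused_orients,
        fused_ancestors,
        fused_labels,
        donor_a_cfg.insertion_length_range,
        donor_a_cfg.flank_length,
        ancestor,
        "fused",
    )
    return FusionResult(fused, seq_a, seq_b, fused_truth, truth_a, truth_b, tuple(plan))


def simulate_divergence_ladder(
    length: int,
    n_levels: int,
    per_round_divergence: float,
    rounds_per_level: int,
    ts_tv_ratio: float,
    seed: int = 0,
    gc: float = 0.5,
) -> list[NucSequence]:
    """Ancestor plus descendants mutated over an increasing number of rounds.

    The levels form a serial chain (each mutated from the previous one), so
    pairwise true divergence grows with level separation and repeated rounds
    hit the same sites more than once — the multiple-hit regime needed to
    exercise saturation detection.
    """
    rng = _rng(seed)
    ancestor = simulate_monomer(length, gc, rng)
    out = [NucSequence("level0", ancestor.seq)]
    seq = ancestor.seq
    for level in range(1, n_levels + 1):
        for _ in range(rounds_per_level):
            seq, _ = mutate(seq, per_round_divergence, ts_tv_ratio, rng)
        out.append(NucSequence(f"level{level}", seq))
    return out
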