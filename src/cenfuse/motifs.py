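"""Degenerate (IUPAC) motif scanning and core-position comparison.

Matching between two IUPAC codes is set intersection: a Y in a motif
matches C or T in a window, and N matches everything. A difference between
two codes is a transition/transversion only when every cross-pair of the
two base sets has that same class; otherwise it is reported as ambiguous
rather than silently guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from cenfuse.core import NucSequence, revcomp

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def iupac_sets_intersect(code_a: str, code_b: str) -> bool:
    """True iff the base sets of two IUPAC codes share a member."""
    try:
        sa, sb = IUPAC_SETS[code_a.upper()], IUPAC_SETS[code_b.upper()]
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code: {exc.args[0]!r}") from None
    return bool(sa & sb)


def classify_codes(code_a: str, code_b: str) -> str:
    """Class of the difference between two non-intersecting IUPAC codes.

    Returns 'transition', 'transversion' or 'ambiguous'. Raises if the
    sets intersect (that is a match, not a difference).
    """
    sa, sb = IUPAC_SETS[code_a.upper()], IUPAC_SETS[code_b.upper()]
    if sa & sb:
        raise ValueError(f"{code_a}/{code_b} intersect; not a difference")
    classes = set()
    for a in sa:
        for b in sb:
            same_family = (a in _PURINES) == (b in _PURINES)
            classes.add("transition" if same_family else "transversion")
    return classes.pop() if len(classes) == 1 else "ambiguous"


@dataclass(frozen=True)
class DegenerateMotif:
    name: str
    iupac: str
    core_mask: tuple[bool, ...]

    def __post_init__(self) -> None:
        seq = self.iupac.upper()
        bad = set(seq) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"motif {self.name!r}: invalid codes {sorted(bad)}")
        if len(self.core_mask) != len(seq):
            raise ValueError(f"motif {self.name!r}: core mask length mismatch")
        object.__setattr__(self, "iupac", seq)

    def __len__(self) -> int:
        return len(self.iupac)

    @property
    def n_core(self) -> int:
        return sum(self.core_mask)


@dataclass(frozen=True)
class Difference:
    position: int  # 1-based within the motif
    expected: str
    observed: str
    cls: str


@dataclass(frozen=True)
class MotifHit:
    source_id: str
    start: int  # 1-based on the forward strand of the source
    strand: str
    window: str  # matched text in motif orientation
    total_mismatches: int
    core_mismatches: int
    differences: tuple[Difference, ...]


@dataclass(frozen=True)
class CoreComparison:
    differences: tuple[Difference, ...]
    n_core: int

    @property
    def n_differences(self) -> int:
        return len(self.differences)

    @property
    def n_transitions(self) -> int:
        return sum(1 for d in self.differences if d.cls == "transition")

    @property
    def n_transversions(self) -> int:
        return sum(1 for d in self.differences if d.cls == "transversion")

    @property
    def n_ambiguous(self) -> int:
        return sum(1 for d in self.differences if d.cls == "ambiguous")

    def pair_count(self, base_a: str, base_b: str) -> int:
        target = {base_a, base_b}
        return sum(1 for d in self.differences if {d.expected, d.observed} == target)


def _window_diffs(motif: DegenerateMotif, window: str) -> list[Difference]:
    diffs = []
    for i, (m, w) in enumerate(zip(motif.iupac, window)):
        if not iupac_sets_intersect(m, w):
            diffs.append(Difference(i + 1, m, w, classify_codes(m, w)))
    return diffs


def scan_motif(
    source: NucSequence,
    motif: DegenerateMotif,
    max_mismatch: int = 4,
    both_strands: bool = True,
    core_max_mismatch: int | None = None,
) -> list[MotifHit]:
    """Report every window within the mismatch budget, on both strands.

    Overlapping hits are all reported; results are sorted by forward-strand
    start position, '+' before '-' at equal starts.
    """
    k = len(motif)
    if k > len(source):
        raise ValueError("motif longer than source")
    hits: list[MotifHit] = []
    texts = [("+", source.seq)]
    if both_strands:
        texts.append(("-", revcomp(source.seq)))
    n = len(source)
    for strand, text in texts:
        for i in range(n - k + 1):
            window = text[i : i + k]
            diffs = _window_diffs(motif, window)
            if len(diffs) > max_mismatch:
                continue
            core = sum(1 for d in diffs if motif.core_mask[d.position - 1])
            if core_max_mismatch is not None and core > core_max_mismatch:
                continue
            start = i + 1 if strand == "+" else n - (i + k) + 1
            hits.append(
                MotifHit(source.id, start, strand, window, len(diffs), core, tuple(diffs))
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def compare_core(observed: DegenerateMotif, canonical: DegenerateMotif) -> CoreComparison:
    """Compare two motifs at the canonical motif's core positions."""
    if len(observed) != len(canonical):
        raise ValueError("motifs must have equal length")
    diffs = []
    for i, (c, o) in enumerate(zip(canonical.iupac, observed.iupac)):
        if not canonical.core_mask[i]:
            continue
        if not iupac_sets_intersect(c, o):
            diffs.append(Difference(i + 1, c, o, classify_codes(c, o)))
    return CoreComparison(tuple(diffs), canonical.n_core)


def derive_consensus_motif(
    hit_windows: list[str], name: str = "consensus"
) -> DegenerateMotif:
    """Minimal IUPAC consensus covering all observed bases per column."""
    if len(hit_windows) < 2:
        raise ValueError("need at least 2 windows")
    lengths = {len(w) for w in hit_windows}
    if len(lengths) != 1:
        raise ValueError("windows must have equal length")
    from cenfuse.blocks import IUPAC_FOR_SET

    cols = []
    for col in zip(*(w.upper() for w in hit_windows)):
        union: set[str] = set()
        for c in col:
            union |= IUPAC_SETS[c]
        cols.append(IUPAC_FOR_SET[frozenset(union)])
    motif = "".join(cols)
    return DegenerateMotif(name, motif, tuple([False] * len(motif)))


def builtin_motifs() -> dict[str, DegenerateMotif]:
    """The shipped motif catalogue (see data/motifs.tsv)."""
    catalogue = {}
    text = resources.files("cenfuse").joinpath("data/motifs.tsv").read_text()
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, iupac, mask = line.split("\t")
        catalogue[name] = DegenerateMotif(name, iupac, tuple(c == "1" for c in mask))
    return catalogue
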