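"""Substitution spectra, p-distances, saturation assessment and NJ trees.

Gap handling is pairwise deletion throughout: gap columns are counted as
deletions and excluded from substitution and p-distance denominators.
Percentages are rounded half-up to two decimals.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from cenfuse.core import DEFAULT_PARAMS, AlignParams, NucSequence, global_align

_PURINES = frozenset("AG")
_BASES = frozenset("ACGT")

TRANSVERSION_PAIRS = ("A/C", "A/T", "C/G", "G/T")
TRANSITION_PAIRS = ("A/G", "C/T")


def round_pct(x: float) -> float:
    """Percentage rounded half-up to two decimals (67.615 -> 67.62)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def classify_substitution(a: str, b: str) -> str:
    """'transition' (within purines or within pyrimidines) or 'transversion'."""
    a, b = a.upper(), b.upper()
    if a not in _BASES or b not in _BASES:
        raise ValueError(f"invalid base in pair ({a}, {b})")
    if a == b:
        raise ValueError(f"({a}, {b}) is not a substitution")
    return "transition" if (a in _PURINES) == (b in _PURINES) else "transversion"


def _pair_key(a: str, b: str) -> str:
    x, y = sorted((a, b))
    return f"{x}/{y}"


@dataclass
class SubstitutionSpectrum:
    n_sites_compared: int
    n_substitutions: int
    n_transitions: int
    n_transversions: int
    n_deletions: int
    pair_counts: dict[str, int]
    prop_transitions: float  # percent of substitutions; 0.0 sentinel if none
    prop_transversions: float

    @classmethod
    def from_counts(
        cls,
        n_transitions: int,
        n_transversions: int,
        n_deletions: int = 0,
        n_sites_compared: int | None = None,
        pair_counts: dict[str, int] | None = None,
    ) -> "SubstitutionSpectrum":
        n_sub = n_transitions + n_transversions
        return cls(
            n_sites_compared=n_sites_compared if n_sites_compared is not None else n_sub,
            n_substitutions=n_sub,
            n_transitions=n_transitions,
            n_transversions=n_transversions,
            n_deletions=n_deletions,
            pair_counts=pair_counts or {},
            prop_transitions=round_pct(100.0 * n_transitions / n_sub) if n_sub else 0.0,
            prop_transversions=round_pct(100.0 * n_transversions / n_sub) if n_sub else 0.0,
        )


def substitution_spectrum(aligned_a: str, aligned_b: str) -> SubstitutionSpectrum:
    """Per-column substitution tally of one aligned pair.

    Columns with a gap in either row count as deletions; columns with an
    ambiguous base (anything outside ACGT) are excluded from comparison.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned rows must have equal length")
    n_del = 0
    n_sites = 0
    pair_counts: dict[str, int] = {}
    n_ts = n_tv = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x == "-" or y == "-":
            if x != y:  # both-gap columns are vacuous
                n_del += 1
            continue
        if x not in _BASES or y not in _BASES:
            continue
        n_sites += 1
        if x == y:
            continue
        if classify_substitution(x, y) == "transition":
            n_ts += 1
        else:
            n_tv += 1
        key = _pair_key(x, y)
        pair_counts[key] = pair_counts.get(key, 0) + 1
    return SubstitutionSpectrum.from_counts(
        n_ts, n_tv, n_deletions=n_del, n_sites_compared=n_sites, pair_counts=pair_counts
    )


def p_distance(
    a: NucSequence, b: NucSequence, params: AlignParams = DEFAULT_PARAMS
) -> float:
    """Proportion of differing sites, gap columns excluded (pairwise deletion)."""
    aln = global_align(a, b, params)
    spec = substitution_spectrum(aln.aligned_query, aln.aligned_target)
    if spec.n_sites_compared == 0:
        raise ValueError("no comparable (gap-free) columns between sequences")
    return spec.n_substitutions / spec.n_sites_compared


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if (m < 0).any() or not np.allclose(np.diag(m), 0):
            raise ValueError("distances must be non-negative with zero diagonal")
        self.matrix = m


def distance_matrix(
    seqs: list[NucSequence], params: AlignParams = DEFAULT_PARAMS
) -> DistanceMatrix:
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(seqs)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        m[i, j] = m[j, i] = p_distance(seqs[i], seqs[j], params)
    return DistanceMatrix([s.id for s in seqs], m)


@dataclass
class SaturationReport:
    pair_table: pd.DataFrame  # columns: p_distance, ts_count, tv_count
    ts_slope: float
    tv_slope: float
    ts_lower_slope: float
    ts_upper_slope: float
    tv_lower_slope: float
    tv_upper_slope: float
    ts_saturated: bool
    tv_saturated: bool


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.ptp(x) == 0:
        return 0.0
    return float(np.polyfit(x, y, 1)[0])


def saturation_analysis(
    seqs: list[NucSequence],
    saturation_ratio_threshold: float = 0.5,
    params: AlignParams = DEFAULT_PARAMS,
) -> SaturationReport:
    """Slope-ratio saturation heuristic over all sequence pairs.

    For each class the substitution count is regressed on p-distance over
    the lower and upper halves of the observed distance range; a class is
    flagged saturated when the upper-half slope falls below
    ``saturation_ratio_threshold`` times the lower-half slope. This is a
    deliberately simple stand-in for entropy-based saturation tests, which
    are out of scope.
    """
    if len(seqs) < 4:
        raise ValueError("saturation_analysis needs at least 4 sequences")
    rows = []
    for a, b in itertools.combinations(seqs, 2):
        aln = global_align(a, b, params)
        spec = substitution_spectrum(aln.aligned_query, aln.aligned_target)
        if spec.n_sites_compared == 0:
            continue
        rows.append(
            {
                "a": a.id,
                "b": b.id,
                "p_distance": spec.n_substitutions / spec.n_sites_compared,
                "ts_count": spec.n_transitions,
                "tv_count": spec.n_transversions,
            }
        )
    table = pd.DataFrame(rows)
    x = table["p_distance"].to_numpy()
    ts = table["ts_count"].to_numpy(dtype=float)
    tv = table["tv_count"].to_numpy(dtype=float)
    ts_slope = _ols_slope(x, ts)
    tv_slope = _ols_slope(x, tv)
    if np.ptp(x) == 0:
        zeros = 0.0
        return SaturationReport(table, ts_slope, tv_slope, zeros, zeros, zeros, zeros, False, False)
    mid = (x.min() + x.max()) / 2.0
    lower = x <= mid
    upper = ~lower
    slopes = {}
    for name, y in (("ts", ts), ("tv", tv)):
        lo = _ols_slope(x[lower], y[lower])
        hi = _ols_slope(x[upper], y[upper])
        saturated = bool(
            lower.sum() >= 2
            and upper.sum() >= 2
            and lo > 0
            and hi < saturation_ratio_threshold * lo
        )
        slopes[name] = (lo, hi, saturated)
    return SaturationReport(
        pair_table=table,
        ts_slope=ts_slope,
        tv_slope=tv_slope,
        ts_lower_slope=slopes["ts"][0],
        ts_upper_slope=slopes["ts"][1],
        tv_lower_slope=slopes["tv"][0],
        tv_upper_slope=slopes["tv"][1],
        ts_saturated=slopes["ts"][2],
        tv_saturated=slopes["tv"][2],
    )


def _sanitize(label: str) -> str:
    return "_".join(label.split())


def nj_tree(d: DistanceMatrix) -> str:
    """Neighbor-joining tree in newick text.

    Recovers additive matrices exactly. Negative branch lengths are clamped
    to zero; the output is unrooted with a trifurcation at the last join.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("nj_tree needs at least 3 labels")
    labels = [_sanitize(x) for x in d.labels]
    active = list(range(n))
    dist = {(i, j): d.matrix[i, j] for i in range(n) for j in range(i + 1, n)}
    newick = {i: labels[i] for i in range(n)}
    next_id = n

    def dd(i: int, j: int) -> float:
        return 0.0 if i == j else dist[(min(i, j), max(i, j))]

    while len(active) > 3:
        r = {i: sum(dd(i, k) for k in active if k != i) for i in active}
        m = len(active)
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                i, j = active[ii], active[jj]
                q = (m - 2) * dd(i, j) - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * dd(i, j) + (r[i] - r[j]) / (2 * (m - 2))
        lj = dd(i, j) - li
        li, lj = max(0.0, li), max(0.0, lj)
        new = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            dist[(min(new, k), max(new, k))] = 0.5 * (dd(i, k) + dd(j, k) - dd(i, j))
        newick[new] = f"({newick[i]}:{li:.10g},{newick[j]}:{lj:.10g})"
        active = [k for k in active if k not in (i, j)] + [new]

    i, j, k = active
    li = max(0.0, 0.5 * (dd(i, j) + dd(i, k) - dd(j, k)))
    lj = max(0.0, 0.5 * (dd(i, j) + dd(j, k) - dd(i, k)))
    lk = max(0.0, 0.5 * (dd(i, k) + dd(j, k) - dd(i, j)))
    return f"({newick[i]}:{li:.10g},{newick[j]}:{lj:.10g},{newick[k]}:{lk:.10g});"
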