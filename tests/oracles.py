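"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: plain-Python dynamic
programming over full matrices of Python tuples, and exhaustive window
enumeration for motif scanning. Slow, obviously correct, small-n only.
"""

from __future__ import annotations

NEG = float("-inf")


def local_align_oracle(q: str, t: str, match=1, mismatch=-1, gap_open=-2, gap_extend=-1):
    """Best local alignment under (score desc, matches desc, columns asc).

    Returns (score, matches, columns); identity = matches / columns.
    A gap of length L costs gap_open + (L-1)*gap_extend. N matches nothing.
    """
    m, n = len(q), len(t)

    def key(triple):
        s, mt, c = triple
        return (s, mt, -c)

    worst = (NEG, 0, 0)
    H = [[(0, 0, 0)] * (n + 1) for _ in range(m + 1)]
    E = [[worst] * (n + 1) for _ in range(m + 1)]
    F = [[worst] * (n + 1) for _ in range(m + 1)]
    best = (0, 0, 0)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e_open = (H[i][j - 1][0] + gap_open, H[i][j - 1][1], H[i][j - 1][2] + 1)
            e_ext = (E[i][j - 1][0] + gap_extend, E[i][j - 1][1], E[i][j - 1][2] + 1)
            E[i][j] = max(e_open, e_ext, key=key)
            f_open = (H[i - 1][j][0] + gap_open, H[i - 1][j][1], H[i - 1][j][2] + 1)
            f_ext = (F[i - 1][j][0] + gap_extend, F[i - 1][j][1], F[i - 1][j][2] + 1)
            F[i][j] = max(f_open, f_ext, key=key)
            is_match = q[i - 1] == t[j - 1] and q[i - 1] in "ACGT"
            d = (
                H[i - 1][j - 1][0] + (match if is_match else mismatch),
                H[i - 1][j - 1][1] + (1 if is_match else 0),
                H[i - 1][j - 1][2] + 1,
            )
            H[i][j] = max(d, E[i][j], F[i][j], (0, 0, 0), key=key)
            best = max(best, H[i][j], key=key)
    return best


IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp_oracle(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def scan_motif_oracle(source: str, motif: str, max_mismatch: int, both_strands=True):
    """All (start_1based, strand) hit positions by exhaustive enumeration."""
    k = len(motif)
    hits = []
    strands = [("+", source)]
    if both_strands:
        strands.append(("-", revcomp_oracle(source)))
    for strand, text in strands:
        for i in range(len(text) - k + 1):
            window = text[i : i + k]
            mm = sum(
                1
                for mc, wc in zip(motif, window)
                if not (IUPAC[mc] & IUPAC.get(wc, set(wc) & set("ACGT")))
            )
            if mm <= max_mismatch:
                start = i + 1 if strand == "+" else len(text) - (i + k) + 1
                hits.append((start, strand, mm))
    return sorted(hits)


def p_distance_oracle(a: str, b: str) -> float:
    """For equal-length, gap-free pairs only: differing / total sites."""
    assert len(a) == len(b)
    diffs = sum(1 for x, y in zip(a, b) if x != y)
    return diffs / len(a)
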