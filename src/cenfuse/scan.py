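"""Satellite monomer detection by greedy iterative masking.

The scanner repeatedly takes the best-scoring local alignment of the
reference monomer against the not-yet-masked source (both strands), emits a
monomer when it passes the identity and coverage thresholds, masks the hit
interval, and stops when no sufficiently scoring hit remains. Monomer
sequences are stored reference-oriented so downstream comparisons are
strand-free; the strand field keeps the genomic orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from cenfuse import _align
from cenfuse.core import (
    DEFAULT_PARAMS,
    AlignParams,
    NucSequence,
    encode,
    revcomp,
)

MASK_CODE = 0  # sentinel that matches nothing (same bit-code as N)


@dataclass(frozen=True)
class Monomer:
    source_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    seq: str  # reference-oriented
    ref_identity: float
    ref_coverage: float
    index: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# scanning profile: stiffer gaps than the general alignment default, because
# tandem monomer copies diverge by substitution far more than by indel and
# cheap gaps let co-optimal gapped alignments blur copy boundaries
SCAN_PARAMS = AlignParams(match_score=1, mismatch_score=-1, gap_open=-4, gap_extend=-2)


@dataclass(frozen=True)
class ScanConfig:
    reference: NucSequence
    min_identity: float = 0.70
    min_coverage: float = 0.90
    params: AlignParams = SCAN_PARAMS

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if not 0 < self.min_coverage <= 1:
            raise ValueError("min_coverage must be in (0, 1]")


def _min_keep_score(cfg: ScanConfig) -> int:
    """Score floor below which scanning stops.

    Expected per-column score of a just-passing hit, over the minimum
    aligned length; conservative for gapped hits, which is acceptable for
    a greedy scanner.
    """
    p = cfg.params
    per_col = cfg.min_identity * p.match_score + (1 - cfg.min_identity) * p.mismatch_score
    return max(2, int(np.floor(len(cfg.reference) * cfg.min_coverage * per_col)))


def _best_hit(enc_fwd, enc_rev, enc_src, p: AlignParams):
    """Best triple-scored hit of either reference strand on the source."""
    f = _align._sw_forward(enc_fwd, enc_src, p.match_score, p.mismatch_score, p.gap_open, p.gap_extend)
    r = _align._sw_forward(enc_rev, enc_src, p.match_score, p.mismatch_score, p.gap_open, p.gap_extend)
    if _align._better(r[0], r[1], r[2], f[0], f[1], f[2]):
        return r, "-"
    return f, "+"


def _locate(enc_q, enc_src, hit, p: AlignParams):
    s, m, c, qe, te = hit
    qr = np.ascontiguousarray(enc_q[:qe][::-1])
    tr = np.ascontiguousarray(enc_src[:te][::-1])
    i, j = _align._nw_origin_find(qr, tr, p.match_score, p.mismatch_score, p.gap_open, p.gap_extend, s, m, c)
    if i < 0:  # pragma: no cover
        raise RuntimeError("inconsistent DP passes in scanner")
    return qe - i + 1, qe, te - j + 1, te


def find_monomers(source: NucSequence, cfg: ScanConfig) -> list[Monomer]:
    """Detect reference-monomer copies on one source sequence.

    Returns monomers sorted by start coordinate, strictly non-overlapping.
    A reference longer than the source simply yields an empty list.
    """
    ref = cfg.reference
    p = cfg.params
    enc_fwd = encode(ref.seq)
    enc_rev = encode(revcomp(ref.seq))
    enc_src = encode(source.seq)
    masked = np.zeros(len(source), dtype=bool)
    floor = _min_keep_score(cfg)
    out: list[Monomer] = []
    max_iter = 4 * (len(source) // max(2, floor) + 2)
    for _ in range(max_iter):
        hit, strand = _best_hit(enc_fwd, enc_rev, enc_src, p)
        if hit[0] < floor:
            break
        enc_q = enc_fwd if strand == "+" else enc_rev
        qs, qe, ts, te = _locate(enc_q, enc_src, hit, p)
        span = masked[ts - 1 : te]
        if span.any():
            # hit bridged a previously masked interval: re-scan the longest
            # unmasked run inside it instead of emitting an overlapping call
            runs = _unmasked_runs(span)
            if not runs:
                enc_src[ts - 1 : te] = MASK_CODE
                masked[ts - 1 : te] = True
                continue
            a, b = max(runs, key=lambda r: r[1] - r[0])
            sub = np.ascontiguousarray(enc_src[ts - 1 + a : ts - 1 + b])
            fh = _align._sw_forward(enc_fwd, sub, p.match_score, p.mismatch_score, p.gap_open, p.gap_extend)
            rh = _align._sw_forward(enc_rev, sub, p.match_score, p.mismatch_score, p.gap_open, p.gap_extend)
            if _align._better(rh[0], rh[1], rh[2], fh[0], fh[1], fh[2]):
                hit2, strand = rh, "-"
            else:
                hit2, strand = fh, "+"
            if hit2[0] < floor:
                enc_src[ts - 1 : te] = MASK_CODE
                masked[ts - 1 : te] = True
                continue
            enc_q = enc_fwd if strand == "+" else enc_rev
            qs, qe, ts2, te2 = _locate(enc_q, sub, hit2, p)
            hit = hit2
            offset = ts - 1 + a  # 0-based source offset of the unmasked run
            ts = offset + ts2
            te = offset + te2
        matches, cols = hit[1], hit[2]
        # local alignment clips mutated terminal bases; rescue short
        # unaligned reference tails by direct (ungapped) extension so that
        # full-length copies report exact coordinates
        slack = max(10, int(0.05 * len(ref)))
        left = qs - 1
        if 0 < left <= slack and ts - 1 - left >= 0 and not masked[ts - 1 - left : ts - 1].any():
            for k in range(1, left + 1):
                if enc_src[ts - 1 - k] & enc_q[qs - 1 - k]:
                    matches += 1
                cols += 1
            ts -= left
            qs -= left
        right = len(ref) - qe
        if 0 < right <= slack and te + right <= len(source) and not masked[te : te + right].any():
            for k in range(right):
                if enc_src[te + k] & enc_q[qe + k]:
                    matches += 1
                cols += 1
            te += right
            qe += right
        identity = matches / cols if cols else 0.0
        coverage = (qe - qs + 1) / len(ref)
        enc_src[ts - 1 : te] = MASK_CODE
        masked[ts - 1 : te] = True
        if identity >= cfg.min_identity and coverage >= cfg.min_coverage:
            raw = source.seq[ts - 1 : te]
            out.append(
                Monomer(
                    source_id=source.id,
                    start=ts,
                    end=te,
                    strand=strand,
                    seq=raw if strand == "+" else revcomp(raw),
                    ref_identity=identity,
                    ref_coverage=min(1.0, coverage),
                )
            )
    out.sort(key=lambda m: m.start)
    return [replace(m, index=i) for i, m in enumerate(out)]


def _unmasked_runs(span: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, end) runs of False in a boolean array."""
    runs = []
    start = None
    for i, flag in enumerate(span):
        if not flag and start is None:
            start = i
        elif flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(span)))
    return runs


def filter_full_length(monomers: list[Monomer], cfg: ScanConfig) -> list[Monomer]:
    """Keep monomers covering at least ``min_coverage`` of the reference."""
    kept = [m for m in monomers if m.ref_coverage >= cfg.min_coverage]
    return [replace(m, index=i) for i, m in enumerate(kept)]


def monomers_to_bed(monomers: list[Monomer], path) -> None:
    """Write monomers as BED6 (0-based half-open), name = source_id.index."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for m in monomers:
            score = int(round(m.ref_identity * 1000))
            fh.write(
                f"{m.source_id}\t{m.start - 1}\t{m.end}\t"
                f"{m.source_id}.{m.index}\t{score}\t{m.strand}\n"
            )


def read_bed(path) -> list[tuple[str, int, int, str, int, str]]:
    """Minimal BED6 reader for round-tripping monomer intervals."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, name, score, strand = line.rstrip("\n").split("\t")
            rows.append((chrom, int(start), int(end), name, int(score), strand))
    return rows


def monomer_table(monomers: list[Monomer]) -> "pandas.DataFrame":  # noqa: F821
    import pandas as pd

    return pd.DataFrame(
        {
            "source_id": [m.source_id for m in monomers],
            "index": [m.index for m in monomers],
            "start": [m.start for m in monomers],
            "end": [m.end for m in monomers],
            "strand": [m.strand for m in monomers],
            "ref_identity": [m.ref_identity for m in monomers],
            "ref_coverage": [m.ref_coverage for m in monomers],
        }
    )
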