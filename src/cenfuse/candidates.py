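"""Gene-anchor tables: candidate fusion scaffolds and syntenic segments.

The genome-scale CDS-vs-chromosome alignment that produces anchor tables is
external input (BLAT-class tooling); this module consumes the resulting TSV.

Expected columns (tab-separated, header required):
    gene_id  scaffold_id  scaffold_start  scaffold_end  target_chrom
    target_start  target_end  identity  strand
Coordinates are 1-based inclusive; identity is a percentage in [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

REQUIRED_COLUMNS = [
    "gene_id",
    "scaffold_id",
    "scaffold_start",
    "scaffold_end",
    "target_chrom",
    "target_start",
    "target_end",
    "identity",
    "strand",
]


class AnchorFormatError(ValueError):
    pass


@dataclass(frozen=True)
class Anchor:
    gene_id: str
    scaffold_id: str
    scaffold_start: int
    scaffold_end: int
    target_chrom: str
    target_start: int
    target_end: int
    identity: float
    strand: str


@dataclass(frozen=True)
class SyntenicSegment:
    scaffold_id: str
    target_chrom: str
    gene_ids: tuple[str, ...]
    scaffold_span: tuple[int, int]
    target_span: tuple[int, int]


@dataclass(frozen=True)
class CandidateSummary:
    scaffold_id: str
    n_anchors_a: int
    n_anchors_b: int
    min_identity: float
    mean_identity: float


def load_anchors(path) -> list[Anchor]:
    """Load and type-check an anchor table; bad rows are rejected by line number."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise AnchorFormatError(f"{path}: missing required columns {missing}")
    anchors = []
    for row_idx, row in df.iterrows():
        line_no = row_idx + 2  # header is line 1
        try:
            a = Anchor(
                gene_id=str(row["gene_id"]),
                scaffold_id=str(row["scaffold_id"]),
                scaffold_start=int(row["scaffold_start"]),
                scaffold_end=int(row["scaffold_end"]),
                target_chrom=str(row["target_chrom"]),
                target_start=int(row["target_start"]),
                target_end=int(row["target_end"]),
                identity=float(row["identity"]),
                strand=str(row["strand"]),
            )
        except (TypeError, ValueError) as exc:
            raise AnchorFormatError(f"{path}: line {line_no}: {exc}") from exc
        if a.scaffold_start > a.scaffold_end or a.target_start > a.target_end:
            raise AnchorFormatError(f"{path}: line {line_no}: end before start")
        if a.scaffold_start <= 0 or a.target_start <= 0:
            raise AnchorFormatError(f"{path}: line {line_no}: non-positive coordinate")
        if not 0 <= a.identity <= 100:
            raise AnchorFormatError(f"{path}: line {line_no}: identity outside [0, 100]")
        if a.strand not in "+-":
            raise AnchorFormatError(f"{path}: line {line_no}: bad strand {a.strand!r}")
        anchors.append(a)
    return anchors


def write_anchors(anchors: list[Anchor], path) -> None:
    df = pd.DataFrame([a.__dict__ for a in anchors], columns=REQUIRED_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def candidate_scaffolds(
    anchors: list[Anchor], chrom_a: str, chrom_b: str, min_each: int = 1
) -> list[CandidateSummary]:
    """Scaffolds with at least ``min_each`` anchors to each donor chromosome."""
    if not anchors:
        raise ValueError("empty anchor collection")
    by_scaffold: dict[str, list[Anchor]] = {}
    for a in anchors:
        by_scaffold.setdefault(a.scaffold_id, []).append(a)
    out = []
    for sid in sorted(by_scaffold):
        members = by_scaffold[sid]
        n_a = sum(1 for a in members if a.target_chrom == chrom_a)
        n_b = sum(1 for a in members if a.target_chrom == chrom_b)
        if n_a >= min_each and n_b >= min_each:
            idents = [a.identity for a in members if a.target_chrom in (chrom_a, chrom_b)]
            out.append(
                CandidateSummary(
                    scaffold_id=sid,
                    n_anchors_a=n_a,
                    n_anchors_b=n_b,
                    min_identity=min(idents),
                    mean_identity=sum(idents) / len(idents),
                )
            )
    return out


def segment_anchors(
    anchors: list[Anchor],
    collinear: bool = False,
    max_target_jump: int = 5_000_000,
) -> list[SyntenicSegment]:
    """Maximal runs of scaffold-consecutive anchors sharing a target chromosome.

    With ``collinear`` (off by default) a run is additionally split when the
    target position jumps by more than ``max_target_jump``, so distant
    landing sites on the same chromosome form separate segments.
    """
    if not anchors:
        return []
    scaffolds = {a.scaffold_id for a in anchors}
    if len(scaffolds) != 1:
        raise ValueError("segment_anchors expects anchors from one scaffold")
    ordered = sorted(anchors, key=lambda a: (a.scaffold_start, a.scaffold_end, a.gene_id))
    segments = []
    run = [ordered[0]]
    for a in ordered[1:]:
        prev = run[-1]
        joins = a.target_chrom == prev.target_chrom
        if joins and collinear:
            gap = max(a.target_start, prev.target_start) - min(a.target_end, prev.target_end)
            joins = gap <= max_target_jump
        if joins:
            run.append(a)
        else:
            segments.append(_make_segment(run))
            run = [a]
    segments.append(_make_segment(run))
    return segments


def _make_segment(run: list[Anchor]) -> SyntenicSegment:
    return SyntenicSegment(
        scaffold_id=run[0].scaffold_id,
        target_chrom=run[0].target_chrom,
        gene_ids=tuple(a.gene_id for a in run),
        scaffold_span=(min(a.scaffold_start for a in run), max(a.scaffold_end for a in run)),
        target_span=(min(a.target_start for a in run), max(a.target_end for a in run)),
    )
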