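"""Filter most-Cons elements down to conserved non-coding sequences (CNSs).

A CNS is a coding-free piece of a conserved element that is at least
``min_len`` bp long and whose mean aligned identity to the reference is at
least ``min_identity`` (both bounds inclusive: "minimal" values pass).
Identity is the element-mean over species of per-column base matches; a
species missing from a column is excluded from that column's comparison
rather than counted as a mismatch, since missing data is not divergence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree

from .conservation import ConservedElement
from .io_formats import AlignmentBlock, GeneModel, GenomicInterval

__all__ = ["CNS", "subtract_coding", "aligned_identity", "call_cns"]

CONTEXTS = ("intergenic", "intron", "UTR", "upstream", "downstream")


@dataclass(frozen=True)
class CNS:
    interval: GenomicInterval
    parent_id: str
    identity: float
    context: str

    @property
    def length(self) -> int:
        return self.interval.length


def _cds_trees(genes: list[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        for iv in g.cds:
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    for t in trees.values():
        t.merge_overlaps()
    return trees


def subtract_coding(
    elements: list[ConservedElement], genes: list[GeneModel]
) -> list[tuple[GenomicInterval, str]]:
    """Split each element by the CDS union; returns (piece, parent id) pairs.

    Parent ids are ``mostCons_<chrom>.<serial>`` in coordinate order, so a
    piece can always be traced to the element it came from.
    """
    trees = _cds_trees(genes)
    pieces: list[tuple[GenomicInterval, str]] = []
    serial_by_chrom: dict[str, int] = {}
    for el in sorted(elements, key=lambda e: (e.interval.chrom, e.interval.start)):
        iv = el.interval
        serial = serial_by_chrom.get(iv.chrom, 0) + 1
        serial_by_chrom[iv.chrom] = serial
        parent = f"mostCons_{iv.chrom}.{serial}"
        tree = trees.get(iv.chrom)
        if tree is None:
            pieces.append((iv, parent))
            continue
        hits = sorted(tree.overlap(iv.start, iv.end))
        cursor = iv.start
        for h in hits:
            if h.begin > cursor:
                pieces.append(
                    (GenomicInterval(iv.chrom, cursor, h.begin), parent)
                )
            cursor = max(cursor, h.end)
        if cursor < iv.end:
            pieces.append((GenomicInterval(iv.chrom, cursor, iv.end), parent))
    return pieces


def aligned_identity(
    interval: GenomicInterval, blocks: list[AlignmentBlock]
) -> float:
    """Mean aligned identity of non-reference species over an interval.

    For each non-reference species, matches / interval-columns where both
    the species and reference base are non-gap and equal; columns where
    the species is absent or gapped drop out of that species' denominator.
    The result is the column-weighted mean over all species comparisons.
    Raises if no block covers the interval.
    """
    matches = 0
    comparisons = 0
    covered = 0
    for block in blocks:
        biv = block.ref_interval
        if biv.chrom != interval.chrom or biv.end <= interval.start or biv.start >= interval.end:
            continue
        ref_pos = block.ref_columns()
        ref_text = block.rows[block.ref_species].text
        in_range = (ref_pos >= interval.start) & (ref_pos < interval.end)
        covered += int(in_range.sum())
        for sp, row in block.rows.items():
            if sp == block.ref_species:
                continue
            for i in np.flatnonzero(in_range):
                r, q = ref_text[i], row.text[i]
                if r == "-" or q == "-" or q == "N":
                    continue
                comparisons += 1
                if r == q:
                    matches += 1
    if covered == 0:
        raise ValueError(f"interval {interval} not covered by any alignment block")
    if comparisons == 0:
        return 0.0
    return matches / comparisons


def _annotate_context(
    iv: GenomicInterval, genes: list[GeneModel], near: int = 5000
) -> str:
    """intron/UTR if inside a gene; else upstream/downstream of the nearest
    gene within ``near`` bp; else intergenic."""
    best: tuple[int, str] | None = None
    for g in genes:
        if g.interval.chrom != iv.chrom:
            continue
        if g.interval.overlaps(iv):
            for u in g.utr5 + g.utr3:
                if u.overlaps(iv):
                    return "UTR"
            return "intron"
        if iv.end <= g.interval.start:
            dist = g.interval.start - iv.end
            side = "upstream" if g.strand == "+" else "downstream"
        else:
            dist = iv.start - g.interval.end
            side = "downstream" if g.strand == "+" else "upstream"
        if dist <= near and (best is None or dist < best[0]):
            best = (dist, side)
    return best[1] if best else "intergenic"


def call_cns(
    elements: list[ConservedElement],
    genes: list[GeneModel],
    blocks: list[AlignmentBlock],
    min_len: int = 20,
    min_identity: float = 0.80,
) -> list[CNS]:
    """Most-Cons elements -> CNSs: subtract CDS, apply length and identity
    floors (inclusive), annotate genomic context."""
    out: list[CNS] = []
    for piece, parent in subtract_coding(elements, genes):
        if piece.length < min_len:
            continue
        ident = aligned_identity(piece, blocks)
        if ident < min_identity:
            continue
        out.append(
            CNS(
                interval=piece,
                parent_id=parent,
                identity=ident,
                context=_annotate_context(piece, genes),
            )
        )
    out.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    return out
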