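"""Cis-RCNE calling, target-gene assignment, and regulatory-pair validation.

A CNS fully contained in the reference span of an N-way collinear segment
becomes a putative cis-regulatory element ("cis-RCNE").  Candidate target
genes are the genes whose bodies lie within ``max_dist`` of the element
and overlap the element's host-segment span; a candidate pair is validated
when the element overlaps a histone-mark peak in exactly one condition of
a condition pair and the gene is called differentially expressed between
those conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cns import CNS
from .io_formats import DERecord, GeneModel, GenomicInterval, SignalTrack
from .synteny import CollinearSegment, segment_span

__all__ = [
    "CisRCNE",
    "RegulatoryPair",
    "PairEvidence",
    "call_cis_rcnes",
    "assign_targets",
    "call_regulatory_pairs",
    "metaprofile",
    "rpkm",
]


@dataclass(frozen=True)
class CisRCNE:
    rcne_id: str  # "cis-RCNE_ID_<chrom>.<serial>"
    cns: CNS
    segment_id: str

    @property
    def interval(self) -> GenomicInterval:
        return self.cns.interval


@dataclass(frozen=True)
class PairEvidence:
    condition_pair: tuple[str, str]
    peak_id: str
    logfc: float
    fdr: float


@dataclass
class RegulatoryPair:
    rcne_id: str
    gene_id: str
    distance: int  # signed bp; negative = element upstream of gene, 0 = overlap
    evidence: list[PairEvidence] = field(default_factory=list)


def call_cis_rcnes(
    cns_set: list[CNS],
    segments: list[CollinearSegment],
    ref_species: str,
) -> list[CisRCNE]:
    """CNSs fully contained in a segment's reference span become cis-RCNEs.

    Serials are per-chromosome in coordinate order, so ids are stable
    across reruns on identical input.
    """
    spans = [(segment_span(s, ref_species), s.segment_id) for s in segments]
    hits: list[tuple[CNS, str]] = []
    for c in sorted(cns_set, key=lambda c: (c.interval.chrom, c.interval.start)):
        for span, seg_id in spans:
            if span.contains(c.interval):
                hits.append((c, seg_id))
                break
    out: list[CisRCNE] = []
    serial: dict[str, int] = {}
    for c, seg_id in hits:
        chrom = c.interval.chrom
        serial[chrom] = serial.get(chrom, 0) + 1
        out.append(
            CisRCNE(
                rcne_id=f"cis-RCNE_ID_{chrom}.{serial[chrom]}",
                cns=c,
                segment_id=seg_id,
            )
        )
    return out


def _signed_distance(element: GenomicInterval, gene: GeneModel) -> int:
    """Edge-to-edge gap, signed: negative when the element sits upstream of
    the gene (5' side, strand-aware), 0 when overlapping."""
    g = gene.interval
    if element.overlaps(g):
        return 0
    if element.end <= g.start:
        gap = g.start - element.end
        upstream = gene.strand == "+"
    else:
        gap = element.start - g.end
        upstream = gene.strand == "-"
    return -gap if upstream else gap


def assign_targets(
    rcnes: list[CisRCNE],
    genes: list[GeneModel],
    segments: list[CollinearSegment],
    ref_species: str,
    max_dist: int = 5000,
) -> list[RegulatoryPair]:
    """Candidate pairs: gene within ``max_dist`` of the element (or
    overlapping) whose body overlaps the element's host-segment span."""
    span_by_id = {s.segment_id: segment_span(s, ref_species) for s in segments}
    pairs: list[RegulatoryPair] = []
    for r in rcnes:
        span = span_by_id[r.segment_id]
        iv = r.interval
        for g in genes:
            if g.interval.chrom != iv.chrom:
                continue
            gap = 0 if g.interval.overlaps(iv) else (
                g.interval.start - iv.end
                if iv.end <= g.interval.start
                else iv.start - g.interval.end
            )
            if gap > max_dist:
                continue
            if not g.interval.overlaps(span):
                continue
            pairs.append(
                RegulatoryPair(
                    rcne_id=r.rcne_id,
                    gene_id=g.gene_id,
                    distance=_signed_distance(iv, g),
                )
            )
    return pairs


def _overlaps_any(
    iv: GenomicInterval, peaks: list[tuple[GenomicInterval, str]]
) -> str | None:
    for piv, pid in peaks:
        if piv.overlaps(iv):
            return pid
    return None


def call_regulatory_pairs(
    candidates: list[RegulatoryPair],
    rcnes: list[CisRCNE],
    peaks_by_condition: dict[str, list[tuple[GenomicInterval, str]]],
    de_results: dict[tuple[str, str], dict[str, DERecord]],
    fdr_max: float = 0.05,
) -> list[RegulatoryPair]:
    """Validate candidates against condition-specific peaks + DE calls.

    For every ordered condition pair (A, B) present in ``de_results``, an
    element is differentially marked iff it overlaps a peak in exactly one
    of A, B; a candidate is validated when its element is differentially
    marked and its gene has FDR <= ``fdr_max`` in that pair's DE table.  A
    pair validated under several condition pairs is returned once with all
    its evidence.
    """
    conditions = set(peaks_by_condition)
    missing = [
        pair
        for pair in {
            tuple(sorted((a, b))) for a in conditions for b in conditions if a != b
        }
        if pair not in de_results and tuple(reversed(pair)) not in de_results
    ]
    if missing:
        raise ValueError(f"DE table missing condition pairs: {sorted(missing)}")

    rcne_by_id = {r.rcne_id: r for r in rcnes}
    validated: dict[tuple[str, str], RegulatoryPair] = {}
    for (cond_a, cond_b), table in sorted(de_results.items()):
        peaks_a = peaks_by_condition.get(cond_a, [])
        peaks_b = peaks_by_condition.get(cond_b, [])
        for cand in candidates:
            r = rcne_by_id.get(cand.rcne_id)
            if r is None:
                continue
            pid_a = _overlaps_any(r.interval, peaks_a)
            pid_b = _overlaps_any(r.interval, peaks_b)
            if (pid_a is None) == (pid_b is None):
                continue  # marked in both or neither
            rec = table.get(cand.gene_id)
            if rec is None or rec.fdr > fdr_max:
                continue
            key = (cand.rcne_id, cand.gene_id)
            if key not in validated:
                validated[key] = RegulatoryPair(
                    rcne_id=cand.rcne_id,
                    gene_id=cand.gene_id,
                    distance=cand.distance,
                )
            validated[key].evidence.append(
                PairEvidence(
                    condition_pair=(cond_a, cond_b),
                    peak_id=pid_a if pid_a is not None else pid_b,
                    logfc=rec.logfc,
                    fdr=rec.fdr,
                )
            )
    return [validated[k] for k in sorted(validated)]


# ---------------------------------------------------------------------------
# signal metaprofile and expression
# ---------------------------------------------------------------------------


def metaprofile(
    track: SignalTrack,
    centers: list[tuple[str, int]],
    cds_mask: list[GenomicInterval],
    expression: dict[int, float] | None = None,
    half_width: int = 2000,
    bin_size: int = 50,
    n_strata: int = 4,
) -> tuple[np.ndarray, list[str]]:
    """Mean signal around element centers, stratified by target expression.

    Positions inside ``cds_mask`` are treated as missing (coding counts
    removed).  ``expression`` maps center index -> expression value (log
    RPKM of the element's target gene); centers without a value form an
    "unstratified" row.  Returns (strata x bins matrix, stratum labels).
    """
    if half_width % bin_size != 0:
        raise ValueError("half_width must be a multiple of bin_size")
    n_bins = 2 * half_width // bin_size
    mask_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in cds_mask:
        mask_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))

    signals = np.empty((len(centers), 2 * half_width))
    for i, (chrom, center) in enumerate(centers):
        start = center - half_width
        vals = track.values(chrom, start, center + half_width)
        for s, e in mask_by_chrom.get(chrom, ()):
            a, b = max(s, start) - start, min(e, center + half_width) - start
            if a < b:
                vals[a:b] = np.nan
        signals[i] = vals

    expr = expression or {}
    have = sorted(i for i in expr if 0 <= i < len(centers))
    strata: list[tuple[str, list[int]]] = []
    if have:
        vals = np.array([expr[i] for i in have])
        qs = np.quantile(vals, np.linspace(0, 1, n_strata + 1))
        for k in range(n_strata):
            lo, hi = qs[k], qs[k + 1]
            members = [
                i for i, v in zip(have, vals)
                if (v >= lo if k == 0 else v > lo) and v <= hi
            ]
            strata.append((f"expr_q{k + 1}", members))
    without = [i for i in range(len(centers)) if i not in expr]
    if without or not have:
        strata.append(("unstratified", without))

    out = np.full((len(strata), n_bins), np.nan)
    labels = []
    for row, (label, members) in enumerate(strata):
        labels.append(label)
        if not members:
            continue
        sub = signals[members].reshape(len(members), n_bins, bin_size)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
            out[row] = np.nanmean(sub, axis=(0, 2))
    return out, labels


def rpkm(
    counts: dict[str, int], gene_lengths: dict[str, int], library_size: int
) -> dict[str, float]:
    """Reads per kilobase of transcript per million mapped reads."""
    if library_size <= 0:
        raise ValueError("library size must be positive")
    out = {}
    for gene, c in counts.items():
        length = gene_lengths[gene]
        if length <= 0:
            raise ValueError(f"gene {gene}: non-positive length")
        if c < 0:
            raise ValueError(f"gene {gene}: negative count")
        out[gene] = c / (length / 1000.0) / (library_size / 1e6)
    return out
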