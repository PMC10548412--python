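"""Sequence-level characterization of conserved elements.

Three analyses: (i) a moving-window A+T profile across element centers and
flanks with a center-vs-flank t-test, (ii) thermodynamic nucleosome
occupancy from a hard-core placement partition function with a pluggable
sequence-energy model, and (iii) population SNP-density contrasts between
genomic region classes (purifying-selection signal), using Yates-corrected
2x2 chi-square tests.

The nucleosome model places 147-bp footprints with Boltzmann weight
W_i = weight_scale * exp(alpha * (ref_at - AT_i)), where AT_i is the A+T
fraction of the footprint starting at i.  AT-rich footprints are
disfavored (alpha > 0), matching the experimental tendency of A+T-rich
sequence to exclude nucleosomes.  The default weight_scale 1.223 puts
background occupancy near 0.8 on sequence at the reference composition,
a typical genome-wide level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2_contingency, ttest_ind

from .io_formats import GeneModel, GenomicInterval

__all__ = [
    "ATProfile",
    "NucleosomeModel",
    "RegionClassStats",
    "at_profile",
    "center_flank_test",
    "nucleosome_occupancy",
    "sample_controls",
    "snp_density_table",
    "region_stats_from_counts",
]


def _at_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    at = sum(1 for c in seq if c in "ATat")
    return at / len(seq)


def _cds_intervals(genes: list[GeneModel]) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        for iv in g.cds:
            out.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return out


def _touches(intervals: list[tuple[int, int]], start: int, end: int) -> bool:
    return any(s < end and start < e for s, e in intervals)


# ---------------------------------------------------------------------------
# A+T profile
# ---------------------------------------------------------------------------


@dataclass
class ATProfile:
    """Mean windowed A+T fraction across elements, centers aligned.

    ``offsets[k]`` is the window-start position relative to the start of
    the profiled region [center - c/2 - flank, center + c/2 + flank).
    """

    offsets: np.ndarray
    values: np.ndarray
    window: int
    step: int
    center: int
    flank: int
    baseline: float
    n_elements: int
    n_excluded: int

    def center_slice(self) -> np.ndarray:
        """Values of windows lying entirely inside the center region."""
        lo = self.flank
        hi = self.flank + self.center - self.window
        mask = (self.offsets >= lo) & (self.offsets <= hi)
        return self.values[mask]


def _element_region(iv: GenomicInterval, flank: int, center: int) -> tuple[int, int]:
    mid = (iv.start + iv.end) // 2
    start = mid - center // 2 - flank
    return start, start + 2 * flank + center


def at_profile(
    elements: list[GenomicInterval],
    genome: dict[str, str],
    genes: list[GeneModel],
    flank: int = 1000,
    window: int = 10,
    step: int = 1,
    center: int = 30,
) -> ATProfile:
    """Moving-window A+T content over element centers and flanks.

    Elements whose profiled region [center - flank, center + flank]
    touches any CDS, or runs off the chromosome, are excluded; raises if
    nothing survives.
    """
    cds = _cds_intervals(genes)
    width = 2 * flank + center
    n_off = (width - window) // step + 1
    offsets = np.arange(n_off) * step
    acc = np.zeros(n_off)
    used = 0
    excluded = 0
    for iv in elements:
        start, end = _element_region(iv, flank, center)
        seq = genome.get(iv.chrom, "")
        if start < 0 or end > len(seq) or _touches(cds.get(iv.chrom, []), start, end):
            excluded += 1
            continue
        sub = seq[start:end].upper()
        is_at = np.frombuffer(sub.encode(), dtype=np.uint8)
        is_at = ((is_at == ord("A")) | (is_at == ord("T"))).astype(float)
        csum = np.concatenate([[0.0], np.cumsum(is_at)])
        acc += (csum[offsets + window] - csum[offsets]) / window
        used += 1
    if used == 0:
        raise ValueError(
            f"all {excluded} element(s) excluded (CDS overlap or chromosome edge)"
        )
    baseline = _at_fraction("".join(genome.values()))
    return ATProfile(
        offsets=offsets,
        values=acc / used,
        window=window,
        step=step,
        center=center,
        flank=flank,
        baseline=baseline,
        n_elements=used,
        n_excluded=excluded,
    )


def center_flank_test(
    elements: list[GenomicInterval],
    genome: dict[str, str],
    genes: list[GeneModel],
    flank: int = 1000,
    center: int = 30,
) -> tuple[float, float]:
    """Welch t-test of per-element center A+T vs flank A+T.

    Uses the same exclusion rule as :func:`at_profile`.  Returns
    (t statistic, two-sided p-value).
    """
    cds = _cds_intervals(genes)
    centers, flanks = [], []
    for iv in elements:
        start, end = _element_region(iv, flank, center)
        seq = genome.get(iv.chrom, "")
        if start < 0 or end > len(seq) or _touches(cds.get(iv.chrom, []), start, end):
            continue
        sub = seq[start:end].upper()
        centers.append(_at_fraction(sub[flank : flank + center]))
        flanks.append(_at_fraction(sub[:flank] + sub[flank + center :]))
    if len(centers) < 2:
        raise ValueError("need at least 2 usable elements for the t-test")
    if np.ptp(centers) == 0 and np.ptp(flanks) == 0:
        return 0.0, 1.0
    res = ttest_ind(centers, flanks, equal_var=False)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# nucleosome occupancy
# ---------------------------------------------------------------------------


@dataclass
class NucleosomeModel:
    """Hard-core nucleosome placement weights from footprint A+T content."""

    footprint: int = 147
    alpha: float = 6.0       # energy per unit A+T fraction; >0 disfavors AT-rich
    weight_scale: float = 1.223  # background occupancy ~0.8 at ref composition
    ref_at: float = 0.65

    def log_weights(self, seq: str) -> np.ndarray:
        """ln W_i for every footprint start in ``seq``."""
        w = self.footprint
        if len(seq) < w:
            raise ValueError(f"sequence shorter than footprint ({len(seq)} < {w})")
        s = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        is_at = ((s == ord("A")) | (s == ord("T"))).astype(float)
        csum = np.concatenate([[0.0], np.cumsum(is_at)])
        at = (csum[w:] - csum[:-w]) / w
        return np.log(self.weight_scale) + self.alpha * (self.ref_at - at)


def occupancy_profile(seq: str, model: NucleosomeModel) -> np.ndarray:
    """Per-base nucleosome occupancy O(j) for one sequence.

    Forward/backward recursion over the hard-core placement partition
    function, in log space: Z_f(i) = Z_f(i-1) + W_{i-w} Z_f(i-w), with the
    start probability P(i) = Z_f(i) W_i Z_b(i+w) / Z and the occupancy the
    w-window sum of start probabilities.
    """
    w = model.footprint
    logW = model.log_weights(seq)
    L = len(seq)
    n = L - w + 1
    logZf = np.zeros(L + 1)
    for i in range(1, L + 1):
        v = logZf[i - 1]
        if i >= w:
            v = np.logaddexp(v, logW[i - w] + logZf[i - w])
        logZf[i] = v
    logZb = np.zeros(L + 1)
    for i in range(L - 1, -1, -1):
        v = logZb[i + 1]
        if i + w <= L:
            v = np.logaddexp(v, logW[i] + logZb[i + w])
        logZb[i] = v
    logZ = logZf[L]
    log_p = logZf[:n] + logW + logZb[w:] - logZ
    p_start = np.exp(log_p)
    occ = np.convolve(p_start, np.ones(w))[:L]
    return np.clip(occ, 0.0, 1.0)


def nucleosome_occupancy(
    sequences: list[str], model: NucleosomeModel | None = None, flank: int = 5000
) -> np.ndarray:
    """Mean occupancy over 2*flank+1 positions centered on each sequence.

    Every sequence must be at least 2*flank+1 long; the central 2*flank+1
    positions of each per-sequence profile are averaged.
    """
    if model is None:
        model = NucleosomeModel()
    span = 2 * flank + 1
    profiles = []
    for seq in sequences:
        if len(seq) < span:
            raise ValueError(f"sequence length {len(seq)} < required {span}")
        occ = occupancy_profile(seq, model)
        mid = len(seq) // 2
        profiles.append(occ[mid - flank : mid + flank + 1])
    if not profiles:
        raise ValueError("no sequences supplied")
    return np.mean(profiles, axis=0)


# ---------------------------------------------------------------------------
# matched random controls
# ---------------------------------------------------------------------------


def sample_controls(
    genome: dict[str, str],
    genes: list[GeneModel],
    lengths: list[int],
    match_at: bool = False,
    at_targets: list[float] | None = None,
    at_tol: float = 0.02,
    seed: int = 0,
    max_tries: int = 5000,
) -> list[GenomicInterval]:
    """Random CDS-free intervals, optionally A+T-matched to paired targets.

    One control per entry of ``lengths``; with ``match_at`` the i-th
    control's A+T fraction must fall within ``at_tol`` of
    ``at_targets[i]``.  Deterministic under ``seed``; raises after
    ``max_tries`` rejections reporting the best tolerance achieved.
    """
    if match_at and (at_targets is None or len(at_targets) != len(lengths)):
        raise ValueError("match_at requires one at_target per length")
    rng = np.random.default_rng(seed)
    cds = _cds_intervals(genes)
    chroms = sorted(c for c, s in genome.items() if len(s) > max(lengths))
    out: list[GenomicInterval] = []
    for i, length in enumerate(lengths):
        best_gap = np.inf
        for _ in range(max_tries):
            chrom = chroms[int(rng.integers(len(chroms)))]
            seq = genome[chrom]
            start = int(rng.integers(0, len(seq) - length))
            if _touches(cds.get(chrom, []), start, start + length):
                continue
            if match_at:
                at = _at_fraction(seq[start : start + length])
                gap = abs(at - at_targets[i])
                best_gap = min(best_gap, gap)
                if gap > at_tol:
                    continue
            out.append(GenomicInterval(chrom, start, start + length))
            break
        else:
            raise RuntimeError(
                f"control {i}: no CDS-free draw within A+T tolerance "
                f"{at_tol} after {max_tries} tries (best {best_gap:.4f})"
            )
    return out


# ---------------------------------------------------------------------------
# SNP density by region class
# ---------------------------------------------------------------------------


@dataclass
class RegionClassStats:
    name: str
    snp_count: int
    total_length: int
    p_vs_genome: float | None = None
    p_vs_coding: float | None = None

    @property
    def per_kb(self) -> float:
        return 1000.0 * self.snp_count / self.total_length


def _yates_p(a: int, la: int, b: int, lb: int) -> float:
    """Yates-corrected chi-square p for SNP/non-SNP x class/comparator."""
    table = np.array([[a, la - a], [b, lb - b]], dtype=float)
    if table.min() < 0:
        raise ValueError("SNP count exceeds region length")
    res = chi2_contingency(table, correction=True)
    return float(res.pvalue)


def region_stats_from_counts(
    counts: dict[str, tuple[int, int]],
    genome_key: str = "whole genome",
    coding_key: str = "coding region",
) -> list[RegionClassStats]:
    """Per-kb rates and chi-square contrasts from (snp_count, length) pairs.

    Region classes may be nested (each is contrasted against the genome
    and coding comparators as printed, not against its complement).
    """
    for key in (genome_key, coding_key):
        if key not in counts:
            raise KeyError(f"counts must include {key!r}")
    g_snp, g_len = counts[genome_key]
    c_snp, c_len = counts[coding_key]
    out = []
    for name, (snp, length) in counts.items():
        if length <= 0:
            raise ValueError(f"class {name!r} has zero length")
        st = RegionClassStats(name=name, snp_count=snp, total_length=length)
        if name != genome_key:
            st.p_vs_genome = _yates_p(snp, length, g_snp, g_len)
        if name != coding_key:
            st.p_vs_coding = _yates_p(snp, length, c_snp, c_len)
        out.append(st)
    return out


def _merged_length_and_hits(
    intervals: list[GenomicInterval], snps: set[tuple[str, int]]
) -> tuple[int, int]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    total = 0
    merged_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        merged: list[tuple[int, int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        merged_by_chrom[chrom] = merged
        total += sum(e - s for s, e in merged)
    hits = 0
    for chrom, pos in snps:
        for s, e in merged_by_chrom.get(chrom, ()):
            if s <= pos < e:
                hits += 1
                break
    return hits, total


def snp_density_table(
    snps: set[tuple[str, int]],
    region_classes: dict[str, list[GenomicInterval]],
    genome_key: str = "whole genome",
    coding_key: str = "coding region",
) -> list[RegionClassStats]:
    """Count SNPs per region class and contrast densities.

    ``region_classes`` maps class name -> interval list (overlapping
    classes are scored independently; a SNP may count in several).  Raises
    on an empty class.
    """
    counts: dict[str, tuple[int, int]] = {}
    for name, intervals in region_classes.items():
        if not intervals:
            raise ValueError(f"region class {name!r} is empty")
        counts[name] = _merged_length_and_hits(intervals, snps)
    return region_stats_from_counts(counts, genome_key, coding_key)
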