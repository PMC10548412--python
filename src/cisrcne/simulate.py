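"""Synthetic clade generator: genomes, annotations, truth-labelled alignment,
population SNPs, and a condition-specific epigenome.

The generator emulates the inputs of a clade-wide conserved-element study
at desk scale: an ancestral sequence with planted genes and conserved
non-coding elements evolves down a known tree under a nucleotide
substitution model, with branches scaled by ``rho_true`` inside planted
elements and CDS.  There is no indel evolution — alignment columns map
one-to-one to homologous positions, so the emitted MAF is exact truth —
and rearrangements (inversions, translocations in chosen lineages) act at
the granularity of fixed-size alignment blocks, which double as anchor
candidates.  Everything is deterministic under the config seed.

The default clade has 5 species on a caterpillar topology whose root-to-
reference divergences span ~0.1-0.44 substitutions/site, mirroring the
divergence spread of a compact, recently radiated plant family; the default genome is
200 kb with plant-like composition (65% A+T), 25 single-block genes and 20
planted non-coding elements whose 30-bp cores are GC-enriched (the A+T dip
real plant CNS centers show).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io_formats as iof
from .io_formats import (
    AlignmentBlock,
    DERecord,
    GeneModel,
    GenomicInterval,
    MafRow,
    SignalTrack,
)
from .phylo import BASES, PhyloTree, SubstitutionModel

__all__ = [
    "Rearrangement",
    "CladeSimConfig",
    "TruthSet",
    "SimulatedClade",
    "simulate_clade",
    "simulate_snps",
    "simulate_epigenome",
]

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


DEFAULT_TREE = (
    "((((ref:0.05,spB:0.05):0.05,spC:0.08):0.06,spD:0.12):0.08,spE:0.20);"
)


@dataclass(frozen=True)
class Rearrangement:
    """A lineage-specific structural event at block granularity."""

    species: str
    kind: str  # "inversion" | "translocation"
    start_block: int
    n_blocks: int
    dest_block: int | None = None  # translocation target (ref block index)


@dataclass
class CladeSimConfig:
    newick: str = DEFAULT_TREE
    ref_species: str = "ref"
    chrom: str = "chr1"
    genome_length: int = 200_000
    block_size: int = 2_000
    at_content: float = 0.65
    kappa: float = 2.0  # transition/transversion bias of the HKY model
    n_genes: int = 25
    n_planted_cne: int = 20
    cne_length_range: tuple[int, int] = (60, 200)
    cne_center_width: int = 30
    cne_center_at: float = 0.35  # GC-enriched core
    cne_near_gene_frac: float = 0.6
    rho_true: float = 0.3
    rearrangements: tuple[Rearrangement, ...] = (
        Rearrangement("spD", "inversion", 55, 6),
        Rearrangement("spE", "translocation", 20, 5, 70),
    )
    dropout_frac: float = 0.12
    snp_rate_neutral: float = 0.016   # per bp, ~whole-genome density
    snp_rate_conserved: float = 0.0076  # per bp inside planted elements / CDS
    conditions: tuple[str, str] = ("leaf", "40DPA")
    marked_fraction: float = 0.5
    de_logfc: float = 1.5
    de_fdr: float = 1e-5
    peak_signal: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.rho_true <= 1.0):
            raise ValueError("rho_true must be in (0,1]")
        if self.snp_rate_neutral < 0 or self.snp_rate_conserved < 0:
            raise ValueError("SNP rates must be >= 0")
        if self.genome_length % self.block_size != 0:
            raise ValueError("genome_length must be a multiple of block_size")

    def substitution_model(self) -> SubstitutionModel:
        at = self.at_content
        pi = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
        return SubstitutionModel.hky(pi, self.kappa)

    def tree(self) -> PhyloTree:
        return PhyloTree.from_newick(self.newick)


@dataclass
class TruthSet:
    """Ground truth consistent with the emitted files."""

    planted: list[GenomicInterval] = field(default_factory=list)
    breakpoints: list[int] = field(default_factory=list)  # ref coords
    snp_counts: dict[str, int] = field(default_factory=dict)
    marked_rcnes: list[str] = field(default_factory=list)
    de_genes: list[str] = field(default_factory=list)
    pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        data = {
            "planted": [
                [iv.chrom, iv.start, iv.end] for iv in self.planted
            ],
            "breakpoints": self.breakpoints,
            "snp_counts": self.snp_counts,
            "marked_rcnes": self.marked_rcnes,
            "de_genes": self.de_genes,
            "pairs": [list(p) for p in self.pairs],
        }
        Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        data = json.loads(Path(path).read_text())
        return cls(
            planted=[GenomicInterval(c, s, e) for c, s, e in data["planted"]],
            breakpoints=list(data["breakpoints"]),
            snp_counts=dict(data["snp_counts"]),
            marked_rcnes=list(data["marked_rcnes"]),
            de_genes=list(data["de_genes"]),
            pairs=[tuple(p) for p in data["pairs"]],
        )


@dataclass
class SimulatedClade:
    config: CladeSimConfig
    tree: PhyloTree
    model: SubstitutionModel
    genomes: dict[str, str]              # species -> its own genome sequence
    genes_by_species: dict[str, list[GeneModel]]
    blocks: list[AlignmentBlock]
    truth: TruthSet

    @property
    def ref_species(self) -> str:
        return self.config.ref_species

    @property
    def ref_genes(self) -> list[GeneModel]:
        return self.genes_by_species[self.config.ref_species]

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for sp in sorted(self.genomes):
            iof.write_fasta({self.config.chrom: self.genomes[sp]}, out / f"{sp}.fa")
            iof.write_gff3(self.genes_by_species[sp], out / f"{sp}.gff3")
        iof.write_maf(self.blocks, out / "alignment.maf")
        self.tree_to_file(out / "tree.nwk")
        self.truth.to_json(out / "truth.json")

    def tree_to_file(self, path: str | Path) -> None:
        Path(path).write_text(self.tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# feature placement
# ---------------------------------------------------------------------------


def _place_features(
    cfg: CladeSimConfig, rng: np.random.Generator
) -> tuple[list[GeneModel], list[GenomicInterval]]:
    """Place genes and planted elements, each inside a single block.

    Keeping every feature within one block means rearrangements never cut
    a gene or element, so per-species annotation mapping stays exact.
    """
    n_blocks = cfg.genome_length // cfg.block_size
    margin = 60
    occupied: list[tuple[int, int]] = []

    def free(start: int, end: int, pad: int = 40) -> bool:
        return all(e + pad <= start or end + pad <= s for s, e in occupied)

    genes: list[GeneModel] = []
    for gi in range(cfg.n_genes):
        for _ in range(400):
            utr5 = int(rng.integers(60, 150))
            n_ex = int(rng.integers(2, 4))
            exons = [int(rng.integers(40, 100)) * 3 for _ in range(n_ex)]
            introns = [int(rng.integers(80, 250)) for _ in range(n_ex - 1)]
            utr3 = int(rng.integers(60, 200))
            total = utr5 + sum(exons) + sum(introns) + utr3
            if total > cfg.block_size - 2 * margin:
                continue
            block = int(rng.integers(n_blocks))
            offset = int(rng.integers(margin, cfg.block_size - margin - total))
            start = block * cfg.block_size + offset
            if not free(start, start + total):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            # physical left-to-right segment list
            segs: list[tuple[str, int]] = [("utr5", utr5)]
            for k, ex in enumerate(exons):
                segs.append(("cds", ex))
                if k < n_ex - 1:
                    segs.append(("intron", introns[k]))
            segs.append(("utr3", utr3))
            if strand == "-":
                segs = segs[::-1]
            pos = start
            cds, u5, u3 = [], [], []
            for kind, length in segs:
                iv = GenomicInterval(cfg.chrom, pos, pos + length, strand)
                if kind == "cds":
                    cds.append(iv)
                elif kind == "utr5":
                    u5.append(iv)
                elif kind == "utr3":
                    u3.append(iv)
                pos += length
            genes.append(
                GeneModel(
                    gene_id=f"gene_{gi + 1:04d}",
                    interval=GenomicInterval(cfg.chrom, start, start + total, strand),
                    cds=cds,
                    utr5=u5,
                    utr3=u3,
                )
            )
            occupied.append((start, start + total))
            break
        else:
            raise RuntimeError(
                "gene placement failed: genome too crowded, lower n_genes"
            )

    planted: list[GenomicInterval] = []
    gene_list = sorted(genes, key=lambda g: g.interval.start)
    for ci in range(cfg.n_planted_cne):
        length = int(rng.integers(*cfg.cne_length_range))
        for attempt in range(600):
            if gene_list and rng.random() < cfg.cne_near_gene_frac:
                g = gene_list[int(rng.integers(len(gene_list)))]
                dist = int(rng.integers(200, 4000))
                side = rng.random() < 0.5
                start = g.interval.end + dist if side else g.interval.start - dist - length
            else:
                block = int(rng.integers(n_blocks))
                start = block * cfg.block_size + int(
                    rng.integers(margin, cfg.block_size - margin - length)
                )
            end = start + length
            block = start // cfg.block_size
            if start < margin or end > cfg.genome_length - margin:
                continue
            if end > (block + 1) * cfg.block_size - margin or start < block * cfg.block_size + margin:
                continue
            if not free(start, end):
                continue
            planted.append(GenomicInterval(cfg.chrom, start, end))
            occupied.append((start, end))
            break
        else:
            raise RuntimeError(
                "element placement failed: genome too crowded, lower n_planted_cne"
            )
    planted.sort(key=lambda iv: iv.start)
    return gene_list, planted


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------


def _sample_ancestor(
    cfg: CladeSimConfig, planted: list[GenomicInterval], rng: np.random.Generator
) -> np.ndarray:
    pi = np.array(
        [cfg.at_content / 2, (1 - cfg.at_content) / 2,
         (1 - cfg.at_content) / 2, cfg.at_content / 2]
    )
    seq = rng.choice(4, size=cfg.genome_length, p=pi)
    if cfg.cne_center_width > 0:
        at_c = cfg.cne_center_at
        pi_c = np.array([at_c / 2, (1 - at_c) / 2, (1 - at_c) / 2, at_c / 2])
        for iv in planted:
            mid = (iv.start + iv.end) // 2
            lo = mid - cfg.cne_center_width // 2
            hi = lo + cfg.cne_center_width
            seq[lo:hi] = rng.choice(4, size=hi - lo, p=pi_c)
    return seq


def _conserved_mask(
    cfg: CladeSimConfig, genes: list[GeneModel], planted: list[GenomicInterval]
) -> np.ndarray:
    """Positions under purifying selection: planted elements plus the first
    and second position of every codon.  Third codon positions stay
    neutral, so four-fold degenerate sites remain a valid neutral proxy
    for model fitting (the premise the conservation scoring rests on)."""
    mask = np.zeros(cfg.genome_length, dtype=bool)
    for g in genes:
        cds_positions: list[int] = []
        for iv in sorted(g.cds, key=lambda v: v.start):
            cds_positions.extend(range(iv.start, iv.end))
        if g.strand == "-":
            cds_positions.reverse()
        for k, pos in enumerate(cds_positions):
            if k % 3 != 2:
                mask[pos] = True
    for iv in planted:
        mask[iv.start : iv.end] = True
    return mask


def _evolve(
    tree: PhyloTree,
    model: SubstitutionModel,
    ancestor: np.ndarray,
    mask: np.ndarray,
    rho_true: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Evolve the ancestor to every leaf; branches scaled by rho_true
    inside the conserved mask."""
    seqs: dict[int, np.ndarray] = {tree.root: ancestor}
    order = list(reversed(tree.postorder))  # preorder: parents first
    for node in order:
        if node == tree.root:
            continue
        parent_seq = seqs[tree.parent[node]]
        t = tree.branch_lengths[node]
        child = parent_seq.copy()
        for conserved, scale in ((False, 1.0), (True, rho_true)):
            P = model.transition_matrix(t * scale)
            sel = mask if conserved else ~mask
            for b in range(4):
                idx = np.flatnonzero(sel & (parent_seq == b))
                if len(idx):
                    child[idx] = rng.choice(4, size=len(idx), p=P[b])
        seqs[node] = child
    return {
        name: seqs[tree.leaf_index[name]] for name in tree.leaf_names
    }


# ---------------------------------------------------------------------------
# rearrangements, per-species genomes and the truth MAF
# ---------------------------------------------------------------------------


def _block_orders(
    cfg: CladeSimConfig, species: list[str]
) -> tuple[dict[str, list[tuple[int, str]]], list[int]]:
    """Per-species block order/orientation after rearrangements."""
    n_blocks = cfg.genome_length // cfg.block_size
    orders = {sp: [(b, "+") for b in range(n_blocks)] for sp in species}
    breakpoints: set[int] = set()
    for r in cfg.rearrangements:
        if r.species not in orders:
            raise ValueError(f"rearrangement references unknown species {r.species!r}")
        order = orders[r.species]
        idx = [i for i, (b, _s) in enumerate(order) if r.start_block <= b < r.start_block + r.n_blocks]
        if not idx:
            continue
        lo, hi = min(idx), max(idx) + 1
        if r.kind == "inversion":
            seg = [(b, "-" if s == "+" else "+") for b, s in order[lo:hi][::-1]]
            orders[r.species] = order[:lo] + seg + order[hi:]
        elif r.kind == "translocation":
            seg = order[lo:hi]
            rest = order[:lo] + order[hi:]
            dest = next(
                (i for i, (b, _s) in enumerate(rest) if b == r.dest_block),
                len(rest),
            )
            orders[r.species] = rest[:dest] + seg + rest[dest:]
        else:
            raise ValueError(f"unknown rearrangement kind {r.kind!r}")
        # truth breakpoints are the source-side boundaries, where reference
        # adjacency is disrupted by the full displacement of the event; a
        # short translocated run reinserts within any reasonable rank-gap
        # tolerance at its destination, so the destination is not a
        # collinearity-breaking point
        breakpoints.add(r.start_block * cfg.block_size)
        breakpoints.add((r.start_block + r.n_blocks) * cfg.block_size)
    return orders, sorted(breakpoints)


def _decode(arr: np.ndarray) -> str:
    return "".join(BASES[b] for b in arr)


def simulate_clade(config: CladeSimConfig | None = None) -> SimulatedClade:
    """Generate genomes, annotations and an exact-truth MAF for the clade."""
    cfg = config or CladeSimConfig()
    rng = np.random.default_rng(cfg.seed)
    tree = cfg.tree()
    model = cfg.substitution_model()
    if cfg.ref_species not in tree.leaf_names:
        raise ValueError(f"reference {cfg.ref_species!r} not a leaf of the tree")

    genes, planted = _place_features(cfg, rng)
    ancestor = _sample_ancestor(cfg, planted, rng)
    mask = _conserved_mask(cfg, genes, planted)
    leaf_seqs = _evolve(tree, model, ancestor, mask, cfg.rho_true, rng)

    species = tree.leaf_names
    orders, breakpoints = _block_orders(cfg, species)
    n_blocks = cfg.genome_length // cfg.block_size
    B = cfg.block_size

    # blocks that must stay complete-profile: those holding planted elements
    cne_blocks = {iv.start // B for iv in planted}
    dropout: dict[int, str] = {}
    non_ref = [sp for sp in species if sp != cfg.ref_species]
    for b in range(n_blocks):
        if b in cne_blocks:
            continue
        if rng.random() < cfg.dropout_frac:
            dropout[b] = non_ref[int(rng.integers(len(non_ref)))]

    # per-species genome strings and block locations
    genomes: dict[str, str] = {}
    block_loc: dict[str, dict[int, tuple[int, str]]] = {}
    for sp in species:
        parts: list[str] = []
        loc: dict[int, tuple[int, str]] = {}
        pos = 0
        for b, strand in orders[sp]:
            seg = _decode(leaf_seqs[sp][b * B : (b + 1) * B])
            if strand == "-":
                seg = _revcomp(seg)
            loc[b] = (pos, strand)
            parts.append(seg)
            pos += B
        genomes[sp] = "".join(parts)
        block_loc[sp] = loc

    # truth MAF: one block per reference block
    blocks: list[AlignmentBlock] = []
    for b in range(n_blocks):
        rows: dict[str, MafRow] = {}
        for sp in species:
            if sp != cfg.ref_species and dropout.get(b) == sp:
                continue
            start, strand = block_loc[sp][b]
            text = _decode(leaf_seqs[sp][b * B : (b + 1) * B])
            rows[sp] = MafRow(
                interval=GenomicInterval(cfg.chrom, start, start + B, strand),
                strand=strand,
                text=text,
                src_size=cfg.genome_length,
            )
        blocks.append(AlignmentBlock(ref_species=cfg.ref_species, rows=rows))

    # per-species gene annotations through the block map
    genes_by_species: dict[str, list[GeneModel]] = {}
    for sp in species:
        mapped: list[GeneModel] = []
        for g in genes:
            b = g.interval.start // B
            start, strand = block_loc[sp][b]
            off = b * B

            def map_iv(iv: GenomicInterval) -> GenomicInterval:
                if strand == "+":
                    s = start + (iv.start - off)
                    new_strand = iv.strand
                else:
                    s = start + (off + B - iv.end)
                    new_strand = "-" if iv.strand == "+" else "+"
                return GenomicInterval(cfg.chrom, s, s + iv.length, new_strand)

            mapped.append(
                GeneModel(
                    gene_id=g.gene_id,
                    interval=map_iv(g.interval),
                    cds=[map_iv(iv) for iv in g.cds],
                    utr5=[map_iv(iv) for iv in g.utr5],
                    utr3=[map_iv(iv) for iv in g.utr3],
                )
            )
        genes_by_species[sp] = sorted(mapped, key=lambda g: g.interval.start)

    truth = TruthSet(planted=planted, breakpoints=breakpoints)
    return SimulatedClade(
        config=cfg,
        tree=tree,
        model=model,
        genomes=genomes,
        genes_by_species=genes_by_species,
        blocks=blocks,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# population SNPs
# ---------------------------------------------------------------------------


def simulate_snps(
    clade: SimulatedClade, seed: int | None = None
) -> list[tuple[str, int, str, str]]:
    """Bernoulli SNP placement: reduced rate in planted elements and CDS.

    Returns (chrom, pos0, ref, alt) records and fills
    ``clade.truth.snp_counts`` with per-class totals.
    """
    cfg = clade.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    mask = _conserved_mask(cfg, clade.ref_genes, clade.truth.planted)
    rates = np.where(mask, cfg.snp_rate_conserved, cfg.snp_rate_neutral)
    hit = rng.random(cfg.genome_length) < rates
    ref_seq = clade.genomes[cfg.ref_species]
    out = []
    for pos in np.flatnonzero(hit):
        ref = ref_seq[pos]
        if ref not in BASES:
            continue
        alt = BASES[(BASES.index(ref) + 1 + int(rng.integers(3))) % 4]
        out.append((cfg.chrom, int(pos), ref, alt))
    clade.truth.snp_counts = {
        "conserved": int(hit[mask].sum()),
        "neutral": int(hit[~mask].sum()),
    }
    return out


# ---------------------------------------------------------------------------
# condition-specific epigenome
# ---------------------------------------------------------------------------


def simulate_epigenome(
    clade: SimulatedClade,
    rcnes,          # list[rcne.CisRCNE]
    candidates,     # list[rcne.RegulatoryPair]
    seed: int | None = None,
):
    """Peaks, coverage and DE tables that plant known regulatory pairs.

    A ``marked_fraction`` of the cis-RCNEs that have candidate target
    genes receive a peak in the second condition only, with a smooth
    coverage bump; every candidate gene of a marked element gets a
    significant DE record.  A couple of elements get peaks in both
    conditions (never differentially marked), and background peaks avoid
    all elements.  ``clade.truth`` records the pairs the validation step
    must recover exactly.

    Returns (peaks_by_condition, de_results, coverage_by_condition).
    """
    cfg = clade.config
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    cond_a, cond_b = cfg.conditions  # peaks appear in cond_b only

    with_candidates = sorted(
        {c.rcne_id for c in candidates},
        key=lambda rid: next(r.interval.start for r in rcnes if r.rcne_id == rid),
    )
    n_marked = int(round(cfg.marked_fraction * len(with_candidates)))
    marked = sorted(
        rng.choice(len(with_candidates), size=min(n_marked, len(with_candidates)),
                   replace=False).tolist()
    )
    marked_ids = [with_candidates[i] for i in marked]
    unmarked_ids = [rid for rid in with_candidates if rid not in marked_ids]

    rcne_by_id = {r.rcne_id: r for r in rcnes}
    peaks_b: list[tuple[GenomicInterval, str]] = []
    peaks_a: list[tuple[GenomicInterval, str]] = []
    for k, rid in enumerate(marked_ids):
        peaks_b.append((rcne_by_id[rid].interval, f"peak_{cond_b}_{k:03d}"))
    # both-condition peaks over a couple of unmarked elements
    for k, rid in enumerate(unmarked_ids[:2]):
        iv = rcne_by_id[rid].interval
        peaks_a.append((iv, f"peak_shared_a_{k:03d}"))
        peaks_b.append((iv, f"peak_shared_b_{k:03d}"))
    # background peaks away from every element
    element_ivs = [r.interval for r in rcnes]
    for k in range(5):
        for _ in range(200):
            start = int(rng.integers(0, cfg.genome_length - 400))
            iv = GenomicInterval(cfg.chrom, start, start + 300)
            if not any(iv.overlaps(e) for e in element_ivs):
                peaks_a.append((iv, f"peak_bg_{k:03d}"))
                break

    target_genes = sorted(
        {c.gene_id for c in candidates if c.rcne_id in marked_ids}
    )
    de: dict[str, DERecord] = {}
    for g in clade.ref_genes:
        if g.gene_id in target_genes:
            sign = 1.0 if rng.random() < 0.7 else -1.0
            de[g.gene_id] = DERecord(
                g.gene_id,
                sign * (cfg.de_logfc + float(rng.random())),
                cfg.de_fdr * (0.5 + float(rng.random())),
            )
        else:
            de[g.gene_id] = DERecord(
                g.gene_id,
                float(rng.normal(0.0, 0.2)),
                float(rng.uniform(0.2, 1.0)),
            )
    de_results = {(cond_a, cond_b): de}

    # coverage: flat background, cosine bump over marked elements in cond_b
    def bump_frame(peaked: list[GenomicInterval]):
        import pandas as pd

        rows = [(cfg.chrom, 0, cfg.genome_length, 1.0)]
        for iv in peaked:
            mid = (iv.start + iv.end) // 2
            half = max(150, iv.length)
            for x0 in range(mid - half, mid + half, 25):
                rel = (x0 + 12 - mid) / half
                val = 1.0 + cfg.peak_signal * max(0.0, np.cos(rel * np.pi / 2)) ** 2
                rows.append((cfg.chrom, max(0, x0), max(0, x0) + 25, round(val, 3)))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])

    coverage = {
        cond_a: SignalTrack(bump_frame([])),
        cond_b: SignalTrack(bump_frame([rcne_by_id[rid].interval for rid in marked_ids])),
    }

    clade.truth.marked_rcnes = marked_ids
    clade.truth.de_genes = target_genes
    clade.truth.pairs = sorted(
        {(c.rcne_id, c.gene_id) for c in candidates if c.rcne_id in marked_ids}
    )
    return {cond_a: peaks_a, cond_b: peaks_b}, de_results, coverage
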