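"""Phylogenetic substitution models and likelihood machinery.

The conservation caller needs three things from this module: column
log-likelihoods under a tree + nucleotide substitution model (Felsenstein
pruning, with gaps treated as missing data), maximum-likelihood fitting of
a neutral model from annotated site classes (four-fold degenerate third
codon positions as the neutral proxy), and path distances on the fitted
tree.  Branch lengths are expected substitutions per site: every model's
rate matrix is normalized so that -sum_i pi_i Q_ii = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio.Data import CodonTable
from scipy.linalg import expm
from scipy.optimize import minimize

from .io_formats import AlignmentBlock, GeneModel

__all__ = [
    "PhyloTree",
    "SubstitutionModel",
    "SiteClassColumns",
    "FitError",
    "BASE_INDEX",
    "encode_base",
    "column_log_likelihood",
    "alignment_log_likelihoods",
    "fit_model",
    "path_distance",
    "extract_site_classes",
    "class_columns",
    "save_model",
    "load_model",
]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
MISSING = -1

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def encode_base(ch: str) -> int:
    """Map a character to 0..3, or -1 for gap/ambiguity (missing data)."""
    return BASE_INDEX.get(ch.upper(), MISSING)


class FitError(RuntimeError):
    """Optimizer failed to converge; carries the best point seen so far."""

    def __init__(self, message: str, best_params=None, grad_norm=None):
        super().__init__(message)
        self.best_params = best_params
        self.grad_norm = grad_norm


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------


class PhyloTree:
    """Rooted tree with branch lengths, flattened to postorder arrays.

    Node 0..n_leaves-1 are leaves (in ``leaf_names`` order); internal nodes
    follow in postorder; the root is last.  ``branch_lengths[i]`` is the
    length of the edge above node i (0 for the root).
    """

    def __init__(
        self,
        leaf_names: list[str],
        postorder: list[int],
        children: list[list[int]],
        parent: np.ndarray,
        branch_lengths: np.ndarray,
    ):
        self.leaf_names = list(leaf_names)
        self.leaf_index = {n: i for i, n in enumerate(leaf_names)}
        self.postorder = list(postorder)
        self.children = [list(c) for c in children]
        self.parent = np.asarray(parent, dtype=np.int64)
        self.branch_lengths = np.asarray(branch_lengths, dtype=float)
        if np.any(self.branch_lengths < 0):
            raise ValueError("negative branch length")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls._from_dendropy(tree)

    @classmethod
    def from_newick_file(cls, path: str) -> "PhyloTree":
        tree = dendropy.Tree.get(path=path, schema="newick")
        return cls._from_dendropy(tree)

    @classmethod
    def _from_dendropy(cls, tree: dendropy.Tree) -> "PhyloTree":
        leaves = [lf.taxon.label.replace(" ", "_") for lf in tree.leaf_node_iter()]
        if len(set(leaves)) != len(leaves):
            raise ValueError("duplicate leaf names in tree")
        index: dict = {}
        n_leaves = len(leaves)
        leaf_pos = {name: i for i, name in enumerate(leaves)}
        next_internal = n_leaves
        postorder: list[int] = []
        n_total = sum(1 for _ in tree.preorder_node_iter())
        children: list[list[int]] = [[] for _ in range(n_total)]
        parent = np.full(n_total, -1, dtype=np.int64)
        blen = np.zeros(n_total, dtype=float)
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                idx = leaf_pos[nd.taxon.label.replace(" ", "_")]
            else:
                idx = next_internal
                next_internal += 1
            index[nd] = idx
            postorder.append(idx)
            blen[idx] = nd.edge.length if nd.edge.length is not None else 0.0
            for ch in nd.child_nodes():
                children[idx].append(index[ch])
                parent[index[ch]] = idx
        root = index[tree.seed_node]
        blen[root] = 0.0
        return cls(leaves, postorder, children, parent, blen)

    # -- basic queries -------------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    @property
    def n_nodes(self) -> int:
        return len(self.postorder)

    @property
    def root(self) -> int:
        return self.postorder[-1]

    def free_branches(self) -> list[int]:
        """Indices of nodes whose edge length is a free parameter (non-root)."""
        return [i for i in self.postorder if i != self.root]

    def with_branch_lengths(self, lengths: dict[int, float] | np.ndarray) -> "PhyloTree":
        blen = self.branch_lengths.copy()
        if isinstance(lengths, dict):
            for i, v in lengths.items():
                blen[i] = v
        else:
            blen = np.asarray(lengths, dtype=float).copy()
        blen[self.root] = 0.0
        return PhyloTree(self.leaf_names, self.postorder, self.children, self.parent, blen)

    def scaled(self, factor: float) -> "PhyloTree":
        return self.with_branch_lengths(self.branch_lengths * factor)

    def total_length(self) -> float:
        return float(self.branch_lengths.sum())

    def to_newick(self) -> str:
        def fmt(i: int) -> str:
            if not self.children[i]:
                return f"{self.leaf_names[i]}:{self.branch_lengths[i]:.10g}"
            inner = ",".join(fmt(c) for c in self.children[i])
            if i == self.root:
                return f"({inner});"
            return f"({inner}):{self.branch_lengths[i]:.10g}"

        return fmt(self.root)


def path_distance(tree: PhyloTree, species_a: str, species_b: str) -> float:
    """Sum of branch lengths on the unique path between two leaves."""
    for sp in (species_a, species_b):
        if sp not in tree.leaf_index:
            raise KeyError(f"unknown leaf {sp!r}")
    if species_a == species_b:
        return 0.0
    a, b = tree.leaf_index[species_a], tree.leaf_index[species_b]
    anc_a: dict[int, float] = {}
    node, dist = a, 0.0
    while node != -1:
        anc_a[node] = dist
        dist += tree.branch_lengths[node]
        node = tree.parent[node]
    node, dist = b, 0.0
    while node not in anc_a:
        dist += tree.branch_lengths[node]
        node = tree.parent[node]
    return dist + anc_a[node]


# ---------------------------------------------------------------------------
# substitution models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubstitutionModel:
    """Normalized reversible nucleotide rate matrix with equilibrium pi."""

    Q: np.ndarray
    pi: np.ndarray
    family: str = "GTR"

    def __post_init__(self) -> None:
        Q = np.asarray(self.Q, dtype=float)
        pi = np.asarray(self.pi, dtype=float)
        if Q.shape != (4, 4) or pi.shape != (4,):
            raise ValueError("Q must be 4x4 and pi length 4")
        if np.any(pi <= 0):
            raise ValueError("pi entries must be positive")
        if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-8):
            raise ValueError("Q rows must sum to 0")
        object.__setattr__(self, "Q", Q)
        object.__setattr__(self, "pi", pi / pi.sum())

    @staticmethod
    def _normalize(Q: np.ndarray, pi: np.ndarray) -> np.ndarray:
        rate = -float(np.sum(pi * np.diag(Q)))
        return Q / rate

    @classmethod
    def jc(cls) -> "SubstitutionModel":
        Q = np.full((4, 4), 1.0 / 3.0)
        np.fill_diagonal(Q, -1.0)
        return cls(Q=Q, pi=np.full(4, 0.25), family="JC")

    @classmethod
    def hky(cls, pi, kappa: float) -> "SubstitutionModel":
        pi = np.asarray(pi, dtype=float)
        Q = np.zeros((4, 4))
        # transitions: A<->G (0,2), C<->T (1,3)
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                rate = kappa if {i, j} in ({0, 2}, {1, 3}) else 1.0
                Q[i, j] = rate * pi[j]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return cls(Q=cls._normalize(Q, pi), pi=pi, family="HKY")

    @classmethod
    def gtr(cls, pi, rates) -> "SubstitutionModel":
        """GTR from 6 exchangeabilities in order AC, AG, AT, CG, CT, GT."""
        pi = np.asarray(pi, dtype=float)
        r = np.asarray(rates, dtype=float)
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        Q = np.zeros((4, 4))
        for (i, j), rate in zip(pairs, r):
            Q[i, j] = rate * pi[j]
            Q[j, i] = rate * pi[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return cls(Q=cls._normalize(Q, pi), pi=pi, family="GTR")

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("negative time")
        if t == 0:
            return np.eye(4)
        return expm(self.Q * t)


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------


def alignment_log_likelihoods(
    tree: PhyloTree,
    model: SubstitutionModel,
    columns: np.ndarray,
    scale: float = 1.0,
) -> np.ndarray:
    """Log-likelihood of each alignment column by Felsenstein pruning.

    Parameters
    ----------
    columns
        Integer array (n_columns, n_leaves) in ``tree.leaf_names`` order;
        entries in 0..3, with -1 for gap/missing (marginalized: the leaf's
        partial vector is all ones).
    scale
        Multiplier applied to every branch length (the conserved state of
        the phylo-HMM uses scale=rho).

    Returns
    -------
    (n_columns,) array of natural-log likelihoods.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    cols = np.asarray(columns, dtype=np.int64)
    if cols.ndim == 1:
        cols = cols[None, :]
    n_col, n_leaf = cols.shape
    if n_leaf != tree.n_leaves:
        raise ValueError(
            f"columns have {n_leaf} leaves but tree has {tree.n_leaves}"
        )
    if n_col == 0:
        return np.zeros(0)

    P = {
        i: model.transition_matrix(scale * tree.branch_lengths[i])
        for i in tree.postorder
        if i != tree.root
    }
    partial = np.empty((tree.n_nodes, n_col, 4))
    log_scale = np.zeros(n_col)
    eye = np.eye(4)
    ones = np.ones(4)
    for i in tree.postorder:
        if not tree.children[i]:
            obs = cols[:, i]
            leaf_part = np.where(obs[:, None] >= 0, eye[np.clip(obs, 0, 3)], ones)
            partial[i] = leaf_part
        else:
            acc = np.ones((n_col, 4))
            for c in tree.children[i]:
                acc *= partial[c] @ P[c].T
            # renormalize to dodge underflow on deep trees
            m = acc.max(axis=1)
            m = np.where(m > 0, m, 1.0)
            log_scale += np.log(m)
            partial[i] = acc / m[:, None]
    lik = partial[tree.root] @ model.pi
    with np.errstate(divide="ignore"):
        return np.log(lik) + log_scale


def column_log_likelihood(
    tree: PhyloTree,
    model: SubstitutionModel,
    column: dict[str, str],
    scale: float = 1.0,
) -> float:
    """Log-likelihood of a single column given as {species: base}."""
    for sp in column:
        if sp not in tree.leaf_index:
            raise KeyError(f"species {sp!r} not in tree")
    arr = np.full(tree.n_leaves, MISSING, dtype=np.int64)
    for sp, base in column.items():
        arr[tree.leaf_index[sp]] = encode_base(base)
    return float(alignment_log_likelihoods(tree, model, arr[None, :], scale)[0])


def collapse_columns(columns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique column patterns and their multiplicities."""
    cols = np.asarray(columns, dtype=np.int64)
    uniq, counts = np.unique(cols, axis=0, return_counts=True)
    return uniq, counts


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

_MIN_BLEN = 1e-6
_MAX_BLEN = 20.0


def _empirical_pi(columns: np.ndarray) -> np.ndarray:
    counts = np.bincount(columns[columns >= 0].ravel(), minlength=4).astype(float)
    counts += 1.0  # avoid zero frequencies on tiny inputs
    return counts / counts.sum()


def _build_model(family: str, pi: np.ndarray, extra: np.ndarray) -> SubstitutionModel:
    if family == "JC":
        return SubstitutionModel.jc()
    if family == "HKY":
        return SubstitutionModel.hky(pi, float(np.exp(extra[0])))
    if family == "GTR":
        rates = np.concatenate([np.exp(extra), [1.0]])  # GT fixed at 1
        return SubstitutionModel.gtr(pi, rates)
    raise ValueError(f"unknown model family {family!r}")


def _n_extra(family: str) -> int:
    return {"JC": 0, "HKY": 1, "GTR": 5}[family]


def fit_model(
    columns: np.ndarray,
    tree: PhyloTree,
    family: str = "GTR",
    max_iter: int = 500,
    tol: float = 1e-8,
) -> tuple[SubstitutionModel, PhyloTree]:
    """Fit branch lengths (and family parameters) by maximum likelihood.

    Optimization is deterministic: bounded quasi-Newton (L-BFGS-B) on
    log-branch-lengths from a fixed start of 0.1 per branch.  Equilibrium
    frequencies are empirical for HKY/GTR.  Raises :class:`FitError` if
    the optimizer does not report convergence.
    """
    cols = np.asarray(columns, dtype=np.int64)
    if cols.shape[0] < 50:
        raise ValueError(f"need >= 50 columns to fit a model, got {cols.shape[0]}")
    uniq, counts = collapse_columns(cols)
    pi = np.full(4, 0.25) if family == "JC" else _empirical_pi(cols)
    free = tree.free_branches()
    n_extra = _n_extra(family)

    def unpack(x: np.ndarray) -> tuple[PhyloTree, SubstitutionModel]:
        blens = dict(zip(free, np.exp(x[: len(free)])))
        return tree.with_branch_lengths(blens), _build_model(family, pi, x[len(free):])

    def nll(x: np.ndarray) -> float:
        t, m = unpack(x)
        ll = alignment_log_likelihoods(t, m, uniq)
        return -float(np.dot(ll, counts))

    bounds = [(np.log(_MIN_BLEN), np.log(_MAX_BLEN))] * len(free) + [
        (np.log(1e-3), np.log(1e3))
    ] * n_extra
    # deterministic ladder of starts: highly diverged data can trap a
    # single far-off start on the saturation plateau (all branches at the
    # stationary limit), which is a genuine local optimum
    res = None
    for start in (0.1, 0.5, 1.5):
        x0 = np.concatenate(
            [np.full(len(free), np.log(start)), np.zeros(n_extra)]
        )
        r = minimize(
            nll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-7},
        )
        if res is None or r.fun < res.fun:
            res = r
    if not res.success and "ABNORMAL" in str(res.message).upper():
        raise FitError(
            f"model fit did not converge: {res.message}",
            best_params=res.x,
            grad_norm=float(np.linalg.norm(res.jac)),
        )
    fitted_tree, fitted_model = unpack(res.x)
    return fitted_model, fitted_tree


# ---------------------------------------------------------------------------
# site classes
# ---------------------------------------------------------------------------

FOURFOLD = "fourfold_degenerate"
CODON12 = "codon12"
NONCODING = "noncoding"
OTHER = "other"


def _is_fourfold(codon: str) -> bool:
    """True if the amino acid is invariant to the third codon position."""
    if len(codon) != 3 or any(b not in BASES for b in codon):
        return False
    try:
        aas = {_STANDARD_TABLE.forward_table.get(codon[:2] + b) for b in BASES}
    except KeyError:
        return False
    return len(aas) == 1 and None not in aas


@dataclass
class SiteClassColumns:
    """Reference-position site-class labels derived from the annotation.

    ``labels`` maps chrom -> {pos: label}; positions absent from the map
    were never covered by an alignment block.
    """

    labels: dict[str, dict[int, str]] = field(default_factory=dict)
    skipped_genes: list[str] = field(default_factory=list)

    def label_of(self, chrom: str, pos: int) -> str | None:
        return self.labels.get(chrom, {}).get(pos)

    def positions(self, label: str) -> set[tuple[str, int]]:
        return {
            (chrom, pos)
            for chrom, d in self.labels.items()
            for pos, lab in d.items()
            if lab == label
        }

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for d in self.labels.values():
            for lab in d.values():
                out[lab] = out.get(lab, 0) + 1
        return out


def extract_site_classes(
    blocks: list[AlignmentBlock], genes: list[GeneModel]
) -> SiteClassColumns:
    """Label aligned reference positions by codon role.

    Third positions of codons whose amino acid is invariant to that
    position (per the reference sequence) are ``fourfold_degenerate``;
    first/second codon positions are ``codon12``; positions overlapping no
    CDS are ``noncoding``; everything else in CDS is ``other``.  Genes
    whose total CDS length is not a multiple of 3 are skipped with a
    warning.
    """
    # reference base per aligned position
    ref_base: dict[str, dict[int, str]] = {}
    for block in blocks:
        row = block.rows[block.ref_species]
        chrom = row.interval.chrom
        store = ref_base.setdefault(chrom, {})
        pos = row.interval.start
        for ch in row.text:
            if ch != "-":
                store[pos] = ch.upper()
                pos += 1

    labels: dict[str, dict[int, str]] = {
        chrom: {pos: NONCODING for pos in d} for chrom, d in ref_base.items()
    }
    skipped: list[str] = []
    for gene in genes:
        if not gene.cds:
            continue
        if gene.cds_length() % 3 != 0:
            skipped.append(gene.gene_id)
            continue
        chrom = gene.interval.chrom
        cds_positions: list[int] = []
        for iv in sorted(gene.cds, key=lambda v: v.start):
            cds_positions.extend(range(iv.start, iv.end))
        if gene.strand == "-":
            cds_positions.reverse()
        store = labels.get(chrom, {})
        bases = ref_base.get(chrom, {})
        for ci in range(0, len(cds_positions), 3):
            codon_pos = cds_positions[ci : ci + 3]
            codon = ""
            for p in codon_pos:
                b = bases.get(p)
                if b is None:
                    codon = None
                    break
                codon += COMPLEMENT.get(b, "N") if gene.strand == "-" else b
            for k, p in enumerate(codon_pos):
                if p not in store:
                    continue
                if codon is None:
                    store[p] = OTHER
                elif k < 2:
                    store[p] = CODON12
                elif _is_fourfold(codon):
                    store[p] = FOURFOLD
                else:
                    store[p] = OTHER
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} gene(s) with CDS length not divisible by 3"
        )
    return SiteClassColumns(labels=labels, skipped_genes=skipped)


def class_columns(
    blocks: list[AlignmentBlock],
    site_classes: SiteClassColumns,
    label: str,
    species: list[str],
) -> np.ndarray:
    """Alignment columns (encoded, missing=-1) whose reference position has ``label``."""
    wanted = site_classes.positions(label)
    out = []
    for block in blocks:
        chrom = block.ref_interval.chrom
        ref_pos = block.ref_columns()
        texts = {sp: block.rows[sp].text if sp in block.rows else None for sp in species}
        for i, pos in enumerate(ref_pos):
            if pos < 0 or (chrom, int(pos)) not in wanted:
                continue
            out.append(
                [
                    encode_base(texts[sp][i]) if texts[sp] is not None else MISSING
                    for sp in species
                ]
            )
    return np.asarray(out, dtype=np.int64).reshape(-1, len(species))


# ---------------------------------------------------------------------------
# model serialization (plain text key: value)
# ---------------------------------------------------------------------------


def save_model(
    model: SubstitutionModel, tree: PhyloTree, path: str, rho: float | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(f"family: {model.family}\n")
        fh.write("pi: " + " ".join(f"{v:.10g}" for v in model.pi) + "\n")
        for i in range(4):
            fh.write(
                f"Q{i}: " + " ".join(f"{v:.10g}" for v in model.Q[i]) + "\n"
            )
        fh.write(f"tree: {tree.to_newick()}\n")
        if rho is not None:
            fh.write(f"rho: {rho:.10g}\n")


def load_model(path: str) -> tuple[SubstitutionModel, PhyloTree, float | None]:
    data: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if ":" in line:
                k, v = line.split(":", 1)
                data[k.strip()] = v.strip()
    pi = np.array([float(x) for x in data["pi"].split()])
    Q = np.array(
        [[float(x) for x in data[f"Q{i}"].split()] for i in range(4)]
    )
    model = SubstitutionModel(Q=Q, pi=pi, family=data.get("family", "GTR"))
    tree = PhyloTree.from_newick(data["tree"])
    rho = float(data["rho"]) if "rho" in data else None
    return model, tree, rho
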