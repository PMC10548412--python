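"""Two-state phylogenetic HMM conservation scoring.

State 0 ("conserved") emits alignment columns under the neutral model with
every branch scaled by rho (0 < rho <= 1); state 1 ("neutral") emits under
scale 1.  The chain is tuned by target coverage gamma and expected element
length omega: mu = 1/omega, nu = gamma*mu/(1-gamma).  Discrete most-Cons
elements are maximal conserved-state runs of the Viterbi path; per-site
scores come from a likelihood-ratio test of a free branch-scale against
the neutral scale of 1.

HMM chains run along the reference: consecutive alignment blocks that are
adjacent on the reference (zero gap) share a chain; any gap breaks the
chain and the next one restarts at the stationary distribution, since
unaligned reference sequence carries no evidence either way.  Columns in
which the reference row is gapped occupy no reference position and are
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io_formats import AlignmentBlock, GeneModel, GenomicInterval
from .phylo import (
    MISSING,
    PhyloTree,
    SubstitutionModel,
    alignment_log_likelihoods,
    encode_base,
)

__all__ = [
    "PhyloHMM",
    "ConservedElement",
    "hmm_from_tuning",
    "posterior_conserved",
    "call_most_cons",
    "estimate_rho",
    "per_site_score",
    "class_score_fractions",
    "DEFAULT_CLASS_BINS",
]

_LLR_CLIP = 500.0


@dataclass
class PhyloHMM:
    """Tuned two-state phylo-HMM (parameters + emission models)."""

    gamma: float
    omega: float
    mu: float
    nu: float
    rho: float
    neutral_model: SubstitutionModel
    tree: PhyloTree

    def transition_matrix(self) -> np.ndarray:
        # state 0 = conserved, state 1 = neutral
        return np.array([[1 - self.mu, self.mu], [self.nu, 1 - self.nu]])

    def initial_distribution(self) -> np.ndarray:
        return np.array([self.gamma, 1 - self.gamma])


@dataclass(frozen=True)
class ConservedElement:
    """Maximal Viterbi conserved run mapped to reference coordinates."""

    interval: GenomicInterval
    score: float  # sum of per-column log-odds ln P(col|cons)/P(col|neut)
    mean_posterior: float


def hmm_from_tuning(
    gamma: float,
    omega: float,
    rho: float,
    neutral_model: SubstitutionModel,
    tree: PhyloTree,
) -> PhyloHMM:
    """Build the HMM from target coverage and expected element length."""
    if not (0.0 < gamma < 1.0):
        raise ValueError(f"gamma must be in (0,1), got {gamma}")
    if omega < 1:
        raise ValueError(f"omega must be >= 1, got {omega}")
    if not (0.0 < rho <= 1.0):
        raise ValueError(f"rho must be in (0,1], got {rho}")
    mu = 1.0 / omega
    nu = gamma * mu / (1.0 - gamma)
    return PhyloHMM(
        gamma=gamma, omega=omega, mu=mu, nu=nu, rho=rho,
        neutral_model=neutral_model, tree=tree,
    )


# ---------------------------------------------------------------------------
# chains and emissions
# ---------------------------------------------------------------------------


@dataclass
class Chain:
    """A maximal run of reference-adjacent alignment columns."""

    chrom: str
    positions: np.ndarray  # consecutive reference positions
    columns: np.ndarray    # (n, n_leaves) encoded bases, -1 missing


def build_chains(blocks: list[AlignmentBlock], species: list[str]) -> list[Chain]:
    """Split reference-sorted blocks into chains broken at reference gaps."""
    sp_index = {s: i for i, s in enumerate(species)}
    chains: list[Chain] = []
    cur_pos: list[int] = []
    cur_cols: list[list[int]] = []
    cur_chrom: str | None = None
    last_end: int | None = None

    def flush() -> None:
        nonlocal cur_pos, cur_cols
        if cur_pos:
            chains.append(
                Chain(
                    chrom=cur_chrom,
                    positions=np.asarray(cur_pos, dtype=np.int64),
                    columns=np.asarray(cur_cols, dtype=np.int64),
                )
            )
        cur_pos, cur_cols = [], []

    for block in blocks:
        iv = block.ref_interval
        if cur_chrom != iv.chrom or last_end != iv.start:
            flush()
            cur_chrom = iv.chrom
        last_end = iv.end
        ref_positions = block.ref_columns()
        encoded = np.full((block.width, len(species)), MISSING, dtype=np.int64)
        for sp, row in block.rows.items():
            if sp not in sp_index:
                continue
            j = sp_index[sp]
            encoded[:, j] = [encode_base(c) for c in row.text]
        for i in range(block.width):
            if ref_positions[i] < 0:
                continue  # insertion relative to the reference
            cur_pos.append(int(ref_positions[i]))
            cur_cols.append(encoded[i].tolist())
    flush()
    return chains


def _chain_llr(chains: list[Chain], hmm: PhyloHMM) -> list[np.ndarray]:
    """Per-position log-odds ln P(col|conserved) - ln P(col|neutral).

    Columns with fewer than two non-missing species are uninformative and
    get log-odds 0.  Patterns are deduplicated across chains.
    """
    if not chains:
        return []
    all_cols = np.concatenate([c.columns for c in chains], axis=0)
    uniq, inverse = np.unique(all_cols, axis=0, return_inverse=True)
    informative = (uniq >= 0).sum(axis=1) >= 2
    llr_uniq = np.zeros(len(uniq))
    if informative.any():
        sub = uniq[informative]
        ll_neut = alignment_log_likelihoods(hmm.tree, hmm.neutral_model, sub, 1.0)
        ll_cons = alignment_log_likelihoods(hmm.tree, hmm.neutral_model, sub, hmm.rho)
        llr_uniq[informative] = np.clip(ll_cons - ll_neut, -_LLR_CLIP, _LLR_CLIP)
    llr_all = llr_uniq[inverse]
    out, off = [], 0
    for c in chains:
        out.append(llr_all[off : off + len(c.positions)])
        off += len(c.positions)
    return out


# ---------------------------------------------------------------------------
# forward-backward / Viterbi
# ---------------------------------------------------------------------------


def _forward_backward(llr: np.ndarray, hmm: PhyloHMM) -> tuple[np.ndarray, float]:
    """Posterior P(conserved) per position and the chain's relative log-lik.

    Works on the emission *ratio* e = exp(llr) for the conserved state and
    1 for the neutral state; the returned log-likelihood omits the common
    neutral-emission term (constant in rho), which cancels everywhere it
    is used.
    """
    n = len(llr)
    if n == 0:
        return np.zeros(0), 0.0
    T = hmm.transition_matrix()
    init = hmm.initial_distribution()
    e = np.ones((n, 2))
    e[:, 0] = np.exp(llr)

    alpha = np.empty((n, 2))
    c = np.empty(n)
    a = init * e[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, n):
        a = (alpha[t - 1] @ T) * e[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]

    beta = np.empty((n, 2))
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        b = T @ (e[t + 1] * beta[t + 1])
        beta[t] = b / c[t + 1]

    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    return post[:, 0], float(np.log(c).sum())


def _viterbi(llr: np.ndarray, hmm: PhyloHMM) -> np.ndarray:
    """Most probable state path (0 conserved, 1 neutral); ties -> neutral."""
    n = len(llr)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    logT = np.log(hmm.transition_matrix())
    log_init = np.log(hmm.initial_distribution())
    loge = np.zeros((n, 2))
    loge[:, 0] = llr

    delta = np.empty((n, 2))
    back = np.zeros((n, 2), dtype=np.int64)
    delta[0] = log_init + loge[0]
    for t in range(1, n):
        for s in (0, 1):
            cand = delta[t - 1] + logT[:, s]
            # tie -> predecessor neutral (state 1)
            best = 1 if cand[1] >= cand[0] else 0
            back[t, s] = best
            delta[t, s] = cand[best] + loge[t, s]
    path = np.empty(n, dtype=np.int64)
    path[-1] = 1 if delta[-1, 1] >= delta[-1, 0] else 0
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def posterior_conserved(
    blocks: list[AlignmentBlock], hmm: PhyloHMM
) -> dict[str, dict[int, float]]:
    """Posterior P(state = conserved | data) per reference position."""
    chains = build_chains(blocks, hmm.tree.leaf_names)
    llrs = _chain_llr(chains, hmm)
    out: dict[str, dict[int, float]] = {}
    for chain, llr in zip(chains, llrs):
        post, _ = _forward_backward(llr, hmm)
        store = out.setdefault(chain.chrom, {})
        for pos, p in zip(chain.positions, post):
            store[int(pos)] = float(p)
    return out


def call_most_cons(
    blocks: list[AlignmentBlock], hmm: PhyloHMM
) -> list[ConservedElement]:
    """Discrete most-Cons elements: maximal Viterbi conserved-state runs."""
    chains = build_chains(blocks, hmm.tree.leaf_names)
    llrs = _chain_llr(chains, hmm)
    elements: list[ConservedElement] = []
    for chain, llr in zip(chains, llrs):
        path = _viterbi(llr, hmm)
        post, _ = _forward_backward(llr, hmm)
        i = 0
        n = len(path)
        while i < n:
            if path[i] != 0:
                i += 1
                continue
            j = i
            while j < n and path[j] == 0:
                j += 1
            start = int(chain.positions[i])
            end = int(chain.positions[j - 1]) + 1
            elements.append(
                ConservedElement(
                    interval=GenomicInterval(chain.chrom, start, end),
                    score=float(llr[i:j].sum()),
                    mean_posterior=float(post[i:j].mean()),
                )
            )
            i = j
    elements.sort(key=lambda e: (e.interval.chrom, e.interval.start))
    return elements


def total_log_likelihood(blocks: list[AlignmentBlock], hmm: PhyloHMM) -> float:
    """HMM log-likelihood up to the rho-independent neutral-emission term."""
    chains = build_chains(blocks, hmm.tree.leaf_names)
    llrs = _chain_llr(chains, hmm)
    return sum(_forward_backward(llr, hmm)[1] for llr in llrs)


def _emission_cache(
    blocks: list[AlignmentBlock],
    tree: PhyloTree,
    model: SubstitutionModel,
):
    """Chains + deduplicated column patterns + neutral log-likelihoods."""
    chains = build_chains(blocks, tree.leaf_names)
    if not chains:
        return chains, None, None, None
    all_cols = np.concatenate([c.columns for c in chains], axis=0)
    uniq, inverse = np.unique(all_cols, axis=0, return_inverse=True)
    informative = (uniq >= 0).sum(axis=1) >= 2
    ll_neut = np.zeros(len(uniq))
    if informative.any():
        ll_neut[informative] = alignment_log_likelihoods(
            tree, model, uniq[informative], 1.0
        )
    return chains, uniq, inverse, (informative, ll_neut)


def _batched_forward_loglik(
    chains: list[Chain],
    inverse: np.ndarray,
    llr_by_pattern: np.ndarray,  # (n_settings, n_patterns)
    mus: np.ndarray,
    nus: np.ndarray,
) -> np.ndarray:
    """Relative HMM log-likelihood for many (rho, gamma) settings at once."""
    K = llr_by_pattern.shape[0]
    T = np.empty((K, 2, 2))
    T[:, 0, 0] = 1 - mus
    T[:, 0, 1] = mus
    T[:, 1, 0] = nus
    T[:, 1, 1] = 1 - nus
    gammas = nus / (mus + nus)
    total = np.zeros(K)
    off = 0
    for chain in chains:
        n = len(chain.positions)
        e_cons = np.exp(llr_by_pattern[:, inverse[off : off + n]])  # (K, n)
        off += n
        a = np.empty((K, 2))
        a[:, 0] = gammas * e_cons[:, 0]
        a[:, 1] = 1 - gammas
        c = a.sum(axis=1)
        total += np.log(c)
        a /= c[:, None]
        for t in range(1, n):
            a = np.einsum("ki,kij->kj", a, T)
            a[:, 0] *= e_cons[:, t]
            c = a.sum(axis=1)
            total += np.log(c)
            a /= c[:, None]
    return total


def estimate_rho(
    blocks: list[AlignmentBlock],
    gamma: float,
    omega: float,
    neutral_model: SubstitutionModel,
    tree: PhyloTree,
    bounds: tuple[float, float] = (0.02, 1.0),
    grid_size: int = 15,
    estimate_gamma: bool = True,
) -> float:
    """ML estimate of the conserved branch scale rho.

    By default the state-mixing weight gamma is profiled out on a grid
    alongside rho (holding the expected element length omega fixed): with
    a badly mismatched gamma the rho estimate is biased toward the neutral
    scale, so joint profiling is what makes the estimate consistent when
    the true conserved coverage differs from the tuning target.
    Deterministic: grid scan + golden-section refinement of rho at the
    best gamma.
    """
    from scipy.optimize import minimize_scalar

    chains, uniq, inverse, neut = _emission_cache(blocks, tree, neutral_model)
    if uniq is None:
        raise ValueError("no alignment columns")
    informative, ll_neut = neut

    def llr_for(rhos: np.ndarray) -> np.ndarray:
        out = np.zeros((len(rhos), len(uniq)))
        sub = uniq[informative]
        for k, r in enumerate(rhos):
            ll_cons = alignment_log_likelihoods(tree, neutral_model, sub, float(r))
            out[k, informative] = np.clip(
                ll_cons - ll_neut[informative], -_LLR_CLIP, _LLR_CLIP
            )
        return out

    rho_grid = np.geomspace(bounds[0], bounds[1], grid_size)
    if estimate_gamma:
        gamma_grid = np.unique(np.concatenate([
            np.geomspace(0.003, 0.5, 8), [gamma]
        ]))
    else:
        gamma_grid = np.array([gamma])
    rhos = np.repeat(rho_grid, len(gamma_grid))
    gammas = np.tile(gamma_grid, len(rho_grid))
    mus = np.full_like(rhos, 1.0 / omega)
    nus = gammas * mus / (1.0 - gammas)
    llr_rho = llr_for(rho_grid)
    llr_all = np.repeat(llr_rho, len(gamma_grid), axis=0)
    ll = _batched_forward_loglik(chains, inverse, llr_all, mus, nus)
    best = int(np.argmax(ll))
    best_gamma = float(gammas[best])
    k_rho = best // len(gamma_grid)
    lo = rho_grid[max(0, k_rho - 1)]
    hi = rho_grid[min(len(rho_grid) - 1, k_rho + 1)]
    mu = 1.0 / omega
    nu = best_gamma * mu / (1.0 - best_gamma)

    def nll(rho: float) -> float:
        llr = llr_for(np.array([rho]))
        return -float(
            _batched_forward_loglik(
                chains, inverse, llr, np.array([mu]), np.array([nu])
            )[0]
        )

    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-3})
    return float(res.x)


# ---------------------------------------------------------------------------
# per-site conservation scores
# ---------------------------------------------------------------------------


def per_site_score(
    blocks: list[AlignmentBlock],
    tree: PhyloTree,
    neutral_model: SubstitutionModel,
    scale_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Signed per-site conservation scores from a branch-scale LRT.

    For each column the branch scale s is profiled over a fixed log-spaced
    grid; the statistic 2*(l(s_hat) - l(1)) is referred to the one-sided
    boundary null (a 1/2 chi2_1 mixture).  Score = -log10 p, positive when
    s_hat < 1 (conservation), negative when s_hat > 1 (acceleration), and
    exactly 0 when the MLE sits at the neutral scale.  Columns with fewer
    than two non-missing species score 0.

    Returns a DataFrame with columns chrom, pos, score.
    """
    if scale_grid is None:
        scale_grid = np.unique(np.concatenate([
            np.geomspace(1e-3, 10.0, 81), [1.0]
        ]))
    chains = build_chains(blocks, tree.leaf_names)
    if not chains:
        return pd.DataFrame(columns=["chrom", "pos", "score"])
    all_cols = np.concatenate([c.columns for c in chains], axis=0)
    uniq, inverse = np.unique(all_cols, axis=0, return_inverse=True)
    informative = (uniq >= 0).sum(axis=1) >= 2

    scores_uniq = np.zeros(len(uniq))
    if informative.any():
        sub = uniq[informative]
        ll = np.stack(
            [alignment_log_likelihoods(tree, neutral_model, sub, s) for s in scale_grid],
            axis=0,
        )  # (n_scales, n_patterns)
        idx1 = int(np.where(np.isclose(scale_grid, 1.0))[0][0])
        best = ll.max(axis=0)
        best_idx = ll.argmax(axis=0)
        stat = np.maximum(0.0, 2.0 * (best - ll[idx1]))
        pvals = 0.5 * chi2.sf(stat, df=1)
        sign = np.where(scale_grid[best_idx] < 1.0, 1.0, -1.0)
        # conserved positive, accelerated negative, MLE at the boundary -> 0
        s = np.where(stat < 1e-12, 0.0, sign * -np.log10(np.maximum(pvals, 1e-300)))
        scores_uniq[informative] = s

    per_col = scores_uniq[inverse]
    rows = []
    off = 0
    for c in chains:
        for pos, sc in zip(c.positions, per_col[off : off + len(c.positions)]):
            rows.append((c.chrom, int(pos), float(sc)))
        off += len(c.positions)
    return pd.DataFrame(rows, columns=["chrom", "pos", "score"])


# ---------------------------------------------------------------------------
# region-class score fractions
# ---------------------------------------------------------------------------

# (name, side, lo, hi): distance bins measured from the start codon
# (upstream, negative side) and stop codon (downstream); gene-structure
# classes carry side None.
DEFAULT_CLASS_BINS: list[tuple[str, int, int]] = [
    ("upstream[-5000,-2000)", -5000, -2000),
    ("upstream[-2000,-1000)", -2000, -1000),
    ("upstream[-1000,-500)", -1000, -500),
    ("upstream[-500,-100)", -500, -100),
    ("upstream[-100,0)", -100, 0),
    ("downstream[0,100)", 0, 100),
    ("downstream[100,500)", 100, 500),
    ("downstream[500,1000)", 500, 1000),
    ("downstream[1000,2000)", 1000, 2000),
    ("downstream[2000,5000)", 2000, 5000),
]
STRUCT_CLASSES = ["CDS", "intron", "5'UTR", "3'UTR"]


def _gene_codon_edges(gene: GeneModel) -> tuple[int, int]:
    """(start-codon position, stop-codon position) on the forward strand."""
    if gene.cds:
        lo = min(iv.start for iv in gene.cds)
        hi = max(iv.end for iv in gene.cds)
    else:
        lo, hi = gene.interval.start, gene.interval.end
    return (lo, hi) if gene.strand == "+" else (hi, lo)


def class_score_fractions(
    site_scores: pd.DataFrame,
    genes: list[GeneModel],
    class_bins: list[tuple[str, int, int]] | None = None,
    top_percents: tuple[int, ...] = (10, 20, 30, 40, 50, 60),
) -> pd.DataFrame:
    """Fraction of each region class's sites in the global top score tiers.

    Thresholds are global score quantiles; gene-structure classes (CDS,
    intron, UTRs) are assigned per site with CDS > UTR > intron priority;
    flanking-distance bins are keyed to the start codon (upstream) and
    stop codon (downstream) of each gene and exclude any position that
    overlaps a gene body.  An empty class yields NaN, not 0.
    """
    if class_bins is None:
        class_bins = DEFAULT_CLASS_BINS
    scores = site_scores["score"].to_numpy(float)
    if len(scores) == 0:
        raise ValueError("no site scores supplied")
    thresholds = {p: float(np.percentile(scores, 100 - p)) for p in top_percents}

    score_at: dict[str, dict[int, float]] = {}
    for chrom, sub in site_scores.groupby("chrom"):
        score_at[str(chrom)] = dict(
            zip(sub["pos"].astype(int), sub["score"].astype(float))
        )

    gene_body: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        gene_body.setdefault(g.interval.chrom, []).append(
            (g.interval.start, g.interval.end)
        )

    def in_gene_body(chrom: str, pos: int) -> bool:
        return any(s <= pos < e for s, e in gene_body.get(chrom, ()))

    members: dict[str, list[float]] = {
        name: [] for name in STRUCT_CLASSES + [b[0] for b in class_bins]
    }

    # gene-structure classes
    for g in genes:
        chrom = g.interval.chrom
        at = score_at.get(chrom, {})
        claimed: dict[int, str] = {}
        for iv in g.cds:
            for p in range(iv.start, iv.end):
                claimed[p] = "CDS"
        for iv in g.utr5:
            for p in range(iv.start, iv.end):
                claimed.setdefault(p, "5'UTR")
        for iv in g.utr3:
            for p in range(iv.start, iv.end):
                claimed.setdefault(p, "3'UTR")
        for iv in g.introns:
            for p in range(iv.start, iv.end):
                claimed.setdefault(p, "intron")
        for p, cls in claimed.items():
            if p in at:
                members[cls].append(at[p])

    # flanking bins, gene-body overlaps removed
    for g in genes:
        chrom = g.interval.chrom
        at = score_at.get(chrom, {})
        start_codon, stop_codon = _gene_codon_edges(g)
        sign = 1 if g.strand == "+" else -1
        for name, lo, hi in class_bins:
            anchor = start_codon if lo < 0 else stop_codon
            for d in range(lo, hi):
                pos = anchor + sign * d
                if pos in at and not in_gene_body(chrom, pos):
                    members[name].append(at[pos])

    rows = []
    for name, vals in members.items():
        row: dict[str, float] = {"class": name, "n_sites": len(vals)}
        arr = np.asarray(vals, dtype=float)
        for p in top_percents:
            row[f"top{p}"] = (
                float(np.mean(arr >= thresholds[p])) if len(arr) else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("class")
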