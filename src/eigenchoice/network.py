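"""Signed weighted co-expression network construction and module detection.

Pipeline: robust pairwise correlation (biweight midcorrelation) ->
signed soft-threshold adjacency ``((1 + cor) / 2) ** power`` -> topological
overlap similarity -> average-linkage clustering of ``1 - TOM`` with a
dynamic-hybrid-style branch cut -> module eigengenes (first PC of each
module's standardized expression) -> merging of modules with similar
eigengenes.

Everything in this module is deterministic; no random number generator is
used anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .datatypes import (
    EigengeneMatrix,
    ExpressionMatrix,
    ModuleAssignment,
    UNASSIGNED,
)
from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

#: WGCNA-style cosmetic aliases for size-ranked module labels.
COLOR_ALIASES = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
)


@dataclass
class NetworkParams:
    """Network-construction parameters (defaults follow the analysis contract)."""

    power: float = 9.0
    network_type: str = "signed"
    cor_type: str = "bicor"
    max_p_outliers: float = 0.05
    min_module_size: int = 30
    merge_cut_height: float = 0.25
    deep_split: int = 2
    detect_cut_height: float = 0.995
    max_block_size: int = 30000

    def __post_init__(self) -> None:
        if self.power <= 0:
            raise ConfigurationError("power", "must be positive")
        if self.network_type != "signed":
            raise ConfigurationError("network_type", "only 'signed' is supported")
        if self.cor_type not in ("bicor", "pearson"):
            raise ConfigurationError("cor_type", "must be 'bicor' or 'pearson'")
        if not (0 < self.max_p_outliers <= 0.5):
            raise ConfigurationError("max_p_outliers", "must lie in (0, 0.5]")
        if self.min_module_size < 1:
            raise ConfigurationError("min_module_size", "must be >= 1")
        if not (0 < self.merge_cut_height <= 1):
            raise ConfigurationError("merge_cut_height", "must lie in (0, 1]")
        if self.deep_split not in (0, 1, 2, 3, 4):
            raise ConfigurationError("deep_split", "must be an integer in 0..4")
        if not (0 < self.detect_cut_height <= 1):
            raise ConfigurationError("detect_cut_height", "must lie in (0, 1]")
        if self.max_block_size < 1:
            raise ConfigurationError("max_block_size", "must be >= 1")


# ---------------------------------------------------------------------------
# biweight midcorrelation
# ---------------------------------------------------------------------------

def _bicor_normalize(X: np.ndarray, max_p_outliers: float) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise robust normalization for biweight midcorrelation.

    Each row ``x`` is median-centred and weighted by ``(1 - u^2)^2`` for
    ``|u| < 1`` with ``u = (x - med) / (9 * MAD)``.  Before weighting, each
    side of ``u`` is rescaled so at most ``max_p_outliers`` of the points
    per side fall at or beyond ``|u| = 1`` (zero weight).  Rows with zero
    MAD fall back to mean-centred Pearson vectors.

    Returns the unit-norm weighted centred rows and a boolean mask of rows
    that used the Pearson fallback.
    """
    X = np.asarray(X, dtype=float)
    med = np.median(X, axis=1, keepdims=True)
    dev = X - med
    mad = np.median(np.abs(dev), axis=1, keepdims=True)
    fallback = (mad[:, 0] == 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        u = dev / (9.0 * mad)
    u[fallback] = 0.0

    # side-wise rescaling: cap u so at most max_p_outliers per side get
    # zero weight
    lo = np.quantile(u, max_p_outliers, axis=1, keepdims=True)
    hi = np.quantile(u, 1.0 - max_p_outliers, axis=1, keepdims=True)
    neg_scale = np.maximum(1.0, -lo)
    pos_scale = np.maximum(1.0, hi)
    u = np.where(u < 0, u / neg_scale, u / pos_scale)

    w = np.square(1.0 - np.square(u)) * (np.abs(u) < 1.0)
    vec = dev * w
    if fallback.any():
        mean_centred = X[fallback] - X[fallback].mean(axis=1, keepdims=True)
        vec[fallback] = mean_centred
    norms = np.linalg.norm(vec, axis=1, keepdims=True)
    if (norms[:, 0] == 0).any():
        bad = np.where(norms[:, 0] == 0)[0]
        raise DataError(f"constant vector(s) at row index {bad.tolist()[:5]}")
    return vec / norms, fallback


def bicor(x, y, max_p_outliers: float = 0.05) -> float:
    """Biweight midcorrelation of two vectors, in [-1, 1].

    Falls back to Pearson (with a logged warning) for a vector whose median
    absolute deviation is zero.  Raises for constant vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise DataError("bicor requires two equal-length vectors of length >= 3")
    if np.ptp(x) == 0:
        raise DataError("constant vector: x")
    if np.ptp(y) == 0:
        raise DataError("constant vector: y")
    vecs, fallback = _bicor_normalize(np.vstack([x, y]), max_p_outliers)
    if fallback.any():
        which = [name for name, f in zip("xy", fallback) if f]
        logger.warning("MAD is zero for %s; falling back to Pearson", which)
    return float(np.clip(vecs[0] @ vecs[1], -1.0, 1.0))


def correlation_matrix(
    expr: ExpressionMatrix, params: NetworkParams
) -> pd.DataFrame:
    """Gene x gene correlation across samples (bicor or Pearson).

    Constant genes are dropped with a warning and recorded in
    ``result.attrs['dropped_genes']``.  Gene blocks of at most
    ``max_block_size`` bound the working-set size; results are block-size
    invariant.
    """
    X = expr.data.to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise DataError("correlation requires at least 3 samples")
    keep = np.ptp(X, axis=1) > 0
    dropped = [g for g, k in zip(expr.gene_ids, keep) if not k]
    if dropped:
        logger.warning("dropping %d constant gene(s)", len(dropped))
        X = X[keep]
    genes = [g for g, k in zip(expr.gene_ids, keep) if k]

    if params.cor_type == "bicor":
        vecs, fallback = _bicor_normalize(X, params.max_p_outliers)
        if fallback.any():
            logger.warning(
                "%d gene(s) with zero MAD fell back to Pearson", int(fallback.sum())
            )
    else:
        centred = X - X.mean(axis=1, keepdims=True)
        vecs = centred / np.linalg.norm(centred, axis=1, keepdims=True)

    n = len(genes)
    cor = np.empty((n, n))
    block = max(1, int(params.max_block_size))
    for i in range(0, n, block):
        cor[i:i + block] = vecs[i:i + block] @ vecs.T
    np.clip(cor, -1.0, 1.0, out=cor)
    cor = (cor + cor.T) / 2.0
    np.fill_diagonal(cor, 1.0)
    out = pd.DataFrame(cor, index=genes, columns=genes)
    out.attrs["dropped_genes"] = dropped
    return out


# ---------------------------------------------------------------------------
# adjacency and topological overlap
# ---------------------------------------------------------------------------

def signed_adjacency(cor: pd.DataFrame | np.ndarray, power: float) -> pd.DataFrame | np.ndarray:
    """Signed soft-threshold adjacency ``((1 + cor) / 2) ** power``."""
    values = cor.to_numpy() if isinstance(cor, pd.DataFrame) else np.asarray(cor, dtype=float)
    if values.size and (values.min() < -1 - 1e-9 or values.max() > 1 + 1e-9):
        raise DataError("correlation entries must lie in [-1, 1]")
    adj = np.power((1.0 + np.clip(values, -1.0, 1.0)) / 2.0, power)
    np.fill_diagonal(adj, 1.0)
    if isinstance(cor, pd.DataFrame):
        return pd.DataFrame(adj, index=cor.index, columns=cor.columns)
    return adj


def tom_similarity(adj: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap similarity of a symmetric adjacency in [0, 1].

    ``TOM_ij = (sum_{k != i,j} a_ik a_kj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``
    with connectivity ``k_i = sum_{k != i} a_ik``; diagonal set to 1.
    """
    A = adj.to_numpy() if isinstance(adj, pd.DataFrame) else np.asarray(adj, dtype=float)
    if A.shape[0] != A.shape[1]:
        raise DataError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise DataError("adjacency must be symmetric")
    if A.size and (A.min() < -1e-12 or A.max() > 1 + 1e-12):
        raise DataError("adjacency entries must lie in [0, 1]")
    A = np.clip(A, 0.0, 1.0)
    off = A.copy()
    np.fill_diagonal(off, 0.0)
    k = off.sum(axis=1)
    shared = off @ off  # includes k == i and k == j terms only via zeros on diag
    numer = shared + off
    denom = np.minimum.outer(k, k) + 1.0 - off
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = np.where(denom > 0, numer / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    if isinstance(adj, pd.DataFrame):
        return pd.DataFrame(tom, index=adj.index, columns=adj.columns)
    return tom


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------

#: Relative cut quantile per deep-split level: higher sensitivity cuts
#: branches lower, producing more and smaller modules.  The constants are
#: implementation-defined (the published procedure leaves them open).
_DEEP_SPLIT_Q = (0.95, 0.90, 0.85, 0.75, 0.65)


def _maximal_subnodes(node, height: float) -> list:
    """Maximal subtrees whose root merge height is <= ``height``."""
    out, stack = [], [node]
    while stack:
        nd = stack.pop()
        if nd.is_leaf() or nd.dist <= height:
            out.append(nd)
        else:
            stack.extend((nd.get_left(), nd.get_right()))
    return out


def _min_merge_height(node) -> float:
    best, stack = np.inf, [node]
    while stack:
        nd = stack.pop()
        if not nd.is_leaf():
            best = min(best, nd.dist)
            stack.extend((nd.get_left(), nd.get_right()))
    return 0.0 if not np.isfinite(best) else best


def detect_modules(
    tom: pd.DataFrame, params: NetworkParams
) -> ModuleAssignment:
    """Cut the average-linkage dendrogram of ``1 - TOM`` into modules.

    A dynamic-hybrid-style procedure: merges above ``detect_cut_height``
    are never part of a module, giving coarse branches; within each coarse
    branch the tree is re-cut at an adaptive height
    ``h_lo + q * (h_branch - h_lo)`` (``h_lo`` = lowest merge in the
    branch, ``q`` set by ``deep_split``), so that tight sub-branches
    separate from the noise plateau near the branch root regardless of the
    absolute dissimilarity scale.  Each level of ``deep_split`` refines the
    previous level's modules and a module is only replaced when refinement
    yields at least one piece of ``min_module_size`` — module count is
    therefore non-decreasing in ``deep_split``.  Genes in no accepted
    module are left unassigned.  Final labels are size-ranked ("M1", ...).
    """
    genes = list(tom.index)
    n = len(genes)
    if n < params.min_module_size:
        logger.warning(
            "fewer genes (%d) than min_module_size (%d); nothing assigned",
            n, params.min_module_size,
        )
        return ModuleAssignment(
            pd.Series(UNASSIGNED, index=genes, dtype=str), labels=[UNASSIGNED]
        )
    dissim = 1.0 - tom.to_numpy()
    np.fill_diagonal(dissim, 0.0)
    Z = linkage(squareform(dissim, checks=False), method="average")
    root = to_tree(Z)
    min_size = params.min_module_size

    module_nodes: list = []
    for branch in _maximal_subnodes(root, params.detect_cut_height):
        if branch.get_count() < min_size:
            continue
        h_lo = _min_merge_height(branch)
        span = max(branch.dist - h_lo, 0.0)

        def level_nodes(parent, level: int) -> list:
            h_ref = h_lo + _DEEP_SPLIT_Q[level] * span
            return [
                nd for nd in _maximal_subnodes(parent, h_ref)
                if nd.get_count() >= min_size
            ]

        current = level_nodes(branch, 0) or (
            [branch] if branch.get_count() >= min_size else []
        )
        for level in range(1, params.deep_split + 1):
            refined = []
            for nd in current:
                pieces = level_nodes(nd, level)
                refined.extend(pieces if pieces else [nd])
            current = refined
        module_nodes.extend(current)

    modules = sorted(
        ([i for i in nd.pre_order()] for nd in module_nodes),
        key=lambda c: (-len(c), min(c)),
    )
    labels = pd.Series(UNASSIGNED, index=genes, dtype=str)
    names = []
    for rank, members in enumerate(modules, start=1):
        name = f"M{rank}"
        names.append(name)
        labels.iloc[members] = name
    return ModuleAssignment(labels, labels=names + [UNASSIGNED])


def color_alias_table(modules: ModuleAssignment) -> dict[str, str]:
    """Optional WGCNA-convention colour names for size-ranked labels."""
    table = {}
    for i, lab in enumerate(modules.module_labels):
        table[lab] = COLOR_ALIASES[i] if i < len(COLOR_ALIASES) else lab
    table[UNASSIGNED] = "grey"
    return table


# ---------------------------------------------------------------------------
# eigengenes
# ---------------------------------------------------------------------------

def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def module_eigengenes(
    expr: ExpressionMatrix, modules: ModuleAssignment
) -> EigengeneMatrix:
    """First principal component of each module's standardized expression.

    The eigengene is the first left singular vector of the samples x genes
    submatrix (genes standardized to mean 0, SD 1), oriented so its mean
    correlation with the module's genes is positive.  ``variance_explained``
    is the first-eigenvalue share.
    """
    if len(expr.sample_ids) < 2:
        raise DataError("eigengenes require at least 2 samples")
    cols = {}
    ve = {}
    for label in modules.module_labels:
        genes = [g for g in modules.genes_in(label) if g in expr.data.index]
        if not genes:
            raise DataError(f"module '{label}' has no genes in the expression matrix")
        sub = _standardize_rows(expr.data.loc[genes].to_numpy(dtype=float))
        if len(genes) == 1:
            logger.info("module '%s' has a single gene; eigengene = that gene", label)
            cols[label] = sub[0]
            ve[label] = 1.0
            continue
        U, S, _ = np.linalg.svd(sub.T, full_matrices=False)  # samples x genes
        eig = U[:, 0]
        # orient: mean correlation with member genes positive
        corr_sign = np.sign((sub @ eig).sum())
        if corr_sign < 0:
            eig = -eig
        cols[label] = eig
        total = float((S**2).sum())
        ve[label] = float(S[0] ** 2 / total) if total > 0 else 0.0
    data = pd.DataFrame(cols, index=expr.sample_ids)
    return EigengeneMatrix(data, variance_explained=pd.Series(ve, dtype=float))


def merge_close_modules(
    expr: ExpressionMatrix,
    modules: ModuleAssignment,
    eigengenes: EigengeneMatrix,
    merge_cut_height: float = 0.25,
) -> tuple[ModuleAssignment, EigengeneMatrix]:
    """Iteratively merge module pairs with eigengene dissimilarity below cut.

    Dissimilarity is ``1 - cor(E_a, E_b)``; the closest qualifying pair is
    merged first, eigengenes are recomputed, and the procedure repeats until
    no pair qualifies.  Unassigned genes never participate.  Final labels
    are re-ranked by size.
    """
    labels = modules.module_of_gene.copy()

    def current_modules() -> ModuleAssignment:
        return ModuleAssignment(labels.copy())

    eg = eigengenes
    while True:
        names = eg.module_labels
        if len(names) < 2:
            break
        E = eg.data[names].to_numpy()
        C = np.corrcoef(E.T)
        dissim = 1.0 - C
        np.fill_diagonal(dissim, np.inf)
        i, j = np.unravel_index(np.argmin(dissim), dissim.shape)
        if dissim[i, j] >= merge_cut_height:
            break
        a, b = names[i], names[j]
        logger.info("merging modules %s and %s (dissimilarity %.4f)", b, a, dissim[i, j])
        labels[labels == b] = a
        eg = module_eigengenes(expr, current_modules())

    # re-rank labels by size for stable, size-ordered naming
    sizes = labels[labels != UNASSIGNED].value_counts()
    order = sorted(sizes.index, key=lambda lab: (-sizes[lab], lab))
    rename = {old: f"M{rank}" for rank, old in enumerate(order, start=1)}
    final = labels.map(lambda lab: rename.get(lab, UNASSIGNED))
    merged = ModuleAssignment(final, labels=[rename[o] for o in order] + [UNASSIGNED])
    eg = module_eigengenes(expr, merged) if merged.module_labels else EigengeneMatrix(
        pd.DataFrame(index=expr.sample_ids), variance_explained=pd.Series(dtype=float)
    )
    return merged, eg


def build_network(
    expr: ExpressionMatrix, params: NetworkParams
) -> tuple[ModuleAssignment, EigengeneMatrix, dict]:
    """Full network stage: correlation -> adjacency -> TOM -> modules -> MEs."""
    cor = correlation_matrix(expr, params)
    adj = signed_adjacency(cor, params.power)
    tom = tom_similarity(adj)
    modules = detect_modules(tom, params)
    if not modules.module_labels:
        summary = {
            "n_genes": len(expr.gene_ids),
            "dropped_genes": cor.attrs.get("dropped_genes", []),
            "module_sizes": {},
            "variance_explained": {},
        }
        empty = EigengeneMatrix(
            pd.DataFrame(index=expr.sample_ids), variance_explained=pd.Series(dtype=float)
        )
        return modules, empty, summary
    eigengenes = module_eigengenes(expr, modules)
    modules, eigengenes = merge_close_modules(
        expr, modules, eigengenes, params.merge_cut_height
    )
    summary = {
        "n_genes": len(expr.gene_ids),
        "dropped_genes": cor.attrs.get("dropped_genes", []),
        "module_sizes": {k: int(v) for k, v in modules.sizes().items()},
        "variance_explained": {
            k: float(v) for k, v in eigengenes.variance_explained.items()
        },
        "color_aliases": color_alias_table(modules),
    }
    return modules, eigengenes, summary
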