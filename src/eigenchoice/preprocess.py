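"""Normalization, variance stabilization, gene filtering, PCA and sample QC.

The variance-stabilizing transform here is ``log2(count / size_factor +
pseudocount)`` — a deliberately simple stand-in for shrinkage-based
regularized-log transforms; downstream contracts depend only on its
stabilization *properties*, which are covered by tests.
"""

from __future__ import annotations

import logging
import numpy as np
import pandas as pd

from .datatypes import (
    CountMatrix,
    ExpressionMatrix,
    PCAResult,
    qc_flags_as_sets,
    validate_samples,
)
from .errors import DataError

logger = logging.getLogger(__name__)

SWAP_FLAG = "suspected_swap"
LOW_MAPPING_FLAG = "low_mapping"


def estimate_size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference profile is the gene-wise geometric mean over samples,
    computed on genes with all-positive counts; each sample's factor is the
    median ratio of its counts to that reference.
    """
    values = counts.data.to_numpy(dtype=float)
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        raise DataError(
            "no gene has positive counts in every sample; size factors are "
            "undefined (consider a pseudo-reference fallback on filtered data)"
        )
    pos = values[all_positive]
    log_geo_mean = np.log(pos).mean(axis=1)
    ratios = np.log(pos) - log_geo_mean[:, None]
    log_factors = np.median(ratios, axis=0)
    log_factors -= log_factors.mean()  # geometric mean 1
    return pd.Series(np.exp(log_factors), index=counts.sample_ids, name="size_factor")


def vst(
    counts: CountMatrix,
    size_factors: pd.Series,
    pseudocount: float = 1.0,
) -> ExpressionMatrix:
    """``log2(count / size_factor + pseudocount)``, per gene monotone."""
    if len(size_factors) != len(counts.sample_ids):
        raise DataError("one size factor per sample is required")
    sf = size_factors.reindex(counts.sample_ids)
    if sf.isna().any():
        raise DataError("size factors missing for some samples")
    if (sf <= 0).any():
        raise DataError("size factors must be positive")
    if pseudocount <= 0:
        raise DataError("pseudocount must be positive")
    normalized = counts.data.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    data = pd.DataFrame(
        np.log2(normalized + pseudocount),
        index=counts.gene_ids,
        columns=counts.sample_ids,
    )
    return ExpressionMatrix(data, transform_tag=f"log2(count/sf + {pseudocount:g})")


def filter_top_variable(expr: ExpressionMatrix, fraction: float) -> ExpressionMatrix:
    """Keep the ``ceil(fraction * G)`` genes with the largest variance.

    Ties are broken by gene id (variance descending, id ascending) and the
    original row order of retained genes is preserved, so the operation is
    deterministic and idempotent at a fixed fraction.
    """
    if not (0 < fraction <= 1):
        raise DataError("fraction must lie in (0, 1]")
    n_keep = int(np.ceil(fraction * len(expr.gene_ids)))
    variances = expr.data.var(axis=1, ddof=1)
    order = sorted(expr.gene_ids, key=lambda g: (-variances[g], g))
    keep = set(order[:n_keep])
    kept = [g for g in expr.gene_ids if g in keep]
    return ExpressionMatrix(expr.data.loc[kept], transform_tag=expr.transform_tag)


def pca_samples(expr: ExpressionMatrix, n_components: int) -> PCAResult:
    """Sample-space PCA of gene-centred (not scaled) expression.

    Scores are ``U * S`` of the SVD of the centred samples x genes matrix;
    the sign convention makes each loading vector's largest-magnitude
    element positive.  ``variance_explained`` is relative to the total
    variance, so it sums to 1 over the full rank.
    """
    X = expr.data.to_numpy(dtype=float).T  # samples x genes
    n_samples, n_genes = X.shape
    if n_samples < 2:
        raise DataError("PCA requires at least two samples")
    max_rank = min(n_samples, n_genes)
    if not (1 <= n_components <= max_rank):
        raise DataError(f"n_components must lie in [1, {max_rank}]")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((S**2).sum())
    k = n_components
    signs = np.ones(k)
    for j in range(k):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            signs[j] = -1.0
    scores = (U[:, :k] * S[:k]) * signs
    loadings = Vt[:k].T * signs
    comp_names = [f"PC{j + 1}" for j in range(k)]
    ve = (S[:k] ** 2) / total if total > 0 else np.zeros(k)
    return PCAResult(
        scores=pd.DataFrame(scores, index=expr.sample_ids, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=expr.gene_ids, columns=comp_names),
        variance_explained=ve,
    )


def flag_qc_samples(
    pca: PCAResult,
    samples: pd.DataFrame,
    swap_margin: float = 2.0,
    n_lowest_mapping: int = 2,
    n_pcs: int = 2,
) -> pd.DataFrame:
    """Annotate (never delete) samples failing quality-control heuristics.

    ``suspected_swap``
        the sample's Mahalanobis distance to its own population centroid in
        PC space exceeds ``swap_margin`` times its distance to some other
        population's centroid (pooled within-population covariance), and is
        more than 2 pooled SD in absolute terms.  Disabled with a warning
        when any population has fewer than 3 samples.
    ``low_mapping``
        the ``n_lowest_mapping`` samples with the lowest
        ``read_mapping_pct`` (stable tie-break by sample id), when that
        column exists.
    """
    samples = validate_samples(samples).copy()
    flags = qc_flags_as_sets(samples)
    meta = samples.set_index("sample_id")
    scores = pca.scores

    pops = meta.loc[scores.index, "population"]
    pop_counts = pops.value_counts()
    if (pop_counts < 3).any():
        logger.warning(
            "swap detection disabled: populations with <3 samples: %s",
            sorted(pop_counts.index[pop_counts < 3]),
        )
    else:
        k = min(n_pcs, scores.shape[1])
        X = scores.to_numpy()[:, :k]
        centroids = {p: X[(pops == p).to_numpy()].mean(axis=0) for p in pop_counts.index}
        pooled = np.zeros((k, k))
        for p in pop_counts.index:
            sub = X[(pops == p).to_numpy()] - centroids[p]
            pooled += sub.T @ sub
        pooled /= max(len(X) - len(pop_counts), 1)
        pooled += np.eye(k) * (1e-8 * max(np.trace(pooled), 1e-12))
        inv = np.linalg.inv(pooled)

        def mahal(x: np.ndarray, c: np.ndarray) -> float:
            d = x - c
            return float(np.sqrt(d @ inv @ d))

        for i, sid in enumerate(scores.index):
            own = str(pops.iloc[i])
            d_own = mahal(X[i], centroids[own])
            d_other = min(
                mahal(X[i], centroids[p]) for p in pop_counts.index if p != own
            )
            # absolute gate: a sample within ~2 pooled SD of its own centroid
            # is never a swap candidate, whatever the ratio — guards against
            # spurious flags when populations overlap in PC space
            if d_own > swap_margin * d_other and d_own > 2.0:
                row = samples.index[samples["sample_id"] == sid][0]
                flags.loc[row] = flags.loc[row] | {SWAP_FLAG}
                logger.warning("sample %s flagged %s", sid, SWAP_FLAG)

    if "read_mapping_pct" in samples.columns and n_lowest_mapping > 0:
        order = samples.sort_values(
            ["read_mapping_pct", "sample_id"], kind="stable"
        ).index[:n_lowest_mapping]
        ties = samples["read_mapping_pct"].nunique() < len(samples)
        if ties:
            logger.info("read_mapping_pct ties broken by sample_id order")
        for row in order:
            flags.loc[row] = flags.loc[row] | {LOW_MAPPING_FLAG}

    samples["qc_flags"] = flags
    return samples


def passing_samples(samples: pd.DataFrame) -> list[str]:
    """Sample ids with an empty QC flag set."""
    flags = qc_flags_as_sets(samples)
    return [
        sid for sid, fl in zip(samples["sample_id"], flags) if not fl
    ]


def drop_flagged(expr: ExpressionMatrix, samples: pd.DataFrame) -> ExpressionMatrix:
    """Expression restricted to samples with no QC flags."""
    keep = [s for s in expr.sample_ids if s in set(passing_samples(samples))]
    return ExpressionMatrix(expr.data[keep], transform_tag=expr.transform_tag)
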