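"""Permutation-based empirical false discovery rates for model terms.

For each response (eigengene or gene) and each ANOVA term, the observed
parametric p-value is compared against the p-values obtained after
shuffling the sample assignment of the response matrix: response rows are
reindexed by each of ``n_perm`` random permutations (the *same* permutation
sequence for every response, preserving inter-response correlation), the
models are refit, and::

    efdr = #{b : p_b <= p_obs} / n_perm

With the fixed design, degrees of freedom do not change across shuffles, so
the comparison is carried out on the F scale (``p_b <= p_obs`` iff
``F_b >= F_obs``), which avoids millions of distribution-function calls.

Two documented switches:

``plus_one``
    report ``(#{p_b <= p_obs} + 1) / (n_perm + 1)`` instead, so the
    smallest attainable value is ``1 / (n_perm + 1)`` rather than 0.
``direction="literal"``
    the literal reading of the procedure's published description — the
    proportion of shuffles whose p-value is *at least* the observed one —
    kept only for documentation; it is inverted relative to standard
    permutation practice and is not used for inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import validate_samples
from .errors import ConfigurationError, DataError
from .models import TERMS, _design_matrix

logger = logging.getLogger(__name__)


@dataclass
class PermutationConfig:
    """Settings of the permutation procedure."""

    n_perm: int = 10000
    seed: int = 0
    scope: str = "per_response"
    plus_one: bool = False
    direction: str = "standard"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ConfigurationError("n_perm", "must be >= 1")
        if self.scope not in ("per_response", "pooled"):
            raise ConfigurationError("scope", "must be 'per_response' or 'pooled'")
        if self.direction not in ("standard", "literal"):
            raise ConfigurationError("direction", "must be 'standard' or 'literal'")


def permutation_plan(n_samples: int, config: PermutationConfig) -> np.ndarray:
    """``n_perm`` independent uniform permutations of ``0..n_samples-1``.

    Drawn from a generator seeded with ``config.seed`` so the plan is
    reproducible; design columns are never permuted, only response rows.
    """
    if n_samples < 3:
        raise DataError("permutation requires at least 3 samples")
    rng = np.random.default_rng(config.seed)
    return np.array([rng.permutation(n_samples) for _ in range(config.n_perm)])


class _TermFEngine:
    """Vectorized type-II F statistics for a fixed interaction design.

    Precomputes orthonormal bases (QR) of the full, additive and
    single-main-effect design matrices; for a response matrix ``Y``
    (samples x responses) the residual sums of squares of every nested
    model are obtained from ``||Y||^2 - ||Q^T Y||^2``.
    """

    def __init__(self, populations: np.ndarray, trait: np.ndarray):
        self.n = len(populations)
        self.n_levels = len(np.unique(populations))
        if self.n_levels < 2:
            raise DataError("at least 2 populations required")
        self.q = {}
        for key in ("full", "additive", "population", "trait"):
            X = _design_matrix(populations, trait, key)
            q, r = np.linalg.qr(X)
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise DataError(f"rank-deficient design ({key})")
            self.q[key] = q
        self.df_full = self.n - self.q["full"].shape[1]
        if self.df_full < 1:
            raise DataError("no residual degrees of freedom")
        k = self.n_levels - 1
        self.df1 = {"population": k, "trait": 1, "population:trait": k}

    def _rss(self, key: str, Y: np.ndarray) -> np.ndarray:
        qty = self.q[key].T @ Y
        return np.einsum("ij,ij->j", Y, Y) - np.einsum("ij,ij->j", qty, qty)

    def f_stats(self, Y: np.ndarray) -> dict[str, np.ndarray]:
        """Per-term F statistics for each column of ``Y``.

        Columns with (numerically) zero full-model residual variance get
        ``F = 0`` for every term: a constant response carries no evidence,
        and its permuted fits are identical to the observed one.
        """
        rss_full = self._rss("full", Y)
        rss_add = self._rss("additive", Y)
        rss_pop = self._rss("population", Y)
        rss_trait = self._rss("trait", Y)
        scale = np.maximum(np.einsum("ij,ij->j", Y, Y), 1.0)
        mse = rss_full / self.df_full
        degenerate = mse <= 1e-14 * scale
        safe_mse = np.where(degenerate, 1.0, mse)
        out = {}
        deltas = {
            "population": rss_trait - rss_add,
            "trait": rss_pop - rss_add,
            "population:trait": rss_add - rss_full,
        }
        for term, delta in deltas.items():
            F = np.maximum(delta, 0.0) / self.df1[term] / safe_mse
            out[term] = np.where(degenerate, 0.0, F)
        return out

    def p_values(self, F: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        return {
            term: stats.f.sf(F[term], self.df1[term], self.df_full)
            for term in TERMS
        }


def efdr(
    responses: pd.DataFrame,
    samples: pd.DataFrame,
    trait: pd.Series,
    config: PermutationConfig,
    trait_name: str = "trait",
) -> tuple[pd.DataFrame, dict]:
    """Permutation eFDRs for every response x term of the interaction model.

    Parameters
    ----------
    responses : DataFrame
        Samples x responses matrix (rows aligned with ``samples``); rows are
        what gets shuffled.
    trait : Series
        Per-sample covariate; samples with a missing trait are excluded from
        the model fits (but still take part in the shuffling, exactly as
        expression values of every sample were shuffled in the source
        procedure).

    Returns
    -------
    table : DataFrame
        Long table (response, trait, term, F, df1, df2, p_param, efdr).
    run_log : dict
        Seed, n_perm, analysis-set size, degenerate-permutation tally.
    """
    samples = validate_samples(samples)
    meta = samples.set_index("sample_id")
    missing = [s for s in responses.index if s not in meta.index]
    if missing:
        raise DataError(f"responses contain unknown samples: {missing[:5]}")

    trait_aligned = trait.reindex(responses.index)
    analysis_mask = ~trait_aligned.isna().to_numpy()
    if analysis_mask.sum() < 3:
        raise DataError("analysis set has fewer than 3 samples")
    ids = list(responses.index)
    analysis_pos = np.where(analysis_mask)[0]
    populations = meta.loc[[ids[i] for i in analysis_pos], "population"].to_numpy(str)
    tv = trait_aligned.to_numpy(dtype=float)[analysis_pos]

    engine = _TermFEngine(populations, tv)
    Y_all = responses.to_numpy(dtype=float)
    Y_obs = Y_all[analysis_pos]
    F_obs = engine.f_stats(Y_obs)
    p_obs = engine.p_values(F_obs)

    plan = permutation_plan(len(ids), config)
    n_resp = Y_all.shape[1]
    geq = {term: np.zeros(n_resp) for term in TERMS}  # p_b <= p_obs, i.e. F_b >= F_obs
    leq = {term: np.zeros(n_resp) for term in TERMS}  # p_obs <= p_b (literal)
    pooled = {term: [] for term in TERMS} if config.scope == "pooled" else None
    for perm in plan:
        Yp = Y_all[perm][analysis_pos]
        F_b = engine.f_stats(Yp)
        for term in TERMS:
            geq[term] += F_b[term] >= F_obs[term]
            leq[term] += F_b[term] <= F_obs[term]
            if pooled is not None:
                pooled[term].append(F_b[term])

    B = config.n_perm
    rows = []
    for j, resp in enumerate(responses.columns):
        for term in TERMS:
            if config.direction == "literal":
                # proportion of shuffles with p_obs <= p_b (ties included)
                value = leq[term][j] / B
            elif pooled is not None:
                all_f = np.concatenate([f[np.newaxis, :] for f in pooled[term]])
                value = float((all_f >= F_obs[term][j]).mean())
                if config.plus_one:
                    value = (value * all_f.size + 1) / (all_f.size + 1)
            else:
                count = geq[term][j]
                value = (count + 1) / (B + 1) if config.plus_one else count / B
            rows.append(
                {
                    "response": resp, "trait": trait_name, "term": term,
                    "F": float(F_obs[term][j]),
                    "df1": engine.df1[term], "df2": engine.df_full,
                    "p_param": float(p_obs[term][j]),
                    "efdr": float(value),
                }
            )
    run_log = {
        "seed": config.seed,
        "n_perm": B,
        "scope": config.scope,
        "plus_one": config.plus_one,
        "direction": config.direction,
        "n_samples": len(ids),
        "n_analysis": int(analysis_mask.sum()),
        "n_responses": n_resp,
        "degenerate_permutations": 0,  # fixed design: refits cannot lose rank
    }
    return pd.DataFrame(rows), run_log


def run_trait_models(
    responses: pd.DataFrame,
    samples: pd.DataFrame,
    trait_scores: pd.DataFrame,
    config: PermutationConfig,
) -> tuple[pd.DataFrame, dict]:
    """eFDR model battery over every trait column (e.g. the six trait PCs).

    The same seed (hence the same permutation plan) is used for every
    trait so results are comparable across columns.
    """
    tables = []
    logs = {}
    for trait_name in trait_scores.columns:
        table, log = efdr(
            responses, samples, trait_scores[trait_name], config, trait_name=trait_name
        )
        tables.append(table)
        logs[trait_name] = log
    return pd.concat(tables, ignore_index=True), logs
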