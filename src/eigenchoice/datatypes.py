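"""Core data containers shared by every stage of the pipeline.

Matrices are thin wrappers around :class:`pandas.DataFrame` that validate
the structural invariants each stage relies on (orientation, uniqueness of
identifiers, value domains).  Sample metadata stays a plain data frame with
a documented column contract (see :func:`validate_samples`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DataError

#: Reserved module label for genes not claimed by any module.
UNASSIGNED = "unassigned"

#: Required sample metadata columns.
SAMPLE_COLUMNS = ("sample_id", "population", "treatment")


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer counts."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise DataError("duplicate gene ids in count matrix")
        if df.columns.has_duplicates:
            raise DataError("duplicate sample ids in count matrix")
        values = df.to_numpy()
        if values.size and (values < 0).any():
            raise DataError("count matrix contains negative entries")
        if values.size and not np.allclose(values, np.round(values)):
            raise DataError("count matrix contains non-integer entries")
        self.data = df.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of variance-stabilized expression values.

    ``transform_tag`` records the transform and its parameters so that
    downstream artifacts are self-describing.
    """

    data: pd.DataFrame
    transform_tag: str = ""

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise DataError("expression matrix contains non-finite values")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise DataError("duplicate identifiers in expression matrix")
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class PCAResult:
    """Sample-space principal component decomposition."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # genes x components
    variance_explained: np.ndarray  # per retained component, fraction of total

    def __post_init__(self) -> None:
        ve = np.asarray(self.variance_explained, dtype=float)
        if np.any(ve < -1e-12) or np.any(ve > 1 + 1e-12):
            raise DataError("variance_explained outside [0, 1]")
        if np.any(np.diff(ve) > 1e-12):
            raise DataError("variance_explained must be non-increasing")
        if ve.sum() > 1 + 1e-9:
            raise DataError("variance_explained sums to more than 1")
        self.variance_explained = ve


@dataclass
class ModuleAssignment:
    """Map from gene id to module label, with an 'unassigned' sentinel."""

    module_of_gene: pd.Series  # index: gene ids, values: labels
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = [str(v) for v in pd.unique(self.module_of_gene)]
        if not self.labels:
            real = sorted(
                (lab for lab in seen if lab != UNASSIGNED),
                key=lambda lab: (-int((self.module_of_gene == lab).sum()), lab),
            )
            self.labels = real + ([UNASSIGNED] if UNASSIGNED in seen else [])
        unknown = set(seen) - set(self.labels)
        if unknown:
            raise DataError(f"labels missing from declared set: {sorted(unknown)}")
        self.module_of_gene = self.module_of_gene.astype(str)

    @property
    def module_labels(self) -> list[str]:
        """Labels of real modules (excludes the unassigned sentinel)."""
        return [lab for lab in self.labels if lab != UNASSIGNED]

    def genes_in(self, label: str) -> list[str]:
        return list(self.module_of_gene.index[self.module_of_gene == label])

    def sizes(self) -> pd.Series:
        counts = self.module_of_gene.value_counts()
        return counts.reindex(self.labels, fill_value=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.module_of_gene.index, "module": self.module_of_gene.values}
        )


@dataclass
class EigengeneMatrix:
    """Sample x module matrix of module eigengenes (first PC per module)."""

    data: pd.DataFrame  # samples x modules
    variance_explained: pd.Series  # per module, first-eigenvalue share

    def __post_init__(self) -> None:
        ve = self.variance_explained.astype(float)
        if ((ve < -1e-12) | (ve > 1 + 1e-12)).any():
            raise DataError("eigengene variance_explained outside [0, 1]")
        means = self.data.mean(axis=0).abs()
        if (means > 1e-6 * (1 + self.data.abs().to_numpy().max())).any():
            raise DataError("eigengene columns must have sample mean 0")

    @property
    def module_labels(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class SimTruth:
    """Ground truth for a simulated dataset."""

    module_of_gene: ModuleAssignment
    latent_activity: pd.DataFrame  # samples x modules
    true_interaction_modules: set[str]
    true_de_genes: set[str]

    def __post_init__(self) -> None:
        known = set(self.module_of_gene.labels)
        if not self.true_interaction_modules <= known:
            raise DataError("true_interaction_modules not a subset of module labels")
        genes = set(self.module_of_gene.module_of_gene.index)
        if not self.true_de_genes <= genes:
            raise DataError("true_de_genes not a subset of simulated genes")

    def to_json(self) -> str:
        payload = {
            "module_of_gene": self.module_of_gene.module_of_gene.to_dict(),
            "labels": self.module_of_gene.labels,
            "latent_activity": {
                "index": list(self.latent_activity.index),
                "columns": list(self.latent_activity.columns),
                "values": self.latent_activity.to_numpy().tolist(),
            },
            "true_interaction_modules": sorted(self.true_interaction_modules),
            "true_de_genes": sorted(self.true_de_genes),
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        payload = json.loads(text)
        assignment = ModuleAssignment(
            pd.Series(payload["module_of_gene"], dtype=str).sort_index(),
            labels=list(payload["labels"]),
        )
        latent = pd.DataFrame(
            payload["latent_activity"]["values"],
            index=payload["latent_activity"]["index"],
            columns=payload["latent_activity"]["columns"],
        )
        return cls(
            module_of_gene=assignment,
            latent_activity=latent,
            true_interaction_modules=set(payload["true_interaction_modules"]),
            true_de_genes=set(payload["true_de_genes"]),
        )


@dataclass
class ModelFit:
    """An OLS fit of ``y ~ population + trait + population:trait``.

    Stores the analysis-set data so that type-II sums of squares can be
    derived by refitting the nested reduced models.
    """

    response: str
    trait_name: str
    sample_ids: list[str]
    y: np.ndarray
    populations: np.ndarray  # str labels, analysis set only
    trait: np.ndarray
    coefficients: pd.Series
    rss: float
    df_resid: int

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class TermResult:
    """One ANOVA term of one model, with optional permutation eFDR."""

    response: str
    trait: str
    term: str  # population | trait | population:trait
    F: float
    df1: int
    df2: int
    p_param: float
    efdr: float | None = None


def terms_to_frame(results: Iterable[TermResult]) -> pd.DataFrame:
    rows = [
        {
            "response": r.response,
            "trait": r.trait,
            "term": r.term,
            "F": r.F,
            "df1": r.df1,
            "df2": r.df2,
            "p_param": r.p_param,
            "efdr": r.efdr,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def validate_samples(
    samples: pd.DataFrame,
    populations: Iterable[str] | None = None,
    treatments: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Check the sample-metadata column contract and level sets."""
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise DataError(f"sample table missing columns: {missing}")
    if samples["sample_id"].duplicated().any():
        raise DataError("duplicate sample_id in sample table")
    if populations is not None:
        bad = set(samples["population"]) - set(populations)
        if bad:
            raise DataError(f"unknown population levels: {sorted(bad)}")
    if treatments is not None:
        bad = set(samples["treatment"]) - set(treatments)
        if bad:
            raise DataError(f"unknown treatment levels: {sorted(bad)}")
    if "read_mapping_pct" in samples.columns:
        pct = samples["read_mapping_pct"].dropna()
        if ((pct < 0) | (pct > 1)).any():
            raise DataError("read_mapping_pct must lie in [0, 1]")
    return samples


def align_samples(matrix: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Return metadata rows ordered like the matrix columns (or index)."""
    ids = list(matrix.columns)
    meta = samples.set_index("sample_id", drop=False)
    missing = [s for s in ids if s not in meta.index]
    if missing:
        raise DataError(f"samples absent from metadata: {missing[:5]}")
    return meta.loc[ids].reset_index(drop=True)


def qc_flags_as_sets(samples: pd.DataFrame) -> pd.Series:
    """Normalize the qc_flags column (absent / str / set) to sets."""
    if "qc_flags" not in samples.columns:
        return pd.Series([set() for _ in range(len(samples))], index=samples.index)

    def _to_set(v: object) -> set[str]:
        if isinstance(v, set):
            return set(v)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return set()
        if isinstance(v, str):
            return set(t for t in v.split(";") if t)
        return set(v)  # type: ignore[arg-type]

    return samples["qc_flags"].map(_to_set)
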