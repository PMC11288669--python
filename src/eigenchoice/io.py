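"""Readers and writers for the plain-text formats used by the pipeline."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, ExpressionMatrix, qc_flags_as_sets
from .errors import DataError

_FLOAT_FMT = "%.10g"


def read_counts(path: str | Path) -> CountMatrix:
    """Read counts from TSV (genes x samples) or MatrixMarket with sidecars.

    For ``foo.mtx``, gene and sample names are read from ``foo.rownames.txt``
    and ``foo.colnames.txt`` (one id per line).
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        values = np.asarray(mmread(path).todense() if hasattr(mmread(path), "todense") else mmread(path))
        genes = _read_names(path.with_suffix(".rownames.txt"))
        cols = _read_names(path.with_suffix(".colnames.txt"))
        if values.shape != (len(genes), len(cols)):
            raise DataError("MatrixMarket shape does not match sidecar name files")
        df = pd.DataFrame(values, index=genes, columns=cols)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
    return CountMatrix(df)


def _read_names(path: Path) -> list[str]:
    if not path.exists():
        raise DataError(f"missing sidecar name file: {path}")
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]


def write_counts(counts: CountMatrix, path: str | Path, mtx: bool = False) -> None:
    path = Path(path)
    counts.data.to_csv(path, sep="\t", index_label="gene_id")
    if mtx:
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        base = path.with_suffix(".mtx")
        mmwrite(str(base), csr_matrix(counts.data.to_numpy()))
        base.with_suffix(".rownames.txt").write_text("\n".join(counts.gene_ids) + "\n")
        base.with_suffix(".colnames.txt").write_text("\n".join(counts.sample_ids) + "\n")


def read_samples(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    out = samples.copy()
    if "qc_flags" in out.columns:
        out["qc_flags"] = [";".join(sorted(s)) for s in qc_flags_as_sets(out)]
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_traits(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    traits.to_csv(path, index_label="sample_id", float_format=_FLOAT_FMT)


def read_expression(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    tag = ""
    tag_path = Path(path).with_suffix(".tag.json")
    if tag_path.exists():
        tag = json.loads(tag_path.read_text()).get("transform_tag", "")
    return ExpressionMatrix(df, transform_tag=tag)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene_id", float_format=_FLOAT_FMT)
    Path(path).with_suffix(".tag.json").write_text(
        json.dumps({"transform_tag": expr.transform_tag}) + "\n"
    )


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format=_FLOAT_FMT)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_json(payload: object, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(obj: object) -> object:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
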