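"""End-to-end pipeline: simulate/load -> preprocess -> network -> models -> eFDR.

One YAML run configuration drives every stage; a single global seed derives
per-stage seeds through a labelled-hash scheme so each stage is
independently reproducible.  Every stage writes its artifacts under the run
directory, and a manifest (config echo, version, per-file checksums, sample
exclusions, wall-clock per stage) is written last.  Re-running with an
identical configuration reproduces byte-identical outputs; ``resume=True``
reuses stages whose outputs already exist.
"""

from __future__ import annotations

import dataclasses
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .datatypes import qc_flags_as_sets
from .efdr import PermutationConfig, run_trait_models
from .errors import ConfigurationError
from .models import module_contrasts, trait_pca
from .network import NetworkParams, build_network
from .preprocess import (
    drop_flagged,
    estimate_size_factors,
    filter_top_variable,
    flag_qc_samples,
    pca_samples,
    vst,
)
from .simulate import SimConfig, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "network", "models", "efdr")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from a labelled hash."""
    return int(
        np.random.SeedSequence(
            [int(global_seed), zlib.crc32(stage.encode())]
        ).generate_state(1)[0]
    )


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run."""

    out_dir: str
    seed: int = 0
    simulate: SimConfig | None = None
    inputs: dict | None = None  # {"counts": ..., "samples": ..., "traits": ...}
    network: NetworkParams = field(default_factory=NetworkParams)
    efdr: PermutationConfig = field(default_factory=PermutationConfig)
    top_variable_fraction: float = 0.9
    vst_pseudocount: float = 1.0
    qc_enabled: bool = True
    swap_margin: float = 2.0
    n_lowest_mapping: int = 2
    exclude_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigurationError(
                "inputs", "exactly one of 'simulate' and 'inputs' must be given"
            )
        if self.inputs is not None:
            for key in ("counts", "samples"):
                if key not in self.inputs:
                    raise ConfigurationError("inputs", f"missing '{key}' path")
                if not Path(self.inputs[key]).exists():
                    raise ConfigurationError("inputs", f"file not found: {self.inputs[key]}")
        if not (0 < self.top_variable_fraction <= 1):
            raise ConfigurationError("top_variable_fraction", "must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        seed = int(raw.get("seed", 0))
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim.setdefault("seed", stage_seed(seed, "simulate"))
            if "module_sizes" in sim:
                sim["module_sizes"] = tuple(sim["module_sizes"])
            if "treatment_effect" in sim and isinstance(sim["treatment_effect"], dict):
                sim["treatment_effect"] = {
                    (int(k.split("|")[0]), k.split("|")[1]): v
                    for k, v in sim["treatment_effect"].items()
                } if all(isinstance(k, str) for k in sim["treatment_effect"]) else sim["treatment_effect"]
            sim = SimConfig(**sim)
        net = NetworkParams(**raw.pop("network", {}))
        efdr_raw = raw.pop("efdr", {})
        efdr_raw.setdefault("seed", stage_seed(seed, "efdr"))
        perm = PermutationConfig(**efdr_raw)
        return cls(
            out_dir=raw.pop("out_dir"),
            seed=seed,
            simulate=sim,
            inputs=raw.pop("inputs", None),
            network=net,
            efdr=perm,
            **{k: v for k, v in raw.items() if k != "seed"},
        )

    def echo(self) -> dict:
        payload = dataclasses.asdict(self)
        if self.simulate is not None:
            sim = payload["simulate"]
            sim.pop("_slopes", None)
            sim.pop("_effects", None)
            sim["trait_slope"] = (
                None if self.simulate._slopes is None
                else np.asarray(self.simulate._slopes).tolist()
            )
            sim["treatment_effect"] = {
                f"{m}|{tr}": v for (m, tr), v in self.simulate._effects.items()
            }
        return payload


def run_pipeline(config: RunConfig, resume: bool = False) -> dict:
    """Execute all stages in order; returns the manifest (also written)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.echo(),
        "version": _version(),
        "stages": {},
        "exclusions": [],
    }

    # ---- stage: simulate / load --------------------------------------
    t0 = time.perf_counter()
    sim_dir = out / "simulate"
    if config.simulate is not None:
        expected = [sim_dir / n for n in ("counts.tsv", "samples.csv", "traits.csv", "truth.json")]
        if resume and all(p.exists() for p in expected):
            logger.info("resume: reusing simulate stage")
            counts = io.read_counts(expected[0])
            samples = io.read_samples(expected[1])
            traits = io.read_traits(expected[2])
            manifest["stages"]["simulate"] = _stage_record(expected, 0.0, reused=True)
        else:
            counts, samples, traits, _truth = simulate_dataset(config.simulate)
            write_dataset(sim_dir, counts, samples, traits, _truth)
            manifest["stages"]["simulate"] = _stage_record(
                expected, time.perf_counter() - t0
            )
    else:
        counts = io.read_counts(config.inputs["counts"])
        samples = io.read_samples(config.inputs["samples"])
        traits = (
            io.read_traits(config.inputs["traits"])
            if "traits" in config.inputs else None
        )
        manifest["stages"]["simulate"] = {
            "reused": True, "inputs": {k: str(v) for k, v in config.inputs.items()},
            "seconds": round(time.perf_counter() - t0, 3),
        }

    # ---- stage: preprocess -------------------------------------------
    t0 = time.perf_counter()
    pre_dir = out / "preprocess"
    pre_files = [pre_dir / n for n in
                 ("vst.tsv", "vst_filtered.tsv", "pca_scores.csv",
                  "samples_qc.csv", "qc_report.json")]
    if resume and all(p.exists() for p in pre_files):
        logger.info("resume: reusing preprocess stage")
        filtered = io.read_expression(pre_files[1])
        samples_qc = io.read_samples(pre_files[3])
        manifest["stages"]["preprocess"] = _stage_record(pre_files, 0.0, reused=True)
    else:
        pre_dir.mkdir(parents=True, exist_ok=True)
        size_factors = estimate_size_factors(counts)
        expr = vst(counts, size_factors, pseudocount=config.vst_pseudocount)
        top = filter_top_variable(expr, config.top_variable_fraction)
        pca = pca_samples(top, n_components=min(5, len(top.sample_ids) - 1))
        if config.qc_enabled:
            samples_qc = flag_qc_samples(
                pca, samples,
                swap_margin=config.swap_margin,
                n_lowest_mapping=config.n_lowest_mapping,
            )
        else:
            samples_qc = samples.copy()
            samples_qc["qc_flags"] = [set() for _ in range(len(samples))]
        if config.exclude_samples:
            flags = qc_flags_as_sets(samples_qc)
            for i, sid in enumerate(samples_qc["sample_id"]):
                if sid in config.exclude_samples:
                    flags.iloc[i] = flags.iloc[i] | {"excluded_by_config"}
            samples_qc["qc_flags"] = flags
        filtered = drop_flagged(top, samples_qc)
        excluded = sorted(set(top.sample_ids) - set(filtered.sample_ids))
        manifest["exclusions"] = [
            {"sample_id": sid,
             "reasons": sorted(qc_flags_as_sets(samples_qc)[
                 samples_qc.index[samples_qc["sample_id"] == sid][0]])}
            for sid in excluded
        ]
        io.write_expression(expr, pre_files[0])
        io.write_expression(filtered, pre_files[1])
        pca.scores.to_csv(pre_files[2], index_label="sample_id", float_format="%.10g")
        io.write_samples(samples_qc, pre_files[3])
        io.write_json(
            {
                "size_factors": {k: float(v) for k, v in size_factors.items()},
                "variance_explained": pca.variance_explained.tolist(),
                "excluded_samples": manifest["exclusions"],
                "transform_tag": expr.transform_tag,
            },
            pre_files[4],
        )
        manifest["stages"]["preprocess"] = _stage_record(
            pre_files, time.perf_counter() - t0
        )

    # ---- stage: network ----------------------------------------------
    t0 = time.perf_counter()
    net_dir = out / "network"
    net_files = [net_dir / n for n in
                 ("modules.tsv", "eigengenes.tsv", "network_summary.json")]
    if resume and all(p.exists() for p in net_files):
        logger.info("resume: reusing network stage")
        eigengenes_df = io.read_matrix(net_files[1])
        manifest["stages"]["network"] = _stage_record(net_files, 0.0, reused=True)
    else:
        net_dir.mkdir(parents=True, exist_ok=True)
        modules, eigengenes, summary = build_network(filtered, config.network)
        modules.to_frame().to_csv(net_files[0], sep="\t", index=False)
        io.write_matrix(eigengenes.data, net_files[1], index_label="sample_id")
        io.write_json({"params": dataclasses.asdict(config.network), **summary},
                      net_files[2])
        eigengenes_df = eigengenes.data
        manifest["stages"]["network"] = _stage_record(
            net_files, time.perf_counter() - t0
        )

    # ---- stage: models (contrasts + trait PCs) ------------------------
    t0 = time.perf_counter()
    mod_dir = out / "models"
    mod_files = [mod_dir / n for n in ("contrasts.tsv", "trait_pcs.tsv")]
    analysis_samples = samples_qc
    sample_set = list(eigengenes_df.index)
    if resume and all(p.exists() for p in mod_files):
        logger.info("resume: reusing models stage")
        trait_scores = io.read_matrix(mod_files[1])
        manifest["stages"]["models"] = _stage_record(mod_files, 0.0, reused=True)
    else:
        mod_dir.mkdir(parents=True, exist_ok=True)
        from .datatypes import EigengeneMatrix

        eg = EigengeneMatrix(
            eigengenes_df, variance_explained=pd.Series(
                0.0, index=eigengenes_df.columns, dtype=float
            )
        )
        contrasts = (
            module_contrasts(eg, samples_qc[samples_qc["sample_id"].isin(sample_set)])
            if eigengenes_df.shape[1] else pd.DataFrame()
        )
        contrasts.to_csv(mod_files[0], sep="\t", index=False, float_format="%.10g")
        if traits is not None:
            pcs = trait_pca(traits)
            trait_scores = pcs.scores.loc[[s for s in sample_set if s in pcs.scores.index]]
        else:
            trait_scores = pd.DataFrame(index=pd.Index(sample_set, name="sample_id"))
        io.write_matrix(trait_scores, mod_files[1], index_label="sample_id")
        manifest["stages"]["models"] = _stage_record(
            mod_files, time.perf_counter() - t0
        )

    # ---- stage: efdr --------------------------------------------------
    t0 = time.perf_counter()
    efdr_dir = out / "efdr"
    efdr_files = [efdr_dir / n for n in ("models_efdr.tsv", "run_log.json")]
    if resume and all(p.exists() for p in efdr_files):
        logger.info("resume: reusing efdr stage")
        manifest["stages"]["efdr"] = _stage_record(efdr_files, 0.0, reused=True)
    else:
        efdr_dir.mkdir(parents=True, exist_ok=True)
        if eigengenes_df.shape[1] and trait_scores.shape[1]:
            responses = eigengenes_df.loc[
                [s for s in eigengenes_df.index if s in trait_scores.index]
            ]
            table, logs = run_trait_models(
                responses, analysis_samples, trait_scores.loc[responses.index],
                config.efdr,
            )
        else:
            table, logs = pd.DataFrame(
                columns=["response", "trait", "term", "F", "df1", "df2",
                         "p_param", "efdr"]
            ), {}
        table.to_csv(efdr_files[0], sep="\t", index=False, float_format="%.10g")
        io.write_json(logs, efdr_files[1])
        manifest["stages"]["efdr"] = _stage_record(
            efdr_files, time.perf_counter() - t0
        )

    io.write_json(manifest, out / "manifest.json")
    return manifest


def _stage_record(files, seconds: float, reused: bool = False) -> dict:
    return {
        "reused": reused,
        "seconds": round(seconds, 3),
        "outputs": {
            str(p): io.sha256_file(p) for p in files if Path(p).exists()
        },
    }


def _version() -> str:
    from . import __version__

    return __version__
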