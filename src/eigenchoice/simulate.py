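"""Synthetic bulk RNA-seq generator with planted co-expression structure.

The generator produces a gene x sample count matrix whose log-scale
expression carries (i) planted co-expression modules driven by one latent
factor each, (ii) constitutive population shifts, (iii) treatment shifts for
designated module x treatment pairs, and (iv) module-trait covariation whose
slope may differ between populations (an opposing-slope pattern plants a
population-by-trait interaction).  Counts have negative-binomial marginals
(Var = mu + alpha * mu^2) and multiplicative library-size factors, so the
full preprocessing stack downstream is exercised with known ground truth.

Model per gene g, sample s (log2 scale)::

    log2 mu_gs = base_g + pop_shift_{g, pop(s)} + treat_shift
                 + sd_g * (sqrt(r) * L_{m(g), s} + sqrt(1 - r) * eps_gs)

where the module latent ``L_{m,s} = z_{m,s} + slope[m, pop(s)] * trait_s``
(the trait term only for courtship samples — control trials have no male,
and carry a missing-value trait sentinel).  Background genes have no latent
term.  With loading ``sqrt(r)`` and noise ``sqrt(1-r)`` the expected
log-scale correlation within a module is ``r``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, ModuleAssignment, SimTruth, UNASSIGNED
from .errors import ConfigurationError

DEFAULT_POPULATIONS = ("paxton_limnetic", "paxton_benthic", "priest_limnetic")
DEFAULT_TREATMENTS = ("conspecific", "heterospecific", "female_control")

#: Trait-table column loadings: each observed trait column is
#: loading * block latent + N(0, noise_sd).
_TRAIT_LOADINGS = {
    "Fbehav": (1.0, 0.9, 0.8, 0.7),
    "Mbehav": (1.0, 0.9, 0.8, 0.7, 0.6),
    "Mmorph": (1.0, 0.9, 0.8, 0.7, 0.6),
}
_TRAIT_NOISE_SD = 0.5


@dataclass
class SimConfig:
    """Parameters of one simulated dataset.

    ``trait_slope`` is an ``n_modules x n_populations`` array (or a mapping
    ``{(module_index, population_label): slope}``) of slopes of latent module
    activity on the simulated male-trait covariate; opposing signs between
    two populations plant a population-by-trait interaction.
    ``treatment_effect`` maps ``(module_index, treatment_label)`` to a
    log2-scale shift applied to that module's genes in that treatment.
    """

    n_genes: int = 2000
    module_sizes: Sequence[int] = (100, 100, 100)
    n_per_cell: int = 6
    populations: Sequence[str] = DEFAULT_POPULATIONS
    treatments: Sequence[str] = DEFAULT_TREATMENTS
    within_module_cor: float = 0.7
    pop_effect_sd: float = 0.0
    trait_slope: object = None
    treatment_effect: Mapping[tuple[int, str], float] | None = None
    nb_dispersion: float = 0.05
    lib_size_range: tuple[float, float] = (0.7, 1.4)
    gene_log_sd: float = 1.0
    base_log2_range: tuple[float, float] = (3.0, 12.0)
    control_treatment: str = "female_control"
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n_genes) <= 0:
            raise ConfigurationError("n_genes", "must be positive")
        sizes = [int(s) for s in self.module_sizes]
        if any(s <= 0 for s in sizes):
            raise ConfigurationError("module_sizes", "all sizes must be positive")
        if sum(sizes) > self.n_genes:
            raise ConfigurationError(
                "module_sizes", f"sum {sum(sizes)} exceeds n_genes {self.n_genes}"
            )
        if int(self.n_per_cell) <= 0:
            raise ConfigurationError("n_per_cell", "must be positive")
        if len(set(self.populations)) != len(self.populations) or not self.populations:
            raise ConfigurationError("populations", "labels must be unique and non-empty")
        if len(set(self.treatments)) != len(self.treatments) or not self.treatments:
            raise ConfigurationError("treatments", "labels must be unique and non-empty")
        if not (0.0 < float(self.within_module_cor) < 1.0):
            raise ConfigurationError("within_module_cor", "must lie in (0, 1)")
        if float(self.pop_effect_sd) < 0:
            raise ConfigurationError("pop_effect_sd", "must be non-negative")
        if float(self.nb_dispersion) < 0:
            raise ConfigurationError("nb_dispersion", "must be non-negative")
        lo, hi = (float(self.lib_size_range[0]), float(self.lib_size_range[1]))
        if not (0 < lo <= hi):
            raise ConfigurationError("lib_size_range", "must satisfy 0 < lo <= hi")
        if float(self.gene_log_sd) <= 0:
            raise ConfigurationError("gene_log_sd", "must be positive")
        if self.control_treatment not in self.treatments:
            raise ConfigurationError(
                "control_treatment", f"'{self.control_treatment}' not in treatments"
            )
        self.module_sizes = tuple(sizes)
        # normalize trait_slope to an (n_modules, n_populations) array
        self._slopes = _slopes_array(self)
        self._effects = dict(self.treatment_effect or {})
        for (m, tr), shift in self._effects.items():
            if not (0 <= int(m) < len(sizes)):
                raise ConfigurationError("treatment_effect", f"unknown module index {m}")
            if tr not in self.treatments:
                raise ConfigurationError("treatment_effect", f"unknown treatment '{tr}'")

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def module_labels(self) -> list[str]:
        return [f"M{i + 1}" for i in range(self.n_modules)]


def _slopes_array(config: SimConfig) -> np.ndarray:
    n_mod, n_pop = len(config.module_sizes), len(config.populations)
    raw = config.trait_slope
    slopes = np.zeros((n_mod, n_pop))
    if raw is None:
        return slopes
    if isinstance(raw, Mapping):
        pop_index = {p: i for i, p in enumerate(config.populations)}
        for (m, pop), value in raw.items():
            if not (0 <= int(m) < n_mod):
                raise ConfigurationError("trait_slope", f"unknown module index {m}")
            if pop not in pop_index:
                raise ConfigurationError("trait_slope", f"unknown population '{pop}'")
            slopes[int(m), pop_index[pop]] = float(value)
        return slopes
    arr = np.asarray(raw, dtype=float)
    if arr.shape != (n_mod, n_pop):
        raise ConfigurationError(
            "trait_slope", f"expected shape ({n_mod}, {n_pop}), got {arr.shape}"
        )
    return arr


def simulate_dataset(
    config: SimConfig,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate counts, sample metadata, a trait table and ground truth.

    Returns
    -------
    counts : CountMatrix
    samples : pandas.DataFrame
        Columns ``sample_id, population, treatment, male_trait,
        read_mapping_pct``; ``male_trait`` is NaN for control samples.
    traits : pandas.DataFrame
        Per-trial measurements in three blocks (``Fbehav_*``, ``Mbehav_*``,
        ``Mmorph_*``); male blocks are NaN for control samples.
    truth : SimTruth
    """
    rng = np.random.default_rng(config.seed)
    pops, treats = list(config.populations), list(config.treatments)
    n_pop, n_treat = len(pops), len(treats)
    n_samples = n_pop * n_treat * config.n_per_cell
    n_genes = config.n_genes
    n_mod = config.n_modules

    sample_ids, pop_of, treat_of = [], [], []
    for pi, pop in enumerate(pops):
        for ti, tr in enumerate(treats):
            for k in range(config.n_per_cell):
                sample_ids.append(f"s{len(sample_ids):03d}_p{pi}t{ti}r{k}")
                pop_of.append(pop)
                treat_of.append(tr)
    pop_idx = np.array([pops.index(p) for p in pop_of])
    is_courtship = np.array([t != config.control_treatment for t in treat_of])

    # --- latent structure (draw order fixed for reproducibility) ---
    male_trait = np.where(is_courtship, rng.normal(size=n_samples), np.nan)
    z = rng.normal(size=(n_mod, n_samples))
    slopes = config._slopes  # (n_mod, n_pop)
    trait_term = np.where(is_courtship, np.nan_to_num(male_trait), 0.0)
    latent = z + slopes[:, pop_idx] * trait_term[None, :]

    base = rng.uniform(*config.base_log2_range, size=n_genes)
    pop_shift = (
        rng.normal(scale=config.pop_effect_sd, size=(n_genes, n_pop))
        if config.pop_effect_sd > 0
        else np.zeros((n_genes, n_pop))
    )
    eps = rng.normal(size=(n_genes, n_samples))
    lib = np.exp(rng.uniform(np.log(config.lib_size_range[0]),
                             np.log(config.lib_size_range[1]), size=n_samples))

    # --- gene -> module map ---
    module_of = np.full(n_genes, UNASSIGNED, dtype=object)
    start = 0
    for m, size in enumerate(config.module_sizes):
        module_of[start:start + size] = config.module_labels[m]
        start += size
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]

    r = config.within_module_cor
    load, noise = np.sqrt(r), np.sqrt(1.0 - r)
    signal = noise * eps
    start = 0
    for m, size in enumerate(config.module_sizes):
        signal[start:start + size] = load * latent[m][None, :] + noise * eps[start:start + size]
        start += size

    log2_mu = base[:, None] + pop_shift[:, pop_idx] + config.gene_log_sd * signal
    for (m, tr), shift in config._effects.items():
        in_mod = module_of == config.module_labels[m]
        in_treat = np.array([t == tr for t in treat_of])
        log2_mu[np.ix_(in_mod, in_treat)] += float(shift)

    mu = np.exp2(np.clip(log2_mu, None, 25.0)) * lib[None, :]
    alpha = float(config.nb_dispersion)
    if alpha > 0:
        lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)

    # --- trait table (three blocks from three latents) ---
    fbehav_latent = rng.normal(size=n_samples)
    mbehav_latent = rng.normal(size=n_samples)
    trait_cols: dict[str, np.ndarray] = {}
    block_latents = {"Fbehav": fbehav_latent, "Mbehav": mbehav_latent,
                     "Mmorph": np.nan_to_num(male_trait)}
    for block, loadings in _TRAIT_LOADINGS.items():
        latent_b = block_latents[block]
        for j, lam_j in enumerate(loadings, start=1):
            col = lam_j * latent_b + rng.normal(scale=_TRAIT_NOISE_SD, size=n_samples)
            if block != "Fbehav":  # male blocks undefined without a courting male
                col = np.where(is_courtship, col, np.nan)
            trait_cols[f"{block}_{j}"] = col
    traits = pd.DataFrame(trait_cols, index=pd.Index(sample_ids, name="sample_id"))

    read_mapping = 0.85 + 0.10 * rng.random(size=n_samples)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "population": pop_of,
            "treatment": treat_of,
            "male_trait": male_trait,
            "read_mapping_pct": np.round(read_mapping, 6),
        }
    )

    assignment = ModuleAssignment(
        pd.Series(module_of, index=gene_ids, dtype=str),
        labels=config.module_labels + [UNASSIGNED],
    )
    # population-dependent slope = interaction; a common nonzero slope is a
    # main trait effect only
    interaction_modules = {
        config.module_labels[m] for m in range(n_mod) if np.ptp(slopes[m]) > 0
    }
    de_genes: set[str] = set()
    for (m, _tr), shift in config._effects.items():
        if shift != 0:
            de_genes.update(g for g, lab in zip(gene_ids, module_of)
                            if lab == config.module_labels[m])
    truth = SimTruth(
        module_of_gene=assignment,
        latent_activity=pd.DataFrame(
            latent.T, index=sample_ids, columns=config.module_labels
        ),
        true_interaction_modules=interaction_modules,
        true_de_genes=de_genes,
    )
    return CountMatrix(counts_df), samples, traits, truth


def simulate_null_dataset(
    config: SimConfig,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Same generator with all effect parameters forced to zero.

    Planted modules keep their co-expression (the network stage still has
    structure to find) but populations, treatments and traits have no effect
    on expression; the truth effect sets are empty.
    """
    null_config = dataclasses.replace(
        config, pop_effect_sd=0.0, trait_slope=None, treatment_effect=None
    )
    counts, samples, traits, truth = simulate_dataset(null_config)
    assert not truth.true_interaction_modules and not truth.true_de_genes
    return counts, samples, traits, truth


def write_dataset(
    out_dir,
    counts: CountMatrix,
    samples: pd.DataFrame,
    traits: pd.DataFrame,
    truth: SimTruth,
    mtx: bool = False,
) -> dict[str, str]:
    """Write the four artifacts into ``out_dir``; returns name -> path."""
    from pathlib import Path

    from . import io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "samples": out / "samples.csv",
        "traits": out / "traits.csv",
        "truth": out / "truth.json",
    }
    io.write_counts(counts, paths["counts"], mtx=mtx)
    io.write_samples(samples, paths["samples"])
    io.write_traits(traits, paths["traits"])
    Path(paths["truth"]).write_text(truth.to_json() + "\n")
    return {k: str(v) for k, v in paths.items()}
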