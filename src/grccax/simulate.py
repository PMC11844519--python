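"""Synthetic bulk RNA-seq data with planted co-expression modules and diagnosis effects.

The generator emulates the statistical structure the downstream pipeline assumes:
negative-binomial counts with library-size variation, block-correlated genes
organised in modules via shared latent factors, a small diagnosis effect placed
on the latent factors of a subset of modules, and diagnosis-correlated ternary
(present/absent/unknown) toxicology exposures.

Ground truth (module membership, per-gene effect) is returned alongside the
data so parameter recovery can be measured exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_dataset",
    "null_config",
]

DIAGNOSES = ("Control", "SCZ", "BD", "MDD")
TOX_LEVELS = ("present", "absent", "unknown")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


# Exposure probabilities by drug class, rows = (Control, SCZ, BD, MDD).
# Modeled on typical postmortem toxicology in psychiatric brain banks:
# antipsychotics concentrate in SCZ/BD, antidepressants in MDD/BD, mood
# stabilizers in BD; sedatives, opioids, stimulants, alcohol and cannabis are
# diffusely elevated in cases. This yields several diagnosis-correlated
# exposure axes rather than a single case-control axis.
_TOX_CLASS_PROFILES = (
    (3, (0.02, 0.55, 0.30, 0.10)),  # antipsychotics
    (3, (0.05, 0.15, 0.35, 0.50)),  # antidepressants
    (2, (0.01, 0.10, 0.45, 0.10)),  # mood stabilizers
    (3, (0.10, 0.25, 0.30, 0.30)),  # benzodiazepines / sedatives
    (2, (0.15, 0.20, 0.20, 0.25)),  # opioids
    (2, (0.10, 0.20, 0.20, 0.15)),  # stimulants
    (1, (0.25, 0.30, 0.35, 0.35)),  # alcohol
    (1, (0.15, 0.30, 0.25, 0.20)),  # cannabis
)


def _default_tox_assoc(n_groups: int, n_tox: int) -> np.ndarray:
    cols = []
    for count, profile in _TOX_CLASS_PROFILES:
        cols.extend([profile] * count)
    base = np.array(cols, dtype=float).T  # 4 x 17
    if n_groups == base.shape[0] and n_tox <= base.shape[1]:
        return base[:, :n_tox].copy()
    # other layouts: tile the class profiles column-wise
    reps = int(np.ceil(n_tox / base.shape[1]))
    tiled = np.tile(base, (1, reps))[:, :n_tox]
    if n_groups <= base.shape[0]:
        return tiled[:n_groups].copy()
    return np.vstack([tiled, np.tile(tiled[-1:], (n_groups - base.shape[0], 1))])


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset.

    Defaults reproduce the study design emulated throughout this package:
    185 samples in four diagnostic groups (55 controls, 44 SCZ, 35 BD, 51 MDD)
    and 17 ternary toxicology exposures.
    """

    n_per_group: tuple[int, ...] = (55, 44, 35, 51)
    group_labels: tuple[str, ...] = DIAGNOSES
    n_genes: int = 2000
    module_sizes: tuple[int, ...] = tuple([60] * 20)
    within_module_cor: float = 0.7
    effect_modules: tuple[int, ...] = ()
    effect_size: float | Mapping[int, float] = 0.0
    effect_group: str = "SCZ"
    n_tox: int = 17
    tox_assoc: np.ndarray | None = None
    unknown_rate: float = 0.05
    nb_dispersion: float = 0.1
    libsize_range: tuple[float, float] = (0.7, 1.4)
    baseline_range: tuple[float, float] = (20.0, 2000.0)
    latent_scale: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tox_assoc is None:
            self.tox_assoc = _default_tox_assoc(len(self.n_per_group), self.n_tox)
        self.tox_assoc = np.asarray(self.tox_assoc, dtype=float)
        self.validate()

    def validate(self) -> None:
        if len(self.n_per_group) != len(self.group_labels):
            raise ConfigurationError("n_per_group and group_labels lengths differ")
        if any(n <= 0 for n in self.n_per_group):
            raise ConfigurationError("all group sizes must be positive")
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigurationError(
                f"sum(module_sizes)={sum(self.module_sizes)} exceeds n_genes={self.n_genes}"
            )
        if any(m < 1 for m in self.module_sizes):
            raise ConfigurationError("module sizes must be >= 1")
        if not 0.0 <= self.within_module_cor < 1.0:
            raise ConfigurationError("within_module_cor must lie in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if not 0.0 <= self.unknown_rate <= 1.0:
            raise ConfigurationError("unknown_rate must lie in [0, 1]")
        if self.effect_group not in self.group_labels:
            raise ConfigurationError(f"effect_group {self.effect_group!r} not a group label")
        n_modules = len(self.module_sizes)
        bad = [m for m in self.effect_modules if not 1 <= m <= n_modules]
        if bad:
            raise ConfigurationError(f"effect_modules {bad} outside 1..{n_modules}")
        if self.tox_assoc.shape != (len(self.n_per_group), self.n_tox):
            raise ConfigurationError(
                f"tox_assoc shape {self.tox_assoc.shape} != "
                f"({len(self.n_per_group)}, {self.n_tox})"
            )
        if np.any(self.tox_assoc < 0) or np.any(self.tox_assoc > 1):
            raise ConfigurationError("tox_assoc entries must be probabilities in [0, 1]")
        lo, hi = self.libsize_range
        if not 0 < lo <= hi:
            raise ConfigurationError("libsize_range must satisfy 0 < low <= high")
        lo, hi = self.baseline_range
        if not 0 < lo <= hi:
            raise ConfigurationError("baseline_range must satisfy 0 < low <= high")

    def effect_vector_per_module(self) -> dict[int, float]:
        """Signed latent-factor shift for every module (0 where no effect)."""
        if isinstance(self.effect_size, Mapping):
            return {m: float(self.effect_size.get(m, 0.0)) for m in self.effect_modules}
        return {m: float(self.effect_size) for m in self.effect_modules}


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset."""

    true_modules: pd.Series  # feature id -> module id (0 = unassigned)
    true_effect: pd.Series  # per-feature signed latent effect
    affected_group: str
    tox_assoc_used: np.ndarray

    def effect_genes(self) -> list[str]:
        return list(self.true_effect.index[self.true_effect != 0.0])


def _module_labels(config: SimulationConfig) -> np.ndarray:
    labels = np.zeros(config.n_genes, dtype=int)
    start = 0
    for m, size in enumerate(config.module_sizes, start=1):
        labels[start : start + size] = m
        start += size
    return labels


def simulate_dataset(
    config: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Draw one synthetic dataset.

    Returns ``(counts, samples, truth)`` where ``counts`` is a genes x samples
    integer DataFrame, ``samples`` holds diagnosis plus the ternary toxicology
    columns, and ``truth`` records the planted structure.

    Mechanism: per sample s and module m a factor f_m(s) ~ N(0,1); gene i in
    module m has latent z_i(s) = sqrt(rho) f_m(s) + sqrt(1-rho) e_i(s);
    unassigned genes are pure noise. Samples of the affected diagnosis add the
    module's signed effect to z. Counts are NB with mean
    L_s * exp(b_i + c * z_i(s)) and dispersion alpha (var = mu + alpha mu^2).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    n = int(sum(config.n_per_group))
    p = config.n_genes
    diagnosis = np.repeat(list(config.group_labels), list(config.n_per_group))
    sample_ids = [f"S{i:04d}" for i in range(n)]
    gene_ids = [f"G{i:05d}" for i in range(p)]

    labels = _module_labels(config)
    rho = config.within_module_cor
    n_modules = len(config.module_sizes)

    factors = rng.standard_normal((n, n_modules))  # sample x module
    noise = rng.standard_normal((n, p))
    z = np.sqrt(1.0 - rho) * noise
    assigned = labels > 0
    z[:, assigned] += np.sqrt(rho) * factors[:, labels[assigned] - 1]
    z[:, ~assigned] = noise[:, ~assigned]  # unassigned: unit-variance pure noise

    effects = config.effect_vector_per_module()
    affected = diagnosis == config.effect_group
    true_effect = np.zeros(p)
    for m, eff in effects.items():
        cols = labels == m
        true_effect[cols] = eff
        z[np.ix_(affected, cols)] += eff

    b = np.exp(
        rng.uniform(np.log(config.baseline_range[0]), np.log(config.baseline_range[1]), size=p)
    )
    lib = np.exp(
        rng.uniform(np.log(config.libsize_range[0]), np.log(config.libsize_range[1]), size=n)
    )
    mu = lib[:, None] * b[None, :] * np.exp(config.latent_scale * z)

    alpha = config.nb_dispersion
    # numpy NB(n, p) has mean n(1-p)/p: n = 1/alpha, p = 1/(1 + alpha*mu).
    counts = rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu))

    tox = np.empty((n, config.n_tox), dtype=object)
    group_index = {g: k for k, g in enumerate(config.group_labels)}
    gi = np.array([group_index[d] for d in diagnosis])
    present = rng.random((n, config.n_tox)) < config.tox_assoc[gi, :]
    unknown = rng.random((n, config.n_tox)) < config.unknown_rate
    tox[:] = "absent"
    tox[present] = "present"
    tox[unknown] = "unknown"

    counts_df = pd.DataFrame(counts.T, index=gene_ids, columns=sample_ids)
    counts_df.index.name = "feature_id"
    samples = pd.DataFrame({"diagnosis": diagnosis}, index=sample_ids)
    samples.index.name = "sample_id"
    for j in range(config.n_tox):
        samples[f"tox{j + 1:02d}"] = tox[:, j]

    truth = SyntheticTruth(
        true_modules=pd.Series(labels, index=gene_ids, name="module_id"),
        true_effect=pd.Series(true_effect, index=gene_ids, name="true_effect"),
        affected_group=config.effect_group,
        tox_assoc_used=config.tox_assoc.copy(),
    )
    return counts_df, samples, truth


def null_config(base: SimulationConfig) -> SimulationConfig:
    """Null copy of a configuration: no diagnosis effect, group-balanced exposures.

    Under the returned config group labels are exchangeable, so any downstream
    test must be calibrated. Idempotent.
    """
    tox = np.tile(base.tox_assoc.mean(axis=0), (len(base.n_per_group), 1))
    return dataclasses.replace(base, effect_size=0.0, effect_modules=(), tox_assoc=tox)
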