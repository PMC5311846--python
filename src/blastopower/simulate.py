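"""Gaussian generative model for single-cell expression on a blastocyst design.

Each gene's expression for sample *i* is

    Y_i = baseline + a[T_i] + c[C_i] + b[B_i] + e_i

with ``a`` the treatment level means, ``c`` the cell-type level means,
``b[B] ~ N(0, blastocyst_sd^2)`` drawn once per blastocyst, and
``e_i ~ N(0, error_sd^2)`` independent per sample. Level means are equally
spaced: a spacing ("unstandardized effect size") of delta places the four
levels at 0, delta, 2*delta, 3*delta, so all four groups differ whenever
delta > 0. Cohen's d for adjacent groups is delta / error_sd; with the
default error SD of 10, a spacing of 1 is d = 0.1 and a spacing of 10 is
d = 1.

Multivariate panels draw genes independently; for differentially expressed
(DE) genes the mapping of treatment levels to effect magnitudes can be
permuted per gene, which models the realistic situation where genes do not
all shift in the same direction between treatments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .design import CELL_TYPES, TREATMENTS, validate_design

__all__ = [
    "SimulationParams",
    "ScenarioPreset",
    "ExpressionMatrix",
    "GeneSimulator",
    "effect_vector",
    "standardize_effect",
    "simulate_gene",
    "simulate_dataset",
]

#: Error standard deviation shared by all default simulations, derived in the
#: source study from the median gene-expression variance of the real data.
DEFAULT_ERROR_SD = 10.0


class ParameterError(ValueError):
    """Raised for invalid generative parameters."""


@dataclass(frozen=True)
class SimulationParams:
    """Generative constants for one simulation setting.

    All quantities are on the (continuous, Gaussian) expression scale.
    ``treatment_spacing`` is the unstandardized treatment effect size
    (adjacent-level mean difference); ``celltype_spacing`` plays the same
    role for cell types and defaults to a small effect (d = 0.1).
    ``blastocyst_sd`` defaults to the error SD: both variance components
    trace back to the same median-variance estimate.
    """

    treatment_spacing: float = 0.0
    celltype_spacing: float = 1.0
    error_sd: float = DEFAULT_ERROR_SD
    blastocyst_sd: float = DEFAULT_ERROR_SD
    baseline_mean: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.error_sd <= 0:
            raise ParameterError(f"error_sd must be > 0, got {self.error_sd}")
        if self.blastocyst_sd < 0:
            raise ParameterError(f"blastocyst_sd must be >= 0, got {self.blastocyst_sd}")
        if self.treatment_spacing < 0 or self.celltype_spacing < 0:
            raise ParameterError("effect spacings must be >= 0")

    def with_spacing(self, treatment_spacing: float) -> "SimulationParams":
        return replace(self, treatment_spacing=treatment_spacing)


@dataclass(frozen=True)
class ScenarioPreset:
    """A multivariate scenario: panel size, DE fraction, DE effect size."""

    n_genes: int
    de_fraction: float
    cohens_d: float
    permute_treatment_order: bool = True
    permute_celltype_order: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.de_fraction <= 1:
            raise ParameterError(f"de_fraction must be in [0, 1], got {self.de_fraction}")
        if self.n_genes < 1:
            raise ParameterError("n_genes must be >= 1")

    @property
    def n_de(self) -> int:
        """Number of DE genes: round(n_genes * de_fraction)."""
        return int(round(self.n_genes * self.de_fraction))


#: Scenario behind the 10%-DE, d = 0.1 score plot (1200 of 12,000 genes DE).
FIG3_PRESET = ScenarioPreset(n_genes=12_000, de_fraction=0.10, cohens_d=0.1)
#: Scenario behind the 1%-DE, d = 0.5 score plot (120 of 12,000 genes DE).
FIG4_PRESET = ScenarioPreset(n_genes=12_000, de_fraction=0.01, cohens_d=0.5)


@dataclass
class ExpressionMatrix:
    """Simulated panel: samples x genes values plus per-gene metadata.

    ``values`` is indexed by sample_id with one column per gene;
    ``gene_meta`` has columns gene_id, is_de, treatment_permutation (the
    level order used for that gene, '|'-joined).
    """

    values: pd.DataFrame
    gene_meta: pd.DataFrame
    design: pd.DataFrame

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_csv(self, values_path, meta_path) -> None:
        self.values.to_csv(values_path, index=True, index_label="sample_id")
        self.gene_meta.to_csv(meta_path, index=False)


def effect_vector(spacing: float) -> np.ndarray:
    """Equally spaced level means (0, s, 2s, 3s) in canonical level order."""
    if spacing < 0:
        raise ParameterError(f"spacing must be >= 0, got {spacing}")
    return np.arange(4, dtype=float) * float(spacing)


def standardize_effect(spacing: float, error_sd: float = DEFAULT_ERROR_SD) -> float:
    """Cohen's d for an unstandardized spacing: spacing / error_sd."""
    if error_sd <= 0:
        raise ParameterError(f"error_sd must be > 0, got {error_sd}")
    return float(spacing) / float(error_sd)


def _level_codes(design: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    t = pd.Categorical(design["treatment"], categories=TREATMENTS).codes
    c = pd.Categorical(design["cell_type"], categories=CELL_TYPES).codes
    b = pd.Categorical(design["blastocyst_id"]).codes
    return t.astype(int), c.astype(int), b.astype(int), int(b.max()) + 1


def _order_to_rank(order: Sequence[str]) -> np.ndarray:
    """Map canonical treatment index -> effect rank under the given order."""
    order = list(order)
    if sorted(order) != sorted(TREATMENTS):
        raise ParameterError(f"treatment order must be a permutation of {TREATMENTS}, got {order}")
    return np.array([order.index(t) for t in TREATMENTS])


class GeneSimulator:
    """Per-design gene sampler with the level codes computed once.

    Useful when many genes are drawn on the same design (power batches,
    multivariate panels); validates the design a single time.
    """

    def __init__(self, design: pd.DataFrame):
        diag = validate_design(design)
        if not diag.is_valid:
            raise ParameterError(f"invalid design: {diag.violations}")
        self.design = design
        self._t, self._c, self._b, self.n_blastocysts = _level_codes(design)
        self.n_samples = len(design)

    def draw(
        self,
        params: SimulationParams,
        rng: np.random.Generator,
        treatment_level_order: Sequence[str] | None = None,
    ) -> np.ndarray:
        a = effect_vector(params.treatment_spacing)
        cvec = effect_vector(params.celltype_spacing)
        rank = _order_to_rank(
            treatment_level_order if treatment_level_order is not None else TREATMENTS
        )
        blast_effects = rng.normal(0.0, params.blastocyst_sd, size=self.n_blastocysts)
        noise = rng.normal(0.0, params.error_sd, size=self.n_samples)
        return params.baseline_mean + a[rank[self._t]] + cvec[self._c] + blast_effects[self._b] + noise


def simulate_gene(
    design: pd.DataFrame,
    params: SimulationParams,
    rng: np.random.Generator,
    treatment_level_order: Sequence[str] | None = None,
) -> np.ndarray:
    """Simulate one gene's expression vector, index-aligned to ``design``.

    ``treatment_level_order`` controls which treatment gets which of the
    equally spaced effect magnitudes: position k in the order receives
    magnitude k * spacing. Default is the canonical order.
    """
    return GeneSimulator(design).draw(params, rng, treatment_level_order)


def simulate_dataset(
    design: pd.DataFrame,
    preset: ScenarioPreset,
    params: SimulationParams,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    """Simulate a multivariate panel under a scenario preset.

    Exactly ``preset.n_de`` genes receive treatment spacing
    ``cohens_d * error_sd`` (the first ``n_de`` columns); the rest receive
    zero treatment effect. With ``permute_treatment_order`` set, each DE
    gene uses an independent uniformly random permutation of the four
    treatment levels, recorded in the metadata. Blastocyst and error draws
    are independent across genes.
    """
    diag = validate_design(design)
    if not diag.is_valid:
        raise ParameterError(f"invalid design: {diag.violations}")
    de_spacing = preset.cohens_d * params.error_sd
    n_de = preset.n_de

    t, c, b, n_blast = _level_codes(design)
    n = len(design)
    cvec_canonical = effect_vector(params.celltype_spacing)
    identity = np.arange(4)

    values = np.empty((n, preset.n_genes))
    meta_rows = []
    for g in range(preset.n_genes):
        is_de = g < n_de
        if preset.permute_treatment_order and is_de:
            perm = rng.permutation(4)
            order = [TREATMENTS[i] for i in perm]
            t_rank = _order_to_rank(order)
        else:
            order = list(TREATMENTS)
            t_rank = identity
        if preset.permute_celltype_order:
            c_rank = np.argsort(rng.permutation(4))
        else:
            c_rank = identity
        a = effect_vector(de_spacing if is_de else 0.0)
        blast_effects = rng.normal(0.0, params.blastocyst_sd, size=n_blast)
        noise = rng.normal(0.0, params.error_sd, size=n)
        values[:, g] = (
            params.baseline_mean + a[t_rank[t]] + cvec_canonical[c_rank[c]] + blast_effects[b] + noise
        )
        meta_rows.append((f"g{g:05d}", is_de, "|".join(order)))

    gene_ids = [m[0] for m in meta_rows]
    vdf = pd.DataFrame(values, index=pd.Index(design["sample_id"], name="sample_id"), columns=gene_ids)
    meta = pd.DataFrame(meta_rows, columns=["gene_id", "is_de", "treatment_permutation"])
    return ExpressionMatrix(values=vdf, gene_meta=meta, design=design)
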