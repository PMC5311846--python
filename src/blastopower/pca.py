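"""PCA score plots of simulated panels and how much treatment they reveal.

The demonstration: simulate a 12,000-gene panel in which a known subset of
genes is genuinely differentially expressed between treatments, but with
the direction of the effect randomized from gene to gene (as it would be in
real data). A PC1/PC2 score plot of such a panel shows no treatment
clustering, even though per-gene tests detect the effects — visual
inspection of principal components is not a test.

Cluster separation is quantified with the mean silhouette coefficient of
the treatment labels on the first two component scores, a number in
[-1, 1] that is near zero when treatments do not cluster.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from ._rng import substream
from .simulate import ExpressionMatrix, ScenarioPreset, SimulationParams, simulate_dataset

__all__ = [
    "PCAResult",
    "SeparationScore",
    "run_pca",
    "treatment_silhouette",
    "run_scenario",
    "ScenarioResult",
]


@dataclass
class PCAResult:
    """Scores, loadings and explained-variance fractions of one PCA."""

    scores: pd.DataFrame  # samples x components, columns PC1..PCk
    components: np.ndarray  # components x genes loadings
    explained_variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class SeparationScore:
    """Mean silhouette of treatment labels on leading PC scores."""

    silhouette_mean: float
    n_components: int
    labels: str = "treatment"


def run_pca(matrix: ExpressionMatrix | pd.DataFrame, center: bool = True, scale: bool = False) -> PCAResult:
    """Gene-wise centered (optionally scaled) PCA via SVD.

    Returns all non-trivial components (at most ``n_samples - 1`` for a
    centered analysis). Component signs follow the convention that each
    component's largest-magnitude gene loading is positive, making scores
    reproducible across runs and platforms.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    X = np.asarray(values, dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError(f"need >= 2 samples and >= 2 genes, got {n} x {p}")
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            names = list(values.columns[zero[:5]]) if hasattr(values, "columns") else zero[:5].tolist()
            raise ValueError(f"zero-variance gene(s) cannot be scaled: {names}")
        X = X / sd

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # drop numerically null directions (e.g. the one lost to centering)
    tol = s.max() * max(n, p) * np.finfo(float).eps if s.size else 0.0
    k = int((s > tol).sum())
    k = min(k, n - 1 if center else n, p)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]

    # sign convention: largest-|loading| positive per component
    flip = np.sign(Vt[np.arange(k), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    scores = U * s * flip

    var = s**2 / (n - 1)
    total_var = (X**2).sum() / (n - 1)
    index = values.index if hasattr(values, "index") else pd.RangeIndex(n)
    scores_df = pd.DataFrame(scores, index=index, columns=[f"PC{i+1}" for i in range(k)])
    return PCAResult(
        scores=scores_df,
        components=Vt,
        explained_variance_fraction=var / total_var,
    )


def treatment_silhouette(
    pca: PCAResult,
    design: pd.DataFrame,
    n_components: int = 2,
    labels: str = "treatment",
) -> SeparationScore:
    """Mean silhouette of ``labels`` groups in the leading score space."""
    if pca.n_components < n_components:
        raise ValueError(f"PCA has {pca.n_components} components, need {n_components}")
    y = np.asarray(design[labels].astype(str))
    if len(np.unique(y)) < 2:
        raise ValueError("silhouette needs >= 2 groups")
    X = pca.scores.iloc[:, :n_components].to_numpy()
    s = float(silhouette_score(X, y, metric="euclidean"))
    return SeparationScore(silhouette_mean=s, n_components=n_components, labels=labels)


@dataclass
class ScenarioResult:
    matrix: ExpressionMatrix
    pca: PCAResult
    separation: SeparationScore
    artifact_paths: dict


def run_scenario(
    design: pd.DataFrame,
    preset: ScenarioPreset,
    params: SimulationParams,
    seed: int,
    out_dir=None,
) -> ScenarioResult:
    """Simulate a panel, run PCA, score treatment separation, persist plots.

    With ``out_dir`` set, writes the PC scores CSV, explained-variance CSV,
    silhouette JSON and two PC1/PC2 scatter plots (colored by treatment and
    by cell type).
    """
    rng = substream(seed, "pca-scenario")
    matrix = simulate_dataset(design, preset, params, rng)
    pca = run_pca(matrix)
    sep = treatment_silhouette(pca, design)

    paths: dict = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        scores = pca.scores.copy()
        scores.insert(0, "cell_type", np.asarray(design["cell_type"].astype(str)))
        scores.insert(0, "treatment", np.asarray(design["treatment"].astype(str)))
        paths["scores_csv"] = str(out / "pca_scores.csv")
        scores.to_csv(paths["scores_csv"], index=True, index_label="sample_id")
        paths["explained_variance_csv"] = str(out / "explained_variance.csv")
        pd.DataFrame(
            {
                "component": [f"PC{i+1}" for i in range(pca.n_components)],
                "explained_variance_fraction": pca.explained_variance_fraction,
            }
        ).to_csv(paths["explained_variance_csv"], index=False)
        paths["silhouette_json"] = str(out / "silhouette.json")
        Path(paths["silhouette_json"]).write_text(
            json.dumps(
                {
                    "silhouette_mean": sep.silhouette_mean,
                    "n_components": sep.n_components,
                    "labels": sep.labels,
                    "seed": seed,
                    "preset": {
                        "n_genes": preset.n_genes,
                        "de_fraction": preset.de_fraction,
                        "cohens_d": preset.cohens_d,
                        "permute_treatment_order": preset.permute_treatment_order,
                    },
                },
                indent=2,
            )
        )
        paths["plot_treatment"] = str(out / "pc1_pc2_by_treatment.png")
        paths["plot_cell_type"] = str(out / "pc1_pc2_by_cell_type.png")
        _scatter(pca, design, "treatment", paths["plot_treatment"])
        _scatter(pca, design, "cell_type", paths["plot_cell_type"])
    return ScenarioResult(matrix=matrix, pca=pca, separation=sep, artifact_paths=paths)


def _scatter(pca: PCAResult, design: pd.DataFrame, color_by: str, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    groups = design[color_by].astype(str)
    evf = pca.explained_variance_fraction
    for level in pd.unique(groups):
        mask = (groups == level).to_numpy()
        ax.scatter(pca.scores.iloc[mask, 0], pca.scores.iloc[mask, 1], label=level, s=30)
    ax.set_xlabel(f"PC1 ({100 * evf[0]:.1f}% var)")
    ax.set_ylabel(f"PC2 ({100 * evf[1]:.1f}% var)")
    ax.legend(title=color_by.replace("_", " "), fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
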