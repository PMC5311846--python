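"""Monte-Carlo power estimation over batches of simulated genes.

Power is estimated the way a transcriptomic screen experiences it: genes
are simulated in batches (default 100 genes per batch, standing in for a
100-gene analysis), each gene is tested with the mixed-model LRT, and the
batch's power is the fraction of significant tests at alpha. Batches are
repeated (default 100) and summarized as a mean with a normal-approximation
95% confidence interval across batch powers.

Two sweeps reproduce the study conditions:

* Set 1 — treatment effect sizes 1..10 on the 8-blastocyst reference
  design (32 samples);
* Set 2 — blastocyst counts 8, 48, 96, 144, 192, 240 at a fixed treatment
  effect size of 2.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .design import build_balanced_design
from .lmm import DesignMatrices, fit_lmm
from .simulate import GeneSimulator, SimulationParams

__all__ = [
    "PowerEstimate",
    "PowerSummary",
    "SweepResult",
    "estimate_power_batch",
    "summarize_batches",
    "run_set1",
    "run_set2",
]

logger = logging.getLogger(__name__)

SET1_EFFECT_SIZES = tuple(range(1, 11))
SET2_BLASTOCYST_COUNTS = (8, 48, 96, 144, 192, 240)
SET2_TREATMENT_SPACING = 2.0


class PowerSimulationError(RuntimeError):
    """Raised when a batch produces no usable fits."""


@dataclass(frozen=True)
class PowerEstimate:
    """Power from one batch: significant fraction among n_tests genes."""

    power: float
    n_tests: int
    alpha: float
    n_nonconverged: int = 0


@dataclass(frozen=True)
class PowerSummary:
    """Across-batch mean power with a 95% CI for one sweep setting."""

    setting: float
    mean_power: float
    ci_low: float
    ci_high: float
    n_batches: int


@dataclass
class SweepResult:
    """Ordered summaries for a sweep plus raw batch powers and config."""

    sweep_name: str
    summaries: list
    batch_powers: pd.DataFrame  # columns: setting, batch, power
    config: dict = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(s) for s in self.summaries])


def estimate_power_batch(
    design: pd.DataFrame,
    params: SimulationParams,
    n_genes: int,
    alpha: float,
    rng: np.random.Generator,
    matrices: DesignMatrices | None = None,
) -> PowerEstimate:
    """Simulate ``n_genes`` independent genes, test each, return the
    significant fraction.

    Non-converged fits count as non-significant (and are tallied); if every
    fit in the batch fails the batch is unusable and an error is raised.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    m = matrices if matrices is not None else DesignMatrices(design)
    sim = GeneSimulator(design)
    n_sig = 0
    n_bad = 0
    for _ in range(n_genes):
        y = sim.draw(params, rng)
        fit = fit_lmm(y, design, matrices=m)
        if not fit.converged:
            n_bad += 1
        elif fit.p_value < alpha:
            n_sig += 1
    if n_bad == n_genes:
        raise PowerSimulationError(
            f"all {n_genes} fits in batch failed to converge (seed state unusable)"
        )
    if n_bad:
        logger.warning("%d of %d fits non-converged; counted as non-significant", n_bad, n_genes)
    return PowerEstimate(power=n_sig / n_genes, n_tests=n_genes, alpha=alpha, n_nonconverged=n_bad)


def summarize_batches(estimates: Sequence[PowerEstimate], setting: float = 0.0) -> PowerSummary:
    """Mean of batch powers with a normal 95% CI, clamped to [0, 1].

    CI = mean +/- 1.96 * sd(batch powers) / sqrt(n_batches).
    """
    if len(estimates) < 2:
        raise ValueError("need >= 2 batch estimates for a confidence interval")
    p = np.array([e.power for e in estimates], dtype=float)
    mean = float(p.mean())
    se = float(p.std(ddof=1) / np.sqrt(len(p)))
    return PowerSummary(
        setting=float(setting),
        mean_power=mean,
        ci_low=max(0.0, mean - 1.96 * se),
        ci_high=min(1.0, mean + 1.96 * se),
        n_batches=len(p),
    )


def _run_sweep(
    sweep_name: str,
    settings: Sequence[float],
    design_for,
    params_for,
    n_batches: int,
    batch_size: int,
    alpha: float,
    seed: int,
    out_dir=None,
) -> SweepResult:
    rows = []
    summaries = []
    for s_idx, setting in enumerate(settings):
        design = design_for(setting)
        params = params_for(setting)
        matrices = DesignMatrices(design)
        batch_estimates = []
        for batch in range(n_batches):
            rng = substream(seed, sweep_name, s_idx, batch)
            try:
                est = estimate_power_batch(design, params, batch_size, alpha, rng, matrices)
            except PowerSimulationError as err:
                raise PowerSimulationError(
                    f"{sweep_name}: setting={setting} batch={batch} seed={seed}: {err}"
                ) from err
            batch_estimates.append(est)
            rows.append({"setting": setting, "batch": batch, "power": est.power})
        summaries.append(summarize_batches(batch_estimates, setting=setting))
    result = SweepResult(
        sweep_name=sweep_name,
        summaries=summaries,
        batch_powers=pd.DataFrame(rows),
        config={
            "sweep": sweep_name,
            "settings": [float(s) for s in settings],
            "n_batches": n_batches,
            "batch_size": batch_size,
            "alpha": alpha,
            "seed": seed,
            "ci_method": "normal approximation across batch powers, mean +/- 1.96*SE",
        },
    )
    if out_dir is not None:
        write_sweep_outputs(result, out_dir)
    return result


def run_set1(
    effect_sizes: Sequence[float] = SET1_EFFECT_SIZES,
    n_blastocysts: int = 8,
    n_batches: int = 100,
    batch_size: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    params: SimulationParams | None = None,
    out_dir=None,
) -> SweepResult:
    """Effect-size sweep on a fixed balanced design (Set 1)."""
    if any(e <= 0 for e in effect_sizes):
        raise ValueError("effect sizes must be positive")
    base = params if params is not None else SimulationParams()
    design = build_balanced_design(n_blastocysts)
    return _run_sweep(
        "set1",
        list(effect_sizes),
        design_for=lambda _: design,
        params_for=lambda e: base.with_spacing(float(e)),
        n_batches=n_batches,
        batch_size=batch_size,
        alpha=alpha,
        seed=seed,
        out_dir=out_dir,
    )


def run_set2(
    blastocyst_counts: Sequence[int] = SET2_BLASTOCYST_COUNTS,
    treatment_spacing: float = SET2_TREATMENT_SPACING,
    n_batches: int = 100,
    batch_size: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    params: SimulationParams | None = None,
    out_dir=None,
) -> SweepResult:
    """Blastocyst-count sweep at a fixed treatment effect size (Set 2)."""
    for c in blastocyst_counts:
        if c % 4 != 0:
            raise ValueError(f"blastocyst count {c} not divisible by 4")
    base = params if params is not None else SimulationParams()
    fixed = base.with_spacing(float(treatment_spacing))
    return _run_sweep(
        "set2",
        [int(c) for c in blastocyst_counts],
        design_for=lambda c: build_balanced_design(int(c)),
        params_for=lambda _: fixed,
        n_batches=n_batches,
        batch_size=batch_size,
        alpha=alpha,
        seed=seed,
        out_dir=out_dir,
    )


_AXIS_LABELS = {
    "set1": "Unstandardized treatment effect size",
    "set2": "Number of blastocysts",
}


def write_sweep_outputs(result: SweepResult, out_dir) -> dict:
    """Persist summary CSV, raw batch-power CSV, config JSON and the power plot."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    name = result.sweep_name
    paths = {
        "summary_csv": out / f"{name}_power_summary.csv",
        "raw_csv": out / f"{name}_batch_powers.csv",
        "config_json": out / f"{name}_config.json",
        "plot_png": out / f"{name}_power_curve.png",
    }
    result.summary_frame().to_csv(paths["summary_csv"], index=False)
    result.batch_powers.to_csv(paths["raw_csv"], index=False)
    paths["config_json"].write_text(json.dumps(result.config, indent=2, sort_keys=True))
    plot_power_curve(result, paths["plot_png"])
    return {k: str(v) for k, v in paths.items()}


def plot_power_curve(result: SweepResult, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.summary_frame()
    fig, ax = plt.subplots(figsize=(6, 4))
    yerr = np.vstack([df["mean_power"] - df["ci_low"], df["ci_high"] - df["mean_power"]])
    ax.errorbar(df["setting"], df["mean_power"], yerr=yerr, fmt="o-", capsize=3)
    ax.set_xlabel(_AXIS_LABELS.get(result.sweep_name, "setting"))
    ax.set_ylabel("Power (mean of batch estimates, 95% CI)")
    ax.set_ylim(-0.02, 1.02)
    ax.axhline(0.8, ls="--", lw=0.8, color="grey")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
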