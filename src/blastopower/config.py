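"""Run configuration, experiment dispatch and output manifests.

A run is fully described by a :class:`RunConfig`: which experiment
(``set1``, ``set2`` or ``pca``), the generative parameters, the sweep or
scenario settings, a master seed and an output directory. Configs are read
from YAML with precedence defaults < file < explicit overrides, echoed to
the log, persisted next to the outputs, and every output file is listed
with its SHA-256 hash in a manifest so any run can be re-derived.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .design import build_balanced_design
from .pca import run_scenario
from .power import run_set1, run_set2
from .simulate import ScenarioPreset, SimulationParams

__all__ = ["RunConfig", "ConfigError", "load_config", "run_experiment", "write_report"]

logger = logging.getLogger(__name__)

EXPERIMENTS = ("set1", "set2", "pca")

#: Named PCA scenario presets selectable from config.
PCA_PRESETS = {
    "fig3": dict(n_genes=12_000, de_fraction=0.10, cohens_d=0.1, permute_treatment_order=True),
    "fig4": dict(n_genes=12_000, de_fraction=0.01, cohens_d=0.5, permute_treatment_order=True),
}


class ConfigError(ValueError):
    """Raised for unknown keys or ill-typed config fields."""


@dataclass
class RunConfig:
    """Everything needed to reproduce one experiment run."""

    experiment: str = "set1"
    seed: int = 0
    out_dir: str = "results"
    # generative parameters
    treatment_spacing: float = 0.0
    celltype_spacing: float = 1.0
    error_sd: float = 10.0
    blastocyst_sd: float = 10.0
    baseline_mean: float = 0.0
    # design / sweep settings
    n_blastocysts: int = 8
    effect_sizes: list = field(default_factory=lambda: list(range(1, 11)))
    blastocyst_counts: list = field(default_factory=lambda: [8, 48, 96, 144, 192, 240])
    set2_spacing: float = 2.0
    n_batches: int = 100
    batch_size: int = 100
    alpha: float = 0.05
    # pca scenario
    pca_preset: str = "fig3"
    n_genes: int = 12_000
    de_fraction: float = 0.10
    cohens_d: float = 0.1
    permute_treatment_order: bool = True

    def params(self) -> SimulationParams:
        return SimulationParams(
            treatment_spacing=self.treatment_spacing,
            celltype_spacing=self.celltype_spacing,
            error_sd=self.error_sd,
            blastocyst_sd=self.blastocyst_sd,
            baseline_mean=self.baseline_mean,
            seed=self.seed,
        )

    def preset(self) -> ScenarioPreset:
        if self.pca_preset in PCA_PRESETS:
            return ScenarioPreset(**PCA_PRESETS[self.pca_preset])
        if self.pca_preset != "custom":
            raise ConfigError(
                f"unknown pca_preset {self.pca_preset!r}; choose from {sorted(PCA_PRESETS)} or 'custom'"
            )
        return ScenarioPreset(
            n_genes=self.n_genes,
            de_fraction=self.de_fraction,
            cohens_d=self.cohens_d,
            permute_treatment_order=self.permute_treatment_order,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELDS = {f.name: f for f in dataclasses.fields(RunConfig)}


def _coerce(name: str, value):
    f = _FIELDS[name]
    try:
        if f.type in ("int",) or name in ("seed", "n_blastocysts", "n_batches", "batch_size", "n_genes"):
            if isinstance(value, bool) or (isinstance(value, float) and value != int(value)):
                raise TypeError
            return int(value)
        if name in (
            "treatment_spacing", "celltype_spacing", "error_sd", "blastocyst_sd",
            "baseline_mean", "set2_spacing", "alpha", "de_fraction", "cohens_d",
        ):
            return float(value)
        if name == "permute_treatment_order":
            if not isinstance(value, bool):
                raise TypeError
            return value
        if name in ("effect_sizes", "blastocyst_counts"):
            return [int(v) if float(v) == int(v) else float(v) for v in value]
        return str(value)
    except (TypeError, ValueError):
        raise ConfigError(f"field {name!r} has invalid value {value!r}") from None


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig with precedence defaults < file < overrides.

    Unknown keys (in file or overrides) raise a :class:`ConfigError`
    listing them; type mismatches raise naming the field.
    """
    merged: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        merged.update(raw)
    if overrides:
        merged.update({k: v for k, v in overrides.items() if v is not None})

    unknown = sorted(set(merged) - set(_FIELDS))
    if unknown:
        raise ConfigError(f"unknown config key(s): {unknown}")
    cfg = RunConfig(**{k: _coerce(k, v) for k, v in merged.items()})
    if cfg.experiment not in EXPERIMENTS:
        raise ConfigError(f"experiment must be one of {EXPERIMENTS}, got {cfg.experiment!r}")
    logger.info("resolved config: %s", json.dumps(cfg.to_dict(), sort_keys=True))
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_experiment(config: RunConfig) -> dict:
    """Dispatch a configured run and write a manifest of its outputs.

    Returns the manifest dict (also written to ``manifest.json`` in the
    output directory). Raises before any computation if the output
    directory cannot be created/written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_probe"
    try:
        probe.write_text("ok")
        probe.unlink()
    except OSError as err:
        raise ConfigError(f"output directory {out} is not writable: {err}") from err

    t0 = time.time()
    params = config.params()
    if config.experiment == "set1":
        run_set1(
            effect_sizes=config.effect_sizes,
            n_blastocysts=config.n_blastocysts,
            n_batches=config.n_batches,
            batch_size=config.batch_size,
            alpha=config.alpha,
            seed=config.seed,
            params=params,
            out_dir=out,
        )
    elif config.experiment == "set2":
        run_set2(
            blastocyst_counts=config.blastocyst_counts,
            treatment_spacing=config.set2_spacing,
            n_batches=config.n_batches,
            batch_size=config.batch_size,
            alpha=config.alpha,
            seed=config.seed,
            params=params,
            out_dir=out,
        )
    else:
        design = build_balanced_design(config.n_blastocysts)
        run_scenario(design, config.preset(), params, seed=config.seed, out_dir=out)

    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))

    import numpy, pandas, scipy, sklearn, statsmodels

    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "experiment": config.experiment,
        "seed": config.seed,
        "config": config.to_dict(),
        "wall_time_s": round(time.time() - t0, 2),
        "versions": {
            "python": platform.python_version(),
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "statsmodels": statsmodels.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("run complete: %d artifacts in %s", len(files), out)
    return manifest


def write_report(run_dirs, path) -> str:
    """Assemble a Markdown summary pointing at the power curves and
    scenario plots of previous runs."""
    lines = ["# Simulation report", ""]
    for d in run_dirs:
        d = Path(d)
        mpath = d / "manifest.json"
        if not mpath.exists():
            lines.append(f"## {d} — no manifest found\n")
            continue
        manifest = json.loads(mpath.read_text())
        lines.append(f"## {manifest['experiment']} ({d})")
        lines.append(f"- seed: {manifest['seed']}")
        lines.append(f"- wall time: {manifest['wall_time_s']} s")
        for rel in sorted(manifest["files"]):
            if rel.endswith(".png"):
                lines.append(f"![{rel}]({d / rel})")
            elif rel.endswith(".csv") or rel.endswith(".json"):
                lines.append(f"- `{d / rel}`")
        lines.append("")
    text = "\n".join(lines)
    Path(path).write_text(text)
    return text
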