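"""Blastocyst-level experimental designs.

A design assigns each single-cell sample to a blastocyst, a treatment and a
cell type. Treatment is applied at the blastocyst level — all samples from
one blastocyst share a treatment — which is what makes the blastocyst, not
the cell, the unit of biological replication.

Designs are plain :class:`pandas.DataFrame` objects with columns
``sample_id``, ``blastocyst_id``, ``treatment``, ``cell_type``; the latter
two are ordered categoricals over the canonical levels below, which fixes
contrast coding downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TREATMENTS",
    "CELL_TYPES",
    "DESIGN_COLUMNS",
    "InvalidDesignError",
    "DesignDiagnostics",
    "build_balanced_design",
    "build_unbalanced_design",
    "hyslop_like_unbalanced_design",
    "validate_design",
    "read_design_csv",
    "write_design_csv",
]

#: Canonical treatment levels, reference level first.
TREATMENTS: tuple[str, ...] = ("control", "autologous", "homologous", "heterologous")

#: Canonical cell-type levels, reference level first.
CELL_TYPES: tuple[str, ...] = (
    "primitive endoderm",
    "epiblast",
    "trophectoderm",
    "ambiguous",
)

DESIGN_COLUMNS = ("sample_id", "blastocyst_id", "treatment", "cell_type")


class InvalidDesignError(ValueError):
    """Raised when a requested design violates a structural constraint."""


def _as_design_frame(rows: list[tuple[str, str, str, str]]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=list(DESIGN_COLUMNS))
    df["treatment"] = pd.Categorical(df["treatment"], categories=TREATMENTS, ordered=True)
    df["cell_type"] = pd.Categorical(df["cell_type"], categories=CELL_TYPES, ordered=True)
    return df


def build_balanced_design(n_blastocysts: int) -> pd.DataFrame:
    """Fully factorial balanced design.

    ``n_blastocysts`` must be divisible by 4; each treatment receives
    ``n_blastocysts / 4`` blastocysts and every blastocyst contributes one
    sample of each of the four cell types (4 samples). The construction is
    deterministic. The reference setting of 8 blastocysts yields 32 rows
    with 2 blastocysts per treatment.
    """
    n_blastocysts = int(n_blastocysts)
    if n_blastocysts <= 0:
        raise InvalidDesignError("n_blastocysts must be a positive integer")
    if n_blastocysts % 4 != 0:
        raise InvalidDesignError(
            f"n_blastocysts must be divisible by 4 (one block per treatment); got {n_blastocysts}"
        )
    per_treatment = n_blastocysts // 4
    rows = []
    sample = 0
    for b in range(n_blastocysts):
        treatment = TREATMENTS[b // per_treatment]
        bid = f"b{b:03d}"
        for cell_type in CELL_TYPES:
            rows.append((f"s{sample:04d}", bid, treatment, cell_type))
            sample += 1
    return _as_design_frame(rows)


def build_unbalanced_design(
    samples_per_blastocyst: Sequence[int],
    treatment_of_blastocyst: Sequence[str],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Design with a caller-chosen number of samples per blastocyst.

    Cell types are assigned by cycling through the canonical order, so a
    blastocyst with 6 samples has cell-type counts (2, 2, 1, 1). If ``rng``
    is given, the cycle start is rotated uniformly at random per blastocyst;
    otherwise every blastocyst starts at the first cell type.
    """
    counts = [int(c) for c in samples_per_blastocyst]
    treatments = list(treatment_of_blastocyst)
    if not counts or not treatments:
        raise InvalidDesignError("samples_per_blastocyst and treatment_of_blastocyst must be non-empty")
    if len(counts) != len(treatments):
        raise InvalidDesignError(
            f"length mismatch: {len(counts)} blastocyst counts vs {len(treatments)} treatments"
        )
    if any(c < 1 for c in counts):
        raise InvalidDesignError("every blastocyst must contribute at least 1 sample")
    unknown = sorted(set(treatments) - set(TREATMENTS))
    if unknown:
        raise InvalidDesignError(f"unknown treatment label(s): {unknown}; expected one of {TREATMENTS}")

    rows = []
    sample = 0
    for b, (count, treatment) in enumerate(zip(counts, treatments)):
        bid = f"b{b:03d}"
        start = int(rng.integers(4)) if rng is not None else 0
        for j in range(count):
            cell_type = CELL_TYPES[(start + j) % 4]
            rows.append((f"s{sample:04d}", bid, treatment, cell_type))
            sample += 1
    return _as_design_frame(rows)


def hyslop_like_unbalanced_design(rng: np.random.Generator) -> pd.DataFrame:
    """Preset approximating the real study's replication structure.

    10 blastocysts with per-blastocyst sample counts drawn uniformly from
    1-11. The exact treatment breakdown of the 10 sequenced blastocysts is
    not published; we allocate 3 control / 1 autologous / 1 homologous /
    5 heterologous, keeping the single procedural controls and the
    heterologous-heavy imbalance of the study.
    """
    counts = rng.integers(1, 12, size=10).tolist()
    treatments = (
        ["control"] * 3 + ["autologous"] + ["homologous"] + ["heterologous"] * 5
    )
    return build_unbalanced_design(counts, treatments, rng=rng)


@dataclass
class DesignDiagnostics:
    """Counts and invariant violations for a design table."""

    n_samples: int
    n_blastocysts: int
    samples_per_treatment: dict = field(default_factory=dict)
    samples_per_cell_type: dict = field(default_factory=dict)
    samples_per_blastocyst: dict = field(default_factory=dict)
    violations: list = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.violations


def validate_design(design: pd.DataFrame) -> DesignDiagnostics:
    """Check design invariants, reporting violations instead of raising."""
    violations: list[str] = []
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        return DesignDiagnostics(0, 0, violations=[f"missing columns: {missing}"])
    if len(design) == 0:
        return DesignDiagnostics(0, 0, violations=["no samples"])

    if design["sample_id"].duplicated().any():
        violations.append("duplicate sample_id")
    bad_t = sorted(set(design["treatment"].astype(str)) - set(TREATMENTS))
    if bad_t:
        violations.append(f"unknown treatment label(s): {bad_t}")
    bad_c = sorted(set(design["cell_type"].astype(str)) - set(CELL_TYPES))
    if bad_c:
        violations.append(f"unknown cell_type label(s): {bad_c}")

    per_blast_treat = design.groupby("blastocyst_id", observed=True)["treatment"].nunique()
    if (per_blast_treat > 1).any():
        offenders = per_blast_treat[per_blast_treat > 1].index.tolist()
        violations.append(f"treatment varies within blastocyst: {offenders}")

    return DesignDiagnostics(
        n_samples=len(design),
        n_blastocysts=design["blastocyst_id"].nunique(),
        samples_per_treatment=design["treatment"].astype(str).value_counts().to_dict(),
        samples_per_cell_type=design["cell_type"].astype(str).value_counts().to_dict(),
        samples_per_blastocyst=design.groupby("blastocyst_id", observed=True).size().to_dict(),
        violations=violations,
    )


def write_design_csv(design: pd.DataFrame, path) -> None:
    design.to_csv(path, index=False)


def read_design_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "blastocyst_id": str})
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidDesignError(f"design CSV missing columns: {missing}")
    return _as_design_frame(list(df[list(DESIGN_COLUMNS)].itertuples(index=False, name=None)))
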