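"""Odds-space integration of a standardized polygenic score with baseline
10-year fracture probabilities.

A baseline absolute probability p (e.g. from the FRAX tool) is converted to
odds o = p/(1-p), divided by factor**z where z is the standardized
polygenic score (gSOS) and the factor is the per-SD odds ratio of the
underlying skeletal trait (1.42 for major osteoporotic fracture, 1.80 for
hip fracture), and converted back: an individual one SD above the mean gets
factor-fold *decreased* odds, one SD below gets factor-fold increased odds.
The transformation is exactly invertible and the per-SD odds change is an
algebraic identity, not an approximation.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MOF_FACTOR = 1.42
HIP_FACTOR = 1.80


@dataclasses.dataclass
class AdjustmentSpec:
    """Per-outcome odds-space adjustment parameters."""

    outcome: str  # "mof" or "hip"
    factor: float = MOF_FACTOR
    clip_eps: float = 1e-6

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError(f"factor must be positive; got {self.factor}")
        if not (0 < self.clip_eps < 0.5):
            raise ValueError(f"clip_eps must be in (0, 0.5); got {self.clip_eps}")


MOF_SPEC = AdjustmentSpec("mof", MOF_FACTOR)
HIP_SPEC = AdjustmentSpec("hip", HIP_FACTOR)


def standardize_scores(
    raw: np.ndarray,
    mean: float | None = None,
    sd: float | None = None,
) -> np.ndarray:
    """Center and scale to mean 0, sample (n-1) standard deviation 1.

    Per-cohort standardization is the default; pass ``mean`` and ``sd``
    (e.g. from a training cohort) to reuse external parameters instead.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size < 2:
        raise ValueError("need at least 2 individuals to standardize")
    if mean is None:
        mean = raw.mean()
    if sd is None:
        sd = raw.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant score (zero variance)")
    return (raw - mean) / sd


def adjust_probability(
    p: np.ndarray | float,
    z: np.ndarray | float,
    spec: AdjustmentSpec = MOF_SPEC,
) -> np.ndarray | float:
    """Apply the odds-space adjustment: (o / f**z) / (1 + o / f**z).

    Probabilities at or beyond the open interval (0,1) boundaries are
    clamped to [clip_eps, 1-clip_eps] and logged; anything outside [0,1] is
    rejected.
    """
    p_arr = np.asarray(p, dtype=float)
    z_arr = np.asarray(z, dtype=float)
    if np.any(p_arr < 0) or np.any(p_arr > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    n_clamped = int(np.sum((p_arr < spec.clip_eps) | (p_arr > 1 - spec.clip_eps)))
    if n_clamped:
        logger.warning(
            "clamped %d boundary probabilit%s to [%g, %g]",
            n_clamped,
            "y" if n_clamped == 1 else "ies",
            spec.clip_eps,
            1 - spec.clip_eps,
        )
    pc = np.clip(p_arr, spec.clip_eps, 1 - spec.clip_eps)
    odds = pc / (1 - pc)
    adj = odds / spec.factor**z_arr
    out = adj / (1 + adj)
    if np.isscalar(p) and np.isscalar(z):
        return float(out)
    return out


def adjust_cohort(
    cohort: pd.DataFrame,
    z: np.ndarray,
    mof_spec: AdjustmentSpec = MOF_SPEC,
    hip_spec: AdjustmentSpec = HIP_SPEC,
) -> pd.DataFrame:
    """Add frax_gsos_mof / frax_gsos_hip columns; originals are untouched."""
    z = np.asarray(z, dtype=float)
    if len(z) != len(cohort):
        raise ValueError(
            f"score length {len(z)} does not match cohort length {len(cohort)}"
        )
    out = cohort.copy()
    out["frax_gsos_mof"] = adjust_probability(
        cohort["frax_mof"].to_numpy(), z, mof_spec
    )
    out["frax_gsos_hip"] = adjust_probability(
        cohort["frax_hip"].to_numpy(), z, hip_spec
    )
    return out
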