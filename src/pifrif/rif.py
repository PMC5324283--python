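"""Regulatory Impact Factor (RIF) differential-connectivity scoring.

RIF detects regulators (typically transcription factors) whose wiring to a
set of differentially expressed target genes changes between two
conditions, even when the regulator's own expression does not. For
regulator r and the n_DE extreme-PIF target genes j = 1..n_DE:

    RIF1_r = (1/n_DE) * sum_j  x_j * d_j * DC_rj^2
    RIF2_r = (1/n_DE) * sum_j [ (x_j^HFE * r_rj^HFE)^2 - (x_j^LFE * r_rj^LFE)^2 ]

where x_j is the target's average expression over all samples, d_j its DE
(M value), r_rj^HFE and r_rj^LFE the within-group Pearson correlations
between regulator and target, and DC_rj = r_rj^HFE - r_rj^LFE the
differential co-expression. Raw scores are z-standardised across
regulators and extreme scores flagged; the scores say nothing about
activation versus repression, only that the regulator's connectivity
differs between states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrices import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

HFE = "HFE"
LFE = "LFE"


def _group_correlations(
    reg_vals: np.ndarray, tgt_vals: np.ndarray
) -> np.ndarray:
    """Pearson correlations between each regulator row and each target row.

    Zero-variance rows contribute r = 0 (logged) rather than NaN, keeping the
    differential co-expression defined.
    """
    n = reg_vals.shape[1]

    def _standardize(x: np.ndarray) -> tuple[np.ndarray, int]:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        flat = (sd == 0).sum()
        safe = np.where(sd == 0, 1.0, sd)
        z = (x - mu) / safe
        z[np.broadcast_to(sd == 0, z.shape)] = 0.0
        return z, int(flat)

    zr, flat_r = _standardize(reg_vals)
    zt, flat_t = _standardize(tgt_vals)
    if flat_r or flat_t:
        logger.warning(
            "zero-variance vectors within group: %d regulators, %d targets; "
            "their correlations set to 0",
            flat_r,
            flat_t,
        )
    r = zr @ zt.T / n
    return np.clip(r, -1.0, 1.0)


@dataclass
class RIFInputs:
    """Everything the two RIF formulae consume, aligned on ordered ids."""

    regulators: list[str]
    targets: list[str]
    x: np.ndarray  # per-target mean expression over all samples
    d: np.ndarray  # per-target DE (M)
    x_hfe: np.ndarray
    x_lfe: np.ndarray
    r_hfe: np.ndarray  # regulators x targets
    r_lfe: np.ndarray

    def __post_init__(self) -> None:
        R, T = len(self.regulators), len(self.targets)
        for name in ("x", "d", "x_hfe", "x_lfe"):
            if getattr(self, name).shape != (T,):
                raise ValidationError(f"{name} must have one entry per target")
        for name in ("r_hfe", "r_lfe"):
            mat = getattr(self, name)
            if mat.shape != (R, T):
                raise ValidationError(f"{name} must be regulators x targets")
            if np.abs(mat).max(initial=0.0) > 1 + 1e-9:
                raise ValidationError(f"{name} has entries outside [-1, 1]")

    @property
    def dc(self) -> np.ndarray:
        """Differential co-expression DC_rj = r^HFE - r^LFE."""
        return self.r_hfe - self.r_lfe


def condition_correlations(
    em: ExpressionMatrix, regulators: list[str], targets: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Within-group regulator-target Pearson correlation matrices."""
    missing = (set(regulators) | set(targets)) - set(em.gene_ids)
    if missing:
        raise ValidationError(
            f"ids absent from expression matrix: {sorted(missing)[:10]}"
        )
    out = []
    for group in (HFE, LFE):
        samples = em.samples_in(group)
        if len(samples) < 3:
            raise ValidationError(
                f"group {group} has {len(samples)} samples; need >= 3"
            )
        sub = em.values[samples]
        out.append(
            _group_correlations(
                sub.loc[regulators].to_numpy(float), sub.loc[targets].to_numpy(float)
            )
        )
    return out[0], out[1]


def build_rif_inputs(
    em: ExpressionMatrix,
    det: pd.DataFrame,
    regulators: list[str],
    targets: list[str],
    exclude_self_pairs: bool = False,
) -> RIFInputs:
    """Assemble RIF inputs from the expression matrix and DE table.

    ``x`` is each target's mean over all samples. Regulators that are
    themselves targets are kept in both roles by default (their self-pair
    contributes DC = 0 to RIF1); ``exclude_self_pairs`` drops such
    regulators from the target list instead.
    """
    if not targets:
        raise ValidationError("empty target set")
    if not regulators:
        raise ValidationError("empty regulator set")
    if exclude_self_pairs:
        targets = [t for t in targets if t not in set(regulators)]
        if not targets:
            raise ValidationError("no targets left after excluding self-pairs")
    missing = set(targets) - set(det.index)
    if missing:
        raise ValidationError(f"targets absent from DE table: {sorted(missing)[:10]}")
    r_hfe, r_lfe = condition_correlations(em, regulators, targets)
    sub = det.loc[targets]
    return RIFInputs(
        regulators=list(regulators),
        targets=list(targets),
        x=em.values.loc[targets].mean(axis=1).to_numpy(float),
        d=sub["m"].to_numpy(float),
        x_hfe=sub["x_hfe"].to_numpy(float),
        x_lfe=sub["x_lfe"].to_numpy(float),
        r_hfe=r_hfe,
        r_lfe=r_lfe,
    )


def compute_rif1(inputs: RIFInputs) -> np.ndarray:
    """RIF1_r = mean over targets of x_j * d_j * DC_rj^2."""
    n_de = len(inputs.targets)
    if n_de == 0:
        raise ValidationError("n_DE = 0")
    return (inputs.dc**2) @ (inputs.x * inputs.d) / n_de


def compute_rif2(inputs: RIFInputs) -> np.ndarray:
    """RIF2_r = mean over targets of (x_j^HFE r_rj^HFE)^2 - (x_j^LFE r_rj^LFE)^2."""
    n_de = len(inputs.targets)
    if n_de == 0:
        raise ValidationError("n_DE = 0")
    hi = (inputs.x_hfe[None, :] * inputs.r_hfe) ** 2
    lo = (inputs.x_lfe[None, :] * inputs.r_lfe) ** 2
    return (hi - lo).mean(axis=1)


def _zscore(v: np.ndarray, label: str) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        logger.warning("%s has zero spread across regulators; z set to 0", label)
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def standardize_and_flag(
    regulators: list[str],
    rif1_raw: np.ndarray,
    rif2_raw: np.ndarray,
    threshold: float = 1.96,
) -> pd.DataFrame:
    """z-score both metrics across regulators and flag |z| >= threshold.

    The threshold is an exploration aid for picking extreme regulators from
    the RIF1-vs-RIF2 scatter, not a significance claim.
    """
    if len(regulators) < 2:
        raise ValidationError("need at least 2 regulators to standardise")
    z1 = _zscore(np.asarray(rif1_raw, float), "RIF1")
    z2 = _zscore(np.asarray(rif2_raw, float), "RIF2")
    out = pd.DataFrame(
        {
            "regulator": regulators,
            "rif1_raw": rif1_raw,
            "rif2_raw": rif2_raw,
            "rif1_z": z1,
            "rif2_z": z2,
        }
    ).set_index("regulator")
    out["outlier"] = (np.abs(z1) >= threshold) | (np.abs(z2) >= threshold)
    return out


def rif_analysis(
    em: ExpressionMatrix,
    det: pd.DataFrame,
    regulators: list[str],
    targets: list[str],
    threshold: float = 1.96,
    exclude_self_pairs: bool = False,
) -> pd.DataFrame:
    """Full RIF table for a regulator list against a target list."""
    inputs = build_rif_inputs(
        em, det, regulators, targets, exclude_self_pairs=exclude_self_pairs
    )
    return standardize_and_flag(
        inputs.regulators,
        compute_rif1(inputs),
        compute_rif2(inputs),
        threshold=threshold,
    )
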