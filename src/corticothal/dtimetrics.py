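"""Diffusion-tensor scalar metrics.

A log-linear least-squares tensor fit maps diffusion-weighted signals
``S = S0 exp(-b g' D g)`` to the six unique tensor components; eigenvalues
then yield the standard scalars

    MD = (l1 + l2 + l3) / 3          mean diffusivity
    AD = l1                          axial diffusivity
    RD = (l2 + l3) / 2               radial diffusivity
    FA = sqrt(3/2) * ||l - MD|| / ||l||   fractional anisotropy in [0, 1]

with eigenvalues sorted descending. The log-linear fit is exactly
invertible on noise-free signals, which makes round-trip testing sharp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MAX_CONDITION_NUMBER = 1e8
SCALAR_NAMES = ("FA", "MD", "AD", "RD")


@dataclass(frozen=True)
class DiffusionProtocol:
    """Acquisition protocol: b-values (s/mm^2) and unit gradient directions."""

    b_values: np.ndarray  # (n,)
    directions: np.ndarray  # (n, 3), unit norm for b > 0

    def __post_init__(self):
        b = np.asarray(self.b_values, dtype=float)
        g = np.asarray(self.directions, dtype=float)
        if g.shape != (b.shape[0], 3):
            raise ValueError(
                f"directions shape {g.shape} does not match {b.shape[0]} b-values"
            )
        dw = b > 0
        norms = np.linalg.norm(g[dw], axis=1)
        if dw.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("diffusion-weighted directions must be unit vectors")
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "directions", g)

    @property
    def n_measurements(self) -> int:
        return self.b_values.shape[0]


@dataclass(frozen=True)
class TensorFit:
    """Fitted tensors (..., 3, 3), S0 estimates, and a clipped-signal count."""

    tensors: np.ndarray
    s0: np.ndarray
    n_clipped: int


def design_matrix(protocol: DiffusionProtocol) -> np.ndarray:
    """(n, 7) log-linear design: [1, -b gx^2, -b gy^2, -b gz^2, -2b gxgy, -2b gxgz, -2b gygz]."""
    b = protocol.b_values
    g = protocol.directions
    x = np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )
    cond = np.linalg.cond(x)
    if cond > MAX_CONDITION_NUMBER or x.shape[0] < 7:
        raise ValueError(
            f"rank-deficient diffusion design (condition number {cond:.3g}); "
            "at least 6 unique non-collinear directions plus b=0 are required"
        )
    return x


def _components_to_tensor(d: np.ndarray) -> np.ndarray:
    """(..., 6) [Dxx, Dyy, Dzz, Dxy, Dxz, Dyz] -> symmetric (..., 3, 3)."""
    t = np.empty(d.shape[:-1] + (3, 3))
    t[..., 0, 0] = d[..., 0]
    t[..., 1, 1] = d[..., 1]
    t[..., 2, 2] = d[..., 2]
    t[..., 0, 1] = t[..., 1, 0] = d[..., 3]
    t[..., 0, 2] = t[..., 2, 0] = d[..., 4]
    t[..., 1, 2] = t[..., 2, 1] = d[..., 5]
    return t


def fit_tensor_loglinear(signals: np.ndarray, protocol: DiffusionProtocol) -> TensorFit:
    """Log-linear least-squares tensor fit, vectorized over voxels.

    ``signals`` has shape (..., n_measurements). Non-positive signals are
    clipped to machine epsilon before the log transform and counted in
    ``n_clipped``.
    """
    s = np.asarray(signals, dtype=float)
    if s.shape[-1] != protocol.n_measurements:
        raise ValueError(
            f"signals last axis {s.shape[-1]} != protocol measurements "
            f"{protocol.n_measurements}"
        )
    x = design_matrix(protocol)
    n_clipped = int((s <= 0).sum())
    if n_clipped:
        logger.warning("clipped %d non-positive signal value(s) before log", n_clipped)
    log_s = np.log(np.maximum(s, np.finfo(float).eps))
    flat = log_s.reshape(-1, protocol.n_measurements)
    beta, *_ = np.linalg.lstsq(x, flat.T, rcond=None)
    beta = beta.T.reshape(s.shape[:-1] + (7,))
    return TensorFit(
        tensors=_components_to_tensor(beta[..., 1:]),
        s0=np.exp(beta[..., 0]),
        n_clipped=n_clipped,
    )


def tensor_eigenvalues(tensors: np.ndarray) -> np.ndarray:
    """Eigenvalues of symmetric tensors, sorted descending along the last axis."""
    return np.linalg.eigvalsh(tensors)[..., ::-1]


def tensor_scalars(eigenvalues: np.ndarray, clip_negative: bool = True) -> dict:
    """Scalar maps from descending eigenvalues.

    Negative eigenvalues (noisy fits) are clipped to 0 for the scalar
    computation and counted under the ``n_negative_clipped`` key. All-zero
    eigenvalues give FA = 0 by definition.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.shape[-1] != 3:
        raise ValueError("eigenvalues must have a last axis of length 3")
    if np.any(lam[..., :-1] < lam[..., 1:] - 1e-12 * np.abs(lam[..., :-1])):
        raise ValueError("eigenvalues must be sorted in descending order")
    n_neg = int((lam < 0).sum())
    if clip_negative and n_neg:
        logger.warning("clipped %d negative eigenvalue(s) to 0", n_neg)
        lam = np.clip(lam, 0.0, None)
    md = lam.mean(axis=-1)
    ad = lam[..., 0]
    rd = lam[..., 1:].mean(axis=-1)
    dev = lam - md[..., None]
    num = np.sqrt((dev**2).sum(axis=-1))
    den = np.sqrt((lam**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    fa = np.clip(fa, 0.0, 1.0)
    return {
        "FA": fa,
        "MD": md,
        "AD": ad,
        "RD": rd,
        "n_negative_clipped": n_neg,
    }


def roi_metric_means(scalar_maps: dict, roi_masks: dict) -> pd.DataFrame:
    """Masked arithmetic means of each scalar map per ROI (tidy long table)."""
    rows = []
    for roi, mask in roi_masks.items():
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError(f"ROI {roi!r} is empty")
        for metric in SCALAR_NAMES:
            m = np.asarray(scalar_maps[metric])
            if mask.shape != m.shape:
                raise ValueError(
                    f"ROI {roi!r} grid {mask.shape} does not match map {m.shape}"
                )
            rows.append({"roi": roi, "metric": metric, "value": float(m[mask].mean())})
    return pd.DataFrame(rows)
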