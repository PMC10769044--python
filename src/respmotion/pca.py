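"""Principal-axis extraction and 1-D projection of respiratory motion.

The respiration-induced displacement of a clamped vertebral tracker is
essentially one-dimensional: the positional covariance of a recording has a
dominant eigenvector (PC1) whose eigenvalue exceeds the second by a factor
of at least six in the clinical regime. Projecting the centred positions
onto PC1 compresses the 3-D trajectory to a scalar respiration signal;
back-projection maps a scalar displacement (or residual) to per-axis
millimetre components in the camera frame.

Covariance uses the population (1/n) normalisation. Projection centres the
data first; the constant offset is retained in ``PrincipalFrame.mean`` so
the map is lossless for on-axis motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PrincipalFrame",
    "ScalarSignal",
    "covariance",
    "principal_frame",
    "project",
    "back_project",
    "explained_ratios",
]


class DegenerateDataError(ValueError):
    """All-zero variance where a direction of motion is required."""


@dataclass(frozen=True)
class ScalarSignal:
    """A 1-D respiration signal with its affine normalisation parameters.

    ``values`` are either raw millimetres (``normalized=False``, offset 0,
    scale 1) or normalised units where raw = values * scale + offset.
    ``label`` records provenance, e.g. ``"raw"`` or ``"augmented(0.1)"``.
    """

    values: np.ndarray
    offset: float = 0.0
    scale: float = 1.0
    label: str = "raw"
    normalized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("signal values must be 1-D")
        if not np.all(np.isfinite(values)):
            raise ValueError("signal values must be finite")
        if self.normalized and not self.scale > 0:
            raise ValueError("scale must be positive for a normalized signal")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PrincipalFrame:
    """Mean and eigendecomposition of a positional covariance.

    ``axes`` holds orthonormal eigenvectors as columns sorted by eigenvalue
    descending (column 0 is PC1); ``eigenvalues`` are the matching variances
    in mm².
    """

    mean: np.ndarray
    axes: np.ndarray  # 3x3, columns are eigenvectors
    eigenvalues: np.ndarray  # descending, >= 0

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        axes = np.asarray(self.axes, dtype=float)
        ev = np.asarray(self.eigenvalues, dtype=float)
        if mean.shape != (3,) or axes.shape != (3, 3) or ev.shape != (3,):
            raise ValueError("frame shapes must be (3,), (3,3), (3,)")
        if np.max(np.abs(axes.T @ axes - np.eye(3))) > 1e-9:
            raise ValueError("axes must be orthonormal within 1e-9")
        if np.any(np.diff(ev) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")
        if np.any(ev < -1e-12):
            raise ValueError("eigenvalues must be non-negative")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "axes", axes)
        object.__setattr__(self, "eigenvalues", np.clip(ev, 0.0, None))

    @property
    def primary_axis(self) -> np.ndarray:
        return self.axes[:, 0]


def covariance(positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and population (1/n) covariance of a 3 x n position matrix."""
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[0] != 3:
        raise ValueError(f"positions must be 3 x n, got {positions.shape}")
    n = positions.shape[1]
    if n < 2:
        raise ValueError("need at least 2 positions to estimate a covariance")
    mean = positions.mean(axis=1)
    dev = positions - mean[:, None]
    cov = (dev @ dev.T) / n
    return mean, 0.5 * (cov + cov.T)  # enforce exact symmetry


def principal_frame(mean: np.ndarray, cov: np.ndarray) -> PrincipalFrame:
    """Eigendecompose a symmetric PSD covariance into a PrincipalFrame.

    Eigenvalues are sorted descending (ties broken by stable sort on the
    eigensolver's order); each eigenvector's sign is fixed by forcing its
    largest-magnitude component positive, making the frame deterministic.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (3, 3):
        raise ValueError("covariance must be 3 x 3")
    if np.max(np.abs(cov - cov.T)) > 1e-9:
        raise ValueError("covariance must be symmetric within 1e-9")
    evals, evecs = np.linalg.eigh(0.5 * (cov + cov.T))
    order = np.argsort(-evals, kind="stable")
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for k in range(3):
        lead = int(np.argmax(np.abs(evecs[:, k])))
        if evecs[lead, k] < 0:
            evecs[:, k] = -evecs[:, k]
    return PrincipalFrame(mean=np.asarray(mean, dtype=float), axes=evecs, eigenvalues=evals)


def project(
    positions: np.ndarray, frame: PrincipalFrame, component: int = 0
) -> ScalarSignal:
    """Project centred positions onto one principal axis (mm, unnormalised).

    ``values[k] = v_component . (position_k - mean)`` — zero-mean by
    construction when the frame was fitted on the same data.
    """
    if component not in (0, 1, 2):
        raise ValueError(f"component must be 0, 1 or 2, got {component}")
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[0] != 3:
        raise ValueError(f"positions must be 3 x n, got {positions.shape}")
    values = frame.axes[:, component] @ (positions - frame.mean[:, None])
    return ScalarSignal(values=values, label=f"pc{component + 1}")


def back_project(signal: ScalarSignal, frame: PrincipalFrame) -> np.ndarray:
    """Map a millimetre-scale scalar signal back to 3 x n camera-frame positions.

    ``position_k = mean + values[k] * PC1``; exact inverse of :func:`project`
    for motion lying on the PC1 line.
    """
    if signal.normalized:
        raise ValueError("back_project requires an unnormalised (mm) signal")
    return frame.mean[:, None] + frame.primary_axis[:, None] * signal.values[None, :]


def explained_ratios(frame: PrincipalFrame) -> np.ndarray:
    """Fractions of total variance per principal component (descending, sum 1)."""
    total = float(frame.eigenvalues.sum())
    if total <= 0:
        raise DegenerateDataError("all eigenvalues are zero")
    return frame.eigenvalues / total
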