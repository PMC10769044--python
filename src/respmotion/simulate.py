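"""Ventilator-driven synthetic tracker trajectories.

Under general anaesthesia with volume-controlled ventilation, vertebral
motion is periodic with fixed rate and phase: the tracked point rises during
inspiration and returns during expiration. The generator reproduces the
statistical structure of such recordings — a dominant motion axis carrying a
2–3 mm peak-to-peak excursion, a much weaker perpendicular secondary
component (PC1/PC2 variance ratio well above 6), isotropic sensor noise, and
a nearly constant orientation — so every downstream stage can be exercised
without clinical data.

The breath waveform is a piecewise raised cosine: a smooth rise over the
inspiratory fraction f_I = i/(i+e) of the cycle and a smooth fall over the
rest. The clinical regime (rate 12/min, I:E 1:2) gives a 5 s cycle peaking
at ~1.67 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import PoseSample, Trajectory

__all__ = ["VentilatorSpec", "ventilator_waveform", "generate_trajectory", "PAPER_AXIS"]

#: Clinically measured primary motion axis in the camera frame (unit vector).
PAPER_AXIS = np.array([-0.960, 0.0634, 0.274])


def _unit(v: np.ndarray) -> np.ndarray:
    return np.asarray(v, dtype=float) / np.linalg.norm(v)


def _perpendicular(axis: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to ``axis``."""
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(axis)))] = 1.0
    return _unit(np.cross(axis, helper))


@dataclass(frozen=True)
class VentilatorSpec:
    """Ventilation and sensing parameters driving the simulator.

    Defaults mirror the clinical measurement regime: 12 breaths/min with an
    inspiratory:expiratory ratio of 1:2, 2 mm peak-to-peak excursion along
    the clinically observed primary axis, a secondary excursion one sixth of
    that (variance ratio 36), 0.02 mm isotropic position noise and quaternion
    jitter bounded by 0.02 per component.
    """

    rate: float = 12.0  # breaths per minute
    ie_ratio: tuple[float, float] = (1.0, 2.0)
    amplitude: float = 2.0  # peak-to-peak along primary axis, mm
    primary_axis: np.ndarray = field(default_factory=lambda: PAPER_AXIS.copy())
    secondary_amplitude: float | None = None  # defaults to amplitude / 6
    noise_sd: float = 0.02  # mm, per component
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    quat_jitter: float = 0.02
    phase0: float = 0.0
    secondary_phase_offset: float = 0.1  # fraction of a cycle
    drift_mm_per_s: float = 0.0  # optional linear baseline drift along primary

    def __post_init__(self) -> None:
        axis = np.asarray(self.primary_axis, dtype=float)
        if abs(np.linalg.norm(axis) - 1.0) > 1e-6:
            axis = _unit(axis)
        object.__setattr__(self, "primary_axis", axis)
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.secondary_amplitude is None:
            object.__setattr__(self, "secondary_amplitude", self.amplitude / 6.0)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.amplitude < 0 or self.noise_sd < 0 or self.secondary_amplitude < 0:
            raise ValueError("amplitude and noise_sd must be non-negative")
        i, e = self.ie_ratio
        if i <= 0 or e <= 0:
            raise ValueError("I:E ratio components must be positive")
        if not (0.0 <= self.phase0 < 1.0):
            raise ValueError("phase0 must lie in [0, 1)")

    @property
    def secondary_axis(self) -> np.ndarray:
        """Unit vector perpendicular to the primary axis (deterministic)."""
        return _perpendicular(self.primary_axis)

    @property
    def period_s(self) -> float:
        return 60.0 / self.rate

    @property
    def inspiratory_fraction(self) -> float:
        i, e = self.ie_ratio
        return i / (i + e)


def ventilator_waveform(
    phase: float | np.ndarray, ie_ratio: tuple[float, float] = (1.0, 2.0)
) -> float | np.ndarray:
    """Displacement fraction in [0, 1] at a given phase of the breath cycle.

    Raised-cosine rise on [0, f_I], raised-cosine fall on [f_I, 1), with
    f_I = i/(i+e). Zero at phase 0, one exactly at f_I, continuous and
    periodic (the value tends to 0 as phase -> 1).
    """
    p = np.asarray(phase, dtype=float)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    if np.any((p < 0) | (p >= 1)):
        raise ValueError("phase must lie in [0, 1)")
    i, e = ie_ratio
    if i <= 0 or e <= 0:
        raise ValueError("I:E ratio components must be positive")
    f_i = i / (i + e)
    w = np.where(
        p <= f_i,
        0.5 * (1.0 - np.cos(np.pi * p / f_i)),
        0.5 * (1.0 + np.cos(np.pi * (p - f_i) / (1.0 - f_i))),
    )
    return float(w[0]) if scalar else w


def generate_trajectory(
    spec: VentilatorSpec,
    duration_s: float = 30.0,
    rate_hz: float = 30.0,
    seed: int = 0,
) -> Trajectory:
    """Simulate ``floor(duration_s * rate_hz)`` tracker pose samples.

    The noiseless position is
    ``center + amplitude*(w(phase)-1/2)*primary + s2*secondary``, where s2 is
    the phase-offset copy of the waveform orthogonalised against the primary
    component and rescaled to ``secondary_amplitude`` peak-to-peak, all
    plus isotropic Gaussian noise of sd ``noise_sd`` per component. The
    quaternion is identity plus clipped Gaussian jitter, renormalised.
    Identical seeds give bit-identical trajectories.
    """
    if duration_s <= 0 or rate_hz <= 0:
        raise ValueError("duration_s and rate_hz must be positive")
    n = int(np.floor(duration_s * rate_hz))
    rng = np.random.default_rng(seed)
    t = np.arange(n) / rate_hz
    phase = np.mod(spec.phase0 + t / spec.period_s, 1.0)
    w1 = ventilator_waveform(phase, spec.ie_ratio)
    w2 = ventilator_waveform(
        np.mod(phase + spec.secondary_phase_offset, 1.0), spec.ie_ratio
    )
    s1 = spec.amplitude * (w1 - 0.5)
    # The phase-shifted secondary waveform correlates with the primary one;
    # orthogonalise it over the recording so the positional covariance has
    # no cross term and PC1 recovers the primary axis exactly. Rescale to
    # the requested peak-to-peak after orthogonalisation.
    s2 = w2 - 0.5
    if spec.amplitude > 0 and spec.secondary_amplitude > 0:
        a = s1 - s1.mean()
        b = s2 - s2.mean()
        denom = float(a @ a)
        if denom > 0:
            b = b - (float(a @ b) / denom) * a
        ptp = b.max() - b.min()
        s2 = b / ptp if ptp > 1e-12 else np.zeros_like(b)
    pos = (
        spec.center[None, :]
        + s1[:, None] * spec.primary_axis[None, :]
        + spec.secondary_amplitude * s2[:, None] * spec.secondary_axis[None, :]
        + spec.drift_mm_per_s * t[:, None] * spec.primary_axis[None, :]
    )
    if spec.noise_sd > 0:
        pos = pos + rng.normal(0.0, spec.noise_sd, size=(n, 3))
    quat = np.zeros((n, 4))
    quat[:, 0] = 1.0
    if spec.quat_jitter > 0:
        jitter = rng.normal(0.0, spec.quat_jitter / 2.0, size=(n, 3))
        np.clip(jitter, -spec.quat_jitter, spec.quat_jitter, out=jitter)
        quat[:, 1:] = jitter
    quat /= np.linalg.norm(quat, axis=1, keepdims=True)
    samples = tuple(
        PoseSample(t=float(t[k]), pos=pos[k], quat=quat[k]) for k in range(n)
    )
    return Trajectory(samples=samples, nominal_rate=rate_hz)
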