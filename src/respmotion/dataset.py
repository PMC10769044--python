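"""Few-shot training corpus: β-mixing augmentation, normalisation, windows.

A single ~30 s recording yields too few supervision pairs to train a
regressor reliably, so the 1-D respiration signal is augmented by mixing the
PC1 and PC2 projections: ``x_new = (1 - β) x_p + β y_p``. For small β this
emulates projecting the same motion onto axes slightly offset from the
primary axis — same respiratory rate and phase, slightly different shape.

Each signal is normalised to [-1, 1] with an affine map fitted on its
training span only (min -> -1, max -> +1); values outside the fit span may
exceed the interval and are deliberately not clipped. Sliding windows of
L = 50 consecutive points are paired with the target h = 10 samples
(333 ms at 30 Hz) after the window's last point. The corpus is split
chronologically 6:2:2 into train/validation/test spans before windowing, so
no sample index leaks across splits; the test split uses only the raw
(β = 0) signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pca import ScalarSignal

__all__ = [
    "AugmentedSet",
    "WindowSet",
    "SplitCorpus",
    "augment",
    "normalize",
    "denormalize",
    "make_windows",
    "split_corpus",
    "save_corpus",
    "load_corpus",
]


class InsufficientDataError(ValueError):
    """Signal too short for the requested windowing or split."""


@dataclass(frozen=True)
class AugmentedSet:
    """β-mixed signals; exactly one entry (the original) has β = 0."""

    signals: tuple[ScalarSignal, ...]
    betas: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.signals) != len(self.betas):
            raise ValueError("one β per signal required")
        if sum(1 for b in self.betas if b == 0.0) != 1:
            raise ValueError("exactly one signal must have β = 0")
        lengths = {len(s) for s in self.signals}
        if len(lengths) != 1:
            raise ValueError("all signals must have the same length")

    @property
    def raw(self) -> ScalarSignal:
        return self.signals[self.betas.index(0.0)]


@dataclass(frozen=True)
class WindowSet:
    """Sliding-window supervision pairs from one signal span.

    ``inputs[j]`` is the window starting at parent-signal index
    ``start_indices[j]``; ``targets[j]`` is the sample ``L + h - 1`` positions
    later, i.e. h samples after the window's last point.
    """

    inputs: np.ndarray  # (n_w, L)
    targets: np.ndarray  # (n_w,)
    L: int
    h: int
    start_indices: np.ndarray  # (n_w,) indices into the parent signal

    def __post_init__(self) -> None:
        if self.inputs.shape != (len(self.targets), self.L):
            raise ValueError("inputs must be (n_w, L)")

    def __len__(self) -> int:
        return len(self.targets)


@dataclass(frozen=True)
class SplitCorpus:
    """Chronological train/val/test windows plus split bookkeeping.

    ``train``/``val`` pool windows from every augmented signal; ``test``
    holds only raw-signal windows. ``spans`` records the (start, stop) sample
    ranges of the three chronological spans of the parent signals.
    """

    train: tuple[WindowSet, ...]
    val: tuple[WindowSet, ...]
    test: tuple[WindowSet, ...]
    ratios: tuple[float, float, float]
    spans: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    norm_offsets: tuple[float, ...]
    norm_scales: tuple[float, ...]
    betas: tuple[float, ...]
    raw_normalized: np.ndarray = field(default=None, repr=False)  # full β=0 signal
    normalized_signals: np.ndarray = field(default=None, repr=False)  # (n_signals, N)

    def stacked(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        """Concatenate a split's windows into (inputs, targets) arrays."""
        sets = getattr(self, which)
        X = np.concatenate([w.inputs for w in sets], axis=0)
        y = np.concatenate([w.targets for w in sets], axis=0)
        return X, y

    @property
    def raw_norm_offset(self) -> float:
        return self.norm_offsets[self.betas.index(0.0)]

    @property
    def raw_norm_scale(self) -> float:
        return self.norm_scales[self.betas.index(0.0)]


def augment(
    xp: ScalarSignal, yp: ScalarSignal, betas: list[float] | tuple[float, ...]
) -> AugmentedSet:
    """Mix PC1 and PC2 projections: one signal ``(1-β)xp + βyp`` per β.

    β = 0 (the unmodified PC1 projection) is prepended if absent from the
    grid. Inputs must be unnormalised projections of the same trajectory.
    """
    if len(xp) != len(yp):
        raise ValueError(
            f"projection lengths differ: {len(xp)} vs {len(yp)}"
        )
    betas = list(betas)
    if 0.0 not in betas:
        betas = [0.0] + betas
    signals = []
    for b in betas:
        values = (1.0 - b) * xp.values + b * yp.values
        label = "raw" if b == 0.0 else f"augmented({b:g})"
        signals.append(ScalarSignal(values=values, label=label))
    return AugmentedSet(signals=tuple(signals), betas=tuple(float(b) for b in betas))


def normalize(signal: ScalarSignal, fit_range: tuple[int, int] | None = None) -> ScalarSignal:
    """Affinely map the signal so min -> -1 and max -> +1 over ``fit_range``.

    The map is fitted on ``fit_range`` (default: the whole signal) and
    applied everywhere, so values outside the fit span may leave [-1, 1];
    they are not clipped. Offset and scale are stored for exact inversion.
    """
    if signal.normalized:
        raise ValueError("signal is already normalized")
    start, stop = fit_range if fit_range is not None else (0, len(signal))
    span = signal.values[start:stop]
    if len(span) < 2:
        raise ValueError("fit_range must cover at least 2 samples")
    lo, hi = float(span.min()), float(span.max())
    if hi <= lo:
        raise ValueError("constant signal over fit_range: cannot normalize")
    scale = (hi - lo) / 2.0
    offset = (hi + lo) / 2.0
    return ScalarSignal(
        values=(signal.values - offset) / scale,
        offset=offset,
        scale=scale,
        label=signal.label,
        normalized=True,
    )


def denormalize(signal: ScalarSignal) -> ScalarSignal:
    """Invert :func:`normalize` exactly."""
    if not signal.normalized:
        raise ValueError("signal is not normalized")
    return ScalarSignal(
        values=signal.values * signal.scale + signal.offset,
        label=signal.label,
    )


def make_windows(
    signal: ScalarSignal, L: int = 50, h: int = 10, index_offset: int = 0
) -> WindowSet:
    """Stride-1 sliding windows with targets h samples past each window end.

    A signal of length N yields ``N - L - h + 1`` windows. ``index_offset``
    shifts the recorded start indices when the signal is a slice of a longer
    parent (used by the chronological split).
    """
    n = len(signal)
    if n < L + h:
        raise InsufficientDataError(
            f"signal length {n} < required minimum L + h = {L + h}"
        )
    n_w = n - L - h + 1
    starts = np.arange(n_w)
    idx = starts[:, None] + np.arange(L)[None, :]
    inputs = signal.values[idx]
    targets = signal.values[starts + L + h - 1]
    return WindowSet(
        inputs=inputs,
        targets=targets,
        L=L,
        h=h,
        start_indices=starts + index_offset,
    )


def split_corpus(
    aug: AugmentedSet,
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    L: int = 50,
    h: int = 10,
) -> SplitCorpus:
    """Chronological 6:2:2 split, normalisation, and windowing of the corpus.

    Each signal is cut into contiguous train/val/test sample spans, then
    normalised with statistics fitted on its training span, then windowed
    within each span (no window straddles a cut). Train and validation take
    windows from every β; the test split takes windows only from β = 0.
    """
    if np.any(np.asarray(ratios) <= 0):
        raise ValueError("ratios must be positive")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    n = len(aug.signals[0])
    n_train = int(np.floor(ratios[0] * n))
    n_val = int(np.floor(ratios[1] * n))
    spans = ((0, n_train), (n_train, n_train + n_val), (n_train + n_val, n))
    for name, (a, b) in zip(("train", "val", "test"), spans):
        if b - a < L + h:
            raise InsufficientDataError(
                f"{name} span has {b - a} samples; needs at least L + h = {L + h}"
            )
    train, val, test = [], [], []
    offsets, scales = [], []
    raw_normalized = None
    all_normalized = []
    for sig, beta in zip(aug.signals, aug.betas):
        norm = normalize(sig, fit_range=spans[0])
        offsets.append(norm.offset)
        scales.append(norm.scale)
        all_normalized.append(norm.values.copy())
        if beta == 0.0:
            raw_normalized = norm.values.copy()
        for dest, (a, b) in zip((train, val, test), spans):
            if dest is test and beta != 0.0:
                continue
            piece = ScalarSignal(
                values=norm.values[a:b],
                offset=norm.offset,
                scale=norm.scale,
                label=norm.label,
                normalized=True,
            )
            dest.append(make_windows(piece, L=L, h=h, index_offset=a))
    return SplitCorpus(
        train=tuple(train),
        val=tuple(val),
        test=tuple(test),
        ratios=tuple(ratios),
        spans=spans,
        norm_offsets=tuple(offsets),
        norm_scales=tuple(scales),
        betas=aug.betas,
        raw_normalized=raw_normalized,
        normalized_signals=np.array(all_normalized),
    )


def save_corpus(path, corpus: SplitCorpus, frame=None) -> None:
    """Persist a corpus (and optionally its PrincipalFrame) as an array bundle.

    Windows are not stored — they are rebuilt deterministically from the
    normalised signals, spans and (L, h) on load.
    """
    L, h = corpus.test[0].L, corpus.test[0].h
    payload = dict(
        normalized_signals=corpus.normalized_signals,
        betas=np.array(corpus.betas),
        norm_offsets=np.array(corpus.norm_offsets),
        norm_scales=np.array(corpus.norm_scales),
        ratios=np.array(corpus.ratios),
        spans=np.array(corpus.spans, dtype=np.int64),
        window_params=np.array([L, h], dtype=np.int64),
    )
    if frame is not None:
        payload.update(
            frame_mean=frame.mean,
            frame_axes=frame.axes,
            frame_eigenvalues=frame.eigenvalues,
        )
    np.savez(path, **payload)


def load_corpus(path):
    """Inverse of :func:`save_corpus`; returns (corpus, frame_or_None)."""
    from .pca import PrincipalFrame  # local import to avoid a cycle

    with np.load(path, allow_pickle=False) as data:
        signals = data["normalized_signals"]
        betas = tuple(float(b) for b in data["betas"])
        offsets = tuple(float(x) for x in data["norm_offsets"])
        scales = tuple(float(x) for x in data["norm_scales"])
        ratios = tuple(float(x) for x in data["ratios"])
        spans = tuple(tuple(int(x) for x in row) for row in data["spans"])
        L, h = (int(x) for x in data["window_params"])
        frame = None
        if "frame_mean" in data.files:
            frame = PrincipalFrame(
                mean=data["frame_mean"],
                axes=data["frame_axes"],
                eigenvalues=data["frame_eigenvalues"],
            )
    train, val, test = [], [], []
    raw_idx = betas.index(0.0)
    for row, (beta, offset, scale) in enumerate(zip(betas, offsets, scales)):
        for dest, (a, b) in zip((train, val, test), spans):
            if dest is test and beta != 0.0:
                continue
            piece = ScalarSignal(
                values=signals[row, a:b],
                offset=offset,
                scale=scale,
                label="raw" if beta == 0.0 else f"augmented({beta:g})",
                normalized=True,
            )
            dest.append(make_windows(piece, L=L, h=h, index_offset=a))
    corpus = SplitCorpus(
        train=tuple(train),
        val=tuple(val),
        test=tuple(test),
        ratios=ratios,
        spans=spans,
        norm_offsets=offsets,
        norm_scales=scales,
        betas=betas,
        raw_normalized=signals[raw_idx].copy(),
        normalized_signals=signals,
    )
    return corpus, frame
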