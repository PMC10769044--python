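"""End-to-end pipeline: trajectory -> axis -> corpus -> model -> report.

``run_pipeline`` chains every stage — read the trajectory, fit the principal
motion axis, project to the 1-D respiration signal, β-augment, normalise,
window, split 6:2:2, train the LSTM-attention-autoencoder, evaluate on the
held-out raw test windows, and optionally run the SVR / ARIMA / plain-LSTM
baselines — and returns a :class:`PredictionReport` that serialises to JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .baselines import baseline_arima, baseline_plain_lstm, baseline_svr
from .dataset import SplitCorpus, augment, split_corpus
from .io import Trajectory, positions_matrix, read_trajectory
from .model import ModelParams, init_params
from .pca import PrincipalFrame, covariance, explained_ratios, principal_frame, project
from .train import (
    TrainConfig,
    max_error_pct,
    per_axis_errors,
    predict_batch,
    rmse_pct,
    train,
)

__all__ = ["PipelineConfig", "PredictionReport", "run_pipeline", "save_checkpoint", "load_checkpoint"]

log = logging.getLogger("respmotion")

DEFAULT_BETAS = (-0.2, -0.1, 0.0, 0.1, 0.2)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce a pipeline run."""

    betas: tuple[float, ...] = DEFAULT_BETAS
    window: int = 50
    horizon: int = 10
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    hidden: int = 64
    latent: int = 16
    train_cfg: TrainConfig = field(default_factory=TrainConfig)
    baselines: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class PredictionReport:
    """Evaluation summary of one pipeline run.

    Percent metrics are on the normalised [-1, 1] scale (one unit = half
    the fitted peak-to-peak range); millimetre maxima come from
    back-projecting the de-normalised residual along the primary axis.
    """

    rmse_pct: float
    max_err_pct: float
    per_axis_max_mm: tuple[float, float, float]
    cartesian_max_mm: float
    curves: dict[str, list[float]]
    baselines: dict[str, dict[str, float]]
    n_train: int
    n_val: int
    n_test: int
    seed: int
    eigenvalues: tuple[float, float, float]
    explained_ratios: tuple[float, float, float]
    config: dict
    version: str = __version__

    def __post_init__(self) -> None:
        if self.rmse_pct > self.max_err_pct + 1e-12:
            raise ValueError("rmse_pct cannot exceed max_err_pct")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def build_corpus(
    traj: Trajectory, cfg: PipelineConfig
) -> tuple[SplitCorpus, PrincipalFrame]:
    """Axis fit, projection, augmentation, normalisation, windows, split."""
    pos = positions_matrix(traj)
    mean, cov = covariance(pos)
    frame = principal_frame(mean, cov)
    ratios = explained_ratios(frame)
    log.info(
        "principal axis %s, eigenvalues %s (PC1/PC2 ratio %.1f)",
        np.round(frame.primary_axis, 4),
        np.round(frame.eigenvalues, 5),
        frame.eigenvalues[0] / max(frame.eigenvalues[1], 1e-30),
    )
    xp = project(pos, frame, component=0)
    yp = project(pos, frame, component=1)
    aug = augment(xp, yp, list(cfg.betas))
    corpus = split_corpus(aug, ratios=cfg.ratios, L=cfg.window, h=cfg.horizon)
    log.info(
        "corpus: %d train / %d val / %d test windows",
        sum(len(w) for w in corpus.train),
        sum(len(w) for w in corpus.val),
        sum(len(w) for w in corpus.test),
    )
    return corpus, frame


def run_pipeline(
    traj: Trajectory | str | Path, config: PipelineConfig | None = None
) -> tuple[PredictionReport, ModelParams]:
    """Execute the full chain on a trajectory (object or CSV path)."""
    cfg = config or PipelineConfig()
    if not isinstance(traj, Trajectory):
        traj = read_trajectory(traj)
    corpus, frame = build_corpus(traj, cfg)
    model = init_params(
        d=cfg.hidden, d_latent=cfg.latent, seed=cfg.train_cfg.seed
    )
    trained, curves = train(corpus, model, cfg.train_cfg)
    X_test, y_test = corpus.stacked("test")
    preds = predict_batch(X_test, trained)
    per_axis, cartesian = per_axis_errors(
        preds, y_test, frame, corpus.raw_norm_scale
    )
    baselines: dict[str, dict[str, float]] = {}
    for name in cfg.baselines:
        if name == "svr":
            baselines["svr"] = baseline_svr(corpus)
        elif name == "arima":
            baselines["arima"] = baseline_arima(corpus)
        elif name == "lstm":
            baselines["lstm"] = baseline_plain_lstm(
                corpus, cfg.train_cfg, d=cfg.hidden
            )[0]
        else:
            raise ValueError(f"unknown baseline {name!r}")
    expl = explained_ratios(frame)
    report = PredictionReport(
        rmse_pct=rmse_pct(preds, y_test),
        max_err_pct=max_error_pct(preds, y_test),
        per_axis_max_mm=tuple(float(x) for x in per_axis),
        cartesian_max_mm=cartesian,
        curves=curves,
        baselines=baselines,
        n_train=sum(len(w) for w in corpus.train),
        n_val=sum(len(w) for w in corpus.val),
        n_test=sum(len(w) for w in corpus.test),
        seed=cfg.train_cfg.seed,
        eigenvalues=tuple(float(x) for x in frame.eigenvalues),
        explained_ratios=tuple(float(x) for x in expl),
        config=cfg.to_dict(),
    )
    return report, trained


def save_checkpoint(
    path: str | Path,
    params: ModelParams,
    frame: PrincipalFrame,
    norm_offset: float,
    norm_scale: float,
    L: int,
    h: int,
) -> None:
    """Persist all parameter arrays plus the geometry needed for mm errors."""
    arrays = {f"param_{k}": v for k, v in params.as_dict().items()}
    np.savez(
        path,
        meta=np.array(
            [params.d, params.d_latent, params.seed, L, h], dtype=np.int64
        ),
        head=np.array([params.head]),
        frame_mean=frame.mean,
        frame_axes=frame.axes,
        frame_eigenvalues=frame.eigenvalues,
        norm=np.array([norm_offset, norm_scale]),
        **arrays,
    )


def load_checkpoint(path: str | Path):
    """Inverse of :func:`save_checkpoint`.

    Returns (params, frame, norm_offset, norm_scale, L, h).
    """
    with np.load(path, allow_pickle=False) as data:
        d, d_latent, seed, L, h = (int(x) for x in data["meta"])
        head = str(data["head"][0])
        kw = dict(d=d, d_latent=d_latent, seed=seed, head=head)
        for key in data.files:
            if key.startswith("param_"):
                kw[key[len("param_"):]] = data[key]
        params = ModelParams(**{**_none_fields(), **kw})
        frame = PrincipalFrame(
            mean=data["frame_mean"],
            axes=data["frame_axes"],
            eigenvalues=data["frame_eigenvalues"],
        )
        offset, scale = (float(x) for x in data["norm"])
    return params, frame, offset, scale, L, h


def _none_fields() -> dict:
    return {k: None for k in ("W_enc", "b_enc", "W_dec", "b_dec", "W_out", "b_out")}
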