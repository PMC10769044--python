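"""The default synthetic ventilator benchmark.

One 30 s, 30 Hz recording (900 frames) is simulated under the clinical
ventilation regime — 12 breaths/min, I:E 1:2, 2 mm peak-to-peak along the
clinically observed primary axis, 0.02 mm sensor noise — and the full
pipeline is trained and evaluated on it once per model seed. Medians across
seeds summarise the stochasticity of initialisation and batch shuffling;
the recording itself is held fixed (data seed 7 by convention).
"""

from __future__ import annotations

import numpy as np

from .baselines import baseline_arima, baseline_plain_lstm, baseline_svr
from .io import Trajectory
from .pipeline import PipelineConfig, build_corpus, run_pipeline
from .simulate import VentilatorSpec, generate_trajectory
from .train import TrainConfig

__all__ = ["benchmark_trajectory", "run_benchmark"]

DEFAULT_MODEL_SEEDS = (1, 2, 3, 4, 5)


def benchmark_trajectory(data_seed: int = 7) -> Trajectory:
    """The standard 30 s / 30 Hz ventilator-driven recording."""
    return generate_trajectory(
        VentilatorSpec(), duration_s=30.0, rate_hz=30.0, seed=data_seed
    )


def run_benchmark(
    model_seeds: tuple[int, ...] = DEFAULT_MODEL_SEEDS,
    data_seed: int = 7,
    baselines: tuple[str, ...] = (),
    config: PipelineConfig | None = None,
) -> dict:
    """Train and evaluate the pipeline once per model seed; report medians.

    ``baselines`` may include ``"svr"``, ``"arima"`` (deterministic, run
    once) and ``"lstm"`` (the plain-LSTM baseline, run once per seed).
    """
    base_cfg = config or PipelineConfig()
    traj = benchmark_trajectory(data_seed)
    per_seed = []
    for seed in model_seeds:
        cfg = PipelineConfig(
            betas=base_cfg.betas,
            window=base_cfg.window,
            horizon=base_cfg.horizon,
            ratios=base_cfg.ratios,
            hidden=base_cfg.hidden,
            latent=base_cfg.latent,
            train_cfg=TrainConfig(
                epochs=base_cfg.train_cfg.epochs,
                lr_initial=base_cfg.train_cfg.lr_initial,
                lr_after=base_cfg.train_cfg.lr_after,
                lr_switch_epoch=base_cfg.train_cfg.lr_switch_epoch,
                batch_size=base_cfg.train_cfg.batch_size,
                seed=seed,
            ),
        )
        report, _ = run_pipeline(traj, cfg)
        per_seed.append(report)
    result = {
        "n_test": per_seed[0].n_test,
        "rmse_pct_median": float(np.median([r.rmse_pct for r in per_seed])),
        "max_err_pct_median": float(np.median([r.max_err_pct for r in per_seed])),
        "cartesian_max_mm_median": float(
            np.median([r.cartesian_max_mm for r in per_seed])
        ),
        "per_axis_max_mm_median": [
            float(np.median([r.per_axis_max_mm[k] for r in per_seed]))
            for k in range(3)
        ],
        "per_seed": per_seed,
    }
    if baselines:
        corpus, _ = build_corpus(traj, base_cfg)
        bl: dict[str, dict] = {}
        if "svr" in baselines:
            bl["svr"] = baseline_svr(corpus)
        if "arima" in baselines:
            bl["arima"] = baseline_arima(corpus)
        if "lstm" in baselines:
            runs = []
            for seed in model_seeds:
                cfg_b = TrainConfig(
                    epochs=base_cfg.train_cfg.epochs,
                    lr_initial=base_cfg.train_cfg.lr_initial,
                    lr_after=base_cfg.train_cfg.lr_after,
                    lr_switch_epoch=base_cfg.train_cfg.lr_switch_epoch,
                    batch_size=base_cfg.train_cfg.batch_size,
                    seed=seed,
                )
                runs.append(baseline_plain_lstm(corpus, cfg_b, d=base_cfg.hidden)[0])
            bl["lstm"] = {
                "rmse_pct_median": float(np.median([r["rmse_pct"] for r in runs])),
                "max_err_pct_median": float(np.median([r["max_err_pct"] for r in runs])),
                "per_seed": runs,
            }
        result["baselines"] = bl
    return result
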