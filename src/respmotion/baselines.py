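"""Reference forecasters the attention model is compared against.

Three classical baselines share the exact test windows of the main model:

* SVR — support-vector regression (RBF kernel) on the raw 50-point window.
* ARIMA — a fixed-order (5,1,0) model fit on the raw training span, rolled
  across the test span producing h-step-ahead forecasts from each window's
  last observed sample.
* plain LSTM — the identical recurrent backbone and training protocol with
  attention and the autoencoder head replaced by a single linear map from
  the final hidden state.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.svm import SVR
from statsmodels.tsa.arima.model import ARIMA

from .dataset import SplitCorpus
from .model import ModelParams, init_params
from .train import TrainConfig, max_error_pct, predict_batch, rmse_pct, train

__all__ = ["baseline_svr", "baseline_arima", "baseline_plain_lstm"]

SVR_PARAMS = dict(kernel="rbf", C=1.0, epsilon=0.01)
ARIMA_ORDER = (5, 1, 0)


def _metrics(y_pred: np.ndarray, y_true: np.ndarray) -> dict[str, float]:
    return {
        "rmse_pct": rmse_pct(y_pred, y_true),
        "max_err_pct": max_error_pct(y_pred, y_true),
    }


def baseline_svr(corpus: SplitCorpus) -> dict[str, float]:
    """RBF-kernel SVR on (window -> target) pairs; metrics on test windows."""
    X_train, y_train = corpus.stacked("train")
    X_test, y_test = corpus.stacked("test")
    model = SVR(**SVR_PARAMS)
    model.fit(X_train, y_train)
    return _metrics(model.predict(X_test), y_test)


def baseline_arima(corpus: SplitCorpus, order: tuple[int, int, int] = ARIMA_ORDER) -> dict[str, float]:
    """Fixed-order ARIMA rolled across the test span at horizon h.

    The model is fit once on the raw signal's normalised training span; its
    parameters are then applied (without refitting) to the history up to
    each test window's last observed sample, and the h-step-ahead forecast
    is compared with that window's target. Deterministic given the data.
    """
    full = corpus.raw_normalized
    test_ws = corpus.test[0]
    L, h = test_ws.L, test_ws.h
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = ARIMA(full[: corpus.spans[0][1]], order=order).fit()
        preds = np.empty(len(test_ws))
        # start_indices are absolute indices into the parent signal
        for j, start in enumerate(test_ws.start_indices):
            origin = start + L  # history is samples [0, origin)
            applied = fit.apply(full[:origin], refit=False)
            preds[j] = applied.forecast(h)[-1]
    return _metrics(preds, test_ws.targets)


def baseline_plain_lstm(
    corpus: SplitCorpus, cfg: TrainConfig, d: int = 64
) -> tuple[dict[str, float], ModelParams]:
    """Plain LSTM with a linear readout, same training protocol as the full model."""
    params = init_params(d=d, d_latent=0, seed=cfg.seed, head="linear")
    trained, _ = train(corpus, params, cfg)
    X_test, y_test = corpus.stacked("test")
    preds = predict_batch(X_test, trained)
    return _metrics(preds, y_test), trained
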