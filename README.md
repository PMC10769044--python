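# respmotion

Patient-specific respiratory motion prediction for optically tracked spine
surgery.

During robot-assisted spine surgery an optical tracker is clamped to an
exposed vertebra and its pose (x, y, z, q0, qx, qy, qz) is sampled at 30 Hz
by an infrared stereo camera. Under volume-controlled ventilation the
vertebra moves quasi-periodically by 2–3 mm peak-to-peak, and the
navigation-to-actuation chain lags by roughly a third of a second — so the
control system needs the tracker position ~333 ms (10 samples) *ahead* of
the latest measurement. `respmotion` builds that predictor from a single
~30 s recording per patient. It is aimed at surgical-navigation researchers
and engineers who need a reproducible, CPU-only reference implementation of
this few-shot pipeline, together with a ventilator-driven simulator for
testing without clinical data.

## Method

1. **Dimension reduction.** From the 3×n position matrix X, compute
   X̄ and Cov = (1/n)(X−X̄)(X−X̄)ᵀ = Σₖ σₖ vₖvₖᵀ. The leading eigenvector
   v₁ (PC1) is the respiration axis (clinically its eigenvalue exceeds the
   next by >6×); the 1-D respiration signal is x_p = v₁ᵀ(X−X̄).
2. **Few-shot augmentation.** β-mixed signals x_new = (1−β)x_p + βx_p₂
   (PC2 projection x_p₂, β ∈ {−0.2,−0.1,0,0.1,0.2}) emulate projections on
   axes near PC1. Each signal is normalised to [−1, 1] on its training
   span.
3. **Supervision.** Sliding windows of L = 50 samples paired with the
   target h = 10 samples after the window end; chronological 6:2:2
   train/validation/test split; the test set uses only the raw signal.
4. **Regressor.** LSTM (hidden d = 64) unrolled over the window →
   dot-product self-attention with the last hidden state as key,
   A = softmax(H·H_l), s = Σₜ Aₜ Hₜ → autoencoder head
   (linear+ReLU to 16-d latent, linear decoder) → scalar prediction.
   Trained 20 epochs with Adam under loss = ‖y_o − y_real‖₂
   (lr 1e-4, dropped to 1e-5 after epoch 5), best-validation checkpoint.
5. **Evaluation.** RMSE% and maximum error% on the normalised scale;
   millimetre worst-case errors per camera axis via back-projection along
   PC1; SVR, ARIMA(5,1,0) and plain-LSTM baselines on identical windows.

The network, BPTT gradients and Adam are implemented directly in
numpy/numba (gradients are validated against finite differences in the
test suite). See `docs/methods.md` for assumptions, parameter rationale and
limitations.

## Worked example

Simulate a ventilated patient (12 breaths/min, I:E 1:2, 2 mm peak-to-peak
along the clinically reported motion axis, 0.02 mm sensor noise) and run
the full pipeline:

```sh
respmotion simulate --duration 30 --rate-hz 30 --breath-rate 12 --ie 1:2 \
    --amplitude 2.0 --noise-sd 0.02 --seed 7 --out traj.csv
respmotion run --in traj.csv --seed 1 --out report.json
```

which prints (numbers produced by this exact invocation):

```
principal axis [ 0.9596 -0.0626 -0.2744], eigenvalues [5.0048e-01 1.2960e-02 3.9000e-04] (PC1/PC2 ratio 38.6)
corpus: 2405 train / 605 val / 121 test windows
test RMSE 1.95%, max error 6.09%, Cartesian max 0.063 mm
```

Reading the output: the recovered principal axis matches the simulator's
(sign is fixed by convention, so it appears flipped); the PC1/PC2
eigenvalue ratio 38.6 is inside the >6 clinical regime; a 900-frame
recording yields 121 held-out test windows. Test RMSE of 1.95% of one
normalised unit means ~0.02 mm on-axis RMS error at this 2 mm motion
range — at the sensor-noise floor — and the worst 3-D error over the test
set is 0.063 mm, far below the ~0.5 mm tolerance of surgical tracking.
The same pipeline is available programmatically:

```python
from respmotion import PipelineConfig, TrainConfig, run_pipeline
report, model = run_pipeline("traj.csv", PipelineConfig(train_cfg=TrainConfig(seed=1)))
print(report.rmse_pct, report.per_axis_max_mm)
```

The stages are also exposed individually — `respmotion fit-axis` (principal
frame as JSON), `respmotion prepare` (corpus container), `respmotion train`
(checkpoint) and `respmotion evaluate` (metrics plus `--baselines
svr,arima,lstm` on the identical test windows).

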