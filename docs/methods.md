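# Methods

## Problem setting

During robot-assisted spine surgery an optical tracker is clamped to an
exposed vertebra and its 6-DoF pose is sampled at 30 Hz by an infrared
stereo camera. Under general anaesthesia with volume-controlled
ventilation, the vertebra moves quasi-periodically with the ventilator
(typically 12 breaths/min, I:E 1:2, 2–3 mm peak-to-peak). Navigation and
actuation introduce a latency of roughly a third of a second, so the
tracking system needs the tracker position ~333 ms (10 samples) ahead of
the latest measurement. `respmotion` builds that predictor from a single
~30 s recording per patient.

## Pipeline

1. **Principal-axis reduction.** The 3×n position matrix X is summarised by
   its mean X̄ and population covariance Cov = (1/n)(X−X̄)(X−X̄)ᵀ. The unit
   eigenvector v₁ with the largest eigenvalue (PC1) is the respiration
   axis; the scalar signal is the centred projection x_p = v₁ᵀ(X−X̄).
   Centring differs from projecting raw coordinates only by a constant,
   which the subsequent normalisation removes anyway; the offset is kept in
   the frame so no information is lost. In both clinical reports and the
   simulator the PC1/PC2 eigenvalue ratio exceeds 6, which justifies
   predicting PC1 motion only.
2. **β-mixing augmentation.** New signals x_new = (1−β)x_p + βy_p (y_p the
   PC2 projection) emulate projections onto axes slightly offset from PC1.
   Default grid β ∈ {−0.2, −0.1, 0, 0.1, 0.2}; β must stay small relative
   to 1 for the "approximate axis" interpretation to hold.
3. **Normalisation.** Each signal is affinely mapped so that its minimum
   and maximum *over the training span* become −1 and +1. Values outside
   the fit span may leave [−1, 1] and are not clipped. Each augmented
   signal is normalised independently (each is a projection onto its own
   axis). One normalised unit therefore equals half the fitted peak-to-peak
   range — ~1 mm for a 2 mm breathing excursion.
4. **Windowing and split.** Stride-1 windows of L = 50 samples are paired
   with the target 10 samples after the window end. The signal is cut
   chronologically 6:2:2 into train/validation/test spans *before*
   windowing: windows overlap heavily at stride 1, so a random split would
   leak near-duplicates across sets. The test set uses only the raw (β = 0)
   signal.
5. **Network.** One LSTM layer (scalar input, hidden size d = 64) unrolled
   over the window; dot-product self-attention with the final hidden state
   H_l as key over all hidden states (A = softmax(H·H_l), s = ΣAₜHₜ, no
   1/√d scaling); an autoencoder head (linear+ReLU encoder to d_latent = 16,
   linear decoder) emitting the scalar prediction. Weights are initialised
   uniformly in ±1/√d (seeded); biases start at zero except the forget
   gate, which starts at 1 — the standard LSTM initialisation that keeps
   cell memory open early in training. Within the short fixed epoch budget
   this is decisive: it roughly halves test RMSE and removes most
   across-seed variance.
6. **Training.** Loss = ‖y_o − y_real‖₂ over the mini-batch (the batch
   Euclidean norm, used verbatim; learning curves are reported as RMS loss
   per window so they are comparable across batch sizes). Adam, 20 epochs,
   learning rate 1e-4 for epochs 1–5 and 1e-5 thereafter. The returned
   parameters are those of the epoch with minimum validation loss.

The network, its backward pass (backpropagation through time through the
attention and autoencoder head) and Adam are implemented directly in
numpy/numba; analytic gradients are verified against central finite
differences in the test suite (per parameter group, by vector-norm relative
error — elementwise comparison is meaningless on near-zero components where
truncation error dominates).

### Batch size

The corpus is small (≈2 400 windows from one 30 s recording) and the epoch
budget and learning rates are fixed by the protocol above. Adam moves each
parameter by at most ~lr per update, so the total movement available is
roughly lr × number of updates; at batch 32 that is ~0.05 — an order of
magnitude below the weight scale the regression needs — and the model
visibly undertrains. The default batch size is therefore 2 (~24 000
updates), i.e. near-online updates, which is also what a 2-minute GPU
training time for 20 epochs on such a corpus implies. Batch size remains
configurable.

## Metrics

* **RMSE% / maximum error%**: 100 × RMS (resp. max abs) residual on the
  normalised scale. With a 2 mm excursion, 5% ≈ 0.05 mm on-axis.
* **Per-axis mm errors**: residuals are de-normalised to mm along PC1 and
  decomposed through the PC1 direction cosines onto the camera x/y/z axes;
  maxima are taken per axis independently. The Cartesian maximum is the
  largest 3-D residual norm (equal to the largest on-axis |residual| since
  PC1 is a unit vector). Because the pipeline predicts PC1 motion only, any
  true off-axis error is excluded from these numbers — a limitation shared
  with any 1-D reduction.

## Baselines

* **SVR**: RBF kernel, C = 1, ε = 0.01, on the raw 50-sample window.
* **ARIMA**(5,1,0): fit once on the raw training span, then applied with
  fixed parameters to the history up to each test window's end; the
  10-step-ahead forecast is scored against that window's target.
* **Plain LSTM**: identical backbone and training protocol with attention
  and the autoencoder replaced by one linear map from H_l.

## Synthetic ventilator benchmark

The simulator emulates a ventilated, anaesthetised patient: a piecewise
raised-cosine breath (smooth rise over the inspiratory fraction
f_I = i/(i+e) of the cycle, smooth fall over the rest — the rounded crests
seen in recorded traces), 12 breaths/min, I:E 1:2, 2 mm peak-to-peak along
the clinically reported axis [−0.960, 0.0634, 0.274], plus a perpendicular
secondary component with one sixth of the excursion. The secondary
component is the phase-offset waveform orthogonalised (over the recording)
against the primary one, so the positional covariance has no cross term:
PC1 then equals the primary axis exactly in the noiseless limit, and the
PC1/PC2 eigenvalue ratio (~36) stays well inside the >6 clinical regime.
Isotropic Gaussian position noise (default sd 0.02 mm — a configuration
choice for a modern optical tracker, not a reported value) and clipped
quaternion jitter ≤ 0.02 complete the model. One seeded generator drives
all randomness; identical seeds give bit-identical recordings.

What the simulator deliberately omits: apnoea and irregular breathing
(excluded under volume-controlled ventilation), baseline drift (off by
default; a linear drift parameter exists), physiological lung mechanics,
and any orientation dynamics beyond jitter. Passing the benchmark therefore
shows the pipeline recovers a near-deterministic ventilator-driven signal
through the full reduction/augmentation/training chain — it does not show
robustness to free-breathing irregularity.

## Problem sizes and numerical choices

* End-to-end evaluations use the full 30 s / 900-frame recording (121 test
  windows); unit tests use 12 s recordings or shorter synthetic signals
  with L = 10 windows, and tiny models (d ≤ 8) where only mechanics are
  under test.
* Eigenvector signs are fixed by making each eigenvector's
  largest-magnitude component positive; ties in eigenvalues are broken by
  a stable sort. Covariance uses 1/n, not 1/(n−1).
* Eigenvalues are clamped at zero from below (tolerance −1e-12);
  quaternion norms are accepted within 1±1e-3.
* The softmax subtracts the row maximum before exponentiation.
* A zero residual vector yields a zero loss subgradient.
* Degenerate inputs fail loudly: constant signals cannot be normalised,
  spans shorter than L+h are rejected with the required minimum, and
  non-finite losses raise a divergence error naming the epoch.

## Known limitations

* Patient-specificity is by construction: one model per recording; no
  cross-patient pooling or transfer.
* The epoch-15 published training-loss value depends on unknown batch and
  reduction conventions and is not a target of this implementation.
* ARIMA order is fixed rather than information-criterion selected
  (selectable via the `order` argument).
* Off-axis prediction error is invisible to the reported mm metrics (see
  Metrics above).
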