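# depmci

Dynamic risk prediction of mild cognitive impairment (MCI) in older adults
with depression, from longitudinal panel data.

Depression in later life is a prodromal marker of cognitive decline, but
cross-sectional risk models ignore *how* symptoms move between survey waves.
`depmci` implements the full dynamic-prediction pipeline for wave-indexed
cohort tables (one row per participant per wave): instrument scoring,
age-normed outcome labeling, feature screening and multiple imputation,
sliding-window sample construction, and a small encoder-decoder transformer
that reads the per-wave feature sequence and outputs the probability of MCI
at the next wave.  Because the survey extracts this design targets are
access-restricted, the package ships a seeded synthetic cohort generator
with a planted depression→cognition effect, so every stage is testable
offline.

## The model in brief

* **Exposure and outcome.** CES-D-10 totals (ten 0–3 items, range 0–30;
  ≥ 10 = depressive symptoms) define exposure.  A cognition composite
  (immediate + delayed word recall 0–20, orientation 0–5, serial
  subtraction 0–5, pentagon copy 0–1; total 0–31) defines the outcome:
  within 5-year age strata, a total strictly below the stratum mean − 1 SD
  is labeled MCI.
* **Samples.** Sliding windows pair consecutive waves: a participant
  depressed and MCI-free at wave *t* contributes a sample with features from
  waves *t* and *t*+1 and the label "MCI at *t*+1".  Splits are by
  participant, stratified on outcome.
* **Network.** One token per wave: linear projection + learnable positional
  embedding; encoder blocks of multi-head self-attention with a learnable
  relative positional bias, `softmax((QKᵀ+B)/√d_k)V`; a GELU feedforward
  gated by a sigmoid GLU (`y ⊙ σ(Wy+b)`) and a depthwise-separable
  convolution along the wave axis; every sublayer wired as
  `AdaLN(x + Sublayer(x))` with `AdaLN(x) = γ·LayerNorm(x) + β`
  (ε = 1e−12).  A single learned decoder query cross-attends to the encoder
  output; a linear + sigmoid head yields the risk.
* **Training.** Binary cross-entropy (mean-reduced internally so gradient
  accumulation over 4 mini-batches is exactly one large-batch step) and a
  decoupled-decay AdamW written from its recurrences
  (θ ← θ − α·m̂/(√v̂+ε) − λθ), with early stopping on validation AUC and a
  learning-rate × decay grid search.  Evaluation reports accuracy,
  sensitivity, precision, specificity, F1 and trapezoidal-ROC AUC, plus
  XGBoost and RBF-SVM baselines on the same splits.

The network and its gradients run on a small numpy reverse-mode autodiff
core included in the package (`depmci.autodiff`); no deep-learning framework
is required.  See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

`examples/` contains one short script per capability.  The end-to-end run
(`examples/04_train_and_evaluate.py`, ~2 minutes on one CPU):

```text
$ python examples/04_train_and_evaluate.py
1508 windows, 24 features
grid winner: lr=0.003, weight_decay=0.001 (validation AUC 0.866, best epoch 12)
transformer  test: AUC 0.744  accuracy 0.900  sensitivity 0.143  specificity 0.976
xgboost      test: AUC 0.793  accuracy 0.900
svm          test: AUC 0.812  accuracy 0.922
```

1200 simulated participants yield 1508 depressed, MCI-free windows; all
three learners recover the planted effect of depressive worsening on
next-wave MCI (AUC well above the 0.5 of a cohort with the effect removed;
the transformer gains a few more points at the full benchmark scale of 2000
participants and d_model = 64).  At ~12% incidence the 0.5 decision
threshold is conservative — hence high specificity and low sensitivity;
ranking quality is what AUC measures.  `examples/05_attention_heatmap.py`
exports the feature × embedding-dimension attention attribution matrix
behind the model's interpretability story.

A command-line interface mirrors the library for scripted use:

```bash
depmci simulate --seed 17 --out cohort.csv
depmci prepare  --cohort cohort.csv --out windows.npz --seed 17
depmci train    --windows windows.npz --out ckpt.npz --seed 17
depmci evaluate --ckpt ckpt.npz --windows windows.npz --report metrics.json
depmci heatmap  --ckpt ckpt.npz --windows windows.npz --out heatmap.csv
```

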