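# myoprog

Quantitative prediction of myopia progression in school-aged children and
adolescents. Given a child's irregularly spaced historical vision checks —
refraction (sphere, cylinder, axis), corneal curvature, axial length, visual
acuity and demographics — the package predicts the eye's **spherical
equivalent** (SE = sphere + cylinder/2, in diopters) at a chosen future time.
SE is the screening quantity for myopia (myopia ⇔ SE ≤ −0.5 D; high myopia
⇔ SE ≤ −6 D), so a reliable SE forecast lets clinicians and parents act
before low myopia progresses.

The core model is a **time-aware LSTM (T-LSTM)**: a recurrent cell that
decomposes its previous memory `C` into a short-term subspace
`C^S = tanh(W_d C + b_d)` and its complement `C^T = C − C^S`, discounts only
the short-term part by a decay `g(Δ)` of the elapsed time between checks,

```
Ĉ^S = g(Δ) · C^S,      C* = C^T + Ĉ^S,      g(Δ) = 1 / log(e + Δ),
```

and then applies the ordinary LSTM gate equations with `C*` in place of `C`.
Visit gaps are quantized to quarter bins 1–10 (bin *i* covers [i−1, i)
quarters of 91 days). Each cell receives the current check `x_t`
(a 16-vector after one-hot encoding) and the interval to the *next* element;
the final interval is the **prediction horizon**, and the last cell state is
projected over that horizon before an affine head maps it to SE. With
`g ≡ 1` the whole construction collapses exactly onto a standard LSTM.

The model, backpropagation through time, and the Adam optimizer are
implemented from scratch in NumPy and verified against scalar-loop oracles
and central finite differences. Training uses MSE loss with
length-stratified batches and validation early stopping; evaluation reports
MAE of SE stratified by prediction horizon × input length, myopia level and
age group.

Because longitudinal school-screening records are not publicly available,
the package ships a **synthetic cohort generator** whose marginals mirror a
published screening cohort (75,172 eyes, 2–6 checks per eye) and whose SE
trajectories decline at an eye-specific, age-decelerating, state-dependent
rate. Every pipeline stage — sample augmentation (every chronological
subsequence of ≥ 2 checks becomes a training sample, 2^r − r − 1 per eye
with r checks), standardization, 80/10/10 length-stratified splits, training,
baselines (standard LSTM, random forest, linear regression) and stratified
reporting — is exercised end-to-end on generated cohorts.

## Worked example

```bash
myoprog simulate --seed 1 --n-subjects 200 --out cohort.csv
myoprog preprocess --in cohort.csv --out data/ --seed 1
echo "hidden_size: 16
max_epochs: 200
learning_rate: 0.002
batch_size: 128
seed: 1" > train.yaml
myoprog train --data data/ --config train.yaml --out model.json --log log.jsonl
myoprog evaluate --data data/ --checkpoint model.json --baselines lr --config train.yaml --out eval/
```

The four commands print:

```
wrote 1238 records (400 eyes) to cohort.csv
samples: train=2110 val=257 test=283 (census total 2650)
best val MSE 0.093838 after 144 epochs
overall MAE 0.140 ± 0.113 (283 samples); outputs in eval
```

Reading: 200 subjects contribute 400 eyes and 1,238 checks; subsequence
augmentation expands them to 2,650 supervised samples, split 80/10/10 at eye
level within each sequence-length layer. Early stopping picks the epoch-144
checkpoint, which predicts future SE on held-out eyes with a mean absolute
error of 0.140 D against a measurement-noise floor of ≈ 0.11 D — well
inside the 0.75 D clinical acceptability bound.
`eval/report.txt` shows the MAE broken down by
prediction horizon and input length with small cells (< 100 samples)
flagged, and `eval/comparison.csv` the per-length comparison against the
baselines.

The same objects are available as a library:

```python
from myoprog import CohortParams, generate_cohort, augment, derive_se

derive_se(sphere=-1.25, astigmatism=-0.75)   # -1.625 D  -> low myopia
cohort = generate_cohort(CohortParams(n_subjects=100, seed=1))
samples = [s for eye in cohort for s in augment(eye)]
```

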