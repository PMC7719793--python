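# smmtransfer

Support matrix machines for matrix-form EEG trials, with
knowledge-leverage model-parameter transfer from a source subject.

## Problem

Motor-imagery brain–computer interfaces classify short EEG epochs into
imagined-movement classes. Calibration data for a new subject is
expensive — a session of a few dozen cued trials — and classifiers
trained on 8–20 labeled trials generalize poorly. Data from other
subjects could help, but raw EEG carries personal information and
subjects' signal patterns differ. This package implements a
*model-parameter* transfer route: only a source subject's fitted model
matrix crosses the boundary, never their recordings.

EEG trial features are naturally matrices (spatial filters × time
segments of band power), and vectorizing them destroys row/column
structure. The core classifier here is therefore a **support matrix
machine (SMM)**: a hinge-loss classifier f(X) = tr(WᵀX) + b whose
coefficient matrix W is regularized by the spectral elastic net

    ½ tr(WᵀW) + τ‖W‖* + C Σᵢ max(0, 1 − yᵢ f(Xᵢ)),

where ‖W‖* (the nuclear norm) is the convex surrogate for rank. The
transfer variant (**KL-SMM**) adds λ‖W_s − W‖²_F, pulling the target
model toward the source matrix W_s: λ = 0 is the plain SMM, λ → ∞
copies the source. Training runs ADMM — a box-constrained dual QP for
(W, b), singular value thresholding for the low-rank split variable,
and a multiplier update — with an optional Nesterov-accelerated mode.

Included around the core: a vectorized linear SVM and an adaptive-SVM
baseline (both on the same dual solver), a bandpass → CSP → band-power
EEG feature front-end, a synthetic transfer-task and planted-ERD EEG
generator with known ground truth, metrics (ACC/PPV/SEN/F1/AUC),
cross-validated grid search, paired t-tests, and a CLI.

## Worked example

Eight labeled target trials, a 200-trial source subject with a small
source→target shift, transfer weight λ selected by cross-validation on
the calibration trials:

```python
import numpy as np
from dataclasses import replace
from smmtransfer import (SyntheticTaskSpec, make_transfer_task, Hyperparams,
                         fit, fit_transfer, select_lambda_cv, predict,
                         confusion_metrics, decision_function)

hyper = Hyperparams(C=1.0, tau=0.1)
task = make_transfer_task(SyntheticTaskSpec(seed=0), n_labeled=8)
X_test, y_test = task.target_test.labeled()

smm = fit(task.labeled_train(), hyper)                    # no transfer
lam = select_lambda_cv(task, hyper,
                       [1e-4, 5e-4, 1e-3, 5e-3, 1e-2, 5e-2, 1e-1, 5e-1, 1e0])
klsmm = fit_transfer(task, replace(hyper, lam=lam))       # leverage W_s

for name, model in [("SMM", smm), ("KL-SMM", klsmm)]:
    rep = confusion_metrics(y_test, predict(model, X_test),
                            decision_function(model, X_test))
    print(f"{name:7s} ACC={rep.ACC:.3f}  F1={rep.F1:.3f}  AUC={rep.AUC:.3f}")
print(f"selected lambda = {lam}")
print(f"||W_t - W_s||_F = {np.linalg.norm(klsmm.W - task.source_model.W):.3f}")
```

prints

```
SMM     ACC=0.605  F1=0.559  AUC=0.682
KL-SMM  ACC=0.915  F1=0.920  AUC=0.955
selected lambda = 0.5
||W_t - W_s||_F = 1.210
```

With only 8 calibration trials the no-transfer SMM barely beats chance
(ACC 0.605), while the transfer fit — trusting the source model fairly
strongly (λ = 0.5, landing 1.21 Frobenius units from W_s) — reaches
ACC 0.915. Averaged over seeds the gap is smaller but systematic; see
`docs/methods.md` for the model, the generator's conditions, and the
regimes where transfer stops helping (large source–target shift).

The same workflow is available from the shell:

```sh
smmtransfer simulate --seed 0 --n 200 --out source_dir
smmtransfer fit-source --data source_dir --tau 0.1 --out source.json
smmtransfer transfer-fit --data target_dir --source-model source.json \
    --lam 0.5 --tau 0.1 --out target.json
smmtransfer evaluate --model target.json --data test_dir
```

and `smmtransfer run --config experiment.yaml` orchestrates a full
multi-seed method comparison with CSV tables and a t-test summary.

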