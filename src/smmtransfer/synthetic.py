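"""Synthetic transfer tasks and planted-effect EEG with known ground truth.

Emulates the cross-subject setting at desk scale: a low-rank "true"
regression matrix defines the source subject, the target subject's truth
is a controllably shifted copy, and trials are Gaussian matrices labeled
by the sign of the true decision value with optional label noise and a
margin enforced by rejection sampling.  The EEG generator plants an
ERD-like effect: in one class the variance of a designated band-limited
source is attenuated, mimicking event-related desynchronization.

Every generator is a pure function of its spec and seed: one explicit
RNG stream per call, no global state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .features import EpochArray
from .smm import Hyperparams, MatrixDataset
from .transfer import TransferTask, fit_source

__all__ = [
    "SyntheticTaskSpec",
    "make_lowrank_model",
    "sample_dataset",
    "make_transfer_task",
    "synth_eeg",
]


@dataclass(frozen=True)
class SyntheticTaskSpec:
    """Conditions of a synthetic source-to-target transfer problem.

    ``shift`` is the relative Frobenius perturbation between the (unit-
    norm) source and target truths: 0 means identical subjects, ~0.5-0.7
    a clearly different but still informative source.  ``margin_scale``
    controls the rejection band around the decision boundary so that the
    few-trial regime stays learnable.  Defaults model a small-shift
    transfer problem with slight label noise: a short 20-trial target
    calibration (subsets of 8/14/20 are taken from its prefix) against a
    200-trial source session.
    """

    p: int = 4
    q: int = 4
    rank: int = 2
    shift: float = 0.2
    label_noise: float = 0.05
    margin_scale: float = 1.0
    N_source: int = 200
    N_target_train: int = 20
    N_target_test: int = 200
    seed: int = 0

    def __post_init__(self):
        if min(self.p, self.q) < 1 or not (1 <= self.rank <= min(self.p, self.q)):
            raise ValueError("need p, q >= 1 and 1 <= rank <= min(p, q)")
        if self.shift < 0:
            raise ValueError("shift must be non-negative")
        if not (0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must lie in [0, 0.5)")
        if self.margin_scale <= 0:
            raise ValueError("margin_scale must be positive")


def _normalize(M: np.ndarray) -> np.ndarray:
    return M / np.linalg.norm(M, "fro")


def make_lowrank_model(spec: SyntheticTaskSpec) -> tuple[np.ndarray, np.ndarray, float]:
    """Unit-Frobenius rank-``rank`` source truth and its shifted target copy."""
    rng = np.random.default_rng(spec.seed)
    A = rng.standard_normal((spec.p, spec.rank))
    B = rng.standard_normal((spec.q, spec.rank))
    W_source = _normalize(A @ B.T)
    if spec.shift == 0:
        return W_source, W_source.copy(), 0.0
    E = _normalize(rng.standard_normal((spec.p, spec.q)))
    W_target = _normalize(W_source + spec.shift * E)
    return W_source, W_target, 0.0


def sample_dataset(
    W_true: np.ndarray,
    b_true: float,
    n: int,
    label_noise: float,
    margin_scale: float,
    seed: int,
    prefix_both_classes: int | None = None,
) -> MatrixDataset:
    """Gaussian trial matrices labeled by the true linear matrix classifier.

    Trials with |decision| below 0.1 * margin_scale * ||W_true||_F are
    rejected and redrawn; labels are then flipped independently with
    probability ``label_noise``; the draw repeats until both classes have
    at least two members.  ``prefix_both_classes=k`` additionally redraws
    until the first k trials contain both classes — the condition a cued
    calibration session must satisfy for its shortest usable prefix.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    p, q = W_true.shape
    thresh = 0.1 * margin_scale * np.linalg.norm(W_true, "fro")
    for _attempt in range(1000):
        X = np.empty((n, p, q))
        d = np.empty(n)
        filled = 0
        while filled < n:
            cand = rng.standard_normal((n, p, q))
            dec = np.einsum("jk,ijk->i", W_true, cand) + b_true
            keep = np.abs(dec) >= thresh
            take = min(int(keep.sum()), n - filled)
            X[filled:filled + take] = cand[keep][:take]
            d[filled:filled + take] = dec[keep][:take]
            filled += take
        y = np.where(d >= 0, 1.0, -1.0)
        if label_noise > 0:
            flips = rng.random(n) < label_noise
            y[flips] = -y[flips]
        ok = min((y > 0).sum(), (y < 0).sum()) >= min(2, n // 2)
        if ok and prefix_both_classes is not None:
            k = min(prefix_both_classes, n)
            ok = np.unique(y[:k]).size == 2
        if ok:
            return MatrixDataset.from_arrays(X, y)
    raise RuntimeError("could not draw a dataset with both classes present")


def make_transfer_task(
    spec: SyntheticTaskSpec,
    source_hyper: Hyperparams | None = None,
    n_labeled: int | None = None,
) -> TransferTask:
    """Sample source/target data, fit the source SMM, package the task.

    Sub-seeds for the three datasets are drawn from one stream seeded by
    ``spec.seed``, so a fixed spec reproduces the task bit-identically.
    """
    if source_hyper is None:
        source_hyper = Hyperparams(C=1.0, tau=0.1)
    W_s_true, W_t_true, b_true = make_lowrank_model(spec)
    seeds = np.random.default_rng(spec.seed).integers(0, 2**31 - 1, size=3)
    source = sample_dataset(W_s_true, b_true, spec.N_source, spec.label_noise,
                            spec.margin_scale, int(seeds[0]))
    # the shortest calibration prefix ever used (8 cued trials) must see
    # both classes, as a real paradigm's balanced cue order guarantees
    prefix = min(8 if n_labeled is None else n_labeled, spec.N_target_train)
    target_train = sample_dataset(W_t_true, b_true, spec.N_target_train,
                                  spec.label_noise, spec.margin_scale, int(seeds[1]),
                                  prefix_both_classes=prefix)
    target_test = sample_dataset(W_t_true, b_true, spec.N_target_test,
                                 spec.label_noise, spec.margin_scale, int(seeds[2]))
    source_model = fit_source(source, source_hyper)
    return TransferTask(
        source_model=source_model,
        target_train=target_train,
        target_test=target_test,
        n_labeled=spec.N_target_train if n_labeled is None else n_labeled,
    )


def synth_eeg(
    n_trials: int = 200,
    n_channels: int = 3,
    sfreq: float = 250.0,
    band: tuple[float, float] = (8.0, 30.0),
    effect_size: float = 0.3,
    window: tuple[float, float] = (0.5, 3.0),
    seed: int = 0,
) -> tuple[EpochArray, np.ndarray]:
    """Planted-ERD epoched EEG: class +1 attenuates one latent source.

    ``n_channels`` independent band-limited noise sources are mixed into
    the channels by a random mixing matrix; in class +1 the variance of
    source 0 is multiplied by ``effect_size`` (1 = no effect, smaller =
    stronger desynchronization).  Labels alternate and are shuffled.
    """
    if sfreq <= 2 * band[1]:
        raise ValueError("sfreq must exceed twice the band high edge")
    rng = np.random.default_rng(seed)
    n_samples = int(round((window[1] - window[0]) * sfreq))
    sos = scipy.signal.butter(4, band, btype="bandpass", fs=sfreq, output="sos")

    labels = np.ones(n_trials)
    labels[: n_trials // 2] = -1.0
    rng.shuffle(labels)

    # pad, filter to the band, then trim edges so variance is stationary
    pad = int(sfreq)
    raw = rng.standard_normal((n_trials, n_channels, n_samples + 2 * pad))
    sources = scipy.signal.sosfiltfilt(sos, raw, axis=-1)[:, :, pad:pad + n_samples]
    sources /= sources.std(axis=-1, keepdims=True)
    amp = np.ones((n_trials, n_channels))
    amp[labels > 0, 0] = np.sqrt(effect_size)
    sources = sources * amp[:, :, None]

    mixing = rng.standard_normal((n_channels, n_channels))
    data = np.einsum("cd,ids->ics", mixing, sources)
    names = tuple(f"CH{i}" for i in range(n_channels))
    return EpochArray(data, sfreq, window, names), labels
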