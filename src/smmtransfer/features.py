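"""EEG feature front-end: bandpass -> CSP spatial filters -> band power.

Turns epoched multichannel EEG (trials x channels x samples) into the
small p x q trial matrices the matrix classifiers consume.  The default
pipeline mirrors standard offline motor-imagery practice: a 5th-order
Butterworth band-pass over 8-30 Hz applied forward-backward (zero phase),
common spatial patterns fit on the two class-average trace-normalized
covariances, then log-variance of each spatially filtered signal over a
few equal time segments.  Rows of the feature matrix index spatial
filters, columns index time segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg
import scipy.signal

from .smm import MatrixDataset, TrialMatrix

__all__ = [
    "EpochArray",
    "FeatureConfig",
    "bandpass",
    "fit_spatial_filters",
    "band_power_matrix",
    "Standardizer",
    "read_gdf_epochs",
    "save_trial_csv_dir",
    "load_trial_csv_dir",
]

LOG_FLOOR = 1e-12  # variance floor before the log


@dataclass(frozen=True)
class EpochArray:
    """Epoched EEG: data (n_trials, n_channels, n_samples) at sfreq Hz.

    ``window`` is the (start, end) time in seconds relative to the cue
    that the samples cover.
    """

    data: np.ndarray
    sfreq: float
    window: tuple[float, float] = (0.5, 3.0)
    channel_names: tuple[str, ...] = ()

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        object.__setattr__(self, "data", d)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class FeatureConfig:
    """Band-power feature settings.

    band : pass band in Hz (default 8-30, the mu+beta range carrying
    motor-imagery ERD/ERS); filter_order : Butterworth design order;
    n_spatial_filters : even count of CSP filters (half per class);
    n_windows : equal time segments per trial; log_power : take log of
    segment variances; standardize : z-score feature entries using
    training statistics.
    """

    band: tuple[float, float] = (8.0, 30.0)
    filter_order: int = 5
    n_spatial_filters: int = 6
    n_windows: int = 5
    log_power: bool = True
    standardize: bool = True

    def __post_init__(self):
        lo, hi = self.band
        if not (0 < lo < hi):
            raise ValueError("band must satisfy 0 < low < high")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if self.n_spatial_filters < 2 or self.n_spatial_filters % 2:
            raise ValueError("n_spatial_filters must be a positive even integer")
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")


def bandpass(epochs: EpochArray, cfg: FeatureConfig) -> EpochArray:
    """Zero-phase Butterworth band-pass along the sample axis."""
    lo, hi = cfg.band
    nyq = epochs.sfreq / 2.0
    if hi >= nyq:
        raise ValueError(f"band high edge {hi} Hz is at or above Nyquist {nyq} Hz")
    sos = scipy.signal.butter(cfg.filter_order, [lo, hi], btype="bandpass",
                              fs=epochs.sfreq, output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return EpochArray(filtered, epochs.sfreq, epochs.window, epochs.channel_names)


def _trial_covariances(data: np.ndarray, shrink: float) -> np.ndarray:
    """Per-trial channel covariance, trace-normalized, shrunk toward identity."""
    n_ch = data.shape[1]
    covs = np.einsum("ics,ids->icd", data, data)
    tr = np.trace(covs, axis1=1, axis2=2)
    tr = np.where(tr <= 0, 1.0, tr)
    covs = covs / tr[:, None, None]
    return (1.0 - shrink) * covs + shrink * (np.eye(n_ch) / n_ch)


def fit_spatial_filters(
    epochs: EpochArray,
    labels: np.ndarray,
    n_filters: int | None = None,
    shrink: float = 1e-6,
) -> np.ndarray:
    """CSP filters (channels x n_filters) from two-class epoched EEG.

    Solves the generalized eigenproblem C1 v = mu (C1 + C2) v on the
    class-average trace-normalized covariances and keeps n_filters/2
    eigenvectors from each end of the spectrum (most discriminative
    variance ratios), interleaved large-end first.
    """
    labels = np.asarray(labels).ravel()
    if labels.shape[0] != epochs.n_trials:
        raise ValueError("labels length must match trials")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("CSP requires exactly two classes")
    if n_filters is None:
        n_filters = 6
    if n_filters % 2 or n_filters < 2:
        raise ValueError("n_filters must be a positive even integer")
    n_ch = epochs.n_channels
    if n_filters > n_ch:
        raise ValueError(f"n_filters={n_filters} exceeds channel count {n_ch}")

    covs = _trial_covariances(epochs.data, shrink)
    C1 = covs[labels == classes[0]].mean(axis=0)
    C2 = covs[labels == classes[1]].mean(axis=0)
    # eigenvalues of (C1, C1+C2) lie in [0,1]; ends of the spectrum carry
    # the largest between-class variance ratios
    evals, evecs = scipy.linalg.eigh(C1, C1 + C2)
    order = np.argsort(evals)[::-1]
    evecs = evecs[:, order]
    half = n_filters // 2
    pick = np.empty(n_filters, dtype=int)
    pick[0::2] = np.arange(half)  # large-eigenvalue end
    pick[1::2] = np.arange(n_ch - half, n_ch)[::-1]  # small end
    return evecs[:, pick]


def band_power_matrix(
    epochs: EpochArray,
    filters: np.ndarray,
    cfg: FeatureConfig,
    labels: np.ndarray | None = None,
) -> MatrixDataset:
    """Project, segment, and take per-segment (log-)variance.

    Output trial matrices are (n_filters x n_windows): p indexes spatial
    filters, q indexes equal time segments over the epoch window.
    """
    filters = np.asarray(filters, dtype=float)
    n_samples = epochs.data.shape[-1]
    seg_len = n_samples // cfg.n_windows
    if seg_len < 10:
        raise ValueError(
            f"n_windows={cfg.n_windows} gives segments of {seg_len} samples (< 10)")
    projected = np.einsum("cf,ics->ifs", filters, epochs.data)
    usable = seg_len * cfg.n_windows
    segs = projected[:, :, :usable].reshape(epochs.n_trials, filters.shape[1],
                                            cfg.n_windows, seg_len)
    power = segs.var(axis=-1)
    if cfg.log_power:
        power = np.log(np.maximum(power, LOG_FLOOR))
    if labels is None:
        return MatrixDataset.from_arrays(power)
    return MatrixDataset.from_arrays(power, np.asarray(labels).ravel())


@dataclass
class Standardizer:
    """Per-entry z-scoring with statistics frozen on the labeled training set."""

    mean: np.ndarray = field(default=None)  # type: ignore[assignment]
    std: np.ndarray = field(default=None)  # type: ignore[assignment]

    def fit(self, data: MatrixDataset) -> "Standardizer":
        X, _ = data.labeled()
        self.mean = X.mean(axis=0)
        std = X.std(axis=0)
        self.std = np.where(std < 1e-12, 1.0, std)
        return self

    def transform(self, data: MatrixDataset) -> MatrixDataset:
        if self.mean is None:
            raise ValueError("standardizer not fitted")
        return MatrixDataset([
            TrialMatrix((t.values - self.mean) / self.std, t.label) for t in data.trials
        ])


# ----------------------------------------------------------------------
# readers / writers
# ----------------------------------------------------------------------

def read_gdf_epochs(path: str | Path, window: tuple[float, float] = (0.5, 3.0),
                    event_ids: dict | None = None) -> tuple[EpochArray, np.ndarray]:
    """Adapter reading a GDF recording into an EpochArray (requires ``mne``).

    Any source of epoched arrays with a sampling rate satisfies the same
    contract; this reader only covers the common competition-format case.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading GDF files requires the optional 'mne' extra") from exc
    raw = mne.io.read_raw_gdf(str(path), preload=True, verbose="error")
    events, ev_map = mne.events_from_annotations(raw, verbose="error")
    if event_ids is None:
        # left/right hand cues in the competition annotation scheme
        event_ids = {k: v for k, v in ev_map.items() if k in ("769", "770")}
    ep = mne.Epochs(raw, events, event_id=event_ids, tmin=window[0], tmax=window[1],
                    baseline=None, preload=True, verbose="error")
    labels = np.where(ep.events[:, 2] == sorted(event_ids.values())[0], 1.0, -1.0)
    arr = ep.get_data()
    return EpochArray(arr, float(ep.info["sfreq"]), window,
                      tuple(ep.ch_names)), labels


def save_trial_csv_dir(data: MatrixDataset, directory: str | Path) -> None:
    """Write one CSV per trial plus a ``labels.csv`` manifest (trial_id,label)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, t in enumerate(data.trials):
        name = f"trial_{i:04d}.csv"
        np.savetxt(directory / name, t.values, delimiter=",")
        rows.append(f"{name},{'' if t.label is None else t.label}")
    (directory / "labels.csv").write_text("trial_id,label\n" + "\n".join(rows) + "\n")


def load_trial_csv_dir(directory: str | Path) -> MatrixDataset:
    directory = Path(directory)
    manifest = (directory / "labels.csv").read_text().strip().splitlines()[1:]
    trials = []
    for line in manifest:
        name, _, lab = line.partition(",")
        values = np.loadtxt(directory / name, delimiter=",", ndmin=2)
        trials.append(TrialMatrix(values, float(lab) if lab.strip() else None))
    return MatrixDataset(trials)
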