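"""EEG front-end: from multichannel trials to 32-bit feature codes.

The chain mirrors the imagined-speech analysis pipeline: an 8–30 Hz
Butterworth band-pass (order 5, zero-phase), baseline correction against
the pre-stimulus window, multivariate empirical mode decomposition, and
selection of the dominant alpha-band (8–12 Hz) IMF.  Pairwise common
spatial pattern filters (/a/ vs /i/, /a/ vs /u/, /i/ vs /u/) are fitted on
the training split of that alpha component; each trial's log-variance CSP
features are thresholded at training-set cutoffs (cluster midpoints by
default) and the three per-pair bit blocks are concatenated and
zero-padded to the 32 bits the crossbar's pre-neurons expect.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .codes import CLASSES, FeatureCode, N_BITS
from .csp import CSPModel, bit_thresholds, csp_features, csp_fit
from .memd import IMFSet, memd

logger = logging.getLogger(__name__)

__all__ = [
    "EEGDataset",
    "FeatureConfig",
    "bandpass",
    "baseline_correct",
    "select_alpha_imf",
    "morlet_tf",
    "binarize",
    "extract_pipeline",
]


@dataclass
class EEGDataset:
    """Epoched multichannel EEG trials.

    trials : (n_trials, n_channels, n_samples) array in microvolts.
    fs : sampling rate in samples/s.
    labels : per-trial vowel class ('a', 'i', 'u').
    baseline_window, task_window : (start, stop) sample intervals inside a
        trial used for baseline correction and feature extraction.
    """

    trials: np.ndarray
    fs: float
    labels: List[str]
    baseline_window: Tuple[int, int]
    task_window: Tuple[int, int]

    def __post_init__(self):
        self.trials = np.asarray(self.trials, dtype=float)
        if self.trials.ndim != 3:
            raise ValueError("trials must be (n_trials, n_channels, n_samples)")
        if len(self.labels) != self.trials.shape[0]:
            raise ValueError("one label per trial required")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_channels(self) -> int:
        return self.trials.shape[1]

    @property
    def n_samples(self) -> int:
        return self.trials.shape[2]

    def map(self, fn: Callable[[np.ndarray], np.ndarray]) -> "EEGDataset":
        return replace(self, trials=np.stack([fn(t) for t in self.trials]))

    # ---- delimited-text round trip -------------------------------------
    def write_text(self, directory) -> None:
        """Write one matrix file per trial plus a sidecar annotation table."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        lines = ["trial\tfile\tclass"]
        for i, (trial, lab) in enumerate(zip(self.trials, self.labels)):
            name = f"trial{i:04d}.tsv"
            np.savetxt(d / name, trial, fmt="%.6g", delimiter="\t")
            lines.append(f"{i}\t{name}\t{lab}")
        (d / "annotations.tsv").write_text("\n".join(lines) + "\n")
        meta = (
            f"fs\t{self.fs}\nbaseline_window\t{self.baseline_window[0]}\t{self.baseline_window[1]}\n"
            f"task_window\t{self.task_window[0]}\t{self.task_window[1]}\n"
        )
        (d / "meta.tsv").write_text(meta)

    @classmethod
    def read_text(cls, directory) -> "EEGDataset":
        d = Path(directory)
        meta = {}
        for line in (d / "meta.tsv").read_text().splitlines():
            parts = line.split("\t")
            meta[parts[0]] = [float(x) for x in parts[1:]]
        rows = (d / "annotations.tsv").read_text().splitlines()[1:]
        trials, labels = [], []
        for row in rows:
            _, name, lab = row.split("\t")
            trials.append(np.loadtxt(d / name, delimiter="\t"))
            labels.append(lab)
        return cls(
            trials=np.stack(trials),
            fs=meta["fs"][0],
            labels=labels,
            baseline_window=tuple(int(x) for x in meta["baseline_window"]),
            task_window=tuple(int(x) for x in meta["task_window"]),
        )

    @classmethod
    def from_edf(cls, path, labels, trial_samples, baseline_window, task_window):
        """Epoch a continuous EDF recording into fixed-length labelled trials.

        Requires :mod:`mne` for EDF parsing.
        """
        try:
            import mne
        except ImportError as e:  # pragma: no cover - optional dependency
            raise ImportError("reading EDF files requires the 'mne' package") from e
        raw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
        data = raw.get_data() * 1e6  # volts -> microvolts
        fs = raw.info["sfreq"]
        n = len(labels)
        trials = np.stack(
            [data[:, i * trial_samples : (i + 1) * trial_samples] for i in range(n)]
        )
        return cls(trials, fs, list(labels), baseline_window, task_window)


def bandpass(
    x: np.ndarray, fs: float, low: float = 8.0, high: float = 30.0, order: int = 5
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    if not 0 < low < high < fs / 2:
        raise ValueError("band edges must satisfy 0 < low < high < fs/2")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def baseline_correct(trial: np.ndarray, baseline_window: Tuple[int, int]) -> np.ndarray:
    """Subtract each channel's mean over the pre-stimulus window from the whole trial."""
    lo, hi = baseline_window
    trial = np.asarray(trial, dtype=float)
    if not 0 <= lo < hi <= trial.shape[-1]:
        raise ValueError("baseline window must be a non-empty interval inside the trial")
    return trial - trial[..., lo:hi].mean(axis=-1, keepdims=True)


def select_alpha_imf(
    imfset: IMFSet, fs: float, band: Tuple[float, float] = (8.0, 12.0)
) -> int:
    """Index of the dominant alpha-band IMF.

    Dominance is measured as the mean (over channels) spectral power inside
    the band: the mode that carries the most alpha activity.  (A pure
    power-*fraction* criterion can prefer a negligible slow mode that
    happens to sit inside the band.)  Ties resolve to the lowest index, the
    fastest mode.
    """
    if imfset.n_imfs == 0:
        raise ValueError("empty IMF set")
    power = np.empty(imfset.n_imfs)
    for k, imf in enumerate(imfset.imfs):
        f, pxx = sps.periodogram(imf, fs=fs, axis=-1)
        mask = (f >= band[0]) & (f <= band[1])
        power[k] = np.mean(pxx[:, mask].sum(axis=-1))
    return int(np.argmax(power))


def morlet_tf(
    x: np.ndarray, fs: float, freqs: Sequence[float], n_cycles: float = 7.0
) -> np.ndarray:
    """Time-frequency power map via convolution with complex Morlet atoms.

    Returns |coefficient|^2 with shape (n_freqs, n_samples).  Each atom is a
    complex exponential under a Gaussian of width sigma_t = n_cycles /
    (2*pi*f), L2-normalised so power scales quadratically with amplitude.
    """
    x = np.asarray(x, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= fs / 2):
        raise ValueError("frequencies must lie in (0, fs/2)")
    out = np.empty((freqs.size, x.shape[-1]))
    for i, f in enumerate(freqs):
        sigma_t = n_cycles / (2 * np.pi * f)
        half = int(np.ceil(3.5 * sigma_t * fs))
        t = np.arange(-half, half + 1) / fs
        atom = np.exp(2j * np.pi * f * t) * np.exp(-(t**2) / (2 * sigma_t**2))
        atom /= np.linalg.norm(atom)
        coef = sps.fftconvolve(x, atom, mode="same")
        out[i] = np.abs(coef) ** 2
    return out


def binarize(
    features: np.ndarray, thresholds: np.ndarray, n_bits: int = N_BITS,
    label: Optional[str] = None,
) -> FeatureCode:
    """Threshold features at their fitted training cutoffs and pad to ``n_bits``.

    A bit is 1 iff the feature strictly exceeds its threshold (a feature
    exactly at the cutoff maps to 0).  Feature blocks longer than
    ``n_bits`` are rejected; shorter ones are zero-padded on the right.
    """
    features = np.asarray(features, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.shape != features.shape:
        raise ValueError("thresholds not fitted for this feature length")
    if features.size > n_bits:
        raise ValueError(f"{features.size} features do not fit in {n_bits} bits")
    bits = np.zeros(n_bits, dtype=int)
    bits[: features.size] = (features > thresholds).astype(int)
    return FeatureCode(bits=tuple(bits), label=label)


@dataclass(frozen=True)
class FeatureConfig:
    """Numeric settings of the feature-extraction chain."""

    band: Tuple[float, float] = (8.0, 30.0)
    filter_order: int = 5
    alpha_band: Tuple[float, float] = (8.0, 12.0)
    n_directions: int = 64
    max_imfs: int = 8
    na_noise_channels: int = 2  # noise-assisted MEMD against mode mixing
    na_noise_scale: float = 0.25
    n_csp_filters: int = 6
    csp_shrinkage: float = 0.1
    threshold_method: str = "cluster"  # bimodal cluster midpoint; "median" also supported
    n_bits: int = N_BITS
    n_train: int = 65
    n_test: int = 15
    seed: int = 0  # train/test split and NA-MEMD noise
    morlet_cycles: float = 7.0
    artifact_hook: Optional[Callable[[np.ndarray], np.ndarray]] = None

    @property
    def class_pairs(self) -> Tuple[Tuple[str, str], ...]:
        return (("a", "i"), ("a", "u"), ("i", "u"))


def _stratified_split(
    labels: Sequence[str], n_train: int, n_test: int, seed: int
) -> Tuple[List[int], List[int]]:
    """Class-balanced train/test indices (within one of equal per class)."""
    rng = np.random.default_rng(seed)
    by_class = {c: [i for i, l in enumerate(labels) if l == c] for c in CLASSES}
    for idx in by_class.values():
        rng.shuffle(idx)
    train, test = [], []
    # spread the requested totals over classes as evenly as possible
    for k, c in enumerate(CLASSES):
        ntr = n_train // 3 + (1 if k < n_train % 3 else 0)
        nte = n_test // 3 + (1 if k < n_test % 3 else 0)
        idx = by_class[c]
        if len(idx) < ntr + nte:
            raise ValueError(
                f"class {c!r} has {len(idx)} trials, needs {ntr + nte} for the split"
            )
        train.extend(idx[:ntr])
        test.extend(idx[ntr : ntr + nte])
    return sorted(train), sorted(test)


def _dedup(codes: List[FeatureCode], name: str, log: Dict) -> List[FeatureCode]:
    seen, out, dropped = set(), [], 0
    for c in codes:
        key = (c.bits, c.label)
        if key in seen:
            dropped += 1
            continue
        seen.add(key)
        out.append(c)
    if dropped:
        logger.warning("%d duplicate %s codes collapsed", dropped, name)
    log[f"duplicates_{name}"] = dropped
    return out


def extract_pipeline(
    dataset: EEGDataset, config: FeatureConfig = FeatureConfig()
) -> Tuple[List[FeatureCode], List[FeatureCode], Dict]:
    """Run the full EEG-to-code chain and return (train_codes, test_codes, log).

    CSP filters and binarization thresholds are fitted on the training split
    only; the test split is transformed with the frozen models.  The log
    records the split, the selected alpha IMF per trial, the fitted CSP
    models and any deduplication.
    """
    log: Dict = {"stages": []}

    filtered = dataset.map(lambda t: bandpass(t, dataset.fs, *config.band, config.filter_order))
    log["stages"].append("bandpass")
    corrected = filtered.map(lambda t: baseline_correct(t, dataset.baseline_window))
    log["stages"].append("baseline_correct")
    if config.artifact_hook is not None:
        corrected = corrected.map(config.artifact_hook)
        log["stages"].append("artifact_hook")

    lo, hi = dataset.task_window
    alpha_components: List[np.ndarray] = []
    alpha_idx: List[int] = []
    na_rng = np.random.default_rng(config.seed)
    for trial in corrected.trials:
        imfset = memd(
            trial,
            n_directions=config.n_directions,
            max_imfs=config.max_imfs,
            noise_channels=config.na_noise_channels,
            noise_scale=config.na_noise_scale,
            rng=na_rng,
        )
        if imfset.n_imfs == 0:
            raise ValueError("trial produced no IMFs; signal too smooth to decompose")
        k = select_alpha_imf(imfset, dataset.fs, config.alpha_band)
        alpha_idx.append(k)
        alpha_components.append(imfset.imfs[k][:, lo:hi])
    log["stages"] += ["memd", "select_alpha_imf"]
    log["alpha_imf_index"] = alpha_idx

    train_idx, test_idx = _stratified_split(
        dataset.labels, config.n_train, config.n_test, config.seed
    )
    log["train_indices"], log["test_indices"] = train_idx, test_idx

    models: List[CSPModel] = []
    for pair in config.class_pairs:
        t1 = [alpha_components[i] for i in train_idx if dataset.labels[i] == pair[0]]
        t2 = [alpha_components[i] for i in train_idx if dataset.labels[i] == pair[1]]
        m = csp_fit(
            t1,
            t2,
            n_filters=config.n_csp_filters,
            class_pair=pair,
            shrinkage=config.csp_shrinkage,
        )
        models.append(m)
    log["stages"].append("csp_fit")
    log["csp_models"] = models

    def trial_features(i: int) -> np.ndarray:
        return np.concatenate(
            [csp_features(m, alpha_components[i]) for m in models]
        )

    train_feats = np.stack([trial_features(i) for i in train_idx])
    thresholds = bit_thresholds(train_feats, method=config.threshold_method)
    log["thresholds"] = thresholds

    def to_code(feats: np.ndarray, label: str) -> FeatureCode:
        return binarize(feats, thresholds, n_bits=config.n_bits, label=label)

    train_codes = [
        to_code(f, dataset.labels[i]) for f, i in zip(train_feats, train_idx)
    ]
    test_codes = [
        to_code(trial_features(i), dataset.labels[i]) for i in test_idx
    ]
    log["stages"] += ["csp_features", "binarize"]

    train_codes = _dedup(train_codes, "train", log)
    test_codes = _dedup(test_codes, "test", log)
    return train_codes, test_codes, log
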