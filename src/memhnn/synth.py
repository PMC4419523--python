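"""Seeded generators for synthetic EEG and synthetic 32-bit feature codes.

The EEG generator emulates the statistical structure the front-end assumes:
pink-noise background on every channel, and — during the imagery window —
an amplitude-enveloped alpha-band (≈10 Hz) oscillation mixed through a
class-specific spatial pattern.  The three patterns occupy disjoint channel
groups, so they are exactly the kind of planted spatial contrast CSP is
built to recover.  The code generator emulates the binarized feature codes
directly: three well-separated 32-bit class prototypes plus independent
per-bit flips.

Both generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .codes import CLASSES, FeatureCode, N_BITS
from .eeg import EEGDataset

__all__ = ["EEGGenConfig", "CodeGenConfig", "gen_eeg", "gen_codes"]


@dataclass(frozen=True)
class EEGGenConfig:
    """Synthetic-EEG settings.

    The trial timeline copies the recording protocol: a 1 s cue, a 1 s
    baseline, a 0.25 s preparation gap and a 1.25 s imagery window, at
    250 samples/s for 3.5 s total.  ``effect_size`` is the planted alpha
    amplitude relative to the background noise RMS; ``n_channels`` defaults
    to 16 for desk-scale runs (64 as in the recording hardware is
    supported).
    """

    n_channels: int = 16
    fs: float = 250.0
    trial_length: float = 3.5
    cue_window: Tuple[float, float] = (0.0, 1.0)
    baseline_window: Tuple[float, float] = (1.0, 2.0)
    prep_window: Tuple[float, float] = (2.0, 2.25)
    imagery_window: Tuple[float, float] = (2.25, 3.5)
    alpha_freq: float = 10.0
    effect_size: float = 2.0
    noise_level: float = 10.0  # microvolts RMS
    noise_exponent: float = 1.0  # 1/f^exponent power spectrum
    trials_per_class: int = 27
    seed: int = 0

    def __post_init__(self):
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        edges = [*self.cue_window, *self.baseline_window, *self.prep_window, *self.imagery_window]
        if edges != sorted(edges) or edges[0] != 0 or edges[-1] != self.trial_length:
            raise ValueError("windows must partition the trial")
        if self.n_channels < 12:
            raise ValueError("need at least 12 channels for three 4-channel patterns")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_length * self.fs))

    def samples(self, window: Tuple[float, float]) -> Tuple[int, int]:
        return int(round(window[0] * self.fs)), int(round(window[1] * self.fs))


def _pink_noise(rng: np.random.Generator, shape: Tuple[int, ...], exponent: float) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, unit RMS, along the last axis."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    white = rng.standard_normal(shape[:-1] + (freqs.size,)) + 1j * rng.standard_normal(
        shape[:-1] + (freqs.size,)
    )
    x = np.fft.irfft(white * scale, n=n, axis=-1)
    rms = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    return x / np.maximum(rms, 1e-300)


def _class_patterns(n_channels: int) -> np.ndarray:
    """Three orthogonal unit-norm spatial patterns on disjoint 4-channel groups."""
    patterns = np.zeros((3, n_channels))
    for k in range(3):
        patterns[k, 4 * k : 4 * (k + 1)] = 0.5
    return patterns


def gen_eeg(config: EEGGenConfig = EEGGenConfig()) -> EEGDataset:
    """Generate a labelled synthetic EEG dataset (classes interleaved a,i,u,...)."""
    rng = np.random.default_rng(config.seed)
    n_samp = config.n_samples
    patterns = _class_patterns(config.n_channels)
    i0, i1 = config.samples(config.imagery_window)
    t = np.arange(i1 - i0) / config.fs
    envelope = np.hanning(i1 - i0)

    trials, labels = [], []
    for trial_idx in range(config.trials_per_class * 3):
        cls_idx = trial_idx % 3
        x = config.noise_level * _pink_noise(
            rng, (config.n_channels, n_samp), config.noise_exponent
        )
        if config.effect_size > 0:
            phase = rng.uniform(0, 2 * np.pi)
            amp = config.effect_size * config.noise_level * rng.lognormal(0.0, 0.2)
            osc = amp * envelope * np.sin(2 * np.pi * config.alpha_freq * t + phase)
            x[:, i0:i1] += patterns[cls_idx][:, None] * osc[None, :]
        trials.append(x)
        labels.append(CLASSES[cls_idx])
    return EEGDataset(
        trials=np.stack(trials),
        fs=config.fs,
        labels=labels,
        baseline_window=config.samples(config.baseline_window),
        task_window=config.samples(config.imagery_window),
    )


@dataclass(frozen=True)
class CodeGenConfig:
    """Synthetic feature-code settings.

    Prototypes are balanced (half the bits set), which mirrors the
    median-thresholded binarizer of the EEG front-end, and are rejected
    until every pair is at least ``min_separation`` bits apart.  Each
    emitted sample is its class prototype with independent bit flips at
    rate ``p``; the default counts match the 65 training / 15 testing
    patterns of the recognition experiment.
    """

    n_bits: int = N_BITS
    min_separation: int = 12
    p_flip: float = 0.05
    n_train: int = 65
    n_test: int = 15
    seed: int = 0
    max_tries: int = 10_000

    def __post_init__(self):
        if not 0 <= self.p_flip < self.min_separation / (2 * self.n_bits):
            raise ValueError("p_flip must satisfy p < separation / (2 n_bits)")
        if self.min_separation > self.n_bits:
            raise ValueError("min_separation cannot exceed n_bits")


def _balanced_prototypes(config: CodeGenConfig, rng: np.random.Generator) -> np.ndarray:
    for _ in range(config.max_tries):
        protos = np.zeros((3, config.n_bits), dtype=int)
        for k in range(3):
            ones = rng.choice(config.n_bits, size=config.n_bits // 2, replace=False)
            protos[k, ones] = 1
        d = [
            int(np.sum(protos[a] != protos[b]))
            for a in range(3)
            for b in range(a + 1, 3)
        ]
        if min(d) >= config.min_separation:
            return protos
    raise RuntimeError("could not draw prototypes at the requested separation")


def gen_codes(
    config: CodeGenConfig = CodeGenConfig(),
) -> Tuple[List[FeatureCode], List[FeatureCode], np.ndarray]:
    """Generate distinct train/test code sets and return (train, test, prototypes).

    Classes are interleaved and balanced to within one of equal; all emitted
    codes are pairwise distinct (across both sets).  With ``p_flip = 0``
    only the three prototypes are distinct, so both sets collapse to those.
    """
    rng = np.random.default_rng(config.seed)
    protos = _balanced_prototypes(config, rng)

    def sample(cls_idx: int, seen: set) -> Optional[FeatureCode]:
        for _ in range(config.max_tries):
            bits = protos[cls_idx].copy()
            flips = rng.random(config.n_bits) < config.p_flip
            bits = np.where(flips, 1 - bits, bits)
            code = FeatureCode(bits=tuple(int(b) for b in bits), label=CLASSES[cls_idx])
            if code.bits not in seen:
                seen.add(code.bits)
                return code
            if config.p_flip == 0:
                return None  # only the prototype exists; sets collapse
        raise RuntimeError("could not draw a fresh distinct code")

    def build(n: int, seen: set) -> List[FeatureCode]:
        out: List[FeatureCode] = []
        counts = [n // 3 + (1 if k < n % 3 else 0) for k in range(3)]
        order = [k for k in range(3) for _ in range(counts[k])]
        # interleave classes a,i,u,a,i,u,... trimming to the per-class counts
        interleaved = []
        remaining = counts.copy()
        k = 0
        while sum(remaining) > 0:
            if remaining[k % 3] > 0:
                interleaved.append(k % 3)
                remaining[k % 3] -= 1
            k += 1
        for cls_idx in interleaved:
            code = sample(cls_idx, seen)
            if code is not None:
                out.append(code)
        return out

    seen: set = set()
    train = build(config.n_train, seen)
    test = build(config.n_test, seen)
    return train, test, protos
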