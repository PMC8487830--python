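"""Seeded synthetic corpora with class-dependent fractal structure.

The real radiotelephony recordings behind the method are restricted, so
this module produces a statistical stand-in (not a speech model): each
class is fractional Gaussian noise (fGn) with a class-specific Hurst
exponent, optionally degraded by additive white noise at a chosen SNR.
The features under study measure exactly this scaling structure — a
non-fatigued class with high H (smooth, persistent) and a fatigued class
with low H (rough, anti-persistent) is the minimal corpus on which every
stage of the pipeline is exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import AudioSignal, write_wav

LABEL_CODES = {"normal": -1, "fatigued": 1}


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Study conditions for a synthetic corpus.

    Defaults: 412 utterances per class (balanced 824 total), 0.25 s at
    16 kHz, H = 0.8 for normal vs 0.3 for fatigued speech, white noise at
    20 dB SNR.
    """

    n_per_class: int = 412
    hurst_by_class: dict = field(
        default_factory=lambda: {"normal": 0.8, "fatigued": 0.3}
    )
    duration_s: float = 0.25
    rate: int = 16000
    snr_db: float | None = 20.0
    integrate: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        for label, h in self.hurst_by_class.items():
            if not 0.0 < h < 1.0:
                raise ValueError(f"Hurst for class {label!r} must lie in (0, 1)")


def generate_fgn(n: int, hurst: float, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Exact unit-variance fractional Gaussian noise by circulant embedding.

    The fGn autocovariance gamma(k) = (|k+1|^2H - 2|k|^2H + |k-1|^2H)/2 is
    embedded in a circulant of size 2(n-1); its eigenvalues are obtained by
    FFT and a complex Gaussian vector is colored accordingly. Falls back to
    clipping tiny negative eigenvalues (with a warning) if the embedding is
    not PSD.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError("hurst must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n == 1:
        return rng.standard_normal(1)
    k = np.arange(n, dtype=float)
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # circulant first row, size 2(n-1)
    eig = np.fft.fft(row).real
    if eig.min() < -1e-8:
        import warnings

        warnings.warn(
            "circulant embedding not PSD; clipping negative eigenvalues "
            "(approximate spectral synthesis)",
            stacklevel=2,
        )
    eig = np.maximum(eig, 0.0)
    m = row.size
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    x = np.fft.fft(np.sqrt(eig / m) * z)
    return x[:n].real


def _add_noise_snr(x: np.ndarray, snr_db: float, rng: np.random.Generator) -> np.ndarray:
    p_signal = float(np.mean(x**2))
    p_noise = p_signal / 10.0 ** (snr_db / 10.0)
    return x + rng.standard_normal(x.size) * np.sqrt(p_noise)


@dataclass
class SyntheticCorpus:
    """Generated signals with labels and a manifest table."""

    signals: list[AudioSignal]
    labels: np.ndarray  # -1 normal / +1 fatigued
    manifest: pd.DataFrame
    spec: SyntheticCorpusSpec


def generate_corpus(
    spec: SyntheticCorpusSpec | None = None, out_dir: str | Path | None = None
) -> SyntheticCorpus:
    """Generate n_per_class signals per class, reproducible from the seed.

    Each signal starts from an fGn realization at the class Hurst exponent
    plus white noise at spec.snr_db on the increments (None or inf means
    noise-free). With integrate=True (default) the running sum is emitted —
    the fBm-like 1/f-type trace whose graph has fractal dimension 2 - H,
    so the class structure survives the fine-scale analysis downstream.
    When out_dir is given, 16-bit WAV files and a manifest.csv are written.
    """
    if spec is None:
        spec = SyntheticCorpusSpec()
    rng = np.random.default_rng(spec.seed)
    n_samples = int(round(spec.duration_s * spec.rate))
    signals: list[AudioSignal] = []
    labels: list[int] = []
    rows: list[dict] = []
    for label, hurst in spec.hurst_by_class.items():
        code = LABEL_CODES.get(label, 1)
        for j in range(spec.n_per_class):
            x = generate_fgn(n_samples, hurst, rng)
            if spec.snr_db is not None and np.isfinite(spec.snr_db):
                x = _add_noise_snr(x, spec.snr_db, rng)
            if spec.integrate:
                x = np.cumsum(x)
            # normalize peak so optional WAV export does not clip
            sig = AudioSignal(samples=x / np.max(np.abs(x)), rate=spec.rate)
            uid = f"{label}_{j:04d}"
            signals.append(sig)
            labels.append(code)
            rows.append({"id": uid, "path": f"{uid}.wav", "label": label})
    manifest = pd.DataFrame(rows)
    corpus = SyntheticCorpus(
        signals=signals, labels=np.array(labels, dtype=float), manifest=manifest, spec=spec
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sig, row in zip(corpus.signals, rows):
            write_wav(out_dir / row["path"], sig)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return corpus
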