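"""Nonlinear vocal features: wavelet-Hurst (pH) and wavelet-fractal (SWFF).

Both features quantify the long-range scaling structure of speech, which
shifts with speaker fatigue. The Hurst exponent H is estimated from the
slope of the log2 wavelet detail-coefficient variance across scales; the
fractal dimension D is estimated with Higuchi's curve-length method and is
tied to H by D = 2 - H for self-affine series.

* pH: [H_0, H_1, ..., H_l] — H of the raw series plus H of each wavelet
  detail sequence.
* SWFF: [D_x, D_d1, ..., D_d4] — Higuchi D of the series plus of each of
  the first four wavelet detail layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .preprocess import FrameMatrix

DEFAULT_WAVELET = "db4"


@dataclass(frozen=True)
class WaveletDecomposition:
    """Mallat pyramid: approximation at the deepest scale + detail layers.

    details[i] is the detail sequence of level i+1, level 1 being the
    finest (upper half-band of the original signal).
    """

    approx: np.ndarray
    details: list[np.ndarray]
    wavelet_name: str
    levels: int


@dataclass(frozen=True)
class HurstEstimate:
    """H = (1 + alpha) / 2, alpha the slope of log2 sigma_l^2 vs level l."""

    H: float
    alpha: float
    per_scale_variance: np.ndarray
    levels: int


@dataclass(frozen=True)
class FDEstimate:
    """Higuchi fractal dimension with its log-log regression inputs."""

    D: float
    curve_lengths: np.ndarray  # (k_max, 2) columns: k, L(k)
    k_max: int


def dwt_decompose(
    series: np.ndarray, wavelet_name: str = DEFAULT_WAVELET, levels: int = 4
) -> WaveletDecomposition:
    """Discrete wavelet transform to `levels` scales (Mallat pyramid)."""
    series = np.asarray(series, dtype=float)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if series.size < 2**levels:
        raise ValueError(
            f"series of length {series.size} too short for {levels} levels"
        )
    coeffs = pywt.wavedec(series, wavelet_name, level=levels)
    approx = coeffs[0]
    details = list(coeffs[:0:-1])  # reorder so details[0] is level 1 (finest)
    return WaveletDecomposition(
        approx=approx, details=details, wavelet_name=wavelet_name, levels=levels
    )


def _max_levels(n: int, wavelet_name: str) -> int:
    return pywt.dwt_max_level(n, pywt.Wavelet(wavelet_name).dec_len)


def wavelet_hurst(
    series: np.ndarray,
    levels: int | None = None,
    wavelet_name: str = DEFAULT_WAVELET,
) -> HurstEstimate:
    """Estimate the Hurst exponent from wavelet detail variances.

    sigma_l^2 = mean of squared detail coefficients at level l; alpha is the
    least-squares slope of log2(sigma_l^2) against l, and H = (1 + alpha)/2.
    With levels=None the maximum usable decomposition depth is taken
    (capped at 6, at least 2 scales for the regression; deeper pyramids
    dilute the fine-scale bias of the estimator).
    """
    series = np.asarray(series, dtype=float)
    if np.ptp(series) == 0.0:
        raise ValueError("zero detail variance: input is constant")
    if levels is None:
        levels = max(2, min(6, _max_levels(series.size, wavelet_name)))
    if levels < 2:
        raise ValueError("need at least 2 scales to regress")
    dec = dwt_decompose(series, wavelet_name, levels)
    var = np.array([np.mean(d**2) for d in dec.details])
    if np.any(var <= 0.0):
        raise ValueError("zero detail variance (constant input?)")
    scale = np.arange(1, levels + 1, dtype=float)
    alpha = float(np.polyfit(scale, np.log2(var), 1)[0])
    return HurstEstimate(
        H=(1.0 + alpha) / 2.0, alpha=alpha, per_scale_variance=var, levels=levels
    )


def ph_feature(
    series: np.ndarray, levels: int = 4, wavelet_name: str = DEFAULT_WAVELET
) -> np.ndarray:
    """pH vector [H_0, H_1, ..., H_levels] of length levels + 1.

    H_0 comes from the raw series; H_i from the i-th detail sequence, whose
    own decomposition depth adapts to its (shorter) length.
    """
    dec = dwt_decompose(series, wavelet_name, levels)
    out = [wavelet_hurst(series, levels=levels, wavelet_name=wavelet_name).H]
    for d in dec.details:
        out.append(wavelet_hurst(d, levels=None, wavelet_name=wavelet_name).H)
    return np.asarray(out)


def higuchi_fd(series: np.ndarray, k_max: int = 10) -> FDEstimate:
    """Higuchi fractal dimension of a time series.

    For each delay k = 1..k_max and offset m = 1..k the normalized curve
    length L_m(k) of the k-decimated subsequence starting at m is

        L_m(k) = (1/k) * sum |X(m+ik) - X(m+(i-1)k)| * (N-1)/(floor((N-m)/k)*k)

    L(k) is the mean over m, and D is the least-squares slope of
    log L(k) against log(1/k).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if n <= k_max:
        raise ValueError(f"series length {n} must exceed k_max={k_max}")
    lk = np.empty(k_max)
    for k in range(1, k_max + 1):
        d = np.abs(x[k:] - x[:-k])  # d[j] = |X(j+1+k) - X(j+1)| 1-based
        lengths = np.empty(k)
        for m in range(1, k + 1):
            n_i = (n - m) // k
            if n_i < 1:
                raise ValueError(f"k_max={k_max} too large for length {n}")
            seg = d[m - 1 : m - 1 + n_i * k : k]
            lengths[m - 1] = seg.sum() * (n - 1) / (n_i * k) / k
        lk[k - 1] = lengths.mean()
    ks = np.arange(1, k_max + 1, dtype=float)
    if np.any(lk <= 0.0):
        raise ValueError("degenerate curve length (constant input?)")
    slope = float(np.polyfit(np.log(1.0 / ks), np.log(lk), 1)[0])
    return FDEstimate(D=slope, curve_lengths=np.column_stack([ks, lk]), k_max=k_max)


def swff_feature(
    frame: np.ndarray,
    wavelet_name: str = DEFAULT_WAVELET,
    levels: int = 4,
    k_max: int = 10,
) -> np.ndarray:
    """SWFF vector [D_x, D_d1, D_d2, D_d3, D_d4] of length levels + 1.

    Higuchi dimension of the frame itself plus of each wavelet detail layer.
    """
    dec = dwt_decompose(frame, wavelet_name, levels)
    out = [higuchi_fd(frame, k_max).D]
    for d in dec.details:
        out.append(higuchi_fd(d, min(k_max, d.size - 1)).D)
    return np.asarray(out)


def utterance_feature_vector(
    frames: FrameMatrix,
    feature_kind: str = "swff",
    target_dim: int = 256,
    wavelet_name: str = DEFAULT_WAVELET,
    levels: int = 4,
    k_max: int = 10,
) -> np.ndarray:
    """Fixed-length per-utterance feature vector.

    Per-frame feature vectors are concatenated in frame order, then
    truncated or right-zero-padded to exactly target_dim.
    """
    if feature_kind not in ("swff", "ph"):
        raise ValueError("feature_kind must be 'swff' or 'ph'")
    if target_dim < levels + 1:
        raise ValueError(f"target_dim must be >= {levels + 1}")
    if frames.n_frames < 1:
        raise ValueError("need at least one frame")
    per_frame = []
    for row in frames.frames:
        if feature_kind == "swff":
            per_frame.append(swff_feature(row, wavelet_name, levels, k_max))
        else:
            per_frame.append(ph_feature(row, levels, wavelet_name))
        if len(per_frame) * (levels + 1) >= target_dim:
            break  # later frames would be truncated anyway
    flat = np.concatenate(per_frame)
    if flat.size >= target_dim:
        return flat[:target_dim]
    return np.pad(flat, (0, target_dim - flat.size))
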