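"""Mean wavelet power (MWP) features.

An undecimated (stationary) db4 wavelet transform is run over each
continuous voltage block; the detail coefficients of scales 3-6 — the
dyadic bands jointly covering the multiunit-activity range (fs/2^7 to
fs/2^3; 234-3,750 Hz at 30 kHz) — are rectified and averaged within each
100 ms bin, standardized per channel and per scale against training
statistics, and the four standardized scales averaged per channel.  The
result is one 96-vector of unitless MWP values per 100 ms of data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from gripdecode.synth import RawRecording


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class WaveletSpec:
    wavelet: str = "db4"
    total_scales: int = 11
    used_scales: tuple = (3, 4, 5, 6)
    bin_ms: float = 100.0
    fs_hz: float = 30_000.0
    #: per-bin magnitude statistic: "abs" (mean |d|) or "square" (mean d^2)
    magnitude: str = "abs"

    def __post_init__(self):
        if self.magnitude not in ("abs", "square"):
            raise FeatureError("magnitude must be 'abs' or 'square'")
        if not set(self.used_scales) <= set(range(1, self.total_scales + 1)):
            raise FeatureError("used scales must lie within 1..total_scales")
        n = self.bin_ms * 1e-3 * self.fs_hz
        if abs(n - round(n)) > 1e-9:
            raise FeatureError(
                f"bin width {self.bin_ms} ms is not an integer number of "
                f"samples at {self.fs_hz} Hz"
            )

    @property
    def bin_samples(self) -> int:
        return int(round(self.bin_ms * 1e-3 * self.fs_hz))


@dataclass
class StandardizationParams:
    """Per-channel, per-scale mean/sd of bin-mean coefficient magnitudes."""

    mean: np.ndarray                 # channels x scales
    sd: np.ndarray                   # channels x scales
    eps: float = 1e-9
    floored: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))


@dataclass
class FeatureMatrix:
    """One standardized 96-dim MWP vector per 100 ms bin."""

    bin_starts_s: np.ndarray
    values: np.ndarray               # bins x channels
    params: StandardizationParams | None = None
    source: str = ""

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


def scale_band_edges(scale: int, fs_hz: float) -> tuple[float, float]:
    """Dyadic frequency band of a wavelet detail scale: (fs/2^(j+1), fs/2^j).

    Scale 3 at 30 kHz gives (1875, 3750) Hz; the union of scales 3-6 spans
    234.375-3750 Hz, the multiunit-activity band.
    """
    if scale < 1:
        raise FeatureError("scale must be >= 1")
    if fs_hz <= 0:
        raise FeatureError("sampling rate must be positive")
    return fs_hz / 2 ** (scale + 1), fs_hz / 2**scale


def decompose_bins(
    rec: RawRecording, spec: WaveletSpec, channel_chunk: int = 16
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin, per-channel, per-scale mean |detail coefficient|.

    The stationary wavelet transform is applied to each channel over the
    whole continuous block with symmetric end padding to the required
    length, and coefficient magnitudes are averaged within each 100 ms bin;
    the trailing partial bin is dropped.  Returns ``(coeffs, bin_starts)``
    with ``coeffs`` of shape (bins, channels, used_scales).
    """
    if abs(spec.fs_hz - rec.fs_hz) > 1e-6:
        raise FeatureError(
            f"spec rate {spec.fs_hz} does not match recording {rec.fs_hz}"
        )
    nb = spec.bin_samples
    n_bins = rec.n_samples // nb
    if n_bins < 1:
        raise FeatureError("recording shorter than one bin")
    n_used = rec.n_samples // nb * nb
    max_level = max(spec.used_scales)
    block = 2**max_level
    pad = (-n_used) % block

    scales = list(spec.used_scales)
    out = np.empty((n_bins, rec.n_channels, len(scales)), dtype=np.float64)
    for c0 in range(0, rec.n_channels, channel_chunk):
        x = rec.voltage[c0:c0 + channel_chunk, :n_used].astype(np.float64)
        if pad:
            x = np.pad(x, ((0, 0), (0, pad)), mode="symmetric")
        coeffs = pywt.swt(x, spec.wavelet, level=max_level,
                          trim_approx=True, axis=-1)
        # trim_approx ordering: [cA_L, cD_L, cD_{L-1}, ..., cD_1]
        for k, j in enumerate(scales):
            d = np.abs(coeffs[1 + (max_level - j)][:, :n_used])
            if spec.magnitude == "square":
                d = d**2
            out[:, c0:c0 + x.shape[0], k] = (
                d.reshape(x.shape[0], n_bins, nb).mean(axis=-1).T
            )
    bin_starts = rec.start_s + np.arange(n_bins) * spec.bin_ms * 1e-3
    return out, bin_starts


def fit_standardization(
    coeffs: np.ndarray, eps: float = 1e-9
) -> StandardizationParams:
    """Per channel-scale mean and sd of the training bin-mean magnitudes."""
    if coeffs.shape[0] < 2:
        raise FeatureError("need at least 2 bins to fit standardization")
    mean = coeffs.mean(axis=0)
    sd = coeffs.std(axis=0, ddof=0)
    floored = np.argwhere(sd < eps)
    sd = np.maximum(sd, eps)
    return StandardizationParams(mean, sd, eps, floored)


def compute_mwp(
    coeffs: np.ndarray,
    params: StandardizationParams,
    bin_starts_s: np.ndarray | None = None,
    source: str = "",
) -> FeatureMatrix:
    """Standardize per channel/scale and average scales into MWP.

    ``coeffs`` is (bins, channels, scales); output is (bins, channels).
    """
    if coeffs.shape[1:] != params.mean.shape:
        raise FeatureError(
            f"coefficient shape {coeffs.shape[1:]} does not match "
            f"standardization shape {params.mean.shape}"
        )
    z = (coeffs - params.mean) / params.sd
    values = z.mean(axis=-1)
    if bin_starts_s is None:
        bin_starts_s = np.arange(coeffs.shape[0]) * 0.1
    return FeatureMatrix(np.asarray(bin_starts_s, dtype=float), values,
                         params, source)


def extract_features(
    rec: RawRecording,
    spec: WaveletSpec,
    params: StandardizationParams | None = None,
) -> FeatureMatrix:
    """Decompose, (fit and) standardize, and average: recording -> MWP.

    When ``params`` is None the standardization is fit on this recording's
    own bins (training mode); otherwise the frozen training parameters are
    applied (decode mode).
    """
    coeffs, starts = decompose_bins(rec, spec)
    if params is None:
        params = fit_standardization(coeffs)
    return compute_mwp(coeffs, params, starts)
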