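"""Sliding-window-variance extraction of the PPG dynamic and static parts.

The pulsatile (AC) intensity is estimated from beat amplitudes: every pulse
peak is differenced against its preceding and its following trough, giving
two amplitude sets.  Each set is sorted descending and truncated to its
larger half — on a pulse train where diastolic sub-waves were also detected
this discards the small diastolic amplitudes, since systolic and diastolic
amplitude counts are close to 1:1 — and within the kept half a sliding
window of half its length picks the minimum-variance window, whose mean is
the set's amplitude estimate.  The two estimates are combined by
inverse-variance weighting.  The static (DC) intensity is the
minimum-variance-window mean of the trough values read off the
baseline-preserving (mean-filtered) trace.  Windowed statistics use an
O(1)-per-step recursion equivalent to the direct-summation population mean
and variance.

The minimum-variance selection makes both estimates insensitive to a small
fraction of corrupted beats: gross outliers either fall outside the kept
half or outside the selected window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core_io import MultichannelPPG
from .dsp import DEFAULT_MA_WINDOW, Landmarks, detect_landmarks, filter_chain
from .errors import QualityError

__all__ = [
    "WindowStats",
    "ChannelFeatures",
    "FeatureVector",
    "sliding_mean_variance",
    "select_min_variance_mean",
    "extract_ac",
    "extract_dc",
    "extract_features",
    "quality_features",
]

#: Variance floor for inverse-variance weights (intensity² units).
VARIANCE_FLOOR = 1e-12

#: Quality feature assigned to a channel whose extraction failed outright.
FAILED_CHANNEL_VARIANCE = 1.0


@dataclass(frozen=True)
class WindowStats:
    """Population mean/variance of the window starting at ``start``."""

    start: int
    window: int
    mean: float
    variance: float


def sliding_mean_variance(x: Sequence[float], window: int) -> list[WindowStats]:
    """Windowed population mean and variance at every start position.

    Each step updates the running sums in O(1); the values equal the
    direct-summation definitions over the ``window``-element window.
    """
    x = np.asarray(x, dtype=float)
    dn = int(window)
    if not 2 <= dn <= x.size:
        raise ValueError(f"window {dn} out of range [2, {x.size}]")
    s = float(np.sum(x[:dn]))
    s2 = float(np.sum(x[:dn] ** 2))
    out = []
    for start in range(x.size - dn + 1):
        if start > 0:
            outgoing, incoming = x[start - 1], x[start + dn - 1]
            s += incoming - outgoing
            s2 += incoming * incoming - outgoing * outgoing
        mean = s / dn
        var = max(s2 / dn - mean * mean, 0.0)
        out.append(WindowStats(start=start, window=dn, mean=mean, variance=var))
    return out


def select_min_variance_mean(values: Sequence[float],
                             window: Optional[int] = None) -> tuple[float, float]:
    """Mean and variance of the minimum-variance window of a sorted sequence.

    The window defaults to half the sequence length (floor), clamped to at
    least 2.  Ties go to the lowest start index.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    if window is None:
        window = max(2, values.size // 2)
    stats = sliding_mean_variance(values, window)
    best = min(stats, key=lambda ws: (ws.variance, ws.start))
    return best.mean, best.variance


def _beat_amplitudes(x: np.ndarray, landmarks: Landmarks) -> tuple[np.ndarray, np.ndarray]:
    """Peak-minus-preceding-trough (A) and peak-minus-following-trough (B) sets."""
    idx, typ = landmarks.merged()
    pre, post = [], []
    for j, (i, t) in enumerate(zip(idx, typ)):
        if t != 1:
            continue
        if j > 0 and typ[j - 1] == -1:
            pre.append(x[i] - x[idx[j - 1]])
        if j + 1 < idx.size and typ[j + 1] == -1:
            post.append(x[i] - x[idx[j + 1]])
    return np.asarray(pre), np.asarray(post)


def _kept_half(amplitudes: np.ndarray) -> np.ndarray:
    ordered = np.sort(amplitudes)[::-1]
    return ordered[:max(2, ordered.size // 2)]


def extract_ac(bandpassed: np.ndarray, landmarks: Landmarks) -> tuple[float, float]:
    """Pulsatile amplitude and its minimum window variance (quality feature).

    Requires at least 4 alternating landmarks (two usable amplitudes per
    set); otherwise the record is flagged unusable.
    """
    x = np.asarray(bandpassed, dtype=float)
    if landmarks.n_peaks + landmarks.n_troughs < 4:
        raise QualityError("fewer than 4 landmarks: cannot estimate AC")
    pre, post = _beat_amplitudes(x, landmarks)
    if pre.size < 2 or post.size < 2:
        raise QualityError("too few beat amplitudes to estimate AC")
    mean_a, var_a = select_min_variance_mean(_kept_half(pre))
    mean_b, var_b = select_min_variance_mean(_kept_half(post))
    w_a = 1.0 / (var_a + VARIANCE_FLOOR)
    w_b = 1.0 / (var_b + VARIANCE_FLOOR)
    ac = (w_a * mean_a + w_b * mean_b) / (w_a + w_b)
    return float(ac), float(min(var_a, var_b))


def extract_dc(mean_filtered: np.ndarray, landmarks: Landmarks) -> float:
    """Static intensity: minimum-variance-window mean of trough values.

    Troughs are read off the baseline-preserving trace so the static level
    is still present (the band-pass stage removes it).
    """
    x = np.asarray(mean_filtered, dtype=float)
    if landmarks.n_troughs < 2:
        raise QualityError("fewer than 2 troughs: cannot estimate DC")
    values = np.sort(x[landmarks.trough_indices])[::-1]
    mean, _ = select_min_variance_mean(values)
    return float(mean)


@dataclass(frozen=True)
class ChannelFeatures:
    """Per-channel AC/DC features plus the quality side-features."""

    wavelength_nm: float
    broadband: bool
    ac: float
    dc: float
    min_window_variance: float
    n_peaks: int
    n_troughs: int

    def __post_init__(self) -> None:
        if not self.dc > 0:
            raise QualityError("non-positive DC estimate")

    @property
    def ratio(self) -> float:
        return self.ac / self.dc


@dataclass(frozen=True)
class FeatureVector:
    """Regression input: 8 per-channel AC/DC ratios (wavelength order,
    broadband last) plus optionally the mean pressure as a ninth feature."""

    ratios: np.ndarray
    mean_pressure: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "ratios", np.asarray(self.ratios, dtype=float))
        values = self.values
        if not np.all(np.isfinite(values)):
            raise ValueError("feature vector must be finite")

    @property
    def values(self) -> np.ndarray:
        if self.mean_pressure is None:
            return self.ratios
        return np.append(self.ratios, self.mean_pressure)

    def __len__(self) -> int:
        return self.values.size


def _channel_features(x: np.ndarray, fs_hz: float, wavelength_nm: float,
                      broadband: bool, ma_window: int) -> ChannelFeatures:
    filt = filter_chain(x, fs_hz, ma_window)
    # a channel with no pulsatile content leaves only numerical ripple after
    # band-passing; guard against mistaking that ripple for beats
    q75, q25 = np.percentile(filt.bandpassed, [75, 25])
    baseline = float(np.median(np.abs(filt.mean_filtered)))
    if q75 - q25 <= 1e-9 * max(baseline, np.finfo(float).tiny):
        raise QualityError("no pulsatile content above the numerical noise floor")
    landmarks = detect_landmarks(filt.bandpassed, fs_hz)
    ac, min_var = extract_ac(filt.bandpassed, landmarks)
    dc = extract_dc(filt.mean_filtered, landmarks)
    return ChannelFeatures(
        wavelength_nm=wavelength_nm, broadband=broadband, ac=ac, dc=dc,
        min_window_variance=min_var, n_peaks=landmarks.n_peaks,
        n_troughs=landmarks.n_troughs)


def extract_features(rec: MultichannelPPG, include_pressure: bool = True,
                     ma_window: int = DEFAULT_MA_WINDOW,
                     ) -> tuple[list[ChannelFeatures], FeatureVector]:
    """Run the per-channel pipeline and assemble the regression features.

    Channels are processed in ascending-wavelength order with the broadband
    channel last.  If any channel fails landmark detection or amplitude
    estimation, a :class:`~ppghb.errors.QualityError` naming the failed
    channels is raised — the record should be quality-gated instead.
    """
    feats: list[ChannelFeatures] = []
    failed: list[str] = []
    names = rec.channel_names()
    for ch in rec.channel_order():
        try:
            feats.append(_channel_features(
                rec.channels[:, ch], rec.fs_hz, float(rec.wavelengths_nm[ch]),
                bool(rec.broadband[ch]), ma_window))
        except QualityError as exc:
            failed.append(f"{names[ch]}: {exc}")
    if failed:
        raise QualityError("channels failed extraction: " + "; ".join(failed))
    ratios = np.array([f.ratio for f in feats])
    vec = FeatureVector(
        ratios=ratios,
        mean_pressure=float(np.mean(rec.pressure)) if include_pressure else None)
    return feats, vec


def quality_features(rec: MultichannelPPG,
                     ma_window: int = DEFAULT_MA_WINDOW) -> np.ndarray:
    """Pooled worst-channel quality features for the signal-quality classifier.

    Per channel: minimum window variance normalized by DC² (scale-free),
    peak count and trough count.  The record is summarized by the channel
    with the largest normalized variance; channels failing extraction
    entirely contribute a sentinel (variance 1.0, zero landmarks) and
    dominate the pooling.
    """
    worst = None
    for ch in rec.channel_order():
        try:
            f = _channel_features(rec.channels[:, ch], rec.fs_hz,
                                  float(rec.wavelengths_nm[ch]),
                                  bool(rec.broadband[ch]), ma_window)
            row = (f.min_window_variance / f.dc ** 2, f.n_peaks, f.n_troughs)
        except QualityError:
            row = (FAILED_CHANNEL_VARIANCE, 0, 0)
        if worst is None or row[0] > worst[0]:
            worst = row
    return np.array(worst, dtype=float)
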