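"""Per-epoch EEG features: Pearson correlation, Welch PSD, sample entropy.

The detector characterizes each 2 s epoch of each channel by two numbers:
its mean Welch power spectral density over the physiological band and its
sample entropy.  Ictal activity raises spectral power and lowers
complexity, so the pair (mean PSD, SampEn) moves in opposite directions
during seizures.  Pearson correlation between channels is used upstream,
to quantify the redundancy of neighboring bipolar derivations during
channel selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import Epoch

__all__ = [
    "Spectrum",
    "SampEnParams",
    "WelchConfig",
    "pearson_correlation",
    "welch_psd",
    "mean_psd",
    "sample_entropy",
    "sampen_counts",
    "epoch_features",
    "feature_names",
]


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient of two equal-length series.

    rho = (E[XY] - E[X]E[Y]) / (sigma_X sigma_Y), with population
    (1/N) moments; raises on constant input, where the coefficient is
    undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 2:
        raise ValueError("need at least two samples")
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for a constant series")
    cov = (x * y).mean() - x.mean() * y.mean()
    return float(cov / (sx * sy))


@dataclass(frozen=True)
class WelchConfig:
    """Welch estimator settings.

    1 s rectangular segments with 50% overlap give 1 Hz resolution and
    L=3 averaged periodograms per 2 s epoch; the averaging band spans the
    physiological EEG range and excludes DC.
    """

    seg_len: int = 256
    overlap: float = 0.5
    window: str = "boxcar"
    band: tuple[float, float] = (0.5, 100.0)


@dataclass
class Spectrum:
    """A one-sided Welch power spectral density estimate.

    ``power`` is in µV²/Hz on the ``freqs`` grid; ``norm_factor`` is the
    window normalization U = (1/M) Σ d(n)², which is 1 for the rectangular
    window.  Scaled so that sum(power)·Δf approximates the signal variance
    for zero-mean input.
    """

    freqs: np.ndarray
    power: np.ndarray
    segment_length: int
    n_segments: int
    norm_factor: float
    window: str

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def welch_psd(
    x: np.ndarray,
    fs: float,
    seg_len: int = 256,
    overlap: float = 0.5,
    window: str = "boxcar",
) -> Spectrum:
    """Averaged modified periodogram (Welch) of a single-channel series.

    The series is mean-removed per segment; with the default rectangular
    window the estimate is the plain average of segment periodograms.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be 1-D")
    if seg_len > x.size:
        raise ValueError(f"seg_len {seg_len} exceeds series length {x.size}")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    noverlap = int(round(seg_len * overlap))
    freqs, power = sps.welch(
        x,
        fs=fs,
        window=window,
        nperseg=seg_len,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
    )
    step = seg_len - noverlap
    n_segments = 1 + (x.size - seg_len) // step
    win = sps.get_window(window, seg_len)
    norm_factor = float((win**2).mean())
    return Spectrum(
        freqs=freqs,
        power=power,
        segment_length=seg_len,
        n_segments=n_segments,
        norm_factor=norm_factor,
        window=window,
    )


def mean_psd(spec: Spectrum, band: tuple[float, float] = (0.5, 100.0)) -> float:
    """Arithmetic mean of the PSD over frequency bins in ``[f_lo, f_hi]``."""
    f_lo, f_hi = band
    if f_lo > f_hi:
        raise ValueError("band must satisfy f_lo <= f_hi")
    mask = (spec.freqs >= f_lo) & (spec.freqs <= f_hi)
    if not mask.any():
        raise ValueError(f"band {band} contains no frequency bins")
    return float(spec.power[mask].mean())


@dataclass(frozen=True)
class SampEnParams:
    """Sample-entropy parameters: embedding length m and tolerance r.

    ``r`` is a fraction of the series' standard deviation (the
    Richman-Moorman convention); Chebyshev distance, self-matches
    excluded.
    """

    m: int = 2
    r: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be positive")


def sampen_counts(x: np.ndarray, params: SampEnParams) -> tuple[int, int]:
    """Template-match pair counts (A, B) underlying sample entropy.

    B counts pairs i<j of length-m templates within Chebyshev distance
    r·sd(x); A is the same for length m+1.  Both counts run over the
    N-m templates that admit an (m+1)-extension, so A ⊆ B pairs.
    Vectorized; exact integer counts.
    """
    x = np.asarray(x, dtype=float)
    m = params.m
    n = x.size
    if n <= m + 1:
        raise ValueError(f"series of length {n} too short for m={m}")
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values")
    sd = x.std()
    tol = params.r * sd if sd > 0 else 1e-12  # absolute fallback for constants
    nt = n - m  # templates admitting an (m+1)-extension
    # Chebyshev distance between templates i, j is the running max of the
    # scalar distance matrix |x_i - x_j| along its diagonal offsets
    d0 = np.abs(x[:, None] - x[None, :])
    dm = d0[:nt, :nt].copy()
    for k in range(1, m):
        np.maximum(dm, d0[k : k + nt, k : k + nt], out=dm)
    iu = np.triu_indices(nt, k=1)
    b = int(np.count_nonzero(dm[iu] <= tol))
    np.maximum(dm, d0[m : m + nt, m : m + nt], out=dm)
    a = int(np.count_nonzero(dm[iu] <= tol))
    return a, b


def sample_entropy(x: np.ndarray, params: SampEnParams = SampEnParams()) -> float:
    """Sample entropy −ln(A/B) of a series.

    Returns +inf when no m-template pair extends to an (m+1)-match
    (A == 0); raises when there are no m-matches at all (B == 0), since
    the statistic is then undefined.
    """
    a, b = sampen_counts(x, params)
    if b == 0:
        raise ValueError("no template matches at length m; SampEn undefined")
    if a == 0:
        return float("inf")
    return float(-np.log(a / b))


def feature_names(channels: list[str]) -> list[str]:
    """Column names of the per-epoch feature vector."""
    out = []
    for ch in channels:
        out += [f"{ch}_psd", f"{ch}_sampen"]
    return out


def epoch_features(
    epoch: Epoch,
    channels: list[str],
    welch_cfg: WelchConfig = WelchConfig(),
    se_params: SampEnParams = SampEnParams(),
) -> np.ndarray:
    """Per-channel (mean PSD, sample entropy) vector for one epoch.

    Returns a vector of length ``2 * len(channels)`` in fixed channel
    order: for each channel, its band-mean Welch PSD followed by its
    sample entropy.
    """
    missing = [c for c in channels if c not in epoch.channel_names]
    if missing:
        raise KeyError(f"epoch is missing requested channels: {missing}")
    out = np.empty(2 * len(channels))
    for k, ch in enumerate(channels):
        x = epoch.channel(ch)
        spec = welch_psd(
            x, epoch.fs, seg_len=welch_cfg.seg_len,
            overlap=welch_cfg.overlap, window=welch_cfg.window,
        )
        out[2 * k] = mean_psd(spec, welch_cfg.band)
        out[2 * k + 1] = sample_entropy(x, se_params)
    return out
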