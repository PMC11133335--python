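"""Reconstruction-quality metrics and sliding-window power spectra.

RelErr — the relative Frobenius error over a whole phase, all channels
jointly — is the headline quality measure; per-channel mean squared error
and Pearson correlation complement it. Spectral summaries use a sliding
rectangular window (30 s by default) with mean removal per window and power
expressed in dB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReconstructionReport",
    "SpectrogramSummary",
    "relative_error",
    "channel_metrics",
    "windowed_power_spectrum",
]

DB_FLOOR = 1e-12  # keeps silent windows finite on the dB scale


@dataclass
class ChannelMetrics:
    channel_id: str
    mse: float
    corr: float | None  # None marks an undefined (zero-variance) correlation


@dataclass
class ReconstructionReport:
    """Quality summary of one phase reconstruction."""

    ns: int
    rank: int
    strategy: str
    rel_err: float
    aic: float
    per_channel: list[ChannelMetrics]

    def __post_init__(self) -> None:
        if self.rel_err < 0:
            raise ValueError("rel_err must be non-negative")
        for cm in self.per_channel:
            if cm.corr is not None and not -1.0 - 1e-12 <= cm.corr <= 1.0 + 1e-12:
                raise ValueError(f"correlation out of [-1, 1]: {cm.corr}")

    def to_dict(self) -> dict:
        return {
            "ns": self.ns,
            "rank": self.rank,
            "strategy": self.strategy,
            "rel_err": self.rel_err,
            "aic": self.aic,
            "per_channel": [
                {"channel": cm.channel_id, "mse": cm.mse, "corr": cm.corr}
                for cm in self.per_channel
            ],
        }


@dataclass
class SpectrogramSummary:
    """Windowed power spectrum of a multi-channel series, channel-averaged.

    ``power_db`` has one row per window and one column per frequency bin;
    power is averaged across channels before conversion to dB.
    """

    window_s: float
    hop_s: float
    freqs: np.ndarray
    times: np.ndarray
    power_db: np.ndarray

    def mean_db(self) -> float:
        return float(np.mean(self.power_db))

    def band_mean_db(self, f_lo: float, f_hi: float) -> float:
        """Mean dB over windows within a frequency band [f_lo, f_hi]."""
        mask = (self.freqs >= f_lo) & (self.freqs <= f_hi)
        if not np.any(mask):
            raise ValueError(f"no frequency bins in [{f_lo}, {f_hi}] Hz")
        return float(np.mean(self.power_db[:, mask]))


def relative_error(observed: np.ndarray, reconstructed: np.ndarray) -> float:
    """Relative Frobenius error ||obs - rec||_F / ||obs||_F over all channels."""
    obs = np.asarray(observed, dtype=float)
    rec = np.asarray(reconstructed, dtype=float)
    if obs.shape != rec.shape:
        raise ValueError(f"shape mismatch: {obs.shape} vs {rec.shape}")
    denom = np.linalg.norm(obs)
    if denom == 0:
        raise ValueError("relative error undefined for an identically zero signal")
    return float(np.linalg.norm(obs - rec) / denom)


def channel_metrics(
    observed: np.ndarray,
    reconstructed: np.ndarray,
    channel_labels: list[str] | None = None,
) -> list[ChannelMetrics]:
    """Per-channel mean squared error and Pearson correlation.

    A channel with zero variance in either signal gets ``corr=None`` (the
    coefficient is undefined there), never a numeric placeholder.
    """
    obs = np.atleast_2d(np.asarray(observed, dtype=float))
    rec = np.atleast_2d(np.asarray(reconstructed, dtype=float))
    if obs.shape != rec.shape:
        raise ValueError(f"shape mismatch: {obs.shape} vs {rec.shape}")
    q = obs.shape[0]
    labels = channel_labels or [f"ch{i}" for i in range(q)]
    out = []
    for i in range(q):
        resid = obs[i] - rec[i]
        mse = float(np.mean(resid**2))
        so, sr = np.std(obs[i]), np.std(rec[i])
        if so == 0 or sr == 0:
            corr = None
        else:
            corr = float(np.corrcoef(obs[i], rec[i])[0, 1])
            corr = min(1.0, max(-1.0, corr))
        out.append(ChannelMetrics(channel_id=labels[i], mse=mse, corr=corr))
    return out


def windowed_power_spectrum(
    series: np.ndarray,
    rate: float,
    window_s: float = 30.0,
    hop_s: float = 15.0,
) -> SpectrogramSummary:
    """Sliding-window periodogram in dB, averaged across channels.

    Each window is mean-removed and transformed with a rectangular taper;
    one-sided power bins are scaled so their sum equals the window's energy
    (Parseval), then averaged over channels and converted to
    ``10*log10(power + 1e-12)``.
    """
    y = np.atleast_2d(np.asarray(series, dtype=float))
    q, m = y.shape
    nw = int(round(window_s * rate))
    hop = max(1, int(round(hop_s * rate)))
    if nw < 2 or nw > m:
        raise ValueError(
            f"window of {window_s} s ({nw} samples) does not fit a series of "
            f"{m} samples at {rate} Hz"
        )
    starts = np.arange(0, m - nw + 1, hop)
    freqs = np.fft.rfftfreq(nw, d=1.0 / rate)
    scale = np.full(freqs.size, 2.0)
    scale[0] = 1.0
    if nw % 2 == 0:
        scale[-1] = 1.0
    power = np.empty((starts.size, freqs.size))
    for w, a in enumerate(starts):
        seg = y[:, a:a + nw]
        seg = seg - seg.mean(axis=1, keepdims=True)
        spec = np.abs(np.fft.rfft(seg, axis=1)) ** 2 / nw  # per-channel bins
        power[w] = np.mean(spec * scale[None, :], axis=0)
    times = (starts + nw / 2) / rate
    return SpectrogramSummary(
        window_s=window_s,
        hop_s=hop_s,
        freqs=freqs,
        times=times,
        power_db=10.0 * np.log10(power + DB_FLOOR),
    )
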