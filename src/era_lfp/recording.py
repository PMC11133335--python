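"""Multi-channel recording container used throughout the pipeline.

A recording is a dense ``channels x samples`` array with a sampling rate,
channel labels, a group tag (awake ``AW``, anesthetized ``AN``, or
``synthetic``) and optional phase boundaries — fence-post sample indices
delimiting consecutive experimental phases (e.g. a pre-CO2 baseline followed
by euthanasia phases).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_GROUPS = ("AW", "AN", "synthetic")


@dataclass
class MultiChannelRecording:
    """Dense multi-channel time series.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal values, arbitrary units. Must be finite.
    rate : float
        Sampling rate in Hz, strictly positive.
    channel_labels : list of str, optional
        One identifier per channel; defaults to ``ch0 .. ch{q-1}``.
    group : str
        One of ``AW``, ``AN``, ``synthetic``.
    phase_boundaries : ndarray of int, optional
        Strictly increasing fence-post indices in ``[0, n_samples]``
        delimiting phases (first entry 0, last entry n_samples when present).
    """

    samples: np.ndarray
    rate: float
    channel_labels: list[str] | None = None
    group: str = "synthetic"
    phase_boundaries: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x samples array")
        if self.samples.shape[1] < 1:
            raise ValueError("recording must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite values")
        if not self.rate > 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        self.rate = float(self.rate)
        if self.group not in VALID_GROUPS:
            raise ValueError(f"group must be one of {VALID_GROUPS}, got {self.group!r}")
        q = self.samples.shape[0]
        if self.channel_labels is None:
            self.channel_labels = [f"ch{i}" for i in range(q)]
        if len(self.channel_labels) != q:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {q} channels"
            )
        if self.phase_boundaries is not None:
            pb = np.asarray(self.phase_boundaries, dtype=int)
            if pb.ndim != 1 or pb.size < 2:
                raise ValueError("phase_boundaries must be a 1-D fence with >= 2 posts")
            if np.any(np.diff(pb) <= 0):
                raise ValueError("phase_boundaries must be strictly increasing")
            if pb[0] < 0 or pb[-1] > self.n_samples:
                raise ValueError("phase_boundaries must lie within [0, n_samples]")
            self.phase_boundaries = pb

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.rate

    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.rate

    def slice_samples(self, start: int, stop: int) -> "MultiChannelRecording":
        """Sub-recording covering sample indices ``[start, stop)``."""
        return MultiChannelRecording(
            samples=self.samples[:, start:stop].copy(),
            rate=self.rate,
            channel_labels=list(self.channel_labels),
            group=self.group,
        )


def samples_per_phase(rate: float, phase_duration: float) -> int:
    """Number of samples in one phase: ``round(rate * phase_duration)``.

    A 5-minute phase sampled at 3000 Hz contains 900 000 samples.
    """
    if rate <= 0 or phase_duration <= 0:
        raise ValueError("rate and phase_duration must be positive")
    return int(round(rate * phase_duration))
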