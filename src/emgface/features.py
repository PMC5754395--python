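"""Surface-EMG feature extraction.

Raw bipolar sEMG is converted into normalised per-muscle feature traces in
three steps:

1. fourth-order Butterworth band-pass, 15–500 Hz, applied forward–backward
   (zero phase) so feature frames stay aligned with marker frames;
2. Willison amplitude (WAMP): within a sliding window of ``N`` samples,
   the count of successive-sample absolute differences that reach a
   threshold ``s_lim``; with maximum overlap the window hops one sample at
   a time and each frame is stamped at the window centre;
3. per-channel min–max normalisation over the time index, mapping each
   nonconstant feature trace onto [0, 1] (constant traces map to zeros so
   silent channels yield zero activation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal


@dataclass
class EMGRecording:
    """A labelled multi-channel bipolar sEMG segment (one repetition).

    ``samples`` is (channels x T) in mV at sample rate ``fs`` (Hz).
    """

    samples: np.ndarray
    fs: float
    labels: list[str]
    instruction: str = ""
    repetition: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x T) array")
        if len(self.labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for "
                f"{self.samples.shape[0]} channels"
            )
        if self.fs <= 1000.0:
            raise ValueError(
                f"fs={self.fs} Hz too low: the 15-500 Hz band requires "
                "fs > 1000 Hz"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class FeatureSeries:
    """Windowed per-channel feature traces (channels x frames)."""

    values: np.ndarray
    times: np.ndarray
    labels: list[str]
    window: int
    hop: int
    s_lim: float
    fs: float
    normalised: bool = False
    instruction: str = ""
    repetition: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (channels x frames)")
        if self.values.shape[1] != self.times.shape[0]:
            raise ValueError("times length must match frame count")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def bandpass(
    rec: EMGRecording,
    lo: float = 15.0,
    hi: float = 500.0,
    order: int = 4,
) -> EMGRecording:
    """Zero-phase Butterworth band-pass of every channel.

    The filter is designed at the stated ``order`` and applied forward and
    backward (``sosfiltfilt``), which doubles the magnitude roll-off and
    cancels the phase delay.
    """
    nyq = rec.fs / 2.0
    if not 0.0 < lo < hi:
        raise ValueError(f"need 0 < lo < hi, got lo={lo}, hi={hi}")
    if hi >= nyq:
        raise ValueError(
            f"high cut-off {hi} Hz must be below the Nyquist "
            f"frequency {nyq} Hz"
        )
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.fs,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=1)
    return replace(rec, samples=filtered)


def wamp(
    rec: EMGRecording,
    s_lim: float = 10.0,
    window: float = 0.2,
    hop: int = 1,
) -> FeatureSeries:
    """Willison amplitude per sliding window.

    For each window of ``N = round(window * fs)`` samples the feature is
    the number of successive-sample differences with ``|s(t+n-1) -
    s(t+n)| >= s_lim`` (n = 1..N-1).  ``hop`` is the frame spacing in
    samples; the default 1 gives maximum overlap.  Frame timestamps are
    window centres.
    """
    n_win = int(round(window * rec.fs))
    if n_win < 2:
        raise ValueError(
            f"window of {window} s is shorter than 2 samples at "
            f"fs={rec.fs} Hz"
        )
    if n_win > rec.n_samples:
        raise ValueError(
            f"window of {n_win} samples exceeds the recording length "
            f"{rec.n_samples}"
        )
    if hop < 1:
        raise ValueError("hop must be a positive sample count")

    crossings = (np.abs(np.diff(rec.samples, axis=1)) >= s_lim)
    # moving sum of the N-1 differences inside each window, via cumsum
    csum = np.concatenate(
        [np.zeros((rec.n_channels, 1)), np.cumsum(crossings, axis=1)],
        axis=1,
    )
    counts = csum[:, n_win - 1:] - csum[:, : csum.shape[1] - n_win + 1]
    starts = np.arange(0, counts.shape[1], hop)
    values = counts[:, starts].astype(float)
    times = (starts + (n_win - 1) / 2.0) / rec.fs
    return FeatureSeries(
        values=values,
        times=times,
        labels=list(rec.labels),
        window=n_win,
        hop=hop,
        s_lim=s_lim,
        fs=rec.fs,
        normalised=False,
        instruction=rec.instruction,
        repetition=rec.repetition,
    )


def minmax_normalise(feat: FeatureSeries) -> FeatureSeries:
    """Min–max normalise each channel over the time index.

    Nonconstant channels are mapped exactly onto [0, 1]; constant channels
    (degenerate denominator) map to all zeros.
    """
    if feat.n_frames == 0:
        raise ValueError("cannot normalise an empty feature series")
    g = feat.values
    lo = g.min(axis=1, keepdims=True)
    hi = g.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.zeros_like(g)
    nonconst = span[:, 0] > 0
    out[nonconst] = (g[nonconst] - lo[nonconst]) / span[nonconst]
    return replace(feat, values=out, normalised=True)
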