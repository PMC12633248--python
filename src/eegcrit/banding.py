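"""Epoch harmonization and log-spaced band-envelope decomposition.

The analysis operates on a fixed-length eyes-closed series per subject:
five 1-min epochs are concatenated (controls) or a continuous ~5-min record
is split, reordered 1-3-5-2-4 and concatenated (patients), then 10.6 s are
trimmed from both ends, leaving 278.8 s in five segments of (49.4, 60, 60,
60, 49.4) s.  All windowed metrics treat the five segments as separate
realizations: no filter, Hilbert transform or analysis window ever crosses
a segment join.

Thirteen frequency bins span 1-73 Hz: one delta bin (1-4 Hz) followed by
twelve geometrically spaced bins from 4 to 73 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .simulate import Recording

__all__ = [
    "HarmonizedSeries",
    "BandSpec",
    "Envelope",
    "TRIM_SECONDS",
    "harmonize",
    "make_bands",
    "band_envelope",
]

TRIM_SECONDS = 10.6
EDGE_TRIM_SECONDS = 1.0


@dataclass
class HarmonizedSeries:
    """Fixed-length multichannel series with its five-segment structure."""

    data: np.ndarray  # channels x time, segments concatenated
    fs: float
    segment_lengths: list[int]  # samples per segment
    mode: str  # which harmonization path produced it ("HC" or "MDD")
    ch_names: list[str]

    @property
    def segment_seconds(self) -> list[float]:
        return [n / self.fs for n in self.segment_lengths]

    @property
    def total_seconds(self) -> float:
        return self.data.shape[1] / self.fs

    def segment_slices(self) -> list[slice]:
        edges = np.concatenate([[0], np.cumsum(self.segment_lengths)])
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


@dataclass(frozen=True)
class BandSpec:
    """Ordered contiguous frequency bins."""

    bins: list[tuple[float, float]]

    def __len__(self) -> int:
        return len(self.bins)

    def __iter__(self):
        return iter(self.bins)

    def __getitem__(self, i: int) -> tuple[float, float]:
        return self.bins[i]

    def labels(self) -> list[str]:
        """Display labels with edges rounded to 0.1 Hz."""
        return [f"{lo:.1f}-{hi:.1f}" for lo, hi in self.display_edges_pairs()]

    def display_edges_pairs(self) -> list[tuple[float, float]]:
        return [(round(lo, 1), round(hi, 1)) for lo, hi in self.bins]


@dataclass
class Envelope:
    """Per-channel nonnegative amplitude envelope of one frequency bin.

    ``data`` holds the concatenated per-segment envelopes after the edge
    trim; ``segment_lengths`` gives the post-trim segment lengths so
    windowed metrics can respect segment joins.
    """

    data: np.ndarray  # channels x time
    fs: float
    band: tuple[float, float]
    segment_lengths: list[int]
    edge_trim: float = EDGE_TRIM_SECONDS

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.min() < 0:
            raise ValueError("envelope must be nonnegative")
        if sum(self.segment_lengths) != self.data.shape[1]:
            raise ValueError("segment lengths do not sum to envelope length")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    def segment_slices(self) -> list[slice]:
        edges = np.concatenate([[0], np.cumsum(self.segment_lengths)])
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def _epoch_matrix(recording: Recording, mode: str) -> list[np.ndarray]:
    """Five 60-s epoch arrays (channels x samples) in analysis order."""
    fs = recording.fs
    need = int(round(60.0 * fs))
    if mode == "HC":
        if len(recording.epochs) < 5:
            raise ValueError(
                f"HC harmonization needs five epochs, got {len(recording.epochs)}"
            )
        epochs = []
        for start, end in recording.epochs[:5]:
            if end - start < need:
                raise ValueError(
                    f"epoch of {(end - start) / fs:.1f} s is shorter than 60 s"
                )
            epochs.append(recording.samples[:, start : start + need])
        return epochs
    if mode == "MDD":
        total = recording.samples.shape[1]
        if total < 5 * need:
            raise ValueError(
                f"MDD harmonization needs >= 300 s of continuous data, got "
                f"{total / fs:.1f} s ({(5 * need - total) / fs:.1f} s short)"
            )
        parts = [recording.samples[:, i * need : (i + 1) * need] for i in range(5)]
        return [parts[i] for i in (0, 2, 4, 1, 3)]  # reorder 1-3-5-2-4
    raise ValueError(f"mode must be 'HC' or 'MDD', got {mode!r}")


def harmonize(recording: Recording, mode: str | None = None) -> HarmonizedSeries:
    """Build the fixed 278.8-s series: concatenate five 60-s epochs (with the
    patient-path 1-3-5-2-4 reordering) and trim 10.6 s from both ends.

    Both paths yield the same total duration and segment structure
    (49.4, 60, 60, 60, 49.4) s.
    """
    if mode is None:
        mode = recording.group
    epochs = _epoch_matrix(recording, mode)
    fs = recording.fs
    trim = int(round(TRIM_SECONDS * fs))
    need = int(round(60.0 * fs))
    data = np.concatenate(epochs, axis=1)[:, trim : 5 * need - trim]
    seg_lengths = [need - trim, need, need, need, need - trim]
    return HarmonizedSeries(
        data=np.ascontiguousarray(data),
        fs=fs,
        segment_lengths=seg_lengths,
        mode=mode,
        ch_names=list(recording.ch_names),
    )


def make_bands(f_min: float = 1.0, f_max: float = 73.0, n_log: int = 12) -> BandSpec:
    """Thirteen contiguous bins spanning ``f_min``-``f_max`` Hz.

    One delta bin (``f_min``-4 Hz) followed by ``n_log`` geometric bins from
    4 Hz to ``f_max`` with common ratio (f_max/4)^(1/n_log).  Edges are kept
    at full precision; rounding to 0.1 Hz is for display only.
    """
    if f_min >= f_max:
        raise ValueError("f_min must be below f_max")
    anchor = 4.0
    edges = [f_min] + list(anchor * (f_max / anchor) ** (np.arange(n_log + 1) / n_log))
    return BandSpec(bins=[(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])])


def _band_sos(band: tuple[float, float], fs: float):
    f_lo, f_hi = band
    nyq = fs / 2.0
    if f_hi >= nyq:
        raise ValueError(f"band upper edge {f_hi} Hz at or above Nyquist {nyq} Hz")
    wn = (f_lo / nyq, f_hi / nyq)
    if wn[1] - wn[0] < 1e-4:
        raise ValueError(f"band {band} too narrow for a stable filter at fs={fs}")
    # order-4 recursive band-pass (two second-order sections), zero phase
    return butter(2, wn, btype="bandpass", output="sos")


def band_envelope(series: HarmonizedSeries, band: tuple[float, float]) -> Envelope:
    """Zero-phase band-pass then analytic-signal magnitude, per segment.

    The order-4 band-pass is applied forward-backward within each of the
    five segments; the Hilbert transform likewise never crosses a segment
    join.  One second is trimmed from both ends of every segment to remove
    filter and Hilbert edge transients.
    """
    sos = _band_sos(band, series.fs)
    trim = int(round(EDGE_TRIM_SECONDS * series.fs))
    pieces = []
    seg_lengths = []
    for sl in series.segment_slices():
        seg = series.data[:, sl]
        if seg.shape[1] <= 2 * trim:
            raise ValueError("segment too short for the envelope edge trim")
        filtered = sosfiltfilt(sos, seg, axis=1)
        env = np.abs(hilbert(filtered, axis=1))[:, trim:-trim]
        pieces.append(env)
        seg_lengths.append(env.shape[1])
    return Envelope(
        data=np.concatenate(pieces, axis=1),
        fs=series.fs,
        band=band,
        segment_lengths=seg_lengths,
    )
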