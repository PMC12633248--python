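"""Subject-level metric extraction: Recording -> one row per subject.

For every frequency bin the five indices (BiS, DFA, E/I_HLP, fE/I,
E+I_HLS) are computed per channel on the band's amplitude envelope and
averaged across channels; broadband Lempel-Ziv complexity is computed on
the 1-45 Hz band-passed signal per channel and averaged.  fE/I values are
averaged over the channels that pass the DFA > 0.6 validity gate and are
missing (NaN) when no channel passes; every other metric is complete.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, decimate, sosfiltfilt

from .banding import BandSpec, HarmonizedSeries, band_envelope, harmonize, make_bands
from .biexp import bistability_index, ei_hlp, ei_hls, fit_biexp, subsample_power
from .dynamics import dfa, fei, lzc
from .simulate import Recording

__all__ = ["METRICS", "subject_metrics", "metric_table", "metric_columns"]

METRICS = ("bis", "dfa", "ei_hlp", "fei", "ei_hls")

LZC_BAND = (1.0, 45.0)
LZC_MAX_FS = 128.0  # decimate broadband signal before LZ76 parsing


def metric_columns(bands: BandSpec) -> list[str]:
    """Column names ``metric@flo-fhi`` (display-rounded edges) plus ``lzc``."""
    cols = [f"{m}@{lab}" for m in METRICS for lab in bands.labels()]
    return cols + ["lzc"]


def _broadband_lzc(series: HarmonizedSeries) -> float:
    """Channel-averaged normalized LZC of the 1-45 Hz signal."""
    nyq = series.fs / 2.0
    hi = min(LZC_BAND[1], 0.95 * nyq)
    sos = butter(2, (LZC_BAND[0] / nyq, hi / nyq), btype="bandpass", output="sos")
    q = max(int(np.ceil(series.fs / LZC_MAX_FS)), 1)
    vals = []
    for ch in range(series.data.shape[0]):
        pieces = []
        for sl in series.segment_slices():
            seg = sosfiltfilt(sos, series.data[ch, sl])
            pieces.append(decimate(seg, q, zero_phase=True) if q > 1 else seg)
        vals.append(lzc(np.concatenate(pieces)).normalized)
    return float(np.mean(vals))


def subject_metrics(
    recording: Recording,
    bands: BandSpec | None = None,
    fei_gate: float = 0.6,
    mode: str | None = None,
) -> dict[str, float]:
    """All channel-averaged metrics for one subject.

    Returns a flat dict keyed by ``metric@band`` plus ``lzc`` and the
    subject covariates.
    """
    bands = bands or make_bands()
    series = harmonize(recording, mode=mode)
    row: dict[str, float] = {
        "subject_id": recording.subject_id,
        "group": recording.group,
        "age": recording.age,
        "sex": recording.sex,
    }
    labels = bands.labels()
    for band, label in zip(bands, labels):
        vals: dict[str, list[float]] = {m: [] for m in METRICS}
        env = band_envelope(series, band)
        for ch in range(env.n_channels):
            d = dfa(env, channel=ch)
            f = fei(env, gate=fei_gate, channel=ch, dfa_result=d)
            fit = fit_biexp(subsample_power(env, channel=ch))
            vals["dfa"].append(d.exponent)
            vals["bis"].append(bistability_index(fit))
            if fit.identified:
                vals["ei_hlp"].append(ei_hlp(fit))
                vals["ei_hls"].append(ei_hls(fit))
            if f.valid:
                vals["fei"].append(f.value)
        for m in METRICS:
            row[f"{m}@{label}"] = float(np.mean(vals[m])) if vals[m] else np.nan
    row["lzc"] = _broadband_lzc(series)
    return row


def metric_table(
    recordings: Sequence[Recording],
    bands: BandSpec | None = None,
    fei_gate: float = 0.6,
    verbose: bool = False,
) -> pd.DataFrame:
    """Stack :func:`subject_metrics` over a cohort into the subjects x
    (metric x band) feature substrate used by the statistics and the
    classifier."""
    bands = bands or make_bands()
    rows = []
    for i, rec in enumerate(recordings):
        rows.append(subject_metrics(rec, bands=bands, fei_gate=fei_gate))
        if verbose and (i + 1) % 20 == 0:
            print(f"  metrics: {i + 1}/{len(recordings)} subjects")
    return pd.DataFrame(rows)
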