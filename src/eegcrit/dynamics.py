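"""Long-range temporal correlations (DFA), the functional E/I ratio, and
Lempel-Ziv complexity.

All windowed computations respect the five-segment structure of the
harmonized series: windows never straddle a segment join, and fluctuation
statistics are pooled across segments before any regression or correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .banding import Envelope

__all__ = [
    "DfaResult",
    "FeiResult",
    "LzcResult",
    "dfa",
    "dfa_smin",
    "count_windows",
    "fei",
    "lzc",
    "lz76_complexity",
]


# --------------------------------------------------------------------------
# detrended fluctuation analysis
# --------------------------------------------------------------------------

@dataclass
class DfaResult:
    exponent: float
    window_sizes: np.ndarray  # seconds
    fluctuations: np.ndarray
    fit_range: tuple[float, float]
    r_squared: float


def dfa_smin(band: tuple[float, float], floor: float = 1.0, cycles: float = 8.0) -> float:
    """Smallest DFA window for a band: at least ``cycles`` cycles of the
    band's lower edge, and never below ``floor`` seconds."""
    return max(floor, cycles / band[0])


def count_windows(
    segment_seconds: list[float] | np.ndarray, window: float, overlap: float = 0.0
) -> int:
    """Number of analysis windows of length ``window`` (s) with fractional
    ``overlap``, summed over segments; windows never span a join."""
    step = window * (1.0 - overlap)
    total = 0
    for seg in segment_seconds:
        if seg >= window:
            total += int(np.floor((seg - window) / step + 1e-9)) + 1
    return total


def _window_starts(n_seg: int, win: int, step: int) -> np.ndarray:
    if n_seg < win:
        return np.empty(0, dtype=int)
    return np.arange(0, n_seg - win + 1, step)


def _detrended_rms_sq(profile: np.ndarray, win: int, step: int) -> np.ndarray:
    """Mean squared residual around a linear trend for every window of one
    segment profile; vectorized over windows."""
    starts = _window_starts(profile.size, win, step)
    if starts.size == 0:
        return np.empty(0)
    idx = starts[:, None] + np.arange(win)[None, :]
    w = profile[idx]  # windows x win
    t = np.arange(win, dtype=float)
    t -= t.mean()
    stt = float(np.sum(t * t))
    wbar = w.mean(axis=1)
    slope = (w @ t) / stt
    msr = np.mean(w * w, axis=1) - wbar**2 - (slope**2) * stt / win
    return np.maximum(msr, 0.0)


def dfa(
    envelope: Envelope | np.ndarray,
    band: tuple[float, float] | None = None,
    s_min: float | None = None,
    s_max: float = 30.0,
    overlap: float = 0.5,
    n_sizes: int = 10,
    channel: int = 0,
) -> DfaResult:
    """DFA exponent of one channel's amplitude envelope.

    Per segment the envelope is demeaned and cumulatively summed into a
    profile; windows of length ``s`` advance with step ``s * (1-overlap)``;
    each window is linearly detrended and its RMS residual computed.
    ``F(s)`` pools the mean squared residuals over all windows of all
    segments; the exponent is the least-squares slope of ``log10 F`` versus
    ``log10 s`` over ``n_sizes`` geometrically spaced sizes in
    ``[s_min, s_max]``.
    """
    if isinstance(envelope, Envelope):
        fs = envelope.fs
        segs = [envelope.data[channel, sl] for sl in envelope.segment_slices()]
        band = band or envelope.band
    else:
        raise TypeError("dfa expects an Envelope; wrap raw arrays in Envelope first")
    if s_min is None:
        if band is None:
            raise ValueError("need either s_min or a band to derive it from")
        s_min = dfa_smin(band)
    if not s_min < s_max:
        raise ValueError(f"need s_min < s_max, got [{s_min}, {s_max}]")

    sizes_s = np.geomspace(s_min, s_max, n_sizes)
    sizes = np.unique(np.round(sizes_s * fs).astype(int))
    sizes = sizes[sizes >= 4]
    fluct = np.empty(sizes.size)
    for i, win in enumerate(sizes):
        step = max(int(round(win * (1.0 - overlap))), 1)
        sqs = []
        for seg in segs:
            if seg.size < win:
                continue
            if np.ptp(seg) == 0:
                raise ValueError("constant envelope: DFA undefined (zero variance)")
            profile = np.cumsum(seg - seg.mean())
            sqs.append(_detrended_rms_sq(profile, int(win), step))
        pooled = np.concatenate(sqs) if sqs else np.empty(0)
        if pooled.size == 0 or (win == sizes[-1] and pooled.size < 2):
            raise ValueError(
                f"fewer than 2 windows at the largest scale {win / fs:.1f} s"
            )
        fluct[i] = np.sqrt(pooled.mean())
    if np.any(fluct <= 0):
        raise ValueError("zero fluctuation encountered; envelope degenerate")
    slope, r2 = fit_scaling_exponent(sizes / fs, fluct)
    return DfaResult(
        exponent=slope,
        window_sizes=sizes / fs,
        fluctuations=fluct,
        fit_range=(float(s_min), float(s_max)),
        r_squared=r2,
    )


def fit_scaling_exponent(sizes_s: np.ndarray, fluct: np.ndarray) -> tuple[float, float]:
    """Least-squares slope (and R^2) of log10 fluctuation vs log10 window
    size -- the scaling exponent estimate at the heart of DFA."""
    logs = np.log10(np.asarray(sizes_s, float))
    logf = np.log10(np.asarray(fluct, float))
    slope, intercept = np.polyfit(logs, logf, 1)
    resid = logf - (slope * logs + intercept)
    ss_tot = float(np.sum((logf - logf.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), r2


# --------------------------------------------------------------------------
# functional E/I ratio
# --------------------------------------------------------------------------

@dataclass
class FeiResult:
    value: float  # NaN when the DFA gate fails or the estimate degenerates
    window_amplitudes: np.ndarray
    window_dnf: np.ndarray
    dfa_exponent: float
    gate: float
    valid: bool
    reason: str = ""


def fei(
    envelope: Envelope,
    window: float = 5.0,
    overlap: float = 0.8,
    gate: float = 0.6,
    channel: int = 0,
    dfa_result: DfaResult | None = None,
) -> FeiResult:
    """Functional E/I ratio: 1 minus the Pearson correlation between
    windowed mean amplitudes and windowed detrended normalized fluctuations.

    Windows of ``window`` seconds advance with ``overlap`` fractional
    overlap and never straddle segment joins.  Per window the envelope is
    normalized by its window mean, cumulatively summed after subtracting 1,
    linearly detrended, and summarized by its RMS (the wDNF).  The estimate
    is only valid when the envelope's DFA exponent exceeds ``gate``.
    """
    fs = envelope.fs
    win = int(round(window * fs))
    step = max(int(round(win * (1.0 - overlap))), 1)
    w_amp: list[np.ndarray] = []
    w_dnf: list[np.ndarray] = []
    for sl in envelope.segment_slices():
        seg = envelope.data[channel, sl]
        starts = _window_starts(seg.size, win, step)
        if starts.size == 0:
            continue
        idx = starts[:, None] + np.arange(win)[None, :]
        wnd = seg[idx]
        amp = wnd.mean(axis=1)
        if np.any(amp <= 0):
            return FeiResult(np.nan, np.empty(0), np.empty(0), np.nan, gate, False,
                             "nonpositive window mean amplitude")
        norm = wnd / amp[:, None]
        prof = np.cumsum(norm - 1.0, axis=1)
        t = np.arange(win, dtype=float)
        t -= t.mean()
        stt = float(np.sum(t * t))
        pbar = prof.mean(axis=1)
        slope = (prof @ t) / stt
        msr = np.maximum(np.mean(prof**2, axis=1) - pbar**2 - slope**2 * stt / win, 0.0)
        w_amp.append(amp)
        w_dnf.append(np.sqrt(msr))
    if not w_amp or sum(a.size for a in w_amp) < 10:
        raise ValueError("envelope too short: fewer than 10 fE/I windows")
    amp = np.concatenate(w_amp)
    dnf = np.concatenate(w_dnf)

    if dfa_result is None:
        dfa_result = dfa(envelope, channel=channel)
    alpha = dfa_result.exponent
    if alpha <= gate:
        return FeiResult(np.nan, amp, dnf, alpha, gate, False,
                         f"DFA exponent {alpha:.3f} <= gate {gate}")
    if amp.std() == 0 or dnf.std() == 0:
        return FeiResult(np.nan, amp, dnf, alpha, gate, False,
                         "zero variance in window statistics")
    corr = float(np.corrcoef(amp, dnf)[0, 1])
    return FeiResult(1.0 - corr, amp, dnf, alpha, gate, True)


# --------------------------------------------------------------------------
# Lempel-Ziv complexity (LZ76, exhaustive history)
# --------------------------------------------------------------------------

@dataclass
class LzcResult:
    count: int  # c(n), number of phrases in the exhaustive parsing
    normalized: float  # c(n) * log2(n) / n
    n: int
    threshold: float
    degenerate: bool = False


def lz76_complexity(bits: np.ndarray | bytes) -> int:
    """Number of phrases in the LZ76 exhaustive parsing of a binary string.

    Each new phrase is the shortest prefix of the remaining string that has
    not appeared in the text seen so far (self-overlap allowed).  Uses the
    C-level substring search of :class:`bytes` for speed.
    """
    if isinstance(bits, np.ndarray):
        s = np.asarray(bits).astype(np.uint8).tobytes()
    else:
        s = bytes(bits)
    n = len(s)
    if n == 0:
        raise ValueError("empty sequence")
    c = 1
    i = 1  # start of the current phrase; first symbol is always one phrase
    while i < n:
        k = 1
        # extend while s[i:i+k] occurs in s[0:i+k-1]
        while i + k <= n and s.find(s[i : i + k], 0, i + k - 1) != -1:
            k += 1
        c += 1
        i += k
    return c


def lzc(series: np.ndarray, threshold: str | float = "median") -> LzcResult:
    """Normalized Lempel-Ziv complexity of one channel.

    The series is binarized at its median (amplitude-robust) and the LZ76
    phrase count ``c(n)`` is normalized as ``c(n) * log2(n) / n``, which
    tends to 1 for an iid fair-coin sequence.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if n < 64:
        raise ValueError("need at least 64 samples for LZC")
    thr = float(np.median(x)) if threshold == "median" else float(threshold)
    bits = (x > thr).astype(np.uint8)
    degenerate = bits.min() == bits.max()
    if degenerate:
        return LzcResult(1, float(np.log2(n) / n), n, thr, degenerate=True)
    c = lz76_complexity(bits)
    return LzcResult(c, float(c * np.log2(n) / n), n, thr)
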