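"""Synthetic resting-state EEG with controllable critical dynamics.

Every downstream stage of the package (band decomposition, bistability /
DFA / fE/I / LZC metrics, group statistics, classification) is exercised on
cohorts produced here.  The generator does not attempt biophysical realism;
it produces signals whose *statistical* structure matches what the metrics
assume:

* band-limited oscillations whose amplitude envelopes carry long-range
  temporal correlations with a programmable Hurst exponent,
* bistable (two-mode) envelope power distributions built from a two-state
  continuous-time Markov chain with exponentially distributed within-mode
  power,
* a programmable correlation between windowed mean amplitude and windowed
  normalized fluctuation (the axis the functional E/I ratio measures),
* two groups with band-specific implanted effects plus age/sex covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng

__all__ = [
    "FractionalProfile",
    "BistableProfile",
    "CoupledProfile",
    "bistable_from_knobs",
    "Recording",
    "CohortSpec",
    "gen_fgn",
    "fgn_lag1_autocorr",
    "realize_envelope",
    "gen_envelope_series",
    "gen_band_signal",
    "gen_subject",
    "gen_cohort",
    "perturbed_cells",
    "STEERABLE_METRICS",
]


# --------------------------------------------------------------------------
# envelope profiles
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FractionalProfile:
    """Envelope with long-range temporal correlations of Hurst exponent ``hurst``.

    The envelope is ``baseline * exp(log_sigma * z)`` where ``z`` is
    unit-variance fractional Gaussian noise; the exponential keeps the
    envelope strictly positive while leaving the scaling exponent of the
    fluctuations essentially untouched for small ``log_sigma``.
    """

    hurst: float
    baseline: float = 1.0
    log_sigma: float = 0.35

    def __post_init__(self) -> None:
        if not 0.0 < self.hurst < 1.0:
            raise ValueError(f"Hurst exponent must lie in (0, 1), got {self.hurst}")
        if self.baseline <= 0:
            raise ValueError("baseline amplitude must be positive")


@dataclass(frozen=True)
class BistableProfile:
    """Two-mode envelope: power alternates between low and high levels.

    A two-state continuous-time Markov chain selects the mode; dwell times
    are exponential with means chosen so the high mode occupies fraction
    ``w_hi`` of the time and the occupancy-weighted mean dwell equals
    ``dwell``.  Within a mode, instantaneous power is ``mu_mode * E(t)``
    where ``E(t) = (g1^2 + g2^2)/2`` for two smoothed unit-variance Gaussian
    processes -- a construction whose marginal is exactly Exp(1), so the
    power distribution is the exponential mixture the bistability index
    assumes.
    """

    mu_lo: float
    mu_hi: float
    w_hi: float
    dwell: float = 4.0  # seconds
    baseline: float = 1.0

    def __post_init__(self) -> None:
        if not (self.mu_hi > self.mu_lo > 0):
            raise ValueError("need mu_hi > mu_lo > 0")
        if not 0.0 < self.w_hi < 1.0:
            raise ValueError("w_hi must lie in (0, 1)")
        if self.dwell <= 0:
            raise ValueError("dwell must be positive")


@dataclass(frozen=True)
class CoupledProfile:
    """Envelope with a programmed amplitude/fluctuation correlation ``rho``.

    Two independent long-range-correlated processes are split spectrally at
    the fE/I window scale: the slow part sets the windowed mean amplitude,
    the fast part the within-window fluctuations.  The local strength of
    the fast part is modulated by an odd bounded function of the slow
    part's level, which makes the Pearson correlation between windowed mean
    amplitudes and windowed detrended normalized fluctuations track
    ``rho``: zero coupling (``rho = 0``) holds by construction because the
    two processes are independent, so the downstream functional E/I ratio
    is ~ 1 there.
    """

    rho: float
    hurst: float = 0.8
    baseline: float = 1.0
    log_sigma: float = 0.3
    jitter: float = 0.3
    window: float = 5.0  # seconds; fE/I window the split is tuned to

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        if not 0.0 < self.hurst < 1.0:
            raise ValueError("Hurst exponent must lie in (0, 1)")


def bistable_from_knobs(
    w_hi: float, log10_sep: float, dwell: float = 0.4, baseline: float = 1.0
) -> BistableProfile:
    """Bistable profile from occupancy and log10 mode separation, normalized
    to unit mean power."""
    sep = 10.0 ** log10_sep
    mu_lo = 1.0 / (1.0 - w_hi + w_hi * sep)
    return BistableProfile(
        mu_lo=mu_lo, mu_hi=sep * mu_lo, w_hi=w_hi, dwell=dwell, baseline=baseline
    )


EnvelopeProfile = FractionalProfile | BistableProfile | CoupledProfile


# --------------------------------------------------------------------------
# fractional Gaussian noise (exact circulant embedding)
# --------------------------------------------------------------------------

def fgn_lag1_autocorr(hurst: float) -> float:
    """Theoretical lag-1 autocorrelation of fractional Gaussian noise."""
    return 2.0 ** (2.0 * hurst - 1.0) - 1.0


def _fgn_autocov(hurst: float, n: int) -> np.ndarray:
    k = np.arange(n, dtype=float)
    h2 = 2.0 * hurst
    return 0.5 * (np.abs(k + 1) ** h2 - 2.0 * np.abs(k) ** h2 + np.abs(k - 1) ** h2)


def gen_fgn(hurst: float, n: int, rng: Generator | int) -> np.ndarray:
    """Exact synthesis of unit-variance fractional Gaussian noise.

    Uses circulant embedding of the fGn autocovariance (Davies-Harte).  The
    embedding eigenvalues are checked and a ``ValueError`` is raised if any
    is materially negative -- the draw is never silently approximated.

    Parameters
    ----------
    hurst : Hurst exponent in (0, 1).  0.5 gives iid Gaussian noise.
    n : number of samples (>= 2).
    rng : :class:`numpy.random.Generator` or integer seed.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError(f"Hurst exponent must lie in (0, 1), got {hurst}")
    if n < 2:
        raise ValueError("need n >= 2")
    rng = default_rng(rng) if not isinstance(rng, Generator) else rng

    m = 1 << int(np.ceil(np.log2(2 * n)))  # circulant size, power of two
    gamma = _fgn_autocov(hurst, m // 2 + 1)
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.rfft(row).real
    if lam.min() < -1e-8 * lam.max():
        raise ValueError(
            f"circulant embedding not positive semi-definite for H={hurst}, n={n} "
            f"(min eigenvalue {lam.min():.3g})"
        )
    lam = np.clip(lam, 0.0, None)
    # complex Gaussian weights; rfft layout (DC and Nyquist real)
    nf = lam.size
    w = rng.standard_normal(nf) + 1j * rng.standard_normal(nf)
    w[0] = np.sqrt(2.0) * w[0].real
    w[-1] = np.sqrt(2.0) * w[-1].real
    spec = np.sqrt(lam / 2.0) * w
    series = np.fft.irfft(spec, n=m) * np.sqrt(m)
    return np.ascontiguousarray(series[:n])


# --------------------------------------------------------------------------
# envelope realizations
# --------------------------------------------------------------------------

def _gauss_smooth(x: np.ndarray, sigma_samp: float) -> np.ndarray:
    """Circular Gaussian smoothing via the frequency domain (O(n log n)
    regardless of kernel width)."""
    if sigma_samp <= 0:
        return x
    n = x.size
    f = np.fft.rfftfreq(n)  # cycles per sample
    kernel = np.exp(-2.0 * (np.pi * f * sigma_samp) ** 2)
    return np.fft.irfft(np.fft.rfft(x) * kernel, n=n)


def _smoothed_unit_gauss(n: int, sigma_samp: float, rng: Generator) -> np.ndarray:
    """Gaussian-filtered white noise renormalized to unit variance."""
    g = _gauss_smooth(rng.standard_normal(n), sigma_samp)
    sd = g.std()
    if sd == 0:
        raise ValueError("degenerate smoothed noise (n too small?)")
    return g / sd


def _mode_path(
    n: int, fs: float, w_hi: float, dwell: float, rng: Generator
) -> np.ndarray:
    """Boolean high-mode indicator from a two-state Markov chain.

    Mean dwell in the high mode is ``2 * dwell * w_hi`` and in the low mode
    ``2 * dwell * (1 - w_hi)`` so that occupancy equals ``w_hi`` and the
    occupancy-weighted mean dwell equals ``dwell``.
    """
    tau_hi = max(2.0 * dwell * w_hi, 2.0 / fs)
    tau_lo = max(2.0 * dwell * (1.0 - w_hi), 2.0 / fs)
    total = n / fs
    state = rng.random() < w_hi
    t = 0.0
    out = np.empty(n, dtype=bool)
    while t < total:
        d = rng.exponential(tau_hi if state else tau_lo)
        i0, i1 = int(t * fs), min(int((t + d) * fs) + 1, n)
        out[i0:i1] = state
        t += d
        state = not state
    return out


def _exp_power_factor(n: int, fs: float, smooth_s: float, rng: Generator) -> np.ndarray:
    """Unit-mean process with exact Exp(1) marginal: (g1^2 + g2^2) / 2."""
    sig = max(smooth_s * fs, 1.0)
    g1 = _smoothed_unit_gauss(n, sig, rng)
    g2 = _smoothed_unit_gauss(n, sig, rng)
    return 0.5 * (g1 * g1 + g2 * g2)


# Rational map between the requested window-level correlation rho and the
# tanh-modulation strength gamma, measured once on the default profile
# (5-s / 80%-overlap windows, log_sigma 0.3, jitter 0.3); see docs/methods.md.
_COUPLING_C1 = 1.75
_COUPLING_C2 = 1.52


def _coupling_gamma(rho: float) -> float:
    rho = float(np.clip(rho, -0.99, 0.99))
    return float(np.clip(rho / (_COUPLING_C1 - _COUPLING_C2 * abs(rho)), -1.0, 1.0))


def _spectral_split(z: np.ndarray, f0: float, fs: float, keep: str) -> np.ndarray:
    """Raised-cosine (in log-frequency) low/high-pass split at ``f0`` Hz."""
    f = np.fft.rfftfreq(z.size, 1.0 / fs)
    lo, hi = f0 / 1.4, f0 * 1.4
    w = np.clip(
        (np.log(np.maximum(f, 1e-9)) - np.log(lo)) / (np.log(hi) - np.log(lo)), 0.0, 1.0
    )
    w = 0.5 - 0.5 * np.cos(np.pi * w)  # 0 below lo, 1 above hi
    mask = w if keep == "hi" else 1.0 - w
    return np.fft.irfft(np.fft.rfft(z) * mask, n=z.size)


def _coupled_factor(
    n: int,
    fs: float,
    hurst: float,
    rho: float,
    log_sigma: float,
    jitter: float,
    window: float,
    rng: Generator,
) -> np.ndarray:
    """Strictly positive modulation with a programmed amplitude/fluctuation
    correlation; unit-median slow level."""
    f0 = 1.0 / (2.0 * window)
    z_slow = _spectral_split(gen_fgn(hurst, n, rng), f0, fs, "lo")
    z_fast = _spectral_split(gen_fgn(hurst, n, rng), f0, fs, "hi")
    sd = z_slow.std()
    u = (z_slow - z_slow.mean()) / sd if sd > 0 else np.zeros(n)
    strength = 1.0 + _coupling_gamma(rho) * np.tanh(u)
    fast = np.exp(jitter * strength * z_fast)
    fast = fast / np.maximum(_gauss_smooth(fast, window * fs), 1e-10)
    return np.exp(log_sigma * z_slow) * fast


def realize_envelope(
    profile: EnvelopeProfile, n: int, fs: float, rng: Generator | int,
    smooth_s: float = 0.02,
) -> np.ndarray:
    """Draw a strictly positive amplitude envelope of length ``n`` at ``fs``.

    ``smooth_s`` sets the correlation time (s) of the fast within-mode power
    fluctuations; callers embedding the envelope in a narrow band should
    widen it so the modulation fits inside the band.
    """
    rng = default_rng(rng) if not isinstance(rng, Generator) else rng
    if isinstance(profile, FractionalProfile):
        z = gen_fgn(profile.hurst, n, rng)
        env = profile.baseline * np.exp(profile.log_sigma * z)
    elif isinstance(profile, BistableProfile):
        hi = _mode_path(n, fs, profile.w_hi, profile.dwell, rng)
        mu = np.where(hi, profile.mu_hi, profile.mu_lo)
        power = mu * _exp_power_factor(n, fs, smooth_s, rng)
        env = profile.baseline * np.sqrt(power)
    elif isinstance(profile, CoupledProfile):
        env = profile.baseline * _coupled_factor(
            n, fs, profile.hurst, profile.rho, profile.log_sigma, profile.jitter,
            profile.window, rng,
        )
    else:  # pragma: no cover
        raise TypeError(f"unknown envelope profile {type(profile).__name__}")
    if not np.all(np.isfinite(env)) or env.min() <= 0:
        raise RuntimeError("generated envelope is not strictly positive and finite")
    return env


def gen_envelope_series(
    profile: EnvelopeProfile,
    fs: float,
    rng: Generator | int,
    segment_seconds: Sequence[float] = (49.4, 60.0, 60.0, 60.0, 49.4),
    band: tuple[float, float] = (8.0, 13.0),
    smooth_s: float = 0.05,
):
    """Realize a profile directly as a segmented :class:`~eegcrit.banding.Envelope`.

    Bypasses carrier synthesis and band filtering: the envelope itself is
    the object under study.  Defaults to the harmonized five-segment layout
    (49.4, 60, 60, 60, 49.4 s); ``band`` only labels the result (it sets
    the default DFA fitting range downstream).
    """
    from .banding import Envelope

    rng = default_rng(rng) if not isinstance(rng, Generator) else rng
    seg_lengths = [int(round(s * fs)) for s in segment_seconds]
    n = int(sum(seg_lengths))
    env = realize_envelope(profile, n, fs, rng, smooth_s=smooth_s)
    return Envelope(data=env[None, :], fs=fs, band=band, segment_lengths=seg_lengths,
                    edge_trim=0.0)


# --------------------------------------------------------------------------
# band-limited signals and subjects
# --------------------------------------------------------------------------

def _fm_carrier(
    f_lo: float, f_hi: float, n: int, fs: float, rng: Generator
) -> np.ndarray:
    """Unit-amplitude band-limited carrier with wandering instantaneous
    frequency and random initial phase.

    Constant instantaneous amplitude means the analytic-signal envelope of
    carrier x envelope reproduces the programmed envelope exactly.
    """
    fc = 0.5 * (f_lo + f_hi)
    dev = 0.35 * (f_hi - f_lo)
    bw = f_hi - f_lo
    sig = max(fs / (2.0 * bw), 1.0)  # wander at ~ bw/2 Hz
    w = np.tanh(_smoothed_unit_gauss(n, sig, rng))
    f_inst = fc + dev * w
    phase = 2.0 * np.pi * (rng.random() + np.cumsum(f_inst) / fs)
    return np.cos(phase)


def gen_band_signal(
    band: tuple[float, float],
    profile: EnvelopeProfile,
    duration: float,
    fs: float,
    rng: Generator | int,
) -> np.ndarray:
    """Band-limited oscillation: FM carrier multiplied by a profile envelope.

    Raises if the band is invalid for ``fs`` or the duration is shorter than
    10 cycles of the band's lower edge.
    """
    f_lo, f_hi = band
    if not 0.0 < f_lo < f_hi < fs / 2.0:
        raise ValueError(f"need 0 < f_lo < f_hi < fs/2, got ({f_lo}, {f_hi}) at fs={fs}")
    if duration * f_lo < 10.0:
        raise ValueError(
            f"duration {duration:.3g} s too short: fewer than 10 cycles of {f_lo} Hz"
        )
    rng = default_rng(rng) if not isinstance(rng, Generator) else rng
    n = int(round(duration * fs))
    # envelope modulation must fit inside the band
    smooth_s = max(0.02, 0.5 / (f_hi - f_lo))
    env = realize_envelope(profile, n, fs, rng, smooth_s=smooth_s)
    sig = env * _fm_carrier(f_lo, f_hi, n, fs, rng)
    # confine the component to its own bin: fast envelope structure (mode
    # switching, jitter) creates sidebands that would otherwise leak into
    # neighbouring bands of a multi-band mixture
    from scipy.signal import butter, sosfiltfilt

    sos = butter(2, (f_lo / (fs / 2), f_hi / (fs / 2)), btype="bandpass", output="sos")
    return sosfiltfilt(sos, sig)


def _one_over_f(n: int, fs: float, rng: Generator) -> np.ndarray:
    """Unit-variance 1/f (power) noise by spectral synthesis."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** -0.5
    phases = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    x = np.fft.irfft(amp * phases, n=n)
    return x / x.std()


@dataclass
class Recording:
    """One subject's multichannel EEG plus metadata."""

    samples: np.ndarray  # channels x time
    fs: float
    ch_names: list[str]
    subject_id: str
    group: str  # "HC" or "MDD"
    age: float
    sex: str  # "male" or "female"
    epochs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be channels x time")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.ch_names) != self.samples.shape[0]:
            raise ValueError("channel label count does not match samples")
        if np.isnan(self.samples).any():
            raise ValueError("samples contain NaN")
        n = self.samples.shape[1]
        for start, end in self.epochs:
            if not 0 <= start < end <= n:
                raise ValueError(f"epoch ({start}, {end}) outside matrix bounds")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs


EPOCH_SECONDS = 60.0
N_EPOCHS = 5


def gen_subject(
    band_profiles: Mapping[tuple[float, float], EnvelopeProfile],
    fs: float,
    rng: Generator | int,
    *,
    n_channels: int = 19,
    subject_id: str = "S000",
    group: str = "HC",
    age: float = 45.0,
    sex: str = "female",
    background_db: float = -20.0,
) -> Recording:
    """Five 60-s eyes-closed epochs: band oscillations plus 1/f background.

    Each channel is an independent realization of the same per-band
    profiles.  The broadband 1/f floor sits ``background_db`` below the
    total oscillatory power.  Deterministic under a fixed seed.
    """
    rng = default_rng(rng) if not isinstance(rng, Generator) else rng
    bands = list(band_profiles)
    for i, b in enumerate(bands):
        for b2 in bands[i + 1 :]:
            if not (b[1] <= b2[0] or b2[1] <= b[0]):
                raise ValueError(f"overlapping band specs {b} and {b2}")
    duration = N_EPOCHS * EPOCH_SECONDS
    n = int(round(duration * fs))
    data = np.empty((n_channels, n))
    for ch in range(n_channels):
        comps = np.zeros(n)
        for band in bands:
            comps += gen_band_signal(band, band_profiles[band], duration, fs, rng)
        osc_power = float(np.mean(comps**2))
        floor = 1.0 if osc_power == 0 else np.sqrt(osc_power * 10.0 ** (background_db / 10.0))
        data[ch] = comps + floor * _one_over_f(n, fs, rng)
    epoch_len = int(round(EPOCH_SECONDS * fs))
    epochs = [(i * epoch_len, (i + 1) * epoch_len) for i in range(N_EPOCHS)]
    return Recording(
        samples=data,
        fs=fs,
        ch_names=[f"CH{i + 1:02d}" for i in range(n_channels)],
        subject_id=subject_id,
        group=group,
        age=age,
        sex=sex,
        epochs=epochs,
    )


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

STEERABLE_METRICS = ("dfa", "bis", "ei_hlp", "ei_hls", "fei")

# generator knob behind each metric axis, with the sign linking a positive
# metric effect to the knob shift, and the between-subject SD of the knob
_KNOB_FOR_METRIC = {
    "dfa": ("hurst", +1.0),
    "bis": ("log10_sep", +1.0),
    "ei_hls": ("log10_sep", +1.0),
    "ei_hlp": ("w_hi", +1.0),
    "fei": ("rho", -1.0),  # fE/I = 1 - corr, so raising fE/I lowers rho
}

_KNOB_BASE = {"hurst": 0.72, "w_hi": 0.35, "log10_sep": 1.0, "rho": 0.0}
_KNOB_SD = {"hurst": 0.05, "w_hi": 0.06, "log10_sep": 0.20, "rho": 0.12}
_KNOB_CLIP = {
    "hurst": (0.55, 0.95),
    "w_hi": (0.08, 0.80),
    "log10_sep": (0.40, 2.20),
    "rho": (-0.65, 0.65),
}

# Which profile kind realizes a band, given the metric axes implanted there.
# A band can carry effects on the bistability axes together, or on DFA
# alone, or on fE/I alone; other combinations share no generator.
_BISTABLE_AXES = frozenset({"bis", "ei_hlp", "ei_hls"})

# cells whose generating distribution moves when a metric axis is implanted.
# Primary couplings are strong (the mode-separation knob is shared by the
# bistability index and the high/low-separation index); the extended set
# adds weaker estimation cross-couplings measured on generated cohorts:
# mode occupancy shifts the windowed amplitude/fluctuation statistics
# (fE/I) and, mildly, the evidence for bimodality, while mode separation
# shifts the occupancy estimate through mixture blurring.
_EFFECT_COUPLING = {
    "dfa": ("dfa",),
    "bis": ("bis", "ei_hls"),
    "ei_hls": ("ei_hls", "bis"),
    "ei_hlp": ("ei_hlp",),
    "fei": ("fei",),
}

_EFFECT_COUPLING_EXTENDED = {
    "dfa": ("dfa",),
    "bis": ("bis", "ei_hls", "ei_hlp"),
    "ei_hls": ("ei_hls", "bis", "ei_hlp"),
    "ei_hlp": ("ei_hlp", "fei", "bis"),
    "fei": ("fei",),
}


def _band_role(metrics: set[str]) -> str:
    """Profile kind for a band from the set of implanted metric axes."""
    if not metrics or metrics <= _BISTABLE_AXES:
        return "bistable"
    if metrics == {"dfa"}:
        return "fractional"
    if metrics == {"fei"}:
        return "coupled"
    raise ValueError(
        f"cannot steer metrics {sorted(metrics)} within one band; a band may "
        f"carry effects on {sorted(_BISTABLE_AXES)} together, on 'dfa' alone, "
        f"or on 'fei' alone"
    )


@dataclass(frozen=True)
class CohortSpec:
    """Two-group study design with band-specific implanted effects.

    ``effects`` maps ``(band_index, metric)`` to a signed effect size in
    units of the between-subject SD of the underlying generator knob; a
    positive value raises the metric in the second (MDD) group.  Sample
    sizes, age and sex distributions default to the study this package
    models: 133 controls and 183 patients, ages ~ Normal(47, 16) truncated
    to [18, 80], male fractions 55/133 and 60/183.
    """

    n_hc: int = 133
    n_mdd: int = 183
    effects: Mapping[tuple[int, str], float] = field(default_factory=dict)
    bands: Sequence[tuple[float, float]] | None = None
    n_channels: int = 4
    fs: float = 250.0
    age_mean: float = 47.0
    age_sd: float = 16.0
    age_range: tuple[float, float] = (18.0, 80.0)
    male_frac_hc: float = 55.0 / 133.0
    male_frac_mdd: float = 60.0 / 183.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hc < 2 or self.n_mdd < 2:
            raise ValueError("need at least 2 subjects per group")
        for (band_idx, metric), eff in self.effects.items():
            if metric not in STEERABLE_METRICS:
                raise ValueError(
                    f"cannot steer metric {metric!r}; steerable axes: "
                    f"{', '.join(STEERABLE_METRICS)}"
                )
            if not np.isfinite(eff):
                raise ValueError("effect sizes must be finite")


def perturbed_cells(spec: CohortSpec, extended: bool = False) -> set[tuple[int, str]]:
    """(band_index, metric) cells whose group distributions genuinely differ.

    With ``extended=False`` only the strong same-knob couplings are listed
    (cells an effect-detection check should expect to flag); with
    ``extended=True`` the weaker estimation cross-couplings are included as
    well (cells a classifier may legitimately select).
    """
    coupling = _EFFECT_COUPLING_EXTENDED if extended else _EFFECT_COUPLING
    out: set[tuple[int, str]] = set()
    for (band_idx, metric), eff in spec.effects.items():
        if eff != 0.0:
            for m in coupling[metric]:
                out.add((band_idx, m))
    return out


def _truncnorm(rng: Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def _default_bands() -> list[tuple[float, float]]:
    from .banding import make_bands

    return make_bands().bins


def gen_cohort(spec: CohortSpec) -> tuple[list[Recording], "pd.DataFrame"]:
    """Generate a two-group cohort plus a ground-truth manifest.

    Returns ``(recordings, manifest)``; the manifest records group, age,
    sex, per-subject seed and every per-band generator knob, so tests can
    verify steerability and feature-recovery claims against ground truth.
    """
    import pandas as pd

    bands = list(spec.bands) if spec.bands is not None else _default_bands()
    for band_idx, _metric in spec.effects:
        if not 0 <= band_idx < len(bands):
            raise ValueError(f"effect band index {band_idx} outside 0..{len(bands) - 1}")
    band_roles = [
        _band_role({m for (b, m), e in spec.effects.items() if b == i and e != 0.0})
        for i in range(len(bands))
    ]

    # per-(band, knob) group means
    def knob_mean(group: str, band_idx: int, knob: str) -> float:
        mean = _KNOB_BASE[knob]
        if group == "MDD":
            for metric, (kn, sign) in _KNOB_FOR_METRIC.items():
                if kn == knob:
                    eff = spec.effects.get((band_idx, metric), 0.0)
                    mean += sign * eff * _KNOB_SD[knob]
        return mean

    # amplitude floor ~ 1/sqrt(f): crude spectral tilt across bands
    baselines = [(flo * fhi) ** -0.25 for flo, fhi in bands]

    ss = SeedSequence(spec.seed)
    child_seeds = ss.spawn(spec.n_hc + spec.n_mdd)
    recordings: list[Recording] = []
    rows = []
    groups = ["HC"] * spec.n_hc + ["MDD"] * spec.n_mdd
    for idx, (group, child) in enumerate(zip(groups, child_seeds)):
        rng = default_rng(child)
        age = _truncnorm(rng, spec.age_mean, spec.age_sd, *spec.age_range)
        male_frac = spec.male_frac_hc if group == "HC" else spec.male_frac_mdd
        sex = "male" if rng.random() < male_frac else "female"
        profiles: dict[tuple[float, float], EnvelopeProfile] = {}
        row = {
            "subject_id": f"{group}{idx:03d}",
            "group": group,
            "age": age,
            "sex": sex,
            "seed": int(child.generate_state(1)[0] & 0x7FFFFFFF),
        }
        for b_idx, band in enumerate(bands):
            knobs = {}
            for knob in _KNOB_BASE:
                lo, hi = _KNOB_CLIP[knob]
                knobs[knob] = float(
                    np.clip(rng.normal(knob_mean(group, b_idx, knob), _KNOB_SD[knob]), lo, hi)
                )
                row[f"{knob}@{b_idx}"] = knobs[knob]
            role = band_roles[b_idx]
            if role == "fractional":
                profiles[band] = FractionalProfile(
                    hurst=knobs["hurst"], baseline=baselines[b_idx]
                )
            elif role == "coupled":
                profiles[band] = CoupledProfile(
                    rho=knobs["rho"], baseline=baselines[b_idx]
                )
            else:
                profiles[band] = bistable_from_knobs(
                    knobs["w_hi"], knobs["log10_sep"], baseline=baselines[b_idx]
                )
        rec = gen_subject(
            profiles,
            spec.fs,
            rng,
            n_channels=spec.n_channels,
            subject_id=row["subject_id"],
            group=group,
            age=age,
            sex=sex,
        )
        recordings.append(rec)
        rows.append(row)
    return recordings, pd.DataFrame(rows)
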