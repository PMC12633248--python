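"""Single- and two-mode exponential models of envelope power.

Near criticality, oscillatory power alternates between a low- and a
high-power mode; for Gaussian narrowband noise the instantaneous power
(squared Hilbert envelope) within one mode is exponentially distributed, so
the two-mode regime produces a two-component exponential mixture.  Three
indices derive from the fit:

* bistability index ``BiS``: evidence for the two-mode model over the
  single-exponential model, here the BIC difference ``BIC1 - BIC2``
  (positive = bimodal preferred);
* high/low-power ratio ``E/I_HLP``: relative occupancy of the high- versus
  low-power mode, ``w_hi / w_lo``;
* high/low separation ``E+I_HLS``: ``log10(mu_hi / mu_lo)``, the distance
  between the mode mean powers.

Each index sits behind its own function so an alternative formula can be
swapped in without touching the fitting machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .banding import Envelope

__all__ = [
    "BiexpFit",
    "fit_biexp",
    "bistability_index",
    "ei_hlp",
    "ei_hls",
    "subsample_power",
]


@dataclass
class BiexpFit:
    n: int
    # single-exponential model
    rate: float  # 1 / mean power
    loglik1: float
    # two-component mixture, ordered mu_lo < mu_hi
    w_lo: float
    w_hi: float
    mu_lo: float
    mu_hi: float
    loglik2: float
    bic1: float
    bic2: float
    converged: bool
    identified: bool  # False when the data cannot support two modes


def subsample_power(envelope: Envelope, channel: int = 0, max_rate: float = 20.0) -> np.ndarray:
    """Squared envelope subsampled to at most ``max_rate`` samples/s.

    The BIC comparison assumes independent samples; envelope autocorrelation
    at the full sampling rate violates that badly, so power is thinned to
    one sample per 1/``max_rate`` seconds before fitting.
    """
    stride = max(int(np.ceil(envelope.fs / max_rate)), 1)
    amp = envelope.data[channel, ::stride]
    return amp * amp


def _exp_mix_loglik(x: np.ndarray, w: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Log-likelihood of two-component exponential mixtures; vectorized over
    parameter rows (w, mu: R x 2; x: n)."""
    t_lo = np.log(w[:, :1] / mu[:, :1]) - x[None, :] / mu[:, :1]
    t_hi = np.log(w[:, 1:] / mu[:, 1:]) - x[None, :] / mu[:, 1:]
    return np.logaddexp(t_lo, t_hi).sum(axis=1)


def fit_biexp(
    power: np.ndarray,
    n_restarts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> BiexpFit:
    """Fit single- and two-component exponential models to power samples.

    The single-exponential MLE is closed form (rate = 1/mean).  The mixture
    is fit by EM with ``n_restarts`` quantile-based initializations run in
    parallel (vectorized), iterating each start until the relative
    log-likelihood change falls below ``tol`` or ``max_iter`` is reached.
    BICs use ``-2 L + k ln n`` with k = 1 and k = 3; components are ordered
    so ``mu_lo < mu_hi``.
    """
    x = np.asarray(power, dtype=float).ravel()
    n = x.size
    if n < 100:
        raise ValueError(f"need at least 100 power samples, got {n}")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("power samples must be finite and nonnegative")

    mean = x.mean()
    if mean <= 0 or np.ptp(x) == 0:
        # all-equal (or all-zero) data: single model only
        ll1 = float(-n * (np.log(mean) + 1.0)) if mean > 0 else np.nan
        bic1 = -2.0 * ll1 + np.log(n) if mean > 0 else np.nan
        return BiexpFit(n, 1.0 / mean if mean > 0 else np.nan, ll1,
                        0.5, 0.5, mean, mean, ll1, bic1, bic1,
                        converged=True, identified=False)

    ll1 = float(-n * (np.log(mean) + 1.0))  # exponential MLE log-likelihood
    bic1 = -2.0 * ll1 + 1.0 * np.log(n)

    # quantile-based initializations: split at q, moments on each side
    qs = np.linspace(0.25, 0.95, n_restarts)
    cuts = np.quantile(x, qs)
    tiny = 1e-12 * mean + 1e-300
    mu0 = np.empty((n_restarts, 2))
    w0 = np.empty((n_restarts, 2))
    for r, c in enumerate(cuts):
        lo = x[x <= c]
        hi = x[x > c]
        if hi.size == 0 or lo.size == 0:
            mu0[r] = (0.5 * mean, 2.0 * mean)
            w0[r] = (0.5, 0.5)
        else:
            mu0[r] = (max(lo.mean(), tiny), max(hi.mean(), tiny))
            w0[r] = (lo.size / n, hi.size / n)

    def em(x_, w, mu, iters, tol_):
        """EM sweeps, vectorized over restart rows; one E step reuses the
        log-likelihood terms.  Returns (w, mu, ll, converged_mask)."""
        R = w.shape[0]
        n_ = x_.size
        sum_x_ = x_.sum()
        ll_prev = None
        done = np.zeros(R, dtype=bool)
        for _ in range(iters):
            t_lo = np.log(w[:, :1] / mu[:, :1]) - x_[None, :] / mu[:, :1]
            t_hi = np.log(w[:, 1:] / mu[:, 1:]) - x_[None, :] / mu[:, 1:]
            ll_terms = np.logaddexp(t_lo, t_hi)
            ll = ll_terms.sum(axis=1)
            if ll_prev is not None:
                done = np.abs(ll - ll_prev) / np.maximum(np.abs(ll_prev), 1.0) < tol_
            ll_prev = ll
            if done.all():
                break
            resp_hi = np.exp(t_hi - ll_terms)  # R x n responsibilities
            n_hi = resp_hi.sum(axis=1)
            sx_hi = resp_hi @ x_
            n_lo = n_ - n_hi
            sx_lo = sum_x_ - sx_hi
            w = np.clip(np.column_stack([n_lo, n_hi]) / n_, 1e-12, 1.0)
            w /= w.sum(axis=1, keepdims=True)
            mu = np.maximum(
                np.column_stack([sx_lo / np.maximum(n_lo, 1e-300),
                                 sx_hi / np.maximum(n_hi, 1e-300)]),
                tiny,
            )
        return w, mu, ll_prev, done

    # stage 1: a short burn-in on a thinned sample ranks the restarts;
    # stage 2: the best start is polished on the full data to tolerance
    x_rank = x[:: int(np.ceil(x.size / 1500))]
    w, mu, ll, done = em(x_rank, w0.copy(), mu0.copy(), min(25, max_iter), tol)
    best = int(np.argmax(ll))
    wb, mb, llb, doneb = em(
        x, w[best : best + 1].copy(), mu[best : best + 1].copy(), max_iter, tol
    )
    converged = bool(doneb[0])

    ll2 = float(_exp_mix_loglik(x, wb, mb)[0])
    order = np.argsort(mb[0])
    mu_lo, mu_hi = float(mb[0][order[0]]), float(mb[0][order[1]])
    w_lo, w_hi = float(wb[0][order[0]]), float(wb[0][order[1]])
    bic2 = -2.0 * ll2 + 3.0 * np.log(n)

    # a mixture that collapsed onto one component is not identified
    identified = (
        w_lo > 1e-6 and w_hi > 1e-6 and mu_hi > mu_lo * (1.0 + 1e-6)
        and ll2 >= ll1 - 1e-6 * max(1.0, abs(ll1))
    )
    return BiexpFit(n, 1.0 / mean, ll1, w_lo, w_hi, mu_lo, mu_hi, ll2,
                    float(bic1), float(bic2), converged=converged, identified=identified)


def bistability_index(fit: BiexpFit) -> float:
    """BiS = BIC1 - BIC2: positive values favour the two-mode model.

    Unbounded and not floored; a non-identified mixture returns 0.
    """
    if not fit.identified:
        return 0.0
    return fit.bic1 - fit.bic2


def ei_hlp(fit: BiexpFit) -> float:
    """High/low-power ratio: occupancy of the high-power mode over the low."""
    if not fit.identified:
        raise ValueError("mixture not identified; E/I_HLP undefined")
    if fit.w_lo <= 0:
        raise ValueError("degenerate fit: w_lo = 0")
    return fit.w_hi / fit.w_lo


def ei_hls(fit: BiexpFit) -> float:
    """High/low separation: log10 of the mode mean-power ratio."""
    if not fit.identified:
        raise ValueError("mixture not identified; E+I_HLS undefined")
    if fit.mu_lo <= 0:
        raise ValueError("degenerate fit: mu_lo = 0")
    return float(np.log10(fit.mu_hi / fit.mu_lo))
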