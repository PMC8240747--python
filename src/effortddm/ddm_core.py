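"""Drift-diffusion model of accept/reject decisions under reward and effort.

The decision on each trial is modelled as noisy evidence accumulation between
two absorbing boundaries separated by ``a``, starting at a fraction ``z`` of
the way up (0.5 = unbiased), with additive Gaussian noise of scale ``c``
(fixed to 1 by convention).  Hitting the upper boundary codes *accept*,
the lower boundary *reject*; the observed reaction time is the first-passage
time plus a non-decision time ``t``.

The drift rate on a trial is a linear function of the offer::

    V = v0 + vr * r_scaled - ve * e_scaled - vre * r_scaled * e_scaled

where ``r_scaled`` is reward divided by the maximum reward of the design and
``e_scaled`` is the squared required force fraction (quadratic effort cost).
``ve`` and ``vre`` are stored as positive cost weights entering with minus
signs.

Three complementary views of the same process are provided:

* closed-form acceptance rate and mean decision time for an unbiased start
  (:func:`predict_acceptance_rate`, :func:`predict_mean_decision_time`),
* the exact Wiener first-passage time density used as the trial likelihood
  (:func:`wfpt_log_density`), with a fixed-probability uniform outlier
  mixture,
* a brute-force Euler-Maruyama simulator with Brownian-bridge crossing
  correction (:func:`simulate_first_passage`), used both to generate
  synthetic data and as an independent numerical oracle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "DDMParameters",
    "NoiseConstant",
    "OfferCell",
    "ChoicePrediction",
    "drift_rate",
    "predict_acceptance_rate",
    "predict_mean_decision_time",
    "predict_choice",
    "accept_probability",
    "wfpt_log_density",
    "wfpt_trial_loglik",
    "simulate_first_passage",
    "simulate_first_passage_batch",
]

logger = logging.getLogger(__name__)

PARAM_NAMES = ("a", "z", "t", "v0", "vr", "ve", "vre")

#: error tolerance per density evaluation for the series truncation
WFPT_SERIES_EPS = 1e-7


@dataclass(frozen=True)
class DDMParameters:
    """Subject-level parameters of the seven-parameter model.

    ``a`` is the full separation between the reject (0) and accept (``a``)
    boundaries; ``z`` the starting point as a fraction of ``a``; ``t`` the
    non-decision time in seconds; ``v0, vr, ve, vre`` the drift components.
    """

    a: float
    z: float = 0.5
    t: float = 0.3
    v0: float = 0.0
    vr: float = 0.0
    ve: float = 0.0
    vre: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ConfigurationError(f"boundary separation a must be > 0, got {self.a}")
        if not (0 < self.z < 1):
            raise ConfigurationError(f"starting fraction z must lie in (0,1), got {self.z}")
        if self.t < 0:
            raise ConfigurationError(f"non-decision time t must be >= 0, got {self.t}")
        for name in ("v0", "vr", "ve", "vre"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigurationError(f"drift component {name} must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "DDMParameters":
        return cls(**dict(zip(PARAM_NAMES, map(float, arr))))

    def replace(self, **kw) -> "DDMParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class NoiseConstant:
    """Diffusion noise scale; 1 by convention (it only sets the unit)."""

    c: float = 1.0

    def __post_init__(self) -> None:
        if not (self.c > 0):
            raise ConfigurationError(f"noise constant c must be > 0, got {self.c}")


@dataclass(frozen=True)
class OfferCell:
    """One reward-effort offer with its drift regressors.

    ``r_scaled`` = reward / max reward of the design (in (0, 1]);
    ``e_scaled`` = effort**2, the squared force fraction (quadratic cost).
    """

    reward: float
    effort: float
    r_scaled: float = field(default=None)  # type: ignore[assignment]
    e_scaled: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.r_scaled is None:
            object.__setattr__(self, "r_scaled", self.reward / 15.0)
        if self.e_scaled is None:
            object.__setattr__(self, "e_scaled", self.effort**2)
        if not (0 < self.r_scaled <= 1):
            raise ConfigurationError(f"r_scaled must lie in (0,1], got {self.r_scaled}")
        if not (0 < self.e_scaled <= 1):
            raise ConfigurationError(f"e_scaled must lie in (0,1], got {self.e_scaled}")

    @classmethod
    def from_levels(cls, reward: float, effort: float, max_reward: float = 15.0,
                    squared_effort: bool = True) -> "OfferCell":
        e = effort**2 if squared_effort else effort
        return cls(reward=reward, effort=effort, r_scaled=reward / max_reward, e_scaled=e)


@dataclass(frozen=True)
class ChoicePrediction:
    acceptance_rate: float
    mean_decision_time: float
    mean_rt: float


def drift_rate(params: DDMParameters, offer: OfferCell):
    """Trial drift rate ``V = v0 + vr*r - ve*e - vre*r*e``.

    ``offer`` regressors may be scalars or arrays; the result broadcasts.
    """
    r = np.asarray(offer.r_scaled, dtype=float)
    e = np.asarray(offer.e_scaled, dtype=float)
    v = params.v0 + params.vr * r - params.ve * e - params.vre * r * e
    return float(v) if v.ndim == 0 else v


def _check_ac(a, c) -> None:
    if np.any(np.asarray(a) <= 0) or np.any(np.asarray(c) <= 0):
        raise ConfigurationError("threshold a and noise c must both be > 0")


def predict_acceptance_rate(V, a, c: float = 1.0):
    """Closed-form acceptance probability for an unbiased start.

    ``a`` here is the distance from the (unbiased) starting point to either
    boundary, i.e. half of :attr:`DDMParameters.a`.  Returns
    ``1 / (1 + exp(-2 V a / c**2))``.
    """
    _check_ac(a, c)
    x = 2.0 * np.asarray(V, dtype=float) * np.asarray(a, dtype=float) / c**2
    out = 1.0 / (1.0 + np.exp(-x))
    return float(out) if np.ndim(out) == 0 else out


def predict_mean_decision_time(V, a, c: float = 1.0):
    """Closed-form mean decision time ``(a/V) tanh(V a / c**2)`` in seconds.

    Same half-separation convention as :func:`predict_acceptance_rate`.
    At ``V = 0`` the analytic limit ``a**2 / c**2`` is used.
    """
    _check_ac(a, c)
    V = np.asarray(V, dtype=float)
    a = np.asarray(a, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        dt_ = np.where(V == 0.0, a**2 / c**2,
                       np.divide(a, np.where(V == 0.0, 1.0, V))
                       * np.tanh(V * a / c**2))
    return float(dt_) if np.ndim(dt_) == 0 else dt_


def predict_choice(params: DDMParameters, offer: OfferCell, c: float = 1.0) -> ChoicePrediction:
    """Closed-form acceptance rate and mean RT for one offer (requires z = 0.5)."""
    if abs(params.z - 0.5) > 1e-12:
        raise ConfigurationError("closed-form predictions assume an unbiased start (z = 0.5)")
    v = drift_rate(params, offer)
    a_half = params.a / 2.0
    ar = predict_acceptance_rate(v, a_half, c)
    dt_ = predict_mean_decision_time(v, a_half, c)
    return ChoicePrediction(acceptance_rate=float(ar), mean_decision_time=float(dt_),
                            mean_rt=float(dt_ + params.t))


def accept_probability(V, a, z, c: float = 1.0):
    """Exact probability of absorbing at the accept (upper) boundary.

    Uses the scale function of the drifted diffusion on [0, a] starting at
    ``z * a``; valid for any starting fraction, unlike the closed forms above.
    """
    _check_ac(a, c)
    V = np.asarray(V, dtype=float)
    k = 2.0 * V * np.asarray(a) / c**2
    with np.errstate(over="ignore", invalid="ignore"):
        num = np.expm1(-k * z)
        den = np.expm1(-k)
        p = np.where(np.abs(k) < 1e-9, np.asarray(z, dtype=float) * np.ones_like(V),
                     np.divide(num, np.where(np.abs(k) < 1e-9, 1.0, den)))
    out = np.clip(p, 0.0, 1.0)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# Wiener first-passage time density (small/large-time series with automatic
# regime switch at truncation error WFPT_SERIES_EPS per evaluation).
# ---------------------------------------------------------------------------

def _f0_lower(tau: np.ndarray, w: np.ndarray, eps: float) -> np.ndarray:
    """Zero-drift first-passage density at the lower boundary.

    Unit separation, start fraction ``w``, in normalized time
    ``tau = t_dec * c**2 / a**2``.  Both the small-time and large-time series
    converge everywhere; the cheaper one at tolerance ``eps`` is chosen
    elementwise.
    """
    tau = np.asarray(tau, dtype=float)
    w = np.broadcast_to(np.asarray(w, dtype=float), tau.shape)
    out = np.zeros_like(tau)
    ok = tau > 0
    if not np.any(ok):
        return out
    tt = tau[ok]
    ww = w[ok]

    with np.errstate(divide="ignore", invalid="ignore"):
        arg_s = 2.0 * eps * np.sqrt(2.0 * np.pi * tt)
        ks = np.where(arg_s < 1.0, 2.0 + np.sqrt(np.maximum(-2.0 * tt * np.log(arg_s), 0.0)), 2.0)
        ks = np.maximum(ks, np.sqrt(tt) + 1.0)
        arg_l = np.pi * tt * eps
        kl = np.where(arg_l < 1.0,
                      np.sqrt(np.maximum(-2.0 * np.log(arg_l), 0.0) / (np.pi**2 * tt)),
                      0.0)
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(tt)))

    small = ks < kl
    dens = np.empty_like(tt)

    if np.any(small):
        ts, ws = tt[small], ww[small]
        K = int(np.ceil(ks[small].max()))
        ki = np.arange(-((K - 1) // 2), ((K - 1) // 2) + (K - 1) % 2 + 1, dtype=float)
        x = ws[:, None] + 2.0 * ki[None, :]
        s = np.sum(x * np.exp(-(x**2) / (2.0 * ts[:, None])), axis=1)
        dens[small] = s / np.sqrt(2.0 * np.pi * ts**3)
    if np.any(~small):
        tl, wl = tt[~small], ww[~small]
        K = max(int(np.ceil(kl[~small].max())), 1)
        ki = np.arange(1, K + 1, dtype=float)
        s = np.sum(ki[None, :] * np.exp(-(ki[None, :]**2) * np.pi**2 * tl[:, None] / 2.0)
                   * np.sin(ki[None, :] * np.pi * wl[:, None]), axis=1)
        dens[~small] = np.pi * s

    out[ok] = np.maximum(dens, 0.0)  # series truncation can leave tiny negatives
    return out


def _wfpt_density(t_dec, accept, V, a, z, c: float = 1.0,
                  eps: float = WFPT_SERIES_EPS) -> np.ndarray:
    """First-passage density at the boundary coded by ``accept``.

    ``t_dec`` is the decision time (RT minus non-decision time).  All of
    ``t_dec``, ``accept`` and ``V`` broadcast together; ``a``, ``z`` and ``c``
    are scalars.  Noise is removed by rescaling (a -> a/c, V -> V/c).
    """
    t_dec = np.asarray(t_dec, dtype=float)
    accept = np.asarray(accept, dtype=bool)
    V = np.asarray(V, dtype=float)
    t_dec, accept, V = np.broadcast_arrays(t_dec, accept, V)
    an = a / c
    vn = V / c
    # accept = upper boundary: reflect to a lower-boundary passage
    v_eff = np.where(accept, -vn, vn)
    w_eff = np.where(accept, 1.0 - z, z)
    tau = t_dec / an**2
    f0 = _f0_lower(tau, w_eff, eps)
    with np.errstate(over="ignore", invalid="ignore"):
        pref = np.exp(-v_eff * an * w_eff - (v_eff**2) * np.maximum(t_dec, 0.0) / 2.0)
    return f0 / an**2 * pref


def wfpt_log_density(rt, choice, params: DDMParameters, offer: OfferCell,
                     c: float = 1.0, outlier_prob: float = 0.05,
                     rt_range: tuple = (0.0, 10.0)):
    """Log likelihood of one (or many) observed trials.

    The density is a two-component mixture: with probability
    ``1 - outlier_prob`` the Wiener first-passage density at the boundary
    coded by ``choice`` (``"accept"``/``True`` = upper), shifted by the
    non-decision time; with probability ``outlier_prob`` a uniform
    contaminant over ``rt_range``, split evenly across the two choices.

    Returns ``-inf`` (never raises) when the density is exactly zero, e.g.
    ``rt <= t`` with no outlier component.
    """
    if not (0 <= outlier_prob < 1):
        raise ConfigurationError("outlier_prob must lie in [0, 1)")
    rt = np.asarray(rt, dtype=float)
    accept = _as_accept_mask(choice, rt.shape)
    v = drift_rate(params, offer)
    return _mixture_loglik(rt, accept, np.asarray(v, dtype=float), params.a, params.z,
                           params.t, c, outlier_prob, rt_range)


def _as_accept_mask(choice, shape) -> np.ndarray:
    if isinstance(choice, str):
        accept = np.full(shape, choice == "accept")
    else:
        ch = np.asarray(choice)
        accept = ch == "accept" if ch.dtype.kind in "US" else ch.astype(bool)
    return np.broadcast_to(accept, shape)


def _mixture_loglik(rt, accept, V, a, z, t, c, outlier_prob, rt_range):
    f = _wfpt_density(rt - t, accept, V, a, z, c)
    lo, hi = rt_range
    unif = np.where((rt >= lo) & (rt <= hi), 1.0 / (hi - lo) / 2.0, 0.0)
    dens = (1.0 - outlier_prob) * f + outlier_prob * unif
    with np.errstate(divide="ignore"):
        out = np.log(dens)
    return float(out) if out.ndim == 0 else out


def wfpt_trial_loglik(rt, accept, r_scaled, e_scaled, theta: np.ndarray,
                      c: float = 1.0, outlier_prob: float = 0.05,
                      rt_range: tuple = (0.0, 10.0)) -> float:
    """Summed log likelihood of a trial batch for a parameter vector.

    Low-level hot path used by the samplers: ``theta`` is the natural-scale
    vector (a, z, t, v0, vr, ve, vre); the per-trial drift is rebuilt from the
    cached regressors.  Returns ``-inf`` for out-of-support ``theta``.
    """
    a, z, t, v0, vr, ve, vre = theta
    if not (a > 0 and 0 < z < 1 and t >= 0):
        return -np.inf
    V = v0 + vr * r_scaled - ve * e_scaled - vre * r_scaled * e_scaled
    ll = _mixture_loglik(rt, accept, V, a, z, t, c, outlier_prob, rt_range)
    return float(np.sum(ll))


# ---------------------------------------------------------------------------
# Brute-force simulator
# ---------------------------------------------------------------------------

def simulate_first_passage_batch(V, a, z, t, c, rng: np.random.Generator,
                                 dt: float = 1e-3, t_max: float = 30.0):
    """Simulate many independent first passages in parallel.

    Euler-Maruyama with exact Gaussian increments plus a Brownian-bridge
    correction for within-step boundary crossings, which removes the leading
    O(sqrt(dt)) bias of naive endpoint checking.  Paths still unabsorbed at
    ``t_max`` are restarted (and counted in the log); with sensible
    parameters this is vanishingly rare.

    Returns ``(accept, rt)`` boolean/float arrays; ``rt`` includes the
    non-decision time ``t`` and is always ``>= t``.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be > 0")
    V = np.atleast_1d(np.asarray(V, dtype=float))
    n = V.shape[0]
    accept = np.zeros(n, dtype=bool)
    rt = np.full(n, np.nan)
    idx = np.arange(n)
    x = np.full(n, z * a)
    v = V.copy()
    elapsed = np.zeros(n)
    sig = c * math.sqrt(dt)
    n_restarts = 0
    max_steps = int(round(t_max / dt))
    step = 0
    while idx.size:
        step += 1
        x_new = x + v * dt + sig * rng.standard_normal(idx.size)
        up = x_new >= a
        lo = x_new <= 0.0
        inside = ~(up | lo)
        if np.any(inside):
            # bridge crossing probabilities given both endpoints interior
            xi, xn = x[inside], x_new[inside]
            p_up = np.exp(-2.0 * (a - xi) * (a - xn) / (c**2 * dt))
            p_lo = np.exp(-2.0 * xi * xn / (c**2 * dt))
            u = rng.random(xi.size)
            b_up = u < p_up
            b_lo = (~b_up) & (u < p_up + p_lo)
            tmp_up = np.zeros(idx.size, dtype=bool)
            tmp_lo = np.zeros(idx.size, dtype=bool)
            tmp_up[inside] = b_up
            tmp_lo[inside] = b_lo
            up = up | tmp_up
            lo = lo | tmp_lo
        done = up | lo
        if np.any(done):
            hit = idx[done]
            accept[hit] = up[done]
            # bridge hits occurred strictly inside the step; use its midpoint
            endpoint = (x_new >= a) | (x_new <= 0.0)
            rt[hit] = elapsed[done] + np.where(endpoint[done], dt, dt / 2.0)
        keep = ~done
        idx = idx[keep]
        x = x_new[keep]
        v = v[keep]
        elapsed = elapsed[keep] + dt
        if step >= max_steps and idx.size:
            n_restarts += idx.size
            x = np.full(idx.size, z * a)
            elapsed = np.zeros(idx.size)
            step = 0
    if n_restarts:
        logger.warning("simulate_first_passage_batch: %d path(s) exceeded t_max=%.1fs and were restarted",
                       n_restarts, t_max)
    return accept, rt + t


def simulate_first_passage(params: DDMParameters, offer: OfferCell,
                           c: float = 1.0, rng: np.random.Generator | None = None,
                           dt: float = 1e-3, t_max: float = 30.0):
    """Simulate a single trial; returns ``("accept"|"reject", rt_seconds)``."""
    if rng is None:
        rng = np.random.default_rng()
    v = drift_rate(params, offer)
    acc, rt = simulate_first_passage_batch(np.array([v]), params.a, params.z,
                                           params.t, c, rng, dt=dt, t_max=t_max)
    return ("accept" if acc[0] else "reject", float(rt[0]))
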