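"""Single-accumulator linear ballistic accumulator (LBA) model of simple reaction time.

The model assumes that on each trial evidence for the single available
response grows linearly from a random start point ``k ~ Uniform(0, a)``
toward a threshold ``b`` at a drift rate ``v ~ Normal(mu, sigma)`` drawn
independently per trial (truncated to ``v > 0`` so every trial
terminates).  The observed reaction time is the accumulation duration
plus a constant non-decision time ``t_er`` that absorbs stimulus
encoding and motor initiation::

    RT = t_er + (b - k) / v

Fitting minimizes the likelihood-ratio chi-square (G-square) between
observed and model-predicted RT quantile bins with a multi-start
Nelder-Mead simplex, recovering ``t_er`` from an RT distribution.

Internally all times are seconds; the public I/O surface accepts and
reports milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import ndtr, ndtri

__all__ = [
    "LBAParams",
    "RTSample",
    "QuantileFitResult",
    "LBAModel",
    "LBAResults",
    "exclude_rts",
    "simulate_lba",
    "lba_cdf",
    "rt_quantiles",
    "gsq_objective",
    "fit_lba",
]

#: Quantile probabilities delimiting the six RT bins used by the fit.
FIT_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)

#: Expected bin proportions implied by those quantiles.
BIN_PROPS = np.array([0.1, 0.2, 0.2, 0.2, 0.2, 0.1])

#: Default RT trial-exclusion bounds in milliseconds (inclusive).
RT_BOUNDS_MS = (150.0, 1500.0)


@dataclass(frozen=True)
class LBAParams:
    """Parameters of the single-accumulator LBA.

    Parameters
    ----------
    t_er : float
        Non-decision time in seconds (> 0).
    b : float
        Decision threshold (evidence units, > ``a``).
    mu : float
        Mean drift rate (evidence / s).
    sigma : float
        Between-trial drift-rate standard deviation (>= 0).
    a : float
        Start-point range; the fixed scaling constant, 0.5 by default.
    """

    t_er: float
    b: float
    mu: float
    sigma: float
    a: float = 0.5

    def __post_init__(self) -> None:
        if not self.t_er > 0:
            raise ValueError(f"t_er must be positive, got {self.t_er}")
        if not self.b > self.a:
            raise ValueError(f"threshold b={self.b} must exceed start-point range a={self.a}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")
        if self.a < 0:
            raise ValueError(f"a must be non-negative, got {self.a}")


@dataclass(frozen=True)
class RTSample:
    """Reaction times (ms) surviving the trial-exclusion bounds."""

    rts_ms: np.ndarray
    n_excluded_low: int = 0
    n_excluded_high: int = 0

    @property
    def n(self) -> int:
        return self.rts_ms.size


@dataclass(frozen=True)
class QuantileFitResult:
    """Outcome of a quantile-based G-square fit."""

    params: LBAParams
    gsq: float
    observed_q_ms: np.ndarray
    predicted_q_ms: np.ndarray
    n_restarts_used: int
    seed: int | None = None


class EmptySampleError(ValueError):
    """All trials excluded or an empty RT vector supplied."""


def exclude_rts(rts_ms, lo_ms: float = RT_BOUNDS_MS[0], hi_ms: float = RT_BOUNDS_MS[1]) -> RTSample:
    """Apply the RT trial-exclusion rule, keeping ``lo <= rt <= hi`` (bounds inclusive).

    Raises :class:`EmptySampleError` when nothing survives.
    """
    rts_ms = np.asarray(rts_ms, dtype=float)
    if rts_ms.size == 0:
        raise EmptySampleError("empty RT vector")
    if not lo_ms < hi_ms:
        raise ValueError("lo must be below hi")
    low = rts_ms < lo_ms
    high = rts_ms > hi_ms
    kept = rts_ms[~(low | high)]
    if kept.size == 0:
        raise EmptySampleError(
            f"all {rts_ms.size} trials excluded by bounds [{lo_ms}, {hi_ms}] ms"
        )
    return RTSample(kept, int(low.sum()), int(high.sum()))


def _truncated_drifts(params: LBAParams, u: np.ndarray) -> np.ndarray:
    """Map uniforms to Normal(mu, sigma) drifts truncated to v > 0."""
    if params.sigma == 0:
        if params.mu <= 0:
            raise ValueError("mu <= 0 with sigma = 0: accumulator never finishes")
        return np.full(u.shape, params.mu)
    p0 = ndtr(-params.mu / params.sigma)  # mass below zero
    return params.mu + params.sigma * ndtri(p0 + u * (1.0 - p0))


def _simulate_from_uniforms(params: LBAParams, u_start: np.ndarray, u_drift: np.ndarray) -> np.ndarray:
    """Deterministic simulation given pre-drawn uniforms (common random numbers)."""
    k = params.a * u_start
    v = _truncated_drifts(params, u_drift)
    return params.t_er + (params.b - k) / v


def simulate_lba(params: LBAParams, n_trials: int, seed) -> np.ndarray:
    """Simulate ``n_trials`` reaction times (seconds) from the model.

    ``seed`` may be an int or a :class:`numpy.random.Generator`.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    u1 = rng.random(n_trials)
    u2 = rng.random(n_trials)
    return _simulate_from_uniforms(params, u1, u2)


def lba_cdf(t, params: LBAParams) -> np.ndarray:
    """Closed-form distribution function of the simulated RT at time ``t`` (seconds).

    Derived from P(k + s*v >= b) for decision time s = t - t_er with the
    untruncated Gaussian drift, renormalized by P(v > 0) to match the
    truncated-drift simulator; proper (limit 1) for any mu when sigma > 0.
    """
    t = np.asarray(t, dtype=float)
    s = t - params.t_er
    out = np.zeros(t.shape if t.shape else (1,), dtype=float)
    pos = s > 0
    sp = np.atleast_1d(s)[np.atleast_1d(pos)]
    a, b, mu, sigma = params.a, params.b, params.mu, params.sigma
    if sigma == 0:
        if mu <= 0:
            raise ValueError("mu <= 0 with sigma = 0: degenerate model")
        # start point alone is random: F = P(k >= b - s*mu)
        if a == 0:
            vals = (sp * mu >= b).astype(float)
        else:
            vals = np.clip((a - (b - sp * mu)) / a, 0.0, 1.0)
    else:
        z_norm = ndtr(mu / sigma)
        if a < 1e-12:
            vals = ndtr((sp * mu - b) / (sp * sigma)) / z_norm
        else:
            zs = (b - sp * mu) / (sp * sigma)
            za = (b - a - sp * mu) / (sp * sigma)
            phi = lambda x: np.exp(-0.5 * x * x) / np.sqrt(2 * np.pi)
            raw = (
                1.0
                + ((b - a - sp * mu) / a) * ndtr(za)
                - ((b - sp * mu) / a) * ndtr(zs)
                + (sp * sigma / a) * (phi(za) - phi(zs))
            )
            vals = np.clip(raw, 0.0, 1.0) / z_norm
    flat = np.zeros(np.atleast_1d(s).shape, dtype=float)
    flat[np.atleast_1d(pos)] = np.clip(vals, 0.0, 1.0)
    return flat.reshape(t.shape) if t.shape else float(flat[0])


def rt_quantiles(rts, probs=FIT_QUANTILES) -> np.ndarray:
    """Empirical quantiles with the linear-interpolation (type-7) convention."""
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise EmptySampleError("empty RT vector")
    probs = np.asarray(probs, dtype=float)
    if np.any(np.diff(probs) <= 0) or np.any((probs <= 0) | (probs >= 1)):
        raise ValueError("probs must be strictly increasing within (0, 1)")
    return np.quantile(rts, probs)


def _gsq_from_probs(n_obs: int, model_probs: np.ndarray, floor: float) -> float:
    pi = np.maximum(model_probs, floor)
    obs = n_obs * BIN_PROPS
    return float(2.0 * np.sum(obs * np.log(obs / (n_obs * pi))))


def _model_bin_probs(params: LBAParams, edges_s: np.ndarray, n_sim: int,
                     u_start: np.ndarray | None, u_drift: np.ndarray | None,
                     method: str, rng=None) -> np.ndarray:
    if method == "cdf":
        cdf_vals = np.concatenate(([0.0], np.atleast_1d(lba_cdf(edges_s, params)), [1.0]))
        return np.diff(cdf_vals)
    if u_start is None:
        rng = np.random.default_rng(rng)
        u_start = rng.random(n_sim)
        u_drift = rng.random(n_sim)
    sims = _simulate_from_uniforms(params, u_start, u_drift)
    counts = np.histogram(sims, bins=np.concatenate(([-np.inf], edges_s, [np.inf])))[0]
    return counts / sims.size


def gsq_objective(params: LBAParams, sample: RTSample, n_sim: int, seed,
                  method: str = "simulate") -> float:
    """Likelihood-ratio chi-square between observed and predicted RT quantile bins.

    The five observed quantiles delimit six bins with fixed observed
    proportions (.1, .2, .2, .2, .2, .1); model bin probabilities come
    from ``n_sim`` simulated trials (or the closed-form CDF with
    ``method='cdf'``), floored at ``1 / (2 * n_sim)``.
    """
    if sample.n == 0:
        raise EmptySampleError("empty sample")
    if np.ptp(sample.rts_ms) == 0:
        raise ValueError("degenerate sample: all RTs identical, quantile bins undefined")
    if method == "simulate" and n_sim < 10 * sample.n:
        raise ValueError("n_sim must be at least 10x the sample size")
    edges_s = rt_quantiles(sample.rts_ms) / 1000.0
    probs = _model_bin_probs(params, edges_s, n_sim, None, None, method, rng=seed)
    return _gsq_from_probs(sample.n, probs, 1.0 / (2.0 * n_sim))


# log-uniform initial-candidate ranges (seconds / evidence units); the
# t_er upper bound is replaced by the sample's minimum RT at fit time
_CAND_RANGES = {"t_er": (0.05, None), "b": (0.5, 5.0), "mu": (0.1, 10.0), "sigma": (0.05, 3.0)}

_PENALTY = 1e6


def fit_lba(sample: RTSample, n_init_candidates: int = 100, n_repeats: int = 20,
            n_sim: int = 100_000, seed=None, method: str = "simulate",
            a: float = 0.5, maxfev: int = 2000) -> QuantileFitResult:
    """Multi-start simplex minimization of the quantile G-square.

    Each repeat scores ``n_init_candidates`` random parameter sets
    (log-uniform over the candidate ranges) and runs Nelder-Mead from
    the best one on log-transformed parameters; the overall minimum
    across repeats is returned.  One stream of common random numbers is
    drawn per repeat so the simulated objective is deterministic within
    a repeat.
    """
    if sample.n < 25:
        raise ValueError("need at least 25 retained trials for stable quantiles")
    if np.ptp(sample.rts_ms) == 0:
        raise ValueError("degenerate sample: all RTs identical")
    edges_s = rt_quantiles(sample.rts_ms) / 1000.0
    min_rt_s = float(np.min(sample.rts_ms)) / 1000.0
    floor = 1.0 / (2.0 * n_sim)
    n_obs = sample.n

    master = np.random.SeedSequence(seed)
    streams = master.spawn(n_repeats)

    lo = np.log([_CAND_RANGES["t_er"][0], _CAND_RANGES["b"][0],
                 _CAND_RANGES["mu"][0], _CAND_RANGES["sigma"][0]])
    hi = np.log([min_rt_s, _CAND_RANGES["b"][1], _CAND_RANGES["mu"][1],
                 _CAND_RANGES["sigma"][1]])

    best = None
    n_used = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        if method == "simulate":
            u_start = rng.random(n_sim)
            u_drift = rng.random(n_sim)
        else:
            u_start = u_drift = None

        def objective(log_theta):
            # the simplex is confined to the candidate box: outside it the
            # scaling ridge t_er -> 0, (b, mu) -> inf fits 5 quantiles
            # arbitrarily well and the fit degenerates
            if np.any(log_theta < lo - 1e-9) or np.any(log_theta > hi + 1e-9):
                return _PENALTY * (1.0 + float(np.abs(log_theta).sum()))
            t_er, b, mu, sigma = np.exp(log_theta)
            if not (0 < t_er < min_rt_s) or b <= a or sigma <= 0:
                return _PENALTY * (1.0 + abs(t_er))
            params = LBAParams(t_er=t_er, b=b, mu=mu, sigma=sigma, a=a)
            probs = _model_bin_probs(params, edges_s, n_sim, u_start, u_drift, method)
            return _gsq_from_probs(n_obs, probs, floor)

        cands = rng.uniform(lo, hi, size=(n_init_candidates, 4))
        scores = np.array([objective(c) for c in cands])
        x0 = cands[int(np.argmin(scores))]
        try:
            res = optimize.minimize(
                objective, x0, method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-4, "maxfev": maxfev},
            )
            n_used += 1
        except Exception:  # pragma: no cover - optimizer blow-up
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= _PENALTY:
        raise RuntimeError(
            "simplex failed on all restarts; best objective "
            f"{None if best is None else best.fun}"
        )

    t_er, b, mu, sigma = np.exp(best.x)
    params = LBAParams(t_er=float(t_er), b=float(b), mu=float(mu), sigma=float(sigma), a=a)
    pred_rng = np.random.default_rng(master.spawn(1)[0])
    sims = simulate_lba(params, max(n_sim, 10 * n_obs), pred_rng)
    predicted_q_ms = rt_quantiles(sims * 1000.0)
    return QuantileFitResult(
        params=params,
        gsq=float(best.fun),
        observed_q_ms=edges_s * 1000.0,
        predicted_q_ms=predicted_q_ms,
        n_restarts_used=n_used,
        seed=seed if isinstance(seed, int) else None,
    )


class LBAModel:
    """Accumulator model of a participant's simple-RT distribution.

    Parameters
    ----------
    rts_ms : array-like
        Raw reaction times in milliseconds.
    rt_bounds_ms : tuple, optional
        Inclusive retention bounds applied before fitting.
    """

    def __init__(self, rts_ms, rt_bounds_ms=RT_BOUNDS_MS):
        self.sample = exclude_rts(rts_ms, *rt_bounds_ms)

    def fit(self, n_init_candidates: int = 100, n_repeats: int = 20,
            n_sim: int = 100_000, seed=None, method: str = "simulate",
            maxfev: int = 2000) -> "LBAResults":
        res = fit_lba(self.sample, n_init_candidates, n_repeats, n_sim,
                      seed=seed, method=method, maxfev=maxfev)
        return LBAResults(self, res)


@dataclass
class LBAResults:
    """Fitted accumulator parameters for one participant."""

    model: LBAModel
    fit_result: QuantileFitResult

    @property
    def params(self) -> LBAParams:
        return self.fit_result.params

    @property
    def t_er_ms(self) -> float:
        return self.fit_result.params.t_er * 1000.0

    @property
    def gsq(self) -> float:
        return self.fit_result.gsq

    def to_dict(self) -> dict:
        fr = self.fit_result
        return {
            "t_er_ms": fr.params.t_er * 1000.0,
            "b": fr.params.b,
            "mu": fr.params.mu,
            "sigma": fr.params.sigma,
            "a": fr.params.a,
            "gsq": fr.gsq,
            "observed_q_ms": list(fr.observed_q_ms),
            "predicted_q_ms": list(fr.predicted_q_ms),
            "seed": fr.seed,
            "n_trials": self.model.sample.n,
        }

    def summary(self) -> str:
        fr = self.fit_result
        lines = [
            "Linear ballistic accumulator fit (single accumulator)",
            "=" * 54,
            f"trials retained      {self.model.sample.n}",
            f"non-decision T_er    {fr.params.t_er * 1000:8.1f} ms",
            f"threshold b          {fr.params.b:8.3f}",
            f"mean drift mu        {fr.params.mu:8.3f} /s",
            f"drift sd sigma       {fr.params.sigma:8.3f} /s",
            f"start range a        {fr.params.a:8.3f} (fixed)",
            f"G-square             {fr.gsq:8.4f}",
            "quantile    observed(ms)  predicted(ms)",
        ]
        for p, o, m in zip(FIT_QUANTILES, fr.observed_q_ms, fr.predicted_q_ms):
            lines.append(f"   {p:.1f}       {o:9.1f}     {m:9.1f}")
        return "\n".join(lines)
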