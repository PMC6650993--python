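"""Segment-wise brain-behavior statistics with TFCE permutation inference.

For every tract segment and microstructural metric, an ordinary
least-squares GLM relates the weighted metric to a behavioral regressor
(non-decision time or mean RT) with age as nuisance covariate.  The
segment-wise t-map is enhanced with one-dimensional threshold-free
cluster enhancement (TFCE),

    tfce(s) = sum_h e(h, s)^E * h^H * dh,

where ``e(h, s)`` is the length of the maximal contiguous run of
segments with statistic >= h containing segment ``s``.  Familywise
error across segments, the four metrics and both signs is controlled by
a Freedman-Lane max-statistic permutation test: behavioral residuals
(after removing the nuisance fit) are permuted, models refit, and each
permutation contributes its single largest TFCE value to the null
distribution.

Also provided: frequentist + default-Bayesian Pearson correlation
(stretched-beta prior on the population correlation, numerical
integration of the exact sampling density of r), and a two-factor
repeated-measures ANOVA (segments x hemispheres) with the
Greenhouse-Geisser sphericity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats as sps

from .segments import TractProfile

__all__ = [
    "DesignMatrix",
    "TFCEResult",
    "CorrelationReport",
    "RmAnovaResult",
    "glm_segment",
    "tfce_1d",
    "permutation_fwe",
    "pearson_report",
    "bayes_factor_pearson",
    "rm_anova_gg",
    "TractAssociationModel",
    "TractAssociationResults",
]

TFCE_E = 0.5
TFCE_H = 2.0
_T_CAP = 1e6


@dataclass
class DesignMatrix:
    """Behavioral regressor plus age nuisance (intercept implicit)."""

    regressor: np.ndarray
    nuisance: np.ndarray
    regressor_name: str = "t_er_ms"

    def __post_init__(self) -> None:
        self.regressor = np.asarray(self.regressor, dtype=float)
        self.nuisance = np.asarray(self.nuisance, dtype=float)
        if self.regressor.shape != self.nuisance.shape:
            raise ValueError("regressor and nuisance must have equal length")
        if np.any(np.isnan(self.regressor)) or np.any(np.isnan(self.nuisance)):
            raise ValueError("design matrix contains missing values")
        if np.var(self.regressor) == 0:
            raise ValueError("regressor has zero variance")

    @property
    def n(self) -> int:
        return self.regressor.size


@dataclass
class TFCEResult:
    """Segment x metric standardized coefficients, TFCE values and FWE p-values."""

    beta_std: np.ndarray
    t_stat: np.ndarray
    tfce: np.ndarray
    p_fwe: np.ndarray
    n_perm: int
    seed: int | None
    metrics: tuple[str, ...]


@dataclass
class CorrelationReport:
    r: float
    p: float
    ci95: tuple[float, float]
    bf10: float
    n: int


@dataclass
class RmAnovaResult:
    """Two-factor within-subject ANOVA with Greenhouse-Geisser correction."""

    effects: pd.DataFrame  # index: effect; columns F, df1, df2, eps_gg, p_gg, p_uncorrected


def _residualize(y: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Residuals of ``y`` against the orthonormal column basis ``Q``."""
    return y - Q @ (Q.T @ y)


def _nuisance_basis(nuisance: np.ndarray) -> np.ndarray:
    Z = np.column_stack([np.ones_like(nuisance), nuisance])
    Q, _ = np.linalg.qr(Z)
    return Q


def glm_segment(y, design: DesignMatrix) -> tuple[float, float]:
    """OLS of ``y`` on [1, regressor, age]; returns (beta_std, t) for the regressor.

    ``beta_std`` is the coefficient after z-scoring ``y`` and the
    regressor; a perfect fit caps the t statistic at 1e6.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n <= 3 + 1:
        raise ValueError("need more participants than regressors + 2")
    Q = _nuisance_basis(design.nuisance)
    x_t = _residualize(design.regressor, Q)
    xx = float(x_t @ x_t)
    if xx < 1e-12 * n * np.var(design.regressor):
        raise ValueError("rank-deficient design: regressor collinear with nuisance")
    y_t = _residualize(y, Q)
    beta = float(x_t @ y_t) / xx
    rss = float(y_t @ y_t) - beta**2 * xx
    df = n - 3
    if rss <= 1e-12 * max(float(y_t @ y_t), 1e-300):
        t = np.sign(beta) * _T_CAP
    else:
        t = beta * np.sqrt(xx * df / rss)
    sy = np.std(y, ddof=1)
    beta_std = beta * np.std(design.regressor, ddof=1) / sy if sy > 0 else np.nan
    return beta_std, float(t)


def _run_lengths(mask: np.ndarray) -> np.ndarray:
    """Per-position length of the contiguous run of True containing it.

    Works on the last axis for any leading shape (each row an
    independent 1-D map).
    """
    shape = mask.shape
    k = shape[-1]
    mask2 = mask.reshape(-1, k)
    r = mask2.shape[0]
    starts = mask2 & ~np.pad(mask2, ((0, 0), (1, 0)))[:, :-1]
    run_id = np.cumsum(starts, axis=1)
    run_id_flat = (run_id + np.arange(r)[:, None] * (k // 2 + 2)) * mask2
    lengths = np.bincount(run_id_flat.ravel(), weights=mask2.ravel())
    return np.where(mask2, lengths[run_id_flat], 0.0).reshape(shape)


def tfce_1d(stat, E: float = TFCE_E, H: float = TFCE_H, dh: float | None = None,
            n_steps: int = 100) -> np.ndarray:
    """One-dimensional TFCE of a non-negative statistic vector.

    Negative entries contribute nothing (enhance ``-stat`` separately
    for the negative direction).  ``dh`` defaults to ``max(stat)/n_steps``.
    """
    stat = np.maximum(np.asarray(stat, dtype=float), 0.0)
    if stat.ndim != 1:
        raise ValueError("stat must be 1-D")
    m = stat.max()
    if m == 0:
        return np.zeros_like(stat)
    if dh is None:
        dh = m / n_steps
    if dh <= 0:
        raise ValueError("dh must be positive")
    return _tfce_rows(stat[None, :], E, H, dh)[0]


try:
    from numba import njit

    @njit(cache=True)
    def _tfce_rows_kernel(stat, E, H, dh, top):  # pragma: no cover - jitted
        r, k = stat.shape
        out = np.zeros((r, k))
        for row in range(r):
            h = dh
            while h <= top + 1e-12:
                hH = h**H * dh
                i = 0
                while i < k:
                    if stat[row, i] >= h:
                        j = i
                        while j < k and stat[row, j] >= h:
                            j += 1
                        val = float(j - i) ** E * hH
                        for t in range(i, j):
                            out[row, t] += val
                        i = j
                    else:
                        i += 1
                h += dh
        return out

except ImportError:  # pragma: no cover
    _tfce_rows_kernel = None


def _tfce_rows(stat: np.ndarray, E: float, H: float, dh: float,
               h_max: float | None = None) -> np.ndarray:
    """Vectorized TFCE over rows (each row one statistic map)."""
    stat = np.maximum(stat, 0.0)
    top = stat.max() if h_max is None else h_max
    if top < dh:
        return np.zeros_like(stat)
    if _tfce_rows_kernel is not None:
        return _tfce_rows_kernel(np.ascontiguousarray(stat, dtype=np.float64),
                                 float(E), float(H), float(dh), float(top))
    heights = np.arange(dh, top + 1e-12, dh)
    mask = stat[None, :, :] >= heights[:, None, None]
    ext = _run_lengths(mask)
    return ((ext**E) * (heights**H)[:, None, None]).sum(axis=0) * dh


def permutation_fwe(profiles: TractProfile, design: DesignMatrix, n_perm: int = 10_000,
                    seed=None, E: float = TFCE_E, H: float = TFCE_H,
                    dh: float | None = None, n_steps: int = 100) -> TFCEResult:
    """Freedman-Lane max-TFCE permutation test across segments, metrics and signs.

    Participants with a missing value in a cell are dropped pairwise for
    that cell, and each cell re-uses the restriction of the shared
    participant permutation to its own subset.  Cells with constant
    metric values are flagged (NaN) and excluded from the max.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    vals = profiles.values
    n, n_seg, n_met = vals.shape
    if n != design.n:
        raise ValueError("profile and design participant counts differ")
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])

    beta = np.full((n_seg, n_met), np.nan)
    tmap = np.full((n_seg, n_met), np.nan)
    # per-cell precomputation
    cell_info = {}
    for m in range(n_met):
        for s in range(n_seg):
            y = vals[:, s, m]
            ok = ~np.isnan(y)
            ys = y[ok]
            if ok.sum() <= 4 or np.ptp(ys) == 0 or np.var(design.regressor[ok]) == 0:
                continue  # flagged: insufficient or constant data
            sub = DesignMatrix(design.regressor[ok], design.nuisance[ok],
                               design.regressor_name)
            beta[s, m], tmap[s, m] = glm_segment(ys, sub)
            Q = _nuisance_basis(sub.nuisance)
            x_t = _residualize(sub.regressor, Q)
            e = _residualize(ys, Q)
            cell_info[(s, m)] = (np.flatnonzero(ok), Q, x_t, float(x_t @ x_t), e)

    if dh is None:
        top = np.nanmax(np.abs(tmap))
        if not np.isfinite(top) or top == 0:
            top = 1.0
        dh = top / n_steps

    tfce_pos = np.zeros((n_seg, n_met))
    tfce_neg = np.zeros((n_seg, n_met))
    for m in range(n_met):
        col = np.nan_to_num(tmap[:, m], nan=0.0)
        tfce_pos[:, m] = _tfce_rows(col[None, :], E, H, dh)[0]
        tfce_neg[:, m] = _tfce_rows(-col[None, :], E, H, dh)[0]
    tfce_obs = np.where(np.nan_to_num(tmap, nan=0.0) >= 0, tfce_pos, tfce_neg)
    tfce_obs[np.isnan(tmap)] = np.nan

    # permutation t-maps, vectorized over permutations; complete cells share
    # the permutation directly, incomplete cells re-use its restriction to
    # their participant subset
    t_perm = np.zeros((n_perm, n_seg, n_met))
    complete = [(sm, info) for sm, info in cell_info.items() if info[0].size == n]
    partial = [(sm, info) for sm, info in cell_info.items() if info[0].size < n]
    if complete:
        Q = complete[0][1][1]
        Emat = np.stack([info[4] for _, info in complete], axis=1)  # (n, C)
        Xmat = np.stack([info[2] for _, info in complete], axis=1)
        xx_vec = np.array([info[3] for _, info in complete])
        ee_vec = np.einsum("nc,nc->c", Emat, Emat)
        df = n - 3
        Ep = Emat[perms]  # (n_perm, n, C)
        betas = np.einsum("pnc,nc->pc", Ep, Xmat) / xx_vec
        proj = np.einsum("pnc,nk->pkc", Ep, Q)
        rss = ee_vec[None, :] - np.einsum("pkc,pkc->pc", proj, proj) - betas**2 * xx_vec
        tvals = betas * np.sqrt(xx_vec * df / np.maximum(rss, 1e-300))
        for j, ((s, m), _) in enumerate(complete):
            t_perm[:, s, m] = tvals[:, j]
    for (s, m), (subset, Q, x_t, xx, e) in partial:
        msub = subset.size
        df = msub - 3
        inset = np.isin(perms, subset)
        idx = perms[inset].reshape(n_perm, msub)
        pos = np.full(n, -1)
        pos[subset] = np.arange(msub)
        idx = pos[idx]
        Ep = e[idx]  # (n_perm, msub)
        betas = (Ep @ x_t) / xx
        proj = Ep @ Q
        rss = float(e @ e) - np.einsum("ij,ij->i", proj, proj) - betas**2 * xx
        t_perm[:, s, m] = betas * np.sqrt(xx * df / np.maximum(rss, 1e-300))

    max_null = np.zeros(n_perm)
    for m in range(n_met):
        cols = t_perm[:, :, m]
        valid = ~np.isnan(tmap[:, m])
        cols = np.where(valid[None, :], cols, 0.0)
        enh_p = _tfce_rows(cols, E, H, dh)
        enh_n = _tfce_rows(-cols, E, H, dh)
        max_null = np.maximum(max_null, np.maximum(enh_p, enh_n).max(axis=1))

    p_fwe = np.full((n_seg, n_met), np.nan)
    valid = ~np.isnan(tfce_obs)
    exceed = (max_null[:, None] >= tfce_obs[valid][None, :] - 1e-12).sum(axis=0)
    p_fwe[valid] = (1.0 + exceed) / (n_perm + 1.0)
    return TFCEResult(beta_std=beta, t_stat=tmap, tfce=tfce_obs, p_fwe=p_fwe,
                      n_perm=n_perm, seed=seed if isinstance(seed, int) else None,
                      metrics=profiles.metrics)


# ---------------------------------------------------------------------------
# correlations

def _r_log_density(r: float, rho: np.ndarray, n: int) -> np.ndarray:
    """Exact (Hotelling) sampling density of the Pearson r, log scale."""
    rho = np.asarray(rho, dtype=float)
    lc = (
        np.log(n - 2)
        + special.gammaln(n - 1)
        + (n - 1) / 2 * np.log1p(-(rho**2))
        + (n - 4) / 2 * np.log1p(-(r**2))
        - 0.5 * np.log(2 * np.pi)
        - special.gammaln(n - 0.5)
        - (n - 1.5) * np.log1p(-rho * r)
    )
    return lc + np.log(special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2))


def bayes_factor_pearson(r: float, n: int, kappa: float = 1.0) -> float:
    """Default two-sided Bayes factor BF10 for a Pearson correlation.

    Stretched-beta prior of width ``kappa`` on the population
    correlation (uniform on [-1, 1] at the default width 1), integrated
    numerically against the exact sampling density of ``r``.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    alpha = 1.0 / kappa

    def integrand(rho):
        log_prior = (
            (alpha - 1) * np.log1p(-(rho**2))
            - special.betaln(alpha, alpha)
            - (2 * alpha - 1) * np.log(2.0)
        )
        return np.exp(_r_log_density(r, rho, n) + log_prior)

    num, _ = integrate.quad(integrand, -1.0, 1.0, limit=200)
    return float(num / np.exp(_r_log_density(r, 0.0, n)))


def pearson_report(x, y, kappa: float = 1.0) -> CorrelationReport:
    """Frequentist and default-Bayesian Pearson correlation between two vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        p = 0.0
        ci = (r, r)
        bf = np.inf
    else:
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        p = float(2 * sps.t.sf(abs(t), n - 2))
        z = np.arctanh(r)
        half = 1.959964 / np.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
        bf = bayes_factor_pearson(r, n, kappa)
    return CorrelationReport(r=r, p=p, ci95=ci, bf10=bf, n=n)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA

def _gg_epsilon(cov: np.ndarray, k: int) -> float:
    """Greenhouse-Geisser epsilon from the covariance of orthonormal contrasts."""
    # cov is the (k-1)-dim covariance of orthonormalized contrast scores
    tr = np.trace(cov)
    tr2 = np.trace(cov @ cov)
    if tr2 <= 0:
        return 1.0
    return float(min(tr**2 / ((k - 1) * tr2), 1.0))


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (Helmert, normalized)."""
    C = np.zeros((k - 1, k))
    for i in range(k - 1):
        C[i, : i + 1] = 1.0
        C[i, i + 1] = -(i + 1)
        C[i] /= np.linalg.norm(C[i])
    return C


def rm_anova_gg(data: np.ndarray, factor_names: tuple[str, str] = ("hemisphere", "segment")
                ) -> RmAnovaResult:
    """Two-factor within-subject ANOVA on a (subjects, A levels, B levels) array.

    F statistics come from the classical sums-of-squares decomposition
    with subject-by-effect error terms; each effect's degrees of freedom
    are scaled by its Greenhouse-Geisser epsilon (exactly 1 for 2-level
    factors).  Missing cells are rejected.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("data must be subjects x A x B")
    if np.any(np.isnan(data)):
        raise ValueError("missing cells are not supported in repeated-measures ANOVA")
    n, a, b = data.shape
    grand = data.mean()
    m_i = data.mean(axis=(1, 2))
    m_a = data.mean(axis=(0, 2))
    m_b = data.mean(axis=(0, 1))
    m_ia = data.mean(axis=2)
    m_ib = data.mean(axis=1)
    m_ab = data.mean(axis=0)

    rows = {}

    def add_effect(name, ss_eff, ss_err, df1, df2, eps):
        if ss_err <= 0:
            f = np.nan
            p = np.nan
            p_gg = np.nan
        else:
            f = (ss_eff / df1) / (ss_err / df2)
            p = float(sps.f.sf(f, df1, df2))
            p_gg = float(sps.f.sf(f, df1 * eps, df2 * eps))
        rows[name] = {"F": f, "df1": df1, "df2": df2, "eps_gg": eps,
                      "p_gg": p_gg, "p_uncorrected": p}

    # main effect A
    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_ea = b * np.sum((m_ia - m_i[:, None] - m_a[None, :] + grand) ** 2)
    Ca = _orthonormal_contrasts(a)
    cov_a = np.cov(m_ia @ Ca.T, rowvar=False).reshape(a - 1, a - 1)
    add_effect(factor_names[0], ss_a, ss_ea, a - 1, (a - 1) * (n - 1),
               1.0 if a == 2 else _gg_epsilon(cov_a, a))

    # main effect B
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_eb = a * np.sum((m_ib - m_i[:, None] - m_b[None, :] + grand) ** 2)
    Cb = _orthonormal_contrasts(b)
    cov_b = np.cov(m_ib @ Cb.T, rowvar=False).reshape(b - 1, b - 1)
    add_effect(factor_names[1], ss_b, ss_eb, b - 1, (b - 1) * (n - 1),
               1.0 if b == 2 else _gg_epsilon(cov_b, b))

    # interaction
    inter = data - m_ia[:, :, None] - m_ib[:, None, :] + m_i[:, None, None]
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_eab = np.sum((inter - inter.mean(axis=0, keepdims=True)) ** 2)
    Cab = np.kron(Ca, Cb)
    scores = data.reshape(n, a * b) @ Cab.T
    cov_ab = np.cov(scores, rowvar=False).reshape((a - 1) * (b - 1), (a - 1) * (b - 1))
    add_effect("x".join(factor_names), ss_ab, ss_eab, (a - 1) * (b - 1),
               (a - 1) * (b - 1) * (n - 1), _gg_epsilon(cov_ab, (a - 1) * (b - 1) + 1))

    return RmAnovaResult(effects=pd.DataFrame(rows).T)


# ---------------------------------------------------------------------------
# model / results front-end

class TractAssociationModel:
    """Segment-wise association between tract profiles and a behavioral measure.

    Parameters
    ----------
    profiles : TractProfile
        participants x segments x metrics weighted means.
    regressor : array-like
        Behavioral variable per participant (e.g. non-decision time, ms).
    age : array-like
        Nuisance covariate (years).
    """

    def __init__(self, profiles: TractProfile, regressor, age,
                 regressor_name: str = "t_er_ms"):
        self.profiles = profiles
        self.design = DesignMatrix(np.asarray(regressor, float), np.asarray(age, float),
                                   regressor_name)
        if profiles.values.shape[0] != self.design.n:
            raise ValueError("profiles and behavioral vectors disagree on n")

    def fit(self, n_perm: int = 10_000, seed=None, E: float = TFCE_E, H: float = TFCE_H,
            dh: float | None = None) -> "TractAssociationResults":
        res = permutation_fwe(self.profiles, self.design, n_perm=n_perm, seed=seed,
                              E=E, H=H, dh=dh)
        return TractAssociationResults(self, res)


@dataclass
class TractAssociationResults:
    model: TractAssociationModel
    tfce_result: TFCEResult

    @property
    def p_fwe(self) -> np.ndarray:
        return self.tfce_result.p_fwe

    @property
    def beta_std(self) -> np.ndarray:
        return self.tfce_result.beta_std

    def significant_segments(self, metric: str, alpha: float = 0.05) -> np.ndarray:
        """1-based indices of segments significant after FWE correction."""
        m = self.tfce_result.metrics.index(metric)
        p = self.tfce_result.p_fwe[:, m]
        return np.flatnonzero(~np.isnan(p) & (p < alpha)) + 1

    def to_dataframe(self) -> pd.DataFrame:
        res = self.tfce_result
        rows = []
        for m, name in enumerate(res.metrics):
            for s in range(res.beta_std.shape[0]):
                rows.append(
                    {
                        "segment": s + 1,
                        "metric": name,
                        "beta_std": res.beta_std[s, m],
                        "t": res.t_stat[s, m],
                        "tfce": res.tfce[s, m],
                        "p_fwe": res.p_fwe[s, m],
                        "significant": bool(res.p_fwe[s, m] < 0.05)
                        if not np.isnan(res.p_fwe[s, m]) else False,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        res = self.tfce_result
        lines = [
            f"Along-tract association: {self.model.design.regressor_name} "
            f"(age-adjusted GLM, {res.n_perm} permutations)",
            "=" * 66,
            f"{'metric':>6} {'sig. segments (p_fwe < 0.05)':>35}   min p_fwe",
        ]
        for m, name in enumerate(res.metrics):
            sig = self.significant_segments(name)
            p = res.p_fwe[:, m]
            pmin = np.nanmin(p) if np.any(~np.isnan(p)) else np.nan
            seg_txt = _format_runs(sig) if sig.size else "none"
            lines.append(f"{name:>6} {seg_txt:>35}   {pmin:.4f}")
        return "\n".join(lines)


def _format_runs(idx: np.ndarray) -> str:
    """Collapse sorted 1-based indices into 'a-b, c' run notation."""
    if idx.size == 0:
        return "none"
    runs = []
    start = prev = idx[0]
    for v in idx[1:]:
        if v == prev + 1:
            prev = v
            continue
        runs.append(f"{start}-{prev}" if prev > start else f"{start}")
        start = prev = v
    runs.append(f"{start}-{prev}" if prev > start else f"{start}")
    return ", ".join(runs)
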