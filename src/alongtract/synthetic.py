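"""Synthetic cohorts with known ground truth for every pipeline stage.

Three generator families:

* **Tube phantoms** — tract probability volumes built around a known
  parametric 3-D curve (line, arc or helix), with voxel value
  ``exp(-d^2 / 2w^2)`` for distance ``d`` to the curve, emulating a
  thresholded probabilistic-tractography output whose ridge coincides
  with the true curve.
* **Metric maps** — NDI/ODI/FA/MD volumes whose values follow smooth
  baseline profiles of arc length plus participant-level offsets and
  voxel noise; a negative association between the behavioral covariate
  (non-decision time) and NDI is planted in a specified range of
  along-tract segments, with the effect coefficient chosen so the
  planted standardized slope equals ``effect_beta_std`` at the segment
  level.  Other metrics receive no effect, making specificity testable.
* **RT cohorts** — per-participant reaction times simulated from the
  single-accumulator model with known parameters, at the study's scale
  (46 participants, 50 trials, non-decision time 250 +/- 48 ms).

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .lba import LBAParams, RTSample, exclude_rts, simulate_lba
from .segments import METRIC_NAMES, TractProfile
from .skeleton import TRACT_PROB_THRESHOLD, TractVolume

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "make_curve",
    "make_phantom",
    "make_metric_maps",
    "make_rt_cohort",
    "make_profile_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a tube-like tract phantom on a regular grid."""

    curve: str = "arc"  # line | arc | helix
    tube_radius_mm: float = 8.0
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 2.0
    prob_decay_mm: float = 3.0  # Gaussian width of tract probability around the curve
    noise_sd: float = 0.0  # multiplicative probability noise

    def __post_init__(self) -> None:
        if self.tube_radius_mm < 3 * self.voxel_size_mm:
            raise ValueError("tube radius must be >= 3 voxels for reliable skeletons")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults mirror the study design this pipeline emulates: 46
    participants aged 19-24, 50 simple-RT trials each, non-decision
    time 250 +/- 48 ms, and a negative NDI association of standardized
    size -0.5 planted in segments 18-30 of a 30-segment tract.
    """

    n_participants: int = 46
    age_range: tuple[float, float] = (19.0, 24.0)
    ter_mean_ms: float = 250.0
    ter_sd_ms: float = 48.0
    n_trials: int = 50
    effect_segments: tuple[int, ...] = tuple(range(18, 31))  # 1-based
    effect_beta_std: float = -0.5
    n_segments: int = 30
    overlap: float = 0.2
    noise_sd: dict = field(default_factory=lambda: {
        "NDI": 0.03, "ODI": 0.03, "FA": 0.04, "MD": 0.03e-3})
    voxel_noise_sd: dict = field(default_factory=lambda: {
        "NDI": 0.01, "ODI": 0.01, "FA": 0.015, "MD": 0.01e-3})
    affine_rot_deg: float = 3.0
    affine_trans_mm: float = 2.0
    # accumulator parameter ranges at the study's RT scale (mean RT ~365 ms)
    b_range: tuple[float, float] = (0.9, 1.4)
    mu_range: tuple[float, float] = (5.5, 8.5)
    sigma_range: tuple[float, float] = (0.8, 2.0)
    a: float = 0.5  # start-point range (the fixed scaling constant)


# smooth baseline profiles of normalized arc position u in [0, 1];
# FA stays well above the 0.2 inclusion gate inside the tube
_BASELINES = {
    "NDI": lambda u: 0.55 + 0.05 * np.cos(2 * np.pi * u),
    "ODI": lambda u: 0.30 + 0.10 * u,
    "FA": lambda u: 0.55 - 0.10 * u,
    "MD": lambda u: 0.80e-3 + 0.10e-3 * u,
}


def make_curve(kind: str, extent_mm: float, n_points: int = 2000) -> np.ndarray:
    """Densely sampled parametric curve fitting inside a cube of side ``extent_mm``."""
    t = np.linspace(0.0, 1.0, n_points)
    # generic sub-voxel offset: a curve lying exactly on an inter-voxel
    # symmetry plane is a measure-zero configuration real data never hits
    c = extent_mm / 2.0 + 0.37 * extent_mm / 100.0
    m = 0.2 * extent_mm
    if kind == "line":
        # oblique to the grid: an axis-aligned line is a degenerate
        # configuration whose voxel projections all quantize to the same
        # arc positions
        span = extent_mm - 2 * m
        pts = np.stack([m + t * span, c - 0.09 * span + 0.18 * t * span,
                        c - 0.055 * span + 0.11 * t * span], axis=1)
    elif kind == "arc":
        r = 0.3 * extent_mm
        ang = t * (np.pi / 2)
        pts = np.stack([c - r * 0.5 + r * np.cos(ang), m + r * np.sin(ang),
                        np.full_like(t, c)], axis=1)
    elif kind == "helix":
        r = 0.15 * extent_mm
        ang = t * (1.5 * np.pi)
        pts = np.stack([c + r * np.cos(ang), c + r * np.sin(ang),
                        m + t * (extent_mm - 2 * m)], axis=1)
    else:
        raise ValueError(f"unknown curve kind {kind!r}")
    return pts


def _curve_geometry(spec: PhantomSpec):
    extent = spec.voxel_size_mm * (min(spec.grid_shape) - 1)
    curve = make_curve(spec.curve, extent)
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    arclen = np.concatenate(([0.0], np.cumsum(seg)))
    return curve, arclen


def _voxel_centers(spec: PhantomSpec) -> np.ndarray:
    idx = np.indices(spec.grid_shape).reshape(3, -1).T
    return idx * spec.voxel_size_mm


def make_phantom(spec: PhantomSpec, seed=None):
    """Tube phantom: returns (TractVolume, true curve points, curve arc lengths).

    Voxel value is ``exp(-d^2/2w^2)`` (optionally with multiplicative
    noise), zeroed below the tractography threshold 5e-5.
    """
    curve, arclen = _curve_geometry(spec)
    centers = _voxel_centers(spec)
    d, _ = cKDTree(curve).query(centers)
    prob = np.exp(-(d**2) / (2 * spec.prob_decay_mm**2))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        prob *= np.clip(1.0 + spec.noise_sd * rng.standard_normal(prob.shape), 0.0, None)
    prob[prob < TRACT_PROB_THRESHOLD] = 0.0
    vol = TractVolume(prob.reshape(spec.grid_shape), spec.affine,
                      threshold=TRACT_PROB_THRESHOLD)
    return vol, curve, arclen


def _segment_intervals(total: float, n: int, overlap: float) -> np.ndarray:
    length = total / (1.0 + (n - 1) * (1.0 - overlap))
    starts = np.arange(n) * (1.0 - overlap) * length
    return np.stack([starts, starts + length], axis=1)


def effect_coefficient(beta_std: float, participant_sd: float) -> float:
    """Slope on z-scored behavior giving standardized effect ``beta_std``.

    At the segment level voxel noise averages out, so the population
    correlation between behavior and segment value is
    ``c / sqrt(c^2 + sd^2)``; inverting gives
    ``c = sign(beta) * sd * |beta| / sqrt(1 - beta^2)``.
    """
    if not -1 < beta_std < 1:
        raise ValueError("beta_std must be in (-1, 1)")
    return participant_sd * beta_std / np.sqrt(1.0 - beta_std**2)


def _participant_jitter(cohort: CohortSpec, rng) -> np.ndarray:
    """Small rigid world transform (native world -> template world)."""
    ang = np.deg2rad(rng.uniform(-cohort.affine_rot_deg, cohort.affine_rot_deg, 3))
    cx, cy, cz = np.cos(ang)
    sx, sy, sz = np.sin(ang)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    out = np.eye(4)
    out[:3, :3] = rz @ ry @ rx
    out[:3, 3] = rng.uniform(-cohort.affine_trans_mm, cohort.affine_trans_mm, 3)
    return out


def make_metric_maps(phantom_spec: PhantomSpec, cohort: CohortSpec, participant: int,
                     z_ter: float, seed=None, jitter: np.ndarray | None = None) -> dict:
    """Native-space NDI/ODI/FA/MD volumes + WM mask + tract probability for one participant.

    ``z_ter`` is the participant's z-scored true non-decision time; the
    planted effect enters NDI only, in the configured segments.  The
    native frame differs from the template frame by the rigid
    ``jitter`` transform (drawn from the cohort bounds when omitted);
    maps are evaluated exactly on the native grid (no resampling).
    """
    if participant >= cohort.n_participants:
        raise ValueError("participant index out of range")
    rng = np.random.default_rng(seed)
    if jitter is None:
        jitter = _participant_jitter(cohort, rng)
    curve, arclen = _curve_geometry(phantom_spec)
    total = arclen[-1]
    intervals = _segment_intervals(total, cohort.n_segments, cohort.overlap)
    effect_lo = min(intervals[s - 1, 0] for s in cohort.effect_segments)
    effect_hi = max(intervals[s - 1, 1] for s in cohort.effect_segments)

    centers_native = _voxel_centers(phantom_spec)
    # native world -> template world, where the phantom anatomy lives
    centers_tpl = centers_native @ jitter[:3, :3].T + jitter[:3, 3]
    d, nearest = cKDTree(curve).query(centers_tpl)
    s_pos = arclen[nearest]
    u = s_pos / total
    inside = d <= phantom_spec.tube_radius_mm

    shape = phantom_spec.grid_shape
    out = {"wm_mask": inside.reshape(shape).astype(np.uint8)}
    prob = np.exp(-(d**2) / (2 * phantom_spec.prob_decay_mm**2))
    prob[prob < TRACT_PROB_THRESHOLD] = 0.0
    out["tract_prob"] = prob.reshape(shape)
    for name in METRIC_NAMES:
        vals = _BASELINES[name](u)
        vals = vals + rng.normal(0.0, cohort.noise_sd[name])  # participant offset
        vals = vals + rng.normal(0.0, cohort.voxel_noise_sd[name], vals.shape)
        if name == "NDI":
            c = effect_coefficient(cohort.effect_beta_std, cohort.noise_sd["NDI"])
            in_effect = (s_pos >= effect_lo) & (s_pos <= effect_hi)
            vals = vals + c * z_ter * in_effect
        vals = np.where(inside, vals, 0.0)
        if name in ("NDI", "ODI", "FA"):
            vals = np.clip(vals, 0.0, 1.0)
        else:
            vals = np.clip(vals, 1e-6, None)
        out[name] = vals.reshape(shape)
    out["native_to_template"] = jitter
    out["affine"] = phantom_spec.affine
    return out


def make_rt_cohort(cohort: CohortSpec, seed=None):
    """Simulated per-participant RT samples with known accumulator parameters.

    Returns ``(samples, truth)`` where ``samples`` is a list of
    :class:`RTSample` (after the 150-1500 ms exclusion) and ``truth`` a
    DataFrame of the generating parameters, ages and mean RTs.
    """
    rng = np.random.default_rng(seed)
    samples: list[RTSample] = []
    rows = []
    for i in range(cohort.n_participants):
        t_er = max(rng.normal(cohort.ter_mean_ms, cohort.ter_sd_ms) / 1000.0, 0.06)
        params = LBAParams(
            t_er=t_er,
            b=rng.uniform(*cohort.b_range),
            mu=rng.uniform(*cohort.mu_range),
            sigma=rng.uniform(*cohort.sigma_range),
            a=cohort.a,
        )
        rts_ms = simulate_lba(params, cohort.n_trials, rng) * 1000.0
        sample = exclude_rts(rts_ms)
        samples.append(sample)
        rows.append(
            {
                "participant": f"sub-{i:03d}",
                "t_er_ms": params.t_er * 1000.0,
                "b": params.b,
                "mu": params.mu,
                "sigma": params.sigma,
                "age": rng.uniform(*cohort.age_range),
                "mean_rt_ms": float(np.mean(sample.rts_ms)),
                "n_trials": sample.n,
            }
        )
    return samples, pd.DataFrame(rows)


def make_profile_cohort(cohort: CohortSpec, seed=None, planted: bool = True):
    """Segment-level profile cohort without the imaging chain.

    Draws participant behavior (z-scored non-decision time and age) and
    builds the participants x segments x metrics table directly from
    the baseline profiles, participant-level noise and (optionally) the
    planted NDI effect — the fast route for calibrating the statistics
    stage.  Returns ``(TractProfile, behavior DataFrame)``.
    """
    rng = np.random.default_rng(seed)
    n, n_seg = cohort.n_participants, cohort.n_segments
    z_ter = rng.standard_normal(n)
    ages = rng.uniform(*cohort.age_range, n)
    u = (np.arange(n_seg) + 0.5) / n_seg
    values = np.empty((n, n_seg, len(METRIC_NAMES)))
    for m, name in enumerate(METRIC_NAMES):
        base = _BASELINES[name](u)
        noise = rng.normal(0.0, cohort.noise_sd[name], (n, n_seg))
        values[:, :, m] = base[None, :] + noise
        if planted and name == "NDI" and cohort.effect_beta_std != 0:
            c = effect_coefficient(cohort.effect_beta_std, cohort.noise_sd["NDI"])
            mask = np.zeros(n_seg)
            mask[[s - 1 for s in cohort.effect_segments]] = 1.0
            values[:, :, m] += c * z_ter[:, None] * mask[None, :]
    profile = TractProfile(values=values, n_voxels=np.full((n, n_seg), 100),
                           metrics=METRIC_NAMES,
                           participants=[f"sub-{i:03d}" for i in range(n)])
    behavior = pd.DataFrame(
        {
            "participant": profile.participants,
            "t_er_ms": cohort.ter_mean_ms + cohort.ter_sd_ms * z_ter,
            "z_ter": z_ter,
            "age": ages,
        }
    )
    return profile, behavior
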