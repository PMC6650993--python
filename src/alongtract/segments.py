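"""Along-tract segmentation and connection-probability-weighted metric profiles.

The clipped skeleton is divided into ``n`` equal-length segments with a
fixed fractional overlap between neighbors (defaults 30 segments, 20 %
overlap): with clipped arc length ``S`` the segment length is

    l = S / (1 + (n - 1) * (1 - overlap))

and segment ``i`` spans ``[i*(1-overlap)*l, i*(1-overlap)*l + l]``.
Every suprathreshold tract voxel is assigned to the segment(s) whose
interval contains the arc-length position of its nearest point on the
skeleton curve (voxels in overlap zones carry two labels).  Segment
sub-volumes are mapped to each participant's native space by
nearest-neighbor resampling, filtered by the voxel-inclusion rules
(white-matter mask, FA > 0.2 strictly, tract probability >= 5e-5), and
summarized per metric as the connection-probability-weighted mean

    M_w = sum_v P(v) m(v) / sum_v P(v).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .skeleton import Skeleton, TractVolume, TRACT_PROB_THRESHOLD

__all__ = [
    "SegmentSet",
    "VoxelInclusionMask",
    "TractProfile",
    "divide_segments",
    "assign_voxels",
    "to_native",
    "include_voxels",
    "weighted_metric",
    "build_profiles",
]

METRIC_NAMES = ("NDI", "ODI", "FA", "MD")
FA_THRESHOLD = 0.2


@dataclass
class SegmentSet:
    """Equal-length overlapping arc-length intervals plus voxel memberships."""

    n_segments: int
    overlap: float
    intervals: np.ndarray  # (n, 2) start/end in mm along the clipped skeleton
    labels: dict[int, np.ndarray] = field(default_factory=dict)  # seg id -> bool mask

    @property
    def segment_length(self) -> float:
        return float(self.intervals[0, 1] - self.intervals[0, 0])


@dataclass
class VoxelInclusionMask:
    """Per-participant native-space gates for voxel inclusion."""

    wm_mask: np.ndarray
    fa_map: np.ndarray
    tract_prob: np.ndarray
    fa_thresh: float = FA_THRESHOLD
    prob_thresh: float = TRACT_PROB_THRESHOLD

    def __post_init__(self) -> None:
        shapes = {self.wm_mask.shape, self.fa_map.shape, self.tract_prob.shape}
        if len(shapes) != 1:
            raise ValueError(f"inclusion volumes disagree on grid shape: {shapes}")

    def gate(self) -> np.ndarray:
        """Voxels passing all three rules (FA strictly above, probability at-or-above)."""
        return (
            (self.wm_mask > 0)
            & (self.fa_map > self.fa_thresh)
            & (self.tract_prob >= self.prob_thresh)
        )


@dataclass
class TractProfile:
    """participants x segments x metrics table of weighted means."""

    values: np.ndarray
    n_voxels: np.ndarray
    metrics: tuple[str, ...] = METRIC_NAMES
    participants: list[str] | None = None

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_segments(self) -> int:
        return self.values.shape[1]

    def metric_matrix(self, metric: str) -> np.ndarray:
        return self.values[:, :, self.metrics.index(metric)]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        pids = self.participants or [f"sub-{i:03d}" for i in range(self.n_participants)]
        for i, pid in enumerate(pids):
            for s in range(self.n_segments):
                for m, name in enumerate(self.metrics):
                    v = self.values[i, s, m]
                    rows.append(
                        {
                            "participant": pid,
                            "segment": s + 1,
                            "metric": name,
                            "value": v,
                            "n_voxels": int(self.n_voxels[i, s]),
                            "flag": "missing" if np.isnan(v) else "ok",
                        }
                    )
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TractProfile":
        pids = list(pd.unique(df["participant"]))
        metrics = tuple(pd.unique(df["metric"]))
        segs = np.sort(pd.unique(df["segment"]))
        values = np.full((len(pids), len(segs), len(metrics)), np.nan)
        n_vox = np.zeros((len(pids), len(segs)), dtype=int)
        pidx = {p: i for i, p in enumerate(pids)}
        midx = {m: i for i, m in enumerate(metrics)}
        sidx = {s: i for i, s in enumerate(segs)}
        for row in df.itertuples(index=False):
            i, s, m = pidx[row.participant], sidx[row.segment], midx[row.metric]
            values[i, s, m] = row.value
            n_vox[i, s] = row.n_voxels
        return cls(values=values, n_voxels=n_vox, metrics=metrics, participants=pids)


def divide_segments(skel: Skeleton, n: int = 30, overlap: float = 0.2) -> SegmentSet:
    """Divide the clipped skeleton into ``n`` equal-length overlapping intervals."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    total = skel.arc_length
    if total <= 0:
        raise ValueError("skeleton has non-positive arc length")
    length = total / (1.0 + (n - 1) * (1.0 - overlap))
    stride = (1.0 - overlap) * length
    starts = np.arange(n) * stride
    intervals = np.stack([starts, starts + length], axis=1)
    return SegmentSet(n_segments=n, overlap=overlap, intervals=intervals)


def assign_voxels(vol: TractVolume, skel: Skeleton, segs: SegmentSet) -> SegmentSet:
    """Assign each suprathreshold voxel to the segment(s) containing its
    nearest-curve-point arc length (Euclidean distance in world mm).

    Returns a new :class:`SegmentSet` with per-segment boolean masks on
    the template grid; a voxel in an overlap zone appears in both masks.
    """
    fg = vol.binarize()
    coords = np.argwhere(fg)
    world = vol.voxels_to_world(coords)
    tree = cKDTree(skel.curve)
    _, nearest = tree.query(world)
    s_pos = skel.arclengths[nearest]
    labels: dict[int, np.ndarray] = {}
    for i, (lo, hi) in enumerate(segs.intervals):
        inside = (s_pos >= lo - 1e-9) & (s_pos <= hi + 1e-9)
        mask = np.zeros(vol.data.shape, dtype=bool)
        mask[tuple(coords[inside].T)] = True
        labels[i] = mask
    return SegmentSet(n_segments=segs.n_segments, overlap=segs.overlap,
                      intervals=segs.intervals, labels=labels)


def to_native(segs: SegmentSet, template_affine: np.ndarray, native_affine: np.ndarray,
              native_shape: tuple[int, int, int],
              world_native_to_template: np.ndarray | None = None) -> SegmentSet:
    """Nearest-neighbor resample segment sub-volumes onto a native grid.

    ``world_native_to_template`` is the participant's affine mapping
    native world mm to template world mm (identity if omitted).  Raises
    if every segment lands fully outside the native grid.
    """
    if not segs.labels:
        raise ValueError("segment set carries no voxel labels; run assign_voxels first")
    tpl_inv = np.linalg.inv(np.asarray(template_affine, dtype=float))
    n2t = np.eye(4) if world_native_to_template is None else np.asarray(world_native_to_template, float)
    chain = tpl_inv @ n2t @ np.asarray(native_affine, dtype=float)  # native idx -> template idx
    idx = np.indices(native_shape).reshape(3, -1).T.astype(float)
    tpl_idx = idx @ chain[:3, :3].T + chain[:3, 3]
    coords = tpl_idx.T  # for map_coordinates
    out: dict[int, np.ndarray] = {}
    any_inside = False
    for seg_id, mask in segs.labels.items():
        resampled = ndimage.map_coordinates(mask.astype(np.uint8), coords, order=0,
                                            mode="constant", cval=0)
        native_mask = resampled.reshape(native_shape).astype(bool)
        any_inside = any_inside or native_mask.any()
        out[seg_id] = native_mask
    if not any_inside and any(m.any() for m in segs.labels.values()):
        raise ValueError("affine maps all segment labels outside the native grid")
    return SegmentSet(n_segments=segs.n_segments, overlap=segs.overlap,
                      intervals=segs.intervals, labels=out)


def include_voxels(mask: VoxelInclusionMask, segs: SegmentSet) -> SegmentSet:
    """Intersect native segment labels with the three inclusion rules."""
    gate = mask.gate()
    out = {seg_id: m & gate for seg_id, m in segs.labels.items()}
    return SegmentSet(n_segments=segs.n_segments, overlap=segs.overlap,
                      intervals=segs.intervals, labels=out)


def weighted_metric(metric_map: np.ndarray, tract_prob: np.ndarray,
                    voxels: np.ndarray) -> float:
    """Connection-probability-weighted mean of a metric over a voxel mask.

    Returns NaN (the missing-value sentinel) for an empty mask or zero
    total weight.
    """
    if not voxels.any():
        return float("nan")
    w = tract_prob[voxels]
    if np.any(w < 0):
        raise ValueError("negative connection probabilities")
    total = w.sum()
    if total == 0:
        return float("nan")
    return float(np.sum(w * metric_map[voxels]) / total)


def build_profiles(participant_data: list[dict], metrics=METRIC_NAMES,
                   missing_warn_fraction: float = 0.5) -> TractProfile:
    """Assemble the participants x segments x metrics profile table.

    Each element of ``participant_data`` is a dict with keys
    ``segments`` (a native-space, inclusion-filtered :class:`SegmentSet`),
    ``tract_prob`` (native probability volume used as weights), one
    volume per metric name, and optionally ``id``.
    """
    if not participant_data:
        raise ValueError("no participants")
    n_seg = participant_data[0]["segments"].n_segments
    values = np.full((len(participant_data), n_seg, len(metrics)), np.nan)
    n_vox = np.zeros((len(participant_data), n_seg), dtype=int)
    pids = []
    for i, part in enumerate(participant_data):
        pids.append(str(part.get("id", f"sub-{i:03d}")))
        segs: SegmentSet = part["segments"]
        prob = part["tract_prob"]
        for s in range(n_seg):
            vox = segs.labels[s]
            n_vox[i, s] = int(vox.sum())
            for m, name in enumerate(metrics):
                values[i, s, m] = weighted_metric(part[name], prob, vox)
        missing = np.isnan(values[i, :, 0]).mean()
        if missing > missing_warn_fraction:
            import warnings

            warnings.warn(
                f"participant {pids[-1]}: {missing:.0%} of segments have no "
                "included voxels; participant retained",
                stacklevel=2,
            )
    return TractProfile(values=values, n_voxels=n_vox, metrics=tuple(metrics),
                        participants=pids)
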