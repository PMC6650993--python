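"""End-to-end orchestration: behavior fits, skeleton, profiles, statistics.

``run_pipeline`` sequences the full analysis on a cohort manifest:

1. fit the accumulator model to each participant's RTs (non-decision
   time and mean RT become the behavioral regressors);
2. build the group tract image (union of thresholded native
   tractography maps in template space) and skeletonize it;
3. divide the skeleton into overlapping segments, assign tract voxels,
   map segment sub-volumes to each native space, apply the inclusion
   rules and compute connection-probability-weighted metric profiles;
4. run the segment-wise GLM + TFCE permutation statistics per
   behavioral regressor.

All randomness derives from one master seed through named substreams,
so a rerun with identical inputs is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import __version__
from .config import RunConfig
from .io import (CohortManifest, read_affine, read_rt_csv, read_volume,
                 write_affine, write_json, write_volume)
from .lba import LBAModel
from .segments import (METRIC_NAMES, VoxelInclusionMask, assign_voxels,
                       build_profiles, divide_segments, include_voxels, to_native)
from .skeleton import Skeleton, TractVolume, skeletonize_tract
from .stats import TractAssociationModel, pearson_report
from .synthetic import CohortSpec, PhantomSpec, make_metric_maps, make_rt_cohort

__all__ = ["run_pipeline", "write_synthetic_cohort", "fit_cohort_lba", "group_tract_image"]

# substream tags hung off the master seed
_SUB_LBA, _SUB_PERM, _SUB_SYNTH = 1, 2, 3


def fit_cohort_lba(manifest: CohortManifest, config: RunConfig) -> pd.DataFrame:
    """Fit the accumulator model per participant; returns the behavioral table."""
    rows = []
    for i, pid in enumerate(manifest.participants):
        rts = read_rt_csv(manifest.path(pid, "rt_file"))
        model = LBAModel(rts, rt_bounds_ms=config.rt_bounds_ms)
        res = model.fit(n_init_candidates=config.n_init, n_repeats=config.n_repeats,
                        n_sim=config.n_sim, seed=[config.seed, _SUB_LBA, i])
        rows.append({"participant": pid, "t_er_ms": res.t_er_ms,
                     "mean_rt_ms": float(np.mean(model.sample.rts_ms)),
                     "b": res.params.b, "mu": res.params.mu, "sigma": res.params.sigma,
                     "gsq": res.gsq, "n_trials": model.sample.n})
    return pd.DataFrame(rows)


def _native_to_template_mask(native_vol: TractVolume, n2t: np.ndarray,
                             template_affine: np.ndarray, template_shape) -> np.ndarray:
    """Nearest-neighbor resampling of a thresholded native mask onto the template grid."""
    chain = (np.linalg.inv(native_vol.affine) @ np.linalg.inv(n2t) @ template_affine)
    idx = np.indices(template_shape).reshape(3, -1).astype(float)
    native_idx = chain[:3, :3] @ idx + chain[:3, 3:4]
    mask = native_vol.binarize().astype(np.uint8)
    res = ndimage.map_coordinates(mask, native_idx, order=0, mode="constant", cval=0)
    return res.reshape(template_shape).astype(bool)


def group_tract_image(manifest: CohortManifest, config: RunConfig,
                      template_affine: np.ndarray | None = None,
                      template_shape=None) -> TractVolume:
    """Proportion-of-overlap group tract image on the template grid.

    The template grid defaults to the first participant's grid (their
    affine file then maps each native frame into it).
    """
    pids = manifest.participants
    first = read_volume(manifest.path(pids[0], "tract_prob"), threshold=config.prob_thresh)
    if template_affine is None:
        template_affine = first.affine
        template_shape = first.data.shape
    acc = np.zeros(template_shape, dtype=float)
    for pid in pids:
        vol = read_volume(manifest.path(pid, "tract_prob"), threshold=config.prob_thresh)
        n2t = read_affine(manifest.path(pid, "affine"))
        acc += _native_to_template_mask(vol, n2t, template_affine, template_shape)
    acc /= len(pids)
    # union of participants' binarized tracts: any overlap proportion > 0
    return TractVolume(acc, template_affine, threshold=np.nextafter(0, 1))


def _profiles_for_cohort(manifest: CohortManifest, config: RunConfig,
                         skel: Skeleton, group_vol: TractVolume):
    segs = divide_segments(skel, n=config.n_segments, overlap=config.overlap)
    segs = assign_voxels(group_vol, skel, segs)
    participant_data = []
    for pid in manifest.participants:
        n2t = read_affine(manifest.path(pid, "affine"))
        prob = read_volume(manifest.path(pid, "tract_prob"))
        native = to_native(segs, group_vol.affine, prob.affine, prob.data.shape,
                           world_native_to_template=n2t)
        mask = VoxelInclusionMask(
            wm_mask=read_volume(manifest.path(pid, "wm_mask")).data,
            fa_map=read_volume(manifest.path(pid, "FA")).data,
            tract_prob=prob.data,
            fa_thresh=config.fa_thresh,
            prob_thresh=config.prob_thresh,
        )
        native = include_voxels(mask, native)
        entry = {"id": pid, "segments": native, "tract_prob": prob.data}
        for name in METRIC_NAMES:
            entry[name] = read_volume(manifest.path(pid, name)).data
        participant_data.append(entry)
    return build_profiles(participant_data), segs


def run_pipeline(manifest: CohortManifest, config: RunConfig, out_dir,
                 regressors=("t_er_ms", "mean_rt_ms")) -> dict:
    """Execute the full analysis; writes artifacts and returns the result bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    behavior = fit_cohort_lba(manifest, config)
    behavior = behavior.merge(manifest.table[["participant", "age"]], on="participant")
    behavior.to_csv(out / "behavior.csv", index=False)

    group_vol = group_tract_image(manifest, config)
    skel = skeletonize_tract(group_vol, kernel_radius_mm=config.dilate_mm,
                             clip_fractions=config.clip_fractions,
                             n_samples=config.skeleton_samples)
    pd.DataFrame(
        np.column_stack([skel.curve, skel.arclengths]),
        columns=["x_mm", "y_mm", "z_mm", "arclength_mm"],
    ).to_csv(out / "skeleton.csv", index=False)

    profiles, segs = _profiles_for_cohort(manifest, config, skel, group_vol)
    profiles.to_dataframe().to_csv(out / "profiles.csv", index=False)

    results = {}
    for k, reg in enumerate(regressors):
        model = TractAssociationModel(profiles, behavior[reg].to_numpy(),
                                      behavior["age"].to_numpy(), regressor_name=reg)
        fit = model.fit(n_perm=config.n_perm, seed=np.random.SeedSequence(
            [config.seed, _SUB_PERM, k]).generate_state(1)[0] % (2**31))
        fit.to_dataframe().to_csv(out / f"stats_{reg}.csv", index=False)
        results[reg] = fit

    corr = pearson_report(behavior["mean_rt_ms"], behavior["t_er_ms"])
    correlations = {
        "mean_rt_vs_t_er": {"r": corr.r, "p": corr.p, "ci95": list(corr.ci95),
                            "bf10": corr.bf10},
    }
    config_json = json.dumps(config.to_dict(), sort_keys=True)
    provenance = {
        "version": __version__,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "n_participants": len(manifest.participants),
        "correlations": correlations,
    }
    write_json(provenance, out / "provenance.json")
    return {"behavior": behavior, "skeleton": skel, "profiles": profiles,
            "stats": results, "provenance": provenance}


def write_synthetic_cohort(out_dir, phantom_spec: PhantomSpec | None = None,
                           cohort: CohortSpec | None = None, seed: int = 0) -> Path:
    """Generate and write a complete synthetic cohort dataset.

    Produces per-participant NIfTI volumes (tract probability, NDI,
    ODI, FA, MD, white-matter mask), native-to-template affine text
    files, RT CSVs, a manifest TSV and a ground-truth JSON.  Returns
    the manifest path.
    """
    phantom_spec = phantom_spec or PhantomSpec()
    cohort = cohort or CohortSpec()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence([seed, _SUB_SYNTH])
    rt_seed, map_seed = master.spawn(2)
    samples, truth = make_rt_cohort(cohort, seed=rt_seed)
    z = (truth["t_er_ms"] - truth["t_er_ms"].mean()) / truth["t_er_ms"].std(ddof=0)
    rows = []
    map_streams = map_seed.spawn(cohort.n_participants)
    for i, pid in enumerate(truth["participant"]):
        pdir = out / pid
        pdir.mkdir(exist_ok=True)
        maps = make_metric_maps(phantom_spec, cohort, i, float(z.iloc[i]),
                                seed=map_streams[i])
        affine = maps["affine"]
        for key, fname in [("tract_prob", "tract_prob.nii.gz"), ("NDI", "ndi.nii.gz"),
                           ("ODI", "odi.nii.gz"), ("FA", "fa.nii.gz"),
                           ("MD", "md.nii.gz"), ("wm_mask", "wm_mask.nii.gz")]:
            write_volume(maps[key], pdir / fname, affine)
        write_affine(maps["native_to_template"], pdir / "native_to_template.txt")
        pd.DataFrame({"rt_ms": samples[i].rts_ms}).to_csv(pdir / "rt.csv", index=False)
        rows.append({
            "participant": pid, "age": truth["age"].iloc[i],
            "tract_prob": f"{pid}/tract_prob.nii.gz", "NDI": f"{pid}/ndi.nii.gz",
            "ODI": f"{pid}/odi.nii.gz", "FA": f"{pid}/fa.nii.gz",
            "MD": f"{pid}/md.nii.gz", "wm_mask": f"{pid}/wm_mask.nii.gz",
            "affine": f"{pid}/native_to_template.txt", "rt_file": f"{pid}/rt.csv",
        })
    manifest_path = out / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)
    truth.to_json(out / "ground_truth.json", orient="records", indent=2)
    return manifest_path
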