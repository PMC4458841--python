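"""Reading and writing the standard on-disk formats.

Volumes go through NIfTI-1 (nibabel) with an affine built from the isotropic
voxel size; tables (motion, events, cluster tables, profiles) are TSV via
pandas; metadata travels in JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import AtlasSpec, LabeledAtlas
from .cohort import SubjectDataset, TaskSpec
from .connectivity import FisherZMap
from .group_maps import ClusterTable


def _affine(voxel_size: float) -> np.ndarray:
    return np.diag([voxel_size, voxel_size, voxel_size, 1.0])


def save_nifti(path, data: np.ndarray, voxel_size: float) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), _affine(voxel_size)), str(path))


def load_nifti(path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), float(abs(img.affine[0, 0]))


def save_atlas(path, atlas: LabeledAtlas) -> None:
    save_nifti(path, atlas.labels.astype(np.int16), atlas.voxel_size)


def load_atlas(path, bilateral: bool = False) -> LabeledAtlas:
    labels, voxel = load_nifti(path)
    labels = labels.astype(np.int16)
    spec = AtlasSpec(grid_shape=tuple(labels.shape), voxel_size=voxel,
                     bilateral=bilateral)
    return LabeledAtlas(labels, voxel, spec)


def save_motion(path, motion: np.ndarray) -> None:
    cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    pd.DataFrame(motion, columns=cols).to_csv(path, sep="\t", index=False)


def load_motion(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)


def save_events(path, task: TaskSpec) -> None:
    rows = [dict(onset=o, duration=d, trial_type=c) for o, d, c in task.events]
    pd.DataFrame(rows, columns=["onset", "duration", "trial_type"]).to_csv(
        path, sep="\t", index=False)


def load_events(path, amplitudes: dict | None = None) -> TaskSpec:
    df = pd.read_csv(path, sep="\t")
    events = tuple((float(r.onset), float(r.duration), str(r.trial_type))
                   for r in df.itertuples())
    conds = {c for _, _, c in events}
    return TaskSpec(events, amplitudes or {c: 1.0 for c in conds})


def save_subject(outdir, ds: SubjectDataset, voxel_size: float) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_nifti(outdir / f"{ds.subject_id}_bold.nii.gz",
               ds.bold.astype(np.float32), voxel_size)
    save_motion(outdir / f"{ds.subject_id}_motion.tsv", ds.motion)
    save_events(outdir / f"{ds.subject_id}_events.tsv", ds.events)
    meta = dict(subject_id=ds.subject_id, tr=ds.tr, n_volumes=ds.n_volumes,
                rng_seed=ds.rng_seed,
                planted_spikes=[int(i) for i in ds.planted_spikes],
                amplitudes=ds.events.amplitudes)
    (outdir / f"{ds.subject_id}_meta.json").write_text(json.dumps(meta, indent=1))


def load_subject(outdir, subject_id: str) -> SubjectDataset:
    outdir = Path(outdir)
    bold, _ = load_nifti(outdir / f"{subject_id}_bold.nii.gz")
    meta = json.loads((outdir / f"{subject_id}_meta.json").read_text())
    events = load_events(outdir / f"{subject_id}_events.tsv",
                         meta.get("amplitudes"))
    return SubjectDataset(
        bold=np.asarray(bold, dtype=np.float64), tr=meta["tr"],
        n_volumes=meta["n_volumes"],
        motion=load_motion(outdir / f"{subject_id}_motion.tsv"),
        events=events, subject_id=subject_id, rng_seed=meta["rng_seed"],
        planted_spikes=np.asarray(meta.get("planted_spikes", []), dtype=int))


def save_fisher_z_map(path_prefix, fz: FisherZMap, voxel_size: float) -> None:
    path_prefix = Path(path_prefix)
    save_nifti(path_prefix.with_suffix(".nii.gz"),
               fz.values.astype(np.float32), voxel_size)
    sidecar = dict(subject_id=fz.subject_id, seed_id=fz.seed_id,
                   band=list(fz.band), df_effective=fz.df_effective,
                   qc_zero_variance=[list(map(int, v)) for v in fz.qc_zero_variance])
    path_prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_fisher_z_map(path_prefix) -> FisherZMap:
    path_prefix = Path(path_prefix)
    values, _ = load_nifti(path_prefix.with_suffix(".nii.gz"))
    values = np.asarray(values, dtype=float)
    meta = json.loads(path_prefix.with_suffix(".json").read_text())
    return FisherZMap(values=values, target_mask=~np.isnan(values),
                      subject_id=meta["subject_id"], seed_id=meta["seed_id"],
                      band=tuple(meta["band"]), df_effective=meta["df_effective"],
                      qc_zero_variance=[tuple(v) for v in meta["qc_zero_variance"]])


def save_cluster_table(path, table: ClusterTable) -> None:
    table.table.to_csv(path, sep="\t", index=False)


def save_manifest(path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
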