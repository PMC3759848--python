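"""NIfTI/CSV cohort I/O, run manifests, and figure/table reporting.

Conventions: NIfTI-1 with RAS+ affines built from the voxel dimensions;
masks stored as unsigned 8-bit, statistic maps as 32-bit float,
displacement fields as 4-D volumes with the vector dimension last.  The
behaviour table is a UTF-8 CSV with a header row (subject_id, group, ffl,
ffr, gsl, gsr).  Every run writes one JSON manifest recording the tool
version, configuration snapshot, seeds, input checksums, timings and
warnings, so exact reruns are reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .deformation import JacobianMap
from .synthetic import SCORE_NAMES, Cohort, Subject, SyntheticConfig

logger = logging.getLogger(__name__)


class CohortReadError(RuntimeError):
    pass


@dataclass
class RunManifest:
    tool_version: str = _pkg_version
    config: dict = dc_field(default_factory=dict)
    seeds: dict = dc_field(default_factory=dict)
    input_checksums: dict = dc_field(default_factory=dict)
    timings_s: dict = dc_field(default_factory=dict)
    warnings: list = dc_field(default_factory=list)

    def add_input(self, path: str | Path):
        p = Path(path)
        self.input_checksums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()

    def time_stage(self, name: str):
        manifest = self

        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                manifest.timings_s[name] = round(time.perf_counter() - self.t0, 4)
                return False

        return _Timer()

    def write(self, path: str | Path):
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def _affine(voxel_dims_mm) -> np.ndarray:
    aff = np.diag(list(voxel_dims_mm) + [1.0])
    return aff


def save_nifti(data: np.ndarray, voxel_dims_mm, path: str | Path, dtype=None):
    data = np.asarray(data)
    if dtype is None:
        dtype = np.uint8 if data.dtype == bool else np.float32
    img = nib.Nifti1Image(data.astype(dtype), _affine(voxel_dims_mm))
    img.header.set_zooms(tuple(voxel_dims_mm) + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def write_cohort(cohort: Cohort, out_dir: str | Path) -> RunManifest:
    """Write a cohort as per-subject NIfTI volumes plus shared tables.

    Layout: ``<id>_image.nii.gz``, ``<id>_lesion.nii.gz``,
    ``<id>_field.nii.gz`` (4-D), ``<id>_logjac.nii.gz``, shared
    ``brain_mask.nii.gz``, ``behaviour.csv``, ``ground_truth.json`` and
    ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dims = cohort.voxel_dims_mm
    manifest = RunManifest(seeds={"cohort": cohort.config.seed})
    with manifest.time_stage("write_cohort"):
        save_nifti(cohort.brain_mask, dims, out / "brain_mask.nii.gz")
        for s in cohort.subjects:
            save_nifti(s.lesion_mask, dims, out / f"{s.subject_id}_lesion.nii.gz")
            if s.image is not None:
                save_nifti(s.image, dims, out / f"{s.subject_id}_image.nii.gz")
            if s.field is not None:
                save_nifti(s.field, dims, out / f"{s.subject_id}_field.nii.gz")
            if s.jacobian is not None:
                save_nifti(s.jacobian.j, dims, out / f"{s.subject_id}_jac.nii.gz")
        cohort.behaviour_table().to_csv(out / "behaviour.csv")
        gt = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in cohort.ground_truth.items()
        }
        (out / "ground_truth.json").write_text(json.dumps(gt, default=str))
    cfg = {k: str(v) for k, v in vars(cohort.config).items()}
    manifest.config = cfg
    manifest.write(out / "manifest.json")
    return manifest


def read_cohort(
    in_dir: str | Path,
    behaviour_csv: str | Path | None = None,
    affine_tol: float = 1e-4,
) -> Cohort:
    """Load a cohort written by :func:`write_cohort`.

    All grids must share shape and affine (within ``affine_tol``).  Subjects
    missing a required file are rejected with their ids named; behaviour
    rows without a matching subject are dropped with a warning.
    """
    src = Path(in_dir)
    beh_path = Path(behaviour_csv) if behaviour_csv else src / "behaviour.csv"
    if not beh_path.exists():
        raise CohortReadError(f"behaviour table not found: {beh_path}")
    behaviour = pd.read_csv(beh_path, index_col="subject_id")

    brain_path = src / "brain_mask.nii.gz"
    if not brain_path.exists():
        raise CohortReadError("brain_mask.nii.gz not found")
    brain, ref_affine = load_nifti(brain_path)
    brain = brain.astype(bool)
    dims = tuple(float(d) for d in np.diag(ref_affine)[:3])

    tags = ("image", "lesion", "field", "jac")
    ids_on_disk = sorted(
        {
            p.name.rsplit(f"_{tag}.nii.gz", 1)[0]
            for tag in tags
            for p in src.glob(f"*_{tag}.nii.gz")
        }
    )
    no_behaviour = sorted(set(ids_on_disk) - set(behaviour.index))
    if no_behaviour:
        raise CohortReadError(
            f"subjects missing behaviour rows: {', '.join(no_behaviour)}"
        )
    unmatched = sorted(set(behaviour.index) - set(ids_on_disk))
    if unmatched:
        warnings.warn(
            f"behaviour rows without image data dropped: {', '.join(unmatched)}",
            stacklevel=2,
        )
        behaviour = behaviour.drop(index=unmatched)

    subjects = []
    for sid in ids_on_disk:
        def _load(tag, required=False):
            p = src / f"{sid}_{tag}.nii.gz"
            if not p.exists():
                if required:
                    raise CohortReadError(f"subject {sid}: missing {tag} volume")
                return None
            data, aff = load_nifti(p)
            if data.shape[:3] != brain.shape:
                raise CohortReadError(
                    f"subject {sid}: {tag} grid {data.shape[:3]} does not "
                    f"match reference {brain.shape}"
                )
            if np.abs(aff - ref_affine).max() > affine_tol:
                raise CohortReadError(f"subject {sid}: {tag} affine mismatch")
            return data

        lesion = _load("lesion", required=True).astype(bool)
        image = _load("image")
        field = _load("field")
        jac = _load("jac")
        row = behaviour.loc[sid]
        subj = Subject(
            subject_id=sid,
            group=str(row["group"]),
            lesion_mask=lesion,
            scores={k: float(row[k]) for k in SCORE_NAMES},
            image=image,
            field=field,
            jacobian=JacobianMap(j=np.asarray(jac, float), voxel_dims_mm=dims)
            if jac is not None
            else None,
        )
        subj._volume = float(lesion.sum()) * float(np.prod(dims))
        subjects.append(subj)

    gt_path = src / "ground_truth.json"
    ground_truth = json.loads(gt_path.read_text()) if gt_path.exists() else {}
    cfg = SyntheticConfig(grid_shape=brain.shape, voxel_dims_mm=dims)
    return Cohort(
        subjects=subjects,
        brain_mask=brain,
        voxel_dims_mm=dims,
        config=cfg,
        ground_truth=ground_truth,
    )


def report_montage(
    stat_map: np.ndarray,
    significant: np.ndarray | None,
    tested: np.ndarray | None,
    out_png: str | Path,
    voxel_dims_mm=(1.0, 1.0, 1.0),
    bregma_offset_mm: float = 0.0,
    n_slices: int = 8,
    title: str = "",
) -> dict:
    """Axial slice montage of a statistic map with significance overlay.

    Untested voxels are shaded grey so "not testable" is distinguishable
    from "not significant"; significant voxels are outlined in the overlay.
    Slice labels are axial positions in mm relative to a configurable
    Bregma-style offset (display only).  Returns overlay voxel counts.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    stat_map = np.asarray(stat_map, dtype=float)
    nz = stat_map.shape[2]
    slices = np.linspace(0, nz - 1, min(n_slices, nz)).astype(int)
    ncol = len(slices)
    fig, axes = plt.subplots(1, ncol, figsize=(2.2 * ncol, 2.6))
    if ncol == 1:
        axes = [axes]
    vmax = np.nanmax(np.abs(stat_map)) or 1.0
    n_overlay = 0
    for ax, z in zip(np.atleast_1d(axes), slices):
        sl = stat_map[:, :, z].T
        ax.imshow(sl, cmap="coolwarm", vmin=-vmax, vmax=vmax, origin="lower")
        if tested is not None:
            un = ~np.asarray(tested, bool)[:, :, z].T
            ax.imshow(
                np.where(un, 0.5, np.nan), cmap="gray", vmin=0, vmax=1,
                alpha=0.35, origin="lower",
            )
        if significant is not None:
            sig = np.asarray(significant, bool)[:, :, z].T
            n_overlay += int(sig.sum())
            ax.contour(sig.astype(float), levels=[0.5], colors="k", linewidths=0.8)
        pos = bregma_offset_mm + z * voxel_dims_mm[2]
        ax.set_title(f"{pos:+.1f} mm", fontsize=8)
        ax.axis("off")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)
    total_sig = int(np.asarray(significant, bool).sum()) if significant is not None else 0
    return {"overlay_voxels_shown": n_overlay, "significant_voxels": total_sig}


def summary_table(result, out_csv: str | Path | None = None) -> pd.DataFrame:
    """One-row CSV summary of a voxelwise result (VLSM or TBM)."""
    stat = getattr(result, "t_map", None)
    if stat is None:
        stat = result.stat_map
    tested = result.tested
    row = {
        "n_tested_voxels": int(tested.sum()),
        "stat_max": float(np.nanmax(stat)) if tested.any() else np.nan,
        "stat_min": float(np.nanmin(stat)) if tested.any() else np.nan,
        "n_significant": int(result.significant.sum())
        if result.significant is not None
        else 0,
        "n_permutations": result.n_permutations_used,
    }
    df = pd.DataFrame([row])
    if out_csv:
        df.to_csv(out_csv, index=False)
    return df
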