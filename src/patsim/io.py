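"""Standard-format I/O: NIfTI volumes, TSV tables, JSON sidecars.

Beta stacks are stored as 4D NIfTI (trials along the 4th axis) together with
a trial-index TSV; searchlight maps and masks as 3D NIfTI with a JSON
sidecar recording the spec that produced them.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .glm import BetaImage

__all__ = [
    "save_beta_image",
    "load_beta_image",
    "save_volume",
    "load_volume",
    "save_trial_table",
    "load_trial_table",
    "save_motion",
    "load_motion",
    "write_sidecar",
]


def save_trial_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)
    return path


def load_trial_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    if "old" in table.columns:
        table["old"] = table["old"].astype(bool)
    return table


def save_motion(motion: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        motion, columns=[f"motion{k}" for k in range(motion.shape[1])]
    ).to_csv(path, sep="\t", index=False)
    return path


def load_motion(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)


def save_volume(data: np.ndarray, affine: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), path)
    return path


def load_volume(path) -> tuple:
    img = nib.load(path)
    return np.asarray(img.get_fdata()), img.affine


def save_beta_image(beta: BetaImage, prefix) -> dict:
    """Write betas (4D NIfTI), mask (3D NIfTI) and trial index (TSV)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "betas": prefix.with_name(prefix.name + "_betas.nii.gz"),
        "mask": prefix.with_name(prefix.name + "_mask.nii.gz"),
        "trials": prefix.with_name(prefix.name + "_trials.tsv"),
    }
    nib.save(nib.Nifti1Image(beta.to_4d().astype(np.float64), beta.affine),
             paths["betas"])
    nib.save(nib.Nifti1Image(beta.mask.astype(np.uint8), beta.affine),
             paths["mask"])
    beta.trials.to_csv(paths["trials"], sep="\t", index=True, index_label="row")
    return paths


def load_beta_image(prefix) -> BetaImage:
    prefix = Path(prefix)
    data, affine = load_volume(prefix.with_name(prefix.name + "_betas.nii.gz"))
    mask, _ = load_volume(prefix.with_name(prefix.name + "_mask.nii.gz"))
    mask = mask > 0.5
    trials = pd.read_csv(
        prefix.with_name(prefix.name + "_trials.tsv"), sep="\t", index_col="row"
    )
    if "old" in trials.columns:
        trials["old"] = trials["old"].astype(bool)
    vox = float(np.abs(affine[0, 0]))
    return BetaImage(
        betas=data[mask, :].T,
        trials=trials,
        mask=mask,
        affine=affine,
        voxel_size_mm=vox,
    )


def write_sidecar(payload: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating, np.bool_)):
            return o.item()
        return str(o)

    path.write_text(json.dumps(payload, indent=2, default=default))
    return path
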