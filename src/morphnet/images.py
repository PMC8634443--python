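"""Gray-matter map and atlas I/O, smoothing, and regional value extraction.

The pipeline consumes spatially normalized, modulated gray-matter (GM)
probability/volume maps — one 3D NIfTI per subject — together with an
integer-labeled parcellation (AAL-90 convention by default).  This module
holds the container types for those images and the operations that turn a
map + atlas into per-region voxel-value samples, the raw material for the
kernel-density network construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

#: FWHM of a Gaussian = sigma * 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class GMMap:
    """One subject's 3D gray-matter value image in a known world space.

    ``values`` are unitless modulated tissue fractions, finite and >= 0.
    ``affine`` maps 0-based voxel indices to RAS mm coordinates.
    """

    subject_id: str
    values: np.ndarray
    affine: np.ndarray
    space_tag: str = "MNI"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.values.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.values)):
            n_bad = int(np.sum(~np.isfinite(self.values)))
            raise ValueError(f"GM map contains {n_bad} non-finite voxels")
        if np.any(self.values < 0):
            raise ValueError("GM values must be >= 0 (clip at load time)")

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class AtlasParcellation:
    """Integer-labeled parcellation volume (0 = background) plus a region table.

    ``regions`` is a DataFrame with columns ``region_id`` (unique positive
    integers) and ``region_name``; every nonzero label in ``labels`` must
    appear in it and each region must own at least one voxel.
    """

    labels: np.ndarray
    regions: pd.DataFrame
    affine: np.ndarray
    allow_empty_regions: bool = False  # resampling can push a region off-grid

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = np.asarray(self.labels)
            if not np.allclose(lab, np.round(lab)):
                raise ValueError("atlas labels must be integers")
            self.labels = np.round(lab).astype(np.int32)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        ids = self.regions["region_id"].to_numpy()
        if len(ids) == 0:
            raise ValueError("atlas has zero regions")
        if len(np.unique(ids)) != len(ids):
            raise ValueError("region ids are not unique")
        present = np.unique(self.labels)
        present = present[present != 0]
        missing = np.setdiff1d(present, ids)
        if missing.size:
            raise ValueError(f"labels {missing.tolist()} absent from region table")
        empty = np.setdiff1d(ids, present)
        if empty.size:
            if not self.allow_empty_regions:
                raise ValueError(f"regions {empty.tolist()} have no voxels")
            logger.warning("%d regions have no voxels after resampling",
                           empty.size)

    @property
    def region_ids(self) -> np.ndarray:
        """Region ids in table order (the canonical node order)."""
        return self.regions["region_id"].to_numpy()


@dataclass
class RegionalSamples:
    """Per-subject map from region id to the vector of voxel GM values."""

    subject_id: str
    samples: dict[int, np.ndarray] = field(default_factory=dict)

    def region_ids(self) -> list[int]:
        return list(self.samples.keys())


def aal90_region_table() -> pd.DataFrame:
    """The packaged 90-region AAL (cerebrum) id/name table."""
    path = Path(__file__).parent / "data" / "aal90_regions.tsv"
    return pd.read_csv(path, sep="\t")


def load_gm_map(path: str | Path, subject_id: str | None = None,
                space_tag: str = "MNI") -> GMMap:
    """Load a 3D NIfTI GM map; negative voxels are clipped to 0 and counted."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path.name}")
    n_bad = int(np.sum(~np.isfinite(data)))
    if n_bad:
        raise ValueError(f"{path.name} contains {n_bad} non-finite voxels")
    n_neg = int(np.sum(data < 0))
    if n_neg:
        logger.warning("%s: clipped %d negative voxels to 0", path.name, n_neg)
        data = np.clip(data, 0.0, None)
    sid = subject_id if subject_id is not None else path.name.split(".")[0]
    return GMMap(subject_id=sid, values=data, affine=img.affine, space_tag=space_tag)


def save_gm_map(gm: GMMap, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(gm.values, gm.affine), str(path))


def load_atlas(labels_path: str | Path, regions_path: str | Path) -> AtlasParcellation:
    """Load a label NIfTI and its region_id/region_name TSV."""
    img = nib.load(str(labels_path))
    labels = np.asarray(img.dataobj)
    labels = np.squeeze(labels)
    regions = pd.read_csv(regions_path, sep="\t")
    return AtlasParcellation(labels=labels, regions=regions, affine=img.affine)


def save_atlas(atlas: AtlasParcellation, labels_path: str | Path,
               regions_path: str | Path) -> None:
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.affine),
             str(labels_path))
    atlas.regions.to_csv(regions_path, sep="\t", index=False)


def smooth_gm_map(gm: GMMap, fwhm_mm: float, truncate: float = 6.0) -> GMMap:
    """Gaussian-smooth a GM map with the kernel width given as FWHM in mm.

    Sigma per axis is ``fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm``; the kernel
    is normalized, so the image sum is conserved for signal away from the
    boundary (constant-zero padding is used at the edges).
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return GMMap(gm.subject_id, gm.values.copy(), gm.affine.copy(), gm.space_tag)
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / gm.voxel_sizes_mm
    out = ndimage.gaussian_filter(gm.values, sigma=sigma_vox, mode="constant",
                                  cval=0.0, truncate=truncate)
    # tiny negative ringing cannot occur for a Gaussian kernel, but guard anyway
    np.clip(out, 0.0, None, out=out)
    return GMMap(gm.subject_id, out, gm.affine.copy(), gm.space_tag)


def resample_atlas_to(atlas: AtlasParcellation, target: GMMap) -> AtlasParcellation:
    """Nearest-neighbor resample the label image onto the map grid.

    Labels are categorical, so only nearest-neighbor assignment is valid.
    Voxel centers of the target grid are mapped through both affines.
    """
    if atlas.labels.shape == target.values.shape and np.allclose(
            atlas.affine, target.affine):
        return atlas
    inv = np.linalg.inv(atlas.affine) @ target.affine
    idx = np.indices(target.values.shape).reshape(3, -1)
    homog = np.vstack([idx, np.ones(idx.shape[1])])
    src = (inv @ homog)[:3]
    src = np.round(src).astype(np.int64)
    inside = np.all((src >= 0) & (src < np.array(atlas.labels.shape)[:, None]), axis=0)
    out = np.zeros(idx.shape[1], dtype=atlas.labels.dtype)
    out[inside] = atlas.labels[tuple(src[:, inside])]
    logger.info("resampled atlas to map grid %s", target.values.shape)
    return AtlasParcellation(labels=out.reshape(target.values.shape),
                             regions=atlas.regions, affine=target.affine.copy(),
                             allow_empty_regions=True)


def extract_regional_samples(gm: GMMap, atlas: AtlasParcellation) -> RegionalSamples:
    """Collect each region's voxel values in ascending flattened-index order."""
    if gm.values.shape != atlas.labels.shape:
        raise ValueError(
            f"grid mismatch: map {gm.values.shape} vs atlas {atlas.labels.shape}; "
            "resample the atlas first (resample_atlas_to)")
    flat_vals = gm.values.ravel()
    flat_lab = atlas.labels.ravel()
    out: dict[int, np.ndarray] = {}
    order = np.argsort(flat_lab, kind="stable")
    sorted_lab = flat_lab[order]
    bounds = np.searchsorted(sorted_lab, atlas.region_ids, side="left")
    ends = np.searchsorted(sorted_lab, atlas.region_ids, side="right")
    for rid, a, b in zip(atlas.region_ids, bounds, ends):
        vox = np.sort(order[a:b])  # ascending flattened index
        out[int(rid)] = flat_vals[vox]
    return RegionalSamples(subject_id=gm.subject_id, samples=out)


def region_mean_table(all_samples: list[RegionalSamples],
                      atlas: AtlasParcellation) -> pd.DataFrame:
    """Subject x region table of mean GM values, columns in atlas order."""
    ids = [int(r) for r in atlas.region_ids]
    rows = []
    for rs in all_samples:
        if sorted(rs.samples.keys()) != sorted(ids):
            raise ValueError(f"subject {rs.subject_id}: region set differs from atlas")
        rows.append([float(np.mean(rs.samples[r])) for r in ids])
    df = pd.DataFrame(rows, columns=[str(r) for r in ids])
    df.insert(0, "subject_id", [rs.subject_id for rs in all_samples])
    return df
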