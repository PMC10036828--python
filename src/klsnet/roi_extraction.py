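"""Parcellated uptake extraction: smoothing, global-mean normalization, ROI sampling.

Input images are assumed pre-registered to the atlas template space;
spatial normalization is outside this package. The canonical pipeline is
smooth -> normalize -> extract, mirroring common PET preprocessing where a
Gaussian smoothing kernel is applied before intensities are scaled to the
average whole-brain uptake.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "VolumeImage",
    "LabelAtlas",
    "ROISampleSet",
    "smooth_gaussian",
    "normalize_global_mean",
    "extract_roi_samples",
    "FWHM_TO_SIGMA",
]

#: FWHM = 2 sqrt(2 ln 2) * sigma for a Gaussian kernel.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class VolumeImage:
    """A 3D uptake volume with voxel geometry.

    Parameters
    ----------
    data
        3D array of uptake values (arbitrary units).
    voxel_size
        Physical voxel edge lengths ``(dx, dy, dz)`` in mm.
    affine
        4x4 voxel-to-world map.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("image data must be a 3D array with all dims >= 1")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive lengths in mm")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @classmethod
    def from_nifti(cls, path) -> "VolumeImage":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        return cls(np.asarray(img.get_fdata(), dtype=float), tuple(zooms), img.affine)

    def to_nifti(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data, self.affine), str(path))


@dataclass
class LabelAtlas:
    """Integer parcellation labelling each voxel with a region id.

    ``region_ids``/``region_names`` are parallel and ordered; ``lobe_map``
    assigns every region to one of six gross anatomical groups (frontal,
    temporal, parietal, occipital, central structures, insula-and-cingulate
    in the 90-region configuration).
    """

    labels: np.ndarray
    region_ids: list[int]
    region_names: list[str]
    lobe_map: dict[int, str]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = np.rint(self.labels).astype(np.int64)
            if not np.allclose(lab, self.labels):
                raise ValueError("atlas labels must be integers")
            self.labels = lab
        self.region_ids = [int(r) for r in self.region_ids]
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("region_ids must be unique")
        if any(r <= 0 for r in self.region_ids):
            raise ValueError("region_ids must be positive")
        if len(self.region_names) != len(self.region_ids):
            raise ValueError("region_names must parallel region_ids")
        present = set(np.unique(self.labels[self.labels != 0]).tolist())
        unknown = present - set(self.region_ids)
        if unknown:
            raise ValueError(f"voxel labels not in region_ids: {sorted(unknown)}")
        missing = set(self.region_ids) - set(self.lobe_map)
        if missing:
            raise ValueError(f"lobe_map missing region ids: {sorted(missing)}")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def name_of(self, region_id: int) -> str:
        return self.region_names[self.region_ids.index(int(region_id))]

    @classmethod
    def from_nifti(cls, label_path, lookup_path) -> "LabelAtlas":
        """Load labels from NIfTI and region metadata from a TSV lookup.

        The lookup file has columns ``id``, ``name``, ``lobe``.
        """
        img = nib.load(str(label_path))
        labels = np.asarray(img.get_fdata())
        tbl = pd.read_csv(lookup_path, sep="\t")
        for col in ("id", "name", "lobe"):
            if col not in tbl.columns:
                raise ValueError(f"atlas lookup missing column {col!r}")
        ids = [int(i) for i in tbl["id"]]
        return cls(
            labels=labels,
            region_ids=ids,
            region_names=[str(n) for n in tbl["name"]],
            lobe_map=dict(zip(ids, (str(g) for g in tbl["lobe"]))),
            affine=img.affine,
        )


@dataclass
class ROISampleSet:
    """Per-region vectors of (normalized) voxel values for one subject."""

    subject_id: str
    samples: dict[int, np.ndarray]
    global_mean: float = 1.0

    def __post_init__(self) -> None:
        self.samples = {int(r): np.asarray(v, dtype=float) for r, v in self.samples.items()}
        for r, v in self.samples.items():
            if v.size == 0:
                raise ValueError(f"region {r} has an empty sample vector")

    @property
    def region_ids(self) -> list[int]:
        return list(self.samples)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (self.subject_id, r, x)
            for r, v in self.samples.items()
            for x in v
        ]
        return pd.DataFrame(rows, columns=["subject_id", "region_id", "value"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ROISampleSet":
        tbl = pd.read_csv(path, sep="\t")
        subjects = tbl["subject_id"].unique()
        if len(subjects) != 1:
            raise ValueError("ROI sample table must hold exactly one subject")
        samples = {
            int(r): grp["value"].to_numpy(dtype=float)
            for r, grp in tbl.groupby("region_id", sort=True)
        }
        return cls(subject_id=str(subjects[0]), samples=samples)


def smooth_gaussian(
    img: VolumeImage, fwhm_mm: float, boundary: str = "constant"
) -> VolumeImage:
    """Smooth with a separable Gaussian of the given FWHM in mm.

    The per-axis sigma in voxel units is ``fwhm_mm * FWHM_TO_SIGMA / voxel_size``.
    ``fwhm_mm = 0`` returns the input unchanged. Default boundary handling is
    constant-zero padding; any :func:`scipy.ndimage.gaussian_filter` mode is
    accepted.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if any(v <= 0 for v in img.voxel_size):
        raise ValueError("voxel sizes must be positive")
    if fwhm_mm == 0:
        return VolumeImage(img.data.copy(), img.voxel_size, img.affine.copy())
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / v for v in img.voxel_size]
    out = ndimage.gaussian_filter(img.data, sigma=sigma_vox, mode=boundary, cval=0.0)
    return VolumeImage(out, img.voxel_size, img.affine.copy())


def _check_registration(img: VolumeImage, atlas: LabelAtlas, tol: float = 1e-4) -> None:
    if img.data.shape != atlas.labels.shape:
        raise ValueError(
            f"image shape {img.data.shape} does not match atlas shape {atlas.labels.shape}"
        )
    if np.max(np.abs(img.affine - atlas.affine)) > tol:
        warnings.warn(
            "image and atlas affines differ beyond tolerance; inputs are assumed "
            "pre-registered to a common template",
            stacklevel=3,
        )


def normalize_global_mean(
    img: VolumeImage, atlas: LabelAtlas, mask: np.ndarray | None = None
) -> VolumeImage:
    """Divide all voxels by the mean uptake over the brain mask.

    The brain mask defaults to all voxels with a nonzero atlas label; an
    explicit boolean ``mask`` overrides it. After normalization the in-mask
    mean equals 1.
    """
    _check_registration(img, atlas)
    if mask is None:
        mask = atlas.labels != 0
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != img.data.shape:
            raise ValueError("mask shape must match image shape")
    if not mask.any():
        raise ValueError("brain mask is empty: no voxel has a nonzero atlas label")
    mean = float(img.data[mask].mean())
    if mean <= 0:
        raise ValueError(f"degenerate image: in-mask mean uptake is {mean} <= 0")
    return VolumeImage(img.data / mean, img.voxel_size, img.affine.copy())


def extract_roi_samples(
    img: VolumeImage, atlas: LabelAtlas, subject_id: str = "subject"
) -> ROISampleSet:
    """Collect the voxel values of every atlas region into per-region vectors.

    Voxels are taken in ascending linear (C storage) order so downstream
    density estimation is reproducible. A region with no voxels is an error.
    """
    _check_registration(img, atlas)
    flat_labels = atlas.labels.ravel(order="C")
    flat_data = img.data.ravel(order="C")
    samples: dict[int, np.ndarray] = {}
    for r in atlas.region_ids:
        vals = flat_data[flat_labels == r]
        if vals.size == 0:
            raise ValueError(f"region {r} ({atlas.name_of(r)}) covers no voxels")
        samples[r] = vals
    inmask = flat_data[flat_labels != 0]
    return ROISampleSet(subject_id=subject_id, samples=samples, global_mean=float(inmask.mean()))


def process_volume(
    img: VolumeImage,
    atlas: LabelAtlas,
    fwhm_mm: float = 6.0,
    subject_id: str = "subject",
    smooth_first: bool = True,
    boundary: str = "constant",
) -> ROISampleSet:
    """Full single-subject preprocessing: smooth, normalize, extract.

    ``smooth_first=False`` swaps the first two steps for sensitivity checks;
    the default order follows the usual PET pipeline convention.
    """
    if smooth_first:
        img = smooth_gaussian(img, fwhm_mm, boundary=boundary)
        img = normalize_global_mean(img, atlas)
    else:
        img = normalize_global_mean(img, atlas)
        img = smooth_gaussian(img, fwhm_mm, boundary=boundary)
    return extract_roi_samples(img, atlas, subject_id=subject_id)
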