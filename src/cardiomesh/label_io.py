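"""Tagged 3D label images with physical-space metadata.

A :class:`LabelImage` is the pipeline's native container: an integer voxel
grid, the voxel spacing and origin in millimetres, and a tag table mapping
labels to anatomical region names (``1 -> "LV_myo"`` etc., 0 reserved for
background).  The voxel-to-world mapping is axis aligned and voxel *centers*
sit at ``origin + (index + 0.5) * spacing``; oblique orientations are
rejected rather than resampled so the mapping stays exact.

NIfTI files are handled through nibabel; NRRD through a small built-in
reader/writer (raw and gzip encodings, axis-aligned space directions).
Neither format standardises label names, so the tag table travels in a JSON
sidecar (``<image>.tags.json``).
"""

from __future__ import annotations

import gzip
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

__all__ = ["LabelImage", "read_label_image", "write_label_image", "binary_mask"]

MAX_LABEL = 65535


@dataclass
class LabelImage:
    """3D integer label grid in physical space.

    Attributes
    ----------
    voxels : (nx, ny, nz) integer array, 0 = background.
    spacing : (3,) voxel edge lengths in mm, strictly positive.
    origin : (3,) world position of the *corner* of voxel (0,0,0) in mm.
    tag_table : mapping label -> region name for every nonzero label present.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    tag_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.ascontiguousarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("non-integer labels")
        if self.voxels.min() < 0 or self.voxels.max() > MAX_LABEL:
            raise ValueError(f"labels must be in [0, {MAX_LABEL}]")
        self.voxels = self.voxels.astype(np.uint16)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if not np.all(self.spacing > 0):
            raise ValueError("spacing must be strictly positive")
        self.tag_table = {int(k): str(v) for k, v in self.tag_table.items()}
        present = set(np.unique(self.voxels).tolist()) - {0}
        missing = present - set(self.tag_table)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from tag_table")

    # -- geometry ---------------------------------------------------------

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers_1d(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates of voxel centers."""
        return tuple(
            self.origin[a] + (np.arange(self.dims[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        )

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """World-space (min_corner, max_corner) of the voxel grid."""
        return self.origin.copy(), self.origin + np.array(self.dims) * self.spacing

    def label_for(self, name: str) -> int:
        """Label carrying region ``name`` (exact match)."""
        for k, v in self.tag_table.items():
            if v == name:
                return k
        raise KeyError(f"no label named {name!r} in tag table")

    def count(self, label: int) -> int:
        return int(np.count_nonzero(self.voxels == label))


# -- operations -----------------------------------------------------------


def binary_mask(image: LabelImage, tags) -> LabelImage:
    """Binary segmentation of a tag set: 1 where the voxel label is in
    ``tags``, else 0.  Geometry metadata is copied unchanged."""
    tags = set(int(t) for t in tags)
    unknown = tags - set(image.tag_table)
    if unknown:
        raise KeyError(f"unknown tags {sorted(unknown)}")
    mask = np.isin(image.voxels, sorted(tags)).astype(np.uint16)
    table = {1: "mask"} if mask.any() else {}
    return LabelImage(mask, image.spacing.copy(), image.origin.copy(), table)


# -- NIfTI ----------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".tags.json")


def _write_sidecar(image: LabelImage, path: Path) -> None:
    _sidecar_path(path).write_text(
        json.dumps({str(k): v for k, v in sorted(image.tag_table.items())}, indent=1)
    )


def _read_sidecar(path: Path) -> dict[int, str]:
    sc = _sidecar_path(path)
    if sc.exists():
        return {int(k): v for k, v in json.loads(sc.read_text()).items()}
    return {}


def _write_nifti(image: LabelImage, path: Path) -> None:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(image.spacing)
    # nibabel maps voxel index i -> affine @ i; our centers are origin+(i+.5)s
    affine[:3, 3] = image.origin + 0.5 * image.spacing
    img = nib.Nifti1Image(image.voxels.astype(np.uint16), affine)
    img.header.set_zooms(tuple(image.spacing))
    nib.save(img, str(path))


def _read_nifti(path: Path) -> LabelImage:
    img = nib.load(str(path))
    affine = np.asarray(img.affine, dtype=float)
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.abs(off_diag).max() > 1e-6 * max(1.0, np.abs(rot).max()):
        raise ValueError("non-axis-aligned orientation matrix is not supported")
    spacing = np.diag(rot)
    if np.any(spacing <= 0):
        raise ValueError("non-axis-aligned orientation matrix is not supported")
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data), atol=0):
            raise ValueError("non-integer labels")
        data = np.round(data).astype(np.int64)
    origin = affine[:3, 3] - 0.5 * spacing
    return LabelImage(data, spacing, origin, _read_sidecar(path))


# -- NRRD (minimal, axis-aligned) -----------------------------------------

_NRRD_TYPES = {
    "uint16": np.uint16, "unsigned short": np.uint16,
    "uint8": np.uint8, "int16": np.int16, "int32": np.int32,
    "uint32": np.uint32, "int64": np.int64, "short": np.int16, "int": np.int32,
}


def _write_nrrd(image: LabelImage, path: Path) -> None:
    dirs = " ".join(
        "({},{},{})".format(*(image.spacing[a] if i == a else 0.0 for i in range(3)))
        for a in range(3)
    )
    header = [
        "NRRD0004",
        "# cardiomesh tagged label image",
        "type: uint16",
        "dimension: 3",
        "space: left-posterior-superior",
        "sizes: {} {} {}".format(*image.dims),
        f"space directions: {dirs}",
        "kinds: domain domain domain",
        "endian: little",
        "encoding: gzip",
        "space origin: ({},{},{})".format(*(image.origin + 0.5 * image.spacing)),
        "",
        "",
    ]
    payload = zlib.compress(
        np.ascontiguousarray(image.voxels.astype("<u2"), dtype="<u2").tobytes(order="F")
    )
    with open(path, "wb") as fh:
        fh.write("\n".join(header).encode("ascii"))
        fh.write(payload)


def _read_nrrd(path: Path) -> LabelImage:
    raw = path.read_bytes()
    end = raw.find(b"\n\n")
    if end < 0:
        raise ValueError("malformed NRRD header")
    fields: dict[str, str] = {}
    for line in raw[:end].decode("ascii", "replace").splitlines()[1:]:
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition(":")
        fields[key.strip().lower()] = val.strip()
    sizes = tuple(int(s) for s in fields["sizes"].split())
    dtype = _NRRD_TYPES.get(fields.get("type", "uint16"))
    if dtype is None:
        raise ValueError(f"unsupported NRRD type {fields.get('type')!r}")
    spacing = np.ones(3)
    if "space directions" in fields:
        vecs = [
            [float(x) for x in grp.strip("()").split(",")]
            for grp in fields["space directions"].replace(") (", ")|(").split("|")
        ]
        mat = np.array(vecs, dtype=float)
        if np.abs(mat - np.diag(np.diag(mat))).max() > 1e-9 * max(1.0, np.abs(mat).max()):
            raise ValueError("non-axis-aligned orientation matrix is not supported")
        spacing = np.diag(mat)
        if np.any(spacing <= 0):
            raise ValueError("non-axis-aligned orientation matrix is not supported")
    elif "spacings" in fields:
        spacing = np.array([float(x) for x in fields["spacings"].split()])
    center0 = np.zeros(3)
    if "space origin" in fields:
        center0 = np.array(
            [float(x) for x in fields["space origin"].strip("()").split(",")]
        )
    payload = raw[end + 2:]
    enc = fields.get("encoding", "raw")
    if enc in ("gzip", "gz"):
        payload = zlib.decompress(payload)
    elif enc != "raw":
        raise ValueError(f"unsupported NRRD encoding {enc!r}")
    data = np.frombuffer(payload, dtype=np.dtype(dtype).newbyteorder("<"))
    data = data[: int(np.prod(sizes))].reshape(sizes, order="F")
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError("non-integer labels")
    origin = center0 - 0.5 * spacing
    return LabelImage(np.ascontiguousarray(data), spacing, origin, _read_sidecar(path))


# -- public IO ------------------------------------------------------------


def read_label_image(path) -> LabelImage:
    """Read a tagged label image (.nii, .nii.gz or .nrrd)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return _read_nifti(path)
    if name.endswith(".nrrd"):
        return _read_nrrd(path)
    raise ValueError(f"unsupported image format: {path.name}")


def write_label_image(image: LabelImage, path) -> None:
    """Write a tagged label image plus its ``.tags.json`` sidecar."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        _write_nifti(image, path)
    elif name.endswith(".nrrd"):
        _write_nrrd(image, path)
    else:
        raise ValueError(f"unsupported image format: {path.name}")
    _write_sidecar(image, path)
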