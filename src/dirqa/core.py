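"""Shared spatial containers for the DIR QA pipeline.

Everything in this package lives on axis-aligned lattices with a fixed
anatomical axis convention:

* axis 0 — LR (left-right, x, mm)
* axis 1 — AP (anterior-posterior, y, mm)
* axis 2 — SI (superior-inferior, z, mm)

The physical center of voxel ``(i, j, k)`` is ``origin + (i, j, k) * spacing``.
Displacement-vector components are stored in the same (LR, AP, SI) order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
from scipy.ndimage import map_coordinates

# component indices of a displacement vector
LR, AP, SI = 0, 1, 2
COMPONENT_ORDER = ("LR", "AP", "SI")

PUSHFORWARD = "pushforward"
PULLBACK = "pullback"


def _as_vec3(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float).reshape(3)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} must be finite, got {a}")
    return a


@dataclass
class ImageVolume:
    """A 3-D scalar lattice (HU or cGy) with physical geometry."""

    data: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got shape {self.data.shape}")
        self.origin = _as_vec3(self.origin, "origin")
        self.spacing = _as_vec3(self.spacing, "spacing")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image data must be finite")

    # ------------------------------------------------------------------ geometry
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) physical coordinates of the first and last voxel centers."""
        lo = self.origin.copy()
        hi = self.origin + (np.array(self.shape) - 1) * self.spacing
        return lo, hi

    def same_geometry(self, other: "ImageVolume | VectorField") -> bool:
        return (
            self.shape == tuple(other.shape)
            and np.allclose(self.origin, other.origin)
            and np.allclose(self.spacing, other.spacing)
        )

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) physical coordinates of every voxel center, C-order."""
        idx = np.indices(self.shape, dtype=float).reshape(3, -1).T
        return self.origin + idx * self.spacing

    def physical_to_index(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    def sample(self, points: np.ndarray, order: int = 1, fill: float = 0.0) -> np.ndarray:
        """Interpolate the volume at physical points (trilinear by default)."""
        idx = self.physical_to_index(points)
        return map_coordinates(
            self.data.astype(float), idx.T, order=order, mode="constant", cval=fill
        )

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.data.copy(), self.origin.copy(), self.spacing.copy())

    # ------------------------------------------------------------------ I/O
    def save(self, path: str | Path) -> None:
        write_image(self, path)

    @staticmethod
    def load(path: str | Path) -> "ImageVolume":
        return read_image(path)


@dataclass
class VectorField:
    """Per-voxel 3-component displacement (mm) on an ImageVolume geometry.

    ``u[..., c]`` is the (LR, AP, SI)[c] displacement component.  The default
    convention is push-forward: a material point at planning position ``p``
    lies at ``p + u(p)`` in the deformed anatomy.
    """

    u: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    convention: str = PUSHFORWARD

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 4 or self.u.shape[-1] != 3:
            raise ValueError(f"expected (nx, ny, nz, 3) displacements, got {self.u.shape}")
        self.origin = _as_vec3(self.origin, "origin")
        self.spacing = _as_vec3(self.spacing, "spacing")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement field must be finite")
        if self.convention not in (PUSHFORWARD, PULLBACK):
            raise ValueError(f"unknown convention {self.convention!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.u.shape[:3]  # type: ignore[return-value]

    @property
    def u_lr(self) -> np.ndarray:
        return self.u[..., LR]

    @property
    def u_ap(self) -> np.ndarray:
        return self.u[..., AP]

    @property
    def u_si(self) -> np.ndarray:
        return self.u[..., SI]

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.u, axis=-1)

    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        lo = self.origin.copy()
        hi = self.origin + (np.array(self.shape) - 1) * self.spacing
        return lo, hi

    def same_geometry(self, other: "ImageVolume | VectorField") -> bool:
        return (
            self.shape == tuple(other.shape)
            and np.allclose(self.origin, other.origin)
            and np.allclose(self.spacing, other.spacing)
        )

    def voxel_centers(self) -> np.ndarray:
        idx = np.indices(self.shape, dtype=float).reshape(3, -1).T
        return self.origin + idx * self.spacing

    def sample(self, points: np.ndarray, fill: float = 0.0, mode: str = "constant") -> np.ndarray:
        """Trilinearly interpolate the displacement (N, 3) at physical points.

        ``mode="nearest"`` extends the field by edge replication instead of a
        constant fill — used during inversion, where the fixed-point iteration
        must remain a contraction even for points displaced past the lattice.
        """
        idx = ((np.asarray(points, dtype=float) - self.origin) / self.spacing).T
        out = np.empty((idx.shape[1], 3))
        for c in range(3):
            out[:, c] = map_coordinates(
                self.u[..., c], idx, order=1, mode=mode, cval=fill
            )
        return out

    def copy(self) -> "VectorField":
        return replace(self, u=self.u.copy(), origin=self.origin.copy(), spacing=self.spacing.copy())

    def save(self, path: str | Path) -> None:
        write_dvf(self, path)

    @staticmethod
    def load(path: str | Path, convention: str | None = None) -> "VectorField":
        return read_dvf(path, convention)


def zero_field_like(geom: ImageVolume | VectorField) -> VectorField:
    return VectorField(
        np.zeros(tuple(geom.shape) + (3,)), geom.origin.copy(), geom.spacing.copy()
    )


# ---------------------------------------------------------------------- file I/O

def _affine(origin: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def _geom_from_affine(aff: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rot = aff[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot))):
        raise ValueError("only axis-aligned (diagonal-affine) volumes are supported")
    spacing = np.diag(rot).astype(float)
    if np.any(spacing <= 0):
        raise ValueError("affine implies non-positive spacing; reorient the volume first")
    return aff[:3, 3].astype(float), spacing


def _is_nifti(path: Path) -> bool:
    return path.name.endswith((".nii", ".nii.gz"))


def write_image(img: ImageVolume, path: str | Path, dtype=None) -> None:
    """Write a scalar volume as NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd)."""
    path = Path(path)
    data = img.data if dtype is None else img.data.astype(dtype)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(np.asanyarray(data), _affine(img.origin, img.spacing)), path)
    elif path.suffix in (".mha", ".mhd"):
        im = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(data, (2, 1, 0))))
        im.SetOrigin(tuple(img.origin))
        im.SetSpacing(tuple(img.spacing))
        sitk.WriteImage(im, str(path))
    else:
        raise ValueError(f"unsupported image format: {path.name}")


def read_image(path: str | Path) -> ImageVolume:
    path = Path(path)
    if _is_nifti(path):
        im = nib.load(path)
        origin, spacing = _geom_from_affine(im.affine)
        return ImageVolume(np.asarray(im.dataobj, dtype=float), origin, spacing)
    if path.suffix in (".mha", ".mhd"):
        im = sitk.ReadImage(str(path))
        data = np.transpose(sitk.GetArrayFromImage(im), (2, 1, 0)).astype(float)
        return ImageVolume(data, np.array(im.GetOrigin()), np.array(im.GetSpacing()))
    raise ValueError(f"unsupported image format: {path.name}")


def write_mask(mask: np.ndarray, origin, spacing, path: str | Path) -> None:
    write_image(ImageVolume(mask.astype(np.uint8), origin, spacing), path, dtype=np.uint8)


def read_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    img = read_image(path)
    return img.data > 0.5, img.origin, img.spacing


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_dvf(f: VectorField, path: str | Path) -> None:
    """Write a 3-component DVF plus a JSON sidecar recording its convention.

    NIfTI output uses a (nx, ny, nz, 3) float64 volume; MetaImage uses a
    3-component vector image.  The sidecar pins units (mm), component order
    (LR, AP, SI) and the push-forward/pull-back convention so an importer
    never has to guess.
    """
    path = Path(path)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(f.u, _affine(f.origin, f.spacing)), path)
    elif path.suffix in (".mha", ".mhd"):
        im = sitk.GetImageFromArray(
            np.ascontiguousarray(np.transpose(f.u, (2, 1, 0, 3))), isVector=True
        )
        im.SetOrigin(tuple(f.origin))
        im.SetSpacing(tuple(f.spacing))
        sitk.WriteImage(im, str(path))
    else:
        raise ValueError(f"unsupported DVF format: {path.name}")
    meta = {
        "convention": f.convention,
        "units": "mm",
        "component_order": list(COMPONENT_ORDER),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_dvf(path: str | Path, convention: str | None = None) -> VectorField:
    """Read a 3-component DVF; the convention comes from the sidecar or caller.

    Raises if neither the JSON sidecar nor ``convention`` declares the
    push-forward/pull-back direction — a DVF of unknown direction is useless
    for QA and guessing silently would corrupt every downstream metric.
    """
    path = Path(path)
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    conv = convention or meta.get("convention")
    if conv is None:
        raise ValueError(
            f"{path.name}: no sidecar convention and none declared; "
            "pass convention='pushforward' or 'pullback' explicitly"
        )
    if meta.get("units", "mm") != "mm":
        raise ValueError(f"unsupported DVF units {meta['units']!r}; expected mm")

    if _is_nifti(path):
        im = nib.load(path)
        origin, spacing = _geom_from_affine(im.affine)
        u = np.asarray(im.dataobj, dtype=float)
        if u.ndim == 5:  # NIfTI vector intent stores (x, y, z, 1, 3)
            u = u[:, :, :, 0, :]
    elif path.suffix in (".mha", ".mhd"):
        im = sitk.ReadImage(str(path))
        u = np.transpose(sitk.GetArrayFromImage(im), (2, 1, 0, 3)).astype(float)
        origin, spacing = np.array(im.GetOrigin()), np.array(im.GetSpacing())
    else:
        raise ValueError(f"unsupported DVF format: {path.name}")

    order = meta.get("component_order", list(COMPONENT_ORDER))
    if tuple(order) != COMPONENT_ORDER:
        perm = [order.index(c) for c in COMPONENT_ORDER]
        u = u[..., perm]
    return VectorField(u, origin, spacing, convention=conv)
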