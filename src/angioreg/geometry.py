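"""C-arm acquisition geometry and the image/volume containers.

Frame convention (fixed throughout the package): the C-arm frame has its
origin at the isocenter, the X-ray point source at ``(0, 0, -source_to_isocenter)``
and the detector plane orthogonal to the +z axis at ``source_to_detector``
millimetres from the source.  Detector pixel (0, 0) is the top-left corner;
row index increases downward (detector +y), column index increases to the
right (detector +x); pixel indices are 0-based and the principal point
defaults to the detector center ``((rows-1)/2, (cols-1)/2)``.

A :class:`~angioreg.se3.RigidTransform` pose places the volume: it maps
volume world coordinates (the NIfTI affine's output space) into this C-arm
frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["CArmGeometry", "VolumeGrid", "Projection2D", "GeometryError"]


class GeometryError(ValueError):
    """Invalid acquisition geometry."""


@dataclass(frozen=True)
class CArmGeometry:
    """Projective C-arm camera parameters.

    Parameters
    ----------
    source_to_detector : float
        Focal length f, mm (source to detector plane).
    detector_rows, detector_cols : int
        Detector size in pixels.
    pixel_spacing : float
        Detector pixel pitch, mm/pixel (isotropic).
    principal_point : (row, col) or None
        Piercing point of the central ray, pixels; detector center if None.
    primary_angle, secondary_angle : float
        Acquisition angles in degrees (LAO/RAO about the patient longitudinal
        axis, and cranio-caudal angulation).
    source_to_isocenter : float or None
        Source-to-isocenter distance, mm; defaults to f/2.
    """

    source_to_detector: float
    detector_rows: int
    detector_cols: int
    pixel_spacing: float
    principal_point: tuple[float, float] | None = None
    primary_angle: float = 0.0
    secondary_angle: float = 0.0
    source_to_isocenter: float | None = None

    def __post_init__(self):
        if self.source_to_detector <= 0:
            raise GeometryError("source_to_detector must be > 0")
        if self.pixel_spacing <= 0:
            raise GeometryError("pixel_spacing must be > 0")
        if self.detector_rows < 2 or self.detector_cols < 2:
            raise GeometryError("detector must be at least 2x2 pixels")
        sid = self.source_to_isocenter
        if sid is None:
            object.__setattr__(self, "source_to_isocenter", self.source_to_detector / 2.0)
        elif not (0 < sid < self.source_to_detector):
            raise GeometryError("need 0 < source_to_isocenter < source_to_detector")
        if self.principal_point is None:
            pp = ((self.detector_rows - 1) / 2.0, (self.detector_cols - 1) / 2.0)
            object.__setattr__(self, "principal_point", pp)
        else:
            object.__setattr__(self, "principal_point", tuple(float(v) for v in self.principal_point))

    @property
    def source_position(self) -> np.ndarray:
        """X-ray source in the C-arm frame, mm."""
        return np.array([0.0, 0.0, -self.source_to_isocenter])

    @property
    def magnification(self) -> float:
        """Geometric magnification of the isocenter plane, f / source_to_isocenter."""
        return self.source_to_detector / self.source_to_isocenter

    def detector_pixel_positions(self) -> np.ndarray:
        """(rows*cols, 3) pixel-center positions in the C-arm frame, mm."""
        rows = np.arange(self.detector_rows, dtype=float)
        cols = np.arange(self.detector_cols, dtype=float)
        pr, pc = self.principal_point
        y = (rows - pr) * self.pixel_spacing
        x = (cols - pc) * self.pixel_spacing
        xx, yy = np.meshgrid(x, y)  # yy varies along rows
        z = self.source_to_detector - self.source_to_isocenter
        pts = np.stack([xx.ravel(), yy.ravel(), np.full(xx.size, z)], axis=1)
        return pts

    def resize(self, rows: int, cols: int) -> "CArmGeometry":
        """Same physical detector, resampled to a new pixel grid."""
        scale = self.detector_rows / rows
        if not np.isclose(self.detector_cols / cols, scale):
            raise GeometryError("resize must preserve the detector aspect ratio")
        return replace(
            self,
            detector_rows=rows,
            detector_cols=cols,
            pixel_spacing=self.pixel_spacing * scale,
            principal_point=None if self.principal_point is None else (
                self.principal_point[0] / scale,
                self.principal_point[1] / scale,
            ),
        )

    def to_json(self, path: str | Path) -> None:
        d = {
            "source_to_detector": self.source_to_detector,
            "detector_rows": self.detector_rows,
            "detector_cols": self.detector_cols,
            "pixel_spacing": self.pixel_spacing,
            "principal_point": list(self.principal_point),
            "primary_angle": self.primary_angle,
            "secondary_angle": self.secondary_angle,
            "source_to_isocenter": self.source_to_isocenter,
        }
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CArmGeometry":
        d = json.loads(Path(path).read_text())
        if "principal_point" in d and d["principal_point"] is not None:
            d["principal_point"] = tuple(d["principal_point"])
        return cls(**d)


@dataclass
class VolumeGrid:
    """3D scalar or binary voxel grid with a voxel-to-world affine (mm).

    ``values[i, j, k]`` lives at world position ``affine @ (i, j, k, 1)``.
    """

    values: np.ndarray
    voxel_to_world: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError(f"volume must be 3D with all dims >= 2, got {self.values.shape}")
        self.voxel_to_world = np.asarray(self.voxel_to_world, dtype=float)
        if self.voxel_to_world.shape != (4, 4):
            raise ValueError("voxel_to_world must be 4x4")
        if np.linalg.det(self.voxel_to_world[:3, :3]) <= 0:
            raise ValueError("voxel_to_world upper 3x3 must have positive determinant")

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths along each axis, mm."""
        return np.linalg.norm(self.voxel_to_world[:3, :3], axis=0)

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(np.unique(self.values), (0, 1)).all())

    def world_corners(self) -> np.ndarray:
        """(8, 3) world coordinates of the voxel-grid bounding-box corners."""
        d, h, w = self.values.shape
        idx = np.array([(i, j, k) for i in (0, d - 1) for j in (0, h - 1) for k in (0, w - 1)], float)
        return (self.voxel_to_world[:3, :3] @ idx.T + self.voxel_to_world[:3, 3:4]).T

    def world_to_voxel_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.voxel_to_world)

    @classmethod
    def centered(cls, values: np.ndarray, spacing: float | tuple = 1.0) -> "VolumeGrid":
        """Grid with isotropic (or per-axis) spacing and world origin at its center."""
        values = np.asarray(values)
        sp = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
        affine = np.diag([*sp, 1.0])
        affine[:3, 3] = -sp * (np.asarray(values.shape) - 1) / 2.0
        return cls(values=values, voxel_to_world=affine)

    def to_nifti(self, path: str | Path) -> None:
        import nibabel as nib

        img = nib.Nifti1Image(np.asarray(self.values, dtype=np.float32), self.voxel_to_world)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "VolumeGrid":
        import nibabel as nib

        img = nib.load(str(path))
        return cls(values=np.asarray(img.get_fdata()), voxel_to_world=np.asarray(img.affine))


@dataclass
class Projection2D:
    """A 2D detector-space image: DRR, binary DSA segmentation, or MinIP."""

    values: np.ndarray
    pixel_spacing: float = 1.0
    kind: str = "drr"

    KINDS = ("drr", "dsa_segmentation", "minip")

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"projection must be 2D, got shape {self.values.shape}")
        if self.kind not in self.KINDS:
            raise ValueError(f"kind must be one of {self.KINDS}, got {self.kind!r}")
        if self.kind == "dsa_segmentation" and not np.isin(np.unique(self.values), (0, 1)).all():
            raise ValueError("dsa_segmentation images must be binary {0, 1}")

    @property
    def shape(self):
        return self.values.shape

    def to_png(self, path: str | Path) -> None:
        import imageio.v3 as iio

        v = np.asarray(self.values, dtype=float)
        vmax = v.max()
        scaled = (v / vmax * 65535.0) if vmax > 0 else v
        iio.imwrite(str(path), scaled.astype(np.uint16))

    def to_nifti(self, path: str | Path) -> None:
        import nibabel as nib

        affine = np.diag([self.pixel_spacing, self.pixel_spacing, 1.0, 1.0])
        nib.save(nib.Nifti1Image(np.asarray(self.values, np.float32)[..., None], affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, kind: str = "drr") -> "Projection2D":
        import nibabel as nib

        img = nib.load(str(path))
        vals = np.squeeze(np.asarray(img.get_fdata()))
        if vals.ndim != 2:
            raise ValueError(f"expected a single 2D image, got shape {vals.shape}")
        spacing = float(np.linalg.norm(img.affine[:3, 0]))
        return cls(values=vals, pixel_spacing=spacing, kind=kind)

    @classmethod
    def from_png(cls, path: str | Path, pixel_spacing: float = 1.0, kind: str = "drr") -> "Projection2D":
        import imageio.v3 as iio

        v = np.asarray(iio.imread(str(path)), dtype=float)
        if v.ndim == 3:  # collapse RGB(A)
            v = v[..., :3].mean(axis=2)
        if kind == "dsa_segmentation":
            v = (v > 0.5 * v.max()).astype(float) if v.max() > 0 else v
        return cls(values=v, pixel_spacing=pixel_spacing, kind=kind)


def load_frames(path: str | Path, pixel_spacing: float = 1.0) -> list[Projection2D]:
    """Read a multi-frame DSA run: multi-page TIFF or 3D NIfTI (frame-major)."""
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(str(path))
    else:
        import nibabel as nib

        arr = np.asarray(nib.load(str(path)).get_fdata())
    arr = np.atleast_3d(arr)
    if arr.ndim != 3:
        raise ValueError(f"expected a stack of 2D frames, got shape {arr.shape}")
    return [Projection2D(values=arr[i].astype(float), pixel_spacing=pixel_spacing, kind="drr") for i in range(arr.shape[0])]


def save_frames(frames: list[Projection2D], path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(str(path), np.stack([np.asarray(f.values, np.float32) for f in frames]))
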