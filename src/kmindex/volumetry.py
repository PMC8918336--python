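"""Label-map volumetry: turn 3-D voxel label maps into perfusion volumes.

A single integer label map encodes the nested perfusion regions:

    0 outside the scan, 1 MIP coverage, 2 MTT (perfused brain),
    3 penumbra, 4 infarct core

Higher labels nest inside lower coverage (core inside penumbra-or-core,
both inside the MTT brain, inside the MIP coverage), which makes the
perfusion-volume invariants hold by construction. Voxel volumes are plain
voxel counts times the spacing product; no partial-volume weighting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import PerfusionVolumes, ValidationError

__all__ = [
    "LABEL_OUTSIDE",
    "LABEL_MIP",
    "LABEL_MTT",
    "LABEL_PENUMBRA",
    "LABEL_CORE",
    "LabelMap",
    "RatioVolumes",
    "mask_volume",
    "extract_volumes",
    "conceptual_ratios",
    "merge_masks",
]

LABEL_OUTSIDE = 0
LABEL_MIP = 1
LABEL_MTT = 2
LABEL_PENUMBRA = 3
LABEL_CORE = 4

_LABEL_NAMES = {
    LABEL_OUTSIDE: "outside",
    LABEL_MIP: "MIP coverage",
    LABEL_MTT: "MTT brain",
    LABEL_PENUMBRA: "penumbra",
    LABEL_CORE: "infarct core",
}


@dataclass(frozen=True)
class LabelMap:
    """3-D integer label volume plus voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None  # orientation passed through, never interpreted

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValidationError(f"label map must be 3-D, got shape {data.shape}")
        if not np.issubdtype(data.dtype, np.integer):
            raise ValidationError(f"label map must be integer-typed, got {data.dtype}")
        if data.size and (data.min() < 0 or data.max() > LABEL_CORE):
            raise ValidationError("labels must lie in {0, 1, 2, 3, 4}")
        if len(self.spacing) != 3 or any(not (s > 0 and np.isfinite(s)) for s in self.spacing):
            raise ValidationError(f"voxel spacing must be three positive reals, got {self.spacing}")
        object.__setattr__(self, "data", data)

    @property
    def voxel_volume_cm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    @classmethod
    def from_nifti(cls, path: str | Path) -> "LabelMap":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if not np.issubdtype(data.dtype, np.integer):
            rounded = np.rint(data)
            if not np.allclose(data, rounded, atol=1e-6):
                raise ValidationError(f"{path}: voxel values are not integer labels")
            data = rounded.astype(np.int16)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(data=data, spacing=spacing, affine=np.asarray(img.affine))

    def to_nifti(self, path: str | Path) -> None:
        affine = self.affine if self.affine is not None else np.diag([*self.spacing, 1.0])
        img = nib.Nifti1Image(self.data.astype(np.int16), affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))


def mask_volume(label_map: LabelMap, labels: "int | set[int] | frozenset[int]") -> float:
    """Volume in cm^3 of all voxels whose label is in ``labels``."""
    if isinstance(labels, int):
        labels = {labels}
    count = int(np.isin(label_map.data, list(labels)).sum())
    return count * label_map.voxel_volume_cm3


def extract_volumes(label_map: LabelMap) -> PerfusionVolumes:
    """Perfusion volumes from a label map.

    MIP coverage is ``label >= 1``, the MTT brain ``label >= 2``, penumbra
    exactly label 3 and core exactly label 4 (disjoint convention).
    """
    data = label_map.data
    vv = label_map.voxel_volume_cm3
    v_mip = int((data >= LABEL_MIP).sum()) * vv
    v_mtt = int((data >= LABEL_MTT).sum()) * vv
    v_pen = int((data == LABEL_PENUMBRA).sum()) * vv
    v_core = int((data == LABEL_CORE).sum()) * vv
    try:
        return PerfusionVolumes(v_core=v_core, v_penumbra=v_pen, v_mip=v_mip, v_mtt=v_mtt)
    except ValidationError as exc:  # pragma: no cover - unreachable for valid maps
        raise ValidationError(f"label map violates volume nesting: {exc}") from exc


def merge_masks(
    mip: np.ndarray,
    mtt: np.ndarray,
    penumbra: np.ndarray,
    core: np.ndarray,
    spacing: tuple[float, float, float],
) -> LabelMap:
    """Merge four boolean masks into one label map, enforcing strict nesting.

    Raises a validation error naming the offending pair if any voxel of an
    inner region falls outside its enclosing region.
    """
    masks = {
        LABEL_MIP: np.asarray(mip, dtype=bool),
        LABEL_MTT: np.asarray(mtt, dtype=bool),
        LABEL_PENUMBRA: np.asarray(penumbra, dtype=bool),
        LABEL_CORE: np.asarray(core, dtype=bool),
    }
    shapes = {m.shape for m in masks.values()}
    if len(shapes) != 1:
        raise ValidationError(f"mask shapes differ: {sorted(shapes)}")
    pairs = [
        (LABEL_CORE, masks[LABEL_CORE], LABEL_MTT, masks[LABEL_MTT]),
        (LABEL_PENUMBRA, masks[LABEL_PENUMBRA], LABEL_MTT, masks[LABEL_MTT]),
        (LABEL_MTT, masks[LABEL_MTT], LABEL_MIP, masks[LABEL_MIP]),
    ]
    for inner_label, inner, outer_label, outer in pairs:
        if np.any(inner & ~outer):
            raise ValidationError(
                f"nesting violation: {_LABEL_NAMES[inner_label]} voxels outside "
                f"{_LABEL_NAMES[outer_label]} region"
            )
    if np.any(masks[LABEL_PENUMBRA] & masks[LABEL_CORE]):
        raise ValidationError("nesting violation: penumbra and infarct core masks overlap")
    data = np.zeros(masks[LABEL_MIP].shape, dtype=np.int16)
    data[masks[LABEL_MIP]] = LABEL_MIP
    data[masks[LABEL_MTT]] = LABEL_MTT
    data[masks[LABEL_PENUMBRA]] = LABEL_PENUMBRA
    data[masks[LABEL_CORE]] = LABEL_CORE
    return LabelMap(data=data, spacing=spacing)


@dataclass(frozen=True)
class RatioVolumes:
    """Conceptual volume ratios relative to the true intracranial volume.

    B = 1 - (vs + vv) / iv is the occupied-space (parenchyma) fraction,
    I = vc / iv and P = vp / iv the core and penumbra fractions.
    """

    iv: float
    vs: float
    vv: float
    vc: float
    vp: float
    B: float
    I: float
    P: float


def conceptual_ratios(iv: float, vs: float, vv: float, vc: float, vp: float) -> RatioVolumes:
    """Dimensionless ratios from explicit CSF-space and lesion volumes."""
    if not (iv > 0):
        raise ValidationError(f"intracranial volume must be > 0, got {iv!r}")
    for name, v in (("vs", vs), ("vv", vv), ("vc", vc), ("vp", vp)):
        if v < 0:
            raise ValidationError(f"{name} must be >= 0, got {v!r}")
    if vs + vv > iv:
        raise ValidationError("CSF spaces (vs + vv) cannot exceed intracranial volume")
    return RatioVolumes(
        iv=iv, vs=vs, vv=vv, vc=vc, vp=vp,
        B=1.0 - (vs + vv) / iv, I=vc / iv, P=vp / iv,
    )
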