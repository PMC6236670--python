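"""NIfTI-1 input/output and the shared in-memory data model.

Every stage of the pipeline consumes or produces one of the containers
defined here: a single 3D :class:`ImageVolume`, an ordered multi-frame
:class:`AcquisitionSeries` (diffusion b-value series or inversion-recovery
TI series), a static :class:`PetFrame`, an integer :class:`AtlasLabels`
volume with a region/hemisphere legend, and a fitted :class:`ParametricMap`.

Conventions
-----------
* NIfTI-1 (``.nii`` / ``.nii.gz``) is the only volume format; JSON sidecars
  carry acquisition metadata (b-values in s/mm², inversion times in seconds,
  injected activity in MBq, body weight in g).
* Voxel coordinates are 0-based array indices.  Hemisphere assignment comes
  only from the atlas legend, never from a midline heuristic.
* All times are seconds internally.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "REGIONS",
    "HEMISPHERES",
    "MAP_QUANTITIES",
    "ImageVolume",
    "AcquisitionSeries",
    "PetFrame",
    "AtlasLabels",
    "ParametricMap",
    "read_volume",
    "read_series",
    "read_pet_frame",
    "write_volume",
    "write_series",
    "write_pet_frame",
    "write_map",
    "read_map",
    "write_atlas",
    "read_atlas",
]

#: Canonical brain regions carried by the atlas legend.
REGIONS = (
    "thalamus",
    "cortex",
    "hypothalamus",
    "hippocampus",
    "cerebellum",
    "amygdala",
    "striatum",
    "ventricles",
)

HEMISPHERES = ("left", "right")

#: Quantities a ParametricMap may carry, with their units.
MAP_QUANTITIES = {
    "ADC": "mm^2/s",
    "T1": "s",
    "R1": "1/s",
    "K1": "1/s",
    "SUV": "g/mL",
}


def _check_finite_affine(affine: np.ndarray) -> None:
    if not np.all(np.isfinite(affine)):
        raise ValueError("NIfTI affine contains non-finite entries")


@dataclass
class ImageVolume:
    """A single 3D image on a regular grid.

    Parameters
    ----------
    voxels
        3D array of real intensities.  NaN is allowed only where an explicit
        mask excludes voxels (parametric maps); raw images must be finite.
    voxel_size
        Edge length of a voxel along each axis, in mm; strictly positive.
    frame_of_reference
        Free-form identifier tying volumes acquired on the same grid.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    frame_of_reference: str = "unknown"
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        if min(self.voxels.shape) < 1:
            raise ValueError("all voxel dimensions must be >= 1")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)  # type: ignore[assignment]
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three strictly positive lengths")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])
        _check_finite_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def same_grid(self, other: "ImageVolume | AtlasLabels") -> bool:
        other_shape = other.labels.shape if isinstance(other, AtlasLabels) else other.shape
        other_vs = other.voxel_size
        return self.shape == tuple(other_shape) and np.allclose(self.voxel_size, other_vs)


@dataclass
class AcquisitionSeries:
    """An ordered stack of frames sharing one grid, indexed by an
    acquisition variable (b-value in s/mm² or inversion time in seconds).

    Frames are kept sorted by ``axis_values``; :func:`read_series` re-sorts
    on load so the series is invariant to on-disk frame permutation.
    """

    frames: list[ImageVolume]
    axis_kind: str  # {"bvalue", "inversion_time", "static"}
    axis_values: np.ndarray
    direction_id: int | None = None  # 1..3 for DWI
    label_state: str | None = None  # {"selective", "nonselective"} for FAIR

    def __post_init__(self) -> None:
        if self.axis_kind not in ("bvalue", "inversion_time", "static"):
            raise ValueError(f"unknown axis_kind {self.axis_kind!r}")
        self.axis_values = np.asarray(self.axis_values, dtype=float)
        if len(self.axis_values) != len(self.frames):
            raise ValueError(
                f"{len(self.frames)} frames but {len(self.axis_values)} axis values"
            )
        if np.any(self.axis_values < 0):
            raise ValueError("axis values must be non-negative")
        if self.label_state is not None and self.label_state not in (
            "selective",
            "nonselective",
        ):
            raise ValueError(f"unknown label_state {self.label_state!r}")
        if self.direction_id is not None and self.direction_id not in (1, 2, 3):
            raise ValueError("direction_id must be 1, 2 or 3")
        ref = self.frames[0]
        for fr in self.frames[1:]:
            if not fr.same_grid(ref):
                raise ValueError("all frames must share shape and voxel_size")
        order = np.argsort(self.axis_values, kind="stable")
        if not np.all(order == np.arange(len(order))):
            self.frames = [self.frames[i] for i in order]
            self.axis_values = self.axis_values[order]
        if self.axis_kind != "static" and len(self.axis_values) > 1:
            if np.any(np.diff(self.axis_values) <= 0):
                raise ValueError("axis values must be strictly increasing after sorting")

    @property
    def data(self) -> np.ndarray:
        """Frames stacked along a trailing axis, shape (nx, ny, nz, nframes)."""
        return np.stack([f.voxels for f in self.frames], axis=-1)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames[0].shape

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return self.frames[0].voxel_size


@dataclass
class PetFrame:
    """A static PET frame with the quantities entering the SUV formula
    SUV = A_conc / (A_inj / BW).

    ``injected_activity`` is in MBq, decay-corrected to a stated reference
    time; when ``injection_to_scan_interval`` (minutes) is given, the SUV
    step corrects the injected activity to scan start with the F-18
    half-life.  ``activity_concentration`` voxels are kBq/mL, body weight g.
    """

    activity_concentration: ImageVolume
    injected_activity: float
    body_weight: float
    injection_to_scan_interval: float | None = None

    def __post_init__(self) -> None:
        if self.injected_activity <= 0:
            raise ValueError("injected_activity must be > 0")
        if self.body_weight <= 0:
            raise ValueError("body_weight must be > 0")


@dataclass
class AtlasLabels:
    """Integer label volume plus a legend mapping label -> (region, hemisphere).

    Background is label 0.  Every non-zero voxel value must appear in the
    legend and each (region, hemisphere) pair maps to exactly one label.
    """

    labels: np.ndarray
    legend: dict[int, tuple[str, str]]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be an integer volume")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"labels {sorted(missing)} present in volume but not in legend")
        pairs = list(self.legend.values())
        if len(pairs) != len(set(pairs)):
            raise ValueError("each (region, hemisphere) pair must map to exactly one label")
        for region, hemi in pairs:
            if region not in REGIONS:
                raise ValueError(f"unknown region {region!r}")
            if hemi not in HEMISPHERES:
                raise ValueError(f"unknown hemisphere {hemi!r}")

    def label_of(self, region: str, hemisphere: str) -> int:
        for lab, (r, h) in self.legend.items():
            if (r, h) == (region, hemisphere):
                return lab
        raise KeyError((region, hemisphere))

    def region_mask(self, region: str, hemisphere: str) -> np.ndarray:
        return self.labels == self.label_of(region, hemisphere)

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0


_RANGE_CHECKS = {
    "ADC": (0.0, 4e-3),
    "T1": (0.0, 10.0),
    "SUV": (0.0, np.inf),
}


@dataclass
class ParametricMap:
    """A fitted 3D map of one quantity with a validity mask.

    ``values`` must be finite wherever ``mask`` is true; outside the mask
    values are unspecified (written to disk as NaN).  ``fit_diagnostics``
    optionally carries the per-voxel residual norm; ``clamped`` marks voxels
    whose fitted value was clamped into the physical range.
    """

    values: np.ndarray
    quantity: str
    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    fit_diagnostics: np.ndarray | None = None
    clamped: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.quantity or self.quantity not in MAP_QUANTITIES:
            raise ValueError(
                f"quantity must be one of {sorted(MAP_QUANTITIES)}, got {self.quantity!r}"
            )
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        inmask = self.values[self.mask]
        if not np.all(np.isfinite(inmask)):
            raise ValueError("in-mask values must be finite")
        lo, hi = _RANGE_CHECKS.get(self.quantity, (-np.inf, np.inf))
        if inmask.size and (inmask.min() < lo or inmask.max() > hi):
            raise ValueError(
                f"{self.quantity} values outside physical range [{lo}, {hi}]"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def units(self) -> str:
        return MAP_QUANTITIES[self.quantity]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _load_nifti(path: str | os.PathLike) -> nib.Nifti1Image:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad payloads
        raise ValueError(f"{path}: not a readable NIfTI file ({exc})") from exc
    _check_finite_affine(img.affine)
    return img


def read_volume(path: str | os.PathLike) -> ImageVolume:
    """Read a single 3D NIfTI-1 volume.

    4D files are rejected here; use :func:`read_series` for those.
    """
    img = _load_nifti(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(
        voxels=np.asarray(data, dtype=float),
        voxel_size=zooms,
        frame_of_reference=str(path),
        affine=np.asarray(img.affine, dtype=float),
    )


def write_volume(vol: ImageVolume, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(vol.voxels.astype(np.float32), vol.affine)
    img.header.set_zooms(vol.voxel_size)
    nib.save(img, str(path))


def _sidecar_path(path: str | os.PathLike) -> str:
    p = str(path)
    for ext in (".nii.gz", ".nii"):
        if p.endswith(ext):
            return p[: -len(ext)] + ".json"
    return p + ".json"


def read_series(
    path: str | os.PathLike, sidecar: str | os.PathLike | None = None
) -> AcquisitionSeries:
    """Read a 4D NIfTI + JSON sidecar as an :class:`AcquisitionSeries`.

    The sidecar must hold ``AxisKind`` (``bvalue``/``inversion_time``) and
    ``AxisValues`` (s/mm² or seconds, one per frame, file order), plus
    optionally ``DirectionId`` (DWI) or ``LabelState`` (FAIR).  Frames are
    re-sorted by axis value on load.
    """
    img = _load_nifti(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D series, got shape {data.shape}")
    sidecar = _sidecar_path(path) if sidecar is None else sidecar
    with open(sidecar) as fh:
        meta = json.load(fh)
    axis_kind = meta.get("AxisKind")
    if axis_kind not in ("bvalue", "inversion_time", "static"):
        raise ValueError(f"{sidecar}: unknown AxisKind {axis_kind!r}")
    axis_values = np.asarray(meta.get("AxisValues", []), dtype=float)
    if len(axis_values) != data.shape[3]:
        raise ValueError(
            f"{sidecar}: {len(axis_values)} axis values for {data.shape[3]} frames"
        )
    if np.any(axis_values < 0):
        raise ValueError(f"{sidecar}: negative axis values")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    frames = [
        ImageVolume(
            voxels=np.asarray(data[..., k], dtype=float),
            voxel_size=zooms,
            frame_of_reference=str(path),
            affine=np.asarray(img.affine, dtype=float),
        )
        for k in range(data.shape[3])
    ]
    return AcquisitionSeries(
        frames=frames,
        axis_kind=axis_kind,
        axis_values=axis_values,
        direction_id=meta.get("DirectionId"),
        label_state=meta.get("LabelState"),
    )


def write_series(series: AcquisitionSeries, path: str | os.PathLike) -> None:
    """Write a series as 4D NIfTI plus a JSON sidecar next to it."""
    stack = series.data.astype(np.float32)
    affine = series.frames[0].affine
    img = nib.Nifti1Image(stack, affine)
    img.header.set_zooms(tuple(series.voxel_size) + (1.0,))
    nib.save(img, str(path))
    meta: dict = {
        "AxisKind": series.axis_kind,
        "AxisValues": [float(v) for v in series.axis_values],
    }
    if series.direction_id is not None:
        meta["DirectionId"] = int(series.direction_id)
    if series.label_state is not None:
        meta["LabelState"] = series.label_state
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_pet_frame(
    path: str | os.PathLike, sidecar: str | os.PathLike | None = None
) -> PetFrame:
    """Read a PET activity-concentration volume (kBq/mL) + its sidecar.

    Sidecar keys (BIDS-flavoured): ``InjectedRadioactivity`` (MBq),
    ``BodyWeight`` (g), optional ``InjectionToScanInterval`` (min).
    """
    vol = read_volume(path)
    sidecar = _sidecar_path(path) if sidecar is None else sidecar
    with open(sidecar) as fh:
        meta = json.load(fh)
    return PetFrame(
        activity_concentration=vol,
        injected_activity=float(meta["InjectedRadioactivity"]),
        body_weight=float(meta["BodyWeight"]),
        injection_to_scan_interval=meta.get("InjectionToScanInterval"),
    )


def write_pet_frame(frame: PetFrame, path: str | os.PathLike) -> None:
    write_volume(frame.activity_concentration, path)
    meta = {
        "InjectedRadioactivity": frame.injected_activity,
        "InjectedRadioactivityUnits": "MBq",
        "BodyWeight": frame.body_weight,
        "BodyWeightUnits": "g",
        "Units": "kBq/mL",
    }
    if frame.injection_to_scan_interval is not None:
        meta["InjectionToScanInterval"] = frame.injection_to_scan_interval
        meta["InjectionToScanIntervalUnits"] = "min"
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def write_map(pmap: ParametricMap, path: str | os.PathLike) -> None:
    """Write a parametric map as NIfTI (masked-out voxels as NaN) + sidecar."""
    out = np.where(pmap.mask, pmap.values, np.nan).astype(np.float32)
    img = nib.Nifti1Image(out, np.diag(list(pmap.voxel_size) + [1.0]))
    img.header.set_zooms(pmap.voxel_size)
    img.header["descrip"] = f"{pmap.quantity} [{pmap.units}]".encode()
    nib.save(img, str(path))
    meta = {
        "Quantity": pmap.quantity,
        "Units": pmap.units,
        "MaskedVoxels": int(pmap.mask.sum()),
        "ClampedVoxels": int(pmap.clamped.sum()) if pmap.clamped is not None else 0,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_map(path: str | os.PathLike) -> ParametricMap:
    vol = read_volume(path)
    sidecar = _sidecar_path(path)
    with open(sidecar) as fh:
        meta = json.load(fh)
    values = vol.voxels
    mask = np.isfinite(values)
    return ParametricMap(
        values=np.where(mask, values, 0.0),
        quantity=meta["Quantity"],
        mask=mask,
        voxel_size=vol.voxel_size,
    )


def write_atlas(atlas: AtlasLabels, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(
        atlas.labels.astype(np.int16), np.diag(list(atlas.voxel_size) + [1.0])
    )
    img.header.set_zooms(atlas.voxel_size)
    nib.save(img, str(path))
    legend = {str(k): list(v) for k, v in atlas.legend.items()}
    with open(_sidecar_path(path), "w") as fh:
        json.dump(legend, fh, indent=1)


def read_atlas(path: str | os.PathLike) -> AtlasLabels:
    img = _load_nifti(path)
    data = np.asanyarray(img.dataobj)
    with open(_sidecar_path(path)) as fh:
        legend_raw = json.load(fh)
    legend = {int(k): (v[0], v[1]) for k, v in legend_raw.items()}
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return AtlasLabels(labels=np.asarray(data).astype(np.int32), legend=legend, voxel_size=zooms)
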