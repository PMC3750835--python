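"""Reading, writing and validating the volumetric formats of the pipeline.

Volumes travel as NIfTI-1 (``.nii`` / ``.nii.gz``) via nibabel; b-values as
FSL-style whitespace-separated ``.bval`` sidecars (one number per volume of
the 4D stack, in s/mm^2); derived-map provenance as a JSON sidecar next to
the map.  Voxel indices are 0-based and the 4th NIfTI dimension is the
acquisition axis.  Readers reject malformed input rather than silently
reinterpreting it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import nibabel as nib
import numpy as np

from .acquisition import validate_bvalues
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_LEGEND = {0: "background", 1: "healthy", 2: "cancer"}


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValidationError(f"spacing must be 3 positive values, got {spacing}")
    return spacing


@dataclass
class DWIStack:
    """A 4D magnitude DWI volume with aligned b-values.

    ``signal`` is indexed ``(x, y, z, acquisition)`` and must be
    nonnegative (magnitude MR data); ``bvalues`` has one entry per
    acquisition, in s/mm^2; ``spacing`` is the voxel size in mm per
    spatial axis; ``affine`` (optional) maps voxel indices to physical
    space and is carried through unchanged.
    """

    signal: np.ndarray
    bvalues: list[float]
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 4:
            raise ValidationError(f"signal must be 4D, got {self.signal.ndim}D")
        if np.any(self.signal < 0):
            raise ValidationError("signal must be nonnegative (magnitude data)")
        self.bvalues = validate_bvalues(self.bvalues)
        if len(self.bvalues) != self.signal.shape[3]:
            raise ValidationError(
                f"{len(self.bvalues)} b-values for {self.signal.shape[3]} volumes"
            )
        self.spacing = _check_spacing(self.spacing)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclass
class ScalarMap:
    """A 3D derived map (CDI or ADC) with provenance metadata.

    ``provenance`` records the map kind and the parameters that produced
    it (b-range or omega set, neighborhood, normalisation, ...).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    provenance: dict[str, Any] = field(default_factory=dict)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValidationError(f"map values must be 3D, got {self.values.ndim}D")
        self.spacing = _check_spacing(self.spacing)


@dataclass
class LabelMap:
    """A 3D integer tissue annotation with a label legend."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    legend: dict[int, str] = field(default_factory=dict)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValidationError(f"labels must be 3D, got {labels.ndim}D")
        if not np.issubdtype(labels.dtype, np.integer):
            rounded = np.rint(labels)
            if not np.allclose(labels, rounded, atol=0, rtol=0):
                raise ValidationError("label volume contains non-integer values")
            labels = rounded.astype(np.int32)
        self.labels = labels.astype(np.int32, copy=False)
        self.spacing = _check_spacing(self.spacing)
        present = set(int(v) for v in np.unique(self.labels))
        if not self.legend:
            self.legend = {
                code: DEFAULT_LEGEND.get(code, f"label_{code}") for code in present
            }
        missing = present - set(self.legend)
        if missing:
            raise ValidationError(f"labels {sorted(missing)} missing from legend")


def _default_affine(spacing) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    return aff


def _spacing_from_img(img) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def read_bvals(path: str | Path) -> list[float]:
    """Parse an FSL-style .bval sidecar (whitespace-separated numbers)."""
    text = Path(path).read_text()
    tokens = text.split()
    if not tokens:
        raise FormatError(f"empty .bval file: {path}")
    try:
        values = [float(t) for t in tokens]
    except ValueError as exc:
        raise FormatError(f"non-numeric entry in {path}: {exc}") from exc
    return validate_bvalues(values)


def write_bvals(bvalues, path: str | Path) -> None:
    """Write b-values as a single whitespace-separated line."""
    Path(path).write_text(" ".join(f"{b:g}" for b in bvalues) + "\n")


def read_dwi(volume_path: str | Path, bval_path: str | Path) -> DWIStack:
    """Load a 4D DWI NIfTI volume and its .bval sidecar as a DWIStack.

    Negative voxels (possible after scanner-side interpolation) are
    clamped to zero; the clamped count is logged.
    """
    img = nib.load(str(volume_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise FormatError(f"{volume_path} is {data.ndim}D; expected a 4D DWI volume")
    bvalues = read_bvals(bval_path)
    if len(bvalues) != data.shape[3]:
        raise FormatError(
            f"{volume_path} has {data.shape[3]} volumes but {bval_path} "
            f"has {len(bvalues)} b-values"
        )
    n_neg = int(np.count_nonzero(data < 0))
    if n_neg:
        logger.warning("clamped %d negative voxels to 0 in %s", n_neg, volume_path)
        data = np.clip(data, 0, None)
    return DWIStack(
        signal=data,
        bvalues=bvalues,
        spacing=_spacing_from_img(img),
        affine=np.asarray(img.affine),
    )


def write_dwi(stack: DWIStack, volume_path: str | Path, bval_path: str | Path) -> None:
    """Write a DWIStack as a 4D NIfTI volume plus .bval sidecar."""
    affine = stack.affine if stack.affine is not None else _default_affine(stack.spacing)
    img = nib.Nifti1Image(stack.signal.astype(np.float32), affine)
    img.header.set_zooms((*stack.spacing, 1.0))
    nib.save(img, str(volume_path))
    write_bvals(stack.bvalues, bval_path)


def _sidecar_path(path: str | Path) -> Path:
    """JSON sidecar path for a NIfTI file (strips .nii / .nii.gz)."""
    p = Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    return p.with_name(name + ".json")


def write_map(scalar_map: ScalarMap, path: str | Path) -> None:
    """Write a derived map as float32 NIfTI-1 plus a JSON provenance sidecar.

    The provenance is also serialised into the NIfTI ``descrip`` field,
    truncated to the format's 80-byte limit.
    """
    affine = (
        scalar_map.affine
        if scalar_map.affine is not None
        else _default_affine(scalar_map.spacing)
    )
    img = nib.Nifti1Image(scalar_map.values.astype(np.float32), affine)
    img.header.set_zooms(scalar_map.spacing)
    descrip = json.dumps(scalar_map.provenance, sort_keys=True, default=str)
    img.header["descrip"] = descrip.encode()[:79]
    nib.save(img, str(path))
    _sidecar_path(path).write_text(
        json.dumps(scalar_map.provenance, indent=2, sort_keys=True, default=str) + "\n"
    )


def read_map(path: str | Path) -> ScalarMap:
    """Load a derived map; provenance comes from the JSON sidecar if present."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise FormatError(f"{path} is {data.ndim}D; expected a 3D map")
    sidecar = _sidecar_path(path)
    provenance: dict[str, Any] = {}
    if sidecar.exists():
        provenance = json.loads(sidecar.read_text())
    return ScalarMap(
        values=data,
        spacing=_spacing_from_img(img),
        provenance=provenance,
        affine=np.asarray(img.affine),
    )


def read_labels(path: str | Path, legend: Mapping[int, str] | None = None) -> LabelMap:
    """Load an integer label volume; non-integer voxel values are rejected."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise FormatError(f"{path} is {data.ndim}D; expected a 3D label volume")
    return LabelMap(
        labels=data,
        spacing=_spacing_from_img(img),
        legend=dict(legend) if legend else {},
        affine=np.asarray(img.affine),
    )


def write_labels(label_map: LabelMap, path: str | Path) -> None:
    """Write a LabelMap as an int16 NIfTI-1 volume."""
    affine = (
        label_map.affine
        if label_map.affine is not None
        else _default_affine(label_map.spacing)
    )
    img = nib.Nifti1Image(label_map.labels.astype(np.int16), affine)
    img.header.set_zooms(label_map.spacing)
    nib.save(img, str(path))


def file_checksum(path: str | Path) -> str:
    """SHA-256 checksum of a file, for provenance records."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
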