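"""Synthetic multi-b-value DWI phantoms with known ground truth.

The phantom is a prostate-like scene on a regular voxel grid: an
ellipsoidal gland of healthy tissue containing spherical lesions with
restricted diffusion (lower diffusivity than the surrounding gland),
embedded in a fluid-like background.  Each tissue decays
mono-exponentially with b,

    S(b) = S0 * exp(-b * D),

and the observed magnitude signal is Rician,

    R = sqrt((S + e1)^2 + e2^2),   e1, e2 ~ N(0, sigma^2) independent,

which is the standard magnitude-MR noise model.  Geometry is specified in
physical millimetres against voxel-centre coordinates (index * spacing),
so the same spec scales across grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np

from .acquisition import validate_bvalues
from .dwi_io import DEFAULT_LEGEND, DWIStack, LabelMap
from .errors import ValidationError


@dataclass(frozen=True)
class TissueParams:
    """Mono-exponential signal parameters of one tissue class.

    S0 is the baseline signal at b=0 (arbitrary units, > 0); D is the
    diffusivity in mm^2/s (>= 0).
    """

    S0: float
    D: float

    def __post_init__(self) -> None:
        if not (self.S0 > 0):
            raise ValidationError(f"S0 must be > 0, got {self.S0}")
        if not (self.D >= 0):
            raise ValidationError(f"D must be >= 0, got {self.D}")


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: centre in voxel indices, semi-axes in mm."""

    center: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]


@dataclass(frozen=True)
class Lesion:
    """Sphere: centre in voxel indices, radius in mm, tissue label code."""

    center: tuple[float, float, float]
    radius_mm: float
    label: int


HEALTHY_LABEL = 1
CANCER_LABEL = 2


@dataclass
class PhantomSpec:
    """Complete description of a synthetic DWI acquisition.

    Invariants: every lesion sphere lies entirely inside the gland
    ellipsoid; every label referenced by the geometry has TissueParams;
    in default-style specs cancer diffusivity is strictly below healthy
    diffusivity (restricted diffusion).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    bvalues: list[float]
    tissues: dict[int, TissueParams]
    gland: Ellipsoid
    lesions: list[Lesion]
    noise_sigma: float
    seed: int

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValidationError(f"shape must be 3 positive ints, got {self.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")
        self.bvalues = validate_bvalues(self.bvalues)
        if self.noise_sigma < 0:
            raise ValidationError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        referenced = {0, HEALTHY_LABEL} | {les.label for les in self.lesions}
        missing = referenced - set(self.tissues)
        if missing:
            raise ValidationError(f"labels {sorted(missing)} have no TissueParams")
        for les in self.lesions:
            self._check_lesion_inside_gland(les)
        if HEALTHY_LABEL in self.tissues and CANCER_LABEL in self.tissues:
            if not (self.tissues[CANCER_LABEL].D < self.tissues[HEALTHY_LABEL].D):
                raise ValidationError(
                    "cancer diffusivity must be strictly below healthy diffusivity"
                )

    def _check_lesion_inside_gland(self, les: Lesion) -> None:
        # The sphere fits if the ellipsoid shrunk by the radius still
        # contains its centre (conservative for unequal semi-axes).
        shrunk = tuple(a - les.radius_mm for a in self.gland.semiaxes_mm)
        if any(a <= 0 for a in shrunk):
            raise ValidationError(
                f"lesion radius {les.radius_mm} mm exceeds a gland semi-axis"
            )
        offset_mm = [
            (les.center[k] - self.gland.center[k]) * self.spacing[k] for k in range(3)
        ]
        r2 = sum((o / a) ** 2 for o, a in zip(offset_mm, shrunk))
        if r2 > 1.0:
            raise ValidationError(
                f"lesion at {les.center} (r={les.radius_mm} mm) extends outside the gland"
            )


def _coordinate_grids(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def build_labels(spec: PhantomSpec) -> LabelMap:
    """Rasterise the phantom geometry into an integer label volume."""
    xx, yy, zz = _coordinate_grids(spec.shape, spec.spacing)
    labels = np.zeros(spec.shape, dtype=np.int32)

    gc = [spec.gland.center[k] * spec.spacing[k] for k in range(3)]
    ga = spec.gland.semiaxes_mm
    inside_gland = (
        ((xx - gc[0]) / ga[0]) ** 2
        + ((yy - gc[1]) / ga[1]) ** 2
        + ((zz - gc[2]) / ga[2]) ** 2
    ) <= 1.0
    labels[inside_gland] = HEALTHY_LABEL

    for les in spec.lesions:
        lc = [les.center[k] * spec.spacing[k] for k in range(3)]
        inside = (
            (xx - lc[0]) ** 2 + (yy - lc[1]) ** 2 + (zz - lc[2]) ** 2
        ) <= les.radius_mm**2
        labels[inside] = les.label

    legend = {
        code: DEFAULT_LEGEND.get(code, f"label_{code}")
        for code in sorted(set(np.unique(labels)) | set(spec.tissues))
    }
    return LabelMap(labels=labels, spacing=spec.spacing, legend=legend)


def noiseless_signal(spec: PhantomSpec, labels: np.ndarray) -> np.ndarray:
    """Closed-form mono-exponential signal for every voxel and acquisition."""
    signal = np.empty((*labels.shape, len(spec.bvalues)), dtype=np.float64)
    bvals = np.asarray(spec.bvalues)
    for code, params in spec.tissues.items():
        mask = labels == code
        if not mask.any():
            continue
        signal[mask, :] = params.S0 * np.exp(-bvals * params.D)
    return signal


def generate_phantom(spec: PhantomSpec) -> tuple[DWIStack, LabelMap]:
    """Generate the observed DWI stack and its ground-truth labels.

    With ``noise_sigma == 0`` every voxel equals its closed-form
    mono-exponential value exactly.  Otherwise each voxel receives
    independent Rician noise drawn from a generator seeded with
    ``spec.seed``, so identical specs produce bit-identical stacks.
    """
    label_map = build_labels(spec)
    signal = noiseless_signal(spec, label_map.labels)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        e1 = rng.normal(0.0, spec.noise_sigma, size=signal.shape)
        e2 = rng.normal(0.0, spec.noise_sigma, size=signal.shape)
        signal = np.sqrt((signal + e1) ** 2 + e2**2)
    stack = DWIStack(signal=signal, bvalues=list(spec.bvalues), spacing=spec.spacing)
    return stack, label_map


def default_prostate_spec(seed: int) -> PhantomSpec:
    """The package's reference phantom.

    A 64 x 64 x 16 grid at (1.56, 1.56, 3.5) mm spacing — the study-median
    DWI resolution — acquired at b = {0, 100, 1000, 2000} s/mm^2, spanning
    the ADC b-value set and the upper end of the CDI diffusion range.  The
    gland is an ellipsoid of healthy tissue (D = 1.5e-3 mm^2/s) holding
    two cancerous spheres of radius 4 and 6 mm with restricted diffusion
    (D = 0.7e-3 mm^2/s); both diffusivities sit in literature-typical
    prostate ranges.  Background is fluid-like (low S0, high D).  Noise
    gives SNR 20 at b = 0 in the gland.
    """
    s0 = 1000.0
    return PhantomSpec(
        shape=(64, 64, 16),
        spacing=(1.56, 1.56, 3.5),
        bvalues=[0.0, 100.0, 1000.0, 2000.0],
        tissues={
            0: TissueParams(S0=150.0, D=3.0e-3),
            HEALTHY_LABEL: TissueParams(S0=s0, D=1.5e-3),
            CANCER_LABEL: TissueParams(S0=s0, D=0.7e-3),
        },
        gland=Ellipsoid(center=(32.0, 32.0, 8.0), semiaxes_mm=(34.0, 28.0, 18.0)),
        lesions=[
            Lesion(center=(24.0, 28.0, 8.0), radius_mm=4.0, label=CANCER_LABEL),
            Lesion(center=(41.0, 36.0, 8.0), radius_mm=6.0, label=CANCER_LABEL),
        ],
        noise_sigma=s0 / 20.0,
        seed=int(seed),
    )


def spec_from_file(path: str | Path, seed: int | None = None) -> PhantomSpec:
    """Load a PhantomSpec from a JSON file mirroring its fields.

    ``tissues`` keys are label codes (JSON strings), values objects with
    ``S0`` and ``D``; ``gland`` has ``center`` and ``semiaxes_mm``;
    ``lesions`` entries have ``center``, ``radius_mm`` and ``label``.
    An explicit ``seed`` argument overrides the file's value.
    """
    raw = json.loads(Path(path).read_text())
    try:
        spec = PhantomSpec(
            shape=tuple(raw["shape"]),
            spacing=tuple(raw["spacing"]),
            bvalues=list(raw["bvalues"]),
            tissues={
                int(code): TissueParams(**params)
                for code, params in raw["tissues"].items()
            },
            gland=Ellipsoid(
                center=tuple(raw["gland"]["center"]),
                semiaxes_mm=tuple(raw["gland"]["semiaxes_mm"]),
            ),
            lesions=[
                Lesion(
                    center=tuple(les["center"]),
                    radius_mm=float(les["radius_mm"]),
                    label=int(les["label"]),
                )
                for les in raw.get("lesions", [])
            ],
            noise_sigma=float(raw.get("noise_sigma", 0.0)),
            seed=int(raw.get("seed", 0)) if seed is None else int(seed),
        )
    except KeyError as exc:
        raise ValidationError(f"phantom spec file missing field {exc}") from exc
    return spec
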