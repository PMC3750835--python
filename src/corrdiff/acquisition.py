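"""Gradient-pulse configurations and their diffusion weightings.

A pulsed-gradient spin-echo sequence is characterised by three parameters:
the gradient pulse strength ``G`` (T/m), the pulse duration ``delta`` (s),
and the separation ``Delta`` (s) between the leading edges of the two
pulses.  The resulting diffusion weighting (b-value) follows the
Stejskal-Tanner relation

    b = gamma^2 G^2 delta^2 (Delta - delta / 3),

with ``gamma`` the proton gyromagnetic ratio.  All arithmetic is carried
out in SI units (T/m, s, s/m^2); b-values cross the API boundary in the
conventional s/mm^2.

Scanners report b-values rather than raw pulse parameters, so most of the
pipeline treats b-values as primary; this module supplies the forward
relation and a closed-form inverse so phantoms can be specified either way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import ValidationError

#: Proton gyromagnetic ratio (CODATA), rad s^-1 T^-1.
GYROMAGNETIC_RATIO = 2.6752218744e8

#: 1 s/m^2 expressed in s/mm^2.
_SI_TO_S_PER_MM2 = 1e-6


@dataclass(frozen=True)
class GradientConfig:
    """One diffusion-sensitising pulse configuration.

    Attributes
    ----------
    G : float
        Gradient pulse strength in T/m.  Must be >= 0.
    delta : float
        Gradient pulse duration in s.  Must be > 0.
    Delta : float
        Time between the two gradient pulses in s.  Must be > 0 and
        satisfy ``Delta - delta / 3 > 0`` so the b-value is nonnegative.
    """

    G: float
    delta: float
    Delta: float

    def __post_init__(self) -> None:
        if not (self.G >= 0):
            raise ValidationError(f"G must be >= 0, got {self.G}")
        if not (self.delta > 0):
            raise ValidationError(f"delta must be > 0, got {self.delta}")
        if not (self.Delta > 0):
            raise ValidationError(f"Delta must be > 0, got {self.Delta}")
        if not (self.Delta - self.delta / 3.0 > 0):
            raise ValidationError(
                "Delta - delta/3 must be > 0 "
                f"(Delta={self.Delta}, delta={self.delta})"
            )


def b_value(config: GradientConfig) -> float:
    """Diffusion weighting of a pulse configuration, in s/mm^2.

    Evaluates the Stejskal-Tanner relation
    ``gamma^2 G^2 delta^2 (Delta - delta/3)`` in SI units and converts
    the result from s/m^2 to s/mm^2.
    """
    g = GYROMAGNETIC_RATIO
    b_si = (g * config.G * config.delta) ** 2 * (config.Delta - config.delta / 3.0)
    return b_si * _SI_TO_S_PER_MM2


def config_set_from_bvalues(
    targets: Sequence[float], delta: float, Delta: float
) -> list[GradientConfig]:
    """Pulse configurations realising the given b-values at fixed timings.

    For each target b-value (s/mm^2) the gradient strength is solved in
    closed form, ``G = sqrt(b_SI / (gamma^2 delta^2 (Delta - delta/3)))``,
    so that :func:`b_value` round-trips each target to floating-point
    precision.  Duplicate targets are permitted (repeated acquisitions).
    """
    # Validate timings once via a throwaway zero-gradient config.
    GradientConfig(G=0.0, delta=delta, Delta=Delta)
    configs = []
    denom = (GYROMAGNETIC_RATIO * delta) ** 2 * (Delta - delta / 3.0)
    for target in targets:
        if target < 0:
            raise ValidationError(f"b-value target must be >= 0, got {target}")
        b_si = target / _SI_TO_S_PER_MM2
        configs.append(GradientConfig(G=math.sqrt(b_si / denom), delta=delta, Delta=Delta))
    return configs


def validate_bvalues(bvalues: Sequence[float]) -> list[float]:
    """Check that every b-value is a finite nonnegative number."""
    out = []
    for b in bvalues:
        b = float(b)
        if not math.isfinite(b) or b < 0:
            raise ValidationError(f"b-value must be finite and >= 0, got {b}")
        out.append(b)
    return out
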