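"""Two-flux (Kubelka-Munk) slab model of diffuse light transport.

Relates the diffuse reflectance ``r_d`` and transmittance ``t_d`` of a
homogeneous slab to a pair of two-flux coefficients: ``s_km`` (scattering of
diffuse radiation) and ``a_km`` (absorption of diffuse radiation), both in
cm^-1.  The closed forms used here are the Kottler ones,

    r_d = sinh(s Y D) / (X sinh(s Y D) + Y cosh(s Y D))
    t_d = Y           / (X sinh(s Y D) + Y cosh(s Y D))

with ``X = 1 + a_km/s_km`` and ``Y = sqrt(X^2 - 1)``, whose exact inverse is

    X = (1 + r_d^2 - t_d^2) / (2 r_d)
    s_km = ln[(1 - r_d (X - Y)) / t_d] / (Y D)
    a_km = (X - 1) s_km.

Some texts print the forward denominator as ``X cosh + Y sinh``; that variant
is inconsistent with the inversion above (the round trip fails and the
zero-absorption limit degenerates), so this module deliberately uses the
self-consistent form.

Two-flux coefficients map to transport coefficients via

    a_km = 2 mu_a,        s_km = (3/4) mu_s' - (1/4) mu_a,

and the diffusion-regime penetration depth is
``delta = 1 / sqrt(3 mu_a (mu_a + mu_s'))``.

All lengths are cm, all coefficients cm^-1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

from .exceptions import (
    DegenerateReflectanceError,
    InvalidParameterError,
    KMInapplicableError,
    NonPhysicalMeasurementError,
)

__all__ = [
    "DiffuseMeasurement",
    "KMCoefficients",
    "OpticalProperties",
    "forward_km",
    "invert_km",
    "km_to_transport",
    "transport_to_km",
    "penetration_depth",
    "effective_attenuation",
    "estimate_optical_properties",
]

#: |X - 1| below this is treated as the zero-absorption limit (the generic
#: closed forms are 0/0 there).
ZERO_ABSORPTION_TOL = 1e-8

#: Above this value of s*Y*D the hyperbolic terms overflow; use asymptotics.
_OVERFLOW_ARG = 350.0


@dataclass(frozen=True)
class DiffuseMeasurement:
    """Calibrated diffuse fractions for one slab at one incident power.

    Parameters
    ----------
    r_d, t_d
        Diffuse reflectance and transmittance as fractions of the incident
        power, each strictly in (0, 1).
    thickness_cm
        Slab optical thickness in cm.
    power_mw
        Incident laser power in mW (metadata, carried through the analysis).
    wavelength_nm
        Probe wavelength in nm (metadata).
    """

    r_d: float
    t_d: float
    thickness_cm: float
    power_mw: float | None = None
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.r_d < 1.0):
            raise InvalidParameterError(f"r_d must be in (0, 1), got {self.r_d}")
        if not (0.0 < self.t_d < 1.0):
            raise InvalidParameterError(f"t_d must be in (0, 1), got {self.t_d}")
        if self.thickness_cm <= 0.0:
            raise InvalidParameterError(
                f"thickness_cm must be positive, got {self.thickness_cm}"
            )


@dataclass(frozen=True)
class KMCoefficients:
    """Two-flux coefficients with their auxiliary parameters.

    ``x >= 1`` and ``y = sqrt(x^2 - 1)``; ``a_km = (x - 1) * s_km``.
    """

    s_km: float
    a_km: float
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.s_km <= 0.0:
            raise InvalidParameterError(f"s_km must be positive, got {self.s_km}")
        if self.a_km < 0.0:
            raise InvalidParameterError(f"a_km must be >= 0, got {self.a_km}")

    @classmethod
    def from_s_a(cls, s_km: float, a_km: float) -> "KMCoefficients":
        """Build coefficients filling ``x`` and ``y`` consistently."""
        if s_km <= 0.0:
            raise InvalidParameterError(f"s_km must be positive, got {s_km}")
        if a_km < 0.0:
            raise InvalidParameterError(f"a_km must be >= 0, got {a_km}")
        x = 1.0 + a_km / s_km
        y = math.sqrt(x * x - 1.0)
        return cls(s_km=s_km, a_km=a_km, x=x, y=y)


@dataclass(frozen=True)
class OpticalProperties:
    """Transport-level optical parameters of one sample/condition.

    ``mu_s_prime`` is the reduced scattering coefficient; when both ``mu_s``
    and ``g`` are given they must satisfy ``mu_s_prime = mu_s * (1 - g)``.
    """

    mu_a: float
    mu_s_prime: float
    thickness_cm: float
    g: float | None = None
    mu_s: float | None = None
    refractive_index: float = 1.0
    power_mw: float | None = None
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        if self.mu_a < 0.0:
            raise InvalidParameterError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s_prime < 0.0:
            raise InvalidParameterError(
                f"mu_s_prime must be >= 0, got {self.mu_s_prime}"
            )
        if self.thickness_cm <= 0.0:
            raise InvalidParameterError(
                f"thickness_cm must be positive, got {self.thickness_cm}"
            )
        if self.g is not None and not (-1.0 < self.g < 1.0):
            raise InvalidParameterError(f"g must be in (-1, 1), got {self.g}")
        if self.g is not None and self.mu_s is not None:
            expected = self.mu_s * (1.0 - self.g)
            if not math.isclose(self.mu_s_prime, expected, rel_tol=1e-12):
                raise InvalidParameterError(
                    f"mu_s_prime={self.mu_s_prime} inconsistent with "
                    f"mu_s*(1-g)={expected}"
                )


def forward_km(
    s_km: float, a_km: float, thickness_cm: float
) -> tuple[float, float]:
    """Diffuse reflectance and transmittance of a slab from two-flux coefficients.

    Parameters
    ----------
    s_km, a_km
        Two-flux scattering (> 0) and absorption (>= 0) coefficients, cm^-1.
    thickness_cm
        Slab thickness, cm (> 0).

    Returns
    -------
    (r_d, t_d)
        Diffuse fractions; ``r_d + t_d <= 1`` with equality iff ``a_km == 0``.

    Notes
    -----
    The zero-absorption limit is handled in closed form,
    ``r_d = sD/(1+sD)``, ``t_d = 1/(1+sD)``.  For very thick/attenuating
    slabs (``s Y D`` beyond hyperbolic overflow) the asymptotic branch
    ``r_d -> 1/(X+Y)``, ``t_d -> 2Y exp(-sYD)/(X+Y)`` is used.
    """
    if s_km <= 0.0:
        raise InvalidParameterError(f"s_km must be positive, got {s_km}")
    if a_km < 0.0:
        raise InvalidParameterError(f"a_km must be >= 0, got {a_km}")
    if thickness_cm <= 0.0:
        raise InvalidParameterError(
            f"thickness_cm must be positive, got {thickness_cm}"
        )

    x = 1.0 + a_km / s_km
    if x - 1.0 < ZERO_ABSORPTION_TOL:
        sd = s_km * thickness_cm
        return sd / (1.0 + sd), 1.0 / (1.0 + sd)

    y = math.sqrt(x * x - 1.0)
    arg = s_km * y * thickness_cm
    if arg > _OVERFLOW_ARG:
        # sinh ~ cosh ~ exp(arg)/2
        r_d = 1.0 / (x + y)
        t_d = 2.0 * y * math.exp(-arg) / (x + y)
        return r_d, t_d
    sh, ch = math.sinh(arg), math.cosh(arg)
    denom = x * sh + y * ch
    return sh / denom, y / denom


def invert_km(m: DiffuseMeasurement) -> KMCoefficients:
    """Recover two-flux coefficients from measured diffuse fractions.

    Raises
    ------
    NonPhysicalMeasurementError
        If ``r_d + t_d >= 1`` (outside the zero-absorption tolerance), which
        makes the auxiliary ``X < 1`` and ``Y`` imaginary.
    DegenerateReflectanceError
        If ``r_d <= 0``.
    """
    r, t, d = m.r_d, m.t_d, m.thickness_cm
    if r <= 0.0:
        raise DegenerateReflectanceError(f"r_d must be positive, got {r}")
    x = (1.0 + r * r - t * t) / (2.0 * r)
    if abs(x - 1.0) < ZERO_ABSORPTION_TOL:
        # zero-absorption limit: r = sD/(1+sD)  =>  s = r / (D (1 - r))
        s_km = r / (d * (1.0 - r))
        return KMCoefficients(s_km=s_km, a_km=0.0, x=1.0, y=0.0)
    if x < 1.0:
        raise NonPhysicalMeasurementError(
            f"r_d + t_d = {r + t:.6g} >= 1: no absorbing slab can produce "
            "these fractions (X < 1, Y imaginary)"
        )
    y = math.sqrt(x * x - 1.0)
    s_km = math.log((1.0 - r * (x - y)) / t) / (y * d)
    a_km = (x - 1.0) * s_km
    return KMCoefficients(s_km=s_km, a_km=a_km, x=x, y=y)


def km_to_transport(
    k: KMCoefficients, thickness_cm: float = 1.0, **metadata: float | None
) -> OpticalProperties:
    """Convert two-flux coefficients to transport coefficients.

    Uses ``mu_a = a_km / 2`` and ``mu_s' = (4 s_km + mu_a) / 3`` (the inverse
    of ``a_km = 2 mu_a``, ``s_km = 0.75 mu_s' - 0.25 mu_a``).
    """
    mu_a = k.a_km / 2.0
    mu_s_prime = (4.0 * k.s_km + mu_a) / 3.0
    return OpticalProperties(
        mu_a=mu_a, mu_s_prime=mu_s_prime, thickness_cm=thickness_cm, **metadata
    )


def transport_to_km(p: OpticalProperties) -> KMCoefficients:
    """Convert transport coefficients to two-flux coefficients.

    Raises
    ------
    KMInapplicableError
        If ``mu_s_prime <= mu_a / 3`` (two-flux scattering coefficient would
        be non-positive; the diffuse-radiance assumption is violated).
    """
    s_km = 0.75 * p.mu_s_prime - 0.25 * p.mu_a
    if s_km <= 0.0:
        raise KMInapplicableError(
            f"mu_s_prime={p.mu_s_prime} <= mu_a/3={p.mu_a / 3.0:.6g}: medium "
            "is not scattering-dominated, two-flux model inapplicable"
        )
    return KMCoefficients.from_s_a(s_km=s_km, a_km=2.0 * p.mu_a)


def effective_attenuation(p: OpticalProperties) -> float:
    """Effective attenuation coefficient ``mu_eff = sqrt(3 mu_a (mu_a + mu_s'))``.

    Shared definition: ``penetration_depth`` is its reciprocal and the
    diffusion solver uses the same quantity.
    """
    return math.sqrt(3.0 * p.mu_a * (p.mu_a + p.mu_s_prime))


def penetration_depth(p: OpticalProperties) -> float:
    """Diffusion-regime light penetration depth ``1 / mu_eff`` in cm.

    For ``mu_a == 0`` the mathematical limit is infinite; ``+inf`` is
    returned with a warning rather than raising.
    """
    if p.mu_a == 0.0:
        warnings.warn(
            "mu_a = 0: penetration depth is infinite (non-absorbing medium)",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.inf
    return 1.0 / effective_attenuation(p)


def estimate_optical_properties(m: DiffuseMeasurement) -> OpticalProperties:
    """Full inversion: measured diffuse fractions -> transport coefficients.

    Composition of :func:`invert_km` and :func:`km_to_transport`; thickness,
    power and wavelength metadata are carried through.
    """
    k = invert_km(m)
    return km_to_transport(
        k,
        thickness_cm=m.thickness_cm,
        power_mw=m.power_mw,
        wavelength_nm=m.wavelength_nm,
    )
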