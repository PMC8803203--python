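"""Steady-state diffusion-approximation fluence rate on a 2D grid.

Solves  mu_a * phi - D * laplacian(phi) = S  on a square domain with a
single-node source at the center and zero-fluence (Dirichlet) boundaries,
by a five-point finite-difference discretization and a direct sparse solve.
D = 1 / (3 (mu_a + mu_s')) is the diffusion coefficient.

The analytic infinite-medium solution in 2D,
phi(r) = S / (2 pi D) * K0(mu_eff r)  with  mu_eff = sqrt(mu_a / D),
serves as the validation oracle away from the source and the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import identity, kron, diags
from scipy.sparse.linalg import spsolve

from .exceptions import GridDomainError, GridResolutionError, InvalidParameterError
from .km_model import OpticalProperties, effective_attenuation

__all__ = [
    "FluenceField",
    "diffusion_coefficient",
    "solve_fluence",
    "profile_width",
    "radial_profile",
]

#: grid guards relative to the penetration depth delta = 1/mu_eff
SPACING_MAX_FRACTION = 0.2   # spacing <= delta / 5
DOMAIN_MIN_FACTOR = 10.0     # domain >= 10 delta


@dataclass(frozen=True)
class FluenceField:
    """Steady-state fluence-rate solution on a uniform square grid."""

    phi: np.ndarray
    grid_spacing_cm: float
    source_xy: tuple[int, int]
    diffusion_coeff_cm: float
    mu_eff_cm1: float
    source_strength: float = 1.0

    @property
    def nx(self) -> int:
        return self.phi.shape[1]

    @property
    def ny(self) -> int:
        return self.phi.shape[0]


def diffusion_coefficient(p: OpticalProperties) -> float:
    """Diffusion coefficient D = 1 / (3 (mu_a + mu_s')) in cm."""
    total = p.mu_a + p.mu_s_prime
    if total <= 0.0:
        raise InvalidParameterError(
            "mu_a + mu_s_prime must be positive for a diffusion coefficient"
        )
    return 1.0 / (3.0 * total)


def solve_fluence(
    p: OpticalProperties,
    domain_cm: float,
    spacing_cm: float,
    source_strength: float = 1.0,
) -> FluenceField:
    """Solve the steady-state diffusion equation with a central point source.

    Parameters
    ----------
    p
        Transport parameters; ``mu_a`` must be positive (the guards are
        expressed in units of the penetration depth).
    domain_cm
        Side length of the square domain; must be >= 10 penetration depths
        so the zero-fluence boundary is far from the region of interest.
    spacing_cm
        Grid spacing; must be <= penetration_depth / 5.
    source_strength
        Total source power; deposited as a delta on the center node.

    Returns
    -------
    FluenceField
        Grid solution including the zero boundary ring; the source node is
        at the exact domain center (grid size is forced odd).
    """
    if p.mu_a <= 0.0:
        raise InvalidParameterError("mu_a must be positive for the grid guards")
    mu_eff = effective_attenuation(p)
    delta = 1.0 / mu_eff
    if spacing_cm > SPACING_MAX_FRACTION * delta:
        raise GridResolutionError(
            f"spacing {spacing_cm:g} cm too coarse for penetration depth "
            f"{delta:.4g} cm; use spacing <= {SPACING_MAX_FRACTION * delta:.4g} cm"
        )
    if domain_cm < DOMAIN_MIN_FACTOR * delta:
        raise GridDomainError(
            f"domain {domain_cm:g} cm too small for penetration depth "
            f"{delta:.4g} cm; use domain >= {DOMAIN_MIN_FACTOR * delta:.4g} cm"
        )

    d_coeff = diffusion_coefficient(p)
    n = int(round(domain_cm / spacing_cm)) + 1
    if n % 2 == 0:
        n += 1  # odd node count => a node sits exactly at the center
    h = spacing_cm
    m = n - 2  # interior nodes per axis

    # five-point Laplacian on the interior (Dirichlet zero on the ring)
    lap1d = diags([1.0, -2.0, 1.0], [-1, 0, 1], shape=(m, m), format="csr") / (h * h)
    eye = identity(m, format="csr")
    laplacian = kron(eye, lap1d, format="csr") + kron(lap1d, eye, format="csr")
    a_mat = (identity(m * m, format="csr") * p.mu_a - d_coeff * laplacian).tocsc()

    rhs = np.zeros(m * m)
    c = (n - 1) // 2  # center index in the full grid
    ci = c - 1  # center index among interior nodes
    rhs[ci * m + ci] = source_strength / (h * h)

    phi_int = spsolve(a_mat, rhs)
    phi = np.zeros((n, n))
    phi[1:-1, 1:-1] = phi_int.reshape(m, m)
    return FluenceField(
        phi=phi,
        grid_spacing_cm=h,
        source_xy=(c, c),
        diffusion_coeff_cm=d_coeff,
        mu_eff_cm1=mu_eff,
        source_strength=source_strength,
    )


def radial_profile(f: FluenceField) -> tuple[np.ndarray, np.ndarray]:
    """Azimuthally averaged fluence versus radius from the source node.

    Bins node values into annuli one grid spacing wide; the source node
    (r = 0 bin) is excluded.  Returns (bin center radii cm, mean phi).
    """
    n = f.phi.shape[0]
    cy, cx = f.source_xy[1], f.source_xy[0]
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(yy - cy, xx - cx) * f.grid_spacing_cm
    h = f.grid_spacing_cm
    nbins = int(np.ceil(r.max() / h))
    idx = np.minimum((r / h).astype(int), nbins - 1)
    counts = np.bincount(idx.ravel(), minlength=nbins)
    sums = np.bincount(idx.ravel(), weights=f.phi.ravel(), minlength=nbins)
    with np.errstate(invalid="ignore"):
        mean = sums / counts
    centers = (np.arange(nbins) + 0.5) * h
    keep = counts > 0
    return centers[1:][keep[1:]], mean[1:][keep[1:]]


def profile_width(f: FluenceField, fraction: float) -> float:
    """Radius at which the azimuthal profile falls to ``fraction`` of its peak.

    The peak is the off-source maximum (first radial bin).  The crossing is
    located by linear interpolation between radial bins.  Raises if the
    profile never drops below the threshold inside the domain.
    """
    if not (0.0 < fraction < 1.0):
        raise InvalidParameterError("fraction must be in (0, 1)")
    radii, prof = radial_profile(f)
    peak = prof[0]
    if peak <= 0:
        raise InvalidParameterError("fluence field has no positive off-source peak")
    target = fraction * peak
    below = np.nonzero(prof < target)[0]
    if below.size == 0:
        raise InvalidParameterError(
            "profile never falls below the requested fraction inside the domain"
        )
    j = below[0]
    if j == 0:
        return float(radii[0])
    # linear interpolation between bins j-1 and j
    r0, r1 = radii[j - 1], radii[j]
    p0, p1 = prof[j - 1], prof[j]
    return float(r0 + (p0 - target) / (p0 - p1) * (r1 - r0))


def greens_function_2d(
    r: np.ndarray | float,
    diffusion_coeff_cm: float,
    mu_eff_cm1: float,
    source_strength: float = 1.0,
) -> np.ndarray | float:
    """Analytic 2D infinite-medium solution S/(2 pi D) K0(mu_eff r)."""
    from scipy.special import k0

    return source_strength / (2.0 * math.pi * diffusion_coeff_cm) * k0(
        mu_eff_cm1 * np.asarray(r, dtype=float)
    )
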