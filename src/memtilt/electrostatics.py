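"""Charge-density and electrostatic-potential profiles along the membrane normal.

Partial charges are binned along z into a volume charge density rho(z)
(e/nm^3), averaged over frames, and the 1-D Poisson equation is integrated
twice:

    psi(z) = -(1/eps0) * int_{z0}^{z} dz' int_{z0}^{z'} rho(z'') dz''

with the reference psi = 0 and dpsi/dz = 0 at the lower box edge (bulk-water
side).  No implicit dielectric is applied: in an all-atom setting the explicit
solvent carries the screening, so eps0 is the vacuum permittivity.

Units: charges in e, lengths in nm, output in volts.  The conversion constant
e/(eps0 * nm) = 18.0951 V (6 s.f.) follows from e = 1.602176634e-19 C and
eps0 = 8.85418781e-12 F/m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .io import Trajectory

__all__ = [
    "E_OVER_EPS0_NM_VOLT",
    "DensityProfile",
    "PotentialProfile",
    "charge_density_profile",
    "integrate_potential",
    "potential_contrast",
    "symmetrize",
]

# e / (eps0 * 1 nm) in volts; documented to 6 significant figures.
E_OVER_EPS0_NM_VOLT = 1.602176634e-19 / (8.8541878128e-12 * 1e-9)  # 18.0951 V


@dataclass
class DensityProfile:
    """Frame-averaged volume charge density rho(z) on uniform z bins.

    ``z`` holds bin centers with the origin at the box (membrane) center.
    """

    z: np.ndarray              # nm
    rho: np.ndarray            # e/nm^3
    bin_width: float           # nm
    n_frames: int
    box: np.ndarray            # (Lx, Ly, Lz) nm


@dataclass
class PotentialProfile:
    """Electrostatic potential psi(z) in volts; psi = dpsi/dz = 0 at z[0]-edge."""

    z: np.ndarray
    psi: np.ndarray


def charge_density_profile(trajectory: Trajectory,
                           charges: np.ndarray | None = None,
                           n_bins: int = 100) -> DensityProfile:
    """Histogram per-atom charges along z, per frame, then average.

    Atoms are wrapped into the primary box before binning.  Charges default to
    ``trajectory.topology.charges`` and must be present and finite.
    """
    if n_bins < 10:
        raise ValueError(f"n_bins must be >= 10, got {n_bins}")
    topo = trajectory.topology
    if charges is None:
        charges = topo.charges
    if charges is None:
        raise ValueError("no charges on topology and none supplied")
    charges = np.asarray(charges, dtype=float)
    if len(charges) != topo.n_atoms:
        raise ValueError("charges length != atom count")
    if not np.all(np.isfinite(charges)):
        bad = np.flatnonzero(~np.isfinite(charges))
        raise ValueError(f"missing/non-finite charges for atoms {bad[:10].tolist()}")
    if trajectory.n_frames == 0:
        raise ValueError("trajectory has no frames")
    box0 = trajectory[0].box
    area = float(box0[0] * box0[1])
    if area <= 0:
        raise ValueError("zero box cross-sectional area")
    lz = float(box0[2])
    dz = lz / n_bins
    rho = np.zeros(n_bins)
    for frame in trajectory:
        if not np.allclose(frame.box, box0, atol=1e-9):
            raise ValueError(
                "charge_density_profile requires a constant box across frames"
            )
        zw = np.mod(frame.coords[:, 2], lz)
        hist, _ = np.histogram(zw, bins=n_bins, range=(0.0, lz), weights=charges)
        rho += hist / (area * dz)
    rho /= trajectory.n_frames
    centers = (np.arange(n_bins) + 0.5) * dz - lz / 2.0
    return DensityProfile(z=centers, rho=rho, bin_width=dz,
                          n_frames=trajectory.n_frames, box=box0.copy())


def integrate_potential(density: DensityProfile) -> PotentialProfile:
    """Double cumulative-trapezoid integration of rho(z) into psi(z) in volts."""
    z, rho = density.z, density.rho
    widths = np.diff(z)
    if not np.allclose(widths, widths[0], rtol=1e-9, atol=1e-12):
        raise ValueError("potential integration requires uniform bin widths")
    field_int = cumulative_trapezoid(rho, z, initial=0.0)       # e/nm^2
    double_int = cumulative_trapezoid(field_int, z, initial=0.0)  # e/nm
    psi = -E_OVER_EPS0_NM_VOLT * double_int
    return PotentialProfile(z=z.copy(), psi=psi)


def potential_contrast(profile_a: PotentialProfile, profile_b: PotentialProfile,
                       region: tuple[float, float]) -> float:
    """Relative difference of mean |psi| between two profiles over a z region.

    Returns ``(<|psi_A|> - <|psi_B|>) / <|psi_B|>`` over bins with
    ``region[0] <= z <= region[1]``.
    """
    if profile_a.z.shape != profile_b.z.shape or not np.allclose(
            profile_a.z, profile_b.z, atol=1e-9):
        raise ValueError("profiles must share identical bins")
    lo, hi = region
    mask = (profile_a.z >= lo) & (profile_a.z <= hi)
    if not np.any(mask):
        raise ValueError(f"region {region} contains no bins")
    mean_a = float(np.mean(np.abs(profile_a.psi[mask])))
    mean_b = float(np.mean(np.abs(profile_b.psi[mask])))
    if mean_b == 0.0:
        raise ZeroDivisionError("reference profile has zero mean |psi| in region")
    return (mean_a - mean_b) / mean_b


def symmetrize(profile: PotentialProfile) -> PotentialProfile:
    """Average psi(z) with psi(-z); appropriate for symmetric membranes only."""
    return PotentialProfile(z=profile.z.copy(),
                            psi=0.5 * (profile.psi + profile.psi[::-1]))
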