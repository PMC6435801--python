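"""Coarse-grained chain model with a generalized-Born / surface-area solvent.

A chain is a set of beads carrying partial charges, intrinsic Born radii,
Lennard-Jones parameters and per-bead surface-tension coefficients, connected
by harmonic bonds (and optional harmonic angles).  The implicit solvent is a
continuum of relative dielectric constant ``eps_r`` with the solute interior
fixed at dielectric 1; its solvation free energy — a pairwise generalized-Born
polar term plus an analytic surface-area nonpolar term — enters the effective
Hamiltonian used for sampling, so that alchemical perturbations in ``eps_r``
move the system between vacuum (``eps_r = 1``) and water (``eps_r = 80``).

GB flavor: Still-style pairwise energy with effective Born radii from a
simple pairwise Coulomb-field descreening integral over non-overlapping
spheres (overlapping pairs are evaluated at contact distance).  The radii
calculation sits behind :func:`effective_born_radii` so an alternative
(e.g. OBC-style) prescription can be swapped in without touching the energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .constants import COULOMB


def _as_array(x, dtype=float) -> np.ndarray:
    # always copy: freezing a view of the caller's array would mutate it
    a = np.array(x, dtype=dtype)
    a.setflags(write=False)
    return a


@dataclass(frozen=True)
class ChainTopology:
    """Bead-spring chain definition.

    Parameters
    ----------
    charges, born_radii, lj_sigma, lj_epsilon, surface_tension
        Per-bead arrays: partial charge (e), intrinsic Born radius (nm),
        LJ σ (nm), LJ ε (kJ mol⁻¹), surface tension (kJ mol⁻¹ nm⁻²).
    bond_atoms, bond_r0, bond_k
        Harmonic bonds: index pairs, equilibrium lengths (nm) and
        stiffnesses (kJ mol⁻¹ nm⁻²).
    angle_atoms, angle_theta0, angle_k
        Optional harmonic angles (rad, kJ mol⁻¹ rad⁻²).
    terminals
        Indices of the two beads whose distance defines the reaction
        coordinate R (the end-to-end distance).
    """

    charges: np.ndarray
    born_radii: np.ndarray
    lj_sigma: np.ndarray
    lj_epsilon: np.ndarray
    surface_tension: np.ndarray
    bond_atoms: np.ndarray
    bond_r0: np.ndarray
    bond_k: np.ndarray
    terminals: tuple[int, int]
    angle_atoms: Optional[np.ndarray] = None
    angle_theta0: Optional[np.ndarray] = None
    angle_k: Optional[np.ndarray] = None
    label: str = "chain"

    def __post_init__(self):
        object.__setattr__(self, "charges", _as_array(self.charges))
        object.__setattr__(self, "born_radii", _as_array(self.born_radii))
        object.__setattr__(self, "lj_sigma", _as_array(self.lj_sigma))
        object.__setattr__(self, "lj_epsilon", _as_array(self.lj_epsilon))
        object.__setattr__(self, "surface_tension", _as_array(self.surface_tension))
        object.__setattr__(self, "bond_atoms", _as_array(self.bond_atoms, dtype=int).reshape(-1, 2))
        object.__setattr__(self, "bond_r0", _as_array(self.bond_r0))
        object.__setattr__(self, "bond_k", _as_array(self.bond_k))
        object.__setattr__(self, "terminals", (int(self.terminals[0]), int(self.terminals[1])))
        if self.angle_atoms is not None:
            object.__setattr__(self, "angle_atoms", _as_array(self.angle_atoms, dtype=int).reshape(-1, 3))
            object.__setattr__(self, "angle_theta0", _as_array(self.angle_theta0))
            object.__setattr__(self, "angle_k", _as_array(self.angle_k))
        n = self.n_beads
        if n < 2:
            raise ValueError("a chain needs at least 2 beads")
        for name in ("born_radii", "lj_sigma", "lj_epsilon", "surface_tension"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have one entry per bead")
        if np.any(self.born_radii <= 0):
            raise ValueError("all Born radii must be positive")
        if len(self.bond_r0) != len(self.bond_atoms) or len(self.bond_k) != len(self.bond_atoms):
            raise ValueError("bond arrays must have consistent lengths")
        i, j = self.terminals
        if i == j or not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"terminal indices {self.terminals} invalid for {n} beads")
        if self.bond_atoms.size and (self.bond_atoms.min() < 0 or self.bond_atoms.max() >= n):
            raise ValueError("bond index out of range")

    @property
    def n_beads(self) -> int:
        return len(self.charges)

    @property
    def contour_length(self) -> float:
        """Sum of bond equilibrium lengths (nm); upper bound on relaxed extension."""
        return float(self.bond_r0.sum())

    def charge_zeroed(self) -> "ChainTopology":
        """Copy with every partial charge set exactly to zero (nonpolar route)."""
        return replace(self, charges=np.zeros(self.n_beads))

    def excluded_pairs(self) -> set[tuple[int, int]]:
        """Directly bonded (1-2) pairs, excluded from intramolecular LJ/Coulomb."""
        return {(min(i, j), max(i, j)) for i, j in self.bond_atoms}


@dataclass(frozen=True)
class Conformation:
    """Bead coordinates of one chain state, in nm."""

    coordinates: np.ndarray
    frame_id: Optional[int] = None

    def __post_init__(self):
        object.__setattr__(self, "coordinates", _as_array(self.coordinates).reshape(-1, 3))
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("conformation has non-finite coordinates")

    @property
    def n_beads(self) -> int:
        return len(self.coordinates)

    def end_to_end(self, topology: ChainTopology) -> float:
        i, j = topology.terminals
        return float(np.linalg.norm(self.coordinates[j] - self.coordinates[i]))


@dataclass(frozen=True)
class SolventModel:
    """Continuum solvent: relative dielectric and surface-area term switch.

    ``eps_r = 1`` with the surface term off is exact vacuum (zero solvation
    energy for every conformation).  The solute interior dielectric is 1.
    """

    eps_r: float = 80.0
    sa_on: bool = True
    probe_radius: float = 0.14

    def __post_init__(self):
        if self.eps_r < 1.0:
            raise ValueError(f"relative dielectric must be >= 1, got {self.eps_r}")


VACUUM = SolventModel(eps_r=1.0, sa_on=False)
WATER = SolventModel(eps_r=80.0, sa_on=True)


def _check_match(topology: ChainTopology, conformation: Conformation) -> np.ndarray:
    if conformation.n_beads != topology.n_beads:
        raise ValueError(
            f"conformation has {conformation.n_beads} beads, topology {topology.n_beads}"
        )
    return conformation.coordinates


def _pair_distances(coords: np.ndarray) -> np.ndarray:
    d = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((d * d).sum(axis=-1))


def intramolecular_energy(topology: ChainTopology, conformation: Conformation) -> float:
    """Bond + angle + non-bonded LJ + Coulomb energy in vacuum (kJ mol⁻¹).

    Non-bonded pairs use Lorentz–Berthelot combining rules; directly bonded
    (1-2) pairs are excluded from both LJ and Coulomb, following the usual
    force-field convention.  The Coulomb term uses interior dielectric 1.
    """
    coords = _check_match(topology, conformation)
    e = 0.0
    if len(topology.bond_atoms):
        d = np.linalg.norm(coords[topology.bond_atoms[:, 1]] - coords[topology.bond_atoms[:, 0]], axis=1)
        e += float(0.5 * np.sum(topology.bond_k * (d - topology.bond_r0) ** 2))
    if topology.angle_atoms is not None and len(topology.angle_atoms):
        a = coords[topology.angle_atoms[:, 0]] - coords[topology.angle_atoms[:, 1]]
        b = coords[topology.angle_atoms[:, 2]] - coords[topology.angle_atoms[:, 1]]
        cos_t = np.einsum("ij,ij->i", a, b) / (
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
        )
        theta = np.arccos(np.clip(cos_t, -1.0, 1.0))
        e += float(0.5 * np.sum(topology.angle_k * (theta - topology.angle_theta0) ** 2))

    n = topology.n_beads
    if n > 1:
        iu, ju = np.triu_indices(n, k=1)
        excl = topology.excluded_pairs()
        keep = np.array([(i, j) not in excl for i, j in zip(iu, ju)])
        iu, ju = iu[keep], ju[keep]
        if len(iu):
            r = np.linalg.norm(coords[ju] - coords[iu], axis=1)
            if np.any(r <= 0):
                raise FloatingPointError("coincident beads in non-bonded pair")
            sig = 0.5 * (topology.lj_sigma[iu] + topology.lj_sigma[ju])
            eps = np.sqrt(topology.lj_epsilon[iu] * topology.lj_epsilon[ju])
            sr6 = (sig / r) ** 6
            e += float(np.sum(4.0 * eps * (sr6 * sr6 - sr6)))
            e += float(COULOMB * np.sum(topology.charges[iu] * topology.charges[ju] / r))
    return e


def effective_born_radii(topology: ChainTopology, coords: np.ndarray) -> np.ndarray:
    """Effective Born radii (nm) by pairwise Coulomb-field descreening.

    1/R_i = 1/ρ_i − Σ_{j≠i} I(r_ij, ρ_j) with the exact descreening integral
    of a non-overlapping sphere,

        I(r, ρ) = ½ [ ρ/(r² − ρ²) + (1/2r) ln((r − ρ)/(r + ρ)) ],

    evaluated at contact (r = ρ_i + ρ_j) when the spheres overlap — a toy-scale
    simplification that keeps I finite and the radii monotone.  The inverse
    radius is floored so R_i never diverges to a non-physical sign.
    """
    rho = topology.born_radii
    n = len(rho)
    inv = 1.0 / rho.copy()
    if n > 1:
        r = _pair_distances(coords)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                rij = max(r[i, j], rho[i] + rho[j])
                p = rho[j]
                term = 0.5 * (p / (rij * rij - p * p) + np.log((rij - p) / (rij + p)) / (2.0 * rij))
                inv[i] -= term
    return 1.0 / np.maximum(inv, 1e-6)


def surface_areas(topology: ChainTopology, coords: np.ndarray, probe_radius: float) -> np.ndarray:
    """Approximate per-bead solvent-accessible areas (nm²).

    The isolated-bead area 4π(ρ_i + probe)² is reduced by the product of
    pairwise spherical-cap occlusion fractions — an analytic, differentiable
    stand-in for a numerically triangulated surface.
    """
    radii = topology.born_radii + probe_radius
    n = len(radii)
    full = 4.0 * np.pi * radii**2
    frac = np.ones(n)
    if n > 1:
        d = _pair_distances(coords)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                ri, rj, dij = radii[i], radii[j], d[i, j]
                if dij >= ri + rj:
                    continue
                if dij <= abs(ri - rj):
                    cap = full[i] if rj >= ri else 0.0
                else:
                    x = (dij * dij + ri * ri - rj * rj) / (2.0 * dij)
                    cap = 2.0 * np.pi * ri * (ri - x)
                frac[i] *= max(0.0, 1.0 - min(cap, full[i]) / full[i])
    return full * frac


def gb_components(
    topology: ChainTopology, conformation: Conformation, probe_radius: float = 0.14
) -> tuple[float, float]:
    """(polar sum, surface term) so that ΔG(ε, sa) is cheap at many ε values.

    Returns S = k_e Σ_{ij} q_i q_j / f_GB and the surface-area energy; the
    solvation free energy at any state is −½(1 − 1/ε)·S (+ surface term if
    the surface switch is on).
    """
    coords = _check_match(topology, conformation)
    pol_sum = 0.0
    if np.any(topology.charges != 0.0):
        reff = effective_born_radii(topology, coords)
        r2 = _pair_distances(coords) ** 2
        rr = np.outer(reff, reff)
        f = np.sqrt(r2 + rr * np.exp(-r2 / (4.0 * rr)))
        qq = np.outer(topology.charges, topology.charges)
        pol_sum = float(COULOMB * np.sum(qq / f))
    sa_term = float(
        np.sum(topology.surface_tension * surface_areas(topology, coords, probe_radius))
    )
    return pol_sum, sa_term


def solvation_free_energy(
    topology: ChainTopology, conformation: Conformation, solvent: SolventModel
) -> float:
    """GB/SA solvation free energy ΔG_solv(ε_r) in kJ mol⁻¹.

    Polar part: Still-style pairwise GB,

        ΔG_pol = −½ (1 − 1/ε_r) Σ_{ij} k_e q_i q_j / f_GB(r_ij, R_i, R_j),

    with f_GB = sqrt(r² + R_i R_j exp(−r²/4R_iR_j)) and the i = j diagonal
    giving the Born self-energies.  Exactly zero at ε_r = 1.  Nonpolar part:
    Σ_i γ_i A_i over approximate accessible areas, when the surface term is on.
    """
    _check_match(topology, conformation)
    pol_sum, sa_term = gb_components(topology, conformation, solvent.probe_radius)
    e = 0.0
    if solvent.eps_r > 1.0:
        e += -0.5 * (1.0 - 1.0 / solvent.eps_r) * pol_sum
    if solvent.sa_on:
        e += sa_term
    return e


def effective_energy(
    topology: ChainTopology, conformation: Conformation, solvent: SolventModel
) -> float:
    """Sampling Hamiltonian: intramolecular energy + solvation free energy."""
    return intramolecular_energy(topology, conformation) + solvation_free_energy(
        topology, conformation, solvent
    )
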