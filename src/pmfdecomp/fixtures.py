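"""Toy systems with closed-form answers: the oracle layer.

Every estimator in the package is validated against systems whose profiles
are known analytically: a harmonic dumbbell (radial potential of mean force
with the 3D Jacobian term) and a freely jointed chain (exact end-to-end
density by convolution of fixed-length links).  The analytic callables are
written independently of the energy/estimator code paths they check, and are
themselves validated against direct brute-force simulation in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .constants import COULOMB, kt
from .model import ChainTopology

__all__ = [
    "ToySystem",
    "harmonic_dumbbell",
    "freely_jointed_chain",
    "born_pair_solvation",
    "generate_reference_tables",
]


@dataclass
class ToySystem:
    """A chain topology bundled with its analytic reference callables."""

    topology: ChainTopology
    label: str
    #: F_exact(R, temperature, eps_r) in k_BT, up to an additive constant
    f_exact: Optional[Callable] = None
    #: exact solvation free energy ΔG(R, eps_r) in kJ mol⁻¹ (rigid geometry)
    solvation_exact: Optional[Callable] = None
    #: end-to-end density p(R), normalized over R ≥ 0, when available
    density: Optional[Callable] = None


def _born_pair_radii(r: float, a1: float, a2: float) -> tuple[float, float]:
    """Effective radii of two Born spheres by pairwise Coulomb-field descreening."""
    out = []
    for a, other in ((a1, a2), (a2, a1)):
        rr = max(r, a1 + a2)
        term = 0.5 * (other / (rr * rr - other * other)
                      + np.log((rr - other) / (rr + other)) / (2.0 * rr))
        out.append(1.0 / max(1.0 / a - term, 1e-6))
    return out[0], out[1]


def born_pair_solvation(r: float, q1: float, q2: float, a1: float, a2: float,
                        eps_r: float) -> float:
    """Closed-form Still-style GB energy of two charged beads at distance r (kJ mol⁻¹).

    Written out independently of the model module: effective radii from the
    pairwise descreening integral, cross term through
    f = sqrt(r² + R₁R₂ exp(−r²/4R₁R₂)), prefactor −½(1 − 1/ε_r).
    """
    if eps_r == 1.0:
        return 0.0
    b1, b2 = _born_pair_radii(r, a1, a2)
    f = np.sqrt(r * r + b1 * b2 * np.exp(-r * r / (4.0 * b1 * b2)))
    s = q1 * q1 / b1 + q2 * q2 / b2 + 2.0 * q1 * q2 / f
    return float(-0.5 * (1.0 - 1.0 / eps_r) * COULOMB * s)


def harmonic_dumbbell(
    bond_k: float = 1000.0,
    bond_r0: float = 0.5,
    charges: tuple[float, float] = (0.0, 0.0),
    born_radius: float = 0.2,
    surface_tension: float = 0.0,
) -> ToySystem:
    """Two beads on a harmonic spring; the PMF along R is known in closed form.

    The radial profile of a particle pair in 3D is
    F(R)/k_BT = βU(R) − 2 ln R + const, the −2 ln R being the spherical-shell
    Jacobian.  With charges, the GB pair energy enters βU as part of the
    effective Hamiltonian at the given dielectric.
    """
    if bond_k <= 0:
        raise ValueError("bond stiffness must be positive")
    q1, q2 = charges
    top = ChainTopology(
        charges=[q1, q2],
        born_radii=[born_radius, born_radius],
        lj_sigma=[0.3, 0.3],
        lj_epsilon=[0.0, 0.0],
        surface_tension=[surface_tension, surface_tension],
        bond_atoms=[[0, 1]],
        bond_r0=[bond_r0],
        bond_k=[bond_k],
        terminals=(0, 1),
        label="harmonic-dumbbell",
    )

    def solvation_exact(r, eps_r=80.0):
        return born_pair_solvation(r, q1, q2, born_radius, born_radius, eps_r)

    def f_exact(r, temperature=298.0, eps_r=1.0):
        r = np.asarray(r, dtype=float)
        if np.any(r <= 0):
            raise ValueError("R must be positive")
        u = 0.5 * bond_k * (r - bond_r0) ** 2
        if eps_r > 1.0:
            u = u + np.vectorize(lambda x: solvation_exact(x, eps_r))(r)
        return u / kt(temperature) - 2.0 * np.log(r)

    return ToySystem(top, "harmonic-dumbbell", f_exact=f_exact,
                     solvation_exact=solvation_exact)


def _fjc_density_grid(n_links: int, b: float, n_pts: int = 4000):
    """Exact end-to-end density of n fixed-length links by radial convolution.

    p₂(r) = r/(2b²) on [0, 2b]; each further link convolves with the radial
    kernel r/(2sb) on |s − b| ≤ r ≤ s + b.  Densities are renormalized after
    each convolution to absorb quadrature error.
    """
    r_max = n_links * b
    dr = r_max / n_pts
    r = (np.arange(n_pts) + 0.5) * dr
    p = np.where(r <= 2 * b, r / (2 * b * b), 0.0)  # two links
    for _ in range(n_links - 2):
        s = r  # integration variable on the same grid
        mask = (np.abs(r[:, None] - b) <= s[None, :]) & (s[None, :] <= r[:, None] + b)
        kern = np.where(mask, r[:, None] / (2.0 * s[None, :] * b), 0.0)
        p = kern @ p * dr
        p /= np.sum(p) * dr
    p /= np.sum(p) * dr
    return r, p


def freely_jointed_chain(n_links: int, bond_length: float = 0.4,
                         bond_k: float = 50_000.0) -> ToySystem:
    """Freely jointed chain of ``n_links`` links (``n_links + 1`` beads).

    The topology uses stiff harmonic bonds as the sampler's approximation of
    rigid links; the analytic callables describe the rigid-link limit: exact
    closed form for two links, numerically exact radial convolution beyond,
    with ⟨R²⟩ = n_links·b² and zero density for R above the contour length.
    """
    if n_links < 2:
        raise ValueError("need at least 2 links")
    n = n_links + 1
    top = ChainTopology(
        charges=np.zeros(n),
        born_radii=np.full(n, 0.15),
        lj_sigma=np.full(n, 0.0),
        lj_epsilon=np.zeros(n),
        surface_tension=np.zeros(n),
        bond_atoms=[[i, i + 1] for i in range(n_links)],
        bond_r0=np.full(n_links, bond_length),
        bond_k=np.full(n_links, bond_k),
        terminals=(0, n - 1),
        label=f"fjc-{n_links}",
    )
    b = bond_length
    r_max = n_links * b

    if n_links == 2:
        def density(r):
            r = np.asarray(r, dtype=float)
            return np.where((r >= 0) & (r <= 2 * b), r / (2 * b * b), 0.0)
    else:
        grid_r, grid_p = _fjc_density_grid(n_links, b)

        def density(r):
            r = np.asarray(r, dtype=float)
            return np.where(r <= r_max, np.interp(r, grid_r, grid_p, left=0.0, right=0.0), 0.0)

    def f_exact(r, temperature=298.0, eps_r=1.0):
        r = np.asarray(r, dtype=float)
        if np.any(r > r_max):
            raise ValueError(f"R beyond contour length {r_max} nm: density is zero")
        p = density(r)
        if np.any(p <= 0):
            raise ValueError("F_exact undefined where the density vanishes")
        return -np.log(p)

    return ToySystem(top, f"fjc-{n_links}", f_exact=f_exact, density=density)


def fjc_direct_sample(n_links: int, bond_length: float, n_samples: int,
                      seed: int = 0) -> np.ndarray:
    """Brute-force end-to-end distances of a rigid freely jointed chain.

    Independent oracle for the analytic density: draws uniform unit vectors
    per link and returns |Σ b·û|.
    """
    rng = np.random.default_rng(seed)
    z = rng.uniform(-1.0, 1.0, (n_samples, n_links))
    phi = rng.uniform(0.0, 2.0 * np.pi, (n_samples, n_links))
    s = np.sqrt(1.0 - z * z)
    vecs = np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=-1) * bond_length
    return np.linalg.norm(vecs.sum(axis=1), axis=-1)


def generate_reference_tables(
    toy: ToySystem,
    protocol,
    ladder,
    backend,
    r_values: Sequence[float],
    out_dir,
    temperature: float = 298.0,
    pressures: Sequence[float] = (1.0,),
):
    """Emit the full per-frame energy tables the estimator modules consume.

    Runs the sequential dielectric-ladder sampling of the toy at each fixed R,
    evaluates the solvation-energy columns and the backend hydration column,
    and writes one TSV per fixed R with provenance (label, seed, ε ladder) in
    the header.  Regenerating with the same seed is byte-identical.  Returns
    the combined in-memory table and the file paths.
    """
    from pathlib import Path

    from .io import write_energy_table
    from .pipeline import ladder_energy_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables, paths = [], []
    for r in r_values:
        table = ladder_energy_table(
            toy.topology, r, ladder, protocol, temperature=temperature,
            backend=backend, pressures=pressures,
        )
        path = out_dir / f"energies_R{r:.4f}.tsv"
        write_energy_table(
            path, table,
            metadata={
                "system": toy.label,
                "seed": protocol.seed,
                "temperature_K": temperature,
                "ladder": ",".join(f"{e:g}" for e in ladder.sequence),
            },
        )
        tables.append(table)
        paths.append(path)
    from .fep import PerFrameEnergyTable

    return PerFrameEnergyTable.concat(tables), paths
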