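"""Equilibrium sampling of the effective Hamiltonian.

Two modes are provided along the end-to-end coordinate R:

* **umbrella** — a harmonic bias ½k(R − R₀)² added to the effective energy,
  for histogram-based profile reconstruction;
* **fixed-R** — ensembles at exactly fixed R, used by the alchemical
  (dielectric-ladder) estimators.  The default implementation pins the two
  terminal beads at separation R and moves only interior beads, which
  preserves R exactly; a stiff auxiliary restraint is available as an
  alternative for cross-validation.

The default integrator is Metropolis Monte Carlo with single-bead Gaussian
displacement moves (no forces needed, so kinks in the analytic surface-area
term are harmless); an overdamped Langevin integrator with finite-difference
forces is available for continuity checks.  All randomness flows from the
recorded protocol seed, so identical configurations reproduce identical
trajectories bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import kt
from .model import ChainTopology, Conformation, SolventModel, effective_energy

#: reference umbrella force constant, kJ mol⁻¹ nm⁻²
DEFAULT_FORCE_CONSTANT = 1875.0


@dataclass(frozen=True)
class UmbrellaWindow:
    """Harmonic restraint on R: center R₀ (nm) and force constant k (kJ mol⁻¹ nm⁻²)."""

    center: float
    force_constant: float = DEFAULT_FORCE_CONSTANT

    def __post_init__(self):
        if self.center <= 0:
            raise ValueError(f"window center must be positive, got {self.center}")
        # k = 0 is allowed as the degenerate unbiased window (WHAM's unbiased limit)
        if self.force_constant < 0:
            raise ValueError(f"force constant must be non-negative, got {self.force_constant}")


@dataclass(frozen=True)
class SamplingProtocol:
    """Run-length, move-size, temperature and seed of one sampling run."""

    integrator: str = "metropolis"
    step_size: float = 0.03
    n_equilibration: int = 2000
    n_production: int = 10000
    stride: int = 2
    temperature: float = 298.0
    seed: int = 0
    fixed_mode: str = "pin"  # "pin" (exact R) or "restraint" (stiff auxiliary spring)
    fixed_force_constant: float = 10.0 * DEFAULT_FORCE_CONSTANT

    def __post_init__(self):
        if self.integrator not in ("metropolis", "langevin"):
            raise ValueError(f"unknown integrator {self.integrator!r}")
        if self.fixed_mode not in ("pin", "restraint"):
            raise ValueError(f"unknown fixed-R mode {self.fixed_mode!r}")
        if self.n_frames < 1:
            raise ValueError("protocol must produce at least one frame")

    @property
    def n_frames(self) -> int:
        return self.n_production // self.stride


@dataclass
class FrameSet:
    """Ordered conformations with per-frame R and full provenance."""

    coordinates: np.ndarray  # (n_frames, n_beads, 3)
    r: np.ndarray  # (n_frames,)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if len(self.coordinates) != len(self.r):
            raise ValueError("coordinates and r must have equal frame counts")
        if not np.all(np.isfinite(self.r)):
            raise ValueError("non-finite R values in frame set")

    def __len__(self) -> int:
        return len(self.coordinates)

    def conformations(self) -> list[Conformation]:
        return [Conformation(c, frame_id=i) for i, c in enumerate(self.coordinates)]

    @property
    def last(self) -> Conformation:
        return Conformation(self.coordinates[-1])


def umbrella_bias_energy(r_or_conformation, window: UmbrellaWindow,
                         topology: Optional[ChainTopology] = None) -> float:
    """½·k·(R − R₀)²; accepts either a scalar R or a conformation + topology."""
    if isinstance(r_or_conformation, Conformation):
        if topology is None:
            raise ValueError("topology required to compute R from a conformation")
        r = r_or_conformation.end_to_end(topology)
    else:
        r = float(r_or_conformation)
    return 0.5 * window.force_constant * (r - window.center) ** 2


def initial_conformation(topology: ChainTopology, fixed_r: Optional[float] = None) -> Conformation:
    """Straight chain along x; if ``fixed_r`` is given the terminals sit at R."""
    n = topology.n_beads
    spacing = topology.bond_r0.mean() if len(topology.bond_r0) else 0.4
    if fixed_r is not None:
        if fixed_r <= 0:
            raise ValueError(f"target R must be positive, got {fixed_r}")
        if fixed_r > 1.5 * max(topology.contour_length, spacing):
            raise ValueError(
                f"target R = {fixed_r} nm unreachable: contour length is "
                f"{topology.contour_length} nm"
            )
        spacing = fixed_r / max(n - 1, 1)
    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n) * spacing
    # small transverse zigzag so interior beads are off the terminal axis
    if n > 2:
        coords[1:-1, 1] = 0.05 * (1 - 2 * (np.arange(1, n - 1) % 2))
    return Conformation(coords)


def _total_energy(topology, solvent, coords, window, fixed_r, fixed_k, terminals):
    conf = Conformation(coords)
    e = effective_energy(topology, conf, solvent)
    r = float(np.linalg.norm(coords[terminals[1]] - coords[terminals[0]]))
    if window is not None:
        e += 0.5 * window.force_constant * (r - window.center) ** 2
    if fixed_r is not None and fixed_k is not None:
        e += 0.5 * fixed_k * (r - fixed_r) ** 2
    return e, r


def run_sampling(
    topology: ChainTopology,
    solvent: SolventModel,
    protocol: SamplingProtocol,
    window: Optional[UmbrellaWindow] = None,
    fixed_r: Optional[float] = None,
    initial: Optional[Conformation] = None,
) -> FrameSet:
    """Sample the effective Hamiltonian; returns production frames.

    Exactly one of ``window`` (umbrella bias) and ``fixed_r`` may be given;
    with neither, sampling is unbiased.  In the default "pin" fixed-R mode the
    terminal beads are held at separation R and excluded from the move set, so
    R is conserved exactly; "restraint" mode instead adds a stiff spring
    (``protocol.fixed_force_constant``) and records the observed R spread.
    """
    if window is not None and fixed_r is not None:
        raise ValueError("give either an umbrella window or a fixed R, not both")
    if initial is None:
        initial = initial_conformation(topology, fixed_r=fixed_r)
    coords = initial.coordinates.copy()
    if coords.shape[0] != topology.n_beads:
        raise ValueError("initial conformation does not match topology")
    terminals = topology.terminals

    pin = fixed_r is not None and protocol.fixed_mode == "pin"
    fixed_k = protocol.fixed_force_constant if (fixed_r is not None and not pin) else None
    if pin:
        i, j = terminals
        # place terminals exactly at separation R along their current axis
        axis = coords[j] - coords[i]
        nrm = np.linalg.norm(axis)
        axis = axis / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
        coords[j] = coords[i] + axis * fixed_r
        movable = [b for b in range(topology.n_beads) if b not in terminals]
    else:
        movable = list(range(topology.n_beads))

    rng = np.random.default_rng(protocol.seed)
    beta = 1.0 / kt(protocol.temperature)
    energy, r_now = _total_energy(topology, solvent, coords, window,
                                  fixed_r if not pin else None, fixed_k, terminals)
    if not np.isfinite(energy):
        raise RuntimeError(f"non-finite initial energy {energy} for {topology.label}")

    frames, rvals = [], []
    n_total = protocol.n_equilibration + protocol.n_production

    if protocol.integrator == "langevin":
        _langevin_run(topology, solvent, protocol, coords, movable, window,
                      None if pin else fixed_r, fixed_k, terminals, rng, frames, rvals)
    else:
        n_acc = 0
        for step in range(n_total):
            if movable:
                b = movable[rng.integers(len(movable))]
                old = coords[b].copy()
                coords[b] = old + rng.normal(0.0, protocol.step_size, 3)
                e_new, r_new = _total_energy(topology, solvent, coords, window,
                                             fixed_r if not pin else None, fixed_k, terminals)
                if not np.isfinite(e_new):
                    raise RuntimeError(
                        f"non-finite energy at step {step} of {topology.label}"
                    )
                if e_new <= energy or rng.random() < np.exp(-beta * (e_new - energy)):
                    energy, r_now = e_new, r_new
                    n_acc += 1
                else:
                    coords[b] = old
            if step >= protocol.n_equilibration and (step - protocol.n_equilibration) % protocol.stride == 0:
                if len(frames) < protocol.n_frames:
                    frames.append(coords.copy())
                    rvals.append(r_now)

    while len(frames) < protocol.n_frames:  # rigid / unmovable systems
        frames.append(coords.copy())
        rvals.append(r_now)

    prov = {
        "seed": protocol.seed,
        "temperature": protocol.temperature,
        "eps_r": solvent.eps_r,
        "sa_on": solvent.sa_on,
        "integrator": protocol.integrator,
    }
    if window is not None:
        prov["window_center"] = window.center
        prov["window_k"] = window.force_constant
    if fixed_r is not None:
        prov["fixed_r"] = fixed_r
        prov["fixed_mode"] = protocol.fixed_mode
        if not pin:
            prov["fixed_tolerance"] = float(np.max(np.abs(np.asarray(rvals) - fixed_r)))
    return FrameSet(np.array(frames), np.array(rvals), prov)


def _langevin_run(topology, solvent, protocol, coords, movable, window, fixed_r,
                  fixed_k, terminals, rng, frames, rvals):
    """Overdamped Euler–Maruyama with central-difference forces (γ = 1)."""
    dt = protocol.step_size**2  # nm² ps⁻¹-free time unit; diffusion kT·dt sets move scale
    kbt = kt(protocol.temperature)
    h = 1e-5
    n_total = protocol.n_equilibration + protocol.n_production

    def grad(c):
        g = np.zeros_like(c)
        for b in movable:
            for d in range(3):
                c[b, d] += h
                ep, _ = _total_energy(topology, solvent, c, window, fixed_r, fixed_k, terminals)
                c[b, d] -= 2 * h
                em, _ = _total_energy(topology, solvent, c, window, fixed_r, fixed_k, terminals)
                c[b, d] += h
                g[b, d] = (ep - em) / (2 * h)
        return g

    for step in range(n_total):
        noise = rng.normal(0.0, 1.0, coords.shape)
        mask = np.zeros(len(coords), dtype=bool)
        mask[movable] = True
        coords[mask] += (-grad(coords) * dt + np.sqrt(2 * kbt * dt) * noise)[mask]
        e, r_now = _total_energy(topology, solvent, coords, window, fixed_r, fixed_k, terminals)
        if not np.isfinite(e):
            raise RuntimeError(f"non-finite energy at Langevin step {step}")
        if step >= protocol.n_equilibration and (step - protocol.n_equilibration) % protocol.stride == 0:
            if len(frames) < protocol.n_frames:
                frames.append(coords.copy())
                rvals.append(r_now)


def sequential_ladder_sampling(
    topology: ChainTopology,
    solvents: Sequence[SolventModel],
    fixed_r: float,
    protocol: SamplingProtocol,
) -> dict[float, FrameSet]:
    """Fixed-R ensembles for a ladder of dielectric states, chained sequentially.

    States are visited in the given order (water → vacuum by convention); the
    final conformation of each run seeds the next, emulating the gradual
    switching-off of solvation.  Each state gets a distinct child seed derived
    from the protocol seed; provenance records the state's ε_r.
    """
    out: dict[float, FrameSet] = {}
    initial = None
    for i, solvent in enumerate(solvents):
        child = SamplingProtocol(
            integrator=protocol.integrator,
            step_size=protocol.step_size,
            n_equilibration=protocol.n_equilibration,
            n_production=protocol.n_production,
            stride=protocol.stride,
            temperature=protocol.temperature,
            seed=int((protocol.seed * 100003 + 7919 * i) % (2**31)),
            fixed_mode=protocol.fixed_mode,
            fixed_force_constant=protocol.fixed_force_constant,
        )
        fs = run_sampling(topology, solvent, child, fixed_r=fixed_r, initial=initial)
        fs.provenance["ladder_index"] = i
        out[solvent.eps_r] = fs
        initial = fs.last
    return out
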