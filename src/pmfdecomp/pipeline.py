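"""End-to-end orchestration: sampling → WHAM → FEP → decomposition.

This module wires the pieces into the full measurement: umbrella sampling of
the solvated chain for F_GB(R), sequential dielectric-ladder sampling at fixed
R for μ_ex^GB(R), backend reweighting for Δμ_ref^GB(R; T, P), the
charge-zeroed route for μ_nonpol(R), and vacuum fixed-R ensembles for the
energy/entropy split of F_vac(R).  Each stage returns ordinary containers
(FrameSet, PerFrameEnergyTable, FreeEnergyProfile) so partial pipelines and
externally produced tables slot in at any point.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .backends import HydrationBackend
from .decompose import (
    DecomposedProfiles,
    add_intramolecular_split,
    add_nonpolar_split,
    assemble_cycle,
    intramolecular_energy_profile,
)
from .fep import (
    DielectricLadder,
    PerFrameEnergyTable,
    bidirectional_ladder,
    gb_column,
    hyd_column,
    reweight_to_reference,
)
from .model import (
    ChainTopology,
    Conformation,
    SolventModel,
    gb_components,
    intramolecular_energy,
)
from .sampler import (
    FrameSet,
    SamplingProtocol,
    UmbrellaWindow,
    run_sampling,
    sequential_ladder_sampling,
)
from .wham import (
    FreeEnergyProfile,
    UmbrellaHistogramSet,
    bootstrap_errors,
    profile_shift,
    wham_solve,
)


def ladder_solvents(ladder: DielectricLadder, sa_on: bool = True,
                    probe_radius: float = 0.14) -> list[SolventModel]:
    """Solvent states along the ladder: surface term on except at exact vacuum."""
    return [
        SolventModel(eps_r=e, sa_on=(sa_on and e > 1.0), probe_radius=probe_radius)
        for e in ladder.sequence
    ]


def _dg_solv(topology, coords, eps_r, sa_on, probe_radius=0.14):
    pol, sa = gb_components(topology, Conformation(coords), probe_radius)
    e = 0.0
    if eps_r > 1.0:
        e += -0.5 * (1.0 - 1.0 / eps_r) * pol
    if sa_on:
        e += sa
    return e


def ladder_energy_table(
    topology: ChainTopology,
    fixed_r: float,
    ladder: DielectricLadder,
    protocol: SamplingProtocol,
    temperature: float = 298.0,
    backend: Optional[HydrationBackend] = None,
    pressures: Sequence[float] = (1.0,),
    sa_on: bool = True,
    framesets: Optional[dict] = None,
) -> PerFrameEnergyTable:
    """Per-frame energy table for one fixed R: all ladder states + backend column.

    Samples the sequential ladder (unless ``framesets`` are supplied), then
    evaluates ΔG_solv at every ladder ε for every frame, and the backend
    hydration free energy at each requested pressure on the water-state
    (ε = 80) frames.
    """
    solvents = ladder_solvents(ladder, sa_on=sa_on)
    if framesets is None:
        proto = SamplingProtocol(
            integrator=protocol.integrator, step_size=protocol.step_size,
            n_equilibration=protocol.n_equilibration, n_production=protocol.n_production,
            stride=protocol.stride, temperature=temperature, seed=protocol.seed,
            fixed_mode=protocol.fixed_mode,
            fixed_force_constant=protocol.fixed_force_constant,
        )
        framesets = sequential_ladder_sampling(topology, solvents, fixed_r, proto)
    rows = []
    for solvent in solvents:
        fs = framesets[solvent.eps_r]
        for i, coords in enumerate(fs.coordinates):
            row = {
                "window_r": fixed_r,
                "state": PerFrameEnergyTable.state_label(solvent.eps_r),
                "frame": i,
            }
            for eps_eval, solv_eval in zip(ladder.sequence, solvents):
                row[gb_column(eps_eval)] = _dg_solv(
                    topology, coords, eps_eval, solv_eval.sa_on, solv_eval.probe_radius
                )
            if backend is not None and solvent.eps_r == 80.0:
                conf = Conformation(coords, frame_id=i)
                for p in pressures:
                    row[hyd_column(temperature, p)] = backend(topology, conf, temperature, p)
            rows.append(row)
    return PerFrameEnergyTable(pd.DataFrame(rows))


def umbrella_histograms(
    topology: ChainTopology,
    windows: Sequence[UmbrellaWindow],
    protocol: SamplingProtocol,
    solvent: SolventModel,
    bin_edges: np.ndarray,
) -> UmbrellaHistogramSet:
    """Run one umbrella window per restraint center and histogram the R values."""
    framesets = []
    for i, w in enumerate(windows):
        proto = SamplingProtocol(
            integrator=protocol.integrator, step_size=protocol.step_size,
            n_equilibration=protocol.n_equilibration, n_production=protocol.n_production,
            stride=protocol.stride, temperature=protocol.temperature,
            seed=int((protocol.seed * 99991 + 6133 * i) % (2**31)),
        )
        init = None
        if i > 0:
            init = framesets[-1].last
        framesets.append(run_sampling(topology, solvent, proto, window=w, initial=init))
    return UmbrellaHistogramSet.from_framesets(framesets, windows, bin_edges,
                                               protocol.temperature)


def f_gb_profile(
    topology: ChainTopology,
    windows: Sequence[UmbrellaWindow],
    protocol: SamplingProtocol,
    solvent: SolventModel,
    bin_edges: np.ndarray,
    n_boot: int = 30,
    r_ref: Optional[float] = None,
) -> FreeEnergyProfile:
    """F_GB(R): umbrella sampling + WHAM + bootstrap errors, shifted to r_ref."""
    hset = umbrella_histograms(topology, windows, protocol, solvent, bin_edges)
    prof = wham_solve(hset, r_ref=r_ref)
    errs = bootstrap_errors(hset, n_boot=n_boot, seed=protocol.seed + 1, r_ref=prof.r_ref)
    prof.errors = errs
    return prof


def profiles_from_tables(
    table: PerFrameEnergyTable,
    r_grid: Sequence[float],
    ladder: DielectricLadder,
    temperature: float,
    pressure: float = 1.0,
    r_ref: Optional[float] = None,
    with_backend: bool = True,
) -> tuple[FreeEnergyProfile, Optional[FreeEnergyProfile]]:
    """μ_ex^GB(R) and Δμ_ref^GB(R; T, P) from a per-frame energy table."""
    r_grid = np.asarray(r_grid, dtype=float)
    mu_vals, mu_errs, dm_vals, dm_errs = [], [], [], []
    for r in r_grid:
        res = bidirectional_ladder(table, r, ladder, temperature)
        mu_vals.append(res.value)
        mu_errs.append(res.error)
        if with_backend:
            dg_hyd = table.energies(r, PerFrameEnergyTable.state_label(80.0),
                                    hyd_column(temperature, pressure))
            dg_gb = table.energies(r, PerFrameEnergyTable.state_label(80.0),
                                   gb_column(80.0))
            rw = reweight_to_reference(dg_hyd, dg_gb, temperature)
            dm_vals.append(rw.value)
            dm_errs.append(rw.error)
    mu = FreeEnergyProfile(r_grid, np.array(mu_vals), np.array(mu_errs),
                           temperature=temperature, component="mu_ex_GB")
    dm = None
    if with_backend:
        dm = FreeEnergyProfile(r_grid, np.array(dm_vals), np.array(dm_errs),
                               temperature=temperature, pressure=pressure,
                               component="dmu_ref_GB")
    if r_ref is not None:
        mu = profile_shift(mu, r_ref)
        if dm is not None:
            dm = profile_shift(dm, r_ref)
    return mu, dm


def nonpolar_profile(
    topology: ChainTopology,
    r_grid: Sequence[float],
    protocol: SamplingProtocol,
    backend: Optional[HydrationBackend],
    temperature: float = 298.0,
    pressure: float = 1.0,
    r_ref: Optional[float] = None,
) -> FreeEnergyProfile:
    """μ_nonpol(R): charge-zeroed single-step route, vacuum ↔ surface-only water.

    The charge-zeroed chain is sampled at ε_r = 1 (vacuum) and at ε_r = 80
    (surface term only — the polar term vanishes without charges); the single
    bidirectional step [Δμ_80^1 − Δμ_1^80]/2, taken in the hydration
    direction, plus the charge-zeroed backend reweighting gives μ_nonpol.
    """
    if np.any(topology.charges != 0.0):
        raise ValueError("nonpolar route requires a charge-zeroed topology")
    r_grid = np.asarray(r_grid, dtype=float)
    ladder2 = DielectricLadder((80.0, 1.0))
    vals, errs = [], []
    for r in r_grid:
        table = ladder_energy_table(
            topology, r, ladder2, protocol, temperature=temperature,
            backend=backend, pressures=(pressure,),
        )
        res = bidirectional_ladder(table, r, ladder2, temperature)
        v, e2 = res.value, res.error**2
        if backend is not None:
            dg_hyd = table.energies(r, PerFrameEnergyTable.state_label(80.0),
                                    hyd_column(temperature, pressure))
            dg_gb = table.energies(r, PerFrameEnergyTable.state_label(80.0),
                                   gb_column(80.0))
            rw = reweight_to_reference(dg_hyd, dg_gb, temperature)
            v += rw.value
            e2 += rw.error**2
        vals.append(v)
        errs.append(np.sqrt(e2))
    prof = FreeEnergyProfile(r_grid, np.array(vals), np.array(errs),
                             temperature=temperature, pressure=pressure,
                             component="mu_nonpol")
    return profile_shift(prof, r_ref) if r_ref is not None else prof


def vacuum_energy_profile(
    topology: ChainTopology,
    r_grid: Sequence[float],
    protocol: SamplingProtocol,
    temperature: float,
    r_ref: float,
) -> FreeEnergyProfile:
    """E_intra(R): mean intramolecular energy over vacuum fixed-R ensembles."""
    energies = {}
    vacuum = SolventModel(eps_r=1.0, sa_on=False)
    for i, r in enumerate(np.asarray(r_grid, dtype=float)):
        proto = SamplingProtocol(
            integrator=protocol.integrator, step_size=protocol.step_size,
            n_equilibration=protocol.n_equilibration, n_production=protocol.n_production,
            stride=protocol.stride, temperature=temperature,
            seed=int((protocol.seed * 90001 + 4099 * i) % (2**31)),
            fixed_mode=protocol.fixed_mode,
            fixed_force_constant=protocol.fixed_force_constant,
        )
        fs = run_sampling(topology, vacuum, proto, fixed_r=float(r))
        energies[float(r)] = [
            intramolecular_energy(topology, Conformation(c)) for c in fs.coordinates
        ]
    return intramolecular_energy_profile(energies, temperature, r_ref)


def compute_decomposition(
    topology: ChainTopology,
    r_grid: Sequence[float],
    windows: Sequence[UmbrellaWindow],
    bin_edges: np.ndarray,
    ladder: DielectricLadder,
    backend: HydrationBackend,
    protocol: SamplingProtocol,
    temperature: float = 298.0,
    pressure: float = 1.0,
    r_ref: Optional[float] = None,
    n_boot: int = 30,
    sa_on: bool = True,
    with_nonpolar: bool = True,
    with_intramolecular: bool = True,
    umbrella_protocol: Optional[SamplingProtocol] = None,
) -> DecomposedProfiles:
    """The full measurement on one system at one (T, P).

    Umbrella sampling at ε_r = 80 gives F_GB(R) (WHAM + bootstrap); fixed-R
    ladder sampling and backend reweighting give μ_ex^GB and Δμ_ref^GB on
    ``r_grid``; the charge-zeroed route gives μ_nonpol; vacuum ensembles give
    the energy/entropy split.  F_GB is resampled onto ``r_grid`` explicitly
    before assembly.  ``umbrella_protocol`` optionally overrides run lengths
    for the umbrella stage (e.g. a longer stride, since histogram errors
    assume roughly independent frames); fixed-R stages use ``protocol``.
    """
    from .wham import resample_profile

    r_grid = np.asarray(r_grid, dtype=float)
    if r_ref is None:
        r_ref = float(r_grid[0])
    water = SolventModel(eps_r=80.0, sa_on=sa_on)
    proto_t = SamplingProtocol(
        integrator=protocol.integrator, step_size=protocol.step_size,
        n_equilibration=protocol.n_equilibration, n_production=protocol.n_production,
        stride=protocol.stride, temperature=temperature, seed=protocol.seed,
        fixed_mode=protocol.fixed_mode,
        fixed_force_constant=protocol.fixed_force_constant,
    )

    umb = umbrella_protocol if umbrella_protocol is not None else protocol
    proto_umb = SamplingProtocol(
        integrator=umb.integrator, step_size=umb.step_size,
        n_equilibration=umb.n_equilibration, n_production=umb.n_production,
        stride=umb.stride, temperature=temperature, seed=umb.seed,
    )
    f_gb = f_gb_profile(topology, windows, proto_umb, water, bin_edges,
                        n_boot=n_boot, r_ref=r_ref)
    f_gb = profile_shift(resample_profile(f_gb, r_grid), r_ref)

    tables = []
    for i, r in enumerate(r_grid):
        proto_r = SamplingProtocol(
            integrator=proto_t.integrator, step_size=proto_t.step_size,
            n_equilibration=proto_t.n_equilibration, n_production=proto_t.n_production,
            stride=proto_t.stride, temperature=temperature,
            seed=int((proto_t.seed * 77003 + 1009 * i) % (2**31)),
            fixed_mode=proto_t.fixed_mode,
            fixed_force_constant=proto_t.fixed_force_constant,
        )
        tables.append(ladder_energy_table(
            topology, float(r), ladder, proto_r, temperature=temperature,
            backend=backend, pressures=(pressure,), sa_on=sa_on,
        ))
    table = PerFrameEnergyTable.concat(tables)
    mu_ex_gb, dmu = profiles_from_tables(table, r_grid, ladder, temperature,
                                         pressure, r_ref=r_ref)

    dec = assemble_cycle(f_gb, mu_ex_gb, dmu, pressure=pressure)
    dec.r_ref = r_ref

    if with_nonpolar:
        mu_np = nonpolar_profile(topology.charge_zeroed(), r_grid, proto_t,
                                 backend, temperature, pressure, r_ref=r_ref)
        add_nonpolar_split(dec, mu_np)
    if with_intramolecular:
        e_intra = vacuum_energy_profile(topology, r_grid, proto_t, temperature, r_ref)
        add_intramolecular_split(dec, e_intra)
    return dec
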