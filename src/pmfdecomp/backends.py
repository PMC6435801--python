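"""Pluggable per-conformation hydration-free-energy providers.

The reweighting correction Δμ_ref^GB(R; T, P) needs one number per
conformation: a hydration free energy ΔG_hyd(topology, conformation, T, P) in
kJ mol⁻¹ from some reference model of water.  That model is deliberately
*outside* this package — a molecular liquid-state theory, an explicit-solvent
estimate, or anything else — so the module boundary is the per-conformation
number.  Three providers are included:

* :func:`gb_backend` — the sampling model itself (self-consistency checks);
* :func:`toy_reference_backend` — a synthetic reference with explicit
  temperature and pressure dependence, for exercising the (T, P) workflows
  with known analytic derivatives;
* :func:`table_backend` — exact-key lookup from a TSV file, so externally
  computed hydration free energies (e.g. from a density-functional water
  model) can be ingested per frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .constants import BAR_CM3_TO_KJ
from .model import ChainTopology, Conformation, SolventModel, solvation_free_energy, surface_areas


@dataclass(frozen=True)
class HydrationBackend:
    """Deterministic callable (topology, conformation, T, P) → ΔG_hyd (kJ mol⁻¹)."""

    name: str
    fn: Callable[[ChainTopology, Conformation, float, float], float]
    t_range: tuple[float, float] = (0.0, np.inf)
    p_range: tuple[float, float] = (-np.inf, np.inf)

    def __call__(
        self, topology: ChainTopology, conformation: Conformation,
        temperature: float, pressure: float,
    ) -> float:
        if not (self.t_range[0] <= temperature <= self.t_range[1]):
            raise ValueError(
                f"backend {self.name!r}: T = {temperature} K outside domain {self.t_range}"
            )
        if not (self.p_range[0] <= pressure <= self.p_range[1]):
            raise ValueError(
                f"backend {self.name!r}: P = {pressure} bar outside domain {self.p_range}"
            )
        return float(self.fn(topology, conformation, temperature, pressure))


def gb_backend(eps_r: float, sa_on: bool = True, probe_radius: float = 0.14) -> HydrationBackend:
    """The GB/SA sampling model itself as a backend; T and P are ignored."""
    solvent = SolventModel(eps_r=eps_r, sa_on=sa_on, probe_radius=probe_radius)

    def fn(top, conf, temperature, pressure):
        return solvation_free_energy(top, conf, solvent)

    return HydrationBackend(name=f"gb[eps={eps_r:g}]", fn=fn)


@dataclass(frozen=True)
class ToyReferenceParams:
    """Parameters of the synthetic reference hydration model.

    ΔG_hyd = ΔG_GB'(conf) + γ(T)·A(conf) + P·v_ex(conf) with
    γ(T) = γ_ref·(1 + c_T (T − 298)) applied on top of the per-bead surface
    tensions, and excluded volume v_ex = v0 + v_area·A (cm³ mol⁻¹) linear in
    the accessible area, so ∂ΔG_hyd/∂P = v_ex exactly.
    """

    eps_r: float = 78.0          # slightly different dielectric than the sampling model
    radius_scale: float = 1.05   # Born radii scaling of the primed GB term
    gamma_ref: float = 0.2       # kJ mol⁻¹ nm⁻², added uniform surface tension at 298 K
    c_t: float = 2.0e-3          # K⁻¹, linear T coefficient of the surface term
    v0: float = 10.0             # cm³ mol⁻¹, conformation-independent excluded volume
    v_area: float = 5.0          # cm³ mol⁻¹ nm⁻², area coefficient of v_ex
    probe_radius: float = 0.14
    t_range: tuple[float, float] = (250.0, 400.0)
    p_range: tuple[float, float] = (0.0, 10000.0)


def toy_excluded_volume(topology: ChainTopology, conformation: Conformation,
                        params: ToyReferenceParams) -> float:
    """v_ex of the toy reference model, cm³ mol⁻¹."""
    area = float(np.sum(surface_areas(topology, conformation.coordinates, params.probe_radius)))
    return params.v0 + params.v_area * area


def toy_reference_backend(params: ToyReferenceParams = ToyReferenceParams()) -> HydrationBackend:
    """Synthetic reference hydration model with explicit (T, P) dependence.

    At P = 0 and T = 298 K it reduces to the primed GB/SA model alone;
    pressure enters only through P·v_ex, so the pressure derivative of
    ΔG_hyd is v_ex exactly (handy for validating the pressure workflow).
    """
    from dataclasses import replace

    def fn(top, conf, temperature, pressure):
        primed = replace(top, born_radii=top.born_radii * params.radius_scale)
        solvent = SolventModel(eps_r=params.eps_r, sa_on=True, probe_radius=params.probe_radius)
        dg = solvation_free_energy(primed, conf, solvent)
        area = float(np.sum(surface_areas(top, conf.coordinates, params.probe_radius)))
        gamma_t = params.gamma_ref * (1.0 + params.c_t * (temperature - 298.0))
        dg += gamma_t * area
        dg += pressure * toy_excluded_volume(top, conf, params) * BAR_CM3_TO_KJ
        return dg

    return HydrationBackend(
        name="toy_reference", fn=fn, t_range=params.t_range, p_range=params.p_range
    )


def table_backend(path) -> HydrationBackend:
    """Backend reading per-frame hydration free energies from a TSV file.

    The file holds columns ``frame_id``, ``temperature_K``, ``pressure_bar``,
    ``dg_hyd_kJ_mol`` (``#`` comment lines allowed).  Lookup is by exact key
    (frame id, T, P); a missing key or a malformed file is an explicit error.
    Conformations passed to this backend must carry their ``frame_id``.
    """
    required = ["frame_id", "temperature_K", "pressure_bar", "dg_hyd_kJ_mol"]
    try:
        df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    except Exception as exc:
        raise ValueError(f"cannot parse backend table {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"backend table {path} missing columns {missing}")
    for ln, row in enumerate(df.itertuples(index=False), start=2):
        if not np.isfinite(row.dg_hyd_kJ_mol):
            raise ValueError(f"backend table {path}: non-finite value at line {ln}")
    lookup = {
        (int(r.frame_id), float(r.temperature_K), float(r.pressure_bar)): float(r.dg_hyd_kJ_mol)
        for r in df.itertuples(index=False)
    }

    def fn(top, conf, temperature, pressure):
        if conf.frame_id is None:
            raise ValueError("table backend requires conformations with a frame_id")
        key = (int(conf.frame_id), float(temperature), float(pressure))
        if key not in lookup:
            raise KeyError(
                f"no table entry for frame {key[0]} at T = {temperature} K, P = {pressure} bar"
            )
        return lookup[key]

    return HydrationBackend(name=f"table[{path}]", fn=fn)


def write_backend_table(path, frame_ids, temperature, pressure, values) -> None:
    """Write a backend TSV in the format :func:`table_backend` reads."""
    df = pd.DataFrame(
        {
            "frame_id": np.asarray(frame_ids, dtype=int),
            "temperature_K": float(temperature),
            "pressure_bar": float(pressure),
            "dg_hyd_kJ_mol": np.asarray(values, dtype=float),
        }
    )
    with open(path, "w") as fh:
        fh.write("# per-frame hydration free energies (kJ mol^-1)\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")
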