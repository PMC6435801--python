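"""Thermodynamic-cycle assembly and decomposition of free-energy profiles.

The profile of a chain in solvent along its end-to-end distance R splits as

    F(R) = F_vac(R) + μ_ex(R),                 (intramolecular + solvent-induced)
    F_vac(R) = E_intra(R) − T·S_intra(R),      (energy + conformational entropy)
    μ_ex(R) = μ_nonpol(R) + μ_pol(R),          (charge-zeroed + remainder)

and is assembled from three measured pieces: the implicit-solvent profile
F_GB(R) (umbrella sampling + WHAM), the dielectric-ladder excess chemical
potential μ_ex^GB(R), and the backend reweighting correction Δμ_ref^GB(R):

    F_vac = F_GB − μ_ex^GB,   F = F_GB + Δμ_ref^GB,   μ_ex = μ_ex^GB + Δμ_ref^GB,

so F = F_vac + μ_ex closes exactly by construction.  Temperature differences
are taken profile-wise in each temperature's own k_BT units; pressure enters
only through the backend, so Δ_P F = Δ_P μ_ex is an identity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .constants import kt, J_PER_BAR_TO_CM3
from .wham import FreeEnergyProfile, profile_shift

#: canonical component keys of a full decomposition
COMPONENTS = (
    "F", "F_GB", "F_vac", "mu_ex", "mu_ex_GB", "dmu_ref_GB",
    "mu_nonpol", "mu_pol", "E_intra", "minus_TS_intra",
)


def _check_aligned(*profiles: FreeEnergyProfile) -> None:
    ref = profiles[0]
    for p in profiles[1:]:
        if len(p.r) != len(ref.r) or not np.allclose(p.r, ref.r, rtol=0, atol=1e-12):
            raise ValueError(
                "profiles are on different R grids; resample explicitly first"
            )
        if p.temperature != ref.temperature:
            raise ValueError("profiles have different temperatures")


def _combine(a: FreeEnergyProfile, b: FreeEnergyProfile, sign: float,
             component: str) -> FreeEnergyProfile:
    return replace(
        a,
        values=a.values + sign * b.values,
        errors=np.sqrt(a.errors**2 + b.errors**2),
        component=component,
    )


@dataclass
class DecomposedProfiles:
    """The full profile set on one R grid, in k_BT, with metadata."""

    profiles: dict
    temperature: float
    pressure: float = 1.0
    r_ref: Optional[float] = None

    def __getitem__(self, key: str) -> FreeEnergyProfile:
        return self.profiles[key]

    def __contains__(self, key: str) -> bool:
        return key in self.profiles

    @property
    def r(self) -> np.ndarray:
        return next(iter(self.profiles.values())).r

    def identity_residuals(self) -> dict:
        """Max |residual| of each bin-wise identity present in the set."""
        out = {}
        p = self.profiles
        if all(k in p for k in ("F", "F_vac", "mu_ex")):
            out["F - F_vac - mu_ex"] = float(
                np.nanmax(np.abs(p["F"].values - p["F_vac"].values - p["mu_ex"].values))
            )
        if all(k in p for k in ("mu_ex", "mu_nonpol", "mu_pol")):
            out["mu_ex - mu_nonpol - mu_pol"] = float(
                np.nanmax(np.abs(p["mu_ex"].values - p["mu_nonpol"].values - p["mu_pol"].values))
            )
        if all(k in p for k in ("F_vac", "E_intra", "minus_TS_intra")):
            out["F_vac - E_intra - (-TS_intra)"] = float(
                np.nanmax(np.abs(
                    p["F_vac"].values - p["E_intra"].values - p["minus_TS_intra"].values
                ))
            )
        return out


def assemble_cycle(
    f_gb: FreeEnergyProfile,
    mu_ex_gb: FreeEnergyProfile,
    dmu_ref_gb: FreeEnergyProfile,
    pressure: float = 1.0,
) -> DecomposedProfiles:
    """Assemble F, F_vac and μ_ex from the three measured profiles.

    All inputs must already share the R grid (resampling is an explicit prior
    step).  Errors combine in quadrature; the closure F = F_vac + μ_ex is an
    algebraic identity of the construction.
    """
    _check_aligned(f_gb, mu_ex_gb, dmu_ref_gb)
    f_vac = _combine(f_gb, mu_ex_gb, -1.0, "F_vac")
    f = _combine(f_gb, dmu_ref_gb, +1.0, "F")
    mu_ex = _combine(mu_ex_gb, dmu_ref_gb, +1.0, "mu_ex")
    profs = {
        "F": f,
        "F_GB": replace(f_gb, component="F_GB"),
        "F_vac": f_vac,
        "mu_ex": mu_ex,
        "mu_ex_GB": replace(mu_ex_gb, component="mu_ex_GB"),
        "dmu_ref_GB": replace(dmu_ref_gb, component="dmu_ref_GB"),
    }
    return DecomposedProfiles(
        profs, temperature=f_gb.temperature, pressure=pressure, r_ref=f_gb.r_ref
    )


def add_nonpolar_split(
    decomposed: DecomposedProfiles, mu_nonpol: FreeEnergyProfile
) -> DecomposedProfiles:
    """Attach μ_nonpol and the implied μ_pol = μ_ex − μ_nonpol."""
    _check_aligned(decomposed["mu_ex"], mu_nonpol)
    mu_pol = _combine(decomposed["mu_ex"], mu_nonpol, -1.0, "mu_pol")
    decomposed.profiles["mu_nonpol"] = replace(mu_nonpol, component="mu_nonpol")
    decomposed.profiles["mu_pol"] = mu_pol
    return decomposed


def add_intramolecular_split(
    decomposed: DecomposedProfiles, e_intra: FreeEnergyProfile
) -> DecomposedProfiles:
    """Attach E_intra and the implied entropy term −TS_intra = F_vac − E_intra."""
    _check_aligned(decomposed["F_vac"], e_intra)
    minus_ts = _combine(decomposed["F_vac"], e_intra, -1.0, "minus_TS_intra")
    decomposed.profiles["E_intra"] = replace(e_intra, component="E_intra")
    decomposed.profiles["minus_TS_intra"] = minus_ts
    return decomposed


def delta_T_profile(at_t1: DecomposedProfiles, at_t2: DecomposedProfiles) -> dict:
    """Δ_T X(R) = X(R, T₂)/k_BT₂ − X(R, T₁)/k_BT₁ per component (dimensionless).

    Both sets must share grid and zero reference; each profile is already in
    its own temperature's k_BT units.  Component additivity
    (Δ_T F = Δ_T F_vac + Δ_T μ_ex, Δ_T μ_ex = Δ_T μ_nonpol + Δ_T μ_pol)
    carries over bin-wise by construction.
    """
    if len(at_t1.r) != len(at_t2.r) or not np.allclose(at_t1.r, at_t2.r, rtol=0, atol=1e-12):
        raise ValueError("temperature sets are on different R grids")
    if at_t1.r_ref != at_t2.r_ref:
        raise ValueError("temperature sets have different zero references")
    out = {}
    for key in at_t1.profiles:
        if key in at_t2.profiles:
            out[key] = at_t2[key].values - at_t1[key].values
    return out


def delta_P_profile(at_p1: DecomposedProfiles, at_p2: DecomposedProfiles) -> dict:
    """Δ_P X(R) per component (dimensionless), with Δ_P F ≡ Δ_P μ_ex enforced.

    Pressure enters the cycle only through the backend reweighting, so the
    vacuum profile is pressure-independent and Δ_P F equals Δ_P μ_ex
    identically; both sets must come from the same temperature and sampling
    ensembles.
    """
    if at_p1.temperature != at_p2.temperature:
        raise ValueError("pressure comparison requires a shared temperature")
    if len(at_p1.r) != len(at_p2.r) or not np.allclose(at_p1.r, at_p2.r, rtol=0, atol=1e-12):
        raise ValueError("pressure sets are on different R grids")
    dvac = at_p2["F_vac"].values - at_p1["F_vac"].values
    if np.nanmax(np.abs(dvac)) > 1e-9:
        raise ValueError(
            "F_vac differs between pressures: pressure must enter only through the backend"
        )
    out = {}
    for key in at_p1.profiles:
        if key in at_p2.profiles:
            out[key] = at_p2[key].values - at_p1[key].values
    out["F"] = out["mu_ex"].copy()  # identity: F_vac is pressure-independent
    return out


def intramolecular_energy_profile(
    energies_by_r: dict,
    temperature: float,
    r_ref: float,
) -> FreeEnergyProfile:
    """E_intra(R): mean intramolecular energy over vacuum fixed-R ensembles.

    ``energies_by_r`` maps each grid R (nm) to the per-frame intramolecular
    energies (kJ mol⁻¹) of the vacuum ensemble at that R.  The mean is
    converted to k_BT and shifted to the zero reference; the standard error is
    the ensemble standard error of the mean.
    """
    rs = np.array(sorted(energies_by_r), dtype=float)
    if len(rs) == 0:
        raise ValueError("no vacuum ensembles supplied")
    means, errs = [], []
    for r in rs:
        e = np.asarray(energies_by_r[r], dtype=float)
        if len(e) == 0:
            raise ValueError(f"missing vacuum ensemble at R = {r} nm")
        means.append(np.mean(e) / kt(temperature))
        errs.append(np.std(e, ddof=1) / np.sqrt(len(e)) / kt(temperature) if len(e) > 1 else 0.0)
    prof = FreeEnergyProfile(
        r=rs, values=np.array(means), errors=np.array(errs),
        temperature=temperature, component="E_intra",
    )
    return profile_shift(prof, r_ref)


def unfolding_free_energy(
    profile: FreeEnergyProfile,
    folded_r: Sequence[float],
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """ΔF_u = ln(p_folded/p_unfolded) in k_BT, with bootstrap error.

    State probabilities are plain grid-point sums of w(R) ∝ exp(−F(R)/k_BT):
    the folded state is the given R set, the unfolded state every other
    sampled grid point.  Positive ΔF_u means the folded state is more stable.
    The error resamples the profile from its per-bin standard errors.
    """
    ok = np.isfinite(profile.values)
    if not ok.any():
        raise ValueError("profile has no finite bins")
    folded_idx = {profile.index_of(r) for r in folded_r}
    if not folded_idx:
        raise ValueError("folded-state R set is empty")
    mask_f = np.zeros(len(profile.r), dtype=bool)
    mask_f[list(folded_idx)] = True
    mask_f &= ok
    mask_u = ok & ~mask_f
    if not mask_f.any() or not mask_u.any():
        raise ValueError("profile does not cover both folded and unfolded regions")

    def dfu(values):
        v = values - np.nanmin(values[ok])
        w = np.exp(-v)
        p_f, p_u = w[mask_f].sum(), w[mask_u].sum()
        if p_f <= 0 or p_u <= 0 or not np.isfinite(p_f) or not np.isfinite(p_u):
            raise ValueError("degenerate profile: a state probability vanished")
        return float(np.log(p_f / p_u))

    value = dfu(profile.values)
    if n_boot >= 2 and np.any(profile.errors[ok] > 0):
        rng = np.random.default_rng(seed)
        reps = [
            dfu(profile.values + rng.normal(0.0, 1.0, len(profile.values))
                * np.where(np.isfinite(profile.errors), profile.errors, 0.0))
            for _ in range(n_boot)
        ]
        err = float(np.std(reps, ddof=1))
    else:
        err = 0.0
    return value, err


def delta_T_unfolding(dfu_t2_kt: float, dfu_t1_kt: float) -> float:
    """Δ_T F_u = ΔF_u(T₂)/k_BT₂ − ΔF_u(T₁)/k_BT₁ (both already in k_BT units)."""
    return float(dfu_t2_kt - dfu_t1_kt)


def partial_molar_volume(
    pressures_bar: Sequence[float],
    dfu_kt: Sequence[float],
    temperature: float,
) -> float:
    """ΔV = (∂ΔF_u/∂P)_T in cm³ mol⁻¹ by least squares over all pressures.

    ΔF_u values are in k_BT; the slope of ΔF_u·k_BT (J mol⁻¹) against P (bar)
    converts via 1 J mol⁻¹ bar⁻¹ = 10 cm³ mol⁻¹.
    """
    p = np.asarray(pressures_bar, dtype=float)
    f = np.asarray(dfu_kt, dtype=float)
    if len(p) < 2:
        raise ValueError("need at least two pressures for a volume estimate")
    slope_kt_per_bar = np.polyfit(p, f, 1)[0]
    slope_j = slope_kt_per_bar * kt(temperature) * 1000.0  # J mol⁻¹ bar⁻¹
    return float(slope_j * J_PER_BAR_TO_CM3)


@dataclass
class ThermoSummary:
    """Unfolding thermodynamics: ΔF_u per (T, P), Δ_T F_u, ΔV."""

    dfu: dict                      # (T, P) → (value k_BT, error)
    folded_r: tuple
    delta_t_fu: Optional[float] = None
    delta_v_cm3: Optional[float] = None

    def __post_init__(self):
        if not self.folded_r:
            raise ValueError("folded-state R set must be non-empty")
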