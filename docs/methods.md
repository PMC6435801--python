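# Methods

## The measurement

`pmfdecomp` measures and decomposes the free-energy profile of a bead-spring
chain along its end-to-end distance R (the distance between the two terminal
beads, the standard one-dimensional measure of chain dimensions).  The profile
in solvent splits into a purely intramolecular part and a solvent-induced
part,

    F(R) = F_vac(R) + μ_ex(R),

where F_vac is the profile the chain would have in vacuum and μ_ex(R) is the
excess chemical potential — the reversible work of transferring the chain from
vacuum to solvent at fixed R, *including* conformational relaxation during the
transfer.  Two further splits are measured:

    F_vac(R) = E_intra(R) − T·S_intra(R)        (energy vs conformational entropy)
    μ_ex(R)  = μ_nonpol(R) + μ_pol(R)           (charge-zeroed vs electrostatic)

μ_nonpol is obtained by literally removing every partial charge and re-running
the transfer; it upper-bounds the hydrophobic contribution because nonpolar
solvation of polar groups is still included.

Direct umbrella sampling of the vacuum chain is impractical when vacuum
barriers are much higher than solvated ones, so the cycle is built the other
way around:

1. **F_GB(R)** — umbrella sampling + WHAM in an implicit solvent (GB/SA at
   ε_r = 80), where barriers are low.
2. **μ_ex^GB(R)** — a free-energy-perturbation ladder that switches the
   dielectric from 80 down to 1 at fixed R, giving the solvation part of the
   implicit model itself; then F_vac = F_GB − μ_ex^GB.
3. **Δμ_ref^GB(R; T, P)** — a one-step exponential reweighting of the ε = 80
   ensemble from the GB/SA hydration free energy to any better reference
   hydration model (a pluggable backend); then F = F_GB + Δμ_ref^GB and
   μ_ex = μ_ex^GB + Δμ_ref^GB.

F = F_vac + μ_ex then closes *by construction*; the test suite asserts all
three identities below 1e−10 k_BT bin-wise on every assembled result.

Because a free-energy difference between two fixed states is path-independent,
the decomposition of the folded↔unfolded difference does not depend on the
choice of R as the coordinate.

## Model

**Chain.** Beads carry partial charges (e), intrinsic Born radii (nm),
Lennard-Jones σ/ε, and per-bead surface-tension coefficients; harmonic bonds
and optional harmonic angles connect them.  Intramolecular energy = bonds +
angles + LJ + Coulomb (interior dielectric 1), with directly bonded (1-2)
pairs excluded from LJ/Coulomb in the usual force-field convention.  Units:
kJ mol⁻¹, nm, e; k_B = 0.0083144621 kJ mol⁻¹ K⁻¹; profiles are reported in
k_BT.

**Solvent.** Still-style pairwise generalized Born:

    ΔG_pol = −½ (1 − 1/ε_r) Σ_ij k_e q_i q_j / f_GB(r_ij, R_i, R_j),
    f_GB = sqrt(r² + R_i R_j exp(−r²/4R_iR_j)),

with the i = j diagonal giving Born self-energies.  Effective radii come from
a pairwise Coulomb-field descreening integral for non-overlapping spheres,
evaluated at contact when spheres overlap — a deliberate toy-scale
simplification kept behind `effective_born_radii` so an OBC-style
prescription can replace it.  The nonpolar term is Σ γ_i A_i with per-bead
accessible areas from an analytic pairwise spherical-cap overlap product
(probe radius 0.14 nm by default); no numerical triangulation, so the energy
is cheap and continuous.  ε_r = 1 with the surface term off is exact vacuum.
Along the dielectric ladder the surface term stays on for every ε_r > 1 and
is off only at the ε_r = 1 endpoint, matching the convention that the
nonpolar route perturbs between "vacuum" and "surface term only"; the SA
discontinuity is handled by the perturbation step like any other energy
difference.

The model is deliberately coarse-grained: the decomposition framework is
resolution-agnostic, and that is the claim the toys test.  Which GB variant or
SA parameterization a particular MD engine uses is absorbed by the backend
interface, not guessed.

## Sampling

Metropolis Monte Carlo with single-bead Gaussian moves is the default (no
forces needed, so the kinked analytic SA term costs nothing); an overdamped
Langevin integrator with central-difference forces exists for continuity
checks.  Umbrella mode adds ½k(R − R₀)²; the reference force constant is
1875 kJ mol⁻¹ nm⁻², at which the window width √(k_BT/k) ≈ 0.036 nm comfortably
overlaps the default window spacings (0.02–0.035 nm in the toy
configurations; the reference configuration is 0.0125 nm spacing × 208
windows).

Fixed-R ensembles (used by every alchemical stage) pin the two terminal beads
at separation R and move only interior beads — R is conserved *exactly*, and
the lost rigid-body freedom is an R-independent constant that cancels in all
profile differences.  A stiff-restraint mode (default 10× the umbrella k) is
provided as a cross-check; it records the observed max |R − R_target|.  For a
two-bead chain the pinned ensemble is a single repeated conformation, which
is exactly what makes the rigid-limit identities machine-exact test oracles.

All randomness flows from recorded integer seeds through
`numpy.random.Generator`; identical configurations are bit-for-bit
reproducible, and ladder/window/grid stages derive distinct child seeds from
the protocol seed.

The reference run lengths (10 ns equilibration + 50 ns production → 5000
frames in the emulated protocol) become configurable step counts; toy
configurations use 10³–10⁵ steps sized so the full acceptance suite runs in
minutes on one CPU.  Umbrella stages save frames at a stride of roughly twice
the measured integrated autocorrelation time of R (≈ 7 MC steps for the
dumbbell), so histogram bootstrap errors treat frames as independent — with
short strides the bootstrap visibly underestimates the true error and 3σ
coverage degrades.

## WHAM

Binned histograms from all windows are combined by the standard
self-consistent equations, iterated in log space (log-sum-exp) until the
window constants move by < 1e−8 k_BT (max 1e5 iterations; non-convergence is
an error carrying the residual).  Bins never visited are reported as NaN,
never interpolated; an interior gap in pooled coverage raises an error naming
the interval (non-overlapping windows).  Per-bin standard errors come from a
multinomial bootstrap of each window's histogram (default 30–50 replicates),
each replicate re-solved and re-aligned to the common zero reference.
Profiles carry a zero-reference distance; shifting is idempotent, preserves
pairwise differences exactly, and everything downstream depends only on
differences (gauge invariance).  Resampling onto a coarser grid is an
explicit call (`resample_profile`), and the acceptance configurations place
the decomposition grid on bin centers so that step is interpolation-free.

## Free-energy perturbation

One-step estimate from state i to j over the state-i ensemble:

    Δμ_j^i(R) = −k_BT ln ⟨exp(−(ΔG_j − ΔG_i)/k_BT)⟩_R^i,

always via log-sum-exp, never raw exponentials.  The dielectric ladder
(default 80, 40, 20, 10, 5, 4.2, 3.5, 2.9, 2.4, 2.0, 1.7, 1.4, 1.2, 1 —
thirteen bidirectional steps) is sampled sequentially: each state's run
starts from the final conformation of the previous (higher-ε) state.  Each
adjacent pair contributes (forward − reverse)/2, and the sum along 80 → 1 is
negated so the result points in the hydration direction and
μ_ex^GB = F_GB − F_vac closes the cycle exactly; for a rigid system the sum
telescopes to ΔG(80) − ΔG(1) at machine precision regardless of ladder
resolution (a tested invariant).  The charge-zeroed (nonpolar) route is the
single bidirectional step 1 ↔ 80 plus the charge-zeroed backend reweighting.

Errors: the estimator is recomputed on five equal contiguous blocks of the
frame series (trailing remainder frames are trimmed when the count is not a
multiple of five) and the standard error is stdev(blocks)/√5.  Every
estimate also reports the exponential-weight effective sample size
n_eff = (Σw)²/Σw²; below a configurable floor (default 50) a warning is
recorded in the result — the ladder and reweighting estimates are only as
good as the overlap of adjacent ensembles, and no published overlap criterion
exists for this protocol, so n_eff is the package's own guard.

## Backends

The reference hydration model enters only as a per-conformation number
ΔG_hyd(topology, conformation, T, P).  Implementing a molecular water theory
is explicitly out of scope; instead:

* `gb_backend(ε)` — the sampling model itself (self-consistency: the
  reweighting correction is identically zero);
* `toy_reference_backend` — a synthetic reference with a primed GB term
  (rescaled radii, shifted dielectric), a linearly temperature-dependent
  surface tension γ(T) = γ_ref(1 + c_T (T − 298)), and a pressure term
  P·v_ex with excluded volume v_ex = v0 + v_area·A linear in accessible
  area, so ∂ΔG_hyd/∂P = v_ex exactly (the analytic oracle for the pressure
  workflow).  Defaults (γ_ref = 0.2 kJ mol⁻¹ nm⁻², c_T = 2e−3 K⁻¹,
  v0 = 10 cm³ mol⁻¹, v_area = 5 cm³ mol⁻¹ nm⁻²) are sized to give k_BT-scale
  corrections on the toys; domain T ∈ [250, 400] K, P ∈ [0, 10⁴] bar.
* `table_backend` — exact-key (frame id, T, P) lookup from TSV, so per-frame
  hydration free energies computed by any external model can be ingested.
  The pipeline produces identical results through an exported table and the
  in-memory callable (tested byte-exact; note `pandas.read_csv` needs
  `float_precision="round_trip"` for that).

## Temperature, pressure, unfolding summaries

Temperature differences Δ_T X(R) = X(R, T₂)/k_BT₂ − X(R, T₁)/k_BT₁ require a
full re-measurement at each temperature (sampling included); component
additivity carries over bin-wise.  Pressure enters only through the backend
reweighting — sampling ensembles are reused — so Δ_P F ≡ Δ_P μ_ex is enforced
as an identity (F_vac is pressure-independent) and verified to machine
precision in the rigid limit against ΔP·v_ex/k_BT.

Unfolding free energy: state weights are plain grid-point sums of
exp(−F/k_BT) (no extra Jacobian — F(R) is already the R-distribution's free
energy); the folded state is a configurable R set, the unfolded state all
other sampled grid points, and ΔF_u = ln(p_f/p_u) so positive means folded
more stable.  Errors come from resampling the profile from its per-bin
standard errors.  ΔV = (∂ΔF_u/∂P)_T is a least-squares slope over all
computed pressures (not a single finite difference), converted via
1 J mol⁻¹ bar⁻¹ = 10 cm³ mol⁻¹.

## Toy systems and what they do (not) show

* **Harmonic dumbbell** — two beads on a spring; F(R)/k_BT = βU(R) − 2 ln R
  (3D radial Jacobian), with the GB pair closed form added for charged
  variants.  Oracle for WHAM, the full pipeline, and the energy/entropy split
  (E = βU exactly, −TS = −2 ln R + const).
* **Freely jointed chain** — n_links rigid links (stiff harmonic bonds in the
  sampled topology); exact end-to-end density by radial convolution
  (closed-form R/2b² for two links), validated in-suite against 10⁷
  direct-sampled chains; ⟨R²⟩ = n_links b².  The parameter counts links, not
  beads, to keep density, contour length and ⟨R²⟩ formulas consistent.

The toys have closed-form answers precisely because they lack what real
chains have: many coupled degrees of freedom, rugged vacuum landscapes,
slow conformational relaxation along the ladder, and backend/sampling-model
disagreement large enough to strain the reweighting overlap.  Passing tests
therefore demonstrate the *estimators and the cycle algebra* are correct and
statistically calibrated, not that any particular molecular system is
described well; the n_eff diagnostics and block errors are the tools that
must be watched when the machinery is pointed at real per-frame energy
tables.

## Numerical choices

* Exponential averages: log-sum-exp everywhere; zero perturbation returns
  exactly 0.
* WHAM: direct iteration in log space; tolerance 1e−8 k_BT on the window
  constants.
* Degenerate inputs: empty frame sets, empty windows, charged topologies in
  the nonpolar route, R targets beyond the contour length, and vanishing
  state probabilities in ΔF_u are explicit errors, not NaNs.
* Overlapping Born spheres: descreening integral evaluated at contact
  distance (keeps radii finite and monotone); inverse radii floored at
  1e−6 nm⁻¹.
* Ties in nearest-grid-point lookups resolve to the lower index
  (`argmin` convention) consistently across shifting and oracles.
* All on-disk floats use 17 significant digits; write → read round-trips are
  exact.

## Known limitations

* The GB descreening and cap-overlap SA formulas are toy-grade; absolute
  solvation energies of dense multi-bead clusters are not meant to match any
  published parameterization.
* `table_backend` keys by frame id within one table, so multi-window
  ingestion uses one table per window (the layout the generator emits).
* The Langevin integrator uses finite-difference forces and is intended for
  continuity checks, not production sampling.
* Bootstrap errors assume effectively independent frames; the sampler does
  not estimate autocorrelation times automatically — choose the stride (the
  shipped configurations already do).
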