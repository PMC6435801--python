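"""Weighted histogram analysis of umbrella-sampling runs.

Combines biased R-histograms from overlapping umbrella windows into a single
unbiased free-energy profile F(R) via the standard self-consistent WHAM
equations, iterated in log space (log-sum-exp) for overflow safety.  Bootstrap
resampling of the per-window histograms supplies per-bin standard errors.

Profiles are stored in units of k_BT on a common R grid and carry a
zero-reference distance: the value at the grid point nearest the reference is
exactly zero, and all downstream decompositions depend only on differences
(gauge invariance).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .constants import kt
from .sampler import FrameSet, UmbrellaWindow


@dataclass
class FreeEnergyProfile:
    """Free energy on an R grid, in k_BT, with standard errors.

    ``r_ref`` is the zero-reference distance: after shifting, the value at the
    nearest grid point is exactly 0.  Bins never visited are NaN ("missing"),
    never interpolated silently.
    """

    r: np.ndarray
    values: np.ndarray
    errors: np.ndarray
    r_ref: Optional[float] = None
    temperature: float = 298.0
    pressure: Optional[float] = None
    component: str = ""

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        if not (len(self.r) == len(self.values) == len(self.errors)):
            raise ValueError("grid, values and errors must have equal lengths")
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("R grid must be strictly increasing")
        if np.any(self.errors[np.isfinite(self.errors)] < 0):
            raise ValueError("standard errors must be non-negative")

    def index_of(self, r_val: float) -> int:
        if r_val < self.r[0] - 1e-12 or r_val > self.r[-1] + 1e-12:
            raise ValueError(f"R = {r_val} nm outside profile grid "
                             f"[{self.r[0]}, {self.r[-1]}]")
        return int(np.argmin(np.abs(self.r - r_val)))

    def value_at(self, r_val: float) -> float:
        return float(self.values[self.index_of(r_val)])

    def shifted(self, r_ref: float) -> "FreeEnergyProfile":
        return profile_shift(self, r_ref)


def profile_shift(profile: FreeEnergyProfile, r_ref: float) -> FreeEnergyProfile:
    """Shift the profile so its value at the grid point nearest ``r_ref`` is 0.

    Pairwise differences between grid points are preserved exactly; shifting
    is idempotent and gauge-invariant (adding a constant before shifting
    changes nothing).
    """
    idx = profile.index_of(r_ref)
    ref_val = profile.values[idx]
    if not np.isfinite(ref_val):
        raise ValueError(f"profile has no data at reference R = {r_ref} nm")
    return replace(profile, values=profile.values - ref_val, r_ref=float(r_ref))


def resample_profile(profile: FreeEnergyProfile, r_grid: np.ndarray) -> FreeEnergyProfile:
    """Linear interpolation onto a new grid — an explicit step, never implicit."""
    r_grid = np.asarray(r_grid, dtype=float)
    ok = np.isfinite(profile.values)
    if ok.sum() < 2:
        raise ValueError("cannot resample a profile with fewer than 2 finite bins")
    if r_grid.min() < profile.r[ok].min() - 1e-9 or r_grid.max() > profile.r[ok].max() + 1e-9:
        raise ValueError("target grid extends beyond the profile's sampled range")
    vals = np.interp(r_grid, profile.r[ok], profile.values[ok])
    errs = np.interp(r_grid, profile.r[ok], profile.errors[ok])
    return replace(profile, r=r_grid, values=vals, errors=errs)


@dataclass
class UmbrellaHistogramSet:
    """Per-window R histograms on shared bin edges, plus the windows themselves."""

    bin_edges: np.ndarray
    counts: np.ndarray  # (n_windows, n_bins)
    windows: Sequence[UmbrellaWindow]
    temperature: float = 298.0

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape != (len(self.windows), len(self.bin_edges) - 1):
            raise ValueError("counts must be (n_windows, n_bins)")
        if np.any(self.counts < 0):
            raise ValueError("histogram counts must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @classmethod
    def from_framesets(
        cls,
        framesets: Sequence[FrameSet],
        windows: Sequence[UmbrellaWindow],
        bin_edges: np.ndarray,
        temperature: float = 298.0,
    ) -> "UmbrellaHistogramSet":
        if len(framesets) != len(windows):
            raise ValueError("one frame set per window required")
        counts = np.array([np.histogram(fs.r, bins=bin_edges)[0] for fs in framesets], dtype=float)
        return cls(bin_edges, counts, list(windows), temperature)


def _coverage_check(pooled: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Populated-bin mask; raises if an interior gap splits the coverage."""
    pop = pooled > 0
    if not pop.any():
        raise ValueError("all histogram bins are empty")
    lo, hi = np.argmax(pop), len(pop) - 1 - np.argmax(pop[::-1])
    interior = pop[lo : hi + 1]
    if not interior.all():
        gap = np.where(~interior)[0] + lo
        raise ValueError(
            "umbrella windows do not overlap: no samples in "
            f"R ∈ [{centers[gap[0]]:.4f}, {centers[gap[-1]]:.4f}] nm"
        )
    return pop


def wham_solve(
    histogram_set: UmbrellaHistogramSet,
    tolerance: float = 1e-8,
    max_iter: int = 100_000,
    r_ref: Optional[float] = None,
) -> FreeEnergyProfile:
    """Self-consistent WHAM solution for the unbiased profile F(R) in k_BT.

    Iterates the window free-energy constants f_w until the largest change is
    below ``tolerance`` (k_BT), then returns −ln of the unbiased density,
    shifted to ``r_ref`` (default: the first populated bin).  Bins with zero
    pooled counts inside the trailing/leading unsampled region are NaN.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    centers = histogram_set.centers
    counts = histogram_set.counts
    beta = 1.0 / kt(histogram_set.temperature)
    pooled = counts.sum(axis=0)
    pop = _coverage_check(pooled, centers)

    n_w = counts.sum(axis=1)  # frames per window
    if np.any(n_w == 0):
        raise ValueError("window with zero counts cannot enter WHAM")
    bias = 0.5 * np.array([[w.force_constant for w in histogram_set.windows]]).T \
        * (centers[None, :] - np.array([[w.center for w in histogram_set.windows]]).T) ** 2
    neg_bu = -beta * bias  # (W, B)

    g = np.zeros(len(n_w))  # βf_w
    ln_m = np.where(pop, np.log(np.where(pop, pooled, 1.0)), -np.inf)
    ln_n = np.log(n_w)
    for _ in range(max_iter):
        # ln p_b = ln M_b − ln Σ_w N_w exp(g_w − βU_wb)
        denom = logsumexp(ln_n[:, None] + g[:, None] + neg_bu, axis=0)
        ln_p = ln_m - denom
        g_new = -logsumexp(ln_p[None, :] + neg_bu, axis=1)
        resid = np.max(np.abs(g_new - g))
        g = g_new
        if resid < tolerance:
            break
    else:
        raise RuntimeError(
            f"WHAM failed to converge in {max_iter} iterations "
            f"(residual {resid:.3e} k_BT)"
        )

    f = np.where(pop, -ln_p, np.nan)
    prof = FreeEnergyProfile(
        r=centers,
        values=f,
        errors=np.zeros_like(f),
        temperature=histogram_set.temperature,
        component="F_GB",
    )
    if r_ref is None:
        r_ref = float(centers[np.argmax(pop)])
    return profile_shift(prof, r_ref)


def bootstrap_errors(
    histogram_set: UmbrellaHistogramSet,
    n_boot: int = 50,
    seed: int = 0,
    tolerance: float = 1e-8,
    max_iter: int = 100_000,
    r_ref: Optional[float] = None,
) -> np.ndarray:
    """Per-bin standard error of the WHAM profile by histogram bootstrap.

    Each replicate redraws every window's bin counts from a multinomial with
    the observed bin fractions and the same total, re-solves WHAM, and aligns
    the replicate to the common zero reference; the per-bin error is the
    standard deviation over replicates.  Seed-reproducible.
    """
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    counts = histogram_set.counts
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("empty window: cannot bootstrap")
    probs = counts / totals[:, None]
    base = wham_solve(histogram_set, tolerance, max_iter, r_ref)
    reps = np.empty((n_boot, len(base.values)))
    done, attempts = 0, 0
    while done < n_boot:
        attempts += 1
        if attempts > 20 * n_boot:
            raise RuntimeError("bootstrap: too many replicates lost coverage")
        rc = np.array(
            [rng.multinomial(int(t), p) for t, p in zip(totals, probs)], dtype=float
        )
        hs = UmbrellaHistogramSet(
            histogram_set.bin_edges, rc, histogram_set.windows, histogram_set.temperature
        )
        try:
            reps[done] = wham_solve(hs, tolerance, max_iter, base.r_ref).values
        except ValueError:
            continue  # resampled histogram lost coverage of an interior bin
        done += 1
    finite = np.isfinite(reps)
    out = np.full(reps.shape[1], np.nan)
    ok = finite.sum(axis=0) >= 2
    masked = np.ma.masked_invalid(reps[:, ok])
    out[ok] = np.ma.std(masked, axis=0, ddof=1).filled(np.nan)
    return out
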