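"""Exponential-average estimators: closed forms, telescoping, block errors."""

import numpy as np
import pandas as pd
import pytest

from pmfdecomp.constants import kt
from pmfdecomp.fep import (
    DielectricLadder,
    PerFrameEnergyTable,
    bidirectional_ladder,
    block_standard_error,
    gb_column,
    one_step_perturbation,
    reweight_to_reference,
)

T = 298.0
KT = kt(T)


class TestOneStepPerturbation:
    def test_identical_columns_exact_zero(self, rng):
        dg = rng.normal(0, 5, 100)
        res = one_step_perturbation(dg, dg, T)
        assert res.value == 0.0
        assert res.error == 0.0
        assert res.n_eff == pytest.approx(100.0)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_two_point_closed_form(self):
        """ΔΔG ∈ {0, k_BT ln 2} → −ln((1 + ½)/2) = ln 2 − ln(3/2)."""
        dgi = np.zeros(2)
        dgj = np.array([0.0, KT * np.log(2.0)])
        res = one_step_perturbation(dgj, dgi, T)
        assert res.value == pytest.approx(-np.log(0.75), abs=1e-12)
        assert res.value == pytest.approx(0.2876820724, abs=1e-9)

    def test_gaussian_fep_identity(self, rng):
        """For ΔΔG ~ N(m, σ²): estimate → m/k_BT − σ²/2k_BT² at large n."""
        m, sigma, n = 2.0, 1.0, 100_000
        ddg = rng.normal(m, sigma, n)
        res = one_step_perturbation(ddg, np.zeros(n), T)
        expected = m / KT - sigma**2 / (2 * KT**2)
        assert res.value == pytest.approx(expected, abs=3 * max(res.error, 1e-3))

    def test_antisymmetry_in_expectation(self, rng):
        """Forward estimate from state i ≈ −reverse estimate from state j for
        Gaussian perturbations (both target m ± σ²/2 appropriately)."""
        m, sigma, n = 1.5, 0.8, 200_000
        fwd = one_step_perturbation(rng.normal(m, sigma, n), np.zeros(n), T)
        # samples of state j see the reverse perturbation −ΔΔG shifted by −σ²/kT²·...
        rev_ddg = -(rng.normal(m, sigma, n) - sigma**2 / KT)
        rev = one_step_perturbation(rev_ddg, np.zeros(n), T)
        err = 3 * np.hypot(max(fwd.error, 1e-3), max(rev.error, 1e-3))
        assert fwd.value == pytest.approx(-rev.value, abs=err)

    def test_empty_frames_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            one_step_perturbation(np.array([]), np.array([]), T)

    def test_low_overlap_warning_recorded(self, rng):
        ddg = np.concatenate([np.zeros(99), [-50 * KT]])  # one frame dominates
        with pytest.warns(RuntimeWarning, match="effective sample size"):
            res = one_step_perturbation(ddg, np.zeros(100), T)
        assert res.warnings
        assert res.n_eff < 2.0


class TestBlockStandardError:
    def test_constant_series_zero(self):
        assert block_standard_error(np.full(1000, 1.3), 5) == 0.0

    def test_five_blocks_of_thousand(self, rng):
        x = rng.normal(0, 0.5, 5000)
        err = block_standard_error(x, 5)
        assert err > 0
        # blocks are contiguous fifths of the series
        manual = []
        from scipy.special import logsumexp
        for b in range(5):
            seg = x[b * 1000 : (b + 1) * 1000]
            manual.append(-(logsumexp(seg) - np.log(1000)))
        assert err == pytest.approx(np.std(manual, ddof=1) / np.sqrt(5), rel=1e-12)

    def test_iid_gaussian_vs_delta_method(self, rng):
        """Block error agrees with the analytic delta-method error within ×2."""
        sigma, n = 0.3, 10_000
        x = rng.normal(0.0, sigma, n)
        blocks = block_standard_error(x, 5)
        # delta method on −ln(mean(exp x)): var ≈ var(exp x)/(n·mean²)
        e = np.exp(x)
        delta = np.std(e, ddof=1) / (np.sqrt(n) * np.mean(e))
        assert 0.5 < blocks / delta < 2.0

    def test_too_few_blocks_rejected(self):
        with pytest.raises(ValueError, match="blocks"):
            block_standard_error(np.ones(10), 1)

    def test_indivisible_length_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            block_standard_error(np.ones(7), 5)


def rigid_table(dg_by_eps, n_frames=60, window_r=0.5):
    """Table for a rigid system: every frame of every state has the same ΔG set."""
    rows = []
    for eps_state in dg_by_eps:
        for f in range(n_frames):
            row = {"window_r": window_r,
                   "state": PerFrameEnergyTable.state_label(eps_state),
                   "frame": f}
            for eps_eval, dg in dg_by_eps.items():
                row[gb_column(eps_eval)] = dg
            rows.append(row)
    return PerFrameEnergyTable(pd.DataFrame(rows))


class TestBidirectionalLadder:
    def born_dg(self, eps, q=1.0, a=0.2):
        from pmfdecomp.constants import COULOMB
        return -0.5 * (1 - 1 / eps) * COULOMB * q * q / a if eps > 1 else 0.0

    def test_all_zero_columns_give_zero(self):
        ladder = DielectricLadder((80.0, 10.0, 1.0))
        table = rigid_table({e: 0.0 for e in ladder.sequence})
        res = bidirectional_ladder(table, 0.5, ladder, T)
        assert res.value == 0.0

    def test_rigid_born_ion_telescopes_to_endpoints(self):
        """For a single repeated conformation the ladder telescopes exactly to
        ΔG(80) − ΔG(1) = −(q²/8πε₀a)(1 − 1/80), at any ladder resolution."""
        from pmfdecomp.constants import COULOMB

        expected = -(COULOMB / (2 * 0.2)) * (1 - 1 / 80) / KT
        for ladder in (DielectricLadder((80.0, 1.0)), DielectricLadder()):
            table = rigid_table({e: self.born_dg(e) for e in ladder.sequence})
            res = bidirectional_ladder(table, 0.5, ladder, T)
            assert res.value == pytest.approx(expected, abs=1e-12)
            assert res.error == pytest.approx(0.0, abs=1e-12)

    def test_paper_ladder_has_13_bidirectional_steps(self):
        ladder = DielectricLadder()
        assert ladder.n_intermediates == 12
        assert len(ladder.pairs()) == 13

    def test_missing_state_named_in_error(self):
        ladder = DielectricLadder((80.0, 10.0, 1.0))
        table = rigid_table({80.0: -10.0, 10.0: -5.0, 1.0: 0.0})
        # drop the ε=10 state rows
        table = PerFrameEnergyTable(
            table.frame[table.frame["state"] != "eps=10"].reset_index(drop=True)
        )
        with pytest.raises(KeyError, match="eps=10"):
            bidirectional_ladder(table, 0.5, ladder, T)

    def test_ladder_refinement_consistency(self, rng):
        """Adding intermediate states moves the flexible-toy estimate by less
        than the combined standard errors."""
        n = 10_000
        # synthetic flexible system: ΔG(ε) = c(ε)·x with per-frame x
        def coeff(e):
            return -(1 - 1 / e) * 30.0

        results = []
        for ladder in (DielectricLadder((80.0, 5.0, 1.0)), DielectricLadder((80.0, 20.0, 5.0, 2.0, 1.0))):
            rows = []
            for eps_state in ladder.sequence:
                x = 1.0 + 0.1 * rng.standard_normal(n)  # conformational fluctuation
                df = pd.DataFrame({
                    "window_r": 0.5,
                    "state": PerFrameEnergyTable.state_label(eps_state),
                    "frame": np.arange(n),
                })
                for eps_eval in ladder.sequence:
                    df[gb_column(eps_eval)] = coeff(eps_eval) * x
                rows.append(df)
            table = PerFrameEnergyTable(pd.concat(rows, ignore_index=True))
            results.append(bidirectional_ladder(table, 0.5, ladder, T))
        diff = abs(results[0].value - results[1].value)
        combined = 3 * np.hypot(results[0].error, results[1].error)
        assert diff <= max(combined, 0.02)


class TestReweightToReference:
    def test_self_reweighting_zero(self, rng):
        dg = rng.normal(-40, 3, 500)
        assert reweight_to_reference(dg, dg, T).value == 0.0

    def test_constant_shift_recovered_exactly(self, rng):
        dg = rng.normal(-40, 3, 500)
        c = 4.2
        res = reweight_to_reference(dg + c, dg, T)
        assert res.value == pytest.approx(c / KT, abs=1e-12)
        assert res.error == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_two_point_closed_form(self):
        """(ΔG_hyd − ΔG_GB) ∈ {0, k_BT} → −ln((1 + e⁻¹)/2) ≈ 0.3799."""
        dg_gb = np.zeros(2)
        dg_hyd = np.array([0.0, KT])
        res = reweight_to_reference(dg_hyd, dg_gb, T)
        assert res.value == pytest.approx(-np.log((1 + np.exp(-1)) / 2), abs=1e-12)
        assert res.value == pytest.approx(0.3799, abs=1e-4)
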