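"""QSSA free-site/free-protein expectations and reduced spatial systems."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spatialssa import (
    BindingChain,
    QssaMethod,
    build_preset,
    free_protein,
    mean_free_sites_exact,
    reduced_counterpart,
    run_ensemble,
    slqssa_free_sites,
    slqssa_low_state_closed_form,
    stqssa_free_sites,
)
from spatialssa.network import SystemState

KD_GRID = (1e-3, 0.02, 1.0, 1e3)


class TestSlqssa:
    @pytest.mark.parametrize(
        "dt, pt, kd, expected",
        [
            (1, 1, 1.0, 0.5),  # two-state chain: Kd / (1 + Kd)
            (2, 0, 7.0, 2.0),  # no protein, every site free
            (1, 2, 1.0, 1 / 3),  # Kd / (P_T + Kd)
            (1, 1, 0.02, 0.02 / 1.02),
        ],
    )
    def test_known_stationary_means(self, dt, pt, kd, expected):
        assert slqssa_free_sites(dt, pt, kd) == pytest.approx(expected, abs=1e-12)

    def test_matches_exact_cme_mean(self):
        worst = 0.0
        for kd in KD_GRID:
            for dt in range(0, 5):
                for pt in range(0, 13):
                    approx = slqssa_free_sites(dt, pt, kd)
                    exact = mean_free_sites_exact(BindingChain.from_kd(dt, pt, kd))
                    worst = max(worst, abs(approx - exact))
        assert worst <= 1e-10

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            slqssa_free_sites(1, 1, 0.0)
        with pytest.raises(ValueError):
            slqssa_free_sites(-1, 1, 1.0)


class TestClosedForm:
    @pytest.mark.parametrize("dt", [1, 2, 3])
    @pytest.mark.parametrize("kd", KD_GRID)
    def test_identical_to_general_expression(self, dt, kd):
        for pt in range(0, 13):
            a = slqssa_low_state_closed_form(dt, pt, kd)
            b = slqssa_free_sites(dt, pt, kd)
            assert a == pytest.approx(b, abs=1e-12, rel=1e-12)

    def test_examples(self):
        assert slqssa_low_state_closed_form(1, 1, 1.0) == pytest.approx(0.5)
        assert slqssa_low_state_closed_form(2, 0, 0.02) == 2.0
        assert slqssa_low_state_closed_form(2, 5, 0.02) == pytest.approx(
            slqssa_free_sites(2, 5, 0.02), rel=1e-12
        )

    def test_domain_limited_to_three_sites(self):
        with pytest.raises(ValueError):
            slqssa_low_state_closed_form(4, 1, 1.0)


class TestStqssa:
    def test_tight_binding_value(self):
        # the quadratic-root expectation at D_T = P_T = 1, Kd = 0.02
        expected = 0.5 * (-0.02 + np.sqrt(0.02**2 + 4 * 0.02))
        assert stqssa_free_sites(1, 1, 0.02) == pytest.approx(expected)
        assert stqssa_free_sites(1, 1, 0.02) == pytest.approx(0.13178, abs=1e-5)

    def test_weak_binding_frees_all_sites(self):
        assert stqssa_free_sites(1, 5, 1e6) == pytest.approx(1.0, abs=1e-5)
        assert stqssa_free_sites(1, 0, 0.37) == pytest.approx(1.0)

    @given(
        dt=st.integers(0, 6),
        pt=st.integers(0, 20),
        kd=st.floats(1e-6, 1e6),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_bounds_and_limits(self, dt, pt, kd):
        x = stqssa_free_sites(dt, pt, kd)
        assert 0.0 <= x <= dt
        # monotone nondecreasing in Kd
        assert stqssa_free_sites(dt, pt, kd * 1.5) >= x - 1e-12
        assert stqssa_free_sites(dt, pt, 1e-12) == pytest.approx(
            max(0, dt - pt), abs=1e-4
        )
        assert stqssa_free_sites(dt, pt, 1e12) == pytest.approx(dt, rel=1e-6, abs=1e-6)

    def test_error_maximal_near_balanced_totals(self):
        # tight binding: worst total-QSSA error sits on the D_T ~ P_T ridge
        kd = 0.02
        for dt in range(1, 5):
            errors = {
                pt: abs(
                    stqssa_free_sites(dt, pt, kd)
                    - mean_free_sites_exact(BindingChain.from_kd(dt, pt, kd))
                )
                for pt in range(0, 13)
            }
            best_pt = max(errors, key=errors.get)
            assert abs(best_pt - dt) <= 1


class TestFreeProtein:
    def test_no_sites_means_all_free(self):
        assert free_protein(0, 9, 0.5, "stqssa") == 9.0

    @pytest.mark.parametrize(
        "method, expected",
        [("slqssa", 0.5), ("stqssa", 0.13177446878757823)],
    )
    def test_balanced_case_symmetry(self, method, expected):
        kd = 1.0 if method == "slqssa" else 0.02
        # with D_T = P_T the expected free proteins equal the free sites
        assert free_protein(1, 1, kd, method) == pytest.approx(expected)

    @given(
        dt=st.integers(0, 4),
        pt=st.integers(0, 12),
        kd=st.sampled_from(KD_GRID),
        tag=st.sampled_from(["slqssa", "stqssa"]),
    )
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_bound_complex_consistency(self, dt, pt, kd, tag):
        from spatialssa.qssa import expected_free_sites

        dq = expected_free_sites(tag, dt, pt, kd)
        pq = free_protein(dt, pt, kd, tag)
        assert 0.0 <= pq <= pt
        # bound sites == bound proteins
        assert (dt - dq) == pytest.approx(pt - pq, abs=1e-9)


class TestReducedSpatialSystem:
    def test_channel_bookkeeping(self, gene_params):
        run = build_preset("fig3d")
        red = reduced_counterpart(run, "slqssa")
        # binding/unbinding eliminated entirely
        assert not any("bind" in ch.label for ch in red.system.channels)
        assert len(red.system.channels) < len(run.system.channels)
        # transcription only where sites sit
        tx = [ch for ch in red.system.channels if ch.label.startswith("transcribe")]
        assert [ch.reactants[0][0] for ch in tx] == [14]

    def test_empty_compartment_diffuses_total_protein(self, gene_params):
        run = build_preset("fig3d")
        red = reduced_counterpart(run, "stqssa")
        counts = red.init.counts.copy()
        state = SystemState(0.0, counts)
        (ch,) = [c for c in red.system.channels if c.label == "P-diff@2->3"]
        d = run.preset.lattice.diffusion_rate(run.preset.params.delta)
        assert ch.propensity(state, red.system) == pytest.approx(
            d * counts[1, red.system.species.index("PT")]
        )

    def test_transcription_uses_expected_free_sites(self, gene_params):
        run = build_preset("fig3d")
        for tag, fn in (("slqssa", slqssa_free_sites), ("stqssa", stqssa_free_sites)):
            red = reduced_counterpart(run, tag)
            state = SystemState(0.0, red.init.counts)
            (tx,) = [
                c for c in red.system.channels if c.label.startswith("transcribe")
            ]
            pt = red.init.counts[14, red.system.species.index("PT")]
            expected = run.preset.params.kp * fn(2, int(pt), gene_params.Kd)
            assert tx.propensity(state, red.system) == pytest.approx(expected)

    def test_total_protein_conserved_in_reduced_runs(self):
        run = build_preset("fig3c")
        red = reduced_counterpart(run, "slqssa")
        ens = run_ensemble(red.system, red.init, 50.0, 3, 33, run.grid)
        assert np.all(ens.totals("PT") == 110)
        assert np.all(ens.totals("DT") == 1)

    def test_rejects_unknown_method(self):
        with pytest.raises(ValueError):
            QssaMethod("qssa", 0.02)
        with pytest.raises(ValueError):
            QssaMethod("slqssa", -1.0)
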