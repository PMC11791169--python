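"""Reaction-network builders, state lumping and the exact SSA kernel."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spatialssa import (
    RateParameters,
    build_activating_variant,
    build_lumped_network,
    build_one_site_network,
    build_two_site_explicit,
    lump_state,
    make_state,
    ssa_run,
)
from spatialssa.network import SystemState


def prop_by_label(system, state, prefix):
    """Sum of propensities of channels whose label starts with prefix."""
    return sum(
        ch.propensity(state, system)
        for ch in system.channels
        if ch.label.startswith(prefix)
    )


class TestRateParameters:
    def test_dissociation_constant_derived(self, gene_params):
        assert gene_params.Kd == pytest.approx(0.02, rel=1e-12)

    def test_inconsistent_kd_rejected(self):
        with pytest.raises(ValueError):
            RateParameters(kf=5000.0, kb=100.0, Kd=0.5)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            RateParameters(kf=-1.0, kb=100.0)


class TestOneSiteNetwork:
    @pytest.mark.parametrize(
        "counts, channel, expected",
        [
            ({"D": 1, "P": 1}, "bind", 5000.0),
            ({"D": 0, "P": 7}, "bind", 0.0),
            ({"D": 1, "P": 2}, "bind", 10000.0),
            ({"D": 1}, "transcribe", 50.0),
            ({"M": 3}, "decay", 0.003),
        ],
    )
    def test_propensities(self, gene_params, counts, channel, expected):
        system = build_one_site_network(gene_params)
        state = make_state(system, counts)
        assert prop_by_label(system, state, channel) == pytest.approx(expected)


class TestTwoSiteExplicit:
    def test_unoccupied_dna_binds_at_either_site(self, gene_params):
        system = build_two_site_explicit(gene_params)
        state = make_state(system, {"D00": 1, "P": 1})
        assert prop_by_label(system, state, "bind") == pytest.approx(
            2 * gene_params.kf_per_omega
        )

    def test_fully_occupied_dna_is_silent_but_unbinds_doubly(self, gene_params):
        system = build_two_site_explicit(gene_params)
        state = make_state(system, {"D11": 1, "P": 5})
        assert prop_by_label(system, state, "transcribe") == 0.0
        assert prop_by_label(system, state, "unbind") == pytest.approx(
            2 * gene_params.kb
        )

    def test_transcription_proportional_to_free_sites(self, gene_params):
        system = build_two_site_explicit(gene_params)
        for counts, n_free in [
            ({"D00": 1}, 2),
            ({"D01": 1}, 1),
            ({"D10": 1}, 1),
        ]:
            state = make_state(system, counts)
            assert prop_by_label(system, state, "transcribe") == pytest.approx(
                n_free * gene_params.kp
            )


class TestLumpedNetwork:
    def test_binding_scales_with_free_sites(self, gene_params):
        system = build_lumped_network(gene_params, n_sites=2)
        state = make_state(system, {"D": 2, "P": 1})
        assert prop_by_label(system, state, "bind") == pytest.approx(
            2 * gene_params.kf_per_omega
        )

    @pytest.mark.parametrize(
        "counts, expected_kp_multiple", [({"D": 1, "D:P": 1}, 1), ({"D": 0, "D:P": 2}, 0)]
    )
    def test_transcription_from_free_sites_only(
        self, gene_params, counts, expected_kp_multiple
    ):
        system = build_lumped_network(gene_params, n_sites=2)
        state = make_state(system, counts)
        assert prop_by_label(system, state, "transcribe") == pytest.approx(
            expected_kp_multiple * gene_params.kp
        )

    def test_rejects_zero_sites(self, gene_params):
        with pytest.raises(ValueError):
            build_lumped_network(gene_params, n_sites=0)


class TestLumpState:
    @pytest.mark.parametrize(
        "counts, free, bound",
        [({"D01": 1}, 1, 1), ({"D00": 1}, 2, 0), ({"D11": 1}, 0, 2)],
    )
    def test_occupancy_mapping(self, gene_params, counts, free, bound):
        explicit = build_two_site_explicit(gene_params)
        lumped = lump_state(make_state(explicit, counts))
        assert lumped.counts[0, 0] == free
        assert lumped.counts[0, 1] == bound

    @given(
        d=st.tuples(*[st.integers(0, 3)] * 4),
        p=st.integers(0, 20),
        m=st.integers(0, 50),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_total_sites_preserved(self, d, p, m):
        state = SystemState(0.0, np.array([[*d, p, m]]))
        lumped = lump_state(state)
        # free + occupied sites = 2 x number of DNA molecules
        assert lumped.counts[0, 0] + lumped.counts[0, 1] == 2 * sum(d)
        assert lumped.counts[0, 2] == p and lumped.counts[0, 3] == m


class TestActivatingVariant:
    def test_transcribes_from_complex(self, gene_params):
        base = build_lumped_network(gene_params, n_sites=1)
        act = build_activating_variant(base)
        silent = make_state(act, {"D": 1})
        assert prop_by_label(act, silent, "transcribe") == 0.0
        for n in (1, 2):
            state = make_state(act, {"D:P": n})
            assert prop_by_label(act, state, "transcribe") == pytest.approx(
                n * gene_params.kp
            )

    def test_requires_transcription_channel(self, gene_params):
        base = build_lumped_network(gene_params, n_sites=1)
        act = build_activating_variant(base)  # transcription already rewired
        with pytest.raises(ValueError):
            build_activating_variant(act)


class TestSsaRun:
    def test_frozen_system_holds_state(self):
        params = RateParameters(kf=0.0, kb=0.0, kp=0.0, kd=0.0)
        system = build_lumped_network(params, n_sites=1)
        init = make_state(system, {"D": 1, "P": 4, "M": 2})
        tr = ssa_run(system, init, 10.0, seed=3, sample_grid=[0, 5, 10])
        assert np.all(tr.counts == init.counts[None])

    def test_determinism_bit_identical(self, gene_params, grid50):
        system = build_one_site_network(gene_params)
        init = make_state(system, {"D": 1, "P": 3})
        a = ssa_run(system, init, 50.0, seed=11, sample_grid=grid50)
        b = ssa_run(system, init, 50.0, seed=11, sample_grid=grid50)
        assert np.array_equal(a.counts, b.counts)
        c = ssa_run(system, init, 50.0, seed=12, sample_grid=grid50)
        assert not np.array_equal(a.counts, c.counts)

    def test_poisson_transcription_mean(self):
        # unrepressed gene, no decay: M(t) is Poisson(kp * t)
        params = RateParameters(kf=0.0, kb=0.0, kp=5.0, kd=0.0)
        system = build_lumped_network(params, n_sites=1)
        init = make_state(system, {"D": 1})
        n, t_max = 1000, 10.0
        finals = np.array(
            [
                ssa_run(system, init, t_max, seed=s, sample_grid=[t_max]).counts[
                    0, 0, 3
                ]
                for s in range(n)
            ],
            dtype=float,
        )
        mean, se = finals.mean(), finals.std(ddof=1) / np.sqrt(n)
        assert abs(mean - params.kp * t_max) < 3 * se

    def test_linear_death_mean(self):
        params = RateParameters(kf=0.0, kb=0.0, kp=0.0, kd=0.2)
        system = build_lumped_network(params, n_sites=1)
        m0, t_max, n = 40, 5.0, 1000
        init = make_state(system, {"M": m0})
        finals = np.array(
            [
                ssa_run(system, init, t_max, seed=s, sample_grid=[t_max]).counts[
                    0, 0, 3
                ]
                for s in range(n)
            ],
            dtype=float,
        )
        expected = m0 * np.exp(-params.kd * t_max)
        se = finals.std(ddof=1) / np.sqrt(n)
        assert abs(finals.mean() - expected) < 3 * se

    def test_mass_conservation_along_trajectory(self, gene_params, grid50):
        system = build_one_site_network(gene_params)
        init = make_state(system, {"D": 1, "P": 30})
        tr = ssa_run(system, init, 50.0, seed=5, sample_grid=grid50)
        d, dp, p = (tr.totals(s) for s in ("D", "D:P", "P"))
        assert np.all(d + dp == 1)
        assert np.all(p + dp == 30)

    def test_rejects_bad_inputs(self, gene_params):
        system = build_one_site_network(gene_params)
        init = make_state(system, {"D": 1, "P": 1})
        with pytest.raises(ValueError):
            ssa_run(system, init, 10.0, 0, [5.0, 1.0])  # unsorted grid
        with pytest.raises(ValueError):
            ssa_run(system, init, 10.0, 0, [0.0, 20.0])  # beyond t_max
        with pytest.raises(ValueError):
            SystemState(0.0, np.array([[0.5, 0, 0, 0]]))
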