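"""Model space structure, RFX-BMS, family inference and BMA."""

import importlib.resources

import numpy as np
import pytest
import scipy.special
import scipy.stats

from sstdbs.connectivity_bms import (
    EvidenceMatrix,
    ModelSpace,
    bma,
    build_model_space,
    exceedance_from_alpha,
    family_bms,
    rfx_bms,
    simulate_connection_params,
    simulate_evidences,
    _dirichlet_posterior,
)


@pytest.fixture(scope="module")
def space() -> ModelSpace:
    return build_model_space()


class TestModelSpace:
    def test_structure_counts(self, space):
        """The inhibition network: 6 regions (5 cortical + hidden BG),
        14 connections, 9 modulation models in 3 families of 3."""
        assert len(space.nodes) == 6
        assert sum(space.coords[n] is not None for n in space.nodes) == 5
        assert space.coords["BG"] is None
        assert len(space.connections) == 14
        assert len(space.models) == 9
        assert len(space.families) == 3
        assert all(len(m) == 3 for m in space.families.values())

    def test_mni_coordinates(self, space):
        assert space.coords["R_IFG"] == (54.0, 12.0, 18.0)
        assert space.coords["L_DLPFC"] == (-37.0, 27.0, 39.0)
        assert space.coords["preSMA_dACC"] == (0.0, -6.0, 56.0)

    def test_modulation_masks_touch_only_bg_edges(self, space):
        bg_edges = {c.name for c in space.connections if "BG" in (c.source, c.target)}
        for mask in space.models.values():
            assert set(mask) <= bg_edges

    def test_inputs_enter_ifg_and_dlpfc(self, space):
        assert set(space.input_nodes) == {"L_IFG", "R_IFG", "L_DLPFC", "R_DLPFC"}

    def test_canonical_yaml_pin(self, space):
        ref = (
            importlib.resources.files("sstdbs") / "data" / "model_space.yaml"
        ).read_text()
        assert ModelSpace.from_yaml(ref) == space
        assert ModelSpace.from_yaml(space.to_yaml()) == space


class TestRfxBms:
    def test_symmetric_evidences(self, space):
        """Identical columns: alpha_k = 1 + N/K and exceedance 1/K."""
        ev = EvidenceMatrix(np.zeros((12, 9)), tuple(f"S{i}" for i in range(12)),
                            tuple(space.model_ids))
        res = rfx_bms(ev, n_samples=200_000, seed=0)
        np.testing.assert_allclose(res.alpha, 1 + 12 / 9, atol=1e-8)
        np.testing.assert_allclose(res.exceedance, 1 / 9, atol=0.01)
        assert res.exceedance.sum() == pytest.approx(1.0, abs=1e-3)
        assert res.expected_freq.sum() == pytest.approx(1.0, abs=1e-12)

    def test_fixed_point_against_independent_solver(self):
        """The variational update matches a from-scratch fixed-point solver
        run to 1e-12 on a two-model problem (and the first responsibility
        iteration is the plain evidence ratio {2/3, 1/3})."""
        lnE = np.array([[np.log(2.0), 0.0], [0.0, 0.0]])
        prior = np.ones(2)

        u0 = np.exp(lnE[0] + scipy.special.psi(prior) - scipy.special.psi(prior.sum()))
        np.testing.assert_allclose(u0 / u0.sum(), [2 / 3, 1 / 3])

        alpha, _, converged, _ = _dirichlet_posterior(lnE, prior, tol=1e-12,
                                                      max_iter=10_000)
        assert converged

        # independent oracle: same fixed point iterated in plain Python
        a = [1.0, 1.0]
        for _ in range(100_000):
            g_rows = []
            for row in lnE:
                w = [np.exp(row[k] + scipy.special.psi(a[k])
                            - scipy.special.psi(sum(a))) for k in range(2)]
                tot = sum(w)
                g_rows.append([x / tot for x in w])
            new = [1.0 + sum(g[k] for g in g_rows) for k in range(2)]
            if max(abs(new[k] - a[k]) for k in range(2)) < 1e-12:
                a = new
                break
            a = new
        np.testing.assert_allclose(alpha, a, atol=1e-8)

    def test_k2_exceedance_matches_beta_closed_form(self):
        """For two models the exceedance reduces to a Beta tail probability:
        P(p1 > 1/2) under Beta(11, 3)."""
        alpha = np.array([11.0, 3.0])
        mc = exceedance_from_alpha(alpha, n_samples=1_000_000, seed=42)
        closed = 1.0 - scipy.stats.beta.cdf(0.5, 11.0, 3.0)
        assert mc[0] == pytest.approx(closed, abs=1e-3)
        assert mc.sum() == pytest.approx(1.0, abs=1e-12)

    def test_row_shift_invariance(self, space):
        rng = np.random.default_rng(5)
        lnE = rng.normal(size=(8, 9))
        ids = tuple(space.model_ids)
        subs = tuple(f"S{i}" for i in range(8))
        a = rfx_bms(EvidenceMatrix(lnE, subs, ids), n_samples=10_000, seed=1)
        shifted = lnE + rng.normal(size=(8, 1))  # per-subject constants
        b = rfx_bms(EvidenceMatrix(shifted, subs, ids), n_samples=10_000, seed=1)
        np.testing.assert_allclose(a.alpha, b.alpha, atol=1e-4)

    def test_alpha_mass_conservation(self, space):
        rng = np.random.default_rng(6)
        ev = EvidenceMatrix(rng.normal(size=(12, 9)), tuple(f"S{i}" for i in range(12)),
                            tuple(space.model_ids))
        res = rfx_bms(ev, n_samples=1000, seed=0)
        assert res.alpha.sum() == pytest.approx(9 * 1.0 + 12, abs=1e-6)

    def test_strong_effect_selects_true_model(self, space):
        ev, _ = simulate_evidences(space, "IFG_efferent", effect_nats=10.0,
                                   noise_nats=1.0, n_subjects=12, seed=3)
        res = rfx_bms(ev, n_samples=50_000, seed=3)
        k = list(res.model_ids).index("IFG_efferent")
        assert res.exceedance[k] > 0.95


class TestSimulateEvidences:
    def test_dimensions(self, space):
        ev, gen = simulate_evidences(space, "both_both", 5.0, 1.0, 12, seed=0)
        assert ev.log_evidence.shape == (12, 9)
        assert len(gen) == 12

    def test_zero_effect_gives_flat_exceedance(self, space):
        ev, _ = simulate_evidences(space, "IFG_both", effect_nats=0.0,
                                   noise_nats=1.0, n_subjects=20, seed=1)
        res = rfx_bms(ev, n_samples=50_000, seed=1)
        assert res.exceedance.max() < 0.5  # no model dominates

    def test_heterogeneity_spreads_generating_models(self, space):
        _, gen = simulate_evidences(space, "IFG_both", 5.0, 1.0, 200,
                                    heterogeneity=0.5, seed=2)
        frac_true = np.mean([g == "IFG_both" for g in gen])
        assert 0.35 < frac_true < 0.65

    def test_unknown_model_rejected(self, space):
        with pytest.raises(ValueError):
            simulate_evidences(space, "nope", 1.0, 1.0, 5)


class TestFamilyBms:
    def test_symmetric_families(self, space):
        ev = EvidenceMatrix(np.zeros((12, 9)), tuple(f"S{i}" for i in range(12)),
                            tuple(space.model_ids))
        fam = family_bms(ev, space.families, n_samples=200_000, seed=0)
        np.testing.assert_allclose(fam.family_exceedance, 1 / 3, atol=0.01)
        assert fam.family_exceedance.sum() == pytest.approx(1.0, abs=1e-3)

    def test_concentrated_family_wins(self, space):
        ev, _ = simulate_evidences(space, "both_efferent", 8.0, 1.0, 12, seed=4)
        fam = family_bms(ev, space.families, n_samples=50_000, seed=4)
        k = list(fam.family_ids).index("both")
        assert fam.family_exceedance[k] > 0.9

    def test_partition_must_cover_models(self, space):
        ev = EvidenceMatrix(np.zeros((3, 9)), ("a", "b", "c"), tuple(space.model_ids))
        with pytest.raises(ValueError):
            family_bms(ev, {"only": tuple(space.model_ids[:5])})


class TestBma:
    def test_single_model_family_returns_parameters(self, space):
        params = simulate_connection_params(space, 5, seed=0, obs_sd=0.0)
        ev, _ = simulate_evidences(space, "IFG_both", 3.0, 1.0, 5, seed=0)
        out = bma(params, ev, ["IFG_both"], space.connection_names)
        np.testing.assert_allclose(out.subject_strengths, params["IFG_both"])
        np.testing.assert_allclose(out.weights, 1.0)

    def test_equal_evidence_midpoint(self, space):
        names = space.connection_names
        n_sub, n_conn = 4, len(names)
        theta = np.ones((n_sub, n_conn, 2))
        params = {"IFG_afferent": theta, "IFG_efferent": 3 * theta}
        ev = EvidenceMatrix(np.zeros((n_sub, 2)), tuple(f"S{i}" for i in range(n_sub)),
                            ("IFG_afferent", "IFG_efferent"))
        out = bma(params, ev, ["IFG_afferent", "IFG_efferent"], names)
        np.testing.assert_allclose(out.subject_strengths, 2.0)

    def test_weights_sum_to_one_per_subject(self, space):
        params = simulate_connection_params(space, 6, seed=1)
        ev, _ = simulate_evidences(space, "both_both", 4.0, 1.0, 6, seed=1)
        out = bma(params, ev, space.families["both"], space.connection_names)
        np.testing.assert_allclose(out.weights.sum(axis=1), 1.0)

    def test_detects_generated_efferent_modulation(self, space):
        """A BG->R_IFG connection scaled by 0.7 in the ON condition is found
        with the correct (negative) sign by the BMA paired test in most
        replicate cohorts."""
        hits = 0
        n_rep = 25
        j = space.connection_names.index("BG->R_IFG")
        for rep in range(n_rep):
            ev, _ = simulate_evidences(space, "both_efferent", 5.0, 1.0, 12,
                                       seed=100 + rep)
            params = simulate_connection_params(
                space, 12, on_scaling={"BG->R_IFG": 0.7}, seed=200 + rep
            )
            out = bma(params, ev, space.families["both"], space.connection_names)
            t = out.paired_tests[j]
            if t.p_value < 0.05 and t.mean_on < t.mean_off:
                hits += 1
        assert hits / n_rep >= 0.8

    def test_missing_parameters_rejected(self, space):
        ev, _ = simulate_evidences(space, "IFG_both", 3.0, 1.0, 5, seed=0)
        with pytest.raises(ValueError):
            bma({}, ev, ["IFG_both"], space.connection_names)
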