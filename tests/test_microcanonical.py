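"""Bezier smoothing, inflection detection, classification, and jackknife bands."""

import numpy as np
import pytest

from polyphase import (
    MicrocanonicalAnalysis,
    TemperatureLadder,
    bezier_smooth,
    classify_transitions,
    curves_from_dos,
    entropy_from_dos,
    find_least_sensitive_inflections,
    jackknife_uncertainties,
    make_toy_dos,
    sample_histograms,
    wham_iterate,
)
from polyphase.reweighting import DensityOfStates


class TestBezierSmoothing:
    def test_linear_data_reproduced_exactly(self):
        x = np.linspace(0, 10, 40)
        y = 2.5 * x - 1.0
        c = bezier_smooth(x, y)
        g = np.linspace(0.5, 9.5, 17)
        assert np.allclose(c(g, 0), 2.5 * g - 1.0, atol=1e-10)
        assert np.allclose(c(g, 1), 2.5, atol=1e-9)
        assert np.max(np.abs(c(g, 2))) < 1e-8

    def test_cubic_derivatives_match_operator_action(self):
        """The smoother's exact action on a cubic: degree is preserved and the
        third derivative is the constant 6 a (1 - 1/n)(1 - 2/n) in the curve
        parameter (symbolic Bernstein-operator oracle)."""
        n_pts = 61
        n = n_pts - 1
        x = np.linspace(2.0, 8.0, n_pts)
        a3, a2, a1, a0 = 0.05, -0.3, 2.0, 1.0
        y = a0 + a1 * x + a2 * x**2 + a3 * x**3
        c = bezier_smooth(x, y)
        g = np.linspace(2.5, 7.5, 21)
        d3_true = 6 * a3
        d3_expected = d3_true * (1 - 1 / n) * (1 - 2 / n)
        assert np.allclose(c(g, 3), d3_expected, rtol=1e-6)
        # value and slope carry the O(1/n) operator bias, bounded by
        # max |f''_t| / (8 n) in the curve parameter
        bias = np.max(np.abs(2 * a2 + 6 * a3 * x)) * (x[-1] - x[0]) ** 2 / (8 * n)
        assert np.allclose(c(g, 0), a0 + a1 * g + a2 * g**2 + a3 * g**3, rtol=0, atol=1.05 * bias)
        assert np.allclose(c(g, 1), a1 + 2 * a2 * g + 3 * a3 * g**2, rtol=0.06, atol=0.05)

    def test_noisy_parabola_stays_within_noise_band(self):
        rng = np.random.default_rng(4)
        sigma = 0.01
        x = np.linspace(0, 1, 201)
        truth = -3 * (x - 0.5) ** 2
        c = bezier_smooth(x, truth + rng.normal(0, sigma, x.size), max_points=40)
        g = np.linspace(0.02, 0.98, 101)
        assert np.max(np.abs(c(g, 0) - (-3 * (g - 0.5) ** 2))) < 5 * sigma

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bezier_smooth(np.array([0.0, 1, 2]), np.zeros(3))  # too few points
        with pytest.raises(ValueError):
            bezier_smooth(np.array([0.0, 2, 1, 3]), np.zeros(4))  # non-monotone


class TestEntropy:
    def test_entropy_is_log_dos(self):
        dos = make_toy_dos("gaussian").tabulate(101)
        e, s = entropy_from_dos(dos)
        assert s.max() == pytest.approx(0.0)
        assert np.allclose(s, dos.ln_g)

    def test_constant_shift_leaves_derivatives_unchanged(self):
        dos = make_toy_dos("gaussian").tabulate(161)
        shifted = DensityOfStates(dos.energies, dos.ln_g - 7.5, normalization="raw")
        a = curves_from_dos(dos, decimate=80)
        b = curves_from_dos(shifted, decimate=80)
        assert np.allclose(a.beta, b.beta, atol=1e-9)
        assert np.allclose(a.gamma, b.gamma, atol=1e-11)
        assert np.allclose(a.entropy - 0.0, b.entropy + 7.5, atol=1e-9)


class TestInflectionDetection:
    def test_monotone_concave_entropy_has_no_first_order_candidates(self):
        curves = curves_from_dos(make_toy_dos("gaussian").tabulate(201))
        assert find_least_sensitive_inflections(curves, "S") == []

    def test_constructed_beta_minimum_found(self):
        # beta(E) = 3 + (E - 50)^2 / 1000: least-sensitive inflection of S at 50
        dos = make_toy_dos("first_order_toy", {"b0": 3.0, "c": 1e-3, "e_t": 50.0})
        curves = curves_from_dos(dos.tabulate(201))
        cands = find_least_sensitive_inflections(curves, "S")
        assert len(cands) == 1
        assert cands[0].energy == pytest.approx(50.0, abs=0.5)
        assert cands[0].value == pytest.approx(3.0, abs=0.02)

    def test_negative_gamma_dip_detected_through_double_integration(self):
        # gamma with a single negative-peaked dip integrates to a beta
        # inflection; the full detector must flag it
        dos = make_toy_dos("second_order_toy", {"e_t": 45.0})
        curves = curves_from_dos(dos.tabulate(201))
        cands = find_least_sensitive_inflections(curves, "beta")
        peaks = [c for c in cands if c.kind == "max" and c.value < 0]
        assert any(abs(c.energy - 45.0) < 1.0 for c in peaks)

    def test_unknown_scan_rejected(self):
        curves = curves_from_dos(make_toy_dos("gaussian").tabulate(101))
        with pytest.raises(ValueError):
            find_least_sensitive_inflections(curves, "delta")


def _recovered(dos, transitions, spacing):
    """True if every planted transition appears with matching order/character
    and E_tr within one control-grid spacing."""
    for p in dos.planted:
        hits = [
            t for t in transitions
            if t.order == p.order and t.character == p.character
            and abs(t.e_tr - p.e_tr) <= spacing + 1e-9
        ]
        if not hits:
            return False
    return True


class TestClassification:
    def test_gaussian_yields_no_transitions(self):
        curves = curves_from_dos(make_toy_dos("gaussian").tabulate(201))
        assert classify_transitions(curves) == []

    @pytest.mark.parametrize(
        "family", ["first_order_toy", "second_order_toy", "third_order_toy", "composite"]
    )
    def test_planted_transitions_recovered_on_exact_curves(self, family):
        for seed in range(8):
            dos = make_toy_dos(family, seed=seed)
            curves = curves_from_dos(dos.tabulate(201), decimate=None)
            recs = classify_transitions(curves)
            assert _recovered(dos, recs, curves.spacing), (
                f"{family} seed {seed}: planted {dos.planted} not recovered in "
                f"{[(t.order, t.character, t.e_tr) for t in recs]}"
            )

    def test_no_false_positives_on_random_concave_entropies(self):
        """Smooth entropies with monotone derivative hierarchy carry no signal."""
        rng = np.random.default_rng(99)
        for _ in range(20):
            e = np.linspace(-100, -10, 181)
            # gamma = -exp(q) with q strictly monotone => no extremum anywhere
            slope = rng.uniform(-0.05, 0.05)
            q = slope * e + rng.uniform(-4, -2)
            gamma = -np.exp(q)
            beta = np.concatenate([[0], np.cumsum((gamma[1:] + gamma[:-1]) / 2 * np.diff(e))])
            beta += 0.1 - beta.min() + rng.uniform(0.5, 3)
            s = np.concatenate([[0], np.cumsum((beta[1:] + beta[:-1]) / 2 * np.diff(e))])
            curves = curves_from_dos(DensityOfStates(e, s - s.max(), normalization="raw"))
            assert classify_transitions(curves) == []

    def test_classification_invariant_under_energy_shift(self):
        dos = make_toy_dos("composite")
        tab = dos.tabulate(201)
        recs0 = classify_transitions(curves_from_dos(tab, decimate=None))
        shift = -312.5
        tab_shifted = DensityOfStates(tab.energies + shift, tab.ln_g)
        recs1 = classify_transitions(curves_from_dos(tab_shifted, decimate=None))
        assert len(recs0) == len(recs1)
        for a, b in zip(recs0, recs1):
            assert b.e_tr - a.e_tr == pytest.approx(shift, abs=1e-6)
            assert (a.order, a.character) == (b.order, b.character)
            assert b.beta_tr == pytest.approx(a.beta_tr, rel=1e-6)

    def test_dependent_records_reference_lower_independent_partner(self):
        dos = make_toy_dos("composite")
        recs = classify_transitions(curves_from_dos(dos.tabulate(201), decimate=None))
        for r in recs:
            assert r.beta_tr > 0
            if r.character == "dependent":
                assert r.parent_e_tr is not None and r.parent_e_tr < r.e_tr

    def test_end_to_end_through_sampled_histograms(self):
        """Sampling + WHAM + smoothing + classification recovers the plant."""
        dos = make_toy_dos("first_order_toy")
        ladder = TemperatureLadder(np.geomspace(0.24, 0.42, 20))
        hits = 0
        for seed in range(5):
            h = sample_histograms(dos, ladder, m_per_thread=100_000, seed=seed)
            est = wham_iterate(h)
            curves = curves_from_dos(est, decimate=100)
            recs = classify_transitions(curves)
            if _recovered(dos, recs, 2 * curves.spacing):
                hits += 1
        assert hits >= 4


class TestJackknife:
    def test_identical_runs_have_zero_bands(self):
        tab = make_toy_dos("gaussian").tabulate(161)
        curves = jackknife_uncertainties([tab, tab, tab], decimate=80)
        assert np.max(curves.se_beta) < 1e-12
        assert np.max(curves.se_delta) < 1e-12

    def test_constant_offset_runs_have_zero_derivative_bands(self):
        tab = make_toy_dos("gaussian").tabulate(161)
        shifted = DensityOfStates(tab.energies, tab.ln_g - 2.0, normalization="raw")
        curves = jackknife_uncertainties([tab, shifted], decimate=80)
        assert np.max(curves.se_entropy) > 0.1  # the offset itself is visible
        assert np.max(curves.se_beta) < 1e-10
        assert np.max(curves.se_gamma) < 1e-12

    def test_single_run_returns_unbanded_curves(self):
        tab = make_toy_dos("gaussian").tabulate(161)
        curves = jackknife_uncertainties([tab])
        assert not curves.has_bands

    def test_bands_cover_truth_on_perturbed_fixtures(self):
        """Jackknife bands are calibrated against sampling noise.

        The bands capture run-to-run scatter only, so this holds in the
        regime where the smoothing bias is subdominant: the control polygon
        is left undecimated (weakest smoothing) and the per-thread sample
        size is modest.
        """
        gaussian = make_toy_dos("gaussian")
        ladder = TemperatureLadder(np.geomspace(0.5, 2.5, 12))
        runs = [
            wham_iterate(sample_histograms(gaussian, ladder, m_per_thread=5_000, seed=s))
            for s in range(10)
        ]
        curves = jackknife_uncertainties(runs, decimate=None)
        inner = slice(40, -40)  # clear of window-edge smoothing artifacts
        truth = gaussian.beta(curves.energies[inner])
        covered = np.abs(curves.beta[inner] - truth) <= 3 * curves.se_beta[inner]
        assert covered.mean() >= 0.8


class TestModelResultsApi:
    def test_fit_summary_and_frame(self):
        dos = make_toy_dos("composite")
        res = MicrocanonicalAnalysis(dos.tabulate(201), e_min=dos.window[0]).fit()
        text = res.summary()
        assert "order" in text and "E_tr" in text
        frame = res.transitions_frame()
        assert {"E_tr", "dE", "beta_tr", "order", "character"} <= set(frame.columns)
        # dE column uses the declared reference energy
        assert np.allclose(frame["dE"], frame["E_tr"] - dos.window[0])

    def test_records_flagged_unvalidated_without_bands(self):
        dos = make_toy_dos("first_order_toy")
        res = MicrocanonicalAnalysis(dos.tabulate(201)).fit()
        assert all(not t.validated for t in res.transitions)
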