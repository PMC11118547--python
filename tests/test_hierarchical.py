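"""Hierarchical-gauge machinery: conditional means, projection,
variance decomposition, truncation, maximum gauge, regions."""

import itertools
import math

import numpy as np
import pytest

import seqgauge as sg

SEED = 20240512


def _enumeration_mean(spec, theta, p, fixed):
    """Brute-force conditional mean: average f over all sequences drawn from
    p with the fixed positions overridden."""
    total, mass = 0.0, 0.0
    fixed = dict(fixed)
    for s in sg.enumerate_sequences(spec):
        w = 1.0
        keep = True
        for l, c in enumerate(s, start=1):
            if l in fixed:
                if c != fixed[l]:
                    keep = False
                    break
            else:
                w *= p.probs[l - 1, spec.alphabet.index(c)]
        if keep:
            total += w * sg.predict(spec, theta, [s])[0]
            mass += w
    return total / mass


def _random_dist(alphabet, length, gen):
    return sg.PositionDistribution(alphabet, gen.dirichlet(np.ones(alphabet.size), size=length))


class TestConditionalMean:
    def test_agrees_with_enumeration_oracle(self, binary, random_theta):
        spec = sg.ModelSpec.all_order(binary, 3)
        theta = random_theta(spec)
        gen = np.random.default_rng(SEED)
        p = _random_dist(binary, 3, gen)
        for fixed in [(), ((1, "0"),), ((2, "1"),), ((1, "1"), (3, "0"))]:
            closed = sg.conditional_mean(theta, p, fixed)
            brute = _enumeration_mean(spec, theta, p, fixed)
            assert closed == pytest.approx(brute, abs=1e-12)

    def test_hierarchical_gauge_identities(self, binary, random_theta):
        # in its own hierarchical gauge: mean = constant, conditional
        # mean on one fixed character = constant + additive term
        spec = sg.ModelSpec.all_order(binary, 3)
        gen = np.random.default_rng(SEED)
        p = _random_dist(binary, 3, gen)
        hier = sg.project_hierarchical(random_theta(spec), p)
        assert sg.conditional_mean(hier, p) == pytest.approx(hier.constant, abs=1e-10)
        assert sg.conditional_mean(hier, p, [(2, "1")]) == pytest.approx(
            hier.constant + hier["*1*"], abs=1e-10
        )
        assert sg.conditional_mean(hier, p, [(1, "0"), (3, "1")]) == pytest.approx(
            hier.constant + hier["0**"] + hier["**1"] + hier["0*1"], abs=1e-10
        )

    def test_bad_inputs(self, binary, random_theta):
        spec = sg.ModelSpec.additive(binary, 2)
        theta = random_theta(spec)
        p = sg.PositionDistribution.uniform(binary, 2)
        with pytest.raises(ValueError, match="out of range"):
            sg.conditional_mean(theta, p, [(3, "0")])
        with pytest.raises(ValueError, match="not in alphabet"):
            sg.conditional_mean(theta, p, [(1, "X")])


class TestProjectHierarchical:
    def test_matches_all_order_kronecker_projector(self, binary, random_theta):
        spec = sg.ModelSpec.all_order(binary, 3)
        theta = random_theta(spec)
        gen = np.random.default_rng(SEED)
        for p in [sg.PositionDistribution.uniform(binary, 3), _random_dist(binary, 3, gen)]:
            via_means = sg.project_hierarchical(theta, p)
            via_kron = sg.projection_matrix(spec, sg.GaugeParams(math.inf, p)).project(theta)
            assert np.abs(via_means.values - via_kron.values).max() <= 1e-10

    def test_protein_scale_pairwise_marginalization(self, random_theta):
        aa = sg.Alphabet.from_string("ACDEFGHIKLMNPQRSTVWY")
        spec = sg.ModelSpec.pairwise(aa, 4)
        theta = random_theta(spec)
        p = sg.PositionDistribution.uniform(aa, 4)
        fixed = sg.project_hierarchical(theta, p)
        scale = np.abs(fixed.values).max()
        assert sg.marginalization_residual(fixed, p) <= 1e-10 * scale
        # zero-sum: every additive group and every pairwise group sums to zero
        for l in range(4):
            sel = (spec.orders == 1) & (spec.codes[:, l] > 0)
            assert abs(fixed.values[sel].sum()) <= 1e-9 * scale

    def test_orbit_preserved(self, dna, random_theta):
        spec = sg.ModelSpec.pairwise(dna, 3)
        theta = random_theta(spec)
        gen = np.random.default_rng(SEED)
        fixed = sg.project_hierarchical(theta, _random_dist(dna, 3, gen))
        ok, disc = sg.same_orbit(spec, theta, fixed)
        assert ok, disc

    def test_indicator_distribution_gives_wild_type_gauge(self, dna, random_theta):
        spec = sg.ModelSpec.pairwise(dna, 3)
        theta = random_theta(spec)
        swt = "GAT"
        fixed = sg.project_hierarchical(
            theta, sg.PositionDistribution.from_sequence(dna, swt)
        )
        for lab in spec.features:
            if lab != "***" and all(a == "*" or a == c for a, c in zip(lab, swt)):
                assert abs(fixed[lab]) <= 1e-10
        assert fixed.constant == pytest.approx(
            sg.predict(spec, theta, [swt])[0], abs=1e-10
        )

    @pytest.mark.parametrize("preset", ["additive", "pairwise", "nearest_neighbor"])
    def test_zero_pattern_preserved(self, dna, preset):
        # projecting within the lower-order spec keeps inactive features at
        # exactly zero, and agrees with projecting the same model embedded
        # in the all-order space
        spec_small = getattr(sg.ModelSpec, preset)(dna, 3)
        gen = np.random.default_rng(SEED)
        theta_small = sg.ParameterVector(
            spec_small, gen.standard_normal(spec_small.n_features)
        )
        p = _random_dist(dna, 3, gen)
        fixed_small = sg.project_hierarchical(theta_small, p)
        spec_full = sg.ModelSpec.all_order(dna, 3)
        full = sg.ParameterVector.from_dict(spec_full, theta_small.to_dict())
        fixed_full = sg.project_hierarchical(full, p)
        embedded = sg.ParameterVector.from_dict(spec_full, fixed_small.to_dict())
        inactive = [
            lab for lab in spec_full.features if lab not in spec_small.feature_index
        ]
        for lab in inactive:
            assert embedded[lab] == 0.0  # structural: feature absent from spec
            assert abs(fixed_full[lab]) <= 1e-10  # embedded route agrees
        assert np.abs(embedded.values - fixed_full.values).max() <= 1e-10

    def test_marginalization_with_zero_probability_characters(self, dna, random_theta):
        spec = sg.ModelSpec.pairwise(dna, 3)
        theta = random_theta(spec)
        p = sg.region_distribution(dna, 3, {2: ["G"], 3: ["A", "C"]})
        fixed = sg.project_hierarchical(theta, p)
        scale = max(1.0, np.abs(fixed.values).max())
        assert sg.marginalization_residual(fixed, p) <= 1e-10 * scale
        ok, _ = sg.same_orbit(spec, theta, fixed)
        assert ok

    def test_refuses_non_hierarchical_model(self, binary):
        spec = sg.ModelSpec.from_features(binary, 2, ["**", "0*", "00"])
        theta = sg.ParameterVector(spec, np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="not hierarchical"):
            sg.project_hierarchical(theta, sg.PositionDistribution.uniform(binary, 2))


class TestVarianceDecomposition:
    def test_additive_model_has_no_higher_order_variance(self, binary, random_theta):
        spec = sg.ModelSpec.additive(binary, 3)
        p = sg.PositionDistribution.uniform(binary, 3)
        fixed = sg.project_hierarchical(random_theta(spec), p)
        table = sg.variance_decomposition(fixed, p)
        assert np.all(table.variances[2:] == 0)
        assert table.variances[0] == 0  # constant carries no variance

    def test_total_equals_population_variance(self, binary, random_theta):
        spec = sg.ModelSpec.all_order(binary, 3)
        theta = random_theta(spec)
        p = sg.PositionDistribution.uniform(binary, 3)
        fixed = sg.project_hierarchical(theta, p)
        table = sg.variance_decomposition(fixed, p)
        f = sg.predict_all(spec, theta)
        assert table.total == pytest.approx(f.var(), rel=1e-10)

    def test_components_are_p_orthogonal(self, binary, random_theta):
        spec = sg.ModelSpec.all_order(binary, 3)
        theta = random_theta(spec)
        gen = np.random.default_rng(SEED)
        p = _random_dist(binary, 3, gen)
        fixed = sg.project_hierarchical(theta, p)
        comps = sg.landscape_components(fixed)
        seqs = list(sg.enumerate_sequences(spec))
        pseq = np.array(
            [np.prod([p.probs[l, binary.index(c)] for l, c in enumerate(s)]) for s in seqs]
        )
        for a, b in itertools.combinations(comps, 2):
            inner = float(np.sum(pseq * a.evaluate(seqs) * b.evaluate(seqs)))
            assert abs(inner) <= 1e-10
        # diagonal terms match sum p(s') theta^2
        pfeat = p.feature_probability(spec)
        for comp in comps:
            mask = comp.member_mask()
            inner = float(np.sum(pseq * comp.evaluate(seqs) ** 2))
            assert inner == pytest.approx(
                float(np.sum(pfeat[mask] * fixed.values[mask] ** 2)), abs=1e-10
            )

    def test_variance_additivity_random_p(self, binary, random_theta):
        spec = sg.ModelSpec.all_order(binary, 3)
        theta = random_theta(spec)
        gen = np.random.default_rng(SEED + 5)
        p = _random_dist(binary, 3, gen)
        fixed = sg.project_hierarchical(theta, p)
        table = sg.variance_decomposition(fixed, p)
        seqs = list(sg.enumerate_sequences(spec))
        pseq = np.array(
            [np.prod([p.probs[l, binary.index(c)] for l, c in enumerate(s)]) for s in seqs]
        )
        f = sg.predict_all(spec, theta)
        mean = float(np.sum(pseq * f))
        var = float(np.sum(pseq * (f - mean) ** 2))
        assert table.total == pytest.approx(var, rel=1e-9)

    def test_rejects_unprojected_input_unless_asked(self, binary, random_theta):
        spec = sg.ModelSpec.all_order(binary, 3)
        theta = random_theta(spec)
        p = sg.PositionDistribution.uniform(binary, 3)
        with pytest.raises(ValueError, match="hierarchical gauge"):
            sg.variance_decomposition(theta, p)
        table = sg.variance_decomposition(theta, p, auto_project=True)
        assert table.total > 0


class TestTruncation:
    def test_full_order_is_identity(self, binary, random_theta):
        spec = sg.ModelSpec.all_order(binary, 3)
        p = sg.PositionDistribution.uniform(binary, 3)
        fixed = sg.project_hierarchical(random_theta(spec), p)
        out = sg.truncate_to_order(fixed, 3)
        np.testing.assert_array_equal(out.values, fixed.values)

    def test_order_zero_is_p_mean(self, binary, random_theta):
        spec = sg.ModelSpec.all_order(binary, 3)
        theta = random_theta(spec)
        p = sg.PositionDistribution.uniform(binary, 3)
        fixed = sg.project_hierarchical(theta, p)
        out = sg.truncate_to_order(fixed, 0)
        assert out.spec.n_features == 1
        assert out.constant == pytest.approx(sg.predict_all(spec, theta).mean(), abs=1e-10)

    def test_additive_truncation_is_least_squares_fit(self, binary, random_theta):
        import pandas as pd

        spec = sg.ModelSpec.all_order(binary, 3)
        theta = random_theta(spec)
        p = sg.PositionDistribution.uniform(binary, 3)
        fixed = sg.project_hierarchical(theta, p)
        trunc = sg.truncate_to_order(fixed, 1)
        seqs = list(sg.enumerate_sequences(spec))
        table = pd.DataFrame(
            {"sequence": seqs, "activity": sg.predict_all(spec, theta)}
        )
        ls = sg.fit_least_squares(table, sg.ModelSpec.additive(binary, 3))
        np.testing.assert_allclose(
            sg.predict_all(trunc.spec, trunc),
            sg.predict_all(ls.spec, ls),
            atol=1e-8,
        )

    def test_weighted_regression_oracle(self):
        # truncating in the hierarchical gauge attains the p-weighted
        # least-squares optimum among additive models
        ab = sg.Alphabet.from_string("ACG")
        spec = sg.ModelSpec.pairwise(ab, 3)
        add_spec = sg.ModelSpec.additive(ab, 3)
        seqs = list(sg.enumerate_sequences(spec))
        Xa = sg.embed_sequences(add_spec, seqs)
        gen = np.random.default_rng(SEED)
        for rep in range(20):
            theta = sg.ParameterVector(spec, gen.standard_normal(spec.n_features))
            f = sg.predict(spec, theta, seqs)
            for _ in range(5):
                p = _random_dist(ab, 3, gen)
                pseq = np.array(
                    [
                        np.prod([p.probs[l, ab.index(c)] for l, c in enumerate(s)])
                        for s in seqs
                    ]
                )
                fixed = sg.project_hierarchical(theta, p)
                trunc = sg.truncate_to_order(fixed, 1)
                f_add = sg.predict(trunc.spec, trunc, seqs)
                # weighted normal-equations oracle
                W = pseq[:, None]
                beta, *_ = np.linalg.lstsq(
                    np.sqrt(W) * Xa, np.sqrt(pseq) * f, rcond=None
                )
                f_opt = Xa @ beta
                err_trunc = float(np.sum(pseq * (f - f_add) ** 2))
                err_opt = float(np.sum(pseq * (f - f_opt) ** 2))
                assert err_trunc <= err_opt + 1e-8

    def test_rejects_bad_order(self, binary, random_theta):
        spec = sg.ModelSpec.additive(binary, 2)
        theta = random_theta(spec)
        with pytest.raises(ValueError):
            sg.truncate_to_order(theta, -1)
        with pytest.raises(ValueError):
            sg.truncate_to_order(theta, 3)


class TestMaximumGauge:
    def test_single_position_forced_values(self):
        ab = sg.Alphabet.from_string("AB")
        spec = sg.ModelSpec.additive(ab, 1)
        theta = sg.ParameterVector.from_dict(spec, {"*": 0.0, "A": 1.0, "B": 3.0})
        out = sg.maximum_gauge_additive(theta)
        assert out["*"] == pytest.approx(3.0)
        assert out["A"] == pytest.approx(-2.0)
        assert out["B"] == pytest.approx(0.0)

    def test_already_anchored_model_unchanged(self, binary):
        spec = sg.ModelSpec.additive(binary, 2)
        theta = sg.ParameterVector.from_dict(
            spec, {"**": 1.0, "0*": 0.0, "1*": -1.0, "*0": -2.0, "*1": 0.0}
        )
        out = sg.maximum_gauge_additive(theta)
        np.testing.assert_array_equal(out.values, theta.values)

    def test_constant_is_best_sequence_activity(self, dna, random_theta):
        spec = sg.ModelSpec.additive(dna, 3)
        theta = random_theta(spec)
        out = sg.maximum_gauge_additive(theta)
        best = sg.predict_all(spec, theta).max()
        assert out.constant == pytest.approx(best, abs=1e-10)
        ok, _ = sg.same_orbit(spec, theta, out)
        assert ok
        # all additive parameters <= 0 with at least one zero per position
        for l in range(3):
            sel = (spec.orders == 1) & (spec.codes[:, l] > 0)
            vals = out.values[sel]
            assert np.all(vals <= 1e-12)
            assert np.any(np.abs(vals) <= 1e-12)

    def test_refuses_interaction_models(self, binary, random_theta):
        spec = sg.ModelSpec.pairwise(binary, 2)
        with pytest.raises(ValueError, match="additive"):
            sg.maximum_gauge_additive(random_theta(spec))


class TestRegionDistribution:
    def test_unrestricted_is_uniform(self, dna):
        p = sg.region_distribution(dna, 4, {})
        np.testing.assert_allclose(p.probs, 0.25)

    def test_single_character_restriction(self, dna):
        p = sg.region_distribution(dna, 4, {3: ["G"]})
        assert p.probs[2, dna.index("G")] == 1.0
        assert p.probs[2].sum() == 1.0
        np.testing.assert_allclose(p.probs[0], 0.25)

    def test_two_position_restriction(self, dna):
        p = sg.region_distribution(dna, 4, {3: ["C", "T"], 4: ["G"]})
        assert p.probs[2, dna.index("C")] == 0.5
        assert p.probs[2, dna.index("T")] == 0.5
        assert p.probs[3, dna.index("G")] == 1.0

    def test_empty_set_rejected(self, dna):
        with pytest.raises(ValueError, match="empty"):
            sg.region_distribution(dna, 4, {1: []})
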