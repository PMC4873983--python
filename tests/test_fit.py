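"""Order-parameter fitting: objective semantics, the constrained search,
evaluation, and the model/results surface."""

import numpy as np
import pytest

import snpkin as sk
from snpkin.fit import (
    LabeledPair,
    SpatialKinship,
    evaluate,
    fit_p,
    objective,
    read_labeled_pairs,
    write_labeled_pairs,
)
from snpkin.kinship import estimate_d_t

from conftest import cross_pedigree_founder_pairs


def un_pairs(ped, k, seed=0):
    pairs = cross_pedigree_founder_pairs(ped)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pairs), k, replace=False)
    return [LabeledPair(pairs[i], "UN") for i in idx]


class TestLabeledPair:
    def test_named_relationships_fill_phi(self):
        assert LabeledPair(("a", "b"), "po").phi_true == 0.25
        assert LabeledPair(("a", "b"), "2nd").phi_true == 0.125

    def test_inconsistent_phi_rejected(self):
        with pytest.raises(ValueError):
            LabeledPair(("a", "b"), "PO", phi_true=0.1)

    def test_custom_relationship_needs_phi(self):
        with pytest.raises(ValueError):
            LabeledPair(("a", "b"), "COUSIN-ONCE-REMOVED")
        lp = LabeledPair(("a", "b"), "custom", phi_true=0.03125)
        assert lp.phi_true == 0.03125

    def test_file_round_trip(self, tmp_path):
        pairs = [LabeledPair(("a", "b"), "UN"), LabeledPair(("c", "d"), "PO")]
        path = tmp_path / "pairs.tsv"
        write_labeled_pairs(pairs, path)
        back = read_labeled_pairs(path)
        assert [(lp.pair, lp.relationship, lp.phi_true) for lp in back] == [
            (lp.pair, lp.relationship, lp.phi_true) for lp in pairs
        ]


class TestObjective:
    def test_single_un_pair_objective_zero_for_every_p(self, toy_matrix):
        train = [LabeledPair(("S1", "S2"), "UN")]
        for p in (0.1, 0.5, 1.0):
            assert objective(toy_matrix, train, p) == pytest.approx(0.0, abs=1e-20)
            assert objective(toy_matrix, train, p, residuals="pair") == pytest.approx(
                0.0, abs=1e-20
            )

    def test_two_un_pairs_class_residual_identically_zero(self, toy_matrix):
        # d_t is the mean training distance, so the UN class mean is 0 at any p
        train = [LabeledPair(("S1", "S2"), "UN"), LabeledPair(("S3", "S4"), "UN")]
        for p in (0.2, 0.5, 0.9):
            assert objective(toy_matrix, train, p) == pytest.approx(0.0, abs=1e-18)

    def test_two_un_pairs_per_pair_algebra(self, toy_matrix):
        # with distances d1, d2 and d_t = (d1+d2)/2, each residual is
        # +-(d2-d1)/(4 d_t): the per-pair objective is 2 (spread / (2 d_t))^2
        train = [LabeledPair(("S1", "S2"), "UN"), LabeledPair(("S3", "S4"), "UN")]
        p = 0.6
        d1 = estimate_d_t(toy_matrix, [("S1", "S2")], p)
        d2 = estimate_d_t(toy_matrix, [("S3", "S4")], p)
        d_t = (d1 + d2) / 2
        spread = abs(d2 - d1) / 2
        expected = 2 * (spread / (2 * d_t)) ** 2
        got = objective(toy_matrix, train, p, residuals="pair")
        assert got == pytest.approx(expected, rel=1e-9)

    def test_duplicate_pair_equals_double_weight_per_pair(self, toy_matrix):
        base = [LabeledPair(("S1", "S3"), "PO"), LabeledPair(("S2", "S4"), "UN")]
        doubled = [base[0], base[0], base[1]]
        p = 0.5
        un = [("S2", "S4")]
        f1 = objective(toy_matrix, base, p, unrelated=un, residuals="pair")
        f2 = objective(toy_matrix, doubled, p, unrelated=un, residuals="pair")
        po_resid = f1 - 0.0  # UN residual is zero by d_t construction
        assert f2 == pytest.approx(f1 + po_resid, rel=1e-9)

    def test_no_unrelated_pairs_anywhere_is_fatal(self, toy_matrix):
        with pytest.raises(ValueError, match="d_t"):
            objective(toy_matrix, [LabeledPair(("S1", "S3"), "PO")], 0.5)


class TestFitP:
    def test_degenerate_objective_keeps_canonical_start(self, toy_matrix):
        fr = fit_p(toy_matrix, [LabeledPair(("S1", "S2"), "UN")])
        assert fr.model.p == 0.5
        assert fr.objective == pytest.approx(0.0, abs=1e-18)
        assert fr.converged

    def test_un_only_training_returns_start_for_any_seeded_data(self, small_sim):
        g, truth, ped = small_sim
        un = truth[truth.relationship == "UN"].head(4)
        train = [LabeledPair((r.id1, r.id2), "UN") for r in un.itertuples()]
        fr = fit_p(g, train)
        assert fr.model.p == 0.5

    def test_fitted_p_within_bounds(self, study_sim):
        g, truth, ped = study_sim
        fr = fit_p(g, un_pairs(ped, 2, seed=5))
        assert 0 < fr.model.p <= 1

    def test_informative_training_matches_grid_search(self, study_sim):
        # two pairs from each relationship class make the objective
        # informative; the constrained fit must find the grid optimum
        g, truth, ped = study_sim
        rng = np.random.default_rng(2)
        train = []
        for rel in ["PO", "FS", "2ND", "3RD", "UN"]:
            sub = truth[truth.relationship == rel]
            pick = sub.iloc[rng.choice(len(sub), 2, replace=False)]
            train += [LabeledPair((r.id1, r.id2), rel) for r in pick.itertuples()]
        fr = fit_p(g, train)
        grid = np.round(np.arange(0.01, 1.001, 0.01), 2)
        vals = [objective(g, train, p) for p in grid]
        p_grid = grid[int(np.argmin(vals))]
        assert 0 < fr.model.p <= 1
        assert abs(fr.model.p - p_grid) <= 0.01
        assert fr.objective <= min(vals) + 1e-9

    def test_explicit_unrelated_set_supports_related_only_training(self, small_sim):
        g, truth, ped = small_sim
        po = truth[truth.relationship == "PO"].head(2)
        train = [LabeledPair((r.id1, r.id2), "PO") for r in po.itertuples()]
        un = truth[truth.relationship == "UN"].head(2)
        fr = fit_p(g, train, unrelated=[(r.id1, r.id2) for r in un.itertuples()])
        assert 0 < fr.model.p <= 1


class TestEvaluate:
    def test_training_un_pairs_have_zero_mean(self, small_sim):
        g, truth, ped = small_sim
        un = truth[truth.relationship == "UN"].head(3)
        train = [LabeledPair((r.id1, r.id2), "UN") for r in un.itertuples()]
        fr = fit_p(g, train)
        ev = evaluate(g, train, fr.model)
        assert float(ev[ev.relationship == "UN"]["mean"].iloc[0]) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_duplicated_genotype_pair_contributes_zero_error(self):
        from conftest import make_matrix

        dosage = np.array([[1, 2, 0, 1], [1, 2, 0, 1], [0, 1, 2, 0], [1, 0, 1, 2]])
        g = make_matrix(dosage)
        fr = fit_p(g, [LabeledPair(("S3", "S4"), "UN")])
        ev = evaluate(
            g, [LabeledPair(("S1", "S2"), "custom", phi_true=0.5)], fr.model
        )
        assert float(ev[ev.relationship == "__overall__"]["mse"].iloc[0]) == 0.0

    def test_empty_test_set_rejected(self, toy_matrix):
        from snpkin.kinship import KinshipModel

        with pytest.raises(ValueError):
            evaluate(toy_matrix, [], KinshipModel(p=0.5, d_t=1.0))


class TestModelResultsSurface:
    def test_fit_predict_summary(self, small_sim):
        g, truth, ped = small_sim
        un = truth[truth.relationship == "UN"].head(2)
        model = SpatialKinship(g, [LabeledPair((r.id1, r.id2), "UN")
                                   for r in un.itertuples()])
        res = model.fit()
        assert res.p == 0.5 and res.d_t > 0
        txt = res.summary()
        assert "Minkowski order" in txt and "0.5" in txt
        tab = res.predict([(g.individuals[0], g.individuals[1])])
        assert len(tab) == 1 and np.isfinite(tab.phi_hat).all()

    def test_save_then_reload_reproduces_estimates(self, small_sim, tmp_path):
        from snpkin.kinship import kinship_matrix, read_model

        g, truth, ped = small_sim
        un = truth[truth.relationship == "UN"].head(2)
        res = SpatialKinship(
            g, [LabeledPair((r.id1, r.id2), "UN") for r in un.itertuples()]
        ).fit()
        res.save(tmp_path / "m.txt")
        model2 = read_model(tmp_path / "m.txt")
        pairs = [(g.individuals[0], g.individuals[9])]
        a = res.predict(pairs).phi_hat[0]
        b = kinship_matrix(g, model2, pairs).phi_hat[0]
        assert a == pytest.approx(b, rel=1e-12)

    def test_unknown_training_individual_rejected(self, toy_matrix):
        with pytest.raises(Exception, match="ghost"):
            SpatialKinship(toy_matrix, [LabeledPair(("S1", "ghost"), "UN")])


class TestTrainingRobustness:
    def test_fit_stable_as_unrelated_training_grows(self, study_sim):
        # fitted order and test error move by <10% from 2 to 10 UN pairs
        g, truth, ped = study_sim
        test = [
            LabeledPair((r.id1, r.id2), r.relationship)
            for r in truth[truth.relationship.isin(["PO", "2ND"])].itertuples()
        ]
        ps, mses = [], []
        for k in (2, 4, 10):
            fr = fit_p(g, un_pairs(ped, k, seed=3))
            ev = fr and evaluate(g, test, fr.model)
            ps.append(fr.model.p)
            mses.append(float(ev[ev.relationship == "__overall__"]["mse"].iloc[0]))
        assert max(ps) - min(ps) <= 0.1 * max(ps)
        assert max(mses) - min(mses) <= 0.1 * max(mses)
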