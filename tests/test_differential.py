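import numpy as np
import pandas as pd
import pytest
from scipy import stats

from omixnet.differential import (
    AssociationResult,
    bh_adjust,
    compute_p_score,
    extract_signature,
    fit_association,
    run_clinical_panel,
    significant,
)
from omixnet.errors import AnalysisError
from omixnet.matrix import OmicsMatrix
from omixnet.synthetic import SyntheticSpec, generate_cohort
from omixnet.preprocess import run_chain

from conftest import make_imputed


def bh_brute_force(pvals):
    """Literal step-up procedure: sort, scale by m/rank, monotonize, cap."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adjusted[i] = min(running, 1.0)
    return adjusted


def make_samples(groups, **outcomes):
    idx = [f"s{i:03d}" for i in range(len(groups))]
    return pd.DataFrame({"group": groups, **outcomes}, index=idx)


class TestBhAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_ties_all_equal(self):
        out = bh_adjust([0.5] * 7)
        np.testing.assert_allclose(out, 0.5)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.uniform(1e-8, 1.0, size=m)
            np.testing.assert_allclose(bh_adjust(p), bh_brute_force(list(p)), rtol=1e-12)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.001, 1, 50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.2], [np.nan, 0.5], []])
    def test_invalid_inputs(self, bad):
        with pytest.raises(AnalysisError):
            bh_adjust(bad)


class TestPScore:
    def test_positive_direction(self):
        assert compute_p_score(0.01, 1) == pytest.approx(2.0)

    def test_negative_direction(self):
        assert compute_p_score(0.01, -1) == pytest.approx(-2.0)

    def test_boundary_one(self):
        assert compute_p_score(1.0, 1) == 0.0
        assert compute_p_score(1.0, -1) == 0.0

    def test_zero_p_adj_errors(self):
        with pytest.raises(AnalysisError):
            compute_p_score(0.0, 1)

    def test_bad_direction_errors(self):
        with pytest.raises(AnalysisError):
            compute_p_score(0.5, 0)


class TestFitAssociation:
    def test_log2fc_on_toy(self):
        # group means 4 and 6 in log2 space -> estimate = +2 for covid
        vals = np.array([[4.0, 4.1, 3.9, 6.0, 6.1, 5.9]])
        m = make_imputed(vals)
        samples = make_samples(["bacterial"] * 3 + ["covid"] * 3)
        (res,) = fit_association(m, samples, "group")
        assert res.estimate == pytest.approx(2.0)
        assert res.d == 1
        t, p = stats.ttest_ind(vals[0, 3:], vals[0, :3])
        assert res.p == pytest.approx(p, abs=1e-12)
        assert res.t_statistic == pytest.approx(t, abs=1e-12)

    def test_matches_pooled_t_test_on_random_toys(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n1, n2 = rng.integers(3, 15, 2)
            vals = rng.normal(0, 1, (4, n1 + n2))
            m = make_imputed(vals)
            samples = make_samples(["bacterial"] * n1 + ["covid"] * n2)
            results = fit_association(m, samples, "group")
            for i, r in enumerate(results):
                t, p = stats.ttest_ind(vals[i, n1:], vals[i, :n1], equal_var=True)
                assert r.p == pytest.approx(p, abs=1e-10)
                est = vals[i, n1:].mean() - vals[i, :n1].mean()
                assert r.estimate == pytest.approx(est, abs=1e-10)

    def test_d_matches_estimate_sign(self):
        rng = np.random.default_rng(8)
        m = make_imputed(rng.normal(0, 1, (20, 16)))
        samples = make_samples(["bacterial"] * 8 + ["covid"] * 8)
        for r in fit_association(m, samples, "group"):
            if r.estimate != 0:
                assert r.d == np.sign(r.estimate)
            assert np.sign(r.p_score) == (r.d if r.p_adj < 1 else 0)

    def test_constant_outcome_errors(self):
        m = make_imputed(np.random.default_rng(0).normal(size=(3, 6)))
        samples = make_samples(["covid"] * 6)
        with pytest.raises(AnalysisError, match="constant"):
            fit_association(m, samples, "group")

    def test_constant_molecule_flagged_not_error(self):
        vals = np.vstack([np.full(6, 3.0), np.random.default_rng(0).normal(size=6)])
        m = make_imputed(vals)
        samples = make_samples(["bacterial"] * 3 + ["covid"] * 3)
        res = fit_association(m, samples, "group")
        assert res[0].p == 1.0
        assert res[0].estimate == 0.0
        assert res[0].p_score == 0.0

    def test_missing_outcome_dropped(self):
        rng = np.random.default_rng(2)
        m = make_imputed(rng.normal(size=(2, 8)))
        mort = [0, 0, 1, 1, np.nan, np.nan, 0, 1]
        samples = make_samples(["covid"] * 8, mortality=mort)
        res = fit_association(m, samples, "mortality")
        assert all(r.n_used == 6 for r in res)

    def test_subset_group(self):
        rng = np.random.default_rng(3)
        m = make_imputed(rng.normal(size=(2, 10)))
        samples = make_samples(
            ["covid"] * 6 + ["bacterial"] * 4,
            mortality=[0, 1, 0, 1, 0, 1, 0, 1, 0, 1],
        )
        res = fit_association(m, samples, "mortality", subset_group="covid")
        assert all(r.n_used == 6 for r in res)

    def test_permutation_of_sample_order_invariant(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(10, 12))
        m = make_imputed(vals)
        samples = make_samples(["covid"] * 12, platelet_count=rng.uniform(50, 400, 12))
        base = {r.molecule_id: r.p for r in fit_association(m, samples, "platelet_count")}
        perm = rng.permutation(12)
        m2 = m.with_data(m.data.iloc[:, perm])
        shuffled = {
            r.molecule_id: r.p for r in fit_association(m2, samples, "platelet_count")
        }
        for mol in base:
            assert shuffled[mol] == pytest.approx(base[mol], rel=1e-9)

    def test_type_i_error_rate_null(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(1000, 59))
        m = make_imputed(vals)
        samples = make_samples(
            ["covid"] * 42 + ["bacterial"] * 17,
        )
        res = fit_association(m, samples, "group")
        frac = np.mean([r.p < 0.05 for r in res])
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_bh_joint_across_omics(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(6, 10))
        ids = [f"f{i}" for i in range(6)]
        data = pd.DataFrame(vals, index=ids, columns=[f"s{i:03d}" for i in range(10)])
        omics = pd.Series(["metabolite"] * 3 + ["protein"] * 3, index=ids)
        m = OmicsMatrix(data, omics, scale_state="imputed")
        samples = make_samples(["bacterial"] * 5 + ["covid"] * 5)
        res = fit_association(m, samples, "group")
        expected = bh_adjust([r.p for r in res])
        np.testing.assert_allclose([r.p_adj for r in res], expected)


class TestSignature:
    def _result(self, mol, p_adj, estimate):
        d = 1 if estimate >= 0 else -1
        return AssociationResult(
            molecule_id=mol, omics_label="protein", outcome_name="mortality",
            estimate=estimate, t_statistic=2.0 * d, p=p_adj / 2, p_adj=p_adj,
            d=d, p_score=compute_p_score(p_adj, d), n_used=42,
        )

    def test_inclusive_threshold(self):
        res = [self._result("a", 0.01, 2.0)]
        assert len(extract_signature(res)) == 1

    def test_excludes_nonsignificant(self):
        res = [self._result("a", 0.10, 5.0)]
        assert extract_signature(res) == []

    def test_excludes_small_effect(self):
        res = [self._result("a", 0.01, 1.9)]
        assert extract_signature(res) == []

    def test_sorted_by_effect_magnitude(self):
        res = [
            self._result("a", 0.01, 2.5),
            self._result("b", 0.01, -4.0),
            self._result("c", 0.01, 3.0),
        ]
        assert [r.molecule_id for r in extract_signature(res)] == ["b", "c", "a"]

    def test_negative_threshold_errors(self):
        with pytest.raises(AnalysisError):
            extract_signature([], lfc_threshold=-1)


@pytest.fixture(scope="module")
def panel_setup():
    spec = SyntheticSpec(
        p_metabolites=60, p_proteins=40, frac_differential=0.0,
        n_outcome_features=6, outcome_effect_log2=3.0,
        missing_rate=0.0, dilution_sigma=0.2, seed=21,
    )
    m, samples, truth = generate_cohort(spec)
    processed, _ = run_chain(m)
    return run_clinical_panel(processed, samples), truth


class TestClinicalPanel:

    def test_planted_mortality_recovered(self, panel_setup):
        panel, truth = panel_setup
        counts = panel.hit_counts().set_index(["group", "outcome"])
        mortality_hits = (
            counts.loc[("covid", "mortality"), "n_significant"]
            + counts.loc[("bacterial", "mortality"), "n_significant"]
        )
        assert mortality_hits > 0
        # platelets carry no planted signal
        assert counts.loc[("covid", "platelet_count"), "n_significant"] <= 2

    def test_eight_analyses(self, panel_setup):
        panel, _ = panel_setup
        assert len(panel.results) + len(panel.skipped) == 8

    def test_mortality_hits_are_planted(self, panel_setup):
        panel, truth = panel_setup
        hits = {
            r.molecule_id
            for r in significant(panel.results[("covid", "mortality")])
        }
        planted = set(truth.outcome_features)
        assert hits  # planted effect is large enough to find something
        assert len(hits - planted) <= max(1, len(hits) // 5)

    def test_skips_underpowered_cells(self):
        rng = np.random.default_rng(9)
        m = make_imputed(rng.normal(size=(5, 6)))
        samples = make_samples(
            ["covid"] * 4 + ["bacterial"] * 2,
            aki=[0, 1, 0, 1, 0, 1],
            mortality=[0.0] * 6,  # constant -> skipped
            platelet_count=rng.uniform(100, 300, 6),
            pao2_fio2=rng.uniform(80, 300, 6),
        )
        panel = run_clinical_panel(m, samples)
        skipped = {(g, o) for g, o, _ in panel.skipped}
        assert ("covid", "mortality") in skipped
        assert ("bacterial", "mortality") in skipped
        assert ("bacterial", "aki") in skipped  # only 2 samples
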