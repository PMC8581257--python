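import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import stepblup as sb
from stepblup.model import VarianceComponents

from helpers import random_kinship, random_pedigree, random_records


def _rec(animal, lact, y=100.0, breed="B1", hys="H1"):
    return sb.LactationRecord(
        animal_id=animal, breed=breed, lactation_number=lact, hys=hys, yield_305d=y
    )


class TestAssignFolds:
    def test_two_records_any_lactations(self):
        # lactations {1, 3} still count as two records
        records = [_rec("c1", 1), _rec("c1", 3), _rec("c2", 2)]
        folds = {f.n_lactations: f for f in sb.assign_folds(records)}
        assert folds[2].test_ids == ["c1"]
        assert folds[1].test_ids == ["c2"]
        assert folds[3].test_ids == []

    def test_single_second_lactation_is_one_record_fold(self):
        folds = {f.n_lactations: f for f in sb.assign_folds([_rec("c1", 2)])}
        assert folds[1].test_ids == ["c1"]

    def test_fixture_partition(self, rng):
        # 10 animals: 3 with one, 4 with two, 3 with three records
        records = []
        counts = [1] * 3 + [2] * 4 + [3] * 3
        for i, c in enumerate(counts):
            lacts = sorted(rng.choice([1, 2, 3], size=c, replace=False).tolist())
            records += [_rec(f"c{i}", l) for l in lacts]
        folds = sb.assign_folds(records)
        assert [len(f.test_ids) for f in folds] == [3, 4, 3]
        total = len(records)
        for fold in folds:
            assert len(fold.test_records) + len(fold.training_records) == total
            assert not set(fold.test_ids) & {r.animal_id for r in fold.training_records}
            n = fold.n_lactations
            for a in fold.test_ids:
                assert sum(r.animal_id == a for r in fold.test_records) == n


class TestAccuracy:
    def test_n1_denominator_is_h(self):
        # at n = 1 the denominator reduces to sqrt(h2) for any repeatability
        assert sb.accuracy(0.10, h2=0.25, rep=0.60, n=1) == pytest.approx(0.20)
        assert sb.accuracy(0.10, h2=0.25, rep=0.31, n=1) == pytest.approx(0.20)

    def test_zero_correlation(self):
        assert sb.accuracy(0.0, h2=0.19, rep=0.40, n=2) == 0.0

    def test_worked_n2_case(self):
        # denominator sqrt(0.19 / 0.70); cross-checked against the
        # heritability-of-a-mean identity h2_n = n h2 / (1 + (n-1) rep)
        r = sb.accuracy(0.20, h2=0.19, rep=0.40, n=2)
        assert r == pytest.approx(0.20 / math.sqrt(0.19 / 0.70))
        h2_mean = 2 * 0.19 / (1 + 0.40)
        assert r == pytest.approx(0.20 / math.sqrt(h2_mean), abs=1e-12)

    def test_invalid_h2(self):
        with pytest.raises(ValueError):
            sb.accuracy(0.1, h2=0.0, rep=0.4, n=1)

    @given(
        h2=st.floats(0.01, 0.5),
        gap=st.floats(0.0, 0.4),
        n=st.integers(1, 3),
    )
    def test_identity_with_mean_heritability(self, h2, gap, n):
        rep = min(h2 + gap, 0.95)
        r = sb.accuracy(0.3, h2=h2, rep=rep, n=n)
        h2_mean = n * h2 / (1 + (n - 1) * rep)
        assert r == pytest.approx(0.3 / math.sqrt(h2_mean), rel=1e-9)


class TestBiasSlope:
    def test_identity_slope_one(self):
        v = np.array([1.0, 2.0, 4.0, 5.0])
        assert sb.bias_slope(v, v) == pytest.approx(1.0)

    def test_doubled_slope_two(self):
        v = np.array([1.0, 2.0, 4.0])
        assert sb.bias_slope(2 * v, v) == pytest.approx(2.0)

    def test_hand_ols(self):
        # dev products 3 over EBV dev squares 2
        assert sb.bias_slope(np.array([2.0, 3.0, 5.0]), np.array([1.0, 2.0, 3.0])) == pytest.approx(1.5)

    def test_zero_variance_is_nan(self):
        assert math.isnan(sb.bias_slope(np.array([1.0, 2.0, 3.0]), np.ones(3)))

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            sb.bias_slope(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


@pytest.fixture(scope="module")
def cv_setup():
    rng = np.random.default_rng(5)
    ped = random_pedigree(rng, 60)
    Kinv, _ = random_kinship(rng, ped, "A")
    records = random_records(rng, ped.ids, n_breeds=2, n_hys=2)
    vc = VarianceComponents.from_ratios(0.19, 0.40, sigma2_p=100.0)
    return records, Kinv, vc


class TestRunCrossValidation:
    def test_report_shape(self, cv_setup):
        records, Kinv, vc = cv_setup
        report = sb.run_cross_validation(records, Kinv, vc, method="pblup", trait="MY")
        assert set(report.folds["n_lactations"]) <= {1, 2, 3}
        assert {"corr", "denominator", "accuracy", "slope"} <= set(report.folds.columns)
        assert report.accuracy_mean == pytest.approx(report.folds["accuracy"].mean())
        assert report.slope_mean == pytest.approx(report.folds["slope"].mean())

    def test_no_leakage(self, cv_setup):
        # dropping the test animals' rows from the input reproduces the
        # training fit bit-identically
        records, Kinv, vc = cv_setup
        fold = sb.assign_folds(records)[0]
        fit_internal = sb.solve_mme(
            sb.build_design(fold.training_records, Kinv.ids), Kinv, vc
        )
        pruned = [r for r in records if r.animal_id not in set(fold.test_ids)]
        fit_pruned = sb.solve_mme(sb.build_design(pruned, Kinv.ids), Kinv, vc)
        assert (fit_internal.ebv.to_numpy() == fit_pruned.ebv.to_numpy()).all()
        assert (fit_internal.beta.to_numpy() == fit_pruned.beta.to_numpy()).all()

    def test_scale_invariance(self, cv_setup):
        records, Kinv, vc = cv_setup
        report1 = sb.run_cross_validation(records, Kinv, vc)
        c = 7.5
        scaled_records = [
            sb.LactationRecord(
                animal_id=r.animal_id,
                breed=r.breed,
                lactation_number=r.lactation_number,
                hys=r.hys,
                yield_305d=r.yield_305d * c,
            )
            for r in records
        ]
        scaled_vc = VarianceComponents(
            vc.sigma2_a * c**2, vc.sigma2_pe * c**2, vc.sigma2_e * c**2
        )
        report2 = sb.run_cross_validation(scaled_records, Kinv, scaled_vc)
        np.testing.assert_allclose(
            report1.folds["accuracy"], report2.folds["accuracy"], atol=1e-8
        )
        np.testing.assert_allclose(
            report1.folds["slope"], report2.folds["slope"], atol=1e-8
        )

    def test_whole_data_adjustment_flag(self, cv_setup):
        records, Kinv, vc = cv_setup
        r_train = sb.run_cross_validation(records, Kinv, vc, adjust_with="training")
        r_whole = sb.run_cross_validation(records, Kinv, vc, adjust_with="whole")
        # same folds, generally different adjusted phenotypes
        assert list(r_train.folds["fold"]) == list(r_whole.folds["fold"])
        assert not np.allclose(r_train.folds["corr"], r_whole.folds["corr"])

    def test_small_fold_skipped(self):
        # two 1-record animals only: every fold below the minimum is skipped
        records = [_rec("c1", 1, 90.0), _rec("c2", 1, 110.0)]
        Kinv = sb.RelationshipMatrix(np.eye(2), ["c1", "c2"], "A_inverse")
        vc = VarianceComponents.from_ratios(0.2, 0.4)
        report = sb.run_cross_validation(records, Kinv, vc)
        assert len(report.folds) == 0
        assert math.isnan(report.accuracy_mean)


def test_noise_free_gblup_accuracy_approaches_one():
    # with (nearly) no residual/PE variance, every animal genotyped and fewer
    # SNPs than training animals, the SNP effects are recoverable and the
    # masked animals' breeding values are predicted (almost) exactly
    cfg = sb.SimConfig(
        n_animals=400,
        n_generations=3,
        n_snps=120,
        n_phenotyped=300,
        genotyped_fraction=1.0,
        h2=0.998,
        repeatability=0.999,
        frac_no_location=0.0,
        frac_non_autosomal=0.0,
        frac_low_maf=0.0,
        frac_hwe_violation=0.0,
        seed=99,
    )
    data = sb.simulate_dataset(cfg)
    geno = data.revealed_genotypes()
    G = sb.build_grm(geno, blend_weight=1e-4)
    Ginv = sb.RelationshipMatrix(np.linalg.inv(G.values), G.ids, "G_inverse")
    report = sb.run_cross_validation(data.records, Ginv, data.truth.vc, method="gblup")
    assert (report.folds["accuracy"] > 0.9).all()
    assert report.accuracy_mean > 0.95


def test_combine_reports_layout(cv_setup=None):
    rng = np.random.default_rng(2)
    ped = random_pedigree(rng, 40)
    Kinv, _ = random_kinship(rng, ped, "A")
    records = random_records(rng, ped.ids)
    vc = VarianceComponents.from_ratios(0.19, 0.40, sigma2_p=100.0)
    rep_p = sb.run_cross_validation(records, Kinv, vc, method="pblup", trait="MY")
    rep_g = sb.run_cross_validation(records, Kinv, vc, method="gblup", trait="MY")
    table = sb.combine_reports([rep_p, rep_g])
    assert list(table["trait"]) == ["MY"]
    for col in (
        "pblup_accuracy",
        "pblup_slope",
        "gblup_accuracy",
        "gblup_slope",
        "pblup_accuracy_sd",
        "gblup_slope_sd",
    ):
        assert col in table.columns
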