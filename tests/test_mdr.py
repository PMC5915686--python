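import numpy as np
import pytest

from polyrisk.io import MISSING
from polyrisk.mdr import (
    EMPTY,
    HIGH,
    LOW,
    MDRSearchConfig,
    balanced_accuracy,
    classify_cells,
    highrisk_or,
    mdr_search,
    permutation_test,
    predict,
    _fold_indices,
)
from polyrisk.simulate import (
    PenetranceModel,
    SimulationConfig,
    epistatic_penetrance,
    simulate_case_control,
)
from conftest import make_dataset
from oracles import oracle_mdr_fold_winner


class TestClassifyCells:
    def test_ratio_against_threshold(self):
        # one cell 10 cases/2 controls, another 2/10; T = 789/531
        codes = np.array([[0]] * 12 + [[1]] * 12)
        y = np.array([1] * 10 + [0] * 2 + [1] * 2 + [0] * 10)
        rm = classify_cells(codes, y, threshold=789 / 531)
        assert rm[0] == HIGH and rm[1] == LOW
        assert rm[2] == EMPTY

    def test_tie_ratio_is_high(self):
        codes = np.array([[0]] * 4)
        y = np.array([1, 1, 0, 0])  # ratio 1.0 == default threshold
        assert classify_cells(codes, y)[0] == HIGH

    def test_all_cases_training_every_occupied_cell_high(self, rng):
        codes = rng.integers(0, 3, size=(30, 2))
        y = np.ones(30, int)
        rm = classify_cells(codes, y)
        occupied = np.unique(codes @ np.array([3, 1]))
        assert (rm[occupied] == HIGH).all()
        assert (rm[np.setdiff1d(np.arange(9), occupied)] == EMPTY).all()

    def test_label_swap_flips_cells_and_preserves_ba(self, rng):
        codes = rng.integers(0, 3, size=(200, 2))
        y = rng.integers(0, 2, size=200)
        t = y.sum() / (len(y) - y.sum())
        rm = classify_cells(codes, y)
        rm_swap = classify_cells(codes, 1 - y)
        idx = codes @ np.array([3, 1])
        cases = np.bincount(idx[y == 1], minlength=9)
        ctrls = np.bincount(idx[y == 0], minlength=9)
        for cell in range(9):
            if cases[cell] + ctrls[cell] == 0:
                continue
            if abs(cases[cell] - t * ctrls[cell]) < 1e-9:
                continue  # threshold tie: stays high under both labellings
            assert rm[cell] != rm_swap[cell]
        if not any(
            cases[c] + ctrls[c] > 0 and abs(cases[c] - t * ctrls[c]) < 1e-9
            for c in range(9)
        ):
            ba = balanced_accuracy(rm, codes, y)
            ba_swap = balanced_accuracy(rm_swap, codes, 1 - y)
            assert ba == pytest.approx(ba_swap)


class TestBalancedAccuracy:
    def test_perfect_map(self):
        codes = np.array([[0], [2]] * 10)
        y = np.array([0, 1] * 10)
        rm = np.array([LOW, EMPTY, HIGH], dtype=np.int8)
        assert balanced_accuracy(rm, codes, y) == 1.0

    def test_all_high_is_half(self):
        codes = np.array([[0], [1], [2], [0]])
        y = np.array([0, 1, 1, 0])
        rm = np.array([HIGH, HIGH, HIGH], dtype=np.int8)
        assert balanced_accuracy(rm, codes, y) == 0.5

    def test_random_map_near_half_on_balanced_data(self, rng):
        bas = []
        for _ in range(50):
            codes = rng.integers(0, 3, size=(400, 1))
            y = rng.permutation(np.r_[np.ones(200, int), np.zeros(200, int)])
            rm = rng.choice([HIGH, LOW], size=3).astype(np.int8)
            bas.append(balanced_accuracy(rm, codes, y))
        assert np.mean(bas) == pytest.approx(0.5, abs=0.02)

    def test_single_class_rejected(self):
        rm = np.array([HIGH, LOW, LOW], dtype=np.int8)
        with pytest.raises(ValueError):
            balanced_accuracy(rm, np.array([[0]]), np.array([1]))

    def test_empty_cells_predict_low(self):
        rm = np.array([EMPTY, LOW, HIGH], dtype=np.int8)
        pred = predict(rm, np.array([[0], [1], [2]]))
        assert pred.tolist() == [0, 0, 1]


class TestSearch:
    def test_fold_winners_match_exhaustive_oracle(self, rng):
        # <=6 SNPs, n<=200: per-fold winner equals brute-force enumeration
        geno = rng.integers(0, 3, size=(120, 5)).astype(np.int8)
        y = rng.integers(0, 2, size=120)
        y[geno[:, 1] + geno[:, 3] >= 2] = 1  # plant a weak 2-locus signal
        ds = make_dataset(geno, y)
        cfg = MDRSearchConfig(k_min=2, k_max=2, folds=5, n_perm=1, seed=7)
        model = mdr_search(ds, cfg)[2]
        splits = _fold_indices(y.astype(int), 5, 7)
        for winner, (train, _) in zip(model.fold_winners, splits):
            ba, combo = oracle_mdr_fold_winner(
                geno.tolist(), y.tolist(), 2, train.tolist()
            )
            assert winner == combo

    def test_k1_strong_marginal_snp_recovered(self, rng):
        n = 600
        g = rng.integers(0, 3, size=(n, 4)).astype(np.int8)
        p = np.where(g[:, 2] >= 1, 0.75, 0.3)
        y = (rng.random(n) < p).astype(int)
        ds = make_dataset(g, y)
        model = mdr_search(ds, MDRSearchConfig(1, 1, folds=10, seed=0))[1]
        assert model.loci == ["snp03"]
        assert model.cvc == 10

    def test_xor_epistasis_recovered(self):
        pen = epistatic_penetrance("xor", 0.45, 0.05, ["snp01", "snp02"])
        cfg = SimulationConfig([0.3] * 6, 500, 500, penetrance=pen, seed=13)
        ds, _ = simulate_case_control(cfg)
        model = mdr_search(ds, MDRSearchConfig(2, 2, folds=10, seed=1))[2]
        assert model.loci == ["snp01", "snp02"]
        assert model.testing_ba > 0.6

    def test_reproducible_for_fixed_seed(self, rng):
        g = rng.integers(0, 3, size=(150, 4)).astype(np.int8)
        y = rng.integers(0, 2, size=150)
        ds = make_dataset(g, y)
        cfg = MDRSearchConfig(1, 2, folds=5, seed=42)
        m1 = mdr_search(ds, cfg)
        m2 = mdr_search(ds, cfg)
        for k in m1:
            assert m1[k].loci == m2[k].loci
            assert m1[k].testing_ba == m2[k].testing_ba
            assert np.array_equal(m1[k].risk_map, m2[k].risk_map)

    def test_k_above_snp_count_rejected(self, rng):
        ds = make_dataset(rng.integers(0, 3, size=(50, 2)), rng.integers(0, 2, 50))
        with pytest.raises(ValueError):
            mdr_search(ds, MDRSearchConfig(3, 3, folds=2))

    def test_missing_locus_individuals_dropped_per_model(self, rng):
        g = rng.integers(0, 3, size=(100, 2)).astype(np.int8)
        g[:40, 0] = MISSING
        y = np.r_[np.ones(50, int), np.zeros(50, int)]
        ds = make_dataset(g, y)
        model = mdr_search(ds, MDRSearchConfig(1, 1, folds=4, seed=0))[1]
        assert model.loci  # search completes despite 40% missing at snp01


class TestPermutation:
    def test_formula_floor_when_observed_unbeatable(self, rng):
        g = rng.integers(0, 3, size=(60, 2)).astype(np.int8)
        y = rng.integers(0, 2, size=60)
        ds = make_dataset(g, y)
        cfg = MDRSearchConfig(1, 1, folds=3, n_perm=9, seed=0)
        p = permutation_test(ds, cfg, observed_tba=1.01, k=1)
        assert p == pytest.approx(1 / 10)

    def test_null_observed_has_large_p(self, rng):
        g = rng.integers(0, 3, size=(100, 3)).astype(np.int8)
        y = rng.permutation(np.r_[np.ones(50, int), np.zeros(50, int)])
        ds = make_dataset(g, y)
        cfg = MDRSearchConfig(1, 1, folds=5, n_perm=19, seed=3)
        model = mdr_search(ds, cfg)[1]
        p = permutation_test(ds, cfg, model.testing_ba, 1)
        assert p > 0.05


class TestHighRiskOr:
    def test_all_one_group_errors(self):
        ds = make_dataset([[0]] * 20, [1] * 10 + [0] * 10)
        model = mdr_search(ds, MDRSearchConfig(1, 1, folds=2, seed=0))[1]
        with pytest.raises(ValueError, match="one risk group"):
            highrisk_or(model, ds)

    def test_epistatic_or_matches_penetrance_contrast(self):
        # expected 2x2 computable from the penetrance table itself
        pen = epistatic_penetrance("xor", 0.45, 0.05, ["snp01", "snp02"])
        maf = 0.3
        cfg = SimulationConfig([maf, maf], 900, 900, penetrance=pen, seed=21)
        ds, _ = simulate_case_control(cfg)
        model = mdr_search(ds, MDRSearchConfig(2, 2, folds=10, seed=2))[2]
        res = highrisk_or(model, ds)
        probs = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
        joint = np.outer(probs, probs)
        high = pen.table == 0.45
        p_case_high = (joint[high] * 0.45).sum()
        p_ctrl_high = (joint[high] * 0.55).sum()
        p_case_low = (joint[~high] * 0.05).sum()
        p_ctrl_low = (joint[~high] * 0.95).sum()
        true_or = (p_case_high * p_ctrl_low) / (p_case_low * p_ctrl_high)
        assert res.ci_low < true_or < res.ci_high
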