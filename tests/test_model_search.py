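import numpy as np
import pandas as pd
import pytest

from pepscreen import model_search
from pepscreen.compile_align import AbundanceMatrix, MasterPeptide
from pepscreen.model_search import (
    ModelResult,
    ModelSpec,
    cv_error,
    enumerate_grid,
    labels_for,
    make_rat_folds,
    run_search,
    select_best,
)


def _toy_matrix(rng, n_rats_per_group=8, p=30, separation=0.0, week=1):
    """One-week matrix with 3 balanced groups; optional separable signal."""
    groups = ["NA"] * n_rats_per_group + ["HA"] * n_rats_per_group + ["HL"] * n_rats_per_group
    rows, values = [], []
    for i, g in enumerate(groups):
        rat = f"{g}{i:02d}"
        rows.append(
            {"sample_id": f"{rat}_W{week}", "rat_id": rat, "group": g, "week": week}
        )
        x = rng.lognormal(mean=3.0, sigma=0.5, size=p)
        if separation:  # distinct six-peptide signature per non-control group
            if g == "HA":
                x[0:6] += separation
            elif g == "HL":
                x[6:12] += separation
        values.append(x)
    peptides = [MasterPeptide(j + 1, 1000.0 + 10 * j, 30.0, None) for j in range(p)]
    return AbundanceMatrix(pd.DataFrame(rows), peptides, np.array(values))


class TestEnumerateGrid:
    def test_full_grid_is_1750(self):
        grid = enumerate_grid()
        assert len(grid) == 1750
        by = {}
        for s in grid:
            by[s.grouping] = by.get(s.grouping, 0) + 1
        assert by == {"four_group_week": 600, "three_group_week": 400, "all_16": 750}

    def test_three_group_subtotal(self):
        grid = enumerate_grid(groupings=("three_group_week",))
        assert len(grid) == 400  # 4 weeks x 2 components x 50 peptide counts

    def test_single_peptide_restriction(self):
        grid = enumerate_grid(n_peptides=[1])
        assert len(grid) == 35  # 4*3 + 4*2 + 15

    def test_deterministic_ordering(self):
        grid = enumerate_grid(n_peptides=[10, 20])
        assert grid[0] == ModelSpec("four_group_week", 1, 1, 10)
        assert grid[1] == ModelSpec("four_group_week", 1, 1, 20)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("three_group_week", 1, 3, 10)  # ncomp > n_groups - 1
        with pytest.raises(ValueError):
            ModelSpec("four_group_week", 5, 1, 10)
        with pytest.raises(ValueError):
            ModelSpec("all_16", 1, 1, 10)  # all_16 takes no week
        with pytest.raises(ValueError):
            ModelSpec("three_group_week", 1, 1, 51)


class TestLabels:
    def test_three_group_merges_standard_diet(self):
        df = pd.DataFrame({"group": ["NA", "NL", "HA", "HL"], "week": [1] * 4})
        assert labels_for(df, "three_group_week").tolist() == ["N", "N", "HA", "HL"]

    def test_all16_crosses_group_and_week(self):
        df = pd.DataFrame({"group": ["NA", "HL"], "week": [1, 4]})
        assert labels_for(df, "all_16").tolist() == ["NA-W1", "HL-W4"]


class TestFolds:
    def test_partition_is_stratified_and_balanced(self):
        rats = [f"R{i}" for i in range(24)]
        groups = ["NA"] * 6 + ["NL"] * 6 + ["HA"] * 6 + ["HL"] * 6
        folds = make_rat_folds(rats, groups, 10, seed=5)
        flat = [r for f in folds for r in f]
        assert sorted(flat) == sorted(rats)
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1
        # each group spread over distinct folds -> at most one rat of a
        # group per fold
        for f in folds:
            gs = [groups[rats.index(r)] for r in f]
            assert len(gs) == len(set(gs))

    def test_seed_changes_layout_deterministically(self):
        rats = [f"R{i}" for i in range(12)]
        groups = ["NA"] * 6 + ["HA"] * 6
        a = make_rat_folds(rats, groups, 4, seed=1)
        b = make_rat_folds(rats, groups, 4, seed=1)
        c = make_rat_folds(rats, groups, 4, seed=2)
        assert a == b
        assert a != c


class TestCvError:
    def test_zero_error_on_separable_data(self, rng):
        mat = _toy_matrix(rng, separation=200.0)
        spec = ModelSpec("three_group_week", 1, 2, 12)
        res = cv_error(spec, mat, seed=3)
        assert res.error_rate == 0.0

    def test_error_is_mean_of_fold_errors(self, rng):
        mat = _toy_matrix(rng, separation=5.0)
        res = cv_error(ModelSpec("three_group_week", 1, 2, 5), mat, seed=9)
        assert res.error_rate == pytest.approx(np.mean(res.per_fold_errors))
        assert 0.0 <= res.error_rate <= 1.0

    def test_permuted_labels_give_chance_error(self):
        # no signal at all: 3 balanced groups classify at ~2/3 error
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            mat = _toy_matrix(rng, separation=0.0)
            res = cv_error(ModelSpec("three_group_week", 1, 2, 10), mat, seed=seed)
            errs.append(res.error_rate)
        assert np.mean(errs) == pytest.approx(2 / 3, abs=0.15)

    def test_bitwise_reproducible_for_fixed_seed(self, small_matrix):
        spec = ModelSpec("three_group_week", 2, 2, 10)
        a = cv_error(spec, small_matrix, seed=17)
        b = cv_error(spec, small_matrix, seed=17)
        assert a.per_fold_errors == b.per_fold_errors
        assert a.error_rate == b.error_rate

    def test_rats_never_straddle_folds_in_all16(self, small_matrix):
        # all_16 uses each rat's four weekly samples; track fold purity
        rat_ids = small_matrix.samples["rat_id"].to_numpy()
        rat_df = small_matrix.samples.drop_duplicates("rat_id")
        y = model_search.labels_for(small_matrix.samples, "all_16")
        folds = model_search.draw_valid_folds(
            rat_df["rat_id"].tolist(),
            model_search.labels_for(rat_df, "four_group_week").tolist(),
            y, rat_ids, 10, seed=2,
        )
        seen = {}
        for k, fold in enumerate(folds):
            for rat in fold:
                assert rat not in seen
                seen[rat] = k
        assert len(seen) == len(rat_df)


class TestSelectBest:
    def _results(self, errors, week=1):
        out = []
        for i, e in enumerate(errors):
            spec = ModelSpec("three_group_week", week, 1 + i % 2, 1 + i)
            out.append(ModelResult(spec, e, [e]))
        return out

    def test_lowest_k_selected(self):
        res = self._results([0.1, 0.3, 0.2, 0.1, 0.4, 0.05, 0.5])
        best = select_best(res, "three_group_week", 1, k=5)
        assert sorted(r.error_rate for r in best) == [0.05, 0.1, 0.1, 0.2, 0.3]

    def test_ties_broken_by_parsimony(self):
        res = self._results([0.2] * 8)
        best = select_best(res, "three_group_week", 1, k=5)
        assert [r.spec.n_peptides for r in best] == [1, 2, 3, 4, 5]

    def test_fewer_than_k_warns_and_returns_all(self):
        res = self._results([0.1, 0.2])
        with pytest.warns(UserWarning):
            best = select_best(res, "three_group_week", 1, k=5)
        assert len(best) == 2

    def test_informative_peptide_favors_small_models(self):
        # one dominant peptide: the selected best model should be sparse
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(2000 + seed)
            mat = _toy_matrix(rng, p=20, separation=0.0)
            col = mat.values[:, 0].copy()
            col[labels_for(mat.samples, "three_group_week") == "HA"] += 300.0
            mat.values[:, 0] = col
            specs = enumerate_grid(
                n_peptides=[1, 2, 5, 10, 20, 30], groupings=("three_group_week",),
                weeks=(1,),
            )
            results = run_search(mat, specs, seed=seed)
            best = select_best(results, "three_group_week", 1, k=1)[0]
            hits += best.spec.n_peptides <= 5
        assert hits >= 8


class TestRunSearch:
    def test_shared_folds_within_slice_and_determinism(self, small_matrix):
        specs = enumerate_grid(
            n_peptides=[5, 10], groupings=("three_group_week",), weeks=(1, 2)
        )
        a = run_search(small_matrix, specs, seed=21)
        b = run_search(small_matrix, specs, seed=21)
        assert [r.error_rate for r in a] == [r.error_rate for r in b]

    def test_results_table_ranks_within_slice(self, small_matrix):
        specs = enumerate_grid(
            n_peptides=[5, 10], groupings=("three_group_week",), weeks=(1,)
        )
        table = model_search.results_table(run_search(small_matrix, specs, seed=4))
        assert set(table["rank"]) == {1.0, 2.0, 3.0, 4.0}
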