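import numpy as np
import pytest

from pepscreen.compile_align import (
    AbundanceMatrix,
    MasterPeptide,
    NormalizationError,
    compile_dataset,
    features_match,
    normalize_run,
    ppm_deviation,
)
from pepscreen.peaklist_io import PeptideFeature, SampleRun


def _run(features, sample_id="S1", group="NA", week=1):
    return SampleRun(sample_id, "R" + sample_id, group, week, list(features))


class TestPpmDeviation:
    def test_arithmetic(self):
        assert ppm_deviation(1000.0, 1000.05) == pytest.approx(50.0)
        assert ppm_deviation(1649.8, 1649.8) == 0.0
        # 0.1 Da at 1649.8 Da is ~60.6 ppm: beyond the matching tolerance
        assert ppm_deviation(1649.8, 1649.9) == pytest.approx(60.6, abs=0.05)

    def test_reference_is_first_mass(self):
        assert ppm_deviation(1000.0, 1001.0) != ppm_deviation(1001.0, 1000.0)

    def test_non_positive_mass_rejected(self):
        with pytest.raises(ValueError):
            ppm_deviation(0.0, 1000.0)


class TestFeaturesMatch:
    def test_within_both_tolerances(self):
        f1 = PeptideFeature(1649.8, 37.2, 1.0)
        f2 = PeptideFeature(1649.84, 38.9, 5.0)  # ~24 ppm, 1.7 min
        assert features_match(f1, f2)

    def test_identical_features_match(self):
        f = PeptideFeature(1000.0, 30.0, 1.0)
        assert features_match(f, f)

    @pytest.mark.parametrize(
        "f2",
        [
            PeptideFeature(1649.8, 39.2, 1.0),  # time gap exactly 2.0 min
            PeptideFeature(1649.8825, 37.2, 1.0),  # mass dev exactly 50 ppm
        ],
    )
    def test_bounds_are_strict(self, f2):
        f1 = PeptideFeature(1649.8, 37.2, 1.0)
        assert not features_match(f1, f2)


STD = [MasterPeptide(1, 1000.0, 20.0, reference_intensity=100.0),
       MasterPeptide(2, 2000.0, 30.0, reference_intensity=60.0),
       MasterPeptide(3, 5000.0, 40.0, reference_intensity=90.0)]


class TestNormalizeRun:
    def _observed(self, ratios):
        # one feature per standard, observed at reference/ratio
        return _run(
            [
                PeptideFeature(s.mass_da, s.mt_min, s.reference_intensity / r)
                for s, r in zip(STD, ratios)
            ]
        )

    def test_identity_when_standards_at_reference(self):
        run = self._observed([1.0, 1.0, 1.0])
        out = normalize_run(run, STD)
        assert [f.intensity for f in out.features] == [
            f.intensity for f in run.features
        ]

    def test_half_reference_doubles_everything(self):
        run = self._observed([2.0, 2.0, 2.0])
        extra = PeptideFeature(8000.0, 15.0, 10.0)
        run.features.append(extra)
        out = normalize_run(run, STD)
        assert out.features[-1].intensity == pytest.approx(20.0)

    def test_median_ratio(self):
        run = self._observed([1.8, 2.0, 2.4])
        out = normalize_run(run, STD)
        # factor = median{1.8, 2.0, 2.4} = 2.0 applied to every feature
        assert out.features[0].intensity == pytest.approx(
            run.features[0].intensity * 2.0
        )

    def test_no_standard_matched_raises_with_run_name(self):
        run = _run([PeptideFeature(9000.0, 10.0, 1.0)], sample_id="S77")
        with pytest.raises(NormalizationError, match="S77"):
            normalize_run(run, STD)


def brute_force_clusters(features, ppm_tol=50.0, mt_tol_min=2.0):
    """Single-linkage clustering under the identity rule (union-find)."""
    n = len(features)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if features_match(features[i], features[j], ppm_tol, mt_tol_min) or \
               features_match(features[j], features[i], ppm_tol, mt_tol_min):
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return sorted(frozenset(g) for g in groups.values())


class TestCompileDataset:
    def test_identical_feature_in_two_runs_gives_one_master(self):
        f = PeptideFeature(1500.0, 30.0, 10.0)
        mat = compile_dataset([_run([f], "A"), _run([f], "B")])
        assert len(mat.peptides) == 1
        assert (mat.values > 0).all()

    def test_two_min_apart_gives_two_masters(self):
        mat = compile_dataset(
            [
                _run([PeptideFeature(1500.0, 30.0, 10.0)], "A"),
                _run([PeptideFeature(1500.0, 32.0, 10.0)], "B"),
            ]
        )
        assert len(mat.peptides) == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compile_dataset([])

    def test_jittered_features_recover_true_clusters(self, rng):
        true = [(1000.0, 20.0), (1000.3, 28.0), (2500.0, 25.0),
                (2500.0, 33.0), (9000.0, 40.0)]
        runs = []
        membership = {}
        for r in range(4):
            feats = []
            for k, (m, t) in enumerate(true):
                jm = m * (1 + rng.uniform(-25e-6, 25e-6))
                jt = t + rng.uniform(-0.5, 0.5)
                membership[(r, len(feats))] = k
                feats.append(PeptideFeature(jm, jt, float(rng.uniform(5, 50))))
            runs.append(_run(feats, f"S{r}"))
        mat = compile_dataset(runs)
        assert len(mat.peptides) == 5
        # greedy clusters agree with the brute-force single-linkage oracle
        flat = [f for run in runs for f in run.features]
        oracle = brute_force_clusters(flat)
        assert len(oracle) == 5
        # each master column holds one intensity per run
        assert (mat.values > 0).all()
        # consensus masses sit within tolerance of the truth
        got = sorted(p.mass_da for p in mat.peptides)
        for g, (m, _) in zip(got, sorted(true)):
            assert abs(g - m) / m * 1e6 < 25

    def test_idempotent_on_compiled_matrix(self, small_matrix):
        runs = [
            SampleRun(
                sample_id=row.sample_id, rat_id=row.rat_id, group=row.group,
                week=row.week,
                features=[
                    PeptideFeature(p.mass_da, p.mt_min, v)
                    for p, v in zip(small_matrix.peptides, small_matrix.values[i])
                    if v > 0
                ],
            )
            for i, row in enumerate(small_matrix.samples.itertuples())
        ]
        again = compile_dataset(runs)
        assert len(again.peptides) == len(small_matrix.peptides)
        np.testing.assert_allclose(
            [p.mass_da for p in again.peptides],
            [p.mass_da for p in small_matrix.peptides],
            rtol=1e-12,
        )
        np.testing.assert_allclose(again.values, small_matrix.values)

    def test_mutual_distinguishability_of_masters(self, small_matrix):
        peps = small_matrix.peptides
        for i in range(len(peps)):
            for j in range(i + 1, len(peps)):
                dev = ppm_deviation(peps[i].mass_da, peps[j].mass_da)
                dt = abs(peps[i].mt_min - peps[j].mt_min)
                assert dev >= 50.0 or dt >= 2.0

    def test_total_intensity_conserved(self, small_sim, small_matrix):
        runs, _ = small_sim
        total = sum(f.intensity for r in runs for f in r.features)
        assert small_matrix.values.sum() == pytest.approx(total, rel=1e-9)

    def test_feature_order_within_runs_is_irrelevant(self, small_sim):
        runs, _ = small_sim
        ref = compile_dataset(runs)
        shuffled = [
            SampleRun(r.sample_id, r.rat_id, r.group, r.week, r.features[::-1])
            for r in runs
        ]
        alt = compile_dataset(shuffled)
        np.testing.assert_allclose(ref.values, alt.values)
        assert [p.mass_da for p in ref.peptides] == [p.mass_da for p in alt.peptides]

    def test_same_run_conflict_keeps_most_intense(self):
        # two features of one run inside one tolerance window: the weaker
        # one must seed its own master, conserving total intensity
        a = PeptideFeature(1500.0, 30.0, 100.0)
        b = PeptideFeature(1500.01, 30.1, 5.0)
        other = _run([PeptideFeature(1500.0, 30.0, 90.0)], "B")
        mat = compile_dataset([_run([a, b], "A"), other])
        assert len(mat.peptides) == 2
        assert mat.values.sum() == pytest.approx(195.0)


class TestAbundanceMatrixIO:
    def test_csv_round_trip(self, small_matrix, tmp_path):
        p = tmp_path / "matrix.csv"
        small_matrix.write_csv(p)
        back = AbundanceMatrix.read_csv(p, peptides=small_matrix.peptides)
        np.testing.assert_allclose(back.values, small_matrix.values)
        assert list(back.samples["group"]) == list(small_matrix.samples["group"])

    def test_negative_values_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            AbundanceMatrix(
                pd.DataFrame(
                    {"sample_id": ["a"], "rat_id": ["r"], "group": ["NA"], "week": [1]}
                ),
                [MasterPeptide(1, 1000.0, 30.0)],
                np.array([[-1.0]]),
            )
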