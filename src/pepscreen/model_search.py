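"""Exhaustive sPLS-DA model grid and cross-validated model selection.

A *basic model* is one point of the search grid: a grouping scheme, the
week it is restricted to (weekly schemes only), a number of latent
components and a number of retained peptides (``keep_x``).  Three grouping
schemes are searched:

``four_group_week``
    NA / NL / HA / HL within one week; 1-3 components.
``three_group_week``
    N (= NA + NL merged, since the two standard-diet subgroups have
    near-identical profiles) / HA / HL within one week; 1-2 components.
``all_16``
    all treatment x week combinations simultaneously (16 classes, 1-15
    components, every sample).

With peptide counts 1..50 the full grid holds 4*3*50 + 4*2*50 + 15*50 =
1750 basic models.  Each is scored by 10-fold cross-validation whose folds
partition *rats*, not samples, stratified by treatment group, so no rat's
samples ever straddle the train/test boundary.  The error rate of a model
is the mean held-out misclassification fraction over folds.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import splsda
from .compile_align import AbundanceMatrix

GROUPINGS = ("four_group_week", "three_group_week", "all_16")
#: components allowed per grouping = n_classes - 1
NCOMP_MAX = {"four_group_week": 3, "three_group_week": 2, "all_16": 15}
MAX_PEPTIDES = 50
WEEKS = (1, 2, 3, 4)

__all__ = [
    "ModelSpec",
    "ModelResult",
    "enumerate_grid",
    "labels_for",
    "make_rat_folds",
    "cv_error",
    "run_search",
    "select_best",
    "results_table",
]


class StratificationError(RuntimeError):
    pass


@dataclass(frozen=True, order=True)
class ModelSpec:
    """One point of the model-search grid."""

    grouping: str
    week: int | None  # None for all_16
    ncomp: int
    n_peptides: int

    def __post_init__(self) -> None:
        if self.grouping not in GROUPINGS:
            raise ValueError(f"unknown grouping {self.grouping!r}")
        if self.grouping == "all_16":
            if self.week is not None:
                raise ValueError("all_16 models span every week")
        elif self.week not in WEEKS:
            raise ValueError(f"week must be in {WEEKS}")
        if not 1 <= self.ncomp <= NCOMP_MAX[self.grouping]:
            raise ValueError(
                f"ncomp {self.ncomp} outside [1, {NCOMP_MAX[self.grouping]}] "
                f"for {self.grouping}"
            )
        if not 1 <= self.n_peptides <= MAX_PEPTIDES:
            raise ValueError(f"n_peptides must be in [1, {MAX_PEPTIDES}]")


@dataclass
class ModelResult:
    spec: ModelSpec
    error_rate: float
    per_fold_errors: list[float] = field(default_factory=list)


def enumerate_grid(
    n_peptides: Iterable[int] | None = None,
    groupings: Sequence[str] = GROUPINGS,
    weeks: Sequence[int] = WEEKS,
) -> list[ModelSpec]:
    """All basic models, ordered by (grouping, week, ncomp, n_peptides).

    With defaults this is the full 1750-model grid.  ``n_peptides`` may be
    thinned (e.g. ``range(5, 51, 5)``) for cheaper sweeps.
    """
    if n_peptides is None:
        n_peptides = range(1, MAX_PEPTIDES + 1)
    n_peptides = list(n_peptides)
    specs: list[ModelSpec] = []
    for grouping in groupings:
        wk_list: Sequence[int | None] = [None] if grouping == "all_16" else list(weeks)
        for week in wk_list:
            for ncomp in range(1, NCOMP_MAX[grouping] + 1):
                for k in n_peptides:
                    specs.append(ModelSpec(grouping, week, ncomp, k))
    return specs


def labels_for(samples: pd.DataFrame, grouping: str) -> np.ndarray:
    """Per-sample class labels under a grouping scheme."""
    group = samples["group"].to_numpy()
    if grouping == "four_group_week":
        return group.astype(str)
    if grouping == "three_group_week":
        return np.where(np.isin(group, ["NA", "NL"]), "N", group).astype(str)
    if grouping == "all_16":
        week = samples["week"].to_numpy()
        return np.array([f"{g}-W{w}" for g, w in zip(group, week)])
    raise ValueError(f"unknown grouping {grouping!r}")


def make_rat_folds(
    rats: Sequence[str],
    rat_groups: Sequence[str],
    n_folds: int,
    seed: int,
) -> list[list[str]]:
    """Partition rats into folds, stratified by treatment group.

    Rats are shuffled within each group (seeded) and dealt consecutively
    across folds, so each group is spread over as many folds as it has
    members and fold sizes differ by at most one.
    """
    if len(rats) < n_folds:
        raise ValueError(f"{len(rats)} rats cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    by_group: dict[str, list[str]] = {}
    for rat, g in sorted(zip(rats, rat_groups)):
        by_group.setdefault(g, []).append(rat)
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    c = int(rng.integers(n_folds))  # rotate the starting fold per seed
    for g in sorted(by_group):
        members = by_group[g]
        rng.shuffle(members)
        for rat in members:
            folds[c % n_folds].append(rat)
            c += 1
    return folds


def _slice_for_spec(spec: ModelSpec, data: AbundanceMatrix) -> AbundanceMatrix:
    return data if spec.week is None else data.subset_week(spec.week)


def cv_error(
    spec: ModelSpec,
    data: AbundanceMatrix,
    n_folds: int = 10,
    seed: int = 0,
    folds: list[list[str]] | None = None,
    max_redraws: int = 10,
) -> ModelResult:
    """Cross-validated misclassification rate of one basic model.

    Folds partition rats; per fold the model is fitted on the other
    folds' samples and the held-out rats' samples are classified, the fold
    error being the misclassified fraction.  A fold layout whose training
    side loses an entire class is redrawn with a new seed-derived shuffle
    (up to ``max_redraws`` times).  The error rate is the mean over folds
    with at least one held-out sample.
    """
    sub = _slice_for_spec(spec, data)
    y = labels_for(sub.samples, spec.grouping)
    rat_ids = sub.samples["rat_id"].to_numpy()
    X = sub.values

    if folds is None:
        rat_df = sub.samples.drop_duplicates("rat_id")
        rat_y = labels_for(rat_df, "four_group_week")  # stratify by treatment
        folds = draw_valid_folds(
            rat_df["rat_id"].tolist(), list(rat_y), y, rat_ids, n_folds, seed, max_redraws
        )

    per_fold: list[float] = []
    for fold_rats in folds:
        test_mask = np.isin(rat_ids, fold_rats)
        if not test_mask.any():
            continue
        model = splsda.fit(
            X[~test_mask], y[~test_mask], ncomp=spec.ncomp, keep_x=spec.n_peptides,
            feature_ids=data.peptide_ids,
        )
        pred = splsda.predict(model, X[test_mask])
        per_fold.append(float(np.mean(pred != y[test_mask])))
    if not per_fold:
        raise StratificationError("no fold held any test sample")
    return ModelResult(spec, float(np.mean(per_fold)), per_fold)


def draw_valid_folds(
    rats: list[str],
    rat_groups: list[str],
    sample_labels: np.ndarray,
    sample_rats: np.ndarray,
    n_folds: int,
    seed: int,
    max_redraws: int = 10,
) -> list[list[str]]:
    """Draw stratified rat folds whose every training side covers all classes."""
    classes = set(sample_labels.tolist())
    for attempt in range(max_redraws):
        folds = make_rat_folds(rats, rat_groups, n_folds, seed + 104729 * attempt)
        ok = True
        for fold_rats in folds:
            train = ~np.isin(sample_rats, fold_rats)
            if set(sample_labels[train].tolist()) != classes:
                ok = False
                break
        if ok:
            if attempt:
                warnings.warn(f"fold layout redrawn {attempt} time(s)")
            return folds
    raise StratificationError(
        f"could not stratify {len(rats)} rats into {n_folds} folds "
        f"covering all classes after {max_redraws} redraws"
    )


def run_search(
    data: AbundanceMatrix,
    specs: Sequence[ModelSpec],
    n_folds: int = 10,
    seed: int = 0,
    cv_repeats: int = 1,
) -> list[ModelResult]:
    """Cross-validate every spec, sharing one fold layout per grid slice.

    All specs of one (grouping, week) slice see the same seed-fixed rat
    partition, so their error rates differ only through the models.  With
    ``cv_repeats`` > 1 the CV is repeated with re-shuffled folds and error
    rates are averaged.
    """
    fold_cache: dict[tuple, list[list[list[str]]]] = {}
    results: list[ModelResult] = []
    for spec in specs:
        key = (spec.grouping, spec.week)
        if key not in fold_cache:
            sub = _slice_for_spec(spec, data)
            y = labels_for(sub.samples, spec.grouping)
            rat_df = sub.samples.drop_duplicates("rat_id")
            rat_y = labels_for(rat_df, "four_group_week")
            fold_cache[key] = [
                draw_valid_folds(
                    rat_df["rat_id"].tolist(), list(rat_y), y,
                    sub.samples["rat_id"].to_numpy(), n_folds,
                    seed + 7919 * rep + zlib.crc32(repr(key).encode()) % 1000,
                )
                for rep in range(cv_repeats)
            ]
        reps = [
            cv_error(spec, data, n_folds=n_folds, seed=seed, folds=f)
            for f in fold_cache[key]
        ]
        err = float(np.mean([r.error_rate for r in reps]))
        per_fold = [e for r in reps for e in r.per_fold_errors]
        results.append(ModelResult(spec, err, per_fold))
    return results


def select_best(
    results: Sequence[ModelResult],
    grouping: str,
    week: int | None,
    k: int = 5,
) -> list[ModelResult]:
    """The k lowest-error models of one (grouping, week) slice.

    Ties favor parsimony: fewer peptides, then fewer components, then
    enumeration order.
    """
    slice_ = [
        (r.error_rate, r.spec.n_peptides, r.spec.ncomp, i, r)
        for i, r in enumerate(results)
        if r.spec.grouping == grouping and r.spec.week == week
    ]
    if len(slice_) < k:
        warnings.warn(
            f"only {len(slice_)} results for ({grouping}, week {week}); "
            f"returning all"
        )
    slice_.sort(key=lambda x: x[:4])
    return [r for *_, r in slice_[:k]]


def results_table(results: Sequence[ModelResult]) -> pd.DataFrame:
    """Results as a tidy table with per-slice error ranks."""
    df = pd.DataFrame(
        {
            "grouping": [r.spec.grouping for r in results],
            "week": [r.spec.week for r in results],
            "ncomp": [r.spec.ncomp for r in results],
            "n_peptides": [r.spec.n_peptides for r in results],
            "error_rate": [r.error_rate for r in results],
        }
    )
    df["rank"] = df.groupby(["grouping", "week"], dropna=False)["error_rate"].rank(
        method="first"
    )
    return df
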