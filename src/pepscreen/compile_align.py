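"""Cross-sample peptide matching, normalization and master-matrix assembly.

Peptides detected in different CE-MS runs are considered the same species
when their masses agree within +/-50 ppm *and* their normalized migration
times agree within 2 min (both bounds strict).  This module applies that
identity rule to compile many per-run peak lists into a single master
peptide list and a samples x peptides relative-abundance matrix, with zero
meaning non-detection.

Cross-run clustering is greedy and reference-based: features are ranked by
how many runs contain a matching feature (then by intensity), the
highest-ranked unassigned feature seeds a master peptide, and every other
feature joins the nearest matching master (smallest ppm deviation,
migration-time gap as tie-break).  A run can contribute at most one feature
per master; when two features of one run compete, the more intense one
stays and the other seeds a new master.  The ppm reference is always the
master (seed) mass.

Run-level intensity normalization against declared internal standard
peptides is provided as median-ratio scaling; data that is already
normalized upstream passes through a no-op bypass.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .peaklist_io import PeptideFeature, SampleRun

DEFAULT_PPM_TOL = 50.0
DEFAULT_MT_TOL_MIN = 2.0

__all__ = [
    "MasterPeptide",
    "AbundanceMatrix",
    "NormalizationError",
    "ppm_deviation",
    "features_match",
    "normalize_run",
    "compile_dataset",
]


class NormalizationError(RuntimeError):
    pass


@dataclass(frozen=True)
class MasterPeptide:
    """One consensus peptide of the compiled dataset."""

    peptide_id: int
    mass_da: float  # intensity-weighted consensus mass
    mt_min: float  # intensity-weighted consensus migration time
    reference_intensity: float | None = None  # set only for internal standards


@dataclass
class AbundanceMatrix:
    """Samples x master-peptides matrix of relative abundances.

    ``samples`` is a DataFrame with columns sample_id, rat_id, group, week
    (one row per run, aligned with the rows of ``values``); ``peptides``
    lists the master peptides aligned with the columns.  A zero entry
    encodes non-detection of that peptide in that sample.
    """

    samples: pd.DataFrame
    peptides: list[MasterPeptide]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.peptides)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.peptides)} peptides"
            )
        if (self.values < 0).any():
            raise ValueError("abundances must be >= 0")

    @property
    def peptide_ids(self) -> list[int]:
        return [p.peptide_id for p in self.peptides]

    def subset_week(self, week: int) -> "AbundanceMatrix":
        mask = (self.samples["week"] == week).to_numpy()
        return AbundanceMatrix(
            self.samples.loc[mask].reset_index(drop=True),
            self.peptides,
            self.values[mask],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.peptide_ids)
        return pd.concat([self.samples.reset_index(drop=True), df], axis=1)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, peptides: list[MasterPeptide] | None = None) -> "AbundanceMatrix":
        meta_cols = ["sample_id", "rat_id", "group", "week"]
        # keep_default_na=False: the treatment label "NA" is data, not missing
        df = pd.read_csv(
            path,
            dtype={"sample_id": str, "rat_id": str, "group": str},
            keep_default_na=False,
        )
        df["week"] = df["week"].astype(int)
        value_cols = [c for c in df.columns if c not in meta_cols]
        if peptides is None:
            peptides = [MasterPeptide(int(c), float("nan"), float("nan")) for c in value_cols]
        return cls(df[meta_cols], peptides, df[value_cols].to_numpy(dtype=float))


def ppm_deviation(m_master: float, m_other: float) -> float:
    """Mass deviation of ``m_other`` from ``m_master`` in parts per million.

    The reference is the first (master/seed) mass, so the predicate built
    on it does not depend on averaging choices.
    """
    if m_master <= 0 or m_other <= 0:
        raise ValueError("masses must be positive")
    return abs(m_master - m_other) / m_master * 1e6


def features_match(
    f1: PeptideFeature | MasterPeptide,
    f2: PeptideFeature | MasterPeptide,
    ppm_tol: float = DEFAULT_PPM_TOL,
    mt_tol_min: float = DEFAULT_MT_TOL_MIN,
) -> bool:
    """True iff two features are the same peptide under the identity rule.

    Mass deviation strictly below ``ppm_tol`` (reference = first argument)
    and migration-time gap strictly below ``mt_tol_min``.
    """
    return (
        ppm_deviation(f1.mass_da, f2.mass_da) < ppm_tol
        and abs(f1.mt_min - f2.mt_min) < mt_tol_min
    )


def normalize_run(
    run: SampleRun,
    standards: Sequence[MasterPeptide],
    ppm_tol: float = DEFAULT_PPM_TOL,
    mt_tol_min: float = DEFAULT_MT_TOL_MIN,
) -> SampleRun:
    """Scale all intensities of a run against internal standard peptides.

    Each declared standard is looked up in the run via the identity rule
    (most intense matching feature wins); the run-level factor is the
    median over matched standards of reference_intensity / observed
    intensity.  Raises :class:`NormalizationError` when no standard is
    found in the run.  Pass an empty ``standards`` sequence upstream to
    skip normalization entirely for pre-normalized data.
    """
    ratios = []
    for std in standards:
        if std.reference_intensity is None:
            raise ValueError(f"standard {std.peptide_id} lacks a reference intensity")
        matches = [
            f for f in run.features if features_match(std, f, ppm_tol, mt_tol_min)
        ]
        if not matches:
            continue
        obs = max(matches, key=lambda f: f.intensity)
        if obs.intensity > 0:
            ratios.append(std.reference_intensity / obs.intensity)
    if not ratios:
        raise NormalizationError(
            f"run {run.sample_id}: no internal standard matched"
        )
    factor = float(np.median(ratios))
    return SampleRun(
        sample_id=run.sample_id,
        rat_id=run.rat_id,
        group=run.group,
        week=run.week,
        features=[replace(f, intensity=f.intensity * factor) for f in run.features],
    )


def _occurrence_counts(
    mass: np.ndarray, mt: np.ndarray, run_idx: np.ndarray,
    ppm_tol: float, mt_tol_min: float,
) -> np.ndarray:
    """Number of distinct runs holding a feature matching each feature."""
    order = np.argsort(mass, kind="stable")
    m = mass[order]
    t = mt[order]
    r = run_idx[order]
    n = len(m)
    counts = np.empty(n, dtype=int)
    # window generous enough to contain every candidate regardless of
    # which mass serves as the ppm reference
    lo_bound = m * (1 - 2 * ppm_tol * 1e-6)
    hi_bound = m * (1 + 2 * ppm_tol * 1e-6)
    lo = np.searchsorted(m, lo_bound, side="left")
    hi = np.searchsorted(m, hi_bound, side="right")
    for i in range(n):
        sl = slice(lo[i], hi[i])
        ok = (np.abs(m[sl] - m[i]) / m[i] * 1e6 < ppm_tol) & (
            np.abs(t[sl] - t[i]) < mt_tol_min
        )
        counts[i] = len(np.unique(r[sl][ok]))
    out = np.empty(n, dtype=int)
    out[order] = counts
    return out


def compile_dataset(
    runs: Sequence[SampleRun],
    ppm_tol: float = DEFAULT_PPM_TOL,
    mt_tol_min: float = DEFAULT_MT_TOL_MIN,
) -> AbundanceMatrix:
    """Compile normalized runs into a master list and abundance matrix.

    See the module docstring for the clustering procedure.  The result is
    deterministic and independent of the input feature order; master
    peptides are numbered 1..K in order of increasing consensus mass.
    """
    if not runs:
        raise ValueError("compile_dataset requires at least one run")

    mass = np.array([f.mass_da for r in runs for f in r.features])
    mt = np.array([f.mt_min for r in runs for f in r.features])
    inten = np.array([f.intensity for r in runs for f in r.features])
    run_idx = np.array([i for i, r in enumerate(runs) for _ in r.features])
    n_feat = len(mass)

    if n_feat == 0:
        samples = _samples_frame(runs)
        return AbundanceMatrix(samples, [], np.zeros((len(runs), 0)))

    occ = _occurrence_counts(mass, mt, run_idx, ppm_tol, mt_tol_min)
    # deterministic processing order: most replicated first, then most
    # intense; remaining keys only break exact ties reproducibly
    order = np.lexsort((run_idx, mt, mass, -inten, -occ))

    seed_mass: list[float] = []  # per master, the seed (reference) mass
    seed_mt: list[float] = []
    members: list[list[int]] = []  # feature indices per master
    member_run_best: list[dict[int, int]] = []  # run -> feature idx kept
    sorted_mass: list[float] = []  # seed masses kept sorted for lookup
    sorted_master: list[int] = []  # master index aligned with sorted_mass

    def new_master(fi: int) -> int:
        mi = len(seed_mass)
        seed_mass.append(mass[fi])
        seed_mt.append(mt[fi])
        members.append([fi])
        member_run_best.append({int(run_idx[fi]): fi})
        pos = bisect.bisect_left(sorted_mass, mass[fi])
        sorted_mass.insert(pos, mass[fi])
        sorted_master.insert(pos, mi)
        return mi

    pending = list(order)
    while pending:
        next_round: list[int] = []
        for fi in pending:
            m_f, t_f = mass[fi], mt[fi]
            lo = bisect.bisect_left(sorted_mass, m_f * (1 - 2 * ppm_tol * 1e-6))
            hi = bisect.bisect_right(sorted_mass, m_f * (1 + 2 * ppm_tol * 1e-6))
            best: tuple[float, float, int] | None = None
            for pos in range(lo, hi):
                mi = sorted_master[pos]
                dev = ppm_deviation(seed_mass[mi], m_f)
                dt = abs(seed_mt[mi] - t_f)
                if dev < ppm_tol and dt < mt_tol_min:
                    key = (dev, dt, mi)
                    if best is None or key < best:
                        best = key
            if best is None:
                new_master(fi)
                continue
            mi = best[2]
            rid = int(run_idx[fi])
            held = member_run_best[mi].get(rid)
            if held is None:
                members[mi].append(fi)
                member_run_best[mi][rid] = fi
            elif inten[fi] > inten[held]:
                # displace the weaker feature; it seeds its own master on
                # a later pass so it is never silently dropped
                members[mi].remove(held)
                members[mi].append(fi)
                member_run_best[mi][rid] = fi
                next_round.append(held)
            else:
                next_round.append(fi)
        if next_round:
            # displaced features must not re-enter the master that
            # rejected them: seed each as its own master directly
            for fi in next_round:
                new_master(fi)
        pending = []

    # consensus coordinates: intensity-weighted means over members
    consensus = []
    for mi, mem in enumerate(members):
        mem_arr = np.asarray(mem)
        w = inten[mem_arr]
        if w.sum() <= 0:
            w = np.ones_like(w)
        cm = float(np.average(mass[mem_arr], weights=w))
        ct = float(np.average(mt[mem_arr], weights=w))
        consensus.append((cm, ct, mi))
    consensus.sort()

    peptides = [
        MasterPeptide(peptide_id=k + 1, mass_da=cm, mt_min=ct)
        for k, (cm, ct, _) in enumerate(consensus)
    ]
    values = np.zeros((len(runs), len(peptides)))
    for k, (_, _, mi) in enumerate(consensus):
        for fi in members[mi]:
            values[int(run_idx[fi]), k] += inten[fi]

    return AbundanceMatrix(_samples_frame(runs), peptides, values)


def _samples_frame(runs: Sequence[SampleRun]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in runs],
            "rat_id": [r.rat_id for r in runs],
            "group": [r.group for r in runs],
            "week": [int(r.week) for r in runs],
        }
    )
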