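"""Synthetic CE-MS urinary-peptidome datasets with known ground truth.

The generator emulates the statistical structure the screening pipeline
assumes: 24 rats in four treatment groups (NA, NL, HA, HL; 6 each), four
weekly urine collections, and ~888 distinct peptides whose relative
abundances are zero-inflated and heavily right-skewed.  A planted subset
of peptides (55 by default) carries a diet effect: their HA log-abundance
is shifted by ``effect_lfc`` natural-log units relative to the standard
diet, while the HL shift is an intermediate fraction ``hl_lambda`` of the
HA shift in weeks 1-3 and converges toward HA (``hl_lambda_week4``) in
week 4 — the temporal pattern the screen is meant to recover.

Abundances follow a zero-inflated log-normal model: a peptide is detected
in a sample with a probability that increases logistically with its group
log-mean (calibrated so overall detection matches ``detect_base``), and a
detected abundance is log-normal around the group log-mean with spread
``sigma_log``.  All distributional choices are generator conventions, not
claims about real urine data.

Peptide coordinates are laid out so that true peptides are mutually
separable under the +/-50 ppm matching rule, with per-run jitter well
inside the tolerance, so the compiled master list can be aligned back to
the ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .compile_align import AbundanceMatrix, MasterPeptide
from .peaklist_io import PeptideFeature, SampleRun

__all__ = [
    "SimConfig",
    "GroundTruth",
    "RecoveryMetrics",
    "generate",
    "evaluate_recovery",
    "matrix_from_panel_table",
]

GROUPS = ("NA", "NL", "HA", "HL")
SUPER = ("N", "HA", "HL")


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults mirror the study design."""

    n_peptides: int = 888
    rats_per_subgroup: int = 6
    weeks: int = 4
    n_planted: int = 55
    effect_lfc: float = 1.5  # natural-log HA-vs-N shift of planted peptides
    hl_lambda: float = 0.5  # HL intermediacy in weeks 1..weeks-1
    hl_lambda_week4: float = 0.95  # HL -> HA convergence in the final week
    detect_base: float = 0.6  # average detection probability
    sigma_log: float = 0.8  # within-group log-normal SD
    missing_run_prob: float = 0.04  # a rat-week collection is absent
    mass_jitter_ppm: float = 20.0
    mt_jitter_min: float = 0.5
    mass_range_da: tuple[float, float] = (800.0, 30000.0)
    mt_range_min: tuple[float, float] = (19.0, 47.0)
    detect_slope: float = 0.5  # logistic slope on the log-mean
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_planted <= self.n_peptides:
            raise ValueError("n_planted must be in (0, n_peptides]")
        for p in (self.detect_base, self.missing_run_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if not 0 < self.hl_lambda < 1:
            raise ValueError("hl_lambda must be in (0, 1)")


@dataclass
class GroundTruth:
    """What was planted, for scoring recovery."""

    planted_ids: set[int]  # true peptide ids (1-based)
    mass_da: np.ndarray  # (p,) true masses
    mt_min: np.ndarray  # (p,) true migration times
    log_mean: np.ndarray  # (p, 3 supergroups, weeks) expected log-abundance
    detect_prob: np.ndarray  # same shape, detection probabilities
    effect_sign: np.ndarray  # (p,) +1/-1 for planted, 0 otherwise
    config: SimConfig = field(repr=False, default=None)

    def map_masters(
        self, peptides: Sequence[MasterPeptide], ppm_tol: float = 50.0,
        mt_tol_min: float = 2.0,
    ) -> dict[int, int]:
        """Match compiled master peptides to true ids by mass and time."""
        order = np.argsort(self.mass_da)
        sorted_mass = self.mass_da[order]
        out: dict[int, int] = {}
        for pep in peptides:
            i = int(np.searchsorted(sorted_mass, pep.mass_da))
            best, best_dev = None, ppm_tol
            for j in (i - 1, i, i + 1):
                if 0 <= j < len(sorted_mass):
                    tid = int(order[j])
                    dev = abs(self.mass_da[tid] - pep.mass_da) / self.mass_da[tid] * 1e6
                    if dev < best_dev and abs(self.mt_min[tid] - pep.mt_min) < mt_tol_min:
                        best, best_dev = tid + 1, dev
            if best is not None:
                out[pep.peptide_id] = best
        return out


@dataclass
class RecoveryMetrics:
    sensitivity: float  # recovered fraction of planted ids, union of weeks
    false_by_week: dict[int, int]
    false_total: int
    recovered: set[int]


def _calibrate_intercept(mu: np.ndarray, slope: float, target: float) -> float:
    """Intercept of the logistic detection model hitting a mean rate."""
    centered = slope * (mu - np.log(500.0))

    def mean_rate(alpha: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + centered)))))

    lo, hi = -20.0, 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mean_rate(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate(cfg: SimConfig) -> tuple[list[SampleRun], GroundTruth]:
    """Generate per-sample runs plus ground truth, fully seed-determined."""
    rng = np.random.default_rng(cfg.seed)
    p, W = cfg.n_peptides, cfg.weeks

    # --- peptide coordinates: log-spaced masses, mutually separable ----
    lo, hi = cfg.mass_range_da
    log_step = (math.log(hi) - math.log(lo)) / p
    if 0.4 * log_step < 1.2e-4:  # min gap must exceed 2x the 50 ppm rule
        raise ValueError(f"cannot pack {p} separable peptides into {cfg.mass_range_da}")
    centers = np.log(lo) + (np.arange(p) + 0.5) * log_step
    mass = np.exp(centers + rng.uniform(-0.3, 0.3, p) * log_step)
    mt = rng.uniform(*cfg.mt_range_min, p)

    # --- planted effects ----------------------------------------------
    planted = rng.choice(p, size=cfg.n_planted, replace=False)
    sign = np.zeros(p)
    sign[planted] = rng.choice([-1.0, 1.0], size=cfg.n_planted)
    mu = rng.normal(math.log(500.0), 1.0, p)

    lam = np.full(W, cfg.hl_lambda)
    if W >= 2:
        lam[W - 1] = cfg.hl_lambda_week4
    log_mean = np.empty((p, 3, W))
    log_mean[:, 0, :] = mu[:, None]  # N
    log_mean[:, 1, :] = (mu + sign * cfg.effect_lfc)[:, None]  # HA
    for w in range(W):
        log_mean[:, 2, w] = mu + lam[w] * sign * cfg.effect_lfc  # HL

    alpha = _calibrate_intercept(mu, cfg.detect_slope, cfg.detect_base)
    detect_prob = 1.0 / (
        1.0 + np.exp(-(alpha + cfg.detect_slope * (log_mean - math.log(500.0))))
    )

    truth = GroundTruth(
        planted_ids={int(i) + 1 for i in planted},
        mass_da=mass,
        mt_min=mt,
        log_mean=log_mean,
        detect_prob=detect_prob,
        effect_sign=sign,
        config=cfg,
    )

    super_of = {"NA": 0, "NL": 0, "HA": 1, "HL": 2}
    runs: list[SampleRun] = []
    for gi, group in enumerate(GROUPS):
        for r in range(cfg.rats_per_subgroup):
            rat_id = f"{group}{r + 1:02d}"
            for week in range(1, W + 1):
                if rng.random() < cfg.missing_run_prob:
                    continue
                g = super_of[group]
                m_gw = log_mean[:, g, week - 1]
                detected = rng.random(p) < detect_prob[:, g, week - 1]
                ab = np.exp(rng.normal(m_gw, cfg.sigma_log))
                jm = mass * (1 + rng.uniform(-1, 1, p) * cfg.mass_jitter_ppm * 1e-6)
                jt = np.clip(mt + rng.uniform(-1, 1, p) * cfg.mt_jitter_min, 0.01, None)
                feats = [
                    PeptideFeature(float(jm[j]), float(jt[j]), float(ab[j]))
                    for j in np.flatnonzero(detected)
                ]
                runs.append(
                    SampleRun(
                        sample_id=f"{rat_id}_W{week}",
                        rat_id=rat_id,
                        group=group,
                        week=week,
                        features=feats,
                    )
                )
    return runs, truth


def evaluate_recovery(
    selected_by_week: Mapping[int, set[int]], truth: GroundTruth
) -> RecoveryMetrics:
    """Score per-week selections (in true peptide ids) against the truth.

    Sensitivity is computed over the union of all weekly selections; false
    selections are counted per week.
    """
    union: set[int] = set()
    false_by_week: dict[int, int] = {}
    for week, sel in selected_by_week.items():
        sel = set(sel)
        union |= sel
        false_by_week[week] = len(sel - truth.planted_ids)
    recovered = union & truth.planted_ids
    return RecoveryMetrics(
        sensitivity=len(recovered) / len(truth.planted_ids),
        false_by_week=false_by_week,
        false_total=sum(false_by_week.values()),
        recovered=recovered,
    )


# ---------------------------------------------------------------------
# Reconstruction of an abundance matrix from a published-style panel table
# ---------------------------------------------------------------------

_N_CANDIDATES = {"N": (12, 11), "HA": (6, 5), "HL": (6, 5)}


def _infer_denominator(freqs: Sequence[float], candidates: Sequence[int]) -> int:
    for n in candidates:
        if all(
            any(abs(round(100.0 * k / n, 1) - f) < 0.05 for k in range(n + 1))
            for f in freqs
        ):
            return n
    raise ValueError(f"no candidate denominator fits frequencies {list(freqs)}")


def matrix_from_panel_table(panel: pd.DataFrame) -> AbundanceMatrix:
    """Build a synthetic abundance matrix reproducing a printed panel.

    ``panel`` holds one row per (week, peptide) with printed group means
    and detection frequencies (columns week, peptide_id, mass_da, mt_min,
    mean_N, freq_N, mean_HA, freq_HA, mean_HL, freq_HL).  For each
    group-week the sample count is inferred from the printed frequencies,
    and detected samples are given equal abundances so that the group mean
    and frequency of every peptide reproduce the printed values.  The
    result is a synthetic stand-in for the unavailable raw data, faithful
    only in the summaries the report prints.
    """
    weeks = sorted(panel["week"].unique())
    pep_meta = panel.drop_duplicates("peptide_id").set_index("peptide_id")
    pep_ids = sorted(pep_meta.index)

    # infer per (supergroup, week) denominators
    denom: dict[tuple[str, int], int] = {}
    for week in weeks:
        sub = panel[panel["week"] == week]
        for g in SUPER:
            denom[(g, week)] = _infer_denominator(
                sub[f"freq_{g}"].tolist(), _N_CANDIDATES[g]
            )

    # sample sheet: N rats split into NA/NL halves for group-label realism
    rows = []
    for week in weeks:
        for g in SUPER:
            n = denom[(g, week)]
            for i in range(n):
                if g == "N":
                    raw_group = "NA" if i < 6 else "NL"
                    rat = f"N{i + 1:02d}"
                else:
                    raw_group = g
                    rat = f"{g}{i + 1:02d}"
                rows.append(
                    {
                        "sample_id": f"{rat}_W{week}",
                        "rat_id": rat,
                        "group": raw_group,
                        "week": week,
                    }
                )
    samples = pd.DataFrame(rows)

    values = np.zeros((len(samples), len(pep_ids)))
    col_of = {pid: j for j, pid in enumerate(pep_ids)}
    for _, prow in panel.iterrows():
        week = int(prow["week"])
        j = col_of[int(prow["peptide_id"])]
        for g in SUPER:
            n = denom[(g, week)]
            freq = float(prow[f"freq_{g}"])
            mean = float(prow[f"mean_{g}"])
            k = int(round(freq * n / 100.0))
            if k == 0:
                continue
            subgroups = {"N": ("NA", "NL"), "HA": ("HA",), "HL": ("HL",)}[g]
            mask = (
                samples["group"].isin(subgroups) & (samples["week"] == week)
            ).to_numpy()
            idx = np.flatnonzero(mask)[:k]
            values[idx, j] = mean * n / k

    peptides = [
        MasterPeptide(
            peptide_id=int(pid),
            mass_da=float(pep_meta.loc[pid, "mass_da"]),
            mt_min=float(pep_meta.loc[pid, "mt_min"]),
        )
        for pid in pep_ids
    ]
    return AbundanceMatrix(samples, peptides, values)
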