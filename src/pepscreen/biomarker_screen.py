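"""Consensus loading filter, frequency filter and panel reporting.

From the five lowest-error weekly models, a peptide is named a *potential
biomarker* when the magnitude of its loading reaches 0.15 on some
component in **every** one of the five models — a stability requirement
that discards peptides whose apparent importance depends on one particular
fit.  A selected peptide must additionally be detected in more than 30% of
the collected samples of at least one group, which removes peptides seen
too sporadically to be clinically usable.

Reporting follows the published panel layout: per (week, peptide) row the
mean relative abundance and detection frequency of groups N (= NA + NL),
HA and HL, and the signed fold changes of HA and HL versus N.  The signed
fold change is the ratio of the larger group mean to the smaller, negative
when the case group is the smaller; it is undefined ("na") whenever either
group mean is zero.  Its magnitude is therefore always >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .compile_align import AbundanceMatrix
from .splsda import SplsdaModel

__all__ = [
    "BiomarkerRecord",
    "ConsensusConfig",
    "consensus_biomarkers",
    "group_mask",
    "group_frequency",
    "mean_rel_abundance",
    "fold_change",
    "build_panel",
]

SUPERGROUPS = {"N": ("NA", "NL"), "HA": ("HA",), "HL": ("HL",)}


@dataclass(frozen=True)
class ConsensusConfig:
    """Thresholds of the biomarker screen."""

    load_threshold: float = 0.15
    min_frequency_pct: float = 30.0
    n_models: int = 5
    per_component: bool = False  # require the threshold on every component

    def __post_init__(self) -> None:
        if self.load_threshold <= 0:
            raise ValueError("load_threshold must be > 0")
        if not 0 < self.min_frequency_pct <= 100:
            raise ValueError("min_frequency_pct must be in (0, 100]")


@dataclass
class BiomarkerRecord:
    """One row of the biomarker panel report."""

    week: int
    peptide_id: int
    mass_da: float
    mt_min: float
    mean_ab_N: float
    freq_N: float
    mean_ab_HA: float
    freq_HA: float
    mean_ab_HL: float
    freq_HL: float
    fold_HA: float | None  # None renders as "na"
    fold_HL: float | None


def consensus_biomarkers(
    models: Sequence[SplsdaModel],
    cfg: ConsensusConfig = ConsensusConfig(),
) -> set:
    """Peptides whose loading reaches the threshold in every model.

    A peptide qualifies when, in each of the ``cfg.n_models`` models, the
    maximum absolute loading over components is >= ``cfg.load_threshold``
    (or on every component, with ``per_component=True``).
    """
    if len(models) != cfg.n_models:
        raise ValueError(f"expected {cfg.n_models} models, got {len(models)}")
    ref_ids = list(models[0].feature_ids)
    for m in models[1:]:
        if list(m.feature_ids) != ref_ids:
            raise ValueError("models were fitted on different peptide sets")
    reduce = np.min if cfg.per_component else np.max
    qualifies = np.ones(len(ref_ids), dtype=bool)
    for m in models:
        load = reduce(np.abs(m.x_loadings), axis=1)
        qualifies &= load >= cfg.load_threshold
    return {pid for pid, q in zip(ref_ids, qualifies) if q}


def group_mask(matrix: AbundanceMatrix, group: str, week: int) -> np.ndarray:
    subgroups = SUPERGROUPS.get(group, (group,))
    s = matrix.samples
    return (s["group"].isin(subgroups) & (s["week"] == week)).to_numpy()


def group_frequency(
    matrix: AbundanceMatrix, peptide_id: int, group: str, week: int
) -> float:
    """Percent of the group-week's collected samples detecting the peptide.

    The denominator is the number of samples actually collected for that
    group and week (collections are occasionally missing), not a nominal
    group size.
    """
    mask = group_mask(matrix, group, week)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"no samples for group {group} week {week}")
    col = matrix.peptide_ids.index(peptide_id)
    return 100.0 * float((matrix.values[mask, col] > 0).sum()) / n


def mean_rel_abundance(
    matrix: AbundanceMatrix,
    peptide_id: int,
    group: str,
    week: int,
    detected_only: bool = False,
) -> float:
    """Mean relative abundance over the group-week's samples.

    By default non-detections contribute zero to the mean; with
    ``detected_only`` the mean is taken over detected samples only.
    """
    mask = group_mask(matrix, group, week)
    if not mask.any():
        raise ValueError(f"no samples for group {group} week {week}")
    col = matrix.peptide_ids.index(peptide_id)
    vals = matrix.values[mask, col]
    if detected_only:
        vals = vals[vals > 0]
        return float(vals.mean()) if len(vals) else 0.0
    return float(vals.mean())


def fold_change(mean_case: float, mean_control: float) -> float | None:
    """Signed-ratio fold change of a case group versus control.

    ratio = case/control when case >= control, else -(control/case); the
    magnitude is always the ratio of the larger mean to the smaller, the
    sign marks the direction (negative = decrease in the case group).
    Returns None ("not applicable") when either mean is zero, and exactly
    1.0 when the means are equal.
    """
    if mean_case < 0 or mean_control < 0:
        raise ValueError("group means must be >= 0")
    if mean_case == 0 or mean_control == 0:
        return None
    if mean_case >= mean_control:
        return mean_case / mean_control
    return -(mean_control / mean_case)


def build_panel(
    weekly_selections: Mapping[int, set],
    matrix: AbundanceMatrix,
    cfg: ConsensusConfig = ConsensusConfig(),
    apply_frequency_filter: bool = True,
) -> tuple[list[BiomarkerRecord], int]:
    """Assemble the final panel from per-week selected peptide sets.

    Each selected (week, peptide) pair passing the detection-frequency
    rule (> ``cfg.min_frequency_pct`` of samples in at least one of N, HA,
    HL) becomes one report row.  Returns the rows (ordered by week, then
    peptide id) and the number of distinct peptides across weeks.
    """
    by_peptide = {p.peptide_id: p for p in matrix.peptides}
    records: list[BiomarkerRecord] = []
    unique: set = set()
    for week in sorted(weekly_selections):
        for pid in sorted(weekly_selections[week]):
            freqs = {
                g: group_frequency(matrix, pid, g, week) for g in ("N", "HA", "HL")
            }
            if apply_frequency_filter and not any(
                f > cfg.min_frequency_pct for f in freqs.values()
            ):
                continue
            means = {
                g: mean_rel_abundance(matrix, pid, g, week) for g in ("N", "HA", "HL")
            }
            pep = by_peptide[pid]
            records.append(
                BiomarkerRecord(
                    week=week,
                    peptide_id=pid,
                    mass_da=pep.mass_da,
                    mt_min=pep.mt_min,
                    mean_ab_N=means["N"],
                    freq_N=freqs["N"],
                    mean_ab_HA=means["HA"],
                    freq_HA=freqs["HA"],
                    mean_ab_HL=means["HL"],
                    freq_HL=freqs["HL"],
                    fold_HA=fold_change(means["HA"], means["N"]),
                    fold_HL=fold_change(means["HL"], means["N"]),
                )
            )
            unique.add(pid)
    return records, len(unique)
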