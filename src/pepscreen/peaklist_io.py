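"""Reading and writing of CE-MS peptide peak lists and derived tables.

A CE-MS run, after upstream peak picking and deconvolution, reduces to a
*peak list*: one row per detected polypeptide giving its molecular mass in
Daltons (valid range 0.8--30 kDa), its normalized capillary-electrophoresis
migration time in minutes, and its normalized signal intensity in ion
counts.  The normalized intensity serves as the peptide's relative
abundance in that sample; absence from the list encodes non-detection.

This module parses such peak lists from delimited text (TSV/CSV, dialect
sniffed), validates rows against the physical ranges, aggregates sets of
runs into 2-D fingerprint grids (migration time x log10 mass), and renders
the final biomarker report table.
"""

from __future__ import annotations

import csv
import io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .biomarker_screen import BiomarkerRecord

MASS_MIN_DA = 800.0
MASS_MAX_DA = 30000.0

__all__ = [
    "PeptideFeature",
    "SampleRun",
    "FingerprintGrid",
    "RowIssue",
    "PeaklistFormatError",
    "read_peaklist",
    "read_samples_table",
    "fingerprint",
    "write_fingerprint",
    "write_report",
    "read_report",
    "REPORT_COLUMNS",
]


class PeaklistFormatError(ValueError):
    """Raised when a peak-list file lacks the required columns."""


@dataclass(frozen=True)
class PeptideFeature:
    """One detected peptide in one run.

    Attributes
    ----------
    mass_da : float
        Molecular mass in Daltons; must lie in [800, 30000].
    mt_min : float
        Normalized CE migration time in minutes (> 0).
    intensity : float
        Normalized signal intensity in ion counts (>= 0); used as the
        relative abundance of the peptide in this sample.
    """

    mass_da: float
    mt_min: float
    intensity: float

    def validate(self) -> None:
        if not (MASS_MIN_DA <= self.mass_da <= MASS_MAX_DA):
            raise ValueError(
                f"mass {self.mass_da} Da outside [{MASS_MIN_DA}, {MASS_MAX_DA}]"
            )
        if not self.mt_min > 0:
            raise ValueError(f"migration time {self.mt_min} min must be > 0")
        if self.intensity < 0:
            raise ValueError(f"intensity {self.intensity} must be >= 0")


@dataclass(frozen=True)
class RowIssue:
    """One rejected or unparseable peak-list row."""

    row: int  # 1-based data-row index (header excluded)
    reason: str


@dataclass
class SampleRun:
    """All peptide features detected in one urine collection of one rat."""

    sample_id: str
    rat_id: str
    group: str  # one of NA, NL, HA, HL
    week: int  # 1..4
    features: list[PeptideFeature] = field(default_factory=list)
    issues: list[RowIssue] = field(default_factory=list, compare=False)

    GROUPS = ("NA", "NL", "HA", "HL")

    def __post_init__(self) -> None:
        if self.group not in self.GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {self.GROUPS}")
        self.week = int(self.week)


@dataclass
class FingerprintGrid:
    """Mean-intensity landscape over (migration time, log10 mass) cells.

    Mirrors the compiled urinary-peptide fingerprint display: CE migration
    time on one axis, molecular mass (kDa) on a log scale on the other, and
    mean signal intensity as cell height.
    """

    time_edges: np.ndarray  # minutes, len = n_time_bins + 1
    logmass_edges: np.ndarray  # log10(kDa), len = n_mass_bins + 1
    values: np.ndarray  # (n_time_bins, n_mass_bins), mean intensity per cell

    def __post_init__(self) -> None:
        self.time_edges = np.asarray(self.time_edges, dtype=float)
        self.logmass_edges = np.asarray(self.logmass_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        expect = (len(self.time_edges) - 1, len(self.logmass_edges) - 1)
        if self.values.shape != expect:
            raise ValueError(f"values shape {self.values.shape} != {expect}")
        if (self.values < 0).any():
            raise ValueError("fingerprint values must be >= 0")


# Column-name synonyms accepted in peak-list headers (lower-cased,
# non-alphanumerics stripped).
_MASS_NAMES = {"massda", "mass", "peptidemassda", "peptidemass", "molecularmass", "mwda"}
_TIME_NAMES = {"mtmin", "migrationtime", "cetime", "cetimemin", "time", "timemin", "mt"}
_INTENSITY_NAMES = {"intensity", "signalintensity", "abundance", "relab", "ioncounts"}


def _canon(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", name.lower())


def _find_column(columns: Sequence[str], synonyms: set[str], what: str) -> str:
    hits = [c for c in columns if _canon(c) in synonyms]
    if not hits:
        raise PeaklistFormatError(
            f"no {what} column found; got {list(columns)!r}"
        )
    return hits[0]


def _sniff_sep(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t" if "\t" in sample else ","


def read_peaklist(path: str | Path, sample_meta: dict | pd.Series) -> SampleRun:
    """Parse one delimited peak-list file into a :class:`SampleRun`.

    ``sample_meta`` must provide ``sample_id``, ``rat_id``, ``group`` and
    ``week``.  Rows with non-numeric cells or values outside the physical
    ranges (mass 800--30000 Da, time > 0, intensity >= 0) are rejected and
    reported in ``SampleRun.issues`` rather than silently dropped.
    Raises :class:`PeaklistFormatError` if a required column is missing.
    """
    meta = dict(sample_meta)
    text = Path(path).read_text()
    header_line = text.splitlines()[0] if text.strip() else ""
    if not header_line:
        raise PeaklistFormatError(f"{path}: empty file, no header")
    sep = _sniff_sep(header_line)
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str)
    mass_col = _find_column(df.columns, _MASS_NAMES, "mass")
    time_col = _find_column(df.columns, _TIME_NAMES, "migration time")
    int_col = _find_column(df.columns, _INTENSITY_NAMES, "intensity")

    run = SampleRun(
        sample_id=str(meta["sample_id"]),
        rat_id=str(meta["rat_id"]),
        group=str(meta["group"]),
        week=int(meta["week"]),
    )
    triples = df[[mass_col, time_col, int_col]].to_numpy(dtype=object)
    for i, (m, t, s) in enumerate(triples, start=1):
        try:
            feat = PeptideFeature(mass_da=float(m), mt_min=float(t), intensity=float(s))
        except (TypeError, ValueError):
            run.issues.append(RowIssue(i, f"non-numeric cell in ({m!r}, {t!r}, {s!r})"))
            continue
        try:
            feat.validate()
        except ValueError as exc:
            run.issues.append(RowIssue(i, str(exc)))
            continue
        run.features.append(feat)
    return run


def read_samples_table(path: str | Path) -> pd.DataFrame:
    """Read the sample-metadata CSV (sample_id, rat_id, group, week).

    Enforces that (rat_id, week) is unique and that each rat keeps one
    treatment group across weeks.
    """
    # keep_default_na=False: the treatment label "NA" is data, not missing
    df = pd.read_csv(
        path,
        dtype={"sample_id": str, "rat_id": str, "group": str},
        keep_default_na=False,
    )
    required = {"sample_id", "rat_id", "group", "week"}
    missing = required - set(df.columns)
    if missing:
        raise PeaklistFormatError(f"samples table missing columns {sorted(missing)}")
    df["week"] = df["week"].astype(int)
    dup = df.duplicated(subset=["rat_id", "week"])
    if dup.any():
        raise ValueError(f"duplicate (rat_id, week) rows: {df.loc[dup].to_dict('records')}")
    per_rat = df.groupby("rat_id")["group"].nunique()
    bad = per_rat[per_rat > 1]
    if len(bad):
        raise ValueError(f"rats with inconsistent group labels: {list(bad.index)}")
    return df


def fingerprint(
    runs: Sequence[SampleRun],
    n_time_bins: int,
    n_mass_bins: int,
    time_range: tuple[float, float] | None = None,
    logmass_range: tuple[float, float] | None = None,
) -> FingerprintGrid:
    """Compile runs into a mean-intensity (time, log10 mass-in-kDa) grid.

    Each cell holds the total intensity of all features of all runs falling
    in that half-open [lo, hi) cell, divided by the number of runs — i.e.
    the per-run mean with absence counting as zero.  This conserves totals:
    ``values.sum() * len(runs) == sum of all feature intensities``.
    """
    if not runs:
        raise ValueError("fingerprint requires at least one run")
    if n_time_bins <= 0 or n_mass_bins <= 0:
        raise ValueError("bin counts must be positive")

    times = np.array([f.mt_min for r in runs for f in r.features], dtype=float)
    logmass = np.array(
        [math.log10(f.mass_da / 1000.0) for r in runs for f in r.features], dtype=float
    )
    intens = np.array([f.intensity for r in runs for f in r.features], dtype=float)

    def _edges(vals: np.ndarray, rng: tuple[float, float] | None, n: int) -> np.ndarray:
        if rng is None:
            if len(vals) == 0:
                rng = (0.0, 1.0)
            else:
                lo, hi = float(vals.min()), float(vals.max())
                # pad the top so the maximum falls inside the last
                # half-open bin
                hi = np.nextafter(hi, np.inf) if hi > lo else lo + 1.0
                rng = (lo, hi)
        return np.linspace(rng[0], rng[1], n + 1)

    t_edges = _edges(times, time_range, n_time_bins)
    m_edges = _edges(logmass, logmass_range, n_mass_bins)

    values = np.zeros((n_time_bins, n_mass_bins))
    if len(times):
        ti = np.searchsorted(t_edges, times, side="right") - 1
        mi = np.searchsorted(m_edges, logmass, side="right") - 1
        ok = (ti >= 0) & (ti < n_time_bins) & (mi >= 0) & (mi < n_mass_bins)
        np.add.at(values, (ti[ok], mi[ok]), intens[ok])
    values /= len(runs)
    return FingerprintGrid(t_edges, m_edges, values)


def write_fingerprint(grid: FingerprintGrid, path: str | Path) -> None:
    """Write a fingerprint grid as a CSV matrix (rows = time bins)."""
    df = pd.DataFrame(
        grid.values,
        index=[f"{a:.3f}-{b:.3f}" for a, b in zip(grid.time_edges[:-1], grid.time_edges[1:])],
        columns=[f"{a:.3f}-{b:.3f}" for a, b in zip(grid.logmass_edges[:-1], grid.logmass_edges[1:])],
    )
    df.index.name = "mt_min_bin"
    df.to_csv(path)


REPORT_COLUMNS = [
    "week",
    "peptide_id",
    "mass_da",
    "mt_min",
    "mean_N",
    "freq_N",
    "mean_HA",
    "freq_HA",
    "mean_HL",
    "freq_HL",
    "fold_HA",
    "fold_HL",
]


def _fmt_fold(x: float | None) -> str:
    return "na" if x is None else f"{x:.2f}"


def write_report(records: Iterable["BiomarkerRecord"], path: str | Path) -> None:
    """Render biomarker records as a delimited report.

    Columns follow the published panel layout; group means, frequencies,
    masses and times are printed to 1 decimal, fold changes to 2 decimals,
    and an undefined fold change (a zero group mean on either side) is
    printed as ``na``.
    """
    rows = []
    for r in records:
        rows.append(
            {
                "week": r.week,
                "peptide_id": r.peptide_id,
                "mass_da": f"{r.mass_da:.1f}",
                "mt_min": f"{r.mt_min:.1f}",
                "mean_N": f"{r.mean_ab_N:.1f}",
                "freq_N": f"{r.freq_N:.1f}",
                "mean_HA": f"{r.mean_ab_HA:.1f}",
                "freq_HA": f"{r.freq_HA:.1f}",
                "mean_HL": f"{r.mean_ab_HL:.1f}",
                "freq_HL": f"{r.freq_HL:.1f}",
                "fold_HA": _fmt_fold(r.fold_HA),
                "fold_HL": _fmt_fold(r.fold_HL),
            }
        )
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, index=False)


def read_report(path: str | Path) -> list["BiomarkerRecord"]:
    """Read back a report written by :func:`write_report`."""
    from .biomarker_screen import BiomarkerRecord

    df = pd.read_csv(path, dtype={"fold_HA": str, "fold_HL": str})
    out = []
    for _, row in df.iterrows():
        def fold(cell: str) -> float | None:
            return None if str(cell).strip() == "na" else float(cell)

        out.append(
            BiomarkerRecord(
                week=int(row["week"]),
                peptide_id=int(row["peptide_id"]),
                mass_da=float(row["mass_da"]),
                mt_min=float(row["mt_min"]),
                mean_ab_N=float(row["mean_N"]),
                freq_N=float(row["freq_N"]),
                mean_ab_HA=float(row["mean_HA"]),
                freq_HA=float(row["freq_HA"]),
                mean_ab_HL=float(row["mean_HL"]),
                freq_HL=float(row["freq_HL"]),
                fold_HA=fold(row["fold_HA"]),
                fold_HL=fold(row["fold_HL"]),
            )
        )
    return out
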