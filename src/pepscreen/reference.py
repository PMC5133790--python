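"""Access to the reference discriminant-peptide panel shipped with the package.

The packaged table transcribes the published 61-row biomarker panel of the
four-week rat steatosis study: per (week, peptide) the consensus mass and
CE migration time, the mean relative abundance and detection frequency of
groups N, HA and HL, and the printed signed fold changes (``na`` marking
an undefined fold change where a group mean is zero).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_reference_panel() -> pd.DataFrame:
    """The reference panel with fold-change columns as nullable floats.

    ``na`` cells become ``NaN`` in ``fold_HA``/``fold_HL``; a parallel
    boolean pair ``fold_HA_defined``/``fold_HL_defined`` is added.
    """
    with resources.files("pepscreen.data").joinpath("reference_panel.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"fold_HA": str, "fold_HL": str})
    for col in ("fold_HA", "fold_HL"):
        defined = df[col].str.strip() != "na"
        df[f"{col}_defined"] = defined
        df[col] = pd.to_numeric(df[col].where(defined), errors="coerce")
    return df
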