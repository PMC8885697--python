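"""Mutation-by-property tables of receptor variant measurements.

A property table holds six functional measurements per GluN2A variant,
compiled from heterologous-expression experiments: glutamate and glycine
EC50 (agonist potency, in oocytes), deactivation time constant, whole-cell
current density, channel open probability, and relative cell-surface level.
A wildtype (WT) reference row is mandatory; individual mutant cells may be
missing.  All observed values must be strictly positive, since downstream
normalisation is a log-ratio against WT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PROPERTY_COLUMNS = [
    "glu_ec50_uM",
    "gly_ec50_uM",
    "deact_tau_ms",
    "current_density_pA_pF",
    "open_prob",
    "surface_rel",
]

#: columns where smaller raw values mean gain of function (EC50 -> potency)
INVERTED_COLUMNS = ["glu_ec50_uM", "gly_ec50_uM"]

WT_LABEL = "WT"


@dataclass
class PropertyTable:
    """Mutation x property matrix with WT reference and missing-value mask.

    ``data`` is indexed by mutation label and has exactly the six property
    columns; missing measurements are NaN.  ``wt`` is the complete WT
    reference row (not part of ``data``).
    """

    data: pd.DataFrame
    wt: pd.Series

    def __post_init__(self):
        if list(self.data.columns) != PROPERTY_COLUMNS:
            raise ValueError(f"expected columns {PROPERTY_COLUMNS}, got {list(self.data.columns)}")
        if self.wt.isna().any():
            raise ValueError("WT reference row must have no missing values")
        bad = self._nonpositive_cells()
        if bad:
            row, col = bad[0]
            raise ValueError(f"non-positive value at mutation {row!r}, column {col!r}")
        if (self.wt <= 0).any():
            raise ValueError("WT reference values must be strictly positive")

    def _nonpositive_cells(self):
        vals = self.data.to_numpy(dtype=float)
        rows, cols = np.where(~np.isnan(vals) & (vals <= 0))
        return [(self.data.index[i], self.data.columns[j]) for i, j in zip(rows, cols)]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    @property
    def mutations(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def copy(self) -> "PropertyTable":
        return PropertyTable(self.data.copy(), self.wt.copy())


def read_property_table(path) -> PropertyTable:
    """Read a property CSV (one row per mutation plus a mandatory "WT" row).

    Empty cells are treated as missing measurements.  Raises on missing WT
    row, unknown/missing columns, or non-positive observed values.
    """
    df = pd.read_csv(path, index_col="mutation")
    missing_cols = [c for c in PROPERTY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"property CSV missing columns: {missing_cols}")
    df = df[PROPERTY_COLUMNS].astype(float)
    if WT_LABEL not in df.index:
        raise ValueError('property CSV must contain a "WT" reference row')
    wt = df.loc[WT_LABEL]
    data = df.drop(index=WT_LABEL)
    return PropertyTable(data, wt)


def write_property_table(tbl: PropertyTable, path) -> None:
    out = pd.concat([tbl.wt.to_frame().T.set_axis([WT_LABEL]), tbl.data])
    out.index.name = "mutation"
    out.to_csv(path)


def approximate_potency_from_proxy(
    potency_ref: float,
    open_freq_ref: float,
    surface_ref: float,
    open_freq_target: float,
    surface_target: float,
) -> float:
    """Approximate a missing agonist potency from single-channel proxies.

    Scales a reference variant's potency by the ratio of surface-corrected
    single-channel opening frequencies:
    ``potency_ref * (f_target / s_target) / (f_ref / s_ref)``.  This mirrors
    the practice of estimating potency for a variant with no dose-response
    data from a related variant with matched single-channel recordings.
    """
    args = (potency_ref, open_freq_ref, surface_ref, open_freq_target, surface_target)
    if any(a <= 0 for a in args):
        raise ValueError("all proxy inputs must be strictly positive")
    return potency_ref * (open_freq_target / surface_target) / (open_freq_ref / surface_ref)
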