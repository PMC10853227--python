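"""The five analysis feature sets built from a paired feature table.

Given features :math:`F_{PET_0}`, :math:`F_{PET_1}` and acquisition times
:math:`t_{PET_0} < t_{PET_1}`:

* STP (single time point): :math:`F_{PET_1}`
* delta-absolute: :math:`F_{PET_1} - F_{PET_0}`
* delta-relative: :math:`(F_{PET_1} - F_{PET_0}) / F_{PET_0}`
* weighted delta-absolute: delta-absolute divided by the scan gap
* weighted delta-relative: delta-relative divided by the scan gap

Each kind may be taken over radiomics columns or over the reserved
``conv_``-prefixed conventional columns.
"""

from __future__ import annotations

import enum
import warnings

import numpy as np
import pandas as pd

from .cohort import CONVENTIONAL_PREFIX, PairedFeatureTable

__all__ = ["FeatureSetKind", "build_feature_set", "split_sources", "FEATURE_SET_LABELS"]


class FeatureSetKind(str, enum.Enum):
    STP = "stp"
    DELTA_ABS = "delta_abs"
    DELTA_REL = "delta_rel"
    WDELTA_ABS = "wdelta_abs"
    WDELTA_REL = "wdelta_rel"

    @property
    def is_weighted(self) -> bool:
        return self in (FeatureSetKind.WDELTA_ABS, FeatureSetKind.WDELTA_REL)

    @property
    def is_delta(self) -> bool:
        return self is not FeatureSetKind.STP


#: short labels in the field's notation, for summaries and plots
FEATURE_SET_LABELS = {
    FeatureSetKind.STP: "STP",
    FeatureSetKind.DELTA_ABS: "ΔA",
    FeatureSetKind.DELTA_REL: "ΔR",
    FeatureSetKind.WDELTA_ABS: "WΔA",
    FeatureSetKind.WDELTA_REL: "WΔR",
}

_REL_EPS = 1e-12


def build_feature_set(paired: PairedFeatureTable, kind: FeatureSetKind | str) -> pd.DataFrame:
    """Construct one analysis table from the paired scans.

    Relative kinds drop (cohort-wide, with a warning) any feature whose
    baseline value is zero for some patient, since a per-patient infinity
    would corrupt downstream Z-scoring.
    """
    kind = FeatureSetKind(kind)
    if kind is FeatureSetKind.STP:
        return paired.pet1.copy()
    delta = paired.pet1 - paired.pet0
    if kind in (FeatureSetKind.DELTA_REL, FeatureSetKind.WDELTA_REL):
        bad = (paired.pet0.abs() < _REL_EPS).any(axis=0)
        if bad.any():
            warnings.warn(
                "dropping features with a zero baseline under a relative delta: "
                f"{list(paired.pet0.columns[bad])}",
                stacklevel=2,
            )
        keep = paired.pet0.columns[~bad]
        delta = delta[keep] / paired.pet0[keep]
    if kind.is_weighted:
        gaps = paired.gap_months.to_numpy(float)
        if np.any(gaps <= 0):
            raise ValueError("weighted deltas need a positive scan gap for every patient")
        delta = delta.div(paired.gap_months, axis=0)
    return delta


def split_sources(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a feature table into (radiomics, conventional) by the ``conv_`` prefix."""
    is_conv = table.columns.str.startswith(CONVENTIONAL_PREFIX)
    return table.loc[:, ~is_conv], table.loc[:, is_conv]
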