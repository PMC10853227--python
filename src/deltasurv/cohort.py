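"""Core data containers: paired feature tables and survival outcomes.

The package works on tidy pandas objects throughout:

* a *feature table* is a ``DataFrame`` indexed by patient id with one named
  feature per column;
* *outcomes* are a ``DataFrame`` with columns ``pfs_months`` (float, months
  from treatment start) and ``event`` (1 = progression observed,
  0 = censored), indexed by patient id;
* a :class:`PairedFeatureTable` bundles the two scan time points together
  with per-patient acquisition times, which the weighted delta feature sets
  need.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sksurv.util import Surv

CONVENTIONAL_PREFIX = "conv_"

#: Reserved column names for the nine conventional (region-level) features.
CONVENTIONAL_FEATURES = (
    "conv_TBR_mean",
    "conv_TBR_max",
    "conv_TBR_peak",
    "conv_TSR_mean",
    "conv_TSR_max",
    "conv_TSR_peak",
    "conv_MTV",
    "conv_TTP",
    "conv_slope",
)


def validate_outcomes(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Check an outcomes frame and return it with canonical dtypes."""
    missing = {"pfs_months", "event"} - set(outcomes.columns)
    if missing:
        raise ValueError(f"outcomes frame lacks columns: {sorted(missing)}")
    out = outcomes.copy()
    out["pfs_months"] = out["pfs_months"].astype(float)
    out["event"] = out["event"].astype(int)
    if (out["pfs_months"] <= 0).any():
        raise ValueError("progression-free survival times must be positive")
    if not out["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 (censored) or 1 (progressed)")
    return out


def as_structured(outcomes: pd.DataFrame) -> np.ndarray:
    """Outcomes frame -> scikit-survival structured array (event, time)."""
    out = validate_outcomes(outcomes)
    return Surv.from_arrays(event=out["event"].to_numpy(bool), time=out["pfs_months"].to_numpy(float))


@dataclass
class PairedFeatureTable:
    """Per-patient features at two PET time points plus acquisition times.

    Attributes
    ----------
    pet0, pet1 : DataFrame
        Feature matrices at the first and second scan. Identical index
        (patient ids) and identical columns (feature names).
    t0, t1 : Series
        Acquisition times in months from treatment start, same index.
    """

    pet0: pd.DataFrame
    pet1: pd.DataFrame
    t0: pd.Series
    t1: pd.Series

    def __post_init__(self) -> None:
        if not self.pet0.columns.equals(self.pet1.columns):
            raise ValueError("PET0 and PET1 tables must share feature columns")
        for other, name in ((self.pet1, "pet1"), (self.t0, "t0"), (self.t1, "t1")):
            if not self.pet0.index.equals(other.index):
                raise ValueError(f"patient ordering of {name} differs from pet0")
        gaps = self.t1.to_numpy(float) - self.t0.to_numpy(float)
        if (gaps <= 0).any():
            raise ValueError("every second scan must postdate the first (t1 > t0)")

    @property
    def patients(self) -> pd.Index:
        return self.pet0.index

    @property
    def features(self) -> pd.Index:
        return self.pet0.columns

    @property
    def gap_months(self) -> pd.Series:
        return self.t1 - self.t0

    def subset_features(self, names) -> "PairedFeatureTable":
        names = list(names)
        unknown = set(names) - set(self.features)
        if unknown:
            raise KeyError(f"features absent from the paired table: {sorted(unknown)}")
        return PairedFeatureTable(self.pet0[names], self.pet1[names], self.t0, self.t1)

    # -- plain-text round trip -------------------------------------------------

    def to_csv_dir(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.pet0.rename_axis("patient_id").to_csv(directory / "features_pet0.csv")
        self.pet1.rename_axis("patient_id").to_csv(directory / "features_pet1.csv")
        dates = pd.DataFrame({"t0_months": self.t0, "t1_months": self.t1})
        dates.rename_axis("patient_id").to_csv(directory / "dates.csv")

    @classmethod
    def from_csv_dir(cls, directory) -> "PairedFeatureTable":
        directory = Path(directory)
        pet0 = pd.read_csv(directory / "features_pet0.csv", index_col="patient_id")
        pet1 = pd.read_csv(directory / "features_pet1.csv", index_col="patient_id")
        dates = pd.read_csv(directory / "dates.csv", index_col="patient_id")
        return cls(pet0, pet1, dates["t0_months"], dates["t1_months"])


def write_outcomes(outcomes: pd.DataFrame, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    validate_outcomes(outcomes).rename_axis("patient_id").to_csv(directory / "outcomes.csv")


def read_outcomes(directory) -> pd.DataFrame:
    return validate_outcomes(pd.read_csv(Path(directory) / "outcomes.csv", index_col="patient_id"))
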