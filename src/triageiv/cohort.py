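"""Patient-level cohort container.

A :class:`Cohort` wraps a :class:`pandas.DataFrame` with fixed canonical
columns (``patient_id``, ``treatment``, ``outcome``), a set of named numeric
covariates, zero or more candidate-instrument columns, and an optional
cluster identifier used for cluster bootstrap resampling.  Treatment is coded
1 for ICU admission and outcome 1 for in-hospital death.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import CohortError

PATIENT_ID = "patient_id"
TREATMENT = "treatment"
OUTCOME = "outcome"


@dataclass
class Cohort:
    data: pd.DataFrame
    covariate_names: tuple[str, ...]
    instrument_names: tuple[str, ...] = ()
    cluster_name: str | None = None

    # -- accessors ---------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def patient_id(self) -> np.ndarray:
        return self.data[PATIENT_ID].to_numpy()

    @property
    def treatment(self) -> np.ndarray:
        return self.data[TREATMENT].to_numpy(dtype=float)

    @property
    def outcome(self) -> np.ndarray:
        return self.data[OUTCOME].to_numpy(dtype=float)

    @property
    def n_treated(self) -> int:
        return int(self.data[TREATMENT].sum())

    def covariates(self, names: tuple[str, ...] | list[str] | None = None) -> pd.DataFrame:
        names = list(self.covariate_names if names is None else names)
        missing = [c for c in names if c not in self.data.columns]
        if missing:
            raise CohortError(f"covariates not present in cohort: {missing}")
        return self.data[names]

    def column(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise CohortError(f"column {name!r} not present in cohort")
        return self.data[name].to_numpy()

    # -- structural checks -------------------------------------------------
    def validate(self) -> "Cohort":
        df = self.data
        for col in (PATIENT_ID, TREATMENT, OUTCOME):
            if col not in df.columns:
                raise CohortError(f"required column {col!r} missing")
        if df[PATIENT_ID].duplicated().any():
            dup = df[PATIENT_ID][df[PATIENT_ID].duplicated()].iloc[0]
            raise CohortError(f"duplicate patient_id {dup!r}")
        for col in (TREATMENT, OUTCOME):
            vals = df[col]
            if vals.isna().any():
                row = int(np.flatnonzero(vals.isna().to_numpy())[0])
                raise CohortError(f"missing value in {col!r} at row {row}")
            bad = ~vals.isin([0, 1])
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise CohortError(
                    f"non-binary value {vals.iloc[row]!r} in {col!r} at row {row}"
                )
        for name in self.covariate_names:
            if name not in df.columns:
                raise CohortError(f"declared covariate {name!r} missing from table")
            if df[name].isna().any():
                raise CohortError(f"missing values in covariate {name!r}")
        if len(set(self.covariate_names)) != len(self.covariate_names):
            raise CohortError("covariate names are not unique")
        for name in self.instrument_names:
            if name not in df.columns:
                raise CohortError(f"declared instrument candidate {name!r} missing")
        if self.cluster_name is not None and self.cluster_name not in df.columns:
            raise CohortError(f"cluster column {self.cluster_name!r} missing")
        return self

    # -- resampling helpers (no re-validation: used in tight bootstrap loops)
    def take(self, indices: np.ndarray) -> "Cohort":
        df = self.data.iloc[indices].reset_index(drop=True)
        # resampled rows duplicate ids; renumber so pair bookkeeping stays unique
        df = df.assign(**{PATIENT_ID: np.arange(len(df))})
        return replace(self, data=df)

    def subset_ids(self, ids) -> "Cohort":
        mask = self.data[PATIENT_ID].isin(list(ids))
        return replace(self, data=self.data[mask].reset_index(drop=True))
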