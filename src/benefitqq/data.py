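"""Long-format longitudinal clinical-trial data.

One row per patient-visit: a patient identifier, a phase label
(``baseline`` before treatment initiation, ``treatment`` afterwards), the
time on treatment in the study's time unit (weeks in the motivating
trials; 0 for baseline rows), a continuous response, and zero or more
binary patient-level covariates that are constant within patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LongitudinalDataset", "read_long_csv"]

PHASES = ("baseline", "treatment")
REQUIRED_COLUMNS = ("patient_id", "phase", "time", "response")


@dataclass(frozen=True)
class LongitudinalDataset:
    """Validated long-format repeated-measures dataset.

    Parameters
    ----------
    table
        One row per visit with columns ``patient_id``, ``phase``, ``time``,
        ``response`` plus the binary covariate columns.
    covariate_columns
        Names of the patient-level binary covariate columns (may be empty).
    allow_zero_treatment_time
        Permit on-treatment rows recorded at time 0 (e.g. a measurement
        taken immediately at treatment initiation).  Off by default.
    """

    table: pd.DataFrame
    covariate_columns: tuple[str, ...] = ()
    allow_zero_treatment_time: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariate_columns", tuple(self.covariate_columns))
        df = self.table
        if len(df) == 0:
            raise ValueError("dataset is empty")
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        missing_cov = [c for c in self.covariate_columns if c not in df.columns]
        if missing_cov:
            raise ValueError(f"missing covariate columns: {missing_cov}")

        df = df.reset_index(drop=True)
        object.__setattr__(self, "table", df)

        bad = df.index[~df["phase"].isin(PHASES)]
        if len(bad):
            raise ValueError(
                f"row {bad[0]}: phase {df.loc[bad[0], 'phase']!r} not in {PHASES}"
            )
        times = pd.to_numeric(df["time"], errors="coerce")
        bad = df.index[times.isna() | (times < 0)]
        if len(bad):
            raise ValueError(f"row {bad[0]}: time must be a non-negative number")
        resp = pd.to_numeric(df["response"], errors="coerce")
        bad = df.index[resp.isna() | ~np.isfinite(resp)]
        if len(bad):
            raise ValueError(f"row {bad[0]}: response must be a finite number")

        base = df["phase"] == "baseline"
        bad = df.index[base & (times != 0)]
        if len(bad):
            raise ValueError(f"row {bad[0]}: baseline rows must have time = 0")
        if not self.allow_zero_treatment_time:
            bad = df.index[~base & (times == 0)]
            if len(bad):
                raise ValueError(
                    f"row {bad[0]}: treatment row has time = 0 "
                    "(pass allow_zero_treatment_time=True if intended)"
                )

        for col in self.covariate_columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[~vals.isin([0, 1])]
            if len(bad):
                raise ValueError(
                    f"row {bad[0]}: covariate {col!r} value "
                    f"{df.loc[bad[0], col]!r} is not binary (0/1)"
                )

        for pid, sub in df.groupby("patient_id", sort=False):
            phases = set(sub["phase"])
            if "baseline" not in phases:
                raise ValueError(f"patient {pid!r} has no baseline row")
            if "treatment" not in phases:
                raise ValueError(f"patient {pid!r} has no treatment row")
            for col in self.covariate_columns:
                if sub[col].nunique() > 1:
                    raise ValueError(
                        f"covariate {col!r} varies within patient {pid!r}"
                    )

    # -- accessors -----------------------------------------------------

    @property
    def patient_ids(self) -> np.ndarray:
        """Patient identifiers in order of first appearance."""
        return self.table["patient_id"].unique()

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def max_treatment_time(self) -> float:
        mask = self.table["phase"] == "treatment"
        return float(self.table.loc[mask, "time"].max())

    def patient_covariates(self) -> pd.DataFrame:
        """One row per patient (indexed by patient id) of covariate values."""
        cols = list(self.covariate_columns)
        first = self.table.groupby("patient_id", sort=False).first()
        out = first[cols].astype(float) if cols else first[[]]
        return out.loc[self.patient_ids]

    def with_response(self, response: np.ndarray) -> "LongitudinalDataset":
        """Copy of the dataset with the response column replaced (row order kept)."""
        df = self.table.copy()
        df["response"] = np.asarray(response, dtype=float)
        return LongitudinalDataset(
            df, self.covariate_columns, self.allow_zero_treatment_time
        )

    # -- I/O -----------------------------------------------------------

    def to_csv(self, path) -> None:
        cols = list(REQUIRED_COLUMNS) + list(self.covariate_columns)
        self.table[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path,
        covariate_columns: tuple[str, ...] | None = None,
        allow_zero_treatment_time: bool = False,
    ) -> "LongitudinalDataset":
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError as exc:
            raise ValueError(f"{path}: file is empty") from exc
        if covariate_columns is None:
            covariate_columns = tuple(
                c for c in df.columns if c not in REQUIRED_COLUMNS
            )
        return cls(df, covariate_columns, allow_zero_treatment_time)


def read_long_csv(path, covariate_columns=None, **kwargs) -> LongitudinalDataset:
    """Read a long-format CSV (``patient_id,phase,time,response,<covariates...>``).

    Covariate columns default to every column beyond the four required ones.
    """
    return LongitudinalDataset.from_csv(path, covariate_columns, **kwargs)
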