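"""Age-indexed annual event-probability tables.

An :class:`AgeRateTable` maps whole-number ages to annual per-person
probabilities (incidence, all-cause mortality, utility norms).  Ages are
contiguous with step 1; an age-``a`` row covers the interval [a, a+1).
Tables serialize as two-column CSV (``age,probability``) with a header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, TableCoverageError, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AgeRateTable:
    ages: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "values", values)
        if ages.ndim != 1 or values.ndim != 1 or len(ages) != len(values):
            raise ValidationError("ages and values must be 1-D and equally long")
        if len(ages) == 0:
            raise ValidationError("table must contain at least one age")
        if not np.all(np.diff(ages) == 1):
            raise ValidationError("ages must be contiguous ascending with step 1")
        if np.any(values < 0) or np.any(values > 1):
            raise ValidationError("annual probabilities must lie in [0, 1]")

    # -- access ---------------------------------------------------------

    @property
    def start(self) -> int:
        return int(self.ages[0])

    @property
    def end(self) -> int:
        """One past the last covered age (closed-open coverage)."""
        return int(self.ages[-1]) + 1

    def covers(self, start_age: int, end_age: int) -> bool:
        return self.start <= start_age and end_age <= self.end

    def require(self, start_age: int, end_age: int) -> None:
        if not self.covers(start_age, end_age):
            raise TableCoverageError(
                f"table covers [{self.start}, {self.end}) but "
                f"[{start_age}, {end_age}) was requested"
            )

    def value_at(self, age: int) -> float:
        self.require(age, age + 1)
        return float(self.values[age - self.start])

    def window(self, start_age: int, end_age: int) -> np.ndarray:
        """Values for ages start_age..end_age-1 as a vector."""
        if end_age <= start_age:
            raise DomainError("end_age must exceed start_age")
        self.require(start_age, end_age)
        lo = start_age - self.start
        return self.values[lo : lo + (end_age - start_age)].copy()

    # -- transforms -----------------------------------------------------

    def scaled(self, factor: float, warn_on_clamp: bool = True) -> "AgeRateTable":
        """Multiply every annual probability by ``factor``, clamping at 1."""
        if factor < 0:
            raise DomainError("scaling factor must be non-negative")
        raw = self.values * factor
        if np.any(raw > 1.0):
            if warn_on_clamp:
                n = int(np.sum(raw > 1.0))
                log.warning("scaled probabilities clamped to 1 at %d age(s)", n)
            raw = np.minimum(raw, 1.0)
        return AgeRateTable(self.ages.copy(), raw)

    def with_values(self, values: np.ndarray) -> "AgeRateTable":
        return AgeRateTable(self.ages.copy(), np.asarray(values, dtype=float))

    # -- equality and I/O ----------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AgeRateTable):
            return NotImplemented
        return bool(
            np.array_equal(self.ages, other.ages)
            and np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:  # frozen dataclass would otherwise derive one
        return hash((self.ages.tobytes(), self.values.tobytes()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "probability": self.values})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "AgeRateTable":
        df = pd.read_csv(path, float_precision="round_trip")
        expected = ["age", "probability"]
        if list(df.columns) != expected:
            raise ValidationError(
                f"{path}: expected columns {expected}, found {list(df.columns)}"
            )
        return cls(df["age"].to_numpy(), df["probability"].to_numpy())
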