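"""Monthly binomial series container.

A :class:`MonthlySeries` holds, for each calendar month of a study window,
an at-risk denominator and an outcome numerator (initiations or cessations),
optionally broken down by a stratum label.  It is the single interchange
object between the simulator, the cohort engine and the segmented
regression model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["MonthlySeries"]

_REQUIRED = ["year", "month", "denominator", "numerator"]


@dataclass
class MonthlySeries:
    """Per-calendar-month counts of an outcome among an at-risk cohort.

    Parameters
    ----------
    data : pandas.DataFrame
        Columns ``year``, ``month`` (1-12), ``denominator``, ``numerator``
        and optionally ``stratum``.  Months must be contiguous within each
        stratum and identical across strata.
    outcome : str
        ``"initiation"``, ``"cessation"`` or a free-text label.
    prevention : str or None
        ``"primary"``, ``"secondary"`` or ``None`` when not applicable.
    grace_days : int or None
        Grace window used to define the outcome, recorded as metadata.
    """

    data: pd.DataFrame
    outcome: str = "outcome"
    prevention: str | None = None
    grace_days: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"MonthlySeries missing columns: {missing}")
        df = self.data.reset_index(drop=True).copy()
        for c in ("year", "month", "denominator", "numerator"):
            df[c] = df[c].astype(np.int64)
        if (df["numerator"] > df["denominator"]).any():
            raise ValueError("numerator exceeds denominator")
        if (df["numerator"] < 0).any() or (df["denominator"] < 0).any():
            raise ValueError("negative counts")
        if ((df["month"] < 1) | (df["month"] > 12)).any():
            raise ValueError("calendar month outside 1-12")
        for _, g in df.groupby("stratum") if "stratum" in df else [(None, df)]:
            idx = g["year"].to_numpy() * 12 + (g["month"].to_numpy() - 1)
            if len(idx) > 1 and not np.array_equal(np.diff(np.sort(idx)), np.ones(len(idx) - 1)):
                raise ValueError("months not contiguous")
        self.data = df

    # ------------------------------------------------------------------
    @property
    def stratified(self) -> bool:
        return "stratum" in self.data.columns

    @property
    def n_months(self) -> int:
        if self.stratified:
            return self.data.groupby(["year", "month"]).ngroups
        return len(self.data)

    def month_index(self) -> np.ndarray:
        """0-based month index from the first month of the series."""
        df = self.totals().data if self.stratified else self.data
        idx = df["year"].to_numpy() * 12 + (df["month"].to_numpy() - 1)
        return idx - idx.min()

    def proportions(self) -> np.ndarray:
        df = self.data
        return df["numerator"].to_numpy() / df["denominator"].to_numpy()

    def totals(self) -> "MonthlySeries":
        """Collapse strata, summing counts month by month."""
        if not self.stratified:
            return self
        agg = (
            self.data.groupby(["year", "month"], as_index=False)[["denominator", "numerator"]]
            .sum()
            .sort_values(["year", "month"])
            .reset_index(drop=True)
        )
        return replace(self, data=agg)

    def strata(self) -> list:
        if not self.stratified:
            return []
        return sorted(self.data["stratum"].unique().tolist())

    def select_stratum(self, label) -> "MonthlySeries":
        if not self.stratified:
            raise ValueError("series is not stratified")
        sub = self.data[self.data["stratum"] == label].drop(columns="stratum")
        if sub.empty:
            raise KeyError(f"unknown stratum {label!r}")
        return replace(self, data=sub.reset_index(drop=True))

    def month_of(self, year: int, month: int) -> int:
        """Index of a calendar month within the series."""
        df = self.totals().data if self.stratified else self.data
        first = df["year"].iloc[0] * 12 + (df["month"].iloc[0] - 1)
        return year * 12 + (month - 1) - first

    # ------------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **meta) -> "MonthlySeries":
        df = pd.read_csv(path)
        return cls(df, **meta)

    @classmethod
    def from_arrays(
        cls,
        numerators: Iterable[int],
        denominators: Iterable[int],
        start_year: int = 2011,
        start_month: int = 1,
        **meta,
    ) -> "MonthlySeries":
        num = np.asarray(list(numerators), dtype=np.int64)
        den = np.asarray(list(denominators), dtype=np.int64)
        if den.ndim == 0 or len(den) == 1:
            den = np.full(len(num), int(den))
        t = np.arange(len(num))
        months0 = (start_month - 1) + t
        df = pd.DataFrame(
            {
                "year": start_year + months0 // 12,
                "month": months0 % 12 + 1,
                "denominator": den,
                "numerator": num,
            }
        )
        return cls(df, **meta)
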