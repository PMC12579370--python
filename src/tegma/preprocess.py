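"""Study exclusion rules and cohort summaries.

Two rules, applied in a fixed order so the per-rule accounting is
reproducible: records with a missing required field are removed first, then
records whose CRT-R exceeds the outlier threshold (5.5 min, five times the
upper limit of normal). A record that is both missing and implausible is
attributed to missingness.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from .errors import ConfigurationError
from .reference import CRT_R_MAX
from .simulate import CHANNEL_COLUMNS, PairedDataset

__all__ = ["ExclusionReport", "ChannelSummary",
           "apply_exclusions", "summarize_cohort"]


@dataclass(frozen=True)
class ExclusionReport:
    """Per-rule exclusion counts; the identity
    ``n_final = n_initial - n_missing_excluded - n_outlier_excluded``
    always holds."""

    n_initial: int
    n_missing_excluded: int
    n_outlier_excluded: int
    n_final: int
    max_crt_r: float

    def __post_init__(self) -> None:
        counts = (self.n_initial, self.n_missing_excluded,
                  self.n_outlier_excluded, self.n_final)
        if any(c < 0 for c in counts):
            raise ValueError("exclusion counts must be non-negative")
        if self.n_final != (self.n_initial - self.n_missing_excluded
                            - self.n_outlier_excluded):
            raise ValueError("exclusion counts do not conserve records")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ChannelSummary:
    """Five-number-style summary of one channel's non-missing values."""

    n: int
    median: float | None
    q1: float | None
    q3: float | None
    min: float | None
    max: float | None

    @property
    def available(self) -> bool:
        return self.n > 0

    def to_dict(self) -> dict:
        return asdict(self)


def apply_exclusions(dataset: PairedDataset, max_crt_r: float = CRT_R_MAX,
                     required: tuple[str, ...] | None = None,
                     ) -> tuple[PairedDataset, ExclusionReport]:
    """Drop records with missing required fields, then implausible CRT-R.

    ``required`` defaults to all six channels (listwise completeness, the
    convention behind the study's exclusion accounting); pass the two
    columns of interest for a pairwise-complete analysis set. CRT-R is
    always required since it drives the outlier rule. The CRT-R comparison
    is strict: a record exactly at ``max_crt_r`` survives.
    """
    if not max_crt_r > 0:
        raise ConfigurationError("max_crt_r must be positive")
    cols = list(CHANNEL_COLUMNS) if required is None else list(required)
    if "crt_r_min" not in cols:
        cols = ["crt_r_min", *cols]
    unknown = [c for c in cols if c not in CHANNEL_COLUMNS]
    if unknown:
        raise ConfigurationError(f"unknown required column(s): {unknown}")

    df = dataset.df
    missing_mask = df[cols].isna().any(axis=1).to_numpy()
    outlier_mask = ~missing_mask & (
        df["crt_r_min"].to_numpy() > max_crt_r)
    keep = ~missing_mask & ~outlier_mask
    report = ExclusionReport(
        n_initial=len(df),
        n_missing_excluded=int(missing_mask.sum()),
        n_outlier_excluded=int(outlier_mask.sum()),
        n_final=int(keep.sum()),
        max_crt_r=float(max_crt_r))
    filtered = PairedDataset(
        df.loc[keep].reset_index(drop=True),
        {**dataset.provenance, "exclusions": report.to_dict()})
    return filtered, report


def _summary(values: np.ndarray) -> ChannelSummary:
    values = values[~np.isnan(values)]
    if values.size == 0:
        return ChannelSummary(n=0, median=None, q1=None, q3=None,
                              min=None, max=None)
    # linear interpolation between order statistics, the convention shared
    # with the bootstrap percentile summaries
    q1, med, q3 = np.percentile(values, [25, 50, 75], method="linear")
    return ChannelSummary(
        n=int(values.size), median=float(med), q1=float(q1), q3=float(q3),
        min=float(values.min()), max=float(values.max()))


def summarize_cohort(dataset: PairedDataset) -> dict[str, ChannelSummary]:
    """Median, quartiles and range per channel over non-missing values.

    An all-missing channel is reported with ``n = 0`` and ``None`` summary
    fields (unavailable) rather than raising.
    """
    df = dataset.df
    out: dict[str, ChannelSummary] = {}
    for col in CHANNEL_COLUMNS:
        vals = df[col].to_numpy(dtype=float) if col in df.columns \
            else np.full(len(df), math.nan)
        out[col] = _summary(vals)
    return out
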