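"""Synthetic TEG6s cohort generator.

Emulates the statistical structure of a perioperative viscoelastic-testing
cohort so the downstream analysis is fully testable without patient data:

* the CRT-R marginal is a truncated log-normal calibrated by quantile
  inversion to a median of 0.7 min and an interquartile range of 0.5-0.9
  min, truncated to the observed 0.3-5.5 min span;
* each maximum-amplitude channel follows its published exponential-decay
  mean structure plus additive homoscedastic Gaussian noise (default sd =
  that channel's published residual RMSE), clipped to physical bounds;
* TEG-ACT is generated deterministically as the exact inverse of the linear
  CRT-R/TEG-ACT map, reproducing the near-perfect linearity of the device's
  internal conversion;
* a small fraction of records receive one missing field (missing completely
  at random) and a small fraction receive an implausibly long CRT-R, so the
  preprocessing exclusions have something to exclude.

One PRNG stream drives a whole cohort; sub-steps draw from it in a fixed,
documented order (CRT-R, then channel noise in config order, then outliers,
then missingness), so an identical configuration yields a bit-identical
dataset.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import reference
from .errors import ConfigurationError, ParseError

__all__ = [
    "ChannelModel",
    "CohortConfig",
    "PairedDataset",
    "lognormal_params_from_quartiles",
    "default_channels",
    "default_cohort_config",
    "sample_crt_r",
    "generate_dataset",
    "inject_missingness",
    "inject_outliers",
    "simulate_cohort",
    "write_fixture",
    "read_fixture",
    "CSV_COLUMNS",
    "CHANNEL_COLUMNS",
]

#: CSV schema, in column order; missing values are empty fields
CSV_COLUMNS = ("record_id", "crt_r_min", "crt_ma_mm", "ckh_r_min",
               "ckh_ma_mm", "cff_ma_mm", "teg_act_s")
#: the six measured channels (everything but the identifier)
CHANNEL_COLUMNS = CSV_COLUMNS[1:]

_CHANNEL_TO_COLUMN = {
    "CRT-MA": "crt_ma_mm",
    "CKH-R": "ckh_r_min",
    "CKH-MA": "ckh_ma_mm",
    "CFF-MA": "cff_ma_mm",
    "TEG-ACT": "teg_act_s",
}


@dataclass(frozen=True)
class ChannelModel:
    """Mean structure and noise for one generated channel.

    ``kind`` selects the mean structure: ``exp_decay`` uses
    ``a * exp(-b * crt_r) + c``; ``linear`` declares the channel an affine
    re-expression of CRT-R itself (``crt_r = slope * value + intercept``)
    generated deterministically by the exact inverse map. ``noise_sd`` is
    the additive Gaussian noise standard deviation in channel units;
    ``clip_lo``/``clip_hi`` are physical bounds applied after noise.
    """

    name: str
    kind: str
    a: float = 0.0
    b: float = 1.0
    c: float = 0.0
    slope: float = 0.0
    intercept: float = 0.0
    noise_sd: float = 0.0
    clip_lo: float = -math.inf
    clip_hi: float = math.inf

    def __post_init__(self) -> None:
        if self.name not in _CHANNEL_TO_COLUMN:
            raise ConfigurationError(
                f"unknown channel {self.name!r}; expected one of "
                f"{sorted(_CHANNEL_TO_COLUMN)}")
        if self.kind not in ("exp_decay", "linear"):
            raise ConfigurationError(f"unknown channel kind {self.kind!r}")
        if self.kind == "exp_decay" and not self.b > 0:
            raise ConfigurationError("exp_decay channel requires b > 0")
        if self.kind == "linear" and self.slope == 0:
            raise ConfigurationError("linear channel requires nonzero slope")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not self.clip_lo < self.clip_hi:
            raise ConfigurationError("clip_lo must be < clip_hi")

    @property
    def column(self) -> str:
        return _CHANNEL_TO_COLUMN[self.name]

    def mean(self, crt_r: np.ndarray) -> np.ndarray:
        """Noise-free channel value at the given CRT-R values."""
        crt_r = np.asarray(crt_r, dtype=float)
        if self.kind == "exp_decay":
            return self.a * np.exp(-self.b * crt_r) + self.c
        # linear: crt_r = slope * value + intercept, inverted exactly
        return (crt_r - self.intercept) / self.slope


def lognormal_params_from_quartiles(median: float, q1: float, q3: float,
                                    ) -> tuple[float, float]:
    """Log-scale (mu, sigma) from a median and quartile pair.

    mu = ln(median); sigma = ln(q3/q1) / (2 * z_0.75). A log-normal has only
    two free parameters, so it matches the median and the quartile *ratio*;
    the individual quartiles are reproduced exactly only when q1*q3 equals
    the squared median.
    """
    if not (0 < q1 < median < q3):
        raise ConfigurationError("need 0 < q1 < median < q3")
    z75 = stats.norm.ppf(0.75)
    return math.log(median), math.log(q3 / q1) / (2.0 * z75)


# calibrated to: median 0.7 min, IQR 0.5-0.9 min
_CRT_R_LOG_MU, _CRT_R_LOG_SIGMA = lognormal_params_from_quartiles(0.7, 0.5, 0.9)


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters for one synthetic cohort.

    Defaults reproduce the study conditions: 2,453 runs, of which about
    3.3% get one missing field and about 1% an implausibly long CRT-R.
    """

    n_records: int = 2453
    crt_r_log_mu: float = _CRT_R_LOG_MU
    crt_r_log_sigma: float = _CRT_R_LOG_SIGMA
    crt_r_lo: float = 0.3
    crt_r_hi: float = 5.5
    missing_rate: float = 80 / 2453
    outlier_rate: float = 24 / 2453
    outlier_lo: float = 5.6
    outlier_hi: float = 15.0
    seed: int = 0
    channels: tuple[ChannelModel, ...] = field(
        default_factory=lambda: default_channels())

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ConfigurationError("n_records must be >= 1")
        for name in ("missing_rate", "outlier_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ConfigurationError(f"{name} must be in [0, 1)")
        if not self.crt_r_lo > 0:
            raise ConfigurationError("crt_r_lo must be positive")
        if not self.crt_r_lo < self.crt_r_hi:
            raise ConfigurationError("crt_r_lo must be < crt_r_hi")
        if self.crt_r_log_sigma < 0:
            raise ConfigurationError("crt_r_log_sigma must be >= 0")
        if not self.outlier_lo > reference.CRT_R_MAX:
            raise ConfigurationError(
                f"outlier_lo must exceed {reference.CRT_R_MAX} min, else "
                "injected outliers would survive the exclusion filter")
        if not self.outlier_hi > self.outlier_lo:
            raise ConfigurationError("outlier_hi must be > outlier_lo")
        object.__setattr__(self, "channels", tuple(self.channels))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channels"] = [dataclasses.asdict(ch) for ch in self.channels]
        return d


@dataclass
class PairedDataset:
    """An ordered collection of paired TEG6s runs.

    ``df`` holds one row per run in the CSV schema; ``provenance`` records
    how the rows were produced (config echo, seed, injection counts).
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CSV_COLUMNS if c not in self.df.columns]
        if missing:
            raise ConfigurationError(f"dataset missing columns: {missing}")

    @property
    def n_records(self) -> int:
        return len(self.df)

    def copy(self) -> "PairedDataset":
        return PairedDataset(self.df.copy(), dict(self.provenance))

    def equals(self, other: "PairedDataset") -> bool:
        return self.df.equals(other.df)


def default_channels(noiseless: bool = False) -> tuple[ChannelModel, ...]:
    """The five generated channels with published mean structures.

    Clip bounds use the published observed range where one was reported
    (CRT-MA 20.1-75.4 mm) and wide physical bounds otherwise; amplitudes
    cannot be negative and reaction times must stay positive. With
    ``noiseless=True`` every ``noise_sd`` is zero (useful for exactness
    tests and for recovering generating parameters).
    """
    rmse = reference.CHANNEL_RMSE

    def sd(col: str) -> float:
        return 0.0 if noiseless else rmse[col]

    return (
        ChannelModel("CRT-MA", "exp_decay",
                     a=reference.CRT_MA_DECAY.a, b=reference.CRT_MA_DECAY.b,
                     c=reference.CRT_MA_DECAY.c, noise_sd=sd("crt_ma_mm"),
                     clip_lo=20.1, clip_hi=75.4),
        ChannelModel("CKH-R", "exp_decay",
                     a=reference.CKH_R_DECAY.a, b=reference.CKH_R_DECAY.b,
                     c=reference.CKH_R_DECAY.c, noise_sd=sd("ckh_r_min"),
                     clip_lo=0.5, clip_hi=30.0),
        ChannelModel("CKH-MA", "exp_decay",
                     a=reference.CKH_MA_DECAY.a, b=reference.CKH_MA_DECAY.b,
                     c=reference.CKH_MA_DECAY.c, noise_sd=sd("ckh_ma_mm"),
                     clip_lo=10.0, clip_hi=80.0),
        ChannelModel("CFF-MA", "exp_decay",
                     a=reference.CFF_MA_DECAY.a, b=reference.CFF_MA_DECAY.b,
                     c=reference.CFF_MA_DECAY.c, noise_sd=sd("cff_ma_mm"),
                     clip_lo=0.0, clip_hi=60.0),
        ChannelModel("TEG-ACT", "linear",
                     slope=reference.ACT_TO_CRT_R_LINE.slope,
                     intercept=reference.ACT_TO_CRT_R_LINE.intercept,
                     clip_lo=0.0, clip_hi=1e6),
    )


def default_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    """The study-condition cohort with a chosen seed."""
    return CohortConfig(seed=seed, **overrides)


def _rng_from(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def sample_crt_r(config: CohortConfig,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``n_records`` CRT-R values from the truncated log-normal.

    Inverse-CDF sampling: uniforms are mapped through the log-normal
    quantile function restricted to [crt_r_lo, crt_r_hi]. A zero
    ``crt_r_log_sigma`` degenerates to the constant exp(crt_r_log_mu).
    """
    rng = _rng_from(config.seed if rng is None else rng)
    n = config.n_records
    if config.crt_r_log_sigma == 0:
        return np.full(n, math.exp(config.crt_r_log_mu))
    dist = stats.lognorm(s=config.crt_r_log_sigma,
                         scale=math.exp(config.crt_r_log_mu))
    f_lo, f_hi = dist.cdf(config.crt_r_lo), dist.cdf(config.crt_r_hi)
    if not f_lo < f_hi:
        raise ConfigurationError(
            "truncation bounds leave no probability mass")
    u = rng.uniform(f_lo, f_hi, size=n)
    return np.clip(dist.ppf(u), config.crt_r_lo, config.crt_r_hi)


def _channel_values(channel: ChannelModel, crt_r: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    vals = channel.mean(crt_r)
    if channel.noise_sd > 0:
        vals = vals + rng.normal(0.0, channel.noise_sd, size=crt_r.size)
    return np.clip(vals, channel.clip_lo, channel.clip_hi)


def generate_dataset(config: CohortConfig,
                     rng: np.random.Generator | None = None) -> PairedDataset:
    """Generate a complete (no missingness, no outliers) paired dataset.

    Channels are filled in config order after the CRT-R draw; the linear
    TEG-ACT channel is deterministic, so the round trip through the forward
    CRT-R/TEG-ACT map is exact to float round-off.
    """
    rng = _rng_from(config.seed if rng is None else rng)
    crt_r = sample_crt_r(config, rng)
    data = {"record_id": np.arange(config.n_records),
            "crt_r_min": crt_r}
    for channel in config.channels:
        data[channel.column] = _channel_values(channel, crt_r, rng)
    for col in CHANNEL_COLUMNS:
        data.setdefault(col, np.full(config.n_records, np.nan))
    df = pd.DataFrame(data, columns=list(CSV_COLUMNS))
    return PairedDataset(df, provenance={"config": config.to_dict(),
                                         "seed": config.seed})


def inject_outliers(dataset: PairedDataset, rate: float, lo: float,
                    hi: float, seed=None,
                    channels: tuple[ChannelModel, ...] | None = None,
                    ) -> PairedDataset:
    """Replace a random fraction of CRT-R values with implausible ones.

    Each record is independently flagged with probability ``rate``; flagged
    records get CRT-R redrawn uniformly from (lo, hi] and every generated
    channel regenerated from its mean structure at the new CRT-R (so the
    rows stay internally consistent). ``lo`` must exceed the 5.5 min
    exclusion threshold, guaranteeing the preprocess filter removes every
    injected record.
    """
    if not lo > reference.CRT_R_MAX:
        raise ConfigurationError(
            f"outlier lower bound must exceed {reference.CRT_R_MAX} min")
    if not hi > lo:
        raise ConfigurationError("outlier upper bound must exceed lower")
    if not 0 <= rate < 1:
        raise ConfigurationError("outlier rate must be in [0, 1)")
    rng = _rng_from(seed)
    out = dataset.copy()
    if channels is None:
        cfg = dataset.provenance.get("config")
        channels = tuple(ChannelModel(**ch) for ch in cfg["channels"]) \
            if cfg else default_channels()
    flagged = rng.random(out.n_records) < rate
    k = int(flagged.sum())
    if k:
        new_crt = hi - rng.uniform(0.0, hi - lo, size=k)  # draws in (lo, hi]
        out.df.loc[flagged, "crt_r_min"] = new_crt
        for channel in channels:
            out.df.loc[flagged, channel.column] = _channel_values(
                channel, new_crt, rng)
    out.provenance["n_outliers_injected"] = k
    return out


def inject_missingness(dataset: PairedDataset, rate: float, seed=None,
                       ) -> PairedDataset:
    """Blank one uniformly chosen field per affected record (MCAR).

    Each record is independently affected with probability ``rate``; the
    affected count is recorded in provenance.
    """
    if not 0 <= rate < 1:
        raise ConfigurationError("missing rate must be in [0, 1)")
    rng = _rng_from(seed)
    out = dataset.copy()
    flagged = rng.random(out.n_records) < rate
    k = int(flagged.sum())
    if k:
        which = rng.integers(0, len(CHANNEL_COLUMNS), size=k)
        rows = np.flatnonzero(flagged)
        for row, col_idx in zip(rows, which):
            out.df.iloc[row, out.df.columns.get_loc(
                CHANNEL_COLUMNS[col_idx])] = np.nan
    out.provenance["n_missing_injected"] = k
    return out


def simulate_cohort(config: CohortConfig) -> PairedDataset:
    """Full study-condition cohort: generate, then outliers, then missingness.

    A single PRNG stream (seeded from ``config.seed``) drives all three
    stages in that order, so the whole cohort is reproducible bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    ds = generate_dataset(config, rng)
    ds = inject_outliers(ds, config.outlier_rate, config.outlier_lo,
                         config.outlier_hi, seed=rng,
                         channels=config.channels)
    ds = inject_missingness(ds, config.missing_rate, seed=rng)
    return ds


def write_fixture(dataset: PairedDataset, path) -> None:
    """Write the dataset as UTF-8, LF-terminated CSV (empty field = missing).

    Floats are written with ``repr`` precision so the round trip through
    :func:`read_fixture` is lossless.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(CSV_COLUMNS) + "\n")
        for row in dataset.df.itertuples(index=False):
            cells = [str(int(row.record_id))]
            for col in CHANNEL_COLUMNS:
                v = getattr(row, col)
                cells.append("" if pd.isna(v) else repr(float(v)))
            fh.write(",".join(cells) + "\n")


def read_fixture(path) -> PairedDataset:
    """Read a CSV fixture back into a :class:`PairedDataset`.

    Malformed files raise :class:`ParseError` naming the offending column
    (and row, for a bad numeric cell). An empty record set is valid.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: file has no header") from exc
    missing = [c for c in CSV_COLUMNS if c not in raw.columns]
    if missing:
        raise ParseError(
            f"{path}: missing required column(s) {', '.join(missing)}",
            column=missing[0])
    df = pd.DataFrame()
    df["record_id"] = pd.to_numeric(raw["record_id"], errors="coerce")
    for col in CHANNEL_COLUMNS:
        cells = raw[col].str.strip()
        vals = pd.to_numeric(cells.replace("", np.nan), errors="coerce")
        bad = vals.isna() & (cells != "")
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(
                f"{path}: row {row + 2}, column {col!r}: "
                f"cannot parse {cells.iloc[row]!r} as a number",
                column=col, row=row + 2)
        df[col] = vals.astype(float)
    if df["record_id"].isna().any():
        row = int(df["record_id"].isna().idxmax())
        raise ParseError(f"{path}: row {row + 2}, column 'record_id': "
                         "not an integer identifier",
                         column="record_id", row=row + 2)
    df["record_id"] = df["record_id"].astype(np.int64)
    df = df[list(CSV_COLUMNS)]
    return PairedDataset(df, provenance={"source": str(path)})
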