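"""End-to-end analysis run: simulate/load -> exclude -> fit -> cutoffs.

`run_analysis` executes the stages in a fixed order and emits a
machine-readable replication report plus per-channel curve tables and a
cutoff table. Identical configuration and seed give a byte-identical
report; stage failures propagate with the stage name attached and leave any
already-written outputs on disk.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .association import fit_exp_decay, fit_linear
from .errors import ConfigurationError, TegmaError
from .preprocess import apply_exclusions, summarize_cohort
from .simulate import (CHANNEL_COLUMNS, CohortConfig, PairedDataset,
                       default_cohort_config, read_fixture, simulate_cohort,
                       write_fixture)
from .threshold import bootstrap_cutoff, classify_at_cutoff

__all__ = ["RunConfig", "AnalysisReport", "run_analysis",
           "load_run_config", "validate_report", "StageError"]

log = logging.getLogger("tegma")

#: analyzed outcome channels and their mean-structure kind; the maximum
#: amplitude channels and CKH-R decay with CRT-R, TEG-ACT is linear in it
DEFAULT_CHANNELS: tuple[tuple[str, str], ...] = (
    ("crt_ma_mm", "exp_decay"),
    ("ckh_r_min", "exp_decay"),
    ("ckh_ma_mm", "exp_decay"),
    ("cff_ma_mm", "exp_decay"),
    ("teg_act_s", "linear"),
)

#: default clinical MA targets (mm) per outcome channel
DEFAULT_MA_TARGETS: dict[str, float] = {
    "crt_ma_mm": 48.0,
    "cff_ma_mm": 12.0,
}


class StageError(TegmaError):
    """A pipeline stage failed; ``stage`` names it, ``__cause__`` has why."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """One reproducible analysis run.

    Either ``input_path`` (a CSV in the package schema) or a generator
    ``cohort`` drives the run; with neither, the default study-condition
    cohort is simulated with ``seed``.
    """

    input_path: str | None = None
    cohort: CohortConfig | None = None
    channels: tuple[tuple[str, str], ...] = DEFAULT_CHANNELS
    ma_targets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MA_TARGETS))
    n_boot: int = 1000
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ConfigurationError("n_boot must be >= 1")
        for col, kind in self.channels:
            if col not in CHANNEL_COLUMNS:
                raise ConfigurationError(f"unknown channel column {col!r}")
            if kind not in ("exp_decay", "linear"):
                raise ConfigurationError(f"unknown model kind {kind!r}")
        analyzed = {col for col, _ in self.channels}
        for col, target in self.ma_targets.items():
            if col not in analyzed:
                raise ConfigurationError(
                    f"MA target for unanalyzed channel {col!r}")
            if not target > 0:
                raise ConfigurationError("MA targets must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict() if self.cohort else None
        d["channels"] = [list(pair) for pair in self.channels]
        return d


@dataclass
class AnalysisReport:
    """Machine-readable result of one run (see ``report_schema.json``)."""

    exclusions: dict
    summaries: dict
    channels: dict
    cutoffs: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {"exclusions": self.exclusions, "summaries": self.summaries,
                "channels": self.channels, "cutoffs": self.cutoffs,
                "provenance": self.provenance}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True,
                          allow_nan=False)


@contextmanager
def _stage(name: str):
    log.info("stage %s: start", name)
    try:
        yield
    except StageError:
        raise
    except Exception as exc:
        raise StageError(name, exc) from exc
    log.info("stage %s: done", name)


def _finite_or_none(v):
    if v is None:
        return None
    v = float(v)
    return v if np.isfinite(v) else None


def _diag_dict(diag) -> dict:
    return {"r": _finite_or_none(diag.r), "abs_r": _finite_or_none(abs(diag.r)),
            "p_value": _finite_or_none(diag.p_value),
            "r2": _finite_or_none(diag.r2), "mae": _finite_or_none(diag.mae),
            "rmse": _finite_or_none(diag.rmse), "n": diag.n}


def _curve_table(model, x: np.ndarray, n_grid: int = 101) -> str:
    grid = np.linspace(float(x.min()), float(x.max()), n_grid)
    fitted = model.predict(grid)
    lines = ["crt_r_min,fitted"]
    lines += [f"{g!r},{f!r}" for g, f in zip(grid, fitted)]
    return "\n".join(lines) + "\n"


def run_analysis(config: RunConfig) -> AnalysisReport:
    """Execute simulate/load -> preprocess -> associate -> threshold.

    Returns the report; when ``config.out_dir`` is set, also writes
    ``report.json``, ``<channel>_curve.csv`` tables, the input echo
    ``dataset.csv`` (simulated runs only) and ``cutoffs.csv``.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    with _stage("acquire"):
        if config.input_path:
            dataset = read_fixture(config.input_path)
        else:
            cohort = config.cohort or default_cohort_config(seed=config.seed)
            dataset = simulate_cohort(cohort)
            if out_dir:
                write_fixture(dataset, out_dir / "dataset.csv")
        log.info("acquired %d records", dataset.n_records)

    with _stage("preprocess"):
        analyzed_cols = ["crt_r_min"] + [c for c, _ in config.channels]
        analysis_set, excl = apply_exclusions(
            dataset, required=tuple(analyzed_cols))
        summaries = {c: s.to_dict()
                     for c, s in summarize_cohort(analysis_set).items()}
        log.info("exclusions: %d missing, %d outliers, %d remain",
                 excl.n_missing_excluded, excl.n_outlier_excluded,
                 excl.n_final)

    crt_r = analysis_set.df["crt_r_min"].to_numpy(dtype=float)
    channel_results: dict[str, dict] = {}
    with _stage("associate"):
        for col, kind in config.channels:
            y = analysis_set.df[col].to_numpy(dtype=float)
            if kind == "exp_decay":
                model, diag = fit_exp_decay(crt_r, y)
                params = {"a": model.a, "b": model.b, "c": model.c}
                curve_x = crt_r
            else:
                # linear channels re-express the reaction time itself, so
                # CRT-R is the response: crt_r = slope * value + intercept
                model, diag = fit_linear(y, crt_r)
                params = {"slope": model.slope, "intercept": model.intercept}
                curve_x = y
            channel_results[col] = {"kind": kind, "params": params,
                                    **_diag_dict(diag)}
            if out_dir:
                (out_dir / f"{col}_curve.csv").write_text(
                    _curve_table(model, curve_x), encoding="utf-8")
            log.info("%s: |r|=%.4f r2=%.4f", col, abs(diag.r), diag.r2)

    cutoff_results: dict[str, dict] = {}
    with _stage("threshold"):
        # one spawned child stream per target, in sorted channel order
        targets = sorted(config.ma_targets.items())
        children = np.random.SeedSequence(config.seed).spawn(len(targets))
        for (col, target), child in zip(targets, children):
            y = analysis_set.df[col].to_numpy(dtype=float)
            est = bootstrap_cutoff(crt_r, y, target, n_boot=config.n_boot,
                                   seed=np.random.default_rng(child))
            metrics = classify_at_cutoff(crt_r, est.boot_median, y, target)
            cutoff_results[col] = {
                "estimate": dataclasses.asdict(est),
                "metrics": {k: _finite_or_none(v) if k not in
                            ("tp", "fp", "tn", "fn") else v
                            for k, v in dataclasses.asdict(metrics).items()},
            }
            log.info("%s target %.1f: cutoff %.4f min "
                     "[%.4f, %.4f]", col, target, est.boot_median,
                     est.boot_ci_lo, est.boot_ci_hi)

    report = AnalysisReport(
        exclusions=excl.to_dict(),
        summaries=summaries,
        channels=channel_results,
        cutoffs=cutoff_results,
        provenance={"config": config.to_dict(), "seed": config.seed,
                    "package": "tegma", "version": __version__})
    validate_report(report.to_dict())
    if out_dir:
        (out_dir / "report.json").write_text(report.to_json() + "\n",
                                             encoding="utf-8")
        (out_dir / "cutoffs.csv").write_text(_cutoff_table(cutoff_results),
                                             encoding="utf-8")
    return report


def _cutoff_table(cutoffs: dict) -> str:
    cols = ("channel", "y_target", "point", "boot_median", "boot_q25",
            "boot_q75", "boot_ci_lo", "boot_ci_hi", "sensitivity",
            "specificity", "ppv", "npv", "accuracy")
    lines = [",".join(cols)]
    for col in sorted(cutoffs):
        est, met = cutoffs[col]["estimate"], cutoffs[col]["metrics"]
        row = [col] + [repr(est[k]) for k in
                       ("y_target", "point", "boot_median", "boot_q25",
                        "boot_q75", "boot_ci_lo", "boot_ci_hi")]
        row += ["" if met[k] is None else repr(met[k]) for k in
                ("sensitivity", "specificity", "ppv", "npv", "accuracy")]
        lines.append(",".join(row))
    return "\n".join(lines) + "\n"


def load_run_config(path) -> RunConfig:
    """Build a :class:`RunConfig` from a flat YAML file.

    Recognized keys mirror the dataclass fields; ``cohort`` may be a nested
    mapping of :class:`CohortConfig` fields (channel overrides excluded —
    use the Python API for those).
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    kwargs: dict = {}
    for key in ("input_path", "n_boot", "seed", "out_dir"):
        if key in raw:
            kwargs[key] = raw.pop(key)
    if "channels" in raw:
        kwargs["channels"] = tuple((str(c), str(k))
                                   for c, k in raw.pop("channels"))
    if "ma_targets" in raw:
        kwargs["ma_targets"] = {str(k): float(v)
                                for k, v in raw.pop("ma_targets").items()}
    if "cohort" in raw:
        cohort_raw = raw.pop("cohort") or {}
        kwargs["cohort"] = CohortConfig(**cohort_raw)
    if raw:
        raise ConfigurationError(
            f"{path}: unknown configuration key(s) {sorted(raw)}")
    return RunConfig(**kwargs)


def _schema() -> dict:
    text = resources.files("tegma").joinpath("report_schema.json") \
        .read_text(encoding="utf-8")
    return json.loads(text)


def validate_report(report: dict, schema: dict | None = None) -> None:
    """Structural validation of a report dict against the published schema.

    Checks required keys recursively (``*`` in the schema matches any key,
    applying its sub-schema to every entry). Raises
    :class:`ConfigurationError` on the first missing key.
    """
    schema = schema if schema is not None else _schema()

    def check(node, spec, path):
        if not isinstance(spec, dict):
            return
        if "*" in spec:
            for key, child in node.items():
                check(child, spec["*"], f"{path}.{key}")
            return
        for key, child_spec in spec.items():
            if key not in node:
                raise ConfigurationError(
                    f"report missing required key {path}.{key}")
            check(node[key], child_spec, f"{path}.{key}")

    check(report, schema, "report")


def simulate_to_csv(config: CohortConfig, path) -> PairedDataset:
    """Simulate one cohort and write it to ``path``; returns the dataset."""
    ds = simulate_cohort(config)
    write_fixture(ds, path)
    return ds
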