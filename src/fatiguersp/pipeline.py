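"""One-config orchestration of the full synthetic experiment.

A single YAML file describes the cohort simulation, preprocessing,
ERSP analysis, inference and classification settings; :func:`run_all`
executes simulate -> preprocess -> ERSP -> stats -> classify and writes
CSV/JSON reports plus a manifest (package versions, seeds, config hash) so
a rerun with the same config reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import ConfigurationError
from .ersp import BASELINE_WINDOWS, TASK_WINDOWS
from .model import FatigueSpectralModel
from .preprocess import OFFSET_WINDOW, ONSET_WINDOW
from .simulate import BandEffect, SimConfig, simulate_cohort

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class Finding:
    """One validation finding; errors block execution, warnings do not."""

    level: str  # "error" | "warning"
    message: str

    def __str__(self) -> str:
        return f"{self.level.upper()}: {self.message}"


@dataclass
class PipelineConfig:
    """Validated settings for a full pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    window: str = "steady"
    low: float = 1.0
    high: float = 100.0
    notch_base: float = 60.0
    peak_to_peak_limit: float = 200.0
    fraction: float = 0.10
    channels: list[str] | None = None
    bands: dict[str, tuple[float, float]] | None = None
    freq_start: float = 3.0
    freq_stop: float = 91.0
    freq_step: float = 1.0
    n_perm: int = 2000
    q: float = 0.05
    permutation_channel: str = "C3"
    stats_seed: int = 0
    folds: int = 10
    cv_seed: int = 0
    write_edf: bool = False

    @property
    def freqs(self) -> np.ndarray:
        return np.arange(self.freq_start, self.freq_stop, self.freq_step)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"unparseable config file: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigurationError("config must be a YAML mapping")
        if raw.get("schema", SCHEMA_VERSION) != SCHEMA_VERSION:
            raise ConfigurationError(
                f"unsupported config schema {raw.get('schema')!r}"
            )
        sim_raw = dict(raw.get("simulate", {}))
        if "band_effects" in sim_raw:
            sim_raw["band_effects"] = {
                name: BandEffect(**spec)
                for name, spec in sim_raw["band_effects"].items()
            }
        if "channel_labels" in sim_raw:
            sim_raw["channel_labels"] = tuple(sim_raw["channel_labels"])
        if "motor_channels" in sim_raw:
            sim_raw["motor_channels"] = tuple(sim_raw["motor_channels"])
        kwargs = {}
        for section in ("filter", "epochs", "analysis", "stats", "classify"):
            kwargs.update(raw.get(section, {}))
        known = {f.name for f in dataclasses.fields(cls)} - {"sim"}
        unknown = set(kwargs) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "bands" in kwargs and kwargs["bands"] is not None:
            kwargs["bands"] = {
                k: tuple(v) for k, v in kwargs["bands"].items()
            }
        return cls(sim=SimConfig(**sim_raw), **kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def validate_config(config: PipelineConfig) -> list[Finding]:
    """Static checks; errors returned here block :func:`run_all`."""
    findings: list[Finding] = []
    err = lambda m: findings.append(Finding("error", m))  # noqa: E731
    warn = lambda m: findings.append(Finding("warning", m))  # noqa: E731

    labels = set(config.sim.channel_labels)
    channels = config.channels or [
        ch for ch in config.sim.motor_channels if ch in labels
    ]
    missing = [ch for ch in channels if ch not in labels]
    if missing:
        err(f"analysis channels not in the montage: {missing}")
    if config.permutation_channel not in channels:
        warn(f"permutation channel {config.permutation_channel!r} is not "
             "among the analysis channels; the stats stage will skip it")

    nyq = config.sim.sampling_rate / 2.0
    if not 0 < config.low < config.high:
        err("filter cutoffs must satisfy 0 < low < high")
    if config.high >= nyq:
        err(f"high cutoff {config.high} Hz >= Nyquist {nyq} Hz")

    if config.window not in TASK_WINDOWS:
        err(f"window must be one of {sorted(TASK_WINDOWS)}")
    else:
        epoch = ONSET_WINDOW if config.window == "steady" else OFFSET_WINDOW
        for name, (w0, w1) in (
            ("task", TASK_WINDOWS[config.window]),
            ("baseline", BASELINE_WINDOWS[config.window]),
        ):
            if w0 < epoch[0] or w1 > epoch[1]:
                err(f"{name} window [{w0}, {w1}] s exceeds the "
                    f"epoch limits [{epoch[0]}, {epoch[1]}] s")
        epoch_len = epoch[1] - epoch[0]
        if config.freq_start < 3.0 and epoch_len < 3.0:
            err("frequency grid extends below 3 Hz; epochs are too short "
                "for the lowest-frequency wavelet")

    if not 0 < config.fraction <= 1:
        err("fraction must be in (0, 1]")
    else:
        t = config.sim.n_trials
        n_sel = max(1, round(config.fraction * t))
        if n_sel > t // 3:
            warn(f"fraction {config.fraction} selects {n_sel} trials per "
                 f"condition but each condition set has only {t // 3}")
    if config.n_perm < 1:
        err("n_perm must be >= 1")
    if not 0 < config.q < 1:
        err("q must be in (0, 1)")
    return findings


def run_all(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute every stage and write reports under ``out_dir``.

    Produces ``ersp_table.csv``, ``anova_<window>.csv`` (channel/band F, p
    and Bonferroni pairwise p-values), ``permutation_<channel>.csv``,
    ``classification.json`` and ``manifest.json``.  Raises on validation
    errors before any computation.
    """
    errors = [f for f in validate_config(config) if f.level == "error"]
    if errors:
        raise ConfigurationError(
            "invalid pipeline config: " + "; ".join(f.message for f in errors)
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage 1/5: simulating cohort")
    recordings = simulate_cohort(config.sim)
    if config.write_edf:
        from .edf import write_edf

        edf_dir = out / "edf"
        edf_dir.mkdir(exist_ok=True)
        for rec in recordings:
            write_edf(rec, edf_dir / f"{rec.subject_id}.edf")

    logger.info("stage 2-3/5: preprocessing and ERSP")
    model = FatigueSpectralModel(
        recordings, window=config.window, channels=config.channels,
        bands=config.bands, freqs=config.freqs, fraction=config.fraction,
        low=config.low, high=config.high, notch_base=config.notch_base,
        peak_to_peak_limit=config.peak_to_peak_limit,
    )
    results = model.fit()
    results.ersp_table.to_csv(out / "ersp_table.csv", index=False,
                              float_format="%.10g")

    logger.info("stage 4/5: inference")
    results.anova_table().to_csv(
        out / f"anova_{config.window}.csv", index=False, float_format="%.10g"
    )
    if config.permutation_channel in model.channels:
        perm = results.permutation_spectrum(
            config.permutation_channel, n_perm=config.n_perm,
            seed=config.stats_seed, q=config.q,
        )
        pd.DataFrame({
            "freq_hz": model.freqs,
            "F": perm.observed_stat,
            "p": perm.p_map,
            "fdr_significant": perm.fdr_mask,
        }).to_csv(out / f"permutation_{config.permutation_channel}.csv",
                  index=False, float_format="%.10g")

    logger.info("stage 5/5: classification")
    clf_report = {}
    if results.features is not None:
        for name, classes in (
            ("binary_min_sev", ("MinFatg", "SevFatg")),
            ("three_class", ("MinFatg", "ModFatg", "SevFatg")),
        ):
            r = results.classify(classes, folds=config.folds,
                                 seed=config.cv_seed)
            clf_report[name] = {
                "accuracy_pct": r.accuracy,
                "confusion": r.confusion.to_dict(),
            }
    (out / "classification.json").write_text(
        json.dumps(clf_report, indent=1, sort_keys=True) + "\n"
    )

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config_hash": config.config_hash(),
        "config": _jsonable(config),
        "seeds": {
            "simulation": config.sim.seed,
            "stats": config.stats_seed,
            "cross_validation": config.cv_seed,
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    logger.info("pipeline complete: %s", out)
    return out
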