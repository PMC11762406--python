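"""Configuration-driven end-to-end runner.

Stage order: generate or ingest -> replicate averaging -> missingness
filter -> per-participant z-scaling -> per-period population cosinor
screen -> power table and amplitude curves.  All tables are plain
comma-separated text; a JSON manifest records the config hash, seed,
and per-stage record counts so identical config + seed reruns are
byte-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, cosinor, power, preprocess, simulate
from .errors import ConfigError, PipelineError, RhythmPowerError

__all__ = ["PipelineConfig", "run_pipeline", "validate_input"]

logger = logging.getLogger("rhythmpower")

DEFAULT_CURVE_GRID = [round(0.01 * i, 2) for i in range(0, 61)]  # A in [0, 0.60]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Exactly one input source: either a synthetic cohort config or a
    (records CSV, DLMO CSV) path pair.
    """

    output_dir: Path
    seed: int = 0
    synthetic: simulate.CohortConfig | None = None
    data_path: Path | None = None
    dlmo_path: Path | None = None
    max_missing: float = 0.10
    periods: tuple[float, ...] = cosinor.DEFAULT_PERIODS
    p_threshold: float = cosinor.DEFAULT_P_THRESHOLD
    amp_threshold: float = cosinor.DEFAULT_AMP_THRESHOLD
    power_params: power.PowerParams = field(default_factory=power.PowerParams)
    variance_convention: power.VarianceConvention = power.DEFAULT_CONVENTION
    curve_amplitudes: tuple[float, ...] = tuple(DEFAULT_CURVE_GRID)
    figures: bool = False
    log_level: str = "INFO"
    raw: dict | None = None  # original mapping, hashed into the manifest

    def validate(self) -> None:
        has_synth = self.synthetic is not None
        has_files = self.data_path is not None
        if has_synth == has_files:
            raise ConfigError("input", "exactly one of 'synthetic' or 'data' must be given")
        if has_files:
            if self.dlmo_path is None:
                raise ConfigError("input.dlmo", "a DLMO clock file is required with 'data'")
            for p in (self.data_path, self.dlmo_path):
                if not Path(p).is_file():
                    raise ConfigError("input", f"input file not found: {p}")
        if has_synth:
            self.synthetic.validate()
        if not (0 <= self.max_missing < 1):
            raise ConfigError("max_missing", f"must be in [0, 1), got {self.max_missing}")

    @classmethod
    def from_mapping(cls, raw: dict, base_dir: Path | None = None) -> "PipelineConfig":
        """Build a config from a parsed YAML/JSON mapping."""
        base = Path(base_dir) if base_dir else Path.cwd()
        inp = raw.get("input", {})
        synthetic = None
        data_path = dlmo_path = None
        if "synthetic" in inp:
            synthetic = _cohort_config_from_mapping(inp["synthetic"], raw.get("seed", 0))
        if "data" in inp:
            data_path = (base / inp["data"]).resolve()
            dlmo_path = (base / inp["dlmo"]).resolve() if "dlmo" in inp else None
        screen = raw.get("screen", {})
        pw = raw.get("power", {})
        cfg = cls(
            output_dir=(base / raw.get("output_dir", "rhythmpower_out")).resolve(),
            seed=int(raw.get("seed", 0)),
            synthetic=synthetic,
            data_path=data_path,
            dlmo_path=dlmo_path,
            max_missing=float(raw.get("max_missing", 0.10)),
            periods=tuple(float(p) for p in screen.get("periods", cosinor.DEFAULT_PERIODS)),
            p_threshold=float(screen.get("p_threshold", cosinor.DEFAULT_P_THRESHOLD)),
            amp_threshold=float(screen.get("amp_threshold", cosinor.DEFAULT_AMP_THRESHOLD)),
            power_params=power.PowerParams(
                alpha=float(pw.get("alpha", 0.05)),
                beta_baseline=float(pw.get("beta_baseline", 0.20)),
                effect_size_d=float(pw.get("effect_size_d", 0.5)),
            ),
            variance_convention=power.VarianceConvention.coerce(
                pw.get("variance_convention", power.DEFAULT_CONVENTION)
            ),
            curve_amplitudes=tuple(
                float(a) for a in raw.get("curve_amplitudes", DEFAULT_CURVE_GRID)
            ),
            figures=bool(raw.get("figures", False)),
            log_level=str(raw.get("log_level", "INFO")),
            raw=raw,
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.is_file():
            raise ConfigError("config", f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise ConfigError("config", f"config root must be a mapping: {path}")
        return cls.from_mapping(raw, base_dir=path.parent)

    def config_hash(self) -> str:
        payload = self.raw if self.raw is not None else {"seed": self.seed}
        canonical = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()


def _cohort_config_from_mapping(raw: dict, seed: int) -> simulate.CohortConfig:
    specs = []
    for item in raw.get("proteins", []):
        specs.append(
            simulate.RhythmSpec(
                protein_id=str(item["protein_id"]),
                components=tuple(
                    simulate.RhythmComponent(
                        period=float(c["period"]),
                        amplitude=float(c["amplitude"]),
                        acrophase=float(c.get("acrophase", 0.0)),
                    )
                    for c in item.get("components", [])
                ),
            )
        )
    kwargs: dict[str, Any] = {"rhythm_specs": tuple(specs), "seed": int(raw.get("seed", seed))}
    for key in (
        "n_participants",
        "n_replicates",
        "noise_sd",
        "replicate_noise_frac",
        "missing_rate",
        "baseline_mean",
        "baseline_sd",
        "dlmo_clock_mean",
        "dlmo_clock_sd",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    if "timepoints" in raw:
        kwargs["timepoints"] = tuple(float(t) for t in raw["timepoints"])
    return simulate.CohortConfig(**kwargs)


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

def validate_input(records_path: str | Path, dlmo_path: str | Path | None = None) -> list[dict]:
    """Check a tidy cohort file (and optional DLMO file) without mutating it.

    Returns a machine-readable issue list; an empty list means the file
    is well-formed.  Checked: column schema, non-numeric abundances
    (with line numbers), duplicate (participant, protein, time,
    replicate) keys, and DLMO coverage of every participant.
    """
    issues: list[dict] = []
    path = Path(records_path)
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed CSV
        return [{"kind": "parse_error", "detail": str(exc), "file": str(path)}]

    missing_cols = [c for c in simulate.RECORD_COLUMNS if c not in raw.columns]
    if missing_cols:
        issues.append({"kind": "missing_columns", "detail": ",".join(missing_cols)})
        return issues

    for col in ("dlmo_time", "replicate", "abundance"):
        values = raw[col].replace("", np.nan)
        numeric = pd.to_numeric(values, errors="coerce")
        bad = values.notna() & numeric.isna()
        for idx in raw.index[bad]:
            issues.append(
                {
                    "kind": "non_numeric",
                    "column": col,
                    "line": int(idx) + 2,  # header is line 1
                    "value": raw.at[idx, col],
                }
            )

    keys = raw[["participant_id", "protein_id", "dlmo_time", "replicate"]]
    dup = keys.duplicated(keep=False)
    for key, grp in raw[dup].groupby(list(keys.columns)):
        issues.append({"kind": "duplicate_key", "key": tuple(key), "n_rows": len(grp)})

    if dlmo_path is not None:
        try:
            dlmo = pd.read_csv(dlmo_path, dtype={"participant_id": str})
        except Exception as exc:
            issues.append({"kind": "parse_error", "detail": str(exc), "file": str(dlmo_path)})
            return issues
        covered = set(dlmo.get("participant_id", pd.Series(dtype=str)))
        for pid in sorted(set(raw["participant_id"]) - covered):
            issues.append({"kind": "missing_dlmo", "participant_id": pid})
    return issues


# ---------------------------------------------------------------------------
# End-to-end run
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write all report files.

    Output files are staged in memory and written only after every
    stage succeeds, so a failed run leaves no partial reports.  Returns
    the manifest (also written as ``manifest.json``).
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    counts: dict[str, int] = {}
    outputs: dict[str, str] = {}

    # --- ingest / generate -------------------------------------------------
    stage = "input"
    try:
        if config.synthetic is not None:
            dataset = simulate.generate_cohort(config.synthetic)
            logger.info("generated synthetic cohort: %d records", len(dataset.records))
        else:
            issues = validate_input(config.data_path, config.dlmo_path)
            fatal = [i for i in issues if i["kind"] in ("parse_error", "missing_columns")]
            if fatal:
                raise PipelineError(stage, f"input validation failed: {fatal}")
            dataset = simulate.read_cohort(config.data_path, config.dlmo_path)
        counts["input_records"] = len(dataset.records)

        stage = "average_replicates"
        averaged = preprocess.average_replicates(dataset)
        counts["averaged_cells"] = len(averaged.records)

        stage = "filter_missing"
        filtered, filter_report = preprocess.filter_missing_proteins(
            averaged, config.max_missing
        )
        counts["proteins_before_filter"] = int(filter_report.shape[0])
        counts["proteins_after_filter"] = int(filter_report["kept"].sum())
        counts["proteins_dropped"] = (
            counts["proteins_before_filter"] - counts["proteins_after_filter"]
        )

        stage = "zscore"
        scaled = preprocess.zscore_per_participant(filtered)
        counts["scaled_points"] = len(scaled.series)

        stage = "screen"
        outcome = cosinor.screen_rhythmic(
            scaled, config.periods, config.p_threshold, config.amp_threshold
        )
        counts["screen_results"] = len(outcome.results)
        counts["screen_failures"] = len(outcome.failures)
        counts["screen_passing"] = len(outcome.passing())

        stage = "power"
        assessments = power.build_table3(
            outcome.results, config.power_params, config.variance_convention
        )
        curve = power.power_curve(
            config.curve_amplitudes, config.power_params, config.variance_convention
        )
        counts["power_rows"] = len(assessments)
    except RhythmPowerError:
        raise
    except Exception as exc:  # pragma: no cover - unexpected stage failure
        raise PipelineError(stage, str(exc)) from exc

    # --- stage outputs -----------------------------------------------------
    outputs["filter_report.csv"] = filter_report.to_csv(index=False)
    outputs["rhythm_screen.csv"] = cosinor.results_to_frame(outcome.results).to_csv(index=False)
    outputs["polar_export.csv"] = cosinor.polar_export(outcome.passing()).to_csv(index=False)
    outputs["power_table.csv"] = power.assessments_to_frame(assessments).to_csv(index=False)
    outputs["power_curve.csv"] = curve.to_csv(index=False)
    if outcome.failures:
        outputs["screen_failures.csv"] = pd.DataFrame(outcome.failures).to_csv(index=False)

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.synthetic is not None:
        simulate.write_cohort(dataset, out_dir / "cohort.csv", out_dir / "dlmo.csv")
        simulate.write_ground_truth(dataset.ground_truth, out_dir / "ground_truth.json")
    for name, text in outputs.items():
        (out_dir / name).write_text(text)
    if config.figures:
        _write_figures(outcome, curve, out_dir)

    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "variance_convention": config.variance_convention.value,
        "counts": counts,
        "outputs": sorted(outputs),
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    logger.info("pipeline complete: %s", counts)
    return manifest


def _write_figures(outcome: cosinor.ScreenOutcome, curve: pd.DataFrame, out_dir: Path) -> None:
    # Optional side-effect; all figure data is also emitted as text.
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    polar = cosinor.polar_export(outcome.passing())
    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="polar")
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    for _, row in polar.iterrows():
        ax.plot([row["angle_rad"]] * 2, [0, row["amplitude_z"]], marker="o")
        ax.annotate(row["protein_id"], (row["angle_rad"], row["amplitude_z"]))
    ax.set_title("Acrophase (DLMO angle) vs amplitude (z-score)")
    fig.savefig(out_dir / "polar_acrophase.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    axes[0].plot(curve["amplitude_z"], curve["n_increase_pct"])
    axes[0].set_xlabel("amplitude (z-score)")
    axes[0].set_ylabel("increase in n (%)")
    axes[1].plot(curve["amplitude_z"], curve["beta_pct"])
    axes[1].set_xlabel("amplitude (z-score)")
    axes[1].set_ylabel("Type II error rate (%)")
    fig.tight_layout()
    fig.savefig(out_dir / "power_curves.png", dpi=120)
    plt.close(fig)
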