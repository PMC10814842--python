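"""CSV schemas, run configuration and the end-to-end pipeline.

All tables are plain CSV with units encoded in the column names
(mg/kg, kg/day, kg) so unit mistakes surface as schema errors.  Output
files carry provenance as '#' comment header lines (tool version, seed,
config hash) which pandas skips transparently on re-read.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .deterministic import PopulationSubgroup, ResidueSummary, ToxicologyReference, risk_table
from .dissipation import DissipationSeries, summarize_fits
from .probabilistic import DEFAULT_PERCENTILE_LEVELS, stratified_run
from .validation import validation_report

__all__ = [
    "SchemaError",
    "PipelineError",
    "SCHEMAS",
    "load_table",
    "write_table",
    "RunConfig",
    "run_pipeline",
    "write_example_inputs",
]


class SchemaError(ValueError):
    """A table violated its declared schema."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; earlier outputs are retained."""


@dataclass(frozen=True)
class _Schema:
    text_columns: tuple[str, ...]
    numeric_columns: tuple[str, ...]
    nonneg_columns: tuple[str, ...] = ()

    @property
    def columns(self) -> tuple[str, ...]:
        return self.text_columns + self.numeric_columns


SCHEMAS: dict[str, _Schema] = {
    "calibration": _Schema(("compound", "medium"), ("level_mg_per_L", "response"), ("level_mg_per_L",)),
    "recovery": _Schema(
        ("compound",), ("spike_mg_per_kg", "replicate", "measured_mg_per_kg"),
        ("spike_mg_per_kg", "measured_mg_per_kg"),
    ),
    "decay": _Schema(
        ("compound", "site"), ("day", "residue_mg_per_kg", "censored"),
        ("day", "residue_mg_per_kg"),
    ),
    "residue": _Schema(("compound",), ("residue_mg_per_kg", "censored"), ("residue_mg_per_kg",)),
    "residue_summary": _Schema(
        ("compound",), ("hr_mg_per_kg", "stmr_mg_per_kg"), ("hr_mg_per_kg", "stmr_mg_per_kg")
    ),
    "subgroups": _Schema(
        ("name",), ("bw_kg", "lp_kg_per_day", "fi_kg_per_day", "v"),
        ("bw_kg", "lp_kg_per_day", "fi_kg_per_day"),
    ),
    "toxicology": _Schema(
        ("compound",), ("adi_mg_per_kg_bw_day", "arfd_mg_per_kg_bw"),
        ("adi_mg_per_kg_bw_day", "arfd_mg_per_kg_bw"),
    ),
    "consumption": _Schema(("subgroup",), ("intake_kg_per_day", "bw_kg"), ("intake_kg_per_day", "bw_kg")),
}


def load_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Raises :class:`SchemaError` naming the offending row and column for
    missing columns, non-numeric values and negative quantities.
    """
    if schema_name not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_name!r}; expected one of {sorted(SCHEMAS)}")
    schema = SCHEMAS[schema_name]
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    missing = [c for c in schema.columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing} for schema {schema_name!r}")
    for col in schema.numeric_columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()]
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric value in column {col!r} at row {int(bad[0])}"
            )
        df[col] = coerced
    for col in schema.nonneg_columns:
        bad = df.index[df[col] < 0]
        if len(bad):
            raise SchemaError(
                f"{path}: negative value in column {col!r} at row {int(bad[0])}"
            )
    return df


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config_hash: str | None = None,
) -> Path:
    """Write a CSV with provenance comment headers; full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = [f"# resrisk {__version__}"]
    if seed is not None:
        header.append(f"# seed={seed}")
    if config_hash is not None:
        header.append(f"# config_hash={config_hash}")
    with open(path, "w", newline="") as fh:
        fh.write("\n".join(header) + "\n")
        # shortest round-trippable float representation
        df.to_csv(fh, index=False, float_format=lambda v: repr(float(v)))
    return path


_INPUT_KEYS = (
    "calibration_csv",
    "recovery_csv",
    "decay_csv",
    "residue_csv",
    "residue_summary_csv",
    "subgroups_csv",
    "toxicology_csv",
    "consumption_csv",
)


class RunConfig(BaseModel):
    """Configuration of a full pipeline run (YAML-compatible key-value)."""

    calibration_csv: Path
    recovery_csv: Path
    decay_csv: Path
    residue_csv: Path
    residue_summary_csv: Path
    subgroups_csv: Path
    toxicology_csv: Path
    consumption_csv: Path
    output_dir: Path
    censor_policy: Literal["drop", "half_loq", "loq"] = "half_loq"
    variability_factor: float = Field(default=3.0, ge=1)
    loq: float = Field(default=0.05, ge=0)
    n_iter: int = Field(default=1000, ge=1)
    seed: int = 0
    percentile_levels: list[str] = list(DEFAULT_PERCENTILE_LEVELS)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        """Load from YAML; relative paths resolve against the config file."""
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent
        for key in list(raw):
            if key.endswith(("_csv", "_dir")) and raw[key] is not None:
                p = Path(raw[key])
                raw[key] = p if p.is_absolute() else base / p
        config = cls(**raw)
        for key in _INPUT_KEYS:
            p = getattr(config, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"input file for {key} not found: {p}")
        return config

    def content_hash(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in self.model_dump().items()}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _subgroups_from_table(df: pd.DataFrame, default_v: float) -> list[PopulationSubgroup]:
    return [
        PopulationSubgroup(
            name=str(r["name"]),
            bw=float(r["bw_kg"]),
            lp=float(r["lp_kg_per_day"]),
            fi=float(r["fi_kg_per_day"]),
            variability_factor=float(r["v"]) if "v" in df.columns else default_v,
        )
        for _, r in df.iterrows()
    ]


def _toxicology_from_table(df: pd.DataFrame) -> list[ToxicologyReference]:
    return [
        ToxicologyReference(
            compound=str(r["compound"]),
            adi=float(r["adi_mg_per_kg_bw_day"]),
            arfd=float(r["arfd_mg_per_kg_bw"]),
        )
        for _, r in df.iterrows()
    ]


def _residue_summaries_from_table(df: pd.DataFrame) -> list[ResidueSummary]:
    return [
        ResidueSummary(
            compound=str(r["compound"]),
            hr=float(r["hr_mg_per_kg"]),
            stmr=float(r["stmr_mg_per_kg"]),
        )
        for _, r in df.iterrows()
    ]


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run validate -> dissipation -> deterministic -> probabilistic -> summary.

    Writes one CSV per stage plus a combined summary into
    ``config.output_dir`` and returns the output paths.  On a stage
    failure, outputs of completed stages are retained and
    :class:`PipelineError` is raised naming the stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.content_hash()
    outputs: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        outputs[name] = write_table(df, out / f"{name}.csv", seed=config.seed, config_hash=chash)

    stage = "validation"
    try:
        calibration = load_table(config.calibration_csv, "calibration")
        recovery = load_table(config.recovery_csv, "recovery")
        _write(stage, validation_report(calibration, recovery))

        stage = "dissipation"
        decay = load_table(config.decay_csv, "decay")
        series = DissipationSeries.from_frame(decay, loq=config.loq)
        _write(stage, summarize_fits(series, censor_policy=config.censor_policy))

        stage = "deterministic_risk"
        summaries = _residue_summaries_from_table(
            load_table(config.residue_summary_csv, "residue_summary")
        )
        subgroups = _subgroups_from_table(
            load_table(config.subgroups_csv, "subgroups"), config.variability_factor
        )
        toxicology = _toxicology_from_table(load_table(config.toxicology_csv, "toxicology"))
        deterministic = risk_table(summaries, subgroups, toxicology)
        _write(stage, deterministic)

        stage = "probabilistic_risk"
        residue = load_table(config.residue_csv, "residue")
        consumption = load_table(config.consumption_csv, "consumption")
        frames = []
        for mode in ("acute", "chronic"):
            reports, errors = stratified_run(
                subgroups,
                residue,
                consumption,
                toxicology,
                mode=mode,
                n_iter=config.n_iter,
                seed=config.seed,
                levels=config.percentile_levels,
                censor_policy=config.censor_policy,
                loq=config.loq,
            )
            if errors:
                raise PipelineError(f"probabilistic stage errors: {errors}")
            frames.extend(r.to_frame(mode=mode) for r in reports)
        probabilistic = pd.concat(frames, ignore_index=True)
        _write(stage, probabilistic)

        stage = "summary"
        summary = pd.concat(
            [
                deterministic.assign(stage="deterministic"),
                probabilistic.assign(stage="probabilistic"),
            ],
            ignore_index=True,
        )
        _write(stage, summary)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return outputs


def write_example_inputs(outdir: str | Path, seed: int = 0, n_iter: int = 1000) -> Path:
    """Write the packaged synthetic study fixture and its run config.

    Generates every input table with :func:`resrisk.synthetic.make_study_tables`
    under ``outdir`` and writes a ``config.yaml`` pointing at them;
    returns the config path.
    """
    from .synthetic import make_study_tables

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = make_study_tables(seed=seed)
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    config = {
        **{f"{name}_csv": f"{name}.csv" for name in tables},
        "output_dir": "outputs",
        "censor_policy": "half_loq",
        "variability_factor": 3.0,
        "loq": 0.05,
        "n_iter": n_iter,
        "seed": seed,
        "percentile_levels": list(DEFAULT_PERCENTILE_LEVELS),
    }
    config_path = outdir / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return config_path
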