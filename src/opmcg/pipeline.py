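"""Configuration, feature-table IO and seeded end-to-end orchestration.

The pipeline composes the package end to end: simulate (or load) -> filter
and average -> map and extract the 65 parameters -> Delta table -> screen ->
stability-select -> final fit -> validate.  Every run is reproducible from
its echoed config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import make_sensor_grid
from .exceptions import FormatError, InvalidArgumentError, OpmcgError
from .features import (
    DELTA_NAMES,
    compute_parameters,
    delta_parameters,
    locate_fiducials,
)
from .model import (
    LAMBDA_MAX,
    LAMBDA_MIN,
    AnginaLassoModel,
    feature_columns,
)
from .preprocess import preprocess_recording
from .simulate import Cohort, CohortSpec, generate_cohort, generate_feature_table


@dataclass
class PipelineConfig:
    """All knobs of one end-to-end run.

    ``mode`` selects the input: "table" (a Delta-feature table, synthetic or
    from ``input_path``) or "recordings" (synthetic raw pre/post scans run
    through the full signal pipeline).
    """

    mode: str = "table"
    input_path: str | None = None
    seed: int = 0
    # cohort (synthetic inputs)
    n_subjects: int = 363
    prevalence: float = 0.369
    # signal chain
    band: tuple[float, float] = (1.0, 40.0)
    notch: float = 50.0
    window_ms: tuple[float, float] = (-300.0, 500.0)
    rejection_z: float = 3.0
    # mapping / features
    resolution: float = 4.0
    area_fraction: float = 0.5
    amplitude: str = "absmax"
    signed_angles: bool = True
    # model
    var_threshold: float = 0.10
    corr_threshold: float = 0.9
    n_boot: int = 1000
    selection_threshold: float = 0.7
    n_folds: int = 10
    repeats: int = 10
    lambda_bounds: tuple[float, float] = (LAMBDA_MIN, LAMBDA_MAX)
    # validation
    n_boot_roc: int = 1000
    strata: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if self.mode not in ("table", "recordings"):
            raise InvalidArgumentError(f"unknown mode {self.mode!r}")
        if not 0.0 < self.prevalence < 1.0:
            raise InvalidArgumentError("prevalence must be in (0, 1)")
        if not 0.0 < self.area_fraction <= 1.0:
            raise InvalidArgumentError("area_fraction must be in (0, 1]")
        if not 0.0 < self.selection_threshold <= 1.0:
            raise InvalidArgumentError("selection_threshold must be in (0, 1]")
        lo, hi = self.lambda_bounds
        if lo < LAMBDA_MIN - 1e-12 or hi > LAMBDA_MAX + 1e-12 or lo >= hi:
            raise InvalidArgumentError(
                f"lambda bounds must lie within [{LAMBDA_MIN}, {LAMBDA_MAX}]")
        if not self.band[0] < self.band[1]:
            raise InvalidArgumentError("band must satisfy low < high")
        if self.n_boot < 1 or self.n_folds < 2 or self.repeats < 1:
            raise InvalidArgumentError("n_boot, n_folds, repeats out of range")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        d["window_ms"] = list(self.window_ms)
        d["lambda_bounds"] = list(self.lambda_bounds)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("band", "window_ms", "lambda_bounds"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# Feature-table IO
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a Delta-feature CSV; unknown columns are preserved as strata.

    Requires a ``label`` column with binary values and unique
    ``subject_id`` values when present.
    """
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise FormatError("feature table is missing the 'label' column")
    if not np.isin(df["label"].to_numpy(), (0, 1)).all():
        raise FormatError("label column must be binary 0/1")
    if "subject_id" in df.columns and df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise FormatError(f"duplicate subject ids: {dupes[:5]}")
    return df


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table as CSV (lossless round-trip with read)."""
    table.to_csv(path, index=False)


def canonical_delta_columns(table: pd.DataFrame) -> list[str]:
    """The canonical Delta-parameter columns present in a table."""
    return [c for c in table.columns if c in DELTA_NAMES]


# ---------------------------------------------------------------------------
# Raw-recording branch
# ---------------------------------------------------------------------------

def extract_delta_table(cohort: Cohort, config: PipelineConfig | None = None
                        ) -> pd.DataFrame:
    """Full signal pipeline for every subject: pre/post scans -> Delta row.

    Failures carry the stage name and subject id so a bad scan can be
    traced.
    """
    config = config or PipelineConfig(mode="recordings")
    grid = make_sensor_grid()
    rows = []
    for subj in cohort.subjects:
        vectors = {}
        for stage, rec in (("pre", subj.pre), ("post", subj.post)):
            try:
                beat = preprocess_recording(
                    rec, band=config.band, notch=config.notch,
                    window_ms=config.window_ms, rejection_z=config.rejection_z)
                fid = locate_fiducials(beat)
                vectors[stage] = compute_parameters(
                    beat, grid, fid, resolution=config.resolution,
                    area_fraction=config.area_fraction,
                    amplitude=config.amplitude,
                    signed_angles=config.signed_angles)
            except OpmcgError as exc:
                raise type(exc)(
                    f"[{stage} scan of subject {subj.subject_id}] {exc}") from exc
        delta = delta_parameters(vectors["pre"], vectors["post"])
        row = {"subject_id": subj.subject_id, **delta.to_series().to_dict(),
               "label": subj.label}
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end run
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    """Self-contained record of one pipeline run (re-runnable from config)."""

    config: dict
    screen: dict
    selection: dict
    selected: list[str]
    final_model: dict | None
    validation: dict | None
    version: str
    runtime_s: float

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the configured pipeline end to end, deterministically."""
    config.validate()
    t0 = time.perf_counter()

    if config.mode == "recordings":
        spec = CohortSpec(n_subjects=config.n_subjects,
                          prevalence=config.prevalence, seed=config.seed)
        cohort = generate_cohort(spec)
        table = extract_delta_table(cohort, config)
    elif config.input_path is not None:
        table = read_feature_table(config.input_path)
    else:
        table = generate_feature_table(n=config.n_subjects,
                                       prevalence=config.prevalence,
                                       seed=config.seed)

    results = AnginaLassoModel(
        table, var_threshold=config.var_threshold,
        corr_threshold=config.corr_threshold,
    ).fit(n_boot=config.n_boot, n_folds=config.n_folds,
          selection_threshold=config.selection_threshold,
          repeats=config.repeats, seed=config.seed)

    validation = None
    if results.final_model is not None:
        report = results.validate(strata=config.strata or None,
                                  n_boot_roc=config.n_boot_roc)
        validation = report.to_dict()

    sel = results.selection
    return RunReport(
        config=config.to_dict(),
        screen={
            "variance_dropped": list(results.screen_report.variance_dropped),
            "correlation_dropped": [list(p) for p in
                                    results.screen_report.correlation_dropped],
            "surviving": list(results.screen_report.surviving),
        },
        selection={
            "n_boot": sel.n_boot,
            "counts": {n: int(c) for n, c in zip(sel.feature_names, sel.counts)},
        },
        selected=list(results.selected),
        final_model=results.final_model.to_dict() if results.final_model else None,
        validation=validation,
        version=__version__,
        runtime_s=time.perf_counter() - t0,
    )
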