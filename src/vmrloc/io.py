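"""Plain-text file formats for datasets and results.

Everything is CSV + YAML: a trial table (one row per reach), optional
per-trial trace CSVs (columns ``t_ms,x_cm,y_cm``) indexed by a manifest,
report CSVs (pointer or 2AFC), and YAML sidecars for the experiment
configuration and the generator's ground-truth parameters.  A loader for
an externally deposited layout is available through a configurable column
mapping, since such layouts vary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Optional

import numpy as np
import pandas as pd
import yaml

from .config import ExperimentConfig, SimParams
from .kinematics import KinematicTrace
from .schedule import TRIAL_COLUMNS
from .simulate import (AFC_REPORT_COLUMNS, POINTER_REPORT_COLUMNS,
                       SimulatedDataset, build_trace)

TRACE_COLUMNS = ["t_ms", "x_cm", "y_cm"]
_VALID_CYCLE_TYPES = {"baseline", "adaptation", "washout"}
_VALID_ROTATION_DIRS = {"cw", "ccw", "none"}


class LoadError(RuntimeError):
    """Input files violate the documented schemas; message lists all violations."""


@dataclass
class DatasetBundle:
    """In-memory dataset: trial table, reports, and a trace source."""

    trials: pd.DataFrame
    pointer_reports: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=POINTER_REPORT_COLUMNS))
    afc_reports: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=AFC_REPORT_COLUMNS))
    trace_source: Optional[Callable[[int], KinematicTrace]] = None
    trace_ids: Optional[list[int]] = None
    trace_iter: Optional[Callable[[], Iterator[KinematicTrace]]] = None
    config: Optional[ExperimentConfig] = None
    params: Optional[SimParams] = None

    @property
    def experiment_id(self) -> str:
        return str(self.trials.experiment_id.iloc[0])

    def iter_traces(self) -> Iterator[KinematicTrace]:
        if self.trace_iter is not None:
            yield from self.trace_iter()
            return
        for tid in self.trial_ids_with_traces():
            yield self.trace_source(tid)

    def trial_ids_with_traces(self) -> list[int]:
        if self.trace_ids is not None:
            return list(self.trace_ids)
        return [int(t) for t in self.trials.trial_id]


def bundle_from_simulation(dataset: SimulatedDataset) -> DatasetBundle:
    return DatasetBundle(trials=dataset.trials,
                         pointer_reports=dataset.pointer_reports,
                         afc_reports=dataset.afc_reports,
                         trace_source=dataset.trace,
                         trace_iter=dataset.iter_traces,
                         config=dataset.config, params=dataset.params)


def write_dataset(dataset: SimulatedDataset, outdir: str | os.PathLike,
                  traces: bool = False, truth: bool = True) -> Path:
    """Write a simulated dataset to a directory of CSV/YAML files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.trials.to_csv(out / "trials.csv", index=False)
    if truth:
        dataset.truth.to_csv(out / "truth.csv", index=False)
    if len(dataset.pointer_reports):
        dataset.pointer_reports.to_csv(out / "pointer_reports.csv", index=False)
    if len(dataset.afc_reports):
        dataset.afc_reports.to_csv(out / "afc_reports.csv", index=False)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataset.config.to_dict(), fh, sort_keys=True)
    with open(out / "params.yaml", "w") as fh:
        yaml.safe_dump({**dataset.params.to_dict(), "seed_used": dataset.seed},
                       fh, sort_keys=True)
    if traces:
        tdir = out / "traces"
        tdir.mkdir(exist_ok=True)
        manifest = []
        for trace in dataset.iter_traces():
            name = f"trial_{trace.trial_id:06d}.csv"
            pd.DataFrame({"t_ms": trace.t_ms, "x_cm": trace.xy_cm[:, 0],
                          "y_cm": trace.xy_cm[:, 1]}).to_csv(tdir / name, index=False)
            manifest.append(dict(trial_id=trace.trial_id, path=f"traces/{name}"))
        pd.DataFrame(manifest).to_csv(out / "trace_manifest.csv", index=False)
    return out


def read_trace(path: str | os.PathLike, home_xy_cm=(0.0, 0.0),
               trial_id: Optional[int] = None) -> KinematicTrace:
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise LoadError(f"{path}: trace missing columns {sorted(missing)}")
    t = df["t_ms"].to_numpy(dtype=float)
    if t.size >= 2:
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], atol=1e-9):
            bad = int(np.argmax(~np.isclose(dt, dt[0]))) + 1
            raise LoadError(f"{path}: non-uniform sampling at row {bad} "
                            f"(dt={dt[bad - 1]:g} ms, expected {dt[0]:g} ms)")
    return KinematicTrace(t_ms=t, xy_cm=df[["x_cm", "y_cm"]].to_numpy(dtype=float),
                          home_xy_cm=tuple(home_xy_cm), trial_id=trial_id)


def _check_columns(df: pd.DataFrame, required, label: str, errors: list) -> None:
    missing = set(required) - set(df.columns)
    if missing:
        errors.append(f"{label}: missing columns {sorted(missing)}")


def read_dataset(indir: str | os.PathLike) -> DatasetBundle:
    """Load a dataset directory, validating all schemas.

    All violations are collected and reported together in a single
    :class:`LoadError`.
    """
    ind = Path(indir)
    errors: list[str] = []
    trials_path = ind / "trials.csv"
    if not trials_path.exists():
        raise LoadError(f"{trials_path} not found")
    trials = pd.read_csv(trials_path)
    _check_columns(trials, TRIAL_COLUMNS, "trials.csv", errors)
    if not errors:
        bad_ct = trials.loc[~trials.cycle_type.isin(_VALID_CYCLE_TYPES)]
        for idx, row in bad_ct.iterrows():
            errors.append(f"trials.csv row {idx + 2}: unknown cycle_type "
                          f"{row.cycle_type!r}")
        bad_rd = trials.loc[~trials.rotation_dir.isin(_VALID_ROTATION_DIRS)]
        for idx, row in bad_rd.iterrows():
            errors.append(f"trials.csv row {idx + 2}: unknown rotation_dir "
                          f"{row.rotation_dir!r}")
    pointer_reports = pd.DataFrame(columns=POINTER_REPORT_COLUMNS)
    prp = ind / "pointer_reports.csv"
    if prp.exists():
        pointer_reports = pd.read_csv(prp)
        if len(pointer_reports):
            _check_columns(pointer_reports, POINTER_REPORT_COLUMNS,
                           "pointer_reports.csv", errors)
    afc_reports = pd.DataFrame(columns=AFC_REPORT_COLUMNS)
    afp = ind / "afc_reports.csv"
    if afp.exists():
        afc_reports = pd.read_csv(afp)
        if len(afc_reports):
            _check_columns(afc_reports, AFC_REPORT_COLUMNS, "afc_reports.csv", errors)
    config = params = None
    if (ind / "config.yaml").exists():
        with open(ind / "config.yaml") as fh:
            config = ExperimentConfig.from_dict(yaml.safe_load(fh))
    if (ind / "params.yaml").exists():
        with open(ind / "params.yaml") as fh:
            d = yaml.safe_load(fh)
            d.pop("seed_used", None)
            params = SimParams.from_dict(d)
    trace_source = None
    trace_ids = None
    manifest_path = ind / "trace_manifest.csv"
    if manifest_path.exists():
        manifest = pd.read_csv(manifest_path)
        _check_columns(manifest, ["trial_id", "path"], "trace_manifest.csv", errors)
        if not errors:
            home = tuple(config.home_xy_cm) if config else (0.0, 0.0)
            paths = dict(zip(manifest.trial_id.astype(int), manifest.path))
            trace_ids = sorted(paths)
            # validate every referenced trace up front so violations are
            # reported together with names
            for tid, rel in paths.items():
                try:
                    read_trace(ind / rel, home, tid)
                except LoadError as exc:
                    errors.append(f"trial {tid}: {exc}")

            def trace_source(tid, _paths=paths, _home=home, _ind=ind):
                return read_trace(_ind / _paths[int(tid)], _home, int(tid))
    elif (truth_path := ind / "truth.csv").exists():
        truth = pd.read_csv(truth_path)
        _check_columns(truth, ["trial_id", "executed_direction_deg", "extent_cm",
                               "duration_ms", "curvature"], "truth.csv", errors)
        if not errors:
            home = tuple(config.home_xy_cm) if config else (0.0, 0.0)
            fs = params.sample_rate_hz if params else 1000.0
            tr = truth.set_index("trial_id")
            trace_ids = [int(t) for t in truth.trial_id]

            def trace_source(tid, _tr=tr, _home=home, _fs=fs):
                r = _tr.loc[int(tid)]
                return build_trace(r.executed_direction_deg, r.extent_cm,
                                   r.duration_ms, home_xy_cm=_home,
                                   sample_rate_hz=_fs, curvature=r.curvature,
                                   trial_id=int(tid))
    if errors:
        raise LoadError("dataset validation failed:\n  " + "\n  ".join(errors))
    return DatasetBundle(trials=trials, pointer_reports=pointer_reports,
                         afc_reports=afc_reports, trace_source=trace_source,
                         trace_ids=trace_ids, config=config, params=params)


def read_deposited_trial_table(path: str | os.PathLike,
                               column_map: dict[str, str]) -> pd.DataFrame:
    """Adapter for an externally deposited trial table.

    ``column_map`` maps the deposit's column names to this package's
    trial-table schema (values must be names from ``TRIAL_COLUMNS``); the
    mapping is configuration, not code, because deposited layouts differ.
    """
    df = pd.read_csv(path).rename(columns=column_map)
    unknown = set(column_map.values()) - set(TRIAL_COLUMNS)
    if unknown:
        raise LoadError(f"column_map targets unknown schema columns {sorted(unknown)}")
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise LoadError(f"{path}: mapped table missing columns {sorted(missing)}")
    return df[TRIAL_COLUMNS]
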