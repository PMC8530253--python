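"""End-to-end study pipeline: simulate/load → build → metrics → compare.

One YAML config drives a full run; every run writes one manifest capturing
the config snapshot, input hashes and per-stage counts, and reruns with
identical inputs and config reproduce identical output bytes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .audit_log import (
    DEFAULT_PERIODS,
    AuditLogError,
    StudyPeriod,
    check_periods,
    filter_patients,
    partition_by_period,
    read_events,
    read_patients,
    roster_from_events,
    to_patient_days,
    write_events,
    write_patients,
)
from .comparison import (
    DEFAULT_SPECIALTIES,
    network_level_compare,
    outcomes_compare,
    results_frame,
    specialty_level_compare,
    text_report,
)
from .network import build_network, network_stats, write_edgelist_csv, write_gexf, write_graphml
from .sociometrics import compute_sociometrics, summarize_by_specialty, write_sociometrics
from .synthetic import RegimeConfig, generate_regime, preset

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


DEFAULT_CONFIG: dict[str, Any] = {
    "periods": {
        "pre": {"start": "2019-09-01", "end": "2019-12-31"},
        "intra": {"start": "2020-03-01", "end": "2020-06-30"},
    },
    "day_binning": "calendar",
    "timezone": "UTC",
    "analysis": {
        "weighted_eigenvector": False,
        "alternative": "two_sided",
        "min_weight": 1,
    },
}


def demo_config(n_patients: int = 50, seed: int = 7) -> dict[str, Any]:
    """The shipped demo: simulate both presets and compare them."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    cfg["simulate"] = {
        "seed": seed,
        "pre": {"preset": "pre_like", "n_patients": n_patients},
        "intra": {"preset": "intra_like", "n_patients": n_patients},
    }
    return cfg


def _merge_defaults(user: Mapping[str, Any]) -> dict[str, Any]:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    user = json.loads(json.dumps(user, default=str))
    for key, val in user.items():
        if isinstance(val, Mapping) and isinstance(cfg.get(key), dict):
            cfg[key] = {**cfg[key], **val}
        else:
            cfg[key] = val
    return cfg


def load_config(path: str) -> dict[str, Any]:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge_defaults(user)


def periods_from_config(cfg: Mapping[str, Any]) -> list[StudyPeriod]:
    periods = [
        StudyPeriod(label, pd.Timestamp(w["start"]).date(),
                    pd.Timestamp(w["end"]).date())
        for label, w in cfg["periods"].items()
    ]
    check_periods(periods)
    return periods


def _regime_config(block: Mapping[str, Any], period: StudyPeriod) -> RegimeConfig:
    cfg = preset(block.get("preset", "pre_like"))
    overrides = {k: v for k, v in block.items() if k != "preset"}
    d = cfg.to_dict()
    d.update(overrides)
    d["admission_start"] = period.start.isoformat()
    d["admission_end"] = period.end.isoformat()
    return RegimeConfig.from_dict(d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: str | Mapping[str, Any],
    out_dir: str,
    seed: int | None = None,
) -> Path:
    """Run the full study described by ``config``; returns the output dir.

    The config either names existing ``inputs`` (events/patients CSVs) or
    carries a ``simulate`` block with one regime per period.  Outputs per
    period: the simulated CSVs (if any), the network in GraphML/GEXF/edge
    list form, the per-clinician sociometric table and per-specialty
    summary; study-wide: the comparison CSV, a text report and the run
    manifest.
    """
    if config is None or isinstance(config, (str, Path)):
        cfg = load_config(config) if config is not None else dict(DEFAULT_CONFIG)
    else:
        cfg = _merge_defaults(json.loads(json.dumps(dict(config))))
    if seed is not None and "simulate" in cfg:
        cfg["simulate"]["seed"] = int(seed)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "tool": "collabnet",
        "version": __version__,
        "config": cfg,
        "inputs": {},
        "stages": {},
        "warnings": [],
    }
    t0 = time.perf_counter()

    if cfg.get("day_binning", "calendar") != "calendar":
        raise PipelineError("config", "only day_binning: calendar is supported")
    try:
        periods = periods_from_config(cfg)
    except AuditLogError as exc:
        _write_manifest(manifest, out, failed_stage="config")
        raise PipelineError("config", str(exc)) from exc

    # --- stage: acquire events/patients -----------------------------------
    try:
        if "simulate" in cfg:
            events, patients = _simulate(cfg, periods, out, manifest)
            events_path, patients_path = out / "events.csv", out / "patients.csv"
        else:
            events_path = Path(cfg["inputs"]["events"])
            patients_path = Path(cfg["inputs"]["patients"])
            events, report = read_events(events_path, timezone=cfg.get("timezone"))
            manifest["stages"]["read_events"] = {
                "read": report.n_read, "accepted": report.n_accepted,
                "rejected": report.n_rejected,
            }
            patients, preport = read_patients(patients_path)
            manifest["stages"]["read_patients"] = {
                "read": preport.n_read, "accepted": preport.n_accepted,
                "rejected": preport.n_rejected,
            }
        manifest["inputs"] = {
            p.name: _sha256(p) for p in (events_path, patients_path) if p.exists()
        }
    except (OSError, KeyError, ValueError) as exc:
        _write_manifest(manifest, out, failed_stage="acquire")
        raise PipelineError("acquire", str(exc)) from exc

    # --- stage: filter + partition ----------------------------------------
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        events, n_excluded = filter_patients(events, patients)
    manifest["warnings"] += [str(w.message) for w in caught]
    by_period, dropped = partition_by_period(events, periods)
    manifest["stages"]["partition"] = {
        **{lab: len(df) for lab, df in by_period.items()},
        "dropped": len(dropped), "excluded_patients": n_excluded,
    }

    roster = roster_from_events(events)
    analysis = cfg.get("analysis", {})
    tables: dict[str, pd.DataFrame] = {}
    patients_by_period: dict[str, pd.DataFrame] = {}

    for period in periods:
        lab = period.label
        try:
            units = to_patient_days(by_period[lab])
            net = build_network(units, roster, period_label=lab,
                                min_weight=int(analysis.get("min_weight", 1)))
            stats = network_stats(net)
            table = compute_sociometrics(
                net, use_weights=bool(analysis.get("weighted_eigenvector", False)))
        except ValueError as exc:
            _write_manifest(manifest, out, failed_stage=f"network[{lab}]")
            raise PipelineError(f"network[{lab}]", str(exc)) from exc
        manifest["stages"][f"network[{lab}]"] = {
            "patient_days": len(units), "nodes": stats.n_nodes,
            "edges": stats.n_edges, "total_weight": stats.total_weight,
            "components": stats.n_components,
        }
        write_graphml(net, out / f"network_{lab}.graphml")
        write_gexf(net, out / f"network_{lab}.gexf")
        write_edgelist_csv(net, out / f"network_{lab}_edges.csv")
        write_sociometrics(table, out / f"sociometrics_{lab}.csv")
        summarize_by_specialty(table).to_csv(
            out / f"specialty_summary_{lab}.csv", index=False, float_format="%.10g")
        tables[lab] = table
        mask = patients["admit_date"].map(period.contains)
        patients_by_period[lab] = patients.loc[mask &
                                               ~patients["excluded"].astype(bool)]

    # --- stage: comparison -------------------------------------------------
    pre_lab, intra_lab = periods[0].label, periods[1].label
    try:
        results = specialty_level_compare(
            tables[pre_lab], tables[intra_lab],
            specialties=tuple(analysis.get("specialties", DEFAULT_SPECIALTIES)),
            alternative=analysis.get("alternative", "two_sided"))
        results += network_level_compare(
            tables[pre_lab], tables[intra_lab],
            alternative=analysis.get("alternative", "two_sided"))
        outcome_results, descriptive = outcomes_compare(
            patients_by_period[pre_lab], patients_by_period[intra_lab],
            alternative=analysis.get("alternative", "two_sided"))
        results += outcome_results
    except ValueError as exc:
        _write_manifest(manifest, out, failed_stage="comparison")
        raise PipelineError("comparison", str(exc)) from exc

    frame = results_frame(results)
    frame.to_csv(out / "comparison.csv", index=False, float_format="%.10g")
    descriptive.to_csv(out / "cohort_table.csv", index=False)
    (out / "report.txt").write_text(text_report(results, descriptive))
    manifest["stages"]["comparison"] = {
        "tests": len(frame),
        "significant": int((frame["p_adjusted"] < 0.05).sum()),
    }
    logger.info("pipeline finished in %.1fs", time.perf_counter() - t0)
    _write_manifest(manifest, out)
    return out


def _simulate(cfg, periods, out: Path, manifest) -> tuple[pd.DataFrame, pd.DataFrame]:
    sim = cfg["simulate"]
    seed = int(sim.get("seed", 0))
    all_events, all_patients = [], []
    sim_configs = {}
    for period in periods:
        block = sim.get(period.label)
        if block is None:
            raise PipelineError("simulate", f"no simulate block for period "
                                f"{period.label!r}")
        rc = _regime_config(block, period)
        patients, roster, events = generate_regime(rc, seed)
        sim_configs[period.label] = rc.to_dict()
        manifest["stages"][f"simulate[{period.label}]"] = {
            "patients": len(patients), "events": len(events),
            "clinicians": int(events["clinician_id"].nunique()),
        }
        all_events.append(events)
        all_patients.append(patients)
    events = pd.concat(all_events, ignore_index=True)
    patients = pd.concat(all_patients, ignore_index=True)
    write_events(events, out / "events.csv")
    write_patients(patients, out / "patients.csv")
    with open(out / "simulate_config.yaml", "w") as fh:
        yaml.safe_dump({"seed": seed, "regimes": sim_configs}, fh,
                       sort_keys=True)
    return events, patients


def _write_manifest(manifest: dict, out: Path, failed_stage: str | None = None) -> None:
    if failed_stage:
        manifest["failed_stage"] = failed_stage
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
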