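"""Configuration validation, orchestration, and report generation.

A run is described by one YAML file; every run directory receives the
exact config and seed used, so re-running the directory reproduces the
report bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import prognosis, recist_engine, segnet
from .phantoms import PhantomConfig
from .recist_engine import RecistParams

log = logging.getLogger("desep")


def setup_logging(verbosity: int = 1):
    logging.basicConfig(
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        level=logging.DEBUG if verbosity > 1 else logging.INFO)


@dataclass
class RunConfig:
    seed: int
    phantoms: PhantomConfig
    net: segnet.UNetConfig
    desep: prognosis.DesepConfig
    recist: RecistParams
    endpoints: tuple = prognosis.ENDPOINTS
    out_dir: str = "desep_run"
    verbosity: int = 1


_SECTIONS = {
    "phantoms": PhantomConfig,
    "net": segnet.UNetConfig,
    "desep": prognosis.DesepConfig,
    "recist": RecistParams,
}


class ConfigError(ValueError):
    pass


def _build_section(cls, data: dict, section: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"{section}: unknown keys {sorted(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            if isinstance(v, list):
                v = tuple(v)
            coerced[f.name] = v
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"{section}: {e}") from e


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML run config; defaults fill missing keys.

    The seed is mandatory — a run without it is not reproducible.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    known = set(_SECTIONS) | {"seed", "endpoints", "out_dir", "verbosity"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level keys {sorted(unknown)}")
    if "seed" not in raw:
        raise ConfigError("seed required for reproducibility")
    seed = int(raw["seed"])
    sections = {}
    for name, cls in _SECTIONS.items():
        data = dict(raw.get(name, {}))
        data.setdefault("seed", seed) if "seed" in {
            f.name for f in dataclasses.fields(cls)} else None
        sections[name] = _build_section(cls, data, name)
    endpoints = tuple(raw.get("endpoints", prognosis.ENDPOINTS))
    bad = set(endpoints) - set(prognosis.ENDPOINTS)
    if bad:
        raise ConfigError(f"endpoints: unknown {sorted(bad)}")
    if not endpoints:
        raise ConfigError("endpoints: empty list")
    return RunConfig(seed=seed, phantoms=sections["phantoms"],
                     net=sections["net"], desep=sections["desep"],
                     recist=sections["recist"], endpoints=endpoints,
                     out_dir=str(raw.get("out_dir", "desep_run")),
                     verbosity=int(raw.get("verbosity", 1)))


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if np.isfinite(v) else str(v)
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj


def build_report(run_output: dict, run_config: RunConfig | None,
                 out_dir) -> Path:
    """Write the report bundle: JSON summary + per-patient prediction CSV.

    Partial runs (an endpoint skipped) are flagged in the JSON rather than
    failing the whole bundle.
    """
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    endpoints = run_output.get("endpoints", {})
    if not endpoints:
        raise ValueError("run produced no endpoint results")
    rows = []
    summary = {"seed": run_output.get("config_seed"),
               "k_selected": run_output.get("k_selected"),
               "silhouette_scores": run_output.get("silhouette_scores"),
               "partial": False, "endpoints": {}}
    if run_config is not None:
        summary["config"] = _jsonable(run_config)
    expected = run_config.endpoints if run_config else list(endpoints)
    for ep in expected:
        if ep not in endpoints:
            summary["partial"] = True
            summary["endpoints"][ep] = None
            continue
        r = endpoints[ep]
        summary["endpoints"][ep] = {
            "harrells_c": r.harrells_c, "hazard_ratio": r.hr,
            "hr_ci95": r.hr_ci, "logrank_chi2": r.logrank_chi2,
            "logrank_p": r.logrank_p, "n_test": r.n_test,
            "n_high_risk": r.n_high,
            "retained_features": r.retained_features,
            "hr_monotone_flagged": r.hr_monotone_flagged,
        }
        for pr in r.predictions:
            rows.append(dict(patient_id=pr.patient_id, endpoint=ep,
                             probability=pr.probability,
                             risk_group=pr.risk_group, cutoff=pr.cutoff))
    if "recist" in run_output:
        summary["recist"] = _jsonable(run_output["recist"])
    if "phi_lpfs_vs_recist" in run_output:
        summary["phi_lpfs_vs_recist"] = _jsonable(
            run_output["phi_lpfs_vs_recist"])
    (out / "report.json").write_text(
        json.dumps(_jsonable(summary), indent=2, sort_keys=True))
    pd.DataFrame(rows).to_csv(out / "predictions.csv", index=False)
    if run_config is not None:
        (out / "config_used.yaml").write_text(
            yaml.safe_dump(_jsonable(run_config)))
    log.info("report written to %s", out)
    return out


def run_full(run_config: RunConfig) -> dict:
    """Generate a phantom cohort and run phases 1-3 plus the RECIST
    comparison; returns the in-memory run output."""
    from . import survival_stats
    from .phantoms import generate_cohort

    t0 = time.time()
    log.info("generating cohort n=%d", run_config.phantoms.n_patients)
    cohort = generate_cohort(run_config.phantoms)
    log.info("running DESEP phases 1-3")
    out = prognosis.run_desep(cohort, config=run_config.desep,
                              endpoints=run_config.endpoints)
    # RECIST finals on the test patients (ground-truth measurement series)
    by_id = {p.patient_id: p for p in cohort}
    finals = {}
    for pid in out["cv_plan"].test_ids:
        p = by_id[pid]
        if not p.true_diameters or p.true_diameters[0] <= 0:
            continue
        cats = recist_engine.categorize_unidimensional(
            p.measurement_series(), run_config.recist)
        finals[pid] = recist_engine.dichotomize_response(
            recist_engine.worst_category(cats))
    out["recist"] = finals
    ep = out["endpoints"].get("lpfs")
    if ep is not None and finals:
        n = {"11": 0, "12": 0, "21": 0, "22": 0}
        for pr in ep.predictions:
            if pr.patient_id not in finals:
                continue
            hi = pr.risk_group == "high"
            pd_ = finals[pr.patient_id] == "PD"
            key = ("1" if hi else "2") + ("1" if pd_ else "2")
            n[key] += 1
        table = survival_stats.TwoByTwo(n["11"], n["12"], n["21"], n["22"])
        try:
            phi, pval = survival_stats.cramers_phi(table)
            out["phi_lpfs_vs_recist"] = {"phi": phi, "p": pval,
                                         "table": dataclasses.asdict(table)}
        except ValueError:
            out["phi_lpfs_vs_recist"] = {"phi": None, "p": None,
                                         "table": dataclasses.asdict(table)}
    log.info("run finished in %.1fs", time.time() - t0)
    return out
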