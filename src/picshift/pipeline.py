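"""Run orchestration: declarative configs, batch fitting, simulation, recovery.

A run is described by a single YAML/JSON config; every tolerance and
threshold lives there with documented defaults, nothing is hard-coded.  Each
run writes delimited result tables plus two logs: a human-readable
``run.log`` and a machine-readable ``decisions.json`` sidecar recording
every per-replicate decision (model chosen, censoring, flagged lanes,
failed fits) so that every summary value is traceable to a per-replicate
fit in the detail table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import synth, tables
from .equilibria import EquilibriumConstants, MixtureTotals
from .fitting import aggregate_replicates, censor_apparent_kd, compare_isotherms, fit_langmuir
from .gelshift import correct_titration, tc_binding_curve
from .kinetics import extent_at_completion, fit_single_exponential
from .synth import (
    EndpointDesign,
    IsothermDesign,
    NoiseModel,
    TimeCourseDesign,
    TitrationDesign,
)

__all__ = [
    "ConfigError",
    "RunConfig",
    "run_simulate",
    "run_fit_eif3",
    "run_fit_tc",
    "run_fit_kinetics",
    "run_recover",
]

MODES = ("simulate", "fit-eif3", "fit-tc", "fit-kinetics", "recover")
DEFAULT_CENSOR_LIMIT = 30.0  # nM 40S in the eIF3 titration assay
DEFAULT_TOLERANCE = 0.15  # relative recovery tolerance


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (a usage error)."""


@dataclass
class RunConfig:
    mode: str
    outdir: Path
    inputs: dict[str, Path] = field(default_factory=dict)
    fixed_totals: MixtureTotals | None = None
    k3_map: dict[str, float] = field(default_factory=dict)
    censor_limit: float = DEFAULT_CENSOR_LIMIT
    axis: str = "free"
    sigma: float = synth.DEFAULT_SIGMA
    seed: int = 0
    fmt: str = "csv"
    conditions: dict[str, dict[str, Any]] = field(default_factory=dict)
    bundle_dir: Path | None = None
    manifest: Path | None = None
    tolerance: float = DEFAULT_TOLERANCE

    @classmethod
    def load(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        """Load a YAML/JSON config file; keyword overrides win (CLI flags)."""
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        mode = raw.get("mode")
        if mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {mode!r}")
        fixed = None
        if "fixed_totals" in raw:
            ft = raw["fixed_totals"]
            fixed = MixtureTotals(
                float(ft.get("r_total_nM", 0.0)),
                float(ft.get("t_total_nM", 0.0)),
                float(ft.get("e_total_nM", 0.0)),
            )
        cfg = cls(
            mode=mode,
            outdir=Path(raw.get("outdir", "picshift-out")),
            inputs={str(k): Path(v) for k, v in (raw.get("inputs") or {}).items()},
            fixed_totals=fixed,
            k3_map={str(k): float(v) for k, v in (raw.get("k3_nM") or {}).items()},
            censor_limit=float(raw.get("censor_limit_nM", DEFAULT_CENSOR_LIMIT)),
            axis=str(raw.get("axis", "free")),
            sigma=float(raw.get("sigma", synth.DEFAULT_SIGMA)),
            seed=int(raw.get("seed", 0)),
            fmt=str(raw.get("format", "csv")),
            conditions=dict(raw.get("conditions") or {}),
            bundle_dir=Path(raw["bundle_dir"]) if "bundle_dir" in raw else None,
            manifest=Path(raw["manifest"]) if "manifest" in raw else None,
            tolerance=float(raw.get("tolerance", DEFAULT_TOLERANCE)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.fmt not in ("csv", "tsv"):
            raise ConfigError(f"format must be csv or tsv, got {self.fmt!r}")
        if self.axis not in ("free", "total"):
            raise ConfigError(f"axis must be 'free' or 'total', got {self.axis!r}")
        if self.mode in ("fit-eif3", "fit-tc", "fit-kinetics"):
            if not self.inputs:
                raise ConfigError(f"mode {self.mode} requires an 'inputs' mapping")
            for name, path in self.inputs.items():
                if not path.exists():
                    raise ConfigError(f"input file for condition {name!r} not found: {path}")
            if self.mode in ("fit-eif3", "fit-tc") and self.fixed_totals is None:
                raise ConfigError(f"mode {self.mode} requires 'fixed_totals'")
            if self.mode == "fit-eif3" and self.axis == "free":
                missing = [c for c in self.inputs if c not in self.k3_map]
                if missing:
                    raise ConfigError(f"'k3_nM' missing for conditions: {missing}")
        if self.mode == "simulate" and not self.conditions:
            raise ConfigError("mode simulate requires a 'conditions' mapping")
        if self.mode == "recover":
            if self.manifest is None or not self.manifest.exists():
                raise ConfigError("mode recover requires an existing 'manifest' file")
            if self.bundle_dir is None or not self.bundle_dir.is_dir():
                raise ConfigError("mode recover requires an existing 'bundle_dir'")


class _RunLog:
    def __init__(self) -> None:
        self.lines: list[str] = []
        self.events: list[dict[str, Any]] = []

    def note(self, message: str, **event: Any) -> None:
        self.lines.append(message)
        self.events.append({"message": message, **event})

    def write(self, outdir: Path) -> None:
        (outdir / "run.log").write_text("\n".join(self.lines) + "\n")
        (outdir / "decisions.json").write_text(json.dumps(self.events, indent=2) + "\n")


def _ext(cfg: RunConfig) -> str:
    return "tsv" if cfg.fmt == "tsv" else "csv"


def _write(df: pd.DataFrame, cfg: RunConfig, name: str) -> Path:
    path = cfg.outdir / f"{name}.{_ext(cfg)}"
    df.to_csv(path, sep="\t" if cfg.fmt == "tsv" else ",", index=False)
    return path


def _design_from_spec(name: str, spec: Mapping[str, Any]):
    kind = spec.get("kind")
    n_rep = int(spec.get("n_replicates", synth.DEFAULT_N_REPLICATES))
    if kind == "eif3_titration":
        constants = EquilibriumConstants.from_cycle(
            float(spec["k1_nM"]), float(spec["k2_nM"]), float(spec["k3_nM"])
        )
        return TitrationDesign(
            "eif3",
            tuple(spec.get("grid") or synth.default_eif3_grid()),
            constants,
            MixtureTotals(
                float(spec.get("r_total_nM", 30.0)), float(spec.get("t_total_nM", 2.0)), 0.0
            ),
            n_rep,
        )
    if kind == "tc_titration":
        return IsothermDesign(
            tuple(spec.get("grid") or synth.default_40s_grid()),
            float(spec["kd_nM"]),
            float(spec.get("amplitude", 0.8)),
            float(spec.get("hill_n", 1.0)),
            "40s",
            str(spec.get("bound_band", "43s")),
            float(spec.get("tracer_nM", 1.0)),
            n_rep,
        )
    if kind == "timecourse":
        k = float(spec["k_per_min"])
        times = tuple(spec.get("times") or synth.default_time_grid(k))
        return TimeCourseDesign(
            times, float(spec.get("amplitude", 0.8)), k, str(spec.get("mRNA_label", "")), name, n_rep
        )
    if kind == "endpoint":
        return EndpointDesign(
            float(spec["endpoint"]), name, str(spec.get("mRNA_label", "")), n_rep
        )
    raise ConfigError(f"condition {name!r}: unknown kind {kind!r}")


def run_simulate(config: RunConfig) -> Path:
    """Generate a synthetic dataset bundle plus a manifest of true parameters."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    log = _RunLog()
    designs = {
        name: _design_from_spec(name, spec) for name, spec in config.conditions.items()
    }
    bundle = synth.variant_panel(designs, NoiseModel(config.sigma, config.seed))
    manifest: dict[str, dict[str, Any]] = {}
    for name, design in designs.items():
        data = bundle.datasets[name]
        entry = dict(bundle.manifest[name])
        if isinstance(design, (TitrationDesign, IsothermDesign)):
            fname = f"titration_{name}.{_ext(config)}"
            tables.write_titrations(config.outdir / fname, data, config.fmt)
            if isinstance(design, TitrationDesign):
                entry["r_total_nM"] = design.fixed_totals.r_total
                entry["t_total_nM"] = design.fixed_totals.t_total
        elif isinstance(design, TimeCourseDesign):
            fname = f"timecourse_{name}.{_ext(config)}"
            tables.write_timecourses(config.outdir / fname, data, config.fmt)
        else:
            fname = f"endpoint_{name}.{_ext(config)}"
            tables.write_endpoints(
                config.outdir / fname, data, condition=name, fmt=config.fmt
            )
        entry["file"] = fname
        manifest[name] = entry
        log.note(f"simulated condition {name!r} -> {fname}", condition=name, file=fname)
    manifest_path = config.outdir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    log.write(config.outdir)
    return manifest_path


def run_fit_eif3(config: RunConfig) -> pd.DataFrame:
    """Fit eIF3 titrations: correct, fit both isotherms, compare, censor, aggregate."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    log = _RunLog()
    detail_rows: list[dict[str, Any]] = []
    summary_rows: list[dict[str, Any]] = []
    for condition, path in config.inputs.items():
        experiments = tables.read_titrations(
            path, config.fixed_totals, config.k3_map.get(condition)
        )
        k_apps: list[float] = []
        models: list[str] = []
        any_censored = False
        for exp in experiments:
            curve = correct_titration(exp, axis=config.axis)
            n_flagged = int(curve.flags.sum())
            if n_flagged:
                log.note(
                    f"{condition}/{exp.replicate_id}: {n_flagged} lane(s) floored at "
                    "free eIF3 = 0 during correction",
                    condition=condition, replicate=exp.replicate_id, flagged=n_flagged,
                )
            try:
                comparison = compare_isotherms(curve)
            except RuntimeError as err:
                log.note(
                    f"{condition}/{exp.replicate_id}: both isotherm fits failed ({err}); "
                    "replicate excluded from summary",
                    condition=condition, replicate=exp.replicate_id, failed=True,
                )
                continue
            chosen = comparison.hill if comparison.preferred == "hill" else comparison.langmuir
            chosen = censor_apparent_kd(chosen, config.censor_limit)
            any_censored |= chosen.censored
            k_apps.append(chosen.k_app)
            models.append(chosen.model)
            log.note(
                f"{condition}/{exp.replicate_id}: {chosen.model} preferred, "
                f"K_app={chosen.k_app:.3g} nM"
                + (f" (censored <= {chosen.censor_limit:g} nM)" if chosen.censored else ""),
                condition=condition, replicate=exp.replicate_id,
                model=chosen.model, k_app=chosen.k_app, censored=chosen.censored,
            )
            detail_rows.append(
                {
                    "condition": condition,
                    "replicate_id": exp.replicate_id,
                    "model": chosen.model,
                    "K_app_nM": chosen.k_app,
                    "hill_n": chosen.hill_n,
                    "amplitude": chosen.amplitude,
                    "rss": chosen.rss,
                    "censored": chosen.censored,
                    "censor_limit_nM": chosen.censor_limit,
                    "flagged_lanes": n_flagged,
                }
            )
        if not k_apps:
            log.note(f"{condition}: no replicate produced a usable fit", condition=condition)
            continue
        summary = aggregate_replicates(k_apps)
        majority = max(set(models), key=models.count)
        summary_rows.append(
            {
                "condition": condition,
                "model": majority,
                "mean_nM": summary.mean,
                "sem_nM": summary.sem,
                "n_replicates": summary.n,
                "censored": any_censored,
            }
        )
    detail = pd.DataFrame(detail_rows)
    summary = pd.DataFrame(summary_rows)
    _write(detail, config, "eif3_fit_detail")
    _write(summary, config, "eif3_fit_summary")
    log.write(config.outdir)
    return summary


def run_fit_tc(config: RunConfig) -> pd.DataFrame:
    """Fit 40S titrations (TC binding) with the Langmuir isotherm per replicate."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    log = _RunLog()
    detail_rows: list[dict[str, Any]] = []
    summary_rows: list[dict[str, Any]] = []
    for condition, path in config.inputs.items():
        experiments = tables.read_titrations(path, config.fixed_totals)
        kds: list[float] = []
        amplitudes: list[float] = []
        for exp in experiments:
            fit = fit_langmuir(tc_binding_curve(exp))
            if not fit.success:
                log.note(
                    f"{condition}/{exp.replicate_id}: Langmuir fit failed ({fit.message}); "
                    "replicate excluded from summary",
                    condition=condition, replicate=exp.replicate_id, failed=True,
                )
                continue
            kds.append(fit.k_app)
            amplitudes.append(fit.amplitude)
            detail_rows.append(
                {
                    "condition": condition,
                    "replicate_id": exp.replicate_id,
                    "model": fit.model,
                    "K_app_nM": fit.k_app,
                    "amplitude": fit.amplitude,
                    "rss": fit.rss,
                }
            )
        if not kds:
            log.note(f"{condition}: no replicate produced a usable fit", condition=condition)
            continue
        kd_summary = aggregate_replicates(kds)
        amp_summary = aggregate_replicates(amplitudes)
        summary_rows.append(
            {
                "condition": condition,
                "model": "langmuir",
                "mean_nM": kd_summary.mean,
                "sem_nM": kd_summary.sem,
                "endpoint_mean": amp_summary.mean,
                "endpoint_sem": amp_summary.sem,
                "n_replicates": kd_summary.n,
            }
        )
    detail = pd.DataFrame(detail_rows)
    summary = pd.DataFrame(summary_rows)
    _write(detail, config, "tc_fit_detail")
    _write(summary, config, "tc_fit_summary")
    log.write(config.outdir)
    return summary


def run_fit_kinetics(config: RunConfig) -> pd.DataFrame:
    """Fit recruitment time courses with single exponentials and aggregate."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    log = _RunLog()
    detail_rows: list[dict[str, Any]] = []
    summary_rows: list[dict[str, Any]] = []
    for condition, path in config.inputs.items():
        courses = tables.read_timecourses(path)
        rates: list[float] = []
        endpoints: list[float] = []
        for tc in courses:
            fit = fit_single_exponential(tc)
            if not fit.success:
                log.note(
                    f"{condition}/{tc.replicate_id}: exponential fit failed ({fit.message})",
                    condition=condition, replicate=tc.replicate_id, failed=True,
                )
                continue
            if fit.rate_resolved:
                rates.append(fit.k_obs)
            else:
                log.note(
                    f"{condition}/{tc.replicate_id}: reaction faster than time resolution; "
                    "rate excluded, endpoint kept",
                    condition=condition, replicate=tc.replicate_id, rate_resolved=False,
                )
            endpoints.append(fit.endpoint)
            detail_rows.append(
                {
                    "condition": condition,
                    "replicate_id": tc.replicate_id,
                    "mRNA_label": tc.mrna_label,
                    "k_obs_per_min": fit.k_obs if fit.rate_resolved else math.nan,
                    "endpoint": fit.endpoint,
                    "rate_resolved": fit.rate_resolved,
                    "rss": fit.rss,
                }
            )
        if not endpoints:
            log.note(f"{condition}: no replicate produced a usable fit", condition=condition)
            continue
        row: dict[str, Any] = {"condition": condition, "n_replicates": len(endpoints)}
        if rates:
            k_summary = aggregate_replicates(rates)
            row.update(k_mean_per_min=k_summary.mean, k_sem_per_min=k_summary.sem)
        else:
            row.update(k_mean_per_min=math.nan, k_sem_per_min=math.nan)
        e_summary = aggregate_replicates(endpoints)
        row.update(endpoint_mean=e_summary.mean, endpoint_sem=e_summary.sem)
        summary_rows.append(row)
    detail = pd.DataFrame(detail_rows)
    summary = pd.DataFrame(summary_rows)
    _write(detail, config, "kinetics_fit_detail")
    _write(summary, config, "kinetics_fit_summary")
    log.write(config.outdir)
    return summary


def _recover_condition(
    name: str, entry: Mapping[str, Any], config: RunConfig
) -> tuple[str, float, float, float, int]:
    """Recover (parameter, true, estimate, sem, n) for one manifest condition."""
    path = config.bundle_dir / str(entry["file"])
    kind = entry["kind"]
    if kind == "eif3_titration":
        fixed = MixtureTotals(float(entry["r_total_nM"]), float(entry["t_total_nM"]), 0.0)
        experiments = tables.read_titrations(path, fixed, float(entry["k3_nM"]))
        values = []
        for exp in experiments:
            comparison = compare_isotherms(correct_titration(exp, axis=config.axis))
            chosen = comparison.hill if comparison.preferred == "hill" else comparison.langmuir
            values.append(chosen.k_app)
        summary = aggregate_replicates(values)
        return "K2_nM", float(entry["k2_nM"]), summary.mean, summary.sem, summary.n
    if kind in ("40s_titration", "tc_titration"):
        fixed = MixtureTotals(0.0, float(entry.get("t_total_nM", 1.0)), 0.0)
        experiments = tables.read_titrations(path, fixed)
        values = [
            fit_langmuir(tc_binding_curve(exp)).k_app
            for exp in experiments
            if fit_langmuir(tc_binding_curve(exp)).success
        ]
        summary = aggregate_replicates(values)
        true = float(entry["k1_nM"] if kind == "40s_titration" else entry["kd_nM"])
        return "KD_nM", true, summary.mean, summary.sem, summary.n
    if kind == "timecourse":
        courses = tables.read_timecourses(path)
        fits = [fit_single_exponential(tc) for tc in courses]
        values = [f.k_obs for f in fits if f.success and f.rate_resolved]
        summary = aggregate_replicates(values)
        return "k_per_min", float(entry["k_per_min"]), summary.mean, summary.sem, summary.n
    if kind == "endpoint":
        summary = extent_at_completion(tables.read_endpoints(path))
        return "endpoint", float(entry["endpoint"]), summary.mean, summary.sem, summary.n
    raise ConfigError(f"condition {name!r}: unknown manifest kind {kind!r}")


def run_recover(config: RunConfig) -> tuple[pd.DataFrame, bool]:
    """Score parameter recovery of a simulated bundle against its manifest.

    Returns the recovery table and an overall pass flag (every condition's
    relative error within ``config.tolerance``).
    """
    config.outdir.mkdir(parents=True, exist_ok=True)
    log = _RunLog()
    manifest = yaml.safe_load(Path(config.manifest).read_text())
    if not isinstance(manifest, dict) or not manifest:
        raise ConfigError(f"{config.manifest}: empty or malformed manifest")
    rows = []
    for name, entry in manifest.items():
        if not (config.bundle_dir / str(entry.get("file", ""))).exists():
            raise ConfigError(
                f"manifest/bundle mismatch: file for condition {name!r} missing in {config.bundle_dir}"
            )
        parameter, true, estimate, sem, n = _recover_condition(name, entry, config)
        rel_error = abs(estimate - true) / abs(true) if true else math.inf
        passed = rel_error <= config.tolerance
        log.note(
            f"{name}: {parameter} true={true:.4g} recovered={estimate:.4g} "
            f"rel_error={rel_error:.2%} -> {'pass' if passed else 'FAIL'}",
            condition=name, parameter=parameter, rel_error=rel_error, passed=passed,
        )
        rows.append(
            {
                "condition": name,
                "kind": entry["kind"],
                "parameter": parameter,
                "true_value": true,
                "recovered_mean": estimate,
                "recovered_sem": sem,
                "n_replicates": n,
                "rel_error": rel_error,
                "passed": passed,
            }
        )
    report = pd.DataFrame(rows)
    _write(report, config, "recovery")
    log.write(config.outdir)
    return report, bool(report["passed"].all())
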