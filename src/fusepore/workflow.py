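"""End-to-end reproducible runs: config, validation, and the report.

A :class:`RunConfig` bundles every stage's parameters (generator,
condition presets, detection thresholds, conductance model, lever
model).  ``run_reproduction`` executes simulate -> analyze -> pore
statistics -> lever model with one master seed and writes delimited-text
tables plus a machine-readable results table carrying the headline
quantities and pass/fail against stored tolerances.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import porestats, synthdata, traces
from .lever import default_model
from .lever.membrane import MembraneParams, ScaffoldParams
from .lever.snares import C2BParams, SnareParams

__all__ = ["RunConfig", "validate_config", "run_reproduction", "load_config"]

log = logging.getLogger("fusepore")


@dataclass
class RunConfig:
    seed: int = 0
    generator: synthdata.GeneratorParams = field(
        default_factory=synthdata.GeneratorParams
    )
    hill: synthdata.HillLaw = field(default_factory=synthdata.HillLaw)
    conditions: list[str] = field(default_factory=lambda: ["no_syt", "c2ab_wt"])
    n_patches: int = 8
    open_threshold: float = traces.DEFAULT_OPEN_THRESHOLD_PS
    min_burst_gap: float = traces.DEFAULT_MIN_BURST_GAP_MS
    min_dwell: float = traces.DEFAULT_MIN_DWELL_MS
    conductance: porestats.ConductanceModel = field(
        default_factory=porestats.ConductanceModel
    )
    model_overrides: dict = field(default_factory=dict)
    saturating_calcium: float = 1000.0
    out_dir: str = "fusepore_out"
    verbosity: int = 1
    run_model: bool = True


def _construct(cls, block: dict):
    return cls(**block)


def load_config(path) -> RunConfig:
    """Read a YAML config whose blocks mirror the parameter dataclasses."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kw = {}
    if "generator" in raw:
        kw["generator"] = _construct(synthdata.GeneratorParams, raw.pop("generator"))
    if "hill" in raw:
        kw["hill"] = _construct(synthdata.HillLaw, raw.pop("hill"))
    if "conductance" in raw:
        kw["conductance"] = _construct(porestats.ConductanceModel, raw.pop("conductance"))
    kw.update(raw)
    return RunConfig(**kw)


def validate_config(config: RunConfig) -> list[str]:
    """List of invariant violations (empty iff the config is valid).

    Each violation names the offending field and the rule it breaks.
    """
    v: list[str] = []
    try:
        gen = dataclasses.replace(config.generator)  # re-runs __post_init__
        v.extend(f"generator.{msg}" for msg in gen.validate())
    except ValueError as err:
        v.append(f"generator: {err}")
    hill = config.hill
    if hill.a < 0 or hill.c < 0:
        v.append("hill.a/hill.c: amplitudes must be non-negative")
    if hill.n <= 0:
        v.append("hill.n: Hill coefficient must be positive")
    if hill.K <= 0:
        v.append("hill.K: half-saturation must be positive")
    for name in ("open_threshold", "min_burst_gap", "min_dwell"):
        if getattr(config, name) <= 0:
            v.append(f"{name}: must be positive")
    if config.conductance.L <= 0:
        v.append("conductance.L: pore length must be positive")
    if config.conductance.sigma <= 0:
        v.append("conductance.sigma: conductivity must be positive")
    for label in config.conditions:
        if label not in synthdata.PRESETS:
            v.append(f"conditions: unknown preset {label!r}")
    if config.n_patches < 1:
        v.append("n_patches: must be >= 1")
    mo = config.model_overrides
    if "kappa" in mo and mo["kappa"] <= 0:
        v.append("model_overrides.kappa: bending modulus must be positive")
    if "gamma" in mo and mo["gamma"] < 0:
        v.append("model_overrides.gamma: tension must be non-negative")
    return v


def _model_from_overrides(config: RunConfig):
    mo = dict(config.model_overrides)
    kw = {}
    mem_kw = {k: mo.pop(k) for k in ("kappa", "gamma", "spontaneous_curvature",
                                     "remote_boundary_radius") if k in mo}
    if mem_kw:
        from .lever.calibrated import CALIBRATED

        base = CALIBRATED["mem"]
        kw["mem"] = dataclasses.replace(base, **mem_kw)
    for key, cls in (("scaf", ScaffoldParams), ("snares", SnareParams), ("c2b", C2BParams)):
        if key in mo:
            kw[key] = cls(**mo.pop(key))
    kw.update(mo)
    return default_model(**kw)


def run_reproduction(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Deterministic for a fixed ``config.seed``.  Returns the results
    dictionary that is also written to ``results.json``.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=logging.INFO if config.verbosity else logging.WARNING,
        format="%(asctime)s [%(name)s] %(message)s",
    )
    t_start = time.time()
    results: dict = {"seed": config.seed}
    master = np.random.SeedSequence(config.seed)

    # ---------------- stage 1: simulate ----------------
    log.info("stage=simulate: %d patches x %d conditions",
             config.n_patches, len(config.conditions))
    all_metrics = []
    summaries = []
    for label in config.conditions:
        preset = synthdata.PRESETS[label]
        for k, child in enumerate(master.spawn(config.n_patches)):
            rng = np.random.default_rng(child)
            rec = synthdata.simulate_patch_recording(
                config.generator, preset, config.hill, rng=rng
            )
            bursts = traces.detect_bursts(
                rec.trace, config.open_threshold, config.min_burst_gap, config.min_dwell
            )
            tab = traces.metrics_table(bursts)
            tab["condition"] = label
            tab["patch"] = k
            all_metrics.append(tab)
            capped = len(rec.annotations) >= config.generator.max_pores_per_patch
            exposure = (
                rec.annotations["t_on_ms"].max() / 60e3
                if capped and len(rec.annotations)
                else config.generator.patch_duration
            )
            summaries.append(
                traces.PatchSummary(
                    n_bursts=len(bursts),
                    observation_time=config.generator.patch_duration,
                    censored=capped,
                    exposure_time=exposure,
                )
            )
    metrics = pd.concat(all_metrics, ignore_index=True) if all_metrics else pd.DataFrame()
    metrics.to_csv(out / "burst_metrics.tsv", sep="\t", index=False)

    # ---------------- stage 2: analyze ----------------
    log.info("stage=analyze: %d bursts", len(metrics))
    if len(metrics):
        rate = traces.nucleation_rate(summaries)
        results["pores_per_min_naive"] = rate.rate_naive
        results["pores_per_min_censoring_aware"] = rate.rate_censoring_aware
        results["mean_G_po_pS"] = float(metrics["G_po_pS"].mean())
        results["mean_r_po_nm"] = float(
            porestats.conductance_to_radius(
                metrics["G_po_pS"].mean(), config.conductance
            )
        )

    # ---------------- stage 3: pore statistics ----------------
    results["radius_at_200pS_nm"] = porestats.conductance_to_radius(
        200.0, config.conductance
    )
    results["radius_at_1nS_nm"] = porestats.conductance_to_radius(
        1000.0, config.conductance
    )
    results["conductance_at_r5nm_nS"] = (
        porestats.radius_to_conductance(5.0, config.conductance) / 1e3
    )

    # ---------------- stage 4: lever model ----------------
    if config.run_model:
        log.info("stage=model: scanning shape landscape")
        model = _model_from_overrides(config)
        ens0 = model.evaluate(0.0)
        ens_sat = model.evaluate(config.saturating_calcium)
        pd.DataFrame(
            {"r_nm": ens0.r, "U_kT": ens0.U, "P": ens0.P, "h_nm": ens0.h_opt}
        ).to_csv(out / "model_profile_ca0.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"r_nm": ens_sat.r, "U_kT": ens_sat.U, "P": ens_sat.P, "h_nm": ens_sat.h_opt}
        ).to_csv(out / "model_profile_sat.tsv", sep="\t", index=False)
        results.update(
            model_mean_r_ca0_nm=ens0.mean_r,
            model_mean_h_ca0_nm=ens0.mean_h,
            model_mean_r_sat_nm=ens_sat.mean_r,
            model_fold_r=ens_sat.mean_r / ens0.mean_r,
            model_fold_G=ens_sat.mean_G / ens0.mean_G,
            model_barrier_ca0_kT=ens0.energy_between(1.0, 2.5),
            model_barrier_sat_kT=ens_sat.energy_between(1.0, 2.5),
        )

    # ---------------- report ----------------
    checks = {
        "radius_at_200pS_nm": (0.76, 0.01),
        "radius_at_1nS_nm": (1.70, 0.01),
        "conductance_at_r5nm_nS": (9.0, 0.5),
    }
    if config.run_model:
        checks.update(
            model_mean_r_ca0_nm=(0.9, 0.18),
            model_mean_h_ca0_nm=(9.0, 1.8),
            model_mean_r_sat_nm=(1.3, 0.26),
            model_fold_r=(1.4, 0.28),
            model_fold_G=(2.3, 0.46),
        )
    table = []
    for key, (target, tol) in checks.items():
        if key in results:
            value = results[key]
            table.append(
                {
                    "quantity": key,
                    "value": value,
                    "target": target,
                    "tolerance": tol,
                    "pass": bool(abs(value - target) <= tol),
                }
            )
    pd.DataFrame(table).to_csv(out / "report.tsv", sep="\t", index=False)
    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, default=float)
    log.info("done in %.1f s; wrote %s", time.time() - t_start, out)
    return results
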