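"""End-to-end orchestration: simulate -> parameterize -> fit -> compare.

A single YAML config drives cohort simulation per anesthetic condition,
TSC parameterization of the outer curves, per-animal exchange-rate fits,
the cohort QC gate on curve volumes, and the group statistics for NER, k1
and k2.  Every run writes a manifest (config echo, config hash, package
version, root seed) alongside the outputs; with a fixed seed the result
tables are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import glymkin
from glymkin import synth
from glymkin.io_core import write_tsc_table
from glymkin.kinetics import cohort_qc_thresholds, fit_exchange_rates, qc_gate
from glymkin.stats import compare_groups
from glymkin.tsc import parameterize

__all__ = ["PipelineError", "RunConfig", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure carrying the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"[{stage}] {detail}")


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    conditions: dict[str, dict] = field(
        default_factory=lambda: {"MED": {"n_animals": 7}, "ISO+MED": {"n_animals": 8}}
    )
    n_frames: int = 40
    duration_min: float = 360.0
    jitter: float = 0.05
    qc_fraction: float = 0.05
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise PipelineError("config", f"missing config file {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run the full synthetic pipeline and write all result tables.

    Returns a dict with per-animal fits, group comparisons for NER/k1/k2
    and the paths of everything written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    times = synth.default_times(config.n_frames, config.duration_min)

    # --- simulate ---------------------------------------------------------
    cohorts = {}
    for name, opts in config.conditions.items():
        try:
            cohorts[name] = synth.cohort_from_presets(
                name,
                int(opts.get("n_animals", 8)),
                times,
                seed=config.seed,
                jitter=config.jitter,
                overrides=opts.get("overrides"),
            )
        except KeyError as exc:
            raise PipelineError("simulate", str(exc)) from exc

    all_curves = []
    for cohort in cohorts.values():
        all_curves.extend(cohort.outer)
        all_curves.extend(cohort.inner)
    write_tsc_table(all_curves, out / "curves.tsv")

    # --- TSC parameterization --------------------------------------------
    rows = []
    for name, cohort in cohorts.items():
        for curve in cohort.outer:
            p = parameterize(curve, t_end=config.duration_min)
            rows.append(
                dict(
                    animal_id=p.animal_id, condition=name, label=p.label,
                    t_a=p.t_a, t_max=p.t_max, s_max=p.s_max, auc=p.auc,
                    a=p.a, b=p.b, decay_valid=p.decay_valid,
                )
            )
    params = pd.DataFrame(rows)
    params.to_csv(out / "tsc_params.tsv", sep="\t", index=False)

    # --- exchange fits ----------------------------------------------------
    fits = {}
    for name, cohort in cohorts.items():
        for i, spec in enumerate(cohort.specs):
            try:
                fit = fit_exchange_rates(cohort.outer[i], cohort.inner[i])
            except Exception as exc:  # pragma: no cover - defensive
                raise PipelineError("fit", f"animal {spec.animal_id}: {exc}") from exc
            fits[spec.animal_id] = (name, fit)

    thr_out, thr_in = cohort_qc_thresholds(
        [f for _, f in fits.values()], fraction=config.qc_fraction
    )
    gated = {aid: (cond, qc_gate(f, thr_out, thr_in)) for aid, (cond, f) in fits.items()}

    fit_records = {
        aid: dict(
            condition=cond, k1=f.k1, k2=f.k2, residual=f.residual,
            v_out=f.v_out, v_in=f.v_in,
            v_out_to_in=f.v_out_to_in, v_in_to_out=f.v_in_to_out,
            ner=f.ner, usable=f.usable, message=f.message,
        )
        for aid, (cond, f) in gated.items()
    }
    _write_json(out / "fits.json", fit_records)

    # --- statistics -------------------------------------------------------
    comparisons = {}
    for param in ("ner", "k1", "k2"):
        table = {}
        for name in cohorts:
            vals = [
                rec[param]
                for rec in fit_records.values()
                if rec["condition"] == name and rec["usable"] and np.isfinite(rec[param])
            ]
            if len(vals) >= 3:
                table[name] = vals
        if len(table) >= 2:
            comparisons[param] = _comparison_to_dict(
                compare_groups(table, alpha=config.alpha)
            )
    _write_json(out / "comparison.json", comparisons)

    manifest = dict(
        config=config.to_dict(),
        config_sha256=config.digest(),
        seed=config.seed,
        version=glymkin.__version__,
        outputs=["curves.tsv", "tsc_params.tsv", "fits.json", "comparison.json"],
    )
    _write_json(out / "manifest.json", manifest)

    return dict(fits=fit_records, comparisons=comparisons, out_dir=str(out))


def _comparison_to_dict(result) -> dict:
    return dict(
        normal=result.verdict.normal,
        normality=[dataclasses.asdict(g) for g in result.verdict.per_group],
        omnibus=dataclasses.asdict(result.omnibus),
        pairwise=[dataclasses.asdict(p) for p in result.pairwise],
        summaries={k: dataclasses.asdict(s) for k, s in result.summaries.items()},
    )


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(_sanitize(payload), indent=2, sort_keys=True) + "\n")


def _sanitize(obj):
    """Make a payload strictly JSON: numpy scalars -> python, non-finite -> null."""
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, np.bool_)):
        return obj.item()
    return obj
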