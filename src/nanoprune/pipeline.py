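"""End-to-end orchestration of the five-stage analysis protocol.

clean -> b-fit -> cluster -> prune -> re-add concentration-dependent
descriptors -> final fit + sensitivity.  Every intermediate artifact
is written into the run directory as CSV/JSON, together with a
manifest embedding the full configuration, so a run is reproducible
and auditable.  The master seed fans out to fixed per-stage sub-seeds,
making each stage independently repeatable.
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

from nanoprune import __version__
from nanoprune.clustering import cluster_descriptors, nominate_representatives
from nanoprune.core_data import (
    DescriptorMatrix,
    aggregate_series,
    clean_missing,
    read_bioassay_table,
    read_descriptor_table,
    write_descriptor_table,
)
from nanoprune.dose_response import fit_log_endpoint
from nanoprune.pruning import run_pruning
from nanoprune.sensitivity import final_fit, sensitivity_report

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

#: default nomination priority: parameters commonly studied in the
#: nanotoxicity literature come first
DEFAULT_PRIORITY = (
    "SSA",
    "d_BET",
    "diameter",
    "zeta_potential",
    "hydrodynamic_size",
    "force_vector_MO",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    descriptor_csv: str = ""
    bioassay_csv: str = ""
    out_dir: str = "run"
    endpoint: str = "reproduction"
    pruning_day: int = 49
    report_days: tuple[int, ...] = (21, 49)
    inconsistency: float = 0.8
    priority: tuple[str, ...] = DEFAULT_PRIORITY
    keep_fraction: float = 0.4
    stop_ratio: float = 0.2
    min_variables: int = 3
    regressor_overrides: dict = field(default_factory=dict)
    sensitivity_grid: int = 21
    seed: int = 0

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        for key in ("report_days", "priority"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return PipelineConfig(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["report_days"] = list(self.report_days)
        d["priority"] = list(self.priority)
        return d


def _stage_seed(master: int, stage_index: int) -> int:
    return (master * 10_007 + stage_index * 7919) % (2**31 - 1)


def run_pipeline(cfg: PipelineConfig, matrix: DescriptorMatrix | None = None,
                 records=None) -> dict:
    """Execute the full protocol; returns a results dict and writes artifacts.

    ``matrix`` and ``records`` may be passed directly (e.g. from the
    synthetic generator); otherwise they are read from the configured
    CSV paths.  Any stage failure raises :class:`PipelineError` naming
    the stage, with artifacts of completed stages retained on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if matrix is None:
        if not cfg.descriptor_csv or not Path(cfg.descriptor_csv).exists():
            raise PipelineError("inputs", f"descriptor table not found: {cfg.descriptor_csv!r}")
        matrix = read_descriptor_table(cfg.descriptor_csv)
    if records is None:
        if not cfg.bioassay_csv or not Path(cfg.bioassay_csv).exists():
            raise PipelineError("inputs", f"bioassay table not found: {cfg.bioassay_csv!r}")
        records = read_bioassay_table(cfg.bioassay_csv)

    results: dict = {"config": cfg.to_dict()}

    # stage 1: clean
    try:
        cleaned, removed = clean_missing(matrix)
    except Exception as exc:
        raise PipelineError("clean", str(exc)) from exc
    results["removed_columns"] = removed
    write_descriptor_table(cleaned, out / "descriptors_clean.csv")

    # stage 2: aggregate and fit the b endpoint per (material, day)
    try:
        series = [s for s in aggregate_series(records) if s.endpoint == cfg.endpoint]
        b_fits = {}
        for s in series:
            b_fits[(s.material, s.day)] = fit_log_endpoint(s)
    except Exception as exc:
        raise PipelineError("b_fit", str(exc)) from exc
    b_frame = pd.DataFrame(
        [
            {"material": m, "day": d, "b": f.b, "b0": f.b0, "r_squared": f.r_squared}
            for (m, d), f in sorted(b_fits.items())
        ]
    )
    b_frame.to_csv(out / "b_endpoints.csv", index=False)
    results["b_endpoints"] = b_frame

    # stage 3: cluster concentration-independent descriptors
    try:
        indep = cleaned.concentration_independent_columns()
        tree, clusters = cluster_descriptors(
            cleaned, inconsistency=cfg.inconsistency, columns=indep
        )
        clusters = nominate_representatives(clusters, priority=list(cfg.priority))
    except Exception as exc:
        raise PipelineError("cluster", str(exc)) from exc
    pd.DataFrame(
        {
            "column": list(clusters.partition),
            "cluster": [clusters.partition[c] for c in clusters.partition],
            "representative": [
                clusters.representatives[clusters.partition[c]] for c in clusters.partition
            ],
        }
    ).to_csv(out / "clusters.csv", index=False)
    (out / "dendrogram.nwk").write_text(tree.to_newick())
    results["clusters"] = clusters

    # stage 4: iterative pruning on the pruning-day b values
    try:
        reps = sorted(set(clusters.representatives.values()))
        b_day = b_frame[b_frame.day == cfg.pruning_day].set_index("material")["b"]
        per_material = (
            cleaned.data[reps].groupby(level="material").first().loc[b_day.index]
        )
        trace = run_pruning(
            b_day,
            per_material,
            seed=_stage_seed(cfg.seed, 4),
            keep_fraction=cfg.keep_fraction,
            stop_ratio=cfg.stop_ratio,
            min_variables=cfg.min_variables,
            regressor_overrides=cfg.regressor_overrides,
        )
    except Exception as exc:
        raise PipelineError("prune", str(exc)) from exc
    trace.importance_frame().to_csv(out / "pruning_importance.csv", index=False)
    (out / "pruning_trace.json").write_text(
        json.dumps(
            {
                "terminated_reason": trace.terminated_reason,
                "final_descriptors": trace.final_descriptors,
                "rounds": [
                    {
                        "index": r.index,
                        "candidates": r.candidates,
                        "survivors": r.survivors,
                        "stop_ratio": r.stop_ratio if np.isfinite(r.stop_ratio) else None,
                    }
                    for r in trace.rounds
                ],
            },
            indent=2,
        )
    )
    results["pruning"] = trace

    # stage 5: re-add concentration-dependent descriptors, final fit +
    # sensitivity per reporting day
    final_set = trace.final_descriptors + cleaned.concentration_dependent_columns()
    results["final_descriptors"] = final_set
    reports = {}
    try:
        X = cleaned.data[final_set]
        for day in cfg.report_days:
            y = _response_per_row(series, cleaned, day)
            front = final_fit(
                X, y, seed=_stage_seed(cfg.seed, 50 + day), **cfg.regressor_overrides
            )
            report = sensitivity_report(front, X, day=day, n_grid=cfg.sensitivity_grid)
            report.table.to_csv(out / f"sensitivity_day{day}.csv")
            front.to_frame().to_csv(out / f"front_day{day}.csv", index=False)
            reports[day] = report
    except Exception as exc:
        raise PipelineError("sensitivity", str(exc)) from exc
    results["sensitivity"] = reports

    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16],
        "final_descriptors": final_set,
        "best_r_squared": {d: reports[d].best_r_squared for d in reports},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results


def _response_per_row(series, cleaned: DescriptorMatrix, day: int) -> np.ndarray:
    """The raw response aligned with the descriptor matrix rows for one day."""
    lookup = {}
    for s in series:
        if s.day != day:
            continue
        for c, mval in zip(s.concentrations, s.mean):
            lookup[(s.material, float(c))] = mval
    y = []
    for mat, conc in cleaned.data.index:
        key = (mat, float(conc))
        if key not in lookup:
            raise ValueError(f"no day-{day} response for row {key}")
        y.append(lookup[key])
    return np.asarray(y, dtype=float)
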