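"""Pipeline driver: ordered stages, plain-text config, run manifests.

A run executes a list of stages against one model under one culture
condition and records every output file with a checksum in a JSON
manifest, so that re-running an identical config reproduces deterministic
stages bit-identically.  Stage order is validated against dependencies
(coupling before the omics comparison; a wild-type FBA before ROOM).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from .fba_engine import (
    CultureCondition,
    ObjectiveSpec,
    robustness_scan,
    solve_fba,
)
from .model_core import MetabolicModel, load_model

__all__ = ["RunConfig", "run_pipeline", "read_config"]

_STAGE_DEPS = {
    "fva": ["fba"],
    "room": ["fba"],
    "omics": ["couple", "fba"],
}
_KNOWN_STAGES = ("fba", "scan", "fva", "couple", "room", "perturb",
                 "coferm", "omics")


@dataclass
class RunConfig:
    model_path: str
    out_dir: str
    stages: list[str] = field(default_factory=lambda: ["fba"])
    objective: str = "yield_per_flux"
    w: float | None = None
    uptakes: dict[str, float] = field(default_factory=dict)
    acetate_constraint_on: bool = False
    seed: int = 12345
    expression_path: str | None = None
    deletions: list[str] = field(default_factory=list)
    perturb_n: int = 200
    perturb_rsd: float = 0.30
    grid: list[float] = field(default_factory=lambda: [0.0, 2.0, 5.0, 10.0])

    def validate(self) -> None:
        if not Path(self.model_path).exists():
            raise FileNotFoundError(self.model_path)
        seen: set[str] = set()
        for st in self.stages:
            if st not in _KNOWN_STAGES:
                raise ValueError(f"unknown stage {st!r}")
            for dep in _STAGE_DEPS.get(st, []):
                if dep not in seen:
                    raise ValueError(f"stage {st!r} requires {dep!r} earlier "
                                     "in the stage list")
            seen.add(st)
        if self.objective == "weighted" and self.w is None:
            raise ValueError("weighted objective requires w")


def read_config(path) -> RunConfig:
    """Plain-text ``key = value`` config; lists comma-separated."""
    kv: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        k, _, v = line.partition("=")
        kv[k.strip()] = v.strip()
    uptakes = {}
    for item in kv.get("uptakes", "").split(","):
        if ":" in item:
            ex, u = item.split(":")
            uptakes[ex.strip()] = float(u)
    return RunConfig(
        model_path=kv["model"],
        out_dir=kv.get("out_dir", "gsmflux_out"),
        stages=[s.strip() for s in kv.get("stages", "fba").split(",") if s.strip()],
        objective=kv.get("objective", "yield_per_flux"),
        w=float(kv["w"]) if "w" in kv else None,
        uptakes=uptakes,
        acetate_constraint_on=kv.get("acetate_constraint", "off") == "on",
        seed=int(kv.get("seed", "12345")),
        expression_path=kv.get("expression") or None,
        deletions=[d.strip() for d in kv.get("deletions", "").split(",") if d.strip()],
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; return the run manifest."""
    import pandas as pd

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = load_model(config.model_path)
    condition = CultureCondition(uptakes=dict(config.uptakes),
                                 acetate_constraint_on=config.acetate_constraint_on)
    spec = ObjectiveSpec(kind=config.objective, w=config.w)

    manifest = {
        "config": {k: v for k, v in vars(config).items()},
        "inputs": {config.model_path: _sha256(Path(config.model_path))},
        "stages": [],
        "outputs": {},
    }
    state: dict = {}

    def record(stage: str, status: str, files: list[Path], log: str = ""):
        for f in files:
            manifest["outputs"][str(f)] = _sha256(f)
        manifest["stages"].append({"stage": stage, "status": status,
                                   "files": [str(f) for f in files],
                                   "log": log})

    failed: set[str] = set()
    for stage in config.stages:
        if any(dep in failed for dep in _STAGE_DEPS.get(stage, [])):
            record(stage, "skipped_upstream_failure", [])
            continue
        t0 = time.time()
        try:
            files = _run_stage(stage, model, condition, spec, config, state, out)
            record(stage, "ok", files, f"{time.time() - t0:.2f}s")
        except Exception as exc:
            failed.add(stage)
            record(stage, "failed", [], repr(exc))
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _run_stage(stage: str, model: MetabolicModel, condition: CultureCondition,
               spec: ObjectiveSpec, config: RunConfig, state: dict,
               out: Path) -> list[Path]:
    import pandas as pd

    if stage == "fba":
        rep = solve_fba(model, condition, spec, seed=config.seed)
        state["fba"] = rep
        f = out / "flux.json"
        rep.flux.to_json(f)
        return [f]
    if stage == "scan":
        table = robustness_scan(model, condition, spec, config.grid,
                                seed=config.seed)
        f = out / "scan.tsv"
        table.to_csv(f, sep="\t", index=False)
        return [f]
    if stage == "fva":
        from .variability import fva

        ranges = fva(model, condition, spec, seed=config.seed,
                     incumbent=state.get("fba"))
        f = out / "fva.tsv"
        pd.DataFrame([vars(r) for r in ranges]).to_csv(f, sep="\t", index=False)
        return [f]
    if stage == "couple":
        from .gap_coupling import flux_coupling

        report = flux_coupling(model)
        state["couple"] = report
        f = out / "coupling.tsv"
        report.to_frame(model).to_csv(f, sep="\t", index=False)
        return [f]
    if stage == "room":
        from .knockout_room import ROOMParams, room

        params = ROOMParams(wild_reference=state["fba"].flux)
        result = room(model, condition, params, config.deletions)
        f = out / "room.json"
        f.write_text(json.dumps({
            "deleted": result.deleted, "viable": result.viable,
            "n_changed": result.n_changed, "yields": result.yields,
        }, indent=1))
        return [f]
    if stage == "perturb":
        from .scenario_screens import perturbation_screen, sample_biomass_compositions

        samples = sample_biomass_compositions(model, config.perturb_n,
                                              config.perturb_rsd, config.seed)
        table, report = perturbation_screen(model, condition, spec, samples,
                                            seed=config.seed)
        f1 = out / "perturb_samples.tsv"
        table.to_csv(f1, sep="\t", index=False)
        f2 = out / "perturb_correlations.json"
        f2.write_text(json.dumps({
            "r_biomass": report.r_biomass, "r_pdo": report.r_pdo,
            "yield_rsd": report.yield_rsd, "n_samples": report.n_samples,
        }, indent=1))
        return [f1, f2]
    if stage == "coferm":
        from .scenario_screens import cofermentation_surface

        table = cofermentation_surface(model, config.grid, config.grid,
                                       spec=None, seed=config.seed)
        f = out / "cofermentation.tsv"
        table.to_csv(f, sep="\t", index=False)
        return [f]
    if stage == "omics":
        from .omics_compare import compare_expression, read_expression_tsv

        expr = read_expression_tsv(config.expression_path)
        report = compare_expression(model, state["fba"].flux, state["couple"],
                                    expr)
        f = out / "omics.json"
        f.write_text(json.dumps({
            "shared": len(report.shared),
            "excluded_blocked": len(report.excluded_blocked),
            "predicted": len(report.predicted),
            "not_predicted": len(report.not_predicted),
            "prediction_rate": report.prediction_rate,
        }, indent=1))
        return [f]
    raise ValueError(f"unknown stage {stage!r}")
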