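"""JSON-configured sequential workflow runner.

A run is a list of named steps executed in order; each step consumes named
artifacts produced by earlier steps, writes its file outputs under the run
directory, and appends a structured status line to the run log.  The global
seed is threaded to every stochastic step, offset by the step index, so a
rerun with the same configuration and seed reproduces every numeric output
exactly.  Docking- and MD-engine step names are reserved: they fail
validation with a pointer to the mock equivalents, which write and read the
same file formats.
"""

from __future__ import annotations

import csv
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from . import chemdata, fepmap, graphmetrics, neswork, posesel, synthgen
from .exceptions import WorkflowConfigError, WorkflowStepError

__all__ = ["WorkflowConfig", "StepConfig", "validate_config", "run_workflow", "STEP_SLOTS"]

#: step type → (required input slots, output slots)
STEP_SLOTS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "read_ligands": ((), ("ligands",)),
    "filter_charge": (("ligands",), ("ligands",)),
    "read_poses": ((), ("poses",)),
    "select_poses": (("poses",), ("selected_poses",)),
    "build_map": (("ligands",), ("map",)),
    "read_map": ((), ("map",)),
    "synth_study": ((), ("map", "truth", "affinities")),
    "mock_nes": (("map", "truth"), ("works_root",)),
    "ingest_work": (("map",), ("works_root",)),
    "estimate_edges": (("map", "works_root"), ("edges",)),
    "solve_graph": (("map", "edges"), ("nodes",)),
    "offset_experiment": (("nodes", "affinities"), ("nodes",)),
    "metrics": (("nodes", "affinities"), ("metrics",)),
    "report": ((), ()),
}

#: engine stages that are out of scope; validation names the replacement
RESERVED_ENGINE_STEPS: dict[str, str] = {
    "dock_glide": "dock externally and use read_poses/select_poses",
    "dock_vina": "dock externally and use read_poses/select_poses",
    "ligprep": "embed externally or rely on SMILES-level records",
    "epik": "pre-assign protonation states; see filter_charge",
    "prepare_simulation": "use mock_nes to generate work values",
    "run_simulation": "use mock_nes to generate work values",
    "pmx_atom_mapper": "hybrid-topology setup is out of scope",
    "pmx_ligand_hybrid": "hybrid-topology setup is out of scope",
}


@dataclass
class StepConfig:
    type: str
    name: str
    settings: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def input_artifact(self, slot: str) -> str:
        return self.inputs.get(slot, slot)

    def output_artifact(self, slot: str) -> str:
        return self.outputs.get(slot, slot)


@dataclass
class WorkflowConfig:
    steps: list[StepConfig]
    seed: int = 0
    temperature: float = 298.0
    output_dir: str | None = None
    raw: dict = field(default_factory=dict)


def validate_config(source) -> WorkflowConfig:
    """Parse and validate a workflow configuration (path, JSON string or dict).

    Checks that every step type is known, that docking/MD engine names are
    rejected explicitly, and that every required input binding refers to an
    artifact produced by an earlier step.
    """
    if isinstance(source, dict):
        data = source
    else:
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise WorkflowConfigError(f"config is not valid JSON: {exc}") from exc
    if not isinstance(data, dict) or "steps" not in data:
        raise WorkflowConfigError("config must be an object with a 'steps' list")
    raw_steps = data["steps"]
    if not isinstance(raw_steps, list) or not raw_steps:
        raise WorkflowConfigError("'steps' must be a non-empty list")

    steps: list[StepConfig] = []
    available: set[str] = set()
    for i, raw in enumerate(raw_steps):
        stype = raw.get("type")
        if stype in RESERVED_ENGINE_STEPS:
            raise WorkflowConfigError(
                f"step {i}: '{stype}' requires an external engine and is not "
                f"runnable here ({RESERVED_ENGINE_STEPS[stype]})"
            )
        if stype not in STEP_SLOTS:
            raise WorkflowConfigError(f"step {i}: unknown step type '{stype}'")
        step = StepConfig(
            type=stype,
            name=raw.get("name", f"{i:02d}_{stype}"),
            settings=raw.get("settings", {}),
            inputs=raw.get("inputs", {}),
            outputs=raw.get("outputs", {}),
        )
        in_slots, out_slots = STEP_SLOTS[stype]
        for slot in in_slots:
            artifact = step.input_artifact(slot)
            optional = stype in ("offset_experiment", "metrics") and slot == "affinities" \
                and "exp_csv" in step.settings
            if artifact not in available and not optional:
                raise WorkflowConfigError(
                    f"step {i} ('{step.name}'): input '{slot}' is bound to "
                    f"artifact '{artifact}' which no earlier step produces"
                )
        for slot in out_slots:
            available.add(step.output_artifact(slot))
        steps.append(step)
    return WorkflowConfig(
        steps=steps,
        seed=int(data.get("seed", 0)),
        temperature=float(data.get("temperature", 298.0)),
        output_dir=data.get("output_dir"),
        raw=data,
    )


class _RunContext:
    def __init__(self, config: WorkflowConfig, run_dir: Path):
        self.config = config
        self.run_dir = run_dir
        self.artifacts: dict = {}

    def step_dir(self, step: StepConfig) -> Path:
        d = self.run_dir / "steps" / step.name
        d.mkdir(parents=True, exist_ok=True)
        return d


# ---------------------------------------------------------------- steps


def _step_read_ligands(ctx, step, rng):
    records = chemdata.read_ligands(step.settings["path"])
    ctx.artifacts[step.output_artifact("ligands")] = records


def _step_filter_charge(ctx, step, rng):
    records = ctx.artifacts[step.input_artifact("ligands")]
    kept, dropped = chemdata.filter_to_single_net_charge(records)
    with open(ctx.step_dir(step) / "dropped.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "net_charge"])
        for r in dropped:
            w.writerow([r.id, r.net_charge])
    ctx.artifacts[step.output_artifact("ligands")] = kept


def _step_read_poses(ctx, step, rng):
    ctx.artifacts[step.output_artifact("poses")] = chemdata.read_poses(step.settings["path"])


def _step_select_poses(ctx, step, rng):
    poses = ctx.artifacts[step.input_artifact("poses")]
    ref_sets = chemdata.read_poses(step.settings["reference_sdf"])
    if len(ref_sets) != 1:
        raise ValueError("reference SDF must contain exactly one ligand")
    (ref_set,) = ref_sets.values()
    ref_mol, ref_coords = ref_set.mol, ref_set.coords[0]
    selected: dict[str, posesel.PoseSet] = {}
    for lig_id, pose_set in poses.items():
        mappings = posesel.compute_mcs_mappings(pose_set.mol, ref_mol)
        best, rmsd = posesel.select_best_pose(pose_set, ref_coords, mappings)
        props = dict(pose_set.props[best])
        props["mcs_rmsd"] = f"{rmsd:.4f}"
        props["pose_rank"] = str(best)
        selected[lig_id] = posesel.PoseSet(lig_id, pose_set.mol, [pose_set.coords[best]], [props])
    chemdata.write_poses(ctx.step_dir(step) / "selected.sdf", selected)
    ctx.artifacts[step.output_artifact("selected_poses")] = selected


def _step_build_map(ctx, step, rng):
    records = ctx.artifacts[step.input_artifact("ligands")]
    pmap = fepmap.build_map(records, target_degree=int(step.settings.get("target_degree", 2)))
    fepmap.write_map(ctx.step_dir(step) / "map.csv", pmap)
    ctx.artifacts[step.output_artifact("map")] = pmap


def _step_read_map(ctx, step, rng):
    ctx.artifacts[step.output_artifact("map")] = fepmap.read_map(step.settings["path"])


def _step_synth_study(ctx, step, rng):
    s = step.settings
    study = synthgen.gen_map_study(
        n_ligands=int(s.get("n_ligands", 10)),
        dg_range=tuple(s.get("dg_range", (-12.0, -7.7))),
        edge_noise_sd=float(s.get("edge_noise_sd", 0.3)),
        exp_noise_sd=float(s.get("exp_noise_sd", 0.43)),
        target_degree=int(s.get("target_degree", 3)),
        seed=int(rng.integers(2**31)),
    )
    d = ctx.step_dir(step)
    fepmap.write_map(d / "map.csv", study.map)
    chemdata.write_affinities(d / "exp.csv", study.affinities)
    with open(d / "truth.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "dg_true_kcal"])
        for lig, dg in study.true_dg.items():
            w.writerow([lig, repr(dg)])
    ctx.artifacts[step.output_artifact("map")] = study.map
    ctx.artifacts[step.output_artifact("truth")] = study.true_dg
    ctx.artifacts[step.output_artifact("affinities")] = study.affinities


def _step_mock_nes(ctx, step, rng):
    pmap = ctx.artifacts[step.input_artifact("map")]
    truth = ctx.artifacts[step.input_artifact("truth")]
    s = step.settings
    root = ctx.step_dir(step) / "works"
    for e in pmap.edges:
        synthgen.mock_nes_backend(
            edge_id=e.id,
            true_ddg=truth[e.b] - truth[e.a],
            dissipation_sigma=float(s.get("dissipation_sigma", 1.0)),
            n_transitions=int(s.get("n_transitions", 80)),
            n_replicas=int(s.get("n_replicas", 3)),
            outdir=root,
            temperature=ctx.config.temperature,
            seed=rng,
        )
    ctx.artifacts[step.output_artifact("works_root")] = root


def _step_ingest_work(ctx, step, rng):
    pmap = ctx.artifacts[step.input_artifact("map")]
    root = Path(step.settings["path"])
    missing = [e.id for e in pmap.edges if not (root / e.id).is_dir()]
    if missing:
        raise FileNotFoundError(f"work directories missing for edges: {missing}")
    ctx.artifacts[step.output_artifact("works_root")] = root


def _step_estimate_edges(ctx, step, rng):
    pmap = ctx.artifacts[step.input_artifact("map")]
    root = Path(ctx.artifacts[step.input_artifact("works_root")])
    n_boot = int(step.settings.get("n_boot", 100))
    temperature = ctx.config.temperature
    leg_rows, edge_results = [], []
    for e in pmap.edges:
        per_leg: dict[str, tuple[float, float]] = {}
        n_reps = 0
        for leg in ("complex", "water"):
            leg_dir = root / e.id / leg
            rep_dirs = sorted(p for p in leg_dir.iterdir() if p.is_dir())
            if not rep_dirs:
                raise FileNotFoundError(f"no replica directories under {leg_dir}")
            estimates = []
            for rep_idx, rep_dir in enumerate(rep_dirs, start=1):
                ws = neswork.WorkSet(
                    e.id, leg, rep_idx,
                    neswork.read_work_file(rep_dir / "forward.dat"),
                    neswork.read_work_file(rep_dir / "reverse.dat"),
                )
                est = neswork.estimate_with_error(ws, temperature, n_boot, rng)
                estimates.append(est)
                leg_rows.append([e.id, leg, rep_idx, repr(est.value), repr(est.se_boot)])
            per_leg[leg] = neswork.combine_replicas(estimates)
            n_reps = len(estimates)
        edge_results.append(
            neswork.edge_ddg(e.id, per_leg["complex"], per_leg["water"], n_reps)
        )
    d = ctx.step_dir(step)
    with open(d / "legs.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["edge", "leg", "replica", "dg_kcal", "se_kcal"])
        w.writerows(leg_rows)
    with open(d / "edges.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["edge", "ddg_kcal", "se_kcal"])
        for r in edge_results:
            w.writerow([r.edge_id, repr(r.ddg), repr(r.se)])
    ctx.artifacts[step.output_artifact("edges")] = edge_results


def _step_solve_graph(ctx, step, rng):
    pmap = ctx.artifacts[step.input_artifact("map")]
    edges = ctx.artifacts[step.input_artifact("edges")]
    se_floor = float(step.settings.get("se_floor", 0.1))
    nodes = graphmetrics.solve_node_dgs(pmap, edges, se_floor)
    cycles = graphmetrics.cycle_closure_errors(pmap, edges)
    d = ctx.step_dir(step)
    with open(d / "nodes.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["ligand", "dg_calc_kcal", "se_kcal"])
        for n in nodes:
            w.writerow([n.id, repr(n.dg_calc), repr(n.se)])
    with open(d / "cycle_closure.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cycle_index", "closure_kcal"])
        for i, c in enumerate(cycles):
            w.writerow([i, repr(c)])
    ctx.artifacts[step.output_artifact("nodes")] = nodes


def _affinities_for(ctx, step):
    if "exp_csv" in step.settings:
        return chemdata.read_affinities(step.settings["exp_csv"])
    return ctx.artifacts[step.input_artifact("affinities")]


def _step_offset_experiment(ctx, step, rng):
    nodes = ctx.artifacts[step.input_artifact("nodes")]
    exp = _affinities_for(ctx, step)
    ctx.artifacts[step.output_artifact("nodes")] = graphmetrics.offset_to_experiment(nodes, exp)


def _step_metrics(ctx, step, rng):
    nodes = ctx.artifacts[step.input_artifact("nodes")]
    exp = _affinities_for(ctx, step)
    paired = [(n.dg_calc, exp.dg(n.id), exp.sigma(n.id)) for n in nodes if n.id in exp]
    calc = np.array([p[0] for p in paired])
    dg_exp = np.array([p[1] for p in paired])
    sigma = np.array([p[2] for p in paired])
    report = graphmetrics.compute_metrics(calc, dg_exp)
    n_boot = int(step.settings.get("n_boot", 1000))
    n_null = int(step.settings.get("n_null", 1000))
    report.ci = graphmetrics.bootstrap_metric_ci(calc, dg_exp, n_boot, rng)
    report.null_band = graphmetrics.experimental_null_band(
        dg_exp, sigma, n_null, rng,
        floor=float(step.settings.get("sigma_floor", 0.43)),
    )
    with open(ctx.step_dir(step) / "metrics.json", "w") as fh:
        json.dump(report.as_dict(), fh, indent=2, sort_keys=True)
    ctx.artifacts[step.output_artifact("metrics")] = report


def _step_report(ctx, step, rng):
    out: dict = {"seed": ctx.config.seed, "temperature": ctx.config.temperature}
    edges = ctx.artifacts.get(step.input_artifact("edges"))
    nodes = ctx.artifacts.get(step.input_artifact("nodes"))
    metrics = ctx.artifacts.get(step.input_artifact("metrics"))
    truth = ctx.artifacts.get(step.input_artifact("truth"))
    if edges is not None:
        out["edges"] = [
            {"edge": e.edge_id, "ddg_kcal": e.ddg, "se_kcal": e.se} for e in edges
        ]
    if nodes is not None:
        out["nodes"] = [
            {"ligand": n.id, "dg_calc_kcal": n.dg_calc, "se_kcal": n.se} for n in nodes
        ]
    if metrics is not None:
        out["metrics"] = metrics.as_dict()
    if truth is not None and nodes is not None:
        calc = [n.dg_calc for n in nodes]
        true = [truth[n.id] for n in nodes]
        out["truth"] = {n.id: truth[n.id] for n in nodes}
        out["kendall_tau_vs_truth"] = float(stats.kendalltau(true, calc).statistic)
    with open(ctx.run_dir / "report.json", "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)


_STEP_FUNCS = {
    "read_ligands": _step_read_ligands,
    "filter_charge": _step_filter_charge,
    "read_poses": _step_read_poses,
    "select_poses": _step_select_poses,
    "build_map": _step_build_map,
    "read_map": _step_read_map,
    "synth_study": _step_synth_study,
    "mock_nes": _step_mock_nes,
    "ingest_work": _step_ingest_work,
    "estimate_edges": _step_estimate_edges,
    "solve_graph": _step_solve_graph,
    "offset_experiment": _step_offset_experiment,
    "metrics": _step_metrics,
    "report": _step_report,
}


def run_workflow(config: WorkflowConfig | dict | str | Path, outdir: str | Path | None = None) -> Path:
    """Execute a validated workflow, returning the run directory.

    Each step gets a deterministic generator seeded by the global seed plus
    its index; per-step status lines go to ``log.jsonl`` (wall time lives
    only there, so ``report.json`` is byte-identical across reruns).  A
    failing step halts the run with the step name and cause; artifacts of
    completed steps are retained.
    """
    if not isinstance(config, WorkflowConfig):
        config = validate_config(config)
    if outdir is None:
        outdir = config.output_dir
    if outdir is None:
        raise WorkflowConfigError("no output directory given (config output_dir or outdir)")
    run_dir = Path(outdir)
    run_dir.mkdir(parents=True, exist_ok=True)
    with open(run_dir / "config.json", "w") as fh:
        json.dump(config.raw, fh, indent=2, sort_keys=True)

    ctx = _RunContext(config, run_dir)
    with open(run_dir / "log.jsonl", "w") as log:
        for i, step in enumerate(config.steps):
            rng = np.random.default_rng((config.seed + i) % 2**31)
            t0 = time.perf_counter()
            try:
                _STEP_FUNCS[step.type](ctx, step, rng)
            except Exception as exc:
                log.write(json.dumps({
                    "step": step.name, "type": step.type, "status": "failed",
                    "error": str(exc), "wall_s": round(time.perf_counter() - t0, 3),
                }) + "\n")
                raise WorkflowStepError(step.name, str(exc)) from exc
            log.write(json.dumps({
                "step": step.name, "type": step.type, "status": "ok",
                "wall_s": round(time.perf_counter() - t0, 3),
                "artifacts": sorted(ctx.artifacts.keys()),
            }) + "\n")
    return run_dir


def synthetic_study_config(
    n_ligands: int = 10,
    seed: int = 0,
    dissipation_sigma: float = 1.0,
    n_transitions: int = 80,
    n_replicas: int = 3,
    dg_range: tuple[float, float] = (-12.0, -7.7),
    exp_noise_sd: float = 0.43,
    n_boot: int = 100,
    output_dir: str | None = None,
) -> dict:
    """Ready-to-run config: synthetic study → mock NES → full analysis."""
    return {
        "seed": seed,
        "temperature": 298.0,
        "output_dir": output_dir,
        "steps": [
            {"type": "synth_study", "settings": {
                "n_ligands": n_ligands, "dg_range": list(dg_range),
                "exp_noise_sd": exp_noise_sd}},
            {"type": "mock_nes", "settings": {
                "dissipation_sigma": dissipation_sigma,
                "n_transitions": n_transitions, "n_replicas": n_replicas}},
            {"type": "estimate_edges", "settings": {"n_boot": n_boot}},
            {"type": "solve_graph"},
            {"type": "offset_experiment"},
            {"type": "metrics", "settings": {"n_boot": 500, "n_null": 500}},
            {"type": "report"},
        ],
    }
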