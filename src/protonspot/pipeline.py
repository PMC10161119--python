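"""End-to-end pipeline stages with manifests and report generation.

Stage order: synth -> qa -> train -> predict -> dose -> robust -> report.
Each stage reads only upstream artifacts from the workspace, writes its
outputs plus a manifest (seed, input hashes, outputs), and is
byte-reproducible from (config, seed).  All randomness derives from the
single global seed through named substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dose import SpotOpticsModel, filter_plan_by_aperture
from .geometry import load_grid, save_grid
from .logfile import parse_log_file, write_log_file, write_pseudo_log_file
from .model import (TrainConfig, dataset_from_logs, model_from_json, model_to_json,
                    predict_plan, train)
from .plan import Spot, load_plan, replace_spots, save_plan
from .qa import agreement_table
from .robust import (NOMINAL, ScenarioConfig, banded_dvh, compare_plans,
                     ctv_v95_by_scenario, evaluate_scenarios, generate_scenarios,
                     percent_of_prescription, robustness_check, scenario_indices,
                     worst_case_table)
from .synthetic import (ErrorModelTruth, PhantomSpec, StructurePrimitive,
                        generate_phantom, generate_plan, generate_qa_grid,
                        generate_training_corpus, load_qa_session,
                        plan_spec_preset, save_qa_session)

STAGES = ["synth", "qa", "train", "predict", "dose", "robust", "report"]


def substream(seed: int, name: str) -> int:
    """Named, collision-stable child seed below 2**31."""
    return int(np.random.SeedSequence([seed, zlib.crc32(name.encode())])
               .generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    seed: int = 0
    plan_preset: str = "two_beam"
    ctv_radius_mm: float = 20.0
    oar_offset_mm: float = 44.0
    oar_radius_mm: float = 6.0
    # bone-like slab upstream of the target: range heterogeneity that makes
    # coverage genuinely sensitive to the +/-3.5% stopping-power scenarios
    slab_rsp: float = 1.8
    slab_thickness_mm: float = 24.0
    slab_center_z_mm: float = -36.0
    corpus_spots: int = 6000
    pulses_per_spot: int = 5
    qa_gantry_angles: tuple[float, ...] = (0.0, 90.0, 180.0)
    truth: ErrorModelTruth = field(default_factory=ErrorModelTruth)
    train: TrainConfig = field(default_factory=TrainConfig)
    dvh_bin_cgy: float = 2.0
    scenario_mode: str = "isotropic_corners"
    density_frac: float = 0.035
    plan_overrides: dict = field(default_factory=dict)  # PlanSpec field overrides

    def plan_spec(self):
        spec = plan_spec_preset(self.plan_preset)
        return dataclasses.replace(spec, **self.plan_overrides) if self.plan_overrides else spec

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        truth = ErrorModelTruth(**raw.pop("truth", {}))
        train_cfg = TrainConfig(**raw.pop("train", {}))
        cfg = cls(truth=truth, train=train_cfg, **raw)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(ws: Path, stage: str, seed: int, inputs: list[Path],
                    outputs: list[Path]) -> None:
    man_dir = ws / "manifests"
    man_dir.mkdir(parents=True, exist_ok=True)
    doc = {
        "stage": stage,
        "seed": seed,
        "version": __version__,
        "inputs": {str(p.relative_to(ws)): _sha256(p) for p in inputs},
        "outputs": sorted(str(p.relative_to(ws)) for p in outputs),
    }
    (man_dir / f"{stage}.json").write_text(json.dumps(doc, indent=2, sort_keys=True))


def _require(ws: Path, stage: str) -> None:
    if not (ws / "manifests" / f"{stage}.json").exists():
        raise FileNotFoundError(
            f"missing upstream artifacts: run stage {stage!r} first")


def default_phantom_spec(cfg: PipelineConfig) -> PhantomSpec:
    structures = [
        StructurePrimitive("CTV", "sphere", (0.0, 0.0, 0.0), radius_mm=cfg.ctv_radius_mm),
        StructurePrimitive("OAR", "sphere", (cfg.oar_offset_mm, 0.0, 0.0),
                           radius_mm=cfg.oar_radius_mm),
    ]
    if cfg.slab_rsp and cfg.slab_thickness_mm > 0:
        structures.insert(0, StructurePrimitive(
            "SLAB", "box", (0.0, 0.0, cfg.slab_center_z_mm),
            half_size_mm=(55.0, 55.0, cfg.slab_thickness_mm / 2.0), rsp=cfg.slab_rsp))
    return PhantomSpec(structures=structures)


def stage_synth(cfg: PipelineConfig, ws: Path) -> dict:
    ws.mkdir(parents=True, exist_ok=True)
    grid, structures = generate_phantom(default_phantom_spec(cfg))
    save_grid(ws / "phantom", grid, structures.masks)
    plan = generate_plan(grid, structures, cfg.plan_spec(),
                         seed=substream(cfg.seed, "synth-plan"))
    save_plan(ws / "plan_clinical.json", plan)
    log_dir = ws / "logs"
    log_dir.mkdir(exist_ok=True)
    corpus = generate_training_corpus(cfg.corpus_spots, cfg.truth,
                                      seed=substream(cfg.seed, "synth-corpus"),
                                      pulses_per_spot=cfg.pulses_per_spot)
    outputs = [ws / "phantom.npz", ws / "phantom.json", ws / "plan_clinical.json"]
    for i, log in enumerate(corpus):
        p = log_dir / f"corpus_{i:03d}.csv"
        write_log_file(p, log)
        outputs.append(p)
    qa_dir = ws / "qa"
    qa_dir.mkdir(exist_ok=True)
    for angle in cfg.qa_gantry_angles:
        session = generate_qa_grid(angle, cfg.truth,
                                   seed=substream(cfg.seed, f"synth-qa-{angle:g}"))
        p = qa_dir / f"qa_gantry{angle:g}.csv"
        save_qa_session(p, session)
        outputs.append(p)
    _write_manifest(ws, "synth", cfg.seed, [], outputs)
    counts = {"beams": len(plan.beams), "plan_spots": plan.n_spots,
              "corpus_logs": len(corpus),
              "corpus_spots": sum(len(np.unique(l.pulses["spot_index"])) for l in corpus)}
    return counts


def stage_qa(cfg: PipelineConfig, ws: Path) -> dict:
    _require(ws, "synth")
    sessions = [load_qa_session(p) for p in sorted((ws / "qa").glob("qa_gantry*.csv"))]
    table = agreement_table(sessions)
    out = ws / "reports"
    out.mkdir(exist_ok=True)
    table.to_csv(out / "qa_agreement.csv")
    _write_manifest(ws, "qa", cfg.seed, sorted((ws / "qa").glob("*.csv")),
                    [out / "qa_agreement.csv"])
    return {"sessions": len(sessions)}


def stage_train(cfg: PipelineConfig, ws: Path) -> dict:
    _require(ws, "synth")
    logs = [parse_log_file(p) for p in sorted((ws / "logs").glob("corpus_*.csv"))]
    X, y, n_excluded = dataset_from_logs(logs)
    train_cfg = dataclasses.replace(cfg.train, seed=substream(cfg.seed, "split-train"))
    model = train(X, y, train_cfg)
    model_to_json(model, ws / "model.json")
    _write_manifest(ws, "train", cfg.seed, sorted((ws / "logs").glob("*.csv")),
                    [ws / "model.json"])
    return {"spots_parsed": len(X), "zero_mu_excluded": n_excluded,
            "test_r2_raw": model.metrics_.r2_raw,
            "test_mse_standardized": model.metrics_.mse_standardized}


def stage_predict(cfg: PipelineConfig, ws: Path) -> dict:
    _require(ws, "train")
    plan = load_plan(ws / "plan_clinical.json")
    model = model_from_json(ws / "model.json")
    preds = predict_plan(model, plan)
    plf_dir = ws / "plf"
    plf_dir.mkdir(exist_ok=True)
    outputs = []
    start = 0
    for beam in plan.beams:
        n = beam.n_spots
        p = plf_dir / f"plf_{beam.beam_id}.csv"
        write_pseudo_log_file(beam, preds[start:start + n], plan.plan_id, path=p)
        outputs.append(p)
        start += n
    _write_manifest(ws, "predict", cfg.seed,
                    [ws / "model.json", ws / "plan_clinical.json"], outputs)
    return {"spots_predicted": len(preds)}


def _ml_plan_from_plfs(ws: Path, plan):
    """Reassemble the predicted-delivery plan from the PLFs on disk."""
    from .logfile import aggregate_pulses_to_spots

    new_spots: dict[tuple[int, int, int], Spot] = {}
    for bi, beam in enumerate(plan.beams):
        log = parse_log_file(ws / "plf" / f"plf_{beam.beam_id}.csv")
        records = aggregate_pulses_to_spots(log)
        k = 0
        for li, layer in enumerate(beam.layers):
            for si in range(len(layer.spots)):
                r = records[k]
                new_spots[(bi, li, si)] = Spot(r.delivered_x_mm, r.delivered_y_mm,
                                               max(r.delivered_mu, 0.0))
                k += 1
    ml = replace_spots(plan, new_spots)
    ml.plan_id = plan.plan_id + "_ml"
    return ml


def stage_dose(cfg: PipelineConfig, ws: Path) -> dict:
    _require(ws, "predict")
    from .dose import normalize_plan

    grid, structures, _ = load_grid(ws / "phantom")
    plan = load_plan(ws / "plan_clinical.json")
    optics = SpotOpticsModel()
    normalized, factor = normalize_plan(plan, grid, optics, structures["CTV"],
                                        plan.prescription_cgy)
    ml_raw = _ml_plan_from_plfs(ws, plan)
    ml_filtered, deleted = filter_plan_by_aperture(ml_raw)
    # the predicted-spot plan reuses the clinical normalization factor (frozen)
    ml_plan = ml_filtered.scale_mu(factor)
    save_plan(ws / "plan_clinical_normalized.json", normalized)
    save_plan(ws / "plan_ml_normalized.json", ml_plan)
    (ws / "reports").mkdir(exist_ok=True)
    pd.DataFrame(deleted).to_csv(ws / "reports" / "aperture_deletions.csv", index=False)
    (ws / "normalization.json").write_text(json.dumps(
        {"factor": factor, "spots_deleted_at_aperture": len(deleted),
         "deleted_mu_unmodelled": float(sum(d["mu"] for d in deleted))}, indent=2))
    _write_manifest(ws, "dose", cfg.seed,
                    [ws / "plan_clinical.json"] + sorted((ws / "plf").glob("*.csv")),
                    [ws / "plan_clinical_normalized.json", ws / "plan_ml_normalized.json",
                     ws / "normalization.json", ws / "reports" / "aperture_deletions.csv"])
    return {"normalization_factor": factor, "spots_deleted_at_aperture": len(deleted)}


def stage_robust(cfg: PipelineConfig, ws: Path) -> dict:
    _require(ws, "dose")
    grid, structures, _ = load_grid(ws / "phantom")
    optics = SpotOpticsModel()
    spec = cfg.plan_spec()
    sc_cfg = ScenarioConfig(shift_mm=spec.setup_shift_mm, density_frac=cfg.density_frac,
                            mode=cfg.scenario_mode)
    scenarios = generate_scenarios(sc_cfg)
    index_specs = {"CTV": ["D99%", "D0.03cc"], "OAR": ["D0.03cc"]}
    results = {}
    for tag in ("clinical", "ml"):
        plan = load_plan(ws / f"plan_{tag}_normalized.json")
        ev = evaluate_scenarios(plan, grid, optics, structures, scenarios + [NOMINAL],
                                bin_width_cgy=cfg.dvh_bin_cgy)
        perturbed = ScenarioEvalView(ev, [s.label for s in scenarios])
        idx = scenario_indices(perturbed.view, index_specs)
        nom_idx = scenario_indices(ScenarioEvalView(ev, ["nominal"]).view, index_specs)
        table = worst_case_table(idx, nom_idx)
        band = banded_dvh({l: ev.dvhs[l] for l in perturbed.labels},
                          ev.dvhs["nominal"])
        v95 = ctv_v95_by_scenario(perturbed.view, plan.prescription_cgy)
        verdict = robustness_check(v95)
        results[tag] = {"table": table, "band": band, "verdict": verdict,
                        "prescription": plan.prescription_cgy}
        table.to_csv(ws / "reports" / f"worst_case_{tag}.csv")
        pd.DataFrame({"scenario": list(v95), "v95_pct": list(v95.values())}).to_csv(
            ws / "reports" / f"v95_{tag}.csv", index=False)
        band_df = pd.DataFrame({"dose_cgy": band.dose_edges_cgy})
        for name in band.lower_pct:
            band_df[f"{name}_min_pct"] = band.lower_pct[name]
            band_df[f"{name}_max_pct"] = band.upper_pct[name]
            band_df[f"{name}_nominal_pct"] = band.nominal[name].volume_pct
        band_df.to_csv(ws / "reports" / f"banded_dvh_{tag}.csv", index=False)
        (ws / "reports" / f"verdict_{tag}.json").write_text(json.dumps(verdict, indent=2))
    diff = compare_plans(results["clinical"]["table"], results["ml"]["table"])
    diff.to_csv(ws / "reports" / "worst_case_diff_ml_minus_clinical.csv")
    outputs = sorted((ws / "reports").glob("worst_case_*.csv")) + \
        sorted((ws / "reports").glob("v95_*.csv")) + \
        sorted((ws / "reports").glob("banded_dvh_*.csv")) + \
        sorted((ws / "reports").glob("verdict_*.json"))
    _write_manifest(ws, "robust", cfg.seed,
                    [ws / "plan_clinical_normalized.json", ws / "plan_ml_normalized.json"],
                    outputs)
    return {"scenarios": len(scenarios),
            "clinical_pass": results["clinical"]["verdict"]["pass"],
            "ml_pass": results["ml"]["verdict"]["pass"]}


class ScenarioEvalView:
    """Restrict a ScenarioEvaluation to a subset of scenario labels."""

    def __init__(self, ev, labels):
        from .robust import ScenarioEvaluation

        self.labels = labels
        keep = {l for l in labels}
        self.view = ScenarioEvaluation(
            [s for s in ev.scenarios if s.label in keep],
            {l: ev.structure_doses[l] for l in labels},
            {l: ev.dvhs[l] for l in labels},
            ev.voxel_volume_cc,
        )


def stage_report(cfg: PipelineConfig, ws: Path) -> dict:
    _require(ws, "robust")
    rep = ws / "reports"
    rx = load_plan(ws / "plan_clinical_normalized.json").prescription_cgy
    clin = pd.read_csv(rep / "worst_case_clinical.csv", index_col=[0, 1])
    ml = pd.read_csv(rep / "worst_case_ml.csv", index_col=[0, 1])

    def fmt_pct(v):
        return f"{v:.0f} ({percent_of_prescription(v, rx):.1f}%)"

    rows = []
    for (structure, index) in clin.index:
        c = clin.loc[(structure, index)]
        m = ml.loc[(structure, index)]
        rows.append({
            "structure": structure, "index": index,
            "clinical_min": fmt_pct(c["min"]), "clinical_nominal": fmt_pct(c["nominal"]),
            "clinical_max": fmt_pct(c["max"]),
            "ml_min": f"{m['min']:.0f} ({m['min'] - c['min']:+.0f})",
            "ml_nominal": fmt_pct(m["nominal"]),
            "ml_max": f"{m['max']:.0f} ({m['max'] - c['max']:+.0f})",
        })
    coverage = pd.DataFrame(rows)
    coverage.to_csv(rep / "coverage_table.csv", index=False)
    verdicts = {tag: json.loads((rep / f"verdict_{tag}.json").read_text())
                for tag in ("clinical", "ml")}
    lines = []
    for tag, v in verdicts.items():
        lines.append(f"{tag}: {'PASS' if v['pass'] else 'FAIL'} "
                     f"(min V95 = {v['min_v95_pct']:.1f}% in {v['worst_scenario']})")
        if not v["pass"]:
            lines.append(f"  failing scenarios: {', '.join(v['failing_scenarios'])}")
    (rep / "robustness_verdict.txt").write_text("\n".join(lines) + "\n")
    _write_manifest(ws, "report", cfg.seed,
                    [rep / "worst_case_clinical.csv", rep / "worst_case_ml.csv"],
                    [rep / "coverage_table.csv", rep / "robustness_verdict.txt"])
    return {"tables": ["coverage_table.csv", "qa_agreement.csv"],
            "verdicts": {t: v["pass"] for t, v in verdicts.items()}}


def run_stage(stage: str, cfg: PipelineConfig, ws: Path) -> dict:
    fns = {"synth": stage_synth, "qa": stage_qa, "train": stage_train,
           "predict": stage_predict, "dose": stage_dose, "robust": stage_robust,
           "report": stage_report}
    if stage not in fns:
        raise KeyError(f"unknown stage {stage!r}; stages are {STAGES}")
    return fns[stage](cfg, Path(ws))


def run_all(cfg: PipelineConfig, ws: Path) -> dict[str, dict]:
    return {stage: run_stage(stage, cfg, ws) for stage in STAGES}
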