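"""End-to-end orchestration: synth -> descriptors -> cell model -> model
training/validation -> diversity -> screening -> report.

Every stage writes plain CSV/JSON into the output directory together with a
manifest (parameters, seed, input hashes), so partial pipelines can be
resumed and any report value is recomputable from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import derive_seed
from .errors import PipelineError
from .cellmodel import CellModelParams, SpeciationProfile, clys_descriptor, required_incubation
from .descriptors import (
    MODEL_DESCRIPTORS,
    compute_descriptors,
    lipinski_violation,
    write_descriptor_matrix,
)
from .diversity import diversity_of
from .io import write_compound_table, write_structures
from .learner import (
    ForestSpec,
    beam_search,
    candidate_pool,
    train_model,
    bootstrap_validate,
    y_scramble,
    zero_rule,
)
from .screening import (
    bimodality_analysis,
    classify_activity,
    group_enrichment,
    logbb_association,
    rof_association,
    virtual_screen,
)
from .synthetic import GeneratorConfig, generate_experimental_set, generate_library

_STAGES = (
    "synth", "descriptors", "cellmodel", "train", "validate",
    "yscramble", "diversity", "screen", "report",
)


@dataclass
class RunConfig:
    """Pipeline settings; the defaults reproduce the study's stated protocol
    (threshold 50.0 %, 200-fold bootstrap, 1000 permutations, similarity
    cutoff 0.85, 51-tree depth-8 forest)."""

    outdir: str = "fiasma-run"
    seed: int = 0
    stages: tuple[str, ...] = _STAGES
    activity_threshold: float = 50.0
    bootstrap_resamples: int = 200
    n_permutations: int = 1000
    yscramble_resamples: int = 200
    similarity_cutoff: float = 0.85
    forest: ForestSpec = field(default_factory=ForestSpec)
    beam_width: int = 10
    beam_max_size: int = 5
    beam_score_resamples: int = 200
    pool_top_q: int = 30
    run_beam_search: bool = False
    cellmodel_compounds: int | None = 25  # None = all; the ODE stage is the slow one
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "forest" in raw:
            raw["forest"] = ForestSpec(**raw["forest"])
        if "generator" in raw:
            raw["generator"] = GeneratorConfig(**raw["generator"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return str(obj)
    return obj


def run_pipeline(config: RunConfig | None = None) -> dict:
    """Execute the enabled stages in order and return the aggregated report.

    Raises :class:`PipelineError` naming the failing stage; the manifest of
    completed stages is flushed to disk after every stage.
    """
    config = config or RunConfig()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    gen = dataclasses.replace(config.generator, seed=derive_seed(config.seed, "generator"))
    report: dict = {"seed": config.seed, "version": __version__}
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": _jsonable(dataclasses.asdict(config)),
        "stages_completed": [],
        "outputs": {},
    }

    def flush(stage: str, *files: Path) -> None:
        manifest["stages_completed"].append(stage)
        for f in files:
            manifest["outputs"][f.name] = _hash_file(f)
        (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))

    state: dict = {}
    for stage in config.stages:
        try:
            _run_stage(stage, config, gen, out, state, report, flush)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return report


def _run_stage(stage, config: RunConfig, gen: GeneratorConfig, out: Path,
               state: dict, report: dict, flush) -> None:
    if stage == "synth":
        exp = generate_experimental_set(gen)
        state["experiment"] = exp
        table_path = out / "experimental.csv"
        write_compound_table(exp.table, table_path)
        smi_path = out / "experimental.smi"
        write_structures(exp.structures, smi_path)
        truth_path = out / "truth.json"
        truth_path.write_text(json.dumps(_jsonable(exp.truth), indent=2))
        flush(stage, table_path, smi_path, truth_path)

    elif stage == "descriptors":
        exp = state["experiment"]
        matrix, labels = exp.labeled_matrix()
        state["matrix"], state["labels"] = matrix, labels
        flags_matrix, flags = compute_descriptors(exp.table, structures=exp.structures)
        mpath, fpath = out / "descriptors.csv", out / "descriptor_flags.csv"
        write_descriptor_matrix(flags_matrix, flags, mpath, fpath)
        flush(stage, mpath, fpath)

    elif stage == "cellmodel":
        exp = state["experiment"]
        params = CellModelParams.default()
        rows = []
        records = exp.table.records
        if config.cellmodel_compounds is not None:
            records = records[: config.cellmodel_compounds]
        for rec in records:
            profile = SpeciationProfile.from_pkas(rec.pka_base1, rec.pka_base2, rec.pka_acid)
            clys = clys_descriptor(profile, params, rec.logp or 0.0)
            t95 = required_incubation(profile, params, rec.logp or 0.0, cap_min=1e4)
            rows.append({"id": rec.id, "variant": profile.variant, "clys_um": clys,
                         "t95_min": t95, "exceeds_30min": t95 > 30.0})
        df = pd.DataFrame(rows).set_index("id")
        path = out / "cellmodel.csv"
        df.to_csv(path)
        report["cellmodel"] = {
            "n": len(df),
            "median_clys_um": float(df["clys_um"].median()),
            "n_slow_accumulators": int(df["exceeds_30min"].sum()),
        }
        flush(stage, path)

    elif stage == "train":
        matrix, labels = state["matrix"], state["labels"]
        if config.run_beam_search:
            pool = candidate_pool(matrix, labels, top_q=config.pool_top_q)
            results = beam_search(
                matrix, labels, pool,
                beam_width=config.beam_width, max_size=config.beam_max_size,
                spec=config.forest, seed=derive_seed(config.seed, "beam"),
                score_resamples=config.beam_score_resamples,
                final_resamples=config.bootstrap_resamples,
            )
            combo = list(results[config.beam_max_size].combination)
            report["beam"] = {
                str(size): {"combination": list(r.combination),
                            **r.report.summary()}
                for size, r in results.items()
            }
        else:
            combo = list(MODEL_DESCRIPTORS)
        model = train_model(matrix, labels, combo, config.forest)
        state["model"], state["combo"] = model, combo
        path = out / "model.pkl"
        model.save(path)
        report["model"] = {"descriptors": combo}
        flush(stage, path)

    elif stage == "validate":
        matrix, labels = state["matrix"], state["labels"]
        rep = bootstrap_validate(
            matrix[state["combo"]], labels, config.forest,
            n_resamples=config.bootstrap_resamples,
            seed=derive_seed(config.seed, "validate"),
        )
        report["validation"] = rep.summary()
        report["zero_rule_accuracy"] = zero_rule(labels)
        path = out / "validation.json"
        path.write_text(json.dumps(_jsonable(report["validation"]), indent=2))
        flush(stage, path)

    elif stage == "yscramble":
        matrix, labels = state["matrix"], state["labels"]
        res = y_scramble(
            matrix, labels, state["combo"], config.forest,
            n_permutations=config.n_permutations,
            seed=derive_seed(config.seed, "yscramble"),
            n_resamples=config.yscramble_resamples,
        )
        report["yscramble"] = {
            "n_permutations": config.n_permutations,
            "scaled_down": config.n_permutations < 1000,
            "null_youden_mean": res.null_youden_mean,
            "null_youden_sd": res.null_youden_sd,
            "null_accuracy_mean": res.null_accuracy_mean,
            "null_accuracy_sd": res.null_accuracy_sd,
            "z_youden": res.z_youden,
        }
        path = out / "yscramble.json"
        path.write_text(json.dumps(_jsonable(report["yscramble"]), indent=2))
        flush(stage, path)

    elif stage == "diversity":
        exp = state["experiment"]
        labels = state["labels"]
        whole, _ = diversity_of(exp.structures, config.similarity_cutoff)
        active_ids = [cid for cid, lab in labels.items() if lab == 1]
        actives, _ = diversity_of(
            {cid: exp.structures[cid] for cid in active_ids}, config.similarity_cutoff
        )
        report["diversity"] = {
            "similarity_cutoff": config.similarity_cutoff,
            "div_rel_whole": whole,
            "div_rel_actives": actives,
        }
        path = out / "diversity.json"
        path.write_text(json.dumps(_jsonable(report["diversity"]), indent=2))
        flush(stage, path)

    elif stage == "screen":
        exp, model = state["experiment"], state["model"]
        labels = state["labels"]
        residuals = [r.residual_activity for r in exp.table]
        bim = bimodality_analysis(residuals)
        report["bimodality"] = {
            "pooled_ks_p": bim.pooled_ks_p,
            "pooled_lilliefors_p": bim.pooled_lilliefors_p,
            "component_means": list(bim.component_means),
            "converged": bim.converged,
        }
        # Rule-of-Five association on the experimental panel
        rof_flags, rof_labels = [], []
        for rec in exp.table:
            res = lipinski_violation(rec.mw, rec.logp, rec.hbd, rec.hba)
            if res.evaluable:
                rof_flags.append(res.violated)
                rof_labels.append(classify_activity(rec.residual_activity).label)
        rof = rof_association(rof_labels, rof_flags)
        report["rule_of_five"] = {
            "chi_square": rof.chi_square, "p": rof.p,
            "violation_pct_active": rof.violation_pct_active,
            "violation_pct_inactive": rof.violation_pct_inactive,
        }
        logbb = logbb_association(
            {r.id: int(labels[r.id]) for r in exp.table},
            {r.id: r.logbb for r in exp.table if r.logbb is not None},
        )
        report["logbb"] = {"n": logbb.n, "violations": logbb.violations}
        screens = {}
        for kind in ("drug_like", "natural_like"):
            lib = generate_library(gen, kind)
            res = virtual_screen(lib.table, model, lib.structures, kind)
            entry = {
                "n_input": res.n_input,
                "n_excluded_incalculable": res.n_excluded_incalculable,
                "n_excluded_quaternary": res.n_excluded_quaternary,
                "n_excluded_duplicates": res.n_excluded_duplicates,
                "n_screened": res.n_screened,
                "n_predicted_active": res.n_predicted_active,
                "predicted_active_pct": 100.0 * res.predicted_active_fraction,
            }
            if kind == "drug_like":
                calls = {
                    cid: int(v)
                    for cid, v in res.predictions["predicted"].dropna().items()
                }
                rows, global_p = group_enrichment(calls, lib.groups)
                entry["global_p"] = global_p
                entry["enriched_groups"] = [r.group for r in rows if r.enriched]
                entry["planted_groups"] = lib.truth["enriched_groups"]
            screens[kind] = entry
            res.predictions.to_csv(out / f"screen_{kind}.csv", index_label="id")
        report["screening"] = screens
        flush(stage, out / "screen_drug_like.csv", out / "screen_natural_like.csv")

    elif stage == "report":
        path = out / "report.json"
        path.write_text(json.dumps(_jsonable(report), indent=2))
        flush(stage, path)

    else:
        raise PipelineError(f"unknown stage {stage!r}")
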