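"""End-to-end orchestration: simulate -> preprocess -> kinship -> MTM ->
decorrelate -> BN -> SEM -> evaluate, with a JSON run manifest.

Each stage writes its artifacts under the configured output directory and
records them (with SHA-256 hashes) in ``manifest.json``; re-runs skip
stages whose artifacts already exist unless forced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from ._engine import CHAIN_PRESETS, ChainSettings
from .bn import bootstrap_average, decorrelate_bvs, hill_climb, tabu_search
from .evaluate import compare_bvs, compare_dic, kfold_predictive_ability
from .kinship import build_A, build_G, filter_snps, impute_mean
from .mtm import MtmSpec, convergence_report, fit_mtm, summarize
from .preprocess import preprocess_pipeline
from .sem import SemSpec, build_lambda_mask, fit_sem, structural_summary
from .simulate import SimulationConfig, simulate_study

log = logging.getLogger("pinesem")

STAGES = ("simulate", "preprocess", "kinship", "fit_mtm", "learn_bn",
          "fit_sem", "evaluate")


@dataclass
class PipelineConfig:
    """Configuration of one full run."""

    outdir: str = "pipeline_out"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    kinship_kind: str = "G"             # A | G
    chain_preset: str = "desk"          # desk | full | cv
    cv_chain_preset: str = "cv"
    learner: str = "hc"                 # hc | tabu
    score: str = "bic"                  # bic | bge
    n_boot: int = 500
    strength_threshold: float = 0.95
    cv_folds: int = 0                   # 0 disables cross-validation
    dag_file: str | None = None         # user-supplied DAG bypasses learn_bn
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    force: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if self.kinship_kind not in ("A", "G"):
            raise ValueError("kinship_kind must be A or G")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def read_inputs(ped_path, geno_path, trait_path):
    """Load and cross-validate the three input files.

    Returns (Pedigree, GenotypeMatrix, TraitTable); raises with the first
    ten offending ids if the files disagree on tree membership.
    """
    ped = pio.read_pedigree(ped_path)
    geno = pio.read_vcf(geno_path) if str(geno_path).endswith(".vcf") \
        else pio.read_genotypes_tsv(geno_path)
    traits = pio.read_traits(trait_path)
    ped_ids = set(ped.ids)
    for label, ids in (("genotype", geno.ids), ("trait", traits.ids)):
        missing = [i for i in ids if i not in ped_ids]
        if missing:
            raise pio.IoError(
                f"{label} trees absent from pedigree: {missing[:10]}"
            )
    return ped, geno, traits


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = {"config": _config_dict(config), "stages": {}, "artifacts": {}}
    if manifest_path.exists() and not config.force:
        manifest["stages"] = json.loads(manifest_path.read_text()).get("stages", {})

    state: dict = {}

    def done(stage: str) -> bool:
        info = manifest["stages"].get(stage)
        if config.force or not info or info.get("status") != "ok":
            return False
        return all(Path(p).exists() for p in info.get("artifacts", []))

    def record(stage: str, artifacts: list[Path]) -> None:
        manifest["stages"][stage] = {
            "status": "ok",
            "seed": config.seed,
            "artifacts": [str(p) for p in artifacts],
            "sha256": {p.name: _sha256(p) for p in artifacts},
        }
        manifest_path.write_text(json.dumps(manifest, indent=1, default=str))

    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.time()
        try:
            arts = _run_stage(stage, config, out, state, skip=done(stage))
        except Exception as exc:  # noqa: BLE001 - manifest captures failures
            manifest["stages"][stage] = {
                "status": "failed", "error": str(exc),
                "traceback": traceback.format_exc(),
            }
            manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
            raise
        record(stage, arts)
        log.info("stage %s finished in %.1fs", stage, time.time() - t0)
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)

    def clean(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        return v

    return clean(d)


def _run_stage(stage, config, out, state, skip=False):
    """Run (or reload the artifacts of) one stage; returns artifact paths."""
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    settings = CHAIN_PRESETS[config.chain_preset]
    settings = ChainSettings(settings.iterations, settings.burn_in,
                             settings.thin, seed=config.seed)

    if stage == "simulate":
        paths = [out / "pedigree.csv", out / "genotypes.tsv",
                 out / "traits_raw.csv", out / "simulation.yaml"]
        if not skip:
            study = simulate_study(sim, with_genotypes=config.kinship_kind == "G")
            pio.write_pedigree(study.pedigree, paths[0])
            if study.genotypes is not None:
                pio.write_genotypes_tsv(study.genotypes, paths[1])
            else:
                paths[1].write_text("")
            pio.write_traits(study.traits, paths[2])
            pio.write_config(sim, paths[3])
            state["study"] = study
        else:
            state["pedigree"] = pio.read_pedigree(paths[0])
        return paths

    if stage == "preprocess":
        path = out / "traits_adjusted.csv"
        if not skip or "study" in state:
            if "study" in state:
                raw = state["study"].traits
            else:
                raw = pio.read_traits(out / "traits_raw.csv")
            adjusted = preprocess_pipeline(raw)
            pio.write_traits(adjusted, path)
            state["traits"] = adjusted
        else:
            state["traits"] = pio.read_traits(path)
        return [path, Path(str(path) + ".provenance.json")]

    if stage == "kinship":
        path = out / f"kinship_{config.kinship_kind}.tsv"
        if not skip:
            if config.kinship_kind == "A":
                ped = (state["study"].pedigree if "study" in state
                       else pio.read_pedigree(out / "pedigree.csv"))
                kin = build_A(ped)
            else:
                geno = (state["study"].genotypes if "study" in state
                        else pio.read_genotypes_tsv(out / "genotypes.tsv"))
                filtered, report = filter_snps(geno)
                log.info("SNP filters: %s", report)
                kin = build_G(impute_mean(filtered))
            pio.write_matrix(kin, path)
            state["kinship"] = kin
        else:
            state["kinship"] = pio.read_matrix(path)
        return [path]

    traits = state.get("traits") or pio.read_traits(out / "traits_adjusted.csv")
    kin = state.get("kinship") or pio.read_matrix(
        out / f"kinship_{config.kinship_kind}.tsv")

    if stage == "fit_mtm":
        paths = [out / "mtm_variances.csv", out / "mtm_correlations.csv",
                 out / "mtm_bvs.csv"]
        spec = MtmSpec(chain=settings)
        chain = fit_mtm(traits, kin, spec)
        state["chain_mtm"] = chain
        summary = summarize(chain)
        state["summary_mtm"] = summary
        summary.variance_table.to_csv(paths[0], index=False)
        summary.correlations.to_csv(paths[1])
        chain.bv_mean.to_csv(paths[2], index_label="id")
        convergence_report(chain, str(out / "diagnostics"))
        return paths

    if stage == "learn_bn":
        paths = [out / "consensus_dag.csv", out / "arc_strengths.csv",
                 out / "consensus_dag.dot", out / "arc_removal.csv"]
        if config.dag_file:
            dag = pio.read_dag(config.dag_file,
                               nodes=tuple(traits.trait_names))
            pio.write_dag(dag, paths[0])
            state["dag"] = dag
            return [paths[0]]
        chain = state["chain_mtm"]
        dec = decorrelate_bvs(chain.bv_mean, kin)
        data = dec.to_data()
        learner_fn = {
            "hc": lambda d: hill_climb(d, score=config.score),
            "tabu": lambda d: tabu_search(d, score=config.score),
        }[config.learner]
        avg = bootstrap_average(data, learner_fn, n_boot=config.n_boot,
                                threshold=config.strength_threshold,
                                seed=config.seed)
        state["dag"] = avg.consensus
        pio.write_dag(avg.consensus, paths[0])
        pio.write_averaged_network(avg, paths[1])
        pio.write_dot(avg.consensus, paths[2], avg)
        from .bn import arc_removal_delta
        if avg.consensus.edges:
            arc_removal_delta(data, avg.consensus, config.score).to_csv(
                paths[3], index=False)
        else:
            paths[3].write_text("from,to,delta\n")
        return paths

    if stage == "fit_sem":
        paths = [out / "sem_lambda.csv", out / "sem_variances.csv",
                 out / "sem_correlations_direct.csv",
                 out / "sem_correlations_reduced.csv", out / "sem_bvs.csv"]
        dag = state.get("dag")
        if dag is None and config.dag_file:
            dag = pio.read_dag(config.dag_file, nodes=tuple(traits.trait_names))
        if dag is None:
            dag = pio.read_dag(out / "consensus_dag.csv",
                               nodes=tuple(traits.trait_names))
        lam = build_lambda_mask(dag)
        spec = SemSpec(chain=settings, lambda_matrix=lam)
        chain = fit_sem(traits, kin, spec)
        state["chain_sem"] = chain
        tables = structural_summary(chain)
        state["summary_sem"] = summarize(chain)
        tables["lambda"].to_csv(paths[0], index=False)
        tables["variances"].to_csv(paths[1], index=False)
        tables["correlations_direct"].to_csv(paths[2])
        tables["correlations_reduced_form"].to_csv(paths[3])
        chain.bv_mean.to_csv(paths[4], index_label="id")
        return paths

    if stage == "evaluate":
        paths = [out / "bv_comparison.csv", out / "dic_comparison.csv"]
        comparison = compare_bvs(state["chain_mtm"], state["chain_sem"])
        comparison.table.to_csv(paths[0], index=False)
        dic_tab = compare_dic(state["summary_mtm"], state["summary_sem"])
        dic_tab["difference_mtm_minus_sem"] = [dic_tab.attrs["difference"], ""]
        dic_tab.to_csv(paths[1], index=False)
        if config.cv_folds >= 2:
            cv_settings = CHAIN_PRESETS[config.cv_chain_preset]
            mtm_spec = MtmSpec(chain=dataclasses.replace(
                cv_settings, seed=config.seed))
            dag = state["dag"]
            sem_spec = SemSpec(chain=dataclasses.replace(
                cv_settings, seed=config.seed),
                lambda_matrix=build_lambda_mask(dag))
            cv_mtm = kfold_predictive_ability(
                traits, kin, mtm_spec, k=config.cv_folds, seed=config.seed)
            cv_sem = kfold_predictive_ability(
                traits, kin, sem_spec, k=config.cv_folds, seed=config.seed)
            gains = cv_sem.gain_over(cv_mtm)
            cv_table = pd.DataFrame({
                "pa_mtm": cv_mtm.per_trait, "pa_sem": cv_sem.per_trait,
                "gain_pct": gains,
            })
            cv_path = out / "cv_predictive_ability.csv"
            cv_table.to_csv(cv_path, index_label="trait")
            paths.append(cv_path)
        return paths

    raise ValueError(f"unknown stage {stage}")
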