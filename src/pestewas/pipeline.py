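"""End-to-end orchestration: simulate -> exposure -> preprocess -> ewas -> dmr -> enrich.

A single :class:`RunConfig` (constructible from YAML) drives the stages; all
randomness flows from one root seed through fixed per-stage derivation keys,
so the same config and seed produce byte-identical output files.  Logs go to
stderr via the ``logging`` module; results never interleave with logs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dmr as dmr_mod
from . import enrichment as enrich_mod
from . import ewas as ewas_mod
from . import exposure as exposure_mod
from . import preprocess as pre_mod
from . import simulate as sim_mod

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "exposure", "preprocess", "ewas", "dmr", "enrich")
FLOAT_FORMAT = "%.8g"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    outdir: str = "pestewas_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # simulation
    n_cases: int = 569
    n_controls: int = 237
    n_probes: int = 20000
    effect_probes: int = 0
    effect_size_r: float = 0.3
    dmr_specs: tuple = ()
    # exposure
    radius_m: float = 500.0
    # preprocess
    winsor: tuple[float, float] = (0.05, 0.95)
    residual_mode: str = "ols"
    # ewas
    threshold: float = 1e-7
    strata: tuple[str, ...] = ("all", "cases", "controls")
    # dmr
    max_gap_bp: int = 1000
    min_probes: int = 5
    cutoff_quantile: float = 0.99
    permutations: int = 100
    # enrichment
    genesets: str | None = None     # GMT path; None -> generate synthetic sets
    n_gene_sets: int = 100

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")
        order = {s: i for i, s in enumerate(ALL_STAGES)}
        object.__setattr__(self, "stages",
                           tuple(sorted(self.stages, key=order.__getitem__)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "dmr_specs" in raw:
            raw = dict(raw)
            raw["dmr_specs"] = tuple(
                sim_mod.DmrSpec(**s) if isinstance(s, dict) else s
                for s in raw["dmr_specs"]
            )
        for key in ("stages", "strata", "winsor"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dmr_specs"] = [dataclasses.asdict(s) if dataclasses.is_dataclass(s) else s
                          for s in self.dmr_specs]
        return d

    def config_hash(self) -> str:
        # outdir is a deployment detail, not part of the analysis identity
        d = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def simulation_config(self) -> sim_mod.SimulationConfig:
        return sim_mod.SimulationConfig(
            n_cases=self.n_cases,
            n_controls=self.n_controls,
            n_probes=self.n_probes,
            effect_probes=self.effect_probes,
            effect_size_r=self.effect_size_r,
            dmr_specs=tuple(self.dmr_specs),
            seed=self.seed,
        )


def _write_csv(df: pd.DataFrame, path: Path, index: bool = True, sep=",") -> None:
    df.to_csv(path, index=index, sep=sep, float_format=FLOAT_FORMAT)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run report.

    Every stage writes its outputs under ``config.outdir`` in plain-text
    formats (CSV/TSV/GMT/JSON/BED).  Any stage failure raises
    :class:`StageError` naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # report files carry no wall-clock times or paths, so identical
    # (config, seed) runs produce byte-identical outputs; timers go to the log
    cfg_dict = {k: v for k, v in config.to_dict().items() if k != "outdir"}
    report: dict = {"config": cfg_dict, "config_hash": config.config_hash(),
                    "stages": {}}
    state: dict = {}
    for stage in config.stages:
        t0 = time.perf_counter()
        logger.info("stage %s: starting", stage)
        try:
            stage_report = _STAGE_FUNCS[stage](config, outdir, state)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raise with stage name
            raise StageError(stage, str(exc)) from exc
        report["stages"][stage] = stage_report
        logger.info("stage %s: done in %.1fs", stage, time.perf_counter() - t0)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    _write_text_report(report, outdir / "report.txt")
    return report


def _stage_simulate(config: RunConfig, outdir: Path, state: dict) -> dict:
    study = sim_mod.simulate_study(config.simulation_config(),
                                   radius_m=config.radius_m)
    state["study"] = study
    _write_csv(study.applications, outdir / "applications.csv", index=False)
    _write_csv(study.addresses, outdir / "addresses.csv", index=False)
    _write_csv(study.covariates, outdir / "covariates.csv")
    _write_csv(study.beta, outdir / "beta.tsv", sep="\t")
    _write_csv(study.annotation, outdir / "annotation.csv")
    study.truth.to_json(outdir / "truth.json")
    return {
        "applications": len(study.applications),
        "participants": len(study.covariates),
        "probes": len(study.beta),
        "planted_probes": len(study.truth.planted_probe_ids),
        "planted_regions": len(study.truth.planted_regions),
    }


def _require(state: dict, key: str, stage: str, hint: str):
    if key not in state:
        raise StageError(stage, f"missing upstream input {key!r}; enable {hint}")
    return state[key]


def _stage_exposure(config: RunConfig, outdir: Path, state: dict) -> dict:
    study: sim_mod.SimulatedStudy = _require(state, "study", "exposure", "simulate")
    annual = exposure_mod.annual_buffer_exposure(
        study.applications, study.addresses, radius_m=config.radius_m,
        participants=study.covariates.index,
    )
    profiles = exposure_mod.average_window(
        annual, study.covariates["blood_draw_year"],
        chemicals=list(study.config.copper_codes) + list(study.config.op_codes),
    )
    controls = study.covariates.index[study.covariates["pd_status"] == 0]
    scores = exposure_mod.dichotomize_and_count(
        profiles, controls, study.config.copper_codes, study.config.op_codes
    )
    state["counts"] = scores.counts
    long = profiles.stack().rename("window_average").reset_index()
    long.columns = ["participant_id", "chemical_code", "window_average"]
    _write_csv(long[long["window_average"] > 0], outdir / "exposure_profiles.csv",
               index=False)
    _write_csv(scores.counts, outdir / "counts.csv")
    corr = float(np.corrcoef(scores.counts["copper_count"],
                             scores.counts["op_count"])[0, 1])
    return {
        "participants": len(scores.counts),
        "copper_op_correlation": round(corr, 4),
        "mean_copper_count": round(float(scores.counts["copper_count"].mean()), 3),
        "mean_op_count": round(float(scores.counts["op_count"].mean()), 3),
    }


def _stage_preprocess(config: RunConfig, outdir: Path, state: dict) -> dict:
    study = _require(state, "study", "preprocess", "simulate")
    counts = _require(state, "counts", "preprocess", "exposure")
    beta_f, annot_f, filter_report = pre_mod.filter_probes(study.beta,
                                                           study.annotation)
    beta_w = pre_mod.winsorize(beta_f, *config.winsor)
    cov = study.covariates
    residuals = pre_mod.residualize(beta_w, cov, mode=config.residual_mode)
    exposure_adj = pre_mod.residualize_exposure(
        cov, counts["copper_count"], sample_ids=list(residuals.columns)
    )
    state.update(residuals=residuals, annot_f=annot_f, beta_w=beta_w,
                 exposure_adj=exposure_adj)
    _write_csv(residuals, outdir / "residuals.tsv", sep="\t")
    with open(outdir / "filter_report.json", "w") as fh:
        json.dump(filter_report, fh, indent=1, sort_keys=True)
    return {"filter": filter_report, "residual_mode": config.residual_mode}


def _stratum_samples(cov: pd.DataFrame, stratum: str) -> list:
    if stratum == "all":
        return list(cov.index)
    want = 1 if stratum == "cases" else 0
    return list(cov.index[cov["pd_status"] == want])


def _stage_ewas(config: RunConfig, outdir: Path, state: dict) -> dict:
    study = _require(state, "study", "ewas", "simulate")
    counts = _require(state, "counts", "ewas", "exposure")
    beta_w = _require(state, "beta_w", "ewas", "preprocess")
    annot_f = state["annot_f"]
    cov = study.covariates
    out: dict = {}
    tables: dict[str, pd.DataFrame] = {}
    inflation: dict = {}
    for stratum in config.strata:
        samples = _stratum_samples(cov, stratum)
        if len(samples) < 10:
            raise StageError("ewas", f"stratum {stratum!r} has too few samples")
        # residualize within the stratum (design refit on the subset)
        resid = state["residuals"] if stratum == "all" else pre_mod.residualize(
            beta_w[samples], cov.loc[samples], mode=config.residual_mode
        )
        x_adj = (state["exposure_adj"] if stratum == "all"
                 else pre_mod.residualize_exposure(
                     cov.loc[samples], counts["copper_count"], sample_ids=samples))
        table = ewas_mod.moderated_fit(
            resid, x_adj, threshold=config.threshold, annot=annot_f,
            residual_df=pre_mod.adjusted_residual_df(cov.loc[samples]),
        )
        z = ewas_mod.z_from_p(table["p"].to_numpy(), sign=table["slope"].to_numpy())
        infl = ewas_mod.empirical_null_correct(z, seed=config.seed)
        table["p_corrected"] = infl.p_corrected
        tables[stratum] = table
        inflation[stratum] = infl.to_dict()
        suffix = "" if stratum == "all" else f"_{stratum}"
        _write_csv(table, outdir / f"ewas_results{suffix}.tsv", sep="\t")
        out[stratum] = {
            "n_samples": len(samples),
            "n_significant": int(table["significant"].sum()),
            "lambda_raw": round(infl.lambda_raw, 4),
            "lambda_corrected": round(infl.lambda_corrected, 4),
        }
    state["ewas_tables"] = tables
    with open(outdir / "inflation.json", "w") as fh:
        json.dump(inflation, fh, indent=1, sort_keys=True)
    if "cases" in tables and "controls" in tables and "all" in tables:
        top = tables["all"]
        subset = list(top.index[top["significant"]])
        if len(subset) < 3:
            subset = list(top.index[: min(100, len(top))])
        out["case_control_concordance"] = round(
            ewas_mod.stratified_concordance(tables["cases"], tables["controls"],
                                            subset), 4)
    if "all" in tables:
        head = tables["all"].head(5)
        out["top_hits"] = [
            {"probe": pid, "bicor_r": round(float(row["bicor_r"]), 4),
             "p": float(row["p"]), "gene": row.get("gene", "")}
            for pid, row in head.iterrows()
        ]
    return out


def _stage_dmr(config: RunConfig, outdir: Path, state: dict) -> dict:
    residuals = _require(state, "residuals", "dmr", "preprocess")
    annot_f = state["annot_f"]
    x_adj = state["exposure_adj"]
    regions = dmr_mod.find_dmrs(
        residuals, x_adj, annot_f,
        max_gap_bp=config.max_gap_bp, min_probes=config.min_probes,
        cutoff_quantile=config.cutoff_quantile,
        B=config.permutations, seed=config.seed,
    )
    state["dmrs"] = regions
    flat = regions.drop(columns=["probe_ids"], errors="ignore")
    _write_csv(flat, outdir / "dmrs.tsv", sep="\t")
    dmr_mod.dmrs_to_bed(regions, outdir / "dmrs.bed")
    return {
        "n_regions": len(regions),
        "cutoff": round(float(regions.attrs.get("cutoff", float("nan"))), 6),
        "n_significant": int((regions["p_perm"] < 0.05).sum()) if len(regions) else 0,
    }


def _stage_enrich(config: RunConfig, outdir: Path, state: dict) -> dict:
    study = _require(state, "study", "enrich", "simulate")
    annot_f = state["annot_f"]
    tables = _require(state, "ewas_tables", "enrich", "ewas")
    if config.genesets:
        sets = enrich_mod.read_gmt(config.genesets)
    else:
        planted = sorted({
            g for p in study.truth.planted_probe_ids
            if (g := str(study.annotation.loc[p, "gene"])) != ""
        })
        sets = sim_mod.generate_gene_sets(
            annot_f, n_sets=config.n_gene_sets,
            planted_genes=planted or None, seed=config.seed,
        )
        enrich_mod.write_gmt(sets, outdir / "genesets.gmt")

    results = []
    out: dict = {}
    dmp_sel = list(tables["all"].index[tables["all"]["significant"]]) \
        if "all" in tables else []
    selections = {"dmp": dmp_sel}
    if "dmrs" in state and len(state["dmrs"]):
        selections["dmr"] = [p for ids in state["dmrs"]["probe_ids"] for p in ids]
    for source, sel in selections.items():
        if sel:
            tab = enrich_mod.run_enrichment(sel, annot_f, sets)
        else:
            logger.warning("no %s probes selected; empty enrichment table", source)
            tab = pd.DataFrame()
        if len(tab):
            tab.insert(0, "source", source)
            results.append(tab)
        out[source] = {"n_selected_probes": len(sel),
                       "n_sets_tested": len(tab),
                       "n_fdr05": int((tab["fdr"] < 0.05).sum()) if len(tab) else 0}
    combined = pd.concat(results, ignore_index=True) if results else pd.DataFrame()
    _write_csv(combined, outdir / "enrichment.tsv", sep="\t", index=False)
    return out


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "exposure": _stage_exposure,
    "preprocess": _stage_preprocess,
    "ewas": _stage_ewas,
    "dmr": _stage_dmr,
    "enrich": _stage_enrich,
}


def _write_text_report(report: dict, path: Path) -> None:
    lines = [
        "pestewas run report",
        f"config hash: {report['config_hash']}",
        "",
    ]
    for stage, info in report["stages"].items():
        lines.append(f"[{stage}]")
        for key, val in info.items():
            lines.append(f"  {key}: {val}")
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
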