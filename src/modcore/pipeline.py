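"""Pipeline orchestration: configuration, stage sequencing, seeding, and
report assembly.

The workflow mirrors the end-to-end study design: decompose the
interactome into modules and test the decomposition against rewired nulls;
locate the module enriched for the disease gene set with a covariate-
matched permutation test; dichotomize the module's tissue expression and
score specificity; call extreme differential expression in matched pairs;
test the variant burden (rare fraction, case-vs-reference frequencies,
reciprocal-regression outliers); and integrate mutation calls over the
k-core layering.

Configuration is a flat ``key = value`` text file with ``[sections]``
(parsed with :mod:`configparser`); CLI flags override file values; unknown
keys are rejected.  All randomness derives from one global seed: stage
``s`` (position i in :data:`STAGES`) uses ``(seed + 7919 * (i + 1)) %
2**31``, so overriding one stage's seed leaves every other stage's stream
unchanged.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__ as _version
from . import enrichment, expression, interactome, simulate, variants

logger = logging.getLogger("modcore")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "make_report", "STAGES"]

STAGES = (
    "simulate", "modularize", "null_test", "enrich", "dichotomize",
    "specificity", "de_call", "burden", "outliers", "integrate",
)

_SCHEMA: dict[str, dict[str, type]] = {
    "inputs": {
        "edge_list": str, "annotation": str, "gene_sets": str,
        "expression": str, "variants": str, "output_dir": str,
    },
    "stages": {name: bool for name in STAGES},
    "params": {
        "seed": int, "n_random": int, "n_perm": int, "restarts": int,
        "min_module_size": int, "fdr_target": float, "balance_threshold": float,
        "fc_min": float, "upper_q": float, "lower_q": float, "min_expr": float,
        "outlier_tail": float, "n_swap_multiplier": float,
        "scene_blocks": int, "scene_block_size": int,
        "scene_p_in": float, "scene_p_out": float,
        "scene_af_shift": float, "scene_confound": float,
    },
}


@dataclass
class PipelineConfig:
    """All inputs, stage toggles and statistical parameters of one run."""

    # inputs
    edge_list: str = ""
    annotation: str = ""
    gene_sets: str = ""
    expression: str = ""
    variants: str = ""
    output_dir: str = "modcore_out"
    # stage toggles
    stages: dict[str, bool] = field(
        default_factory=lambda: {name: True for name in STAGES}
    )
    # parameters
    seed: int = 0
    n_random: int = 100
    n_perm: int = 1000
    restarts: int = 8
    min_module_size: int = 6
    fdr_target: float = 0.1
    balance_threshold: float = 0.05
    fc_min: float = 2.0
    upper_q: float = 0.975
    lower_q: float = 0.025
    min_expr: float = 1.0
    outlier_tail: float = 0.05
    n_swap_multiplier: float = 10.0
    scene_blocks: int = 8
    scene_block_size: int = 40
    scene_p_in: float = 0.3
    scene_p_out: float = 0.005
    scene_af_shift: float = 0.1
    scene_confound: float = 2.0

    @classmethod
    def from_file(cls, path: str | Path, overrides: Mapping[str, Any] | None = None
                  ) -> "PipelineConfig":
        parser = configparser.ConfigParser()
        read = parser.read(path)
        if not read:
            raise FileNotFoundError(f"config file not found: {path}")
        cfg = cls()
        for section in parser.sections():
            if section not in _SCHEMA:
                raise ValueError(f"config: unknown section [{section}]")
            for key, raw in parser[section].items():
                if key not in _SCHEMA[section]:
                    raise ValueError(f"config: unknown key {key!r} in [{section}]")
                typ = _SCHEMA[section][key]
                if section == "stages":
                    cfg.stages[key] = parser[section].getboolean(key)
                elif typ is int:
                    setattr(cfg, key, int(raw))
                elif typ is float:
                    setattr(cfg, key, float(raw))
                else:
                    setattr(cfg, key, raw)
        if overrides:
            cfg.apply_overrides(overrides)
        return cfg

    def apply_overrides(self, overrides: Mapping[str, Any]) -> None:
        for key, value in overrides.items():
            if value is None:
                continue
            if key in self.stages:
                self.stages[key] = bool(value)
            elif hasattr(self, key):
                setattr(self, key, value)
            else:
                raise ValueError(f"config: unknown override {key!r}")

    def stage_seed(self, stage: str) -> int:
        i = STAGES.index(stage)
        return int((self.seed + 7919 * (i + 1)) % (2**31))

    def to_dict(self) -> dict[str, Any]:
        d = {f.name: getattr(self, f.name) for f in fields(self) if f.name != "stages"}
        d["stages"] = dict(self.stages)
        return d

    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-stage result summaries plus run provenance."""

    summary: dict[str, Any]
    tables: dict[str, pd.DataFrame]
    warnings: list[str] = field(default_factory=list)


def _round_floats(obj: Any, ndigits: int = 10) -> Any:
    if isinstance(obj, float):
        if np.isnan(obj):
            return None
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), ndigits)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    return obj


def make_report(report: RunReport, outdir: str | Path) -> Path:
    """Write the TSV bundle and the deterministic JSON summary.

    Floats are serialized at fixed precision and keys sorted, so two runs
    with an identical config and seed produce byte-identical summaries.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in report.tables.items():
        table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False,
                     float_format="%.10g")
    payload = _round_floats({"summary": report.summary, "warnings": report.warnings})
    path = outdir / "report.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the enabled stages in dependency order.

    Inputs come either from the configured files or, when the ``simulate``
    stage is on, from a composite synthetic scene written to the output
    directory.  Each stage's outputs are written before the next stage
    starts; a stage failure aborts with a stage-labelled error.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        summary={
            "provenance": {
                "config": config.to_dict(),
                "config_hash": config.config_hash(),
                "version": _version,
            }
        },
        tables={},
    )
    state: dict[str, Any] = {}

    def stage_enabled(name: str) -> bool:
        return bool(config.stages.get(name, False))

    def run_stage(name: str, fn) -> None:
        if not stage_enabled(name):
            return
        logger.info("stage %s: starting", name)
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    # ---- simulate -------------------------------------------------------
    def _simulate():
        scene = simulate.gen_scene(
            config.stage_seed("simulate"),
            n_blocks=config.scene_blocks, block_size=config.scene_block_size,
            p_in=config.scene_p_in, p_out=config.scene_p_out,
            af_shift=config.scene_af_shift, confound_factor=config.scene_confound,
        )
        state["scene"] = scene
        interactome.write_edge_list(scene.graph, outdir / "edges.tsv")
        enrichment.write_annotation(scene.annotation, outdir / "annotation.tsv")
        expression.write_expression_tsv(scene.atlas, outdir / "atlas.tsv")
        variants.write_variant_table(scene.variants, outdir / "variants.tsv")
        for key, truth in scene.truths.items():
            truth.write(outdir / f"truth_{key}.json")
        state.update(
            graph=scene.graph, annotation=scene.annotation, atlas=scene.atlas,
            variant_table=scene.variants, cases=scene.cases, controls=scene.controls,
            disease=enrichment.GeneSet("disease", frozenset(scene.disease_genes)),
        )
        report.summary["simulate"] = {
            "n_nodes": scene.graph.number_of_nodes(),
            "n_edges": scene.graph.number_of_edges(),
            "n_disease_genes": len(scene.disease_genes),
            "n_variants": len(scene.variants),
        }

    run_stage("simulate", _simulate)

    # ---- load configured inputs where the scene did not provide them ----
    def _need(key: str, loader, path: str, stage: str):
        if key in state:
            return
        if not path:
            raise RuntimeError(
                f"stage {stage!r} failed: no input for {key!r} "
                f"(configure [inputs] or enable the simulate stage)"
            )
        p = Path(path)
        if not p.exists():
            raise RuntimeError(f"stage {stage!r} failed: missing input file {p}")
        state[key] = loader(p)

    # ---- modularize -----------------------------------------------------
    def _modularize():
        _need("graph", interactome.read_edge_list, config.edge_list, "modularize")
        part = interactome.louvain_partition(
            state["graph"], config.stage_seed("modularize"), restarts=config.restarts
        )
        state["partition"] = part
        interactome.write_partition(part, outdir / "partition.tsv")
        coreness = interactome.kcore_decompose(state["graph"])
        state["coreness"] = coreness
        interactome.write_coreness(coreness, outdir / "coreness.tsv")
        report.summary["modularize"] = {
            "q": part.q, "n_modules": part.n_modules,
            "max_coreness": max(coreness.values()),
        }

    run_stage("modularize", _modularize)

    # ---- null test ------------------------------------------------------
    def _null_test():
        _need("graph", interactome.read_edge_list, config.edge_list, "null_test")
        null = interactome.modularity_null_test(
            state["graph"], n_random=config.n_random,
            seed=config.stage_seed("null_test"),
            n_swap_multiplier=config.n_swap_multiplier, restarts=config.restarts,
        )
        state["null"] = null
        report.tables["modularity_null"] = pd.DataFrame({"q_null": list(null.q_null)})
        report.summary["null_test"] = {
            "q_observed": null.q_observed,
            "q_null_max": max(null.q_null),
            "p_empirical": null.p_empirical,
            "n_random": null.n_random,
        }

    run_stage("null_test", _null_test)

    # ---- enrichment -----------------------------------------------------
    def _enrich():
        if "partition" not in state:
            raise RuntimeError("stage 'enrich' failed: requires the modularize stage")
        _need("annotation", enrichment.read_annotation, config.annotation, "enrich")
        ann = state["annotation"]
        if "disease" not in state:
            if config.gene_sets:
                sets = (enrichment.read_gmt(config.gene_sets)
                        if str(config.gene_sets).endswith(".gmt")
                        else [enrichment.read_gene_list(config.gene_sets)])
                state["disease"] = sets[0]
            elif "disease" in ann.columns:
                state["disease"] = enrichment.GeneSet(
                    "disease", frozenset(ann.loc[ann["disease"], "gene"])
                )
            else:
                raise RuntimeError("stage 'enrich' failed: no disease gene set")
        disease = state["disease"]
        universe = set(state["graph"].nodes())
        scan = enrichment.module_set_scan(
            state["partition"], [disease], universe,
            min_module_size=config.min_module_size,
        )
        enrichment.write_enrichment_results(scan, outdir / "enrichment.tsv")
        report.tables["enrichment"] = pd.DataFrame([r.__dict__ for r in scan])
        top = min(scan, key=lambda r: (r.fdr, r.p_value))
        state["top_module_id"] = top.module_id
        state["top_module"] = state["partition"].module_genes(top.module_id)
        pool = enrichment.build_matched_background(
            disease, ann, balance_threshold=config.balance_threshold,
            seed=config.stage_seed("enrich"),
        )
        state["pool"] = pool
        module_set = enrichment.GeneSet("top_module", frozenset(state["top_module"]))
        p_matched = enrichment.matched_permutation_test(
            module_set, disease, pool, n_perm=config.n_perm,
            seed=config.stage_seed("enrich"),
        )
        report.summary["enrich"] = {
            "top_module_id": int(top.module_id),
            "top_module_size": top.n,
            "overlap": top.k,
            "fdr": top.fdr,
            "hypergeom_p": top.p_value,
            "matched_permutation_p": p_matched,
            "pool_size": len(pool.genes),
            "pool_balance": dict(pool.balance),
        }

    run_stage("enrich", _enrich)

    # ---- expression dichotomy ------------------------------------------
    def _dichotomize():
        _need("atlas", expression.read_expression_tsv, config.expression, "dichotomize")
        atlas = state["atlas"]
        target = state.get("top_module")
        matrix = atlas.loc[atlas.index.intersection(sorted(target))] if target else atlas
        dich = expression.dichotomize(matrix)
        state["dichotomy"] = dich
        table = pd.DataFrame({
            "gene": sorted(dich.gene_group),
            "group": [dich.gene_group[g] for g in sorted(dich.gene_group)],
        })
        report.tables["dichotomy_genes"] = table
        n_t1 = sum(1 for v in dich.sample_cluster.values() if v == "T1")
        report.summary["dichotomize"] = {
            "n_group1": int((table["group"] == 1).sum()),
            "n_group2": int((table["group"] == 2).sum()),
            "n_t1_samples": n_t1,
            "n_t2_samples": len(dich.sample_cluster) - n_t1,
        }

    run_stage("dichotomize", _dichotomize)

    # ---- specificity ----------------------------------------------------
    def _specificity():
        _need("atlas", expression.read_expression_tsv, config.expression, "specificity")
        prof = expression.expression_breadth(state["atlas"])
        state["specificity"] = prof
        table = prof.breadth.copy()
        table.insert(0, "tau", prof.tau)
        table = table.reset_index(names="gene")
        table.columns = ["gene", "tau"] + [f"breadth_q{int(q*100)}" for q in prof.thresholds]
        report.tables["specificity"] = table
        summary = {"median_tau": float(prof.tau.median())}
        if "dichotomy" in state:
            gg = state["dichotomy"].gene_group
            g1 = [g for g, grp in gg.items() if grp == 1]
            g2 = [g for g, grp in gg.items() if grp == 2]
            from scipy import stats as _st
            res = _st.ranksums(prof.tau.loc[g1], prof.tau.loc[g2])
            summary.update(
                median_tau_group1=float(prof.tau.loc[g1].median()),
                median_tau_group2=float(prof.tau.loc[g2].median()),
                tau_group_p=float(res.pvalue),
            )
        report.summary["specificity"] = summary

    run_stage("specificity", _specificity)

    # ---- extreme DE -----------------------------------------------------
    def _de_call():
        if "cases" not in state:
            raise RuntimeError(
                "stage 'de_call' failed: matched case/control expression requires "
                "the simulate stage in this configuration"
            )
        de = expression.extreme_de_call(
            state["cases"], state["controls"], fc_min=config.fc_min,
            upper_q=config.upper_q, lower_q=config.lower_q,
            min_expr=config.min_expr,
        )
        state["de"] = de
        report.tables["de_calls"] = de.per_pair[
            de.per_pair["up_extreme"] | de.per_pair["down_extreme"]
        ].reset_index(drop=True)
        summary = {"n_extreme_genes": int(de.any_extreme.sum())}
        if "top_module" in state and "graph" in state:
            enr = expression.de_module_enrichment(
                de, state["top_module"], state["graph"].nodes()
            )
            summary["module_de_enrichment_p"] = enr.p_value
        report.summary["de_call"] = summary

    run_stage("de_call", _de_call)

    # ---- variant burden -------------------------------------------------
    def _burden():
        _need("variant_table", variants.read_variant_table, config.variants, "burden")
        vt = state["variant_table"]
        frac = variants.rare_fraction(vt)
        summary: dict[str, Any] = {
            "rare_fraction": frac.fraction, "n_rare": frac.n_rare,
            "n_nonsynonymous": frac.n_total,
        }
        gene_results, per_variant = variants.af_case_vs_reference(
            vt, fdr_target=config.fdr_target
        )
        state["burden_genes"] = [r.gene for r in gene_results]
        report.tables["burden_variants"] = per_variant[
            ["variant_id", "gene", "consequence", "case_alt", "case_an",
             "ref_af", "p", "fdr"]
        ]
        summary["n_burden_genes"] = len(gene_results)
        if "top_module" in state and "pool" in state:
            module_set = enrichment.GeneSet(
                "top_module", frozenset(state["top_module"])
            )
            obs, exp, p = variants.rare_enrichment_permutation(
                module_set, vt, state["pool"], n_perm=config.n_perm,
                seed=config.stage_seed("burden"),
            )
            summary.update(module_rare_fraction=obs, expected_rare_fraction=exp,
                           rare_enrichment_p=p)
        report.summary["burden"] = summary

    run_stage("burden", _burden)

    # ---- regression outliers -------------------------------------------
    def _outliers():
        _need("variant_table", variants.read_variant_table, config.variants, "outliers")
        res = variants.reciprocal_regression_outliers(
            state["variant_table"], tail=config.outlier_tail
        )
        state["outliers"] = res
        report.tables["outlier_variants"] = res.table[res.table["outlier"]].reset_index(
            drop=True
        )
        report.summary["outliers"] = {
            "n_outlier_variants": int(res.table["outlier"].sum()),
            "n_implicated_genes": len(res.implicated_genes),
        }

    run_stage("outliers", _outliers)

    # ---- integrate ------------------------------------------------------
    def _integrate():
        needed = ("top_module", "coreness", "burden_genes")
        if any(k not in state for k in needed):
            raise RuntimeError(
                "stage 'integrate' failed: requires modularize, enrich and burden"
            )
        module = set(state["top_module"])
        mutated = set(state["burden_genes"]) & module
        summary: dict[str, Any] = {}
        if mutated:
            module_k = [state["coreness"][g] for g in module]
            bins = variants.quantile_coreness_bins(module_k, n_bins=5)
            prof = variants.coreness_burden_profile(
                mutated, module, state["coreness"], bins=bins,
                n_perm=config.n_perm, seed=config.stage_seed("integrate"),
            )
            report.tables["coreness_burden"] = prof.table
            summary.update(u_curve_s=prof.s_observed, u_curve_p=prof.p_curve)
        if "dichotomy" in state:
            gg = state["dichotomy"].gene_group
            group1 = {g for g, grp in gg.items() if grp == 1} & module
            K = state["coreness"]
            core = {g for g in module if K.get(g, 0) >= np.quantile(
                [K[m] for m in module], 0.8)}
            if core and group1:
                bias = variants.core_group_bias(core, group1, module)
                summary["core_group1_bias_p"] = bias.p_value
        report.summary["integrate"] = summary

    run_stage("integrate", _integrate)

    make_report(report, outdir)
    return report
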