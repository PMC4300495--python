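"""Seeded generators for every input shape the pipeline consumes, with
planted ground truth for recovery testing.

These stand in for the external resources an analysis of this kind draws
on — a curated interactome, covariate-annotated disease gene lists, a
multi-section brain expression atlas, and case/control variant tables —
each with a planted signal (community structure, covariate confounding,
a tissue-specific gene group, frequency-shifted genes, fold-changed genes)
that the analysis modules are expected to recover.

Every generator is a pure function of its parameters and seed; the
returned :class:`GroundTruth` serializes to JSON and fully determines
regeneration.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "GroundTruth",
    "gen_modular_network",
    "gen_gene_annotation",
    "gen_expression_matrix",
    "gen_variant_table",
    "gen_paired_case_control_expression",
    "gen_scene",
    "Scene",
]


@dataclass(frozen=True)
class GroundTruth:
    """What a generator planted, keyed by descriptive names.

    ``params`` echoes every generator argument (including the seed) so the
    output can be regenerated byte-identically.
    """

    kind: str
    params: Mapping[str, object]
    planted: Mapping[str, object]

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (set, frozenset)):
                return sorted(o)
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o).__name__)
        return json.dumps(asdict(self), sort_keys=True, default=default)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(kind=d["kind"], params=d["params"], planted=d["planted"])

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _gene_names(n: int, prefix: str = "G") -> list[str]:
    width = max(5, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

def gen_modular_network(
    n_blocks: int = 10,
    block_sizes: int | Sequence[int] = 30,
    p_in: float = 0.3,
    p_out: float = 0.005,
    seed: int = 0,
    degree_heterogeneity: float = 0.0,
) -> tuple[nx.Graph, GroundTruth]:
    """Planted-partition random graph over synthetic gene symbols.

    Edges fall within a block with probability ``p_in`` and between blocks
    with ``p_out``.  With ``degree_heterogeneity`` > 0 the model is
    degree-corrected: each node gets a log-normal propensity w_v (log-sd =
    the parameter, normalized to mean 1) and the pair probability becomes
    p * w_u * w_v (clipped at 1), giving the broad degree — and hence
    coreness — spread of curated interactomes while keeping the planted
    block structure.  Isolated nodes are removed and recorded in the
    ground truth.
    """
    if not (0 <= p_out < p_in <= 1):
        raise ValueError("gen_modular_network: need 0 <= p_out < p_in <= 1")
    if degree_heterogeneity < 0:
        raise ValueError("gen_modular_network: degree_heterogeneity must be >= 0")
    sizes = [block_sizes] * n_blocks if isinstance(block_sizes, int) else list(block_sizes)
    if not sizes or any(s < 1 for s in sizes):
        raise ValueError("gen_modular_network: empty blocks")
    n = sum(sizes)
    rng = np.random.default_rng(seed)
    block_idx = np.repeat(np.arange(len(sizes)), sizes)
    if degree_heterogeneity > 0:
        w = rng.lognormal(0.0, degree_heterogeneity, size=n)
        w /= w.mean()
    else:
        w = np.ones(n)
    names = _gene_names(n)
    graph = nx.Graph()
    graph.add_nodes_from(names)
    # row-wise upper-triangle Bernoulli sampling keeps memory linear in n
    for i in range(n - 1):
        j = np.arange(i + 1, n)
        p = np.where(block_idx[j] == block_idx[i], p_in, p_out) * w[i] * w[j]
        hit = j[rng.random(n - 1 - i) < np.clip(p, 0.0, 1.0)]
        graph.add_edges_from((names[i], names[k]) for k in hit)
    block_of = {names[i]: int(block_idx[i]) for i in range(n)}
    isolated = sorted(nx.isolates(graph))
    graph.remove_nodes_from(isolated)
    if graph.number_of_nodes() == 0:
        raise ValueError("gen_modular_network: parameters produced an empty graph")
    truth = GroundTruth(
        kind="modular_network",
        params={"n_blocks": n_blocks, "block_sizes": sizes, "p_in": p_in,
                "p_out": p_out, "degree_heterogeneity": degree_heterogeneity,
                "seed": seed},
        planted={"partition": {g: block_of[g] for g in graph.nodes()},
                 "removed_isolated": isolated},
    )
    return graph, truth


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def gen_gene_annotation(
    genes: Sequence[str],
    cds_lognormal_params: tuple[float, float] = (7.2, 0.8),
    gc_beta_params: tuple[float, float] = (20.0, 18.0),
    confound_factor: float = 2.0,
    disease_set_size: int = 50,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-gene covariates with a planted length-biased disease set.

    CDS lengths are log-normal (defaults give a median near 1.3 kb), GC
    content is Beta-distributed.  Disease genes are sampled with
    probability proportional to ``cds_length ** log2(confound_factor)``, so
    ``confound_factor`` = 1 means no confounding and 4 means a strong bias
    toward long genes — the bias a matched background must neutralize.
    """
    if confound_factor < 1:
        raise ValueError("gen_gene_annotation: confound_factor must be >= 1")
    genes = list(genes)
    if disease_set_size > len(genes):
        raise ValueError("gen_gene_annotation: disease_set_size exceeds gene count")
    rng = np.random.default_rng(seed)
    mu, sigma = cds_lognormal_params
    cds = np.round(np.exp(rng.normal(mu, sigma, size=len(genes)))).astype(int)
    cds = np.maximum(cds, 60)
    a, b = gc_beta_params
    gc = rng.beta(a, b, size=len(genes))
    w = cds.astype(float) ** np.log2(confound_factor)
    w = w / w.sum()
    disease_idx = rng.choice(len(genes), size=disease_set_size, replace=False, p=w)
    disease = {genes[i] for i in disease_idx}
    df = pd.DataFrame({
        "gene": genes,
        "cds_length": cds,
        "gc_content": gc,
        "disease": [g in disease for g in genes],
    })
    truth = GroundTruth(
        kind="gene_annotation",
        params={"n_genes": len(genes), "cds_lognormal_params": list(cds_lognormal_params),
                "gc_beta_params": list(gc_beta_params),
                "confound_factor": confound_factor,
                "disease_set_size": disease_set_size, "seed": seed},
        planted={"disease_genes": sorted(disease)},
    )
    return df, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def gen_expression_matrix(
    genes: Sequence[str],
    samples: Sequence[str],
    group1_genes: Sequence[str],
    t1_samples: Sequence[str],
    effect_size: float = 2.5,
    noise_sd: float = 0.5,
    baseline_high_genes: Sequence[str] = (),
    baseline_high_shift: float = 1.5,
    t1_depression: float | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Two-group tissue expression structure with log-normal noise.

    All genes share a log-scale baseline; ``group1_genes`` gain
    ``effect_size`` (log units) in ``t1_samples`` only (the
    tissue-specific sub-component), and ``baseline_high_genes`` are
    elevated everywhere (the ubiquitous sub-component) but mildly
    *depressed* by ``t1_depression`` log units in the T1 samples — the
    relative pattern ubiquitously expressed genes show in a tissue they do
    not favor, and what makes the two groups separable after per-gene
    normalization.  ``t1_depression`` defaults to ``effect_size / 5``.
    Values are exponentiated, hence non-negative and FPKM-like.
    """
    genes, samples = list(genes), list(samples)
    g1 = set(group1_genes)
    t1 = set(t1_samples)
    if not g1 <= set(genes) or not t1 <= set(samples):
        raise ValueError("gen_expression_matrix: planted labels outside the axes")
    if g1 & set(baseline_high_genes):
        raise ValueError("gen_expression_matrix: a gene cannot be both tissue-specific "
                         "and baseline-high")
    rng = np.random.default_rng(seed)
    log_base = rng.normal(1.0, 0.3, size=len(genes))
    log_vals = log_base[:, None] + rng.normal(0.0, noise_sd, size=(len(genes), len(samples)))
    g1_mask = np.array([g in g1 for g in genes])
    t1_mask = np.array([s in t1 for s in samples])
    log_vals[np.ix_(g1_mask, t1_mask)] += effect_size
    hi_mask = np.array([g in set(baseline_high_genes) for g in genes])
    log_vals[hi_mask, :] += baseline_high_shift
    if t1_depression is None:
        t1_depression = effect_size / 5.0
    log_vals[np.ix_(hi_mask, t1_mask)] -= t1_depression
    matrix = pd.DataFrame(np.exp(log_vals), index=genes, columns=samples)
    truth = GroundTruth(
        kind="expression_matrix",
        params={"n_genes": len(genes), "n_samples": len(samples),
                "effect_size": effect_size, "noise_sd": noise_sd,
                "baseline_high_shift": baseline_high_shift,
                "t1_depression": t1_depression, "seed": seed},
        planted={"group1_genes": sorted(g1), "t1_samples": sorted(t1),
                 "baseline_high_genes": sorted(baseline_high_genes)},
    )
    return matrix, truth


def gen_paired_case_control_expression(
    genes: Sequence[str],
    n_pairs: int = 6,
    planted_de_genes: Sequence[str] = (),
    fold_change: float = 3.0,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[list[pd.Series], list[pd.Series], GroundTruth]:
    """Matched case/control expression pairs with planted fold changes.

    Per pair, the control profile is the shared baseline with log-normal
    noise; the case profile is the same except planted genes are multiplied
    (first half, up) or divided (second half, down) by ``fold_change``.
    """
    if fold_change <= 1:
        raise ValueError("gen_paired_case_control_expression: fold_change must exceed 1")
    genes = list(genes)
    planted = list(planted_de_genes)
    if not set(planted) <= set(genes):
        raise ValueError("gen_paired_case_control_expression: planted genes not in genes")
    up = set(planted[: (len(planted) + 1) // 2])
    down = set(planted) - up
    rng = np.random.default_rng(seed)
    log_base = rng.normal(1.5, 0.4, size=len(genes))
    cases, controls = [], []
    mult = np.ones(len(genes))
    for i, g in enumerate(genes):
        if g in up:
            mult[i] = fold_change
        elif g in down:
            mult[i] = 1.0 / fold_change
    for p in range(n_pairs):
        ctrl = np.exp(log_base + rng.normal(0, noise_sd, size=len(genes)))
        case = np.exp(log_base + rng.normal(0, noise_sd, size=len(genes))) * mult
        controls.append(pd.Series(ctrl, index=genes, name=f"control_{p}"))
        cases.append(pd.Series(case, index=genes, name=f"case_{p}"))
    truth = GroundTruth(
        kind="paired_case_control_expression",
        params={"n_genes": len(genes), "n_pairs": n_pairs,
                "fold_change": fold_change, "noise_sd": noise_sd, "seed": seed},
        planted={"up_genes": sorted(up), "down_genes": sorted(down)},
    )
    return cases, controls, truth


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

def gen_variant_table(
    genes: Sequence[str],
    variants_per_gene_mean: float = 2.0,
    reference_af_beta: tuple[float, float] = (0.2, 2.0),
    reference_af_bounds: tuple[float, float] = (0.001, 0.5),
    planted_genes: Sequence[str] = (),
    af_shift: float = 0.1,
    rare_rate: float = 0.12,
    rare_enriched_genes: Sequence[str] = (),
    rare_rate_enriched: float = 0.2,
    case_an: int = 1010,
    control_an: int = 982,
    ref_an: int = 5008,
    rare_true_af: float = 0.003,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Case/control variant table with planted frequency-shifted genes.

    Per gene the variant count is Poisson.  Each variant's underlying
    population frequency is drawn from a truncated Beta (a site-frequency-
    spectrum-like skew); with probability ``rare_rate`` (or
    ``rare_rate_enriched`` for genes in ``rare_enriched_genes``) the
    variant is absent from the reference panel (``ref_af`` missing) and
    its true frequency is ``rare_true_af``.  Case alt counts are Binomial
    at the underlying frequency, shifted by ``af_shift`` for planted
    genes; control counts are Binomial at the unshifted frequency.
    """
    if af_shift < 0 or not (0 <= rare_rate <= 1):
        raise ValueError("gen_variant_table: bad af_shift or rare_rate")
    if case_an <= 0 or control_an <= 0:
        raise ValueError("gen_variant_table: allele numbers must be positive")
    genes = list(genes)
    planted = set(planted_genes)
    if not planted <= set(genes):
        raise ValueError("gen_variant_table: planted genes not in genes")
    rare_enriched = set(rare_enriched_genes)
    rng = np.random.default_rng(seed)
    rows = []
    a, b = reference_af_beta
    lo, hi = reference_af_bounds
    vid = 0
    for g in genes:
        n_var = rng.poisson(variants_per_gene_mean)
        if g in planted:
            n_var = max(1, n_var)  # a shifted gene without variants is vacuous
        g_rare_rate = rare_rate_enriched if g in rare_enriched else rare_rate
        for k in range(n_var):
            # a planted shift is defined relative to the reference panel, so
            # a shifted gene always carries one panel-observed variant
            if g in planted and k == 0:
                is_rare = False
            else:
                is_rare = rng.random() < g_rare_rate
            if is_rare:
                f, ref_af = rare_true_af, np.nan
            else:
                f = float(np.clip(rng.beta(a, b), lo, hi))
                ref_af = f
            f_case = min(1.0, f + (af_shift if g in planted else 0.0))
            rows.append({
                "variant_id": f"v{vid:06d}",
                "gene": g,
                "consequence": "nonsynonymous" if rng.random() < 0.7 else "silent",
                "case_alt": int(rng.binomial(case_an, f_case)),
                "case_an": case_an,
                "control_alt": int(rng.binomial(control_an, f)),
                "control_an": control_an,
                "ref_af": ref_af,
                "ref_an": ref_an,
            })
            vid += 1
    df = pd.DataFrame(rows)
    truth = GroundTruth(
        kind="variant_table",
        params={"n_genes": len(genes),
                "variants_per_gene_mean": variants_per_gene_mean,
                "reference_af_beta": list(reference_af_beta),
                "reference_af_bounds": list(reference_af_bounds),
                "af_shift": af_shift, "rare_rate": rare_rate,
                "rare_rate_enriched": rare_rate_enriched,
                "case_an": case_an, "control_an": control_an,
                "ref_an": ref_an, "rare_true_af": rare_true_af, "seed": seed},
        planted={"shifted_genes": sorted(planted),
                 "rare_enriched_genes": sorted(rare_enriched)},
    )
    return df, truth


# ---------------------------------------------------------------------------
# Composite scene
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scene:
    """A composite synthetic study: network, annotation, expression,
    variants, and all planted truths."""

    graph: nx.Graph
    annotation: pd.DataFrame
    atlas: pd.DataFrame                 # module genes x brain sections
    cases: list[pd.Series]
    controls: list[pd.Series]
    variants: pd.DataFrame
    truths: dict[str, GroundTruth]

    @property
    def disease_genes(self) -> frozenset[str]:
        return frozenset(self.truths["annotation"].planted["disease_genes"])

    @property
    def module_genes(self) -> frozenset[str]:
        part = self.truths["network"].planted["partition"]
        target = self.truths["scene"].planted["disease_block"]
        return frozenset(g for g, b in part.items() if b == target)


def gen_scene(
    seed: int = 0,
    *,
    n_blocks: int = 8,
    block_size: int = 40,
    p_in: float = 0.3,
    p_out: float = 0.005,
    confound_factor: float = 2.0,
    disease_set_size: int = 60,
    disease_in_module_frac: float = 0.5,
    n_sections: int = 60,
    expression_effect: float = 2.5,
    expression_noise_sd: float = 0.5,
    af_shift: float = 0.1,
    n_burden_genes: int = 10,
    n_pairs: int = 6,
    de_fold_change: float = 3.0,
    degree_heterogeneity: float = 0.9,
) -> Scene:
    """One coherent synthetic study with a planted disease module.

    Block 0 of the planted-partition network is the disease module: a
    configurable fraction of the disease gene set is planted inside it (the
    enrichment signal); its genes split into a tissue-specific expression
    group (group 1, sampled preferentially from the module's high-coreness
    genes, mirroring the center-vs-group-1 bias the integration stage
    tests) and a ubiquitous group; its variants carry an elevated
    rare-variant rate; allele-frequency-shifted genes are sampled
    preferentially from the extreme coreness strata (the U-shape signal);
    and a subset of module genes is fold-changed in the matched
    case/control expression pairs.
    """
    ss = np.random.SeedSequence(seed)
    s_net, s_ann, s_expr, s_var, s_pair, s_pick = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(6)
    )
    graph, net_truth = gen_modular_network(
        n_blocks, block_size, p_in, p_out, s_net,
        degree_heterogeneity=degree_heterogeneity,
    )
    genes = sorted(graph.nodes())
    partition = net_truth.planted["partition"]
    module = sorted(g for g in genes if partition[g] == 0)

    rng = np.random.default_rng(s_pick)
    n_in = min(int(round(disease_set_size * disease_in_module_frac)), len(module))
    disease_in = list(rng.choice(module, size=n_in, replace=False))
    outside = [g for g in genes if partition[g] != 0]
    disease_out = list(rng.choice(outside, size=disease_set_size - n_in, replace=False))
    disease = sorted(disease_in + disease_out)

    # Annotation: covariates for every gene; the planted disease flag is the
    # curated-list analogue, with a CDS-length confound layered on by
    # reweighting which non-module genes join the list.
    ann, _ = gen_gene_annotation(
        genes, confound_factor=1.0, disease_set_size=1, seed=s_ann
    )
    ann = ann.drop(columns=["disease"])
    if confound_factor > 1:
        # impose the confound by inflating the CDS length of disease genes
        w = np.log2(confound_factor)
        ann.loc[ann["gene"].isin(disease), "cds_length"] = (
            ann.loc[ann["gene"].isin(disease), "cds_length"] * (1 + 0.25 * w)
        ).round().astype(int)
    ann["disease"] = ann["gene"].isin(disease)
    ann_truth = GroundTruth(
        kind="gene_annotation",
        params={"seed": s_ann, "confound_factor": confound_factor,
                "disease_set_size": disease_set_size},
        planted={"disease_genes": disease},
    )

    # Atlas-like expression over the module genes only (the analysis
    # dichotomizes the module, not the transcriptome).  Group 1 (tissue
    # specific) is sampled preferentially from high-coreness module genes.
    coreness = nx.core_number(graph)
    sections = [f"S{i:03d}" for i in range(n_sections)]
    t1 = sections[: int(round(n_sections * 0.6))]
    k_mod = np.array([coreness[g] for g in module], dtype=float)
    w_k = np.exp(1.0 * (k_mod - k_mod.mean()) / max(k_mod.std(), 1e-9))
    w_k /= w_k.sum()
    group1 = sorted(rng.choice(module, size=len(module) // 2, replace=False, p=w_k))
    group2 = [g for g in module if g not in set(group1)]
    atlas, atlas_truth = gen_expression_matrix(
        module, sections, group1, t1,
        effect_size=expression_effect, noise_sd=expression_noise_sd,
        baseline_high_genes=group2, baseline_high_shift=1.5, seed=s_expr,
    )

    # Frequency-shifted genes favor the extreme coreness strata (U-shape):
    # weight the lowest and highest of the quantile strata the integration
    # stage will form, inversely to their size so both extremes are hit.
    from .variants import quantile_coreness_bins

    k_bins = quantile_coreness_bins(k_mod.astype(int), n_bins=5)
    (lo0, hi0), (lon, hin) = k_bins[0], k_bins[-1]
    in_bot = (k_mod >= lo0) & (k_mod <= hi0)
    in_top = (k_mod >= lon) & (k_mod <= hin)
    # per-gene weights: extreme-stratum genes 4x as likely as middle genes
    w_u = np.where(in_bot | in_top, 4.0, 1.0)
    w_u /= w_u.sum()
    burden = sorted(rng.choice(module, size=min(n_burden_genes, len(module)),
                               replace=False, p=w_u))
    variants, var_truth = gen_variant_table(
        genes, planted_genes=burden, af_shift=af_shift,
        rare_enriched_genes=module, seed=s_var,
    )

    de_planted = sorted(rng.choice(module, size=max(4, len(module) // 4), replace=False))
    cases, controls, pair_truth = gen_paired_case_control_expression(
        genes, n_pairs=n_pairs, planted_de_genes=de_planted,
        fold_change=de_fold_change, seed=s_pair,
    )

    scene_truth = GroundTruth(
        kind="scene",
        params={"seed": seed, "n_blocks": n_blocks, "block_size": block_size,
                "p_in": p_in, "p_out": p_out,
                "disease_in_module_frac": disease_in_module_frac},
        planted={"disease_block": 0, "module_genes": module,
                 "burden_genes": burden, "de_genes": de_planted},
    )
    truths = {
        "network": net_truth, "annotation": ann_truth, "atlas": atlas_truth,
        "variants": var_truth, "pairs": pair_truth, "scene": scene_truth,
    }
    return Scene(graph=graph, annotation=ann, atlas=atlas, cases=cases,
                 controls=controls, variants=variants, truths=truths)
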