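"""Variant-table statistics: rare-variant fractions, matched permutation
burden, per-variant case-vs-reference tests, reciprocal-regression outliers,
allele-frequency-difference ranking, and coreness-stratified integration.

A variant table is a pandas DataFrame with one row per variant:

    variant_id, gene, consequence {nonsynonymous, silent, other},
    case_alt, case_an, [control_alt, control_an], [ref_af, ref_an], ...

``ref_af`` missing (NaN) means the variant is absent from the reference
panel; such variants are *rare* by definition here and are routed to the
rare-fraction statistics rather than the frequency-comparison tests.
Extra columns (conservation scores, predicted deleteriousness) are carried
through untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import GeneSet, MatchedBackground, bh_adjust, fisher_2x2, hypergeom_upper_tail
from .enrichment import EnrichmentResult

logger = logging.getLogger("modcore")

__all__ = [
    "RareFraction",
    "GeneBurdenResult",
    "OutlierRegressionResult",
    "BurdenByCoreness",
    "DEFAULT_CORENESS_BINS",
    "quantile_coreness_bins",
    "read_variant_table",
    "write_variant_table",
    "read_variants_vcf",
    "rare_fraction",
    "rare_enrichment_permutation",
    "af_case_vs_reference",
    "reciprocal_regression_outliers",
    "af_difference_rank_curve",
    "coreness_burden_profile",
    "core_group_bias",
    "coreness_expression_correlation",
]

REQUIRED_COLUMNS = ("variant_id", "gene", "consequence", "case_alt", "case_an")

#: Coreness strata: periphery {1}, {2}, intermediate {3..5}, {6..9}, center {>=10}.
DEFAULT_CORENESS_BINS: tuple[tuple[int, float], ...] = (
    (1, 1), (2, 2), (3, 5), (6, 9), (10, float("inf")),
)


def quantile_coreness_bins(
    k_values: Iterable[int], n_bins: int = 5
) -> tuple[tuple[int, float], ...]:
    """Derive coreness strata from the observed K distribution.

    Integer bin edges at the K quantiles, collapsed when ties make a
    stratum empty; the last stratum is open-ended.  Useful when a module's
    coreness range is narrower than the interactome-scale defaults."""
    ks = np.asarray(sorted(k_values))
    if ks.size == 0:
        raise ValueError("quantile_coreness_bins: no coreness values")
    edges = np.unique(
        np.round(np.quantile(ks, np.linspace(0, 1, n_bins + 1)[:-1])).astype(int)
    )
    bins = []
    for i, lo in enumerate(edges):
        hi = edges[i + 1] - 1 if i + 1 < len(edges) else float("inf")
        bins.append((int(lo), hi))
    return tuple(bins)


class RareFraction(NamedTuple):
    n_rare: int
    n_total: int
    fraction: float


@dataclass(frozen=True)
class GeneBurdenResult:
    gene: str
    significant_variants: tuple[str, ...]
    min_fdr: float
    n_variants: int


@dataclass(frozen=True)
class OutlierRegressionResult:
    """Reciprocal OLS of case on control allele frequencies and back.

    ``table`` has one row per variant with residuals from both directions
    and per-direction flags; ``outliers`` is the union of the two
    directions' upper-tail exceedances.
    """

    table: pd.DataFrame
    t_params_case_on_control: tuple[float, float, float]  # (df, loc, scale)
    t_params_control_on_case: tuple[float, float, float]
    outliers: tuple[str, ...]        # variant ids
    implicated_genes: tuple[str, ...]


@dataclass(frozen=True)
class BurdenByCoreness:
    """Mutated-gene fraction per coreness stratum plus the U-shape test.

    The curve statistic S = (f_top + f_bottom) - 2 * f_middle contrasts the
    mutated fractions of the extreme strata against the pooled middle
    strata; its null distribution comes from resampling the mutated set
    uniformly from the module.
    """

    bins: tuple[tuple[int, float], ...]
    table: pd.DataFrame   # bin_lo, bin_hi, n_genes, n_mutated, fraction, p_enrich, p_deplete
    s_observed: float
    s_null: tuple[float, ...]
    p_curve: float


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_variant_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: variant table lacks columns {missing}")
    _validate_variants(df)
    return df


def write_variant_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _validate_variants(df: pd.DataFrame) -> None:
    if ((df["case_alt"] < 0) | (df["case_alt"] > df["case_an"])).any():
        raise ValueError("variant table: need 0 <= case_alt <= case_an")
    if "ref_af" in df.columns:
        bad = df["ref_af"].dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise ValueError("variant table: ref_af must lie in [0, 1]")


def read_variants_vcf(path: str | Path, *, ref_an: int = 5008) -> pd.DataFrame:
    """Ingest a (plain-text) VCF into the variant-table schema.

    INFO keys used: ``GENE``, ``CSQ_CLASS`` (nonsynonymous/silent/other),
    ``AC``/``AN`` for case counts, ``CONTROL_AC``/``CONTROL_AN`` and
    ``REF_AF`` when present.  Coordinates are 1-based as in VCF.
    """
    from cyvcf2 import VCF

    rows = []
    for rec in VCF(str(path)):
        info = dict(rec.INFO)
        rows.append({
            "variant_id": rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}>{rec.ALT[0]}",
            "gene": info.get("GENE", ""),
            "consequence": info.get("CSQ_CLASS", "other"),
            "case_alt": int(info.get("AC", 0)),
            "case_an": int(info.get("AN", 0)),
            "control_alt": info.get("CONTROL_AC", np.nan),
            "control_an": info.get("CONTROL_AN", np.nan),
            "ref_af": float(info["REF_AF"]) if "REF_AF" in info else np.nan,
            "ref_an": int(info.get("REF_AN", ref_an)),
        })
    if not rows:
        raise ValueError(f"{path}: VCF holds no records")
    df = pd.DataFrame(rows)
    _validate_variants(df)
    return df


# ---------------------------------------------------------------------------
# Rare-variant statistics
# ---------------------------------------------------------------------------

def _class_mask(df: pd.DataFrame, class_filter: str | None) -> pd.Series:
    if class_filter is None:
        return pd.Series(True, index=df.index)
    return df["consequence"] == class_filter


def rare_fraction(
    variants: pd.DataFrame,
    class_filter: str | None = "nonsynonymous",
) -> RareFraction:
    """Fraction of variants absent from the reference panel (ref_af missing)."""
    sub = variants[_class_mask(variants, class_filter)]
    if sub.empty:
        raise ValueError(f"rare_fraction: no variants of class {class_filter!r}")
    if "ref_af" in sub.columns:
        n_rare = int(sub["ref_af"].isna().sum())
    else:
        n_rare = len(sub)
    n_total = len(sub)
    return RareFraction(n_rare, n_total, n_rare / n_total)


def rare_enrichment_permutation(
    module: GeneSet,
    variants: pd.DataFrame,
    pool: MatchedBackground,
    n_perm: int = 10_000,
    seed: int = 0,
    class_filter: str | None = "nonsynonymous",
) -> tuple[float, float, float]:
    """Is the rare-variant fraction in a module's genes higher than in
    covariate-matched random gene sets of the same size?

    Returns (observed fraction, expected fraction under the null, empirical
    p).  Permutations whose sampled genes carry no variants contribute a
    fraction of 0 (logged).
    """
    sub = variants[_class_mask(variants, class_filter)]
    obs_sub = sub[sub["gene"].isin(module.genes)]
    if obs_sub.empty:
        raise ValueError("rare_enrichment_permutation: no variants on module genes")
    observed = float(obs_sub["ref_af"].isna().mean())
    rng = np.random.default_rng(seed)
    pool_arr = np.asarray(pool.genes)
    k = len(module.genes)
    if len(pool_arr) < k:
        raise ValueError("rare_enrichment_permutation: pool smaller than module")
    by_gene_rare = sub.groupby("gene")["ref_af"].agg(lambda s: (int(s.isna().sum()), len(s)))
    rare_of = {g: t[0] for g, t in by_gene_rare.items()}
    tot_of = {g: t[1] for g, t in by_gene_rare.items()}
    fractions = np.empty(n_perm)
    n_empty = 0
    for i in range(n_perm):
        draw = pool_arr[rng.choice(len(pool_arr), size=k, replace=False)]
        r = sum(rare_of.get(g, 0) for g in draw)
        t = sum(tot_of.get(g, 0) for g in draw)
        if t == 0:
            n_empty += 1
            fractions[i] = 0.0
        else:
            fractions[i] = r / t
    if n_empty:
        logger.warning(
            "rare_enrichment_permutation: %d/%d permutations had no variants "
            "(fraction taken as 0)", n_empty, n_perm,
        )
    p = (1 + int((fractions >= observed).sum())) / (1 + n_perm)
    return observed, float(fractions.mean()), p


# ---------------------------------------------------------------------------
# Case-vs-reference frequency tests
# ---------------------------------------------------------------------------

def af_case_vs_reference(
    variants: pd.DataFrame,
    fdr_target: float = 0.1,
    *,
    ref_an_default: int = 5008,
) -> tuple[list[GeneBurdenResult], pd.DataFrame]:
    """Per-variant Fisher test of case allele counts against reference-panel
    frequencies, BH-corrected within the variant family.

    Reference allele counts are reconstructed as round(ref_af * ref_an).
    Variants with missing ref_af are excluded (they are "rare" and handled
    by :func:`rare_fraction`).  Returns the genes with >= 1 variant below
    ``fdr_target`` and the per-variant test table.
    """
    if "ref_af" not in variants.columns:
        raise ValueError("af_case_vs_reference: variant table lacks ref_af")
    sub = variants[variants["ref_af"].notna()].copy()
    if sub.empty:
        raise ValueError("af_case_vs_reference: no variants with reference frequencies")
    ref_an = sub["ref_an"] if "ref_an" in sub.columns else pd.Series(
        ref_an_default, index=sub.index
    )
    ref_an = ref_an.fillna(ref_an_default).astype(int)
    if (ref_an <= 0).any():
        raise ValueError("af_case_vs_reference: non-positive reference allele number")
    pvals = []
    for (_, row), an in zip(sub.iterrows(), ref_an):
        ref_alt = int(round(row["ref_af"] * an))
        table = [
            [int(row["case_alt"]), int(row["case_an"] - row["case_alt"])],
            [ref_alt, an - ref_alt],
        ]
        pvals.append(fisher_2x2(table, alternative="two-sided"))
    sub["p"] = pvals
    sub["fdr"] = bh_adjust(pvals)
    hits = sub[sub["fdr"] < fdr_target]
    results = []
    for gene, grp in sub.groupby("gene"):
        sig = grp[grp["fdr"] < fdr_target]
        if sig.empty:
            continue
        results.append(GeneBurdenResult(
            gene=str(gene),
            significant_variants=tuple(sig["variant_id"].astype(str)),
            min_fdr=float(grp["fdr"].min()),
            n_variants=int(len(grp)),
        ))
    results.sort(key=lambda r: (r.min_fdr, r.gene))
    logger.info(
        "af_case_vs_reference: %d/%d variants significant at FDR < %g (%d genes)",
        len(hits), len(sub), fdr_target, len(results),
    )
    return results, sub


def _case_control_af(variants: pd.DataFrame) -> pd.DataFrame:
    for col in ("control_alt", "control_an"):
        if col not in variants.columns:
            raise ValueError("need control_alt/control_an columns")
    sub = variants.dropna(subset=["control_alt", "control_an"]).copy()
    sub["case_af"] = sub["case_alt"] / sub["case_an"]
    sub["control_af"] = sub["control_alt"] / sub["control_an"]
    return sub


def reciprocal_regression_outliers(
    variants: pd.DataFrame,
    tail: float = 0.05,
) -> OutlierRegressionResult:
    """Variants with extreme case-control allele-frequency imbalance.

    Case AF is regressed on control AF by OLS and vice versa; per direction
    a location-scale t-distribution is fit to the residuals by maximum
    likelihood, and the ``tail`` fraction of residuals indicating *case
    excess* is flagged: the upper tail when case AF is the response, the
    lower tail when it is the predictor.  The reported outlier set is the
    union of the two directions (the per-direction flags allow recovering
    the intersection).
    """
    sub = _case_control_af(variants)
    if len(sub) < 20:
        raise ValueError("reciprocal_regression_outliers: need >= 20 variants")
    x = sub["control_af"].to_numpy()
    y = sub["case_af"].to_numpy()

    def direction(pred: np.ndarray, resp: np.ndarray, upper: bool):
        if np.ptp(pred) == 0:
            resid = resp - resp.mean()
        else:
            slope, intercept = np.polyfit(pred, resp, 1)
            resid = resp - (slope * pred + intercept)
        if np.allclose(resid, 0):
            logger.warning("reciprocal_regression_outliers: zero residual variance")
            return resid, (np.inf, 0.0, 0.0), np.zeros(len(resid), dtype=bool)
        df_, loc, scale = stats.t.fit(resid)
        params = (float(df_), float(loc), float(scale))
        if upper:
            return resid, params, resid > stats.t.ppf(1 - tail, df_, loc=loc, scale=scale)
        return resid, params, resid < stats.t.ppf(tail, df_, loc=loc, scale=scale)

    r1, t1, f1 = direction(x, y, upper=True)    # case on control: case excess high
    r2, t2, f2 = direction(y, x, upper=False)   # control on case: case excess low
    table = pd.DataFrame({
        "variant_id": sub["variant_id"].astype(str).to_numpy(),
        "gene": sub["gene"].astype(str).to_numpy(),
        "case_af": y,
        "control_af": x,
        "resid_case_on_control": r1,
        "resid_control_on_case": r2,
        "outlier_case_on_control": f1,
        "outlier_control_on_case": f2,
    })
    table["outlier"] = table["outlier_case_on_control"] | table["outlier_control_on_case"]
    out = table[table["outlier"]]
    return OutlierRegressionResult(
        table=table,
        t_params_case_on_control=t1,
        t_params_control_on_case=t2,
        outliers=tuple(out["variant_id"]),
        implicated_genes=tuple(sorted(set(out["gene"]))),
    )


def af_difference_rank_curve(
    variants: pd.DataFrame,
    candidate_genes: Iterable[str],
    module: Iterable[str],
    n_perm: int = 10_000,
    seed: int = 0,
    k_grid: Sequence[int] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Do the variants with the largest case-control frequency differences
    fall on the candidate genes?

    Variants (restricted to module genes with both cohort AFs) are sorted
    by decreasing |case_af - control_af|; curve(k) is the fraction of the
    top-k variants on candidate genes.  The statistic is the mean of the
    curve over the k grid (default: 5%..50% of the variants); the null
    redraws |candidates| genes uniformly from the module.
    """
    module = set(module)
    candidates = set(candidate_genes)
    if not candidates <= module:
        raise ValueError("af_difference_rank_curve: candidates must lie in the module")
    sub = _case_control_af(variants)
    sub = sub[sub["gene"].isin(module)]
    n = len(sub)
    if k_grid is None:
        k_grid = sorted({max(1, int(round(n * f))) for f in (0.05, 0.1, 0.2, 0.3, 0.4, 0.5)})
    if n < min(k_grid):
        raise ValueError("af_difference_rank_curve: fewer variants than the smallest k")
    order = np.argsort(-np.abs(sub["case_af"] - sub["control_af"]).to_numpy(), kind="stable")
    genes_sorted = sub["gene"].to_numpy()[order]

    def curve_stat(cand: set[str]) -> np.ndarray:
        hits = np.isin(genes_sorted, sorted(cand)).cumsum()
        return np.array([hits[k - 1] / k for k in k_grid])

    obs_curve = curve_stat(candidates)
    s_obs = float(obs_curve.mean())
    rng = np.random.default_rng(seed)
    module_arr = np.asarray(sorted(module))
    exceed = 0
    for _ in range(n_perm):
        draw = set(module_arr[rng.choice(len(module_arr), size=len(candidates), replace=False)])
        if float(curve_stat(draw).mean()) >= s_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    curve = pd.DataFrame({"k": list(k_grid), "fraction_candidate": obs_curve})
    curve.attrs["statistic"] = s_obs
    return curve, p


# ---------------------------------------------------------------------------
# Coreness-stratified integration
# ---------------------------------------------------------------------------

def coreness_burden_profile(
    mutated_genes: Iterable[str],
    module: Iterable[str],
    coreness: Mapping[str, int],
    bins: Sequence[tuple[int, float]] = DEFAULT_CORENESS_BINS,
    n_perm: int = 10_000,
    seed: int = 0,
) -> BurdenByCoreness:
    """Mutated-gene fraction per coreness stratum and the U-shape curve test.

    Per stratum, enrichment and depletion p-values come from the
    hypergeometric tails (universe = module, marked = mutated genes,
    draws = stratum size).  The curve statistic S contrasts the extreme
    strata against the pooled middle ones; empty strata are reported with a
    missing fraction and excluded from S.
    """
    module = sorted(set(module))
    mutated = set(mutated_genes)
    if not mutated <= set(module):
        raise ValueError("coreness_burden_profile: mutated genes must lie in the module")
    missing = [g for g in module if g not in coreness]
    if missing:
        raise ValueError(f"coreness_burden_profile: no coreness for {missing[:3]}")
    K = np.array([coreness[g] for g in module])
    is_mut = np.array([g in mutated for g in module])
    N, M = len(module), len(mutated)
    rows = []
    bin_masks = []
    for lo, hi in bins:
        mask = (K >= lo) & (K <= hi)
        bin_masks.append(mask)
        n_bin = int(mask.sum())
        k_bin = int(is_mut[mask].sum())
        if n_bin == 0:
            rows.append({"bin_lo": lo, "bin_hi": hi, "n_genes": 0, "n_mutated": 0,
                         "fraction": np.nan, "p_enrich": np.nan, "p_deplete": np.nan})
            continue
        p_enrich = hypergeom_upper_tail(k_bin, n_bin, M, N)
        p_deplete = float(stats.hypergeom.cdf(k_bin, N, M, n_bin))
        rows.append({"bin_lo": lo, "bin_hi": hi, "n_genes": n_bin, "n_mutated": k_bin,
                     "fraction": k_bin / n_bin, "p_enrich": p_enrich,
                     "p_deplete": p_deplete})
    table = pd.DataFrame(rows)

    nonempty = [i for i, m in enumerate(bin_masks) if m.sum() > 0]
    if len(nonempty) < 2:
        raise ValueError("coreness_burden_profile: fewer than two non-empty strata")
    i_bot, i_top = nonempty[0], nonempty[-1]
    middle = nonempty[1:-1]

    def s_stat(flags: np.ndarray) -> float:
        f_bot = flags[bin_masks[i_bot]].mean()
        f_top = flags[bin_masks[i_top]].mean()
        if middle:
            mid_mask = np.logical_or.reduce([bin_masks[i] for i in middle])
            f_mid = flags[mid_mask].mean()
        else:
            f_mid = 0.0
        return float(f_top + f_bot - 2.0 * f_mid)

    s_obs = s_stat(is_mut)
    rng = np.random.default_rng(seed)
    s_null = []
    for _ in range(n_perm):
        flags = np.zeros(N, dtype=bool)
        flags[rng.choice(N, size=M, replace=False)] = True
        s_null.append(s_stat(flags))
    exceed = sum(1 for s in s_null if s >= s_obs)
    p_curve = (1 + exceed) / (1 + n_perm)
    return BurdenByCoreness(
        bins=tuple(bins), table=table, s_observed=s_obs,
        s_null=tuple(s_null), p_curve=p_curve,
    )


def core_group_bias(
    core_genes: Iterable[str],
    group1: Iterable[str],
    module: Iterable[str],
) -> EnrichmentResult:
    """Is the module's network center biased toward one expression group?

    Hypergeometric upper tail on |core ∩ group1| with the module as the
    universe, group1 as the marked genes and the core as the draws.
    """
    module = set(module)
    core = set(core_genes) & module
    g1 = set(group1) & module
    if not (set(core_genes) <= module and set(group1) <= module):
        raise ValueError("core_group_bias: core_genes and group1 must lie in the module")
    k = len(core & g1)
    p = hypergeom_upper_tail(k, len(core), len(g1), len(module))
    return EnrichmentResult(
        module_id="core", set_name="group1", k=k, n=len(core),
        K_set=len(g1), N_u=len(module), p_value=p, fdr=p,
    )


def coreness_expression_correlation(
    coreness: Mapping[str, int],
    expression: Mapping[str, float] | pd.Series,
) -> tuple[float, float]:
    """Spearman correlation (average-rank ties, two-sided p) between
    coreness K and per-gene expression in one tissue."""
    expr = pd.Series(expression).dropna()
    genes = sorted(set(expr.index) & set(coreness))
    if len(genes) < 10:
        raise ValueError("coreness_expression_correlation: need >= 10 shared genes")
    k = np.array([coreness[g] for g in genes], dtype=float)
    e = expr.loc[genes].to_numpy(dtype=float)
    if np.ptp(k) == 0 or np.ptp(e) == 0:
        raise ValueError("coreness_expression_correlation: constant vector")
    r, p = stats.spearmanr(k, e)
    return float(r), float(p)
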