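"""Gene-set enrichment statistics with covariate-matched backgrounds.

Module-vs-set enrichment uses the one-sided (upper-tail) hypergeometric
test with the network's node set as the default universe; 2x2 ratio
comparisons use Fisher's exact test (two-sided by default); families of
p-values are corrected with Benjamini-Hochberg.

Because disease gene lists are confounded by gene-level covariates (longer
coding sequences accumulate more curated evidence and more variants), the
permutation machinery here samples from a *matched background*: a pool of
non-target genes whose CDS-length and GC-content distributions are
statistically indistinguishable (Wilcoxon rank-sum) from the target set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .interactome import ModulePartition

logger = logging.getLogger("modcore")

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "MatchedBackground",
    "read_gmt",
    "read_gene_list",
    "read_annotation",
    "write_annotation",
    "hypergeom_upper_tail",
    "fisher_2x2",
    "bh_adjust",
    "build_matched_background",
    "matched_permutation_test",
    "module_set_scan",
    "size_threshold_scan",
    "write_enrichment_results",
]

ANNOTATION_COLUMNS = ("gene", "cds_length", "gc_content")


@dataclass(frozen=True)
class GeneSet:
    """A named flat collection of gene symbols."""

    name: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"GeneSet {self.name!r}: empty gene set")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class EnrichmentResult:
    """One module-times-set overlap test."""

    module_id: int | str
    set_name: str
    k: int            # overlap
    n: int            # module size (draws)
    K_set: int        # marked genes in the universe
    N_u: int          # universe size
    p_value: float
    fdr: float = float("nan")


@dataclass(frozen=True)
class MatchedBackground:
    """Covariate-balanced control pool, disjoint from its target set.

    ``balance`` maps covariate name to the final two-sample rank-test
    p-value of pool vs target (all above the construction threshold).
    """

    genes: tuple[str, ...]
    balance: Mapping[str, float]
    target_name: str = ""


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read GMT (name, description, genes...) into gene sets."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT needs >=3 columns")
            sets.append(GeneSet(name=parts[0], genes=frozenset(g for g in parts[2:] if g)))
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return sets


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene list."""
    path = Path(path)
    genes = frozenset(
        line.strip() for line in path.read_text().splitlines() if line.strip()
    )
    return GeneSet(name=name or path.stem, genes=genes)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the gene annotation TSV (gene, cds_length, gc_content, flags...)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: annotation lacks columns {missing}")
    _validate_annotation(df)
    return df


def write_annotation(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _validate_annotation(df: pd.DataFrame) -> None:
    if df["gene"].duplicated().any():
        raise ValueError("annotation: duplicated gene symbols")
    if (df["cds_length"] <= 0).any():
        raise ValueError("annotation: cds_length must be positive")
    if ((df["gc_content"] < 0) | (df["gc_content"] > 1)).any():
        raise ValueError("annotation: gc_content must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def hypergeom_upper_tail(k: int, n_draws: int, K_marked: int, N_universe: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N_universe, K_marked, n_draws)."""
    if not (0 <= k <= n_draws <= N_universe):
        raise ValueError(f"impossible counts: k={k}, n={n_draws}, N={N_universe}")
    if not (0 <= K_marked <= N_universe):
        raise ValueError(f"impossible counts: K={K_marked}, N={N_universe}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N_universe, K_marked, n_draws))


def fisher_2x2(table: Sequence[Sequence[int]], alternative: str = "two-sided") -> float:
    """Exact conditional p-value for a 2x2 contingency table."""
    tab = np.asarray(table)
    if tab.shape != (2, 2):
        raise ValueError("fisher_2x2: table must be 2x2")
    if (tab < 0).any():
        raise ValueError("fisher_2x2: negative cell count")
    if tab.sum() == 0:
        raise ValueError("fisher_2x2: all-zero table")
    return float(stats.fisher_exact(tab, alternative=alternative)[1])


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("bh_adjust: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Matched backgrounds and permutation tests
# ---------------------------------------------------------------------------

def build_matched_background(
    target: GeneSet,
    annotation: pd.DataFrame,
    covariates: Sequence[str] = ("cds_length", "gc_content"),
    balance_threshold: float = 0.05,
    seed: int = 0,
) -> MatchedBackground:
    """Construct a control pool covariate-matched to the target set.

    Per covariate: start from all annotated non-target genes inside the
    target's [2.5, 97.5] percentile range, then iteratively trim 5% off the
    distribution tail that lies away from the target's median until a
    Wilcoxon rank-sum test against the target exceeds
    ``balance_threshold``.  The final pool is the intersection of the
    per-covariate pools (trimming resumes on the intersection for any
    covariate still unbalanced).  Deterministic; ``seed`` is accepted for
    interface uniformity with the samplers that consume the pool.
    """
    ann = annotation.set_index("gene")
    missing = target.genes - set(ann.index)
    if missing:
        raise ValueError(
            f"build_matched_background: target genes missing from annotation: "
            f"{sorted(missing)[:5]}"
        )
    for cov in covariates:
        if cov not in ann.columns:
            raise ValueError(f"build_matched_background: unknown covariate {cov!r}")

    target_vals = {cov: ann.loc[sorted(target.genes), cov].to_numpy() for cov in covariates}
    nontarget = ann.drop(index=list(target.genes))

    def trim_until_balanced(pool: pd.Index, cov: str) -> pd.Index:
        vals = nontarget.loc[pool, cov]
        lo, hi = np.percentile(target_vals[cov], [2.5, 97.5])
        vals = vals[(vals >= lo) & (vals <= hi)]
        while True:
            if len(vals) < len(target.genes):
                raise ValueError(
                    f"build_matched_background: matched pool for {cov!r} smaller "
                    f"than the target set; relax balance_threshold"
                )
            p = stats.ranksums(vals.to_numpy(), target_vals[cov]).pvalue
            if p > balance_threshold:
                return vals.index
            # trim the tail on the side away from the target's median
            if vals.median() < np.median(target_vals[cov]):
                trimmed = vals[vals > vals.quantile(0.05)]
            else:
                trimmed = vals[vals < vals.quantile(0.95)]
            if len(trimmed) == len(vals):  # no progress possible
                raise ValueError(
                    f"build_matched_background: cannot balance covariate {cov!r}; "
                    f"relax balance_threshold"
                )
            vals = trimmed

    pool = nontarget.index
    for cov in covariates:
        pool = pool.intersection(trim_until_balanced(nontarget.index, cov))
    # Re-check on the intersection; resume trimming where needed.
    for _ in range(50):
        balance = {
            cov: float(stats.ranksums(nontarget.loc[pool, cov].to_numpy(),
                                      target_vals[cov]).pvalue)
            for cov in covariates
        }
        bad = [cov for cov, p in balance.items() if p <= balance_threshold]
        if not bad:
            break
        pool = pool.intersection(trim_until_balanced(pool, bad[0]))
    else:
        raise ValueError("build_matched_background: balance not reached; relax threshold")
    if len(pool) < len(target.genes):
        raise ValueError(
            "build_matched_background: final pool smaller than the target set; "
            "relax balance_threshold"
        )
    logger.info(
        "matched background for %s: %d genes, balance %s",
        target.name, len(pool),
        {c: round(p, 3) for c, p in balance.items()},
    )
    return MatchedBackground(
        genes=tuple(sorted(pool)), balance=balance, target_name=target.name
    )


def matched_permutation_test(
    module: GeneSet,
    target: GeneSet,
    pool: MatchedBackground,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Empirical enrichment p-value by matched resampling.

    Draws ``|target|`` genes from the matched pool ``n_perm`` times; the
    statistic is the overlap with the module; the p-value uses the add-one
    convention (never zero).
    """
    if n_perm < 1:
        raise ValueError("matched_permutation_test: n_perm must be >= 1")
    if len(pool.genes) < len(target.genes):
        raise ValueError("matched_permutation_test: pool smaller than target")
    observed = len(target.genes & module.genes)
    rng = np.random.default_rng(seed)
    pool_arr = np.asarray(pool.genes)
    in_module = np.isin(pool_arr, sorted(module.genes))
    k = len(target.genes)
    exceed = 0
    for _ in range(n_perm):
        draw = rng.choice(len(pool_arr), size=k, replace=False)
        if int(in_module[draw].sum()) >= observed:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


# ---------------------------------------------------------------------------
# Scans over a partition
# ---------------------------------------------------------------------------

def module_set_scan(
    partition: ModulePartition,
    sets: Sequence[GeneSet],
    universe: Iterable[str],
    min_module_size: int = 6,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of every qualifying module against every
    gene set, BH-corrected across the whole scan (one family)."""
    if not sets:
        raise ValueError("module_set_scan: empty list of gene sets")
    if min_module_size < 1:
        raise ValueError("module_set_scan: min_module_size must be >= 1")
    uni = set(universe)
    N = len(uni)
    results: list[EnrichmentResult] = []
    modules = {
        mid: genes & uni
        for mid, genes in partition.modules().items()
        if len(genes & uni) >= min_module_size
    }
    for mid in sorted(modules):
        mod_genes = modules[mid]
        for gs in sets:
            marked = gs.genes & uni
            k = len(mod_genes & marked)
            p = hypergeom_upper_tail(k, len(mod_genes), len(marked), N)
            results.append(EnrichmentResult(
                module_id=mid, set_name=gs.name, k=k, n=len(mod_genes),
                K_set=len(marked), N_u=N, p_value=p,
            ))
    if results:
        fdrs = bh_adjust([r.p_value for r in results])
        results = [
            EnrichmentResult(**{**r.__dict__, "fdr": float(f)})
            for r, f in zip(results, fdrs)
        ]
    return results


def size_threshold_scan(
    partition: ModulePartition,
    sets: Sequence[GeneSet],
    universe: Iterable[str],
    thresholds: Sequence[int],
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Sensitivity of the enrichment scan to the module-size threshold.

    One scan (and one BH family) is computed at the smallest threshold;
    each larger threshold then counts the enriched modules that remain
    after filtering by module size, so counts are non-increasing.  The
    gradient column is the first difference between consecutive thresholds.
    """
    thresholds = list(thresholds)
    if not thresholds or any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("size_threshold_scan: thresholds must be non-empty, increasing")
    base = module_set_scan(partition, sets, universe, min_module_size=thresholds[0])
    enriched_sizes = sorted(
        {r.module_id for r in base if r.fdr < fdr_cut and not np.isnan(r.fdr)}
    )
    size_of = {r.module_id: r.n for r in base}
    counts = [
        sum(1 for mid in enriched_sizes if size_of[mid] >= t) for t in thresholds
    ]
    gradient = [np.nan] + [counts[i] - counts[i - 1] for i in range(1, len(counts))]
    return pd.DataFrame({
        "threshold": thresholds,
        "n_enriched_modules": counts,
        "gradient": gradient,
    })


def write_enrichment_results(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    df = pd.DataFrame([r.__dict__ for r in results])
    df = df.rename(columns={"p_value": "p"})
    df.to_csv(path, sep="\t", index=False,
              columns=["module_id", "set_name", "k", "n", "K_set", "N_u", "p", "fdr"])
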