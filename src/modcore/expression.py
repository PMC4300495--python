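"""Expression-matrix analyses: normalization, two-way dichotomization,
tissue specificity, breadth, background comparisons, co-expression QC and
extreme differential-expression calling.

Matrices are pandas DataFrames with genes as rows and samples (tissue
sections) as columns, holding non-negative array intensities or FPKM.
Values mapped to the same gene symbol (multiple probes) are averaged at
read time.

The tissue-specificity index of a gene with expression x_1..x_N is

    tau = sum_i (1 - x_i / max_j x_j) / (N - 1)

which is 0 for perfectly uniform expression and 1 when expression is
confined to a single sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .enrichment import EnrichmentResult, hypergeom_upper_tail

logger = logging.getLogger("modcore")

__all__ = [
    "DichotomyResult",
    "SpecificityProfile",
    "DEResult",
    "CoexpressionSummary",
    "read_expression_tsv",
    "write_expression_tsv",
    "normalize_per_gene",
    "denormalize",
    "dichotomize",
    "tau_index",
    "expression_breadth",
    "specificity_profile",
    "group_vs_background",
    "coexpression_qc",
    "extreme_de_call",
    "de_module_enrichment",
]


@dataclass(frozen=True)
class DichotomyResult:
    """Two-way split of genes and samples from hierarchical clustering.

    Gene group 1 is, by convention, the group with the higher mean
    (normalized) expression in sample cluster T1; T1/group-1 labels are
    chosen jointly as the (group, cluster) cell with the largest mean.
    """

    gene_group: Mapping[str, int]        # gene -> 1 | 2
    sample_cluster: Mapping[str, str]    # sample -> "T1" | "T2"
    linkage_method: str = "average"
    distance_metric: str = "correlation/euclidean"


@dataclass(frozen=True)
class SpecificityProfile:
    """Per-gene tissue-specificity index and expression breadth."""

    tau: pd.Series                        # gene -> tau in [0, 1] (NaN when undefined)
    breadth: pd.DataFrame                 # genes x thresholds, active-sample counts
    thresholds: tuple[float, ...]
    cutoffs: tuple[float, ...]            # pooled-quantile cutoff per threshold


@dataclass(frozen=True)
class CoexpressionSummary:
    """Interacting-pair vs random-pair co-expression comparison."""

    median_r_interacting: float
    median_r_random: float
    p_value: float
    n_interacting: int
    n_random: int


@dataclass(frozen=True)
class DEResult:
    """Extreme fold-change calls across matched case-control pairs."""

    per_pair: pd.DataFrame   # columns: gene, pair_id, fold_change, up_extreme, down_extreme
    any_extreme: pd.Series   # gene -> bool, OR over pairs

    @property
    def extreme_genes(self) -> frozenset[str]:
        return frozenset(self.any_extreme.index[self.any_extreme])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes-x-samples TSV (first column gene symbols).

    Rows sharing a gene symbol (multiple probes per gene) are averaged.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty expression matrix")
    if (df < 0).any().any():
        raise ValueError(f"{path}: negative expression values")
    if df.index.duplicated().any():
        n = int(df.index.duplicated().sum())
        logger.info("read_expression_tsv(%s): averaging %d duplicate gene rows", path, n)
        df = df.groupby(level=0).mean()
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicated sample ids")
    return df


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


# ---------------------------------------------------------------------------
# Normalization and dichotomization
# ---------------------------------------------------------------------------

def normalize_per_gene(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene's profile across samples (mean 0, sd 1).

    Constant rows are dropped with a warning; the per-gene center and scale
    are stored in ``.attrs['center']`` / ``.attrs['scale']`` so the
    transform can be inverted with :func:`denormalize`.
    """
    if matrix.shape[1] < 2:
        raise ValueError("normalize_per_gene: need >= 2 samples")
    sd = matrix.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("normalize_per_gene: all rows are constant")
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("normalize_per_gene: dropping %d constant rows", dropped)
    sub = matrix.loc[keep]
    center = sub.mean(axis=1)
    scale = sd.loc[keep]
    z = sub.sub(center, axis=0).div(scale, axis=0)
    z.attrs["center"] = center
    z.attrs["scale"] = scale
    return z


def denormalize(z: pd.DataFrame) -> pd.DataFrame:
    """Invert :func:`normalize_per_gene` using the stored center/scale."""
    return z.mul(z.attrs["scale"], axis=0).add(z.attrs["center"], axis=0)


def dichotomize(
    matrix: pd.DataFrame,
    *,
    linkage_method: str = "average",
) -> DichotomyResult:
    """Two-way hierarchical split of genes and samples.

    Rows are z-scored, genes are clustered with correlation distance
    (1 - Pearson r) and samples with Euclidean distance, both trees cut at
    k = 2.  Labels follow the convention documented on
    :class:`DichotomyResult`.
    """
    if matrix.shape[0] < 4 or matrix.shape[1] < 4:
        raise ValueError("dichotomize: need at least 4 genes and 4 samples")
    z = normalize_per_gene(matrix)
    if z.shape[0] < 4:
        raise ValueError("dichotomize: too few non-constant genes")
    zv = z.to_numpy()
    gene_link = linkage(pdist(zv, metric="correlation"), method=linkage_method)
    gene_lab = fcluster(gene_link, t=2, criterion="maxclust")
    samp_link = linkage(pdist(zv.T, metric="euclidean"), method=linkage_method)
    samp_lab = fcluster(samp_link, t=2, criterion="maxclust")
    if len(set(gene_lab)) < 2 or len(set(samp_lab)) < 2:
        raise ValueError("dichotomize: degenerate matrix, could not split in two")
    # label convention: (group 1, T1) is the cell with the largest mean
    means = np.full((2, 2), -np.inf)
    for g in (1, 2):
        for s in (1, 2):
            cell = zv[np.ix_(gene_lab == g, samp_lab == s)]
            if cell.size:
                means[g - 1, s - 1] = cell.mean()
    g1, t1 = np.unravel_index(int(np.argmax(means)), means.shape)
    gene_group = {
        gene: 1 if lab == g1 + 1 else 2 for gene, lab in zip(z.index, gene_lab)
    }
    sample_cluster = {
        s: "T1" if lab == t1 + 1 else "T2" for s, lab in zip(z.columns, samp_lab)
    }
    return DichotomyResult(
        gene_group=gene_group,
        sample_cluster=sample_cluster,
        linkage_method=linkage_method,
    )


# ---------------------------------------------------------------------------
# Specificity
# ---------------------------------------------------------------------------

def tau_index(expression_vector: Sequence[float]) -> float:
    """Tissue-specificity index tau of a non-negative expression profile."""
    x = np.asarray(expression_vector, dtype=float)
    if x.size < 2:
        raise ValueError("tau_index: need >= 2 samples")
    if (x < 0).any():
        raise ValueError("tau_index: negative expression values")
    xmax = x.max()
    if xmax == 0:
        logger.warning("tau_index: all-zero profile; tau undefined")
        return float("nan")
    return float(np.sum(1.0 - x / xmax) / (x.size - 1))


def expression_breadth(
    matrix: pd.DataFrame,
    quantile_thresholds: Sequence[float] = (0.15, 0.25, 0.50),
) -> SpecificityProfile:
    """Active-sample counts at pooled-quantile activity cutoffs.

    For each threshold q, the cutoff is the q-quantile (linear
    interpolation) of all values pooled across genes and samples; a gene is
    active in a sample when its value is >= the cutoff.
    """
    qs = tuple(quantile_thresholds)
    if any(not (0 < q < 1) for q in qs):
        raise ValueError("expression_breadth: thresholds must lie in (0, 1)")
    pooled = matrix.to_numpy().ravel()
    cutoffs = tuple(float(np.quantile(pooled, q)) for q in qs)
    breadth = pd.DataFrame(
        {q: (matrix >= c).sum(axis=1) for q, c in zip(qs, cutoffs)},
        index=matrix.index,
    )
    tau = matrix.apply(lambda row: tau_index(row.to_numpy()), axis=1)
    return SpecificityProfile(tau=tau, breadth=breadth, thresholds=qs, cutoffs=cutoffs)


specificity_profile = expression_breadth  # tau + breadth in one pass


# ---------------------------------------------------------------------------
# Group and pair comparisons
# ---------------------------------------------------------------------------

def group_vs_background(
    matrix: pd.DataFrame,
    group: Iterable[str],
    background_size: int = 1000,
    seed: int = 0,
    *,
    sample_clusters: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-sample Wilcoxon rank-sum of a gene group against a random
    transcriptome background.

    Returns a DataFrame with one row per sample (or per cluster when
    ``sample_clusters`` is given, pooling values within each cluster):
    statistic, two-sided p, and direction (+1 when the group median exceeds
    the background median).
    """
    group_genes = sorted(set(group) & set(matrix.index))
    if not group_genes:
        raise ValueError("group_vs_background: group is empty after intersection")
    others = matrix.index.difference(group_genes)
    if len(others) == 0:
        raise ValueError("group_vs_background: no background genes left")
    rng = np.random.default_rng(seed)
    size = min(background_size, len(others))
    bg_genes = rng.choice(others.to_numpy(), size=size, replace=False)
    rows = []
    if sample_clusters is None:
        units = {s: [s] for s in matrix.columns}
    else:
        units = {}
        for s, c in sample_clusters.items():
            units.setdefault(c, []).append(s)
    for unit, samples in units.items():
        gvals = matrix.loc[group_genes, samples].to_numpy().ravel()
        bvals = matrix.loc[bg_genes, samples].to_numpy().ravel()
        res = stats.ranksums(gvals, bvals)
        rows.append({
            "unit": unit,
            "statistic": float(res.statistic),
            "p": float(res.pvalue),
            "direction": int(np.sign(np.median(gvals) - np.median(bvals))),
        })
    return pd.DataFrame(rows)


def coexpression_qc(
    graph: nx.Graph,
    matrix: pd.DataFrame,
    n_random_pairs: int = 1000,
    seed: int = 0,
) -> CoexpressionSummary:
    """Network quality check: are interacting pairs more co-expressed than
    random non-adjacent pairs?

    Pearson correlation across samples is computed per interacting pair
    (pairs involving a constant profile are excluded, logged) and per
    random non-adjacent pair; the two correlation distributions are
    compared with a two-sided Wilcoxon rank-sum test.
    """
    present = [g for g in matrix.index if g in graph]
    present_set = set(present)
    sd = matrix.std(axis=1, ddof=0)
    usable = {g for g in present if sd[g] > 0}
    n_const = len(present_set) - len(usable)
    if n_const:
        logger.info("coexpression_qc: excluding %d constant genes", n_const)
    edges = [
        (u, v) for u, v in graph.edges() if u in usable and v in usable
    ]
    if not edges:
        raise ValueError("coexpression_qc: no usable interacting pairs")
    X = matrix.loc[sorted(usable)]
    z = X.sub(X.mean(axis=1), axis=0).div(X.std(axis=1, ddof=0), axis=0)
    zv = z.to_numpy() / np.sqrt(z.shape[1])
    idx = {g: i for i, g in enumerate(z.index)}
    r_int = np.array([float(zv[idx[u]] @ zv[idx[v]]) for u, v in edges])
    rng = np.random.default_rng(seed)
    genes = list(z.index)
    r_rand = []
    guard = 0
    while len(r_rand) < n_random_pairs and guard < 50 * n_random_pairs:
        guard += 1
        u, v = rng.choice(len(genes), size=2, replace=False)
        gu, gv = genes[u], genes[v]
        if graph.has_edge(gu, gv):
            continue
        r_rand.append(float(zv[idx[gu]] @ zv[idx[gv]]))
    if not r_rand:
        raise ValueError("coexpression_qc: could not sample non-adjacent pairs")
    res = stats.ranksums(r_int, np.asarray(r_rand))
    return CoexpressionSummary(
        median_r_interacting=float(np.median(r_int)),
        median_r_random=float(np.median(r_rand)),
        p_value=float(res.pvalue),
        n_interacting=len(r_int),
        n_random=len(r_rand),
    )


# ---------------------------------------------------------------------------
# Extreme differential expression
# ---------------------------------------------------------------------------

def _as_profile(m: pd.DataFrame | pd.Series) -> pd.Series:
    """Average replicate columns down to one per-gene profile."""
    if isinstance(m, pd.Series):
        return m
    return m.mean(axis=1)


def extreme_de_call(
    case_matrices: Sequence[pd.DataFrame | pd.Series],
    control_matrices: Sequence[pd.DataFrame | pd.Series],
    fc_min: float = 2.0,
    upper_q: float = 0.975,
    lower_q: float = 0.025,
    min_expr: float = 1.0,
    eps: float = 0.01,
) -> DEResult:
    """Call genes with extreme expression changes in matched pairs.

    Per pair: genes with case AND control expression below ``min_expr`` are
    excluded; the fold change (case+eps)/(control+eps) is computed for the
    rest; a gene is up-extreme when its fold change exceeds both ``fc_min``
    and the pair's transcriptome-wide ``upper_q`` quantile, and
    down-extreme symmetrically with 1/``fc_min`` and ``lower_q``.  A gene is
    called when extreme in at least one pair.
    """
    if len(case_matrices) != len(control_matrices):
        raise ValueError("extreme_de_call: case/control lists must be index-paired")
    if not case_matrices:
        raise ValueError("extreme_de_call: no pairs")
    if fc_min <= 1:
        raise ValueError("extreme_de_call: fc_min must exceed 1")
    if not (0 < lower_q < upper_q < 1):
        raise ValueError("extreme_de_call: need 0 < lower_q < upper_q < 1")
    records = []
    for pair_id, (cm, km) in enumerate(zip(case_matrices, control_matrices)):
        case = _as_profile(cm)
        ctrl = _as_profile(km)
        common = case.index.intersection(ctrl.index)
        case, ctrl = case.loc[common], ctrl.loc[common]
        keep = (case >= min_expr) | (ctrl >= min_expr)
        case, ctrl = case[keep], ctrl[keep]
        if case.empty:
            continue
        fc = (case + eps) / (ctrl + eps)
        hi = fc.quantile(upper_q)
        lo = fc.quantile(lower_q)
        # quantile comparisons are inclusive so ties at the bound (many
        # genes at one extreme fold change) still qualify
        up = (fc > fc_min) & (fc >= hi)
        down = (fc < 1.0 / fc_min) & (fc <= lo)
        records.append(pd.DataFrame({
            "gene": fc.index,
            "pair_id": pair_id,
            "fold_change": fc.to_numpy(),
            "up_extreme": up.to_numpy(),
            "down_extreme": down.to_numpy(),
        }))
    per_pair = pd.concat(records, ignore_index=True) if records else pd.DataFrame(
        columns=["gene", "pair_id", "fold_change", "up_extreme", "down_extreme"]
    )
    if per_pair.empty:
        any_extreme = pd.Series(dtype=bool)
    else:
        flag = per_pair["up_extreme"] | per_pair["down_extreme"]
        any_extreme = flag.groupby(per_pair["gene"]).any().sort_index()
    return DEResult(per_pair=per_pair, any_extreme=any_extreme)


def de_module_enrichment(
    de: DEResult,
    module: Iterable[str],
    universe: Iterable[str],
) -> EnrichmentResult:
    """Hypergeometric enrichment of extreme-DE genes inside a module,
    with the network gene set as universe."""
    uni = set(universe)
    mod = set(module) & uni
    de_genes = set(de.extreme_genes) & uni
    k = len(de_genes & mod)
    p = hypergeom_upper_tail(k, len(mod), len(de_genes), len(uni))
    return EnrichmentResult(
        module_id="module", set_name="extreme_de", k=k, n=len(mod),
        K_set=len(de_genes), N_u=len(uni), p_value=p, fdr=p,
    )
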