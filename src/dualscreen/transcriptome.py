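"""Expression normalization, differential expression, clustering and trajectories.

Counts are normalized to log2 counts-per-million with a small prior:
``log2((count + prior) / (libsize + 1) * 1e6)``.  This fixed formula is a
documented simplified stand-in for edgeR's ``cpm(log=TRUE)`` (whose
prior rescaling per library is not replicated here).

Differential expression between two sample groups uses a per-gene Welch
two-sample t-test on log2-CPM values with Benjamini-Hochberg adjustment —
a deliberately simple, well-calibrated substitute for a full
negative-binomial GLM engine; externally computed DE tables can be
ingested instead via :func:`read_de_table`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .enrichment import GeneSet
from .highcontent import CorrelationMatrix

__all__ = [
    "DEResult",
    "DESummary",
    "TrajectorySummary",
    "log2_cpm",
    "simple_de",
    "de_gene_sets",
    "de_summary",
    "log2fc_matrix",
    "row_zscore",
    "transcriptome_correlation",
    "hierarchical_clusters",
    "trajectory_summary",
    "ddct",
    "read_counts",
    "read_de_table",
    "write_de_table",
]

DE_COLUMNS = ("gene", "log2fc", "p", "padj")


@dataclass(frozen=True)
class DEResult:
    """A differential-expression table plus the genes excluded before testing.

    ``table`` has columns gene, log2fc (group B minus group A, i.e.
    knockdown vs control when A is the control), p and padj (BH).
    ``excluded_genes`` had zero counts in every sample and were not tested.
    """

    table: pd.DataFrame
    excluded_genes: tuple[str, ...] = ()


@dataclass(frozen=True)
class DESummary:
    """Headline numbers of a DE table at a significance cutoff.

    ``fraction_up`` and ``mean_abs_log2fc`` are ``None`` (absent, not zero)
    when no gene is significant.
    """

    n_deregulated: int
    fraction_up: float | None
    mean_abs_log2fc: float | None


@dataclass(frozen=True)
class TrajectorySummary:
    """Median max-normalized expression per timepoint with bootstrap 95% CI."""

    timepoints: tuple[str, ...]
    median: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_genes: int


def log2_cpm(counts: pd.DataFrame, prior: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million: ``log2((count + prior) / (libsize + 1) * 1e6)``."""
    x = counts.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("negative counts")
    lib = x.sum(axis=0)
    if np.any(lib <= 0):
        empty = [c for c, s in zip(counts.columns, lib) if s <= 0]
        raise ValueError(f"library size is zero for samples: {empty}")
    vals = np.log2((x + prior) / (lib + 1.0) * 1e6)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def simple_de(
    counts: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    prior: float = 0.5,
    moderated: bool = True,
) -> DEResult:
    """Per-gene t-test on log2-CPM, group B (treatment) vs group A (control).

    By default the per-gene variance is shrunk toward a common prior fitted
    across all genes (empirical-Bayes moderation in the style of limma's
    moderated t), which restores power at the 2-3 replicates typical of
    knockdown screens, where raw per-gene variance estimates are too noisy
    to detect even large fold changes.  ``moderated=False`` gives the plain
    Welch two-sample test instead.

    Genes with zero counts in all samples of both groups are excluded and
    reported.  Two-sided p-values; undefined tests (both groups constant
    and identical) get p = 1.  BH adjustment over the tested genes.
    """
    group_a, group_b = list(group_a), list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"sample groups overlap: {sorted(overlap)}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    missing = [s for s in group_a + group_b if s not in counts.columns]
    if missing:
        raise ValueError(f"samples not in count matrix: {missing}")
    sub = counts[group_a + group_b]
    all_zero = sub.sum(axis=1).to_numpy() == 0
    excluded = tuple(sub.index[all_zero])
    sub = sub.loc[~all_zero]
    lcpm = log2_cpm(sub, prior=prior)
    # median-of-ratios size correction: library totals are distorted by the
    # DE genes themselves (composition bias), so each sample is re-centered
    # by its median log-ratio to the gene-wise mean profile
    x = lcpm.to_numpy()
    offsets = np.median(x - x.mean(axis=1, keepdims=True), axis=0)
    lcpm = lcpm - offsets
    xa = lcpm[group_a].to_numpy()
    xb = lcpm[group_b].to_numpy()
    lfc = xb.mean(axis=1) - xa.mean(axis=1)
    if moderated:
        p = _moderated_t_pvalues(xa, xb, lfc)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # 0/0, constant genes
            t = stats.ttest_ind(xb, xa, axis=1, equal_var=False)
        p = np.nan_to_num(t.pvalue, nan=1.0)
    padj = benjamini_hochberg(p)
    table = pd.DataFrame(
        {"gene": sub.index, "log2fc": lfc, "p": p, "padj": padj}
    ).reset_index(drop=True)
    return DEResult(table, excluded)


def _moderated_t_pvalues(xa: np.ndarray, xb: np.ndarray, lfc: np.ndarray) -> np.ndarray:
    """Two-sided p-values from an empirical-Bayes moderated two-sample t.

    The pooled per-gene residual variance (df = na + nb - 2) is squeezed
    toward a scaled inverse-chi-square prior fitted by the method of
    moments on log variances (Smyth 2004), with the prior scale following
    the mean-variance trend over average log2-CPM (counts have higher
    relative variance at low expression, so a constant prior would
    anti-conservatively shrink low-expression genes).  The moderated t has
    df = d0 + d.  Genes with identical values in both groups get p = 1.
    """
    na, nb = xa.shape[1], xb.shape[1]
    d = na + nb - 2
    rss = xa.var(axis=1, ddof=1) * (na - 1) + xb.var(axis=1, ddof=1) * (nb - 1)
    s2 = rss / d
    amean = np.concatenate([xa, xb], axis=1).mean(axis=1)
    ok = s2 > 0
    if not np.any(ok):
        return np.ones_like(lfc)
    d0, s0_sq = _fit_variance_prior(s2[ok], d, amean[ok], amean)
    if np.isinf(d0):
        s2_post = s0_sq
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return np.where(np.isfinite(t), p, 1.0)


def _fit_variance_prior(
    s2: np.ndarray, df: int, amean: np.ndarray, amean_all: np.ndarray
) -> tuple[float, np.ndarray]:
    """Fit (d0, per-gene s0^2) of a trended scaled inverse-chi-square prior.

    On z = log(s2), E[z] follows a smooth trend in average log-expression
    (estimated by binned means over expression quantiles, linearly
    interpolated) and var(z) around the trend is trigamma(df/2) +
    trigamma(d0/2).  Non-positive excess spread means the variances are
    essentially exchangeable given the trend: d0 = inf.
    """
    z = np.log(s2)
    e = z - digamma(df / 2.0) + math.log(df / 2.0)
    n = len(e)
    if n < 30:  # too few genes to fit a trend; constant prior
        trend_at = np.full_like(amean_all, e.mean())
        resid = e - e.mean()
    else:
        n_bins = min(20, n // 15)
        edges = np.quantile(amean, np.linspace(0, 1, n_bins + 1))
        centers, means = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            in_bin = (amean >= lo) & (amean <= hi)
            if in_bin.sum() >= 3:
                centers.append(amean[in_bin].mean())
                means.append(e[in_bin].mean())
        trend_at = np.interp(amean_all, centers, means)
        resid = e - np.interp(amean, centers, means)
    if n < 2:
        return np.inf, np.exp(trend_at)
    evar = float(np.sum(resid**2) / (n - 1) - polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, np.exp(trend_at)
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = np.exp(trend_at + digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return d0, s0_sq


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        step = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y - step
        if abs(step) < 1e-10 * y:
            break
    return float(y)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (delegates to statsmodels)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def de_gene_sets(
    table: pd.DataFrame, alpha: float = 0.05, name_prefix: str = "de"
) -> tuple[GeneSet, GeneSet, GeneSet]:
    """Split a DE table at ``padj < alpha`` (strict) into up / down / universe sets."""
    _check_de_table(table)
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    sig = table["padj"] < alpha
    up = table.loc[sig & (table["log2fc"] > 0), "gene"]
    down = table.loc[sig & (table["log2fc"] < 0), "gene"]
    universe_name = f"{name_prefix}_universe"
    return (
        GeneSet.from_symbols(f"{name_prefix}_up", up, universe_name),
        GeneSet.from_symbols(f"{name_prefix}_down", down, universe_name),
        GeneSet.from_symbols(universe_name, table["gene"]),
    )


def de_summary(table: pd.DataFrame, alpha: float = 0.05) -> DESummary:
    """Count deregulated genes and summarize direction and effect size."""
    _check_de_table(table)
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    sig = table[table["padj"] < alpha]
    if sig.empty:
        return DESummary(0, None, None)
    return DESummary(
        int(len(sig)),
        float((sig["log2fc"] > 0).mean()),
        float(sig["log2fc"].abs().mean()),
    )


def log2fc_matrix(
    tables: Mapping[str, pd.DataFrame],
    genes: Iterable[str],
    policy: str = "fill-zero",
) -> pd.DataFrame:
    """Assemble a genes x conditions log2FC matrix from per-condition DE tables.

    ``policy`` decides what happens when a requested gene is absent from a
    table: ``fill-zero`` inserts 0 with a warning, ``drop-gene`` removes the
    gene from the matrix entirely.
    """
    if policy not in ("fill-zero", "drop-gene"):
        raise ValueError(f"unknown policy {policy!r}")
    genes = list(dict.fromkeys(genes))
    cols = {}
    missing_by_gene: dict[str, list[str]] = {}
    for cond, table in tables.items():
        _check_de_table(table)
        lfc = table.set_index("gene")["log2fc"]
        col = lfc.reindex(genes)
        for g in col.index[col.isna()]:
            missing_by_gene.setdefault(g, []).append(cond)
        cols[cond] = col
    mat = pd.DataFrame(cols, index=genes)
    if missing_by_gene:
        shown = ", ".join(
            f"{g} ({len(c)} tables)" for g, c in list(missing_by_gene.items())[:10]
        )
        if policy == "fill-zero":
            warnings.warn(
                f"{len(missing_by_gene)} genes missing from some DE tables, "
                f"filled with log2FC = 0: {shown}"
            )
            mat = mat.fillna(0.0)
        else:
            warnings.warn(
                f"{len(missing_by_gene)} genes missing from some DE tables, "
                f"dropped: {shown}"
            )
            mat = mat.dropna()
    return mat


def row_zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each row to mean 0, sample SD 1 (ddof=1).

    Constant rows cannot be scaled; they are excluded from the output with
    a warning naming them.
    """
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    flat = ~(sd > 0)
    if flat.any():
        names = list(matrix.index[flat])
        warnings.warn(f"{len(names)} constant rows excluded from row_zscore: {names[:10]}")
    keep = ~flat
    z = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    return pd.DataFrame(z, index=matrix.index[keep], columns=matrix.columns)


def transcriptome_correlation(matrix: pd.DataFrame) -> CorrelationMatrix:
    """Knockdown-to-knockdown Pearson correlation over the gene axis.

    ``matrix`` is genes x knockdowns (e.g. log2FC vs a common control).
    """
    if matrix.shape[0] < 3:
        raise ValueError("need at least 3 genes")
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    flat = [kd for kd, s in zip(matrix.columns, sd) if not s > 0]
    if flat:
        raise ValueError(f"zero-variance column for knockdowns: {flat}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(tuple(matrix.columns), r)


def hierarchical_clusters(
    matrix: pd.DataFrame | np.ndarray,
    k: int,
    metric: str = "euclidean",
    linkage: str = "average",
) -> np.ndarray:
    """Agglomerative clustering of rows, cut to ``k`` clusters.

    ``metric`` is ``euclidean`` or ``correlation``; ``linkage`` is
    ``average``, ``complete`` or ``ward`` (ward requires euclidean).
    Cluster labels are renumbered 1..k by decreasing cluster size, ties
    broken by first row index, so the labelling is deterministic and
    invariant to row order up to relabeling.
    """
    x = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds the number of rows ({x.shape[0]})")
    if metric not in ("euclidean", "correlation"):
        raise ValueError(f"unknown metric {metric!r}")
    if linkage not in ("average", "complete", "ward"):
        raise ValueError(f"unknown linkage {linkage!r}")
    if linkage == "ward" and metric != "euclidean":
        raise ValueError("ward linkage requires the euclidean metric")
    d = pdist(x, metric=metric)
    z = scipy_linkage(d, method=linkage)
    raw = fcluster(z, t=k, criterion="maxclust")
    return _renumber_by_size(raw)


def _renumber_by_size(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    order = sorted(
        np.unique(labels),
        key=lambda c: (-(labels == c).sum(), int(np.argmax(labels == c))),
    )
    remap = {c: i + 1 for i, c in enumerate(order)}
    return np.array([remap[c] for c in labels], dtype=int)


def trajectory_summary(
    expr: pd.DataFrame,
    gene_set: GeneSet | Iterable[str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 95.0,
) -> TrajectorySummary:
    """Median max-normalized trajectory of a gene set across timepoints.

    Each gene's expression vector (columns = ordered timepoints, strictly
    positive values, e.g. log2-CPM of well-expressed genes) is divided by
    its own maximum, so every gene peaks at 1.  Per timepoint the median
    over genes is reported with a bootstrap (resampling genes) percentile
    confidence interval.
    """
    if gene_set is not None:
        wanted = gene_set.members if isinstance(gene_set, GeneSet) else set(gene_set)
        idx = [g for g in expr.index if str(g).upper() in {str(w).upper() for w in wanted}]
        if not idx:
            raise ValueError("gene set has no genes in the expression matrix")
        expr = expr.loc[idx]
    if expr.empty:
        raise ValueError("empty expression matrix")
    x = expr.to_numpy(dtype=float)
    if np.any(x <= 0):
        raise ValueError(
            "non-positive expression values; max-normalization needs strictly "
            "positive input (use shifted or log-scale expression)"
        )
    norm = x / x.max(axis=1, keepdims=True)
    med = np.median(norm, axis=0)
    rng = np.random.default_rng(seed)
    n = norm.shape[0]
    boot_idx = rng.integers(0, n, size=(n_boot, n))
    boot_med = np.median(norm[boot_idx], axis=1)
    lo_q, hi_q = (100 - ci) / 2, 100 - (100 - ci) / 2
    ci_low = np.percentile(boot_med, lo_q, axis=0)
    ci_high = np.percentile(boot_med, hi_q, axis=0)
    # percentile bootstrap can nick the observed median on tiny sets
    ci_low = np.minimum(ci_low, med)
    ci_high = np.maximum(ci_high, med)
    return TrajectorySummary(tuple(map(str, expr.columns)), med, ci_low, ci_high, n)


def ddct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression by the delta-delta-Ct method: ``2**(-ddCt)``.

    ``ddCt = (Ct_target,sample - Ct_ref,sample) - (Ct_target,control -
    Ct_ref,control)`` with a housekeeping reference gene (e.g. GAPDH).
    """
    vals = (ct_target_sample, ct_ref_sample, ct_target_control, ct_ref_control)
    if not all(np.isfinite(v) for v in vals):
        raise ValueError("Ct values must be finite")
    d = (ct_target_sample - ct_ref_sample) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-d))


def _check_de_table(table: pd.DataFrame) -> None:
    if table.empty:
        raise ValueError("DE table is empty")
    missing = [c for c in DE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"DE table is missing columns: {missing}")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples count matrix TSV (first column = gene labels)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError("duplicate gene labels in count matrix")
    return df


def read_de_table(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read an (external) DE table TSV, mapping column names onto gene/log2fc/p/padj.

    ``columns`` maps canonical names to the file's column names, e.g.
    ``{"gene": "symbol", "log2fc": "log2FoldChange", "p": "pvalue",
    "padj": "padj"}``; by default the canonical names are expected.
    """
    df = pd.read_csv(path, sep="\t")
    if columns:
        rename = {v: k for k, v in columns.items()}
        df = df.rename(columns=rename)
    _check_de_table(df)
    return df[list(DE_COLUMNS)].copy()


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    _check_de_table(table)
    table[list(DE_COLUMNS)].to_csv(path, sep="\t", index=False, lineterminator="\n")
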