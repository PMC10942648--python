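"""Integration of reporter-defined enhancers with in vivo cohort data.

Matched per-individual methylation and expression (baseline vs infected)
are filtered, summarized to window-level methylation, linked to genes
(nearest gene within 100 kb, or a supplied link table), and correlated:
within each individual across enhancer-gene pairs (Bonferroni across
individuals), and per pair across individuals (Storey q-values).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import GenomicWindow
from .fdr import storey_qvalue

log = logging.getLogger("mstarr")


@dataclass
class CohortDataset:
    """Individuals x windows methylation plus individuals x genes expression
    in two conditions, gene coordinates, and enhancer-gene links."""

    individuals: list[str]
    meth_baseline: pd.DataFrame  # individuals x windows, in [0, 1]
    expr_baseline: pd.DataFrame  # individuals x genes, log-CPM scale
    expr_infected: pd.DataFrame
    genes: pd.DataFrame  # gene_id, chrom, start, end[, strand]
    links: pd.DataFrame | None = None  # window_id, gene_id, distance, source

    def __post_init__(self) -> None:
        m = self.meth_baseline.to_numpy(float)
        if ((m < 0) | (m > 1)).any():
            raise ValueError("methylation outside [0, 1]")
        for df in (self.expr_baseline, self.expr_infected):
            if list(df.index) != list(self.individuals):
                raise ValueError("individual sets do not match across matrices")

    def fold_change(self) -> pd.DataFrame:
        return fold_change_matrix(self.expr_infected, self.expr_baseline)


# ---------------------------------------------------------------- filtering

def filter_cpg_coverage(
    coverage_baseline: pd.DataFrame,
    coverage_infected: pd.DataFrame,
    min_cov: int = 4,
    min_frac_samples: float = 0.5,
) -> pd.Series:
    """CpG retained iff covered >= min_cov in >= min_frac of samples within
    the non-infected set OR within the infected set."""
    def ok(cov: pd.DataFrame) -> pd.Series:
        return (cov >= min_cov).mean(axis=0) >= min_frac_samples

    return ok(coverage_baseline) | ok(coverage_infected)


def filter_genes_expression(
    expr_by_condition: dict[str, pd.DataFrame], rule: str = "mean-threshold"
) -> pd.Series:
    """Gene-inclusion presets.

    "mean-threshold" (cohort): mean expression > 2 in at least one
    condition. "per-sample-threshold" (cell-line): expression > 3 in at
    least 3 samples of at least one condition. The caller supplies
    expression on the rule's scale (RPKM / TPM respectively).
    """
    mats = list(expr_by_condition.values())
    if rule == "mean-threshold":
        masks = [m.mean(axis=0) > 2.0 for m in mats]
    elif rule == "per-sample-threshold":
        masks = [(m > 3.0).sum(axis=0) >= 3 for m in mats]
    else:
        raise ValueError(f"unknown rule {rule!r}")
    out = masks[0]
    for m in masks[1:]:
        out = out | m
    if not out.any():
        log.warning("no genes pass the %s expression filter", rule)
    return out


def residualize_covariates(
    matrix: pd.DataFrame, covariates: np.ndarray, restore_means: bool = True
) -> pd.DataFrame:
    """Per row, OLS residuals against the covariates (plus intercept);
    row means restored by default."""
    C = np.column_stack([np.ones(matrix.shape[1]), np.asarray(covariates, float)])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("rank-deficient covariates")
    Y = matrix.to_numpy(float)
    beta = Y @ np.linalg.pinv(C).T
    resid = Y - beta @ C.T
    if restore_means:
        resid = resid + Y.mean(axis=1, keepdims=True)
    return pd.DataFrame(resid, index=matrix.index, columns=matrix.columns)


def fold_change_matrix(
    expr_infected: pd.DataFrame, expr_baseline: pd.DataFrame
) -> pd.DataFrame:
    """Per-individual response: infected minus baseline log-CPM."""
    common = expr_infected.index.intersection(expr_baseline.index)
    dropped = set(expr_infected.index).symmetric_difference(expr_baseline.index)
    if dropped:
        log.warning("dropping %d individuals missing one condition", len(dropped))
    genes = expr_infected.columns.intersection(expr_baseline.columns)
    return expr_infected.loc[common, genes] - expr_baseline.loc[common, genes]


# ------------------------------------------------------- window summarization

def window_mean_methylation(
    meth: pd.DataFrame,
    cpg_positions: pd.DataFrame,
    windows: Sequence[GenomicWindow],
    min_var: float = 0.0,
) -> pd.DataFrame:
    """Mean methylation per window per individual.

    ``meth`` is individuals x CpGs (columns aligned positionally with the
    rows of ``cpg_positions``: chrom, pos). CpGs map to windows by
    half-open containment; with min_var > 0, CpGs whose across-individual
    variance is below the cut are excluded, and windows left with no
    qualifying CpG are dropped from the output.
    """
    if len(cpg_positions) != meth.shape[1]:
        raise ValueError("cpg_positions rows must match meth columns")
    variances = meth.to_numpy(float).var(axis=0)
    keep = variances >= min_var if min_var > 0 else np.ones(len(variances), bool)

    chrom = cpg_positions["chrom"].to_numpy()
    pos = cpg_positions["pos"].to_numpy()
    cols: dict[str, np.ndarray] = {}
    for w in windows:
        inside = (chrom == w.chrom) & (pos >= w.start) & (pos < w.end) & keep
        if inside.any():
            cols[w.window_id] = meth.to_numpy(float)[:, inside].mean(axis=1)
    return pd.DataFrame(cols, index=meth.index)


def link_enhancers_to_genes(
    windows: Sequence[GenomicWindow],
    gene_coords: pd.DataFrame,
    max_dist: int = 100_000,
    link_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Enhancer-gene links: supplied table, or nearest gene within max_dist.

    Distance is the bp gap between the window and the gene body (0 when
    overlapping); equidistant genes are all linked. Returns columns
    window_id, gene_id, distance, source.
    """
    if link_table is not None:
        out = link_table.copy()
        if "source" not in out.columns:
            out["source"] = "table"
        return out
    rows = []
    for w in windows:
        genes_c = gene_coords[gene_coords["chrom"] == w.chrom]
        if len(genes_c) == 0:
            continue
        gap = np.maximum(
            0,
            np.maximum(
                genes_c["start"].to_numpy() - w.end, w.start - genes_c["end"].to_numpy()
            ),
        )
        # overlap => gap 0; interval arithmetic: gene.start - w.end when gene
        # right of window, w.start - gene.end when left; off-by-one-free in
        # half-open coords up to the +1 adjacency convention, which cancels
        # in nearest-gene comparisons
        best = gap.min()
        if best > max_dist:
            continue
        for gid, d in zip(genes_c["gene_id"].to_numpy()[gap == best], [best] * int((gap == best).sum())):
            rows.append({"window_id": w.window_id, "gene_id": gid,
                         "distance": int(d), "source": "nearest"})
    return pd.DataFrame(rows, columns=["window_id", "gene_id", "distance", "source"])


def _window_response(
    response: pd.DataFrame, links: pd.DataFrame, window_ids: Sequence[str]
) -> pd.DataFrame:
    """Per-window response = mean response across its linked genes."""
    cols = {}
    grouped = links.groupby("window_id")["gene_id"].apply(list)
    for wid in window_ids:
        if wid not in grouped.index:
            continue
        genes = [g for g in grouped[wid] if g in response.columns]
        if genes:
            cols[wid] = response[genes].mean(axis=1)
    return pd.DataFrame(cols, index=response.index)


def _fisher_z_ci(r: float, n: int) -> tuple[float, float]:
    if n <= 3 or abs(r) >= 1:
        return (np.nan, np.nan)
    z = np.arctanh(r)
    half = 1.959963984540054 / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def within_individual_correlation(
    window_meth: pd.DataFrame,
    gene_response: pd.DataFrame,
    links: pd.DataFrame,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Per individual, Pearson r between baseline window methylation and
    linked-gene response across enhancer-gene pairs.

    Returns per-individual r, Fisher-z 95% CI, R^2, two-sided p, and
    Bonferroni-adjusted p across individuals. Individuals with fewer than
    ``min_pairs`` linked pairs are skipped with a warning.
    """
    resp = _window_response(gene_response, links, list(window_meth.columns))
    shared = [w for w in window_meth.columns if w in resp.columns]
    rows = []
    for ind in window_meth.index:
        x = window_meth.loc[ind, shared].to_numpy(float)
        y = resp.loc[ind, shared].to_numpy(float)
        okm = np.isfinite(x) & np.isfinite(y)
        if okm.sum() < min_pairs:
            log.warning("individual %s has < %d linked pairs; skipped", ind, min_pairs)
            continue
        r, p = stats.pearsonr(x[okm], y[okm])
        lo, hi = _fisher_z_ci(r, int(okm.sum()))
        rows.append({"unit": ind, "n_pairs": int(okm.sum()), "r": r, "r2": r**2,
                     "ci_low": lo, "ci_high": hi, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    return out


def locuswise_association(
    window_meth: pd.DataFrame,
    gene_fc: pd.DataFrame,
    links: pd.DataFrame,
    min_individuals: int = 5,
) -> pd.DataFrame:
    """Per enhancer-gene pair, Pearson r across individuals between
    baseline window methylation and the linked gene's response, with
    Storey q-values; pairs ranked by p."""
    if window_meth.shape[0] < min_individuals:
        raise ValueError(f"need >= {min_individuals} individuals")
    rows = []
    for link in links.itertuples(index=False):
        if link.window_id not in window_meth.columns or link.gene_id not in gene_fc.columns:
            continue
        x = window_meth[link.window_id].to_numpy(float)
        y = gene_fc[link.gene_id].to_numpy(float)
        okm = np.isfinite(x) & np.isfinite(y)
        if okm.sum() < min_individuals or np.std(x[okm]) == 0 or np.std(y[okm]) == 0:
            continue
        r, p = stats.pearsonr(x[okm], y[okm])
        lo, hi = _fisher_z_ci(r, int(okm.sum()))
        rows.append({"window_id": link.window_id, "gene_id": link.gene_id,
                     "n": int(okm.sum()), "r": r, "r2": r**2,
                     "ci_low": lo, "ci_high": hi, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = storey_qvalue(out["p"].to_numpy())
        out = out.sort_values("p").reset_index(drop=True)
    return out


def group_response_ttest(
    values_a: np.ndarray, values_b: np.ndarray, paired: bool = False
) -> tuple[float, float, float]:
    """Welch two-sample t (unpaired) or paired t; returns (t, df, p).

    Degenerate zero-variance comparisons with equal means return p = 1.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal lengths")
        d = a - b
        if np.std(d, ddof=1) == 0:
            log.warning("degenerate paired t-test (constant differences)")
            return (0.0 if d.mean() == 0 else np.inf, float(a.size - 1), 1.0 if d.mean() == 0 else 0.0)
        res = stats.ttest_rel(a, b)
        return (float(res.statistic), float(a.size - 1), float(res.pvalue))
    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        if a.mean() == b.mean():
            log.warning("degenerate t-test: zero variance, equal means")
            return (0.0, float(a.size + b.size - 2), 1.0)
        return (np.inf if a.mean() > b.mean() else -np.inf, float(a.size + b.size - 2), 0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    return (float(res.statistic), float(res.df), float(res.pvalue))
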