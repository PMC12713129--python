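"""Replicate-level pseudobulk aggregation and negative-binomial testing.

The two-group test fits, per gene, a saturated group-mean NB model with
size-factor offsets: the two group means are independent one-parameter
maximum-likelihood problems solved by Newton iteration on the log mean.
The Wald statistic uses the observed Fisher information, which makes the
test exactly symmetric under swapping the contrast groups. Dispersions are
method-of-moments estimates shrunk 50/50 toward a fitted mean-dispersion
trend ``a0 + a1/mean``. This is a deliberately simplified stand-in for a
full pseudobulk engine: no LFC shrinkage, no independent filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from scrhythm.io import CellCountMatrix, PipelineConfig, logger

DISPERSION_FLOOR = 1e-8


@dataclass
class PseudobulkMatrix:
    """Gene x sample summed counts with a sample-level design table."""

    counts: np.ndarray                 # genes x samples, nonnegative ints
    gene_ids: np.ndarray
    design: pd.DataFrame               # one row per sample column
    size_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (genes x samples)")
        if len(self.design) != self.counts.shape[1]:
            raise ValueError("one design row required per sample column")
        if self.counts.size and np.any(self.counts < 0):
            raise ValueError("negative pseudobulk counts")

    @property
    def sample_ids(self) -> np.ndarray:
        return self.design["sample"].to_numpy()

    def columns_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([lookup[s] for s in sample_ids], dtype=int)


def passes_thresholds(
    padj: float, log2fc: float, alpha: float, lfc_threshold: float
) -> bool:
    """Significance rule shared by every DE path: adjusted p below alpha
    AND absolute log2FC at or above the fold-change cutoff."""
    return bool(padj < alpha) and bool(abs(log2fc) >= lfc_threshold)


def aggregate_pseudobulk(
    cells: CellCountMatrix,
    group_keys: Sequence[str] = ("sample", "cell_type"),
) -> PseudobulkMatrix:
    """Sum cell counts per group (default: per sample within cell type).

    Groups with zero cells do not appear as zero columns. The output is
    conservative: its total equals the total of the contributing cells.
    """
    group_keys = list(group_keys)
    meta = cells.cells
    codes, uniques = pd.factorize(
        pd.MultiIndex.from_frame(meta[group_keys]), sort=True
    )
    n_groups = len(uniques)
    indicator = sp.csr_matrix(
        (np.ones(len(codes)), (np.arange(len(codes)), codes)),
        shape=(len(codes), n_groups),
    )
    counts = np.asarray((cells.counts @ indicator).todense()).astype(np.int64)

    design_rows = []
    for gi, key in enumerate(uniques):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(group_keys, key))
        members = meta[codes == gi]
        row["sample"] = "|".join(str(v) for v in key)
        row["timepoint_hours"] = float(members["timepoint_hours"].iloc[0])
        row["n_cells"] = len(members)
        for extra in ("age_group", "replicate"):
            if extra in meta.columns:
                row[extra] = members[extra].iloc[0]
        design_rows.append(row)
    design = pd.DataFrame(design_rows)
    return PseudobulkMatrix(
        counts=counts, gene_ids=cells.gene_ids, design=design
    )


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors over genes positive in every sample.

    Falls back to library-size ratios (rescaled to geometric mean 1) with a
    warning when no gene is positive in all samples.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("size factors need at least 2 samples")
    reference = np.all(counts > 0, axis=1)
    if not reference.any():
        warnings.warn(
            "no gene positive in all samples; using library-size factors",
            RuntimeWarning,
        )
        lib = counts.sum(axis=0)
        if np.any(lib <= 0):
            raise ValueError("a sample has zero total counts")
        sf = lib / np.exp(np.mean(np.log(lib)))
        return sf
    ref = counts[reference]
    log_geo = np.mean(np.log(ref), axis=1, keepdims=True)
    ratios = np.log(ref) - log_geo
    log_sf = np.median(ratios, axis=0)
    log_sf -= log_sf.mean()  # pin geometric mean at exactly 1
    return np.exp(log_sf)


def _fit_group_mean(
    y: np.ndarray, sf: np.ndarray, alpha: float
) -> tuple[float, float]:
    """MLE of the NB group mean with offsets; returns (mean, Fisher info).

    Solves d/d(log m) sum log NB(y_i | m * sf_i, alpha) = 0 by Newton steps
    with step halving; the information is I = sum mu_i / (1 + alpha * mu_i).
    """
    total = y.sum()
    if total == 0:
        return 0.0, 0.0
    m = max(np.mean(y / sf), 1e-8)
    log_m = np.log(m)
    for _ in range(100):
        mu = np.exp(log_m) * sf
        score = np.sum((y - mu) / (1.0 + alpha * mu))
        info = np.sum(mu / (1.0 + alpha * mu))
        if info <= 0:
            break
        step = score / info
        step = np.clip(step, -5.0, 5.0)
        log_m += step
        if abs(step) < 1e-12:
            break
    m = np.exp(log_m)
    mu = m * sf
    info = np.sum(mu / (1.0 + alpha * mu))
    return m, info


def estimate_dispersions(
    counts: np.ndarray, sf: np.ndarray, groups: np.ndarray
) -> np.ndarray:
    """Per-gene dispersion: method of moments shrunk toward a 1/mean trend.

    MoM uses the pooled within-group variance of normalized counts with a
    Poisson correction term; estimates are shrunk 50/50 toward the fitted
    trend ``a0 + a1/mean`` and floored at 1e-8.
    """
    z = counts / sf[None, :]
    labels = np.unique(groups)
    ss = np.zeros(counts.shape[0])
    dof = 0
    means = []
    for g in labels:
        cols = groups == g
        zg = z[:, cols]
        mg = zg.mean(axis=1)
        ss += ((zg - mg[:, None]) ** 2).sum(axis=1)
        dof += cols.sum() - 1
        means.append(mg)
    pooled_var = ss / max(dof, 1)
    base_mean = np.mean(means, axis=0)
    inv_sf = np.mean(1.0 / sf)
    with np.errstate(divide="ignore", invalid="ignore"):
        mom = (pooled_var - base_mean * inv_sf) / base_mean**2
    mom = np.where(np.isfinite(mom), mom, 0.0)

    # parametric trend a0 + a1/mean, fit on the raw (possibly negative)
    # moment estimates so clipping cannot bias the trend upward; weighted by
    # the approximate precision of each moment estimate (low-mean genes have
    # enormous MoM variance and would otherwise dominate the fit)
    usable = base_mean > 0
    if usable.sum() >= 10:
        m = base_mean[usable]
        x = np.column_stack([np.ones(m.size), 1.0 / m])
        target = mom[usable]
        trend_vals = np.full_like(target, max(float(np.median(target)), 0.0))
        for _ in range(2):
            rel_var = inv_sf / m + np.clip(trend_vals, 0.0, None)
            w = 1.0 / rel_var**2
            xw = x * w[:, None]
            coef, *_ = np.linalg.lstsq(
                xw.T @ x, xw.T @ target, rcond=None
            )
            a0, a1 = np.clip(coef, 0.0, None)
            trend_vals = a0 + a1 / m
        with np.errstate(divide="ignore"):
            trend = a0 + a1 / np.maximum(base_mean, 1e-12)
    else:
        trend = np.full_like(mom, max(np.median(mom), 0.0) if mom.size else 0.1)
    shrunk = 0.5 * mom + 0.5 * trend
    return np.clip(shrunk, DISPERSION_FLOOR, None)


def nb_de(
    pb: PseudobulkMatrix,
    contrast: tuple[Sequence[str], Sequence[str]],
    alpha: float = 0.05,
    lfc_threshold: float = 0.2,
) -> pd.DataFrame:
    """Two-group NB Wald test; log2FC is group B over group A.

    Returns one row per gene: ``gene_id, base_mean, log2fc, se, stat,
    pvalue, padj, tested, passed``. Genes with zero counts in every sample
    of both groups are excluded before Benjamini-Hochberg correction.
    ``passed`` requires adjusted p < alpha and |log2FC| >= lfc_threshold.
    """
    group_a, group_b = contrast
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each contrast group needs at least 2 samples")
    cols_a = pb.columns_for(group_a)
    cols_b = pb.columns_for(group_b)
    cols = np.concatenate([cols_a, cols_b])
    y = pb.counts[:, cols].astype(float)
    groups = np.array([0] * len(cols_a) + [1] * len(cols_b))

    sf = size_factors(y) if y.any() else np.ones(len(cols))
    disp = estimate_dispersions(y, sf, groups)

    n_genes = y.shape[0]
    log2fc = np.zeros(n_genes)
    se = np.full(n_genes, np.nan)
    stat = np.full(n_genes, np.nan)
    pval = np.full(n_genes, np.nan)
    tested = y.sum(axis=1) > 0
    base_mean = (y / sf[None, :]).mean(axis=1)

    sf_a, sf_b = sf[groups == 0], sf[groups == 1]
    ln2 = np.log(2.0)
    for gi in np.flatnonzero(tested):
        ya, yb = y[gi, groups == 0], y[gi, groups == 1]
        m_a, i_a = _fit_group_mean(ya, sf_a, disp[gi])
        m_b, i_b = _fit_group_mean(yb, sf_b, disp[gi])
        if m_a == 0.0 or m_b == 0.0:
            # all-zero group: pseudocount guard on normalized means
            q_a = np.mean(ya / sf_a) + 0.5
            q_b = np.mean(yb / sf_b) + 0.5
            log2fc[gi] = np.log2(q_b / q_a)
            i_a = max(i_a, 0.5)
            i_b = max(i_b, 0.5)
        else:
            log2fc[gi] = np.log2(m_b / m_a)
        var_beta = 1.0 / i_a + 1.0 / i_b
        se[gi] = np.sqrt(var_beta) / ln2
        stat[gi] = log2fc[gi] / se[gi]
        pval[gi] = 2.0 * stats.norm.sf(abs(stat[gi]))

    padj = np.full(n_genes, np.nan)
    if tested.any():
        padj[tested] = multipletests(pval[tested], method="fdr_bh")[1]
    with np.errstate(invalid="ignore"):
        passed = tested & np.array(
            [passes_thresholds(q, l, alpha, lfc_threshold)
             for q, l in zip(padj, log2fc)]
        )

    return pd.DataFrame(
        {
            "gene_id": pb.gene_ids,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "stat": stat,
            "pvalue": pval,
            "padj": padj,
            "tested": tested,
            "passed": passed,
        }
    )


def de_between_timepoints(
    cells: CellCountMatrix,
    t_a: float,
    t_b: float,
    cell_type: str | None = None,
    alpha: float = 0.05,
    lfc_threshold: float = 0.2,
) -> pd.DataFrame:
    """Aggregate per sample and run :func:`nb_de` between two timepoints."""
    ccm = cells
    if cell_type is not None:
        ccm = ccm.subset_cells(
            (ccm.cells["cell_type"] == cell_type).to_numpy()
        )
    pb = aggregate_pseudobulk(ccm, group_keys=["sample"])
    tp = pb.design["timepoint_hours"].to_numpy()
    group_a = pb.sample_ids[tp == t_a]
    group_b = pb.sample_ids[tp == t_b]
    return nb_de(pb, (list(group_a), list(group_b)), alpha, lfc_threshold)


def count_degs_per_celltype(
    cells: CellCountMatrix,
    t_a: float,
    t_b: float,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """DEG count between two timepoints for each sufficiently abundant type.

    Cell types with fewer than ``min_cells_per_timepoint`` cells at either
    timepoint are excluded and reported with a reason.
    """
    config = config or PipelineConfig()
    meta = cells.cells
    rows = []
    for ct in sorted(meta["cell_type"].unique()):
        n_a = int(((meta["cell_type"] == ct)
                   & (meta["timepoint_hours"] == t_a)).sum())
        n_b = int(((meta["cell_type"] == ct)
                   & (meta["timepoint_hours"] == t_b)).sum())
        if min(n_a, n_b) < config.min_cells_per_timepoint:
            rows.append(
                {
                    "cell_type": ct, "n_cells_a": n_a, "n_cells_b": n_b,
                    "included": False,
                    "reason": f"<{config.min_cells_per_timepoint} cells at a timepoint",
                    "n_deg": pd.NA,
                }
            )
            continue
        res = de_between_timepoints(
            cells, t_a, t_b, cell_type=ct,
            alpha=config.alpha, lfc_threshold=config.lfc_pseudobulk,
        )
        rows.append(
            {
                "cell_type": ct, "n_cells_a": n_a, "n_cells_b": n_b,
                "included": True, "reason": "",
                "n_deg": int(res["passed"].sum()),
            }
        )
    logger.debug("DEG counts over %d cell types", len(rows))
    return pd.DataFrame(rows)


def min_detectable_lfc(
    n_per_group: int,
    variance_log2: float,
    alpha: float = 0.05,
    power_target: float = 0.8,
) -> float:
    """Smallest |log2FC| detectable by a two-sided two-sample t-test.

    Power is computed from the noncentral t distribution with
    ``df = 2n - 2`` and noncentrality ``delta / sqrt(2*var/n)``; the
    equation power(delta) = power_target is solved by bisection to 1e-6.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if variance_log2 <= 0:
        raise ValueError("variance_log2 must be > 0")
    if not alpha < power_target < 1.0:
        raise ValueError("power_target must lie in (alpha, 1)")

    df = 2 * n_per_group - 2
    se = np.sqrt(2.0 * variance_log2 / n_per_group)
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)

    def power(delta: float) -> float:
        ncp = delta / se
        return float(
            stats.nct.sf(t_crit, df, ncp) + stats.nct.cdf(-t_crit, df, ncp)
        )

    lo, hi = 0.0, se
    while power(hi) < power_target:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("power target unreachable")
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        if power(mid) < power_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def lfc_to_percent(lfc: float, rounded: bool = False) -> float:
    """Percent change implied by a log2 fold change: ``100*(2^|lfc| - 1)``.

    With ``rounded=True`` the result is rounded to the nearest multiple of 5.
    """
    pct = 100.0 * (2.0 ** abs(lfc) - 1.0)
    if rounded:
        return 5.0 * round(pct / 5.0)
    return pct
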