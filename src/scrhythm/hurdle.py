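"""Cell-level differential expression with a two-part hurdle model.

Each gene is modelled in two parts: a ridge-penalized logistic regression of
detection (count > 0) on the design plus the standardized cellular detection
rate (CDR), and an ordinary least-squares model of log2(1 + normalized
count) among detected cells on the same covariates. Per-timepoint "shift"
contrasts compare each timepoint against the pooled remaining timepoints
(one-vs-rest) with a 2-df likelihood-ratio test; the peak-and-trough filter
then calls a gene rhythmic when at least two timepoints show significant
shifts, at least one positive and one negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from scrhythm.io import CellCountMatrix, PipelineConfig, logger

RIDGE = 1e-4
MIN_DETECTED = 3


def compute_cdr(cells: CellCountMatrix, scale: bool = True) -> np.ndarray:
    """Cellular detection rate: fraction of genes detected per cell.

    With ``scale=True`` the CDR is centered and scaled to unit variance
    across the cells of the matrix. A single cell raises; zero variance
    falls back to an all-zero covariate with a warning (effectively dropping
    it from any design).
    """
    if cells.n_cells == 0:
        raise ValueError("empty matrix")
    detected = (cells.counts > 0).sum(axis=0)
    cdr = np.asarray(detected).ravel() / cells.n_genes
    if not scale:
        return cdr
    if cells.n_cells < 2:
        raise ValueError("cannot scale CDR for a single cell")
    sd = cdr.std()
    if sd == 0:
        warnings.warn("CDR has zero variance; covariate dropped", RuntimeWarning)
        return np.zeros_like(cdr)
    return (cdr - cdr.mean()) / sd


def normalized_log_expression(cells: CellCountMatrix) -> np.ndarray:
    """Dense log2(1 + counts scaled to the median library size)."""
    lib = np.asarray(cells.counts.sum(axis=0)).ravel().astype(float)
    lib[lib == 0] = 1.0
    target = np.median(lib)
    dense = np.asarray(cells.counts.todense(), dtype=float)
    return np.log2(1.0 + dense * (target / lib)[None, :])


# ---------------------------------------------------------------------------
# per-gene fits
# ---------------------------------------------------------------------------

def _logistic_ridge(
    X: np.ndarray, y: np.ndarray, ridge: float = RIDGE,
    max_iter: int = 100, tol: float = 1e-8,
) -> tuple[np.ndarray, float, bool]:
    """IRLS for logistic regression with a ridge penalty on non-intercept terms.

    Returns (coefficients, penalized log-likelihood, converged).
    """
    n, p = X.shape
    pen = np.full(p, ridge)
    pen[0] = 0.0  # intercept unpenalized
    beta = np.zeros(p)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = X.T @ (y - mu) - pen * beta
        hess = (X * w[:, None]).T @ X + np.diag(pen)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        eta = np.clip(X @ beta, -30, 30)
        ll = float(
            np.sum(y * eta - np.log1p(np.exp(eta))) - 0.5 * np.sum(pen * beta**2)
        )
        if abs(ll - ll_old) < tol:
            converged = True
            ll_old = ll
            break
        ll_old = ll
    return beta, ll_old, converged


def _gaussian_ll(rss: float, n: int) -> float:
    """Profile log-likelihood of an OLS fit at the MLE variance."""
    if n == 0:
        return 0.0
    sigma2 = max(rss / n, 1e-12)
    return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + rss / (n * sigma2))


@dataclass
class HurdleFit:
    """Fitted two-part model for one gene on one design matrix."""

    coef_discrete: np.ndarray
    coef_continuous: np.ndarray
    ll_discrete: float
    ll_continuous: float
    rss: float
    n_detected: int
    converged: bool
    degenerate: bool

    @property
    def loglik(self) -> float:
        return self.ll_discrete + self.ll_continuous


def fit_hurdle(
    counts: np.ndarray,
    log_expr: np.ndarray,
    X: np.ndarray,
) -> HurdleFit:
    """Fit the two-part hurdle model for a single gene.

    ``counts`` are raw per-cell counts (detection indicator source),
    ``log_expr`` the matching log2(1+normalized) values, and ``X`` the
    design matrix (first column must be the intercept).
    """
    detected = counts > 0
    n_det = int(detected.sum())
    if n_det < MIN_DETECTED:
        raise ValueError(f"only {n_det} detected cells (< {MIN_DETECTED})")
    beta_d, ll_d, conv = _logistic_ridge(X, detected.astype(float))

    Xd = X[detected]
    yd = log_expr[detected]
    coef_c, _, rank, _ = np.linalg.lstsq(Xd, yd, rcond=None)
    resid = yd - Xd @ coef_c
    rss = float(resid @ resid)
    degenerate = rss <= 1e-12 or rank < Xd.shape[1]
    ll_c = 0.0 if degenerate else _gaussian_ll(rss, n_det)
    return HurdleFit(
        coef_discrete=beta_d,
        coef_continuous=coef_c,
        ll_discrete=ll_d,
        ll_continuous=ll_c,
        rss=rss,
        n_detected=n_det,
        converged=conv,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# shift contrasts and the rhythmicity filter
# ---------------------------------------------------------------------------

def _combined_mean(fit: HurdleFit, x_row: np.ndarray) -> float:
    """Model-implied expected log2 expression at one covariate setting.

    Expected value of the hurdle: detection probability times the
    continuous-part mean.
    """
    eta = float(np.clip(x_row @ fit.coef_discrete, -30, 30))
    p_det = 1.0 / (1.0 + np.exp(-eta))
    return p_det * float(x_row @ fit.coef_continuous)


def timepoint_shift_contrasts(
    cells: CellCountMatrix,
    config: PipelineConfig | None = None,
    genes: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene, per-timepoint shift from the average of the other timepoints.

    For each timepoint tau the full model adds a one-vs-rest indicator
    1{t = tau} to an intercept + CDR design; the reduced model drops it from
    both hurdle components, giving a likelihood-ratio test with df = 2. The
    shift log2FC is the model-implied mean at tau minus the pooled mean of
    the remaining timepoints, evaluated at the average CDR. BH correction is
    applied jointly across all gene x timepoint tests.

    Genes failing the ``min_pct`` screen in every timepoint, or with fewer
    than 3 detected cells, are reported untested.
    """
    config = config or PipelineConfig()
    times = np.sort(cells.cells["timepoint_hours"].unique())
    if len(times) < 3:
        raise ValueError("shift contrasts need >= 3 distinct timepoints")
    tp = cells.cells["timepoint_hours"].to_numpy()
    cdr = compute_cdr(cells)
    log_expr_all = normalized_log_expression(cells)
    counts_all = np.asarray(cells.counts.todense())
    gene_idx = (
        np.arange(cells.n_genes) if genes is None else cells.gene_index(genes)
    )

    n_cells = cells.n_cells
    X_reduced = np.column_stack([np.ones(n_cells), cdr])
    rows = []
    for gi in gene_idx:
        gene = cells.gene_ids[gi]
        counts = counts_all[gi]
        log_expr = log_expr_all[gi]
        detected = counts > 0
        pct_by_tp = {t: detected[tp == t].mean() for t in times}
        if max(pct_by_tp.values()) < config.min_pct:
            rows.append(_untested_row(gene, times, "min_pct"))
            continue
        if detected.sum() < MIN_DETECTED:
            rows.append(_untested_row(gene, times, "too_few_detected"))
            continue
        try:
            reduced = fit_hurdle(counts, log_expr, X_reduced)
        except ValueError:
            rows.append(_untested_row(gene, times, "fit_failure"))
            continue
        for t in times:
            focal = tp == t
            if not focal.any():
                continue
            X_full = np.column_stack(
                [np.ones(n_cells), focal.astype(float), cdr]
            )
            full = fit_hurdle(counts, log_expr, X_full)
            d_ll = full.ll_discrete - reduced.ll_discrete
            if full.degenerate or reduced.degenerate:
                c_ll = 0.0
            else:
                c_ll = full.ll_continuous - reduced.ll_continuous
            lrt = max(0.0, 2.0 * (d_ll + c_ll))
            pval = float(stats.chi2.sf(lrt, 2))
            at_tau = np.array([1.0, 1.0, 0.0])
            at_rest = np.array([1.0, 0.0, 0.0])
            shift = _combined_mean(full, at_tau) - _combined_mean(full, at_rest)
            rows.append(
                {
                    "gene_id": gene,
                    "timepoint": t,
                    "tested": True,
                    "reason": "",
                    "shift_lfc": shift,
                    "stat": lrt,
                    "df": 2,
                    "pvalue": pval,
                    "pct_in": float(detected[focal].mean()),
                    "pct_out": float(detected[~focal].mean()),
                }
            )
    result = pd.DataFrame(rows) if rows else _empty_contrast_frame()
    tested = result["tested"].to_numpy(bool)
    padj = np.full(len(result), np.nan)
    if tested.any():
        padj[tested] = multipletests(
            result.loc[tested, "pvalue"], method="fdr_bh"
        )[1]
    result["padj"] = padj
    logger.debug(
        "shift contrasts: %d tests over %d genes",
        int(tested.sum()), len(gene_idx),
    )
    return result


def _untested_row(gene: str, times: np.ndarray, reason: str) -> dict:
    return {
        "gene_id": gene, "timepoint": float(times[0]), "tested": False,
        "reason": reason, "shift_lfc": np.nan, "stat": np.nan, "df": 2,
        "pvalue": np.nan, "pct_in": np.nan, "pct_out": np.nan,
    }


def _empty_contrast_frame() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "gene_id", "timepoint", "tested", "reason", "shift_lfc",
            "stat", "df", "pvalue", "pct_in", "pct_out",
        ]
    )


def peak_trough_filter(
    contrasts: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Call genes rhythmic from their per-timepoint shift contrasts.

    A gene is rhythmic iff at least two timepoints are significant
    (adjusted p < alpha, |shift| >= lfc_cell, pct-expressing >= min_pct on
    either side) with at least one positive and one negative shift. The
    peak is the largest significant positive shift and the trough the most
    negative one; ties break toward the smaller timepoint.
    """
    config = config or PipelineConfig()
    rows = []
    for gene, sub in contrasts.groupby("gene_id", sort=True):
        tested = bool(sub["tested"].any())
        sig = sub[
            sub["tested"]
            & (sub["padj"] < config.alpha)
            & (sub["shift_lfc"].abs() >= config.lfc_cell)
            & (sub[["pct_in", "pct_out"]].max(axis=1) >= config.min_pct)
        ].sort_values("timepoint")
        pos = sig[sig["shift_lfc"] > 0]
        neg = sig[sig["shift_lfc"] < 0]
        rhythmic = tested and len(sig) >= 2 and len(pos) >= 1 and len(neg) >= 1
        peak = trough = np.nan
        if rhythmic:
            best = pos["shift_lfc"].max()
            peak = float(pos.loc[pos["shift_lfc"] == best, "timepoint"].min())
            worst = neg["shift_lfc"].min()
            trough = float(
                neg.loc[neg["shift_lfc"] == worst, "timepoint"].min()
            )
        rows.append(
            {
                "gene_id": gene,
                "tested": tested,
                "rhythmic": rhythmic,
                "n_significant": len(sig),
                "significant_timepoints": ",".join(
                    f"{t:g}{'+' if s > 0 else '-'}"
                    for t, s in zip(sig["timepoint"], sig["shift_lfc"])
                ),
                "peak_timepoint": peak,
                "trough_timepoint": trough,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "tested", "rhythmic", "n_significant",
            "significant_timepoints", "peak_timepoint", "trough_timepoint",
        ],
    )


def rhythm_call(
    cells: CellCountMatrix,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: shift contrasts followed by the rhythm filter."""
    contrasts = timepoint_shift_contrasts(cells, config)
    calls = peak_trough_filter(contrasts, config)
    return contrasts, calls


# ---------------------------------------------------------------------------
# Wilcoxon cross-check and marker calling
# ---------------------------------------------------------------------------

def wilcoxon_de(
    cells: CellCountMatrix,
    group_a: np.ndarray,
    group_b: np.ndarray,
    min_pct: float = 0.05,
    lfc_threshold: float = 0.2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test per gene on log-normalized values.

    Genes must be detected in at least ``min_pct`` of cells in one of the
    two groups to be tested. The p-value uses the exact null distribution
    for small tie-free samples and the tie-corrected normal approximation
    otherwise; log2FC is the difference of group means of log-normalized
    expression (B minus A).
    """
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if group_a.dtype == bool:
        group_a = np.flatnonzero(group_a)
    if group_b.dtype == bool:
        group_b = np.flatnonzero(group_b)
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    log_expr = normalized_log_expression(cells)
    counts = cells.counts
    det_a = np.asarray((counts[:, group_a] > 0).mean(axis=1)).ravel()
    det_b = np.asarray((counts[:, group_b] > 0).mean(axis=1)).ravel()
    tested = (det_a >= min_pct) | (det_b >= min_pct)

    n = cells.n_genes
    log2fc = np.full(n, np.nan)
    pval = np.full(n, np.nan)
    for gi in np.flatnonzero(tested):
        xa = log_expr[gi, group_a]
        xb = log_expr[gi, group_b]
        log2fc[gi] = xb.mean() - xa.mean()
        if np.all(xa == xa[0]) and np.all(xb == xb[0]) and xa[0] == xb[0]:
            pval[gi] = 1.0
            continue
        res = stats.mannwhitneyu(xb, xa, alternative="two-sided", method="auto")
        pval[gi] = float(res.pvalue)
    padj = np.full(n, np.nan)
    if tested.any():
        padj[tested] = multipletests(pval[tested], method="fdr_bh")[1]
    passed = tested & (padj < alpha) & (np.abs(log2fc) >= lfc_threshold)
    return pd.DataFrame(
        {
            "gene_id": cells.gene_ids,
            "pct_a": det_a,
            "pct_b": det_b,
            "log2fc": log2fc,
            "pvalue": pval,
            "padj": padj,
            "tested": tested,
            "passed": passed,
        }
    )


def find_markers(
    cells: CellCountMatrix,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon markers per cell type (0.25 / 0.405 thresholds)."""
    config = config or PipelineConfig()
    ct = cells.cells["cell_type"].to_numpy()
    frames = []
    for level in sorted(pd.unique(ct)):
        mask = ct == level
        res = wilcoxon_de(
            cells,
            group_a=~mask,
            group_b=mask,
            min_pct=config.marker_min_pct,
            lfc_threshold=config.marker_lfc,
            alpha=config.alpha,
        )
        res.insert(0, "cell_type", level)
        frames.append(res[res["passed"] & (res["log2fc"] > 0)])
    return pd.concat(frames, ignore_index=True)
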