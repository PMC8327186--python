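"""MAST-style two-part hurdle differential expression between genotypes.

Each gene is modelled in two parts: a logistic model of detection
(count > 0) and a Gaussian model of log2(1 + CP10K) on the detected cells,
both with genotype and a standardized log-UMI cellular-detection-rate (CDR)
covariate.  The test statistic is the sum of the two components'
likelihood-ratio statistics for dropping genotype, with degrees of freedom
equal to the number of non-degenerate components, referred to a chi-square
distribution.  The continuous part uses plain maximum likelihood (no
variance shrinkage); calibration is verified by simulation instead.

The entry points are the :class:`HurdleDE` model / :class:`HurdleDEResults`
pair and the functional wrapper :func:`run_de`.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .datatypes import CountMatrix, PipelineConfig, ValidationError

log = logging.getLogger(__name__)

__all__ = ["compute_cdr", "fit_hurdle_gene", "run_de", "HurdleDE", "HurdleDEResults"]

_CLAMP = 1e-8


def compute_cdr(cells: pd.DataFrame, focal: set) -> pd.Series:
    """Standardized log total-UMI count per focal cell (mean 0, sd 1).

    Serves as the cellular-detection-rate confounder; raises when the UMI
    counts are constant (suggest disabling the covariate instead).
    """
    if not focal:
        raise ValidationError("focal cell set is empty")
    sub = cells[cells["cell_id"].isin(focal)]
    logs = np.log(sub["n_umis"].to_numpy(dtype=float))
    sd = logs.std(ddof=0)
    if sd < 1e-12:
        raise ValidationError(
            "all focal cells have identical UMI totals; disable the CDR covariate"
        )
    vals = (logs - logs.mean()) / sd
    return pd.Series(vals, index=sub["cell_id"], name="cdr")


def _logistic_loglik(X: np.ndarray, y: np.ndarray, max_iter: int = 60) -> float:
    """Maximized Bernoulli log-likelihood by Newton iterations with
    probability clamping; never raises on perfect separation."""
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.clip(expit(eta), _CLAMP, 1 - _CLAMP)
        ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
        if ll - ll_old < 1e-10 and ll_old > -np.inf:
            break
        ll_old = ll
        w = mu * (1 - mu)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess + 1e-10 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            break
        # dampen huge steps that arise under separation
        norm = np.linalg.norm(step)
        if norm > 30:
            step *= 30 / norm
        beta = beta + step
    eta = X @ beta
    mu = np.clip(expit(eta), _CLAMP, 1 - _CLAMP)
    return float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))


def _gaussian_lrt(X_full: np.ndarray, X_red: np.ndarray, y: np.ndarray) -> float:
    """Gaussian ML likelihood-ratio statistic: n * log(RSS0 / RSS1)."""
    n = len(y)
    rss_full = float(np.sum((y - X_full @ np.linalg.lstsq(X_full, y, rcond=None)[0]) ** 2))
    rss_red = float(np.sum((y - X_red @ np.linalg.lstsq(X_red, y, rcond=None)[0]) ** 2))
    if rss_full <= 0 or rss_red <= 0:
        return 0.0
    return max(0.0, n * np.log(rss_red / rss_full))


def fit_hurdle_gene(
    expr: np.ndarray,
    detected: np.ndarray,
    genotype: np.ndarray,
    cdr: np.ndarray | None,
):
    """Two-part hurdle test for one gene; returns (lr_stat, df, pvalue).

    ``expr`` is log2(1+CP10K), ``detected`` boolean, ``genotype`` a 0/1
    indicator (1 = KO), ``cdr`` the standardized covariate or None.
    A component is degenerate (contributes 0 with df reduced) when detection
    is constant, or when fewer than 3 cells are detected for the continuous
    part; both degenerate gives p = 1.
    """
    expr = np.asarray(expr, dtype=float)
    detected = np.asarray(detected, dtype=float)
    genotype = np.asarray(genotype, dtype=float)
    if expr.shape != detected.shape:
        raise ValidationError("expression and detection vectors differ in length")
    n = len(expr)
    cols = [np.ones(n), genotype]
    if cdr is not None:
        cols.append(np.asarray(cdr, dtype=float))
    X_full = np.column_stack(cols)
    X_red = np.delete(X_full, 1, axis=1)

    lr = 0.0
    df = 0
    # discrete component
    if 0 < detected.sum() < n:
        ll_full = _logistic_loglik(X_full, detected)
        ll_red = _logistic_loglik(X_red, detected)
        lr += max(0.0, 2.0 * (ll_full - ll_red))
        df += 1
    # continuous component on detected cells
    mask = detected > 0
    if mask.sum() >= 3 and len(np.unique(genotype[mask])) > 1:
        lr += _gaussian_lrt(X_full[mask], X_red[mask], expr[mask])
        df += 1
    if df == 0:
        return 0.0, 0, 1.0
    return lr, df, float(chi2.sf(lr, df))


class HurdleDE:
    """Hurdle differential-expression model over the focal cell population.

    Parameters
    ----------
    counts : CountMatrix
        Filtered genes x cells counts.
    cells : DataFrame
        Cell table with sample_id / genotype / n_umis populated.
    focal : set
        Cell ids to test (must span both genotypes).
    config : PipelineConfig
    """

    def __init__(self, counts: CountMatrix, cells: pd.DataFrame, focal: set,
                 config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()
        focal_order = [c for c in counts.cell_ids if c in focal]
        if not focal_order:
            raise ValidationError("focal cell set is empty")
        self.counts = counts.subset(cells=focal_order)
        self.cells = cells.loc[focal_order]
        genos = set(self.cells["genotype"])
        if genos != {"WT", "KO"}:
            raise ValidationError(f"focal set must span both genotypes, found {sorted(genos)}")
        self.genotype = (self.cells["genotype"] == "KO").to_numpy(dtype=float)
        if self.config.use_cdr:
            self.cdr = compute_cdr(self.cells, set(focal_order)).loc[focal_order].to_numpy()
        else:
            self.cdr = None

    def fit(self) -> "HurdleDEResults":
        counts = self.counts
        cfg = self.config
        totals = counts.cell_totals().astype(float)
        x = counts.values.tocsr().astype(float) @ sp.diags(1e4 / totals)
        x = x.tocsr()
        x.data = np.log2(1.0 + x.data)

        ko = self.genotype > 0
        wt = ~ko
        rows = []
        if counts.n_genes == 0:
            log.warning("no genes retained; empty DE result")
        for i in range(counts.n_genes):
            expr = np.asarray(x[i].todense()).ravel()
            raw = np.asarray(counts.values[i].todense()).ravel()
            detected = raw > 0
            lr, df, p = fit_hurdle_gene(expr, detected, self.genotype, self.cdr)
            rows.append(
                {
                    "gene_id": counts.gene_ids[i],
                    "symbol": counts.gene_symbols[i],
                    "log2fc": float(expr[ko].mean() - expr[wt].mean()),
                    "lr_stat": lr,
                    "df": df,
                    "pvalue": p,
                    "pct_expr_wt": float(detected[wt].mean()),
                    "pct_expr_ko": float(detected[ko].mean()),
                }
            )
        table = pd.DataFrame(rows)
        if len(table):
            table["fdr"] = multipletests(table["pvalue"], method="fdr_bh")[1]
            table["is_de"] = (table["fdr"] < cfg.de_fdr) & (
                table["log2fc"].abs() > cfg.de_min_abs_log2fc
            )
        else:
            table["fdr"] = pd.Series(dtype=float)
            table["is_de"] = pd.Series(dtype=bool)
        return HurdleDEResults(table=table, model=self)


class HurdleDEResults:
    """Per-gene hurdle-test results with BH-adjusted significance calls."""

    def __init__(self, table: pd.DataFrame, model: HurdleDE | None = None):
        self.table = table
        self.model = model

    @property
    def degs(self) -> list:
        """Gene ids called differentially expressed at the configured
        FDR and fold-change thresholds."""
        if not len(self.table):
            return []
        return sorted(self.table.loc[self.table["is_de"], "gene_id"])

    def summary(self) -> str:
        t = self.table
        n_up = int(((t["is_de"]) & (t["log2fc"] > 0)).sum()) if len(t) else 0
        n_dn = int(((t["is_de"]) & (t["log2fc"] < 0)).sum()) if len(t) else 0
        lines = [
            "Hurdle differential expression (KO vs WT)",
            f"  genes tested: {len(t)}",
            f"  DEGs: {n_up + n_dn} ({n_up} up, {n_dn} down in KO)",
        ]
        if len(t):
            top = t.sort_values(["fdr", "gene_id"]).head(10)
            lines.append("  top genes (fdr, log2fc):")
            for _, r in top.iterrows():
                lines.append(f"    {r.gene_id:>12s}  fdr={r.fdr:.3g}  log2fc={r.log2fc:+.3f}")
        return "\n".join(lines)


def run_de(counts: CountMatrix, cells: pd.DataFrame, focal: set, cfg: PipelineConfig) -> pd.DataFrame:
    """Fit the hurdle model to every retained gene; returns the DE table."""
    return HurdleDE(counts, cells, focal, cfg).fit().table
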