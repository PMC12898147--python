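"""Per-drug differential expression between resistant and sensitive cell lines.

The test is a negative-binomial Wald procedure in the DESeq2 mould, specified
completely here so it is testable from first principles:

* library-size normalization by the median-of-ratios method;
* per-gene NB dispersion ``alpha`` by method-of-moments on normalized counts
  (variance model ``Var = mu + alpha * mu^2``), floored at 1e-8 and capped
  at 10;
* a per-gene NB GLM with log link, design = resistant-label indicator and
  size-factor offsets, fitted by iteratively reweighted least squares
  (closed-form 2x2 solve, vectorized across genes);
* two-sided normal Wald p-value on the label coefficient.

No independent filtering, fold-change shrinkage, or outlier handling is
applied. A gene is called differentially expressed iff
``|log2FoldChange| >= lfc_min`` (inclusive) and ``padj < padj_max`` (strict),
with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .types import ExpressionMatrix, ResistomeError, SensitivityTable

log = logging.getLogger(__name__)

_LN2 = np.log(2.0)
_BETA1_MAX = 15.0  # natural-log scale; |log2FC| cap ~21.6
_ALPHA_FLOOR = 1e-8
_ALPHA_CAP = 10.0


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors.

    Parameters
    ----------
    counts : array, shape (n_samples, n_genes)

    Returns
    -------
    array of positive per-sample factors.

    Genes with any zero count are excluded from the reference geometric
    means; if no gene has all-positive counts the routine falls back to
    library-size scaling (logged).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ResistomeError("counts must be 2-D (samples x genes)")
    if not np.any(counts > 0):
        raise ResistomeError("all-zero count matrix: size factors undefined")
    allpos = np.all(counts > 0, axis=0)
    if not np.any(allpos):
        log.warning("size_factors: no gene with all-positive counts; "
                    "falling back to library-size scaling")
        lib = counts.sum(axis=1)
        if np.any(lib == 0):
            raise ResistomeError("sample with zero library size")
        return lib / stats.gmean(lib)
    ref = counts[:, allpos]
    log_geo = np.mean(np.log(ref), axis=0)
    factors = np.exp(np.median(np.log(ref) - log_geo, axis=1))
    return factors


def estimate_dispersion(counts: np.ndarray, labels: np.ndarray,
                        sf: np.ndarray) -> np.ndarray:
    """Method-of-moments per-gene NB dispersion on normalized counts.

    Within each label group, ``Var(q) ~= mu * mean(1/s) + alpha * mu^2``;
    the group estimates are combined weighted by degrees of freedom, then
    floored at 1e-8 and capped at 10.
    """
    q = np.asarray(counts, dtype=float) / sf[:, None]
    labels = np.asarray(labels)
    n_genes = q.shape[1]
    num = np.zeros(n_genes)
    den = np.zeros(n_genes)
    for lab in (0, 1):
        grp = q[labels == lab]
        inv_s = np.mean(1.0 / sf[labels == lab])
        n_g = grp.shape[0]
        if n_g < 2:
            continue
        mu = grp.mean(axis=0)
        var = grp.var(axis=0, ddof=1)
        ok = mu > 0
        a = np.zeros(n_genes)
        a[ok] = (var[ok] - mu[ok] * inv_s) / mu[ok] ** 2
        w = np.where(ok, n_g - 1.0, 0.0)
        num += w * a
        den += w
    alpha = np.divide(num, den, out=np.zeros(n_genes), where=den > 0)
    return np.clip(alpha, _ALPHA_FLOOR, _ALPHA_CAP)


def _nb_wald_matrix(counts: np.ndarray, labels: np.ndarray, sf: np.ndarray,
                    alpha: np.ndarray, maxiter: int = 50,
                    tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized NB-GLM Wald test for all genes at once.

    Returns (log2FoldChange, wald_p, standard_error_log2) arrays.
    """
    Y = np.asarray(counts, dtype=float)
    x = np.asarray(labels, dtype=float)
    if set(np.unique(x)) - {0.0, 1.0}:
        raise ResistomeError("labels must be binary 0/1")
    if np.all(x == x[0]):
        raise ResistomeError("single-class input: both labels required")
    n, n_genes = Y.shape
    s = np.asarray(sf, dtype=float)
    log_s = np.log(s)

    q = Y / s[:, None]
    eps = 1e-8
    m0 = q[x == 0].mean(axis=0)
    m1 = q[x == 1].mean(axis=0)
    beta0 = np.log(np.maximum(m0, eps))
    beta1 = np.clip(np.log(np.maximum(m1, eps)) - beta0, -_BETA1_MAX, _BETA1_MAX)

    xm = x[:, None]
    for _ in range(maxiter):
        eta = beta0[None, :] + beta1[None, :] * xm + log_s[:, None]
        mu = np.clip(np.exp(np.clip(eta, -30.0, 30.0)), 1e-10, 1e12)
        w = mu / (1.0 + alpha[None, :] * mu)
        z = (eta - log_s[:, None]) + (Y - mu) / mu
        A = w.sum(axis=0)
        B = (w * xm).sum(axis=0)
        u = (w * z).sum(axis=0)
        v = (w * xm * z).sum(axis=0)
        denom0 = np.maximum(A - B, 1e-12)
        new_b0 = (u - v) / denom0
        new_b1 = v / np.maximum(B, 1e-12) - new_b0
        new_b0 = np.clip(new_b0, -30.0, 30.0)
        new_b1 = np.clip(new_b1, -_BETA1_MAX, _BETA1_MAX)
        delta = np.maximum(np.abs(new_b0 - beta0), np.abs(new_b1 - beta1))
        beta0, beta1 = new_b0, new_b1
        if np.max(delta) < tol:
            break

    eta = beta0[None, :] + beta1[None, :] * xm + log_s[:, None]
    mu = np.clip(np.exp(np.clip(eta, -30.0, 30.0)), 1e-10, 1e12)
    w = mu / (1.0 + alpha[None, :] * mu)
    B = (w * xm).sum(axis=0)
    A0 = w.sum(axis=0) - B
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(1.0 / B + 1.0 / A0)
    wald_z = np.where(np.isfinite(se) & (se > 0), beta1 / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(wald_z))

    all_zero = Y.sum(axis=0) == 0
    lfc = beta1 / _LN2
    lfc[all_zero] = 0.0
    p[all_zero] = 1.0
    se_l2 = se / _LN2
    return lfc, np.clip(p, 0.0, 1.0), se_l2


def nb_wald_test(counts_gene: np.ndarray, labels: np.ndarray, sf: np.ndarray,
                 dispersion_estimate: float) -> tuple[float, float]:
    """Single-gene NB Wald test: returns (log2FoldChange, two-sided p)."""
    labels = np.asarray(labels)
    for lab in (0, 1):
        if np.sum(labels == lab) < 2:
            raise ResistomeError("need at least 2 samples per label")
    lfc, p, _ = _nb_wald_matrix(
        np.asarray(counts_gene, dtype=float).reshape(-1, 1),
        labels, np.asarray(sf, dtype=float),
        np.array([float(dispersion_estimate)]),
    )
    return float(lfc[0]), float(p[0])


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``padj_(i) = min_{j >= i} (m/j) p_(j)``, clipped at 1, where ``p_(j)``
    are the sorted raw p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ResistomeError("p-values must be 1-D")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ResistomeError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def call_degs(lfc: np.ndarray, padj: np.ndarray, lfc_min: float = 1.0,
              padj_max: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Significance flags and signed directions for a fitted DEG table.

    ``significant`` iff ``|lfc| >= lfc_min`` (inclusive) and
    ``padj < padj_max`` (strict). Direction is the sign of the fold change.
    """
    lfc = np.asarray(lfc, dtype=float)
    padj = np.asarray(padj, dtype=float)
    sig = (np.abs(lfc) >= lfc_min) & (padj < padj_max)
    direction = np.sign(lfc).astype(int)
    return sig, direction


def log_z_transform(counts: np.ndarray) -> np.ndarray:
    """log2(x + 1) then per-gene z-score across cell lines.

    Rows are cell lines, columns genes; constant genes map to all-zero
    columns (guarded division).
    """
    y = np.log2(np.asarray(counts, dtype=float) + 1.0)
    mean = y.mean(axis=0)
    sd = y.std(axis=0)
    out = np.zeros_like(y)
    ok = sd > 0
    out[:, ok] = (y[:, ok] - mean[ok]) / sd[ok]
    return out


def run_de(expr: ExpressionMatrix, sens: SensitivityTable, drug: str,
           config: RunConfig | None = None) -> pd.DataFrame:
    """Resistant-vs-sensitive differential expression for one drug.

    Cell lines lacking either expression or a sensitivity record for the
    drug are dropped (logged). Returns a DataFrame with columns
    ``gene, baseMean, log2FoldChange, pvalue, padj, significant, direction``
    and ``df.attrs['drug']`` set.
    """
    config = config or RunConfig()
    recs = sens.for_drug(drug)
    present = [c for c in expr.cell_line_ids if c in set(recs["cell_line"])]
    n_drop = expr.n_cell_lines - len(present)
    if n_drop:
        log.info("run_de[%s]: dropped %d cell line(s) without sensitivity", drug, n_drop)
    if len(present) < 4:
        raise ResistomeError(f"drug {drug!r}: fewer than 4 usable cell lines")
    idx = expr.cell_index(present)
    counts = expr.counts[idx]
    labels = sens.labels_for(drug, present)
    for lab, name in ((0, "sensitive"), (1, "resistant")):
        if np.sum(labels == lab) < 2:
            raise ResistomeError(f"drug {drug!r}: fewer than 2 {name} cell lines")

    sf = size_factors(counts)
    alpha = estimate_dispersion(counts, labels, sf)
    lfc, p, _ = _nb_wald_matrix(counts, labels, sf, alpha)
    padj = bh_adjust(p)
    sig, direction = call_degs(lfc, padj, config.lfc_min, config.padj_max)
    base_mean = (counts / sf[:, None]).mean(axis=0)
    df = pd.DataFrame({
        "gene": expr.gene_ids,
        "baseMean": base_mean,
        "log2FoldChange": lfc,
        "pvalue": p,
        "padj": padj,
        "significant": sig,
        "direction": direction,
    })
    df.attrs["drug"] = drug
    return df


def deg_gene_set(deg_table: pd.DataFrame) -> set:
    """The set of significant genes of one per-drug DEG table."""
    return set(deg_table.loc[deg_table["significant"], "gene"])
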