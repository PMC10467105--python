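"""Differential-expression signatures from count matrices.

A deliberately simple negative-binomial Wald procedure: median-of-ratios
size factors, gene-wise method-of-moments dispersion, a delta-method Wald
statistic on the log2 fold change, a normal reference distribution and
Benjamini-Hochberg FDR control.  Any method producing disjoint up/down gene
lists can substitute for this stage.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from sigconn.errors import DataError
from sigconn.io import CountMatrix, QuerySignature

logger = logging.getLogger(__name__)

LN2_SQ = np.log(2.0) ** 2
DISPERSION_FLOOR = 1e-8
PSEUDOCOUNT = 0.5


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    The pseudo-reference is the per-gene geometric mean over samples,
    restricted to genes with nonzero counts in every sample; each sample's
    factor is the median ratio of its counts to that reference.
    """
    counts = cm.counts.to_numpy(dtype=float)
    all_nonzero = (counts > 0).all(axis=1)
    if not all_nonzero.any():
        raise DataError(
            "no gene has nonzero counts in all samples; size factors undefined "
            "(consider a pseudo-reference fallback)"
        )
    ref = counts[all_nonzero]
    log_geomean = np.mean(np.log(ref), axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=cm.counts.columns, name="size_factor")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise DataError("p must be a 1-D array")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _mom_dispersion(norm: np.ndarray, groups: list[np.ndarray], inv_sf: np.ndarray) -> np.ndarray:
    """Per-gene NB dispersion by method of moments on normalized counts.

    For normalized counts q = K/s, Var(q) ~= mu * (1/s) + alpha * mu**2, so
    within each group alpha is estimated from the excess of the sample
    variance over the Poisson term, then pooled across groups weighted by
    degrees of freedom.
    """
    n_genes = norm.shape[0]
    num = np.zeros(n_genes)
    den = 0.0
    for idx in groups:
        q = norm[:, idx]
        n = len(idx)
        if n < 2:
            continue
        mu = q.mean(axis=1)
        var = q.var(axis=1, ddof=1)
        mean_inv_s = inv_sf[idx].mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_g = (var - mu * mean_inv_s) / np.square(mu)
        alpha_g = np.where(np.isfinite(alpha_g), alpha_g, 0.0)
        num += (n - 1) * alpha_g
        den += n - 1
    alpha = num / den
    return np.clip(alpha, DISPERSION_FLOOR, None)


def build_signature(
    cm: CountMatrix,
    treated: list[str],
    controls: list[str],
    alpha: float = 0.05,
    query_id: str | None = None,
) -> tuple[QuerySignature, pd.DataFrame]:
    """NB-Wald differential expression; returns the signature and gene stats.

    Genes with all-zero counts are excluded before testing.  The returned
    table is indexed by gene with columns ``base_mean``, ``log2fc``, ``wald``,
    ``p``, ``p_adj``; the signature holds genes with ``p_adj < alpha`` split
    by the sign of the fold change.
    """
    treated, controls = list(treated), list(controls)
    if len(treated) < 2 or len(controls) < 2:
        raise DataError("need at least 2 samples per group")
    if set(treated) & set(controls):
        raise DataError("treated and control sample sets overlap")
    for s in treated + controls:
        if s not in cm.counts.columns:
            raise DataError(f"unknown sample id {s!r}")

    sub = cm.counts[treated + controls]
    sf = size_factors(CountMatrix(sub, cm.sample_meta.loc[treated + controls]))
    norm_df = sub / sf
    nonzero = (sub.to_numpy() > 0).any(axis=1)
    if not nonzero.any():
        raise DataError("no genes with nonzero counts in the selected samples")
    genes = sub.index[nonzero]
    norm = norm_df.loc[genes].to_numpy(dtype=float)

    cols = list(sub.columns)
    t_idx = np.array([cols.index(s) for s in treated])
    c_idx = np.array([cols.index(s) for s in controls])
    inv_sf = 1.0 / sf.to_numpy()

    mu_t = norm[:, t_idx].mean(axis=1)
    mu_c = norm[:, c_idx].mean(axis=1)
    base_mean = norm.mean(axis=1)
    disp = _mom_dispersion(norm, [t_idx, c_idx], inv_sf)

    # pseudocount only where a group mean is zero, so the fold change of
    # genes expressed in both groups is exactly invariant to depth scaling
    needs_pc = (mu_t == 0) | (mu_c == 0)
    m_t = mu_t + np.where(needs_pc, PSEUDOCOUNT, 0.0)
    m_c = mu_c + np.where(needs_pc, PSEUDOCOUNT, 0.0)
    log2fc = np.log2(m_t / m_c)

    # Var(mean of q) = (mu * sum(1/s_j)) / n^2 + alpha * mu^2 / n, per group
    n_t, n_c = len(t_idx), len(c_idx)
    var_mean_t = (m_t * inv_sf[t_idx].sum()) / n_t**2 + disp * m_t**2 / n_t
    var_mean_c = (m_c * inv_sf[c_idx].sum()) / n_c**2 + disp * m_c**2 / n_c
    se_lfc = np.sqrt((var_mean_t / m_t**2 + var_mean_c / m_c**2) / LN2_SQ)
    wald = log2fc / se_lfc
    p = 2.0 * stats.norm.sf(np.abs(wald))
    p_adj = bh_adjust(p)

    table = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "wald": wald,
            "p": p,
            "p_adj": p_adj,
        },
        index=pd.Index(genes, name="gene"),
    )
    sig_mask = table["p_adj"] < alpha
    up = [g for g in table.index[sig_mask & (table["log2fc"] > 0)]]
    down = [g for g in table.index[sig_mask & (table["log2fc"] < 0)]]
    sig = QuerySignature(query_id or "query", up, down)
    logger.info(
        "signature %s: %d up, %d down of %d tested genes (alpha=%g)",
        sig.query_id, len(up), len(down), len(table), alpha,
    )
    return sig, table
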