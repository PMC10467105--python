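"""Technical-validation statistics for the connectivity pipeline.

Two views: (1) within-class tau scores versus a null of tau scores to all
class-annotated references, tested per drug with independent two-sample
t-tests; (2) rank percentiles of each query's expected ("true") class in
the descending mean-tau ordering of all classes, aggregated by cell line
or by drug and tested against the uniform-null center of 0.5.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from sigconn.connectivity import ConnectivityTable
from sigconn.diff_expr import bh_adjust
from sigconn.errors import DataError
from sigconn.io import ReferenceDatabase

logger = logging.getLogger(__name__)


def within_pcl_test(
    table: ConnectivityTable,
    annotations: Mapping[str, str],
    db: ReferenceDatabase,
) -> pd.DataFrame:
    """Per annotated drug: mean within-PCL tau minus mean null tau, with p.

    The null for each drug is its tau to every reference belonging to any
    PCL.  PCLs with fewer than 2 reference members are skipped (logged).
    Effect size is exactly mean(within) - mean(null); p-values are
    independent two-sample Student's t-tests, BH-adjusted across rows.
    """
    df = table.scores
    if "tau" not in df.columns:
        raise DataError("connectivity table has no tau column; run the full chain first")
    any_pcl_members = sorted({m for members in db.pcls.values() for m in members})
    rows = []
    for drug, pcl_id in annotations.items():
        if pcl_id not in db.pcls:
            logger.warning("drug %s: unknown PCL %s; skipped", drug, pcl_id)
            continue
        members = db.pcls[pcl_id]
        if len(members) < 2:
            logger.info("PCL %s has < 2 members; row for %s skipped", pcl_id, drug)
            continue
        sub = df[df["query"] == drug].set_index("reference")["tau"]
        if sub.empty:
            logger.warning("drug %s: no connectivity scores; skipped", drug)
            continue
        within = sub.loc[[m for m in members if m in sub.index]].to_numpy()
        null = sub.loc[[m for m in any_pcl_members if m in sub.index]].to_numpy()
        effect = float(within.mean() - null.mean())
        t, p = stats.ttest_ind(within, null, equal_var=True)
        rows.append(
            {
                "drug": drug,
                "pcl": pcl_id,
                "effect_size": effect,
                "p": float(p),
                "n_within": within.size,
                "n_null": null.size,
            }
        )
    out = pd.DataFrame(rows, columns=["drug", "pcl", "effect_size", "p", "n_within", "n_null"])
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.nan
    return out


def _mean_tau_per_pcl(
    df: pd.DataFrame, db: ReferenceDatabase, restrict_refs: set[str] | None = None
) -> pd.Series | None:
    """Mean tau of one query's scores per PCL, optionally restricted to a
    reference subset (e.g. one cell line); None if no PCL is scoreable."""
    taus = df.set_index("reference")["tau"]
    means = {}
    for pcl_id, members in db.pcls.items():
        use = [m for m in members if m in taus.index]
        if restrict_refs is not None:
            use = [m for m in use if m in restrict_refs]
        if use:
            means[pcl_id] = taus.loc[use].mean()
    if not means:
        return None
    return pd.Series(means)


def rank_percentiles(
    table: ConnectivityTable,
    db: ReferenceDatabase,
    annotations: Mapping[str, str],
    group_by: str = "cell_line",
    test: str = "t",
) -> pd.DataFrame:
    """Expected-PCL rank percentiles grouped by cell line or by drug.

    For each (group, query): PCLs are ranked by mean tau descending (ties
    get the mean rank); the true PCL's percentile is rank / #PCLs.  Group
    statistic is the mean percentile, tested against 0.5 (one-sample t, or
    KS against U(0,1) with ``test='ks'``), BH-adjusted across groups.
    Queries lacking a true-PCL annotation are excluded (logged).
    """
    if group_by not in ("cell_line", "drug"):
        raise DataError("group_by must be 'cell_line' or 'drug'")
    if test not in ("t", "ks"):
        raise DataError("test must be 't' or 'ks'")
    df = table.scores
    n_pcls = len(db.pcls)
    if n_pcls == 0:
        raise DataError("reference database has no PCLs")

    percentiles: dict[str, list[float]] = {}
    for query, qdf in df.groupby("query", sort=False):
        if query not in annotations:
            logger.info("query %s has no true-PCL annotation; excluded", query)
            continue
        true_pcl = annotations[query]
        if group_by == "cell_line":
            contexts = [
                (cell, set(db.meta.index[db.meta["cell_line"] == cell]))
                for cell in sorted(db.meta["cell_line"].unique())
            ]
        else:
            contexts = [(query, None)]
        for key, restrict in contexts:
            means = _mean_tau_per_pcl(qdf, db, restrict)
            if means is None or true_pcl not in means.index:
                continue
            # descending mean tau; ties -> mean rank; divided by the number
            # of PCLs in the ranked list (all PCLs whenever all are scoreable)
            ranks = means.rank(ascending=False, method="average")
            pct = float(ranks.loc[true_pcl] / len(means))
            percentiles.setdefault(key, []).append(pct)

    rows = []
    for key in sorted(percentiles):
        vals = np.asarray(percentiles[key])
        if test == "t":
            if vals.size > 1 and np.ptp(vals) > 0:
                _, p = stats.ttest_1samp(vals, 0.5)
            else:
                p = 1.0 if vals.size and np.allclose(vals, 0.5) else (
                    1.0 if vals.size <= 1 else 0.0
                )
        else:
            _, p = stats.kstest(vals, "uniform")
        rows.append(
            {
                "group": key,
                "mean_rank_percentile": float(vals.mean()),
                "n_queries": int(vals.size),
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows, columns=["group", "mean_rank_percentile", "n_queries", "p"])
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.nan
    return out
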