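"""Connectivity scoring chain: ES -> WCS -> NCS -> tau -> class aggregation.

The enrichment score is a signed Kolmogorov-Smirnov-like statistic over a
reference profile ranked descending by score (largest first, ties broken by
gene id so results are deterministic).  Up- and down-list scores combine
into a weighted connectivity score (WCS), which is mean-normalized within
(cell line, perturbagen type) groups (NCS), converted to a signed quantile
tau on a +/-100 scale across each query's row, and finally aggregated per
perturbagen class (PCL) by a max-quantile rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from sigconn.errors import DataError
from sigconn.io import QuerySignature, ReferenceDatabase

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------


@dataclass
class RankedReference:
    """One reference profile with genes ordered by descending score.

    ``gene_order[k]`` is the gene at 1-based rank ``k + 1``; ``rank_of`` maps
    gene id -> 1-based rank.  Ties in score are broken lexicographically by
    gene id.
    """

    reference_id: str
    gene_order: list[str]
    rank_of: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if not self.rank_of:
            self.rank_of = {g: i + 1 for i, g in enumerate(self.gene_order)}
        if len(self.rank_of) != len(self.gene_order):
            raise DataError("gene order contains duplicates")

    @classmethod
    def from_scores(cls, reference_id: str, scores: pd.Series) -> "RankedReference":
        # stable sort on -score after a pre-sort by gene id -> lexicographic ties
        df = (
            pd.DataFrame({"score": scores.to_numpy(), "gene": scores.index.astype(str)})
            .sort_values("gene", kind="mergesort")
            .sort_values("score", ascending=False, kind="mergesort")
        )
        return cls(reference_id=reference_id, gene_order=list(df["gene"]))

    @property
    def n(self) -> int:
        return len(self.gene_order)


def _rank_matrix(db: ReferenceDatabase) -> np.ndarray:
    """1-based rank of each gene in each reference (genes x references).

    Descending score, ties broken by gene id: achieved by pre-sorting rows
    lexicographically, then a stable argsort of -score per column.
    """
    genes = np.asarray(db.genes, dtype=object)
    gene_sort = np.argsort(genes.astype(str), kind="mergesort")
    scores = db.zscores.to_numpy(dtype=float)[gene_sort]
    order = np.argsort(-scores, axis=0, kind="stable")
    n, m = scores.shape
    ranks_sorted = np.empty((n, m), dtype=np.int64)
    rows = np.arange(1, n + 1)[:, None]
    np.put_along_axis(ranks_sorted, order, np.broadcast_to(rows, (n, m)), axis=0)
    ranks = np.empty((n, m), dtype=np.int64)
    ranks[gene_sort] = ranks_sorted
    return ranks


# ---------------------------------------------------------------------------
# Enrichment score
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnrichmentResult:
    a: float
    b: float

    @property
    def es(self) -> float:
        if self.a > self.b:
            return self.a
        if self.b > self.a:
            return -self.b
        return 0.0


def _es_from_positions(positions: np.ndarray, n: int) -> EnrichmentResult:
    """ES from ascending-sorted 1-based positions of the gene set."""
    t = positions.size
    if t == 0:
        return EnrichmentResult(0.0, 0.0)
    j = np.arange(1, t + 1, dtype=float)
    v = positions.astype(float)
    a = float(np.max(j / t - v / n))
    b = float(np.max(v / n - (j - 1) / t))
    return EnrichmentResult(a, b)


def enrichment_score(gene_set: Iterable[str], ranked: RankedReference) -> EnrichmentResult:
    """Signed KS-like enrichment of *gene_set* in a ranked reference.

    Positive ES means the set concentrates near the top (largest scores) of
    the ranking.  An empty set scores 0 by convention.
    """
    gene_set = list(gene_set)
    if not gene_set:
        logger.debug("empty gene set -> ES = 0")
        return EnrichmentResult(0.0, 0.0)
    try:
        positions = np.sort(np.array([ranked.rank_of[g] for g in gene_set]))
    except KeyError as e:
        raise DataError(f"gene {e.args[0]!r} not in the reference universe") from e
    return _es_from_positions(positions, ranked.n)


def weighted_connectivity(es_up: float, es_down: float) -> float:
    """WCS: (ES_up - ES_down)/2 when the two have strictly opposite signs, else 0."""
    if (es_up > 0 and es_down < 0) or (es_up < 0 and es_down > 0):
        return (es_up - es_down) / 2.0
    return 0.0


# ---------------------------------------------------------------------------
# Normalization, tau, aggregation
# ---------------------------------------------------------------------------


@dataclass
class ConnectivityTable:
    """Long-format per-(query, reference) scores.

    ``scores`` columns: query, reference, es_up, es_down, w, and after
    normalization ncs and tau.  ``group_means`` records the per-(cell line,
    perturbagen type) positive/negative WCS means used for normalization.
    """

    scores: pd.DataFrame
    group_means: pd.DataFrame | None = None


def normalize_connectivity(table: ConnectivityTable, db: ReferenceDatabase) -> ConnectivityTable:
    """Mean-normalize WCS within (cell line, perturbagen type) groups.

    Positive scores are divided by the group mean of positive scores;
    negative scores by the absolute group mean of negative scores (sign
    preserved); zeros stay zero.  Groups lacking positive (negative) scores
    fall back to the global positive (negative) mean, logged.
    """
    df = table.scores.copy()
    meta = db.meta
    df["_cell"] = meta.loc[df["reference"], "cell_line"].to_numpy()
    df["_ptype"] = meta.loc[df["reference"], "perturbagen_type"].to_numpy()

    w = df["w"].to_numpy(dtype=float)
    pos_global = w[w > 0]
    neg_global = w[w < 0]
    if pos_global.size == 0 and neg_global.size == 0:
        logger.warning("all WCS are zero: NCS set to zero everywhere")
        df["ncs"] = 0.0
        df.drop(columns=["_cell", "_ptype"], inplace=True)
        return ConnectivityTable(scores=df, group_means=pd.DataFrame())
    mu_pos_global = pos_global.mean() if pos_global.size else np.nan
    mu_neg_global = neg_global.mean() if neg_global.size else np.nan

    ncs = np.zeros_like(w)
    rows = []
    for (cell, ptype), idx in df.groupby(["_cell", "_ptype"], sort=False).groups.items():
        loc = df.index.get_indexer(idx)
        wg = w[loc]
        pos, neg = wg[wg > 0], wg[wg < 0]
        mu_pos = pos.mean() if pos.size else mu_pos_global
        mu_neg = neg.mean() if neg.size else mu_neg_global
        sub = np.zeros_like(wg)
        if np.any(wg > 0):
            if not pos.size:
                logger.info("group (%s, %s): falling back to global positive mean", cell, ptype)
            sub[wg > 0] = wg[wg > 0] / mu_pos
        if np.any(wg < 0):
            if not neg.size:
                logger.info("group (%s, %s): falling back to global negative mean", cell, ptype)
            sub[wg < 0] = wg[wg < 0] / abs(mu_neg)
        ncs[loc] = sub
        rows.append({"cell_line": cell, "perturbagen_type": ptype,
                     "mu_pos": mu_pos, "mu_neg": mu_neg})
    df["ncs"] = ncs
    df.drop(columns=["_cell", "_ptype"], inplace=True)
    return ConnectivityTable(scores=df, group_means=pd.DataFrame(rows))


def tau_quantile(ncs_row: Sequence[float]) -> np.ndarray:
    """Signed quantile score on a +/-100 scale for one query's NCS row.

    tau_r = sgn(NCS_r) * 100/N * #{i : |NCS_i| < |NCS_r|}, strict inequality
    over the row's N values.
    """
    ncs = np.asarray(ncs_row, dtype=float)
    n = ncs.size
    if n < 1:
        raise DataError("need at least one NCS value")
    mag = np.abs(ncs)
    order = np.argsort(mag, kind="mergesort")
    sorted_mag = mag[order]
    counts = np.searchsorted(sorted_mag, mag, side="left")
    return np.sign(ncs) * 100.0 * counts / n


def _nearest_rank(sorted_vals: np.ndarray, q: float) -> float:
    m = sorted_vals.size
    k = int(np.ceil(q / 100.0 * m))
    k = min(max(k, 1), m)
    return float(sorted_vals[k - 1])


def aggregate_pcl(taus: Sequence[float], q: float = 67.0) -> float:
    """Max-quantile aggregation of member tau scores.

    Takes the nearest-rank q-th and (100-q)-th percentiles and returns the
    one with the larger absolute value (ties favor the upper percentile).
    """
    taus = np.asarray(taus, dtype=float)
    if taus.size == 0:
        raise DataError("cannot aggregate an empty member list")
    s = np.sort(taus)
    s_hi = _nearest_rank(s, q)
    s_lo = _nearest_rank(s, 100.0 - q)
    return s_hi if abs(s_hi) >= abs(s_lo) else s_lo


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------


def _es_batch(rank_cols: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized a/b maxima for one gene set across many references.

    ``rank_cols`` is (t x N): the set's 1-based ranks in each reference,
    sorted ascending per column.
    """
    t = rank_cols.shape[0]
    j = np.arange(1, t + 1, dtype=float)[:, None]
    v = rank_cols.astype(float)
    a = np.max(j / t - v / n, axis=0)
    b = np.max(v / n - (j - 1) / t, axis=0)
    return a, b


def connect_all(
    queries: Sequence[QuerySignature],
    db: ReferenceDatabase,
    q: float = 67.0,
) -> tuple[ConnectivityTable, pd.DataFrame, pd.DataFrame]:
    """Run the full scoring chain for every query against every reference.

    Returns the connectivity table (with es_up/es_down/w/ncs/tau per pair),
    a per-(query, PCL) aggregated score table with ranks and rank
    percentiles, and a per-query sparsity summary (fraction of negative,
    zero and positive scores).
    """
    gene_index = {g: i for i, g in enumerate(db.genes)}
    ranks = _rank_matrix(db)  # genes x references, 1-based
    n = db.n_genes
    ref_ids = db.reference_ids

    frames = []
    kept_queries = []
    for sig in queries:
        sig = sig.restrict_to(gene_index)
        if len(sig) == 0:
            logger.warning("query %s: no genes in the reference universe; skipped", sig.query_id)
            continue
        kept_queries.append(sig.query_id)
        es = {}
        for direction, genes in (("up", sig.up), ("down", sig.down)):
            if genes:
                rows = np.array([gene_index[g] for g in genes])
                cols = np.sort(ranks[rows], axis=0)
                a, b = _es_batch(cols, n)
                val = np.where(a > b, a, np.where(b > a, -b, 0.0))
            else:
                val = np.zeros(len(ref_ids))
            es[direction] = val
        opposite = ((es["up"] > 0) & (es["down"] < 0)) | ((es["up"] < 0) & (es["down"] > 0))
        w = np.where(opposite, (es["up"] - es["down"]) / 2.0, 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "query": sig.query_id,
                    "reference": ref_ids,
                    "es_up": es["up"],
                    "es_down": es["down"],
                    "w": w,
                }
            )
        )
    if not frames:
        raise DataError("no query signature maps to the reference universe")
    table = ConnectivityTable(scores=pd.concat(frames, ignore_index=True))
    table = normalize_connectivity(table, db)

    df = table.scores
    taus = np.empty(len(df))
    for qid, idx in df.groupby("query", sort=False).groups.items():
        loc = df.index.get_indexer(idx)
        taus[loc] = tau_quantile(df["ncs"].to_numpy()[loc])
    df["tau"] = taus

    pcl_rows = []
    for qid in kept_queries:
        sub = df[df["query"] == qid].set_index("reference")["tau"]
        agg = {}
        for pcl_id, members in db.pcls.items():
            members = [m for m in members if m in sub.index]
            if not members:
                continue
            agg[pcl_id] = aggregate_pcl(sub.loc[members].to_numpy(), q=q)
        if not agg:
            continue
        srt = pd.Series(agg).sort_values(ascending=False, kind="mergesort")
        n_pcls = len(srt)
        for rank, (pcl_id, score) in enumerate(srt.items(), start=1):
            pcl_rows.append(
                {
                    "query": qid,
                    "pcl": pcl_id,
                    "score": score,
                    "rank": rank,
                    "rank_percentile": rank / n_pcls,
                }
            )
    pcl_table = pd.DataFrame(
        pcl_rows, columns=["query", "pcl", "score", "rank", "rank_percentile"]
    )

    sparsity = (
        df.assign(
            negative=df["tau"] < 0,
            zero=df["tau"] == 0,
            positive=df["tau"] > 0,
        )
        .groupby("query", sort=False)[["negative", "zero", "positive"]]
        .mean()
        .reset_index()
    )
    return table, pcl_table, sparsity
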