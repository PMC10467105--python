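"""Regulon-enrichment ("master regulator") analysis.

Per-gene Welch t-tests on log2(CPM+1) give a signed Z-score signature; the
same statistic is recomputed over permuted sample labels to build an
empirical null that preserves gene-gene correlation; each regulon's
weighted, mode-signed mean Z is standardized against that null (NES) with
an empirical two-sided p-value; significant regulators are joined to
diseases through a curated TF-disease map, keeping only diseases supported
by at least two significant regulators, and rolled up to ICD-9 chapters.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from sigconn._icd9 import UNCLASSIFIED, chapter_of
from sigconn.diff_expr import bh_adjust
from sigconn.errors import DataError
from sigconn.io import CountMatrix, RegulonSet, TFDiseaseMap

logger = logging.getLogger(__name__)

Z_CAP = 8.0
MIN_REGULON_TARGETS = 5


@dataclass
class NullScores:
    """Per-gene Z-scores over permuted label assignments (genes x perms)."""

    z: pd.DataFrame
    seed: int


def _log2_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    totals = counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        raise DataError("sample with zero total counts")
    return np.log2(counts.div(totals, axis=1) * 1e6 + 1.0)


def _zscores_from_groups(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Welch t per gene -> signed normal quantile, capped at +/-Z_CAP.

    Genes with zero variance in both groups and equal means get z = 0.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    mean_diff = a.mean(axis=1) - b.mean(axis=1)
    degenerate = ~np.isfinite(t)
    with np.errstate(invalid="ignore"):
        # zero variance, unequal means: certain difference in-sample
        t = np.where(degenerate & (mean_diff != 0), np.sign(mean_diff) * np.inf, t)
        p = np.where(degenerate & (mean_diff != 0), 0.0, p)
        t = np.where(degenerate & (mean_diff == 0), 0.0, t)
        p = np.where(degenerate & (mean_diff == 0), 1.0, p)
    with np.errstate(divide="ignore"):
        z = np.sign(t) * stats.norm.isf(np.clip(p, 0.0, 1.0) / 2.0)
    z = np.where(p >= 1.0, 0.0, z)
    return np.clip(z, -Z_CAP, Z_CAP)


def gene_zscores(cm: CountMatrix, treated: list[str], controls: list[str]) -> pd.Series:
    """Signed per-gene Z-scores for treated vs control on log2(CPM+1)."""
    treated, controls = list(treated), list(controls)
    if len(treated) < 2 or len(controls) < 2:
        raise DataError("need at least 2 samples per group")
    expr = _log2_cpm(cm.counts[treated + controls])
    z = _zscores_from_groups(
        expr[treated].to_numpy(dtype=float), expr[controls].to_numpy(dtype=float)
    )
    return pd.Series(z, index=cm.counts.index, name="z")


def permutation_null(
    cm: CountMatrix,
    treated: list[str],
    controls: list[str],
    n_perms: int,
    seed: int,
) -> NullScores:
    """Z-scores under *n_perms* distinct relabelings (original excluded)."""
    treated, controls = list(treated), list(controls)
    samples = treated + controls
    n, k = len(samples), len(treated)
    max_perms = comb(n, k) - 1
    if n_perms > max_perms:
        raise DataError(
            f"n_perms={n_perms} exceeds the {max_perms} distinct label "
            f"permutations available for {k} of {n} samples"
        )
    rng = np.random.default_rng(seed)
    original = frozenset(range(k))

    if comb(n, k) <= 200_000:
        combos = [c for c in itertools.combinations(range(n), k) if frozenset(c) != original]
        pick = rng.choice(len(combos), size=n_perms, replace=False)
        chosen = [combos[i] for i in pick]
    else:
        seen: set[frozenset] = {original}
        chosen = []
        while len(chosen) < n_perms:
            c = frozenset(rng.choice(n, size=k, replace=False).tolist())
            if c not in seen:
                seen.add(c)
                chosen.append(tuple(sorted(c)))

    expr = _log2_cpm(cm.counts[samples]).to_numpy(dtype=float)
    cols = {}
    for i, combo in enumerate(chosen):
        t_idx = np.array(combo)
        c_idx = np.setdiff1d(np.arange(n), t_idx)
        cols[f"perm{i}"] = _zscores_from_groups(expr[:, t_idx], expr[:, c_idx])
    z = pd.DataFrame(cols, index=cm.counts.index)
    return NullScores(z=z, seed=seed)


def regulon_enrichment(
    z: pd.Series,
    regulons: RegulonSet,
    null: NullScores,
    min_targets: int = MIN_REGULON_TARGETS,
) -> pd.DataFrame:
    """NES, empirical p and BH-FDR per regulon.

    Raw score S = sum(weight * mode * z_target) / sum(weight); NES
    standardizes S against the same statistic over each null column; the
    two-sided p-value is empirical with add-one smoothing.  Regulons with
    fewer than *min_targets* targets in the universe are skipped (logged);
    regulons with a degenerate null sd are flagged with NES = NaN.
    """
    universe = set(z.index)
    rows = []
    null_mat = null.z.to_numpy(dtype=float)
    null_index = {g: i for i, g in enumerate(null.z.index)}
    n_perms = null_mat.shape[1]
    for tf, targets in regulons.items():
        present = [t for t in targets if t.target in universe and t.target in null_index]
        if len(present) < min_targets:
            logger.info(
                "regulon %s skipped: %d of %d targets in universe (< %d)",
                tf, len(present), len(targets), min_targets,
            )
            continue
        wts = np.array([t.weight for t in present])
        modes = np.array([t.mode for t in present], dtype=float)
        zt = z.loc[[t.target for t in present]].to_numpy(dtype=float)
        score = float(np.sum(wts * modes * zt) / np.sum(wts))
        idx = np.array([null_index[t.target] for t in present])
        null_scores = (wts * modes) @ null_mat[idx] / np.sum(wts)
        mu, sd = float(null_scores.mean()), float(null_scores.std(ddof=1))
        if sd < 1e-12:
            logger.warning("regulon %s: degenerate null sd; NES undefined", tf)
            rows.append({"tf": tf, "n_targets": len(present), "score": score,
                         "nes": np.nan, "p": np.nan, "degenerate": True})
            continue
        nes = (score - mu) / sd
        p = (1.0 + np.sum(np.abs(null_scores) >= abs(score))) / (n_perms + 1.0)
        rows.append({"tf": tf, "n_targets": len(present), "score": score,
                     "nes": nes, "p": p, "degenerate": False})
    table = pd.DataFrame(
        rows, columns=["tf", "n_targets", "score", "nes", "p", "degenerate"]
    )
    table["fdr"] = np.nan
    ok = ~table["p"].isna()
    if ok.any():
        table.loc[ok, "fdr"] = bh_adjust(table.loc[ok, "p"].to_numpy())
    return table


def map_to_diseases(
    enrichment: pd.DataFrame,
    tf_disease: TFDiseaseMap,
    fdr_threshold: float = 0.05,
    min_tfs: int = 2,
    direction: str = "both",
) -> pd.DataFrame:
    """Join significant regulators to diseases; keep >= *min_tfs* support.

    *direction* restricts to positively ("up") or negatively ("down")
    enriched regulators, or keeps both.  Output is sorted by support count
    descending, then CUI, with an ICD-9 chapter per disease.
    """
    if direction not in ("up", "down", "both"):
        raise DataError("direction must be 'up', 'down' or 'both'")
    sig = enrichment[(~enrichment["fdr"].isna()) & (enrichment["fdr"] < fdr_threshold)]
    if direction == "up":
        sig = sig[sig["nes"] > 0]
    elif direction == "down":
        sig = sig[sig["nes"] < 0]
    sig_tfs = set(sig["tf"])
    joined = tf_disease.table[tf_disease.table["tf"].isin(sig_tfs)]
    rows = []
    for (cui, name), grp in joined.groupby(["cui", "disease_name"], sort=True):
        tfs = sorted(set(grp["tf"]))
        if len(tfs) < min_tfs:
            continue
        codes = sorted({c for codes in grp["icd9"] for c in codes})
        rows.append(
            {
                "cui": cui,
                "disease_name": name,
                "supporting_tfs": "|".join(tfs),
                "support": len(tfs),
                "icd9_chapter": icd9_rollup(codes),
            }
        )
    out = pd.DataFrame(
        rows, columns=["cui", "disease_name", "supporting_tfs", "support", "icd9_chapter"]
    )
    if len(out):
        out = out.sort_values(
            ["support", "cui"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    return out


def icd9_rollup(codes: list[str]) -> str:
    """Chapter label for a disease's ICD-9 codes.

    When codes span several chapters the shortest (most general-category,
    hence most specific disease entry) code wins, which steers away from
    'not elsewhere classified' subcodes.  Unmappable codes fall into
    UNCLASSIFIED, logged.
    """
    mapped = []
    for code in codes:
        chapter = chapter_of(code)
        if chapter == UNCLASSIFIED:
            logger.info("ICD-9 code %r unmappable; bucketed as UNCLASSIFIED", code)
            continue
        mapped.append((len(str(code).strip()), str(code), chapter))
    if not mapped:
        return UNCLASSIFIED
    mapped.sort()
    return mapped[0][2]
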