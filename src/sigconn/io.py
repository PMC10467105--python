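"""Readers/writers for every external artifact and the shared domain types.

All tabular formats are tab-separated UTF-8 with ``#`` comment lines ignored.
Gene identifiers are opaque, case-sensitive strings; no identifier translation
is attempted.  Loading never reorders: gene, sample and reference order is
preserved exactly as found in the file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from sigconn.errors import DataError

logger = logging.getLogger(__name__)

_TSV_KW = dict(sep="\t", comment="#", dtype=str)

META_COLUMNS = ("perturbagen", "time_point", "replicate", "is_control", "control_kind")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Gene x sample matrix of nonnegative integer counts plus sample metadata.

    ``counts`` is a genes-by-samples DataFrame with unique string indices;
    ``sample_meta`` is indexed by sample id and carries at least the columns
    in :data:`META_COLUMNS`.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene identifiers: {dupes}")
        if self.counts.columns.duplicated().any():
            raise DataError("duplicate sample identifiers")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if np.any(vals != np.floor(vals)) or np.any(~np.isfinite(vals)):
                raise DataError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise DataError("counts must be nonnegative")
        missing = [s for s in self.counts.columns if s not in self.sample_meta.index]
        if missing:
            raise DataError(f"samples without metadata: {missing}")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def samples_for(self, perturbagen: str) -> list[str]:
        """Sample ids treated with the given perturbagen."""
        meta = self.sample_meta.loc[self.counts.columns]
        mask = (meta["perturbagen"] == perturbagen) & (~meta["is_control"].astype(bool))
        return list(meta.index[mask])

    def control_samples(self) -> list[str]:
        meta = self.sample_meta.loc[self.counts.columns]
        return list(meta.index[meta["is_control"].astype(bool)])


@dataclass(frozen=True)
class QuerySignature:
    """Disjoint up/down gene lists for one perturbagen."""

    query_id: str
    up: tuple[str, ...]
    down: tuple[str, ...]

    def __init__(self, query_id: str, up: Iterable[str], down: Iterable[str]):
        up_t, down_t = tuple(up), tuple(down)
        overlap = set(up_t) & set(down_t)
        if overlap:
            raise DataError(f"up/down lists overlap: {sorted(overlap)}")
        object.__setattr__(self, "query_id", str(query_id))
        object.__setattr__(self, "up", up_t)
        object.__setattr__(self, "down", down_t)

    def restrict_to(self, universe: Iterable[str]) -> "QuerySignature":
        """Drop genes absent from *universe*, logging the dropped count."""
        uni = set(universe)
        up = tuple(g for g in self.up if g in uni)
        down = tuple(g for g in self.down if g in uni)
        dropped = (len(self.up) - len(up)) + (len(self.down) - len(down))
        if dropped:
            logger.warning(
                "query %s: dropped %d gene(s) absent from the reference universe",
                self.query_id,
                dropped,
            )
        return QuerySignature(self.query_id, up, down)

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


@dataclass
class ReferenceDatabase:
    """N reference profiles over one shared gene universe, plus PCL classes.

    ``zscores``: genes x references DataFrame of per-gene scores.
    ``meta``: indexed by reference id with columns
    ``cell_line``, ``perturbagen_type``, ``perturbagen_id``.
    ``pcls``: PCL id -> list of member reference ids.
    """

    zscores: pd.DataFrame
    meta: pd.DataFrame
    pcls: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.zscores.shape[1] < 1:
            raise DataError("reference database must contain at least one profile")
        if self.zscores.index.duplicated().any():
            raise DataError("duplicate gene identifiers in reference matrix")
        if self.zscores.columns.duplicated().any():
            raise DataError("duplicate reference identifiers")
        if self.zscores.isna().any().any():
            bad = self.zscores.columns[self.zscores.isna().any()].tolist()
            raise DataError(f"profiles with missing gene values: {bad}")
        missing = [r for r in self.zscores.columns if r not in self.meta.index]
        if missing:
            raise DataError(f"references without metadata: {missing}")

    @property
    def genes(self) -> list[str]:
        return list(self.zscores.index)

    @property
    def reference_ids(self) -> list[str]:
        return list(self.zscores.columns)

    @property
    def n_genes(self) -> int:
        return self.zscores.shape[0]

    @property
    def n_references(self) -> int:
        return self.zscores.shape[1]

    def pcls_of(self, reference_id: str) -> list[str]:
        return [p for p, members in self.pcls.items() if reference_id in members]


class RegulonTarget(NamedTuple):
    target: str
    mode: int  # +1 activation, -1 repression
    weight: float  # confidence in (0, 1]


@dataclass
class RegulonSet:
    """TF id -> signed, weighted target list."""

    regulons: dict[str, list[RegulonTarget]]

    def __post_init__(self) -> None:
        for tf, targets in self.regulons.items():
            seen: set[str] = set()
            for t in targets:
                if t.target in seen:
                    raise DataError(f"duplicate target {t.target!r} in regulon {tf!r}")
                seen.add(t.target)
                if t.mode not in (1, -1):
                    raise DataError(f"regulon {tf!r}: mode must be +1 or -1")
                if not (0.0 < t.weight <= 1.0):
                    raise DataError(
                        f"regulon {tf!r} target {t.target!r}: weight {t.weight} outside (0, 1]"
                    )

    def __len__(self) -> int:
        return len(self.regulons)

    def __getitem__(self, tf: str) -> list[RegulonTarget]:
        return self.regulons[tf]

    def items(self):
        return self.regulons.items()


@dataclass
class TFDiseaseMap:
    """Rows of (TF id, disease CUI, disease name, ICD-9 codes)."""

    table: pd.DataFrame  # columns: tf, cui, disease_name, icd9 (list of str)

    def __post_init__(self) -> None:
        if self.table.duplicated(subset=["tf", "cui"]).any():
            raise DataError("duplicate (TF, CUI) pairs in TF-disease map")

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------


def load_count_matrix(counts_path, meta_path) -> CountMatrix:
    """Load a gene x sample count TSV and its sample-metadata TSV."""
    raw = pd.read_csv(counts_path, sep="\t", comment="#", index_col=0)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    if raw.index.duplicated().any():
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate gene identifiers: {dupes}")
    vals = raw.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise DataError("non-numeric count value encountered")
    meta = pd.read_csv(meta_path, sep="\t", comment="#", index_col=0)
    meta.index = meta.index.astype(str)
    for col in META_COLUMNS:
        if col not in meta.columns:
            raise DataError(
                f"metadata missing column {col!r}; expected columns {META_COLUMNS}"
            )
    meta["is_control"] = _parse_bool(meta["is_control"])
    return CountMatrix(counts=raw, sample_meta=meta)


def write_count_matrix(cm: CountMatrix, counts_path, meta_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene")
    cm.sample_meta.to_csv(meta_path, sep="\t", index_label="sample")


def _parse_bool(col: pd.Series) -> pd.Series:
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False,
    }

    def conv(v):
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        s = str(v).strip().lower()
        if s not in mapping:
            raise DataError(f"cannot interpret {v!r} as a boolean")
        return mapping[s]

    return col.map(conv)


# ---------------------------------------------------------------------------
# Reference databases / GMT
# ---------------------------------------------------------------------------


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file: per line, set id, description, then member ids."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataError(f"malformed GMT line: {line!r}")
            set_id = parts[0]
            if set_id in sets:
                raise DataError(f"duplicate GMT set id {set_id!r}")
            sets[set_id] = [m for m in parts[2:] if m]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path, descriptions=None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id, members in sets.items():
            desc = (descriptions or {}).get(set_id, "na")
            fh.write("\t".join([set_id, desc, *members]) + "\n")


def load_reference_db(matrix_path, meta_path, gmt_path=None) -> ReferenceDatabase:
    """Load a reference score matrix, its metadata and (optionally) PCL GMT.

    GMT members absent from the score matrix are dropped with a logged
    warning reporting the dropped count.
    """
    mat = pd.read_csv(matrix_path, sep="\t", comment="#", index_col=0)
    mat.index = mat.index.astype(str)
    mat.columns = mat.columns.astype(str)
    meta = pd.read_csv(meta_path, sep="\t", comment="#", index_col=0)
    meta.index = meta.index.astype(str)
    pcls: dict[str, list[str]] = {}
    if gmt_path is not None:
        raw_pcls = read_gmt(gmt_path)
        known = set(mat.columns)
        n_dropped = 0
        for pcl_id, members in raw_pcls.items():
            kept = [m for m in members if m in known]
            n_dropped += len(members) - len(kept)
            pcls[pcl_id] = kept
        if n_dropped:
            logger.warning(
                "dropped %d PCL member id(s) absent from the reference matrix",
                n_dropped,
            )
    return ReferenceDatabase(zscores=mat, meta=meta, pcls=pcls)


def write_reference_db(db: ReferenceDatabase, matrix_path, meta_path, gmt_path=None) -> None:
    db.zscores.to_csv(matrix_path, sep="\t", index_label="gene")
    db.meta.to_csv(meta_path, sep="\t", index_label="reference_id")
    if gmt_path is not None:
        write_gmt(db.pcls, gmt_path)


# ---------------------------------------------------------------------------
# Regulons
# ---------------------------------------------------------------------------

_MODE_VALUES = {"+": 1, "-": -1, "+1": 1, "-1": -1, "1": 1,
                "−": -1, "−1": -1}  # tolerate unicode minus


def load_regulons(path) -> RegulonSet:
    """Load a 4-column TSV (tf, target, mode, weight) into a RegulonSet."""
    df = pd.read_csv(path, **_TSV_KW)
    expected = ["tf", "target", "mode", "weight"]
    if list(df.columns[:4]) != expected:
        raise DataError(
            f"regulon file must have columns {expected}, found {list(df.columns)}"
        )
    regulons: dict[str, list[RegulonTarget]] = {}
    for row in df.itertuples(index=False):
        mode_s = str(row.mode).strip()
        if mode_s not in _MODE_VALUES:
            raise DataError(f"invalid mode {row.mode!r}; expected + or -")
        weight = float(row.weight)
        regulons.setdefault(str(row.tf), []).append(
            RegulonTarget(str(row.target), _MODE_VALUES[mode_s], weight)
        )
    return RegulonSet(regulons=regulons)


def write_regulons(rs: RegulonSet, path) -> None:
    rows = [
        {"tf": tf, "target": t.target, "mode": "+" if t.mode > 0 else "-", "weight": t.weight}
        for tf, targets in rs.items()
        for t in targets
    ]
    pd.DataFrame(rows, columns=["tf", "target", "mode", "weight"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# TF-disease map
# ---------------------------------------------------------------------------


def load_tf_disease_map(path) -> TFDiseaseMap:
    """Load a TSV with columns tf, cui, disease_name, icd9 ('|'-separated codes)."""
    df = pd.read_csv(path, **_TSV_KW)
    expected = ["tf", "cui", "disease_name", "icd9"]
    if list(df.columns[:4]) != expected:
        raise DataError(
            f"TF-disease file must have columns {expected}, found {list(df.columns)}"
        )
    df = df.fillna({"icd9": ""})
    df["icd9"] = df["icd9"].map(lambda s: [c for c in str(s).split("|") if c])
    return TFDiseaseMap(table=df[expected].copy())


def write_tf_disease_map(m: TFDiseaseMap, path) -> None:
    out = m.table.copy()
    out["icd9"] = out["icd9"].map(lambda codes: "|".join(codes))
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Signatures
# ---------------------------------------------------------------------------

SIGNATURE_COLUMNS = ["Gene", "Base Mean", "log2-FC", "Wald Statistic", "p-Adj", "direction"]


def write_signature(sig: QuerySignature, table: pd.DataFrame, path) -> tuple[Path, Path]:
    """Write a signature as a per-gene statistics TSV plus a compact JSON.

    ``table`` is indexed by gene id with columns ``base_mean``, ``log2fc``,
    ``wald`` and ``p_adj``.  The TSV carries only the signature genes; the
    JSON carries the up/down lists and round-trips via :func:`load_signature`.
    """
    path = Path(path)
    members = list(sig.up) + list(sig.down)
    missing = [g for g in members if g not in table.index]
    if missing:
        raise DataError(f"signature genes missing from statistics table: {missing}")
    rows = []
    for gene in members:
        rec = table.loc[gene]
        rows.append(
            {
                "Gene": gene,
                "Base Mean": rec["base_mean"],
                "log2-FC": rec["log2fc"],
                "Wald Statistic": rec["wald"],
                "p-Adj": rec["p_adj"],
                "direction": "up" if gene in sig.up else "down",
            }
        )
    pd.DataFrame(rows, columns=SIGNATURE_COLUMNS).to_csv(path, sep="\t", index=False)
    json_path = path.with_suffix(".json")
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(
            {"query_id": sig.query_id, "up": list(sig.up), "down": list(sig.down)},
            fh,
            indent=1,
        )
        fh.write("\n")
    return path, json_path


def load_signature(json_path) -> QuerySignature:
    with open(json_path, encoding="utf-8") as fh:
        obj = json.load(fh)
    return QuerySignature(obj["query_id"], obj["up"], obj["down"])
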