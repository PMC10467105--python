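"""Seeded generators emulating every input the pipeline consumes.

Each generator draws from its own random stream derived from
``(spec.seed, generator name)``, so adding a generator never perturbs the
draws of another.  All outputs are pure functions of the spec.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from sigconn.dose_response import DoseResponseCurve, hill
from sigconn.errors import DataError
from sigconn.io import (
    CountMatrix,
    QuerySignature,
    ReferenceDatabase,
    RegulonSet,
    RegulonTarget,
    TFDiseaseMap,
)


@dataclass
class SimSpec:
    """Ground-truth parameters for all synthetic generators."""

    seed: int
    # counts
    n_genes: int = 2000
    n_treated: int = 3
    n_control: int = 21
    dispersion: float = 0.1
    n_planted: int = 100
    planted_log2fc: float = 2.0
    baseline_log_mean: float = np.log(100.0)
    baseline_log_sd: float = 1.0
    planted: dict | None = None  # explicit gene -> log2fc map, overrides n_planted
    # reference compendium
    ref_n_genes: int = 978
    n_classes: int = 20
    members_per_class: int = 10
    snr: float = 2.0
    cell_lines: tuple = ("CL1", "CL2", "CL3")
    # regulons
    n_tfs: int = 10
    targets_per_tf: int = 20
    planted_tf_shift: float = 2.0
    n_diseases: int = 6
    # dose-response
    hill_bottom: float = 0.0
    hill_top: float = 100.0
    hill_loggi50: float = -1.0
    hill_h: float = -2.0
    dose_sigma: float = 0.0
    n_doses: int = 12
    start_concentration: float = 2.0  # ug/uL, halved n_doses-1 times

    def rng(self, name: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, zlib.crc32(name.encode())])

    @classmethod
    def from_dict(cls, d: dict) -> "SimSpec":
        spec = cls(**{k: v for k, v in d.items()})
        if isinstance(spec.cell_lines, list):
            spec.cell_lines = tuple(spec.cell_lines)
        return spec

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cell_lines"] = list(self.cell_lines)
        return d


def _gene_ids(n: int, prefix: str = "G") -> list[str]:
    width = len(str(n - 1))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def sim_counts(spec: SimSpec) -> tuple[CountMatrix, pd.DataFrame]:
    """NB counts with a log-normal baseline and planted fold changes.

    Returns the count matrix (treated + control arms for one perturbagen,
    plus metadata) and a truth table (gene, log2fc) of planted genes.
    """
    rng = spec.rng("counts")
    genes = _gene_ids(spec.n_genes)
    base = np.exp(rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_genes))

    lfc = np.zeros(spec.n_genes)
    if spec.planted is not None:
        gene_pos = {g: i for i, g in enumerate(genes)}
        for g, v in spec.planted.items():
            if g not in gene_pos:
                raise DataError(f"planted gene {g!r} outside the simulated universe")
            lfc[gene_pos[g]] = v
    elif spec.n_planted > 0:
        idx = rng.choice(spec.n_genes, size=spec.n_planted, replace=False)
        signs = rng.choice([-1.0, 1.0], size=spec.n_planted)
        lfc[idx] = signs * spec.planted_log2fc

    n_nb = 1.0 / spec.dispersion  # NB shape; variance = mu + disp * mu^2
    def draw(mean_vec, n_samples):
        mu = np.repeat(mean_vec[:, None], n_samples, axis=1)
        p = n_nb / (n_nb + mu)
        return rng.negative_binomial(n_nb, p)

    control = draw(base, spec.n_control)
    treated = draw(base * 2.0**lfc, spec.n_treated)
    t_ids = [f"T{i}" for i in range(spec.n_treated)]
    c_ids = [f"C{i}" for i in range(spec.n_control)]
    counts = pd.DataFrame(
        np.hstack([treated, control]), index=genes, columns=t_ids + c_ids
    )
    meta = pd.DataFrame(
        {
            "perturbagen": ["venom1"] * spec.n_treated + ["none"] * spec.n_control,
            "time_point": ["24h"] * (spec.n_treated + spec.n_control),
            "replicate": list(range(spec.n_treated)) + list(range(spec.n_control)),
            "is_control": [False] * spec.n_treated + [True] * spec.n_control,
            "control_kind": ["na"] * spec.n_treated + ["water"] * spec.n_control,
        },
        index=t_ids + c_ids,
    )
    truth = pd.DataFrame(
        {"gene": [genes[i] for i in np.nonzero(lfc)[0]], "log2fc": lfc[np.nonzero(lfc)[0]]}
    )
    return CountMatrix(counts=counts, sample_meta=meta), truth


def sim_reference_db(spec: SimSpec) -> tuple[ReferenceDatabase, pd.DataFrame]:
    """Reference compendium with planted classes and cell-line structure.

    Each class has a latent standard-normal template over the gene
    universe; members are ``snr * template + N(0, 1)`` noise.  Every class
    doubles as a PCL containing its members; cell lines are assigned
    round-robin.  Returns the database and the templates (genes x classes).
    """
    rng = spec.rng("reference")
    genes = _gene_ids(spec.ref_n_genes)
    classes = [f"class{k:02d}" for k in range(spec.n_classes)]
    templates = rng.normal(size=(spec.ref_n_genes, spec.n_classes))

    profiles, meta_rows, pcls = {}, [], {}
    for k, cls_id in enumerate(classes):
        members = []
        for m in range(spec.members_per_class):
            ref_id = f"{cls_id}_m{m:02d}"
            noise = rng.normal(size=spec.ref_n_genes)
            profiles[ref_id] = spec.snr * templates[:, k] + noise
            cell = spec.cell_lines[(k * spec.members_per_class + m) % len(spec.cell_lines)]
            meta_rows.append(
                {
                    "reference_id": ref_id,
                    "cell_line": cell,
                    "perturbagen_type": "trt_cp",
                    "perturbagen_id": f"{cls_id}_drug{m:02d}",
                }
            )
            members.append(ref_id)
        pcls[cls_id] = members
    zscores = pd.DataFrame(profiles, index=genes)
    meta = pd.DataFrame(meta_rows).set_index("reference_id")
    truth = pd.DataFrame(templates, index=genes, columns=classes)
    return ReferenceDatabase(zscores=zscores, meta=meta, pcls=pcls), truth


def sim_class_queries(
    spec: SimSpec, truth: pd.DataFrame, n_queries: int, set_size: int = 50
) -> list[tuple[QuerySignature, str]]:
    """Queries drawn from planted classes: a fresh member-like realization's
    top/bottom *set_size* genes become the up/down lists."""
    rng = spec.rng("queries")
    classes = list(truth.columns)
    out = []
    for i in range(n_queries):
        cls = classes[int(rng.integers(len(classes)))]
        profile = spec.snr * truth[cls].to_numpy() + rng.normal(size=truth.shape[0])
        order = np.argsort(-profile, kind="stable")
        up = [truth.index[j] for j in order[:set_size]]
        down = [truth.index[j] for j in order[-set_size:]]
        out.append((QuerySignature(f"q{i:03d}", up, down), cls))
    return out


def sim_regulons(spec: SimSpec) -> tuple[RegulonSet, TFDiseaseMap, str]:
    """Disjoint-target regulons, a TF-disease fixture and the planted TF.

    Targets are drawn without replacement from the count-simulation gene
    universe; modes are random signs and weights uniform on (0.2, 1].  The
    disease fixture links every disease to >= 1 TF and at least one disease
    to >= 2 TFs, exercising the multi-regulator evidence filter.
    """
    rng = spec.rng("regulons")
    genes = _gene_ids(spec.n_genes)
    needed = spec.n_tfs * spec.targets_per_tf
    if needed > spec.n_genes:
        raise DataError("not enough genes for disjoint regulon targets")
    chosen = rng.choice(spec.n_genes, size=needed, replace=False)
    tfs = [f"TF{k:02d}" for k in range(spec.n_tfs)]
    regulons = {}
    for k, tf in enumerate(tfs):
        idx = chosen[k * spec.targets_per_tf : (k + 1) * spec.targets_per_tf]
        modes = rng.choice([1, -1], size=spec.targets_per_tf)
        weights = 0.2 + 0.8 * rng.random(spec.targets_per_tf)
        regulons[tf] = [
            RegulonTarget(genes[g], int(m), float(w))
            for g, m, w in zip(idx, modes, weights)
        ]
    planted_tf = tfs[0]

    icd9_pool = ["401", "295.1", "332.0", "250.00", "162.9", "493.9", "714.0", "580"]
    rows = []
    for d in range(spec.n_diseases):
        cui = f"C{d:07d}"
        name = f"disease_{d}"
        n_linked = 2 if d == 0 else int(rng.integers(1, 3))
        linked = rng.choice(spec.n_tfs, size=min(n_linked, spec.n_tfs), replace=False)
        for tf_i in linked:
            rows.append(
                {
                    "tf": tfs[tf_i],
                    "cui": cui,
                    "disease_name": name,
                    "icd9": [icd9_pool[d % len(icd9_pool)]],
                }
            )
    tf_disease = TFDiseaseMap(table=pd.DataFrame(rows, columns=["tf", "cui", "disease_name", "icd9"]))
    return RegulonSet(regulons=regulons), tf_disease, planted_tf


def planted_regulon_truth(regulons: RegulonSet, tf: str, shift_log2fc: float) -> dict:
    """Gene -> log2fc map shifting a TF's targets along their modes."""
    return {t.target: t.mode * shift_log2fc for t in regulons[tf]}


def sim_dose_response(spec: SimSpec) -> tuple[DoseResponseCurve, dict]:
    """Hill-generated responses on a 2-fold dilution grid with noise.

    The grid starts at ``start_concentration`` and halves ``n_doses - 1``
    times (spanning >= 3 log10 units at the default 12 doses).
    """
    rng = spec.rng("dose_response")
    conc = spec.start_concentration * 0.5 ** np.arange(spec.n_doses)
    x = np.log10(conc)
    y = hill(x, spec.hill_bottom, spec.hill_top, spec.hill_loggi50, spec.hill_h)
    if spec.dose_sigma > 0:
        y = y + rng.normal(0.0, spec.dose_sigma, size=y.shape)
    truth = {
        "bottom": spec.hill_bottom,
        "top": spec.hill_top,
        "loggi50": spec.hill_loggi50,
        "h": spec.hill_h,
    }
    return DoseResponseCurve(x=x, y=y), truth
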