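import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sigconn import simulate
from sigconn.errors import DataError
from sigconn.io import CountMatrix, RegulonSet, RegulonTarget, TFDiseaseMap
from sigconn.master_regulator import (
    gene_zscores,
    icd9_rollup,
    map_to_diseases,
    permutation_null,
    regulon_enrichment,
)


@pytest.fixture
def null_cm():
    spec = simulate.SimSpec(seed=50, n_genes=300, n_treated=4, n_control=4, n_planted=0)
    cm, _ = simulate.sim_counts(spec)
    return cm


def groups(cm):
    t = [s for s in cm.samples if s.startswith("T")]
    c = [s for s in cm.samples if s.startswith("C")]
    return t, c


class TestGeneZscores:
    def test_sign_convention(self):
        counts = pd.DataFrame(
            {
                "t1": [1000, 10], "t2": [1100, 12], "t3": [900, 9],
                "c1": [10, 10], "c2": [12, 11], "c3": [11, 12],
            },
            index=["big", "flat"],
        )
        meta = pd.DataFrame(
            {
                "perturbagen": ["v"] * 3 + ["none"] * 3,
                "time_point": ["6h"] * 6,
                "replicate": [0, 1, 2] * 2,
                "is_control": [False] * 3 + [True] * 3,
                "control_kind": ["na"] * 3 + ["water"] * 3,
            },
            index=counts.columns,
        )
        cm = CountMatrix(counts=counts, sample_meta=meta)
        z = gene_zscores(cm, ["t1", "t2", "t3"], ["c1", "c2", "c3"])
        assert z["big"] > 0

    def test_identical_groups_zero(self):
        counts = pd.DataFrame({f"s{i}": [5, 7] for i in range(6)}, index=["a", "b"])
        meta = pd.DataFrame(
            {
                "perturbagen": ["v"] * 6, "time_point": ["6h"] * 6,
                "replicate": range(6), "is_control": [False] * 6,
                "control_kind": ["na"] * 6,
            },
            index=counts.columns,
        )
        cm = CountMatrix(counts=counts, sample_meta=meta)
        z = gene_zscores(cm, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert np.allclose(z, 0.0)

    def test_normal_quantile_identity(self):
        # two-sided p = 0.05 with positive shift -> z = +1.959964
        z = np.sign(1.0) * stats.norm.isf(0.05 / 2.0)
        assert z == pytest.approx(1.959964, abs=1e-6)

    def test_group_too_small(self, null_cm):
        t, c = groups(null_cm)
        with pytest.raises(DataError):
            gene_zscores(null_cm, t[:1], c)


class TestPermutationNull:
    def test_seed_determinism(self, null_cm):
        t, c = groups(null_cm)
        a = permutation_null(null_cm, t, c, n_perms=10, seed=4)
        b = permutation_null(null_cm, t, c, n_perms=10, seed=4)
        pd.testing.assert_frame_equal(a.z, b.z)

    def test_different_seeds_differ(self, null_cm):
        t, c = groups(null_cm)
        a = permutation_null(null_cm, t, c, n_perms=10, seed=4)
        b = permutation_null(null_cm, t, c, n_perms=10, seed=5)
        assert not a.z.equals(b.z)

    def test_null_mean_near_zero(self):
        spec = simulate.SimSpec(seed=60, n_genes=150, n_treated=5, n_control=5,
                                n_planted=0)
        cm, _ = simulate.sim_counts(spec)
        t, c = groups(cm)
        null = permutation_null(cm, t, c, n_perms=200, seed=1)
        grand = null.z.to_numpy().mean()
        assert -0.2 <= grand <= 0.2

    def test_max_permutation_boundary(self):
        spec = simulate.SimSpec(seed=61, n_genes=20, n_treated=2, n_control=3,
                                n_planted=0)
        cm, _ = simulate.sim_counts(spec)
        t, c = groups(cm)
        max_perms = 10 - 1  # C(5,2) - 1, original excluded
        null = permutation_null(cm, t, c, n_perms=max_perms, seed=0)
        assert null.z.shape[1] == max_perms
        with pytest.raises(DataError, match="exceeds"):
            permutation_null(cm, t, c, n_perms=max_perms + 1, seed=0)


def make_null_like(z_index, n_perms, seed, scale=1.0):
    rng = np.random.default_rng(seed)
    from sigconn.master_regulator import NullScores

    z = pd.DataFrame(
        rng.normal(scale=scale, size=(len(z_index), n_perms)),
        index=z_index,
        columns=[f"perm{i}" for i in range(n_perms)],
    )
    return NullScores(z=z, seed=seed)


class TestRegulonEnrichment:
    def test_planted_regulon_ranks_first(self):
        genes = [f"g{i}" for i in range(100)]
        z = pd.Series(0.0, index=genes)
        planted_targets = genes[:20]
        z[planted_targets] = 3.0
        regulons = RegulonSet(
            {
                "PLANTED": [RegulonTarget(g, 1, 1.0) for g in planted_targets],
                "OTHER": [RegulonTarget(g, 1, 1.0) for g in genes[30:50]],
            }
        )
        null = make_null_like(z.index, 100, seed=8)
        enr = regulon_enrichment(z, regulons, null).set_index("tf")
        assert enr.loc["PLANTED", "nes"] > 0
        assert enr["nes"].abs().idxmax() == "PLANTED"

    def test_zero_z_targets_score_zero(self):
        genes = [f"g{i}" for i in range(30)]
        z = pd.Series(0.0, index=genes)
        regulons = RegulonSet({"TF": [RegulonTarget(g, 1, 0.5) for g in genes[:10]]})
        null = make_null_like(z.index, 50, seed=9)
        enr = regulon_enrichment(z, regulons, null)
        assert enr["score"].iloc[0] == 0.0

    def test_mode_flip_negates_score_and_nes(self):
        genes = [f"g{i}" for i in range(40)]
        rng = np.random.default_rng(3)
        z = pd.Series(rng.normal(size=40), index=genes)
        fwd = RegulonSet({"TF": [RegulonTarget(g, 1, 0.8) for g in genes[:12]]})
        rev = RegulonSet({"TF": [RegulonTarget(g, -1, 0.8) for g in genes[:12]]})
        null = make_null_like(z.index, 100, seed=10)
        e1 = regulon_enrichment(z, fwd, null).iloc[0]
        # flipping every mode negates both the raw score and each null column,
        # so the NES is exactly antisymmetric
        e2 = regulon_enrichment(z, rev, null).iloc[0]
        assert e2["score"] == pytest.approx(-e1["score"], abs=1e-12)
        assert e2["nes"] == pytest.approx(-e1["nes"], abs=1e-12)

    def test_small_regulon_skipped(self):
        genes = [f"g{i}" for i in range(20)]
        z = pd.Series(1.0, index=genes)
        regulons = RegulonSet({"TINY": [RegulonTarget(g, 1, 1.0) for g in genes[:3]]})
        null = make_null_like(z.index, 20, seed=11)
        enr = regulon_enrichment(z, regulons, null)
        assert enr.empty

    def test_degenerate_null_flagged(self):
        genes = [f"g{i}" for i in range(20)]
        z = pd.Series(1.0, index=genes)
        regulons = RegulonSet({"TF": [RegulonTarget(g, 1, 1.0) for g in genes[:6]]})
        from sigconn.master_regulator import NullScores

        null = NullScores(
            z=pd.DataFrame(0.0, index=z.index, columns=[f"perm{i}" for i in range(30)]),
            seed=0,
        )
        enr = regulon_enrichment(z, regulons, null)
        assert enr["degenerate"].iloc[0]
        assert np.isnan(enr["nes"].iloc[0])

    def test_null_calibration(self):
        # no planted structure: ~5% of TFs at empirical p < 0.05
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(2000)]
        hits = total = 0
        for rep in range(20):
            z = pd.Series(rng.normal(size=2000), index=genes)
            regulons = RegulonSet(
                {
                    f"TF{k}": [
                        RegulonTarget(genes[i], 1, 1.0)
                        for i in rng.choice(2000, 10, replace=False)
                    ]
                    for k in range(10)
                }
            )
            null = make_null_like(z.index, 200, seed=100 + rep)
            enr = regulon_enrichment(z, regulons, null)
            hits += int((enr["p"] < 0.05).sum())
            total += len(enr)
        frac = hits / total
        assert 0.01 <= frac <= 0.12  # binomial tolerance around 0.05 (n=200)


class TestMapToDiseases:
    @pytest.fixture
    def enr(self):
        return pd.DataFrame(
            {
                "tf": ["A", "B", "C"],
                "nes": [3.0, 2.5, -0.1],
                "p": [0.001, 0.002, 0.9],
                "fdr": [0.003, 0.003, 0.9],
                "degenerate": False,
            }
        )

    @pytest.fixture
    def tf_map(self):
        return TFDiseaseMap(
            table=pd.DataFrame(
                {
                    "tf": ["A", "B", "C", "A"],
                    "cui": ["C1", "C1", "C2", "C2"],
                    "disease_name": ["dz1", "dz1", "dz2", "dz2"],
                    "icd9": [["401"], ["401"], ["295.1"], ["295.1"]],
                }
            )
        )

    def test_two_tf_support(self, enr, tf_map):
        out = map_to_diseases(enr, tf_map)
        assert list(out["cui"]) == ["C1"]
        assert out["support"].iloc[0] == 2
        assert out["supporting_tfs"].iloc[0] == "A|B"

    def test_single_tf_disease_excluded(self, enr, tf_map):
        out = map_to_diseases(enr, tf_map)
        assert "C2" not in set(out["cui"])  # only A significant among its links

    def test_no_significant_tfs_empty(self, tf_map):
        enr = pd.DataFrame(
            {"tf": ["A"], "nes": [0.1], "p": [0.9], "fdr": [0.9], "degenerate": False}
        )
        assert map_to_diseases(enr, tf_map).empty

    def test_direction_filter(self, tf_map):
        enr = pd.DataFrame(
            {
                "tf": ["A", "B"],
                "nes": [3.0, -3.0],
                "p": [0.001, 0.001],
                "fdr": [0.002, 0.002],
                "degenerate": False,
            }
        )
        assert map_to_diseases(enr, tf_map, direction="up").empty  # only A up
        both = map_to_diseases(enr, tf_map, direction="both")
        assert len(both) == 1

    def test_min_support_invariant(self, enr, tf_map):
        out = map_to_diseases(enr, tf_map, min_tfs=2)
        assert (out["support"] >= 2).all()


class TestIcd9Rollup:
    def test_circulatory(self):
        assert icd9_rollup(["401"]) == "DISEASES OF THE CIRCULATORY SYSTEM"

    def test_specificity_rule(self):
        # 401 (circulatory) beats 997.91 (injury/poisoning NEC subcode)
        assert icd9_rollup(["401", "997.91"]) == "DISEASES OF THE CIRCULATORY SYSTEM"

    def test_unknown_code_unclassified(self):
        assert icd9_rollup(["X99"]) == "UNCLASSIFIED"

    def test_empty_unclassified(self):
        assert icd9_rollup([]) == "UNCLASSIFIED"

    def test_mental_disorders(self):
        assert icd9_rollup(["295.1"]) == "MENTAL DISORDERS"

    def test_v_code_chapter(self):
        assert icd9_rollup(["V70.0"]).startswith("SUPPLEMENTARY")
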