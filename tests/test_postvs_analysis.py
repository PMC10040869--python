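"""Drug-likeness profiling, score summaries, clustering, t-SNE, Tanimoto."""

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem
from rdkit.Chem import Descriptors, QED

from hitfinder.chem_io import standardize_molecule
from hitfinder.postvs_analysis import (
    ClusteringSpec,
    cluster_library,
    embed_2d,
    profile_compound,
    profile_library,
    summarize_scores,
    tanimoto,
    tanimoto_search,
)
from hitfinder.vectorization import ConfigError, FingerprintMatrix, FingerprintSpec, vectorize_set


class TestProfiles:
    def test_qed_in_unit_interval(self):
        for smiles in ["CCO", "c1ccccc1", "CC(=O)Oc1ccccc1C(=O)O", "O=S(=O)(N)c1ccccc1"]:
            assert 0.0 <= profile_compound(standardize_molecule(smiles)).qed <= 1.0

    def test_notation_invariance(self):
        assert profile_compound(standardize_molecule("OCC")) == profile_compound(
            standardize_molecule("CCO")
        )

    def test_ethanol_against_direct_toolkit_calls(self):
        profile = profile_compound(standardize_molecule("CCO"))
        mol = Chem.MolFromSmiles("CCO")
        assert profile.hbd == Descriptors.NumHDonors(mol) == 1
        assert profile.hba == Descriptors.NumHAcceptors(mol) == 1
        assert profile.rotatable_bonds == Descriptors.NumRotatableBonds(mol) == 0
        assert profile.qed == pytest.approx(QED.qed(mol))
        assert profile.mw == pytest.approx(Descriptors.MolWt(mol))
        assert profile.tpsa == pytest.approx(Descriptors.TPSA(mol))

    def test_library_profile_table(self):
        mols = [standardize_molecule(s) for s in ["CCO", "c1ccccc1O"]]
        df = profile_library(mols)
        assert len(df) == 2
        assert not df["profile_failed"].any()
        assert set(["qed", "mw", "logp", "hba", "hbd", "rotatable_bonds", "tpsa"]) <= set(df.columns)


class TestScoreSummaries:
    def _report(self, scores):
        return pd.DataFrame({"inchikey": [f"K{i}" for i in range(len(scores))],
                             "score_rf": scores})

    def test_histogram_conservation(self):
        rng = np.random.default_rng(0)
        scores = rng.random(500)
        summary = summarize_scores(self._report(scores))["rf"]
        assert sum(summary["counts"]) == 500
        assert len(summary["counts"]) == 50

    def test_constant_scores_single_bin(self):
        summary = summarize_scores(self._report(np.full(100, 0.4321)))["rf"]
        assert sorted(summary["counts"])[-1] == 100
        assert sum(1 for c in summary["counts"] if c) == 1

    def test_mean_consistency(self):
        rng = np.random.default_rng(1)
        scores = rng.random(257)
        summary = summarize_scores(self._report(scores))["rf"]
        assert summary["mean"] == pytest.approx(float(np.mean(scores)), abs=1e-12)


class TestClustering:
    def test_two_separated_blobs_recovered(self):
        rng = np.random.default_rng(2)
        n = 40
        bits = np.zeros((2 * n, 64), dtype=np.uint8)
        bits[:n, :16] = (rng.random((n, 16)) < 0.9).astype(np.uint8)
        bits[n:, 48:] = (rng.random((n, 16)) < 0.9).astype(np.uint8)
        matrix = FingerprintMatrix(
            keys=[f"K{i:03d}" for i in range(2 * n)], bits=bits,
            spec=FingerprintSpec("morgan", n_bits=64),
        )
        scores = np.concatenate([np.full(n, 0.9), np.full(n, 0.1)])
        assignments, table = cluster_library(matrix, ClusteringSpec(n_clusters=2, seed=0), scores)
        assert len(set(assignments[:n])) == 1
        assert len(set(assignments[n:])) == 1
        assert assignments[0] != assignments[-1]
        assert table.loc[0, "mean_score"] == pytest.approx(0.9)

    def test_k_equals_n_degenerate(self):
        rng = np.random.default_rng(3)
        n = 12
        bits = (rng.random((n, 32)) < 0.5).astype(np.uint8)
        matrix = FingerprintMatrix(
            keys=[f"K{i}" for i in range(n)], bits=bits,
            spec=FingerprintSpec("morgan", n_bits=32),
        )
        scores = rng.random(n)
        assignments, table = cluster_library(matrix, ClusteringSpec(n_clusters=n, seed=1), scores)
        assert len(set(assignments)) == n
        assert np.allclose(sorted(table["mean_score"]), sorted(scores))

    def test_same_seed_same_assignments(self):
        rng = np.random.default_rng(4)
        bits = (rng.random((60, 32)) < 0.3).astype(np.uint8)
        matrix = FingerprintMatrix(
            keys=[f"K{i}" for i in range(60)], bits=bits,
            spec=FingerprintSpec("morgan", n_bits=32),
        )
        scores = rng.random(60)
        a, _ = cluster_library(matrix, ClusteringSpec(n_clusters=5, seed=7), scores)
        b, _ = cluster_library(matrix, ClusteringSpec(n_clusters=5, seed=7), scores)
        assert np.array_equal(a, b)

    def test_k_larger_than_n_is_config_error(self):
        matrix = FingerprintMatrix(
            keys=["K1", "K2"], bits=np.zeros((2, 32), dtype=np.uint8),
            spec=FingerprintSpec("morgan", n_bits=32),
        )
        with pytest.raises(ConfigError):
            cluster_library(matrix, ClusteringSpec(n_clusters=5, seed=0), np.zeros(2))


class TestEmbedding:
    def _matrix(self, n=30, seed=5):
        rng = np.random.default_rng(seed)
        bits = (rng.random((n, 64)) < 0.2).astype(np.uint8)
        return FingerprintMatrix(
            keys=[f"K{i:03d}" for i in range(n)], bits=bits,
            spec=FingerprintSpec("morgan", n_bits=64),
        )

    def test_two_coordinates_per_compound(self):
        matrix = self._matrix()
        df = embed_2d(matrix, seed=0)
        assert list(df.columns) == ["inchikey", "x", "y", "group"]
        assert len(df) == len(matrix)

    def test_fixed_seed_reproducible(self):
        matrix = self._matrix()
        a = embed_2d(matrix, seed=1)
        b = embed_2d(matrix, seed=1)
        assert np.allclose(a[["x", "y"]], b[["x", "y"]])

    def test_duplicate_rows_land_together(self):
        matrix = self._matrix(n=20)
        bits = np.vstack([matrix.bits, matrix.bits[:1]])
        dup = FingerprintMatrix(keys=matrix.keys + ["DUP"], bits=bits, spec=matrix.spec)
        df = embed_2d(dup, seed=2)
        orig = df.iloc[0][["x", "y"]].to_numpy(dtype=float)
        copy = df.iloc[-1][["x", "y"]].to_numpy(dtype=float)
        span = max(np.ptp(df["x"]), np.ptp(df["y"]))
        assert np.linalg.norm(orig - copy) < 0.05 * span


class TestTanimoto:
    def test_identity_disjoint_and_example(self):
        a = np.zeros(16, dtype=np.uint8)
        b = np.zeros(16, dtype=np.uint8)
        a[[1, 2, 3]] = 1
        b[[2, 3, 4]] = 1
        assert tanimoto(a, a) == 1.0
        assert tanimoto(a, 1 - a) == 0.0
        assert tanimoto(a, b) == 0.5

    def test_brute_force_oracle_500_pairs(self):
        rng = np.random.default_rng(6)
        for _ in range(500):
            n = int(rng.integers(8, 128))
            a = (rng.random(n) < 0.3).astype(np.uint8)
            b = (rng.random(n) < 0.3).astype(np.uint8)
            sa = set(np.flatnonzero(a))
            sb = set(np.flatnonzero(b))
            expected = len(sa & sb) / len(sa | sb) if sa | sb else 0.0
            assert tanimoto(a, b) == expected
            assert tanimoto(b, a) == tanimoto(a, b)
            assert 0.0 <= tanimoto(a, b) <= 1.0

    def test_all_zero_pair_defined_as_zero(self):
        z = np.zeros(32, dtype=np.uint8)
        assert tanimoto(z, z) == 0.0

    def test_search_self_is_rank_one(self):
        mols = [standardize_molecule(s) for s in ["CCO", "CCN", "c1ccccc1", "CCOC"]]
        spec = FingerprintSpec("morgan", n_bits=512)
        matrix = vectorize_set(mols, spec)
        ranked = tanimoto_search(mols[0], matrix, spec)
        assert ranked.loc[0, "inchikey"] == mols[0].inchikey
        assert ranked.loc[0, "tanimoto"] == 1.0
        assert ranked["rank"].tolist() == [1, 2, 3, 4]
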