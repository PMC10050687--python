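"""Consensus HVG selection, the frozen scale+PCA transform, and MNN
batch correction."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import marrowatlas as ma
from marrowatlas import CellDataset, ReferenceEmbedding
from sklearn.neighbors import NearestNeighbors


def dataset_with_normalized(norm, samples):
    """Build a dataset whose normalized matrix is exactly ``norm``."""
    n_genes, n_cells = norm.shape
    counts = sp.csr_matrix((norm > 0).astype(int))
    ds = CellDataset(
        counts=counts,
        cell_table=pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(n_cells)],
            "sample_id": samples,
            "study_id": "st0",
        }),
        gene_table=pd.DataFrame({
            "gene_id": [f"g{i:02d}" for i in range(n_genes)],
            "symbol": [f"g{i:02d}" for i in range(n_genes)],
        }),
        sample_table=pd.DataFrame({
            "sample_id": sorted(set(samples)), "study_id": "st0",
        }),
    )
    ds.normalized = sp.csr_matrix(norm)
    return ds


class TestConsensusHVG:
    def brute_force(self, norm, samples, per_sample_n, consensus_n):
        """Exhaustive enumeration with the documented tie rules."""
        gene_ids = [f"g{i:02d}" for i in range(norm.shape[0])]
        sample_list = sorted(set(samples))
        tops = {}
        var_by_sample = {}
        for s in sample_list:
            cols = [j for j, x in enumerate(samples) if x == s]
            sub = norm[:, cols]
            var = sub.var(axis=1)
            mean = sub.mean(axis=1)
            ranked = sorted(
                range(len(gene_ids)),
                key=lambda i: (-var[i], -mean[i], gene_ids[i]),
            )
            tops[s] = set(ranked[:per_sample_n])
            var_by_sample[s] = var
        count = {i: sum(i in tops[s] for s in sample_list)
                 for i in range(len(gene_ids))}
        mean_var = {
            i: np.mean([var_by_sample[s][i] for s in sample_list])
            for i in range(len(gene_ids))
        }
        final = sorted(range(len(gene_ids)),
                       key=lambda i: (-count[i], -mean_var[i], gene_ids[i]))
        return [gene_ids[i] for i in final[:consensus_n]]

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(0)
        samples = ["s0"] * 6 + ["s1"] * 6 + ["s2"] * 6
        norm = np.round(rng.gamma(2.0, 1.0, size=(10, 18)), 2)
        ds = dataset_with_normalized(norm, samples)
        got = ma.consensus_hvg(ds, per_sample_n=4, consensus_n=3)
        assert got == self.brute_force(norm, samples, 4, 3)

    def test_single_sample_is_own_top_list(self):
        rng = np.random.default_rng(1)
        norm = rng.gamma(2.0, 1.0, size=(12, 8))
        ds = dataset_with_normalized(norm, ["s0"] * 8)
        got = ma.consensus_hvg(ds, per_sample_n=5, consensus_n=5)
        var = norm.var(axis=1)
        expect = [f"g{i:02d}" for i in np.argsort(-var)[:5]]
        assert got == expect

    def test_gene_in_every_top_list_always_selected(self):
        rng = np.random.default_rng(2)
        samples = ["s0"] * 5 + ["s1"] * 5
        norm = rng.normal(0, 0.1, size=(8, 10)) ** 2
        norm[3] = rng.normal(0, 5.0, size=10) ** 2  # dominant everywhere
        ds = dataset_with_normalized(np.abs(norm), samples)
        got = ma.consensus_hvg(ds, per_sample_n=2, consensus_n=1)
        assert got == ["g03"]

    def test_requesting_more_than_available_warns(self):
        norm = np.random.default_rng(3).gamma(1, 1, size=(5, 6))
        ds = dataset_with_normalized(norm, ["s0"] * 6)
        with pytest.warns(UserWarning, match="returning all"):
            got = ma.consensus_hvg(ds, per_sample_n=5, consensus_n=10)
        assert len(got) == 5


class TestReferenceEmbedding:
    def fit_on(self, norm, samples=None, n_components=4, seed=0):
        samples = samples or ["s0"] * norm.shape[1]
        ds = dataset_with_normalized(norm, samples)
        model = ReferenceEmbedding(n_components=n_components,
                                   random_state=seed)
        model.fit(ds, hvg_genes=list(ds.gene_ids))
        return ds, model

    def test_rank_deficient_data_has_tiny_trailing_variance(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 10))
        coords = rng.normal(size=(40, 2))
        norm = (coords @ basis).T  # genes x cells, rank 2
        _, model = self.fit_on(norm, n_components=5)
        assert (model.explained_variance_[2:] < 1e-8).all()

    def test_variance_nonincreasing_and_loadings_orthonormal(self, ref_norm, atlas):
        ev = atlas.embedding_model.explained_variance_
        assert (np.diff(ev) <= 1e-9).all()
        L = atlas.embedding_model.loadings_
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-6)

    def test_embedding_equals_scaled_times_loadings(self):
        rng = np.random.default_rng(1)
        norm = rng.gamma(2, 1, size=(15, 30))
        ds, model = self.fit_on(norm)
        X = norm.T
        Xs = np.clip((X - model.scale_means_) / model.scale_sds_, -10, 10)
        assert np.allclose(model.embedding_, Xs @ model.loadings_, atol=1e-6)

    def test_reference_projects_onto_itself(self, ref_norm, atlas):
        model = atlas.embedding_model
        proj = model.transform(ref_norm)
        assert np.allclose(proj, model.embedding_, atol=1e-6)

    def test_all_zero_query(self):
        rng = np.random.default_rng(2)
        norm = rng.gamma(2, 1, size=(12, 25))
        ds, model = self.fit_on(norm)
        zero = dataset_with_normalized(np.zeros((12, 3)), ["s0"] * 3)
        got = model.transform(zero)
        expect = np.clip(-model.scale_means_ / model.scale_sds_, -10, 10) \
            @ model.loadings_
        assert np.allclose(got, np.tile(expect, (3, 1)))

    def test_projection_linearity(self):
        rng = np.random.default_rng(3)
        norm = rng.gamma(2, 1, size=(10, 20))
        ds, model = self.fit_on(norm)
        # work on centred inputs so clipping never triggers
        x = rng.normal(0, 0.1, size=10) + model.scale_means_
        y = rng.normal(0, 0.1, size=10) + model.scale_means_

        def project(v):
            q = dataset_with_normalized(v[:, None], ["s0"])
            return model.transform(q)[0]

        a, b = 0.3, 0.7
        combo = a * x + b * y + (1 - a - b) * model.scale_means_
        assert np.allclose(project(combo),
                           a * project(x) + b * project(y)
                           + (1 - a - b) * project(model.scale_means_),
                           atol=1e-8)

    def test_insufficient_gene_overlap_raises(self):
        rng = np.random.default_rng(4)
        norm = rng.gamma(2, 1, size=(10, 20))
        ds, model = self.fit_on(norm)
        query = dataset_with_normalized(norm[:4], ["s0"] * 20)
        with pytest.raises(ValueError, match="feature genes"):
            model.transform(query)

    def test_too_many_components_raises(self):
        norm = np.random.default_rng(5).gamma(2, 1, size=(6, 5))
        with pytest.raises(ValueError, match="n_components"):
            self.fit_on(norm, n_components=10)


class TestBatchCorrect:
    def test_single_study_identity(self):
        rng = np.random.default_rng(0)
        emb = rng.normal(size=(50, 5))
        out, _ = ma.batch_correct_mnn(emb, ["s"] * 50)
        assert np.array_equal(out, emb)

    def _offset_pair(self, seed=1, offset=4.0, n=150):
        # biology spans dims 0-2; the batch shift acts on dim 4 — the
        # orthogonal-batch-vector setting MNN correction assumes
        rng = np.random.default_rng(seed)
        base = np.zeros((n, 6))
        base[:, :3] = rng.normal(size=(n, 3))
        shift = np.zeros(6)
        shift[4] = offset
        emb = np.vstack([base, base + shift])
        studies = ["a"] * n + ["b"] * n
        return emb, studies, n

    def test_constant_offset_removed(self):
        emb, studies, n = self._offset_pair()
        out, info = ma.batch_correct_mnn(emb, studies, k_mnn=10)
        before = np.linalg.norm(emb[:n].mean(0) - emb[n:].mean(0))
        after = np.linalg.norm(out[:n].mean(0) - out[n:].mean(0))
        assert after <= 0.1 * before

    def test_within_study_neighbours_preserved(self):
        emb, studies, n = self._offset_pair(seed=2)
        out, _ = ma.batch_correct_mnn(emb, studies, k_mnn=10)
        k = 10
        overlaps = []
        for block in (slice(0, n), slice(n, 2 * n)):
            nn0 = NearestNeighbors(n_neighbors=k + 1).fit(emb[block])
            nn1 = NearestNeighbors(n_neighbors=k + 1).fit(out[block])
            a = nn0.kneighbors(return_distance=False)
            b = nn1.kneighbors(return_distance=False)
            overlaps.append(np.mean([
                len(set(a[i]) & set(b[i])) / k for i in range(n)
            ]))
        assert min(overlaps) >= 0.8

    def test_small_study_reduces_k_with_warning(self):
        rng = np.random.default_rng(3)
        emb = np.vstack([rng.normal(size=(40, 4)), rng.normal(size=(5, 4))])
        studies = ["a"] * 40 + ["b"] * 5
        with pytest.warns(UserWarning, match="k_mnn"):
            out, _ = ma.batch_correct_mnn(emb, studies, k_mnn=20)
        assert out.shape == emb.shape
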