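"""Pseudobulk aggregation, the age-gene Pearson screen, and local ORA."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import t as t_dist

import marrowatlas as ma
from marrowatlas import CellDataset
from marrowatlas.pseudobulk import PseudobulkTable


def labelled_dataset(rng, n_samples=4, cells_per=14, n_genes=6):
    """Small dataset with two cell types and known normalized values."""
    n_cells = n_samples * cells_per
    counts = rng.poisson(5.0, size=(n_genes, n_cells)) + 1
    samples = np.repeat([f"s{i}" for i in range(n_samples)], cells_per)
    labels = np.tile(["T"] * (cells_per // 2) + ["B"] * (cells_per - cells_per // 2),
                     n_samples)
    ds = CellDataset(
        counts=sp.csr_matrix(counts),
        cell_table=pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(n_cells)],
            "sample_id": samples, "study_id": "st0", "label": labels,
        }),
        gene_table=pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n_genes)],
            "symbol": [f"g{i}" for i in range(n_genes)],
        }),
        sample_table=pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n_samples)],
            "study_id": "st0",
            "age_years": np.linspace(20, 70, n_samples),
        }),
    )
    return ma.normalize_total(ds)


class TestPseudobulk:
    def test_means_match_naive_averages(self):
        ds = labelled_dataset(np.random.default_rng(0))
        pb = ma.pseudobulk(ds, min_cells=1, min_samples=1, detect_fraction=0.0)
        norm = ds.normalized.toarray()
        for (sid, ct) in pb.values.index:
            cols = [
                j for j in range(ds.n_cells)
                if ds.cell_table["sample_id"][j] == sid
                and ds.cell_table["label"][j] == ct
            ]
            naive = norm[:, cols].mean(axis=1)
            assert np.allclose(pb.values.loc[(sid, ct)].to_numpy(), naive)
            assert pb.cells_per_entry.loc[(sid, ct)] == len(cols)

    def test_type_in_19_samples_ineligible(self):
        ds = labelled_dataset(np.random.default_rng(1), n_samples=19,
                              cells_per=44)
        pb = ma.pseudobulk(ds, min_cells=20, min_samples=20)
        assert pb.eligible_cell_types == []
        ds20 = labelled_dataset(np.random.default_rng(1), n_samples=20,
                                cells_per=44)
        pb20 = ma.pseudobulk(ds20, min_cells=20, min_samples=20)
        assert set(pb20.eligible_cell_types) == {"B", "T"}

    def test_detection_boundary_is_strict(self):
        """A gene detected in exactly 10.0% of a type's cells is excluded."""
        rng = np.random.default_rng(2)
        ds = labelled_dataset(rng, n_samples=2, cells_per=20)  # 20 T cells
        counts = ds.counts.toarray()
        t_cols = np.nonzero((ds.cell_table["label"] == "T").to_numpy())[0]
        counts[0, :] = 0
        counts[0, t_cols[:2]] = 3   # exactly 2/20 = 10.0% of T cells
        ds2 = CellDataset(sp.csr_matrix(counts), ds.cell_table, ds.gene_table,
                          ds.sample_table)
        ds2 = ma.normalize_total(ds2)
        pb = ma.pseudobulk(ds2, min_cells=1, min_samples=1,
                           detect_fraction=0.10)
        assert "g0" not in pb.eligible_genes["T"]
        # one more detected cell tips it over the strict boundary
        counts[0, t_cols[2]] = 3
        ds3 = ma.normalize_total(CellDataset(
            sp.csr_matrix(counts), ds.cell_table, ds.gene_table,
            ds.sample_table))
        pb3 = ma.pseudobulk(ds3, min_cells=1, min_samples=1,
                            detect_fraction=0.10)
        assert "g0" in pb3.eligible_genes["T"]

    def test_filter_order_independence(self, screen_cohort):
        """Gene eligibility restricted to eligible types equals computing
        gene eligibility first and then dropping ineligible types."""
        pb = screen_cohort["pb"]
        loose = ma.pseudobulk(screen_cohort["ds"], min_cells=1, min_samples=1)
        for ct in pb.eligible_cell_types:
            assert pb.eligible_genes[ct] == loose.eligible_genes[ct]

    def test_no_eligible_types_warns(self):
        ds = labelled_dataset(np.random.default_rng(3))
        with pytest.warns(UserWarning, match="no eligible cell types"):
            ma.pseudobulk(ds, min_cells=100, min_samples=100)


class TestAgeCorrelation:
    def make_pb(self, X, genes, ct="T"):
        samples = [f"s{i}" for i in range(X.shape[0])]
        idx = pd.MultiIndex.from_tuples([(s, ct) for s in samples],
                                        names=["sample_id", "cell_type"])
        values = pd.DataFrame(X, index=idx, columns=genes)
        return PseudobulkTable(
            values=values,
            cells_per_entry=pd.Series(30, index=idx),
            eligible_cell_types=[ct],
            eligible_genes={ct: list(genes)},
            min_cells=20,
        )

    def test_perfect_linear_gene(self):
        ages = np.linspace(10, 80, 12)
        pb = self.make_pb(np.column_stack([2 + 0.05 * ages]), ["g0"])
        agt = ma.age_correlation(pb, dict(zip(pb.values.index.get_level_values(0), ages)))
        assert agt.iloc[0]["pearson_r"] == pytest.approx(1.0)
        assert agt.iloc[0]["p"] < 1e-10

    def test_closed_form_oracle_on_printed_vectors(self):
        # six fixed (age, expression) pairs
        ages = np.array([5.0, 18.0, 33.0, 47.0, 61.0, 80.0])
        expr = np.array([1.10, 1.45, 1.32, 1.80, 1.66, 2.05])
        pb = self.make_pb(expr[:, None], ["g0"])
        ages_map = dict(zip(pb.values.index.get_level_values(0), ages))
        agt = ma.age_correlation(pb, ages_map, keep_all=True)
        # independent closed form: r via definition, p via t transform
        r = (np.sum((ages - ages.mean()) * (expr - expr.mean()))
             / math.sqrt(np.sum((ages - ages.mean()) ** 2)
                         * np.sum((expr - expr.mean()) ** 2)))
        t = r * math.sqrt((6 - 2) / (1 - r * r))
        p = 2 * t_dist.sf(abs(t), df=4)
        assert agt.iloc[0]["pearson_r"] == pytest.approx(r, abs=1e-12)
        assert agt.iloc[0]["p"] == pytest.approx(p, abs=1e-12)

    def test_null_retention_near_threshold(self):
        """Pure-noise genes are retained at ~ the p threshold."""
        rng = np.random.default_rng(9)
        n_samples, n_genes = 40, 10_000
        X = rng.normal(size=(n_samples, n_genes))
        genes = [f"g{i}" for i in range(n_genes)]
        pb = self.make_pb(X, genes)
        ages = dict(zip(pb.values.index.get_level_values(0),
                        rng.uniform(2, 84, n_samples)))
        agt = ma.age_correlation(pb, ages, p_threshold=0.01)
        rate = len(agt) / n_genes
        # 3 sigma around 0.01 for 10,000 draws
        assert 0.007 <= rate <= 0.013

    def test_zero_variance_gene_skipped(self):
        ages = np.linspace(10, 80, 8)
        X = np.column_stack([np.full(8, 3.0), 1 + 0.01 * ages])
        pb = self.make_pb(X, ["flat", "rising"])
        ages_map = dict(zip(pb.values.index.get_level_values(0), ages))
        with pytest.warns(UserWarning, match="zero-variance"):
            agt = ma.age_correlation(pb, ages_map, keep_all=True)
        assert list(agt["gene_id"]) == ["rising"]


class TestSharedGeneSummary:
    def make_table(self):
        return pd.DataFrame({
            "cell_type": ["T", "B", "NK", "T"],
            "gene_id": ["g1", "g1", "g1", "g2"],
            "pearson_r": [0.5, 0.6, -0.4, 0.7],
            "p": [0.001] * 4,
            "direction": ["up", "up", "down", "up"],
        })

    def test_counts_match_brute_force(self):
        out = ma.shared_gene_summary(self.make_table()).set_index("gene_id")
        assert out.loc["g1", "n_cell_types"] == 3
        assert out.loc["g2", "n_cell_types"] == 1
        assert not out.loc["g1", "direction_consistent"]
        assert out.loc["g2", "direction_consistent"]

    def test_double_counting_identity(self, screen_cohort):
        agt = ma.age_correlation(screen_cohort["pbc"], screen_cohort["ages"])
        out = ma.shared_gene_summary(agt)
        assert out["n_cell_types"].sum() == len(agt)

    def test_empty_table_raises(self):
        with pytest.raises(ValueError, match="non-empty"):
            ma.shared_gene_summary(pd.DataFrame(columns=["gene_id", "direction"]))


class TestORA:
    universe = [f"g{i}" for i in range(100)]

    def test_disjoint_set_p_one(self):
        out = ma.ora_enrichment(
            hits=self.universe[:10],
            gene_sets={"s": self.universe[50:60]},
            universe=self.universe,
        )
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_exact_tail_sum_oracle(self):
        """M=100, K=10, n=10, overlap 5: p from direct summation."""
        hits = self.universe[:10]
        gset = self.universe[5:15]  # overlap exactly 5
        out = ma.ora_enrichment(hits, {"s": gset}, self.universe)
        p_direct = sum(
            math.comb(10, k) * math.comb(90, 10 - k) / math.comb(100, 10)
            for k in range(5, 11)
        )
        assert out.iloc[0]["p"] == pytest.approx(p_direct, rel=1e-12)

    def test_set_equal_to_universe_uninformative(self):
        out = ma.ora_enrichment(self.universe[:7], {"all": self.universe},
                                self.universe)
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_hits_outside_universe_listed(self):
        with pytest.raises(ValueError, match="zzz"):
            ma.ora_enrichment(["g1", "zzz"], {"s": ["g1"]}, self.universe)

    def test_bh_monotone_and_planted_set_enriched(self):
        rng = np.random.default_rng(4)
        hits = self.universe[:15]
        sets = {"planted": self.universe[:12]}
        for i in range(20):
            sets[f"rand{i}"] = list(rng.choice(self.universe, 10, replace=False))
        out = ma.ora_enrichment(hits, sets, self.universe)
        assert out.iloc[0]["gene_set"] == "planted"
        assert out.iloc[0]["significant"]
        s = out.sort_values("p", kind="stable")
        assert (np.diff(s["p_adj"].to_numpy()) >= -1e-12).all()

    def test_gmt_roundtrip(self, tmp_path):
        sets = {"a": {"g1", "g2"}, "b": {"g3"}}
        ma.write_gmt(sets, tmp_path / "x.gmt")
        assert ma.read_gmt(tmp_path / "x.gmt") == sets
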