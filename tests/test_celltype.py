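"""KS cell-type enrichment, deconvolution, proportion tests and cwFC."""

import numpy as np
import pandas as pd
import pytest

from pituiseq import celltype, synthetic
from pituiseq.errors import InputError


def _bruteforce_ks_greater(in_type, others):
    grid = sorted(set(in_type) | set(others))
    best = 0.0
    for x in grid:
        f_in = sum(v <= x for v in in_type) / len(in_type)
        f_out = sum(v <= x for v in others) / len(others)
        best = max(best, f_out - f_in)
    return best


class TestKS:
    def test_d_matches_cdf_oracle_on_five_point_samples(self):
        cases = [
            ([1, 2, 3, 4, 5], [0.5, 1.5, 2.5, 3.5, 4.5]),
            ([2, 2, 3, 9, 10], [1, 2, 3, 4, 5]),
            ([1, 1, 1, 1, 1], [2, 2, 2, 2, 2]),
            ([5, 6, 7, 8, 9], [5, 6, 7, 8, 9]),
        ]
        for in_type, others in cases:
            d, _ = celltype.ks_greater(np.array(in_type), np.array(others))
            assert d == pytest.approx(_bruteforce_ks_greater(in_type, others), abs=1e-12)

    def test_identical_distributions_null(self):
        v = np.arange(20.0)
        d, p = celltype.ks_greater(v, v)
        assert d == 0.0 and p == 1.0

    def test_random_samples_match_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(200):
            a = rng.integers(0, 6, size=rng.integers(3, 12)).astype(float)
            b = rng.integers(0, 6, size=rng.integers(3, 12)).astype(float)
            d, _ = celltype.ks_greater(a, b)
            assert d == pytest.approx(_bruteforce_ks_greater(list(a), list(b)), abs=1e-12)

    def test_fourfold_elevated_gene_detected(self):
        """A gene lognormally 4-fold higher in one type is KS-significant
        there in >= 95% of simulations."""
        rng = np.random.default_rng(15)
        hits = runs = 0
        for _ in range(40):
            runs += 1
            cells = {
                "gene1": np.concatenate(
                    [rng.lognormal(np.log(4.0), 0.5, 200), rng.lognormal(0.0, 0.5, 400)]
                )
            }
            expr = pd.DataFrame(cells, index=[f"c{i}" for i in range(600)])
            labels = pd.Series(
                ["T1"] * 200 + ["T2"] * 200 + ["T3"] * 200, index=expr.index
            )
            ks = celltype.ks_celltype_enrichment(["gene1"], expr, labels)
            row = ks.set_index("celltype").loc["T1"]
            hits += bool(row.FDR <= 0.05)
        assert hits / runs >= 0.95

    def test_absent_gene_skipped_and_logged(self, cell_reference):
        ks = celltype.ks_celltype_enrichment(
            ["g0000", "not_a_gene"], cell_reference.cell_expr, cell_reference.labels
        )
        assert ks.attrs["skipped"] == ["not_a_gene"]
        assert set(ks.gene) == {"g0000"}

    def test_small_cell_types_rejected(self):
        expr = pd.DataFrame({"g": np.ones(30)}, index=[f"c{i}" for i in range(30)])
        labels = pd.Series(["A"] * 25 + ["B"] * 5, index=expr.index)
        with pytest.raises(InputError):
            celltype.ks_celltype_enrichment(["g"], expr, labels)


class TestHypergeometric:
    def test_exact_enumeration_example(self):
        ks = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(20)],
                "celltype": "T1",
                "D": 0.5,
                "p": 0.01,
                "FDR": [0.01] * 10 + [0.5] * 10,
            }
        )
        membership = pd.Series(
            [1] * 5 + [2] * 15, index=[f"g{i}" for i in range(20)]
        )
        out = celltype.module_celltype_enrichment(ks, membership)
        row = out.set_index("module").loc[1]
        # N=20, K=10, n=5, k=5 -> C(10,5)/C(20,5) = 252/15504
        assert row.p == pytest.approx(252 / 15504, rel=1e-12)

    def test_zero_hits_p_is_one(self):
        ks = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(10)],
                "celltype": "T1",
                "D": 0.1,
                "p": 0.9,
                "FDR": 0.9,
            }
        )
        membership = pd.Series([1] * 4 + [2] * 6, index=[f"g{i}" for i in range(10)])
        out = celltype.module_celltype_enrichment(ks, membership)
        assert (out.p == 1.0).all()

    def test_matches_exact_enumeration_small_universes(self):
        from math import comb

        rng = np.random.default_rng(16)
        for _ in range(50):
            N = int(rng.integers(8, 26))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            genes = [f"g{i}" for i in range(N)]
            sig = set(rng.choice(genes, size=K, replace=False))
            mod_genes = set(rng.choice(genes, size=n, replace=False))
            k = len(sig & mod_genes)
            ks = pd.DataFrame(
                {
                    "gene": genes,
                    "celltype": "T",
                    "D": 0.5,
                    "p": 0.5,
                    "FDR": [0.01 if g in sig else 0.9 for g in genes],
                }
            )
            membership = pd.Series(
                [1 if g in mod_genes else 2 for g in genes], index=genes
            )
            out = celltype.module_celltype_enrichment(ks, membership)
            expected = sum(
                comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1)
            ) / comb(N, n)
            assert out.set_index("module").loc[1, "p"] == pytest.approx(expected, rel=1e-9)

    def test_marker_module_enriched_in_its_type(self, cell_reference):
        ref = cell_reference
        module_genes = []
        membership = {}
        for i, (ct, markers) in enumerate(sorted(ref.markers.items())):
            module_genes += markers
            for g in markers:
                membership[g] = i + 1
        ks = celltype.ks_celltype_enrichment(module_genes, ref.cell_expr, ref.labels)
        out = celltype.module_celltype_enrichment(ks, pd.Series(membership))
        first_type = sorted(ref.markers)[0]
        row = out[(out.module == 1) & (out.celltype == first_type)].iloc[0]
        assert row.FDR < 0.05


class TestDeconvolution:
    def test_noiseless_mixture_recovered_exactly(self, cell_reference):
        sig = celltype.build_signature(
            cell_reference.cell_expr, cell_reference.labels, n_top_variance=300
        )
        p_true = np.array([0.4, 0.3, 0.15, 0.1, 0.05])
        bulk = pd.DataFrame({"x": sig.S.to_numpy() @ p_true}, index=sig.S.index)
        est = celltype.deconvolve(sig, bulk)
        assert np.abs(est.proportions.to_numpy()[0] - p_true).max() <= 1e-6

    def test_single_signature_column_gives_unit_vector(self, cell_reference):
        sig = celltype.build_signature(
            cell_reference.cell_expr, cell_reference.labels, n_top_variance=300
        )
        ct = sig.S.columns[2]
        bulk = pd.DataFrame({"x": sig.S[ct]}, index=sig.S.index)
        est = celltype.deconvolve(sig, bulk)
        p = est.proportions.iloc[0]
        assert p[ct] == pytest.approx(1.0, abs=1e-6)

    def test_proportions_on_simplex(self, cell_reference):
        sig = celltype.build_signature(
            cell_reference.cell_expr, cell_reference.labels, n_top_variance=300
        )
        est = celltype.deconvolve(sig, cell_reference.bulk)
        p = est.proportions.to_numpy()
        assert (p >= 0).all()
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_nb_mixture_error_small(self, cell_reference):
        sig = celltype.build_signature(
            cell_reference.cell_expr, cell_reference.labels, n_top_variance=300
        )
        mae = celltype.mixture_benchmark(sig, n_samples=25, seed=3)
        assert mae <= 0.02

    def test_too_few_shared_genes(self, cell_reference):
        sig = celltype.build_signature(
            cell_reference.cell_expr, cell_reference.labels, n_top_variance=300
        )
        bulk = pd.DataFrame({"x": [1.0] * 3}, index=["a", "b", "c"])
        with pytest.raises(InputError, match="shared"):
            celltype.deconvolve(sig, bulk)


class TestProportionSexTest:
    def test_identical_groups_p_one(self):
        props = pd.DataFrame(
            {"T1": [0.2, 0.3, 0.4, 0.2, 0.3, 0.4], "T2": [0.8, 0.7, 0.6, 0.8, 0.7, 0.6]},
            index=[f"s{i}" for i in range(6)],
        )
        est = celltype.ProportionEstimate(props, pd.Series(0.0, index=props.index))
        meta = pd.DataFrame(
            {"sex": ["F"] * 3 + ["M"] * 3, "age": "PD12"}, index=props.index
        )
        out = celltype.test_proportion_sex_difference(est, meta)
        assert (out.p == 1.0).all()

    def test_separated_groups_exact_p(self):
        props = pd.DataFrame(
            {"T1": [0.10, 0.11, 0.12, 0.20, 0.21, 0.22]},
            index=[f"s{i}" for i in range(6)],
        )
        est = celltype.ProportionEstimate(props, pd.Series(0.0, index=props.index))
        meta = pd.DataFrame(
            {"sex": ["F"] * 3 + ["M"] * 3, "age": "PD12"}, index=props.index
        )
        out = celltype.test_proportion_sex_difference(est, meta)
        assert out.p.iloc[0] == pytest.approx(0.1)
        assert out.method.iloc[0] == "exact"

    def test_simulated_proportion_shift_detected(self):
        rng = np.random.default_rng(18)
        hits = runs = 0
        for _ in range(30):
            runs += 1
            f = np.clip(rng.normal(0.30, 0.02, 6), 0, 1)
            m = np.clip(rng.normal(0.38, 0.02, 6), 0, 1)
            props = pd.DataFrame({"Somatotrope": np.concatenate([f, m])})
            props.index = [f"s{i}" for i in range(12)]
            est = celltype.ProportionEstimate(props, pd.Series(0.0, index=props.index))
            meta = pd.DataFrame(
                {"sex": ["F"] * 6 + ["M"] * 6, "age": "PD27"}, index=props.index
            )
            out = celltype.test_proportion_sex_difference(est, meta)
            hits += bool(out.p.iloc[0] < 0.05)
        assert hits / runs >= 0.9

    def test_group_size_enforced(self):
        props = pd.DataFrame({"T1": [0.1, 0.2, 0.3]}, index=["a", "b", "c"])
        est = celltype.ProportionEstimate(props, pd.Series(0.0, index=props.index))
        meta = pd.DataFrame({"sex": ["F", "F", "M"], "age": "PD12"}, index=props.index)
        with pytest.raises(InputError):
            celltype.test_proportion_sex_difference(est, meta)


def _uniform_props(index, types):
    p = pd.DataFrame(1.0 / len(types), index=index, columns=types)
    return celltype.ProportionEstimate(p, pd.Series(0.0, index=index))


class TestCwFC:
    def _setup(self, s_rows, types=("T1", "T2", "T3", "T4")):
        genes = list(s_rows.keys())
        S = pd.DataFrame.from_dict(s_rows, orient="index", columns=list(types))
        sig = celltype.SignatureMatrix(S=S, marker_type=S.idxmax(axis=1))
        samples = [f"s{i}" for i in range(8)]
        meta = pd.DataFrame({"sex": ["F"] * 4 + ["M"] * 4}, index=samples)
        props = _uniform_props(samples, list(types))
        return sig, props, meta

    def test_single_type_gene_fully_assigned(self):
        sig, props, meta = self._setup({"gA": [50.0, 0.0, 0.0, 0.0]})
        de = pd.DataFrame({"gene": ["gA"], "log2FC": [1.2]})
        out = celltype.compute_cwfc(de, sig, props, meta)
        row = out.set_index("celltype").loc["T1"]
        assert row.cwfc_norm == pytest.approx(1.0) and bool(row.called)

    def test_uniform_four_type_gene_never_called(self):
        sig, props, meta = self._setup({"gB": [10.0, 10.0, 10.0, 10.0]})
        de = pd.DataFrame({"gene": ["gB"], "log2FC": [-2.0]})
        out = celltype.compute_cwfc(de, sig, props, meta)
        assert np.allclose(out.cwfc_norm.abs(), 0.25)
        assert not out.called.any()

    def test_sign_matches_bulk_log2fc(self):
        sig, props, meta = self._setup(
            {"gC": [5.0, 1.0, 0.5, 0.1], "gD": [0.2, 8.0, 1.0, 3.0]}
        )
        de = pd.DataFrame({"gene": ["gC", "gD"], "log2FC": [1.5, -0.9]})
        out = celltype.compute_cwfc(de, sig, props, meta)
        for _, row in out.iterrows():
            lfc = de.set_index("gene").loc[row.gene, "log2FC"]
            if row.cwfc != 0:
                assert np.sign(row.cwfc) == np.sign(lfc)

    def test_norms_sum_to_one_per_gene(self):
        sig, props, meta = self._setup(
            {"gC": [5.0, 1.0, 0.5, 0.1], "gD": [0.2, 8.0, 1.0, 3.0]}
        )
        de = pd.DataFrame({"gene": ["gC", "gD"], "log2FC": [1.5, -0.9]})
        out = celltype.compute_cwfc(de, sig, props, meta)
        sums = out.groupby("gene").cwfc_norm.apply(lambda v: v.abs().sum())
        assert np.allclose(sums, 1.0)

    def test_missing_gene_dropped_and_logged(self):
        sig, props, meta = self._setup({"gA": [50.0, 0.0, 0.0, 0.0]})
        de = pd.DataFrame({"gene": ["gA", "gX"], "log2FC": [1.0, 1.0]})
        out = celltype.compute_cwfc(de, sig, props, meta)
        assert out.attrs["dropped"] == ["gX"]

    def test_proportion_shift_localizes_sex_bias(self, cell_reference):
        """Bulk sex bias driven purely by a sex-biased proportion of one
        cell type is predominantly called in marker genes of that type."""
        ref = cell_reference
        sig = celltype.build_signature(ref.cell_expr, ref.labels, n_top_variance=300)
        est = celltype.deconvolve(sig, ref.bulk)
        # bulk log2FC of the shifted type's markers, M vs F
        male = ref.bulk_meta.sex == "M"
        cpm = ref.bulk / ref.bulk.sum(axis=0) * 1e6
        shifted = ref.markers["Somatotrope"]  # male-shifted in the generator
        lfc = np.log2(
            cpm.loc[shifted, male.to_numpy()].mean(axis=1)
            / cpm.loc[shifted, (~male).to_numpy()].mean(axis=1)
        )
        de = pd.DataFrame({"gene": shifted, "log2FC": lfc.to_numpy()})
        out = celltype.compute_cwfc(de, sig, est, ref.bulk_meta)
        called = out[out.called]
        assert len(called) > 0
        assert (called.celltype == "Somatotrope").mean() >= 0.8
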