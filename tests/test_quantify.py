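"""TPM normalization, KO aggregation, expression ratios and rollups."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amdtox import quantify as q
from amdtox.errors import SchemaError, ValidationError


def frame(counts, genes, columns=("s1",)):
    counts = np.atleast_2d(np.asarray(counts, dtype=float)).T
    return pd.DataFrame(counts, index=genes["gene_id"][: counts.shape[0]], columns=list(columns))


class TestComputeTPM:
    def test_hand_calculation(self):
        genes = pd.DataFrame({"gene_id": ["a", "b"], "length": [100, 400]})
        counts = frame([10, 10], genes)
        tpm = q.compute_tpm(counts, genes)
        # rates 0.1 and 0.025 -> shares 0.8 / 0.2
        assert tpm.loc["a", "s1"] == pytest.approx(800_000)
        assert tpm.loc["b", "s1"] == pytest.approx(200_000)

    def test_single_gene_gets_full_million(self):
        genes = pd.DataFrame({"gene_id": ["a"], "length": [250]})
        tpm = q.compute_tpm(frame([7], genes), genes)
        assert tpm.loc["a", "s1"] == pytest.approx(1e6)

    def test_all_zero_sample_stays_zero(self):
        genes = pd.DataFrame({"gene_id": ["a", "b"], "length": [100, 200]})
        tpm = q.compute_tpm(frame([0, 0], genes), genes)
        assert (tpm["s1"] == 0).all()

    def test_nonpositive_length_rejected(self):
        genes = pd.DataFrame({"gene_id": ["a"], "length": [0]})
        with pytest.raises(SchemaError):
            q.compute_tpm(frame([5], genes), genes)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_columns_sum_to_one_million(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        genes = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(n)],
             "length": rng.integers(100, 5000, n)}
        )
        counts = pd.DataFrame(
            rng.integers(0, 1000, size=(n, 2)), index=genes["gene_id"], columns=["s1", "s2"]
        )
        tpm = q.compute_tpm(counts, genes)
        for col in tpm:
            total = counts[col].sum()
            expected = 1e6 if total > 0 else 0.0
            assert tpm[col].sum() == pytest.approx(expected, rel=1e-6)


class TestAggregateByKO:
    def test_additivity(self):
        genes = pd.DataFrame(
            {"gene_id": ["a", "b"], "length": [100, 400], "ko": ["K00001", "K00001"]}
        )
        tpm = q.compute_tpm(frame([10, 10], genes), genes)
        profile = q.aggregate_by_ko_tpm(tpm, genes)
        assert profile.loc["K00001", "s1"] == pytest.approx(1e6)

    def test_unannotated_contribute_to_no_row_but_to_denominator(self, toy_genes, toy_counts):
        tpm = q.compute_tpm(toy_counts, toy_genes)
        profile = q.aggregate_by_ko_tpm(tpm, toy_genes)
        assert set(profile.index) == {"K00001", "K00002"}
        annotated = toy_genes.loc[toy_genes["ko"].notna(), "gene_id"]
        assert profile.sum().to_numpy() == pytest.approx(
            tpm.loc[annotated].sum().to_numpy()
        )

    def test_matches_brute_force_groupby(self):
        rng = np.random.default_rng(5)
        n = 20
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "length": rng.integers(100, 2000, n),
                "ko": rng.choice(["K00001", "K00002", "K00003", "K00004"], n),
            }
        )
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(n, 3)),
            index=genes["gene_id"],
            columns=["s1", "s2", "s3"],
        )
        tpm = q.compute_tpm(counts, genes)
        profile = q.aggregate_by_ko_tpm(tpm, genes)
        for ko in genes["ko"].unique():
            members = genes.loc[genes["ko"] == ko, "gene_id"]
            brute = tpm.loc[members].sum()
            assert profile.loc[ko].to_numpy() == pytest.approx(brute.to_numpy())

    def test_permutation_invariance(self, toy_genes, toy_counts):
        tpm = q.compute_tpm(toy_counts, toy_genes)
        reference = q.aggregate_by_ko_tpm(tpm, toy_genes)
        perm = toy_genes.sample(frac=1, random_state=1)
        shuffled = q.aggregate_by_ko_tpm(
            q.compute_tpm(toy_counts.loc[perm["gene_id"]], perm), perm
        )
        pd.testing.assert_frame_equal(reference, shuffled)


class TestExpressionRatio:
    def make(self, rna, dna):
        r = pd.DataFrame({"s1": rna}, index=[f"K0000{i}" for i in range(1, len(rna) + 1)])
        d = pd.DataFrame({"s1": dna}, index=[f"K0000{i}" for i in range(1, len(dna) + 1)])
        return q.expression_ratio(r, d)

    def test_equal_tpm_gives_one(self):
        assert self.make([500.0], [500.0]).loc["K00001", "s1"] == pytest.approx(1.0)

    def test_zero_dna_is_missing_not_infinite(self):
        out = self.make([300.0], [0.0])
        assert np.isnan(out.loc["K00001", "s1"])

    def test_zero_rna_with_positive_dna_is_zero(self):
        assert self.make([0.0], [400.0]).loc["K00001", "s1"] == 0.0

    def test_outer_join_over_kos(self):
        r = pd.DataFrame({"s1": [10.0]}, index=["K00001"])
        d = pd.DataFrame({"s1": [20.0]}, index=["K00002"])
        out = q.expression_ratio(r, d)
        assert np.isnan(out.loc["K00001", "s1"])  # DNA absent -> 0 -> missing
        assert out.loc["K00002", "s1"] == 0.0


class TestSubsetAndFraction:
    def test_subset_restricts_in_catalog_order(self, mrg_catalog):
        profile = pd.DataFrame(
            {"s1": [1.0, 2.0, 3.0]}, index=["K03325", "K99991", "K13283"]
        )
        sub = q.mrg_subset_profile(profile, mrg_catalog)
        assert list(sub.index) == [k for k in mrg_catalog.kos if k in {"K03325", "K13283"}]

    def test_empty_catalog_like_object(self):
        class Empty:
            kos: list = []
        profile = pd.DataFrame({"s1": [1.0]}, index=["K00001"])
        assert q.mrg_subset_profile(profile, Empty()).empty

    def test_annotated_fraction_extremes(self, mrg_catalog):
        all_in = pd.DataFrame(
            {"gene_id": ["a", "b"], "length": [100, 100], "ko": ["K03325", "K13283"]}
        )
        none_in = pd.DataFrame(
            {"gene_id": ["a", "b"], "length": [100, 100], "ko": ["K99991", None]}
        )
        assert q.annotated_fraction(all_in, mrg_catalog) == 1.0
        assert q.annotated_fraction(none_in, mrg_catalog) == 0.0

    def test_annotated_fraction_denominators(self, mrg_catalog):
        genes = pd.DataFrame(
            {"gene_id": list("abcd"), "length": [100] * 4,
             "ko": ["K03325", "K99991", None, None]}
        )
        assert q.annotated_fraction(genes, mrg_catalog) == pytest.approx(0.5)
        assert q.annotated_fraction(genes, mrg_catalog, denominator="all") == pytest.approx(0.25)

    def test_no_annotated_genes_is_error(self, mrg_catalog):
        genes = pd.DataFrame({"gene_id": ["a"], "length": [100], "ko": [None]})
        with pytest.raises(ValueError):
            q.annotated_fraction(genes, mrg_catalog)


class TestRollup:
    def test_two_by_two_hand_table(self, mrg_catalog):
        genes = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c", "d"],
                "length": [100, 100, 100, 100],
                "ko": ["K03325", "K03325", "K03741", "K99991"],  # Export, Export, Bioch Trans, decoy
                "domain": ["Bacteria", "Archaea", "Bacteria", "Bacteria"],
            }
        )
        tpm = pd.DataFrame(
            {"s1": [100.0, 200.0, 300.0, 400.0]}, index=genes["gene_id"]
        )
        rollup = q.domain_mechanism_rollup(tpm, genes, mrg_catalog)
        assert rollup.loc[("Bacteria", "Export"), "s1"] == 100.0
        assert rollup.loc[("Archaea", "Export"), "s1"] == 200.0
        assert rollup.loc[("Bacteria", "Biochemical Transformation"), "s1"] == 300.0
        # conservation against the KO-level subset
        ko_profile = q.aggregate_by_ko_tpm(tpm, genes)
        subset = q.mrg_subset_profile(ko_profile, mrg_catalog)
        assert rollup["s1"].sum() == pytest.approx(subset["s1"].sum())

    def test_missing_domain_label_is_validation_error(self, mrg_catalog):
        genes = pd.DataFrame(
            {"gene_id": ["a"], "length": [100], "ko": ["K03325"], "domain": [None]}
        )
        tpm = pd.DataFrame({"s1": [10.0]}, index=["a"])
        with pytest.raises(ValidationError, match="a"):
            q.domain_mechanism_rollup(tpm, genes, mrg_catalog)


class TestSlopeSign:
    @pytest.mark.parametrize(
        "expr,conc,expected",
        [
            ((1.0, 2.0, 3.0), (10.0, 20.0, 30.0), "positive"),
            ((3.0, 2.0, 1.0), (10.0, 20.0, 30.0), "negative"),
            ((1.0, 1.0, 1.0), (10.0, 20.0, 30.0), "flat"),
            ((1.0, 5.0), (10.0, 40.0), "positive"),  # two points: difference quotient
        ],
    )
    def test_signs(self, expr, conc, expected):
        layers = [f"L{i}" for i in range(len(expr))]
        assert q.slope_sign(dict(zip(layers, expr)), dict(zip(layers, conc))) == expected

    def test_fewer_than_two_points_is_error(self):
        with pytest.raises(ValueError):
            q.slope_sign({"L1": 1.0}, {"L1": 10.0})

    def test_nan_expression_dropped(self):
        expr = {"L1": 1.0, "L2": float("nan"), "L3": 3.0}
        conc = {"L1": 10.0, "L2": 20.0, "L3": 30.0}
        assert q.slope_sign(expr, conc) == "positive"
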