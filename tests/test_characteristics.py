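import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microsubtype import (
    AbundanceTable,
    characteristics,
    correlation_screen,
    default_trait_table,
    enterotype_labels,
    membership_indicators,
    significance_tier,
    spearman,
)
from microsubtype.simulate import balanced_design, generate_cohort
from microsubtype.tables import normalize_tss


class TestSpearman:
    def test_perfect_anticorrelation(self):
        r, _ = spearman([1, 2, 3], [3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_monotone_transform_gives_one(self):
        x = np.array([0.3, 1.2, 2.9, 4.4, 7.0])
        r, _ = spearman(x, np.exp(x))
        assert r == pytest.approx(1.0)

    def test_symmetry(self, rng):
        x, y = rng.random(15), rng.random(15)
        assert spearman(x, y)[0] == pytest.approx(spearman(y, x)[0])

    def test_zero_variance_reported_missing(self):
        r, p = spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert math.isnan(r) and math.isnan(p)

    def test_tied_data_matches_midrank_formula(self, rng):
        # brute-force oracle: Pearson correlation of midranks
        for _ in range(10):
            x = rng.integers(0, 4, 8).astype(float)
            y = rng.integers(0, 4, 8).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            rx, ry = stats.rankdata(x), stats.rankdata(y)
            expected = np.corrcoef(rx, ry)[0, 1]
            assert spearman(x, y)[0] == pytest.approx(expected, abs=1e-12)

    def test_tiers_match_heatmap_legend(self):
        assert significance_tier(0.04) == "*"
        assert significance_tier(0.005) == "**"
        assert significance_tier(0.0005) == "***"
        assert significance_tier(0.2) == ""


def toy_rel(values, taxa, taxonomy=None):
    frame = pd.DataFrame(values, index=[f"s{i}" for i in range(len(values))], columns=taxa)
    frame = frame.div(frame.sum(axis=1), axis=0)
    return AbundanceTable(frame, taxonomy or {}, is_relative=True)


class TestCorrelationScreen:
    def test_subtype_exclusive_taxon_peaks_on_its_subtype(self, rng):
        n = 40
        base = rng.random((n, 3)) + 0.2
        marker = np.where(np.arange(n) < 10, 0.8, 1e-6)
        table = toy_rel(np.column_stack([base, marker]), ["x", "y", "z", "marker"])
        labels = ["B"] * 10 + ["A"] * 30
        out = correlation_screen(table, membership_indicators(labels))
        rows = out[out["feature"] == "marker"].set_index("group")["r"]
        assert rows["B"] > 0
        assert rows.idxmax() == "B"

    def test_constant_feature_masked(self, rng):
        x = rng.random(9) * 0.5
        frame = pd.DataFrame(
            {"flat": 0.5, "a": x, "b": 0.5 - x},
            index=[f"s{i}" for i in range(9)],
        )
        table = AbundanceTable(frame, is_relative=True)
        out = correlation_screen(table, membership_indicators(["A"] * 4 + ["B"] * 5))
        flat = out[out["feature"] == "flat"]
        assert flat["r"].isna().all() and (~flat["shown"]).all()

    def test_permutation_alignment_contract(self, rng):
        vals = rng.random((12, 3)) + 0.1
        labels = ["A"] * 6 + ["B"] * 6
        table = toy_rel(vals, ["a", "b", "c"])
        out1 = correlation_screen(table, membership_indicators(labels))
        perm = rng.permutation(12)
        table2 = toy_rel(vals[perm], ["a", "b", "c"])
        out2 = correlation_screen(
            table2, membership_indicators([labels[i] for i in perm])
        )
        merged = out1.merge(out2, on=["feature", "group"], suffixes=("_1", "_2"))
        np.testing.assert_allclose(merged["r_1"], merged["r_2"], atol=1e-12)


PHYLA = {
    "f1": "Bacteria;Firmicutes;;;;f1",
    "f2": "Bacteria;Firmicutes;;;;f2",
    "b1": "Bacteria;Bacteroidetes;;;;b1",
    "o1": "Bacteria;Fusobacteria;;;;o1",
}


class TestCharacteristics:
    @staticmethod
    def table_with_phyla(values):
        from microsubtype.tables import parse_lineage

        taxa = list(PHYLA)
        taxonomy = {t: parse_lineage(PHYLA[t]) for t in taxa}
        frame = pd.DataFrame(values, index=[f"s{i}" for i in range(len(values))], columns=taxa)
        return AbundanceTable(frame, taxonomy, is_relative=False)

    def test_richness_counts_present_taxa(self):
        table = self.table_with_phyla([[0, 3, 1, 0]])
        out = characteristics(table, default_trait_table())
        assert out["richness"].iloc[0] == 2

    def test_fb_ratio_one_when_masses_equal(self):
        table = self.table_with_phyla([[2, 2, 4, 4]])
        out = characteristics(table, default_trait_table())
        assert out["fb_ratio"].iloc[0] == pytest.approx(1.0)

    def test_fb_ratio_infinite_without_bacteroidetes(self):
        table = self.table_with_phyla([[2, 2, 0, 1]])
        out = characteristics(table, default_trait_table())
        assert np.isinf(out["fb_ratio"].iloc[0])

    def test_shannon_uniform_is_log_n(self):
        table = self.table_with_phyla([[1, 1, 1, 1]])
        out = characteristics(table, default_trait_table())
        assert out["diversity_index"].iloc[0] == pytest.approx(math.log(4))

    def test_shannon_zero_for_single_taxon(self):
        table = self.table_with_phyla([[5, 0, 0, 0]])
        out = characteristics(table, default_trait_table())
        assert out["diversity_index"].iloc[0] == pytest.approx(0.0)

    def test_role_contents_partition_to_one(self):
        design = balanced_design(n_per_subtype=10, signature_boost=5)
        table, _, _ = generate_cohort(design, seed=3)
        traits = default_trait_table()
        out = characteristics(normalize_tss(table), traits)
        rel = normalize_tss(table)
        role_of = {t: traits.lookup(t)["role"] for t in rel.taxon_ids}
        rest = [t for t in rel.taxon_ids if role_of[t] in ("neutral", "unknown")]
        other = rel.data[rest].sum(axis=1)
        np.testing.assert_allclose(
            out["beneficial_content"] + out["harmful_content"] + other, 1.0, atol=1e-9
        )

    def test_planted_facultative_boost_correlates(self):
        # subtype B's signature (Streptococcus) is facultative: its
        # facultative_content correlation must peak on subtype B
        design = balanced_design(n_per_subtype=25, signature_boost=30)
        table, _, truth = generate_cohort(design, seed=9)
        out = characteristics(normalize_tss(table), default_trait_table())
        screen = correlation_screen(
            out[["facultative_content"]], membership_indicators(truth.tolist())
        )
        rows = screen.set_index("group")["r"]
        assert rows.idxmax() == "B" and rows["B"] > 0.5

    def test_balance_score_sign(self):
        table = self.table_with_phyla([[1, 1, 1, 1]])
        traits_good = {"f1": {"role": "beneficial"}, "f2": {"role": "harmful"}}
        from microsubtype import TaxonTraitTable

        out = characteristics(table, TaxonTraitTable(traits_good))
        assert out["balance_score"].iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_all_fifteen_columns_present(self):
        from microsubtype.characteristics import CHARACTERISTIC_COLUMNS

        table = self.table_with_phyla([[1, 2, 3, 4], [4, 3, 2, 1]])
        out = characteristics(table, default_trait_table())
        assert list(out.columns) == CHARACTERISTIC_COLUMNS
        assert len(CHARACTERISTIC_COLUMNS) == 15


class TestEnterotype:
    def test_dominant_marker_rule(self):
        frame = pd.DataFrame(
            [[0.6, 0.2, 0.2], [0.1, 0.6, 0.3], [0.2, 0.2, 0.6]],
            index=["s1", "s2", "s3"],
            columns=["Prevotella", "Bacteroides", "Ruminococcus"],
        )
        table = AbundanceTable(frame, is_relative=True)
        assert enterotype_labels(table).tolist() == [
            "Prevotella", "Bacteroides", "Ruminococcus",
        ]

    def test_markers_absent_is_unknown(self):
        frame = pd.DataFrame([[1.0]], index=["s"], columns=["Blautia"])
        table = AbundanceTable(frame, is_relative=True)
        assert enterotype_labels(table).tolist() == ["unknown"]

    def test_jsd_partitioning_recovers_dominant_regimes(self, rng):
        rows, expected = [], []
        for marker in ("Prevotella", "Bacteroides", "Ruminococcus"):
            for _ in range(6):
                base = rng.random(3) * 0.1
                row = {"Prevotella": base[0], "Bacteroides": base[1], "Ruminococcus": base[2]}
                row[marker] += 0.8
                rows.append(row)
                expected.append(marker)
        frame = pd.DataFrame(rows, index=[f"s{i}" for i in range(18)])
        frame = frame.div(frame.sum(axis=1), axis=0)
        table = AbundanceTable(frame, is_relative=True)
        labels = enterotype_labels(table, method="jsd", seed=1)
        assert (labels.to_numpy() == np.array(expected)).mean() > 0.8
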