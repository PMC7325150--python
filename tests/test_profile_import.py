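import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rankenrich.exceptions import (
    AmbiguousFormatError,
    UnrecognisedFormatError,
    ValidationError,
)
from rankenrich.profile_import import (
    detect_format,
    import_profile,
    join_profiles,
    map_identifiers,
    rank_and_center,
    read_de_table,
    score_genes,
)


def _table(columns, n=4):
    rng = np.random.default_rng(0)
    data = {}
    for c in columns:
        if "p" in c.lower() or c in ("FDR", "padj", "Stouffer"):
            data[c] = rng.uniform(0.001, 1, n)
        else:
            data[c] = rng.standard_normal(n)
    return pd.DataFrame(data, index=[f"G{i}" for i in range(n)])


class TestDetectFormat:
    @pytest.mark.parametrize(
        "columns,tool,score_cols",
        [
            (["baseMean", "log2FoldChange", "lfcSE", "stat", "pvalue", "padj"],
             "deseq2", ("stat",)),
            (["logFC", "logCPM", "PValue", "FDR"], "edger", ("logFC", "PValue")),
            (["logFC", "AveExpr", "t", "P.Value", "adj.P.Val", "B"], "limma", ("t",)),
            (["p_val", "avg_logFC", "pct.1", "pct.2", "p_val_adj"],
             "seurat", ("avg_logFC", "p_val")),
            (["b", "pval", "qval"], "sleuth", ("b", "pval")),
        ],
    )
    def test_autodetects_known_dialects(self, columns, tool, score_cols):
        fmt = detect_format(_table(columns))
        assert fmt.tool == tool
        assert fmt.score_columns == score_cols

    def test_unknown_columns_error_names_them(self):
        with pytest.raises(UnrecognisedFormatError, match="foo"):
            detect_format(_table(["foo", "bar"]))

    def test_ambiguous_match_requires_hint(self):
        # edgeR (logFC, PValue) and muscat (logFC, p_val) both fit
        table = _table(["logFC", "PValue", "p_val"])
        with pytest.raises(AmbiguousFormatError):
            detect_format(table)
        assert detect_format(table, hint="edger").tool == "edger"

    def test_hint_overrides_autodetection(self):
        table = _table(["baseMean", "log2FoldChange", "stat", "pvalue"])
        fmt = detect_format(table, hint="swish")
        assert fmt.tool == "swish"

    def test_single_numeric_column_is_prescored(self):
        table = pd.DataFrame({"score": [1.0, -2.0]}, index=["a", "b"])
        fmt = detect_format(table)
        assert fmt.tool == "prescored" and fmt.score_columns == ("score",)

    def test_unknown_hint_rejected(self):
        with pytest.raises(UnrecognisedFormatError, match="unknown format hint"):
            detect_format(_table(["stat"]), hint="nonsense")


class TestScoreGenes:
    def test_directional_significance_score(self):
        table = pd.DataFrame(
            {"logFC": [-2.0, 3.7, 1.0], "PValue": [0.01, 1.0, 0.001]},
            index=["a", "b", "c"],
        )
        score = score_genes(table, detect_format(table))
        assert score["a"] == pytest.approx(-2.0)
        assert score["b"] == 0.0
        assert score["c"] == pytest.approx(3.0)

    def test_statistic_copied_verbatim(self):
        table = pd.DataFrame(
            {"baseMean": [1.0], "log2FoldChange": [0.5], "stat": [5.43], "pvalue": [0.1]},
            index=["g"],
        )
        assert score_genes(table, detect_format(table))["g"] == 5.43

    def test_zero_pvalue_clamped_finite(self):
        table = pd.DataFrame({"logFC": [2.0], "PValue": [0.0]}, index=["g"])
        d = score_genes(table, detect_format(table))["g"]
        assert np.isfinite(d) and d > 300

    def test_pvalue_outside_unit_interval_rejected(self):
        table = pd.DataFrame({"logFC": [1.0], "PValue": [1.5]}, index=["g"])
        with pytest.raises(ValidationError, match="p-values"):
            score_genes(table, detect_format(table))

    def test_duplicate_genes_rejected_unless_opted_in(self):
        table = pd.DataFrame({"score": [1.0, -3.0]}, index=["g", "g"])
        fmt = detect_format(table)
        with pytest.raises(ValidationError, match="duplicate"):
            score_genes(table, fmt)
        resolved = score_genes(table, fmt, on_duplicate="max_abs")
        assert resolved["g"] == -3.0

    @settings(deadline=None, max_examples=50)
    @given(
        p=st.floats(min_value=1e-12, max_value=1.0, exclude_min=False),
        lfc=st.floats(min_value=-50, max_value=50, allow_nan=False),
    )
    def test_d_score_antisymmetric_in_effect(self, p, lfc):
        def d(effect):
            table = pd.DataFrame({"logFC": [effect], "PValue": [p]}, index=["g"])
            return score_genes(table, detect_format(table))["g"]

        assert d(-lfc) == pytest.approx(-d(lfc), abs=1e-12)


class TestJoinProfiles:
    def setup_method(self):
        self.a = pd.Series({"g1": 1.0, "g2": 2.0, "g3": 3.0}, name="A")
        self.b = pd.Series({"g2": -1.0, "g3": 0.5, "g4": 2.0}, name="B")

    def test_intersect_keeps_shared_genes(self):
        joined = join_profiles([self.a, self.b], mode="intersect")
        assert sorted(joined.index) == ["g2", "g3"]
        assert list(joined.columns) == ["A", "B"]

    def test_union_fills_missing_with_zero(self):
        joined = join_profiles([self.a, self.b], mode="union")
        assert sorted(joined.index) == ["g1", "g2", "g3", "g4"]
        assert joined.loc["g1", "B"] == 0.0
        assert joined.loc["g4", "A"] == 0.0

    @pytest.mark.parametrize("mode", ["intersect", "union"])
    def test_single_profile_identity(self, mode):
        joined = join_profiles([self.a], mode=mode)
        pd.testing.assert_series_equal(joined["A"], self.a)

    def test_empty_intersection_suggests_union(self):
        c = pd.Series({"x1": 1.0}, name="C")
        with pytest.raises(ValidationError, match="union"):
            join_profiles([self.a, c], mode="intersect")

    def test_duplicate_contrast_names_rejected(self):
        with pytest.raises(ValidationError, match="unique"):
            join_profiles([self.a, self.a.rename("A")])


class TestMapIdentifiers:
    def test_maps_and_drops_unmapped(self):
        idmap = pd.DataFrame({"src": ["ENSG1"], "tgt": ["GeneA"]})
        profile = pd.Series({"ENSG1": 2.0, "ENSG2": -1.0}, name="A")
        mapped = map_identifiers(profile, idmap)
        assert dict(mapped) == {"GeneA": 2.0}

    def test_collision_keeps_largest_absolute_score(self):
        idmap = pd.DataFrame({"src": ["T1", "T2"], "tgt": ["G", "G"]})
        profile = pd.Series({"T1": 1.0, "T2": -3.0}, name="A")
        assert dict(map_identifiers(profile, idmap)) == {"G": -3.0}

    def test_disjoint_map_warns_and_returns_empty(self):
        idmap = pd.DataFrame({"src": ["X"], "tgt": ["Y"]})
        profile = pd.Series({"T1": 1.0}, name="A")
        with pytest.warns(UserWarning, match="no profile genes"):
            mapped = map_identifiers(profile, idmap)
        assert mapped.empty


class TestRankAndCenter:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ([3.0, 1.0, -2.0, -5.0], [1.5, 0.5, -0.5, -1.5]),
            ([2.0, 0.0, -1.0], [1.0, 0.0, -1.0]),
            ([1.0, 1.0], [1.0, 1.0]),
        ],
    )
    def test_centring_examples(self, scores, expected):
        profile = pd.Series(scores, index=[f"g{i}" for i in range(len(scores))], name="A")
        ranked = rank_and_center(profile)
        assert ranked["A"].tolist() == expected

    def test_nonfinite_score_names_gene_and_contrast(self):
        profile = pd.Series({"good": 1.0, "bad": np.nan}, name="C1")
        with pytest.raises(ValidationError, match=r"bad.*C1"):
            rank_and_center(profile)

    @settings(deadline=None, max_examples=60)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=2,
            max_size=40,
        )
    )
    def test_sign_and_order_preserved(self, scores):
        profile = pd.Series(scores, index=[f"g{i}" for i in range(len(scores))], name="A")
        ranked = rank_and_center(profile)["A"].to_numpy()
        x = np.asarray(scores)
        # with average ties, sign preservation holds unconditionally
        assert (np.sign(ranked) == np.sign(x)).all()
        # order preservation
        for i in range(len(x)):
            for j in range(len(x)):
                if x[i] > x[j]:
                    assert ranked[i] > ranked[j]

    def test_zero_score_maps_to_zero_rank(self, rng):
        x = np.concatenate([rng.standard_normal(21), [0.0]])
        profile = pd.Series(x, index=[f"g{i}" for i in range(len(x))], name="A")
        ranked = rank_and_center(profile)["A"]
        assert ranked.iloc[-1] == 0.0

    def test_sign_preserving_monotone_transform_leaves_ranks_unchanged(self, rng):
        # an odd increasing transform keeps sign structure, hence the offset
        x = rng.standard_normal(100)
        profile = pd.Series(x, index=[f"g{i}" for i in range(100)], name="A")
        transformed = pd.Series(x**3, index=profile.index, name="A")
        pd.testing.assert_frame_equal(rank_and_center(profile), rank_and_center(transformed))

    def test_general_monotone_transform_shifts_ranks_by_constant(self, rng):
        # moving the zero-crossing shifts each contrast's centred ranks by a
        # constant, which cancels in every downstream test statistic
        x = rng.standard_normal(100)
        profile = pd.Series(x, index=[f"g{i}" for i in range(100)], name="A")
        transformed = pd.Series(np.exp(x) + x**3, index=profile.index, name="A")
        delta = rank_and_center(transformed)["A"] - rank_and_center(profile)["A"]
        assert delta.nunique() == 1


def test_import_profile_roundtrip(tmp_path):
    table = pd.DataFrame(
        {
            "gene": ["g1", "g2", "g3"],
            "logFC": [1.0, -2.0, 0.5],
            "logCPM": [5.0, 6.0, 7.0],
            "PValue": [0.1, 0.01, 0.5],
            "FDR": [0.2, 0.05, 0.6],
        }
    )
    path = tmp_path / "edger.tsv"
    table.to_csv(path, sep="\t", index=False)
    score = import_profile(path, contrast="kd")
    assert score.name == "kd"
    assert score["g2"] == pytest.approx(-2.0)
    # comma-delimited variant sniffs fine too
    path_csv = tmp_path / "edger.csv"
    table.to_csv(path_csv, index=False)
    pd.testing.assert_series_equal(import_profile(path_csv, contrast="kd"), score)
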