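import numpy as np
import pandas as pd
import pytest

from oracles import fisher_twosided_oracle
from scapa import (
    CellAnnotation,
    EnrichmentMatrix,
    SignatureModel,
    contingency,
    odds_ratio,
    select_signatures,
    shortening_overexpression_flags,
    within_type_pcc,
)


def _es(rows, cells, channel="apa"):
    return EnrichmentMatrix(
        pd.DataFrame(rows, index=list(rows.keys()) if isinstance(rows, dict) else None,
                     columns=cells)
        if not isinstance(rows, pd.DataFrame) else rows,
        channel=channel,
    )


def _pair(short, expr, cells=None):
    cells = cells or [f"c{i}" for i in range(len(short))]
    apa = EnrichmentMatrix(pd.DataFrame([short], index=["comp"], columns=cells),
                           channel="apa")
    ex = EnrichmentMatrix(pd.DataFrame([expr], index=["comp"], columns=cells),
                          channel="expression")
    return apa, ex


def _annot(types, cells=None):
    cells = cells or [f"c{i}" for i in range(len(types))]
    return CellAnnotation(pd.DataFrame(
        {"patient": "p0", "cell_type": types},
        index=pd.Index(cells, name="cell")))


class TestFlags:
    def test_opposed_rankings_flag_nothing(self):
        apa, ex = _pair([1, 2, 3, 4], [4, 3, 2, 1])
        flags = shortening_overexpression_flags(apa, ex, "comp")
        assert not flags.any()

    def test_concordant_rankings_flag_top_half(self):
        apa, ex = _pair([1, 2, 3, 4], [1, 2, 3, 4])
        flags = shortening_overexpression_flags(apa, ex, "comp")
        assert flags.tolist() == [False, False, True, True]

    def test_constant_component_flags_nothing(self):
        apa, ex = _pair([2, 2, 2, 2], [1, 2, 3, 4])
        assert not shortening_overexpression_flags(apa, ex, "comp").any()

    def test_cells_missing_either_score_are_excluded(self):
        apa, ex = _pair([1, 2, 3, 4, np.nan, 6], [1, 2, np.nan, 4, 5, 6])
        flags = shortening_overexpression_flags(apa, ex, "comp")
        assert list(flags.index) == ["c0", "c1", "c3", "c5"]

    def test_too_few_observed_cells_is_an_error(self):
        apa, ex = _pair([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError, match="fewer than 4"):
            shortening_overexpression_flags(apa, ex, "comp")

    def test_flags_invariant_to_monotone_transforms(self, rng):
        s = rng.normal(size=30)
        e = rng.normal(size=30)
        apa, ex = _pair(s, e)
        base = shortening_overexpression_flags(apa, ex, "comp")
        apa2, ex2 = _pair(np.exp(s), 3 * e - 7)
        warped = shortening_overexpression_flags(apa2, ex2, "comp")
        pd.testing.assert_series_equal(base, warped)


class TestContingency:
    def test_perfect_separation(self):
        flags = pd.Series([True] * 10 + [False] * 10,
                          index=[f"c{i}" for i in range(20)])
        annot = _annot(["T"] * 10 + ["B"] * 10)
        assert contingency(flags, annot, "T") == (10, 0, 0, 10)

    def test_nothing_flagged(self):
        flags = pd.Series([False] * 6, index=[f"c{i}" for i in range(6)])
        annot = _annot(["T"] * 2 + ["B"] * 4)
        assert contingency(flags, annot, "T") == (0, 0, 2, 4)

    def test_unknown_cell_type_is_an_error(self):
        flags = pd.Series([True], index=["c0"])
        annot = _annot(["T"])
        with pytest.raises(ValueError, match="absent"):
            contingency(flags, annot, "stromal")

    def test_swapping_labels_inverts_odds_ratio(self, rng):
        flags = pd.Series(rng.random(40) < 0.4,
                          index=[f"c{i}" for i in range(40)])
        annot = _annot(["T"] * 15 + ["B"] * 25)
        a, b, c, d = contingency(flags, annot, "T")
        or1, p1 = odds_ratio((a, b, c, d))
        or2, p2 = odds_ratio((b, a, d, c))  # in/out swapped
        assert or2 == pytest.approx(1.0 / or1)
        assert p2 == pytest.approx(p1, abs=1e-12)


class TestOddsRatio:
    def test_plain_odds_ratio(self):
        orv, _ = odds_ratio((8, 2, 2, 8))
        assert orv == pytest.approx(16.0)

    def test_perfect_table_fisher_p(self):
        """(5,0,0,5) at margins (5,5)/(5,5): p = 2/252 by enumeration."""
        orv, p = odds_ratio((5, 0, 0, 5))
        assert p == pytest.approx(2 / 252, abs=1e-12)
        # Haldane-Anscombe applied to the OR because zeros are present
        assert orv == pytest.approx((5.5 * 5.5) / (0.5 * 0.5))

    @pytest.mark.parametrize("k", [1, 3, 7])
    def test_balanced_table_is_null(self, k):
        orv, p = odds_ratio((k, k, k, k))
        assert orv == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValueError):
            odds_ratio((0, 0, 0, 0))

    def test_agrees_with_exhaustive_enumeration(self, rng):
        for _ in range(40):
            n = int(rng.integers(1, 41))
            a, b, c, d = rng.multinomial(n, [0.25] * 4)
            _, p = odds_ratio((int(a), int(b), int(c), int(d)))
            assert p == pytest.approx(
                fisher_twosided_oracle(int(a), int(b), int(c), int(d)),
                abs=1e-12)


def _vectors_with_r(rng, n, r):
    """Construct x, y with sample correlation exactly r."""
    x = rng.normal(size=n)
    e = rng.normal(size=n)
    x = (x - x.mean()) / x.std()
    e = e - e.mean()
    e = e - (e @ x) / (x @ x) * x  # orthogonal to x
    e = e / e.std()
    return x, r * x + np.sqrt(1 - r * r) * e


class TestWithinTypePCC:
    def test_fisher_z_reference_value(self, rng):
        """r = 0.5 at n = 12 gives z = atanh(0.5) and p ~ 0.0994."""
        x, y = _vectors_with_r(rng, 12, 0.5)
        apa, ex = _pair(x, y)
        annot = _annot(["T"] * 12)
        r, p = within_type_pcc(apa, ex, "comp", annot, "T")
        assert r == pytest.approx(0.5, abs=1e-12)
        assert p == pytest.approx(0.09938, abs=1e-4)

    def test_zero_correlation_gives_p_one(self, rng):
        x, y = _vectors_with_r(rng, 20, 0.0)
        apa, ex = _pair(x, y)
        r, p = within_type_pcc(apa, ex, "comp", _annot(["T"] * 20), "T")
        assert abs(r) < 1e-12 and p == pytest.approx(1.0)

    def test_collinear_scores_report_p_zero(self):
        x = np.arange(8.0)
        apa, ex = _pair(x, 2 * x + 1)
        r, p = within_type_pcc(apa, ex, "comp", _annot(["T"] * 8), "T")
        assert r == 1.0 and p == 0.0

    def test_small_or_constant_groups_are_ineligible(self):
        apa, ex = _pair([1, 2, 3, 4], [1, 2, 3, 4])
        with pytest.raises(ValueError):
            within_type_pcc(apa, ex, "comp", _annot(["T", "T", "T", "B"]), "T")
        apa2, ex2 = _pair([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])
        with pytest.raises(ValueError, match="variance"):
            within_type_pcc(apa2, ex2, "comp", _annot(["T"] * 5), "T")


def _model_on(short, expr, types):
    cells = [f"c{i}" for i in range(len(types))]
    apa = EnrichmentMatrix(pd.DataFrame([short], index=["comp"], columns=cells),
                           channel="apa")
    ex = EnrichmentMatrix(pd.DataFrame([expr], index=["comp"], columns=cells),
                          channel="expression")
    return SignatureModel(apa, ex, _annot(types, cells))


class TestSelectSignatures:
    def test_planted_pair_with_negative_pcc_is_rejected(self, rng):
        """High OR but anti-correlated within the type: PCC > 0 is required."""
        n_in, n_out = 12, 24
        x, y = _vectors_with_r(rng, n_in, -0.9)
        short = np.concatenate([x + 10, rng.normal(size=n_out)])
        expr = np.concatenate([y + 10, rng.normal(size=n_out)])
        res = _model_on(short, expr, ["T"] * n_in + ["B"] * n_out).fit()
        row = res.stats.set_index("cell_type").loc["T"]
        assert row["odds_ratio"] > 2 and row["or_p"] < 0.01
        assert row["pcc"] < 0
        assert not row["hit"]

    def test_planted_pair_with_positive_pcc_is_a_hit(self, rng):
        n_in, n_out = 12, 24
        x, y = _vectors_with_r(rng, n_in, 0.9)
        short = np.concatenate([x + 10, rng.normal(size=n_out)])
        expr = np.concatenate([y + 10, rng.normal(size=n_out)])
        res = _model_on(short, expr, ["T"] * n_in + ["B"] * n_out).fit()
        by_type = res.stats.set_index("cell_type")
        assert bool(by_type.loc["T", "hit"])
        assert not bool(by_type.loc["B", "hit"])

    def test_recovers_planted_sets_on_small_cohort(self, small_cohort):
        from scapa.pipeline import signature_pipeline
        res = signature_pipeline(small_cohort.apa, small_cohort.expression,
                                 small_cohort.annotation,
                                 small_cohort.gene_sets)
        truth_pairs = {(s, t) for t, d in small_cohort.truth.items()
                       for s in d["gene_sets"]}
        recovered = truth_pairs & res.hit_pairs()
        assert len(recovered) >= 0.8 * len(truth_pairs)

    def test_output_sorted_by_type_then_odds_ratio(self, small_cohort, rng):
        from scapa.pipeline import signature_pipeline
        res = signature_pipeline(small_cohort.apa, small_cohort.expression,
                                 small_cohort.annotation,
                                 small_cohort.gene_sets)
        for _, grp in res.stats.groupby("cell_type"):
            ors = grp["odds_ratio"].dropna().to_numpy()
            assert (np.diff(ors) <= 1e-12).all()

    def test_functional_wrapper_matches_model(self, small_cohort):
        from scapa.pipeline import enrich_both_channels
        apa_es, expr_es = enrich_both_channels(
            small_cohort.apa, small_cohort.expression, small_cohort.gene_sets)
        annot = small_cohort.annotation.subset(apa_es.cells)
        df = select_signatures(apa_es, expr_es, annot)
        res = SignatureModel(apa_es, expr_es, annot).fit()
        pd.testing.assert_frame_equal(df, res.stats)
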