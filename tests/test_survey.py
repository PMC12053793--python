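"""Survey I/O, snapshot pairing, event classification and local abundance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_survey
from metapatch import survey
from metapatch.survey import (SurveyDataError, SurveyFormatError,
                              classify_extinction_outcomes,
                              extinction_outcome_summary, local_abundance,
                              pair_surveys, read_survey, summarize_events,
                              write_survey)


class TestReadWrite:
    def test_round_trip(self, tmp_path, toy_pair_surveys):
        t1, _ = toy_pair_surveys
        path = tmp_path / "s.csv"
        write_survey(t1, path)
        back = read_survey(path, year=2019)
        assert len(back) == 3 + 1
        pd.testing.assert_frame_equal(
            back.reset_index(drop=True), t1[back.columns].reset_index(drop=True),
            check_dtype=False)

    def test_area_bound_rejected_with_row(self, tmp_path):
        df = make_survey([("A", 1.0, 0.0, 0.0, 30.0, 0)], 2019)
        df.drop(columns=["causes"]).to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(SurveyDataError, match=r"suitable_area_m2.*\[0"):
            read_survey(tmp_path / "bad.csv")

    def test_missing_column_is_format_error(self, tmp_path):
        pd.DataFrame({"plot_id": ["A"], "dist_km": [1.0]}).to_csv(
            tmp_path / "bad.csv", index=False)
        with pytest.raises(SurveyFormatError, match="missing required column"):
            read_survey(tmp_path / "bad.csv")

    def test_non_numeric_abundance_names_row(self, tmp_path):
        df = make_survey([("A", 1.0, 0.0, 0.0, 2.0, 1)], 2019)
        df["abundance"] = ["many"]
        df.drop(columns=["causes"]).to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(SurveyDataError, match="non-numeric 'abundance'"):
            read_survey(tmp_path / "bad.csv")

    def test_multi_label_causes(self, tmp_path):
        df = make_survey([("A", 1.0, 0.0, 0.0, 0.0, 0)], 2019)
        df["causes"] = ["succession;wind"]
        df.to_csv(tmp_path / "s.csv", index=False)
        back = read_survey(tmp_path / "s.csv")
        assert back.loc[0, "causes"] == frozenset({"succession", "wind"})

    def test_unknown_cause_rejected(self, tmp_path):
        df = make_survey([("A", 1.0, 0.0, 0.0, 0.0, 0)], 2019)
        df["causes"] = ["landslide"]
        df.to_csv(tmp_path / "s.csv", index=False)
        with pytest.raises(SurveyDataError, match="unknown cause"):
            read_survey(tmp_path / "s.csv")


class TestPairing:
    def test_toy_candidate_classification(self, toy_pair_surveys):
        pairs = pair_surveys(*toy_pair_surveys).set_index("plot_id")
        assert pairs.loc["A", "colonisation_candidate"] and pairs.loc["A", "colonised"]
        assert pairs.loc["B", "extinction_candidate"] and pairs.loc["B", "extinct"]
        assert not pairs.loc["C", "colonisation_candidate"]
        assert not pairs.loc["C", "extinction_candidate"]
        assert pairs.loc["D", "extinction_candidate"] and not pairs.loc["D", "extinct"]
        # outcomes undefined outside the pools
        assert pd.isna(pairs.loc["C", "colonised"]) and pd.isna(pairs.loc["C", "extinct"])

    def test_extinction_candidate_regardless_of_t2_suitability(self):
        t1 = make_survey([("A", 1.0, 0.0, 0.0, 3.0, 2)], 2019)
        t2 = make_survey([("A", 1.0, 0.0, 0.0, 0.0, 0)], 2022)
        pairs = pair_surveys(t1, t2)
        assert pairs.loc[0, "extinction_candidate"] and pairs.loc[0, "extinct"]

    def test_colonisation_candidate_not_suitable_at_t1(self):
        t1 = make_survey([("A", 1.0, 0.0, 0.0, 0.0, 0)], 2019)
        t2 = make_survey([("A", 1.0, 0.0, 0.0, 4.0, 0)], 2022)
        pairs = pair_surveys(t1, t2)
        assert pairs.loc[0, "colonisation_candidate"] and not pairs.loc[0, "colonised"]

    def test_non_dune_and_unmatched_plots_excluded(self, toy_pair_surveys):
        t1, t2 = toy_pair_surveys
        t1 = t1.copy()
        t1.loc[t1["plot_id"] == "C", "is_dune"] = False
        t2 = t2[t2["plot_id"] != "D"]
        pairs = pair_surveys(t1, t2)
        assert set(pairs["plot_id"]) == {"A", "B"}

    def test_duplicate_plot_id_rejected(self, toy_pair_surveys):
        t1, t2 = toy_pair_surveys
        dup = pd.concat([t1, t1.iloc[[0]]], ignore_index=True)
        with pytest.raises(SurveyDataError, match="duplicate plot_id"):
            pair_surveys(dup, t2)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 5), st.floats(0, 25), st.floats(0, 25),
                              st.integers(0, 5)), min_size=1, max_size=20))
    def test_candidate_pools_partition(self, rows):
        """Every paired plot is in exactly one of: colonisation pool,
        extinction pool, or (vacant and unsuitable-at-t2)."""
        t1 = make_survey([(f"P{i}", 1.0, i * 1000.0, 0.0, a1, n1)
                          for i, (n1, a1, _, _) in enumerate(rows)], 2019)
        t2 = make_survey([(f"P{i}", 1.0, i * 1000.0, 0.0, a2, n2)
                          for i, (_, _, a2, n2) in enumerate(rows)], 2022)
        pairs = pair_surveys(t1, t2)
        col = pairs["colonisation_candidate"]
        ext = pairs["extinction_candidate"]
        neither = ~pairs["occupied_t1"] & ~pairs["suitable_t2"]
        assert (col.astype(int) + ext.astype(int) + neither.astype(int) == 1).all()


class TestLocalAbundance:
    def test_three_collinear_plots(self):
        t1 = make_survey([("A", 1, 0.0, 0.0, 2.0, 4), ("B", 1, 300.0, 0.0, 2.0, 0),
                          ("C", 1, 900.0, 0.0, 2.0, 7)], 2019)
        t2 = make_survey([("A", 1, 0.0, 0.0, 2.0, 4), ("B", 1, 300.0, 0.0, 2.0, 0),
                          ("C", 1, 900.0, 0.0, 2.0, 7)], 2022)
        pairs = local_abundance(pair_surveys(t1, t2))
        L = pairs.set_index("plot_id")["L_t1"]
        assert L["A"] == 0.0        # sole neighbour B is vacant
        assert L["B"] == 4.0
        assert np.isnan(L["C"])     # no neighbour within 500 m

    def test_isolated_plot_missing(self):
        t1 = make_survey([("A", 1, 0.0, 0.0, 2.0, 1)], 2019)
        t2 = make_survey([("A", 1, 0.0, 0.0, 2.0, 1)], 2022)
        pairs = local_abundance(pair_surveys(t1, t2))
        assert np.isnan(pairs.loc[0, "L_t1"])

    def test_matches_brute_force_and_order_invariant(self):
        rng = np.random.default_rng(7)
        n = 400
        rows = [(f"P{i}", 1.0, x, y, 2.0, int(nn)) for i, (x, y, nn) in enumerate(
            zip(rng.uniform(0, 20000, n), rng.uniform(-200, 200, n),
                rng.poisson(3, n)))]
        t1 = make_survey(rows, 2019)
        t2 = make_survey(rows, 2022)
        pairs = local_abundance(pair_surveys(t1, t2))
        xy = pairs[["x_m", "y_m"]].to_numpy()
        N = pairs["N_t1"].to_numpy(float)
        D = np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(-1))
        for i in range(n):
            nbr = (D[i] <= 500.0) & (np.arange(n) != i)
            expect = N[nbr].mean() if nbr.any() else np.nan
            got = pairs.loc[i, "L_t1"]
            assert (np.isnan(expect) and np.isnan(got)) or got == pytest.approx(expect)
        # permutation invariance
        perm = rng.permutation(n)
        shuffled = local_abundance(pair_surveys(t1.iloc[perm], t2))
        merged = shuffled.set_index("plot_id")["L_t1"].reindex(pairs["plot_id"])
        np.testing.assert_allclose(merged.to_numpy(), pairs["L_t1"].to_numpy())


class TestEventSummary:
    def test_printed_count_rates(self):
        """232 colonisations of 1223 candidates and 195 extinctions of 638
        give crude rates 0.190 and 0.306."""
        pairs = _counts_to_pairs(1223, 232, 638, 195)
        ev = summarize_events(pairs)
        assert round(ev.crude_c, 3) == 0.190
        assert round(ev.crude_e, 3) == 0.306

    def test_all_colonised(self):
        pairs = _counts_to_pairs(10, 10, 5, 0)
        ev = summarize_events(pairs)
        assert ev.crude_c == 1.0 and ev.crude_e == 0.0

    def test_empty_pool_gives_nan_not_zero(self, toy_pair_surveys):
        t1, t2 = toy_pair_surveys
        keep = ["B", "D"]  # occupied at t1: no colonisation candidates
        pairs = pair_surveys(t1[t1.plot_id.isin(keep)], t2[t2.plot_id.isin(keep)])
        ev = summarize_events(pairs)
        assert np.isnan(ev.crude_c) and not np.isnan(ev.crude_e)

    def test_row_permutation_invariant(self, toy_pair_surveys):
        pairs = pair_surveys(*toy_pair_surveys)
        ev1 = summarize_events(pairs)
        ev2 = summarize_events(pairs.iloc[::-1])
        assert ev1 == ev2


from conftest import counts_to_pairs as _counts_to_pairs  # noqa: E402


class TestExtinctionOutcomes:
    def test_printed_split_fraction_still_suitable(self):
        """189 extinct plots with complete cause data, 54 of them unsuitable:
        135/189 = 71.4% still held suitable habitat."""
        rows_t1 = [(f"P{i}", 1.0, i * 10.0, 0.0, 3.0, 2) for i in range(189)]
        t2_rows = []
        for i in range(189):
            if i < 54:
                t2_rows.append((f"P{i}", 1.0, i * 10.0, 0.0, 0.0, 0))
            else:
                t2_rows.append((f"P{i}", 1.0, i * 10.0, 0.0, 3.0, 0))
        t1 = make_survey(rows_t1, 2019)
        t2 = make_survey(t2_rows, 2022)
        t2["causes"] = [frozenset({"succession"}) if i < 54 else frozenset()
                        for i in range(189)]
        out = classify_extinction_outcomes(pair_surveys(t1, t2))
        summ = extinction_outcome_summary(out)
        assert summ["n_unsuitable"] == 54
        assert round(summ["fraction_still_suitable"], 3) == 0.714

    def test_multilabel_cause_counted_in_each_numerator(self):
        t1 = make_survey([("A", 1, 0.0, 0.0, 3.0, 2), ("B", 1, 9000.0, 0.0, 3.0, 2)], 2019)
        t2 = make_survey([("A", 1, 0.0, 0.0, 0.0, 0), ("B", 1, 9000.0, 0.0, 0.0, 0)], 2022)
        t2["causes"] = [frozenset({"succession", "wind"}), frozenset({"wind"})]
        summ = extinction_outcome_summary(
            classify_extinction_outcomes(pair_surveys(t1, t2)))
        assert summ["cause_proportions"]["wind"] == 1.0
        assert summ["cause_proportions"]["succession"] == 0.5

    def test_cause_missing_excluded(self):
        t1 = make_survey([("A", 1, 0.0, 0.0, 3.0, 2), ("B", 1, 9000.0, 0.0, 3.0, 2)], 2019)
        t2 = make_survey([("A", 1, 0.0, 0.0, 0.0, 0), ("B", 1, 9000.0, 0.0, 0.0, 0)], 2022)
        t2["causes"] = [frozenset({"wind"}), frozenset()]
        out = classify_extinction_outcomes(pair_surveys(t1, t2))
        assert out.set_index("plot_id").loc["B", "cause_missing"]
        summ = extinction_outcome_summary(out)
        assert summ["n_complete"] == 1 and summ["n_unsuitable"] == 1

    def test_no_extinctions_empty_table(self, toy_pair_surveys):
        t1, t2 = toy_pair_surveys
        keep = ["A", "D"]
        out = classify_extinction_outcomes(
            pair_surveys(t1[t1.plot_id.isin(keep)], t2[t2.plot_id.isin(keep)]))
        assert len(out) == 0
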