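"""Threshold discrimination, network extraction, second-level summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.tree import DecisionTreeClassifier

from spectperf import network as nw


class TestFirstLevelCompare:
    def test_identical_samples(self):
        assert nw.first_level_compare([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_zero_variance_equal_means(self):
        assert nw.first_level_compare([1.0, 1.0], [1.0, 1.0]) == (0.0, 1.0)

    def test_sign_positive_when_ictal_higher(self):
        t1, _ = nw.first_level_compare([11, 12, 13], [1, 2, 3])
        t2, _ = nw.first_level_compare([1, 2, 3], [11, 12, 13])
        assert t1 > 0 > t2
        t3, _ = nw.first_level_compare([21, 22, 23], [1, 2, 3])
        assert t3 > t1  # |t| grows with the shift

    def test_matches_pooled_variance_formula(self):
        """Hand-evaluated textbook pooled-variance t for tiny samples."""
        a, b = np.array([1.0, 1.2]), np.array([0.8, 0.9])
        sp2 = (a.var(ddof=1) + b.var(ddof=1)) / 2  # equal n
        want = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 2 + 1 / 2))
        t, p = nw.first_level_compare(a, b)
        assert t == pytest.approx(want)
        assert 0 < p < 1

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            nw.first_level_compare([1.0], [1.0, 2.0])


def brute_force_tree_threshold(ictal, interictal):
    """Exhaustive Gini search over all midpoints, via explicit counting."""
    values = sorted(set(list(ictal) + list(interictal)))
    pooled = list(ictal) + list(interictal)
    labels = [1] * len(ictal) + [0] * len(interictal)
    n = len(pooled)
    best = None
    for lo, hi in zip(values, values[1:]):
        cut = (lo + hi) / 2
        cost = 0.0
        for side in (True, False):
            grp = [l for v, l in zip(pooled, labels) if (v <= cut) == side]
            if grp:
                p = sum(grp) / len(grp)
                cost += len(grp) * 2 * p * (1 - p)
        cost /= n
        if best is None or cost < best[0] - 1e-12:
            best = (cost, [cut])
        elif abs(cost - best[0]) <= 1e-12:
            best[1].append(cut)
    med = float(np.median(pooled))
    cands = sorted(best[1], key=lambda c: (abs(c - med), c))
    return cands[0]


class TestTreeThreshold:
    def test_separable_samples_split_at_gap_midpoint(self):
        assert nw.tree_threshold([1.2, 1.3], [0.8, 0.9]) == pytest.approx(1.05)

    def test_identical_values_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            nw.tree_threshold([1.0], [1.0])

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_matches_exhaustive_oracle(self, data):
        """Single Gini split equals exhaustive search for random samples."""
        floats = st.floats(0.25, 2.0, allow_nan=False, width=32)
        a = data.draw(st.lists(floats, min_size=1, max_size=40))
        b = data.draw(st.lists(floats, min_size=1, max_size=40))
        if len(set(a) | set(b)) < 2:
            return
        got = nw.tree_threshold(a, b)
        want = brute_force_tree_threshold(a, b)
        assert got == pytest.approx(want)

    def test_agrees_with_sklearn_stump_on_separable_data(self):
        """Cross-check against an independent CART implementation."""
        rng = np.random.default_rng(7)
        ictal = rng.normal(1.25, 0.05, 30)
        inter = rng.normal(0.85, 0.05, 30)
        x = np.concatenate([ictal, inter]).reshape(-1, 1)
        y = np.array([1] * 30 + [0] * 30)
        stump = DecisionTreeClassifier(max_depth=1, random_state=0).fit(x, y)
        sk_cut = stump.tree_.threshold[0]
        ours = nw.tree_threshold(ictal, inter)
        # both must land in the same inter-class gap
        lo, hi = inter.max(), ictal.min()
        assert lo < ours < hi and lo < sk_cut < hi

    def test_oracle_equivalence_on_cohort_like_samples(self):
        rng = np.random.default_rng(7)
        a = rng.normal(1.1, 0.1, 6)
        b = rng.normal(0.9, 0.1, 6)
        assert nw.tree_threshold(a, b) == pytest.approx(
            brute_force_tree_threshold(a, b))


class TestTraditionalThreshold:
    def test_zero_spread(self):
        assert nw.traditional_threshold([1.0, 1.0, 1.0], "interictal") == 1.0

    def test_hand_computed_sd(self):
        want = 1.0 - np.sqrt(((0.9 - 1.0) ** 2 + (1.1 - 1.0) ** 2) / 1)
        assert nw.traditional_threshold([0.9, 1.1], "interictal") == pytest.approx(want)
        assert want == pytest.approx(1.0 - 0.1414, abs=1e-4)

    def test_k_monotonically_lowers_interictal_cutoff(self):
        v = [0.8, 1.0, 1.2]
        t = [nw.traditional_threshold(v, "interictal", k=k) for k in (0.5, 1, 2)]
        assert t[0] > t[1] > t[2]

    def test_ictal_gate_adds_spread(self):
        assert nw.traditional_threshold([0.9, 1.1], "ictal") > 1.0


def table(rows, state="interictal", subject="S1"):
    return pd.DataFrame(
        [{"subject_id": subject, "state": state, "name": n, "side": s, "pi": p}
         for n, s, p in rows])


class TestExtractNetwork:
    def test_inclusive_boundary_both_states(self):
        """A PI exactly at the cut-off is a member in either state."""
        for state in ("ictal", "interictal"):
            t = table([("H", "i", 0.9)], state=state)
            assert nw.extract_network(t, 0.9, state) == {("H", "i")}

    def test_interictal_keeps_low_values(self):
        t = table([("H", "i", 0.8), ("T", "c", 1.1)])
        assert nw.extract_network(t, 0.9, "interictal") == {("H", "i")}

    def test_ictal_keeps_high_values(self):
        t = table([("H", "i", 0.8), ("T", "c", 1.1)], state="ictal")
        assert nw.extract_network(t, 0.9, "ictal") == {("T", "c")}

    def test_empty_table(self):
        empty = table([]).reindex(columns=["subject_id", "state", "name",
                                           "side", "pi"])
        assert nw.extract_network(empty, 0.9, "ictal") == set()

    def test_state_mismatch_rejected(self):
        t = table([("H", "i", 0.8)], state="interictal")
        with pytest.raises(ValueError, match="match"):
            nw.extract_network(t, 0.9, "ictal")

    def test_published_interictal_subject(self, pi_interictal):
        """TLE-1 at its published cut-off 0.854 keeps (MO, c) at 0.523."""
        sub = pi_interictal[pi_interictal["subject_id"] == "TLE-1"]
        members = nw.extract_network(sub, 0.854, "interictal")
        assert ("MO", "c") in members
        above = sub[sub["pi"] > 0.854]
        assert all((n, s) not in members
                   for n, s in zip(above["name"], above["side"]))

    def test_published_ictal_subject(self, pi_ictal):
        sub = pi_ictal[pi_ictal["subject_id"] == "PQE-2"]
        members = nw.extract_network(sub, 1.155, "ictal")
        assert ("SOG", "i") in members


class TestConsensusNetwork:
    def test_min_one_is_union(self):
        nets = [{("H", "i")}, {("T", "c")}]
        cons = nw.consensus_network(nets, 1)
        assert set(zip(cons["name"], cons["side"])) == {("H", "i"), ("T", "c")}

    def test_min_above_count_is_empty(self):
        assert len(nw.consensus_network([{("H", "i")}], 2)) == 0

    def test_mixed_states_rejected(self):
        nets = [("ictal", {("H", "i")}), ("interictal", {("H", "i")})]
        with pytest.raises(ValueError, match="mixed"):
            nw.consensus_network(nets, 1)

    def test_counts_match_brute_tally_on_tle_group(self, pi_interictal,
                                                   thresholds):
        """Consensus counts equal a direct row tally over the fixture."""
        tle = [f"TLE-{i}" for i in range(1, 5)]
        nets, tally = [], {}
        for sid in tle:
            thr = thresholds.query(
                "subject_id == @sid and state == 'interictal'")["threshold"].iloc[0]
            sub = pi_interictal[pi_interictal["subject_id"] == sid]
            members = nw.extract_network(sub, thr, "interictal")
            nets.append(members)
            for key in members:
                tally[key] = tally.get(key, 0) + 1
        cons = nw.consensus_network(nets, 3)
        want = {k: c for k, c in tally.items() if c >= 3}
        got = {(r["name"], r["side"]): r["n_subjects"]
               for _, r in cons.iterrows()}
        assert got == want
        assert len(got) > 0  # brainstem structures recur in this group


class TestSummaries:
    def test_single_value_is_degenerate(self):
        s = nw.summarize_thresholds([0.9])
        assert s.mean == s.median == s.min == s.max == 0.9
        assert s.sd == 0.0 and s.sd_degenerate

    def test_published_injection_time_statistics(self):
        s = nw.summarize_thresholds([7, 17])
        assert s.mean == 12 and round(s.sd, 2) == 7.07
        s = nw.summarize_thresholds([2, 8, 4, 10, 5])
        assert s.mean == pytest.approx(5.8) and round(s.sd, 2) == 3.19

    @given(st.lists(st.floats(0.01, 10, allow_nan=False), min_size=1,
                    max_size=30))
    def test_order_statistics_are_ordered(self, values):
        s = nw.summarize_thresholds(values)
        assert s.min <= s.p5 <= s.median <= s.p95 <= s.max
        assert s.median <= s.max_quartile <= s.max

    def test_per_patient_extremes_single_subject(self):
        t = table([("H", "i", 0.8), ("T", "c", 1.1)])
        per, summ = nw.per_patient_extremes(t, "interictal")
        assert per["min_pi"].iloc[0] == 0.8 and per["max_pi"].iloc[0] == 1.1
        row = summ.set_index("statistic").loc["min_pi"]
        assert row["mean"] == 0.8 and row["sd"] == 0.0

    def test_extremes_match_row_scan_of_fixture(self, pi_interictal):
        per, _ = nw.per_patient_extremes(pi_interictal, "interictal")
        for _, r in per.iterrows():
            vals = pi_interictal[
                pi_interictal["subject_id"] == r["subject_id"]]["pi"]
            assert r["min_pi"] == vals.min() and r["max_pi"] == vals.max()


class TestSubjectThresholds:
    def test_tree_needs_both_states(self):
        t = table([("H", "i", 0.8), ("T", "c", 1.1)])
        res = nw.subject_thresholds(t, method="tree")
        assert len(res) == 0

    def test_traditional_per_state(self):
        t = pd.concat([
            table([("H", "i", 0.8), ("T", "c", 1.0), ("A", "i", 1.2)]),
            table([("H", "i", 1.0), ("T", "c", 1.2), ("A", "i", 1.4)],
                  state="ictal"),
        ])
        res = nw.subject_thresholds(t, method="traditional", k=1.0)
        by = res.set_index("state")["threshold"]
        assert by["interictal"] == pytest.approx(1.0 - 0.2)
        assert by["ictal"] == pytest.approx(1.2 + 0.2)
        assert (res["t_statistic"] > 0).all()

    def test_tree_shares_split_across_states(self):
        t = pd.concat([
            table([("H", "i", 0.8), ("T", "c", 0.9)]),
            table([("H", "i", 1.2), ("T", "c", 1.3)], state="ictal"),
        ])
        res = nw.subject_thresholds(t, method="tree")
        assert len(res) == 2
        assert res["threshold"].nunique() == 1
        assert res["threshold"].iloc[0] == pytest.approx(1.05)
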