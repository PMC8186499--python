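"""Screening: z-scores, alignment, KS test vs enumeration, ranking."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydroscreen.screening import (
    ScreenConfig,
    ScreeningError,
    align,
    ks_screen,
    ks_two_sample,
    rank_candidates,
    screen,
    zscore,
)


# --- independent KS oracle (naive, for cross-checking) ---------------------

def naive_ks_d(a, b):
    """D via explicit counting at every pooled value."""
    a, b = list(a), list(b)
    best = 0.0
    for v in sorted(set(a) | set(b)):
        fa = sum(1 for u in a if u <= v) / len(a)
        fb = sum(1 for u in b if u <= v) / len(b)
        best = max(best, abs(fa - fb))
    return best


def naive_ks_exact(a, b):
    """(D, exact p) by brute-force enumeration of label assignments."""
    a, b = list(a), list(b)
    m = len(a)
    pooled = sorted(a + b)
    d_obs = naive_ks_d(a, b)
    hits = 0
    for idx in combinations(range(len(pooled)), m):
        aa = [pooled[i] for i in idx]
        bb = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        if naive_ks_d(aa, bb) >= d_obs - 1e-12:
            hits += 1
    return d_obs, hits / comb(len(pooled), m)


class TestZscore:
    def test_simple(self):
        assert np.allclose(zscore([1, 2, 3]), [-1, 0, 1])

    def test_constant_rejected(self):
        with pytest.raises(ScreeningError, match="zero variance"):
            zscore([2.0, 2.0, 2.0])

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=20, unique=True))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_mean_zero_sd_one(self, xs):
        z = zscore(xs)
        assert abs(z.mean()) < 1e-9
        assert z.std(ddof=1) == pytest.approx(1.0)


class TestAlign:
    def test_nearest_within_tolerance(self):
        assert align([13, 20, 27], [13, 21, 27]) == [(13, 13), (20, 21), (27, 27)]

    def test_gap_beyond_tolerance_dropped(self, caplog):
        import logging

        with caplog.at_level(logging.INFO, logger="hydroscreen.screening"):
            pairs = align([13, 20, 40], [13, 21, 27])
        assert (40, 27) not in pairs and len(pairs) == 2
        assert any("dropped" in r.message for r in caplog.records)

    def test_identity_pairing(self):
        days = [13, 20, 27, 34]
        assert align(days, days) == [(d, d) for d in days]

    def test_tie_prefers_earlier_sample(self):
        assert align([20], [18, 22]) == [(20, 18)]

    def test_injective(self):
        pairs = align([20, 21], [20])
        assert pairs == [(20, 20)]


class TestKsTwoSample:
    def test_identical_samples(self):
        d, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and p == 1.0

    def test_disjoint_samples_exact_p(self):
        # all C(6,3)=20 assignments; only 2 fully separate the samples
        d, p = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert d == 1.0
        assert p == pytest.approx(0.1)

    def test_equals_enumeration_oracle_with_ties(self, rng):
        for _ in range(40):
            m = int(rng.integers(3, 7))
            n = int(rng.integers(3, 7))
            a = rng.integers(0, 5, size=m)  # integer support forces ties
            b = rng.integers(0, 5, size=n)
            d, p = ks_two_sample(a, b)
            d0, p0 = naive_ks_exact(a, b)
            assert d == pytest.approx(d0, abs=1e-12)
            assert p == pytest.approx(p0, abs=1e-12)

    def test_asymptotic_tail_beyond_exact_limit(self, rng):
        a, b = rng.normal(size=12), rng.normal(size=12)  # m+n=24 > 16
        d, p = ks_two_sample(a, b)
        from scipy.special import kolmogorov

        en = 12 * 12 / 24
        assert p == pytest.approx(float(kolmogorov(np.sqrt(en) * d)))

    def test_short_samples_rejected(self):
        with pytest.raises(ScreeningError):
            ks_two_sample([1, 2], [1, 2, 3])


class TestKsScreen:
    def test_identical_trajectory_retained_with_zero_d(self, rng):
        z_act = zscore(rng.normal(size=8))
        # ASV whose z-trajectory equals the activity z exactly
        rel2 = pd.DataFrame({"same": z_act - z_act.min() + 1.0})
        out = ks_screen(rel2, z_act)
        assert bool(out.loc["same", "retained"])
        assert out.loc["same", "ks_D"] == 0.0

    def test_mirror_is_order_blind(self, rng):
        # -activity has the mirrored z-value multiset; KS sees distributions
        # only, so retention of the mirror depends on value symmetry alone
        z_act = zscore(np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0]))
        rel = pd.DataFrame({"mirror": (-z_act) - (-z_act).min() + 1.0})
        out = ks_screen(rel, z_act)
        d_direct, _ = ks_two_sample(zscore(-z_act), z_act)
        assert out.loc["mirror", "ks_D"] == pytest.approx(d_direct)

    def test_low_prevalence_excluded(self, rng):
        z_act = zscore(rng.normal(size=8))
        rel = pd.DataFrame({"rare": [0.0] * 6 + [0.1, 0.2]})
        out = ks_screen(rel, z_act, min_prevalence=4)
        assert out.loc["rare", "excluded_reason"] == "low_prevalence"
        assert not bool(out.loc["rare", "retained"])


class TestRanking:
    def _run(self, rel, z_act, **kw):
        stats_df = ks_screen(rel, z_act)
        return rank_candidates(stats_df, rel, z_act, **kw)

    def test_perfect_responders_rank_first(self, rng):
        z_act = zscore(np.sort(rng.normal(size=9)))
        cols = {f"bg{i}": np.abs(rng.normal(1, 0.3, size=9)) for i in range(50)}
        for i in range(3):
            cols[f"resp{i}"] = 0.01 * np.exp(z_act) * (1 + 0.001 * i)
        rel = pd.DataFrame(cols)
        ranking = self._run(rel, z_act, n_top=3)
        assert set(ranking.table["asv_id"]) == {"resp0", "resp1", "resp2"}

    def test_r_squared_equals_pearson_squared(self, rng):
        z_act = zscore(rng.normal(size=10))
        rel = pd.DataFrame({f"a{i}": np.abs(rng.normal(1, 0.5, size=10)) for i in range(5)})
        ranking = self._run(rel, z_act, n_top=5)
        for _, row in ranking.table.iterrows():
            r = np.corrcoef(zscore(rel[row["asv_id"]]), z_act)[0, 1]
            assert row["r_squared"] == pytest.approx(r**2, abs=1e-12)
            assert row["slope"] == pytest.approx(r, abs=1e-12)

    def test_empty_retained_gives_empty_ranking(self):
        stats_df = pd.DataFrame(
            {"ks_D": [], "ks_p": [], "retained": pd.Series([], dtype=bool),
             "excluded_reason": []},
        ).rename_axis("asv_id")
        ranking = rank_candidates(stats_df, pd.DataFrame(), np.zeros(4))
        assert ranking.table.empty

    def test_deterministic_tiebreak(self, rng):
        z_act = zscore(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        base = np.exp(z_act)
        rel = pd.DataFrame({"b": 0.02 * base, "a": 0.01 * base, "c": 0.03 * base})
        ranking = self._run(rel, z_act, n_top=3)
        # identical R2: order by mean abundance desc, then asv id
        assert ranking.table["asv_id"].tolist() == ["c", "b", "a"]


class TestScreenEndToEnd:
    def test_recovers_planted_responders(self, synthetic_dataset):
        activity, table, taxonomy, truth = synthetic_dataset
        ranking = screen("R2", "cellulase", table, taxonomy, activity)
        top = set(ranking.table["asv_id"])
        assert len(top & set(truth.responder_ids)) >= 8

    def test_scale_invariance_in_counts_and_activity_units(self, synthetic_dataset):
        activity, table, taxonomy, truth = synthetic_dataset
        r1 = screen("R2", "cellulase", table, taxonomy, activity)
        doubled = table
        doubled.counts.loc[:, :] = doubled.counts.to_numpy() * 2
        import dataclasses

        act2 = dataclasses.replace(
            activity, rates=activity.rates * 3.6 + 0.0, qc_flags=activity.qc_flags)
        r2 = screen("R2", "cellulase", doubled, taxonomy, act2)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_invalid_config_rejected(self, synthetic_dataset):
        activity, table, taxonomy, _ = synthetic_dataset
        with pytest.raises(ScreeningError, match="ks_alpha"):
            screen("R2", "cellulase", table, taxonomy, activity,
                   ScreenConfig(ks_alpha=1.1))

    def test_null_retention_matches_exact_attainable_size(self, rng):
        """Under equal distributions the exact KS test is conservative: its
        rejection rate equals the attainable size P(p <= alpha) computed from
        the permutation null, not nominal alpha."""
        m = n = 6
        ranks = np.arange(1.0, m + n + 1)
        from hydroscreen.screening import _ks_statistic

        ds = []
        for idx in combinations(range(m + n), m):
            aa = ranks[list(idx)]
            bb = np.delete(ranks, list(idx))
            ds.append(_ks_statistic(aa, bb))
        ds = np.array(ds)
        pvals = np.array([(ds >= d - 1e-12).mean() for d in ds])
        attainable = (pvals <= 0.05).mean()

        rejections = 0
        trials = 300
        for _ in range(trials):
            _, p = ks_two_sample(rng.normal(size=m), rng.normal(size=n))
            rejections += p <= 0.05
        rate = rejections / trials
        se = np.sqrt(attainable * (1 - attainable) / trials)
        assert abs(rate - attainable) <= 3 * se + 1e-9
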