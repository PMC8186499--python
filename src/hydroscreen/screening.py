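"""Candidate-ASV screening against hydrolase-activity time series.

The screening procedure: align weekly abundance samples to activity
measurement days, z-score both the per-ASV relative-abundance
trajectories and the activity series, retain the ASVs whose z-value
distribution is statistically indistinguishable from the activity's
(two-sample Kolmogorov–Smirnov non-rejection), and rank the retained
ASVs by the fit (R²) of the linear regression of z-scored abundance on
z-scored activity. The top-N ranked ASVs are reported as hydrolytic
candidates with their KS and regression statistics and taxonomy.

Note the KS test compares value *distributions* and is blind to temporal
ordering; the subsequent regression supplies the ordering-sensitive
ranking. Both steps operate on z-scores, so results are invariant to
affine rescaling of activity units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy import special, stats

from hydroscreen.assay import ActivitySeries
from hydroscreen.profiles import AsvCountTable, TaxonomyTable, filter_samples, to_relative

logger = logging.getLogger(__name__)

#: Largest pooled size for which the exact permutation p-value is used.
EXACT_KS_LIMIT = 16


class ScreeningError(ValueError):
    pass


def zscore(series) -> np.ndarray:
    """(x − mean) / sd with the sample (n−1) standard deviation."""
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        raise ScreeningError("zscore: need >= 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ScreeningError("zscore: zero variance (exclude constant series)")
    return (x - x.mean()) / sd


def align(
    activity_days, sample_days, tolerance_days: int = 3
) -> list[tuple[int, int]]:
    """Pair activity days with the nearest sample day within tolerance.

    The pairing is injective and greedy by smallest gap; ties prefer the
    earlier sample day. Activity days with no sample within
    ``tolerance_days`` are dropped (logged). Returns (activity_day,
    sample_day) pairs sorted by activity day.
    """
    a_days = [int(d) for d in activity_days]
    s_days = [int(d) for d in sample_days]
    cands = sorted(
        (abs(a - s), s, a)
        for a in a_days
        for s in s_days
        if abs(a - s) <= tolerance_days
    )
    used_a: set[int] = set()
    used_s: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for gap, s, a in cands:
        if a in used_a or s in used_s:
            continue
        pairs.append((a, s))
        used_a.add(a)
        used_s.add(s)
    for a in a_days:
        if a not in used_a:
            logger.info("align: activity day %d dropped (no sample within %d days)",
                        a, tolerance_days)
    return sorted(pairs)


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided D = sup over pooled points of |F_a − F_b|.

    Ties are handled by evaluating both right-continuous ECDFs at every
    pooled value, which realises both one-sided suprema at tied points.
    """
    pooled = np.unique(np.concatenate([a, b]))
    fa = np.searchsorted(np.sort(a), pooled, side="right") / len(a)
    fb = np.searchsorted(np.sort(b), pooled, side="right") / len(b)
    return float(np.max(np.abs(fa - fb)))


def _exact_ks_pvalue(a: np.ndarray, b: np.ndarray, d_obs: float) -> float:
    """Permutation-exact P(D ≥ d_obs) by enumerating label assignments.

    Valid with ties: every C(m+n, m) relabelling of the pooled values is
    enumerated and its D compared with d_obs.
    """
    m, n = len(a), len(b)
    pooled = np.sort(np.concatenate([a, b]))
    total = comb(m + n, m)
    hits = 0
    idx_all = frozenset(range(m + n))
    for a_idx in combinations(range(m + n), m):
        aa = pooled[list(a_idx)]
        bb = pooled[list(idx_all - set(a_idx))]
        if _ks_statistic(aa, bb) >= d_obs - 1e-12:
            hits += 1
    return hits / total


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test: (D, p).

    D is the supremum ECDF distance. The p-value is exact (enumeration
    over label assignments of the pooled values) for m + n ≤ 16 — the
    relevant regime for ~10–11 weekly time points, where asymptotics are
    poor — and the asymptotic Kolmogorov tail with effective size
    mn/(m+n) otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ScreeningError("ks_two_sample: both samples need >= 3 values")
    d = _ks_statistic(a, b)
    m, n = len(a), len(b)
    if m + n <= EXACT_KS_LIMIT:
        p = _exact_ks_pvalue(a, b, d)
    else:
        en = m * n / (m + n)
        p = float(np.clip(special.kolmogorov(sqrt(en) * d), 0.0, 1.0))
    return d, p


@dataclass
class ScreenConfig:
    """Thresholds and switches of the screening procedure."""

    min_reads: int = 10_000
    ks_alpha: float = 0.05
    min_prevalence: int = 4
    n_top: int = 25
    align_tolerance_days: int = 3
    taxonomy_rank: str = "genus"
    #: 'z_on_z' regresses z-abundance on z-activity (default reading);
    #: 'ratio_trend' regresses the abundance/activity ratio on day.
    regression: str = "z_on_z"

    def validate(self) -> None:
        if not 0 < self.ks_alpha < 1:
            raise ScreeningError("ks_alpha: must be in (0, 1)")
        if self.n_top < 1:
            raise ScreeningError("n_top: must be >= 1")
        if self.min_prevalence < 2:
            raise ScreeningError("min_prevalence: must be >= 2")
        if self.min_reads < 0:
            raise ScreeningError("min_reads: must be >= 0")
        if self.regression not in ("z_on_z", "ratio_trend"):
            raise ScreeningError(f"regression: unknown {self.regression!r}")


@dataclass
class CandidateRanking:
    """Ranked hydrolytic-candidate table for one reactor–enzyme pair."""

    reactor: str
    enzyme: str
    table: pd.DataFrame  # rank, asv_id, taxonomy, ks_D, ks_p, r_squared, slope, mean_rel_abundance
    n_screened: int
    n_retained: int
    days_used: list[int] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def ks_screen(
    rel_abundance: pd.DataFrame,
    z_activity: np.ndarray,
    alpha: float = 0.05,
    min_prevalence: int = 4,
) -> pd.DataFrame:
    """KS similarity screen of every ASV against the activity z-values.

    ASVs present (non-zero) in fewer than ``min_prevalence`` samples, or
    with zero variance, are excluded before testing (their z-scores are
    degenerate). An ASV is retained when the two-sample KS test does NOT
    reject (p > alpha): its z-value distribution is consistent with the
    activity's. Returns per-ASV D, p, retained, and exclusion reasons.
    """
    rows = []
    for asv in rel_abundance.columns:
        x = rel_abundance[asv].to_numpy(dtype=float)
        if (x > 0).sum() < min_prevalence:
            rows.append((asv, np.nan, np.nan, False, "low_prevalence"))
            continue
        if np.ptp(x) == 0:
            rows.append((asv, np.nan, np.nan, False, "constant"))
            continue
        # z-vectors are rounded so that trajectories identical up to affine
        # maps compare as exact ties (D = 0) despite float rounding
        d, p = ks_two_sample(np.round(zscore(x), 9), np.round(z_activity, 9))
        rows.append((asv, d, p, p > alpha, ""))
    return pd.DataFrame(
        rows, columns=["asv_id", "ks_D", "ks_p", "retained", "excluded_reason"]
    ).set_index("asv_id")


def rank_candidates(
    screen_stats: pd.DataFrame,
    rel_abundance: pd.DataFrame,
    z_activity: np.ndarray,
    taxonomy: TaxonomyTable | None = None,
    n_top: int = 25,
    taxonomy_rank: str = "genus",
    reactor: str = "",
    enzyme: str = "",
    days_used: list[int] | None = None,
    regression: str = "z_on_z",
    days: np.ndarray | None = None,
    activity: np.ndarray | None = None,
) -> CandidateRanking:
    """Rank KS-retained ASVs by regression fit and emit the top N.

    Default ranking regresses each retained ASV's z-scored abundance on
    the z-scored activity by OLS and sorts by R² (descending); on
    z-scored pairs R² = r² and the slope equals the Pearson correlation.
    Ties break toward higher mean relative abundance, then lexicographic
    ASV id, so emitted tables are byte-reproducible.
    """
    retained = screen_stats[screen_stats["retained"]]
    if retained.empty:
        logger.warning("rank_candidates: no ASVs retained by the KS screen")
    rows = []
    for asv in retained.index:
        x = rel_abundance[asv].to_numpy(dtype=float)
        zx = zscore(x)
        if regression == "z_on_z":
            res = stats.linregress(z_activity, zx)
            r2, slope = float(res.rvalue**2), float(res.slope)
        else:  # ratio_trend: abundance normalised by activity, regressed on day
            if days is None or activity is None:
                raise ScreeningError("regression: ratio_trend needs days and activity")
            ratio = x / np.asarray(activity, dtype=float)
            res = stats.linregress(np.asarray(days, dtype=float), ratio)
            r2, slope = float(res.rvalue**2), float(res.slope)
        rows.append(
            {
                "asv_id": asv,
                "taxonomy": taxonomy.label(asv, taxonomy_rank) if taxonomy else "",
                "ks_D": float(retained.loc[asv, "ks_D"]),
                "ks_p": float(retained.loc[asv, "ks_p"]),
                "r_squared": r2,
                "slope": slope,
                "mean_rel_abundance": float(x.mean()),
            }
        )
    cols = ["rank", "asv_id", "taxonomy", "ks_D", "ks_p", "r_squared", "slope",
            "mean_rel_abundance"]
    if rows:
        df = pd.DataFrame(rows)
        df = df.sort_values(
            by=["r_squared", "mean_rel_abundance", "asv_id"],
            ascending=[False, False, True],
            kind="mergesort",
        ).head(n_top)
        df.insert(0, "rank", np.arange(1, len(df) + 1))
        df = df.reset_index(drop=True)
    else:
        df = pd.DataFrame(columns=cols)
    n_screened = int((screen_stats["excluded_reason"] == "").sum())
    return CandidateRanking(
        reactor=reactor,
        enzyme=enzyme,
        table=df[cols],
        n_screened=n_screened,
        n_retained=int(screen_stats["retained"].sum()),
        days_used=days_used or [],
    )


def screen(
    reactor: str,
    enzyme: str,
    table: AsvCountTable,
    taxonomy: TaxonomyTable | None,
    activity: ActivitySeries,
    config: ScreenConfig | None = None,
    replicate: str | None = None,
) -> CandidateRanking:
    """End-to-end screen for one reactor–enzyme combination.

    Depth-filter → subset to the reactor (and, optionally, the replicate
    in which enzymes were assayed) → relative abundance → align days →
    z-score → KS screen → regression ranking. Deterministic given inputs.
    """
    config = config or ScreenConfig()
    config.validate()
    sub = table.for_reactor(reactor, replicate)
    if sub.counts.empty:
        raise ScreeningError(f"screen: no samples for reactor {reactor!r}")
    sub = filter_samples(sub, config.min_reads)
    if sub.counts.empty:
        raise ScreeningError("screen: all samples removed by the depth filter")
    rel = to_relative(sub)

    day_of_sample = sub.metadata["day"].astype(int)
    pairs = align(activity.days, day_of_sample.tolist(), config.align_tolerance_days)
    if len(pairs) < 4:
        raise ScreeningError("screen: fewer than 4 aligned time points")
    act_day_to_rate = dict(zip((int(d) for d in activity.days), activity.rates))
    # one sample per day: with both replicates present, the first sample id
    # (sorted) stands in for the assayed reactor unless `replicate` is given
    sample_for_day: dict[int, str] = {}
    for sid in sorted(day_of_sample.index):
        sample_for_day.setdefault(int(day_of_sample[sid]), sid)
    sample_order = [sample_for_day[s_day] for _, s_day in pairs]
    act_values = np.array([act_day_to_rate[a_day] for a_day, _ in pairs])

    rel_aligned = rel.loc[sample_order]
    z_act = zscore(act_values)
    stats_df = ks_screen(rel_aligned, z_act, config.ks_alpha, config.min_prevalence)
    return rank_candidates(
        stats_df,
        rel_aligned,
        z_act,
        taxonomy=taxonomy,
        n_top=config.n_top,
        taxonomy_rank=config.taxonomy_rank,
        reactor=reactor,
        enzyme=enzyme,
        days_used=[a for a, _ in pairs],
        regression=config.regression,
        days=np.array([a for a, _ in pairs], dtype=float),
        activity=act_values,
    )
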