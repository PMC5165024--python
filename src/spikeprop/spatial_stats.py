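"""Spatial autocorrelation (Moran Index), permutation nulls, group stats.

The Moran Index of a per-channel scalar field F with spatial weights w is

    I = N / (sum_ij w_ij) * sum_ij w_ij (F_i - F_avg)(F_j - F_avg)
                            / sum_i (F_i - F_avg)^2,

ranging in practice from -1 (neighboring channels anti-correlated) to +1
(similar values cluster in space), with 0 meaning no spatial pattern; under
random relabeling its expectation is -1/(N-1).  Weights are inverse
distance with a 1.5 cm cutoff (immediate neighbors, including diagonals,
on a 10 mm grid).  The same statistic is applied to spike-frequency maps
(spikes/min) and to recruitment-latency maps (ms); for latency maps the
computation restricts N, F_avg and the weights to channels that carry
latency data.

Outcome groups are compared with the Wilcoxon rank-sum test.  With the
small group sizes typical of surgical cohorts (n = 9 per arm) the p-value
is computed by exact enumeration of the rank-sum distribution over all
C(n_a + n_b, n_a) group relabelings, using mid-ranks for ties; larger
samples fall back to the tie-corrected normal approximation.  A Bonferroni
threshold alpha / n_comparisons accompanies each comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import DegenerateInputError, ValidationError
from .geometry import SpatialWeights


@dataclass(frozen=True)
class MoranResult:
    I: float
    n_used: int
    radius_mm: float
    expected_null: float  # -1/(N-1)


def moran_index(field, weights: SpatialWeights) -> MoranResult:
    """Moran Index of a per-channel field (Series/dict keyed by channel id).

    The field is restricted to channels present in both the field and the
    weights; the mean, variance and weight sums are recomputed on that
    subset.  Errors on zero variance or when no channel pair falls within
    the weight radius.
    """
    f = pd.Series(field).astype(float)
    ids = f.index.to_numpy()
    common = ids[np.isin(ids, weights.channel_ids)]
    if len(common) < 2:
        raise ValidationError("need >= 2 channels with defined values and weights")
    w = weights.subset(common).matrix
    x = f.loc[common].to_numpy()
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise DegenerateInputError("constant field: Moran Index undefined")
    w_sum = w.sum()
    if w_sum == 0:
        raise DegenerateInputError("no neighbor pairs within radius")
    num = float(z @ w @ z)
    n = len(common)
    return MoranResult(I=n / w_sum * num / denom, n_used=n,
                       radius_mm=weights.radius_mm, expected_null=-1.0 / (n - 1))


@dataclass(frozen=True)
class MoranPermutation:
    observed: float
    mean: float
    sd: float
    p_upper: float  # (1 + #{I_perm >= I_obs}) / (n_perm + 1)
    n_perm: int


def moran_permutation_null(field, weights: SpatialWeights, n_perm: int = 999,
                           seed: int = 0) -> MoranPermutation:
    """Null distribution of I under random relabeling of values to channels."""
    f = pd.Series(field).astype(float)
    obs = moran_index(f, weights)
    ids = f.index.to_numpy()
    common = ids[np.isin(ids, weights.channel_ids)]
    w = weights.subset(common).matrix
    x = f.loc[common].to_numpy()
    n = len(common)
    w_sum = w.sum()
    rng = np.random.default_rng(seed)
    draws = np.empty(n_perm)
    for k in range(n_perm):
        z = rng.permutation(x)
        z = z - z.mean()
        draws[k] = n / w_sum * (z @ w @ z) / (z @ z)
    p = (1 + np.sum(draws >= obs.I)) / (n_perm + 1)
    return MoranPermutation(obs.I, float(draws.mean()), float(draws.std(ddof=1)),
                            float(p), n_perm)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum with exact mid-rank enumeration for small samples


def _exact_ranksum_p(ranks: np.ndarray, n_a: int) -> float:
    """Two-sided exact p for the rank-sum of group A given pooled mid-ranks.

    Enumerates the distribution of the sum of ``n_a`` ranks drawn without
    replacement from ``ranks`` by dynamic programming over doubled ranks
    (mid-ranks are multiples of 1/2, so doubling makes them integers).
    p = P(|W - E[W]| >= |w_obs - E[W]|), where w_obs is the observed sum of
    group A's ranks (conventionally the first n_a entries of ``ranks``).
    """
    r2 = np.round(ranks * 2).astype(int)
    n = len(r2)
    total = r2.sum()
    # ways[k][s] = number of k-subsets of r2 with sum s
    max_s = total
    ways = np.zeros((n_a + 1, max_s + 1), dtype=float)
    ways[0, 0] = 1.0
    for r in r2:
        for k in range(n_a - 1, -1, -1):
            ways[k + 1, r:] += ways[k, :max_s + 1 - r]
    counts = ways[n_a]
    n_comb = math.comb(n, n_a)
    w_obs2 = int(np.round(ranks[:n_a].sum() * 2))
    mu2 = n_a * (total / n)  # doubled-scale expectation
    dev = abs(w_obs2 - mu2)
    sums = np.arange(max_s + 1)
    hit = np.abs(sums - mu2) >= dev - 1e-9
    return float(counts[hit].sum() / n_comb)


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    statistic: float  # rank-sum of group A (mid-ranks)
    p: float
    alpha_adjusted: float
    method: str  # "exact" | "normal"

    @property
    def significant(self) -> bool:
        return self.p < self.alpha_adjusted


def group_compare(values_a, values_b, n_comparisons: int = 2,
                  alpha: float = 0.05, exact_max_n: int = 10) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of two value lists.

    Exact mid-rank enumeration when both groups have at most
    ``exact_max_n`` members, tie-corrected normal approximation (with
    continuity correction) otherwise.  Group means +/- sample SD are
    reported alongside the Bonferroni-adjusted alpha.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    w = float(ranks[:a.size].sum())
    if np.unique(pooled).size == 1:
        p, method = 1.0, "degenerate"
    elif max(a.size, b.size) <= exact_max_n:
        p, method = _exact_ranksum_p(ranks, a.size), "exact"
    else:
        n, n_a = pooled.size, a.size
        mu = n_a * (n + 1) / 2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(tie_counts ** 3 - tie_counts) / ((n) * (n - 1))
        var = n_a * b.size / 12 * ((n + 1) - tie_term / 1.0)
        z = (w - mu - np.sign(w - mu) * 0.5) / np.sqrt(var)
        from scipy.stats import norm
        p, method = float(2 * norm.sf(abs(z))), "normal"
    sd = lambda v: float(np.std(v, ddof=1)) if v.size > 1 else 0.0  # noqa: E731
    return GroupComparison(float(a.mean()), sd(a), float(b.mean()), sd(b),
                           w, min(p, 1.0), alpha / n_comparisons, method)


# ---------------------------------------------------------------------------
# Cohort reference tables


def load_cohort_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Packaged 18-patient cohort tables (clinical + spike-analysis columns)."""
    pkg = resources.files("spikeprop") / "data"
    t1 = pd.read_csv(str(pkg / "table1.csv"), comment="#")
    t2 = pd.read_csv(str(pkg / "table2.csv"), comment="#")
    if len(t1) != 18 or len(t2) != 18:
        raise ValidationError("cohort tables must have 18 patient rows")
    return t1, t2


def _printed_ulp(x: float, text: str) -> float:
    """Half of the last printed digit of ``text`` (e.g. '0.377' -> 5e-4)."""
    if "." not in text:
        return 0.5
    return 0.5 * 10 ** -len(text.split(".")[1].rstrip())


def reproduce_cohort_stats(t1: pd.DataFrame, t2: pd.DataFrame,
                           alpha: float = 0.05) -> dict:
    """Recompute every derived cell and group summary of the cohort tables.

    Derived per-patient cells — spike density = spikes / (electrodes x
    minutes) and sequence frequency = sequences / minutes — are checked
    against their printed values with an error-propagation tolerance:
    the printed analyzed-minutes are rounded to 2 decimals, so a derived
    cell may drift by up to value * (0.005 / minutes) beyond half its own
    printed ulp.  Cells exceeding that bound are reported under
    ``mismatches``.

    Group rows (Sz-Free = Engel 1, Sz-Persist = Engel >= 2, n = 9 each)
    are recomputed as mean +/- sample SD with exact rank-sum p-values.
    """
    merged = t1.merge(t2, on="patient")
    free = merged[merged["engel"] == 1]
    persist = merged[merged["engel"] > 1]
    if len(free) != 9 or len(persist) != 9:
        raise ValidationError("expected 9 patients per outcome group")

    mismatches = []
    for _, row in merged.iterrows():
        minutes = row["analyzed_minutes"]
        checks = [
            ("spike_density", row["spikes"] / (row["electrodes"] * minutes)),
            ("sequence_frequency", row["total_sequences"] / minutes),
        ]
        for col, computed in checks:
            printed = row[col]
            tol = printed * (0.005 / minutes) + _printed_ulp(printed, f"{printed}") + 1e-12
            if abs(computed - printed) > tol:
                mismatches.append({"patient": row["patient"], "column": col,
                                   "printed": printed, "computed": computed})

    comparisons = {}
    for col in ("age_years", "electrodes", "soz_pct", "analyzed_minutes",
                "spike_density", "frequency_moran", "total_sequences",
                "sequence_frequency", "latency_moran"):
        comparisons[col] = group_compare(free[col], persist[col],
                                         n_comparisons=2, alpha=alpha)

    return {
        "groups": {"sz_free": free["patient"].tolist(),
                   "sz_persist": persist["patient"].tolist()},
        "comparisons": comparisons,
        "overall": {
            "mean_age_years": float(merged["age_years"].mean()),
            "mean_sequence_frequency": float(merged["sequence_frequency"].mean()),
            "sd_sequence_frequency": float(merged["sequence_frequency"].std(ddof=1)),
        },
        "mismatches": mismatches,
    }
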