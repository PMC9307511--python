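"""Nucleotide-resolution detection of structurally variable regions (SVRs).

Given normalized reactivities for two conditions, structural variation is
first scored per nucleotide: at position j the reactivities of all replicates
within a window of radius r around j (default 2 nt, truncated at transcript
ends) are pooled per condition and compared with a two-sided Wilcoxon
rank-sum test, giving positional p-values p_j.

Positional evidence is then aggregated over candidate regions R (every
window with length between L_min and L_max) through the scan statistic

    Q(R) = (-Σ_{j∈R} log p_j) / sqrt(|R|),

which rewards accumulated signal while penalizing region length, so that SVR
boundaries can be located by maximizing Q over overlapping regions of
different lengths.

Significance is calibrated by Monte Carlo against the null hypothesis of no
structural difference, under which the positional p-values are marginally
Uniform(0,1): B null transcripts of the same length are synthesized, the
maximum of Q over all candidate regions is recorded for each, and a region's
p-value is its Q's add-one tail rank among those maxima. Because the null
maximum ranges over every candidate region, thresholding at the (1-alpha)
quantile controls the family-wise error rate across the overlapping tests.

Because test windows of neighboring positions overlap, neighboring p_j are
strongly positively correlated even under the null; a null that draws the
p_j independently ignores this and is anti-conservative. The default
("windowed") null therefore simulates at the reactivity level: i.i.d.
replicate values are drawn with the real replicate counts, the windowed
rank-sum p-values are recomputed with the same geometry, and max Q is taken
— reproducing the dependence exactly. The literal i.i.d.-uniform null and a
replicate-label permutation null are available as alternatives.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io import ReactivityDataset, ValidationError

__all__ = [
    "PositionalPValues",
    "CandidateRegion",
    "NullDistribution",
    "ScanResult",
    "positional_pvalues",
    "rank_sum_pvalue",
    "scan_statistic",
    "enumerate_candidate_regions",
    "simulate_null_distribution",
    "simulate_windowed_null",
    "call_svrs",
    "rank_nucleotides",
    "NullCache",
    "scan_dataset",
    "write_svr_table",
    "write_position_table",
]

logger = logging.getLogger(__name__)

DEFAULT_RADIUS = 2
DEFAULT_L_MIN = 1
DEFAULT_L_MAX = 100
DEFAULT_ALPHA = 0.05
DEFAULT_B = 1000
MIN_OBS = 3  # smallest pooled sample size for which the rank test is run
# nulls are shared between transcripts whose lengths differ by at most this
# relative amount; the shared null is simulated at the bin's upper edge so
# reuse errs on the conservative side
NULL_BIN_REL = 0.05
EXACT_MAX = 10  # exact rank-sum enumeration when both pooled samples <= this


# ---------------------------------------------------------------------------
# Positional rank-sum tests
# ---------------------------------------------------------------------------


def rank_sum_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value for two pooled samples.

    Exact enumeration of the rank-sum distribution when both samples have at
    most ``EXACT_MAX`` values and there are no ties; otherwise the normal
    approximation with tie and continuity corrections. Identical sample
    multisets return exactly 1 so that p stays in (0, 1].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("rank-sum test requires nonempty samples")
    if a.size == b.size and np.array_equal(np.sort(a), np.sort(b)):
        return 1.0
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and a.size <= EXACT_MAX and b.size <= EXACT_MAX:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


@dataclass
class PositionalPValues:
    """Per-position two-sided p-values p_j for one transcript (NaN = untestable)."""

    transcript_id: str
    p: np.ndarray
    radius: int = DEFAULT_RADIUS

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        finite = self.p[~np.isnan(self.p)]
        if finite.size and ((finite <= 0).any() or (finite > 1).any()):
            raise ValidationError("positional p-values must lie in (0, 1]")

    @property
    def length(self) -> int:
        return int(self.p.size)


def _positional_pvalues_one(
    mat_a: np.ndarray, mat_b: np.ndarray, radius: int, min_obs: int
) -> np.ndarray:
    n = mat_a.shape[1]
    p = np.full(n, np.nan)
    finite_a = ~np.isnan(mat_a)
    finite_b = ~np.isnan(mat_b)
    for j in range(n):
        lo = max(0, j - radius)
        hi = min(n, j + radius + 1)
        wa = mat_a[:, lo:hi]
        a = wa[finite_a[:, lo:hi]]
        if a.size < min_obs:
            continue
        wb = mat_b[:, lo:hi]
        b = wb[finite_b[:, lo:hi]]
        if b.size < min_obs:
            continue
        p[j] = rank_sum_pvalue(a, b)
    return p


def positional_pvalues(
    dataset: ReactivityDataset,
    radius: int = DEFAULT_RADIUS,
    min_obs: int = MIN_OBS,
) -> dict[str, PositionalPValues]:
    """Windowed rank-sum p-values for every transcript of a two-condition dataset.

    For each position j, reactivities of all replicates over the window
    [j-r, j+r] (clipped to the transcript) are pooled per condition;
    positions where either pooled sample has fewer than ``min_obs``
    non-missing values are untestable (NaN).
    """
    cond_a, cond_b = dataset.condition_pair()
    out: dict[str, PositionalPValues] = {}
    for tx in dataset.transcript_ids:
        mat_a = dataset.matrix(tx, cond_a)
        mat_b = dataset.matrix(tx, cond_b)
        p = _positional_pvalues_one(mat_a, mat_b, radius, min_obs)
        n_missing = int(np.isnan(p).sum())
        if n_missing:
            logger.info("%s: %d of %d positions untestable", tx, n_missing, p.size)
        out[tx] = PositionalPValues(tx, p, radius)
    return out


# ---------------------------------------------------------------------------
# Scan statistic and candidate regions
# ---------------------------------------------------------------------------


def scan_statistic(p_values: Sequence[float]) -> float:
    """Q(R) = (-Σ log p_j) / sqrt(|R|) with natural logs."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("scan statistic of an empty region is undefined")
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValidationError("scan statistic requires all p in (0, 1]")
    return float(-np.log(p).sum() / math.sqrt(p.size))


@dataclass
class CandidateRegion:
    """A candidate region [start, end] (1-based inclusive) and its Q score."""

    transcript_id: str
    start: int
    end: int
    q: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def positions(self) -> np.ndarray:
        return np.arange(self.start, self.end + 1)

    def overlaps(self, other: "CandidateRegion") -> bool:
        return self.start <= other.end and other.start <= self.end


def enumerate_candidate_regions(
    pvals: PositionalPValues,
    L_min: int = DEFAULT_L_MIN,
    L_max: int = DEFAULT_L_MAX,
) -> list[CandidateRegion]:
    """All windows of length L_min..L_max whose positions are all testable.

    Stride 1; L_max is clamped to the transcript length. Regions are returned
    ordered by (start, length).
    """
    if L_min < 1 or L_max < L_min:
        raise ValidationError(f"need 1 <= L_min <= L_max, got ({L_min}, {L_max})")
    n = pvals.length
    L_max = min(L_max, n)
    s = -np.log(pvals.p)  # NaN propagates for untestable positions
    cs = np.concatenate([[0.0], np.nancumsum(s)])
    bad = np.concatenate([[0], np.cumsum(np.isnan(s).astype(np.int64))])
    regions: list[CandidateRegion] = []
    for start0 in range(n):
        for L in range(L_min, min(L_max, n - start0) + 1):
            end0 = start0 + L
            if bad[end0] - bad[start0]:
                continue
            q = (cs[end0] - cs[start0]) / math.sqrt(L)
            regions.append(CandidateRegion(pvals.transcript_id, start0 + 1, end0, q))
    return regions


def _max_scan_statistic(neglogp: np.ndarray, L_min: int, L_max: int) -> np.ndarray:
    """Row-wise max of Q over all candidate regions; neglogp is (B, n)."""
    B, n = neglogp.shape
    L_max = min(L_max, n)
    cs = np.concatenate([np.zeros((B, 1)), np.cumsum(neglogp, axis=1)], axis=1)
    best = np.full(B, -np.inf)
    for L in range(L_min, L_max + 1):
        sums = cs[:, L:] - cs[:, :-L]
        np.maximum(best, sums.max(axis=1) / math.sqrt(L), out=best)
    return best


# ---------------------------------------------------------------------------
# Monte-Carlo null and SVR calling
# ---------------------------------------------------------------------------


@dataclass
class NullDistribution:
    """Monte-Carlo sample of max-Q under i.i.d. Uniform(0,1) positional p-values."""

    n: int
    L_min: int
    L_max: int
    samples: np.ndarray  # sorted ascending, length B
    seed: int | None = None
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        self.samples = np.sort(np.asarray(self.samples, dtype=float))
        if self.samples.size < 100:
            raise ValidationError("null distribution needs B >= 100 samples")

    @property
    def B(self) -> int:
        return int(self.samples.size)

    @property
    def threshold(self) -> float:
        """(1 - alpha) empirical quantile of the null maxima."""
        return float(np.quantile(self.samples, 1.0 - self.alpha))

    def pvalue(self, q: float) -> float:
        """Add-one Monte-Carlo p-value (1 + #{T_b >= q}) / (B + 1)."""
        n_ge = self.B - int(np.searchsorted(self.samples, q, side="left"))
        return (1 + n_ge) / (self.B + 1)


def simulate_null_distribution(
    n: int,
    L_min: int = DEFAULT_L_MIN,
    L_max: int = DEFAULT_L_MAX,
    B: int = DEFAULT_B,
    seed: int | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> NullDistribution:
    """Draw B null transcripts of length n and record each one's max Q.

    Under H0 the positional p-values are i.i.d. Uniform(0,1); T_b is the
    maximum of Q over every candidate region of the b-th draw.
    """
    if B < 100:
        raise ValidationError("B must be >= 100")
    rng = np.random.default_rng(seed)
    neglogp = rng.standard_exponential(size=(B, n))  # -log U(0,1)
    samples = _max_scan_statistic(neglogp, L_min, min(L_max, n))
    return NullDistribution(n=n, L_min=L_min, L_max=L_max, samples=samples,
                            seed=seed, alpha=alpha)


from functools import lru_cache


@lru_cache(maxsize=64)
def _ranksum_pmf(m: int, n: int) -> np.ndarray:
    """Exact null pmf of the rank-sum W of the first sample (sizes m, n, no ties).

    Entry k is P(W = k + m(m+1)/2). Computed by the classic subset-sum
    recursion over ranks 1..m+n.
    """
    N = m + n
    w_min = m * (m + 1) // 2
    w_max = m * (2 * N - m + 1) // 2
    span = w_max - w_min + 1
    # dp[k, s] = #subsets of size k of {1..i} with sum s - shifted by k*(k+1)/2
    dp = np.zeros((m + 1, span), dtype=float)
    dp[0, 0] = 1.0
    for i in range(1, N + 1):
        for k in range(min(i, m), 0, -1):
            # adding rank i to a (k-1)-subset shifts the sum by i - k
            shift = i - k
            dp[k, shift:] += dp[k - 1, : span - shift] if shift else dp[k - 1]
    pmf = dp[m]
    return pmf / pmf.sum()


def _exact_two_sided_p(m: int, n: int, w: np.ndarray) -> np.ndarray:
    """Vectorized exact two-sided rank-sum p-values for integer rank sums w."""
    pmf = _ranksum_pmf(m, n)
    cdf = np.cumsum(pmf)
    sf = np.cumsum(pmf[::-1])[::-1]  # P(W >= w)
    idx = np.asarray(np.rint(w), dtype=np.int64) - m * (m + 1) // 2
    return np.minimum(1.0, 2.0 * np.minimum(cdf[idx], sf[idx]))


def simulate_windowed_null(
    n: int,
    n_a: int,
    n_b: int,
    radius: int = DEFAULT_RADIUS,
    L_min: int = DEFAULT_L_MIN,
    L_max: int = DEFAULT_L_MAX,
    B: int = DEFAULT_B,
    seed: int | None = None,
    alpha: float = DEFAULT_ALPHA,
    min_obs: int = MIN_OBS,
) -> NullDistribution:
    """Dependence-preserving Monte-Carlo null for the windowed scan.

    Each of the B null transcripts draws i.i.d. continuous values for n_a
    and n_b replicates over n positions, computes the windowed two-sided
    rank-sum p-value at every position with the same radius as the real
    analysis (exact, tie-free), and records the maximum of Q over all
    candidate regions. Unlike drawing p_j i.i.d. Uniform(0,1), this retains
    the strong positive correlation between neighboring p_j caused by the
    overlapping windows, which would otherwise make the scan
    anti-conservative.
    """
    if B < 100:
        raise ValidationError("B must be >= 100")
    if n_a < 1 or n_b < 1:
        raise ValidationError("need at least one replicate per condition")
    rng = np.random.default_rng(seed)
    xa = rng.random((B, n_a, n))
    xb = rng.random((B, n_b, n))
    p = np.full((B, n), np.nan)
    for j in range(n):
        lo = max(0, j - radius)
        hi = min(n, j + radius + 1)
        a = xa[:, :, lo:hi].reshape(B, -1)
        b = xb[:, :, lo:hi].reshape(B, -1)
        m, nn = a.shape[1], b.shape[1]
        if m < min_obs or nn < min_obs:
            continue
        pooled = np.concatenate([a, b], axis=1)
        # continuous draws: ranks via argsort, no ties almost surely
        order = np.argsort(pooled, axis=1)
        ranks = np.empty_like(order)
        rows = np.arange(B)[:, None]
        ranks[rows, order] = np.arange(1, m + nn + 1)
        w = ranks[:, :m].sum(axis=1)
        p[:, j] = _exact_two_sided_p(m, nn, w)
    neglogp = -np.log(p)
    neglogp[np.isnan(neglogp)] = 0.0
    samples = _max_scan_statistic(neglogp, L_min, min(L_max, n))
    return NullDistribution(n=n, L_min=L_min, L_max=min(L_max, n),
                            samples=samples, seed=seed, alpha=alpha)


@dataclass
class ScanResult:
    """Called SVRs for one transcript plus everything needed to rank positions."""

    transcript_id: str
    n: int
    svrs: list[CandidateRegion]
    svr_pvalues: list[float]
    pvals: PositionalPValues | None
    null: NullDistribution
    alpha: float

    def svr_positions(self) -> np.ndarray:
        if not self.svrs:
            return np.empty(0, dtype=np.int64)
        return np.concatenate([r.positions() for r in self.svrs])


def call_svrs(
    regions: Sequence[CandidateRegion],
    null: NullDistribution,
    alpha: float = DEFAULT_ALPHA,
    n: int | None = None,
    pvals: PositionalPValues | None = None,
) -> ScanResult:
    """Report significant, mutually non-overlapping regions as SVRs.

    Each region gets the add-one Monte-Carlo p-value of its Q against the
    null maxima; regions with p <= alpha are candidates, and a greedy pass in
    order of descending Q (ties: longer region, then smaller start) keeps a
    non-overlapping subset.
    """
    if n is None:
        n = max((r.end for r in regions), default=null.n)
    if regions:
        L_obs_max = max(r.length for r in regions)
        L_obs_min = min(r.length for r in regions)
        if L_obs_min < null.L_min or L_obs_max > null.L_max:
            raise ValidationError(
                f"region lengths [{L_obs_min}, {L_obs_max}] outside null's "
                f"[{null.L_min}, {null.L_max}]"
            )
        if null.n < n or null.n > math.ceil(n * (1 + NULL_BIN_REL)):
            raise ValidationError(
                f"null simulated for length {null.n} cannot cover transcript "
                f"length {n} (allowed up to +{NULL_BIN_REL:.0%})"
            )
    tx = regions[0].transcript_id if regions else (pvals.transcript_id if pvals else "")
    significant = [r for r in regions if null.pvalue(r.q) <= alpha]
    significant.sort(key=lambda r: (-r.q, -r.length, r.start))
    chosen: list[CandidateRegion] = []
    for r in significant:
        if not any(r.overlaps(c) for c in chosen):
            chosen.append(r)
    chosen.sort(key=lambda r: r.start)
    return ScanResult(
        transcript_id=tx,
        n=n,
        svrs=chosen,
        svr_pvalues=[null.pvalue(r.q) for r in chosen],
        pvals=pvals,
        null=null,
        alpha=alpha,
    )


def rank_nucleotides(result: ScanResult) -> np.ndarray:
    """Total order of positions (best first) for top-k evaluation curves.

    Positions inside called SVRs rank above all others, ordered by the Q of
    the covering called region (descending), then by positional p-value
    (ascending). Remaining positions follow, ordered by positional p-value;
    untestable positions come last. With no called SVRs, the order falls
    back to ascending positional p.
    """
    n = result.n
    in_svr = np.zeros(n, dtype=bool)
    cover_q = np.full(n, -np.inf)
    for r in result.svrs:
        sl = slice(r.start - 1, r.end)
        in_svr[sl] = True
        cover_q[sl] = np.maximum(cover_q[sl], r.q)
    if result.pvals is not None:
        p = result.pvals.p.copy()
    else:
        p = np.full(n, np.nan)
    p_key = np.where(np.isnan(p), 2.0, p)  # untestable ranks after any real p
    order = sorted(
        range(n),
        key=lambda j: (0 if in_svr[j] else 1, -cover_q[j] if in_svr[j] else 0.0,
                       p_key[j], j),
    )
    return np.asarray(order, dtype=np.int64) + 1


# ---------------------------------------------------------------------------
# Orchestration over a dataset
# ---------------------------------------------------------------------------


class NullCache:
    """Shares null distributions across transcripts of similar length.

    Lengths are binned geometrically by factors of (1 + NULL_BIN_REL) and the
    null is simulated at the bin's upper edge, so a cached null is valid (and
    slightly conservative) for every length in its bin. In "windowed" mode
    the cache key also carries the replicate counts and radius, which the
    dependence-preserving null depends on. Seeds per bin are derived
    deterministically from the root seed.
    """

    def __init__(self, L_min: int, L_max: int, B: int, seed: int,
                 alpha: float = DEFAULT_ALPHA, mode: str = "windowed",
                 radius: int = DEFAULT_RADIUS, min_obs: int = MIN_OBS):
        if mode not in ("windowed", "uniform"):
            raise ValidationError(f"NullCache mode must be windowed or uniform, got {mode!r}")
        self.L_min = L_min
        self.L_max = L_max
        self.B = B
        self.seed = seed
        self.alpha = alpha
        self.mode = mode
        self.radius = radius
        self.min_obs = min_obs
        self._cache: dict[tuple, NullDistribution] = {}

    def _bin_length(self, n: int) -> int:
        k = math.ceil(math.log(n) / math.log(1 + NULL_BIN_REL) - 1e-9)
        n_rep = math.ceil((1 + NULL_BIN_REL) ** k - 1e-9)
        return max(n, n_rep)

    def get(self, n: int, n_a: int = 0, n_b: int = 0) -> NullDistribution:
        n_rep = self._bin_length(n)
        key = (n_rep, n_a, n_b) if self.mode == "windowed" else (n_rep,)
        if key not in self._cache:
            ss = np.random.SeedSequence(entropy=self.seed, spawn_key=key)
            bin_seed = int(ss.generate_state(1)[0] % (2**31))
            if self.mode == "windowed":
                if n_a < 1 or n_b < 1:
                    raise ValidationError("windowed null needs replicate counts")
                null = simulate_windowed_null(
                    n=n_rep, n_a=n_a, n_b=n_b, radius=self.radius,
                    L_min=self.L_min, L_max=min(self.L_max, n_rep),
                    B=self.B, seed=bin_seed, alpha=self.alpha,
                    min_obs=self.min_obs,
                )
            else:
                null = simulate_null_distribution(
                    n=n_rep, L_min=self.L_min, L_max=min(self.L_max, n_rep),
                    B=self.B, seed=bin_seed, alpha=self.alpha,
                )
            self._cache[key] = null
        return self._cache[key]


def _permutation_null(
    dataset: ReactivityDataset,
    tx: str,
    radius: int,
    L_min: int,
    L_max: int,
    B: int,
    seed: int,
    alpha: float,
    min_obs: int = MIN_OBS,
) -> NullDistribution:
    """Null from random relabelings of replicates between conditions.

    A sensitivity-analysis alternative to the uniform null: condition labels
    of replicates are shuffled (group sizes preserved), positional p-values
    recomputed, and the max Q recorded per shuffle. Retains the dependence
    between neighboring p-values induced by overlapping windows.
    """
    cond_a, cond_b = dataset.condition_pair()
    mats = [dataset.matrix(tx, cond_a), dataset.matrix(tx, cond_b)]
    all_rows = np.vstack(mats)
    n_a = mats[0].shape[0]
    rng = np.random.default_rng(seed)
    samples = np.empty(B)
    n = all_rows.shape[1]
    for b in range(B):
        perm = rng.permutation(all_rows.shape[0])
        pa = all_rows[perm[:n_a]]
        pb = all_rows[perm[n_a:]]
        p = _positional_pvalues_one(pa, pb, radius, min_obs)
        neglogp = -np.log(p)
        neglogp[np.isnan(neglogp)] = 0.0  # untestable contributes no signal
        samples[b] = _max_scan_statistic(neglogp[None, :], L_min, min(L_max, n))[0]
    return NullDistribution(n=n, L_min=L_min, L_max=min(L_max, n),
                            samples=samples, seed=seed, alpha=alpha)


def scan_dataset(
    dataset: ReactivityDataset,
    radius: int = DEFAULT_RADIUS,
    L_min: int = DEFAULT_L_MIN,
    L_max: int = DEFAULT_L_MAX,
    alpha: float = DEFAULT_ALPHA,
    B: int = DEFAULT_B,
    seed: int = 0,
    global_fwer: bool = False,
    null_mode: str = "windowed",
    null_cache: NullCache | None = None,
    min_obs: int = MIN_OBS,
) -> dict[str, ScanResult]:
    """Run the full scan on a normalized two-condition dataset.

    Family-wise error is controlled per transcript by default; with
    ``global_fwer`` the nominal level is Bonferroni-divided by the number of
    transcripts. ``null_mode`` is ``"windowed"`` (default: i.i.d. replicate
    values, windowed p-values recomputed — preserves the window-overlap
    dependence), ``"uniform"`` (positional p drawn i.i.d. Uniform(0,1)) or
    ``"permutation"`` (replicate-label shuffling).
    """
    if null_mode not in ("windowed", "uniform", "permutation"):
        raise ValidationError(f"unknown null_mode {null_mode!r}")
    cond_a, cond_b = dataset.condition_pair()
    pvals = positional_pvalues(dataset, radius=radius, min_obs=min_obs)
    eff_alpha = alpha / len(pvals) if (global_fwer and pvals) else alpha
    if null_cache is None and null_mode != "permutation":
        null_cache = NullCache(L_min, L_max, B, seed, alpha=eff_alpha,
                               mode=null_mode, radius=radius, min_obs=min_obs)
    results: dict[str, ScanResult] = {}
    for i, (tx, pv) in enumerate(pvals.items()):
        regions = enumerate_candidate_regions(pv, L_min, L_max)
        if null_mode != "permutation":
            null = null_cache.get(
                pv.length,
                n_a=len(dataset.profiles(tx, cond_a)),
                n_b=len(dataset.profiles(tx, cond_b)),
            )
        else:
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(7919, i))
            null = _permutation_null(
                dataset, tx, radius, L_min, L_max, B,
                int(ss.generate_state(1)[0] % (2**31)), eff_alpha, min_obs,
            )
        results[tx] = call_svrs(regions, null, alpha=eff_alpha, n=pv.length, pvals=pv)
        logger.info("%s: %d candidate regions, %d SVRs called",
                    tx, len(regions), len(results[tx].svrs))
    return results


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------


def write_svr_table(results: Mapping[str, ScanResult], path: str | Path) -> None:
    """Called SVRs as TSV: transcript_id, start, end, q, p_value.

    Coordinates are 1-based inclusive (unlike 0-based half-open BED).
    """
    lines = ["transcript_id\tstart\tend\tq\tp_value"]
    for tx, res in results.items():
        for r, p in zip(res.svrs, res.svr_pvalues):
            lines.append(f"{tx}\t{r.start}\t{r.end}\t{r.q:.6g}\t{p:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_position_table(results: Mapping[str, ScanResult], path: str | Path) -> None:
    """Per-position TSV: transcript_id, position, p_value, rank."""
    lines = ["transcript_id\tposition\tp_value\trank"]
    for tx, res in results.items():
        order = rank_nucleotides(res)
        rank = np.empty(res.n, dtype=np.int64)
        rank[order - 1] = np.arange(1, res.n + 1)
        p = res.pvals.p if res.pvals is not None else np.full(res.n, np.nan)
        for j in range(res.n):
            pj = "NA" if np.isnan(p[j]) else f"{p[j]:.6g}"
            lines.append(f"{tx}\t{j + 1}\t{pj}\t{rank[j]}")
    Path(path).write_text("\n".join(lines) + "\n")
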