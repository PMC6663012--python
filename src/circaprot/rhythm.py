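"""Circadian rhythm detection: one-way ANOVA prefilter + JTK_CYCLE.

The rhythm caller mirrors the two-stage funnel used for circadian 'omics
time courses: proteins whose abundance differs by time-of-day at all (one-way
fixed-effects ANOVA over zeitgeber-time bins, p < 0.1) are then tested for a
24-h rhythm with JTK_CYCLE, a nonparametric test that compares the data ranks
against phased cosine reference orderings through a Kendall-type statistic.

JTK_CYCLE mechanics implemented here:

* the reference at lag ``L`` is ``cos(2*pi*(t - L)/period)`` evaluated at the
  sample times, converted to dense ranks; replicates collected at the same
  time share a reference rank (a tie group);
* the statistic ``S`` is the number of concordant minus discordant data pairs
  over pairs with distinct reference ranks (pairs tied in the data count 0);
* the null distribution of ``S`` under a random permutation of the data is
  exact: ``S = 2*J - max(S)`` where ``J`` is a Jonckheere-Terpstra sum of
  independent Mann-Whitney counts between successive reference tie groups, so
  its pmf is a convolution of Mann-Whitney pmfs (Gaussian-binomial
  polynomials).  Beyond a configurable size a normal approximation with
  continuity correction is used;
* the reported p-value is the minimum two-sided exact tail over the lag grid,
  Bonferroni-multiplied by the number of distinct reference orderings (counted
  up to reversal, since a two-sided tail cannot distinguish a reference from
  its mirror), capped at 1;
* the phase estimate is the lag of the best (most concordant) reference, so it
  lives on the lag grid (default 2-h steps over a 24-h period).

Because the test only uses ranks, its p-value is invariant under strictly
monotone transforms of the abundances (such as ArcSinH).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# one-way ANOVA over ZT bins (vectorized, detection-masked)
# ---------------------------------------------------------------------------

def anova_by_zt(values: pd.DataFrame, detected: pd.DataFrame, zt: pd.Series,
                min_reps_per_bin: int = 2) -> pd.DataFrame:
    """Per-protein one-way fixed-effects ANOVA with the ZT bin as the factor.

    Only detected measurements enter the test.  A protein is eligible when
    every ZT bin holds at least ``min_reps_per_bin`` detected replicates.
    Returns a frame with ``anova_p`` (NaN for ineligible or degenerate
    proteins) and an ``anova_reason`` column naming exclusions.
    """
    X = values.to_numpy(dtype=float).copy()
    mask = detected.to_numpy(dtype=bool)
    X[~mask] = np.nan
    bins = np.sort(zt.unique())
    groups = [np.flatnonzero(zt.to_numpy() == b) for b in bins]

    n_g = np.stack([mask[:, g].sum(axis=1) for g in groups], axis=1)
    eligible = (n_g >= min_reps_per_bin).all(axis=1)

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins yield NaN means
        mean_g = np.stack([np.nanmean(X[:, g], axis=1) for g in groups], axis=1)
    n_tot = n_g.sum(axis=1)
    grand = np.nansum(np.where(mask, X, 0.0), axis=1) / np.maximum(n_tot, 1)
    ssb = (n_g * (mean_g - grand[:, None]) ** 2).sum(axis=1)
    ssw = np.zeros(len(X))
    for g, m in zip(groups, mean_g.T):
        d = X[:, g] - m[:, None]
        ssw += np.nansum(d * d, axis=1)

    dfb = len(bins) - 1
    dfw = n_tot - len(bins)
    p = np.full(len(X), np.nan)
    reason = np.where(eligible, "", "not detected in >= %d replicates per bin" % min_reps_per_bin)
    tol = 1e-12 * np.maximum(ssb + ssw, 1.0)
    degenerate = eligible & (ssw <= tol) & (ssb <= tol)
    exact = eligible & (ssw <= tol) & (ssb > tol)
    regular = eligible & (ssw > tol)
    reason = np.where(degenerate, "degenerate: zero variance in all groups", reason)
    p[exact] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb[regular] / dfb) / (ssw[regular] / dfw[regular])
    p[regular] = stats.f.sf(F, dfb, dfw[regular])
    n_deg = int(degenerate.sum())
    if n_deg:
        log.info("ANOVA: %d proteins excluded as degenerate (zero variance)", n_deg)
    return pd.DataFrame({"anova_p": p, "anova_reason": reason}, index=values.index)


def anova_prefilter(values: pd.DataFrame, detected: pd.DataFrame, zt: pd.Series,
                    alpha: float = 0.1, min_reps_per_bin: int = 2) -> pd.DataFrame:
    """Proteins with at least one time-of-day different from the others
    (one-way ANOVA p < ``alpha``)."""
    res = anova_by_zt(values, detected, zt, min_reps_per_bin=min_reps_per_bin)
    return res[res["anova_p"] < alpha]


# ---------------------------------------------------------------------------
# JTK_CYCLE
# ---------------------------------------------------------------------------

def _dense_ranks(ref: np.ndarray) -> np.ndarray:
    return stats.rankdata(np.round(ref, 9), method="dense").astype(int)


def jtk_reference(timepoints, lag: float, period: float = 24.0) -> np.ndarray:
    """Reference ordering for one lag: cosine values at the sample times,
    as dense ranks (replicates at one timepoint share a rank)."""
    t = np.asarray(timepoints, dtype=float)
    ref = np.cos(2 * np.pi * (t - lag) / period)
    return _dense_ranks(ref)


def jtk_statistic(series, reference_ranks) -> int:
    """Kendall-type score: concordant minus discordant pairs over pairs with
    distinct reference ranks; data ties contribute zero."""
    x = np.asarray(series, dtype=float)
    r = np.asarray(reference_ranks)
    if x.shape != r.shape:
        raise ValueError("series and reference must have the same length")
    dx = np.sign(x[:, None] - x[None, :])
    dr = np.sign(r[:, None] - r[None, :])
    return int(round((dx * dr).sum() / 2))


@dataclass
class JtkNull:
    """Exact (or approximate) null distribution of the JTK score S for one
    reference tie structure."""

    n: int
    tie_sizes: tuple[int, ...]
    s_values: np.ndarray | None  # grid of attainable S under the null
    pmf: np.ndarray | None
    s_max: int
    sd: float
    exact: bool

    def sf_abs(self, s_obs: float) -> float:
        """Two-sided exact tail P(|S*| >= |s_obs|)."""
        s_abs = abs(float(s_obs))
        if self.s_max == 0:
            return 1.0
        if self.exact:
            return float(self.pmf[np.abs(self.s_values) >= s_abs - 1e-9].sum())
        if s_abs <= 0:
            return 1.0
        z = (s_abs - 1.0) / self.sd  # continuity correction (S steps by 2)
        return min(1.0, 2.0 * stats.norm.sf(z))


def _mwu_counts(m: int, n: int) -> np.ndarray:
    """Number of arrangements for each value of the Mann-Whitney count U(m, n),
    via the Gaussian-binomial polynomial product_{j=1..n} (1-z^(m+j))/(1-z^j)."""
    p = np.array([1.0])
    for j in range(1, n + 1):
        deg = len(p) - 1 + (m + j)
        q = np.zeros(deg + 1)
        q[: len(p)] += p
        q[m + j: m + j + len(p)] -= p
        for k in range(j, len(q)):
            q[k] += q[k - j]
        p = q[: (len(p) - 1) + m + 1]
    return p


def jtk_null(tie_sizes, exact_limit: int = 60) -> JtkNull:
    """Null pmf of S for a reference with tie-group sizes ``tie_sizes``.

    Exact by dynamic-programming convolution for series up to
    ``exact_limit`` observations; a tie-matched normal approximation with
    continuity correction beyond that.
    """
    sizes = tuple(int(s) for s in tie_sizes)
    if any(s < 1 for s in sizes):
        raise ValueError("tie sizes must be positive")
    n = sum(sizes)
    s_max = (n * n - sum(s * s for s in sizes)) // 2
    var = (n * n * (2 * n + 3) - sum(s * s * (2 * s + 3) for s in sizes)) / 72.0
    sd = 2.0 * np.sqrt(var) if var > 0 else 0.0  # S = 2J - s_max
    if n > exact_limit:
        return JtkNull(n, sizes, None, None, s_max, sd, exact=False)
    pmf = np.array([1.0])
    m = sizes[0]
    for sz in sizes[1:]:
        pmf = np.convolve(pmf, _mwu_counts(m, sz))
        m += sz
    pmf = pmf / pmf.sum()
    s_values = 2 * np.arange(s_max + 1) - s_max
    return JtkNull(n, sizes, s_values, pmf, s_max, sd, exact=True)


def _lag_tables(timepoints, period: float, lag_step: float):
    """Per-lag reference ranks, tie structures, and the Bonferroni factor
    (distinct orderings up to reversal)."""
    lags = np.arange(0.0, period, lag_step)
    refs, ties = [], []
    keys = set()
    for lag in lags:
        r = jtk_reference(timepoints, lag, period)
        refs.append(r)
        _, counts = np.unique(r, return_counts=True)
        ties.append(tuple(sorted(counts)))
        rev = tuple(int(r.max()) + 1 - r)
        keys.add(min(tuple(int(v) for v in r), rev))
    return lags, refs, ties, len(keys)


@dataclass
class JtkResult:
    jtk_p: float
    phase_zt: float  # NaN when undefined (flat series)
    tau: float
    s: int
    n_effective_tests: int


def jtk_cycle(series, timepoints, period: float = 24.0, lag_step: float = 2.0,
              exact_limit: int = 60, _null_cache: dict | None = None) -> JtkResult:
    """JTK_CYCLE for one series; NaN measurements are dropped first."""
    x = np.asarray(series, dtype=float)
    t = np.asarray(timepoints, dtype=float)
    keep = np.isfinite(x)
    x, t = x[keep], t[keep]
    if x.size < 3 or np.all(x == x[0]):
        return JtkResult(1.0, float("nan"), 0.0, 0, 0)
    res = jtk_cycle_matrix(x[None, :], t, period=period, lag_step=lag_step,
                           exact_limit=exact_limit, _null_cache=_null_cache)
    row = res.iloc[0]
    return JtkResult(float(row["jtk_p"]), float(row["phase_zt"]), float(row["tau"]),
                     int(row["s"]), int(row["n_effective_tests"]))


def jtk_cycle_matrix(X, timepoints, period: float = 24.0, lag_step: float = 2.0,
                     exact_limit: int = 60, index=None,
                     _null_cache: dict | None = None) -> pd.DataFrame:
    """Vectorized JTK_CYCLE over a (proteins x samples) matrix of complete
    series (no NaNs; route incomplete series through :func:`jtk_cycle`)."""
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("jtk_cycle_matrix requires complete series")
    P, N = X.shape
    lags, refs, ties, n_eff = _lag_tables(timepoints, period, lag_step)
    cache = _null_cache if _null_cache is not None else {}

    D = np.sign(X[:, :, None] - X[:, None, :])  # (P, N, N)
    best_p = np.full(P, np.inf)
    best_s = np.full(P, -np.inf)
    best_lag = np.full(P, np.nan)
    best_smax = np.ones(P)
    for lag, r, tie in zip(lags, refs, ties):
        key = (tie, exact_limit)
        if key not in cache:
            cache[key] = jtk_null(tie, exact_limit=exact_limit)
        null = cache[key]
        R = np.sign(r[:, None] - r[None, :])
        S = np.einsum("pij,ij->p", D, R) / 2.0
        S = np.round(S)
        if null.exact:
            # P(|S*| >= |s|): tail over the symmetric pmf
            tail = np.concatenate([np.cumsum(null.pmf[::-1])[::-1], [0.0]])
            idx = np.searchsorted(null.s_values, np.abs(S) - 1e-9, side="left")
            upper = tail[idx]
            p = np.where(np.abs(S) < 1e-9, 1.0, np.minimum(1.0, 2.0 * upper - 0))
            # symmetric pmf: P(|S*|>=s) = 2*P(S*>=s) for s>0
        else:
            p = np.array([null.sf_abs(s) for s in S])
        better = (p < best_p) | ((p == best_p) & (S > best_s))
        best_p = np.where(better, p, best_p)
        best_s = np.where(better, S, best_s)
        best_lag = np.where(better, lag, best_lag)
        best_smax = np.where(better, max(null.s_max, 1), best_smax)

    jtk_p = np.minimum(1.0, best_p * n_eff)
    tau = best_s / best_smax
    phase = np.where(best_s > 0, best_lag, np.nan)
    out = pd.DataFrame({
        "jtk_p": jtk_p,
        "phase_zt": phase,
        "tau": tau,
        "s": best_s.astype(int),
        "n_effective_tests": n_eff,
    }, index=index if index is not None else pd.RangeIndex(P))
    return out


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def call_rhythmic(results: pd.DataFrame, alpha_jtk: float = 0.1) -> pd.DataFrame:
    """Flag rhythmic proteins (jtk_p < alpha) and attach Benjamini-Hochberg
    q-values computed across the tested set."""
    out = results.copy()
    if out.empty:
        out["q_value"] = pd.Series(dtype=float)
        out["rhythmic"] = pd.Series(dtype=bool)
        return out
    _, q, _, _ = multipletests(out["jtk_p"].to_numpy(), method="fdr_bh")
    out["q_value"] = q
    out["rhythmic"] = out["jtk_p"] < alpha_jtk
    return out


def rhythm_analysis(matrix, alpha_anova: float = 0.1, alpha_jtk: float = 0.1,
                    period: float = 24.0, lag_step: float = 2.0,
                    min_reps_per_bin: int = 2,
                    min_peptides_per_sample: int | None = 2) -> tuple[pd.DataFrame, dict]:
    """Full rhythm funnel on a :class:`~circaprot.quantify.ProteinAbundanceMatrix`.

    Stages: restrict to proteins detected at every ZT bin (and, when
    ``min_peptides_per_sample`` is set, quantified from more than one peptide
    in each detected sample) -> ANOVA prefilter -> JTK_CYCLE -> BH q-values.
    Returns the per-protein result table and the funnel counts.
    """
    zt = matrix.sample_meta["zt"]
    values, detected = matrix.values, matrix.detected
    eligible_mask = pd.Series(True, index=values.index)
    if min_peptides_per_sample is not None:
        pc = matrix.peptide_counts
        ok = (~detected | (pc >= min_peptides_per_sample)).all(axis=1)
        eligible_mask &= ok
    anova = anova_by_zt(values[eligible_mask], detected[eligible_mask], zt,
                        min_reps_per_bin=min_reps_per_bin)
    tested = anova[anova["anova_p"].notna()]
    passing = tested[tested["anova_p"] < alpha_anova]

    cache: dict = {}
    rows = []
    t_all = zt.to_numpy(dtype=float)
    for pid in passing.index:
        det = detected.loc[pid].to_numpy(dtype=bool)
        x = values.loc[pid].to_numpy(dtype=float)[det]
        r = jtk_cycle(x, t_all[det], period=period, lag_step=lag_step, _null_cache=cache)
        rows.append({"protein_id": pid, "anova_p": passing.loc[pid, "anova_p"],
                     "jtk_p": r.jtk_p, "phase_zt": r.phase_zt, "tau": r.tau,
                     "period": period})
    res = pd.DataFrame(rows).set_index("protein_id") if rows else pd.DataFrame(
        columns=["anova_p", "jtk_p", "phase_zt", "tau", "period"])
    res = call_rhythmic(res, alpha_jtk=alpha_jtk)
    funnel = {
        "n_quantifiable": int(len(values)),
        "n_eligible": int(tested.shape[0]),
        "n_anova_pass": int(passing.shape[0]),
        "n_rhythmic": int(res["rhythmic"].sum()) if "rhythmic" in res else 0,
    }
    log.info("rhythm funnel: %(n_quantifiable)d quantifiable -> %(n_eligible)d eligible "
             "-> %(n_anova_pass)d ANOVA pass -> %(n_rhythmic)d rhythmic", funnel)
    return res, funnel
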