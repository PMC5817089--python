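"""Two-state hidden-Markov multiple testing over genome-ordered z-scores.

Array probes are correlated with their genomic neighbours, so per-probe
p-values are not exchangeable and rank-based FDR rules waste the local
information.  Here the sequence of z-scores along each chromosome is
modelled as a homogeneous two-state HMM (null / non-null) with an empirical
Gaussian null (mean and SD estimated by weighted maximum likelihood) and a
nonparametric kernel alternative.  EM alternates forward-backward
posteriors with closed-form M-steps; the local index of significance (LIS)
of a probe is its posterior null probability given the whole chain, and the
adjusted LIS (aLIS) is the running mean of rank-ordered LIS values — the
step-up quantity whose thresholding controls the marginal FDR over
dependent tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats
from sklearn.base import BaseEstimator

_DENS_FLOOR = 1e-300


@njit(cache=False)
def _forward_backward(f0, f1, A, pi, seg_starts):
    """Scaled forward-backward over concatenated chain segments.

    Returns (posterior null probabilities, expected transition counts,
    log-likelihood).  Each segment restarts from the initial distribution
    ``pi``.
    """
    n = f0.shape[0]
    gamma0 = np.empty(n)
    trans = np.zeros((2, 2))
    loglik = 0.0
    alpha = np.empty((n, 2))
    beta = np.empty((n, 2))
    c = np.empty(n)
    for s in range(seg_starts.shape[0] - 1):
        a, b = seg_starts[s], seg_starts[s + 1]
        a0 = pi[0] * f0[a]
        a1 = pi[1] * f1[a]
        c[a] = a0 + a1
        alpha[a, 0] = a0 / c[a]
        alpha[a, 1] = a1 / c[a]
        for t in range(a + 1, b):
            v0 = (alpha[t - 1, 0] * A[0, 0] + alpha[t - 1, 1] * A[1, 0]) * f0[t]
            v1 = (alpha[t - 1, 0] * A[0, 1] + alpha[t - 1, 1] * A[1, 1]) * f1[t]
            ct = v0 + v1
            alpha[t, 0] = v0 / ct
            alpha[t, 1] = v1 / ct
            c[t] = ct
        beta[b - 1, 0] = 1.0
        beta[b - 1, 1] = 1.0
        for t in range(b - 2, a - 1, -1):
            b0 = A[0, 0] * f0[t + 1] * beta[t + 1, 0] + A[0, 1] * f1[t + 1] * beta[t + 1, 1]
            b1 = A[1, 0] * f0[t + 1] * beta[t + 1, 0] + A[1, 1] * f1[t + 1] * beta[t + 1, 1]
            beta[t, 0] = b0 / c[t + 1]
            beta[t, 1] = b1 / c[t + 1]
        for t in range(a, b):
            g0 = alpha[t, 0] * beta[t, 0]
            g1 = alpha[t, 1] * beta[t, 1]
            gamma0[t] = g0 / (g0 + g1)
            loglik += np.log(c[t])
        for t in range(a, b - 1):
            trans[0, 0] += alpha[t, 0] * A[0, 0] * f0[t + 1] * beta[t + 1, 0] / c[t + 1]
            trans[0, 1] += alpha[t, 0] * A[0, 1] * f1[t + 1] * beta[t + 1, 1] / c[t + 1]
            trans[1, 0] += alpha[t, 1] * A[1, 0] * f0[t + 1] * beta[t + 1, 0] / c[t + 1]
            trans[1, 1] += alpha[t, 1] * A[1, 1] * f1[t + 1] * beta[t + 1, 1] / c[t + 1]
    return gamma0, trans, loglik


def _stationary(A: np.ndarray) -> np.ndarray:
    p1 = A[0, 1] / (A[0, 1] + A[1, 0])
    return np.array([1.0 - p1, p1])


def _weighted_quantile(z_sorted, w_sorted, q):
    cw = np.cumsum(w_sorted)
    return float(np.interp(q * cw[-1], cw, z_sorted))


def _silverman_bandwidth(z: np.ndarray, w: np.ndarray) -> float:
    """Silverman's rule on posterior-weighted data (effective sample size)."""
    W = w.sum()
    if W <= 1e-8:
        return 1.0
    mu = (w * z).sum() / W
    sd = np.sqrt(np.maximum((w * (z - mu) ** 2).sum() / W, 1e-12))
    order = np.argsort(z, kind="stable")
    iqr = _weighted_quantile(z[order], w[order], 0.75) - _weighted_quantile(
        z[order], w[order], 0.25
    )
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    neff = W**2 / np.maximum((w**2).sum(), 1e-300)
    return max(0.9 * spread * neff ** (-0.2), 1e-3)


def _weighted_kde(z: np.ndarray, w: np.ndarray, grid: np.ndarray, bw: float) -> np.ndarray:
    """Binned Gaussian KDE of weighted data evaluated on the grid."""
    W = w.sum()
    if W <= 1e-8:
        # no alternative mass yet: fall back to a wide reference density
        return stats.norm.pdf(grid, 0.0, 3.0)
    nbins = 2048
    hist, edges = np.histogram(z, bins=nbins, range=(grid[0], grid[-1]), weights=w)
    centers = 0.5 * (edges[:-1] + edges[1:])
    used = hist > 0
    d = (grid[:, None] - centers[None, used]) / bw
    dens = (np.exp(-0.5 * d * d) * hist[used][None, :]).sum(axis=1)
    dens /= W * bw * np.sqrt(2.0 * np.pi)
    # renormalise on the grid so the density integrates to 1 there
    area = np.trapezoid(dens, grid)
    if area > 0:
        dens = dens / area
    return dens


def _segment_starts(chrom, n: int, restart: bool) -> np.ndarray:
    if chrom is None or not restart:
        return np.array([0, n], dtype=np.int64)
    chrom = np.asarray(chrom)
    breaks = np.flatnonzero(chrom[1:] != chrom[:-1]) + 1
    return np.concatenate(([0], breaks, [n])).astype(np.int64)


class HmmLisFdr(BaseEstimator):
    """HMM-based local-index-of-significance FDR procedure.

    Parameters
    ----------
    alpha : float
        aLIS significance cutoff (calls are aLIS < alpha).
    max_iter : int
        EM iteration cap.
    epsilon : float
        EM stops when the log-likelihood improves by less than this.
    kernel_bandwidth : "silverman" or float
        Bandwidth for the kernel alternative density.
    restart_per_chromosome : bool
        Restart the chain at the stationary distribution at each
        chromosome boundary.
    grid_size : int
        Evaluation grid for the alternative density.
    zero_window : float
        The semiparametric null/alternative split is not identifiable where
        the null dominates: the EM can park spurious alternative mass under
        the null peak, which makes the LIS anti-conservative.  The standard
        zero assumption pins the alternative density to zero within
        ``zero_window`` null SDs of the null mean (0 disables).

    Attributes
    ----------
    transition_ : (2, 2) ndarray — fitted transition matrix (null, non-null).
    pi0_start_ : float — stationary null probability.
    null_mean_, null_sd_ : float — empirical null parameters.
    alt_grid_, alt_density_ : ndarray — kernel alternative on its grid.
    log_likelihood_trace_ : list of float.
    converged_ : bool.
    lis_ : ndarray — posterior null probability per observation.
    alis_ : ndarray — running-mean-adjusted LIS per observation.
    significant_ : ndarray of bool — aLIS < alpha calls.
    """

    def __init__(
        self,
        alpha: float = 0.01,
        max_iter: int = 100,
        epsilon: float = 1e-2,
        kernel_bandwidth="silverman",
        restart_per_chromosome: bool = True,
        grid_size: int = 512,
        zero_window: float = 1.0,
    ):
        self.alpha = alpha
        self.max_iter = max_iter
        self.epsilon = epsilon
        self.kernel_bandwidth = kernel_bandwidth
        self.restart_per_chromosome = restart_per_chromosome
        self.grid_size = grid_size
        self.zero_window = zero_window

    # ------------------------------------------------------------------
    def fit(self, z, chrom=None):
        z = np.asarray(z, dtype=float)
        if z.ndim != 1:
            raise ValueError("z must be one-dimensional")
        if len(z) < 100:
            raise ValueError("need at least 100 observations to fit the HMM")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.max_iter < 1 or self.epsilon <= 0:
            raise ValueError("max_iter must be >= 1 and epsilon > 0")
        segs = _segment_starts(chrom, len(z), self.restart_per_chromosome)

        grid = np.linspace(z.min() - 4.0, z.max() + 4.0, self.grid_size)
        # deterministic initialisation: standard-normal null, sticky chain,
        # symmetric two-bump alternative
        mu0, sd0 = 0.0, 1.0
        A = np.array([[0.95, 0.05], [0.05, 0.95]])
        f1z = 0.5 * stats.norm.pdf(z, -3.0, 1.0) + 0.5 * stats.norm.pdf(z, 3.0, 1.0)
        alt_dens = 0.5 * stats.norm.pdf(grid, -3.0, 1.0) + 0.5 * stats.norm.pdf(
            grid, 3.0, 1.0
        )

        trace: list[float] = []
        converged = False
        gamma0 = np.full(len(z), 0.95)
        for _ in range(self.max_iter):
            f0z = np.maximum(stats.norm.pdf(z, mu0, sd0), _DENS_FLOOR)
            f1z = np.maximum(f1z, _DENS_FLOOR)
            pi = _stationary(A)
            gamma0, trans, ll = _forward_backward(f0z, f1z, A, pi, segs)
            if trace and abs(ll - trace[-1]) < self.epsilon:
                trace.append(ll)
                converged = True
                break
            trace.append(ll)

            # M-step
            rows = trans.sum(axis=1)
            if np.all(rows > 0):
                A = trans / rows[:, None]
                A = np.clip(A, 1e-8, 1 - 1e-8)
                A = A / A.sum(axis=1, keepdims=True)
            w0 = gamma0
            W0 = w0.sum()
            if W0 <= 0:
                raise ValueError("degenerate fit: no null mass; inspect the input z")
            mu0 = (w0 * z).sum() / W0
            sd0 = np.sqrt((w0 * (z - mu0) ** 2).sum() / W0)
            if sd0 < 1e-3:
                raise ValueError(
                    "degenerate fit: null SD collapsed toward 0; inspect the input z"
                )
            w1 = 1.0 - gamma0
            if self.kernel_bandwidth == "silverman":
                bw = _silverman_bandwidth(z, w1)
            else:
                bw = float(self.kernel_bandwidth)
            alt_dens = _weighted_kde(z, w1, grid, bw)
            if self.zero_window > 0:
                core = np.abs(grid - mu0) < self.zero_window * sd0
                trimmed = np.where(core, 0.0, alt_dens)
                area = np.trapezoid(trimmed, grid)
                if area > 1e-12:
                    alt_dens = trimmed / area
            f1z = np.interp(z, grid, alt_dens)

        # final posteriors under the last parameter set
        f0z = np.maximum(stats.norm.pdf(z, mu0, sd0), _DENS_FLOOR)
        f1z = np.maximum(f1z, _DENS_FLOOR)
        pi = _stationary(A)
        gamma0, _, _ = _forward_backward(f0z, f1z, A, pi, segs)

        self.transition_ = A
        self.pi0_start_ = float(pi[0])
        self.null_mean_ = float(mu0)
        self.null_sd_ = float(sd0)
        self.alt_grid_ = grid
        self.alt_density_ = alt_dens
        self.log_likelihood_trace_ = trace
        self.converged_ = converged
        self.n_iter_ = len(trace)
        self.lis_ = gamma0
        self.alis_, self.significant_ = alis_threshold(gamma0, self.alpha)
        return self

    def fit_predict(self, z, chrom=None):
        self.fit(z, chrom)
        return self.significant_

    def posterior_null(self, z, chrom=None) -> np.ndarray:
        """LIS for new data under the fitted parameters."""
        z = np.asarray(z, dtype=float)
        segs = _segment_starts(chrom, len(z), self.restart_per_chromosome)
        f0z = np.maximum(stats.norm.pdf(z, self.null_mean_, self.null_sd_), _DENS_FLOOR)
        f1z = np.maximum(np.interp(z, self.alt_grid_, self.alt_density_), _DENS_FLOOR)
        pi = np.array([self.pi0_start_, 1.0 - self.pi0_start_])
        gamma0, _, _ = _forward_backward(f0z, f1z, self.transition_, pi, segs)
        return gamma0


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def order_and_clean(stats_df: pd.DataFrame) -> pd.DataFrame:
    """Sort per-probe stats by (chrom, pos) and drop unusable p-values.

    Entries whose p is missing or exactly 0 or 1 are removed; z is
    recomputed from p and the sign of delta_beta when absent.
    """
    df = stats_df.copy()
    required = {"chrom", "pos", "p_raw"}
    if not required.issubset(df.columns):
        raise ValueError(f"stats need columns {sorted(required)}")
    key = df.reset_index()[[df.index.name or "index", "chrom", "pos"]]
    if key.duplicated().any():
        raise ValueError("duplicate (probe, chrom, pos) entries")
    df = df.sort_values(["chrom", "pos"], kind="stable")
    p = df["p_raw"]
    df = df[p.notna() & (p > 0) & (p < 1)]
    if "z" not in df.columns or df["z"].isna().any():
        sign = np.where(df.get("delta_beta", pd.Series(1.0, index=df.index)) < 0, -1.0, 1.0)
        df = df.assign(z=sign * stats.norm.isf(df["p_raw"] / 2.0))
    return df


def fit_hmm(z, chrom=None, **config) -> HmmLisFdr:
    """Fit the two-state HMM; returns the fitted estimator."""
    return HmmLisFdr(**config).fit(z, chrom)


def compute_lis(fit: HmmLisFdr, z, chrom=None) -> np.ndarray:
    """Posterior null probability of each observation under a fitted HMM."""
    return fit.posterior_null(z, chrom)


def alis_threshold(lis, alpha: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Running-mean step-up rule on sorted LIS values.

    Sorting LIS ascending, ``aLIS_(k)`` is the mean of the k smallest LIS
    values; an observation is significant iff its aLIS < alpha.  Returns
    (alis, significant) in the original order.
    """
    lis = np.asarray(lis, dtype=float)
    if np.any((lis < 0) | (lis > 1)):
        raise ValueError("lis values must lie in [0, 1]")
    order = np.argsort(lis, kind="stable")
    running = np.cumsum(lis[order]) / np.arange(1, len(lis) + 1)
    alis = np.empty_like(lis)
    alis[order] = running
    return alis, alis < alpha
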