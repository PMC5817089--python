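"""Per-probe species-differential testing with latent-factor confounder
adjustment and genomic-inflation diagnostics.

The estimator fits, for every probe, the linear model

    beta ~ species + beadchip + F_1 + ... + F_k

where the F_j are latent-factor scores recovered by truncated SVD of the
nuisance-only (intercept + beadchip) residual matrix.  Keeping species in
that residual lets a factor carry the species-correlated component of a
confounder — the part that actually biases the species test; projecting
species out first would discard exactly that part and leave the inflation
untouched.  So that genuine sparse species effects cannot masquerade as a
factor, the probes with the largest unadjusted species |t| are trimmed
before the SVD (a dense confounder survives the trim, concentrated signal
does not).  The factor count is fixed or chosen by Horn's parallel
analysis on the full-design residuals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

_CHI2_1_MEDIAN = 0.4549364231195724  # median of chi-square with 1 df


def _design_matrix(sheet: pd.DataFrame, sample_order) -> tuple[np.ndarray, np.ndarray, int]:
    """Full design (intercept + species + beadchip dummies) and the nuisance
    part (intercept + chips only).

    Returns (X_full, X_nuisance, species_column_index).  Raises if a
    beadchip structure makes the species contrast unidentifiable.
    """
    sheet = sheet.set_index("sample_id").loc[list(sample_order)]
    species = (sheet["species"] == "human").to_numpy(dtype=float)
    chips = pd.get_dummies(sheet["beadchip"], drop_first=True, dtype=float)
    n = len(sheet)
    X_nuis = np.column_stack([np.ones(n)] + [chips[c].to_numpy() for c in chips.columns])
    rank_without = np.linalg.matrix_rank(X_nuis)
    rank_with = np.linalg.matrix_rank(np.column_stack([X_nuis, species]))
    if rank_with == rank_without:
        raise ValueError(
            "species is aliased with the beadchip layout: every chip carries a "
            "single species, so the species effect cannot be separated from batch"
        )
    X = np.column_stack([np.ones(n), species] + [chips[c].to_numpy() for c in chips.columns])
    return X, X_nuis, 1


def _residual_factors(
    Y: np.ndarray,
    X_full: np.ndarray,
    X_nuis: np.ndarray,
    k: int,
    s_idx: int,
    trim_frac: float = 0.05,
) -> np.ndarray:
    """Latent-factor scores (samples x k) for the confounder adjustment.

    Scores are the leading left singular vectors of the nuisance-only
    (intercept + beadchip) residual matrix: keeping species in the residual
    lets a factor carry the species-correlated component of a confounder —
    the part that actually biases the species test.  To stop genuine sparse
    species effects from defining a factor, the ``trim_frac`` probes with
    the largest unadjusted species |t| are excluded before the SVD; a dense
    confounder is unaffected by dropping a small fraction of probes,
    whereas concentrated true signal is removed almost entirely.
    """
    if k == 0:
        return np.zeros((Y.shape[0], 0))
    coef_n, *_ = np.linalg.lstsq(X_nuis, Y, rcond=None)
    R_nuis = Y - X_nuis @ coef_n
    if trim_frac > 0:
        coef_f, *_ = np.linalg.lstsq(X_full, Y, rcond=None)
        R_full = Y - X_full @ coef_f
        dof = Y.shape[0] - np.linalg.matrix_rank(X_full)
        sigma2 = (R_full**2).sum(axis=0) / max(dof, 1)
        gram_inv = np.linalg.pinv(X_full.T @ X_full)
        se = np.sqrt(np.maximum(sigma2 * gram_inv[s_idx, s_idx], 1e-300))
        t_abs = np.abs(coef_f[s_idx] / se)
        keep = t_abs <= np.quantile(t_abs, 1.0 - trim_frac)
        R_nuis = R_nuis[:, keep]
    U, _, _ = np.linalg.svd(R_nuis, full_matrices=False)
    return U[:, :k]


def estimate_factor_count(
    betas: pd.DataFrame,
    sheet: pd.DataFrame,
    max_k: int = 10,
    n_perm: int = 1000,
    seed: int = 0,
    quantile: float = 0.95,
) -> int:
    """Horn's parallel analysis on the design-residual matrix.

    Observed residual eigenvalues are compared rank-by-rank with the chosen
    quantile of eigenvalues from matrices whose columns (probes) are
    independently permuted across samples; k is the number of leading
    observed eigenvalues exceeding their null counterpart, stopping at the
    first failure.
    """
    X, _, _ = _design_matrix(sheet, betas.columns)
    n_samples = X.shape[0]
    d_rank = np.linalg.matrix_rank(X)
    if max_k >= n_samples - d_rank:
        raise ValueError(
            f"max_k={max_k} infeasible with {n_samples} samples and design rank {d_rank}"
        )
    Y = betas.dropna(axis=0, how="any").to_numpy().T  # samples x probes
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ coef

    def _std_rows(M):
        # correlation-scale spectra: leverage from the design projection
        # makes raw residual row variances unequal even under pure noise
        sd = M.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return M / sd

    Rs = _std_rows(R)
    obs = np.sort(np.linalg.eigvalsh(Rs @ Rs.T))[::-1][:max_k]

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, max_k))
    n, p = R.shape
    # permuted matrices are re-projected and re-standardised so observed and
    # null spectra share the design-induced rank deficiency and row scaling
    proj = np.eye(n) - X @ np.linalg.pinv(X)
    for b in range(n_perm):
        idx = rng.random((n, p)).argsort(axis=0)
        Rp = _std_rows(proj @ np.take_along_axis(Rs, idx, axis=0))
        null[b] = np.sort(np.linalg.eigvalsh(Rp @ Rp.T))[::-1][:max_k]
    thresh = np.quantile(null, quantile, axis=0)
    k = 0
    for i in range(max_k):
        if obs[i] > thresh[i]:
            k += 1
        else:
            break
    return k


def genomic_inflation(p_values) -> float:
    """Genomic inflation factor: median observed chi-square over its null
    median.  Calibrated tests give lambda close to 1."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if len(p) < 100:
        raise ValueError("need at least 100 p-values for a stable lambda")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p-values must lie strictly inside (0, 1)")
    chi2 = stats.norm.isf(p / 2.0) ** 2
    return float(np.median(chi2) / _CHI2_1_MEDIAN)


class ConfounderAdjustedTester(BaseEstimator):
    """Factor-augmented per-probe species test on a beta matrix.

    Parameters
    ----------
    k_factors : int or "auto"
        Latent-factor count; "auto" runs parallel analysis.
    max_k : int
        Upper bound for "auto".
    n_permutations : int
        Permutations for parallel analysis.
    use_m_values : bool
        Test on M-values ``log2(beta / (1 - beta))`` instead of raw betas.
    signal_trim : float
        Fraction of probes with the largest unadjusted species |t| excluded
        from factor-score estimation, so concentrated true effects cannot
        define a factor.
    random_state : int
        Seed for the parallel-analysis permutations.

    Attributes
    ----------
    k_factors_ : int
        Factor count actually used.
    factors_ : ndarray of shape (n_samples, k_factors_)
        Estimated factor scores.
    results_ : DataFrame indexed by probe
        Columns ``delta_beta`` (human mean - monkey mean), ``p_raw``, ``z``.
    lambda_ : float
        Genomic inflation factor of the fitted p-values.
    """

    def __init__(
        self,
        k_factors="auto",
        max_k: int = 5,
        n_permutations: int = 1000,
        use_m_values: bool = False,
        signal_trim: float = 0.05,
        random_state: int = 0,
    ):
        self.k_factors = k_factors
        self.max_k = max_k
        self.n_permutations = n_permutations
        self.use_m_values = use_m_values
        self.signal_trim = signal_trim
        self.random_state = random_state

    def fit(self, betas: pd.DataFrame, sheet: pd.DataFrame):
        for sp in ("human", "monkey"):
            if (sheet["species"] == sp).sum() < 2:
                raise ValueError(f"need at least 2 {sp} samples")
        X, X_nuis, s_idx = _design_matrix(sheet, betas.columns)
        Y_df = betas
        if self.use_m_values:
            clipped = betas.clip(1e-6, 1 - 1e-6)
            Y_df = np.log2(clipped / (1.0 - clipped))

        if self.k_factors == "auto":
            k = estimate_factor_count(
                Y_df,
                sheet,
                max_k=self.max_k,
                n_perm=self.n_permutations,
                seed=self.random_state,
            )
        else:
            k = int(self.k_factors)
        n_samples = X.shape[0]
        if k >= n_samples - np.linalg.matrix_rank(X):
            raise ValueError(f"k_factors={k} leaves no residual degrees of freedom")

        complete = Y_df.dropna(axis=0, how="any")
        U = _residual_factors(
            complete.to_numpy().T, X, X_nuis, k, s_idx, trim_frac=self.signal_trim
        )
        self.factors_ = U
        self.k_factors_ = k
        Xf = np.column_stack([X, U]) if k else X

        p_raw = pd.Series(np.nan, index=betas.index)
        # vectorised OLS over complete probes
        p_raw.loc[complete.index] = self._ols_pvalues(
            Xf, complete.to_numpy().T, s_idx
        )
        # per-probe refits where samples are missing
        incomplete = Y_df.index.difference(complete.index)
        for pid in incomplete:
            y = Y_df.loc[pid].to_numpy(dtype=float)
            ok = ~np.isnan(y)
            if ok.sum() <= Xf.shape[1]:
                continue
            p_raw.loc[pid] = float(
                self._ols_pvalues(Xf[ok], y[ok][:, None], s_idx)[0]
            )

        sheet_idx = sheet.set_index("sample_id").loc[list(betas.columns)]
        human = betas.loc[:, (sheet_idx["species"] == "human").to_numpy()]
        monkey = betas.loc[:, (sheet_idx["species"] == "monkey").to_numpy()]
        delta = human.mean(axis=1, skipna=True) - monkey.mean(axis=1, skipna=True)
        sign = np.where(delta.to_numpy() < 0, -1.0, 1.0)
        with np.errstate(divide="ignore"):
            z = sign * stats.norm.isf(p_raw.to_numpy() / 2.0)
        self.results_ = pd.DataFrame(
            {"delta_beta": delta, "p_raw": p_raw, "z": z}, index=betas.index
        )
        inside = p_raw[(p_raw > 0) & (p_raw < 1)].to_numpy()
        self.lambda_ = genomic_inflation(inside) if len(inside) >= 100 else np.nan
        return self

    @staticmethod
    def _ols_pvalues(X: np.ndarray, Y: np.ndarray, s_idx: int) -> np.ndarray:
        """Two-sided t-test p-values for the species coefficient, probe-wise."""
        XtX = X.T @ X
        XtX_inv = np.linalg.pinv(XtX)
        B = XtX_inv @ (X.T @ Y)
        resid = Y - X @ B
        dof = X.shape[0] - np.linalg.matrix_rank(X)
        if dof <= 0:
            raise ValueError("no residual degrees of freedom")
        sigma2 = (resid**2).sum(axis=0) / dof
        se = np.sqrt(np.maximum(sigma2 * XtX_inv[s_idx, s_idx], 1e-300))
        t = B[s_idx] / se
        return 2.0 * stats.t.sf(np.abs(t), dof)


def adjusted_test(
    betas: pd.DataFrame,
    sheet: pd.DataFrame,
    k_factors="auto",
    annotation: pd.DataFrame | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Functional wrapper around :class:`ConfounderAdjustedTester`.

    Returns the per-probe results frame, with ``chrom``/``pos`` joined in
    when an annotation is supplied.
    """
    est = ConfounderAdjustedTester(k_factors=k_factors, **kwargs).fit(betas, sheet)
    res = est.results_
    if annotation is not None:
        res = res.join(annotation[["chrom", "pos"]], how="left")
        res = res[["chrom", "pos", "delta_beta", "p_raw", "z"]]
    return res
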