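"""Expression units and negative-binomial differential expression.

This module provides the statistical core used everywhere downstream:

* :func:`compute_tpm` — transcripts-per-million from gene-level counts and
  canonical transcript lengths;
* :func:`tmm_factors` — trimmed-mean-of-M-values effective-library-size
  normalization (reference by 75th-percentile proximity, 30% two-sided trim
  on M, 5% on A, inverse asymptotic-binomial-variance weights);
* :func:`estimate_dispersion` — common and tagwise NB dispersion by
  Cox-Reid adjusted profile likelihood on a log grid, with empirical-Bayes
  shrinkage toward the common value (prior df 10);
* :func:`nb_lrt` — per-gene NB generalized linear model with log link and
  log-effective-library-size offset, likelihood-ratio tested against a
  reduced model, chi-square p-values and BH correction;
* :func:`bh_adjust` — Benjamini-Hochberg step-up, NA-preserving.

The GLM fits are vectorized across genes (batched IRLS with step halving),
so genome-scale contrasts run in seconds on one CPU.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .io import CountMatrix

LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# TPM


def compute_tpm(counts: pd.DataFrame | CountMatrix, lengths: pd.Series) -> pd.DataFrame:
    """TPM_gs = (count_gs / length_g) / sum_g'(count_g's / length_g') * 1e6.

    ``lengths`` must cover every gene with a positive transcript length.
    An all-zero sample yields an all-zero column with a warning.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = counts.index[lengths.isna()].tolist()
        raise ValueError(f"genes missing transcript length: {missing[:5]}")
    if (lengths <= 0).any():
        bad = counts.index[lengths <= 0][0]
        raise ValueError(f"non-positive transcript length for gene {bad!r}")
    rate = counts.to_numpy(dtype=float) / lengths.to_numpy()[:, None]
    denom = rate.sum(axis=0)
    zero = denom == 0
    if zero.any():
        warnings.warn(f"all-zero samples in TPM computation: "
                      f"{list(counts.columns[zero])}")
        denom = np.where(zero, 1.0, denom)
    return pd.DataFrame(rate / denom * 1e6, index=counts.index,
                        columns=counts.columns)


# ---------------------------------------------------------------------------
# TMM normalization


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              log_ratio_trim: float = 0.3, abs_expr_trim: float = 0.05) -> float:
    """TMM factor of one sample against the reference (log2 scale)."""
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return 0.0
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[finite], a[finite], w[finite]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = m.size
    lo_m, hi_m = np.floor(n * log_ratio_trim) + 1, n + 1 - (np.floor(n * log_ratio_trim) + 1)
    lo_a, hi_a = np.floor(n * abs_expr_trim) + 1, n + 1 - (np.floor(n * abs_expr_trim) + 1)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 0.0
    return float(np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2]))


def tmm_factors(counts: pd.DataFrame | CountMatrix,
                ref_sample: str | None = None) -> pd.Series:
    """Trimmed-mean-of-M-values factors, rescaled to geometric mean 1.

    The reference is the sample whose 75th-percentile count fraction is
    closest to the mean across samples (unless ``ref_sample`` is given).
    A sample sharing no positive genes with the reference gets factor 1
    with a warning.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    y = counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample must have positive library size")
    f75 = np.array([np.quantile(y[:, j][y[:, j] >= 0], 0.75) for j in range(y.shape[1])]) / lib
    if ref_sample is None:
        ref_j = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_j = list(counts.columns).index(ref_sample)
    log2f = np.zeros(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref_j:
            continue
        if not ((y[:, j] > 0) & (y[:, ref_j] > 0)).any():
            warnings.warn(f"sample {counts.columns[j]!r} shares no expressed genes "
                          f"with the reference; factor set to 1")
            log2f[j] = 0.0
        else:
            log2f[j] = _tmm_pair(y[:, j], y[:, ref_j], lib[j], lib[ref_j])
    factors = 2.0 ** log2f
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def effective_lib_sizes(counts: pd.DataFrame | CountMatrix,
                        factors: pd.Series | None = None) -> pd.Series:
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    if factors is None:
        factors = tmm_factors(counts)
    return counts.sum(axis=0).astype(float) * factors


# ---------------------------------------------------------------------------
# batched NB GLM


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row sums of the NB log likelihood; phi per gene (column vector)."""
    r = 1.0 / np.maximum(phi, 1e-10)
    mu = np.maximum(mu, 1e-10)
    ll = (gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
          + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu)))
    return ll.sum(axis=1)


def _fit_nb_glm(y: np.ndarray, X: np.ndarray, offset: np.ndarray,
                phi: np.ndarray, maxiter: int = 50, tol: float = 1e-10):
    """Batched IRLS fit of NB GLMs with log link.

    y (g, n); X (n, p); offset (n,) or (g, n); phi (g,).
    Returns (beta, mu, loglik, converged, xtwx).
    """
    g, n = y.shape
    p = X.shape[1]
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (g,)).copy()
    phi_col = phi[:, None]
    offset = np.broadcast_to(offset, (g, n))
    # initial values via weighted least squares on a stabilized log response
    mu0 = y + np.mean(y, axis=1, keepdims=True) * 0.1 + 0.5
    z0 = np.log(mu0) - offset
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T  # (g, p)

    def eta_of(b):
        return np.clip(b @ X.T, -30.0, 30.0)

    eta = eta_of(beta)
    mu = np.exp(eta + offset)
    ll = _nb_loglik(y, mu, phi_col)
    converged = np.zeros(g, dtype=bool)
    xtwx = None
    ridge = 1e-8 * np.eye(p)
    for _ in range(maxiter):
        w = mu / (1.0 + phi_col * mu)
        w = np.maximum(w, 1e-12)
        z = eta + (y - mu) / np.maximum(mu, 1e-12)
        xtwx = np.einsum("gn,ni,nj->gij", w, X, X)
        xtwz = np.einsum("gn,ni,gn->gi", w, X, z)
        beta_new = np.linalg.solve(xtwx + ridge, xtwz[..., None])[..., 0]
        # step halving where the likelihood would drop
        step = beta_new - beta
        ll_new = _nb_loglik(y, np.exp(eta_of(beta + step) + offset), phi_col)
        for _half in range(8):
            worse = ll_new < ll - 1e-8
            if not worse.any():
                break
            step[worse] *= 0.5
            ll_try = _nb_loglik(y[worse], np.exp(eta_of(beta[worse] + step[worse])
                                                 + offset[worse]), phi_col[worse])
            ll_new[worse] = ll_try
        beta = beta + step
        eta = eta_of(beta)
        mu = np.exp(eta + offset)
        delta = np.abs(ll_new - ll)
        newly = delta < tol * (np.abs(ll) + 1.0)
        converged |= newly
        ll = ll_new
        if converged.all():
            break
    w = np.maximum(mu / (1.0 + phi_col * mu), 1e-12)
    xtwx = np.einsum("gn,ni,nj->gij", w, X, X)
    return beta, mu, ll, converged, xtwx


@dataclass
class DispersionEstimate:
    common: float
    tagwise: pd.Series
    grid: np.ndarray
    apl: np.ndarray  # genes x grid Cox-Reid adjusted profile log-likelihoods
    flagged: pd.Series  # all-zero genes set to the common value


def _interp_max(logx: np.ndarray, fx: np.ndarray) -> float:
    """Quadratic interpolation of the maximizer on an equally spaced grid."""
    j = int(np.argmax(fx))
    if j == 0 or j == len(logx) - 1:
        return float(logx[j])
    h = logx[j + 1] - logx[j]
    f0, f1, f2 = fx[j - 1], fx[j], fx[j + 1]
    denom = f0 - 2 * f1 + f2
    if denom >= -1e-12:
        return float(logx[j])
    return float(logx[j] + 0.5 * h * (f0 - f2) / denom)


def estimate_dispersion(counts: pd.DataFrame | CountMatrix, design: np.ndarray,
                        offset: np.ndarray | None = None, prior_df: float = 10.0,
                        grid_size: int = 21,
                        grid_range: tuple[float, float] = (1e-4, 4.0),
                        maxiter: int = 25) -> DispersionEstimate:
    """Common + tagwise NB dispersion via Cox-Reid adjusted profile likelihood.

    For each dispersion on a log grid, all genes are refit and the adjusted
    profile log-likelihood APL_g = ll_g - 0.5 log det(X'WX) recorded.  The
    common value maximizes the mean APL; tagwise values maximize
    APL_g + prior_n * mean(APL) with prior_n = prior_df / residual df,
    shrinking noisy per-gene estimates toward the common one.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    y = counts.to_numpy(dtype=float)
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if n - p < 1:
        raise ValueError("need at least one residual degree of freedom")
    if offset is None:
        offset = np.log(y.sum(axis=0))
    grid = np.exp(np.linspace(np.log(grid_range[0]), np.log(grid_range[1]), grid_size))
    nonzero = y.sum(axis=1) > 0
    yz = y[nonzero]
    apl = np.full((y.shape[0], grid_size), np.nan)
    for k, phi in enumerate(grid):
        _, _, ll, _, xtwx = _fit_nb_glm(yz, X, offset, np.full(yz.shape[0], phi),
                                        maxiter=maxiter)
        sign, logdet = np.linalg.slogdet(xtwx)
        apl[nonzero, k] = ll - 0.5 * logdet
    mean_apl = np.nanmean(apl[nonzero], axis=0)
    loggrid = np.log(grid)
    common = float(np.clip(np.exp(_interp_max(loggrid, mean_apl)), *grid_range))
    prior_n = prior_df / max(n - p, 1)
    tag = np.full(y.shape[0], common)
    obj = apl[nonzero] + prior_n * mean_apl[None, :]
    for i, gi in enumerate(np.flatnonzero(nonzero)):
        tag[gi] = np.clip(np.exp(_interp_max(loggrid, obj[i])), *grid_range)
    flagged = pd.Series(~nonzero, index=counts.index, name="dispersion_flagged")
    return DispersionEstimate(common=common,
                              tagwise=pd.Series(tag, index=counts.index, name="phi"),
                              grid=grid, apl=apl, flagged=flagged)


# ---------------------------------------------------------------------------
# likelihood-ratio test


def nb_lrt(counts: pd.DataFrame | CountMatrix, design: np.ndarray,
           coef: int | list[int], dispersion: pd.Series | np.ndarray | float | None = None,
           norm_factors: pd.Series | None = None,
           lib_size: pd.Series | None = None,
           prior_df: float = 10.0) -> pd.DataFrame:
    """Per-gene NB GLM likelihood-ratio test dropping ``coef`` column(s).

    The offset is log(effective library size) = log(raw library size x TMM
    factor).  Returns a DEResult table: gene_id, log2FC (tested coefficient
    on the log2 scale), LR_stat, p_value, fdr, flag.  Genes whose fits do
    not converge are flagged and assigned p = 1 (conservative); all-zero
    genes get log2FC 0, p 1.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    y = counts.to_numpy(dtype=float)
    X = np.asarray(design, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is not full rank")
    coefs = [coef] if np.isscalar(coef) else list(coef)
    if lib_size is None:
        lib_size = counts.sum(axis=0).astype(float)
    if norm_factors is None:
        norm_factors = tmm_factors(counts)
    offset = np.log(lib_size.to_numpy() * norm_factors.reindex(counts.columns).to_numpy())
    if dispersion is None:
        # default to the common Cox-Reid estimate: with the handful of
        # residual df these designs carry, per-gene (tagwise) estimates are
        # noisy enough that chance-low values inflate the LRT tail, and the
        # measured null calibration is visibly better under the pooled value
        dispersion = estimate_dispersion(counts, X, offset=offset,
                                         prior_df=prior_df).common
    phi = (np.full(y.shape[0], float(dispersion)) if np.isscalar(dispersion)
           else np.asarray(dispersion, dtype=float))
    X_red = np.delete(X, coefs, axis=1)
    beta_f, _, ll_f, conv_f, _ = _fit_nb_glm(y, X, offset, phi)
    _, _, ll_r, conv_r, _ = _fit_nb_glm(y, X_red, offset, phi)
    lr = np.maximum(2.0 * (ll_f - ll_r), 0.0)
    df = len(coefs)
    p = chi2.sf(lr, df)
    log2fc = beta_f[:, coefs[0]] / LN2
    all_zero = y.sum(axis=1) == 0
    nonconv = ~(conv_f & conv_r) & ~all_zero
    flag = np.where(all_zero, "all_zero", np.where(nonconv, "nonconverged", ""))
    p = np.where(all_zero | nonconv, 1.0, p)
    lr = np.where(all_zero, 0.0, lr)
    log2fc = np.where(all_zero, 0.0, log2fc)
    out = pd.DataFrame({
        "gene_id": counts.index,
        "log2FC": log2fc,
        "LR_stat": lr,
        "p_value": p,
        "fdr": bh_adjust(p),
        "flag": flag,
    })
    return out


def two_group_design(groups: pd.Series | np.ndarray, test_level: str,
                     ref_level: str) -> tuple[np.ndarray, int]:
    """Intercept + indicator design; coefficient 1 is log(test/ref)."""
    groups = np.asarray(groups)
    used = np.isin(groups, [test_level, ref_level])
    if not used.all():
        raise ValueError("groups contain levels outside the contrast")
    ind = (groups == test_level).astype(float)
    X = np.column_stack([np.ones_like(ind), ind])
    return X, 1


def de_two_group(counts: pd.DataFrame | CountMatrix, groups: pd.Series | np.ndarray,
                 test_level: str, ref_level: str, **kwargs) -> pd.DataFrame:
    """Convenience two-group LRT; log2FC is log2(test / ref)."""
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    groups = np.asarray(groups)
    keep = np.isin(groups, [test_level, ref_level])
    X, coef = two_group_design(groups[keep], test_level, ref_level)
    return nb_lrt(counts.loc[:, keep], X, coef, **kwargs)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NA preserved."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    ps = p[ok]
    if ps.size:
        if (ps < 0).any() or (ps > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        m = ps.size
        order = np.argsort(ps, kind="mergesort")
        ranked = ps[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        res = np.empty(m)
        res[order] = np.minimum(adj, 1.0)
        out[ok] = res
    return out
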