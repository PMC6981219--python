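"""The five differential-expression models and BH adjustment.

All models share conventions:

* two-group designs only; log2 fold change is treatment over control;
* all tests are two-sided;
* genes with zero counts in every sample are not dropped — they receive
  ``p = q = 1``, ``lfc = 0`` and a ``"all-zero"`` flag, so the gene universe
  is identical across every grid cell;
* q-values are Benjamini-Hochberg within one (normalization, model) cell.

The two negative-binomial models (Wald and robust LRT) share a dispersion
fit (:func:`fit_dispersion`): gene-wise method-of-moments estimates shrunk
toward an ``a / mu + b`` mean-dispersion trend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .data import DEResult, StudyDesign
from .errors import DesignError

__all__ = [
    "DispersionFit",
    "fit_dispersion",
    "nb_wald_test",
    "nb_lrt_robust_test",
    "voom_weights",
    "voom_moderated_t_test",
    "mann_whitney_test",
    "welch_t_test",
    "bh_adjust",
    "MODELS",
]

_PHI_FLOOR = 1e-8
_PSEUDO = 0.5


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} p_(j) * m / j`` capped at 1, mapped back to the
    input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------


@dataclass
class DispersionFit:
    """Gene-wise NB dispersions: raw moments, fitted trend, shrunken final.

    The NB variance convention is ``var = mu + phi * mu**2``. The trend is
    ``phi(mu) = a / mu + b``; the final dispersion is the geometric mean of
    raw and trend values (equal weights), or the trend where the raw
    estimate is zero or undefined.
    """

    raw: np.ndarray
    trend: np.ndarray
    final: np.ndarray
    trend_a: float
    trend_b: float
    messages: list[str] = field(default_factory=list)


def _as_counts_array(counts) -> np.ndarray:
    if hasattr(counts, "counts"):
        return np.asarray(counts.counts, dtype=float)
    return np.asarray(counts, dtype=float)


def _relative_depths(offsets: np.ndarray | None, n_samples: int) -> np.ndarray:
    if offsets is None:
        return np.ones(n_samples)
    o = np.asarray(offsets, dtype=float)
    return np.exp(o - o.mean())


def fit_dispersion(counts, offsets: np.ndarray | None, design: StudyDesign) -> DispersionFit:
    """Estimate gene-wise NB dispersions shared by the two count models.

    Raw dispersions come from within-group moments of depth-adjusted counts
    (clipped at zero); the ``a/mu + b`` trend is fit by robust least squares
    over genes with positive raw dispersion; the final value shrinks the raw
    estimate toward the trend with weight 0.5 on the log scale.

    Two small-sample bias corrections keep the estimate mean-accurate: the
    moment denominator uses ``mu_hat^2 - s^2/n`` (the unbiased estimate of
    ``mu^2``, floored at ``mu_hat^2 / 4`` for stability), and the log of the
    raw estimate entering the geometric shrinkage is corrected for Jensen
    bias by ``log(df/2) - digamma(df/2)``.
    """
    y = _as_counts_array(counts)
    n_genes, n_samples = y.shape
    d = _relative_depths(offsets, n_samples)
    z = y / d
    inv_d_mean = float(np.mean(1.0 / d))

    masks = [np.asarray(design.control_mask), np.asarray(design.treatment_mask)]
    ss = np.zeros(n_genes)
    df = 0.0
    mu_w = np.zeros(n_genes)
    mu2_w = np.zeros(n_genes)
    mu_all = np.zeros(n_genes)
    for mask in masks:
        zk = z[:, mask]
        nk = int(mask.sum())
        mk = zk.mean(axis=1)
        s2k = zk.var(axis=1, ddof=1)
        ss += ((zk - mk[:, None]) ** 2).sum(axis=1)
        df += nk - 1
        mu_w += (nk - 1) * mk
        mu2_w += (nk - 1) * np.maximum(mk**2 - s2k / nk, 0.25 * mk**2)
        mu_all += nk * mk
    mu_w /= df
    mu2_w /= df
    mu_all /= n_samples
    s2 = ss / df

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (s2 - mu_w * inv_d_mean) / mu2_w
    raw = np.where(mu2_w > 0, raw, np.nan)
    raw = np.where(np.isnan(raw), np.nan, np.clip(raw, 0.0, None))

    messages: list[str] = []
    positive = np.isfinite(raw) & (raw > 0) & (mu_all > 0)
    if positive.sum() < 3:
        finite = raw[np.isfinite(raw) & (raw > 0)]
        b = float(np.median(finite)) if finite.size else 0.1
        a = 0.0
        messages.append(
            f"only {int(positive.sum())} genes with positive raw dispersion; "
            f"trend replaced by global median {b:.4g}"
        )
        warnings.warn(messages[0])
    else:
        mu_fit = mu_all[positive]
        phi_fit = raw[positive]
        design_x = np.column_stack([1.0 / mu_fit, np.ones_like(mu_fit)])

        def resid(ab):
            return design_x @ ab - phi_fit

        ls0, *_ = np.linalg.lstsq(design_x, phi_fit, rcond=None)
        x0 = np.clip(ls0, 1e-6, None)
        sol = optimize.least_squares(resid, x0=x0, loss="soft_l1", bounds=(0.0, np.inf))
        a, b = float(sol.x[0]), float(sol.x[1])

    with np.errstate(divide="ignore"):
        trend = np.where(mu_all > 0, a / np.clip(mu_all, 1e-12, None) + b, b)
    trend = np.clip(trend, _PHI_FLOOR, None)

    final = trend.copy()
    use_raw = np.isfinite(raw) & (raw > 0)
    log_bias = float(np.log(df / 2.0) - special.digamma(df / 2.0))
    final[use_raw] = np.exp(
        0.5 * (np.log(raw[use_raw]) + log_bias) + 0.5 * np.log(trend[use_raw])
    )
    return DispersionFit(
        raw=np.where(np.isfinite(raw), raw, np.nan),
        trend=trend,
        final=np.clip(final, _PHI_FLOOR, None),
        trend_a=a,
        trend_b=b,
        messages=messages,
    )


# ---------------------------------------------------------------------------
# negative binomial fitting machinery
# ---------------------------------------------------------------------------


def _fit_group_means(
    y: np.ndarray, d: np.ndarray, phi: np.ndarray, w: np.ndarray | None = None,
    max_iter: int = 100, tol: float = 1e-13,
) -> np.ndarray:
    """Per-gene NB mean MLE with fixed dispersion and per-sample depths.

    Solves ``sum_j w_j (y_j - m d_j) / (1 + phi m d_j) = 0`` by the fixed
    point ``m <- sum(u y) / sum(u d)`` with ``u = w / (1 + phi m d)``. With
    equal depths and weights this converges to the sample mean exactly.
    Returns the vector of fitted means ``m`` (on the depth-1 scale).
    """
    if w is None:
        w = np.ones_like(y)
    m = (w * y).sum(axis=1) / (w * d).sum(axis=1)
    for _ in range(max_iter):
        u = w / (1.0 + phi[:, None] * m[:, None] * d[None, :])
        m_new = (u * y).sum(axis=1) / (u * d).sum(axis=1)
        delta = np.max(np.abs(m_new - m) / np.maximum(m, 1e-8))
        m = m_new
        if delta < tol:
            break
    return m


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray, w: np.ndarray | None = None) -> np.ndarray:
    """Per-gene (optionally weighted) NB log-likelihood, phi fixed."""
    mu = np.clip(mu, 1e-12, None)
    r = 1.0 / np.clip(phi, _PHI_FLOOR, None)[:, None]
    ll = (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )
    if w is not None:
        ll = w * ll
    return ll.sum(axis=1)


def _group_data(counts, design: StudyDesign, offsets):
    y = _as_counts_array(counts)
    d = _relative_depths(offsets, y.shape[1])
    c_mask = np.asarray(design.control_mask)
    t_mask = np.asarray(design.treatment_mask)
    if c_mask.sum() < 2 or t_mask.sum() < 2:
        raise DesignError("each condition group needs at least two samples")
    return y, d, c_mask, t_mask


def _zero_group_pseudo(m: np.ndarray, d_sum: float) -> tuple[np.ndarray, np.ndarray]:
    """Replace zero fitted means by a half-count equivalent; flag them."""
    zero = m <= 0
    m_eff = np.where(zero, _PSEUDO / d_sum, m)
    return m_eff, zero


def _finish(
    normalization: str, model: str, gene_ids: list[str],
    lfc: np.ndarray, stat: np.ndarray, p: np.ndarray, flags: list[str],
    all_zero: np.ndarray,
) -> DEResult:
    lfc = np.where(all_zero, 0.0, lfc)
    stat = np.where(all_zero, 0.0, stat)
    p = np.where(all_zero, 1.0, p)
    flags = [("all-zero" if az else f) for f, az in zip(flags, all_zero)]
    q = bh_adjust(p)
    return DEResult(
        normalization=normalization,
        model=model,
        gene_ids=gene_ids,
        log2_fold_change=lfc,
        statistic=stat,
        p_value=p,
        q_value=q,
        flags=flags,
    )


def _gene_ids_of(counts, n: int) -> list[str]:
    if hasattr(counts, "gene_ids"):
        return list(counts.gene_ids)
    return [f"g{i}" for i in range(n)]


def nb_wald_test(
    counts, design: StudyDesign, dispersion: DispersionFit,
    offsets: np.ndarray | None = None, normalization: str = "",
) -> DEResult:
    """Negative-binomial Wald test for a two-group contrast.

    Group means are fit by maximum likelihood with fixed gene-wise
    dispersion and sample offsets; the statistic is the log fold change over
    its standard error from the observed Fisher information, referred to a
    standard normal. No fold-change shrinkage is applied, so with equal
    offsets the reported log2 fold change is exactly the log2 ratio of group
    sample means.
    """
    y, d, c_mask, t_mask = _group_data(counts, design, offsets)
    n_genes = y.shape[0]
    phi = np.clip(dispersion.final, _PHI_FLOOR, None)

    m_c = _fit_group_means(y[:, c_mask], d[c_mask], phi)
    m_t = _fit_group_means(y[:, t_mask], d[t_mask], phi)
    m_c, zero_c = _zero_group_pseudo(m_c, float(d[c_mask].sum()))
    m_t, zero_t = _zero_group_pseudo(m_t, float(d[t_mask].sum()))

    lfc = np.log2(m_t / m_c)
    mu_c = m_c[:, None] * d[None, c_mask]
    mu_t = m_t[:, None] * d[None, t_mask]
    info_c = (mu_c / (1.0 + phi[:, None] * mu_c)).sum(axis=1)
    info_t = (mu_t / (1.0 + phi[:, None] * mu_t)).sum(axis=1)
    se_ln = np.sqrt(1.0 / info_c + 1.0 / info_t)
    z = np.log(m_t / m_c) / se_ln
    p = 2.0 * stats.norm.sf(np.abs(z))

    all_zero = y.sum(axis=1) == 0
    flags = [("zero-group" if zc or zt else "") for zc, zt in zip(zero_c, zero_t)]
    return _finish(normalization, "nb_wald", _gene_ids_of(counts, n_genes), lfc, z, p, flags, all_zero)


def nb_lrt_robust_test(
    counts, design: StudyDesign, dispersion: DispersionFit,
    offsets: np.ndarray | None = None, normalization: str = "",
    residual_cutoff: float = 2.5,
) -> DEResult:
    """Robust negative-binomial likelihood-ratio test.

    Compares group-specific vs common NB means at fixed gene-wise
    dispersion. Observations whose Pearson residual from a first-pass fit
    exceeds ``residual_cutoff`` are down-weighted (``w = cutoff / |r|``) in
    both the full and null fits and in the likelihoods, so single outliers
    cannot drive significance. The statistic is referred to chi-square with
    one degree of freedom.
    """
    y, d, c_mask, t_mask = _group_data(counts, design, offsets)
    n_genes = y.shape[0]
    phi = np.clip(dispersion.final, _PHI_FLOOR, None)

    # first pass: unweighted full fit for residuals
    m_c0 = _fit_group_means(y[:, c_mask], d[c_mask], phi)
    m_t0 = _fit_group_means(y[:, t_mask], d[t_mask], phi)
    mu0 = np.empty_like(y)
    mu0[:, c_mask] = m_c0[:, None] * d[None, c_mask]
    mu0[:, t_mask] = m_t0[:, None] * d[None, t_mask]
    with np.errstate(divide="ignore", invalid="ignore"):
        pearson = (y - mu0) / np.sqrt(mu0 * (1.0 + phi[:, None] * mu0))
    pearson = np.where(np.isfinite(pearson), pearson, 0.0)
    absr = np.abs(pearson)
    w = np.where(absr > residual_cutoff, residual_cutoff / np.clip(absr, 1e-12, None), 1.0)

    m_c = _fit_group_means(y[:, c_mask], d[c_mask], phi, w=w[:, c_mask])
    m_t = _fit_group_means(y[:, t_mask], d[t_mask], phi, w=w[:, t_mask])
    m_null = _fit_group_means(y, d, phi, w=w)
    m_ce, zero_c = _zero_group_pseudo(m_c, float(d[c_mask].sum()))
    m_te, zero_t = _zero_group_pseudo(m_t, float(d[t_mask].sum()))

    mu_full = np.empty_like(y)
    mu_full[:, c_mask] = m_c[:, None] * d[None, c_mask]
    mu_full[:, t_mask] = m_t[:, None] * d[None, t_mask]
    mu_null = m_null[:, None] * d[None, :]
    ll_full = _nb_loglik(y, mu_full, phi, w)
    ll_null = _nb_loglik(y, mu_null, phi, w)
    lrt = np.clip(2.0 * (ll_full - ll_null), 0.0, None)
    p = stats.chi2.sf(lrt, df=1)
    lfc = np.log2(m_te / m_ce)

    all_zero = y.sum(axis=1) == 0
    flags = [("zero-group" if zc or zt else "") for zc, zt in zip(zero_c, zero_t)]
    return _finish(
        normalization, "nb_lrt_robust", _gene_ids_of(counts, n_genes), lfc, lrt, p, flags, all_zero
    )


# ---------------------------------------------------------------------------
# voom-style moderated t
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y (Newton on the log scale)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_fdist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F prior (d0, s0^2) to sample variances.

    Empirical-Bayes hyperparameters from the distribution of log variances,
    using digamma/trigamma moments; d0 = inf when the variances are less
    spread than chi-square sampling alone would produce.
    """
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
    return d0, s0_2


def voom_weights(
    counts, design: StudyDesign, effective_depths: np.ndarray | None = None,
    lowess_frac: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Log-CPM values and observation-level precision weights.

    The mean-variance trend (lowess of sqrt residual SD on average
    log-count) is evaluated at every observation's fitted log-count; the
    weight is the inverse of the implied variance (``trend**-4``). When the
    variance does not depend on the mean the trend is flat and the weights
    approach equality.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    y_counts, _, c_mask, t_mask = _group_data(counts, design, None)
    n_samples = y_counts.shape[1]
    if effective_depths is None:
        depths = y_counts.sum(axis=0)
    else:
        depths = np.asarray(effective_depths, dtype=float)
    ylog = np.log2((y_counts + _PSEUDO) / (depths + 1.0)[None, :] * 1e6)

    fitted = np.empty_like(ylog)
    fitted[:, c_mask] = ylog[:, c_mask].mean(axis=1, keepdims=True)
    fitted[:, t_mask] = ylog[:, t_mask].mean(axis=1, keepdims=True)
    s2_raw = ((ylog - fitted) ** 2).sum(axis=1) / (n_samples - 2)
    sqrt_sd = s2_raw**0.25

    log_depth_term = np.log2(np.exp(np.mean(np.log(depths + 1.0)))) - np.log2(1e6)
    x_gene = ylog.mean(axis=1) + log_depth_term
    trend = lowess(sqrt_sd, x_gene, frac=lowess_frac, return_sorted=True)
    tx, ty = trend[:, 0], np.clip(trend[:, 1], 1e-6, None)

    obs_logcount = fitted + np.log2(depths + 1.0)[None, :] - np.log2(1e6)
    pred = np.interp(obs_logcount, tx, ty)
    return ylog, pred**-4.0


def voom_moderated_t_test(
    counts, design: StudyDesign, effective_depths: np.ndarray | None = None,
    normalization: str = "", lowess_frac: float = 0.5,
) -> DEResult:
    """Precision-weighted moderated t on log-CPM values.

    ``y = log2((count + 0.5) / (depth + 1) * 1e6)``; the mean-variance trend
    (lowess of sqrt residual SD on average log-count) converts each
    observation's fitted log-count into an inverse-variance precision
    weight; a weighted two-group fit per gene yields the fold change and
    residual variance, which empirical Bayes moderates toward a common prior
    before forming a t statistic with ``d0 + d_g`` degrees of freedom.
    """
    y_counts, _, c_mask, t_mask = _group_data(counts, design, None)
    n_genes, n_samples = y_counts.shape
    gene_ids = _gene_ids_of(counts, n_genes)
    if effective_depths is None:
        depths = y_counts.sum(axis=0)
    else:
        depths = np.asarray(effective_depths, dtype=float)
    if np.any(depths <= 0):
        raise ValueError("effective depths must be positive")

    ylog = np.log2((y_counts + _PSEUDO) / (depths + 1.0)[None, :] * 1e6)
    all_zero = y_counts.sum(axis=1) == 0

    if n_genes < 10:
        warnings.warn("fewer than 10 genes: mean-variance trend unreliable, using unweighted Welch t")
        res = welch_t_test(ylog, design, log_scale=False, normalization=normalization)
        lfc = ylog[:, t_mask].mean(axis=1) - ylog[:, c_mask].mean(axis=1)
        return _finish(
            normalization, "voom", gene_ids, lfc, res.statistic, res.p_value,
            ["small-panel"] * n_genes, all_zero,
        )

    ylog, weights = voom_weights(y_counts, design, depths, lowess_frac=lowess_frac)
    df_resid = n_samples - 2

    w_c, w_t = weights[:, c_mask], weights[:, t_mask]
    sw_c, sw_t = w_c.sum(axis=1), w_t.sum(axis=1)
    mean_c = (w_c * ylog[:, c_mask]).sum(axis=1) / sw_c
    mean_t = (w_t * ylog[:, t_mask]).sum(axis=1) / sw_t
    lfc = mean_t - mean_c
    resid = np.empty_like(ylog)
    resid[:, c_mask] = ylog[:, c_mask] - mean_c[:, None]
    resid[:, t_mask] = ylog[:, t_mask] - mean_t[:, None]
    s2 = (weights * resid**2).sum(axis=1) / df_resid

    d0, s0_2 = _fit_fdist(s2, float(df_resid))
    if np.isfinite(d0):
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = min(d0 + df_resid, 1e6)
    else:
        s2_post = np.full_like(s2, s0_2)
        df_total = 1e6
    se = np.sqrt(s2_post * (1.0 / sw_c + 1.0 / sw_t))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t_stat), df=df_total)
    return _finish(normalization, "voom", gene_ids, lfc, t_stat, p, [""] * n_genes, all_zero)


# ---------------------------------------------------------------------------
# rank and t tests on normalized values
# ---------------------------------------------------------------------------


def mann_whitney_test(
    normalized, design: StudyDesign, normalization: str = "", exact_max_n: int = 10,
) -> DEResult:
    """Two-sided Mann-Whitney rank-sum test per gene.

    Exact p-values by full enumeration when the total sample count is at
    most ``exact_max_n`` and the gene has no ties; otherwise the normal
    approximation with tie and continuity corrections. The reported fold
    change (``log2`` of pseudo-counted group-mean ratio) is for display
    only — the test itself is rank-based.
    """
    vals = _as_counts_array(normalized)
    n_genes, n_samples = vals.shape
    gene_ids = _gene_ids_of(normalized, n_genes)
    c_mask = np.asarray(design.control_mask)
    t_mask = np.asarray(design.treatment_mask)
    xt, xc = vals[:, t_mask], vals[:, c_mask]
    n1, n2 = xt.shape[1], xc.shape[1]

    constant = np.all(vals == vals[:, [0]], axis=1)
    has_ties = np.array([len(np.unique(row)) < n_samples for row in vals])
    use_exact = (~has_ties) & (n_samples <= exact_max_n)

    stat = np.full(n_genes, n1 * n2 / 2.0)
    p = np.ones(n_genes)
    for mask, method in ((use_exact & ~constant, "exact"), (~use_exact & ~constant, "asymptotic")):
        if not np.any(mask):
            continue
        res = stats.mannwhitneyu(
            xt[mask], xc[mask], axis=1, alternative="two-sided",
            method=method, use_continuity=True,
        )
        stat[mask] = res.statistic
        p[mask] = np.clip(np.where(np.isfinite(res.pvalue), res.pvalue, 1.0), 0.0, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2((xt.mean(axis=1) + _PSEUDO) / (xc.mean(axis=1) + _PSEUDO))
    lfc = np.where(np.isfinite(lfc), lfc, 0.0)  # display-only; undefined for signed values
    all_zero = np.all(vals == 0, axis=1)
    flags = [("constant" if c else "") for c in constant]
    return _finish(normalization, "mann_whitney", gene_ids, lfc, stat, p, flags, all_zero)


def welch_t_test(
    normalized, design: StudyDesign, log_scale: bool = True, normalization: str = "",
) -> DEResult:
    """Welch two-sample t-test per gene with Satterthwaite df.

    With ``log_scale`` (default) values are ``log2(x + 0.5)`` transformed
    first, and the fold change is the difference of group means of log2
    values.
    """
    vals = _as_counts_array(normalized)
    n_genes = vals.shape[0]
    gene_ids = _gene_ids_of(normalized, n_genes)
    if log_scale:
        if np.any(vals < 0):
            raise ValueError("log-scale Welch t requires nonnegative values")
        work = np.log2(vals + _PSEUDO)
    else:
        work = vals
    c_mask = np.asarray(design.control_mask)
    t_mask = np.asarray(design.treatment_mask)
    xt, xc = work[:, t_mask], work[:, c_mask]

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(xt, xc, axis=1, equal_var=False)
    t_stat = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)

    var_t, var_c = xt.var(axis=1, ddof=1), xc.var(axis=1, ddof=1)
    mean_t, mean_c = xt.mean(axis=1), xc.mean(axis=1)
    both_const = (var_t == 0) & (var_c == 0)
    equal_const = both_const & (mean_t == mean_c)
    unequal_const = both_const & (mean_t != mean_c)
    t_stat = np.where(equal_const, 0.0, t_stat)
    p = np.where(equal_const, 1.0, p)
    t_stat = np.where(unequal_const, np.sign(mean_t - mean_c) * 1e6, t_stat)
    p = np.where(unequal_const, 0.0, p)
    t_stat = np.where(np.isfinite(t_stat), t_stat, 0.0)
    p = np.clip(np.where(np.isfinite(p), p, 1.0), 0.0, 1.0)

    if log_scale:
        lfc = mean_t - mean_c
    else:
        lfc = mean_t - mean_c  # same display convention: difference of means
    all_zero = np.all(vals == 0, axis=1)
    flags = [("degenerate" if u else "") for u in unequal_const]
    return _finish(normalization, "welch_t", gene_ids, lfc, t_stat, p, flags, all_zero)


#: Model registry: tag -> runner(counts, design, *, offsets, effective_depths,
#: values, dispersion, normalization). The consensus grid prepares the inputs
#: each model family consumes (raw/rounded counts for the NB models and voom,
#: normalized values for the rank and t tests).
MODELS = {
    "nb_wald": lambda counts, design, *, offsets=None, effective_depths=None, values=None,
    dispersion=None, normalization="": nb_wald_test(
        counts, design, dispersion, offsets=offsets, normalization=normalization
    ),
    "nb_lrt_robust": lambda counts, design, *, offsets=None, effective_depths=None, values=None,
    dispersion=None, normalization="": nb_lrt_robust_test(
        counts, design, dispersion, offsets=offsets, normalization=normalization
    ),
    "voom": lambda counts, design, *, offsets=None, effective_depths=None, values=None,
    dispersion=None, normalization="": voom_moderated_t_test(
        counts, design, effective_depths=effective_depths, normalization=normalization
    ),
    "mann_whitney": lambda counts, design, *, offsets=None, effective_depths=None, values=None,
    dispersion=None, normalization="": mann_whitney_test(
        values if values is not None else counts, design, normalization=normalization
    ),
    "welch_t": lambda counts, design, *, offsets=None, effective_depths=None, values=None,
    dispersion=None, normalization="": welch_t_test(
        values if values is not None else counts, design, normalization=normalization
    ),
}
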