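"""Component tests and p-value combination machinery.

Each gene is tested for three kinds of difference between two cell groups:

* ``proportion_test`` -- pooled two-proportion z-test on the fraction of
  cells expressing the gene (the "On" proportion).
* ``location_test`` -- Welch t-test on the positive ("On") counts only.
* ``scale_test`` -- Brown-Forsythe test (Levene with group medians) on the
  positive counts, upper-tail F(1, m1 + m2 - 2).

The three p-values are combined with Fisher's method,
``Q = -2 * sum(log Li)``.  Under independence Q would be chi-square with
6 degrees of freedom, but the components are correlated (the location and
dispersion tests share the positive part), so the effective degrees of
freedom are estimated from the genome-wide Q distribution by a trimmed
maximum-likelihood fit on [2, 6].

All p-values are clamped to ``[P_FLOOR, 1]`` before logs so Q is always
finite; degenerate components (nothing to test) report p = 1 and contribute
no evidence.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import optimize, stats as sps

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: floor applied to every p-value before taking logs
P_FLOOR = 1e-300


def _clamp(p):
    return np.clip(p, P_FLOOR, 1.0)


# ---------------------------------------------------------------------------
# component tests
# ---------------------------------------------------------------------------


def proportion_test(m1, n1, m2, n2):
    """Pooled two-proportion z-test on expressing-cell counts.

    Parameters are the number of positive cells ``m_g`` out of ``n_g`` cells
    in each group; all four accept arrays.  Returns ``(z, L1)`` where
    ``L1 = 2 P(Z > |z|)``.  When the pooled proportion is 0 or 1 the
    statistic is undefined and the test reports no evidence (z = 0, L1 = 1).
    """
    m1, n1, m2, n2 = (np.asarray(a, dtype=float) for a in (m1, n1, m2, n2))
    if np.any(m1 < 0) or np.any(m2 < 0) or np.any(m1 > n1) or np.any(m2 > n2):
        raise ValidationError("need 0 <= m_g <= n_g")
    if np.any(n1 < 1) or np.any(n2 < 1):
        raise ValidationError("need n_g >= 1")
    pooled = (m1 + m2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (m1 / n1 - m2 / n2) / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
    L1 = _clamp(2.0 * sps.norm.sf(np.abs(z)))
    if z.ndim == 0:
        return float(z), float(L1)
    return z, L1


def _welch_from_stats(xbar1, v1, m1, xbar2, v2, m2):
    """Welch t, Satterthwaite df and two-sided p from sufficient statistics.

    Vectorized; inputs are positive-part means, sample variances (ddof=1)
    and positive-cell counts.  Zero pooled standard error is handled per
    the degenerate-component convention.
    """
    se2 = v1 / m1 + v2 / m2
    diff = xbar1 - xbar2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se2 > 0, diff / np.sqrt(np.where(se2 > 0, se2, 1.0)), 0.0)
        df = np.where(
            se2 > 0,
            se2**2
            / ((v1 / m1) ** 2 / np.maximum(m1 - 1, 1) + (v2 / m2) ** 2 / np.maximum(m2 - 1, 1)),
            m1 + m2 - 2,
        )
        L2 = np.where(se2 > 0, 2.0 * sps.t.sf(np.abs(t), np.maximum(df, 1e-12)), 1.0)
    # zero variance in both groups but different means: overwhelming evidence
    exact_diff = (se2 == 0) & (diff != 0)
    with np.errstate(invalid="ignore"):
        t = np.where(exact_diff, np.sign(diff) * np.inf, t)
    L2 = np.where(exact_diff, P_FLOOR, L2)
    return t, df, _clamp(L2)


def location_test(x1, x2):
    """Welch t-test on the positive parts of one gene.

    ``x1`` and ``x2`` are the positive counts of the gene in the two groups
    (zeros must already be removed).  Returns ``(t, df_t, L2)`` with
    ``L2 = 2 P(T > |t|)``.  If both sample variances are zero the test
    returns L2 = 1 for equal means and the underflow-clamped minimum p-value
    otherwise.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if np.any(x1 <= 0) or np.any(x2 <= 0):
        raise ValidationError("positive parts only: remove zeros before calling")
    if x1.size < 2 or x2.size < 2:
        raise ValidationError("need at least 2 positive cells per group")
    t, df, L2 = _welch_from_stats(
        x1.mean(), x1.var(ddof=1), x1.size, x2.mean(), x2.var(ddof=1), x2.size
    )
    return float(t), float(df), float(L2)


def _brown_forsythe_from_groups(x1, x2):
    """Scalar Brown-Forsythe statistic for two groups of positive values."""
    m1, m2 = x1.size, x2.size
    z1 = np.abs(x1 - np.median(x1))
    z2 = np.abs(x2 - np.median(x2))
    zbar1, zbar2 = z1.mean(), z2.mean()
    zbar = (z1.sum() + z2.sum()) / (m1 + m2)
    ss_between = m1 * (zbar1 - zbar) ** 2 + m2 * (zbar2 - zbar) ** 2
    ss_within = np.sum((z1 - zbar1) ** 2) + np.sum((z2 - zbar2) ** 2)
    dof = m1 + m2 - 2
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, 1.0
        return float("inf"), P_FLOOR
    W = dof * ss_between / ss_within
    return float(W), float(_clamp(sps.f.sf(W, 1, dof)))


def scale_test(x1, x2):
    """Brown-Forsythe dispersion test on the positive parts of one gene.

    Absolute deviations from each group's median are compared by a one-way
    ANOVA F statistic; the p-value ``L3 = P(F(1, m1+m2-2) > W)`` is
    one-sided upper-tail.  Degenerate deviations (all equal within groups)
    report L3 = 1 when the group means of deviations also agree, else the
    clamped minimum p-value.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if np.any(x1 <= 0) or np.any(x2 <= 0):
        raise ValidationError("positive parts only: remove zeros before calling")
    if x1.size < 2 or x2.size < 2:
        raise ValidationError("need at least 2 positive cells per group")
    return _brown_forsythe_from_groups(x1, x2)


# ---------------------------------------------------------------------------
# combination
# ---------------------------------------------------------------------------


def combine_fisher(L, valid_mask=None) -> float:
    """Fisher combination ``Q = -2 sum(ln Li)`` over the valid components."""
    L = np.asarray(L, dtype=float)
    if valid_mask is None:
        valid_mask = np.ones(L.shape, dtype=bool)
    valid_mask = np.asarray(valid_mask, dtype=bool)
    if not valid_mask.any():
        raise ValidationError("at least one component must be valid")
    used = L[valid_mask]
    if np.any(used <= 0) or np.any(used > 1):
        raise ValidationError("p-values must lie in (0, 1]; clamp before combining")
    return float(-2.0 * np.sum(np.log(used)))


def q_to_pvalue(Q, df):
    """Upper-tail chi-square probability of the combined statistic."""
    Q = np.asarray(Q, dtype=float)
    if np.any(Q < 0):
        raise ValidationError("Q must be non-negative")
    if np.any(np.asarray(df) <= 0):
        raise ValidationError("df must be positive")
    p = _clamp(sps.chi2.sf(Q, df))
    return float(p) if p.ndim == 0 else p


def estimate_df(
    Q_values,
    lower: float = 2.0,
    upper: float = 6.0,
    trim: float = 0.05,
    min_values: int = 50,
) -> float:
    """Estimate the chi-square degrees of freedom of the combined statistic.

    Fits df by maximum likelihood on the central ``1 - 2*trim`` fraction of
    the Q values (a truncated likelihood with the empirical trim points as
    truncation bounds), so that the handful of genuinely DE genes in the
    upper tail cannot drag the estimate.  The optimum is searched on
    ``[lower, upper]``: 6 is the independent-components ceiling and 2 the
    single-component floor.

    Falls back to df = 6 with a warning when fewer than ``min_values``
    usable values are supplied.
    """
    Q = np.asarray(Q_values, dtype=float)
    Q = Q[np.isfinite(Q)]
    if Q.size < min_values:
        logger.warning(
            "only %d usable Q values (< %d); falling back to df=6", Q.size, min_values
        )
        return 6.0
    lo, hi = np.quantile(Q, [trim, 1.0 - trim])
    core = Q[(Q >= lo) & (Q <= hi)]
    # Q can carry an atom at 0 (all components degenerate); the continuous
    # chi-square model only describes the positive part.
    core = core[core > 0]
    if core.size < min_values:
        logger.warning("too few positive Q values after trimming; falling back to df=6")
        return 6.0
    lo = max(lo, np.min(core))

    def negloglik(df: float) -> float:
        mass = sps.chi2.cdf(hi, df) - sps.chi2.cdf(lo, df)
        if mass <= 0:
            return np.inf
        return -(np.sum(sps.chi2.logpdf(core, df)) - core.size * np.log(mass))

    res = optimize.minimize_scalar(negloglik, bounds=(lower, upper), method="bounded")
    return float(res.x)


def bh_adjust(p_values):
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Returns an array aligned with the input; empty input gives an empty
    array.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
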