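"""Two-group linear-model testing with empirical-Bayes variance moderation.

Feature-wise two-group comparisons on arrays (expression features or
methylation probes) share a hierarchical model for the residual variances:
each feature's pooled variance s_g^2 (d residual degrees of freedom) is
treated as drawn from a scaled inverse-chi-square prior with d0 degrees of
freedom and scale s0^2.  The posterior variance

    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

replaces s_g^2 in an ordinary pooled-variance t statistic, which then has
d + d0 degrees of freedom.  Hyperparameters (d0, s0^2) are fitted to the
observed variances by method of moments on the log scale (digamma/trigamma
matching).  With d0 = 0 the statistic is the ordinary pooled two-sample t;
as d0 -> inf every feature is tested against the common prior variance.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

__all__ = ["trigamma_inverse", "fit_variance_prior", "two_group_test"]


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Fit (d0, s0_sq) of the scaled inverse-chi-square variance prior.

    Method of moments on z = log(s2): under the model z has mean
    log(s0^2) + digamma(d/2) - log(d/2) - digamma(d0/2) + log(d0/2)
    and variance trigamma(d/2) + trigamma(d0/2).  If the observed
    log-variance spread does not exceed trigamma(d/2), d0 is infinite
    (a single common variance explains the data).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 3:
        return 0.0, float(np.nanmean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1))
    evar_prior = evar - float(special.polygamma(1, df / 2.0))
    if evar_prior > 0:
        d0 = 2.0 * trigamma_inverse(evar_prior)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


def two_group_test(X: np.ndarray, group_a: np.ndarray, moderated: bool = True) -> dict:
    """Per-row two-group comparison of ``X`` (features x samples).

    Parameters
    ----------
    X
        Matrix of values, one row per feature.
    group_a
        Boolean mask over columns selecting the first group; the reported
        difference is mean(A) - mean(B).
    moderated
        Apply empirical-Bayes variance shrinkage.  When False the statistic
        is the ordinary pooled-variance two-sample t.

    Returns a dict of per-feature arrays ``diff``, ``t``, ``p`` plus the
    scalars ``df``, ``d0``, ``s0_sq``.
    """
    X = np.asarray(X, dtype=float)
    group_a = np.asarray(group_a, dtype=bool)
    if X.ndim != 2 or X.shape[1] != group_a.size:
        raise ValueError("X must be features x samples aligned with group_a")
    n1 = int(group_a.sum())
    n2 = int((~group_a).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >= 2 samples (got {n1} and {n2})")
    Xa = X[:, group_a]
    Xb = X[:, ~group_a]
    diff = Xa.mean(axis=1) - Xb.mean(axis=1)
    v1 = Xa.var(axis=1, ddof=1)
    v2 = Xb.var(axis=1, ddof=1)
    d = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / d
    c = 1.0 / n1 + 1.0 / n2

    if moderated:
        d0, s0_sq = fit_variance_prior(s2, d)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_total = np.inf
        else:
            s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
            df_total = d + d0
    else:
        d0, s0_sq = 0.0, float("nan")
        s2_post = s2
        df_total = float(d)

    se = np.sqrt(s2_post * c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    # identical degenerate groups: 0/0 -> no evidence of difference
    t = np.where((diff == 0) & (se == 0), 0.0, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    # zero residual variance with a real difference: evidence is unbounded
    p = np.where(np.isinf(t), 0.0, p)
    return {"diff": diff, "t": t, "p": p, "df": df_total, "d0": d0, "s0_sq": s0_sq}
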