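"""Independent numerical oracles used across the test suite.

These deliberately avoid the package's closed forms: the breath-curve
density is rebuilt by quadrature over the convolution integrand of
scipy.stats densities, cumulative recovery by adaptive quadrature of the
rate, AUC by brute-force pair counting, and Youden thresholds by
exhaustive scan.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, stats


def conv_pdr_rate(rho: float, pi: float, kappa: float, t: float) -> float:
    """100*kappa x (Gamma(2, rho) convolved with Exp(pi*rho)) density at t."""
    if t == 0:
        return 0.0
    gamma = stats.gamma(a=2, scale=1.0 / rho)
    expon = stats.expon(scale=1.0 / (pi * rho))

    def integrand(u):
        return gamma.pdf(u) * expon.pdf(t - u)

    val, _ = integrate.quad(integrand, 0.0, t, limit=400, epsabs=1e-13, epsrel=1e-12)
    return 100.0 * kappa * val


def quad_cumulative(pdr_fn, t: float) -> float:
    """Adaptive quadrature of a rate function over [0, t]."""
    if t == 0:
        return 0.0
    val, _ = integrate.quad(pdr_fn, 0.0, t, limit=400, epsabs=1e-11, epsrel=1e-10)
    return val


def pairwise_auc(pos_scores, neg_scores) -> float:
    """Mann-Whitney pair statistic: (concordant + half ties) / (n+ * n-)."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (pos.size * neg.size)


def exhaustive_best_j(oriented_scores, labels):
    """Best Youden J over every cutpoint, by direct scan of all rules
    'positive iff score >= c' with c between consecutive values or +/-inf."""
    s = np.asarray(oriented_scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    values = np.unique(s)
    cuts = [-np.inf, *((values[:-1] + values[1:]) / 2.0), np.inf]
    best = -np.inf
    for c in cuts:
        pred = s >= c
        tp = np.sum(pred & (y == 1))
        fn = np.sum(~pred & (y == 1))
        tn = np.sum(~pred & (y == 0))
        fp = np.sum(pred & (y == 0))
        j = tp / (tp + fn) + tn / (tn + fp) - 1.0
        best = max(best, j)
    return best


def manual_confusion(pred, labels):
    """Direct loop-based confusion counts and metric formulas."""
    tp = fp = tn = fn = 0
    for p, y in zip(pred, labels):
        if p and y:
            tp += 1
        elif p and not y:
            fp += 1
        elif not p and y:
            fn += 1
        else:
            tn += 1
    n = tp + fp + tn + fn
    acc = (tp + tn) / n
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / denom**0.5 if denom else 0.0
    return dict(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=acc, sensitivity=sens, specificity=spec, mcc=mcc,
    )


#: parameter grid shared by the closed-form and conservation checks
PARAM_GRID = [
    (rho, pi) for rho in (0.3, 1.0, 3.0) for pi in (0.2, 0.9, 1.1, 5.0)
]
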