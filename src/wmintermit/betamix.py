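"""One- vs two-state descriptions of delay confidence.

Delay-window confidence values (pooled over timepoints within trials) are fit
with a single beta density, p(c) = Beta(c; a, b), and with a two-component
beta mixture, p(c) = w Beta(c; a, b) + (1 - w) Beta(c; a', b'). Both are
scored by four-fold cross-validation at the trial level (all timepoints of a
trial stay in one fold); held-out log-likelihood in base 2 normalized by the
trial count gives each model's bits per trial, and the mixture-minus-single
difference (averaged over folds and cue conditions) decides which description
wins for the session.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from ._glm import CLIP

__all__ = ["BetaModelFit", "fit_beta_models", "fit_beta_single",
           "fit_beta_mixture", "cv_model_comparison"]


@dataclass
class BetaModelFit:
    model: str                  # "single" | "mixture"
    a: float
    b: float
    a2: float | None = None
    b2: float | None = None
    w: float | None = None
    loglik: float = np.nan      # natural-log train likelihood
    converged: bool = True

    def logpdf(self, x) -> np.ndarray:
        x = np.clip(np.asarray(x, float), CLIP, 1 - CLIP)
        lp1 = stats.beta.logpdf(x, self.a, self.b)
        if self.model == "single":
            return lp1
        lp2 = stats.beta.logpdf(x, self.a2, self.b2)
        return np.logaddexp(np.log(self.w) + lp1, np.log1p(-self.w) + lp2)


def _weighted_beta_mle(x, r, init=None, max_newton=60, tol=1e-11):
    """MLE of beta shapes under weights r.

    The weighted log-likelihood depends on the data only through the
    weighted means of log x and log(1-x); it is maximized by damped Newton
    iterations (digamma gradient, trigamma Hessian), warm-startable from a
    previous estimate, which makes the EM M-step cheap.
    """
    R = r.sum()
    m1 = (r * np.log(x)).sum() / R
    m2 = (r * np.log1p(-x)).sum() / R
    if init is None:
        mean = (r * x).sum() / R
        var = max((r * (x - mean) ** 2).sum() / R, 1e-6)
        nu0 = max(mean * (1 - mean) / var - 1.0, 0.1)
        a, b = max(mean * nu0, 1e-2), max((1 - mean) * nu0, 1e-2)
    else:
        a, b = init

    def nll(a, b):
        return special.betaln(a, b) - (a - 1) * m1 - (b - 1) * m2

    f = nll(a, b)
    for _ in range(max_newton):
        psum = special.digamma(a + b)
        ga = special.digamma(a) - psum - m1
        gb = special.digamma(b) - psum - m2
        if max(abs(ga), abs(gb)) < tol:
            break
        tsum = special.polygamma(1, a + b)
        haa = special.polygamma(1, a) - tsum
        hbb = special.polygamma(1, b) - tsum
        det = haa * hbb - tsum * tsum
        if det <= 0:
            da, db = ga / max(haa, 1e-8), gb / max(hbb, 1e-8)
        else:
            da = (hbb * ga + tsum * gb) / det
            db = (tsum * ga + haa * gb) / det
        t = 1.0
        for _ in range(30):  # damp: stay positive and non-increasing
            na, nb = a - t * da, b - t * db
            if na > 1e-6 and nb > 1e-6:
                fn = nll(na, nb)
                if fn <= f + 1e-13:
                    a, b, f = na, nb, fn
                    break
            t *= 0.5
        else:
            break
    return float(a), float(b)


def fit_beta_single(x) -> BetaModelFit:
    x = np.clip(np.asarray(x, float), CLIP, 1 - CLIP)
    a, b = _weighted_beta_mle(x, np.ones_like(x))
    ll = float(stats.beta.logpdf(x, a, b).sum())
    return BetaModelFit("single", a, b, loglik=ll)


def fit_beta_mixture(x, n_restarts: int = 5, seed: int = 0,
                     max_iter: int = 200, tol: float = 1e-7) -> BetaModelFit:
    """EM fit of the two-component beta mixture, best of several restarts.

    Initialization is method-of-moments on a random responsibility split;
    label switching is resolved by ordering components by mean.
    """
    x = np.clip(np.asarray(x, float), CLIP, 1 - CLIP)
    lx, l1x = np.log(x), np.log1p(-x)

    def logpdf(a, b):
        return (a - 1) * lx + (b - 1) * l1x - special.betaln(a, b)

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        # split responsibilities at a random quantile: breaks the symmetric
        # fixed point where both components converge to the single-beta fit
        thr = np.quantile(x, rng.uniform(0.2, 0.8))
        r = np.where(x < thr, 0.9, 0.1) + rng.uniform(-0.05, 0.05, x.size)
        w = 0.5
        ll_prev, converged = -np.inf, False
        p1 = p2 = None
        for it in range(max_iter):
            # warm-started partial M-steps (generalized EM)
            a1, b1 = _weighted_beta_mle(x, r, init=p1,
                                        max_newton=60 if it == 0 else 8)
            a2, b2 = _weighted_beta_mle(x, 1 - r, init=p2,
                                        max_newton=60 if it == 0 else 8)
            p1, p2 = (a1, b1), (a2, b2)
            lp1 = np.log(w) + logpdf(a1, b1)
            lp2 = np.log1p(-w) + logpdf(a2, b2)
            norm = np.logaddexp(lp1, lp2)
            ll = float(norm.sum())
            r = np.clip(np.exp(lp1 - norm), 1e-10, 1 - 1e-10)
            w = float(np.clip(r.mean(), 1e-4, 1 - 1e-4))
            if abs(ll - ll_prev) < tol * (abs(ll) + 1):
                converged = True
                break
            ll_prev = ll
        cand = BetaModelFit("mixture", a1, b1, a2, b2, w, loglik=ll,
                            converged=converged)
        if best is None or cand.loglik > best.loglik:
            best = cand
    # order components by mean for identifiability
    m1 = best.a / (best.a + best.b)
    m2 = best.a2 / (best.a2 + best.b2)
    if m1 > m2:
        best = BetaModelFit("mixture", best.a2, best.b2, best.a, best.b,
                            1 - best.w, loglik=best.loglik,
                            converged=best.converged)
    return best


def fit_beta_models(conf_values, n_restarts: int = 5, seed: int = 0):
    """Single and mixture MLE fits of one session x condition's confidence."""
    x = np.asarray(conf_values, float)
    if x.size < 50:
        raise ValueError("need at least 50 confidence values for a stable fit")
    if np.ptp(x) == 0:
        raise ValueError("degenerate all-equal confidence values")
    return fit_beta_single(x), fit_beta_mixture(x, n_restarts, seed)


def cv_model_comparison(values, trial_ids, k: int = 4, seed: int = 0,
                        conditions=None, n_restarts: int = 3) -> float:
    """Cross-validated bits-per-trial advantage of the mixture model.

    ``values``/``trial_ids`` are aligned 1-D arrays (one entry per delay
    timepoint of a trial). Folds are drawn at the trial level. Returns
    delta bits per trial = mixture score - single score, averaged over folds
    (and over ``conditions`` when given, one trial-to-condition label each).
    """
    values = np.asarray(values, float)
    trial_ids = np.asarray(trial_ids)
    if conditions is None:
        return _cv_delta_one(values, trial_ids, k, seed, n_restarts)
    conditions = np.asarray(conditions)  # aligned elementwise with values
    deltas = []
    for c in np.unique(conditions):
        m = conditions == c
        deltas.append(_cv_delta_one(values[m], trial_ids[m], k, seed, n_restarts))
    return float(np.nanmean(deltas))


def _cv_delta_one(values, trial_ids, k, seed, n_restarts):
    rng = np.random.default_rng(seed)
    utr = np.unique(trial_ids)
    kk = k
    while kk > 1 and utr.size // kk < 10:
        kk -= 1  # re-fold with fewer folds when trials are scarce
    if kk < 2:
        kk = 2
    order = rng.permutation(utr)
    folds = np.array_split(order, kk)
    deltas = []
    for f in folds:
        te = np.isin(trial_ids, f)
        tr = ~te
        if te.sum() == 0 or tr.sum() < 50:
            continue
        single = fit_beta_single(values[tr])
        mix = fit_beta_mixture(values[tr], n_restarts=n_restarts, seed=seed)
        n_te_trials = len(f)
        s_bits = single.logpdf(values[te]).sum() / np.log(2) / n_te_trials
        m_bits = mix.logpdf(values[te]).sum() / np.log(2) / n_te_trials
        deltas.append(m_bits - s_bits)
    return float(np.mean(deltas)) if deltas else np.nan
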