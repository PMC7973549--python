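"""Independent oracles used by the test suite.

These deliberately avoid the package's estimation code paths: the marginal
likelihood is computed by adaptive Gauss-Hermite quadrature with its own
mode search, and ROC / logistic oracles are brute force.
"""

import numpy as np
from scipy import optimize

from oxcpk.model import _conc_profile


def subject_neg_log_joint(pop, y, dose, tau, t, wt):
    """-log p(y, eta) with all normalization constants, as a function of eta."""
    om = np.array([pop.omega2_cl, pop.omega2_v])

    def nlj(eta):
        rel = wt / pop.wt_ref
        cl = pop.theta1_cl * rel**pop.theta2_wt_cl * np.exp(eta[0])
        vv = pop.theta3_v * rel**pop.theta4_wt_v * np.exp(eta[1])
        f = np.maximum(_conc_profile(dose, tau, t, cl, vv, pop.ka), 1e-10)
        var = pop.sigma_add**2 + pop.sigma_prop**2 * f**2
        out = 0.5 * np.sum((y - f) ** 2 / var + np.log(2 * np.pi * var))
        out += 0.5 * np.sum(eta**2 / om + np.log(2 * np.pi * om))
        return out

    return nlj


def marginal_m2ll_quadrature(c, pop, n_nodes=32):
    """-2 log marginal likelihood by adaptive Gauss-Hermite (per-subject mode
    and curvature rescaling), including every 2*pi constant."""
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    counts = np.bincount(c.subj_idx, minlength=c.n_subjects)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    Z1, Z2 = np.meshgrid(nodes, nodes)
    W = np.outer(weights, weights).ravel()
    Z = np.stack([Z1.ravel(), Z2.ravel()])
    total = 0.0
    for i in range(c.n_subjects):
        sl = slice(offsets[i], offsets[i + 1])
        nlj = subject_neg_log_joint(pop, c.y[sl], c.dose[sl], c.tau[sl],
                                    c.t_after_dose[sl], c.wt[sl])
        res = optimize.minimize(nlj, np.zeros(2), method="Nelder-Mead",
                                options=dict(xatol=1e-12, fatol=1e-14,
                                             maxiter=5000))
        mode = res.x
        h = 1e-4
        H = np.zeros((2, 2))
        for a in range(2):
            for b in range(2):
                ea, eb = np.zeros(2), np.zeros(2)
                ea[a] = h
                eb[b] = h
                H[a, b] = (nlj(mode + ea + eb) - nlj(mode + ea - eb)
                           - nlj(mode - ea + eb) + nlj(mode - ea - eb)) / (4 * h * h)
        L = np.linalg.cholesky(np.linalg.inv(H))
        pts = mode[:, None] + np.sqrt(2.0) * L @ Z
        g = np.array([nlj(pts[:, k]) for k in range(pts.shape[1])])
        logsum = -g + Z[0] ** 2 + Z[1] ** 2 + np.log(W)
        m = logsum.max()
        log_integral = (m + np.log(np.sum(np.exp(logsum - m)))
                        + np.log(2.0) + np.log(abs(np.linalg.det(L))))
        total += -2.0 * log_integral
    return total


def foce_quadrature_gap(c, pop):
    """FOCE-I OFV minus the quadrature -2logL on the NONMEM constant scale."""
    from oxcpk.estimate import foce_ofv

    ofv = foce_ofv(c, pop, inner_tol=1e-9)
    oracle = marginal_m2ll_quadrature(c, pop) - c.n_obs * np.log(2 * np.pi)
    return ofv - oracle


def roc_youden_bruteforce(values, labels):
    """Exhaustive threshold search for max Youden's J (higher value = call)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos, n_neg = labels.sum(), (~labels).sum()
    distinct = np.unique(values)
    thresholds = np.concatenate(
        [[-np.inf], (distinct[:-1] + distinct[1:]) / 2, [np.inf]]
    )
    best_j, best_thr, best = -np.inf, None, None
    for thr in thresholds:  # ascending: ties keep the lowest threshold
        call = values > thr
        sens = (call & labels).sum() / n_pos
        spec = (~call & ~labels).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_thr, best = j, thr, (sens, spec)
    return best_thr, best_j, best


def logistic_m2ll(beta, X, y):
    eta = X @ beta
    return -2.0 * np.sum(y * eta - np.logaddexp(0.0, eta))


def logistic_mle_direct(X, y):
    """Independent ML fit of the logistic model by generic minimization."""
    from scipy.special import expit

    beta0 = np.zeros(X.shape[1])

    def score(beta):
        return -2.0 * X.T @ (y - expit(X @ beta))

    res = optimize.minimize(lambda b: logistic_m2ll(b, X, y), beta0, jac=score,
                            method="BFGS", options=dict(gtol=1e-9, maxiter=2000))
    return res.x
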