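"""Independent brute-force oracles used by the test suite.

Each oracle deliberately uses a different computational route than the
implementation it checks: explicit loops instead of matrix algebra, grid +
simplex search instead of IRLS, interval scans instead of vectorised
classification.
"""

import numpy as np
from scipy import optimize
from scipy.special import gammaln


def tom_triple_loop(A: np.ndarray) -> np.ndarray:
    """Topological overlap by explicit summation over shared neighbours."""
    n = A.shape[0]
    k = A.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (l_ij + A[i, j]) / (min(k[i], k[j]) + 1.0 - A[i, j])
    return out


def nb_loglik_direct(y, mu, alpha):
    return float(
        np.sum(
            gammaln(y + alpha)
            - gammaln(alpha)
            - gammaln(y + 1)
            + alpha * np.log(alpha / (alpha + mu))
            + y * np.log(mu / (alpha + mu))
        )
    )


def nb_fit_brute(y: np.ndarray, g: np.ndarray):
    """Maximise the NB regression likelihood by coarse grid search followed
    by Nelder-Mead polish. Returns (beta0, beta1, alpha, loglik)."""
    y = np.asarray(y, float)
    g = np.asarray(g, float)
    X = np.column_stack([np.ones_like(g), g])

    def nll(theta):
        b0, b1, la = theta
        mu = np.exp(np.clip(X @ np.array([b0, b1]), -30, 30))
        return -nb_loglik_direct(y, mu, np.exp(la))

    best = None
    m0 = np.log(max(y[g == 0].mean(), 0.1))
    for b0 in m0 + np.linspace(-1, 1, 7):
        for b1 in np.linspace(-3, 3, 13):
            for la in np.linspace(-3, 9, 13):
                v = nll((b0, b1, la))
                if best is None or v < best[0]:
                    best = (v, (b0, b1, la))
    res = optimize.minimize(
        nll,
        best[1],
        method="Nelder-Mead",
        options={"xatol": 1e-11, "fatol": 1e-13, "maxiter": 50000, "maxfev": 50000},
    )
    b0, b1, la = res.x
    return b0, b1, float(np.exp(la)), -float(res.fun)


def bh_by_hand(p):
    """Step-up Benjamini-Hochberg computed directly from its definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        q[i] = running_min
    return np.minimum(q, 1.0)


def classify_bouts_scan(events, gap_s):
    """Bout classification by direct interval scan over every pair."""
    rows = sorted(events, key=lambda e: e[1])
    attacks = [e for e in rows if e[0] == "attack"]
    invs = [e for e in rows if e[0] == "investigation"]
    out = []
    for label, start, stop in rows:
        if label == "investigation":
            hit = any(0 <= a[1] - stop <= gap_s for a in attacks)
            out.append(
                "investigation_preceding_attack" if hit else "investigation_isolated"
            )
        elif label == "attack":
            hit = any(0 <= start - i[2] <= gap_s for i in invs)
            out.append(
                "attack_with_prior_investigation"
                if hit
                else "attack_without_prior_investigation"
            )
        else:
            out.append(label)
    return [e + (c,) for e, c in zip(rows, out)]
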