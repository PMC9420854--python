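"""Independent brute-force oracle for the pooling formulas.

Deliberately written with plain Python loops and ``math`` only, so it
shares no code path with the numpy implementation it checks.
"""

import math


def brute_force_pool(y, se):
    """Direct evaluation of the inverse-variance, Q, DL-tau2, I2 and
    random-effects formulas. Returns a dict of every pooled field."""
    k = len(y)
    w = [1.0 / s**2 for s in se]
    sw = sum(w)
    mu_fe = sum(wi * yi for wi, yi in zip(w, y)) / sw
    se_fe = sw ** -0.5
    q = sum(wi * (yi - mu_fe) ** 2 for wi, yi in zip(w, y))
    df = k - 1
    c = sw - sum(wi * wi for wi in w) / sw
    tau2 = max(0.0, (q - df) / c)
    i2 = 0.0 if q <= 0 else max(0.0, 100.0 * (q - df) / q)
    wr = [1.0 / (s**2 + tau2) for s in se]
    swr = sum(wr)
    mu_re = sum(wi * yi for wi, yi in zip(wr, y)) / swr
    se_re = swr ** -0.5
    return {
        "k": k,
        "mu_fe": mu_fe,
        "se_fe": se_fe,
        "Q": q,
        "df": df,
        "tau2": tau2,
        "i2": i2,
        "mu_re": mu_re,
        "se_re": se_re,
        "weights_fe": [wi / sw for wi in w],
        "weights_re": [wi / swr for wi in wr],
    }


def two_group_poisson_grid_mle(d_a, t_a, d_b, t_b, lo=0.01, hi=10.0, n=200_000):
    """Grid-search MLE of the rate ratio in a two-group Poisson model.

    Profiles the reference rate analytically at each candidate ratio r
    (the MLE of the reference rate given r is (d_a + d_b)/(r t_a + t_b))
    and maximizes the joint log-likelihood over a log-spaced grid.
    """
    best_r, best_ll = None, -math.inf
    log_lo, log_hi = math.log(lo), math.log(hi)
    for i in range(n):
        r = math.exp(log_lo + (log_hi - log_lo) * i / (n - 1))
        lam_b = (d_a + d_b) / (r * t_a + t_b)
        lam_a = r * lam_b
        ll = d_a * math.log(lam_a) - lam_a * t_a + d_b * math.log(lam_b) - lam_b * t_b
        if ll > best_ll:
            best_r, best_ll = r, ll
    return best_r
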