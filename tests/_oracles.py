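"""Independent oracles used by the test suite.

Everything here is deliberately naive — brute-force enumeration or
direct numerical maximization — and shares no code with the package
paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import scipy.optimize


def triplet_lookup_table(pattern: tuple[int, int, int, int]) -> dict:
    """Classify all 64 triplets by direct successor lookup."""
    nxt = {pattern[i]: pattern[(i + 1) % 4] for i in range(4)}
    out = {}
    for e1, e2, e3 in itertools.product((1, 2, 3, 4), repeat=3):
        out[(e1, e2, e3)] = {
            "high": nxt[e1] == e3,
            "trill": e1 == e3 and e1 != e2,
            "repetition": e1 == e2 == e3,
        }
    return out


def fisher_2x2_enumeration(table: np.ndarray) -> float:
    """Two-sided Fisher p for a 2x2 table by hypergeometric enumeration."""
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_p(x: int) -> float:
        return (
            math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
            + math.lgamma(r2 + 1) - math.lgamma(c1 - x + 1)
            - math.lgamma(r2 - c1 + x + 1)
            - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = log_p(a)
    return min(
        1.0,
        sum(math.exp(log_p(x)) for x in range(lo, hi + 1) if log_p(x) <= p_obs + 1e-9),
    )


def chi2_from_scratch(table: np.ndarray) -> float:
    """Sum (O-E)^2 / E with E from the margins."""
    table = np.asarray(table, float)
    e = np.outer(table.sum(1), table.sum(0)) / table.sum()
    return float((((table - e) ** 2)[e > 0] / e[e > 0]).sum())


def bruteforce_mixedlm(
    data: pd.DataFrame,
    fixed_cols: list[str],
    response: str = "median_rt_ms",
    group_col: str = "participant_id",
    slope_col: str = "epoch",
    n_starts: int = 8,
    seed: int = 0,
) -> dict:
    """ML estimation of a random-intercept + random-slope mixed model by
    direct numerical maximization of the marginal likelihood.

    The fixed effects are profiled out by GLS at each covariance
    candidate; the four covariance parameters (log SDs, atanh
    correlation, log residual SD) are optimized by Nelder-Mead from
    multiple starts.  Returns fixed-effect estimates and the maximized
    log-likelihood.
    """
    y = data[response].to_numpy(float)
    X = np.column_stack([np.ones(len(data))] + [data[c].to_numpy(float) for c in fixed_cols])
    groups = data[group_col].to_numpy()
    z_slope = data[slope_col].to_numpy(float)
    idx = [np.flatnonzero(groups == g) for g in pd.unique(groups)]

    def neg_profile_loglik(theta: np.ndarray) -> float:
        ls0, ls1, zrho, lse = theta
        s0, s1, se = math.exp(ls0), math.exp(ls1), math.exp(lse)
        rho = math.tanh(zrho)
        cov = np.array(
            [[s0**2, rho * s0 * s1], [rho * s0 * s1, s1**2]]
        )
        XtViX = np.zeros((X.shape[1], X.shape[1]))
        XtViy = np.zeros(X.shape[1])
        logdet = 0.0
        Vinvs = []
        for ii in idx:
            Z = np.column_stack([np.ones(len(ii)), z_slope[ii]])
            V = Z @ cov @ Z.T + se**2 * np.eye(len(ii))
            sign, ld = np.linalg.slogdet(V)
            if sign <= 0:
                return 1e12
            logdet += ld
            Vi = np.linalg.inv(V)
            Vinvs.append(Vi)
            XtViX += X[ii].T @ Vi @ X[ii]
            XtViy += X[ii].T @ Vi @ y[ii]
        try:
            beta = np.linalg.solve(XtViX, XtViy)
        except np.linalg.LinAlgError:
            return 1e12
        quad = 0.0
        for ii, Vi in zip(idx, Vinvs):
            r = y[ii] - X[ii] @ beta
            quad += r @ Vi @ r
        n = len(y)
        return 0.5 * (logdet + quad + n * math.log(2 * math.pi))

    rng = np.random.default_rng(seed)
    best = None
    sd_y = y.std()
    for k in range(n_starts):
        x0 = np.array(
            [
                math.log(sd_y * rng.uniform(0.2, 1.0)),
                math.log(sd_y * rng.uniform(0.02, 0.3)),
                rng.uniform(-0.5, 0.5),
                math.log(sd_y * rng.uniform(0.1, 0.8)),
            ]
        )
        res = scipy.optimize.minimize(
            neg_profile_loglik, x0, method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res

    ls0, ls1, zrho, lse = best.x
    s0, s1, se = math.exp(ls0), math.exp(ls1), math.exp(lse)
    rho = math.tanh(zrho)
    cov = np.array([[s0**2, rho * s0 * s1], [rho * s0 * s1, s1**2]])
    XtViX = np.zeros((X.shape[1], X.shape[1]))
    XtViy = np.zeros(X.shape[1])
    for ii in idx:
        Z = np.column_stack([np.ones(len(ii)), z_slope[ii]])
        V = Z @ cov @ Z.T + se**2 * np.eye(len(ii))
        Vi = np.linalg.inv(V)
        XtViX += X[ii].T @ Vi @ X[ii]
        XtViy += X[ii].T @ Vi @ y[ii]
    beta = np.linalg.solve(XtViX, XtViy)
    return {
        "beta": dict(zip(["intercept"] + fixed_cols, beta)),
        "loglik": -best.fun,
        "sd_intercept": s0,
        "sd_slope": s1,
        "rho": rho,
        "sd_resid": se,
    }
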