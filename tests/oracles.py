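"""Independent oracles used by the test suite.

Deliberately naive re-implementations (O(n²) scans, statsmodels fits) kept
separate from the package so that agreement between the two routes is
meaningful.
"""

from __future__ import annotations

import numpy as np


def wls_ivw(betas, ses):
    """Inverse-variance fixed-effect estimate via an intercept-only WLS fit."""
    import statsmodels.api as sm

    betas = np.asarray(betas, dtype=float)
    w = 1.0 / np.asarray(ses, dtype=float) ** 2
    fit = sm.WLS(betas, np.ones_like(betas), weights=w).fit()
    beta = float(fit.params[0])
    se = float(1.0 / np.sqrt(w.sum()))  # fixed-effect (known-variance) SE
    q = float((w * (betas - beta) ** 2).sum())
    return beta, se, q


def brute_force_clump(variants, r2_lookup, p_threshold, window, r2_threshold):
    """Exhaustive restatement of the greedy clumping rule.

    ``variants``: list of dicts with keys id, chrom, pos, ref, alt, p.
    Returns a list of (index_id, sorted member ids) in formation order.
    """
    qualifying = {v["id"]: v for v in variants if v["p"] < p_threshold}
    clumps = []
    while qualifying:
        # lowest p; ties by chromosome, position, alleles
        index = min(
            qualifying.values(),
            key=lambda v: (v["p"], _chrom_key(v["chrom"]), v["pos"], v["ref"], v["alt"]),
        )
        members = []
        for v in list(qualifying.values()):
            if abs(v["pos"] - index["pos"]) > window:
                continue
            if v["id"] != index["id"] and r2_lookup(index["id"], v["id"]) <= r2_threshold:
                continue
            members.append(v["id"])
            del qualifying[v["id"]]
        clumps.append((index["id"], sorted(members)))
    return clumps


def _chrom_key(c):
    c = str(c)
    return (0, int(c)) if c.isdigit() else (1, c)


def dersimonian_laird(betas, ses):
    """Closed-form DerSimonian–Laird random-effects estimate."""
    b = np.asarray(betas, dtype=float)
    se = np.asarray(ses, dtype=float)
    w = 1.0 / se**2
    fixed = (w * b).sum() / w.sum()
    q = (w * (b - fixed) ** 2).sum()
    df = len(b) - 1
    c = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - df) / c)
    w_star = 1.0 / (se**2 + tau2)
    return (w_star * b).sum() / w_star.sum(), 1.0 / np.sqrt(w_star.sum()), tau2
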