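"""Independent reference implementations used to cross-check the package.

Each oracle deliberately takes a different computational route from the
code under test: the IVW oracle goes through a statsmodels weighted
regression through the origin rather than the closed-form sums; the
clumping oracle is a filter-and-recurse enumeration over row dicts
rather than an index loop; the Egger oracle solves the weighted normal
equations explicitly.
"""

import numpy as np
import statsmodels.api as sm


def ivw_oracle(bx, by, sey):
    """Weighted regression of by on bx through the origin, weights 1/sey^2.

    Returns (beta, fixed_se, mre_se_floored).
    """
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    w = 1.0 / np.asarray(sey, float) ** 2
    res = sm.WLS(by, bx[:, None], weights=w).fit()
    beta = float(res.params[0])
    # normalized_cov_params is (X'WX)^-1: fixed-effect variance with scale 1
    var_fixed = float(res.normalized_cov_params[0, 0])
    se_fixed = np.sqrt(var_fixed)
    scale = float(res.scale)  # residual variance estimate = Q/(J-1)
    se_mre = se_fixed * np.sqrt(max(1.0, scale))
    return beta, se_fixed, se_mre


def egger_oracle(bx, by, sey):
    """Weighted least squares with intercept via explicit normal equations.

    Pairs are oriented so bx >= 0 first.  Returns (intercept, slope,
    se_intercept, se_slope) with the residual scale floored at 1.
    """
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sey = np.asarray(sey, float)
    sign = np.where(bx < 0, -1.0, 1.0)
    x, y = bx * sign, by * sign
    w = 1.0 / sey ** 2
    X = np.column_stack([np.ones_like(x), x])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * y)
    params = np.linalg.solve(xtwx, xtwy)
    resid = y - X @ params
    scale = float(resid @ (w * resid)) / (len(x) - 2)
    cov = np.linalg.inv(xtwx) * max(1.0, scale)
    se = np.sqrt(np.diag(cov))
    return params[0], params[1], se[0], se[1]


def clump_oracle(rows, r2_lookup, clump_r2, window_kb):
    """Greedy-by-p elimination, enumerated over plain row dicts.

    ``rows``: iterable of dicts with variant_id, chrom, pos, pval.
    ``r2_lookup``: callable (id_a, id_b) -> r2.
    Returns the retained variant ids in selection order.
    """
    pool = sorted(rows, key=lambda r: (r["pval"], r["variant_id"]))
    kept = []
    while pool:
        index, pool = pool[0], pool[1:]
        kept.append(index["variant_id"])

        def independent(r):
            if r["chrom"] != index["chrom"]:
                return True
            if abs(r["pos"] - index["pos"]) > window_kb * 1000.0:
                return True
            r2 = 1.0 if r["variant_id"] == index["variant_id"] else r2_lookup(
                index["variant_id"], r["variant_id"])
            return r2 < clump_r2

        pool = [r for r in pool if independent(r)]
    return kept


def random_ld_blocks(rng, ids, block_r2_range=(0.0, 1.0), n_blocks=5):
    """Random block-structured r2 lookup over the given ids."""
    assignment = {v: int(rng.integers(n_blocks)) for v in ids}
    block_r2 = {b: float(rng.uniform(*block_r2_range)) for b in range(n_blocks)}

    def lookup(a, b):
        if a == b:
            return 1.0
        if assignment.get(a) == assignment.get(b):
            return block_r2[assignment[a]]
        return 0.0

    return lookup, assignment
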