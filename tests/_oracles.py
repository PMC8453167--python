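"""Independent reference implementations used only to check the package.

Each oracle is deliberately naive — dense linear algebra, explicit loops,
textbook formulas — and shares no code with the implementation it checks.
"""

import numpy as np
from scipy import stats
from scipy.optimize import minimize


def reml_mixed_oracle(y, design):
    """Numeric REML fit of the random-intercept model with race*tissue fixed
    effects; returns per-contrast estimate/se/t/p plus variance components.

    The fixed part uses cell-mean coding over the four (race, tissue) cells;
    the covariance is sigma2*I + omega2*Z Z' with Z the patient indicator.
    The REML criterion is maximised numerically over the log variances, and
    contrasts are tested on t with residual df N - 2.
    """
    t = design.table
    y = np.asarray(y, dtype=float)
    cells = [("AA", "tumor"), ("AA", "adjacent"), ("EA", "tumor"), ("EA", "adjacent")]
    X = np.column_stack(
        [
            ((t["race"] == r) & (t["tissue"] == k)).to_numpy(dtype=float)
            for r, k in cells
        ]
    )
    patients = t["patient_id"].drop_duplicates().tolist()
    Z = np.column_stack(
        [(t["patient_id"] == p).to_numpy(dtype=float) for p in patients]
    )
    n = len(y)
    N = len(patients)

    def neg_reml(params):
        s2, o2 = np.exp(params)
        V = s2 * np.eye(n) + o2 * (Z @ Z.T)
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        r = y - X @ beta
        _, ld_v = np.linalg.slogdet(V)
        _, ld_x = np.linalg.slogdet(XtViX)
        return 0.5 * (ld_v + ld_x + r @ Vi @ r)

    best = None
    for start in ([0.0, 0.0], [np.log(np.var(y) + 1e-3), -2.0], [-2.0, 0.0]):
        res = minimize(neg_reml, start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    s2, o2 = np.exp(best.x)
    V = s2 * np.eye(n) + o2 * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    cov = np.linalg.inv(XtViX)
    beta = cov @ X.T @ Vi @ y

    contrasts = {
        "AA": np.array([1.0, -1.0, 0.0, 0.0]),
        "EA": np.array([0.0, 0.0, 1.0, -1.0]),
        "ALL": np.array([0.5, -0.5, 0.5, -0.5]),
    }
    df = N - 2
    out = {"sigma2": s2, "omega2": o2}
    for name, c in contrasts.items():
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        tval = est / se
        out[name] = {
            "estimate": est,
            "se": se,
            "t": tval,
            "p": float(2 * stats.t.sf(abs(tval), df)),
        }
    return out


def naive_tmm_factors(counts, trim_m=0.30, trim_a=0.05):
    """Loop-based TMM factors: explicit sorting, trimming and weighting."""
    counts = np.asarray(counts, dtype=float)
    libs = counts.sum(axis=0)
    f75 = np.array([np.quantile(counts[:, j], 0.75) / libs[j]
                    for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    log_f = []
    for j in range(counts.shape[1]):
        if j == ref:
            log_f.append(0.0)
            continue
        rows = [
            g
            for g in range(counts.shape[0])
            if counts[g, j] > 0 and counts[g, ref] > 0
        ]
        m = [np.log2((counts[g, j] / libs[j]) / (counts[g, ref] / libs[ref]))
             for g in rows]
        a = [0.5 * np.log2((counts[g, j] / libs[j]) * (counts[g, ref] / libs[ref]))
             for g in rows]
        w = [
            (libs[j] - counts[g, j]) / (libs[j] * counts[g, j])
            + (libs[ref] - counts[g, ref]) / (libs[ref] * counts[g, ref])
            for g in rows
        ]
        n = len(rows)
        rank = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        num = den = 0.0
        for i in range(n):
            if lo_m <= rank[i] <= hi_m and lo_a <= rank_a[i] <= hi_a:
                num += m[i] / w[i]
                den += 1.0 / w[i]
        log_f.append(num / den if den > 0 else 0.0)
    log_f = np.array(log_f)
    log_f -= log_f.mean()
    return 2.0 ** log_f, ref


def naive_bh(p):
    """Textbook step-up BH by explicit sorting."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        prev = min(prev, p[i] * n / rank_from_top)
        q[i] = prev
    return q


def textbook_pearson(x, y):
    """Pearson r via the raw sum formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    num = n * np.sum(x * y) - np.sum(x) * np.sum(y)
    den = np.sqrt(n * np.sum(x * x) - np.sum(x) ** 2) * np.sqrt(
        n * np.sum(y * y) - np.sum(y) ** 2
    )
    return num / den
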