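"""Mediation analysis with the joint-significance rule, the serial
recursive path model, and a bootstrap companion for the indirect
effect.

All variables are standardized before regression, so coefficients are
standardized path weights and the identity c = c' + a*b holds exactly
on complete data. The mediation verdict follows the joint-significance
rule: M mediates X -> Y when max(p(a), p(b)) < 0.05 and the direct path
shrinks once the mediator is accounted for (|c'| < |c|; absolute values
because paths may be negative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

ALPHA = 0.05


@dataclass(frozen=True)
class MediationResult:
    a: float
    b: float
    c: float
    c_prime: float
    p_a: float
    p_b: float
    p_c: float
    p_c_prime: float
    mediation_p: float
    significant: bool
    n: int


@dataclass(frozen=True)
class PathModelResult:
    edges: dict          # edge name -> standardized coefficient
    p_values: dict
    r_squared: dict      # endogenous node -> R^2
    n: int


def _standardize(*arrays):
    cols = [np.asarray(a, dtype=float) for a in arrays]
    ok = np.ones(len(cols[0]), dtype=bool)
    for c in cols:
        ok &= np.isfinite(c)
    out = []
    for c in cols:
        v = c[ok]
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError("zero-variance variable")
        out.append((v - v.mean()) / sd)
    return out


def _ols(y, X):
    res = sm.OLS(y, sm.add_constant(np.column_stack(X))).fit()
    return res.params[1:], res.pvalues[1:], res.rsquared


def simple_mediation(X, M, Y) -> MediationResult:
    """Test whether M mediates X -> Y.

    Paths: a from M ~ X; b and c' from Y ~ X + M; c from Y ~ X.
    ``mediation_p`` is max(p(a), p(b)) (joint significance); the
    verdict additionally requires |c'| < |c|.
    """
    x, m, y = _standardize(X, M, Y)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 complete cases")
    if abs(np.corrcoef(x, m)[0, 1]) > 0.999:
        raise ValueError("X and M are (near-)collinear")
    (a,), (p_a,), _ = _ols(m, [x])
    (c_prime, b), (p_cp, p_b), _ = _ols(y, [x, m])
    (c,), (p_c,), _ = _ols(y, [x])
    mediation_p = max(p_a, p_b)
    significant = bool(mediation_p < ALPHA and abs(c_prime) < abs(c))
    return MediationResult(
        a=float(a), b=float(b), c=float(c), c_prime=float(c_prime),
        p_a=float(p_a), p_b=float(p_b), p_c=float(p_c),
        p_c_prime=float(p_cp), mediation_p=float(mediation_p),
        significant=significant, n=n,
    )


def serial_path_model(X1, X2, X3, Y,
                      names: tuple[str, str, str, str] = ("x1", "x2", "x3", "y")
                      ) -> PathModelResult:
    """Recursive serial path model X1 -> X2 -> X3 -> Y.

    Estimated as the sequence of regressions X2 ~ X1; X3 ~ X1 + X2;
    Y ~ X1 + X2 + X3 on standardized complete cases — exact for this
    just-identified recursive system — with R^2 per endogenous node.
    """
    x1, x2, x3, y = _standardize(X1, X2, X3, Y)
    n = len(x1)
    if n < 10:
        raise ValueError("need at least 10 complete cases")
    n1, n2, n3, ny = names
    edges, pvals, r2 = {}, {}, {}
    for target, zt, preds in ((n2, x2, [(n1, x1)]),
                              (n3, x3, [(n1, x1), (n2, x2)]),
                              (ny, y, [(n1, x1), (n2, x2), (n3, x3)])):
        coefs, ps, rsq = _ols(zt, [p for _, p in preds])
        for (pname, _), coef, p in zip(preds, coefs, ps):
            edges[f"{target}~{pname}"] = float(coef)
            pvals[f"{target}~{pname}"] = float(p)
        r2[target] = float(rsq)
    return PathModelResult(edges=edges, p_values=pvals, r_squared=r2, n=n)


def bootstrap_indirect(X, M, Y, n_boot: int = 2000, seed: int = 0,
                       ci: float = 0.95) -> dict:
    """Percentile bootstrap CI for the indirect effect a*b (a
    robustness companion to the joint-significance verdict)."""
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    x, m, y = _standardize(X, M, Y)
    n = len(x)
    rng = np.random.default_rng(seed)
    ab = np.empty(n_boot)
    skipped = 0
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xs, ms, ys = x[idx], m[idx], y[idx]
        if xs.std() == 0 or ms.std() == 0 or ys.std() == 0:
            ab[i] = np.nan
            skipped += 1
            continue
        # closed-form OLS on the resample (standardized inputs)
        a = np.polyfit(xs, ms, 1)[0]
        Z = np.column_stack([np.ones(n), xs, ms])
        beta = np.linalg.lstsq(Z, ys, rcond=None)[0]
        ab[i] = a * beta[2]
    lo, hi = np.nanpercentile(ab, [100 * (1 - ci) / 2, 100 * (1 + ci) / 2])
    point = simple_mediation(X, M, Y)
    return {"indirect": point.a * point.b, "ci": (float(lo), float(hi)),
            "level": ci, "n_boot": n_boot, "skipped": skipped}
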