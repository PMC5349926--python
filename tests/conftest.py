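"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive results through different algorithmic
routes than the package (NIPALS power iteration instead of SVD-based sparse
PLS; brute-force enumeration instead of scipy's rank-sum machinery) so that
agreement is evidence, not circularity.
"""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from mirisk import SimulationParams, simulate_tissue_cohort


def dense_pls2_oracle(Xs: np.ndarray, Ys: np.ndarray, ncomp: int):
    """Classical dense PLS2 via NIPALS power iteration on pre-scaled data.

    Returns (W, P, D): x-weights, x-loadings, y-loadings, one column per
    component. Independent of the package's SVD-based implementation.
    """
    Xh, Yh = Xs.copy(), Ys.copy()
    Ws, Ps, Ds = [], [], []
    for _ in range(ncomp):
        u = Yh[:, [0]]
        w_old = None
        for _ in range(5000):
            w = Xh.T @ u
            w /= np.linalg.norm(w)
            t = Xh @ w
            q = Yh.T @ t
            q /= np.linalg.norm(q)
            u = Yh @ q
            if w_old is not None and np.linalg.norm(w - w_old) < 1e-13:
                break
            w_old = w
        t = Xh @ w
        tt = float((t.T @ t).item())
        c = Xh.T @ t / tt
        d = Yh.T @ t / tt
        Xh = Xh - t @ c.T
        Yh = Yh - t @ d.T
        Ws.append(w)
        Ps.append(c)
        Ds.append(d)
    return np.hstack(Ws), np.hstack(Ps), np.hstack(Ds)


def scale_xy(X: np.ndarray, y, positive_class: str):
    """Center/unit-variance X and the dummy response exactly as the fit does."""
    y = np.asarray(list(y))
    classes = sorted(set(y))
    neg = next(c for c in classes if c != positive_class)
    Y = np.column_stack([(y == neg).astype(float), (y == positive_class).astype(float)])
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    Ys = (Y - Y.mean(0)) / Y.std(0, ddof=1)
    return Xs, Ys, Y


def mannwhitney_exact_oracle(x, y) -> float:
    """Two-sided exact rank-sum p by full enumeration of group assignments.

    Valid for untied data; p = fraction of assignments whose U deviates from
    its null mean at least as much as the observed U.
    """
    x, y = list(x), list(y)
    pooled = x + y
    n1, n = len(x), len(x) + len(y)
    mid = n1 * len(y) / 2.0
    all_idx = set(range(n))

    def ustat(idx):
        rest = all_idx - set(idx)
        return sum(1 for i in idx for j in rest if pooled[i] > pooled[j])

    obs_dev = abs(ustat(tuple(range(n1))) - mid)
    devs = [abs(ustat(idx) - mid) for idx in combinations(range(n), n1)]
    return sum(d >= obs_dev - 1e-12 for d in devs) / len(devs)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact tissue cohort with strong planted signal (shared, read-only)."""
    params = SimulationParams(
        n_probes=120, n_negative_controls=6, n_positive_controls=6,
        group_sizes={"low": 30, "high": 15}, n_informative=8, seed=11,
    )
    return simulate_tissue_cohort(params)


@pytest.fixture()
def toy_matrix():
    """4 probes x 4 samples integer matrix with one low-expressed probe."""
    from mirisk import ExpressionMatrix

    values = pd.DataFrame(
        {
            "s1": [5, 8, 0, 3],
            "s2": [6, 9, 0, 4],
            "s3": [7, 10, 2, 5],
            "s4": [8, 11, 2, 6],
        },
        index=["p1", "p2", "p3", "p4"],
    )
    return ExpressionMatrix(values, state="raw")
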