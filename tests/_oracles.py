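"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the implementation's code paths: pairwise loops
instead of site-frequency vectorisation, explicit harmonic sums, explicit
tree traversals.  They are only ever run on tiny instances.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd


def pi_pairwise(matrix: pd.DataFrame) -> float:
    """Mean pairwise Hamming distance with per-site pairwise deletion,
    summed per-site as differing-pair fraction."""
    values = matrix.to_numpy(dtype=float)
    n_sites = values.shape[1]
    total = 0.0
    for s in range(n_sites):
        col = values[:, s]
        pairs = diff = 0
        for i, j in itertools.combinations(range(len(col)), 2):
            if math.isnan(col[i]) or math.isnan(col[j]):
                continue
            pairs += 1
            if col[i] != col[j]:
                diff += 1
        if pairs:
            total += diff / pairs
    return total


def tajimas_d_textbook(matrix: pd.DataFrame) -> float:
    """Tajima's D from explicit pairwise differences and harmonic numbers."""
    values = matrix.to_numpy(dtype=float)
    n = values.shape[0]
    seg = 0
    for s in range(values.shape[1]):
        col = values[:, s][~np.isnan(values[:, s])]
        if len(col) >= 2 and 0 < col.sum() < len(col):
            seg += 1
    theta_pi = pi_pairwise(matrix)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    theta_w = seg / a1
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * seg + e2 * seg * (seg - 1)
    return (theta_pi - theta_w) / math.sqrt(var)


def fay_wu_h_direct(matrix: pd.DataFrame) -> float:
    """H = θ_π − θ_H by direct per-site summation over derived counts."""
    values = matrix.to_numpy(dtype=float)
    theta_h = 0.0
    for s in range(values.shape[1]):
        col = values[:, s][~np.isnan(values[:, s])]
        n_s = len(col)
        x = col.sum()
        if n_s >= 2 and 0 < x < n_s:
            theta_h += 2.0 * x * x / (n_s * (n_s - 1))
    return pi_pairwise(matrix) - theta_h


def random_binary_matrix(
    rng: np.random.Generator,
    n_lineages: int,
    n_sites: int,
    missing_frac: float = 0.0,
) -> pd.DataFrame:
    """Random segregating binary matrix (at least one 0 and one 1 per site)."""
    cols = {}
    for s in range(n_sites):
        while True:
            col = rng.integers(0, 2, size=n_lineages).astype(float)
            if missing_frac > 0:
                col[rng.random(n_lineages) < missing_frac] = np.nan
            obs = col[~np.isnan(col)]
            if len(obs) >= 2 and 0 < obs.sum() < len(obs):
                break
        cols[f"v{s}"] = col
    return pd.DataFrame(cols, index=[f"L{i}" for i in range(n_lineages)])


def decay_by_tree_traversal(tree, threshold: float) -> float:
    """Ground-truth Σ f·n by exhaustive traversal, independent of the
    implementation's bookkeeping: recompute each branch's carrier set from
    tip labels."""
    tips = {t.label for t in tree.tips()}
    n = len(tips)
    total = 0.0
    for node in tree.nodes():
        if node.is_tip:
            continue
        carriers = len(set(tree.tip_labels_under(node)))
        vaf = 0.5 * (carriers / n)
        if vaf >= threshold:
            total += vaf * len(node.mutations)
    return total


def loo_refit_oracle(ages, lams):
    """Hand-rolled leave-one-out loop using closed-form log-scale OLS."""
    ages = np.asarray(ages, dtype=float)
    lams = np.asarray(lams, dtype=float)
    preds = []
    for i in range(len(ages)):
        keep = np.ones(len(ages), dtype=bool)
        keep[i] = False
        x, y = ages[keep], np.log(lams[keep])
        b = np.cov(x, y, bias=True)[0, 1] / np.var(x)
        a = y.mean() - b * x.mean()
        preds.append((math.log(lams[i]) - a) / b)
    return np.array(preds)
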