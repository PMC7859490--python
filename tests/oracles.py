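"""Independent brute-force oracles used to validate the implementation.

Each oracle takes a route deliberately different from the package code:
exact rational arithmetic for the Hardy-Weinberg test, recursive coancestry
for the pedigree relationship matrix, dense joint GLS for the mixed-model
equations, and grid search for the REML ratio.
"""

from fractions import Fraction
from functools import lru_cache
from math import comb

import numpy as np


def hwe_exact_oracle(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact-rational two-sided HWE p-value by full enumeration.

    Conditional on allele counts, P(h heterozygotes) =
    (N! / (n_AA! h! n_aa!)) 2^h / C(2N, R) ... computed as exact integer
    'ways' so the comparison with the observed configuration is exact.
    """
    n = n_het + n_hom1 + n_hom2
    rare = 2 * min(n_hom1, n_hom2) + n_het
    common = 2 * n - rare
    if rare == 0:
        return 1.0

    def ways(h: int) -> int:
        n_aa = (rare - h) // 2
        n_bb = n - h - n_aa
        if n_aa < 0 or n_bb < 0:
            return 0
        # multinomial N! / (n_bb! h! n_aa!) * 2^h
        return comb(n, h) * comb(n - h, n_aa) * 2**h

    hs = list(range(rare % 2, min(rare, common) + 1, 2))
    all_ways = {h: ways(h) for h in hs}
    total = sum(all_ways.values())
    obs = all_ways[n_het]
    p = Fraction(sum(w for w in all_ways.values() if w <= obs), total)
    return float(min(p, Fraction(1)))


def kinship_oracle(pedigree_table) -> np.ndarray:
    """A = 2 * coancestry by the recursive definition (memoised)."""
    ids = list(pedigree_table["animal_id"])
    idx = {a: i for i, a in enumerate(ids)}
    sire = [idx.get(s, -1) for s in pedigree_table["sire_id"]]
    dam = [idx.get(d, -1) for d in pedigree_table["dam_id"]]

    @lru_cache(maxsize=None)
    def f(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        if i > j:
            i, j = j, i
        if i == j:
            return 0.5 * (1.0 + f(sire[i], dam[i]))
        # j is the later animal: recurse through j's parents
        return 0.5 * (f(i, sire[j]) + f(i, dam[j]))

    n = len(ids)
    a = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            a[i, j] = a[j, i] = 2.0 * f(i, j)
    return a


def mme_gls_oracle(y, X, Z, K, lam):
    """Joint GLS closed form for Henderson's equations.

    With V* = Z K Z' / lam + I (V scaled by sigma_e^2):
    b = (X' V*^-1 X)^-1 X' V*^-1 y and u = K Z' V*^-1 (y - X b) / lam.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    K = np.asarray(K, float)
    vstar = Z @ K @ Z.T / lam + np.eye(len(y))
    vinv = np.linalg.inv(vstar)
    b = np.linalg.solve(X.T @ vinv @ X, X.T @ vinv @ y)
    u = K @ Z.T @ vinv @ (y - X @ b) / lam
    return b, u


def reml_grid_oracle(model, n_grid: int = 1000, lo: float = -6.0, hi: float = 6.0):
    """Arg-max of the profiled REML log-likelihood on a dense log-ratio grid."""
    grid = np.linspace(lo, hi, n_grid)
    lls = np.array([model.reml_loglik(t) for t in grid])
    return grid[int(np.argmax(lls))], grid[1] - grid[0]


def prune_oracle(dosages, r2_max: float) -> int:
    """Minimum removals so that no retained pair exceeds r2_max, by
    exhaustive greedy over all pairs (valid for tiny single-window panels):
    returns the number of markers that must be removed when duplicates form
    cliques (clique size - 1 per clique)."""
    m = dosages.shape[1]
    x = dosages.astype(float)
    r = np.corrcoef(x, rowvar=False) ** 2
    # connected components of the "too correlated" graph
    adj = r > r2_max
    np.fill_diagonal(adj, False)
    seen = np.zeros(m, dtype=bool)
    removals = 0
    for s in range(m):
        if seen[s]:
            continue
        stack, comp = [s], []
        seen[s] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for w in np.flatnonzero(adj[v]):
                if not seen[w]:
                    seen[w] = True
                    stack.append(w)
        if len(comp) > 1:
            removals += len(comp) - 1
    return removals
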