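"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive quantities from their defining
formulas (brute-force counting, union-find, step-up recursion,
exhaustive enumeration) so the package's optimized paths are checked
against something that cannot share their bugs.
"""

import math

import numpy as np
import pandas as pd
import pytest


# ---------------------------------------------------------------------------
# oracles


def brute_force_condfdr(p1, p2):
    """condFDR by literal O(n^2) counting of the defining fractions."""
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    n = len(p1)
    out = np.empty(n)
    for lo in range(0, n, 256):
        hi = min(lo + 256, n)
        d = (p2[None, :] <= p2[lo:hi, None]).sum(axis=1)
        m = ((p1[None, :] <= p1[lo:hi, None]) & (p2[None, :] <= p2[lo:hi, None])).sum(axis=1)
        out[lo:hi] = p1[lo:hi] * d / m
    return np.minimum(out, 1.0)


class UnionFind:
    """Minimal disjoint-set forest used as the component oracle."""

    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def components(self):
        groups = {}
        for x in self.parent:
            groups.setdefault(self.find(x), set()).add(x)
        return {frozenset(g) for g in groups.values()}


def components_oracle(variants, edges):
    """Connected components via union-find over (a, b) edge tuples."""
    uf = UnionFind(list(variants))
    for a, b in edges:
        if a in uf.parent and b in uf.parent:
            uf.union(a, b)
    return uf.components()


def bh_stepup_oracle(p):
    """BH adjusted values from the step-up definition, literally."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * n / np.arange(1, n + 1)
    for i in range(n - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    q_sorted = np.minimum(q_sorted, 1.0)
    out = np.empty(n)
    out[order] = q_sorted
    return out


def welch_oracle(x, y):
    """Welch t statistic and two-sided p from the textbook formulas."""
    from scipy.stats import t as tdist

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, 2 * tdist.sf(abs(t), df)


def hypergeom_enumeration_oracle(M, K, n, k):
    """P(X >= k) for overlap of a size-n draw with a size-K set in M."""
    total = math.comb(M, n)
    return sum(math.comb(K, j) * math.comb(M - K, n - j) for j in range(k, min(K, n) + 1)) / total


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture()
def small_paired():
    """The four-variant worked condFDR example."""
    return pd.DataFrame(
        {
            "snp": list("ABCD"),
            "p1": [0.02, 0.001, 0.5, 0.9],
            "p2": [0.005, 0.5, 0.4, 0.8],
        }
    )


@pytest.fixture()
def paired_from_simulation():
    """Factory: simulate a paired dataset and run it through read/harmonize."""
    from crosstrait import harmonize_pair, read_sumstats, simulate_sumstats_pair

    def _make(tmp_path, n_variants=3000, seed=0, **kw):
        s1, s2, ld, truth = simulate_sumstats_pair(n_variants=n_variants, seed=seed, **kw)
        p1 = tmp_path / "s1.tsv"
        p2 = tmp_path / "s2.tsv"
        s1.to_csv(p1, sep="\t", index=False)
        s2.to_csv(p2, sep="\t", index=False)
        cm = {"snp": "SNP", "chrom": "CHR", "pos": "BP",
              "a1": "A1", "a2": "A2", "z": "Z", "p": "P"}
        paired = harmonize_pair(read_sumstats(p1, cm), read_sumstats(p2, cm))
        return paired, ld, truth

    return _make
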