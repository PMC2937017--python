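"""Pairwise association of binary aberration calls.

The parametric path is a score test on the 2x2 contingency table: the signed
square root of the Pearson chi-square statistic, referenced to a standard
normal, with Benjamini-Hochberg correction across all testable pairs.  The
permutation path shuffles every matrix column independently (preserving column
sums), recomputes |z| for every admissible pair, and estimates a false
discovery rate from the average number of null exceedances at each observed
statistic.  Positive z means co-occurrence, negative z mutual exclusivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ContingencyCounts:
    n11: int  # both aberrant
    n10: int  # A only
    n01: int  # B only
    n00: int  # neither

    def __post_init__(self):
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def nA(self) -> int:
        return self.n11 + self.n10

    @property
    def nB(self) -> int:
        return self.n11 + self.n01

    @classmethod
    def from_columns(cls, a: np.ndarray, b: np.ndarray) -> "ContingencyCounts":
        a = np.asarray(a).astype(bool)
        b = np.asarray(b).astype(bool)
        return cls(
            n11=int(np.sum(a & b)),
            n10=int(np.sum(a & ~b)),
            n01=int(np.sum(~a & b)),
            n00=int(np.sum(~a & ~b)),
        )

    def testable(self) -> bool:
        return 0 < self.nA < self.n and 0 < self.nB < self.n


@dataclass
class PairAssociation:
    i: int
    j: int
    counts: ContingencyCounts
    z: float
    p: float
    testable: bool
    q: float = np.nan
    perm_p: float = np.nan
    perm_fdr: float = np.nan

    @property
    def direction(self) -> str:
        return "positive" if self.z >= 0 else "negative"


@dataclass(frozen=True)
class PermutationPlan:
    B: int = 1000
    seed: int | None = None
    chunk: int = 200

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("need at least one permutation")


def score_test(counts: ContingencyCounts) -> tuple[float, float]:
    """Signed square root of the 2x2 Pearson chi-square (no continuity
    correction), with a two-sided standard-normal p-value.

    Raises on degenerate margins (an all-zero or all-one column), for which
    the statistic is undefined.
    """
    if not counts.testable():
        raise ValueError(
            "degenerate margin: pair is untestable "
            f"(nA={counts.nA}, nB={counts.nB}, n={counts.n})"
        )
    n, nA, nB = counts.n, counts.nA, counts.nB
    delta = counts.n11 * n - nA * nB
    denom = np.sqrt(float(nA) * nB * (n - nA) * (n - nB))
    z = np.sqrt(n) * delta / denom
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def expected_cooccurrence(freq_a: float, freq_b: float) -> float:
    """Expected doubly-aberrant fraction under independence."""
    if not (0 <= freq_a <= 1 and 0 <= freq_b <= 1):
        raise ValueError("frequencies must lie in [0, 1]")
    return freq_a * freq_b


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, monotone, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _as_array(X) -> np.ndarray:
    if hasattr(X, "X"):
        X = X.X
    X = np.asarray(X)
    if X.ndim != 2 or not np.isin(X, (0, 1)).all():
        raise ValueError("X must be a binary 2-D matrix")
    return X.astype(np.int64)


def _all_index_pairs(k: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(k) for j in range(i + 1, k)]


def all_pairs(
    X, pairs: Sequence[tuple[int, int]] | None = None
) -> list[PairAssociation]:
    """Score test per admissible pair, BH-corrected jointly over the testable
    pairs (positive and negative directions together), sorted by (q, -|z|)."""
    Xa = _as_array(X)
    n, k = Xa.shape
    if pairs is None:
        pairs = _all_index_pairs(k)
    results: list[PairAssociation] = []
    for i, j in pairs:
        counts = ContingencyCounts.from_columns(Xa[:, i], Xa[:, j])
        if counts.testable():
            z, p = score_test(counts)
            results.append(PairAssociation(i, j, counts, z, p, testable=True))
        else:
            results.append(
                PairAssociation(i, j, counts, np.nan, np.nan, testable=False)
            )
    testable = [r for r in results if r.testable]
    if testable:
        q = bh_adjust([r.p for r in testable])
        for r, qv in zip(testable, q):
            r.q = float(qv)
    results.sort(
        key=lambda r: (
            r.q if np.isfinite(r.q) else np.inf,
            -abs(r.z) if np.isfinite(r.z) else 0.0,
        )
    )
    return results


def _pair_z_matrix(
    Xp: np.ndarray, pair_idx: tuple[np.ndarray, np.ndarray], colsums: np.ndarray
) -> np.ndarray:
    """|z| for every admissible pair across a block of permuted matrices.

    Xp has shape (b, n, k); column sums are invariant under the permutation,
    so z is an affine function of the pairwise co-occurrence counts.
    """
    b, n, _ = Xp.shape
    C = np.einsum("bnk,bnl->bkl", Xp, Xp)
    n11 = C[:, pair_idx[0], pair_idx[1]].astype(float)
    nA = colsums[pair_idx[0]].astype(float)
    nB = colsums[pair_idx[1]].astype(float)
    denom = np.sqrt(nA * nB * (n - nA) * (n - nB))
    return np.abs(np.sqrt(n) * (n11 * n - nA * nB) / denom)


def permutation_test(
    X,
    pairs: Sequence[tuple[int, int]] | None = None,
    plan: PermutationPlan | None = None,
    results: Sequence[PairAssociation] | None = None,
) -> list[PairAssociation]:
    """Monte Carlo column-permutation test.

    Each permutation shuffles every column of X independently, keeping column
    sums fixed; |z| is recomputed for every admissible pair.  Per pair,
    perm_p = (1 + #{b : |z_b| >= |z_obs|}) / (B + 1).  The FDR at each
    observed |z| is the average number of permuted pairs at or above it,
    divided by the number of observed pairs at or above it (enforced monotone
    in |z|, capped at 1).  Untestable pairs are skipped exactly as in the
    parametric path.
    """
    plan = plan or PermutationPlan()
    Xa = _as_array(X)
    n, k = Xa.shape
    if results is None:
        results = all_pairs(Xa, pairs)
    testable = [r for r in results if r.testable]
    if not testable:
        return list(results)
    obs = np.array([abs(r.z) for r in testable])
    pair_i = np.array([r.i for r in testable])
    pair_j = np.array([r.j for r in testable])
    colsums = Xa.sum(axis=0)
    rng = np.random.default_rng(plan.seed)
    Xf = Xa.astype(float)
    exceed_own = np.zeros(len(testable), dtype=np.int64)
    null_pool: list[np.ndarray] = []
    done = 0
    while done < plan.B:
        b = min(plan.chunk, plan.B - done)
        keys = rng.random((b, n, k))
        order = np.argsort(keys, axis=1)
        Xp = np.take_along_axis(np.broadcast_to(Xf, (b, n, k)), order, axis=1)
        z_null = _pair_z_matrix(Xp, (pair_i, pair_j), colsums)
        exceed_own += (z_null >= obs[None, :]).sum(axis=0)
        null_pool.append(z_null.ravel())
        done += b
    perm_p = (1.0 + exceed_own) / (plan.B + 1.0)
    pooled = np.sort(np.concatenate(null_pool))
    # expected null exceedances at each observed |z|, averaged over permutations
    expected = (pooled.size - np.searchsorted(pooled, obs, side="left")) / plan.B
    observed_at = np.array([(obs >= t).sum() for t in obs], dtype=float)
    raw_fdr = np.minimum(expected / observed_at, 1.0)
    # q-value construction: each pair gets the best estimate among thresholds
    # it survives, i.e. a cumulative min over ascending |z|
    order = np.argsort(obs, kind="mergesort")
    fdr = np.empty_like(raw_fdr)
    fdr[order] = np.minimum.accumulate(raw_fdr[order])
    for r, pp, fd in zip(testable, perm_p, fdr):
        r.perm_p = float(pp)
        r.perm_fdr = float(fd)
    return list(results)


def select(
    results: Iterable[PairAssociation], fdr: float = 0.05, method: str = "parametric"
) -> list[PairAssociation]:
    """Pairs significant at the FDR threshold under one of the two paths."""
    if method == "parametric":
        return [r for r in results if r.testable and r.q <= fdr]
    if method == "permutation":
        return [r for r in results if r.testable and r.perm_fdr <= fdr]
    raise ValueError("method must be 'parametric' or 'permutation'")


def replicate(
    results_test: Sequence[PairAssociation],
    results_validation: Sequence[PairAssociation],
    fdr: float = 0.05,
    method: str = "parametric",
    labels_test: Sequence[str] | None = None,
    labels_validation: Sequence[str] | None = None,
) -> list[tuple[int, int, str]]:
    """Pairs significant in BOTH result sets at the FDR threshold with the
    same direction, as (i, j, direction) tuples."""
    if labels_test is not None and labels_validation is not None:
        if list(labels_test) != list(labels_validation):
            raise ValueError("mismatched region universes between cohorts")
    sel_test = {
        (r.i, r.j): r.direction for r in select(results_test, fdr, method)
    }
    sel_val = {
        (r.i, r.j): r.direction for r in select(results_validation, fdr, method)
    }
    common = []
    for pair, direction in sel_test.items():
        if sel_val.get(pair) == direction:
            common.append((pair[0], pair[1], direction))
    return sorted(common)


def method_agreement(
    selection_a: Iterable[tuple], selection_b: Iterable[tuple]
) -> dict[str, float]:
    """Overlap of two selections: Jaccard plus both conditional fractions.
    Both empty counts as full agreement."""
    a, b = set(selection_a), set(selection_b)
    if not a and not b:
        return {"jaccard": 1.0, "frac_of_a": 1.0, "frac_of_b": 1.0}
    inter = len(a & b)
    return {
        "jaccard": inter / len(a | b),
        "frac_of_a": inter / len(a) if a else 1.0,
        "frac_of_b": inter / len(b) if b else 1.0,
    }


def results_to_frame(
    results: Sequence[PairAssociation], labels: Sequence[str] | None = None
) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "region_a": labels[r.i] if labels else r.i,
                "region_b": labels[r.j] if labels else r.j,
                "n11": r.counts.n11,
                "n10": r.counts.n10,
                "n01": r.counts.n01,
                "n00": r.counts.n00,
                "z": r.z,
                "p": r.p,
                "q": r.q,
                "perm_p": r.perm_p,
                "perm_fdr": r.perm_fdr,
                "direction": r.direction if r.testable else "NA",
                "testable": int(r.testable),
            }
        )
    return pd.DataFrame(rows)
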