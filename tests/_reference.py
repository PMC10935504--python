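"""Independent brute-force oracles for the test suite.

Everything here is written as plain nested loops over the definitions,
deliberately sharing no code with the package's optimised implementation.
"""

from __future__ import annotations

import math
from fractions import Fraction
from functools import lru_cache

import numpy as np


# -- exact binomial statistics ------------------------------------------


@lru_cache(maxsize=None)
def exact_segment_similarity(k: int, l: int) -> float:
    """-log10 of the exact rational binomial upper tail at rate 1/4."""
    tail = Fraction(0)
    for j in range(k, l + 1):
        tail += (
            Fraction(math.comb(l, j))
            * Fraction(1, 4) ** j
            * Fraction(3, 4) ** (l - j)
        )
    if tail == 1:
        return 0.0
    return -math.log10(float(tail))


def enumerated_cooccurrence_pvalue(o: int, n_j: int, p: float) -> float:
    """P(X >= o) by enumerating all 2^n_j success/failure outcomes."""
    total = 0.0
    for mask in range(2 ** n_j):
        successes = bin(mask).count("1")
        if successes >= o:
            total += p ** successes * (1 - p) ** (n_j - successes)
    return total


# -- brute-force two-stage alignment ------------------------------------

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


def strand_rows(sequences, coverages):
    """Interleaved (sequence, coverage) strand rows: fwd, revcomp, ..."""
    rows = []
    for seq, cov in zip(sequences, coverages):
        rows.append((seq, list(cov)))
        rows.append((revcomp(seq), list(reversed(cov))))
    return rows


def identities(a: str, b: str) -> int:
    return sum(x == y and x != "N" for x, y in zip(a, b))


def row_pairs(n_seqs):
    for a in range(n_seqs):
        for b in range(a + 1, n_seqs):
            for ra in (2 * a, 2 * a + 1):
                for rb in (2 * b, 2 * b + 1):
                    yield ra, rb


def _qualifies(f_vals, fprime_vals, threshold, alpha):
    """Mask of qualifying segment pairs for one row pair."""
    positives = sorted((v for v in fprime_vals.values() if v > 0), reverse=True)
    if not positives:
        cutoff = None
    elif len(positives) <= alpha:
        cutoff = min(positives)
    else:
        cutoff = positives[alpha - 1]
    out = set()
    for key, f in f_vals.items():
        by_rank = cutoff is not None and fprime_vals[key] > 0 and fprime_vals[key] >= cutoff
        if f > threshold or by_rank:
            out.add(key)
    return out


def brute_force_pipeline(sequences, coverages, l, threshold=3.0, alpha=5, beta=3):
    """M1, M2 and the graph edge dict computed straight from the rules.

    Returns (m1, m2, mh_norm, edges) where m1/m2 are lists of per-row
    lists over valid starts, mh_norm the row-max-normalised coverage, and
    edges maps frozenset({(row, start), (row, start)}) -> weight.
    """
    rows = strand_rows(sequences, coverages)
    n_rows = len(rows)
    n_seqs = n_rows // 2
    starts = [len(seq) - l + 1 for seq, _ in rows]

    # identity counts tabulated once per row pair, reused by all stages
    ktab = {}
    for r1, r2 in row_pairs(n_seqs):
        ktab[(r1, r2)] = [
            [identities(rows[r1][0][j : j + l], rows[r2][0][q : q + l])
             for q in range(starts[r2])]
            for j in range(starts[r1])
        ]

    def f_of(r1, j, r2, q):
        return exact_segment_similarity(ktab[(r1, r2)][j][q], l)

    m1 = [[0.0] * starts[r] for r in range(n_rows)]
    for r1, r2 in row_pairs(n_seqs):
        f_vals, fp_vals = {}, {}
        for j in range(starts[r1]):
            for q in range(starts[r2]):
                f = f_of(r1, j, r2, q)
                f_vals[(j, q)] = f
                fp_vals[(j, q)] = f * (rows[r1][1][j] + rows[r2][1][q])
        for j, q in _qualifies(f_vals, fp_vals, threshold, alpha):
            m1[r1][j] += 1
            m1[r2][q] += 1

    def window_max(vals, center):
        lo, hi = max(0, center - 2), min(len(vals) - 1, center + 2)
        return max(vals[lo : hi + 1]) if vals else 0.0

    m2 = [[0.0] * starts[r] for r in range(n_rows)]
    for r1, r2 in row_pairs(n_seqs):
        f_vals, fp_vals = {}, {}
        for j in range(starts[r1]):
            for q in range(starts[r2]):
                f = f_of(r1, j, r2, q)
                f_vals[(j, q)] = f
                fp_vals[(j, q)] = f * (window_max(m1[r1], j) + window_max(m1[r2], q))
        for j, q in _qualifies(f_vals, fp_vals, threshold, alpha):
            m2[r1][j] += 1
            m2[r2][q] += 1

    mh_norm = []
    for seq, cov in rows:
        top = max(cov) if cov else 0.0
        mh_norm.append([c / top if top > 0 else 0.0 for c in cov])
    m2_final = []
    for r in range(n_rows):
        top = max(m2[r]) if m2[r] else 0.0
        m2_final.append(
            [
                (v / top if top > 0 else 0.0) + mh_norm[r][i]
                for i, v in enumerate(m2[r])
            ]
        )

    edges = {}
    for r1, r2 in row_pairs(n_seqs):
        f_vals, fp_vals = {}, {}
        for j in range(starts[r1]):
            for q in range(starts[r2]):
                f = f_of(r1, j, r2, q)
                f_vals[(j, q)] = f
                fp_vals[(j, q)] = f * (m2_final[r1][j] + m2_final[r2][q])
        positives = sorted((v for v in fp_vals.values() if v > 0), reverse=True)
        if not positives:
            continue
        cutoff = positives[beta - 1] if len(positives) > beta else min(positives)
        for (j, q), v in fp_vals.items():
            if v > 0 and v >= cutoff:
                key = frozenset({(r1, j), (r2, q)})
                edges[key] = max(edges.get(key, -np.inf), v)
    return m1, m2_final, mh_norm, edges


def random_instance(rng, m, n):
    """Random ACGT sequences and positive coverage vectors."""
    sequences = ["".join(rng.choice(list("ACGT"), size=n)) for _ in range(m)]
    coverages = [rng.uniform(0.05, 1.0, size=n).tolist() for _ in range(m)]
    return sequences, coverages


# -- brute-force ROC -----------------------------------------------------


def brute_force_pauc(pos, neg):
    """Standardised restricted pAUCs from an explicit threshold sweep.

    ROC points are counted per distinct score; the restricted areas are
    integrated on a dense union grid with linear interpolation, then
    rescaled so random maps to 0.5 and perfect to 1.0.
    """
    pos, neg = list(pos), list(neg)
    thresholds = sorted(set(pos) | set(neg), reverse=True)
    points = [(0.0, 0.0)]
    for th in thresholds:
        tpr = sum(s >= th for s in pos) / len(pos)
        fpr = sum(s >= th for s in neg) / len(neg)
        points.append((fpr, tpr))
    points.sort()

    def area(xy, lo, hi):
        # clip every corner-to-corner segment to the band and add its
        # trapezoid; vertical runs have zero width and contribute nothing
        total = 0.0
        for (x0, y0), (x1, y1) in zip(xy, xy[1:]):
            a, b = max(x0, lo), min(x1, hi)
            if b <= a or x1 == x0:
                continue
            ya = y0 + (y1 - y0) * (a - x0) / (x1 - x0)
            yb = y0 + (y1 - y0) * (b - x0) / (x1 - x0)
            total += 0.5 * (ya + yb) * (b - a)
        return total

    a_spec = area(points, 0.0, 0.2)
    spec = 0.5 * (1 + (a_spec - 0.02) / (0.2 - 0.02))

    flipped = sorted((tpr, fpr) for fpr, tpr in points)
    a_fpr = area(flipped, 0.8, 1.0)
    sens = 0.5 * (1 + ((0.2 - a_fpr) - 0.02) / (0.2 - 0.02))
    return max(0.0, min(1.0, sens)), max(0.0, min(1.0, spec))
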