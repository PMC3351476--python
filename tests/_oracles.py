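"""Independent brute-force implementations used as test oracles.

Everything here is deliberately written from first principles (explicit
loops, set logic, exhaustive window scans) and shares no code with the
package, so agreement between the two is meaningful evidence of
correctness.
"""

from __future__ import annotations

import math

import numpy as np

VALID = set("ACGT")


def effective_columns(seqs: list[str]) -> list[int]:
    return [
        j
        for j in range(len(seqs[0]))
        if all(s[j] in VALID for s in seqs)
    ]


def column(seqs: list[str], j: int) -> list[str]:
    return [s[j] for s in seqs]


def segregating_columns(seqs: list[str]) -> list[int]:
    return [
        j for j in effective_columns(seqs) if len(set(column(seqs, j))) > 1
    ]


def pi_total_brute(seqs: list[str]) -> float:
    """Mean pairwise difference count by explicit double loop."""
    cols = effective_columns(seqs)
    n = len(seqs)
    total, pairs = 0, 0
    for i in range(n):
        for j in range(i + 1, n):
            pairs += 1
            total += sum(seqs[i][c] != seqs[j][c] for c in cols)
    return total / pairs


def watterson_brute(seqs: list[str]) -> float:
    n = len(seqs)
    s = len(segregating_columns(seqs))
    a = sum(1.0 / i for i in range(1, n))
    return s / (a * len(effective_columns(seqs)))


def singletons_brute(seqs: list[str]) -> tuple[int, int]:
    """(Sin, LSin) by per-column allele counting."""
    n = len(seqs)
    sin_cols = []
    carriers: set[int] = set()
    for j in segregating_columns(seqs):
        col = column(seqs, j)
        alleles = {a: col.count(a) for a in set(col)}
        single = [a for a, c in alleles.items() if c == 1]
        if single:
            sin_cols.append(j)
            for i in range(n):
                if col[i] in single:
                    carriers.add(i)
    return len(sin_cols), len(carriers)


def tajima_d_brute(seqs: list[str]) -> float:
    """Textbook-formula Tajima's D, independently transcribed."""
    n = len(seqs)
    s = len(segregating_columns(seqs))
    if s == 0:
        raise ValueError("undefined")
    k_hat = pi_total_brute(seqs)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i / i for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    var = (c1 / a1) * s + (c2 / (a1 * a1 + a2)) * s * (s - 1.0)
    return (k_hat - s / a1) / math.sqrt(var)


def fu_li_fstar_brute(seqs: list[str]) -> float:
    """Fu & Li's F* with the Simonsen-corrected constants, transcribed
    separately from the package (different algebraic arrangement)."""
    n = len(seqs)
    cols = segregating_columns(seqs)
    eta = 0
    eta_s = 0
    for j in cols:
        col = column(seqs, j)
        alleles = {a: col.count(a) for a in set(col)}
        eta += len(alleles) - 1
        eta_s += sum(1 for c in alleles.values() if c == 1)
    if eta == 0:
        raise ValueError("undefined")
    pi_t = pi_total_brute(seqs)
    an = sum(1.0 / i for i in range(1, n))
    bn = sum(1.0 / i**2 for i in range(1, n))
    an1 = an + 1.0 / n
    nf = float(n)
    v = (
        (2 * nf**3 + 110 * nf**2 - 255 * nf + 153) / (9 * nf**2 * (nf - 1))
        + (2 * (nf - 1) * an) / nf**2
        - (8 * bn) / nf
    ) / (an**2 + bn)
    u = (
        nf / (nf + 1)
        + (nf + 1) / (3 * (nf - 1))
        - 4.0 / (nf * (nf - 1))
        + ((2 * (nf + 1)) / (nf - 1) ** 2) * (an1 - (2 * nf) / (nf + 1))
    ) / an - v
    num = pi_t - ((nf - 1) / nf) * eta_s
    return num / math.sqrt(u * eta + v * eta**2)


def haplotypes_brute(seqs: list[str]) -> tuple[int, float, float]:
    cols = effective_columns(seqs)
    strings = ["".join(s[c] for c in cols) for s in seqs]
    counts: dict[str, int] = {}
    for h in strings:
        counts[h] = counts.get(h, 0) + 1
    n = len(seqs)
    freqs = [c / n for c in counts.values()]
    he = n / (n - 1) * (1.0 - sum(f * f for f in freqs))
    return len(counts), max(freqs), he


def classify_brute(
    wild: list[str], dom: list[str]
) -> dict[str, int]:
    """Wakeley–Hey site classification by set logic."""
    cols = [
        j
        for j in range(len(wild[0]))
        if all(s[j] in VALID for s in wild + dom)
    ]
    out = {
        "fixed_diffs": 0,
        "shared_poly": 0,
        "excl_p1": 0,
        "excl_p2": 0,
        "monomorphic": 0,
    }
    for j in cols:
        a1 = set(column(wild, j))
        a2 = set(column(dom, j))
        p1, p2 = len(a1) > 1, len(a2) > 1
        if not p1 and not p2:
            if a1 == a2:
                out["monomorphic"] += 1
            else:
                out["fixed_diffs"] += 1
        elif p1 and not p2:
            out["excl_p1"] += 1
        elif p2 and not p1:
            out["excl_p2"] += 1
        elif len(a1 & a2) >= 2:
            out["shared_poly"] += 1
        else:
            out["excl_p1"] += 1
            out["excl_p2"] += 1
    return out


def hpd_brute(
    values: np.ndarray, weights: np.ndarray, mass: float = 0.95
) -> tuple[float, float]:
    """Shortest 95% interval by scanning every contiguous window."""
    order = np.argsort(values)
    v = values[order]
    w = weights[order] / weights.sum()
    best = None
    for i in range(len(v)):
        acc = 0.0
        for j in range(i, len(v)):
            acc += w[j]
            if acc >= mass - 1e-12:
                width = v[j] - v[i]
                if best is None or width < best[0]:
                    best = (width, float(v[i]), float(v[j]))
                break
    assert best is not None
    return best[1], best[2]


def runs_count_brute(labels: list[int]) -> int:
    runs = 1
    for a, b in zip(labels, labels[1:]):
        if a != b:
            runs += 1
    return runs


def nearest_distance_brute(
    from_pos: list[float], to_pos: list[float]
) -> list[float]:
    return [min(abs(p - q) for q in to_pos) for p in from_pos]


def fixed_s_counts_oracle(ts, focal: np.ndarray, s: int, rng) -> np.ndarray:
    """Independent fixed-S placement via the raw edge table.

    Reimplements branch-length-proportional placement over branches that
    subtend a proper, nonempty subset of the focal samples, using explicit
    parent maps per tree instead of the tskit traversal API.
    """
    focal_set = set(int(x) for x in focal)
    time = ts.tables.nodes.time
    cands = []  # (weight, k)
    for tree in ts.trees():
        span = tree.interval.right - tree.interval.left
        # build children map from the parent array
        below: dict[int, set[int]] = {}

        def leaves_below(u: int) -> set[int]:
            if u in below:
                return below[u]
            kids = tree.children(u)
            if not kids:
                out = {u} if u in focal_set else set()
            else:
                out = set()
                for c in kids:
                    out |= leaves_below(c)
            below[u] = out
            return out

        for u in tree.nodes():
            p = tree.parent(u)
            if p == -1:
                continue
            k = len(leaves_below(u))
            if 0 < k < len(focal_set):
                cands.append(((time[p] - time[u]) * span, k))
    w = np.array([c[0] for c in cands])
    ks = np.array([c[1] for c in cands])
    pick = rng.choice(len(w), size=s, replace=True, p=w / w.sum())
    return ks[pick]
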