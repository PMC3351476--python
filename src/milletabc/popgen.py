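"""Single-population sequence statistics.

All statistics are computed on the effective sites of an alignment (complete
deletion of gap/ambiguous columns) or directly on simulated 0/1 haplotype
matrices. Frequency-spectrum tests follow the standard definitions:
Tajima's D contrasts mean pairwise differences with the Watterson estimate;
Fu & Li's F* contrasts pairwise differences with the number of singleton
mutations, using the corrected variance constants of Simonsen et al. (the
form implemented by DnaSP/libsequence). Because no outgroup is available,
singletons are defined by minor-allele count 1 regardless of ancestral
state, and F* uses the total-singleton (eta_s) form.

Undefined statistics (D and F* require S >= 1) raise
:class:`StatisticUndefinedError` rather than returning 0; the ABC layer
treats such entries as missing and imputes them across loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from milletabc.alignment import SiteData, as_site_data


class StatisticUndefinedError(ValueError):
    """A statistic has no defined value for this input (e.g. S = 0)."""


@dataclass
class OnePopSummary:
    """Per-locus single-population summary (one row of a diversity table)."""

    n: int
    L_eff: int
    S: int
    Sin: int
    LSin: int
    pi: float
    pi_total: float
    thetaW: float
    He: float
    n_hap: int
    max_hap_freq: float
    var_pairwise: float
    raggedness: float
    D: float | None
    Fstar: float | None


# ---------------------------------------------------------------------------
# low-level helpers on code matrices


def _require_n(sd: SiteData, min_n: int = 2) -> None:
    if sd.n < min_n:
        raise ValueError(f"statistic requires at least {min_n} sequences, got {sd.n}")


def _allele_counts(codes: np.ndarray) -> np.ndarray:
    """(n_alleles, n_cols) counts of each allele code per column."""
    n_alleles = int(codes.max(initial=0)) + 1
    if n_alleles <= 2:  # binary (simulated) data
        k = codes.sum(axis=0)
        return np.stack([codes.shape[0] - k, k])
    return np.stack([(codes == a).sum(axis=0) for a in range(n_alleles)])


def _segregating_mask(counts: np.ndarray, n: int) -> np.ndarray:
    return (counts < n).all(axis=0) if counts.size else np.zeros(0, bool)


def pairwise_differences(codes: np.ndarray) -> np.ndarray:
    """(n, n) matrix of pairwise difference counts over the given columns."""
    n, ncols = codes.shape
    if int(codes.max(initial=0)) <= 1:  # binary: d_ij = r_i + r_j - 2 g_i.g_j
        g = codes.astype(np.float32)
        r = g.sum(axis=1)
        diffs = r[:, None] + r[None, :] - 2.0 * (g @ g.T)
    else:
        matches = np.zeros((n, n), dtype=np.float32)
        for a in range(int(codes.max(initial=0)) + 1):
            ind = (codes == a).astype(np.float32)
            matches += ind @ ind.T
        diffs = ncols - matches
    diffs = np.rint(diffs).astype(np.float64)
    np.fill_diagonal(diffs, 0.0)
    return diffs


def _pair_values(codes: np.ndarray) -> np.ndarray:
    """Condensed vector of the n(n-1)/2 pairwise difference counts."""
    d = pairwise_differences(codes)
    iu = np.triu_indices(d.shape[0], k=1)
    return d[iu]


def _hap_counts(codes: np.ndarray) -> np.ndarray:
    """Multiplicities of distinct rows (haplotypes) of a code matrix."""
    n = codes.shape[0]
    if codes.shape[1] == 0:
        return np.array([n])
    b = np.ascontiguousarray(codes)
    view = b.view(np.dtype((np.void, b.dtype.itemsize * b.shape[1]))).ravel()
    _, counts = np.unique(view, return_counts=True)
    return counts


def _gene_diversity(hap_counts: np.ndarray, n: int) -> float:
    p = hap_counts / n
    return n * (1.0 - float(np.sum(p**2))) / (n - 1)


# ---------------------------------------------------------------------------
# constants


@lru_cache(maxsize=None)
def harmonic_numbers(n: int) -> tuple[float, float]:
    """(a_n, b_n) = (sum 1/i, sum 1/i^2) for i = 1..n-1."""
    i = np.arange(1, n)
    return float(np.sum(1.0 / i)), float(np.sum(1.0 / i**2))


@lru_cache(maxsize=None)
def _tajima_constants(n: int) -> tuple[float, float, float]:
    a1, a2 = harmonic_numbers(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


@lru_cache(maxsize=None)
def _fu_li_fstar_constants(n: int) -> tuple[float, float]:
    """(u_F*, v_F*) with the corrected constants (Simonsen et al. 1995)."""
    a, b = harmonic_numbers(n)
    a1n = a + 1.0 / n  # a_{n+1}
    vfs = (
        (2.0 * n**3 + 110.0 * n**2 - 255.0 * n + 153.0) / (9.0 * n**2 * (n - 1.0))
        + 2.0 * (n - 1.0) * a / n**2
        - 8.0 * b / n
    ) / (a**2 + b)
    ufs = (
        n / (n + 1.0)
        + (n + 1.0) / (3.0 * (n - 1.0))
        - 4.0 / (n * (n - 1.0))
        + 2.0 * (n + 1.0) / (n - 1.0) ** 2 * (a1n - 2.0 * n / (n + 1.0))
    ) / a - vfs
    return ufs, vfs


# ---------------------------------------------------------------------------
# operations


def effective_sites(aln) -> list[int]:
    """Indices of columns containing only {A,C,G,T} in every sequence."""
    from milletabc.alignment import Alignment

    if isinstance(aln, Alignment):
        return [int(i) for i in aln.effective_site_indices()]
    sd = as_site_data(aln)
    return [int(p) for p in sd.positions]


def segregating_sites(aln) -> tuple[int, list[int]]:
    """Number of polymorphic effective sites and their positions."""
    sd = as_site_data(aln)
    _require_n(sd)
    counts = _allele_counts(sd.codes)
    mask = _segregating_mask(counts, sd.n)
    return int(mask.sum()), [int(p) for p in sd.positions[mask]]


def singletons(aln) -> tuple[int, int]:
    """(Sin, LSin): singleton sites and lineages carrying >= 1 singleton."""
    sd = as_site_data(aln)
    _require_n(sd)
    counts = _allele_counts(sd.codes)
    seg = _segregating_mask(counts, sd.n)
    singleton_allele = (counts == 1) & seg  # (alleles, cols)
    site_is_singleton = singleton_allele.any(axis=0)
    alleles, cols = np.nonzero(singleton_allele)
    if alleles.size:
        carrier = (sd.codes[:, cols] == alleles[None, :]).any(axis=1)
        n_carriers = int(carrier.sum())
    else:
        n_carriers = 0
    return int(site_is_singleton.sum()), n_carriers


def singleton_mutation_count(aln) -> int:
    """eta_s: total number of singleton alleles at segregating sites."""
    sd = as_site_data(aln)
    _require_n(sd)
    counts = _allele_counts(sd.codes)
    seg = _segregating_mask(counts, sd.n)
    return int(((counts == 1) & seg).sum())


def mutation_count(aln) -> int:
    """eta: total mutations, counting a k-allele site as k-1 mutations."""
    sd = as_site_data(aln)
    counts = _allele_counts(sd.codes)
    n_alleles = (counts > 0).sum(axis=0)
    return int(np.maximum(n_alleles - 1, 0).sum())


def pi(aln) -> tuple[float, float]:
    """(pi per site, pi_total = mean pairwise difference count)."""
    sd = as_site_data(aln)
    _require_n(sd)
    if sd.L_eff == 0:
        raise StatisticUndefinedError("no effective sites: pi undefined")
    pv = _pair_values(sd.codes)
    pi_total = float(pv.mean()) if pv.size else 0.0
    return pi_total / sd.L_eff, pi_total


def watterson_theta_from_counts(n: int, S: int, L_eff: int) -> float:
    """theta_W = S / (a_n * L_eff)."""
    if n < 2:
        raise ValueError("need n >= 2")
    if L_eff < 1:
        raise StatisticUndefinedError("L_eff must be >= 1")
    a1, _ = harmonic_numbers(n)
    return S / (a1 * L_eff)


def watterson_theta(aln) -> float:
    sd = as_site_data(aln)
    S, _ = segregating_sites(sd)
    return watterson_theta_from_counts(sd.n, S, sd.L_eff)


def tajimas_d_from_counts(n: int, S: int, pi_total: float) -> float:
    """Tajima's D from sample size, segregating sites and mean pairwise diffs."""
    if S < 1:
        raise StatisticUndefinedError("Tajima's D undefined for S = 0")
    a1, e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:  # degenerate (e.g. n = 3, S = 1)
        raise StatisticUndefinedError("Tajima's D variance is zero")
    return (pi_total - S / a1) / math.sqrt(var)


def tajimas_d(aln) -> float:
    sd = as_site_data(aln)
    S, _ = segregating_sites(sd)
    _, pi_total = pi(sd)
    return tajimas_d_from_counts(sd.n, S, pi_total)


def fu_li_f_star_from_counts(n: int, eta: int, eta_s: int, pi_total: float) -> float:
    """Fu & Li's F* from total mutations, singleton mutations and pi_total."""
    if eta < 1:
        raise StatisticUndefinedError("Fu & Li's F* undefined for S = 0")
    ufs, vfs = _fu_li_fstar_constants(n)
    var = ufs * eta + vfs * eta**2
    if var <= 0:
        raise StatisticUndefinedError("F* variance is not positive")
    return (pi_total - (n - 1.0) / n * eta_s) / math.sqrt(var)


def fu_li_f_star(aln) -> float:
    sd = as_site_data(aln)
    _, pi_total = pi(sd)
    return fu_li_f_star_from_counts(
        sd.n, mutation_count(sd), singleton_mutation_count(sd), pi_total
    )


def haplotype_diversity(aln) -> tuple[int, float, float]:
    """(n_hap, max_hap_freq, He) from distinct strings on effective sites.

    He is haplotype gene diversity: He = n (1 - sum p_k^2) / (n - 1).
    """
    sd = as_site_data(aln)
    _require_n(sd)
    hap_counts = _hap_counts(sd.codes)
    he = _gene_diversity(hap_counts, sd.n)
    return int(hap_counts.size), float(hap_counts.max() / sd.n), he


def mismatch_raggedness(aln) -> tuple[np.ndarray, float, float]:
    """(mismatch distribution, var of pairwise diffs, Harpending raggedness).

    The mismatch distribution is the relative frequency x_0..x_d of pairwise
    difference counts (d = max observed); raggedness = sum_{i=1..d}
    (x_i - x_{i-1})^2, 0 for the degenerate all-identical case (d = 0).
    var_pairwise is the population (divide-by-m) variance over pair counts.
    """
    sd = as_site_data(aln)
    _require_n(sd)
    pv = _pair_values(sd.codes)
    d = int(pv.max()) if pv.size else 0
    x = np.bincount(pv.astype(int), minlength=d + 1) / pv.size
    var = float(np.var(pv))
    rag = float(np.sum(np.diff(x) ** 2)) if d > 0 else 0.0
    return x, var, rag


def _one_pop_summary_from_parts(
    sd: SiteData, pv: np.ndarray
) -> OnePopSummary:
    """OnePopSummary given precomputed pairwise difference values."""
    counts = _allele_counts(sd.codes)
    seg = _segregating_mask(counts, sd.n)
    S = int(seg.sum())
    singleton_allele = (counts == 1) & seg
    sin = int(singleton_allele.any(axis=0).sum())
    eta_s = int(singleton_allele.sum())
    eta = int(np.maximum((counts > 0).sum(axis=0) - 1, 0).sum())
    alleles, cols = np.nonzero(singleton_allele)
    lsin = (
        int((sd.codes[:, cols] == alleles[None, :]).any(axis=1).sum())
        if alleles.size
        else 0
    )
    if sd.L_eff == 0:
        raise StatisticUndefinedError("no effective sites")
    pi_total = float(pv.mean()) if pv.size else 0.0
    theta = watterson_theta_from_counts(sd.n, S, sd.L_eff)
    hap_counts = _hap_counts(sd.codes)
    d = int(pv.max()) if pv.size else 0
    x = np.bincount(pv.astype(int), minlength=d + 1) / max(pv.size, 1)
    try:
        d_val = tajimas_d_from_counts(sd.n, S, pi_total)
    except StatisticUndefinedError:
        d_val = None
    try:
        f_val = fu_li_f_star_from_counts(sd.n, eta, eta_s, pi_total)
    except StatisticUndefinedError:
        f_val = None
    return OnePopSummary(
        n=sd.n,
        L_eff=sd.L_eff,
        S=S,
        Sin=sin,
        LSin=lsin,
        pi=pi_total / sd.L_eff,
        pi_total=pi_total,
        thetaW=theta,
        He=_gene_diversity(hap_counts, sd.n),
        n_hap=int(hap_counts.size),
        max_hap_freq=float(hap_counts.max() / sd.n),
        var_pairwise=float(np.var(pv)) if pv.size else 0.0,
        raggedness=float(np.sum(np.diff(x) ** 2)) if d > 0 else 0.0,
        D=d_val,
        Fstar=f_val,
    )


def one_pop_summary(aln) -> OnePopSummary:
    """Aggregate all single-population statistics for one locus."""
    sd = as_site_data(aln)
    _require_n(sd)
    S, _ = segregating_sites(sd)
    sin, lsin = singletons(sd)
    pi_site, pi_total = pi(sd)
    theta = watterson_theta_from_counts(sd.n, S, sd.L_eff)
    n_hap, mhf, he = haplotype_diversity(sd)
    _, var_pw, rag = mismatch_raggedness(sd)
    try:
        d_val = tajimas_d_from_counts(sd.n, S, pi_total)
    except StatisticUndefinedError:
        d_val = None
    try:
        f_val = fu_li_f_star_from_counts(
            sd.n, mutation_count(sd), singleton_mutation_count(sd), pi_total
        )
    except StatisticUndefinedError:
        f_val = None
    return OnePopSummary(
        n=sd.n,
        L_eff=sd.L_eff,
        S=S,
        Sin=sin,
        LSin=lsin,
        pi=pi_site,
        pi_total=pi_total,
        thetaW=theta,
        He=he,
        n_hap=n_hap,
        max_hap_freq=mhf,
        var_pairwise=var_pw,
        raggedness=rag,
        D=d_val,
        Fstar=f_val,
    )
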