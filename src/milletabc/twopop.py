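"""Two-population statistics and the across-locus ABC feature vector.

Variable sites are classified between the wild and domestic samples after
joint complete deletion, following the Wakeley–Hey scheme: fixed
differences, shared polymorphisms, and polymorphisms exclusive to one
population. Between-population distances, Hudson's Fst with a permutation
test, and three spatial statistics on the arrangement of site classes along
the sequence (RS, Wx2s1, Wx1s2) complete the per-locus battery; the
multi-locus summary collects across-locus means and variances in a fixed
named order, which is the feature vector compared between observed and
simulated data in the ABC.

The spatial statistics are explicit stand-ins for an unpublished statistic
family sensitive to the presence and direction of gene flow; they are
pluggable (``spatial_stat_fns``) so alternative definitions can be swapped
in without touching the ABC layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy.stats import norm

from milletabc.alignment import SiteData, as_site_data
from milletabc.popgen import (
    OnePopSummary,
    _allele_counts,
    _gene_diversity,
    _hap_counts,
    _one_pop_summary_from_parts,
    _pair_values,
    one_pop_summary,
    pairwise_differences,
)


class SiteClass(IntEnum):
    MONOMORPHIC = 0
    EXCLUSIVE_P1 = 1
    EXCLUSIVE_P2 = 2
    SHARED = 3
    FIXED_DIFF = 4
    # polymorphic in both populations with no shared segregating base
    # (possible only at multi-allelic sites); counted once per population
    # in the exclusive-polymorphism tallies.
    EXCLUSIVE_BOTH = 5


@dataclass
class TwoPopSummary:
    """Per-locus two-population summary."""

    fixed_diffs: int
    shared_poly: int
    excl_p1: int
    excl_p2: int
    total_He: float
    d_min: float
    d_mean: float
    d_var: float
    Fst: float | None
    RS: float | None
    Wx2s1: float | None
    Wx1s2: float | None


def paired_site_data(aln_wild, aln_dom) -> tuple[SiteData, SiteData]:
    """Joint complete deletion across the two samples of one locus."""
    from milletabc.alignment import Alignment

    if isinstance(aln_wild, Alignment) and isinstance(aln_dom, Alignment):
        if aln_wild.length != aln_dom.length:
            raise ValueError("alignments of one locus must share coordinates")
        ok = (aln_wild.codes >= 0).all(axis=0) & (aln_dom.codes >= 0).all(axis=0)
        idx = np.flatnonzero(ok)
        pos = idx.astype(float)
        return (
            SiteData(np.ascontiguousarray(aln_wild.codes[:, idx]), int(idx.size), pos),
            SiteData(np.ascontiguousarray(aln_dom.codes[:, idx]), int(idx.size), pos),
        )
    sd1, sd2 = as_site_data(aln_wild), as_site_data(aln_dom)
    if sd1.codes.shape[1] != sd2.codes.shape[1] or sd1.L_eff != sd2.L_eff:
        raise ValueError("site data of one locus must share columns")
    return sd1, sd2


def classify_sites(aln_wild, aln_dom) -> tuple[np.ndarray, dict[str, int]]:
    """Per-site Wakeley–Hey class vector and class counts.

    The returned vector has one entry per shared effective column; counts
    report fixed differences, shared polymorphisms and per-population
    exclusive polymorphisms (the rare no-shared-base double-polymorphic
    case increments both exclusive tallies).
    """
    sd1, sd2 = paired_site_data(aln_wild, aln_dom)
    return _classify_from_counts(
        _allele_counts(sd1.codes),
        _allele_counts(sd2.codes),
        sd1.codes.shape[1],
        sd1.L_eff,
    )


def _classify_from_counts(
    c1: np.ndarray, c2: np.ndarray, n_cols: int, L_eff: int
) -> tuple[np.ndarray, dict[str, int]]:
    n_all = max(c1.shape[0], c2.shape[0])
    if c1.shape[0] < n_all:
        c1 = np.vstack([c1, np.zeros((n_all - c1.shape[0], c1.shape[1]), int)])
    if c2.shape[0] < n_all:
        c2 = np.vstack([c2, np.zeros((n_all - c2.shape[0], c2.shape[1]), int)])
    present1, present2 = c1 > 0, c2 > 0
    poly1 = present1.sum(axis=0) > 1
    poly2 = present2.sum(axis=0) > 1
    shared_bases = (present1 & present2).sum(axis=0)

    cls = np.full(n_cols, int(SiteClass.MONOMORPHIC), dtype=np.int8)
    cls[poly1 & ~poly2] = SiteClass.EXCLUSIVE_P1
    cls[~poly1 & poly2] = SiteClass.EXCLUSIVE_P2
    both = poly1 & poly2
    cls[both & (shared_bases >= 2)] = SiteClass.SHARED
    cls[both & (shared_bases < 2)] = SiteClass.EXCLUSIVE_BOTH
    mono_both = ~poly1 & ~poly2
    fixed = mono_both & (shared_bases == 0)
    cls[fixed] = SiteClass.FIXED_DIFF

    counts = {
        "fixed_diffs": int((cls == SiteClass.FIXED_DIFF).sum()),
        "shared_poly": int((cls == SiteClass.SHARED).sum()),
        "excl_p1": int(
            ((cls == SiteClass.EXCLUSIVE_P1) | (cls == SiteClass.EXCLUSIVE_BOTH)).sum()
        ),
        "excl_p2": int(
            ((cls == SiteClass.EXCLUSIVE_P2) | (cls == SiteClass.EXCLUSIVE_BOTH)).sum()
        ),
        "monomorphic": int((cls == SiteClass.MONOMORPHIC).sum())
        + (L_eff - n_cols),
    }
    return cls, counts


def between_pop_distances(aln_wild, aln_dom) -> tuple[float, float, float]:
    """(d_min, d_mean, d_var) of difference counts over all wild x dom pairs."""
    sd1, sd2 = paired_site_data(aln_wild, aln_dom)
    if sd1.n < 1 or sd2.n < 1:
        raise ValueError("both populations must contain at least one sequence")
    stacked = np.vstack([sd1.codes, sd2.codes])
    d = pairwise_differences(stacked)[: sd1.n, sd1.n :]
    return float(d.min()), float(d.mean()), float(np.var(d))


def hudson_fst(aln_wild, aln_dom) -> float:
    """Hudson's Fst = 1 - pi_within / pi_between on pairwise difference counts."""
    sd1, sd2 = paired_site_data(aln_wild, aln_dom)
    if sd1.n < 2 or sd2.n < 2:
        raise ValueError("Fst requires n >= 2 in each population")
    pw = float(_pair_values(sd1.codes).mean())
    pd_ = float(_pair_values(sd2.codes).mean())
    _, d_mean, _ = between_pop_distances(sd1, sd2)
    if d_mean == 0.0:
        raise ZeroDivisionError("pi_between = 0: Fst undefined")
    return 1.0 - 0.5 * (pw + pd_) / d_mean


def fst_permutation_test(
    aln_wild, aln_dom, n_perm: int = 10000, seed: int | None = None
) -> float:
    """One-sided permutation p-value for the observed Fst.

    Sequences are randomly reassigned to the two populations preserving
    sample sizes; p = (1 + #{Fst_perm >= Fst_obs}) / (n_perm + 1).
    """
    sd1, sd2 = paired_site_data(aln_wild, aln_dom)
    n1 = sd1.n
    stacked = np.vstack([sd1.codes, sd2.codes])
    d = pairwise_differences(stacked)
    n = stacked.shape[0]

    def fst_of(order: np.ndarray) -> float:
        g1, g2 = order[:n1], order[n1:]
        pw = d[np.ix_(g1, g1)][np.triu_indices(len(g1), k=1)].mean()
        pd_ = d[np.ix_(g2, g2)][np.triu_indices(len(g2), k=1)].mean()
        db = d[np.ix_(g1, g2)].mean()
        if db == 0.0:
            return -np.inf
        return 1.0 - 0.5 * (pw + pd_) / db

    obs = fst_of(np.arange(n))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if fst_of(rng.permutation(n)) >= obs:
            hits += 1
    return (1 + hits) / (n_perm + 1)


# ---------------------------------------------------------------------------
# spatial statistics on site classes


def runs_statistic(cls: np.ndarray, positions: np.ndarray, L_eff: int) -> float | None:
    """RS: Wald–Wolfowitz standardized run count over exclusive-site labels."""
    order = np.argsort(positions)
    lab = cls[order]
    keep = (lab == SiteClass.EXCLUSIVE_P1) | (lab == SiteClass.EXCLUSIVE_P2)
    lab = lab[keep]
    n1 = int((lab == SiteClass.EXCLUSIVE_P1).sum())
    n2 = int((lab == SiteClass.EXCLUSIVE_P2).sum())
    if n1 < 1 or n2 < 1 or n1 + n2 < 2:
        return None
    runs = 1 + int(np.sum(lab[1:] != lab[:-1]))
    m = n1 + n2
    mu = 1.0 + 2.0 * n1 * n2 / m
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - m) / (m**2 * (m - 1.0))
    if var <= 0:
        return None
    return (runs - mu) / math.sqrt(var)


def _nearest_shared_distance(
    cls: np.ndarray,
    positions: np.ndarray,
    L_eff: int,
    excl_class: SiteClass,
) -> float | None:
    excl_pos = positions[cls == excl_class]
    if excl_pos.size == 0:
        return None
    shared_pos = positions[cls == SiteClass.SHARED]
    if shared_pos.size == 0:
        return 1.0
    shared_sorted = np.sort(shared_pos)
    if shared_sorted.size == 1:
        dist = np.abs(excl_pos - shared_sorted[0])
    else:
        idx = np.clip(
            np.searchsorted(shared_sorted, excl_pos), 1, shared_sorted.size - 1
        )
        dist = np.minimum(
            np.abs(excl_pos - shared_sorted[idx - 1]),
            np.abs(shared_sorted[idx] - excl_pos),
        )
    return float(np.mean(dist) / L_eff)


def wx1s2(cls: np.ndarray, positions: np.ndarray, L_eff: int) -> float | None:
    """Mean normalized distance from exclusive-P1 sites to the nearest shared site."""
    return _nearest_shared_distance(cls, positions, L_eff, SiteClass.EXCLUSIVE_P1)


def wx2s1(cls: np.ndarray, positions: np.ndarray, L_eff: int) -> float | None:
    """Mean normalized distance from exclusive-P2 sites to the nearest shared site."""
    return _nearest_shared_distance(cls, positions, L_eff, SiteClass.EXCLUSIVE_P2)


#: pluggable battery of spatial statistics (name -> fn(cls, positions, L_eff))
spatial_stat_fns = {"RS": runs_statistic, "Wx2s1": wx2s1, "Wx1s2": wx1s2}


def spatial_stats(
    cls: np.ndarray, positions: np.ndarray, L_eff: int
) -> dict[str, float | None]:
    return {name: fn(cls, positions, L_eff) for name, fn in spatial_stat_fns.items()}


# ---------------------------------------------------------------------------
# per-locus and across-locus assembly


def total_heterozygosity(aln_wild, aln_dom) -> float:
    """Pooled-sample haplotype gene diversity."""
    sd1, sd2 = paired_site_data(aln_wild, aln_dom)
    stacked = np.vstack([sd1.codes, sd2.codes])
    n = stacked.shape[0]
    if stacked.shape[1] == 0:
        return 0.0
    _, hap_counts = np.unique(stacked, axis=0, return_counts=True)
    p = hap_counts / n
    return n * (1.0 - float(np.sum(p**2))) / (n - 1)


def two_pop_summary(aln_wild, aln_dom) -> TwoPopSummary:
    sd1, sd2 = paired_site_data(aln_wild, aln_dom)
    cls, counts = classify_sites(sd1, sd2)
    d_min, d_mean, d_var = between_pop_distances(sd1, sd2)
    try:
        fst = hudson_fst(sd1, sd2)
    except (ZeroDivisionError, ValueError):
        fst = None
    spatial = spatial_stats(cls, sd1.positions, sd1.L_eff)
    return TwoPopSummary(
        fixed_diffs=counts["fixed_diffs"],
        shared_poly=counts["shared_poly"],
        excl_p1=counts["excl_p1"],
        excl_p2=counts["excl_p2"],
        total_He=total_heterozygosity(sd1, sd2),
        d_min=d_min,
        d_mean=d_mean,
        d_var=d_var,
        Fst=fst,
        RS=spatial["RS"],
        Wx2s1=spatial["Wx2s1"],
        Wx1s2=spatial["Wx1s2"],
    )


@dataclass
class LocusSummaryPair:
    """Everything the multi-locus summary needs from one locus."""

    name: str
    wild: OnePopSummary
    dom: OnePopSummary
    two: TwoPopSummary


def summarize_locus(name: str, aln_wild, aln_dom) -> LocusSummaryPair:
    """All per-locus summaries, computing shared intermediates only once.

    Equivalent to composing :func:`one_pop_summary` per population with
    :func:`two_pop_summary` (asserted in the test suite), but the stacked
    pairwise-difference matrix, allele counts and haplotype tallies are
    computed a single time, which matters when summarizing millions of
    simulated loci for the ABC reference table.
    """
    sd1, sd2 = paired_site_data(aln_wild, aln_dom)
    n1, n2 = sd1.n, sd2.n
    stacked = np.vstack([sd1.codes, sd2.codes])
    d = pairwise_differences(stacked)
    iu1 = np.triu_indices(n1, k=1)
    iu2 = np.triu_indices(n2, k=1)
    pv1 = d[:n1, :n1][iu1]
    pv2 = d[n1:, n1:][iu2]
    between = d[:n1, n1:]

    wild = _one_pop_summary_from_parts(sd1, pv1)
    dom = _one_pop_summary_from_parts(sd2, pv2)

    cls, counts = _classify_from_counts(
        _allele_counts(sd1.codes),
        _allele_counts(sd2.codes),
        sd1.codes.shape[1],
        sd1.L_eff,
    )
    d_mean = float(between.mean())
    if d_mean > 0:
        fst = 1.0 - 0.5 * (wild.pi_total + dom.pi_total) / d_mean
    else:
        fst = None
    spatial = spatial_stats(cls, sd1.positions, sd1.L_eff)
    n_tot = n1 + n2
    two = TwoPopSummary(
        fixed_diffs=counts["fixed_diffs"],
        shared_poly=counts["shared_poly"],
        excl_p1=counts["excl_p1"],
        excl_p2=counts["excl_p2"],
        total_He=_gene_diversity(_hap_counts(stacked), n_tot),
        d_min=float(between.min()),
        d_mean=d_mean,
        d_var=float(np.var(between)),
        Fst=fst,
        RS=spatial["RS"],
        Wx2s1=spatial["Wx2s1"],
        Wx1s2=spatial["Wx1s2"],
    )
    return LocusSummaryPair(name=name, wild=wild, dom=dom, two=two)


# fixed entry order of the ABC feature vector
_ONEPOP_STATS = ["He", "pi", "excl", "var_pairwise", "D"]
_DOM_EXTRA = ["max_hap_freq", "Sin", "raggedness"]
_TWOPOP_STATS = [
    "total_He",
    "d_min",
    "d_mean",
    "d_var",
    "fixed_diffs",
    "excl_p1",
    "excl_p2",
    "shared_poly",
]
_SPATIAL = ["RS", "Wx2s1", "Wx1s2"]


def summary_names() -> list[str]:
    names = []
    for pop in ("wild", "dom"):
        for stat in _ONEPOP_STATS:
            names += [f"{pop}_{stat}_mean", f"{pop}_{stat}_var"]
    for stat in _DOM_EXTRA:
        names += [f"dom_{stat}_mean", f"dom_{stat}_var"]
    for stat in _TWOPOP_STATS:
        names += [f"two_{stat}_mean", f"two_{stat}_var"]
    for stat in _SPATIAL:
        names += [f"{stat}_mean", f"{stat}_ksd"]
    return names


@dataclass
class MultiLocusSummary:
    """Ordered, named across-locus feature vector for the ABC."""

    names: list[str]
    values: np.ndarray
    flagged: np.ndarray  # True where the entry was undefined at every locus

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def _impute(values: list[float | None]) -> tuple[np.ndarray, bool]:
    """Replace per-locus missing values by the mean of defined ones."""
    arr = np.array([np.nan if v is None else float(v) for v in values])
    defined = ~np.isnan(arr)
    if not defined.any():
        return arr, True
    arr[~defined] = arr[defined].mean()
    return arr, False


def _mean_var(values: list[float | None]) -> tuple[float, float, bool]:
    arr, flagged = _impute(values)
    if flagged:
        return math.nan, math.nan, True
    return float(arr.mean()), float(np.var(arr, ddof=1)), False


def _ks_standard_normal(values: np.ndarray) -> float | None:
    """One-sample KS D of z-scored values against N(0, 1)."""
    sd = values.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return None
    z = np.sort((values - values.mean()) / sd)
    cdf = norm.cdf(z)
    n = z.size
    upper = np.arange(1, n + 1) / n - cdf
    lower = cdf - np.arange(0, n) / n
    return float(max(upper.max(), lower.max()))


def multilocus_summary(loci: list[LocusSummaryPair]) -> MultiLocusSummary:
    """Across-locus means/variances in the fixed feature order.

    Per-locus missing statistics are imputed with the across-locus mean of
    the defined values; entries undefined at every locus are flagged (NaN)
    and dropped consistently from distance computations downstream.
    """
    if len(loci) < 2:
        raise ValueError("multilocus summary requires >= 2 loci")
    values: list[float] = []
    flags: list[bool] = []

    def push(vals: list[float | None]) -> None:
        m, v, f = _mean_var(vals)
        values.extend([m, v])
        flags.extend([f, f])

    for pop in ("wild", "dom"):
        for stat in _ONEPOP_STATS:
            if stat == "excl":
                key = "excl_p1" if pop == "wild" else "excl_p2"
                push([getattr(lp.two, key) for lp in loci])
            else:
                push([getattr(getattr(lp, pop), stat) for lp in loci])
    for stat in _DOM_EXTRA:
        push([getattr(lp.dom, stat) for lp in loci])
    for stat in _TWOPOP_STATS:
        push([getattr(lp.two, stat) for lp in loci])
    for stat in _SPATIAL:
        arr, flagged = _impute([getattr(lp.two, stat) for lp in loci])
        if flagged:
            values.extend([math.nan, math.nan])
            flags.extend([True, True])
            continue
        values.append(float(arr.mean()))
        flags.append(False)
        ksd = _ks_standard_normal(arr)
        values.append(math.nan if ksd is None else ksd)
        flags.append(ksd is None)

    return MultiLocusSummary(
        names=summary_names(),
        values=np.asarray(values),
        flagged=np.asarray(flags, dtype=bool),
    )
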