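"""The two-scenario domestication coalescent model.

A constant-size wild population gives rise, ``t`` generations ago, to a
domestic population that starts from a bottleneck (scaled diversity
``theta_d0``) and grows exponentially to its present size (``theta_d1``).
Gene flow between the two populations may occur in both directions until
the domestication time (backwards in time, all domestic lineages then merge
into the wild population and migration ceases). All diversity parameters
are scaled per bp: ``theta = 4 Ne mu``; migration rates are ``4 Ne_W m``;
``rho = 4 Ne_W r`` per consecutive bp; ``T = t mu / theta_w`` is the
domestication time in units of ``4 Ne_W`` generations.

Genealogies are generated with msprime (one generation per year, annual
plant). Mutations are placed either at rate ``mu`` under the infinite-sites
model, or — for posterior-predictive tests — as exactly ``S`` mutations
dropped on the branches of the focal subsample's marginal genealogy with
probability proportional to branch length (the fixed-S conditioning of
ms -s, restricted to the tested group).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import msprime
import numpy as np
import tskit

from milletabc.alignment import SiteData

WITH_MIGRATION = "with_migration"
WITHOUT_MIGRATION = "without_migration"


@dataclass(frozen=True)
class DemographicParams:
    """One draw of the domestication model's parameters."""

    theta_w: float  # 4 Ne_W mu per bp
    theta_d0: float  # 4 Ne_0 mu per bp (domestic, at domestication time)
    theta_d1: float  # 4 Ne_1 mu per bp (domestic, present)
    rho: float  # 4 Ne_W r per consecutive bp
    mig_wd: float  # 4 Ne m, wild -> domestic (forward in time)
    mig_dw: float  # 4 Ne m, domestic -> wild (forward in time)
    mu: float  # mutations / bp / generation
    t_years: float  # generations (1 per year)
    scenario: str = WITH_MIGRATION

    def __post_init__(self) -> None:
        if self.theta_d0 > min(self.theta_d1, self.theta_w) * (1 + 1e-12):
            raise ValueError("theta_d0 must not exceed min(theta_d1, theta_w)")
        for name in ("theta_w", "theta_d0", "theta_d1", "mu", "t_years"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("rho", "mig_wd", "mig_dw"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.scenario == WITHOUT_MIGRATION and (self.mig_wd or self.mig_dw):
            raise ValueError("without_migration scenario requires zero migration")
        if self.scenario not in (WITH_MIGRATION, WITHOUT_MIGRATION):
            raise ValueError(f"unknown scenario {self.scenario!r}")

    @property
    def T(self) -> float:
        """Domestication time in units of 4 Ne_W generations."""
        return self.t_years * self.mu / self.theta_w

    def as_dict(self) -> dict[str, float]:
        return {
            "theta_w": self.theta_w,
            "theta_d0": self.theta_d0,
            "theta_d1": self.theta_d1,
            "rho": self.rho,
            "mig_wd": self.mig_wd,
            "mig_dw": self.mig_dw,
            "mu": self.mu,
            "t_years": self.t_years,
            "T": self.T,
        }


@dataclass(frozen=True)
class PriorConfig:
    """Prior distributions of the domestication model.

    Defaults: theta_w ~ log-uniform(1e-3, 1); theta_d1 ~ log-uniform(1e-8, 1);
    rho ~ log-uniform(1e-50, 1); each migration rate ~ uniform(0, 100) in the
    with-migration scenario; t ~ uniform(3000, 12000) generations (the
    archaeological window for Sahelian agriculture); mu ~ log-normal with
    log-mean -17.7 and log-sd 1 (median ~2.04e-8 per bp per year, spanning
    published grass mutation-rate estimates); theta_d0 ~ log-uniform on
    (1e-5 m, m) with m = min(theta_d1, theta_w), which enforces a bottleneck
    followed by expansion.
    """

    theta_w_bounds: tuple[float, float] = (1e-3, 1.0)
    theta_d1_bounds: tuple[float, float] = (1e-8, 1.0)
    rho_bounds: tuple[float, float] = (1e-50, 1.0)
    mig_bounds: tuple[float, float] = (0.0, 100.0)
    t_bounds: tuple[float, float] = (3000.0, 12000.0)
    mu_log_mean: float = -17.7
    mu_log_sd: float = 1.0
    theta_d0_span: float = 1e-5  # lower bound = span * min(theta_d1, theta_w)
    shared_migration_rate: bool = False
    scenario: str = WITH_MIGRATION

    def __post_init__(self) -> None:
        for name in ("theta_w_bounds", "theta_d1_bounds", "rho_bounds",
                     "mig_bounds", "t_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: need min < max, got ({lo}, {hi})")


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def sample_prior(prior: PriorConfig, rng: np.random.Generator) -> DemographicParams:
    """One independent draw from the prior."""
    theta_w = _log_uniform(rng, *prior.theta_w_bounds)
    theta_d1 = _log_uniform(rng, *prior.theta_d1_bounds)
    m = min(theta_d1, theta_w)
    theta_d0 = _log_uniform(rng, prior.theta_d0_span * m, m)
    rho = _log_uniform(rng, *prior.rho_bounds)
    if prior.scenario == WITH_MIGRATION:
        mig_wd = float(rng.uniform(*prior.mig_bounds))
        mig_dw = mig_wd if prior.shared_migration_rate else float(
            rng.uniform(*prior.mig_bounds)
        )
    else:
        mig_wd = mig_dw = 0.0
    t_years = float(rng.uniform(*prior.t_bounds))
    mu = float(np.exp(rng.normal(prior.mu_log_mean, prior.mu_log_sd)))
    return DemographicParams(
        theta_w=theta_w,
        theta_d0=theta_d0,
        theta_d1=theta_d1,
        rho=rho,
        mig_wd=mig_wd,
        mig_dw=mig_dw,
        mu=mu,
        t_years=t_years,
        scenario=prior.scenario,
    )


# ---------------------------------------------------------------------------
# event schedule


@dataclass(frozen=True)
class CoalescentSchedule:
    """The model translated to simulator units.

    msprime runs with haploid (ploidy-1) populations whose sizes are chosen
    so that a population of size N has per-bp diversity 2 N mu: the wild
    size is theta_w / (2 mu) (equal to 2 Ne_W of the diploid-convention
    scaling), time is in generations, and the scaled migration /
    recombination rates divide by 2 N_wild accordingly.
    """

    n_wild: float  # simulator wild population size (= 2 Ne_W)
    n_dom_present: float
    n_dom_founder: float
    growth_rate: float  # per generation, domestic population
    merge_time: float  # generations
    mig_backward_dom_to_wild: float  # per generation per lineage
    mig_backward_wild_to_dom: float
    recomb_per_bp: float
    mu: float
    # scaled-unit view (time in 4 Ne_W generations)
    T: float
    growth_rate_scaled: float  # g = ln(theta_d1 / theta_d0) / T

    def domestic_relative_size(self, tau: float) -> float:
        """Domestic size / wild size at scaled time tau in [0, T] (backwards)."""
        if tau > self.T:
            raise ValueError("domestic population does not exist before T")
        rel_present = self.n_dom_present / self.n_wild
        return rel_present * math.exp(-self.growth_rate_scaled * tau)

    def demography(self) -> msprime.Demography:
        dem = msprime.Demography()
        dem.add_population(name="wild", initial_size=self.n_wild)
        dem.add_population(
            name="dom", initial_size=self.n_dom_present, growth_rate=self.growth_rate
        )
        # msprime's source/dest are in the backward-time sense
        dem.set_migration_rate(
            source="dom", dest="wild", rate=self.mig_backward_dom_to_wild
        )
        dem.set_migration_rate(
            source="wild", dest="dom", rate=self.mig_backward_wild_to_dom
        )
        dem.add_mass_migration(
            time=self.merge_time, source="dom", dest="wild", proportion=1.0
        )
        dem.add_migration_rate_change(time=self.merge_time, rate=0.0)
        dem.add_population_parameters_change(
            time=self.merge_time, population="dom", growth_rate=0.0
        )
        return dem


def event_schedule(params: DemographicParams) -> CoalescentSchedule:
    """Convert one parameter draw to a coalescent event schedule."""
    n_wild = params.theta_w / (2.0 * params.mu)
    n_dom1 = params.theta_d1 / (2.0 * params.mu)
    n_dom0 = params.theta_d0 / (2.0 * params.mu)
    t = params.t_years
    growth = math.log(n_dom1 / n_dom0) / t if n_dom1 != n_dom0 else 0.0
    T = params.T
    growth_scaled = (
        math.log(params.theta_d1 / params.theta_d0) / T
        if params.theta_d1 != params.theta_d0
        else 0.0
    )
    # forward wild->dom gene flow moves domestic lineages into wild backwards
    return CoalescentSchedule(
        n_wild=n_wild,
        n_dom_present=n_dom1,
        n_dom_founder=n_dom0,
        growth_rate=growth,
        merge_time=t,
        mig_backward_dom_to_wild=params.mig_wd / (2.0 * n_wild),
        mig_backward_wild_to_dom=params.mig_dw / (2.0 * n_wild),
        recomb_per_bp=params.rho / (2.0 * n_wild),
        mu=params.mu,
        T=T,
        growth_rate_scaled=growth_scaled,
    )


# ---------------------------------------------------------------------------
# loci


@dataclass(frozen=True)
class LocusSpec:
    """Sample sizes and length of one locus."""

    name: str
    n_wild: int
    n_dom: int
    L: int

    def __post_init__(self) -> None:
        if self.n_wild < 0 or self.n_dom < 0 or self.n_wild + self.n_dom < 2:
            raise ValueError("need n_wild, n_dom >= 0 and n_wild + n_dom >= 2")
        if self.L < 1:
            raise ValueError("locus length must be >= 1 bp")

    @property
    def n(self) -> int:
        return self.n_wild + self.n_dom


@dataclass
class SimulatedLocus:
    """Binary haplotypes of one simulated locus.

    Rows are sampled chromosomes (wild block first, then domestic);
    columns are segregating sites at strictly increasing bp positions.
    """

    name: str
    haplotypes: np.ndarray  # (n, S) int8 in {0, 1}
    positions: np.ndarray  # float bp coordinates in (0, L)
    n_wild: int
    n_dom: int
    L: int

    @property
    def S(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def pop_labels(self) -> list[str]:
        return ["wild"] * self.n_wild + ["dom"] * self.n_dom

    def site_data(self) -> SiteData:
        return SiteData(self.haplotypes, self.L, self.positions)

    def population(self, pop: str) -> SiteData:
        if pop == "wild":
            rows = slice(0, self.n_wild)
        elif pop == "dom":
            rows = slice(self.n_wild, self.n_wild + self.n_dom)
        else:
            raise KeyError(pop)
        return SiteData(self.haplotypes[rows], self.L, self.positions)

    def site_pair(self) -> tuple[SiteData, SiteData]:
        """(wild, dom) views sharing the full column set of the locus."""
        return self.population("wild"), self.population("dom")


def _sample_sets(n_wild: int, n_dom: int) -> list[msprime.SampleSet]:
    sets = []
    if n_wild:
        sets.append(msprime.SampleSet(n_wild, population="wild", ploidy=1))
    if n_dom:
        sets.append(msprime.SampleSet(n_dom, population="dom", ploidy=1))
    return sets


def _msp_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


def _sim_ancestry(
    schedule: CoalescentSchedule,
    n_wild: int,
    n_dom: int,
    L: float,
    rng: np.random.Generator,
    num_replicates: int | None = None,
):
    return msprime.sim_ancestry(
        samples=_sample_sets(n_wild, n_dom),
        demography=schedule.demography(),
        ploidy=1,
        sequence_length=L,
        recombination_rate=schedule.recomb_per_bp,
        num_replicates=num_replicates,
        random_seed=_msp_seed(rng),
    )


def _poisson_mutations(
    ts: tskit.TreeSequence,
    mu: float,
    rng: np.random.Generator,
    until: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Infinite-sites mutations at rate mu; ((n, S) matrix, bp positions).

    With ``until`` set, mutations are restricted to [0, until) — used when
    a shorter locus is carved out of a longer simulated configuration.
    """
    if until is not None and until < ts.sequence_length:
        rate = msprime.RateMap(
            position=[0.0, float(until), ts.sequence_length],
            rate=[mu, 0.0],
        )
    else:
        rate = mu
    mts = msprime.sim_mutations(
        ts,
        rate=rate,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=_msp_seed(rng),
    )
    G = mts.genotype_matrix().T.astype(np.int8)
    return np.ascontiguousarray(G), mts.tables.sites.position.copy()


# ---------------------------------------------------------------------------
# fixed-S conditioning


def _fixed_s_candidates(
    ts: tskit.TreeSequence, focal_ids: np.ndarray
) -> dict[str, np.ndarray]:
    """Branches on which a mutation is polymorphic within the focal sample.

    Returns parallel arrays: sampling weight (branch length x span), derived
    count within the focal sample, node id, tree index and tree interval.
    """
    n_f = len(focal_ids)
    weights, counts, nodes, trees, lefts, rights = [], [], [], [], [], []
    for tree in ts.trees(tracked_samples=focal_ids):
        span = tree.span
        if span <= 0 or tree.num_edges == 0:
            continue
        left, right = tree.interval
        for u in tree.nodes():
            p = tree.parent(u)
            if p == tskit.NULL:
                continue
            k = tree.num_tracked_samples(u)
            if 0 < k < n_f:
                weights.append((tree.time(p) - tree.time(u)) * span)
                counts.append(k)
                nodes.append(u)
                trees.append(tree.index)
                lefts.append(left)
                rights.append(right)
    return {
        "weight": np.asarray(weights, dtype=float),
        "count": np.asarray(counts, dtype=int),
        "node": np.asarray(nodes, dtype=int),
        "tree": np.asarray(trees, dtype=int),
        "left": np.asarray(lefts, dtype=float),
        "right": np.asarray(rights, dtype=float),
    }


def fixed_s_focal_counts(
    ts: tskit.TreeSequence, focal_ids: np.ndarray, s: int, rng: np.random.Generator
) -> np.ndarray:
    """Derived-allele counts (within the focal sample) of s conditioned sites."""
    cand = _fixed_s_candidates(ts, focal_ids)
    prob = cand["weight"] / cand["weight"].sum()
    chosen = rng.choice(len(prob), size=s, replace=True, p=prob)
    return cand["count"][chosen]


def _fixed_s_matrix(
    ts: tskit.TreeSequence, focal_ids: np.ndarray, s: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """((n_samples, s) 0/1 matrix, bp positions) of s conditioned mutations."""
    cand = _fixed_s_candidates(ts, focal_ids)
    prob = cand["weight"] / cand["weight"].sum()
    chosen = rng.choice(len(prob), size=s, replace=True, p=prob)
    positions = rng.uniform(cand["left"][chosen], cand["right"][chosen])
    order = np.argsort(positions)
    chosen, positions = chosen[order], positions[order]

    sample_ids = ts.samples()
    G = np.zeros((len(sample_ids), s), dtype=np.int8)
    id_to_row = {int(sid): i for i, sid in enumerate(sample_ids)}
    needed = {int(t) for t in cand["tree"][chosen]}
    for tree in ts.trees():
        if tree.index not in needed:
            continue
        for j in np.flatnonzero(cand["tree"][chosen] == tree.index):
            node = int(cand["node"][chosen[j]])
            for sid in tree.samples(node):
                G[id_to_row[int(sid)], j] = 1
    return G, positions


_FOCAL_CHOICES = ("all", "wild", "dom")


def _focal_ids(spec: LocusSpec, focal: str) -> np.ndarray:
    if focal == "all":
        return np.arange(spec.n)
    if focal == "wild":
        if spec.n_wild < 2:
            raise ValueError("focal group 'wild' needs n_wild >= 2")
        return np.arange(spec.n_wild)
    if focal == "dom":
        if spec.n_dom < 2:
            raise ValueError("focal group 'dom' needs n_dom >= 2")
        return np.arange(spec.n_wild, spec.n)
    raise ValueError(f"focal must be one of {_FOCAL_CHOICES}")


def simulate_locus(
    params: DemographicParams,
    spec: LocusSpec,
    *,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    fixed_s: int | None = None,
    focal: str = "all",
) -> SimulatedLocus:
    """Simulate one locus under the domestication model.

    Without ``fixed_s``, mutations arise at rate ``mu`` under the
    infinite-sites model. With ``fixed_s``, exactly that many mutations are
    placed on branches of the ``focal`` subsample's marginal genealogy with
    probability proportional to branch length, so every simulated site is
    polymorphic within the focal group.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    schedule = event_schedule(params)
    ts = _sim_ancestry(schedule, spec.n_wild, spec.n_dom, spec.L, rng)
    if fixed_s is None:
        G, positions = _poisson_mutations(ts, params.mu, rng)
    elif fixed_s == 0:
        G = np.zeros((spec.n, 0), dtype=np.int8)
        positions = np.zeros(0)
    else:
        G, positions = _fixed_s_matrix(ts, _focal_ids(spec, focal), fixed_s, rng)
    return SimulatedLocus(
        name=spec.name,
        haplotypes=G,
        positions=positions,
        n_wild=spec.n_wild,
        n_dom=spec.n_dom,
        L=spec.L,
    )


def _restrict(
    G: np.ndarray,
    positions: np.ndarray,
    spec: LocusSpec,
    n_wild_max: int,
) -> SimulatedLocus:
    """Carve one locus out of the maximal sample/length configuration.

    Rows are subset by coalescent exchangeability and columns restricted to
    the locus length by spatial consistency of the ancestral recombination
    graph; columns monomorphic within the kept rows are dropped.
    """
    rows = np.r_[0 : spec.n_wild, n_wild_max : n_wild_max + spec.n_dom]
    keep = positions < spec.L
    sub = G[np.ix_(rows, np.flatnonzero(keep))]
    seg = (sub.min(axis=0) == 0) & (sub.max(axis=0) == 1)
    return SimulatedLocus(
        name=spec.name,
        haplotypes=np.ascontiguousarray(sub[:, seg]),
        positions=positions[keep][seg],
        n_wild=spec.n_wild,
        n_dom=spec.n_dom,
        L=spec.L,
    )


def simulate_dataset(
    params: DemographicParams,
    specs: list[LocusSpec],
    *,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    batch: bool = True,
    summarize: bool = True,
):
    """Simulate all loci under one parameter draw.

    Genealogies are independent across loci (unlinked loci); per-bp rates
    are shared. With ``batch=True`` (default), all loci come from one
    msprime call at the maximal (n_wild, n_dom, L) configuration and each
    locus is obtained by subsampling lineages and restricting the sequence
    interval — distributionally identical to per-locus simulation and much
    faster. Returns ``(loci, MultiLocusSummary)`` (the summary is ``None``
    if ``summarize=False``).
    """
    from milletabc.twopop import multilocus_summary, summarize_locus

    if not specs:
        raise ValueError("need at least one locus")
    if rng is None:
        rng = np.random.default_rng(seed)
    schedule = event_schedule(params)
    loci: list[SimulatedLocus] = []
    if batch:
        n_w = max(s.n_wild for s in specs)
        n_d = max(s.n_dom for s in specs)
        l_max = max(s.L for s in specs)
        reps = _sim_ancestry(
            schedule, n_w, n_d, l_max, rng, num_replicates=len(specs)
        )
        for spec, ts in zip(specs, reps):
            G, positions = _poisson_mutations(
                ts, params.mu, rng, until=float(spec.L)
            )
            loci.append(_restrict(G, positions, spec, n_w))
    else:
        for spec in specs:
            loci.append(simulate_locus(params, spec, rng=rng))
    if not summarize:
        return loci, None
    pairs = [
        summarize_locus(locus.name, *locus.site_pair())
        for locus in loci
    ]
    return loci, multilocus_summary(pairs)


# ---------------------------------------------------------------------------
# ms-style text interchange


def write_ms(loci: list[SimulatedLocus], path) -> None:
    """Write loci as ms-style text (//, segsites:, positions:, 0/1 rows)."""
    with open(path, "w") as fh:
        fh.write("milletabc-ms\n\n")
        for locus in loci:
            fh.write("//\n")
            fh.write(f"segsites: {locus.S}\n")
            if locus.S:
                frac = " ".join(f"{p / locus.L:.6f}" for p in locus.positions)
                fh.write(f"positions: {frac}\n")
                for row in locus.haplotypes:
                    fh.write("".join(str(int(v)) for v in row) + "\n")
            fh.write("\n")


def read_ms(path, specs: list[LocusSpec]) -> list[SimulatedLocus]:
    """Read ms-style text back into loci (specs give sizes and lengths)."""
    blocks: list[list[str]] = []
    with open(path) as fh:
        block: list[str] | None = None
        for line in fh:
            line = line.strip()
            if line == "//":
                block = []
                blocks.append(block)
            elif block is not None and line:
                block.append(line)
    if len(blocks) != len(specs):
        raise ValueError(f"{len(blocks)} replicates but {len(specs)} specs")
    loci = []
    for spec, block in zip(specs, blocks):
        s = int(block[0].split(":")[1])
        if s == 0:
            G = np.zeros((spec.n, 0), dtype=np.int8)
            positions = np.zeros(0)
        else:
            positions = np.array(
                [float(x) for x in block[1].split(":")[1].split()]
            ) * spec.L
            G = np.array(
                [[int(c) for c in row] for row in block[2 : 2 + spec.n]],
                dtype=np.int8,
            )
        loci.append(
            SimulatedLocus(
                name=spec.name,
                haplotypes=G,
                positions=positions,
                n_wild=spec.n_wild,
                n_dom=spec.n_dom,
                L=spec.L,
            )
        )
    return loci
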