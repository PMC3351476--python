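"""Study-shaped synthetic datasets.

Generates FASTA alignments plus a population map emulating the study
design — eight unlinked sequence-tagged-site loci with the published
per-locus sample sizes and lengths — simulated under the domestication
model with known ("truth") parameters, so that every pipeline stage can be
exercised and validated end to end without the original sequence data.
Also provides caricature loci used as positive/negative controls for the
frequency-spectrum tests: a star-genealogy locus (every variant a
singleton, strongly negative Tajima's D, sweep-like) and an
intermediate-frequency locus (every variant at ~50%, positive D).

Binary simulated haplotypes are encoded as nucleotides with one ancestral
and one derived base per site (infinite-sites, biallelic); the monomorphic
background is a fixed reference sequence drawn once per locus. No indels
are synthesized, so complete deletion keeps every site (L_eff = L) and
worked examples stay exact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from milletabc.alignment import Alignment, write_fasta, write_popmap
from milletabc.simulate import (
    DemographicParams,
    LocusSpec,
    SimulatedLocus,
    simulate_dataset,
)

_BASES = "ACGT"


def _integer_positions(
    positions: np.ndarray, L: int, rng: np.random.Generator
) -> np.ndarray:
    """Map continuous bp positions to distinct 0-based integer sites.

    Uses ceil(x) - 1; collisions (two mutations in the same bp) are
    resolved by resampling the later position uniformly, preserving the
    infinite-sites assumption of the nucleotide encoding.
    """
    taken: set[int] = set()
    out = np.empty(len(positions), dtype=int)
    for i, p in enumerate(positions):
        site = min(int(np.ceil(p)) - 1 if p > 0 else 0, L - 1)
        while site in taken:
            site = int(rng.integers(0, L))
        taken.add(site)
        out[i] = site
    return out


def binary_to_alignment(
    matrix: np.ndarray,
    sites: np.ndarray,
    L: int,
    ids: list[str],
    rng: np.random.Generator,
) -> Alignment:
    """Encode a 0/1 haplotype matrix as a nucleotide alignment."""
    n = matrix.shape[0]
    ref = rng.integers(0, 4, size=L)
    rows = np.tile(ref, (n, 1))
    for j, site in enumerate(sites):
        anc = int(rng.integers(0, 4))
        der = (anc + int(rng.integers(1, 4))) % 4
        rows[:, site] = np.where(matrix[:, j] == 1, der, anc)
    lut = np.frombuffer(_BASES.encode(), dtype=np.uint8)
    seqs = [bytes(lut[r]).decode() for r in rows]
    return Alignment(ids=list(ids), seqs=seqs)


def locus_to_alignment(
    locus: SimulatedLocus, rng: np.random.Generator
) -> tuple[Alignment, dict[str, str]]:
    """(nucleotide alignment, popmap entries) for one simulated locus."""
    sites = _integer_positions(locus.positions, locus.L, rng)
    ids = [f"wild_{i + 1:03d}" for i in range(locus.n_wild)] + [
        f"dom_{i + 1:03d}" for i in range(locus.n_dom)
    ]
    aln = binary_to_alignment(locus.haplotypes, sites, locus.L, ids, rng)
    popmap = {sid: ("wild" if sid.startswith("wild") else "dom") for sid in ids}
    return aln, popmap


@dataclass
class StudyFixture:
    """A written synthetic dataset plus the truth needed to re-simulate it."""

    params: DemographicParams
    specs: list[LocusSpec]
    seed: int
    outdir: Path
    fasta_paths: dict[str, Path]
    popmap_path: Path
    truth_path: Path
    loci: list[SimulatedLocus]


def make_fixture(
    params: DemographicParams,
    specs: list[LocusSpec],
    seed: int,
    outdir: str | Path,
) -> StudyFixture:
    """Simulate every locus and write FASTA files, popmap and truth record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    loci, _ = simulate_dataset(params, specs, rng=rng, summarize=False)
    fasta_paths: dict[str, Path] = {}
    popmap: dict[str, str] = {}
    for locus in loci:
        aln, entries = locus_to_alignment(locus, rng)
        path = outdir / f"{locus.name}.fasta"
        write_fasta(aln, path)
        fasta_paths[locus.name] = path
        popmap.update(entries)
    popmap_path = outdir / "popmap.tsv"
    write_popmap(popmap, popmap_path)
    truth_path = outdir / "truth.json"
    truth = {
        "params": params.as_dict() | {"scenario": params.scenario},
        "specs": [asdict(s) for s in specs],
        "seed": seed,
    }
    truth_path.write_text(json.dumps(truth, indent=2) + "\n")
    return StudyFixture(
        params=params,
        specs=specs,
        seed=seed,
        outdir=outdir,
        fasta_paths=fasta_paths,
        popmap_path=popmap_path,
        truth_path=truth_path,
        loci=loci,
    )


def star_locus(n: int, s: int, seed: int, L: int | None = None) -> Alignment:
    """Star-genealogy caricature: every variant is a singleton.

    Each of the ``s`` mutations is assigned to one random leaf, the
    extreme of a star-shaped genealogy (as after a complete sweep or an
    explosive expansion); Tajima's D and F* are strongly negative.
    """
    if n < 3 or s < 1:
        raise ValueError("need n >= 3 and s >= 1")
    L = 5 * s if L is None else L
    rng = np.random.default_rng(seed)
    matrix = np.zeros((n, s), dtype=np.int8)
    carriers = rng.integers(0, n, size=s)
    matrix[carriers, np.arange(s)] = 1
    sites = np.sort(rng.choice(L, size=s, replace=False))
    ids = [f"seq_{i + 1:03d}" for i in range(n)]
    return binary_to_alignment(matrix, sites, L, ids, rng)


def intermediate_frequency_locus(
    n: int, s: int, seed: int, L: int | None = None
) -> Alignment:
    """Balancing-selection caricature: every variant at frequency n//2.

    Each mutation is carried by ``n // 2`` random sequences, producing an
    excess of intermediate-frequency alleles and positive Tajima's D.
    """
    if n < 4 or s < 1:
        raise ValueError("need n >= 4 and s >= 1")
    L = 5 * s if L is None else L
    rng = np.random.default_rng(seed)
    matrix = np.zeros((n, s), dtype=np.int8)
    for j in range(s):
        matrix[rng.choice(n, size=n // 2, replace=False), j] = 1
    sites = np.sort(rng.choice(L, size=s, replace=False))
    ids = [f"seq_{i + 1:03d}" for i in range(n)]
    return binary_to_alignment(matrix, sites, L, ids, rng)
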