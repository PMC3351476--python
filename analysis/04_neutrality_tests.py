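"""Posterior-predictive neutrality tests under the fitted demography.

Uses the posterior sample written by 03_abc_fit.py in two ways:

1. positive/negative controls — a star-genealogy locus (sweep-like, all
   variants singletons) and an intermediate-frequency locus tested as
   domestic candidate genes, plus a locus simulated from the posterior
   itself (which must NOT reject);
2. the published candidate-gene observations (PgHd3a, PgDwarf8, PgPHYC:
   observed Tajima's D and Fu & Li's F* per group with S fixed to the
   printed segregating-site counts) re-tested against nulls simulated
   under our fitted demography.

Writes results/neutrality_controls.tsv and results/neutrality_candidates.tsv.

Run:  python analysis/04_neutrality_tests.py [seed] [n_sims]
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from milletabc.inference import PARAM_NAMES, PosteriorSample
from milletabc.neutrality import (
    neutrality_report,
    test_locus,
    test_observed_statistic,
)
from milletabc.simulate import LocusSpec, simulate_locus
from milletabc.studydata import candidate_gene_table
from milletabc.synthetic import intermediate_frequency_locus, star_locus

ROOT = Path(__file__).resolve().parents[1]


def load_posterior() -> PosteriorSample:
    df = pd.read_csv(ROOT / "results" / "abc" / "posterior_sample.tsv", sep="\t")
    return PosteriorSample(
        params=df[PARAM_NAMES],
        weights=df["weight"].to_numpy(),
        distances=np.zeros(len(df)),
        method="loclinear",
    )


def main(seed: int = 1, n_sims: int = 2000) -> None:
    post = load_posterior()
    rng = np.random.default_rng(seed)
    results = []

    spec = LocusSpec("control", n_wild=14, n_dom=40, L=900)
    star = star_locus(40, 25, seed=seed, L=900)
    results += test_locus(star, post, spec, focal="dom", n_sims=n_sims,
                          rng=rng, name="star_control")
    inter = intermediate_frequency_locus(40, 12, seed=seed, L=900)
    results += test_locus(inter, post, spec, focal="dom", n_sims=n_sims,
                          rng=rng, name="intermediate_control")
    neutral = simulate_locus(post.draw(rng), spec, rng=rng)
    dom = neutral.population("dom")
    from milletabc.popgen import one_pop_summary

    if one_pop_summary(dom).S >= 1:
        results += test_locus(dom, post, spec, focal="dom", n_sims=n_sims,
                              rng=rng, name="posterior_draw_control")
    controls = neutrality_report(results)
    controls.to_csv(ROOT / "results" / "neutrality_controls.tsv",
                    sep="\t", index=False)
    print("controls:")
    print(controls.to_string(index=False))

    # published candidate-gene statistics vs our fitted null
    cand_results = []
    genes = candidate_gene_table()
    focal_sizes = {"dom": "dom", "early": "dom", "late": "dom", "wild": "wild"}
    for _, row in genes.iterrows():
        group = row["group"]
        if focal_sizes[group] == "dom":
            spec_g = LocusSpec(row["gene"], n_wild=14, n_dom=int(row["n"]),
                               L=int(row["length"]))
            focal = "dom"
        else:
            spec_g = LocusSpec(row["gene"], n_wild=int(row["n"]), n_dom=30,
                               L=int(row["length"]))
            focal = "wild"
        for stat, col in (("D", "tajimas_d"), ("Fstar", "fu_li_fstar")):
            cand_results.append(
                test_observed_statistic(
                    f"{row['gene']}:{group}", float(row[col]), stat, post,
                    spec_g, focal, s_obs=int(row["S"]), n_sims=n_sims,
                    seed=int(rng.integers(1, 2**31)),
                )
            )
    cand = neutrality_report(cand_results)
    cand.to_csv(ROOT / "results" / "neutrality_candidates.tsv",
                sep="\t", index=False)
    print("\npublished candidate-gene statistics vs fitted null:")
    print(cand.to_string(index=False))


if __name__ == "__main__":
    main(
        int(sys.argv[1]) if len(sys.argv) > 1 else 1,
        int(sys.argv[2]) if len(sys.argv) > 2 else 2000,
    )
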