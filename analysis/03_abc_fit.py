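"""Fit the domestication model by ABC on the synthetic dataset.

Builds reference tables under the two scenarios (with and without
wild-domestic gene flow), chooses between them by weighted logistic
regression, and estimates parameter posteriors for the chosen scenario by
rejection plus local-linear adjustment. Emits the posterior-median /
95%-HPD table, the posterior sample (reused by the neutrality driver),
derived quantities (domestication time in years, bottleneck and expansion
ratios) and marginal posterior density plots.

Scaled down relative to the study (default 4000 simulations per scenario
vs 1e6, keeping 10%); pass a different size as the second argument.

Run:  python analysis/03_abc_fit.py [seed] [n_sims]
"""

import json
import sys
from pathlib import Path

import numpy as np

from milletabc.alignment import read_fasta, read_popmap, split_populations
from milletabc.inference import (
    abc_reject,
    build_reference_table,
    derived_quantities,
    estimates_table,
    model_choice,
    posterior_summary,
    regression_adjust,
)
from milletabc.simulate import WITHOUT_MIGRATION, PriorConfig
from milletabc.studydata import sts_locus_specs
from milletabc.twopop import multilocus_summary, summarize_locus

ROOT = Path(__file__).resolve().parents[1]


def observed_summary():
    fixture_dir = ROOT / "results" / "fixture"
    popmap = read_popmap(fixture_dir / "popmap.tsv")
    pairs = []
    for fasta in sorted(fixture_dir.glob("*.fasta")):
        pops = split_populations(read_fasta(fasta), popmap)
        pairs.append(summarize_locus(fasta.stem, pops["wild"], pops["dom"]))
    return multilocus_summary(pairs)


def main(seed: int = 1, n_sims: int = 4000) -> None:
    outdir = ROOT / "results" / "abc"
    outdir.mkdir(parents=True, exist_ok=True)
    specs = sts_locus_specs()
    obs = observed_summary()

    print(f"building reference tables ({n_sims} simulations per scenario)...")
    table_mig = build_reference_table(
        PriorConfig(), specs, n_sims, seed=seed, progress=True
    )
    table_nomig = build_reference_table(
        PriorConfig(scenario=WITHOUT_MIGRATION), specs, n_sims,
        seed=seed + 1, progress=True,
    )

    n_keep = max(n_sims // 10, 100)
    choice = model_choice(obs, table_mig, table_nomig, n_keep=2 * n_keep)
    print("scenario posterior probabilities:")
    for scen, p in choice.posterior_prob.items():
        print(f"  {scen}: {p:.3f}")
    best = max(choice.posterior_prob, key=choice.posterior_prob.get)
    table = table_mig if best == "with_migration" else table_nomig
    print(f"fitting parameters under the '{best}' scenario")

    rej = abc_reject(obs, table, n_keep=n_keep)
    post = regression_adjust(obs, table, rej, method="loclinear")
    est = estimates_table(posterior_summary(post))
    est.to_csv(outdir / "estimates.tsv", sep="\t", index=False)
    print(est.to_string(index=False))

    dq = derived_quantities(post)
    summary = {
        "scenario_posterior": choice.posterior_prob,
        "domestication_time_years": dq.t_years,
        "bottleneck_ratio": dq.bottleneck_ratio,
        "expansion_ratio": dq.expansion_ratio,
        "n_sims_per_scenario": n_sims,
        "n_keep": n_keep,
        "seed": seed,
    }
    (outdir / "fit_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"domestication time ~ {dq.t_years:.0f} years; "
          f"bottleneck theta_D0/theta_W = {dq.bottleneck_ratio:.3g}; "
          f"expansion theta_D1/theta_D0 = {dq.expansion_ratio:.3g}")

    # persist the posterior sample for the neutrality driver
    sample = post.params.copy()
    sample["weight"] = post.weights
    sample.to_csv(outdir / "posterior_sample.tsv", sep="\t", index=False)

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 3, figsize=(11, 6))
        for ax, name in zip(
            axes.ravel(), ["theta_w", "theta_d0", "theta_d1", "T", "mu", "rho"]
        ):
            vals = np.log10(post.params[name].to_numpy(dtype=float))
            ax.hist(vals, bins=30, weights=post.weights, density=True)
            ax.set_xlabel(f"log10 {name}")
        fig.tight_layout()
        fig.savefig(outdir / "posteriors.png", dpi=120)
        print(f"wrote marginal posterior plots to {outdir / 'posteriors.png'}")
    except Exception as err:  # plotting is cosmetic
        print(f"skipped plots: {err}")


if __name__ == "__main__":
    main(
        int(sys.argv[1]) if len(sys.argv) > 1 else 1,
        int(sys.argv[2]) if len(sys.argv) > 2 else 4000,
    )
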