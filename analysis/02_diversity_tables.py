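"""Per-locus diversity statistics and wild/domestic differentiation.

Reads the synthetic dataset written by 01_make_dataset.py and produces
the per-locus diversity table (segregating sites, singletons, pi, the
Watterson estimator, Tajima's D per population) and per-locus Hudson Fst
with a permutation test — the synthetic twins of the study's STS
diversity and differentiation tables. Writes results/diversity_sts.tsv
and results/fst_sts.tsv.

Run:  python analysis/02_diversity_tables.py
"""

from pathlib import Path

import pandas as pd

from milletabc.alignment import read_fasta, read_popmap, split_populations
from milletabc.twopop import fst_permutation_test, summarize_locus

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    fixture_dir = ROOT / "results" / "fixture"
    popmap = read_popmap(fixture_dir / "popmap.tsv")
    rows, fst_rows = [], []
    for fasta in sorted(fixture_dir.glob("*.fasta")):
        locus = fasta.stem
        pops = split_populations(read_fasta(fasta), popmap)
        lp = summarize_locus(locus, pops["wild"], pops["dom"])
        for group in ("dom", "wild"):
            s = getattr(lp, group)
            rows.append({
                "locus": locus, "group": group, "n": s.n, "L_eff": s.L_eff,
                "S": s.S, "Sin": s.Sin, "LSin": s.LSin,
                "pi_e3": round(s.pi * 1e3, 2),
                "theta_e3": round(s.thetaW * 1e3, 2),
                "tajimas_d": None if s.D is None else round(s.D, 2),
            })
        p = fst_permutation_test(pops["wild"], pops["dom"],
                                 n_perm=1000, seed=1)
        fst_rows.append({
            "locus": locus, "Fst": None if lp.two.Fst is None
            else round(lp.two.Fst, 3), "perm_p": round(p, 4),
        })
    df = pd.DataFrame(rows)
    fst = pd.DataFrame(fst_rows)
    df.to_csv(ROOT / "results" / "diversity_sts.tsv", sep="\t", index=False)
    fst.to_csv(ROOT / "results" / "fst_sts.tsv", sep="\t", index=False)

    dom = df[df["group"] == "dom"].set_index("locus")
    wild = df[df["group"] == "wild"].set_index("locus")
    ratio = dom["pi_e3"] / wild["pi_e3"]
    print(df.to_string(index=False))
    print(f"\nmean pi (dom)  = {dom['pi_e3'].mean():.2f} e-3")
    print(f"mean pi (wild) = {wild['pi_e3'].mean():.2f} e-3")
    print(f"mean dom/wild pi ratio = {ratio.mean():.2f}")
    print(f"mean Fst = {fst['Fst'].mean():.3f}")


if __name__ == "__main__":
    main()
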