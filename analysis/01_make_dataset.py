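"""Generate the study-shaped synthetic dataset.

Simulates the eight STS reference loci (published sample sizes and
lengths) under the domestication model at the fitted posterior medians,
with moderate bidirectional wild-domestic gene flow, and writes per-locus
FASTA alignments, the population map and the truth record to
results/fixture/. Downstream drivers treat these files exactly as the
study treated its sequence data.

Run:  python analysis/01_make_dataset.py [seed]
"""

import sys
from pathlib import Path

from milletabc.studydata import fitted_params, sts_locus_specs
from milletabc.synthetic import make_fixture

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 1) -> None:
    outdir = ROOT / "results" / "fixture"
    params = fitted_params()
    fixture = make_fixture(params, sts_locus_specs(), seed=seed, outdir=outdir)
    print(f"simulated {len(fixture.loci)} loci at the fitted medians:")
    print(f"  theta_w={params.theta_w}, theta_d0={params.theta_d0}, "
          f"theta_d1={params.theta_d1}, T={params.T:.4f}")
    for locus in fixture.loci:
        print(f"  {locus.name}: n_wild={locus.n_wild}, n_dom={locus.n_dom}, "
              f"L={locus.L}, S={locus.S}")
    print(f"wrote FASTA + popmap + truth.json to {outdir}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
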