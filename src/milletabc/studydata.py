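"""Published study constants used as inputs.

The study design (per-locus sample sizes and lengths of the eight
sequence-tagged-site loci), the printed per-locus diversity values, the
candidate flowering-gene observations, and the reported posterior medians
of the domestication model. These are inputs to worked examples, synthetic
data generation and the analysis drivers; nothing in the package derives
them at run time.
"""

from __future__ import annotations

import pandas as pd

# Eight STS reference loci: name, linkage group, length (bp), and per-group
# printed diversity values. pi and theta are per-site values x 1e3.
_STS_ROWS = [
    # name, group, n, L, S, Sin, specific, pi_e3, theta_e3, LSin, D
    ("STS306", "dom", 51, 563, 5, 2, 1, 2.13, 1.97, 2, 0.20),
    ("STS306", "wild", 17, 563, 5, 1, 1, 2.95, 2.63, 1, 0.40),
    ("STS344", "dom", 43, 710, 33, 15, 20, 10.1, 11.0, 12, -0.27),
    ("STS344", "wild", 12, 710, 20, 6, 6, 9.5, 9.5, 2, -0.02),
    ("STS359", "dom", 49, 440, 15, 6, 8, 7.43, 8.86, 6, -0.20),
    ("STS359", "wild", 18, 440, 15, 6, 6, 9.53, 10.72, 4, -0.46),
    ("STS476", "dom", 61, 752, 10, 5, 6, 2.09, 2.86, 5, -0.74),
    ("STS476", "wild", 15, 752, 14, 8, 9, 4.03, 5.92, 4, -1.26),
    ("STS521", "dom", 46, 617, 29, 16, 16, 5.34, 11.56, 11, -1.80),
    ("STS521", "wild", 19, 617, 25, 21, 10, 6.18, 12.35, 10, -1.95),
    ("STS713", "dom", 51, 1065, 30, 18, 20, 2.87, 6.62, 12, -1.87),
    ("STS713", "wild", 22, 1065, 32, 16, 19, 6.45, 8.25, 9, -0.83),
    ("STS738", "dom", 29, 1995, 64, 47, 48, 4.93, 8.32, 21, -1.54),
    ("STS738", "wild", 12, 1995, 42, 26, 24, 5.33, 7.07, 10, -1.12),
    ("STS870", "dom", 49, 744, 36, 18, 28, 8.0, 12.87, 13, -1.19),
    ("STS870", "wild", 20, 744, 23, 14, 9, 5.78, 8.94, 7, -1.36),
]

_STS_COLUMNS = [
    "locus",
    "group",
    "n",
    "length",
    "S",
    "Sin",
    "specific_sites",
    "pi_e3",
    "theta_e3",
    "LSin",
    "tajimas_d",
]


def sts_reference_table() -> pd.DataFrame:
    """Printed per-locus diversity values for the eight STS loci."""
    return pd.DataFrame(_STS_ROWS, columns=_STS_COLUMNS)


# Candidate flowering genes: observed per-group values, including the
# frequency-spectrum test statistics tested against the fitted demography.
_CANDIDATE_ROWS = [
    # gene, group, n, L, S, Sin, pi_e3, theta_e3, LSin, D, Fstar
    ("PgHd3a", "dom", 59, 918, 47, 42, 2.48, 11.2, 23, -2.62, -5.92),
    ("PgHd3a", "early", 26, 918, 22, 19, 2.40, 6.38, 9, -2.26, -3.69),
    ("PgHd3a", "late", 28, 918, 25, 22, 2.59, 7.07, 14, -2.30, -4.12),
    ("PgHd3a", "wild", 14, 918, 17, 11, 3.47, 5.88, 7, -1.69, -1.69),
    ("PgDwarf8", "dom", 33, 1233, 46, 40, 3.15, 9.73, 15, -2.47, -4.48),
    ("PgDwarf8", "early", 14, 1233, 14, 11, 2.40, 3.70, 7, -1.39, -2.08),
    ("PgDwarf8", "late", 16, 1233, 32, 29, 3.81, 8.02, 7, -2.18, -3.17),
    ("PgDwarf8", "wild", 12, 1233, 56, 26, 11.22, 15.26, 10, -1.22, -0.76),
    ("PgPHYC", "dom", 38, 823, 24, 13, 5.67, 6.96, 6, -0.63, -1.89),
    ("PgPHYC", "early", 18, 823, 20, 10, 6.39, 7.07, 4, -0.37, -0.93),
    ("PgPHYC", "late", 17, 823, 10, 2, 4.78, 3.60, 1, 1.20, 0.81),
    ("PgPHYC", "wild", 15, 823, 13, 6, 3.91, 4.86, 3, -0.77, -0.73),
]


def candidate_gene_table() -> pd.DataFrame:
    """Observed diversity and test statistics for the candidate genes."""
    return pd.DataFrame(
        _CANDIDATE_ROWS,
        columns=[
            "gene",
            "group",
            "n",
            "length",
            "S",
            "Sin",
            "pi_e3",
            "theta_e3",
            "LSin",
            "tajimas_d",
            "fu_li_fstar",
        ],
    )


#: reported posterior medians of the with-migration domestication model
POSTERIOR_MEDIANS = {
    "theta_w": 0.0082,
    "theta_d0": 9.79e-5,
    "theta_d1": 0.1409,
    "T": 0.0704,
    "mu": 6.50e-8,
}

#: reported 95% highest-posterior-density intervals (same model)
POSTERIOR_HPD = {
    "theta_w": (0.0042, 0.0142),
    "theta_d0": (6.05e-7, 0.0017),
    "theta_d1": (0.0060, 4.5243),
    "T": (0.0133, 0.4524),
    "mu": (1.39e-8, 3.41e-7),
}


def sts_locus_specs():
    """The eight STS loci as simulation specs (sample sizes and lengths)."""
    from milletabc.simulate import LocusSpec

    df = sts_reference_table()
    specs = []
    for locus in df["locus"].unique():
        sub = df[df["locus"] == locus]
        specs.append(
            LocusSpec(
                name=locus,
                n_wild=int(sub.loc[sub["group"] == "wild", "n"].iloc[0]),
                n_dom=int(sub.loc[sub["group"] == "dom", "n"].iloc[0]),
                L=int(sub["length"].iloc[0]),
            )
        )
    return specs


def fitted_params(mig_wd: float = 1.0, mig_dw: float = 1.0, rho: float = 0.0082):
    """Domestication-model parameters at the reported posterior medians.

    The migration rates and the per-bp recombination rate were not point
    estimated (their posteriors track the priors); the defaults here are a
    moderate crop-wild gene-flow level (4Nm = 1 in each direction) and
    rho = theta_W, a plausible ratio for an outcrossing grass.
    """
    from milletabc.simulate import DemographicParams

    m = POSTERIOR_MEDIANS
    t_years = m["T"] * m["theta_w"] / m["mu"]
    return DemographicParams(
        theta_w=m["theta_w"],
        theta_d0=m["theta_d0"],
        theta_d1=m["theta_d1"],
        rho=rho,
        mig_wd=mig_wd,
        mig_dw=mig_dw,
        mu=m["mu"],
        t_years=t_years,
        scenario="with_migration",
    )
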