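from __future__ import annotations

import numpy as np
import pytest

from milletabc.alignment import Alignment

BASES = "ACGT"


def random_alignment(
    rng: np.random.Generator,
    n: int,
    L: int,
    n_snps: int | None = None,
    gap_prob: float = 0.0,
) -> Alignment:
    """Random alignment: a reference with planted biallelic SNPs.

    With ``gap_prob`` > 0, random positions are replaced by '-' or 'N'.
    """
    ref = rng.integers(0, 4, size=L)
    rows = np.tile(ref, (n, 1))
    if n_snps is None:
        n_snps = int(rng.integers(0, max(L // 3, 1)))
    snp_sites = rng.choice(L, size=min(n_snps, L), replace=False)
    for j in snp_sites:
        derived = (ref[j] + rng.integers(1, 4)) % 4
        n_der = int(rng.integers(1, n))
        carriers = rng.choice(n, size=n_der, replace=False)
        rows[carriers, j] = derived
    seqs = []
    for i in range(n):
        chars = [BASES[c] for c in rows[i]]
        if gap_prob > 0:
            for j in range(L):
                if rng.random() < gap_prob:
                    chars[j] = "-" if rng.random() < 0.5 else "N"
        seqs.append("".join(chars))
    return Alignment(ids=[f"s{i}" for i in range(n)], seqs=seqs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
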