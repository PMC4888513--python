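"""Shared fixtures: small synthetic datasets and codon-model helpers."""

import numpy as np
import pytest

from orphanscan import SimulationConfig, generate_dataset
from orphanscan.codonmodel import uniform_frequencies


@pytest.fixture(scope="session")
def uniform_pi():
    return uniform_frequencies()


@pytest.fixture(scope="session")
def small_dataset():
    """A 40-gene synthetic study shared by IO/cluster/pipeline tests."""
    cfg = SimulationConfig(n_conserved=24, n_orphan=16, seed=42)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_dataset_dir(small_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("synth")
    small_dataset.write(out)
    return out


def expm_oracle(omega, kappa, pi):
    """Independent GY94 rate matrix built with plain loops (test oracle)."""
    import itertools

    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1]
    sense = sorted(
        c
        for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
        if c not in table.stop_codons
    )
    aa = {c: table.forward_table[c] for c in sense}
    purines = {"A", "G"}
    n = len(sense)
    Q = np.zeros((n, n))
    for i, a in enumerate(sense):
        for j, b in enumerate(sense):
            if i == j:
                continue
            diffs = [p for p in range(3) if a[p] != b[p]]
            if len(diffs) != 1:
                continue
            p = diffs[0]
            rate = pi[j]
            if (a[p] in purines) == (b[p] in purines):
                rate *= kappa
            if aa[a] != aa[b]:
                rate *= omega
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(np.asarray(pi) * np.diag(Q)).sum()
    return sense, Q / scale
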