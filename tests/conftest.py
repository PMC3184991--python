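from collections import Counter

import pytest

from haplopars.records import Haplotype, HaplotypeTable
from haplopars.simulate import SimulationConfig, simulate_complex


def make_table(seqs, counts=None, countries=None):
    """Hand-build a HaplotypeTable from raw sequences."""
    counts = counts or [1] * len(seqs)
    haps = []
    for i, (seq, n) in enumerate(zip(seqs, counts)):
        cc = countries[i] if countries else Counter({"unknown": n})
        haps.append(
            Haplotype(
                code=f"H{i + 1:03d}",
                representative_id=f"ACC{i + 1:04d}",
                seq=seq,
                count=n,
                countries=cc,
            )
        )
    return HaplotypeTable(haplotypes=haps, L=len(seqs[0]))


@pytest.fixture(scope="session")
def sim_default():
    """One seeded default-condition simulation shared across tests."""
    return simulate_complex(SimulationConfig(seed=2024))


@pytest.fixture
def small_star_table():
    """A 5-haplotype star: hub plus four 1-step leaves."""
    hub = "ACGTACGTACGTACGTACGT"
    leaves = [hub[:i] + ("T" if hub[i] != "T" else "A") + hub[i + 1 :] for i in (0, 5, 10, 15)]
    return make_table([hub] + leaves, counts=[10, 1, 1, 1, 1])
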