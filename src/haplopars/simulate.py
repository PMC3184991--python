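"""Synthetic species-complex generator with known ground truth.

Emulates the structure of a barcode dataset for a cryptic species complex
of global invaders: K well-separated haplotype clusters (between-cluster
step distance above the parsimony connection limit), within-cluster
unit-step star/chain radiation around a hub haplotype, strongly skewed
per-haplotype record counts (one hub dominating, as a single haplotype does
in the real invaders), and home/invaded country labels producing home-only,
invaded-only and shared haplotypes.  Substitutions are drawn with a
configurable transition:transversion ratio (default 2:1) so the K2P model
exercises both its P and Q terms; sequences contain no gaps and no stop
codons in frame 1 under the invertebrate mitochondrial code.  Mutated sites
are globally unique across the complex, so planted within- and
between-cluster step distances are exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .records import SequenceRecord

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass
class SimulationConfig:
    """Study-condition parameters of the generator.

    Defaults reflect the regime of the real barcode complex scaled to desk
    size: a 657 bp window, clusters separated by 40 steps (~6% divergence,
    far beyond the 95% connection limit of 10 steps and the 3.5% species
    threshold), shallow within-cluster radiation, and a hub haplotype
    carrying 80% of its species' records (the real invaders concentrate
    ~80% of records on one to three haplotypes).
    """

    n_species: int = 5
    L: int = 657
    within_max_steps: int = 8
    between_min_steps: int = 40
    haplotypes_per_species: int = 8
    records_per_species: int = 120
    count_skew: float = 0.8
    invaded_fraction: float = 0.6
    topology: str = "star"
    ts_tv_ratio: float = 2.0
    n_home_countries: int = 3
    n_invaded_countries: int = 4
    translation_table: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.between_min_steps <= self.within_max_steps:
            raise ValueError("between_min_steps must exceed within_max_steps")
        if self.L < self.between_min_steps:
            raise ValueError("alignment shorter than between_min_steps")
        if not 0.0 < self.count_skew <= 1.0:
            raise ValueError("count_skew must lie in (0, 1]")
        if self.topology not in ("star", "chain", "mixed"):
            raise ValueError("topology must be star, chain or mixed")
        if self.topology != "star" and self.haplotypes_per_species > self.within_max_steps + 1:
            raise ValueError(
                "chain topology needs haplotypes_per_species <= within_max_steps + 1"
            )
        if self.records_per_species < self.haplotypes_per_species:
            raise ValueError("records_per_species must cover every haplotype")
        per_hap = (
            self.haplotypes_per_species - 1
            if self.topology == "chain"
            else (self.haplotypes_per_species - 1) * max(1, self.within_max_steps // 2)
        )
        budget = (self.n_species - 1) * self.between_min_steps + self.n_species * per_hap
        if budget > self.L:
            raise ValueError(
                f"infeasible config: needs up to {budget} distinct sites, window has {self.L}"
            )


@dataclass
class SimulationResult:
    config: SimulationConfig
    records: list[SequenceRecord]
    truth: pd.DataFrame         # seq, species, is_hub, steps_from_hub, planted_count
    species_names: list[str] = field(default_factory=list)

    @property
    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "country": [r.country for r in self.records],
                "species": [r.species_ref for r in self.records],
                "range": [r.range_class for r in self.records],
            }
        )

    def write(self, fasta_path, metadata_path, truth_path=None) -> None:
        with open(fasta_path, "w") as fh:
            for r in self.records:
                fh.write(f">{r.id}\n{r.seq}\n")
        self.metadata.to_csv(metadata_path, sep="\t", index=False)
        if truth_path is not None:
            self.truth.to_csv(truth_path, sep="\t", index=False)


def _random_coding_sequence(rng: np.random.Generator, L: int, stops: set[str]) -> str:
    """Random sequence of full codons with no frame-1 stop codons."""
    codons = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
    pool = [c for c in codons if c not in stops]
    n_codons, rem = divmod(L, 3)
    seq = "".join(rng.choice(pool) for _ in range(n_codons))
    if rem:
        seq += "".join(rng.choice(list(_BASES)) for _ in range(rem))
    return seq


def _mutate(seq: list, site: int, rng: np.random.Generator, ts_tv_ratio: float,
            stops: set[str]) -> None:
    """Substitute at ``site`` in place, avoiding frame-1 stop codons.

    Transitions are chosen with probability ratio/(ratio+1); among the
    candidate bases the first that leaves the codon stop-free is applied.
    """
    old = seq[site]
    p_ts = ts_tv_ratio / (ts_tv_ratio + 1.0)
    cands = [_TRANSITION[old]] + list(_TRANSVERSIONS[old])
    if rng.random() >= p_ts:
        tv = list(_TRANSVERSIONS[old])
        rng.shuffle(tv)
        cands = tv + [_TRANSITION[old]]
    codon_start = (site // 3) * 3
    for new in cands:
        seq[site] = new
        codon = "".join(seq[codon_start : codon_start + 3])
        if len(codon) < 3 or codon not in stops:
            return
    seq[site] = old
    raise RuntimeError(f"no stop-free substitution at site {site}")


def simulate_complex(config: SimulationConfig) -> SimulationResult:
    """Generate a seeded species complex; same seed, byte-identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    stops = set(
        CodonTable.unambiguous_dna_by_id[config.translation_table].stop_codons
    )
    species_names = [f"SP{i + 1:02d}" for i in range(config.n_species)]
    invaded_pool = [f"Invaded_{i + 1}" for i in range(config.n_invaded_countries)]

    # one global shuffled site pool; every substitution consumes a fresh site,
    # so pairwise step distances equal the number of planted substitutions
    site_pool = list(rng.permutation(config.L))

    def take_sites(n: int) -> list[int]:
        if n > len(site_pool):
            raise RuntimeError("site pool exhausted (config.validate should prevent this)")
        return [site_pool.pop() for _ in range(n)]

    ancestor = list(_random_coding_sequence(rng, config.L, stops))
    hubs = []
    for k in range(config.n_species):
        hub = list(ancestor)
        if k > 0:
            for site in take_sites(config.between_min_steps):
                _mutate(hub, site, rng, config.ts_tv_ratio, stops)
        hubs.append(hub)

    truth_rows = []
    records: list[SequenceRecord] = []
    acc = 0

    for k, sp in enumerate(species_names):
        hub = hubs[k]
        H = config.haplotypes_per_species
        haplos = [("".join(hub), 0, True)]
        if config.topology in ("star", "mixed"):
            max_arm = max(1, config.within_max_steps // 2)
        prev = list(hub)
        chain_len = 0
        for i in range(H - 1):
            top = config.topology if config.topology != "mixed" else ("star" if i % 2 == 0 else "chain")
            if top == "star":
                s = int(rng.integers(1, max_arm + 1))
                leaf = list(hub)
                for site in take_sites(s):
                    _mutate(leaf, site, rng, config.ts_tv_ratio, stops)
                haplos.append(("".join(leaf), s, False))
            else:
                for site in take_sites(1):
                    _mutate(prev, site, rng, config.ts_tv_ratio, stops)
                chain_len += 1
                haplos.append(("".join(prev), chain_len, False))

        # record counts: hub takes the skew fraction, every leaf >= 1 record,
        # remainder spread uniformly (multinomial)
        R = config.records_per_species
        hub_n = max(1, round(config.count_skew * R))
        hub_n = min(hub_n, R - (H - 1))
        leaf_n = np.ones(H - 1, dtype=int) if H > 1 else np.array([], dtype=int)
        spare = R - hub_n - leaf_n.sum()
        if spare > 0 and H > 1:
            leaf_n += rng.multinomial(spare, np.full(H - 1, 1.0 / (H - 1)))
        elif spare > 0:
            hub_n += spare
        counts = [hub_n] + list(leaf_n)

        homes = [f"{sp}_Home_{i + 1}" for i in range(config.n_home_countries)]
        for (seq, steps, is_hub), n in zip(haplos, counts):
            if is_hub:
                n_inv = int(round(config.invaded_fraction * n))
                if n >= 2:
                    n_inv = min(max(n_inv, 1), n - 1)  # hub appears in both ranges
                ranges = ["invaded"] * n_inv + ["home"] * (n - n_inv)
            else:
                klass = "invaded" if rng.random() < config.invaded_fraction else "home"
                ranges = [klass] * n
            for rc in ranges:
                acc += 1
                country = (
                    str(rng.choice(invaded_pool)) if rc == "invaded" else str(rng.choice(homes))
                )
                records.append(
                    SequenceRecord(
                        id=f"SYN{acc:05d}", seq=seq, country=country,
                        species_ref=sp, range_class=rc,
                    )
                )
            truth_rows.append((seq, sp, is_hub, steps, n))

    truth = pd.DataFrame(
        truth_rows, columns=["seq", "species", "is_hub", "steps_from_hub", "planted_count"]
    )
    return SimulationResult(
        config=config, records=records, truth=truth, species_names=species_names
    )


def make_reference_consensuses(result: SimulationResult) -> list[tuple[str, str]]:
    """Majority-rule consensus per species over its generated haplotypes.

    Column ties resolve to the alphabetically first base.  With a dominant
    hub and private leaf mutations the consensus equals the hub sequence.
    """
    out = []
    for sp in result.species_names:
        seqs = result.truth.loc[result.truth["species"] == sp, "seq"].tolist()
        cols = zip(*seqs)
        consensus = "".join(
            max(sorted(set(col)), key=col.count) for col in cols
        )
        out.append((sp, consensus))
    return out
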