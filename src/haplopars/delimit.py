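"""Barcode species assignment by K2P divergence and network congruence.

Haplotypes are assigned to the putative species whose reference consensus
lies closest under the K2P distance, provided that minimum divergence does
not exceed the delimitation threshold (3.5% for the whitefly mtCOI
complex); otherwise the haplotype is flagged ``NEW_SPECIES``.  The
congruence report then classifies each species by how its haplotypes fall
across parsimony networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .distances import k2p_distance, distance_matrix
from .network import HaplotypeNetwork
from .records import NEW_SPECIES, HaplotypeTable

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.035


@dataclass
class SpeciesAssignment:
    """Haplotype -> species map with nearest-reference diagnostics."""

    frame: pd.DataFrame  # index code; columns species, nearest_reference, min_divergence
    threshold: float
    method: str = "reference"  # or "cluster-fallback"

    def species_of(self, code: str) -> str:
        return str(self.frame.loc[code, "species"])

    @property
    def new_species(self) -> list[str]:
        return list(self.frame.index[self.frame["species"] == NEW_SPECIES])


def assign_species(
    table: HaplotypeTable,
    references: list[tuple[str, str]],
    threshold: float = DEFAULT_THRESHOLD,
) -> SpeciesAssignment:
    """Assign each haplotype to its nearest reference consensus.

    ``references`` holds ``(species_name, consensus_sequence)`` pairs aligned
    to the same window as the table.  Ties on the minimum divergence go to
    the alphabetically first species, with a warning.
    """
    if not references:
        raise ValueError("assign_species: references must be non-empty")
    for name, seq in references:
        if len(seq) != table.L:
            raise ValueError(
                f"reference {name!r} length {len(seq)} != alignment length {table.L}"
            )
    refs = sorted(references)
    rows = []
    for h in table:
        divs = [(k2p_distance(h.seq, seq, label=f"{h.code}-{name}").d_k2p, name)
                for name, seq in refs]
        best_d = min(d for d, _ in divs)
        winners = [name for d, name in divs if d == best_d]
        if len(winners) > 1:
            log.warning(
                "haplotype %s ties between references %s at %.4f; taking %s",
                h.code, winners, best_d, winners[0],
            )
        species = winners[0] if best_d <= threshold else NEW_SPECIES
        rows.append((h.code, species, winners[0], best_d))
    frame = pd.DataFrame(
        rows, columns=["code", "species", "nearest_reference", "min_divergence"]
    ).set_index("code")
    return SpeciesAssignment(frame=frame, threshold=threshold, method="reference")


def delimit_by_clustering(
    table: HaplotypeTable, threshold: float = DEFAULT_THRESHOLD
) -> SpeciesAssignment:
    """Reference-free fallback: single-linkage clusters at the K2P threshold.

    Used when no reference consensuses are available; clusters are labeled
    ``cluster_1``, ``cluster_2``, ... by decreasing size and the report is
    marked as a clustering-based delimitation.
    """
    if len(table) == 1:
        frame = pd.DataFrame(
            [(table.codes[0], "cluster_1", "", 0.0)],
            columns=["code", "species", "nearest_reference", "min_divergence"],
        ).set_index("code")
        return SpeciesAssignment(frame=frame, threshold=threshold, method="cluster-fallback")
    k2p = distance_matrix(table, metric="k2p")
    Z = linkage(squareform(k2p.to_numpy(), checks=False), method="single")
    raw = fcluster(Z, t=threshold, criterion="distance")
    # relabel clusters by decreasing size, ties by first member code
    order = sorted(
        set(raw),
        key=lambda c: (-(raw == c).sum(), min(np.array(table.codes)[raw == c])),
    )
    label = {c: f"cluster_{i + 1}" for i, c in enumerate(order)}
    frame = pd.DataFrame(
        {
            "code": table.codes,
            "species": [label[c] for c in raw],
            "nearest_reference": "",
            "min_divergence": np.nan,
        }
    ).set_index("code")
    return SpeciesAssignment(frame=frame, threshold=threshold, method="cluster-fallback")


@dataclass
class CongruenceReport:
    """Per-species classification of network structure (single network,
    network plus unconnected singletons, or split across networks)."""

    frame: pd.DataFrame  # index species; n_networks, n_singletons, category
    haplotypes_per_network: dict[str, dict[int, int]]


CATEGORIES = ("single_network", "network_plus_singletons", "split")


def congruence(
    assignment: SpeciesAssignment, networks: list[HaplotypeNetwork]
) -> CongruenceReport:
    """Cross-classify species assignments against parsimony networks.

    A species is ``single_network`` when all its haplotypes share one
    network, ``network_plus_singletons`` when at most one network holds more
    than one haplotype and the rest are unconnected singletons, and
    ``split`` when two or more multi-haplotype networks are involved.
    Network size here is the species' own haplotype count in the network.
    """
    net_of: dict[str, int] = {}
    size_of: dict[int, int] = {}
    for net in networks:
        size_of[net.network_id] = net.n_observed
        for code in net.observed:
            net_of[code] = net.network_id

    missing = [c for c in assignment.frame.index if c not in net_of]
    if missing:
        raise ValueError(f"haplotypes missing from all networks: {missing[:5]}")

    per_species: dict[str, dict[int, int]] = {}
    for code, row in assignment.frame.iterrows():
        per_species.setdefault(str(row["species"]), {}).setdefault(net_of[code], 0)
        per_species[str(row["species"])][net_of[code]] += 1

    rows = []
    for species in sorted(per_species):
        nets = per_species[species]
        n_networks = len(nets)
        # singleton = network containing exactly one observed haplotype overall
        singles = sum(1 for nid in nets if size_of[nid] == 1)
        multi = n_networks - singles
        if n_networks == 1:
            cat = "single_network"
        elif multi <= 1:
            cat = "network_plus_singletons"
        else:
            cat = "split"
        rows.append((species, n_networks, singles, cat))
    frame = pd.DataFrame(
        rows, columns=["species", "n_networks", "n_singletons", "category"]
    ).set_index("species")
    return CongruenceReport(frame=frame, haplotypes_per_network=per_species)


def write_assignment(assignment: SpeciesAssignment, path) -> None:
    assignment.frame.to_csv(path, sep="\t")


def write_congruence(report: CongruenceReport, path) -> None:
    df = report.frame.copy()
    df["haplotypes_per_network"] = [
        ";".join(f"{nid}:{n}" for nid, n in sorted(report.haplotypes_per_network[s].items()))
        for s in df.index
    ]
    df.to_csv(path, sep="\t")
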