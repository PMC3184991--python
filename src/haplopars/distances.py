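"""Mutational step counts and Kimura 2-parameter distances.

The K2P model corrects pairwise divergence separately for transitions
(A<->G, C<->T; proportion P of compared sites) and transversions
(proportion Q):

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Ambiguous bases and missing data (anything outside A/C/G/T) are excluded
pairwise: a site contributes only when both sequences carry an unambiguous
base there, and ``sites_compared`` shrinks accordingly.  Distances are
stored as proportions (substitutions per site); report writers render
percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .records import HaplotypeTable

# encoding chosen so that code >> 1 gives the purine(0)/pyrimidine(1) class
_CODE = {"A": 0, "G": 1, "C": 2, "T": 3}
_INVALID = 255


class SaturationError(ValueError):
    """K2P logarithm domain violated: the pair is too divergent."""


def encode(seq: str) -> np.ndarray:
    """Map a sequence onto uint8 codes; non-ACGT characters become invalid."""
    arr = np.full(len(seq), _INVALID, dtype=np.uint8)
    for base, code in _CODE.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = code
    return arr


def encode_matrix(seqs: list[str]) -> np.ndarray:
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("sequences must share a common length")
    return np.vstack([encode(s) for s in seqs])


@dataclass(frozen=True)
class DistancePair:
    """Pairwise comparison summary under the K2P model."""

    P: float
    Q: float
    sites_compared: int
    steps: int
    d_k2p: float


def count_steps(seq_a: str, seq_b: str) -> int:
    """Number of sites at which both sequences differ with unambiguous bases."""
    if len(seq_a) != len(seq_b):
        raise ValueError(f"length mismatch: {len(seq_a)} vs {len(seq_b)}")
    a, b = encode(seq_a), encode(seq_b)
    valid = (a != _INVALID) & (b != _INVALID)
    return int(np.count_nonzero(valid & (a != b)))


def _k2p_from_counts(ts: int, tv: int, comp: int, label: str = "pair") -> DistancePair:
    if comp == 0:
        raise ValueError(f"{label}: no comparable sites")
    P, Q = ts / comp, tv / comp
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"{label}: K2P distance undefined (P={P:.4f}, Q={Q:.4f})")
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return DistancePair(P=P, Q=Q, sites_compared=comp, steps=ts + tv, d_k2p=d)


def k2p_distance(seq_a: str, seq_b: str, label: Optional[str] = None) -> DistancePair:
    """K2P distance between two aligned sequences with pairwise exclusion."""
    if len(seq_a) != len(seq_b):
        raise ValueError(f"length mismatch: {len(seq_a)} vs {len(seq_b)}")
    a, b = encode(seq_a), encode(seq_b)
    valid = (a != _INVALID) & (b != _INVALID)
    diff = valid & (a != b)
    ts = int(np.count_nonzero(diff & ((a >> 1) == (b >> 1))))
    tv = int(np.count_nonzero(diff)) - ts
    return _k2p_from_counts(ts, tv, int(np.count_nonzero(valid)), label or "pair")


def distance_matrix(table: HaplotypeTable, metric: str = "steps") -> pd.DataFrame:
    """Symmetric pairwise matrix over the haplotypes of a table.

    ``metric='steps'`` counts differing unambiguous sites; ``'k2p'`` applies
    the K2P closed form per pair.  Saturated pairs raise
    :class:`SaturationError` naming the offending pair.
    """
    if len(table) < 2:
        raise ValueError("distance_matrix needs at least two haplotypes")
    if metric not in ("steps", "k2p"):
        raise ValueError(f"unknown metric {metric!r}")
    codes = table.codes
    X = encode_matrix(table.seqs)
    valid = X != _INVALID
    n = len(codes)
    out = np.zeros((n, n))
    for i in range(n):
        v = valid[i] & valid[i + 1 :]
        diff = v & (X[i] != X[i + 1 :])
        if metric == "steps":
            out[i, i + 1 :] = diff.sum(axis=1)
        else:
            ts = (diff & ((X[i] >> 1) == (X[i + 1 :] >> 1))).sum(axis=1)
            tot = diff.sum(axis=1)
            comp = v.sum(axis=1)
            for k, j in enumerate(range(i + 1, n)):
                pair = _k2p_from_counts(
                    int(ts[k]), int(tot[k] - ts[k]), int(comp[k]),
                    label=f"{codes[i]}-{codes[j]}",
                )
                out[i, j] = pair.d_k2p
    out = out + out.T
    return pd.DataFrame(out, index=codes, columns=codes)


@dataclass
class NetworkDistanceSummary:
    """Within- and between-network K2P summaries plus composition report."""

    within: pd.DataFrame          # index network id; columns n, min, mean, max
    between: pd.DataFrame         # symmetric mean-K2P matrix, NaN diagonal
    overall_mean: float
    base_composition: pd.DataFrame


def _composition(table: HaplotypeTable, members: dict[int, list[str]]) -> pd.DataFrame:
    rows = {}
    by_code = {h.code: h.seq for h in table}
    for net, codes in members.items():
        joined = "".join(by_code[c] for c in codes)
        tot = sum(joined.count(b) for b in "ACGT") or 1
        rows[net] = {b: joined.count(b) / tot for b in "ACGT"}
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def summarize_network_distances(
    k2p: pd.DataFrame,
    membership: dict[str, int],
    table: Optional[HaplotypeTable] = None,
) -> NetworkDistanceSummary:
    """Per-network within stats and between-network mean K2P matrix.

    Within-network statistics are undefined (NaN) for singleton networks.
    The between matrix averages K2P over all cross pairs of two networks.
    """
    missing = set(k2p.index) - set(membership)
    if missing:
        raise ValueError(f"membership does not cover haplotypes: {sorted(missing)[:5]}")
    members: dict[int, list[str]] = {}
    for code in k2p.index:
        members.setdefault(membership[code], []).append(code)
    nets = sorted(members)

    within_rows = []
    for net in nets:
        codes = members[net]
        if len(codes) < 2:
            within_rows.append((net, len(codes), np.nan, np.nan, np.nan))
        else:
            sub = k2p.loc[codes, codes].to_numpy()
            vals = sub[np.triu_indices(len(codes), k=1)]
            within_rows.append((net, len(codes), vals.min(), vals.mean(), vals.max()))
    within = pd.DataFrame(
        within_rows, columns=["network", "n", "min", "mean", "max"]
    ).set_index("network")

    between = pd.DataFrame(np.nan, index=nets, columns=nets, dtype=float)
    for a_i, a in enumerate(nets):
        for b in nets[a_i + 1 :]:
            m = float(k2p.loc[members[a], members[b]].to_numpy().mean())
            between.loc[a, b] = between.loc[b, a] = m

    full = k2p.to_numpy()
    overall = float(full[np.triu_indices(len(full), k=1)].mean())
    comp = (
        _composition(table, members)
        if table is not None
        else pd.DataFrame(index=nets, columns=list("ACGT"), dtype=float)
    )
    return NetworkDistanceSummary(
        within=within, between=between, overall_mean=overall, base_composition=comp
    )


def write_matrix(df: pd.DataFrame, path, *, lower_triangle: bool = False) -> None:
    """Write a distance matrix as TSV; optionally blank the upper triangle."""
    if lower_triangle:
        df = df.copy()
        arr = df.to_numpy(dtype=float)
        arr[np.triu_indices(len(df), k=0)] = np.nan
        df.iloc[:, :] = arr
    df.to_csv(path, sep="\t", na_rep="")
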