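"""AMOVA and pairwise PhiST over haplotype networks.

Analysis of molecular variance partitions the total molecular variance of
sequence copies into among-group and within-group components from squared
pairwise distances (two-level design).  With groups g = 1..G of sizes n_g,
N = sum n_g:

    SSD_total  = (1/N) * sum_{i<j} d_ij^2
    SSD_within = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    MS_among   = (SSD_total - SSD_within) / (G - 1)
    MS_within  = SSD_within / (N - G)
    n0         = (N - sum_g n_g^2 / N) / (G - 1)
    sigma2_within = MS_within
    sigma2_among  = (MS_among - MS_within) / n0
    PhiST = sigma2_among / (sigma2_among + sigma2_within)

Each haplotype is expanded into its number of identical records, so the
statistics are frequency-weighted exactly as when every database record is
an individual.  Significance comes from permuting individuals among groups
(fraction of permuted statistics >= observed, with the +1 correction), or
from exhaustive enumeration of assignments for small two-group problems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class AmovaResult:
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: float
    n_permutations: int
    seed: int | None
    df_among: int
    df_within: int
    sigma2_among_raw: float


@dataclass
class PhiStMatrix:
    phist: pd.DataFrame
    p_values: pd.DataFrame
    alpha: float = 0.05
    n_permutations: int = 0
    seed: int | None = None


def _expand(D: np.ndarray, weights: np.ndarray) -> np.ndarray:
    idx = np.repeat(np.arange(len(weights)), weights)
    return D[np.ix_(idx, idx)]


def _components(D2: np.ndarray, labels: np.ndarray):
    """Variance components from a squared-distance matrix over individuals."""
    N = len(labels)
    groups = np.unique(labels)
    G = len(groups)
    if G < 2:
        raise ValueError("AMOVA requires at least two groups")
    total = D2.sum() / 2.0 / N
    within = 0.0
    sum_n2 = 0.0
    for g in groups:
        m = labels == g
        n_g = int(m.sum())
        sum_n2 += n_g * n_g
        if n_g > 1:
            within += D2[np.ix_(m, m)].sum() / 2.0 / n_g
    ssd_among = total - within
    df_among, df_within = G - 1, N - G
    if df_within == 0:
        raise ValueError("AMOVA requires more individuals than groups")
    ms_among = ssd_among / df_among
    ms_within = within / df_within
    n0 = (N - sum_n2 / N) / df_among
    s2w = ms_within
    s2a = (ms_among - ms_within) / n0
    return s2a, s2w, df_among, df_within


def _phi(s2a: float, s2w: float) -> float:
    denom = s2a + s2w
    return 0.0 if denom == 0 else s2a / denom


def amova(
    D: pd.DataFrame | np.ndarray,
    grouping,
    weights=None,
    n_permutations: int = 1000,
    seed: int | None = None,
    squared: bool = False,
) -> AmovaResult:
    """Two-level AMOVA over sequence copies.

    ``D`` is a pairwise distance matrix over units (typically haplotypes),
    ``grouping`` the group label per unit and ``weights`` the number of
    identical copies each unit represents (default 1).  Distances are
    squared internally unless ``squared=True``.  A negative among-group
    component is clamped to zero with a warning; the raw value is retained
    in ``sigma2_among_raw``.
    """
    Dm = D.to_numpy(dtype=float) if isinstance(D, pd.DataFrame) else np.asarray(D, float)
    labels = np.asarray(list(grouping))
    if len(labels) != len(Dm):
        raise ValueError("grouping length must match distance matrix size")
    w = np.ones(len(Dm), int) if weights is None else np.asarray(list(weights), int)
    D2 = Dm if squared else Dm**2
    D2e = _expand(D2, w)
    labels_e = np.repeat(labels, w)

    s2a_raw, s2w, dfa, dfw = _components(D2e, labels_e)
    s2a = s2a_raw
    if s2a < 0:
        log.warning("negative among-group variance component %.6g clamped to 0", s2a)
        s2a = 0.0
    phi = _phi(s2a, s2w)

    p_value = float("nan")
    if n_permutations:
        rng = np.random.default_rng(seed)
        hits = 0
        perm = labels_e.copy()
        for _ in range(n_permutations):
            rng.shuffle(perm)
            pa, pw, _, _ = _components(D2e, perm)
            if _phi(max(pa, 0.0), pw) >= phi - 1e-12:
                hits += 1
        p_value = (hits + 1) / (n_permutations + 1)

    tot = s2a + s2w
    return AmovaResult(
        sigma2_among=s2a,
        sigma2_within=s2w,
        pct_among=100.0 * s2a / tot if tot else 0.0,
        pct_within=100.0 * s2w / tot if tot else 100.0,
        phi_st=phi,
        p_value=p_value,
        n_permutations=n_permutations,
        seed=seed,
        df_among=dfa,
        df_within=dfw,
        sigma2_among_raw=s2a_raw,
    )


def two_group_phist(D2e: np.ndarray, mask_a: np.ndarray) -> float:
    """PhiST of a two-group split given a squared-distance matrix over
    individuals and the boolean mask of group-A members."""
    labels = np.where(mask_a, "A", "B")
    s2a, s2w, _, _ = _components(D2e, labels)
    return _phi(max(s2a, 0.0), s2w)


def pairwise_phist(
    D: pd.DataFrame | np.ndarray,
    grouping,
    weights=None,
    n_permutations: int = 1000,
    seed: int | None = 0,
    exact: bool = False,
    squared: bool = False,
    alpha: float = 0.05,
    max_exact: int = 20000,
) -> PhiStMatrix:
    """PhiST for every pair of groups, with permutation p-values.

    ``exact=True`` enumerates all assignments of the pooled individuals to
    the two group sizes (feasible for small pairs; guarded by
    ``max_exact``), in which case the p-value is the exact fraction of
    assignments with PhiST >= observed.  Otherwise ``n_permutations``
    random reallocations are drawn from a generator seeded per pair, making
    results reproducible bit for bit for a given seed.
    """
    Dm = D.to_numpy(dtype=float) if isinstance(D, pd.DataFrame) else np.asarray(D, float)
    labels = np.asarray(list(grouping))
    w = np.ones(len(Dm), int) if weights is None else np.asarray(list(weights), int)
    D2 = Dm if squared else Dm**2

    groups = sorted(set(labels))
    phi = pd.DataFrame(0.0, index=groups, columns=groups)
    pvals = pd.DataFrame(np.nan, index=groups, columns=groups)
    for gi, ga in enumerate(groups):
        for gb in groups[gi + 1 :]:
            m = (labels == ga) | (labels == gb)
            sub_w = w[m]
            subD2 = D2[np.ix_(m, m)]
            D2e = _expand(subD2, sub_w)
            is_a = np.repeat(labels[m] == ga, sub_w)
            N, nA = len(is_a), int(is_a.sum())
            if N < 3 or nA == 0 or nA == N:
                log.warning("pair %s-%s has too few copies; entry skipped", ga, gb)
                continue
            obs = two_group_phist(D2e, is_a)
            phi.loc[ga, gb] = phi.loc[gb, ga] = obs

            if exact:
                total = comb(N, nA)
                if total > max_exact:
                    raise ValueError(
                        f"exact enumeration infeasible for pair {ga}-{gb} ({total} assignments)"
                    )
                hits = 0
                for pos in combinations(range(N), nA):
                    mask = np.zeros(N, bool)
                    mask[list(pos)] = True
                    if two_group_phist(D2e, mask) >= obs - 1e-12:
                        hits += 1
                p = hits / total
            else:
                rng = np.random.default_rng(
                    None if seed is None else (seed, gi, groups.index(gb))
                )
                hits = 0
                mask = is_a.copy()
                for _ in range(n_permutations):
                    rng.shuffle(mask)
                    if two_group_phist(D2e, mask) >= obs - 1e-12:
                        hits += 1
                p = (hits + 1) / (n_permutations + 1)
            pvals.loc[ga, gb] = pvals.loc[gb, ga] = p
    np.fill_diagonal(pvals.values, 0.0)
    return PhiStMatrix(
        phist=phi, p_values=pvals, alpha=alpha,
        n_permutations=0 if exact else n_permutations, seed=seed,
    )


def write_phist(result: PhiStMatrix, phist_path, pvalue_path) -> None:
    result.phist.to_csv(phist_path, sep="\t", float_format="%.4f")
    result.p_values.to_csv(pvalue_path, sep="\t", float_format="%.4f")


def write_amova(result: AmovaResult, path) -> None:
    with open(path, "w") as fh:
        for k in (
            "sigma2_among", "sigma2_within", "pct_among", "pct_within",
            "phi_st", "p_value", "n_permutations", "seed", "df_among", "df_within",
        ):
            fh.write(f"{k}\t{getattr(result, k)}\n")
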