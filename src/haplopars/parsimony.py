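"""Probability of parsimony and the statistical-parsimony connection limit.

Statistical parsimony connects two haplotypes only while the probability
that their observed differences arose without homoplasy (no superimposed,
parallel or back substitutions) stays at or above a confidence level,
conventionally 95%.  The largest number of steps ``j_max`` satisfying the
criterion is the connection limit: haplotype pairs further apart stay in
separate networks.

Probability model
-----------------
Two aligned haplotypes of length ``L`` differ at ``j`` sites.  Sites are
independent with a common per-site probability ``q`` that a mutational
event falls on the site along the path separating the haplotypes, with at
most two events per site (the classical truncation for closely related
haplotypes).  Events per site are therefore 0, 1 or 2 with probabilities
``(1-q)^2``, ``2q(1-q)``, ``q^2``.  With four nucleotide states a single
event is always visible; a second event at the same site reverts the base
with probability 1/3 and yields a (homoplasious) visible difference with
probability 2/3.  The connection is parsimonious exactly when every
differing site carried one event and every identical site none.  ``q`` is
unknown and is integrated out under a uniform prior, giving the posterior
probability of parsimony

    P(j, L) = Int [2q(1-q)]^j [(1-q)^2]^(L-j) dq
              -----------------------------------------------------
              Int [2q(1-q) + (2/3)q^2]^j [(1-q)^2 + (1/3)q^2]^(L-j) dq

Both integrals reduce to finite Beta-function sums, evaluated exactly in
log space; no quadrature is involved.  ``P(0) = 1`` by convention:
identical haplotypes are trivially connected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, gammaln, logsumexp

_LOG2 = np.log(2.0)
_LOG23 = np.log(2.0 / 3.0)
_LOG13 = np.log(1.0 / 3.0)


def _logC(n: int, k: np.ndarray | int) -> np.ndarray:
    return gammaln(n + 1) - gammaln(np.asarray(k) + 1) - gammaln(n - np.asarray(k) + 1)


def parsimony_probability(j: int, L: int) -> float:
    """Posterior probability that ``j`` differences over ``L`` sites are
    free of homoplasy (see module docstring for the model)."""
    if j < 0 or L <= 0:
        raise ValueError("require j >= 0 and L > 0")
    if j > L:
        raise ValueError(f"j={j} exceeds alignment length L={L}")
    if j == 0:
        return 1.0

    log_num = j * _LOG2 + betaln(j + 1, 2 * L - j + 1)

    # denominator: expand both binomials; a = double-hit differing sites,
    # b = double-hit identical sites
    a = np.arange(j + 1)
    b = np.arange(L - j + 1)
    A, B = np.meshgrid(a, b, indexing="ij")
    terms = (
        _logC(j, A)
        + _logC(L - j, B)
        + (j - A) * _LOG2
        + A * _LOG23
        + B * _LOG13
        + betaln(j + A + 2 * B + 1, 2 * L - j - A - 2 * B + 1)
    )
    log_den = logsumexp(terms)
    return float(np.exp(log_num - log_den))


@dataclass
class ConnectionLimit:
    """Connection limit of statistical parsimony for a given alignment length.

    ``j_max`` is the largest step count whose probability of parsimony is at
    least ``confidence``; ``prob_table`` retains P(j) for j = 0..j_max+1 for
    reporting.
    """

    L: int
    confidence: float = 0.95
    prob_table: dict[int, float] = field(default_factory=dict)
    j_max: int = 0


def connection_limit(L: int, confidence: float = 0.95) -> ConnectionLimit:
    """Compute ``j_max = max{j : P(j, L) >= confidence}`` plus the P table."""
    if L <= 0:
        raise ValueError("alignment length must be positive")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie strictly between 0 and 1")
    table = {0: 1.0}
    j = 0
    while j < L:
        p = parsimony_probability(j + 1, L)
        table[j + 1] = p
        if p < confidence:
            break
        j += 1
    return ConnectionLimit(L=L, confidence=confidence, prob_table=table, j_max=j)
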