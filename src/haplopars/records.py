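"""Core domain containers shared across the pipeline stages.

The pipeline works on unique haplotypes rather than raw database records:
identical sequences are collapsed into one :class:`Haplotype` carrying the
number of records it represents and the multiset of source countries, which
is what the downstream frequency-sensitive statistics (AMOVA, range
accounting) operate on.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

#: sentinel used by the delimitation stage for haplotypes beyond the
#: divergence threshold from every reference
NEW_SPECIES = "NEW_SPECIES"

RANGE_CLASSES = ("home", "invaded", "unknown")


@dataclass
class SequenceRecord:
    """A single database record: one accession with its source metadata."""

    id: str
    seq: str
    country: str = "unknown"
    species_ref: Optional[str] = None
    range_class: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if not self.seq:
            raise ValueError(f"SequenceRecord {self.id!r}: empty sequence")
        self.seq = self.seq.upper()
        if self.range_class is not None and self.range_class not in RANGE_CLASSES:
            raise ValueError(
                f"range_class must be one of {RANGE_CLASSES}, got {self.range_class!r}"
            )


@dataclass
class Haplotype:
    """A unique aligned sequence with its record count and country multiset."""

    code: str
    representative_id: str
    seq: str
    count: int
    countries: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"haplotype {self.code}: count must be positive")


@dataclass
class HaplotypeTable:
    """Unique haplotypes of a dataset, all aligned to a common length ``L``.

    Invariants enforced at construction: equal sequence lengths, distinct
    sequences, and count == size of the country multiset for every row.
    """

    haplotypes: list[Haplotype]
    L: int

    def __post_init__(self) -> None:
        if not self.haplotypes:
            raise ValueError("HaplotypeTable must contain at least one haplotype")
        seqs = set()
        for h in self.haplotypes:
            if len(h.seq) != self.L:
                raise ValueError(
                    f"haplotype {h.code}: length {len(h.seq)} != table L={self.L}"
                )
            if h.seq in seqs:
                raise ValueError(f"duplicate haplotype sequence at {h.code}")
            seqs.add(h.seq)
            if sum(h.countries.values()) != h.count:
                raise ValueError(
                    f"haplotype {h.code}: country multiset size != count"
                )

    def __len__(self) -> int:
        return len(self.haplotypes)

    def __iter__(self):
        return iter(self.haplotypes)

    @property
    def codes(self) -> list[str]:
        return [h.code for h in self.haplotypes]

    @property
    def seqs(self) -> list[str]:
        return [h.seq for h in self.haplotypes]

    @property
    def counts(self) -> list[int]:
        return [h.count for h in self.haplotypes]

    @property
    def total_records(self) -> int:
        return sum(h.count for h in self.haplotypes)

    def get(self, code: str) -> Haplotype:
        for h in self.haplotypes:
            if h.code == code:
                return h
        raise KeyError(code)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: one row per haplotype, countries serialized."""
        return pd.DataFrame(
            {
                "code": self.codes,
                "representative_id": [h.representative_id for h in self.haplotypes],
                "count": self.counts,
                "countries": [
                    ";".join(f"{c}:{n}" for c, n in sorted(h.countries.items()))
                    for h in self.haplotypes
                ],
                "seq": self.seqs,
            }
        )
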