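"""Reading, window trimming, quality filtering and haplotype collapsing.

The curation mirrors a standard mtCOI barcode workflow: records are trimmed
to an anchor-delimited window on a reference (for the whitefly dataset the
5' anchor GAAAATTAGAGGTATTT and 3' anchor TCCTTTCTTCTTCTGCGGT delimit a
657 bp fragment of AB204577), then records with alignment gaps, in-frame
stop codons under the invertebrate mitochondrial code, or fewer than 610
unambiguous window bases are removed, and the survivors are collapsed into
unique haplotypes with record counts.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

from .records import Haplotype, HaplotypeTable, SequenceRecord

log = logging.getLogger(__name__)

#: anchors of the mtCOI analysis window used throughout the whitefly study
DEFAULT_ANCHOR5 = "GAAAATTAGAGGTATTT"
DEFAULT_ANCHOR3 = "TCCTTTCTTCTTCTGCGGT"

#: NCBI translation table 5, invertebrate mitochondrial
DEFAULT_TRANSLATION_TABLE = 5

GAP_CHARS = {"-", "."}
UNAMBIGUOUS = set("ACGT")


def read_dataset(
    fasta_path, metadata_path=None, *, id_column: str = "id", country_column: str = "country"
) -> list[SequenceRecord]:
    """Read a FASTA file and join per-record metadata by sequence id.

    The metadata table is tab-separated with a header; ``id`` and ``country``
    columns are required, ``species`` and ``range`` are picked up when
    present.  Records without metadata keep ``country='unknown'`` (with a
    logged warning); metadata rows whose id is absent from the FASTA are
    ignored with a warning.  Duplicate FASTA ids are an error.
    """
    seen: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        seen[rec.id] = str(rec.seq).upper()
    if not seen:
        raise ValueError(f"no sequences found in {fasta_path}")

    meta: dict[str, dict] = {}
    if metadata_path is not None:
        df = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
        if id_column not in df.columns or country_column not in df.columns:
            raise ValueError(
                f"metadata must contain {id_column!r} and {country_column!r} columns"
            )
        for _, row in df.iterrows():
            rid = row[id_column]
            if rid not in seen:
                log.warning("metadata id %s not present in FASTA; ignored", rid)
                continue
            meta[rid] = {
                "country": row[country_column] or "unknown",
                "species_ref": row.get("species") or None,
                "range_class": row.get("range") or None,
            }

    records = []
    for rid, seq in seen.items():
        m = meta.get(rid)
        if m is None:
            if metadata_path is not None:
                log.warning("no metadata for %s; country set to 'unknown'", rid)
            m = {"country": "unknown", "species_ref": None, "range_class": None}
        records.append(SequenceRecord(id=rid, seq=seq, **m))
    return records


def locate_window(reference: str, anchor5: str, anchor3: str) -> tuple[int, int]:
    """Find the inclusive 0-based [start, end] window on the reference.

    The window spans from the first base of the 5' anchor to the last base
    of the 3' anchor, both motifs included.
    """
    reference = reference.upper()
    i5 = reference.find(anchor5.upper())
    if i5 < 0:
        raise ValueError("5' anchor not found on reference")
    i3 = reference.find(anchor3.upper(), i5 + len(anchor5))
    if i3 < 0:
        raise ValueError("3' anchor not found on reference downstream of 5' anchor")
    return i5, i3 + len(anchor3) - 1


def trim_to_window(
    records: Iterable[SequenceRecord],
    anchor5: str = DEFAULT_ANCHOR5,
    anchor3: str = DEFAULT_ANCHOR3,
    reference: Optional[str] = None,
) -> tuple[list[SequenceRecord], int]:
    """Trim records to the anchor-delimited analysis window.

    Records whose length matches the reference are assumed pre-aligned and
    sliced at the reference window coordinates.  Other records fall back to
    an exact anchor search on their own sequence; partially covered windows
    are padded with ``N`` so every output sequence has the window length
    (the missing flank then counts against the minimum-length filter
    downstream, never as a gap).

    Returns the trimmed records and the window length ``L``.
    """
    records = list(records)
    if reference is None:
        if not records:
            raise ValueError("no records to trim")
        reference = records[0].seq
    i5, i3 = locate_window(reference, anchor5, anchor3)
    L = i3 - i5 + 1
    a5, a3 = anchor5.upper(), anchor3.upper()

    out = []
    for rec in records:
        seq = rec.seq
        if len(seq) == len(reference):
            window = seq[i5 : i3 + 1]
        else:
            j5 = seq.find(a5)
            j3 = seq.find(a3, j5 + len(a5)) if j5 >= 0 else seq.find(a3)
            if j5 >= 0 and j3 >= 0:
                window = seq[j5 : j3 + len(a3)]
            elif j5 >= 0:
                window = seq[j5 : j5 + L]
            elif j3 >= 0:
                start = max(0, j3 + len(a3) - L)
                window = seq[start : j3 + len(a3)]
            else:
                # window not locatable: keep what there is, right-padded;
                # the record will fail the minimum-length screen
                window = seq[:L]
        if len(window) < L:
            window = window + "N" * (L - len(window))
        out.append(
            SequenceRecord(
                id=rec.id,
                seq=window,
                country=rec.country,
                species_ref=rec.species_ref,
                range_class=rec.range_class,
            )
        )
    return out, L


def _stop_codons(table_id: int) -> set[str]:
    return set(CodonTable.unambiguous_dna_by_id[table_id].stop_codons)


def detect_frame(reference: str, table_id: int = DEFAULT_TRANSLATION_TABLE) -> int:
    """Pick the reading frame (1, 2 or 3) with zero stops on the reference.

    Raises if no frame is stop-free, in which case an explicit frame must be
    configured.  If several frames are stop-free the smallest is used, with
    a warning.
    """
    stops = _stop_codons(table_id)
    clean = []
    for f in (1, 2, 3):
        codons = [
            reference[i : i + 3]
            for i in range(f - 1, len(reference) - 2, 3)
        ]
        if not any(c in stops for c in codons if set(c) <= UNAMBIGUOUS):
            clean.append(f)
    if not clean:
        raise ValueError(
            "frame=auto: no reading frame is stop-free on this reference; "
            "set the frame explicitly"
        )
    if len(clean) > 1:
        log.warning("multiple stop-free frames %s on reference; using frame %d", clean, clean[0])
    return clean[0]


def _has_stop(seq: str, frame: int, stops: set[str]) -> bool:
    for i in range(frame - 1, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if set(codon) <= UNAMBIGUOUS and codon in stops:
            return True
    return False


def qc_filter(
    records: Sequence[SequenceRecord],
    min_length: int = 610,
    table_id: int = DEFAULT_TRANSLATION_TABLE,
    frame: int | str = "auto",
    reference: Optional[str] = None,
) -> tuple[list[SequenceRecord], list[tuple[SequenceRecord, str]]]:
    """Remove records with gaps, in-frame stop codons, or too few bases.

    ``frame='auto'`` resolves the reading frame on ``reference`` (default:
    the first record).  Returns ``(kept, removed)`` where ``removed`` pairs
    each record with its reason (``gap``, ``stop`` or ``short``); the two
    lists partition the input.
    """
    records = list(records)
    if not records:
        return [], []
    if frame == "auto":
        frame = detect_frame(reference or records[0].seq, table_id)
    elif frame not in (1, 2, 3):
        raise ValueError("frame must be 1, 2, 3 or 'auto'")
    stops = _stop_codons(table_id)

    kept, removed = [], []
    for rec in records:
        if any(c in GAP_CHARS for c in rec.seq):
            removed.append((rec, "gap"))
        elif _has_stop(rec.seq, frame, stops):
            removed.append((rec, "stop"))
        elif sum(1 for c in rec.seq if c in UNAMBIGUOUS) < min_length:
            removed.append((rec, "short"))
        else:
            kept.append(rec)
    log.info(
        "qc_filter: kept %d, removed %d (frame %d, table %d)",
        len(kept), len(removed), frame, table_id,
    )
    return kept, removed


def collapse_haplotypes(records: Sequence[SequenceRecord]) -> HaplotypeTable:
    """Collapse identical sequences into unique haplotypes with counts.

    Haplotypes are ordered by descending record count then by code; codes
    are assigned in that order (``H001``, ``H002``, ...).  The representative
    accession is the lexicographically smallest id among the records of the
    haplotype, and the country multiset aggregates record countries.
    """
    records = list(records)
    if not records:
        raise ValueError("collapse_haplotypes: empty input")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"records have unequal lengths: {sorted(lengths)}")
    L = lengths.pop()

    groups: dict[str, list[SequenceRecord]] = {}
    for rec in records:
        groups.setdefault(rec.seq, []).append(rec)

    ordered = sorted(
        groups.items(), key=lambda kv: (-len(kv[1]), min(r.id for r in kv[1]))
    )
    width = max(3, len(str(len(ordered))))
    haplotypes = [
        Haplotype(
            code=f"H{i + 1:0{width}d}",
            representative_id=min(r.id for r in recs),
            seq=seq,
            count=len(recs),
            countries=Counter(r.country for r in recs),
        )
        for i, (seq, recs) in enumerate(ordered)
    ]
    return HaplotypeTable(haplotypes=haplotypes, L=L)


def expand_haplotypes(table: HaplotypeTable) -> list[SequenceRecord]:
    """Inverse of :func:`collapse_haplotypes` up to record identity.

    Each haplotype is expanded into ``count`` records (synthetic ids derived
    from the representative accession), reproducing the country multiset.
    """
    out = []
    for h in table:
        i = 0
        for country, n in sorted(h.countries.items()):
            for _ in range(n):
                rid = h.representative_id if i == 0 else f"{h.representative_id}.{i}"
                out.append(SequenceRecord(id=rid, seq=h.seq, country=country))
                i += 1
    return out


def write_removal_report(removed, path) -> None:
    pd.DataFrame(
        [(rec.id, reason) for rec, reason in removed], columns=["id", "reason"]
    ).to_csv(path, sep="\t", index=False)


def write_haplotype_table(table: HaplotypeTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)
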