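"""Reading, validating, filtering, trimming and writing aligned barcode libraries.

A reference library couples an aligned FASTA file (all records the same
length) with a sidecar taxonomy table (TSV with columns ``id``, ``bin_id``,
``order``, ``family``).  FASTA headers may be BOLD-style pipe-delimited;
only the first token is used as the record id.  Alignment columns are
1-based and inclusive throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

#: characters counted as unambiguous nucleotides
_CANONICAL = frozenset("ACGTacgt")
#: alignment gap character
GAP = "-"

TAXONOMY_COLUMNS = ("id", "bin_id", "order", "family")


class LibraryError(ValueError):
    """Base class for reference-library construction failures."""


class AlignmentError(LibraryError):
    """Sequences do not share a common alignment width."""


class FormatError(LibraryError):
    """Malformed input (duplicate ids, bad taxonomy table, bad ids)."""


class JoinError(LibraryError):
    """FASTA ids missing from the taxonomy table."""


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned barcode sequence with its BIN and higher-taxon labels."""

    id: str
    bin_id: str
    order: str
    family: str
    seq: str

    @property
    def effective_length(self) -> int:
        """Number of non-gap characters (bp)."""
        return len(self.seq) - self.seq.count(GAP)

    @property
    def n_ambiguous(self) -> int:
        """Non-gap characters that are not plain A/C/G/T (N and IUPAC codes)."""
        return sum(1 for c in self.seq if c != GAP and c not in _CANONICAL)

    @property
    def ambiguity_fraction(self) -> float:
        n = self.effective_length
        return self.n_ambiguous / n if n else 0.0


@dataclass
class ReferenceLibrary:
    """An ordered collection of equally long aligned records.

    ``region`` tracks the 1-based inclusive column span of the current
    window relative to the original alignment, so that successive trims
    stay interpretable in the original coordinate system.
    """

    records: list[SequenceRecord]
    alignment_width: int = field(default=None)  # type: ignore[assignment]
    region: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.alignment_width is None:
            self.alignment_width = len(self.records[0].seq) if self.records else 0
        for r in self.records:
            if len(r.seq) != self.alignment_width:
                raise AlignmentError(
                    f"record {r.id!r} has length {len(r.seq)}, "
                    f"expected alignment width {self.alignment_width}"
                )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate record ids: {dupes}")
        if self.region is None:
            self.region = (1, self.alignment_width)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def taxonomy_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.id, r.bin_id, r.order, r.family) for r in self.records],
            columns=list(TAXONOMY_COLUMNS),
        )

    def subset(self, keep_ids: Iterable[str]) -> "ReferenceLibrary":
        """Records whose id is in ``keep_ids``, input order preserved."""
        keep = set(keep_ids)
        return ReferenceLibrary(
            [r for r in self.records if r.id in keep],
            alignment_width=self.alignment_width,
            region=self.region,
        )


def read_library(fasta_path, taxonomy_path) -> ReferenceLibrary:
    """Join an aligned FASTA with its taxonomy TSV into a ReferenceLibrary.

    Records whose taxonomy row lacks an order or family label are dropped
    (their count is logged).  FASTA ids absent from the taxonomy raise
    :class:`JoinError`; unequal sequence lengths raise
    :class:`AlignmentError`.
    """
    seqs: dict[str, str] = {}
    width = None
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        rid = rec.id.split("|")[0]
        if rid in seqs:
            raise FormatError(f"duplicate FASTA id {rid!r}")
        s = str(rec.seq)
        if width is None:
            width = len(s)
        elif len(s) != width:
            raise AlignmentError(
                f"record {rid!r} has length {len(s)}, expected {width}"
            )
        seqs[rid] = s

    tax = pd.read_csv(taxonomy_path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in TAXONOMY_COLUMNS if c not in tax.columns]
    if missing_cols:
        raise FormatError(f"taxonomy table missing columns: {missing_cols}")
    if tax["id"].duplicated().any():
        dupes = sorted(tax.loc[tax["id"].duplicated(), "id"].unique())
        raise FormatError(f"duplicate taxonomy ids: {dupes}")
    tax = tax.set_index("id")

    orphans = sorted(set(seqs) - set(tax.index))
    if orphans:
        raise JoinError(f"FASTA ids absent from taxonomy table: {orphans}")

    records: list[SequenceRecord] = []
    n_dropped = 0
    for rid, s in seqs.items():
        row = tax.loc[rid]
        if not row["family"] or not row["order"]:
            n_dropped += 1
            continue
        records.append(
            SequenceRecord(rid, row["bin_id"], row["order"], row["family"], s)
        )
    if n_dropped:
        logger.info(
            "dropped %d record(s) lacking an order/family label", n_dropped
        )
    return ReferenceLibrary(records, alignment_width=width or 0)


def filter_compliant(
    lib: ReferenceLibrary, min_len_bp: int = 500, max_ambig: float = 0.01
) -> ReferenceLibrary:
    """Keep records with >= ``min_len_bp`` non-gap bp and < ``max_ambig``
    ambiguous fraction (barcode-compliance rule).  Order preserved."""
    kept = [
        r
        for r in lib.records
        if r.effective_length >= min_len_bp and r.ambiguity_fraction < max_ambig
    ]
    if not kept:
        logger.warning("filter_compliant removed every record")
    return ReferenceLibrary(kept, alignment_width=lib.alignment_width, region=lib.region)


def select_bin_representatives(lib: ReferenceLibrary) -> ReferenceLibrary:
    """One record per BIN: longest effective length, then fewest ambiguous
    characters, then lexicographically smallest id."""
    best: dict[str, SequenceRecord] = {}
    order_of_bin: list[str] = []
    for r in lib.records:
        cur = best.get(r.bin_id)
        if cur is None:
            best[r.bin_id] = r
            order_of_bin.append(r.bin_id)
            continue
        key_new = (-r.effective_length, r.n_ambiguous, r.id)
        key_cur = (-cur.effective_length, cur.n_ambiguous, cur.id)
        if key_new < key_cur:
            best[r.bin_id] = r
    return ReferenceLibrary(
        [best[b] for b in order_of_bin],
        alignment_width=lib.alignment_width,
        region=lib.region,
    )


def trim_to_region(
    lib: ReferenceLibrary, start_col: int, end_col: int
) -> ReferenceLibrary:
    """Slice every record to alignment columns [start_col, end_col]
    (1-based, inclusive, in the library's current coordinate system)."""
    if not (1 <= start_col <= end_col <= lib.alignment_width):
        raise ValueError(
            f"column span [{start_col}, {end_col}] out of range for "
            f"alignment width {lib.alignment_width}"
        )
    records = [
        replace(r, seq=r.seq[start_col - 1 : end_col]) for r in lib.records
    ]
    offset = lib.region[0] - 1
    return ReferenceLibrary(
        records,
        alignment_width=end_col - start_col + 1,
        region=(offset + start_col, offset + end_col),
    )


def write_library(lib: ReferenceLibrary, fasta_path, taxonomy_path) -> None:
    """Write FASTA + taxonomy TSV; round-trips losslessly with
    :func:`read_library`.  Ids containing whitespace or '|' are rejected
    (they would not survive the header dialect)."""
    for r in lib.records:
        if any(c.isspace() for c in r.id) or "|" in r.id:
            raise FormatError(f"id {r.id!r} contains whitespace or '|'")
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in lib.records
    ]
    SeqIO.write(bio, str(fasta_path), "fasta")
    lib.taxonomy_frame().to_csv(taxonomy_path, sep="\t", index=False)
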