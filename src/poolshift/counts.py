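"""Read-level QC, SAM-to-nucleotide-count conversion and count-table I/O.

The central data structure is the :class:`CountTable`: one row per
(sample, locus) with read counts of each nucleotide at that reference
position, plus the factorial sample labels (group, stage, treatment,
replicate).  Tables are serialized as plain tab-delimited text and may be
read/written gzipped transparently.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = ("A", "C", "G", "T")
COUNT_COLUMNS = [
    "sample_id",
    "group",
    "stage",
    "treatment",
    "replicate",
    "locus_id",
    "scaffold",
    "position",
    "countA",
    "countC",
    "countG",
    "countT",
]

#: Length of a restriction tag; loci within the same 36-bp window of a
#: scaffold belong to one tag.
TAG_LENGTH = 36


class MalformedRecordError(ValueError):
    """Raised when an input record cannot be parsed; carries the record index."""

    def __init__(self, index: int, message: str):
        self.index = index
        super().__init__(f"record {index}: {message}")


@dataclass
class CountTable:
    """Per-sample, per-locus nucleotide read counts with sample metadata.

    ``df`` has the columns in :data:`COUNT_COLUMNS`; ``(sample_id, locus_id)``
    pairs are unique, positions are 1-based and counts are non-negative.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COUNT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"count table missing columns: {missing}")
        self.df = self.df[COUNT_COLUMNS].reset_index(drop=True)
        counts = self.df[["countA", "countC", "countG", "countT"]]
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative nucleotide counts")
        if (self.df["position"] < 1).any():
            raise ValueError("positions must be 1-based (>= 1)")
        if self.df.duplicated(subset=["sample_id", "locus_id"]).any():
            dup = self.df[self.df.duplicated(subset=["sample_id", "locus_id"])]
            raise ValueError(
                f"duplicate (sample_id, locus_id) keys, e.g. {dup.iloc[0].tolist()[:6]}"
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def depth(self) -> pd.Series:
        """Total read depth per row (sum over the four nucleotides)."""
        return self.df[["countA", "countC", "countG", "countT"]].sum(axis=1)

    def total_counts(self) -> int:
        """Grand total of nucleotide counts across all rows."""
        return int(self.df[["countA", "countC", "countG", "countT"]].to_numpy().sum())

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", dtype={"scaffold": str, "locus_id": str, "sample_id": str})
        return cls(df)


@dataclass
class QCSummary:
    """Counts of reads retained/discarded by :func:`quality_filter_reads`."""

    retained: int = 0
    discarded_short: int = 0
    discarded_quality: int = 0

    @property
    def discarded(self) -> int:
        return self.discarded_short + self.discarded_quality

    @property
    def total(self) -> int:
        return self.retained + self.discarded


def _open_maybe_gzip(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def quality_filter_reads(
    reads: str | Path | Iterable[SeqRecord],
    trunc_len: int = 36,
    max_low_bases: int = 10,
    phred_floor: int = 20,
    phred_offset: int = 33,
) -> tuple[list[SeqRecord], QCSummary]:
    """Truncate reads to ``trunc_len`` and drop low-quality ones.

    A read is retained when, after truncation, it is exactly ``trunc_len``
    long and has strictly fewer than ``max_low_bases`` positions with phred
    quality below ``phred_floor``.  Reads shorter than ``trunc_len`` are
    discarded.

    Parameters
    ----------
    reads
        Path to a FASTQ file (``.gz`` allowed) or an iterable of Biopython
        ``SeqRecord`` objects with ``phred_quality`` annotations.
    phred_offset
        33 (Sanger, default) or 64 (old Illumina); only used when reading
        from a path.

    Returns
    -------
    (retained_reads, summary)
    """
    if phred_offset not in (33, 64):
        raise ValueError("phred_offset must be 33 or 64")
    close = None
    if isinstance(reads, (str, Path)):
        handle = _open_maybe_gzip(reads)
        fmt = "fastq" if phred_offset == 33 else "fastq-illumina"
        records: Iterator[SeqRecord] = SeqIO.parse(handle, fmt)
        close = handle
    else:
        records = iter(reads)

    kept: list[SeqRecord] = []
    summary = QCSummary()
    index = -1
    try:
        while True:
            index += 1
            try:
                rec = next(records)
            except StopIteration:
                break
            except ValueError as exc:  # Biopython parse error
                raise MalformedRecordError(index, str(exc)) from exc
            if len(rec) < trunc_len:
                summary.discarded_short += 1
                continue
            rec = rec[:trunc_len]
            quals = rec.letter_annotations["phred_quality"]
            n_low = sum(1 for q in quals if q < phred_floor)
            if n_low < max_low_bases:
                kept.append(rec)
                summary.retained += 1
            else:
                summary.discarded_quality += 1
    finally:
        if close is not None:
            close.close()
    return kept, summary


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> int:
    with _open_maybe_gzip(path, "wt") as handle:
        return SeqIO.write(records, handle, "fastq")


@dataclass
class SamConversionStats:
    used: int = 0
    skipped_unmapped: int = 0
    skipped_secondary: int = 0
    skipped_no_cigar: int = 0
    skipped_low_match: int = 0


def _matched_bases(aln) -> int | None:
    """Number of aligned positions identical to the reference.

    Prefers the MD tag (exact per-base comparison); falls back to NM
    (edit distance minus indel bases).  Returns ``None`` when neither is
    available.
    """
    if aln.has_tag("MD"):
        seq = aln.query_sequence
        matched = 0
        for qpos, _rpos, ref_base in aln.get_aligned_pairs(with_seq=True):
            if qpos is None or ref_base is None:
                continue
            if seq[qpos].upper() == ref_base.upper():
                matched += 1
        return matched
    if aln.has_tag("NM"):
        aligned = 0
        indel_bases = 0
        for op, length in aln.cigartuples:
            if op in (0, 7, 8):  # M, =, X
                aligned += length
            elif op in (1, 2):  # I, D
                indel_bases += length
        mismatches = aln.get_tag("NM") - indel_bases
        return aligned - mismatches
    return None


def sam_to_counts(
    sam_path: str | Path,
    sample_id: str,
    group: str,
    stage: str,
    treatment: str,
    replicate: int,
    min_match: int = 30,
) -> tuple[CountTable, SamConversionStats]:
    """Convert single-best alignments to per-position nucleotide counts.

    Only primary, mapped alignments with >= ``min_match`` bases identical to
    the reference contribute.  Each aligned (reference position, read base)
    pair adds one count at that position; reverse-strand reads are already
    stored in reference orientation in SAM, so no extra complementing is
    needed.  Positions in the output are 1-based; ``locus_id`` is
    ``scaffold:position``.
    """
    import pysam

    stats = SamConversionStats()
    # counts[(scaffold, pos1)] -> [A, C, G, T]
    acc: dict[tuple[str, int], list[int]] = {}
    nuc_index = {n: i for i, n in enumerate(NUCLEOTIDES)}

    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                stats.skipped_unmapped += 1
                continue
            if aln.is_secondary or aln.is_supplementary:
                stats.skipped_secondary += 1
                continue
            if aln.cigartuples is None:
                stats.skipped_no_cigar += 1
                continue
            matched = _matched_bases(aln)
            if matched is None:
                stats.skipped_no_cigar += 1
                continue
            if matched < min_match:
                stats.skipped_low_match += 1
                continue
            stats.used += 1
            scaffold = aln.reference_name
            seq = aln.query_sequence
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                base = seq[qpos].upper()
                if base not in nuc_index:
                    continue
                key = (scaffold, rpos + 1)
                row = acc.setdefault(key, [0, 0, 0, 0])
                row[nuc_index[base]] += 1

    rows = [
        {
            "sample_id": sample_id,
            "group": group,
            "stage": stage,
            "treatment": treatment,
            "replicate": replicate,
            "locus_id": f"{scaffold}:{pos}",
            "scaffold": scaffold,
            "position": pos,
            "countA": a,
            "countC": c,
            "countG": g,
            "countT": t,
        }
        for (scaffold, pos), (a, c, g, t) in sorted(acc.items())
    ]
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    return CountTable(df), stats


def merge_counts(tables: Iterable[CountTable]) -> CountTable:
    """Union of count tables from disjoint samples; count mass is conserved.

    Raises ``ValueError`` on duplicate (sample_id, locus_id) keys.
    """
    frames = [t.df for t in tables]
    if not frames:
        return CountTable(pd.DataFrame(columns=COUNT_COLUMNS))
    merged = pd.concat(frames, ignore_index=True)
    return CountTable(merged)  # constructor enforces key uniqueness
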