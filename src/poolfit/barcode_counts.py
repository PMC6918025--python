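"""Barcode extraction from amplicon FASTQ reads and barcode-by-sample counting.

Barcode amplicons have the architecture ``5'flank + barcode + 3'flank``; a
read yields a barcode only when both flanks are found (within a configurable
Hamming tolerance, strict by default) around a barcode of the expected
length.  Extracted barcodes are matched to the pool exactly — no error
correction — so every read is accounted for as counted, unmapped (extracted
but absent from the pool), or unextractable.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .pool_model import InsertionPool

UNMAPPED_ROW = "_unmapped"
UNEXTRACTABLE_ROW = "_unextractable"


@dataclass(frozen=True)
class FlankConfig:
    """Amplicon architecture: flanking sequences around a fixed-length barcode.

    ``max_flank_mismatches`` is the Hamming tolerance applied to each flank
    independently (default 0: exact flanks).  ``scan_reverse_complement``
    additionally scans the reverse complement of each read.
    """

    pre_flank: str
    post_flank: str
    barcode_length: int = 20
    max_flank_mismatches: int = 0
    scan_reverse_complement: bool = False

    def __post_init__(self) -> None:
        if not self.pre_flank or not self.post_flank:
            raise ValueError("flanks must be non-empty")
        if self.barcode_length < 1:
            raise ValueError("barcode_length must be >= 1")
        if self.max_flank_mismatches < 0:
            raise ValueError("max_flank_mismatches must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "FlankConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class CountMatrix:
    """Nonnegative integer counts, rows (barcodes or genes) by samples.

    ``samples`` carries per-sample condition and replicate labels;
    ``unmapped`` and ``unextractable`` track per-sample reads that produced
    no pool barcode.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame = None  # columns: sample, condition, replicate
    unmapped: pd.Series = None
    unextractable: pd.Series = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("row and column ids must be unique")
        if self.samples is None:
            self.samples = pd.DataFrame(
                {"sample": self.counts.columns, "condition": "", "replicate": 0}
            )
        if self.unmapped is None:
            self.unmapped = pd.Series(0, index=self.counts.columns)
        if self.unextractable is None:
            self.unextractable = pd.Series(0, index=self.counts.columns)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.loc[UNMAPPED_ROW] = self.unmapped
        out.loc[UNEXTRACTABLE_ROW] = self.unextractable
        out.to_csv(path, sep="\t", index_label="barcode")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        unmapped = df.loc[UNMAPPED_ROW] if UNMAPPED_ROW in df.index else None
        unext = df.loc[UNEXTRACTABLE_ROW] if UNEXTRACTABLE_ROW in df.index else None
        df = df.drop(index=[UNMAPPED_ROW, UNEXTRACTABLE_ROW], errors="ignore")
        return cls(counts=df.astype(int), unmapped=unmapped, unextractable=unext)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _find_flank(read: str, flank: str, max_mm: int) -> int:
    """Index of the first occurrence of ``flank`` within ``max_mm`` mismatches.

    Exact search delegates to str.find; the tolerant path slides a Hamming
    window. Returns -1 when absent.
    """
    if max_mm == 0:
        return read.find(flank)
    k = len(flank)
    for i in range(len(read) - k + 1):
        window = read[i : i + k]
        mm = sum(a != b for a, b in zip(window, flank))
        if mm <= max_mm:
            return i
    return -1


def _matches(seq: str, flank: str, max_mm: int) -> bool:
    if len(seq) < len(flank):
        return False
    return sum(a != b for a, b in zip(seq, flank)) <= max_mm


def extract_barcode(read: str, flanks: FlankConfig) -> str | None:
    """Extract the barcode from one read, or None when the architecture
    (pre-flank, barcode_length bases, post-flank) is not found.

    Absence is a value, not an error: truncated or off-target reads simply
    yield None.
    """
    read = read.upper()
    orientations = [read]
    if flanks.scan_reverse_complement:
        orientations.append(_reverse_complement(read))
    mm = flanks.max_flank_mismatches
    for seq in orientations:
        i = _find_flank(seq, flanks.pre_flank, mm)
        if i < 0:
            continue
        start = i + len(flanks.pre_flank)
        end = start + flanks.barcode_length
        if end + len(flanks.post_flank) > len(seq):
            continue
        if _matches(seq[end : end + len(flanks.post_flank)], flanks.post_flank, mm):
            return seq[start:end]
    return None


def _open_fastq(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def count_barcodes(
    fastq_paths,
    pool: InsertionPool,
    flanks: FlankConfig,
    sample_names: list[str] | None = None,
) -> CountMatrix:
    """Count pool-barcode occurrences in one FASTQ per sample.

    Every row of the result corresponds to a pool barcode (zero-filled when
    unseen); extracted barcodes not in the pool accumulate in the per-sample
    unmapped tally.  Read conservation holds exactly:
    counted + unmapped + unextractable = number of reads, per sample.
    """
    if len(pool) == 0:
        raise ValueError("pool is empty")
    if isinstance(fastq_paths, (str, Path)):
        fastq_paths = [fastq_paths]
    if sample_names is None:
        sample_names = [Path(p).name.split(".")[0] for p in fastq_paths]
    if len(sample_names) != len(fastq_paths):
        raise ValueError("one sample name per FASTQ required")

    pool_barcodes = pool.barcodes
    pool_set = set(pool_barcodes)
    counts = pd.DataFrame(
        0, index=pool_barcodes, columns=sample_names, dtype=int
    )
    unmapped = pd.Series(0, index=sample_names)
    unextractable = pd.Series(0, index=sample_names)

    for path, sample in zip(fastq_paths, sample_names):
        tally: dict[str, int] = {}
        n_unmapped = 0
        n_unext = 0
        with _open_fastq(path) as fh:
            for _title, seq, _qual in FastqGeneralIterator(fh):
                bc = extract_barcode(seq, flanks)
                if bc is None:
                    n_unext += 1
                elif bc in pool_set:
                    tally[bc] = tally.get(bc, 0) + 1
                else:
                    n_unmapped += 1
        if tally:
            counts.loc[list(tally), sample] = list(tally.values())
        unmapped[sample] = n_unmapped
        unextractable[sample] = n_unext

    return CountMatrix(
        counts=counts, unmapped=unmapped, unextractable=unextractable
    )
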