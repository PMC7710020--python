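"""Genome, interval and sequencing-tag primitives.

Everything downstream (event calling, accessibility, motif scanning)
operates on aligned reads reduced to stranded 5' positions ("tags") held
in per-chromosome sorted arrays, and on 0-based half-open intervals.
BED is the native interval format; 1-based inputs must be converted at
the boundary by their readers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

_VALID_SEQ = re.compile(r"^[ACGTN]*$")

#: byte -> base code lookup (A=0, C=1, G=2, T=3, N/other=4)
BASE_CODES = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    BASE_CODES[_b] = _i
    BASE_CODES[_b + 32] = _i  # lower case

CODE_TO_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)


class FastaFormatError(ValueError):
    """Malformed FASTA input (empty record, duplicate name, bad alphabet)."""


class TagFormatError(ValueError):
    """Malformed tag (BED/tagAlign) input."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval; strand '.' means unstranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class Genome:
    """An in-memory reference genome over the {A,C,G,T,N} alphabet.

    Sequences are case-folded to upper on construction and chromosome
    order is preserved (it defines the sort order of all writers).
    """

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise FastaFormatError("genome has no chromosomes")
        self.chrom_names: list[str] = list(sequences)
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            if not seq:
                raise FastaFormatError(f"empty record {name!r}")
            if not _VALID_SEQ.match(seq):
                bad = sorted(set(seq) - set("ACGTN"))
                raise FastaFormatError(
                    f"record {name!r} contains non-IUPAC characters {bad}"
                )
            self._seqs[name] = seq
        self.lengths: dict[str, int] = {n: len(s) for n, s in self._seqs.items()}
        self.total_length: int = sum(self.lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Clipped subsequence (out-of-bounds coordinates are truncated)."""
        seq = self._seqs[chrom]
        return seq[max(0, start): min(len(seq), end)]

    def codes(self, chrom: str) -> np.ndarray:
        """Sequence as a uint8 code array (A=0,C=1,G=2,T=3,N=4)."""
        return BASE_CODES[np.frombuffer(self._seqs[chrom].encode(), dtype=np.uint8)]

    def mononucleotide_freqs(self) -> np.ndarray:
        """Genome-wide (A,C,G,T) frequencies over non-N positions."""
        counts = np.zeros(5, dtype=np.int64)
        for chrom in self.chrom_names:
            counts += np.bincount(self.codes(chrom), minlength=5)
        acgt = counts[:4].astype(float)
        if acgt.sum() == 0:
            raise ValueError("genome is all N")
        return acgt / acgt.sum()


def load_fasta(path) -> Genome:
    """Read a genome from FASTA; order preserved, sequences upper-cased."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FastaFormatError(f"duplicate record name {record.id!r}")
        if len(record.seq) == 0:
            raise FastaFormatError(f"empty record {record.id!r}")
        sequences[record.id] = str(record.seq)
    if not sequences:
        raise FastaFormatError(f"no FASTA records in {path}")
    return Genome(sequences)


def write_fasta(genome: Genome, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chrom_names:
            fh.write(f">{chrom}\n")
            seq = genome.sequence(chrom)
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


@dataclass
class ChromTags:
    """Tags on one chromosome, sorted by 5' position."""

    positions: np.ndarray  # int64, sorted ascending
    strands: np.ndarray    # bool, True for '-'

    @property
    def n(self) -> int:
        return len(self.positions)


@dataclass
class TagLibrary:
    """One sequencing experiment replicate reduced to stranded 5' positions."""

    experiment_id: str = ""
    condition: str = ""
    replicate_id: str = ""
    tags: dict[str, ChromTags] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(ct.n for ct in self.tags.values())

    def chrom_positions(self, chrom: str) -> np.ndarray:
        ct = self.tags.get(chrom)
        return ct.positions if ct is not None else np.empty(0, dtype=np.int64)

    @classmethod
    def from_arrays(cls, chroms, positions, strands, sort=True, **meta) -> "TagLibrary":
        """Build from parallel arrays of chrom name / position / is_minus."""
        chroms = np.asarray(chroms)
        positions = np.asarray(positions, dtype=np.int64)
        strands = np.asarray(strands, dtype=bool)
        lib = cls(**meta)
        for chrom in pd.unique(chroms):
            mask = chroms == chrom
            pos, neg = positions[mask], strands[mask]
            if sort:
                order = np.argsort(pos, kind="stable")
                pos, neg = pos[order], neg[order]
            lib.tags[str(chrom)] = ChromTags(pos, neg)
        return lib

    def validate_against(self, genome: Genome) -> None:
        for chrom, ct in self.tags.items():
            if chrom not in genome:
                raise ValueError(f"tag chromosome {chrom!r} not in genome")
            if ct.n and (ct.positions[0] < 0 or ct.positions[-1] >= genome.lengths[chrom]):
                raise ValueError(f"tag position out of bounds on {chrom}")


@dataclass
class BinnedCoverage:
    chrom: str
    bin_width: int
    counts: np.ndarray


def load_tags(path, format: str = "BED", **meta) -> TagLibrary:
    """Read aligned reads from BED6/tagAlign, reducing each to its 5' end.

    The 5' coordinate is ``start`` for + reads and ``end - 1`` for - reads.
    """
    if format not in ("BED", "tagAlign"):
        raise ValueError(f"unsupported tag format {format!r}")
    chroms, positions, strands = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise TagFormatError(f"{path}:{lineno}: expected >=6 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise TagFormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = fields[5]
            if strand not in ("+", "-"):
                raise TagFormatError(f"{path}:{lineno}: invalid strand {strand!r}")
            if not (0 <= start < end):
                raise TagFormatError(f"{path}:{lineno}: invalid interval {start}-{end}")
            chroms.append(fields[0])
            positions.append(start if strand == "+" else end - 1)
            strands.append(strand == "-")
    if not chroms:
        return TagLibrary(**meta)
    return TagLibrary.from_arrays(chroms, positions, strands, **meta)


def write_tags(lib: TagLibrary, path, chrom_order: list[str] | None = None) -> None:
    """Write tags as 1-bp BED6 records; deterministic chrom/start order."""
    order = chrom_order or sorted(lib.tags)
    with open(path, "w") as fh:
        for chrom in order:
            ct = lib.tags.get(chrom)
            if ct is None:
                continue
            for pos, minus in zip(ct.positions.tolist(), ct.strands.tolist()):
                strand = "-" if minus else "+"
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\ttag\t0\t{strand}\n")


def extend_tags(lib: TagLibrary, genome: Genome, length_bp: int = 100):
    """Extend each tag 3'-ward from its 5' end into a ``length_bp`` interval.

    Returns ``{chrom: (starts, ends)}`` with arrays clipped at chromosome
    bounds; a + tag at p becomes [p, p+L) and a - tag [p-L+1, p+1).
    """
    if length_bp < 1:
        raise ValueError("length_bp must be >= 1")
    out = {}
    for chrom, ct in lib.tags.items():
        clen = genome.lengths[chrom]
        starts = np.where(ct.strands, ct.positions - length_bp + 1, ct.positions)
        ends = np.where(ct.strands, ct.positions + 1, ct.positions + length_bp)
        out[chrom] = (np.clip(starts, 0, clen), np.clip(ends, 0, clen))
    return out


def bin_counts(lib: TagLibrary, genome: Genome, bin_width: int) -> dict[str, BinnedCoverage]:
    """Histogram tag 5' positions into fixed-width bins per chromosome."""
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    out = {}
    for chrom in genome.chrom_names:
        n_bins = -(-genome.lengths[chrom] // bin_width)
        ct = lib.tags.get(chrom)
        if ct is None or ct.n == 0:
            counts = np.zeros(n_bins, dtype=np.int64)
        else:
            counts = np.bincount(ct.positions // bin_width, minlength=n_bins)
        out[chrom] = BinnedCoverage(chrom, bin_width, counts)
    return out


def count_in_window(lib: TagLibrary, interval: GenomicInterval,
                    mode: str = "five_prime", extend: int = 100) -> int:
    """Tags whose 5' end (or whose extension overlaps) falls in the interval."""
    ct = lib.tags.get(interval.chrom)
    if ct is None or ct.n == 0:
        return 0
    if mode == "five_prime":
        lo = np.searchsorted(ct.positions, interval.start, side="left")
        hi = np.searchsorted(ct.positions, interval.end, side="left")
        return int(hi - lo)
    if mode == "extended":
        starts = np.where(ct.strands, ct.positions - extend + 1, ct.positions)
        ends = np.where(ct.strands, ct.positions + 1, ct.positions + extend)
        return int(np.count_nonzero((starts < interval.end) & (ends > interval.start)))
    raise ValueError(f"unknown mode {mode!r}")


def window_counts(positions: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Vectorized per-window 5'-tag counts (positions must be sorted)."""
    return (np.searchsorted(positions, ends, side="left")
            - np.searchsorted(positions, starts, side="left"))


def write_bed(df: pd.DataFrame, path, columns=("chrom", "start", "end"),
              chrom_order: list[str] | None = None) -> None:
    """Deterministic BED writer: sorted by chromosome order then start."""
    df = df.copy()
    if chrom_order:
        key = {c: i for i, c in enumerate(chrom_order)}
        df["_k"] = df["chrom"].map(key)
        df = df.sort_values(["_k", "start"], kind="stable").drop(columns="_k")
    else:
        df = df.sort_values(["chrom", "start"], kind="stable")
    df[list(columns)].to_csv(path, sep="\t", header=False, index=False)
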