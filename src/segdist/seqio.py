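"""Genome sequence I/O, base groupings and constant-time composition queries.

Sequences are kept as plain uppercase strings.  All composition arithmetic
goes through :class:`CountsIndex`, a per-contig cumulative base-count table,
so that the (#A, #C, #G, #T) content of any half-open range is available in
O(1).  That range query is what makes the recursive segmentation run in
O(N log m) overall.

Coordinates are 0-based and half-open everywhere.  IUPAC ambiguity codes
(including N) are accepted on input; they occupy coordinates but contribute
nothing to any count.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "BASES",
    "IUPAC_CODES",
    "Grouping",
    "SW",
    "RY",
    "KM",
    "GROUPINGS",
    "Contig",
    "GenomeSequence",
    "CountsIndex",
    "FastaParseError",
    "CompositionError",
    "read_fasta",
    "write_fasta",
    "split_on_gaps",
    "range_counts",
    "grouping_fraction",
    "encode",
]

#: The unambiguous DNA alphabet, in the fixed count-vector order.
BASES = "ACGT"
BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}

#: IUPAC one-letter nucleotide codes accepted on input.
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")
_AMBIGUOUS = IUPAC_CODES - frozenset(BASES)

# byte -> code lookup: 0..3 for ACGT, -1 for ambiguity codes, -2 for invalid
_CODE_LUT = np.full(256, -2, dtype=np.int8)
for _b, _i in BASE_TO_CODE.items():
    _CODE_LUT[ord(_b)] = _i
for _b in _AMBIGUOUS:
    _CODE_LUT[ord(_b)] = -1


class FastaParseError(ValueError):
    """Malformed FASTA input (empty file/record or a non-IUPAC symbol)."""


class CompositionError(ValueError):
    """A composition query over a range with no unambiguous bases."""


@dataclass(frozen=True)
class Grouping:
    """A binary grouping of the four bases into a positive and negative set.

    The three groupings used throughout are strong/weak (``SW``: G+C vs A+T,
    i.e. G+C content), purine/pyrimidine (``RY``: A+G vs C+T) and keto/amino
    (``KM``: G+T vs A+C).  Each captures a distinct chemical axis of the
    double helix; custom two-base groupings are allowed for experimentation.
    """

    name: str
    positive_set: frozenset

    def __post_init__(self):
        pos = frozenset(self.positive_set)
        if not self.name:
            raise ValueError("grouping needs a name")
        if len(pos) != 2 or not pos <= frozenset(BASES):
            raise ValueError(
                f"positive_set must be exactly 2 of {BASES!r}, got {sorted(pos)}"
            )
        object.__setattr__(self, "positive_set", pos)

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask over the ACGT count-vector order."""
        return np.array([b in self.positive_set for b in BASES])


SW = Grouping("SW", frozenset("CG"))
RY = Grouping("RY", frozenset("AG"))
KM = Grouping("KM", frozenset("GT"))

#: The built-in groupings, keyed by name.
GROUPINGS: Mapping[str, Grouping] = {"SW": SW, "RY": RY, "KM": KM}


def encode(symbols: str, contig_id: str = "?") -> np.ndarray:
    """Map a sequence string to int8 codes (A=0 C=1 G=2 T=3, ambiguity=-1).

    Raises :class:`FastaParseError` naming the contig and 0-based offset of
    the first non-IUPAC character.
    """
    raw = np.frombuffer(symbols.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _CODE_LUT[raw]
    bad = np.nonzero(codes == -2)[0]
    if bad.size:
        off = int(bad[0])
        raise FastaParseError(
            f"non-IUPAC character {symbols[off]!r} in contig {contig_id!r} at offset {off}"
        )
    return codes


@dataclass
class Contig:
    """One contiguous sequence, with provenance back to its source record.

    ``source_id``/``source_start`` track the original assembly coordinates
    so intervals derived after gap splitting can still be reported in the
    source frame (BED output).
    """

    id: str
    symbols: str
    source_id: str = ""
    source_start: int = 0

    def __post_init__(self):
        if not self.source_id:
            self.source_id = self.id

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class GenomeSequence:
    """A taxon's assembly: an ordered collection of contigs."""

    taxon_id: str
    contigs: list

    def __post_init__(self):
        ids = [c.id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate contig ids in taxon {self.taxon_id!r}")
        if sum(len(c) for c in self.contigs) == 0:
            raise ValueError(f"taxon {self.taxon_id!r} has no sequence")

    @classmethod
    def from_strings(cls, taxon_id: str, contigs: Iterable[tuple]) -> "GenomeSequence":
        built = []
        for cid, symbols in contigs:
            symbols = symbols.upper()
            encode(symbols, cid)  # validates
            built.append(Contig(cid, symbols))
        return cls(taxon_id, built)

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    def contig(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise KeyError(contig_id)


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path, taxon_id: str | None = None, include_pattern: str | None = None) -> GenomeSequence:
    """Read a (multi-)FASTA file into a :class:`GenomeSequence`.

    One contig per record, order preserved; soft-masked lowercase is
    uppercased; the record description after the first whitespace is
    dropped.  Gzip input is transparent (``.gz`` suffix).

    Parameters
    ----------
    taxon_id:
        Label for the genome; defaults to the file stem.
    include_pattern:
        Optional regular expression; only contigs whose id matches
        (``re.search``) are kept.  Useful to exclude unplaced scaffolds or
        organelle sequences.
    """
    path = Path(path)
    if taxon_id is None:
        taxon_id = path.name.removesuffix(".gz").rsplit(".", 1)[0]
    pattern = re.compile(include_pattern) if include_pattern else None
    contigs = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            cid = rec.id
            if pattern and not pattern.search(cid):
                continue
            symbols = str(rec.seq).upper()
            if not symbols:
                raise FastaParseError(f"record {cid!r} in {path} has an empty sequence")
            encode(symbols, cid)  # validates characters
            contigs.append(Contig(cid, symbols))
    if not contigs:
        raise FastaParseError(f"no FASTA records read from {path}")
    return GenomeSequence(taxon_id, contigs)


def write_fasta(genome: GenomeSequence, path, width: int = 70) -> None:
    """Write a genome back out as FASTA (inverse of :func:`read_fasta`)."""
    with _open_text(path, "wt") as fh:
        for c in genome.contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.symbols), width):
                fh.write(c.symbols[i : i + width] + "\n")


def split_on_gaps(genome: GenomeSequence, min_gap: int = 10) -> GenomeSequence:
    """Split contigs at assembly gaps (runs of >= ``min_gap`` N symbols).

    Runs shorter than ``min_gap`` are retained in place (they are still
    excluded from counts).  Split parts keep their source contig id and
    offset so downstream intervals can be reported in assembly coordinates.
    """
    if min_gap < 1:
        raise ValueError("min_gap must be >= 1")
    gap_re = re.compile("N{%d,}" % min_gap)
    parts = []
    for c in genome.contigs:
        pos = 0
        pieces = []
        for m in gap_re.finditer(c.symbols):
            if m.start() > pos:
                pieces.append((pos, m.start()))
            pos = m.end()
        if pos < len(c.symbols):
            pieces.append((pos, len(c.symbols)))
        if len(pieces) == 1 and pieces[0] == (0, len(c.symbols)):
            parts.append(c)
            continue
        for k, (a, b) in enumerate(pieces):
            parts.append(
                Contig(
                    id=f"{c.id}|{a}-{b}",
                    symbols=c.symbols[a:b],
                    source_id=c.source_id,
                    source_start=c.source_start + a,
                )
            )
    if not parts:
        raise ValueError(f"genome {genome.taxon_id!r} is entirely gaps")
    return GenomeSequence(genome.taxon_id, parts)


class CountsIndex:
    """Per-contig cumulative base counts for O(1) range composition.

    ``cumulative(cid)`` returns an int32 array of shape (L+1, 4) whose row
    ``i`` holds the ACGT counts of the prefix [0, i); ambiguity codes add
    nothing, so range counts are exact over unambiguous bases only.
    """

    def __init__(self, genome: GenomeSequence):
        self.taxon_id = genome.taxon_id
        self._cum: dict = {}
        self._lengths: dict = {}
        for c in genome.contigs:
            codes = encode(c.symbols, c.id)
            onehot = codes[:, None] == np.arange(4, dtype=np.int8)
            cum = np.zeros((len(codes) + 1, 4), dtype=np.int32)
            np.cumsum(onehot, axis=0, out=cum[1:], dtype=np.int32)
            self._cum[c.id] = cum
            self._lengths[c.id] = len(codes)

    @property
    def contig_ids(self) -> list:
        return list(self._cum)

    def contig_length(self, contig_id: str) -> int:
        return self._lengths[contig_id]

    def cumulative(self, contig_id: str) -> np.ndarray:
        return self._cum[contig_id]

    def range_counts(self, contig_id: str, start: int, end: int) -> np.ndarray:
        """ACGT counts over [start, end); bounds-checked."""
        L = self._lengths[contig_id]
        if not (0 <= start < end <= L):
            raise IndexError(
                f"range [{start}, {end}) out of bounds for contig "
                f"{contig_id!r} of length {L}"
            )
        cum = self._cum[contig_id]
        return (cum[end] - cum[start]).astype(np.int64)


def range_counts(index: CountsIndex, contig_id: str, start: int, end: int) -> np.ndarray:
    """Module-level convenience wrapper around :meth:`CountsIndex.range_counts`."""
    return index.range_counts(contig_id, start, end)


def grouping_fraction(counts, grouping: Grouping) -> float:
    """Fraction of unambiguous bases belonging to the grouping's positive set.

    For ``SW`` this is the familiar G+C content of the range.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (4,) or (counts < 0).any():
        raise ValueError("counts must be a non-negative 4-vector (A,C,G,T)")
    total = counts.sum()
    if total == 0:
        raise CompositionError("no unambiguous bases: composition undefined")
    return float(counts[grouping.mask].sum() / total)


def grouped_cumulative(cum: np.ndarray, grouping: Grouping) -> np.ndarray:
    """Collapse a 4-column cumulative table to 2 columns (positive, negative)."""
    mask = grouping.mask
    out = np.empty((cum.shape[0], 2), dtype=cum.dtype)
    out[:, 0] = cum[:, mask].sum(axis=1)
    out[:, 1] = cum[:, ~mask].sum(axis=1)
    return out
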