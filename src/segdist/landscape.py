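"""Compositional landscapes: histograms of per-segment grouping fractions.

Once a genome has been segmented into m compositionally homogeneous
segments, the distribution of a per-segment compositional property (G+C,
A+G or G+T fraction) across those segments is the genome's *compositional
landscape* -- a compact, alignment-free signature.  Landscapes are stored
as normalised equal-width histograms over the fixed support [0, 1] so that
histograms from different genomes are directly comparable.

Each segment counts once, regardless of its length ("fraction of segments",
not of bases); a length-weighted variant is available but off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .seqio import (
    GROUPINGS,
    CountsIndex,
    GenomeSequence,
    Grouping,
    grouping_fraction,
    read_fasta,
    split_on_gaps,
)
from .segmentation import (
    SegmentationConfig,
    SegmentationResult,
    SignificanceModel,
    calibrate_null,
    segment_sequence,
    tapered_sims,
)

__all__ = [
    "CompositionHistogram",
    "segment_compositions",
    "build_histogram",
    "landscape_pipeline",
    "write_histogram_tsv",
    "read_histogram_tsv",
    "default_length_grid",
]


@dataclass
class CompositionHistogram:
    """An n-bin normalised histogram of per-segment grouping fractions.

    ``edges`` are the n+1 equally spaced bin boundaries spanning [0, 1]
    (bins are left-closed, the last bin also right-closed); ``probs`` sum
    to one; ``m_segments`` records how many segments were binned.
    """

    taxon_id: str
    grouping: str
    edges: np.ndarray
    probs: np.ndarray
    m_segments: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.edges.ndim != 1 or self.probs.ndim != 1:
            raise ValueError("edges and probs must be 1-D")
        if self.edges.size != self.probs.size + 1:
            raise ValueError("need n+1 edges for n probabilities")
        if (np.diff(self.edges) <= 0).any():
            raise ValueError("edges must be strictly increasing")
        if (self.probs < 0).any():
            raise ValueError("negative bin probability")
        if abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {self.probs.sum()!r}, not 1")
        if self.m_segments < 1:
            raise ValueError("histogram needs at least one segment")

    @property
    def n(self) -> int:
        """Number of bins."""
        return self.probs.size

    def compatible_with(self, other: "CompositionHistogram") -> bool:
        return (
            self.grouping == other.grouping
            and self.n == other.n
            and np.allclose(self.edges, other.edges)
        )


def segment_compositions(result: SegmentationResult, grouping: Grouping) -> np.ndarray:
    """One grouping fraction per segment, order preserved.

    Segments with no unambiguous base (all-N stretches) cannot be assigned
    a composition; they are dropped with a warning.
    """
    values = []
    dropped = 0
    for s in result.segments:
        if sum(s.counts) == 0:
            dropped += 1
            continue
        values.append(grouping_fraction(s.counts, grouping))
    if dropped:
        warnings.warn(
            f"{dropped} segment(s) of {result.taxon_id} had no unambiguous "
            "bases and were dropped from the landscape"
        )
    if not values:
        raise ValueError(f"no segments with defined composition in {result.taxon_id}")
    return np.asarray(values)


def build_histogram(values, n: int = 50, taxon_id: str = "",
                    grouping: str = "", meta: dict | None = None,
                    weights=None) -> CompositionHistogram:
    """Bin fractions into an n-bin normalised histogram over [0, 1].

    Bins are [i/n, (i+1)/n), the last bin closed at 1.0, and each value
    counts once unless explicit ``weights`` (e.g. segment lengths) are
    given.
    """
    values = np.asarray(values, dtype=float)
    if n < 2:
        raise ValueError("need at least 2 bins")
    if values.size == 0:
        raise ValueError("no values to bin")
    if ((values < 0) | (values > 1)).any():
        raise ValueError("fractions must lie in [0, 1]")
    edges = np.arange(n + 1) / n  # exact i/n edges
    counts, _ = np.histogram(values, bins=edges, weights=weights)
    probs = counts / counts.sum()
    return CompositionHistogram(
        taxon_id=taxon_id,
        grouping=grouping,
        edges=edges,
        probs=probs,
        m_segments=int(values.size),
        meta=dict(meta or {}),
    )


def default_length_grid(max_length: int, min_length: int = 8) -> list:
    """Powers of two spanning [min_length, >= max_length] for null calibration."""
    grid = []
    n = int(min_length)
    while n < max_length:
        grid.append(n)
        n *= 2
    grid.append(n)
    return grid


def landscape_pipeline(source, config: SegmentationConfig | None = None,
                       model: SignificanceModel | None = None,
                       n_bins: int = 50,
                       groupings=("SW", "RY", "KM"),
                       min_gap: int = 10,
                       include_pattern: str | None = None,
                       null_sims: int = 1000,
                       seed: int = 0) -> dict:
    """FASTA (or GenomeSequence) -> {grouping: CompositionHistogram}.

    One segmentation (default four-letter alphabet) is performed and reused
    for all requested groupings.  When no calibrated null model is passed,
    one is built on a powers-of-two length grid covering the longest contig,
    with null symbol probabilities estimated from the genome itself.
    """
    config = config or SegmentationConfig()
    if isinstance(source, GenomeSequence):
        genome = source
    else:
        genome = read_fasta(source, include_pattern=include_pattern)
    genome = split_on_gaps(genome, min_gap=min_gap)
    index = CountsIndex(genome)
    if model is None:
        max_len = max(index.contig_length(c) for c in index.contig_ids)
        totals = sum(
            (index.cumulative(c)[-1].astype(np.int64) for c in index.contig_ids),
            start=np.zeros(4, dtype=np.int64),
        )
        probs = totals / totals.sum()
        if config.alphabet != "ACGT":
            g = GROUPINGS[config.alphabet]
            probs = np.array([probs[g.mask].sum(), probs[~g.mask].sum()])
        model = calibrate_null(
            default_length_grid(max_len),
            k=config.k,
            n_sims=tapered_sims(null_sims),
            seed=seed,
            probs=probs,
            min_segment_length=config.min_segment_length,
        )
    result = segment_sequence(genome, config, model, index=index)
    meta = {
        "significance": config.significance,
        "alphabet": config.alphabet,
        "n_bins": n_bins,
        "seed": seed,
        "min_gap": min_gap,
    }
    out = {}
    for gname in groupings:
        values = segment_compositions(result, GROUPINGS[gname])
        out[gname] = build_histogram(values, n=n_bins, taxon_id=genome.taxon_id,
                                     grouping=gname, meta=meta)
    return out


def write_histogram_tsv(hist: CompositionHistogram, path) -> None:
    """Histogram as TSV with a self-describing provenance header."""
    with open(path, "wt") as fh:
        fh.write("#segdist-histogram\tv1\n")
        fh.write(f"#taxon={hist.taxon_id}\tgrouping={hist.grouping}\t"
                 f"n={hist.n}\tm_segments={hist.m_segments}\n")
        if hist.meta:
            fh.write("#" + "\t".join(f"{k}={v}" for k, v in sorted(hist.meta.items())) + "\n")
        fh.write("bin_lo\tbin_hi\tprob\n")
        for lo, hi, p in zip(hist.edges[:-1], hist.edges[1:], hist.probs):
            fh.write(f"{lo:.10g}\t{hi:.10g}\t{p:.12g}\n")


def read_histogram_tsv(path) -> CompositionHistogram:
    meta: dict = {}
    lo, hi, probs = [], [], []
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#segdist-histogram"):
            raise ValueError(f"{path} is not a histogram file")
        for line in fh:
            if line.startswith("#"):
                for part in line.lstrip("#").rstrip("\n").split("\t"):
                    key, _, val = part.partition("=")
                    meta[key] = val
                continue
            if line.startswith("bin_lo"):
                continue
            a, b, p = line.split("\t")
            lo.append(float(a))
            hi.append(float(b))
            probs.append(float(p))
    edges = np.array(lo + [hi[-1]])
    probs = np.array(probs)
    probs = probs / probs.sum()  # guard against rounding in the file
    return CompositionHistogram(
        taxon_id=meta.get("taxon", ""),
        grouping=meta.get("grouping", ""),
        edges=edges,
        probs=probs,
        m_segments=int(meta.get("m_segments", 1)),
        meta={k: v for k, v in meta.items()
              if k not in {"taxon", "grouping", "n", "m_segments"}},
    )
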