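"""Segment Compositional Distance between genomes and the comparative layer.

The distance D between two genomes is the Jensen-Shannon *distance* (the
square root of the Jensen-Shannon divergence, log base 2) between their
compositional landscapes.  With the square root, D satisfies all metric
axioms -- identity, symmetry, and the triangle inequality -- and is bounded
in [0, 1], hitting 1 exactly when the two histograms have disjoint
supports.  The raw-divergence variant (no square root) is available via
``mode="raw"``; the two coincide at the extreme values 0 and 1.

On top of D this module provides distance matrices, within/between-group
comparisons (Mann-Whitney U and Welch's t, one-sided) and correlation of D
with divergence times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import entr

from .landscape import CompositionHistogram

__all__ = [
    "js_divergence",
    "js_distance",
    "DistanceMatrix",
    "distance_matrix",
    "WithinBetweenReport",
    "within_between_test",
    "DivergenceTimes",
    "CorrelationReport",
    "correlate_with_time",
]

_LN2 = math.log(2.0)


def js_divergence(p, q) -> float:
    """Jensen-Shannon divergence (bits) between two probability vectors.

    H((P+Q)/2) - H(P)/2 - H(Q)/2, with 0 log 0 = 0 handled exactly (no
    pseudocounts needed for empty bins).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = 0.5 * (p + q)
    # grouping the flank entropies keeps the result bit-for-bit symmetric
    d = (entr(m).sum() - 0.5 * (entr(p).sum() + entr(q).sum())) / _LN2
    return float(min(max(d, 0.0), 1.0))


def js_distance(P: CompositionHistogram, Q: CompositionHistogram,
                mode: str = "sqrt") -> float:
    """Segment Compositional Distance between two landscapes.

    ``mode="sqrt"`` (default) returns the Jensen-Shannon distance, a true
    metric; ``mode="raw"`` returns the divergence itself.
    """
    if mode not in ("sqrt", "raw"):
        raise ValueError("mode must be 'sqrt' or 'raw'")
    if not P.compatible_with(Q):
        raise ValueError(
            f"incompatible histograms: {P.grouping}/{P.n} bins vs {Q.grouping}/{Q.n} bins"
        )
    d = js_divergence(P.probs, Q.probs)
    return math.sqrt(d) if mode == "sqrt" else d


@dataclass
class DistanceMatrix:
    """Symmetric taxon-by-taxon matrix of D values with zero diagonal."""

    taxa: tuple
    values: np.ndarray
    grouping: str = ""
    n_bins: int | None = None
    significance: float | None = None
    mode: str = "sqrt"

    def __post_init__(self):
        self.taxa = tuple(self.taxa)
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        v = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} taxa")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        v = 0.5 * (v + v.T)  # make symmetry exact
        np.fill_diagonal(v, 0.0)
        if (v < -1e-12).any():
            raise ValueError("negative distances")
        self.values = v

    def __len__(self) -> int:
        return len(self.taxa)

    def index(self, taxon: str) -> int:
        return self.taxa.index(taxon)

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def pairs(self):
        """Yield (taxon_a, taxon_b, D) over unordered pairs, a before b."""
        for i in range(len(self.taxa)):
            for j in range(i + 1, len(self.taxa)):
                yield self.taxa[i], self.taxa[j], float(self.values[i, j])

    def reorder(self, order) -> "DistanceMatrix":
        idx = [self.index(t) for t in order]
        return DistanceMatrix(tuple(order), self.values[np.ix_(idx, idx)],
                              self.grouping, self.n_bins, self.significance, self.mode)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.taxa), columns=list(self.taxa))

    # -- plain-text I/O ----------------------------------------------------

    def write_tsv(self, path) -> None:
        with open(path, "wt") as fh:
            fh.write(f"#segdist-matrix\tv1\tgrouping={self.grouping}\t"
                     f"n_bins={self.n_bins}\tsignificance={self.significance}\t"
                     f"mode={self.mode}\n")
            fh.write("taxon\t" + "\t".join(self.taxa) + "\n")
            for t, row in zip(self.taxa, self.values):
                fh.write(t + "\t" + "\t".join(f"{x:.12g}" for x in row) + "\n")

    @classmethod
    def read_tsv(cls, path) -> "DistanceMatrix":
        meta = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#segdist-matrix"):
                raise ValueError(f"{path} is not a distance-matrix file")
            for part in header.rstrip("\n").split("\t")[2:]:
                key, _, val = part.partition("=")
                meta[key] = val
            taxa = fh.readline().rstrip("\n").split("\t")[1:]
            rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
        values = np.array([[float(x) for x in r[1:]] for r in rows])
        n_bins = None if meta.get("n_bins") in (None, "None") else int(meta["n_bins"])
        sig = None if meta.get("significance") in (None, "None") else float(meta["significance"])
        return cls(tuple(taxa), values, meta.get("grouping", ""), n_bins, sig,
                   meta.get("mode", "sqrt"))

    def write_phylip(self, path) -> None:
        """Lower-triangle PHYLIP-compatible matrix."""
        with open(path, "wt") as fh:
            fh.write(f"{len(self.taxa)}\n")
            for i, t in enumerate(self.taxa):
                row = " ".join(f"{self.values[i, j]:.6f}" for j in range(i))
                fh.write(f"{t:<12s} {row}".rstrip() + "\n")


def distance_matrix(histograms, mode: str = "sqrt") -> DistanceMatrix:
    """All pairwise D between a collection of per-taxon landscapes."""
    hists = list(histograms)
    if len(hists) < 2:
        raise ValueError("need at least 2 taxa")
    taxa = [h.taxon_id for h in hists]
    if len(set(taxa)) != len(taxa):
        raise ValueError(f"duplicate taxon labels: {taxa}")
    n = len(hists)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = js_distance(hists[i], hists[j], mode=mode)
    h0 = hists[0]
    return DistanceMatrix(
        tuple(taxa), values, grouping=h0.grouping, n_bins=h0.n,
        significance=h0.meta.get("significance"), mode=mode,
    )


@dataclass
class WithinBetweenReport:
    """Within-group vs between-group D, with one-sided tests (within < between)."""

    groups: dict
    within: np.ndarray
    between: np.ndarray
    mannwhitney_u: float
    mannwhitney_p: float
    welch_t: float
    welch_p: float

    def to_dict(self) -> dict:
        return {
            "n_within": int(self.within.size),
            "n_between": int(self.between.size),
            "within_mean": float(self.within.mean()),
            "between_mean": float(self.between.mean()),
            "mannwhitney_u": self.mannwhitney_u,
            "mannwhitney_p": self.mannwhitney_p,
            "welch_t": self.welch_t,
            "welch_p": self.welch_p,
        }


def within_between_test(m: DistanceMatrix, labels: Mapping) -> WithinBetweenReport:
    """Partition pairs by shared group label and test within < between.

    Runs the Mann-Whitney U rank test and Welch's unequal-variance t test,
    both one-sided with the alternative that within-group distances are
    smaller.  Groups of size one contribute no within pairs (warned via the
    report's counts); at least one group must have two members.
    """
    missing = [t for t in m.taxa if t not in labels]
    if missing:
        raise ValueError(f"no group label for taxa: {missing}")
    groups = set(labels[t] for t in m.taxa)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    within, between = [], []
    for a, b, d in m.pairs():
        (within if labels[a] == labels[b] else between).append(d)
    if not within:
        raise ValueError("no within-group pairs (all groups of size 1?)")
    within = np.asarray(within)
    between = np.asarray(between)
    u, up = stats.mannwhitneyu(within, between, alternative="less")
    t, tp = stats.ttest_ind(within, between, equal_var=False, alternative="less")
    return WithinBetweenReport(
        groups={g: [t_ for t_ in m.taxa if labels[t_] == g] for g in sorted(groups, key=str)},
        within=within,
        between=between,
        mannwhitney_u=float(u),
        mannwhitney_p=float(up),
        welch_t=float(t),
        welch_p=float(tp),
    )


class DivergenceTimes:
    """Pairwise divergence times (My), possibly anchored to a reference taxon.

    Built either from a symmetric pairwise table or from a table of times
    to a single reference species (the usual TimeTree export).
    """

    def __init__(self, pairwise: Mapping):
        self._times: dict = {}
        for (a, b), t in pairwise.items():
            t = float(t)
            if t < 0:
                raise ValueError(f"negative divergence time for ({a}, {b})")
            self._times[frozenset((a, b))] = t

    @classmethod
    def from_reference_table(cls, times: Mapping, reference: str) -> "DivergenceTimes":
        return cls({(reference, taxon): t for taxon, t in times.items()
                    if taxon != reference})

    @classmethod
    def from_tree(cls, tree) -> "DivergenceTimes":
        """Half the patristic distance between each tip pair of an ultrametric tree."""
        labels = tree.tip_labels
        pat = tree.patristic_matrix(labels)
        return cls({(labels[i], labels[j]): pat[i, j] / 2.0
                    for i in range(len(labels)) for j in range(i + 1, len(labels))})

    def has_pair(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self._times

    def get(self, a: str, b: str) -> float:
        try:
            return self._times[frozenset((a, b))]
        except KeyError:
            raise KeyError(f"no divergence time for pair ({a}, {b})") from None


@dataclass
class CorrelationReport:
    """Pearson and Spearman correlation of D against divergence time."""

    pearson_r: float | None
    pearson_p: float | None
    spearman_rho: float | None
    spearman_p: float | None
    n_pairs: int
    note: str = ""


def correlate_with_time(m: DistanceMatrix, times: DivergenceTimes,
                        mode: str = "all", reference: str | None = None) -> CorrelationReport:
    """Correlate pairwise D with divergence times.

    ``mode="all"`` uses every unordered pair; ``mode="reference"`` restricts
    to pairs involving ``reference`` (the species-anchored analysis).
    Degenerate inputs (constant D or constant time) are reported as
    undefined rather than propagating NaN.
    """
    if mode not in ("all", "reference"):
        raise ValueError("mode must be 'all' or 'reference'")
    if mode == "reference":
        if reference is None or reference not in m.taxa:
            raise ValueError("reference mode needs a reference taxon present in the matrix")
        pairs = [(reference, t) for t in m.taxa if t != reference]
    else:
        pairs = [(a, b) for a, b, _ in m.pairs()]
    missing = [p for p in pairs if not times.has_pair(*p)]
    if missing:
        raise ValueError(f"missing divergence times for pairs: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    d = np.array([m.pair(a, b) for a, b in pairs])
    t = np.array([times.get(a, b) for a, b in pairs])
    if np.ptp(d) == 0 or np.ptp(t) == 0:
        return CorrelationReport(None, None, None, None, len(pairs),
                                 note="undefined: constant input")
    pr, pp = stats.pearsonr(d, t)
    sr, sp = stats.spearmanr(d, t)
    return CorrelationReport(float(pr), float(pp), float(sr), float(sp), len(pairs))
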