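"""Recursive entropic segmentation of DNA with a Monte-Carlo calibrated test.

The segmenter slides a cursor along a sequence and, at every admissible cut
position i, evaluates the Jensen-Shannon divergence between the nucleotide
frequency vectors of the left and right flanks,

    d(i) = H(S) - (n1/N) H(S1) - (n2/N) H(S2)        [bits],

where H is the Shannon entropy of the base frequencies.  The position
maximising d is accepted as a change point when the maximum is statistically
significant against the null hypothesis of an i.i.d. homogeneous sequence of
the same length, and the procedure recurses into both halves.  The null
distribution of the maximum divergence has no convenient closed form, so it
is estimated here by Monte-Carlo simulation over a grid of sequence lengths
and interpolated on log N (:func:`calibrate_null`).

A dynamic-programming segmenter that is globally optimal for a fixed number
of cuts (:func:`optimal_segmentation_dp`) is provided as a slow, quadratic
reference for validating the heuristic; the recursion and the DP optimise
the same objective.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import xlogy

from .seqio import (
    GROUPINGS,
    CountsIndex,
    GenomeSequence,
    encode,
    grouped_cumulative,
)

__all__ = [
    "shannon_entropy",
    "jsd_split",
    "divergence_profile",
    "max_split",
    "SplitCandidate",
    "SignificanceModel",
    "calibrate_null",
    "p_value",
    "SegmentationConfig",
    "Segment",
    "SegmentationResult",
    "segment_sequence",
    "optimal_segmentation_dp",
    "write_segments_bed",
    "write_segments_tsv",
    "NullModelRangeError",
]

_LN2 = np.log(2.0)


class NullModelRangeError(ValueError):
    """A p-value was requested for a length outside the calibrated grid."""


def shannon_entropy(freqs) -> float:
    """Shannon entropy of a probability vector, in bits (0 log 0 = 0)."""
    f = np.asarray(freqs, dtype=float)
    if (f < -1e-12).any():
        raise ValueError("negative frequency")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies sum to {f.sum()!r}, not 1")
    f = np.clip(f, 0.0, None)
    return float(-(xlogy(f, f)).sum() / _LN2)


def _counts_entropy(counts) -> float:
    """Entropy (bits) of the frequency vector implied by a count vector."""
    c = np.asarray(counts, dtype=float)
    n = c.sum()
    if n <= 0:
        raise ValueError("empty count vector")
    return float(np.log2(n) - (xlogy(c, c)).sum() / _LN2 / n)


def jsd_split(left_counts, right_counts) -> float:
    """Jensen-Shannon divergence (bits) between two flank count vectors.

    Frequencies are taken from the counts; the flank entropies are weighted
    by their share of the total.  Symmetric, in [0, log2 k].
    """
    left = np.asarray(left_counts, dtype=float)
    right = np.asarray(right_counts, dtype=float)
    n1, n2 = left.sum(), right.sum()
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both flanks need at least one counted symbol")
    n = n1 + n2
    d = (
        _counts_entropy(left + right)
        - (n1 / n) * _counts_entropy(left)
        - (n2 / n) * _counts_entropy(right)
    )
    return float(max(d, 0.0))


def _xlog2_table(nmax: int) -> np.ndarray:
    """Lookup table t[c] = c*log2(c) for integer counts 0..nmax."""
    c = np.arange(nmax + 1, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = c * np.log2(c)
    t[0] = 0.0
    return t


@dataclass(frozen=True)
class SplitCandidate:
    """A candidate change point: cut between position-1 and position."""

    position: int
    divergence: float


def _d_at_positions(cum: np.ndarray, start: int, end: int,
                    positions: np.ndarray, table: np.ndarray) -> np.ndarray:
    """d at the given cut positions of [start, end), from a cumulative table.

    Cuts leaving a flank without any counted symbol get d = -inf (no valid
    frequency vector on that side).
    """
    total = (cum[end] - cum[start]).astype(np.int64)
    ntot = int(total.sum())
    if ntot == 0:
        return np.full(positions.size, -np.inf)
    left = (cum[positions] - cum[start]).astype(np.int64)
    nl = left.sum(axis=1)
    right = total[None, :] - left
    nr = ntot - nl
    h_total = np.log2(ntot) - table[total].sum() / ntot
    sl = table[left].sum(axis=1)
    sr = table[right].sum(axis=1)
    nl_safe = np.maximum(nl, 1)
    nr_safe = np.maximum(nr, 1)
    # weighted flank entropies: (n_side/ntot) * (log2 n_side - S_side/n_side)
    d = h_total - (nl * np.log2(nl_safe) - sl + nr * np.log2(nr_safe) - sr) / ntot
    d = np.maximum(d, 0.0)
    d[(nl == 0) | (nr == 0)] = -np.inf
    return d


def _profile_from_cum(cum: np.ndarray, start: int, end: int,
                      min_segment_length: int = 1,
                      table: np.ndarray | None = None):
    """d(i) for every admissible cut of [start, end); returns (positions, d)."""
    positions = np.arange(start + min_segment_length,
                          end - min_segment_length + 1, dtype=np.int64)
    if positions.size == 0 or end - start < 2:
        return positions[:0], np.empty(0)
    if table is None:
        ntot = int((cum[end] - cum[start]).sum())
        table = _xlog2_table(max(ntot, 1))
    return positions, _d_at_positions(cum, start, end, positions, table)


#: Above this subsequence length the maximising cut is located by a coarse
#: stride scan followed by exact refinement around the coarse optimum.  The
#: profile changes by O(log N / N) per position, so the refined maximum is
#: within O(stride log N / N) of the global one, while the search cost drops
#: from O(N) to O(N/stride).  The Monte-Carlo null simulation applies the
#: identical search, so the significance test stays exactly calibrated
#: against its own statistic.  Below the limit the search is exhaustive.
_EXHAUSTIVE_LIMIT = 16_384


def _best_split(cum: np.ndarray, start: int, end: int,
                min_segment_length: int, table: np.ndarray):
    """Maximising cut of [start, end), or None if no admissible cut exists."""
    lo = start + min_segment_length
    hi = end - min_segment_length
    if hi < lo or end - start < 2:
        return None
    n = end - start
    if n <= _EXHAUSTIVE_LIMIT:
        positions = np.arange(lo, hi + 1, dtype=np.int64)
        d = _d_at_positions(cum, start, end, positions, table)
    else:
        stride = max(2, n // 8_192)
        coarse = np.arange(lo, hi + 1, stride, dtype=np.int64)
        d_coarse = _d_at_positions(cum, start, end, coarse, table)
        j0 = int(coarse[np.argmax(d_coarse)])
        positions = np.arange(max(lo, j0 - 2 * stride),
                              min(hi, j0 + 2 * stride) + 1, dtype=np.int64)
        d = _d_at_positions(cum, start, end, positions, table)
    if not np.isfinite(d.max()):
        return None
    return max_split(positions, d)


def divergence_profile(index: CountsIndex, contig_id: str,
                       start: int | None = None, end: int | None = None,
                       min_segment_length: int = 1):
    """Divergence d(i) at every admissible cut of a contig range.

    Equivalent to calling :func:`jsd_split` at every position, but O(1) per
    position via the cumulative count table.  Returns (positions, d) where
    position i means a cut between i-1 and i (flanks [start,i), [i,end)).
    """
    L = index.contig_length(contig_id)
    start = 0 if start is None else start
    end = L if end is None else end
    if not (0 <= start < end <= L):
        raise IndexError(f"range [{start}, {end}) out of bounds (contig length {L})")
    return _profile_from_cum(index.cumulative(contig_id), start, end,
                             min_segment_length)


def max_split(positions: np.ndarray, d: np.ndarray) -> SplitCandidate:
    """The maximising cut; ties broken by the leftmost position."""
    if len(positions) == 0:
        raise ValueError("empty divergence profile")
    i = int(np.argmax(d))  # argmax returns the first maximum -> leftmost tie-break
    return SplitCandidate(position=int(positions[i]), divergence=float(max(d[i], 0.0)))


# ---------------------------------------------------------------------------
# Null model for the maximum divergence of an i.i.d. sequence
# ---------------------------------------------------------------------------


@dataclass
class SignificanceModel:
    """Empirical null distribution of max d(i) for i.i.d. sequences.

    For each length N on a grid, ``samples[N]`` holds the sorted maxima of
    the divergence profile over ``n_sims`` simulated i.i.d. sequences.  The
    CDF at intermediate lengths is interpolated linearly on log N.
    """

    k: int
    grid: tuple
    samples: dict
    n_sims: int
    seed: int
    probs: tuple | None = None
    min_segment_length: int = 1

    def covers(self, n: int) -> bool:
        return self.grid[0] <= n <= self.grid[-1]

    def _cdf_at_grid(self, dmax: float, n_grid: int) -> float:
        s = self.samples[n_grid]
        return float(np.searchsorted(s, dmax, side="right") / s.size)

    def cdf(self, dmax: float, n: int) -> float:
        """P(max null divergence <= dmax) at sequence length n."""
        if not self.covers(n):
            raise NullModelRangeError(
                f"length {n} outside calibrated grid [{self.grid[0]}, {self.grid[-1]}]"
            )
        if n in self.samples:
            return self._cdf_at_grid(dmax, n)
        hi_idx = int(np.searchsorted(self.grid, n))
        n_lo, n_hi = self.grid[hi_idx - 1], self.grid[hi_idx]
        w = (np.log(n) - np.log(n_lo)) / (np.log(n_hi) - np.log(n_lo))
        return (1.0 - w) * self._cdf_at_grid(dmax, n_lo) + w * self._cdf_at_grid(dmax, n_hi)

    def p_value(self, dmax: float, n: int) -> float:
        """1 - P(dmax); monotone non-increasing in dmax."""
        if dmax <= 0.0:
            return 1.0
        if dmax >= np.log2(self.k) - 1e-12:
            return 0.0
        return 1.0 - self.cdf(dmax, n)

    def quantile(self, q: float, n: int) -> float:
        if n not in self.samples:
            raise NullModelRangeError(f"{n} is not a grid point")
        return float(np.quantile(self.samples[n], q))

    # -- plain-text persistence -------------------------------------------

    def save(self, path) -> None:
        with open(path, "wt") as fh:
            fh.write("#segdist-null-table\tv1\n")
            probs = "uniform" if self.probs is None else ",".join(f"{p:.10g}" for p in self.probs)
            fh.write(f"#k={self.k}\tn_sims={self.n_sims}\tseed={self.seed}\t"
                     f"min_segment_length={self.min_segment_length}\tprobs={probs}\n")
            for n in self.grid:
                for v in self.samples[n]:
                    fh.write(f"{n}\t{v:.12g}\n")

    @classmethod
    def load(cls, path) -> "SignificanceModel":
        meta = {}
        samples: dict = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#segdist-null-table"):
                raise ValueError(f"{path} is not a null-table file")
            for part in fh.readline().lstrip("#").split("\t"):
                key, _, val = part.partition("=")
                meta[key.strip()] = val.strip()
            for line in fh:
                n_s, v_s = line.split("\t")
                samples.setdefault(int(n_s), []).append(float(v_s))
        probs = None if meta["probs"] == "uniform" else tuple(float(x) for x in meta["probs"].split(","))
        grid = tuple(sorted(samples))
        return cls(
            k=int(meta["k"]),
            grid=grid,
            samples={n: np.sort(np.array(v)) for n, v in samples.items()},
            n_sims=int(meta["n_sims"]),
            seed=int(meta["seed"]),
            probs=probs,
            min_segment_length=int(meta["min_segment_length"]),
        )


def _simulate_max_divergence(n: int, k: int, n_sims: int, rng: np.random.Generator,
                             probs=None, min_segment_length: int = 1) -> np.ndarray:
    table = _xlog2_table(n)
    out = np.empty(n_sims)
    cum = np.empty((n + 1, k), dtype=np.int32)
    codes_range = np.arange(k, dtype=np.int8)
    for s in range(n_sims):
        if probs is None:
            codes = rng.integers(0, k, size=n, dtype=np.int8)
        else:
            codes = rng.choice(k, size=n, p=probs).astype(np.int8)
        cum[0] = 0
        np.cumsum(codes[:, None] == codes_range, axis=0, out=cum[1:], dtype=np.int32)
        cand = _best_split(cum, 0, n, min_segment_length, table)
        out[s] = cand.divergence if cand is not None else 0.0
    return np.sort(out)


def calibrate_null(n_grid: Sequence[int], k: int = 4, n_sims: int = 1000,
                   seed: int = 0, probs=None,
                   min_segment_length: int = 1) -> SignificanceModel:
    """Estimate the null distribution of max d(i) by Monte-Carlo simulation.

    Parameters
    ----------
    n_grid:
        Sequence lengths to calibrate at (each >= 4).  p-values at other
        lengths are interpolated on log N, so the grid should bracket every
        length that will be tested.
    n_sims:
        Simulations per grid point: an int, or a callable N -> int to spend
        fewer simulations on the largest lengths (each simulation is O(N)).
    probs:
        Symbol probabilities of the i.i.d. null (``None`` = uniform).
        Typically the frequency vector estimated from the data under study.

    Deterministic given ``seed``: each grid point draws from an independent
    stream keyed by (seed, N), so the table does not depend on grid order.
    """
    grid = tuple(sorted(set(int(n) for n in n_grid)))
    if not grid:
        raise ValueError("empty length grid")
    if grid[0] < 4:
        raise ValueError(f"grid lengths must be >= 4, got {grid[0]}")
    if k not in (2, 4):
        raise ValueError("alphabet size must be 2 or 4")
    if probs is not None:
        probs = np.asarray(probs, dtype=float)
        if probs.size != k or abs(probs.sum() - 1) > 1e-9 or (probs < 0).any():
            raise ValueError("probs must be a length-k probability vector")
    sims_at = n_sims if callable(n_sims) else (lambda _n: int(n_sims))
    samples = {}
    for n in grid:
        rng = np.random.default_rng([int(seed), int(n)])
        samples[n] = _simulate_max_divergence(n, k, max(int(sims_at(n)), 100),
                                              rng, probs, min_segment_length)
    return SignificanceModel(
        k=k,
        grid=grid,
        samples=samples,
        n_sims=min(s.size for s in samples.values()),
        seed=int(seed),
        probs=None if probs is None else tuple(probs),
        min_segment_length=min_segment_length,
    )


def p_value(dmax: float, n: int, model: SignificanceModel) -> float:
    """Probability of a null max divergence >= dmax at sequence length n."""
    return model.p_value(dmax, n)


def tapered_sims(base: int, knee: int = 131072, factor: int = 4):
    """Simulation-count schedule spending ``base`` sims up to ``knee`` and
    ``base/factor`` beyond, where each null simulation costs O(N)."""
    return lambda n: base if n <= knee else max(100, base // factor)


# ---------------------------------------------------------------------------
# Recursive segmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegmentationConfig:
    """Knobs of the recursive segmenter.

    ``significance`` is s = 1 - p0: a cut is accepted when its p-value falls
    below p0.  ``alphabet`` is ``"ACGT"`` (the default four-letter
    segmentation) or one of the grouping names (``"SW"``/``"RY"``/``"KM"``),
    in which case the sequence is first mapped to the two-letter grouping
    alphabet and segmented there.
    """

    significance: float = 0.95
    alphabet: str = "ACGT"
    min_segment_length: int = 1
    max_depth: int | None = None

    def __post_init__(self):
        if not (0.0 < self.significance < 1.0):
            raise ValueError("significance must be in (0, 1)")
        if self.alphabet != "ACGT" and self.alphabet not in GROUPINGS:
            raise ValueError(f"alphabet must be 'ACGT' or one of {list(GROUPINGS)}")
        if self.min_segment_length < 1:
            raise ValueError("min_segment_length must be >= 1")

    @property
    def p0(self) -> float:
        return 1.0 - self.significance

    @property
    def k(self) -> int:
        return 4 if self.alphabet == "ACGT" else 2


@dataclass(frozen=True)
class Segment:
    """A homogeneous segment [start, end) of a contig, with its base counts."""

    contig: str
    start: int
    end: int
    counts: tuple  # (#A, #C, #G, #T) over unambiguous bases

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SegmentationResult:
    """Ordered, tiling segments of a genome at a given significance level."""

    taxon_id: str
    config: SegmentationConfig
    segments: list
    contig_lengths: dict

    @property
    def m(self) -> int:
        """Number of segments."""
        return len(self.segments)

    def validate(self) -> None:
        """Check that segments tile every contig exactly."""
        by_contig: dict = {}
        for s in self.segments:
            by_contig.setdefault(s.contig, []).append(s)
        if set(by_contig) != set(self.contig_lengths):
            raise AssertionError("segment contigs do not match contig set")
        for cid, segs in by_contig.items():
            segs = sorted(segs, key=lambda s: s.start)
            if segs[0].start != 0 or segs[-1].end != self.contig_lengths[cid]:
                raise AssertionError(f"contig {cid} not fully covered")
            for a, b in zip(segs, segs[1:]):
                if a.end != b.start:
                    raise AssertionError(f"gap/overlap at {cid}:{a.end}")


def segment_sequence(genome: GenomeSequence, config: SegmentationConfig,
                     model: SignificanceModel,
                     index: CountsIndex | None = None) -> SegmentationResult:
    """Recursively segment every contig of a genome.

    Each subsequence is tested at its own length N: the maximising cut is
    accepted when ``model.p_value(dmax, N) < p0`` and the recursion then
    descends into both halves.  Subsequences shorter than the calibrated
    grid minimum are never cut (at such lengths no divergence can clear a
    sensibly calibrated null); contigs longer than the grid maximum raise
    :class:`NullModelRangeError` rather than extrapolating silently.
    """
    if model.k != config.k:
        raise ValueError(
            f"null model alphabet size {model.k} does not match config ({config.k})"
        )
    if index is None:
        index = CountsIndex(genome)
    p0 = config.p0
    msl = config.min_segment_length
    segments = []
    contig_lengths = {}
    for contig in genome.contigs:
        cid = contig.id
        L = index.contig_length(cid)
        contig_lengths[cid] = L
        cum4 = index.cumulative(cid)
        if config.alphabet == "ACGT":
            cum_seg = cum4
        else:
            cum_seg = grouped_cumulative(cum4, GROUPINGS[config.alphabet])
        if L > model.grid[-1]:
            raise NullModelRangeError(
                f"contig {cid!r} (length {L}) exceeds null grid max {model.grid[-1]}"
            )
        ntot = int(cum_seg[L].sum() - cum_seg[0].sum())
        table = _xlog2_table(max(ntot, 1))
        stack = [(0, L, 0)]
        while stack:
            a, b, depth = stack.pop()
            n = b - a
            cut = None
            depth_ok = config.max_depth is None or depth < config.max_depth
            if depth_ok and n >= 2 * msl and n >= model.grid[0]:
                cand = _best_split(cum_seg, a, b, msl, table)
                if cand is not None and cand.divergence > 0 \
                        and model.p_value(cand.divergence, n) < p0:
                    cut = cand.position
            if cut is None:
                counts = tuple(int(x) for x in (cum4[b] - cum4[a]))
                segments.append(Segment(cid, a, b, counts))
            else:
                stack.append((cut, b, depth + 1))
                stack.append((a, cut, depth + 1))
    segments.sort(key=lambda s: (list(contig_lengths).index(s.contig), s.start))
    return SegmentationResult(genome.taxon_id, config, segments, contig_lengths)


# ---------------------------------------------------------------------------
# Optimal dynamic-programming segmenter (quadratic; reference implementation)
# ---------------------------------------------------------------------------


def optimal_segmentation_dp(seq, n_cuts: int, min_segment_length: int = 1):
    """Globally optimal placement of ``n_cuts`` cuts on a single sequence.

    Maximises the total weighted divergence

        J = H(S) - sum_j (n_j / N) H(S_j),

    the same objective the recursive heuristic optimises greedily (for one
    cut the two coincide exactly).  O(n_cuts * N^2); intended for validation
    on short sequences, not production use.

    ``seq`` may be a string, an int8 code array, or a single-contig
    :class:`~segdist.seqio.GenomeSequence`.  Returns ``(segments, J)`` with
    segments as (start, end) pairs.
    """
    if isinstance(seq, GenomeSequence):
        if len(seq.contigs) != 1:
            raise ValueError("DP oracle operates on a single contig")
        codes = encode(seq.contigs[0].symbols, seq.contigs[0].id)
    elif isinstance(seq, str):
        codes = encode(seq)
    else:
        codes = np.asarray(seq, dtype=np.int8)
    n = len(codes)
    if n_cuts < 0 or n_cuts >= n:
        raise ValueError(f"number of cuts must be in [0, {n - 1}]")
    if n > 50_000:
        raise ValueError("sequence too long for the quadratic DP oracle")
    k = 4
    cum = np.zeros((n + 1, k), dtype=np.int64)
    np.cumsum(codes[:, None] == np.arange(k, dtype=np.int8), axis=0, out=cum[1:])
    total = cum[n]
    ntot = int(total.sum())
    if ntot == 0:
        raise ValueError("sequence has no unambiguous bases")
    table = _xlog2_table(ntot)

    def weighted_cost(a_idx: np.ndarray, b: int) -> np.ndarray:
        """n_seg * H(seg) (in bits) for segments [a, b), vector over a."""
        c = cum[b] - cum[a_idx]
        nseg = c.sum(axis=1).astype(np.float64)
        with np.errstate(divide="ignore", invalid="ignore"):
            cost = nseg * np.log2(np.maximum(nseg, 1)) - table[c].sum(axis=1)
        return cost

    msl = min_segment_length
    inf = np.inf
    # dp[b] = min total weighted entropy of covering [0, b) with (c+1) segments
    dp = np.full(n + 1, inf)
    for b in range(msl, n + 1):
        dp[b] = weighted_cost(np.array([0]), b)[0]
    back = [np.zeros(n + 1, dtype=np.int64)]
    for c in range(1, n_cuts + 1):
        dp_new = np.full(n + 1, inf)
        back_c = np.zeros(n + 1, dtype=np.int64)
        lo = (c + 1) * msl  # earliest b with c+1 segments of length >= msl
        for b in range(lo, n + 1):
            a_lo, a_hi = c * msl, b - msl
            a_idx = np.arange(a_lo, a_hi + 1)
            cand = dp[a_idx] + weighted_cost(a_idx, b)
            j = int(np.argmin(cand))  # first minimum -> leftmost cut
            dp_new[b] = cand[j]
            back_c[b] = a_idx[j]
        dp = dp_new
        back.append(back_c)
    # backtrack
    cuts = []
    b = n
    for c in range(n_cuts, 0, -1):
        a = int(back[c][b])
        cuts.append(a)
        b = a
    cuts = sorted(cuts)
    bounds = [0] + cuts + [n]
    segments = list(zip(bounds[:-1], bounds[1:]))
    h_total = float(np.log2(ntot) - table[total].sum() / ntot)
    objective = h_total - float(dp[n]) / ntot
    return segments, objective


# ---------------------------------------------------------------------------
# Plain-text writers
# ---------------------------------------------------------------------------


def write_segments_bed(result: SegmentationResult, genome: GenomeSequence, path) -> None:
    """BED4 of segments, in source-assembly coordinates."""
    contig_by_id = {c.id: c for c in genome.contigs}
    with open(path, "wt") as fh:
        for k_, s in enumerate(result.segments):
            c = contig_by_id[s.contig]
            fh.write(f"{c.source_id}\t{c.source_start + s.start}\t"
                     f"{c.source_start + s.end}\tseg_{k_}\n")


def write_segments_tsv(result: SegmentationResult, path) -> None:
    """Per-segment counts and SW/RY/KM fractions, with a provenance header."""
    from .seqio import GROUPINGS as _G
    from .seqio import grouping_fraction

    cfg = result.config
    with open(path, "wt") as fh:
        fh.write(f"#taxon={result.taxon_id}\tsignificance={cfg.significance}\t"
                 f"alphabet={cfg.alphabet}\tmin_segment_length={cfg.min_segment_length}\n")
        fh.write("contig\tstart\tend\tn_A\tn_C\tn_G\tn_T\tSW\tRY\tKM\n")
        for s in result.segments:
            if sum(s.counts) > 0:
                fr = [f"{grouping_fraction(s.counts, g):.6f}" for g in _G.values()]
            else:
                fr = ["NA", "NA", "NA"]
            fh.write(f"{s.contig}\t{s.start}\t{s.end}\t"
                     + "\t".join(str(c) for c in s.counts)
                     + "\t" + "\t".join(fr) + "\n")
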