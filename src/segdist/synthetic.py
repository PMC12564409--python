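"""Synthetic genomes, drifting landscapes and traits with known ground truth.

Real genomes enter the method only through two properties: they are
concatenations of compositionally homogeneous segments, and the per-segment
compositions differ between species in a way that accumulates with
separation time.  The generator here reproduces exactly those two
properties -- segments with lengths drawn from a geometric or log-normal
law, per-segment G+C drawn from a beta mixture, purine (RY) and keto (KM)
fractions drawn from near-symmetric betas around 0.5 (Chargaff's second
rule), and bases i.i.d. within a segment.  Species are derived from a
common ancestor by Brownian drift of the component means on the logit
scale, so compositions stay in (0, 1) without truncation and the expected
compositional distance grows with separation time.

Everything is deterministic given (parameters, seed) and returns its ground
truth (true segment boundaries and compositions, the guide tree) alongside
the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .phylo import PhyloTree
from .seqio import Contig, GenomeSequence

__all__ = [
    "LandscapeModel",
    "TrueSegment",
    "simulate_genome",
    "sample_segment_compositions",
    "EvolutionParams",
    "evolve_models",
    "evolve_landscapes",
    "simulate_bm_trait",
    "coalescent_tree",
    "pure_birth_tree",
    "clade_tree",
    "ladder_tree",
    "mammal_divergence_table",
    "mammal_guide_tree",
]

_BASE_LUT = np.frombuffer("ACGT".encode(), dtype=np.uint8)


def _default_gc_families(k: int = 24, lo: float = 0.22, hi: float = 0.72,
                         centre: float = 0.46, width: float = 0.13) -> tuple:
    """Means and weights of the default segment-GC family mixture."""
    means = np.linspace(lo, hi, k)
    w = np.exp(-0.5 * ((means - centre) / width) ** 2)
    return tuple(means), tuple(w / w.sum())


_DEFAULT_GC_MEANS, _DEFAULT_GC_WEIGHTS = _default_gc_families()


@dataclass(frozen=True)
class LandscapeModel:
    """Generative model of a genome's compositional landscape.

    Defaults describe a genome built from many isochore-like segment
    families: per-segment G+C is drawn from a fine mixture of 24 narrow
    beta components spanning G+C 0.22-0.72 with a smooth unimodal weight
    profile, so the landscape has many independently evolvable degrees of
    freedom (family positions *and* abundances) -- the property that makes
    compositional distance track divergence time.  RY and KM fractions sit
    tightly around 0.5 (Chargaff's second rule).  ``concentration``
    parameters are beta concentrations (a + b); larger means narrower
    spread around the mean.  The 5 Mb default length with 2.5 kb mean
    segments yields about two thousand segments per genome.
    """

    genome_length: int = 5_000_000
    n_contigs: int = 8
    mean_segment_length: float = 2_500.0
    segment_length_law: str = "lognormal"  # or "geometric"
    segment_length_sigma: float = 0.6  # log-sd of the lognormal law
    gc_weights: tuple = _DEFAULT_GC_WEIGHTS
    gc_means: tuple = _DEFAULT_GC_MEANS
    gc_concentration: float = 1_200.0
    ry_mean: float = 0.5
    km_mean: float = 0.5
    skew_concentration: float = 800.0

    def __post_init__(self):
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        if not (1 <= self.n_contigs <= self.genome_length):
            raise ValueError("n_contigs must be in [1, genome_length]")
        if self.mean_segment_length < 1:
            raise ValueError("mean_segment_length must be >= 1")
        if self.segment_length_law not in ("geometric", "lognormal"):
            raise ValueError("segment_length_law must be 'geometric' or 'lognormal'")
        w = np.asarray(self.gc_weights, dtype=float)
        if len(w) != len(self.gc_means) or abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
            raise ValueError("gc_weights must be a probability vector matching gc_means")
        for v in (*self.gc_means, self.ry_mean, self.km_mean):
            if not (0.0 < v < 1.0):
                raise ValueError("composition means must be in (0, 1)")
        for c in (self.gc_concentration, self.skew_concentration):
            if c <= 0:
                raise ValueError("concentrations must be positive")


@dataclass(frozen=True)
class TrueSegment:
    """Ground-truth segment: coordinates plus the generating composition."""

    start: int
    end: int
    gc: float
    ry: float
    km: float
    probs: tuple  # (A, C, G, T) base probabilities
    contig: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


def _base_probs(gc: float, ry: float, km: float) -> np.ndarray:
    """(A, C, G, T) probabilities with given G+C, A+G and G+T fractions.

    The linear system has the closed-form solution fG = (gc+ry+km-1)/2 and
    the rest by subtraction.  Extreme draws can push a base probability
    slightly negative; those are clipped to a small floor and renormalised
    (a rare event for the near-symmetric skews the generator uses).
    """
    fg = (gc + ry + km - 1.0) / 2.0
    p = np.array([ry - fg, gc - fg, fg, km - fg])
    p = np.clip(p, 1e-4, None)
    return p / p.sum()


def _draw_beta(rng: np.random.Generator, mean: float, concentration: float) -> float:
    return float(rng.beta(mean * concentration, (1.0 - mean) * concentration))


def _segment_lengths(model: LandscapeModel, rng: np.random.Generator) -> np.ndarray:
    lengths = []
    total = 0
    while total < model.genome_length:
        if model.segment_length_law == "geometric":
            L = int(rng.geometric(1.0 / model.mean_segment_length))
        else:
            s = model.segment_length_sigma
            mu = math.log(model.mean_segment_length) - 0.5 * s * s
            L = max(1, int(round(rng.lognormal(mu, s))))
        lengths.append(L)
        total += L
    lengths[-1] -= total - model.genome_length  # truncate to exact length
    if lengths[-1] == 0:
        lengths.pop()
    return np.array(lengths, dtype=np.int64)


def sample_segment_compositions(model: LandscapeModel,
                                rng: np.random.Generator) -> list:
    """Draw ground-truth segments (no bases) from a landscape model."""
    lengths = _segment_lengths(model, rng)
    weights = np.asarray(model.gc_weights, dtype=float)
    segments = []
    pos = 0
    for L in lengths:
        comp = int(rng.choice(len(weights), p=weights))
        gc = _draw_beta(rng, model.gc_means[comp], model.gc_concentration)
        ry = _draw_beta(rng, model.ry_mean, model.skew_concentration)
        km = _draw_beta(rng, model.km_mean, model.skew_concentration)
        probs = _base_probs(gc, ry, km)
        segments.append(TrueSegment(pos, pos + int(L), gc, ry, km, tuple(probs)))
        pos += int(L)
    return segments


def simulate_genome(model: LandscapeModel, seed: int,
                    taxon_id: str = "sim") -> tuple:
    """Simulate one genome: (GenomeSequence, ground-truth segment list).

    Bases are i.i.d. within each segment according to its composition
    vector.  The segment stream is packed into ``model.n_contigs`` contigs
    of (near-)equal length; segments straddling a contig boundary are
    split there.  Ground-truth coordinates are contig-local.  Deterministic
    given (model, seed).
    """
    rng = np.random.default_rng(seed)
    stream = sample_segment_compositions(model, rng)
    contig_len = -(-model.genome_length // model.n_contigs)  # ceil
    truth = []
    contigs = []
    chunk_buf = []
    pos_in_contig = 0
    contig_no = 1

    def flush():
        nonlocal chunk_buf, pos_in_contig, contig_no
        if not chunk_buf:
            return
        symbols = np.concatenate(chunk_buf).tobytes().decode("ascii")
        contigs.append(Contig(f"{taxon_id}_c{contig_no}", symbols))
        chunk_buf = []
        pos_in_contig = 0
        contig_no += 1

    for s in stream:
        remaining = s.length
        while remaining > 0:
            take = min(remaining, contig_len - pos_in_contig)
            codes = rng.choice(4, size=take, p=np.asarray(s.probs))
            chunk_buf.append(_BASE_LUT[codes])
            truth.append(TrueSegment(pos_in_contig, pos_in_contig + take,
                                     s.gc, s.ry, s.km, s.probs,
                                     contig=f"{taxon_id}_c{contig_no}"))
            pos_in_contig += take
            remaining -= take
            if pos_in_contig == contig_len:
                flush()
    flush()
    genome = GenomeSequence(taxon_id, contigs)
    return genome, truth


# ---------------------------------------------------------------------------
# Drift along a tree
# ---------------------------------------------------------------------------


@dataclass
class EvolutionParams:
    """Brownian drift of landscape parameters along a guide tree.

    Two things evolve: the logit of each G+C family mean (drift standard
    deviation ``sigma`` per square-root unit of branch length, My for time
    trees) and the log of each family weight (``sigma *
    weight_sigma_scale``), i.e. families slowly shift their composition
    and, faster, their genomic abundance -- both processes are seen between
    real lineages.  RY/KM means drift with ``sigma * skew_sigma_scale``,
    staying near 0.5.  With the defaults, lineages 100 My apart differ by
    a few percentage points in family G+C and substantially in family
    abundances.  ``boundary_resample_fraction`` is retained for interface
    completeness: tips redraw their segment boundaries independently
    (fraction 1), the regime the distance is designed for, since the
    landscape is invariant to where segments sit.
    """

    tree: PhyloTree
    sigma: float = 0.006
    weight_sigma_scale: float = 6.0
    skew_sigma_scale: float = 0.25
    boundary_resample_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0.0 <= self.boundary_resample_fraction <= 1.0):
            raise ValueError("boundary_resample_fraction must be in [0, 1]")


def evolve_models(ancestor: LandscapeModel, params: EvolutionParams) -> dict:
    """Drift the ancestor model along the guide tree; one model per tip."""
    rng = np.random.default_rng(params.seed)
    tree = params.tree.dendropy_tree
    state: dict = {}
    root_state = (
        logit(np.asarray(ancestor.gc_means, dtype=float)),
        np.log(np.asarray(ancestor.gc_weights, dtype=float)),
        float(logit(ancestor.ry_mean)),
        float(logit(ancestor.km_mean)),
    )
    tips = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            state[node] = root_state
            continue
        g, lw, r, k = state[node.parent_node]
        t = node.edge.length or 0.0
        sd = params.sigma * math.sqrt(t)
        g = g + rng.normal(0.0, sd, size=g.shape)
        lw = lw + rng.normal(0.0, sd * params.weight_sigma_scale, size=lw.shape)
        r = r + float(rng.normal(0.0, sd * params.skew_sigma_scale))
        k = k + float(rng.normal(0.0, sd * params.skew_sigma_scale))
        state[node] = (g, lw, r, k)
        if node.is_leaf():
            w = np.exp(lw)
            tips[node.taxon.label] = replace(
                ancestor,
                gc_means=tuple(expit(g)),
                gc_weights=tuple(w / w.sum()),
                ry_mean=float(expit(r)),
                km_mean=float(expit(k)),
            )
    return tips


def evolve_landscapes(ancestor: LandscapeModel, params: EvolutionParams,
                      emit_genomes: bool = True) -> dict:
    """Drifted model (and simulated genome) per tip of the guide tree.

    Returns ``{tip_label: (model, genome, true_segments)}``; with
    ``emit_genomes=False`` the genome slot is None and only ground-truth
    segment compositions are drawn (cheap, for distribution-level checks).
    """
    models = evolve_models(ancestor, params)
    out = {}
    for i, (label, model) in enumerate(sorted(models.items())):
        tip_seed = np.random.SeedSequence([params.seed, 1000 + i]).generate_state(1)[0]
        if emit_genomes:
            genome, truth = simulate_genome(model, int(tip_seed), taxon_id=label)
        else:
            rng = np.random.default_rng(int(tip_seed))
            genome, truth = None, sample_segment_compositions(model, rng)
        out[label] = (model, genome, truth)
    return out


def simulate_bm_trait(tree: PhyloTree, sigma2: float = 1.0, seed: int = 0) -> pd.Series:
    """Brownian-motion trait simulated from the root; one value per tip."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    dt = tree.dendropy_tree
    values = {}
    tips = {}
    for node in dt.preorder_node_iter():
        if node.parent_node is None:
            values[node] = 0.0
        else:
            t = node.edge.length or 0.0
            values[node] = values[node.parent_node] + rng.normal(0.0, math.sqrt(sigma2 * t))
        if node.is_leaf():
            tips[node.taxon.label] = values[node]
    return pd.Series(tips).reindex(tree.tip_labels)


# ---------------------------------------------------------------------------
# Random and structured guide trees
# ---------------------------------------------------------------------------


def coalescent_tree(n_tips: int, seed: int = 0, pop_scale: float = 1.0,
                    prefix: str = "t") -> PhyloTree:
    """Ultrametric random tree from the Kingman coalescent."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    lineages = [(f"{prefix}{i + 1}", 0.0) for i in range(n_tips)]
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 * pop_scale / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (nw_j, h_j) = lineages.pop(j)
        (nw_i, h_i) = lineages.pop(i)
        lineages.append((f"({nw_i}:{t - h_i:.10g},{nw_j}:{t - h_j:.10g})", t))
    return PhyloTree.from_newick(lineages[0][0] + ";")


def pure_birth_tree(n_tips: int, seed: int = 0, rate: float = 1.0,
                    prefix: str = "t") -> PhyloTree:
    """Ultrametric Yule (pure-birth) tree, grown forward in time."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    records = [{"birth": 0.0, "children": None}]
    active = [0]  # indices of extant lineages in `records`
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (rate * k))
        pick = int(rng.integers(k))
        parent = active.pop(pick)
        left = len(records)
        records.append({"birth": t, "children": None})
        right = len(records)
        records.append({"birth": t, "children": None})
        records[parent]["children"] = (left, right)
        active.extend([left, right])
    t += rng.exponential(1.0 / (rate * n_tips))  # present-day horizon
    counter = [0]

    def build(idx: int) -> str:
        rec = records[idx]
        if rec["children"] is None:
            counter[0] += 1
            return f"{prefix}{counter[0]}:{t - rec['birth']:.10g}"
        l, r = rec["children"]
        length = records[l]["birth"] - rec["birth"]
        return f"({build(l)},{build(r)}):{length:.10g}"

    l, r = records[0]["children"]
    newick = f"({build(l)},{build(r)});"
    return PhyloTree.from_newick(newick)


def ladder_tree(n_tips: int = 20, min_depth: float = 5.0,
                max_depth: float = 160.0, prefix: str = "t") -> PhyloTree:
    """Ultrametric caterpillar with log-spaced divergence depths.

    Tip k joins the backbone at depth ``min_depth * (max_depth/min_depth) **
    ((k-1)/(n_tips-2))``, so pairwise divergence times span two orders of
    magnitude -- the sampling structure of a reference species plus
    relatives at graded distances (a TimeTree-style backbone).
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    depths = np.geomspace(min_depth, max_depth, n_tips - 1)
    width = len(str(n_tips))
    nwk, h = f"{prefix}{1:0{width}d}", 0.0
    for k, d in enumerate(depths):
        nwk = f"({nwk}:{d - h:.10g},{prefix}{k + 2:0{width}d}:{d:.10g})"
        h = float(d)
    return PhyloTree.from_newick(nwk + ";")


def clade_tree(n_clades: int = 3, tips_per_clade: int = 3,
               clade_depth: float = 20.0, root_depth: float = 80.0,
               prefix: str = "c") -> PhyloTree:
    """Deterministic ultrametric tree with well-separated clades.

    Within each clade, tips join in a ladder with splits evenly spaced up
    to ``clade_depth``; clades join in a ladder between 0.7*root_depth and
    root_depth.  Useful ground truth for within/between-group and
    monophyly checks.
    """
    if n_clades < 2 or tips_per_clade < 2:
        raise ValueError("need >= 2 clades of >= 2 tips")
    if clade_depth >= 0.7 * root_depth:
        raise ValueError("clade_depth must be < 0.7 * root_depth")

    def ladder(labels, heights):
        nwk, h_prev = labels[0], 0.0
        for label, h in zip(labels[1:], heights):
            nwk = f"({nwk}:{h - h_prev:.10g},{label}:{h:.10g})"
            h_prev = h
        return nwk, h_prev

    clade_frags = []
    for c in range(n_clades):
        labels = [f"{prefix}{c + 1}_t{i + 1}" for i in range(tips_per_clade)]
        heights = np.linspace(clade_depth / tips_per_clade, clade_depth,
                              tips_per_clade - 1)
        clade_frags.append(ladder(labels, heights))
    join_heights = np.linspace(0.7 * root_depth, root_depth, n_clades - 1)
    nwk, h_prev = clade_frags[0]
    for (frag, h_frag), h in zip(clade_frags[1:], join_heights):
        nwk = f"({nwk}:{h - h_prev:.10g},{frag}:{h - h_frag:.10g})"
        h_prev = h
    return PhyloTree.from_newick(nwk + ";")


# ---------------------------------------------------------------------------
# Bundled mammalian divergence-time fixture
# ---------------------------------------------------------------------------


def mammal_divergence_table() -> pd.DataFrame:
    """Divergence times (My) between human and 41 mammals (TimeTree estimates).

    Columns: scientific_name, common_name, delta_t_my, order.  Includes the
    human row with delta_t_my = 0.
    """
    with resources.files("segdist.data").joinpath(
        "mammal_divergence_times_my.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def mammal_guide_tree() -> PhyloTree:
    """Ultrametric guide tree consistent with the bundled human-anchored times.

    The human-to-X divergence times fix the backbone exactly; species that
    share the same time to human (e.g. the rodents at 87 My) have unknown
    internal structure here, so their within-group splits are synthetic --
    a deterministic ladder placed between 55% and 90% of the group's depth.
    Suitable as a realistic 42-tip topology for simulation studies, not as
    an estimate of mammalian phylogeny.
    """
    df = mammal_divergence_table()
    df = df.sort_values(["delta_t_my", "order", "scientific_name"])
    human = df[df.delta_t_my == 0].scientific_name.iloc[0].replace(" ", "_")

    def ladder(labels, heights):
        nwk, h_prev = labels[0], 0.0
        for label, h in zip(labels[1:], heights):
            nwk = f"({nwk}:{h - h_prev:.10g},{label}:{h:.10g})"
            h_prev = h
        return nwk, h_prev

    nwk, h_prev = human, 0.0
    for t_level, group in df[df.delta_t_my > 0].groupby("delta_t_my"):
        labels = [s.replace(" ", "_") for s in group.scientific_name]
        if len(labels) == 1:
            frag, h_frag = labels[0], 0.0
        else:
            heights = np.linspace(0.55 * t_level, 0.90 * t_level, len(labels) - 1)
            frag, h_frag = ladder(labels, heights)
        nwk = f"({nwk}:{t_level - h_prev:.10g},{frag}:{t_level - h_frag:.10g})"
        h_prev = float(t_level)
    return PhyloTree.from_newick(nwk + ";")
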