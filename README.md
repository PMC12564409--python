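# segdist

Alignment-free genome divergence from the compositional structure of DNA.

`segdist` measures how far apart two genomes are without aligning them.  It
(1) partitions each genome into compositionally homogeneous segments by
recursive Jensen–Shannon segmentation with a calibrated significance test,
(2) summarises the genome as its *compositional landscape* — the normalised
histogram of per-segment G+C (strong/weak), A+G (purine) or G+T (keto)
fractions — and (3) defines the **Segment Compositional Distance**

> D(A, B) = √JSD(P, Q)

where P and Q are the two genomes' landscapes and JSD is the Jensen–Shannon
divergence in bits.  D is a true metric on [0, 1]: zero exactly for
identical landscapes, one exactly for landscapes with disjoint support.  A
comparative layer turns matrices of D into biology: within/between-group
contrasts, correlation with divergence times, phylogenetic-signal indices
(Abouheif's C<sub>mean</sub>, Moran's I, Blomberg's K and K*, Pagel's λ) on
the first principal-coordinate axis, and UPGMA/neighbor-joining trees.

It is aimed at comparative genomicists who want a scalable genome signature
that works on fragmented assemblies and across deep divergences where
alignment fails.

## The method in brief

**Segmentation.**  For a sequence S of length N, the divergence at cut i is

    d(i) = H(S) − (n1/N)·H(S1) − (n2/N)·H(S2)      [bits]

with H the Shannon entropy of base frequencies and S1, S2 the flanks.  The
maximising cut is accepted when d(i_max) is significant at level s (default
0.95) against the null of an i.i.d. homogeneous sequence of the same length;
the null distribution of the maximum is estimated by Monte-Carlo simulation
over a grid of lengths.  Accepted cuts recurse into both halves; the result
is a tiling of the genome into segments, each homogeneous at level s.

**Landscape.**  Each segment contributes one value (its G+C, A+G or G+T
fraction) to an n-bin histogram over [0, 1] (n = 50 by default).  Segments
count once regardless of length.

**Distance and comparison.**  D is the Jensen–Shannon distance between two
landscapes with matching bins.  Distance matrices feed the statistical
layer: Mann–Whitney/Welch within-vs-between tests, Pearson/Spearman
correlation with divergence times, permutation-tested signal indices
against an ultrametric time tree, and distance-based tree building.

## Worked example

Simulate a small fixture genome, segment it, and build its landscape:

```bash
segdist simulate --out-dir demo --seed 9 --genome-length 30000 \
    --mean-segment-length 2000
segdist segment demo/sim.fasta --null-sims 300 --seed 1 \
    --out-bed demo/sim.bed --out-tsv demo/sim.tsv
segdist landscape demo/sim.fasta --null-sims 300 --seed 1 --out-prefix demo/sim
head -4 demo/sim.SW.tsv
```

```
#segdist-histogram	v1
#taxon=sim	grouping=SW	n=50	m_segments=13
#alphabet=ACGT	min_gap=10	n_bins=50	seed=1	significance=0.95
bin_lo	bin_hi	prob
```

`m_segments=13` means the 30 kb toy genome was cut into 13 homogeneous
segments at the 95% significance level; the rows that follow give the
fraction of segments per G+C bin.  Landscapes from several genomes combine
into a distance matrix and a tree:

```bash
segdist distance a.SW.tsv b.SW.tsv c.SW.tsv --out D.tsv --phylip D.phy
segdist tree --matrix D.tsv --out D.nwk          # UPGMA (NJ via --method nj)
segdist signal --matrix D.tsv --tree timetree.nwk --out signal.json
```

As a library, the same example in three lines:

```python
from segdist import landscape_pipeline, distance_matrix, js_distance
hists = {t: landscape_pipeline(f"{t}.fasta")["SW"] for t in ("a", "b", "c")}
print(distance_matrix(list(hists.values())).to_dataframe().round(3))
```

A distance of 0.0 sits on the diagonal; off-diagonal values near 0 mean
near-identical G+C landscapes, values near 1 mean essentially disjoint
compositional structure.

## Layout

- `segdist.seqio` — FASTA I/O, gap splitting, O(1) range composition queries
- `segdist.segmentation` — the recursive segmenter, Monte-Carlo null, DP reference
- `segdist.landscape` — per-segment fractions and histograms
- `segdist.distance` — D, distance matrices, group/time statistics
- `segdist.phylo` — trees, PCoA, the five signal indices, UPGMA/NJ
- `segdist.synthetic` — genome/landscape/trait generators with ground truth
- `segdist.cli` — the `segdist` command

See `docs/methods.md` for the statistical details and design choices.
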