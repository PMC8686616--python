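# Methods

## Problem and model

structnet asks whether proteins of a multi-protein complex that change in
relative abundance between conditions are *spatially confined*: clustered
into a particular region of the assembled complex rather than scattered
across it. The motivating case is ribosome substoichiometry — rProtein
families depleted from or enriched in translating complexes — but nothing
in the method is ribosome-specific: any complex with a resolved structure
and a binary change table per protein (or per paralog) can be analysed.

The pipeline has three stages:

1. **Structure → proximity graph.** Protein chains are coarse-grained to
   one point per residue, the unweighted centroid of its non-hydrogen
   atoms (Å). Two proteins x, y are connected when at least one pair of
   residue centers (one from each chain) lies within a distance threshold
   d_t; the number of such pairs is the symmetric contact count
   c(x, y). Normalising by the source protein's total contacts gives
   asymmetric weights w(x, y) = c(x, y) / Σ_z c(x, z) and transit
   probabilities P(x, y) = w(x, y) / w(x) with w(x) = Σ_y w(x, y); since
   w(x) = 1 for every non-isolated node, P equals w, and each row of P
   sums to 1.

2. **Graph → regions.** From every node, I random walks of L steps are
   restarted. Each step is drawn from the current node's transit row;
   by default the edge just traversed is excluded and the remaining
   probabilities renormalised (*no-immediate-reverse*), so walks cannot
   oscillate across a single strong edge; a pure memoryless mode is
   available. Dead ends and isolated nodes terminate walks early. Every
   node visit is tallied, including repeat visits within one walk, and
   the start node counts once per iteration. The *pre-region* of a start
   node is {node : tally × 2 ≥ I} ∪ {start}. The final *regions* are a
   minimum set cover selected from the |V| pre-regions, so they span
   every node while allowing overlaps — the natural output for a complex
   in which neighborhoods interpenetrate.

3. **Regions → enrichment.** Change flags live at the paralog level; a
   region's paralogs are all paralogs of its member families. For each
   region a 2×2 table (changed/unchanged × inside/outside) over the full
   paralog universe is tested with the exact hypergeometric (Fisher)
   test. The null hypothesis is that changed paralogs are randomly
   scattered over the complex; the baseline enrichment probability is
   the overall changed fraction. Raw p-values are Bonferroni-adjusted
   with m = the number of regions in the tested cover.

## Parameters

| parameter | default | meaning |
|---|---|---|
| d_t | 12 Å | residue-center contact threshold. 8 Å is the consensus residue-contact distance inside a protein; 12 Å additionally captures proximities mediated by an RNA scaffold, which is appropriate for ribosome-like complexes where the RNA itself is excluded from the graph. |
| walk_length L | 0.25·\|V\| | steps per walk; fractions in (0, 1) resolve as max(1, round(fraction·\|V\|)). Larger L yields larger regions; 0.13·\|V\| gives regions of roughly 5–10 proteins on ~70-node ribosome graphs. |
| iterations I | 50 | restarts per start node. Low I admits "outlier" nodes visited by chance; raising I stabilises the consensus (the pre-region threshold scales with I). |
| backtrack_mode | no-immediate-reverse | one-step walk memory; `memoryless` disables it. |
| seed | required | master seed; per-start-node streams are derived as (seed, crc32(node)), so results are independent of node iteration order. |
| alternative | two-sided | Fisher sidedness; use `greater` to test pure enrichment only. |
| alpha | 0.05 | familywise significance level after Bonferroni. |

**Choosing L from the data.** If a fraction f of all paralogs is changed,
a region should hold at least ceil(1/f) nodes, so that a single changed
node does not already exceed the background proportion
(`recommend_region_size`: f = 0.20 → 5 nodes, f = 0.08 → 13). Tune L
until the mean region size reaches that bound.

## Numerical and algorithmic choices

- **Contact boundary is inclusive** (distance ≤ d_t), making behaviour
  deterministic at exact ties; distances are double precision and never
  rounded. Contact counting uses a KD-tree; tests verify it against a
  brute-force double loop.
- **Centroid, not center of mass:** residue points are unweighted means
  of atom positions; hydrogens are excluded. Mass weighting would shift
  centers by fractions of an Å without changing contact topology at the
  thresholds used.
- **Cleaning:** HETATM records are removed (a flag retains modified
  residues); for alternate locations the highest-occupancy conformer is
  kept, ties resolved by listing order. Residue indices are renumbered
  densely per chain. Isolated proteins stay in the graph as degree-0
  nodes and become singleton regions.
- **Completeness QC:** coverage of a modeled chain against its reference
  sequence is the fraction of reference positions matched — exact
  substring first, then best local alignment with a warning. Structures
  whose chains have low coverage produce unreliable contact counts (the
  low-resolution wheat ribosome deposit is the canonical example) and
  should be treated with care.
- **Consensus threshold** is tally × 2 ≥ I (exact arithmetic, no
  rounding of I/2), and the start node is always a member. Whether the
  original convention used strict inequality is not documented anywhere
  we know of; the inclusive rule is declared here as the package's
  convention.
- **Minimum set cover** is NP-hard; selection is greedy (most uncovered
  nodes, then larger total size, then lexicographically smallest start
  node). When at most 20 distinct candidate member sets remain after
  deduplication and subset-dominance pruning, an exact branch-and-bound
  optimum is computed as well; the greedy solution is returned whenever
  it attains the optimal size, otherwise the exact cover. The exhaustive
  oracle in `synthetic` double-checks optimality in tests.
- **Bonferroni is strict:** p_adj = min(1, m·p) with m the number of
  regions tested in the run. Published analyses sometimes report
  adjusted values implying other effective multipliers (sub-category
  testing, rounding); we do not emulate that.
- **Degenerate inputs:** empty regions, non-binary flags, p-values
  outside [0, 1], universes not covered by the pre-regions, and
  coincident generator centers all raise errors rather than propagate.

## What the synthetic generator emulates — and what it does not

`synthetic.make_blob_complex` produces proteins as isotropic Gaussian
point clouds of single-atom residues placed on ring, lattice, two-cluster
or custom layouts; `clustered_centers` builds a two-level layout of
dense clusters whose true community structure is known. Because each
generated residue has exactly one atom, centroids equal coordinates and
the geometric ground truth (`brute_force_adjacency`) is exact.
`plant_cra` draws paralog flags Bernoulli(q_in) inside a target region
and Bernoulli(q_out) outside, returning the ground truth for power
analysis; q_in = q_out is the null generator.

The generator does **not** emulate realistic protein shapes, secondary
structure, chain connectivity constraints, rRNA scaffolds, or the
contact-count heterogeneity of real interfaces. Passing tests therefore
demonstrate the correctness of the graph construction, sampling,
cover and testing machinery, and the statistical calibration of the
enrichment test under the stated generative model — they do not by
themselves validate biological conclusions on any particular complex,
which additionally depend on structure quality and threshold choice.

## Study conditions used by the acceptance script

`scripts/acceptance.py` regenerates everything from scratch at the given
seed: a 72-protein complex (9 clusters of 8; 12 residues per protein,
cluster spacing 6 Å, inter-cluster spacing 60 Å, cloud sd 1 Å), its 12 Å
graph, regions at L = 8, I = 50, and a 100-paralog universe (28 families
with two paralogs). It reports graph and cover metrics, agreement of the
exact test with rational-arithmetic enumeration over 1000 random tables,
greedy-cover optimality against the exhaustive oracle over 80 random
instances, planted-region recovery over 100 replicates at
q_in = 0.9 / q_out = 0.05, and the familywise error over 1000 null
replicates at a 15% changed fraction.

## Known limitations

- Bonferroni over overlapping regions is conservative (observed
  familywise error ≈ 2–3% at nominal 5% under the null generator).
- Region membership is binary; visit tallies are reported but not used
  beyond the threshold.
- With low I or L near 1, region composition varies across seeds;
  reproducibility should be checked with `region_overlap` across seeds.
- Proximity at large d_t is a *potential* for interaction, not evidence
  of physical contact — edges through an excluded scaffold (e.g. rRNA)
  are indirect by construction.
- Paralogs are assumed exchangeable within a family; family-level
  structure nodes cannot distinguish which paralog occupies the site.
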