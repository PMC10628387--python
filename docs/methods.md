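# Methods

## Similarity measures

All five scores operate on a `PairwiseAlignment`, an ordered list of
columns pairing residue indices of two proteins (gaps are one-sided; indices
strictly increase on each side).

**Aligned fraction.** `ali = L_ali / max(L1, L2)`. Normalizing by the longer
protein penalizes indels and length mismatch.

**Sequence identity.** Identical residues over aligned columns; indels are
not scored, so SI is insensitive to flanking gaps.

**TM-score.** `TM = (1/L_norm) Σ 1/(1 + (dᵢ/d₀)²)` with
`d₀ = 1.24 (L−15)^⅓ − 1.8` Å. Two numerical choices:

* `L_norm` defaults to the number of aligned positions, making TM symmetric
  under swapping the proteins; `norm_by_max_length=True` switches to the
  common max-length convention.
* The printed d₀ formula is non-positive for L ≲ 21; d₀ is clamped at
  0.5 Å (the convention of the TM-score literature) so short alignments
  stay finite.

The superposition is found self-consistently: a least-squares (Kabsch) fit
on all aligned columns, then repeated restriction of the working subset to
columns with dᵢ < max(d₀, 3 Å) and refitting until the subset stops
changing (cap 50 passes); the fit is then polished by iteratively
reweighted least squares with weights (1 + (dᵢ/d₀)²)⁻², which is the
majorize-minimize update for the TM objective and therefore monotone.
Because the TM landscape of very small alignments is multimodal, alignments
of ≤ 12 columns add a coarse octahedral rotation-grid multistart; larger
alignments start from the least-squares basin plus three 180° flips. The
best-scoring transform seen is returned; everything is deterministic.

**Contact overlap.** Binary contact maps mark residue pairs with any two
heavy atoms closer than 4.5 Å. Pairs with sequence separation < 3 are
excluded (configurable `min_sep`): trivially adjacent contacts carry no
fold information and would inflate CO. The overlap counts each unordered
shared contact once and normalizes by the geometric mean of the two contact
counts, so CO is symmetric, has maximum 1, and needs no rotation. A protein
with no contacts makes CO undefined (NaN, logged); it enters PC_sim as 0.

**PC_sim.** Fixed-weight combination
`(0.84 ali + 0.79 SI + 0.95 TM + 0.95 CO)/3.53`; the weights are the
first-principal-component loads of the four measures. `pca_loads`
recomputes loads on any user score table: covariance PCA on the raw [0, 1]
scores, no standardization (the fixed loads are all below 1 and
sum-normalized, which is the covariance convention), leading-eigenvector
sign fixed positive.

## Divergences

Each similarity *s* with baseline *s₀* (value expected without homology)
maps to `−ln((s − s₀)/(1 − s₀))`: the maximum-likelihood divergence time
under a Jukes–Cantor-like model where each site/contact/position reverts to
the background independently. Baselines: SI₀ = 0.05, TM₀ = 0.167,
q(L) = 0.39 L^−0.55 + 6.64 L^−0.67 for CO, and for PC_sim the same weighted
combination of the individual baselines with ali₀ = 0.5, so PC₀ depends on
the aligned length L like q does. Similarities at or below baseline give
UNDEFINED (NaN) — a value, not an error. For tree building UNDEFINED cells
are imputed as (largest defined divergence) + 1, which preserves rank order
while keeping no-signal pairs most distant; output files keep the raw
UNDEF. The PC_div denominator uses (1 − PC₀) for consistency with the
other three transforms; a `denom_pc` switch provides the (1 − PC) variant.

## Pairwise refinement without gap scoring

`ss_realign` relocates every gap opened strictly inside a
secondary-structure element of the partner protein to the nearer end of
that element (shift count in residues; ties go N-terminal), reflecting that
a deletion inside an SSE makes the structural correspondence slide to the
element's end. SI and TM are computed for the input and the modified
alignment and the larger of each is reported; if the modified TM is higher,
CO is also taken from the modified alignment.

`refine_pa` targets TM, CO or PC_sim. Per pass: (i) each residue's nearest
residue in the other protein is found under the target (minimal superposed
Cα distance for TM; maximal shared-contact count in the context of the
current alignment for CO; for PC a residue-level mirror of the PC weights —
identity + proximity-within-d₀ + normalized shared contacts — since the
aligned fraction has no residue-level analogue); (ii) mutual best matches
("double matches") that are already aligned form fixed frames;
(iii) remaining double matches consistent with sequential order are added
between frames left to right. Passes repeat with recomputed neighbors until
the alignment is stable (cap 5). The final result is the better of
(refined, input) under the target score — the keep-better guarantee.

`denovo_pa` builds an alignment with no input: global affine-gap dynamic
programming (gap open 0.35, extend 0.05 on the [0, 1] score scale) over
`S(i,j) = (0.79·blosum̂ + 0.95·[ssᵢ = ssⱼ] + 0.95·cvs(i,j)) / 2.69`, where
blosum̂ is BLOSUM62 rescaled to [0, 1] over the 20 standard residues,
secondary-structure identity replaces the TM term and the contact-vector
similarity replaces CO — both computable without a pre-existing alignment.
`cvs(i,j) = 1 − |Δ multiset difference| / (deg i + deg j)` compares the
signed sequence offsets of the two residues' contacts (0 when both degrees
are 0). Traceback prefers diagonal > up > left; the two inputs are ordered
canonically internally so that swapping them returns the exact mirror.

## Clique-based seeding

Residues of the n proteins are graph nodes; edges join residues aligned in
some pairwise alignment, so a residue has at most one link into each other
protein (degree ≤ n−1) and, for mutually consistent alignments, MSA columns
are maximal cliques. Nodes are ranked by a local clustering count (adjacent
neighbor pairs). Cliques per node grow incrementally over the neighbor
list: each next neighbor joins every clique it is fully linked to,
otherwise seeds a new clique from the compatible previously-processed
neighbors; only the 100 largest cliques survive each step (ties keep the
earlier-created). After a node is processed, any node whose stored maximum
clique size or summed clique sizes exceeds n/2 is skipped as a future seed
— a completeness/cost compromise.

Assembly accepts cliques greedily by decreasing size (ties: larger summed
clustering coefficient, then lexicographic member order) into a maintained
total column order; a clique is accepted only if its residues are unused
and a slot exists between the columns holding each member protein's
neighboring residues (insertion at the leftmost consistent slot). The
maintained total order is itself a topological order of the column partial
order, which keeps the consistency test O(columns) instead of requiring
cycle detection. Orphan residues attach to the consistent accepted column
with most graph edges to them (ties leftmost) or seed a singleton column.
A final stable topological sort orders mutually unordered columns by the
average normalized residue position of their members. The output MSA always
reproduces every input sequence exactly when ungapped (asserted).

## Progressive refinement

Each round: (1) all structures are superposed in a common frame —
initialized on the protein with the largest summed pairwise PC_sim, then
Kabsch-fit iteratively onto the evolving column-average consensus (≤ 20
rounds, best summed-pairwise-TM transform set retained, so the score never
degrades); (2) the PC_div matrix of the current MSA feeds an
average-linkage (UPGMA) guide tree, heights = half the cluster-average
divergence, ties broken on the lexicographically smallest cluster pair;
(3) clusters merge leaf-to-root by global affine-gap DP over column pairs.
The column score is the mean over cross pairs of
`(0.79 blosum̂ + 0.95/(1+(d/d₀)²) + 0.95·shared-contacts + bonus·aligned)
/ 2.69`, with distances from the consensus superposition, shared contacts
counted in the context of the previous MSA (normalized by the maximum
contact degree), d₀ from the mean protein length, and a 0.1 bonus for
pairs aligned in the previous MSA (configurable; the magnitude only has to
break ties toward stability). Cluster-internal columns are never split.
Although profile merging is named after the Smith–Waterman family, the DP
is global: clusters must be aligned end to end.

Up to seven rounds run; iteration stops early when the average PC_sim
changes by < 1e−6 or an MSA repeats (hash of its rows). The MSA with the
largest average PC_sim over all logged rounds (including the seed) is
returned — so the output is never worse than the seed by that criterion.
The guide tree is always average linkage; the tree written to
`.PCAli.tree` is a classic neighbor-joining tree on the final PC_div
matrix, which is the more conventional output for downstream phylogenetics.

## MSA comparison

The sum-of-pairs score counts residue pairs aligned in the same column in
both MSAs and normalizes by the geometric mean of the two pair counts
(symmetric, penalizes overalignment); a reference mode divides by the
reference's pairs instead. The column overlap score matches columns
greedily by decreasing shared-residue count (each column used once, ties
leftmost) and reports matched shared residues over total residues; since
columns may be split or merged between two MSAs, no canonical
correspondence exists, and the greedy choice is cross-checked against an
optimal-assignment oracle in the tests. Sequences present in only one MSA
are dropped with a warning.

## Structure input

PDB reading uses Bio.PDB: first model, requested chain, waters/heteroatoms
skipped, hydrogens excluded, highest-occupancy altloc kept, residues
without a Cα dropped with a warning, unknown residue names mapped to 'X'.
Secondary structure is assigned from Cα geometry alone: window tests on
the i→i+2/3/4 distances classify helix (≈5.4/5.1/6.2 Å) and strand
(≈6.6/9.9 Å), with the additional requirement that consecutive Cα spacing
stays near the canonical 3.8 Å so that tight turns do not mimic helices;
anything else is coil, and chains under 5 residues are all coil. A
DSSP-format file can override the assignment (H/G/I→H, E/B→E, else C).
Structures whose sequences are equal length and within one substitution are
grouped by single linkage (the relation is not transitive; single linkage
is the conservative closure); the representative is the member with most
resolved residues, ties by id. Representative-pair similarities reported in
`.prot.sim` take the maximum over member conformation pairs.

## The synthetic-data generator

`fixtures` builds idealized scaffolds — a straight α-helix (1.5 Å rise,
100°/residue, r = 2.3 Å), an antiparallel β-hairpin (3.3 Å rise, 4.8 Å
strand spacing), or a mixed fold packing a helix against a hairpin — with
pseudo backbone/side-chain atoms placed so that contact maps are informative
(an axial atom mimics the helix hydrogen-bond proximity; strand atoms reach
toward the paired strand). A family evolves along a planted tree:
substitutions are Poisson events per site that draw uniformly from the 20
letters (two leaves at total separation T then have expected identity
`exp(−rT)·19/20 + 1/20`); indels are deletions with geometric lengths,
never within 3 residues of a terminus (an insertion in one lineage equals a
deletion in all others, so truth bookkeeping is exact); coordinates jitter
by a per-residue Gaussian displacement of σ√t per branch, applied rigidly
to all atoms of the residue. Default conditions — six proteins, length 60,
rate 0.3/site/time on a star tree of branch length 1 (pairwise identity
≈ 0.57, mid-range for a superfamily), indel rate 1.5/branch with mean
length 2, σ = 1 Å — exercise every code path at desk scale.

What the generator does *not* emulate: real side-chain packing, correlated
structural rearrangements, insertions with novel geometry, conformational
heterogeneity between crystal forms, or domain-boundary disagreements.
Passing recovery tests therefore demonstrates algorithmic correctness on
controllable inputs, not benchmark-level accuracy on crystallographic
superfamilies.

## Problem sizes and determinism

The test suite and the acceptance script use families of 2–6 proteins of
length 40–80 and ten-step divergence ladders; these sizes separate signal
from noise cleanly while keeping every oracle (brute-force contact scans,
rotation-grid searches, exhaustive clique enumeration, optimal assignment)
exact and fast. All randomness flows through explicit integer seeds; equal
seeds give bit-identical families, alignments and scores.

## Known limitations

* The de novo DP scores gaps (open 0.35, extend 0.05); only the
  *refinement* stage is gap-penalty-free.
* The residue-level PC score used by the PC-target refinement is a
  reconstruction mirroring the global PC weights; the aligned-fraction term
  has no residue-level analogue and is omitted.
* Greedy clique assembly is a heuristic for an NP-hard consistent-subset
  problem; tests bound it at ≥ 90% of the exhaustive optimum on tiny
  instances.
* Contact-free proteins (no pair of heavy atoms within 4.5 Å beyond the
  near diagonal) make CO undefined; PC_sim then degrades gracefully to the
  remaining three terms with CO = 0.
* mmCIF input, multi-model averaging and local alignment modes are out of
  scope.
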