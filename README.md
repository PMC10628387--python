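# pcali

Hybrid protein sequence + structure similarity scoring and multiple
alignment.

## The problem

Multiple sequence alignments of distantly related proteins — superfamily
members in the twilight zone of sequence identity — drive most downstream
evolutionary inference, and no single similarity measure describes such
pairs well. Sequence aligners overfit sequence identity at the expense of
structural agreement; structure aligners do the reverse. `pcali` is for
structural bioinformaticians and molecular evolution researchers who have
structures (or structure-aware alignments) for a protein family and want
alignments and divergence estimates that balance both signals.

## The score and the method

For a pairwise alignment of two structures the package computes four
elementary similarities, each in [0, 1]:

* **ali** — aligned (non-gap) columns over the longer protein's length;
* **SI** — sequence identity over aligned columns (indels unscored);
* **TM** — the TM-score, `TM = (1/L) Σᵢ 1/(1 + (dᵢ/d₀)²)` with
  `d₀ = 1.24 (L−15)^⅓ − 1.8` Å, under the self-consistently optimized
  superposition;
* **CO** — contact overlap,
  `CO = Σ C_ij C′_{a(i)a(j)} / √(Σ C_ij · Σ C′_ij)`, over binary
  heavy-atom contact maps (4.5 Å cutoff), independent of any rotation.

These are combined into the hybrid score, the fixed first principal
component of the four measures:

```
PC_sim = (0.84 ali + 0.79 SI + 0.95 TM + 0.95 CO) / 3.53
```

Each similarity *s* with no-homology baseline *s₀* maps to a
Poisson-corrected divergence `−ln((s − s₀)/(1 − s₀))` (the Tajima–Nei
form): `TNdiv` from SI (s₀ = 0.05), `TMdiv` from TM (s₀ = 0.167), the
contact divergence `CD` from CO (s₀ = q(L) = 0.39 L^−0.55 + 6.64 L^−0.67),
and `PC_div` from PC_sim.

The aligner works in three stages: (1) pairwise alignments — read from an
input MSA or built de novo by structure-aware dynamic programming — are
refined toward PC_sim by a mutual-best-match "neighbor frame" procedure
that never scores a gap; (2) a seed MSA is assembled from the maximal
cliques of the graph whose nodes are residues and whose edges join residues
aligned in some pairwise alignment; (3) the seed is polished by up to seven
rounds of progressive alignment along an average-linkage guide tree built
from PC_div, and the round with the largest average PC_sim is returned.

## Worked example

`examples/04_multiple_alignment.py` evolves a synthetic six-protein family
(length-60 mixed α/β scaffold, substitution rate 0.3/site/time on a star
tree, 1–2 short deletions and 1 Å coordinate jitter per lineage), runs the
full de novo pipeline and compares the result with the planted alignment:

```
stage averages (ali / SI / TM / CO / PC):
  input    0.957 0.476 0.517 0.507 0.610
  ...
  clique   0.882 0.493 0.501 0.462 0.579
  iter1    0.947 0.566 0.590 0.543 0.657
  selected 0.947 0.566 0.590 0.543 0.657

selected MSA: 60 columns
sum-of-pairs vs planted truth : 0.9940
column overlap vs truth       : 0.9971
```

The stage table shows the average pair scores improving from the de novo
pairwise alignments through the clique seed to the selected progressive
round; the final two numbers say that 99.4% of the residue pairs the method
aligns (geometric-mean normalized) agree with the planted homology.

The other examples score a single pair (`01`), print the divergence ladder
(`02`), repair a planted misalignment without gap penalties (`03`) and
compare two MSAs (`05`). The same pipeline is available from a shell:

```
pcali align -i family.manifest -seq -o out       # de novo
pcali align -i family.manifest -ali input.fas -o out
pcali compare a.fas b.fas
```

`align` writes the full output suite (`.sim`, `.div`, `.prot.sim`,
`.prot.div`, `.PCAli.fas`, `.PCAli_ss.msa`, `.PCAli.tree`, `.PCAli.pdb`,
`_summary.dat`, `.id`).

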