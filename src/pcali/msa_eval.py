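"""Comparison of two multiple alignments.

Sum-of-pairs score: the number of residue pairs aligned in the same column
in both MSAs, normalized by the geometric mean of each MSA's pair count
(symmetric; penalizes overalignment), or by the reference's pair count in
reference mode. Column overlap: the fraction of residues placed in
corresponding columns, with columns matched greedily by shared-residue
count (columns may be split or merged between two MSAs, so correspondence
is not one-to-one by construction).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .structio import GAP, Msa

logger = logging.getLogger(__name__)


@dataclass
class MsaSimilarity:
    sum_of_pairs: float
    column_overlap: float
    shared_pairs: int
    pairs_A: int
    pairs_B: int


def _common(msaA: Msa, msaB: Msa) -> tuple:
    common = [nm for nm in msaA.names if nm in set(msaB.names)]
    if not common:
        raise ValueError("MSAs share no sequence names")
    for nm in set(msaA.names) ^ set(msaB.names):
        logger.warning("sequence %s present in only one MSA; dropped", nm)
    for nm in common:
        a = msaA.row_of(nm).replace(GAP, "")
        b = msaB.row_of(nm).replace(GAP, "")
        if a != b:
            raise ValueError(f"ungapped sequence of {nm} differs between MSAs")
    subA = Msa(common, [msaA.row_of(nm) for nm in common]).drop_empty_columns()
    subB = Msa(common, [msaB.row_of(nm) for nm in common]).drop_empty_columns()
    return subA, subB


def _pair_set(msa: Msa) -> set:
    idx = msa.column_residue_indices()
    n = len(msa.names)
    pairs = set()
    for c in range(msa.ncols):
        present = [(p, idx[p, c]) for p in range(n) if idx[p, c] >= 0]
        for a in range(len(present)):
            for b in range(a + 1, len(present)):
                pairs.add((present[a], present[b]))
    return pairs


def sum_of_pairs(msaA: Msa, msaB: Msa, reference: bool = False) -> MsaSimilarity:
    """Shared aligned residue pairs over the geometric mean of pair counts
    (or over the reference ``msaB``'s pair count when ``reference``)."""
    A, B = _common(msaA, msaB)
    pa = _pair_set(A)
    pb = _pair_set(B)
    shared = len(pa & pb)
    if reference:
        denom = len(pb)
    else:
        denom = math.sqrt(len(pa) * len(pb))
    sp = shared / denom if denom > 0 else 0.0
    return MsaSimilarity(sum_of_pairs=sp, column_overlap=column_overlap(msaA, msaB),
                         shared_pairs=shared, pairs_A=len(pa), pairs_B=len(pb))


def column_overlap(msaA: Msa, msaB: Msa) -> float:
    """Fraction of residues appearing in corresponding columns.

    Columns of A are matched to columns of B greedily by decreasing
    shared-residue count (each column used at most once, ties leftmost);
    the score is the matched shared residues over the total residue count.
    """
    A, B = _common(msaA, msaB)
    idxA = A.column_residue_indices()
    idxB = B.column_residue_indices()
    n = len(A.names)

    def col_sets(idx, ncols):
        return [frozenset((p, idx[p, c]) for p in range(n) if idx[p, c] >= 0)
                for c in range(ncols)]

    colsA = col_sets(idxA, A.ncols)
    colsB = col_sets(idxB, B.ncols)
    total = sum(len(c) for c in colsA)
    if total == 0:
        return 0.0
    overlaps = []
    for a, ca in enumerate(colsA):
        for b, cb in enumerate(colsB):
            k = len(ca & cb)
            if k > 0:
                overlaps.append((-k, a, b))
    overlaps.sort()
    usedA, usedB = set(), set()
    shared = 0
    for negk, a, b in overlaps:
        if a in usedA or b in usedB:
            continue
        usedA.add(a)
        usedB.add(b)
        shared += -negk
    return shared / total
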