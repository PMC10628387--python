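"""Structure-guided modification of pairwise alignments.

Four operations on an input pairwise alignment (PA):

* ``ss_realign`` — gaps opened strictly inside a secondary-structure
  element are relocated to the nearer end of the element (structures
  rearrange after an indel, so sequence and structure correspondence need
  not coincide inside SSEs); the better of the input/modified scores is
  reported.
* ``nearest_map`` / ``refine_pa`` — neighbor-frame refinement targeting
  TM, CO or PC_sim: residues that are mutual best matches under the target
  score ("double matches") define frames where they are already aligned in
  the input; additional double matches are inserted between frames in
  sequential order; iterate. This raises the target score without ever
  scoring a gap.
* ``denovo_pa`` — global affine-gap dynamic programming when no input MSA
  exists, over a PC_sim-inspired position score that uses secondary
  structure identity in place of the TM term and contact-vector similarity
  in place of the contact overlap.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .simscore import (DEFAULT_WEIGHTS, PairwiseAlignment, SimilarityScores,
                       d0_from_length, optimal_superposition, score_pair)


class Target(str, Enum):
    SS = "SS"
    TM = "TM"
    CO = "CO"
    PC = "PC"


@dataclass
class NeighborMap:
    """Per-residue nearest residue in the other protein under a target
    score (None where no candidate contributes), plus the symmetric double
    matches (i is j's nearest and j is i's)."""

    nearest1: list
    nearest2: list
    double_matches: list
    target: Target


@dataclass
class RefinementResult:
    refined: PairwiseAlignment
    scores_in: SimilarityScores
    scores_out: SimilarityScores
    target: Target
    iterations: int


def target_value(scores: SimilarityScores, target: Target) -> float:
    v = {Target.TM: scores.TM, Target.CO: scores.CO, Target.PC: scores.PC,
         Target.SS: scores.TM}[Target(target)]
    return 0.0 if math.isnan(v) else v


# ---------------------------------------------------------------------------
# SS_ali: gap relocation inside secondary structure elements

def _sse_extent(ss: str, pos: int) -> tuple:
    """(start, end) of the maximal same-type run of ss containing pos."""
    t = ss[pos]
    a = pos
    while a > 0 and ss[a - 1] == t:
        a -= 1
    b = pos
    while b + 1 < len(ss) and ss[b + 1] == t:
        b += 1
    return a, b


def _move_gaps_in_side(columns: list, side: int, ss_other: str) -> list:
    """Relocate, on one side of the alignment, each gap run that falls
    strictly inside an SSE of the other protein to the nearer SSE end
    (fewer shifted residues; ties go to the N-terminal end)."""
    other = 1 - side
    cols = [list(c) for c in columns]
    c = 0
    while c < len(cols):
        if cols[c][side] is not None:
            c += 1
            continue
        # gap run on `side`; all such columns carry a residue of `other`
        c1 = c
        while c1 + 1 < len(cols) and cols[c1 + 1][side] is None:
            c1 += 1
        run_res = [cols[k][other] for k in range(c, c1 + 1)]
        if any(r is None for r in run_res):
            c = c1 + 1
            continue
        sstypes = {ss_other[r] for r in run_res}
        if len(sstypes) != 1 or sstypes == {"C"}:
            c = c1 + 1
            continue
        e0, e1 = _sse_extent(ss_other, run_res[0])
        if not (e0 < run_res[0] and run_res[-1] < e1):
            c = c1 + 1  # gap touches an SSE end: nothing to move
            continue
        # columns spanned by the SSE; require the other side gapless there
        span = [k for k in range(len(cols))
                if cols[k][other] is not None and e0 <= cols[k][other] <= e1]
        if (span != list(range(span[0], span[-1] + 1))
                or any(k < c or k > c1 for k in range(c, c1 + 1))):
            c = c1 + 1
            continue
        seg0, seg1 = span[0], span[-1]
        n_gaps_span = sum(1 for k in range(seg0, seg1 + 1) if cols[k][side] is None)
        if n_gaps_span != c1 - c + 1:
            c = c1 + 1  # another gap run shares this SSE: leave both in place
            continue
        n_left = sum(1 for k in range(seg0, c) if cols[k][side] is not None)
        n_right = sum(1 for k in range(c1 + 1, seg1 + 1) if cols[k][side] is not None)
        if n_left == 0 and n_right == 0:
            c = c1 + 1
            continue
        n_gap = c1 - c + 1
        side_entries = [cols[k][side] for k in range(seg0, seg1 + 1)
                        if cols[k][side] is not None]
        if n_left <= n_right:
            new_side = [None] * n_gap + side_entries
        else:
            new_side = side_entries + [None] * n_gap
        for off, k in enumerate(range(seg0, seg1 + 1)):
            cols[k][side] = new_side[off]
        c = seg1 + 1
    return [tuple(x) for x in cols]


def ss_realign(pa: PairwiseAlignment, s1, s2) -> RefinementResult:
    """Relocate gaps inside SSEs and report the better of input/modified.

    SI and TM are computed for both alignments and the larger of each is
    reported; when the modified TM is higher, the CO is also taken from the
    modified alignment.
    """
    cols = _move_gaps_in_side(pa.columns, 0, s2.sstruct)
    cols = _move_gaps_in_side(cols, 1, s1.sstruct)
    modified = PairwiseAlignment(pa.id1, pa.id2, cols)
    sc_in = score_pair(pa, s1, s2)
    if cols == pa.columns:
        return RefinementResult(pa, sc_in, sc_in, Target.SS, 0)
    sc_mod = score_pair(modified, s1, s2)
    tm_better = sc_mod.TM > sc_in.TM
    co = sc_mod.CO if tm_better else sc_in.CO
    from .simscore import pc_sim
    reported = SimilarityScores(
        ali=sc_in.ali,
        SI=max(sc_in.SI, sc_mod.SI),
        TM=max(sc_in.TM, sc_mod.TM),
        CO=co,
        PC=pc_sim(sc_in.ali, max(sc_in.SI, sc_mod.SI),
                  max(sc_in.TM, sc_mod.TM), 0.0 if math.isnan(co) else co),
        ss_id=max(sc_in.ss_id, sc_mod.ss_id),
        L_ali=sc_in.L_ali,
    )
    refined = modified if tm_better else pa
    return RefinementResult(refined, sc_in, reported, Target.SS, 1)


# ---------------------------------------------------------------------------
# Neighbor maps

def _shared_contact_counts(pa: PairwiseAlignment, C1, C2) -> np.ndarray:
    """count[i, j] = number of shared contacts gained if i<->j were aligned,
    in the context of the current alignment: sum over k aligned to a(k) of
    C1[i,k] * C2[j,a(k)]."""
    pairs = pa.aligned_pairs
    L1, L2 = C1.shape[0], C2.shape[0]
    if not pairs:
        return np.zeros((L1, L2), dtype=int)
    I = np.array([i for i, _ in pairs])
    J = np.array([j for _, j in pairs])
    # (L1, n_pairs) x (n_pairs, L2)
    return np.asarray(C1, int)[:, I] @ np.asarray(C2, int)[J, :]


def nearest_map(pa: PairwiseAlignment, s1, s2, target: Target) -> NeighborMap:
    """Mutual-best-match map under the target score.

    TM: nearest = minimal C-alpha distance after the current superposition.
    CO: nearest = residue maximizing the shared-contact count in the context
    of the current alignment (None at count 0). PC: argmax of the
    residue-level PC combination (identity + proximity + shared contacts).
    Ties go to the lowest residue index.
    """
    target = Target(target)
    L1, L2 = len(s1), len(s2)
    if target in (Target.TM, Target.PC):
        if pa.n_aligned < 3:
            raise ValueError("TM/PC targets need a superposition (>= 3 aligned)")
        sup = optimal_superposition(pa, s1.calpha, s2.calpha)
        D = np.linalg.norm(sup.apply(s1.calpha)[:, None, :]
                           - np.asarray(s2.calpha, float)[None, :, :], axis=2)
    if target == Target.TM:
        n1 = [int(np.argmin(D[i])) for i in range(L1)]
        n2 = [int(np.argmin(D[:, j])) for j in range(L2)]
    elif target == Target.CO:
        cc = _shared_contact_counts(pa, s1.contacts, s2.contacts)
        n1 = [int(np.argmax(cc[i])) if cc[i].max() > 0 else None for i in range(L1)]
        n2 = [int(np.argmax(cc[:, j])) if cc[:, j].max() > 0 else None for j in range(L2)]
    else:  # PC: residue-level mirror of the PC_sim weights (ali is global)
        w = DEFAULT_WEIGHTS
        cc = _shared_contact_counts(pa, s1.contacts, s2.contacts).astype(float)
        deg = max(int(np.asarray(s1.contacts).sum(1).max(initial=0)),
                  int(np.asarray(s2.contacts).sum(1).max(initial=0)), 1)
        seq_eq = (np.frombuffer(s1.sequence.encode(), dtype="S1")[:, None]
                  == np.frombuffer(s2.sequence.encode(), dtype="S1")[None, :])
        S = (w.w_SI * seq_eq + w.w_TM * (D < sup.d0) + w.w_CO * cc / deg)
        S /= (w.w_SI + w.w_TM + w.w_CO)
        n1 = [int(np.argmax(S[i])) if S[i].max() > 0 else None for i in range(L1)]
        n2 = [int(np.argmax(S[:, j])) if S[:, j].max() > 0 else None for j in range(L2)]
    dm = [(i, j) for i, j in enumerate(n1)
          if j is not None and n2[j] == i]
    return NeighborMap(nearest1=n1, nearest2=n2, double_matches=dm, target=target)


# ---------------------------------------------------------------------------
# Frame refinement

def _pairs_to_alignment(pairs: list, L1: int, L2: int, id1: str, id2: str) -> PairwiseAlignment:
    """Build a full PA from a monotone list of aligned pairs: unpaired
    residues become gap columns (protein 1's residues emitted first between
    consecutive pairs)."""
    cols = []
    pi = pj = 0
    for i, j in list(pairs) + [(L1, L2)]:
        while pi < i:
            cols.append((pi, None))
            pi += 1
        while pj < j:
            cols.append((None, pj))
            pj += 1
        if i < L1:
            cols.append((i, j))
            pi, pj = i + 1, j + 1
    return PairwiseAlignment(id1, id2, cols)


def refine_pa(pa: PairwiseAlignment, s1, s2, target: Target,
              max_iter: int = 5) -> RefinementResult:
    """Neighbor-frame refinement of a PA toward a target score.

    Per pass: frames are double matches already aligned in the current
    alignment (kept fixed); between consecutive frames, remaining double
    matches consistent with sequential order are added left to right.
    Iterates with recomputed neighbors until the alignment stops changing
    or ``max_iter``; the final result is the better of (refined, input)
    under the target score.
    """
    target = Target(target)
    L1, L2 = len(s1), len(s2)
    current = pa
    iterations = 0
    for _ in range(max_iter):
        try:
            nm = nearest_map(current, s1, s2, target)
        except ValueError:
            break
        dm = sorted(nm.double_matches)
        aligned = set(current.aligned_pairs)
        frames = [p for p in dm if p in aligned]
        # insert non-frame double matches between consecutive frames,
        # proceeding left to right
        inserted = []
        prev = (-1, -1)
        for f in frames + [(L1, L2)]:
            cand = [p for p in dm if p not in aligned
                    and prev[0] < p[0] < f[0] and prev[1] < p[1] < f[1]]
            li, lj = prev
            for (i, j) in cand:
                if i > li and j > lj:
                    inserted.append((i, j))
                    li, lj = i, j
            prev = f
        new_pairs = sorted(set(frames) | set(inserted))
        new_pa = _pairs_to_alignment(new_pairs, L1, L2, pa.id1, pa.id2)
        iterations += 1
        if new_pa.columns == current.columns:
            break
        current = new_pa
    sc_in = score_pair(pa, s1, s2)
    sc_ref = score_pair(current, s1, s2) if current is not pa else sc_in
    if target_value(sc_ref, target) >= target_value(sc_in, target):
        return RefinementResult(current, sc_in, sc_ref, target, iterations)
    return RefinementResult(pa, sc_in, sc_in, target, iterations)


# ---------------------------------------------------------------------------
# De novo pairwise alignment

def _blosum_hat(submat: dict | None) -> dict:
    """Substitution matrix rescaled to [0, 1] over the 20 standard residues."""
    from .structio import load_blosum62

    m = submat or load_blosum62()
    aas = "ACDEFGHIKLMNPQRSTVWY"
    vals = [m[(a, b)] for a in aas for b in aas if (a, b) in m]
    lo, hi = min(vals), max(vals)
    out = {}
    for a in aas:
        for b in aas:
            v = m.get((a, b), m.get((b, a), lo))
            out[(a, b)] = (v - lo) / (hi - lo)
    return out


def _contact_offset_multisets(C: np.ndarray) -> list:
    C = np.asarray(C)
    return [Counter((np.nonzero(C[i])[0] - i).tolist()) for i in range(C.shape[0])]


def contact_vector_similarity(C1: np.ndarray, C2: np.ndarray) -> np.ndarray:
    """cvs[i, j] = 1 - |offsets(i) symmetric-difference offsets(j)| /
    (deg(i) + deg(j)), comparing the signed sequence offsets of the two
    residues' contacts; 0 when both degrees are 0."""
    m1 = _contact_offset_multisets(C1)
    m2 = _contact_offset_multisets(C2)
    d1 = [sum(c.values()) for c in m1]
    d2 = [sum(c.values()) for c in m2]
    out = np.zeros((len(m1), len(m2)))
    for i, ci in enumerate(m1):
        for j, cj in enumerate(m2):
            tot = d1[i] + d2[j]
            if tot == 0:
                continue
            inter = sum((ci & cj).values())
            out[i, j] = 1.0 - (tot - 2 * inter) / tot
    return out


def _gotoh_global(S: np.ndarray, gap_open: float, gap_extend: float) -> list:
    """Global affine-gap DP; returns the aligned (i, j) pairs. Traceback
    prefers diagonal > up (gap in seq 2) > left."""
    n, m = S.shape
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in protein 2 (consume i)
    Y = np.full((n + 1, m + 1), NEG)  # gap in protein 1 (consume j)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - gap_extend * (j - 1)
    for i in range(1, n + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Si = S[i - 1]
        for j in range(1, m + 1):
            best = max(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1])
            Mi[j] = best + Si[j - 1]
            Xi[j] = max(Mi1[j] - gap_open, Xi1[j] - gap_extend, Yi1[j] - gap_open)
            Yi[j] = max(Mi[j - 1] - gap_open, Yi[j - 1] - gap_extend, Xi[j - 1] - gap_open)
    # traceback
    i, j = n, m
    state = max(((M[i, j], 0), (X[i, j], 1), (Y[i, j], 2)), key=lambda t: t[0])[1]
    pairs = []
    eps = 1e-11
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            pairs.append((i - 1, j - 1))
            prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            if abs(M[i - 1, j - 1] - prev) < eps:
                state = 0
            elif abs(X[i - 1, j - 1] - prev) < eps:
                state = 1
            else:
                state = 2
            i, j = i - 1, j - 1
        elif state == 1 and i > 0:
            if j == 0:
                i -= 1
                continue
            if abs(M[i - 1, j] - gap_open - X[i, j]) < eps:
                state = 0
            elif abs(X[i - 1, j] - gap_extend - X[i, j]) < eps:
                state = 1
            else:
                state = 2
            i -= 1
        elif state == 2 and j > 0:
            if i == 0:
                j -= 1
                continue
            if abs(M[i, j - 1] - gap_open - Y[i, j]) < eps:
                state = 0
            elif abs(Y[i, j - 1] - gap_extend - Y[i, j]) < eps:
                state = 2
            else:
                state = 1
            j -= 1
        else:  # boundary
            if i > 0:
                state = 1
            else:
                state = 2
    pairs.reverse()
    return pairs


def denovo_pa(s1, s2, submat: dict | None = None, gap_open: float = 0.35,
              gap_extend: float = 0.05) -> PairwiseAlignment:
    """Global structure-aware alignment with no input MSA.

    Position score S(i, j) = (w_SI blosum^(aa_i, aa_j)
    + w_TM [ss_i == ss_j] + w_CO cvs(i, j)) / (w_SI + w_TM + w_CO),
    with affine gaps on the same [0, 1] scale. Secondary-structure identity
    stands in for the TM term and contact-vector similarity for the CO term
    since neither needs a pre-existing alignment. Swapping the inputs
    yields the mirrored alignment exactly (internal canonical ordering).
    """
    key1 = (s1.sequence, s1.sstruct or "", s1.id)
    key2 = (s2.sequence, s2.sstruct or "", s2.id)
    if key2 < key1:
        return denovo_pa(s2, s1, submat, gap_open, gap_extend).swapped()
    w = DEFAULT_WEIGHTS
    bl = _blosum_hat(submat)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    seq_term = np.array([[bl.get((a, b), 0.0) for b in s2.sequence]
                         for a in s1.sequence])
    ss1 = s1.sstruct or "C" * len(s1)
    ss2 = s2.sstruct or "C" * len(s2)
    ss_term = np.array([[1.0 if a == b else 0.0 for b in ss2] for a in ss1])
    cvs = contact_vector_similarity(s1.contacts, s2.contacts)
    S = (w.w_SI * seq_term + w.w_TM * ss_term + w.w_CO * cvs)
    S /= (w.w_SI + w.w_TM + w.w_CO)
    pairs = _gotoh_global(S, gap_open, gap_extend)
    return _pairs_to_alignment(pairs, len(s1), len(s2), s1.id, s2.id)
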