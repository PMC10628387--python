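"""Iterative progressive multiple alignment guided by PC_div.

Each round superimposes all structures on the current MSA, computes the
PC_div divergence matrix, builds an average-linkage (UPGMA) guide tree, and
re-aligns the proteins leaf-to-root with profile-profile dynamic
programming whose column score mirrors the PC_sim weights (BLOSUM62 for the
sequence term, superposition proximity for the TM term, shared contacts for
the CO term, plus a small bonus for pairs already aligned in the previous
MSA). Up to seven rounds are run, stopping early on convergence or a
repeated MSA; the MSA with the largest average PC_sim is returned.

A neighbor-joining tree on the same PC_div matrix is available for output;
the guide tree itself is always average linkage.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import evodiv
from .pair_refine import _blosum_hat, _shared_contact_counts
from .simscore import (DEFAULT_WEIGHTS, PairwiseAlignment, d0_from_length,
                       kabsch, optimal_superposition, score_pair)
from .structio import GAP, Msa

logger = logging.getLogger(__name__)

_AAS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: k for k, a in enumerate(_AAS)}


# ---------------------------------------------------------------------------
# Guide trees

@dataclass
class GuideTree:
    """Binary average-linkage merge tree. Node ids: 0..n-1 are leaves in
    ``names`` order; internal node n+k is created by ``merges[k] =
    (left, right, height)`` with heights nondecreasing."""

    names: list
    merges: list

    def newick(self) -> str:
        n = len(self.names)
        height = {k: 0.0 for k in range(n)}
        label = {k: self.names[k] for k in range(n)}
        for k, (a, b, h) in enumerate(self.merges):
            node = n + k
            la = h - height[a]
            lb = h - height[b]
            label[node] = f"({label[a]}:{la:.6f},{label[b]}:{lb:.6f})"
            height[node] = h
        return label[n + len(self.merges) - 1] + ";" if self.merges else f"({self.names[0]});"

    def merge_order(self) -> list:
        return list(self.merges)


def build_guide_tree(div_matrix: np.ndarray, names: list) -> GuideTree:
    """UPGMA with heights = half the cluster-average divergence and
    deterministic tie-breaking (lexicographically smallest cluster pair)."""
    D = np.asarray(div_matrix, float)
    if np.isnan(D).any():
        raise ValueError("divergence matrix contains NaN; impute UNDEFINED first")
    n = len(names)
    active = {k: (tuple(sorted([names[k]])), 1) for k in range(n)}
    dist = {}
    for a in range(n):
        for b in range(a + 1, n):
            dist[(a, b)] = D[a, b]
    merges = []
    next_id = n
    while len(active) > 1:
        best = None
        for (a, b), d in dist.items():
            if a not in active or b not in active:
                continue
            key = (d, min(active[a][0], active[b][0]),
                   max(active[a][0], active[b][0]))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        d_ab = dist[(min(a, b), max(a, b))]
        la, sa = active[a]
        lb, sb = active[b]
        merges.append((a, b, d_ab / 2.0))
        for c in list(active):
            if c in (a, b):
                continue
            dac = dist[(min(a, c), max(a, c))]
            dbc = dist[(min(b, c), max(b, c))]
            dist[(c, next_id)] = (sa * dac + sb * dbc) / (sa + sb)
        active.pop(a)
        active.pop(b)
        active[next_id] = (tuple(sorted(la + lb)), sa + sb)
        next_id += 1
    return GuideTree(names=list(names), merges=merges)


def nj_tree(div_matrix: np.ndarray, names: list) -> str:
    """Classic neighbor joining; returns a newick string."""
    D = np.asarray(div_matrix, float).copy()
    nodes = [f"{nm}" for nm in names]
    labels = list(names)
    idx = list(range(len(names)))
    n = len(idx)
    if n == 1:
        return f"({nodes[0]});"
    if n == 2:
        return f"({nodes[0]}:{D[0, 1] / 2:.6f},{nodes[1]}:{D[0, 1] / 2:.6f});"
    act = list(range(n))
    newick = list(nodes)
    M = D.copy()
    while len(act) > 2:
        r = len(act)
        totals = {a: sum(M[a, b] for b in act if b != a) for a in act}
        best = None
        for ai in range(r):
            for bi in range(ai + 1, r):
                a, b = act[ai], act[bi]
                q = (r - 2) * M[a, b] - totals[a] - totals[b]
                key = (q, min(labels[a], labels[b]), max(labels[a], labels[b]))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        da = 0.5 * M[a, b] + (totals[a] - totals[b]) / (2 * (r - 2))
        db = M[a, b] - da
        da, db = max(da, 0.0), max(db, 0.0)
        new = f"({newick[a]}:{da:.6f},{newick[b]}:{db:.6f})"
        Mnew = np.zeros((M.shape[0] + 1, M.shape[1] + 1))
        Mnew[:M.shape[0], :M.shape[1]] = M
        k = M.shape[0]
        for c in act:
            if c in (a, b):
                continue
            Mnew[k, c] = Mnew[c, k] = 0.5 * (M[a, c] + M[b, c] - M[a, b])
        M = Mnew
        newick.append(new)
        labels.append(min(labels[a], labels[b]))
        act = [c for c in act if c not in (a, b)] + [k]
    a, b = act
    return f"({newick[a]}:{max(M[a, b], 0.0) / 2:.6f},{newick[b]}:{max(M[a, b], 0.0) / 2:.6f});"


# ---------------------------------------------------------------------------
# Consensus multiple superposition

def multiple_superposition(msa: Msa, structures: list, max_rounds: int = 20,
                           tol: float = 1e-6) -> dict:
    """Rigid transforms placing every structure in a common frame so the
    summed pairwise TM-score over MSA columns is (locally) maximal.

    Starts from the protein with the largest summed pairwise PC_sim (the
    medoid), superimposes all others onto it, then iterates Kabsch fits
    onto the evolving column-average consensus, retaining the best-scoring
    transform set. Deterministic.
    """
    by_id = {s.id: s for s in structures}
    order = list(msa.names)
    n = len(order)
    col_idx = msa.column_residue_indices()

    def induced_pa(a: int, b: int) -> PairwiseAlignment:
        return PairwiseAlignment.from_gapped(msa.rows[a], msa.rows[b],
                                             order[a], order[b])

    pc_sum = np.zeros(n)
    for a in range(n):
        for b in range(a + 1, n):
            sc = score_pair(induced_pa(a, b), by_id[order[a]], by_id[order[b]])
            pc_sum[a] += sc.PC
            pc_sum[b] += sc.PC
    medoid = int(np.argmax(pc_sum))

    transforms = {}
    med = by_id[order[medoid]]
    for a in range(n):
        if a == medoid:
            transforms[order[a]] = (np.eye(3), np.zeros(3))
            continue
        pa = induced_pa(a, medoid)
        if pa.n_aligned >= 3:
            sup = optimal_superposition(pa, by_id[order[a]].calpha, med.calpha)
            transforms[order[a]] = (sup.rotation, sup.translation)
        else:
            logger.warning("%s shares <3 columns with the medoid; left in place",
                           order[a])
            transforms[order[a]] = (np.eye(3), np.zeros(3))

    def placed(a):
        R, t = transforms[order[a]]
        return by_id[order[a]].calpha @ R.T + t

    def summed_tm():
        total = 0.0
        for a in range(n):
            Xa = placed(a)
            for b in range(a + 1, n):
                Xb = placed(b)
                mask = (col_idx[a] >= 0) & (col_idx[b] >= 0)
                if mask.sum() < 1:
                    continue
                d = np.linalg.norm(Xa[col_idx[a][mask]] - Xb[col_idx[b][mask]],
                                   axis=1)
                d0 = d0_from_length(int(mask.sum()))
                total += float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / mask.sum())
        return total

    best_score = summed_tm()
    best = dict(transforms)
    prev = best_score
    for _ in range(max_rounds):
        # consensus over columns where >= 2 proteins are placed
        counts = (col_idx >= 0).sum(axis=0)
        cons = np.zeros((msa.ncols, 3))
        for a in range(n):
            Xa = placed(a)
            mask = col_idx[a] >= 0
            cons[mask] += Xa[col_idx[a][mask]]
        with np.errstate(invalid="ignore"):
            cons = cons / np.maximum(counts, 1)[:, None]
        for a in range(n):
            mask = (col_idx[a] >= 0) & (counts >= 2)
            if mask.sum() < 3:
                continue
            P = by_id[order[a]].calpha[col_idx[a][mask]]
            R, t = kabsch(P, cons[mask])
            transforms[order[a]] = (R, t)
        score = summed_tm()
        if score > best_score:
            best_score = score
            best = dict(transforms)
        if abs(score - prev) < tol:
            break
        prev = score
    return best


# ---------------------------------------------------------------------------
# Profile-profile merge

@dataclass
class ProfileColumnScore:
    """Parameters of the cluster-cluster column score."""

    gap_open: float = 0.35
    gap_extend: float = 0.05
    aligned_bonus: float = 0.1
    weights: object = DEFAULT_WEIGHTS
    submat: dict | None = None


def _encode(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(a, -1) for a in seq], dtype=int)


def _pair_term_matrices(structures: list, msa: Msa, transforms: dict,
                        params: ProfileColumnScore) -> dict:
    """T[(x, y)][i, j]: the summed-weight position score between residue i
    of protein x and residue j of protein y, given the current MSA context
    (shared contacts, superposed distances, aligned-pair bonus)."""
    w = params.weights
    bl = _blosum_hat(params.submat)
    blmat = np.zeros((21, 21))
    for a, ai in _AA_INDEX.items():
        for b, bi in _AA_INDEX.items():
            blmat[ai, bi] = bl[(a, b)]
    by_id = {s.id: s for s in structures}
    names = msa.names
    col_idx = msa.column_residue_indices()
    Lmean = np.mean([len(s) for s in structures])
    d0 = d0_from_length(int(round(Lmean)))
    coords = {}
    for nm in names:
        R, t = transforms[nm]
        coords[nm] = by_id[nm].calpha @ R.T + t
    maxdeg = max(1, max(int(np.asarray(s.contacts).sum(1).max(initial=0))
                        for s in structures))
    T = {}
    for a in range(len(names)):
        for b in range(len(names)):
            if a == b:
                continue
            x, y = names[a], names[b]
            if (y, x) in T:
                T[(x, y)] = T[(y, x)].T
                continue
            sx, sy = by_id[x], by_id[y]
            e1 = _encode(sx.sequence)
            e2 = _encode(sy.sequence)
            e1 = np.where(e1 < 0, 20, e1)  # unknown residues score 0
            e2 = np.where(e2 < 0, 20, e2)
            seq_term = blmat[np.ix_(e1, e2)]
            D = np.linalg.norm(coords[x][:, None, :] - coords[y][None, :, :],
                               axis=2)
            tm_term = 1.0 / (1.0 + (D / d0) ** 2)
            pa = PairwiseAlignment.from_gapped(msa.rows[a], msa.rows[b], x, y)
            cc = _shared_contact_counts(pa, sx.contacts, sy.contacts) / maxdeg
            bonus = np.zeros_like(seq_term)
            for i, j in pa.aligned_pairs:
                bonus[i, j] = params.aligned_bonus
            T[(x, y)] = (w.w_SI * seq_term + w.w_TM * tm_term
                         + w.w_CO * cc + bonus) / (w.w_SI + w.w_TM + w.w_CO)
    return T


def _column_score_matrix(rowsA: dict, rowsB: dict, T: dict) -> np.ndarray:
    """Mean cross-pair position score for every column pair of two
    internally aligned clusters."""
    def indices(rows):
        out = {}
        for nm, row in rows.items():
            idx = np.full(len(row), -1, int)
            k = 0
            for c, ch in enumerate(row):
                if ch != GAP:
                    idx[c] = k
                    k += 1
            out[nm] = idx
        return out

    ia = indices(rowsA)
    ib = indices(rowsB)
    nA = len(next(iter(rowsA.values())))
    nB = len(next(iter(rowsB.values())))
    total = np.zeros((nA, nB))
    count = np.zeros((nA, nB))
    for x, idxA in ia.items():
        mA = idxA >= 0
        for y, idxB in ib.items():
            mB = idxB >= 0
            if not mA.any() or not mB.any():
                continue
            sub = T[(x, y)][np.ix_(np.maximum(idxA, 0), np.maximum(idxB, 0))]
            valid = np.outer(mA, mB)
            total += np.where(valid, sub, 0.0)
            count += valid
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    return S


def align_clusters(rowsA: dict, rowsB: dict, T: dict,
                   params: ProfileColumnScore) -> dict:
    """Global affine-gap DP over column pairs; cluster-internal columns are
    never split. Returns the merged name -> row mapping."""
    from .pair_refine import _gotoh_global

    S = _column_score_matrix(rowsA, rowsB, T)
    pairs = _gotoh_global(S, params.gap_open, params.gap_extend)
    nA, nB = S.shape
    colsA, colsB = [], []
    pa = pb = 0
    for i, j in pairs + [(nA, nB)]:
        while pa < i:
            colsA.append(pa)
            colsB.append(None)
            pa += 1
        while pb < j:
            colsA.append(None)
            colsB.append(pb)
            pb += 1
        if i < nA:
            colsA.append(i)
            colsB.append(j)
            pa, pb = i + 1, j + 1
    merged = {}
    for nm, row in rowsA.items():
        merged[nm] = "".join(GAP if c is None else row[c] for c in colsA)
    for nm, row in rowsB.items():
        merged[nm] = "".join(GAP if c is None else row[c] for c in colsB)
    return merged


# ---------------------------------------------------------------------------
# The iterative driver

def average_pc(msa: Msa, structures: list):
    """Average PC_sim (and full score list) over all pairs of an MSA."""
    by_id = {s.id: s for s in structures}
    n = len(msa.names)
    scores = []
    for a in range(n):
        for b in range(a + 1, n):
            pa = PairwiseAlignment.from_gapped(msa.rows[a], msa.rows[b],
                                               msa.names[a], msa.names[b])
            scores.append(score_pair(pa, by_id[msa.names[a]], by_id[msa.names[b]]))
    return float(np.mean([s.PC for s in scores])), scores


def mean_scores(scores: list) -> dict:
    """Mean of each similarity over a list of SimilarityScores (NaN-safe)."""
    def m(vals):
        vals = [v for v in vals if not math.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    return {"ali": m([s.ali for s in scores]), "SI": m([s.SI for s in scores]),
            "SS": m([s.ss_id for s in scores]), "TM": m([s.TM for s in scores]),
            "CO": m([s.CO for s in scores]), "PC": m([s.PC for s in scores])}


def _progressive_round(msa: Msa, structures: list,
                       params: ProfileColumnScore) -> tuple:
    """One guide-tree rebuild + leaf-to-root merge. Returns (new MSA, tree)."""
    by_id = {s.id: s for s in structures}
    names = list(msa.names)
    transforms = multiple_superposition(msa, structures)
    # PC_div matrix from the current MSA
    divs = {}
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            pa = PairwiseAlignment.from_gapped(msa.rows[a], msa.rows[b],
                                               names[a], names[b])
            sc = score_pair(pa, by_id[names[a]], by_id[names[b]])
            divs[(names[a], names[b])] = evodiv.pc_divergence(
                sc.PC, max(sc.L_ali, 1))
    _, imputed = evodiv.divergence_matrix(names, divs)
    tree = build_guide_tree(imputed, names)
    T = _pair_term_matrices(structures, msa, transforms, params)

    clusters = {k: {names[k]: by_id[names[k]].sequence} for k in range(len(names))}
    next_id = len(names)
    for a, b, _h in tree.merges:
        clusters[next_id] = align_clusters(clusters.pop(a), clusters.pop(b),
                                           T, params)
        next_id += 1
    final = clusters[next_id - 1]
    out = Msa(names, [final[nm] for nm in names]).drop_empty_columns()
    return out, tree


def run_progressive(structures: list, seed_msa: Msa, max_rounds: int = 7,
                    params: ProfileColumnScore | None = None,
                    tol: float = 1e-6):
    """Iterate progressive rounds and return the argmax-average-PC_sim MSA.

    Stops early when the average PC_sim converges (< ``tol`` change) or an
    MSA repeats. Returns (best MSA, log) where log is a list of
    {"iteration", "avg_pc", "n_columns"} dicts covering the seed and every
    round actually run; the selection guarantee is that the returned MSA's
    average PC_sim equals the maximum logged value.
    """
    params = params or ProfileColumnScore()
    current = seed_msa
    log = []
    best = None
    seen_hashes = set()
    prev_pc = None
    last_tree = None
    for it in range(max_rounds + 1):
        avg, sc = average_pc(current, structures)
        log.append({"iteration": it, "avg_pc": avg, "n_columns": current.ncols,
                    "means": mean_scores(sc)})
        if best is None or avg > best[0]:
            best = (avg, current, last_tree)
        h = hashlib.sha1("\n".join(current.rows).encode()).hexdigest()
        cycled = h in seen_hashes
        seen_hashes.add(h)
        converged = prev_pc is not None and abs(avg - prev_pc) < tol
        prev_pc = avg
        if it == max_rounds or cycled or converged:
            break
        current, last_tree = _progressive_round(current, structures, params)
    return best[1], log
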