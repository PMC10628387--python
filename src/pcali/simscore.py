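"""Pairwise sequence+structure similarity scores.

Implements the four elementary similarity measures between two aligned
protein structures — aligned fraction (ali), sequence identity (SI),
TM-score (TM) and contact overlap (CO) — and their fixed-weight hybrid
combination PC_sim, the first principal component of the four measures:

    PC = (0.84 ali + 0.79 SI + 0.95 TM + 0.95 CO) / 3.53

Also provides the TM-score iterative superposition, a covariance-PCA
routine to recompute the loads on user data, and the pairwise score table
writer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Alignment container

@dataclass
class PairwiseAlignment:
    """Ordered gapped correspondence between two residue index sets.

    ``columns`` is a list of ``(i, j)`` pairs where either side may be
    ``None`` (a gap). Non-gap indices are strictly increasing on each side
    and no column is (None, None).
    """

    id1: str
    id2: str
    columns: list

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        last_i = last_j = -1
        for i, j in self.columns:
            if i is None and j is None:
                raise ValueError("(gap, gap) column")
            if i is not None:
                if i <= last_i:
                    raise ValueError("indices of protein 1 not strictly increasing")
                last_i = i
            if j is not None:
                if j <= last_j:
                    raise ValueError("indices of protein 2 not strictly increasing")
                last_j = j

    @property
    def aligned_pairs(self) -> list:
        return [(i, j) for i, j in self.columns if i is not None and j is not None]

    @property
    def n_aligned(self) -> int:
        return len(self.aligned_pairs)

    @classmethod
    def identity(cls, L: int, id1: str = "a", id2: str = "b") -> "PairwiseAlignment":
        return cls(id1, id2, [(k, k) for k in range(L)])

    @classmethod
    def from_gapped(cls, row1: str, row2: str, id1: str = "a", id2: str = "b",
                    gap: str = "-") -> "PairwiseAlignment":
        """Build from two equal-length gapped strings (all-gap columns dropped)."""
        if len(row1) != len(row2):
            raise ValueError("gapped rows differ in length")
        cols, i, j = [], 0, 0
        for a, b in zip(row1, row2):
            gi = gj = None
            if a != gap:
                gi = i
                i += 1
            if b != gap:
                gj = j
                j += 1
            if gi is not None or gj is not None:
                cols.append((gi, gj))
        return cls(id1, id2, cols)

    def to_gapped(self, seq1: str, seq2: str, gap: str = "-") -> tuple:
        r1 = "".join(gap if i is None else seq1[i] for i, _ in self.columns)
        r2 = "".join(gap if j is None else seq2[j] for _, j in self.columns)
        return r1, r2

    def swapped(self) -> "PairwiseAlignment":
        return PairwiseAlignment(self.id2, self.id1,
                                 [(j, i) for i, j in self.columns])


@dataclass
class Superposition:
    """Rigid transform of protein 1 onto protein 2 plus per-column distances."""

    rotation: np.ndarray
    translation: np.ndarray
    distances: np.ndarray  # per aligned column, after the transform (Å)
    d0: float

    def __post_init__(self):
        R = np.asarray(self.rotation, float)
        if np.linalg.norm(R.T @ R - np.eye(3)) > 1e-9 or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with det +1")
        self.rotation = R
        self.translation = np.asarray(self.translation, float)
        self.distances = np.asarray(self.distances, float)

    def apply(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class PcWeights:
    """Fixed PC_sim loads (first principal component of ali/SI/TM/CO)."""

    w_ali: float = 0.84
    w_SI: float = 0.79
    w_TM: float = 0.95
    w_CO: float = 0.95
    norm: float = 3.53

    def __post_init__(self):
        s = self.w_ali + self.w_SI + self.w_TM + self.w_CO
        if abs(s - self.norm) > 0.005 + 1e-9:
            raise ValueError(f"norm {self.norm} != weight sum {s}")
        if min(self.w_ali, self.w_SI, self.w_TM, self.w_CO) <= 0:
            raise ValueError("weights must be positive")


DEFAULT_WEIGHTS = PcWeights()


@dataclass
class SimilarityScores:
    """The five pair similarities plus secondary-structure identity."""

    ali: float
    SI: float
    TM: float
    CO: float
    PC: float
    ss_id: float = float("nan")
    L_ali: int = 0


# ---------------------------------------------------------------------------
# Elementary measures

def d0_from_length(L: int, floor: float = 0.5) -> float:
    """TM-score distance scale d0 = 1.24 (L-15)^(1/3) - 1.8, clamped at
    ``floor`` so short alignments stay finite (the raw formula is <= 0 for
    L <~ 21)."""
    if L > 15:
        d0 = 1.24 * (L - 15.0) ** (1.0 / 3.0) - 1.8
    else:
        d0 = floor
    return max(d0, floor)


def aligned_fraction(pa: PairwiseAlignment, L1: int, L2: int) -> float:
    """Fraction of no-gap columns relative to the longer protein."""
    if L1 < 1 or L2 < 1:
        raise ValueError("protein lengths must be >= 1")
    return pa.n_aligned / max(L1, L2)


def sequence_identity(pa: PairwiseAlignment, seq1: str, seq2: str) -> float:
    """Fraction of aligned columns with identical residues (indels unscored)."""
    pairs = pa.aligned_pairs
    if not pairs:
        return 0.0
    same = sum(1 for i, j in pairs if seq1[i] == seq2[j])
    return same / len(pairs)


def ss_identity(pa: PairwiseAlignment, ss1: str, ss2: str) -> float:
    pairs = pa.aligned_pairs
    if not pairs:
        return 0.0
    return sum(1 for i, j in pairs if ss1[i] == ss2[j]) / len(pairs)


def kabsch(P: np.ndarray, Q: np.ndarray, weights: np.ndarray | None = None) -> tuple:
    """Least-squares rigid transform (R, t) minimizing sum w ||R P + t - Q||²."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if weights is None:
        w = np.ones(len(P))
    else:
        w = np.asarray(weights, float)
    w = w / w.sum()
    cp, cq = w @ P, w @ Q
    H = (P - cp).T @ ((Q - cq) * w[:, None])
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    return R, t


def optimal_superposition(pa: PairwiseAlignment, calpha1: np.ndarray,
                          calpha2: np.ndarray, L_norm: int | None = None,
                          max_iter: int = 50) -> Superposition:
    """TM-score-maximizing superposition, determined self-consistently.

    Starting from the plain least-squares fit on all aligned columns, the
    working subset is repeatedly restricted to columns with distance below
    max(d0, 3 Å) and refit until the subset stops changing (or ``max_iter``
    passes); each fit is then polished by iteratively reweighted
    least squares with weights (1 + (d_i/d0)²)^-2, the
    majorize-minimize update for the TM objective, from the plain fit and
    three 180°-flipped restarts. The transform with the highest TM-score
    seen is returned. Deterministic.
    """
    pairs = pa.aligned_pairs
    if len(pairs) < 3:
        raise ValueError("too few aligned residues (need >= 3)")
    I = np.array([i for i, _ in pairs])
    J = np.array([j for _, j in pairs])
    P = np.asarray(calpha1, float)[I]
    Q = np.asarray(calpha2, float)[J]
    n = len(pairs)
    if L_norm is None:
        L_norm = n
    d0 = d0_from_length(L_norm)
    thr = max(d0, 3.0)

    def evaluate(R, t):
        d = np.linalg.norm(P @ R.T + t - Q, axis=1)
        return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L_norm), d

    def irls(R, t):
        # majorize-minimize on the TM objective: monotone in exact arithmetic
        best_local = (*evaluate(R, t), R, t)
        for _ in range(max_iter):
            d = best_local[1]
            w = 1.0 / (1.0 + (d / d0) ** 2) ** 2
            R, t = kabsch(P, Q, weights=w)
            tm, d = evaluate(R, t)
            if tm <= best_local[0] + 1e-12:
                break
            best_local = (tm, d, R, t)
        return best_local

    subset = np.arange(n)
    best = None
    seen = set()
    for _ in range(max_iter):
        R, t = kabsch(P[subset], Q[subset])
        tm, d = evaluate(R, t)
        if best is None or tm > best[0]:
            best = (tm, d, R, t)
        new = np.nonzero(d < thr)[0]
        if len(new) < 3:
            new = np.argsort(d, kind="stable")[:3]
        key = tuple(new.tolist())
        if key in seen:
            break
        seen.add(key)
        subset = new

    # polish with reweighted fits from the best transform and flip restarts
    _, _, R0, t0 = best
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    starts = [(R0, t0)]
    for F in (np.diag([1.0, -1.0, -1.0]), np.diag([-1.0, 1.0, -1.0]),
              np.diag([-1.0, -1.0, 1.0])):
        Rf = F @ R0
        starts.append((Rf, cq - Rf @ cp))
    if n <= 12:
        # tiny alignments have a multimodal TM landscape: add a coarse
        # rotation-grid multistart (octahedral group, centroid-matched)
        from scipy.spatial.transform import Rotation

        for Rg in Rotation.create_group("O").as_matrix():
            starts.append((Rg, cq - Rg @ cp))
    for R, t in starts:
        cand = irls(R, t)
        if cand[0] > best[0]:
            best = cand
    _, d, R, t = best
    return Superposition(rotation=R, translation=t, distances=d, d0=d0)


def tm_score(superposition: Superposition, L_norm: int) -> float:
    """TM = (1/L_norm) sum_i 1 / (1 + (d_i/d0)^2) over superimposed columns."""
    if L_norm < 1:
        raise ValueError("L_norm must be >= 1")
    d0 = d0_from_length(L_norm)
    d = superposition.distances
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L_norm)


def contact_overlap(pa: PairwiseAlignment, C1: np.ndarray, C2: np.ndarray) -> float:
    """Rotation-free fraction of shared contacts.

    CO = sum_{i<j} C1[i,j] C2[a(i),a(j)] / sqrt(sum C1 * sum C2), where a()
    maps through the alignment and gap-aligned residues contribute nothing.
    Returns NaN (flagged in the log) when either protein has no contacts.
    """
    C1 = np.asarray(C1)
    C2 = np.asarray(C2)
    tot1 = int(np.triu(C1, 1).sum())
    tot2 = int(np.triu(C2, 1).sum())
    if tot1 == 0 or tot2 == 0:
        logger.warning("contact overlap undefined: a protein has no contacts")
        return float("nan")
    pairs = pa.aligned_pairs
    if not pairs:
        return 0.0
    I = np.array([i for i, _ in pairs])
    J = np.array([j for _, j in pairs])
    sub1 = C1[np.ix_(I, I)]
    sub2 = C2[np.ix_(J, J)]
    shared = int(np.triu(sub1 * sub2, 1).sum())
    return shared / math.sqrt(tot1 * tot2)


def pc_sim(ali: float, SI: float, TM: float, CO: float,
           weights: PcWeights = DEFAULT_WEIGHTS) -> float:
    """Hybrid similarity: fixed-weight combination of the four measures."""
    for name, v in (("ali", ali), ("SI", SI), ("TM", TM), ("CO", CO)):
        if not (-1e-9 <= v <= 1 + 1e-9):
            raise ValueError(f"{name}={v} outside [0, 1]")
    return (weights.w_ali * ali + weights.w_SI * SI
            + weights.w_TM * TM + weights.w_CO * CO) / weights.norm


def score_pair(pa: PairwiseAlignment, s1, s2,
               weights: PcWeights = DEFAULT_WEIGHTS,
               norm_by_max_length: bool = False) -> SimilarityScores:
    """All five similarities for one pairwise alignment of two structures.

    ``norm_by_max_length`` switches the TM normalization from the number of
    aligned positions (the default) to max(L1, L2). A contact overlap that
    is undefined (a contact-free protein) enters PC as 0.
    """
    L1, L2 = len(s1), len(s2)
    ali = aligned_fraction(pa, L1, L2)
    SI = sequence_identity(pa, s1.sequence, s2.sequence)
    L_ali = pa.n_aligned
    L_norm = max(L1, L2) if norm_by_max_length else L_ali
    if L_ali >= 3:
        sup = optimal_superposition(pa, s1.calpha, s2.calpha, L_norm=L_norm)
        TM = tm_score(sup, L_norm)
    else:
        TM = 0.0
    CO = contact_overlap(pa, s1.contacts, s2.contacts)
    co_for_pc = 0.0 if math.isnan(CO) else CO
    PC = pc_sim(ali, SI, TM, co_for_pc, weights)
    ss = float("nan")
    if s1.sstruct is not None and s2.sstruct is not None:
        ss = ss_identity(pa, s1.sstruct, s2.sstruct)
    return SimilarityScores(ali=ali, SI=SI, TM=TM, CO=CO, PC=PC,
                            ss_id=ss, L_ali=L_ali)


# ---------------------------------------------------------------------------
# PCA of a score table

def pca_loads(score_table) -> tuple:
    """First principal component of an (n, 4) table of (ali, SI, TM, CO).

    Covariance PCA on the raw [0, 1] scores (no standardization). Returns
    (loads, variance_fractions); the leading eigenvector's sign is fixed so
    that its component sum is positive (all-positive when possible).
    """
    X = np.asarray(score_table, float)
    if X.ndim != 2 or X.shape[0] < 4:
        raise ValueError("need a table with >= 4 rows")
    C = np.cov(X, rowvar=False)
    if not np.all(np.isfinite(C)) or np.allclose(C, 0):
        raise ValueError("degenerate covariance")
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0, None)
    vecs = vecs[:, order]
    loads = vecs[:, 0]
    if loads.sum() < 0:
        loads = -loads
    total = vals.sum()
    if total <= 0:
        raise ValueError("degenerate covariance")
    return loads, vals / total


# ---------------------------------------------------------------------------
# Score table writer

def write_sim_table(rows, path) -> None:
    """Whitespace table 'id1 id2 ali SI SS TM CO PC', one row per pair.

    ``rows`` yields (id1, id2, SimilarityScores); SS is the
    secondary-structure identity of the aligned columns.
    """
    with open(path, "w") as fh:
        fh.write("#id1 id2 ali SI SS TM CO PC\n")
        for id1, id2, s in rows:
            fh.write(f"{id1} {id2} {s.ali:.4f} {s.SI:.4f} {s.ss_id:.4f} "
                     f"{s.TM:.4f} {s.CO:.4f} {s.PC:.4f}\n")
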