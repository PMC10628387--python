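"""Evolutionary divergences inferred from similarity measures.

Each similarity s with baseline s0 (the value expected between unrelated
proteins) maps to a Poisson-corrected divergence -ln((s - s0)/(1 - s0)),
the Tajima-Nei form. Divergences exist only for similarities above their
baseline; below it they are UNDEFINED (returned as NaN, which is a value,
not an error). At similarity 1 every divergence is 0.

Baselines: SI0 = 0.05 (unrelated sequences), TM0 = 0.167 (convergent
evolution), q(L) = 0.39 L^-0.55 + 6.64 L^-0.67 for the contact overlap,
and for PC_sim the same weighted combination of the individual baselines
with ali0 = 0.5.
"""

from __future__ import annotations

import math

import numpy as np

from .simscore import DEFAULT_WEIGHTS, PcWeights

SI0 = 0.05
TM0 = 0.167
ALI0 = 0.5

UNDEFINED = float("nan")


def is_defined(x: float) -> bool:
    return not math.isnan(x)


def _tn_form(s: float, s0: float) -> float:
    if not (-1e-9 <= s <= 1 + 1e-9):
        raise ValueError(f"similarity {s} outside [0, 1]")
    if s <= s0:
        return UNDEFINED
    return -math.log(min((s - s0) / (1.0 - s0), 1.0))


def tn_divergence(SI: float) -> float:
    """Tajima-Nei divergence from sequence identity: -ln((SI-0.05)/0.95)."""
    return _tn_form(SI, SI0)


def tm_divergence(TM: float) -> float:
    """Structure divergence from the TM-score: -ln((TM-0.167)/0.833)."""
    return _tn_form(TM, TM0)


def q_contact(L: int) -> float:
    """Contact overlap expected under convergent evolution for L aligned
    residues: q(L) = 0.39 L^-0.55 + 6.64 L^-0.67."""
    if L < 1:
        raise ValueError("L must be >= 1")
    return 0.39 * L ** -0.55 + 6.64 * L ** -0.67


def contact_divergence(CO: float, L: int) -> float:
    """Contact divergence: -ln((CO - q(L)) / (1 - q(L)))."""
    if math.isnan(CO):
        return UNDEFINED
    q = q_contact(L)
    if q >= 1.0:  # very short alignments: any overlap is expected by chance
        return UNDEFINED
    return _tn_form(CO, q)


def pc_baseline(L: int, weights: PcWeights = DEFAULT_WEIGHTS) -> float:
    """PC_sim expected without homology: the weighted combination of the
    individual baselines, PC0 = (w_ali ali0 + w_SI SI0 + w_TM TM0 + w_CO q(L)) / norm."""
    return (weights.w_ali * ALI0 + weights.w_SI * SI0
            + weights.w_TM * TM0 + weights.w_CO * q_contact(L)) / weights.norm


def pc_divergence(PC: float, L: int, weights: PcWeights = DEFAULT_WEIGHTS,
                  denom_pc: bool = False) -> float:
    """Hybrid divergence from PC_sim, the TN form with baseline PC0(L).

    ``denom_pc`` switches the denominator from (1 - PC0) to (1 - PC); the
    default keeps the same functional form as the other three divergences.
    """
    pc0 = pc_baseline(L, weights)
    if not denom_pc:
        return _tn_form(PC, pc0)
    if PC <= pc0 or PC >= 1.0:
        return 0.0 if PC >= 1.0 else UNDEFINED
    return -math.log((PC - pc0) / (1.0 - PC))


def divergence_matrix(ids: list, pair_divergences: dict) -> tuple:
    """Symmetric divergence matrix over ``ids`` with UNDEFINED imputation.

    ``pair_divergences`` maps unordered id pairs to a divergence (NaN for
    UNDEFINED). Returns ``(raw, imputed)``: ``raw`` keeps NaNs for output
    files; ``imputed`` replaces them with (max defined divergence) + 1 so
    tree building keeps undefined pairs most distant. Raises if every pair
    is UNDEFINED.
    """
    n = len(ids)
    raw = np.zeros((n, n), float)
    for a in range(n):
        for b in range(a + 1, n):
            key = (ids[a], ids[b])
            if key not in pair_divergences:
                key = (ids[b], ids[a])
            d = pair_divergences[key]
            raw[a, b] = raw[b, a] = d
    off = raw[~np.eye(n, dtype=bool)]
    defined = off[~np.isnan(off)]
    if n > 1 and defined.size == 0:
        raise ValueError("no homology signal: all pair divergences UNDEFINED")
    imputed = raw.copy()
    if np.isnan(imputed).any():
        fill = float(defined.max()) + 1.0
        imputed[np.isnan(imputed)] = fill
    return raw, imputed


def write_div_table(rows, path) -> None:
    """Whitespace table 'id1 id2 TN TMdiv CD PCdiv' (UNDEF for NaN)."""

    def fmt(x):
        return "UNDEF" if math.isnan(x) else f"{x:.4f}"

    with open(path, "w") as fh:
        fh.write("#id1 id2 TN TMdiv CD PCdiv\n")
        for id1, id2, tn, tmd, cd, pcd in rows:
            fh.write(f"{id1} {id2} {fmt(tn)} {fmt(tmd)} {fmt(cd)} {fmt(pcd)}\n")
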