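"""Natural-abundance correction of measured isotopologue distributions.

Measured peak areas for M+0..M+n mix tracer-derived labeling with natural
¹³C (abundance ~1.07%) at the unlabeled positions.  The forward model is a
lower-triangular binomial matrix; correction inverts it by non-negative
least squares, which keeps noisy inputs from producing negative fractions.
Correction is carbon-only: O/N/H/S isotopes and tracer impurity are out of
scope here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls
from scipy.special import comb

from .isosim import MIDVector

__all__ = [
    "NATURAL_13C_ABUNDANCE",
    "PeakAreaVector",
    "correction_matrix",
    "apply_natural_abundance",
    "correct_mid",
    "fractional_enrichment",
]

#: default natural abundance of ¹³C
NATURAL_13C_ABUNDANCE = 0.0107


@dataclass
class PeakAreaVector:
    """Raw LC-MS peak areas for the isotopologues M+0..M+n of one metabolite."""

    metabolite: str
    areas: np.ndarray
    sample: str = ""

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.ndim != 1 or len(self.areas) < 1:
            raise ValueError("areas must be a 1-D vector")


def correction_matrix(n_carbons: int, p: float = NATURAL_13C_ABUNDANCE) -> np.ndarray:
    """Binomial matrix M with M[i, j] = P(observed shift i | j tracer labels).

    A molecule with j tracer-derived ¹³C has n-j positions left where
    natural ¹³C (probability ``p`` each) can add further mass shifts:
    M[i, j] = C(n-j, i-j) p^(i-j) (1-p)^(n-i) for i >= j.  Columns sum to 1.
    """
    if not 0.0 <= p < 0.5:
        raise ValueError(f"natural abundance p={p} outside [0, 0.5)")
    n = n_carbons
    M = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        for i in range(j, n + 1):
            M[i, j] = comb(n - j, i - j, exact=True) * p ** (i - j) * (1 - p) ** (n - i)
    return M


def apply_natural_abundance(
    true_mid: np.ndarray | MIDVector, p: float = NATURAL_13C_ABUNDANCE
) -> np.ndarray:
    """Forward model: what a tracer-only MID looks like when measured."""
    v = true_mid.values if isinstance(true_mid, MIDVector) else np.asarray(true_mid, float)
    M = correction_matrix(len(v) - 1, p)
    out = M @ v
    return out / out.sum()


def correct_mid(
    measured: PeakAreaVector | np.ndarray,
    p: float = NATURAL_13C_ABUNDANCE,
    metabolite: str = "",
) -> tuple[MIDVector, float]:
    """Invert the natural-abundance forward model by non-negative least
    squares; returns the corrected MID (renormalized to 1) and the NNLS
    residual in fraction units."""
    if isinstance(measured, PeakAreaVector):
        areas = measured.areas
        metabolite = metabolite or measured.metabolite
    else:
        areas = np.asarray(measured, dtype=float)
    total = areas.sum()
    if total <= 0:
        raise ValueError(f"{metabolite or 'MID'}: all-zero peak areas")
    fractions = areas / total
    M = correction_matrix(len(areas) - 1, p)
    x, residual = nnls(M, fractions)
    s = x.sum()
    if s <= 0:
        raise ValueError(f"{metabolite or 'MID'}: correction produced a zero vector")
    return MIDVector(metabolite, x / s, state="na_corrected"), float(residual)


def correct_mid_table(
    areas_by_metabolite: dict[str, np.ndarray],
    p: float = NATURAL_13C_ABUNDANCE,
    min_total_area: float = 0.0,
    enabled: bool = True,
) -> dict[str, MIDVector | None]:
    """Correct a batch of peak-area vectors.

    Vectors whose total area falls below ``min_total_area`` are marked
    missing (None) rather than corrected, to avoid amplifying noise.  With
    ``enabled=False`` raw fractions are propagated (state ``raw``) for
    sensitivity analysis.
    """
    out: dict[str, MIDVector | None] = {}
    for met, areas in areas_by_metabolite.items():
        areas = np.asarray(areas, dtype=float)
        total = areas.sum()
        if total <= min_total_area or total <= 0:
            out[met] = None
            continue
        if enabled:
            out[met], _ = correct_mid(areas, p, metabolite=met)
        else:
            out[met] = MIDVector(met, areas / total, state="raw")
    return out


def fractional_enrichment(mid: np.ndarray | MIDVector) -> float:
    """Average fraction of heavy carbons: sum_i (i/n) MID_i, in [0, 1]."""
    v = mid.values if isinstance(mid, MIDVector) else np.asarray(mid, float)
    n = len(v) - 1
    if n == 0:
        return 0.0
    return float(np.arange(n + 1) @ v / n)
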