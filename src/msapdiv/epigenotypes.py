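"""Methylation-state classification of MSAP band pairs and Mix1 scoring.

HpaII and MspI are isoschizomers of the CCGG site that differ in methylation
sensitivity, so the joint presence/absence of a fragment in the two parallel
profiles encodes the methylation state of its restriction site:

========  ========  ==========================================
HpaII     MspI      state
========  ========  ==========================================
1         1         unmethylated site
1         0         hemi-methylated CHG (external cytosine)
0         1         hemi- or fully methylated CG (internal)
0         0         uninformative (methylation of other types,
                    or the restriction site itself is absent)
========  ========  ==========================================

The Mix1 scoring scheme turns each epilocus into two dominant markers: a
U-MSAP marker scoring the unmethylated condition as 1, and an M-MSAP marker
scoring either methylated condition as 1.  The uninformative pair scores 0 in
both (it is not treated as missing data: the band-based index formulas
require complete binary matrices).  Consequently ``u + m <= 1`` holds for
every cell.

After encoding, loci are filtered independently within the U and the M
matrix over all individuals of the species dataset: monomorphic columns are
dropped, and polymorphic columns whose minority state is carried by fewer
than ``min_poly`` individuals are dropped as effectively uninformative.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .marker_io import BinaryMarkerMatrix, MarkerType, MSAPProfileBundle

__all__ = [
    "EpigenotypeState",
    "EpiMatrices",
    "classify_epilocus",
    "mix1_encode",
    "extract_epigenotypes",
]


class EpigenotypeState(Enum):
    UNMETHYLATED = "unmethylated"
    HEMI_CHG = "hemi_methylated_chg"
    METH_CG = "methylated_cg"
    UNINFORMATIVE = "uninformative"


_CLASSIFY = {
    (1, 1): EpigenotypeState.UNMETHYLATED,
    (1, 0): EpigenotypeState.HEMI_CHG,
    (0, 1): EpigenotypeState.METH_CG,
    (0, 0): EpigenotypeState.UNINFORMATIVE,
}

_MIX1 = {
    EpigenotypeState.UNMETHYLATED: (1, 0),
    EpigenotypeState.HEMI_CHG: (0, 1),
    EpigenotypeState.METH_CG: (0, 1),
    EpigenotypeState.UNINFORMATIVE: (0, 0),
}


def classify_epilocus(hpa: int, msp: int) -> EpigenotypeState:
    """Map one (HpaII, MspI) band pair to its methylation state."""
    try:
        return _CLASSIFY[(int(hpa), int(msp))]
    except KeyError:
        raise ValueError(f"band pair must be binary, got ({hpa!r}, {msp!r})") from None


def mix1_encode(state: EpigenotypeState) -> tuple[int, int]:
    """Return the (u_bit, m_bit) Mix1 scores for a methylation state."""
    return _MIX1[state]


@dataclass
class EpiMatrices:
    """Filtered Mix1 output: the U-MSAP and M-MSAP marker matrices.

    ``filter_log`` records, per matrix, every dropped locus with its reason
    (``"monomorphic"`` or ``"below_min_poly"``).  U and M are filtered
    independently, so their locus sets generally differ.
    """

    u: BinaryMarkerMatrix
    m: BinaryMarkerMatrix
    filter_log: dict[str, list[tuple[str, str]]]


def _filter_columns(
    values: np.ndarray, locus_ids: list[str], min_poly: int, delete_monomorphic: bool
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    k = values.shape[0]
    ones = values.sum(axis=0)
    minority = np.minimum(ones, k - ones)
    keep = np.ones(values.shape[1], dtype=bool)
    log: list[tuple[str, str]] = []
    for j in range(values.shape[1]):
        if minority[j] == 0:
            if delete_monomorphic:
                keep[j] = False
                log.append((locus_ids[j], "monomorphic"))
        elif minority[j] < min_poly:
            keep[j] = False
            log.append((locus_ids[j], "below_min_poly"))
    return keep, log


def extract_epigenotypes(
    bundle: MSAPProfileBundle,
    min_poly: int = 2,
    delete_monomorphic: bool = True,
) -> EpiMatrices:
    """Classify every cell of an aligned bundle and emit filtered U/M matrices.

    Applied once per species dataset (its populations pooled); the
    ``min_poly`` threshold is the minimum count of the minority bit across
    all individuals of the dataset for a polymorphic locus to be retained.
    Monomorphic-locus deletion is controlled separately by
    ``delete_monomorphic``.
    """
    if min_poly < 1:
        raise ValueError("min_poly must be >= 1")
    if bundle.n_samples == 0 or bundle.n_epiloci == 0:
        raise ValueError("empty bundle: no individuals or no epiloci")

    hpa = bundle.hpa.values.astype(np.uint8)
    msp = bundle.msp.values.astype(np.uint8)
    # Vectorized Mix1: the unmethylated condition is hpa AND msp, either
    # methylated condition is hpa XOR msp; (0,0) scores 0 in both.
    u_vals = hpa & msp
    m_vals = hpa ^ msp

    locus_ids = list(bundle.hpa.locus_ids)
    keep_u, log_u = _filter_columns(u_vals, locus_ids, min_poly, delete_monomorphic)
    keep_m, log_m = _filter_columns(m_vals, locus_ids, min_poly, delete_monomorphic)
    if not keep_u.any() or not keep_m.any():
        empty = "U-MSAP" if not keep_u.any() else "M-MSAP"
        raise ValueError(f"no polymorphic epiloci after filtering ({empty} matrix empty)")

    samples = list(bundle.hpa.samples)
    u = BinaryMarkerMatrix(
        samples=samples,
        locus_ids=[lid for lid, k in zip(locus_ids, keep_u) if k],
        values=u_vals[:, keep_u],
        marker_type=MarkerType.U_MSAP,
    )
    m = BinaryMarkerMatrix(
        samples=list(samples),
        locus_ids=[lid for lid, k in zip(locus_ids, keep_m) if k],
        values=m_vals[:, keep_m],
        marker_type=MarkerType.M_MSAP,
    )
    return EpiMatrices(u=u, m=m, filter_log={"U_MSAP": log_u, "M_MSAP": log_m})
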