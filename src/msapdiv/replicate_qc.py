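"""Scoring-error estimation from technical replicates and band elimination.

Repeating the whole fingerprinting protocol on a subset of samples gives
replicate pairs whose profile disagreements estimate the per-band scoring
error.  Bands that disagree in more than ``drop_threshold`` of the pairs are
eliminated as irreproducible; the overall error rate is then the Bonin-style
mismatch rate on the surviving loci,

    overall_error_rate = total mismatches / (n_pairs * n_retained_loci),

which is the quantity conventionally reported for AFLP/MSAP data sets
(typically a few percent).  Dropping loci can only remove mismatches, so it
never increases the overall rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .marker_io import BinaryMarkerMatrix, MSAPProfileBundle

__all__ = ["ErrorReport", "pair_replicates", "compute_error_report", "qc_bundle"]


@dataclass
class ErrorReport:
    n_pairs: int
    per_locus_mismatch: dict[str, float]
    dropped_loci: list[str]
    overall_error_rate: float
    n_retained_loci: int = 0

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "overall_error_rate": self.overall_error_rate,
            "n_retained_loci": self.n_retained_loci,
            "dropped_loci": list(self.dropped_loci),
            "per_locus_mismatch": dict(self.per_locus_mismatch),
        }


def pair_replicates(m: BinaryMarkerMatrix) -> list[tuple[str, str]]:
    """Return (original_id, replicate_id) pairs from the sample metadata.

    Replicate links are already validated at matrix construction (a
    replicate may not point at another replicate, i.e. no chains).
    """
    pairs = []
    for s in m.samples:
        if s.is_replicate:
            pairs.append((s.replicate_of, s.individual_id))
    return pairs


def compute_error_report(
    m: BinaryMarkerMatrix,
    pairs: list[tuple[str, str]],
    drop_threshold: float = 0.5,
) -> tuple[ErrorReport, BinaryMarkerMatrix]:
    """Estimate scoring error and drop irreproducible bands.

    Per-locus mismatch = fraction of replicate pairs disagreeing at that
    locus; loci with mismatch > ``drop_threshold`` are removed, and the
    overall error rate is computed on the retained loci only.  Returns the
    report and the filtered matrix (replicate rows kept; use
    ``analysis_subset()`` afterwards to drop them).
    """
    if not 0.0 <= drop_threshold <= 1.0:
        raise ValueError(f"drop_threshold must be in [0, 1], got {drop_threshold}")
    if not pairs:
        raise ValueError("no replicate pairs: cannot compute an error report")
    idx = {s.individual_id: i for i, s in enumerate(m.samples)}
    orig_rows = np.array([idx[a] for a, _ in pairs])
    rep_rows = np.array([idx[b] for _, b in pairs])
    mism = (m.values[orig_rows, :] != m.values[rep_rows, :])  # n_pairs x n_loci
    frac = mism.mean(axis=0)
    keep = frac <= drop_threshold
    dropped = [lid for lid, k in zip(m.locus_ids, keep) if not k]
    n_ret = int(keep.sum())
    if n_ret == 0:
        rate = 0.0
    else:
        rate = float(mism[:, keep].sum()) / (len(pairs) * n_ret)
    report = ErrorReport(
        n_pairs=len(pairs),
        per_locus_mismatch={lid: float(f) for lid, f in zip(m.locus_ids, frac)},
        dropped_loci=dropped,
        overall_error_rate=rate,
        n_retained_loci=n_ret,
    )
    return report, m.select_loci(keep)


def qc_bundle(
    bundle: MSAPProfileBundle,
    pairs: list[tuple[str, str]],
    drop_threshold: float = 0.5,
) -> tuple[dict[str, ErrorReport], MSAPProfileBundle]:
    """Replicate QC for an aligned HpaII/MspI bundle.

    Each profile matrix is screened separately with the same pairs; an
    epilocus eliminated in either profile is removed from both so the bundle
    stays aligned.  Reports are returned per profile.
    """
    rep_h, _ = compute_error_report(bundle.hpa, pairs, drop_threshold)
    rep_m, _ = compute_error_report(bundle.msp, pairs, drop_threshold)
    bad = set(rep_h.dropped_loci) | set(rep_m.dropped_loci)
    keep = np.array([lid not in bad for lid in bundle.hpa.locus_ids])
    out = MSAPProfileBundle(
        hpa=bundle.hpa.select_loci(keep), msp=bundle.msp.select_loci(keep)
    )
    # rates recomputed on the common retained set so both profiles report
    # error over the same loci
    if keep.any():
        idx = {s.individual_id: i for i, s in enumerate(bundle.hpa.samples)}
        orig = np.array([idx[a] for a, _ in pairs])
        rep = np.array([idx[b] for _, b in pairs])
        denom = len(pairs) * int(keep.sum())
        for r, mat in ((rep_h, bundle.hpa), (rep_m, bundle.msp)):
            mism = (mat.values[orig][:, keep] != mat.values[rep][:, keep]).sum()
            r.overall_error_rate = float(mism) / denom
            r.n_retained_loci = int(keep.sum())
            r.dropped_loci = sorted(bad)
    return {"hpa": rep_h, "msp": rep_m}, out
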