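"""Band-based population diversity indices for dominant markers.

All four indices work directly on presence/absence band counts, avoiding
allele-frequency estimation (which is unreliable for dominant markers):

* **PPOL** -- proportion of the species' retained loci that are polymorphic
  (both states observed) within the population.
* **SI** -- Shannon's diversity index per locus,
  ``SI = -(p ln p + (1-p) ln(1-p))`` with ``p`` the band presence frequency
  in the population and ``0 ln 0 := 0``; the population value is the mean
  over loci (units: nats; maximum ``ln 2`` for a two-state marker).
* **PPRIV** -- proportion of the population's present bands that occur in no
  other population of the species (private bands).
* **RI** -- frequency-down-weighted marker value ("rarity index"): for
  individual ``x``, ``RI_x = sum_i s_ix / D_i`` where ``s_ix`` is the band
  state and ``D_i`` the number of occurrences of marker ``i`` over all
  analysis individuals of the species dataset; the population RI is the mean
  of ``RI_x`` over its members.  Rare bands therefore contribute close to 1,
  ubiquitous bands close to ``1/k``.  Summed over the whole species dataset,
  the individual values add up exactly to the number of markers present.

Indices are always computed inside one species dataset (the 3 sampled
populations pooled), after species-level locus filtering and with technical
replicates excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .marker_io import BinaryMarkerMatrix, MarkerType

__all__ = [
    "DiversityRecord",
    "drop_monomorphic",
    "ppol",
    "shannon_index",
    "pprivate",
    "rarity_index",
    "species_diversity_records",
    "build_diversity_table",
    "DIVERSITY_COLUMNS",
]

DIVERSITY_COLUMNS = [
    "species",
    "population",
    "distribution",
    "marker_type",
    "n_individuals",
    "n_loci",
    "PPOL",
    "SI",
    "PPRIV",
    "RI",
]


@dataclass
class DiversityRecord:
    """One population x marker-type row of the four indices."""

    species: str
    population: str
    distribution: str
    marker_type: str
    n_individuals: int
    n_loci: int
    ppol: float
    si: float
    ppriv: float
    ri: float


def drop_monomorphic(m: BinaryMarkerMatrix) -> BinaryMarkerMatrix:
    """Remove loci fixed (all 0 or all 1) over the whole species dataset."""
    ones = m.values.sum(axis=0)
    keep = (ones > 0) & (ones < m.n_samples)
    return m.select_loci(keep)


def _pop_mask(m: BinaryMarkerMatrix, population: str) -> np.ndarray:
    mask = m.populations == population
    if not mask.any():
        raise ValueError(f"population '{population}' not present in matrix")
    return mask


def ppol(m: BinaryMarkerMatrix, population: str) -> float:
    """Proportion of polymorphic fragments within one population.

    The denominator is every locus retained in the species matrix, so
    populations of one species are directly comparable.
    """
    if m.n_loci == 0:
        raise ValueError("matrix has zero loci")
    mask = _pop_mask(m, population)
    sub = m.values[mask, :]
    if sub.shape[0] < 2:
        raise ValueError(f"population '{population}' has fewer than 2 individuals")
    ones = sub.sum(axis=0)
    poly = (ones > 0) & (ones < sub.shape[0])
    return float(poly.mean())


def shannon_index(m: BinaryMarkerMatrix, population: str) -> float:
    """Mean per-locus two-state Shannon entropy (nats) in one population."""
    if m.n_loci == 0:
        raise ValueError("matrix has zero loci")
    mask = _pop_mask(m, population)
    sub = m.values[mask, :]
    if sub.shape[0] < 2:
        raise ValueError(f"population '{population}' has fewer than 2 individuals")
    p = sub.mean(axis=0)
    return float(np.mean(_entropy2(p)))


def _entropy2(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    for q in (p, 1.0 - p):
        nz = q > 0
        out[nz] -= q[nz] * np.log(q[nz])
    return out


def pprivate(m: BinaryMarkerMatrix, population: str) -> float:
    """Proportion of the focal population's bands private to it.

    A band is private when present in the focal population (any count >= 1)
    and absent from every other population of the species.  The denominator
    is the number of bands present in the focal population.
    """
    pops = np.unique(m.populations)
    if len(pops) < 2:
        raise ValueError("pprivate needs a species matrix with >= 2 populations")
    mask = _pop_mask(m, population)
    present_focal = m.values[mask, :].any(axis=0)
    n_present = int(present_focal.sum())
    if n_present == 0:
        raise ValueError(f"population '{population}' has no present bands")
    present_others = m.values[~mask, :].any(axis=0)
    private = present_focal & ~present_others
    return float(private.sum()) / n_present


def rarity_index(
    m: BinaryMarkerMatrix, population: str
) -> tuple[np.ndarray, float]:
    """Frequency-down-weighted marker value per individual and its mean.

    Denominators ``D_i`` are marker occurrence counts over ALL analysis
    individuals of the species dataset; markers absent from the whole
    dataset are skipped.
    """
    if m.n_loci == 0:
        raise ValueError("matrix has zero loci")
    occ = m.values.sum(axis=0).astype(float)  # D_i over the species dataset
    informative = occ > 0
    mask = _pop_mask(m, population)
    sub = m.values[mask][:, informative].astype(float)
    ri_x = sub @ (1.0 / occ[informative])
    return ri_x, float(ri_x.mean())


def species_diversity_records(m: BinaryMarkerMatrix) -> list[DiversityRecord]:
    """All per-population records for one species x marker-type matrix.

    Expects an analysis matrix (replicates removed, species-level filtering
    already applied).  Populations are emitted in order of first appearance.
    """
    if any(s.is_replicate for s in m.samples):
        m = m.analysis_subset()
    seen: list[str] = []
    for s in m.samples:
        if s.population not in seen:
            seen.append(s.population)
    species = m.samples[0].species
    distribution = m.samples[0].distribution.value
    records = []
    for pop in seen:
        mask = m.populations == pop
        ri_x, ri = rarity_index(m, pop)
        records.append(
            DiversityRecord(
                species=species,
                population=pop,
                distribution=distribution,
                marker_type=m.marker_type.value,
                n_individuals=int(mask.sum()),
                n_loci=m.n_loci,
                ppol=ppol(m, pop),
                si=shannon_index(m, pop),
                ppriv=pprivate(m, pop),
                ri=ri,
            )
        )
    return records


def build_diversity_table(
    species_matrices: dict[str, dict[str, BinaryMarkerMatrix]],
    expected_populations: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Assemble the population x marker-type diversity table.

    ``species_matrices`` maps species name -> marker-type name
    (``"AFLP" | "U_MSAP" | "M_MSAP"``) -> analysis matrix.  One row per
    population per marker type; for a 14-species x 3-population design this
    is 126 rows, 42 per marker type.
    """
    rows = []
    for species, by_marker in species_matrices.items():
        for marker_name, m in by_marker.items():
            if MarkerType(marker_name) != m.marker_type:
                raise ValueError(
                    f"{species}: matrix labelled {marker_name} has "
                    f"marker_type {m.marker_type.value}"
                )
            recs = species_diversity_records(m)
            if expected_populations is not None:
                got = {r.population for r in recs}
                missing = set(expected_populations[species]) - got
                if missing:
                    raise ValueError(
                        f"{species}/{marker_name}: populations missing from "
                        f"matrix: {sorted(missing)}"
                    )
            rows.extend(recs)
    df = pd.DataFrame(
        [
            {
                "species": r.species,
                "population": r.population,
                "distribution": r.distribution,
                "marker_type": r.marker_type,
                "n_individuals": r.n_individuals,
                "n_loci": r.n_loci,
                "PPOL": r.ppol,
                "SI": r.si,
                "PPRIV": r.ppriv,
                "RI": r.ri,
            }
            for r in rows
        ],
        columns=DIVERSITY_COLUMNS,
    )
    return df
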