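"""Reading, validating, merging and writing binary fingerprint matrices.

AFLP and MSAP fingerprints are dominant markers: each locus is scored as band
presence (1) or absence (0) per individual.  All on-disk exchange uses one CSV
dialect: a header row, six leading metadata columns
(``individual_id, genus, species, population, distribution, replicate_of``)
followed by one column per locus, cells strictly ``0``/``1``.  Matrices are
complete after scoring -- missing values are rejected at read time because the
downstream band-based index formulas assume complete binary data.

Sample alignment between the parallel HpaII and MspI profile runs of an MSAP
assay is positional-safety-critical, so nothing in this module ever reorders
samples silently; mismatches raise.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Distribution",
    "MarkerType",
    "SampleMeta",
    "BinaryMarkerMatrix",
    "MSAPProfileBundle",
    "MarkerFormatError",
    "read_marker_matrix",
    "write_marker_matrix",
    "merge_primer_panels",
    "read_msap_bundle",
]

META_COLUMNS = (
    "individual_id",
    "genus",
    "species",
    "population",
    "distribution",
    "replicate_of",
)

#: locus ids must survive CSV round trips; ":" is reserved as the panel
#: namespace separator used by :func:`merge_primer_panels`.
LOCUS_ID_RE = re.compile(r"^[A-Za-z0-9_.:\-]+$")


class MarkerFormatError(ValueError):
    """A fingerprint file or matrix violates the format contract."""


class Distribution(str, Enum):
    RESTRICTED = "restricted"
    WIDESPREAD = "widespread"


class MarkerType(str, Enum):
    AFLP = "AFLP"
    U_MSAP = "U_MSAP"
    M_MSAP = "M_MSAP"
    HPA_PROFILE = "HPA_PROFILE"
    MSP_PROFILE = "MSP_PROFILE"


@dataclass(frozen=True)
class SampleMeta:
    """Identity and grouping of one sampled individual.

    ``replicate_of`` is non-empty when this sample is a technical replicate
    (the whole fingerprinting protocol repeated on the same plant); it names
    the original, non-replicate individual in the same population.
    """

    individual_id: str
    genus: str
    species: str
    population: str
    distribution: Distribution
    replicate_of: str | None = None

    @property
    def is_replicate(self) -> bool:
        return bool(self.replicate_of)


@dataclass
class BinaryMarkerMatrix:
    """Individuals x loci presence/absence table plus sample metadata.

    ``values`` is a ``k x n`` uint8 array of 0/1 cells where ``k`` is the
    number of samples and ``n`` the number of loci, in file order.
    """

    samples: list[SampleMeta]
    locus_ids: list[str]
    values: np.ndarray
    marker_type: MarkerType

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2:
            raise MarkerFormatError("values must be a 2-D array")
        k, n = self.values.shape
        if k != len(self.samples):
            raise MarkerFormatError(
                f"{len(self.samples)} samples but {k} value rows"
            )
        if n != len(self.locus_ids):
            raise MarkerFormatError(
                f"{len(self.locus_ids)} locus ids but {n} value columns"
            )
        bad = (self.values > 1).nonzero()
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise MarkerFormatError(
                f"non-binary cell at individual "
                f"'{self.samples[i].individual_id}', locus "
                f"'{self.locus_ids[j]}'"
            )
        _check_unique("individual_id", [s.individual_id for s in self.samples])
        _check_unique("locus_id", self.locus_ids)
        self._validate_replicate_links()

    def _validate_replicate_links(self) -> None:
        by_id = {s.individual_id: s for s in self.samples}
        for s in self.samples:
            if not s.replicate_of:
                continue
            target = by_id.get(s.replicate_of)
            if target is None:
                raise MarkerFormatError(
                    f"replicate '{s.individual_id}' points at unknown "
                    f"individual '{s.replicate_of}'"
                )
            if target.is_replicate:
                raise MarkerFormatError(
                    f"replicate '{s.individual_id}' points at another "
                    f"replicate '{s.replicate_of}' (chains are not allowed)"
                )
            if target.population != s.population:
                raise MarkerFormatError(
                    f"replicate '{s.individual_id}' and its original "
                    f"'{s.replicate_of}' are in different populations"
                )

    # -- convenience accessors -------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [s.individual_id for s in self.samples]

    @property
    def populations(self) -> np.ndarray:
        return np.array([s.population for s in self.samples])

    def analysis_subset(self) -> "BinaryMarkerMatrix":
        """Drop technical replicates (they never enter diversity/statistics)."""
        keep = [i for i, s in enumerate(self.samples) if not s.is_replicate]
        return BinaryMarkerMatrix(
            samples=[self.samples[i] for i in keep],
            locus_ids=list(self.locus_ids),
            values=self.values[keep, :],
            marker_type=self.marker_type,
        )

    def select_loci(self, keep: Sequence[int] | np.ndarray) -> "BinaryMarkerMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return BinaryMarkerMatrix(
            samples=list(self.samples),
            locus_ids=[self.locus_ids[j] for j in keep],
            values=self.values[:, keep],
            marker_type=self.marker_type,
        )

    def with_marker_type(self, marker_type: MarkerType) -> "BinaryMarkerMatrix":
        return BinaryMarkerMatrix(
            samples=list(self.samples),
            locus_ids=list(self.locus_ids),
            values=self.values.copy(),
            marker_type=marker_type,
        )

    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "individual_id": [s.individual_id for s in self.samples],
                "genus": [s.genus for s in self.samples],
                "species": [s.species for s in self.samples],
                "population": [s.population for s in self.samples],
                "distribution": [s.distribution.value for s in self.samples],
                "replicate_of": [s.replicate_of or "" for s in self.samples],
            }
        )
        data = pd.DataFrame(self.values, columns=self.locus_ids)
        return pd.concat([meta, data.set_index(meta.index)], axis=1)

    def equals(self, other: "BinaryMarkerMatrix") -> bool:
        return (
            self.marker_type == other.marker_type
            and self.samples == other.samples
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass
class MSAPProfileBundle:
    """Aligned MseI/HpaII and MseI/MspI profile matrices for one species.

    Each column is one epilocus (a CCGG-anchored fragment) scored jointly in
    the two isoschizomer runs; rows (samples) and columns (epiloci) are in
    identical order in both matrices.
    """

    hpa: BinaryMarkerMatrix
    msp: BinaryMarkerMatrix

    def __post_init__(self) -> None:
        if self.hpa.marker_type != MarkerType.HPA_PROFILE:
            raise MarkerFormatError("bundle.hpa must have marker_type HPA_PROFILE")
        if self.msp.marker_type != MarkerType.MSP_PROFILE:
            raise MarkerFormatError("bundle.msp must have marker_type MSP_PROFILE")
        _check_aligned(self.hpa, self.msp)

    @property
    def n_samples(self) -> int:
        return self.hpa.n_samples

    @property
    def n_epiloci(self) -> int:
        return self.hpa.n_loci

    def analysis_subset(self) -> "MSAPProfileBundle":
        return MSAPProfileBundle(
            hpa=self.hpa.analysis_subset(), msp=self.msp.analysis_subset()
        )


def _check_unique(what: str, ids: Sequence[str]) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise MarkerFormatError(f"duplicate {what} '{x}'")
        seen.add(x)


def _check_aligned(hpa: BinaryMarkerMatrix, msp: BinaryMarkerMatrix) -> None:
    hl, ml = set(hpa.locus_ids), set(msp.locus_ids)
    if hl != ml:
        diff = sorted(hl.symmetric_difference(ml))
        raise MarkerFormatError(
            f"HpaII/MspI epilocus sets differ; symmetric difference: {diff}"
        )
    if hpa.locus_ids != msp.locus_ids:
        raise MarkerFormatError(
            "HpaII/MspI epilocus order differs (no silent reordering)"
        )
    hs, ms = set(hpa.sample_ids), set(msp.sample_ids)
    if hs != ms:
        diff = sorted(hs.symmetric_difference(ms))
        raise MarkerFormatError(
            f"HpaII/MspI sample sets differ; symmetric difference: {diff}"
        )
    if hpa.sample_ids != msp.sample_ids:
        raise MarkerFormatError(
            "HpaII/MspI sample order differs (no silent reordering)"
        )


def read_marker_matrix(path: str | Path, marker_type: MarkerType) -> BinaryMarkerMatrix:
    """Read one fingerprint CSV and validate it.

    Raises :class:`MarkerFormatError` naming the offending row/column on any
    contract violation (non-binary cell, duplicate id, unknown distribution
    class, bad replicate link).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in META_COLUMNS if c not in df.columns[: len(META_COLUMNS)].tolist()]
    if list(df.columns[: len(META_COLUMNS)]) != list(META_COLUMNS):
        raise MarkerFormatError(
            f"{path}: leading columns must be {', '.join(META_COLUMNS)}"
            + (f" (missing {missing})" if missing else "")
        )
    locus_ids = list(df.columns[len(META_COLUMNS):])
    for lid in locus_ids:
        if not LOCUS_ID_RE.match(lid):
            raise MarkerFormatError(f"{path}: invalid locus id '{lid}'")

    samples = []
    for row in df.itertuples(index=False):
        dist = getattr(row, "distribution")
        try:
            dist = Distribution(dist)
        except ValueError:
            raise MarkerFormatError(
                f"{path}: individual '{row.individual_id}' has distribution "
                f"'{dist}' (expected 'restricted' or 'widespread')"
            ) from None
        samples.append(
            SampleMeta(
                individual_id=row.individual_id,
                genus=row.genus,
                species=row.species,
                population=row.population,
                distribution=dist,
                replicate_of=row.replicate_of or None,
            )
        )

    raw = df[locus_ids].to_numpy(dtype=object) if locus_ids else np.empty((len(df), 0), dtype=object)
    values = np.zeros(raw.shape, dtype=np.uint8)
    for (i, j), cell in np.ndenumerate(raw):
        cell = str(cell).strip()
        if cell == "1":
            values[i, j] = 1
        elif cell != "0":
            raise MarkerFormatError(
                f"{path}: non-binary cell '{cell}' at individual "
                f"'{samples[i].individual_id}', locus '{locus_ids[j]}'"
            )
    return BinaryMarkerMatrix(
        samples=samples, locus_ids=locus_ids, values=values, marker_type=marker_type
    )


def write_marker_matrix(m: BinaryMarkerMatrix, path: str | Path) -> None:
    """Write the CSV dialect that :func:`read_marker_matrix` inverts bit-exactly."""
    for lid in m.locus_ids:
        if not LOCUS_ID_RE.match(lid):
            raise MarkerFormatError(
                f"locus id '{lid}' not writable (allowed charset: A-Za-z0-9_.:-)"
            )
    m.to_frame().to_csv(path, index=False)


def merge_primer_panels(
    panels: Mapping[str, BinaryMarkerMatrix] | Iterable[tuple[str, BinaryMarkerMatrix]],
) -> BinaryMarkerMatrix:
    """Column-concatenate the per-primer-pair matrices of one species.

    Each primer combination yields its own scored panel; they are merged into
    a single table with locus ids namespaced as ``"<panel>:<locus>"``.  All
    panels must carry the identical samples in identical order and the same
    marker type.
    """
    items = list(panels.items()) if isinstance(panels, Mapping) else list(panels)
    if not items:
        raise MarkerFormatError("no panels to merge")
    first = items[0][1]
    merged_ids: list[str] = []
    blocks: list[np.ndarray] = []
    for name, panel in items:
        if panel.marker_type != first.marker_type:
            raise MarkerFormatError(
                f"panel '{name}' marker_type {panel.marker_type.value} != "
                f"{first.marker_type.value}"
            )
        if panel.samples != first.samples:
            raise MarkerFormatError(
                f"panel '{name}' samples differ from panel '{items[0][0]}' "
                "(same individuals in the same order are required)"
            )
        merged_ids.extend(f"{name}:{lid}" for lid in panel.locus_ids)
        blocks.append(panel.values)
    _check_unique("merged locus id", merged_ids)
    return BinaryMarkerMatrix(
        samples=list(first.samples),
        locus_ids=merged_ids,
        values=np.concatenate(blocks, axis=1) if blocks else first.values,
        marker_type=first.marker_type,
    )


def read_msap_bundle(hpa_path: str | Path, msp_path: str | Path) -> MSAPProfileBundle:
    """Read the paired HpaII/MspI profile files and verify their alignment."""
    hpa = read_marker_matrix(hpa_path, MarkerType.HPA_PROFILE)
    msp = read_marker_matrix(msp_path, MarkerType.MSP_PROFILE)
    return MSAPProfileBundle(hpa=hpa, msp=msp)
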