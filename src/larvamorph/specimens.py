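"""Specimen metadata: records, packaged inventory, filters, measurements.

The package ships a small TSV inventory of the 98 long-nosed antlion
(Psychopsidae) larvae underlying the analysis: 52 previously studied
specimens (12 extant, 12 Eocene, 28 Upper Cretaceous — only epoch and
provenance are carried, since their per-specimen details were published
elsewhere) plus 46 newly described fossils (44 Cretaceous Kachin-amber
larvae with PED repository numbers, body lengths and labrum-morphotype
assignments, and 2 Eocene Baltic-amber specimens known from photographs).

Body lengths printed as ranges are stored as the midpoint with
``length_is_estimate = True``; where a directly measured length differs
from the estimated complete length (incomplete specimens), the estimate
is stored and the measured value noted.  Records carrying an explicit
"not included in the final analysis" statement are flagged and removed
by :func:`filter_for_analysis`.
"""

from __future__ import annotations

import enum
import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .outlines import OutlineContour

__all__ = [
    "Epoch",
    "Morphotype",
    "SpecimenRecord",
    "HeadMeasurement",
    "FixtureError",
    "load_paper_metadata",
    "filter_for_analysis",
    "count_by",
    "measure_head",
]


class Epoch(str, enum.Enum):
    cretaceous = "Cretaceous"
    eocene = "Eocene"
    extant = "extant"


class Morphotype(str, enum.Enum):
    """Labrum morphotype families used to group larvae qualitatively."""

    triangular = "triangular"
    pentagonal = "pentagonal"
    trident = "trident"
    trident_bifid = "trident_bifid"
    pentadent = "pentadent"
    broad = "broad"
    unknown = "unknown"


class FixtureError(RuntimeError):
    """Raised when the packaged metadata fixture is missing or corrupt."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One specimen of the published inventory."""

    specimen_no: int
    repository_id: str
    epoch: Epoch
    provenance: str  # "prior_study" | "this_study"
    included_in_analysis: bool
    body_length_mm: float | None = None
    length_is_estimate: bool = False
    labrum_morphotype: Morphotype = Morphotype.unknown
    notes: str = ""

    def __post_init__(self) -> None:
        if self.body_length_mm is not None and not self.body_length_mm > 0:
            raise ValueError("body_length_mm must be positive when present")
        if self.provenance not in ("prior_study", "this_study"):
            raise ValueError(f"bad provenance: {self.provenance!r}")
        if (
            self.provenance == "this_study"
            and self.epoch is Epoch.cretaceous
            and not self.repository_id.startswith("PED")
        ):
            raise ValueError(
                f"new Cretaceous specimen {self.specimen_no} lacks a PED id"
            )


@dataclass(frozen=True)
class HeadMeasurement:
    """Head-capsule length/width extents along a chosen anatomical axis."""

    head_length: float
    head_width_max: float
    body_length: float | None = None

    def __post_init__(self) -> None:
        if not (self.head_length > 0 and self.head_width_max > 0):
            raise ValueError("head measurements must be positive")


_FIXTURE_NAME = "specimens.tsv"


def _fixture_path() -> Path:
    return Path(resources.files("larvamorph").joinpath("data", _FIXTURE_NAME))


def load_paper_metadata(path: str | Path | None = None) -> list[SpecimenRecord]:
    """Load the packaged 98-specimen inventory (checksum-verified).

    A different TSV in the same dialect may be passed for user data; the
    checksum is then not enforced.
    """
    verify = path is None
    path = _fixture_path() if path is None else Path(path)
    if not path.exists():
        raise FixtureError(f"metadata fixture missing: {path}")
    raw = path.read_bytes()
    if verify:
        expected = (
            path.with_suffix(".tsv.sha256").read_text().split()[0].strip()
        )
        got = hashlib.sha256(raw).hexdigest()
        if got != expected:
            raise FixtureError(
                f"metadata fixture corrupt: sha256 {got} != expected {expected}"
            )
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SpecimenRecord(
                specimen_no=int(row.specimen_no),
                repository_id=row.repository_id,
                epoch=Epoch(row.epoch),
                provenance=row.provenance,
                included_in_analysis=row.included_in_analysis == "true",
                body_length_mm=(
                    float(row.body_length_mm) if row.body_length_mm else None
                ),
                length_is_estimate=row.length_is_estimate == "true",
                labrum_morphotype=Morphotype(row.labrum_morphotype),
                notes=row.notes,
            )
        )
    nos = [r.specimen_no for r in records]
    if len(set(nos)) != len(nos):
        raise FixtureError("duplicate specimen numbers in fixture")
    return records


def filter_for_analysis(records: list[SpecimenRecord]) -> list[SpecimenRecord]:
    """Keep only records flagged for the final analysis, order preserved."""
    return [r for r in records if r.included_in_analysis]


def count_by(
    records: list[SpecimenRecord],
    *,
    epoch: Epoch | None = None,
    provenance: str | None = None,
    included: bool | None = None,
) -> int:
    """Count records matching all the given filters."""
    out = records
    if epoch is not None:
        out = [r for r in out if r.epoch is epoch]
    if provenance is not None:
        out = [r for r in out if r.provenance == provenance]
    if included is not None:
        out = [r for r in out if r.included_in_analysis == included]
    return len(out)


def measure_head(
    contour: OutlineContour, axis: np.ndarray | tuple[float, float] = (1.0, 0.0)
) -> HeadMeasurement:
    """Length and maximum width of an outline along an anatomical axis.

    ``head_length`` is the extent of vertex projections onto the unit
    ``axis``; ``head_width_max`` the extent onto the perpendicular —
    i.e. width at the maximum expansion, measured perpendicular to the
    length axis.
    """
    ax = np.asarray(axis, dtype=float)
    norm = np.hypot(*ax)
    if norm == 0:
        raise ValueError("axis must be non-zero")
    ax = ax / norm
    perp = np.array([-ax[1], ax[0]])
    along = contour.points @ ax
    across = contour.points @ perp
    return HeadMeasurement(
        head_length=float(along.max() - along.min()),
        head_width_max=float(across.max() - across.min()),
    )
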