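"""Data model and delimited-text I/O for strip-transect survey records.

Three record types cover the field protocols: :class:`TransectRecord`
(one surveyed transect), :class:`DetectionEvent` (one detected cluster,
with a perpendicular distance for distance-design transects), and
:class:`QuadratCount` (one quadrat count).  Files are UTF-8 CSV with a
header row; readers validate every record and report the offending row
on failure.

Coordinate convention: ``half_width_m`` is the half-width *w* such that
the surveyed strip area is ``2 * w * L``.  A distance transect searched
up to 1 m either side of the line has ``w = 1.0``; a removal strip 1 m
wide in total has ``w = 0.5``.  Quadrat transects carry an explicit
quadrat count and per-quadrat area instead.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ReferentialError, SchemaError, ValidationError


class Design(str, enum.Enum):
    """Survey design of a transect."""

    QUADRAT = "quadrat"
    REMOVAL = "removal"
    DISTANCE = "distance"


class History(str, enum.Enum):
    """Two-observer capture history of a detection event.

    ``FIRST_OBSERVER`` — detected by the lead observer (and flagged, so
    unavailable to the trailing observer); ``SECOND_OBSERVER_ONLY`` —
    missed by the lead observer, found by the trailing one.
    """

    FIRST_OBSERVER = "first_observer"
    SECOND_OBSERVER_ONLY = "second_observer_only"


@dataclass(frozen=True)
class TransectRecord:
    """One surveyed transect.

    Parameters
    ----------
    transect_id, lake : str
        Labels.
    design : Design
        Survey design used on this transect.
    length_m : float
        Transect length ``l_i`` in metres, > 0.
    half_width_m : float or None
        Strip half-width *w* in metres; required (> 0) for removal and
        distance designs, unused for quadrat transects.
    n_quadrats : int or None
        Number of quadrats sampled (quadrat design only, >= 1).
    quadrat_area_m2 : float or None
        Area of one quadrat in m^2 (quadrat design only, > 0).
    """

    transect_id: str
    lake: str
    design: Design
    length_m: float
    half_width_m: float | None = None
    n_quadrats: int | None = None
    quadrat_area_m2: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "design", Design(self.design))
        if not (self.length_m > 0):
            raise ValidationError(
                f"transect {self.transect_id!r}: length_m must be > 0, "
                f"got {self.length_m}"
            )
        if self.design in (Design.REMOVAL, Design.DISTANCE):
            if self.half_width_m is None or not (self.half_width_m > 0):
                raise ValidationError(
                    f"transect {self.transect_id!r}: half_width_m must be > 0 "
                    f"for {self.design.value} design, got {self.half_width_m}"
                )
        else:  # quadrat
            if self.n_quadrats is None or self.n_quadrats < 1:
                raise ValidationError(
                    f"transect {self.transect_id!r}: quadrat design requires "
                    f"n_quadrats >= 1, got {self.n_quadrats}"
                )
            if self.quadrat_area_m2 is None or not (self.quadrat_area_m2 > 0):
                raise ValidationError(
                    f"transect {self.transect_id!r}: quadrat design requires "
                    f"quadrat_area_m2 > 0, got {self.quadrat_area_m2}"
                )


@dataclass(frozen=True)
class DetectionEvent:
    """One detected cluster (druse) on a strip transect.

    ``distance_m`` is the perpendicular distance from the transect line
    (distance design only); ``cluster_size`` is the number of
    individuals in the cluster (>= 1).
    """

    transect_id: str
    history: History
    cluster_size: int
    distance_m: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "history", History(self.history))
        if self.cluster_size < 1:
            raise ValidationError(
                f"event on transect {self.transect_id!r}: cluster_size must "
                f"be >= 1, got {self.cluster_size}"
            )
        if self.distance_m is not None and not (self.distance_m >= 0):
            raise ValidationError(
                f"event on transect {self.transect_id!r}: distance_m must be "
                f">= 0, got {self.distance_m}"
            )


@dataclass(frozen=True)
class QuadratCount:
    """Count of individuals inside one quadrat."""

    transect_id: str
    quadrat_index: int
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValidationError(
                f"quadrat {self.quadrat_index} on transect "
                f"{self.transect_id!r}: count must be >= 0, got {self.count}"
            )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_TRANSECT_COLUMNS = (
    "transect_id",
    "lake",
    "design",
    "length_m",
    "half_width_m",
    "n_quadrats",
    "quadrat_area_m2",
)
_DETECTION_COLUMNS = ("transect_id", "history", "distance_m", "cluster_size")
_QUADRAT_COLUMNS = ("transect_id", "quadrat_index", "count")


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def _opt_int(value) -> int | None:
    f = _opt_float(value)
    return None if f is None else int(round(f))


_LABEL_DTYPES = {"transect_id": str, "lake": str}


def read_transects(path) -> list[TransectRecord]:
    """Read transect metadata from CSV, validating each row."""
    df = pd.read_csv(path, dtype=_LABEL_DTYPES, keep_default_na=False,
                     na_values=[""])
    _require_columns(df, ("transect_id", "lake", "design", "length_m"), path)
    records: list[TransectRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        design = str(row.design)
        if design not in Design._value2member_map_:
            raise ValidationError(
                f"{path}:{i}: unknown design label {design!r}; expected one "
                f"of {[d.value for d in Design]}"
            )
        try:
            records.append(
                TransectRecord(
                    transect_id=str(row.transect_id),
                    lake=str(row.lake),
                    design=Design(design),
                    length_m=float(row.length_m),
                    half_width_m=_opt_float(getattr(row, "half_width_m", None)),
                    n_quadrats=_opt_int(getattr(row, "n_quadrats", None)),
                    quadrat_area_m2=_opt_float(
                        getattr(row, "quadrat_area_m2", None)
                    ),
                )
            )
        except ValidationError as err:
            raise ValidationError(f"{path}:{i}: {err}") from err
    return records


def write_transects(transects: Sequence[TransectRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "transect_id": t.transect_id,
                "lake": t.lake,
                "design": t.design.value,
                "length_m": t.length_m,
                "half_width_m": t.half_width_m,
                "n_quadrats": t.n_quadrats,
                "quadrat_area_m2": t.quadrat_area_m2,
            }
            for t in transects
        ],
        columns=_TRANSECT_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_detections(path, transects: Sequence[TransectRecord]) -> list[DetectionEvent]:
    """Read detection events, cross-referencing against ``transects``.

    Enforces that a perpendicular distance is present exactly when the
    transect uses the distance design, and that recorded distances do
    not exceed the transect half-width.
    """
    by_id = {t.transect_id: t for t in transects}
    df = pd.read_csv(path, dtype=_LABEL_DTYPES, keep_default_na=False,
                     na_values=[""])
    _require_columns(df, ("transect_id", "history", "cluster_size"), path)
    events: list[DetectionEvent] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        tid = str(row.transect_id)
        transect = by_id.get(tid)
        if transect is None:
            raise ReferentialError(
                f"{path}:{i}: transect_id {tid!r} not present in transect file"
            )
        history = str(row.history)
        if history not in History._value2member_map_:
            raise ValidationError(
                f"{path}:{i}: unknown history label {history!r}"
            )
        distance = _opt_float(getattr(row, "distance_m", None))
        if transect.design is Design.DISTANCE:
            if distance is not None and distance > transect.half_width_m:
                raise ValidationError(
                    f"{path}:{i}: distance {distance} m exceeds half-width "
                    f"{transect.half_width_m} m of transect {tid!r}"
                )
        elif distance is not None:
            raise ValidationError(
                f"{path}:{i}: distance_m given for non-distance transect {tid!r}"
            )
        try:
            events.append(
                DetectionEvent(
                    transect_id=tid,
                    history=History(history),
                    cluster_size=int(row.cluster_size),
                    distance_m=distance,
                )
            )
        except ValidationError as err:
            raise ValidationError(f"{path}:{i}: {err}") from err
    return events


def write_detections(events: Sequence[DetectionEvent], path) -> None:
    df = pd.DataFrame(
        [
            {
                "transect_id": e.transect_id,
                "history": e.history.value,
                "distance_m": e.distance_m,
                "cluster_size": e.cluster_size,
            }
            for e in events
        ],
        columns=_DETECTION_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_quadrats(path, transects: Sequence[TransectRecord]) -> list[QuadratCount]:
    by_id = {t.transect_id: t for t in transects}
    df = pd.read_csv(path, dtype=_LABEL_DTYPES, keep_default_na=False,
                     na_values=[""])
    _require_columns(df, _QUADRAT_COLUMNS, path)
    counts: list[QuadratCount] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        tid = str(row.transect_id)
        if tid not in by_id:
            raise ReferentialError(
                f"{path}:{i}: transect_id {tid!r} not present in transect file"
            )
        try:
            counts.append(
                QuadratCount(
                    transect_id=tid,
                    quadrat_index=int(row.quadrat_index),
                    count=int(row.count),
                )
            )
        except ValidationError as err:
            raise ValidationError(f"{path}:{i}: {err}") from err
    return counts


def write_quadrats(counts: Sequence[QuadratCount], path) -> None:
    df = pd.DataFrame(
        [dataclasses.asdict(q) for q in counts], columns=_QUADRAT_COLUMNS
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# density-estimate results
# ---------------------------------------------------------------------------

_RESULT_COLUMNS = (
    "design",
    "D_hat",
    "se_D",
    "cv",
    "n",
    "Es_hat",
    "se_Es",
    "P_hat",
    "se_P",
    "var_n",
    "area_m2",
    "T",
    "prop_var_count",
    "prop_var_cluster_size",
    "prop_var_detection",
    "flags",
)


def write_results(estimates, path, metadata: dict | None = None) -> None:
    """Write density estimates to CSV with a JSON metadata sidecar.

    ``metadata`` (seed, configuration hash, provenance) is written to
    ``<path stem>.meta.json`` next to the results file.
    """
    rows = []
    for est in estimates:
        comp = est.components
        rows.append(
            {
                "design": est.design.value,
                "D_hat": est.D_hat,
                "se_D": est.se_D,
                "cv": est.cv,
                "n": est.n,
                "Es_hat": est.Es_hat,
                "se_Es": est.se_Es,
                "P_hat": est.P_hat,
                "se_P": est.se_P,
                "var_n": est.var_n,
                "area_m2": est.area_m2,
                "T": est.T,
                "prop_var_count": comp["count"],
                "prop_var_cluster_size": comp["cluster_size"],
                "prop_var_detection": comp["detection"],
                "flags": ";".join(est.flags),
            }
        )
    df = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    df.to_csv(path, index=False)
    meta_path = Path(path).with_suffix("").with_suffix(".meta.json")
    with open(meta_path, "w") as fh:
        json.dump(metadata or {}, fh, indent=2, default=str)
        fh.write("\n")


def read_results(path):
    """Read back a results file written by :func:`write_results`."""
    from .density import DensityEstimate  # local import to avoid a cycle

    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    estimates = []
    for row in df.itertuples(index=False):
        raw_flags = row.flags if isinstance(row.flags, str) else ""
        flags = tuple(raw_flags.split(";")) if raw_flags else ()
        estimates.append(
            DensityEstimate(
                design=Design(row.design),
                D_hat=float(row.D_hat),
                se_D=float(row.se_D),
                cv=float(row.cv),
                n=int(row.n),
                Es_hat=float(row.Es_hat),
                se_Es=float(row.se_Es),
                P_hat=float(row.P_hat),
                se_P=float(row.se_P),
                var_n=float(row.var_n),
                area_m2=float(row.area_m2),
                T=int(row.T),
                components={
                    "count": float(row.prop_var_count),
                    "cluster_size": float(row.prop_var_cluster_size),
                    "detection": float(row.prop_var_detection),
                },
                flags=flags,
            )
        )
    return estimates
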