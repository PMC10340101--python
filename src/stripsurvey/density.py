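"""Density estimation with a delta-method variance decomposition.

The estimator for strip designs is

    D_hat = n * Es_hat / (2 w * P_hat * L)

with *n* the total number of detected clusters over all transects,
``Es_hat`` the mean cluster size, *w* the strip half-width, *L* the
summed transect length and ``P_hat`` the average detection probability.
Quadrat surveys assume perfect detection and use the explicit sampled
area, ``D_hat = total count / total quadrat area``.

Its uncertainty follows the first-order (delta-method) decomposition

    Var(D_hat) ~= D_hat^2 * ( Var(n)/n^2
                            + Var(Es_hat)/Es_hat^2
                            + Var(P_hat)/P_hat^2 )

where Var(n) is the design-based, length-weighted encounter-rate
variance over transects.  The three relative-variance terms, divided by
their sum, are the "count", "cluster size" and "detection" shares of
the total variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .detection import DetectionFit
from .errors import ValidationError
from .survey_io import Design, DetectionEvent, QuadratCount, TransectRecord

__all__ = [
    "DensityEstimate",
    "mean_cluster_size",
    "encounter_variance",
    "estimate_density",
    "variance_components",
    "surveyed_area",
]


@dataclass(frozen=True)
class DensityEstimate:
    """Estimated density (individuals per m^2) with its variance budget."""

    design: Design
    D_hat: float
    se_D: float
    cv: float
    n: int
    Es_hat: float
    se_Es: float
    P_hat: float
    se_P: float
    var_n: float
    area_m2: float
    T: int
    components: dict[str, float]
    flags: tuple[str, ...] = field(default_factory=tuple)


def mean_cluster_size(sizes: Sequence[int]) -> tuple[float, float]:
    """Mean cluster size and its standard error.

    The plain sample mean with the usual standard error (sample standard
    deviation with n-1 denominator over sqrt(n)); zero when there is a
    single observation or all sizes are equal.
    """
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("mean_cluster_size requires at least one size")
    mean = float(np.mean(sizes))
    if sizes.size == 1:
        return mean, 0.0
    se = float(np.std(sizes, ddof=1) / math.sqrt(sizes.size))
    return mean, se


def encounter_variance(counts: Sequence[float], lengths: Sequence[float]) -> float:
    """Design-based, length-weighted variance of the total count.

        Var(n) = L/(T-1) * sum_i l_i * (n_i/l_i - n/L)^2

    with ``l_i`` the per-transect effort (length, or sampled quadrat
    area when quadrats are the sampling frames within a site).
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError("counts and lengths must have equal length")
    T = counts.size
    if T < 2:
        raise ValueError(
            "the encounter-rate variance is inestimable from a single "
            "transect (need T >= 2)"
        )
    if np.any(lengths <= 0):
        raise ValueError("all transect lengths must be > 0")
    L = float(np.sum(lengths))
    n = float(np.sum(counts))
    rates = counts / lengths
    return float(L / (T - 1) * np.sum(lengths * (rates - n / L) ** 2))


def surveyed_area(transects: Sequence[TransectRecord]) -> float:
    """Total surveyed area in m^2: ``2 w L`` for strip designs, summed
    ``n_quadrats * quadrat_area_m2`` for quadrat transects."""
    total = 0.0
    for t in transects:
        if t.design is Design.QUADRAT:
            total += t.n_quadrats * t.quadrat_area_m2
        else:
            total += 2.0 * t.half_width_m * t.length_m
    return total


def _single_design(transects: Sequence[TransectRecord]) -> Design:
    designs = {t.design for t in transects}
    if len(designs) != 1:
        raise ValidationError(
            f"mixed designs in one estimate: {sorted(d.value for d in designs)}"
        )
    return designs.pop()


def _relvar_terms(
    D: float, n: float, var_n: float, Es: float, se_Es: float,
    P: float, se_P: float,
) -> tuple[float, dict[str, float], tuple[str, ...]]:
    rv = {
        "count": var_n / n**2,
        "cluster_size": (se_Es / Es) ** 2,
        "detection": (se_P / P) ** 2 if math.isfinite(se_P) else float("nan"),
    }
    flags: tuple[str, ...] = ()
    if not math.isfinite(rv["detection"]):
        flags = ("se_P_unavailable",)
        rv["detection"] = float("nan")
    total = rv["count"] + rv["cluster_size"] + (
        rv["detection"] if math.isfinite(rv["detection"]) else 0.0
    )
    var_D = D**2 * total
    if total > 0:
        comp = {k: (v / total if math.isfinite(v) else float("nan"))
                for k, v in rv.items()}
    else:
        comp = {k: float("nan") for k in rv}
        flags = flags + ("zero_total_variance",)
    return var_D, comp, flags


def estimate_density(
    transects: Sequence[TransectRecord],
    data: Sequence[DetectionEvent] | Sequence[QuadratCount],
    fit: DetectionFit | None = None,
) -> DensityEstimate:
    """Estimate density from one design's transects and observations.

    For removal/distance designs ``data`` is the detection events and
    ``fit`` the fitted detection model.  For quadrat transects ``data``
    is the quadrat counts; detection is assumed perfect (``P_hat = 1``,
    ``se_P = 0``) and each site's sampled quadrat area serves as its
    effort weight in the encounter-rate variance.

    A survey with zero detections returns a flagged zero estimate (cv
    undefined) rather than raising, so low-density simulation sweeps can
    proceed.
    """
    if not transects:
        raise ValidationError("no transects supplied")
    design = _single_design(transects)
    ids = [t.transect_id for t in transects]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate transect_id in transect collection")

    if design is Design.QUADRAT:
        if fit is not None:
            raise ValidationError(
                "quadrat surveys assume perfect detection; no fit applies"
            )
        counts_by_tid = {tid: 0.0 for tid in ids}
        for q in data:
            if q.transect_id not in counts_by_tid:
                raise ValidationError(
                    f"quadrat count references unknown transect "
                    f"{q.transect_id!r}"
                )
            counts_by_tid[q.transect_id] += q.count
        efforts = [t.n_quadrats * t.quadrat_area_m2 for t in transects]
        counts = [counts_by_tid[tid] for tid in ids]
        n = int(sum(counts))
        area = float(sum(efforts))
        Es_hat, se_Es = 1.0, 0.0
        P_hat, se_P = 1.0, 0.0
        var_n = encounter_variance(counts, efforts) if len(ids) > 1 else 0.0
        D_hat = n / area
    else:
        if fit is None:
            raise ValidationError(
                f"{design.value} surveys require a detection fit"
            )
        widths = {t.half_width_m for t in transects}
        if len(widths) != 1:
            raise ValidationError(
                f"transects of one strip estimate must share a half-width, "
                f"got {sorted(widths)}"
            )
        w = widths.pop()
        counts_by_tid = {tid: 0.0 for tid in ids}
        sizes = []
        for e in data:
            if e.transect_id not in counts_by_tid:
                raise ValidationError(
                    f"event references unknown transect {e.transect_id!r}"
                )
            counts_by_tid[e.transect_id] += 1
            sizes.append(e.cluster_size)
        lengths = [t.length_m for t in transects]
        counts = [counts_by_tid[tid] for tid in ids]
        n = int(sum(counts))
        L = float(sum(lengths))
        area = 2.0 * w * L
        P_hat, se_P = fit.P_hat, fit.se_P
        var_n = encounter_variance(counts, lengths) if len(ids) > 1 else 0.0
        if n > 0:
            Es_hat, se_Es = mean_cluster_size(sizes)
        else:
            Es_hat, se_Es = 1.0, 0.0
        D_hat = n * Es_hat / (area * P_hat)

    T = len(ids)
    if n == 0:
        return DensityEstimate(
            design=design, D_hat=0.0, se_D=float("nan"), cv=float("nan"),
            n=0, Es_hat=Es_hat, se_Es=se_Es, P_hat=P_hat, se_P=se_P,
            var_n=var_n, area_m2=area, T=T,
            components={k: float("nan") for k in ("count", "cluster_size", "detection")},
            flags=("no_detections",),
        )
    var_D, comp, flags = _relvar_terms(D_hat, n, var_n, Es_hat, se_Es, P_hat, se_P)
    se_D = math.sqrt(var_D)
    cv = se_D / D_hat
    return DensityEstimate(
        design=design, D_hat=D_hat, se_D=se_D, cv=cv, n=n,
        Es_hat=Es_hat, se_Es=se_Es, P_hat=P_hat, se_P=se_P,
        var_n=var_n, area_m2=area, T=T, components=comp, flags=flags,
    )


def variance_components(estimate: DensityEstimate) -> dict[str, float]:
    """Proportions of Var(D_hat) attributable to counts, cluster size
    and detection under the delta approximation (each relative-variance
    term divided by their sum)."""
    if not (estimate.D_hat > 0):
        raise ValueError("variance components require D_hat > 0")
    _, comp, _ = _relvar_terms(
        estimate.D_hat, estimate.n, estimate.var_n,
        estimate.Es_hat, estimate.se_Es, estimate.P_hat, estimate.se_P,
    )
    return comp
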