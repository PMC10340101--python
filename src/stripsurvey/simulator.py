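"""Synthetic shoreline strips and virtual execution of the three survey
protocols.

The generator emulates the field system: mussel clusters (druses) are
points with integer sizes scattered in a rectangular shoreline strip —
either a homogeneous Poisson process or a Thomas cluster process whose
parents represent patches of hard substrate.  Transects run
perpendicular to shore (the x axis) at fixed spacing; each virtual
protocol then surveys the same realised population:

* quadrat — two parallel lines 1 m apart per site, a 0.5 m x 0.5 m
  quadrat every 2 m along each line starting at 0 m, perfect detection;
* removal — a 1-m-wide strip (half-width 0.5 m) searched by two
  observers in sequence, constant per-observer detection probability;
* distance — a strip up to 1 m either side of a single line, detection
  declining with perpendicular distance by a half-normal curve that is
  imperfect on the line, two observers in sequence, distances recorded.

A druse is one detection unit at one location; within-druse positions
are not modelled.  Reproducibility: every random stream is a
``numpy.random.Generator`` seeded as ``default_rng([seed, replicate,
stream])``, so any replicate can be regenerated in isolation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .density import estimate_density
from .detection import fit_distance_removal, fit_removal_fi
from .errors import FitError, ValidationError
from .survey_io import (
    Design,
    DetectionEvent,
    History,
    QuadratCount,
    TransectRecord,
)

__all__ = [
    "ClusterSizeLaw",
    "FixedOne",
    "ZeroTruncatedPoisson",
    "ZeroTruncatedNegBin",
    "SimScenario",
    "SyntheticLake",
    "simulate_population",
    "simulate_quadrat_survey",
    "simulate_removal_survey",
    "simulate_distance_survey",
    "recovery_experiment",
    "summarize_recovery",
    "florida_like",
    "burgan_like",
    "little_birch_like",
    "scenario_from_dict",
    "scenario_to_dict",
]


# ---------------------------------------------------------------------------
# cluster-size laws
# ---------------------------------------------------------------------------

class ClusterSizeLaw:
    """Distribution of the number of individuals per druse (support >= 1)."""

    name: str

    @property
    def mean(self) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        raise NotImplementedError


@dataclass(frozen=True)
class FixedOne(ClusterSizeLaw):
    """Every druse is a single individual (pioneer populations)."""

    name: str = field(default="fixed_one", init=False)

    @property
    def mean(self) -> float:
        return 1.0

    def sample(self, rng, size):
        return np.ones(size, dtype=int)


def _resample_zeros(draw, rng, size):
    """Draw from a nonnegative law conditioned on being positive."""
    out = draw(rng, size)
    zeros = out == 0
    while np.any(zeros):
        out[zeros] = draw(rng, int(zeros.sum()))
        zeros = out == 0
    return out


@dataclass(frozen=True)
class ZeroTruncatedPoisson(ClusterSizeLaw):
    """Poisson(lam) conditioned on being >= 1.

    ``lam`` is the untruncated rate; the truncated mean is
    ``lam / (1 - exp(-lam))`` in closed form.
    """

    lam: float
    name: str = field(default="zero_truncated_poisson", init=False)

    def __post_init__(self):
        if not (self.lam > 0):
            raise ValidationError(f"lam must be > 0, got {self.lam}")

    @property
    def mean(self) -> float:
        return self.lam / (1.0 - math.exp(-self.lam))

    def sample(self, rng, size):
        return _resample_zeros(
            lambda r, m: r.poisson(self.lam, m), rng, size
        ).astype(int)


@dataclass(frozen=True)
class ZeroTruncatedNegBin(ClusterSizeLaw):
    """Negative binomial (mean ``mu``, dispersion ``k``) conditioned on >= 1.

    Smaller ``k`` gives a heavier tail.  With zero-probability
    ``P0 = (k / (k + mu))^k``, the truncated mean is ``mu / (1 - P0)``.
    """

    mu: float
    k: float
    name: str = field(default="zero_truncated_negbin", init=False)

    def __post_init__(self):
        if not (self.mu > 0 and self.k > 0):
            raise ValidationError(
                f"mu and k must be > 0, got mu={self.mu}, k={self.k}"
            )

    @property
    def _p0(self) -> float:
        return (self.k / (self.k + self.mu)) ** self.k

    @property
    def mean(self) -> float:
        return self.mu / (1.0 - self._p0)

    def sample(self, rng, size):
        p = self.k / (self.k + self.mu)
        return _resample_zeros(
            lambda r, m: r.negative_binomial(self.k, p, m), rng, size
        ).astype(int)


# ---------------------------------------------------------------------------
# scenario
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimScenario:
    """Generative parameters for one synthetic lake and its survey layout.

    Spatial law: either ``druse_intensity`` (homogeneous Poisson,
    druses per m^2) or the Thomas-process triple ``parent_intensity``
    (substrate patches per m^2), ``mean_offspring`` (mean druses per
    patch) and ``dispersal_sd`` (Gaussian scatter, m).

    Layout: ``n_transects`` sites spaced ``transect_spacing_m`` apart
    along shore; per-design transect lengths may differ (surveys run on
    different days may stop at different depths).  The strip spans
    ``x in [0, n_transects * spacing]`` alongshore and
    ``y in [0, max(lengths)]`` offshore.
    """

    # spatial process (exactly one of the two parameterisations)
    druse_intensity: float | None = None
    parent_intensity: float | None = None
    mean_offspring: float | None = None
    dispersal_sd: float | None = None
    # cluster sizes
    cluster_size_law: ClusterSizeLaw = FixedOne()
    # layout
    n_transects: int = 15
    transect_spacing_m: float = 20.0
    quadrat_length_m: float = 30.0
    removal_length_m: float = 30.0
    distance_length_m: float = 30.0
    quadrat_every_m: float = 2.0
    quadrat_side_m: float = 0.5
    removal_half_width_m: float = 0.5
    distance_half_width_m: float = 1.0
    # observers
    removal_p: float = 0.9
    distance_p0: float = 0.75
    distance_sigma: float = 0.42
    # sensitivity switches (off by default)
    quadrat_miscount_sd: float = 0.0
    size_detection_exponent: float = 0.0
    # provenance
    seed: int = 0
    label: str = "scenario"

    def __post_init__(self):
        poisson_mode = self.druse_intensity is not None
        thomas_mode = self.parent_intensity is not None
        if poisson_mode == thomas_mode:
            raise ValidationError(
                "specify exactly one of druse_intensity or "
                "(parent_intensity, mean_offspring, dispersal_sd)"
            )
        if thomas_mode and (
            self.mean_offspring is None or self.dispersal_sd is None
        ):
            raise ValidationError(
                "Thomas mode requires parent_intensity, mean_offspring and "
                "dispersal_sd"
            )
        for name in ("removal_p", "distance_p0"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        for name in (
            "distance_sigma", "transect_spacing_m", "quadrat_every_m",
            "quadrat_side_m", "removal_half_width_m", "distance_half_width_m",
            "quadrat_length_m", "removal_length_m", "distance_length_m",
        ):
            if not (getattr(self, name) > 0):
                raise ValidationError(
                    f"{name} must be > 0, got {getattr(self, name)}"
                )
        if self.n_transects < 1:
            raise ValidationError("n_transects must be >= 1")
        if poisson_mode and self.druse_intensity < 0:
            raise ValidationError("druse_intensity must be >= 0")

    # --- derived geometry -------------------------------------------------
    @property
    def strip_length_m(self) -> float:
        return self.n_transects * self.transect_spacing_m

    @property
    def strip_width_m(self) -> float:
        return max(
            self.quadrat_length_m, self.removal_length_m, self.distance_length_m
        )

    @property
    def strip_area_m2(self) -> float:
        return self.strip_length_m * self.strip_width_m

    def transect_centers(self) -> np.ndarray:
        s = self.transect_spacing_m
        return s / 2.0 + s * np.arange(self.n_transects)

    # --- derived intensities ----------------------------------------------
    @property
    def effective_druse_intensity(self) -> float:
        if self.druse_intensity is not None:
            return self.druse_intensity
        return self.parent_intensity * self.mean_offspring

    @property
    def true_density(self) -> float:
        """True individual density D (individuals per m^2), in closed form."""
        return self.effective_druse_intensity * self.cluster_size_law.mean


@dataclass(frozen=True)
class SyntheticLake:
    """One realised druse pattern: coordinates (m), sizes, and totals."""

    x: np.ndarray
    y: np.ndarray
    sizes: np.ndarray
    scenario: SimScenario

    @property
    def n_druses(self) -> int:
        return int(self.x.size)

    @property
    def n_individuals(self) -> int:
        return int(self.sizes.sum())


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def simulate_population(
    scenario: SimScenario, seed=None, rng: np.random.Generator | None = None
) -> SyntheticLake:
    """Realise the druse point pattern and cluster sizes.

    Thomas mode generates parents in a strip buffered by five dispersal
    standard deviations so the pattern is homogeneous inside the strip;
    offspring falling outside the strip are discarded.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed if seed is None else seed)
    Lx, Ly = scenario.strip_length_m, scenario.strip_width_m
    expected = scenario.effective_druse_intensity * Lx * Ly
    if expected > 1e7:
        raise ValidationError(
            f"expected druse count {expected:.3g} exceeds 1e7; lower the "
            "intensity or shrink the strip"
        )
    if scenario.druse_intensity is not None:
        n = rng.poisson(scenario.druse_intensity * Lx * Ly)
        x = rng.uniform(0.0, Lx, n)
        y = rng.uniform(0.0, Ly, n)
    else:
        buf = 5.0 * scenario.dispersal_sd
        area = (Lx + 2 * buf) * (Ly + 2 * buf)
        n_par = rng.poisson(scenario.parent_intensity * area)
        px = rng.uniform(-buf, Lx + buf, n_par)
        py = rng.uniform(-buf, Ly + buf, n_par)
        counts = rng.poisson(scenario.mean_offspring, n_par)
        x = np.repeat(px, counts) + rng.normal(
            0.0, scenario.dispersal_sd, int(counts.sum())
        )
        y = np.repeat(py, counts) + rng.normal(
            0.0, scenario.dispersal_sd, int(counts.sum())
        )
        inside = (x >= 0) & (x <= Lx) & (y >= 0) & (y <= Ly)
        x, y = x[inside], y[inside]
    sizes = scenario.cluster_size_law.sample(rng, x.size)
    return SyntheticLake(x=x, y=y, sizes=sizes, scenario=scenario)


# ---------------------------------------------------------------------------
# virtual surveys
# ---------------------------------------------------------------------------

def _transect_ids(scenario, prefix):
    return [f"{prefix}{i + 1:02d}" for i in range(scenario.n_transects)]


def simulate_quadrat_survey(
    lake: SyntheticLake,
    rng: np.random.Generator | None = None,
    lake_label: str | None = None,
) -> tuple[list[QuadratCount], list[TransectRecord]]:
    """Count individuals in 0.5 x 0.5 m quadrats every 2 m along two
    parallel lines 1 m apart per site (a full 30-m transect gives 30
    counts).  Detection is perfect unless the scenario's optional
    per-quadrat miscount noise is switched on."""
    sc = lake.scenario
    label = lake_label or sc.label
    if rng is None:
        rng = np.random.default_rng(sc.seed)
    half_gap = 0.5  # lines 1 m apart, centred on the site
    side = sc.quadrat_side_m
    marks = np.arange(0.0, sc.quadrat_length_m, sc.quadrat_every_m)
    marks = marks[marks + side <= sc.quadrat_length_m + 1e-9]
    counts: list[QuadratCount] = []
    transects: list[TransectRecord] = []
    ids = _transect_ids(sc, "q")
    for tid, xc in zip(ids, sc.transect_centers()):
        qidx = 0
        for line_x in (xc - half_gap, xc + half_gap):
            for y0 in marks:
                inside = (
                    (lake.x >= line_x - side / 2)
                    & (lake.x <= line_x + side / 2)
                    & (lake.y >= y0)
                    & (lake.y <= y0 + side)
                )
                c = int(lake.sizes[inside].sum())
                if sc.quadrat_miscount_sd > 0:
                    c = max(0, c + int(round(rng.normal(0, sc.quadrat_miscount_sd))))
                counts.append(QuadratCount(tid, qidx, c))
                qidx += 1
        transects.append(
            TransectRecord(
                transect_id=tid,
                lake=label,
                design=Design.QUADRAT,
                length_m=sc.quadrat_length_m,
                n_quadrats=qidx,
                quadrat_area_m2=side * side,
            )
        )
    return counts, transects


def _two_pass_detection(g, rng):
    """Full-independence two-pass detection given per-druse probability g.

    Returns (detected mask, first-observer mask among detected order).
    """
    u1 = rng.uniform(size=g.shape)
    u2 = rng.uniform(size=g.shape)
    first = u1 < g
    second = ~first & (u2 < g)
    return first | second, first


def _size_adjusted(g, sizes, beta):
    if beta == 0.0:
        return g
    return np.minimum(1.0, g * sizes.astype(float) ** beta)


def simulate_removal_survey(
    lake: SyntheticLake,
    rng: np.random.Generator | None = None,
    lake_label: str | None = None,
) -> tuple[list[DetectionEvent], list[TransectRecord]]:
    """Two-observer removal pass over 1-m-wide strips: the first
    observer detects each in-strip druse with probability p, the second
    observer searches the misses with the same p."""
    sc = lake.scenario
    label = lake_label or sc.label
    if rng is None:
        rng = np.random.default_rng(sc.seed)
    hw = sc.removal_half_width_m
    events: list[DetectionEvent] = []
    transects: list[TransectRecord] = []
    ids = _transect_ids(sc, "r")
    for tid, xc in zip(ids, sc.transect_centers()):
        inside = (np.abs(lake.x - xc) <= hw) & (lake.y <= sc.removal_length_m)
        sizes = lake.sizes[inside]
        g = _size_adjusted(
            np.full(sizes.shape, sc.removal_p), sizes, sc.size_detection_exponent
        )
        detected, first = _two_pass_detection(g, rng)
        for det, fst, s in zip(detected, first, sizes):
            if det:
                events.append(
                    DetectionEvent(
                        transect_id=tid,
                        history=History.FIRST_OBSERVER
                        if fst
                        else History.SECOND_OBSERVER_ONLY,
                        cluster_size=int(s),
                    )
                )
        transects.append(
            TransectRecord(
                transect_id=tid,
                lake=label,
                design=Design.REMOVAL,
                length_m=sc.removal_length_m,
                half_width_m=hw,
            )
        )
    return events, transects


def simulate_distance_survey(
    lake: SyntheticLake,
    rng: np.random.Generator | None = None,
    lake_label: str | None = None,
) -> tuple[list[DetectionEvent], list[TransectRecord]]:
    """Two-observer distance survey up to 1 m either side of the line;
    per-observer detection follows the half-normal curve in the
    perpendicular distance, which is recorded for every event."""
    sc = lake.scenario
    label = lake_label or sc.label
    if rng is None:
        rng = np.random.default_rng(sc.seed)
    hw = sc.distance_half_width_m
    events: list[DetectionEvent] = []
    transects: list[TransectRecord] = []
    ids = _transect_ids(sc, "d")
    for tid, xc in zip(ids, sc.transect_centers()):
        inside = (np.abs(lake.x - xc) <= hw) & (lake.y <= sc.distance_length_m)
        dist = np.abs(lake.x[inside] - xc)
        sizes = lake.sizes[inside]
        g = sc.distance_p0 * np.exp(-(dist**2) / (2.0 * sc.distance_sigma**2))
        g = _size_adjusted(g, sizes, sc.size_detection_exponent)
        detected, first = _two_pass_detection(g, rng)
        for det, fst, s, d in zip(detected, first, sizes, dist):
            if det:
                events.append(
                    DetectionEvent(
                        transect_id=tid,
                        history=History.FIRST_OBSERVER
                        if fst
                        else History.SECOND_OBSERVER_ONLY,
                        cluster_size=int(s),
                        distance_m=float(d),
                    )
                )
        transects.append(
            TransectRecord(
                transect_id=tid,
                lake=label,
                design=Design.DISTANCE,
                length_m=sc.distance_length_m,
                half_width_m=hw,
            )
        )
    return events, transects


# ---------------------------------------------------------------------------
# replicated recovery experiments
# ---------------------------------------------------------------------------

_DESIGNS = ("quadrat", "removal", "distance")


def _estimate_one(design: str, lake: SyntheticLake, rng):
    if design == "quadrat":
        counts, transects = simulate_quadrat_survey(lake, rng=rng)
        return estimate_density(transects, counts)
    if design == "removal":
        events, transects = simulate_removal_survey(lake, rng=rng)
        fit = fit_removal_fi(events)
        return estimate_density(transects, events, fit)
    events, transects = simulate_distance_survey(lake, rng=rng)
    fit = fit_distance_removal(events, lake.scenario.distance_half_width_m)
    return estimate_density(transects, events, fit)


def recovery_experiment(
    scenario: SimScenario,
    replicates: int,
    seed: int,
    designs: Sequence[str] = _DESIGNS,
) -> pd.DataFrame:
    """Run all three protocols on ``replicates`` independent synthetic
    lakes and return a tidy per-replicate table.

    Each replicate draws one population (stream ``[seed, rep, 0]``) that
    all designs survey, with design-specific observer streams
    ``[seed, rep, 1 + design_index]``; any replicate is therefore
    reproducible in isolation.  Replicates whose fit fails are recorded
    with the failure reason rather than aborting the sweep.
    """
    if replicates < 2:
        raise ValidationError("recovery_experiment needs replicates >= 2")
    unknown = set(designs) - set(_DESIGNS)
    if unknown:
        raise ValidationError(f"unknown designs: {sorted(unknown)}")
    rows = []
    for rep in range(replicates):
        lake = simulate_population(
            scenario, rng=np.random.default_rng([seed, rep, 0])
        )
        for d_idx, design in enumerate(_DESIGNS):
            if design not in designs:
                continue
            rng = np.random.default_rng([seed, rep, 1 + d_idx])
            row = {
                "replicate": rep,
                "design": design,
                "D_true": scenario.true_density,
                "D_hat": np.nan,
                "se_D": np.nan,
                "cv": np.nan,
                "n": np.nan,
                "P_hat": np.nan,
                "se_P": np.nan,
                "error": "",
            }
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    est = _estimate_one(design, lake, rng)
                row.update(
                    D_hat=est.D_hat, se_D=est.se_D, cv=est.cv, n=est.n,
                    P_hat=est.P_hat, se_P=est.se_P,
                )
            except (FitError, ValidationError, ValueError) as err:
                row["error"] = f"{type(err).__name__}: {err}"
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_recovery(table: pd.DataFrame) -> pd.DataFrame:
    """Per-design summary of a recovery experiment.

    Columns: replicate counts, mean estimate, relative bias with its
    Monte-Carlo standard error, empirical CV (SD over mean of the
    estimates), mean estimated CV, and coverage of D_true by
    ``D_hat +/- 2 se_D``.
    """
    out = []
    for design, grp in table.groupby("design", sort=False):
        ok = grp[grp["error"] == ""].copy()
        d_true = float(grp["D_true"].iloc[0])
        d = ok["D_hat"].to_numpy(float)
        se = ok["se_D"].to_numpy(float)
        mean_d = float(np.mean(d)) if d.size else np.nan
        mc_se = float(np.std(d, ddof=1) / math.sqrt(d.size)) if d.size > 1 else np.nan
        with_se = np.isfinite(se)
        covered = np.abs(d[with_se] - d_true) <= 2.0 * se[with_se]
        out.append(
            {
                "design": design,
                "replicates": int(len(grp)),
                "failed": int((grp["error"] != "").sum()),
                "D_true": d_true,
                "mean_D_hat": mean_d,
                "rel_bias": mean_d / d_true - 1.0 if d_true > 0 else np.nan,
                "mc_se_rel": mc_se / d_true if d_true > 0 else np.nan,
                "empirical_cv": float(np.std(d, ddof=1) / mean_d)
                if d.size > 1 and mean_d > 0
                else np.nan,
                "mean_estimated_cv": float(np.nanmean(ok["cv"].to_numpy(float)))
                if len(ok)
                else np.nan,
                "coverage_2se": float(np.mean(covered)) if covered.size else np.nan,
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# scenario presets (three-lake synthetic study)
# ---------------------------------------------------------------------------
#
# The presets follow the full 15-site field protocol and are calibrated
# to the published per-lake totals (surveyed areas, detection counts,
# mean cluster sizes, and detection-probability ranges); the spatial
# clustering parameters, which the field study did not measure, are
# chosen to be ecologically plausible for patchy hard substrate.
# docs/methods.md walks through the calibration.


def florida_like(**overrides) -> SimScenario:
    """Low-density pioneer lake: sparse singleton druses, no patchiness."""
    params = dict(
        label="florida_like",
        druse_intensity=0.07,
        cluster_size_law=FixedOne(),
        n_transects=15,
        quadrat_length_m=30.0,
        removal_length_m=30.0,
        distance_length_m=30.0,
        removal_p=0.90,
        distance_p0=0.90,
        distance_sigma=0.38,
    )
    params.update(overrides)
    return SimScenario(**params)


def burgan_like(**overrides) -> SimScenario:
    """Intermediate-density lake: mild substrate patchiness, small clusters."""
    params = dict(
        label="burgan_like",
        parent_intensity=0.012,
        mean_offspring=20.0,
        dispersal_sd=2.5,
        cluster_size_law=ZeroTruncatedPoisson(lam=0.4),
        n_transects=15,
        quadrat_length_m=19.0,
        removal_length_m=18.5,
        distance_length_m=20.0,
        removal_p=0.93,
        distance_p0=0.90,
        distance_sigma=0.38,
    )
    params.update(overrides)
    return SimScenario(**params)


def little_birch_like(**overrides) -> SimScenario:
    """High-density lake: strong substrate patchiness, heavy-tailed sizes."""
    params = dict(
        label="little_birch_like",
        parent_intensity=4.8 / 450.0,
        mean_offspring=450.0,
        dispersal_sd=2.5,
        cluster_size_law=ZeroTruncatedNegBin(mu=3.0, k=0.3),
        n_transects=15,
        quadrat_length_m=21.0,
        removal_length_m=21.0,
        distance_length_m=15.5,
        removal_p=0.92,
        distance_p0=0.95,
        distance_sigma=0.25,
    )
    params.update(overrides)
    return SimScenario(**params)


PRESETS = {
    "florida_like": florida_like,
    "burgan_like": burgan_like,
    "little_birch_like": little_birch_like,
}


# ---------------------------------------------------------------------------
# (de)serialisation for YAML configs
# ---------------------------------------------------------------------------

_LAW_BUILDERS = {
    "fixed_one": lambda d: FixedOne(),
    "zero_truncated_poisson": lambda d: ZeroTruncatedPoisson(lam=float(d["lam"])),
    "zero_truncated_negbin": lambda d: ZeroTruncatedNegBin(
        mu=float(d["mu"]), k=float(d["k"])
    ),
}


def scenario_from_dict(d: dict) -> SimScenario:
    """Build a scenario from a plain dict (e.g. parsed YAML).

    Either a ``preset`` key naming one of the built-in scenarios (other
    keys override its fields), or the full set of SimScenario fields
    with ``cluster_size_law`` as a nested mapping with a ``law`` key.
    """
    d = dict(d)
    preset = d.pop("preset", None)
    if "cluster_size_law" in d and isinstance(d["cluster_size_law"], dict):
        law_spec = dict(d["cluster_size_law"])
        law_name = law_spec.pop("law", None)
        if law_name not in _LAW_BUILDERS:
            raise ValidationError(
                f"unknown cluster_size_law {law_name!r}; expected one of "
                f"{sorted(_LAW_BUILDERS)}"
            )
        try:
            d["cluster_size_law"] = _LAW_BUILDERS[law_name](law_spec)
        except KeyError as err:
            raise ValidationError(
                f"cluster_size_law {law_name!r} missing parameter {err}"
            ) from err
    valid = set(SimScenario.__dataclass_fields__)
    unknown = set(d) - valid
    if unknown:
        raise ValidationError(
            f"unknown scenario fields: {sorted(unknown)}; valid fields are "
            f"{sorted(valid)}"
        )
    if preset is not None:
        if preset not in PRESETS:
            raise ValidationError(
                f"unknown preset {preset!r}; expected one of {sorted(PRESETS)}"
            )
        return PRESETS[preset](**d)
    return SimScenario(**d)


def scenario_to_dict(sc: SimScenario) -> dict:
    d = {
        k: getattr(sc, k)
        for k in SimScenario.__dataclass_fields__
        if k != "cluster_size_law" and getattr(sc, k) is not None
    }
    law = sc.cluster_size_law
    spec = {"law": law.name}
    for attr in ("lam", "mu", "k"):
        if hasattr(law, attr):
            spec[attr] = getattr(law, attr)
    d["cluster_size_law"] = spec
    return d
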