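"""Synthetic virtual cohorts with the study's structure.

The generator reproduces the composition of the reference cohort — 72
sidewall aneurysms, 41 ruptured and 31 unruptured, each stratified into
narrow-necked (aspect ratio >= 1.4) and wide-necked (AR < 1.4 or neck
>= 4 mm) — in two modes:

* **metric mode** — per-group hemodynamic metrics are drawn directly from
  group-calibrated distributions.  Metrics reported as mean +/- SD use a
  normal truncated at zero; metrics reported as median and quartiles use a
  log-normal matched to those order statistics (respecting the reported
  normality dichotomy).  The aneurysm-to-parent ratios are always derived
  from the sampled MWSS/HWSS/PWSS, never sampled independently, so every
  record satisfies the metric invariants.  The default calibration encodes
  the four published group summaries (narrow ruptured/unruptured, wide
  ruptured/unruptured).
* **geometry mode** — sac shape parameters are drawn per stratum and
  rejected until the constructed geometry classifies into its intended
  stratum; records are completed by running the flow solver
  (:func:`run_cohort_cfd`).

A single seed fans out to independent per-record substreams
(`numpy.random.SeedSequence.spawn`), so cohorts are reproducible even if
records are generated in parallel or out of order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import (
    AneurysmGeometry,
    MorphologyMeasures,
    NeckCategory,
    ParameterError,
    classify_neck,
    make_geometry,
)
from .meshing import build_mesh
from .solver import FlowConditions, Numerics, SolverError, simulate_pulsatile
from .wss import HemodynamicMetrics, compute_metrics, time_average_wss, wall_shear_series

__all__ = [
    "GROUPS",
    "MetricSpec",
    "GroupMetricSpec",
    "GeometryStratumSpec",
    "CohortConfig",
    "CohortRecord",
    "ConfigError",
    "default_metric_calibration",
    "default_geometry_strata",
    "sample_metric_cohort",
    "sample_geometry_cohort",
    "run_cohort_cfd",
    "cohort_to_frame",
]

#: the four analysis groups: (rupture label, neck category)
GROUPS = (
    ("ruptured", "narrow"),
    ("unruptured", "narrow"),
    ("ruptured", "wide"),
    ("unruptured", "wide"),
)

_Z_Q = 0.6744897501960817  # standard normal upper quartile


class ConfigError(ValueError):
    """Inconsistent or infeasible cohort configuration."""


@dataclass(frozen=True)
class MetricSpec:
    """Distribution of one metric in one group.

    ``family`` is ``"truncnorm"`` (location/scale = mean/SD of the
    untruncated normal, truncated at ``lower``) or ``"lognormal"``
    (location = median, scale = the published single 'quartiles' number,
    read as the IQR by default or as Q3 via ``quartile_kind``).
    """

    family: str
    location: float
    scale: float
    lower: float = 0.0
    upper: float = math.inf
    quartile_kind: str = "iqr"  # or "q3"

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ConfigError(f"scale must be > 0 (got {self.scale})")
        if self.family not in ("truncnorm", "lognormal"):
            raise ConfigError(f"unknown distribution family {self.family!r}")
        if self.quartile_kind not in ("iqr", "q3"):
            raise ConfigError(f"quartile_kind must be 'iqr' or 'q3'")

    def _frozen(self):
        if self.family == "truncnorm":
            a = (self.lower - self.location) / self.scale
            b = (self.upper - self.location) / self.scale
            return stats.truncnorm(a, b, loc=self.location, scale=self.scale)
        mu = math.log(self.location)
        if self.quartile_kind == "iqr":
            # Q3 - Q1 = 2 * median * sinh(z * sigma)
            sigma = math.asinh(self.scale / (2.0 * self.location)) / _Z_Q
        else:
            sigma = math.log(self.scale / self.location) / _Z_Q
        if sigma <= 0:
            raise ConfigError("log-normal scale must imply sigma > 0")
        return stats.lognorm(s=sigma, scale=math.exp(mu))

    def mean(self) -> float:
        return float(self._frozen().mean())

    def sample(self, rng: np.random.Generator, size: int | None = None):
        d = self._frozen()
        x = d.ppf(rng.uniform(size=size))
        return np.clip(x, self.lower, self.upper)


@dataclass(frozen=True)
class GroupMetricSpec:
    """Distributions of MWSS, HWSS, PWSS and LSAR in one group."""

    mwss: MetricSpec
    hwss: MetricSpec
    pwss: MetricSpec
    lsar: MetricSpec

    def __post_init__(self) -> None:
        if self.hwss.location < self.mwss.location:
            raise ConfigError("HWSS location below MWSS location is inconsistent")


def default_metric_calibration(quartile_kind: str = "iqr") -> dict[tuple[str, str], GroupMetricSpec]:
    """Per-group metric distributions calibrated to the published group
    summaries (mean +/- SD -> truncated normal; median & quartiles ->
    log-normal)."""
    tn = lambda m, s: MetricSpec("truncnorm", m, s)
    tn01 = lambda m, s: MetricSpec("truncnorm", m, s, upper=1.0)
    ln = lambda med, q: MetricSpec("lognormal", med, q, quartile_kind=quartile_kind)
    return {
        ("ruptured", "narrow"): GroupMetricSpec(
            mwss=tn(1.96, 1.30), hwss=tn(9.08, 6.64),
            pwss=tn(7.85, 3.98), lsar=tn01(0.340, 0.308),
        ),
        ("unruptured", "narrow"): GroupMetricSpec(
            mwss=tn(3.33, 1.45), hwss=tn(8.19, 3.69),
            pwss=tn(7.14, 3.08), lsar=tn01(0.093, 0.125),
        ),
        ("ruptured", "wide"): GroupMetricSpec(
            mwss=ln(4.04, 5.24), hwss=tn(14.58, 10.93),
            pwss=tn(8.94, 6.13), lsar=tn01(0.075, 0.082),
        ),
        ("unruptured", "wide"): GroupMetricSpec(
            mwss=ln(4.44, 2.96), hwss=tn(9.95, 3.73),
            pwss=tn(7.73, 2.53), lsar=tn01(0.026, 0.032),
        ),
    }


@dataclass(frozen=True)
class GeometryStratumSpec:
    """Parameter ranges for one stratum's sac shapes (uniform draws, mm)."""

    shape_family: str
    sac_size: tuple[float, float]
    neck_width: tuple[float, float] | None = None
    sac_offset: tuple[float, float] = (0.0, 0.0)


def default_geometry_strata() -> dict[str, GeometryStratumSpec]:
    """Deep constricted-neck flasks for the narrow stratum, shallow
    hemispherical bumps for the wide one; both at calibers where the sac
    fits a desk-scale channel."""
    return {
        "narrow": GeometryStratumSpec(
            shape_family="circular-sac-with-neck",
            sac_size=(1.6, 2.6),
            neck_width=(1.6, 2.4),
            sac_offset=(1.2, 2.6),
        ),
        "wide": GeometryStratumSpec(
            shape_family="hemispherical-bump",
            sac_size=(1.4, 2.6),
        ),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Composition, mode and distributions of one synthetic cohort.

    Defaults mirror the reference cohort: 41 ruptured and 31 unruptured
    aneurysms, half of each label narrow-necked (rounded down for the
    ruptured label).
    """

    n_ruptured: int = 41
    n_unruptured: int = 31
    narrow_fraction_ruptured: float = 0.5
    narrow_fraction_unruptured: float = 0.5
    seed: int = 0
    mode: str = "metric"
    metric_specs: dict | None = None  # (label, category) -> GroupMetricSpec
    geometry_strata: dict | None = None  # category -> GeometryStratumSpec
    parent_caliber: float = 3.24  # mm
    quartile_kind: str = "iqr"

    def __post_init__(self) -> None:
        if self.n_ruptured <= 0 or self.n_unruptured <= 0:
            raise ConfigError("group counts must be > 0")
        if self.mode not in ("metric", "geometry"):
            raise ConfigError(f"unknown cohort mode {self.mode!r}")
        for f in (self.narrow_fraction_ruptured, self.narrow_fraction_unruptured):
            if not 0.0 <= f <= 1.0:
                raise ConfigError("narrow fractions must lie in [0, 1]")

    def group_sizes(self) -> dict[tuple[str, str], int]:
        nrn = int(round(self.n_ruptured * self.narrow_fraction_ruptured))
        nun = int(round(self.n_unruptured * self.narrow_fraction_unruptured))
        return {
            ("ruptured", "narrow"): nrn,
            ("ruptured", "wide"): self.n_ruptured - nrn,
            ("unruptured", "narrow"): nun,
            ("unruptured", "wide"): self.n_unruptured - nun,
        }


@dataclass(frozen=True)
class CohortRecord:
    """One synthetic aneurysm: label, morphology, metrics, group."""

    id: str
    rupture_label: str
    morphology: MorphologyMeasures
    metrics: HemodynamicMetrics
    group: tuple[str, str]

    def __post_init__(self) -> None:
        cat = self.morphology.neck_category.value
        if self.group != (self.rupture_label, cat):
            raise ValueError("group inconsistent with label and neck category")


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def _sample_morphology(rng: np.random.Generator, category: str) -> MorphologyMeasures:
    """Morphology consistent with the stratum (heights 2.5–15.7 mm, AR
    0.49–3.10, the published cohort ranges)."""
    if category == "narrow":
        # clip strictly inside the stratum so height/neck roundoff cannot
        # drop the recomputed ratio below the 1.4 cutoff
        ar = float(np.clip(rng.normal(1.9, 0.4), 1.4 + 1e-6, 3.10))
        neck = float(rng.uniform(1.5, 3.9))
    else:
        ar = float(np.clip(rng.normal(1.0, 0.3), 0.49, 1.4 - 1e-9))
        neck = float(rng.uniform(2.0, 6.0))
        if classify_neck((ar, neck)) is not NeckCategory.WIDE:  # ar==1.4 edge
            ar = 1.3
    height = max(ar * neck, 2.5)
    ar = height / neck
    # planar dome arc of a sac with this height and opening
    dome = math.pi * max(height, neck / 2.0)
    return MorphologyMeasures(height=height, neck_width=neck, aspect_ratio=ar, dome_measure=dome)


def sample_metric_cohort(config: CohortConfig) -> list[CohortRecord]:
    """Draw a metric-mode cohort; deterministic for a fixed seed."""
    if config.mode != "metric":
        raise ConfigError("sample_metric_cohort requires mode='metric'")
    specs = config.metric_specs or default_metric_calibration(config.quartile_kind)
    for g in GROUPS:
        if g not in specs:
            raise ConfigError(f"missing metric spec for group {g}")
    sizes = config.group_sizes()
    n_total = sum(sizes.values())
    rngs = iter(_spawn_rngs(config.seed, n_total))
    records: list[CohortRecord] = []
    k = 0
    for group in GROUPS:
        spec: GroupMetricSpec = specs[group]
        label, category = group
        for _ in range(sizes[group]):
            rng = next(rngs)
            morph = _sample_morphology(rng, category)
            mwss = float(spec.mwss.sample(rng))
            # conditional truncation keeps the invariant HWSS >= MWSS
            hw = replace(spec.hwss, lower=max(spec.hwss.lower, mwss))
            hwss = float(hw.sample(rng))
            pwss = float(spec.pwss.sample(rng))
            if pwss <= 0:
                pwss = spec.pwss.location  # truncation guards this already
            lsar = float(spec.lsar.sample(rng))
            metrics = HemodynamicMetrics(
                mwss=mwss, hwss=hwss, pwss=pwss, lsar=lsar,
                mp_ratio=mwss / pwss, hp_ratio=hwss / pwss,
                low_shear_threshold=0.1 * pwss,
            )
            records.append(
                CohortRecord(
                    id=f"a{k:03d}", rupture_label=label,
                    morphology=morph, metrics=metrics, group=group,
                )
            )
            k += 1
    return records


def sample_geometry_cohort(
    config: CohortConfig, max_rejection: float = 0.9, resolution: int = 200
) -> list[tuple[str, AneurysmGeometry]]:
    """Draw labelled geometries per stratum, rejecting shapes that do not
    classify into the intended stratum.  Returns (label, geometry) pairs in
    group order; raises :class:`ConfigError` if a stratum rejects more than
    ``max_rejection`` of its draws."""
    if config.mode != "geometry":
        raise ConfigError("sample_geometry_cohort requires mode='geometry'")
    strata = config.geometry_strata or default_geometry_strata()
    sizes = config.group_sizes()
    n_total = sum(sizes.values())
    rngs = iter(_spawn_rngs(config.seed, n_total))
    out: list[tuple[str, AneurysmGeometry]] = []
    for group in GROUPS:
        label, category = group
        spec: GeometryStratumSpec = strata[category]
        for _ in range(sizes[group]):
            rng = next(rngs)
            accepted = None
            tries = 0
            max_tries = 200
            while tries < max_tries:
                tries += 1
                try:
                    geom = _draw_geometry(rng, spec, config.parent_caliber, resolution)
                except ParameterError:
                    continue
                from .geometry import measure_morphology

                cat = measure_morphology(geom).neck_category.value
                if cat == category:
                    accepted = geom
                    break
            if accepted is None or (tries > 10 and (tries - 1) / tries > max_rejection):
                raise ConfigError(
                    f"stratum {category!r} rejected {tries - 1}/{tries} draws; "
                    "infeasible stratum specification"
                )
            out.append((label, accepted))
    return out


def _draw_geometry(rng, spec: GeometryStratumSpec, caliber: float, resolution: int):
    sac = float(rng.uniform(*spec.sac_size))
    neck = float(rng.uniform(*spec.neck_width)) if spec.neck_width else None
    off = float(rng.uniform(*spec.sac_offset))
    return make_geometry(
        spec.shape_family,
        parent_caliber=caliber,
        neck_width=neck,
        sac_size=sac,
        sac_offset=off,
        resolution=resolution,
    )


def run_cohort_cfd(
    labelled_geoms: Sequence[tuple[str, AneurysmGeometry]],
    flow: FlowConditions,
    numerics: Numerics | None = None,
    cell_size: float | None = None,
    hwss_mode: str = "time-averaged",
) -> tuple[list[CohortRecord], list[tuple[str, str]]]:
    """Mesh, simulate and post-process each labelled geometry.

    Per-aneurysm failures are isolated: the record is skipped and reported
    in the returned failure list as (id, reason) instead of aborting the
    cohort.  Returns (records, failures).
    """
    from .geometry import measure_morphology

    records: list[CohortRecord] = []
    failures: list[tuple[str, str]] = []
    for k, (label, geom) in enumerate(labelled_geoms):
        rid = f"g{k:03d}"
        try:
            cs = cell_size if cell_size is not None else geom.parent_caliber / 8.0
            mesh = build_mesh(geom, cs)
            field_ = simulate_pulsatile(mesh, flow, numerics)
            series = time_average_wss(wall_shear_series(field_, mesh, flow.viscosity))
            metrics = compute_metrics(series, hwss_mode=hwss_mode)
            morph = measure_morphology(geom)
            records.append(
                CohortRecord(
                    id=rid, rupture_label=label, morphology=morph,
                    metrics=metrics, group=(label, morph.neck_category.value),
                )
            )
        except (SolverError, ValueError) as exc:  # isolate per-id failures
            failures.append((rid, f"{type(exc).__name__}: {exc}"))
    return records, failures


def cohort_to_frame(records: Iterable[CohortRecord]) -> pd.DataFrame:
    """Flatten records to the cohort CSV schema (one row per aneurysm)."""
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "rupture_label": r.rupture_label,
                "neck_category": r.morphology.neck_category.value,
                "height_mm": r.morphology.height,
                "neck_width_mm": r.morphology.neck_width,
                "aspect_ratio": r.morphology.aspect_ratio,
                "dome_measure_mm": r.morphology.dome_measure,
                **r.metrics.as_dict(),
            }
        )
    return pd.DataFrame(rows)
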