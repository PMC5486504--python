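"""Wall shear stress extraction and the rupture-risk metric suite.

Instantaneous WSS at a wall element is the viscous tangential drag
``mu * |du_t/dn|`` evaluated one-sided from the adjacent fluid cell (the
wall itself is no-slip, half a cell away from the cell centre).  The
cycle-averaged WSS per element is the time integral of the instantaneous
magnitude over one cardiac period divided by the period, evaluated by
trapezoidal quadrature.

From the averaged field the standard sac metrics follow:

* MWSS — arc-length-weighted mean over the sac wall (Pa)
* HWSS — highest sac WSS (of the averaged field by default; optionally the
  peak over elements *and* instants)
* PWSS — weighted mean over the parent reference segment 1 cm from the
  neck (Pa); the normalizing denominator
* LSAR — fraction of sac arc length with averaged WSS strictly below 10%
  of PWSS (the "dome area" of the planar model is the sac arc length)
* M-P and H-P ratios — MWSS/PWSS and HWSS/PWSS
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import units
from .meshing import Face, Mesh, Region
from .solver import FlowField

__all__ = [
    "WallShearSeries",
    "HemodynamicMetrics",
    "TaggingError",
    "UndefinedRatioError",
    "wall_shear_series",
    "time_average_wss",
    "compute_metrics",
]

#: LSAR threshold as a fraction of PWSS
LOW_SHEAR_FRACTION = 0.1


class TaggingError(ValueError):
    """A required wall region (sac or parent probe) is empty."""


class UndefinedRatioError(ZeroDivisionError):
    """PWSS is zero, so the aneurysm-to-parent ratios are undefined."""


@dataclass
class WallShearSeries:
    """Per-wall-element instantaneous |WSS| over the last cycle.

    ``wss`` has shape (n_times, n_elements), Pa; ``weights`` are element
    arc lengths in mm; ``regions`` are :class:`~hemoshear.meshing.Region`
    codes.  ``time_averaged`` is filled by :func:`time_average_wss`.
    """

    times: np.ndarray  # s, strictly increasing, spanning one period
    period: float  # s
    wss: np.ndarray  # (n_t, n_elem) Pa
    weights: np.ndarray  # mm
    regions: np.ndarray  # Region codes
    time_averaged: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.wss < 0):
            raise ValueError("wss entries are magnitudes and must be >= 0")


@dataclass(frozen=True)
class HemodynamicMetrics:
    """The six per-aneurysm hemodynamic metrics."""

    mwss: float  # Pa
    hwss: float  # Pa
    pwss: float  # Pa
    lsar: float  # dimensionless fraction of sac arc length
    mp_ratio: float  # MWSS / PWSS
    hp_ratio: float  # HWSS / PWSS
    low_shear_threshold: float  # Pa, = LOW_SHEAR_FRACTION * PWSS

    def __post_init__(self) -> None:
        if not (0.0 <= self.lsar <= 1.0):
            raise ValueError("LSAR must lie in [0, 1]")
        if self.hwss < self.mwss - 1e-12 * max(self.hwss, 1.0):
            raise ValueError("HWSS must be >= MWSS")

    def as_dict(self) -> dict[str, float]:
        return {
            "MWSS": self.mwss,
            "HWSS": self.hwss,
            "PWSS": self.pwss,
            "LSAR": self.lsar,
            "MP_ratio": self.mp_ratio,
            "HP_ratio": self.hp_ratio,
        }


def wall_shear_series(field_: FlowField, mesh: Mesh, mu: float) -> WallShearSeries:
    """Extract |WSS| at every wall element and snapshot of the last cycle.

    The tangential velocity is interpolated to the adjacent cell centre and
    differenced one-sided against the no-slip wall half a cell away:
    ``wss = mu * |u_t| / (cell/2)``.
    """
    if field_.mesh is not mesh and (
        field_.mesh.nx != mesh.nx or field_.mesh.ny != mesh.ny
    ):
        raise ValueError("flow field and mesh are inconsistent")
    half = units.mm_to_m(mesh.cell_size) / 2.0
    ci, cj = mesh.wall_cell[:, 0], mesh.wall_cell[:, 1]
    horiz = (mesh.wall_face == int(Face.N)) | (mesh.wall_face == int(Face.S))
    n_t = len(field_.times)
    wss = np.empty((n_t, mesh.n_wall))
    for k in range(n_t):
        ut = 0.5 * (field_.u[k, ci, cj] + field_.u[k, ci + 1, cj])
        vt = 0.5 * (field_.v[k, ci, cj] + field_.v[k, ci, cj + 1])
        tang = np.where(horiz, ut, vt)
        wss[k] = mu * np.abs(tang) / half
    return WallShearSeries(
        times=field_.times.copy(),
        period=field_.period,
        wss=wss,
        weights=mesh.wall_weight.copy(),
        regions=mesh.wall_region.copy(),
    )


def time_average_wss(series: WallShearSeries) -> WallShearSeries:
    """Cycle-average each element's |WSS| by trapezoidal quadrature.

    For a single-snapshot (steady) series the average is that snapshot.
    Returns the same series with ``time_averaged`` filled.
    """
    if len(series.times) == 1:
        series.time_averaged = series.wss[0].copy()
        return series
    if len(series.times) < 2:
        raise ValueError("need at least 2 time samples spanning the period")
    span = series.times[-1] - series.times[0]
    avg = np.trapezoid(np.abs(series.wss), series.times, axis=0) / span
    series.time_averaged = avg
    return series


def compute_metrics(
    series: WallShearSeries,
    threshold_fraction: float = LOW_SHEAR_FRACTION,
    hwss_mode: str = "time-averaged",
) -> HemodynamicMetrics:
    """Compute MWSS, HWSS, PWSS, LSAR and the M-P / H-P ratios.

    ``hwss_mode`` is ``"time-averaged"`` (highest cycle-averaged sac WSS,
    the default) or ``"peak"`` (highest instantaneous sac WSS over the
    whole cycle).
    """
    if series.time_averaged is None:
        series = time_average_wss(series)
    if hwss_mode not in ("time-averaged", "peak"):
        raise ValueError(f"unknown hwss_mode {hwss_mode!r}")
    sac = series.regions == int(Region.SAC)
    probe = series.regions == int(Region.PARENT_PROBE)
    if not sac.any():
        raise TaggingError("no sac wall elements")
    if not probe.any():
        raise TaggingError("no parent_probe wall elements")
    avg = series.time_averaged
    w_sac = series.weights[sac]
    w_sum = float(w_sac.sum())
    mwss = float(np.sum(avg[sac] * w_sac) / w_sum)
    if hwss_mode == "peak":
        hwss = float(series.wss[:, sac].max())
    else:
        hwss = float(avg[sac].max())
    w_probe = series.weights[probe]
    pwss = float(np.sum(avg[probe] * w_probe) / w_probe.sum())
    if pwss == 0.0:
        raise UndefinedRatioError(
            "PWSS is zero (degenerate flow); aneurysm-to-parent ratios undefined"
        )
    threshold = threshold_fraction * pwss
    lsar = float(np.sum(w_sac[avg[sac] < threshold]) / w_sum)
    return HemodynamicMetrics(
        mwss=mwss,
        hwss=hwss,
        pwss=pwss,
        lsar=lsar,
        mp_ratio=mwss / pwss,
        hp_ratio=hwss / pwss,
        low_shear_threshold=threshold,
    )
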