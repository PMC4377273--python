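"""Idealized coastal ocean fields for larval drift experiments.

The physical picture is a straight meridional coastline at ``x = 0`` with
land occupying ``x < 0``: the y-axis points northward along the coast and x
offshore.  A northward coastal jet (the analogue of the Norwegian Coastal /
Atlantic Current system) decays offshore, a divergence-free mesoscale eddy
perturbation is derived from a smoothed random streamfunction, and sea
surface temperature combines a seasonal warming ramp with a south-to-north
cooling gradient (water in the south is warmer, which is what makes
southern-origin larvae grow larger during their longer drift).

Scenario presets add a transient alongshore "wave pulse" south of the
colony that sweeps southern-origin larvae northward in a bunch, emulating
the episodic arrival of southern larvae in the scenario years: a wave that
peaks during the hatching period, the same wave delayed by 25 days, or no
wave at all (a weak gradual southern influx).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field

import numpy as np
import xarray as xr
from scipy.ndimage import gaussian_filter

__all__ = [
    "GridSpec",
    "WavePulse",
    "OceanParams",
    "OceanFields",
    "ScenarioPreset",
    "make_coastal_fields",
    "scenario_preset",
    "divergence",
    "MEAN_HATCH_DAY",
    "SEASON_START_DAY",
    "SEASON_END_DAY",
    "SCENARIO_NAMES",
]

#: Simulation day index (0 = 1 March) of the colony's mean hatch date,
#: ~22 June, matching mean hatching dates of 21-24 June.
MEAN_HATCH_DAY = 113

#: Breeding-season window (day indices, 0 = 1 March) used for seasonal
#: summaries: mid-May through end of July.
SEASON_START_DAY = 75
SEASON_END_DAY = 153

SCENARIO_NAMES = ("matched_wave", "late_wave", "flat_south")


@dataclass(frozen=True)
class GridSpec:
    """Regular grid: cell column 0 is land (center at -dx/2), coast at x=0.

    The y-axis is northward along the coast; alongshore cell size equals
    the offshore cell size ``dx`` (km).  ``origin`` is the calendar date of
    day index 0; the default horizon covers 1 March - 31 August.
    """

    nx: int = 31
    ny: int = 200
    dx: float = 10.0
    origin: datetime.date = datetime.date(2001, 3, 1)
    n_days: int = 184

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValueError("grid needs nx, ny >= 2")
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")

    @property
    def x_centers(self) -> np.ndarray:
        # column i center at (i - 0.5) * dx; column 0 is the land strip
        return (np.arange(self.nx) - 0.5) * self.dx

    @property
    def y_centers(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.dx

    @property
    def x_max(self) -> float:
        """Eastern (offshore) open-boundary coordinate."""
        return (self.nx - 1) * self.dx

    @property
    def y_max(self) -> float:
        """Northern open-boundary coordinate."""
        return self.ny * self.dx

    def date_of(self, day: int) -> datetime.date:
        return self.origin + datetime.timedelta(days=int(day))


#: Days between the center of the velocity pulse and the peak of the
#: resulting in-box southern abundance: swept particles need to cover the
#: remaining distance and accumulate in the box (calibrated on the default
#: geometry).
PULSE_ARRIVAL_LAG = 26


@dataclass(frozen=True)
class WavePulse:
    """Transient alongshore speed pulse confined south of ``y_max_km``.

    The time envelope is a cosine-squared bump supported on
    ``[center_day - half_width_days, center_day + half_width_days]``; the
    spatial envelope tapers to zero over 50 km below ``y_max_km`` and
    follows the jet's offshore profile.
    """

    amplitude: float = 45.0  # km/day added alongshore speed at the coast
    center_day: int = 87
    half_width_days: int = 22
    y_max_km: float | None = 1750.0  # None: the pulse spans the whole domain

    def time_envelope(self, days: np.ndarray) -> np.ndarray:
        u = (np.asarray(days, dtype=float) - self.center_day) / self.half_width_days
        env = np.where(np.abs(u) < 1.0, np.cos(0.5 * np.pi * u) ** 2, 0.0)
        return env

    def y_envelope(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if self.y_max_km is None:
            return np.ones_like(y)
        taper = 50.0
        u = (self.y_max_km - y) / taper
        return np.clip(u, 0.0, 1.0)


@dataclass(frozen=True)
class OceanParams:
    """Parameters of the idealized coastal current and SST fields.

    jet_speed : peak alongshore speed (km/day) at the coast.
    jet_width : e-folding offshore decay scale (km).
    offshore_floor : fraction of jet_speed retained far offshore; keeping
        ``eddy_amplitude <= offshore_floor * jet_speed`` guarantees the
        total alongshore velocity is non-negative everywhere off land.
    eddy_amplitude : peak speed (km/day) of the divergence-free eddy
        perturbation derived from a smoothed random streamfunction.
    eddy_length : eddy correlation length (km); must be >= dx.
    sst_base : SST (deg C) at the northern end on day 0.
    sst_seasonal_ramp : seasonal warming rate (deg C / day).
    sst_south_excess : warm anomaly (deg C) at the southern boundary,
        decaying linearly to zero at the northern boundary.
    """

    jet_speed: float = 8.0
    jet_width: float = 50.0
    offshore_floor: float = 0.25
    eddy_amplitude: float = 2.0
    eddy_length: float = 60.0
    eddy_period: float = 15.0  # days; the eddy field rotates through two
    # random streamfunction phases with this period, so particles sample
    # many eddy configurations instead of being trapped by a frozen field
    sst_base: float = 4.0
    sst_seasonal_ramp: float = 0.04
    sst_south_excess: float = 3.0
    seed: int = 0
    pulse: WavePulse | None = None

    def __post_init__(self) -> None:
        if self.jet_speed < 0:
            raise ValueError("jet_speed must be >= 0")
        if self.eddy_amplitude < 0:
            raise ValueError("eddy_amplitude must be >= 0")
        if not 0.0 <= self.offshore_floor <= 1.0:
            raise ValueError("offshore_floor must lie in [0, 1]")


@dataclass
class OceanFields:
    """Gridded daily velocity (km/day) and SST (deg C) with a land mask.

    Arrays ``u``, ``v``, ``sst`` have shape ``(n_days, ny, nx)``;
    ``land_mask`` has shape ``(ny, nx)`` and is True on land, where
    velocities are exactly zero.  ``psi`` holds the two streamfunction
    phases (km^2/day, shape (2, ny, nx)) the rotating eddy perturbation
    was derived from, kept for diagnostics.
    """

    u: np.ndarray
    v: np.ndarray
    sst: np.ndarray
    land_mask: np.ndarray
    grid: GridSpec
    params: OceanParams
    psi: np.ndarray | None = None

    @property
    def n_days(self) -> int:
        return self.u.shape[0]

    def eddy_velocity(self, day: int) -> tuple[np.ndarray, np.ndarray]:
        """Reconstruct the day's eddy perturbation from the stored
        streamfunction phases (for diagnostics and divergence checks)."""
        if self.psi is None:
            raise ValueError("streamfunction phases were not retained")
        phase = 2.0 * np.pi * day / self.params.eddy_period
        psi_day = np.cos(phase) * self.psi[0] + np.sin(phase) * self.psi[1]
        return _psi_velocity(psi_day, self.grid.dx)

    def to_dataset(self) -> xr.Dataset:
        g = self.grid
        times = [np.datetime64(g.date_of(d)) for d in range(self.n_days)]
        ds = xr.Dataset(
            {
                "u": (("time", "y", "x"), self.u, {"units": "km day-1", "long_name": "offshore velocity"}),
                "v": (("time", "y", "x"), self.v, {"units": "km day-1", "long_name": "alongshore (northward) velocity"}),
                "sst": (("time", "y", "x"), self.sst, {"units": "degC", "long_name": "sea surface temperature"}),
                "mask": (("y", "x"), self.land_mask.astype(np.int8), {"long_name": "land mask (1 = land)"}),
            },
            coords={
                "time": times,
                "y": ("y", g.y_centers, {"units": "km", "long_name": "alongshore distance (north)"}),
                "x": ("x", g.x_centers, {"units": "km", "long_name": "offshore distance"}),
            },
            attrs={"ocean_params": json.dumps(_params_dict(self.params)), "dx_km": g.dx,
                   "origin_date": g.origin.isoformat()},
        )
        return ds

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path)

    @classmethod
    def from_netcdf(cls, path) -> "OceanFields":
        with xr.open_dataset(path) as ds:
            ds = ds.load()
        params = _params_from_dict(json.loads(ds.attrs["ocean_params"]))
        grid = GridSpec(
            nx=ds.sizes["x"],
            ny=ds.sizes["y"],
            dx=float(ds.attrs["dx_km"]),
            origin=datetime.date.fromisoformat(ds.attrs["origin_date"]),
            n_days=ds.sizes["time"],
        )
        return cls(
            u=ds["u"].values,
            v=ds["v"].values,
            sst=ds["sst"].values,
            land_mask=ds["mask"].values.astype(bool),
            grid=grid,
            params=params,
        )


def _params_dict(params: OceanParams) -> dict:
    d = dataclasses.asdict(params)
    return d


def _params_from_dict(d: dict) -> OceanParams:
    d = dict(d)
    pulse = d.pop("pulse", None)
    if pulse is not None:
        pulse = WavePulse(**pulse)
    return OceanParams(pulse=pulse, **d)


def _jet_profile(x: np.ndarray, params: OceanParams) -> np.ndarray:
    """Dimensionless offshore profile: 1 at the coast, floor far offshore."""
    f = params.offshore_floor
    prof = f + (1.0 - f) * np.exp(-np.maximum(x, 0.0) / params.jet_width)
    return np.where(x < 0.0, 0.0, prof)


def _streamfunction_pair(grid: GridSpec, params: OceanParams) -> np.ndarray:
    """Two independent smoothed, edge-tapered random streamfunctions of
    shape (2, ny, nx); the daily eddy field rotates between them."""
    ny, nx = grid.ny, grid.nx
    rng = np.random.default_rng(params.seed)
    sigma = params.eddy_length / grid.dx
    psi = gaussian_filter(rng.standard_normal((2, ny, nx)), sigma=(0, sigma, sigma),
                          mode="constant")
    # taper to exactly zero in the outer three rings so boundary one-sided
    # differences cannot break the divergence-free property
    ramp_y = np.clip((np.minimum(np.arange(ny), ny - 1 - np.arange(ny)) - 2) / 3.0, 0.0, 1.0)
    ramp_x = np.clip((np.minimum(np.arange(nx), nx - 1 - np.arange(nx)) - 2) / 3.0, 0.0, 1.0)
    return psi * ramp_y[None, :, None] * ramp_x[None, None, :]


def _psi_velocity(psi: np.ndarray, dx: float) -> tuple[np.ndarray, np.ndarray]:
    """u' = -dpsi/dy, v' = +dpsi/dx with central differences: the discrete
    divergence computed with the same operators vanishes identically."""
    dpsi_dy, dpsi_dx = np.gradient(psi, dx, dx, axis=(-2, -1))
    return -dpsi_dy, dpsi_dx


def _eddy_perturbation(
    grid: GridSpec, params: OceanParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Divergence-free daily eddy velocities (n_days, ny, nx).

    The streamfunction rotates between two random phases with period
    ``eddy_period`` so the Lagrangian sampling of eddies averages out;
    fields are normalized so the peak perturbation speed over the whole
    horizon equals ``eddy_amplitude``.  Returns (psi_pair, u', v').
    """
    psi_pair = _streamfunction_pair(grid, params)
    upa, vpa = _psi_velocity(psi_pair[0], grid.dx)
    upb, vpb = _psi_velocity(psi_pair[1], grid.dx)
    days = np.arange(grid.n_days)
    phase = 2.0 * np.pi * days / params.eddy_period
    c = np.cos(phase)[:, None, None]
    s = np.sin(phase)[:, None, None]
    up = c * upa[None] + s * upb[None]
    vp = c * vpa[None] + s * vpb[None]
    speed = np.hypot(up, vp).max()
    if speed > 0 and params.eddy_amplitude > 0:
        scale = params.eddy_amplitude / speed
        psi_pair, up, vp = psi_pair * scale, up * scale, vp * scale
    else:
        psi_pair, up, vp = psi_pair * 0.0, up * 0.0, vp * 0.0
    return psi_pair, up, vp


def make_coastal_fields(grid: GridSpec, params: OceanParams) -> OceanFields:
    """Generate daily u/v/SST fields on the grid.

    The alongshore velocity is ``jet_speed * profile(x)`` plus the optional
    wave pulse and the eddy perturbation; the offshore velocity is the eddy
    perturbation alone.  Velocities are zero on land.  Bit-reproducible
    given ``params.seed``.
    """
    if params.eddy_length < grid.dx:
        raise ValueError(
            f"eddy_length ({params.eddy_length} km) must be >= grid dx ({grid.dx} km)"
        )
    x = grid.x_centers
    y = grid.y_centers
    land = (x < 0.0)[None, :] & np.ones((grid.ny, 1), dtype=bool)
    prof = _jet_profile(x, params)[None, :]  # (1, nx)

    psi_pair, up, vp = _eddy_perturbation(grid, params)

    days = np.arange(grid.n_days)
    v_jet = params.jet_speed * prof  # (1, nx) broadcast over y
    v_base = np.broadcast_to(v_jet, (grid.ny, grid.nx)).copy()

    v = np.empty((grid.n_days, grid.ny, grid.nx))
    if params.pulse is not None:
        tenv = params.pulse.time_envelope(days)  # (n_days,)
        yenv = params.pulse.y_envelope(y)  # (ny,)
        pulse_xy = params.pulse.amplitude * yenv[:, None] * prof  # (ny, nx)
        v[:] = v_base[None] + tenv[:, None, None] * pulse_xy[None]
    else:
        v[:] = v_base[None]
    v += vp
    u = up

    # guard: the jet floor >= eddy amplitude keeps v >= 0 analytically;
    # clip as a safety net for extreme parameter choices
    np.clip(v, 0.0, None, out=v)
    u[:, land] = 0.0
    v[:, land] = 0.0

    sst = (
        params.sst_base
        + params.sst_seasonal_ramp * days[:, None, None]
        + params.sst_south_excess * (1.0 - y[None, :, None] / grid.y_max)
    )
    sst = np.broadcast_to(sst, (grid.n_days, grid.ny, grid.nx)).copy()

    return OceanFields(u=u, v=v, sst=sst, land_mask=land, grid=grid, params=params,
                       psi=psi_pair)


def divergence(u: np.ndarray, v: np.ndarray, dx: float) -> np.ndarray:
    """Discrete divergence du/dx + dv/dy with the same central-difference
    operators used to derive the eddy perturbation from its streamfunction."""
    du_dx = np.gradient(u, dx, axis=-1)
    dv_dy = np.gradient(v, dx, axis=-2)
    return du_dx + dv_dy


@dataclass(frozen=True)
class ScenarioPreset:
    """A named study-year configuration: ocean parameters plus the timing
    anchors the downstream analysis uses."""

    name: str
    ocean: OceanParams
    mean_hatch_day: int = MEAN_HATCH_DAY
    season: tuple[int, int] = (SEASON_START_DAY, SEASON_END_DAY)

    @property
    def pulse_peak_day(self) -> int | None:
        """Expected day of the in-box southern abundance peak: the velocity
        pulse center plus the calibrated arrival lag."""
        if self.ocean.pulse is None:
            return None
        return self.ocean.pulse.center_day + PULSE_ARRIVAL_LAG


def scenario_preset(name: str, seed: int = 0) -> ScenarioPreset:
    """Study-year presets for the southern larval influx.

    ``matched_wave``: an episodic wave of southern larvae whose in-box peak
    coincides (within +/-3 days) with the mean hatch date.  ``late_wave``:
    the same wave delayed by 25 days.  ``flat_south``: no wave, only a weak
    gradual southern influx late in the season (a slightly faster base jet
    lets the nearest southern grounds trickle in).
    """
    if name == "matched_wave":
        pulse = WavePulse(center_day=MEAN_HATCH_DAY - PULSE_ARRIVAL_LAG)
        params = OceanParams(seed=seed, pulse=pulse)
    elif name == "late_wave":
        pulse = WavePulse(center_day=MEAN_HATCH_DAY - PULSE_ARRIVAL_LAG + 25)
        params = OceanParams(seed=seed, pulse=pulse)
    elif name == "flat_south":
        # weak, season-long enhancement: a slow gradual southern influx
        pulse = WavePulse(amplitude=12.0, center_day=70, half_width_days=60)
        params = OceanParams(seed=seed, pulse=pulse)
    else:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")
    return ScenarioPreset(name=name, ocean=params)
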