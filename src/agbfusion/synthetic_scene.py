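"""Synthetic UAV study generator.

Emulates the three potato field experiments the analysis pipeline is designed
for — a cultivar × density trial (E1, 18 plots), a cultivar × nitrogen trial
(E2, 40 plots) and a nitrogen × potassium trial (E3, 36 plots) — observed by
a six-band multispectral + RGB sensor on four flight dates per experiment.
Each plot-date sample gets a latent above-ground biomass drawn from a
logistic growth curve in the cultivar's growth process ratio, a canopy-cover
fraction that saturates with biomass, and a rendered plot raster in which a
spatially clumped vegetation mask mixes vegetation and soil endmember
spectra plus sensor noise.

Nothing here is fit to real imagery: the generator exists so every
downstream stage (zonal statistics, vegetation indices, texture, canopy
cover, selection, regression) is testable end to end with known ground
truth.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .agromet import DEFAULT_BASE_TEMP, gpr_at

__all__ = [
    "DesignPlot",
    "CultivarInfo",
    "BandStack",
    "GroundTruth",
    "Endmembers",
    "AGBParams",
    "SceneConfig",
    "DEFAULT_CULTIVARS",
    "DEFAULT_FLIGHT_DATES",
    "build_design",
    "simulate_weather",
    "simulate_agb",
    "render_plot_image",
    "generate_dataset",
    "iterate_scene",
]

BAND_ROLES = {
    "band1": "blue",
    "band2": "green",
    "band3": "pan",
    "band4": "red",
    "band5": "red_edge",
    "band6": "nir",
}
#: growth stages: tuber formation, tuber expansion, starch accumulation, mature harvest
STAGES = ("S1", "S2", "S3", "S4")

EXPERIMENTS = ("E1", "E2", "E3")


@dataclass(frozen=True)
class DesignPlot:
    """One experimental plot of a randomized-block field trial."""

    experiment_id: str
    plot_id: str
    cultivar_id: str
    density: float  # plants/ha
    n_rate: float  # kg N/ha
    k_rate: float  # kg K/ha
    replicate: int
    block: int


@dataclass(frozen=True)
class CultivarInfo:
    """Cultivar phenology: total growth period and emergence date."""

    cultivar_id: str
    total_period_days: int
    emergence_date: dt.date
    base_temp: float = DEFAULT_BASE_TEMP


@dataclass
class BandStack:
    """Per-plot multi-band reflectance raster plus an RGB rendering.

    ``ms`` is H×W×6 reflectance in [0, 1] with slot order band1..band6;
    ``rgb`` is H×W×3 digital numbers in [0, 255].  ``veg_mask`` records the
    generating vegetation mask when the stack is synthetic (diagnostic only;
    real imagery has no such field).
    """

    ms: np.ndarray
    rgb: np.ndarray
    band_roles: dict[str, str]
    plot_id: str
    flight_date: dt.date
    veg_mask: np.ndarray | None = None

    def band(self, role: str) -> np.ndarray:
        """Return the reflectance plane for a band role (e.g. ``"nir"``)."""
        for slot, r in self.band_roles.items():
            if r == role:
                return self.ms[..., int(slot[-1]) - 1]
        raise KeyError(f"no band with role {role!r}")


@dataclass(frozen=True)
class GroundTruth:
    """Latent state of one plot at one flight: biomass, cover, stage."""

    plot_id: str
    flight_date: dt.date
    true_agb: float  # ton/ha
    true_cc: float  # fraction of ground covered by canopy
    stage: str


@dataclass(frozen=True)
class Endmembers:
    """Pure-material reflectance spectra used to mix plot pixels.

    Soil is flat and mid-grey across bands; vegetation shows the classic
    red absorption / NIR plateau so index-style features carry signal.
    Order: blue, green, pan, red, red_edge, nir.
    """

    soil: tuple[float, ...] = (0.22, 0.24, 0.26, 0.27, 0.28, 0.30)
    vegetation: tuple[float, ...] = (0.04, 0.09, 0.12, 0.05, 0.28, 0.50)

    def validate(self) -> None:
        for name, spec in (("soil", self.soil), ("vegetation", self.vegetation)):
            if len(spec) != 6:
                raise ValueError(f"{name} endmember needs 6 bands, got {len(spec)}")
            if any(not 0.0 <= v <= 1.0 for v in spec):
                raise ValueError(f"{name} endmember reflectance outside [0, 1]: {spec}")
        if not self.vegetation[5] > self.soil[5]:
            raise ValueError("vegetation NIR must exceed soil NIR")
        if not self.vegetation[3] < self.soil[3]:
            raise ValueError("vegetation red must be below soil red")


@dataclass(frozen=True)
class AGBParams:
    """Parameters of the latent logistic growth model.

    ``asymptote`` is the peak AGB (ton/ha) of a reference plot (density
    60 000 plants/ha, non-limiting N and K).  The curve is logistic in GPR
    with midpoint ``midpoint`` and steepness ``steepness``; nitrogen acts
    with diminishing returns (Michaelis–Menten), density sub-linearly, and
    potassium weakly.  Multiplicative lognormal noise has log-sd
    ``noise_sd``.
    """

    asymptote: float = 8.0  # ton/ha at reference management
    midpoint: float = 0.45  # GPR at half asymptote
    steepness: float = 8.0
    n_half_sat: float = 100.0  # kg/ha
    n_floor: float = 0.55  # response with zero N
    k_half_sat: float = 120.0  # kg/ha
    k_floor: float = 0.85
    density_ref: float = 60000.0
    density_exp: float = 0.5
    late_bonus: float = 0.004  # asymptote gain per growth-period day over 75
    noise_sd: float = 0.15  # lognormal log-sd
    cc_rate: float = 0.40  # canopy-cover saturation per ton/ha (latest cultivar)
    cc_maturity_ref: float = 110.0  # growth-period days of the reference cultivar


#: cultivar catalog: early (Z5, Z35), mid (Z27) and late (Z19, Z49) maturing.
#: Emergence dates are back-computed from first-flight growth stages.
DEFAULT_CULTIVARS: dict[str, CultivarInfo] = {
    "Z5": CultivarInfo("Z5", 75, dt.date(2023, 6, 15)),
    "Z35": CultivarInfo("Z35", 75, dt.date(2023, 6, 15)),
    "Z27": CultivarInfo("Z27", 95, dt.date(2023, 6, 15)),
    "Z19": CultivarInfo("Z19", 105, dt.date(2023, 6, 16)),
    "Z49": CultivarInfo("Z49", 110, dt.date(2023, 6, 14)),
}

#: four UAV flights per experiment covering stages S1-S4
DEFAULT_FLIGHT_DATES: dict[str, tuple[dt.date, ...]] = {
    "E1": (
        dt.date(2023, 7, 4),
        dt.date(2023, 7, 17),
        dt.date(2023, 8, 3),
        dt.date(2023, 8, 13),
    ),
    "E2": (
        dt.date(2023, 7, 5),
        dt.date(2023, 7, 18),
        dt.date(2023, 8, 3),
        dt.date(2023, 8, 14),
    ),
    "E3": (
        dt.date(2023, 7, 6),
        dt.date(2023, 7, 20),
        dt.date(2023, 8, 5),
        dt.date(2023, 8, 18),
    ),
}

# management defaults for factors an experiment does not vary
_BASELINE_DENSITY = 60000.0
_BASELINE_N = 150.0
_BASELINE_K = 180.0

#: E1 density levels, plants/ha (T1-T3)
E1_DENSITIES = (52500.0, 60000.0, 75000.0)
E2_N_RATES = (0.0, 50.0, 100.0, 250.0, 400.0)
E3_N_RATES = (0.0, 120.0, 240.0)
E3_K_RATES = (0.0, 120.0, 240.0, 360.0)


def build_design(experiment_id: str, seed: int = 0) -> list[DesignPlot]:
    """Build the randomized-block plot layout of one experiment.

    Treatments are fully crossed and replicated in blocks; the within-block
    plot order is randomized by ``seed`` but the returned list is sorted by
    plot id, so plot membership is seed-invariant.
    """
    if experiment_id == "E1":
        treatments = [
            (cv, d, _BASELINE_N, _BASELINE_K)
            for cv in ("Z27", "Z19")
            for d in E1_DENSITIES
        ]
        n_blocks = 3
    elif experiment_id == "E2":
        treatments = [
            (cv, _BASELINE_DENSITY, n, _BASELINE_K)
            for cv in ("Z5", "Z49")
            for n in E2_N_RATES
        ]
        n_blocks = 4
    elif experiment_id == "E3":
        treatments = [
            ("Z35", _BASELINE_DENSITY, n, k)
            for n in E3_N_RATES
            for k in E3_K_RATES
        ]
        n_blocks = 3
    else:
        raise ValueError(
            f"unknown experiment_id {experiment_id!r}; expected one of {EXPERIMENTS}"
        )

    rng = np.random.default_rng(seed)
    plots: list[DesignPlot] = []
    for block in range(1, n_blocks + 1):
        order = rng.permutation(len(treatments))
        for pos, t_idx in enumerate(order):
            cv, density, n_rate, k_rate = treatments[t_idx]
            plots.append(
                DesignPlot(
                    experiment_id=experiment_id,
                    plot_id=f"{experiment_id}-B{block}-P{pos + 1:02d}",
                    cultivar_id=cv,
                    density=density,
                    n_rate=n_rate,
                    k_rate=k_rate,
                    replicate=block,
                    block=block,
                )
            )
    return sorted(plots, key=lambda p: p.plot_id)


def simulate_weather(
    start_date: dt.date,
    end_date: dt.date,
    seed: int = 0,
    *,
    mean_temp: float = 17.0,
    amplitude: float = 7.0,
    peak_doy: int = 200,
    noise_sd: float = 1.5,
    diurnal_range: tuple[float, float] = (6.0, 14.0),
) -> pd.DataFrame:
    """Simulate a daily Tmax/Tmin series for a temperate highland summer.

    Daily mean temperature follows a sinusoid over the year peaking around
    ``peak_doy`` plus Gaussian noise; the diurnal range is drawn uniformly
    within ``diurnal_range`` so Tmax > Tmin always holds.
    """
    if start_date > end_date:
        raise ValueError(f"start_date {start_date} is after end_date {end_date}")
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start_date, end_date, freq="D")
    doy = dates.dayofyear.to_numpy()
    daily_mean = (
        mean_temp
        + amplitude * np.cos(2 * np.pi * (doy - peak_doy) / 365.25)
        + rng.normal(0.0, noise_sd, len(dates))
    )
    rng_span = rng.uniform(*diurnal_range, len(dates))
    return pd.DataFrame(
        {
            "date": dates.date,
            "tmax": daily_mean + rng_span / 2.0,
            "tmin": daily_mean - rng_span / 2.0,
        }
    )


def _agb_curve(gpr_value: float, plot: DesignPlot, cultivar: CultivarInfo,
               params: AGBParams) -> float:
    """Noise-free latent AGB (ton/ha) at a growth-process-ratio value."""
    p = params
    n_eff = p.n_floor + (1 - p.n_floor) * plot.n_rate / (plot.n_rate + p.n_half_sat)
    k_eff = p.k_floor + (1 - p.k_floor) * plot.k_rate / (plot.k_rate + p.k_half_sat)
    d_eff = (plot.density / p.density_ref) ** p.density_exp
    late = 1.0 + p.late_bonus * (cultivar.total_period_days - 75)
    asym = p.asymptote * n_eff * k_eff * d_eff * late
    return asym / (1.0 + np.exp(-p.steepness * (gpr_value - p.midpoint)))


def expected_agb(plot: DesignPlot, cultivar: CultivarInfo, flight_date: dt.date,
                 params: AGBParams = AGBParams()) -> float:
    """Noise-free latent AGB of a plot at a flight date (the curve mean)."""
    g = gpr_at(
        cultivar.cultivar_id,
        cultivar.total_period_days,
        cultivar.emergence_date,
        flight_date,
    )
    return float(_agb_curve(g.gpr, plot, cultivar, params))


def simulate_agb(
    plot: DesignPlot,
    cultivar: CultivarInfo,
    flight_date: dt.date,
    params: AGBParams = AGBParams(),
    seed: int = 0,
    stage: str = "",
) -> GroundTruth:
    """Draw the latent ground truth of one plot at one flight date.

    AGB is logistic in the growth process ratio with asymptote modulated by
    cultivar maturity class, nitrogen (diminishing returns), density and
    potassium, times lognormal noise.  Canopy cover saturates with AGB at a
    cultivar-dependent rate, ``cc = 1 - exp(-rate_c * AGB)`` clipped to
    [0, 1], where ``rate_c = cc_rate * cc_maturity_ref / T_total``:
    early-maturing cultivars spread more canopy per unit biomass, so plots
    with identical cover can carry different biomass depending on cultivar —
    the ambiguity that phenology-aware features exist to resolve.
    """
    g = gpr_at(
        cultivar.cultivar_id,
        cultivar.total_period_days,
        cultivar.emergence_date,
        flight_date,
    )
    mean_agb = _agb_curve(g.gpr, plot, cultivar, params)
    rng = np.random.default_rng(seed)
    noise = np.exp(rng.normal(0.0, params.noise_sd)) if params.noise_sd > 0 else 1.0
    agb = float(mean_agb * noise)
    rate_c = params.cc_rate * params.cc_maturity_ref / cultivar.total_period_days
    cc = float(np.clip(1.0 - np.exp(-rate_c * agb), 0.0, 1.0))
    return GroundTruth(
        plot_id=plot.plot_id,
        flight_date=flight_date,
        true_agb=agb,
        true_cc=cc,
        stage=stage,
    )


def clumped_mask(shape: tuple[int, int], fraction: float, rng: np.random.Generator,
                 *, sigma: float | None = None, iid: bool = False) -> np.ndarray:
    """Boolean vegetation mask covering ``fraction`` of the pixels.

    The default placement thresholds a Gaussian-smoothed random field at the
    matching quantile, which produces contiguous canopy blobs (so texture
    statistics carry spatial signal) while hitting the target pixel count
    exactly up to rounding.  ``iid=True`` falls back to independent random
    placement, useful as a degenerate oracle.
    """
    h, w = shape
    n_veg = int(round(fraction * h * w))
    if n_veg <= 0:
        return np.zeros(shape, dtype=bool)
    if n_veg >= h * w:
        return np.ones(shape, dtype=bool)
    if iid:
        field_ = rng.random(shape)
    else:
        if sigma is None:
            sigma = min(h, w) / 10.0
        field_ = gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    flat = field_.ravel()
    cutoff = np.partition(flat, len(flat) - n_veg)[len(flat) - n_veg]
    mask = field_ >= cutoff
    # quantile ties can overshoot; trim deterministically
    excess = int(mask.sum()) - n_veg
    if excess > 0:
        idx = np.flatnonzero(mask.ravel() & (field_.ravel() == cutoff))[:excess]
        mask.ravel()[idx] = False
    return mask


def render_plot_image(
    truth: GroundTruth,
    size: tuple[int, int] = (64, 64),
    endmembers: Endmembers = Endmembers(),
    seed: int = 0,
    *,
    noise_sd: float = 0.01,
    iid_placement: bool = False,
) -> BandStack:
    """Render a plot raster mixing vegetation and soil endmember spectra.

    A clumped mask covering ``truth.true_cc`` of the pixels selects the
    vegetation endmember, the rest take the soil spectrum; per-pixel
    Gaussian sensor noise is added and reflectance clipped to [0, 1].  The
    RGB rendering scales the blue/green/red reflectance slots to [0, 255].
    """
    h, w = size
    if h < 16 or w < 16:
        raise ValueError(f"image size must be at least 16x16, got {size}")
    endmembers.validate()
    rng = np.random.default_rng(seed)
    mask = clumped_mask((h, w), truth.true_cc, rng, iid=iid_placement)
    soil = np.asarray(endmembers.soil)
    veg = np.asarray(endmembers.vegetation)
    ms = np.where(mask[..., None], veg, soil).astype(float)
    if noise_sd > 0:
        ms = ms + rng.normal(0.0, noise_sd, ms.shape)
    ms = np.clip(ms, 0.0, 1.0)
    rgb = np.clip(ms[..., [3, 1, 0]] * 255.0, 0, 255)  # red, green, blue slots
    return BandStack(
        ms=ms,
        rgb=rgb,
        band_roles=dict(BAND_ROLES),
        plot_id=truth.plot_id,
        flight_date=truth.flight_date,
        veg_mask=mask,
    )


@dataclass
class SceneConfig:
    """Configuration of a full synthetic study."""

    experiments: tuple[str, ...] = EXPERIMENTS
    flight_dates: dict[str, tuple[dt.date, ...]] = field(
        default_factory=lambda: dict(DEFAULT_FLIGHT_DATES)
    )
    cultivars: dict[str, CultivarInfo] = field(
        default_factory=lambda: dict(DEFAULT_CULTIVARS)
    )
    agb_params: AGBParams = field(default_factory=AGBParams)
    endmembers: Endmembers = field(default_factory=Endmembers)
    image_size: tuple[int, int] = (64, 64)
    image_noise_sd: float = 0.01
    weather_start: dt.date = dt.date(2023, 6, 1)
    weather_end: dt.date = dt.date(2023, 8, 31)

    def with_experiments(self, experiments: tuple[str, ...]) -> "SceneConfig":
        return replace(self, experiments=tuple(experiments))


def _spawn_seed(base_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(base_seed, spawn_key=key))


def iterate_scene(config: SceneConfig, seed: int):
    """Yield ``(plot, truth, stack)`` for every plot-date of the study.

    Deterministic given ``seed``; per-sample random streams are spawned from
    a seed sequence so regeneration is bit-identical and order-independent.
    """
    for ei, exp in enumerate(config.experiments):
        plots = build_design(exp, seed=seed + ei)
        dates = config.flight_dates[exp]
        for fi, date in enumerate(dates):
            stage = STAGES[fi] if fi < len(STAGES) else f"S{fi + 1}"
            for pi, plot in enumerate(plots):
                cultivar = config.cultivars[plot.cultivar_id]
                agb_seed = int(
                    _spawn_seed(seed, ei, fi, pi, 0).integers(0, 2**31 - 1)
                )
                img_seed = int(
                    _spawn_seed(seed, ei, fi, pi, 1).integers(0, 2**31 - 1)
                )
                truth = simulate_agb(
                    plot, cultivar, date, config.agb_params, seed=agb_seed,
                    stage=stage,
                )
                stack = render_plot_image(
                    truth,
                    size=config.image_size,
                    endmembers=config.endmembers,
                    seed=img_seed,
                    noise_sd=config.image_noise_sd,
                )
                yield plot, truth, stack


def ground_truth_table(config: SceneConfig, seed: int) -> pd.DataFrame:
    """Ground-truth table (one row per plot-date) without rendering rasters."""
    rows = []
    for ei, exp in enumerate(config.experiments):
        plots = build_design(exp, seed=seed + ei)
        for fi, date in enumerate(config.flight_dates[exp]):
            stage = STAGES[fi] if fi < len(STAGES) else f"S{fi + 1}"
            for pi, plot in enumerate(plots):
                cultivar = config.cultivars[plot.cultivar_id]
                agb_seed = int(
                    _spawn_seed(seed, ei, fi, pi, 0).integers(0, 2**31 - 1)
                )
                truth = simulate_agb(
                    plot, cultivar, date, config.agb_params, seed=agb_seed,
                    stage=stage,
                )
                rows.append(
                    {
                        "experiment": exp,
                        "plot_id": plot.plot_id,
                        "flight_date": date.isoformat(),
                        "stage": stage,
                        "cultivar": plot.cultivar_id,
                        "density": plot.density,
                        "n_rate": plot.n_rate,
                        "k_rate": plot.k_rate,
                        "block": plot.block,
                        "true_agb": truth.true_agb,
                        "true_cc": truth.true_cc,
                    }
                )
    return pd.DataFrame(rows)


def generate_dataset(config: SceneConfig, seed: int, outdir, *,
                     overwrite: bool = False) -> pd.DataFrame:
    """Write the full synthetic study to ``outdir`` and return the truth table.

    Layout: one multi-band TIFF per plot-date (six float reflectance bands
    then three RGB bands; band metadata in the TIFF description tag), a
    GeoJSON of plot polygons in pixel coordinates, ``weather.csv`` and
    ``ground_truth.csv`` with ISO-8601 dates.
    """
    import tifffile
    from pathlib import Path

    out = Path(outdir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(
            f"output directory {out} is not empty; pass overwrite=True"
        )
    (out / "rasters").mkdir(parents=True, exist_ok=True)

    weather = simulate_weather(config.weather_start, config.weather_end, seed=seed)
    weather.to_csv(out / "weather.csv", index=False)

    h, w = config.image_size
    polygons = []
    rows = []
    for plot, truth, stack in iterate_scene(config, seed):
        name = f"{plot.plot_id}_{truth.flight_date.isoformat()}.tif"
        planes = np.concatenate([stack.ms, stack.rgb / 255.0], axis=-1)
        meta = {
            "plot_id": plot.plot_id,
            "flight_date": truth.flight_date.isoformat(),
            "band_roles": stack.band_roles,
            "extra_bands": ["red_dn", "green_dn", "blue_dn"],
        }
        tifffile.imwrite(
            out / "rasters" / name,
            np.moveaxis(planes.astype(np.float32), -1, 0),
            description=json.dumps(meta),
        )
        rows.append(
            {
                "experiment": plot.experiment_id,
                "plot_id": plot.plot_id,
                "flight_date": truth.flight_date.isoformat(),
                "stage": truth.stage,
                "cultivar": plot.cultivar_id,
                "density": plot.density,
                "n_rate": plot.n_rate,
                "k_rate": plot.k_rate,
                "block": plot.block,
                "true_agb": truth.true_agb,
                "true_cc": truth.true_cc,
                "raster": f"rasters/{name}",
            }
        )
        if not any(p["properties"]["plot_id"] == plot.plot_id for p in polygons):
            polygons.append(
                {
                    "type": "Feature",
                    "properties": {
                        "plot_id": plot.plot_id,
                        "experiment": plot.experiment_id,
                    },
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [
                            [[0, 0], [w, 0], [w, h], [0, h], [0, 0]]
                        ],
                    },
                }
            )

    with open(out / "plots.geojson", "w") as fh:
        json.dump({"type": "FeatureCollection", "features": polygons}, fh)

    truth_df = pd.DataFrame(rows)
    truth_df.to_csv(out / "ground_truth.csv", index=False)

    catalog = pd.DataFrame(
        [
            {
                "cultivar_id": c.cultivar_id,
                "total_period_days": c.total_period_days,
                "emergence_date": c.emergence_date.isoformat(),
                "base_temp": c.base_temp,
            }
            for c in config.cultivars.values()
        ]
    )
    catalog.to_csv(out / "cultivars.csv", index=False)
    return truth_df
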