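"""Seeded synthetic-data generators with known ground truth.

Every analysis stage in this package can be exercised without field
data: these generators emulate the structure of a small, permanently
stratified alpine lake — a warm oxic mixolimnion over a cold, ion-rich
anoxic monimolimnion separated by a chemocline at ~10–12 m, with a
Gaussian-like turbidity peak from the phototrophic-sulfur-bacteria
layer in the lower chemocline — plus cytometer event clouds and
warm-season mountain weather.  Each generator is deterministic for a
fixed seed and returns (or embeds) the exact truth used to build the
data, so recovery tests compare detected against known quantities.

Functional forms are the simplest consistent with the observed
phenomenology: logistic (sigmoid) transitions for temperature, κ20 and
dissolved oxygen across the chemocline, a Gaussian turbidity peak, and
log-normal cytometer clusters.  They are scenario conventions, not
claims about the lake.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit

from .errors import ParameterError, ScenarioError
from .profiles import CTDProfile

SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class LakeScenario:
    """Ground-truth description of one synthetic stratified cast.

    Defaults describe a mid-July situation: ~15 °C surface water over a
    ~4 °C bottom, surface conductivity ~150 µS cm⁻¹ rising to
    ~400 µS cm⁻¹ in the monimolimnion, chemocline centred at 11 m, a
    24-FTU bacterial-layer turbidity peak at 13 m with σ = 0.5 m, and
    oxygen vanishing sigmoidally below the chemocline.
    """

    t_surface: float = 15.0          # degC
    t_bottom: float = 4.0            # degC
    k20_surface: float = 150.0       # uS/cm
    k20_bottom: float = 400.0        # uS/cm
    chemocline_depth: float = 11.0   # m
    chemocline_width: float = 0.8    # m (logistic scale)
    bl_center: float = 13.0          # m
    bl_halfwidth_sigma: float = 0.5  # m (Gaussian sigma)
    bl_peak_ftu: float = 24.0        # FTU above baseline
    turb_baseline_ftu: float = 1.0   # FTU
    do_surface: float = 8.0          # mg/L
    do_cline_width: float = 0.5      # m
    z_bot: float = 21.0              # m
    noise_sd: dict = field(default_factory=lambda: {
        "temperature": 0.01, "conductivity": 0.5,
        "dissolved_oxygen": 0.02, "turbidity": 0.05, "bga_pc": 0.05})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_surface < self.t_bottom:
            raise ScenarioError("t_surface must be >= t_bottom")
        if self.k20_bottom < self.k20_surface:
            raise ScenarioError("k20_bottom must be >= k20_surface")
        if not self.bl_center > self.chemocline_depth:
            raise ScenarioError("bacterial layer must sit below chemocline")
        for w in (self.chemocline_width, self.bl_halfwidth_sigma,
                  self.do_cline_width):
            if w <= 0:
                raise ScenarioError("all widths must be > 0")

    def true_bl_crossings(self, threshold: float = 10.0
                          ) -> tuple[float, float]:
        """Analytic depths where turbidity crosses *threshold*."""
        excess = threshold - self.turb_baseline_ftu
        if not 0 < excess < self.bl_peak_ftu:
            raise ScenarioError("threshold outside the peak's range")
        half = self.bl_halfwidth_sigma * np.sqrt(
            2.0 * np.log(self.bl_peak_ftu / excess))
        return self.bl_center - half, self.bl_center + half


def gen_ctd_profile(
    scenario: LakeScenario = LakeScenario(),
    grid_step: float = 0.1,
    cast_id: str = "synthetic",
    timestamp: datetime | None = None,
) -> CTDProfile:
    """One synthetic CTD cast with the scenario's two-layer structure.

    Temperature and κ20 follow logistic transitions across the
    chemocline; dissolved oxygen decays sigmoidally to zero below it;
    turbidity is a flat baseline plus the bacterial layer's Gaussian
    peak; phycocyanin forms a small peak just above the layer.  Gaussian
    channel noise with the scenario's per-channel sd; channels with
    physical lower bounds are clipped at zero after adding noise.
    """
    s = scenario
    rng = np.random.default_rng(s.seed)
    n = int(round(s.z_bot / grid_step)) + 1
    z = np.linspace(0.0, s.z_bot, n)

    temp = s.t_bottom + (s.t_surface - s.t_bottom) * expit(
        (s.chemocline_depth - z) / s.chemocline_width)
    k20 = s.k20_surface + (s.k20_bottom - s.k20_surface) * expit(
        (z - s.chemocline_depth) / s.chemocline_width)
    do = s.do_surface * expit((s.chemocline_depth - z) / s.do_cline_width)
    turb = s.turb_baseline_ftu + s.bl_peak_ftu * np.exp(
        -((z - s.bl_center) ** 2) / (2.0 * s.bl_halfwidth_sigma ** 2))
    # Cyanobacteria concentrate just above the bacterial layer.
    bga = 2.0 * np.exp(-((z - (s.bl_center - 1.5)) ** 2) / (2.0 * 0.6 ** 2))

    def noisy(x, key, floor=None):
        sd = s.noise_sd.get(key, 0.0)
        if sd > 0:
            x = x + rng.normal(0.0, sd, size=x.shape)
        return np.clip(x, floor, None) if floor is not None else x

    # In-situ conductivity consistent with the linear 2 %/degC model, so
    # normalization recovers the scenario's k20 exactly at zero noise.
    cond_raw = k20 * (1.0 + 0.020 * (temp - 20.0))

    return CTDProfile(
        cast_id=cast_id,
        timestamp=timestamp,
        depth=z,
        temperature=noisy(temp, "temperature"),
        conductivity_raw=noisy(cond_raw, "conductivity", floor=0.0),
        dissolved_oxygen=noisy(do, "dissolved_oxygen", floor=0.0),
        turbidity=noisy(turb, "turbidity", floor=0.0),
        bga_pc=noisy(bga, "bga_pc", floor=0.0),
    )


@dataclass(frozen=True)
class SeasonScenario:
    """A warm-season sequence of casts with drifting layer geometry."""

    n_casts: int = 10
    start: datetime = datetime(2020, 6, 15)
    end: datetime = datetime(2020, 10, 1)
    bl_center_start: float = 12.5    # m
    bl_center_drift: float = 1.5     # m over the whole season (+ = deepens)
    bl_sigma_start: float = 0.5      # m
    bl_sigma_drift: float = 0.0      # m over the season
    base: LakeScenario = LakeScenario()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_casts < 1:
            raise ScenarioError("n_casts must be >= 1")


def gen_season(scenario: SeasonScenario = SeasonScenario(),
               grid_step: float = 0.1
               ) -> tuple[list[CTDProfile], pd.DataFrame]:
    """Season of casts whose layer follows linear trajectories.

    Returns the profiles and a truth table (one row per cast) with the
    exact layer center, sigma, and analytic threshold crossings used to
    build each cast.
    """
    sc = scenario
    frac = (np.linspace(0.0, 1.0, sc.n_casts) if sc.n_casts > 1
            else np.array([0.0]))
    centers = sc.bl_center_start + sc.bl_center_drift * frac
    sigmas = sc.bl_sigma_start + sc.bl_sigma_drift * frac
    span = (sc.end - sc.start).total_seconds()

    profiles, truth = [], []
    for i, (c, sig) in enumerate(zip(centers, sigmas)):
        if not sc.base.chemocline_depth < c < sc.base.z_bot:
            raise ScenarioError(
                f"layer trajectory leaves the water column at cast {i} "
                f"(center {c:.2f} m)")
        if sig <= 0:
            raise ScenarioError(f"layer sigma <= 0 at cast {i}")
        lake = LakeScenario(
            **{**sc.base.__dict__, "bl_center": float(c),
               "bl_halfwidth_sigma": float(sig),
               "seed": sc.seed + 1000 + i})
        when = sc.start + timedelta(seconds=span * float(frac[i]))
        cast_id = f"syn{i:03d}"
        profiles.append(gen_ctd_profile(lake, grid_step, cast_id, when))
        top, bottom = lake.true_bl_crossings()
        truth.append({"cast_id": cast_id, "date": when, "bl_center": c,
                      "bl_sigma": sig, "true_top": top,
                      "true_bottom": bottom})
    return profiles, pd.DataFrame(truth)


#: Default log10 cluster locations: (FSC-A mean, FSC-A sd, FL3-A mean,
#: FL3-A sd).  Size ordering reflects cell diameters: GSB < 1 µm, small
#: PSB ~ 4 µm, large PSB (Chromatium-type) ~ 10 µm.
DEFAULT_CLUSTERS: dict[str, tuple[float, float, float, float]] = {
    "gsb": (4.0, 0.1, 4.0, 0.15),
    "small_psb": (5.0, 0.1, 4.2, 0.15),
    "large_psb": (6.0, 0.1, 4.5, 0.15),
}


def gen_fcm_events(
    fractions: dict[str, float] | None = None,
    n: int = 10_000,
    cluster_params: dict[str, tuple[float, float, float, float]] | None = None,
    debris_fraction: float = 0.0,
    volume_ml: float = 0.05,
    sample_label: str | None = None,
    seed: int = 0,
):
    """Synthetic cytometer events with known phenotype labels.

    Phenotype fractions plus ``debris_fraction`` must sum to 1.  Cluster
    events draw log10(FSC-A) and log10(FL3-A) from per-phenotype
    normals; FSC-H tracks FSC-A (area slightly above height, as for
    near-singlet events).  Debris is drawn strictly below both
    acquisition thresholds (FSC-H < 2000, FL3-A < 1100), so threshold
    retention has the analytic expectation 1 − debris_fraction.

    Returns an :class:`~meromix.cytometry.EventTable` whose events carry
    a ``true_label`` column ('debris' or phenotype) for recovery tests.
    """
    from .cytometry import ALL_CHANNELS, EventTable  # noqa: F401

    if fractions is None:  # equal phenotype shares of the non-debris mass
        share = (1.0 - debris_fraction) / 3.0
        fractions = {"gsb": share, "small_psb": share, "large_psb": share}
    else:
        fractions = dict(fractions)
    clusters = dict(DEFAULT_CLUSTERS, **(cluster_params or {}))
    total = sum(fractions.values()) + debris_fraction
    if abs(total - 1.0) > 1e-9 or min(*fractions.values(),
                                      debris_fraction) < 0:
        raise ParameterError(
            f"fractions + debris must form a simplex; sum = {total}")
    if n < 0:
        raise ParameterError("n must be >= 0")

    rng = np.random.default_rng(seed)
    names = list(fractions) + ["debris"]
    probs = [fractions[k] for k in fractions] + [debris_fraction]
    counts = rng.multinomial(n, probs) if n else np.zeros(len(probs), int)

    parts = []
    for name, m in zip(names, counts):
        if m == 0:
            continue
        if name == "debris":
            fsch = rng.uniform(50.0, 1999.0, m)
            fsca = fsch * rng.uniform(1.0, 1.3, m)
            fl3 = rng.uniform(10.0, 1099.0, m)
        else:
            mu_a, sd_a, mu_f, sd_f = clusters[name]
            fsca = 10.0 ** rng.normal(mu_a, sd_a, m)
            fsch = fsca * rng.uniform(0.75, 0.95, m)
            fl3 = 10.0 ** rng.normal(mu_f, sd_f, m)
        parts.append(pd.DataFrame({
            "FSC-H": fsch, "FSC-A": fsca,
            "FL1-A": rng.uniform(100.0, 1000.0, m),
            "FL2-A": rng.uniform(100.0, 1000.0, m),
            "FL3-A": fl3,
            "FL4-A": rng.uniform(100.0, 1000.0, m),
            "true_label": name,
        }))
    if parts:
        events = pd.concat(parts, ignore_index=True)
        events = events.sample(frac=1.0, random_state=int(seed) % 2**32
                               ).reset_index(drop=True)
    else:
        events = pd.DataFrame(columns=list(ALL_CHANNELS) + ["true_label"])
    return EventTable(events, acquired_volume_ml=volume_ml,
                      sample_label=sample_label)


def gen_meteo(
    days: int = 120,
    start: datetime = datetime(2020, 6, 1),
    mean_temp: float = 8.0,
    seasonal_amplitude: float = 9.0,
    trend: float = 0.0325,          # degC per year
    noise_sd: float = 1.5,          # degC, AR(1) innovations
    ar_coeff: float = 0.8,
    storm_rate: float = 0.15,       # storms per day
    radiation_peak: float = 800.0,  # W m^-2 clear-sky noon peak
    cadence_minutes: float = 10.0,
    seed: int = 0,
):
    """Warm-season mountain weather with storms and a warming trend.

    Air temperature = annual sinusoid (peak late July) + linear trend +
    AR(1) noise.  Rainfall: Poisson storm arrivals (``storm_rate`` per
    day) dropping gamma-distributed depths spread over a few hours.
    Net radiation: clear-sky half-sine diurnal cycle modulated by the
    season, damped to 20 % on storm intervals.  Deterministic per seed.
    """
    from .seasons import MeteoSeries

    if days < 1:
        raise ParameterError("days must be >= 1")
    rng = np.random.default_rng(seed)
    step = timedelta(minutes=cadence_minutes)
    n = int(round(days * SECONDS_PER_DAY / step.total_seconds()))
    idx = pd.date_range(start, periods=n, freq=step)
    t_days = (idx - idx[0]).total_seconds().to_numpy() / SECONDS_PER_DAY
    doy = idx.dayofyear.to_numpy(float) + (
        idx.hour.to_numpy(float) / 24.0)

    seasonal = seasonal_amplitude * np.cos(2 * np.pi * (doy - 205.0) / 365.25)
    trend_part = trend * t_days / 365.25
    if noise_sd > 0:
        innov = rng.normal(0.0, noise_sd * np.sqrt(1 - ar_coeff ** 2), n)
        noise = lfilter([1.0], [1.0, -ar_coeff], innov)
    else:
        noise = np.zeros(n)
    temp = mean_temp + seasonal + trend_part + noise

    rain = np.zeros(n)
    per_interval = step.total_seconds() / SECONDS_PER_DAY
    n_storms = rng.poisson(storm_rate * days)
    storm_idx = np.sort(rng.integers(0, n, size=n_storms)) if n_storms else \
        np.array([], dtype=int)
    storm_mask = np.zeros(n, dtype=bool)
    for i0 in storm_idx:
        depth_mm = rng.gamma(2.0, 6.0)  # mean 12 mm per storm
        dur = max(1, int(rng.uniform(2, 6) * 3600 / step.total_seconds()))
        i1 = min(n, i0 + dur)
        rain[i0:i1] += depth_mm / (i1 - i0)
        storm_mask[i0:i1] = True

    hour = idx.hour.to_numpy(float) + idx.minute.to_numpy(float) / 60.0
    diurnal = np.clip(np.sin(np.pi * (hour - 6.0) / 12.0), 0.0, None)
    season_rad = 0.7 + 0.3 * np.cos(2 * np.pi * (doy - 172.0) / 365.25)
    radiation = radiation_peak * diurnal * season_rad
    radiation[storm_mask] *= 0.2

    df = pd.DataFrame({"temp_c": temp, "netrad_wm2": radiation,
                       "rain_mm": rain}, index=idx)
    truth = {"trend_per_year": trend, "n_storms": int(n_storms),
             "total_rain_mm": float(rain.sum())}
    return MeteoSeries(df), truth
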