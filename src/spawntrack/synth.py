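"""Synthetic survey and telemetry generators with known ground truth.

The telemetry generator emulates a 42-receiver inlet array: a 17-receiver
core array with overlapping ranges covering the spawning site (zones 2-3), two
Gulf-side receivers (zone 1), a transit corridor (zone 4), a northern refuge
(zone 7, containing the heavily used refuge receiver 23), and estuary interior
zones 5-6. Fish presence at the site follows a daily logistic process with a
cyclic seasonal term, a semi-lunar term, a sex offset, and a per-fish random
intercept; present fish visit the site during the 1400-2000 h spawning window
and hold near the refuge before and after, leaving the array overnight.
Detection is Bernoulli per transmission with a logistic distance kernel
calibrated to 50% at the stated half-range.

The survey generator emulates a stratified-random haul-seine survey with
zero-inflated catches: presence is Bernoulli on a logit scale driven by year,
region (concentrated vs not), spawning season, and binned temperature;
positive catches are lognormal driven by year, region, and bottom vegetation.
Salinity is generated but carries no effect, serving as a decoy covariate for
selection tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .residence import _active_mask

V9_DELAY_S = (15.0, 45.0)
V13_DELAY_S = (30.0, 90.0)
V9_BATTERY_DAYS = 149
V13_BATTERY_DAYS = 540
#: V13 annual duty cycle: active 22 March (doy 81) through 20 September (doy 263)
V13_ACTIVE_DOY = (81, 263)


# ---------------------------------------------------------------------------
# Default array geometry and tag cohort
# ---------------------------------------------------------------------------

def default_deployments() -> pd.DataFrame:
    """42-receiver synthetic array mirroring the inlet layout.

    Receivers 3-19 form the core array (zones 2-3, 100 m spacing along the
    beach); receivers 1-2 sit in the Gulf (zone 1); 20-22 and 24 line the
    transit corridor (zone 4); 23 and 25-27 cover the northern refuge
    (zone 7); 28-33 and 34-42 cover the estuary interior (zones 5-6).
    """
    rows = [(1, -420.0, 0.0, 1), (2, -220.0, 0.0, 1)]
    for rid in range(3, 20):
        rows.append((rid, (rid - 3) * 100.0, 0.0, 2 if rid <= 11 else 3))
    rows += [(20, 1750.0, 120.0, 4), (21, 1850.0, 240.0, 4),
             (22, 1950.0, 360.0, 4), (24, 2050.0, 480.0, 4),
             (23, 1800.0, 750.0, 7), (25, 1600.0, 850.0, 7),
             (26, 2000.0, 950.0, 7), (27, 2300.0, 800.0, 7)]
    for rid in range(28, 34):
        rows.append((rid, 2400.0 + (rid - 28) * 180.0, 0.0, 5))
    for rid in range(34, 43):
        rows.append((rid, 3500.0 + (rid - 34) * 160.0, 0.0, 6))
    df = pd.DataFrame(rows, columns=["receiver_id", "easting", "northing", "zone"])
    df["core_array"] = df["receiver_id"].between(3, 19)
    return df.sort_values("receiver_id").reset_index(drop=True)


def default_zone_polygons() -> dict[int, np.ndarray]:
    def box(x0, x1, y0, y1):
        return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])

    return {1: box(-600, -50, -300, 300), 2: box(-50, 850, -300, 300),
            3: box(850, 1650, -300, 300), 4: box(1650, 2350, -300, 600),
            5: box(2350, 3400, -300, 600), 6: box(3400, 4900, -300, 600),
            7: box(1450, 2400, 600, 1100)}


def default_control_tags() -> pd.DataFrame:
    """Three fixed 60 s delay control tags; C1 sits midway between receivers 9 and 10."""
    return pd.DataFrame({
        "control_id": ["C1", "C2", "C3"],
        "easting": [650.0, 2620.0, 3750.0],
        "northing": [0.0, 30.0, 20.0],
        "delay_s": [60.0, 60.0, 60.0],
    })


def make_tags(n_fish: int = 31, v13_fraction: float = 11 / 31,
              implant_start: str = "2007-06-04", seed: int = 0) -> pd.DataFrame:
    """Tag cohort with sexes, sizes, models, and staggered June implant dates.

    Defaults mirror the study cohort: 31 fish, 20 single-season (V9, 149 d)
    and 11 multi-year (V13, 540 d spread over three 22 Mar - 20 Sep seasons);
    female sizes average larger than male (650 vs 591 mm TL).
    """
    rng = np.random.default_rng(seed)
    n_v13 = int(round(n_fish * v13_fraction))
    sexes = np.array(["M", "F"])[np.arange(n_fish) % 2]
    sizes = np.where(sexes == "F", rng.normal(650, 55, n_fish),
                     rng.normal(591, 45, n_fish)).round(0)
    model = np.array(["V9"] * n_fish, dtype=object)
    model[n_fish - n_v13:] = "V13"
    start = pd.Timestamp(implant_start)
    implant = [start + pd.Timedelta(days=int(d), hours=18)
               for d in rng.integers(0, 25, n_fish)]
    df = pd.DataFrame({
        "tag_id": [str(i + 1) for i in range(n_fish)],
        "sex": sexes, "total_length_mm": sizes, "tag_model": model,
        "implant_time": implant,
    })
    df["battery_days"] = np.where(model == "V9", V9_BATTERY_DAYS, V13_BATTERY_DAYS)
    df["active_start_doy"] = np.where(model == "V13", V13_ACTIVE_DOY[0], np.nan)
    df["active_end_doy"] = np.where(model == "V13", V13_ACTIVE_DOY[1], np.nan)
    df["ping_delay_lo"] = np.where(model == "V9", V9_DELAY_S[0], V13_DELAY_S[0])
    df["ping_delay_hi"] = np.where(model == "V9", V9_DELAY_S[1], V13_DELAY_S[1])
    df["censor_date"] = pd.NaT
    return df


# ---------------------------------------------------------------------------
# Truth parameter containers
# ---------------------------------------------------------------------------

@dataclass
class TelemetryTruth:
    """Generating parameters of the daily presence process and detection model.

    Log-odds scale throughout. The seasonal term is
    ``doy_amplitude * cos(2 pi (doy - doy_peak) / 365.25)`` and the lunar term
    ``lunar_amplitude * cos(2 * phase)``, peaking at both new (0/360) and full
    (180) moon. Detection probability per transmission is
    ``1 / (1 + exp(steepness * (distance - halfrange)))``, i.e. 50% at the
    half-range.
    """

    baseline: float = -1.2
    doy_amplitude: float = 1.5
    doy_peak: float = 182.0  # around 1 July
    lunar_amplitude: float = 0.8
    sex_effect: float = 1.0  # male minus female, log-odds
    random_intercept_sd: float = 0.8
    detection_halfrange_m: float = 85.0
    detection_steepness: float = 0.05  # per meter
    spurious_rate: float = 0.02  # stray single detections per tag-day
    refuge_attendance_prob: float = 0.35  # refuge-only array visits on absent days
    site_jitter_m: float = 40.0
    refuge_jitter_m: float = 30.0
    site_hours: tuple = (14, 20)  # [14:00, 20:00)
    refuge_hours: tuple = ((10, 14), (20, 24))

    def __post_init__(self):
        if self.detection_halfrange_m <= 0:
            raise ValueError("detection_halfrange_m must be positive")
        if self.random_intercept_sd < 0:
            raise ValueError("random_intercept_sd must be non-negative")

    def presence_logit(self, doy, lunar_deg, is_male, u=0.0):
        doy = np.asarray(doy, float)
        lunar = np.deg2rad(np.asarray(lunar_deg, float))
        return (self.baseline
                + self.doy_amplitude * np.cos(2 * np.pi * (doy - self.doy_peak) / 365.25)
                + self.lunar_amplitude * np.cos(2.0 * lunar)
                + self.sex_effect * np.asarray(is_male, float) + u)

    def detection_prob(self, distance_m):
        return special.expit(-self.detection_steepness
                             * (np.asarray(distance_m, float) - self.detection_halfrange_m))


@dataclass
class SurveyTruth:
    """Generating parameters of the zero-inflated survey process.

    ``year_effects`` maps year to (log-odds shift, log-mean shift). The
    temperature effect is binwise: shift = ``temperature_slope_per_c`` times
    (bin midpoint - 22.5 C), applied to the presence part only. Vegetation
    shifts the positive-catch log mean only. Salinity has no effect by
    construction.
    """

    presence_intercept: float = -1.55
    region_effect: tuple[float, float] = (1.5, 0.5)  # (log-odds, log-mean)
    season_effect: float = 0.8  # log-odds, spawning season
    temperature_slope_per_c: float = 0.06
    vegetation_effect: float = 0.3  # log-mean
    positive_meanlog: float = 1.1
    positive_sdlog: float = 0.8
    year_effects: dict = field(default_factory=dict)  # year -> (logit, log)
    hotspot_centers: tuple = ((3.0, 7.0), (8.0, 2.0))  # grid-unit coordinates
    hotspot_radius: float = 2.2
    grid_extent: tuple = (0.0, 12.0, 0.0, 10.0)  # x0, x1, y0, y1 (grid units)
    temp_bin_width: float = 2.5

    def __post_init__(self):
        if self.positive_sdlog <= 0:
            raise ValueError("positive_sdlog must be positive")
        if not self.hotspot_centers:
            raise ValueError("at least one hotspot is required")

    def temperature_shift(self, temp_c):
        mid = (np.floor(np.asarray(temp_c, float) / self.temp_bin_width) + 0.5) \
            * self.temp_bin_width
        return self.temperature_slope_per_c * (mid - 22.5)

    def year_effect(self, year):
        return self.year_effects.get(int(year), (0.0, 0.0))

    def true_index(self, years, temps=(17.5, 22.5, 27.5)) -> pd.Series:
        """True standardized index per year: balanced-grid marginal means of
        both parts, back-transformed (with the lognormal half-variance
        correction) and multiplied."""
        out = {}
        grid = [(r, s, t, v) for r in (0, 1) for s in (0, 1) for t in temps
                for v in (0, 1)]
        for y in years:
            ly, lg = self.year_effect(y)
            logits = [self.presence_intercept + ly + self.region_effect[0] * r
                      + self.season_effect * s + self.temperature_shift(t)
                      for r, s, t, v in grid]
            logs = [self.positive_meanlog + lg + self.region_effect[1] * r
                    + self.vegetation_effect * v for r, s, t, v in grid]
            p = special.expit(np.mean(logits))
            mu = np.exp(np.mean(logs) + self.positive_sdlog ** 2 / 2.0)
            out[int(y)] = float(p * mu)
        return pd.Series(out, name="true_index")


def default_survey_truth(years=range(1996, 2013)) -> SurveyTruth:
    """Study-condition defaults: stable abundance through 2008, a 2009 decline,
    and the lowest levels in 2010-2011."""
    year_effects = {}
    for y in years:
        if y <= 2008:
            year_effects[y] = (0.0, 0.0)
        elif y == 2009:
            year_effects[y] = (-0.5, -0.3)
        elif y in (2010, 2011):
            year_effects[y] = (-0.9, -0.5)
        else:
            year_effects[y] = (-0.6, -0.35)
    return SurveyTruth(year_effects=year_effects)


# ---------------------------------------------------------------------------
# Survey simulator
# ---------------------------------------------------------------------------

@dataclass
class SurveySim:
    hauls: pd.DataFrame
    truth: SurveyTruth
    grids: pd.DataFrame  # grid_id, x, y, concentrated_true

    def __iter__(self):  # allow `hauls, truth = simulate_survey(...)`
        return iter((self.hauls, self.truth))


def simulate_survey(truth: SurveyTruth, n_grids: int = 120,
                    years=range(1996, 2013), hauls_per_month: int = 24,
                    seed: int = 0) -> SurveySim:
    """Stratified-random zero-inflated haul-seine survey with known truth.

    Presence per haul is Bernoulli(inverse-logit(linear predictor)); given
    presence the adult count is round(lognormal(meanlog, sdlog)), forced >= 1.
    Grid cells within ``hotspot_radius`` of a hotspot center are the true
    concentrated region.
    """
    years = list(years)
    if n_grids < 4 or len(years) < 2:
        raise ValueError("need n_grids >= 4 and >= 2 years")
    rng = np.random.default_rng(seed)
    x0, x1, y0, y1 = truth.grid_extent
    nx = int(np.ceil(np.sqrt(n_grids * (x1 - x0) / (y1 - y0))))
    ny = int(np.ceil(n_grids / nx))
    gx, gy = np.meshgrid(np.linspace(x0 + 0.5, x1 - 0.5, nx),
                         np.linspace(y0 + 0.5, y1 - 0.5, ny))
    gx, gy = gx.ravel()[:n_grids], gy.ravel()[:n_grids]
    centers = np.asarray(truth.hotspot_centers, float)
    d2 = ((gx[:, None] - centers[None, :, 0]) ** 2
          + (gy[:, None] - centers[None, :, 1]) ** 2).min(axis=1)
    conc = d2 <= truth.hotspot_radius ** 2
    grids = pd.DataFrame({"grid_id": [f"G{i:03d}" for i in range(len(gx))],
                          "x": gx, "y": gy, "concentrated_true": conc})

    n = len(years) * 12 * hauls_per_month
    year = np.repeat(years, 12 * hauls_per_month)
    month = np.tile(np.repeat(np.arange(1, 13), hauls_per_month), len(years))
    gidx = rng.integers(0, len(gx), n)
    day = rng.integers(1, 28, n)
    temp = 22.5 + 7.5 * np.cos(2 * np.pi * (month - 8) / 12.0) + rng.normal(0, 1.5, n)
    sal = np.clip(26.0 + rng.normal(0, 4.0, n), 5.0, 38.0)
    veg = rng.random(n) < 0.4
    spawning = np.isin(month, (4, 5, 6, 7, 8, 9))

    ylogit = np.array([truth.year_effect(y)[0] for y in year])
    ylog = np.array([truth.year_effect(y)[1] for y in year])
    logit_p = (truth.presence_intercept + ylogit
               + truth.region_effect[0] * conc[gidx]
               + truth.season_effect * spawning
               + truth.temperature_shift(temp))
    p = special.expit(logit_p)
    if p.max() == 0.0:
        raise ValueError("degenerate truth: presence probability is zero everywhere")
    present = rng.random(n) < p
    meanlog = (truth.positive_meanlog + ylog
               + truth.region_effect[1] * conc[gidx]
               + truth.vegetation_effect * veg)
    counts = np.where(
        present,
        np.maximum(1, np.round(rng.lognormal(meanlog, truth.positive_sdlog))), 0,
    ).astype(int)

    hauls = pd.DataFrame({
        "haul_id": [f"H{i:06d}" for i in range(n)],
        "date": pd.to_datetime({"year": year, "month": month, "day": day}),
        "grid_id": grids["grid_id"].to_numpy()[gidx],
        "x": gx[gidx], "y": gy[gidx],
        "adult_count": counts,
        "temperature_c": np.round(temp, 2),
        "salinity_ppt": np.round(sal, 2),
        "bottom_vegetation": veg,
        "year": year, "month": month,
        "season": np.where(spawning, "spawning", "non-spawning"),
    })
    return SurveySim(hauls=hauls, truth=truth, grids=grids)


# ---------------------------------------------------------------------------
# Telemetry simulator
# ---------------------------------------------------------------------------

@dataclass
class TelemetrySim:
    detections: pd.DataFrame
    truth_presence: pd.DataFrame  # tag_id, date, present, p_present
    random_intercepts: pd.DataFrame  # tag_id, u

    def __iter__(self):
        return iter((self.detections, self.truth_presence))


def _emit_hours(dates: pd.DatetimeIndex, present: np.ndarray,
                truth: TelemetryTruth, core_xy: np.ndarray,
                refuge_xy: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    """Hour-start timestamps and positions for one fish's within-day track.

    Days present at the spawning site get site hours plus flanking refuge
    hours; a fraction of absent days are refuge-only array visits (fish loiter
    behind the barrier island without moving to the site), so whole-array
    residence exceeds spawning-site residence as in real arrays. The rest of
    the time the fish is outside receiver range.
    """
    ts, xy = [], []
    site_h = range(*truth.site_hours)
    present = present.astype(bool)
    refuge_only = (~present) & (rng.random(len(dates)) < truth.refuge_attendance_prob)
    for d, at_site, at_refuge in zip(dates, present, refuge_only):
        if at_site:
            anchor = core_xy[rng.integers(0, len(core_xy))]
            for h in site_h:
                ts.append(d + pd.Timedelta(hours=h))
                xy.append(anchor + rng.normal(0, truth.site_jitter_m, 2))
        if at_site or at_refuge:
            for lo, hi in truth.refuge_hours:
                for h in range(lo, hi):
                    ts.append(d + pd.Timedelta(hours=h))
                    xy.append(refuge_xy + rng.normal(0, truth.refuge_jitter_m, 2))
    if not ts:
        return np.array([], dtype="datetime64[ns]"), np.empty((0, 2))
    return np.array(ts, dtype="datetime64[ns]"), np.asarray(xy)


def _detect(hour_ts, hour_xy, n_pings, rec_xy, rec_ids, truth, rng,
            p_floor: float = 1e-5):
    """Binomial per-receiver detection counts expanded to timestamped rows.

    Transmissions are detected independently per receiver, so per-receiver
    counts given the ping count are exact binomials; detection times are
    uniform within the hourly emission window.
    """
    if len(hour_ts) == 0:
        return pd.DataFrame(columns=["receiver_id", "timestamp"])
    d = np.sqrt(((hour_xy[:, None, :] - rec_xy[None, :, :]) ** 2).sum(axis=2))
    p = truth.detection_prob(d)
    p[p < p_floor] = 0.0
    counts = rng.binomial(np.asarray(n_pings)[:, None], p)
    hr, rc = np.nonzero(counts)
    k = counts[hr, rc]
    rows_rec = np.repeat(rec_ids[rc], k)
    base = np.repeat(hour_ts[hr], k)
    offs = rng.uniform(0, 3600.0, k.sum())
    return pd.DataFrame({"receiver_id": rows_rec,
                         "timestamp": base + (offs * 1e9).astype("timedelta64[ns]")})


def simulate_telemetry(truth: TelemetryTruth, deployments: pd.DataFrame,
                       tags: pd.DataFrame, control_tags: pd.DataFrame | None,
                       date_range: tuple, seed: int = 0) -> TelemetrySim:
    """Detection table plus daily truth-presence for a tagged cohort.

    Each fish gets an independent random stream spawned from the master seed,
    so adding a fish never perturbs another fish's draws. Pings follow each
    tag's uniform inter-pulse delay and only occur inside the tag's battery /
    duty-cycle window and before its censor date; control tags ping every
    ``delay_s`` seconds around the clock.
    """
    if deployments.empty:
        raise ValueError("deployments must be non-empty")
    dates = pd.date_range(date_range[0], date_range[1], freq="D")
    if len(dates) == 0:
        raise ValueError("empty date range")

    rec_xy = deployments[["easting", "northing"]].to_numpy(float)
    rec_ids = deployments["receiver_id"].to_numpy(int)
    core_xy = deployments.loc[deployments["core_array"],
                              ["easting", "northing"]].to_numpy(float)
    refuge = deployments.loc[deployments["receiver_id"] == 23]
    refuge_xy = (refuge[["easting", "northing"]].to_numpy(float)[0]
                 if len(refuge) else core_xy.mean(axis=0))
    core_rec_ids = rec_ids[deployments["core_array"].to_numpy(bool)]

    master = np.random.SeedSequence(seed)
    streams = master.spawn(len(tags) + 1)
    active = _active_mask(tags, dates)
    doy = dates.dayofyear.to_numpy()
    from .presence import lunar_phase
    lunar = np.array([lunar_phase(d) for d in dates])

    det_frames, truth_rows, u_rows = [], [], []
    for (_, tag), seq in zip(tags.iterrows(), streams):
        rng = np.random.default_rng(seq)
        u = rng.normal(0.0, truth.random_intercept_sd)
        u_rows.append({"tag_id": tag["tag_id"], "u": u})
        on = active[tag["tag_id"]].to_numpy(bool)
        p = special.expit(truth.presence_logit(doy, lunar, tag["sex"] == "M", u))
        present = np.zeros(len(dates), dtype=int)
        present[on] = (rng.random(on.sum()) < p[on]).astype(int)
        truth_rows.append(pd.DataFrame({"tag_id": tag["tag_id"], "date": dates,
                                        "active": on, "present": present,
                                        "p_present": np.where(on, p, 0.0)}))
        hour_ts, hour_xy = _emit_hours(dates[on], present[on], truth, core_xy,
                                       refuge_xy, rng)
        if len(hour_ts):
            mean_delay = (tag["ping_delay_lo"] + tag["ping_delay_hi"]) / 2.0
            n_pings = rng.poisson(3600.0 / mean_delay, len(hour_ts))
            det = _detect(hour_ts, hour_xy, n_pings, rec_xy, rec_ids, truth, rng)
            det["tag_id"] = tag["tag_id"]
            det_frames.append(det)
        # stray single detections (code collisions) at random core receivers
        if truth.spurious_rate > 0:
            n_spur = rng.poisson(truth.spurious_rate * len(dates))
            if n_spur:
                sp_dates = dates[rng.integers(0, len(dates), n_spur)]
                secs = rng.uniform(0, 86400.0, n_spur)
                det_frames.append(pd.DataFrame({
                    "receiver_id": core_rec_ids[rng.integers(0, len(core_rec_ids), n_spur)],
                    "timestamp": sp_dates.to_numpy()
                    + (secs * 1e9).astype("timedelta64[ns]"),
                    "tag_id": tag["tag_id"],
                }))

    if control_tags is not None and len(control_tags):
        rng = np.random.default_rng(streams[-1])
        hours = pd.date_range(dates[0], dates[-1] + pd.Timedelta(hours=23), freq="h")
        for _, ct in control_tags.iterrows():
            hour_ts = hours.to_numpy()
            hour_xy = np.tile([ct["easting"], ct["northing"]], (len(hours), 1))
            n_pings = np.full(len(hours), int(round(3600.0 / ct["delay_s"])))
            det = _detect(hour_ts, hour_xy, n_pings, rec_xy, rec_ids, truth, rng)
            det["tag_id"] = str(ct["control_id"])
            det_frames.append(det)

    if det_frames:
        detections = pd.concat(det_frames, ignore_index=True)
        detections = (detections[["tag_id", "receiver_id", "timestamp"]]
                      .sort_values(["tag_id", "timestamp"], kind="mergesort")
                      .reset_index(drop=True))
    else:
        detections = pd.DataFrame(columns=["tag_id", "receiver_id", "timestamp"])
    if truth_rows:
        truth_presence = pd.concat(truth_rows, ignore_index=True)
    else:
        truth_presence = pd.DataFrame(columns=["tag_id", "date", "active",
                                               "present", "p_present"])
    return TelemetrySim(detections=detections, truth_presence=truth_presence,
                        random_intercepts=pd.DataFrame(u_rows))


def simulate_presence_records(truth: TelemetryTruth, n_fish: int = 30,
                              date_range=("2007-04-01", "2007-09-30"),
                              seed: int = 0) -> pd.DataFrame:
    """Presence records drawn directly from the daily logistic process.

    Bypasses the detection layer: one Bernoulli presence draw per fish-day
    with the same linear predictor the full simulator uses. Intended for
    model-calibration studies (e.g. null-effect replicates) where the
    detection pipeline is exercised separately.
    """
    from .presence import lunar_phase

    rng = np.random.default_rng(seed)
    dates = pd.date_range(*date_range, freq="D")
    doy = dates.dayofyear.to_numpy()
    lunar = np.array([lunar_phase(d) for d in dates])
    rows = []
    for i in range(n_fish):
        sex = "M" if i % 2 == 0 else "F"
        size = rng.normal(591 if sex == "M" else 650, 50)
        u = rng.normal(0.0, truth.random_intercept_sd)
        p = special.expit(truth.presence_logit(doy, lunar, sex == "M", u))
        rows.append(pd.DataFrame({
            "tag_id": f"F{i:03d}", "date": dates,
            "present": (rng.random(len(dates)) < p).astype(int),
            "sex": sex, "total_length_mm": round(size),
            "doy": doy, "lunar_deg": lunar, "year": dates.year,
        }))
    return pd.concat(rows, ignore_index=True)
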