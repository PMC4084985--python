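"""Detection filtering, weighted-means positioning, zone assignment, control-tag audit.

The processing chain mirrors standard passive-telemetry practice: drop
presumed-spurious single detections, split off the post-release acclimation
period, truncate dead or shed tags, then collapse detections to hourly
weighted-mean positions on two location scales (planar coordinates and
receiver number) and label each position with a monitoring zone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath


def filter_spurious(detections: pd.DataFrame, deployments: pd.DataFrame,
                    window: str = "day") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove single core-array detections per tag per 24 h period.

    A lone detection of a transmitter code in the core array within a 24 h
    period is treated as a false detection (code collision) and removed;
    everything else is kept. ``window='day'`` uses the local calendar day,
    the documented default; ``'rolling'`` uses a centred 24 h neighbourhood.
    Returns ``(kept, removed)``; the two partition the input exactly.
    """
    core = set(deployments.loc[deployments["core_array"], "receiver_id"])
    is_core = detections["receiver_id"].isin(core)
    if window == "day":
        period = detections["timestamp"].dt.normalize()
        grp = detections.groupby([detections["tag_id"], period.where(is_core)],
                                 dropna=True, sort=False)
        core_count = grp["receiver_id"].transform("size")
        removed_mask = is_core & (core_count == 1)
    elif window == "rolling":
        removed_mask = pd.Series(False, index=detections.index)
        for tag, sub in detections[is_core].groupby("tag_id", sort=False):
            t = sub["timestamp"].to_numpy()
            # a core detection is spurious if no other core detection of the
            # same tag lies within +/- 24 h
            order = np.argsort(t)
            ts_sorted = t[order]
            lone = np.ones(len(ts_sorted), dtype=bool)
            if len(ts_sorted) > 1:
                prev_gap = np.diff(ts_sorted) <= np.timedelta64(24, "h")
                lone[1:] &= ~prev_gap
                lone[:-1] &= ~prev_gap
            removed_mask.loc[sub.index[order[lone]]] = True
    else:
        raise ValueError(f"window must be 'day' or 'rolling', got {window!r}")
    removed_mask = removed_mask.fillna(False).astype(bool)
    return (detections[~removed_mask].reset_index(drop=True),
            detections[removed_mask].reset_index(drop=True))


def split_post_release(detections: pd.DataFrame, tags: pd.DataFrame,
                       window_h: float = 48.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition detections into post-release (< window_h after implant) and study period."""
    implant = tags.set_index("tag_id")["implant_time"]
    missing = sorted(set(detections["tag_id"]) - set(implant.index))
    if missing or implant.isna().any():
        bad = missing or implant.index[implant.isna()].tolist()
        raise ValueError(f"tags without implant_time: {bad}")
    cutoff = detections["tag_id"].map(implant) + pd.to_timedelta(window_h, unit="h")
    post = detections["timestamp"] < cutoff
    return (detections[post].reset_index(drop=True),
            detections[~post].reset_index(drop=True))


def apply_censoring(detections: pd.DataFrame, tags: pd.DataFrame) -> pd.DataFrame:
    """Drop detections after each tag's censor date (death or tag loss).

    Detections on the censor date itself are retained: the censor date is the
    last date the fish was considered alive.
    """
    if "censor_date" not in tags.columns or tags["censor_date"].isna().all():
        return detections.copy()
    censor = tags.set_index("tag_id")["censor_date"]
    limit = detections["tag_id"].map(censor)
    keep = limit.isna() | (detections["timestamp"].dt.normalize() <= limit)
    return detections[keep].reset_index(drop=True)


def flag_stationary(detections: pd.DataFrame, min_days: int = 14,
                    receiver_spread: int = 1) -> pd.DataFrame:
    """Flag tags pinned to a narrow band of adjacent receivers for a long run.

    Candidate mortality/tag-loss events: runs of >= ``min_days`` consecutive
    detected days whose receivers span at most ``receiver_spread`` adjacent
    receiver numbers. Returns one row per flagged run with its onset date.
    Supports the manual dead-fish call; it does not make it.
    """
    out = []
    daily = (detections.assign(date=detections["timestamp"].dt.normalize())
             .groupby(["tag_id", "date"])["receiver_id"].agg(["min", "max"])
             .reset_index())
    for tag, sub in daily.groupby("tag_id", sort=False):
        sub = sub.sort_values("date")
        dates = sub["date"].to_numpy()
        start = 0
        lo, hi = sub["min"].iloc[0], sub["max"].iloc[0]
        n = len(sub)
        for i in range(1, n + 1):
            contiguous = i < n and (dates[i] - dates[i - 1]) == np.timedelta64(1, "D")
            if contiguous:
                nlo = min(lo, sub["min"].iloc[i])
                nhi = max(hi, sub["max"].iloc[i])
                if nhi - nlo + 1 <= receiver_spread:
                    lo, hi = nlo, nhi
                    continue
            run_days = int((dates[i - 1] - dates[start]) / np.timedelta64(1, "D")) + 1
            if run_days >= min_days and hi - lo + 1 <= receiver_spread:
                out.append({"tag_id": tag, "onset_date": pd.Timestamp(dates[start]),
                            "n_days": run_days, "receiver_lo": lo, "receiver_hi": hi})
            if i < n:
                start = i
                lo, hi = sub["min"].iloc[i], sub["max"].iloc[i]
    return pd.DataFrame(out, columns=["tag_id", "onset_date", "n_days",
                                      "receiver_lo", "receiver_hi"])


def estimate_positions(detections: pd.DataFrame, deployments: pd.DataFrame,
                       bin_hours: float = 1.0,
                       zone_map: "ZoneMap | None" = None) -> pd.DataFrame:
    """Weighted-means positions per (tag, clock-aligned hourly bin).

    Each detection contributes one unit of weight at its receiver, so the bin
    position is the detection-count-weighted mean of receiver coordinates and
    the mean receiver number is the same weighting applied to receiver ids.
    Bins are half-open ``[HH:00, HH+1:00)`` in local EST.
    """
    dep = deployments.set_index("receiver_id")
    df = detections.copy()
    df["bin_start"] = df["timestamp"].dt.floor(f"{int(bin_hours * 60)}min")
    df["easting"] = df["receiver_id"].map(dep["easting"])
    df["northing"] = df["receiver_id"].map(dep["northing"])
    pos = (df.groupby(["tag_id", "bin_start"], sort=True)
           .agg(easting=("easting", "mean"), northing=("northing", "mean"),
                mean_receiver_number=("receiver_id", "mean"),
                n_detections=("receiver_id", "size"))
           .reset_index())
    if zone_map is not None:
        pos["zone"] = zone_map.assign(pos["easting"].to_numpy(),
                                      pos["northing"].to_numpy())
    return pos


@dataclass
class ZoneMap:
    """Zone geometry: optional polygons per zone plus receiver fallbacks.

    A position gets the zone of the polygon containing it; points outside all
    polygons (or on shared boundaries, where containment is ambiguous) go to
    the nearest zone centroid. Without polygons the zone of the nearest
    receiver is used, which is the Voronoi partition of receivers merged by
    zone.
    """

    receiver_xy: np.ndarray  # (n, 2)
    receiver_zone: np.ndarray  # (n,)
    polygons: dict[int, np.ndarray] = field(default_factory=dict)  # zone -> (m, 2) vertices

    @classmethod
    def from_deployments(cls, deployments: pd.DataFrame,
                         polygons: dict[int, np.ndarray] | None = None) -> "ZoneMap":
        dep = deployments.dropna(subset=["zone"])
        return cls(receiver_xy=dep[["easting", "northing"]].to_numpy(float),
                   receiver_zone=dep["zone"].to_numpy(int),
                   polygons=polygons or {})

    def _centroids(self) -> tuple[np.ndarray, np.ndarray]:
        zones = np.unique(self.receiver_zone)
        cents = np.array([self.receiver_xy[self.receiver_zone == z].mean(axis=0)
                          for z in zones])
        return zones, cents

    def assign(self, easting, northing) -> np.ndarray:
        pts = np.column_stack([np.asarray(easting, float), np.asarray(northing, float)])
        out = np.zeros(len(pts), dtype=int)
        if self.polygons:
            hits = np.zeros(len(pts), dtype=int)
            for zone, verts in self.polygons.items():
                inside = MplPath(verts).contains_points(pts)
                newly = inside & (out == 0)
                out[newly] = zone
                hits += inside.astype(int)
            ambiguous = (hits != 1)
        else:
            ambiguous = np.ones(len(pts), dtype=bool)
        if ambiguous.any():
            if self.polygons:
                zones, cents = self._centroids_from_polygons()
            else:
                zones, cents = self._centroids()
            d2 = ((pts[ambiguous, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
            out[ambiguous] = zones[np.argmin(d2, axis=1)]
        return out

    def _centroids_from_polygons(self) -> tuple[np.ndarray, np.ndarray]:
        zones = np.array(sorted(self.polygons))
        cents = np.array([self.polygons[z].mean(axis=0) for z in zones])
        return zones, cents


def assign_zone(positions: pd.DataFrame, zone_map: ZoneMap) -> pd.DataFrame:
    """Zone-label a position table (adds/overwrites the ``zone`` column)."""
    out = positions.copy()
    out["zone"] = zone_map.assign(out["easting"].to_numpy(), out["northing"].to_numpy())
    return out


def audit_control_tags(detections: pd.DataFrame, control_tags: pd.DataFrame,
                       deployments: pd.DataFrame,
                       zone_map: ZoneMap | None = None,
                       error_threshold_m: float = 200.0) -> pd.DataFrame:
    """Position-error and detection-rate audit for fixed control tags.

    Easting error is the audited quantity (positions here resolve along the
    channel axis); the full Euclidean error is also reported. The detection
    rate divides detections logged by the receiver nearest each control tag by
    the number of transmissions expected from its fixed delay over the span
    between its first and last detection.
    """
    rows = []
    for _, ct in control_tags.iterrows():
        sub = detections[detections["tag_id"] == str(ct["control_id"])]
        if sub.empty:
            continue
        pos = estimate_positions(sub, deployments, zone_map=zone_map)
        err_e = np.abs(pos["easting"] - ct["easting"])
        err_full = np.hypot(pos["easting"] - ct["easting"], pos["northing"] - ct["northing"])
        dxy = deployments[["easting", "northing"]].to_numpy(float) - \
            np.array([ct["easting"], ct["northing"]], float)
        nearest = deployments["receiver_id"].iloc[int(np.argmin((dxy ** 2).sum(axis=1)))]
        span_s = (sub["timestamp"].max() - sub["timestamp"].min()).total_seconds()
        expected = max(span_s / float(ct["delay_s"]), 1.0)
        detected = int((sub["receiver_id"] == nearest).sum())
        zone = (int(zone_map.assign([ct["easting"]], [ct["northing"]])[0])
                if zone_map is not None else -1)
        rows.append({
            "control_id": ct["control_id"], "zone": zone,
            "mean_error_m": float(err_e.mean()),
            "se_error_m": float(err_e.std(ddof=1) / np.sqrt(len(err_e))) if len(err_e) > 1 else 0.0,
            "fraction_gt_200m": float((err_e > error_threshold_m).mean()),
            "mean_euclidean_error_m": float(err_full.mean()),
            "detection_rate": float(min(detected / expected, 1.0)),
            "n_bins": len(pos),
        })
    return pd.DataFrame(rows)
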