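"""Site geometry: coordinate rotation, depth strata, areas, cruise route.

The survey grid sits on a continental shelf whose inner–outer axis runs
NW–SE.  Rotating the coordinates so this axis aligns with N–S turns the
cross-shelf position into a single covariate, the *rotated latitude* rλ,
which carries the geographic size-at-age gradient.  The cruise route is
modelled as the rank order of rotated latitude (SE sites first), matching a
survey that starts in the SE inner-middle shelf and works toward the NW.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: depth cuts (m) separating inner / middle / outer shelf strata
STRATUM_CUTS = (50.0, 100.0)

#: default rotation aligning a NW–SE shelf axis with N–S (clockwise 45°)
DEFAULT_ROTATION_ANGLE = -np.pi / 4


def rotate_coordinates(
    longitude: np.ndarray,
    latitude: np.ndarray,
    angle: float,
    pivot: tuple[float, float] | None = None,
):
    """Planar rotation of (longitude, latitude) about a pivot.

    Parameters
    ----------
    angle
        Rotation angle in radians, counter-clockwise positive.
    pivot
        (lon, lat) pivot; defaults to the centroid of the point cloud.

    Returns
    -------
    (rotated_longitude, rotated_latitude) arrays.  Pairwise distances are
    preserved exactly (planar treatment; geodesy is out of scope at survey
    scale).
    """
    lon = np.asarray(longitude, dtype=float)
    lat = np.asarray(latitude, dtype=float)
    if pivot is None:
        pivot = (float(np.mean(lon)), float(np.mean(lat)))
    px, py = pivot
    c, s = np.cos(angle), np.sin(angle)
    dx, dy = lon - px, lat - py
    return px + c * dx - s * dy, py + s * dx + c * dy


def depth_stratum(depth: np.ndarray) -> np.ndarray:
    """Classify depths (m) into inner (<50), middle (50–100), outer (>100)."""
    depth = np.asarray(depth, dtype=float)
    out = np.where(depth < STRATUM_CUTS[0], "inner", np.where(depth <= STRATUM_CUTS[1], "middle", "outer"))
    return out.astype(object)


def build_site_table(
    hauls: pd.DataFrame,
    rotation_angle: float = DEFAULT_ROTATION_ANGLE,
    pivot: tuple[float, float] | None = None,
    area_boundary: float | None = None,
) -> pd.DataFrame:
    """Derive the sampling-site table from a haul table.

    Sites are the unique (longitude, latitude) locations; the survey revisits
    the same stations every year.  The returned frame has one row per site:
    ``site_id, longitude, latitude, rotated_longitude, rotated_latitude,
    depth, stratum, area, route_index``.

    * ``stratum``: inner/middle/outer by the 50/100 m depth cuts.
    * ``area``: NW vs SE split at ``area_boundary`` on rotated latitude
      (default: the median, giving a balanced split).
    * ``route_index``: rank of rotated latitude ascending, so the SE end of
      the shelf is visited first.
    """
    sites = (
        hauls.groupby(["longitude", "latitude"], as_index=False)
        .agg(depth=("depth", "mean"))
        .reset_index(drop=True)
    )
    rlon, rlat = rotate_coordinates(
        sites["longitude"].to_numpy(), sites["latitude"].to_numpy(), rotation_angle, pivot
    )
    # rλ is centered on the domain mean so the geographic term of the
    # size-at-age relation is a deviation effect, not an absolute offset
    sites["rotated_longitude"] = rlon - np.mean(rlon)
    sites["rotated_latitude"] = rlat - np.mean(rlat)
    sites["stratum"] = depth_stratum(sites["depth"].to_numpy())
    if area_boundary is None:
        area_boundary = float(np.median(sites["rotated_latitude"]))
    sites["area"] = np.where(sites["rotated_latitude"] > area_boundary, "NW", "SE").astype(object)
    order = np.argsort(sites["rotated_latitude"].to_numpy(), kind="stable")
    route = np.empty(len(sites), dtype=int)
    route[order] = np.arange(len(sites))
    sites["route_index"] = route
    sites.insert(0, "site_id", [f"S{i:04d}" for i in range(len(sites))])
    return sites
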