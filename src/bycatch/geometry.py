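"""Study-domain geometry: ocean boundary, coastline barriers, fishing zones.

The study region is a rectangle of ocean in geographic coordinates with a
piecewise-linear "coastline" barrier along its western edge and a set of named
fishing zones tiling the open-water part.  All distance-based computation
(meshes, Matérn ranges, the 50-mile redistribution rule) happens in planar
kilometres obtained by equirectangular scaling about the domain mid-latitude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon, mapping, shape

KM_PER_DEG_LAT = 110.574
KM_PER_DEG_LON_EQ = 111.320


@dataclass
class DomainSpec:
    """Ocean study domain with barrier polygons and named fishing zones.

    All polygons are in degrees (lon, lat).  ``planar_scale`` holds the
    km-per-degree factors ``(kx, ky)`` used for the planar projection.
    """

    boundary: Polygon
    barriers: list[Polygon] = field(default_factory=list)
    zones: dict[str, Polygon] = field(default_factory=dict)
    planar_scale: tuple[float, float] = (KM_PER_DEG_LON_EQ, KM_PER_DEG_LAT)

    # -- projection -------------------------------------------------------
    def to_planar(self, lon, lat):
        """Project degrees to planar km about the domain origin."""
        lon0, lat0 = self.origin
        kx, ky = self.planar_scale
        return (np.asarray(lon) - lon0) * kx, (np.asarray(lat) - lat0) * ky

    def from_planar(self, x, y):
        lon0, lat0 = self.origin
        kx, ky = self.planar_scale
        return np.asarray(x) / kx + lon0, np.asarray(y) / ky + lat0

    @property
    def origin(self) -> tuple[float, float]:
        minx, miny, _, _ = self.boundary.bounds
        return minx, miny

    def polygon_planar(self, poly: Polygon) -> Polygon:
        ext = np.asarray(poly.exterior.coords)
        x, y = self.to_planar(ext[:, 0], ext[:, 1])
        return Polygon(np.column_stack([x, y]))

    # -- membership -------------------------------------------------------
    def in_water(self, lon, lat) -> np.ndarray:
        """True where a point is inside the boundary and outside every barrier."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        ok = shapely.contains_xy(self.boundary, lon, lat)
        for b in self.barriers:
            ok &= ~shapely.contains_xy(b, lon, lat)
        return ok

    def zone_of(self, lon, lat) -> np.ndarray:
        """Zone code per point ('' where no zone contains the point)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        out = np.full(lon.shape, "", dtype=object)
        for name, poly in self.zones.items():
            hit = shapely.contains_xy(poly, lon, lat) & (out == "")
            out[hit] = name
        return out

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        for b in self.barriers:
            if not self.boundary.covers(b):
                raise ValueError("barrier polygon extends outside the boundary")
        names = list(self.zones)
        for i, a in enumerate(names):
            if not self.boundary.covers(self.zones[a]):
                raise ValueError(f"zone {a} extends outside the boundary")
            for b in names[i + 1:]:
                inter = self.zones[a].intersection(self.zones[b])
                if inter.area > 1e-9:
                    raise ValueError(f"zones {a} and {b} overlap")

    # -- serialization ----------------------------------------------------
    def to_geojson(self) -> dict:
        feats = [{"type": "Feature",
                  "properties": {"role": "boundary"},
                  "geometry": mapping(self.boundary)}]
        for i, b in enumerate(self.barriers):
            feats.append({"type": "Feature",
                          "properties": {"role": "barrier", "index": i},
                          "geometry": mapping(b)})
        for name, z in self.zones.items():
            feats.append({"type": "Feature",
                          "properties": {"role": "zone", "name": name},
                          "geometry": mapping(z)})
        return {"type": "FeatureCollection",
                "properties": {"planar_scale": list(self.planar_scale)},
                "features": feats}

    @classmethod
    def from_geojson(cls, obj: dict) -> "DomainSpec":
        boundary = None
        barriers, zones = [], {}
        for f in obj["features"]:
            geom = shape(f["geometry"])
            role = f["properties"]["role"]
            if role == "boundary":
                boundary = geom
            elif role == "barrier":
                barriers.append(geom)
            else:
                zones[f["properties"]["name"]] = geom
        scale = tuple(obj.get("properties", {}).get(
            "planar_scale", (KM_PER_DEG_LON_EQ, KM_PER_DEG_LAT)))
        return cls(boundary=boundary, barriers=barriers, zones=zones,
                   planar_scale=scale)

    def write_geojson(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_geojson(), fh, indent=1)

    @classmethod
    def read_geojson(cls, path) -> "DomainSpec":
        with open(path, encoding="utf-8") as fh:
            return cls.from_geojson(json.load(fh))


def gen_domain(seed: int,
               lon_range: tuple[float, float] = (-80.0, -65.0),
               lat_range: tuple[float, float] = (28.0, 42.0),
               coast_max_lon: float = -77.2) -> DomainSpec:
    """Stylized study region: rectangular ocean with a jagged western coastline.

    The coastline barrier runs the full latitude span of the western edge; its
    eastern boundary is a seeded piecewise-linear polyline (one vertex per
    degree of latitude).  Six named zones tile the open water east of the
    coastline's maximum reach; three of them (MAB, NEC, SAB) play the role of
    the contiguous high-bycatch shelf zones.
    """
    rng = np.random.default_rng(seed)
    lon_w, lon_e = lon_range
    lat_s, lat_n = lat_range
    mid_lat = 0.5 * (lat_s + lat_n)
    scale = (KM_PER_DEG_LON_EQ * float(np.cos(np.radians(mid_lat))),
             KM_PER_DEG_LAT)

    boundary = Polygon([(lon_w, lat_s), (lon_e, lat_s),
                        (lon_e, lat_n), (lon_w, lat_n)])

    # jagged coastline: base longitude ~2 deg east of the west edge
    base = lon_w + 2.0
    lats = np.arange(lat_s, lat_n + 1e-9, 1.0)
    jitter = rng.uniform(-0.7, min(0.7, coast_max_lon - base), size=lats.size)
    coast_lons = np.clip(base + jitter, lon_w + 0.3, coast_max_lon)
    coast = [(lon_w, lat_s)] + list(zip(coast_lons, lats)) + [(lon_w, lat_n)]
    barrier = Polygon(coast)
    if not barrier.is_valid:
        barrier = barrier.buffer(0)

    x0 = coast_max_lon  # zones start east of the coastline's maximal reach
    lat_mid1, lat_mid2 = 31.5, 35.5
    lat_nec = 39.0
    lon_split = -71.0
    zones = {
        "NEC": Polygon([(x0, lat_nec), (lon_e, lat_nec),
                        (lon_e, lat_n), (x0, lat_n)]),
        "MAB": Polygon([(x0, lat_mid2), (lon_e, lat_mid2),
                        (lon_e, lat_nec), (x0, lat_nec)]),
        "SAB": Polygon([(x0, lat_mid1), (lon_split, lat_mid1),
                        (lon_split, lat_mid2), (x0, lat_mid2)]),
        "FEC": Polygon([(x0, lat_s), (lon_split, lat_s),
                        (lon_split, lat_mid1), (x0, lat_mid1)]),
        "GOM": Polygon([(lon_split, lat_s), (lon_e, lat_s),
                        (lon_e, lat_mid1), (lon_split, lat_mid1)]),
        "SAR": Polygon([(lon_split, lat_mid1), (lon_e, lat_mid1),
                        (lon_e, lat_mid2), (lon_split, lat_mid2)]),
    }

    dom = DomainSpec(boundary=boundary, barriers=[barrier], zones=zones,
                     planar_scale=scale)
    dom.validate()
    return dom


# Zones treated as the contiguous high-bycatch shelf sub-region.
HIGH_BYCATCH_ZONES = ("MAB", "NEC", "SAB")


def subdomain(domain: DomainSpec, zone_names) -> DomainSpec:
    """Restrict a domain to the union of the named zones (barriers clipped)."""
    polys = [domain.zones[z] for z in zone_names]
    boundary = shapely.union_all(polys)
    barriers = [b.intersection(boundary) for b in domain.barriers]
    barriers = [b for b in barriers if not b.is_empty and b.area > 0]
    return DomainSpec(boundary=boundary, barriers=barriers,
                      zones={z: domain.zones[z] for z in zone_names},
                      planar_scale=domain.planar_scale)
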