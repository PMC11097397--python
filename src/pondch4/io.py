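"""File formats: pond inventories (CSV/GeoJSON), climate and surface series,
inventory tables and run metadata sidecars."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from shapely.geometry import shape

from pondch4.inventory import SQM_PER_HA

__all__ = [
    "read_ponds_csv",
    "write_ponds_csv",
    "read_ponds_geojson",
    "read_climate_csv",
    "read_surfaces_csv",
    "read_fractions_csv",
    "write_inventory_csv",
    "write_sidecar",
]

POND_COLUMNS = [
    "id",
    "region",
    "lat",
    "lon",
    "max_area_ha",
    "perimeter_m",
    "established_year",
    "zone",
]


def read_ponds_csv(path: str | Path) -> pd.DataFrame:
    """Read a pond inventory CSV; `id`, `region`, `max_area_ha` are required,
    the other columns optional."""
    df = pd.read_csv(path)
    missing = {"id", "region", "max_area_ha"} - set(df.columns)
    if missing:
        raise ValueError(f"pond CSV missing columns: {sorted(missing)}")
    return df


def write_ponds_csv(ponds: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in POND_COLUMNS if c in ponds.columns]
    ponds[cols].to_csv(path, index=False)


def read_ponds_geojson(path: str | Path) -> pd.DataFrame:
    """Read ponds from GeoJSON polygon features.

    Geometry coordinates are assumed to be in a planar equal-area projection
    in metres; area (ha) and perimeter (m) are derived from the geometry, and
    `id`/`region` and other attributes come from feature properties.
    """
    data = json.loads(Path(path).read_text())
    rows = []
    for i, feat in enumerate(data.get("features", [])):
        geom = shape(feat["geometry"])
        props = dict(feat.get("properties") or {})
        rows.append(
            {
                "id": props.get("id", f"feature_{i}"),
                "region": props.get("region", "UNKNOWN"),
                "lat": props.get("lat"),
                "lon": props.get("lon"),
                "max_area_ha": geom.area / SQM_PER_HA,
                "perimeter_m": geom.length,
                "established_year": props.get("established_year"),
                "zone": props.get("zone"),
            }
        )
    return pd.DataFrame(rows)


def read_climate_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"region", "year", "month", "temp_c", "rain_mm"} - set(df.columns)
    if missing:
        raise ValueError(f"climate CSV missing columns: {sorted(missing)}")
    return df


def read_surfaces_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"pond_id", "year", "month", "area_ha"} - set(df.columns)
    if missing:
        raise ValueError(f"surface CSV missing columns: {sorted(missing)}")
    return df


def read_fractions_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"pond_id", "year", "month", "fraction"} - set(df.columns)
    if missing:
        raise ValueError(f"fraction CSV missing columns: {sorted(missing)}")
    return df


def write_inventory_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def write_sidecar(path: str | Path, seed: int, config_text: str, **extra) -> None:
    """Run-metadata sidecar: seed and a hash of the resolved configuration."""
    meta = {
        "seed": seed,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        **extra,
    }
    Path(path).write_text(json.dumps(meta, indent=2))
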