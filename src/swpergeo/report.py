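"""Reporting deliverables: choropleth bins, geometry dissolve, box-plot data,
map rendering.

Geometry is handled as plain GeoJSON (feature id + shapely geometry); the
package ships no administrative boundary data — users supply their own
geometry files, e.g. district polygons or assembly-constituency polygons to
be dissolved into updated district boundaries.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.ops import unary_union

from .errors import MappingError

__all__ = [
    "GeometryTable",
    "ChoroplethSpec",
    "equal_interval_bins",
    "dissolve_units",
    "export_boxplot_data",
    "render_maps",
    "read_geojson",
    "write_geojson",
]


@dataclass
class GeometryTable:
    """Unit id, shapely geometry, optional parent id and numeric attributes."""

    table: pd.DataFrame  # columns: unit_id, geometry, [parent_id], attrs...

    def __post_init__(self):
        if "unit_id" not in self.table.columns or "geometry" not in self.table.columns:
            raise ValueError("GeometryTable needs unit_id and geometry columns")
        if self.table["unit_id"].duplicated().any():
            dupes = self.table["unit_id"][self.table["unit_id"].duplicated()].tolist()
            raise ValueError(f"duplicate unit ids: {dupes}")
        # repair invalid rings (self-intersections) with the zero-buffer trick
        self.table = self.table.copy()
        self.table["geometry"] = [
            g if g.is_valid else g.buffer(0) for g in self.table["geometry"]
        ]

    @property
    def unit_ids(self):
        return self.table["unit_id"].tolist()

    def total_area(self) -> float:
        return float(sum(g.area for g in self.table["geometry"]))


@dataclass(frozen=True)
class ChoroplethSpec:
    """Classification used for the maps: equal intervals, default 10 classes."""

    variable: str
    k: int = 10
    mode: str = "equal_interval"
    cmap: str = "viridis"

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("class count must be >= 2")
        if self.mode != "equal_interval":
            raise ValueError(f"unsupported classification mode {self.mode!r}")


def equal_interval_bins(values, k: int = 10):
    """k equal-width bins over [min, max]; lower-closed, max goes to the top bin.

    Returns (edges, assignments). An internal edge value is assigned to the
    upper of its two adjacent bins (half-open [lo, hi) convention); the
    maximum is assigned to bin k-1. A degenerate max == min input yields a
    single bin with a warning.
    """
    x = np.asarray(values, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        warnings.warn("max == min: single-bin degenerate classification", stacklevel=2)
        return np.array([lo, hi]), np.zeros(len(x), dtype=int)
    edges = np.linspace(lo, hi, k + 1)
    assign = np.minimum(np.searchsorted(edges, x, side="right") - 1, k - 1)
    return edges, assign


def dissolve_units(geometry: GeometryTable, mapping_: dict) -> GeometryTable:
    """Merge child polygons into one geometry per parent (e.g. ACs -> districts).

    ``mapping_`` maps child unit_id -> parent id; every child must be mapped.
    Numeric attribute columns are summed per parent.
    """
    tab = geometry.table
    unmapped = [uid for uid in tab["unit_id"] if uid not in mapping_]
    if unmapped:
        raise MappingError(f"children without a parent in mapping: {unmapped}")
    parents = tab["unit_id"].map(mapping_)
    rows = []
    numeric = [
        c
        for c in tab.columns
        if c not in ("unit_id", "geometry", "parent_id")
        and pd.api.types.is_numeric_dtype(tab[c])
    ]
    for parent, grp in tab.groupby(parents, sort=True):
        merged = unary_union(list(grp["geometry"]))
        row = {"unit_id": parent, "geometry": merged}
        for c in numeric:
            row[c] = grp[c].sum()
        rows.append(row)
    return GeometryTable(table=pd.DataFrame(rows))


def export_boxplot_data(estimates: pd.DataFrame, by: str = "state_id") -> pd.DataFrame:
    """Per-area box-plot statistics of community prevalences.

    Quartiles by linear interpolation; whiskers reach the most extreme data
    point within 1.5 IQR of the box (Tukey convention); points beyond are
    listed as outliers.
    """
    rows = []
    for area, grp in estimates.groupby(by, sort=True):
        x = grp["prevalence_pct"].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        iqr = q3 - q1
        in_lo = x[x >= q1 - 1.5 * iqr]
        in_hi = x[x <= q3 + 1.5 * iqr]
        lo_wh = float(in_lo.min()) if len(in_lo) else q1
        hi_wh = float(in_hi.max()) if len(in_hi) else q3
        outliers = x[(x < lo_wh) | (x > hi_wh)]
        rows.append(
            {
                by: area,
                "n_communities": len(x),
                "min": float(x.min()),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "max": float(x.max()),
                "whisker_low": lo_wh,
                "whisker_high": hi_wh,
                "outliers": outliers.tolist(),
            }
        )
    return pd.DataFrame(rows)


def read_geojson(path, id_property: str = "district_id") -> GeometryTable:
    """Load a GeoJSON FeatureCollection into a GeometryTable."""
    with open(path) as fh:
        gj = json.load(fh)
    rows = []
    for feat in gj["features"]:
        props = feat.get("properties", {}) or {}
        if id_property not in props:
            raise MappingError(f"feature without {id_property!r} property")
        rows.append({"unit_id": props[id_property], "geometry": shape(feat["geometry"]), **{
            k: v for k, v in props.items() if k != id_property
        }})
    return GeometryTable(table=pd.DataFrame(rows))


def write_geojson(geometry: GeometryTable, path, id_property: str = "district_id") -> None:
    feats = []
    for row in geometry.table.to_dict(orient="records"):
        geom = row.pop("geometry")
        props = {id_property: row.pop("unit_id"), **row}
        feats.append({"type": "Feature", "properties": props, "geometry": mapping(geom)})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def render_maps(
    geometry: GeometryTable,
    values: pd.DataFrame,
    spec: ChoroplethSpec,
    out_path,
    id_column: str = "district_id",
) -> dict:
    """Render one equal-interval choropleth and write legend metadata.

    ``values`` must carry ``id_column`` and ``spec.variable``. Districts in
    the geometry with no matching value are drawn as hatched no-data and
    listed (with a warning). Returns legend metadata: exact bin edges, class
    assignments and the joined table; a ``<out_path>.legend.json`` sidecar is
    written next to the image.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import PathPatch
    from matplotlib.path import Path as MplPath

    joined = geometry.table[["unit_id", "geometry"]].merge(
        values[[id_column, spec.variable]],
        left_on="unit_id",
        right_on=id_column,
        how="left",
    )
    missing = joined.loc[joined[spec.variable].isna(), "unit_id"].tolist()
    if missing:
        warnings.warn(f"no data for {len(missing)} units: {missing}", stacklevel=2)
    present = joined[spec.variable].notna()
    vals = joined.loc[present, spec.variable].to_numpy(dtype=float)
    edges, assign = equal_interval_bins(vals, spec.k)
    n_classes = len(edges) - 1
    joined["bin"] = -1
    joined.loc[present, "bin"] = assign

    cmap = plt.get_cmap(spec.cmap, n_classes)
    fig, ax = plt.subplots(figsize=(8, 8))
    for row in joined.itertuples():
        geom = row.geometry
        polys = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
        for poly in polys:
            verts, codes = _poly_path(poly)
            patch = PathPatch(
                MplPath(verts, codes),
                facecolor=cmap(row.bin) if row.bin >= 0 else "white",
                hatch=None if row.bin >= 0 else "//",
                edgecolor="black",
                linewidth=0.3,
            )
            ax.add_patch(patch)
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.set_axis_off()
    labels = [f"[{edges[i]:.2f}, {edges[i + 1]:.2f})" for i in range(n_classes)]
    if labels:
        labels[-1] = labels[-1][:-1] + "]"
    handles = [plt.Rectangle((0, 0), 1, 1, facecolor=cmap(i)) for i in range(n_classes)]
    ax.legend(handles, labels, loc="lower right", fontsize=6, title=spec.variable)
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)

    legend = {
        "variable": spec.variable,
        "bin_edges": edges.tolist(),
        "labels": labels,
        "n_classes": n_classes,
        "missing_units": missing,
    }
    with open(str(out_path) + ".legend.json", "w") as fh:
        json.dump(legend, fh, indent=2)
    legend["joined"] = joined
    return legend


def _poly_path(poly):
    """Exterior + interior rings of a shapely polygon as a matplotlib path."""
    verts, codes = [], []
    for ring in [poly.exterior, *poly.interiors]:
        pts = np.asarray(ring.coords)
        verts.extend(pts.tolist())
        codes.extend([1] + [2] * (len(pts) - 2) + [79])  # MOVETO, LINETO..., CLOSEPOLY
    return verts, codes
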