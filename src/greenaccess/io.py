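"""File readers/writers, pipeline configuration, and the end-to-end pipeline.

All tabular outputs are CSV with a fixed column order and floats printed with
10 significant digits, so identical runs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accessibility import (
    AccessConfig,
    AccessResult,
    Community,
    GreenSpace,
    compute_mode_travel_times,
    estimate_threshold,
    flag_below_standard,
    stratified_accessibility,
)
from .deprivation import cross_sectional_analysis, render_tables
from .network import MODES, ModeSpeedTable, RoadNetwork, load_network, snap_points
from .synthetic_city import SyntheticCity

log = logging.getLogger("greenaccess")

FLOAT_FMT = "%.10g"

MODE_POP_COLUMNS = {
    "walking": "pop_walking",
    "cycling": "pop_cycling",
    "public_transport": "pop_transit",
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


# ---------------------------------------------------------------------------
# geometry / table readers


def read_geo(path: str | Path) -> pd.DataFrame:
    """Read point records from CSV (x, y columns) or GeoJSON.

    GeoJSON Point features become one row each (x, y + properties); Polygon
    features are reduced to entrance points — exterior vertices listed in an
    ``entrances`` property (vertex indices), or the centroid if none are
    flagged.  Coordinates are planar meters.
    """
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as err:
            raise ValueError(
                f"{path}: malformed JSON at line {err.lineno}, column {err.colno}: {err.msg}"
            ) from err
        if doc.get("type") != "FeatureCollection":
            raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
        rows = []
        for k, feat in enumerate(doc.get("features", [])):
            geom = feat.get("geometry") or {}
            props = dict(feat.get("properties") or {})
            gtype = geom.get("type")
            if gtype == "Point":
                x, y = geom["coordinates"][:2]
                rows.append({"x": float(x), "y": float(y), **props})
            elif gtype == "Polygon":
                from shapely.geometry import shape

                poly = shape(geom)
                verts = list(poly.exterior.coords)
                flagged = props.pop("entrances", None)
                if flagged:
                    pts = [verts[int(i)] for i in flagged]
                else:
                    c = poly.centroid
                    pts = [(c.x, c.y)]
                for x, y in pts:
                    rows.append({"x": float(x), "y": float(y), **props})
            else:
                raise ValueError(
                    f"{path}: feature {k} has unsupported geometry type {gtype!r}"
                )
        return pd.DataFrame(rows)
    df = pd.read_csv(path)
    if "x" not in df.columns or "y" not in df.columns:
        raise ValueError(f"{path}: CSV point input needs x and y columns")
    return df


def read_network(nodes_path: str | Path, edges_path: str | Path) -> RoadNetwork:
    """Load a road network from nodes.csv (id,x,y) and edges.csv
    (u,v,length_m,road_class[,oneway]) or a GeoJSON LineString collection."""
    edges_path = Path(edges_path)
    if edges_path.suffix.lower() in (".geojson", ".json"):
        nodes_df, edges_df = _network_tables_from_geojson(edges_path)
    else:
        nodes_df = pd.read_csv(nodes_path)
        edges_df = pd.read_csv(edges_path)
    return load_network(nodes_df, edges_df)


def _network_tables_from_geojson(path: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    from shapely.geometry import shape

    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as err:
        raise ValueError(
            f"{path}: malformed JSON at line {err.lineno}, column {err.colno}: {err.msg}"
        ) from err
    node_ids: dict[tuple[float, float], int] = {}
    edge_rows = []
    for k, feat in enumerate(doc.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "LineString":
            raise ValueError(f"{path}: feature {k} is not a LineString")
        props = dict(feat.get("properties") or {})
        coords = geom["coordinates"]
        a = (float(coords[0][0]), float(coords[0][1]))
        b = (float(coords[-1][0]), float(coords[-1][1]))
        for pt in (a, b):
            if pt not in node_ids:
                node_ids[pt] = len(node_ids)
        length = props.get("length_m")
        if length is None:
            length = shape(geom).length
        edge_rows.append(
            {
                "u": node_ids[a],
                "v": node_ids[b],
                "length_m": float(length),
                "road_class": props.get("road_class", "main_street"),
                "oneway": int(props.get("oneway", 0)),
            }
        )
    nodes_df = pd.DataFrame(
        [{"id": i, "x": pt[0], "y": pt[1]} for pt, i in node_ids.items()]
    )
    return nodes_df, pd.DataFrame(edge_rows)


def read_communities(
    path: str | Path, net: RoadNetwork, snap_tolerance_m: float = 500.0
) -> tuple[list[Community], pd.DataFrame]:
    """Read communities.csv and snap each community to its nearest node.

    Returns the community list and the SES table (indexed by community id).
    """
    df = read_geo(path)
    snap = snap_points(df[["x", "y"]].to_numpy(), net, snap_tolerance_m)
    ses_cols = [
        c
        for c in df.columns
        if c not in ("id", "x", "y", *MODE_POP_COLUMNS.values())
    ]
    comms = []
    for i, r in enumerate(df.itertuples()):
        if snap.unreachable[i]:
            continue
        pops = {
            mode: float(getattr(r, col, 0.0)) for mode, col in MODE_POP_COLUMNS.items()
        }
        ses = {c: float(df.iloc[i][c]) for c in ses_cols}
        comms.append(
            Community(id=int(r.id), node=int(snap.node_ids[i]), pop_by_mode=pops, ses=ses)
        )
    ses_df = df.set_index("id")[ses_cols]
    return comms, ses_df


def read_ugs(
    path: str | Path, net: RoadNetwork, snap_tolerance_m: float = 500.0
) -> list[GreenSpace]:
    """Read ugs.csv (one row per entrance: id, entrance_x/x, entrance_y/y,
    area_m2, level) and snap entrances to nodes."""
    df = pd.read_csv(path)
    xcol = "entrance_x" if "entrance_x" in df.columns else "x"
    ycol = "entrance_y" if "entrance_y" in df.columns else "y"
    snap = snap_points(df[[xcol, ycol]].to_numpy(), net, snap_tolerance_m)
    out = []
    for gid, grp in df.groupby("id", sort=True):
        idx = grp.index.to_numpy()
        entrances = [int(snap.node_ids[i]) for i in idx if not snap.unreachable[i]]
        if not entrances:
            raise PipelineError(f"green space {gid}: every entrance is unsnappable")
        out.append(
            GreenSpace(
                id=int(gid),
                entrance_nodes=sorted(set(entrances)),
                area_m2=float(grp["area_m2"].iloc[0]),
                level=int(grp["level"].iloc[0]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# writers


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, float_format=FLOAT_FMT)
    return path


def city_tables(city: SyntheticCity) -> dict[str, pd.DataFrame]:
    """A synthetic city as plain node/edge/community/green-space tables."""
    net = city.net
    nodes = pd.DataFrame(
        [{"id": i, "x": xy[0], "y": xy[1]} for i, xy in sorted(net.nodes.items())]
    )
    seen = set()
    edge_rows = []
    for u, v, length, cls in net.arcs:
        key = (min(u, v), max(u, v), cls)
        if key in seen:
            continue
        seen.add(key)
        edge_rows.append(
            {"u": key[0], "v": key[1], "length_m": length, "road_class": cls, "oneway": 0}
        )
    edges = pd.DataFrame(edge_rows)
    comm_rows = []
    for c in sorted(city.communities, key=lambda c: c.id):
        x, y = net.nodes[c.node]
        row = {"id": c.id, "x": x, "y": y}
        for mode, col in MODE_POP_COLUMNS.items():
            row[col] = c.pop_by_mode.get(mode, 0.0)
        row.update(c.ses)
        comm_rows.append(row)
    communities = pd.DataFrame(comm_rows)
    ugs_rows = []
    for g in sorted(city.ugs, key=lambda g: g.id):
        for e in g.entrance_nodes:
            x, y = net.nodes[e]
            ugs_rows.append(
                {
                    "id": g.id,
                    "entrance_x": x,
                    "entrance_y": y,
                    "area_m2": g.area_m2,
                    "level": g.level,
                }
            )
    ugs = pd.DataFrame(ugs_rows)
    return {"nodes": nodes, "edges": edges, "communities": communities, "ugs": ugs}


def write_city(city: SyntheticCity, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    paths = {}
    for name, df in city_tables(city).items():
        paths[name] = _write_csv(df, out_dir / f"{name}.csv")
    return paths


def write_access(result: AccessResult, path: str | Path) -> Path:
    table = result.table.copy()
    table["below_standard"] = flag_below_standard(result).astype(int)
    return _write_csv(table.reset_index(), Path(path))


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    nodes: str
    edges: str
    communities: str
    ugs: str
    out_dir: str
    trips: str | None = None
    thresholds_min: dict[str, float] = field(
        default_factory=lambda: {"walking": 18.0, "cycling": 23.0, "public_transport": 33.0}
    )
    snap_tolerance_m: float = 500.0
    covariates: list[str] = field(default_factory=list)
    seed: int = 0
    speed_overrides: dict = field(default_factory=dict)
    quiet: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run the full chain: network -> travel times -> 2SFCA -> deprivation.

    Writes travel-time matrices, the access table, deprivation tables and a
    run manifest under ``cfg.out_dir``.  Re-running with an identical config
    reproduces identical files.
    """
    t0 = time.time()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def stage(name: str):
        if not cfg.quiet:
            log.info("[%7.2fs] stage: %s", time.time() - t0, name)

    def fail(name: str, detail: str, err: Exception) -> PipelineError:
        return PipelineError(f"stage {name!r} failed on {detail}: {err}")

    stage("load network")
    try:
        net = read_network(cfg.nodes, cfg.edges)
    except Exception as err:
        raise fail("load network", f"{cfg.nodes} / {cfg.edges}", err) from err

    stage("load communities")
    try:
        comms, ses_df = read_communities(cfg.communities, net, cfg.snap_tolerance_m)
    except Exception as err:
        raise fail("load communities", str(cfg.communities), err) from err

    stage("load green spaces")
    try:
        ugs = read_ugs(cfg.ugs, net, cfg.snap_tolerance_m)
    except Exception as err:
        raise fail("load green spaces", str(cfg.ugs), err) from err

    thresholds = dict(cfg.thresholds_min)
    if cfg.trips:
        stage("estimate thresholds")
        try:
            trips = pd.read_csv(cfg.trips)
            thresholds.update(estimate_threshold(trips))
        except Exception as err:
            raise fail("estimate thresholds", str(cfg.trips), err) from err
    access_cfg = AccessConfig(thresholds_min=thresholds)

    stage("travel-time matrices")
    speeds = ModeSpeedTable.with_overrides(
        {(m, c): v for (m, c), v in cfg.speed_overrides.items()}
    ) if cfg.speed_overrides else None
    try:
        ttms = compute_mode_travel_times(net, comms, ugs, speeds)
    except Exception as err:
        raise fail("travel-time matrices", "network routing", err) from err
    for mode in MODES:
        df = ttms[mode].to_frame()
        df.index.name = "origin_node"
        outputs[f"ttm_{mode}"] = _write_csv(df, out_dir / f"ttm_{mode}.csv", index=True)

    stage("2SFCA accessibility")
    try:
        result = stratified_accessibility(comms, ugs, ttms, access_cfg)
    except Exception as err:
        raise fail("2SFCA accessibility", "accessibility computation", err) from err
    outputs["access"] = write_access(result, out_dir / "access.csv")

    if cfg.covariates:
        stage("deprivation analysis")
        try:
            table = cross_sectional_analysis(result, ses_df, list(cfg.covariates))
        except Exception as err:
            raise fail("deprivation analysis", "KRLS fitting", err) from err
        paths = render_tables(table, out_dir, stem="deprivation")
        outputs["deprivation_csv"] = paths["csv"]
        outputs["deprivation_txt"] = paths["txt"]

    manifest = {
        "config": asdict(cfg),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "thresholds_min": thresholds,
        "versions": {
            "greenaccess": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": sorted(p.name for p in outputs.values()),
    }
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    outputs["manifest"] = mpath
    stage("done")
    return outputs


def setup_logging(quiet: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.WARNING if quiet else logging.INFO)
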