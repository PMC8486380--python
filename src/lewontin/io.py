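"""File formats, configuration, and the end-to-end pipeline runner.

Conventions: CSV is UTF-8, comma-separated with a header and '.' decimals;
geometry is GeoJSON (RFC 7946); trees are newick with branch lengths;
configuration is YAML; run manifests are JSON. Logging goes to standard
error; data outputs are never mixed into the log stream.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import shapely
import shapely.geometry
import yaml

from . import biomass_validation, census_allometry, linked_selection, phylo_comparative
from .errors import InvalidTreeError, SchemaError
from .linked_selection import SelectionParams
from .phylo_comparative import SamplerConfig

__all__ = [
    "read_taxa",
    "write_taxa",
    "read_tree",
    "write_tree",
    "read_occurrences",
    "write_occurrences",
    "read_geojson_geometry",
    "write_range_geojson",
    "read_selection_params",
    "PipelineConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

TAXA_REQUIRED = ["species", "pi"]
TAXA_NUMERIC = [
    "pi", "length_cm", "mass_g", "density_km2", "range_km2", "N_c",
    "map_length_M", "genome_size_bp",
]


def read_taxa(path: str | Path) -> pd.DataFrame:
    """Read a taxon table, averaging duplicate species rows.

    Requires ``species`` and ``pi`` columns; tolerates any extras. Multiple
    rows for one species are collapsed by the arithmetic mean of numeric
    columns (diversity estimates from different sources are averaged);
    non-numeric columns keep their first value.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    missing = [c for c in TAXA_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    for col in TAXA_NUMERIC:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise SchemaError(f"{path}: non-numeric {col!r} at line {line}")
        df[col] = coerced
    n_dups = int(df["species"].duplicated().sum())
    if n_dups:
        logger.info("read_taxa: averaging %d duplicate species rows", n_dups)
        numeric = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
        agg = {c: ("mean" if c in numeric else "first") for c in df.columns if c != "species"}
        df = df.groupby("species", as_index=False, sort=False).agg(agg)
    logger.info("read_taxa: %d records from %s", len(df), path)
    return df


def write_taxa(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read and validate a newick chronogram (branch lengths required)."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise InvalidTreeError(f"{path}: branch without length")
    tree.is_rooted = True
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


def read_occurrences(path: str | Path):
    """Read occurrences from GeoJSON (Point features) or CSV (species,lon,lat).

    Returns a dict species_id -> OccurrenceSet.
    """
    from .range_geometry import OccurrenceSet

    path = Path(path)
    records: dict[str, list] = {}
    if path.suffix.lower() in (".geojson", ".json"):
        payload = json.loads(path.read_text())
        for feat in payload.get("features", []):
            sp = feat.get("properties", {}).get("species", "unknown")
            geom = feat.get("geometry", {})
            if geom.get("type") != "Point":
                continue
            records.setdefault(sp, []).append(geom["coordinates"])
    else:
        df = pd.read_csv(path)
        for col in ("species", "lon", "lat"):
            if col not in df.columns:
                raise SchemaError(f"{path}: missing column {col!r}")
        for sp, grp in df.groupby("species"):
            records[sp] = grp[["lon", "lat"]].to_numpy().tolist()
    return {
        sp: OccurrenceSet(species_id=sp, points=np.asarray(pts, float))
        for sp, pts in records.items()
    }


def write_occurrences(occurrences: dict, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"species": sp},
            "geometry": {"type": "Point", "coordinates": [float(lon), float(lat)]},
        }
        for sp, occ in occurrences.items()
        for lon, lat in occ.points
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_geojson_geometry(path: str | Path) -> shapely.Geometry:
    """Union of all geometries in a GeoJSON file (e.g. landmass polygons)."""
    payload = json.loads(Path(path).read_text())
    geoms = []
    if payload.get("type") == "FeatureCollection":
        for feat in payload["features"]:
            geoms.append(shapely.geometry.shape(feat["geometry"]))
    elif payload.get("type") == "Feature":
        geoms.append(shapely.geometry.shape(payload["geometry"]))
    else:
        geoms.append(shapely.geometry.shape(payload))
    return shapely.union_all(geoms)


def write_range_geojson(ranges: list, path: str | Path) -> None:
    """Write RangePolygon records as a GeoJSON FeatureCollection."""
    features = []
    for rp in ranges:
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "species": rp.species_id,
                    "realm": rp.realm,
                    "area_km2": rp.area_km2,
                    "alpha_used": None if np.isnan(rp.alpha_used) else rp.alpha_used,
                },
                "geometry": shapely.geometry.mapping(rp.geometry),
            }
        )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_selection_params(path: str | Path) -> SelectionParams:
    """Load linked-selection parameters from a YAML mapping."""
    payload = yaml.safe_load(Path(path).read_text()) or {}
    valid = {f.name for f in dataclasses.fields(SelectionParams)}
    unknown = set(payload) - valid
    if unknown:
        raise SchemaError(f"{path}: unknown selection parameters {sorted(unknown)}")
    return SelectionParams(**payload)


@dataclass
class PipelineConfig:
    """Paths, toggles and settings for the full analysis pipeline."""

    taxa_csv: str
    tree_newick: str | None = None
    params_yaml: str | None = None
    output_dir: str = "lewontin_out"
    seed: int = 0
    stages: tuple[str, ...] = (
        "census", "ols", "phylo_mm", "node_height", "linked_selection", "biomass",
    )
    sampler: SamplerConfig = field(default_factory=SamplerConfig)

    def validate(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise SchemaError("seed must be an integer")
        for p in (self.taxa_csv, self.tree_newick, self.params_yaml):
            if p is not None and not Path(p).exists():
                raise SchemaError(f"configured path does not exist: {p}")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages in order, writing outputs and a manifest.

    Stage order: census -> OLS -> phylogenetic mixed model -> node-height
    tests -> linked-selection band -> biomass. Each stage writes CSV or JSON
    outputs into the output directory; the JSON manifest records the seed,
    per-stage outputs, and warnings. A failing stage halts the run with a
    :class:`StageError` after writing the partial manifest.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": int(config.seed), "stages": [], "warnings": []}
    manifest_path = out / "manifest.json"

    taxa = read_taxa(config.taxa_csv)
    tree = read_tree(config.tree_newick) if config.tree_newick else None
    params = (
        read_selection_params(config.params_yaml)
        if config.params_yaml
        else linked_selection.DROSOPHILA_DEFAULTS
    )

    def record(stage: str, outputs: list[str]) -> None:
        manifest["stages"].append({"name": stage, "outputs": outputs})
        manifest_path.write_text(json.dumps(manifest, indent=2))

    def fail(stage: str, exc: Exception):
        manifest["warnings"].append(f"stage {stage} failed: {exc}")
        manifest_path.write_text(json.dumps(manifest, indent=2))
        raise StageError(stage, exc)

    for stage in config.stages:
        try:
            if stage == "census":
                taxa = census_allometry.estimate_census_sizes(taxa)
                path = out / "taxa_census.csv"
                write_taxa(taxa, path)
                record(stage, [str(path)])
            elif stage == "ols":
                ok = taxa.dropna(subset=["pi", "N_c"])
                fit = phylo_comparative.ols_diversity_nc(
                    ok["pi"], ok["N_c"], seed=config.seed
                )
                path = out / "ols_fit.json"
                path.write_text(json.dumps({
                    "slope": fit.slope, "intercept": fit.intercept,
                    "adj_r2": fit.adj_r2,
                    "percent_per_decade": fit.percent_per_decade,
                    "slope_ci": fit.slope_ci, "n_boot": fit.n_boot,
                }, indent=2))
                record(stage, [str(path)])
            elif stage == "phylo_mm":
                if tree is None:
                    raise InvalidTreeError("phylo_mm stage requires a tree")
                fit = phylo_comparative.fit_phylo_mm_subset(
                    taxa, tree, phylum=None, config=config.sampler, seed=config.seed
                )
                path = out / "phylo_mm_fit.json"
                path.write_text(json.dumps({
                    "summary": fit.summary.to_dict(),
                    "rhat": fit.rhat, "ess": fit.ess,
                    "converged": fit.converged, "flags": fit.flags,
                }, indent=2))
                draws_path = out / "phylo_mm_draws.csv"
                fit.draws.to_csv(draws_path, index=False)
                record(stage, [str(path), str(draws_path)])
            elif stage == "node_height":
                if tree is None:
                    raise InvalidTreeError("node_height stage requires a tree")
                tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
                ok = taxa.dropna(subset=["pi", "N_c"])
                ok = ok[ok["species"].isin(tips)]
                sub = tree.extract_tree_with_taxa_labels(sorted(ok["species"]))
                results = {}
                for trait_name, values in (
                    ("log10_pi", np.log10(ok.set_index("species")["pi"])),
                    ("log10_Nc", np.log10(ok.set_index("species")["N_c"])),
                ):
                    res = phylo_comparative.node_height_test(
                        sub, values.to_dict(), seed=config.seed
                    )
                    results[trait_name] = {"slope": res.slope, "p_value": res.p_value}
                path = out / "node_height.json"
                path.write_text(json.dumps(results, indent=2))
                record(stage, [str(path)])
            elif stage == "linked_selection":
                per_taxon, envelope, skipped = linked_selection.prediction_band(
                    taxa.dropna(subset=["N_c"]), params
                )
                p1, p2 = out / "ls_per_taxon.csv", out / "ls_envelope.csv"
                per_taxon.to_csv(p1, index=False)
                envelope.to_csv(p2, index=False)
                if skipped:
                    manifest["warnings"].append(
                        f"linked_selection: skipped taxa without map length: {skipped}"
                    )
                record(stage, [str(p1), str(p2)])
            elif stage == "biomass":
                reference = biomass_validation.load_reference_biomass()
                rows = []
                for _, ref in reference.iterrows():
                    sample = taxa[taxa.get("phylum", "") == ref["phylum"]]
                    b = biomass_validation.sample_biomass(sample) if len(sample) else 0.0
                    rows.append({**ref.to_dict(), "sample_biomass_gtc_recomputed": b})
                table = pd.DataFrame(rows)
                derived = biomass_validation.biomass_table(table)
                path = out / "biomass_table.csv"
                derived.to_csv(path, index=False)
                record(stage, [str(path)])
            else:
                raise SchemaError(f"unknown stage {stage!r}")
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - typed re-raise with stage name
            fail(stage, exc)
    return manifest
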