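"""Configured end-to-end pipeline: simulate -> terrain -> close -> segment ->
features -> classify -> summarise -> composition -> ordination.

Every stage writes its artefacts under the run directory; a manifest records
the configuration hash and seed so a rerun with an identical configuration
reproduces identical outputs.  All randomness flows from the single
configuration seed through per-stage derived seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Point

from . import io as cio
from .classify import cross_validate, train_classifier
from .composition import (
    change_map,
    idw_accuracy,
    idw_surfaces,
    to_proportions,
)
from .features import extract_objects, zonal_summaries
from .grids import DemGrid
from .morphology import disc_element, grayscale_closing
from .ordination import rda
from .segmentation import region_growing, select_seeds
from .summary import build_inventory, density, geometry_report
from .synthetic import (
    DEFAULT_TAXON_PROBS,
    TerrainScenario,
    generate_charcoal_samples,
    generate_dtm,
    generate_forest_plots,
)
from .terrain import slope

log = logging.getLogger("charcoalscape")

_STAGES = (
    "simulate", "terrain", "close", "segment", "features", "classify",
    "summary", "composition", "ordination",
)


@dataclass
class PipelineConfig:
    """All pipeline stage parameters; serialisable to/from YAML.

    Unknown keys in a config file are rejected rather than ignored.
    """

    seed: int = 0
    out_dir: str = "run"
    stages: list[str] = field(default_factory=lambda: list(_STAGES))
    dtm_path: str | None = None          # external DTM instead of simulation
    # scenario
    extent_m: float = 1280.0
    cell_size_m: float = 0.5
    base_slope_deg: float = 25.0
    relief_amplitude_m: float = 0.35
    n_platforms: int = 212
    n_confusers: int = 453
    # detection
    disc_diameter_px: int = 7
    seed_min_distance_m: float = 15.0
    flatness_quantile: float = 0.03
    srg_threshold: float = 8.0
    max_area_m2: float = 340.0
    # classification
    n_trees: int = 500
    k_folds: int = 5
    # composition / idw
    idw_cell_m: float = 10.0
    idw_power: float = 2.0
    idw_neighbours: int = 50
    n_plots: int = 267
    # ordination
    rda_standardise_y: bool = True
    rda_permutations: int = 999

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        with path.open("w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
        return path

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)


# ---------------------------------------------------------------------------
# detection (terrain -> close -> segment -> features -> classify)
# ---------------------------------------------------------------------------

@dataclass
class DetectionResult:
    dem: DemGrid
    slope: DemGrid
    closed_slope: DemGrid
    labels: "object"
    objects: list
    feature_table: pd.DataFrame
    is_rch: np.ndarray               # reference class per object (truth overlap)
    report: "object"                 # ClassificationReport
    predicted: np.ndarray            # RF prediction per object (fit on all data)
    rch_jaccard: np.ndarray          # per-truth best Jaccard with a segment

    @property
    def n_objects(self) -> int:
        return len(self.objects)


def truth_overlap(labels, truths) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-object truth-overlap fraction and per-truth best Jaccard.

    Returns (object ids, overlap fraction of each object's pixels covered by
    any truth footprint, per-truth max Jaccard against any single segment).
    """
    lab = labels.labels
    truth_id = np.zeros(lab.shape, dtype=np.int64)
    for t in truths:
        truth_id[t.rows, t.cols] = t.id
    ids = np.unique(lab)
    ids = ids[ids > 0]
    obj_area = np.bincount(lab.ravel(), minlength=int(lab.max()) + 1)
    truth_area = np.bincount(truth_id.ravel(), minlength=len(truths) + 1)
    both = (lab > 0) & (truth_id > 0)
    pair_counts: dict[tuple[int, int], int] = {}
    if both.any():
        pairs = lab[both] * (len(truths) + 1) + truth_id[both]
        uniq, counts = np.unique(pairs, return_counts=True)
        for u, c in zip(uniq, counts):
            pair_counts[(int(u) // (len(truths) + 1), int(u) % (len(truths) + 1))] = int(c)
    overlap = np.zeros(ids.size)
    for k, lid in enumerate(ids):
        inter = sum(c for (l, _), c in pair_counts.items() if l == lid)
        overlap[k] = inter / obj_area[lid]
    jac = np.zeros(len(truths))
    for (lid, tid), c in pair_counts.items():
        j = c / (obj_area[lid] + truth_area[tid] - c)
        if j > jac[tid - 1]:
            jac[tid - 1] = j
    return ids, overlap, jac


def detect(dem: DemGrid, truths=None, config: PipelineConfig | None = None) -> DetectionResult:
    """Run the full object-based detection chain on a DTM."""
    cfg = config or PipelineConfig()
    slope_grid = slope(dem)
    closed = grayscale_closing(slope_grid, disc_element(cfg.disc_diameter_px))
    seeds = select_seeds(closed, cfg.seed_min_distance_m, cfg.flatness_quantile)
    log.info("selected %d seeds", len(seeds))
    labels = region_growing(closed, seeds, cfg.srg_threshold, cfg.max_area_m2)
    stack = {"slope": slope_grid, "closed_slope": closed, "dem": dem}
    objects = extract_objects(labels, stack)
    feats = pd.DataFrame([o.features for o in objects],
                         index=[o.label for o in objects])
    feats = feats.drop(columns=[c for c in feats.columns if c.endswith("n_valid")])
    feats = feats.dropna(axis=1)
    is_rch = None
    report = None
    predicted = None
    jac = np.zeros(0)
    if truths is not None:
        ids, overlap, jac = truth_overlap(labels, truths)
        is_rch = overlap >= 0.5
        y = np.where(is_rch, "RCH", "non-RCH")
        if len(np.unique(y)) == 2 and min(np.bincount(is_rch.astype(int))) >= cfg.k_folds:
            report = cross_validate(feats, y, k=cfg.k_folds, n_trees=cfg.n_trees,
                                    seed=cfg.stage_seed("classify"))
            model = train_classifier(feats, y, n_trees=cfg.n_trees,
                                     seed=cfg.stage_seed("classify"))
            predicted = model.predict(feats.to_numpy(dtype=float))
    return DetectionResult(
        dem=dem, slope=slope_grid, closed_slope=closed, labels=labels,
        objects=objects, feature_table=feats,
        is_rch=is_rch if is_rch is not None else np.zeros(len(objects), bool),
        report=report,
        predicted=predicted if predicted is not None else np.array([]),
        rch_jaccard=jac,
    )


# ---------------------------------------------------------------------------
# orchestrated run
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages, writing artefacts under the run dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest = {"config_digest": config.digest(), "seed": config.seed}
    logging.basicConfig(level=logging.INFO)

    if "simulate" in config.stages:
        scenario = TerrainScenario(
            extent_m=(config.extent_m, config.extent_m),
            cell_size_m=config.cell_size_m,
            base_slope_deg=config.base_slope_deg,
            relief_amplitude_m=config.relief_amplitude_m,
            n_platforms=config.n_platforms,
            n_confusers=config.n_confusers,
            seed=config.stage_seed("simulate"),
        )
        dem, truths = generate_dtm(scenario)
        cio.write_ascii_grid(dem, out / "dtm.asc")
        cio.write_geojson(
            [Point(t.centroid_xy) for t in truths],
            out / "truth.geojson",
            [{"id": t.id, "area_m2": t.area_m2} for t in truths],
        )
    elif config.dtm_path:
        dem = cio.read_raster(config.dtm_path)
        truths = None
    else:
        raise FileNotFoundError("no DTM: enable the simulate stage or set dtm_path")

    result = detect(dem, truths, config)
    result.feature_table.to_csv(out / "object_features.csv")
    if result.report is not None:
        (out / "classification_report.json").write_text(
            json.dumps(result.report.to_dict(), indent=2)
        )

    if "summary" in config.stages:
        det_objs = [o for o, r in zip(result.objects, result.is_rch) if r]
        if det_objs:
            inv = build_inventory(det_objs, dem, result.slope)
            inv.to_csv(out / "rch_inventory.csv", index=False)
            area_ha = dem.extent_m[0] * dem.extent_m[1] / 10_000.0
            rep = geometry_report(inv)
            rep["area_histogram"] = rep["area_histogram"].to_dict("list")
            rep["density"] = density(len(det_objs), area_ha)
            (out / "rch_summary.json").write_text(json.dumps(rep, indent=2))

    if "composition" in config.stages and truths is not None:
        charcoal = generate_charcoal_samples(
            truths[: min(125, len(truths))], seed=config.stage_seed("charcoal")
        )
        charcoal.to_csv(out / "charcoal_counts.csv", index=False)
        hist = to_proportions(charcoal)
        taxa = list(DEFAULT_TAXON_PROBS)
        grid10 = _coarse_grid(dem, config.idw_cell_m)
        surfaces = idw_surfaces(
            hist[["x", "y"]].to_numpy(), hist[taxa].to_numpy(), grid10,
            power=config.idw_power, n_neighbours=config.idw_neighbours,
        )
        for taxon, surf in zip(taxa, surfaces):
            cio.write_ascii_grid(surf, out / f"{taxon}_historical.asc")
        acc = {
            taxon: idw_accuracy(hist[["x", "y"]].to_numpy(), hist[taxon].to_numpy(),
                                config.idw_power, config.idw_neighbours)
            for taxon in taxa
        }
        (out / "idw_accuracy.json").write_text(json.dumps(acc, indent=2))

    if "ordination" in config.stages:
        plots = generate_forest_plots(config.n_plots, seed=config.stage_seed("plots"))
        plots.plots.to_csv(out / "forest_plots.csv", index=False)
        plots.env.to_csv(out / "forest_env.csv", index=False)
        res = rda(plots.response_matrix, plots.env_matrix,
                  standardise_y=config.rda_standardise_y,
                  n_permutations=config.rda_permutations,
                  seed=config.stage_seed("ordination"))
        frames = res.scores_frames(response_names=list(plots.response_matrix.columns))
        frames["sites"].to_csv(out / "rda_site_scores.csv", index=False)
        frames["responses"].to_csv(out / "rda_response_scores.csv")
        frames["biplot"].to_csv(out / "rda_biplot_scores.csv")
        (out / "rda_summary.json").write_text(json.dumps({
            "eigenvalues": res.eigenvalues.tolist(),
            "explained_pct": res.explained_pct.tolist(),
            "p_value": res.p_value,
            "n_permutations": res.n_permutations,
        }, indent=2))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _coarse_grid(dem: DemGrid, cell_m: float) -> DemGrid:
    n_cols = max(int(np.ceil(dem.extent_m[0] / cell_m)), 1)
    n_rows = max(int(np.ceil(dem.extent_m[1] / cell_m)), 1)
    return DemGrid(np.zeros((n_rows, n_cols)), cell_size_m=cell_m,
                   origin_xy=dem.origin_xy, nodata=dem.nodata)
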