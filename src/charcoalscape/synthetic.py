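"""Synthetic landscape, charcoal and forest-plot generators.

The study's LiDAR terrain model and field data are emulated by ground-truthed
synthetic inputs so that every downstream stage is testable: a dissected
hillslope DTM with embedded flat elliptical charcoal-hearth platforms
(20-170 m2, bounded by 1-2 m lips), confuser landforms (gullies, boulders,
terracettes), multinomial charcoal fragment counts per hearth (2-6 fragments)
and plot-level structure/composition tables with known linear responses to
environmental gradients.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import DemGrid

__all__ = [
    "TerrainScenario",
    "RchTruth",
    "PlacementError",
    "generate_dtm",
    "generate_charcoal_samples",
    "generate_forest_plots",
    "ForestPlotData",
    "DEFAULT_TAXON_PROBS",
    "RESPONSE_CODES",
    "ENV_CODES",
]

# Taxon categories mirror the anthracological record: pine dominates,
# followed by beech, an anatomically indistinct larch/spruce class, spruce,
# and a residual class.
DEFAULT_TAXON_PROBS = {
    "Pinus": 0.62,
    "Fagus": 0.15,
    "Picea": 0.08,
    "Larix_Picea": 0.13,
    "other": 0.02,
}


class PlacementError(RuntimeError):
    """Raised when non-overlapping feature placement fails; carries the
    number of features successfully placed."""

    def __init__(self, requested: int, placed: int):
        super().__init__(
            f"could only place {placed} of {requested} features without overlap"
        )
        self.requested = requested
        self.placed = placed


@dataclass
class TerrainScenario:
    """Parameters of a synthetic hillslope with embedded hearth platforms.

    Defaults mirror the study conditions: 0.5 m cells, platform areas
    20-170 m2 with 1-2 m lips, 212 platforms and 453 confuser landforms
    (the sizes of the ground-validated / visually interpreted training
    classes), on an extent large enough to hold them without overlap.
    """

    extent_m: tuple[float, float] = (1280.0, 1280.0)
    cell_size_m: float = 0.5
    base_slope_deg: float = 25.0
    relief_amplitude_m: float = 0.35
    noise_bandwidth_m: float = 8.0
    n_platforms: int = 212
    platform_area_range_m2: tuple[float, float] = (20.0, 170.0)
    lip_width_m: tuple[float, float] = (1.0, 2.0)
    n_confusers: int = 453
    platform_microrelief_m: float = 0.02
    microrelief_bandwidth_m: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        if self.extent_m[0] <= 0 or self.extent_m[1] <= 0:
            raise ValueError("extent must be positive")
        lo, hi = self.platform_area_range_m2
        if not (0 < lo <= hi):
            raise ValueError("platform_area_range_m2 must be an increasing positive pair")
        wlo, whi = self.lip_width_m
        if not (0 < wlo <= whi):
            raise ValueError("lip_width_m must be an increasing positive pair")
        if self.n_platforms < 0 or self.n_confusers < 0:
            raise ValueError("feature counts must be non-negative")


@dataclass
class RchTruth:
    """Ground truth for one synthetic hearth platform."""

    id: int
    centroid_xy: tuple[float, float]
    area_m2: float                      # analytic ellipse area pi*a*b
    ellipse_axes_m: tuple[float, float]
    theta_rad: float
    lip_width_m: float
    rows: np.ndarray                    # pixel footprint of the flat platform
    cols: np.ndarray

    def footprint_mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.rows, self.cols] = True
        return m

    @property
    def footprint_area_m2(self) -> float:
        # set by generate_dtm; pixel count x cell^2
        return self._pixel_area

    _pixel_area: float = 0.0


def _correlated_noise(shape, rng, amplitude_m, bandwidth_m, cell):
    """Band-limited texture: white noise smoothed by a Gaussian kernel and
    rescaled to the requested standard deviation."""
    if amplitude_m <= 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    sigma_px = max(bandwidth_m / cell, 1e-6)
    smooth = ndimage.gaussian_filter(white, sigma_px, mode="reflect")
    sd = smooth.std()
    if sd == 0:
        return np.zeros(shape)
    return smooth * (amplitude_m / sd)


def generate_dtm(scenario: TerrainScenario) -> tuple[DemGrid, list[RchTruth]]:
    """Generate the synthetic DTM and the platform ground truth.

    The terrain is a planar ramp of ``base_slope_deg`` (dipping towards +x)
    plus correlated noise.  Each platform is an ellipse levelled at the
    terrain elevation of its centre, blended back into the hillslope by a
    linear ramp across a lip annulus of the drawn width; the cut uphill and
    the fill downhill make the lip locally steeper than the hillslope while
    the platform interior stays essentially flat.  Confusers are gullies,
    boulders and terracettes: locally steep landforms without a flat
    elliptical centre.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    cell = scenario.cell_size_m
    n_cols = int(round(scenario.extent_m[0] / cell))
    n_rows = int(round(scenario.extent_m[1] / cell))
    grid = DemGrid(np.zeros((n_rows, n_cols)), cell_size_m=cell,
                   origin_xy=(0.0, scenario.extent_m[1]))
    x, y = grid.cell_centers()
    tan_s = np.tan(np.radians(scenario.base_slope_deg))
    z = 2000.0 - tan_s * x
    z += _correlated_noise((n_rows, n_cols), rng, scenario.relief_amplitude_m,
                           scenario.noise_bandwidth_m, cell)
    # degraded platforms are not perfectly flat: short-wavelength micro-relief
    # (centimetre scale) keeps their interior slope small but non-zero
    micro = _correlated_noise((n_rows, n_cols), rng,
                              scenario.platform_microrelief_m,
                              scenario.microrelief_bandwidth_m, cell)

    # --- draw platform geometries, then place without overlap -------------
    lo, hi = scenario.platform_area_range_m2
    areas = rng.uniform(lo, hi, scenario.n_platforms)
    ratios = rng.uniform(0.7, 1.0, scenario.n_platforms)   # ellipse b/a
    thetas = rng.uniform(0.0, np.pi, scenario.n_platforms)
    lips = rng.uniform(*scenario.lip_width_m, scenario.n_platforms)
    semi_a = np.sqrt(areas / (np.pi * ratios))
    semi_b = semi_a * ratios
    outer_r = semi_a + lips  # conservative footprint radius

    conf_r = rng.uniform(2.0, 8.0, scenario.n_confusers)

    radii = np.concatenate([outer_r, conf_r])
    if radii.size:
        centers = _place_without_overlap(
            radii, scenario.extent_m, rng,
            margin=radii.max() + 2.0, clearance=3.0,
            n_platforms=scenario.n_platforms,
        )
    else:
        centers = np.zeros((0, 2))

    truths: list[RchTruth] = []
    for i in range(scenario.n_platforms):
        cx, cy = centers[i]
        a, b, th, w = semi_a[i], semi_b[i], thetas[i], lips[i]
        r_ext = a + w + cell
        r0, c0 = grid.rowcol_of(cx + r_ext, cy + r_ext)
        r1, c1 = grid.rowcol_of(cx - r_ext, cy - r_ext)
        r0, r1 = max(min(r0, r1), 0), min(max(r0, r1) + 1, n_rows)
        c0c, c1c = grid.rowcol_of(cx - r_ext, cy)[1], grid.rowcol_of(cx + r_ext, cy)[1]
        c0c, c1c = max(min(c0c, c1c), 0), min(max(c0c, c1c) + 1, n_cols)
        xs = x[r0:r1, c0c:c1c] - cx
        ys = y[r0:r1, c0c:c1c] - cy
        u = xs * np.cos(th) + ys * np.sin(th)
        v = -xs * np.sin(th) + ys * np.cos(th)
        r_local = np.hypot(u, v)
        with np.errstate(invalid="ignore", divide="ignore"):
            ang = np.arctan2(v, u)
            r_inner = 1.0 / np.sqrt((np.cos(ang) / a) ** 2 + (np.sin(ang) / b) ** 2)
        d_out = r_local - r_inner          # metres beyond the platform edge
        rr, cc = grid.rowcol_of(cx, cy)
        z_center = z[rr, cc]
        t = np.clip(d_out / w, 0.0, 1.0)   # 0 on platform, 1 beyond the lip
        patch = (1.0 - t) * (z_center + micro[r0:r1, c0c:c1c]) + t * z[r0:r1, c0c:c1c]
        z[r0:r1, c0c:c1c] = patch
        inside = d_out <= 0
        prow, pcol = np.nonzero(inside)
        truth = RchTruth(
            id=i + 1,
            centroid_xy=(cx, cy),
            area_m2=float(np.pi * a * b),
            ellipse_axes_m=(float(a), float(b)),
            theta_rad=float(th),
            lip_width_m=float(w),
            rows=prow + r0,
            cols=pcol + c0c,
        )
        truth._pixel_area = float(prow.size * cell * cell)
        truths.append(truth)

    # --- confusers --------------------------------------------------------
    conf_types = rng.integers(0, 3, scenario.n_confusers)
    for j in range(scenario.n_confusers):
        cx, cy = centers[scenario.n_platforms + j]
        size = conf_r[j]
        kind = conf_types[j]
        if kind == 0:
            _carve_gully(z, x, y, cx, cy, length=size * 4, width=max(size / 2, 1.0),
                         depth=rng.uniform(0.5, 1.5))
        elif kind == 1:
            _add_boulder(z, x, y, cx, cy, radius=max(size / 2, 1.0),
                         height=rng.uniform(0.5, 2.0))
        else:
            _cut_terracette(z, x, y, cx, cy, length=size * 3,
                            width=rng.uniform(0.8, 1.5), tan_s=tan_s)

    grid = grid.like(z)
    return grid, truths


def _place_without_overlap(radii, extent, rng, margin, clearance, n_platforms,
                           max_tries_per_feature: int = 200):
    """Greedy dart-throwing placement; features i and j must be at least
    r_i + r_j + clearance apart.  Raises PlacementError when a feature
    cannot be placed."""
    w, h = extent
    placed_xy = np.zeros((len(radii), 2))
    for i, r in enumerate(radii):
        ok = False
        for _ in range(max_tries_per_feature):
            cx = rng.uniform(margin, w - margin)
            cy = rng.uniform(margin, h - margin)
            if i == 0:
                ok = True
            else:
                d = np.hypot(placed_xy[:i, 0] - cx, placed_xy[:i, 1] - cy)
                ok = bool(np.all(d >= radii[:i] + r + clearance))
            if ok:
                placed_xy[i] = (cx, cy)
                break
        if not ok:
            raise PlacementError(len(radii), i)
    return placed_xy


def _carve_gully(z, x, y, cx, cy, length, width, depth):
    """Gaussian-section trench running downhill (+x)."""
    sel = (np.abs(x - cx) <= length / 2 + 3 * width) & (np.abs(y - cy) <= 4 * width)
    if not sel.any():
        return
    along = np.clip(np.abs(x[sel] - cx) - length / 2, 0.0, None)
    perp = y[sel] - cy
    prof = np.exp(-0.5 * (perp / width) ** 2) * np.exp(-0.5 * (along / width) ** 2)
    z[sel] -= depth * prof


def _add_boulder(z, x, y, cx, cy, radius, height):
    sel = (np.abs(x - cx) <= 4 * radius) & (np.abs(y - cy) <= 4 * radius)
    if not sel.any():
        return
    r2 = (x[sel] - cx) ** 2 + (y[sel] - cy) ** 2
    z[sel] += height * np.exp(-0.5 * r2 / radius**2)


def _cut_terracette(z, x, y, cx, cy, length, width, tan_s):
    """Narrow quasi-bench along the contour (y direction): the terrain step
    across the strip is partially flattened, leaving a feature that is
    locally steep at its edges but too narrow to survive a disc closing."""
    sel = (np.abs(y - cy) <= length / 2) & (np.abs(x - cx) <= width / 2)
    if not sel.any():
        return
    z_line = z[sel] + tan_s * (x[sel] - cx)   # elevation projected to the axis
    z[sel] = 0.35 * z[sel] + 0.65 * z_line


# ---------------------------------------------------------------------------
# charcoal samples
# ---------------------------------------------------------------------------

def generate_charcoal_samples(
    truths,
    taxon_probs: dict[str, float] | None = None,
    frags_per_rch: tuple[int, int] = (2, 6),
    seed: int = 0,
    prob_field=None,
) -> pd.DataFrame:
    """Multinomial charcoal fragment counts per hearth.

    Each hearth yields a uniform number of fragments in ``frags_per_rch``
    distributed over taxa by ``taxon_probs`` (must sum to 1).  Optional
    spatial structure: ``prob_field(x, y)`` returns a per-location
    probability vector, enabling smooth composition gradients.
    Returns a table with unit id, coordinates, per-taxon counts and an
    ``era`` tag of ``"historical"``.
    """
    if taxon_probs is None:
        taxon_probs = dict(DEFAULT_TAXON_PROBS)
    probs = np.asarray(list(taxon_probs.values()), dtype=float)
    if np.any(probs < 0):
        raise ValueError("taxon probabilities must be non-negative")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("taxon probabilities must sum to 1")
    lo, hi = frags_per_rch
    if lo < 1 or hi < lo:
        raise ValueError("frags_per_rch must satisfy 1 <= min <= max")
    rng = np.random.default_rng(seed)
    taxa = list(taxon_probs)
    rows = []
    for t in truths:
        n_frag = int(rng.integers(lo, hi + 1))
        p = probs
        if prob_field is not None:
            p = np.asarray(prob_field(*t.centroid_xy), dtype=float)
            p = p / p.sum()
        counts = rng.multinomial(n_frag, p)
        rec = {"unit_id": t.id, "x": t.centroid_xy[0], "y": t.centroid_xy[1]}
        rec.update(dict(zip(taxa, counts.astype(int))))
        rec["era"] = "historical"
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# forest plots
# ---------------------------------------------------------------------------

RESPONSE_CODES = [
    "tph", "ba", "dbh", "tcd", "piun", "pisy", "lade", "fasy", "piab",
    "otbr", "brill",
]
ENV_CODES = [
    "Rch_d", "Rch_k", "movCo", "road", "build", "elev", "slope", "roug",
    "hli", "Twet", "Tpi", "Tri", "pH", "Corg", "C_N",
]

# Default response model: standardised responses load on two latent spatial
# gradients (G1 elevation-like, G2 heat-load-like) through the standardised
# environmental variables.  The secondary loadings are orthogonal to the
# primary ones so the constrained structure has two distinct axes, with the
# first clearly dominant (roughly 60% vs 20% of response variance) and about
# 80% of the response variance explained overall.
_ENV_G1_LOADING = np.array(
    [0.3, 0.5, 0.1, 0.2, 0.2, 0.95, 0.4, 0.35, -0.2, -0.3, 0.1, 0.35, -0.5, 0.4, 0.5]
)
_ENV_G2_LOADING = np.array(
    [-0.510, -0.337, 0.297, 0.173, 0.173, 0.157, 0.486, 0.478, 1.227, -0.330,
     0.297, 0.478, 0.197, -0.354, -0.197]
)
_RESP_G1_LOADING = np.array(
    [1.0, -0.625, -0.75, 0.625, 1.062, -0.75, 0.375, -0.875, -0.375, -0.75, -0.625]
)
_RESP_G2_LOADING = np.array(
    [-0.046, 0.369, 0.474, -0.209, -0.019, -0.006, 1.363, -0.700, 0.317,
     -0.006, 0.369]
)


@dataclass
class ForestPlotData:
    """Plot-level structure/composition responses, environmental matrix and
    the generating coefficients (for recovery tests)."""

    plots: pd.DataFrame      # n x (xy + 11 responses)
    env: pd.DataFrame        # n x (xy + 15 predictors)
    coef: pd.DataFrame       # predictors x responses, true linear coefficients
    noise_sd: float

    @property
    def response_matrix(self) -> pd.DataFrame:
        return self.plots.drop(columns=["x", "y"])

    @property
    def env_matrix(self) -> pd.DataFrame:
        return self.env.drop(columns=["x", "y"])


def generate_forest_plots(
    n_plots: int = 267,
    env_model: dict | None = None,
    seed: int = 0,
    extent_m: tuple[float, float] = (1280.0, 1280.0),
) -> ForestPlotData:
    """Plot tables with known linear responses to environmental gradients.

    The 15 environmental variables are built from two smooth spatial latent
    gradients plus independent noise; the 11 structure/composition
    descriptors are exact linear responses ``Y = X_std B + E`` with the
    returned coefficient matrix ``B`` and Gaussian noise of standard
    deviation ``noise_sd`` (default 0.45 on standardised responses).

    ``env_model`` may override ``coef`` (p x q array), ``noise_sd``,
    ``env_names``, ``response_names``.  A zero-variance predictor column in
    a custom model raises.
    """
    if n_plots < 10:
        raise ValueError("need at least 10 plots")
    model = dict(env_model or {})
    noise_sd = float(model.get("noise_sd", 0.45))
    env_names = list(model.get("env_names", ENV_CODES))
    resp_names = list(model.get("response_names", RESPONSE_CODES))
    rng = np.random.default_rng(seed)

    xy = rng.uniform([0, 0], list(extent_m), size=(n_plots, 2))
    # latent spatial gradients: smooth low-order trends of the coordinates
    gx = (xy[:, 0] / extent_m[0]) * 2 - 1
    gy = (xy[:, 1] / extent_m[1]) * 2 - 1
    g1 = gx + 0.4 * gy + 0.3 * np.sin(2.2 * np.pi * gy)
    g2 = gy - 0.5 * gx + 0.3 * np.cos(1.7 * np.pi * gx)
    g1 = (g1 - g1.mean()) / g1.std()
    g2 = g2 - (g2 @ g1) / (g1 @ g1) * g1   # second gradient independent of first
    g2 = (g2 - g2.mean()) / g2.std()

    if "env" in model:
        X = np.asarray(model["env"], dtype=float)
        if X.shape[0] != n_plots:
            raise ValueError("custom env matrix must have n_plots rows")
    else:
        p = len(env_names)
        unique = rng.standard_normal((n_plots, p))
        X = (
            np.outer(g1, _ENV_G1_LOADING[:p])
            + np.outer(g2, _ENV_G2_LOADING[:p])
            + 0.55 * unique
        )
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [env_names[j] for j in np.nonzero(sd == 0)[0]]
        raise ValueError(f"zero-variance environmental predictors: {bad}")

    if "coef" in model:
        B = np.asarray(model["coef"], dtype=float)
        if B.shape[0] != X.shape[1]:
            raise ValueError("coef rows must match the number of predictors")
        resp_names = resp_names[: B.shape[1]]
    else:
        # responses react to the gradients through their strongest markers
        p, q = len(env_names), len(resp_names)
        B = (
            np.outer(_ENV_G1_LOADING[:p], _RESP_G1_LOADING[:q])
            + np.outer(_ENV_G2_LOADING[:p], _RESP_G2_LOADING[:q])
        ) / 3.0
    X_std = (X - X.mean(axis=0)) / sd
    E = noise_sd * rng.standard_normal((n_plots, B.shape[1]))
    Y = X_std @ B + E

    env_df = pd.DataFrame(X, columns=env_names)
    env_df.insert(0, "y", xy[:, 1])
    env_df.insert(0, "x", xy[:, 0])
    plot_df = pd.DataFrame(Y, columns=resp_names)
    plot_df.insert(0, "y", xy[:, 1])
    plot_df.insert(0, "x", xy[:, 0])
    coef_df = pd.DataFrame(B, index=env_names, columns=resp_names)
    return ForestPlotData(plots=plot_df, env=env_df, coef=coef_df, noise_sd=noise_sd)
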