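"""Synthetic multi-channel time-lapse movies with known ground truth.

Generates movies that emulate live-cell imaging of nucleolar-nucleoplasmic
protein shuttling: each nucleus (nuclear-stain channel) contains a few bright
nucleolar-marker foci (marker channel), and a protein-of-interest (POI)
channel whose nucleolar enrichment relaxes exponentially from a baseline
``E0`` toward a post-treatment plateau ``E_inf`` with time constant
``tau_min``.  The paired :class:`SimulationTruth` carries the exact label
maps and the generating kinetics, so every downstream stage of the analysis
pipeline can be validated against known answers.

The camera model is Poisson photon noise followed by additive Gaussian read
noise and integer quantization.  Disabling both noise sources
(``photon_scale=None`` and ``read_noise_sd=0``) switches the renderer into an
exact mode: frames are emitted as float64 without quantization, so region
means computed downstream reproduce the generating enrichment to floating
point accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse

__all__ = [
    "SimConfig",
    "SimulationTruth",
    "PlacementError",
    "enrichment_at",
    "render_movie",
    "render_sir_hoechst_response",
    "make_brush_labels",
]


class PlacementError(RuntimeError):
    """Raised when the requested number of cells cannot be placed.

    Attributes
    ----------
    n_placed : int
        Number of cells successfully placed before giving up.
    """

    def __init__(self, n_requested: int, n_placed: int):
        self.n_requested = n_requested
        self.n_placed = n_placed
        super().__init__(
            f"could only place {n_placed} of {n_requested} cells within "
            f"image bounds after bounded retries"
        )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic movie.

    Defaults emulate a typical acquisition: 5-min frame interval over
    ~2 h (25 frames), 30 cells per image, 1-4 nucleoli per nucleus, and a
    >= 4-fold spread of per-cell nucleolar-marker brightness so that the
    "dim marker" failure mode of plain global thresholding is represented.
    """

    image_size_px: tuple[int, int] = (360, 360)
    n_cells: int = 30
    n_frames: int = 25
    frame_interval_min: float = 5.0
    nucleus_radius_px: tuple[float, float] = (14.0, 2.0)  # mean, sd
    nucleoli_per_cell: tuple[int, int] = (1, 4)  # inclusive range
    nucleolus_radius_px: tuple[float, float] = (4.0, 0.8)  # mean, sd
    clustering_fraction: float = 0.3
    E0: float = 3.0
    E_inf: float = 1.2
    tau_min: float = 30.0
    treatment_frame: int = 0
    marker_intensity_range: tuple[float, float] = (0.25, 1.0)
    marker_distribution: str = "uniform"  # "uniform" | "bimodal"
    photon_scale: float | None = 50.0
    read_noise_sd: float = 2.0
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.E0 < 1 or self.E_inf < 1:
            raise ValueError("E0 and E_inf must be >= 1 (enrichment ratios)")
        if self.tau_min <= 0:
            raise ValueError("tau_min must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.nucleus_radius_px[0] <= 0 or self.nucleolus_radius_px[0] <= 0:
            raise ValueError("radii must be > 0")
        if not 0 <= self.clustering_fraction <= 1:
            raise ValueError("clustering_fraction must be in [0, 1]")
        lo, hi = self.nucleoli_per_cell
        if not 1 <= lo <= hi:
            raise ValueError("nucleoli_per_cell must be an increasing range >= 1")
        if self.marker_distribution not in ("uniform", "bimodal"):
            raise ValueError("marker_distribution must be 'uniform' or 'bimodal'")

    @property
    def noise_free(self) -> bool:
        ps = self.photon_scale
        return (ps is None or math.isinf(ps)) and self.read_noise_sd == 0

    def without_noise(self) -> "SimConfig":
        """Copy of this config with all noise sources disabled."""
        return replace(self, photon_scale=None, read_noise_sd=0.0)


@dataclass
class SimulationTruth:
    """Ground truth paired with a rendered movie.

    Cells do not move, divide, or drift, so the label maps are constant
    across frames and stored once; ``nucleus_labels``/``nucleolus_labels``
    are 2D integer arrays valid for every frame.
    """

    nucleus_labels: np.ndarray  # (Y, X) int, 0 background, 1..n_cells
    nucleolus_labels: np.ndarray  # (Y, X) int, 0 background, 1..n_nucleoli
    nucleolus_to_cell: dict[int, int]  # nucleolus label -> nucleus label
    per_cell_E_t: pd.DataFrame  # columns: cell, frame, time_min, enrichment
    config: SimConfig

    def enrichment_series(self) -> pd.DataFrame:
        """True enrichment per frame (identical for all cells in v1)."""
        return (
            self.per_cell_E_t.groupby("frame", as_index=False)
            .agg(time_min=("time_min", "first"), enrichment=("enrichment", "mean"))
        )


def enrichment_at(t: float, E0: float, E_inf: float, tau: float) -> float:
    """Nucleolar enrichment at time ``t`` minutes after treatment.

    Single-exponential relaxation ``E(t) = E_inf + (E0 - E_inf) exp(-t/tau)``:
    the simplest kinetic law consistent with an immediate post-treatment onset
    and a plateau after roughly three time constants.

    Parameters
    ----------
    t : float
        Minutes elapsed since treatment (>= 0).
    E0, E_inf : float
        Baseline and plateau enrichment (dimensionless, >= 1).
    tau : float
        Time constant in minutes (> 0).
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    return E_inf + (E0 - E_inf) * math.exp(-t / tau)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def _sample_ellipse(rng: np.random.Generator, cfg: SimConfig) -> tuple[float, float, float]:
    """Semi-axes (a, b) and orientation for one nucleus."""
    mean_r, sd_r = cfg.nucleus_radius_px
    r = max(4.0, rng.normal(mean_r, sd_r))
    ecc = rng.uniform(0.75, 1.0)  # mild elongation; star-convex
    a, b = r / math.sqrt(ecc), r * math.sqrt(ecc)
    theta = rng.uniform(0, math.pi)
    return a, b, theta


def _ellipse_mask(shape, cy, cx, a, b, theta) -> tuple[np.ndarray, np.ndarray]:
    rr, cc = draw_ellipse(cy, cx, a, b, rotation=theta, shape=shape)
    return rr, cc


def _place_cells(rng: np.random.Generator, cfg: SimConfig):
    """Place non-overlapping elliptical nuclei; a fraction touch a neighbor.

    Returns the nucleus label map.  Raises :class:`PlacementError` if fewer
    than ``n_cells`` fit after bounded retries.
    """
    h, w = cfg.image_size_px
    labels = np.zeros((h, w), dtype=np.int32)
    occupied = np.zeros((h, w), dtype=bool)
    border_margin = 4  # keep truth objects off the border
    n_clustered = int(round(cfg.clustering_fraction * cfg.n_cells))

    placed = 0
    struct = np.ones((5, 5), bool)  # 2-px separation for non-clustered cells
    for i in range(cfg.n_cells):
        want_cluster = placed > 0 and (cfg.n_cells - i) <= n_clustered
        a, b, theta = _sample_ellipse(rng, cfg)
        ok = False
        for _attempt in range(400):
            if want_cluster:
                # anchor next to an existing cell: walk inward along a ray
                # until the candidate just touches the occupied set
                anchor_lab = int(rng.integers(1, placed + 1))
                ys, xs = np.nonzero(labels == anchor_lab)
                acy, acx = ys.mean(), xs.mean()
                ang = rng.uniform(0, 2 * math.pi)
                max_r = max(a, b)
                found = None
                for d in np.arange(2.4 * max_r, 0.8 * max_r, -1.0):
                    cy = acy + d * math.sin(ang)
                    cx = acx + d * math.cos(ang)
                    if not (border_margin + max_r < cy < h - border_margin - max_r
                            and border_margin + max_r < cx < w - border_margin - max_r):
                        continue
                    rr, cc = _ellipse_mask((h, w), cy, cx, a, b, theta)
                    if occupied[rr, cc].any():
                        break  # previous d (if any) was the touching position
                    cand = np.zeros((h, w), bool)
                    cand[rr, cc] = True
                    touch = ndi.binary_dilation(cand, np.ones((3, 3), bool)) & occupied
                    found = (rr, cc) if touch.any() else found
                    if touch.any():
                        break
                if found is None:
                    continue
                rr, cc = found
            else:
                max_r = max(a, b)
                cy = rng.uniform(border_margin + max_r, h - border_margin - max_r)
                cx = rng.uniform(border_margin + max_r, w - border_margin - max_r)
                rr, cc = _ellipse_mask((h, w), cy, cx, a, b, theta)
                cand = np.zeros((h, w), bool)
                cand[rr, cc] = True
                if (ndi.binary_dilation(cand, struct) & occupied).any():
                    continue
            labels[rr, cc] = placed + 1
            occupied[rr, cc] = True
            placed += 1
            ok = True
            break
        if not ok:
            raise PlacementError(cfg.n_cells, placed)
    return labels


def _place_nucleoli(rng: np.random.Generator, cfg: SimConfig, nucleus_labels: np.ndarray):
    """Disk nucleoli fully inside each nucleus with >= 2 px margin."""
    h, w = nucleus_labels.shape
    nucleolus_labels = np.zeros((h, w), dtype=np.int32)
    nucleolus_to_cell: dict[int, int] = {}
    next_label = 1
    lo, hi = cfg.nucleoli_per_cell
    mean_r, sd_r = cfg.nucleolus_radius_px
    yy, xx = np.mgrid[0:h, 0:w]
    for cell in range(1, int(nucleus_labels.max()) + 1):
        mask = nucleus_labels == cell
        dist_in = ndi.distance_transform_edt(mask)
        n_nuc = int(rng.integers(lo, hi + 1))
        placed_centers: list[tuple[float, float, float]] = []
        for _ in range(n_nuc):
            r = max(2.0, rng.normal(mean_r, sd_r))
            # candidate centers: deep enough inside the nucleus, clear of
            # nucleoli already placed in this cell
            cand = dist_in >= (r + 2.0)
            for (pcy, pcx, pr) in placed_centers:
                cand &= (yy - pcy) ** 2 + (xx - pcx) ** 2 > (r + pr + 1.0) ** 2
            ys, xs = np.nonzero(cand)
            if ys.size == 0:
                continue  # nucleus too small/full; fewer nucleoli for this cell
            k = int(rng.integers(0, ys.size))
            cy, cx = float(ys[k]), float(xs[k])
            rr, cc = draw_ellipse(cy, cx, r, r, shape=(h, w))
            nucleolus_labels[rr, cc] = next_label
            nucleolus_to_cell[next_label] = cell
            placed_centers.append((cy, cx, r))
            next_label += 1
    return nucleolus_labels, nucleolus_to_cell


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_BG = {"nuclear_stain": 5.0, "nucleolar_marker": 5.0, "poi": 2.0}
_NUCLEAR_BASE = 120.0
_MARKER_NUCLEOLUS = 200.0
_MARKER_NUCLEOPLASM = 15.0

CHANNEL_ROLES = {"nuclear_stain": 0, "nucleolar_marker": 1, "poi": 2}


def _apply_camera(clean: np.ndarray, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Poisson photon noise, Gaussian read noise, clip + quantize."""
    if cfg.noise_free:
        return clean.astype(np.float64)
    img = clean
    ps = cfg.photon_scale
    if ps is not None and not math.isinf(ps):
        img = rng.poisson(np.clip(img, 0, None) * ps).astype(np.float64) / ps
    if cfg.read_noise_sd > 0:
        img = img + rng.normal(0.0, cfg.read_noise_sd, size=img.shape)
    maxval = 2 ** cfg.bit_depth - 1
    img = np.clip(np.rint(img), 0, maxval)
    dtype = np.uint8 if cfg.bit_depth <= 8 else np.uint16 if cfg.bit_depth <= 16 else np.uint32
    return img.astype(dtype)


def render_movie(
    config: SimConfig,
    gain_fn: Callable[[float], float] | None = None,
):
    """Render a synthetic movie and its paired ground truth.

    Channels (T, C, Y, X order): nuclear stain (uniform nuclear level with a
    smooth intranuclear texture), nucleolar marker (bright foci, per-cell
    brightness factor drawn from ``marker_intensity_range``, constant over
    time), and POI (per-cell nucleoplasmic baseline ``b`` and nucleolar level
    ``b * E(t)``).

    Returns
    -------
    (pixels, truth)
        ``pixels`` is a (T, C, Y, X) array — float64 in noise-free mode,
        unsigned integer otherwise; ``truth`` is a :class:`SimulationTruth`.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size_px

    nucleus_labels = _place_cells(rng, config)
    nucleolus_labels, nucleolus_to_cell = _place_nucleoli(rng, config, nucleus_labels)
    n_cells = int(nucleus_labels.max())

    # per-cell scalars; the bimodal option is the designed mixed-brightness
    # scene: half the cells sit at the dim end, half at the bright end of
    # marker_intensity_range (a 4x contrast at the defaults), which is the
    # regime where one global threshold cannot serve all cells
    if config.marker_distribution == "bimodal":
        lo, hi = config.marker_intensity_range
        marker_factor = np.where(rng.permutation(n_cells) % 2 == 0, lo, hi).astype(float)
    else:
        marker_factor = rng.uniform(*config.marker_intensity_range, size=n_cells)
    poi_baseline = rng.uniform(80.0, 120.0, size=n_cells)

    # smooth intranuclear texture for the nuclear-stain channel (+/- 10%)
    texture = ndi.gaussian_filter(rng.standard_normal((h, w)), sigma=8.0)
    texture = 1.0 + 0.1 * texture / max(np.abs(texture).max(), 1e-12)

    nuc_mask = nucleus_labels > 0
    base_nuclear = np.full((h, w), _BG["nuclear_stain"])
    base_nuclear[nuc_mask] = _NUCLEAR_BASE * texture[nuc_mask]

    base_marker = np.full((h, w), _BG["nucleolar_marker"])
    for cell in range(1, n_cells + 1):
        m = marker_factor[cell - 1]
        base_marker[nucleus_labels == cell] = _MARKER_NUCLEOPLASM * m
    for lab, cell in nucleolus_to_cell.items():
        base_marker[nucleolus_labels == lab] = _MARKER_NUCLEOLUS * marker_factor[cell - 1]

    poi_np = np.full((h, w), _BG["poi"])
    for cell in range(1, n_cells + 1):
        poi_np[nucleus_labels == cell] = poi_baseline[cell - 1]

    # nucleolus pixels indexed once; per frame only the enrichment changes
    nl_y, nl_x = np.nonzero(nucleolus_labels)
    nl_cells = np.array(
        [nucleolus_to_cell[lab] for lab in nucleolus_labels[nl_y, nl_x]], dtype=int
    )
    nl_base = poi_baseline[nl_cells - 1] if nl_cells.size else np.empty(0)

    frames = []
    rows = []
    for f in range(config.n_frames):
        t_since = max(0.0, (f - config.treatment_frame) * config.frame_interval_min)
        if f < config.treatment_frame:
            E = config.E0
        else:
            E = enrichment_at(t_since, config.E0, config.E_inf, config.tau_min)
        poi = poi_np.copy()
        poi[nl_y, nl_x] = nl_base * E
        t_min = f * config.frame_interval_min
        gain = 1.0 if gain_fn is None else float(gain_fn(t_min))
        if gain < 0:
            raise ValueError("intensity gain must be >= 0")
        clean = np.stack([base_nuclear * gain, base_marker, poi])
        frames.append(_apply_camera(clean, config, rng))
        for cell in range(1, n_cells + 1):
            rows.append((cell, f, t_min, E))

    pixels = np.stack(frames)  # (T, C, Y, X)
    truth = SimulationTruth(
        nucleus_labels=nucleus_labels,
        nucleolus_labels=nucleolus_labels,
        nucleolus_to_cell=nucleolus_to_cell,
        per_cell_E_t=pd.DataFrame(rows, columns=["cell", "frame", "time_min", "enrichment"]),
        config=config,
    )
    return pixels, truth


def render_sir_hoechst_response(
    config: SimConfig, intensity_gain_fn: Callable[[float], float]
):
    """Movie whose nuclear-stain channel is scaled frame-wise by a gain.

    Emulates a treatment-induced change in chromatin-stain intensity; the
    marker and POI channels are untouched.  ``intensity_gain_fn`` maps time
    in minutes to a multiplier >= 0 applied to the clean nuclear channel
    before the camera model.
    """
    return render_movie(config, gain_fn=intensity_gain_fn)


def make_brush_labels(
    truth: SimulationTruth,
    n_per_class: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Sparse brush-stroke-style training labels drawn from the truth masks.

    Emulates a user clicking examples of the two classes: returns a (Y, X)
    uint8 image with 0 = unlabeled, 1 = nucleolus, 2 = background, with
    ``n_per_class`` pixels of each class sampled at random.  Background
    samples are split between nucleoplasm and extranuclear pixels so the
    classifier sees both kinds of non-nucleolar signal.
    """
    rng = np.random.default_rng(seed)
    out = np.zeros(truth.nucleolus_labels.shape, dtype=np.uint8)
    bg_np = np.flatnonzero(((truth.nucleus_labels > 0) & (truth.nucleolus_labels == 0)).ravel())
    bg_out = np.flatnonzero((truth.nucleus_labels == 0).ravel())
    n_nucleoli = int(truth.nucleolus_labels.max())
    if n_nucleoli == 0:
        raise ValueError("truth contains no nucleolus pixels")
    flat = out.ravel()
    # stratify foreground strokes across nucleoli so that dim cells are
    # always represented in the training set
    per_obj = max(1, n_per_class // n_nucleoli)
    nl_flat = truth.nucleolus_labels.ravel()
    for lab in range(1, n_nucleoli + 1):
        px = np.flatnonzero(nl_flat == lab)
        flat[rng.choice(px, size=min(per_obj, px.size), replace=False)] = 1
    half = n_per_class // 2
    flat[rng.choice(bg_np, size=min(half, bg_np.size), replace=False)] = 2
    flat[rng.choice(bg_out, size=min(n_per_class - half, bg_out.size), replace=False)] = 2
    return out
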