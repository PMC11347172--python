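"""From label maps to the time-resolved shuttling readout.

The readout follows the workflow's label arithmetic: each detected nucleolus
is assigned to the nucleus it overlaps most, the nucleoplasm is the nucleus
minus its (pooled) nucleoli, and for every cell and time point the ratio of
the mean nucleolar to mean nucleoplasmic intensity of the protein of
interest is computed, minus 1 so that "no enrichment" reads as zero.

Aggregation convention: per-cell ratio -> per-image mean over cells ->
per-condition mean +/- SEM over images.  The microscopic image is the
replication unit, so the SEM is computed across images, not across cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import curve_fit

from .imgio import ImageStack
from .segment_nuclei import LabelMap

logger = logging.getLogger(__name__)

__all__ = [
    "CellRegionSet",
    "ShuttlingSeries",
    "KineticsFit",
    "derive_regions",
    "extract_features",
    "ratio_series",
    "nuclear_intensity_series",
    "recover_kinetics",
]


@dataclass
class CellRegionSet:
    """Per-nucleus nucleolar and nucleoplasmic pixel sets for one frame.

    ``nucleolar_owner`` holds, at every assigned nucleolar pixel, the label
    of the owning nucleus (0 elsewhere); pixels of a nucleolus that stick
    out of its assigned nucleus are clipped away, so for every cell k the
    nucleolar and nucleoplasmic masks partition the nucleus mask exactly.
    """

    nucleus_labels: LabelMap
    nucleolar_owner: np.ndarray  # (Y, X) int: owning nucleus label at nucleolar px
    assignment: dict[int, int]  # nucleolus label -> nucleus label
    n_discarded: int = 0

    @property
    def cell_labels(self) -> np.ndarray:
        vals = np.unique(self.nucleus_labels)
        return vals[vals != 0]

    def nucleolar_mask(self, cell: int) -> np.ndarray:
        return self.nucleolar_owner == cell

    def nucleoplasm_mask(self, cell: int) -> np.ndarray:
        return (self.nucleus_labels == cell) & (self.nucleolar_owner != cell)

    @property
    def nucleoplasm_labels(self) -> LabelMap:
        return np.where(self.nucleolar_owner == 0, self.nucleus_labels, 0)


def derive_regions(nuclei: LabelMap, nucleoli: LabelMap) -> CellRegionSet:
    """Assign nucleoli to nuclei and derive nucleoplasmic regions.

    Each nucleolus goes to the nucleus with maximal pixel overlap (ties to
    the lower nucleus label); a nucleolus with zero overlap with any nucleus
    is discarded and logged.  Nucleolus pixels outside the assigned nucleus
    are clipped to the nucleus.
    """
    nuclei = np.asarray(nuclei)
    nucleoli = np.asarray(nucleoli)
    if nuclei.shape != nucleoli.shape:
        raise ValueError(f"shape mismatch: nuclei {nuclei.shape} vs nucleoli {nucleoli.shape}")
    assignment: dict[int, int] = {}
    n_discarded = 0
    sel = nucleoli > 0
    nl_vals = nucleoli[sel]
    nuc_vals = nuclei[sel]
    owner = np.zeros_like(nuclei, dtype=np.int32)
    if nl_vals.size:
        n_nuc = int(nuclei.max())
        # joint histogram of (nucleolus label, nucleus label) over nucleolus px
        pair = nl_vals.astype(np.int64) * (n_nuc + 1) + nuc_vals
        counts = np.bincount(pair, minlength=(int(nl_vals.max()) + 1) * (n_nuc + 1))
        counts = counts.reshape(-1, n_nuc + 1)
        for lab in np.unique(nl_vals):
            overlaps = counts[lab, 1:]  # overlap with each nucleus, bg excluded
            if overlaps.sum() == 0:
                n_discarded += 1
                logger.info("nucleolus %d overlaps no nucleus; discarded", lab)
                continue
            cell = int(np.argmax(overlaps)) + 1  # argmax -> lowest label on ties
            assignment[int(lab)] = cell
            owner[(nucleoli == lab) & (nuclei == cell)] = cell
    return CellRegionSet(
        nucleus_labels=nuclei,
        nucleolar_owner=owner,
        assignment=assignment,
        n_discarded=n_discarded,
    )


def _labeled_means(values: np.ndarray, labels: np.ndarray, index: np.ndarray):
    """Mean of ``values`` per label; NaN where a label has no pixels."""
    areas = np.bincount(labels.ravel(), minlength=int(index.max()) + 1 if index.size else 1)
    sums = np.bincount(labels.ravel(), weights=values.ravel(),
                       minlength=int(index.max()) + 1 if index.size else 1)
    means = np.full(index.shape, np.nan)
    for i, lab in enumerate(index):
        if areas[lab] > 0:
            means[i] = sums[lab] / areas[lab]
    return means, areas[index] if index.size else np.array([], dtype=int)


def extract_features(
    stack: ImageStack,
    regions_per_frame: list[CellRegionSet],
    image_id: str = "img0",
) -> pd.DataFrame:
    """Per-cell, per-frame mean intensities and areas.

    Returns a long-format table with columns image, cell, frame,
    mean_poi_nucleolar, mean_poi_nucleoplasm, mean_nuclear_stain,
    area_nucleus, area_nucleolar, area_nucleoplasm.  Means are plain
    arithmetic means of the raw pixel values; a cell with an empty
    nucleolar mask gets NaN for the nucleolar mean (excluded downstream).
    """
    if len(regions_per_frame) != stack.n_frames:
        raise ValueError("one CellRegionSet per frame required")
    poi = stack.channel("poi")
    nuc_stain = stack.channel("nuclear_stain")
    rows = []
    for f, regions in enumerate(regions_per_frame):
        cells = regions.cell_labels
        if cells.size == 0:
            continue
        m_no, a_no = _labeled_means(poi[f], regions.nucleolar_owner, cells)
        m_np, a_np = _labeled_means(poi[f], regions.nucleoplasm_labels, cells)
        m_ns, a_nu = _labeled_means(nuc_stain[f], regions.nucleus_labels, cells)
        for i, cell in enumerate(cells):
            rows.append(
                (image_id, int(cell), f, m_no[i], m_np[i], m_ns[i],
                 int(a_nu[i]), int(a_no[i]), int(a_np[i]))
            )
    return pd.DataFrame(
        rows,
        columns=[
            "image", "cell", "frame",
            "mean_poi_nucleolar", "mean_poi_nucleoplasm", "mean_nuclear_stain",
            "area_nucleus", "area_nucleolar", "area_nucleoplasm",
        ],
    )


@dataclass
class ShuttlingSeries:
    """Per-condition time series of the ratio readout.

    ``table`` columns: condition, time_min, iteration, mean_ratio_minus1,
    sem, n_images, n_cells.  ``n_excluded`` counts cells dropped for a
    missing nucleolar mean or non-positive nucleoplasmic mean.
    """

    table: pd.DataFrame
    n_excluded: int = 0

    def condition(self, name: str) -> pd.DataFrame:
        sub = self.table[self.table["condition"] == name]
        if sub.empty:
            raise KeyError(f"no condition {name!r} in series")
        return sub.sort_values("iteration").reset_index(drop=True)


def _aggregate(
    per_cell: pd.DataFrame,
    value_col: str,
    grouping: Mapping[str, str],
    frame_interval_min: float,
    out_col: str,
) -> ShuttlingSeries:
    df = per_cell.copy()
    df["condition"] = df["image"].map(lambda im: grouping[im])
    n_excluded = int(df[value_col].isna().sum())
    df = df.dropna(subset=[value_col])
    per_image = (
        df.groupby(["condition", "image", "frame"], as_index=False)
        .agg(value=(value_col, "mean"), n_cells=(value_col, "size"))
    )
    def sem(x):
        return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
    per_cond = (
        per_image.groupby(["condition", "frame"], as_index=False)
        .agg(**{out_col: ("value", "mean")},
             sem=("value", sem), n_images=("value", "size"), n_cells=("n_cells", "sum"))
    )
    per_cond["iteration"] = per_cond["frame"]
    per_cond["time_min"] = per_cond["frame"] * frame_interval_min
    table = per_cond[
        ["condition", "time_min", "iteration", out_col, "sem", "n_images", "n_cells"]
    ].sort_values(["condition", "iteration"]).reset_index(drop=True)
    return ShuttlingSeries(table=table, n_excluded=n_excluded)


def ratio_series(
    features: pd.DataFrame,
    grouping: Mapping[str, str],
    frame_interval_min: float = 5.0,
) -> ShuttlingSeries:
    """The platform's primary readout: mean-of-images (ratio - 1) +/- SEM.

    Per cell, r = mean nucleolar POI / mean nucleoplasmic POI - 1; cells
    with a missing nucleolar mean or a non-positive nucleoplasmic mean are
    excluded and counted.  Per image and frame the cell ratios are averaged;
    per condition and frame the image means are averaged with their SEM.
    """
    df = features.copy()
    bad = df["mean_poi_nucleoplasm"].isna() | (df["mean_poi_nucleoplasm"] <= 0)
    df.loc[bad, "mean_poi_nucleolar"] = np.nan
    df["ratio_minus1"] = df["mean_poi_nucleolar"] / df["mean_poi_nucleoplasm"] - 1.0
    return _aggregate(df, "ratio_minus1", grouping, frame_interval_min, "mean_ratio_minus1")


def nuclear_intensity_series(
    features: pd.DataFrame,
    grouping: Mapping[str, str],
    frame_interval_min: float = 5.0,
) -> ShuttlingSeries:
    """Mean nuclear-stain intensity per condition and time point.

    Same aggregation convention as :func:`ratio_series`, applied to the
    per-cell mean nuclear-stain intensity (chromatin-compaction readout).
    """
    return _aggregate(
        features, "mean_nuclear_stain", grouping, frame_interval_min,
        "mean_nuclear_intensity",
    )


@dataclass
class KineticsFit:
    E0: float
    E_inf: float
    tau_min: float
    rmse: float
    identifiable: bool
    success: bool
    message: str = ""


def recover_kinetics(
    series: ShuttlingSeries | pd.DataFrame,
    treatment_frame: int = 0,
    condition: str | None = None,
    seed: int = 0,
) -> KineticsFit:
    """Fit the single-exponential shuttling model to a measured series.

    Model: r(t) = (E_inf - 1) + (E0 - E_inf) * exp(-(t - t0)/tau), fit by
    seeded multi-start nonlinear least squares on the post-treatment frames.
    A flat series (no detectable transition) is reported with
    ``identifiable=False`` rather than a spurious time constant.
    """
    table = series.table if isinstance(series, ShuttlingSeries) else series
    if condition is not None:
        table = table[table["condition"] == condition]
    elif "condition" in table and table["condition"].nunique() > 1:
        raise ValueError("multiple conditions present; pass condition=...")
    table = table.sort_values("iteration")
    post = table[table["iteration"] >= treatment_frame]
    if len(post) < 5:
        raise ValueError("need at least 5 post-treatment frames to fit kinetics")
    t = post["time_min"].to_numpy(dtype=float)
    r = post["mean_ratio_minus1"].to_numpy(dtype=float)
    t0 = float(t[0])

    spread = float(np.std(r))
    if spread < 1e-3 * max(1.0, float(np.abs(r).mean())):
        level = float(r.mean()) + 1.0
        return KineticsFit(
            E0=level, E_inf=level, tau_min=np.nan, rmse=spread,
            identifiable=False, success=True,
            message="series is flat; tau unidentifiable",
        )

    def model(tt, e0, einf, tau):
        return (einf - 1.0) + (e0 - einf) * np.exp(-(tt - t0) / tau)

    rng = np.random.default_rng(seed)
    tau_starts = [5.0, 15.0, 30.0, 60.0, 120.0] + list(rng.uniform(5, 150, 3))
    e0_guess = float(r[0]) + 1.0
    einf_guess = float(r[-1]) + 1.0
    best = None
    for tau0 in tau_starts:
        try:
            popt, _ = curve_fit(
                model, t, r,
                p0=[e0_guess, einf_guess, tau0],
                bounds=([0.0, 0.0, 1e-3], [np.inf, np.inf, 1e5]),
                maxfev=10000,
            )
        except RuntimeError:
            continue
        resid = model(t, *popt) - r
        sse = float(resid @ resid)
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        return KineticsFit(
            E0=np.nan, E_inf=np.nan, tau_min=np.nan, rmse=np.nan,
            identifiable=False, success=False, message="fit did not converge",
        )
    sse, (e0, einf, tau) = best
    rmse = float(np.sqrt(sse / len(t)))
    return KineticsFit(
        E0=float(e0), E_inf=float(einf), tau_min=float(tau), rmse=rmse,
        identifiable=True, success=True,
    )
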