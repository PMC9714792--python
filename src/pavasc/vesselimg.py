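"""Vessel-wall image quantification.

Two workflows over multichannel transverse vessel sections:

* radial intensity profiling — segment the vessel (lumen + outer
  circumference) from the combined structural channels, cast evenly spaced
  probes from the lumen center of mass, and average each channel's
  lumen-boundary-to-outer-boundary intensity trace on a common normalized
  radial axis;
* medial proliferation-marker quantification — Yen-threshold the nuclear
  channel, split nuclei by watershed on the distance transform, call each
  nucleus medial when dilated ACTA2 signal overlaps it while no VWF signal
  lies within it, and report the percentage of medial nuclei whose
  marker-positive area fraction exceeds a cutoff.

Images are (channels, rows, cols) arrays; z-stacks are reduced first with
:func:`max_project`.  Coordinates are row/col, 0-based, pixel centers at
integer coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure, morphology
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .sc_qc_stats import rank_sum_test

__all__ = [
    "VesselROIs",
    "RadialProfile",
    "max_project",
    "segment_vessel",
    "radial_profile",
    "yen_threshold",
    "segment_nuclei",
    "assign_medial",
    "quantify_marker",
    "compare_groups",
    "SegmentationError",
]


class SegmentationError(RuntimeError):
    """Raised when the vessel geometry cannot be segmented."""


@dataclass
class VesselROIs:
    lumen_mask: np.ndarray  # binary
    outer_mask: np.ndarray  # filled vessel region, binary
    center: tuple[float, float]  # lumen center of mass (row, col)


@dataclass
class RadialProfile:
    positions: np.ndarray  # normalized radial axis in [0, 1]
    profiles: dict  # channel role -> mean intensity vector
    traces: dict = field(default_factory=dict)  # role -> (n_probes, F) raw traces
    dropped_probes: list = field(default_factory=list)


def max_project(stack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum across z-planes; (Z, ..., Y, X) -> (..., Y, X)."""
    stack = np.asarray(stack)
    if stack.ndim < 3:
        raise ValueError("expected a stack with a leading z axis")
    return stack.max(axis=0)


def segment_vessel(
    image: np.ndarray,
    roles: list[str],
    shape_channels: tuple[str, ...] = ("vcan", "acta2"),
) -> VesselROIs:
    """Vessel lumen and outer-circumference ROIs from structural channels.

    The named channels are combined by per-pixel maximum and thresholded
    (Otsu).  The outer mask is the filled largest connected component; the
    lumen is the largest hole inside it; the lumen center of mass is taken
    on the binary lumen mask.
    """
    idx = [roles.index(c) for c in shape_channels if c in roles]
    if not idx:
        raise ValueError(f"none of {shape_channels} found in roles {roles}")
    combined = image[idx].max(axis=0)
    binary = combined > threshold_otsu(combined)
    labels = measure.label(binary)
    if labels.max() == 0:
        raise SegmentationError("no foreground after thresholding")
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    component = labels == largest
    filled = ndi.binary_fill_holes(component)
    holes = filled & ~component
    hole_labels = measure.label(holes)
    if hole_labels.max() == 0:
        raise SegmentationError("no lumen hole found (vessel not transverse?)")
    lumen = hole_labels == (np.argmax(np.bincount(hole_labels.ravel())[1:]) + 1)
    center = ndi.center_of_mass(lumen)
    return VesselROIs(lumen_mask=lumen, outer_mask=filled, center=center)


def radial_profile(
    image: np.ndarray,
    roles: list[str],
    rois: VesselROIs,
    n_probes: int = 32,
    samples_per_probe: int = 100,
    step: float = 0.25,
    max_dropped_fraction: float = 0.5,
) -> RadialProfile:
    """Average radial intensity traces over evenly spaced probes.

    Probes are rays from the lumen center at angles 2*pi*k/n_probes.  Along
    each ray the lumen-boundary and outer-boundary crossings are located by
    marching in ``step``-pixel increments; intensities are then sampled with
    bilinear interpolation at ``samples_per_probe`` positions evenly spaced
    between the two crossings, i.e. on a common normalized axis where 0 is
    the lumen boundary and 1 the outer boundary.  Probes failing to cross
    both boundaries inside the image are dropped and reported; more than
    ``max_dropped_fraction`` dropped probes is a geometry error.
    """
    cy, cx = rois.center
    h, w = rois.lumen_mask.shape
    r_max = float(np.hypot(h, w))
    t = np.linspace(0.0, 1.0, samples_per_probe)
    traces = {role: np.full((n_probes, samples_per_probe), np.nan) for role in roles}
    dropped = []
    for k in range(n_probes):
        ang = 2.0 * np.pi * k / n_probes
        dy, dx = np.sin(ang), np.cos(ang)
        radii = np.arange(0.0, r_max, step)
        ys, xs = cy + radii * dy, cx + radii * dx
        inside = (ys >= 0) & (ys <= h - 1) & (xs >= 0) & (xs <= w - 1)
        lum = np.zeros(len(radii), dtype=bool)
        out = np.zeros(len(radii), dtype=bool)
        yi = np.clip(np.round(ys), 0, h - 1).astype(int)
        xi = np.clip(np.round(xs), 0, w - 1).astype(int)
        lum[inside] = rois.lumen_mask[yi[inside], xi[inside]]
        out[inside] = rois.outer_mask[yi[inside], xi[inside]]
        exit_lumen = np.flatnonzero(~lum)
        exit_lumen = exit_lumen[exit_lumen > 0]
        if not lum[0] or len(exit_lumen) == 0:
            dropped.append(k)
            continue
        r_lumen = radii[exit_lumen[0]]
        beyond = np.flatnonzero(~out & (radii >= r_lumen) & inside)
        outside_img = np.flatnonzero(~inside & (radii >= r_lumen))
        if len(beyond) == 0 or (
            len(outside_img) and outside_img[0] < beyond[0]
        ):
            dropped.append(k)  # ray leaves the image while still in the vessel
            continue
        r_outer = radii[beyond[0]]
        rr = r_lumen + t * (r_outer - r_lumen)
        coords = np.vstack([cy + rr * dy, cx + rr * dx])
        for role, chan in zip(roles, image):
            traces[role][k] = ndi.map_coordinates(
                chan.astype(float), coords, order=1, mode="nearest"
            )
    if len(dropped) > max_dropped_fraction * n_probes:
        raise SegmentationError(
            f"{len(dropped)}/{n_probes} probes failed to cross both boundaries"
        )
    profiles = {
        role: np.nanmean(tr, axis=0) for role, tr in traces.items()
    }
    return RadialProfile(
        positions=t, profiles=profiles, traces=traces, dropped_probes=dropped
    )


def yen_threshold(channel: np.ndarray, nbins: int = 256) -> float:
    """Yen's maximum-correlation automatic threshold.

    Builds an ``nbins`` histogram over the channel's intensity range and
    returns the bin center maximizing Yen's criterion

        TC(t) = -ln[ P(t)^2 * (1 - P(t))^2 / (G1(t) * G2(t)) ]

    with P the cumulative probability and G1/G2 the cumulative sums of
    squared bin probabilities below/above t.  A constant image is an error.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.max() == channel.min():
        raise ValueError("constant image has no threshold")
    hist, edges = np.histogram(channel.ravel(), bins=nbins)
    p = hist.astype(float) / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    P = np.cumsum(p)
    G = np.cumsum(p ** 2)
    g1 = G[:-1]
    g2 = G[-1] - g1
    p1 = P[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        crit = -np.log(g1 * g2) + 2.0 * np.log(p1 * (1.0 - p1))
    crit[~np.isfinite(crit)] = -np.inf
    return float(centers[int(np.argmax(crit))])


def _binary(channel: np.ndarray, min_object_area: int = 0) -> np.ndarray:
    """Yen-thresholded mask; a constant channel yields an empty mask.

    ``min_object_area`` removes connected components below that pixel area,
    suppressing isolated above-threshold noise speckles.
    """
    if channel.max() == channel.min():
        return np.zeros(channel.shape, dtype=bool)
    mask = channel > yen_threshold(channel)
    if min_object_area > 1 and mask.any():
        mask = morphology.remove_small_objects(mask, max_size=min_object_area - 1)
    return mask


def segment_nuclei(
    dapi: np.ndarray,
    nucleus_radius: float = 4.0,
    min_area: float | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Label nuclei: Yen threshold, fill holes, watershed split, area floor.

    Touching nuclei are separated by watershed on the Euclidean distance
    transform with markers at distance-transform peaks at least
    ``nucleus_radius`` apart.  Objects smaller than ``min_area`` (default
    pi * (nucleus_radius / 2)^2) are discarded.  Returns the label image and
    a per-nucleus table (id, area, centroid).
    """
    if min_area is None:
        min_area = np.pi * (nucleus_radius / 2.0) ** 2
    if dapi.max() == dapi.min():
        warnings.warn("blank nuclear channel; no nuclei detected")
        return np.zeros(dapi.shape, dtype=int), _nucleus_table(np.zeros(dapi.shape, int))
    mask = ndi.binary_fill_holes(_binary(dapi))
    if not mask.any():
        warnings.warn("no nuclei above threshold")
        return np.zeros(dapi.shape, dtype=int), _nucleus_table(np.zeros(dapi.shape, int))
    distance = ndi.distance_transform_edt(mask)
    coords = peak_local_max(
        distance,
        min_distance=max(1, int(round(nucleus_radius))),
        labels=measure.label(mask),
        exclude_border=False,
    )
    markers = np.zeros(dapi.shape, dtype=int)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    labels = watershed(-distance, markers, mask=mask)
    labels = morphology.remove_small_objects(labels, max_size=int(np.ceil(min_area)) - 1)
    return labels, _nucleus_table(labels)


def _nucleus_table(labels: np.ndarray) -> pd.DataFrame:
    rows = [
        (r.label, int(r.area), r.centroid[0], r.centroid[1])
        for r in measure.regionprops(labels)
    ]
    return pd.DataFrame(
        rows, columns=["nucleus", "area", "centroid_row", "centroid_col"]
    )


def assign_medial(
    labels: np.ndarray,
    acta2: np.ndarray,
    vwf: np.ndarray,
    dilation_radius: int = 2,
    min_object_area: int = 5,
) -> pd.Series:
    """Medial call per nucleus.

    A nucleus is medial iff the ACTA2 mask, dilated by a disk of
    ``dilation_radius`` pixels, overlaps the nucleus AND no VWF signal lies
    within the nuclear region.  Channels are Yen-thresholded to binary;
    speckles below ``min_object_area`` pixels are dropped first so that
    shot noise neither grants nor vetoes medial status.
    """
    acta2_mask = _binary(acta2, min_object_area)
    if dilation_radius > 0:
        acta2_mask = morphology.dilation(acta2_mask, morphology.disk(dilation_radius))
    vwf_mask = _binary(vwf, min_object_area)
    ids = [r.label for r in measure.regionprops(labels)]
    flags = {}
    for i in ids:
        nucleus = labels == i
        flags[i] = bool(acta2_mask[nucleus].any() and not vwf_mask[nucleus].any())
    return pd.Series(flags, name="medial", dtype=bool)


def quantify_marker(
    labels: np.ndarray,
    medial: pd.Series,
    marker: np.ndarray,
    positivity_cutoff: float = 0.1,
    min_marker_object_area: int = 4,
) -> tuple[pd.DataFrame, dict]:
    """Marker-positive area fraction per nucleus and the vessel summary.

    The marker channel is Yen-thresholded; speckle objects smaller than
    ``min_marker_object_area`` pixels are removed before measuring, so that
    diffuse noise does not register as positivity.  Per nucleus the fraction
    of its area overlapped by the marker mask is reported; the vessel
    summary is the percentage of medial nuclei whose fraction is >=
    ``positivity_cutoff``.  Zero medial nuclei leave the summary undefined.
    """
    marker_mask = _binary(marker)
    if min_marker_object_area > 1 and marker_mask.any():
        marker_mask = morphology.remove_small_objects(
            marker_mask, max_size=min_marker_object_area - 1
        )
    rows = []
    for r in measure.regionprops(labels):
        nucleus = labels == r.label
        frac = float(marker_mask[nucleus].mean())
        rows.append(
            (r.label, int(r.area), r.centroid[0], r.centroid[1],
             bool(medial.get(r.label, False)), frac)
        )
    records = pd.DataFrame(
        rows,
        columns=["nucleus", "area", "centroid_row", "centroid_col", "medial",
                 "marker_area_fraction"],
    )
    med = records[records["medial"]]
    if len(med) == 0:
        warnings.warn("no medial nuclei; vessel summary undefined")
        summary = {"n_medial": 0, "n_positive": 0, "positive_percentage": float("nan")}
    else:
        pos = int((med["marker_area_fraction"] >= positivity_cutoff).sum())
        summary = {
            "n_medial": int(len(med)),
            "n_positive": pos,
            "positive_percentage": 100.0 * pos / len(med),
        }
    return records, summary


def compare_groups(group_a: list[float], group_b: list[float]) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of per-vessel summaries."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 vessels per group")
    p = rank_sum_test(group_a, group_b)
    return {"p": p, "n_a": len(group_a), "n_b": len(group_b)}
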