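"""Intensity-spot summary statistics.

Two scalar summaries track how scattering degrades the image of a buried
fluorophore as its depth grows: the mean intensity

    <I> = (total photon count) / (total pixel count)

over the full configured detector frame, and the mean spot radius

    <R> = (1/N) * sum_i R_i

with R_i the Euclidean distance of photon i's exit position from the spot
center.  <I> falls and <R> rises with depth; the growth of <R> saturates
at large depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detector import DetectorConfig, GateStack, total_intensity_image

__all__ = ["SpotSummary", "mean_intensity", "spot_center", "mean_radius", "summarize_stack"]


@dataclass(frozen=True)
class SpotSummary:
    mean_intensity: float
    mean_radius: float
    center_x: float
    center_y: float
    n_photons: int
    depth_cm: float | None = None


def mean_intensity(image: np.ndarray) -> float:
    """Total photon count divided by total pixel count (counts/pixel)."""
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    return float(img.sum()) / img.size


def spot_center(
    x: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None
) -> tuple[float, float]:
    """Intensity-weighted centroid of photon exit positions (cm)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise ValueError("no photons: centroid undefined")
    if weights is None:
        return float(x.mean()), float(y.mean())
    w = np.asarray(weights, dtype=float)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("non-positive total weight")
    return float((w * x).sum() / wsum), float((w * y).sum() / wsum)


def mean_radius(
    x: np.ndarray, y: np.ndarray, center: tuple[float, float] | None = None
) -> float:
    """Mean Euclidean distance of exit positions from the spot center (cm)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise ValueError("no photons: mean radius undefined")
    cx, cy = center if center is not None else spot_center(x, y)
    return float(np.hypot(x - cx, y - cy).mean())


def _positions_from_image(image: np.ndarray, det: DetectorConfig):
    """Pixel-center positions and weights for a loaded (binned) image."""
    iy, ix = np.nonzero(image)
    xs, ys = det.pixel_centers()
    return xs[ix], ys[iy], np.asarray(image)[iy, ix].astype(float)

def summarize_stack(
    stack: GateStack, true_center: tuple[float, float] | None = None
) -> SpotSummary:
    """<I>, <R> and centroid of a simulated or loaded stack.

    Uses the continuous exit records when the stack carries them, falling
    back to pixel-center positions of the binned image.  ``true_center``
    substitutes a known source position for the fitted centroid.
    """
    image = total_intensity_image(stack)
    mi = mean_intensity(image)
    if stack.records is not None and stack.records["x"].size > 0:
        x, y = stack.records["x"], stack.records["y"]
        w = None
        n = int(x.size)
    else:
        x, y, w = _positions_from_image(image, stack.detector)
        n = int(image.sum())
    if n == 0:
        raise ValueError("stack contains no detected photons")
    cx, cy = true_center if true_center is not None else spot_center(x, y, w)
    if w is None:
        mr = mean_radius(x, y, (cx, cy))
    else:
        mr = float((w * np.hypot(x - cx, y - cy)).sum() / w.sum())
    depth = None
    srcs = stack.meta.get("scene")
    if srcs:
        zs = {s["z"] for s in srcs}
        if len(zs) == 1:
            depth = float(zs.pop())
    return SpotSummary(
        mean_intensity=mi,
        mean_radius=mr,
        center_x=cx,
        center_y=cy,
        n_photons=n,
        depth_cm=depth,
    )
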