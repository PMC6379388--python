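"""Compartment morphometry of dynamical networks.

The pipeline mirrors how the experimental movies are quantified: render
local-density images from particle snapshots (or take grayscale movie
frames directly), smooth them with a trailing moving average, binarize,
thin the bundle mask to one-pixel-wide curves, and measure the areas of
the regions those curves enclose.  The area distribution is then
summarised by a log-normal fit with a quantile--quantile linearity
statistic, and by the mean compartment size above a small-size cutoff
(spurious slivers appear inside bundles because the agents are points,
so the small-size range is excluded from averaging).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import skeletonize

from .core import Trajectory

__all__ = [
    "DensityField",
    "CompartmentSet",
    "LogNormalFit",
    "render_density",
    "moving_average",
    "binarize",
    "measure_compartments",
    "fit_lognormal",
    "mean_large_size",
    "compartments_from_trajectory",
]


@dataclass
class DensityField:
    """Sequence of gridded local-density frames (particles per unit area)."""

    frames: np.ndarray  # (n_frames, ny, nx)
    times: np.ndarray  # frame times (end of the averaging window)
    pixel_size: float
    window: float

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, ny, nx)")
        if np.any(self.frames < 0) or not np.all(np.isfinite(self.frames)):
            raise ValueError("density values must be finite and non-negative")


@dataclass
class CompartmentSet:
    """Areas enclosed by skeleton lines in one analysed frame."""

    areas_px: np.ndarray
    unit_scale: float  # physical area per pixel
    min_size: float = 0.0
    border_excluded: bool = True

    @property
    def areas(self) -> np.ndarray:
        """Areas in physical units (length units squared)."""
        return self.areas_px * self.unit_scale

    def filtered(self, min_size: float | None = None) -> np.ndarray:
        thr = self.min_size if min_size is None else min_size
        a = self.areas
        return a[a > thr]


@dataclass
class LogNormalFit:
    """Gaussian fit to ln(area) above a size threshold, with Q-Q linearity."""

    mu: float
    sigma: float
    threshold: float
    n: int
    qq_empirical: np.ndarray = field(repr=False, default=None)
    qq_fitted: np.ndarray = field(repr=False, default=None)
    linearity: float = np.nan  # squared correlation of the Q-Q pairs


def render_density(
    traj: Trajectory,
    window: float = 10.0,
    pixel_size: float = 0.25,
) -> DensityField:
    """Average local density over a trailing time window, per output frame.

    Particles are binned by ``floor(position / pixel_size)``; the count
    image is averaged over all snapshots in ``(t - window, t]`` and
    divided by the pixel area, so each frame integrates back to N:
    ``sum(frame) * pixel_size**2 == n_particles``.
    """
    L = traj.params.box_side
    h = float(pixel_size)
    if not (0 < h <= L):
        raise ValueError("pixel_size must lie in (0, box_side]")
    npx = int(round(L / h))
    if abs(npx * h - L) > 1e-9 * L:
        raise ValueError("pixel_size must divide box_side")
    per = max(1, int(round(window / traj.delta_out)))
    if len(traj.states) < per:
        raise ValueError("trajectory shorter than the averaging window")
    counts = np.empty((len(traj.states), npx, npx))
    for k, st in enumerate(traj.states):
        iy = np.minimum((st.y / h).astype(np.int64), npx - 1)
        ix = np.minimum((st.x / h).astype(np.int64), npx - 1)
        counts[k] = np.bincount(
            iy * npx + ix, minlength=npx * npx
        ).reshape(npx, npx)
    kern = np.ones(per) / per
    csum = np.cumsum(counts, axis=0)
    avg = np.empty((len(traj.states) - per + 1, npx, npx))
    avg[0] = csum[per - 1] / per
    avg[1:] = (csum[per:] - csum[:-per]) / per
    frames = avg / h**2
    times = traj.times[per - 1 :]
    return DensityField(frames, times, h, window)


def moving_average(
    frames: np.ndarray,
    times: np.ndarray,
    window: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Trailing boxcar mean of an image sequence over ``window`` time units.

    Output frame k is the mean of all input frames in ``(t_k - window, t_k]``
    with t_k running over the input timestamps from the first for which a
    full window is available.
    """
    frames = np.asarray(frames, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(times) < 2:
        raise ValueError("need at least two frames")
    dt_frame = times[1] - times[0]
    per = int(round(window / dt_frame))
    if per < 2:
        raise ValueError("window must span at least two frames")
    if per > len(frames):
        raise ValueError("window longer than the sequence")
    csum = np.cumsum(frames, axis=0)
    out = np.empty((len(frames) - per + 1,) + frames.shape[1:])
    out[0] = csum[per - 1] / per
    out[1:] = (csum[per:] - csum[:-per]) / per
    return out, times[per - 1 :]


def binarize(img: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Bundle mask: pixels above a global threshold (Otsu unless given)."""
    img = np.asarray(img, dtype=float)
    if img.max() == img.min():
        raise ValueError("flat image: no dynamic range to threshold")
    if threshold is None:
        threshold = threshold_otsu(img)
    return img > threshold


def _merge_seam_labels(lab: np.ndarray) -> np.ndarray:
    """Union labels that are 4-adjacent across the periodic seams."""
    n = int(lab.max())
    parent = np.arange(n + 1)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in zip(lab[0, :], lab[-1, :]):
        if a and b:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    for a, b in zip(lab[:, 0], lab[:, -1]):
        if a and b:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    roots = np.array([find(l) for l in range(n + 1)])
    return roots[lab]


def measure_compartments(
    skeleton: np.ndarray,
    unit_scale: float = 1.0,
    min_size: float = 0.0,
    exclude_border: bool = True,
    periodic: bool = False,
) -> CompartmentSet:
    """Areas of the connected background regions enclosed by skeleton lines.

    The background (non-skeleton pixels) is labelled with 4-connectivity,
    complementary to the 8-connected skeleton so regions cannot leak
    through diagonal line pixels.  Components touching the image border
    are excluded by default, matching measurement on camera frames where
    border regions are truncated by the field of view.  With
    ``periodic=True`` (simulation domains) components are instead merged
    across the wrap-around seams and nothing is excluded.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    lab = label(~skeleton, connectivity=1)
    if lab.max() == 0:
        return CompartmentSet(np.array([]), unit_scale, min_size, exclude_border)
    if periodic:
        lab = _merge_seam_labels(lab)
        drop: set[int] = set()
        exclude_border = False
    elif exclude_border:
        border = np.unique(
            np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])
        )
        drop = set(border.tolist()) - {0}
    else:
        drop = set()
    sizes = np.bincount(lab.ravel())
    keep = [s for lbl, s in enumerate(sizes) if lbl != 0 and lbl not in drop and s > 0]
    return CompartmentSet(
        np.asarray(keep, dtype=float), unit_scale, min_size, exclude_border
    )


def skeletonize_mask(mask: np.ndarray, periodic: bool = False) -> np.ndarray:
    """Topology-preserving thinning of the bundle mask to 1-px curves.

    With ``periodic=True`` the mask is padded with wrapped copies before
    thinning and cropped back, so bundles crossing the seam thin the same
    way as interior ones (thinning is a local operation, so a pad of a
    few bundle widths suffices).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if not periodic:
        return skeletonize(mask)
    pad = min(16, min(mask.shape) // 2)
    padded = np.pad(mask, pad, mode="wrap")
    return skeletonize(padded)[pad:-pad, pad:-pad]


def fit_lognormal(areas, threshold: float, min_count: int = 20) -> LogNormalFit:
    """Moment fit of a Gaussian to ln(area) above ``threshold`` plus Q-Q check.

    The Q-Q pairs compare empirical quantiles at plotting positions
    (k - 0.5)/n against the quantiles of the fitted normal; ``linearity``
    is their squared Pearson correlation, close to 1 when the large-size
    tail is genuinely log-normal.
    """
    areas = np.asarray(areas, dtype=float)
    sel = np.sort(areas[areas > threshold])
    n = len(sel)
    if n < min_count:
        raise ValueError(f"only {n} areas above threshold (need >= {min_count})")
    ln = np.log(sel)
    mu = float(np.mean(ln))
    sigma = float(np.std(ln, ddof=1))
    if sigma <= 1e-12 * max(1.0, abs(mu)):
        raise ValueError("degenerate sample: all areas equal")
    probs = (np.arange(1, n + 1) - 0.5) / n
    fitted = stats.norm.ppf(probs, loc=mu, scale=sigma)
    r = np.corrcoef(ln, fitted)[0, 1]
    return LogNormalFit(mu, sigma, threshold, n, ln, fitted, float(r**2))


def mean_large_size(areas, threshold: float = 30.0) -> float:
    """Mean area strictly above ``threshold`` (physical units).

    The cutoff drops the spurious slivers that appear inside bundles of
    point particles; 30 square length units is the default used for the
    model's compartment statistics.
    """
    areas = np.asarray(areas, dtype=float)
    big = areas[areas > threshold]
    if len(big) == 0:
        raise ValueError("no areas above threshold: mean undefined")
    return float(np.mean(big))


def compartments_from_trajectory(
    traj: Trajectory,
    density_window: float = 10.0,
    ma_window: float = 100.0,
    pixel_size: float = 0.25,
    burn_in: float | None = None,
    frame_stride: float = 20.0,
    threshold: float | None = None,
    smooth_sigma: float = 1.5,
    periodic: bool = True,
) -> list[CompartmentSet]:
    """Full pipeline: trajectory -> compartment areas of analysis frames.

    Density frames (``density_window`` trailing average) are smoothed
    with a ``ma_window`` moving average; the smoothed frames whose end
    time exceeds ``burn_in`` are analysed every ``frame_stride`` time
    units.  ``burn_in`` defaults to two-thirds of the run so the pattern
    is measured near its statistical steady state.

    Because the agents are points, the rendered density keeps
    pixel-level shot noise that worm-bodied camera images do not have;
    a light Gaussian blur (``smooth_sigma`` pixels, about a third of a
    bundle width at the default pixel size) is applied before
    thresholding so the bundle mask is contiguous.  ``periodic=True``
    treats the frame as a torus: thinning works on a wrap-padded copy
    and compartments are merged across the seams instead of dropping
    border-touching ones.
    """
    dens = render_density(traj, window=density_window, pixel_size=pixel_size)
    ma, t_ma = moving_average(dens.frames, dens.times, ma_window)
    duration = traj.times[-1]
    if burn_in is None:
        burn_in = 2.0 * duration / 3.0
    stride = max(1, int(round(frame_stride / traj.delta_out)))
    out: list[CompartmentSet] = []
    last = len(t_ma) - 1
    picks = [k for k in range(last, -1, -stride) if t_ma[k] > burn_in]
    for k in sorted(picks):
        img = ma[k]
        if smooth_sigma > 0:
            img = gaussian_filter(
                img, smooth_sigma, mode="wrap" if periodic else "nearest"
            )
        mask = binarize(img, threshold=threshold)
        skel = skeletonize_mask(mask, periodic=periodic)
        out.append(
            measure_compartments(
                skel,
                unit_scale=pixel_size**2,
                min_size=30.0,
                periodic=periodic,
            )
        )
    return out
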