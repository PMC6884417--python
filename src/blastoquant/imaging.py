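"""Confocal stack handling: I/O, equatorial maximum-intensity projection,
embryo orientation, ROI derivation and batch intensity normalization.

The imaging protocol this module mirrors: two-channel (FISH + DAPI) z-stacks
of 512x512 px are reduced to a 10-slice maximum-intensity projection (MIP)
taken in the equatorial region of the specimen, oriented so the long axis of
the blastomeres is parallel to the image y-axis, and normalized with one
shared contrast window per batch so that intensity-weighted statistics are
comparable across specimens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
import tifffile
from scipy import ndimage
from skimage.filters import threshold_li, threshold_otsu
from skimage.morphology import disk
from skimage.measure import regionprops, label as sklabel
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed
from skimage.transform import rotate as _sk_rotate

__all__ = [
    "ZStack",
    "Projection",
    "ROI",
    "load_stack",
    "write_stack",
    "equatorial_projection",
    "orient_long_axis",
    "rotate_mask",
    "derive_rois",
    "normalize_intensity",
]

ROI_KINDS = ("blastomere", "whole_embryo", "oocyte")


@dataclass
class ZStack:
    """A multi-channel confocal z-stack.

    Parameters
    ----------
    voxels
        Intensity array of shape ``(channel, slice, row, column)``, all
        values non-negative.
    channel_names
        One name per channel; the FISH channel must be named ``"FISH"`` and
        the nuclear counterstain ``"DAPI"`` for the default pipeline.
    pixel_size_um
        In-plane pixel size in micrometres.
    slice_interval_um
        Axial distance between consecutive slices in micrometres.
    """

    voxels: np.ndarray
    channel_names: list[str]
    pixel_size_um: float
    slice_interval_um: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(
                f"voxels must be (channel, slice, row, column); got ndim={self.voxels.ndim}"
            )
        if self.voxels.shape[0] != len(self.channel_names):
            raise ValueError("channel_names length must match the channel axis")
        if self.voxels.shape[0] < 1 or self.voxels.shape[1] < 1:
            raise ValueError("need at least one channel and one slice")
        if np.any(self.voxels < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixel_size_um <= 0 or self.slice_interval_um <= 0:
            raise ValueError("pixel size and slice interval must be positive")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[1]

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channel_names}") from None
        return self.voxels[idx]


@dataclass
class Projection:
    """A 2D projection of a stack (normally a 10-slice equatorial MIP)."""

    pixels: np.ndarray
    source_slices: tuple[int, int]  # [start, stop) into the stack
    span_um: float
    oriented: bool = False
    normalization: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("projection pixels must be 2D")

    @property
    def n_source_slices(self) -> int:
        return self.source_slices[1] - self.source_slices[0]


@dataclass
class ROI:
    """A labelled region of interest on a projection.

    ``blastomere`` ROIs are drawn precisely around individual cells;
    ``whole_embryo`` and ``oocyte`` ROIs may be approximated as circles,
    recorded in ``shape_spec`` as ``("circle", (cx, cy, radius))``.
    """

    mask: np.ndarray
    kind: str
    label: str = ""
    shape_spec: Optional[tuple] = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.kind not in ROI_KINDS:
            raise ValueError(f"kind must be one of {ROI_KINDS}, got {self.kind!r}")
        if not self.mask.any():
            raise ValueError("ROI mask is empty")
        if (
            self.shape_spec is not None
            and self.shape_spec[0] == "circle"
            and self.kind == "blastomere"
        ):
            raise ValueError("circle ROIs are only for whole_embryo/oocyte")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# I/O: multi-page TIFF, channel-major, with a YAML sidecar for the metadata
# TIFF itself cannot carry reliably.

_SIDECAR_FIELDS = ("channel_names", "pixel_size_um", "slice_interval_um")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_stack(stack: ZStack, path: str | Path) -> Path:
    """Write a stack as channel-major multi-page TIFF plus a YAML sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.voxels, dtype=np.float32))
    meta = {
        "channel_names": list(stack.channel_names),
        "pixel_size_um": float(stack.pixel_size_um),
        "slice_interval_um": float(stack.slice_interval_um),
        "shape": [int(s) for s in stack.voxels.shape],
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh)
    return path


def load_stack(path: str | Path) -> ZStack:
    """Read a stack written by :func:`write_stack`.

    Raises
    ------
    FileNotFoundError
        If the TIFF or its sidecar is missing.
    ValueError
        If a required metadata field is absent (the message names it) or
        the TIFF cannot be parsed; no partial object is returned.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(f"sidecar metadata file missing: {side}")
    with open(side) as fh:
        meta = yaml.safe_load(fh)
    for fieldname in _SIDECAR_FIELDS:
        if fieldname not in meta:
            raise ValueError(f"sidecar metadata missing required field {fieldname!r}")
    try:
        voxels = tifffile.imread(path)
    except Exception as exc:  # corrupt / truncated file
        raise ValueError(f"could not parse TIFF {path}: {exc}") from exc
    voxels = np.asarray(voxels)
    if voxels.ndim == 3:  # single channel written without channel axis
        voxels = voxels[None]
    names = list(meta["channel_names"])
    if len(names) != 2:
        if "FISH" in names:
            warnings.warn(
                f"expected a 2-channel (FISH, DAPI) stack, got {len(names)} channels; "
                "proceeding with the identifiable FISH channel",
                stacklevel=2,
            )
        else:
            raise ValueError(
                f"stack has {len(names)} channels and none is named 'FISH'"
            )
    return ZStack(
        voxels=voxels,
        channel_names=names,
        pixel_size_um=float(meta["pixel_size_um"]),
        slice_interval_um=float(meta["slice_interval_um"]),
    )


# ---------------------------------------------------------------------------
# Equatorial MIP


def find_equatorial_slice(stack: ZStack) -> int:
    """Index of the slice with maximal specimen cross-section.

    The equator is taken as the slice whose foreground area (Otsu threshold
    on the summed channels) is largest, i.e. the largest cross section of
    the sample; ties resolve to the centre of the maximal plateau.
    """
    summed = stack.voxels.sum(axis=0)
    try:
        thr = threshold_otsu(summed.ravel())
    except ValueError:  # constant stack
        return stack.n_slices // 2
    areas = (summed > thr).sum(axis=(1, 2))
    best = int(areas.max())
    where = np.flatnonzero(areas == best)
    return int(where[len(where) // 2])


def equatorial_projection(
    stack: ZStack, channel: str = "FISH", n_slices: int = 10
) -> Projection:
    """Maximum-intensity projection of ``n_slices`` around the equator.

    The window is centred on the equatorial slice (maximal cross-section)
    and clipped to the stack. ``span_um`` is recorded as
    ``n_slices * slice_interval_um``, following the source protocol's own
    bookkeeping (10 slices at 0.222 um -> 2.22 um).
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if stack.n_slices < n_slices:
        raise ValueError(
            f"stack has {stack.n_slices} slices, fewer than the {n_slices} requested"
        )
    eq = find_equatorial_slice(stack)
    start = eq - n_slices // 2
    start = min(max(start, 0), stack.n_slices - n_slices)
    stop = start + n_slices
    pixels = stack.channel(channel)[start:stop].max(axis=0)
    return Projection(
        pixels=pixels,
        source_slices=(start, stop),
        span_um=n_slices * stack.slice_interval_um,
    )


# ---------------------------------------------------------------------------
# Orientation


def mask_orientation_deg(mask: np.ndarray) -> float:
    """Angle (degrees, CCW, in (-90, 90]) between the mask's major principal
    axis and the image y-axis (rows), from second central moments."""
    props = regionprops(mask.astype(np.uint8))
    if not props:
        raise ValueError("empty mask")
    p = props[0]
    # regionprops orientation: angle between 0th axis (rows) and major axis,
    # in (-pi/2, pi/2], counter-clockwise.
    ang = np.degrees(p.orientation)
    if ang <= -90.0:
        ang += 180.0
    return float(ang)


def _elongation(mask: np.ndarray) -> float:
    p = regionprops(mask.astype(np.uint8))[0]
    minor = p.axis_minor_length
    return p.axis_major_length / minor if minor > 0 else np.inf


def orient_long_axis(
    projection: Projection, embryo_mask: ROI, *, elongation_tol: float = 1.02
) -> tuple[Projection, float]:
    """Rotate a projection so the specimen's long axis is parallel to y.

    Returns the rotated projection and the rotation angle in degrees
    (in (-90, 90]). A near-circular mask (major/minor axis ratio below
    ``elongation_tol``) has no defined long axis: the angle defaults to 0
    and a warning is emitted. Rotation uses bilinear interpolation about
    the image centre.
    """
    if not embryo_mask.mask.any():
        raise ValueError("embryo mask is empty")
    if _elongation(embryo_mask.mask) < elongation_tol:
        warnings.warn(
            "mask is nearly circular; orientation ambiguous, using angle 0",
            stacklevel=2,
        )
        angle = 0.0
    else:
        angle = mask_orientation_deg(embryo_mask.mask)
    rotated = _sk_rotate(projection.pixels, -angle, order=1, preserve_range=True)
    out = replace(projection, pixels=rotated, oriented=True)
    return out, angle


def rotate_mask(mask: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate a boolean mask with the same convention as orient_long_axis."""
    return _sk_rotate(mask.astype(float), -angle_deg, order=0, preserve_range=True) > 0.5


# ---------------------------------------------------------------------------
# ROI derivation


def _foreground(
    projection: Projection,
    dapi: Optional[Projection],
    smooth_sigma: float = 4.0,
    erode: bool = True,
) -> np.ndarray:
    """Specimen foreground from the (FISH + DAPI) sum.

    FISH signal is punctate, so the summed image is smoothed before
    thresholding to turn the spot carpet into a filled cell region; the
    threshold itself is Otsu's.
    """
    def _prep(a: np.ndarray) -> np.ndarray:
        # smooth the punctate signal into a filled region, then scale by a
        # high percentile so a few bright pixels cannot dominate
        sm = ndimage.gaussian_filter(a, smooth_sigma) if smooth_sigma > 0 else a
        lo = np.percentile(sm, 1.0)
        hi = np.percentile(sm, 99.5)
        if hi <= lo:
            return np.zeros_like(sm)
        return np.clip((sm - lo) / (hi - lo), 0, 1)

    img = _prep(projection.pixels)
    if dapi is not None:
        img = np.maximum(img, _prep(dapi.pixels))
    if img.max() == img.min():
        raise ValueError("no foreground found in projection (constant image)")
    thr = threshold_li(img)
    fg = img > thr
    fg = ndimage.binary_fill_holes(fg)
    fg = remove_small_objects(fg, max_size=int(4 * smooth_sigma**2))
    if erode and smooth_sigma > 0:
        # the blur dilates the cell boundary by ~0.75 sigma; compensate
        fg = ndimage.binary_erosion(fg, disk(max(1, round(0.75 * smooth_sigma))))
    if not fg.any():
        raise ValueError("no foreground found in projection")
    return fg


def _split_two_cells(fg: np.ndarray) -> np.ndarray:
    """Watershed split of a touching two-blastomere foreground into 2 labels."""
    dist = ndimage.distance_transform_edt(fg)
    # two markers: the two strongest distance maxima, well separated
    from skimage.feature import peak_local_max

    min_dist = max(8, int(np.sqrt(fg.sum() / np.pi) / 2))
    peaks = peak_local_max(dist, min_distance=min_dist, num_peaks=2, labels=fg)
    markers = np.zeros_like(fg, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    return watershed(-dist, markers, mask=fg)


def derive_rois(
    projection: Projection,
    dapi: Optional[Projection] = None,
    mode: str = "segment",
    geometry: str = "two_cell",
    ground_truth_masks: Optional[Sequence[np.ndarray]] = None,
) -> list[ROI]:
    """Derive ROIs from an (oriented) projection.

    Modes
    -----
    ``ground_truth``
        Pass the generator's masks straight through (requires
        ``ground_truth_masks``); used when the simulation oracle is wanted.
    ``segment``
        Otsu threshold on the FISH+DAPI sum; for ``two_cell`` geometry the
        foreground must resolve into exactly two blastomere components
        (touching cells are split by watershed), otherwise an error reports
        the component count.
    ``circle_fit``
        One circular ROI enclosing the whole foreground (whole-embryo or
        oocyte convention).
    """
    if mode == "ground_truth":
        if ground_truth_masks is None:
            raise ValueError("ground_truth mode requires ground_truth_masks")
        kind = "blastomere" if geometry == "two_cell" else "oocyte"
        return [
            ROI(mask=np.asarray(m, bool), kind=kind, label=chr(ord("a") + i))
            for i, m in enumerate(ground_truth_masks)
        ]

    fg = _foreground(projection, dapi, erode=(mode == "segment"))

    if mode == "segment":
        if geometry == "two_cell":
            labels = sklabel(fg)
            n = labels.max()
            if n == 1:
                labels = _split_two_cells(fg)
                n = labels.max()
            if n != 2:
                raise ValueError(
                    f"expected 2 blastomere components for two_cell geometry, found {n}"
                )
            rois = []
            # stable ordering: left cell first
            order = np.argsort(
                [np.nonzero(labels == i)[1].mean() for i in (1, 2)]
            )
            for out_i, lab_i in enumerate(np.array([1, 2])[order]):
                rois.append(
                    ROI(mask=labels == lab_i, kind="blastomere", label=chr(ord("a") + out_i))
                )
            return rois
        kind = "oocyte" if geometry == "oocyte" else "whole_embryo"
        return [ROI(mask=fg, kind=kind, label="a")]

    if mode == "circle_fit":
        # the circle approximates the specimen itself: fit the largest
        # connected component so stray background blobs cannot inflate it
        labels = sklabel(fg)
        if labels.max() > 1:
            sizes = np.bincount(labels.ravel())[1:]
            fg = labels == (int(np.argmax(sizes)) + 1)
        ys, xs = np.nonzero(fg)
        cy, cx = ys.mean(), xs.mean()
        radius = float(np.hypot(ys - cy, xs - cx).max()) + 1.0
        yy, xx = np.ogrid[: fg.shape[0], : fg.shape[1]]
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        kind = "oocyte" if geometry == "oocyte" else "whole_embryo"
        return [ROI(mask=mask, kind=kind, label="a", shape_spec=("circle", (cx, cy, radius)))]

    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Batch normalization


def normalize_intensity(
    projections: Sequence[Projection],
    bounds: Optional[tuple[float, float]] = None,
    percentiles: tuple[float, float] = (0.1, 99.9),
) -> list[Projection]:
    """Apply ONE shared (low, high) contrast window to a whole batch.

    All projections in a batch are rescaled with identical settings so that
    their intensity-weighted statistics remain comparable, mirroring the
    "identical settings for contrast and brightness" convention. If
    ``bounds`` is not given, the batch-global ``percentiles`` of the pooled
    pixel values are used. Output pixel values are clipped to [0, 1].

    A degenerate window (constant batch) maps everything to 0 with a
    warning; explicitly supplied bounds with low >= high are an error.
    """
    if len(projections) == 0:
        raise ValueError("need at least one projection")
    if bounds is not None:
        low, high = float(bounds[0]), float(bounds[1])
        if low >= high:
            raise ValueError(f"invalid bounds: low={low} >= high={high}")
    else:
        pooled = np.concatenate([p.pixels.ravel() for p in projections])
        low, high = np.percentile(pooled, percentiles)
        if low >= high:
            warnings.warn(
                "degenerate intensity range in batch; mapping all pixels to 0",
                stacklevel=2,
            )
            return [
                replace(p, pixels=np.zeros_like(p.pixels), normalization=(low, low))
                for p in projections
            ]
    out = []
    for p in projections:
        scaled = np.clip((p.pixels - low) / (high - low), 0.0, 1.0)
        out.append(replace(p, pixels=scaled, normalization=(low, high)))
    return out
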