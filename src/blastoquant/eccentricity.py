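"""The core statistic: FISH-signal eccentricity.

For a uniformly distributed signal, the unweighted mean position of the
pixels inside an ROI (the centroid) and their intensity-weighted mean
position (the centre of mass) coincide. For a spatially inhomogeneous
signal the centre of mass departs from the centroid; the eccentricity E is
the Euclidean distance between the two — the hypotenuse of the right
triangle whose legs are delta-x and delta-y. E = 0 for any constant signal
and grows with the inhomogeneity of the mRNA distribution (except for
purely radial inhomogeneity, which it cannot see).

E is reported both in pixels (``e_px``) and normalized by the equivalent
ROI radius sqrt(area/pi) (``e_norm``), since absolute figure units of the
original protocol are unstated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .imaging import Projection, ROI, equatorial_projection, normalize_intensity

__all__ = [
    "EccentricityResult",
    "GroupComparison",
    "eccentricity",
    "batch_eccentricity",
    "compare_groups",
]


@dataclass
class EccentricityResult:
    """Centroid, intensity-weighted centre of mass and their distance for one ROI.

    Coordinates are (x, y) with x = column index increasing rightward and
    y = row index increasing downward, pixel centres at integers.
    """

    centroid: tuple[float, float]
    centre_of_mass: tuple[float, float]
    delta: tuple[float, float]
    e_px: float
    e_norm: float
    roi_label: str
    total_intensity: float
    roi_area_px: int
    specimen_id: str = ""


@dataclass
class GroupComparison:
    """Two-group rank-sum comparison of eccentricity values."""

    group_labels: tuple[str, str]
    n_per_group: tuple[int, int]
    statistic: float  # Mann-Whitney U of the first group
    p_value: float
    medians: tuple[float, float]
    method: str


def eccentricity(
    image: Union[Projection, np.ndarray],
    roi: ROI,
    specimen_id: str = "",
    subtract_background: Optional[float] = None,
) -> EccentricityResult:
    """Eccentricity of the signal within one ROI.

    Both the centroid and the centre of mass are computed over the ROI mask
    pixels only; pixels outside the drawn region never contribute.

    ``subtract_background`` optionally removes a constant background
    estimate (clipped at 0) before weighting. No subtraction is the
    default — the protocol applies only shared contrast normalization —
    but note that any residual constant background strictly *shrinks* E
    (dilution of the weighted mean), so comparisons across backgrounds
    should either share a window or subtract.

    Raises
    ------
    ValueError
        If the ROI does not match the image shape, or if the total
        intensity inside the ROI is zero (which is distinct from E = 0 and
        would make the centre of mass undefined).
    """
    pixels = image.pixels if isinstance(image, Projection) else np.asarray(image, float)
    if subtract_background is not None:
        pixels = np.clip(pixels - float(subtract_background), 0.0, None)
    if roi.mask.shape != pixels.shape:
        raise ValueError(
            f"ROI mask shape {roi.mask.shape} does not match image shape {pixels.shape}"
        )
    ys, xs = np.nonzero(roi.mask)
    weights = pixels[ys, xs].astype(float)
    total = float(weights.sum())
    if total <= 0:
        raise ValueError("zero total intensity inside ROI; eccentricity undefined")
    cx, cy = float(xs.mean()), float(ys.mean())
    mx = float((xs * weights).sum() / total)
    my = float((ys * weights).sum() / total)
    dx, dy = mx - cx, my - cy
    e_px = float(np.hypot(dx, dy))
    area = int(len(xs))
    e_norm = e_px / float(np.sqrt(area / np.pi))
    return EccentricityResult(
        centroid=(cx, cy),
        centre_of_mass=(mx, my),
        delta=(dx, dy),
        e_px=e_px,
        e_norm=e_norm,
        roi_label=roi.label,
        total_intensity=total,
        roi_area_px=area,
        specimen_id=specimen_id,
    )


_LEVEL_KIND = {
    "blastomere": "blastomere",
    "embryo": "whole_embryo",
    "oocyte": "oocyte",
}


def batch_eccentricity(
    items: Sequence[tuple],
    level: str = "blastomere",
    channel: str = "FISH",
    n_slices: int = 10,
    normalize: bool = True,
    bounds: Optional[tuple[float, float]] = None,
    specimen_ids: Optional[Sequence[str]] = None,
) -> list[EccentricityResult]:
    """Project, batch-normalize and measure a whole batch of stacks.

    Parameters
    ----------
    items
        Sequence of ``(ZStack, rois)`` where ``rois`` is a list of
        :class:`ROI` on the projected image.
    level
        Which ROI kind to measure: ``blastomere`` (two polygon ROIs per
        embryo), ``embryo`` (one circle per embryo) or ``oocyte``.
    normalize
        Apply one shared contrast window to the whole batch before
        measuring (the comparability convention); eccentricity itself is
        invariant to the linear part of this but not to the clipping.

    Errors raised by a pipeline stage are re-raised with the specimen
    identifier attached.
    """
    if level not in _LEVEL_KIND:
        raise ValueError(f"level must be one of {sorted(_LEVEL_KIND)}")
    kind = _LEVEL_KIND[level]
    if specimen_ids is None:
        specimen_ids = [f"specimen{i + 1}" for i in range(len(items))]
    projections = []
    for sid, (stack, _rois) in zip(specimen_ids, items):
        try:
            projections.append(equatorial_projection(stack, channel=channel, n_slices=n_slices))
        except Exception as exc:
            raise RuntimeError(f"projection failed for {sid}: {exc}") from exc
    if normalize:
        projections = normalize_intensity(projections, bounds=bounds)
    results: list[EccentricityResult] = []
    for sid, proj, (stack, rois) in zip(specimen_ids, projections, items):
        for roi in rois:
            if roi.kind != kind:
                continue
            try:
                results.append(eccentricity(proj, roi, specimen_id=sid))
            except Exception as exc:
                raise RuntimeError(f"eccentricity failed for {sid}/{roi.label}: {exc}") from exc
    return results


# ---------------------------------------------------------------------------
# Group comparison (two-sided rank-sum; exact for small samples)


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided rank-sum p-value by dynamic programming.

    Enumerates the permutation distribution of the rank sum of the first
    group over all C(N, n1) assignments (midranks for ties; doubled to stay
    integral). The distribution is symmetric about n1(N+1)/2, so the
    two-sided p is P(|W - mu| >= |w_obs - mu|). Returns (U, p).
    """
    from scipy.stats import rankdata

    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    r2 = np.round(2 * ranks).astype(int)  # midranks doubled -> integers
    w2_obs = int(round(2 * ranks[:n1].sum()))
    total2 = int(r2.sum())
    # dp[k, s] = number of k-subsets with doubled-rank sum s
    dp = np.zeros((n1 + 1, total2 + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in r2:
        dp[1 : n1 + 1, r:] += dp[0:n1, : total2 + 1 - r]
    counts = dp[n1]
    n_total = counts.sum()
    mu2 = n1 * (len(combined) + 1)  # doubled mean of W
    dev = np.abs(np.arange(total2 + 1) - mu2)
    p = counts[dev >= abs(w2_obs - mu2) - 1e-9].sum() / n_total
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u), float(min(p, 1.0))


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
    paired: bool = False,
    exact_max_n: int = 25,
) -> GroupComparison:
    """Compare two groups of eccentricity values (Wilcoxon family).

    Groups are independent specimens by default, so the test is the
    two-sided Mann-Whitney rank-sum: exact (full permutation distribution,
    with midranks for ties) when the combined sample size is at most
    ``exact_max_n``, normal approximation with tie correction otherwise.
    ``paired=True`` switches to the signed-rank test for within-embryo
    pairings of equal length.
    """
    x = np.asarray(a, float)
    y = np.asarray(b, float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs n >= 3")
    if paired:
        from scipy.stats import wilcoxon

        if len(x) != len(y):
            raise ValueError("paired comparison requires equal group sizes")
        stat, p = wilcoxon(x, y)
        method = "wilcoxon-signed-rank"
    elif len(x) + len(y) <= exact_max_n:
        stat, p = _exact_ranksum_p(x, y)
        method = "rank-sum-exact"
    else:
        from scipy.stats import mannwhitneyu

        res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        stat, p = float(res.statistic), float(res.pvalue)
        method = "rank-sum-normal"
    return GroupComparison(
        group_labels=labels,
        n_per_group=(len(x), len(y)),
        statistic=float(stat),
        p_value=float(p),
        medians=(float(np.median(x)), float(np.median(y))),
        method=method,
    )
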