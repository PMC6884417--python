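"""Synthetic data generators for the whole pipeline.

Three generators emulate the three kinds of specimen data the analysis
consumes, each with known ground truth so that every downstream statistic
can be validated against what was actually put in:

* :func:`generate_embryo_stack` — post-deconvolution Airyscan-like confocal
  z-stacks (FISH + DAPI) of MII oocytes or 2-cell embryos, with a
  configurable spatial distribution of FISH spots and an analytic
  centre-of-mass offset recorded per cell.
* :func:`generate_twin_counts` — per-blastocyst CDX2/SOX17/NANOG lineage
  counts for twin pairs (bisected 2-cell embryos grown to blastocysts),
  with a tunable epiblast split imbalance.
* :func:`generate_expression_pairs` — log-normal expression matrices of
  sister-blastomere pairs with a shared pair effect and per-gene
  within-pair divergence.

All generators are driven by :class:`numpy.random.Generator` seeded from
the params object: same seed, bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import i0, i1

from .imaging import ZStack

__all__ = [
    "ImageSimParams",
    "GroundTruth",
    "CountSimParams",
    "ExprSimParams",
    "generate_embryo_stack",
    "generate_twin_counts",
    "generate_expression_pairs",
    "analytic_com_offset",
]

DISTRIBUTIONS = ("uniform", "gradient", "cortical", "polarized_cap")

#: kappa of the von Mises angular density of the polarized_cap model when
#: gradient_strength = 1; the strength parameter scales kappa linearly.
CAP_KAPPA_SCALE = 5.0

#: default EPI split imbalance, calibrated by Monte Carlo (n_pairs=1000) so
#: the median NANOG C^high/C^low ratio is ~2 while the median CDX2 ratio
#: stays below 1.2 (see scripts/calibrate_beta.py output frozen here).
DEFAULT_EPI_IMBALANCE_BETA = 0.5


# ---------------------------------------------------------------------------
# Image simulation


@dataclass
class ImageSimParams:
    """Parameters of the confocal-stack simulator.

    The defaults emulate the acquisition the analysis targets: 512x512 px
    slices at 0.22 um axial spacing, a thin equatorial slab through an
    embryo whose blastomeres are modelled as spheres, diffraction-limited
    FISH spots rendered as Gaussians, Poisson shot noise plus Gaussian read
    noise on a constant background.

    ``injected_cell_factor`` multiplies the expected spot count of the
    first blastomere only, emulating an mRNA micro-injection control;
    ``rnase_mode`` zeroes all specific signal, emulating hybridization
    after RNase treatment (background only).
    """

    image_shape: tuple[int, int] = (512, 512)
    n_slices: int = 25
    slice_interval_um: float = 0.22
    pixel_size_um: float = 0.18
    geometry: str = "two_cell"  # or "oocyte"
    blastomere_radii_px: Optional[tuple[float, ...]] = None
    n_spots: int = 2000
    distribution: str = "uniform"
    gradient_strength: float = 0.0
    psf_sigma_px: float = 1.0
    background_level: float = 2.0
    poisson_noise: bool = True
    read_noise_sd: float = 1.0
    spot_amplitude: float = 500.0
    injected_cell_factor: float = 1.0
    rnase_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in ("oocyte", "two_cell"):
            raise ValueError(f"geometry must be 'oocyte' or 'two_cell', got {self.geometry!r}")
        if self.distribution not in DISTRIBUTIONS:
            raise ValueError(f"distribution must be one of {DISTRIBUTIONS}")
        if not 0.0 <= self.gradient_strength <= 1.0:
            raise ValueError("gradient_strength must be in [0, 1]")
        for name in (
            "n_slices",
            "slice_interval_um",
            "pixel_size_um",
            "n_spots",
            "psf_sigma_px",
            "background_level",
            "read_noise_sd",
            "spot_amplitude",
            "injected_cell_factor",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.blastomere_radii_px is None:
            # blastomere of a ~80 um embryo at 0.18 um/px -> r ~ 110 px
            self.blastomere_radii_px = (110.0, 110.0) if self.geometry == "two_cell" else (140.0,)
        radii = tuple(float(r) for r in self.blastomere_radii_px)
        n_cells = 2 if self.geometry == "two_cell" else 1
        if len(radii) != n_cells:
            raise ValueError(f"{self.geometry} geometry needs {n_cells} radii, got {len(radii)}")
        if any(r <= 0 for r in radii):
            raise ValueError("radii must be positive")
        self.blastomere_radii_px = radii
        # cells must fit inside the frame with a small margin
        h, w = self.image_shape
        margin = 4
        for (cy, cx), r in zip(self.cell_centres(), radii):
            if cx - r < margin or cx + r > w - margin or cy - r < margin or cy + r > h - margin:
                raise ValueError("cell overlaps the image frame boundary")

    def cell_centres(self) -> list[tuple[float, float]]:
        """(row, col) centres; two-cell embryos are two tangent spheres."""
        h, w = self.image_shape
        cy, cx = h / 2.0, w / 2.0
        if self.geometry == "oocyte":
            return [(cy, cx)]
        r1, r2 = self.blastomere_radii_px
        return [(cy, cx - r1), (cy, cx + r2)]


@dataclass
class GroundTruth:
    """What the simulator actually drew, for use as a downstream oracle."""

    cell_masks: np.ndarray  # (n_cells, n_slices, H, W) bool
    nucleus_masks: np.ndarray  # same shape
    spot_positions: list[np.ndarray]  # per cell, (n_i, 3) float (z, row, col)
    density_com_offset: np.ndarray  # (n_cells, 2) expected (drow, dcol) in px
    cell_centres: np.ndarray  # (n_cells, 2) (row, col)
    cell_radii: np.ndarray  # (n_cells,)

    @property
    def offset_magnitude(self) -> np.ndarray:
        return np.hypot(self.density_com_offset[:, 0], self.density_com_offset[:, 1])

    def roi_masks(self, source_slices: Optional[tuple[int, int]] = None) -> list[np.ndarray]:
        """Per-cell 2D masks (union over the slice window) for ROI use."""
        if source_slices is None:
            sel = slice(None)
        else:
            sel = slice(*source_slices)
        return [m[sel].any(axis=0) for m in self.cell_masks]

    def window_spot_count(self, cell: int, source_slices: tuple[int, int]) -> int:
        """Number of spots of ``cell`` whose z lies inside a slice window."""
        z = self.spot_positions[cell][:, 0]
        lo, hi = source_slices
        return int(((z >= lo) & (z < hi)).sum())

    def sampling_se(self, cell: int, source_slices: tuple[int, int]) -> float:
        """Spot-count sampling SE of a centre-of-mass estimate from the
        spots visible in a projection window: sd(coordinate)/sqrt(n) with
        the uniform-disc per-axis sd r/2 as the sampling-theory scale."""
        n = self.window_spot_count(cell, source_slices)
        if n == 0:
            return float("inf")
        return float(self.cell_radii[cell] / 2.0 / np.sqrt(n))


def analytic_com_offset(distribution: str, strength: float, radius_px: float) -> float:
    """Expected in-plane distance between cell centroid and spot-density COM.

    Closed forms over a disc of radius ``r``:

    * uniform, cortical: symmetric -> 0.
    * gradient, density ∝ (1 + g·u/r): offset = g·r/4 along the ramp.
    * polarized_cap, density ∝ exp(kappa·cos(theta)): offset =
      (2r/3)·I1(kappa)/I0(kappa), with kappa = CAP_KAPPA_SCALE·strength.
    """
    if distribution in ("uniform", "cortical"):
        return 0.0
    if distribution == "gradient":
        return strength * radius_px / 4.0
    if distribution == "polarized_cap":
        kappa = CAP_KAPPA_SCALE * strength
        if kappa == 0:
            return 0.0
        return 2.0 * radius_px / 3.0 * float(i1(kappa) / i0(kappa))
    raise ValueError(distribution)


def _sample_inplane(
    rng: np.random.Generator, n: int, radius: float, distribution: str, strength: float,
    direction: float,
) -> np.ndarray:
    """Rejection-sample n points (drow, dcol) from the in-plane density."""
    if n == 0:
        return np.empty((0, 2))
    out = np.empty((0, 2))
    kappa = CAP_KAPPA_SCALE * strength
    while len(out) < n:
        m = max(2 * (n - len(out)), 64)
        rho = radius * np.sqrt(rng.uniform(size=m))
        theta = rng.uniform(0, 2 * np.pi, size=m)
        if distribution == "uniform":
            accept = np.ones(m, bool)
        elif distribution == "gradient":
            u = rho * np.cos(theta - direction)
            accept = rng.uniform(size=m) < (1 + strength * u / radius) / (1 + strength)
        elif distribution == "cortical":
            w = np.exp(-((rho - 0.85 * radius) ** 2) / (2 * (0.08 * radius) ** 2))
            accept = rng.uniform(size=m) < w
        elif distribution == "polarized_cap":
            w = np.exp(kappa * (np.cos(theta - direction) - 1.0))
            accept = rng.uniform(size=m) < w
        else:
            raise ValueError(distribution)
        pts = np.column_stack(
            [rho[accept] * np.sin(theta[accept]), rho[accept] * np.cos(theta[accept])]
        )
        out = np.vstack([out, pts])
    return out[:n]


def _render_spots(
    fish: np.ndarray, spots: np.ndarray, amplitude: float, sigma: float
) -> None:
    """Add Gaussian spots (in-place). Each spot lives on its nearest slice
    with a Gaussian amplitude falloff over +/-2 neighbouring slices."""
    n_slices, h, w = fish.shape
    half = max(1, int(np.ceil(4 * sigma)))
    ax = np.arange(-half, half + 1)
    for z, row, col in spots:
        r0, c0 = int(round(row)), int(round(col))
        rr = ax + r0
        cc = ax + c0
        rsel = (rr >= 0) & (rr < h)
        csel = (cc >= 0) & (cc < w)
        gy = np.exp(-((rr[rsel] - row) ** 2) / (2 * sigma**2))
        gx = np.exp(-((cc[csel] - col) ** 2) / (2 * sigma**2))
        patch = amplitude * np.outer(gy, gx)
        z0 = int(round(z))
        for dz in range(-2, 3):
            k = z0 + dz
            if 0 <= k < n_slices:
                zfac = np.exp(-((k - z) ** 2) / 2.0)  # z sigma = 1 slice
                fish[k, rr[rsel][:, None], cc[csel][None, :]] += zfac * patch


def generate_embryo_stack(params: ImageSimParams) -> tuple[ZStack, GroundTruth]:
    """Render a two-channel (FISH, DAPI) stack plus its ground truth.

    The imaged volume is a thin slab of ``n_slices`` through the equator of
    spherical cells: slice ``k`` of cell ``i`` is a disc of radius
    ``sqrt(R_i^2 - dz_k^2)`` with ``dz`` the axial offset converted to
    pixels, so the equatorial slice has the largest cross-section. FISH
    spots are sampled from the requested in-plane density (the in-plane
    marginal is exactly the stated 2D family; the axial coordinate is
    uniform over the sphere chord) and rendered as Gaussians; DAPI shows a
    smoothed nuclear disc. Shot and read noise are applied per voxel.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    h, w = p.image_shape
    nz = p.n_slices
    centres = p.cell_centres()
    radii = p.blastomere_radii_px
    n_cells = len(centres)

    z_c = (nz - 1) / 2.0
    dz_px = (np.arange(nz) - z_c) * p.slice_interval_um / p.pixel_size_um

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cell_masks = np.zeros((n_cells, nz, h, w), bool)
    nucleus_masks = np.zeros_like(cell_masks)
    for i, ((cy, cx), r) in enumerate(zip(centres, radii)):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        rk2 = np.maximum(r**2 - dz_px**2, 0.0)
        rnk2 = np.maximum((r / 3.0) ** 2 - dz_px**2, 0.0)
        cell_masks[i] = d2[None] <= rk2[:, None, None]
        cell_masks[i, rk2 == 0] = False
        nucleus_masks[i] = d2[None] <= rnk2[:, None, None]
        nucleus_masks[i, rnk2 == 0] = False

    fish = np.zeros((nz, h, w))
    dapi = np.zeros((nz, h, w))

    spot_positions: list[np.ndarray] = []
    offsets = np.zeros((n_cells, 2))
    for i, ((cy, cx), r) in enumerate(zip(centres, radii)):
        direction = rng.uniform(0, 2 * np.pi)  # ramp / cap axis, per cell
        expected = p.n_spots * (p.injected_cell_factor if i == 0 else 1.0)
        n_i = 0 if p.rnase_mode else int(rng.poisson(expected))
        pts = _sample_inplane(rng, n_i, r, p.distribution, p.gradient_strength, direction)
        mag = analytic_com_offset(p.distribution, p.gradient_strength, r)
        offsets[i] = (mag * np.sin(direction), mag * np.cos(direction))
        # axial: uniform over the sphere chord at that in-plane radius,
        # clipped to the slab
        rho = np.hypot(pts[:, 0], pts[:, 1])
        a_px = np.sqrt(np.maximum(r**2 - rho**2, 0.0))
        a_sl = a_px * p.pixel_size_um / p.slice_interval_um
        zlo = np.maximum(z_c - a_sl, 0.0)
        zhi = np.minimum(z_c + a_sl, nz - 1.0)
        z = rng.uniform(zlo, zhi) if n_i else np.empty(0)
        spots = np.column_stack([z, pts[:, 0] + cy, pts[:, 1] + cx]) if n_i else np.empty((0, 3))
        spot_positions.append(spots)
        if n_i:
            _render_spots(fish, spots, p.spot_amplitude, p.psf_sigma_px)
        # DAPI: smoothed nuclear disc
        dapi += 100.0 * nucleus_masks[i].astype(float)

    from scipy.ndimage import gaussian_filter

    if dapi.any():
        dapi = gaussian_filter(dapi, sigma=(0, 2.0, 2.0))

    fish += p.background_level
    dapi += p.background_level
    if p.poisson_noise:
        fish = rng.poisson(fish).astype(float)
        dapi = rng.poisson(dapi).astype(float)
    if p.read_noise_sd > 0:
        fish = fish + rng.normal(0, p.read_noise_sd, fish.shape)
        dapi = dapi + rng.normal(0, p.read_noise_sd, dapi.shape)
    voxels = np.clip(np.stack([fish, dapi]), 0, None).astype(np.float32)

    stack = ZStack(
        voxels=voxels,
        channel_names=["FISH", "DAPI"],
        pixel_size_um=p.pixel_size_um,
        slice_interval_um=p.slice_interval_um,
    )
    truth = GroundTruth(
        cell_masks=cell_masks,
        nucleus_masks=nucleus_masks,
        spot_positions=spot_positions,
        density_com_offset=offsets,
        cell_centres=np.asarray(centres, float),
        cell_radii=np.asarray(radii, float),
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Lineage count simulation


@dataclass
class CountSimParams:
    """Parameters of the twin-pair lineage-count generator.

    ``mu_total``/``sigma_total`` describe the total cell count of a
    reconstituted pair (twin + co-twin), matching the observation that the
    sum of the two halves equals an intact blastocyst. ``lineage_fractions``
    are the mean (TE, PE, EPI) fractions of that total.

    ``epi_imbalance_beta`` controls how unevenly the epiblast is split
    between twin and co-twin: the split fraction is Beta(a, a) with
    ``a = 1/beta``, so beta=0 is the exactly balanced limit and larger beta
    gives heavier imbalance. The PE split follows the EPI split (PE
    formation depends on FGF4 from the EPI); the TE split is independent
    and tight (Normal(0.5, te_split_sd)).
    """

    n_pairs: int = 38
    mu_total: float = 100.0
    sigma_total: float = 15.0
    lineage_fractions: tuple[float, float, float] = (0.70, 0.17, 0.13)  # TE, PE, EPI
    epi_imbalance_beta: float = DEFAULT_EPI_IMBALANCE_BETA
    te_split_sd: float = 0.04
    pe_coupling_sd: float = 0.03
    n_intact: int = 0
    treatment: str = "KSOM(aa)"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if not np.isclose(sum(self.lineage_fractions), 1.0):
            raise ValueError("lineage_fractions must sum to 1")
        if self.epi_imbalance_beta < 0 or self.te_split_sd < 0 or self.sigma_total < 0:
            raise ValueError("noise parameters must be non-negative")


def _split_counts(total: float, s: float) -> tuple[int, int]:
    a = int(round(total * s))
    b = int(round(total * (1.0 - s)))
    return max(a, 0), max(b, 0)


def generate_twin_counts(params: CountSimParams) -> pd.DataFrame:
    """Simulate a lineage count table: 2 rows per pair (+ optional intacts).

    Columns: embryo_id, pair_id, member (a/b/intact), treatment, cdx2,
    sox17, nanog. Counts are non-negative integers; the expected twin +
    co-twin total equals ``mu_total`` by construction.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    f_te, f_pe, f_epi = p.lineage_fractions
    rows = []
    for j in range(p.n_pairs):
        total = max(2.0, np.round(rng.normal(p.mu_total, p.sigma_total)))
        if p.epi_imbalance_beta == 0:
            s_epi = 0.5
        else:
            a = 1.0 / p.epi_imbalance_beta
            s_epi = float(rng.beta(a, a))
        s_pe = float(np.clip(rng.normal(s_epi, p.pe_coupling_sd), 0.0, 1.0)) \
            if p.pe_coupling_sd > 0 else s_epi
        s_te = float(np.clip(rng.normal(0.5, p.te_split_sd), 0.0, 1.0)) \
            if p.te_split_sd > 0 else 0.5
        te = _split_counts(total * f_te, s_te)
        pe = _split_counts(total * f_pe, s_pe)
        epi = _split_counts(total * f_epi, s_epi)
        for m, member in enumerate("ab"):
            rows.append(
                dict(
                    embryo_id=f"{j + 1}{member}",
                    pair_id=j + 1,
                    member=member,
                    treatment=p.treatment,
                    cdx2=te[m],
                    sox17=pe[m],
                    nanog=epi[m],
                )
            )
    for j in range(p.n_intact):
        total = max(2.0, np.round(rng.normal(p.mu_total, p.sigma_total)))
        rows.append(
            dict(
                embryo_id=f"intact{j + 1}",
                pair_id=-1,
                member="intact",
                treatment=p.treatment,
                cdx2=int(round(total * f_te)),
                sox17=int(round(total * f_pe)),
                nanog=int(round(total * f_epi)),
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Expression simulation


@dataclass
class ExprSimParams:
    """Parameters of the sister-blastomere expression generator.

    Log-normal model: log expression of gene g in member m of pair j is
    ``b_g + u_{gj} + e_{gjm}`` with gene baseline b, shared pair effect
    u ~ N(0, pair_effect_sd^2) and member deviation
    e ~ N(0, within_pair_sd^2). Genes listed in ``high_cv_genes`` get their
    within-pair SD multiplied by ``high_cv_factor``, emulating transcripts
    with strong blastomere-to-blastomere variability.
    """

    n_pairs: int = 9
    n_genes: int = 200
    pair_effect_sd: float = 0.25
    within_pair_sd: float = 0.3
    high_cv_genes: tuple[int, ...] = ()
    high_cv_factor: float = 10.0
    baseline_log_mean: float = 6.0
    baseline_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1 or self.n_genes < 1:
            raise ValueError("n_pairs and n_genes must be >= 1")
        if self.within_pair_sd < 0 or self.pair_effect_sd < 0:
            raise ValueError("SDs must be non-negative")
        if any(g < 0 or g >= self.n_genes for g in self.high_cv_genes):
            raise ValueError("high_cv_genes must be valid gene indices")


def generate_expression_pairs(params: ExprSimParams) -> pd.DataFrame:
    """Simulate a genes x samples expression matrix of blastomere pairs.

    Columns are sample labels ``"<pair><member>"`` (e.g. "7a", "7b"), rows
    are gene ids; values are strictly positive (log-normal).
    """
    p = params
    rng = np.random.default_rng(p.seed)
    baseline = rng.normal(p.baseline_log_mean, p.baseline_log_sd, size=p.n_genes)
    within_sd = np.full(p.n_genes, p.within_pair_sd)
    if p.high_cv_genes:
        within_sd[list(p.high_cv_genes)] *= p.high_cv_factor
    cols = {}
    for j in range(1, p.n_pairs + 1):
        u = rng.normal(0, p.pair_effect_sd, size=p.n_genes)
        for member in "ab":
            e = rng.normal(0, 1.0, size=p.n_genes) * within_sd
            cols[f"{j}{member}"] = np.exp(baseline + u + e)
    genes = [f"gene{g + 1:04d}" for g in range(p.n_genes)]
    return pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
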