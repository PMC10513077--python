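"""Seeded synthetic inputs with known ground truth.

Every downstream stage of the pipeline (segmentation, morphometry,
stereology, slit-density quantification, assay calculations, single-cell
QC) is exercised against data produced here, where the true object counts,
areas, arc lengths and concentrations are known exactly by construction.

The image model is deliberately simple: objects are smoothed indicator
functions plus additive Gaussian noise.  Two channels emulate the two
stains used for podocyte phenotyping — a nuclear stain (WT-1-like, bright
podocyte nuclei on a dim glomerular tuft) and a cytoplasmic stain
(nephrin-like, textured tuft signal).  Super-resolution z-stacks are
emulated as bright curvilinear ridges of known analytic arc length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate, ndimage

__all__ = [
    "SceneParams",
    "GlomerulusTruth",
    "SceneGroundTruth",
    "SlitSceneTruth",
    "PlateTruth",
    "CountMatrixTruth",
    "Segment",
    "Circle",
    "Sinusoid",
    "generate_glomerulus_scene",
    "generate_sted_scene",
    "sample_sphere_profiles",
    "generate_plate",
    "generate_count_matrix",
]


class PackingError(RuntimeError):
    """Raised when the requested tufts cannot be placed in the frame."""


# ---------------------------------------------------------------------------
# glomerulus scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneParams:
    """Parameters of a synthetic two-stain glomerulus micrograph.

    Defaults are desk-scale: a 512 px frame at the acquisition resolution
    of 8.8 px/µm holds two moderately sized tufts; full-scale runs use
    2048 px frames with the same pixel size.
    """

    frame_size_px: tuple[int, int] = (512, 512)
    pixels_per_micron: float = 8.8
    n_glomeruli: int = 2
    tuft_radius_um: tuple[float, float] = (8.0, 14.0)
    nuclei_per_glomerulus: tuple[int, int] = (5, 12)
    nucleus_radius_um: tuple[float, float] = (2.0, 3.2)
    tuft_eccentricity: tuple[float, float] = (0.75, 1.0)
    noise_sd: float = 0.05
    edge_touch_fraction: float = 0.0
    merged_pair_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixels_per_micron <= 0:
            raise ValueError("pixels_per_micron must be positive")
        if self.tuft_radius_um[0] > self.tuft_radius_um[1]:
            raise ValueError("tuft_radius_um range is empty")
        if self.nuclei_per_glomerulus[0] > self.nuclei_per_glomerulus[1]:
            raise ValueError("nuclei_per_glomerulus range is empty")
        max_r_px = self.tuft_radius_um[1] * self.pixels_per_micron
        if 2 * max_r_px > max(self.frame_size_px) and self.n_glomeruli > 0:
            raise ValueError("frame too small for requested tuft radii")
        if not (0.0 <= self.edge_touch_fraction <= 1.0):
            raise ValueError("edge_touch_fraction must be in [0, 1]")
        if not (0.0 <= self.merged_pair_fraction <= 1.0):
            raise ValueError("merged_pair_fraction must be in [0, 1]")


@dataclass(frozen=True)
class GlomerulusTruth:
    """Per-glomerulus ground truth record."""

    label: int
    nucleus_count: int
    tuft_area_um2: float
    mean_nuclear_area_um2: float
    edge_flag: bool
    merged_flag: bool


@dataclass
class SceneGroundTruth:
    """A synthetic scene: both stain channels, label masks and truth."""

    image_wt1: np.ndarray
    image_nephrin: np.ndarray
    tuft_mask: np.ndarray
    nuclei_mask: np.ndarray
    per_glomerulus: list[GlomerulusTruth]
    params: SceneParams | None = None

    @property
    def n_glomeruli(self) -> int:
        return len(self.per_glomerulus)


def _ellipse_mask(shape, center, semi_axes, angle):
    """Boolean mask of a rotated ellipse; pixel-center convention."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    return (u / semi_axes[0]) ** 2 + (v / semi_axes[1]) ** 2 <= 1.0


def _inside_ellipse(point, center, semi_axes, angle, shrink=1.0):
    dr = point[0] - center[0]
    dc = point[1] - center[1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    return (u / (semi_axes[0] * shrink)) ** 2 + (v / (semi_axes[1] * shrink)) ** 2 <= 1.0


_MAX_PLACEMENT_TRIES = 2000

# intensity levels of the two-stain model (arbitrary units in [0, 1])
_BG = 0.05
_TUFT_WT1 = 0.30
_NUCLEUS = 0.90
_TUFT_NEPHRIN = 0.65


def generate_glomerulus_scene(params: SceneParams) -> SceneGroundTruth:
    """Draw a seeded two-channel scene of elliptical glomerular tufts.

    Each tuft is a mildly eccentric ellipse containing non-overlapping
    circular nuclei.  Designated fractions of glomeruli touch the frame
    edge or are drawn as merged overlapping pairs sharing a single label —
    the two failure modes downstream post-processing must exclude.

    Raises
    ------
    PackingError
        If non-overlapping placement fails after bounded retries.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.frame_size_px
    ppm = params.pixels_per_micron

    tuft_labels = np.zeros((h, w), dtype=np.int32)
    nuclei_labels = np.zeros((h, w), dtype=np.int32)
    wt1 = np.full((h, w), _BG, dtype=np.float64)
    nephrin = np.full((h, w), _BG, dtype=np.float64)
    records: list[GlomerulusTruth] = []

    n = params.n_glomeruli
    n_edge = int(round(params.edge_touch_fraction * n))
    n_merged = int(round(params.merged_pair_fraction * n))
    roles = ["edge"] * n_edge + ["merged"] * n_merged + ["plain"] * (n - n_edge - n_merged)
    rng.shuffle(roles)

    placed: list[tuple[tuple[float, float], float]] = []  # (center, bounding radius)
    nucleus_label = 0

    for g, role in enumerate(roles, start=1):
        r_um = rng.uniform(*params.tuft_radius_um)
        r_px = r_um * ppm
        ecc = rng.uniform(*params.tuft_eccentricity)
        semi = (r_px, r_px * ecc)
        angle = rng.uniform(0.0, math.pi)

        center = None
        for _ in range(_MAX_PLACEMENT_TRIES):
            if role == "edge":
                # center near a frame border so the tuft is cut
                side = rng.integers(0, 4)
                along = rng.uniform(0.2, 0.8)
                off = rng.uniform(-0.3, 0.3) * r_px
                if side == 0:
                    cand = (off, along * w)
                elif side == 1:
                    cand = (h + off, along * w)
                elif side == 2:
                    cand = (along * h, off)
                else:
                    cand = (along * h, w + off)
            else:
                m = r_px * (1.02 if role == "merged" else 1.0) + 2
                if h - m <= m or w - m <= m:
                    continue
                cand = (rng.uniform(m, h - m), rng.uniform(m, w - m))
            if all(
                math.hypot(cand[0] - c[0], cand[1] - c[1]) > r_px + br + 4
                for c, br in placed
            ):
                center = cand
                break
        if center is None:
            raise PackingError(
                f"could not place glomerulus {g} after {_MAX_PLACEMENT_TRIES} tries"
            )

        ellipses = [(center, semi, angle)]
        if role == "merged":
            # second overlapping tuft, same label -> one merged component
            theta = rng.uniform(0.0, 2 * math.pi)
            d = rng.uniform(0.9, 1.3) * r_px
            c2 = (center[0] + d * math.cos(theta), center[1] + d * math.sin(theta))
            r2 = rng.uniform(*params.tuft_radius_um) * ppm
            ellipses.append((c2, (r2, r2 * rng.uniform(*params.tuft_eccentricity)),
                             rng.uniform(0.0, math.pi)))
            bound = d + max(r2, r_px)
        else:
            bound = r_px
        placed.append((center, bound))

        tuft = np.zeros((h, w), dtype=bool)
        for c, s, a in ellipses:
            tuft |= _ellipse_mask((h, w), c, s, a)
        tuft &= tuft_labels == 0
        tuft_labels[tuft] = g

        edge_flag = role == "edge" or _touches_edge(tuft)

        # nuclei: non-overlapping disks with centers inside the tuft
        n_nuc = int(rng.integers(params.nuclei_per_glomerulus[0],
                                 params.nuclei_per_glomerulus[1] + 1))
        nuc_centers: list[tuple[float, float, float]] = []
        count = 0
        nuc_areas = []
        for _ in range(n_nuc):
            nr_px = rng.uniform(*params.nucleus_radius_um) * ppm
            ok = None
            for _ in range(_MAX_PLACEMENT_TRIES // 4):
                c, s, a = ellipses[int(rng.integers(0, len(ellipses)))]
                ang = rng.uniform(0.0, 2 * math.pi)
                rad = math.sqrt(rng.uniform(0.0, 1.0))
                pr = c[0] + rad * s[0] * 0.78 * math.cos(ang)
                pc = c[1] + rad * s[1] * 0.78 * math.sin(ang)
                # rotate into frame coordinates
                ca, sa_ = math.cos(a), math.sin(a)
                p = (c[0] + ca * (pr - c[0]) - sa_ * (pc - c[1]),
                     c[1] + sa_ * (pr - c[0]) + ca * (pc - c[1]))
                if not (0 <= p[0] < h and 0 <= p[1] < w):
                    continue
                if not any(_inside_ellipse(p, ci, si, ai, shrink=0.88)
                           for ci, si, ai in ellipses):
                    continue
                if all(math.hypot(p[0] - q0, p[1] - q1) > nr_px + qr + 3
                       for (q0, q1, qr) in nuc_centers):
                    ok = p
                    break
            if ok is None:
                continue  # tuft saturated; truth reflects what was drawn
            nucleus_label += 1
            disk = _ellipse_mask((h, w), ok, (nr_px, nr_px), 0.0) & (tuft_labels == g)
            if disk.sum() == 0:
                nucleus_label -= 1
                continue
            nuclei_labels[disk] = nucleus_label
            nuc_centers.append((ok[0], ok[1], nr_px))
            nuc_areas.append(disk.sum() / ppm**2)
            count += 1

        records.append(
            GlomerulusTruth(
                label=g,
                nucleus_count=count,
                tuft_area_um2=float((tuft_labels == g).sum() / ppm**2),
                mean_nuclear_area_um2=float(np.mean(nuc_areas)) if nuc_areas else float("nan"),
                edge_flag=bool(edge_flag),
                merged_flag=role == "merged",
            )
        )

    # render intensities: smoothed indicators + Gaussian noise
    wt1[tuft_labels > 0] = _TUFT_WT1
    wt1[nuclei_labels > 0] = _NUCLEUS
    nephrin[tuft_labels > 0] = _TUFT_NEPHRIN
    wt1 = ndimage.gaussian_filter(wt1, 1.0)
    nephrin = ndimage.gaussian_filter(nephrin, 1.0)
    # cytoplasmic texture on the nephrin channel
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), 3.0)
    nephrin = np.where(tuft_labels > 0, nephrin + 0.25 * texture, nephrin)
    if params.noise_sd > 0:
        wt1 = wt1 + rng.normal(0.0, params.noise_sd, size=(h, w))
        nephrin = nephrin + rng.normal(0.0, params.noise_sd, size=(h, w))
    wt1 = np.clip(wt1, 0.0, 1.0)
    nephrin = np.clip(nephrin, 0.0, 1.0)

    return SceneGroundTruth(
        image_wt1=wt1,
        image_nephrin=nephrin,
        tuft_mask=tuft_labels,
        nuclei_mask=nuclei_labels,
        per_glomerulus=records,
        params=params,
    )


def _touches_edge(mask: np.ndarray) -> bool:
    return bool(mask[0, :].any() or mask[-1, :].any()
                or mask[:, 0].any() or mask[:, -1].any())


# ---------------------------------------------------------------------------
# STED-like slit scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """Straight segment between two points, coordinates in µm (row, col)."""

    p0: tuple[float, float]
    p1: tuple[float, float]

    def point(self, t: np.ndarray) -> np.ndarray:
        p0 = np.asarray(self.p0, dtype=float)
        p1 = np.asarray(self.p1, dtype=float)
        return p0[None, :] + t[:, None] * (p1 - p0)[None, :]

    def length(self) -> float:
        return math.dist(self.p0, self.p1)


@dataclass(frozen=True)
class Circle:
    """Full circle of given radius, coordinates in µm."""

    center: tuple[float, float]
    radius: float

    def point(self, t: np.ndarray) -> np.ndarray:
        ang = 2 * math.pi * t
        return np.stack(
            [self.center[0] + self.radius * np.sin(ang),
             self.center[1] + self.radius * np.cos(ang)], axis=1
        )

    def length(self) -> float:
        return 2 * math.pi * self.radius


@dataclass(frozen=True)
class Sinusoid:
    """y = amplitude * sin(2π x / wavelength) along a horizontal span (µm)."""

    origin: tuple[float, float]
    span: float
    amplitude: float
    wavelength: float

    def point(self, t: np.ndarray) -> np.ndarray:
        x = t * self.span
        y = self.amplitude * np.sin(2 * math.pi * x / self.wavelength)
        return np.stack([self.origin[0] + y, self.origin[1] + x], axis=1)

    def length(self) -> float:
        k = 2 * math.pi / self.wavelength
        val, _ = integrate.quad(
            lambda x: math.sqrt(1.0 + (self.amplitude * k * math.cos(k * x)) ** 2),
            0.0, self.span, limit=500,
        )
        return val


@dataclass
class SlitSceneTruth:
    """Z-stack of curvilinear ridges and the analytic truth."""

    zstack: np.ndarray  # (depth, H, W)
    true_total_length_um: float
    field_area_um2: float
    pixels_per_micron: float


def generate_sted_scene(
    curves: Sequence[Segment | Circle | Sinusoid],
    field_size_um: tuple[float, float],
    ppm: float,
    seed: int = 0,
    depth: int = 6,
    line_width_px: float = 4.0,
    noise_sd: float = 0.04,
) -> SlitSceneTruth:
    """Render parametric curves as bright ridges in a noisy z-stack.

    The recorded truth is the analytic arc length of the in-field portion
    of each curve; curves exiting the field are clipped and their length
    truncated by dense polyline integration (step ≪ pixel).
    """
    rng = np.random.default_rng(seed)
    h = int(round(field_size_um[0] * ppm))
    w = int(round(field_size_um[1] * ppm))
    canvas = np.zeros((h, w), dtype=np.float64)

    total_len = 0.0
    n_samp = 20000
    t = np.linspace(0.0, 1.0, n_samp)
    for curve in curves:
        pts = curve.point(t)  # µm
        inside = (
            (pts[:, 0] >= 0) & (pts[:, 0] <= field_size_um[0])
            & (pts[:, 1] >= 0) & (pts[:, 1] <= field_size_um[1])
        )
        if inside.all():
            total_len += curve.length()
        else:
            seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            keep = inside[:-1] & inside[1:]
            total_len += float(seg[keep].sum())
        px = pts[inside] * ppm
        ij = np.round(px).astype(int)
        ij[:, 0] = np.clip(ij[:, 0], 0, h - 1)
        ij[:, 1] = np.clip(ij[:, 1], 0, w - 1)
        canvas[ij[:, 0], ij[:, 1]] = 1.0

    # dilate to the requested ridge width, then soften
    if line_width_px > 1:
        r = line_width_px / 2.0
        canvas = ndimage.grey_dilation(
            canvas, footprint=_disk_footprint(r)
        )
    canvas = ndimage.gaussian_filter(canvas, 0.8)

    # distribute over slices: ridge visible in a few adjacent planes
    stack = np.zeros((depth, h, w), dtype=np.float64)
    focal = rng.integers(0, depth)
    for z in range(depth):
        att = math.exp(-0.5 * ((z - focal) / max(1.0, depth / 3.0)) ** 2)
        stack[z] = att * canvas
    stack += rng.normal(0.0, noise_sd, size=stack.shape)
    stack = np.clip(stack, 0.0, 1.0)

    return SlitSceneTruth(
        zstack=stack,
        true_total_length_um=float(total_len),
        field_area_um2=float(field_size_um[0] * field_size_um[1]),
        pixels_per_micron=ppm,
    )


def _disk_footprint(radius: float) -> np.ndarray:
    r = int(math.ceil(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2) <= radius**2


# ---------------------------------------------------------------------------
# sphere-section oracle for stereology
# ---------------------------------------------------------------------------

def sample_sphere_profiles(radius: float, n: int, seed: int = 0) -> np.ndarray:
    """Areas of random planar sections through a sphere of given radius.

    A plane at signed distance u ~ Uniform(−R, R) from the center
    (conditioned on hitting the sphere) cuts a disk of area π(R²−u²);
    the mean over sections is (2/3)πR².  Serves as the exact simulation
    oracle for the caliper-diameter inversion.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if radius <= 0:
        raise ValueError("radius must be positive")
    rng = np.random.default_rng(seed)
    u = rng.uniform(-radius, radius, size=n)
    return math.pi * (radius**2 - u**2)


# ---------------------------------------------------------------------------
# plates and count matrices
# ---------------------------------------------------------------------------

@dataclass
class PlateTruth:
    """A standard-curve plate: absorbance affine in concentration."""

    standard_concentrations: np.ndarray
    standard_absorbances: np.ndarray
    sample_true_concentrations: np.ndarray
    sample_absorbances: np.ndarray
    blank: float
    slope: float
    intercept: float


def generate_plate(
    standard_concentrations: Sequence[float] = (0.0, 12.5, 25.0, 50.0, 100.0, 200.0),
    n_samples: int = 8,
    sample_range: tuple[float, float] = (5.0, 180.0),
    slope: float = 0.004,
    intercept: float = 0.05,
    blank: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PlateTruth:
    """Simulate a plate read: A = blank + intercept + slope·C + noise.

    The blanked signal (A − blank) is affine in concentration, so a
    noiseless plate is recovered exactly by linear regression.
    """
    rng = np.random.default_rng(seed)
    conc = np.asarray(standard_concentrations, dtype=float)
    std_abs = blank + intercept + slope * conc
    true_samples = rng.uniform(*sample_range, size=n_samples)
    samp_abs = blank + intercept + slope * true_samples
    if noise_sd > 0:
        std_abs = std_abs + rng.normal(0.0, noise_sd, size=std_abs.shape)
        samp_abs = samp_abs + rng.normal(0.0, noise_sd, size=samp_abs.shape)
    return PlateTruth(
        standard_concentrations=conc,
        standard_absorbances=std_abs,
        sample_true_concentrations=true_samples,
        sample_absorbances=samp_abs,
        blank=blank,
        slope=slope,
        intercept=intercept,
    )


@dataclass
class CountMatrixTruth:
    """Cell-by-gene counts with mitochondrial genes and the true QC count."""

    counts: np.ndarray  # (cells, genes) nonnegative ints
    gene_names: list[str]
    true_pass_count: int
    cell_names: list[str] = field(default_factory=list)


def generate_count_matrix(
    n_cells: int = 500,
    n_genes: int = 800,
    n_mito_genes: int = 13,
    mean_counts_per_cell: float = 2000.0,
    mito_fraction_dist: str = "beta",
    seed: int = 0,
    max_mito_fraction: float = 0.40,
    min_genes: int = 200,
) -> CountMatrixTruth:
    """Simulate a UMI count matrix with a known QC-pass count.

    Per-cell library sizes are log-normal; a target mitochondrial read
    fraction is drawn per cell (Beta(2, 5) by default, or Uniform(0, 1)
    with ``mito_fraction_dist='uniform'``) and reads are multinomially
    split between the 13 mouse ``mt-`` genes and the nuclear genes.  The
    true pass count applies the printed rule directly: mitochondrial
    fraction < ``max_mito_fraction`` AND expressed genes > ``min_genes``.
    """
    rng = np.random.default_rng(seed)
    mito_names = [f"mt-Gene{i}" for i in range(n_mito_genes)]
    nuc_names = [f"Gene{i}" for i in range(n_genes - n_mito_genes)]
    gene_names = mito_names + nuc_names

    counts = np.zeros((n_cells, n_genes), dtype=np.int64)
    lib = rng.lognormal(math.log(mean_counts_per_cell), 0.5, size=n_cells)
    if mito_fraction_dist == "uniform":
        mfrac = rng.uniform(0.0, 1.0, size=n_cells)
    else:
        mfrac = rng.beta(2.0, 5.0, size=n_cells)

    # heterogeneous nuclear expression so some cells express few genes
    n_nuc = n_genes - n_mito_genes
    base = rng.dirichlet(np.full(n_nuc, 0.3))
    for i in range(n_cells):
        total = max(1, int(round(lib[i])))
        m = rng.binomial(total, mfrac[i])
        counts[i, :n_mito_genes] = rng.multinomial(
            m, np.full(n_mito_genes, 1.0 / n_mito_genes)
        )
        counts[i, n_mito_genes:] = rng.multinomial(total - m, base)

    totals = counts.sum(axis=1)
    mito = counts[:, :n_mito_genes].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / totals, 0.0)
    genes_expr = (counts > 0).sum(axis=1)
    passed = (frac < max_mito_fraction) & (genes_expr > min_genes)

    return CountMatrixTruth(
        counts=counts,
        gene_names=gene_names,
        true_pass_count=int(passed.sum()),
        cell_names=[f"cell{i}" for i in range(n_cells)],
    )
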