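"""Synthetic cohorts and synthetic IHC images with planted ground truth.

Two generators:

* :func:`generate_cohort` — a bulk RNA-seq count matrix plus a matching
  compartmental CD8 density table for a cohort with three planted
  phenotypes (infiltrated / excluded / desert) and gene modules wired to
  the latent CD8 quantity (R) and stroma-skew (theta);
* :func:`generate_ihc_image` — a cartoon 2-channel brightfield raster
  (haematoxylin nuclei + DAB CD8 blobs) with a per-pixel compartment
  truth mask and exact planted CD8 counts.

Counts follow a negative-binomial model: per-gene relative abundances on
a log2 scale plus module effects, multiplied into a log-uniform library
size, with gamma-Poisson overdispersion. Latent (R, theta) are drawn per
phenotype from truncated normals and densities are back-computed as
(R cos theta, R sin theta), so the polar transform is exactly invertible
on the truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import histoquant
from .histoquant import BACKGROUND, STROMA, TUMOUR  # noqa: F401 (re-export)

__all__ = [
    "MODULE_NAMES",
    "SimConfig",
    "GroundTruth",
    "IHCImageSpec",
    "ImageGroundTruth",
    "generate_cohort",
    "generate_ihc_image",
    "worked_fixture",
    "save_cohort",
    "load_cohort",
    "save_ihc_image",
]

MODULE_NAMES = (
    "cytotoxic",
    "antigen_presentation",
    "tgfb_stroma",
    "desert_program",
    "housekeeping",
    "noise",
)

PHENOTYPES = ("infiltrated", "excluded", "desert")

#: housekeeping gene names matching the default normalization list
NAMED_HK_GENES = ("ACTB", "ACTG1", "HSP90AB1", "UBC")

_MODULE_PREFIX = {
    "cytotoxic": "CYT",
    "antigen_presentation": "AP",
    "tgfb_stroma": "TGFB",
    "desert_program": "DES",
    "housekeeping": "HK",
    "noise": "NOISE",
}


@dataclass(frozen=True)
class SimConfig:
    """Cohort-generator configuration.

    ``phenotype_prevalence`` is (infiltrated, excluded, desert) and must
    sum to 1; the default is the renormalized (0.30, 0.20, 0.41) split.
    ``module_sizes`` maps each module name to a gene count; a ``noise``
    value of ``None`` means "all remaining genes".
    """

    n_samples: int = 150
    n_genes: int = 2000
    phenotype_prevalence: tuple[float, float, float] = (
        0.30 / 0.91,
        0.20 / 0.91,
        0.41 / 0.91,
    )
    module_sizes: dict = field(
        default_factory=lambda: {
            "cytotoxic": 300,
            "antigen_presentation": 170,
            "tgfb_stroma": 170,
            "desert_program": 70,
            "housekeeping": 20,
            "noise": None,
        }
    )
    effect_size: float = 2.0
    dispersion: float = 0.05
    lib_size_range: tuple[float, float] = (8e5, 1.6e6)
    seed: int = 0

    def resolved_module_sizes(self) -> dict[str, int]:
        sizes = dict(self.module_sizes)
        for name in MODULE_NAMES:
            sizes.setdefault(name, 0)
        fixed = sum(v for k, v in sizes.items() if k != "noise" and v is not None)
        if sizes.get("noise") is None:
            sizes["noise"] = self.n_genes - fixed
        return {k: int(sizes[k]) for k in MODULE_NAMES}

    def validate(self) -> None:
        if self.n_samples <= 0 or self.n_genes <= 0:
            raise ValueError("n_samples and n_genes must be positive")
        if abs(sum(self.phenotype_prevalence) - 1.0) > 1e-9:
            raise ValueError("phenotype prevalences must sum to 1")
        if any(p < 0 for p in self.phenotype_prevalence):
            raise ValueError("prevalences must be non-negative")
        sizes = self.resolved_module_sizes()
        if any(v < 0 for v in sizes.values()):
            raise ValueError(f"module sizes invalid: {sizes}")
        if sum(sizes.values()) > self.n_genes:
            raise ValueError(
                f"module sizes sum to {sum(sizes.values())} > n_genes={self.n_genes}"
            )
        if sizes["housekeeping"] > 0 and sizes["housekeeping"] < len(NAMED_HK_GENES):
            raise ValueError(
                f"housekeeping module needs >= {len(NAMED_HK_GENES)} genes"
            )
        if self.effect_size < 0 or self.dispersion < 0:
            raise ValueError("effect_size and dispersion must be non-negative")
        lo, hi = self.lib_size_range
        if not (0 < lo <= hi):
            raise ValueError("lib_size_range must satisfy 0 < min <= max")


@dataclass
class GroundTruth:
    """Planted cohort truth: per-sample phenotype and latent metrics,
    per-gene module membership."""

    sample_ids: list[str]
    phenotype: np.ndarray  # str per sample
    true_R: np.ndarray
    true_theta: np.ndarray
    gene_module: pd.Series  # index = gene ids, values = module names

    def __post_init__(self) -> None:
        if not set(np.unique(self.phenotype)) <= set(PHENOTYPES):
            raise ValueError("unknown phenotype label in truth")
        if ((self.true_theta < 0) | (self.true_theta > np.pi / 2)).any():
            raise ValueError("true_theta must lie in [0, pi/2]")

    def to_dict(self) -> dict:
        return {
            "sample_ids": list(self.sample_ids),
            "phenotype": [str(p) for p in self.phenotype],
            "true_R": [float(v) for v in self.true_R],
            "true_theta": [float(v) for v in self.true_theta],
            "gene_module": {g: str(m) for g, m in self.gene_module.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            sample_ids=list(d["sample_ids"]),
            phenotype=np.array(d["phenotype"]),
            true_R=np.array(d["true_R"], dtype=float),
            true_theta=np.array(d["true_theta"], dtype=float),
            gene_module=pd.Series(d["gene_module"]),
        )


def _trunc_normal(rng, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_latents(rng: np.random.Generator, phenotype: np.ndarray):
    """Per-phenotype truncated-normal latent (R, theta)."""
    n = len(phenotype)
    R = np.empty(n)
    theta = np.empty(n)
    q = np.pi / 4
    for pheno, (rm, rs, rlo, rhi), (tm, ts, tlo, thi) in (
        ("infiltrated", (300, 80, 120, 700), (0.35, 0.12, 0.03, q - 0.05)),
        ("excluded", (300, 80, 120, 700), (1.20, 0.12, q + 0.05, np.pi / 2 - 0.02)),
        ("desert", (25, 15, 0.0, 70), (0.60, 0.45, 0.0, np.pi / 2)),
    ):
        idx = np.where(phenotype == pheno)[0]
        if idx.size:
            R[idx] = _trunc_normal(rng, rm, rs, rlo, rhi, idx.size)
            theta[idx] = _trunc_normal(rng, tm, ts, tlo, thi, idx.size)
    return R, theta


def _gene_table(config: SimConfig, rng: np.random.Generator):
    """Gene ids, module labels, baseline log2 abundances, noise SDs."""
    sizes = config.resolved_module_sizes()
    gene_ids: list[str] = []
    modules: list[str] = []
    for name in MODULE_NAMES:
        k = sizes[name]
        if name == "housekeeping" and k > 0:
            ids = list(NAMED_HK_GENES[:k]) + [
                f"HK{i:04d}" for i in range(len(NAMED_HK_GENES) + 1, k + 1)
            ]
        else:
            ids = [f"{_MODULE_PREFIX[name]}{i:04d}" for i in range(1, k + 1)]
        gene_ids.extend(ids)
        modules.extend([name] * k)
    module_arr = np.array(modules)
    n = len(gene_ids)
    base = rng.uniform(2.0, 7.0, size=n)
    noise_sd = np.full(n, 0.35)
    hk = module_arr == "housekeeping"
    base[hk] = 10.0 + rng.uniform(-0.2, 0.2, size=hk.sum())
    noise_sd[hk] = 0.05
    return gene_ids, module_arr, base, noise_sd


def generate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a cohort.

    Returns
    -------
    counts : DataFrame
        Integer counts, genes x samples (index = gene ids).
    densities : DataFrame
        Columns ``sample_id, cd8_tumour_density, cd8_stroma_density``.
    truth : GroundTruth
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    phenotype = rng.choice(PHENOTYPES, size=n, p=list(config.phenotype_prevalence))
    R, theta = _draw_latents(rng, phenotype)
    t_dens = R * np.cos(theta)
    s_dens = R * np.sin(theta)

    gene_ids, module_arr, base, noise_sd = _gene_table(config, rng)
    g = len(gene_ids)

    # module effects on the log2 scale, all proportional to effect_size
    effects = np.zeros((g, n))
    e = config.effect_size
    r_hat = np.clip(R / 300.0, 0.0, 1.5)
    excl = (phenotype == "excluded").astype(float)
    des = (phenotype == "desert").astype(float)
    effects[module_arr == "cytotoxic"] = e * r_hat
    effects[module_arr == "antigen_presentation"] = -e * excl
    effects[module_arr == "tgfb_stroma"] = e * excl
    effects[module_arr == "desert_program"] = e * des

    log2_w = base[:, None] + effects + rng.normal(0.0, noise_sd[:, None], size=(g, n))
    w = np.exp2(log2_w)
    p = w / w.sum(axis=0, keepdims=True)

    lo, hi = config.lib_size_range
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    mu = p * lib[None, :]
    if config.dispersion > 0:
        lam = rng.gamma(1.0 / config.dispersion, mu * config.dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(np.int64)

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=sample_ids)
    densities_df = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cd8_tumour_density": t_dens,
            "cd8_stroma_density": s_dens,
        }
    )
    truth = GroundTruth(
        sample_ids=sample_ids,
        phenotype=phenotype,
        true_R=R,
        true_theta=theta,
        gene_module=pd.Series(module_arr, index=gene_ids),
    )
    return counts_df, densities_df, truth


def worked_fixture() -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Small deterministic cohort (12 samples x 60 genes) for examples
    and smoke tests. Regenerated from a fixed configuration, so it needs
    no bundled data files."""
    config = SimConfig(
        n_samples=12,
        n_genes=60,
        module_sizes={
            "cytotoxic": 10,
            "antigen_presentation": 8,
            "tgfb_stroma": 8,
            "desert_program": 6,
            "housekeeping": 4,
            "noise": None,
        },
        effect_size=4.0,
        seed=20201104,
    )
    return generate_cohort(config)


# ---------------------------------------------------------------------------
# synthetic IHC images
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IHCImageSpec:
    """Configuration of one synthetic 2-channel IHC image.

    Tumour nuclei must be drawn larger and rounder than stroma nuclei
    (strictly greater mean area, strictly lower mean eccentricity) so
    the shape/size classification rule is recoverable.
    """

    image_size: int = 512
    pixel_size: float = 0.5  # um / pixel
    n_tumour_nests: int = 3
    nest_radius_um: float = 42.0
    n_tumour_nuclei: int = 60
    n_stroma_nuclei: int = 130
    tumour_nucleus_area: tuple[float, float] = (62.0, 6.0)  # mean, sd (um^2)
    tumour_nucleus_ecc: tuple[float, float] = (0.30, 0.10)
    stroma_nucleus_area: tuple[float, float] = (23.0, 3.0)
    stroma_nucleus_ecc: tuple[float, float] = (0.85, 0.04)
    cd8_tumour_count: int = 10
    cd8_stroma_count: int = 20
    cd8_radius_um: float = 2.5
    cd8_margin_um: float = 5.0  # keep planted cells away from boundaries
    dilation_radius_um: float = histoquant.DEFAULT_DILATION_UM
    closing_radius_um: float = histoquant.DEFAULT_CLOSING_UM
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.image_size < 64:
            raise ValueError("image_size too small")
        if self.tumour_nucleus_area[0] <= self.stroma_nucleus_area[0]:
            raise ValueError("tumour nuclei must be larger than stroma nuclei on average")
        if self.tumour_nucleus_ecc[0] >= self.stroma_nucleus_ecc[0]:
            raise ValueError("tumour nuclei must be rounder than stroma nuclei on average")
        if self.cd8_tumour_count < 0 or self.cd8_stroma_count < 0:
            raise ValueError("CD8 counts must be non-negative")


@dataclass
class ImageGroundTruth:
    """Planted truth for one synthetic image."""

    cd8_tumour_count: int
    cd8_stroma_count: int
    nuclei: pd.DataFrame  # row, col, area_um2, eccentricity, nucleus_class
    cd8_positions: pd.DataFrame  # row, col, compartment
    tumour_area_mm2: float
    stroma_area_mm2: float

    def to_dict(self) -> dict:
        return {
            "cd8_tumour_count": int(self.cd8_tumour_count),
            "cd8_stroma_count": int(self.cd8_stroma_count),
            "nuclei": self.nuclei.to_dict(orient="list"),
            "cd8_positions": self.cd8_positions.to_dict(orient="list"),
            "tumour_area_mm2": self.tumour_area_mm2,
            "stroma_area_mm2": self.stroma_area_mm2,
        }


def _render_ellipse(img: np.ndarray, cy: float, cx: float, a: float, b: float,
                    angle: float, value: float) -> None:
    """Paint a filled rotated ellipse (semi-axes a, b in pixels)."""
    r = int(np.ceil(max(a, b))) + 1
    h, w = img.shape
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    img[y0:y1, x0:x1][inside] = value


def _place_points(
    rng: np.random.Generator,
    allowed: np.ndarray,
    n: int,
    min_dist_px: float,
    existing: list[tuple[float, float]],
    existing_min_dist_px: float | None = None,
    max_tries: int = 20000,
) -> list[tuple[float, float]]:
    """Dart-throwing placement inside ``allowed`` with a minimum
    centre-to-centre distance among new points and (separately, when
    given) against ``existing`` points."""
    coords = np.argwhere(allowed)
    if coords.size == 0 and n > 0:
        raise ValueError("no room to place the requested objects")
    others = np.array(existing, dtype=float).reshape(-1, 2)
    cross_dist = existing_min_dist_px if existing_min_dist_px is not None else min_dist_px
    for _restart in range(5):  # a stuck configuration gets fresh throws
        placed: list[tuple[float, float]] = []
        tries = 0
        while len(placed) < n and tries < max_tries:
            tries += 1
            cy, cx = coords[rng.integers(len(coords))]
            cand = np.array([cy, cx], dtype=float)
            pts = np.array(placed, dtype=float).reshape(-1, 2)
            if pts.size and np.min(np.hypot(*(pts - cand).T)) < min_dist_px:
                continue
            if others.size and np.min(np.hypot(*(others - cand).T)) < cross_dist:
                continue
            placed.append((float(cy), float(cx)))
        if len(placed) == n:
            return placed
    raise ValueError(
        f"could not place {n} objects (placed {len(placed)}); "
        "requested count exceeds available compartment area"
    )


def generate_ihc_image(
    spec: IHCImageSpec,
) -> tuple[np.ndarray, np.ndarray, ImageGroundTruth]:
    """Render one synthetic image.

    Returns
    -------
    image : ndarray, shape (2, H, W), float32
        Channel 0 haematoxylin, channel 1 DAB.
    mask : ndarray, uint8
        Truth compartments {0 background, 1 stroma, 2 tumour}, built
        with the same geometric rule used by the quantifier (tissue
        envelope = closing of the nuclear support; tumour = dilated
        tumour-nucleus centroids).
    truth : ImageGroundTruth
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    px = spec.pixel_size
    haema = np.full((size, size), 12.0, dtype=np.float32)
    dab = np.full((size, size), 6.0, dtype=np.float32)

    yy, xx = np.mgrid[0:size, 0:size]
    centre = (size - 1) / 2.0
    tissue_region = np.hypot(yy - centre, xx - centre) <= 0.44 * size

    # tumour nests: non-overlapping discs inside the tissue region
    nest_r_px = spec.nest_radius_um / px
    nest_margin = tissue_region & (
        np.hypot(yy - centre, xx - centre) <= 0.44 * size - nest_r_px
    )
    nest_centres = _place_points(
        rng, nest_margin, spec.n_tumour_nests, 1.6 * nest_r_px, []
    )
    nests = np.zeros((size, size), dtype=bool)
    for cy, cx in nest_centres:
        nests |= np.hypot(yy - cy, xx - cx) <= nest_r_px

    # nuclei; realized shapes are clipped away from the classification
    # cutoffs so the tumour/stroma rule stays recoverable by construction
    area_cut = histoquant.DEFAULT_AREA_CUTOFF_UM2
    ecc_cut = histoquant.DEFAULT_ECC_CUTOFF
    shape_bounds = {
        "tumour": ((area_cut + 5.0, 200.0), (0.02, ecc_cut - 0.15)),
        "stroma": ((6.0, area_cut - 8.0), (ecc_cut + 0.06, 0.97)),
    }

    def draw_nuclei(n, region, area_params, ecc_params, cls, existing, min_dist,
                    cross_dist=None):
        pts = _place_points(rng, region, n, min_dist, existing, cross_dist)
        (a_lo, a_hi), (e_lo, e_hi) = shape_bounds[cls]
        rows = []
        for cy, cx in pts:
            area = float(np.clip(rng.normal(*area_params), a_lo, a_hi))
            ecc = float(np.clip(rng.normal(*ecc_params), e_lo, e_hi))
            ratio = np.sqrt(1.0 - ecc**2)  # b / a
            a_um = np.sqrt(area / (np.pi * ratio))
            a_px, b_px = a_um / px, a_um * ratio / px
            angle = rng.uniform(0, np.pi)
            _render_ellipse(haema, cy, cx, a_px, b_px, angle, 200.0)
            rows.append((cy, cx, area, ecc, cls))
        return rows

    min_dist_t = 2.4 * np.sqrt(spec.tumour_nucleus_area[0] / np.pi) / px
    min_dist_s = 3.0 * np.sqrt(spec.stroma_nucleus_area[0] / np.pi) / px
    # tumour and stroma nuclei must never touch (a merged blob would have
    # a blended, unrecoverable shape): tumour ellipses are confined
    # strictly inside the nests and stroma ellipses strictly outside, via
    # worst-case semi-major-axis margins on either side of the nest edge
    def a_max_px(area_params, ecc_hi):
        area_hi = area_params[0] + 4 * area_params[1]
        return np.sqrt(area_hi / (np.pi * np.sqrt(1 - ecc_hi**2))) / px

    margin_t = int(np.ceil(a_max_px(spec.tumour_nucleus_area,
                                    shape_bounds["tumour"][1][1])))
    margin_s = int(np.ceil(a_max_px(spec.stroma_nucleus_area,
                                    shape_bounds["stroma"][1][1])))
    from scipy import ndimage as _ndi

    tumour_region = _ndi.binary_erosion(nests, iterations=margin_t)
    stroma_region = tissue_region & ~_ndi.binary_dilation(nests, iterations=margin_s)
    tumour_rows = draw_nuclei(
        spec.n_tumour_nuclei, tumour_region, spec.tumour_nucleus_area,
        spec.tumour_nucleus_ecc, "tumour", [], min_dist_t,
    )
    stroma_rows = draw_nuclei(
        spec.n_stroma_nuclei, stroma_region, spec.stroma_nucleus_area,
        spec.stroma_nucleus_ecc, "stroma", [p[:2] for p in tumour_rows],
        min_dist_s,
    )
    nuclei_df = pd.DataFrame(
        tumour_rows + stroma_rows,
        columns=["row", "col", "area_um2", "eccentricity", "nucleus_class"],
    )

    # truth mask from the true nuclei, using the shared compartment rule
    support = haema > 100.0
    tissue = histoquant._tissue_envelope(
        (size, size), px, support, spec.closing_radius_um
    )
    tumour_centroids = nuclei_df.loc[
        nuclei_df.nucleus_class == "tumour", ["row", "col"]
    ].to_numpy()
    mask = histoquant.compartments_from_centroids(
        (size, size), px, tumour_centroids, tissue, spec.dilation_radius_um
    )

    # CD8 cells: disks fully inside their compartment, well separated
    cd8_r_px = spec.cd8_radius_um / px
    pad = int(np.ceil((spec.cd8_radius_um + spec.cd8_margin_um) / px)) + 1
    from scipy import ndimage as ndi

    cd8_rows = []
    existing_cd8: list[tuple[float, float]] = []
    for comp_label, comp_name, count in (
        (TUMOUR, "tumour", spec.cd8_tumour_count),
        (STROMA, "stroma", spec.cd8_stroma_count),
    ):
        interior = ndi.binary_erosion(mask == comp_label, iterations=pad)
        pts = _place_points(rng, interior, count, 2 * cd8_r_px + 4, existing_cd8)
        existing_cd8.extend(pts)
        for cy, cx in pts:
            _render_ellipse(dab, cy, cx, cd8_r_px, cd8_r_px, 0.0, 220.0)
            cd8_rows.append((cy, cx, comp_name))
    cd8_df = pd.DataFrame(cd8_rows, columns=["row", "col", "compartment"])

    if spec.noise_sd > 0:
        haema += rng.normal(0, spec.noise_sd, haema.shape).astype(np.float32)
        dab += rng.normal(0, spec.noise_sd, dab.shape).astype(np.float32)
        np.clip(haema, 0, 255, out=haema)
        np.clip(dab, 0, 255, out=dab)

    px_mm2 = (px / 1000.0) ** 2
    truth = ImageGroundTruth(
        cd8_tumour_count=spec.cd8_tumour_count,
        cd8_stroma_count=spec.cd8_stroma_count,
        nuclei=nuclei_df,
        cd8_positions=cd8_df,
        tumour_area_mm2=float(np.sum(mask == TUMOUR) * px_mm2),
        stroma_area_mm2=float(np.sum(mask == STROMA) * px_mm2),
    )
    return np.stack([haema, dab]), mask, truth


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_cohort(
    outdir: str | Path,
    counts: pd.DataFrame,
    densities: pd.DataFrame,
    truth: GroundTruth | None = None,
) -> None:
    """Write counts.tsv, densities.tsv and (optionally) truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    densities.to_csv(outdir / "densities.tsv", sep="\t", index=False)
    if truth is not None:
        (outdir / "truth.json").write_text(json.dumps(truth.to_dict(), indent=1))


def load_cohort(
    indir: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth | None]:
    indir = Path(indir)
    counts = pd.read_csv(indir / "counts.tsv", sep="\t", index_col="gene_id")
    densities = pd.read_csv(indir / "densities.tsv", sep="\t")
    truth = None
    truth_path = indir / "truth.json"
    if truth_path.exists():
        truth = GroundTruth.from_dict(json.loads(truth_path.read_text()))
    return counts, densities, truth


def save_ihc_image(
    outdir: str | Path,
    image: np.ndarray,
    mask: np.ndarray,
    truth: ImageGroundTruth | None = None,
    stem: str = "image",
) -> None:
    """Write <stem>.tif (2-channel), <stem>_preview.png, <stem>_mask.png
    and <stem>_truth.json."""
    import imageio.v3 as iio
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / f"{stem}.tif", image.astype(np.float32))
    preview = np.zeros((*image.shape[1:], 3), dtype=np.uint8)
    preview[..., 2] = np.clip(image[0], 0, 255).astype(np.uint8)  # haema -> blue
    preview[..., 0] = np.clip(image[1], 0, 255).astype(np.uint8)  # DAB -> red
    iio.imwrite(outdir / f"{stem}_preview.png", preview)
    iio.imwrite(outdir / f"{stem}_mask.png", mask.astype(np.uint8))
    if truth is not None:
        (outdir / f"{stem}_truth.json").write_text(json.dumps(truth.to_dict(), indent=1))
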