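"""Digital pathology: nucleus segmentation, tumour/stroma compartments,
CD8 counting.

Works on 2-channel brightfield-like rasters: channel 0 is the
haematoxylin (nuclear) signal, channel 1 the DAB (CD8) signal, both as
intensity images where signal is bright. The compartment logic is:

1. segment nuclei from the haematoxylin channel;
2. call a nucleus *tumour* when it is large and round
   (area >= ``area_cutoff`` and eccentricity <= ``eccentricity_cutoff``),
   otherwise *stroma*;
3. the tumour compartment is the union of disks of radius
   ``dilation_radius_um`` around tumour-nucleus centroids, clipped to the
   tissue envelope; remaining tissue is stroma; the rest is background;
4. DAB+ blobs are counted and assigned to the compartment containing
   their centroid.

All thresholds are explicit parameters; defaults are documented choices,
not claims about any published instrument configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.morphology import closing, disk
from skimage.segmentation import watershed

__all__ = [
    "BACKGROUND",
    "STROMA",
    "TUMOUR",
    "NucleusRecord",
    "CompartmentMask",
    "CompartmentDensities",
    "segment_nuclei",
    "classify_nucleus",
    "classify_compartments",
    "compartments_from_centroids",
    "count_cd8",
    "quantify_image",
]

BACKGROUND, STROMA, TUMOUR = 0, 1, 2

DEFAULT_AREA_CUTOFF_UM2 = 45.0
DEFAULT_ECC_CUTOFF = 0.7
DEFAULT_DILATION_UM = 12.0
DEFAULT_CLOSING_UM = 15.0


@dataclass(frozen=True)
class NucleusRecord:
    """One segmented nucleus."""

    centroid: tuple[float, float]  # (row, col) in pixels, 0-based
    area: float  # um^2
    eccentricity: float  # in [0, 1)
    nucleus_class: str  # "tumour" | "stroma"

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("nucleus area must be positive")


@dataclass
class CompartmentMask:
    """Per-pixel compartment labels plus physical areas."""

    labels: np.ndarray  # int array, values in {BACKGROUND, STROMA, TUMOUR}
    pixel_size: float  # um / pixel
    tumour_area_mm2: float = field(init=False)
    stroma_area_mm2: float = field(init=False)

    def __post_init__(self) -> None:
        px_mm2 = (self.pixel_size / 1000.0) ** 2
        self.tumour_area_mm2 = float(np.sum(self.labels == TUMOUR) * px_mm2)
        self.stroma_area_mm2 = float(np.sum(self.labels == STROMA) * px_mm2)


@dataclass
class CompartmentDensities:
    """Compartmental CD8 counts, areas and densities for one sample."""

    sample_id: str
    cd8_tumour_count: int
    cd8_stroma_count: int
    tumour_area_mm2: float
    stroma_area_mm2: float
    cd8_tumour_density: float  # cells / mm^2; NaN when area is 0
    cd8_stroma_density: float

    @classmethod
    def from_counts(
        cls,
        sample_id: str,
        cd8_tumour_count: int,
        cd8_stroma_count: int,
        tumour_area_mm2: float,
        stroma_area_mm2: float,
    ) -> "CompartmentDensities":
        t_dens = cd8_tumour_count / tumour_area_mm2 if tumour_area_mm2 > 0 else float("nan")
        s_dens = cd8_stroma_count / stroma_area_mm2 if stroma_area_mm2 > 0 else float("nan")
        return cls(sample_id, int(cd8_tumour_count), int(cd8_stroma_count),
                   float(tumour_area_mm2), float(stroma_area_mm2), t_dens, s_dens)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def classify_nucleus(
    area_um2: float,
    eccentricity: float,
    area_cutoff: float = DEFAULT_AREA_CUTOFF_UM2,
    eccentricity_cutoff: float = DEFAULT_ECC_CUTOFF,
) -> str:
    """Tumour iff large and round (area >= cutoff, ecc <= cutoff)."""
    if area_um2 >= area_cutoff and eccentricity <= eccentricity_cutoff:
        return "tumour"
    return "stroma"


def segment_nuclei(
    haematoxylin: np.ndarray,
    pixel_size: float,
    intensity_threshold: float | None = None,
    min_area: float = 10.0,
    area_cutoff: float = DEFAULT_AREA_CUTOFF_UM2,
    eccentricity_cutoff: float = DEFAULT_ECC_CUTOFF,
    min_peak_distance_um: float = 3.0,
    peak_smoothing_px: float = 2.0,
) -> list[NucleusRecord]:
    """Segment nuclei from the haematoxylin channel.

    Thresholds the channel (Otsu when ``intensity_threshold`` is None),
    splits touching objects by watershed on the distance transform, and
    drops objects smaller than ``min_area`` (um^2). Each record carries
    the tumour/stroma class implied by ``area_cutoff`` /
    ``eccentricity_cutoff``.

    An image with no signal yields an empty list, not an error.
    """
    img = np.asarray(haematoxylin, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D single-channel image")
    if intensity_threshold is None:
        if img.max() == img.min():
            return []
        from skimage.filters import threshold_otsu

        intensity_threshold = threshold_otsu(img)
    binary = img > intensity_threshold
    if not binary.any():
        return []
    binary = ndi.binary_fill_holes(binary)

    distance = ndi.distance_transform_edt(binary)
    # smoothing collapses the flat distance ridge of an elongated object
    # into a single peak, preventing watershed over-splitting
    peaks_from = ndi.gaussian_filter(distance, sigma=peak_smoothing_px)
    min_dist_px = max(1, int(round(min_peak_distance_um / pixel_size)))
    coords = peak_local_max(
        peaks_from, min_distance=min_dist_px, labels=binary, exclude_border=False
    )
    markers = np.zeros(binary.shape, dtype=int)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    markers, _ = ndi.label(markers > 0)
    labels = watershed(-distance, markers, mask=binary)

    records: list[NucleusRecord] = []
    for prop in regionprops(labels):
        area_um2 = prop.area * pixel_size**2
        if area_um2 < min_area:
            continue
        records.append(
            NucleusRecord(
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                area=float(area_um2),
                eccentricity=float(prop.eccentricity),
                nucleus_class=classify_nucleus(
                    area_um2, prop.eccentricity, area_cutoff, eccentricity_cutoff
                ),
            )
        )
    return records


def _disk_stamp(radius_px: float) -> np.ndarray:
    """Boolean disk: pixels whose centre lies within ``radius_px``."""
    r = int(np.floor(radius_px))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2) <= radius_px**2


def _stamp_disks(mask: np.ndarray, centroids: np.ndarray, radius_px: float) -> None:
    """OR disks of ``radius_px`` around each (row, col) centroid into mask."""
    stamp = _disk_stamp(radius_px)
    r = stamp.shape[0] // 2
    h, w = mask.shape
    for cy, cx in centroids:
        cy, cx = int(round(cy)), int(round(cx))
        y0, y1 = max(0, cy - r), min(h, cy + r + 1)
        x0, x1 = max(0, cx - r), min(w, cx + r + 1)
        mask[y0:y1, x0:x1] |= stamp[y0 - (cy - r) : y1 - (cy - r),
                                    x0 - (cx - r) : x1 - (cx - r)]


def compartments_from_centroids(
    shape: tuple[int, int],
    pixel_size: float,
    tumour_centroids: np.ndarray,
    tissue_mask: np.ndarray,
    dilation_radius_um: float = DEFAULT_DILATION_UM,
) -> np.ndarray:
    """Label image from tumour centroids and a tissue envelope.

    Tumour = union of disks of radius ``dilation_radius_um`` around the
    given centroids, clipped to tissue; stroma = remaining tissue;
    background = everything else. Shared by the estimator and by the
    synthetic-truth generator so the compartment definition has a single
    source.
    """
    labels = np.zeros(shape, dtype=np.uint8)
    labels[tissue_mask] = STROMA
    if len(tumour_centroids):
        tmask = np.zeros(shape, dtype=bool)
        _stamp_disks(tmask, np.asarray(tumour_centroids, dtype=float),
                     dilation_radius_um / pixel_size)
        labels[tmask & tissue_mask] = TUMOUR
    return labels


def _tissue_envelope(
    shape: tuple[int, int],
    pixel_size: float,
    support: np.ndarray,
    closing_radius_um: float,
) -> np.ndarray:
    """Morphological closing of the signal support; fills gaps between
    nuclei so inter-nuclear space counts as tissue, not glass."""
    if not support.any():
        return np.zeros(shape, dtype=bool)
    radius_px = max(1, int(round(closing_radius_um / pixel_size)))
    closed = closing(support, disk(radius_px))
    return ndi.binary_fill_holes(closed)


def classify_compartments(
    nuclei: list[NucleusRecord],
    shape: tuple[int, int],
    pixel_size: float,
    area_cutoff: float = DEFAULT_AREA_CUTOFF_UM2,
    eccentricity_cutoff: float = DEFAULT_ECC_CUTOFF,
    dilation_radius_um: float = DEFAULT_DILATION_UM,
    support_mask: np.ndarray | None = None,
    closing_radius_um: float = DEFAULT_CLOSING_UM,
) -> CompartmentMask:
    """Build the compartment mask from segmented nuclei.

    ``support_mask`` should be the binary union of nuclear and DAB
    signal; when omitted, equivalent-area disks at nucleus centroids are
    used. With no nuclei at all, the whole tissue envelope is labelled
    stroma and a warning is issued.
    """
    if support_mask is None:
        support_mask = np.zeros(shape, dtype=bool)
        for nuc in nuclei:
            r_px = np.sqrt(nuc.area / np.pi) / pixel_size
            _stamp_disks(support_mask, np.array([nuc.centroid]), r_px)
    tissue = _tissue_envelope(shape, pixel_size, support_mask, closing_radius_um)

    if not nuclei:
        warnings.warn("no nuclei provided; labelling all tissue as stroma", stacklevel=2)
        labels = np.zeros(shape, dtype=np.uint8)
        labels[tissue] = STROMA
        return CompartmentMask(labels=labels, pixel_size=pixel_size)

    tumour_centroids = np.array(
        [
            n.centroid
            for n in nuclei
            if classify_nucleus(n.area, n.eccentricity, area_cutoff, eccentricity_cutoff)
            == "tumour"
        ]
    )
    labels = compartments_from_centroids(
        shape, pixel_size, tumour_centroids, tissue, dilation_radius_um
    )
    return CompartmentMask(labels=labels, pixel_size=pixel_size)


def count_cd8(
    dab: np.ndarray,
    mask: CompartmentMask,
    sample_id: str = "sample",
    dab_threshold: float | None = None,
    min_blob_area: float = 4.0,
) -> CompartmentDensities:
    """Count DAB+ blobs per compartment and derive densities.

    Each connected DAB+ component with area >= ``min_blob_area`` (um^2)
    is counted once and assigned to the compartment of its centroid
    pixel. Blobs whose centroid falls on background are ignored.
    A zero-area compartment keeps its count but reports NaN density.
    """
    img = np.asarray(dab, dtype=float)
    if img.shape != mask.labels.shape:
        raise ValueError("DAB channel and mask geometry differ")
    if dab_threshold is None:
        dab_threshold = img.min() + 0.5 * (img.max() - img.min()) if img.max() > img.min() else np.inf
    binary = img > dab_threshold
    t_count = s_count = 0
    if binary.any():
        labelled = sk_label(binary)
        for prop in regionprops(labelled):
            if prop.area * mask.pixel_size**2 < min_blob_area:
                continue
            cy, cx = (int(round(c)) for c in prop.centroid)
            cy = min(max(cy, 0), mask.labels.shape[0] - 1)
            cx = min(max(cx, 0), mask.labels.shape[1] - 1)
            comp = mask.labels[cy, cx]
            if comp == TUMOUR:
                t_count += 1
            elif comp == STROMA:
                s_count += 1
    return CompartmentDensities.from_counts(
        sample_id, t_count, s_count, mask.tumour_area_mm2, mask.stroma_area_mm2
    )


def quantify_image(
    image: np.ndarray,
    pixel_size: float,
    sample_id: str = "sample",
    intensity_threshold: float | None = None,
    dab_threshold: float | None = None,
    min_area: float = 10.0,
    min_blob_area: float = 4.0,
    area_cutoff: float = DEFAULT_AREA_CUTOFF_UM2,
    eccentricity_cutoff: float = DEFAULT_ECC_CUTOFF,
    dilation_radius_um: float = DEFAULT_DILATION_UM,
    closing_radius_um: float = DEFAULT_CLOSING_UM,
) -> tuple[CompartmentDensities, CompartmentMask, list[NucleusRecord]]:
    """Full quantification of one 2-channel image (haema, DAB)."""
    if image.ndim != 3 or image.shape[0] != 2:
        raise ValueError("expected image with shape (2, H, W)")
    haema, dab = image[0], image[1]
    nuclei = segment_nuclei(
        haema, pixel_size, intensity_threshold, min_area,
        area_cutoff, eccentricity_cutoff,
    )
    # tissue envelope support = thresholded haema + DAB signal
    haema_f = np.asarray(haema, dtype=float)
    dab_f = np.asarray(dab, dtype=float)
    if intensity_threshold is None and haema_f.max() > haema_f.min():
        from skimage.filters import threshold_otsu

        h_thr = threshold_otsu(haema_f)
    else:
        h_thr = intensity_threshold if intensity_threshold is not None else np.inf
    if dab_threshold is None:
        d_thr = dab_f.min() + 0.5 * (dab_f.max() - dab_f.min()) if dab_f.max() > dab_f.min() else np.inf
    else:
        d_thr = dab_threshold
    support = (haema_f > h_thr) | (dab_f > d_thr)
    mask = classify_compartments(
        nuclei, haema.shape, pixel_size, area_cutoff, eccentricity_cutoff,
        dilation_radius_um, support_mask=support, closing_radius_um=closing_radius_um,
    )
    dens = count_cd8(dab, mask, sample_id, dab_threshold, min_blob_area)
    return dens, mask, nuclei
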