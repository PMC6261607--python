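"""High-content image analysis: nuclei detection, seeded cell segmentation
and per-cell feature extraction.

Nuclei in the DAPI channel identify cells; a seeded watershed on the
whole-cell channel partitions the foreground into one region per nucleus;
per cell and per marker channel (α-SMA, fibronectin) the extractor computes
intensity statistics, a morphological granularity spectrum, grey-level
co-occurrence texture and shape descriptors. Granularity — the size-resolved
fraction of signal removed by successive morphological openings — is the
feature family that most strongly separates fiber-rich myofibroblasts from
diffuse fibroblasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats as sps
from skimage.feature import graycomatrix, graycoprops
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import disk, opening
from skimage.segmentation import watershed

__all__ = [
    "FeatureConfig",
    "detect_nuclei",
    "segment_cells",
    "granularity_spectrum",
    "extract_cell_features",
    "extract_plate_features",
]

SMA_CHANNEL = 1
FN_CHANNEL = 2
WHOLECELL_CHANNEL = 3
DAPI_CHANNEL = 0


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-extraction settings.

    ``granularity_scales`` are opening radii in px; the background top-hat
    radius defaults to twice the largest scale. Texture uses co-occurrence
    matrices of 32-level quantized intensities at the given pixel offsets,
    averaged over four orientations.
    """

    granularity_scales: tuple[int, ...] = (1, 2, 3, 4, 6, 8)
    texture_offsets: tuple[int, ...] = (1, 3)
    texture_levels: int = 32
    tophat_radius: int | None = None  # default: 2 * max granularity scale
    min_nucleus_area: int = 30
    drop_border_cells: bool = False

    @property
    def bg_radius(self) -> int:
        return self.tophat_radius or 2 * max(self.granularity_scales)


def detect_nuclei(
    dapi: np.ndarray,
    min_area: int = 30,
    *,
    smoothing_sigma: float = 2.0,
    min_distance: int = 5,
):
    """Detect nuclei in a DAPI image.

    Gaussian smoothing, Otsu threshold, small-object removal, then
    distance-transform maxima seed a watershed to split touching nuclei.

    Returns ``(labels, centroids)`` where ``centroids`` is a DataFrame with
    ``label, y, x``. A blank image yields zero nuclei.
    """
    dapi = np.asarray(dapi)
    if dapi.ndim != 2:
        raise ValueError("DAPI input must be a single 2-D channel")
    img = ndi.gaussian_filter(dapi.astype(float), smoothing_sigma)
    if img.max() <= img.min():
        return np.zeros(dapi.shape, dtype=np.int32), pd.DataFrame(
            columns=["label", "y", "x"]
        )
    mask = img > threshold_otsu(img)
    comp, n = ndi.label(mask)
    if n:
        sizes = np.bincount(comp.ravel())
        mask = sizes[comp] >= min_area
        mask &= comp > 0
    if not mask.any():
        return np.zeros(dapi.shape, dtype=np.int32), pd.DataFrame(
            columns=["label", "y", "x"]
        )

    dist = ndi.distance_transform_edt(mask)
    # Local maxima of the distance map, suppressed within min_distance.
    footprint = np.ones((2 * min_distance + 1,) * 2, dtype=bool)
    peaks = (dist == ndi.maximum_filter(dist, footprint=footprint)) & mask
    seeds, _ = ndi.label(peaks)
    labels = watershed(-dist, seeds, mask=mask).astype(np.int32)

    # Watershed fragments below min_area are absorbed, not counted.
    sizes = np.bincount(labels.ravel())
    small = np.flatnonzero(sizes < min_area)
    if small.size:
        labels[np.isin(labels, small[small > 0])] = 0
    labels, _, _ = _relabel(labels)

    rows = [
        {"label": p.label, "y": p.centroid[0], "x": p.centroid[1]}
        for p in regionprops(labels)
    ]
    return labels, pd.DataFrame(rows, columns=["label", "y", "x"])


def _relabel(labels: np.ndarray):
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    lut[ids] = np.arange(1, ids.size + 1, dtype=np.int32)
    return lut[labels], ids, lut


def segment_cells(
    wholecell: np.ndarray,
    nucleus_seeds: np.ndarray,
    *,
    smoothing_sigma: float = 1.0,
) -> np.ndarray:
    """Partition the whole-cell foreground into one region per nucleus seed.

    Seeded watershed on the inverted, smoothed whole-cell intensity within
    an Otsu foreground mask (union'd with the seeds, so every seed is
    segmentable). Regions are disjoint and each contains exactly one seed.
    """
    wholecell = np.asarray(wholecell, dtype=float)
    if wholecell.shape != nucleus_seeds.shape:
        raise ValueError("whole-cell raster and seeds must share shape")
    if not (nucleus_seeds > 0).any():
        raise ValueError("no nucleus seeds provided")
    img = ndi.gaussian_filter(wholecell, smoothing_sigma)
    mask = img > threshold_otsu(img) if img.max() > img.min() else np.zeros_like(img, bool)
    mask |= nucleus_seeds > 0
    return watershed(-img, nucleus_seeds.astype(np.int32), mask=mask).astype(np.int32)


def granularity_spectrum(
    values: np.ndarray,
    scales,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Morphological granularity spectrum of a (masked) region.

    Entry *i* is the percentage of total signal removed between successive
    greyscale openings with disks of the given radii (applied to the result
    of the previous opening, so the sequence is monotone non-increasing).
    Entries are nonnegative and sum to at most 100. A region with no signal
    yields the zero vector.
    """
    scales = list(scales)
    if any(b <= a for a, b in zip(scales, scales[1:])):
        raise ValueError("scales must be strictly increasing")
    img = np.asarray(values, dtype=float)
    if mask is not None:
        if mask.shape != img.shape:
            raise ValueError("mask and values must share shape")
        img = img * (mask > 0)
    if img.size == 0:
        return np.zeros(len(scales))
    total = img.sum()
    if total <= 0:
        return np.zeros(len(scales))
    out = np.empty(len(scales))
    prev = img
    prev_sum = total
    for i, s in enumerate(scales):
        cur = opening(prev, disk(s))
        if mask is not None:
            cur = cur * (mask > 0)
        cur_sum = cur.sum()
        out[i] = 100.0 * (prev_sum - cur_sum) / total
        prev, prev_sum = cur, cur_sum
    return out


def _finite(x: float) -> float:
    return float(x) if np.isfinite(x) else 0.0


def _intensity_features(vals: np.ndarray) -> dict[str, float]:
    q10, q25, med, q75, q90 = np.percentile(vals, [10, 25, 50, 75, 90])
    mean = vals.mean()
    sd = vals.std()
    total = vals.sum()
    feats = {
        "mean": mean,
        "sd": sd,
        "cv": sd / mean if mean > 0 else 0.0,
        "median": med,
        "q10": q10,
        "q25": q25,
        "q75": q75,
        "q90": q90,
        "iqr": q75 - q25,
        "min": vals.min(),
        "max": vals.max(),
        "integrated": total,
        "mad": np.median(np.abs(vals - med)),
        "skew": _finite(sps.skew(vals)) if vals.size > 2 else 0.0,
        "kurtosis": _finite(sps.kurtosis(vals)) if vals.size > 3 else 0.0,
        "frac_high": float(np.mean(vals > mean)),
        "upper_mass": float(vals[vals >= q90].sum() / total) if total > 0 else 0.0,
    }
    return {k: _finite(v) for k, v in feats.items()}


def _texture_features(
    vals_img: np.ndarray, mask: np.ndarray, cfg: FeatureConfig
) -> dict[str, float]:
    inm = vals_img[mask]
    lo, hi = (inm.min(), inm.max()) if inm.size else (0.0, 0.0)
    feats: dict[str, float] = {}
    props = ("contrast", "correlation", "homogeneity", "dissimilarity", "ASM")
    if hi <= lo:
        for d in cfg.texture_offsets:
            for p in props:
                feats[f"glcm{d}_{p.lower()}"] = 0.0
            feats[f"glcm{d}_entropy"] = 0.0
        return feats
    q = np.zeros(vals_img.shape, dtype=np.uint8)
    q[mask] = np.clip(
        ((vals_img[mask] - lo) / (hi - lo) * (cfg.texture_levels - 1)).astype(int),
        0, cfg.texture_levels - 1,
    ) + 1  # reserve level 0 for outside-mask pixels
    angles = (0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
    glcm = graycomatrix(
        q, distances=cfg.texture_offsets, angles=angles,
        levels=cfg.texture_levels + 1, symmetric=True, normed=False,
    )[1:, 1:, :, :].astype(float)  # drop outside-mask co-occurrences
    sums = glcm.sum(axis=(0, 1), keepdims=True)
    ok = sums > 0
    glcm = np.divide(glcm, sums, out=np.zeros_like(glcm), where=ok)
    for di, d in enumerate(cfg.texture_offsets):
        sub = glcm[:, :, di : di + 1, :]
        for p in props:
            v = graycoprops(sub, p)[0].mean()
            feats[f"glcm{d}_{p.lower()}"] = _finite(v)
        pmat = sub.mean(axis=3)[:, :, 0]
        nz = pmat[pmat > 0]
        feats[f"glcm{d}_entropy"] = _finite(-(nz * np.log2(nz)).sum())
    return feats


def _channel_features(
    corrected: np.ndarray,
    region,
    nucleus_mask_crop: np.ndarray,
    cfg: FeatureConfig,
) -> dict[str, float]:
    sl = region.slice
    crop = corrected[sl]
    mask = region.image
    vals = crop[mask]
    feats = _intensity_features(vals)

    gran = granularity_spectrum(crop, cfg.granularity_scales, mask)
    for s, g in zip(cfg.granularity_scales, gran):
        feats[f"gran_{s}"] = float(g)

    feats.update(_texture_features(crop, mask, cfg))

    # Sub-cellular structure: nucleus vs cytoplasm and rim vs interior.
    nuc = nucleus_mask_crop & mask
    cyto = mask & ~nuc
    nuc_mean = float(crop[nuc].mean()) if nuc.any() else 0.0
    cyto_mean = float(crop[cyto].mean()) if cyto.any() else 0.0
    feats["nucleus_mean"] = nuc_mean
    feats["cyto_mean"] = cyto_mean
    feats["nuc_cyto_ratio"] = _finite(nuc_mean / cyto_mean) if cyto_mean > 0 else 0.0
    inner = ndi.binary_erosion(mask, iterations=2)
    rim = mask & ~inner
    rim_mean = float(crop[rim].mean()) if rim.any() else 0.0
    inner_mean = float(crop[inner].mean()) if inner.any() else 0.0
    feats["rim_mean"] = rim_mean
    feats["rim_inner_ratio"] = _finite(rim_mean / inner_mean) if inner_mean > 0 else 0.0
    return feats


def extract_cell_features(
    image: np.ndarray,
    cells: np.ndarray,
    nuclei: np.ndarray,
    cfg: FeatureConfig = FeatureConfig(),
    *,
    well: str = "",
) -> pd.DataFrame:
    """Per-cell feature table for one field.

    ``image`` is the (4, H, W) stack in channel order DAPI, α-SMA, FN,
    whole-cell. Intensity/granularity/texture features are computed on
    top-hat background-corrected marker channels; shape features come from
    the cell and nucleus masks. All values are finite.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[0] < 4:
        raise ValueError("image must be a (4, H, W) channel stack")
    if image.shape[1:] != cells.shape or cells.shape != nuclei.shape:
        raise ValueError("image, cell and nucleus rasters must share shape")

    r = cfg.bg_radius
    size = 2 * r + 1
    corrected = {}
    for name, ch in (("sma", SMA_CHANNEL), ("fn", FN_CHANNEL)):
        chan = image[ch].astype(float)
        corrected[name] = ndi.white_tophat(chan, size=(size, size))

    nuc_mask = nuclei > 0
    dapi = image[DAPI_CHANNEL].astype(float)

    rows = []
    for region in regionprops(cells):
        sl = region.slice
        if cfg.drop_border_cells:
            if (
                sl[0].start == 0 or sl[1].start == 0
                or sl[0].stop == cells.shape[0] or sl[1].stop == cells.shape[1]
            ):
                continue
        row: dict[str, float | str | int] = {
            "well": well,
            "cell_id": int(region.label),
        }
        for name in ("sma", "fn"):
            ch_feats = _channel_features(
                corrected[name], region, nuc_mask[sl], cfg
            )
            row.update({f"{name}_{k}": v for k, v in ch_feats.items()})

        # Shape (channel-independent).
        area = float(region.area)
        per = float(region.perimeter)
        row["shape_area"] = area
        row["shape_perimeter"] = per
        row["shape_eccentricity"] = _finite(region.eccentricity)
        row["shape_solidity"] = _finite(region.solidity)
        row["shape_form_factor"] = _finite(4 * np.pi * area / per**2) if per > 0 else 0.0
        row["shape_major_axis"] = _finite(region.axis_major_length)
        row["shape_minor_axis"] = _finite(region.axis_minor_length)
        row["shape_extent"] = _finite(region.extent)
        nuc_in = nuc_mask[sl] & region.image
        nuc_area = float(nuc_in.sum())
        row["shape_nucleus_area"] = nuc_area
        row["shape_nuc_cell_area_ratio"] = nuc_area / area if area > 0 else 0.0

        dvals = dapi[sl][nuc_in] if nuc_in.any() else dapi[sl][region.image]
        row["dapi_mean"] = _finite(dvals.mean())
        row["dapi_sd"] = _finite(dvals.std())
        row["dapi_integrated"] = _finite(dvals.sum())
        rows.append(row)

    df = pd.DataFrame(rows)
    if df.empty:
        return df
    feat_cols = [c for c in df.columns if c not in ("well", "cell_id")]
    assert df[feat_cols].to_numpy(dtype=float).size == 0 or np.isfinite(
        df[feat_cols].to_numpy(dtype=float)
    ).all(), "non-finite feature value produced"
    return df


def feature_columns(df: pd.DataFrame) -> list[str]:
    """Names of the numeric feature columns of a cell feature table."""
    skip = {"well", "cell_id", "class", "label"}
    return [c for c in df.columns if c not in skip]


def extract_plate_features(
    fields: dict,
    cfg: FeatureConfig = FeatureConfig(),
    *,
    use_truth_masks: bool = False,
    attach_truth_labels: bool = False,
) -> pd.DataFrame:
    """Segment and extract features for every simulated field of a plate.

    With ``use_truth_masks`` the generator's label rasters replace the
    segmentation (useful for isolating feature/classifier behaviour from
    segmentation error). ``attach_truth_labels`` joins each cell's
    ground-truth class by nearest ground-truth centroid.
    """
    tables = []
    for wname, fld in fields.items():
        if use_truth_masks:
            cells, nuclei = fld.cell_labels, fld.nucleus_labels
        else:
            nuclei, _ = detect_nuclei(
                fld.image[DAPI_CHANNEL], cfg.min_nucleus_area
            )
            if not (nuclei > 0).any():
                continue
            cells = segment_cells(fld.image[WHOLECELL_CHANNEL], nuclei)
        tab = extract_cell_features(fld.image, cells, nuclei, cfg, well=wname)
        if tab.empty:
            continue
        if attach_truth_labels and len(fld.truth):
            props = {p.label: p.centroid for p in regionprops(cells)}
            gx = fld.truth["x"].to_numpy()
            gy = fld.truth["y"].to_numpy()
            gcls = fld.truth["class"].to_numpy()
            labels = []
            for cid in tab["cell_id"]:
                cy, cx = props[int(cid)]
                j = int(np.argmin((gx - cx) ** 2 + (gy - cy) ** 2))
                labels.append(gcls[j])
            tab = tab.assign(**{"class": labels})
        tables.append(tab)
    if not tables:
        return pd.DataFrame()
    return pd.concat(tables, ignore_index=True)
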