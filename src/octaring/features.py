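"""Percentile vessel-density features per concentric region.

Within each annulus the empirical distribution of pixel intensities is
summarized by its inverse CDF evaluated at a fixed set of percentile
ranks.  Because en-face OCTA intensity is a proxy for local perfusion,
lower percentiles track capillary dropout while upper percentiles track
the bright large-vessel signal.  The rank of a pixel within its region is
``P = n / N * 100`` (%); the feature at rank ``p`` is the intensity at
sorted position ``ceil(p/100 * N)`` (lower-interpolation inverse CDF).

The default configuration uses the nine deciles 10..90, giving a
7 regions x 9 ranks = 63-column feature vector per image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import RegionMaskSet, RegionScheme, compute_region_masks

__all__ = [
    "CLASS_LABELS",
    "PercentileConfig",
    "RegionFeatureVector",
    "percentile_rank_of_pixel",
    "extract_region_percentiles",
    "build_feature_table",
    "feature_columns",
    "region_columns",
    "read_feature_table",
    "write_feature_table",
]

#: Fixed three-class label order used throughout the package.
CLASS_LABELS: tuple[str, str, str] = ("normal", "mild", "moderate")

_META_COLUMNS = ("image_path", "patient_id", "label")


@dataclass(frozen=True)
class PercentileConfig:
    """Ordered percentile ranks (strictly increasing, each in (0, 100))."""

    ranks: tuple[float, ...] = (10, 20, 30, 40, 50, 60, 70, 80, 90)

    def __post_init__(self) -> None:
        r = np.asarray(self.ranks, dtype=float)
        if r.size == 0 or np.any(r <= 0) or np.any(r >= 100):
            raise ValueError("ranks must lie strictly inside (0, 100)")
        if np.any(np.diff(r) <= 0):
            raise ValueError("ranks must be strictly increasing")

    @property
    def n_ranks(self) -> int:
        return len(self.ranks)


@dataclass(frozen=True)
class RegionFeatureVector:
    """Inverse-CDF intensities of one region at the configured ranks."""

    region_index: int
    values: tuple[float, ...]


def percentile_rank_of_pixel(rank_n: int, total_n: int) -> float:
    """Percentile rank ``P = n / N * 100`` of the n-th smallest of N pixels."""
    if not 1 <= rank_n <= total_n:
        raise ValueError(f"rank {rank_n} out of range 1..{total_n}")
    return rank_n / total_n * 100.0


def extract_region_percentiles(
    image: np.ndarray,
    mask: np.ndarray,
    config: PercentileConfig = PercentileConfig(),
    region_index: int = 0,
) -> RegionFeatureVector:
    """Inverse-CDF intensity at each configured rank over the masked pixels.

    The value at rank ``p`` is the smallest intensity whose empirical CDF
    reaches ``p/100`` — i.e. sorted position ``ceil(p/100 * N)``.  Zero
    intensities are ordinary observations (absent flow signal), never
    background to exclude.
    """
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError(
            f"image shape {image.shape} != mask shape {mask.shape}"
        )
    vals = image[mask]
    if vals.size == 0:
        raise ValueError(f"region {region_index}: mask selects no pixels")
    feats = np.percentile(
        vals.astype(float), list(config.ranks), method="inverted_cdf"
    )
    return RegionFeatureVector(
        region_index=region_index, values=tuple(float(v) for v in feats)
    )


def feature_columns(
    n_regions: int, config: PercentileConfig = PercentileConfig()
) -> list[str]:
    """Canonical column order: region-major, ``R{region}_p{rank}``."""
    cols = []
    for r in range(1, n_regions + 1):
        for p in config.ranks:
            p_str = str(int(p)) if float(p).is_integer() else str(p)
            cols.append(f"R{r}_p{p_str}")
    return cols


def region_columns(
    region_index: int, n_regions: int, config: PercentileConfig = PercentileConfig()
) -> list[str]:
    """The 9-column block of one region within the full feature layout."""
    if not 1 <= region_index <= n_regions:
        raise IndexError(f"region index {region_index} out of range")
    all_cols = feature_columns(n_regions, config)
    k = config.n_ranks
    return all_cols[(region_index - 1) * k : region_index * k]


def _load_grayscale(path: str) -> np.ndarray:
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)


def build_feature_table(
    manifest: pd.DataFrame,
    scheme: RegionScheme,
    config: PercentileConfig = PercentileConfig(),
    mask_set: RegionMaskSet | None = None,
    images: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Assemble the per-image feature table from a manifest.

    Parameters
    ----------
    manifest : DataFrame with columns image_path, patient_id, label.
    scheme : RegionScheme matching the (uniform) image shape.
    mask_set : optional precomputed masks (avoids re-rasterizing).
    images : optional mapping image_path -> array; paths found here are
        used directly instead of being read from disk.

    Returns
    -------
    DataFrame with the metadata columns plus ``n_regions * n_ranks``
    feature columns named ``R{region}_p{rank}`` in region-major order.
    Slicing one region's block with :func:`region_columns` recovers the
    regional dataset used to train that region's classifier.
    """
    missing = [c for c in _META_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if len(manifest) == 0:
        raise ValueError("manifest is empty; nothing to extract")
    bad = set(manifest["label"]) - set(CLASS_LABELS)
    if bad:
        row = manifest.index[manifest["label"].isin(bad)][0]
        raise ValueError(
            f"manifest row {row}: unknown label(s) {sorted(bad)}; "
            f"expected one of {CLASS_LABELS}"
        )

    cols = feature_columns(scheme.n_regions, config)
    rows = []
    for idx, rec in manifest.iterrows():
        if images is not None and rec["image_path"] in images:
            img = np.asarray(images[rec["image_path"]])
        else:
            try:
                img = _load_grayscale(rec["image_path"])
            except Exception as exc:  # noqa: BLE001 - report the offending row
                raise ValueError(
                    f"manifest row {idx}: cannot read image "
                    f"{rec['image_path']!r} ({exc})"
                ) from exc
        if mask_set is None:
            mask_set = compute_region_masks(scheme, img.shape)
        if img.shape != mask_set.image_shape:
            raise ValueError(
                f"manifest row {idx}: image shape {img.shape} does not "
                f"match scheme shape {mask_set.image_shape}"
            )
        feats: list[float] = []
        for r, mask in enumerate(mask_set.masks, start=1):
            rv = extract_region_percentiles(img, mask, config, region_index=r)
            feats.extend(rv.values)
        rows.append(
            dict(
                zip(cols, feats),
                image_path=rec["image_path"],
                patient_id=rec["patient_id"],
                label=rec["label"],
            )
        )
    table = pd.DataFrame(rows, columns=list(_META_COLUMNS) + cols)
    return table


def write_feature_table(table: pd.DataFrame, path: str) -> None:
    """CSV export with the canonical fixed column order."""
    table.to_csv(path, index=False)


def read_feature_table(path: str) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    table = pd.read_csv(path)
    missing = [c for c in _META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    if table.isna().any().any():
        raise ValueError("feature table contains missing values")
    return table


def n_regions_of_table(table: pd.DataFrame, config: PercentileConfig) -> int:
    n_feat = len([c for c in table.columns if c not in _META_COLUMNS])
    n, rem = divmod(n_feat, config.n_ranks)
    if rem:
        raise ValueError(
            f"{n_feat} feature columns not divisible by {config.n_ranks} ranks"
        )
    return n
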