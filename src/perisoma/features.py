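"""Feature assembly: the three-step object filter, 800-nm z-slab
normalization, per-feature z-scoring, and per-cell feature vectors.

Filtering removes (in order) nucleus detections smaller than 25 um^3, cells
whose 15-um bounding box contains more than 20% error-id-0 voxels, and cells
the object classifier later predicts as errors.  Slab normalization corrects
abrupt section-thickness shifts along the sectioning (z) axis by dividing
each size feature by its 800-nm slab mean; ratios are recomputed afterwards.
Features are then independently z-scored across cells (population sd).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import NUCLEUS_FEATURE_NAMES, SOMA_FEATURE_NAMES

#: strict lower volume bound (um^3): smaller objects are nucleolus fragments
MIN_NUCLEUS_VOLUME_UM3 = 25.0
#: strict upper bound on the error-id-0 fraction of the 15-um bounding box
MAX_ERROR_ID_FRACTION = 0.20
#: z-slab width for section-thickness normalization (nm)
SLAB_WIDTH_NM = 800.0

#: size features that are divided by their slab mean; ratio features are
#: recomputed from them afterwards
SIZE_FEATURES = (
    "nucleus_volume_um3", "nucleus_area_um2", "nucleus_fold_area_um2",
    "soma_volume_um3", "soma_area_um2",
)

#: the 13 nucleus + soma feature columns, in canonical order
FEATURE_COLUMNS = tuple(NUCLEUS_FEATURE_NAMES) + tuple(SOMA_FEATURE_NAMES)


@dataclass
class FilterReport:
    """Bookkeeping of the sequential three-step object filter."""

    n_input: int
    n_removed_small: int
    n_removed_error_fraction: int
    n_removed_predicted_error: int
    kept_ids: set = field(default_factory=set)

    @property
    def n_kept(self) -> int:
        return len(self.kept_ids)

    def check(self) -> None:
        total = (self.n_kept + self.n_removed_small
                 + self.n_removed_error_fraction + self.n_removed_predicted_error)
        if total != self.n_input:
            raise AssertionError("filter report counts do not reconcile")


def filter_objects(ids,
                   volumes_um3,
                   bbox_error_fractions,
                   predicted_error_ids=None) -> FilterReport:
    """Apply the three filtering steps sequentially and report counts.

    Thresholds are strict exactly as stated: volume < 25 um^3 removes,
    volume == 25 um^3 keeps; error fraction > 0.20 removes, == 0.20 keeps.
    """
    ids = np.asarray(list(ids))
    volumes = np.asarray(volumes_um3, dtype=float)
    fractions = np.asarray(bbox_error_fractions, dtype=float)
    if len(ids) != len(volumes) or len(ids) != len(fractions):
        raise ValueError("ids, volumes and error fractions must align")
    if np.isnan(volumes).any() or np.isnan(fractions).any():
        raise ValueError("missing volume or error-fraction values")
    predicted_error_ids = set(predicted_error_ids or ())

    small = volumes < MIN_NUCLEUS_VOLUME_UM3
    remain = ~small
    high_error = remain & (fractions > MAX_ERROR_ID_FRACTION)
    remain = remain & ~high_error
    predicted = remain & np.isin(ids, list(predicted_error_ids))
    remain = remain & ~predicted

    report = FilterReport(
        n_input=len(ids),
        n_removed_small=int(small.sum()),
        n_removed_error_fraction=int(high_error.sum()),
        n_removed_predicted_error=int(predicted.sum()),
        kept_ids=set(ids[remain].tolist()),
    )
    report.check()
    return report


def z_slab_normalize(values, slab_coordinates_nm,
                     slab_width_nm: float = SLAB_WIDTH_NM) -> np.ndarray:
    """Divide each value by the mean of its z slab.

    Slab index = floor(coordinate / width).  A slab whose mean is zero is an
    error; slabs holding a single value normalize to 1.0 (degenerate, warned).
    """
    values = np.asarray(values, dtype=float)
    coords = np.asarray(slab_coordinates_nm, dtype=float)
    if values.shape[0] != coords.shape[0]:
        raise ValueError("values and slab coordinates must align")
    slabs = np.floor(coords / slab_width_nm).astype(int)
    out = np.empty_like(values)
    singletons = 0
    for s in np.unique(slabs):
        m = slabs == s
        mean = values[m].mean()
        if mean == 0:
            raise ValueError(f"slab {s} has zero mean; cannot normalize")
        if m.sum() == 1:
            singletons += 1
        out[m] = values[m] / mean
    if singletons:
        warnings.warn(f"{singletons} z slab(s) contain a single cell; "
                      "their normalized values are degenerate (1.0)")
    return out


def zscore_features(matrix) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Independently z-score each feature across cells (population sd).

    Returns the standardized matrix and the (means, sds) needed to apply the
    same transform to new cells.  Constant columns are dropped with a warning.
    """
    df = pd.DataFrame(matrix).astype(float)
    if len(df) < 2:
        raise ValueError("need at least 2 cells to z-score")
    means = df.mean(axis=0)
    sds = df.std(axis=0, ddof=0)
    constant = sds[sds == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping constant feature column(s): {constant}")
        df = df.drop(columns=constant)
        means = means.drop(constant)
        sds = sds.drop(constant)
    return (df - means) / sds, means, sds


def apply_zscore(matrix, means: pd.Series, sds: pd.Series) -> pd.DataFrame:
    """Standardize new cells with previously fitted parameters."""
    df = pd.DataFrame(matrix).astype(float)
    return (df[means.index] - means) / sds


def _recompute_ratios(df: pd.DataFrame) -> pd.DataFrame:
    """Rebuild derived ratio features after slab normalization of sizes."""
    df = df.copy()
    if {"nucleus_area_um2", "nucleus_volume_um3"} <= set(df.columns):
        df["nucleus_area_to_volume"] = df["nucleus_area_um2"] / df["nucleus_volume_um3"]
    if {"nucleus_fold_area_um2", "nucleus_area_um2"} <= set(df.columns):
        df["nucleus_fold_fraction"] = df["nucleus_fold_area_um2"] / df["nucleus_area_um2"]
    if {"soma_area_um2", "soma_volume_um3"} <= set(df.columns):
        df["soma_area_to_volume"] = df["soma_area_um2"] / df["soma_volume_um3"]
    if {"soma_synapse_count", "soma_area_um2"} <= set(df.columns):
        df["soma_synapse_density"] = df["soma_synapse_count"] / df["soma_area_um2"]
    if {"nucleus_volume_um3", "soma_volume_um3"} <= set(df.columns):
        df["nucleus_to_soma_volume_ratio"] = (df["nucleus_volume_um3"]
                                              / df["soma_volume_um3"])
    return df


@dataclass
class AssembledFeatures:
    """Per-cell feature vectors, raw and standardized."""

    raw: pd.DataFrame
    standardized: pd.DataFrame
    zscore_means: pd.Series
    zscore_sds: pd.Series
    excluded_ids: list = field(default_factory=list)
    pss_missing_ids: list = field(default_factory=list)


def assemble(nucleus_table: pd.DataFrame,
             soma_table: pd.DataFrame,
             pss_table: pd.DataFrame | None = None,
             z_nm_column: str = "z_nm",
             slab_width_nm: float = SLAB_WIDTH_NM,
             slab_normalize: bool = True) -> AssembledFeatures:
    """Join nucleus/soma(/PSS) tables keyed by cell_id and standardize.

    Cells missing soma features are excluded and reported.  The standardized
    block is built by the two normalizations in order: z-slab normalization
    of size features (ratios recomputed) followed by per-feature z-scoring.
    PSS columns, present only for the inhibitory-routed subset, are z-scored
    over the cells that have them; cells without PSS are flagged.
    """
    for name, table in (("nucleus", nucleus_table), ("soma", soma_table)):
        if table.index.name != "cell_id":
            raise ValueError(f"{name} table must be indexed by cell_id")
        if table.index.duplicated().any():
            raise ValueError(f"duplicate cell_id in {name} table")

    joined = nucleus_table.join(soma_table, how="inner")
    excluded = sorted(set(nucleus_table.index) - set(joined.index))
    if len(joined) == 0:
        empty = joined.copy()
        return AssembledFeatures(raw=empty, standardized=empty,
                                 zscore_means=pd.Series(dtype=float),
                                 zscore_sds=pd.Series(dtype=float),
                                 excluded_ids=excluded)

    raw = joined.copy()
    norm = joined.copy()
    if slab_normalize and len(norm) and z_nm_column in norm.columns:
        coords = norm[z_nm_column].to_numpy()
        for col in SIZE_FEATURES:
            if col in norm.columns:
                norm[col] = z_slab_normalize(norm[col].to_numpy(), coords,
                                             slab_width_nm)
        norm = _recompute_ratios(norm)

    feature_cols = [c for c in FEATURE_COLUMNS if c in norm.columns]
    if len(norm) < 2:
        raise ValueError("need at least 2 joined cells to assemble features")
    standardized, means, sds = zscore_features(norm[feature_cols])

    pss_missing: list = []
    if pss_table is not None and len(pss_table):
        if pss_table.index.name != "cell_id":
            raise ValueError("pss table must be indexed by cell_id")
        if pss_table.index.duplicated().any():
            raise ValueError("duplicate cell_id in pss table")
        pss_cells = standardized.index.intersection(pss_table.index)
        pss_missing = sorted(set(standardized.index) - set(pss_cells))
        if len(pss_cells) >= 2:
            pss_std, pss_means, pss_sds = zscore_features(
                pss_table.loc[pss_cells])
            standardized = standardized.join(pss_std, how="left")
            means = pd.concat([means, pss_means])
            sds = pd.concat([sds, pss_sds])
            raw = raw.join(pss_table, how="left")

    return AssembledFeatures(raw=raw, standardized=standardized,
                             zscore_means=means, zscore_sds=sds,
                             excluded_ids=excluded,
                             pss_missing_ids=pss_missing)
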