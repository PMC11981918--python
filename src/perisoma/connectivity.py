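"""Connectivity analyses: rare-cell search, axo-axonic (chandelier) targeting
statistics, 5P-NP output preference, Fisher enrichment, proofreading and
truncation statistics, and subclass density maps.

Chandelier cells synapse on the axon initial segment (AIS), located just
below the soma of excitatory targets; the angle phi between the pia
direction and the soma-to-synapse vector (0 deg = directly above the target
soma, 180 deg = directly below) together with the distance r is a spatial
proxy for AIS targeting: synapses with phi in [160, 180] deg within 60 um of
the soma are counted as AIS synapses, and a cell with more than 40% of its
outputs in that window is called a chandelier cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .types import DepthReference, validate_synapse_table, synapse_xyz

#: AIS angular window (degrees) and radius (um)
AIS_ANGLE_WINDOW_DEG = (160.0, 180.0)
AIS_MAX_RADIUS_UM = 60.0
#: strict chandelier threshold on the AIS fraction
CHANDELIER_THRESHOLD = 0.40
#: inclusive 5P-NP output-preference threshold ("at least 30%")
NP_PREFERENCE_THRESHOLD = 0.30
#: axons should be proofread/extended to at least this many outputs
MIN_OUTPUT_SYNAPSES = 100


# ---------------------------------------------------------------------------
# nearest-neighbour rare-cell search


def nearest_neighbors(standardized: pd.DataFrame, query_id, k: int = 20) -> list:
    """Top-k nearest neighbours of a cell in the standardized feature space.

    Euclidean distance via a KD-tree; the query itself is excluded and ties
    break by ascending cell id.
    """
    if query_id not in standardized.index:
        raise KeyError(f"query id {query_id!r} not in the feature table")
    n = len(standardized)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    X = standardized.to_numpy(dtype=float)
    ids = standardized.index.to_numpy()
    qpos = standardized.index.get_loc(query_id)
    tree = cKDTree(X)
    dist, idx = tree.query(X[qpos], k=n)
    dist, idx = np.atleast_1d(dist), np.atleast_1d(idx)
    keep = idx != qpos
    dist, idx = dist[keep], idx[keep]
    # stable tie-break on (distance, id)
    order = np.lexsort((ids[idx], dist))
    return ids[idx[order][:k]].tolist()


# ---------------------------------------------------------------------------
# targeting geometry


@dataclass
class TargetingProfile:
    """Per-output-synapse angular targeting records of one axon."""

    records: pd.DataFrame     # phi_deg, r_um, target_id, target_label
    n_outputs: int
    n_unmatched: int = 0


def targeting_profile(outputs: pd.DataFrame,
                      target_somata: pd.DataFrame,
                      depth_reference: DepthReference | None = None,
                      target_labels: pd.Series | None = None) -> TargetingProfile:
    """Angle/distance profile of an axon's output synapses.

    ``target_somata`` is indexed by cell id with columns x_nm, y_nm, z_nm.
    phi is the angle between the pia direction and the vector from the
    target soma centroid to the synapse (0 deg = directly above the soma on
    the pial side); r is the Euclidean distance in um.  Outputs without a
    known target soma are excluded from the records (counted as unmatched).
    """
    validate_synapse_table(outputs)
    depth_reference = depth_reference or DepthReference()
    if len(outputs) == 0:
        raise ValueError("empty output synapse table")
    if len(outputs) < MIN_OUTPUT_SYNAPSES:
        import warnings
        warnings.warn(f"axon has {len(outputs)} outputs; the targeting "
                      f"statistics assume >= {MIN_OUTPUT_SYNAPSES} "
                      "(extend/proofread the axon)")

    known = outputs["post_id"].isin(target_somata.index)
    matched = outputs[known]
    xyz = synapse_xyz(matched)
    soma = target_somata.loc[matched["post_id"],
                             ["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    v = xyz - soma
    r_um = np.linalg.norm(v, axis=1) / 1000.0
    pia_dir = -depth_reference.depth_direction()
    with np.errstate(invalid="ignore"):
        cosang = (v @ pia_dir) / np.maximum(np.linalg.norm(v, axis=1), 1e-12)
    phi = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    records = pd.DataFrame({
        "phi_deg": phi,
        "r_um": r_um,
        "target_id": matched["post_id"].to_numpy(),
    })
    if target_labels is not None:
        records["target_label"] = target_labels.reindex(
            records["target_id"]).to_numpy()
    return TargetingProfile(records=records, n_outputs=len(outputs),
                            n_unmatched=int((~known).sum()))


def chandelier_score(profile: TargetingProfile,
                     angle_window_deg: tuple = AIS_ANGLE_WINDOW_DEG,
                     r_max_um: float = AIS_MAX_RADIUS_UM,
                     threshold: float = CHANDELIER_THRESHOLD) -> tuple[float, bool]:
    """(ais_fraction, is_chandelier) of an axon's targeting profile.

    The AIS fraction is the share of all outputs with phi in the angular
    window and r within 60 um; the chandelier call is strict (> threshold).
    """
    if profile.n_outputs == 0:
        raise ValueError("profile has zero outputs")
    rec = profile.records
    lo, hi = angle_window_deg
    ais = ((rec["phi_deg"] >= lo) & (rec["phi_deg"] <= hi)
           & (rec["r_um"] <= r_max_um))
    fraction = float(ais.sum()) / profile.n_outputs
    return fraction, fraction > threshold


def target_fractions(profile: TargetingProfile,
                     np_label: str = "5P-NP",
                     threshold: float = NP_PREFERENCE_THRESHOLD,
                     strict: bool = False) -> tuple[pd.Series, bool]:
    """Output fractions per target label and the 5P-NP preference flag.

    Fractions are over labelled targets and sum to 1.  The preference rule
    defaults to inclusive (>= 30%, "at least 30%"); ``strict=True`` applies
    the strict reading (> 30%).
    """
    rec = profile.records
    if "target_label" not in rec.columns or rec["target_label"].isna().all():
        raise ValueError("profile has no labelled targets")
    labelled = rec.dropna(subset=["target_label"])
    fractions = labelled["target_label"].value_counts(normalize=True).sort_index()
    np_frac = float(fractions.get(np_label, 0.0))
    preferring = np_frac > threshold if strict else np_frac >= threshold
    return fractions, bool(preferring)


# ---------------------------------------------------------------------------
# enrichment


@dataclass
class EnrichmentResult:
    table: np.ndarray
    p_two_tailed: float
    odds_ratio: float


def fisher_enrichment(a: int, b: int, c: int, d: int) -> EnrichmentResult:
    """Two-tailed Fisher exact test on the 2x2 table [[a, b], [c, d]].

    The two-tailed p sums the hypergeometric probabilities of all tables
    with the observed margins whose point probability does not exceed the
    observed table's (the conventional probability-mass definition).
    """
    table = np.array([[a, b], [c, d]], dtype=int)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("all table margins must be positive")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(table=table, p_two_tailed=float(p),
                            odds_ratio=float(odds))


# ---------------------------------------------------------------------------
# proofreading and truncation


def proofreading_deltas(synapses_before, synapses_after) -> dict[str, float]:
    """Fractions of synapses removed, added and maintained by proofreading.

    Inputs are sets/sequences of comparable synapse ids (call once for
    inputs and once for outputs).  removed and maintained are fractions of
    the before set; added is a fraction of the after set.
    """
    before = set(synapses_before)
    after = set(synapses_after)
    if not before and not after:
        raise ValueError("both synapse sets are empty")
    removed = len(before - after) / len(before) if before else 0.0
    added = len(after - before) / len(after) if after else 0.0
    maintained = len(before & after) / len(before) if before else 0.0
    return {"removed": removed, "added": added, "maintained": maintained}


def radial_extent(input_synapses_xyz_nm: np.ndarray,
                  soma_position_nm: np.ndarray,
                  percentile: float = 97.0) -> float:
    """Dendritic radial extent: a percentile (default 97th) of the input
    synapse-to-soma distance distribution, in um (linear interpolation)."""
    xyz = np.atleast_2d(np.asarray(input_synapses_xyz_nm, dtype=float))
    if len(xyz) == 0:
        raise ValueError("no input synapses")
    d_um = np.linalg.norm(xyz - np.asarray(soma_position_nm, dtype=float),
                          axis=1) / 1000.0
    return float(np.percentile(d_um, percentile, method="linear"))


def truncation_estimate(radial_extents_um, border_distances_um) -> float:
    """Fraction of cells potentially truncated by the volume border: cells
    whose minimum border distance is below the cohort median radial extent."""
    extents = np.asarray(radial_extents_um, dtype=float)
    borders = np.asarray(border_distances_um, dtype=float)
    if len(extents) == 0 or len(borders) == 0:
        raise ValueError("both distributions must be nonempty")
    threshold = float(np.median(extents))
    return float((borders < threshold).mean())


# ---------------------------------------------------------------------------
# density maps


def subclass_density_map(predictions: pd.Series,
                         xz_positions_nm: pd.DataFrame,
                         bin_um: float = 50.0) -> dict[str, pd.DataFrame]:
    """Per-subclass cell densities on a square grid in the x-z plane.

    Counts per ``bin_um`` x ``bin_um`` bin are scaled to cells per mm^2.
    Returns one count grid (as a DataFrame of densities) per predicted label.
    """
    predictions = pd.Series(predictions)
    pos = xz_positions_nm.loc[predictions.index, ["x_nm", "z_nm"]].to_numpy(float)
    bin_nm = bin_um * 1000.0
    ix = np.floor(pos[:, 0] / bin_nm).astype(int)
    iz = np.floor(pos[:, 1] / bin_nm).astype(int)
    if len(pos):
        x0, x1 = ix.min(), ix.max()
        z0, z1 = iz.min(), iz.max()
    else:
        x0 = x1 = z0 = z1 = 0
    scale = 1.0 / (bin_um / 1000.0) ** 2        # bins per mm^2
    out = {}
    for label in sorted(predictions.unique()):
        m = (predictions == label).to_numpy()
        grid = np.zeros((x1 - x0 + 1, z1 - z0 + 1))
        np.add.at(grid, (ix[m] - x0, iz[m] - z0), 1.0)
        out[label] = pd.DataFrame(
            grid * scale,
            index=pd.Index((np.arange(x0, x1 + 1)) * bin_um, name="x_um"),
            columns=pd.Index((np.arange(z0, z1 + 1)) * bin_um, name="z_um"))
    return out
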