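"""Postsynaptic shape (PSS) features.

For every synapse within 60 um of the nucleus centre, a 3,500-nm region of
the cell surface around the synapse is cut out, segmented by local thickness,
and reduced to the postsynaptic compartment proper (a spine head+neck, a
stretch of dendritic shaft, or a patch of soma).  Each shape is pose-
normalized, embedded as a fixed-size latent vector, assigned to one of k = 30
dictionary shape types, and accumulated into a 30 x 4 histogram over four
15-um radial bins (0-60 um), flattened to the 120-D spatial shape histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .meshutil import MeshProximity, local_diameter, sample_surface

#: cutout radius around each synapse (nm)
REGION_RADIUS_NM = 3500.0
#: PSS are collected within this radius of the nucleus centre (um)
PSS_MAX_RADIUS_UM = 60.0
#: radial bin edges (um)
RADIAL_EDGES_UM = (0.0, 15.0, 30.0, 45.0, 60.0)
#: dictionary size
DICTIONARY_K = 30
#: latent embedding size
LATENT_SIZE = 1024


# ---------------------------------------------------------------------------
# region extraction


def synapse_region_mesh(cell_surface: trimesh.Trimesh,
                        synapse_location_nm: np.ndarray,
                        radius_nm: float = REGION_RADIUS_NM) -> trimesh.Trimesh:
    """Sub-mesh of all faces with a vertex within ``radius_nm`` of the
    synapse, restricted to the connected component containing the vertex
    nearest the synapse."""
    syn = np.asarray(synapse_location_nm, dtype=float)
    d_vert = np.linalg.norm(cell_surface.vertices - syn, axis=1)
    keep_vert = d_vert <= radius_nm
    keep_face = keep_vert[cell_surface.faces].any(axis=1)
    if not keep_face.any():
        raise ValueError("no face within the region radius of the synapse")
    region = cell_surface.submesh([np.flatnonzero(keep_face)], append=True)
    parts = region.split(only_watertight=False)
    if len(parts) <= 1:
        return region
    # component containing the synapse-nearest vertex
    best, best_d = None, np.inf
    for part in parts:
        d = np.linalg.norm(part.vertices - syn, axis=1).min()
        if d < best_d:
            best, best_d = part, d
    return best


# ---------------------------------------------------------------------------
# thickness segmentation


@dataclass
class ThicknessSegment:
    """One edge-connected, thickness-homogeneous piece of a region mesh."""

    mesh: trimesh.Trimesh
    thickness_nm: float
    faces: np.ndarray  # face indices into the region mesh

    def __iter__(self):
        return iter((self.mesh, self.thickness_nm))


def _smooth_labels(labels: np.ndarray, adjacency: np.ndarray, n_labels: int,
                   n_iter: int = 10) -> np.ndarray:
    """Majority smoothing of face labels over the face-adjacency graph."""
    n = len(labels)
    i, j = adjacency[:, 0], adjacency[:, 1]
    for _ in range(n_iter):
        votes = np.zeros((n, n_labels))
        votes[np.arange(n), labels] += 1.5   # self vote keeps thin regions alive
        np.add.at(votes, i, np.eye(n_labels)[labels[j]])
        np.add.at(votes, j, np.eye(n_labels)[labels[i]])
        new = votes.argmax(axis=1)
        if (new == labels).all():
            break
        labels = new
    return labels


def segment_by_thickness(region_mesh: trimesh.Trimesh,
                         max_components: int = 4,
                         r_max_nm: float = REGION_RADIUS_NM,
                         max_thickness_samples: int = 1500,
                         random_state: int = 0) -> list[ThicknessSegment]:
    """Split a region mesh into edge-connected segments of homogeneous local
    thickness.

    Per-face local thickness is the shrinking-ball shape diameter (the
    diameter of the maximal inscribed ball tangent at the face, equivalent in
    scale to an inward ray-cast chord).  Faces are soft-clustered on log
    thickness with a Gaussian mixture whose component count is selected by
    BIC, labels are majority-smoothed so boundaries fall at thickness
    transitions, and each same-label connected patch becomes one segment.
    """
    if len(region_mesh.faces) == 0:
        raise ValueError("empty region mesh")
    areas = region_mesh.area_faces
    if not np.isfinite(region_mesh.face_normals).all() or (areas <= 0).any():
        raise ValueError("degenerate face normals in region mesh")

    centroids = region_mesh.triangles_center
    # vertex-averaged normals: raw face normals of faceted walls are tilted
    # off the true surface normal, which makes the shrinking ball drift and
    # under-estimate thickness
    fn = region_mesh.vertex_normals[region_mesh.faces].mean(axis=1)
    norms = np.linalg.norm(fn, axis=1, keepdims=True)
    fn = np.where(norms > 1e-12, fn / np.maximum(norms, 1e-12),
                  region_mesh.face_normals)
    n_faces = len(region_mesh.faces)
    if n_faces > max_thickness_samples:
        # evaluate the shrinking ball on a face subsample and interpolate by
        # nearest centroid; thickness varies smoothly at the face scale
        rng = np.random.default_rng(random_state)
        sample = rng.choice(n_faces, size=max_thickness_samples, replace=False)
        t_sample = local_diameter(region_mesh, centroids[sample],
                                  -fn[sample], r_max=r_max_nm)
        from scipy.spatial import cKDTree
        _, nearest = cKDTree(centroids[sample]).query(centroids)
        thickness = t_sample[nearest]
    else:
        thickness = local_diameter(region_mesh, centroids, -fn,
                                   r_max=r_max_nm)
    logt = np.log(np.maximum(thickness, 1.0)).reshape(-1, 1)
    # fit the mixture on genuinely measured values only; interpolated
    # duplicates would inflate the evidence for spurious components
    fit_data = logt if n_faces <= max_thickness_samples else \
        np.log(np.maximum(t_sample, 1.0)).reshape(-1, 1)

    spread = fit_data.std()
    if spread < 0.05 or len(fit_data) < 8:
        labels = np.zeros(len(logt), dtype=int)
        n_comp = 1
    else:
        best, best_bic = None, np.inf
        for k in range(1, max_components + 1):
            gm = GaussianMixture(n_components=k, random_state=random_state,
                                 n_init=2, covariance_type="full")
            gm.fit(fit_data)
            bic = gm.bic(fit_data)
            if bic < best_bic - 1e-9:
                best, best_bic = gm, bic
        # merge components that are not meaningfully different in thickness
        # (< ~1.35x contrast), then relabel by ascending mean
        means = best.means_.ravel()
        order = np.argsort(means)
        merged = np.zeros(len(means), dtype=int)
        group = 0
        for rank_i, ci in enumerate(order):
            if rank_i > 0 and means[ci] - means[order[rank_i - 1]] > 0.30:
                group += 1
            merged[ci] = group
        labels = merged[best.predict(logt)]
        n_comp = group + 1

    adjacency = region_mesh.face_adjacency
    if n_comp > 1 and len(adjacency):
        labels = _smooth_labels(labels, adjacency, n_comp)

    # connected components of same-label faces
    same = labels[adjacency[:, 0]] == labels[adjacency[:, 1]] if len(adjacency) \
        else np.zeros(0, dtype=bool)
    pairs = adjacency[same]
    graph = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
        shape=(n_faces, n_faces))
    _, cc = connected_components(graph, directed=False)
    cc = _merge_small_segments(cc, adjacency, areas, min_area_fraction=0.02)

    segments = []
    for c in np.unique(cc):
        faces = np.flatnonzero(cc == c)
        sub = region_mesh.submesh([faces], append=True)
        mean_t = float(np.average(thickness[faces], weights=areas[faces]))
        segments.append(ThicknessSegment(mesh=sub, thickness_nm=mean_t, faces=faces))
    segments.sort(key=lambda s: -s.mesh.area)
    return segments


def _merge_small_segments(cc: np.ndarray, adjacency: np.ndarray,
                          areas: np.ndarray,
                          min_area_fraction: float) -> np.ndarray:
    """Merge segments below an area fraction into the adjacent segment with
    the longest shared boundary (by adjacent-face-pair count)."""
    cc = cc.copy()
    total = areas.sum()
    while True:
        ids, inv = np.unique(cc, return_inverse=True)
        seg_area = np.bincount(inv, weights=areas)
        order = np.argsort(seg_area)
        merged = False
        a, b = inv[adjacency[:, 0]], inv[adjacency[:, 1]]
        cross = a != b
        for si in order:
            if seg_area[si] >= min_area_fraction * total or len(ids) == 1:
                break
            touch_a = cross & (a == si)
            touch_b = cross & (b == si)
            neighbors = np.concatenate([b[touch_a], a[touch_b]])
            if len(neighbors) == 0:
                continue
            target = np.bincount(neighbors).argmax()
            cc[inv == si] = ids[target]
            merged = True
            break
        if not merged:
            return cc


# ---------------------------------------------------------------------------
# PSS extraction


@dataclass
class PSSExtraction:
    mesh: trimesh.Trimesh
    on_shaft: bool = False
    fallback: bool = False


def extract_pss(region_mesh: trimesh.Trimesh,
                segments: list[ThicknessSegment],
                synapse_location_nm: np.ndarray,
                shaft_thickness_ratio: float = 0.75) -> PSSExtraction:
    """Isolate the postsynaptic shape from a segmented region mesh.

    The local skeleton is approximated by the segment-adjacency graph.  The
    main dendritic shaft is the thickest segment together with adjacent
    segments of comparable thickness; the PSS is the union of segments on the
    synapse side once the shaft is removed (a spine head plus neck), or the
    synapse-bearing shaft stretch / soma patch itself when the synapse sits
    on the shaft.
    """
    if not segments:
        raise ValueError("no segments supplied")
    syn = np.asarray(synapse_location_nm, dtype=float)
    try:
        # segment containing the synapse-nearest face
        best_seg, best_d = 0, np.inf
        for si, seg in enumerate(segments):
            d = np.linalg.norm(seg.mesh.vertices - syn, axis=1).min()
            if d < best_d:
                best_seg, best_d = si, d

        face_to_seg = np.full(len(region_mesh.faces), -1, dtype=int)
        for si, seg in enumerate(segments):
            face_to_seg[seg.faces] = si
        adjacency = region_mesh.face_adjacency
        a, b = face_to_seg[adjacency[:, 0]], face_to_seg[adjacency[:, 1]]
        seg_edges = {(int(x), int(y)) for x, y in zip(a, b) if x != y}

        thick = np.array([s.thickness_nm for s in segments])
        shaft_seed = int(np.argmax(thick))
        shaft = {shaft_seed} | {
            si for si in range(len(segments))
            if thick[si] >= shaft_thickness_ratio * thick[shaft_seed]
            and ((si, shaft_seed) in seg_edges or (shaft_seed, si) in seg_edges)}

        if best_seg in shaft:
            return PSSExtraction(mesh=segments[best_seg].mesh, on_shaft=True)

        # flood fill from the synapse segment without entering the shaft
        component = {best_seg}
        frontier = [best_seg]
        while frontier:
            cur = frontier.pop()
            for (x, y) in seg_edges:
                for nxt in ((y,) if x == cur else (x,) if y == cur else ()):
                    if nxt not in shaft and nxt not in component:
                        component.add(nxt)
                        frontier.append(nxt)
        faces = np.concatenate([segments[si].faces for si in sorted(component)])
        mesh = region_mesh.submesh([faces], append=True)
        return PSSExtraction(mesh=mesh, on_shaft=False)
    except Exception:
        return PSSExtraction(mesh=segments[best_seg].mesh, fallback=True)


# ---------------------------------------------------------------------------
# pose normalization


def normalize_pose(pss_mesh: trimesh.Trimesh, n_points: int = 1024,
                   seed: int = 0) -> np.ndarray:
    """Surface-uniform point sample in a canonical pose.

    The cloud is centred, rotated into its principal axes (largest variance
    first) with signs fixed by the third moment along each axis (falling back
    to the extremal coordinate for near-symmetric shapes), and made
    right-handed.  Scale is preserved.  The canonical cloud is invariant to
    rigid rotations of the input.
    """
    if pss_mesh.is_empty or pss_mesh.area <= 0:
        raise ValueError("degenerate mesh")
    rng = np.random.default_rng(seed)
    pts = sample_surface(pss_mesh, n_points, rng)
    pts = pts - pts.mean(axis=0)
    cov = pts.T @ pts / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evecs = evecs[:, order]
    proj = pts @ evecs
    for ax in range(3):
        x = proj[:, ax]
        skew = (x ** 3).mean()
        scale = (x ** 2).mean() ** 1.5
        if scale > 0 and abs(skew) > 1e-3 * scale:
            s = np.sign(skew)
        else:
            s = np.sign(x.max() + x.min()) or 1.0
        proj[:, ax] *= s
        evecs[:, ax] *= s
    if np.linalg.det(evecs) < 0:
        proj[:, 2] *= -1.0
    return proj


# ---------------------------------------------------------------------------
# encoders


class DeterministicShapeEncoder:
    """Classical shape descriptor padded to the latent size.

    Deterministic drop-in for the learned encoder: per-axis scale/skewness/
    kurtosis in the canonical frame, covariance spectrum, radial distance
    statistics and a radial histogram.  Shape-discriminative and scale-aware,
    which is all the dictionary semantics require.
    """

    def __init__(self, latent_size: int = LATENT_SIZE):
        if latent_size <= 0:
            raise ValueError("latent_size must be positive")
        self.latent_size = latent_size

    def encode(self, cloud: np.ndarray) -> np.ndarray:
        x = np.asarray(cloud, dtype=float)
        if x.ndim != 2 or x.shape[1] != 3:
            raise ValueError("cloud must be (n, 3)")
        c = x - x.mean(axis=0)
        std = c.std(axis=0)
        safe = np.where(std > 0, std, 1.0)
        z = c / safe
        r = np.linalg.norm(c, axis=1)
        cov = c.T @ c / len(c)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        hist, _ = np.histogram(r, bins=16, range=(0.0, max(r.max(), 1.0)))
        feats = np.concatenate([
            std,                                  # 3  absolute scale
            (z ** 3).mean(axis=0),                # 3  skewness
            (z ** 4).mean(axis=0),                # 3  kurtosis
            [(z[:, 0] * z[:, 1]).mean(), (z[:, 0] * z[:, 2]).mean(),
             (z[:, 1] * z[:, 2]).mean()],         # 3  cross moments
            evals,                                # 3  covariance spectrum
            np.sqrt(np.maximum(evals, 0)),        # 3
            [r.mean(), r.std(), np.median(r)],    # 3
            np.percentile(r, [5, 25, 75, 95]),    # 4
            hist / len(c),                        # 16
        ])
        out = np.zeros(self.latent_size)
        out[:len(feats)] = feats
        return out

    def encode_many(self, clouds) -> np.ndarray:
        return np.array([self.encode(c) for c in clouds])


class PointCloudAutoencoder:
    """Small point-cloud autoencoder (numpy).

    Encoder: per-point MLP (3 -> hidden, tanh) followed by max-pooling over
    points and a linear map to the latent size.  Decoder: latent -> hidden
    (tanh) -> n_points x 3.  Trained with Adam on an L2 loss between decoded
    points and their nearest target points (correspondences refreshed every
    epoch).  Fully deterministic under the seed.
    """

    def __init__(self, latent_size: int = LATENT_SIZE, hidden: int = 64,
                 n_points: int = 64, lr: float = 3e-3, seed: int = 0):
        if latent_size <= 0:
            raise ValueError("latent_size must be positive")
        self.latent_size = latent_size
        self.hidden = hidden
        self.n_points = n_points
        self.lr = lr
        self.seed = seed
        self.loss_history_: list[float] = []
        self._params = None
        self._scale = 1.0

    # -- parameter handling

    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        h, L, m = self.hidden, self.latent_size, self.n_points
        def g(*shape, s):
            return rng.normal(0, s, size=shape)
        return {
            "W1": g(3, h, s=0.5), "b1": np.zeros(h),
            "W2": g(h, L, s=1.0 / np.sqrt(h)),
            "W3": g(L, h, s=1.0 / np.sqrt(L)), "b3": np.zeros(h),
            "W4": g(h, 3 * m, s=1.0 / np.sqrt(h)),
        }

    def _resample(self, cloud: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        n = len(cloud)
        if n == self.n_points:
            return cloud
        idx = rng.choice(n, size=self.n_points, replace=n < self.n_points)
        return cloud[idx]

    def fit(self, clouds, epochs: int = 60) -> "PointCloudAutoencoder":
        if len(clouds) < 2:
            raise ValueError("need at least 2 clouds to train")
        rng = np.random.default_rng(self.seed)
        X = np.stack([self._resample(np.asarray(c, dtype=float), rng)
                      for c in clouds])                       # (B, m, 3)
        self._scale = float(np.abs(X).max()) or 1.0
        X = X / self._scale
        p = self._params = self._init_params(rng)
        adam = {k: [np.zeros_like(v), np.zeros_like(v)] for k, v in p.items()}
        b1a, b2a, eps = 0.9, 0.999, 1e-8
        B, m, _ = X.shape
        t = 0
        self.loss_history_ = []
        for _ in range(epochs):
            # forward
            H = np.tanh(X @ p["W1"] + p["b1"])                # (B, m, h)
            arg = H.argmax(axis=1)                            # (B, h)
            G = np.take_along_axis(H, arg[:, None, :], axis=1)[:, 0, :]
            Z = G @ p["W2"]                                   # (B, L)
            D = np.tanh(Z @ p["W3"] + p["b3"])                # (B, h)
            Y = (D @ p["W4"]).reshape(B, m, 3)
            # nearest-target correspondence, refreshed each epoch
            d2 = ((Y[:, :, None, :] - X[:, None, :, :]) ** 2).sum(-1)  # (B,m,m)
            match = d2.argmin(axis=2)
            T = np.take_along_axis(X, match[:, :, None], axis=1)
            diff = Y - T
            loss = float((diff ** 2).mean())
            self.loss_history_.append(loss)
            # backward
            gY = (2.0 / diff.size) * diff
            gW4 = np.einsum("bh,bmc->hmc", D, gY.reshape(B, m * 3).reshape(B, m, 3))
            gW4 = np.einsum("bh,bk->hk", D, gY.reshape(B, 3 * m))
            gD = gY.reshape(B, 3 * m) @ p["W4"].T
            gpre = gD * (1 - D ** 2)
            gW3 = Z.T @ gpre
            gb3 = gpre.sum(axis=0)
            gZ = gpre @ p["W3"].T
            gW2 = G.T @ gZ
            gG = gZ @ p["W2"].T                               # (B, h)
            gH = np.zeros_like(H)
            np.put_along_axis(gH, arg[:, None, :], gG[:, None, :], axis=1)
            gpre1 = gH * (1 - H ** 2)
            gW1 = np.einsum("bmi,bmh->ih", X, gpre1)
            gb1 = gpre1.sum(axis=(0, 1))
            grads = {"W1": gW1, "b1": gb1, "W2": gW2, "W3": gW3,
                     "b3": gb3, "W4": gW4}
            t += 1
            for k, v in p.items():
                mom, vel = adam[k]
                gk = grads[k]
                mom[:] = b1a * mom + (1 - b1a) * gk
                vel[:] = b2a * vel + (1 - b2a) * gk * gk
                mhat = mom / (1 - b1a ** t)
                vhat = vel / (1 - b2a ** t)
                v -= self.lr * mhat / (np.sqrt(vhat) + eps)
        return self

    def encode(self, cloud: np.ndarray) -> np.ndarray:
        if self._params is None:
            raise RuntimeError("autoencoder is not fitted")
        x = np.asarray(cloud, dtype=float) / self._scale
        H = np.tanh(x @ self._params["W1"] + self._params["b1"])
        return H.max(axis=0) @ self._params["W2"]

    def encode_many(self, clouds) -> np.ndarray:
        return np.array([self.encode(c) for c in clouds])


def train_autoencoder(point_clouds, latent_size: int = LATENT_SIZE,
                      epochs: int = 60, seed: int = 0) -> PointCloudAutoencoder:
    """Train the point-cloud autoencoder on a corpus of canonical clouds."""
    ae = PointCloudAutoencoder(latent_size=latent_size, seed=seed)
    return ae.fit(point_clouds, epochs=epochs)


# ---------------------------------------------------------------------------
# dictionary and histogram


@dataclass
class ShapeDictionary:
    """k-means shape dictionary in latent space."""

    centres: np.ndarray                  # (k, latent)
    ordering: np.ndarray                 # display permutation
    trained_on: str = ""

    @property
    def k(self) -> int:
        return len(self.centres)

    def assign(self, latents: np.ndarray) -> np.ndarray:
        """Nearest centre by Euclidean distance; ties break to lowest index."""
        latents = np.atleast_2d(np.asarray(latents, dtype=float))
        d2 = ((latents[:, None, :] - self.centres[None, :, :]) ** 2).sum(-1)
        return d2.argmin(axis=1)


def build_dictionary(latents: np.ndarray, k: int = DICTIONARY_K,
                     seed: int = 0, trained_on: str = "") -> ShapeDictionary:
    """Cluster latent vectors with k-means (k-means++ init, 50 restarts)."""
    latents = np.asarray(latents, dtype=float)
    distinct = np.unique(latents, axis=0)
    if len(distinct) < k:
        raise ValueError(f"need at least {k} distinct latents, got {len(distinct)}")
    km = KMeans(n_clusters=k, n_init=50, random_state=seed)
    km.fit(latents)
    # stable display order: by decreasing cluster population, then centre norm
    _, counts = np.unique(km.labels_, return_counts=True)
    ordering = np.argsort(-counts, kind="stable")
    return ShapeDictionary(centres=km.cluster_centers_.copy(),
                           ordering=ordering, trained_on=trained_on)


@dataclass
class PSSDescriptor:
    """One extracted postsynaptic shape."""

    synapse_id: int
    mesh: trimesh.Trimesh | None
    latent: np.ndarray
    cluster: int
    distance_to_nucleus_um: float


@dataclass
class SpatialShapeHistogram:
    """Shape x radial-bin count matrix and its flattened 120-D form."""

    counts: np.ndarray                       # (k, n_bins) of ints
    edges_um: tuple = RADIAL_EDGES_UM
    standardized: np.ndarray | None = None

    @property
    def flattened(self) -> np.ndarray:
        return self.counts.reshape(-1)


def spatial_histogram(pss_list: list[PSSDescriptor],
                      dictionary: ShapeDictionary,
                      edges_um: tuple = RADIAL_EDGES_UM) -> SpatialShapeHistogram:
    """Bin PSS descriptors by shape cluster and radial distance.

    Radial bins are half-open [lo, hi) except the last, which is closed.
    The histogram conserves counts: the total equals the number of PSSs.
    """
    edges = np.asarray(edges_um, dtype=float)
    n_bins = len(edges) - 1
    counts = np.zeros((dictionary.k, n_bins), dtype=int)
    for pss in pss_list:
        d = pss.distance_to_nucleus_um
        if d < edges[0] or d > edges[-1]:
            raise ValueError(
                f"synapse {pss.synapse_id}: distance {d:.1f} um outside radial range")
        b = min(int(np.searchsorted(edges, d, side="right")) - 1, n_bins - 1)
        if not 0 <= pss.cluster < dictionary.k:
            raise ValueError(f"cluster {pss.cluster} outside the dictionary")
        counts[pss.cluster, b] += 1
    return SpatialShapeHistogram(counts=counts, edges_um=tuple(edges))


# ---------------------------------------------------------------------------
# per-cell convenience pipeline


def describe_synapses(cell_surface: trimesh.Trimesh,
                      synapse_locations_nm: np.ndarray,
                      nucleus_centroid_nm: np.ndarray,
                      encoder,
                      dictionary: ShapeDictionary | None = None,
                      n_points: int = 256,
                      seed: int = 0) -> list[PSSDescriptor]:
    """Extract, embed and (optionally) cluster the PSS of each synapse."""
    out = []
    centroid = np.asarray(nucleus_centroid_nm, dtype=float)
    for sid, loc in enumerate(np.atleast_2d(synapse_locations_nm)):
        d_um = float(np.linalg.norm(np.asarray(loc) - centroid)) / 1000.0
        if d_um > PSS_MAX_RADIUS_UM:
            continue
        region = synapse_region_mesh(cell_surface, loc)
        segments = segment_by_thickness(region)
        pss = extract_pss(region, segments, loc)
        cloud = normalize_pose(pss.mesh, n_points=n_points, seed=seed)
        latent = encoder.encode(cloud)
        cluster = int(dictionary.assign(latent)[0]) if dictionary is not None else -1
        out.append(PSSDescriptor(synapse_id=sid, mesh=pss.mesh, latent=latent,
                                 cluster=cluster, distance_to_nucleus_um=d_um))
    return out
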