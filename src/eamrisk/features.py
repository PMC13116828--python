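"""Derived substrate features from a projected map.

Four scalar substrate parameters plus their per-region analogues:

* **GR** — activation-gradient value.  For each point, the maximum
  |ΔLAT| / distance (ms/mm) over neighbors within a Euclidean radius; high
  values mark conduction deceleration zones.  The scalar summary is a high
  percentile of the per-point values, the regional value is the regional max.
* **VLT** — extent of clustered critical bipolar–unipolar discrepancy, a
  surrogate for intramural substrate.  The per-face difference d = bip − uni
  is thresholded at the top 20 % of its range; critical faces are clustered
  by face adjacency and clusters of at least ``min_cluster`` faces count.
* **LAT** — late-potential extent: faces in the latest 20 % of the LAT
  range, clustered the same way, expressed relative to the non-late faces.
* **Scar Areas** — clustered extent of faces with bipolar voltage below the
  dense-scar cutoff (0.5 mV), relative to all occupied faces.

plus **IMP1..IMP8**, the mean impedance per region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io import EamExport
from .sphere import FaceValueMap, SphereModel, canonical_orientation, project_points

__all__ = [
    "FeatureParams",
    "GradientResult",
    "FeatureVector",
    "gradient_value",
    "vlt_extent",
    "late_extent",
    "scar_extent",
    "regional_impedance",
    "extract_features",
]

N_REGIONS = 8


@dataclass(frozen=True)
class FeatureParams:
    """Tunable feature parameters (units in field names where applicable)."""

    gr_radius_mm: float = 7.0           # neighbor radius for the gradient
    gr_percentile: float = 95.0         # scalar summary of per-point gradients
    gr_min_distance_mm: float = 0.1     # pairs closer than this are skipped
    min_cluster: int = 3                # faces needed for a cluster to count
    cluster_angle_deg: float | None = 8.0  # cluster-adjacency neighborhood (None: edge)
    scar_threshold_mv: float = 0.5      # dense-scar bipolar cutoff
    reference_rms_radius_mm: float = 35.0  # size normalization before GR
    vlt_signed: bool = True             # signed bip-uni difference (False: |.|)
    late_direction: str = "latest"      # or "earliest"
    late_denominator: str = "non_late"  # or "total"
    frame: str = "data"                 # canonical frame mode


@dataclass
class GradientResult:
    per_point: np.ndarray
    scalar: float
    regional: np.ndarray | None = None


def gradient_value(
    positions: np.ndarray,
    lat: np.ndarray,
    radius: float = 7.0,
    *,
    min_distance: float = 0.1,
    percentile: float = 95.0,
    regions: np.ndarray | None = None,
) -> GradientResult:
    """Per-point maximum |ΔLAT| / distance over neighbors within `radius` mm.

    Pairs closer than ``min_distance`` are skipped (never divided by).  The
    scalar summary is the given percentile of per-point values; if a region
    index (1..8, or <=0 for unassigned) is supplied per point, the regional
    value is the maximum per-point gradient within each region (NaN when a
    region holds no points).
    """
    positions = np.asarray(positions, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if len(positions) < 2:
        raise ValueError("gradient requires at least 2 points")
    if radius <= 0:
        raise ValueError("radius must be positive")
    tree = cKDTree(positions)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    per_point = np.zeros(len(positions))
    if len(pairs):
        d = np.linalg.norm(positions[pairs[:, 0]] - positions[pairs[:, 1]], axis=1)
        ok = d >= min_distance
        pairs, d = pairs[ok], d[ok]
        if len(pairs):
            g = np.abs(lat[pairs[:, 0]] - lat[pairs[:, 1]]) / d
            np.maximum.at(per_point, pairs[:, 0], g)
            np.maximum.at(per_point, pairs[:, 1], g)
    scalar = float(np.percentile(per_point, percentile))
    regional = None
    if regions is not None:
        regions = np.asarray(regions)
        regional = np.full(N_REGIONS, np.nan)
        for r in range(1, N_REGIONS + 1):
            m = regions == r
            if m.any():
                regional[r - 1] = per_point[m].max()
    return GradientResult(per_point=per_point, scalar=scalar, regional=regional)


def _face_clusters(
    sphere: SphereModel, faces: np.ndarray, angle_deg: float | None = 8.0
) -> list[list[int]]:
    """Connected components of a face subset.

    Occupied faces are sparse on the grid (the tessellation holds at most one
    projected point per face), so "adjacent" points rarely occupy
    edge-sharing faces.  Two faces are therefore connected when their center
    directions are within ``angle_deg`` geodesically (default 8°, about 5 mm
    on the 35 mm reference chamber); ``angle_deg=None`` restores literal
    edge-adjacency on the grid.
    """
    faces = np.asarray(faces, dtype=int)
    if len(faces) == 0:
        return []
    if angle_deg is None:
        pending = set(int(f) for f in faces)
        clusters: list[list[int]] = []
        while pending:
            seed = pending.pop()
            comp, frontier = [seed], [seed]
            while frontier:
                f = frontier.pop()
                for nb in sphere.neighbors(f):
                    if nb in pending:
                        pending.discard(nb)
                        comp.append(nb)
                        frontier.append(nb)
            clusters.append(sorted(comp))
        return clusters
    centers = sphere.face_centers[faces]
    adj = centers @ centers.T >= np.cos(np.deg2rad(angle_deg)) - 1e-12
    n = len(faces)
    seen = np.zeros(n, dtype=bool)
    clusters = []
    for start in range(n):
        if seen[start]:
            continue
        comp_idx, frontier = [start], [start]
        seen[start] = True
        while frontier:
            i = frontier.pop()
            for j in np.flatnonzero(adj[i] & ~seen):
                seen[j] = True
                comp_idx.append(j)
                frontier.append(j)
        clusters.append(sorted(int(faces[i]) for i in comp_idx))
    return clusters


def _clustered_faces(
    sphere: SphereModel, faces: np.ndarray, min_cluster: int, angle_deg: float | None
) -> np.ndarray:
    kept: list[int] = []
    for comp in _face_clusters(sphere, faces, angle_deg):
        if len(comp) >= min_cluster:
            kept.extend(comp)
    return np.array(sorted(kept), dtype=int)


def _regional_extent(
    sphere: SphereModel,
    counted: np.ndarray,
    denominator_faces: np.ndarray,
) -> np.ndarray:
    """Per-region 100 * |counted ∩ region| / |denominator ∩ region|."""
    out = np.full(N_REGIONS, np.nan)
    reg_counted = sphere.region_of_face[counted] if len(counted) else np.empty(0, int)
    reg_denom = sphere.region_of_face[denominator_faces] if len(denominator_faces) else np.empty(0, int)
    for r in range(1, N_REGIONS + 1):
        denom = int((reg_denom == r).sum())
        if denom > 0:
            out[r - 1] = 100.0 * int((reg_counted == r).sum()) / denom
    return out


def _undefined(name: str) -> tuple[float, np.ndarray]:
    warnings.warn(f"{name}: fewer than 2 occupied faces; extent undefined", stacklevel=3)
    return float("nan"), np.full(N_REGIONS, np.nan)


def vlt_extent(
    face_map: FaceValueMap,
    sphere: SphereModel,
    min_cluster: int = 3,
    signed: bool = True,
    cluster_angle_deg: float | None = 8.0,
) -> tuple[float, np.ndarray]:
    """Extent of clustered critical bipolar–unipolar discrepancy, percent.

    d = bip − uni per occupied face (or |bip − uni| with ``signed=False``);
    faces with d strictly above min(d) + 0.8·range(d) are critical.  With the
    signed difference the top of the range is the tissue whose unipolar
    voltage is depressed relative to its bipolar voltage — the intramural
    substrate signature.  Critical faces are clustered by adjacency; clusters
    of at least ``min_cluster`` faces count toward the extent, globally and
    per region (denominator: occupied faces, resp. occupied faces in region).
    """
    if face_map.n_occupied < 2:
        return _undefined("vlt_extent")
    d = face_map.channel("bip_v") - face_map.channel("uni_v")
    if not signed:
        d = np.abs(d)
    lo, hi = float(d.min()), float(d.max())
    thr = lo + 0.8 * (hi - lo)
    critical = face_map.faces[d > thr]
    counted = _clustered_faces(sphere, critical, min_cluster, cluster_angle_deg)
    scalar = 100.0 * len(counted) / face_map.n_occupied
    return scalar, _regional_extent(sphere, counted, face_map.faces)


def late_extent(
    face_map: FaceValueMap,
    sphere: SphereModel,
    min_cluster: int = 3,
    direction: str = "latest",
    denominator: str = "non_late",
    cluster_angle_deg: float | None = 8.0,
) -> tuple[float, np.ndarray]:
    """Late-potential extent, percent.

    Late faces are those in the extreme 20 % of the LAT range — by default the
    latest (LAT strictly above min + 0.8·range); ``direction="earliest"``
    selects the literal other reading.  Clustered as in :func:`vlt_extent`.
    The default denominator is the number of non-late faces, so the extent can
    exceed 100; ``denominator="total"`` uses all occupied faces instead.
    """
    if face_map.n_occupied < 2:
        return _undefined("late_extent")
    lat = face_map.channel("lat")
    lo, hi = float(lat.min()), float(lat.max())
    rng = hi - lo
    if direction == "latest":
        is_late = lat > lo + 0.8 * rng
    elif direction == "earliest":
        is_late = lat < lo + 0.2 * rng
    else:
        raise ValueError(f"unknown direction {direction!r}")
    late_faces = face_map.faces[is_late]
    counted = _clustered_faces(sphere, late_faces, min_cluster, cluster_angle_deg)
    if denominator == "non_late":
        denom_faces = face_map.faces[~is_late]
    elif denominator == "total":
        denom_faces = face_map.faces
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    scalar = 100.0 * len(counted) / len(denom_faces) if len(denom_faces) else float("nan")
    return scalar, _regional_extent(sphere, counted, denom_faces)


def scar_extent(
    face_map: FaceValueMap,
    sphere: SphereModel,
    threshold: float = 0.5,
    min_cluster: int = 3,
    cluster_angle_deg: float | None = 8.0,
) -> tuple[float, np.ndarray]:
    """Extent of clustered low-amplitude (dense scar) faces, percent.

    Faces with bipolar voltage strictly below ``threshold`` (mV) are scar
    candidates; adjacency clusters of at least ``min_cluster`` faces count.
    Denominator: occupied faces (per region for the regional values).
    """
    if face_map.n_occupied < 2:
        return _undefined("scar_extent")
    low = face_map.faces[face_map.channel("bip_v") < threshold]
    counted = _clustered_faces(sphere, low, min_cluster, cluster_angle_deg)
    scalar = 100.0 * len(counted) / face_map.n_occupied
    return scalar, _regional_extent(sphere, counted, face_map.faces)


def regional_impedance(face_map: FaceValueMap, sphere: SphereModel) -> np.ndarray:
    """Mean impedance (Ω) of occupied faces per region; NaN when empty."""
    out = np.full(N_REGIONS, np.nan)
    regions = sphere.region_of_face[face_map.faces]
    imp = face_map.channel("imp")
    for r in range(1, N_REGIONS + 1):
        m = regions == r
        if m.any():
            out[r - 1] = float(imp[m].mean())
    return out


@dataclass
class FeatureVector:
    """Per-patient substrate features (global scalars + per-region vectors)."""

    gr: float
    vlt: float
    lat: float
    scar: float
    gr_regional: np.ndarray
    vlt_regional: np.ndarray
    lat_regional: np.ndarray
    scar_regional: np.ndarray
    imp_regional: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    @staticmethod
    def columns() -> list[str]:
        cols = ["GR", "VLT", "LAT", "ScarAreas"]
        for fam in ("GR", "VLT", "LAT", "Scar", "IMP"):
            cols.extend(f"{fam}{r}" for r in range(1, N_REGIONS + 1))
        return cols

    def as_dict(self) -> dict[str, float]:
        out = {"GR": self.gr, "VLT": self.vlt, "LAT": self.lat, "ScarAreas": self.scar}
        for fam, vec in (
            ("GR", self.gr_regional),
            ("VLT", self.vlt_regional),
            ("LAT", self.lat_regional),
            ("Scar", self.scar_regional),
            ("IMP", self.imp_regional),
        ):
            for r in range(N_REGIONS):
                out[f"{fam}{r + 1}"] = float(vec[r])
        return out

    def as_array(self) -> np.ndarray:
        d = self.as_dict()
        return np.array([d[c] for c in self.columns()])


def extract_features(
    export: EamExport,
    sphere: SphereModel,
    params: FeatureParams | None = None,
) -> FeatureVector:
    """Full feature pipeline for one export.

    Orientation-canonicalizes the cloud, projects it onto the sphere, and
    computes all substrate features.  Before the gradient computation the
    cloud is rescaled so its RMS centroid distance equals the reference
    chamber scale, making every feature invariant to rigid motion and uniform
    scaling of the input while keeping gradients in ms/mm of the reference
    chamber.
    """
    p = params or FeatureParams()
    canon = canonical_orientation(export, frame=p.frame)
    face_map = project_points(canon, sphere)

    pos = canon.positions()  # already centered on the centroid
    rms = float(np.sqrt((np.linalg.norm(pos, axis=1) ** 2).mean()))
    scale = p.reference_rms_radius_mm / rms if rms > 0 else 1.0
    point_regions = np.where(
        face_map.point_faces >= 0,
        sphere.region_of_face[np.maximum(face_map.point_faces, 0)],
        0,
    )
    gr = gradient_value(
        pos * scale,
        canon.channel("lat"),
        radius=p.gr_radius_mm,
        min_distance=p.gr_min_distance_mm,
        percentile=p.gr_percentile,
        regions=point_regions,
    )
    vlt, vlt_r = vlt_extent(
        face_map, sphere, min_cluster=p.min_cluster, signed=p.vlt_signed,
        cluster_angle_deg=p.cluster_angle_deg,
    )
    lat, lat_r = late_extent(
        face_map, sphere, min_cluster=p.min_cluster,
        direction=p.late_direction, denominator=p.late_denominator,
        cluster_angle_deg=p.cluster_angle_deg,
    )
    scar, scar_r = scar_extent(
        face_map, sphere, threshold=p.scar_threshold_mv, min_cluster=p.min_cluster,
        cluster_angle_deg=p.cluster_angle_deg,
    )
    imp_r = regional_impedance(face_map, sphere)
    return FeatureVector(
        gr=gr.scalar, vlt=vlt, lat=lat, scar=scar,
        gr_regional=gr.regional,
        vlt_regional=vlt_r, lat_regional=lat_r, scar_regional=scar_r,
        imp_regional=imp_r,
        diagnostics={
            "n_collisions": face_map.n_collisions,
            "n_dropped": face_map.n_dropped,
            "n_occupied": face_map.n_occupied,
            "scale": scale,
        },
    )
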