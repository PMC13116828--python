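"""Spatial normalization: equal-area spherical tessellation and projection.

Chamber point clouds from different patients differ in size, position and
orientation.  To compare them, each cloud is projected from its centroid onto
a fixed sphere whose surface is divided into 14,400 equal-area faces, and the
sphere is partitioned into 8 regions carrying nominal anatomical labels.

The tessellation is the cylindrical equal-area grid: ``n_lon`` longitude
sectors of equal angular width crossed with ``n_bands`` latitude bands of
equal height in z.  By Archimedes' hat-box theorem every band has the same
area, so all faces are exactly equal-area, and face lookup from a direction
is O(1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import EamExport, MapPoint

__all__ = [
    "REGION_LABELS",
    "DEFAULT_OCTANT_TABLE",
    "SphereModel",
    "FaceValueMap",
    "build_sphere",
    "project_points",
    "canonical_orientation",
    "region_of",
]

#: Nominal anatomical label of each region index.  Regions are geometric
#: octants of the canonical frame; the labels name the macro-projection zones
#: they stand for and can be remapped via the octant table.
REGION_LABELS: dict[int, str] = {
    1: "anterior sub-mitral",
    2: "posterior mid-apical",
    3: "antero-septal mitro-aortic valvular",
    4: "postero-septal mid-apical",
    5: "antero-lateral sub-valvular mitro-aortic",
    6: "postero-lateral mid-basal",
    7: "antero-lateral mid-basal",
    8: "apical and infero-apical mid-apical",
}

#: Sign triple (sx, sy, sz) of the face-center direction -> region index.
#: Odd indices sit in the basal half-space (+z), even in the apical one.
DEFAULT_OCTANT_TABLE: dict[tuple[int, int, int], int] = {
    (1, 1, 1): 1,
    (1, 1, -1): 2,
    (-1, 1, 1): 3,
    (-1, 1, -1): 4,
    (1, -1, 1): 5,
    (1, -1, -1): 6,
    (-1, -1, 1): 7,
    (-1, -1, -1): 8,
}


@dataclass
class SphereModel:
    """Fixed sphere with an equal-area band/sector tessellation.

    Face ``i`` is the cell at band ``i // n_lon`` (z increasing) and
    longitude sector ``i % n_lon``.
    """

    n_bands: int
    n_lon: int
    radius: float
    face_centers: np.ndarray      # (n_faces, 3) unit directions
    region_of_face: np.ndarray    # (n_faces,) region index 1..8
    octant_table: dict[tuple[int, int, int], int]

    @property
    def n_faces(self) -> int:
        return self.n_bands * self.n_lon

    @property
    def face_area(self) -> float:
        """Common face area, steradians x radius^2."""
        return 4.0 * np.pi * self.radius**2 / self.n_faces

    def face_areas(self) -> np.ndarray:
        """Per-face spherical areas computed from the cell boundaries."""
        z_edges = np.linspace(-1.0, 1.0, self.n_bands + 1)
        dz = np.diff(z_edges)
        dphi = 2.0 * np.pi / self.n_lon
        per_band = dz * dphi * self.radius**2
        return np.repeat(per_band, self.n_lon)

    def face_of_directions(self, dirs: np.ndarray) -> np.ndarray:
        """Face index containing each unit direction; vectorized."""
        dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
        z = np.clip(dirs[:, 2] / np.linalg.norm(dirs, axis=1), -1.0, 1.0)
        band = np.minimum(((z + 1.0) * 0.5 * self.n_bands).astype(int), self.n_bands - 1)
        phi = np.mod(np.arctan2(dirs[:, 1], dirs[:, 0]), 2.0 * np.pi)
        lon = np.minimum((phi / (2.0 * np.pi) * self.n_lon).astype(int), self.n_lon - 1)
        return band * self.n_lon + lon

    def neighbors(self, face: int) -> tuple[int, ...]:
        """Edge-sharing neighbors: longitude wrap-around plus band neighbors."""
        if not 0 <= face < self.n_faces:
            raise IndexError(f"face index {face} out of range")
        b, l = divmod(face, self.n_lon)
        out = [b * self.n_lon + (l - 1) % self.n_lon,
               b * self.n_lon + (l + 1) % self.n_lon]
        if b > 0:
            out.append((b - 1) * self.n_lon + l)
        if b < self.n_bands - 1:
            out.append((b + 1) * self.n_lon + l)
        return tuple(out)


@dataclass
class FaceValueMap:
    """Sparse per-face channel values produced by projecting one export.

    At most one source point occupies a face; collisions are resolved by
    keeping the point whose direction is closest to the face center, and the
    number of discarded points is reported in ``n_collisions``.
    """

    faces: np.ndarray                 # sorted occupied face indices
    point_index: np.ndarray           # winning source-point index per face
    values: dict[str, np.ndarray]     # channel -> values aligned with `faces`
    point_faces: np.ndarray           # face index of every source point (-1 dropped)
    n_collisions: int = 0
    n_dropped: int = 0

    @property
    def n_occupied(self) -> int:
        return len(self.faces)

    def channel(self, name: str) -> np.ndarray:
        return self.values[name]


def build_sphere(
    n_bands: int = 120,
    n_lon: int = 120,
    radius: float = 1.0,
    octant_table: dict[tuple[int, int, int], int] | None = None,
) -> SphereModel:
    """Build the tessellated sphere (defaults: 120 x 120 = 14,400 faces)."""
    if n_bands <= 0 or n_lon <= 0:
        raise ValueError("n_bands and n_lon must be positive")
    if radius <= 0:
        raise ValueError("radius must be positive")
    table = dict(octant_table) if octant_table is not None else dict(DEFAULT_OCTANT_TABLE)
    if sorted(table.values()) != list(range(1, 9)):
        raise ValueError("octant table must be a bijection onto region indices 1..8")

    z_centers = -1.0 + (2.0 * np.arange(n_bands) + 1.0) / n_bands
    phi_centers = (2.0 * np.pi) * (np.arange(n_lon) + 0.5) / n_lon
    zz = np.repeat(z_centers, n_lon)
    pp = np.tile(phi_centers, n_bands)
    rho = np.sqrt(np.maximum(0.0, 1.0 - zz**2))
    centers = np.column_stack([rho * np.cos(pp), rho * np.sin(pp), zz])

    signs = np.sign(centers).astype(int)
    signs[signs == 0] = 1  # centers never lie exactly on a coordinate plane at even counts
    regions = np.fromiter(
        (table[(sx, sy, sz)] for sx, sy, sz in signs), dtype=int, count=len(signs)
    )
    return SphereModel(
        n_bands=n_bands,
        n_lon=n_lon,
        radius=radius,
        face_centers=centers,
        region_of_face=regions,
        octant_table=table,
    )


def region_of(face_index: int, sphere: SphereModel) -> int:
    """Region index 1..8 of a face."""
    if not 0 <= face_index < sphere.n_faces:
        raise IndexError(f"face index {face_index} out of range")
    return int(sphere.region_of_face[face_index])


def project_points(export: EamExport, sphere: SphereModel) -> FaceValueMap:
    """Project every point from the cloud centroid onto the sphere.

    The centroid is the arithmetic mean of point positions; each point is
    assigned to the face containing its centroid-to-point direction and its
    channels are carried to that face.
    """
    pos = export.positions()
    if len(pos) < 4:
        raise ValueError("projection requires at least 4 points")
    centroid = pos.mean(axis=0)
    vec = pos - centroid
    norms = np.linalg.norm(vec, axis=1)
    valid = norms > 1e-9
    if not valid.any():
        raise ValueError("all points coincide with the centroid; cannot project")
    n_dropped = int((~valid).sum())

    dirs = vec[valid] / norms[valid, None]
    faces_all = np.full(len(pos), -1, dtype=int)
    faces_all[valid] = sphere.face_of_directions(dirs)

    idx_valid = np.flatnonzero(valid)
    face_of_valid = faces_all[idx_valid]
    dots = np.einsum("ij,ij->i", dirs, sphere.face_centers[face_of_valid])
    # keep, per face, the point whose direction is closest to the face center
    order = np.lexsort((-dots, face_of_valid))
    ordered_faces = face_of_valid[order]
    first = np.ones(len(order), dtype=bool)
    first[1:] = ordered_faces[1:] != ordered_faces[:-1]
    winners = idx_valid[order[first]]
    faces = ordered_faces[first]
    n_collisions = int(len(idx_valid) - len(winners))
    if n_collisions:
        warnings.warn(
            f"{n_collisions} point(s) collided with an already-occupied face and were discarded",
            stacklevel=2,
        )

    values = {
        ch: export.channel(ch)[winners] for ch in ("uni_v", "bip_v", "lat", "imp")
    }
    return FaceValueMap(
        faces=faces,
        point_index=winners,
        values=values,
        point_faces=faces_all,
        n_collisions=n_collisions,
        n_dropped=n_dropped,
    )


def _signed_axis(axis: np.ndarray, coords: np.ndarray, weight: np.ndarray) -> np.ndarray:
    """Orient `axis` toward the half-space with larger weighted coordinate.

    `coords` are centered positions; the sign is chosen so the covariance of
    the (centered) weight channel with the axis coordinate is non-negative.
    Exact ties (e.g. a constant channel) fall back to making the largest-
    magnitude component of the axis positive, which is deterministic.
    """
    w = weight - weight.mean()
    score = float(w @ (coords @ axis))
    if score > 0:
        return axis
    if score < 0:
        return -axis
    k = int(np.argmax(np.abs(axis)))
    return axis if axis[k] > 0 else -axis


def canonical_orientation(export: EamExport, frame: str = "data") -> EamExport:
    """Rotate the cloud into a canonical frame so patients are comparable.

    ``frame="data"`` (default): principal axes of the centered cloud, long
    axis to z and second axis to x, with data-driven sign conventions — z
    toward the hemisphere of latest mean activation (apex proxy), x toward
    higher mean unipolar voltage — and y = z × x, so the rotation is always
    proper (determinant +1; no reflection).  ``frame="fixed"`` keeps the
    acquisition frame (translation to the centroid only).
    """
    pos = export.positions()
    if len(pos) < 4:
        raise ValueError("canonical orientation requires at least 4 points")
    centroid = pos.mean(axis=0)
    X = pos - centroid
    if frame == "fixed":
        new = X
    elif frame == "data":
        cov = (X.T @ X) / len(X)
        evals, evecs = np.linalg.eigh(cov)  # ascending
        if evals[0] <= 1e-10 * max(evals[2], 1e-30):
            raise ValueError("degenerate point cloud (rank < 3); cannot orient")
        z_axis = _signed_axis(evecs[:, 2], X, export.channel("lat"))
        x_axis = _signed_axis(evecs[:, 1], X, export.channel("uni_v"))
        y_axis = np.cross(z_axis, x_axis)
        R = np.vstack([x_axis, y_axis, z_axis])
        new = X @ R.T
    else:
        raise ValueError(f"unknown frame {frame!r}")

    points = [
        MapPoint(
            x=float(new[i, 0]), y=float(new[i, 1]), z=float(new[i, 2]),
            alpha=p.alpha, beta=p.beta, gamma=p.gamma,
            uni_v=p.uni_v, bip_v=p.bip_v, lat=p.lat, imp=p.imp,
        )
        for i, p in enumerate(export.points)
    ]
    return EamExport(patient_id=export.patient_id, points=points, metadata=dict(export.metadata))
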