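import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eamrisk import EamExport, MapPoint, build_sphere

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sphere():
    """The default 14,400-face sphere (shared; construction is cheap but reused a lot)."""
    return build_sphere()


@pytest.fixture(scope="session")
def small_sphere():
    """A 12x12 sphere for tests that enumerate faces by hand."""
    return build_sphere(12, 12)


def make_export(rng: np.random.Generator, n: int = 200, patient_id: str = "T-1") -> EamExport:
    """Random shell-like export for oracle tests."""
    u = rng.standard_normal((n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pos = u * (30.0 + rng.normal(0, 2.0, n)[:, None]) + rng.uniform(-5, 5, 3)
    points = [
        MapPoint(
            x=pos[i, 0], y=pos[i, 1], z=pos[i, 2],
            alpha=rng.uniform(-180, 180), beta=rng.uniform(-180, 180),
            gamma=rng.uniform(-180, 180),
            uni_v=rng.uniform(0.1, 15.0), bip_v=rng.uniform(0.1, 6.0),
            lat=rng.uniform(-50, 150), imp=rng.uniform(80, 140),
        )
        for i in range(n)
    ]
    return EamExport(patient_id=patient_id, points=points)


def brute_force_faces(sphere, dirs: np.ndarray) -> np.ndarray:
    """Face containing each direction, by exhaustive cell-bound checks."""
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    z_edges = np.linspace(-1.0, 1.0, sphere.n_bands + 1)
    phi_edges = np.linspace(0.0, 2 * np.pi, sphere.n_lon + 1)
    bands = np.arange(sphere.n_faces) // sphere.n_lon
    lons = np.arange(sphere.n_faces) % sphere.n_lon
    z_lo, z_hi = z_edges[bands], z_edges[bands + 1]
    p_lo, p_hi = phi_edges[lons], phi_edges[lons + 1]
    z_hi = np.where(bands == sphere.n_bands - 1, np.nextafter(z_hi, 2.0), z_hi)
    p_hi = np.where(lons == sphere.n_lon - 1, np.nextafter(p_hi, 7.0), p_hi)
    z = dirs[:, 2][:, None]
    phi = np.mod(np.arctan2(dirs[:, 1], dirs[:, 0]), 2 * np.pi)[:, None]
    inside = (z >= z_lo) & (z < z_hi) & (phi >= p_lo) & (phi < p_hi)
    assert np.all(inside.sum(axis=1) == 1)
    return np.argmax(inside, axis=1)


def brute_force_components(sphere, faces: np.ndarray, angle_deg: float) -> list[frozenset]:
    """Cluster membership from pairwise angular distances via scipy csgraph."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    faces = np.asarray(faces, dtype=int)
    if len(faces) == 0:
        return []
    c = sphere.face_centers[faces]
    adj = (c @ c.T) >= np.cos(np.deg2rad(angle_deg)) - 1e-12
    _, labels = connected_components(csr_matrix(adj), directed=False)
    return [frozenset(faces[labels == k]) for k in np.unique(labels)]


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-random proper rotation matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
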