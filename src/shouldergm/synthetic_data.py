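"""Synthetic landmark datasets with known ground truth.

Generates datasets that emulate the statistical structure of a
multi-taxon anthropoid shoulder sample: several extant groups with
distinct mean shapes (a common anatomical template perturbed per group by
a seeded random direction of stated magnitude), isotropic Gaussian
landmark noise within groups, an optional linear allometric shape vector
tied to centroid size, a per-group torsion covariate, a stated fraction
of specimens emitted mirrored as left-sided, and singleton "fossil"
specimens built as convex combinations (mosaics) of group means.

Templates: a hemispherical articular surface with four insertion-facet
clusters for the 25-point proximal-humerus protocol, a shallow oval dish
for the 13-point glenoid protocol, and a deterministic spherical spiral
for any other landmark count.  All randomness flows from the single
``seed`` of the :class:`SimulationSpec`; identical specs give
bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landmark_io import LandmarkConfiguration, LandmarkDataset, LandmarkProtocol
from .landmark_io import humerus_protocol, glenoid_protocol, mirror_configuration

__all__ = [
    "GroupSpec",
    "FossilSpec",
    "SimulationSpec",
    "GroundTruth",
    "make_base_shapes",
    "simulate_dataset",
    "humerus_like_spec",
    "glenoid_like_spec",
]


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n: int
    cs_range: tuple[float, float] = (40.0, 160.0)
    torsion_mean: float | None = None
    torsion_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.label!r}: n must be >= 1")


@dataclass(frozen=True)
class FossilSpec:
    name: str
    weights: dict[str, float]  # group label -> mixture weight, sums to 1
    covariates: dict[str, float] = field(default_factory=dict)
    cs: float | None = None

    def __post_init__(self) -> None:
        w = np.array(list(self.weights.values()))
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"fossil {self.name!r}: mixture weights must be nonnegative and sum to 1"
            )


@dataclass
class SimulationSpec:
    """Full description of one synthetic dataset."""

    protocol: LandmarkProtocol
    groups: list[GroupSpec]
    mean_offset_magnitude: float = 0.1  # group separation in shape space
    within_sd: float = 0.02  # isotropic landmark noise, shape units
    allometry_magnitude: float = 0.0  # shape displacement per CS unit
    fossils: list[FossilSpec] = field(default_factory=list)
    left_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.within_sd <= 0:
            raise ValueError("within_sd must be positive")
        if not 0.0 <= self.left_fraction <= 1.0:
            raise ValueError("left_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator actually used; the recovery target for tests."""

    group_means: dict[str, np.ndarray]  # (k, 3) per group, unit CS
    allometric_vector: np.ndarray  # (k, 3), shape change per CS unit
    memberships: dict[str, str]  # specimen id -> group label
    centroid_sizes: dict[str, float]
    torsion: dict[str, float]
    fossil_weights: dict[str, dict[str, float]]


def _unit_cs(X: np.ndarray) -> np.ndarray:
    X = X - X.mean(axis=0)
    return X / np.sqrt((X**2).sum())


def _humerus_template() -> np.ndarray:
    """Hemisphere-plus-facets template for the 25-point humerus protocol."""
    pts = np.zeros((25, 3))
    # four insertion facets (L1-L16): diamonds of half-width 0.25 centred
    # around the head at distinct orientations
    centers = np.array(
        [
            [0.9, -0.5, 0.3],  # subscapularis (minor tubercle, anterior)
            [0.5, 0.9, 0.4],  # supraspinatus (major tubercle, superior)
            [-0.2, 1.0, 0.1],  # infraspinatus
            [-0.7, 0.8, -0.2],  # teres minor
        ]
    )
    offsets = np.array(
        [[0.0, -0.25, 0.0], [0.0, 0.25, 0.0], [0.25, 0.0, 0.1], [-0.25, 0.0, -0.1]]
    )
    for f in range(4):
        pts[4 * f : 4 * f + 4] = centers[f] + offsets
    # articular arc L17-L21 on the hemisphere (radius 1, pole +z)
    arc_angles = np.deg2rad([-80.0, -15.0, 50.0, 115.0, 180.0])
    azim = np.deg2rad([10.0, 40.0, 80.0, 120.0, 160.0])
    polar = np.deg2rad([75.0, 20.0, 60.0, 85.0, 80.0])
    for i, (az, po) in enumerate(zip(azim, polar)):
        pts[16 + i] = [np.sin(po) * np.cos(az), np.sin(po) * np.sin(az), np.cos(po)]
    # semilandmarks at chord midpoints of their anchor pairs, pushed onto
    # the sphere so they sit on the articular surface
    for sl_idx, (a, b) in zip(range(21, 25), [(16, 17), (17, 18), (19, 17), (20, 17)]):
        mid = 0.5 * (pts[a] + pts[b])
        pts[sl_idx] = mid / np.linalg.norm(mid)
    return _unit_cs(pts)


def _glenoid_template() -> np.ndarray:
    """Shallow oval dish for the 13-point glenoid protocol."""
    pts = np.zeros((13, 3))
    # margin: oval with semi-axes 1.0 (craniocaudal) x 0.7 (anteroposterior)
    pts[0] = [0.0, 1.0, 0.0]  # L1 proximal
    pts[1] = [0.0, -1.0, 0.0]  # L2 distal
    pts[2] = [0.7, 0.0, 0.0]  # L3 anterior
    pts[3] = [-0.7, 0.0, 0.0]  # L4 posterior
    pts[4] = [0.0, 0.0, -0.35]  # L5 centre, depressed (dish concavity)
    margin_pairs = [(0, 2), (2, 1), (1, 3), (3, 0)]
    for sl_idx, (a, b) in zip(range(5, 9), margin_pairs):
        mid = 0.5 * (pts[a] + pts[b])
        mid[:2] *= 1.0 / np.hypot(mid[0] / 0.7, mid[1] / 1.0)  # back to the oval
        mid[2] = -0.05
        pts[sl_idx] = mid
    for sl_idx, a in zip(range(9, 13), range(4)):
        mid = 0.5 * (pts[a] + pts[4])
        mid[2] = -0.25
        pts[sl_idx] = mid
    return _unit_cs(pts)


def _spiral_template(k: int) -> np.ndarray:
    """Deterministic golden-spiral points on a sphere (generic fallback)."""
    i = np.arange(k, dtype=float)
    phi = np.arccos(1.0 - 2.0 * (i + 0.5) / k)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    pts = np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )
    return _unit_cs(pts)


def template_shape(protocol: LandmarkProtocol) -> np.ndarray:
    if protocol.name == "humerus" and protocol.expected_k == 25:
        return _humerus_template()
    if protocol.name == "glenoid" and protocol.expected_k == 13:
        return _glenoid_template()
    return _spiral_template(protocol.expected_k)


def make_base_shapes(spec: SimulationSpec) -> dict[str, np.ndarray]:
    """Per-group mean shapes: template + seeded random offset of stated magnitude.

    Deterministic given the spec seed; with zero offset magnitude all group
    means coincide with the template.
    """
    template = template_shape(spec.protocol)
    k = template.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1]))
    means: dict[str, np.ndarray] = {}
    for group in spec.groups:
        direction = rng.standard_normal((k, 3))
        direction /= np.sqrt((direction**2).sum())
        means[group.label] = _unit_cs(template + spec.mean_offset_magnitude * direction)
    return means


def _allometric_vector(spec: SimulationSpec) -> np.ndarray:
    """Seeded allometric direction, centred and orthogonal to the template.

    The displacement lives in the tangent space at the template shape
    (no translation or pure-scale component), so it is exactly the shape
    change per CS unit that a shape-on-size regression models.
    """
    k = spec.protocol.expected_k
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 2]))
    v = rng.standard_normal((k, 3))
    v -= v.mean(axis=0)
    t = template_shape(spec.protocol).ravel()  # unit CS already
    flat = v.ravel() - (v.ravel() @ t) * t
    v = flat.reshape(k, 3)
    v /= np.sqrt((v**2).sum())
    return spec.allometry_magnitude * v


def _random_rigid(rng: np.random.Generator, X: np.ndarray) -> np.ndarray:
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    t = rng.uniform(-100.0, 100.0, size=3)
    return X @ Q + t


def simulate_dataset(spec: SimulationSpec) -> tuple[LandmarkDataset, GroundTruth]:
    """Draw a full dataset (and its ground truth) from a simulation spec.

    Each specimen is its group mean, plus the allometric displacement
    scaled by (CS - group mid CS), plus isotropic Gaussian noise of sd
    ``within_sd`` per coordinate, rigidly transformed at random and scaled
    to its target centroid size.  Fossil mosaics are convex combinations
    of group means plus the same noise.  A ``left_fraction`` of extant
    specimens is emitted mirrored with side="left".
    """
    means = make_base_shapes(spec)
    allom = _allometric_vector(spec)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 3]))
    specimens: list[LandmarkConfiguration] = []
    truth = GroundTruth(
        group_means=means,
        allometric_vector=allom,
        memberships={},
        centroid_sizes={},
        torsion={},
        fossil_weights={},
    )

    for group in spec.groups:
        lo, hi = group.cs_range
        mid = 0.5 * (lo + hi)
        for j in range(group.n):
            sid = f"{group.label}_{j + 1:03d}"
            cs = float(rng.uniform(lo, hi))
            shape = (
                means[group.label]
                + allom * (cs - mid)
                + rng.normal(0.0, spec.within_sd, size=means[group.label].shape)
            )
            shape = _unit_cs(shape) * cs
            shape = _random_rigid(rng, shape)
            cov: dict[str, float] = {}
            if group.torsion_mean is not None:
                cov["torsion_deg"] = float(
                    rng.normal(group.torsion_mean, group.torsion_sd)
                )
                truth.torsion[sid] = cov["torsion_deg"]
            config = LandmarkConfiguration(
                specimen_id=sid,
                group=group.label,
                side="right",
                coords=shape,
                covariates=cov,
            )
            if rng.uniform() < spec.left_fraction:
                config = mirror_configuration(config)  # emitted as a left element
            specimens.append(config)
            truth.memberships[sid] = group.label
            truth.centroid_sizes[sid] = cs

    group_mid_cs = {g.label: 0.5 * sum(g.cs_range) for g in spec.groups}
    for fossil in spec.fossils:
        mix = sum(w * means[g] for g, w in fossil.weights.items())
        cs = fossil.cs or sum(w * group_mid_cs[g] for g, w in fossil.weights.items())
        shape = mix + rng.normal(0.0, spec.within_sd, size=mix.shape)
        shape = _unit_cs(shape) * cs
        shape = _random_rigid(rng, shape)
        specimens.append(
            LandmarkConfiguration(
                specimen_id=fossil.name,
                group=f"fossil:{fossil.name}",
                side="right",
                coords=shape,
                covariates=dict(fossil.covariates),
            )
        )
        truth.memberships[fossil.name] = f"fossil:{fossil.name}"
        truth.centroid_sizes[fossil.name] = float(cs)
        truth.fossil_weights[fossil.name] = dict(fossil.weights)
        if "torsion_deg" in fossil.covariates:
            truth.torsion[fossil.name] = fossil.covariates["torsion_deg"]

    dataset = LandmarkDataset(
        protocol=spec.protocol,
        specimens=specimens,
        provenance=f"simulated(seed={spec.seed})",
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# default study conditions

_HUMERUS_GROUPS = [
    # (label, n, cs_range, torsion mean/sd): sample sizes follow the extant
    # comparative sample (133 humeri over 7 genus-level groups); CS ranges
    # span the observed small-taxon to Gorilla extremes (~40-160 mm);
    # torsion means/SDs are the published per-genus values (degrees,
    # 90-degree offset convention)
    GroupSpec("Hylobatids", 20, (40.0, 70.0), 112.40, 9.63),
    GroupSpec("Ateles", 9, (40.0, 65.0), 116.63, 6.01),
    GroupSpec("Lagothrix", 18, (40.0, 65.0), 94.17, 5.86),
    GroupSpec("Pongo", 20, (80.0, 125.0), 132.36, 16.24),
    GroupSpec("Gorilla", 15, (120.0, 160.0), 152.71, 7.11),
    GroupSpec("Pan", 17, (80.0, 120.0), 139.41, 11.21),
    GroupSpec("H_sapiens", 34, (90.0, 130.0), 135.32, 11.14),
]

_GLENOID_GROUPS = [
    GroupSpec("Hylobatids", 11, (15.0, 27.0)),
    GroupSpec("Ateles", 6, (15.0, 25.0)),
    GroupSpec("Lagothrix", 16, (15.0, 25.0)),
    GroupSpec("Pongo", 16, (30.0, 48.0)),
    GroupSpec("Gorilla", 14, (45.0, 60.0)),
    GroupSpec("Pan", 14, (30.0, 45.0)),
    GroupSpec("H_sapiens", 19, (33.0, 50.0)),
]

_HUMERUS_FOSSILS = [
    # mosaics emulating singleton fossils intermediate between group means
    FossilSpec("AL-288-1r", {"H_sapiens": 0.7, "Hylobatids": 0.3}, {"torsion_deg": 103.0}, cs=52.0),
    FossilSpec("Sts-7", {"Pongo": 0.7, "H_sapiens": 0.3}, {"torsion_deg": 130.0}, cs=95.0),
    FossilSpec("Omo-119", {"Lagothrix": 0.7, "H_sapiens": 0.3}, {"torsion_deg": 122.0}, cs=90.0),
    FossilSpec("Tabun-1", {"H_sapiens": 0.9, "Pongo": 0.1}, cs=100.0),
]

_GLENOID_FOSSILS = [
    FossilSpec("AL-288-1l", {"Gorilla": 0.6, "Pan": 0.4}, cs=20.0),
    FossilSpec("Sts-7", {"Lagothrix": 0.7, "Pongo": 0.3}, cs=28.0),
    FossilSpec("KNM-WT-15000", {"Hylobatids": 0.8, "H_sapiens": 0.2}, cs=30.0),
]


def humerus_like_spec(
    seed: int = 0,
    within_sd: float = 0.02,
    mean_offset_magnitude: float = 0.1,
    allometry_magnitude: float = 0.0005,
    left_fraction: float = 0.15,
    with_fossils: bool = True,
) -> SimulationSpec:
    """Default proximal-humerus study conditions: 7 groups, N = 133 extant."""
    return SimulationSpec(
        protocol=humerus_protocol(),
        groups=list(_HUMERUS_GROUPS),
        mean_offset_magnitude=mean_offset_magnitude,
        within_sd=within_sd,
        allometry_magnitude=allometry_magnitude,
        fossils=list(_HUMERUS_FOSSILS) if with_fossils else [],
        left_fraction=left_fraction,
        seed=seed,
    )


def glenoid_like_spec(
    seed: int = 0,
    within_sd: float = 0.02,
    mean_offset_magnitude: float = 0.1,
    allometry_magnitude: float = 0.001,
    left_fraction: float = 0.15,
    with_fossils: bool = True,
) -> SimulationSpec:
    """Default glenoid study conditions: 7 groups, N = 96 extant."""
    return SimulationSpec(
        protocol=glenoid_protocol(),
        groups=list(_GLENOID_GROUPS),
        mean_offset_magnitude=mean_offset_magnitude,
        within_sd=within_sd,
        allometry_magnitude=allometry_magnitude,
        fossils=list(_GLENOID_FOSSILS) if with_fossils else [],
        left_fraction=left_fraction,
        seed=seed,
    )
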