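"""Shared fixtures: small protocols, simulated datasets, fixed configurations."""

from __future__ import annotations

import numpy as np
import pytest

from shouldergm.landmark_io import (
    Curve,
    LandmarkConfiguration,
    LandmarkDataset,
    LandmarkProtocol,
    humerus_protocol,
)
from shouldergm.synthetic_data import (
    GroupSpec,
    SimulationSpec,
    humerus_like_spec,
    simulate_dataset,
)


def simple_protocol(k: int, name: str = "simple") -> LandmarkProtocol:
    """Protocol of k plain type-II landmarks, no curves."""
    return LandmarkProtocol(name, tuple((f"P{i + 1}", "II") for i in range(k)))


def arc_protocol(n_sl: int = 4) -> LandmarkProtocol:
    """One slideable curve A-SL1..SLn-B plus two off-curve anchors C, D."""
    landmarks = (
        [("A", "II")]
        + [(f"SL{i + 1}", "SL") for i in range(n_sl)]
        + [("B", "II"), ("C", "II"), ("D", "II")]
    )
    curve = Curve("A", tuple(f"SL{i + 1}" for i in range(n_sl)), "B")
    return LandmarkProtocol("arc", tuple(landmarks), (curve,))


def random_config(rng: np.random.Generator, k: int = 10, scale: float = 1.0) -> np.ndarray:
    return rng.standard_normal((k, 3)) * scale


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


def rigid_motion(rng: np.random.Generator, X: np.ndarray, scale: bool = True) -> np.ndarray:
    s = rng.uniform(0.5, 2.0) if scale else 1.0
    return s * X @ random_rotation(rng) + rng.uniform(-10, 10, size=3)


def make_dataset(coords_list, protocol=None, groups=None) -> LandmarkDataset:
    k = coords_list[0].shape[0]
    protocol = protocol or simple_protocol(k)
    groups = groups or ["g"] * len(coords_list)
    specs = [
        LandmarkConfiguration(f"s{i + 1}", groups[i], np.asarray(c, float))
        for i, c in enumerate(coords_list)
    ]
    return LandmarkDataset(protocol, specs)


def clustered_dataset(
    seed: int,
    n_groups: int = 3,
    n_per_group: int = 8,
    k: int = 10,
    separation: float = 0.5,
    noise: float = 0.02,
    fossils: dict[str, dict[str, float]] | None = None,
):
    """Well-separated random group means with isotropic noise; returns (dataset, means)."""
    rng = np.random.default_rng(seed)
    means = {f"G{g + 1}": random_config(rng, k) for g in range(n_groups)}
    for lab in means:
        means[lab] = means[lab] - means[lab].mean(axis=0)
        means[lab] /= np.sqrt((means[lab] ** 2).sum())
        means[lab] = means[lab] + separation * rng.standard_normal((k, 3)) / np.sqrt(3 * k)
    coords, labels = [], []
    for lab, mean in means.items():
        for _ in range(n_per_group):
            coords.append(rigid_motion(rng, mean + rng.normal(0, noise, (k, 3))))
            labels.append(lab)
    specs = [
        LandmarkConfiguration(f"s{i + 1}", labels[i], c) for i, c in enumerate(coords)
    ]
    if fossils:
        for name, weights in fossils.items():
            mix = sum(w * means[g] for g, w in weights.items())
            specs.append(
                LandmarkConfiguration(
                    name, f"fossil:{name}", rigid_motion(rng, mix + rng.normal(0, noise, (k, 3)))
                )
            )
    return LandmarkDataset(simple_protocol(k), specs), means


@pytest.fixture(scope="session")
def humerus_proto():
    return humerus_protocol()


@pytest.fixture(scope="session")
def small_humerus_run():
    """A small 4-group humerus-like dataset with fossils (session-cached)."""
    spec = humerus_like_spec(seed=11, with_fossils=True)
    spec.groups = [GroupSpec(g.label, max(5, g.n // 3), g.cs_range, g.torsion_mean, g.torsion_sd)
                   for g in spec.groups]
    return simulate_dataset(spec)


# fixed asymmetric 5-point configuration (chirality carrier for mirror tests)
ASYMMETRIC_5PT = np.array(
    [
        [0.0, 0.0, 0.0],
        [1.0, 0.0, 0.0],
        [0.0, 1.3, 0.0],
        [0.0, 0.0, 1.7],
        [0.9, 0.8, 0.4],
    ]
)
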