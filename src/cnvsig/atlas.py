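"""Spherical parcellation with network labels.

The analysis operates on parcel-level grey-matter volumes. Each parcel (region)
has a centroid on the unit sphere and belongs to one of K large-scale networks
(K = 7 by default, mirroring the canonical seven-network cortical grouping:
visual, somatomotor, dorsal attention, salience/ventral attention, limbic,
frontoparietal, default mode). The centroids feed the spin-permutation spatial
null; the network labels feed the per-network coefficient summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEVEN_NETWORKS = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "salience_ventral_attention",
    "limbic",
    "frontoparietal",
    "default_mode",
)


class InvalidDesignError(ValueError):
    """A simulation or analysis design that cannot be realized."""


@dataclass(frozen=True)
class AtlasSpec:
    """Parcellation: unit-sphere centroids plus a network label per region.

    Attributes
    ----------
    network_label : (n_regions,) int array with values in 1..K
    centroid : (n_regions, 3) array, each row unit Euclidean norm
    network_names : K human-readable network labels
    """

    network_label: np.ndarray
    centroid: np.ndarray
    network_names: tuple[str, ...] = field(default=SEVEN_NETWORKS)

    @property
    def n_regions(self) -> int:
        return self.centroid.shape[0]

    @property
    def n_networks(self) -> int:
        return len(self.network_names)

    def __post_init__(self):
        c = np.asarray(self.centroid, dtype=float)
        lab = np.asarray(self.network_label, dtype=int)
        if c.ndim != 2 or c.shape[1] != 3:
            raise InvalidDesignError("centroids must be an (n_regions, 3) array")
        if lab.shape != (c.shape[0],):
            raise InvalidDesignError("one network label per region required")
        norms = np.linalg.norm(c, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise InvalidDesignError("all centroids must have unit norm")
        k = len(self.network_names)
        if lab.min() < 1 or lab.max() > k:
            raise InvalidDesignError("network labels must lie in 1..K")
        counts = np.bincount(lab, minlength=k + 1)[1:]
        if (counts == 0).any():
            empty = [self.network_names[i] for i in np.flatnonzero(counts == 0)]
            raise InvalidDesignError(f"empty networks: {empty}")
        object.__setattr__(self, "network_label", lab)
        object.__setattr__(self, "centroid", c)

    def region_ids(self) -> np.ndarray:
        return np.arange(self.n_regions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.region_ids(),
                "network": self.network_label,
                "x": self.centroid[:, 0],
                "y": self.centroid[:, 1],
                "z": self.centroid[:, 2],
            }
        )


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform lattice of n points on the unit sphere (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def make_atlas(n_regions: int, n_networks: int = 7, seed: int = 0) -> AtlasSpec:
    """Build a deterministic single-sphere atlas.

    Centroids form a Fibonacci lattice; network labels come from nearest of
    ``n_networks`` random seed directions, producing spatially contiguous
    patches. Empty networks are repaired greedily: the region closest to the
    orphan seed direction is pulled from a network that still has >= 2 regions,
    so every network ends non-empty (pigeonhole: n_regions == n_networks gives
    exactly one region per network).
    """
    if n_networks < 1 or n_regions < n_networks:
        raise InvalidDesignError(
            f"need n_regions >= n_networks >= 1, got {n_regions} regions, "
            f"{n_networks} networks"
        )
    rng = np.random.default_rng(seed)
    centroids = _fibonacci_sphere(n_regions)
    seeds = rng.standard_normal((n_networks, 3))
    seeds /= np.linalg.norm(seeds, axis=1, keepdims=True)
    # nearest seed on the sphere == largest dot product
    label = np.argmax(centroids @ seeds.T, axis=1)

    counts = np.bincount(label, minlength=n_networks)
    while (counts == 0).any():
        k = int(np.flatnonzero(counts == 0)[0])
        donors = np.flatnonzero(counts[label] >= 2)
        best = donors[np.argmax(centroids[donors] @ seeds[k])]
        counts[label[best]] -= 1
        label[best] = k
        counts[k] += 1

    if n_networks == 7:
        names = SEVEN_NETWORKS
    else:
        names = tuple(f"network_{i + 1}" for i in range(n_networks))
    return AtlasSpec(network_label=label + 1, centroid=centroids, network_names=names)


def write_atlas_tsv(atlas: AtlasSpec, path) -> None:
    atlas.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_atlas_tsv(path) -> AtlasSpec:
    df = pd.read_csv(path, sep="\t")
    c = df[["x", "y", "z"]].to_numpy()
    # renormalize against round-trip rounding
    c = c / np.linalg.norm(c, axis=1, keepdims=True)
    k = int(df["network"].max())
    names = SEVEN_NETWORKS if k == 7 else tuple(f"network_{i + 1}" for i in range(k))
    return AtlasSpec(
        network_label=df["network"].to_numpy(),
        centroid=c,
        network_names=names,
    )
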