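"""Synthetic chromatin structures and Hi-C-like contact maps.

The generator produces the three ingredients every other module is
tested against:

* a smooth 3D chain with unit bond lengths (ground-truth structure),
* a contact map whose expected counts follow the power-law inverse of
  the wish-distance rule used by :mod:`unicorn_hic.reconstruct3d`
  (``lambda_ij = scale * d_ij**(-1/alpha)``), optionally with Poisson
  counting noise and TAD-like block enrichment,
* high/low-depth training pairs, where the low-depth member is produced
  by binomial read thinning of the high-depth member.

Everything is seeded and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from unicorn_hic.hic_io import ContactMap, Patch, extract_patches
from unicorn_hic.reconstruct3d import Structure3D

__all__ = [
    "SimulationConfig",
    "TrainingPair",
    "generate_structure",
    "structure_to_contacts",
    "thin_counts",
    "make_training_pairs",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    ``alpha_true`` is the contact–distance conversion exponent: expected
    counts decay as ``d**(-1/alpha_true)`` so that the reconstruction
    rule ``d = IF**(-alpha)`` inverts the generator exactly at
    ``alpha = alpha_true`` in the noiseless case.  ``thinning_range``
    holds the read-retention probabilities used when degrading
    high-depth maps to low-depth ones (binomial thinning); the default
    span (0.3–0.95) covers severe to mild depth loss.
    """

    n_loci: int = 60
    alpha_true: float = 1.0
    count_scale: float = 1.0
    noise: str = "none"  # {"none", "poisson"}
    thinning_range: tuple[float, float] = (0.3, 0.95)
    tad_blocks: Optional[list[tuple[int, int, float]]] = None
    max_turn_deg: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 4:
            raise ValueError("n_loci must be >= 4")
        if self.alpha_true <= 0 or self.count_scale <= 0:
            raise ValueError("alpha_true and count_scale must be positive")
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        lo, hi = self.thinning_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("thinning_range must satisfy 0 < low <= high <= 1")
        for blk in self.tad_blocks or []:
            s, e, f = blk
            if not (0 <= s < e <= self.n_loci) or f <= 0:
                raise ValueError(f"invalid TAD block {blk}")


@dataclass(frozen=True)
class TrainingPair:
    """High-depth patch, its binomially thinned low-depth counterpart,
    and the retention probability that produced it."""

    hr: Patch
    lr: Patch
    retention: float


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of vector ``v`` about unit ``axis``."""
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c)


def generate_structure(config: SimulationConfig) -> Structure3D:
    """Smooth random chain with unit bond lengths.

    Each step rotates the previous direction by an angle drawn
    uniformly from ``[0, max_turn_deg]`` about a random axis orthogonal
    to it, giving a locally stiff, self-avoiding-ish walk.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_loci
    coords = np.zeros((n, 3))
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    max_turn = np.deg2rad(config.max_turn_deg)
    for i in range(1, n):
        coords[i] = coords[i - 1] + d
        # random axis orthogonal to current direction
        a = rng.normal(size=3)
        a -= d * np.dot(a, d)
        norm = np.linalg.norm(a)
        if norm < 1e-12:
            a = np.array([1.0, 0.0, 0.0])
        else:
            a /= norm
        d = _rotate(d, a, rng.uniform(0.0, max_turn))
        d /= np.linalg.norm(d)
    return Structure3D(coords=coords)


def structure_to_contacts(s: Structure3D, config: SimulationConfig) -> ContactMap:
    """Contact map whose expected counts invert the wish-distance rule.

    ``lambda_ij = count_scale * d_ij**(-1/alpha_true)`` off-diagonal,
    multiplied by the enrichment factor inside each TAD block; the
    diagonal is zero.  With ``noise='poisson'`` counts are drawn
    symmetrically from ``Poisson(lambda)``.
    """
    coords = np.asarray(s.coords, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=-1))
    n = len(coords)
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] <= 0):
        raise ValueError("coincident loci: zero off-diagonal distance")
    lam = np.zeros((n, n))
    lam[off] = config.count_scale * d[off] ** (-1.0 / config.alpha_true)
    for start, end, factor in config.tad_blocks or []:
        block = np.zeros(n, dtype=bool)
        block[start:end] = True
        sel = np.outer(block, block) & off
        lam[sel] *= factor
    if config.noise == "poisson":
        rng = np.random.default_rng(config.seed + 1)
        iu = np.triu_indices(n, k=1)
        counts = rng.poisson(lam[iu]).astype(float)
        m = np.zeros((n, n))
        m[iu] = counts
        m = m + m.T
    else:
        m = lam
    return ContactMap(m)


def thin_counts(cm: ContactMap, retention: float, seed: int) -> ContactMap:
    """Binomial read thinning: each count replaced by
    ``Binomial(count, retention)``, drawn on the upper triangle and
    mirrored.  Non-integer counts are rounded first."""
    if not (0 < retention <= 1):
        raise ValueError("retention must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = cm.n_bins
    counts = np.rint(cm.matrix).astype(np.int64)
    iu = np.triu_indices(n)
    thinned = rng.binomial(counts[iu], retention).astype(float)
    m = np.zeros((n, n))
    m[iu] = thinned
    m = m + m.T - np.diag(np.diag(m))
    return cm.with_matrix(m)


def make_training_pairs(
    cms: Sequence[ContactMap],
    config: SimulationConfig,
    patch_side: int = 40,
    stride: int | None = None,
) -> list[TrainingPair]:
    """High/low-depth patch pairs for super-resolution training.

    Each map is tiled into ``patch_side`` patches; for every patch a
    retention probability is drawn uniformly from
    ``config.thinning_range`` and the low-depth member is the binomial
    thinning of the (rounded) high-depth patch at that retention.
    """
    if not cms:
        raise ValueError("need at least one contact map")
    rng = np.random.default_rng(config.seed)
    stride = patch_side if stride is None else stride
    lo, hi = config.thinning_range
    pairs: list[TrainingPair] = []
    for cm in cms:
        for patch in extract_patches(cm, patch_side, stride):
            retention = float(rng.uniform(lo, hi))
            hr = np.rint(patch.values)
            thin_seed = int(rng.integers(0, 2 ** 31 - 1))
            lr_vals = _thin_dense(hr, retention, thin_seed)
            pairs.append(TrainingPair(
                hr=Patch(hr, patch.origin),
                lr=Patch(lr_vals, patch.origin),
                retention=retention,
            ))
    return pairs


def _thin_dense(values: np.ndarray, retention: float, seed: int) -> np.ndarray:
    """Thin a dense (possibly asymmetric off-diagonal) patch entrywise."""
    rng = np.random.default_rng(seed)
    counts = np.rint(values).astype(np.int64)
    return rng.binomial(counts, retention).astype(float)
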