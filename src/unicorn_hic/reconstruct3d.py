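"""Maximum-likelihood 3D chromosome reconstruction from contact maps.

Contact frequencies are converted into target ("wish") distances with a
power law, ``X_ij = IF_ij ** (-alpha)``; pairs with zero contact count
are excluded.  A structure ``S`` (one 3D point per bin) is scored by the
log-likelihood

    L(S) = -n/2 - n * log( (1/n) * sum_i (X_i^s - X_i)^2 )

where ``X_i^s`` are the model's pairwise distances and ``n`` the number
of scored pairs, and is optimized by gradient ascent with backtracking
step control.  The conversion factor alpha is estimated by a grid
search, scoring each candidate by the Pearson correlation between
reconstructed and wish distances.  Model units are arbitrary: the
likelihood is invariant under rigid transforms, so downstream
comparisons are correlation- or superposition-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from unicorn_hic.hic_io import ContactMap

__all__ = [
    "Structure3D",
    "WishDistances",
    "ReconstructionConfig",
    "EnsembleResult",
    "wish_distances",
    "log_likelihood",
    "likelihood_gradient",
    "optimize_structure",
    "estimate_alpha",
    "build_ensemble",
    "select_representative",
    "probe_distance",
    "write_structure",
    "read_xyz",
]

#: Pairwise distances are floored at this value inside the likelihood and
#: its gradient so coincident loci cannot produce division by zero.
DIST_FLOOR = 1e-9


@dataclass
class Structure3D:
    """Ordered 3D coordinates of genomic loci (one point per bin)."""

    coords: np.ndarray
    locus_bins: Optional[np.ndarray] = None
    resolution_bp: int = 1
    chrom: str = "chr?"

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3 or c.shape[0] < 2:
            raise ValueError(f"coords must be (n>=2, 3), got {c.shape}")
        if not np.all(np.isfinite(c)):
            raise ValueError("coords contain non-finite values")
        self.coords = c
        if self.locus_bins is None:
            self.locus_bins = np.arange(len(c))
        else:
            self.locus_bins = np.asarray(self.locus_bins, dtype=int)
            if len(self.locus_bins) != len(c):
                raise ValueError("locus_bins length mismatch")

    @property
    def n_loci(self) -> int:
        return len(self.coords)

    def pair_distances(self, i_idx: np.ndarray, j_idx: np.ndarray) -> np.ndarray:
        diff = self.coords[i_idx] - self.coords[j_idx]
        return np.sqrt((diff ** 2).sum(axis=1))

    def distance_matrix(self) -> np.ndarray:
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=-1))


@dataclass
class WishDistances:
    """Target distances for the scored (upper-triangle, nonzero) pairs."""

    i: np.ndarray
    j: np.ndarray
    x: np.ndarray
    alpha: float
    n_bins: int

    @property
    def n_pairs(self) -> int:
        return len(self.x)


@dataclass
class ReconstructionConfig:
    """Optimization settings for structure inference.

    ``alpha_grid`` is the candidate set for the contact-to-distance
    exponent (default 0.1–2.0 in steps of 0.1); ``alpha_search_iters``
    caps the per-candidate optimization during the grid search so the
    search stays cheap relative to the final fit.  ``mse_floor`` keeps
    the log-likelihood finite when the fit is exact.
    """

    alpha_grid: Sequence[float] = field(
        default_factory=lambda: [round(0.1 * k, 1) for k in range(1, 21)])
    max_iters: int = 2000
    learning_rate: float = 0.05
    tol: float = 1e-9
    mse_floor: float = 1e-12
    ensemble_size: int = 20
    alpha_search_iters: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.alpha_grid or any(a <= 0 for a in self.alpha_grid):
            raise ValueError("alpha_grid must be non-empty with positive values")
        if self.ensemble_size < 1 or self.mse_floor <= 0:
            raise ValueError("ensemble_size >= 1 and mse_floor > 0 required")


def wish_distances(cm: ContactMap, alpha: float) -> WishDistances:
    """Convert contact frequencies to target distances, ``X = IF**(-alpha)``.

    Only upper-triangle pairs with positive contact frequency are
    included; ``n`` in the likelihood counts exactly these pairs.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    iu = np.triu_indices(cm.n_bins, k=1)
    vals = cm.matrix[iu]
    keep = vals > 0
    if not np.any(keep):
        raise ValueError("contact map has no positive off-diagonal entries")
    i_idx = iu[0][keep]
    j_idx = iu[1][keep]
    x = vals[keep] ** (-alpha)
    return WishDistances(i=i_idx, j=j_idx, x=x, alpha=float(alpha), n_bins=cm.n_bins)


def _msd(s: Structure3D, wd: WishDistances) -> tuple[float, np.ndarray]:
    d = np.maximum(s.pair_distances(wd.i, wd.j), DIST_FLOOR)
    dev = d - wd.x
    return float(np.mean(dev ** 2)), d


def log_likelihood(s: Structure3D, wd: WishDistances, mse_floor: float = 1e-12) -> float:
    """``L(S) = -n/2 - n*log(max(mean squared deviation, mse_floor))``."""
    n = wd.n_pairs
    msd, _ = _msd(s, wd)
    return -n / 2.0 - n * np.log(max(msd, mse_floor))


def likelihood_gradient(s: Structure3D, wd: WishDistances,
                        mse_floor: float = 1e-12) -> np.ndarray:
    """Analytic gradient of the log-likelihood w.r.t. every coordinate.

    On the floor (mean squared deviation <= ``mse_floor``) the
    likelihood is constant, so the gradient is zero there.
    """
    msd, d = _msd(s, wd)
    grad = np.zeros_like(s.coords)
    if msd <= mse_floor:
        return grad
    vec = s.coords[wd.i] - s.coords[wd.j]
    # dL/dc_i = -(2/D) * sum over pairs containing i of (d - X)/d * (c_i - c_j)
    per_pair = (-2.0 / msd) * ((d - wd.x) / d)[:, None] * vec
    np.add.at(grad, wd.i, per_pair)
    np.add.at(grad, wd.j, -per_pair)
    return grad


def _init_coords(wd: WishDistances, n_loci: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    half = float(np.mean(wd.x))
    return rng.uniform(-half, half, size=(n_loci, 3))


def optimize_structure(
    wd: WishDistances,
    cfg: ReconstructionConfig,
    seed: int | None = None,
    max_iters: int | None = None,
) -> tuple[Structure3D, float, int]:
    """Gradient ascent on the log-likelihood with backtracking steps.

    Coordinates start uniform in a cube scaled to the mean wish
    distance.  A step is accepted only if it increases the likelihood
    (the step then grows 10%); otherwise the step is halved.  Stops when
    the relative likelihood change of an accepted step falls below
    ``cfg.tol``, the step underflows, or ``max_iters`` is reached.
    """
    seed = cfg.seed if seed is None else seed
    iters_cap = cfg.max_iters if max_iters is None else max_iters
    coords = _init_coords(wd, wd.n_bins, seed)
    s = Structure3D(coords, resolution_bp=1)
    like = log_likelihood(s, wd, cfg.mse_floor)
    if not np.isfinite(like):
        raise RuntimeError("non-finite initial likelihood")
    step = cfg.learning_rate
    it = 0
    done = False
    while it < iters_cap and not done:
        it += 1
        grad = likelihood_gradient(s, wd, cfg.mse_floor)
        if float(np.linalg.norm(grad)) < 1e-14:
            break
        # backtracking line search: accept only improvements
        while True:
            cand = Structure3D(s.coords + step * grad)
            cand_like = log_likelihood(cand, wd, cfg.mse_floor)
            if not np.isfinite(cand_like):
                raise RuntimeError("non-finite likelihood during optimization")
            if cand_like > like:
                rel = (cand_like - like) / max(abs(like), 1e-12)
                s, like = cand, cand_like
                step *= 1.1
                if rel < cfg.tol:
                    done = True
                break
            step *= 0.5
            if step < 1e-16:
                done = True
                break
    return s, like, it


def estimate_alpha(
    cm: ContactMap,
    cfg: ReconstructionConfig,
) -> tuple[float, pd.DataFrame]:
    """Grid-search the conversion factor alpha.

    Each candidate is scored by the Pearson correlation between the
    reconstructed pairwise distances and the wish distances after a
    reduced-iteration optimization run with a shared seed (so the score
    differences reflect alpha, not initialization).  Ties break toward
    the smaller alpha.
    """
    from unicorn_hic.metrics import pearson

    rows = []
    best_alpha, best_score = None, -np.inf
    for alpha in cfg.alpha_grid:
        try:
            wd = wish_distances(cm, alpha)
            s, like, iters = optimize_structure(
                wd, cfg, seed=cfg.seed, max_iters=cfg.alpha_search_iters)
            score = pearson(s.pair_distances(wd.i, wd.j), wd.x)
        except (ValueError, RuntimeError) as exc:
            rows.append({"alpha": alpha, "score": np.nan, "likelihood": np.nan,
                         "iterations": 0, "error": str(exc)})
            continue
        rows.append({"alpha": alpha, "score": score, "likelihood": like,
                     "iterations": iters, "error": ""})
        if score > best_score:
            best_alpha, best_score = alpha, score
    table = pd.DataFrame(rows)
    if best_alpha is None:
        raise RuntimeError("alpha estimation failed for every grid value")
    return float(best_alpha), table


@dataclass
class EnsembleResult:
    """Ensemble of independently initialized reconstructions."""

    structures: list[Structure3D]
    likelihoods: list[float]
    alpha: float
    alpha_table: Optional[pd.DataFrame] = None

    def __len__(self) -> int:
        return len(self.structures)


def build_ensemble(
    cm: ContactMap,
    cfg: ReconstructionConfig,
    alpha: float | None = None,
) -> EnsembleResult:
    """Reconstruct ``cfg.ensemble_size`` structures at the best alpha.

    Alpha is grid-estimated unless given.  Each ensemble member uses a
    distinct seed derived from ``cfg.seed``; failed runs are skipped as
    long as at least one succeeds.
    """
    table = None
    if alpha is None:
        alpha, table = estimate_alpha(cm, cfg)
    wd = wish_distances(cm, alpha)
    structures, likelihoods = [], []
    errors = []
    for k in range(cfg.ensemble_size):
        seed = (cfg.seed + 7919 * (k + 1)) % (2 ** 31 - 1)
        try:
            s, like, _ = optimize_structure(wd, cfg, seed=seed)
        except RuntimeError as exc:
            errors.append(str(exc))
            continue
        structures.append(s)
        likelihoods.append(like)
    if not structures:
        raise RuntimeError(f"every ensemble run failed: {errors}")
    return EnsembleResult(structures=structures, likelihoods=likelihoods,
                          alpha=alpha, alpha_table=table)


def select_representative(ens: EnsembleResult, method: str = "likelihood") -> Structure3D:
    """Pick one structure: ``likelihood`` (max) or ``medoid`` (highest
    mean TM-score against the rest of the ensemble)."""
    if method == "likelihood":
        return ens.structures[int(np.argmax(ens.likelihoods))]
    if method == "medoid":
        from unicorn_hic.metrics import tm_score

        n = len(ens.structures)
        if n == 1:
            return ens.structures[0]
        means = []
        for a in range(n):
            scores = [tm_score(ens.structures[a], ens.structures[b])
                      for b in range(n) if b != a]
            means.append(np.mean(scores))
        return ens.structures[int(np.argmax(means))]
    raise ValueError(f"unknown selector {method!r}")


def _range_bins(rng) -> np.ndarray:
    if isinstance(rng, tuple) and len(rng) == 2:
        bins = np.arange(rng[0], rng[1])
    else:
        bins = np.asarray(list(rng), dtype=int)
    if bins.size == 0:
        raise ValueError("empty bin range")
    return bins


def probe_distance(s: Structure3D, bin_a_range, bin_b_range) -> float:
    """Euclidean distance between the centroids of two bin ranges.

    Ranges are ``(start, stop)`` half-open bin tuples or explicit bin
    iterables; the result is in model units.
    """
    a = _range_bins(bin_a_range)
    b = _range_bins(bin_b_range)
    for bins in (a, b):
        if bins.min() < 0 or bins.max() >= s.n_loci:
            raise ValueError("bin range outside structure")
    ca = s.coords[a].mean(axis=0)
    cb = s.coords[b].mean(axis=0)
    return float(np.linalg.norm(ca - cb))


def write_structure(s: Structure3D, path: str | Path, format: str = "xyz") -> None:
    """Write coordinates as XYZ text (``bin x y z``, exact round trip)
    or as a PDB of CA pseudo-atoms (coordinates scaled to fit the fixed
    8.3 field width when necessary)."""
    path = Path(path)
    if format == "xyz":
        with open(path, "w") as fh:
            for b, (x, y, z) in zip(s.locus_bins, s.coords):
                fh.write(f"{int(b)}\t{float(x)!r}\t{float(y)!r}\t{float(z)!r}\n")
        return
    if format == "pdb":
        coords = s.coords
        span = np.abs(coords).max()
        scale = 999.0 / span if span > 999.0 else 1.0
        with open(path, "w") as fh:
            fh.write(f"HEADER    CHROMATIN MODEL {s.chrom}\n")
            for k, (x, y, z) in enumerate(coords * scale, start=1):
                fh.write(
                    f"ATOM  {k:5d}  CA  GLY A{k:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n")
            fh.write("TER\nEND\n")
        return
    raise ValueError(f"unknown format {format!r}")


def read_xyz(path: str | Path, resolution_bp: int = 1, chrom: str = "chr?") -> Structure3D:
    bins, pts = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            bins.append(int(parts[0]))
            pts.append([float(p) for p in parts[1:4]])
    return Structure3D(np.asarray(pts), locus_bins=np.asarray(bins),
                       resolution_bp=resolution_bp, chrom=chrom)
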