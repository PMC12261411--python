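"""Evaluation metrics for contact maps and 3D structures.

Map-level: PSNR, SSIM, GenomeDISCO reproducibility, insulation-score
consistency.  Structure-level: least-squares (Kabsch) superposition,
RMSD, TM-score, and Pearson correlation of distance vectors.

Conventions that shift absolute values (PSNR ``MAX``, SSIM window,
GenomeDISCO walk length) are parameters with documented defaults and are
echoed in the report objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from unicorn_hic.hic_io import ContactMap

__all__ = [
    "MapPairReport",
    "StructurePairReport",
    "psnr",
    "PSNR_CAP_DB",
    "ssim",
    "genomedisco",
    "pearson",
    "superpose",
    "tm_score",
    "insulation_scores",
    "insulation_l2",
    "compare_maps",
]

#: Sentinel PSNR (dB) reported when the two matrices are identical (MSE = 0).
PSNR_CAP_DB = 99.0


@dataclass(frozen=True)
class MapPairReport:
    """All contact-map metrics for one pair, with the conventions used."""

    psnr_db: float
    psnr_capped: bool
    ssim: float
    genomedisco: float
    max_value: float
    ssim_window: int
    disco_t: int


@dataclass(frozen=True)
class StructurePairReport:
    """Rigid superposition result: transform, RMSD and derived scores."""

    rmsd: float
    rotation: np.ndarray
    translation: np.ndarray
    reflected: bool


def _as_matrix(x) -> np.ndarray:
    m = x.matrix if isinstance(x, ContactMap) else np.asarray(x, dtype=float)
    return np.asarray(m, dtype=float)


def _resolve_max(a: np.ndarray, b: np.ndarray, max_value) -> float:
    if max_value is None or max_value == "auto":
        m = float(max(a.max(), b.max()))
        if m <= 0:
            raise ValueError("auto MAX is non-positive; pass max_value explicitly")
        return m
    m = float(max_value)
    if m <= 0:
        raise ValueError("max_value must be positive")
    return m


def psnr(a, b, max_value="auto") -> float:
    """Peak signal-to-noise ratio ``10*log10(MAX^2 / MSE)`` in dB.

    ``max_value='auto'`` uses the maximum over both matrices.  Identical
    inputs (MSE = 0) return the capped sentinel :data:`PSNR_CAP_DB`.
    """
    a, b = _as_matrix(a), _as_matrix(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    mx = _resolve_max(a, b, max_value)
    if mse == 0.0:
        return PSNR_CAP_DB
    return min(10.0 * np.log10(mx * mx / mse), PSNR_CAP_DB)


def ssim(a, b, max_value="auto", alpha_c: float = 0.01, beta_c: float = 0.03,
         window: int = 7) -> float:
    """Structural similarity index with uniform sliding window.

    The stabilization constants are ``D1 = (alpha_c*M)^2`` and
    ``D2 = (beta_c*M)^2`` where ``M`` is the value range.  Local means,
    variances (population form) and covariance are computed over a
    ``window``×``window`` uniform window; the reported value is the mean
    of the local SSIM map over the valid (fully covered) region.  For
    matrices smaller than the window a single global window is used.
    """
    a, b = _as_matrix(a), _as_matrix(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    m = _resolve_max(a, b, max_value)
    d1 = (alpha_c * m) ** 2
    d2 = (beta_c * m) ** 2

    if min(a.shape) < window:
        mu_a, mu_b = a.mean(), b.mean()
        va, vb = a.var(), b.var()
        cov = ((a - mu_a) * (b - mu_b)).mean()
        return float(((2 * mu_a * mu_b + d1) * (2 * cov + d2))
                     / ((mu_a ** 2 + mu_b ** 2 + d1) * (va + vb + d2)))

    mu_a = uniform_filter(a, window)
    mu_b = uniform_filter(b, window)
    va = uniform_filter(a * a, window) - mu_a ** 2
    vb = uniform_filter(b * b, window) - mu_b ** 2
    cov = uniform_filter(a * b, window) - mu_a * mu_b
    smap = ((2 * mu_a * mu_b + d1) * (2 * cov + d2)) / (
        (mu_a ** 2 + mu_b ** 2 + d1) * (va + vb + d2))
    pad = window // 2
    return float(smap[pad:-pad or None, pad:-pad or None].mean())


def _transition(m: np.ndarray) -> np.ndarray:
    rows = m.sum(axis=1)
    t = np.zeros_like(m)
    nz = rows > 0
    t[nz] = m[nz] / rows[nz, None]
    return t


def genomedisco(a, b, t_steps: int = 3) -> float:
    """GenomeDISCO reproducibility score for two contact maps.

    Each map is row-normalized to a random-walk transition matrix
    (all-zero rows stay zero) and raised to the power ``t_steps``; the
    score is ``1 - sum|A^t - B^t| / mean(nonzero rows of A, B)``.
    Identical maps score exactly 1; the score is unbounded below.
    """
    a, b = _as_matrix(a), _as_matrix(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    nza = int(np.count_nonzero(a.sum(axis=1)))
    nzb = int(np.count_nonzero(b.sum(axis=1)))
    if nza == 0 and nzb == 0:
        raise ValueError("both maps are all-zero; GenomeDISCO undefined")
    ta = np.linalg.matrix_power(_transition(a), t_steps)
    tb = np.linalg.matrix_power(_transition(b), t_steps)
    diff = float(np.abs(ta - tb).sum())
    denom = (nza + nzb) / 2.0
    return 1.0 - diff / denom


def pearson(x, y) -> float:
    """Pearson correlation coefficient, two-pass centered form."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("need at least two points")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = float(np.sqrt((dx * dx).sum()))
    sy = float(np.sqrt((dy * dy).sum()))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance input; correlation undefined")
    return float(np.clip((dx * dy).sum() / (sx * sy), -1.0, 1.0))


def _coords(s) -> np.ndarray:
    c = getattr(s, "coords", s)
    return np.asarray(c, dtype=float)


def _kabsch(p: np.ndarray, q: np.ndarray, weights: np.ndarray | None = None,
            allow_reflection: bool = True) -> tuple[np.ndarray, np.ndarray, bool]:
    """Optimal rigid transform (R, t) minimizing ||p - (q @ R.T + t)||_w.

    Returns the rotation matrix, translation vector and whether a
    reflection was used (only possible when ``allow_reflection``).
    """
    if weights is None:
        weights = np.ones(len(p))
    w = weights / weights.sum()
    pc = (w[:, None] * p).sum(axis=0)
    qc = (w[:, None] * q).sum(axis=0)
    p0, q0 = p - pc, q - qc
    c = (w[:, None] * q0).T @ p0
    u, _, vt = np.linalg.svd(c)
    det = np.linalg.det(vt.T @ u.T)
    reflected = False
    if det < 0 and not allow_reflection:
        d = np.ones(3)
        d[-1] = -1.0
        r = vt.T @ np.diag(d) @ u.T
    else:
        r = vt.T @ u.T
        reflected = det < 0
    t = pc - r @ qc
    return r, t, bool(reflected)


def superpose(a, b, allow_reflection: bool = True) -> StructurePairReport:
    """Least-squares rigid superposition of structure ``b`` onto ``a``.

    Reflections are allowed by default because contact data cannot
    determine chirality; pass ``allow_reflection=False`` to restrict to
    proper rotations.
    """
    p, q = _coords(a), _coords(b)
    if p.shape != q.shape:
        raise ValueError("structures must have equal locus counts")
    if len(p) < 3:
        raise ValueError("need at least 3 loci")
    r, t, refl = _kabsch(p, q, allow_reflection=allow_reflection)
    moved = q @ r.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((p - moved) ** 2, axis=1))))
    return StructurePairReport(rmsd=rmsd, rotation=r, translation=t, reflected=refl)


def tm_d0(n_loci: int, d0_min: float = 0.5) -> float:
    """Length-dependent TM-score normalization distance."""
    return max(1.24 * np.cbrt(max(n_loci - 15, 0)) - 1.8, d0_min)


def tm_score(a, b, allow_reflection: bool = True, max_refine: int = 20) -> float:
    """TM-score between two equal-length structures, in (0, 1].

    Starts from the least-squares superposition and iteratively
    reweights it toward the TM objective (weights ``1/(1+(d/d0)^2)^2``),
    then reports ``mean(1 / (1 + (d_i/d0)^2))`` with
    ``d0 = max(1.24*(L-15)^(1/3) - 1.8, 0.5)``.
    """
    p, q = _coords(a), _coords(b)
    if p.shape != q.shape:
        raise ValueError("structures must have equal locus counts")
    n = len(p)
    if n < 3:
        raise ValueError("need at least 3 loci")
    d0 = tm_d0(n)

    def score(moved):
        d2 = np.sum((p - moved) ** 2, axis=1)
        return float(np.mean(1.0 / (1.0 + d2 / d0 ** 2)))

    r, t, _ = _kabsch(p, q, allow_reflection=allow_reflection)
    best = score(q @ r.T + t)
    for _ in range(max_refine):
        moved = q @ r.T + t
        d2 = np.sum((p - moved) ** 2, axis=1)
        w = 1.0 / (1.0 + d2 / d0 ** 2) ** 2
        r, t, _ = _kabsch(p, q, weights=w, allow_reflection=allow_reflection)
        s = score(q @ r.T + t)
        if s <= best + 1e-12:
            break
        best = s
    return best


def insulation_scores(cm, window_bins: int) -> np.ndarray:
    """Diagonal insulation profile of a contact map.

    For each interior bin ``i`` the mean count in the off-diagonal
    square ``[i-w, i) x (i, i+w]`` is taken, then log2-normalized by the
    mean of those values over all interior bins.  Minima of the profile
    mark TAD boundaries.  Window means are floored at 1e-12 so the
    profile stays finite when a window is empty.
    """
    m = _as_matrix(cm)
    n = m.shape[0]
    w = int(window_bins)
    if w < 1:
        raise ValueError("window_bins must be >= 1")
    if n <= 2 * w:
        raise ValueError(f"matrix side {n} too small for window {w}")
    raw = np.empty(n - 2 * w)
    for k, i in enumerate(range(w, n - w)):
        raw[k] = m[i - w:i, i + 1:i + w + 1].mean()
    mean = raw.mean()
    if mean <= 0:
        raise ValueError("all insulation windows are empty")
    return np.log2(np.maximum(raw / mean, 1e-12))


def insulation_l2(a, b, window_bins: int) -> float:
    """Euclidean distance between two insulation profiles (lower = more
    consistent TAD topology)."""
    sa = insulation_scores(a, window_bins)
    sb = insulation_scores(b, window_bins)
    return float(np.linalg.norm(sa - sb))


def compare_maps(a: ContactMap, b: ContactMap, max_value="auto",
                 ssim_window: int = 7, disco_t: int = 3) -> MapPairReport:
    """All map-level metrics for one pair, with conventions echoed."""
    am, bm = _as_matrix(a), _as_matrix(b)
    mx = _resolve_max(am, bm, max_value)
    p = psnr(am, bm, max_value=mx)
    return MapPairReport(
        psnr_db=p,
        psnr_capped=p >= PSNR_CAP_DB,
        ssim=ssim(am, bm, max_value=mx, window=ssim_window),
        genomedisco=genomedisco(am, bm, t_steps=disco_t),
        max_value=mx,
        ssim_window=ssim_window,
        disco_t=disco_t,
    )
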