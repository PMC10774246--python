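"""Segmentation of the quantized volume: Otsu and Chan-Vese (ICTM).

Otsu's method exhaustively minimises the weighted within-class variance

    sigma_w^2(t) = omega_b(t) sigma_b^2(t) + omega_f(t) sigma_f^2(t)

over the 256-level histogram; the foreground is the bright class
(values >= t).

The Chan-Vese piecewise-constant energy

    F(c1, c2, C) = mu*area(C) + lambda1 int_inside |u0 - c1|^2
                               + lambda2 int_outside |u0 - c2|^2

is minimised by the iterative convolution-thresholding method (ICTM): the
interface (area) term is relaxed to sqrt(pi/tau) * sum u * (G_tau * (1-u))
with a Gaussian kernel G_tau, which makes the update a pointwise threshold of
a convolved field. Each sweep recomputes the region means c1 (inside) and c2
(outside), then sets u = 1 exactly where

    lambda1 (f - c1)^2 - lambda2 (f - c2)^2 + sqrt(pi/tau) G_tau*(1 - 2u) < 0.

Both the mean update and the thresholding step decrease the relaxed energy,
so the energy trace is non-increasing. The fidelity weight is parameterised
as lambda1(k, tau) = k * sqrt(pi/tau): the user chooses the step length tau
and the fidelity scale k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import DegenerateHistogramError, MaskCollapseError, SelectionError
from .preprocess import QuantizedVolume

__all__ = [
    "IntensityHistogram",
    "OtsuResult",
    "BinaryMask",
    "ICTMConfig",
    "ICTMState",
    "histogram_256",
    "otsu_threshold",
    "otsu_segment",
    "lambda1_of",
    "ictm_segment",
    "select_k",
]

_LEVELS = 256


@dataclass(frozen=True)
class IntensityHistogram:
    """Normalised 256-bin grey-level histogram."""

    p: np.ndarray
    n_voxels: int

    def __post_init__(self):
        if self.p.shape != (_LEVELS,):
            raise ValueError("histogram must have 256 bins")


@dataclass(frozen=True)
class OtsuResult:
    """Minimising threshold plus the class statistics at that threshold."""

    threshold: int
    sigma_w2: float
    omega_b: float
    omega_f: float
    sigma_b2: float
    sigma_f2: float


@dataclass(frozen=True)
class BinaryMask:
    """Binary segmentation with physical voxel size."""

    u: np.ndarray  # bool
    voxel_size: float

    @property
    def segmented_volume_ml(self) -> float:
        return int(self.u.sum()) * self.voxel_size**3 / 1000.0

    def to_nifti(self, path) -> None:
        affine = np.diag([self.voxel_size] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.u.astype(np.uint8), affine), str(path))


def lambda1_of(k: float, tau: float) -> float:
    """Fidelity weight lambda1(k, tau) = k * sqrt(pi / tau)."""
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    if k < 0:
        raise ValueError(f"k must be non-negative, got {k}")
    return k * np.sqrt(np.pi / tau)


@dataclass
class ICTMConfig:
    """ICTM parameters.

    tau is the step length (kernel variance is 2*tau in voxel units); k sets
    the fidelity scale through lambda1 = k*sqrt(pi/tau); lambda2 defaults to
    lambda1 (symmetric fidelity). init is 'otsu' (threshold of the input,
    deterministic and content-aware) or 'sphere'.
    """

    tau: float = 0.3
    k: float = 3e-4
    lambda1: float | None = None
    lambda2: float | None = None
    max_iterations: int = 500
    init: str = "otsu"
    seed: int | None = None

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.k < 0:
            raise ValueError("k must be non-negative")
        if self.lambda1 is None:
            self.lambda1 = lambda1_of(self.k, self.tau)
        if self.lambda2 is None:
            self.lambda2 = self.lambda1
        if self.init not in ("otsu", "sphere"):
            raise ValueError(f"unknown init strategy {self.init!r}")


@dataclass
class ICTMState:
    """Final mask with region means, energy trace and convergence flag."""

    mask: BinaryMask
    c1: float
    c2: float
    energy_trace: list[float] = field(default_factory=list)
    converged: bool = False
    iterations: int = 0


def histogram_256(q: QuantizedVolume) -> IntensityHistogram:
    """Normalised histogram over all voxels of an 8-bit volume."""
    values = q.values
    if values.size == 0:
        raise ValueError("empty volume")
    counts = np.bincount(values.ravel(), minlength=_LEVELS).astype(np.float64)
    return IntensityHistogram(p=counts / values.size, n_voxels=values.size)


def _class_stats(p: np.ndarray):
    """Cumulative class weights/means/variances for every threshold t=0..256."""
    i = np.arange(_LEVELS, dtype=np.float64)
    w_cum = np.concatenate([[0.0], np.cumsum(p)])  # w_cum[t] = sum_{i<t} p(i)
    m_cum = np.concatenate([[0.0], np.cumsum(p * i)])
    s_cum = np.concatenate([[0.0], np.cumsum(p * i * i)])
    return i, w_cum, m_cum, s_cum


def otsu_threshold(h: IntensityHistogram) -> OtsuResult:
    """Exhaustive minimiser of the weighted within-class variance.

    All candidate thresholds t = 1..255 are evaluated; ties are broken by the
    smallest t; a class with zero weight contributes zero variance.
    """
    p = h.p
    if (p > 0).sum() < 2:
        raise DegenerateHistogramError("histogram needs at least two occupied bins")
    _, w_cum, m_cum, s_cum = _class_stats(p)
    total_w, total_m, total_s = w_cum[-1], m_cum[-1], s_cum[-1]

    t = np.arange(1, _LEVELS)
    wb = w_cum[t]
    wf = total_w - wb
    mb_sum = m_cum[t]
    mf_sum = total_m - mb_sum
    with np.errstate(divide="ignore", invalid="ignore"):
        mb = np.where(wb > 0, mb_sum / wb, 0.0)
        mf = np.where(wf > 0, mf_sum / wf, 0.0)
        vb = np.where(wb > 0, s_cum[t] / wb - mb**2, 0.0)
        vf = np.where(wf > 0, (total_s - s_cum[t]) / wf - mf**2, 0.0)
    vb = np.clip(vb, 0.0, None)  # guard tiny negative round-off
    vf = np.clip(vf, 0.0, None)
    sigma_w2 = wb * vb + wf * vf
    best = int(np.argmin(sigma_w2))  # argmin returns the first (smallest t) tie
    return OtsuResult(
        threshold=int(t[best]),
        sigma_w2=float(sigma_w2[best]),
        omega_b=float(wb[best]),
        omega_f=float(wf[best]),
        sigma_b2=float(vb[best]),
        sigma_f2=float(vf[best]),
    )


def otsu_segment(q: QuantizedVolume) -> BinaryMask:
    """Threshold the volume at the Otsu level (foreground: values >= t)."""
    res = otsu_threshold(histogram_256(q))
    return BinaryMask(u=q.values >= res.threshold, voxel_size=q.voxel_size)


def _initial_mask(q: QuantizedVolume, cfg: ICTMConfig) -> np.ndarray:
    if cfg.init == "otsu":
        return otsu_segment(q).u.copy()
    shape = np.array(q.values.shape)
    center = (shape - 1) / 2.0
    radius = shape.min() / 4.0
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def _ictm_energy(f, u, c1, c2, lam1, lam2, gamma, sigma):
    fid = lam1 * float(((f - c1) ** 2)[u].sum()) + lam2 * float(
        ((f - c2) ** 2)[~u].sum()
    )
    conv = ndimage.gaussian_filter((~u).astype(np.float64), sigma, mode="nearest", truncate=4.0)
    return fid + gamma * float(conv[u].sum())


def ictm_segment(q: QuantizedVolume, cfg: ICTMConfig | None = None) -> ICTMState:
    """Chan-Vese segmentation by iterative convolution-thresholding.

    Stops when the mask is unchanged between sweeps (exact binary fixed
    point) or after ``cfg.max_iterations`` sweeps (flagged unconverged).
    Raises :class:`MaskCollapseError` if the mask becomes empty or fills the
    volume, reporting the offending k.
    """
    cfg = cfg or ICTMConfig()
    f = q.values.astype(np.float64)
    gamma = np.sqrt(np.pi / cfg.tau)
    sigma = np.sqrt(2.0 * cfg.tau)  # kernel variance 2*tau, voxel units

    u = _initial_mask(q, cfg)
    if not u.any() or u.all():
        raise MaskCollapseError("initial mask is degenerate", k=cfg.k)

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, cfg.max_iterations + 1):
        c1 = float(f[u].mean())
        c2 = float(f[~u].mean())
        conv = ndimage.gaussian_filter(
            1.0 - 2.0 * u, sigma, mode="nearest", truncate=4.0
        )
        phi = (
            cfg.lambda1 * (f - c1) ** 2
            - cfg.lambda2 * (f - c2) ** 2
            + gamma * conv
        )
        u_new = phi < 0
        if not u_new.any() or u_new.all():
            raise MaskCollapseError(
                f"mask collapsed to {'full' if u_new.all() else 'empty'} volume "
                f"at iteration {it}",
                k=cfg.k,
            )
        trace.append(
            _ictm_energy(f, u_new, float(f[u_new].mean()), float(f[~u_new].mean()),
                         cfg.lambda1, cfg.lambda2, gamma, sigma)
        )
        if (u_new == u).all():
            converged = True
            break
        u = u_new

    c1 = float(f[u].mean())
    c2 = float(f[~u].mean())
    return ICTMState(
        mask=BinaryMask(u=u, voxel_size=q.voxel_size),
        c1=c1,
        c2=c2,
        energy_trace=trace,
        converged=converged,
        iterations=it,
    )


def select_k(
    q: QuantizedVolume,
    k_grid,
    cfg_base: ICTMConfig | None = None,
    plateau_rel_tol: float = 0.05,
):
    """Pick k from a volume-vs-k curve by the widest-plateau rule.

    Runs the ICTM at every candidate, records segmented volumes, and returns
    the centre of the longest run of consecutive k values whose volumes agree
    pairwise within ``plateau_rel_tol``; the full curve is returned for
    audit. Candidates whose mask collapses are recorded as NaN. If no
    plateau of length >= 2 exists the base configuration's k is returned.
    """
    cfg_base = cfg_base or ICTMConfig()
    k_grid = sorted(float(k) for k in k_grid)
    if not k_grid:
        raise ValueError("k_grid is empty")

    curve = []
    for k in k_grid:
        cfg = ICTMConfig(
            tau=cfg_base.tau,
            k=k,
            max_iterations=cfg_base.max_iterations,
            init=cfg_base.init,
        )
        try:
            state = ictm_segment(q, cfg)
            curve.append((k, state.mask.segmented_volume_ml))
        except MaskCollapseError:
            curve.append((k, np.nan))

    vols = np.array([v for _, v in curve])
    if np.isnan(vols).all():
        raise SelectionError("every candidate k collapsed")
    if len(k_grid) == 1:
        return k_grid[0], curve

    best_start, best_len = None, 0
    start = 0
    for i in range(len(vols)):
        window = vols[start : i + 1]
        ok = (
            not np.isnan(window).any()
            and (window.max() - window.min()) < plateau_rel_tol * window.mean()
        )
        while not ok and start < i:
            start += 1
            window = vols[start : i + 1]
            ok = (
                not np.isnan(window).any()
                and (window.max() - window.min()) < plateau_rel_tol * window.mean()
            )
        if ok and i - start + 1 > best_len:
            best_start, best_len = start, i - start + 1
    if best_len < 2:
        return cfg_base.k, curve
    return k_grid[best_start + best_len // 2], curve
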