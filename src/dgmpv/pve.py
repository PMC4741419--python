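"""Two-tissue partial-volume estimation on quantitative T1 maps.

Model
-----
Within one deep gray matter region, every voxel value is a mixture of two
tissue-characteristic T1 values with additive Gaussian noise::

    y_i = mu_gm * c_i + mu_wm * (1 - c_i) + eps_i,   eps_i ~ N(0, sigma)

where ``mu_gm > mu_wm`` are region-global characteristic intensities (the T1
of 100% gray and 100% white matter) and ``c_i`` in [0, 1] is the local GM
concentration.  The concentrations are latent: treating them as free
per-voxel parameters makes the least-squares objective degenerate (any
(mu_gm, mu_wm) bracket covering the data range fits exactly), so the fit
maximizes the marginal likelihood with the concentrations integrated out
under a uniform prior on [0, 1]:

    p(y_i | mu_gm, mu_wm, sigma)
        = [Phi((y_i - mu_wm)/sigma) - Phi((y_i - mu_gm)/sigma)] / (mu_gm - mu_wm)

The ``1/(mu_gm - mu_wm)`` factor penalizes needlessly wide brackets and makes
the problem identifiable; for noise-free data the maximizer collapses onto
the tightest bracket covering the data, which equals the true pair whenever
the region contains (near-)pure voxels of both tissues.

Fitting alternates the two steps of the source algorithm: Step 1 estimates
the concentration map given the characteristic values (the posterior mean of
``c_i``, which reduces to ``clip((y_i - mu_wm)/(mu_gm - mu_wm), 0, 1)`` as
``sigma -> 0``); Step 2 re-estimates the characteristic intensities by
(variance-corrected) least squares.  These EM iterations monotonically
decrease the marginal negative log-likelihood; a bounded quasi-Newton
polish then drives the three parameters to the optimum, with dedicated
handling of the noise-free boundary where the likelihood collapses onto
the tightest bracket covering the data (see :func:`_polish`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr

from .volumes import BinaryMask, LabelVolume, QuantitativeT1Volume, require_same_grid

log = logging.getLogger(__name__)

DEFAULT_INIT_GM = 1350.0  # standard GM T1 at 3T, ms
DEFAULT_INIT_WM = 850.0   # standard WM T1 at 3T, ms
DEFAULT_N_ITER = 10
DEFAULT_MIN_VOXELS = 20

_SQRT_2PI = np.sqrt(2.0 * np.pi)
_TINY = 1e-300


class NonIdentifiableError(ValueError):
    """The data cannot pin down the two characteristic intensities."""


class DegenerateFitError(NonIdentifiableError):
    """Rank-deficient design in the intensity re-estimation step."""


@dataclass(frozen=True)
class TissueIntensities:
    """Region-global characteristic T1 pair and residual noise scale (ms)."""

    mu_gm: float
    mu_wm: float
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if not (self.mu_gm > self.mu_wm > 0):
            raise ValueError(
                f"require mu_gm > mu_wm > 0, got ({self.mu_gm}, {self.mu_wm})")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


@dataclass
class ConcentrationField:
    """Per-voxel GM fraction over a region's voxel set.

    Only the GM concentration is stored; the WM concentration is its
    complement under the two-tissue closure c_gm + c_wm = 1.
    """

    c_gm: np.ndarray

    def __post_init__(self) -> None:
        self.c_gm = np.asarray(self.c_gm, dtype=np.float64).ravel()
        if self.c_gm.size and (self.c_gm.min() < -1e-12 or self.c_gm.max() > 1 + 1e-12):
            raise ValueError("concentrations must lie in [0, 1]")
        self.c_gm = np.clip(self.c_gm, 0.0, 1.0)

    @property
    def c_wm(self) -> np.ndarray:
        return 1.0 - self.c_gm

    def __len__(self) -> int:
        return self.c_gm.size


@dataclass
class PVEFitResult:
    """Outcome of the alternating partial-volume fit on one voxel set."""

    intensities: TissueIntensities
    concentrations: ConcentrationField
    objective_trace: np.ndarray      # marginal NLL per iteration, non-increasing
    n_iterations: int
    converged_early: bool
    rss: float                       # conditional residual sum of squares (ms^2)
    n_voxels: int
    sigma_marginal: float = 0.0      # noise scale at which the final objective holds
    region: str | None = None
    voxel_indices: tuple | None = None

    @property
    def nll(self) -> float:
        return float(self.objective_trace[-1])

    def concentration_volume(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Scatter the GM concentrations back onto the grid (background 0)."""
        if self.voxel_indices is None:
            raise ValueError("fit has no recorded voxel coordinates")
        out = np.zeros(shape, dtype=np.float64)
        out[self.voxel_indices] = self.concentrations.c_gm
        return out


@dataclass
class PVEOptions:
    """Tunable knobs of the per-region fit."""

    init_gm: float = DEFAULT_INIT_GM
    init_wm: float = DEFAULT_INIT_WM
    n_iter: int = DEFAULT_N_ITER
    tol: float = 0.0            # early-stop threshold on parameter change (ms); 0 = off
    polish: bool = True
    min_voxels: int = DEFAULT_MIN_VOXELS

    def init_intensities(self) -> TissueIntensities:
        return TissueIntensities(self.init_gm, self.init_wm)


# ---------------------------------------------------------------------------
# Step 1: concentrations given intensities
# ---------------------------------------------------------------------------

def _phi(x: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * np.clip(x * x, 0.0, 1400.0)) / _SQRT_2PI


def _posterior_moments(y, mu_gm, mu_wm, sigma):
    """Posterior mean/variance of c_i ~ U[0,1] given y_i (truncated normal)."""
    d = mu_gm - mu_wm
    m = (y - mu_wm) / d
    s = sigma / d
    lo = -m / s
    hi = (1.0 - m) / s
    z = ndtr(hi) - ndtr(lo)
    with np.errstate(all="ignore"):
        p_lo, p_hi = _phi(lo), _phi(hi)
        mean = m + s * (p_lo - p_hi) / z
        var = s * s * (1.0 + (lo * p_lo - hi * p_hi) / z - ((p_lo - p_hi) / z) ** 2)
    degenerate = z < 1e-12
    mean = np.where(degenerate, np.clip(m, 0.0, 1.0), np.clip(mean, 0.0, 1.0))
    var = np.where(degenerate, 0.0,
                   np.clip(np.nan_to_num(var, nan=0.0, posinf=0.0, neginf=0.0),
                           0.0, 0.25))
    return mean, var


def estimate_concentrations(y, intensities: TissueIntensities) -> ConcentrationField:
    """Step 1: per-voxel GM concentration given characteristic intensities.

    With ``sigma == 0`` this is the constrained least-squares solution
    ``clip((y - mu_wm) / (mu_gm - mu_wm), 0, 1)``; with ``sigma > 0`` it is
    the posterior mean of the latent concentration, which smoothly
    approaches the clipped ratio as the noise vanishes.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    if intensities.mu_gm == intensities.mu_wm:  # unreachable via the type, kept for raw use
        raise NonIdentifiableError("mu_gm == mu_wm: concentrations undefined")
    if intensities.sigma == 0:
        c = np.clip((y - intensities.mu_wm)
                    / (intensities.mu_gm - intensities.mu_wm), 0.0, 1.0)
        return ConcentrationField(c)
    mean, _ = _posterior_moments(y, intensities.mu_gm, intensities.mu_wm,
                                 intensities.sigma)
    return ConcentrationField(mean)


# ---------------------------------------------------------------------------
# Step 2: intensities given concentrations
# ---------------------------------------------------------------------------

def _solve_normal_equations(y, c, c_var=None):
    """Least-squares (mu_gm, mu_wm) for y ~ mu_gm*c + mu_wm*(1-c).

    ``c_var`` adds the per-voxel concentration variance (EM moment
    correction).  Returns (mu_gm, mu_wm, rss) without ordering enforcement,
    or None when the 2x2 system is numerically rank-deficient.
    """
    v = np.zeros_like(c) if c_var is None else c_var
    s_cc = float(np.sum(c * c + v))
    s_cw = float(np.sum(c * (1.0 - c) - v))
    s_ww = float(np.sum((1.0 - c) ** 2 + v))
    det = s_cc * s_ww - s_cw * s_cw
    if det <= 1e-10 * max(s_cc * s_ww, 1.0):
        return None
    r_g = float(y @ c)
    r_w = float(y @ (1.0 - c))
    mu_gm = (s_ww * r_g - s_cw * r_w) / det
    mu_wm = (s_cc * r_w - s_cw * r_g) / det
    resid = y - mu_gm * c - mu_wm * (1.0 - c)
    rss = float(resid @ resid + (mu_gm - mu_wm) ** 2 * v.sum())
    return mu_gm, mu_wm, rss


def estimate_tissue_intensities(y, c: ConcentrationField | np.ndarray) -> TissueIntensities:
    """Step 2: ordinary-least-squares characteristic intensities.

    Minimizes ``sum_i (y_i - mu_gm c_i - mu_wm (1 - c_i))^2`` in closed form
    and reports ``sigma = sqrt(RSS / N)``.  Raises
    :class:`DegenerateFitError` when all concentrations are equal (rank-1
    design) and :class:`NonIdentifiableError` when the solution violates the
    ``mu_gm > mu_wm`` ordering.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    c_arr = c.c_gm if isinstance(c, ConcentrationField) else np.asarray(c, float).ravel()
    if y.size != c_arr.size:
        raise ValueError("y and concentrations differ in length")
    sol = _solve_normal_equations(y, c_arr)
    if sol is None:
        raise DegenerateFitError(
            "all concentrations are (numerically) equal: the design matrix "
            "of regressors (c, 1-c) has rank 1 and the intensity pair is "
            "not identifiable for this ROI")
    mu_gm, mu_wm, rss = sol
    if not mu_gm > mu_wm:
        raise NonIdentifiableError(
            f"fitted intensities violate mu_gm > mu_wm "
            f"({mu_gm:.2f} <= {mu_wm:.2f}); the ROI does not support the "
            "two-tissue ordering")
    sigma = float(np.sqrt(max(rss, 0.0) / y.size))
    return TissueIntensities(mu_gm, mu_wm, sigma)


# ---------------------------------------------------------------------------
# Marginal likelihood and the full alternating fit
# ---------------------------------------------------------------------------

def marginal_nll(y, mu_gm: float, mu_wm: float, sigma: float) -> float:
    """Negative log-likelihood of the uniform-concentration mixture model."""
    y = np.asarray(y, dtype=np.float64).ravel()
    if not (mu_gm > mu_wm) or sigma <= 0:
        return np.inf
    z = ndtr((y - mu_wm) / sigma) - ndtr((y - mu_gm) / sigma)
    z = np.maximum(z, _TINY)
    return float(np.sum(np.log(mu_gm - mu_wm) - np.log(z)))


def _nll_and_grad(p: np.ndarray, y: np.ndarray):
    """Marginal NLL and gradient in the (mu_wm, log width, log sigma) chart."""
    with np.errstate(all="ignore"):
        b, log_d, log_s = p
        d, sig = np.exp(log_d), np.exp(log_s)
        a = b + d
        za = (y - a) / sig
        zb = (y - b) / sig
        z = np.maximum(ndtr(zb) - ndtr(za), _TINY)
        f = float(np.sum(np.log(d) - np.log(z)))
        pa, pb = _phi(za), _phi(zb)
        n = y.size
        df_da = n / d - float(np.sum(pa / (sig * z)))
        df_db = -n / d + float(np.sum(pb / (sig * z)))
        df_dsig = -float(np.sum((pa * za - pb * zb) / (sig * z)))
        g = np.array([df_da + df_db, df_da * d, df_dsig * sig])
    if not np.isfinite(f):
        f = 1e300
    g = np.nan_to_num(g, nan=0.0, posinf=1e12, neginf=-1e12)
    return f, np.clip(g, -1e12, 1e12)


def _polish(y, a, b, sigma, f_current):
    """Refine (mu_gm, mu_wm, sigma) by direct likelihood optimization.

    Bounded quasi-Newton with analytic gradients descends from the
    alternation's endpoint, with the noise scale floored at 1e-3 of the
    data span (the marginal likelihood has a degenerate sigma -> 0
    attractor where the bracket collapses onto the data hull; the floor
    keeps the descent well-posed).  When the descent rides down to the
    floor the data are treated as (near-)noise-free: a derivative-free
    continuation at the floor finishes the bracket search and the result
    is canonicalized to the data hull, which is the exact sigma -> 0
    limit of the maximum-likelihood bracket.

    Returns ``(mu_gm, mu_wm, sigma, nll, collapsed)``.
    """
    lo, hi = float(y.min()), float(y.max())
    span = hi - lo
    floor = 1e-3 * span
    bounds = [(lo - 10 * span, hi + 10 * span),
              (np.log(1e-4 * span), np.log(1e3 * span)),
              (np.log(floor), np.log(10 * span))]

    def clip_start(b0, d0, s0):
        return np.array([np.clip(b0, *bounds[0]),
                         np.clip(np.log(d0), *bounds[1]),
                         np.clip(np.log(s0), *bounds[2])])

    best = (a, b, sigma, f_current)
    res = minimize(_nll_and_grad, clip_start(b, a - b, sigma), args=(y,),
                   jac=True, method="L-BFGS-B", bounds=bounds,
                   options=dict(maxiter=500, ftol=1e-14, gtol=1e-10))
    if np.isfinite(res.fun) and res.fun < best[3]:
        b_n = float(res.x[0])
        d_n, s_n = float(np.exp(res.x[1])), float(np.exp(res.x[2]))
        best = (b_n + d_n, b_n, s_n, float(res.fun))
    a, b, sigma, f_val = best

    collapsed = sigma <= 3.0 * floor
    if collapsed:
        # bracket search at the floor, then snap to the hull limit
        log_s = np.log(floor)
        start = np.array([b, np.log(a - b)])
        for _ in range(3):
            res = minimize(
                lambda p: _nll_and_grad(np.r_[p, log_s], y)[0], start,
                method="Nelder-Mead",
                options=dict(maxiter=1500, xatol=1e-9, fatol=1e-11))
            if np.isfinite(res.fun) and res.fun < best[3]:
                b_n = float(res.x[0])
                d_n = float(np.exp(res.x[1]))
                best = (b_n + d_n, b_n, floor, float(res.fun))
            start = res.x
            if res.success:
                break
        a, b, sigma, f_val = best
        d = a - b
        # at the floor the optimal bracket sits within a few noise-floors
        # of the hull (inside for large samples, outside for small ones)
        slack = max(0.02 * d, 10.0 * floor)
        if abs(a - hi) < slack and abs(b - lo) < slack:
            best = (hi, lo, sigma, f_val)
    return (*best, collapsed)


def fit_pve(y,
            init: TissueIntensities | None = None,
            n_iter: int = DEFAULT_N_ITER,
            tol: float = 0.0,
            polish: bool = True) -> PVEFitResult:
    """Alternating estimation of concentrations and characteristic intensities.

    Runs ``n_iter`` Step-1/Step-2 iterations from ``init`` (default
    1350/850 ms, the standard 3T GM/WM values), optionally stopping early
    once the largest parameter change drops below ``tol`` (ms; 0 disables),
    then polishes the marginal likelihood directly.  The recorded
    ``objective_trace`` (marginal negative log-likelihood after each
    intensity update) is non-increasing.

    Raises :class:`NonIdentifiableError` for constant input, collapsed
    brackets, or an ordering violation of the final estimates.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    if y.size < 3:
        raise ValueError(f"need at least 3 voxels, got {y.size}")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite voxel values; clean the ROI first")
    lo, hi = float(y.min()), float(y.max())
    if hi - lo < 1e-9 * max(abs(hi), 1.0):
        raise NonIdentifiableError(
            "constant ROI: every voxel maps to a single concentration and "
            "the Step-2 design is rank-deficient")

    if init is None:
        init = TissueIntensities(DEFAULT_INIT_GM, DEFAULT_INIT_WM)
    a, b = float(init.mu_gm), float(init.mu_wm)
    if a <= lo or b >= hi:
        # the initial bracket misses the data range entirely: every voxel
        # would clamp to one pure tissue; restart from the data hull
        log.debug("initial bracket (%.0f, %.0f) disjoint from data range "
                  "[%.0f, %.0f]; re-initializing to the hull", a, b, lo, hi)
        a, b = hi, lo
    sigma = init.sigma if init.sigma > 0 else max(0.5 * float(y.std()), 1e-6)

    trace: list[float] = []
    converged_early = False
    for _ in range(int(n_iter)):
        e_c, v_c = _posterior_moments(y, a, b, sigma)
        sol = _solve_normal_equations(y, e_c, v_c)
        if sol is None:
            # bracket collapsed or wandered off; one rescue from the hull
            a_r, b_r = hi, lo
            e_c, v_c = _posterior_moments(y, a_r, b_r,
                                          max(0.1 * float(y.std()), 1e-6))
            sol = _solve_normal_equations(y, e_c, v_c)
            if sol is None:
                raise NonIdentifiableError(
                    "degenerate ROI: concentration estimates carry no "
                    "contrast between the two tissues")
        a_new, b_new, e_rss = sol
        sigma = float(np.sqrt(max(e_rss, 1e-24) / y.size))
        delta = max(abs(a_new - a), abs(b_new - b))
        a, b = a_new, b_new
        trace.append(marginal_nll(y, a, b, sigma))
        if tol > 0 and delta < tol:
            converged_early = True
            break

    collapsed = False
    if polish:
        a_p, b_p, s_p, f_p, collapsed = _polish(y, a, b, sigma, trace[-1])
        if f_p < trace[-1]:
            a, b, sigma = a_p, b_p, s_p
            trace.append(f_p)

    if not a > b:
        raise NonIdentifiableError(
            f"estimates lost the mu_gm > mu_wm ordering (mu_gm={a:.2f}, "
            f"mu_wm={b:.2f}); the ROI intensity distribution does not "
            "separate two tissue pools")

    sigma_marginal = max(sigma, 0.0)
    intensities = TissueIntensities(a, b, max(sigma, 0.0))
    if collapsed:
        # degenerate boundary: concentrations are the sigma -> 0 limit
        # (hard clip) and the reported noise is the conditional residual SD
        # (zero for exactly noise-free data) rather than the numerical floor
        conc = estimate_concentrations(y, TissueIntensities(a, b, 0.0))
        resid = y - a * conc.c_gm - b * conc.c_wm
        intensities = TissueIntensities(
            a, b, float(np.sqrt(max(resid @ resid, 0.0) / y.size)))
    else:
        conc = estimate_concentrations(y, intensities)
        resid = y - a * conc.c_gm - b * conc.c_wm
    return PVEFitResult(
        intensities=intensities,
        concentrations=conc,
        objective_trace=np.asarray(trace),
        n_iterations=len(trace),
        converged_early=converged_early,
        rss=float(resid @ resid),
        n_voxels=int(y.size),
        sigma_marginal=sigma_marginal,
    )


def fit_region(volume: QuantitativeT1Volume,
               labels: LabelVolume,
               region: str,
               lesions: BinaryMask | None = None,
               options: PVEOptions | None = None) -> PVEFitResult:
    """Fit the partial-volume model on one region's normal-appearing voxels.

    Lesion voxels are excluded first; non-finite or non-positive T1 values
    are dropped with a logged count.  Raises when the surviving voxel count
    falls below ``options.min_voxels``.
    """
    opts = options or PVEOptions()
    require_same_grid(volume, labels, "T1 map and label volume")
    mask = labels.region_mask(region).mask
    if not mask.any():
        raise ValueError(f"region {region!r} is empty in the label volume")
    if lesions is not None:
        require_same_grid(volume, lesions, "T1 map and lesion mask")
        mask = mask & ~lesions.mask
    idx = np.nonzero(mask)
    y = volume.values[idx]
    good = np.isfinite(y) & (y > 0)
    n_dropped = int((~good).sum())
    if n_dropped:
        log.warning("region %s: dropped %d non-finite/non-positive voxels",
                    region, n_dropped)
        y = y[good]
        idx = tuple(ax[good] for ax in idx)
    if y.size < opts.min_voxels:
        raise ValueError(
            f"region {region!r}: only {y.size} usable voxels after lesion "
            f"exclusion (minimum {opts.min_voxels})")
    result = fit_pve(y, init=opts.init_intensities(), n_iter=opts.n_iter,
                     tol=opts.tol, polish=opts.polish)
    result.region = region
    result.voxel_indices = idx
    return result
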