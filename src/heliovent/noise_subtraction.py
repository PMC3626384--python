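"""Statistical noise subtraction.

Background noise in magnitude MR images is Rayleigh distributed.  Each
slice's background is sampled from an automated 25 x 50 pixel box at the
bottom centre of the image, and its intensity histogram h(f) is fitted with
an *adjusted Rayleigh* curve

    r(f) = (alpha*f + delta) * exp(-(alpha*f + delta)^2 / (2 sigma^2)) / sigma^2

with scale ``sigma``, intensity scaling ``alpha`` and a horizontal shift
``delta``.  The optimal threshold tau_n minimises the error term

    eps_tau = sum_{f=0}^{tau-1} g(f) + sum_{f=tau}^{F} r(f),    g(f) = r(f) - h(f)

i.e. the (signed) model-minus-data residual kept below the threshold plus
the model noise mass left above it.  Pixels at or above tau_n form the
initial binary lung mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .image_io import ImageStack, MaskStack

BOX_ROWS = 25
BOX_COLS = 50

__all__ = [
    "NoiseHistogram",
    "NoiseFit",
    "adjusted_rayleigh",
    "sample_background",
    "background_box",
    "fit_adjusted_rayleigh",
    "compute_threshold",
    "apply_threshold",
    "fit_stack",
    "sample_adjusted_rayleigh",
]


class FitError(RuntimeError):
    """Degenerate histogram or optimiser failure."""


@dataclass(frozen=True)
class NoiseHistogram:
    """Unit-width integer-bin pmf of sampled background intensities.

    ``density[f]`` is the fraction of sampled pixels whose rounded intensity
    equals ``f``, for f = 0 .. f_max; the bins sum to 1.
    """

    density: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        d = np.asarray(self.density, dtype=float)
        if d.ndim != 1 or d.size == 0:
            raise ValueError("density must be a nonempty 1-D array")
        if np.any(d < 0) or abs(d.sum() - 1.0) > 1e-9:
            raise ValueError("density must be a pmf (nonnegative, sums to 1)")
        object.__setattr__(self, "density", d)

    @property
    def f(self) -> np.ndarray:
        """Integer intensity levels 0..f_max."""
        return np.arange(self.density.size)

    @property
    def f_max(self) -> int:
        return self.density.size - 1

    @property
    def n_populated(self) -> int:
        return int(np.count_nonzero(self.density))

    @classmethod
    def from_values(cls, values: np.ndarray) -> "NoiseHistogram":
        vals = np.rint(np.asarray(values, dtype=float).ravel()).astype(int)
        vals = np.clip(vals, 0, None)
        counts = np.bincount(vals)
        return cls(density=counts / counts.sum(), n_samples=vals.size)


@dataclass(frozen=True)
class NoiseFit:
    """Fitted adjusted-Rayleigh parameters and optimal threshold.

    ``tau`` is None until :func:`compute_threshold` has been applied.
    """

    sigma: float
    alpha: float
    delta: float
    rss: float
    tau: int | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.alpha <= 0:
            raise ValueError("sigma and alpha must be > 0")

    def r(self, f: np.ndarray | float) -> np.ndarray:
        return adjusted_rayleigh(f, self.sigma, self.alpha, self.delta)

    def with_tau(self, tau: int) -> "NoiseFit":
        return NoiseFit(self.sigma, self.alpha, self.delta, self.rss, tau=int(tau))


def adjusted_rayleigh(
    f: np.ndarray | float, sigma: float, alpha: float, delta: float
) -> np.ndarray:
    """Evaluate r(f); negative-argument values (alpha*f + delta < 0) clamp to 0."""
    f = np.asarray(f, dtype=float)
    u = alpha * f + delta
    r = np.where(u >= 0, u * np.exp(-np.square(u) / (2.0 * sigma**2)) / sigma**2, 0.0)
    return r


def background_box(
    n_rows: int, n_cols: int, box_rows: int = BOX_ROWS, box_cols: int = BOX_COLS
) -> tuple[slice, slice]:
    """Row/col slices of the bottom-centre sampling box.

    The box's bottom edge is the last image row; columns are centred, with an
    even/odd tie shifted left by one (integer floor of the margin).
    """
    if n_rows < box_rows or n_cols < box_cols:
        raise ValueError(
            f"slice ({n_rows}x{n_cols}) smaller than sampling box ({box_rows}x{box_cols})"
        )
    c0 = (n_cols - box_cols) // 2
    return slice(n_rows - box_rows, n_rows), slice(c0, c0 + box_cols)


def sample_background(
    slice_2d: np.ndarray, box_rows: int = BOX_ROWS, box_cols: int = BOX_COLS
) -> NoiseHistogram:
    """Histogram of the bottom-centre background box of one slice."""
    slice_2d = np.asarray(slice_2d)
    rows, cols = background_box(slice_2d.shape[0], slice_2d.shape[1], box_rows, box_cols)
    return NoiseHistogram.from_values(slice_2d[rows, cols])


def fit_adjusted_rayleigh(
    hist: NoiseHistogram,
    init: tuple[float, float, float] | None = None,
    max_iter: int = 1000,
) -> NoiseFit:
    """Least-squares fit of r(f) to the histogram pmf.

    Initialisation defaults to (sigma0 = empirical mode, alpha0 = 1,
    delta0 = 0); sigma and alpha are bounded below by 1e-6, delta is free.
    Deterministic given ``init``.
    """
    if hist.n_populated < 3:
        raise FitError(
            f"histogram has {hist.n_populated} populated bins; need >= 3 to fit"
        )
    f = hist.f.astype(float)
    h = hist.density
    if init is None:
        mode = float(np.argmax(h))
        init = (max(mode, 1.0), 1.0, 0.0)

    def residuals(p: np.ndarray) -> np.ndarray:
        return adjusted_rayleigh(f, p[0], p[1], p[2]) - h

    res = least_squares(
        residuals,
        x0=np.asarray(init, dtype=float),
        bounds=([1e-6, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
        max_nfev=max_iter,
        method="trf",
    )
    if not res.success:
        raise FitError(f"adjusted-Rayleigh fit did not converge: {res.message}; last iterate {res.x}")
    sigma, alpha, delta = (float(v) for v in res.x)
    return NoiseFit(sigma=sigma, alpha=alpha, delta=delta, rss=float(np.sum(res.fun**2)))


def _tail_limit(fit: NoiseFit, f_max: int, tol: float = 1e-6) -> int:
    """Upper limit F for the model tail sum: max(f_max, point where the
    cumulative model mass exceeds 1 - tol)."""
    F = f_max
    cum = float(np.sum(fit.r(np.arange(F + 1))))
    # extend until negligible tail; the density decays like a Gaussian tail
    while cum < 1.0 - tol:
        nxt = fit.r(float(F + 1))
        if nxt < tol * 1e-3 and F > f_max:
            break
        F += 1
        cum += float(nxt)
        if F > f_max + 100000:  # safety on pathological parameters
            break
    return F


def compute_threshold(fit: NoiseFit, hist: NoiseHistogram, clamp_g: bool = False) -> int:
    """Integer threshold minimising eps_tau over tau in [0, f_max + 1].

    g(f) = r(f) - h(f) is used signed unless ``clamp_g`` (then negative
    residuals are clamped to 0).  Ties take the smallest tau.
    """
    if hist.density.size == 0:
        raise ValueError("empty histogram support")
    f_max = hist.f_max
    F = _tail_limit(fit, f_max)
    f_all = np.arange(F + 1)
    r = fit.r(f_all)
    h = np.zeros(F + 1)
    h[: f_max + 1] = hist.density
    g = r - h
    if clamp_g:
        g = np.clip(g, 0.0, None)
    # eps(tau) = sum_{f<tau} g(f) + sum_{f>=tau} r(f), tau = 0..f_max+1
    cum_g = np.concatenate([[0.0], np.cumsum(g)])            # prefix sums of g
    tail_r = np.concatenate([np.cumsum(r[::-1])[::-1], [0.0]])  # suffix sums of r
    taus = np.arange(f_max + 2)
    eps = cum_g[taus] + tail_r[taus]
    return int(np.argmin(eps))  # argmin returns the first (smallest) tie


def fit_stack(
    stack: ImageStack,
    box_rows: int = BOX_ROWS,
    box_cols: int = BOX_COLS,
    clamp_g: bool = False,
) -> list[NoiseFit]:
    """Per-slice background sampling, fit and threshold for a whole stack."""
    fits = []
    for sl in stack:
        hist = sample_background(sl, box_rows, box_cols)
        fit = fit_adjusted_rayleigh(hist)
        fits.append(fit.with_tau(compute_threshold(fit, hist, clamp_g=clamp_g)))
    return fits


def apply_threshold(stack: ImageStack, fits: Sequence[NoiseFit]) -> MaskStack:
    """Initial binary mask: pixel = 1 iff intensity >= its slice's tau_n."""
    if len(fits) != stack.n_slices:
        raise ValueError(f"{len(fits)} fits for {stack.n_slices} slices")
    out = np.zeros_like(stack.slices, dtype=np.uint8)
    for i, (sl, fit) in enumerate(zip(stack, fits)):
        if fit.tau is None:
            raise ValueError(f"fit for slice {i} has no threshold; run compute_threshold")
        out[i] = (sl >= fit.tau).astype(np.uint8)
    return MaskStack.like(stack, out)


def sample_adjusted_rayleigh(
    n: int,
    sigma: float,
    alpha: float = 1.0,
    delta: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Inverse-transform draws f = max(0, (sigma*sqrt(-2 ln U) - delta)/alpha)."""
    rng = np.random.default_rng() if rng is None else rng
    u = rng.uniform(size=n)
    f = (sigma * np.sqrt(-2.0 * np.log(u)) - delta) / alpha
    return np.clip(f, 0.0, None)
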