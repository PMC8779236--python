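"""Parametric models for nanosurgically manipulated titin topographs.

The models implemented here quantify the shapes and distributions that AFM
nanosurgery produces on surface-adsorbed titin:

* **Thin-plate loop model** — when an AFM tip drags a titin filament
  sideways, the displaced segment forms a loop whose transverse
  displacement follows the logarithmic profile predicted by the theory of
  in-plane-stressed two-dimensional plates adapted to fibers,

  .. math:: u(r) = k \\, \\ln(r_0 / |r|),

  where ``r`` is arc distance along the original contour from the point of
  manipulation, ``r0`` is the half-extent of the displaced region, and
  ``k`` lumps the applied tension, Young's modulus and Poisson ratio into
  a single coefficient (they are not separately identifiable).  Because
  the finite tip carves a gap of half-width ``d`` (the tip radius) at the
  loop vertex, a tip-shifted variant replaces ``|r|`` by ``|r| - d``:

  .. math:: u(r) = k \\, \\ln\\bigl(r_0 / (|r| - d)\\bigr), \\qquad |r| > d.

  The original model is the ``d = 0`` special case, so the two fits are
  nested and the tip-shifted fit can never have a larger residual sum.

* **Sigmoidal axial height decay** — the topographical height of a strand
  pulled out of an M-complex decays with distance ``x`` from the complex
  centre from a maximal plateau ``T`` to a minimal plateau ``B``:

  .. math:: h(x) = B + (T - B) / (1 + (x / x_{1/2})^S),

  with ``h(x_{1/2}) = B + (T - B)/2`` exactly; ``S > 0`` sets how abrupt
  the bulky-to-thin transition is.

* **Exponential, Gaussian and linear fits** — for pulled-length and
  volume-increment distributions, contour-length and segment-length
  histograms, and the M-complex volume versus titin count relation.

Every model follows the ``Model(data).fit() -> Results`` convention;
results carry the estimates, their standard errors, the coefficient of
determination ``r² = 1 - SS_res / SS_tot``, and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

from .exceptions import DomainError, FitConvergenceError

__all__ = [
    "ThinPlateParams",
    "SigmoidParams",
    "eval_thin_plate",
    "eval_sigmoid",
    "fold_volume",
    "ThinPlateModel",
    "SigmoidModel",
    "ExponentialModel",
    "GaussianModel",
    "LinearModel",
    "FitResults",
]


# ---------------------------------------------------------------------------
# Parameter containers and model evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThinPlateParams:
    """Thin-plate loop parameters.

    ``k`` (nm) is the lumped stress/stiffness coefficient, ``r0`` (nm) the
    half-extent of the displaced contour, ``d`` (nm) the tip-radius shift
    (0 recovers the original model).
    """

    k: float
    r0: float
    d: float = 0.0

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise DomainError(f"k must be > 0, got {self.k}")
        if not self.d >= 0:
            raise DomainError(f"d must be >= 0, got {self.d}")
        if not self.r0 > self.d:
            raise DomainError(f"need r0 > d, got r0={self.r0}, d={self.d}")


@dataclass(frozen=True)
class SigmoidParams:
    """Axial height-decay parameters.

    ``B``/``T`` (nm) are the minimal/maximal plateau heights,
    ``half_height`` (nm) the distance at which the height equals
    ``B + (T - B)/2``, and ``S`` the dimensionless slope factor.
    """

    B: float
    T: float
    half_height: float
    S: float

    def __post_init__(self) -> None:
        if not self.T > self.B:
            raise DomainError(f"need T > B, got T={self.T}, B={self.B}")
        if not self.half_height > 0:
            raise DomainError(f"half_height must be > 0, got {self.half_height}")
        if not self.S > 0:
            raise DomainError(f"S must be > 0, got {self.S}")


def eval_thin_plate(params: ThinPlateParams, r) -> np.ndarray | float:
    """Transverse loop displacement u(r) at contour distance(s) ``r``.

    For ``d = 0``: ``u = k ln(r0/|r|)`` on ``0 < |r| <= r0``.
    For ``d > 0``: ``u = k ln(r0/(|r| - d))`` on ``d < |r| <= r0 + d``
    (the sign-symmetric form; both branches of the printed two-branch
    model collapse onto it by taking ``|r|``).

    Raises
    ------
    DomainError
        If any ``|r|`` falls inside the excluded apex gap (``|r| <= d``,
        or ``|r| == 0`` for the original model) or beyond the point where
        the displacement returns to zero (``|r| - d > r0``).
    """
    r_arr = np.abs(np.asarray(r, dtype=float))
    scalar = r_arr.ndim == 0
    r_arr = np.atleast_1d(r_arr)
    if np.any(r_arr <= params.d):
        raise DomainError(
            f"|r| must exceed the apex gap half-width d={params.d} "
            f"(got min |r| = {r_arr.min()})"
        )
    if np.any(r_arr - params.d > params.r0 * (1 + 1e-12)):
        raise DomainError(
            f"|r| - d must not exceed r0={params.r0} "
            f"(got max |r| - d = {(r_arr - params.d).max()})"
        )
    u = params.k * np.log(params.r0 / (r_arr - params.d))
    return float(u[0]) if scalar else u


def eval_sigmoid(params: SigmoidParams, x) -> np.ndarray | float:
    """Sigmoidal height decay h(x) = B + (T-B)/(1 + (x/half)^S).

    Decays from ``T`` at the M-complex centre (x -> 0) to ``B`` far out,
    and returns exactly ``B + (T-B)/2`` at ``x = half_height``.
    """
    x_arr = np.asarray(x, dtype=float)
    scalar = x_arr.ndim == 0
    x_arr = np.atleast_1d(x_arr)
    if np.any(x_arr < 0):
        raise DomainError("distance x must be >= 0")
    with np.errstate(divide="ignore"):
        ratio = np.where(x_arr > 0, x_arr / params.half_height, 0.0)
        h = params.B + (params.T - params.B) / (1.0 + ratio**params.S)
    h = np.where(x_arr == 0, params.T, h)
    return float(h[0]) if scalar else h


def _sigmoid_curve(x, B, T, half, S):
    # unchecked fast path used inside the optimizer
    with np.errstate(divide="ignore", invalid="ignore"):
        out = B + (T - B) / (1.0 + (x / half) ** S)
    return np.where(x == 0, T, out)


def fold_volume(height_wet: float, height_dry: float, geometry: str) -> float:
    """Hydrated/dry volume fold change from apparent topographical heights.

    Treats the measured height as the diameter of the object: a sphere
    for the globular M-complex (volume ∝ h³) or a fixed-length cylinder
    for the titin filament (volume ∝ h²).
    """
    if not (height_wet > 0 and height_dry > 0):
        raise DomainError("heights must be > 0")
    ratio = height_wet / height_dry
    if geometry == "sphere":
        return ratio**3
    if geometry == "cylinder":
        return ratio**2
    raise DomainError(f"geometry must be 'sphere' or 'cylinder', got {geometry!r}")


# ---------------------------------------------------------------------------
# Shared fit machinery
# ---------------------------------------------------------------------------


def _r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - np.mean(observed)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def _restarted_least_squares(
    residual: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    bounds: tuple[np.ndarray, np.ndarray],
    n_restarts: int = 5,
    seed: int = 0,
) -> optimize.OptimizeResult:
    """Trust-region least squares with jittered restarts.

    The initial guess is tried as-is, then ``n_restarts`` times with
    multiplicative log-normal jitter (20%).  The convergent solution with
    the smallest residual sum wins; ties go to the smallest parameter
    norm.  Raises :class:`FitConvergenceError` with diagnostics if no
    start converges.
    """
    rng = np.random.default_rng(seed)
    lo, hi = bounds
    best = None
    failures = []
    for attempt in range(n_restarts + 1):
        if attempt == 0:
            start = x0
        else:
            start = x0 * np.exp(rng.normal(0.0, 0.2, size=len(x0)))
        start = np.clip(start, lo, hi)
        try:
            res = optimize.least_squares(
                residual, start, bounds=(lo, hi), method="trf", x_scale="jac"
            )
        except Exception as exc:  # pragma: no cover - scipy internal failures
            failures.append(f"start {attempt}: {exc}")
            continue
        if not res.success or not np.all(np.isfinite(res.x)):
            failures.append(f"start {attempt}: status={res.status}")
            continue
        if (
            best is None
            or res.cost < best.cost - 1e-12
            or (
                abs(res.cost - best.cost) <= 1e-12
                and np.linalg.norm(res.x) < np.linalg.norm(best.x)
            )
        ):
            best = res
    if best is None:
        raise FitConvergenceError(
            "nonlinear least squares failed to converge; initial guess "
            f"{x0.tolist()}, attempts: {failures}"
        )
    return best


def _stderr_from_jacobian(res: optimize.OptimizeResult, n: int) -> np.ndarray:
    """Asymptotic standard errors from the final Jacobian."""
    p = len(res.x)
    dof = max(n - p, 1)
    s2 = 2.0 * res.cost / dof
    try:
        jtj = res.jac.T @ res.jac
        cov = np.linalg.pinv(jtj) * s2
        return np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        return np.full(p, np.nan)


@dataclass
class FitResults:
    """Common results container: estimates, uncertainties, diagnostics."""

    model_name: str
    param_names: tuple
    param_values: np.ndarray
    bse: np.ndarray
    r2: float
    ssr: float
    nobs: int
    extra: dict = field(default_factory=dict)

    @property
    def params_dict(self) -> dict:
        return dict(zip(self.param_names, (float(v) for v in self.param_values)))

    def summary(self) -> str:
        lines = [
            f"{self.model_name} fit results",
            "=" * 46,
            f"{'parameter':<14}{'estimate':>14}{'std err':>14}",
            "-" * 46,
        ]
        for name, val, se in zip(self.param_names, self.param_values, self.bse):
            se_txt = f"{se:>14.5g}" if np.isfinite(se) else f"{'--':>14}"
            lines.append(f"{name:<14}{val:>14.6g}{se_txt}")
        lines.append("-" * 46)
        lines.append(f"n = {self.nobs}, SSR = {self.ssr:.6g}, r^2 = {self.r2:.4f}")
        for key, val in self.extra.items():
            if isinstance(val, (int, float, str, bool)):
                lines.append(f"{key} = {val}")
        return "\n".join(lines)

    def to_record(self) -> dict:
        """JSON-serializable fit record."""
        return {
            "model": self.model_name,
            "params": self.params_dict,
            "stderr": {
                n: (float(s) if np.isfinite(s) else None)
                for n, s in zip(self.param_names, self.bse)
            },
            "r2": float(self.r2),
            "ssr": float(self.ssr),
            "n": int(self.nobs),
            **{
                k: v
                for k, v in self.extra.items()
                if isinstance(v, (int, float, str, bool, type(None)))
            },
        }


# ---------------------------------------------------------------------------
# Thin-plate loop model
# ---------------------------------------------------------------------------


class ThinPlateResults(FitResults):
    @property
    def thin_plate_params(self) -> ThinPlateParams:
        p = self.params_dict
        return ThinPlateParams(k=p["k"], r0=p["r0"],
                               d=p.get("d", self.extra["d_fixed"]))

    def predict(self, r) -> np.ndarray:
        return eval_thin_plate(self.thin_plate_params, r)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        r = self.extra["r_data"]
        u = self.extra["u_data"]
        ax.plot(r, u, "o", ms=4, label="data")
        grid = np.linspace(np.min(np.abs(r[np.abs(r) > 0])), np.max(np.abs(r)), 200)
        p = self.thin_plate_params
        grid = grid[grid > p.d]
        ax.plot(grid, self.predict(grid), "-", label=f"fit (d={p.d:.2f} nm)")
        ax.set_xlabel("contour distance r (nm)")
        ax.set_ylabel("displacement u (nm)")
        ax.legend()
        return ax


class ThinPlateModel:
    """Fit the (optionally tip-shifted) thin-plate loop displacement model.

    Parameters
    ----------
    r : array
        Signed or unsigned contour distances from the manipulation point
        (nm); the model is symmetric in ``|r|`` — the displacement must be
        nearly symmetric about the manipulation axis for the model to
        apply, which the caller asserts.
    u : array
        Transverse displacements (nm).
    with_tip_shift : bool
        Fit the tip-shifted variant (free ``d``) instead of the original
        ``d = 0`` model.
    fixed_d : float or None
        Pin ``d`` at a known tip radius instead of estimating it.
    """

    def __init__(self, r, u, with_tip_shift: bool = True,
                 fixed_d: float | None = None):
        r = np.asarray(r, dtype=float)
        u = np.asarray(u, dtype=float)
        if r.shape != u.shape or r.ndim != 1:
            raise ValueError("r and u must be 1D arrays of equal length")
        if len(r) < 4:
            raise ValueError(f"need >= 4 points, got {len(r)}")
        self.r = r
        self.u = u
        self.abs_r = np.abs(r)
        if np.any(self.abs_r <= 0):
            raise DomainError("|r| = 0 lies in the excluded apex gap")
        self.with_tip_shift = bool(with_tip_shift)
        self.fixed_d = None if fixed_d is None else float(fixed_d)
        if self.fixed_d is not None and not self.fixed_d >= 0:
            raise DomainError("fixed_d must be >= 0")

    def fit(self, n_restarts: int = 5, seed: int = 0) -> ThinPlateResults:
        abs_r, u = self.abs_r, self.u
        rmin, rmax = abs_r.min(), abs_r.max()
        umax = max(u.max(), 1e-6)
        free_d = self.with_tip_shift and self.fixed_d is None
        d_fixed = 0.0
        if not self.with_tip_shift:
            d_fixed = 0.0
        elif self.fixed_d is not None:
            d_fixed = self.fixed_d
            if d_fixed >= rmin:
                raise DomainError(
                    f"fixed_d={d_fixed} >= min |r|={rmin}: data inside apex gap"
                )

        d_init = min(7.0, 0.5 * rmin)  # 7 nm: nominal AFM tip radius
        r0_init = rmax
        k_init = umax / math.log(r0_init / max(d_init, 1e-6) + 1.0)

        if free_d:
            x0 = np.array([k_init, r0_init, d_init])
            lo = np.array([1e-9, 1e-6, 0.0])
            hi = np.array([np.inf, np.inf, rmin * (1 - 1e-9)])

            def residual(theta):
                k, r0, d = theta
                return k * np.log(r0 / (abs_r - d)) - u

        else:
            x0 = np.array([k_init, r0_init])
            lo = np.array([1e-9, 1e-6])
            hi = np.array([np.inf, np.inf])

            def residual(theta):
                k, r0 = theta
                return k * np.log(r0 / (abs_r - d_fixed)) - u

        res = _restarted_least_squares(residual, x0, (lo, hi),
                                       n_restarts=n_restarts, seed=seed)
        if free_d:
            # the d = 0 model is nested inside the tip-shifted one; if the
            # reduced fit ends up lower (optimizer tolerance), adopt it so
            # the nesting inequality SSR(tip-shift) <= SSR(d=0) always holds
            def residual_d0(theta):
                k, r0 = theta
                return k * np.log(r0 / abs_r) - u

            res_d0 = _restarted_least_squares(
                residual_d0, np.array([k_init, r0_init]),
                (np.array([1e-9, 1e-6]), np.array([np.inf, np.inf])),
                n_restarts=n_restarts, seed=seed,
            )
            if res_d0.cost < res.cost:
                res = res_d0
                res.x = np.array([res_d0.x[0], res_d0.x[1], 0.0])
                res.jac = np.column_stack(
                    [res_d0.jac, np.zeros(len(res_d0.fun))]
                )
        pred = u + res.fun
        ssr = float(np.sum(res.fun**2))
        bse = _stderr_from_jacobian(res, len(u))
        if free_d:
            names = ("k", "r0", "d")
            values = res.x
        else:
            names = ("k", "r0")
            values = res.x
        return ThinPlateResults(
            model_name="thin-plate loop"
            + (" (tip-shifted)" if self.with_tip_shift else " (original)"),
            param_names=names,
            param_values=np.asarray(values, dtype=float),
            bse=bse,
            r2=_r2(u, pred),
            ssr=ssr,
            nobs=len(u),
            extra={"d_fixed": None if free_d else d_fixed,
                   "r_data": self.r, "u_data": self.u,
                   "tip_shift": self.with_tip_shift},
        )


# ---------------------------------------------------------------------------
# Sigmoidal axial height decay
# ---------------------------------------------------------------------------


class SigmoidResults(FitResults):
    @property
    def sigmoid_params(self) -> SigmoidParams:
        p = self.params_dict
        return SigmoidParams(B=p["B"], T=p["T"],
                             half_height=p["half_height"], S=p["S"])

    def predict(self, x) -> np.ndarray:
        return eval_sigmoid(self.sigmoid_params, x)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.extra["x_data"]
        h = self.extra["h_data"]
        ax.plot(x, h, "o", ms=4, label="data")
        grid = np.linspace(0, np.max(x), 300)
        ax.plot(grid, self.predict(grid), "-", label="sigmoid fit")
        ax.set_xlabel("distance from origin (nm)")
        ax.set_ylabel("height (nm)")
        ax.legend()
        return ax


class SigmoidModel:
    """Fit the sigmoidal height-vs-distance decay of a pulled-out strand."""

    def __init__(self, x, h):
        x = np.asarray(x, dtype=float)
        h = np.asarray(h, dtype=float)
        if x.shape != h.shape or x.ndim != 1:
            raise ValueError("x and h must be 1D arrays of equal length")
        if len(x) < 5:
            raise ValueError(f"need >= 5 points, got {len(x)}")
        if np.any(x < 0):
            raise DomainError("distances must be >= 0")
        order = np.argsort(x)
        self.x = x[order]
        self.h = h[order]

    def fit(self, n_restarts: int = 5, seed: int = 0) -> SigmoidResults:
        x, h = self.x, self.h
        n = len(x)
        q = max(n // 4, 1)
        t_init = float(np.mean(h[:q]))  # plateau near the origin
        b_init = float(np.mean(h[-q:]))  # far plateau
        if t_init <= b_init:
            t_init, b_init = max(h.max(), b_init + 1e-3), h.min()
        mid = b_init + 0.5 * (t_init - b_init)
        crossing = np.nonzero(h <= mid)[0]
        half_init = float(x[crossing[0]]) if len(crossing) else float(np.median(x))
        half_init = max(half_init, 1e-3)
        x0 = np.array([b_init, t_init, half_init, 2.0])
        span = float(h.max() - h.min()) or 1.0
        lo = np.array([h.min() - span, h.min() - span, 1e-6, 1e-3])
        hi = np.array([h.max() + span, h.max() + span, np.inf, 1e3])

        def residual(theta):
            return _sigmoid_curve(x, *theta) - h

        res = _restarted_least_squares(residual, x0, (lo, hi),
                                       n_restarts=n_restarts, seed=seed)
        pred = h + res.fun
        return SigmoidResults(
            model_name="sigmoidal height decay",
            param_names=("B", "T", "half_height", "S"),
            param_values=np.asarray(res.x, dtype=float),
            bse=_stderr_from_jacobian(res, n),
            r2=_r2(h, pred),
            ssr=float(np.sum(res.fun**2)),
            nobs=n,
            extra={"x_data": x, "h_data": h},
        )


# ---------------------------------------------------------------------------
# Distribution fits
# ---------------------------------------------------------------------------


def _fd_bin_width(samples: np.ndarray) -> float:
    iqr = float(np.subtract(*np.percentile(samples, [75, 25])))
    if iqr <= 0:
        iqr = float(np.std(samples)) or 1.0
    return 2.0 * iqr / len(samples) ** (1.0 / 3.0)


def _fixed_origin_histogram(samples: np.ndarray, bin_width: float | None):
    """Histogram with bins anchored at 0 (fixed-origin convention)."""
    if bin_width is None:
        bin_width = _fd_bin_width(samples)
    if not bin_width > 0:
        raise ValueError("bin width must be > 0")
    n_bins = int(np.ceil(samples.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, edges = np.histogram(samples, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts.astype(float), bin_width


class ExponentialResults(FitResults):
    @property
    def rate(self) -> float:
        return float(self.params_dict["rate"])

    @property
    def mle_rate(self) -> float | None:
        return self.extra.get("mle_rate")

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        centers = self.extra["bin_centers"]
        freq = self.extra["frequency"]
        ax.bar(centers, freq, width=self.extra["bin_width"] * 0.9,
               alpha=0.5, label="data")
        grid = np.linspace(centers[0], centers[-1], 200)
        ax.plot(grid, np.exp(-self.rate * (grid - centers[0])), "-",
                label="exponential fit")
        ax.set_ylabel("statistical frequency")
        ax.legend()
        return ax


class ExponentialModel:
    """Exponential fit f = exp(-rate * l) to a histogram of positive values.

    The histogram is normalized so that the model value at the first bin
    is 1 (the zero-intercept convention): frequencies are counts divided
    by the first occupied bin's count, and the rate is estimated by least
    squares of ``exp(-rate * (l - l_first))`` on the bin centres.  The
    closed-form maximum-likelihood rate ``1/mean`` is reported alongside
    for comparison.
    """

    def __init__(self, samples: Sequence[float], bin_width: float | None = None):
        samples = np.asarray(samples, dtype=float)
        if len(samples) < 10:
            raise ValueError(f"need >= 10 samples, got {len(samples)}")
        if np.any(samples <= 0):
            raise ValueError("samples must be positive")
        if np.ptp(samples) == 0:
            raise ValueError("all samples identical: degenerate histogram")
        self.samples = samples
        centers, counts, bw = _fixed_origin_histogram(samples, bin_width)
        self._centers, self._counts, self._bin_width = centers, counts, bw
        self._mle_rate = 1.0 / float(np.mean(samples))

    @classmethod
    def from_histogram(cls, centers, counts, bin_width: float | None = None):
        """Build directly from histogram bin centres and counts."""
        obj = cls.__new__(cls)
        obj.samples = None
        obj._centers = np.asarray(centers, dtype=float)
        obj._counts = np.asarray(counts, dtype=float)
        if len(obj._centers) < 2:
            raise ValueError("need >= 2 bins")
        obj._bin_width = (
            float(bin_width)
            if bin_width is not None
            else float(np.median(np.diff(obj._centers)))
        )
        obj._mle_rate = None
        return obj

    def fit(self) -> ExponentialResults:
        occupied = np.nonzero(self._counts > 0)[0]
        first = occupied[0]
        last = occupied[-1]
        centers = self._centers[first : last + 1]
        counts = self._counts[first : last + 1]
        freq = counts / counts[0]
        l0 = centers[0]
        rate0 = self._mle_rate or 1.0 / max(float(np.mean(centers - l0)), 1e-9)

        def residual(theta):
            return np.exp(-theta[0] * (centers - l0)) - freq

        res = _restarted_least_squares(
            residual, np.array([rate0]),
            (np.array([1e-300]), np.array([np.inf])),
        )
        pred = freq + res.fun
        nobs = len(self.samples) if self.samples is not None else len(centers)
        return ExponentialResults(
            model_name="exponential distribution",
            param_names=("rate",),
            param_values=np.asarray(res.x, dtype=float),
            bse=_stderr_from_jacobian(res, len(centers)),
            r2=_r2(freq, pred),
            ssr=float(np.sum(res.fun**2)),
            nobs=nobs,
            extra={
                "mle_rate": self._mle_rate,
                "bin_centers": centers,
                "frequency": freq,
                "bin_width": self._bin_width,
                "n_bins": len(centers),
            },
        )


class GaussianResults(FitResults):
    @property
    def mean(self) -> float:
        return float(self.params_dict["mean"])

    @property
    def sd(self) -> float:
        return float(self.params_dict["sd"])

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        centers = self.extra["bin_centers"]
        counts = self.extra["counts"]
        ax.bar(centers, counts, width=self.extra["bin_width"] * 0.9,
               alpha=0.5, label="data")
        grid = np.linspace(centers[0], centers[-1], 200)
        p = self.params_dict
        ax.plot(grid, p["amplitude"]
                * np.exp(-((grid - p["mean"]) ** 2) / (2 * p["sd"] ** 2)),
                "-", label="gaussian fit")
        ax.legend()
        return ax


class GaussianModel:
    """Gaussian fit A·exp(-(x-μ)²/2σ²) to a fixed-origin histogram."""

    def __init__(self, samples: Sequence[float], bin_width: float | None = None):
        samples = np.asarray(samples, dtype=float)
        if len(samples) < 5:
            raise ValueError(f"need >= 5 samples, got {len(samples)}")
        if np.ptp(samples) == 0:
            raise ValueError("all samples identical: degenerate histogram")
        self.samples = samples
        centers, counts, bw = _fixed_origin_histogram(
            samples - samples.min() if samples.min() < 0 else samples, bin_width
        )
        self._offset = float(min(samples.min(), 0.0))
        self._centers = centers + self._offset
        self._counts = counts
        self._bin_width = bw

    @classmethod
    def from_histogram(cls, centers, counts, bin_width: float | None = None):
        """Build directly from histogram bin centres and counts."""
        obj = cls.__new__(cls)
        obj.samples = None
        obj._centers = np.asarray(centers, dtype=float)
        obj._counts = np.asarray(counts, dtype=float)
        if len(obj._centers) < 3:
            raise ValueError("need >= 3 bins")
        obj._bin_width = (
            float(bin_width)
            if bin_width is not None
            else float(np.median(np.diff(obj._centers)))
        )
        obj._offset = 0.0
        return obj

    def fit(self) -> GaussianResults:
        centers, counts = self._centers, self._counts
        if self.samples is not None:
            mu0 = float(np.mean(self.samples))
            sd0 = float(np.std(self.samples, ddof=1)) or 1.0
            nobs = len(self.samples)
            sample_mean = mu0
            sample_sd = float(np.std(self.samples, ddof=1))
        else:
            weights = counts / counts.sum()
            mu0 = float(np.sum(weights * centers))
            sd0 = float(np.sqrt(np.sum(weights * (centers - mu0) ** 2))) or 1.0
            nobs = len(centers)
            sample_mean, sample_sd = mu0, sd0
        a0 = float(counts.max()) or 1.0
        x0 = np.array([mu0, sd0, a0])
        lo = np.array([-np.inf, 1e-9, 1e-12])
        hi = np.array([np.inf, np.inf, np.inf])

        def residual(theta):
            mu, sd, a = theta
            return a * np.exp(-((centers - mu) ** 2) / (2 * sd**2)) - counts

        res = _restarted_least_squares(residual, x0, (lo, hi))
        pred = counts + res.fun
        return GaussianResults(
            model_name="gaussian distribution",
            param_names=("mean", "sd", "amplitude"),
            param_values=np.asarray(res.x, dtype=float),
            bse=_stderr_from_jacobian(res, len(centers)),
            r2=_r2(counts, pred),
            ssr=float(np.sum(res.fun**2)),
            nobs=nobs,
            extra={
                "sample_mean": sample_mean,
                "sample_sd": sample_sd,
                "bin_centers": centers,
                "counts": counts,
                "bin_width": self._bin_width,
            },
        )


class LinearResults(FitResults):
    @property
    def slope(self) -> float:
        return float(self.params_dict["slope"])

    @property
    def intercept(self) -> float:
        return float(self.params_dict["intercept"])

    @property
    def intercept_ci(self) -> tuple[float, float]:
        return self.extra["intercept_ci"]

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


class LinearModel:
    """Ordinary least squares y = intercept + slope·x with an intercept CI.

    Used for the M-complex volume versus titin-count relation, where a
    zero intercept is the scientifically meaningful (and testable) claim.
    """

    def __init__(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1D arrays of equal length")
        if len(x) < 5:
            raise ValueError(f"need >= 5 points, got {len(x)}")
        if np.ptp(x) == 0:
            raise ValueError("x is constant: rank-deficient design")
        self.x = x
        self.y = y

    def fit(self, alpha: float = 0.05) -> LinearResults:
        import statsmodels.api as sm

        X = sm.add_constant(self.x)
        ols = sm.OLS(self.y, X).fit()
        intercept, slope = ols.params
        ci = ols.conf_int(alpha=alpha)
        pred = ols.fittedvalues
        return LinearResults(
            model_name="linear (OLS)",
            param_names=("slope", "intercept"),
            param_values=np.array([slope, intercept], dtype=float),
            bse=np.array([ols.bse[1], ols.bse[0]], dtype=float),
            r2=float(ols.rsquared),
            ssr=float(ols.ssr),
            nobs=len(self.x),
            extra={
                "intercept_ci": (float(ci[0, 0]), float(ci[0, 1])),
                "slope_ci": (float(ci[1, 0]), float(ci[1, 1])),
                "alpha": alpha,
            },
        )
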