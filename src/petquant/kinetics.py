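"""Tracer kinetics: TACs, the one-tissue compartment model, and Patlak
graphical analysis.

The one-tissue compartment model describes tissue tracer concentration as
the blood curve convolved with an exponential impulse response,

    C_t(t) = K1 ∫₀ᵗ C_p(τ) e^{-k2 (t-τ)} dτ,

with uptake K1 (mL/min/g) and clearance k2 (min⁻¹).  Fitting is nonlinear
least squares with a fixed multistart grid so results are deterministic.
Patlak analysis linearises irreversible uptake: plotting C_t/C_p against
the "normalised time" ∫₀ᵗ C_p dτ / C_p(t) gives, past an equilibration
time t*, a line whose slope is the net influx constant (equal to K1 when
k2 = 0) and whose intercept is the initial distribution volume.

Both estimators follow scikit-learn conventions (``fit`` on data, fitted
attributes with a trailing underscore, ``get_params``/``set_params``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .blood import BloodInputModel
from .dosimetry import DECAY_LOG2, F18_HALF_LIFE_MIN
from .image import DynamicImage

__all__ = [
    "TAC",
    "OneTissueParams",
    "PatlakResult",
    "OneTissueCompartmentModel",
    "PatlakModel",
    "extract_tac",
    "simulate_1tcm",
    "fit_1tcm",
    "patlak_plot",
    "patlak_parametric",
]


@dataclass(frozen=True)
class OneTissueParams:
    """One-tissue compartment parameters: K1 (mL/min/g), k2 (min⁻¹)."""

    K1: float
    k2: float

    def __post_init__(self) -> None:
        if self.K1 < 0 or self.k2 < 0:
            raise ValueError("K1 and k2 must be non-negative")


@dataclass(frozen=True)
class TAC:
    """A time–activity curve: ROI activity (kBq/ml) at frame mid-times (min)."""

    t: np.ndarray
    value: np.ndarray
    duration: np.ndarray | None = None
    decay_corrected: bool = True

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "value", v)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("t and value must be equal-length 1-D arrays")
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ValueError("frame mid-times must be non-negative and strictly increasing")
        if self.duration is not None:
            d = np.asarray(self.duration, dtype=float)
            object.__setattr__(self, "duration", d)
            if d.shape != t.shape or np.any(d <= 0):
                raise ValueError("durations must match t and be positive")

    def __len__(self) -> int:
        return self.t.size

    def decay_correct(
        self,
        *,
        half_life: float = F18_HALF_LIFE_MIN,
        exact_ln2: bool = False,
    ) -> "TAC":
        """Correct values to injection time (t = 0); no-op if already corrected."""
        if self.decay_corrected:
            return self
        lam = (np.log(2.0) if exact_ln2 else DECAY_LOG2) / half_life
        return replace(self, value=self.value * np.exp(lam * self.t), decay_corrected=True)


@dataclass(frozen=True)
class PatlakResult:
    """Patlak regression: slope (mL/min/g), intercept (mL/g), fit window, r²."""

    slope: float
    intercept: float
    linear_window: tuple[float, float]
    r2_linear: float
    n_points: int


# ---------------------------------------------------------------------------
# forward model


def _frame_average(func, start: np.ndarray, duration: np.ndarray, order: int = 8) -> np.ndarray:
    """Mean of a smooth function over each frame by Gauss–Legendre quadrature."""
    nodes, weights = np.polynomial.legendre.leggauss(order)
    # map nodes from [-1, 1] onto each frame
    t = start[:, None] + (nodes[None, :] + 1.0) * (duration[:, None] / 2.0)
    return func(t.ravel()).reshape(t.shape) @ weights / 2.0


def _plin_conv_knots(tk: np.ndarray, ck: np.ndarray, k2: float) -> np.ndarray:
    """Unit-K1 tissue curve at knots for piecewise-linear blood samples.

    Exact for blood linear on each knot interval; vectorised recursion
    C_{j+1} = C_j e^{-k2 Δ} + J_j with J_j the closed-form segment integral.
    """
    dt = np.diff(tk)
    x = k2 * dt
    if k2 > 0:
        em = -np.expm1(-x)  # 1 - e^{-x}
        a = em / k2
        b = (em - x * np.exp(-x)) / k2**2
    else:
        a = dt
        b = dt**2 / 2.0
    slope = np.diff(ck) / dt
    seg = ck[1:] * a - slope * b  # ∫ c_p(s) e^{-k2 (t_{j+1}-s)} ds
    # C_n = Σ_j seg_j e^{-k2 (t_n - t_{j+1})}: do it with scaled cumsum
    scale = np.exp(k2 * tk[1:])
    cum = np.cumsum(seg * scale)
    out = np.zeros_like(tk)
    out[1:] = cum * np.exp(-k2 * tk[1:])
    return out


def _refine_knots(tk: np.ndarray, ck: np.ndarray, extra: np.ndarray, dt_max: float):
    """Merge extra time points and subdivide long intervals, interpolating blood."""
    grid = [tk]
    if extra.size:
        grid.append(extra)
    base = np.unique(np.concatenate(grid))
    pieces = [base]
    long = np.diff(base) > dt_max
    for i in np.nonzero(long)[0]:
        n = int(np.ceil((base[i + 1] - base[i]) / dt_max))
        pieces.append(np.linspace(base[i], base[i + 1], n + 1)[1:-1])
    knots = np.unique(np.concatenate(pieces))
    return knots, np.interp(knots, tk, ck)


class _SampledBloodModel:
    """Piecewise-linear tissue-model engine for a sampled blood curve."""

    def __init__(self, btac: TAC, dt_max: float = 1.0 / 3.0):
        tb, cb = btac.t, btac.value
        if tb[0] > 0:  # the bolus starts at zero activity at injection
            tb = np.concatenate([[0.0], tb])
            cb = np.concatenate([[0.0], cb])
        self.tb, self.cb = tb, cb
        self.dt_max = dt_max

    def tissue_at(self, k1: float, k2: float, t_out: np.ndarray) -> np.ndarray:
        knots, ck = _refine_knots(self.tb, self.cb, t_out, self.dt_max)
        unit = _plin_conv_knots(knots, ck, k2)
        return k1 * np.interp(t_out, knots, unit)

    def tissue_frame_mean(
        self, k1: float, k2: float, start: np.ndarray, duration: np.ndarray
    ) -> np.ndarray:
        edges = np.concatenate([start, start + duration])
        knots, ck = _refine_knots(self.tb, self.cb, edges, self.dt_max)
        unit = k1 * _plin_conv_knots(knots, ck, k2)
        out = np.empty(start.size)
        for i, (a, b) in enumerate(zip(start, start + duration)):
            sel = (knots >= a - 1e-12) & (knots <= b + 1e-12)
            out[i] = np.trapezoid(unit[sel], knots[sel]) / (b - a)
        return out


def simulate_1tcm(
    params: OneTissueParams,
    blood,
    t,
    durations=None,
) -> TAC:
    """Simulate a one-tissue compartment tissue curve.

    ``blood`` may be a :class:`BloodInputModel` (closed-form convolution),
    a sampled :class:`TAC` (exact piecewise-linear convolution), or any
    callable of time in minutes (ODE integration).  With ``durations``
    the returned values are frame averages rather than point samples.
    """
    t = np.asarray(t, dtype=float)
    if isinstance(blood, BloodInputModel):
        if durations is None:
            vals = blood.tissue_curve(params.K1, params.k2, t)
        else:
            d = np.asarray(durations, dtype=float)
            vals = _frame_average(
                lambda tt: blood.tissue_curve(params.K1, params.k2, tt), t - d / 2.0, d
            )
    elif isinstance(blood, TAC):
        engine = _SampledBloodModel(blood)
        if durations is None:
            vals = engine.tissue_at(params.K1, params.k2, t)
        else:
            d = np.asarray(durations, dtype=float)
            vals = engine.tissue_frame_mean(params.K1, params.k2, t - d / 2.0, d)
    elif callable(blood):
        t_end = float(t[-1] + (0 if durations is None else durations[-1]))
        sol = solve_ivp(
            lambda tt, c: params.K1 * float(np.asarray(blood(tt))) - params.k2 * c,
            (0.0, max(t_end, 1e-9)),
            [0.0],
            dense_output=True,
            rtol=1e-9,
            atol=1e-12,
            max_step=0.5,
        )
        if durations is None:
            vals = sol.sol(t)[0]
        else:
            d = np.asarray(durations, dtype=float)
            vals = _frame_average(lambda tt: sol.sol(tt)[0], t - d / 2.0, d)
    else:
        raise TypeError("blood must be a BloodInputModel, a TAC, or a callable")
    dur = None if durations is None else np.asarray(durations, dtype=float)
    return TAC(t=t, value=vals, duration=dur)


# ---------------------------------------------------------------------------
# estimators


class OneTissueCompartmentModel(BaseEstimator):
    """Least-squares one-tissue compartment fit of a tissue TAC.

    Parameters
    ----------
    weights : {"duration", "uniform"}
        Residual weights; ``"duration"`` weights each frame by its length
        (counting statistics improve with frame duration).
    multistart : sequence of (K1, k2) pairs
        Fixed, ordered initial guesses; the best converged fit wins, so
        results are deterministic.
    bounds : ((K1_lo, k2_lo), (K1_hi, k2_hi))
        Box constraints for the optimiser.
    dt_max : float
        Maximum sub-interval (minutes) used when convolving the sampled
        blood curve; long late frames are subdivided to this resolution.
    decay_correct : bool
        Decay-correct both TACs to injection time before fitting if they
        are not already corrected.

    Attributes
    ----------
    K1_, k2_ : float
        Fitted parameters.
    residual_norm_ : float
        Weighted residual 2-norm at the solution.
    converged_ : bool
        Whether any start converged.
    """

    def __init__(
        self,
        weights: str = "duration",
        multistart=((0.01, 0.1, 0.5), (0.001, 0.01, 0.1)),
        bounds=((0.0, 0.0), (10.0, 2.0)),
        dt_max: float = 1.0 / 3.0,
        decay_correct: bool = True,
    ):
        self.weights = weights
        self.multistart = multistart
        self.bounds = bounds
        self.dt_max = dt_max
        self.decay_correct = decay_correct

    def _model(self, ttac: TAC, blood) -> callable:
        if isinstance(blood, BloodInputModel):
            if ttac.duration is None:
                return lambda k1, k2: blood.tissue_curve(k1, k2, ttac.t)
            start = ttac.t - ttac.duration / 2.0
            return lambda k1, k2: _frame_average(
                lambda tt: blood.tissue_curve(k1, k2, tt), start, ttac.duration
            )
        engine = _SampledBloodModel(blood, dt_max=self.dt_max)
        if ttac.duration is None:
            return lambda k1, k2: engine.tissue_at(k1, k2, ttac.t)
        start = ttac.t - ttac.duration / 2.0
        return lambda k1, k2: engine.tissue_frame_mean(k1, k2, start, ttac.duration)

    def fit(self, ttac: TAC, btac) -> "OneTissueCompartmentModel":
        """Fit (K1, k2) to ``ttac`` given a blood curve ``btac`` (TAC or model)."""
        if len(ttac) < 10:
            raise ValueError("need at least 10 frames to fit a compartment model")
        if isinstance(btac, TAC) and btac.t[-1] < ttac.t[-1] - 1e-9:
            raise ValueError("blood TAC must cover the tissue TAC support")
        if self.decay_correct:
            ttac = ttac.decay_correct()
            if isinstance(btac, TAC):
                btac = btac.decay_correct()

        if self.weights == "duration":
            w = ttac.duration if ttac.duration is not None else np.ones(len(ttac))
        elif self.weights == "uniform":
            w = np.ones(len(ttac))
        else:
            raise ValueError(f"unknown weights mode {self.weights!r}")
        sw = np.sqrt(w / w.sum())

        model = self._model(ttac, btac)
        y = ttac.value

        def resid(x):
            return sw * (model(x[0], x[1]) - y)

        lo, hi = self.bounds
        best = None
        starts = [(k1, k2) for k1 in self.multistart[0] for k2 in self.multistart[1]]
        for x0 in starts:
            res = least_squares(resid, x0=np.array(x0), bounds=(lo, hi), method="trf")
            if res.success and (best is None or res.cost < best.cost):
                best = res
                self.best_start_ = x0
        if best is None:
            raise RuntimeError(
                f"one-tissue fit failed to converge from any of {len(starts)} starts"
            )
        self.K1_ = float(best.x[0])
        self.k2_ = float(best.x[1])
        self.residual_norm_ = float(np.sqrt(2.0 * best.cost))
        self.converged_ = True
        self._fitted_model = model
        self._blood = btac
        return self

    @property
    def params_(self) -> OneTissueParams:
        return OneTissueParams(K1=self.K1_, k2=self.k2_)

    def predict(self, t=None) -> np.ndarray:
        """Fitted tissue curve at the training frames (or at times ``t``)."""
        if t is None:
            return self._fitted_model(self.K1_, self.k2_)
        return simulate_1tcm(self.params_, self._blood, np.asarray(t, dtype=float)).value


class PatlakModel(BaseEstimator):
    """Patlak graphical analysis of a tissue TAC against a blood TAC.

    Ordinary least squares of y = C_t(t)/C_p(t) on x = ∫₀ᵗ C_p dτ / C_p(t)
    over frames with t ≥ ``t_star``.  ``slope_`` is the net influx constant
    (mL/min/g), ``intercept_`` the initial distribution volume (mL/g), and
    ``r2_`` the squared correlation over the fitted window — inspect it to
    audit the choice of t*.
    """

    def __init__(self, t_star: float = 20.0, decay_correct: bool = True):
        self.t_star = t_star
        self.decay_correct = decay_correct

    @staticmethod
    def _blood_arrays(btac, t: np.ndarray):
        if isinstance(btac, BloodInputModel):
            return btac(t), btac.cumulative_integral(t)
        if isinstance(btac, TAC):
            tb, cb = btac.t, btac.value
            if tb[0] > 0:
                tb = np.concatenate([[0.0], tb])
                cb = np.concatenate([[0.0], cb])
            from scipy.integrate import cumulative_trapezoid

            cum = cumulative_trapezoid(cb, tb, initial=0.0)
            return np.interp(t, tb, cb), np.interp(t, tb, cum)
        raise TypeError("btac must be a TAC or a BloodInputModel")

    def fit(self, ttac: TAC, btac) -> "PatlakModel":
        if self.t_star >= ttac.t[-1]:
            raise ValueError("t_star must lie inside the scan duration")
        if self.decay_correct:
            ttac = ttac.decay_correct()
            if isinstance(btac, TAC):
                btac = btac.decay_correct()
        cp, cum = self._blood_arrays(btac, ttac.t)
        sel = (ttac.t >= self.t_star) & (cp > 0)
        if sel.sum() < 3:
            raise ValueError("need at least 3 frames past t_star with positive blood activity")
        x = cum[sel] / cp[sel]
        y = ttac.value[sel] / cp[sel]
        vx = x - x.mean()
        denom = float(vx @ vx)
        if denom == 0:
            raise ValueError("degenerate Patlak abscissa (constant normalised time)")
        self.slope_ = float(vx @ (y - y.mean()) / denom)
        self.intercept_ = float(y.mean() - self.slope_ * x.mean())
        resid = y - (self.slope_ * x + self.intercept_)
        sst = float(((y - y.mean()) ** 2).sum())
        self.r2_ = 1.0 if sst == 0 else 1.0 - float((resid**2).sum()) / sst
        self.n_points_ = int(sel.sum())
        self.window_ = (float(self.t_star), float(ttac.t[-1]))
        return self

    @property
    def result_(self) -> PatlakResult:
        return PatlakResult(
            slope=self.slope_,
            intercept=self.intercept_,
            linear_window=self.window_,
            r2_linear=self.r2_,
            n_points=self.n_points_,
        )


# ---------------------------------------------------------------------------
# functional wrappers


def extract_tac(img: DynamicImage, mask: np.ndarray, decay_correct: bool = False) -> TAC:
    """Per-frame ROI mean of a dynamic image at frame mid-times.

    The ROI is fixed once and applied to every frame.  With
    ``decay_correct`` the curve is corrected to injection time when the
    image holds physically decaying activity.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError(f"mask shape {mask.shape} does not match image {img.shape}")
    if not mask.any():
        raise ValueError("empty ROI mask")
    if img.schedule is None:
        raise ValueError("dynamic image has no frame schedule")
    values = img.data[mask].mean(axis=0).astype(float)
    tac = TAC(
        t=img.schedule.mid,
        value=values,
        duration=img.schedule.duration,
        decay_corrected=img.decay_corrected,
    )
    return tac.decay_correct() if decay_correct else tac


def fit_1tcm(
    ttac: TAC,
    btac,
    init=None,
    weights: str = "duration",
) -> tuple[OneTissueParams, dict]:
    """Multistart least-squares fit; returns parameters and diagnostics."""
    model = OneTissueCompartmentModel(weights=weights)
    if init is not None:
        model.set_params(multistart=((init[0],), (init[1],)))
    model.fit(ttac, btac)
    diag = {
        "residual_norm": model.residual_norm_,
        "converged": model.converged_,
        "best_start": model.best_start_,
    }
    return model.params_, diag


def patlak_plot(ttac: TAC, btac, t_star: float = 20.0) -> PatlakResult:
    """ROI-level Patlak analysis; see :class:`PatlakModel`."""
    return PatlakModel(t_star=t_star).fit(ttac, btac).result_


def patlak_parametric(
    img: DynamicImage,
    btac,
    t_star: float = 20.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-wise Patlak OLS: slope and intercept images plus a validity mask.

    Voxels whose TAC is identically zero are reported as slope = 0,
    intercept = 0 and flagged invalid.
    """
    if img.schedule is None:
        raise ValueError("dynamic image has no frame schedule")
    t = img.schedule.mid
    if t_star >= t[-1]:
        raise ValueError("t_star must lie inside the scan duration")
    if isinstance(btac, TAC):
        btac = btac.decay_correct()
    cp, cum = PatlakModel._blood_arrays(btac, t)
    sel = (t >= t_star) & (cp > 0)
    if sel.sum() < 3:
        raise ValueError("need at least 3 frames past t_star with positive blood activity")
    x = cum[sel] / cp[sel]  # shared abscissa, (F,)
    data = img.data.reshape(-1, img.n_frames).astype(float)
    y = data[:, sel] / cp[sel]  # (N, F)
    vx = x - x.mean()
    slope = (y - y.mean(axis=1, keepdims=True)) @ vx / float(vx @ vx)
    intercept = y.mean(axis=1) - slope * x.mean()
    valid = ~np.all(data == 0, axis=1)
    slope[~valid] = 0.0
    intercept[~valid] = 0.0
    shp = img.shape
    return slope.reshape(shp), intercept.reshape(shp), valid.reshape(shp)
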