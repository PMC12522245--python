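"""Four-parameter distributional regression (GAMLSS-style centile models).

A model assigns each distribution parameter (mu, sigma, nu, tau) its own
smooth curve in age, expressed on the parameter's link scale as a linear
basis expansion:

    g_j(theta_j(age)) = B_j(age) @ beta_j

with B_j a constant / linear / fractional-polynomial / regression-spline
basis.  All coefficient blocks are estimated jointly by direct maximum
likelihood (weighted by analytic survey weights) with a quasi-Newton
optimizer; the objective trace is recorded so the deviance-descent
property is checkable.  Effective degrees of freedom are counted as the
number of basis coefficients (the bases are unpenalized regression
splines, so no dimension is absorbed by a penalty), and candidate models
are ranked by the generalized Akaike criterion

    GAIC(k) = -2 * loglik + k * edf.

Fitted models evaluate their parameter curves at arbitrary ages in
[45, 85] and expose centile curves via the family quantile function;
reported centiles are floored at zero because the score is non-negative
while every family has unbounded-below support.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize

from .distributions import (Family, ParamVector, get_family, inv_link_fn,
                            link_fn)
from .quantreg import expand_fractional_polynomial

__all__ = [
    "SmootherSpec",
    "FitControls",
    "CentileModel",
    "GamlssSpec",
    "fit_distributional_model",
    "gaic",
    "rank_families",
    "centile",
    "ConvergenceError",
]

AGE_MIN, AGE_MAX = 45.0, 85.0

#: shape-parameter starting values (raw scale) per family
_SHAPE_START = {
    "SHASH": (1.0, 1.0), "SHASHo": (0.0, 1.0), "SHASHo2": (0.0, 1.0),
    "SEP1": (0.0, 2.0), "SEP2": (0.0, 2.0), "SEP4": (2.0, 2.0),
    "JSU": (0.0, 1.5), "JSUo": (0.0, 1.5), "ST1": (0.0, 10.0),
    "ST5": (0.0, 0.3),
}


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class SmootherSpec:
    """How one parameter curve depends on age.

    kind:
      - "constant":               intercept only (df 1)
      - "linear":                 intercept + slope (df 2)
      - "cubic_spline":           cubic regression B-spline with `df` basis
                                  functions (df >= 4)
      - "polynomial_spline":      quadratic regression B-spline (df >= 3)
      - "fractional_polynomial":  FP basis with the given powers from
                                  {-2, -1, -0.5, 0, 0.5, 1, 2, 3}
    """

    kind: str = "constant"
    df: int = 1
    powers: tuple[float, ...] = ()

    def __post_init__(self):
        kinds = ("constant", "linear", "cubic_spline", "polynomial_spline",
                 "fractional_polynomial")
        if self.kind not in kinds:
            raise ValueError(f"unknown smoother kind {self.kind!r}")
        min_df = {"constant": 1, "linear": 2, "cubic_spline": 4,
                  "polynomial_spline": 3, "fractional_polynomial": 1}[self.kind]
        if self.kind in ("cubic_spline", "polynomial_spline") and self.df < min_df:
            raise ValueError(f"{self.kind} needs df >= {min_df}")

    def build(self, train_ages: np.ndarray) -> "_Basis":
        return _Basis.build(self, train_ages)


@dataclass(frozen=True)
class _Basis:
    """A concrete, serializable design-matrix builder for one parameter."""

    kind: str
    knots: tuple[float, ...] = ()     # full knot vector for spline kinds
    degree: int = 0
    powers: tuple[float, ...] = ()
    ncol: int = 1

    @classmethod
    def build(cls, spec: SmootherSpec, train_ages: np.ndarray) -> "_Basis":
        if spec.kind == "constant":
            return cls("constant", ncol=1)
        if spec.kind == "linear":
            return cls("linear", ncol=2)
        if spec.kind == "fractional_polynomial":
            powers = spec.powers or (1.0,)
            ncol = 1 + len(powers)
            return cls("fractional_polynomial", powers=tuple(powers), ncol=ncol)
        degree = 3 if spec.kind == "cubic_spline" else 2
        n_interior = spec.df - (degree + 1)
        if n_interior > 0:
            qs = np.linspace(0, 1, n_interior + 2)[1:-1]
            interior = np.quantile(np.asarray(train_ages, float), qs)
        else:
            interior = np.array([])
        knots = np.concatenate([[AGE_MIN] * (degree + 1), interior,
                                [AGE_MAX] * (degree + 1)])
        return cls(spec.kind, knots=tuple(float(k) for k in knots),
                   degree=degree, ncol=spec.df)

    def design(self, ages: np.ndarray) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        t = (ages - AGE_MIN) / (AGE_MAX - AGE_MIN)
        if self.kind == "constant":
            return np.ones((ages.size, 1))
        if self.kind == "linear":
            return np.column_stack([np.ones_like(t), t])
        if self.kind == "fractional_polynomial":
            cols = expand_fractional_polynomial(ages, self.powers)
            return np.column_stack([np.ones_like(t), cols])
        from scipy.interpolate import BSpline

        kn = np.asarray(self.knots)
        x = np.clip(ages, AGE_MIN, AGE_MAX)
        dm = BSpline.design_matrix(x, kn, self.degree, extrapolate=False)
        return dm.toarray()

    def describe(self) -> dict:
        return {"kind": self.kind, "knots": list(self.knots),
                "degree": self.degree, "powers": list(self.powers),
                "ncol": self.ncol}

    @classmethod
    def from_description(cls, d: dict) -> "_Basis":
        return cls(kind=d["kind"], knots=tuple(d["knots"]), degree=d["degree"],
                   powers=tuple(d["powers"]), ncol=d["ncol"])


@dataclass(frozen=True)
class FitControls:
    max_iter: int = 200
    #: relative deviance change declaring convergence
    tol: float = 1e-6
    #: ages checked for parameter-domain validity of the fitted curves
    grid_points: int = 81


_PARAM_NAMES = ("mu", "sigma", "nu", "tau")

DEFAULT_SMOOTHERS = {
    "mu": SmootherSpec("cubic_spline", df=5),
    "sigma": SmootherSpec("cubic_spline", df=4),
    "nu": SmootherSpec("constant"),
    "tau": SmootherSpec("constant"),
}


@dataclass
class CentileModel:
    """A fitted distributional centile model."""

    family: str
    bases: dict[str, _Basis]
    coefs: dict[str, np.ndarray]
    loglik: float
    edf: int
    converged: bool
    iterations: int
    deviance_trace: list[float] = field(default_factory=list)
    n_obs: int = 0

    # -- evaluation ---------------------------------------------------------
    def params_at(self, age) -> ParamVector:
        """Parameter curves evaluated at age(s), on the raw scale."""
        age = np.asarray(age, dtype=float)
        fam = get_family(self.family)
        vals = {}
        for nm in _PARAM_NAMES:
            eta = self.bases[nm].design(np.atleast_1d(age)) @ self.coefs[nm]
            theta = inv_link_fn(fam.links[nm])(eta)
            vals[nm] = theta if age.ndim else float(theta[0])
        return ParamVector(vals["mu"], vals["sigma"], vals["nu"], vals["tau"])

    def centile(self, age, p, floor: bool = True):
        age = np.asarray(age, dtype=float)
        if np.any(age < AGE_MIN) or np.any(age > AGE_MAX):
            raise ValueError(f"age outside [{AGE_MIN:.0f}, {AGE_MAX:.0f}]")
        fam = get_family(self.family)
        pv = self.params_at(age)
        q = fam.quantile(p, *pv)
        return np.maximum(q, 0.0) if floor else q

    def centile_curve(self, ages, p, floor: bool = True) -> np.ndarray:
        return np.asarray(self.centile(np.asarray(ages, float), p, floor=floor))

    def score_percentile(self, age, score) -> float:
        """100 * F(score) at the given age (the lookup inverse of centile)."""
        fam = get_family(self.family)
        pv = self.params_at(age)
        return float(100.0 * fam.cdf(score, *pv))

    def gaic(self, k: float) -> float:
        return gaic(self.loglik, self.edf, k)

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        fam = get_family(self.family)
        payload = {
            "model_kind": "distributional",
            "family": self.family,
            "links": dict(fam.links),
            "bases": {nm: b.describe() for nm, b in self.bases.items()},
            "coefs": {nm: list(map(float, c)) for nm, c in self.coefs.items()},
            "loglik": self.loglik,
            "edf": self.edf,
            "converged": self.converged,
            "iterations": self.iterations,
            "n_obs": self.n_obs,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "CentileModel":
        if isinstance(text_or_path, Path) or (
                isinstance(text_or_path, str) and "\n" not in text_or_path
                and Path(text_or_path).exists()):
            text = Path(text_or_path).read_text()
        else:
            text = str(text_or_path)
        d = json.loads(text)
        if d.get("model_kind") != "distributional":
            raise ValueError("not a distributional-model file")
        return cls(
            family=d["family"],
            bases={nm: _Basis.from_description(b) for nm, b in d["bases"].items()},
            coefs={nm: np.asarray(c, dtype=float) for nm, c in d["coefs"].items()},
            loglik=d["loglik"], edf=d["edf"], converged=d["converged"],
            iterations=d["iterations"], n_obs=d.get("n_obs", 0),
        )


def gaic(loglik_max: float, effective_df: float, k: float) -> float:
    """Generalized Akaike criterion -2*loglik + k*df (k = 2 is AIC)."""
    if effective_df < 0:
        raise ValueError("effective df must be >= 0")
    return -2.0 * loglik_max + k * effective_df


def _prepare(age, score, weight):
    age = np.asarray(age, dtype=float)
    score = np.asarray(score, dtype=float)
    weight = (np.ones_like(score) if weight is None
              else np.asarray(weight, dtype=float))
    ok = np.isfinite(age) & np.isfinite(score) & np.isfinite(weight)
    age, score, weight = age[ok], score[ok], weight[ok]
    if len(age) < 50:
        raise ValueError("need at least 50 observations to fit a centile model")
    if age.max() - age.min() <= 1.0:
        raise ValueError("observations must span more than one year of age")
    if np.any(weight <= 0):
        raise ValueError("weights must be strictly positive")
    return age, score, weight


def fit_distributional_model(age, score, weight=None,
                             family: str | Family = "SHASHo2",
                             smoothers: dict[str, SmootherSpec] | None = None,
                             controls: FitControls = FitControls(),
                             fixed: dict[str, float] | None = None) -> CentileModel:
    """Fit one family with the given parameter smoothers by direct weighted ML.

    ``fixed`` pins named parameters at constant raw-scale values instead of
    estimating them (e.g. ``{"nu": 0, "tau": 1}`` reduces a sinh-arcsinh
    family to its two-parameter Gaussian submodel); pinned parameters do
    not count towards the effective df.

    Returns a :class:`CentileModel`; ``converged`` is False when the
    deviance did not stabilize within ``controls.max_iter`` quasi-Newton
    iterations (such models are excluded from GAIC ranking).  Raises if the
    fitted scale/kurtosis curves leave their domain on the age grid.
    """
    fam = family if isinstance(family, Family) else get_family(family)
    smoothers = {**DEFAULT_SMOOTHERS, **(smoothers or {})}
    fixed = dict(fixed or {})
    for nm in fixed:
        if nm not in _PARAM_NAMES:
            raise ValueError(f"cannot fix unknown parameter {nm!r}")
        smoothers[nm] = SmootherSpec("constant")
    age, score, weight = _prepare(age, score, weight)

    bases = {nm: smoothers[nm].build(age) for nm in _PARAM_NAMES}
    designs = {nm: bases[nm].design(age) for nm in _PARAM_NAMES}
    free = [nm for nm in _PARAM_NAMES if nm not in fixed]
    sizes = [bases[nm].ncol for nm in free]
    splits = np.cumsum(sizes)[:-1]

    # starting values: weighted least squares for the location curve,
    # weighted SD for the scale intercept, family-specific shape points
    w_sqrt = np.sqrt(weight)
    Xm = designs["mu"]
    beta_mu, *_ = np.linalg.lstsq(Xm * w_sqrt[:, None], score * w_sqrt, rcond=None)
    mean0 = float(np.sum(weight * score) / np.sum(weight))
    sd0 = float(np.sqrt(np.sum(weight * (score - mean0) ** 2) / np.sum(weight)))
    sd0 = max(sd0, 1e-6)
    nu0, tau0 = _SHAPE_START[fam.name]
    start_raw = {"sigma": sd0, "nu": nu0, "tau": tau0}

    def init_block(nm: str) -> np.ndarray:
        if nm == "mu":
            return beta_mu
        b = np.zeros(bases[nm].ncol)
        b[0] = link_fn(fam.links[nm])(start_raw[nm]) \
            if fam.links[nm] != "identity" else start_raw[nm]
        return b

    theta0 = np.concatenate([init_block(nm) for nm in free])

    inv_links = {nm: inv_link_fn(fam.links[nm]) for nm in _PARAM_NAMES}
    fixed_coefs = {nm: np.array([link_fn(fam.links[nm])(v)])
                   for nm, v in fixed.items()}

    def unpack(theta):
        blocks = dict(zip(free, np.split(theta, splits)))
        out = {}
        for nm in _PARAM_NAMES:
            b = blocks[nm] if nm in blocks else fixed_coefs[nm]
            out[nm] = inv_links[nm](designs[nm] @ b)
        return out

    BIG = 1e12

    def negloglik(theta):
        p = unpack(theta)
        with np.errstate(all="ignore"):
            lp = fam.logpdf(score, p["mu"], p["sigma"], p["nu"], p["tau"])
        if not np.all(np.isfinite(lp)):
            return BIG
        return -float(np.sum(weight * lp))

    trace: list[float] = [2.0 * negloglik(theta0)]

    def cb(xk):
        trace.append(2.0 * negloglik(xk))

    res = optimize.minimize(negloglik, theta0, method="L-BFGS-B",
                            callback=cb,
                            options={"maxiter": controls.max_iter,
                                     "ftol": 1e-12, "gtol": 1e-8})
    # convergence per the deviance-stabilization rule
    converged = bool(res.success)
    if len(trace) >= 2:
        rel = abs(trace[-1] - trace[-2]) / (abs(trace[-2]) + 1e-12)
        converged = converged or rel < controls.tol
    if negloglik(res.x) >= BIG:
        raise ConvergenceError(f"{fam.name}: likelihood degenerate at optimum")

    coefs = dict(zip(free, np.split(res.x, splits)))
    coefs.update(fixed_coefs)
    model = CentileModel(
        family=fam.name, bases=bases, coefs=coefs,
        loglik=-float(res.fun), edf=int(sum(sizes)),
        converged=converged, iterations=int(res.nit),
        deviance_trace=trace, n_obs=len(score),
    )

    # in-domain check of the fitted curves over the age grid
    grid = np.linspace(AGE_MIN, AGE_MAX, controls.grid_points)
    pv = model.params_at(grid)
    if (np.any(~np.isfinite(pv.mu)) or np.any(pv.sigma <= 0)
            or np.any(pv.tau <= 0)):
        raise ConvergenceError(
            f"{fam.name}: fitted parameter curves leave the domain on [45, 85]")
    return model


@dataclass(frozen=True)
class GamlssSpec:
    """A refittable model specification (family + smoothers + controls)."""

    family: str = "SHASHo2"
    smoothers: tuple[tuple[str, SmootherSpec], ...] = ()
    controls: FitControls = FitControls()
    #: ((param, raw value), ...) pins, e.g. (("nu", 0.0), ("tau", 1.0))
    fixed: tuple[tuple[str, float], ...] = ()
    label: str = ""

    @property
    def name(self) -> str:
        if self.label:
            return self.label
        suffix = "".join(f";{nm}={v:g}" for nm, v in self.fixed)
        return f"gamlss:{self.family}{suffix}"

    def fit(self, age, score, weight=None) -> CentileModel:
        return fit_distributional_model(age, score, weight, self.family,
                                        dict(self.smoothers), self.controls,
                                        fixed=dict(self.fixed))


def rank_families(age, score, weight=None,
                  family_list=("SHASH", "SHASHo", "SHASHo2", "SEP1", "SEP2"),
                  smoothers: dict[str, SmootherSpec] | None = None,
                  k: float = 2.0,
                  top_m: int | None = None):
    """Fit each candidate and return converged models sorted by ascending
    GAIC(k); ties (within 1e-9) break by smaller edf, then by the order the
    candidates were given.  Candidates are family names (sharing
    ``smoothers``) or ``(family, smoothers)`` pairs.  Raises if every
    candidate fails, with per-candidate diagnostics."""
    if len(family_list) < 1:
        raise ValueError("need at least one candidate family")
    fitted, failures = [], {}
    for order, cand in enumerate(family_list):
        name, sm = (cand, smoothers) if isinstance(cand, str) else cand
        try:
            m = fit_distributional_model(age, score, weight, name, sm)
        except Exception as e:  # noqa: BLE001 - diagnostics per model
            failures[f"{name}#{order}"] = f"{type(e).__name__}: {e}"
            continue
        if not m.converged:
            failures[f"{name}#{order}"] = \
                f"no convergence in {m.iterations} iterations"
            continue
        fitted.append((m.gaic(k), m.edf, order, m))
    if not fitted:
        raise ConvergenceError(f"all candidate families failed: {failures}")
    fitted.sort(key=lambda t: (round(t[0], 9), t[1], t[2]))
    models = [m for *_, m in fitted]
    return models[:top_m] if top_m else models


def centile(model: CentileModel, age, p, floor: bool = True):
    """Score at the p-th centile of the fitted model at the given age."""
    return model.centile(age, p, floor=floor)
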