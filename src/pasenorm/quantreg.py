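"""Per-percentile quantile regression of score on age.

The tau-th regression quantile minimizes the weighted pinball (check) loss

    L(beta) = sum_i w_i * rho_tau(y_i - f(age_i)),   rho_tau(u) = u*(tau - 1{u<0})

over curves f in one of four basis families: age linear, polynomial (order
2-4), fractional polynomial (conventional powers, degree <= 2), or a
smoothed additive fit (piecewise-linear in age with a total-variation
penalty on the slope changes).  Every fit is solved exactly as a linear
program (HiGHS), so the achieved loss is optimal for the basis, not just a
local minimum.

Independently fitted quantile curves can cross in finite samples; the
monotone rearrangement :func:`rearrange_noncrossing` sorts fitted values
across quantile levels at every age, which never increases total pinball
loss and leaves already-ordered curves untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import optimize, sparse

__all__ = [
    "FP_POWERS",
    "DEFAULT_TAUS",
    "expand_fractional_polynomial",
    "fit_quantile",
    "fit_smoothed_additive_quantile",
    "rearrange_noncrossing",
    "pinball_loss",
    "QuantRegBasis",
    "QuantRegSpec",
    "QuantileModelSet",
]

#: the conventional fractional-polynomial power set
FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

#: percentile levels reported in the norm tables
DEFAULT_TAUS = (0.05, 0.10, 0.20, 0.25, 0.50, 0.75, 0.80, 0.90, 0.95)

AGE_MIN, AGE_MAX = 45.0, 85.0


def pinball_loss(residuals, tau, weights=None) -> float:
    u = np.asarray(residuals, dtype=float)
    w = np.ones_like(u) if weights is None else np.asarray(weights, dtype=float)
    return float(np.sum(w * u * (tau - (u < 0))))


def expand_fractional_polynomial(ages, powers, scale: float = 10.0) -> np.ndarray:
    """Fractional-polynomial basis columns for x = age / scale.

    Power p maps to x**p, with p = 0 meaning log(x); a power repeated m
    times contributes x**p * log(x)**(m-1) per the usual FP convention.
    Ages must be strictly positive after scaling.
    """
    x = np.asarray(ages, dtype=float) / scale
    if np.any(x <= 0):
        raise ValueError("fractional polynomials need strictly positive ages "
                         "(supply a shift or scale)")
    powers = tuple(float(p) for p in powers)
    for p in powers:
        if p not in FP_POWERS:
            raise ValueError(f"power {p} not in the conventional set {FP_POWERS}")
    cols: list[np.ndarray] = []
    prev: float | None = None
    for p in sorted(powers):
        base = np.log(x) if p == 0.0 else x ** p
        if prev is not None and p == prev:
            cols.append(cols[-1] * np.log(x))
        else:
            cols.append(base)
        prev = p
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# core LP solver


def _solve_pinball_lp(X: np.ndarray, y: np.ndarray, w: np.ndarray, tau: float,
                      D: np.ndarray | None = None, penalty: float = 0.0):
    """Exact LP minimizer of sum w*rho_tau(y - X beta) (+ penalty * |D beta|_1).

    Variables: beta (free), residual splits u+, u- >= 0 and, when D is
    given, penalty splits v+, v- >= 0 with D beta = v+ - v-.
    """
    n, p = X.shape
    m = 0 if D is None else D.shape[0]
    c = np.concatenate([np.zeros(p), tau * w, (1.0 - tau) * w,
                        np.full(2 * m, penalty)])
    A_top = sparse.hstack([sparse.csr_matrix(X), sparse.eye(n), -sparse.eye(n)]
                          + ([sparse.csr_matrix((n, 2 * m))] if m else []))
    blocks = [A_top]
    if m:
        A_pen = sparse.hstack([sparse.csr_matrix(D),
                               sparse.csr_matrix((m, 2 * n)),
                               -sparse.eye(m), sparse.eye(m)])
        blocks.append(A_pen)
    A_eq = sparse.vstack(blocks, format="csc")
    b_eq = np.concatenate([y, np.zeros(m)])
    bounds = [(None, None)] * p + [(0, None)] * (2 * n + 2 * m)
    res = optimize.linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
                           method="highs")
    if not res.success:
        raise RuntimeError(f"quantile LP failed: {res.message}")
    beta = res.x[:p]
    loss = pinball_loss(y - X @ beta, tau, w)
    return beta, loss


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a minimal set of columns beyond a full-rank prefix
        bad = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            cand = X[:, kept + [j]]
            if np.linalg.matrix_rank(cand) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_quantile(age, score, weight=None, basis: "QuantRegBasis | None" = None,
                 tau: float = 0.5):
    """Fit one regression quantile; returns (coefficients, achieved loss).

    ``basis=None`` means intercept-only (the weighted tau-quantile of the
    scores)."""
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    age = np.asarray(age, dtype=float)
    y = np.asarray(score, dtype=float)
    w = np.ones_like(y) if weight is None else np.asarray(weight, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    basis = basis or QuantRegBasis("intercept")
    X, names = basis.design(age, with_names=True)
    _check_rank(X, names)
    return _solve_pinball_lp(X, y, w, tau)


def fit_smoothed_additive_quantile(age, score, weight=None, tau: float = 0.5,
                                   penalty: float = 1.0, n_knots: int = 20):
    """Penalized piecewise-linear regression quantile.

    Minimizes pinball loss plus ``penalty`` times the total variation of the
    fitted curve's slope (the l1 norm of its knot-to-knot slope changes).
    penalty -> infinity therefore recovers the straight-line fit; penalty 0
    lets the curve bend freely at every knot.  Returns (knots, values, loss).
    """
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    age = np.asarray(age, dtype=float)
    y = np.asarray(score, dtype=float)
    w = np.ones_like(y) if weight is None else np.asarray(weight, dtype=float)
    uniq = np.unique(age)
    if uniq.size < 2:
        raise ValueError("need at least two distinct ages")
    if uniq.size <= n_knots:
        knots = uniq
    else:
        knots = np.unique(np.quantile(age, np.linspace(0, 1, n_knots)))
    X = _interp_matrix(age, knots)
    h = np.diff(knots)
    m = knots.size
    # slope-change operator: rows are (theta[j+2]-theta[j+1])/h2 - (theta[j+1]-theta[j])/h1
    D = np.zeros((m - 2, m))
    for j in range(m - 2):
        D[j, j] = 1.0 / h[j]
        D[j, j + 1] = -1.0 / h[j] - 1.0 / h[j + 1]
        D[j, j + 2] = 1.0 / h[j + 1]
    theta, loss = _solve_pinball_lp(X, y, w, tau, D=D, penalty=penalty)
    return knots, theta, loss


def _interp_matrix(ages: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Rows of piecewise-linear interpolation weights from knot values to
    the given ages (linear extrapolation outside the knot span)."""
    n, m = ages.size, knots.size
    X = np.zeros((n, m))
    j = np.clip(np.searchsorted(knots, ages, side="right") - 1, 0, m - 2)
    t = (ages - knots[j]) / (knots[j + 1] - knots[j])
    X[np.arange(n), j] = 1.0 - t
    X[np.arange(n), j + 1] = t
    return X


def rearrange_noncrossing(curves: dict[float, np.ndarray]) -> dict[float, np.ndarray]:
    """Monotone rearrangement across quantile levels on a common age grid.

    At every grid age, the fitted values are sorted and reassigned to the
    quantile levels in ascending order; already-monotone inputs come back
    unchanged (idempotent), and total pinball loss never increases."""
    taus = sorted(curves)
    stacked = np.vstack([np.asarray(curves[t], dtype=float) for t in taus])
    stacked = np.sort(stacked, axis=0)
    return {t: stacked[i] for i, t in enumerate(taus)}


# ---------------------------------------------------------------------------
# basis + model-set containers


@dataclass(frozen=True)
class QuantRegBasis:
    """One of the four model bases (plus plain intercept for tests).

    kind: "intercept", "linear", "polynomial" (order 2-4),
    "fractional_polynomial" (powers, degree <= 2) or "smoothed_additive"
    (penalty; handled by the penalized piecewise-linear fitter).
    """

    kind: str = "linear"
    order: int = 2
    powers: tuple[float, ...] = (0.0, 1.0)
    penalty: float = 1.0

    def __post_init__(self):
        if self.kind not in ("intercept", "linear", "polynomial",
                             "fractional_polynomial", "smoothed_additive"):
            raise ValueError(f"unknown basis kind {self.kind!r}")
        if self.kind == "polynomial" and not 2 <= self.order <= 4:
            raise ValueError("polynomial order must be 2-4")
        if self.kind == "fractional_polynomial" and len(self.powers) > 2:
            raise ValueError("fractional-polynomial degree is capped at 2")

    @property
    def label(self) -> str:
        return {"intercept": "intercept",
                "linear": "linear",
                "polynomial": f"poly{self.order}",
                "fractional_polynomial": "fp" + ",".join(map(str, self.powers)),
                "smoothed_additive": f"smooth(l={self.penalty:g})"}[self.kind]

    def design(self, ages: np.ndarray, with_names: bool = False):
        ages = np.asarray(ages, dtype=float)
        t = (ages - AGE_MIN) / (AGE_MAX - AGE_MIN)
        if self.kind == "intercept":
            X, names = np.ones((ages.size, 1)), ["const"]
        elif self.kind == "linear":
            X, names = np.column_stack([np.ones_like(t), t]), ["const", "age"]
        elif self.kind == "polynomial":
            cols = [np.ones_like(t)] + [t ** d for d in range(1, self.order + 1)]
            X = np.column_stack(cols)
            names = ["const"] + [f"age^{d}" for d in range(1, self.order + 1)]
        elif self.kind == "fractional_polynomial":
            fp = expand_fractional_polynomial(ages, self.powers)
            X = np.column_stack([np.ones(ages.size), fp])
            names = ["const"] + [f"fp({p})" for p in sorted(self.powers)]
        else:
            raise ValueError("smoothed_additive has no fixed design matrix")
        return (X, names) if with_names else X


@dataclass(frozen=True)
class QuantRegSpec:
    """Refittable quantile-model specification: one basis shared by all
    requested quantile levels."""

    basis: QuantRegBasis = QuantRegBasis("linear")
    taus: tuple[float, ...] = DEFAULT_TAUS
    use_weights: bool = True
    label: str = ""

    @property
    def name(self) -> str:
        return self.label or f"quantreg:{self.basis.label}"

    def fit(self, age, score, weight=None) -> "QuantileModelSet":
        w = weight if self.use_weights else None
        coefs, losses, knots = {}, {}, None
        for tau in self.taus:
            if self.basis.kind == "smoothed_additive":
                knots, theta, loss = fit_smoothed_additive_quantile(
                    age, score, w, tau, self.basis.penalty)
                coefs[tau] = theta
            else:
                beta, loss = fit_quantile(age, score, w, self.basis, tau)
                coefs[tau] = beta
            losses[tau] = loss
        return QuantileModelSet(basis=self.basis, taus=tuple(self.taus),
                                coefs=coefs, losses=losses,
                                knots=None if knots is None else np.asarray(knots))


@dataclass
class QuantileModelSet:
    """Fitted per-percentile regression curves sharing one basis."""

    basis: QuantRegBasis
    taus: tuple[float, ...]
    coefs: dict[float, np.ndarray]
    losses: dict[float, float]
    knots: np.ndarray | None = None
    converged: bool = True   # LP solutions are exact

    def _predict_one(self, ages: np.ndarray, tau: float) -> np.ndarray:
        if tau not in self.coefs:
            raise KeyError(f"tau {tau} was not fitted (have {sorted(self.coefs)})")
        if self.basis.kind == "smoothed_additive":
            X = _interp_matrix(np.asarray(ages, float), self.knots)
        else:
            X = self.basis.design(ages)
        return X @ self.coefs[tau]

    def centile(self, age, p, floor: bool = True):
        """Fitted score at quantile level p (one of the fitted taus) with
        per-age monotone rearrangement across the fitted levels."""
        ages = np.atleast_1d(np.asarray(age, dtype=float))
        if np.any(ages < AGE_MIN) or np.any(ages > AGE_MAX):
            raise ValueError(f"age outside [{AGE_MIN:.0f}, {AGE_MAX:.0f}]")
        p = float(p)
        matches = [t for t in self.taus if abs(t - p) < 1e-9]
        if not matches:
            raise KeyError(f"quantile level {p} not fitted (have {self.taus})")
        raw = {t: self._predict_one(ages, t) for t in self.taus}
        fixed = rearrange_noncrossing(raw)
        out = fixed[matches[0]]
        if floor:
            out = np.maximum(out, 0.0)
        return out if np.ndim(age) else float(out[0])

    def centile_curve(self, ages, p, floor: bool = True) -> np.ndarray:
        return np.asarray(self.centile(np.asarray(ages, float), p, floor=floor))

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "model_kind": "quantreg",
            "basis": {"kind": self.basis.kind, "order": self.basis.order,
                      "powers": list(self.basis.powers),
                      "penalty": self.basis.penalty},
            "taus": list(self.taus),
            "coefs": {str(t): list(map(float, c)) for t, c in self.coefs.items()},
            "losses": {str(t): float(v) for t, v in self.losses.items()},
            "knots": None if self.knots is None else list(map(float, self.knots)),
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "QuantileModelSet":
        if isinstance(text_or_path, Path) or (
                isinstance(text_or_path, str) and "\n" not in text_or_path
                and Path(text_or_path).exists()):
            text = Path(text_or_path).read_text()
        else:
            text = str(text_or_path)
        d = json.loads(text)
        if d.get("model_kind") != "quantreg":
            raise ValueError("not a quantile-model file")
        b = d["basis"]
        basis = QuantRegBasis(kind=b["kind"], order=b["order"],
                              powers=tuple(b["powers"]), penalty=b["penalty"])
        return cls(
            basis=basis, taus=tuple(d["taus"]),
            coefs={float(t): np.asarray(c, float) for t, c in d["coefs"].items()},
            losses={float(t): v for t, v in d["losses"].items()},
            knots=None if d["knots"] is None else np.asarray(d["knots"], float),
        )
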