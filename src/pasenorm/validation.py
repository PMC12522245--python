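"""Repeated cross-validation of centile models by holdout coverage.

The comparison procedure: split the sample 70/30 at random *within every
year of age* (so both halves span the age range), fit each candidate model
specification on the training part, and measure on the holdout the
weighted fraction of subjects whose score falls below the fitted 5th and
50th centile curves and above the 95th.  A well-calibrated model gives
fractions near 0.05 / 0.50 / 0.05.  The split-fit-evaluate cycle is
repeated (100 times in the reference procedure) and coverages averaged.

Model selection prioritizes the lowest centile: among candidates the rule
is lexicographic — smallest |mean below-P5 - 0.05| first, with ties
(within 0.002) broken by the 50th, then the 95th, then by fewer failed
replicates — because identifying the least-active individuals is the
main clinical use of the curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CoverageReport",
    "stratified_split",
    "holdout_coverage",
    "cross_validate",
    "select_model",
]

_GRID_STEP = 0.25  # age resolution for centile-curve interpolation


def stratified_split(data: pd.DataFrame, train_fraction: float = 0.70,
                     seed: int | None = 0, age_col: str = "age"):
    """Random train/test split within each integer-year age stratum.

    Within a stratum of size n, round-half-up of ``train_fraction * n``
    records go to train.  Strata with a single record are flagged and sent
    whole to train.  Deterministic given the seed.  Returns
    (train, test, flagged_strata).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    years = np.floor(data[age_col].to_numpy(float)).astype(int)
    train_idx, test_idx, flagged = [], [], []
    for year in np.unique(years):
        idx = data.index[years == year].to_numpy()
        n = idx.size
        if n < 2:
            flagged.append(int(year))
            train_idx.extend(idx)
            continue
        k = int(np.floor(train_fraction * n + 0.5))  # round half up
        k = min(max(k, 1), n - 1)
        perm = rng.permutation(n)
        train_idx.extend(idx[perm[:k]])
        test_idx.extend(idx[perm[k:]])
    return data.loc[train_idx], data.loc[test_idx], flagged


def holdout_coverage(model, test: pd.DataFrame,
                     weight_col: str | None = "analytic_weight",
                     age_col: str = "age", score_col: str = "pase_total"):
    """Weighted holdout coverage at the 5th/50th/95th fitted centiles.

    Returns (below_P5, below_P50, above_P95): weighted fractions of test
    subjects with score strictly below the fitted 5th / 50th centile at
    their age, and strictly above the fitted 95th.  Centile curves are
    evaluated on a fine age grid and interpolated to subject ages.
    """
    ages = test[age_col].to_numpy(float)
    scores = test[score_col].to_numpy(float)
    w = (np.ones_like(scores) if weight_col is None
         else test[weight_col].to_numpy(float))
    grid = np.arange(np.floor(ages.min()), np.ceil(ages.max()) + _GRID_STEP,
                     _GRID_STEP)
    grid = np.clip(grid, 45.0, 85.0)
    tot = float(np.sum(w))

    def frac(level, above=False):
        curve = np.asarray(model.centile_curve(grid, level))
        at_age = np.interp(ages, grid, curve)
        hit = scores > at_age if above else scores < at_age
        return float(np.sum(w[hit]) / tot)

    return frac(0.05), frac(0.50), frac(0.95, above=True)


@dataclass
class CoverageReport:
    """Averaged holdout coverage for one model specification."""

    model: str
    reps: int
    mean_below_p5: float
    mean_below_p50: float
    mean_above_p95: float
    sd_below_p5: float
    sd_below_p50: float
    sd_above_p95: float
    n_failed: int
    per_rep: pd.DataFrame = field(repr=False, default=None)

    def to_row(self) -> dict:
        return {k: getattr(self, k) for k in
                ("model", "reps", "mean_below_p5", "mean_below_p50",
                 "mean_above_p95", "sd_below_p5", "sd_below_p50",
                 "sd_above_p95", "n_failed")}


def cross_validate(model_specs, data: pd.DataFrame, reps: int = 100,
                   seed: int = 0, train_fraction: float = 0.70,
                   weight_col: str | None = "analytic_weight",
                   age_col: str = "age", score_col: str = "pase_total"):
    """Repeated split-fit-evaluate over every spec; returns a list of
    :class:`CoverageReport`, one per spec, in the given order.

    Every spec sees the identical sequence of splits (per-rep seeds are
    spawned from the master seed), so reports are comparable and the
    procedure is deterministic.  A spec that fails to fit in some replicate
    has that replicate recorded as failed and excluded from its averages.
    """
    specs = list(model_specs)
    if not specs:
        raise ValueError("need at least one model specification")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rep_seeds = np.random.SeedSequence(seed).generate_state(reps) % (2 ** 31)
    records: dict[str, list] = {s.name: [] for s in specs}
    for r in range(reps):
        train, test, _ = stratified_split(data, train_fraction,
                                          seed=int(rep_seeds[r]),
                                          age_col=age_col)
        w_train = (None if weight_col is None
                   else train[weight_col].to_numpy(float))
        for s in specs:
            try:
                fitted = s.fit(train[age_col].to_numpy(float),
                               train[score_col].to_numpy(float), w_train)
                if getattr(fitted, "converged", True) is False:
                    raise RuntimeError("model did not converge")
                cov = holdout_coverage(fitted, test, weight_col,
                                       age_col, score_col)
                records[s.name].append((r, *cov, False))
            except Exception:  # noqa: BLE001 - failure is a recorded outcome
                records[s.name].append((r, np.nan, np.nan, np.nan, True))
    reports = []
    for s in specs:
        df = pd.DataFrame(records[s.name],
                          columns=["rep", "below_p5", "below_p50",
                                   "above_p95", "failed"])
        ok = df[~df["failed"]]
        n_failed = int(df["failed"].sum())
        if len(ok):
            means = ok[["below_p5", "below_p50", "above_p95"]].mean()
            sds = ok[["below_p5", "below_p50", "above_p95"]].std(ddof=0)
        else:
            means = sds = pd.Series(np.nan, index=["below_p5", "below_p50",
                                                   "above_p95"])
        reports.append(CoverageReport(
            model=s.name, reps=reps,
            mean_below_p5=float(means["below_p5"]),
            mean_below_p50=float(means["below_p50"]),
            mean_above_p95=float(means["above_p95"]),
            sd_below_p5=float(sds["below_p5"]),
            sd_below_p50=float(sds["below_p50"]),
            sd_above_p95=float(sds["above_p95"]),
            n_failed=n_failed, per_rep=df))
    return reports


def select_model(reports) -> CoverageReport:
    """Choose the best-calibrated specification, weighting the 5th centile
    most: lexicographically minimize |below_P5 - 0.05|, breaking ties
    (within 0.002) by |below_P50 - 0.50|, then |above_P95 - 0.05|, then
    fewer failed replicates."""
    candidates = [r for r in reports
                  if r.reps > r.n_failed and np.isfinite(r.mean_below_p5)]
    if not candidates:
        raise ValueError("no successful coverage reports to select from")
    TIE = 0.002

    def coarse(x):  # bucket within the tie tolerance
        return round(x / TIE)

    return min(candidates, key=lambda r: (
        coarse(abs(r.mean_below_p5 - 0.05)),
        coarse(abs(r.mean_below_p50 - 0.50)),
        coarse(abs(r.mean_above_p95 - 0.05)),
        r.n_failed,
        abs(r.mean_below_p5 - 0.05),
    ))
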