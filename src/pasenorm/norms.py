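"""Normative tables and charts, score lookup, and the end-to-end pipeline.

A norm table is an age (45-85, integer grid) by percentile
(5, 10, 20, 25, 50, 75, 80, 90, 95) grid of scores for one sex and
optionally one season, produced from a fitted centile model.  Values are
floored at zero and made strictly increasing across percentiles at every
age by monotone rearrangement (plus a minimal epsilon where a floor
creates ties).  Tables round to whole scores for display but keep full
precision in machine-readable output.

:func:`run_pipeline` composes the whole procedure — simulate (or load) a
cohort, apply eligibility filtering, fit the distributional and
quantile-regression candidates per sex, compare them by repeated 70/30
cross-validation coverage, select a model, and emit tables, charts,
serialized models and a manifest keyed by a config hash and master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as _cohort
from .cohort import (GeneratorSpec, apply_exclusions, assign_season,
                     generate_cohort, weighted_descriptives)
from .gamlss import GamlssSpec
from .quantreg import QuantRegBasis, QuantRegSpec
from .validation import cross_validate, select_model

__all__ = [
    "PERCENTILES",
    "NormTable",
    "build_norm_table",
    "lookup_percentile",
    "PercentileStatement",
    "render_norm_chart",
    "PipelineConfig",
    "run_pipeline",
]

PERCENTILES = (5, 10, 20, 25, 50, 75, 80, 90, 95)
AGES = tuple(range(45, 86))


@dataclass
class NormTable:
    sex: str
    season: str                 # "all" or winter/spring/summer/fall
    ages: np.ndarray            # integer age grid
    percentiles: tuple[int, ...]
    values: np.ndarray          # (n_ages, n_percentiles)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ages = np.asarray(self.ages)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.ages.size, len(self.percentiles)):
            raise ValueError("values grid does not match ages x percentiles")
        if np.any(self.values < 0) or np.any(~np.isfinite(self.values)):
            raise ValueError("norm-table cells must be finite and non-negative")
        if np.any(np.diff(self.values, axis=1) <= 0):
            raise ValueError("norm-table rows must increase strictly with percentile")

    def cell(self, age: int, percentile: int) -> float:
        i = int(np.where(self.ages == age)[0][0])
        j = self.percentiles.index(percentile)
        return float(self.values[i, j])

    def to_frame(self, rounded: bool = False) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.ages):
            for j, p in enumerate(self.percentiles):
                v = self.values[i, j]
                rows.append({"sex": self.sex, "season": self.season,
                             "age": int(a), "percentile": int(p),
                             "score": int(round(v)) if rounded else float(v)})
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path, rounded: bool = False) -> None:
        self.to_frame(rounded=rounded).to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "NormTable":
        sexes = frame["sex"].unique()
        seasons = frame["season"].unique()
        if len(sexes) != 1 or len(seasons) != 1:
            raise ValueError("frame must hold exactly one sex/season stratum")
        pivot = frame.pivot(index="age", columns="percentile", values="score")
        pivot = pivot.sort_index().sort_index(axis=1)
        return cls(sex=str(sexes[0]), season=str(seasons[0]),
                   ages=pivot.index.to_numpy(),
                   percentiles=tuple(int(p) for p in pivot.columns),
                   values=pivot.to_numpy())


def build_norm_table(model, sex: str, season: str = "all",
                     ages=AGES, percentiles=PERCENTILES,
                     provenance: dict | None = None) -> NormTable:
    """Evaluate a fitted model's centiles on the integer age grid.

    Cells are floored at zero; strict monotonicity across the percentile
    axis is enforced by per-age sorting plus an epsilon lift where the zero
    floor (or rearrangement) leaves exact ties."""
    if getattr(model, "converged", True) is False:
        raise ValueError("refusing to tabulate a non-converged model")
    ages = np.asarray(list(ages))
    if len(percentiles) == 0:
        raise ValueError("no percentiles requested")
    grid = ages.astype(float)
    cols = [np.maximum(np.asarray(model.centile_curve(grid, p / 100.0)), 0.0)
            for p in percentiles]
    values = np.sort(np.column_stack(cols), axis=1)
    # break exact ties (e.g. several low centiles floored to 0)
    eps = 1e-9
    for j in range(1, values.shape[1]):
        values[:, j] = np.maximum(values[:, j], values[:, j - 1] + eps)
    return NormTable(sex=sex, season=season, ages=ages,
                     percentiles=tuple(int(p) for p in percentiles),
                     values=values, provenance=provenance or {})


@dataclass(frozen=True)
class PercentileStatement:
    """Result of placing a score on the normative scale."""

    statement: str
    percentile: float | None = None  # numeric value when determinable

    def __str__(self):
        return self.statement


def lookup_percentile(table_or_model, age: float, score: float) -> PercentileStatement:
    """Place a score: with a model, the exact percentile 100*F(score|age);
    with only a table, linear interpolation between the bracketing
    percentile rows (scores outside [P5, P95] report "<5" / ">95")."""
    if score < 0:
        raise ValueError("score must be >= 0")
    if isinstance(table_or_model, NormTable):
        table = table_or_model
        if not table.ages.min() <= age <= table.ages.max():
            raise ValueError("age outside the table grid")
        pcts = np.asarray(table.percentiles, dtype=float)
        # interpolate each percentile's score to the requested age
        row = np.array([np.interp(age, table.ages.astype(float), table.values[:, j])
                        for j in range(len(pcts))])
        if score < row[0]:
            return PercentileStatement(f"<{int(pcts[0])}")
        if score > row[-1]:
            return PercentileStatement(f">{int(pcts[-1])}")
        p = float(np.interp(score, row, pcts))
        lo = int(pcts[np.searchsorted(row, score, side="right") - 1])
        hi = int(pcts[min(np.searchsorted(row, score, side="left"),
                          len(pcts) - 1)])
        return PercentileStatement(
            f"~{p:.0f} (between P{lo} and P{hi})" if lo != hi else f"{p:.0f}",
            percentile=p)
    model = table_or_model
    if not 45.0 <= age <= 85.0:
        raise ValueError("age outside [45, 85]")
    p = float(model.score_percentile(age, score))
    return PercentileStatement(f"{p:.1f}", percentile=p)


def render_norm_chart(table: NormTable, path: str | Path) -> Path:
    """Percentile chart: age on x, score on y, one labeled line per
    percentile.  Deterministic output (fixed renderer settings, no
    timestamp metadata)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(table.percentiles) == 0:
        raise ValueError("nothing to draw: table has no percentiles")
    with plt.rc_context({"svg.hashsalt": "pasenorm"}):
        fig, ax = plt.subplots(figsize=(7, 5))
        for j, p in enumerate(table.percentiles):
            ax.plot(table.ages, table.values[:, j], label=f"P{p}")
        ax.set_xlabel("Age (years)")
        ax.set_ylabel("PASE total score")
        title = f"PASE percentiles, {table.sex}"
        if table.season != "all":
            title += f" ({table.season})"
        ax.set_title(title)
        ax.legend(loc="upper right", fontsize=8, ncol=2)
        fig.tight_layout()
        path = Path(path)
        fig.savefig(path, metadata=_svg_metadata(path))
        plt.close(fig)
    return path


def _svg_metadata(path: Path):
    if path.suffix.lower() == ".svg":
        return {"Date": None, "Creator": None}
    return None


# ---------------------------------------------------------------------------
# the pipeline


def default_model_specs(family: str) -> list:
    """The standard candidate set: one distributional model plus the six
    quantile-regression bases (linear, polynomial 2-4, smoothed, FP2)."""
    return [
        GamlssSpec(family=family),
        QuantRegSpec(QuantRegBasis("linear")),
        QuantRegSpec(QuantRegBasis("polynomial", order=2)),
        QuantRegSpec(QuantRegBasis("polynomial", order=3)),
        QuantRegSpec(QuantRegBasis("polynomial", order=4)),
        QuantRegSpec(QuantRegBasis("smoothed_additive", penalty=10.0)),
        QuantRegSpec(QuantRegBasis("fractional_polynomial", powers=(0.0, 1.0))),
    ]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the end-to-end run needs; hashable into a manifest key."""

    seed: int = 0
    #: path to a cohort CSV, or None to simulate
    input_csv: str | None = None
    generator: GeneratorSpec = GeneratorSpec()
    #: candidate families screened by GAIC per sex (first stage)
    families: tuple[str, ...] = ("SHASHo2", "SEP4", "JSU", "SHASHo")
    gaic_k: tuple[float, ...] = (2.0, 3.84, 5.0, 9.0)
    cv_reps: int = 20
    #: quantile-regression competitors included in the CV comparison
    quantreg_bases: tuple[str, ...] = ("linear", "poly3", "fp")
    season_stratified: bool = False
    out_dir: str = "pasenorm_out"

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")  # where artifacts land is not part of the run
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _quantreg_specs(names, taus=None) -> list[QuantRegSpec]:
    lut = {
        "linear": QuantRegBasis("linear"),
        "poly2": QuantRegBasis("polynomial", order=2),
        "poly3": QuantRegBasis("polynomial", order=3),
        "poly4": QuantRegBasis("polynomial", order=4),
        "smooth": QuantRegBasis("smoothed_additive", penalty=10.0),
        "fp": QuantRegBasis("fractional_polynomial", powers=(0.0, 1.0)),
    }
    kw = {} if taus is None else {"taus": tuple(taus)}
    return [QuantRegSpec(lut[n], **kw) for n in names]


def run_pipeline(config: PipelineConfig = PipelineConfig()) -> dict:
    """Simulate/load -> filter -> fit -> rank -> cross-validate -> select ->
    tables and charts.  Writes all artifacts under ``config.out_dir`` and
    returns the manifest (also written as ``manifest.json``).

    Any stage failure raises after writing partial outputs under a
    ``failed/`` prefix inside the output directory.
    """
    from .gamlss import rank_families

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    stage = "simulate"
    try:
        if config.input_csv:
            df = pd.read_csv(config.input_csv, parse_dates=["interview_date"])
        else:
            df = generate_cohort(config.generator, seed=config.seed)
        included, excluded, missing = apply_exclusions(df)
        manifest["stages"]["filter"] = {
            "n_total": len(df), "n_included": len(included),
            "n_excluded": len(excluded), "n_missing_dropped": len(missing)}
        included = included.assign(season=assign_season(included["interview_date"]))

        desc = weighted_descriptives(included, "inflation_weight")
        desc.to_csv(out / "descriptives.csv", index=False)
        manifest["stages"]["descriptives"] = {
            r["stratum"] + ":" + r["variable"]:
                round(r["weighted_mean"], 2) for _, r in desc.iterrows()}

        tables: list[NormTable] = []
        cv_rows = []
        for sex in ("male", "female"):
            stage = f"fit:{sex}"
            sub = included[included["sex"] == sex]
            strata = (("all", sub),) if not config.season_stratified else tuple(
                (s, sub[sub["season"] == s]) for s in _cohort.SEASONS)
            for season, sdata in strata:
                stage = f"fit:{sex}:{season}"
                age = sdata["age"].to_numpy(float)
                y = sdata["pase_total"].to_numpy(float)
                w = sdata["analytic_weight"].to_numpy(float)

                ranked = rank_families(age, y, w, config.families,
                                       k=config.gaic_k[0])
                best_family = ranked[0].family
                manifest["stages"][f"gaic:{sex}:{season}"] = {
                    m.family: {f"k={k:g}": round(m.gaic(k), 1)
                               for k in config.gaic_k} for m in ranked}

                # CV refits each spec per replicate; the quantile models only
                # need the three coverage levels there, the final fit gets all
                cv_specs = [GamlssSpec(family=best_family)]
                cv_specs += _quantreg_specs(config.quantreg_bases,
                                            taus=(0.05, 0.50, 0.95))
                specs = [GamlssSpec(family=best_family)]
                specs += _quantreg_specs(config.quantreg_bases)
                stage = f"cv:{sex}:{season}"
                reports = cross_validate(cv_specs, sdata, reps=config.cv_reps,
                                         seed=config.seed)
                for r in reports:
                    cv_rows.append({"sex": sex, "season": season, **r.to_row()})
                chosen = select_model(reports)
                manifest["stages"][f"select:{sex}:{season}"] = chosen.model

                stage = f"norms:{sex}:{season}"
                spec_by_name = {s.name: s for s in specs}
                final = spec_by_name[chosen.model].fit(age, y, w)
                model_path = out / f"model_{sex}_{season}.json"
                final.to_json(model_path)
                table = build_norm_table(
                    final, sex, season,
                    provenance={"model": chosen.model, "seed": config.seed,
                                "config_hash": config.config_hash()})
                table.to_csv(out / f"norms_{sex}_{season}.csv")
                render_norm_chart(table, out / f"chart_{sex}_{season}.svg")
                tables.append(table)

        cv_df = pd.DataFrame(cv_rows)
        cv_df.to_csv(out / "cv_report.csv", index=False)
        manifest["stages"]["cv"] = {
            f"{r['sex']}:{r['season']}:{r['model']}":
                [round(r["mean_below_p5"], 4), round(r["mean_below_p50"], 4),
                 round(r["mean_above_p95"], 4)] for r in cv_rows}
        manifest["n_tables"] = len(tables)
        manifest["manifest_hash"] = hashlib.sha256(
            json.dumps(manifest, sort_keys=True).encode()).hexdigest()[:16]
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
        return manifest
    except Exception as e:
        fail = out / "failed"
        fail.mkdir(exist_ok=True)
        (fail / "error.json").write_text(json.dumps(
            {"stage": stage, "error": f"{type(e).__name__}: {e}"}, indent=1))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e
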