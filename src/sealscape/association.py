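"""Structure-association statistics.

Time within a 250 m buffer of sea-floor structures per trip, cohort
summaries of structure visitation, Kruskal-Wallis comparisons of
per-structure-type model contributions, and AICc-based comparison (with
Akaike-weight model averaging) of linear models linking morphometrics to
structure importance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .structures import LAYER_GROUPS, StructureSet
from .tracks import Trajectory

DEFAULT_BUFFER_M = 250.0


@dataclass
class OccupancySummary:
    """Per-individual time within the structure buffer, by structure type."""

    individual_id: str
    trip_duration: float  # s
    seconds_by_type: dict = field(default_factory=dict)
    any_structure_seconds: float = 0.0

    @property
    def proportions_by_type(self) -> dict:
        return {
            k: (v / self.trip_duration if self.trip_duration > 0 else 0.0)
            for k, v in self.seconds_by_type.items()
        }

    @property
    def any_structure_proportion(self) -> float:
        if self.trip_duration <= 0:
            return 0.0
        return self.any_structure_seconds / self.trip_duration

    @property
    def n_types_visited(self) -> int:
        return sum(1 for v in self.seconds_by_type.values() if v > 0)

    @property
    def visited(self) -> bool:
        return self.any_structure_seconds > 0

    def to_row(self) -> dict:
        row = {
            "individual_id": self.individual_id,
            "trip_duration_s": self.trip_duration,
            "any_structure_s": self.any_structure_seconds,
            "any_structure_prop": self.any_structure_proportion,
            "n_types_visited": self.n_types_visited,
        }
        for k, v in self.seconds_by_type.items():
            row[f"{k}_s"] = v
            row[f"{k}_prop"] = v / self.trip_duration if self.trip_duration else 0.0
        return row


def buffer_occupancy(
    traj: Trajectory,
    structures: StructureSet,
    radius: float = DEFAULT_BUFFER_M,
) -> OccupancySummary:
    """Time the regularised track spends within ``radius`` of each structure type.

    Each regular interval contributes its full length when its midpoint lies
    inside the buffered geometry of a type; the union ("any structure") allows
    overlap between types, so per-type seconds may sum to more than the union.
    """
    if traj.regular_interval is None:
        raise ValueError("trajectory must be regularised first")
    import shapely

    dt = traj.regular_interval
    mx = (traj.x[:-1] + traj.x[1:]) / 2
    my = (traj.y[:-1] + traj.y[1:]) / 2
    pts = shapely.points(mx, my)
    summary = OccupancySummary(
        individual_id=traj.individual_id, trip_duration=traj.duration
    )
    any_mask = np.zeros(len(mx), dtype=bool)
    for layer, stypes in LAYER_GROUPS.items():
        geoms = structures.geometries(stypes)
        if not geoms:
            summary.seconds_by_type[layer] = 0.0
            continue
        buffered = shapely.unary_union([g.buffer(radius) for g in geoms])
        shapely.prepare(buffered)
        inside = shapely.contains(buffered, pts)
        summary.seconds_by_type[layer] = float(inside.sum() * dt)
        any_mask |= inside
    summary.any_structure_seconds = float(any_mask.sum() * dt)
    return summary


def summarize_structure_use(summaries) -> dict:
    """Cohort tabulation of structure visitation.

    "Visiting" means any time at all inside the union buffer. Per-type visit
    percentages are relative to the visitors, matching how cohort visitation
    is usually reported.
    """
    summaries = list(summaries)
    n = len(summaries)
    visitors = [s for s in summaries if s.visited]
    out = {
        "n_individuals": n,
        "n_visiting": len(visitors),
        "pct_visiting": 100.0 * len(visitors) / n if n else 0.0,
        "n_multi_type": sum(1 for s in visitors if s.n_types_visited > 1),
        "mean_any_structure_prop": float(
            np.mean([s.any_structure_proportion for s in summaries])
        )
        if n
        else 0.0,
    }
    for layer in LAYER_GROUPS:
        n_vis = sum(1 for s in visitors if s.seconds_by_type.get(layer, 0) > 0)
        out[f"pct_visiting_{layer}"] = (
            100.0 * n_vis / len(visitors) if visitors else 0.0
        )
    return out


def kruskal_wallis(*groups):
    """Tie-corrected Kruskal-Wallis rank test.

    Returns ``(H, df, p)`` with ``df = k - 1`` and p from the chi-square
    approximation. Identical values throughout give ``H = 0, p = 1``.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group needs at least one value")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    df = len(groups) - 1
    if np.ptp(pooled) == 0:
        return 0.0, df, 1.0
    H, p = stats.kruskal(*groups)
    return float(H), df, float(p)


def arcsin_transform(p, sqrt: bool = True):
    """Angular transform of a proportion: ``arcsin(sqrt(p))`` (or plain arcsin)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(p)) if sqrt else np.arcsin(p)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# AICc model comparison


@dataclass
class ModelComparison:
    """AICc-ranked candidate OLS models with Akaike weights."""

    table: pd.DataFrame  # model, df, aicc, delta_aicc, weight, r2
    averaged_params: pd.Series
    n: int

    def summary(self) -> str:
        lines = [
            f"AICc model comparison (n = {self.n})",
            "=" * 56,
            f"{'model':<30}{'df':>4}{'dAICc':>8}{'weight':>8}{'R2':>6}",
            "-" * 56,
        ]
        for _, r in self.table.iterrows():
            lines.append(
                f"{r['model']:<30}{int(r['df']):>4}{r['delta_aicc']:>8.2f}"
                f"{r['weight']:>8.3f}{r['r2']:>6.2f}"
            )
        lines += ["", "model-averaged coefficients (full average):"]
        for name, val in self.averaged_params.items():
            lines.append(f"  {name:<12}{val:>12.5f}")
        return "\n".join(lines)


def _aicc(res, n: int, k: int) -> float:
    return res.aic + 2 * k * (k + 1) / (n - k - 1)


def aicc_model_set(
    data: pd.DataFrame,
    response: str,
    candidates=None,
    predictors=None,
) -> ModelComparison:
    """Fit candidate OLS models and rank them by AICc.

    ``candidates`` is an iterable of predictor-name tuples (the intercept-only
    model is the empty tuple). If omitted, all subsets of ``predictors`` are
    fitted (an all-subsets "dredge"). ``k`` counts the residual variance, so
    the intercept-only model has df = 2. Model-averaged coefficients use the
    full average: a predictor absent from a model contributes zero with that
    model's weight.
    """
    if candidates is None:
        if predictors is None:
            raise ValueError("give either candidates or predictors")
        candidates = [
            combo
            for r in range(len(predictors) + 1)
            for combo in itertools.combinations(predictors, r)
        ]
    candidates = [tuple(c) for c in candidates]
    y = data[response].to_numpy(dtype=float)
    n = len(y)
    max_k = max(len(c) for c in candidates) + 2
    if n <= max_k + 1:
        raise ValueError("too few observations for the largest candidate model")
    rows, fits = [], []
    for combo in candidates:
        X = sm.add_constant(
            data[list(combo)].to_numpy(dtype=float)
            if combo
            else np.empty((n, 0)),
            has_constant="add",
        )
        if np.linalg.matrix_rank(X) < X.shape[1]:
            rows.append(None)
            fits.append(None)
            continue
        res = sm.OLS(y, X).fit()
        k = X.shape[1] + 1  # + residual variance
        rows.append(
            {
                "model": " + ".join(combo) if combo else "(intercept)",
                "df": k,
                "aicc": _aicc(res, n, k),
                "r2": res.rsquared,
            }
        )
        fits.append((combo, res))
    kept = [r for r in rows if r is not None]
    if not kept:
        raise ValueError("no candidate model could be fitted")
    tab = pd.DataFrame(kept)
    best = tab["aicc"].min()
    tab["delta_aicc"] = tab["aicc"] - best
    w = np.exp(-0.5 * tab["delta_aicc"].to_numpy())
    tab["weight"] = w / w.sum()
    tab = tab.sort_values("delta_aicc", kind="stable").reset_index(drop=True)

    # full model averaging
    all_preds = sorted({p for c in candidates for p in c})
    avg = dict.fromkeys(["const", *all_preds], 0.0)
    weight_of = dict(zip(tab["model"], tab["weight"]))
    for fit in fits:
        if fit is None:
            continue
        combo, res = fit
        name = " + ".join(combo) if combo else "(intercept)"
        wgt = weight_of[name]
        avg["const"] += wgt * res.params[0]
        for i, pname in enumerate(combo, start=1):
            avg[pname] += wgt * res.params[i]
    return ModelComparison(
        table=tab[["model", "df", "aicc", "delta_aicc", "weight", "r2"]],
        averaged_params=pd.Series(avg),
        n=n,
    )
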