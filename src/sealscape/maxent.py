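"""Presence-background maximum-entropy habitat model.

Estimates the Gibbs distribution over background cells

    P(x) = exp(w . f(x)) / Z

that maximises the L1-regularised log gain over the presence sample,

    G(w) = mean_presence[w . f(x)] - log mean_background[exp(w . f(x))]
           - sum_f lambda_f |w_f|,

with linear and quadratic features of each covariate scaled to [0, 1] by the
background range. The per-feature penalty is
``lambda_f = r * beta * s_f / sqrt(m)`` with class constant ``beta = 0.05``,
``s_f`` the feature's presence-sample standard deviation and ``m`` the number
of presences; ``r`` is the regularisation multiplier (default 1).

Optimisation is greedy coordinate-wise Newton ascent with backtracking and a
soft-threshold at zero, so each iteration moves exactly one feature. The gain
increment of every accepted step is credited to the feature's variable; the
summed positive credits, normalised to percentages, are the model's variable
contributions. Model discrimination is summarised by the rank-based AUC of
presence versus background scores.

Usage follows the fit/results convention::

    model = MaxentHabitatModel(presences, background)
    res = model.fit()
    res.contributions()       # percent per variable
    res.auc(test_presences)   # held-out discrimination
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import rankdata

MIN_PRESENCES = 5


class InsufficientPresencesError(ValueError):
    """Too few presence cells to build a model (fewer than 5)."""


def partition_data(presences: pd.DataFrame, train_frac: float = 0.7, seed: int = 0):
    """Random disjoint train/test split of presence rows.

    The training set takes ``ceil(train_frac * n)`` rows. Fewer than 5
    presences raises :class:`InsufficientPresencesError` — with so few
    occurrence cells no model is attempted for that individual.
    """
    n = len(presences)
    if n < MIN_PRESENCES:
        raise InsufficientPresencesError(
            f"{n} presence cells; at least {MIN_PRESENCES} required"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.ceil(train_frac * n))
    return (
        presences.iloc[order[:n_train]].reset_index(drop=True),
        presences.iloc[order[n_train:]].reset_index(drop=True),
    )


def sample_background(stack, n: int = 10_000, seed: int = 0, replace: bool = False) -> pd.DataFrame:
    """Uniform random background cells with their covariates."""
    table = stack.table()
    if n > len(table) and not replace:
        raise ValueError(
            f"requested {n} background cells from a {len(table)}-cell grid "
            "without replacement"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(table), size=n, replace=replace)
    return table.iloc[idx].reset_index(drop=True)


def auc_score(pos_scores, neg_scores) -> float:
    """Rank-based AUC (midrank tie convention)."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


@dataclass
class _FeatureSpace:
    variables: list
    names: list          # feature names, e.g. "depth", "depth^2"
    var_of: np.ndarray   # variable index per feature
    lo: np.ndarray       # background min per variable
    rng: np.ndarray      # background range per variable

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        X = df[self.variables].to_numpy(dtype=float)
        S = (X - self.lo) / self.rng
        return np.column_stack([S, S**2])


class MaxentHabitatModel:
    """Presence-background maximum-entropy model of habitat use.

    Parameters
    ----------
    presences : DataFrame
        Training presence cells (one row per cell) with covariate columns.
    background : DataFrame
        Background cells sampled from the study area.
    variables : sequence of str, optional
        Covariate columns to use; defaults to all shared numeric columns.
    features : {"lq", "l"}
        Feature classes: linear + quadratic (default) or linear only.
    reg_multiplier : float
        MaxEnt regularisation multiplier ``r``.
    """

    def __init__(
        self,
        presences: pd.DataFrame,
        background: pd.DataFrame,
        variables=None,
        features: str = "lq",
        reg_multiplier: float = 1.0,
    ):
        if len(presences) == 0:
            raise ValueError("no presence rows")
        if variables is None:
            variables = [
                c
                for c in background.columns
                if c in presences.columns
                and np.issubdtype(background[c].dtype, np.number)
            ]
        self.variables = list(variables)
        if not self.variables:
            raise ValueError("no covariate columns")
        if features not in {"lq", "l"}:
            raise ValueError("features must be 'lq' or 'l'")
        self.features = features
        self.reg_multiplier = float(reg_multiplier)

        bg = background[self.variables].to_numpy(dtype=float)
        lo = bg.min(axis=0)
        rng_ = np.where(np.ptp(bg, axis=0) > 0, np.ptp(bg, axis=0), 1.0)
        names = list(self.variables)
        var_of = list(range(len(self.variables)))
        if features == "lq":
            names += [f"{v}^2" for v in self.variables]
            var_of += list(range(len(self.variables)))
        self.space = _FeatureSpace(
            variables=self.variables,
            names=names,
            var_of=np.array(var_of),
            lo=lo,
            rng=rng_,
        )
        if features == "l":
            self.space.transform = lambda df, s=self.space: (  # type: ignore[assignment]
                (df[s.variables].to_numpy(dtype=float) - s.lo) / s.rng
            )
        self.F_pres = self.space.transform(presences)
        self.F_bg = self.space.transform(background)
        self.presences = presences
        self.background = background

    # -- fitting -------------------------------------------------------------

    def fit(self, tol: float = 1e-5, max_iter: int = 1000) -> "MaxentResults":
        Fp, Fb = self.F_pres, self.F_bg
        m, K = Fp.shape
        mean_pres = Fp.mean(axis=0)
        s_f = Fp.std(axis=0)
        s_bg = Fb.std(axis=0)
        s_f = np.where(s_f > 0, s_f, s_bg)
        lam = self.reg_multiplier * 0.05 * s_f / np.sqrt(m)
        active = s_bg > 0  # constant-over-background features carry no information

        w = np.zeros(K)
        eta = np.zeros(len(Fb))

        def gain(w_, eta_):
            return float(
                mean_pres @ w_
                - (logsumexp(eta_) - np.log(len(Fb)))
                - lam @ np.abs(w_)
            )

        g_now = gain(w, eta)
        gain_path = [g_now]
        credit = np.zeros(len(self.variables))
        converged = False
        n_iter = 0

        for n_iter in range(1, max_iter + 1):
            z = eta - eta.max()
            q = np.exp(z)
            q /= q.sum()
            e_model = q @ Fb
            grad = mean_pres - e_model
            # penalised (sub)gradient per feature
            pg = np.where(
                w != 0,
                grad - lam * np.sign(w),
                np.sign(grad) * np.maximum(np.abs(grad) - lam, 0.0),
            )
            pg[~active] = 0.0
            j = int(np.argmax(np.abs(pg)))
            if np.abs(pg[j]) == 0:
                converged = True
                break
            var_j = q @ (Fb[:, j] ** 2) - (q @ Fb[:, j]) ** 2
            step = pg[j] / max(var_j, 1e-12)
            # soft-threshold: do not let the weight jump across zero
            if w[j] != 0 and np.sign(w[j] + step) != np.sign(w[j]):
                step = -w[j]
            improved = False
            for _ in range(40):
                w_new = w[j] + step
                eta_new = eta + step * Fb[:, j]
                g_new = gain(
                    np.concatenate([w[:j], [w_new], w[j + 1 :]]), eta_new
                )
                if g_new >= g_now:
                    improved = True
                    break
                step /= 2.0
            if not improved:
                converged = True
                break
            delta = g_new - g_now
            w[j] = w[j] + step
            eta = eta_new
            credit[self.space.var_of[j]] += max(delta, 0.0)
            g_now = g_new
            gain_path.append(g_now)
            if delta < tol:
                converged = True
                break

        return MaxentResults(
            model=self,
            weights=pd.Series(w, index=self.space.names),
            log_z=float(logsumexp(eta)),
            gain=g_now + float(lam @ np.abs(w)),  # unpenalised training gain
            gain_path=np.array(gain_path),
            gain_credit=pd.Series(credit, index=self.variables),
            n_iter=n_iter,
            converged=converged,
            penalties=pd.Series(lam, index=self.space.names),
        )


@dataclass
class MaxentResults:
    """Fitted maximum-entropy habitat model."""

    model: MaxentHabitatModel
    weights: pd.Series
    log_z: float
    gain: float
    gain_path: np.ndarray
    gain_credit: pd.Series
    n_iter: int
    converged: bool
    penalties: pd.Series = field(default_factory=pd.Series)

    @property
    def params(self) -> pd.Series:
        return self.weights

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        """Raw (relative occurrence rate) scores; they sum to 1 over background."""
        F = self.model.space.transform(df)
        return np.exp(F @ self.weights.to_numpy() - self.log_z)

    def background_scores(self) -> np.ndarray:
        return self.predict(self.model.background)

    def auc(self, test_presences: pd.DataFrame) -> float:
        """Rank AUC of held-out presences versus the background sample."""
        if len(test_presences) == 0:
            raise ValueError("empty test set")
        return auc_score(self.predict(test_presences), self.background_scores())

    def contributions(self) -> pd.Series:
        """Percent contribution per variable (training-gain attribution)."""
        credit = self.gain_credit.clip(lower=0.0)
        total = credit.sum()
        if total <= 0:
            warnings.warn("zero total gain; contributions set uniform")
            return pd.Series(
                100.0 / len(credit), index=credit.index, name="contribution_pct"
            )
        return (100.0 * credit / total).rename("contribution_pct")

    def permutation_importance(self, seed: int = 0, n_repeats: int = 1) -> pd.Series:
        """AUC drop when one variable is shuffled across presence+background rows."""
        rng = np.random.default_rng(seed)
        pres = self.model.presences
        base = auc_score(self.predict(pres), self.background_scores())
        drops = {}
        for v in self.model.variables:
            d = 0.0
            for _ in range(n_repeats):
                p2 = pres.copy()
                b2 = self.model.background.copy()
                pooled = np.concatenate([p2[v].to_numpy(), b2[v].to_numpy()])
                rng.shuffle(pooled)
                p2[v] = pooled[: len(p2)]
                b2[v] = pooled[len(p2):]
                d += base - auc_score(self.predict(p2), self.predict(b2))
            drops[v] = max(d / n_repeats, 0.0)
        s = pd.Series(drops)
        total = s.sum()
        if total <= 0:
            return pd.Series(100.0 / len(s), index=s.index, name="permutation_pct")
        return (100.0 * s / total).rename("permutation_pct")

    def summary(self) -> str:
        contrib = self.contributions()
        lines = [
            "Maximum-entropy habitat model",
            "=" * 44,
            f"presences: {len(self.model.presences)}   "
            f"background: {len(self.model.background)}",
            f"features: {self.model.features}   r = {self.model.reg_multiplier}",
            f"iterations: {self.n_iter}   converged: {self.converged}",
            f"training gain: {self.gain:.4f}",
            "",
            f"{'variable':<16}{'weight(l)':>12}{'contribution %':>16}",
            "-" * 44,
        ]
        for v in self.model.variables:
            lines.append(f"{v:<16}{self.weights[v]:>12.4f}{contrib[v]:>16.1f}")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "variables": self.model.variables,
                "features": self.model.features,
                "reg_multiplier": self.model.reg_multiplier,
                "weights": self.weights.to_dict(),
                "scaling": {
                    "lo": self.model.space.lo.tolist(),
                    "range": self.model.space.rng.tolist(),
                },
                "log_z": self.log_z,
                "gain": self.gain,
                "n_iter": self.n_iter,
                "converged": self.converged,
                "contributions": self.contributions().to_dict(),
            },
            indent=2,
        )
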