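"""Linear mutation-rate models with stepwise-AIC selection and VIF control.

The response is the untransformed per-bp mutation rate of each genic
feature instance (SNV or indel rate) and the predictors are region-level
epigenomic and sequence features. Model search is bidirectional stepwise
minimization of AIC starting from the full model; collinearity is handled
separately by iterative variance-inflation-factor (VIF) pruning. The
fitted object predicts a mutation probability score: predicted SNV +
indel rate per bp, per region and length-weighted per gene.

Follows the statsmodels idiom: ``MutationRateModel`` is built from a
feature table and ``fit()`` returns a ``MutationRateResults`` carrying
estimates, t-values, AIC, adjusted R^2, VIFs and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: table columns that are never predictors
_BOOKKEEPING = {
    "gene_id", "kind", "rank", "chrom", "start", "end", "length",
    "snv_count", "indel_count", "snv_rate", "indel_rate", "true_rate",
}

_AIC_TOL = 1e-9


def _profile_aic(X: np.ndarray, y: np.ndarray) -> float:
    """Gaussian profile AIC, n*log(RSS/n) + 2*edf (R's extractAIC form)."""
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    n = y.size
    # floor at numerical precision of an exact fit so that zero-noise
    # responses tie (the smaller model then wins the tie-break) instead of
    # ranking models by round-off
    floor = n * max(float(np.var(y)), 1.0) * 1e-20
    rss = max(rss, floor, np.finfo(float).tiny)
    return n * np.log(rss / n) + 2 * (X.shape[1])


class MutationRateModel:
    """OLS (identity link) model of per-bp mutation rate on region features.

    Parameters
    ----------
    table : DataFrame
        Region feature table (one row per genic-feature instance).
    response : str
        Response column, e.g. ``"snv_rate"`` or ``"indel_rate"``.
    predictors : list of str, optional
        Candidate predictor columns; defaults to every numeric non-
        bookkeeping column. Candidate order fixes stepwise determinism.
    family : {"gaussian", "poisson"}
        ``"gaussian"`` is the untransformed-rate OLS used throughout;
        ``"poisson"`` (log link on counts with length offset) is provided
        for sensitivity checks only.
    weight_by_length : bool
        Weight rows by region length (off by default).
    """

    def __init__(
        self,
        table: pd.DataFrame,
        response: str = "snv_rate",
        predictors: list[str] | None = None,
        family: str = "gaussian",
        weight_by_length: bool = False,
    ):
        if predictors is None:
            predictors = [
                c
                for c in table.columns
                if c not in _BOOKKEEPING
                and c != response
                and pd.api.types.is_numeric_dtype(table[c])
            ]
        if len(predictors) < 1:
            raise ValueError("need at least one candidate predictor")
        cols = predictors + [response] + (["length"] if weight_by_length else [])
        data = table[list(dict.fromkeys(cols))].apply(pd.to_numeric, errors="coerce")
        complete = data.dropna()
        self.n_dropped = len(data) - len(complete)
        if self.n_dropped:
            warnings.warn(f"{self.n_dropped} rows with missing values excluded from fit")
        constant = [p for p in predictors if complete[p].nunique() <= 1]
        if constant:
            warnings.warn(f"constant predictor columns dropped: {constant}")
            predictors = [p for p in predictors if p not in constant]
        if not predictors:
            raise ValueError("no non-constant candidate predictors")
        self.table = table
        self.data = complete
        self.response = response
        self.candidates = list(predictors)
        self.family = family
        self.weight_by_length = weight_by_length
        self._y = complete[response].to_numpy(float)
        self._X = complete[predictors].to_numpy(float)

    @classmethod
    def from_feature_table(cls, table: pd.DataFrame, response: str = "snv_rate", **kw):
        return cls(table, response=response, **kw)

    # -- design helpers ----------------------------------------------------
    def _design(self, names: list[str]) -> np.ndarray:
        idx = [self.candidates.index(n) for n in names]
        X = self._X[:, idx]
        return np.column_stack([np.ones(len(X)), X])

    def _check_rank(self, names: list[str]) -> None:
        X = self._design(names)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # name the offending columns by greedy elimination
            bad = []
            keep: list[str] = []
            for n in names:
                trial = keep + [n]
                if np.linalg.matrix_rank(self._design(trial)) < len(trial) + 1:
                    bad.append(n)
                else:
                    keep.append(n)
            raise np.linalg.LinAlgError(
                f"rank-deficient design; collinear columns: {bad}"
            )

    # -- fitting -----------------------------------------------------------
    def fit(self, method: str = "stepwise") -> "MutationRateResults":
        """Fit the model. ``method="stepwise"`` performs bidirectional
        AIC minimization from the full model (ties broken toward the
        smaller model); ``method="ols"`` fits all candidates."""
        if method not in ("stepwise", "ols"):
            raise ValueError(f"unknown method {method!r}")
        self._check_rank(self.candidates)
        full_aic = _profile_aic(self._design(self.candidates), self._y)
        selected = (
            self._stepwise() if method == "stepwise" else list(self.candidates)
        )
        return self._results_for(selected, full_aic)

    def _stepwise(self) -> list[str]:
        current = list(self.candidates)
        cur_aic = _profile_aic(self._design(current), self._y)
        while True:
            moves: list[tuple[float, int, int, str, str]] = []
            order = 0
            for p in list(current):
                trial = [c for c in current if c != p]
                a = _profile_aic(self._design(trial), self._y)
                moves.append((a, len(trial), order, "drop", p))
                order += 1
            for p in self.candidates:
                if p not in current:
                    trial = current + [p]
                    a = _profile_aic(self._design(trial), self._y)
                    moves.append((a, len(trial), order, "add", p))
                    order += 1
            if not moves:
                break
            best_a = min(a for a, *_ in moves)
            # among moves within tolerance of the best, prefer the smallest
            # model, then candidate order (deterministic)
            near = sorted(
                (m for m in moves if m[0] <= best_a + _AIC_TOL),
                key=lambda m: (m[1], m[2]),
            )
            a, k, _, kind, p = near[0]
            better = a < cur_aic - _AIC_TOL
            same_but_smaller = a <= cur_aic + _AIC_TOL and k < len(current)
            if not (better or same_but_smaller):
                break
            if kind == "drop":
                current.remove(p)
            else:
                current.append(p)
                current = [c for c in self.candidates if c in current]
            cur_aic = _profile_aic(self._design(current), self._y)
        return [c for c in self.candidates if c in current]

    def _results_for(self, selected: list[str], full_aic: float) -> "MutationRateResults":
        X = self._design(selected)
        if self.family == "poisson":
            counts = np.round(self._y * self.data["length"].to_numpy(float)) \
                if self.weight_by_length else np.round(self._y)
            res = sm.GLM(counts, X, family=sm.families.Poisson()).fit()
        elif self.weight_by_length:
            res = sm.WLS(self._y, X, weights=self.data["length"].to_numpy(float)).fit()
        else:
            res = sm.OLS(self._y, X).fit()
        return MutationRateResults(self, selected, res, full_aic)


@dataclass
class MutationRateResults:
    """Fitted mutation-rate model: estimates, diagnostics, prediction."""

    model: MutationRateModel
    selected: list[str]
    _sm_results: object
    full_model_aic: float

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._sm_results.params, index=["intercept"] + self.selected)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self._sm_results.bse, index=["intercept"] + self.selected)

    @property
    def tvalues(self) -> pd.Series:
        return pd.Series(self._sm_results.tvalues, index=["intercept"] + self.selected)

    @property
    def aic(self) -> float:
        return float(self._sm_results.aic)

    @property
    def profile_aic(self) -> float:
        return _profile_aic(self.model._design(self.selected), self.model._y)

    @property
    def rsquared(self) -> float:
        return float(getattr(self._sm_results, "rsquared", np.nan))

    @property
    def rsquared_adj(self) -> float:
        return float(getattr(self._sm_results, "rsquared_adj", np.nan))

    @property
    def vif(self) -> pd.Series:
        """Variance inflation factor of each selected predictor."""
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        X = self.model._design(self.selected)
        if len(self.selected) < 2:
            return pd.Series([1.0] * len(self.selected), index=self.selected)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vals = [variance_inflation_factor(X, i + 1) for i in range(len(self.selected))]
        return pd.Series(vals, index=self.selected)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Predicted per-bp rate for each row of ``table``."""
        missing = [c for c in self.selected if c not in table.columns]
        if missing:
            raise ValueError(f"table lacks selected predictor columns {missing}")
        X = np.column_stack(
            [np.ones(len(table))] + [table[c].to_numpy(float) for c in self.selected]
        )
        p = self.params.to_numpy()
        if self.model.family == "poisson":
            return np.exp(X @ p)
        return X @ p

    def reduce_by_vif(self, threshold: float = 3.0, direction: str = "high") -> "MutationRateResults":
        """Collinearity pruning.

        ``direction="high"`` (default): iteratively remove the predictor
        with the largest VIF while any VIF exceeds the threshold, refitting
        each time. ``direction="literal"``: remove every predictor with VIF
        below the threshold in one pass (the low-VIF reading; kept for
        comparability, it discards the *independent* predictors).
        """
        selected = list(self.selected)
        if direction == "literal":
            res = self.model._results_for(selected, self.full_model_aic)
            keep = [p for p in selected if res.vif[p] >= threshold]
            return self.model._results_for(keep, self.full_model_aic)
        if direction != "high":
            raise ValueError("direction must be 'high' or 'literal'")
        while len(selected) >= 2:
            res = self.model._results_for(selected, self.full_model_aic)
            v = res.vif
            worst = v.replace(np.inf, np.finfo(float).max).idxmax()
            if v[worst] > threshold or not np.isfinite(v[worst]):
                selected.remove(worst)
            else:
                break
        return self.model._results_for(selected, self.full_model_aic)

    def summary(self) -> str:
        rows = pd.DataFrame(
            {
                "coef": self.params,
                "std err": self.bse,
                "t": self.tvalues,
                "VIF": pd.concat([pd.Series({"intercept": np.nan}), self.vif]),
            }
        )
        head = (
            f"Mutation rate model ({self.model.response}, family={self.model.family})\n"
            f"n = {len(self.model.data)}  selected = {len(self.selected)}/"
            f"{len(self.model.candidates)} predictors\n"
            f"AIC = {self.aic:.4f}  adj. R^2 = {self.rsquared_adj:.6f}\n"
        )
        return head + rows.to_string(float_format=lambda x: f"{x: .6g}")


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def fit_mutation_glm(
    table: pd.DataFrame,
    response: str = "snv_rate",
    predictors: list[str] | None = None,
    **kw,
) -> MutationRateResults:
    """Fit the stepwise-AIC mutation-rate model for one response kind."""
    return MutationRateModel(table, response=response, predictors=predictors, **kw).fit()


def reduce_by_vif(
    results: MutationRateResults, threshold: float = 3.0, direction: str = "high"
) -> MutationRateResults:
    return results.reduce_by_vif(threshold, direction)


def predict_scores(
    snv_results: MutationRateResults,
    indel_results: MutationRateResults | None,
    table: pd.DataFrame,
) -> pd.DataFrame:
    """Mutation probability scores per region and per gene.

    score = predicted SNV rate + predicted indel rate (per bp). Negative
    predictions are retained but flagged. Gene-level score is the
    length-weighted mean over the gene's regions.
    """
    out = table[[c for c in ("gene_id", "kind", "rank", "length") if c in table.columns]].copy()
    out["pred_snv_rate"] = snv_results.predict(table)
    out["pred_indel_rate"] = (
        indel_results.predict(table) if indel_results is not None else 0.0
    )
    out["score"] = out["pred_snv_rate"] + out["pred_indel_rate"]
    out["negative_flag"] = out["score"] < 0
    return out


def gene_scores(region_scores: pd.DataFrame) -> pd.Series:
    """Length-weighted mean score per gene."""
    def agg(grp):
        return np.average(grp["score"], weights=grp["length"])

    return region_scores.groupby("gene_id").apply(agg, include_groups=False)


def rank_deciles(scores: pd.Series) -> pd.Series:
    """Equal-size decile labels 1..10 by score, ties broken by stable
    (gene-id) order; decile 1 = lowest scores."""
    if len(scores) < 10:
        raise ValueError("need at least 10 genes to form deciles")
    s = scores.sort_index()
    order = np.argsort(s.to_numpy(), kind="stable")
    n = len(s)
    labels = np.empty(n, dtype=int)
    labels[order] = np.floor(np.arange(n) * 10 / n).astype(int) + 1
    return pd.Series(labels, index=s.index, name="decile")
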