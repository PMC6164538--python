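"""Model-assessment battery: jackknife prediction, frequency comparison,
spatial autocorrelation diagnostics, and the model-comparison table.

The jackknife refits the model on every leave-one-out subset (optionally a
seeded random subsample of leave-outs for desk-scale runs) and predicts the
held-out block with the marginal (RE-integrated) mean — a held-out block has
no estimated random intercept.  MPE/MAE summarize the signed and absolute
leave-one-out errors; a Pearson chi-square compares the observed count
frequencies with the (rounded) predictions; Moran's I measures residual
spatial autocorrelation under the normality approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .likelihoods import (
    FAMILIES,
    FitResult,
    ModelSpec,
    fit,
    predict_expected_counts,
    predicted_count_probabilities,
)
from .synthetic_data import SpatialWeights

__all__ = [
    "MoranResult",
    "FrequencyChi2",
    "ValidationReport",
    "jackknife",
    "mpe",
    "mae",
    "frequency_chi2",
    "frequency_chi2_from_probabilities",
    "morans_i",
    "spearman_obs_pred",
    "compare_models",
]


# ---------------------------------------------------------------------------
# elementary error summaries
# ---------------------------------------------------------------------------


def _paired(y, yhat):
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted vectors must have equal length")
    if y.size == 0:
        raise ValueError("empty input")
    return y, yhat


def mpe(y, yhat):
    """Mean prediction error, mean of (y_i - yhat_i)."""
    y, yhat = _paired(y, yhat)
    return float(np.mean(y - yhat))


def mae(y, yhat):
    """Mean absolute prediction error."""
    y, yhat = _paired(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def spearman_obs_pred(y, yhat):
    """Spearman rank correlation (average ranks for ties)."""
    y, yhat = _paired(y, yhat)
    if y.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        warnings.warn("constant input; Spearman correlation undefined")
        return np.nan
    return float(stats.spearmanr(y, yhat).statistic)


# ---------------------------------------------------------------------------
# frequency-distribution chi-square
# ---------------------------------------------------------------------------


@dataclass
class FrequencyChi2:
    chi2: float
    df: int
    table: pd.DataFrame
    max_category: int
    min_expected: float
    merged: bool


def _tabulate(values, max_category):
    """Counts per category 0, 1, ..., max_category-1, and max_category+."""
    v = np.minimum(np.asarray(values, dtype=int), max_category)
    return np.bincount(v, minlength=max_category + 1)


def frequency_chi2(y, yhat, max_category=5, min_expected=1.0):
    """Pearson chi-square between observed and predicted count frequencies.

    Predictions are rounded to the nearest integer; both vectors are
    tabulated into categories 0..max_category-1 plus an open top category.
    Categories whose predicted frequency falls below ``min_expected`` are
    merged into the neighbouring upper category (the top one merges
    downward).  ``chi2 = sum (O_k - P_k)^2 / P_k`` over categories with
    positive predicted frequency; a category with observations but zero
    predicted frequency makes the statistic infinite (with a warning).
    """
    y, yhat = _paired(y, yhat)
    if max_category < 1:
        raise ValueError("max_category must be >= 1")
    obs = _tabulate(np.round(y).astype(int), max_category)
    pred = _tabulate(np.clip(np.round(yhat), 0, None).astype(int), max_category)

    labels = [str(i) for i in range(max_category)] + [f"{max_category}+"]
    cats = [[lab, float(o), float(p)] for lab, o, p in zip(labels, obs, pred)]
    merged = False
    i = 0
    while i < len(cats):
        if cats[i][2] < min_expected and len(cats) > 1:
            j = i + 1 if i + 1 < len(cats) else i - 1
            cats[j][0] = f"{cats[min(i, j)][0]}&{cats[max(i, j)][0]}"
            cats[j][1] += cats[i][1]
            cats[j][2] += cats[i][2]
            del cats[i]
            merged = True
            if j < i:
                break  # merged the tail downward; done
        else:
            i += 1

    table = pd.DataFrame(cats, columns=["category", "observed", "predicted"])
    if np.any((table["predicted"] == 0) & (table["observed"] > 0)):
        warnings.warn("observed counts in a category with zero predicted frequency")
        chi2 = np.inf
    else:
        keep = table["predicted"] > 0
        chi2 = float(
            np.sum(
                (table.loc[keep, "observed"] - table.loc[keep, "predicted"]) ** 2
                / table.loc[keep, "predicted"]
            )
        )
    return FrequencyChi2(
        chi2=chi2,
        df=len(table) - 1,
        table=table,
        max_category=max_category,
        min_expected=min_expected,
        merged=merged,
    )


def frequency_chi2_from_probabilities(y, fit_result, data, max_category=5, min_expected=1.0):
    """Variant whose predicted frequencies sum model-implied category
    probabilities instead of rounding point predictions."""
    y = np.asarray(y, dtype=float)
    probs = predicted_count_probabilities(fit_result, data, max_category)
    # fold the tail mass into the open category
    pred = probs.sum(axis=0)
    pred[-1] += len(y) - probs.sum()
    obs = _tabulate(np.round(y).astype(int), max_category)
    labels = [str(i) for i in range(max_category)] + [f"{max_category}+"]
    table = pd.DataFrame(
        {"category": labels, "observed": obs.astype(float), "predicted": pred}
    )
    keep = table["predicted"] >= max(min_expected, 1e-12)
    chi2 = float(
        np.sum(
            (table.loc[keep, "observed"] - table.loc[keep, "predicted"]) ** 2
            / table.loc[keep, "predicted"]
        )
    )
    return FrequencyChi2(
        chi2=chi2,
        df=int(keep.sum()) - 1,
        table=table,
        max_category=max_category,
        min_expected=min_expected,
        merged=bool((~keep).any()),
    )


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------


@dataclass
class MoranResult:
    I: float
    expected_i: float
    variance: float
    z: float
    p_value: float
    n: int
    row_standardized: bool


def morans_i(values, weights: SpatialWeights) -> MoranResult:
    """Moran's I with Z and two-sided p under the normality approximation.

    ``values`` must be aligned with ``weights.ids``.  Expectation under no
    autocorrelation is -1/(n-1).
    """
    v = np.asarray(values, dtype=float)
    n = weights.n
    if len(v) != n:
        raise ValueError("values must align with weights.ids")
    if n < 3:
        raise ValueError("need at least 3 blocks")
    z = v - v.mean()
    denom = np.sum(z * z)
    if denom == 0:
        raise ValueError("Moran's I undefined for a constant vector")
    W = weights.to_dense()
    s0 = W.sum()
    num = z @ W @ z
    i_stat = float(n / s0 * num / denom)

    s1 = 0.5 * np.sum((W + W.T) ** 2)
    s2 = np.sum((W.sum(axis=1) + W.sum(axis=0)) ** 2)
    e_i = -1.0 / (n - 1)
    var_i = (n * n * s1 - n * s2 + 3.0 * s0 * s0) / ((n * n - 1.0) * s0 * s0) - e_i**2
    z_score = (i_stat - e_i) / np.sqrt(var_i)
    p = 2.0 * stats.norm.sf(abs(z_score))
    return MoranResult(
        I=i_stat,
        expected_i=e_i,
        variance=float(var_i),
        z=float(z_score),
        p_value=float(p),
        n=n,
        row_standardized=weights.row_standardized,
    )


# ---------------------------------------------------------------------------
# jackknife
# ---------------------------------------------------------------------------


def jackknife(
    spec: ModelSpec,
    data: pd.DataFrame,
    subsample: Optional[int] = None,
    seed: Optional[int] = None,
    warm_start: bool = True,
    full_fit: FitResult = None,
) -> pd.DataFrame:
    """Leave-one-out predictions ``yhat_(i,-i)`` for each (selected) block.

    Each refit drops one block, warm-starts from the full-data estimates,
    and predicts the held-out block with the marginal mean.  ``subsample``
    validates a seeded random subset of leave-outs.  Refits that fail to
    converge yield a missing prediction (flagged, to be excluded from
    MPE/MAE by the caller).
    """
    n = len(data)
    if n < 3:
        raise ValueError("jackknife needs at least 3 blocks")
    if full_fit is None:
        full_fit = fit(spec, data, compute_se=False)
    if subsample is not None:
        if subsample < 1:
            raise ValueError("subsample must be positive")
        rng = np.random.default_rng(seed)
        chosen = np.sort(rng.choice(n, size=min(subsample, n), replace=False))
    else:
        chosen = np.arange(n)

    data = data.reset_index(drop=True)
    y = data[spec.response_column].to_numpy(dtype=float)
    ids = (
        data["block_id"].to_numpy()
        if "block_id" in data.columns
        else np.arange(n).astype(str)
    )
    yhat = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)
    start = full_fit.params if warm_start else None
    for i in chosen:
        rest = data.drop(index=i)
        try:
            f_i = fit(spec, rest, start=start, compute_se=False)
        except Exception:
            continue
        if not f_i.converged:
            continue
        pred = predict_expected_counts(f_i, data.iloc[[i]], mode="marginal")
        yhat[i] = float(pred[0])
        ok[i] = True

    out = pd.DataFrame(
        {"block_id": ids, "y": y, "yhat": yhat, "converged": ok}
    )
    n_failed = int(len(chosen) - ok[chosen].sum())
    if n_failed:
        warnings.warn(f"{n_failed} leave-one-out refits failed to converge")
    out.attrs["n_failed"] = n_failed
    out.attrs["selected"] = chosen
    return out


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Comparison-table layout: per-model fit and jackknife summaries."""

    table: pd.DataFrame
    fits: dict
    predictions: dict
    jackknife_predictions: dict
    frequency_tables: dict
    best_family: str
    settings: dict

    def to_dict(self):
        table = self.table.replace({np.inf: "inf"})
        return {
            "settings": self.settings,
            "best_family": self.best_family,
            "models": table.to_dict(orient="records"),
            "frequency_tables": {
                f: t.table.to_dict(orient="records")
                for f, t in self.frequency_tables.items()
            },
        }


def compare_models(
    data: pd.DataFrame,
    families: Sequence[str] = FAMILIES,
    random_effects: bool = True,
    weights: SpatialWeights = None,
    jackknife_mode: Optional[str] = None,
    seed: int = 0,
    max_category: int = 5,
    chi2_method: str = "probabilities",
    spec_kwargs: dict = None,
) -> ValidationReport:
    """Fit the requested families and assemble the comparison battery.

    Per model: -2 logL, AIC (and the difference to the best model), number
    of parameters, in-sample Spearman on marginal predictions, an in-sample
    frequency chi-square, residual Moran's I (empirical-Bayes residuals for
    RE models) when weights are given, and jackknife MPE/MAE/chi-square when
    ``jackknife_mode`` is ``"full"`` or ``"subsample:K"``.  Per-model
    failures are recorded, not fatal.

    ``chi2_method`` controls the in-sample frequency comparison:
    ``"probabilities"`` (default) sums model-implied category probabilities,
    which is what actually discriminates the families; ``"rounded"``
    tabulates rounded point predictions.  The jackknife chi-square always
    rounds, since only point predictions exist for held-out blocks.
    """
    if len(families) < 1:
        raise ValueError("need at least one family")
    if chi2_method not in ("probabilities", "rounded"):
        raise ValueError("chi2_method must be 'probabilities' or 'rounded'")
    spec_kwargs = dict(spec_kwargs or {})
    rows = []
    fits, preds, jk_preds, freq_tables = {}, {}, {}, {}
    for fam in families:
        spec = ModelSpec(family=fam, random_effects=random_effects, **spec_kwargs)
        row = {"family": fam, "random_effects": random_effects}
        try:
            res = fit(spec, data)
        except Exception as exc:  # per-model failures propagate as rows
            row["error"] = str(exc)
            rows.append(row)
            continue
        fits[fam] = res
        y = data[spec.response_column].to_numpy(dtype=float)
        pred = predict_expected_counts(res, data, mode="marginal")
        preds[fam] = pred
        if chi2_method == "probabilities":
            fc = frequency_chi2_from_probabilities(
                y, res, data, max_category=max_category
            )
        else:
            fc = frequency_chi2(y, pred, max_category=max_category)
        freq_tables[fam] = fc
        row.update(
            minus2_loglik=-2.0 * res.loglik,
            aic=res.aic,
            n_params=res.n_params,
            converged=res.converged,
            spearman_rho=spearman_obs_pred(y, pred),
            chi2_fit=fc.chi2,
        )
        if weights is not None:
            mode = "conditional" if random_effects else "marginal"
            resid = y - predict_expected_counts(res, data, mode=mode)
            mi = morans_i(resid, weights)
            row.update(moran_i=mi.I, moran_z=mi.z, moran_p=mi.p_value)
        if jackknife_mode:
            sub = None
            if jackknife_mode.startswith("subsample:"):
                sub = int(jackknife_mode.split(":", 1)[1])
            elif jackknife_mode != "full":
                raise ValueError("jackknife_mode must be 'full' or 'subsample:K'")
            jk = jackknife(spec, data, subsample=sub, seed=seed, full_fit=res)
            jk_preds[fam] = jk
            good = jk["converged"].to_numpy()
            row.update(
                mpe=mpe(jk.loc[good, "y"], jk.loc[good, "yhat"]),
                mae=mae(jk.loc[good, "y"], jk.loc[good, "yhat"]),
                chi2_jackknife=frequency_chi2(
                    jk.loc[good, "y"], jk.loc[good, "yhat"], max_category=max_category
                ).chi2,
                jackknife_n=int(good.sum()),
                jackknife_failed=jk.attrs["n_failed"],
            )
        rows.append(row)

    table = pd.DataFrame(rows)
    best = ""
    if "aic" in table.columns and table["aic"].notna().any():
        table["delta_aic"] = table["aic"] - table["aic"].min()
        table["aic_winner"] = table["aic"] == table["aic"].min()
        table["delta_aic_significant"] = table["delta_aic"] > 2.0
        best = str(table.loc[table["aic"].idxmin(), "family"])
    return ValidationReport(
        table=table,
        fits=fits,
        predictions=preds,
        jackknife_predictions=jk_preds,
        frequency_tables=freq_tables,
        best_family=best,
        settings={
            "families": list(families),
            "random_effects": random_effects,
            "jackknife": jackknife_mode,
            "max_category": max_category,
            "chi2_method": chi2_method,
            "seed": seed,
            "jackknife_prediction_mode": "marginal",
        },
    )
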