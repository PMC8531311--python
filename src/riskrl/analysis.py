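"""Behavioral indices and parameter/trait statistics.

Behavioral summaries follow the experiment's trial-type taxonomy.  Pairs
containing a strictly better option by expected coded outcome form five
advantageous trial types (0 vs 10, 0 vs Risk, 0 vs 20, 10 vs 20, Risk vs
20); the two sure-zero options against each other have no better choice, and
the risky option against the sure 10 is the risk-preference probe (equal
expected value), counted separately as the risky-choice proportion.  Each
210-trial block is split into halves at trial 105 by presentation order.

The reflection effect is the loss-domain risky-choice proportion minus the
gain-domain one: positive values mean more risk taking under losses than
under gains.  The learning-rate contrast (a_p - a_n)/(a_p + a_n) summarizes
the asymmetry of learning from better- vs worse-than-expected outcomes.

Regression helpers standardize all variables (z-scores) so coefficients are
comparable across predictors, and the moderated (hierarchical) regression
implements the centering / step-1 / step-2 / simple-slopes procedure used
for trait-by-trait interactions on learning parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .task import GAIN, LOSS, SubjectDataset, option_expected_value

#: Trial-type label per unordered pair.
TRIAL_TYPES = {
    frozenset(("Z1", "T10")): "0v10",
    frozenset(("Z2", "T10")): "0v10",
    frozenset(("Z1", "R")): "0vR",
    frozenset(("Z2", "R")): "0vR",
    frozenset(("Z1", "W20")): "0v20",
    frozenset(("Z2", "W20")): "0v20",
    frozenset(("T10", "W20")): "10v20",
    frozenset(("R", "W20")): "Rv20",
    frozenset(("Z1", "Z2")): "0v0",
    frozenset(("R", "T10")): "Rv10",
}
ADVANTAGEOUS_TYPES = ("0v10", "0vR", "0v20", "10v20", "Rv20")
HALF_SPLIT = 105  # within-block presentation order


@dataclass
class BehaviorSummary:
    """Per-subject behavioral proportions.

    ``advantageous``: long table (subject, domain, half, trial_type,
    n_trials, prop) — ``prop`` is NaN for empty cells (flagged, not zero).
    ``risk``: (subject, domain, half, n_trials, prop) on the Rv10 probe,
    with half='all' rows for the whole block.  ``reflection``: per-subject
    loss-minus-gain risky proportion.
    """

    advantageous: pd.DataFrame
    risk: pd.DataFrame
    reflection: pd.Series

    def risk_proportion(self, domain: str) -> pd.Series:
        sel = self.risk[(self.risk["domain"] == domain) & (self.risk["half"] == "all")]
        return sel.set_index("subject")["prop"]


def _advantageous_option(pair: frozenset, domain: str) -> str | None:
    """The higher-expected-value member of a pair, or None for ties."""
    a, b = sorted(pair)
    ev_a = option_expected_value(a, domain)
    ev_b = option_expected_value(b, domain)
    if ev_a == ev_b:
        return None
    return a if ev_a > ev_b else b


def summarize_behavior(cohort: Iterable[SubjectDataset]) -> BehaviorSummary:
    """Compute advantageous-choice and risky-choice proportions per subject."""
    adv_rows, risk_rows, refl = [], [], {}
    for data in cohort:
        adv_counts: dict[tuple, list[int]] = {}
        risk_counts: dict[tuple, list[int]] = {}
        for rec in data.records:
            pair = frozenset(rec.pair)
            ttype = TRIAL_TYPES[pair]
            half = "first" if rec.trial_index <= HALF_SPLIT else "second"
            if ttype == "Rv10":
                for h in (half, "all"):
                    key = (rec.domain, h)
                    cnt = risk_counts.setdefault(key, [0, 0])
                    cnt[0] += 1
                    cnt[1] += rec.chosen == "R"
            elif ttype in ADVANTAGEOUS_TYPES:
                best = _advantageous_option(pair, rec.domain)
                key = (rec.domain, half, ttype)
                cnt = adv_counts.setdefault(key, [0, 0])
                cnt[0] += 1
                cnt[1] += rec.chosen == best
        for domain in (GAIN, LOSS):
            for half in ("first", "second"):
                for ttype in ADVANTAGEOUS_TYPES:
                    n, k = adv_counts.get((domain, half, ttype), [0, 0])
                    adv_rows.append(
                        {
                            "subject": data.subject_id,
                            "domain": domain,
                            "half": half,
                            "trial_type": ttype,
                            "n_trials": n,
                            "prop": k / n if n else np.nan,
                        }
                    )
            for half in ("first", "second", "all"):
                n, k = risk_counts.get((domain, half), [0, 0])
                risk_rows.append(
                    {
                        "subject": data.subject_id,
                        "domain": domain,
                        "half": half,
                        "n_trials": n,
                        "prop": k / n if n else np.nan,
                    }
                )
        gain_n, gain_k = risk_counts.get((GAIN, "all"), [0, 0])
        loss_n, loss_k = risk_counts.get((LOSS, "all"), [0, 0])
        refl[data.subject_id] = (
            (loss_k / loss_n if loss_n else np.nan)
            - (gain_k / gain_n if gain_n else np.nan)
        )
    return BehaviorSummary(
        pd.DataFrame(adv_rows),
        pd.DataFrame(risk_rows),
        pd.Series(refl, name="reflection"),
    )


def learning_rate_contrast(alpha_p: float, alpha_n: float) -> float:
    """Signed learning-rate asymmetry (a_p - a_n) / (a_p + a_n)."""
    total = alpha_p + alpha_n
    if total < 1e-12:
        raise ValueError("both learning rates ~0: contrast undefined")
    return (alpha_p - alpha_n) / total


def reflection_effect(risk_prop_gain: float, risk_prop_loss: float) -> float:
    """Loss-domain minus gain-domain risky-choice proportion."""
    return risk_prop_loss - risk_prop_gain


@dataclass
class RegressionResult:
    """Standardized OLS summary (optionally two hierarchical steps)."""

    coefficients: pd.Series  # final-step standardized betas
    r2: float
    f_stat: float
    f_p: float
    n: int
    step1_coefficients: pd.Series | None = None
    step1_r2: float | None = None
    delta_r2: float | None = None
    delta_f: float | None = None
    delta_p: float | None = None
    p_values: pd.Series | None = None
    simple_slopes: dict[str, dict[str, float]] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def _zscore(x: pd.Series | np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd < 1e-12:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _fit_ols(X: pd.DataFrame, y: np.ndarray) -> sm.regression.linear_model.RegressionResultsWrapper:
    return sm.OLS(y, sm.add_constant(X)).fit()


def parameter_behavior_regression(
    predictors: pd.DataFrame, outcome: pd.Series | np.ndarray
) -> RegressionResult:
    """Standardized OLS of a behavioral index on learning parameters.

    Typical use: risky-choice proportion on {utility weight, learning-rate
    contrast} within one domain.  Predictors and outcome are z-scored before
    fitting so coefficients are standardized.  Near-collinear designs
    (condition number > 1e8) are flagged.
    """
    if len(predictors) < predictors.shape[1] + 2:
        raise ValueError("need at least n_predictors + 2 observations")
    Xz = predictors.apply(_zscore)
    yz = _zscore(outcome)
    flags = []
    cond = np.linalg.cond(Xz.to_numpy()) if Xz.shape[1] > 1 else 1.0
    if cond > 1e8:
        flags.append(f"collinear predictors (condition number {cond:.3g})")
    res = _fit_ols(Xz, yz)
    return RegressionResult(
        coefficients=res.params.drop("const"),
        r2=float(res.rsquared),
        f_stat=float(res.fvalue) if np.isfinite(res.fvalue) else 0.0,
        f_p=float(res.f_pvalue) if np.isfinite(res.f_pvalue) else 1.0,
        n=len(predictors),
        p_values=res.pvalues.drop("const"),
        flags=flags,
    )


def hierarchical_trait_regression(
    traits: pd.DataFrame,
    param_values: pd.Series | np.ndarray,
    simple_slope_pairs: Sequence[tuple[str, str]] | None = None,
    alpha: float = 0.05,
) -> RegressionResult:
    """Moderated regression of one learning parameter on trait scores.

    Traits are centered/standardized; step 1 enters the main effects, step 2
    adds all pairwise products of the standardized traits.  The step-2 gain
    is tested by the F test on the R-squared change.  For each requested
    (predictor, moderator) pair — by default every interaction whose step-2
    slope is significant at ``alpha`` — simple slopes are computed by
    re-fitting with the moderator recoded at +1 SD and at -1 SD.
    """
    cols = list(traits.columns)
    if "subject" in cols:
        traits = traits.drop(columns="subject")
        cols = list(traits.columns)
    y = _zscore(param_values)
    if np.allclose(y, 0.0):
        zero = pd.Series(0.0, index=cols)
        return RegressionResult(zero, 0.0, 0.0, 1.0, len(traits),
                                step1_coefficients=zero, step1_r2=0.0,
                                delta_r2=0.0, delta_f=0.0, delta_p=1.0)
    Z = traits.apply(_zscore)
    step1 = _fit_ols(Z, y)

    def interactions(frame: pd.DataFrame) -> pd.DataFrame:
        X = frame.copy()
        for i, a in enumerate(cols):
            for b in cols[i + 1 :]:
                X[f"{a}:{b}"] = frame[a] * frame[b]
        return X

    X2 = interactions(Z)
    step2 = _fit_ols(X2, y)
    df_num = X2.shape[1] - Z.shape[1]
    df_den = len(traits) - X2.shape[1] - 1
    delta_r2 = float(step2.rsquared - step1.rsquared)
    if step2.rsquared < 1.0 and df_den > 0:
        delta_f = (delta_r2 / df_num) / ((1.0 - step2.rsquared) / df_den)
        from scipy.stats import f as f_dist

        delta_p = float(f_dist.sf(delta_f, df_num, df_den))
    else:
        delta_f, delta_p = np.inf, 0.0

    inter_names = [c for c in X2.columns if ":" in c]
    if simple_slope_pairs is None:
        simple_slope_pairs = [
            tuple(name.split(":"))
            for name in inter_names
            if step2.pvalues[name] < alpha
        ]
    slopes: dict[str, dict[str, float]] = {}
    for predictor, moderator in simple_slope_pairs:
        entry: dict[str, float] = {}
        for label, shift in (("low", -1.0), ("high", 1.0)):
            Zs = Z.copy()
            # recode the moderator at +/-1 SD: subtract the probe level so
            # the predictor's main slope is its effect at that level
            Zs[moderator] = Z[moderator] - shift
            res = _fit_ols(interactions(Zs), y)
            entry[f"slope_{label}"] = float(res.params[predictor])
            entry[f"p_{label}"] = float(res.pvalues[predictor])
        slopes[f"{predictor}|{moderator}"] = entry

    return RegressionResult(
        coefficients=step2.params.drop("const"),
        r2=float(step2.rsquared),
        f_stat=float(step2.fvalue) if np.isfinite(step2.fvalue) else 0.0,
        f_p=float(step2.f_pvalue) if np.isfinite(step2.f_pvalue) else 1.0,
        n=len(traits),
        step1_coefficients=step1.params.drop("const"),
        step1_r2=float(step1.rsquared),
        delta_r2=delta_r2,
        delta_f=float(delta_f),
        delta_p=delta_p,
        p_values=step2.pvalues.drop("const"),
        simple_slopes=slopes,
    )


def trait_correlation_screen(
    traits: pd.DataFrame, params: pd.DataFrame
) -> pd.DataFrame:
    """Trait-by-parameter Pearson correlation grid with raw and
    Bonferroni-corrected p-values (corrected over the whole grid)."""
    from scipy.stats import pearsonr

    tcols = [c for c in traits.columns if c != "subject"]
    pcols = [c for c in params.columns if c != "subject"]
    n_tests = len(tcols) * len(pcols)
    rows = []
    for t in tcols:
        for p in pcols:
            r, pv = pearsonr(traits[t], params[p])
            rows.append(
                {
                    "trait": t,
                    "parameter": p,
                    "r": r,
                    "p": pv,
                    "p_bonferroni": min(pv * n_tests, 1.0),
                }
            )
    return pd.DataFrame(rows)
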