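"""Per-subject exposure metrics and the exposure-adverse-event analysis.

Exposure is derived from the fitted model's empirical Bayes parameters:
steady-state AUC over 24 h as daily dose / individual CL/F, and the trough as
the steady-state concentration one full interval after a dose (equivalently
pre-dose).  The association analysis mirrors the study design: Mann-Whitney U
and Fisher exact group comparisons, ROC curves with Youden-index cut-offs
(higher exposure calls the adverse event), and multivariable logistic
regression of the event on the exposure metric adjusted for sex, age and GFR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .estimate import FitResult
from .io import PKDataset
from .model import Regimen, conc_steady_state, individual_params


def derive_exposure(dataset: PKDataset, fit_result: FitResult) -> pd.DataFrame:
    """Per-subject daily dose, individual CL/F, AUC and steady-state trough.

    Only subjects with a steady-state regimen (SS=1 dose row) are exposed;
    single-dose-arm subjects are skipped with a warning.  AUC is exactly
    daily_dose / CL_i (mg*h/L); the trough is the model concentration at
    t = tau after the last dose under the subject's own regimen.
    """
    ebes = fit_result.ebes.set_index("ID")
    pop = fit_result.estimates
    rows, skipped = [], []
    for sid, block in dataset.df.groupby("ID", sort=False):
        doses = block[(block["EVID"] == 1) & (block["SS"] == 1)]
        if doses.empty:
            skipped.append(sid)
            continue
        drow = doses.iloc[-1]
        reg = Regimen(dose_amount=float(drow["AMT"]), interval=float(drow["II"]))
        eta = ebes.loc[sid]
        cov = {col: block.iloc[0][col] for col in block.columns}
        ind = individual_params(pop, float(eta["ETA_CL"]), float(eta["ETA_V"]),
                                float(drow["WT"]), covariates=cov)
        daily = reg.daily_dose
        rows.append({
            "ID": sid,
            "daily_dose": daily,
            "cl_i": ind.cl,
            "auc": daily / ind.cl,
            "trough": conc_steady_state(ind, reg, reg.interval),
        })
    if skipped:
        warnings.warn(
            f"{len(skipped)} subject(s) without a steady-state regimen skipped "
            f"from the exposure table"
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def mann_whitney(a, b) -> float:
    """Two-sided Mann-Whitney U p-value (normal approximation, tie-corrected)."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value by the point-probability rule."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be a non-negative 2x2 contingency table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        warnings.warn("degenerate margin in 2x2 table; p = 1")
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided").pvalue)


def group_compare(values, groups) -> float:
    """Dispatch: binary values -> Fisher exact; continuous -> Mann-Whitney U.

    ``groups`` is a boolean/0-1 split of the subjects.
    """
    values = np.asarray(values)
    groups = np.asarray(groups).astype(bool)
    if groups.all() or not groups.any():
        raise ValueError("both groups must be nonempty")
    uniq = np.unique(values[~pd.isna(values)])
    if set(uniq.tolist()) <= {0, 1}:
        v = values.astype(int)
        table = [
            [int(((v == 1) & groups).sum()), int(((v == 0) & groups).sum())],
            [int(((v == 1) & ~groups).sum()), int(((v == 0) & ~groups).sum())],
        ]
        return fisher_exact_2x2(table)
    return mann_whitney(values[groups], values[~groups])


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc_roc: float
    cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float

    @property
    def youden(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0


def roc_youden(values, labels) -> ROCResult:
    """ROC curve over all candidate thresholds and the Youden-optimal cut-off.

    A subject is called positive when its exposure exceeds the threshold.
    Candidate thresholds are midpoints between consecutive distinct values
    plus -inf/+inf; ties on Youden's J break toward the lower threshold
    (higher sensitivity).  The ROC area is the trapezoidal integral.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("values and labels must be 1-D and aligned")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    distinct = np.unique(x)
    thr = np.concatenate([[-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf]])
    sens = np.array([(y[x > t] == 1).sum() / n_pos for t in thr])
    spec = np.array([(y[x <= t] == 0).sum() / n_neg for t in thr])

    j = sens + spec - 1.0
    # thresholds ascending, ties (to rounding) break toward the lower
    # threshold, i.e. the higher-sensitivity operating point
    best = np.flatnonzero(j >= j.max() - 1e-12)[0]
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))  # step-function corners in curve order
    auc = float(np.trapezoid(sens[order], fpr[order]))
    return ROCResult(
        thresholds=thr, sensitivity=sens, specificity=spec, auc_roc=auc,
        cutoff=float(thr[best]), sens_at_cutoff=float(sens[best]),
        spec_at_cutoff=float(spec[best]),
    )


# ---------------------------------------------------------------------------
# adjusted logistic regression
# ---------------------------------------------------------------------------

@dataclass
class LogisticResult:
    table: pd.DataFrame     # covariate, or, lo, hi, p
    converged: bool
    warnings: list[str] = field(default_factory=list)

    def odds_ratio(self, covariate: str) -> float:
        return float(self.table.set_index("covariate").loc[covariate, "or"])

    def p_value(self, covariate: str) -> float:
        return float(self.table.set_index("covariate").loc[covariate, "p"])


def logistic_adjusted(
    outcome, exposure, sex, age, gfr, exposure_name: str = "exposure"
) -> LogisticResult:
    """Multivariable logistic regression of the AE on exposure + sex/age/GFR.

    Maximum-likelihood fit with intercept; odds ratios exp(beta) with Wald
    95% CIs from the observed information.  Constant columns are dropped with
    a warning; separation (non-finite/huge estimates) flags the result.
    """
    y = np.asarray(outcome).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one event and one non-event")
    cols = {exposure_name: np.asarray(exposure, dtype=float),
            "sex": np.asarray(sex, dtype=float),
            "age": np.asarray(age, dtype=float),
            "gfr": np.asarray(gfr, dtype=float)}
    msgs = []
    for name in list(cols):
        if np.ptp(cols[name]) == 0:
            msgs.append(f"covariate {name!r} is constant and was dropped")
            warnings.warn(msgs[-1])
            del cols[name]
    X = sm.add_constant(pd.DataFrame(cols))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        try:
            res = model.fit(disp=False, maxiter=500, tol=1e-12)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception as exc:  # perfect separation raises in statsmodels
            msgs.append(f"logistic fit failed: {exc}")
            return LogisticResult(
                table=pd.DataFrame(columns=["covariate", "or", "lo", "hi", "p"]),
                converged=False, warnings=msgs,
            )
    params, bse, pvals = res.params, res.bse, res.pvalues
    if not np.all(np.isfinite(bse)) or np.any(np.abs(params) > 50):
        msgs.append("possible separation: non-finite or extreme coefficients")
        warnings.warn(msgs[-1])
        converged = False
    rows = []
    for name in cols:
        beta, se = params[name], bse[name]
        rows.append({
            "covariate": name,
            "or": np.exp(beta),
            "lo": np.exp(beta - 1.96 * se),
            "hi": np.exp(beta + 1.96 * se),
            "p": pvals[name],
        })
    return LogisticResult(table=pd.DataFrame(rows), converged=converged,
                          warnings=msgs)


# ---------------------------------------------------------------------------
# combined report
# ---------------------------------------------------------------------------

def ae_analysis_report(
    exposure_table: pd.DataFrame,
    labels: pd.DataFrame,
    subjects: pd.DataFrame,
    outcome: str = "DRAE",
    metric: str = "trough",
) -> str:
    """Text report: group comparison, ROC/Youden summary and adjusted ORs."""
    merged = exposure_table.merge(labels, on="ID").merge(
        subjects[["ID", "SEX", "AGE", "GFR"]], on="ID"
    )
    flag = merged[outcome].to_numpy().astype(bool)
    x = merged[metric].to_numpy()
    p_group = mann_whitney(x[flag], x[~flag])
    roc = roc_youden(x, flag)
    logit = logistic_adjusted(flag, x, merged["SEX"], merged["AGE"],
                              merged["GFR"], exposure_name=metric)
    lines = [
        f"Exposure metric: {metric}    outcome: {outcome}",
        f"n = {len(merged)}  events = {int(flag.sum())} "
        f"({100 * flag.mean():.2f}%)",
        "",
        f"{metric} in event vs no-event group: "
        f"{x[flag].mean():.2f} vs {x[~flag].mean():.2f} "
        f"(Mann-Whitney p = {p_group:.3f})",
        "",
        f"ROC: area {roc.auc_roc:.3f}; Youden cut-off {roc.cutoff:.2f} "
        f"(sensitivity {roc.sens_at_cutoff:.3f}, "
        f"specificity {roc.spec_at_cutoff:.3f})",
        "",
        "Adjusted logistic regression (odds ratio, 95% CI, Wald p):",
    ]
    for _, r in logit.table.iterrows():
        lines.append(
            f"  {r['covariate']:<10} {r['or']:.3f} ({r['lo']:.3f}-{r['hi']:.3f})"
            f"  p = {r['p']:.3f}"
        )
    if not logit.converged:
        lines.append("  [warning: logistic fit flagged as unreliable]")
    return "\n".join(lines)


__all__ = [
    "derive_exposure",
    "mann_whitney",
    "fisher_exact_2x2",
    "group_compare",
    "ROCResult",
    "roc_youden",
    "LogisticResult",
    "logistic_adjusted",
    "ae_analysis_report",
]
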