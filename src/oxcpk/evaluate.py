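"""Model evaluation: nonparametric bootstrap, visual predictive check, CWRES.

The bootstrap resamples *subjects* with replacement (covariates and all event
rows travel together) and refits each replicate starting from the original
estimates.  The VPC simulates replicate datasets at the original design (same
subjects, doses and sampling times; fresh random effects and residual noise)
and compares observed percentiles per time bin with the simulated percentile
bands, stratified by study arm.  CWRES are the FOCE-linearized standardized
residuals; a well-specified model gives mean ~ 0 and SD ~ 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .estimate import (
    FitConfig,
    FitResult,
    _eta_jacobian,
    _residual_var,
    compute_ebes,
    fit,
)
from .io import CompiledDataset, PKDataset, compile_dataset
from .model import PopulationParameters, predict_compiled


@dataclass
class BootstrapResult:
    n_resamples: int
    n_converged: int
    summary: pd.DataFrame     # parameter, estimate, median, lo, hi
    replicates: pd.DataFrame  # one row per converged replicate
    warnings: list[str] = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.summary.to_csv(path, index=False)


@dataclass
class VPCResult:
    table: pd.DataFrame
    # columns: stratum, bin_mid, bin_lo, bin_hi, n_obs,
    #          obs_p5, obs_p50, obs_p95,
    #          sim_p5, sim_p50, sim_p95 (+ _lo/_hi CI bounds across replicates)
    n_sim: int
    warnings: list[str] = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


_BOOT_PARAMS = [
    ("theta1_cl", "CL/F typical (L/h)"),
    ("theta2_wt_cl", "CL/F weight exponent"),
    ("theta3_v", "V/F typical (L)"),
    ("theta4_wt_v", "V/F weight exponent"),
    ("ka", "ka (1/h)"),
    ("iiv_cl_cv", "IIV CL/F (%CV)"),
    ("iiv_v_cv", "IIV V/F (%CV)"),
    ("sigma_prop", "Proportional error (SD)"),
]


def _param_row(pop: PopulationParameters) -> dict[str, float]:
    return {
        "theta1_cl": pop.theta1_cl,
        "theta2_wt_cl": pop.theta2_wt_cl,
        "theta3_v": pop.theta3_v,
        "theta4_wt_v": pop.theta4_wt_v,
        "ka": pop.ka,
        "iiv_cl_cv": pop.iiv_cl_cv_percent,
        "iiv_v_cv": pop.iiv_v_cv_percent,
        "sigma_prop": pop.sigma_prop,
    }


def bootstrap(
    dataset: PKDataset,
    fit_result: FitResult,
    n: int = 1000,
    seed: int = 0,
    cfg: FitConfig | None = None,
) -> BootstrapResult:
    """Subject-level nonparametric bootstrap of the parameter estimates.

    Each replicate is refit from the original estimates (single start).
    Medians and 2.5/97.5 percentiles are taken over converged replicates.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base_cfg = cfg or fit_result.config or FitConfig()
    base_cfg = replace(base_cfg, init=fit_result.estimates, n_starts=1)
    ids = dataset.subject_ids
    rng = np.random.default_rng(seed)

    rows, msgs = [], []
    n_converged = 0
    for _ in range(n):
        take = rng.choice(ids, size=len(ids), replace=True)
        rep = dataset.subset(take, renumber=True)
        res = fit(rep, base_cfg)
        if res.converged:
            n_converged += 1
            rows.append(_param_row(res.estimates))
    if n_converged < n * 0.8:
        msgs.append(
            f"only {n_converged}/{n} bootstrap replicates converged (>20% failures)"
        )
        warnings.warn(msgs[-1])
    reps = pd.DataFrame(rows)
    orig = _param_row(fit_result.estimates)
    summary = pd.DataFrame(
        {
            "parameter": [label for _, label in _BOOT_PARAMS],
            "estimate": [orig[k] for k, _ in _BOOT_PARAMS],
            "median": [reps[k].median() if len(reps) else np.nan for k, _ in _BOOT_PARAMS],
            "lo": [reps[k].quantile(0.025) if len(reps) else np.nan for k, _ in _BOOT_PARAMS],
            "hi": [reps[k].quantile(0.975) if len(reps) else np.nan for k, _ in _BOOT_PARAMS],
        }
    )
    return BootstrapResult(
        n_resamples=n, n_converged=n_converged, summary=summary,
        replicates=reps, warnings=msgs,
    )


def simulate_observations(
    c: CompiledDataset, pop: PopulationParameters, rng: np.random.Generator
) -> np.ndarray:
    """One replicate of DV at the dataset's design with fresh eta and epsilon."""
    etas = rng.multivariate_normal(
        [0.0, 0.0], np.diag([pop.omega2_cl, pop.omega2_v]), size=c.n_subjects
    )
    f = predict_compiled(c, pop, etas)
    dv = f * (1.0 + pop.sigma_prop * rng.standard_normal(c.n_obs))
    if pop.sigma_add > 0:
        dv = dv + pop.sigma_add * rng.standard_normal(c.n_obs)
    return np.maximum(dv, 0.0)


def _bin_edges_registry(t: np.ndarray, n_bins: int = 10) -> np.ndarray:
    edges = np.unique(np.quantile(t, np.linspace(0, 1, n_bins + 1)))
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    return edges


def vpc(
    dataset: PKDataset,
    pop: PopulationParameters,
    n_sim: int = 1000,
    seed: int = 0,
    registry_bins: int = 10,
) -> VPCResult:
    """Visual predictive check stratified by study arm.

    Registry-arm observations are binned at deciles of time after dose; the
    rich arm uses one bin per nominal sampling time (nearest-neighbour
    assignment of the jittered actual times).
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    c = compile_dataset(dataset)
    study = c.covariate("STUDY").astype(int)
    rng = np.random.default_rng(seed)
    sims = np.stack([simulate_observations(c, pop, rng) for _ in range(n_sim)])

    msgs: list[str] = []
    rows = []
    pcts = (5.0, 50.0, 95.0)

    def add_rows(stratum: str, mask: np.ndarray, bin_ids: np.ndarray,
                 mids: np.ndarray, los: np.ndarray, his: np.ndarray) -> None:
        for b in range(len(mids)):
            sel = mask & (bin_ids == b)
            if sel.sum() == 0:
                msgs.append(f"{stratum}: empty bin at t~{mids[b]:.2f} h dropped")
                continue
            row = {
                "stratum": stratum, "bin_mid": mids[b],
                "bin_lo": los[b], "bin_hi": his[b], "n_obs": int(sel.sum()),
            }
            for p, tag in zip(pcts, ("p5", "p50", "p95")):
                row[f"obs_{tag}"] = np.percentile(c.y[sel], p)
                per_rep = np.percentile(sims[:, sel], p, axis=1)
                row[f"sim_{tag}"] = np.median(per_rep)
                row[f"sim_{tag}_lo"] = np.percentile(per_rep, 2.5)
                row[f"sim_{tag}_hi"] = np.percentile(per_rep, 97.5)
            rows.append(row)

    reg_mask = study == 1
    if reg_mask.any():
        t = c.t_after_dose[reg_mask]
        edges = _bin_edges_registry(t, registry_bins)
        ids = np.full(c.n_obs, -1)
        ids[reg_mask] = np.clip(np.searchsorted(edges, t, side="right") - 1,
                                0, len(edges) - 2)
        mids = 0.5 * (edges[:-1] + edges[1:])
        add_rows("registry", reg_mask, ids, mids, edges[:-1], edges[1:])

    rich_mask = study == 2
    if rich_mask.any():
        nominal = np.unique(np.asarray([2.0, 4.0, 6.0, 8.0, 12.0, 14.0, 16.0, 24.0]))
        ids = np.full(c.n_obs, -1)
        ids[rich_mask] = np.argmin(
            np.abs(c.t_after_dose[rich_mask, None] - nominal[None, :]), axis=1
        )
        add_rows("single-dose", rich_mask, ids, nominal,
                 nominal, nominal)

    for m in msgs:
        warnings.warn(m)
    return VPCResult(table=pd.DataFrame(rows), n_sim=n_sim, warnings=msgs)


def plot_vpc(result: VPCResult, path) -> None:
    """Simple two-panel rendering of the VPC bands (one panel per stratum)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    strata = result.table["stratum"].unique()
    fig, axes = plt.subplots(1, max(len(strata), 1), figsize=(6 * len(strata), 4),
                             squeeze=False)
    for ax, st in zip(axes[0], strata):
        tb = result.table[result.table["stratum"] == st]
        x = tb["bin_mid"]
        for tag, style in (("p5", ":"), ("p50", "-"), ("p95", ":")):
            ax.fill_between(x, tb[f"sim_{tag}_lo"], tb[f"sim_{tag}_hi"],
                            alpha=0.3, color="tab:blue")
            ax.plot(x, tb[f"obs_{tag}"], style, color="tab:red")
        ax.set_title(st)
        ax.set_xlabel("time after dose (h)")
        ax.set_ylabel("MHD (mg/L)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def cwres(dataset: PKDataset, fit_result: FitResult) -> pd.DataFrame:
    """Conditional weighted residuals per observation.

    CWRES_i = V_i^{-1/2} (y_i - (f_i(eta_hat) - G_i eta_hat)), with V_i the
    FOCE-I conditional covariance and the matrix square root taken by
    symmetric eigendecomposition.  Returns ID, TIME after dose, PRED (the
    linearized population prediction) and CWRES per observation row.
    """
    c = compile_dataset(dataset)
    pop = fit_result.estimates
    etas = _align_etas(c, fit_result)
    f = predict_compiled(c, pop, etas)
    v = _residual_var(pop, f)
    G = _eta_jacobian(c, pop, etas)
    omega = np.diag([pop.omega2_cl, pop.omega2_v])
    mean_lin = f - np.einsum("jk,jk->j", G, etas[c.subj_idx])

    counts = np.bincount(c.subj_idx, minlength=c.n_subjects)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    out = np.empty(c.n_obs)
    for i in range(c.n_subjects):
        sl = slice(offsets[i], offsets[i + 1])
        g = G[sl]
        V = g @ omega @ g.T + np.diag(v[sl])
        w, Q = np.linalg.eigh(V)
        if np.any(w <= 0):
            raise np.linalg.LinAlgError(
                f"singular conditional variance for subject {c.ids[i]}"
            )
        V_inv_sqrt = (Q * (1.0 / np.sqrt(w))) @ Q.T
        out[sl] = V_inv_sqrt @ (c.y[sl] - mean_lin[sl])
    return pd.DataFrame({
        "ID": c.ids[c.subj_idx],
        "TAD": c.t_after_dose,
        "PRED": mean_lin,
        "CWRES": out,
    })


def _align_etas(c: CompiledDataset, fit_result: FitResult) -> np.ndarray:
    ebes = fit_result.ebes.set_index("ID")
    try:
        return ebes.loc[c.ids, ["ETA_CL", "ETA_V"]].to_numpy()
    except KeyError:
        # ids differ (e.g. CWRES on new data): recompute modes at the estimates
        etas, _ = compute_ebes(c, fit_result.estimates)
        return etas


__all__ = [
    "BootstrapResult",
    "VPCResult",
    "bootstrap",
    "simulate_observations",
    "vpc",
    "plot_vpc",
    "cwres",
]
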