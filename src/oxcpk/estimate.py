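"""FOCE-I estimation of the population PK model, plus stepwise covariate search.

The marginal likelihood of a nonlinear mixed-effects model has no closed
form; the first-order conditional estimation method with interaction (FOCE-I)
approximates it by linearizing the model in the random effects around each
subject's empirical Bayes mode eta_hat.  Writing f_i(eta) for the vector of
model predictions of subject i, G_i = df_i/deta at eta_hat_i, and a residual
variance evaluated at the conditional prediction (the "interaction"), the
objective function value is

    OFV = sum_i [ log|V_i| + r_i' V_i^{-1} r_i ],
    r_i = y_i - f_i(eta_hat_i) + G_i eta_hat_i,
    V_i = G_i Omega G_i' + diag(sigma_add^2 + sigma_prop^2 f_ij(eta_hat_i)^2),

with the n*log(2*pi) constant omitted (NONMEM convention).  The empirical
Bayes mode minimizes the conditional joint objective

    L_i(eta) = sum_j [ (y_ij - f_ij)^2 / v_ij + log v_ij ] + eta' Omega^{-1} eta,

v_ij the residual variance at f_ij(eta).  The outer search runs
unconstrained on transformed parameters (log for positive quantities, log1p
for fractional covariate coefficients); Omega is diagonal (IIV on CL and V
only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import CompiledDataset, PKDataset, compile_dataset
from .model import PRED_FLOOR, CovariateEffect, PopulationParameters, predict_compiled

#: Central finite-difference step (relative) for df/deta.
ETA_FD_STEP = 1e-4

#: Central finite-difference step on the transformed outer parameters.
OUTER_FD_STEP = 1e-6

#: Relative central-difference step for the outer Hessian used for RSEs.
#: Smaller steps drown the curvature in the (tiny) noise left by the
#: iterative inner eta search; 5e-3 gives a stable positive-definite Hessian.
HESS_REL_STEP = 5e-3

_POSITIVE_PARAMS = frozenset(
    {"theta1_cl", "theta3_v", "ka", "omega2_cl", "omega2_v", "sigma_prop", "sigma_add"}
)


def forward_threshold() -> float:
    """OFV drop required to add a covariate: chi2(1 df) 0.95 quantile."""
    return float(stats.chi2.ppf(0.95, df=1))


def backward_threshold() -> float:
    """OFV rise required to keep a covariate: chi2(1 df) 0.99 quantile."""
    return float(stats.chi2.ppf(0.99, df=1))


@dataclass
class FitConfig:
    """Configuration of the outer/inner optimization.

    ``fix`` lists parameter names frozen at their initial values (covariate
    coefficients are named ``beta_<column>``).  ``n_starts`` jittered starts
    guard against outer local minima; jitter is seeded.
    """

    init: PopulationParameters = field(default_factory=PopulationParameters)
    outer_tol: float = 1e-6
    inner_tol: float = 1e-6
    max_outer_iter: int = 500
    fix: tuple[str, ...] = ()
    seed: int = 0
    n_starts: int = 3
    jitter_sd: float = 0.1
    error_model: str = "proportional"  # proportional | additive | combined

    def __post_init__(self) -> None:
        if self.outer_tol <= 0 or self.inner_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_outer_iter < 1:
            raise ValueError("max_outer_iter must be >= 1")
        if self.error_model not in ("proportional", "additive", "combined"):
            raise ValueError(f"unknown error model {self.error_model!r}")
        self.fix = tuple(self.fix)


@dataclass
class FitResult:
    estimates: PopulationParameters
    ofv: float
    se: dict[str, float]
    rse: dict[str, float]           # percent
    ebes: pd.DataFrame              # columns ID, ETA_CL, ETA_V
    converged: bool
    n_subjects: int
    n_obs: int
    config: FitConfig | None = None
    ofv_trace: list[float] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)

    def eta_matrix(self) -> np.ndarray:
        return self.ebes[["ETA_CL", "ETA_V"]].to_numpy()

    def to_json(self, path) -> None:
        import json
        from dataclasses import asdict

        est = self.estimates
        payload = {
            "estimates": {
                "theta1_cl": est.theta1_cl, "theta2_wt_cl": est.theta2_wt_cl,
                "theta3_v": est.theta3_v, "theta4_wt_v": est.theta4_wt_v,
                "ka": est.ka, "omega2_cl": est.omega2_cl,
                "omega2_v": est.omega2_v, "sigma_prop": est.sigma_prop,
                "sigma_add": est.sigma_add, "wt_ref": est.wt_ref,
                "cl_effects": [asdict(e) for e in est.cl_effects],
            },
            "ofv": self.ofv,
            "se": self.se,
            "rse": self.rse,
            "converged": self.converged,
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
            "ebes": {
                str(r.ID): [r.ETA_CL, r.ETA_V] for r in self.ebes.itertuples()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FitResult":
        import json

        with open(path) as fh:
            payload = json.load(fh)
        e = dict(payload["estimates"])
        e["cl_effects"] = tuple(CovariateEffect(**d) for d in e.get("cl_effects", []))
        est = PopulationParameters(**e)
        ebes = pd.DataFrame(
            [(int(k), v[0], v[1]) for k, v in payload["ebes"].items()],
            columns=["ID", "ETA_CL", "ETA_V"],
        )
        return cls(
            estimates=est, ofv=payload["ofv"], se=payload["se"],
            rse=payload["rse"], ebes=ebes, converged=payload["converged"],
            n_subjects=payload["n_subjects"], n_obs=payload["n_obs"],
        )


# ---------------------------------------------------------------------------
# parameter vector <-> PopulationParameters
# ---------------------------------------------------------------------------

def _param_names(pop: PopulationParameters, error_model: str) -> list[str]:
    names = ["theta1_cl", "theta2_wt_cl", "theta3_v", "theta4_wt_v", "ka",
             "omega2_cl", "omega2_v"]
    if error_model in ("proportional", "combined"):
        names.append("sigma_prop")
    if error_model in ("additive", "combined"):
        names.append("sigma_add")
    names.extend(f"beta_{eff.column}" for eff in pop.cl_effects)
    return names


def _get_param(pop: PopulationParameters, name: str) -> float:
    if name.startswith("beta_"):
        col = name[5:]
        for eff in pop.cl_effects:
            if eff.column == col:
                return eff.beta
        raise KeyError(name)
    return getattr(pop, name)


def _set_params(pop: PopulationParameters, values: dict[str, float]) -> PopulationParameters:
    plain = {k: v for k, v in values.items() if not k.startswith("beta_")}
    out = pop.replace(**plain) if plain else pop
    betas = {k[5:]: v for k, v in values.items() if k.startswith("beta_")}
    if betas:
        effects = tuple(
            replace(eff, beta=betas.get(eff.column, eff.beta)) for eff in out.cl_effects
        )
        out = out.replace(cl_effects=effects)
    return out


class _Transform:
    """Unconstrained outer parameterization.

    Positive parameters are searched on the log scale; fractional covariate
    coefficients through log1p (so the CL multiplier 1+beta stays positive);
    allometric/power exponents are untransformed.
    """

    def __init__(self, pop: PopulationParameters, cfg: FitConfig):
        all_names = _param_names(pop, cfg.error_model)
        self.free = [n for n in all_names if n not in cfg.fix]
        self.kinds = {eff.column: eff.kind for eff in pop.cl_effects}

    def _is_fractional(self, name: str) -> bool:
        return name.startswith("beta_") and self.kinds.get(name[5:]) == "fractional"

    def to_x(self, pop: PopulationParameters) -> np.ndarray:
        x = []
        for n in self.free:
            v = _get_param(pop, n)
            if n in _POSITIVE_PARAMS:
                x.append(math.log(v))
            elif self._is_fractional(n):
                x.append(math.log1p(v))
            else:
                x.append(v)
        return np.asarray(x)

    def to_pop(self, x: np.ndarray, base: PopulationParameters) -> PopulationParameters:
        vals = {}
        for n, xi in zip(self.free, x):
            if n in _POSITIVE_PARAMS:
                vals[n] = math.exp(min(xi, 700.0))
            elif self._is_fractional(n):
                vals[n] = math.expm1(min(xi, 700.0))
            else:
                vals[n] = xi
        return _set_params(base, vals)


# ---------------------------------------------------------------------------
# inner problem: batched empirical Bayes modes
# ---------------------------------------------------------------------------

def _residual_var(pop: PopulationParameters, f: np.ndarray) -> np.ndarray:
    fc = np.maximum(f, PRED_FLOOR)
    return pop.sigma_add**2 + pop.sigma_prop**2 * fc**2


def _free_eta_dims(pop: PopulationParameters) -> np.ndarray:
    return np.array([pop.omega2_cl > 0, pop.omega2_v > 0])


def _inner_objective(c: CompiledDataset, pop: PopulationParameters,
                     etas: np.ndarray) -> np.ndarray:
    """Per-subject conditional joint objective L_i(eta)."""
    with np.errstate(all="ignore"):
        f = predict_compiled(c, pop, etas)
        v = _residual_var(pop, f)
        per_obs = (c.y - f) ** 2 / v + np.log(v)
    out = np.bincount(c.subj_idx, weights=per_obs, minlength=c.n_subjects)
    for k, om2 in enumerate((pop.omega2_cl, pop.omega2_v)):
        if om2 > 0:
            out = out + etas[:, k] ** 2 / om2
    return out


def _eta_jacobian(c: CompiledDataset, pop: PopulationParameters,
                  etas: np.ndarray) -> np.ndarray:
    """df/deta per observation by central differences, shape (n_obs, 2).

    Columns of fixed (omega2=0) dimensions are zero: those etas never move.
    """
    G = np.zeros((c.n_obs, 2))
    for k in np.flatnonzero(_free_eta_dims(pop)):
        h = ETA_FD_STEP
        ep = etas.copy(); ep[:, k] += h
        em = etas.copy(); em[:, k] -= h
        G[:, k] = (predict_compiled(c, pop, ep) - predict_compiled(c, pop, em)) / (2 * h)
    return G


def compute_ebes(
    c: CompiledDataset,
    pop: PopulationParameters,
    eta0: np.ndarray | None = None,
    inner_tol: float = 1e-6,
    max_iter: int = 80,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched damped (Gauss-Newton) search for all subjects' eta modes.

    Returns (etas, grad_norms).  Dimensions with zero IIV variance are pinned
    at eta = 0 (the infinite-shrinkage limit).
    """
    n = c.n_subjects
    free = _free_eta_dims(pop)
    etas = np.zeros((n, 2)) if eta0 is None else np.array(eta0, dtype=float)
    # sanitize warm starts: a diverged previous solve must not poison this one
    etas[~np.isfinite(etas)] = 0.0
    np.clip(etas, -40.0, 40.0, out=etas)
    etas[:, ~free] = 0.0
    if not free.any():
        return etas, np.zeros(n)

    omega2 = np.array([pop.omega2_cl, pop.omega2_v])
    obj = _inner_objective(c, pop, etas)
    bad = ~np.isfinite(obj)
    if bad.any():
        etas[bad] = 0.0
        obj = _inner_objective(c, pop, etas)
    grad_norms = np.full(n, np.inf)
    frozen = np.zeros(n, dtype=bool)  # subjects stalled at their mode

    for _ in range(max_iter):
        with np.errstate(all="ignore"):
            f = predict_compiled(c, pop, etas)
            fc = np.maximum(f, PRED_FLOOR)
            v = _residual_var(pop, f)
            dv_df = 2 * pop.sigma_prop**2 * fc * (f > PRED_FLOOR)
            res = c.y - f
            # dL/df per observation
            dl_df = -2 * res / v - res**2 * dv_df / v**2 + dv_df / v
            dl_df = np.nan_to_num(dl_df, nan=0.0, posinf=0.0, neginf=0.0)
            G = _eta_jacobian(c, pop, etas)

        grad = np.zeros((n, 2))
        H = np.zeros((n, 2, 2))
        with np.errstate(all="ignore"):
            for k in np.flatnonzero(free):
                grad[:, k] = np.bincount(c.subj_idx, weights=dl_df * G[:, k], minlength=n)
                grad[:, k] += 2 * etas[:, k] / omega2[k]
                for l in np.flatnonzero(free):
                    w = np.nan_to_num(2 * G[:, k] * G[:, l] / v,
                                      nan=0.0, posinf=0.0, neginf=0.0)
                    H[:, k, l] = np.bincount(c.subj_idx, weights=w, minlength=n)
                H[:, k, k] += 2 / omega2[k]

        grad_norms = np.linalg.norm(grad, axis=1)
        grad_norms[~np.isfinite(grad_norms)] = np.inf
        active = (grad_norms > inner_tol) & ~frozen
        if not active.any():
            break

        # Solve the 2x2 (or pinned 1x1) Gauss-Newton systems in closed form.
        H = H + 1e-12 * np.eye(2)
        for k in np.flatnonzero(~free):
            H[:, k, k] = 1.0  # pinned dims: harmless identity row/col
        det = H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] * H[:, 1, 0]
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        step = np.empty_like(grad)
        step[:, 0] = (H[:, 1, 1] * grad[:, 0] - H[:, 0, 1] * grad[:, 1]) / det
        step[:, 1] = (H[:, 0, 0] * grad[:, 1] - H[:, 1, 0] * grad[:, 0]) / det
        step[:, ~free] = 0.0

        # Per-subject backtracking line search on L_i.
        alpha = np.where(active, 1.0, 0.0)
        best_obj = obj.copy()
        new_etas = etas.copy()
        pending = active.copy()
        for _bt in range(16):
            if not pending.any():
                break
            trial = etas - alpha[:, None] * step
            np.clip(trial, -40.0, 40.0, out=trial)
            trial[~np.isfinite(trial)] = 0.0
            trial[:, ~free] = 0.0
            trial_obj = _inner_objective(c, pop, trial)
            improved = pending & (trial_obj < best_obj - 1e-12)
            new_etas[improved] = trial[improved]
            best_obj[improved] = trial_obj[improved]
            pending = pending & ~improved
            alpha = np.where(pending, alpha / 2, alpha)
        frozen |= pending  # no descent direction left: already at the mode
        moved = active & ~pending
        etas, obj = new_etas, best_obj
        if not moved.any():  # every active subject stalled at its mode
            break

    return etas, grad_norms


def inner_ebe(
    dataset: PKDataset,
    subject_id,
    pop: PopulationParameters,
    inner_tol: float = 1e-8,
) -> tuple[np.ndarray, float, float]:
    """Empirical Bayes mode of one subject: (eta_hat, L(eta_hat), |grad|)."""
    c = compile_dataset(dataset.subset([subject_id], renumber=True))
    if c.n_obs < 1:
        raise ValueError(f"subject {subject_id} has no usable observation")
    etas, gnorm = compute_ebes(c, pop, inner_tol=inner_tol)
    obj = _inner_objective(c, pop, etas)
    return etas[0], float(obj[0]), float(gnorm[0])


# ---------------------------------------------------------------------------
# FOCE-I objective
# ---------------------------------------------------------------------------

def _ofv_from_etas(c: CompiledDataset, pop: PopulationParameters,
                   etas: np.ndarray) -> float:
    with np.errstate(all="ignore"):
        f = predict_compiled(c, pop, etas)
        v = _residual_var(pop, f)
        G = _eta_jacobian(c, pop, etas)
        omega = np.diag([pop.omega2_cl, pop.omega2_v])
        r = c.y - f + np.einsum("jk,jk->j", G, etas[c.subj_idx])

    counts = np.bincount(c.subj_idx, minlength=c.n_subjects)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    contribs = []
    single = counts == 1
    if single.any():
        # scalar path for one-observation subjects (the sparse arm)
        idx = offsets[:-1][single]
        g = G[idx]
        vi = np.einsum("jk,kl,jl->j", g, omega, g) + v[idx]
        if not np.all(vi > 0):
            bad = c.ids[np.flatnonzero(single)[np.flatnonzero(~(vi > 0))[0]]]
            raise np.linalg.LinAlgError(f"singular conditional variance for subject {bad}")
        with np.errstate(all="ignore"):
            contribs.extend(np.log(vi) + r[idx] ** 2 / vi)
    for i in np.flatnonzero(~single):
        sl = slice(offsets[i], offsets[i + 1])
        g = G[sl]
        V = g @ omega @ g.T + np.diag(v[sl])
        sign, logdet = np.linalg.slogdet(V)
        if sign <= 0:
            raise np.linalg.LinAlgError(
                f"singular conditional variance for subject {c.ids[i]}"
            )
        contribs.append(logdet + r[sl] @ np.linalg.solve(V, r[sl]))
    # fsum: exact rounding makes the OFV invariant to subject ordering
    return math.fsum(contribs)


def foce_ofv(
    dataset_or_compiled,
    pop: PopulationParameters,
    eta0: np.ndarray | None = None,
    inner_tol: float = 1e-6,
    return_etas: bool = False,
):
    """FOCE-I objective function value of a dataset at ``pop``."""
    c = (dataset_or_compiled if isinstance(dataset_or_compiled, CompiledDataset)
         else compile_dataset(dataset_or_compiled))
    etas, _ = compute_ebes(c, pop, eta0=eta0, inner_tol=inner_tol)
    ofv = _ofv_from_etas(c, pop, etas)
    return (ofv, etas) if return_etas else ofv


# ---------------------------------------------------------------------------
# outer optimization
# ---------------------------------------------------------------------------

def fit(dataset: PKDataset | CompiledDataset, cfg: FitConfig | None = None) -> FitResult:
    """Estimate population parameters by FOCE-I.

    The outer minimization (L-BFGS-B on transformed parameters) is warm-started
    on the empirical Bayes modes between objective evaluations.  Multi-start
    jitter and all other randomness derive from ``cfg.seed``.  Non-convergence
    yields ``converged=False``, never an exception.
    """
    cfg = cfg or FitConfig()
    c = dataset if isinstance(dataset, CompiledDataset) else compile_dataset(dataset)
    if c.n_obs == 0:
        raise ValueError("dataset has no usable observations")
    tr = _Transform(cfg.init, cfg)
    messages: list[str] = []

    if not tr.free:  # everything fixed: evaluate and return the init
        ofv, etas = foce_ofv(c, cfg.init, inner_tol=cfg.inner_tol, return_etas=True)
        return FitResult(
            estimates=cfg.init, ofv=ofv, se={}, rse={},
            ebes=_ebe_frame(c, etas), converged=True,
            n_subjects=c.n_subjects, n_obs=c.n_obs, config=cfg, ofv_trace=[ofv],
        )

    warm = {"etas": None, "best": np.inf}

    def objective(x: np.ndarray) -> float:
        """OFV with excursions soft-capped above the running best.

        Line searches on log-scale parameters can probe points where the OFV
        overflows by tens of orders of magnitude; squashing everything above
        best+1e3 monotonically keeps the search stable without touching the
        landscape near the optimum.
        """
        pop = tr.to_pop(x, cfg.init)
        try:
            ofv, etas = foce_ofv(c, pop, eta0=warm["etas"],
                                 inner_tol=cfg.inner_tol, return_etas=True)
        except (np.linalg.LinAlgError, FloatingPointError):
            ofv = np.nan
        else:
            warm["etas"] = etas
        if np.isfinite(warm["best"]):
            cap = warm["best"] + 1e3
        elif np.isfinite(ofv):
            cap = ofv + 1e3
        else:
            return 1e12
        if not np.isfinite(ofv):
            return cap + 100.0
        warm["best"] = min(warm["best"], ofv)
        if ofv > cap:
            return cap + np.log10(ofv - cap + 1.0)
        return ofv

    def gradient(x: np.ndarray) -> np.ndarray:
        """Central differences with the eta warm start reset per probe.

        Resetting cancels the (tiny) hysteresis the warm-started inner search
        would otherwise leak into the finite differences.
        """
        snap = None if warm["etas"] is None else warm["etas"].copy()
        g = np.zeros_like(x)
        for k in range(len(x)):
            e = np.zeros_like(x)
            e[k] = OUTER_FD_STEP
            if snap is not None:
                warm["etas"] = snap.copy()
            fp = objective(x + e)
            if snap is not None:
                warm["etas"] = snap.copy()
            fm = objective(x - e)
            g[k] = (fp - fm) / (2 * OUTER_FD_STEP)
        if snap is not None:
            warm["etas"] = snap
        return g

    rng = np.random.default_rng(cfg.seed)
    x0 = tr.to_x(cfg.init)
    best: tuple[float, np.ndarray, bool, list[float]] | None = None
    for s in range(max(1, cfg.n_starts)):
        xs = x0 if s == 0 else x0 + rng.normal(0.0, cfg.jitter_sd, size=x0.shape)
        warm["etas"] = None
        warm["best"] = np.inf
        trace: list[float] = []
        f_prev = np.inf
        x_cur = xs
        start_converged = False
        # BFGS restarts: a fresh Hessian recovers from "precision loss" stops
        # until the OFV improvement between rounds falls under outer_tol.
        for _round in range(5):
            res = optimize.minimize(
                objective, x_cur, jac=gradient, method="BFGS",
                callback=lambda xk: trace.append(objective(xk)),
                options=dict(gtol=1e-5, maxiter=cfg.max_outer_iter),
            )
            x_cur = res.x
            gain = f_prev - res.fun
            f_prev = res.fun
            if res.success or gain < cfg.outer_tol * max(abs(res.fun), 1.0):
                start_converged = True
                break
        if best is None or f_prev < best[0]:
            best = (f_prev, x_cur, start_converged, trace)
    f_best, x_best, start_converged, trace = best

    class _Res:  # minimal result shim for downstream bookkeeping
        x = x_best
        fun = f_best

    res = _Res()
    converged = start_converged and f_best < 1e11
    if not converged:
        messages.append("outer optimizer did not reach the OFV tolerance")

    est = tr.to_pop(res.x, cfg.init)
    warm["etas"] = None
    ofv, etas = foce_ofv(c, est, inner_tol=cfg.inner_tol, return_etas=True)
    se, rse = _standard_errors(c, est, cfg, tr, messages)
    return FitResult(
        estimates=est, ofv=ofv, se=se, rse=rse, ebes=_ebe_frame(c, etas),
        converged=converged, n_subjects=c.n_subjects, n_obs=c.n_obs,
        config=cfg, ofv_trace=trace, messages=messages,
    )


def _ebe_frame(c: CompiledDataset, etas: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({"ID": c.ids, "ETA_CL": etas[:, 0], "ETA_V": etas[:, 1]})


def _standard_errors(c, pop, cfg, tr, messages) -> tuple[dict, dict]:
    """SEs from the inverse central-difference Hessian of OFV/2 (natural scale)."""
    names = tr.free
    theta = np.array([_get_param(pop, n) for n in names])
    h = HESS_REL_STEP * np.maximum(np.abs(theta), 1e-8)
    warm = {"etas": None}

    def ofv_at(vals: np.ndarray) -> float:
        p = _set_params(pop, dict(zip(names, vals)))
        try:
            o, etas = foce_ofv(c, p, eta0=warm["etas"],
                               inner_tol=cfg.inner_tol, return_etas=True)
        except (np.linalg.LinAlgError, ValueError, FloatingPointError):
            return np.nan
        warm["etas"] = etas
        return o

    p = len(names)
    f0 = ofv_at(theta)
    H = np.empty((p, p))
    for i in range(p):
        ei = np.zeros(p); ei[i] = h[i]
        H[i, i] = (ofv_at(theta + ei) + ofv_at(theta - ei) - 2 * f0) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                ofv_at(theta + ei + ej) - ofv_at(theta + ei - ej)
                - ofv_at(theta - ei + ej) + ofv_at(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    H *= 0.5  # Hessian of OFV/2 = observed information
    se = dict.fromkeys(names, np.nan)
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        if np.any(d <= 0) or not np.all(np.isfinite(d)):
            raise np.linalg.LinAlgError("non-positive variance")
        for n, v in zip(names, d):
            se[n] = math.sqrt(v)
    except np.linalg.LinAlgError as exc:
        messages.append(f"standard errors unavailable: {exc}")
    rse = {
        n: (100.0 * se[n] / abs(_get_param(pop, n))
            if np.isfinite(se[n]) and _get_param(pop, n) != 0 else np.nan)
        for n in names
    }
    return se, rse


# ---------------------------------------------------------------------------
# stepwise covariate search
# ---------------------------------------------------------------------------

@dataclass
class CovariateSearchResult:
    selected: list[CovariateEffect]
    trace: list[tuple[str, float, str]]   # (candidate column, dOFV, decision)
    final_fit: FitResult
    forward_threshold: float
    backward_threshold: float


def default_candidates(dataset: PKDataset) -> list[CovariateEffect]:
    """Age (power), sex (fractional) and each ASM/EIASM flag (fractional) on CL."""
    subj = dataset.subjects_table()
    cands = [
        CovariateEffect("AGE", kind="power", ref=float(subj["AGE"].median())),
        CovariateEffect("SEX", kind="fractional"),
        CovariateEffect("EIASM", kind="fractional"),
    ]
    cands.extend(CovariateEffect(col, kind="fractional") for col in dataset.extra_columns)
    return cands


def covariate_search(
    dataset: PKDataset | CompiledDataset,
    base_cfg: FitConfig,
    candidates: list[CovariateEffect],
) -> CovariateSearchResult:
    """Stepwise forward selection / backward elimination on CL/F covariates.

    Forward: the candidate with the largest OFV drop enters while the drop is
    at least the chi2(1) 95% quantile; backward: a retained effect is removed
    unless deleting it raises the OFV by at least the 99% quantile.  Body
    weight is part of the structural model and is never searched.
    """
    c = dataset if isinstance(dataset, CompiledDataset) else compile_dataset(dataset)
    for cand in candidates:
        if cand.column not in c.subjects.columns:
            raise KeyError(f"candidate covariate column {cand.column!r} not in dataset")
    fwd, bwd = forward_threshold(), backward_threshold()

    def fit_with(effects: tuple[CovariateEffect, ...], init: PopulationParameters) -> FitResult:
        cfg = replace(base_cfg, init=init.replace(cl_effects=effects), n_starts=1)
        return fit(c, cfg)

    base_fit_res = fit_with(tuple(base_cfg.init.cl_effects), base_cfg.init)
    current = base_fit_res
    selected: list[CovariateEffect] = list(base_cfg.init.cl_effects)
    remaining = [x for x in candidates]
    trace: list[tuple[str, float, str]] = []

    while remaining:
        results = []
        for cand in remaining:
            trial = fit_with(tuple(selected) + (replace(cand, beta=0.0),),
                             current.estimates)
            results.append((current.ofv - trial.ofv, cand, trial))
        results.sort(key=lambda t: -t[0])
        d_ofv, cand, trial = results[0]
        for d, cd, _ in results[1:]:
            trace.append((cd.column, d, "not added"))
        if d_ofv >= fwd:
            trace.append((cand.column, d_ofv, "added"))
            selected = list(trial.estimates.cl_effects)
            current = trial
            remaining = [x for x in remaining if x.column != cand.column]
        else:
            trace.append((cand.column, d_ofv, "not added"))
            break

    searched = [e for e in selected if e.column not in
                {x.column for x in base_cfg.init.cl_effects}]
    while searched:
        results = []
        for eff in searched:
            reduced = tuple(e for e in selected if e.column != eff.column)
            trial = fit_with(reduced, current.estimates)
            results.append((trial.ofv - current.ofv, eff, trial))
        results.sort(key=lambda t: t[0])
        d_ofv, eff, trial = results[0]
        if d_ofv < bwd:
            trace.append((eff.column, d_ofv, "removed"))
            selected = [e for e in selected if e.column != eff.column]
            searched = [e for e in searched if e.column != eff.column]
            current = trial
        else:
            for d, e, _ in results:
                trace.append((e.column, d, "kept"))
            break

    return CovariateSearchResult(
        selected=[e for e in selected if e.column not in
                  {x.column for x in base_cfg.init.cl_effects}],
        trace=trace,
        final_fit=current,
        forward_threshold=fwd,
        backward_threshold=bwd,
    )


def format_fit_report(res: FitResult) -> str:
    """Plain-text parameter table (estimate, RSE%) in the conventional layout."""
    est = res.estimates
    lines = [
        "Population PK parameter estimates",
        "=" * 49,
        f"{'Parameter':<32}{'Estimate':>10}{'RSE%':>7}",
        "-" * 49,
    ]

    def row(label, name, value):
        rse = res.rse.get(name, np.nan)
        rse_s = f"{rse:.1f}" if np.isfinite(rse) else "-"
        lines.append(f"{label:<32}{value:>10.4g}{rse_s:>7}")

    row("CL/F typical (L/h)", "theta1_cl", est.theta1_cl)
    row("CL/F weight exponent", "theta2_wt_cl", est.theta2_wt_cl)
    row("V/F typical (L)", "theta3_v", est.theta3_v)
    row("V/F weight exponent", "theta4_wt_v", est.theta4_wt_v)
    row("ka (1/h)", "ka", est.ka)
    row("IIV CL/F (%CV)", "omega2_cl", est.iiv_cl_cv_percent)
    row("IIV V/F (%CV)", "omega2_v", est.iiv_v_cv_percent)
    if est.sigma_prop > 0:
        row("Proportional error (SD)", "sigma_prop", est.sigma_prop)
    if est.sigma_add > 0:
        row("Additive error (SD, mg/L)", "sigma_add", est.sigma_add)
    for eff in est.cl_effects:
        row(f"{eff.column} effect on CL ({eff.kind})", f"beta_{eff.column}", eff.beta)
    lines += [
        "-" * 49,
        f"OFV {res.ofv:.3f}   subjects {res.n_subjects}   observations {res.n_obs}"
        f"   converged {res.converged}",
    ]
    return "\n".join(lines)


__all__ = [
    "FitConfig",
    "FitResult",
    "CovariateSearchResult",
    "forward_threshold",
    "backward_threshold",
    "compute_ebes",
    "inner_ebe",
    "foce_ofv",
    "fit",
    "covariate_search",
    "default_candidates",
    "format_fit_report",
]
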