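"""Virtual cohorts emulating the adult-epilepsy MHD study design.

Two arms are generated:

* a sparse registry arm (default 447 subjects) on chronic oral dosing assumed
  at steady state, predominantly twice daily, contributing one concentration
  each at a random time within the dosing interval; and
* a rich single-dose arm (default 40 subjects) dosed 30 mg/kg and sampled at
  the nominal times 2, 4, 6, 8, 12, 14, 16 and 24 h post dose.

Concentrations follow the one-compartment model with log-normal IIV on CL/F
and V/F and proportional residual error.  Dose-related adverse events (DRAE)
are drawn from a logistic link on each subject's model-true steady-state
trough; "sole dizziness" is a sub-flag of DRAE.  Randomness is organised as
one master seed with deterministic per-subject substreams, so enlarging the
cohort never perturbs previously generated subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .io import CORE_COLUMNS, PKDataset
from .model import (
    IndividualParameters,
    PopulationParameters,
    Regimen,
    conc_steady_state,
    individual_params,
)

#: Marginal prevalence of each concomitant ASM flag in the registry arm.
DEFAULT_ASM_PREVALENCE: dict[str, float] = {
    "LEV": 0.36, "TPM": 0.21, "LTG": 0.15, "VPA": 0.12, "ZNS": 0.08,
    "PGB": 0.05, "CLB": 0.05, "PHT": 0.03, "PB": 0.02, "VGB": 0.01, "LZP": 0.01,
}


@dataclass
class CohortConfig:
    """Design constants of the emulated study; defaults reproduce its cohort."""

    n_sparse: int = 447
    n_rich: int = 40
    truth: PopulationParameters = field(default_factory=PopulationParameters)
    weight_mean: float = 65.8
    weight_sd: float = 12.5
    weight_min: float = 39.0
    weight_max: float = 116.0
    age_mean: float = 39.2
    age_sd: float = 14.7
    age_min: float = 16.0
    age_max: float = 80.0
    male_frac: float = 0.591
    daily_dose_mean: float = 999.0
    daily_dose_sd: float = 338.0
    daily_dose_min: float = 150.0
    daily_dose_max: float = 2100.0
    dose_step: float = 150.0
    bid_frac: float = 438.0 / 447.0
    rich_dose_per_kg: float = 30.0
    rich_times: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0, 12.0, 14.0, 16.0, 24.0)
    rich_time_jitter: float = 0.10
    rich_dropout: float = 0.05
    eiasm_frac: float = 0.051
    asm_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ASM_PREVALENCE)
    )
    gfr_mean: float = 100.0
    gfr_sd: float = 15.0
    gfr_min: float = 30.0
    drae_prevalence: float = 0.0626
    ae_slope: float = float(np.log(1.079))      # per mg/L of trough
    ae_intercept: float | None = None           # None -> solved from prevalence
    dizziness_given_drae: float = 18.0 / 28.0
    seed: int = 0
    #: fractional CL/F multipliers applied in truth, e.g. {"EIASM": 0.3}
    true_cl_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("male_frac", "bid_frac", "eiasm_frac", "rich_dropout",
                     "dizziness_given_drae", "drae_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for lo, hi in (("weight_min", "weight_max"), ("age_min", "age_max"),
                       ("daily_dose_min", "daily_dose_max")):
            if getattr(self, lo) >= getattr(self, hi):
                raise ValueError(f"{lo} must be below {hi}")
        if self.n_sparse < 0 or self.n_rich < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.daily_dose_min <= 0:
            raise ValueError("doses must be positive")

    def replace(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


@dataclass
class SyntheticCohort:
    dataset: PKDataset
    true_etas: pd.DataFrame       # ID, ETA_CL, ETA_V
    ae_labels: pd.DataFrame       # ID, DRAE, DIZZINESS (sparse arm only)
    true_troughs: pd.DataFrame    # ID, TROUGH (sparse arm only, model-true)
    config: CohortConfig


def _rng_for(cfg_seed: int, subject_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(cfg_seed, spawn_key=(subject_index,))
    return np.random.default_rng(ss)


def _trunc_normal(rng, mean, sd, lo, hi=np.inf):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _true_individual(cfg: CohortConfig, wt, eta_cl, eta_v, flags: dict) -> IndividualParameters:
    ind = individual_params(cfg.truth, eta_cl, eta_v, wt)
    mult = 1.0
    for col, beta in cfg.true_cl_effects.items():
        mult *= 1.0 + beta * flags.get(col, 0)
    if mult != 1.0:
        ind = IndividualParameters(cl=ind.cl * mult, v=ind.v, ka=ind.ka)
    return ind


def _draw_subject(cfg: CohortConfig, i: int, rich: bool) -> dict:
    rng = _rng_for(cfg.seed, i)
    wt = _trunc_normal(rng, cfg.weight_mean, cfg.weight_sd, cfg.weight_min, cfg.weight_max)
    age = _trunc_normal(rng, cfg.age_mean, cfg.age_sd, cfg.age_min, cfg.age_max)
    sex = int(rng.random() < cfg.male_frac)
    gfr = _trunc_normal(rng, cfg.gfr_mean, cfg.gfr_sd, cfg.gfr_min)
    eiasm = int(rng.random() < cfg.eiasm_frac) if not rich else 0
    asm = {col: (int(rng.random() < p) if not rich else 0)
           for col, p in cfg.asm_prevalence.items()}
    eta = rng.multivariate_normal(
        [0.0, 0.0], np.diag([cfg.truth.omega2_cl, cfg.truth.omega2_v])
    )
    out = dict(wt=wt, age=age, sex=sex, gfr=gfr, eiasm=eiasm, asm=asm,
               eta_cl=eta[0], eta_v=eta[1], rng=rng)

    if rich:
        dose = cfg.rich_dose_per_kg * wt
        times, eps = [], []
        for t in cfg.rich_times:
            if rng.random() < cfg.rich_dropout:
                continue
            jit = 1.0 + rng.uniform(-cfg.rich_time_jitter, cfg.rich_time_jitter)
            times.append(t * jit)
            eps.append(rng.standard_normal())
        if not times:  # keep the >=1 observation invariant
            times = [float(cfg.rich_times[-1])]
            eps = [rng.standard_normal()]
        out.update(dose=dose, times=times, eps=eps)
    else:
        daily = _trunc_normal(rng, cfg.daily_dose_mean, cfg.daily_dose_sd,
                              cfg.daily_dose_min, cfg.daily_dose_max)
        daily = float(np.clip(cfg.dose_step * round(daily / cfg.dose_step),
                              cfg.daily_dose_min, cfg.daily_dose_max))
        u = rng.random()
        if u < cfg.bid_frac:
            n_per_day = 2
        else:
            n_per_day = 1 if rng.random() < 0.5 else 3
        tau = 24.0 / n_per_day
        out.update(daily_dose=daily, tau=tau, dose=daily / n_per_day,
                   t_obs=rng.uniform(0.0, tau), eps=[rng.standard_normal()],
                   u_drae=rng.random(), u_dizzy=rng.random())
    if out["dose"] <= 0:
        raise ValueError("configuration produced a non-positive dose")
    return out


def default_ae_link(cfg: CohortConfig, troughs: np.ndarray | None = None) -> tuple[float, float]:
    """(intercept, slope) of the trough->DRAE logistic link.

    The slope defaults to ``cfg.ae_slope``; the intercept is solved so that the
    expected DRAE prevalence over the cohort's trough distribution matches
    ``cfg.drae_prevalence``.  ``troughs`` may be supplied to avoid regenerating
    the cohort.
    """
    if troughs is None:
        troughs = _sparse_troughs(cfg)
    troughs = np.asarray(troughs, dtype=float)
    if troughs.size == 0:
        raise ValueError("no sparse-arm subjects to calibrate the AE link on")
    slope = cfg.ae_slope

    def excess(a: float) -> float:
        return float(np.mean(expit(a + slope * troughs))) - cfg.drae_prevalence

    lo, hi = -20.0, 0.0
    if excess(lo) > 0 or excess(hi) < 0:
        raise ValueError("no intercept in [-20, 0] attains the target prevalence")
    return float(brentq(excess, lo, hi, xtol=1e-10)), slope


def _sparse_troughs(cfg: CohortConfig) -> np.ndarray:
    troughs = np.empty(cfg.n_sparse)
    for i in range(cfg.n_sparse):
        s = _draw_subject(cfg, i, rich=False)
        ind = _true_individual(cfg, s["wt"], s["eta_cl"], s["eta_v"],
                               {**s["asm"], "EIASM": s["eiasm"]})
        reg = Regimen(dose_amount=s["dose"], interval=s["tau"])
        troughs[i] = conc_steady_state(ind, reg, s["tau"])
    return troughs


def generate(cfg: CohortConfig | None = None) -> SyntheticCohort:
    """Draw a full two-arm cohort with PK observations and AE labels."""
    cfg = cfg or CohortConfig()
    rows: list[dict] = []
    etas, labels, troughs = [], [], []

    # AE link calibration needs the sparse-arm trough distribution first.
    sparse = [_draw_subject(cfg, i, rich=False) for i in range(cfg.n_sparse)]
    trough_vals = np.empty(cfg.n_sparse)
    for i, s in enumerate(sparse):
        ind = _true_individual(cfg, s["wt"], s["eta_cl"], s["eta_v"],
                               {**s["asm"], "EIASM": s["eiasm"]})
        reg = Regimen(dose_amount=s["dose"], interval=s["tau"])
        trough_vals[i] = conc_steady_state(ind, reg, s["tau"])
    if cfg.n_sparse:
        intercept, slope = (
            (cfg.ae_intercept, cfg.ae_slope) if cfg.ae_intercept is not None
            else default_ae_link(cfg, trough_vals)
        )

    def base_cols(sid, s, study):
        return dict(ID=sid, WT=s["wt"], AGE=s["age"], SEX=s["sex"], GFR=s["gfr"],
                    EIASM=s["eiasm"], STUDY=study, **s["asm"])

    sid = 0
    for i, s in enumerate(sparse):
        sid += 1
        ind = _true_individual(cfg, s["wt"], s["eta_cl"], s["eta_v"],
                               {**s["asm"], "EIASM": s["eiasm"]})
        reg = Regimen(dose_amount=s["dose"], interval=s["tau"])
        common = base_cols(sid, s, study=1)
        rows.append(dict(common, TIME=0.0, AMT=s["dose"], DV=np.nan, EVID=1,
                         MDV=1, SS=1, II=s["tau"]))
        pred = conc_steady_state(ind, reg, s["t_obs"])
        dv = pred * (1.0 + cfg.truth.sigma_prop * s["eps"][0])
        if cfg.truth.sigma_add > 0:
            dv += cfg.truth.sigma_add * s["rng"].standard_normal()
        dv = max(dv, 0.0)
        rows.append(dict(common, TIME=s["t_obs"], AMT=np.nan, DV=dv, EVID=0,
                         MDV=0, SS=0, II=0.0))
        etas.append((sid, s["eta_cl"], s["eta_v"]))
        troughs.append((sid, trough_vals[i]))
        p = expit(intercept + slope * trough_vals[i])
        drae = int(s["u_drae"] < p)
        dizzy = int(drae and s["u_dizzy"] < cfg.dizziness_given_drae)
        labels.append((sid, drae, dizzy))

    from .model import conc_single_dose  # local to keep module top uncluttered

    for i in range(cfg.n_rich):
        s = _draw_subject(cfg, cfg.n_sparse + i, rich=True)
        sid += 1
        ind = _true_individual(cfg, s["wt"], s["eta_cl"], s["eta_v"], {})
        common = base_cols(sid, s, study=2)
        rows.append(dict(common, TIME=0.0, AMT=s["dose"], DV=np.nan, EVID=1,
                         MDV=1, SS=0, II=0.0))
        for t, e in zip(s["times"], s["eps"]):
            pred = conc_single_dose(ind, s["dose"], t)
            dv = pred * (1.0 + cfg.truth.sigma_prop * e)
            if cfg.truth.sigma_add > 0:
                dv += cfg.truth.sigma_add * s["rng"].standard_normal()
            dv = max(dv, 0.0)
            rows.append(dict(common, TIME=t, AMT=np.nan, DV=dv, EVID=0,
                             MDV=0, SS=0, II=0.0))
        etas.append((sid, s["eta_cl"], s["eta_v"]))

    df = pd.DataFrame(rows)
    extra = [c for c in df.columns if c not in CORE_COLUMNS]
    df = df[CORE_COLUMNS + extra]
    return SyntheticCohort(
        dataset=PKDataset(df),
        true_etas=pd.DataFrame(etas, columns=["ID", "ETA_CL", "ETA_V"]),
        ae_labels=pd.DataFrame(labels, columns=["ID", "DRAE", "DIZZINESS"]),
        true_troughs=pd.DataFrame(troughs, columns=["ID", "TROUGH"]),
        config=cfg,
    )


__all__ = [
    "DEFAULT_ASM_PREVALENCE",
    "CohortConfig",
    "SyntheticCohort",
    "default_ae_link",
    "generate",
]
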