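"""Non-compartmental IV-bolus pharmacokinetics and Hamilton pooling.

Model-free parameter estimation from a concentration-time profile:
Cmax/Tmax read off the observations, AUC/AUMC by the linear trapezoidal
rule, the terminal elimination rate constant (lambda_z) from the
log-linear terminal phase selected by adjusted R^2, extrapolation to
infinity with the standard tail terms, then

    CL  = Dose / AUC_inf          MRT = AUMC_inf / AUC_inf
    t_half = ln 2 / lambda_z      Vss = CL x MRT

Units follow the mouse-study convention throughout: time in minutes,
concentration in ng/mL, dose in mg/kg, hence AUC in min*ng/mL, CL in
mL/min/kg and Vss in mL/kg.  Hamilton pooling computes per-time-point
plasma volume weights proportional to the trapezoidal time weights, so the
pooled sample's concentration equals AUC_last / (t_last - t_first) by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import ComputationError, ValidationError

__all__ = [
    "DEFAULT_SAMPLING_GRID",
    "ConcentrationTimeProfile",
    "LambdaZFit",
    "NCAResult",
    "PoolingPlan",
    "auc_trapezoid",
    "fit_lambda_z",
    "nca_iv_bolus",
    "hamilton_pool",
    "dose_proportionality",
    "DoseProportionalityReport",
    "summarize_nca",
]

#: Serial blood-sampling grid of the IV mouse study (minutes post-dose).
DEFAULT_SAMPLING_GRID = (2.0, 10.0, 30.0, 60.0, 120.0, 240.0, 420.0)


@dataclass
class ConcentrationTimeProfile:
    """One subject's IV-bolus concentration-time course."""

    subject_id: str
    dose: float  # mg/kg
    times: np.ndarray  # minutes, strictly increasing
    concs: np.ndarray  # ng/mL
    blq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concs = np.asarray(self.concs, dtype=float)
        if self.blq is None:
            self.blq = np.zeros_like(self.times, dtype=bool)
        else:
            self.blq = np.asarray(self.blq, dtype=bool)
        if self.dose <= 0:
            raise ValidationError(f"dose must be > 0, got {self.dose}")
        if self.times.size != self.concs.size or self.times.size != self.blq.size:
            raise ValidationError("times, concs and blq must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(self.concs < 0):
            raise ValidationError("concentrations must be >= 0")


@dataclass(frozen=True)
class LambdaZFit:
    lambda_z: float  # 1/min
    n_points: int
    adj_r2: float
    intercept: float  # ln(conc) at t = 0 of the terminal line


@dataclass(frozen=True)
class NCAResult:
    subject_id: str
    dose: float
    cmax: float
    tmax: float
    auc_last: float
    aumc_last: float
    lambda_z: float
    t_half: float
    auc_inf: float
    aumc_inf: float
    cl: float
    mrt: float
    vss: float
    lambda_z_n_points: int
    lambda_z_adj_r2: float
    c0: float | None = None


def auc_trapezoid(
    times: Sequence[float], concs: Sequence[float]
) -> tuple[float, float]:
    """Linear trapezoidal AUC and AUMC over the observed interval."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.size < 2:
        raise ValidationError("need at least 2 points for a trapezoidal AUC")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")
    auc = float(np.trapezoid(c, t))
    aumc = float(np.trapezoid(t * c, t))
    return auc, aumc


def fit_lambda_z(
    times: Sequence[float], concs: Sequence[float]
) -> LambdaZFit:
    """Terminal log-linear regression with window selection by adjusted R^2.

    Candidate windows are the last k points (k = 3 ... all points after
    Tmax, Tmax itself excluded, zero concentrations dropped); the window
    maximizing adjusted R^2 wins, ties broken toward more points.  A
    positive slope everywhere means the terminal phase is undefined.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    tmax_idx = int(np.argmax(c))
    mask = np.zeros(t.size, dtype=bool)
    mask[tmax_idx + 1 :] = True
    mask &= c > 0
    tt, cc = t[mask], c[mask]
    if tt.size < 3:
        raise ComputationError(
            "terminal phase undefined: fewer than 3 positive post-Tmax points"
        )
    log_c = np.log(cc)
    best: LambdaZFit | None = None
    for k in range(3, tt.size + 1):
        tw, lw = tt[-k:], log_c[-k:]
        slope, intercept = np.polyfit(tw, lw, 1)
        ss_tot = float(np.sum((lw - lw.mean()) ** 2))
        # a window with no decline (zero log-variance) carries no terminal phase
        if slope >= 0 or ss_tot <= 1e-20:
            continue
        predicted = slope * tw + intercept
        ss_res = float(np.sum((lw - predicted) ** 2))
        r2 = 1.0 - ss_res / ss_tot
        adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2)
        if (
            best is None
            or adj > best.adj_r2 + 1e-12
            or (abs(adj - best.adj_r2) <= 1e-12 and k > best.n_points)
        ):
            best = LambdaZFit(
                lambda_z=float(-slope),
                n_points=k,
                adj_r2=float(adj),
                intercept=float(intercept),
            )
    if best is None:
        raise ComputationError(
            "terminal phase undefined: no window with a negative slope"
        )
    return best


def _extrapolate_c0(times: np.ndarray, concs: np.ndarray) -> float:
    """Log-linear back-extrapolation to t = 0 from the first two positive
    observations (IV-bolus convention); falls back to the first
    concentration when the profile does not decline."""
    positive = concs > 0
    idx = np.flatnonzero(positive)
    if idx.size < 2:
        return float(concs[idx[0]]) if idx.size else 0.0
    i1, i2 = idx[0], idx[1]
    c1, c2 = concs[i1], concs[i2]
    if c2 >= c1:
        return float(c1)
    slope = (math.log(c2) - math.log(c1)) / (times[i2] - times[i1])
    return float(math.exp(math.log(c1) - slope * times[i1]))


def nca_iv_bolus(
    profile: ConcentrationTimeProfile,
    extrapolate_t0: bool = True,
) -> NCAResult:
    """Full IV-bolus NCA for one profile.

    BLQ handling: leading BLQ observations are set to zero, trailing BLQ
    observations are dropped.  When ``extrapolate_t0`` is on and sampling
    starts after t = 0, the AUC includes a [0, t1] segment using the
    back-extrapolated C0.
    """
    t = profile.times.copy()
    c = profile.concs.copy()
    blq = profile.blq.copy()
    # trailing BLQ: drop; leading BLQ: zero
    while t.size and blq[-1]:
        t, c, blq = t[:-1], c[:-1], blq[:-1]
    leading = 0
    while leading < t.size and blq[leading]:
        leading += 1
    c[:leading] = 0.0
    if not np.any(c > 0):
        raise ComputationError("profile is entirely BLQ")
    if t.size < 2:
        raise ComputationError("too few quantifiable points for NCA")

    cmax_idx = int(np.argmax(c))
    cmax = float(c[cmax_idx])
    tmax = float(t[cmax_idx])

    c0: float | None = None
    t_auc, c_auc = t, c
    if extrapolate_t0 and t[0] > 0:
        c0 = _extrapolate_c0(t, c)
        t_auc = np.concatenate([[0.0], t])
        c_auc = np.concatenate([[c0], c])
    auc_last, aumc_last = auc_trapezoid(t_auc, c_auc)

    lz = fit_lambda_z(t, c)
    last_pos = int(np.flatnonzero(c > 0)[-1])
    c_last, t_last = float(c[last_pos]), float(t[last_pos])
    auc_inf = auc_last + c_last / lz.lambda_z
    aumc_inf = (
        aumc_last
        + c_last * t_last / lz.lambda_z
        + c_last / lz.lambda_z**2
    )
    dose_ng_per_kg = profile.dose * 1e6  # mg/kg -> ng/kg
    cl = dose_ng_per_kg / auc_inf  # mL/min/kg
    mrt = aumc_inf / auc_inf  # min
    vss = cl * mrt  # mL/kg
    return NCAResult(
        subject_id=profile.subject_id,
        dose=profile.dose,
        cmax=cmax,
        tmax=tmax,
        auc_last=auc_last,
        aumc_last=aumc_last,
        lambda_z=lz.lambda_z,
        t_half=math.log(2.0) / lz.lambda_z,
        auc_inf=auc_inf,
        aumc_inf=aumc_inf,
        cl=cl,
        mrt=mrt,
        vss=vss,
        lambda_z_n_points=lz.n_points,
        lambda_z_adj_r2=lz.adj_r2,
        c0=c0,
    )


@dataclass(frozen=True)
class PoolingPlan:
    """Per-time-point plasma volume fractions (sum to 1)."""

    times: tuple[float, ...]
    weights: tuple[float, ...]

    def pooled_concentration(self, concs: Sequence[float]) -> float:
        c = np.asarray(concs, dtype=float)
        if c.size != len(self.weights):
            raise ValidationError(
                "concentration vector length does not match the pooling plan"
            )
        return float(np.dot(self.weights, c))


def hamilton_pool(times: Sequence[float]) -> PoolingPlan:
    """AUC-representative pooling weights (Hamilton method).

    Each time point contributes plasma volume proportional to its
    trapezoidal time weight (half the span of its neighbouring intervals,
    half-intervals at the ends), normalized to 1, so the pooled
    concentration equals AUC_last / (t_last - t_first) for any profile.
    """
    t = np.asarray(times, dtype=float)
    if t.size < 2:
        raise ValidationError("need at least 2 time points to pool")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")
    raw = np.empty_like(t)
    raw[0] = (t[1] - t[0]) / 2.0
    raw[-1] = (t[-1] - t[-2]) / 2.0
    if t.size > 2:
        raw[1:-1] = (t[2:] - t[:-2]) / 2.0
    weights = raw / raw.sum()
    return PoolingPlan(times=tuple(t), weights=tuple(weights))


@dataclass(frozen=True)
class DoseProportionalityReport:
    doses: tuple[float, ...]
    auc_ratios: tuple[float, ...]  # dose-normalized, consecutive pairs
    cmax_ratios: tuple[float, ...] | None
    supra_flags: tuple[bool, ...]
    power_exponent: float
    threshold: float

    @property
    def any_supra(self) -> bool:
        return any(self.supra_flags)


def dose_proportionality(
    doses: Sequence[float],
    aucs: Sequence[float],
    cmaxs: Sequence[float] | None = None,
    threshold: float = 1.25,
) -> DoseProportionalityReport:
    """Dose-normalized exposure ratios and the power-model exponent.

    For consecutive dose pairs the ratio (AUC_hi/d_hi)/(AUC_lo/d_lo) is
    reported; a ratio above ``threshold`` flags supra-proportionality.  The
    exponent is the OLS slope of ln(AUC) on ln(dose) (1 under exact
    proportionality).
    """
    d = np.asarray(doses, dtype=float)
    a = np.asarray(aucs, dtype=float)
    if d.size < 2:
        raise ValidationError("need at least 2 dose levels")
    if d.size != a.size:
        raise ValidationError("doses and AUCs must have equal length")
    order = np.argsort(d)
    d, a = d[order], a[order]
    norm = a / d
    auc_ratios = tuple(float(norm[i + 1] / norm[i]) for i in range(d.size - 1))
    cmax_ratios = None
    if cmaxs is not None:
        cm = np.asarray(cmaxs, dtype=float)[order]
        cm_norm = cm / d
        cmax_ratios = tuple(
            float(cm_norm[i + 1] / cm_norm[i]) for i in range(d.size - 1)
        )
    supra = tuple(r > threshold for r in auc_ratios)
    exponent = float(np.polyfit(np.log(d), np.log(a), 1)[0])
    return DoseProportionalityReport(
        doses=tuple(d),
        auc_ratios=auc_ratios,
        cmax_ratios=cmax_ratios,
        supra_flags=supra,
        power_exponent=exponent,
        threshold=threshold,
    )


def summarize_nca(results: Sequence[NCAResult]) -> pd.DataFrame:
    """Mean +/- SD of the headline PK parameters per dose group."""
    frame = pd.DataFrame(
        {
            "dose": [r.dose for r in results],
            "t_half": [r.t_half for r in results],
            "cmax": [r.cmax for r in results],
            "auc_last": [r.auc_last for r in results],
            "cl": [r.cl for r in results],
            "vss": [r.vss for r in results],
        }
    )
    grouped = frame.groupby("dose")
    summary = pd.concat(
        [
            grouped.mean().add_suffix("_mean"),
            grouped.std(ddof=1).add_suffix("_sd"),
            grouped.size().rename("n"),
        ],
        axis=1,
    ).reset_index()
    order = ["dose", "n"] + [
        f"{p}_{s}"
        for p in ("t_half", "cmax", "auc_last", "cl", "vss")
        for s in ("mean", "sd")
    ]
    return summary[order]
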