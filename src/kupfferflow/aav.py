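"""Statistical models of anterior angular velocity (AAV) across somite stages.

The anterior angular velocity of luminal flow in the zebrafish left-right
organizer (LRO / Kupffer's vesicle) rises over somite stages 3-8 as cilia
become motile, collapses to near zero when the vesicle fluid is extracted,
and recovers over the following stages.  Two population models describe
this:

* a linear mixed model for sham-operated embryos,
  ``AAV(t) = phi1 + phi2 * (t - 5)`` with a random intercept per embryo;
* a sigmoidal recovery model for embryos whose fluid was extracted at 5 ss,
  ``AAV(t) = phi1 * [sigma(0.9 (t - 5 - phi2)) - sigma(-0.9 phi2)]
  + phi3 * sigma(8 (t - 5.5))`` with a random effect on ``phi3`` only,
  where ``sigma`` is the logistic function.  The subtraction anchors the
  curve at (essentially) zero at the intervention stage, giving a smooth
  increase from zero.

Interventions at other stages reuse the 5 ss curve shifted in time; stages
earlier than 6 ss are additionally rescaled by the observed fraction of
motile cilia at each stage, which grows from ~6% at 3 ss to ~76% at 6 ss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "InterventionAAVParams",
    "ShamAAVParams",
    "MotileCiliaFractions",
    "InterventionScenario",
    "intervention_mean",
    "sham_mean",
    "rescale_early",
    "sample_trajectory",
    "sample_trajectories",
    "fit_aav_model",
    "STAGES",
]

log = logging.getLogger(__name__)

#: Somite stages over which the symmetry-breaking signal is integrated.
STAGES = (3, 4, 5, 6, 7, 8)


@dataclass(frozen=True)
class InterventionAAVParams:
    """Fixed effects and shape constants of the post-extraction recovery curve."""

    phi1: float = 0.778
    phi2: float = 0.969
    phi3: float = 0.126
    sd_phi3: float = 0.169
    k_recovery: float = 0.9
    k_late: float = 8.0
    t_ref: float = 5.0
    t_late: float = 5.5

    def __post_init__(self) -> None:
        if self.k_recovery <= 0 or self.k_late <= 0:
            raise ValueError("sigmoid steepness constants must be positive")
        if self.sd_phi3 < 0:
            raise ValueError("sd_phi3 must be non-negative")


@dataclass(frozen=True)
class ShamAAVParams:
    """Fixed effects of the sham (puncture-only) linear AAV model."""

    phi1: float = 0.356
    phi2: float = 0.0362
    sd_phi1: float = 0.0378

    def __post_init__(self) -> None:
        if self.sd_phi1 < 0:
            raise ValueError("sd_phi1 must be non-negative")


@dataclass(frozen=True)
class MotileCiliaFractions:
    """Percentage of motile cilia per somite stage (3-6 ss)."""

    percent: dict[int, float] = field(
        default_factory=lambda: {3: 5.57, 4: 42.9, 5: 62.1, 6: 76.3}
    )

    def __post_init__(self) -> None:
        stages = sorted(self.percent)
        vals = [self.percent[s] for s in stages]
        if any(not (0 < v <= 100) for v in vals):
            raise ValueError("motile fractions must lie in (0, 100]")
        if any(a >= b for a, b in zip(vals, vals[1:])):
            raise ValueError("motile fractions must increase with stage")

    def ratio(self, t: int) -> float:
        """fraction(t) / fraction(6), the Stokes-linearity rescale factor."""
        return self.percent[t] / self.percent[6]


@dataclass(frozen=True)
class InterventionScenario:
    """One experimental condition: fluid extractions at the listed stages.

    An empty ``extraction_stages`` denotes the sham intervention.
    """

    label: str
    extraction_stages: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        st = self.extraction_stages
        if list(st) != sorted(set(st)):
            raise ValueError("extraction stages must be sorted and unique")
        if any(s < 3 or s > 12 for s in st):
            raise ValueError("extraction stages must lie in 3..12")

    @property
    def is_sham(self) -> bool:
        return len(self.extraction_stages) == 0


def intervention_mean(
    t: float,
    params: InterventionAAVParams = InterventionAAVParams(),
    phi3_draw: float | None = None,
) -> float:
    """Mean AAV (rad/s) at stage ``t`` after fluid extraction at ``params.t_ref``.

    ``phi3_draw`` replaces the fixed-effect phi3 with a per-embryo draw.
    Raises for ``t < t_ref``: the curve only describes the recovery.
    """
    if t < params.t_ref:
        raise ValueError(f"recovery curve is defined for t >= {params.t_ref}")
    phi3 = params.phi3 if phi3_draw is None else phi3_draw
    k = params.k_recovery
    recovery = params.phi1 * (
        expit(k * (t - params.t_ref - params.phi2)) - expit(-k * params.phi2)
    )
    late = phi3 * expit(params.k_late * (t - params.t_late))
    return float(recovery + late)


def sham_mean(
    t: float,
    params: ShamAAVParams = ShamAAVParams(),
    phi1_draw: float | None = None,
) -> float:
    """Mean AAV (rad/s) at stage ``t >= 5`` for sham-operated embryos."""
    phi1 = params.phi1 if phi1_draw is None else phi1_draw
    return float(phi1 + params.phi2 * (t - 5.0))


def rescale_early(
    aav6: float,
    fractions: MotileCiliaFractions = MotileCiliaFractions(),
    t: int = 3,
) -> float:
    """AAV at an early stage ``t in {3,4,5}`` from the stage-6 value.

    By linearity of Stokes flow the angular velocity scales with the number
    of motile cilia, so AAV(t) = fraction(t)/fraction(6) * AAV(6).
    """
    if t not in (3, 4, 5):
        raise ValueError("early-stage rescaling applies to stages 3, 4, 5 only")
    return fractions.ratio(t) * aav6


def _recovery_values(
    stages: np.ndarray,
    extraction_stage: int,
    params: InterventionAAVParams,
    phi3_draw: float,
) -> np.ndarray:
    """Recovery curve anchored at ``extraction_stage``: the 5 ss curve shifted."""
    shift = extraction_stage - params.t_ref
    return np.array(
        [
            intervention_mean(t - shift, params, phi3_draw)
            if t >= extraction_stage
            else np.nan
            for t in stages
        ]
    )


def sample_trajectory(
    scenario: InterventionScenario,
    rng: np.random.Generator,
    interv_params: InterventionAAVParams = InterventionAAVParams(),
    sham_params: ShamAAVParams = ShamAAVParams(),
    fractions: MotileCiliaFractions = MotileCiliaFractions(),
) -> np.ndarray:
    """Draw one embryo's AAV(t) for t = 3..8 under ``scenario``.

    Per-embryo variability enters through a normal draw of the sham
    intercept phi1 (SD 0.0378) and, for intervened embryos, of the
    late-recovery amplitude phi3 (SD 0.169).  Stages before the first
    extraction follow the sham model; stages at or after each extraction
    follow the recovery curve re-anchored at that extraction; stages 3-5
    are rescaled by the motile-cilia fractions in either case.  Negative
    draws are not truncated.
    """
    stages = np.array(STAGES, dtype=float)
    phi1 = rng.normal(sham_params.phi1, sham_params.sd_phi1)
    sham6 = sham_mean(6.0, sham_params, phi1)
    # sham values: linear for t >= 6, motile-fraction rescale of AAV(6) below
    aav = np.array(
        [
            fractions.ratio(int(t)) * sham6 if t <= 5 else sham_mean(t, sham_params, phi1)
            for t in stages
        ]
    )
    if scenario.is_sham:
        return aav

    phi3 = rng.normal(interv_params.phi3, interv_params.sd_phi3)
    for ex in scenario.extraction_stages:
        if ex > STAGES[-1]:
            log.info("extraction at %s ss lies outside the 3-8 ss window", ex)
            continue
        rec = _recovery_values(stages, ex, interv_params, phi3)
        mask = stages >= ex
        aav[mask] = rec[mask]
        if ex < 5:
            # shift-then-rescale: early stages scale off the curve's own 6 ss value
            six = rec[stages == 6.0][0]
            early = (stages >= ex) & (stages <= 5)
            aav[early] = [fractions.ratio(int(t)) * six for t in stages[early]]
    return aav


def sample_trajectories(
    scenario: InterventionScenario,
    n: int,
    rng: np.random.Generator,
    **kwargs,
) -> np.ndarray:
    """Draw ``n`` AAV trajectories; shape (n, 6) for stages 3..8."""
    return np.vstack([sample_trajectory(scenario, rng, **kwargs) for _ in range(n)])


# ---------------------------------------------------------------------------
# Nonlinear mixed-effects fitting
# ---------------------------------------------------------------------------


def _intervention_marginal_nll(
    theta: np.ndarray, t: np.ndarray, y: np.ndarray, embryo_idx: np.ndarray,
    base: InterventionAAVParams,
) -> float:
    """Negative marginal log-likelihood of the recovery model.

    The random effect b_i enters linearly (phi3 + b_i multiplies the late
    sigmoid), so integrating it out leaves a Gaussian with a rank-one
    covariance per embryo: y_i ~ N(f(t_i), sigma^2 I + tau^2 z_i z_i^T).
    """
    phi1, phi2, phi3, log_tau, log_sigma = theta
    tau2, sigma2 = np.exp(2 * log_tau), np.exp(2 * log_sigma)
    p = replace(base, phi1=phi1, phi2=phi2, phi3=phi3)
    mean = np.array([intervention_mean(ti, p) for ti in t])
    z = expit(base.k_late * (t - base.t_late))
    nll = 0.0
    for i in np.unique(embryo_idx):
        m = embryo_idx == i
        r, zi = y[m] - mean[m], z[m]
        # Woodbury / matrix determinant lemma on sigma2*I + tau2*zi zi^T
        s = zi @ zi
        denom = sigma2 + tau2 * s
        quad = (r @ r) / sigma2 - tau2 * (zi @ r) ** 2 / (sigma2 * denom)
        logdet = (m.sum() - 1) * np.log(sigma2) + np.log(denom)
        nll += 0.5 * (quad + logdet + m.sum() * np.log(2 * np.pi))
    return nll


def fit_aav_model(
    observations,
    model: str = "intervention",
    n_starts: int = 8,
    seed: int = 0,
    params: InterventionAAVParams = InterventionAAVParams(),
):
    """Fit the sham or intervention AAV model to per-embryo stage observations.

    Parameters
    ----------
    observations
        DataFrame with columns ``embryo_id``, ``stage``, ``aav``.
    model
        ``"sham"`` (linear, random intercept) or ``"intervention"``
        (sigmoidal recovery, random effect on phi3).
    n_starts
        Multistart count for the nonlinear fit.

    Returns
    -------
    dict with keys ``fixed`` (name -> estimate), ``random_sd``,
    ``residual_sd``, ``se`` (name -> standard error), ``loglik``.
    """
    obs = observations
    if obs["embryo_id"].nunique() < 5:
        raise ValueError("need at least 5 embryos to fit the AAV model")
    if obs["stage"].nunique() < 2:
        raise ValueError("need observations at >= 2 stages (unidentifiable)")

    if model == "sham":
        import statsmodels.formula.api as smf

        frame = obs.copy()
        frame["t5"] = frame["stage"] - 5.0
        model = smf.mixedlm("aav ~ 1 + t5", frame, groups=frame["embryo_id"])
        fit = None
        for method in ("bfgs", "lbfgs", "cg", "powell"):
            try:
                fit = model.fit(reml=False, method=method)
                break
            except np.linalg.LinAlgError:
                continue
        if fit is None:
            raise RuntimeError("sham AAV mixed model failed to converge")
        return {
            "fixed": {"phi1": float(fit.params["Intercept"]), "phi2": float(fit.params["t5"])},
            "random_sd": float(np.sqrt(fit.cov_re.iloc[0, 0])),
            "residual_sd": float(np.sqrt(fit.scale)),
            "se": {"phi1": float(fit.bse["Intercept"]), "phi2": float(fit.bse["t5"])},
            "loglik": float(fit.llf),
        }
    if model != "intervention":
        raise ValueError("model must be 'sham' or 'intervention'")

    t = obs["stage"].to_numpy(dtype=float)
    y = obs["aav"].to_numpy(dtype=float)
    _, embryo_idx = np.unique(obs["embryo_id"], return_inverse=True)
    rng = np.random.default_rng(seed)
    x0 = np.array([params.phi1, params.phi2, params.phi3, np.log(0.1), np.log(0.1)])
    best = None
    for k in range(n_starts):
        start = x0 if k == 0 else x0 + rng.normal(0, [0.3, 0.5, 0.1, 0.5, 0.5])
        res = minimize(
            _intervention_marginal_nll, start,
            args=(t, y, embryo_idx, params), method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"AAV model fit failed; best incumbent: {best}")

    # standard errors from a central-difference Hessian of the NLL
    se = _numeric_se(
        lambda th: _intervention_marginal_nll(th, t, y, embryo_idx, params), best.x
    )
    names = ["phi1", "phi2", "phi3"]
    return {
        "fixed": dict(zip(names, map(float, best.x[:3]))),
        "random_sd": float(np.exp(best.x[3])),
        "residual_sd": float(np.exp(best.x[4])),
        "se": dict(zip(names, map(float, se[:3]))),
        "loglik": float(-best.fun),
    }


def _numeric_se(fun, x, h: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * h * h)
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov).copy()
        d[d < 0] = np.nan
        return np.sqrt(d)
    except np.linalg.LinAlgError:
        return np.full(n, np.nan)
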