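"""Linear mixed-effects regression of the LRO angular-velocity field.

Two model specifications describe how track-level angular velocity varies
across the organizer and over developmental time, and how interventions
alter the pattern:

* suction experiment:   AAV ~ 1 + Group*LR + Group*PA + Group*Time
                        + (1 + Group | embryo)
  with groups Sham (reference), NoDefects, Defects;
* injection experiment: same fixed structure with intervention levels
  Sham (reference), DB (buffer dilution), MC (methylcellulose).

Time is somite stage minus a time origin (default 6, the first
post-intervention observation stage).  The random part is an unstructured
covariance over intercept plus the two group dummies (6 covariance
parameters) plus the residual variance, 7 in total.  Inference is Wald;
estimation defaults to REML.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "DESIGNS",
    "MixedModelFit",
    "build_design",
    "fit_mixed_model",
    "report_effects",
]

log = logging.getLogger(__name__)

#: Group level sets per experimental design, reference level first.
DESIGNS = {
    "suction": ("Sham", "NoDefects", "Defects"),
    "injection": ("Sham", "DB", "MC"),
}


@dataclass
class MixedModelFit:
    """Fixed effects with Wald CIs and p-values, plus variance components."""

    fixed: pd.DataFrame  # index: term; columns: estimate, lower, upper, pvalue
    random_sd: dict[str, float]
    residual_sd: float
    n_obs: int
    n_embryos: int
    loglik: float
    converged: bool
    downgraded: bool = False

    def __post_init__(self) -> None:
        bad = (self.fixed["lower"] > self.fixed["estimate"]) | (
            self.fixed["estimate"] > self.fixed["upper"]
        )
        if bad.any():
            raise ValueError("confidence limits must bracket the estimate")


def build_design(
    observations: pd.DataFrame,
    design: str = "suction",
    time_origin: float = 6.0,
) -> pd.DataFrame:
    """Model frame with treatment-coded groups and interaction columns.

    Sham is the reference level; ``time`` is stage minus ``time_origin``.
    With all three groups present the fixed design expands to 12 columns
    (intercept, 2 group dummies, lr, pa, time, and 6 interactions).
    """
    levels = DESIGNS[design]
    obs = observations.copy()
    unknown = set(obs["group"].unique()) - set(levels)
    if unknown:
        raise ValueError(f"unknown group levels {sorted(unknown)}; expected {levels}")
    obs["group"] = pd.Categorical(obs["group"], categories=levels)
    obs["time"] = obs["stage"].astype(float) - time_origin

    frame = pd.DataFrame(
        {
            "aav": obs["aav"].astype(float),
            "embryo_id": obs["embryo_id"],
            "Intercept": 1.0,
            "lr": obs["lr"].astype(float),
            "pa": obs["pa"].astype(float),
            "time": obs["time"],
        }
    )
    for lev in levels[1:]:
        d = (obs["group"] == lev).astype(float).to_numpy()
        frame[f"group[{lev}]"] = d
        frame[f"group[{lev}]:lr"] = d * frame["lr"].to_numpy()
        frame[f"group[{lev}]:pa"] = d * frame["pa"].to_numpy()
        frame[f"group[{lev}]:time"] = d * frame["time"].to_numpy()
    frame.attrs["design"] = design
    frame.attrs["levels"] = levels
    return frame


#: Fixed-effect column order mirroring the study's coefficient tables.
def _term_order(levels) -> list[str]:
    g1, g2 = levels[1], levels[2]
    return [
        "Intercept",
        f"group[{g1}]", f"group[{g2}]",
        "lr", "pa", "time",
        f"group[{g1}]:lr", f"group[{g2}]:lr",
        f"group[{g1}]:pa", f"group[{g2}]:pa",
        f"group[{g1}]:time", f"group[{g2}]:time",
    ]


def fit_mixed_model(
    frame: pd.DataFrame,
    reml: bool = True,
    alpha: float = 0.05,
    max_retries: int = 3,
) -> MixedModelFit:
    """Fit the mixed model on a frame from :func:`build_design`.

    Random effects: intercept plus the group dummies per embryo with
    unstructured covariance.  A singular random-effects fit is retried
    from perturbed starts and finally downgraded to a random intercept
    (logged).
    """
    levels = frame.attrs.get("levels")
    if levels is None:
        raise ValueError("frame must come from build_design")
    if frame["embryo_id"].nunique() < 2:
        raise ValueError("need at least 2 embryos")

    present = [c for c in _term_order(levels) if c in frame.columns]
    exog = frame[present]
    re_cols = ["Intercept"] + [f"group[{lev}]" for lev in levels[1:] if f"group[{lev}]" in frame.columns]
    exog_re = frame[re_cols]

    def _try(exog_re_, method="lbfgs"):
        model = sm.MixedLM(
            frame["aav"], exog, groups=frame["embryo_id"], exog_re=exog_re_
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(reml=reml, method=method, maxiter=500)

    # bfgs first: on degenerate (zero-variance) data lbfgs can report
    # convergence at a spurious point while bfgs finds the optimum
    methods = ["bfgs", "lbfgs", "cg", "powell"]
    result, downgraded, ok = None, False, False
    for method in methods[:max_retries]:
        try:
            result = _try(exog_re, method)
            if result.converged and np.all(np.isfinite(result.bse_fe)):
                ok = True
                break
        except (np.linalg.LinAlgError, ValueError):
            continue
    if not ok:
        log.warning("singular random-effects structure; downgrading to random intercept")
        downgraded = True
        result = None
        for method in methods:
            try:
                result = _try(frame[["Intercept"]], method)
                if result.converged and np.all(np.isfinite(result.bse_fe)):
                    break
            except (np.linalg.LinAlgError, ValueError):
                continue
        if result is None:
            raise RuntimeError("mixed model failed to converge even after downgrade")

    k_fe = len(present)
    params = result.fe_params
    bse = result.bse_fe[:k_fe]
    z = stats.norm.ppf(1 - alpha / 2)
    est = params.to_numpy()[:k_fe]
    fixed = pd.DataFrame(
        {
            "estimate": est,
            "lower": est - z * np.asarray(bse),
            "upper": est + z * np.asarray(bse),
            "pvalue": 2 * stats.norm.sf(np.abs(est / np.asarray(bse))),
        },
        index=present,
    )
    re_sd = {}
    cov_re = np.atleast_2d(np.asarray(result.cov_re))
    re_names = list(result.cov_re.index) if hasattr(result.cov_re, "index") else ["Intercept"]
    for i, name in enumerate(re_names):
        re_sd[name] = float(np.sqrt(max(cov_re[i, i], 0.0)))
    return MixedModelFit(
        fixed=fixed,
        random_sd=re_sd,
        residual_sd=float(np.sqrt(result.scale)),
        n_obs=int(len(frame)),
        n_embryos=int(frame["embryo_id"].nunique()),
        loglik=float(result.llf),
        converged=bool(result.converged),
        downgraded=downgraded,
    )


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def report_effects(fit: MixedModelFit, alpha: float = 0.05) -> pd.DataFrame:
    """Coefficient table in the study's layout with significance stars."""
    table = fit.fixed.copy()
    table["stars"] = [_stars(p) for p in table["pvalue"]]
    table.index.name = "name"
    return table.reset_index()
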