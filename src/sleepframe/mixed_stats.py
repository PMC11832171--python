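"""Linear mixed-effects inference on behavioural parameter tables.

Each parameter is compared between groups with a linear mixed-effects model
fitted separately on day and night data points (one value per larva per
window).  The model has group as the fixed effect and random intercepts for
experiment (clutch), larva nested in experiment, and larval age (dpf, as a
crossed component):

    value ~ group + (1 | experiment/larva) + (1 | dpf)

The group effect is tested with a likelihood-ratio test against the null
model without the fixed effect; both models are fitted by maximum likelihood
(not REML) so the LRT on a fixed effect is valid.  The LRT statistic is
referred to χ² with (number of groups − 1) degrees of freedom.  With more
than two groups, each group is also compared to the reference group with a
Wald test on its fitted coefficient (marginal-means contrast, no
multiplicity adjustment).  No adjustment is applied across the 32 behavioural
parameters either: p-values are reported raw, one per parameter per phase.

Effect sizes are reported as percentage change of the modelled knockout mean
over the per-clutch control mean: ef% = 100·(−1 + ko/con), averaged across
clutches.  Drug effects on a mutant background are classified per parameter
from two significance calls (mutant vs control, drug-treated mutant vs
control) into rescue / missed rescue / side effect / no effect.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05

RESCUE = "rescue"
MISSED_RESCUE = "missed rescue"
SIDE_EFFECT = "side effect"
NO_EFFECT = "no effect"
INDETERMINATE = "indeterminate"


@dataclass
class LmeResult:
    parameter: str
    phase: str  # "day" or "night"
    reference_group: str
    slopes: dict[str, float]  # non-reference group -> fixed-effect slope
    slope_ses: dict[str, float]
    lrt_stat: float
    lrt_df: int
    p_value: float
    contrasts: dict[str, float] = field(default_factory=dict)  # group -> Wald p
    converged: bool = True
    singular: bool = False
    method: str = "ML"
    n_per_group: dict[str, int] = field(default_factory=dict)

    @property
    def slope(self) -> float:
        """The single slope, for the common two-group design."""
        if len(self.slopes) != 1:
            raise ValueError("multiple non-reference groups; use .slopes")
        return next(iter(self.slopes.values()))

    @property
    def slope_se(self) -> float:
        if len(self.slope_ses) != 1:
            raise ValueError("multiple non-reference groups; use .slope_ses")
        return next(iter(self.slope_ses.values()))


def _prepare(params: pd.DataFrame, parameter: str, phase: str) -> pd.DataFrame:
    is_day = phase == "day"
    sub = params[(params["parameter"] == parameter) & (params["is_day"] == is_day)]
    sub = sub.dropna(subset=["value"]).copy()
    if sub.empty:
        raise ValueError(f"no data for {parameter} ({phase})")
    sub["larva"] = sub["experiment"].astype(str) + ":" + sub["well"].astype(str)
    return sub


def _fit_lme(data: pd.DataFrame, formula: str, vc: dict[str, str],
             reml: bool = False):
    """Fit one mixed model, taking the best log-likelihood over optimizers.

    Gradient methods occasionally stall short of the optimum when variance
    components sit on the boundary; a derivative-free pass catches those, and
    maximising over both keeps the LRT's two fits comparable.
    """
    model = sm.MixedLM.from_formula(
        formula,
        data=data,
        groups=np.ones(len(data)),
        re_formula="0",
        vc_formula=vc,
    )
    best = None
    any_converged = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for method in ("lbfgs", "powell"):
            try:
                fit = model.fit(reml=reml, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            any_converged = any_converged or bool(fit.converged)
            if np.isfinite(fit.llf) and (best is None or fit.llf > best.llf):
                best = fit
    if best is None:
        raise np.linalg.LinAlgError("all optimizers failed")
    msgs = " ".join(str(w.message) for w in caught)
    singular = "singular" in msgs.lower() or "boundary" in msgs.lower()
    return best, any_converged, singular


def fit_parameter_lme(
    params: pd.DataFrame,
    parameter: str,
    phase: str,
    reference_group: str,
    reml_slopes: bool = False,
) -> LmeResult:
    """Fit the group model for one parameter and phase and run the LRT.

    ``params`` is the long parameter table (columns experiment, well, group,
    window, is_day, dpf, parameter, value).  Day and night are fitted
    separately; pass ``phase`` as "day" or "night".
    """
    data = _prepare(params, parameter, phase)
    groups = [g for g in data["group"].unique()]
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not in data")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    vc: dict[str, str] = {"larva": "0 + C(larva)"}
    if data["experiment"].nunique() > 1:
        vc["experiment"] = "0 + C(experiment)"
    else:
        warnings.warn(
            "single clutch: experiment variance component dropped", stacklevel=2
        )
    if data["dpf"].nunique() > 1:
        vc["dpf"] = "0 + C(dpf)"
    fixed = f"value ~ C(group, Treatment('{reference_group}'))"
    try:
        full, conv_full, sing_full = _fit_lme(data, fixed, vc)
        null, conv_null, sing_null = _fit_lme(data, "value ~ 1", vc)
    except np.linalg.LinAlgError as exc:
        logger.warning("LME fit failed for %s (%s): %s", parameter, phase, exc)
        return LmeResult(
            parameter, phase, reference_group, {}, {}, float("nan"), len(groups) - 1,
            float("nan"), converged=False,
        )
    converged = conv_full and conv_null
    lrt = max(0.0, 2.0 * (full.llf - null.llf))
    df = len(groups) - 1
    p = float(stats.chi2.sf(lrt, df)) if converged else float("nan")

    slopes, ses, contrasts = {}, {}, {}
    slope_fit = full
    if reml_slopes:
        slope_fit, _, _ = _fit_lme(data, fixed, vc, reml=True)
    prefix = f"C(group, Treatment('{reference_group}'))[T."
    for name, coef in slope_fit.fe_params.items():
        if name.startswith(prefix):
            grp = name[len(prefix) : -1]
            slopes[grp] = float(coef)
            ses[grp] = float(slope_fit.bse_fe[name])
            z = coef / slope_fit.bse_fe[name]
            contrasts[grp] = float(2 * stats.norm.sf(abs(z)))
    return LmeResult(
        parameter=parameter,
        phase=phase,
        reference_group=reference_group,
        slopes=slopes,
        slope_ses=ses,
        lrt_stat=float(lrt),
        lrt_df=df,
        p_value=p,
        contrasts=contrasts,
        converged=converged,
        singular=sing_full or sing_null,
        method="REML" if reml_slopes else "ML",
        n_per_group=data.groupby("group")["larva"].nunique().to_dict(),
    )


def group_contrasts(fit: LmeResult) -> dict[str, float]:
    """Pairwise Wald p-values of each non-reference group vs the reference.

    For a two-group design this equals the Wald p of the single slope; no
    multiplicity adjustment is applied.
    """
    if not fit.contrasts:
        raise ValueError("model has no fitted contrasts (unfitted or failed)")
    return dict(fit.contrasts)


def lme_report(
    params: pd.DataFrame,
    reference_group: str,
    parameters: list[str] | None = None,
) -> pd.DataFrame:
    """LRT statistics for every (parameter, phase) present in a table."""
    rows = []
    todo = parameters or list(params["parameter"].unique())
    for parameter in todo:
        for phase in ("day", "night"):
            is_day = phase == "day"
            sub = params[
                (params["parameter"] == parameter) & (params["is_day"] == is_day)
            ]
            if sub["value"].dropna().empty:
                continue
            res = fit_parameter_lme(params, parameter, phase, reference_group)
            for grp in res.slopes:
                rows.append(
                    {
                        "parameter": parameter,
                        "phase": phase,
                        "group": grp,
                        "reference": reference_group,
                        "slope": res.slopes[grp],
                        "slope_se": res.slope_ses[grp],
                        "lrt_stat": res.lrt_stat,
                        "p_value": res.p_value,
                        "contrast_p": res.contrasts.get(grp, float("nan")),
                        "converged": res.converged,
                        "n_reference": res.n_per_group.get(reference_group, 0),
                        "n_group": res.n_per_group.get(grp, 0),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Effect sizes
# ---------------------------------------------------------------------------


@dataclass
class EffectSizeReport:
    parameter: str
    per_clutch: pd.DataFrame  # columns: clutch, con, ko, ef_pct
    ef_pct: float  # averaged across clutches


def percent_effect(con_means: dict[str, float], slope: float, parameter: str = "") -> EffectSizeReport:
    """Percentage effect size per clutch: ef% = 100·(−1 + ko/con), ko = con + slope."""
    rows = []
    for clutch, con in con_means.items():
        if con == 0:
            raise ZeroDivisionError(f"zero control mean for clutch {clutch!r}")
        ko = con + slope
        rows.append({"clutch": clutch, "con": con, "ko": ko,
                     "ef_pct": 100.0 * (-1.0 + ko / con)})
    per_clutch = pd.DataFrame(rows)
    return EffectSizeReport(parameter, per_clutch, float(per_clutch["ef_pct"].mean()))


# ---------------------------------------------------------------------------
# Drug-effect classification
# ---------------------------------------------------------------------------


def classify_drug_effect(
    p_ko: float, p_drug: float, alpha: float = DEFAULT_ALPHA
) -> str:
    """Four-way call for one parameter from the knockout and drug p-values.

    The knockout p-value compares untreated mutants with controls; the drug
    p-value compares drug-treated mutants with controls.  A parameter that
    was altered in the mutant and is no longer distinguishable from controls
    under drug is a rescue.
    """
    if p_ko is None or p_drug is None or np.isnan(p_ko) or np.isnan(p_drug):
        return INDETERMINATE
    ko_sig = p_ko < alpha
    drug_sig = p_drug < alpha
    if ko_sig and not drug_sig:
        return RESCUE
    if ko_sig and drug_sig:
        return MISSED_RESCUE
    if not ko_sig and drug_sig:
        return SIDE_EFFECT
    return NO_EFFECT
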