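"""Two-level mixed models for regulation effectiveness.

Post-regulation affect is modelled on repeated regulation instances
(level 1) nested within persons (level 2).  Predictors follow the
standard intensive-longitudinal decomposition: each time-varying
predictor (pre-regulation affect, the instance-level top-tactic flags)
is split into a between-person component (the person mean) and a
within-person component (the occasion deviation from that mean).  Age
enters as dummy codes with the middle-aged group as reference; burst is
centered to the first burst.

The model sequence:

* unconditional (random-intercept-only) model, yielding the ICC;
* Model 1: burst + age + pre-affect (within and between);
* Model 2: + top-tactic use overall and by category, within and between
  (the negativity-upregulating flags are built but left out of the
  default formulas because top-tactic NEG_UP use is rare and skewed);
* Model 3: + age x within-person top-tactic interactions;
* Final: Model 2 plus only the significant interactions, plus random
  slopes retained by likelihood-ratio test at p < .10.

Reported fits use REML; likelihood-ratio comparisons of fixed-effect
blocks are refit with ML, as required for nested fixed-effect tests.
Marginal and conditional R^2 follow the Nakagawa variance-partition
formulas.  A heterogeneity check compares the homogeneous unconditional
model against one with age-group-specific residual variances (fit by
direct ML on the compound-symmetric per-person likelihood, since the
standard random-effects fitters assume a single residual variance).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.formula.api as smf

from .codebook import DEFAULT_AGE_GROUPS, age_group_of

log = logging.getLogger(__name__)

#: Within/between predictor pairs built by build_model_frame.
WB_PREDICTORS = ("pre", "any", "pos_up", "neg_down", "acceptance", "neg_up")

MODEL1_TERMS = ("burst_c", "age_ya", "age_oa", "pre_b", "pre_w")
MODEL2_TERMS = MODEL1_TERMS + (
    "any_b",
    "pos_up_b",
    "neg_down_b",
    "acceptance_b",
    "any_w",
    "pos_up_w",
    "neg_down_w",
    "acceptance_w",
)
INTERACTION_TERMS = tuple(
    f"{age}:{x}"
    for age in ("age_ya", "age_oa")
    for x in ("any_w", "pos_up_w", "neg_down_w", "acceptance_w")
)
MODEL3_TERMS = MODEL2_TERMS + INTERACTION_TERMS


#: Default mapping from short predictor names to instance-table columns.
DEFAULT_FLAG_MAP = {
    "pre": "pre_affect",
    "any": "top_any",
    "pos_up": "top_pos_up",
    "neg_down": "top_neg_down",
    "acceptance": "top_acceptance",
    "neg_up": "top_neg_up",
}


def build_model_frame(
    codings: pd.DataFrame,
    participants: pd.DataFrame,
    age_groups=DEFAULT_AGE_GROUPS,
    flag_map: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """One row per coded regulation instance, ready for model formulas.

    Columns: post_affect, burst_c (burst - 1), age_ya / age_oa dummies
    (middle-aged reference), and for pre-affect and each top-tactic flag
    a ``_b`` person-mean column and a ``_w`` occasion-deviation column.
    Within components are mean-zero per participant by construction.
    ``flag_map`` (short name -> column) may redirect the predictors to
    other instance-level indicators, e.g. raw category-use flags.
    """
    flag_map = dict(DEFAULT_FLAG_MAP if flag_map is None else flag_map)
    needed = ["participant_id", "burst", "post_affect"] + list(flag_map.values())
    missing = [c for c in needed if c not in codings.columns]
    if missing:
        raise ValueError(f"codings table missing columns {missing}")
    frame = codings[needed].dropna(subset=needed[2:]).copy()
    frame["post_affect"] = frame["post_affect"].astype(float)
    frame["burst_c"] = frame["burst"].astype(int) - 1

    ages = participants.set_index("participant_id")["age_years"]
    group = frame["participant_id"].map(lambda p: age_group_of(int(ages[p]), age_groups))
    frame["age_group"] = group
    frame["age_ya"] = (group == "YA").astype(int)
    frame["age_oa"] = (group == "OA").astype(int)

    singles = frame.groupby("participant_id").size()
    n_single = int((singles == 1).sum())
    if n_single:
        log.warning(
            "%d participant(s) contribute a single instance; their within-person "
            "deviations are 0",
            n_single,
        )
    for short, col in flag_map.items():
        vals = frame[col].astype(float)
        pmean = vals.groupby(frame["participant_id"]).transform("mean")
        frame[f"{short}_b"] = pmean
        frame[f"{short}_w"] = vals - pmean
    return frame.reset_index(drop=True)


@dataclass
class MixedModelFit:
    """A fitted two-level model and its summary quantities."""

    name: str
    formula: str
    re_formula: str
    reml: bool
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    cov_re: pd.DataFrame
    scale: float
    llf: float
    aic: float
    bic: float
    n_obs: int
    n_groups: int
    icc: float
    r2_marginal: float
    r2_conditional: float
    converged: bool
    singular: bool = False

    def fixed_effects_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.params, "se": self.bse, "p": self.pvalues}
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "formula": self.formula,
            "re_formula": self.re_formula,
            "reml": self.reml,
            "fixed_effects": {
                k: {
                    "estimate": float(self.params[k]),
                    "se": float(self.bse[k]),
                    "p": float(self.pvalues[k]),
                }
                for k in self.params.index
            },
            "variance_components": {
                "residual": float(self.scale),
                **{
                    f"re_{r}": float(self.cov_re.loc[r, r])
                    for r in self.cov_re.index
                },
            },
            "logLik": float(self.llf),
            "AIC": float(self.aic),
            "BIC": float(self.bic),
            "ICC": float(self.icc),
            "R2_marginal": float(self.r2_marginal),
            "R2_conditional": float(self.r2_conditional),
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "converged": self.converged,
        }


def _random_effect_variance(result) -> float:
    """Average z' G z over observations (reduces to tau00 for intercepts)."""
    model = result.model
    exog_re = model.exog_re
    if exog_re is None:
        return float(result.cov_re.iloc[0, 0])
    G = np.asarray(result.cov_re)
    Z = np.asarray(exog_re)
    return float(np.mean(np.einsum("ij,jk,ik->i", Z, G, Z)))


def fit_mixed(
    frame: pd.DataFrame,
    terms: Sequence[str],
    re_formula: str = "1",
    reml: bool = True,
    name: str = "model",
) -> MixedModelFit:
    """Fit post_affect on the given fixed-effect terms with random effects.

    p values use the normal (Wald) approximation.  A near-zero random
    effect variance marks the fit singular; it is reported, not an error.
    """
    rhs = " + ".join(terms) if terms else "1"
    formula = f"post_affect ~ {rhs}"
    model = smf.mixedlm(
        formula, frame, groups=frame["participant_id"], re_formula=re_formula
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=reml)
        if not result.converged:
            result = model.fit(reml=reml, method="powell")
    tau00 = float(result.cov_re.iloc[0, 0])
    sigma2 = float(result.scale)
    icc = tau00 / (tau00 + sigma2) if tau00 + sigma2 > 0 else float("nan")
    singular = tau00 < 1e-8
    if singular:
        log.warning("%s: intercept variance ~0 (singular fit); ICC reported with caveat", name)

    fe_names = [n for n in result.fe_params.index]
    X = np.asarray(model.exog)
    var_f = float(np.var(X @ np.asarray(result.fe_params), ddof=0))
    var_re = _random_effect_variance(result)
    denom = var_f + var_re + sigma2
    r2m = var_f / denom if denom > 0 else float("nan")
    r2c = (var_f + var_re) / denom if denom > 0 else float("nan")

    bse = result.bse_fe
    z = result.fe_params / bse
    pvals = pd.Series(2 * stats.norm.sf(np.abs(z)), index=fe_names)
    # AIC/BIC from the fitted criterion's llf; parameter count = fixed
    # effects + covariance parameters + residual variance.
    k = len(fe_names) + len(result.cov_re) * (len(result.cov_re) + 1) // 2 + 1
    n = model.nobs
    aic = -2 * result.llf + 2 * k
    bic = -2 * result.llf + k * np.log(n)
    return MixedModelFit(
        name=name,
        formula=formula,
        re_formula=re_formula,
        reml=reml,
        params=result.fe_params,
        bse=bse,
        pvalues=pvals,
        cov_re=result.cov_re,
        scale=sigma2,
        llf=float(result.llf),
        aic=float(aic),
        bic=float(bic),
        n_obs=int(n),
        n_groups=int(model.n_groups),
        icc=icc,
        r2_marginal=r2m,
        r2_conditional=r2c,
        converged=bool(result.converged),
        singular=singular,
    )


def fit_unconditional(frame: pd.DataFrame, reml: bool = True) -> MixedModelFit:
    """Random-intercept-only model of post_affect; its ICC is the share of
    variance at the person level."""
    if frame["participant_id"].nunique() < 2:
        raise ValueError("unconditional model needs at least two participants")
    return fit_mixed(frame, (), re_formula="1", reml=reml, name="unconditional")


def lr_test(fit_small: MixedModelFit, fit_big: MixedModelFit, df: int) -> dict:
    """Likelihood-ratio test between two nested fits (same criterion)."""
    if fit_small.reml != fit_big.reml:
        raise ValueError("LRT requires fits under the same criterion")
    lr = 2 * (fit_big.llf - fit_small.llf)
    lr = max(lr, 0.0)
    p = float(stats.chi2.sf(lr, df)) if df > 0 else float("nan")
    return {"lr": float(lr), "df": df, "p": p}


def forward_select(
    frame: pd.DataFrame,
    blocks: Sequence[tuple[str, Sequence[str]]],
    re_formula: str = "1",
) -> tuple[list[dict], MixedModelFit]:
    """Add predictor blocks in order, comparing nested ML fits.

    Each block is (label, terms).  Per step the trace records AIC, BIC and
    the likelihood-ratio test against the previous model, and whether the
    block improved fit (LRT p < .05).  Returns the trace and the final
    (all-blocks) ML fit; with an empty block list the baseline is
    returned unchanged.
    """
    current_terms: list[str] = []
    current = fit_mixed(frame, current_terms, re_formula, reml=False, name="baseline")
    trace: list[dict] = [
        {"step": "baseline", "terms_added": [], "aic": current.aic, "bic": current.bic}
    ]
    for label, terms in blocks:
        terms = list(terms)
        if not set(terms) - set(current_terms):
            raise ValueError(f"block {label!r} adds no new terms (non-nested comparison)")
        new_terms = current_terms + [t for t in terms if t not in current_terms]
        candidate = fit_mixed(frame, new_terms, re_formula, reml=False, name=label)
        test = lr_test(current, candidate, df=len(new_terms) - len(current_terms))
        improved = test["p"] < 0.05
        trace.append(
            {
                "step": label,
                "terms_added": terms,
                "aic": candidate.aic,
                "bic": candidate.bic,
                "lrt": test,
                "improves_fit": bool(improved),
            }
        )
        current_terms = new_terms
        current = candidate
    return trace, current


def select_random_slopes(
    frame: pd.DataFrame,
    fixed_terms: Sequence[str],
    candidates: Sequence[str],
    alpha: float = 0.10,
) -> tuple[list[str], list[dict]]:
    """Retain random slopes for within-person predictors by LRT at p < alpha.

    Candidates are tried in order, each tested against the model without
    it (REML fits; the fixed part is identical, so REML LRTs are valid).
    Slopes whose variance estimate collapses to the boundary are treated
    as non-improving.  Duplicate candidates are rejected.
    """
    retained: list[str] = []
    trace: list[dict] = []
    base = fit_mixed(frame, fixed_terms, "1", reml=True, name="slopes_base")
    for cand in candidates:
        if cand in retained:
            raise ValueError(f"duplicate random-slope candidate {cand!r}")
        re_f = "1 + " + " + ".join(retained + [cand])
        try:
            trial = fit_mixed(frame, fixed_terms, re_f, reml=True, name=f"+slope {cand}")
        except Exception as exc:  # non-convergence of a trial slope model
            trace.append({"slope": cand, "kept": False, "error": str(exc)})
            continue
        slope_var = float(trial.cov_re.loc[cand, cand]) if cand in trial.cov_re.index else 0.0
        # adding one slope adds a variance and its covariances with
        # existing random effects
        df = 1 + len(retained) + 1
        test = lr_test(base, trial, df=df)
        boundary = slope_var < 1e-8
        kept = (test["p"] < alpha) and not boundary and trial.converged
        trace.append(
            {"slope": cand, "kept": bool(kept), "slope_var": slope_var, "lrt": test}
        )
        if kept:
            retained.append(cand)
            base = trial
    return retained, trace


@dataclass
class ModelSequence:
    """The four reported fits plus selection metadata."""

    unconditional: MixedModelFit
    model1: MixedModelFit
    model2: MixedModelFit
    model3: MixedModelFit
    final: MixedModelFit
    kept_interactions: list[str]
    kept_slopes: list[str]
    slope_trace: list[dict] = field(default_factory=list)

    def fits(self) -> dict[str, MixedModelFit]:
        return {
            "unconditional": self.unconditional,
            "model1": self.model1,
            "model2": self.model2,
            "model3": self.model3,
            "final": self.final,
        }

    def to_dict(self) -> dict:
        return {
            **{k: v.to_dict() for k, v in self.fits().items()},
            "kept_interactions": self.kept_interactions,
            "kept_slopes": self.kept_slopes,
        }


def fit_model_sequence(
    frame: pd.DataFrame,
    select_slopes: bool = True,
    interaction_alpha: float = 0.05,
) -> ModelSequence:
    """Fit the reported model sequence with REML.

    Model 3's age x within-person interactions are screened at
    ``interaction_alpha`` (Wald, two-sided); only significant ones enter
    the final model, along with random slopes retained at p < .10.
    """
    uncond = fit_unconditional(frame)
    m1 = fit_mixed(frame, MODEL1_TERMS, name="model1")
    m2 = fit_mixed(frame, MODEL2_TERMS, name="model2")
    m3 = fit_mixed(frame, MODEL3_TERMS, name="model3")
    kept = [
        t
        for t in INTERACTION_TERMS
        if t in m3.pvalues.index and m3.pvalues[t] < interaction_alpha
    ]
    final_terms = list(MODEL2_TERMS) + kept
    slopes: list[str] = []
    slope_trace: list[dict] = []
    if select_slopes:
        slopes, slope_trace = select_random_slopes(
            frame, final_terms, ["any_w", "pos_up_w", "neg_down_w", "acceptance_w"]
        )
    re_f = "1" if not slopes else "1 + " + " + ".join(slopes)
    final = fit_mixed(frame, final_terms, re_formula=re_f, name="final")
    return ModelSequence(uncond, m1, m2, m3, final, kept, slopes, slope_trace)


# -- heterogeneous residual variance (direct ML on compound-symmetric blocks) --


def _cs_block_loglik(y: np.ndarray, mu: float, tau: float, sigma2: float) -> float:
    """Log-density of one person's vector under mu + u + e, u~N(0,tau),
    e~N(0,sigma2 I); uses the closed-form determinant/inverse of the
    compound-symmetric covariance."""
    n = len(y)
    r = y - mu
    denom = sigma2 + n * tau
    logdet = (n - 1) * np.log(sigma2) + np.log(denom)
    quad = (r @ r) / sigma2 - (tau / (sigma2 * denom)) * np.sum(r) ** 2
    return -0.5 * (n * np.log(2 * np.pi) + logdet + quad)


def _fit_cs_ml(
    groups: list[np.ndarray], group_labels: list[str], heterogeneous: bool
) -> dict:
    labels = sorted(set(group_labels))
    n_sigma = len(labels) if heterogeneous else 1

    def negll(theta):
        mu = theta[0]
        tau = np.exp(theta[1])
        sigmas = np.exp(theta[2 : 2 + n_sigma])
        total = 0.0
        for y, lab in zip(groups, group_labels):
            s2 = sigmas[labels.index(lab)] if heterogeneous else sigmas[0]
            total += _cs_block_loglik(y, mu, tau, s2)
        return -total

    allvals = np.concatenate(groups)
    v = np.var(allvals)
    x0 = np.array([np.mean(allvals), np.log(v / 2 + 1e-6)] + [np.log(v / 2 + 1e-6)] * n_sigma)
    res = optimize.minimize(negll, x0, method="Nelder-Mead", options={"maxiter": 5000, "xatol": 1e-8, "fatol": 1e-10})
    k = 2 + n_sigma
    return {
        "llf": -float(res.fun),
        "aic": 2 * res.fun + 2 * k,
        "n_params": k,
        "mu": float(res.x[0]),
        "tau00": float(np.exp(res.x[1])),
        "sigma2": {
            lab: float(np.exp(res.x[2 + (labels.index(lab) if heterogeneous else 0)]))
            for lab in labels
        },
        "converged": bool(res.success),
    }


def test_variance_heterogeneity(
    frame: pd.DataFrame, grouping: str = "age_group"
) -> dict:
    """Compare age-group-specific residual variances to the homogeneous
    unconditional model (direct ML, compound-symmetric person blocks).

    Returns both fits, the likelihood-ratio test (df = #groups - 1), the
    AIC difference and a keep/drop recommendation.
    """
    if grouping not in frame.columns:
        raise ValueError(f"frame has no grouping column {grouping!r}")
    labels_by_pid = frame.groupby("participant_id")[grouping].first()
    counts = labels_by_pid.value_counts()
    if len(counts) < 2:
        raise ValueError("variance-heterogeneity test needs at least two groups")
    small = counts[counts < 2]
    if len(small):
        raise ValueError(
            f"group(s) with fewer than 2 participants: {small.index.tolist()}"
        )
    groups, glabels = [], []
    for pid, sub in frame.groupby("participant_id"):
        groups.append(sub["post_affect"].to_numpy(dtype=float))
        glabels.append(labels_by_pid[pid])
    homo = _fit_cs_ml(groups, glabels, heterogeneous=False)
    hetero = _fit_cs_ml(groups, glabels, heterogeneous=True)
    df = hetero["n_params"] - homo["n_params"]
    lr = max(0.0, 2 * (hetero["llf"] - homo["llf"]))
    p = float(stats.chi2.sf(lr, df))
    prefer_hetero = p < 0.05 and hetero["aic"] < homo["aic"]
    return {
        "homogeneous": homo,
        "heterogeneous": hetero,
        "lrt": {"lr": lr, "df": df, "p": p},
        "delta_aic": float(hetero["aic"] - homo["aic"]),
        "recommendation": "heterogeneous" if prefer_hetero else "homogeneous",
    }
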