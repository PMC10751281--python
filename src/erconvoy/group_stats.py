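"""Between-person descriptives and group-difference tests.

Covers three analyses over convoy outputs:

* per-participant summaries of affect and tactic use (the between-person
  descriptive table),
* the age-group x category x circle x burst factorial ANOVA on circle
  category shares, with partial eta squared and its noncentral-F
  confidence interval, and
* Games-Howell pairwise comparisons, which are robust to unequal
  variances and group sizes (Welch-type standard errors, Welch
  Satterthwaite degrees of freedom, studentized-range reference
  distribution).
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .codebook import Codebook, age_group_of, DEFAULT_AGE_GROUPS

log = logging.getLogger(__name__)


def person_level_summaries(
    instances: pd.DataFrame,
    participants: pd.DataFrame,
    codebook: Codebook,
    codings: Optional[pd.DataFrame] = None,
    age_groups=DEFAULT_AGE_GROUPS,
) -> pd.DataFrame:
    """One row per participant: mean affect and tactic-use proportions.

    Proportions are uses / regulation instances over the whole study; with
    multi-tactic instances they may sum above 1 across tactics.  Strategy
    proportions count instances that used any tactic of the strategy.
    When instance-level top-tactic ``codings`` are supplied, person means
    of the 0/1 flags are included (used downstream as between-person
    predictors).  Participants with zero regulation instances are
    excluded and logged.
    """
    tcols = [t for t in codebook.ids if t in instances.columns]
    strategies = sorted({t.strategy for t in codebook})
    rows = []
    with_instances = set()
    for pid, group in instances.groupby("participant_id"):
        n = len(group)
        with_instances.add(pid)
        row: dict = {"participant_id": pid, "n_instances": n}
        row["mean_pre_affect"] = float(group["pre_affect"].mean())
        row["mean_post_affect"] = float(group["post_affect"].mean())
        for t in tcols:
            row[f"p_{t}"] = float(group[t].fillna(0).mean())
        for s in strategies:
            s_cols = [t.id for t in codebook if t.strategy == s and t.id in tcols]
            row[f"p_strategy_{s}"] = float(
                (group[s_cols].fillna(0).sum(axis=1) > 0).mean()
            )
        rows.append(row)
    skipped = set(participants["participant_id"]) - with_instances
    if skipped:
        log.info(
            "%d participant(s) had no regulation instances and were excluded "
            "from person-level summaries",
            len(skipped),
        )
    out = pd.DataFrame(rows)
    if codings is not None and len(out):
        flag_cols = [c for c in codings.columns if c.startswith("top_")]
        means = (
            codings.dropna(subset=flag_cols)
            .groupby("participant_id")[flag_cols]
            .mean()
            .add_prefix("p_")
            .reset_index()
        )
        out = out.merge(means, on="participant_id", how="left")
    ages = participants.set_index("participant_id")["age_years"]
    out["age_group"] = [
        age_group_of(int(ages[pid]), age_groups) for pid in out["participant_id"]
    ]
    return out


def partial_eta_squared_ci(
    f_value: float, df1: float, df2: float, conf: float = 0.95
) -> tuple[float, float]:
    """Noncentral-F confidence interval for partial eta squared.

    Inverts the noncentral-F CDF at (1+conf)/2 and (1-conf)/2 to bound
    the noncentrality parameter, then maps lambda to eta^2_p via
    lambda / (lambda + df1 + df2 + 1).
    """
    alpha = 1.0 - conf

    def _ncp_bound(target: float) -> float:
        # Largest lambda with P(F' <= f | lambda) >= target (0 if none).
        if stats.ncf.cdf(f_value, df1, df2, 0.0) < target:
            return 0.0
        lo, hi = 0.0, max(10.0, 4.0 * f_value * df1)
        while stats.ncf.cdf(f_value, df1, df2, hi) > target:
            hi *= 2
            if hi > 1e7:
                break
        return float(
            optimize.brentq(
                lambda lam: stats.ncf.cdf(f_value, df1, df2, lam) - target, lo, hi
            )
        )

    lam_lo = _ncp_bound(1 - alpha / 2)
    lam_hi = _ncp_bound(alpha / 2)
    to_eta = lambda lam: lam / (lam + df1 + df2 + 1)
    return to_eta(lam_lo), to_eta(lam_hi)


def factorial_anova(
    shares: pd.DataFrame,
    factors: Sequence[str] = ("age_group", "category", "circle", "burst"),
    response: str = "share",
    ss_type: int = 1,
    conf: float = 0.95,
) -> pd.DataFrame:
    """Factorial ANOVA over circle-category shares.

    One observation per participant x burst x circle x category share.
    Returns main effects and all interactions with sums of squares, F,
    degrees of freedom, p, partial eta squared and its noncentral-F CI.
    Sequential (Type I) sums of squares by default, matching a base-R
    ``aov`` workflow; Type III available via ``ss_type=3``.  Cells absent
    from the data are simply not estimated (logged).
    """
    data = shares.copy()
    for f in factors:
        if f not in data.columns:
            raise ValueError(f"shares table missing factor column {f!r}")
        data[f] = data[f].astype(str)
    n_cells = data.groupby(list(factors), observed=True).size()
    expected = int(np.prod([data[f].nunique() for f in factors]))
    if len(n_cells) < expected:
        log.info(
            "design has %d of %d cells populated; effects estimated on the "
            "observed subset",
            len(n_cells),
            expected,
        )
    formula = f"{response} ~ " + " * ".join(f"C({f})" for f in factors)
    fit = smf.ols(formula, data=data).fit()
    table = anova_lm(fit, typ=ss_type)
    resid_row = "Residual"
    ss_err = float(table.loc[resid_row, "sum_sq"])
    df_err = float(table.loc[resid_row, "df"])
    rows = []
    for name, row in table.iterrows():
        if name == resid_row:
            continue
        ss, df1, f_val, p = (
            float(row["sum_sq"]),
            float(row["df"]),
            float(row["F"]),
            float(row["PR(>F)"]),
        )
        # a numerically-zero effect (e.g. constant response) is reported as
        # a true null rather than a 0/0 ratio
        scale = max(float(np.mean(np.square(data[response]))) * len(data), 1e-12)
        if ss / scale < 1e-12 or not np.isfinite(f_val):
            ss, f_val, p = 0.0, 0.0, 1.0
        eta_p = ss / (ss + ss_err) if ss + ss_err > 0 else 0.0
        lo, hi = partial_eta_squared_ci(f_val, df1, df_err, conf) if f_val > 0 else (0.0, 0.0)
        label = (
            name.replace("C(", "").replace(")", "").replace(":", " x ")
        )
        rows.append(
            {
                "effect": label,
                "sum_sq": ss,
                "df1": df1,
                "df2": df_err,
                "F": f_val,
                "p": p,
                "eta_p_sq": eta_p,
                "eta_ci_low": lo,
                "eta_ci_high": hi,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["ss_error"] = ss_err
    out.attrs["df_error"] = df_err
    out.attrs["ss_total"] = float(table["sum_sq"].sum())
    out.attrs["ss_type"] = ss_type
    return out


def games_howell(groups: Mapping[str, Iterable[float]]) -> pd.DataFrame:
    """Games-Howell pairwise comparisons across groups.

    For each pair (a, b): mean difference, Welch-type standard error
    sqrt(va/na + vb/nb), Welch-Satterthwaite df, studentized-range
    statistic q = |diff| / sqrt((va/na + vb/nb)/2) and its adjusted p
    value from the range distribution with k groups.
    """
    arrays = {k: np.asarray(list(v), dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("Games-Howell requires at least two groups")
    for name, a in arrays.items():
        if len(a) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
        if np.var(a, ddof=1) <= 0:
            raise ValueError(f"group {name!r} has zero variance")
    k = len(arrays)
    rows = []
    for a, b in itertools.combinations(arrays, 2):
        xa, xb = arrays[a], arrays[b]
        na, nb = len(xa), len(xb)
        va, vb = np.var(xa, ddof=1), np.var(xb, ddof=1)
        diff = float(np.mean(xa) - np.mean(xb))
        se = float(np.sqrt(va / na + vb / nb))
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
        q = abs(diff) / (se / np.sqrt(2.0))
        p = float(stats.studentized_range.sf(q, k, df))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "mean_diff": diff,
                "se": se,
                "df": float(df),
                "q": float(q),
                "p_adj": min(1.0, p),
            }
        )
    return pd.DataFrame(rows)


def shares_with_age(
    shares: pd.DataFrame, participants: pd.DataFrame, age_groups=DEFAULT_AGE_GROUPS
) -> pd.DataFrame:
    """Attach an age_group column to a circle-category shares table."""
    ages = participants.set_index("participant_id")["age_years"]
    out = shares.copy()
    out["age_group"] = [
        age_group_of(int(ages[pid]), age_groups) for pid in out["participant_id"]
    ]
    return out
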