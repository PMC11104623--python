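"""Permutation statistics for the oculomotor analysis pipeline.

Contains the permutation t-test (sign-flip for paired/one-sample data,
label permutation for two independent groups), a permutation-based mixed
ANOVA for balanced one-between / one-or-two-within designs, Bonferroni-Holm
correction, and a participant-level learning-trend test on per-trial binary
decoding outcomes (per-participant logistic slopes + a group-level sign-flip
test).  Hartigan's dip test lives in :mod:`gazehmi.dip`.

All permutation p-values use the add-one formula
``p = (#{permuted as extreme as observed} + 1) / (n_perm + 1)``, are strictly
positive, and are reproducible given a seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.special import expit
from statsmodels.stats.multitest import multipletests

from .exceptions import DegenerateTestError, UnbalancedDesignError

__all__ = [
    "PermTestResult",
    "AnovaResult",
    "perm_ttest",
    "perm_mixed_anova",
    "holm_correct",
    "learning_trend_test",
    "TrendTestResult",
]


@dataclass(frozen=True)
class PermTestResult:
    """Observed statistic and permutation p-value of one test."""

    statistic: float
    p_value: float
    n_perm: int
    alternative: str
    scheme: str
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "p": self.p_value,
                "n_perm": self.n_perm, "alternative": self.alternative,
                "scheme": self.scheme, "seed": self.seed}


def _t_one_sample(d: np.ndarray) -> float:
    n = d.shape[-1]
    m = d.mean(axis=-1)
    s = d.std(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (s / np.sqrt(n))
    return np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)


def _t_welch(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.shape[-1], b.shape[-1]
    va = a.var(axis=-1, ddof=1)
    vb = b.var(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=-1) - b.mean(axis=-1)) / np.sqrt(va / na + vb / nb)
    return np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)


def _perm_p(t_obs: float, t_perm: np.ndarray, alternative: str) -> float:
    if alternative == "two-sided":
        count = np.count_nonzero(np.abs(t_perm) >= abs(t_obs))
    elif alternative == "greater":
        count = np.count_nonzero(t_perm >= t_obs)
    elif alternative == "less":
        count = np.count_nonzero(t_perm <= t_obs)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (count + 1) / (t_perm.size + 1)


def perm_ttest(a, b=0.0, paired: bool = False,
               alternative: str = "two-sided",
               n_perm: int = 10000, seed=None) -> PermTestResult:
    """Permutation t-test.

    Paired/one-sample data use sign-flip permutation of the (differences
    from ``b``); two independent samples use group-label permutation with a
    Welch t statistic.  ``b`` may be a scalar (one-sample null value) or a
    second sample.
    """
    rng = np.random.default_rng(seed)
    a = np.asarray(a, dtype=float).ravel()
    if np.isscalar(b):
        paired = True
        d = a - float(b)
    elif paired:
        b_arr = np.asarray(b, dtype=float).ravel()
        if b_arr.size != a.size:
            raise ValueError("paired samples must have equal length")
        d = a - b_arr
    else:
        d = None

    if d is not None:
        if d.size < 2:
            raise DegenerateTestError("need at least 2 pairs")
        t_obs = float(_t_one_sample(d))
        signs = rng.integers(0, 2, size=(n_perm, d.size)) * 2 - 1
        t_perm = _t_one_sample(signs * d)
        scheme = "sign-flip"
    else:
        b_arr = np.asarray(b, dtype=float).ravel()
        if a.size < 2 or b_arr.size < 2:
            raise DegenerateTestError("need at least 2 observations per group")
        if a.var(ddof=1) == 0.0 and b_arr.var(ddof=1) == 0.0:
            raise DegenerateTestError("zero variance in both groups")
        pooled = np.concatenate([a, b_arr])
        t_obs = float(_t_welch(a, b_arr))
        mat = np.broadcast_to(pooled, (n_perm, pooled.size)).copy()
        mat = rng.permuted(mat, axis=1)
        t_perm = _t_welch(mat[:, :a.size], mat[:, a.size:])
        scheme = "label-permutation"

    return PermTestResult(statistic=t_obs,
                          p_value=_perm_p(t_obs, t_perm, alternative),
                          n_perm=n_perm, alternative=alternative,
                          scheme=scheme,
                          seed=seed if np.isscalar(seed) else None)


# ---------------------------------------------------------------------------
# mixed ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Per-effect F statistics (parametric df) with permutation p-values."""

    effects: Dict[str, dict]
    between: str
    within: Tuple[str, ...]
    n_perm: int
    scheme: str = ("between effects: participant group labels permuted; "
                   "within effects & interactions: cell labels permuted "
                   "within each participant")
    seed: Optional[int] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.effects).T


def _ss(x) -> float:
    return float(np.sum(np.square(x)))


def _mixed_anova_F(y: np.ndarray, groups: np.ndarray, a: int) -> Dict[str, tuple]:
    """F statistics of a balanced one-between, one-or-two-within design.

    ``y`` has shape (N_subjects, b, c) (c may be 1) and ``groups`` assigns
    each subject to one of ``a`` between-participant groups.  Returns
    ``{effect: (F, df1, df2)}`` with the classical error-term pairing:
    between effect over subjects-within-groups; each within effect and its
    group interaction over the matching within x subject error stratum.
    """
    N, b, c = y.shape
    n_per = N // a
    M = y.mean()
    S = y.mean(axis=(1, 2))                      # subject means
    gidx = [np.flatnonzero(groups == i) for i in range(a)]
    A = np.array([S[ix].mean() for ix in gidx])
    B = y.mean(axis=(0, 2))
    AB = np.stack([y[ix].mean(axis=(0, 2)) for ix in gidx])   # (a, b)
    BS = y.mean(axis=2)                          # (N, b)

    A_of = A[groups]
    AB_of = AB[groups]                           # (N, b)

    out: Dict[str, tuple] = {}
    ss_A = n_per * b * c * _ss(A - M)
    ss_S = b * c * _ss(S - A_of)
    df_S = a * (n_per - 1)
    out["between"] = (ss_A, a - 1, ss_S, df_S)

    ss_B = N * c * _ss(B - M)
    ss_AB = n_per * c * _ss(AB - A[:, None] - B[None, :] + M)
    ss_BS = c * _ss(BS - S[:, None] - AB_of + A_of[:, None])
    df_BS = a * (n_per - 1) * (b - 1)
    out["within1"] = (ss_B, b - 1, ss_BS, df_BS)
    out["between:within1"] = (ss_AB, (a - 1) * (b - 1), ss_BS, df_BS)

    if c > 1:
        C = y.mean(axis=(0, 1))
        AC = np.stack([y[ix].mean(axis=(0, 1)) for ix in gidx])  # (a, c)
        CS = y.mean(axis=1)                      # (N, c)
        BC = y.mean(axis=0)                      # (b, c)
        ABC = np.stack([y[ix].mean(axis=0) for ix in gidx])      # (a, b, c)
        AC_of = AC[groups]
        ABC_of = ABC[groups]

        ss_C = N * b * _ss(C - M)
        ss_AC = n_per * b * _ss(AC - A[:, None] - C[None, :] + M)
        ss_CS = b * _ss(CS - S[:, None] - AC_of + A_of[:, None])
        df_CS = a * (n_per - 1) * (c - 1)
        out["within2"] = (ss_C, c - 1, ss_CS, df_CS)
        out["between:within2"] = (ss_AC, (a - 1) * (c - 1), ss_CS, df_CS)

        ss_BC = N * _ss(BC - B[:, None] - C[None, :] + M)
        ss_ABC = n_per * _ss(
            ABC - AB[:, :, None] - AC[:, None, :] - BC[None, :, :]
            + A[:, None, None] + B[None, :, None] + C[None, None, :] - M)
        resid = (y - BS[:, :, None] - CS[:, None, :] - ABC_of
                 + S[:, None, None] + AB_of[:, :, None] + AC_of[:, None, :]
                 - A_of[:, None, None])
        ss_BCS = _ss(resid)
        df_BCS = a * (n_per - 1) * (b - 1) * (c - 1)
        out["within1:within2"] = (ss_BC, (b - 1) * (c - 1), ss_BCS, df_BCS)
        out["between:within1:within2"] = (
            ss_ABC, (a - 1) * (b - 1) * (c - 1), ss_BCS, df_BCS)

    effects: Dict[str, tuple] = {}
    for name, (ss_eff, df1, ss_err, df2) in out.items():
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2 if df2 > 0 else np.nan
        if ms_err == 0.0:
            F = 0.0 if ms_eff == 0.0 else np.inf
        else:
            F = ms_eff / ms_err
        effects[name] = (float(F), df1, df2)
    return effects


def _pivot_balanced(table: pd.DataFrame, dv: str, subject: str,
                    between: str, within: Sequence[str]):
    """Pivot a tidy cell-means table to (N, b, c) enforcing balance."""
    within = list(within)
    counts = table.groupby([subject] + within, observed=True)[dv].count()
    if (counts != 1).any():
        raise UnbalancedDesignError(
            "each participant must contribute exactly one value per cell")
    wide = table.pivot_table(index=subject, columns=within, values=dv,
                             observed=True)
    if wide.isna().any().any():
        raise UnbalancedDesignError("missing cells in the design")
    gmap = table.groupby(subject, observed=True)[between].nunique()
    if (gmap != 1).any():
        raise UnbalancedDesignError(
            "each participant must belong to exactly one between-group")
    group_of = table.groupby(subject, observed=True)[between].first()
    group_of = group_of.loc[wide.index]
    levels = sorted(group_of.unique())
    a = len(levels)
    groups = group_of.map({g: i for i, g in enumerate(levels)}).to_numpy()
    sizes = np.bincount(groups, minlength=a)
    if len(set(sizes)) != 1:
        raise UnbalancedDesignError(
            f"unequal group sizes {dict(zip(levels, sizes))}; the analysis "
            "requires a balanced design (drop participants to rebalance)")
    if len(within) == 1:
        b = wide.shape[1]
        y = wide.to_numpy(dtype=float).reshape(len(wide), b, 1)
        dims = (b, 1)
    else:
        lv1 = wide.columns.get_level_values(0).unique()
        lv2 = wide.columns.get_level_values(1).unique()
        wide = wide.reindex(columns=pd.MultiIndex.from_product([lv1, lv2]))
        if wide.isna().any().any():
            raise UnbalancedDesignError("missing cells in the design")
        y = wide.to_numpy(dtype=float).reshape(len(wide), len(lv1), len(lv2))
        dims = (len(lv1), len(lv2))
    return y, groups, a, dims, levels


def perm_mixed_anova(table: pd.DataFrame, dv: str = "value",
                     subject: str = "participant", between: str = "order",
                     within: Union[str, Sequence[str]] = ("condition",),
                     n_perm: int = 10000, seed=None) -> AnovaResult:
    """Permutation-based mixed ANOVA on a balanced cell-means table.

    Classical F statistics are computed per effect; permutation nulls permute
    between-group labels across participants (for the between effect) and
    within-condition cell labels within each participant (for within effects
    and all interactions involving a within factor).  Both the parametric F
    (with its df) and the permutation p-value are reported.
    """
    if isinstance(within, str):
        within = (within,)
    within = tuple(within)
    if not 1 <= len(within) <= 2:
        raise ValueError("supported designs have 1 or 2 within factors")
    rng = np.random.default_rng(seed)
    y, groups, a, (b, c), _ = _pivot_balanced(table, dv, subject, between,
                                              within)
    obs = _mixed_anova_F(y, groups, a)

    rename = {"between": between, "within1": within[0],
              "between:within1": f"{between}:{within[0]}"}
    if c > 1:
        rename.update({
            "within2": within[1],
            "between:within2": f"{between}:{within[1]}",
            "within1:within2": f"{within[0]}:{within[1]}",
            "between:within1:within2":
                f"{between}:{within[0]}:{within[1]}",
        })

    counts = {k: 0 for k in obs}
    N = y.shape[0]
    flat = y.reshape(N, b * c)
    for _ in range(n_perm):
        g_perm = rng.permutation(groups)
        f_between = _mixed_anova_F(y, g_perm, a)
        counts["between"] += f_between["between"][0] >= obs["between"][0]
        y_perm = rng.permuted(flat, axis=1).reshape(N, b, c)
        f_within = _mixed_anova_F(y_perm, groups, a)
        for k in obs:
            if k != "between":
                counts[k] += f_within[k][0] >= obs[k][0]

    effects = {}
    for k, (F, df1, df2) in obs.items():
        effects[rename[k]] = {
            "F": F, "df1": df1, "df2": df2,
            "p_perm": (counts[k] + 1) / (n_perm + 1),
        }
    return AnovaResult(effects=effects, between=between, within=within,
                       n_perm=n_perm,
                       seed=seed if np.isscalar(seed) else None)


def holm_correct(p_values, alpha: float = 0.05):
    """Bonferroni-Holm step-down adjusted p-values and reject decisions."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return p_adj, reject


# ---------------------------------------------------------------------------
# learning trend on per-trial decoding outcomes
# ---------------------------------------------------------------------------

@dataclass
class TrendTestResult:
    """Group-level learning-trend result with per-participant slopes."""

    test: PermTestResult
    slopes: pd.DataFrame   # participant, slope, fallback flag

    @property
    def p_value(self) -> float:
        return self.test.p_value


def _logistic_slope(t: np.ndarray, y: np.ndarray, ridge: float = 0.0,
                    max_iter: int = 100, tol: float = 1e-10):
    """Intercept + slope logistic fit by iteratively reweighted least
    squares; optional ridge penalty stabilises separated data."""
    X = np.column_stack([np.ones_like(t), t])
    beta = np.zeros(2)
    for _ in range(max_iter):
        p = expit(X @ beta)
        w = p * (1.0 - p)
        H = X.T @ (X * w[:, None]) + ridge * np.eye(2)
        g = X.T @ (y - p) - ridge * beta
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return beta, False
        beta = beta + step
        if not np.all(np.isfinite(beta)) or abs(beta[1]) > 1e3:
            return beta, False
        if np.max(np.abs(step)) < tol:
            return beta, True
    return beta, False


def learning_trend_test(outcomes: pd.DataFrame, n_perm: int = 10000,
                        seed=None, alternative: str = "greater",
                        ridge_fallback: float = 1.0) -> TrendTestResult:
    """Does the probability of valid decoding increase across trials?

    Fits a per-participant logistic regression of the binary outcome on the
    centred trial number, then tests the participant slopes against zero
    with a one-sample sign-flip permutation test (default alternative:
    mean slope > 0).  Participants with separated or degenerate outcome
    series (e.g. all successes) fall back to a ridge-penalised fit and are
    flagged in the returned slope table.
    """
    required = {"participant", "trial_centered", "outcome"}
    if not required.issubset(outcomes.columns):
        raise ValueError(f"outcome table needs columns {sorted(required)}")
    rows = []
    for pid, grp in outcomes.groupby("participant", observed=True):
        t = grp["trial_centered"].to_numpy(dtype=float)
        y = grp["outcome"].to_numpy(dtype=float)
        beta, ok = _logistic_slope(t, y)
        fallback = not ok
        if fallback:
            beta, _ = _logistic_slope(t, y, ridge=ridge_fallback)
        rows.append({"participant": pid, "slope": float(beta[1]),
                     "fallback": fallback})
    slopes = pd.DataFrame(rows)
    test = perm_ttest(slopes["slope"].to_numpy(), 0.0,
                      alternative=alternative, n_perm=n_perm, seed=seed)
    test = PermTestResult(statistic=test.statistic, p_value=test.p_value,
                          n_perm=test.n_perm, alternative=test.alternative,
                          scheme="per-participant logistic slope, "
                                 "group-level sign-flip", seed=test.seed)
    return TrendTestResult(test=test, slopes=slopes)
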