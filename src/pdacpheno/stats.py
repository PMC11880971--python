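"""Heterogeneity statistics: phenotype co-occurrence, predominant-cluster
shifts across slides, survival stratification, and scorer concordance.

Survival machinery delegates to the standard tools — lifelines for the
product-limit estimator and log-rank test, statsmodels PHReg (Breslow tie
handling) for Cox regression — behind small result containers tailored to
the per-tumor phenotype calls produced upstream.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps
from statsmodels.duration.hazard_regression import PHReg
from statsmodels.stats.multitest import multipletests

from .config import PHENOTYPES

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- co-occurrence

@dataclass
class CooccurrenceResult:
    phenotype_a: str
    phenotype_b: str
    table: np.ndarray          # [[both, a only], [b only, neither]]
    odds_ratio: float          # nan when a margin is degenerate
    p_value: float
    p_adjusted: float = np.nan

    @property
    def odds_ratio_defined(self) -> bool:
        return np.isfinite(self.odds_ratio)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test (point-probability summation) on a 2×2
    table. Returns (odds ratio, p)."""
    odds, p = sps.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(odds), float(p)


def _presence_matrix(compositions: pd.DataFrame) -> pd.DataFrame:
    cols = {f"present_{p}": p for p in PHENOTYPES}
    missing = [c for c in cols if c not in compositions.columns]
    if missing:
        raise ValueError(f"compositions lack presence columns: {missing}")
    return compositions[list(cols)].rename(columns=cols).astype(bool)


def cooccurrence_test(compositions: pd.DataFrame,
                      phenotypes=PHENOTYPES) -> list[CooccurrenceResult]:
    """Pairwise Fisher exact tests of per-tumor phenotype presence.

    For each phenotype pair a 2×2 presence/absence table is built across
    tumors; two-sided p-values come from the exact hypergeometric
    point-probability summation; BH adjustment is applied across pairs.
    A degenerate margin (phenotype present in all or no tumors) leaves the
    odds ratio undefined (nan) with p = 1.
    """
    pres = _presence_matrix(compositions)
    if len(pres) < 2:
        raise ValueError("co-occurrence needs at least 2 tumors")
    results = []
    for a, b in itertools.combinations(phenotypes, 2):
        pa, pb = pres[a].to_numpy(), pres[b].to_numpy()
        tab = np.array([
            [int((pa & pb).sum()), int((pa & ~pb).sum())],
            [int((~pa & pb).sum()), int((~pa & ~pb).sum())],
        ])
        if 0 in tab.sum(axis=0) or 0 in tab.sum(axis=1):
            results.append(CooccurrenceResult(a, b, tab, np.nan, 1.0))
            continue
        odds, p = fisher_exact_2x2(tab)
        results.append(CooccurrenceResult(a, b, tab, odds, p))
    padj = multipletests([r.p_value for r in results], method="fdr_bh")[1]
    for r, q in zip(results, padj):
        r.p_adjusted = float(q)
    return results


def cooccurrence_frame(results: list[CooccurrenceResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "phenotype_a": r.phenotype_a, "phenotype_b": r.phenotype_b,
        "n_both": r.table[0, 0], "n_a_only": r.table[0, 1],
        "n_b_only": r.table[1, 0], "n_neither": r.table[1, 1],
        "odds_ratio": r.odds_ratio, "p_value": r.p_value,
        "p_adjusted": r.p_adjusted,
    } for r in results])


# --------------------------------------------------------------------- shifts

@dataclass(frozen=True)
class Shift:
    tumor_id: str
    from_phenotype: str
    to_phenotype: str


def detect_shifts(per_slide_compositions: pd.DataFrame
                  ) -> tuple[list[Shift], int]:
    """Shifts in predominant phenotype between slides of the same tumor.

    Input: one row per (tumor_id, slide_id) with a `predominant` column.
    Only tumors with ≥ 2 slides enter the denominator; a shift is recorded
    for each consecutive slide pair (slide order sorted by slide_id) whose
    predominant phenotypes differ. Returns (shifts, n_tumors_compared).
    """
    req = {"tumor_id", "slide_id", "predominant"}
    if not req.issubset(per_slide_compositions.columns):
        raise ValueError(f"need columns {sorted(req)}")
    shifts: list[Shift] = []
    n_compared = 0
    for tumor, grp in per_slide_compositions.groupby("tumor_id"):
        grp = grp.sort_values("slide_id")
        if len(grp) < 2:
            continue
        n_compared += 1
        doms = grp["predominant"].tolist()
        for prev, cur in zip(doms, doms[1:]):
            if prev != cur:
                shifts.append(Shift(str(tumor), prev, cur))
    return shifts, n_compared


# ------------------------------------------------------------------- survival

@dataclass
class KMGroup:
    label: str
    n: int
    n_events: int
    curve: pd.DataFrame            # columns: time, survival, at_risk
    median: float                  # nan when never reaching 0.5


@dataclass
class KMLogrankResult:
    groups: dict[str, KMGroup]
    chi_square: float
    p_value: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.chi_square)

    def summary(self) -> str:
        lines = ["Kaplan–Meier / log-rank", "-" * 40]
        for g in self.groups.values():
            med = f"{g.median:.1f}" if np.isfinite(g.median) else "not reached"
            lines.append(f"{g.label}: n={g.n}, events={g.n_events}, "
                         f"median survival={med} months")
        if self.defined:
            lines.append(f"log-rank chi2={self.chi_square:.4f}, "
                         f"p={self.p_value:.4g}")
        else:
            lines.append("log-rank undefined (no events)")
        return "\n".join(lines)


def km_logrank(records: pd.DataFrame, group_field: str,
               time_col: str = "time_months", event_col: str = "event"
               ) -> KMLogrankResult:
    """Product-limit curves and median survival per group, with the
    standard two-group log-rank test."""
    for c in (group_field, time_col, event_col):
        if c not in records.columns:
            raise ValueError(f"missing column {c!r}")
    if (records[time_col] <= 0).any():
        raise ValueError("survival times must be positive")
    levels = sorted(records[group_field].unique(), key=str)
    if len(levels) != 2:
        raise ValueError(f"group field must have 2 levels, got {levels}")
    groups: dict[str, KMGroup] = {}
    for lev in levels:
        sub = records[records[group_field] == lev]
        if sub.empty:
            raise ValueError(f"group {lev!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], sub[event_col].astype(bool))
        curve = pd.DataFrame({
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
        })
        curve["at_risk"] = [
            int((sub[time_col] >= t).sum()) for t in curve["time"]]
        med = kmf.median_survival_time_
        groups[str(lev)] = KMGroup(str(lev), len(sub),
                                   int(sub[event_col].astype(bool).sum()),
                                   curve, float(med) if np.isfinite(med) else np.nan)
    total_events = int(records[event_col].astype(bool).sum())
    if total_events == 0:
        return KMLogrankResult(groups, np.nan, np.nan)
    a, b = levels
    ga = records[records[group_field] == a]
    gb = records[records[group_field] == b]
    res = logrank_test(ga[time_col], gb[time_col],
                       ga[event_col].astype(bool), gb[event_col].astype(bool))
    return KMLogrankResult(groups, float(res.test_statistic),
                           float(res.p_value))


@dataclass
class CoxResult:
    """Per-covariate hazard ratios with Wald confidence intervals."""

    table: pd.DataFrame    # index covariate; coef, hr, hr_low, hr_high, se, p
    n: int
    n_events: int

    def hr(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hr"])

    def ci(self, covariate: str) -> tuple[float, float]:
        row = self.table.loc[covariate]
        return float(row["hr_low"]), float(row["hr_high"])

    def summary(self) -> str:
        lines = [f"Cox proportional hazards (Breslow ties): "
                 f"n={self.n}, events={self.n_events}", "-" * 60]
        for cov, row in self.table.iterrows():
            lines.append(f"{cov:<22s} HR={row['hr']:.3f} "
                         f"[{row['hr_low']:.3f}, {row['hr_high']:.3f}] "
                         f"p={row['p']:.4g}")
        return "\n".join(lines)


def cox_fit(records: pd.DataFrame, covariates: list[str],
            time_col: str = "time_months", event_col: str = "event",
            conf_level: float = 0.95) -> CoxResult:
    """Cox partial-likelihood fit with Breslow tie handling.

    Raises on constant covariates, and on non-finite estimates (separation
    or collinearity) with a diagnostic message.
    """
    if not covariates:
        raise ValueError("need at least one covariate")
    missing = [c for c in covariates if c not in records.columns]
    if missing:
        raise ValueError(f"missing covariate column(s): {missing}")
    X = records[covariates].astype(float)
    const = [c for c in covariates if X[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariate(s): {const}")
    n_events = int(records[event_col].astype(bool).sum())
    if n_events < len(covariates):
        raise ValueError(f"{n_events} events cannot support "
                         f"{len(covariates)} covariates")
    model = PHReg(records[time_col].to_numpy(), X.to_numpy(),
                  status=records[event_col].astype(int).to_numpy(),
                  ties="breslow")
    fit = model.fit(disp=False)
    coef, se = np.asarray(fit.params), np.asarray(fit.bse)
    if not (np.isfinite(coef).all() and np.isfinite(se).all()):
        raise RuntimeError(
            "Cox fit failed (non-finite estimates): likely separation or "
            f"collinearity among {covariates}")
    z = sps.norm.ppf(0.5 + conf_level / 2.0)
    pvals = 2 * sps.norm.sf(np.abs(coef / se))
    table = pd.DataFrame({
        "coef": coef, "se": se, "hr": np.exp(coef),
        "hr_low": np.exp(coef - z * se), "hr_high": np.exp(coef + z * se),
        "p": pvals,
    }, index=pd.Index(covariates, name="covariate"))
    return CoxResult(table, len(records), n_events)


# ---------------------------------------------------------------- concordance

def scorer_concordance(scores_a, scores_b, method: str = "pearson"
                       ) -> tuple[float, float]:
    """Inter-scorer concordance of H-scores: correlation and p-value.

    Pearson by default; `method="spearman"` ranks first (so exactly
    reversed rankings give r = −1).
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.shape != b.shape:
        raise ValueError("score vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 paired scores")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance score vector")
    if method == "pearson":
        r, p = sps.pearsonr(a, b)
    elif method == "spearman":
        r, p = sps.spearmanr(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)
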