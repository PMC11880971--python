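"""Marker-triage machinery for the subtype IHC panel.

Candidate markers pass through three gates before joining the panel:

1. *in silico* screening — correlation of bulk expression with a continuous
   classical/basal signature score, plus the AUC of the marker as a ranking
   predictor of the binary subtype label;
2. TMA specificity — on a tissue microarray of clear-classical and
   clear-basal cases, a marker must (i) reach moderate/strong intensity in
   at least half the cases of its own subtype, (ii) be essentially absent
   from the opposite subtype, and (iii) never stain stromal cells;
3. IHC–RNA concordance — the per-case H-score must correlate significantly
   with the transcript level, otherwise the marker is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class MarkerDecision:
    marker: str
    stage: str              # "in_silico" | "tma" | "concordance"
    passed: bool
    reason: str = ""
    statistics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.passed and not self.reason:
            raise ValueError("failed decisions must carry a reason")


# ------------------------------------------------------------------ screening

def signature_screen(expression: pd.DataFrame, signature_score,
                     subtype_label) -> pd.DataFrame:
    """Per-marker Pearson r against the continuous signature score and AUC
    against the binary subtype label (ties rank-averaged).

    Returns a DataFrame indexed by marker with columns r, r_p, auc.
    Constant markers get nan r; single-class labels make every AUC nan.
    """
    score = np.asarray(signature_score, float)
    label = np.asarray(subtype_label)
    if len(expression) != score.size or score.size != label.size:
        raise ValueError("expression, score and labels must align on cases")
    if len(expression) < 3:
        raise ValueError("need at least 3 cases")
    classes = np.unique(label)
    if classes.size > 2:
        raise ValueError("subtype labels must be binary")
    auc_ok = classes.size == 2
    pos = classes.max() if auc_ok else None

    rows = {}
    for marker in expression.columns:
        x = expression[marker].to_numpy(float)
        if np.std(x) == 0:
            r, rp = np.nan, np.nan
        else:
            r, rp = sps.pearsonr(x, score)
        auc = roc_auc_score(label == pos, x) if auc_ok else np.nan
        rows[marker] = {"r": r, "r_p": rp, "auc": auc}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "marker"
    return out


# ---------------------------------------------------------------- TMA filter

def tma_specificity_filter(records: pd.DataFrame, target_subtype: str,
                           marker: str | None = None,
                           lenient: bool = False) -> MarkerDecision:
    """Apply the three TMA specificity rules to one marker's records.

    `records` columns: marker, case_id, subtype ("classical"/"basal"),
    intensity (0–3, max per case), stromal_expression (bool). Pass requires

    (i)   ≥ 50% of target-subtype cases at intensity ≥ 2 (moderate/strong);
    (ii)  opposite subtype essentially negative — by default the strict
          conjunction: zero strong (3) and at most one moderate (2) case;
          with ``lenient=True`` the disjunctive reading (zero strong OR at
          most one moderate) is used instead;
    (iii) no stromal expression in any record.
    """
    if target_subtype not in ("classical", "basal"):
        raise ValueError("target_subtype must be 'classical' or 'basal'")
    df = records
    if marker is not None:
        df = df[df["marker"] == marker]
    markers = df["marker"].unique() if "marker" in df.columns else [marker]
    if len(markers) != 1:
        raise ValueError("records must concern exactly one marker")
    name = str(markers[0])
    if not df["intensity"].isin([0, 1, 2, 3]).all():
        raise ValueError("intensity must be in {0,1,2,3}")
    opposite = "basal" if target_subtype == "classical" else "classical"
    tgt = df[df["subtype"] == target_subtype]
    opp = df[df["subtype"] == opposite]
    if tgt.empty or opp.empty:
        raise ValueError("records must cover both subtype groups")

    frac_modstrong = float((tgt["intensity"] >= 2).mean())
    n_strong = int((opp["intensity"] == 3).sum())
    n_moderate = int((opp["intensity"] == 2).sum())
    stromal = bool(df["stromal_expression"].astype(bool).any())
    stat = {"target_frac_moderate_or_strong": frac_modstrong,
            "opposite_n_strong": n_strong,
            "opposite_n_moderate": n_moderate,
            "any_stromal": stromal}

    reasons = []
    if frac_modstrong < 0.5:
        reasons.append(
            f"rule (i): only {frac_modstrong:.0%} of {target_subtype} cases "
            "reach moderate/strong expression (need >= 50%)")
    no_strong, few_moderate = n_strong < 1, n_moderate < 2
    rule2 = (no_strong or few_moderate) if lenient else (no_strong and few_moderate)
    if not rule2:
        reasons.append(
            f"rule (ii): opposite subtype shows {n_strong} strong and "
            f"{n_moderate} moderate expressions")
    if stromal:
        reasons.append("rule (iii): expression in stromal cells")
    return MarkerDecision(name, "tma", passed=not reasons,
                          reason="; ".join(reasons), statistics=stat)


# --------------------------------------------------------------- concordance

def ihc_rna_concordance(hscores, rna, alpha: float = 0.05,
                        marker: str = "marker",
                        method: str = "pearson") -> MarkerDecision:
    """Keep a marker iff its H-score / transcript correlation is significant
    (p < alpha). Statistics (r, p, n) are recorded with the decision."""
    h = np.asarray(hscores, float)
    r_ = np.asarray(rna, float)
    if h.shape != r_.shape:
        raise ValueError("paired vectors must have equal length")
    if h.size < 3:
        raise ValueError("need at least 3 paired cases")
    if h.std() == 0 or r_.std() == 0:
        raise ValueError("zero-variance input")
    if method == "pearson":
        r, p = sps.pearsonr(h, r_)
    elif method == "spearman":
        r, p = sps.spearmanr(h, r_)
    else:
        raise ValueError(f"unknown method {method!r}")
    keep = bool(p < alpha)
    reason = "" if keep else (
        f"nonsignificant IHC–RNA association (r = {r:.2f}, p = {p:.2g})")
    return MarkerDecision(marker, "concordance", passed=keep, reason=reason,
                          statistics={"r": float(r), "p": float(p),
                                      "n": int(h.size)})


def decisions_frame(decisions: list[MarkerDecision]) -> pd.DataFrame:
    return pd.DataFrame([{
        "marker": d.marker, "stage": d.stage, "passed": d.passed,
        "reason": d.reason, **{f"stat_{k}": v for k, v in d.statistics.items()},
    } for d in decisions])
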