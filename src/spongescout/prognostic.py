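"""Survival stratification of triplets by expression pattern.

Patients are split by the up-down-up (lncRNA high, miRNA low, mRNA high) or
down-up-down pattern at per-RNA cutoffs chosen to minimize the single-RNA
log-rank p-value.  A triplet is prognostic when the pattern split separates
survival (p < 0.05) while no single member RNA does (all single p >= 0.05);
the f-score is the log-fold decrease of the pattern p-value relative to the
best single-RNA p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MIN_GROUP_SIZE = 10          # both groups must be strictly larger
PATTERNS = ("up-down-up", "down-up-down")
CUTOFF_LABELS = ("P10", "P90", "mean", "median", "Q1", "Q3")


class DegenerateCutoffError(ValueError):
    pass


@dataclass
class SurvivalRecord:
    patient: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("follow-up time must be >= 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def survival_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {"patient": [r.patient for r in records],
         "time": [r.time for r in records],
         "event": [r.event for r in records]}
    ).set_index("patient")


@dataclass
class PrognosticResult:
    lncrna: str
    mirna: str
    mrna: str
    pattern: str
    cutoffs: dict = field(default_factory=dict)     # rna id -> (label, value)
    n_pattern: int = 0
    n_rest: int = 0
    p_xyz: float = float("nan")
    p_x: float = float("nan")
    p_y: float = float("nan")
    p_z: float = float("nan")
    f_score: float = float("nan")
    verdict: str = "non-evaluable"

    @property
    def prognostic(self) -> bool:
        return self.verdict == "prognostic"


def candidate_cutoffs(values) -> list[tuple[str, float]]:
    """The six candidate cutoffs: P10, P90, mean, median, Q1, Q3.

    Percentiles use the linear-interpolation convention.  Duplicated values
    (e.g. mean == median) keep their distinct labels.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 20:
        raise ValueError("need at least 20 values")
    if np.ptp(v) == 0:
        raise DegenerateCutoffError("constant expression vector")
    return [
        ("P10", float(np.percentile(v, 10))),
        ("P90", float(np.percentile(v, 90))),
        ("mean", float(v.mean())),
        ("median", float(np.median(v))),
        ("Q1", float(np.percentile(v, 25))),
        ("Q3", float(np.percentile(v, 75))),
    ]


def logrank(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank chi-squared statistic (1 df) and p-value.

    Standard observed-minus-expected tabulation over distinct event times
    with the hypergeometric variance; ties handled by simultaneous risk-set
    accounting.  Matches ``lifelines.statistics.logrank_test``.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    time = np.concatenate([group_a["time"].to_numpy(float),
                           group_b["time"].to_numpy(float)])
    event = np.concatenate([group_a["event"].to_numpy(int),
                            group_b["event"].to_numpy(int)])
    in_a = np.concatenate([np.ones(len(group_a), bool),
                           np.zeros(len(group_b), bool)])
    return _logrank_arrays(time, event, in_a)


def _logrank_arrays(time, event, in_a) -> tuple[float, float]:
    if event.sum() == 0:
        return 0.0, 1.0   # all censored: curves indistinguishable
    order = np.argsort(time, kind="stable")
    time, event, in_a = time[order], event[order], in_a[order]
    uniq, start = np.unique(time, return_index=True)
    n = time.size
    # risk-set sizes just before each distinct time
    at_risk = n - start
    at_risk_a = in_a[::-1].cumsum()[::-1][start]
    d_tot = np.add.reduceat(event, start)
    d_a = np.add.reduceat(event & in_a, start)
    with np.errstate(invalid="ignore", divide="ignore"):
        expect_a = d_tot * at_risk_a / at_risk
        var = (
            d_tot * (at_risk_a / at_risk) * (1 - at_risk_a / at_risk)
            * (at_risk - d_tot) / np.maximum(at_risk - 1, 1)
        )
    keep = at_risk > 1
    o_minus_e = float((d_a - expect_a)[keep].sum())
    v = float(var[keep].sum())
    if v == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / v
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def select_cutoff(values: pd.Series, survival: pd.DataFrame):
    """Best single-RNA cutoff by minimal log-rank p over valid splits.

    ``values`` is indexed by patient.  A split is valid when both sides
    have more than MIN_GROUP_SIZE patients.  Returns (label, cutoff, p) or
    None when no candidate yields a valid split.
    """
    v = values.loc[survival.index]
    best = None
    for label, cut in candidate_cutoffs(v.to_numpy()):
        up = v > cut
        if up.sum() <= MIN_GROUP_SIZE or (~up).sum() <= MIN_GROUP_SIZE:
            continue
        _, p = logrank(survival.loc[up.values], survival.loc[~up.values])
        if best is None or p < best[2]:
            best = (label, cut, p)
    return best


def pattern_groups(
    expr: pd.DataFrame, cutoffs: dict, pattern: str
) -> tuple[pd.Index, pd.Index]:
    """Patient split for a triplet pattern.

    ``expr`` has rows lncrna/mirna/mrna (in that order) and patient
    columns; ``cutoffs`` maps each of the three RNA ids to a cutoff value.
    Ties go down: value <= cutoff counts as down-regulated.
    """
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}")
    lnc_id, mir_id, mrna_id = expr.index
    lnc_up = expr.loc[lnc_id] > cutoffs[lnc_id]
    mir_up = expr.loc[mir_id] > cutoffs[mir_id]
    mrna_up = expr.loc[mrna_id] > cutoffs[mrna_id]
    if pattern == "up-down-up":
        in_pattern = lnc_up & ~mir_up & mrna_up
    else:
        in_pattern = ~lnc_up & mir_up & ~mrna_up
    cols = expr.columns
    return cols[in_pattern.values], cols[~in_pattern.values]


def evaluate_triplet(
    triplet: tuple[str, str, str],
    expr: pd.DataFrame,
    survival: pd.DataFrame,
    log_base: float = 10.0,
) -> list[PrognosticResult]:
    """Evaluate both patterns for one triplet; one result per pattern.

    ``expr`` is the full expression matrix (RNAs x patients) on the log
    scale; ``survival`` is indexed by patient with time/event columns.
    """
    lnc, mir, mrna = triplet
    patients = survival.index.intersection(expr.columns)
    survival = survival.loc[patients]
    sub = expr.loc[[lnc, mir, mrna], patients]

    selections = {}
    for rna in (lnc, mir, mrna):
        selections[rna] = select_cutoff(sub.loc[rna], survival)

    results = []
    for pattern in PATTERNS:
        res = PrognosticResult(lncrna=lnc, mirna=mir, mrna=mrna, pattern=pattern)
        if any(sel is None for sel in selections.values()):
            res.verdict = "non-evaluable"
            results.append(res)
            continue
        cutoffs = {rna: sel[1] for rna, sel in selections.items()}
        res.cutoffs = {rna: (sel[0], sel[1]) for rna, sel in selections.items()}
        res.p_x, res.p_y, res.p_z = (
            selections[lnc][2], selections[mrna][2], selections[mir][2],
        )
        grp, rest = pattern_groups(sub, cutoffs, pattern)
        res.n_pattern, res.n_rest = len(grp), len(rest)
        if len(grp) <= MIN_GROUP_SIZE or len(rest) <= MIN_GROUP_SIZE:
            res.verdict = "non-evaluable"
            results.append(res)
            continue
        _, res.p_xyz = logrank(survival.loc[grp], survival.loc[rest])
        p_min_single = min(res.p_x, res.p_y, res.p_z)
        res.f_score = f_score(res.p_xyz, p_min_single, log_base)
        if res.p_xyz < 0.05 and p_min_single >= 0.05:
            res.verdict = "prognostic"
        else:
            res.verdict = "not-prognostic"
        results.append(res)
    return results


def f_score(p_xyz: float, p_min_single: float, log_base: float = 10.0) -> float:
    """-log(p_xyz / min single p); 0 when the triplet adds nothing."""
    return float(-np.log(p_xyz / p_min_single) / np.log(log_base))


def rank_triplets(
    triplets: list[tuple[str, str, str]],
    expr: pd.DataFrame,
    survival: pd.DataFrame,
    log_base: float = 10.0,
) -> pd.DataFrame:
    """Evaluate all triplets and return a table ranked by f-score."""
    rows = []
    for t in triplets:
        for res in evaluate_triplet(t, expr, survival, log_base):
            rows.append({
                "lncrna": res.lncrna, "mirna": res.mirna, "mrna": res.mrna,
                "pattern": res.pattern,
                "n_pattern": res.n_pattern, "n_rest": res.n_rest,
                "p_xyz": res.p_xyz, "p_x": res.p_x, "p_y": res.p_y,
                "p_z": res.p_z, "f_score": res.f_score,
                "verdict": res.verdict,
            })
    df = pd.DataFrame(rows, columns=[
        "lncrna", "mirna", "mrna", "pattern", "n_pattern", "n_rest",
        "p_xyz", "p_x", "p_y", "p_z", "f_score", "verdict",
    ])
    return df.sort_values("f_score", ascending=False, na_position="last"
                          ).reset_index(drop=True)
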