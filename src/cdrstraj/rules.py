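"""Early-change prognosis rules: thresholds, minimum symptom counts,
and rule evaluation against the null information rate.

A prognosis rule attaches to one (baseline, mid) stratum transition and
reads: "at least ``min_items`` of the prognostic symptoms improved by at
least (or at most) ``delta`` points between baseline and the 4-6 week
visit" -> predicted outcome at 10-12 weeks.  Thresholds come from median
severity changes on the symptom dynamic paths; the minimum count is the
smallest count whose 2x2 association with the target outcome reaches
chi-square significance.  Accuracy is benchmarked against the null
information rate (NIR): the accuracy of naively carrying a 4-6 week
nonresponder status forward as "still actively depressed at 10-12 weeks".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom, chi2_contingency, ks_2samp

from .cohort import Cohort
from .mixture import BaselineMixture, assign_baseline_stratum
from .pgm import TrajectoryPath
from .scale import ACTIVE_CUT


class DegenerateTableError(RuntimeError):
    """Every candidate count splits the cohort degenerately."""


@dataclass(frozen=True)
class PrognosisRule:
    baseline: str
    mid: str
    predicted_outcome: str
    direction: str  # "at_least" | "at_most"
    delta: int
    min_items: int
    item_ids: tuple[int, ...]

    def __post_init__(self):
        if self.direction not in ("at_least", "at_most"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if not 1 <= self.min_items <= len(self.item_ids):
            raise ValueError("min_items outside 1..|prognostic set|")


@dataclass(frozen=True)
class RuleEvaluation:
    n_transition: int
    n_covered: int
    coverage: float
    n_correct: int
    accuracy: float
    odds_ratio: float
    ci95: tuple[float, float]
    p_vs_nir: float
    nir: float
    defined: bool = True


# ---------------------------------------------------------------------------
# labelling helpers

def transition_labels(cohort: Cohort, mixture: BaselineMixture, response_reference="scale_floor"):
    a = np.array(
        [assign_baseline_stratum(int(t), mixture) for t in cohort.totals("baseline")]
    )
    b = cohort.followup_strata("mid")
    o_end = cohort.outcomes("end", response_reference)
    return a, b, o_end


def improvement_matrix(cohort: Cohort, item_ids) -> np.ndarray:
    """(patients x items) baseline-minus-mid change; positive = improvement."""
    idx = [i - 1 for i in item_ids]
    return cohort.items("baseline")[:, idx] - cohort.items("mid")[:, idx]


def items_meeting(impr: np.ndarray, direction: str, delta: int) -> np.ndarray:
    """Per-patient count of prognostic items meeting the change condition."""
    if direction == "at_least":
        return (impr >= delta).sum(axis=1)
    return (impr <= delta).sum(axis=1)


def rule_met(cohort: Cohort, rule: PrognosisRule) -> np.ndarray:
    impr = improvement_matrix(cohort, rule.item_ids)
    return items_meeting(impr, rule.direction, rule.delta) >= rule.min_items


# ---------------------------------------------------------------------------
# Step 4 derivations

def derive_change_threshold(
    cohort: Cohort, mask: np.ndarray, item_ids, *, per_item: bool = False
) -> int:
    """Absolute difference of pooled median prognostic severity,
    baseline vs mid, over patients on the path(s); rounded half-up.
    """
    if len(item_ids) == 0:
        raise ValueError("empty prognostic set")
    if int(np.sum(mask)) < 3:
        raise ValueError("need >= 3 patients on the path")
    idx = [i - 1 for i in item_ids]
    base = cohort.items("baseline")[mask][:, idx]
    mid = cohort.items("mid")[mask][:, idx]
    if per_item:
        diffs = np.abs(np.median(base, axis=0) - np.median(mid, axis=0))
        d = float(np.median(diffs))
    else:
        d = abs(float(np.median(base)) - float(np.median(mid)))
    return int(np.floor(d + 0.5))


def derive_min_symptom_count(
    counts: np.ndarray,
    is_target: np.ndarray,
    n_items: int,
    *,
    alpha: float = 0.05,
    yates: bool = False,
    fallback: str = "smallest",
) -> tuple[int, dict[int, float]]:
    """Smallest count m whose 2x2 [count >= m] x [outcome == target]
    table is chi-square significant; degenerate candidates are skipped.

    When no candidate reaches significance the scan falls back, with a
    warning, to the smallest count that splits the cohort at all
    (``fallback="smallest"``, deterministic) or to the count with the
    largest statistic (``fallback="argmax"``).
    """
    pvals: dict[int, float] = {}
    stats: dict[int, float] = {}
    for m in range(1, n_items + 1):
        met = counts >= m
        table = np.array(
            [
                [np.sum(met & is_target), np.sum(met & ~is_target)],
                [np.sum(~met & is_target), np.sum(~met & ~is_target)],
            ]
        )
        if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
            continue
        stat, p, _, _ = chi2_contingency(table, correction=yates)
        pvals[m], stats[m] = float(p), float(stat)
    if not pvals:
        raise DegenerateTableError(
            "every candidate minimum count yields a degenerate 2x2 table"
        )
    significant = [m for m, p in sorted(pvals.items()) if p < alpha]
    if significant:
        return significant[0], pvals
    if fallback == "argmax":
        best = max(stats, key=stats.get)
    else:
        best = min(pvals)
    warnings.warn(
        f"no candidate count reached p < {alpha}; falling back to m={best}",
        stacklevel=2,
    )
    return best, pvals


def exact_binomial_tail(n_correct: int, n: int, p0: float) -> float:
    """One-sided exact binomial upper tail P(X >= n_correct | n, p0)."""
    if n == 0:
        return 1.0
    return float(binom.sf(n_correct - 1, n, p0))


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> tuple[float, tuple[float, float]]:
    """Odds ratio with Haldane-Anscombe 0.5 correction on zero cells and
    the Woolf logit 95% confidence interval."""
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    or_ = (a_ * d_) / (b_ * c_)
    se = np.sqrt((1 / cells).sum())
    lo = float(np.exp(np.log(or_) - 1.96 * se))
    hi = float(np.exp(np.log(or_) + 1.96 * se))
    return float(or_), (lo, hi)


def compute_nir(cohort: Cohort, response_reference: str = "scale_floor") -> float:
    """Null information rate: the fraction of 4-6 week nonresponders whose
    10-12 week total still marks active depression (>= 40).

    Returns 0.0 when no patient is a mid-visit nonresponder.
    """
    mid_nr = cohort.outcomes("mid", response_reference) == "nonresponse"
    if not mid_nr.any():
        return 0.0
    still_active = cohort.totals("end") >= ACTIVE_CUT
    return float((mid_nr & still_active).sum() / mid_nr.sum())


def evaluate_rule(
    rule: PrognosisRule,
    cohort: Cohort,
    mixture: BaselineMixture,
    nir: float,
    *,
    response_reference: str = "scale_floor",
) -> RuleEvaluation:
    """Coverage, accuracy, odds ratio and exact NIR comparison of one rule
    on the patients making its (baseline, mid) transition."""
    a, b, o_end = transition_labels(cohort, mixture, response_reference)
    on_tr = (a == rule.baseline) & (b == rule.mid)
    n_tr = int(on_tr.sum())
    met = rule_met(cohort, rule) & on_tr
    n_cov = int(met.sum())
    if n_cov == 0:
        return RuleEvaluation(n_tr, 0, 0.0, 0, float("nan"), float("nan"),
                              (float("nan"), float("nan")), float("nan"), nir,
                              defined=False)
    correct = o_end == rule.predicted_outcome
    n_correct = int((met & correct).sum())
    unmet = on_tr & ~met
    or_, ci = odds_ratio_2x2(
        n_correct,
        n_cov - n_correct,
        int((unmet & correct).sum()),
        int((unmet & ~correct).sum()),
    )
    return RuleEvaluation(
        n_transition=n_tr,
        n_covered=n_cov,
        coverage=n_cov / n_tr if n_tr else float("nan"),
        n_correct=n_correct,
        accuracy=n_correct / n_cov,
        odds_ratio=or_,
        ci95=ci,
        p_vs_nir=exact_binomial_tail(n_correct, n_cov, nir),
        nir=nir,
    )


# ---------------------------------------------------------------------------
# rule table (Step 4 end-to-end)

def build_rule_table(
    cohort: Cohort,
    paths: list[TrajectoryPath],
    item_ids,
    mixture: BaselineMixture,
    *,
    alpha: float = 0.05,
    yates: bool = False,
    min_transition_n: int = 10,
    nir: float | None = None,
    response_reference: str = "scale_floor",
) -> tuple[list[tuple[PrognosisRule, RuleEvaluation]], dict]:
    """One rule per (baseline, mid) transition on the selected paths.

    The predicted outcome is the modal end outcome of the patients on the
    transition's selected path(s); the direction follows the prediction
    (at_most for nonresponse, at_least otherwise).  Also returns a
    summary with the uncovered-patient outcome mix.
    """
    if len(item_ids) == 0:
        raise ValueError("empty prognostic symptom set")
    item_ids = tuple(sorted(item_ids))
    a, b, o_end = transition_labels(cohort, mixture, response_reference)
    if nir is None:
        nir = compute_nir(cohort, response_reference)
    c = cohort.followup_strata("end")

    transitions: dict[tuple[str, str], list[TrajectoryPath]] = {}
    for p in paths:
        transitions.setdefault((p.baseline, p.mid), []).append(p)

    impr = improvement_matrix(cohort, item_ids)
    results: list[tuple[PrognosisRule, RuleEvaluation]] = []
    uncovered_masks = []
    for (sa, sb), tr_paths in sorted(transitions.items(), key=lambda t: (t[0][0], t[0][1])):
        on_tr = (a == sa) & (b == sb)
        if int(on_tr.sum()) < min_transition_n:
            continue
        on_paths = np.zeros(len(cohort), dtype=bool)
        for p in tr_paths:
            on_paths |= on_tr & (c == p.end)
        vals, cnts = np.unique(o_end[on_paths], return_counts=True)
        predicted = str(vals[np.argmax(cnts)])
        direction = "at_most" if predicted == "nonresponse" else "at_least"
        delta = derive_change_threshold(cohort, on_tr, item_ids)
        counts = items_meeting(impr[on_tr], direction, delta)
        m, _pvals = derive_min_symptom_count(
            counts, o_end[on_tr] == predicted, len(item_ids), alpha=alpha, yates=yates
        )
        rule = PrognosisRule(sa, sb, predicted, direction, delta, m, item_ids)
        ev = evaluate_rule(rule, cohort, mixture, nir, response_reference=response_reference)
        results.append((rule, ev))
        uncovered_masks.append(on_tr & ~rule_met(cohort, rule))

    uncovered = np.zeros(len(cohort), dtype=bool)
    for msk in uncovered_masks:
        uncovered |= msk
    n_unc = int(uncovered.sum())
    summary = {
        "nir": nir,
        "n_rules": len(results),
        "mean_accuracy": float(
            np.mean([ev.accuracy for _, ev in results if ev.defined])
        ) if results else float("nan"),
        "pooled_coverage": float(
            sum(ev.n_covered for _, ev in results)
            / max(1, sum(ev.n_transition for _, ev in results))
        ),
        "n_uncovered": n_unc,
        "uncovered_nonresponse_fraction": (
            float((o_end[uncovered] == "nonresponse").mean()) if n_unc else float("nan")
        ),
    }
    return results, summary


def rule_table_frame(results) -> pd.DataFrame:
    rows = []
    for rule, ev in results:
        rows.append(
            {
                "baseline": rule.baseline,
                "mid": rule.mid,
                "n": ev.n_transition,
                "predicted_outcome": rule.predicted_outcome,
                "delta_direction": rule.direction,
                "delta": rule.delta,
                "min_items": rule.min_items,
                "coverage": ev.coverage,
                "accuracy": ev.accuracy,
                "p_vs_nir": ev.p_vs_nir,
                "odds_ratio": ev.odds_ratio,
                "ci_low": ev.ci95[0],
                "ci_high": ev.ci95[1],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# demographic invariance

def _chi2_categorical(groups: np.ndarray, values: np.ndarray):
    """Chi-square independence test collapsing empty levels."""
    tab = pd.crosstab(pd.Series(values), pd.Series(groups))
    tab = tab.loc[(tab.sum(axis=1) > 0), (tab.sum(axis=0) > 0)]
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return float("nan"), float("nan")
    stat, p, _, _ = chi2_contingency(tab.to_numpy())
    return float(stat), float(p)


def demographic_invariance(
    cohort: Cohort,
    rules: list[PrognosisRule],
    mixture: BaselineMixture,
    *,
    response_reference: str = "scale_floor",
) -> pd.DataFrame:
    """KS tests on age and chi-square tests on sex/race for the
    covered-vs-uncovered and correct-vs-incorrect splits of each rule."""
    a, b, o_end = transition_labels(cohort, mixture, response_reference)
    age = cohort.frame["age"].to_numpy(dtype=float)
    sex = cohort.frame["sex"].to_numpy()
    race = cohort.frame["race"].to_numpy()
    rows = []
    for rule in rules:
        on_tr = (a == rule.baseline) & (b == rule.mid)
        met = rule_met(cohort, rule) & on_tr
        correct = met & (o_end == rule.predicted_outcome)
        for split_name, g1, g2 in (
            ("covered_vs_not", met, on_tr & ~met),
            ("correct_vs_not", correct, met & ~correct),
        ):
            if g1.sum() < 3 or g2.sum() < 3:
                rows.append(
                    dict(baseline=rule.baseline, mid=rule.mid, split=split_name,
                         age_ks=float("nan"), age_p=float("nan"),
                         sex_chi2=float("nan"), sex_p=float("nan"),
                         race_chi2=float("nan"), race_p=float("nan"))
                )
                continue
            ks = ks_2samp(age[g1], age[g2], method="asymp")
            grp = np.where(g1, "g1", "g2")[g1 | g2]
            sx_stat, sx_p = _chi2_categorical(grp, sex[g1 | g2])
            rc_stat, rc_p = _chi2_categorical(grp, race[g1 | g2])
            rows.append(
                dict(baseline=rule.baseline, mid=rule.mid, split=split_name,
                     age_ks=float(ks.statistic), age_p=float(ks.pvalue),
                     sex_chi2=sx_stat, sex_p=sx_p,
                     race_chi2=rc_stat, race_p=rc_p)
            )
    return pd.DataFrame(rows)
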