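"""Model / Results interface tying the five pipeline stages together.

:class:`TreatmentCourseModel` holds a training cohort plus configuration;
``fit`` runs, in order: baseline mixture stratification, chain-model
estimation, forward-algorithm path selection, prognostic-symptom
identification and prognosis-rule derivation, returning a
:class:`TreatmentCourseResults` that carries every intermediate artefact,
a ``summary()`` table, and ``predict``/``replicate`` for applying the
frozen rules to independent testing cohorts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import symptoms as symptoms_mod
from .cohort import Cohort, read_cohort_csv, validate_cohort
from .mixture import BaselineMixture, fit_baseline_mixture
from .pgm import (
    PGModel,
    TrajectoryPath,
    estimate_pgm,
    paths_to_frame,
    select_symptom_dynamic_paths,
)
from .rules import (
    PrognosisRule,
    RuleEvaluation,
    build_rule_table,
    compute_nir,
    demographic_invariance,
    evaluate_rule,
    rule_met,
    rule_table_frame,
)
from .scale import assign_followup_stratum


class PipelineError(RuntimeError):
    """A pipeline stage could not proceed (e.g. no prognostic symptoms)."""


@dataclass
class PipelineConfig:
    """Tunable analysis parameters (defaults follow the published workflow)."""

    seed: int = 0
    min_coverage: float = 0.10
    alpha: float = 0.05
    majority: float = 0.5
    selection_mode: str = "coverage_only"
    n_clusters: int | None = None  # None = cut the tree at cut_height instead
    cut_height: float = 0.9
    test_method: str = "ks"
    test_visits: tuple[str, ...] = ("mid", "end")
    yates: bool = False
    min_transition_n: int = 10
    mixture_restarts: int = 10
    response_reference: str = "scale_floor"
    fallback_nonresponse: bool = False  # predict nonresponse for uncovered patients

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


class TreatmentCourseModel:
    """Five-step severity-trajectory model of acute antidepressant response.

    Parameters
    ----------
    cohort : Cohort
        Training completers (three CDRS-R visits each).
    config : PipelineConfig, optional
    """

    def __init__(self, cohort: Cohort, config: PipelineConfig | None = None):
        self.cohort = cohort
        self.config = config or PipelineConfig()
        report = validate_cohort(cohort)
        if not report.ok:
            raise ValueError("invalid training cohort:\n" + report.summary())

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, config: PipelineConfig | None = None):
        return cls(Cohort(frame), config)

    @classmethod
    def from_csv(cls, path: str | Path, config: PipelineConfig | None = None):
        cohort, report = read_cohort_csv(path)
        if not report.ok:
            raise ValueError("invalid training cohort:\n" + report.summary())
        return cls(cohort, config)

    def fit(self, seed: int | None = None) -> "TreatmentCourseResults":
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        mixture = fit_baseline_mixture(
            self.cohort.totals("baseline"), restarts=cfg.mixture_restarts,
            seed=seed, bic_scan=True,
        )
        pgm = estimate_pgm(self.cohort, mixture, response_reference=cfg.response_reference)
        paths = select_symptom_dynamic_paths(
            pgm, self.cohort, mixture, cfg.min_coverage,
            selection_mode=cfg.selection_mode,
            response_reference=cfg.response_reference,
        )
        symptom_set = symptoms_mod.identify_prognostic_symptoms(
            self.cohort, paths, mixture,
            alpha=cfg.alpha, majority=cfg.majority, n_clusters=cfg.n_clusters,
            cut_height=cfg.cut_height,
            test_method=cfg.test_method, test_visits=tuple(cfg.test_visits),
        )
        if not symptom_set.item_ids:
            raise PipelineError(
                "no prognostic symptoms: all 17 items failed at least one of "
                "the three criteria (expected for placebo-like cohorts)"
            )
        nir = compute_nir(self.cohort, cfg.response_reference)
        rule_results, rule_summary = build_rule_table(
            self.cohort, paths, symptom_set.item_ids, mixture,
            alpha=cfg.alpha, yates=cfg.yates,
            min_transition_n=cfg.min_transition_n, nir=nir,
            response_reference=cfg.response_reference,
        )
        demo = demographic_invariance(
            self.cohort, [r for r, _ in rule_results], mixture,
            response_reference=cfg.response_reference,
        )
        return TreatmentCourseResults(
            model=self, mixture=mixture, pgm=pgm, paths=paths,
            prognostic_symptoms=symptom_set, nir=nir,
            rules=rule_results, rule_summary=rule_summary,
            demographics=demo, seed=seed,
        )


@dataclass
class FrozenModel:
    """Serializable training-derived artefacts applied to testing data."""

    boundary: int
    pgm: PGModel
    paths: list[TrajectoryPath]
    item_ids: tuple[int, ...]
    rules: list[PrognosisRule]
    rule_accuracies: dict[str, float]
    nir: float
    response_reference: str = "scale_floor"

    def to_dict(self) -> dict:
        return {
            "boundary": self.boundary,
            "pgm": self.pgm.to_dict(),
            "paths": [asdict(p) for p in self.paths],
            "item_ids": list(self.item_ids),
            "rules": [asdict(r) for r in self.rules],
            "rule_accuracies": self.rule_accuracies,
            "nir": self.nir,
            "response_reference": self.response_reference,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FrozenModel":
        rules = []
        for r in d["rules"]:
            r = dict(r)
            r["item_ids"] = tuple(r["item_ids"])
            rules.append(PrognosisRule(**r))
        return cls(
            boundary=int(d["boundary"]),
            pgm=PGModel.from_dict(d["pgm"]),
            paths=[TrajectoryPath(**p) for p in d["paths"]],
            item_ids=tuple(d["item_ids"]),
            rules=rules,
            rule_accuracies={k: float(v) for k, v in d["rule_accuracies"].items()},
            nir=float(d["nir"]),
            response_reference=d.get("response_reference", "scale_floor"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "FrozenModel":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    # -- prediction ----------------------------------------------------
    def predict_patient(
        self, baseline_items: np.ndarray, mid_items: np.ndarray,
        *, fallback_nonresponse: bool = False,
    ) -> tuple[str, PrognosisRule | None]:
        """Predict the end-of-acute-phase outcome from the first two
        visits only; returns ("uncovered", None) when no rule matches."""
        b0 = int(np.sum(baseline_items))
        a = "A1" if b0 <= self.boundary else "A2"
        b = assign_followup_stratum(int(np.sum(mid_items)), "mid")
        candidates = [r for r in self.rules if r.baseline == a and r.mid == b]
        if not candidates:
            return ("nonresponse" if fallback_nonresponse else "uncovered"), None
        candidates.sort(
            key=lambda r: -self.rule_accuracies.get(f"{r.baseline}-{r.mid}", 0.0)
        )
        for rule in candidates:
            idx = [i - 1 for i in rule.item_ids]
            impr = np.asarray(baseline_items)[idx] - np.asarray(mid_items)[idx]
            n_meet = int(
                (impr >= rule.delta).sum() if rule.direction == "at_least"
                else (impr <= rule.delta).sum()
            )
            if n_meet >= rule.min_items:
                return rule.predicted_outcome, rule
        return ("nonresponse" if fallback_nonresponse else "uncovered"), None


@dataclass
class TreatmentCourseResults:
    """Fitted artefacts of the five-step workflow."""

    model: TreatmentCourseModel
    mixture: BaselineMixture
    pgm: PGModel
    paths: list[TrajectoryPath]
    prognostic_symptoms: symptoms_mod.PrognosticSymptomSet
    nir: float
    rules: list[tuple[PrognosisRule, RuleEvaluation]]
    rule_summary: dict
    demographics: pd.DataFrame
    seed: int = 0

    # -- views ---------------------------------------------------------
    @property
    def rule_frame(self) -> pd.DataFrame:
        return rule_table_frame(self.rules)

    @property
    def path_frame(self) -> pd.DataFrame:
        return paths_to_frame(self.paths)

    def to_frozen(self) -> FrozenModel:
        return FrozenModel(
            boundary=self.mixture.boundary,
            pgm=self.pgm,
            paths=self.paths,
            item_ids=tuple(self.prognostic_symptoms.item_ids),
            rules=[r for r, _ in self.rules],
            rule_accuracies={
                f"{r.baseline}-{r.mid}": ev.accuracy for r, ev in self.rules
            },
            nir=self.nir,
            response_reference=self.model.config.response_reference,
        )

    def save(self, path: str | Path) -> None:
        self.to_frozen().save(path)

    def summary(self) -> str:
        mix = self.mixture
        lines = [
            "Severity-trajectory prognosis model",
            "=" * 60,
            f"training patients: {len(self.model.cohort)}   seed: {self.seed}",
            (
                f"baseline mixture: A1 ~ N({mix.means[0]:.1f}, {mix.sds[0]:.1f}) "
                f"w={mix.weights[0]:.2f} | A2 ~ N({mix.means[1]:.1f}, "
                f"{mix.sds[1]:.1f}) w={mix.weights[1]:.2f}"
            ),
            f"stratum boundary: A1 <= {mix.boundary} < A2",
            f"symptom dynamic paths ({len(self.paths)}):",
        ]
        for p in self.paths:
            lines.append(
                f"  {p.baseline}->{p.mid}->{p.end}  obs=({p.mid_observation[:4]},"
                f"{p.end_observation[:4]})  L={p.likelihood:.4f}  "
                f"n={p.n_on_path}  cov={p.coverage:.2f}"
            )
        labels = ", ".join(self.prognostic_symptoms.labels())
        lines.append(f"prognostic symptoms ({len(self.prognostic_symptoms.item_ids)}): {labels}")
        lines.append(f"NIR = {self.nir:.3f}")
        lines.append("rules:")
        with pd.option_context("display.width", 120):
            lines.append(self.rule_frame.round(3).to_string(index=False))
        s = self.rule_summary
        lines.append(
            f"mean accuracy {s['mean_accuracy']:.3f} | pooled coverage "
            f"{s['pooled_coverage']:.3f} | uncovered nonresponders "
            f"{s['uncovered_nonresponse_fraction']:.3f}"
        )
        return "\n".join(lines)

    # -- application to new cohorts -------------------------------------
    def predict(self, cohort: Cohort, *, fallback_nonresponse: bool | None = None):
        """Per-patient predictions (never reads the end visit)."""
        fb = (
            self.model.config.fallback_nonresponse
            if fallback_nonresponse is None
            else fallback_nonresponse
        )
        frozen = self.to_frozen()
        base = cohort.items("baseline")
        mid = cohort.items("mid")
        out = []
        for i in range(len(cohort)):
            pred, rule = frozen.predict_patient(base[i], mid[i], fallback_nonresponse=fb)
            out.append(
                {
                    "patient_id": cohort.frame.at[i, "patient_id"],
                    "predicted": pred,
                    "rule": f"{rule.baseline}-{rule.mid}" if rule else None,
                }
            )
        return pd.DataFrame(out)

    def replicate(self, cohort: Cohort) -> "ReplicationReport":
        """Evaluate the frozen rules on an independent labelled cohort."""
        return replication_report(self.to_frozen(), cohort)


@dataclass
class ReplicationReport:
    table: pd.DataFrame
    mean_accuracy: float
    pooled_coverage: float
    uncovered_nonresponse_fraction: float
    nir: float

    def summary(self) -> str:
        lines = ["Replication on testing cohort", "-" * 40]
        lines.append(self.table.round(3).to_string(index=False))
        lines.append(
            f"mean accuracy {self.mean_accuracy:.3f} | pooled coverage "
            f"{self.pooled_coverage:.3f} | uncovered nonresponders "
            f"{self.uncovered_nonresponse_fraction:.3f} (training NIR {self.nir:.2f})"
        )
        return "\n".join(lines)


def replication_report(frozen: FrozenModel, cohort: Cohort) -> ReplicationReport:
    """Apply frozen rules to a labelled testing cohort, reusing the
    training NIR for the exact binomial comparison."""
    report = validate_cohort(cohort)
    if not report.ok:
        raise ValueError("invalid testing cohort:\n" + report.summary())

    class _FrozenMixture:
        boundary = frozen.boundary

    mix = _FrozenMixture()
    evals = []
    uncovered = np.zeros(len(cohort), dtype=bool)
    a = np.array(
        ["A1" if t <= frozen.boundary else "A2" for t in cohort.totals("baseline")]
    )
    b = cohort.followup_strata("mid")
    o_end = cohort.outcomes("end", frozen.response_reference)
    for rule in frozen.rules:
        ev = evaluate_rule(
            rule, cohort, mix, frozen.nir,
            response_reference=frozen.response_reference,
        )
        evals.append((rule, ev))
        on_tr = (a == rule.baseline) & (b == rule.mid)
        uncovered |= on_tr & ~rule_met(cohort, rule)
    table = rule_table_frame(evals)
    accs = [ev.accuracy for _, ev in evals if ev.defined]
    n_unc = int(uncovered.sum())
    return ReplicationReport(
        table=table,
        mean_accuracy=float(np.mean(accs)) if accs else float("nan"),
        pooled_coverage=float(
            sum(ev.n_covered for _, ev in evals)
            / max(1, sum(ev.n_transition for _, ev in evals))
        ),
        uncovered_nonresponse_fraction=(
            float((o_end[uncovered] == "nonresponse").mean()) if n_unc else float("nan")
        ),
        nir=frozen.nir,
    )
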