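"""Calibration study: rerun the five-step pipeline on freshly generated
cohorts across seeds and pool the headline quantities.

This is the package's own reproduction harness: every number is computed
from scratch by generating a synthetic training cohort at the published
size (n=271), fitting the full model, and measuring the quantity of
interest; nothing is read from stored results.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .mixture import fit_baseline_mixture
from .model import PipelineConfig, PipelineError, TreatmentCourseModel
from .simulate import default_configs, draw_baseline_totals, generate_cohort


def _derived_seed(base_seed: int, i: int) -> int:
    return (base_seed * 100_003 + 7919 * i + 1) % (2**31 - 1)


def boundary_recovery(n_seeds: int = 20, base_seed: int = 0, n: int = 2000) -> dict:
    """Fit the baseline mixture on fresh draws of ``n`` totals per seed
    and report the modal integer stratum boundary."""
    cfg = default_configs()["training_fluoxetine"]
    boundaries = []
    for i in range(n_seeds):
        s = _derived_seed(base_seed, 1000 + i)
        rng = np.random.default_rng(s)
        totals = draw_baseline_totals(cfg, n, rng)
        boundaries.append(fit_baseline_mixture(totals, seed=s % 10_000).boundary)
    modal = Counter(boundaries).most_common(1)[0][0]
    return {"boundaries": boundaries, "modal": int(modal), "n": n}


def calibration_study(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """Generate ``n_seeds`` training cohorts, run Steps 1-4 on each, and
    pool path counts, band compositions, rule performance, NIR and the
    uncovered-patient outcome mix.
    """
    cfg = default_configs()["training_fluoxetine"]
    path_counts: list[int] = []
    band_mid = np.zeros(2)   # (response count, total) in the 29-39 bands
    band_high = np.zeros(2)  # (nonresponse count, total) in the >= 40 bands
    nir_counts = np.zeros(2)
    acc: dict[tuple[str, str], np.ndarray] = {}
    cov: dict[tuple[str, str], np.ndarray] = {}
    uncovered = np.zeros(2)
    mean_accs: list[float] = []
    failures = 0

    for i in range(n_seeds):
        s = _derived_seed(base_seed, i)
        cohort = generate_cohort(cfg, seed=s)
        model = TreatmentCourseModel(cohort, PipelineConfig(seed=s % 10_000))
        try:
            res = model.fit()
        except PipelineError:
            failures += 1
            continue
        path_counts.append(len(res.paths))

        for visit, band2, band3 in (("mid", "B2", "B3"), ("end", "C2", "C3")):
            strata = cohort.followup_strata(visit)
            outc = cohort.outcomes(visit)
            m2, m3 = strata == band2, strata == band3
            band_mid += [np.sum(m2 & (outc == "response")), m2.sum()]
            band_high += [np.sum(m3 & (outc == "nonresponse")), m3.sum()]

        mid_nr = cohort.outcomes("mid") == "nonresponse"
        nir_counts += [np.sum(mid_nr & (cohort.totals("end") >= 40)), mid_nr.sum()]

        accs_this = []
        for rule, ev in res.rules:
            key = (rule.baseline, rule.mid)
            acc.setdefault(key, np.zeros(2))[:] += [ev.n_correct, ev.n_covered]
            cov.setdefault(key, np.zeros(2))[:] += [ev.n_covered, ev.n_transition]
            if ev.defined:
                accs_this.append(ev.accuracy)
        if accs_this:
            mean_accs.append(float(np.mean(accs_this)))
        summ = res.rule_summary
        if summ["n_uncovered"]:
            uncovered += [
                summ["n_uncovered"] * summ["uncovered_nonresponse_fraction"],
                summ["n_uncovered"],
            ]

    n_ok = n_seeds - failures
    pooled_acc = {k: v[0] / max(v[1], 1) for k, v in acc.items()}
    pooled_cov = {k: v[0] / max(v[1], 1) for k, v in cov.items()}
    return {
        "n_seeds": n_seeds,
        "n_failed": failures,
        "path_counts": path_counts,
        "path_count_modal": int(Counter(path_counts).most_common(1)[0][0]),
        "band_mid_response": band_mid[0] / band_mid[1],
        "band_mid_n": band_mid[1] / n_ok,
        "band_high_nonresponse": band_high[0] / band_high[1],
        "band_high_n": band_high[1] / n_ok,
        "accuracy": pooled_acc,
        "accuracy_n": {k: v[1] / n_ok for k, v in acc.items()},
        "coverage": pooled_cov,
        "min_coverage": min(pooled_cov.values()) if pooled_cov else float("nan"),
        "min_coverage_n": min(v[1] / n_ok for v in cov.values()) if cov else 0,
        "mean_accuracy": float(np.mean(mean_accs)) if mean_accs else float("nan"),
        "nir": nir_counts[0] / nir_counts[1],
        "nir_n": nir_counts[1] / n_ok,
        "uncovered_nonresponse": uncovered[0] / uncovered[1],
        "uncovered_n": uncovered[1] / n_ok,
    }


def binomial_band(p: float, n: float, k: float = 3.0) -> float:
    """k standard errors of a binomial proportion at problem size n."""
    return k * float(np.sqrt(p * (1 - p) / n))
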