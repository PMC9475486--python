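"""Severity-strata chain model and forward-algorithm path selection.

The model is a three-visit hidden-Markov-style chain whose hidden states
are severity strata (A1/A2 at baseline, B1-B3 at weeks 4-6, C1-C3 at
weeks 10-12) and whose observations are categorical treatment outcomes
(remission / response / nonresponse) emitted at the two follow-up visits.
With only completers and observed strata, every table is estimated as a
count fraction; the forward algorithm then scores each labelled path

    pi[a] * T1[a,b] * E_mid[b,o_mid] * T2[b,c] * E_end[c,o_end]

and "symptom dynamic paths" are the strata trajectories traversed by at
least ``min_coverage`` of their baseline stratum's patients.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import Cohort
from .mixture import BaselineMixture, assign_baseline_stratum
from .scale import BASELINE_STRATA, MID_STRATA, END_STRATA, OUTCOMES

_A = list(BASELINE_STRATA)
_B = list(MID_STRATA)
_C = list(END_STRATA)
_O = list(OUTCOMES)


def _fractions(counts: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Row-normalise integer counts; zero rows become uniform and are flagged."""
    counts = np.asarray(counts, dtype=float)
    probs = np.empty_like(counts)
    flagged = []
    for i, row in enumerate(counts):
        s = row.sum()
        if s == 0:
            probs[i] = 1.0 / row.size
            flagged.append(i)
        else:
            probs[i] = row / s
    return probs, flagged


@dataclass
class PGModel:
    """Estimated probability tables with their raw integer counts.

    ``pi`` is over (A1, A2); ``T1`` is 2x3 over B given A; ``T2`` is 3x3
    over C given B (pooled over baseline strata by default); ``E_mid`` and
    ``E_end`` are 3x3 outcome-emission tables over (remission, response,
    nonresponse) given the follow-up stratum.
    """

    pi: np.ndarray
    T1: np.ndarray
    T2: np.ndarray
    E_mid: np.ndarray
    E_end: np.ndarray
    counts: dict[str, np.ndarray]
    uniform_rows: dict[str, list[int]] = field(default_factory=dict)
    T2_by_baseline: np.ndarray | None = None  # (2,3,3) when stratified

    def validate(self, atol: float = 1e-9) -> None:
        for name in ("T1", "T2", "E_mid", "E_end"):
            mat = getattr(self, name)
            if not np.allclose(mat.sum(axis=1), 1.0, atol=atol):
                raise ValueError(f"{name} rows do not sum to 1")
        if not np.isclose(self.pi.sum(), 1.0, atol=atol):
            raise ValueError("pi does not sum to 1")

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "pi": self.pi.tolist(),
            "T1": self.T1.tolist(),
            "T2": self.T2.tolist(),
            "E_mid": self.E_mid.tolist(),
            "E_end": self.E_end.tolist(),
            "counts": {k: np.asarray(v).tolist() for k, v in self.counts.items()},
            "uniform_rows": self.uniform_rows,
        }
        if self.T2_by_baseline is not None:
            d["T2_by_baseline"] = self.T2_by_baseline.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PGModel":
        return cls(
            pi=np.asarray(d["pi"], dtype=float),
            T1=np.asarray(d["T1"], dtype=float),
            T2=np.asarray(d["T2"], dtype=float),
            E_mid=np.asarray(d["E_mid"], dtype=float),
            E_end=np.asarray(d["E_end"], dtype=float),
            counts={k: np.asarray(v, dtype=int) for k, v in d["counts"].items()},
            uniform_rows={k: list(v) for k, v in d.get("uniform_rows", {}).items()},
            T2_by_baseline=(
                np.asarray(d["T2_by_baseline"], dtype=float)
                if "T2_by_baseline" in d
                else None
            ),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "PGModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class TrajectoryPath:
    """A (baseline, mid, end) strata trajectory with modal observations."""

    baseline: str
    mid: str
    end: str
    mid_observation: str
    end_observation: str
    likelihood: float
    n_on_path: int
    coverage: float


def estimate_pgm(
    cohort: Cohort,
    mixture: BaselineMixture,
    *,
    stratify_t2: bool = False,
    response_reference: str = "scale_floor",
) -> PGModel:
    """Estimate every table as a count fraction from a labelled cohort."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    a = np.array(
        [assign_baseline_stratum(int(t), mixture) for t in cohort.totals("baseline")]
    )
    b = cohort.followup_strata("mid")
    c = cohort.followup_strata("end")
    o_mid = cohort.outcomes("mid", response_reference)
    o_end = cohort.outcomes("end", response_reference)

    pi_counts = np.array([(a == s).sum() for s in _A])
    t1_counts = np.array([[((a == s) & (b == u)).sum() for u in _B] for s in _A])
    t2_counts = np.array([[((b == u) & (c == v)).sum() for v in _C] for u in _B])
    em_counts = np.array([[((b == u) & (o_mid == o)).sum() for o in _O] for u in _B])
    ee_counts = np.array([[((c == v) & (o_end == o)).sum() for o in _O] for v in _C])

    pi = pi_counts / pi_counts.sum()
    T1, f1 = _fractions(t1_counts)
    T2, f2 = _fractions(t2_counts)
    E_mid, fm = _fractions(em_counts)
    E_end, fe = _fractions(ee_counts)

    t2b = None
    counts = {
        "pi": pi_counts,
        "T1": t1_counts,
        "T2": t2_counts,
        "E_mid": em_counts,
        "E_end": ee_counts,
    }
    if stratify_t2:
        t2b_counts = np.array(
            [
                [[((a == s) & (b == u) & (c == v)).sum() for v in _C] for u in _B]
                for s in _A
            ]
        )
        t2b = np.stack([_fractions(m)[0] for m in t2b_counts])
        counts["T2_by_baseline"] = t2b_counts

    model = PGModel(
        pi=pi,
        T1=T1,
        T2=T2,
        E_mid=E_mid,
        E_end=E_end,
        counts=counts,
        uniform_rows={"T1": f1, "T2": f2, "E_mid": fm, "E_end": fe},
        T2_by_baseline=t2b,
    )
    model.validate()
    return model


def path_likelihood(model: PGModel, path: tuple[str, str, str, str, str]) -> float:
    """Forward-algorithm likelihood of one fully labelled path.

    ``path`` is (baseline stratum, mid stratum, end stratum, mid
    observation, end observation).  The 162 labelled paths sum to 1.
    """
    a, b, c, o_mid, o_end = path
    try:
        ia, ib, ic = _A.index(a), _B.index(b), _C.index(c)
        im, ie = _O.index(o_mid), _O.index(o_end)
    except ValueError as exc:
        raise ValueError(f"unknown stratum or observation label in {path}") from exc
    t2 = model.T2[ib, ic]
    if model.T2_by_baseline is not None:
        t2 = model.T2_by_baseline[ia, ib, ic]
    return float(
        model.pi[ia]
        * model.T1[ia, ib]
        * model.E_mid[ib, im]
        * t2
        * model.E_end[ic, ie]
    )


def enumerate_labelled_paths() -> list[tuple[str, str, str, str, str]]:
    """All 2x3x3x3x3 = 162 labelled paths in canonical order."""
    return list(itertools.product(_A, _B, _C, _O, _O))


def forward_predict(model: PGModel, a: str, b: str, o_mid: str) -> np.ndarray:
    """Distribution over end strata given baseline stratum, mid stratum
    and the mid observation; ties in the argmax break toward lower
    severity (the caller takes ``argmax`` of the returned vector, which
    numpy resolves to the first, i.e. least severe, stratum).
    """
    ia, ib = _A.index(a), _B.index(b)
    im = _O.index(o_mid)
    mass = model.pi[ia] * model.T1[ia, ib] * model.E_mid[ib, im]
    if mass == 0:
        raise ValueError(
            f"conditioning event (baseline={a}, mid={b}, obs={o_mid}) has "
            "zero probability in the estimated model"
        )
    row = model.T2[ib] if model.T2_by_baseline is None else model.T2_by_baseline[ia, ib]
    return row / row.sum()


def most_likely_end_stratum(model: PGModel, a: str, b: str, o_mid: str) -> str:
    return _C[int(np.argmax(forward_predict(model, a, b, o_mid)))]


def count_possible_paths(
    n_baseline_strata: int, n_followup_strata: int, n_followup_visits: int
) -> int:
    """Number of strata trajectories: N_baseline * N_followup^visits."""
    if min(n_baseline_strata, n_followup_strata, n_followup_visits) < 1:
        raise ValueError("arguments must be positive integers")
    return n_baseline_strata * n_followup_strata**n_followup_visits


def _modal(values: np.ndarray) -> str:
    """Most frequent label, ties toward the canonical outcome order."""
    if values.size == 0:
        return _O[2]
    uniq, cnt = np.unique(values, return_counts=True)
    order = {o: i for i, o in enumerate(_O)}
    best = sorted(zip(uniq, cnt), key=lambda t: (-t[1], order.get(t[0], 99)))
    return str(best[0][0])


def select_symptom_dynamic_paths(
    model: PGModel,
    cohort: Cohort,
    mixture: BaselineMixture,
    min_coverage: float = 0.10,
    *,
    selection_mode: str = "coverage_only",
    response_reference: str = "scale_floor",
) -> list[TrajectoryPath]:
    """Select the symptom dynamic paths.

    Enumerates the 18 strata trajectories, counts the training patients
    whose (baseline, mid, end) strata match, and keeps those traversed by
    at least ``min_coverage`` of the patients in the path's baseline
    stratum.  ``selection_mode="argmax_plus_coverage"`` additionally
    restricts to the highest-likelihood path within each (baseline, end)
    pair.  Observations attached to a selected path are the modal outcome
    labels of the patients on it; output is sorted by likelihood
    descending with ties broken toward lower severity.
    """
    if selection_mode not in ("coverage_only", "argmax_plus_coverage"):
        raise ValueError(f"unknown selection_mode {selection_mode!r}")
    a = np.array(
        [assign_baseline_stratum(int(t), mixture) for t in cohort.totals("baseline")]
    )
    b = cohort.followup_strata("mid")
    c = cohort.followup_strata("end")
    o_mid = cohort.outcomes("mid", response_reference)
    o_end = cohort.outcomes("end", response_reference)

    denom = {s: int((a == s).sum()) for s in _A}
    if all(v == 0 for v in denom.values()):
        raise ValueError("empty cohort: no baseline strata populated")

    paths: list[TrajectoryPath] = []
    for sa, sb, sc in itertools.product(_A, _B, _C):
        if denom[sa] == 0:
            continue  # no patients start here; its paths have no coverage
        on = (a == sa) & (b == sb) & (c == sc)
        n = int(on.sum())
        cov = n / denom[sa]
        mo, eo = _modal(o_mid[on]), _modal(o_end[on])
        lik = path_likelihood(model, (sa, sb, sc, mo, eo))
        paths.append(TrajectoryPath(sa, sb, sc, mo, eo, lik, n, cov))

    selected = [p for p in paths if p.coverage >= min_coverage]
    if selection_mode == "argmax_plus_coverage":
        best: dict[tuple[str, str], TrajectoryPath] = {}
        for p in selected:
            key = (p.baseline, p.end)
            cur = best.get(key)
            if cur is None or _path_sort_key(p) < _path_sort_key(cur):
                best[key] = p
        selected = list(best.values())
    selected.sort(key=_path_sort_key)
    return selected


def _path_sort_key(p: TrajectoryPath):
    # likelihood descending, then lower severity, then lexicographic
    return (-p.likelihood, p.mid, p.end, p.baseline)


def paths_to_frame(paths: list[TrajectoryPath]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "baseline": p.baseline,
                "mid": p.mid,
                "end": p.end,
                "mid_obs": p.mid_observation,
                "end_obs": p.end_observation,
                "likelihood": p.likelihood,
                "n": p.n_on_path,
                "coverage": p.coverage,
            }
            for p in paths
        ]
    )
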