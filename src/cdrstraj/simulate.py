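"""Seeded synthetic cohorts with the statistical structure of acute
antidepressant trials in depressed youth.

The generator emulates, patient by patient, the joint structure the
analysis pipeline assumes: a two-component baseline severity mixture
(boundary 55/56), stratum-to-stratum transition frequencies matching the
published training counts, a latent early-change flag whose rate is each
transition's rule coverage, end-of-acute-phase outcomes drawn
conditionally on that flag at the published rule accuracies, and 17-item
score allocations in which exactly six planted items (difficulty having
fun, social withdrawal, excessive fatigue, irritability, low self-esteem,
depressed feelings) carry the path-discriminating early change.  In
``placebo_mode`` all item-path association is removed and outcomes are
drawn independently of item changes.

Every quantity is drawn from a single ``numpy`` Generator, so cohorts are
bit-reproducible from the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._alloc import allocate_excess, bounded_adjust_sum
from .cohort import Cohort, ITEM_COLS, META_COLS
from .scale import ITEM_MAXES, N_ITEMS, REMISSION_CUT, TOTAL_MIN

log = logging.getLogger(__name__)

#: Planted prognostic items (1-based CDRS-R ids).
PROGNOSTIC_ITEMS = (2, 3, 6, 8, 10, 11)
#: Non-prognostic item groups used by the allocation plans.
GROUP_1 = (1, 7, 9, 12, 13)   # schoolwork, physical, guilt, morbid, suicidal
GROUP_2 = (14, 15, 17)        # weeping, facial affect, hypoactivity
GROUP_3 = (4, 5, 16)          # the 1-5 observational items

_OUTCOMES = ("remission", "response", "nonresponse")


@dataclass(frozen=True)
class RowPlan:
    """Per-(baseline, mid) transition parameters of the generator."""

    coverage: float                 # P(early-change flag)
    predicted: str                  # rule's target outcome
    direction: str                  # at_least | at_most
    delta: int                      # per-item change threshold
    min_items: int                  # planted minimum symptom count
    sat_split: dict[str, float]     # outcome dist given flag
    unsat_split: dict[str, float]   # outcome dist given no flag
    k_spread: float = 0.0           # P(each extra item beyond min_items changes too)


@dataclass(frozen=True)
class GeneratorConfig:
    n: int
    arm: str
    seed: int = 0
    # baseline mixture (weights/means/sds; components truncated to their
    # stratum's integer range so generated strata match the 55/56 boundary)
    w_a2: float = 156 / 271
    mean_a1: float = 49.0
    sd_a1: float = 4.5
    range_a1: tuple[int, int] = (40, 54)
    mean_a2: float = 65.0
    sd_a2: float = 5.0
    range_a2: tuple[int, int] = (57, 113)
    # transitions (B1, B2, B3) given baseline stratum
    t_a1: tuple[float, float, float] = (27 / 115, 42 / 115, 46 / 115)
    t_a2: tuple[float, float, float] = (35 / 156, 38 / 156, 83 / 156)
    rows: dict = field(default_factory=dict)
    prognostic_items: tuple[int, ...] = PROGNOSTIC_ITEMS
    placebo_mode: bool = False
    # within-band draw dials (calibrated once against the printed
    # band-composition figures; see docs/methods.md)
    p_midresp_b3: float = 0.18   # eligible high-baseline B3 nonresponders rated responders at mid
    q_nr_c2: float = 0.10        # end nonresponders drawn into the 29-39 band when feasible
    resp_c3_cap: float = 0.32    # fraction of high-baseline responders capped below 40 at end
    balanced: bool = True        # quota sampling of the discrete layers
    k_extra_p: float = 0.0       # extra items beyond min_items for flagged patients
    # demographics (independent of outcome unless the knob is set)
    age_mean: float = 14.5
    age_sd: float = 1.8
    age_shift_nonresponse: float = 0.0
    p_female: float = 0.55
    race_probs: tuple[float, float, float] = (0.74, 0.12, 0.14)


# ---------------------------------------------------------------------------
# default (calibrated) configurations

def _training_rows() -> dict:
    return {
        ("A2", "B3"): RowPlan(0.80, "nonresponse", "at_most", 2, 4,
                              {"nonresponse": .62, "response": .32, "remission": .06},
                              {"nonresponse": .95, "response": .03, "remission": .02},
                              k_spread=0.35),
        ("A2", "B2"): RowPlan(0.92, "response", "at_least", 2, 3,
                              {"response": .86, "remission": .09, "nonresponse": .05},
                              {"nonresponse": .97, "response": .02, "remission": .01},
                              k_spread=0.5),
        ("A2", "B1"): RowPlan(0.97, "remission", "at_least", 3, 4,
                              {"remission": .67, "response": .28, "nonresponse": .05},
                              {"nonresponse": .97, "response": .02, "remission": .01}),
        ("A1", "B3"): RowPlan(0.71, "nonresponse", "at_most", 1, 5,
                              {"nonresponse": .66, "response": .16, "remission": .18},
                              {"nonresponse": .97, "response": .02, "remission": .01}),
        ("A1", "B2"): RowPlan(0.73, "response", "at_least", 1, 4,
                              {"response": .84, "remission": .13, "nonresponse": .03},
                              {"nonresponse": .62, "response": .28, "remission": .10}),
        ("A1", "B1"): RowPlan(0.77, "remission", "at_least", 2, 4,
                              {"remission": .72, "response": .23, "nonresponse": .05},
                              {"nonresponse": .97, "response": .02, "remission": .01}),
    }


def _duloxetine_rows() -> dict:
    return {
        ("A2", "B3"): RowPlan(0.80, "nonresponse", "at_most", 2, 4,
                              {"nonresponse": .63, "response": .31, "remission": .06},
                              {"nonresponse": .93, "response": .05, "remission": .02},
                              k_spread=0.35),
        ("A2", "B2"): RowPlan(0.92, "response", "at_least", 2, 3,
                              {"response": .84, "remission": .11, "nonresponse": .05},
                              {"nonresponse": .95, "response": .03, "remission": .02},
                              k_spread=0.5),
        ("A2", "B1"): RowPlan(0.97, "remission", "at_least", 3, 4,
                              {"remission": .78, "response": .18, "nonresponse": .04},
                              {"nonresponse": .95, "response": .03, "remission": .02}),
        ("A1", "B3"): RowPlan(0.77, "nonresponse", "at_most", 1, 5,
                              {"nonresponse": .70, "response": .18, "remission": .12},
                              {"nonresponse": .95, "response": .03, "remission": .02}),
        ("A1", "B2"): RowPlan(0.78, "response", "at_least", 1, 4,
                              {"response": .84, "remission": .13, "nonresponse": .03},
                              {"nonresponse": .70, "response": .20, "remission": .10}),
        ("A1", "B1"): RowPlan(0.80, "remission", "at_least", 2, 4,
                              {"remission": .70, "response": .25, "nonresponse": .05},
                              {"nonresponse": .95, "response": .03, "remission": .02}),
    }


def _placebo_rows() -> dict:
    # no flag/outcome association: both splits identical
    splits = {
        ("A2", "B3"): {"nonresponse": .50, "response": .35, "remission": .15},
        ("A2", "B2"): {"response": .80, "remission": .12, "nonresponse": .08},
        ("A2", "B1"): {"remission": .72, "response": .23, "nonresponse": .05},
        ("A1", "B3"): {"nonresponse": .45, "response": .35, "remission": .20},
        ("A1", "B2"): {"response": .78, "remission": .14, "nonresponse": .08},
        ("A1", "B1"): {"remission": .70, "response": .25, "nonresponse": .05},
    }
    rows = {}
    for key, split in splits.items():
        rows[key] = RowPlan(0.75, "nonresponse", "at_most", 1, 4, split, dict(split))
    return rows


def default_configs() -> dict[str, GeneratorConfig]:
    """The three named study cohorts the pipeline is calibrated on."""
    return {
        "training_fluoxetine": GeneratorConfig(n=271, arm="fluoxetine", rows=_training_rows()),
        "testing_duloxetine": GeneratorConfig(n=255, arm="duloxetine", rows=_duloxetine_rows()),
        "testing_placebo": GeneratorConfig(
            n=265, arm="placebo", rows=_placebo_rows(), placebo_mode=True
        ),
    }


# ---------------------------------------------------------------------------
# item allocation plans: relative excess weights per item group, chosen so
# that the six planted items always form an isolated top-severity cluster
# while the non-prognostic groups regroup between visits (see methods note)

def _plan(groups: dict[tuple[int, ...], float], items=None) -> np.ndarray:
    w = np.zeros(N_ITEMS)
    for ids, weight in groups.items():
        for i in ids:
            w[i - 1] = weight
    return w

# mid-visit plans are keyed by the baseline stratum too: the severity
# budget left for non-prognostic items differs a lot between A1 and A2
# trajectories, and the bands must stay clear of the planted items
NONPROG_PLANS = {
    ("baseline", "A1"): _plan({GROUP_1: 0.8, GROUP_2: 1.0, GROUP_3: 0.8}),
    ("baseline", "A2"): _plan({GROUP_1: 1.0, GROUP_2: 1.0, GROUP_3: 0.8}),
    ("mid", "B1", "A1"): _plan({GROUP_1: 0.02, GROUP_2: 0.02, GROUP_3: 0.02}),
    ("mid", "B1", "A2"): _plan({GROUP_1: 0.02, GROUP_2: 0.02, GROUP_3: 0.02}),
    ("mid", "B2", "A1"): _plan({GROUP_1: 0.60, GROUP_2: 0.70, GROUP_3: 0.05}),
    ("mid", "B2", "A2"): _plan({GROUP_1: 0.60, GROUP_2: 0.70, GROUP_3: 0.05}),
    # high-baseline nonresponders keep schoolwork/physical complaints and
    # the vegetative items severe; lower-baseline ones only the vegetative
    ("mid", "B3", "A2"): _plan({(1, 7): 3.0, (9, 12, 13): 0.05,
                                GROUP_2: 0.05, GROUP_3: 3.2}),
    ("mid", "B3", "A1"): _plan({(1, 7): 0.05, (9, 12, 13): 0.05,
                                GROUP_2: 0.05, GROUP_3: 3.2}),
}
# end visits pin the planted items to narrow per-item severity levels
# (residual severity tracks the end stratum); the remainder is allocated
# over the other items by these weights
END_NONPROG_PLANS = {
    "C1": _plan({GROUP_1: 0.04, GROUP_2: 0.04, GROUP_3: 0.04}),
    "C2": _plan({GROUP_1: 0.35, GROUP_2: 0.45, GROUP_3: 0.20}),
    "C3": _plan({GROUP_1: 0.50, GROUP_2: 0.60, GROUP_3: 0.40}),
}
FLAT_PLAN = _plan({tuple(range(1, 18)): 1.0, GROUP_3: 0.55})
#: placebo cohorts have no planted prognostic structure, but the
#: vegetative items still stay severe in persistently-depressed patients,
#: which is what breaks item-cluster stability across visits there
PLACEBO_B3_PLAN = _plan({tuple(range(1, 18)): 1.0, GROUP_3: 3.2})

_MAXES = np.array(ITEM_MAXES)


class GenerationError(RuntimeError):
    pass


def allocate_items(
    total: int,
    visit: str,
    profile: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    fixed: dict[int, int] | None = None,
) -> np.ndarray:
    """Allocate a visit total across the 17 items.

    ``profile`` gives relative excess weights (defaults to a flat
    profile); ``fixed`` pins individual item scores (1-based ids).  The
    returned scores always sum exactly to ``total`` and respect each
    item's scale range; infeasible demands raise :class:`GenerationError`.
    """
    rng = rng or np.random.default_rng()
    w = FLAT_PLAN.copy() if profile is None else np.asarray(profile, dtype=float).copy()
    scores = np.ones(N_ITEMS, dtype=int)
    caps = _MAXES - 1
    if fixed:
        for item_id, sc in fixed.items():
            scores[item_id - 1] = sc
            caps = caps.copy()
            caps[item_id - 1] = 0
            w[item_id - 1] = 0.0
    budget = total - int(scores.sum())
    if budget < 0 or budget > caps.sum():
        raise GenerationError(
            f"total {total} infeasible given fixed scores at {visit} visit"
        )
    return scores + allocate_excess(budget, w, caps, rng)


# ---------------------------------------------------------------------------
# per-patient machinery

def _draw_truncnorm_int(rng, mean, sd, lo, hi) -> int:
    for _ in range(1000):
        v = int(round(rng.normal(mean, sd)))
        if lo <= v <= hi:
            return v
    raise GenerationError("truncated normal rejection loop exhausted")


def _draw_split(rng, split: dict[str, float]) -> str:
    labels = list(split)
    return labels[rng.choice(len(labels), p=np.array([split[l] for l in labels]))]


def _tstar(b0: int) -> int:
    return (b0 + TOTAL_MIN) // 2


def _uniform(rng, lo, hi) -> int:
    if lo > hi:
        raise GenerationError(f"empty draw region [{lo}, {hi}]")
    return int(rng.integers(lo, hi + 1))


def _mid_region(cfg, a, mid, b0, outcome, rng) -> tuple[int, int]:
    """Score region for the mid total inside the drawn stratum band."""
    ts = _tstar(b0)
    if mid == "B1":
        # remitted totals concentrate just under the cut so the planted
        # items keep a visible severity margin over the rest
        return (REMISSION_CUT - 4, REMISSION_CUT)
    if mid == "B2":
        nr = (max(29, ts + 1), 39)
        resp = (29, min(39, ts))
        if a == "A1":
            return nr
        if outcome == "response" and ts <= 38:  # b0 <= 60: rate a responder as still lagging
            return nr
        return resp if resp[0] <= resp[1] else nr
    # B3
    hi = max(b0, 40)
    if (
        not cfg.placebo_mode
        and outcome == "nonresponse"
        and ts >= 40
        and rng.random() < cfg.p_midresp_b3
    ):
        return (40, ts)
    return (max(40, ts + 1), hi)


def _end_total(cfg, b0, outcome, rng) -> int:
    ts = _tstar(b0)
    if outcome == "remission":
        return _uniform(rng, REMISSION_CUT - 4, REMISSION_CUT)
    if outcome == "response":
        hi = 39 if (ts > 39 and rng.random() < cfg.resp_c3_cap) else ts
        return _uniform(rng, 29, hi)
    sub40 = (max(29, ts + 1), 39)
    if sub40[0] <= sub40[1] and rng.random() < cfg.q_nr_c2:
        return _uniform(rng, *sub40)
    return _uniform(rng, max(40, ts + 1), max(b0, 40))


def _prog_ranges(base: np.ndarray, meeting: np.ndarray, direction: str, delta: int):
    """Admissible mid-score range per prognostic item given its planted
    meeting/non-meeting status."""
    lows = np.empty_like(base)
    highs = np.empty_like(base)
    for i, (b, m) in enumerate(zip(base, meeting)):
        if direction == "at_least":
            if m:
                lows[i], highs[i] = 1, b - delta
            else:
                lows[i], highs[i] = max(1, b - delta + 1), b
        else:
            if m:
                lows[i], highs[i] = max(1, b - delta), b
            else:
                lows[i], highs[i] = 1, b - delta - 1
    if (lows > highs).any():
        raise GenerationError("inconsistent prognostic score ranges")
    return lows, highs


def _preferred_mid_scores(rng, base, meeting, direction, delta, lows, highs):
    scores = np.empty_like(base)
    for i, (b, m) in enumerate(zip(base, meeting)):
        if direction == "at_least":
            impr = delta + (1 if (rng.random() < 0.35 and b - delta - 1 >= 1) else 0) if m else (
                delta - 1 if (delta >= 1 and rng.random() < 0.6) else int(rng.integers(0, max(1, delta)))
            )
        else:
            if m:
                probs = {1: [.45, .55], 2: [.15, .35, .50], 3: [.05, .15, .30, .50]}[delta]
                impr = int(rng.choice(delta + 1, p=probs))
            else:
                impr = delta + 1 + (1 if rng.random() < 0.3 else 0)
        scores[i] = int(np.clip(b - impr, lows[i], highs[i]))
    return scores


def _patient_items(cfg, rng, a, b0, mid, t_mid, t_end, end_stratum, sat, rotation=0):
    """Baseline/mid/end item score triplets for one drug-arm patient."""
    prog = np.array(cfg.prognostic_items)
    row = cfg.rows[(a, mid)]
    level = 5 if a == "A2" else 4
    # balanced multiset: per-item baseline severities equalise across the
    # cohort, keeping the planted cluster tight
    base_prog = level + rng.permutation([-1, 0, 0, 0, 0, 1])

    # keep the baseline feasible: non-prognostic items need >= 11 points
    while base_prog.sum() > b0 - 11 - 0:
        cand = np.flatnonzero(base_prog > level - 1)
        if cand.size == 0:
            cand = np.flatnonzero(base_prog > 3)
        base_prog[cand[rng.integers(cand.size)]] -= 1
    base = allocate_items(
        b0, "baseline",
        profile=NONPROG_PLANS[("baseline", a)], rng=rng,
        fixed={int(i): int(s) for i, s in zip(prog, base_prog)},
    )

    # mid: planted improvements for the prognostic items
    m = row.min_items
    k = (m - 1) if not sat else m + int(rng.binomial(prog.size - m, row.k_spread))
    for k_try in _k_candidates(k, m, prog.size, sat):
        # contiguous window rotating across patients: every planted item
        # carries the early change equally often
        meeting = np.zeros(prog.size, dtype=bool)
        meeting[(rotation + np.arange(k_try)) % prog.size] = True
        lows, highs = _prog_ranges(base_prog, meeting, row.direction, row.delta)
        lo_t = max(int(lows.sum()), t_mid - 71)
        hi_t = min(int(highs.sum()), t_mid - 11)
        if mid in ("B1", "B2"):
            # remitted/intermediate totals: push the planted items to the
            # top of their admissible budget so the other items stay near
            # the scale floor (keeps the planted cluster separated)
            lo_t = hi_t
        if lo_t <= hi_t and hi_t >= int(lows.sum()):
            scores = _preferred_mid_scores(
                rng, base_prog, meeting, row.direction, row.delta, lows, highs
            )
            scores = bounded_adjust_sum(scores, lows, highs, lo_t, hi_t, rng)
            mid_items = allocate_items(
                t_mid, "mid",
                profile=NONPROG_PLANS[("mid", mid, a)], rng=rng,
                fixed={int(i): int(s) for i, s in zip(prog, scores)},
            )
            break
    else:
        raise GenerationError(
            f"no feasible prognostic allocation for {a}->{mid} total {t_mid}"
        )

    end_items = _end_items(cfg, rng, a, t_end, end_stratum)
    return base, mid_items, end_items


def _end_prog_level(rng, a: str, end_stratum: str) -> np.ndarray:
    n = len(PROGNOSTIC_ITEMS)
    if end_stratum == "C1":
        return 2 + rng.choice([0, 1], size=n, p=[.75, .25])
    if end_stratum == "C2":
        return 3 + rng.choice([-1, 0, 1], size=n, p=[.2, .6, .2])
    level = 5 if a == "A2" else 4
    return level + rng.choice([-1, 0, 1], size=n, p=[.25, .5, .25])


def _end_items(cfg, rng, a, t_end, end_stratum) -> np.ndarray:
    prog = np.array(cfg.prognostic_items)
    scores = _end_prog_level(rng, a, end_stratum)
    while scores.sum() > t_end - 11:
        cand = np.flatnonzero(scores > 1)
        scores[cand[rng.integers(cand.size)]] -= 1
    return allocate_items(
        t_end, "end",
        profile=END_NONPROG_PLANS[end_stratum], rng=rng,
        fixed={int(i): int(sc) for i, sc in zip(prog, scores)},
    )


def _k_candidates(k_first: int, m: int, n_items: int, sat: bool):
    if not sat:
        return [m - 1]
    rest = [k for k in range(m, n_items + 1) if k != k_first]
    return [k_first] + rest


def _demographics(cfg, rng, outcome):
    age = float(np.clip(round(rng.normal(cfg.age_mean, cfg.age_sd)), 8, 17))
    if cfg.age_shift_nonresponse and outcome == "nonresponse":
        age = float(np.clip(age + cfg.age_shift_nonresponse, 8, 20))
    sex = "female" if rng.random() < cfg.p_female else "male"
    race = ("white", "black", "other")[rng.choice(3, p=np.array(cfg.race_probs))]
    return age, sex, race


def draw_baseline_totals(
    config: GeneratorConfig, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n baseline totals from the calibrated two-component mixture
    (used on its own for boundary-recovery checks)."""
    out = np.empty(n, dtype=int)
    for i in range(n):
        if rng.random() < config.w_a2:
            out[i] = _draw_truncnorm_int(
                rng, config.mean_a2, config.sd_a2, *config.range_a2
            )
        else:
            out[i] = _draw_truncnorm_int(
                rng, config.mean_a1, config.sd_a1, *config.range_a1
            )
    return out


def _quota_counts(n: int, probs) -> np.ndarray:
    """Largest-remainder apportionment of n units to the given fractions."""
    probs = np.asarray(probs, dtype=float)
    base = np.floor(n * probs).astype(int)
    rem = n - int(base.sum())
    if rem > 0:
        frac = n * probs - base
        base[np.argsort(-frac)[:rem]] += 1
    return base


def _quota_assign(rng: np.random.Generator, n: int, probs) -> np.ndarray:
    """Shuffled category indices with exact largest-remainder counts."""
    arr = np.repeat(np.arange(len(probs)), _quota_counts(n, probs))
    rng.shuffle(arr)
    return arr


def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> Cohort:
    """Generate one seeded synthetic cohort as a :class:`Cohort`.

    The same (config, seed) pair always reproduces the identical cohort.
    The discrete layers (baseline stratum, stratum transition, early-change
    flag, end outcome) are assigned by balanced quota sampling, so their
    marginal fractions match the configured probabilities exactly at any
    cohort size (``balanced=False`` reverts to independent draws); severity
    totals, item allocations and demographics remain stochastic.
    Infeasible outcome/severity combinations (a response band that is
    empty at the lowest baselines) are resolved by relabelling to
    remission, with a debug-logged count.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    strata_b = ("B1", "B2", "B3")
    n = config.n

    if config.balanced:
        a_idx = _quota_assign(rng, n, [1 - config.w_a2, config.w_a2])
    else:
        a_idx = (rng.random(n) < config.w_a2).astype(int)
    a_lab = np.where(a_idx == 1, "A2", "A1")

    mid_lab = np.empty(n, dtype=object)
    for s_idx, label in ((0, "A1"), (1, "A2")):
        idx = np.flatnonzero(a_idx == s_idx)
        t = config.t_a1 if label == "A1" else config.t_a2
        if config.balanced:
            picks = _quota_assign(rng, idx.size, t)
        else:
            picks = rng.choice(3, size=idx.size, p=np.asarray(t))
        mid_lab[idx] = [strata_b[j] for j in picks]

    sat = np.zeros(n, dtype=bool)
    outcome = np.empty(n, dtype=object)
    for (sa, sb), row in config.rows.items():
        on = np.flatnonzero((a_lab == sa) & (mid_lab == sb))
        if on.size == 0:
            continue
        if config.balanced:
            n_sat = int(round(row.coverage * on.size))
            chosen = rng.permutation(on)[:n_sat]
            sat[chosen] = True
            for flag in (True, False):
                cell = on[sat[on] == flag]
                split = row.sat_split if flag else row.unsat_split
                probs = [split.get(o, 0.0) for o in _OUTCOMES]
                outcome[cell] = [
                    _OUTCOMES[j] for j in _quota_assign(rng, cell.size, probs)
                ]
        else:
            sat[on] = rng.random(on.size) < row.coverage
            for i in on:
                outcome[i] = _draw_split(
                    rng, row.sat_split if sat[i] else row.unsat_split
                )

    records = []
    n_relabelled = 0
    for i in range(n):
        a, mid, o, is_sat = a_lab[i], mid_lab[i], outcome[i], bool(sat[i])
        if a == "A1":
            b0 = _draw_truncnorm_int(rng, config.mean_a1, config.sd_a1, *config.range_a1)
        else:
            b0 = _draw_truncnorm_int(rng, config.mean_a2, config.sd_a2, *config.range_a2)
        if o == "response" and _tstar(b0) < 29:
            o = "remission"
            n_relabelled += 1

        t_mid = _uniform(rng, *_mid_region(config, a, mid, b0, o, rng))
        t_end = _end_total(config, b0, o, rng)
        end_stratum = "C1" if t_end <= 28 else ("C2" if t_end < 40 else "C3")

        if config.placebo_mode:
            base = allocate_items(b0, "baseline", profile=FLAT_PLAN, rng=rng)
            mid_plan = PLACEBO_B3_PLAN if mid == "B3" else FLAT_PLAN
            mid_items = allocate_items(t_mid, "mid", profile=mid_plan, rng=rng)
            end_items = allocate_items(t_end, "end", profile=FLAT_PLAN, rng=rng)
        else:
            # mid totals in B1 may need more headroom than the planted
            # improvement structure allows; retry within the band
            for attempt in range(20):
                try:
                    base, mid_items, end_items = _patient_items(
                        config, rng, a, b0, mid, t_mid, t_end, end_stratum, is_sat,
                        rotation=(i * 5) % 6,
                    )
                    break
                except GenerationError:
                    lo, hi = _mid_region(config, a, mid, b0, o, rng)
                    t_mid = _uniform(rng, min(hi, lo + 6 + attempt), hi)
            else:
                raise GenerationError(f"could not allocate items for patient {i}")

        age, sex, race = _demographics(config, rng, o)
        rec = {
            "patient_id": f"{config.arm[:3]}-{i:04d}",
            "arm": config.arm,
            "age": age,
            "sex": sex,
            "race": race,
        }
        for cols, items in (
            (ITEM_COLS["baseline"], base),
            (ITEM_COLS["mid"], mid_items),
            (ITEM_COLS["end"], end_items),
        ):
            rec.update({c: int(sc) for c, sc in zip(cols, items)})
        records.append(rec)
    if n_relabelled:
        log.debug("relabelled %d infeasible response draws to remission", n_relabelled)
    frame = pd.DataFrame(
        records, columns=META_COLS + [c for v in ITEM_COLS.values() for c in v]
    )
    return Cohort(frame)
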