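"""Prognostic symptom identification (three-criterion screen).

A CDRS-R item is *prognostic* when

(a) it has room to improve: more than a majority of patients score it
    above its scale minimum at baseline;
(b) it belongs to a severity cluster that is stable -- same co-members --
    at every visit along every symptom dynamic path (items are clustered
    hierarchically on their mean-severity profiles within each stratum a
    path traverses, restricted to patients from the path's baseline
    stratum);
(c) its severity distribution along the path (4-6 and 10-12 week scores)
    differs between at least one pair of symptom dynamic paths sharing a
    baseline stratum (two-sample Kolmogorov-Smirnov by default,
    Benjamini-Hochberg adjusted across the 17 items within each pair).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import ks_2samp, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .cohort import Cohort
from .mixture import BaselineMixture, assign_baseline_stratum
from .pgm import TrajectoryPath
from .scale import CDRS_ITEMS, N_ITEMS


@dataclass
class SymptomClustering:
    stratum: str
    visit: str
    clusters: dict[int, list[int]]  # cluster label -> item ids
    linkage_method: str
    n_clusters: int | None
    profiles: np.ndarray  # per-item mean severity
    silhouette_by_k: dict[int, float] | None = None

    def co_members(self, item_id: int) -> frozenset[int]:
        for members in self.clusters.values():
            if item_id in members:
                return frozenset(members)
        raise KeyError(item_id)


class DistributionTest(NamedTuple):
    statistic: float
    pvalue: float
    flag: bool
    indeterminate: bool = False


@dataclass
class PrognosticSymptomSet:
    item_ids: list[int]
    diagnostics: pd.DataFrame
    alpha: float
    majority: float
    clusterings: dict = field(default_factory=dict, repr=False)

    def labels(self) -> list[str]:
        return [CDRS_ITEMS[i - 1].label for i in self.item_ids]


def baseline_nonzero_filter(cohort: Cohort, majority: float = 0.5) -> set[int]:
    """Items scored strictly above their scale minimum in more than
    ``majority`` of patients at baseline (criterion a).

    CDRS-R items are anchored at 1, so "non-zero severity" means a score
    above the item minimum.
    """
    base = cohort.items("baseline")
    keep = set()
    for idx, scale_ in enumerate(CDRS_ITEMS):
        frac = float((base[:, idx] > scale_.min_score).mean())
        if frac > majority:
            keep.add(scale_.item_id)
    return keep


def _mean_profiles(items: np.ndarray) -> np.ndarray:
    return items.mean(axis=0)


def cluster_symptoms(
    items: np.ndarray,
    stratum: str,
    visit: str,
    *,
    n_clusters: int | None = None,
    cut_height: float = 0.9,
    linkage_method: str = "average",
    profile: str = "mean",
    silhouette_scan: bool = False,
) -> SymptomClustering:
    """Agglomerative clustering of the 17 items by severity profile.

    ``items`` is the (patients x 17) score matrix of one stratum at one
    visit (>= 5 patients).  Items are represented by their mean (default)
    or median severity across patients; distances are Euclidean.  By
    default the average-linkage tree is cut at ``cut_height`` severity
    points, so items travel together while their mean severities stay
    within about one scale point; a fixed cluster count can be forced
    with ``n_clusters``.
    """
    if items.shape[0] < 5:
        raise ValueError(
            f"need >= 5 patients to cluster symptoms in {stratum}/{visit}, "
            f"got {items.shape[0]}"
        )
    if profile == "mean":
        prof = _mean_profiles(items)
    elif profile == "median":
        prof = np.median(items, axis=0)
    else:
        raise ValueError(f"unknown profile {profile!r}")
    Z = linkage(prof.reshape(-1, 1), method=linkage_method)
    if n_clusters is None:
        labels = fcluster(Z, t=cut_height, criterion="distance")
    else:
        labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    n_found = len(set(labels))
    clusters: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(idx + 1)
    sil = None
    if silhouette_scan:
        sil = {k: _within_between(prof, Z, k) for k in (2, 3, 4)}
    return SymptomClustering(
        stratum=stratum,
        visit=visit,
        clusters=clusters,
        linkage_method=linkage_method,
        n_clusters=n_found,
        profiles=prof,
        silhouette_by_k=sil,
    )


def _within_between(prof: np.ndarray, Z, k: int) -> float:
    labels = fcluster(Z, t=k, criterion="maxclust")
    within, between = [], []
    for i in range(prof.size):
        for j in range(i + 1, prof.size):
            d = abs(prof[i] - prof[j])
            (within if labels[i] == labels[j] else between).append(d)
    if not within or not between:
        return np.inf
    return float(np.mean(within) / np.mean(between))


def path_distribution_test(
    scores_path1: np.ndarray,
    scores_path2: np.ndarray,
    alpha: float = 0.05,
    method: str = "ks",
) -> DistributionTest:
    """Two-sample test of an item's severity between two paths.

    Samples smaller than 3 make the comparison indeterminate (never
    significant).  The flag here uses the raw p-value; multiplicity
    adjustment across items is applied by the caller.
    """
    x = np.asarray(scores_path1, dtype=float)
    y = np.asarray(scores_path2, dtype=float)
    if x.size < 3 or y.size < 3:
        return DistributionTest(0.0, 1.0, False, indeterminate=True)
    if np.array_equal(np.sort(x), np.sort(y)):
        return DistributionTest(0.0, 1.0, False)
    if method == "ks":
        res = ks_2samp(x, y, method="asymp")
    elif method == "mannwhitney":
        res = mannwhitneyu(x, y, alternative="two-sided")
    else:
        raise ValueError(f"unknown method {method!r}")
    return DistributionTest(float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha))


def _path_masks(cohort: Cohort, mixture: BaselineMixture, paths) -> list[np.ndarray]:
    a = np.array(
        [assign_baseline_stratum(int(t), mixture) for t in cohort.totals("baseline")]
    )
    b = cohort.followup_strata("mid")
    c = cohort.followup_strata("end")
    return [(a == p.baseline) & (b == p.mid) & (c == p.end) for p in paths]


def identify_prognostic_symptoms(
    cohort: Cohort,
    paths: list[TrajectoryPath],
    mixture: BaselineMixture,
    *,
    alpha: float = 0.05,
    majority: float = 0.5,
    n_clusters: int | None = None,
    cut_height: float = 0.9,
    test_method: str = "ks",
    test_visits: tuple[str, ...] = ("mid", "end"),
    profile: str = "mean",
) -> PrognosticSymptomSet:
    """Intersect the three prognostic-symptom criteria.

    Requires at least two selected paths sharing a baseline stratum
    (criterion c is undefined otherwise).  Diagnostics are retained for
    every item, member or not.
    """
    if not paths:
        raise ValueError("no symptom dynamic paths supplied")
    by_base: dict[str, list[int]] = {}
    for i, p in enumerate(paths):
        by_base.setdefault(p.baseline, []).append(i)
    if not any(len(v) >= 2 for v in by_base.values()):
        raise ValueError(
            "criterion (c) undefined: no two selected paths share a baseline stratum"
        )

    masks = _path_masks(cohort, mixture, paths)
    crit_a = baseline_nonzero_filter(cohort, majority)

    # criterion (b): cluster items within each stratum a path traverses
    # (patients restricted to the path's baseline stratum, not the full
    # path, for stable profiles), then require identical co-membership
    # across the strata sequence of every path
    visit_items = {v: cohort.items(v) for v in ("baseline", "mid", "end")}
    a_lab = np.array(
        [assign_baseline_stratum(int(t), mixture) for t in cohort.totals("baseline")]
    )
    strata_at = {
        "baseline": a_lab,
        "mid": cohort.followup_strata("mid"),
        "end": cohort.followup_strata("end"),
    }
    stable = {i: True for i in range(1, N_ITEMS + 1)}
    clusterings: dict[tuple, SymptomClustering] = {}
    for p in paths:
        per_visit = []
        for visit, stratum in (("baseline", p.baseline), ("mid", p.mid), ("end", p.end)):
            key = (p.baseline, stratum, visit)
            if key not in clusterings:
                mask = (a_lab == p.baseline) & (strata_at[visit] == stratum)
                clusterings[key] = cluster_symptoms(
                    visit_items[visit][mask],
                    stratum,
                    visit,
                    n_clusters=n_clusters,
                    cut_height=cut_height,
                    profile=profile,
                )
            per_visit.append(clusterings[key])
        for item in range(1, N_ITEMS + 1):
            members = {cl.co_members(item) for cl in per_visit}
            if len(members) > 1:
                stable[item] = False

    # criterion (c): distribution differences between paths sharing a
    # baseline stratum, BH-adjusted across items within each pair
    minp = {i: 1.0 for i in range(1, N_ITEMS + 1)}
    flagged = {i: False for i in range(1, N_ITEMS + 1)}
    for base, idxs in by_base.items():
        for k1 in range(len(idxs)):
            for k2 in range(k1 + 1, len(idxs)):
                m1, m2 = masks[idxs[k1]], masks[idxs[k2]]
                pvals, ok = [], []
                for item in range(1, N_ITEMS + 1):
                    s1 = np.concatenate(
                        [visit_items[v][m1, item - 1] for v in test_visits]
                    )
                    s2 = np.concatenate(
                        [visit_items[v][m2, item - 1] for v in test_visits]
                    )
                    t = path_distribution_test(s1, s2, alpha, test_method)
                    pvals.append(t.pvalue)
                    ok.append(not t.indeterminate)
                adj = np.ones(N_ITEMS)
                if any(ok):
                    rej, adj_ok, _, _ = multipletests(
                        np.array(pvals)[ok], alpha=alpha, method="fdr_bh"
                    )
                    adj[np.array(ok)] = adj_ok
                for item in range(1, N_ITEMS + 1):
                    if ok[item - 1]:
                        minp[item] = min(minp[item], float(adj[item - 1]))
                        if adj[item - 1] < alpha:
                            flagged[item] = True

    rows = []
    for item in range(1, N_ITEMS + 1):
        rows.append(
            {
                "item_id": item,
                "label": CDRS_ITEMS[item - 1].label,
                "criterion_a": item in crit_a,
                "criterion_b": stable[item],
                "criterion_c_minp": minp[item],
                "criterion_c": flagged[item],
                "selected": (item in crit_a) and stable[item] and flagged[item],
            }
        )
    diag = pd.DataFrame(rows)
    selected = sorted(diag.loc[diag["selected"], "item_id"].tolist())
    return PrognosticSymptomSet(
        item_ids=selected,
        diagnostics=diag,
        alpha=alpha,
        majority=majority,
        clusterings=clusterings,
    )
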