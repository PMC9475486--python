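"""Baseline severity stratification by two-component Gaussian mixture.

Baseline CDRS-R totals in antidepressant trials of moderately-to-severely
depressed youth are well described by two overlapping Gaussian components;
the posterior crossover of the fitted mixture converts the continuous fit
into an integer boundary separating a lower-severity stratum A1 from a
higher-severity stratum A2 (in the calibrated cohorts, A1 <= 55 and
A2 >= 56).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.mixture import GaussianMixture

from .scale import TOTAL_MIN, TOTAL_MAX, ACTIVE_CUT


class MixtureFitError(RuntimeError):
    """Degenerate EM solution (collapsed component); more data needed."""


@dataclass(frozen=True)
class BaselineMixture:
    """Fitted two-component univariate Gaussian mixture over baseline totals.

    ``boundary`` is the largest integer total assigned to the lower-mean
    component (posterior >= 0.5), i.e. the largest total labelled A1.
    Components are ordered by mean.
    """

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    boundary: int
    log_likelihood: float
    bic_by_k: dict[int, float] | None = None

    def posterior_lower(self, totals: np.ndarray) -> np.ndarray:
        """Posterior probability of the lower-mean component."""
        t = np.asarray(totals, dtype=float)
        dens = [
            w * _normal_pdf(t, m, s)
            for w, m, s in zip(self.weights, self.means, self.sds)
        ]
        total = dens[0] + dens[1]
        with np.errstate(invalid="ignore"):
            post = np.where(total > 0, dens[0] / np.where(total > 0, total, 1.0), 0.5)
        return post

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _normal_pdf(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    z = (x - mean) / sd
    return np.exp(-0.5 * z * z) / (sd * np.sqrt(2 * np.pi))


def fit_baseline_mixture(
    totals,
    restarts: int = 10,
    seed: int = 0,
    *,
    bic_scan: bool = False,
) -> BaselineMixture:
    """Fit the two-component baseline mixture by EM and locate the boundary.

    Parameters
    ----------
    totals : sequence of int
        Baseline CDRS-R totals, all >= 40, at least 20 of them.
    restarts : int
        Number of seeded EM restarts; the best log-likelihood is kept.
    seed : int
        Seed for the restarts.
    bic_scan : bool
        If True, also record BIC for K in {1..4} as a diagnostic.  The
        number of components is always 2 regardless of the scan.

    The boundary is the largest integer t with posterior
    P(lower-mean component | t) >= 0.5 on the admissible score range.
    """
    x = np.asarray(list(totals), dtype=float)
    if x.size < 20:
        raise ValueError(f"need >= 20 baseline totals, got {x.size}")
    if np.any(x < ACTIVE_CUT):
        raise ValueError("baseline totals below the inclusion threshold 40")
    if np.ptp(x) == 0:
        raise MixtureFitError("all baseline totals identical; no mixture structure")

    gm = GaussianMixture(
        n_components=2,
        n_init=restarts,
        init_params="k-means++",
        tol=1e-8,
        max_iter=500,
        random_state=seed,
        covariance_type="full",
        reg_covar=1e-6,
    ).fit(x.reshape(-1, 1))

    weights = gm.weights_.copy()
    means = gm.means_.ravel().copy()
    sds = np.sqrt(gm.covariances_.ravel().copy())
    order = np.argsort(means)
    weights, means, sds = weights[order], means[order], sds[order]

    if weights.min() < 0.02 or sds.min() < 0.5:
        raise MixtureFitError(
            "degenerate mixture fit (component weight < 0.02 or sd collapse); "
            "more data or fewer restarts needed"
        )

    grid = np.arange(TOTAL_MIN, TOTAL_MAX + 1, dtype=float)
    dens_lo = weights[0] * _normal_pdf(grid, means[0], sds[0])
    dens_hi = weights[1] * _normal_pdf(grid, means[1], sds[1])
    lower_wins = dens_lo >= dens_hi
    # largest integer between the means still assigned to the lower component
    between = (grid >= means[0]) & (grid <= means[1]) & lower_wins
    if between.any():
        boundary = int(grid[between].max())
    else:  # crossover below the lower mean (very unequal weights)
        boundary = int(np.floor(means[0]))

    bic = None
    if bic_scan:
        bic = {}
        for k in range(1, 5):
            g = GaussianMixture(
                n_components=k, n_init=4, random_state=seed, reg_covar=1e-6
            ).fit(x.reshape(-1, 1))
            bic[k] = float(g.bic(x.reshape(-1, 1)))

    return BaselineMixture(
        weights=(float(weights[0]), float(weights[1])),
        means=(float(means[0]), float(means[1])),
        sds=(float(sds[0]), float(sds[1])),
        boundary=boundary,
        log_likelihood=float(gm.score(x.reshape(-1, 1)) * x.size),
        bic_by_k=bic,
    )


def assign_baseline_stratum(total: int, mixture: BaselineMixture) -> str:
    """A1 iff the total is at or below the fitted integer boundary."""
    return "A1" if total <= mixture.boundary else "A2"
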