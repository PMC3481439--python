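"""Empirical-null standardisation of module scores.

Observed module scores are median-centered; a normal null N(delta, sigma)
is fitted to the central bulk of the centered scores by truncated-normal
maximum likelihood (central matching). Each module is then standardised,
ZS = (Zm' - delta) / sigma, and assigned P = 1 - Phi(ZS).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import NumericalError, ValidationError
from .module_search import Module

MIN_SCORES = 20


@dataclass(frozen=True)
class NullFit:
    """Location/scale of the empirical null plus the centering median."""

    delta: float
    sigma: float
    n_scores: int
    median: float
    central_fraction: float = 0.5


@dataclass
class ScoredModule:
    """A module with its empirical-null statistics attached."""

    module_id: str
    seed: str
    members: frozenset
    zm: float
    zm_centered: float
    zs: float
    p_module: float

    @property
    def k(self) -> int:
        return len(self.members)


def fit_empirical_null(
    scores: Sequence[float], central_fraction: float = 0.5
) -> NullFit:
    """Fit N(delta, sigma) to the central bulk of median-centered scores.

    Central matching: scores are median-centered and the central
    ``central_fraction`` quantile window [a, b] is taken as null-dominated.
    (delta, sigma) maximise the censored-normal likelihood in which scores
    inside the window contribute their density and scores outside only the
    censored tail masses — identified (unlike a purely truncated fit, whose
    scale is nearly flat over a narrow window) yet insensitive to the shape
    of the tails. Fewer than 20 scores raise a :class:`ValidationError`
    advising the exact-null fallback (:func:`exact_null_fit`).
    """
    scores = np.asarray(list(scores), dtype=float)
    if scores.size < MIN_SCORES:
        raise ValidationError(
            f"need >= {MIN_SCORES} module scores to fit the empirical null "
            f"(got {scores.size}); use the exact-null fallback instead"
        )
    if not 0 < central_fraction <= 1:
        raise ValidationError("central_fraction must lie in (0, 1]")
    med = float(np.median(scores))
    y = scores - med
    lo = (1 - central_fraction) / 2
    a, b = np.quantile(y, [lo, 1 - lo])
    core = y[(y >= a) & (y <= b)]
    if core.size < 2 or np.std(core) == 0 or b <= a:
        raise NumericalError("degenerate score distribution: zero spread")
    n_lo = int((y < a).sum())
    n_hi = int((y > b).sum())
    sigma0 = max((b - a) / 1.349, 1e-3)

    def negloglik(theta):
        delta, log_sigma = theta
        sigma = np.exp(log_sigma)
        ll = stats.norm.logpdf(core, loc=delta, scale=sigma).sum()
        if n_lo:
            ll += n_lo * stats.norm.logcdf((a - delta) / sigma)
        if n_hi:
            ll += n_hi * stats.norm.logsf((b - delta) / sigma)
        return -ll if np.isfinite(ll) else 1e12

    res = optimize.minimize(
        negloglik, x0=np.array([0.0, np.log(sigma0)]), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 4000},
    )
    delta = float(res.x[0])
    sigma = float(np.exp(res.x[1]))
    if sigma < 1e-6:
        raise NumericalError(
            "empirical-null sigma collapsed (< 1e-6): scores nearly constant"
        )
    return NullFit(delta=delta, sigma=sigma, n_scores=scores.size, median=med,
                   central_fraction=central_fraction)


def exact_null_fit(scores: Sequence[float]) -> NullFit:
    """Standard-normal fallback null (delta=0, sigma=1) for small searches."""
    scores = np.asarray(list(scores), dtype=float)
    if scores.size == 0:
        raise ValidationError("no module scores supplied")
    return NullFit(delta=0.0, sigma=1.0, n_scores=scores.size,
                   median=float(np.median(scores)), central_fraction=1.0)


def module_pvalues(modules: Iterable[Module], fit: NullFit) -> list:
    """Attach ZS and empirical-null P to each module.

    Modules are ordered (and numbered) by descending Zm, ties by seed id;
    P = 1 - Phi((Zm - median - delta) / sigma) is strictly decreasing in Zm.
    """
    ordered = sorted(modules, key=lambda m: (-m.zm, m.seed))
    out = []
    for i, m in enumerate(ordered, start=1):
        centered = m.zm - fit.median
        zs = (centered - fit.delta) / fit.sigma
        out.append(
            ScoredModule(
                module_id=f"M{i:04d}",
                seed=m.seed,
                members=m.members,
                zm=m.zm,
                zm_centered=centered,
                zs=zs,
                p_module=float(stats.norm.sf(zs)),
            )
        )
    return out


def select_significant(
    stats_list: Iterable[ScoredModule], alpha: float = 0.05
) -> tuple[list, set]:
    """Modules with p_module < alpha, plus the union of their member genes."""
    selected = [m for m in stats_list if m.p_module < alpha]
    pooled: set = set()
    for m in selected:
        pooled |= m.members
    return selected, pooled
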