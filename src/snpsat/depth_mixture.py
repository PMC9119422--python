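"""Exponential + normal mixture over a strain's base-depth histogram.

In shotgun metagenomes the per-base depth of a correctly recruited strain
is approximately normal around the strain's genome depth, while bases from
sequencing errors and cross-mapping of homologous reads pile up at low
depth and are well described by an exponential component.  Fitting the
two-component mixture to the depth histogram lets us place a per-strain
(and per-subsample-level) depth cutoff separating noise-derived bases from
truly assigned ones, instead of a fixed global threshold that stops being
appropriate as sequencing depth grows.

The likelihood is defined over positive integer depths (uncovered
positions carry no reads and are excluded).  The exponential component is
discretised as the law of ``ceil(Exp(lambda))`` — a geometric-form pmf
``(1 - e^-lambda) * e^(-lambda (k-1))`` for k >= 1 — which admits an exact
closed-form M-step; the normal component uses the Gaussian density at
integer depths (its lattice sum is ~1 for sigma >= 0.5).  Both M-steps are
exact maximisers, so the EM log-likelihood is monotone non-decreasing.

Threshold selection works on the fitted continuous distributions: keep the
depths retaining at least ``keep_normal`` of the (truncated-at-zero)
normal mass, discard at least ``discard_exp`` of the exponential mass, and
take the smaller of the two cutoffs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import norm

from .errors import DegenerateInputError, InputError
from .io_formats import DepthTable, VariantRecord

logger = logging.getLogger(__name__)

SIGMA_FLOOR = 0.5
_LAMBDA_MAX = 50.0


@dataclass
class DepthHistogram:
    """Counts of genome positions per (positive integer) depth value."""

    strain: str
    counts: dict[int, int]
    genome_length: Optional[int] = None

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.counts):
            raise InputError("depth histogram keys must be >= 1")
        if any(c < 0 for c in self.counts.values()):
            raise InputError("negative count in depth histogram")
        if (
            self.genome_length is not None
            and self.total_positions > self.genome_length
        ):
            raise InputError("covered positions exceed genome length")

    @property
    def total_positions(self) -> int:
        return int(sum(self.counts.values()))

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        depths = np.array(sorted(d for d, c in self.counts.items() if c > 0))
        weights = np.array([self.counts[d] for d in depths], dtype=float)
        return depths.astype(float), weights

    @classmethod
    def from_depth_table(
        cls, depths: DepthTable, genome_length: Optional[int] = None
    ) -> "DepthHistogram":
        d = depths.table["depth"]
        vc = d[d >= 1].value_counts()
        return cls(
            strain=depths.strain,
            counts={int(k): int(v) for k, v in vc.items()},
            genome_length=genome_length,
        )


@dataclass
class EMConfig:
    tol: float = 1e-8
    max_iter: int = 500
    n_restarts: int = 3
    seed: int = 42
    sigma_floor: float = SIGMA_FLOOR
    min_positions: int = 50


@dataclass
class DepthMixtureFit:
    """Fitted mixture ``w_exp * Exp(lambda) + w_norm * N(mu, sigma)``."""

    strain: str
    w_exp: float
    w_norm: float
    lam: float
    mu: float
    sigma: float
    log_likelihood: float
    n_iterations: int
    converged: bool
    degenerate: bool = False
    ll_trace: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if abs(self.w_exp + self.w_norm - 1.0) > 1e-9:
            raise InputError("component weights must sum to 1")


@dataclass
class FilterThreshold:
    """Depth cutoff below which sites are discarded."""

    strain: str
    level: Optional[int]
    t_norm: int
    t_exp: int
    t_final: int
    harmonized: bool = False


# ---------------------------------------------------------------------------
# EM fitting


def _log_pmf_exp(k: np.ndarray, lam: float) -> np.ndarray:
    # pmf of ceil(Exp(lam)) on k >= 1
    return math.log1p(-math.exp(-lam)) - lam * (k - 1.0)


def _log_pdf_norm(k: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return -0.5 * ((k - mu) / sigma) ** 2 - math.log(sigma * math.sqrt(2 * math.pi))


def _lambda_from_mean(m: float) -> float:
    # mean of ceil(Exp(lam)) is 1 / (1 - e^-lam)
    if m <= 1.0 + 1e-12:
        return _LAMBDA_MAX
    return min(-math.log1p(-1.0 / m), _LAMBDA_MAX)


def _em_once(
    k: np.ndarray,
    w: np.ndarray,
    init: tuple[float, float, float, float],
    config: EMConfig,
) -> DepthMixtureFit:
    w_exp, lam, mu, sigma = init
    n = w.sum()
    ll_prev = -np.inf
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        log_e = np.log(max(w_exp, 1e-300)) + _log_pmf_exp(k, lam)
        log_n = np.log(max(1.0 - w_exp, 1e-300)) + _log_pdf_norm(k, mu, sigma)
        m = np.maximum(log_e, log_n)
        log_mix = m + np.log(np.exp(log_e - m) + np.exp(log_n - m))
        ll = float((w * log_mix).sum())
        trace.append(ll)

        r_exp = np.exp(log_e - log_mix)  # responsibility of the exp component
        s_exp = float((w * r_exp).sum())
        s_norm = n - s_exp

        if ll_prev > -np.inf and abs(ll - ll_prev) <= config.tol * abs(ll_prev):
            converged = True
            break
        ll_prev = ll

        w_exp = s_exp / n
        if s_exp > 1e-12:
            lam = _lambda_from_mean(float((w * r_exp * k).sum() / s_exp))
        if s_norm > 1e-12:
            mu = float((w * (1 - r_exp) * k).sum() / s_norm)
            var = float((w * (1 - r_exp) * (k - mu) ** 2).sum() / s_norm)
            sigma = max(math.sqrt(max(var, 0.0)), config.sigma_floor)

    return DepthMixtureFit(
        strain="",
        w_exp=float(w_exp),
        w_norm=float(1.0 - w_exp),
        lam=float(lam),
        mu=float(mu),
        sigma=float(sigma),
        log_likelihood=trace[-1],
        n_iterations=it,
        converged=converged,
        ll_trace=trace,
    )


def _moment_init(k: np.ndarray, w: np.ndarray) -> tuple[float, float, float, float]:
    order = np.argsort(k)
    cum = np.cumsum(w[order]) / w.sum()
    q25 = k[order][np.searchsorted(cum, 0.25)]
    low = k <= q25
    high = ~low
    if w[low].sum() == 0 or w[high].sum() == 0:
        mean_all = float((w * k).sum() / w.sum())
        return 0.3, _lambda_from_mean(mean_all), mean_all, max(1.0, SIGMA_FLOOR)
    lam = _lambda_from_mean(float((w[low] * k[low]).sum() / w[low].sum()))
    mu = float((w[high] * k[high]).sum() / w[high].sum())
    var = float((w[high] * (k[high] - mu) ** 2).sum() / w[high].sum())
    sigma = max(math.sqrt(max(var, 0.0)), SIGMA_FLOOR)
    return float(w[low].sum() / w.sum()), lam, mu, sigma


def fit_depth_mixture(
    hist: DepthHistogram, config: EMConfig | None = None
) -> DepthMixtureFit:
    """Fit the two-component mixture by EM with restarts.

    Returns the highest-likelihood fit over one moment-based initialisation
    plus ``config.n_restarts`` random restarts.  A histogram concentrated
    on a single depth yields a flagged degenerate fit (pure normal at that
    depth); fewer than ``config.min_positions`` covered positions is an
    error.
    """
    config = config or EMConfig()
    total = hist.total_positions
    if total < config.min_positions:
        raise DegenerateInputError(
            f"only {total} covered positions (need >= {config.min_positions})"
        )
    k, w = hist.arrays()
    if len(k) == 1:
        logger.warning("%s: all depths identical, degenerate fit", hist.strain)
        return DepthMixtureFit(
            strain=hist.strain,
            w_exp=0.0,
            w_norm=1.0,
            lam=1.0,
            mu=float(k[0]),
            sigma=config.sigma_floor,
            log_likelihood=float(
                (w * _log_pdf_norm(k, float(k[0]), config.sigma_floor)).sum()
            ),
            n_iterations=0,
            converged=True,
            degenerate=True,
        )

    rng = np.random.default_rng(config.seed)
    inits = [_moment_init(k, w)]
    kmin, kmax = float(k.min()), float(k.max())
    for _ in range(config.n_restarts):
        w0 = rng.uniform(0.05, 0.6)
        lam0 = _lambda_from_mean(rng.uniform(1.2, max(2.0, 0.3 * kmax)))
        mu0 = rng.uniform(kmin, kmax)
        sig0 = max(rng.uniform(0.05, 0.3) * (kmax - kmin + 1), config.sigma_floor)
        inits.append((w0, lam0, mu0, sig0))

    best: DepthMixtureFit | None = None
    for init in inits:
        fit = _em_once(k, w, init, config)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    assert best is not None
    best.strain = hist.strain
    return best


# ---------------------------------------------------------------------------
# Threshold selection


def select_threshold(
    fit: DepthMixtureFit,
    keep_normal: float = 0.9,
    discard_exp: float = 0.5,
    strain: Optional[str] = None,
    level: Optional[int] = None,
) -> FilterThreshold:
    """Derive the depth cutoff from a fitted mixture.

    ``t_norm`` is the largest integer t whose truncated-at-zero normal
    survival P(D >= t | D > 0) is still >= ``keep_normal``; ``t_exp`` is
    the smallest integer t discarding at least ``discard_exp`` of the
    exponential mass (P(D < t) >= discard_exp).  The final cutoff is the
    smaller of the two.  Degenerate fits get t_final = 0 (no filtering).
    """
    if not (0.0 <= keep_normal <= 1.0 and 0.0 <= discard_exp <= 1.0):
        raise InputError("keep_normal and discard_exp must be in [0, 1]")
    strain = strain if strain is not None else fit.strain
    if fit.degenerate:
        logger.warning("%s: degenerate fit, threshold set to 0", strain)
        return FilterThreshold(strain, level, 0, 0, 0)

    sf0 = float(norm.sf(0.0, loc=fit.mu, scale=fit.sigma))
    target = keep_normal * sf0
    if target >= sf0:
        t_norm = 0
    else:
        t_norm = max(0, math.floor(norm.isf(target, loc=fit.mu, scale=fit.sigma) + 1e-9))

    if discard_exp <= 0.0:
        t_exp = 0
    else:
        x = -math.log1p(-min(discard_exp, 1.0 - 1e-15)) / fit.lam
        t_exp = max(0, math.ceil(x - 1e-9))

    return FilterThreshold(strain, level, int(t_norm), int(t_exp), int(min(t_norm, t_exp)))


def harmonize_thresholds(series: Sequence[FilterThreshold]) -> list[FilterThreshold]:
    """Enforce non-decreasing cutoffs across increasing subsample levels.

    When a deeper level's cutoff falls below the previous level's, the
    previous cutoff is carried forward (flagged ``harmonized``).
    """
    levels = [t.level for t in series]
    if any(l is None for l in levels) and len(series) > 1:
        raise InputError("all thresholds must carry a subsample level")
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise InputError("subsample levels must be strictly increasing")
    out: list[FilterThreshold] = []
    running = -1
    for t in series:
        if t.t_final < running:
            out.append(
                FilterThreshold(
                    t.strain, t.level, t.t_norm, t.t_exp, running, harmonized=True
                )
            )
        else:
            out.append(t)
            running = t.t_final
        running = max(running, out[-1].t_final)
    return out


def apply_depth_filter(
    snps: Iterable[VariantRecord], depths: DepthTable, t: FilterThreshold
) -> tuple[list[VariantRecord], int]:
    """Keep SNPs whose site depth >= t_final; positions absent from the
    depth table count as depth 0.  Returns (kept records, removed count)."""
    lookup = depths.depth_lookup()
    kept: list[VariantRecord] = []
    removed = 0
    for r in snps:
        if lookup.get((r.chrom, r.pos), 0) >= t.t_final:
            kept.append(r)
        else:
            removed += 1
    return kept, removed
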