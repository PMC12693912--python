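"""Chromosome-wise meta-QTL analysis.

Projected QTL peaks on one chromosome are modelled as draws from a
K-component Gaussian mixture in which each observation carries a *known*
variance s_i² derived from its projected confidence interval:

    lnL = sum_i ln sum_k pi_k * phi(x_i; mu_k, s_i^2)

Only the component means mu_k and proportions pi_k are free, so a
K-component model has p = 2K - 1 free parameters. The component count is
chosen by fitting K = 1..Kmax and taking the K that attains the minimum in
at least three of five penalized-likelihood criteria (AIC, AICc, AIC3,
BIC, AWE). Each QTL is assigned to the component for which its posterior
membership probability exceeds 60%, provided its peak falls inside that
component's 95% interval; the component's peak and interval come from the
responsibility-weighted inverse-variance combination of its members.

A per-chromosome "QTL-overview index" summarizes where QTL probability
mass concentrates, in 0.5 cM bins by default.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .consensus_map import ProjectedQTL

__all__ = [
    "MixtureFit",
    "CriteriaRow",
    "MQTL",
    "OverviewIndex",
    "ChromosomeResult",
    "fit_mixture",
    "information_criteria",
    "select_model",
    "assign_members",
    "mqtl_summary",
    "run_chromosome",
    "overview_index",
]

logger = logging.getLogger(__name__)

RESP_FLOOR = 1e-300
MEMBERSHIP_THRESHOLD = 0.60


@dataclass
class MixtureFit:
    """A fitted K-component heteroscedastic mixture (means sorted ascending)."""

    k: int
    means: np.ndarray
    weights: np.ndarray
    loglik: float
    responsibilities: np.ndarray  # n x K posterior membership matrix
    converged: bool
    n_iter: int
    loglik_path: list[float] = dataclasses.field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return self.responsibilities.shape[0]

    @property
    def p_free(self) -> int:
        return 2 * self.k - 1


@dataclass(frozen=True)
class CriteriaRow:
    """Model-selection criteria for one candidate K."""

    k: int
    p_free: int
    n_obs: int
    aic: float
    aicc: float
    aic3: float
    bic: float
    awe: float

    CRITERIA = ("aic", "aicc", "aic3", "bic", "awe")


@dataclass
class MQTL:
    """A consensus locus: peak, 95% interval and member QTLs."""

    mqtl_id: str
    chromosome: int
    peak_cm: float
    ci_low_cm: float
    ci_high_cm: float
    members: list[tuple[str, float]]  # (qtl_id, membership probability)

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class OverviewIndex:
    """Per-bin QTL occurrence probability along a chromosome."""

    chromosome: int
    bin_width_cm: float
    bins: list[tuple[float, float, float]]  # (start, end, index)


@dataclass
class ChromosomeResult:
    """Everything the meta-analysis produces for one chromosome."""

    chromosome: int
    fit: MixtureFit | None
    criteria: list[CriteriaRow]
    selected_k: int
    mqtls: list[MQTL]
    unassigned: list[str]


_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _loglik_matrix(x: np.ndarray, s: np.ndarray, means: np.ndarray) -> np.ndarray:
    """n x K matrix of ln phi(x_i; mu_k, s_i^2)."""
    z = (x[:, None] - means[None, :]) / s[:, None]
    return -0.5 * z * z - np.log(s)[:, None] - _LOG_SQRT_2PI


def _logsumexp_rows(a: np.ndarray) -> np.ndarray:
    m = a.max(axis=1)
    return m + np.log(np.exp(a - m[:, None]).sum(axis=1))


def _em_once(
    x: np.ndarray,
    s: np.ndarray,
    means0: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, bool, int]:
    k = means0.size
    n = x.size
    means = means0.astype(float).copy()
    weights = np.full(k, 1.0 / k)
    inv_var = 1.0 / s**2
    prev = -np.inf
    resp = np.full((n, k), 1.0 / k)
    converged = False
    it = 0
    path: list[float] = []
    for it in range(1, max_iter + 1):
        logphi = _loglik_matrix(x, s, means)
        logjoint = logphi + np.log(np.maximum(weights, RESP_FLOOR))[None, :]
        lognorm = _logsumexp_rows(logjoint)
        loglik = float(lognorm.sum())
        path.append(loglik)
        resp = np.exp(logjoint - lognorm[:, None])
        resp = np.maximum(resp, RESP_FLOOR)
        resp /= resp.sum(axis=1, keepdims=True)
        # M-step: inverse-variance weighted means, mean responsibilities
        wr = resp * inv_var[:, None]
        means = (wr * x[:, None]).sum(axis=0) / wr.sum(axis=0)
        weights = resp.mean(axis=0)
        if loglik - prev < tol and it > 1:
            converged = True
            prev = loglik
            break
        prev = loglik
    # score the final parameters
    logphi = _loglik_matrix(x, s, means)
    logjoint = logphi + np.log(np.maximum(weights, RESP_FLOOR))[None, :]
    lognorm = _logsumexp_rows(logjoint)
    loglik = float(lognorm.sum())
    resp = np.exp(logjoint - lognorm[:, None])
    resp = np.maximum(resp, RESP_FLOOR)
    resp /= resp.sum(axis=1, keepdims=True)
    path.append(loglik)
    return means, weights, loglik, resp, converged, it, path


def _initial_means(
    x: np.ndarray, k: int, rng: np.random.Generator, start: int
) -> np.ndarray:
    """Quantile-spread initial means; jittered for restarts after the first."""
    qs = (np.arange(k) + 0.5) / k
    means = np.quantile(x, qs)
    if start > 0:
        scale = max(np.ptp(x) / max(k, 1), 1e-3)
        means = means + rng.normal(0.0, 0.25 * scale, size=k)
    return np.sort(means)


def fit_mixture(
    positions: Sequence[float],
    sds: Sequence[float],
    k: int,
    n_starts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 2000,
    seed: int | None = None,
) -> MixtureFit:
    """Fit the known-variance Gaussian mixture by multi-start EM.

    Returns the best-log-likelihood run; the EM log-likelihood is
    non-decreasing across iterations by construction.
    """
    x = np.asarray(positions, dtype=float)
    s = np.asarray(sds, dtype=float)
    if x.ndim != 1 or x.shape != s.shape:
        raise ValueError("positions and sds must be 1-D and the same length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(s))):
        raise ValueError("non-finite input")
    if np.any(s <= 0):
        raise ValueError("all sds must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > x.size:
        raise ValueError(f"k={k} exceeds number of observations {x.size}")

    rng = np.random.default_rng(seed)
    best: MixtureFit | None = None
    for start in range(max(1, n_starts)):
        means0 = _initial_means(x, k, rng, start)
        means, weights, loglik, resp, converged, n_iter, path = _em_once(
            x, s, means0, tol, max_iter
        )
        if best is None or loglik > best.loglik:
            best = MixtureFit(
                k=k, means=means, weights=weights, loglik=loglik,
                responsibilities=resp, converged=converged, n_iter=n_iter,
                loglik_path=path,
            )
        if k == 1:
            break  # single-component EM has a unique fixed point
    order = np.argsort(best.means)
    best.means = best.means[order]
    best.weights = best.weights[order]
    best.responsibilities = best.responsibilities[:, order]
    return best


def information_criteria(fit: MixtureFit, n_obs: int | None = None) -> CriteriaRow:
    """AIC, AICc, AIC3, BIC and AWE for a fitted mixture.

    AWE penalizes the completed-data log-likelihood
    lnL_c = lnL + sum_ik r_ik ln r_ik (with 0 ln 0 = 0):
    AWE = -2 lnL_c + 2p(3/2 + ln n).
    """
    n = int(n_obs if n_obs is not None else fit.n_obs)
    p = fit.p_free
    d = -2.0 * fit.loglik
    aic = d + 2.0 * p
    if n > p + 1:
        aicc = aic + 2.0 * p * (p + 1) / (n - p - 1)
    else:
        warnings.warn(
            f"AICc undefined for n={n}, p={p} (n <= p+1); reporting +inf",
            RuntimeWarning, stacklevel=2,
        )
        aicc = math.inf
    aic3 = d + 3.0 * p
    bic = d + p * math.log(n)
    r = fit.responsibilities
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = np.where(r > 0, r * np.log(r), 0.0)
    loglik_c = fit.loglik + float(ent.sum())
    awe = -2.0 * loglik_c + 2.0 * p * (1.5 + math.log(n))
    return CriteriaRow(k=fit.k, p_free=p, n_obs=n,
                       aic=aic, aicc=aicc, aic3=aic3, bic=bic, awe=awe)


def select_model(rows: Sequence[CriteriaRow]) -> int:
    """Pick K by the three-of-five minimum rule.

    Each criterion votes for its argmin K (smallest K on exact ties). The K
    holding at least three votes wins; failing that, the K with the most
    votes; remaining ties go to the smallest K (parsimony).
    """
    if not rows:
        raise ValueError("no criteria rows")
    votes: dict[int, int] = {}
    for crit in CriteriaRow.CRITERIA:
        winner = min(rows, key=lambda r: (getattr(r, crit), r.k)).k
        votes[winner] = votes.get(winner, 0) + 1
    for k, count in votes.items():
        if count >= 3:
            return k
    most = max(votes.values())
    return min(k for k, count in votes.items() if count == most)


def mqtl_summary(
    members: Sequence[ProjectedQTL],
    responsibilities: Sequence[float] | None = None,
) -> tuple[float, float, float]:
    """Peak and 95% interval from a responsibility-weighted precision combination.

    peak = sum r_i x_i / s_i^2 / sum r_i / s_i^2; var = 1 / sum r_i / s_i^2;
    CI = peak +/- 1.96 sd. Returns (peak, ci_low, ci_high).
    """
    if not members:
        raise ValueError("need at least one member")
    x = np.array([m.position_cm for m in members])
    prec = np.array([1.0 / m.sd_cm**2 for m in members])
    r = np.ones(len(members)) if responsibilities is None else np.asarray(responsibilities, float)
    wsum = float((r * prec).sum())
    peak = float((r * prec * x).sum() / wsum)
    half = 1.96 * math.sqrt(1.0 / wsum)
    return peak, peak - half, peak + half


def assign_members(
    fit: MixtureFit,
    qtls: Sequence[ProjectedQTL],
    threshold: float = MEMBERSHIP_THRESHOLD,
) -> tuple[list[MQTL], list[str]]:
    """Turn a fit into named MQTLs plus the list of unassigned QTL ids.

    A QTL joins component k iff r_ik strictly exceeds ``threshold`` AND its
    peak lies inside that component's 95% interval (both conditions, the
    stricter reading). The interval check uses the summary computed from
    the provisionally assigned members in a single pass; QTLs failing it
    become unassigned without re-summarizing. Unassigned QTLs are reported,
    never dropped silently.
    """
    if fit.responsibilities.shape[0] != len(qtls):
        raise ValueError("responsibility matrix does not match QTL list")
    chrom = qtls[0].chromosome if qtls else 0
    provisional: dict[int, list[int]] = {}
    unassigned: list[str] = []
    for i, q in enumerate(qtls):
        k = int(np.argmax(fit.responsibilities[i]))
        if fit.responsibilities[i, k] > threshold:
            provisional.setdefault(k, []).append(i)
        else:
            unassigned.append(q.qtl.qtl_id)

    mqtls: list[MQTL] = []
    for k in sorted(provisional):
        idx = provisional[k]
        members = [qtls[i] for i in idx]
        resp = [float(fit.responsibilities[i, k]) for i in idx]
        _, lo, hi = mqtl_summary(members, resp)
        kept = [
            (i, ri) for i, ri in zip(idx, resp)
            if lo <= qtls[i].position_cm <= hi
        ]
        dropped = [qtls[i].qtl.qtl_id for i in idx
                   if not lo <= qtls[i].position_cm <= hi]
        unassigned.extend(dropped)
        if not kept:
            continue
        members = [qtls[i] for i, _ in kept]
        resp = [ri for _, ri in kept]
        peak, lo, hi = mqtl_summary(members, resp)
        mqtls.append(
            MQTL(
                mqtl_id="",  # named after the positional sort below
                chromosome=chrom,
                peak_cm=peak, ci_low_cm=lo, ci_high_cm=hi,
                members=[(qtls[i].qtl.qtl_id, ri) for i, ri in kept],
            )
        )
    mqtls.sort(key=lambda m: m.peak_cm)
    for rank, m in enumerate(mqtls, start=1):
        m.mqtl_id = f"MQTL{chrom}.{rank}"
    return mqtls, unassigned


def candidate_ks(n: int, kmax_cap: int = 12) -> list[int]:
    """Candidate component counts for a chromosome with ``n`` QTLs.

    Small panels (n <= 10) search K = 1..min(4, n); larger panels search
    K = 1..min(ceil(n/2), kmax_cap).
    """
    if n <= 0:
        return []
    if n <= 10:
        return list(range(1, min(4, n) + 1))
    return list(range(1, min(math.ceil(n / 2), kmax_cap) + 1))


def run_chromosome(
    qtls: Sequence[ProjectedQTL],
    kmax_cap: int = 12,
    n_starts: int = 20,
    tol: float = 1e-8,
    seed: int | None = None,
    threshold: float = MEMBERSHIP_THRESHOLD,
) -> ChromosomeResult:
    """Fit all candidate K on one chromosome, select K, and build MQTLs."""
    if not qtls:
        return ChromosomeResult(0, None, [], 0, [], [])
    chroms = {q.chromosome for q in qtls}
    if len(chroms) != 1:
        raise ValueError(f"QTLs span multiple chromosomes: {sorted(chroms)}")
    chrom = chroms.pop()
    x = [q.position_cm for q in qtls]
    s = [q.sd_cm for q in qtls]
    fits: dict[int, MixtureFit] = {}
    rows: list[CriteriaRow] = []
    for k in candidate_ks(len(qtls), kmax_cap):
        fit = fit_mixture(x, s, k, n_starts=n_starts, tol=tol,
                          seed=None if seed is None else seed + k)
        fits[k] = fit
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rows.append(information_criteria(fit))
    chosen = select_model(rows)
    mqtls, unassigned = assign_members(fits[chosen], qtls, threshold)
    return ChromosomeResult(chrom, fits[chosen], rows, chosen, mqtls, unassigned)


def overview_index(
    qtls: Sequence[ProjectedQTL],
    span: tuple[float, float],
    bin_width: float = 0.5,
) -> OverviewIndex:
    """QTL-overview index: per-bin QTL occurrence probability.

    QTL i contributes Phi((b - x_i)/s_i) - Phi((a - x_i)/s_i) to bin
    [a, b); the bin index is the mean contribution over QTLs, so each
    QTL's total mass across bins is at most 1.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    start, end = span
    if end < start:
        raise ValueError("empty span")
    edges = np.arange(start, end, bin_width)
    edges = np.append(edges, end)  # last bin may be short, tiling the span
    chrom = qtls[0].chromosome if qtls else 0
    if not qtls:
        bins = [(float(a), float(b), 0.0) for a, b in zip(edges[:-1], edges[1:])]
        return OverviewIndex(chrom, bin_width, bins)
    x = np.array([q.position_cm for q in qtls])
    s = np.array([q.sd_cm for q in qtls])
    cdf = norm.cdf((edges[:, None] - x[None, :]) / s[None, :])
    contrib = np.diff(cdf, axis=0)  # bins x qtls
    index = contrib.mean(axis=1)
    bins = [
        (float(a), float(b), float(v))
        for a, b, v in zip(edges[:-1], edges[1:], index)
    ]
    return OverviewIndex(chrom, bin_width, bins)
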