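"""Branching-process model of arm-level copy-number evolution.

The evolutionary history of a tumour genome is divided into ``N`` discrete
time periods.  Within each period every extant copy of every chromosome arm
is independently deleted with probability ``alpha``, left unchanged with
probability ``beta``, or duplicated with probability ``gamma``
(``alpha + beta + gamma = 1``).  Starting from a single copy, the copy-number
distribution after ``N`` periods is the ``N``-fold composition of the
offspring probability generating function

    f(s) = alpha + beta*s + gamma*s**2.

A whole-genome doubling (WGD) after ``M`` periods doubles every extant copy
synchronously, giving the generating function

    G(s) = F_M( F_{N-M}(s) ** 2 ),

where ``F_k`` is the ``k``-fold composition of ``f``.  All generating
functions are represented as coefficient vectors and composed by exact
polynomial arithmetic, so per-allele supports up to ``2**(N+1)`` are handled
without any symbolic algebra.

Each arm contributes two independent single-copy lineages — its major and
minor allele — to the likelihood.  Competing models (aneuploidy alone versus
aneuploidy plus one WGD) are compared by AIC; ``delta_aic = aic_non_wgd -
aic_wgd > 0`` supports genome doubling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Optional

import numpy as np

from .errors import (FitError, ParameterError, UnrepresentableStateError,
                     ValidationError)
from .io_formats import ArmDefinitions, SegmentTable

_NEG_SENTINEL = -1e12  # stands in for -inf during grid search
_PROB_TOL = 1e-12


@dataclass(frozen=True)
class BranchingParams:
    """Per-period, per-copy event probabilities of the branching process."""

    alpha: float
    beta: float
    gamma: float
    n_periods: int
    wgd_time: Optional[int] = None
    constrained: bool = False

    def __post_init__(self) -> None:
        for name, p in (("alpha", self.alpha), ("beta", self.beta),
                        ("gamma", self.gamma)):
            if p < -_PROB_TOL:
                raise ParameterError(f"{name} = {p} is negative")
        if abs(self.alpha + self.beta + self.gamma - 1.0) > 1e-9:
            raise ParameterError(
                f"alpha + beta + gamma = {self.alpha + self.beta + self.gamma}"
                " != 1")
        if self.constrained and abs(self.alpha - self.gamma) > 1e-9:
            raise ParameterError("constrained model requires alpha == gamma")
        if self.n_periods < 0:
            raise ParameterError("n_periods must be >= 0")
        if self.wgd_time is not None and not (1 <= self.wgd_time <= self.n_periods):
            raise ParameterError(
                f"wgd_time {self.wgd_time} outside [1, {self.n_periods}]")

    @property
    def with_wgd(self) -> bool:
        return self.wgd_time is not None

    @classmethod
    def symmetric(cls, rate: float, n_periods: int,
                  wgd_time: Optional[int] = None) -> "BranchingParams":
        """Constrained parameterisation with alpha = gamma = rate."""
        return cls(alpha=rate, beta=1.0 - 2.0 * rate, gamma=rate,
                   n_periods=n_periods, wgd_time=wgd_time, constrained=True)


def offspring_pgf(params: BranchingParams) -> np.ndarray:
    """Single-period per-copy offspring distribution [P(0), P(1), P(2)]."""
    return np.array([params.alpha, params.beta, params.gamma], float)


def _poly_compose(outer: np.ndarray, inner: np.ndarray) -> np.ndarray:
    """Evaluate outer(inner(s)) on coefficient vectors (Horner scheme)."""
    result = np.array([outer[-1]], float)
    for c in outer[-2::-1]:
        result = np.convolve(result, inner)
        result[0] += c
    return result


@lru_cache(maxsize=4096)
def _pmf_cached(alpha: float, beta: float, gamma: float, n_periods: int,
                wgd_time: Optional[int]) -> np.ndarray:
    f = np.array([alpha, beta, gamma], float)
    def compose_n(k: int) -> np.ndarray:
        g = np.array([0.0, 1.0])  # identity: F_0(s) = s
        for _ in range(k):
            g = _poly_compose(f, g)
        return g
    if wgd_time is None:
        coeffs = compose_n(n_periods)
    else:
        inner = compose_n(n_periods - wgd_time)
        doubled = np.convolve(inner, inner)
        coeffs = _poly_compose(compose_n(wgd_time), doubled)
    coeffs = np.clip(coeffs, 0.0, None)
    coeffs.setflags(write=False)
    return coeffs


def copy_number_pmf(params: BranchingParams) -> np.ndarray:
    """Exact per-allele copy-number distribution from one starting copy.

    Support is bounded by ``2**N`` (no WGD) or ``2**(N+1)`` (with WGD).
    """
    pmf = _pmf_cached(params.alpha, params.beta, params.gamma,
                      params.n_periods, params.wgd_time)
    total = pmf.sum()
    if abs(total - 1.0) > 1e-9:
        raise ParameterError(f"pmf mass {total} deviates from 1")
    return pmf


def max_total_copy_number(n_periods: int, with_wgd: bool) -> int:
    """Largest total (two-allele) arm copy number the model can represent."""
    if n_periods < 0:
        raise ParameterError("n_periods must be >= 0")
    return 2 * 2 ** n_periods * (2 if with_wgd else 1)


@dataclass
class ArmCNProfile:
    """Arm-level allele-specific copy numbers of one sample.

    ``arms`` maps arm id to an integer (major, minor) pair or ``None`` for
    undetermined arms.
    """

    sample_id: str
    arms: dict[str, Optional[tuple[int, int]]]

    def __post_init__(self) -> None:
        for arm, state in self.arms.items():
            if state is None:
                continue
            major, minor = state
            if major < 0 or minor < 0 or major < minor:
                raise ValidationError(
                    f"arm {arm}: invalid (major, minor) = ({major}, {minor})")

    def determined(self) -> dict[str, tuple[int, int]]:
        return {a: s for a, s in self.arms.items() if s is not None}

    def allele_counts(self) -> np.ndarray:
        """Flat array of per-allele copy numbers (two lineages per arm)."""
        states = list(self.determined().values())
        return np.array([c for pair in states for c in pair], dtype=np.int64)


def log_likelihood(profile: ArmCNProfile, params: BranchingParams) -> float:
    """Log-likelihood of the arm profile under the branching process.

    Each determined arm contributes two independent single-copy lineages
    (its major and minor allele).  Returns ``-inf`` when any observed count
    has zero probability; raises when a count exceeds the model's support.
    """
    pmf = copy_number_pmf(params)
    total = 0.0
    for arm, state in profile.arms.items():
        if state is None:
            continue
        for count in state:
            if count >= len(pmf):
                raise UnrepresentableStateError(
                    f"arm {arm}: copy number {count} exceeds model support "
                    f"{len(pmf) - 1}; increase n_periods")
            p = pmf[count]
            if p <= 0.0:
                return -math.inf
            total += math.log(p)
    return total


@dataclass
class FitResult:
    """Maximum-likelihood fit of one model to one arm profile."""

    model: str  # "wgd" | "non_wgd"
    params: BranchingParams
    log_likelihood: float
    k: int
    aic: float
    sample_id: str = ""
    n_arms: int = 0
    delta_aic: Optional[float] = None
    selected: Optional[str] = None


def _golden_section(fun, lo: float, hi: float, tol: float = 1e-5) -> tuple[float, float]:
    """Deterministic golden-section minimisation of ``fun`` on [lo, hi]."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = fun(c), fun(d)
    while (b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fun(d)
    x = (a + b) / 2.0
    return x, fun(x)


def _safe_loglik(profile: ArmCNProfile, params: BranchingParams) -> float:
    ll = log_likelihood(profile, params)
    return ll if math.isfinite(ll) else _NEG_SENTINEL


def fit_model(profile: ArmCNProfile, with_wgd: bool, n_periods: int = 6,
              constrained: bool = True) -> FitResult:
    """Fit the branching process to one sample's arm profile by maximum
    likelihood.

    The constrained model imposes alpha = gamma = r and searches r over
    [0, 0.5] (coarse grid then golden-section refinement); the WGD model
    additionally enumerates the doubling time M in {1, ..., N}.  The
    unconstrained model optimises (alpha, gamma) on a 2-D grid with
    Nelder-Mead refinement.  Fitting is fully deterministic.
    """
    if not profile.determined():
        raise FitError("profile has no determined arms")
    counts = profile.allele_counts()
    support = 2 ** (n_periods + (1 if with_wgd else 0))
    if counts.max() > support:
        raise UnrepresentableStateError(
            f"observed per-allele copy number {int(counts.max())} exceeds "
            f"model support {support}; increase n_periods")

    m_values = list(range(1, n_periods + 1)) if with_wgd else [None]

    if constrained:
        def neg_ll(r: float, m: Optional[int]) -> float:
            r = min(max(r, 0.0), 0.5)
            return -_safe_loglik(profile, BranchingParams.symmetric(r, n_periods, m))

        best = None
        grid = np.arange(0.0, 0.5 + 1e-12, 0.005)
        for m in m_values:
            vals = np.array([neg_ll(r, m) for r in grid])
            i = int(np.argmin(vals))
            lo = grid[max(i - 1, 0)]
            hi = grid[min(i + 1, len(grid) - 1)]
            r_hat, f_hat = _golden_section(lambda r, m=m: neg_ll(r, m), lo, hi)
            if f_hat > vals[i]:  # keep the grid point if refinement regressed
                r_hat, f_hat = grid[i], vals[i]
            if best is None or f_hat < best[0]:
                best = (f_hat, r_hat, m)
        f_best, r_best, m_best = best
        params = BranchingParams.symmetric(round(r_best, 10), n_periods, m_best)
        k = 2 if with_wgd else 1
    else:
        from scipy.optimize import minimize

        def neg_ll2(ag, m: Optional[int]) -> float:
            a, g = ag
            if a < 0 or g < 0 or a + g > 1:
                return -_NEG_SENTINEL
            p = BranchingParams(alpha=a, beta=1.0 - a - g, gamma=g,
                                n_periods=n_periods, wgd_time=m)
            return -_safe_loglik(profile, p)

        best = None
        steps = np.arange(0.0, 0.51, 0.02)
        for m in m_values:
            grid_best = None
            for a in steps:
                for g in steps:
                    v = neg_ll2((a, g), m)
                    if grid_best is None or v < grid_best[0]:
                        grid_best = (v, a, g)
            res = minimize(neg_ll2, x0=[grid_best[1], grid_best[2]], args=(m,),
                           method="Nelder-Mead",
                           options={"xatol": 1e-6, "fatol": 1e-9})
            cand = (res.fun, res.x[0], res.x[1], m) if res.fun < grid_best[0] \
                else (grid_best[0], grid_best[1], grid_best[2], m)
            if best is None or cand[0] < best[0]:
                best = cand
        f_best, a_best, g_best, m_best = best
        a_best = min(max(a_best, 0.0), 1.0)
        g_best = min(max(g_best, 0.0), 1.0 - a_best)
        params = BranchingParams(alpha=a_best, beta=1.0 - a_best - g_best,
                                 gamma=g_best, n_periods=n_periods,
                                 wgd_time=m_best)
        k = 3 if with_wgd else 2

    ll = -f_best
    if ll <= _NEG_SENTINEL:
        raise FitError("all parameter values give zero likelihood; "
                       "increase n_periods")
    return FitResult(model="wgd" if with_wgd else "non_wgd", params=params,
                     log_likelihood=ll, k=k, aic=2 * k - 2 * ll,
                     sample_id=profile.sample_id,
                     n_arms=len(profile.determined()))


@dataclass
class ModelSelection:
    """AIC comparison of the WGD and non-WGD fits on one profile.

    AIC values use the general (unconstrained) parameter counting — 3 for
    the WGD model, 2 without — applied uniformly, which offsets constrained
    fits by a constant +2 on both sides and leaves ``delta_aic`` unchanged.
    """

    fit_wgd: FitResult
    fit_non_wgd: FitResult
    aic_wgd: float
    aic_non_wgd: float
    delta_aic: float
    selected: str


GENERAL_K = {"wgd": 3, "non_wgd": 2}


def select_model(fit_wgd: FitResult, fit_non_wgd: FitResult) -> ModelSelection:
    """Pick the better-supported model; delta_aic > 0 favours WGD.

    Ties resolve to the non-WGD model (parsimony).
    """
    if fit_wgd.model != "wgd" or fit_non_wgd.model != "non_wgd":
        raise ValidationError("select_model expects (wgd fit, non-wgd fit)")
    if (fit_wgd.sample_id != fit_non_wgd.sample_id
            or fit_wgd.n_arms != fit_non_wgd.n_arms
            or fit_wgd.params.n_periods != fit_non_wgd.params.n_periods):
        raise ValidationError("fits compare different profiles or N")
    aic_w = 2 * GENERAL_K["wgd"] - 2 * fit_wgd.log_likelihood
    aic_nw = 2 * GENERAL_K["non_wgd"] - 2 * fit_non_wgd.log_likelihood
    delta = aic_nw - aic_w
    selected = "wgd" if delta > 0 else "non_wgd"
    fit_wgd = replace(fit_wgd, delta_aic=delta, selected=selected)
    fit_non_wgd = replace(fit_non_wgd, delta_aic=delta, selected=selected)
    return ModelSelection(fit_wgd=fit_wgd, fit_non_wgd=fit_non_wgd,
                          aic_wgd=aic_w, aic_non_wgd=aic_nw,
                          delta_aic=delta, selected=selected)


def summarize_arms(segments: SegmentTable, arms: ArmDefinitions,
                   min_coverage: float = 0.5) -> ArmCNProfile:
    """Collapse a segment table to one (major, minor) state per included arm.

    The arm state is the length-weighted modal pair among overlapping
    determined segments; an arm is undetermined when determined segments
    cover less than ``min_coverage`` of its length.
    """
    det = segments.determined
    profile: dict[str, Optional[tuple[int, int]]] = {}
    any_covered = False
    for arm in arms.included_arms():
        chrom, a_start, a_end = arms.interval(arm)
        arm_len = a_end - a_start
        weights: dict[tuple[int, int], int] = {}
        covered = 0
        sub = det[det["chromosome"] == chrom]
        for _, row in sub.iterrows():
            lo = max(int(row["start"]), a_start)
            hi = min(int(row["end"]), a_end)
            if hi <= lo:
                continue
            pair = (int(row["major_cn"]), int(row["minor_cn"]))
            weights[pair] = weights.get(pair, 0) + (hi - lo)
            covered += hi - lo
        if covered > 0:
            any_covered = True
        if covered < min_coverage * arm_len:
            profile[arm] = None
            continue
        # deterministic tie-break: largest weight, then smallest pair
        profile[arm] = min(weights, key=lambda p: (-weights[p], p))
    if not any_covered:
        raise FitError("no segments overlap any included arm")
    return ArmCNProfile(sample_id=segments.sample_id, arms=profile)
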