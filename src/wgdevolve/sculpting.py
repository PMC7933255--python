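"""LOH "sculpting" statistics.

If loss of heterozygosity were selected because it deletes deleterious
non-synonymous mutations or neoantigens, acquired-LOH segments should
preferentially remove regions carrying more non-synonymous mutations than
expected.  The expected count is derived from the observed synonymous count
and the genetic code: under a substitution model, a random coding
single-nucleotide change is non-synonymous with probability ``p_ns``
(codon-usage weighted), so a segment with ``n_syn`` synonymous mutations is
expected to carry ``n_syn * p_ns / p_s`` non-synonymous ones.  Per-segment
excess flags are aggregated with an exact one-sided binomial test, losses of
predicted expressed neoantigens are accounted per merged LOH event, and
mutual exclusivity of high neo-antigenicity versus high non-synonymous load
across a patient's LOH regions is tested with a two-sided unconditional
exact (Barnard) test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ai_loh import LohEvent
from .errors import InsufficientDataError, ValidationError
from .io_formats import SENSE_CODONS, STOP_CODONS
from Bio.Data.CodonTable import standard_dna_table

_BASES = "ACGT"


@dataclass(frozen=True)
class CodonMutabilityProfile:
    """Probability that a random coding single-nucleotide change is
    non-synonymous (``p_ns``) or synonymous (``p_s``)."""

    p_ns: float
    p_s: float

    @property
    def ratio(self) -> float:
        """Expected non-synonymous per synonymous mutation, p_ns / p_s."""
        return self.p_ns / self.p_s


def _neighbour_fractions() -> dict[str, float]:
    """Per-codon fraction of its 9 single-nucleotide neighbours that are
    non-synonymous (stop-gain counts as non-synonymous)."""
    code = standard_dna_table.forward_table
    out = {}
    for codon in SENSE_CODONS:
        aa = code[codon]
        nonsyn = 0
        for i in range(3):
            for b in _BASES:
                if b == codon[i]:
                    continue
                alt = codon[:i] + b + codon[i + 1:]
                if alt in STOP_CODONS or code[alt] != aa:
                    nonsyn += 1
        out[codon] = nonsyn / 9.0
    return out


_NEIGHBOUR_NS_FRACTION = _neighbour_fractions()


def codon_mutability(usage: Mapping[str, float]) -> CodonMutabilityProfile:
    """Usage-weighted probability that a coding SNV is non-synonymous.

    Assumes a uniform substitution model over the nine single-nucleotide
    neighbours of each codon.
    """
    if not usage:
        raise ValidationError("empty codon usage table")
    total = sum(usage.values())
    if total <= 0:
        raise ValidationError("codon usage weights sum to zero")
    p_ns = sum(w * _NEIGHBOUR_NS_FRACTION[c] for c, w in usage.items()) / total
    return CodonMutabilityProfile(p_ns=p_ns, p_s=1.0 - p_ns)


@dataclass
class SegmentMutationSummary:
    """Observed and expected mutation counts of one acquired-LOH segment."""

    chromosome: str
    start: int
    end: int
    n_syn: int
    n_nonsyn: int
    expected_nonsyn: float
    exceeds: bool

    @property
    def length(self) -> int:
        return self.end - self.start


def segment_excess(segment: tuple[str, int, int], mutations: pd.DataFrame,
                   profile: CodonMutabilityProfile) -> SegmentMutationSummary:
    """Compare a segment's non-synonymous count with the codon-usage
    expectation ``n_syn * p_ns / p_s``."""
    chrom, start, end = segment
    sub = mutations[(mutations["chromosome"] == str(chrom))
                    & (mutations["position"] >= start)
                    & (mutations["position"] < end)]
    n_syn = int((sub["consequence"] == "synonymous").sum())
    n_nonsyn = int((sub["consequence"] == "nonsynonymous").sum())
    expected = n_syn * profile.ratio
    return SegmentMutationSummary(chromosome=str(chrom), start=start, end=end,
                                  n_syn=n_syn, n_nonsyn=n_nonsyn,
                                  expected_nonsyn=expected,
                                  exceeds=n_nonsyn > expected)


def filter_large_segments(segments: pd.DataFrame,
                          min_length: int = 10_000_000) -> pd.DataFrame:
    """Keep segments strictly longer than ``min_length`` bp (default 10 Mb),
    discarding small fragments prone to over-segmentation."""
    lengths = segments["end"] - segments["start"]
    return segments[lengths > min_length].reset_index(drop=True)


@dataclass
class BinomialExcessResult:
    k: int          # segments exceeding expectation
    n: int          # segments tested
    null_p: float   # per-segment exceedance probability under the null
    p_value: float  # one-sided, P(X >= k) for X ~ Binomial(n, null_p)


def binomial_excess_test(summaries: Sequence[SegmentMutationSummary],
                         null: str = "per_segment",
                         profile: Optional[CodonMutabilityProfile] = None
                         ) -> BinomialExcessResult:
    """One-sided exact binomial test of segment-level excess flags.

    ``null='half'`` takes the exceedance probability as 0.5.  The default
    ``null='per_segment'`` derives it from the data: for a segment with
    ``m`` mutations the null exceedance probability is
    ``P(Binomial(m, p_ns) > m * p_ns)`` — the chance of exceeding its own
    expectation when consequences are assigned independently of position —
    and ``null_p`` is the mean over segments.  Note ``n_nonsyn >
    n_syn * p_ns / p_s`` is equivalent to ``n_nonsyn > m * p_ns``.
    """
    n = len(summaries)
    if n == 0:
        raise InsufficientDataError("no segments to test")
    k = sum(1 for s in summaries if s.exceeds)
    if null == "half":
        null_p = 0.5
    elif null == "per_segment":
        probs = []
        for s in summaries:
            m = s.n_syn + s.n_nonsyn
            if m == 0:
                probs.append(0.0)
                continue
            if profile is not None:
                p_ns = profile.p_ns
            elif s.n_syn + s.expected_nonsyn > 0:
                # invert expected = n_syn * p_ns / p_s
                p_ns = s.expected_nonsyn / (s.n_syn + s.expected_nonsyn)
            else:
                p_ns = 0.0
            probs.append(float(stats.binom.sf(math.floor(m * p_ns), m, p_ns)))
        null_p = float(np.mean(probs))
    else:
        raise ValueError(f"unknown null mode {null!r}")
    p_value = float(stats.binom.sf(k - 1, n, null_p))  # P(X >= k)
    return BinomialExcessResult(k=k, n=n, null_p=null_p,
                                p_value=min(p_value, 1.0))


def binomial_excess_from_counts(counts: Iterable[tuple[int, int]],
                                profile: CodonMutabilityProfile,
                                null: str = "per_segment") -> BinomialExcessResult:
    """Convenience wrapper taking (n_syn, n_nonsyn) count pairs directly."""
    summaries = []
    for i, (n_syn, n_nonsyn) in enumerate(counts):
        expected = n_syn * profile.ratio
        summaries.append(SegmentMutationSummary(
            chromosome="", start=0, end=0, n_syn=n_syn, n_nonsyn=n_nonsyn,
            expected_nonsyn=expected, exceeds=n_nonsyn > expected))
    return binomial_excess_test(summaries, null=null, profile=profile)


def neoantigen_losses(events: Sequence[LohEvent], neoantigens: pd.DataFrame,
                      mutations: pd.DataFrame,
                      expressed_only: bool = True) -> tuple[list[int], int]:
    """Count predicted neoantigenic mutations deleted by each LOH event.

    A neoantigenic mutation is lost to an event when its position lies in
    the event interval and it is absent from every member late sample.
    Returns per-event counts and the patient total de-duplicated across
    events.
    """
    known = set(mutations["mutation_id"])
    dangling = set(neoantigens["mutation_id"]) - known
    if dangling:
        raise ValidationError(
            f"neoantigen records reference unknown mutations: {sorted(dangling)[:5]}")
    neo = neoantigens
    if expressed_only:
        neo = neo[neo["expressed"]]
    neo_ids = set(neo["mutation_id"])
    muts = mutations[mutations["mutation_id"].isin(neo_ids)]

    per_event: list[int] = []
    lost_ids: set[str] = set()
    for ev in events:
        inside = muts[(muts["chromosome"] == ev.chromosome)
                      & (muts["position"] >= ev.start)
                      & (muts["position"] < ev.end)]
        absent = inside[inside["present_in"].map(
            lambda s: all(m not in s for m in ev.samples)).astype(bool)]
        per_event.append(len(absent))
        lost_ids.update(absent["mutation_id"])
    return per_event, len(lost_ids)


@dataclass(frozen=True)
class TwoByTwoTable:
    """Joint classification of LOH regions by neo-antigenicity and
    non-synonymous load.

    a: high-neo & low-nonsyn, b: high-neo & high-nonsyn,
    c: low-neo & low-nonsyn, d: low-neo & high-nonsyn.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("negative cell count")
        if self.a + self.b + self.c + self.d < 1:
            raise ValidationError("empty table")


def classify_2x2(neo_scores: Sequence[float], nonsyn_counts: Sequence[float],
                 split: str = "median") -> TwoByTwoTable:
    """Median-split each measure into high/low (ties -> low) and cross-tab."""
    if split != "median":
        raise ValueError(f"unknown split {split!r}")
    if len(neo_scores) != len(nonsyn_counts):
        raise ValidationError("measure vectors differ in length")
    n = len(neo_scores)
    if n < 4:
        raise InsufficientDataError(f"only {n} events; need >= 4")
    neo = np.asarray(neo_scores, float)
    ns = np.asarray(nonsyn_counts, float)
    hi_neo = neo > np.median(neo)
    hi_ns = ns > np.median(ns)
    return TwoByTwoTable(
        a=int(np.sum(hi_neo & ~hi_ns)), b=int(np.sum(hi_neo & hi_ns)),
        c=int(np.sum(~hi_neo & ~hi_ns)), d=int(np.sum(~hi_neo & hi_ns)))


def _wald_statistics(n1: int, n2: int) -> np.ndarray:
    """Pooled Wald statistic for every (x1, x2) outcome pair; zero where the
    pooled proportion is degenerate."""
    x1 = np.arange(n1 + 1, dtype=float)[:, None]
    x2 = np.arange(n2 + 1, dtype=float)[None, :]
    pooled = (x1 + x2) / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
        t = (x1 / n1 - x2 / n2) / se
    t[~np.isfinite(t)] = 0.0
    return t


def barnard_test(table: TwoByTwoTable, grid_size: int = 999) -> float:
    """Two-sided unconditional exact (Barnard) test with fixed column margins.

    The two columns (high-neo and low-neo regions) are treated as
    independent binomial samples with a common nuisance success probability
    pi; the test statistic is the pooled Wald score.  The p-value is the
    maximum over a uniform pi grid of the total probability of outcomes at
    least as extreme as observed.
    """
    n1, n2 = table.a + table.b, table.c + table.d
    if n1 == 0 and n2 == 0:
        raise InsufficientDataError("both margins empty")
    t = _wald_statistics(n1, n2)
    t_obs = t[table.b, table.d]
    extreme = np.abs(t) >= np.abs(t_obs) - 1e-12

    pis = np.linspace(1.0 / (grid_size + 1), grid_size / (grid_size + 1), grid_size)
    x1 = np.arange(n1 + 1)
    x2 = np.arange(n2 + 1)
    # pmf1: (n1+1, grid), pmf2: (n2+1, grid)
    pmf1 = stats.binom.pmf(x1[:, None], n1, pis[None, :])
    pmf2 = stats.binom.pmf(x2[:, None], n2, pis[None, :])
    # For each pi: sum over extreme (x1, x2) of pmf1 * pmf2
    tail = np.einsum("ig,jg,ij->g", pmf1, pmf2, extreme.astype(float))
    return float(min(max(tail.max(), 0.0), 1.0))
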