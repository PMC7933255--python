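"""Allelic-imbalance and LOH genome summarisation.

A segment's allelic state follows from its (major, minor) copy numbers:
equal copies of both parental alleles is *balanced*; unequal but both
present is *allelic imbalance without LOH*; minor copy number zero —
including homozygous deletion — is *LOH*.  Acquired LOH between an early
and a late lesion of the same patient is the genomic territory that is LOH
in the late sample but was determined and not LOH in the early one.
Overlapping acquired-LOH segments across the late samples of a patient are
collected into events by single-linkage merging, and mirrored allelic
imbalance (the same region imbalanced in two lesions with opposite parental
alleles favoured) is detected from B-allele frequencies of shared
heterozygous SNPs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .io_formats import BafTable, SegmentTable

BALANCED = "balanced"
AI_NO_LOH = "ai_no_loh"
AI_LOH = "ai_loh"
UNDETERMINED = "undetermined"
STATES = (BALANCED, AI_NO_LOH, AI_LOH, UNDETERMINED)


def classify_state(major_cn, minor_cn) -> str:
    """Classify a (major, minor) copy-number pair into an allelic state."""
    if major_cn is None or minor_cn is None or pd.isna(major_cn) or pd.isna(minor_cn):
        return UNDETERMINED
    major, minor = int(major_cn), int(minor_cn)
    if minor > major:
        raise ValidationError(f"minor_cn {minor} > major_cn {major}")
    if minor < 0:
        raise ValidationError("negative copy number")
    if minor == 0:  # includes (0, 0) homozygous deletion
        return AI_LOH
    if major == minor:
        return BALANCED
    return AI_NO_LOH


@dataclass
class GenomeStateSummary:
    """Length fractions of the genome per allelic state, plus mean ploidy."""

    fractions: dict[str, float]
    mean_ploidy: float

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"state fractions sum to {total}, not 1")


def _states_column(df: pd.DataFrame) -> pd.Series:
    return df.apply(lambda r: classify_state(r["major_cn"], r["minor_cn"]), axis=1)


def genome_summary(segments: SegmentTable, genome_length: int) -> GenomeStateSummary:
    """Summarise a sample's genome by allelic state and mean ploidy.

    Genome not covered by any segment counts as undetermined; mean ploidy
    is the length-weighted mean total copy number over determined segments.
    """
    df = segments.df
    lengths = (df["end"] - df["start"]).astype(float)
    if genome_length < lengths.sum() - 1e-9:
        raise ValidationError("genome_length smaller than total segment length")
    states = _states_column(df) if len(df) else pd.Series(dtype=object)
    fractions = {s: 0.0 for s in STATES}
    for state, length in zip(states, lengths):
        fractions[state] += length / genome_length
    covered = lengths.sum()
    fractions[UNDETERMINED] += (genome_length - covered) / genome_length

    det = df["total_cn"].notna()
    det_len = lengths[det].sum()
    if det_len <= 0:
        raise InsufficientDataError("no determined segments; mean ploidy undefined")
    ploidy = float((df.loc[det, "total_cn"].astype(float) * lengths[det]).sum() / det_len)
    return GenomeStateSummary(fractions=fractions, mean_ploidy=ploidy)


def acquired_loh(early: SegmentTable, late: SegmentTable) -> pd.DataFrame:
    """Regions that are LOH in the late sample but not in the early one.

    Returns the interval intersection of late LOH segments with
    early-determined non-LOH segments, as a frame with columns chromosome,
    start, end, early_sample, late_sample, early_state, length.
    Early-undetermined territory is excluded (conservative).
    """
    early_df = early.df.assign(state=_states_column(early.df) if len(early.df) else [])
    late_df = late.df.assign(state=_states_column(late.df) if len(late.df) else [])
    rows = []
    for chrom, late_sub in late_df[late_df["state"] == AI_LOH].groupby("chromosome"):
        early_sub = early_df[(early_df["chromosome"] == chrom)
                             & early_df["state"].isin([BALANCED, AI_NO_LOH])]
        for _, lrow in late_sub.iterrows():
            for _, erow in early_sub.iterrows():
                lo = max(int(lrow["start"]), int(erow["start"]))
                hi = min(int(lrow["end"]), int(erow["end"]))
                if hi > lo:
                    rows.append({"chromosome": chrom, "start": lo, "end": hi,
                                 "early_sample": early.sample_id,
                                 "late_sample": late.sample_id,
                                 "early_state": erow["state"],
                                 "length": hi - lo})
    out = pd.DataFrame(rows, columns=["chromosome", "start", "end",
                                      "early_sample", "late_sample",
                                      "early_state", "length"])
    return out.sort_values(["chromosome", "start"]).reset_index(drop=True)


@dataclass
class LostMutationResult:
    """Attribution of mutations lost between two samples to acquired LOH."""

    n_lost: int
    n_in_loh: int
    fraction: float  # NaN when no mutations were lost
    ccf_in_loh: list[float] = field(default_factory=list)
    ccf_elsewhere: list[float] = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return self.n_lost > 0


def lost_mutation_loh_fraction(mutations: pd.DataFrame, early_sample: str,
                               late_sample: str,
                               acquired: pd.DataFrame) -> LostMutationResult:
    """Fraction of lost mutations that fall inside acquired-LOH intervals.

    A mutation is *lost* when present in the early sample and absent from
    the late one.  Early-disease CCFs are returned split by group for
    descriptive comparison.
    """
    lost = mutations[mutations["present_in"].map(
        lambda s: early_sample in s and late_sample not in s).astype(bool)]
    n_lost = len(lost)
    if n_lost == 0:
        return LostMutationResult(n_lost=0, n_in_loh=0, fraction=math.nan)
    in_loh = np.zeros(n_lost, dtype=bool)
    for i, (_, mut) in enumerate(lost.iterrows()):
        hits = acquired[(acquired["chromosome"] == mut["chromosome"])
                        & (acquired["start"] <= mut["position"])
                        & (mut["position"] < acquired["end"])]
        in_loh[i] = len(hits) > 0
    ccf = lost["ccf"].to_numpy(float)
    return LostMutationResult(
        n_lost=n_lost, n_in_loh=int(in_loh.sum()),
        fraction=float(in_loh.mean()),
        ccf_in_loh=[c for c, f in zip(ccf, in_loh) if f and not math.isnan(c)],
        ccf_elsewhere=[c for c, f in zip(ccf, in_loh) if not f and not math.isnan(c)])


@dataclass
class LohEvent:
    """A merged acquired-LOH interval shared by one patient's late samples."""

    chromosome: str
    start: int
    end: int
    samples: frozenset[str]
    members: tuple[tuple[str, int, int], ...]  # (late_sample, start, end)

    @property
    def length(self) -> int:
        return self.end - self.start


def merge_loh_events(acquired_by_sample: dict[str, pd.DataFrame]) -> list[LohEvent]:
    """Single-linkage merge of overlapping acquired-LOH segments (>= 1 bp)
    across a patient's late samples into events."""
    intervals = []  # (chrom, start, end, sample)
    for sample, df in acquired_by_sample.items():
        for _, row in df.iterrows():
            intervals.append((str(row["chromosome"]), int(row["start"]),
                              int(row["end"]), sample))
    events: list[LohEvent] = []
    by_chrom: dict[str, list] = {}
    for iv in intervals:
        by_chrom.setdefault(iv[0], []).append(iv)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x[1], x[2]))
        cur_start, cur_end = ivs[0][1], ivs[0][2]
        cur_members = [ivs[0]]
        for iv in ivs[1:]:
            if iv[1] < cur_end:  # strict overlap, not mere adjacency
                cur_end = max(cur_end, iv[2])
                cur_members.append(iv)
            else:
                events.append(_make_event(chrom, cur_start, cur_end, cur_members))
                cur_start, cur_end, cur_members = iv[1], iv[2], [iv]
        events.append(_make_event(chrom, cur_start, cur_end, cur_members))
    return events


def _make_event(chrom: str, start: int, end: int, members: list) -> LohEvent:
    return LohEvent(chromosome=chrom, start=start, end=end,
                    samples=frozenset(m[3] for m in members),
                    members=tuple((m[3], m[1], m[2]) for m in members))


@dataclass
class MirroredAiResult:
    mirror_score: float
    is_mirrored: bool
    n_snps: int
    mean_dev_a: float
    mean_dev_b: float


def detect_mirrored_ai(bafs_a: BafTable, bafs_b: BafTable, region,
                       imbalance_threshold: float = 0.1,
                       score_threshold: float = 0.5) -> MirroredAiResult:
    """Test two samples for mirrored allelic imbalance over a region.

    ``region`` is a chromosome name or (chromosome, start, end).  The mirror
    score is the negated Pearson correlation of (baf - 0.5) across shared
    SNPs; a call requires both samples imbalanced (mean |baf - 0.5| above
    ``imbalance_threshold``) and a score above ``score_threshold``.
    """
    if isinstance(region, str):
        chrom, lo, hi = region, 0, np.inf
    else:
        chrom, lo, hi = region
    def subset(t: BafTable) -> pd.DataFrame:
        df = t.df
        return df[(df["chromosome"] == str(chrom)) & (df["position"] >= lo)
                  & (df["position"] < hi)]
    merged = subset(bafs_a).merge(subset(bafs_b), on=["chromosome", "position"],
                                  suffixes=("_a", "_b"))
    n = len(merged)
    if n < 10:
        raise InsufficientDataError(
            f"only {n} shared heterozygous SNPs in region (need >= 10)")
    dev_a = merged["baf_a"].to_numpy(float) - 0.5
    dev_b = merged["baf_b"].to_numpy(float) - 0.5
    if dev_a.std() > 0 and dev_b.std() > 0:
        score = -float(np.corrcoef(dev_a, dev_b)[0, 1])
    else:
        # degenerate (noise-free) tracks: score by the sign of the mean devs
        prod = dev_a.mean() * dev_b.mean()
        score = 0.0 if prod == 0 else (1.0 if prod < 0 else -1.0)
    imbalanced = (np.abs(dev_a).mean() > imbalance_threshold
                  and np.abs(dev_b).mean() > imbalance_threshold)
    return MirroredAiResult(mirror_score=score,
                            is_mirrored=bool(imbalanced and score > score_threshold),
                            n_snps=n,
                            mean_dev_a=float(np.abs(dev_a).mean()),
                            mean_dev_b=float(np.abs(dev_b).mean()))
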