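"""Synthetic multi-sample melanoma-like cohorts with known ground truth.

Each simulated patient mirrors the structure of a rapid-autopsy series:
near-diploid early lesions (primary or regional disease) and late distant
metastases whose arm-level copy numbers are drawn from the same branching
process the inference fits, with or without a single whole-genome doubling.
Acquired-LOH events are planted by forcing the minor allele to zero on
chosen arms of every late sample; point mutations are placed with a stated
synonymous/non-synonymous split, a planted fraction of the mutations lost
between early and late disease falls inside the LOH territory, neoantigen
records are attached with known per-event loss counts, and B-allele
frequency tracks (optionally mirrored between two lesions) are emitted.
Every planted quantity is recorded in a ground-truth ledger so pipeline
stages can be checked exactly; with jitter and noise parameters at zero the
recovery is exact rather than statistical.

Arm geometry is the bundled hg19 table.  One RNG stream per patient is
derived from the master seed, so cohorts are stable under appending
patients.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import genome
from .cn_model import ArmCNProfile, BranchingParams
from .errors import ConfigError
from .io_formats import (ArmDefinitions, BafTable, SegmentTable,
                         segment_table_from_records, write_baf_table,
                         write_mutation_table, write_neoantigen_table,
                         write_segment_table)


def default_arm_definitions() -> ArmDefinitions:
    """ArmDefinitions over the bundled hg19 autosomal arm table."""
    rows = [{"arm": a, "chromosome": c, "start": s, "end": e, "included": inc}
            for a, c, s, e, inc in genome.default_arm_table()]
    return ArmDefinitions(table=pd.DataFrame(rows))


def simulate_arm_counts(params: BranchingParams, n_lineages: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Forward-simulate ``n_lineages`` independent single-copy lineages.

    Each period every extant copy is deleted (alpha), kept (beta) or
    duplicated (gamma); after period ``wgd_time`` all extant copies double.
    Returns final copy numbers.
    """
    counts = np.ones(n_lineages, dtype=np.int64)
    keep_or_dup = params.beta + params.gamma
    dup_given_kept = params.gamma / keep_or_dup if keep_or_dup > 0 else 0.0
    for period in range(1, params.n_periods + 1):
        deleted = rng.binomial(counts, params.alpha)
        survivors = counts - deleted
        duplicated = rng.binomial(survivors, dup_given_kept)
        counts = survivors + duplicated
        if params.wgd_time is not None and period == params.wgd_time:
            counts *= 2
    return counts


def simulate_arm_profile(params: BranchingParams, n_arms: int,
                         rng: np.random.Generator | int,
                         arm_ids: Optional[list[str]] = None,
                         sample_id: str = "sim") -> ArmCNProfile:
    """Draw an arm-level (major, minor) profile from the branching process,
    two independent allele lineages per arm."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if arm_ids is None:
        arm_ids = [f"arm{i}" for i in range(n_arms)]
    counts = simulate_arm_counts(params, 2 * n_arms, rng).reshape(n_arms, 2)
    arms = {arm: (int(max(a, b)), int(min(a, b)))
            for arm, (a, b) in zip(arm_ids, counts)}
    return ArmCNProfile(sample_id=sample_id, arms=arms)


@dataclass
class PatientConfig:
    """Per-patient simulation settings.

    Defaults describe a post-WGD late-disease patient: the branching rate
    0.05 per copy per period over N = 6 periods with doubling midway, 39
    modelled autosomal arms, an acquired-LOH target near 20% of the genome,
    a 3:1 non-synonymous:synonymous mutation split typical of coding SNVs,
    and most early-to-late mutation loss co-located with acquired LOH.
    """

    patient_id: str = "SIM-A"
    rate: float = 0.05
    early_rate: float = 0.0
    n_periods: int = 6
    wgd: bool = True
    wgd_time: int = 3
    n_arms: int = 39
    n_early: int = 1
    n_late: int = 2
    loh_target_fraction: float = 0.2
    n_mutations: int = 400
    p_ns: float = 0.75
    lost_fraction: float = 0.25
    lost_in_loh_fraction: float = 0.8
    event_neoantigen_losses: tuple[int, ...] = (2, 5, 1)
    n_background_neoantigens: int = 30
    baf_n_snps: int = 200
    baf_imbalance: float = 0.3
    baf_noise_sd: float = 0.03
    mirrored_baf: bool = True
    ccf_sd: float = 0.05
    segment_jitter: int = 1_000_000

    def noise_free(self) -> "PatientConfig":
        """Copy with every stochastic nuisance switched off (exact-recovery
        mode): no background CN events, jitter, BAF or CCF noise."""
        return dataclasses.replace(self, rate=0.0, early_rate=0.0,
                                   segment_jitter=0, baf_noise_sd=0.0,
                                   ccf_sd=0.0)


@dataclass
class CohortConfig:
    seed: int
    n_patients: int = 3
    patient: PatientConfig = field(default_factory=PatientConfig)


@dataclass
class PatientBundle:
    """All simulated inputs for one patient plus the ground-truth ledger."""

    patient_id: str
    seed: int
    early_samples: list[str]
    late_samples: list[str]
    segment_tables: dict[str, SegmentTable]
    arm_profiles: dict[str, ArmCNProfile]
    mutations: pd.DataFrame
    neoantigens: pd.DataFrame
    baf_tables: dict[str, BafTable]
    ground_truth: dict


def _uniform_position(rng: np.random.Generator, start: int, end: int,
                      margin: int) -> int:
    lo, hi = start + margin, end - margin
    if hi <= lo:
        lo, hi = start, end
    return int(rng.integers(lo, hi))


def simulate_patient(config: PatientConfig, seed: int) -> PatientBundle:
    """Generate one synthetic patient; deterministic for a given seed."""
    rng = np.random.default_rng(seed)
    arms = default_arm_definitions()
    included = arms.included_arms()
    if config.n_arms > len(included):
        raise ConfigError(f"n_arms {config.n_arms} exceeds available "
                          f"{len(included)} included arms")
    arm_ids = included[:config.n_arms]
    intervals = {a: arms.interval(a) for a in arm_ids}
    genome_length = genome.autosome_length()

    early_ids = [f"{config.patient_id}-E{i + 1}" for i in range(config.n_early)]
    late_ids = [f"{config.patient_id}-L{i + 1}" for i in range(config.n_late)]

    early_params = BranchingParams.symmetric(config.early_rate, config.n_periods)
    late_params = BranchingParams.symmetric(
        config.rate, config.n_periods,
        config.wgd_time if config.wgd else None)

    profiles: dict[str, ArmCNProfile] = {}
    for sid in early_ids:
        profiles[sid] = simulate_arm_profile(early_params, len(arm_ids), rng,
                                             arm_ids=arm_ids, sample_id=sid)
    for sid in late_ids:
        profiles[sid] = simulate_arm_profile(late_params, len(arm_ids), rng,
                                             arm_ids=arm_ids, sample_id=sid)

    # --- plant acquired-LOH events -------------------------------------
    # Candidate arms must be heterozygous in every early sample so the LOH
    # is genuinely acquired.
    candidates = [a for a in arm_ids
                  if all(profiles[s].arms[a] is not None
                         and profiles[s].arms[a][1] >= 1 for s in early_ids)]
    order = list(rng.permutation(len(candidates)))
    event_arms: list[str] = []
    planted_length = 0
    for idx in order:
        if planted_length >= config.loh_target_fraction * genome_length:
            break
        arm = candidates[idx]
        event_arms.append(arm)
        _, a_start, a_end = intervals[arm]
        planted_length += a_end - a_start
    if config.loh_target_fraction > 0 and not event_arms:
        raise ConfigError("no heterozygous early arms available to plant LOH")
    event_arms.sort(key=arm_ids.index)
    for sid in late_ids:
        for arm in event_arms:
            major, _ = profiles[sid].arms[arm]
            profiles[sid].arms[arm] = (max(major, 1), 0)

    # --- segment tables -------------------------------------------------
    seg_tables: dict[str, SegmentTable] = {}
    for sid, profile in profiles.items():
        records = []
        for arm in arm_ids:
            chrom, a_start, a_end = intervals[arm]
            j1 = int(rng.integers(0, config.segment_jitter + 1))
            j2 = int(rng.integers(0, config.segment_jitter + 1))
            start, end = a_start + j1, a_end - j2
            if end <= start:
                start, end = a_start, a_end
            major, minor = profile.arms[arm]
            records.append((chrom, start, end, major, minor))
        seg_tables[sid] = segment_table_from_records(sid, records)

    # --- mutations ------------------------------------------------------
    n_lost = int(round(config.lost_fraction * config.n_mutations))
    n_lost_loh = int(round(config.lost_in_loh_fraction * n_lost))
    n_events = len(event_arms)
    event_losses = [config.event_neoantigen_losses[i % len(config.event_neoantigen_losses)]
                    if config.event_neoantigen_losses else 0
                    for i in range(n_events)]
    if sum(event_losses) > n_lost_loh:
        raise ConfigError(
            f"planted neoantigen losses ({sum(event_losses)}) exceed "
            f"lost-in-LOH mutation budget ({n_lost_loh})")
    if n_lost > config.n_mutations:
        raise ConfigError("more lost mutations than mutations")
    safe_arms = [a for a in arm_ids if a not in event_arms]
    if not safe_arms and n_lost > n_lost_loh:
        raise ConfigError("no LOH-free arms to place lost-elsewhere mutations")

    all_samples = early_ids + late_ids
    margin = config.segment_jitter
    rows = []
    mut_index = 0

    def add_mutation(arm: str, consequence: str, present: frozenset[str],
                     ccf_centre: float) -> str:
        nonlocal mut_index
        chrom, a_start, a_end = intervals[arm]
        pos = _uniform_position(rng, a_start, a_end, margin)
        ccf = float(np.clip(ccf_centre + rng.normal(0.0, config.ccf_sd)
                            if config.ccf_sd > 0 else ccf_centre, 0.0, 1.0))
        mut_id = f"{config.patient_id}-M{mut_index:05d}"
        mut_index += 1
        rows.append({"mutation_id": mut_id, "chromosome": chrom,
                     "position": pos, "gene": f"GENE{mut_index:05d}",
                     "consequence": consequence, "present_in": present,
                     "ccf": ccf})
        return mut_id

    present_all = frozenset(all_samples)
    present_early_only = frozenset(early_ids)

    neo_rows = []
    hla_pool = ("HLA-A*02:01", "HLA-B*07:02", "HLA-C*06:02")

    def attach_neoantigen(mut_id: str) -> None:
        neo_rows.append({"mutation_id": mut_id,
                         "hla_allele": hla_pool[len(neo_rows) % len(hla_pool)],
                         "binding_rank": round(float(rng.uniform(0.05, 2.0)), 3),
                         "expressed": True})

    # lost-in-LOH mutations, including the planted neoantigenic ones
    placed_loh = 0
    per_event_planted = []
    for arm, losses in zip(event_arms, event_losses):
        for _ in range(losses):
            mid = add_mutation(arm, "nonsynonymous", present_early_only, 0.9)
            attach_neoantigen(mid)
            placed_loh += 1
        per_event_planted.append(losses)
    while placed_loh < n_lost_loh:
        arm = event_arms[int(rng.integers(len(event_arms)))]
        consequence = "nonsynonymous" if rng.random() < config.p_ns else "synonymous"
        add_mutation(arm, consequence, present_early_only, 0.9)
        placed_loh += 1
    # lost elsewhere (never inside planted LOH arms)
    for _ in range(n_lost - n_lost_loh):
        arm = safe_arms[int(rng.integers(len(safe_arms)))]
        consequence = "nonsynonymous" if rng.random() < config.p_ns else "synonymous"
        add_mutation(arm, consequence, present_early_only, 0.35)
    # retained mutations, anywhere
    n_retained = config.n_mutations - n_lost
    retained_ids = []
    for _ in range(n_retained):
        arm = arm_ids[int(rng.integers(len(arm_ids)))]
        consequence = "nonsynonymous" if rng.random() < config.p_ns else "synonymous"
        retained_ids.append(add_mutation(arm, consequence, present_all, 1.0))
    # background neoantigens on retained (not lost) mutations
    retained_nonsyn = [r["mutation_id"] for r in rows
                       if r["present_in"] == present_all
                       and r["consequence"] == "nonsynonymous"]
    n_bg = min(config.n_background_neoantigens, len(retained_nonsyn))
    for mid in retained_nonsyn[:n_bg]:
        attach_neoantigen(mid)

    mutations = pd.DataFrame(rows, columns=["mutation_id", "chromosome",
                                            "position", "gene", "consequence",
                                            "present_in", "ccf"])
    neoantigens = pd.DataFrame(neo_rows, columns=["mutation_id", "hla_allele",
                                                  "binding_rank", "expressed"])

    # --- B-allele frequency tracks --------------------------------------
    baf_chrom = intervals[event_arms[0]][0] if event_arms else "10"
    chrom_len = genome.HG19_CHROMOSOMES[baf_chrom][0]
    positions = np.sort(rng.integers(0, chrom_len, size=config.baf_n_snps))
    baf_tables: dict[str, BafTable] = {}

    def make_baf(sample_id: str, centre: float) -> BafTable:
        noise = (rng.normal(0.0, config.baf_noise_sd, size=len(positions))
                 if config.baf_noise_sd > 0 else 0.0)
        baf = np.clip(centre + noise, 0.0, 1.0)
        return BafTable(sample_id=sample_id,
                        df=pd.DataFrame({"chromosome": baf_chrom,
                                         "position": positions, "baf": baf}))

    for sid in early_ids:
        baf_tables[sid] = make_baf(sid, 0.5)
    if late_ids:
        baf_tables[late_ids[0]] = make_baf(late_ids[0], 0.5 + config.baf_imbalance)
    for sid in late_ids[1:]:
        centre = 0.5 - config.baf_imbalance if config.mirrored_baf \
            else 0.5 + config.baf_imbalance
        baf_tables[sid] = make_baf(sid, centre)

    # --- realized ground truth -------------------------------------------
    acquired_fraction = {}
    for sid in late_ids:
        acq_len = 0
        for arm in arm_ids:
            late_state = profiles[sid].arms[arm]
            early_ok = all(profiles[e].arms[arm][1] >= 1 for e in early_ids)
            if early_ok and late_state[1] == 0:
                _, a_start, a_end = intervals[arm]
                acq_len += a_end - a_start
        acquired_fraction[sid] = acq_len / genome_length

    ground_truth = {
        "patient_id": config.patient_id,
        "seed": int(seed),
        "rate": config.rate,
        "n_periods": config.n_periods,
        "wgd": config.wgd,
        "wgd_time": config.wgd_time if config.wgd else None,
        "genome_length": genome_length,
        "event_arms": event_arms,
        "event_intervals": [list(intervals[a]) for a in event_arms],
        "planted_loh_fraction": planted_length / genome_length,
        "acquired_loh_fraction": acquired_fraction,
        "n_lost": n_lost,
        "n_lost_in_loh": n_lost_loh,
        "lost_in_loh_fraction": (n_lost_loh / n_lost) if n_lost else None,
        "per_event_neoantigen_losses": per_event_planted,
        "event_losses_by_arm": {arm: loss for arm, loss
                                in zip(event_arms, per_event_planted)},
        "total_neoantigen_losses": int(sum(per_event_planted)),
        "p_ns": config.p_ns,
        "baf_chromosome": baf_chrom,
        "mirrored_baf": config.mirrored_baf,
    }

    return PatientBundle(patient_id=config.patient_id, seed=int(seed),
                         early_samples=early_ids, late_samples=late_ids,
                         segment_tables=seg_tables, arm_profiles=profiles,
                         mutations=mutations, neoantigens=neoantigens,
                         baf_tables=baf_tables, ground_truth=ground_truth)


def simulate_cohort(config: CohortConfig) -> list[PatientBundle]:
    """Simulate ``n_patients`` independent patients, one RNG substream each."""
    bundles = []
    for i in range(config.n_patients):
        pconf = dataclasses.replace(config.patient,
                                    patient_id=f"{config.patient.patient_id}{i + 1}")
        sub_seed = int(np.random.SeedSequence([config.seed, i]).generate_state(1)[0]
                       % (2 ** 31))
        bundles.append(simulate_patient(pconf, seed=sub_seed))
    return bundles


def write_bundle(bundle: PatientBundle, outdir: str | Path) -> dict[str, str]:
    """Write all tables of a patient bundle as TSV plus ground_truth.json;
    returns a name -> path mapping."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for sid, table in bundle.segment_tables.items():
        p = outdir / f"{sid}.segments.tsv"
        write_segment_table(table, p)
        paths[f"segments:{sid}"] = str(p)
    p = outdir / f"{bundle.patient_id}.mutations.tsv"
    write_mutation_table(bundle.mutations, p)
    paths["mutations"] = str(p)
    p = outdir / f"{bundle.patient_id}.neoantigens.tsv"
    write_neoantigen_table(bundle.neoantigens, p)
    paths["neoantigens"] = str(p)
    for sid, table in bundle.baf_tables.items():
        p = outdir / f"{sid}.baf.tsv"
        write_baf_table(table, p)
        paths[f"baf:{sid}"] = str(p)
    p = outdir / f"{bundle.patient_id}.ground_truth.json"
    with open(p, "wt") as fh:
        json.dump(bundle.ground_truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["ground_truth"] = str(p)
    return paths
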