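"""End-to-end orchestration: simulate -> fit-wgd -> ai-loh -> sculpt.

The pipeline operates on per-patient collections of early and late samples.
Each stage writes a JSON document (with a schema-version field and the seed
where randomness was involved) and the run ends with a manifest listing
every output file with its SHA-256 digest, so deterministic stages can be
verified to reproduce bit-identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .ai_loh import (acquired_loh, detect_mirrored_ai, genome_summary,
                     lost_mutation_loh_fraction, merge_loh_events)
from .cn_model import fit_model, select_model, summarize_arms
from .errors import ConfigError, InsufficientDataError
from .genome import autosome_length
from .io_formats import (ArmDefinitions, SegmentTable, read_arm_definitions,
                         read_baf_table, read_codon_usage,
                         read_mutation_table, read_neoantigen_table,
                         read_segment_table, uniform_codon_usage)
from .sculpting import (barnard_test, binomial_excess_test, classify_2x2,
                        codon_mutability, filter_large_segments,
                        neoantigen_losses, segment_excess)
from .synthetic import (CohortConfig, PatientBundle, PatientConfig,
                        default_arm_definitions, simulate_cohort, write_bundle)

SCHEMA_VERSION = 1


@dataclass
class RunManifest:
    version: str
    seed: Optional[int]
    config_sha256: str
    input_digests: dict[str, str] = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(doc: dict, path: Path) -> None:
    doc = {"schema_version": SCHEMA_VERSION, **doc}
    with open(path, "wt") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


@dataclass
class PatientData:
    """In-memory inputs of one patient, however they were obtained."""

    patient_id: str
    early_samples: list[str]
    late_samples: list[str]
    segment_tables: dict[str, SegmentTable]
    mutations: Optional[pd.DataFrame] = None
    neoantigens: Optional[pd.DataFrame] = None
    baf_tables: dict = field(default_factory=dict)


def patient_data_from_bundle(bundle: PatientBundle) -> PatientData:
    return PatientData(patient_id=bundle.patient_id,
                       early_samples=bundle.early_samples,
                       late_samples=bundle.late_samples,
                       segment_tables=bundle.segment_tables,
                       mutations=bundle.mutations,
                       neoantigens=bundle.neoantigens,
                       baf_tables=bundle.baf_tables)


def fit_wgd_stage(patient: PatientData, arms: ArmDefinitions,
                  n_periods: int = 6, constrained: bool = True) -> dict:
    """Fit both branching-process models to every sample and select by AIC."""
    results = {}
    for sid, table in patient.segment_tables.items():
        profile = summarize_arms(table, arms)
        fw = fit_model(profile, with_wgd=True, n_periods=n_periods,
                       constrained=constrained)
        fnw = fit_model(profile, with_wgd=False, n_periods=n_periods,
                        constrained=constrained)
        sel = select_model(fw, fnw)
        results[sid] = {
            "rate_wgd": fw.params.alpha,
            "wgd_time": fw.params.wgd_time,
            "rate_non_wgd": fnw.params.alpha,
            "log_likelihood_wgd": fw.log_likelihood,
            "log_likelihood_non_wgd": fnw.log_likelihood,
            "aic_wgd": sel.aic_wgd,
            "aic_non_wgd": sel.aic_non_wgd,
            "delta_aic": sel.delta_aic,
            "selected": sel.selected,
            "n_arms": fw.n_arms,
        }
    return {"n_periods": n_periods, "constrained": constrained,
            "samples": results}


def ai_loh_stage(patient: PatientData, genome_length: Optional[int] = None,
                 baf_region: Optional[str] = None) -> tuple[dict, dict[str, pd.DataFrame]]:
    """Genome state summaries, acquired LOH per late sample, lost-mutation
    attribution and mirrored-AI detection.  Returns the JSON-able summary
    and the per-late-sample acquired-LOH frames for downstream sculpting."""
    genome_length = genome_length or autosome_length()
    summaries = {}
    for sid, table in patient.segment_tables.items():
        gs = genome_summary(table, genome_length)
        summaries[sid] = {"fractions": gs.fractions, "mean_ploidy": gs.mean_ploidy}

    early0 = patient.early_samples[0]
    acquired_frames: dict[str, pd.DataFrame] = {}
    acquired_out = {}
    lost_out = {}
    for late in patient.late_samples:
        acq = acquired_loh(patient.segment_tables[early0],
                           patient.segment_tables[late])
        acquired_frames[late] = acq
        acquired_out[late] = {
            "n_segments": int(len(acq)),
            "total_length": int(acq["length"].sum()) if len(acq) else 0,
            "fraction_of_genome": float(acq["length"].sum() / genome_length)
            if len(acq) else 0.0,
        }
        if patient.mutations is not None:
            res = lost_mutation_loh_fraction(patient.mutations, early0, late, acq)
            lost_out[late] = {
                "n_lost": res.n_lost, "n_in_loh": res.n_in_loh,
                "fraction": res.fraction if res.defined else None,
                "median_ccf_in_loh": float(pd.Series(res.ccf_in_loh).median())
                if res.ccf_in_loh else None,
                "median_ccf_elsewhere": float(pd.Series(res.ccf_elsewhere).median())
                if res.ccf_elsewhere else None,
            }

    mirrored = None
    if len(patient.late_samples) >= 2 and patient.baf_tables:
        a, b = patient.late_samples[0], patient.late_samples[1]
        if a in patient.baf_tables and b in patient.baf_tables:
            region = baf_region or str(
                patient.baf_tables[a].df["chromosome"].iloc[0])
            try:
                res = detect_mirrored_ai(patient.baf_tables[a],
                                         patient.baf_tables[b], region)
                mirrored = {"samples": [a, b], "region": region,
                            "mirror_score": res.mirror_score,
                            "is_mirrored": res.is_mirrored,
                            "n_snps": res.n_snps}
            except InsufficientDataError as exc:
                mirrored = {"samples": [a, b], "region": region,
                            "error": str(exc)}

    doc = {"genome_length": genome_length, "samples": summaries,
           "acquired_loh": acquired_out, "lost_mutations": lost_out,
           "mirrored_ai": mirrored}
    return doc, acquired_frames


def sculpt_stage(patient: PatientData,
                 acquired_frames: dict[str, pd.DataFrame],
                 codon_usage: Optional[dict[str, float]] = None,
                 null: str = "per_segment",
                 min_segment_length: int = 10_000_000) -> dict:
    """Sculpting statistics over a patient's acquired-LOH segments/events."""
    profile = codon_mutability(codon_usage or uniform_codon_usage())
    all_segments = pd.concat(acquired_frames.values(), ignore_index=True) \
        if acquired_frames else pd.DataFrame(columns=["chromosome", "start", "end"])
    large = filter_large_segments(all_segments, min_length=min_segment_length)

    summaries = []
    if patient.mutations is not None:
        for _, row in large.iterrows():
            summaries.append(segment_excess(
                (row["chromosome"], int(row["start"]), int(row["end"])),
                patient.mutations, profile))
    binom = None
    if summaries:
        res = binomial_excess_test(summaries, null=null, profile=profile)
        binom = {"k": res.k, "n": res.n, "null_p": res.null_p,
                 "p_value": res.p_value}

    events = merge_loh_events(acquired_frames)
    neo = None
    two_by_two = None
    if (patient.neoantigens is not None and patient.mutations is not None
            and events):
        per_event, total = neoantigen_losses(events, patient.neoantigens,
                                             patient.mutations,
                                             expressed_only=True)
        neo = {"per_event": per_event, "patient_total": total,
               "n_events": len(events)}
        nonsyn_counts = []
        for ev in events:
            s = segment_excess((ev.chromosome, ev.start, ev.end),
                               patient.mutations, profile)
            nonsyn_counts.append(s.n_nonsyn)
        if len(events) >= 4:
            table = classify_2x2(per_event, nonsyn_counts)
            two_by_two = {"a": table.a, "b": table.b, "c": table.c,
                          "d": table.d, "barnard_p": barnard_test(table)}

    return {"p_ns": profile.p_ns,
            "n_large_segments": int(len(large)),
            "segments": [dataclasses.asdict(s) for s in summaries],
            "binomial_excess": binom,
            "neoantigen_losses": neo,
            "two_by_two": two_by_two}


def _load_patients_from_config(config: dict, base: Path) -> list[PatientData]:
    patients = []
    for pconf in config.get("inputs", {}).get("patients", []):
        seg_tables = {}
        for role in ("early", "late"):
            for path in pconf.get(role, []):
                sid = Path(path).name.split(".")[0]
                seg_tables[sid] = read_segment_table(base / path, sid)
        early = [Path(p).name.split(".")[0] for p in pconf.get("early", [])]
        late = [Path(p).name.split(".")[0] for p in pconf.get("late", [])]
        muts = read_mutation_table(base / pconf["mutations"]) \
            if "mutations" in pconf else None
        neo = read_neoantigen_table(base / pconf["neoantigens"]) \
            if "neoantigens" in pconf else None
        bafs = {}
        for path in pconf.get("baf", []):
            sid = Path(path).name.split(".")[0]
            bafs[sid] = read_baf_table(base / path, sid)
        patients.append(PatientData(
            patient_id=pconf.get("patient_id", "patient"),
            early_samples=early, late_samples=late,
            segment_tables=seg_tables, mutations=muts, neoantigens=neo,
            baf_tables=bafs))
    return patients


def _preflight(config: dict, base: Path) -> list[str]:
    """All input files referenced by the config; raises if any is missing."""
    paths = []
    for pconf in config.get("inputs", {}).get("patients", []):
        for role in ("early", "late", "baf"):
            paths.extend(pconf.get(role, []))
        for key in ("mutations", "neoantigens"):
            if key in pconf:
                paths.append(pconf[key])
    for key in ("arms", "codon_usage"):
        if key in config.get("files", {}):
            paths.append(config["files"][key])
    missing = [p for p in paths if not (base / p).exists()]
    if missing:
        raise ConfigError(f"missing input files: {missing}")
    return paths


def run_pipeline(config: dict, outdir: str | Path,
                 base_dir: str | Path = ".") -> RunManifest:
    """Execute the configured stages in dependency order.

    ``config`` holds either a ``simulate`` section or an ``inputs`` section
    listing per-patient files, plus optional ``fit``/``sculpt`` settings.
    Pre-flight validation runs before any stage; the manifest is written
    last.
    """
    outdir = Path(outdir)
    base = Path(base_dir)
    seed = config.get("seed")
    if "simulate" not in config and "inputs" not in config:
        raise ConfigError("config needs a 'simulate' or 'inputs' section")
    input_paths = _preflight(config, base)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(
        version=__version__, seed=seed,
        config_sha256=hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()).hexdigest(),
        input_digests={p: _sha256_file(base / p) for p in input_paths})

    files = config.get("files", {})
    arms = read_arm_definitions(base / files["arms"]) if "arms" in files \
        else default_arm_definitions()
    usage = read_codon_usage(base / files["codon_usage"]) \
        if "codon_usage" in files else None

    patients: list[PatientData]
    if "simulate" in config:
        if seed is None:
            raise ConfigError("simulate stage requires a seed")
        sim_conf = config["simulate"]
        patient_overrides = {k: v for k, v in sim_conf.get("patient", {}).items()}
        if "event_neoantigen_losses" in patient_overrides:
            patient_overrides["event_neoantigen_losses"] = tuple(
                patient_overrides["event_neoantigen_losses"])
        cohort = CohortConfig(seed=int(seed),
                              n_patients=int(sim_conf.get("n_patients", 1)),
                              patient=PatientConfig(**patient_overrides))
        bundles = simulate_cohort(cohort)
        stage_outputs = {}
        for bundle in bundles:
            paths = write_bundle(bundle, outdir / "simulated" / bundle.patient_id)
            stage_outputs.update(paths)
        manifest.stages.append(_stage_entry("simulate", stage_outputs))
        patients = [patient_data_from_bundle(b) for b in bundles]
    else:
        patients = _load_patients_from_config(config, base)
        if not patients:
            raise ConfigError("inputs section lists no patients")

    fit_conf = config.get("fit", {})
    sculpt_conf = config.get("sculpt", {})

    fit_outputs, ai_outputs, sculpt_outputs = {}, {}, {}
    for patient in patients:
        pid = patient.patient_id
        fit_doc = fit_wgd_stage(patient, arms,
                                n_periods=int(fit_conf.get("n_periods", 6)),
                                constrained=bool(fit_conf.get("constrained", True)))
        path = outdir / f"{pid}.fit_wgd.json"
        _write_json(fit_doc, path)
        fit_outputs[f"fit:{pid}"] = str(path)

        ai_doc, acquired = ai_loh_stage(patient)
        path = outdir / f"{pid}.ai_loh.json"
        _write_json(ai_doc, path)
        ai_outputs[f"ai_loh:{pid}"] = str(path)
        bed_path = outdir / f"{pid}.acquired_loh.tsv"
        if acquired:
            pd.concat(acquired.values(), ignore_index=True).to_csv(
                bed_path, sep="\t", index=False)
        else:
            pd.DataFrame().to_csv(bed_path, sep="\t", index=False)
        ai_outputs[f"acquired_loh:{pid}"] = str(bed_path)

        sculpt_doc = sculpt_stage(
            patient, acquired, codon_usage=usage,
            null=sculpt_conf.get("null", "per_segment"),
            min_segment_length=int(sculpt_conf.get("min_segment_length",
                                                   10_000_000)))
        path = outdir / f"{pid}.sculpt.json"
        _write_json(sculpt_doc, path)
        sculpt_outputs[f"sculpt:{pid}"] = str(path)

    manifest.stages.append(_stage_entry("fit-wgd", fit_outputs))
    manifest.stages.append(_stage_entry("ai-loh", ai_outputs))
    manifest.stages.append(_stage_entry("sculpt", sculpt_outputs))

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "wt") as fh:
        fh.write(manifest.to_json())
        fh.write("\n")
    return manifest


def _stage_entry(name: str, outputs: dict[str, str]) -> dict:
    return {"name": name, "status": "ok",
            "outputs": {k: {"path": v, "sha256": _sha256_file(v)}
                        for k, v in sorted(outputs.items())}}
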