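"""Readers and writers for the tabular formats consumed by the pipeline.

All genomic coordinates are stored internally as 0-based half-open intervals.
On disk the segment dialect follows the Sequenza convention of 1-based closed
intervals; readers and writers convert at the boundary.  ``chr`` prefixes are
accepted and stripped.  Missing copy numbers are encoded as ``NA`` or an empty
field and surface downstream as an "undetermined" state rather than being
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .errors import FormatError, ValidationError
from .genome import DEFAULT_EXCLUDED_ARMS

SENSE_CODONS: tuple[str, ...] = tuple(sorted(standard_dna_table.forward_table))
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)

_SEGMENT_SYNONYMS = {
    "chromosome": ("chromosome", "chrom", "chr"),
    "start": ("start", "start.pos", "start_pos", "startpos"),
    "end": ("end", "end.pos", "end_pos", "endpos"),
    "major_cn": ("major_cn", "major", "a"),
    "minor_cn": ("minor_cn", "minor", "b"),
    "total_cn": ("total_cn", "total", "cnt"),
}


def _open(source: str | Path | IO[str]) -> IO[str]:
    if isinstance(source, (str, Path)):
        return open(source, "rt")
    return source


def _strip_chr(name: str) -> str:
    name = str(name).strip()
    return name[3:] if name.lower().startswith("chr") else name


def _resolve_columns(columns: Iterable[str], required: tuple[str, ...],
                     synonyms: Mapping[str, tuple[str, ...]]) -> dict[str, str]:
    lower = {c.lower(): c for c in columns}
    mapping: dict[str, str] = {}
    for canonical, alternates in synonyms.items():
        for alt in alternates:
            if alt in lower:
                mapping[canonical] = lower[alt]
                break
    for name in required:
        if name not in mapping:
            raise FormatError(f"missing mandatory column '{name}'")
    return mapping


@dataclass
class SegmentTable:
    """Allele-specific copy-number segments of one sample.

    ``df`` columns: chromosome (str), start, end (int, 0-based half-open),
    major_cn, minor_cn, total_cn (nullable Int64).
    """

    sample_id: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.df
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValidationError(
                f"segment with start >= end: {bad['chromosome']}:{bad['start']}-{bad['end']}")
        both = df["major_cn"].notna() & df["minor_cn"].notna()
        if (df.loc[both, "major_cn"] < df.loc[both, "minor_cn"]).any():
            raise ValidationError("segment with major_cn < minor_cn")
        all3 = both & df["total_cn"].notna()
        mismatch = df.loc[all3, "total_cn"] != df.loc[all3, "major_cn"] + df.loc[all3, "minor_cn"]
        if mismatch.any():
            raise ValidationError("segment with total_cn != major_cn + minor_cn")
        for chrom, sub in df.groupby("chromosome", sort=False):
            s = sub.sort_values("start").reset_index(drop=True)
            for i in range(1, len(s)):
                if s.loc[i, "start"] < s.loc[i - 1, "end"]:
                    ov_start = int(s.loc[i, "start"])
                    ov_end = int(min(s.loc[i, "end"], s.loc[i - 1, "end"]))
                    raise ValidationError(
                        f"overlapping segments on chromosome {chrom}: "
                        f"overlap spans {ov_start}-{ov_end}")

    @property
    def determined(self) -> pd.DataFrame:
        """Rows with both allele-specific copy numbers present."""
        m = self.df["major_cn"].notna() & self.df["minor_cn"].notna()
        return self.df[m]

    def total_length(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())


def read_segment_table(source: str | Path | IO[str], sample_id: str) -> SegmentTable:
    """Parse a Sequenza-style tab-separated segment file.

    Rows whose copy-number fields fail numeric parsing become missing-CN
    rows; row order is preserved.
    """
    stream = _open(source)
    df = pd.read_csv(stream, sep="\t", dtype=str, comment="#")
    df.columns = [c.strip() for c in df.columns]
    has_allelic = any(a in {c.lower() for c in df.columns}
                      for a in _SEGMENT_SYNONYMS["major_cn"])
    required = ("chromosome", "start", "end") + (
        ("major_cn", "minor_cn") if has_allelic else ("total_cn",))
    cols = _resolve_columns(df.columns, required, _SEGMENT_SYNONYMS)

    out = pd.DataFrame()
    out["chromosome"] = df[cols["chromosome"]].map(_strip_chr)
    for key in ("start", "end"):
        vals = pd.to_numeric(df[cols[key]], errors="coerce")
        if vals.isna().any():
            raise FormatError(f"non-numeric value in column '{cols[key]}'")
        out[key] = vals.astype(np.int64)
    out["start"] -= 1  # 1-based closed on disk -> 0-based half-open
    for key in ("major_cn", "minor_cn", "total_cn"):
        if key in cols:
            out[key] = pd.to_numeric(df[cols[key]], errors="coerce").astype("Int64")
        else:
            out[key] = pd.Series([pd.NA] * len(df), dtype="Int64")
    fill = out["total_cn"].isna() & out["major_cn"].notna() & out["minor_cn"].notna()
    out.loc[fill, "total_cn"] = out.loc[fill, "major_cn"] + out.loc[fill, "minor_cn"]
    return SegmentTable(sample_id=sample_id, df=out.reset_index(drop=True))


def write_segment_table(table: SegmentTable, dest: str | Path | IO[str]) -> None:
    out = table.df.copy()
    out["start"] = out["start"] + 1  # back to 1-based closed
    out["chromosome"] = "chr" + out["chromosome"].astype(str)
    stream = open(dest, "wt") if isinstance(dest, (str, Path)) else dest
    out.to_csv(stream, sep="\t", index=False, na_rep="NA")


@dataclass
class ArmDefinitions:
    """Chromosome-arm intervals derived from a cytogenetic band table.

    ``table`` columns: arm, chromosome, start, end (0-based half-open),
    included (bool).
    """

    table: pd.DataFrame

    def included_arms(self) -> list[str]:
        return list(self.table.loc[self.table["included"], "arm"])

    def interval(self, arm: str) -> tuple[str, int, int]:
        row = self.table.set_index("arm").loc[arm]
        return str(row["chromosome"]), int(row["start"]), int(row["end"])

    def to_cytoband(self) -> str:
        """Serialise back to cytoBand lines (arm boundaries preserved)."""
        lines = []
        for chrom, sub in self.table.groupby("chromosome", sort=False):
            sub = sub.sort_values("start")
            p = sub[sub["arm"].str.endswith("p")]
            q = sub[sub["arm"].str.endswith("q")]
            boundary = int(q["start"].iloc[0]) if len(q) else int(p["end"].iloc[0])
            end = int(sub["end"].max())
            lines.append(f"chr{chrom}\t0\t{boundary - 1}\tp12\tgneg")
            lines.append(f"chr{chrom}\t{boundary - 1}\t{boundary}\tp11\tacen")
            lines.append(f"chr{chrom}\t{boundary}\t{boundary + 1}\tq11\tacen")
            lines.append(f"chr{chrom}\t{boundary + 1}\t{end}\tq12\tgneg")
        return "\n".join(lines) + "\n"


def read_arm_definitions(source: str | Path | IO[str],
                         excluded_arms: frozenset[str] = DEFAULT_EXCLUDED_ARMS,
                         include_sex: bool = False) -> ArmDefinitions:
    """Derive p/q arm intervals from a UCSC cytoBand-format stream.

    Arms are split at the centromere: the p/q boundary is the start of the
    first q band.  Every chromosome must carry at least one ``acen`` band.
    Acrocentric short arms in ``excluded_arms`` and (by default) the sex
    chromosomes are parsed but flagged excluded.
    """
    stream = _open(source)
    bands: dict[str, list[tuple[int, int, str, str]]] = {}
    for line in stream:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 5:
            parts = line.split()
        if len(parts) < 5:
            raise FormatError(f"cytoBand line with <5 fields: {line!r}")
        chrom = _strip_chr(parts[0])
        bands.setdefault(chrom, []).append(
            (int(parts[1]), int(parts[2]), parts[3], parts[4]))

    rows = []
    for chrom, blist in bands.items():
        stains = {b[3] for b in blist}
        if "acen" not in stains:
            raise FormatError(f"chromosome {chrom} has no acen (centromere) band")
        blist.sort()
        q_starts = [b[0] for b in blist if b[2].startswith("q")]
        chrom_end = max(b[1] for b in blist)
        boundary = min(q_starts) if q_starts else chrom_end
        is_sex = chrom.upper() in {"X", "Y"}
        for arm_suffix, (start, end) in (("p", (0, boundary)), ("q", (boundary, chrom_end))):
            if start >= end:
                continue
            arm = f"{chrom}{arm_suffix}"
            included = (arm not in excluded_arms) and (include_sex or not is_sex)
            rows.append({"arm": arm, "chromosome": chrom,
                         "start": start, "end": end, "included": included})
    return ArmDefinitions(table=pd.DataFrame(rows))


_CONSEQUENCE_ALIASES = {
    "synonymous": "synonymous", "syn": "synonymous", "s": "synonymous",
    "nonsynonymous": "nonsynonymous", "non-synonymous": "nonsynonymous",
    "non_synonymous": "nonsynonymous", "nonsyn": "nonsynonymous",
    "non-syn": "nonsynonymous", "ns": "nonsynonymous",
}


def read_mutation_table(source: str | Path | IO[str]) -> pd.DataFrame:
    """Parse a per-mutation TSV.

    Expected columns: mutation_id, chromosome, position (1-based on disk),
    gene, consequence (synonymous/nonsynonymous, aliases accepted),
    present_in (comma-separated sample ids), optional ccf.  Returns a frame
    with 0-based positions and ``present_in`` as frozensets.
    """
    df = pd.read_csv(_open(source), sep="\t", dtype=str, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("mutation_id", "chromosome", "position", "consequence", "present_in"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column '{col}'")
    out = pd.DataFrame()
    out["mutation_id"] = df["mutation_id"]
    out["chromosome"] = df["chromosome"].map(_strip_chr)
    pos = pd.to_numeric(df["position"], errors="coerce")
    if pos.isna().any():
        raise FormatError("non-numeric value in column 'position'")
    out["position"] = pos.astype(np.int64) - 1
    out["gene"] = df.get("gene", pd.Series([""] * len(df)))
    cons = df["consequence"].str.strip().str.lower().map(_CONSEQUENCE_ALIASES)
    if cons.isna().any():
        bad = df.loc[cons.isna(), "consequence"].iloc[0]
        raise FormatError(f"unknown consequence class {bad!r}")
    out["consequence"] = cons
    out["present_in"] = df["present_in"].map(
        lambda s: frozenset(x.strip() for x in str(s).split(",") if x.strip()))
    if out["present_in"].map(len).eq(0).any():
        raise ValidationError("mutation with empty present_in set")
    if "ccf" in df.columns:
        ccf = pd.to_numeric(df["ccf"], errors="coerce")
        if ((ccf < 0) | (ccf > 1)).any():
            raise ValidationError("ccf outside [0, 1]")
        out["ccf"] = ccf
    else:
        out["ccf"] = np.nan
    if out["mutation_id"].duplicated().any():
        raise ValidationError("duplicate mutation_id")
    return out


def write_mutation_table(df: pd.DataFrame, dest: str | Path | IO[str]) -> None:
    out = df.copy()
    out["position"] = out["position"] + 1
    out["present_in"] = out["present_in"].map(lambda s: ",".join(sorted(s)))
    stream = open(dest, "wt") if isinstance(dest, (str, Path)) else dest
    out.to_csv(stream, sep="\t", index=False, na_rep="NA")


def read_neoantigen_table(source: str | Path | IO[str]) -> pd.DataFrame:
    """Parse predicted-neoantigen records (mutation_id, hla_allele,
    binding_rank in (0, 100], expressed flag)."""
    df = pd.read_csv(_open(source), sep="\t", dtype=str, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("mutation_id", "hla_allele", "binding_rank"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column '{col}'")
    out = pd.DataFrame()
    out["mutation_id"] = df["mutation_id"]
    out["hla_allele"] = df["hla_allele"]
    rank = pd.to_numeric(df["binding_rank"], errors="coerce")
    if rank.isna().any() or (rank <= 0).any() or (rank > 100).any():
        raise ValidationError("binding_rank must be in (0, 100]")
    out["binding_rank"] = rank
    if "expressed" in df.columns:
        out["expressed"] = df["expressed"].str.strip().str.lower().isin(
            {"true", "1", "yes", "t"})
    else:
        out["expressed"] = True
    return out


def write_neoantigen_table(df: pd.DataFrame, dest: str | Path | IO[str]) -> None:
    stream = open(dest, "wt") if isinstance(dest, (str, Path)) else dest
    df.to_csv(stream, sep="\t", index=False, na_rep="NA")


@dataclass
class BafTable:
    """Per-SNP B-allele frequencies of germline-heterozygous sites."""

    sample_id: str
    df: pd.DataFrame  # chromosome, position (0-based), baf

    def __post_init__(self) -> None:
        baf = self.df["baf"]
        if ((baf < 0) | (baf > 1)).any():
            raise ValidationError("baf outside [0, 1]")


def read_baf_table(source: str | Path | IO[str], sample_id: str) -> BafTable:
    df = pd.read_csv(_open(source), sep="\t", dtype=str, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("chromosome", "position", "baf"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column '{col}'")
    out = pd.DataFrame()
    out["chromosome"] = df["chromosome"].map(_strip_chr)
    out["position"] = pd.to_numeric(df["position"]).astype(np.int64) - 1
    out["baf"] = pd.to_numeric(df["baf"])
    return BafTable(sample_id=sample_id, df=out)


def write_baf_table(table: BafTable, dest: str | Path | IO[str]) -> None:
    out = table.df.copy()
    out["position"] = out["position"] + 1
    stream = open(dest, "wt") if isinstance(dest, (str, Path)) else dest
    out.to_csv(stream, sep="\t", index=False)


def read_codon_usage(source: str | Path | IO[str]) -> dict[str, float]:
    """Parse a two-column codon -> relative-frequency table.

    Stop codons are permitted in the input but excluded; the returned
    mapping is normalised over the sense codons present.
    """
    raw: dict[str, float] = {}
    for line in _open(source):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise FormatError(f"codon-usage line with <2 fields: {line!r}")
        codon = parts[0].upper().replace("U", "T")
        freq = float(parts[1])
        if freq < 0:
            raise FormatError(f"negative frequency for codon {codon}")
        if codon in STOP_CODONS:
            continue
        if codon not in SENSE_CODONS:
            raise FormatError(f"codon {codon!r} not in the standard genetic code")
        raw[codon] = raw.get(codon, 0.0) + freq
    total = sum(raw.values())
    if not raw or total <= 0:
        raise FormatError("codon usage table empty or all-zero")
    return {c: f / total for c, f in raw.items()}


def uniform_codon_usage() -> dict[str, float]:
    """Uniform usage over the 61 sense codons."""
    return {c: 1.0 / len(SENSE_CODONS) for c in SENSE_CODONS}


def segment_table_from_records(sample_id: str,
                               records: Iterable[tuple[str, int, int, object, object]]
                               ) -> SegmentTable:
    """Build a SegmentTable from (chromosome, start, end, major, minor)
    records already in 0-based half-open coordinates; ``None`` means
    undetermined."""
    rows = []
    for chrom, start, end, major, minor in records:
        total = major + minor if (major is not None and minor is not None) else None
        rows.append({"chromosome": _strip_chr(chrom), "start": int(start),
                     "end": int(end), "major_cn": major, "minor_cn": minor,
                     "total_cn": total})
    df = pd.DataFrame(rows, columns=["chromosome", "start", "end",
                                     "major_cn", "minor_cn", "total_cn"])
    for col in ("major_cn", "minor_cn", "total_cn"):
        df[col] = df[col].astype("Int64")
    return SegmentTable(sample_id=sample_id, df=df)
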