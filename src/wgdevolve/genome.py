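"""Static hg19 genome geometry: chromosome lengths and centromere bands.

Coordinates are 0-based half-open throughout.  The centromere interval of a
chromosome is the union of its two acrocentric-stain (``acen``) cytogenetic
bands; the p/q boundary is the junction between them.  Values follow the UCSC
hg19 cytogenetic band table rounded to the 100-kb resolution at which that
table reports band edges.
"""

from __future__ import annotations

# chromosome -> (length, acen_start, pq_boundary, acen_end)
HG19_CHROMOSOMES: dict[str, tuple[int, int, int, int]] = {
    "1": (249_250_621, 121_500_000, 125_000_000, 128_900_000),
    "2": (243_199_373, 90_500_000, 93_300_000, 96_800_000),
    "3": (198_022_430, 87_900_000, 91_000_000, 93_900_000),
    "4": (191_154_276, 48_200_000, 50_400_000, 52_700_000),
    "5": (180_915_260, 46_100_000, 48_400_000, 50_700_000),
    "6": (171_115_067, 58_700_000, 61_000_000, 63_300_000),
    "7": (159_138_663, 58_000_000, 59_900_000, 61_700_000),
    "8": (146_364_022, 43_100_000, 45_600_000, 48_100_000),
    "9": (141_213_431, 47_300_000, 49_000_000, 50_700_000),
    "10": (135_534_747, 38_000_000, 40_200_000, 42_300_000),
    "11": (135_006_516, 51_600_000, 53_700_000, 55_700_000),
    "12": (133_851_895, 33_300_000, 35_800_000, 38_200_000),
    "13": (115_169_878, 16_300_000, 17_900_000, 19_500_000),
    "14": (107_349_540, 16_100_000, 17_600_000, 19_100_000),
    "15": (102_531_392, 15_800_000, 19_000_000, 20_700_000),
    "16": (90_354_753, 34_600_000, 36_600_000, 38_600_000),
    "17": (81_195_210, 22_200_000, 24_000_000, 25_800_000),
    "18": (78_077_248, 15_400_000, 17_200_000, 19_000_000),
    "19": (59_128_983, 24_400_000, 26_500_000, 28_600_000),
    "20": (63_025_520, 25_600_000, 27_500_000, 29_400_000),
    "21": (48_129_895, 10_900_000, 13_200_000, 14_300_000),
    "22": (51_304_566, 12_200_000, 14_700_000, 17_900_000),
    "X": (155_270_560, 58_100_000, 60_600_000, 61_700_000),
    "Y": (59_373_566, 11_600_000, 12_500_000, 13_400_000),
}

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))

#: Acrocentric short arms with no reliably assayable sequence; excluded from
#: arm-level modelling by default, leaving 39 autosomal arms.
DEFAULT_EXCLUDED_ARMS: frozenset[str] = frozenset({"13p", "14p", "15p", "21p", "22p"})


def autosome_length() -> int:
    """Total autosomal genome length in bp."""
    return sum(HG19_CHROMOSOMES[c][0] for c in AUTOSOMES)


def arm_intervals(chromosome: str) -> dict[str, tuple[int, int]]:
    """Return the p and q arm intervals of ``chromosome`` (0-based half-open)."""
    length, _, boundary, _ = HG19_CHROMOSOMES[chromosome]
    return {
        f"{chromosome}p": (0, boundary),
        f"{chromosome}q": (boundary, length),
    }


def default_arm_table() -> list[tuple[str, str, int, int, bool]]:
    """All autosomal arms as (arm_id, chromosome, start, end, included)."""
    rows = []
    for chrom in AUTOSOMES:
        for arm_id, (start, end) in arm_intervals(chrom).items():
            rows.append((arm_id, chrom, start, end, arm_id not in DEFAULT_EXCLUDED_ARMS))
    return rows


def cytoband_lines(chromosomes: tuple[str, ...] | None = None) -> list[str]:
    """Render a minimal UCSC-style cytogenetic band file.

    Each chromosome is reduced to four bands: one non-staining band per arm
    flanking the two ``acen`` centromere bands.  This carries exactly the
    information needed to reconstruct arm boundaries.
    """
    chromosomes = chromosomes or tuple(HG19_CHROMOSOMES)
    lines = []
    for chrom in chromosomes:
        length, acen_start, boundary, acen_end = HG19_CHROMOSOMES[chrom]
        lines.append(f"chr{chrom}\t0\t{acen_start}\tp12\tgneg")
        lines.append(f"chr{chrom}\t{acen_start}\t{boundary}\tp11\tacen")
        lines.append(f"chr{chrom}\t{boundary}\t{acen_end}\tq11\tacen")
        lines.append(f"chr{chrom}\t{acen_end}\t{length}\tq12\tgneg")
    return lines
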