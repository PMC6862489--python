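"""Published segregation counts for the Koshihikari x Inochinoichi material.

These are the phenotype-class counts reported in the original field study
of the Inochinoichi large-grain introgression and the d60-combining
backcross programme, embedded here so the ``reproduce`` report can rerun
every printed test from first principles and flag any printed statistic
that does not match the recomputation.  Two printed chi-square values are
known not to match the uncorrected Pearson statistic (the BC4F2 grain
test printed as 0.20 and the BC4F2 culm test printed as 0.01); they are
reported with a flag, never asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class SegregationRecord:
    """One printed segregation test: counts, the tested ratio, printed stats."""

    label: str
    class_labels: tuple[str, ...]
    counts: tuple[int, ...]
    ratio: tuple[float, ...] | None  # Mendelian ratio, or None -> model-derived
    design: str | None  # builtin design name when expectations come from the model
    classifier: str | None  # "culm" | "grain" for model-derived expectations
    printed_chi2: float
    printed_df: int
    printed_p: str
    note: str = ""


SEGREGATION_RECORDS: tuple[SegregationRecord, ...] = (
    SegregationRecord(
        "F2 Koshihikari x Inochinoichi, grain diameter",
        ("large", "small"), (134, 52), (3, 1), None, None,
        0.87, 1, "0.35 < P < 0.40",
    ),
    SegregationRecord(
        "F3 lines of Koshihikari x Inochinoichi, grain size",
        ("large-fixed", "segregating", "small-fixed"), (10, 32, 8), (1, 2, 1),
        None, None,
        4.08, 1, "0.10 < P < 0.25",
        note="printed df = 1; a three-class test has df = 2 (printed P range matches df = 2)",
    ),
    SegregationRecord(
        "BC1F2 (Koshihikari recurrent), grain size",
        ("large", "medium+small"), (10, 32), (1, 3), None, None,
        0.03, 1, "0.50 < P < 0.90",
    ),
    SegregationRecord(
        "BC2F2 (Koshihikari recurrent), grain size",
        ("large", "medium", "small"), (17, 39, 14), (1, 2, 1), None, None,
        1.17, 2, "0.55 < P < 0.60",
    ),
    SegregationRecord(
        "BC3F2 (Koshihikari recurrent), grain size",
        ("large", "medium", "small"), (15, 13, 7), (1, 2, 1), None, None,
        5.97, 2, "0.05 < P < 0.10",
    ),
    SegregationRecord(
        "BC4F2 (Koshihikari recurrent), grain size",
        ("large", "medium", "small"), (8, 18, 10), (1, 2, 1), None, None,
        0.20, 2, "0.85 < P < 0.90",
        note="printed 0.20 does not match the uncorrected statistic (0.22); flagged",
    ),
    SegregationRecord(
        "BC1F2 of the d60 scheme, culm classes",
        ("semidwarf", "partially sterile", "long-stem"), (11, 26, 75), None,
        "bc1f2", "culm",
        0.22, 2, "0.85 < P < 0.90",
    ),
    SegregationRecord(
        "BC2F2 of the d60 scheme (d60d60 background), grain size",
        ("large", "medium", "small"), (3, 14, 7), (1, 2, 1), None, None,
        2.00, 2, "0.30 < P < 0.50",
    ),
    SegregationRecord(
        "BC3F2 of the d60 scheme (d60d60 background), grain size",
        ("large", "medium", "small"), (20, 55, 19), (1, 2, 1),
        "bc3f2-d60", "grain",
        2.74, 2, "0.20 < P < 0.30",
    ),
    SegregationRecord(
        "BC4F2 of the d60 scheme, culm classes",
        ("semidwarf", "partially sterile", "long-stem"), (17, 36, 104), None,
        "bc4f2", "culm",
        0.01, 2, "0.9 < P < 0.95",
        note="printed 0.01 does not match the uncorrected statistic (0.05); flagged",
    ),
)

# semidwarf-class grain-genotype counts of the d60-scheme BC4F2:
# GW2 homozygous : heterozygous : gw2 homozygous, printed recombination value
SEMIDWARF_GRAIN_COUNTS: tuple[int, int, int] = (11, 6, 0)
PRINTED_RECOMBINATION_VALUE: float = 17.6

# marker panel of the recessive-class F2 mapping population
# (marker, chromosome, position in Mb from the distal end of the short arm,
#  printed recombination value)
MARKER_PANEL: tuple[tuple[str, str, float, float], ...] = (
    ("J521", "2", 7.6, 21.7),
    ("RM3390", "2", 7.7, 17.5),
    ("J527", "2", 8.2, 15.2),
    ("J529", "2", 8.6, 19.6),
    ("J536", "2", 9.1, 28.3),
    ("RM6375", "2", 9.6, 30.0),
    ("RM1358", "2", 10.2, 34.5),
)
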