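"""Published contingency counts used as worked examples.

Case/control counts by exposure category, transcribed from the report
tables of a Korean gastric-cancer case-control study of dietary-pattern
networks and the gastric microbiome (268 cases / 288 controls). Each
record carries the printed crude odds ratio and 95% CI alongside the
integer counts, so the crude-OR machinery can be validated against
independently published arithmetic. The published estimates were rounded
from unrounded model output, so recomputation from the integer counts
agrees to within one unit in the last printed digit.

Counts are stored as (cases_exposed, controls_exposed, cases_ref,
controls_ref); for the combined pattern-by-dysbiosis tables the
reference is the (low pattern, low MDI) cell.
"""

from __future__ import annotations

from dataclasses import dataclass

from dietmicrobe.association import OrEstimate, crude_or_ci

__all__ = ["PublishedRow", "PUBLISHED_CRUDE_ORS", "recompute_row"]


@dataclass(frozen=True)
class PublishedRow:
    table: str  # which published table the row comes from
    stratum: str  # total | male | female | histology subtype
    exposure: str  # pattern / index name
    level: str  # tertile or combined-cell label
    cases_exposed: int
    controls_exposed: int
    cases_ref: int
    controls_ref: int
    published_or: float
    published_lo: float
    published_hi: float


_R = PublishedRow

PUBLISHED_CRUDE_ORS: list[PublishedRow] = [
    # --- dietary pattern tertiles, total population ---
    _R("diet_total", "total", "vegetables_seafood", "T2", 97, 96, 97, 95, 0.99, 0.66, 1.48),
    _R("diet_total", "total", "vegetables_seafood", "T3", 74, 97, 97, 95, 0.75, 0.50, 1.13),
    _R("diet_total", "total", "meat_beverages", "T2", 87, 95, 109, 96, 0.81, 0.54, 1.20),
    _R("diet_total", "total", "meat_beverages", "T3", 72, 97, 109, 96, 0.65, 0.43, 0.98),
    _R("diet_total", "total", "snacks", "T2", 106, 96, 92, 95, 1.14, 0.77, 1.70),
    _R("diet_total", "total", "snacks", "T3", 70, 97, 92, 95, 0.75, 0.50, 1.14),
    _R("diet_total", "total", "dairy", "T2", 67, 95, 133, 96, 0.51, 0.34, 0.77),
    _R("diet_total", "total", "dairy", "T3", 68, 97, 133, 96, 0.51, 0.34, 0.76),
    _R("diet_total", "total", "fruits", "T2", 87, 96, 129, 95, 0.67, 0.45, 0.98),
    _R("diet_total", "total", "fruits", "T3", 52, 97, 129, 95, 0.40, 0.26, 0.61),
    # --- dietary pattern tertiles, females ---
    _R("diet_female", "female", "vegetables_seafood", "T2", 30, 37, 34, 35, 0.84, 0.43, 1.64),
    _R("diet_female", "female", "vegetables_seafood", "T3", 32, 35, 34, 35, 0.94, 0.48, 1.84),
    _R("diet_female", "female", "meats", "T2", 31, 36, 37, 36, 0.84, 0.43, 1.63),
    _R("diet_female", "female", "meats", "T3", 28, 35, 37, 36, 0.78, 0.40, 1.53),
    _R("diet_female", "female", "snacks", "T2", 45, 35, 34, 36, 1.36, 0.72, 2.60),
    _R("diet_female", "female", "snacks", "T3", 17, 36, 34, 36, 0.50, 0.24, 1.05),
    _R("diet_female", "female", "dairy", "T2", 28, 36, 47, 36, 0.60, 0.31, 1.15),
    _R("diet_female", "female", "dairy", "T3", 21, 35, 47, 36, 0.46, 0.23, 0.92),
    _R("diet_female", "female", "fruits", "T2", 15, 35, 60, 36, 0.26, 0.12, 0.54),
    _R("diet_female", "female", "fruits", "T3", 21, 36, 60, 36, 0.35, 0.18, 0.69),
    # --- dysbiosis index tertiles ---
    _R("mdi", "total", "mdi", "T2", 75, 97, 91, 96, 0.82, 0.54, 1.24),
    _R("mdi", "total", "mdi", "T3", 102, 95, 91, 96, 1.13, 0.76, 1.69),
    _R("mdi", "male", "mdi", "T2", 42, 60, 74, 60, 0.57, 0.34, 0.96),
    _R("mdi", "male", "mdi", "T3", 56, 61, 74, 60, 0.74, 0.45, 1.22),
    _R("mdi", "female", "mdi", "T2", 31, 36, 18, 36, 1.72, 0.82, 3.62),
    _R("mdi", "female", "mdi", "T3", 47, 35, 18, 36, 2.69, 1.31, 5.49),
    _R("mdi", "intestinal", "mdi", "T2", 31, 97, 37, 96, 0.83, 0.48, 1.44),
    _R("mdi", "intestinal", "mdi", "T3", 37, 96, 37, 96, 1.01, 0.59, 1.73),
    _R("mdi", "diffuse", "mdi", "T2", 30, 97, 35, 96, 0.85, 0.48, 1.49),
    _R("mdi", "diffuse", "mdi", "T3", 44, 95, 35, 96, 1.27, 0.75, 2.15),
    _R("mdi", "mixed", "mdi", "T2", 9, 97, 15, 96, 0.59, 0.25, 1.42),
    _R("mdi", "mixed", "mdi", "T3", 12, 95, 15, 96, 0.81, 0.36, 1.82),
    # --- combined pattern x MDI cells, males (ref = low pattern, low MDI) ---
    _R("combined_male", "male", "vegetables_seafood", "highP_lowM", 40, 47, 54, 44, 0.69, 0.39, 1.24),
    _R("combined_male", "male", "vegetables_seafood", "lowP_highM", 39, 46, 54, 44, 0.69, 0.38, 1.24),
    _R("combined_male", "male", "vegetables_seafood", "highP_highM", 39, 44, 54, 44, 0.72, 0.40, 1.30),
    _R("combined_male", "male", "meats_snacks", "highP_lowM", 36, 51, 58, 40, 0.49, 0.27, 0.88),
    _R("combined_male", "male", "meats_snacks", "lowP_highM", 45, 51, 58, 40, 0.61, 0.35, 1.07),
    _R("combined_male", "male", "meats_snacks", "highP_highM", 33, 39, 58, 40, 0.58, 0.32, 1.08),
    _R("combined_male", "male", "fruit", "highP_lowM", 34, 45, 60, 46, 0.58, 0.32, 1.04),
    _R("combined_male", "male", "fruit", "lowP_highM", 42, 45, 60, 46, 0.72, 0.41, 1.27),
    _R("combined_male", "male", "fruit", "highP_highM", 36, 45, 60, 46, 0.61, 0.34, 1.09),
    # --- combined pattern x MDI cells, females ---
    _R("combined_female", "female", "vegetables_seafood", "highP_lowM", 15, 25, 18, 29, 0.97, 0.41, 2.31),
    _R("combined_female", "female", "vegetables_seafood", "lowP_highM", 27, 24, 18, 29, 1.81, 0.81, 4.05),
    _R("combined_female", "female", "vegetables_seafood", "highP_highM", 36, 29, 18, 29, 2.00, 0.93, 4.30),
    _R("combined_female", "female", "meats", "highP_lowM", 13, 27, 20, 27, 0.65, 0.27, 1.57),
    _R("combined_female", "female", "meats", "lowP_highM", 36, 26, 20, 27, 1.87, 0.87, 4.03),
    _R("combined_female", "female", "meats", "highP_highM", 27, 27, 20, 27, 1.35, 0.62, 2.97),
    _R("combined_female", "female", "snacks", "highP_lowM", 6, 25, 27, 29, 0.26, 0.10, 0.73),
    _R("combined_female", "female", "snacks", "lowP_highM", 37, 25, 27, 29, 1.59, 0.77, 3.30),
    _R("combined_female", "female", "snacks", "highP_highM", 26, 28, 27, 29, 0.99, 0.47, 2.11),
    _R("combined_female", "female", "dairy", "highP_lowM", 8, 31, 25, 23, 0.24, 0.10, 0.62),
    _R("combined_female", "female", "dairy", "lowP_highM", 37, 31, 25, 23, 1.09, 0.52, 2.30),
    _R("combined_female", "female", "dairy", "highP_highM", 26, 22, 25, 23, 1.09, 0.49, 2.42),
    _R("combined_female", "female", "fruits", "highP_lowM", 10, 26, 23, 28, 0.47, 0.18, 1.17),
    _R("combined_female", "female", "fruits", "lowP_highM", 45, 26, 23, 28, 2.11, 1.01, 4.39),
    _R("combined_female", "female", "fruits", "highP_highM", 18, 27, 23, 28, 0.81, 0.36, 1.83),
]


def recompute_row(row: PublishedRow) -> OrEstimate:
    """Crude OR and Woolf CI recomputed from the row's integer counts."""
    return crude_or_ci(
        row.cases_exposed, row.controls_exposed, row.cases_ref, row.controls_ref, level=row.level
    )
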