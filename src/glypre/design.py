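"""The 16-condition, 11-tube, two-set study design.

Ten donors were sampled in two sets of five, six months apart.  Each donor
gives eleven collection tubes (A-K); tubes F (serum reference) and K
(hemolysis) feed multiple conditions.  Conditions 1-15 exist for both sets;
condition 16 (overnight-shaking hemolysis) exists only for the second set.
MALDI preparations are triplicates, CE preparations duplicates.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ConditionSpec",
    "CONDITIONS",
    "SERUM_REFERENCE",
    "PLASMA_REFERENCE",
    "SERUM_ALTERED",
    "PLASMA_ALTERED",
    "MS_REPLICATES",
    "CE_REPLICATES",
    "N_DONORS",
    "DONORS",
]

MS_REPLICATES = 3
CE_REPLICATES = 2
N_DONORS = 10
#: donor id -> collection set (two sets of five donors)
DONORS = {f"D{i:02d}": (1 if i <= 5 else 2) for i in range(1, N_DONORS + 1)}


@dataclass(frozen=True)
class ConditionSpec:
    id: int
    matrix: str            # 'serum' | 'plasma'
    tube: str              # collection tube A-K
    label: str
    is_reference: bool = False
    set2_only: bool = False
    hemolysis_mode: str | None = None  # 'hypotonic' | 'shaking'


CONDITIONS: tuple[ConditionSpec, ...] = (
    ConditionSpec(1, "serum", "F", "serum reference (30 min RT, immediate aliquot)", True),
    ConditionSpec(2, "serum", "A", "RT 2 h before centrifugation"),
    ConditionSpec(3, "serum", "B", "RT 6 h before centrifugation"),
    ConditionSpec(4, "serum", "C", "4C 2 h before centrifugation"),
    ConditionSpec(5, "serum", "D", "RT 6 h after centrifugation"),
    ConditionSpec(6, "serum", "E", "separation-gel tube"),
    ConditionSpec(7, "serum", "F", "-20C storage, 2 months"),
    ConditionSpec(8, "serum", "F", "-80C storage, 2 months"),
    ConditionSpec(9, "serum", "F", "4C 48 h after centrifugation"),
    ConditionSpec(10, "serum", "F", "delayed aliquoting"),
    ConditionSpec(11, "plasma", "H", "citrate plasma reference", True),
    ConditionSpec(12, "plasma", "G", "citrate, evacuated collection"),
    ConditionSpec(13, "plasma", "I", "K3 EDTA plasma"),
    ConditionSpec(14, "plasma", "J", "lithium-heparin plasma"),
    ConditionSpec(15, "plasma", "K", "hypotonic hemolysis", hemolysis_mode="hypotonic"),
    ConditionSpec(16, "plasma", "K", "overnight-shaking hemolysis",
                  set2_only=True, hemolysis_mode="shaking"),
)

_BY_ID = {c.id: c for c in CONDITIONS}


def condition(cid: int) -> ConditionSpec:
    return _BY_ID[cid]


SERUM_REFERENCE = 1
PLASMA_REFERENCE = 11
SERUM_ALTERED: tuple[int, ...] = tuple(
    c.id for c in CONDITIONS if c.matrix == "serum" and not c.is_reference
)
PLASMA_ALTERED: tuple[int, ...] = tuple(
    c.id for c in CONDITIONS if c.matrix == "plasma" and not c.is_reference
)
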