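"""Rule systems assigning one of four molecular genetic subtypes.

Each system is a conjunction of strict inequalities / equalities over the
per-biomarker indicators.  A diagnosis is produced only when exactly one
system is fully satisfied; boundary values (e.g. an ER area of exactly 0.66)
satisfy neither strict inequality and legitimately yield Indeterminate.

The Luminal B and HER2-amplified systems contain an unqualified intensity
condition ("KI = 1"); it is bound to the HER2 intensity by default because it
directly follows the HER2 area condition in both systems.  The binding is
configurable, as is the direction of the HER2 area condition in the
HER2-amplified system (printed as "< 0.1").
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from fractions import Fraction

from ihcquant.core_io import BiomarkerKind, Grade
from ihcquant.indicators import IndicatorSet

_T_066 = Fraction("0.66")
_T_02 = Fraction("0.2")
_T_01 = Fraction("0.1")


class Subtype(enum.Enum):
    LUMINAL_A = "LuminalA"
    LUMINAL_B = "LuminalB"
    HER2_AMPLIFIED = "HER2Amplified"
    BASAL_LIKE = "BasalLike"
    INDETERMINATE = "Indeterminate"


#: grade levels each subtype is described as occurring with
GRADE_ASSOCIATIONS = {
    Subtype.LUMINAL_A: {Grade.G1, Grade.G2},
    Subtype.LUMINAL_B: {Grade.G2, Grade.G3},
    Subtype.HER2_AMPLIFIED: {Grade.G3},
}

#: human-readable condition names, in evaluation order, per system
CONDITION_NAMES = {
    "BCA": ["ER_sigma>0.66", "ER_KI=3", "PR_sigma>0.2", "HER2_sigma<0.1", "KI67_sigma<0.2"],
    "BCB": [
        "ER_sigma<0.66",
        "ER_KI=3",
        "PR_sigma<0.2",
        "HER2_sigma<0.1",
        "KI=1",
        "KI67_sigma>0.2",
    ],
    "BCH": ["HER2_sigma<0.1", "KI=1", "ER_sigma<0.1", "PR_sigma<0.1"],
    "BCZ": ["ER_sigma<0.1", "PR_sigma<0.1", "HER2_sigma<0.1", "KI67_KI=3"],
}

_SYSTEM_SUBTYPE = {
    "BCA": Subtype.LUMINAL_A,
    "BCB": Subtype.LUMINAL_B,
    "BCH": Subtype.HER2_AMPLIFIED,
    "BCZ": Subtype.BASAL_LIKE,
}

_KI_BINDING = {
    "her2": BiomarkerKind.HER2,
    "er": BiomarkerKind.ER,
    "ki67": BiomarkerKind.KI67,
}


@dataclass
class SubtypeResult:
    subtype: Subtype
    satisfied: dict = field(default_factory=dict)
    matched_systems: list = field(default_factory=list)
    grade_warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "subtype": self.subtype.value,
            "satisfied": {
                system: dict(zip(CONDITION_NAMES[system], flags))
                for system, flags in self.satisfied.items()
            },
            "matched_systems": list(self.matched_systems),
            "grade_warnings": list(self.grade_warnings),
        }


def is_luminal_a(ind: IndicatorSet) -> list[bool]:
    """Five conditions of the Luminal A system."""
    return [
        ind.sigma_s(BiomarkerKind.ER) > _T_066,
        ind.ki(BiomarkerKind.ER) == 3,
        ind.sigma_s(BiomarkerKind.PR) > _T_02,
        ind.sigma_s(BiomarkerKind.HER2) < _T_01,
        ind.sigma_s(BiomarkerKind.KI67) < _T_02,
    ]


def is_luminal_b(ind: IndicatorSet, unqualified_ki_binding: str = "her2") -> list[bool]:
    """Six conditions of the Luminal B system."""
    ki_kind = _KI_BINDING[unqualified_ki_binding]
    return [
        ind.sigma_s(BiomarkerKind.ER) < _T_066,
        ind.ki(BiomarkerKind.ER) == 3,
        ind.sigma_s(BiomarkerKind.PR) < _T_02,
        ind.sigma_s(BiomarkerKind.HER2) < _T_01,
        ind.ki(ki_kind) == 1,
        ind.sigma_s(BiomarkerKind.KI67) > _T_02,
    ]


def is_her2_amplified(
    ind: IndicatorSet,
    unqualified_ki_binding: str = "her2",
    her2_area_direction: str = "less",
) -> list[bool]:
    """Four conditions of the HER2-amplified system (area direction as printed)."""
    ki_kind = _KI_BINDING[unqualified_ki_binding]
    her2_sigma = ind.sigma_s(BiomarkerKind.HER2)
    area_ok = her2_sigma < _T_01 if her2_area_direction == "less" else her2_sigma > _T_01
    return [
        area_ok,
        ind.ki(ki_kind) == 1,
        ind.sigma_s(BiomarkerKind.ER) < _T_01,
        ind.sigma_s(BiomarkerKind.PR) < _T_01,
    ]


def is_basal_like(ind: IndicatorSet) -> list[bool]:
    """Four conditions of the basal-like system."""
    return [
        ind.sigma_s(BiomarkerKind.ER) < _T_01,
        ind.sigma_s(BiomarkerKind.PR) < _T_01,
        ind.sigma_s(BiomarkerKind.HER2) < _T_01,
        ind.ki(BiomarkerKind.KI67) == 3,
    ]


def classify(
    ind: IndicatorSet,
    grade: Grade | None = None,
    unqualified_ki_binding: str = "her2",
    her2_area_direction: str = "less",
) -> SubtypeResult:
    """Evaluate all four systems; exactly one fully satisfied gives the subtype.

    Zero or multiple matches yield Indeterminate with full satisfaction
    detail.  A supplied grade never changes the decision; it only adds a
    warning when the subtype/grade pairing contradicts the described
    associations.
    """
    if not isinstance(ind, IndicatorSet):
        raise TypeError("classify requires a complete IndicatorSet")
    satisfied = {
        "BCA": is_luminal_a(ind),
        "BCB": is_luminal_b(ind, unqualified_ki_binding),
        "BCH": is_her2_amplified(ind, unqualified_ki_binding, her2_area_direction),
        "BCZ": is_basal_like(ind),
    }
    matched = [system for system, flags in satisfied.items() if all(flags)]
    subtype = _SYSTEM_SUBTYPE[matched[0]] if len(matched) == 1 else Subtype.INDETERMINATE

    warnings: list[str] = []
    if grade is not None and subtype in GRADE_ASSOCIATIONS:
        expected = GRADE_ASSOCIATIONS[subtype]
        if grade not in expected:
            names = "/".join(sorted(g.value for g in expected))
            warnings.append(
                f"grade {grade.value} is atypical for subtype {subtype.value} "
                f"(described for {names})"
            )
    return SubtypeResult(
        subtype=subtype,
        satisfied=satisfied,
        matched_systems=matched,
        grade_warnings=warnings,
    )
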