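"""IAP subelement registry: which RepeatMasker names count as IAP, and
whether each is an LTR or an internal (protein-coding) portion.

The default registry covers the 25 subelement names used to define IAP
elements in the mm10 RepeatMasker annotation.  A subelement is typed
internal when its name ends in ``-int`` (IAPLTR4_I is the one documented
exception: it is an internal portion despite the name); everything else is
an LTR.  The mapping can be overridden from a YAML file so non-default
annotations or corrections do not require code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

#: The IAP subelement names defining membership of the IAP catalogue.
DEFAULT_IAP_TYPES: tuple[str, ...] = (
    "IAPLTR1a_Mm",
    "IAPEY2_LTR",
    "IAPEy-int",
    "IAPEY3_LTR",
    "IAPLTR2b",
    "IAPLTR2_Mm",
    "IAPEz-int",
    "IAPEY4_I-int",
    "IAP-d-int",
    "IAPEY3-int",
    "RLTR10B2",
    "IAP1-MM_I-int",
    "IAP1-MM_LTR",
    "IAPLTR2a2_Mm",
    "IAPLTR4",
    "IAPLTR1_Mm",
    "IAPEY3C_LTR",
    "IAPLTR4_I",
    "IAPLTR3",
    "IAPLTR3-int",
    "IAPEY5_LTR",
    "IAPEY5_I-int",
    "IAPEY_LTR",
    "IAPEY4_LTR",
    "IAPA_MM-int",
)

#: Names typed internal despite not ending in "-int".
_EXPLICIT_INTERNAL: frozenset[str] = frozenset({"IAPLTR4_I"})


@dataclass(frozen=True)
class SubelementRegistry:
    """Partition of IAP subelement names into LTR and internal types."""

    internal_types: frozenset[str]
    ltr_types: frozenset[str]

    def __post_init__(self) -> None:
        if self.internal_types & self.ltr_types:
            raise ValueError(
                "internal and LTR type sets overlap: "
                f"{sorted(self.internal_types & self.ltr_types)}"
            )

    @property
    def iap_types(self) -> frozenset[str]:
        return self.internal_types | self.ltr_types

    def __contains__(self, rep_name: str) -> bool:
        return rep_name in self.internal_types or rep_name in self.ltr_types

    def is_internal(self, rep_name: str) -> bool:
        return rep_name in self.internal_types

    def is_ltr(self, rep_name: str) -> bool:
        return rep_name in self.ltr_types

    @classmethod
    def default(cls) -> "SubelementRegistry":
        """Registry of the 25 IAP subelement types with name-based typing."""
        internal = frozenset(
            n for n in DEFAULT_IAP_TYPES if n.endswith("-int") or n in _EXPLICIT_INTERNAL
        )
        return cls(internal_types=internal,
                   ltr_types=frozenset(DEFAULT_IAP_TYPES) - internal)

    @classmethod
    def from_yaml(cls, path: str) -> "SubelementRegistry":
        """Load a registry from a YAML file with ``internal`` and ``ltr`` lists."""
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(internal_types=frozenset(doc["internal"]),
                   ltr_types=frozenset(doc["ltr"]))

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"internal": sorted(self.internal_types), "ltr": sorted(self.ltr_types)},
                fh,
            )
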