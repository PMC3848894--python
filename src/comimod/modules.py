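"""Grouping of surviving CoMi features into GO-term modules.

All miRNAs acting on one GO biological-process term form a module, named by
that term; modules below the size cutoff (more than five miRNAs, i.e. >= 6
members by default) are dropped.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import DataError


@dataclass
class Module:
    """One GO-BP term plus its retained (miRNA, GO-BP) features, in profile order."""

    gobp_id: str
    member_features: list[tuple[str, str]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_features)

    def mirnas(self) -> list[str]:
        return [m for m, _ in self.member_features]


def build_modules(profile: pd.DataFrame, min_module_size: int = 6) -> list[Module]:
    """Group a filtered CoMi profile's features by GO term.

    Modules are ordered by the first appearance of their term in the profile;
    features within a module keep profile order.  Raises when no module has
    at least *min_module_size* members.
    """
    if min_module_size < 1:
        raise DataError("min_module_size must be >= 1")
    grouped: dict[str, Module] = {}
    for mirna, gobp in profile.index:
        grouped.setdefault(gobp, Module(gobp)).member_features.append((mirna, gobp))
    modules = [m for m in grouped.values() if m.size >= min_module_size]
    if not modules:
        raise DataError(
            f"no module with >= {min_module_size} member features; "
            "check the pair filters or lower min_module_size"
        )
    return modules
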