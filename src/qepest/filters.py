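"""Classical rule-based likeness filters: Lipinski, Tice, Hao.

Each filter counts violations of its descriptor bounds; a molecule
passes with zero violations.  Bounds printed as "<=" or as ranges are
inclusive; the rotatable-bond bound of the Tice rules ("< 12") is strict.

The original publications used vendor logP models (MLogP for
Lipinski/Tice, ClogP for Hao); here a single logP value feeds every
filter by default, which shifts absolute pass rates slightly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, List, Tuple

from qepest.descriptors import DescriptorVector

__all__ = ["FilterResult", "lipinski", "tice_herbicide", "tice_insecticide", "hao", "FILTERS"]


@dataclass(frozen=True)
class FilterResult:
    rule_name: str
    violations: int
    passed: bool
    violated_criteria: Tuple[str, ...]


def _require(dv: DescriptorVector, rule: str, names: List[str]) -> None:
    for name in names:
        v = getattr(dv, name)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            if name == "arb":
                raise ValueError(
                    f"{rule}: the Hao filter needs aromatic-bond counts (arB); "
                    "supply an arB column or structure input"
                )
            raise ValueError(f"{rule}: missing descriptor {name!r}")


def _evaluate(rule: str, checks: List[Tuple[str, bool]]) -> FilterResult:
    violated = tuple(name for name, ok in checks if not ok)
    return FilterResult(rule_name=rule, violations=len(violated),
                        passed=len(violated) == 0, violated_criteria=violated)


def lipinski(dv: DescriptorVector) -> FilterResult:
    """Rule of five: MW <= 500, logP <= 5, HBD <= 5, HBA <= 10."""
    _require(dv, "lipinski", ["mw", "logp", "hbd", "hba"])
    return _evaluate("lipinski", [
        ("MW", dv.mw <= 500),
        ("logP", dv.logp <= 5),
        ("HBD", dv.hbd <= 5),
        ("HBA", dv.hba <= 10),
    ])


def tice_herbicide(dv: DescriptorVector) -> FilterResult:
    """Tice herbicide rule: 150 <= MW <= 500, logP <= 3.5, HBD <= 3,
    2 <= HBA <= 12, RB < 12."""
    _require(dv, "tice_herbicide", ["mw", "logp", "hbd", "hba", "rb"])
    return _evaluate("tice_herbicide", [
        ("MW", 150 <= dv.mw <= 500),
        ("logP", dv.logp <= 3.5),
        ("HBD", dv.hbd <= 3),
        ("HBA", 2 <= dv.hba <= 12),
        ("RB", dv.rb < 12),
    ])


def tice_insecticide(dv: DescriptorVector) -> FilterResult:
    """Tice insecticide rule: 150 <= MW <= 500, 0 <= logP <= 5, HBD <= 2,
    1 <= HBA <= 8, RB < 12."""
    _require(dv, "tice_insecticide", ["mw", "logp", "hbd", "hba", "rb"])
    return _evaluate("tice_insecticide", [
        ("MW", 150 <= dv.mw <= 500),
        ("logP", 0 <= dv.logp <= 5),
        ("HBD", dv.hbd <= 2),
        ("HBA", 1 <= dv.hba <= 8),
        ("RB", dv.rb < 12),
    ])


def hao(dv: DescriptorVector) -> FilterResult:
    """Hao pesticide rule: MW <= 435, logP <= 6, HBD <= 2, HBA <= 6,
    RB <= 9, aromatic bonds <= 17."""
    _require(dv, "hao", ["mw", "logp", "hbd", "hba", "rb", "arb"])
    return _evaluate("hao", [
        ("MW", dv.mw <= 435),
        ("logP", dv.logp <= 6),
        ("HBD", dv.hbd <= 2),
        ("HBA", dv.hba <= 6),
        ("RB", dv.rb <= 9),
        ("aromatic bonds", dv.arb <= 17),
    ])


FILTERS: dict[str, Callable[[DescriptorVector], FilterResult]] = {
    "lipinski": lipinski,
    "tice_herbicide": tice_herbicide,
    "tice_insecticide": tice_insecticide,
    "hao": hao,
}
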