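"""Combine descriptor desirabilities into QEH/QEI/QEF and the QEP fusions.

A class score is the unweighted geometric mean of the six descriptor
desirabilities,

    QEX = exp( (1/6) * sum_i ln df_i ),    X in {H, I, F},

with the Derringer-Suich zero rule: if any df_i is zero (the descriptor
value is unacceptable for that class) the whole score is zero.  The two
pesticide-likeness fusions are QEP_max = max(QEH, QEI, QEF) and
QEP_avg = (QEH + QEI + QEF) / 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence

from qepest.descriptors import DESCRIPTOR_NAMES, DescriptorVector
from qepest.desirability import DesirabilityParams, eval_df

__all__ = ["ClassProfile", "ScoreSet", "qe_score", "score_batch", "CLASS_LABELS"]

CLASS_LABELS = ("H", "I", "F")


@dataclass(frozen=True)
class ClassProfile:
    """Six scaled desirability parameter sets defining one class scorer."""

    class_label: str
    params: Dict[str, DesirabilityParams]

    def __post_init__(self) -> None:
        missing = [n for n in DESCRIPTOR_NAMES if n not in self.params]
        if missing:
            raise ValueError(f"profile {self.class_label!r} missing descriptors: {missing}")
        unscaled = [n for n in DESCRIPTOR_NAMES if self.params[n].max_value is None]
        if unscaled:
            raise ValueError(f"profile {self.class_label!r} has unscaled params: {unscaled}")


@dataclass(frozen=True)
class ScoreSet:
    """The five per-molecule pesticide-likeness scores, all in [0, 1]."""

    id: str
    qeh: float
    qei: float
    qef: float
    qep_max: float
    qep_avg: float


def qe_score(dv: DescriptorVector, profile: ClassProfile) -> float:
    """Geometric mean of the six descriptor desirabilities under a profile.

    Returns 0.0 exactly when any desirability is zero (an unacceptable
    descriptor makes the compound unacceptable).
    """
    log_sum = 0.0
    for name in DESCRIPTOR_NAMES:
        df = eval_df(dv.get(name), profile.params[name])
        if df <= 0.0:
            return 0.0
        log_sum += math.log(df)
    return math.exp(log_sum / len(DESCRIPTOR_NAMES))


def score_batch(dvs: Sequence[DescriptorVector], profiles: Dict[str, ClassProfile],
                ids: Sequence[str] | None = None) -> List[ScoreSet]:
    """Score molecules against all three class profiles, order preserved.

    ``profiles`` must hold exactly the classes H, I and F.
    """
    for label in CLASS_LABELS:
        if label not in profiles:
            raise ValueError(f"missing class profile {label!r} (need all of H, I, F)")
    if ids is None:
        ids = [f"mol{i + 1}" for i in range(len(dvs))]
    out = []
    for mol_id, dv in zip(ids, dvs):
        qeh = qe_score(dv, profiles["H"])
        qei = qe_score(dv, profiles["I"])
        qef = qe_score(dv, profiles["F"])
        out.append(ScoreSet(id=mol_id, qeh=qeh, qei=qei, qef=qef,
                            qep_max=max(qeh, qei, qef),
                            qep_avg=(qeh + qei + qef) / 3.0))
    return out
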