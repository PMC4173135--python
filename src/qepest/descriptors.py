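"""Compute the six scoring descriptors plus the aromatic-bond count.

The scoring functions use molecular weight (MW), the octanol-water log
partition coefficient (LogP), hydrogen-bond acceptor and donor counts
(HBA, HBD), the rotatable-bond count (RB) and the aromatic-ring count
(arR).  The aromatic-bond count (arB) is computed in addition because the
Hao pesticide filter bounds it.

Conventions
-----------
* MW uses average (natural-abundance) atomic masses.
* LogP is the Wildman-Crippen atom-contribution estimate.  Vendor logP
  models differ by constant-ish offsets; callers holding vendor values can
  supply them through a descriptor-table column instead.
* HBA/HBD use the toolkit's Lipinski-style perception (amide nitrogens are
  not acceptors; each N-H/O-H *atom* counts once as a donor, so urea has
  HBD = 2).  Setting ``hba_mode="no_count"`` switches HBA to the plain
  N+O count used by some rule-of-five implementations.
* RB counts acyclic single bonds between two non-terminal heavy atoms,
  excluding amide C-N bonds (the "strict" definition).
* arR counts aromatic rings in the smallest set of smallest rings; arB
  counts aromatic bonds, so fused systems share bonds (naphthalene:
  arR = 2, arB = 11).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

from rdkit.Chem import Descriptors, Lipinski, rdMolDescriptors

DESCRIPTOR_NAMES = ("MW", "LogP", "HBA", "HBD", "RB", "arR")
#: Descriptors binned with an optimized continuous bin width.
CONTINUOUS_DESCRIPTORS = ("MW", "LogP")
#: Descriptors binned with unit-width integer bins.
DISCRETE_DESCRIPTORS = ("HBA", "HBD", "RB", "arR")


@dataclass(frozen=True)
class DescriptorVector:
    """The per-molecule descriptors consumed by all scoring and filtering.

    ``arb`` is optional: descriptor tables without an ``arB`` column can
    feed every scorer and filter except Hao's.
    """

    mw: float
    logp: float
    hba: int
    hbd: int
    rb: int
    arr: int
    arb: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mw < 0:
            raise ValueError(f"mw must be >= 0, got {self.mw}")
        for name in ("hba", "hbd", "rb", "arr"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.arb is not None and self.arb < 0:
            raise ValueError(f"arb must be >= 0, got {self.arb}")

    def get(self, name: str) -> float:
        """Return a descriptor by its canonical column name (e.g. ``"MW"``)."""
        return getattr(self, name.lower() if name != "arB" else "arb")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compute_descriptors(record, hba_mode: str = "perception") -> DescriptorVector:
    """Compute the descriptor vector for one molecule record.

    Parameters
    ----------
    record : MoleculeRecord
        Record with a parsed (and preferably normalized) structure.
    hba_mode : {"perception", "no_count"}
        "perception" uses the toolkit's acceptor perception; "no_count"
        counts all nitrogen and oxygen atoms.

    Raises
    ------
    ValueError
        If the record carries no structure (descriptor-table inputs
        already hold their values and must not pass through here).
    """
    mol = getattr(record, "structure", record)
    if mol is None:
        raise ValueError(
            "record has no molecular structure; descriptor-table inputs "
            "already carry descriptor values -- use those directly"
        )
    if hba_mode == "perception":
        hba = Lipinski.NumHAcceptors(mol)
    elif hba_mode == "no_count":
        hba = Lipinski.NOCount(mol)
    else:
        raise ValueError(f"unknown hba_mode {hba_mode!r}")
    return DescriptorVector(
        mw=Descriptors.MolWt(mol),
        logp=Descriptors.MolLogP(mol),
        hba=hba,
        hbd=Lipinski.NumHDonors(mol),
        rb=rdMolDescriptors.CalcNumRotatableBonds(
            mol, rdMolDescriptors.NumRotatableBondsOptions.Strict
        ),
        arr=rdMolDescriptors.CalcNumAromaticRings(mol),
        arb=sum(1 for b in mol.GetBonds() if b.GetIsAromatic()),
    )
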