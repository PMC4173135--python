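"""Synthetic descriptor populations and a frozen molecule fixture set.

The marketed-pesticide training set and the patented-pesticide /
PubChem-decoy evaluation sets behind the original likeness profiles are
not distributable, so this module generates stand-ins:

* Pesticide-class populations whose per-descriptor marginals follow the
  same Gumbel-like single-peak shape the desirability curves are fitted
  with (offset o = 0, rejection sampling), with class-specific modes
  chosen to echo the qualitative class differences (insecticides more
  lipophilic and less aromatic, fungicides fewer rotatable bonds, ...).
* Decoy populations drawn uniformly over broad descriptor ranges that
  straddle all class modes, mirroring a 10x random background set.
* A frozen list of small, hand-checkable molecules whose expected counts
  (HBA/HBD/RB/arR/arB, toolkit-perception conventions documented in
  :mod:`qepest.descriptors`) and atomic-mass-sum MW anchor the
  descriptor tests.

Descriptors are sampled independently per molecule: the synthetic
populations carry no inter-descriptor correlation and correspond to no
real chemotypes, which suffices for exercising fitting, scoring and
enrichment but says nothing about behavior on real chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from qepest.descriptors import DESCRIPTOR_NAMES, DISCRETE_DESCRIPTORS, DescriptorVector

__all__ = ["PopulationSpec", "CLASS_SPECS", "DECOY_RANGES", "sample_population",
           "fixture_molecules", "default_spec"]

#: Per-class (mode b, width c) generating shapes, o = 0, unit amplitude.
#: Herbicides: mid-size, moderately polar, aromatic.  Insecticides: more
#: lipophilic, often non-aromatic, flexible.  Fungicides: smaller, rigid.
CLASS_SPECS: Dict[str, Dict[str, Tuple[float, float]]] = {
    "H": {"MW": (300.0, 60.0), "LogP": (2.5, 1.2), "HBA": (4.0, 1.5),
          "HBD": (1.0, 0.8), "RB": (5.0, 2.0), "arR": (2.0, 0.8)},
    "I": {"MW": (320.0, 70.0), "LogP": (4.5, 1.5), "HBA": (3.0, 1.5),
          "HBD": (0.5, 0.8), "RB": (6.0, 2.5), "arR": (0.0, 1.0)},
    "F": {"MW": (280.0, 55.0), "LogP": (3.0, 1.2), "HBA": (3.0, 1.5),
          "HBD": (1.0, 0.8), "RB": (2.0, 1.5), "arR": (1.0, 0.8)},
}

#: Uniform decoy ranges, broad enough to straddle every class mode.
DECOY_RANGES: Dict[str, Tuple[float, float]] = {
    "MW": (50.0, 1200.0), "LogP": (-5.0, 12.0), "HBA": (0.0, 25.0),
    "HBD": (0.0, 10.0), "RB": (0.0, 25.0), "arR": (0.0, 10.0),
}


@dataclass(frozen=True)
class PopulationSpec:
    """Generating recipe for one synthetic descriptor population."""

    class_label: str  # H, I, F or "decoy"
    n: int
    seed: int
    shapes: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"population size must be > 0, got {self.n}")
        if self.class_label not in ("H", "I", "F", "decoy"):
            raise ValueError(f"unknown class label {self.class_label!r}")


def default_spec(class_label: str, n: int, seed: int) -> PopulationSpec:
    shapes = DECOY_RANGES if class_label == "decoy" else CLASS_SPECS[class_label]
    return PopulationSpec(class_label=class_label, n=n, seed=seed, shapes=dict(shapes))


def _peak_shape(t: np.ndarray) -> np.ndarray:
    # unit-amplitude curve exp(-exp(-t) - t + 1); max 1 at t = 0
    return np.exp(-np.exp(np.minimum(-t, 700.0)) - t + 1.0)


def _rejection_sample(rng: np.random.Generator, b: float, c: float, n: int,
                      lo: float | None = None) -> np.ndarray:
    """Sample the density proportional to the o=0 peak shape on [b-10c, b+10c]."""
    left = b - 10.0 * c if lo is None else max(b - 10.0 * c, lo)
    right = b + 10.0 * c
    if right <= left:
        raise ValueError(
            f"empty sampling domain for shape b={b}, c={c} with lower bound {lo}: "
            "degenerate spec"
        )
    out = np.empty(0)
    n_proposed = 0
    while out.size < n:
        m = max(4 * (n - out.size), 256)
        x = rng.uniform(left, right, size=m)
        u = rng.uniform(0.0, 1.0, size=m)  # envelope height = peak max = 1
        accepted = x[u < _peak_shape((x - b) / c)]
        n_proposed += m
        out = np.concatenate([out, accepted])
        if n_proposed >= 100 * n and out.size < 0.01 * n_proposed:
            raise ValueError(
                f"rejection acceptance rate below 1% for shape b={b}, c={c}: degenerate spec"
            )
    return out[:n]


def sample_population(spec: PopulationSpec) -> List[DescriptorVector]:
    """Draw a descriptor population; reproducible from the spec's seed.

    Each descriptor is sampled independently.  Pesticide classes use
    rejection sampling from the class's peak shape; decoys are uniform.
    Count descriptors are rounded to the nearest integer and clamped at
    zero; MW is kept strictly positive.
    """
    rng = np.random.default_rng(spec.seed)
    shapes = spec.shapes or (
        DECOY_RANGES if spec.class_label == "decoy" else CLASS_SPECS[spec.class_label]
    )
    columns: Dict[str, np.ndarray] = {}
    for name in DESCRIPTOR_NAMES:
        lo_bound = 1e-3 if name == "MW" else None
        if spec.class_label == "decoy":
            lo, hi = shapes[name]
            values = rng.uniform(lo, hi, size=spec.n)
        else:
            b, c = shapes[name]
            values = _rejection_sample(rng, b, c, spec.n, lo=lo_bound)
        if name in DISCRETE_DESCRIPTORS:
            values = np.maximum(np.rint(values), 0.0)
        columns[name] = values
    out = []
    for i in range(spec.n):
        arr = int(columns["arR"][i])
        # aromatic bonds follow the linearly-fused-ring convention: six bonds
        # for one ring, five more per additional fused ring (naphthalene: 11)
        arb = 5 * arr + 1 if arr >= 1 else 0
        out.append(DescriptorVector(
            mw=float(columns["MW"][i]), logp=float(columns["LogP"][i]),
            hba=int(columns["HBA"][i]), hbd=int(columns["HBD"][i]),
            rb=int(columns["RB"][i]), arr=arr, arb=arb,
        ))
    return out


def fixture_molecules() -> List[Tuple[str, str, DescriptorVector]]:
    """Frozen (name, SMILES, expected descriptors) fixture list.

    Counts follow the package's documented conventions (per-donor-atom
    HBD, toolkit acceptor perception, strict rotatable bonds, SSSR
    aromatic rings, shared fused aromatic bonds) and were verified by
    manual counting; MW is the sum of average atomic masses.  LogP is
    model-dependent and deliberately not frozen here (0.0 placeholder).
    """
    rows = [
        # name, smiles, mw, hba, hbd, rb, arr, arb
        ("benzene", "c1ccccc1", 78.114, 0, 0, 0, 1, 6),
        ("toluene", "Cc1ccccc1", 92.141, 0, 0, 0, 1, 6),
        ("n-propylbenzene", "CCCc1ccccc1", 120.195, 0, 0, 2, 1, 6),
        ("biphenyl", "c1ccccc1-c1ccccc1", 154.212, 0, 0, 1, 2, 12),
        ("naphthalene", "c1ccc2ccccc2c1", 128.174, 0, 0, 0, 2, 11),
        ("pyridine", "c1ccncc1", 79.102, 1, 0, 0, 1, 6),
        ("phenol", "Oc1ccccc1", 94.113, 1, 1, 0, 1, 6),
        ("aniline", "Nc1ccccc1", 93.129, 1, 1, 0, 1, 6),
        ("ethanol", "CCO", 46.069, 1, 1, 0, 0, 0),
        ("dimethyl ether", "COC", 46.069, 1, 0, 0, 0, 0),
        ("n-butane", "CCCC", 58.124, 0, 0, 1, 0, 0),
        ("cyclohexane", "C1CCCCC1", 84.162, 0, 0, 0, 0, 0),
        ("acetic acid", "CC(=O)O", 60.052, 1, 1, 0, 0, 0),
        ("acetamide", "CC(N)=O", 59.068, 1, 1, 0, 0, 0),
        ("urea", "NC(=O)N", 60.056, 1, 2, 0, 0, 0),
        ("benzamide", "NC(=O)c1ccccc1", 121.139, 1, 1, 1, 1, 6),
        ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C", 194.194, 6, 0, 0, 2, 10),
        ("atrazine", "CCNc1nc(Cl)nc(NC(C)C)n1", 215.685, 5, 2, 4, 1, 6),
        ("glyphosate", "OC(=O)CNCP(=O)(O)O", 169.073, 3, 4, 4, 0, 0),
        ("2,4-D", "OC(=O)COc1ccc(Cl)cc1Cl", 221.033, 2, 1, 3, 1, 6),
        ("carbaryl", "CNC(=O)Oc1cccc2ccccc12", 201.225, 2, 1, 1, 2, 11),
        ("imidacloprid", "[O-][N+](=O)/N=C1\\NCCN1Cc1ccc(Cl)nc1", 255.662, 3, 1, 3, 1, 6),
    ]
    return [
        (name, smi, DescriptorVector(mw=mw, logp=0.0, hba=hba, hbd=hbd,
                                     rb=rb, arr=arr, arb=arb))
        for name, smi, mw, hba, hbd, rb, arr, arb in rows
    ]
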