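"""Read molecular structures and descriptor tables; write score reports.

Supported inputs:

* SMILES files (``.smi``): whitespace-separated ``SMILES id`` per line;
  a missing id becomes ``mol<line>``.
* SDF V2000 files: the molecule title (or ``mol<n>``) is the id.
* Descriptor CSVs: comma-separated, header row, UTF-8, with the
  case-sensitive columns ``MW, LogP, HBA, HBD, RB, arR`` and optionally
  ``arB`` and ``id``.

Unparseable entries are skipped, counted and logged with their line
numbers -- never silently dropped.  Duplicate ids within a batch are
suffixed ``_2``, ``_3``, ... in input order.

Normalization reduces a structure to its largest organic fragment (salt
stripping), neutralizes charges where chemically valid, and
canonicalizes.  Tautomers and stereochemistry are left untouched.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

from qepest.descriptors import DescriptorVector

logger = logging.getLogger(__name__)

REQUIRED_CSV_COLUMNS = ("MW", "LogP", "HBA", "HBD", "RB", "arR")

# RDKit parse warnings go to its own C++ logger; silence the chatter and
# report skips through our logger instead.
RDLogger.DisableLog("rdApp.error")


@dataclass
class MoleculeRecord:
    """One input molecule: an id, a structure and/or a descriptor vector."""

    id: str
    structure: Optional[Chem.Mol]
    source_line: int
    descriptors: Optional[DescriptorVector] = None
    normalization_failed: bool = False


def _dedupe_ids(records: List[MoleculeRecord]) -> List[MoleculeRecord]:
    seen: dict = {}
    out = []
    for rec in records:
        n = seen.get(rec.id, 0) + 1
        seen[rec.id] = n
        out.append(rec if n == 1 else replace(rec, id=f"{rec.id}_{n}"))
    return out


def _read_smiles(path: Path) -> List[MoleculeRecord]:
    records = []
    skipped = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                skipped.append(lineno)
                logger.warning("line %d: unparseable SMILES %r -- skipped", lineno, smiles)
                continue
            records.append(MoleculeRecord(id=mol_id, structure=mol, source_line=lineno))
    if skipped:
        logger.warning("skipped %d unparseable entries (lines %s)", len(skipped), skipped)
    return records


def _read_sdf(path: Path) -> List[MoleculeRecord]:
    records = []
    n_skipped = 0
    supplier = Chem.SDMolSupplier(str(path))
    for idx, mol in enumerate(supplier, start=1):
        if mol is None:
            n_skipped += 1
            logger.warning("SDF record %d: unparseable -- skipped", idx)
            continue
        title = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        records.append(MoleculeRecord(id=title.strip() or f"mol{idx}", structure=mol, source_line=idx))
    if n_skipped:
        logger.warning("skipped %d unparseable SDF records", n_skipped)
    return records


def _read_csv(path: Path) -> List[MoleculeRecord]:
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty descriptor CSV")
        for col in REQUIRED_CSV_COLUMNS:
            if col not in reader.fieldnames:
                raise ValueError(f"{path}: missing required descriptor column {col!r}")
        has_arb = "arB" in reader.fieldnames
        has_id = "id" in reader.fieldnames
        records = []
        skipped = []
        for lineno, row in enumerate(reader, start=2):  # header is line 1
            try:
                dv = DescriptorVector(
                    mw=float(row["MW"]),
                    logp=float(row["LogP"]),
                    hba=int(float(row["HBA"])),
                    hbd=int(float(row["HBD"])),
                    rb=int(float(row["RB"])),
                    arr=int(float(row["arR"])),
                    arb=int(float(row["arB"])) if has_arb and row["arB"] not in ("", None) else None,
                )
            except (TypeError, ValueError) as exc:
                skipped.append(lineno)
                logger.warning("line %d: bad descriptor row (%s) -- skipped", lineno, exc)
                continue
            mol_id = row["id"].strip() if has_id and row["id"] else f"mol{lineno}"
            records.append(MoleculeRecord(id=mol_id, structure=None, source_line=lineno, descriptors=dv))
    if skipped:
        logger.warning("skipped %d bad rows (lines %s)", len(skipped), skipped)
    return records


def read_structures(path, format: Optional[str] = None) -> List[MoleculeRecord]:
    """Read molecules from a SMILES, SDF or descriptor-CSV file.

    Parameters
    ----------
    path : str or Path
        Input file.
    format : {"smiles", "sdf", "csv"}, optional
        Inferred from the file extension (.smi/.sdf/.csv) when omitted.

    Returns
    -------
    list of MoleculeRecord
        In file order, ids made unique.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValueError
        If no record is parseable, the format is unknown, or a required
        CSV column is missing.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"input file not found: {path}")
    if format is None:
        format = {".smi": "smiles", ".smiles": "smiles", ".sdf": "sdf", ".csv": "csv"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise ValueError(f"cannot infer format from extension of {path}; pass format=")
    if format == "smiles":
        records = _read_smiles(path)
    elif format == "sdf":
        records = _read_sdf(path)
    elif format == "csv":
        records = _read_csv(path)
    else:
        raise ValueError(f"unknown format {format!r} (expected smiles, sdf or csv)")
    if not records:
        raise ValueError(f"{path}: no parseable records")
    return _dedupe_ids(records)


_FRAGMENT_CHOOSER = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_UNCHARGER = rdMolStandardize.Uncharger()


def normalize_structure(record: MoleculeRecord) -> MoleculeRecord:
    """Return the record with a normalized structure.

    Normalization: largest organic fragment, charge neutralization where
    chemically valid, canonical atom ordering.  Idempotent.  On failure
    the record is returned flagged (``normalization_failed=True``) and the
    event is logged; flagged records are excluded from scoring.
    """
    if record.structure is None:
        raise ValueError(f"record {record.id!r} has no structure to normalize")
    try:
        mol = _FRAGMENT_CHOOSER.choose(record.structure)
        mol = _UNCHARGER.uncharge(mol)
        mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
        if mol is None:
            raise ValueError("re-parse of normalized SMILES failed")
    except Exception as exc:  # normalization must never abort a batch
        logger.warning("normalization failed for %r: %s -- record flagged", record.id, exc)
        return replace(record, normalization_failed=True)
    return replace(record, structure=mol)


def write_descriptor_csv(path, ids: Sequence[str], vectors: Sequence[DescriptorVector]) -> None:
    """Write a descriptor table that :func:`read_structures` can re-read."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "MW", "LogP", "HBA", "HBD", "RB", "arR", "arB"])
        for mol_id, dv in zip(ids, vectors):
            writer.writerow(
                [mol_id, repr(dv.mw), repr(dv.logp), dv.hba, dv.hbd, dv.rb, dv.arr,
                 "" if dv.arb is None else dv.arb]
            )


def write_score_csv(path, score_sets, vectors: Sequence[DescriptorVector],
                    filter_results: Optional[Sequence[dict]] = None) -> None:
    """Write the score report: id, descriptors, the five QE scores, and
    optional per-rule pass/violation columns.  Scores print with 4 decimals."""
    filter_names = sorted(filter_results[0].keys()) if filter_results else []
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        header = ["id", "MW", "LogP", "HBA", "HBD", "RB", "arR",
                  "QEH", "QEI", "QEF", "QEPmax", "QEPavg"]
        for name in filter_names:
            header += [f"{name}_pass", f"{name}_violations"]
        writer.writerow(header)
        for i, (ss, dv) in enumerate(zip(score_sets, vectors)):
            row = [ss.id, f"{dv.mw:.3f}", f"{dv.logp:.3f}", dv.hba, dv.hbd, dv.rb, dv.arr,
                   f"{ss.qeh:.4f}", f"{ss.qei:.4f}", f"{ss.qef:.4f}",
                   f"{ss.qep_max:.4f}", f"{ss.qep_avg:.4f}"]
            if filter_results:
                for name in filter_names:
                    fr = filter_results[i][name]
                    row += [int(fr.passed), fr.violations]
            writer.writerow(row)
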