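"""Compound tables and molecular structures.

The experimental unit is a *compound record*: a small drug-like molecule with
an identity, an optional structure, the measured residual activity of acid
sphingomyelinase (ASM, as percent of solvent control) and the physicochemical
inputs the downstream descriptors are built from (logP, up to two basic pKa
values, the most acidic pKa, molecular weight, polar van-der-Waals surface
area, H-bond donor/acceptor counts, ...).

Tables travel as CSV/TSV with a header row; ``id`` and ``mw`` are mandatory.
Unknown columns are preserved verbatim in :attr:`CompoundRecord.extras` so a
superset export (e.g. a hand-converted supplementary table) loads unchanged.
Missing numeric cells stay *missing* (``None``) until the documented
imputation step in :mod:`fiasma.descriptors`; no sentinel values are invented
at parse time.

Structures are read from SMILES (one molecule per line, identifier after
whitespace) or SDF V2000 via RDKit; unparseable entries are reported, not
fatal.
"""

from __future__ import annotations

import csv
import logging
import sys
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

from rdkit import Chem
from rdkit import RDLogger

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)
logging.basicConfig(stream=sys.stderr)

RDLogger.DisableLog("rdApp.*")  # parse failures are reported through our own channel

#: canonical column order for table round-trips
_NUMERIC_FLOAT = (
    "residual_activity",
    "incubation_min",
    "logp",
    "pka_base1",
    "pka_base2",
    "pka_acid",
    "mw",
    "vsa_pol",
    "logbb",
)
_NUMERIC_INT = ("cid", "hbd", "hba", "k")


@dataclass
class CompoundRecord:
    """One compound with identity, structure reference and measured inputs.

    ``residual_activity`` is normalised to the solvent control (= 100 %);
    values above 100 are legitimate (stimulation within assay noise).
    ``pka_base1`` is the most basic pKa, ``pka_base2`` the second-most basic;
    ``k`` counts heavy atoms at the most basic nitrogen.
    """

    id: str
    name: str = ""
    cid: int | None = None
    smiles: str | None = None
    residual_activity: float | None = None
    incubation_min: float | None = None
    logp: float | None = None
    pka_base1: float | None = None
    pka_base2: float | None = None
    pka_acid: float | None = None
    mw: float = 0.0
    vsa_pol: float | None = None
    hbd: int | None = None
    hba: int | None = None
    k: int | None = None
    logbb: float | None = None
    atc_codes: list[str] = field(default_factory=list)
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mw is None or self.mw <= 0:
            raise ValidationError(f"compound {self.id!r}: mw must be > 0, got {self.mw}")
        if self.residual_activity is not None and self.residual_activity < 0:
            raise ValidationError(
                f"compound {self.id!r}: residual_activity must be >= 0"
            )
        if (
            self.pka_base1 is not None
            and self.pka_base2 is not None
            and self.pka_base1 < self.pka_base2
        ):
            raise ValidationError(
                f"compound {self.id!r}: pka_base1 must be >= pka_base2"
            )


@dataclass
class CompoundTable:
    """Ordered collection of :class:`CompoundRecord` with unique ids."""

    records: list[CompoundRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        dupes = []
        for r in self.records:
            seen[r.id] = seen.get(r.id, 0) + 1
            if seen[r.id] == 2:
                dupes.append(r.id)
        if dupes:
            raise ValidationError(f"duplicate compound ids: {', '.join(sorted(dupes))}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def get(self, cid: str) -> CompoundRecord:
        for r in self.records:
            if r.id == cid:
                return r
        raise KeyError(cid)


def _parse_cell(column: str, raw: str):
    raw = raw.strip()
    if raw == "":
        return None
    if column in _NUMERIC_FLOAT:
        try:
            return float(raw)
        except ValueError as exc:
            raise FormatError(f"column {column!r}: cannot parse {raw!r} as number") from exc
    if column in _NUMERIC_INT:
        try:
            return int(float(raw))
        except ValueError as exc:
            raise FormatError(f"column {column!r}: cannot parse {raw!r} as integer") from exc
    if column == "atc_codes":
        return [c for c in raw.split(";") if c]
    return raw


def read_compound_table(path: str | Path, format: str = "csv") -> CompoundTable:
    """Read a compound table from CSV or TSV.

    One record per data row, order preserved. Empty cells map to absent
    optional fields; columns outside the known inventory are kept as strings
    in :attr:`CompoundRecord.extras`.
    """
    delim = {"csv": ",", "tsv": "\t"}.get(format)
    if delim is None:
        raise FormatError(f"unknown table format {format!r}")
    path = Path(path)
    known = {f.name for f in dc_fields(CompoundRecord)} - {"extras"}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, header row required")
        for mandatory in ("id", "mw"):
            if mandatory not in reader.fieldnames:
                raise FormatError(f"{path}: missing mandatory column {mandatory!r}")
        records = []
        for row in reader:
            kwargs = {}
            extras = {}
            for col, raw in row.items():
                if col is None:
                    raise FormatError(f"{path}: row has more cells than header columns")
                if col in known:
                    val = _parse_cell(col, raw or "")
                    if val is not None:
                        kwargs[col] = val
                elif raw not in (None, ""):
                    extras[col] = raw
            if "id" not in kwargs:
                raise ValidationError(f"{path}: row with empty id")
            records.append(CompoundRecord(extras=extras, **kwargs))
    table = CompoundTable(records, provenance=str(path))
    logger.info("read %d compound records from %s", len(records), path)
    return table


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)  # shortest string that round-trips exactly
    if isinstance(value, list):
        return ";".join(value)
    return str(value)


def write_compound_table(table: CompoundTable, path: str | Path, format: str = "csv") -> None:
    """Write a table so that :func:`read_compound_table` reproduces it exactly."""
    delim = {"csv": ",", "tsv": "\t"}.get(format)
    if delim is None:
        raise FormatError(f"unknown table format {format!r}")
    core = [f.name for f in dc_fields(CompoundRecord) if f.name != "extras"]
    extra_cols: list[str] = []
    for r in table.records:
        for c in r.extras:
            if c not in extra_cols:
                extra_cols.append(c)
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(core + extra_cols)
        for r in table.records:
            row = [_format_cell(getattr(r, c)) for c in core]
            row += [r.extras.get(c, "") for c in extra_cols]
            writer.writerow(row)


class StructureSet(NamedTuple):
    """Parsed molecular graphs keyed by compound id, plus reported failures."""

    molecules: dict[str, Chem.Mol]
    failures: list[str]


def _sanitize(mol: Chem.Mol) -> Chem.Mol | None:
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def read_structures(path: str | Path, format: str = "smiles") -> StructureSet:
    """Read molecular structures from a SMILES or SDF file.

    Each returned entry is a sanitized RDKit molecule (explicit charges,
    aromaticity perceived). Unparseable entries are collected in
    ``failures``; only a file with zero parseable structures is an error.
    """
    path = Path(path)
    molecules: dict[str, Chem.Mol] = {}
    failures: list[str] = []
    if format == "smiles":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                smiles = parts[0]
                key = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
                mol = Chem.MolFromSmiles(smiles)
                if mol is None:
                    failures.append(key)
                    continue
                molecules[key] = mol
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=False)
        for i, mol in enumerate(supplier):
            if mol is None:
                failures.append(f"record{i}")
                continue
            key = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"record{i}"
            mol = _sanitize(mol)
            if mol is None:
                failures.append(key)
                continue
            molecules[key] = mol
    else:
        raise FormatError(f"unknown structure format {format!r}")
    if not molecules:
        raise FormatError(f"{path}: no parseable structures")
    if failures:
        logger.warning("%s: %d structure(s) failed to parse: %s", path, len(failures), failures)
    return StructureSet(molecules, failures)


def write_structures(molecules: Mapping[str, "Chem.Mol"] | Iterable[tuple[str, str]],
                     path: str | Path) -> None:
    """Write id-keyed molecules (or (id, smiles) pairs) as a SMILES file."""
    with Path(path).open("w", encoding="utf-8") as fh:
        items = molecules.items() if isinstance(molecules, Mapping) else molecules
        for key, mol in items:
            smiles = mol if isinstance(mol, str) else Chem.MolToSmiles(mol)
            fh.write(f"{smiles} {key}\n")
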