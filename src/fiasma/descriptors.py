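"""Molecular descriptors for lysosomotropism modelling.

Derived descriptors
-------------------
The model works on a small, mechanistically interpretable descriptor set:

* ``logp_logweight`` = logP - 1/2 * log10(MW): a molecular-weight-corrected
  lipophilicity, more closely related to diffusion of small molecules through
  lipid phases than logP itself (the same correction is used for blood-brain
  barrier permeation models).
* ``pka_sum_basic_mod``: pKa of the most basic nitrogen plus, if positive,
  the pKa of the second-most basic nitrogen -- captures the extra proton that
  a second basic centre can pick up inside the acidic lysosome.
* ``pka_most_acidic``: guards against acids, which are excluded from acidic
  compartments (anionic species are membrane-impermeant and electrically
  repelled).
* ``si_vsa_pol`` = vsa_pol / MW: size-intensive polar van-der-Waals surface
  area (both H-bond donors and acceptors count as polar atoms).

Missing-value handling follows fixed, auditable rules (`impute_descriptors`):
a missing basic pKa means "no basic group" and becomes 0, a missing acidic
pKa means "no acidic group" and becomes 15, a missing heavy-atom count k
becomes 12. Every imputed entry is flagged.

logP, pKa values, vsa_pol, and H-bond counts are *inputs* (they come from
external property calculators); only the derived and count descriptors are
computed here. An optional structure-based surrogate for vsa_pol is provided
and explicitly flagged as such.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from .errors import FiasmaError, ValidationError
from .io import CompoundRecord, CompoundTable

#: imputation constants: "no basic group", "no acidic group", "default k"
IMPUTE_PKA_BASE = 0.0
IMPUTE_PKA_ACID = 15.0
IMPUTE_K = 12

#: relevance thresholds for ionization-category assignment
RELEVANT_BASE_PKA = 3.0
RELEVANT_ACID_PKA = 10.0

#: base of the logarithm in the molecular-weight correction of logP
LOGWEIGHT_BASE = 10.0


class IonizationCategory(enum.Enum):
    ACID = "acid"
    MONOBASE = "monobase"
    BIBASE = "bibase"
    ZWITTER = "zwitter"
    NONE = "none"


@dataclass
class DescriptorVector:
    """Named numeric descriptors for one compound with per-entry provenance.

    ``flags[name]`` is one of ``"input"``, ``"derived"``, ``"imputed"``.
    """

    values: dict[str, float] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)

    def set(self, name: str, value: float, flag: str) -> None:
        self.values[name] = value
        self.flags[name] = flag


def impute_descriptors(values: Mapping[str, float | None]) -> DescriptorVector:
    """Apply the fixed imputation rules to the raw physicochemical inputs.

    Total function: any of ``pka_base1``, ``pka_base2``, ``pka_acid``, ``k``
    missing from (or ``None`` in) ``values`` receives its documented
    substitute and is flagged ``"imputed"``; everything else passes through
    flagged ``"input"``.
    """
    out = DescriptorVector()
    substitutes = {
        "pka_base1": IMPUTE_PKA_BASE,
        "pka_base2": IMPUTE_PKA_BASE,
        "pka_acid": IMPUTE_PKA_ACID,
        "k": float(IMPUTE_K),
    }
    for name, val in values.items():
        if val is not None:
            out.set(name, float(val), "input")
    for name, sub in substitutes.items():
        if values.get(name) is None:
            out.set(name, sub, "imputed")
    return out


def classify_ionization(
    pka_base1: float | None,
    pka_base2: float | None,
    pka_acid: float | None,
) -> IonizationCategory:
    """Assign the ionization category from *pre-imputation* pKa values.

    A basic group is relevant iff its pKa >= 3; an acidic group is relevant
    iff its pKa < 10 (outside these windows a group is not ionized to a
    biologically meaningful extent between lysosomal and extracellular pH).
    An acid together with at least one relevant base is a zwitterion.
    """
    base1 = pka_base1 is not None and pka_base1 >= RELEVANT_BASE_PKA
    base2 = pka_base2 is not None and pka_base2 >= RELEVANT_BASE_PKA
    acid = pka_acid is not None and pka_acid < RELEVANT_ACID_PKA
    n_bases = int(base1) + int(base2)
    if acid and n_bases >= 1:
        return IonizationCategory.ZWITTER
    if acid:
        return IonizationCategory.ACID
    if n_bases == 1:
        return IonizationCategory.MONOBASE
    if n_bases == 2:
        return IonizationCategory.BIBASE
    return IonizationCategory.NONE


def logp_logweight(logp: float, mw: float) -> float:
    """Molecular-weight-corrected lipophilicity: logP - 1/2*log10(MW)."""
    if mw <= 0:
        raise ValidationError(f"mw must be > 0, got {mw}")
    return logp - 0.5 * math.log(mw, LOGWEIGHT_BASE)


def pka_sum_mod(pka_base1: float, pka_base2: float) -> float:
    """Sum of the two most basic pKa values, counting the second only if positive.

    Inputs are post-imputation (a missing second base is already 0).
    """
    if pka_base2 > 0:
        return pka_base1 + pka_base2
    return pka_base1


def size_intensive(value: float, mw: float) -> float:
    """Size-intensive form of a descriptor: value divided by molecular weight."""
    if mw <= 0:
        raise ValidationError(f"mw must be > 0, got {mw}")
    return value / mw


# --- count descriptors -------------------------------------------------------

# SMARTS definitions are documented choices; the source descriptors name the
# chemistry ("quaternary nitrogen", "carboxylic acid", "amine") without
# printing patterns, so these stand in and are fixed here in one place.
_SMARTS = {
    # N with formal charge +1, four connections, no attached H
    "n_qN": Chem.MolFromSmarts("[N+;X4;H0]"),
    # carboxylic acid: trigonal C double-bonded to O with an OH
    "n_COOH": Chem.MolFromSmarts("[CX3](=O)[OX2H1]"),
    # amine: neutral trivalent non-aromatic N, not an amide/sulfonamide N
    "n_amines": Chem.MolFromSmarts("[NX3;+0;!a;!$([N][C,S]=[O,S,N])]"),
    # protonizable delocalized nitrogen in an N-C=N (amidine/guanidine) motif
    "n_pdN": Chem.MolFromSmarts("[NX3][CX3]=[NX2]"),
}
_HALOGENS = {9, 17, 35, 53}


def count_descriptors(mol: Chem.Mol) -> dict[str, int]:
    """Integer count descriptors from a sanitized molecular graph.

    Returns ``n_qN`` (quaternary nitrogens), ``n_COOH`` (carboxylic acid
    functions), ``n_OpN`` (nitrogen + oxygen atoms), ``n_hal`` (halogens),
    ``n_XpC`` (halogens + carbons), ``n_amines`` (non-amide, non-aromatic
    amines) and ``n_pdN`` (N-C=N amidine/guanidine motifs).
    """
    if mol is None:
        raise ValidationError("count_descriptors requires a sanitized molecule")
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - invalid graphs are rare
        raise ValidationError(f"invalid molecular graph: {exc}") from exc
    nums = [a.GetAtomicNum() for a in mol.GetAtoms()]
    counts = {
        "n_OpN": sum(1 for z in nums if z in (7, 8)),
        "n_hal": sum(1 for z in nums if z in _HALOGENS),
        "n_XpC": sum(1 for z in nums if z == 6 or z in _HALOGENS),
    }
    for name, patt in _SMARTS.items():
        counts[name] = len(mol.GetSubstructMatches(patt, uniquify=True))
    return counts


@dataclass
class LipinskiResult:
    """Rule-of-Five evaluation; ``evaluable`` is False when an input is missing."""

    evaluable: bool
    count: int | None = None
    violated: bool | None = None


def lipinski_violation(
    mw: float | None, logp: float | None, hbd: int | None, hba: int | None
) -> LipinskiResult:
    """Count violations of the Rule-of-Five (MW>500, logP>5, HBD>5, HBA>10).

    A compound violates the rule if it contradicts *any* of the four
    conditions; all comparisons are strict. Missing inputs yield an explicit
    not-evaluable result (excluded from downstream contingency tables).
    """
    if any(v is None for v in (mw, logp, hbd, hba)):
        return LipinskiResult(evaluable=False)
    count = sum([mw > 500.0, logp > 5.0, hbd > 5, hba > 10])
    return LipinskiResult(evaluable=True, count=count, violated=count > 0)


def vsa_pol_surrogate(mol: Chem.Mol) -> float:
    """Structure-based *surrogate* for the polar van-der-Waals surface area.

    Sums Labute approximate-surface-area contributions over polar atoms
    (N and O, i.e. H-bond donors and acceptors both count as polar) plus the
    implicit-hydrogen contribution attached to them. This stands in when no
    externally computed ``vsa_pol`` column is available and is flagged as a
    surrogate in the descriptor matrix.
    """
    contribs = rdMolDescriptors._CalcLabuteASAContribs(mol)
    per_atom, h_contrib = contribs[0], contribs[1]
    polar = 0.0
    n_polar_h = 0
    n_h_total = 0
    for atom, c in zip(mol.GetAtoms(), per_atom):
        n_h_total += atom.GetTotalNumHs()
        if atom.GetAtomicNum() in (7, 8):
            polar += c
            n_polar_h += atom.GetTotalNumHs()
    if n_h_total:
        polar += h_contrib * n_polar_h / n_h_total
    return float(polar)


#: stable column order of the descriptor matrix
MODEL_DESCRIPTORS = ["logp_logweight", "pka_sum_basic_mod", "pka_most_acidic", "si_vsa_pol"]
#: raw input columns carried alongside; the imputed most-acidic pKa appears
#: only once, under its descriptor name pka_most_acidic
_RAW_COLUMNS = ["mw", "logp", "pka_base1", "pka_base2", "k", "vsa_pol", "hbd", "hba"]


def compute_descriptors(
    table: CompoundTable,
    structures: Mapping[str, Chem.Mol] | None = None,
    clys: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the descriptor matrix for a compound table.

    Returns ``(matrix, flags)``: two aligned DataFrames indexed by compound
    id, the first numeric, the second holding per-entry provenance flags
    (``input``/``derived``/``imputed``/``surrogate``). Rows for which a
    mandatory input (logp, mw, or vsa_pol with no structure to approximate it
    from) is absent carry NaN in the affected derived columns; downstream
    screening treats them as incalculable.
    """
    rows = {}
    flag_rows = {}
    for rec in table:
        imp = impute_descriptors(
            {
                "pka_base1": rec.pka_base1,
                "pka_base2": rec.pka_base2,
                "pka_acid": rec.pka_acid,
                "k": rec.k,
            }
        )
        vals: dict[str, float] = {}
        flags: dict[str, str] = {}

        def put(name, value, flag):
            vals[name] = value
            flags[name] = flag

        put("mw", rec.mw, "input")
        for name in ("pka_base1", "pka_base2", "k"):
            put(name, imp.values[name], imp.flags[name])
        put("logp", rec.logp if rec.logp is not None else np.nan,
            "input" if rec.logp is not None else "missing")
        for name in ("hbd", "hba"):
            v = getattr(rec, name)
            put(name, float(v) if v is not None else np.nan,
                "input" if v is not None else "missing")

        vsa = rec.vsa_pol
        vsa_flag = "input"
        if vsa is None and structures is not None and rec.id in structures:
            vsa = vsa_pol_surrogate(structures[rec.id])
            vsa_flag = "surrogate"
        put("vsa_pol", vsa if vsa is not None else np.nan,
            vsa_flag if vsa is not None else "missing")

        if rec.logp is not None:
            put("logp_logweight", logp_logweight(rec.logp, rec.mw), "derived")
        else:
            put("logp_logweight", np.nan, "missing")
        put("pka_sum_basic_mod",
            pka_sum_mod(imp.values["pka_base1"], imp.values["pka_base2"]), "derived")
        put("pka_most_acidic", imp.values["pka_acid"], imp.flags["pka_acid"])
        if vsa is not None:
            put("si_vsa_pol", size_intensive(vsa, rec.mw), "derived")
        else:
            put("si_vsa_pol", np.nan, "missing")

        if structures is not None and rec.id in structures:
            for name, v in count_descriptors(structures[rec.id]).items():
                put(name, float(v), "derived")
        if clys is not None and rec.id in clys:
            put("clys", clys[rec.id], "derived")

        rows[rec.id] = vals
        flag_rows[rec.id] = flags

    matrix = pd.DataFrame.from_dict(rows, orient="index")
    flags_df = pd.DataFrame.from_dict(flag_rows, orient="index").reindex(columns=matrix.columns)
    order = [c for c in _RAW_COLUMNS + MODEL_DESCRIPTORS if c in matrix.columns]
    order += [c for c in matrix.columns if c not in order]
    return matrix[order].loc[table.ids()], flags_df[order].loc[table.ids()]


def write_descriptor_matrix(matrix: pd.DataFrame, flags: pd.DataFrame, path, flags_path) -> None:
    """Emit the matrix and its provenance flags as sidecar CSVs."""
    matrix.to_csv(path, index_label="id")
    flags.to_csv(flags_path, index_label="id")
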