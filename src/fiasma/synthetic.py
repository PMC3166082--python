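"""Synthetic compound sets with the statistical structure of the ASM panel.

The generator emulates a 276-compound experimental panel: an ionization-
category mix of 23 acids, 155 monobases, 22 zwitterions, 45 bibases and 31
compounds without a relevantly ionizable group; a bimodal residual-activity
distribution (active mode near 35 %, inactive mode near 85 % of control,
truncated to [0, 120]); replicate measurement noise of ~16 % per replicate
(means of three replicates are reported); and -- crucially -- an activity
*mechanism*: the probability of being a functional ASM inhibitor is a
logistic function of weight-corrected lipophilicity, summed basic pKa,
most-acidic pKa and size-intensive polar surface area, i.e. exactly the
descriptor axes a lysosomotropism model should recover. Beam search
therefore has a recoverable planted signal, and the truth record suffices
to compute oracle labels.

Structures are small template molecules (decorated ring scaffolds with
amine/acid/halide substituents) consistent with the sampled ionization
category. They exist to exercise parsers, count descriptors, quaternary-
nitrogen filters and fingerprints -- not to emulate real chemical space.

Screening libraries come in two flavours: ``drug_like`` (a licensed-drug-like
library, a mid-single-digit-percent active fraction, group labels with a few
planted enriched groups) and ``natural_like`` (a natural-product-like
library, almost no actives, plus configurable counts of descriptor-
incalculable entries, quaternary-nitrogen compounds and exact duplicates to
exercise the screening filters).

Everything is a deterministic function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from rdkit import Chem

from ._rng import generator
from .errors import ConfigurationError
from .descriptors import compute_descriptors
from .io import CompoundRecord, CompoundTable
from .screening import ACTIVITY_THRESHOLD, classify_activity

#: number of replicate measurements averaged into one reported residual
N_REPLICATES = 3


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study; defaults emulate the experimental panel."""

    n_compounds: int = 276
    #: ionization-category mix (proportions are counts / total)
    category_counts: dict[str, int] = field(
        default_factory=lambda: {
            "acid": 23, "monobase": 155, "zwitter": 22, "bibase": 45, "none": 31
        }
    )
    active_mode_mean: float = 32.0
    active_mode_sd: float = 6.0
    inactive_mode_mean: float = 85.0
    inactive_mode_sd: float = 10.0
    truncation: tuple[float, float] = (0.0, 120.0)
    replicate_sd: float = 16.0
    n_noise_descriptors: int = 8
    #: logistic activity mechanism on the four mechanistic descriptor axes
    mech_coef_lipo: float = 1.6
    mech_coef_base: float = 0.5
    mech_coef_acid: float = 0.7
    mech_coef_polar: float = 30.0
    mech_offset: float = -4.25
    mech_scale: float = 0.5
    #: generated-active fraction of the experimental panel (latent-utility
    #: top-k); slightly above the target observed fraction 72/276 because
    #: measurement noise flips more actives to inactive than vice versa
    generated_active_fraction: float = 0.266
    #: fraction of compounds with literature logBB values
    logbb_fraction: float = 0.23
    #: screening-library structure
    library_n: int = 2000
    natural_n: int = 800
    n_incalculable: int = 13
    n_quaternary: int = 2
    n_duplicates: int = 17
    n_groups: int = 20
    enriched_groups: tuple[str, ...] = ("G03", "G05", "G08")
    enrichment_odds: float = 16.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ConfigurationError("n_compounds must be >= 1")
        if any(v < 0 for v in self.category_counts.values()) or not any(
            self.category_counts.values()
        ):
            raise ConfigurationError("category mix must contain compounds")
        for sd in (self.active_mode_sd, self.inactive_mode_sd):
            if sd <= 0:
                raise ConfigurationError("mode SDs must be > 0")


# --- structure templates ------------------------------------------------------
#
# Every compound gets a unique structure: a category-specific scaffold with
# an aromatic substituent {X} and an aliphatic tail {Y}, decoded from a
# per-category counter (mixed radix over template x X x Y). A canonical-
# SMILES uniqueness guard skips colliding codes, so the screening duplicate
# filter sees exactly the duplicates the generator plants.

_SUBS = ("F", "Cl", "Br", "C", "CC", "OC", "C(F)(F)F", "CCC")
_TAILS = ("C", "CC", "CCC", "CCCC", "CCCCC", "CC(C)C", "CCCCCC", "C1CC1")
_ARO2 = ("", "C", "F", "Cl", "OC", "CC", "Br", "C(C)C")
_TEMPLATES = {
    "acid": (
        "OC(=O)C({Y})c1cc({Z})cc({X})c1",
        "OC(=O)CC({Y})c1cc({Z})cc({X})c1",
        "CC({Y})c1cc({Z})cc({X})c1O",
    ),
    "monobase": (
        "CCN(CC)CC({Y})c1cc({Z})cc({X})c1",
        "CN1CCC(CC1)OC({Y})c1cc({Z})cc({X})c1",
        "CN(C)CC({Y})Cc1cc({Z})cc({X})c1",
        "CNCC({Y})c1cc({Z})cc({X})c1",
        "CC({Y})c1cc({Z})cc({X})n1",
    ),
    "bibase": (
        "CN(C)CCCN1CCN(CC1)C({Y})c1cc({Z})cc({X})c1",
        "NCCCN(C)C({Y})Cc1cc({Z})cc({X})c1",
        "CN1CCN(CC({Y})c2cc({Z})cc({X})c2)CC1",
    ),
    "zwitter": (
        "NC(CC({Y})c1cc({Z})cc({X})c1)C(=O)O",
        "OC(=O)CC1CCN(CC({Y})c2cc({Z})cc({X})c2)CC1",
    ),
    "none": (
        "CCCCOC({Y})c1cc({Z})cc({X})c1",
        "CCOCC({Y})c1cc({Z})cc({X})c1",
        "CCOC(=O)C({Y})c1cc({Z})cc({X})c1",
    ),
}
_QUAT_TEMPLATE = "C[N+](C)(C)CC({Y})c1cc({Z})cc({X})c1"


class _StructureFactory:
    """Deterministic unique-structure supply, one counter per category."""

    def __init__(self) -> None:
        self._counters: dict[str, int] = {}
        self._seen: set[str] = set()

    def make(self, category: str, templates: tuple[str, ...] | None = None) -> str:
        templates = templates or _TEMPLATES[category]
        while True:
            code = self._counters.get(category, 0)
            self._counters[category] = code + 1
            tpl = templates[code % len(templates)]
            code //= len(templates)
            x = _SUBS[code % len(_SUBS)]
            code //= len(_SUBS)
            y = _TAILS[code % len(_TAILS)]
            code //= len(_TAILS)
            z = _ARO2[code % len(_ARO2)]
            if code >= len(_ARO2):
                raise ConfigurationError(
                    f"structure-template capacity exhausted for {category!r}"
                )
            smiles = tpl.replace("{X}", x).replace("{Y}", y)
            smiles = smiles.replace("({Z})", "" if z == "" else f"({z})")
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:  # pragma: no cover - templates are pre-validated
                continue
            canonical = Chem.MolToSmiles(mol)
            if canonical not in self._seen:
                self._seen.add(canonical)
                return smiles


def _trunc_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return v
    return float(np.clip(mean, lo, hi))


@dataclass
class SyntheticExperiment:
    """Generated panel: table + structures + noise columns + truth record."""

    table: CompoundTable
    structures: dict[str, Chem.Mol]
    noise: pd.DataFrame  # uncorrelated descriptor columns, index = compound id
    truth: dict  # mechanism coefficients and per-compound latent state

    def labeled_matrix(self) -> tuple[pd.DataFrame, pd.Series]:
        """Descriptor matrix (mechanistic + raw + noise columns) and 0/1 labels
        derived from the observed residual activities via the 50 % threshold."""
        matrix, _ = compute_descriptors(self.table, structures=self.structures)
        # hbd/hba feed the Rule-of-Five analysis, not the learner; raw logp
        # differs from its weight-corrected form only by 0.5*log10(mw)
        # (r > 0.99 here), so the matrix carries the derived form once
        drop = [c for c in ("hbd", "hba", "logp") if c in matrix.columns]
        matrix = matrix.drop(columns=drop)
        full = pd.concat([matrix, self.noise], axis=1)
        labels = pd.Series(
            {
                rec.id: classify_activity(rec.residual_activity).label
                for rec in self.table
            },
            name="label",
        ).loc[full.index]
        return full, labels


def _sample_categories(config: GeneratorConfig, n: int, rng: np.random.Generator) -> list[str]:
    cats = list(config.category_counts)
    weights = np.array([config.category_counts[c] for c in cats], dtype=float)
    return [cats[i] for i in rng.choice(len(cats), size=n, p=weights / weights.sum())]


def _draw_compound(
    cid: str, category: str, config: GeneratorConfig, rng: np.random.Generator,
    factory: _StructureFactory,
) -> tuple[dict, str]:
    """Sample the physicochemical inputs and a structure for one compound."""
    mw = _trunc_normal(rng, 360.0, 85.0, 88.0, 850.0)
    logp = _trunc_normal(rng, 3.5, 1.6, -3.0, 9.0)
    hbd = int(min(rng.poisson(1.2 + (category in ("acid", "zwitter"))), 6))
    hba = int(min(1 + rng.poisson(3.0), 12))
    vsa = float(np.clip(8.0 * (hbd + hba) + rng.normal(20.0, 12.0), 5.0, 220.0))
    k = int(rng.integers(3, 13))
    rec: dict = {
        "id": cid,
        "name": f"synthetic-{cid}",
        "mw": mw,
        "logp": logp,
        "hbd": hbd,
        "hba": hba,
        "vsa_pol": vsa,
        "k": k,
    }
    if category == "acid":
        rec["pka_acid"] = _trunc_normal(rng, 4.5, 1.5, 1.0, 9.89)
    elif category == "monobase":
        rec["pka_base1"] = _trunc_normal(rng, 8.6, 1.4, 3.0, 11.5)
    elif category == "bibase":
        b1 = _trunc_normal(rng, 8.8, 1.2, 4.0, 11.5)
        b2 = float(np.clip(b1 - abs(rng.normal(1.5, 1.0)), 3.0, b1))
        rec["pka_base1"], rec["pka_base2"] = b1, b2
    elif category == "zwitter":
        rec["pka_base1"] = _trunc_normal(rng, 7.8, 1.5, 3.0, 11.0)
        rec["pka_acid"] = _trunc_normal(rng, 4.5, 1.8, 1.0, 9.89)
    else:  # none: no group at all, or groups outside the relevant windows
        if rng.random() < 22.0 / 31.0:
            if rng.random() < 0.5:
                rec["pka_base1"] = float(rng.uniform(0.5, 2.9))
            else:
                rec["pka_acid"] = float(rng.uniform(10.0, 14.0))
    smiles = factory.make(category)
    return rec, smiles


def _mechanism_score(rec: Mapping[str, float], config: GeneratorConfig) -> float:
    """Latent activity propensity on the four mechanistic descriptor axes."""
    x_lipo = rec["logp"] - 0.5 * np.log10(rec["mw"])
    b1 = rec.get("pka_base1") or 0.0
    b2 = rec.get("pka_base2") or 0.0
    x_base = b1 + (b2 if b2 > 0 else 0.0)
    x_acid = rec.get("pka_acid") if rec.get("pka_acid") is not None else 15.0
    x_polar = rec["vsa_pol"] / rec["mw"]
    return float(
        config.mech_offset
        + config.mech_coef_lipo * (x_lipo - 2.2)
        + config.mech_coef_base * (x_base - 8.2)
        + config.mech_coef_acid * (x_acid - 13.0)
        - config.mech_coef_polar * (x_polar - 0.22)
    )


def _observed_residual(
    active: bool, config: GeneratorConfig, rng: np.random.Generator
) -> float:
    """Class-conditional mode draw plus replicate noise on the mean of three.

    The latent compound-level residual stays on its class's side of the
    50 % threshold; measurement noise (replicate SD / sqrt(3)) can carry the
    *observed* value across, which is what produces the low-reliability
    calls near the threshold.
    """
    lo, hi = config.truncation
    if active:
        true = _trunc_normal(rng, config.active_mode_mean, config.active_mode_sd,
                             lo, ACTIVITY_THRESHOLD)
    else:
        true = _trunc_normal(rng, config.inactive_mode_mean, config.inactive_mode_sd,
                             np.nextafter(ACTIVITY_THRESHOLD, np.inf), hi)
    noise_sd = config.replicate_sd / np.sqrt(N_REPLICATES)
    if noise_sd > 0:
        return float(np.clip(true + rng.normal(0.0, noise_sd), lo, hi))
    return true


def generate_experimental_set(config: GeneratorConfig | None = None) -> SyntheticExperiment:
    """Generate the synthetic experimental panel (table, structures, truth)."""
    config = config or GeneratorConfig()
    rng = generator(config.seed, "experimental")
    factory = _StructureFactory()
    categories = _sample_categories(config, config.n_compounds, rng)
    # latent-utility mechanism: activity utility = mechanism score + logistic
    # noise; the top fraction becomes active. Equivalent to the logistic
    # model conditioned on the panel's designed class proportion.
    drawn = []
    for i, category in enumerate(categories):
        cid = f"S{i + 1:04d}"
        rec, smiles = _draw_compound(cid, category, config, rng, factory)
        score = _mechanism_score(rec, config)
        utility = score + config.mech_scale * float(rng.logistic())
        drawn.append((cid, category, rec, smiles, score, utility))
    n_active = int(round(config.generated_active_fraction * config.n_compounds))
    active_set = {
        d[0] for d in sorted(drawn, key=lambda d: -d[5])[:n_active]
    }
    records, structures, truth_rows = [], {}, []
    for cid, category, rec, smiles, score, utility in drawn:
        p_active = float(1.0 / (1.0 + np.exp(-score / config.mech_scale)))
        active = cid in active_set
        rec["residual_activity"] = _observed_residual(active, config, rng)
        slow = (rec.get("pka_base1") or 0) + max(rec.get("pka_base2") or 0, 0) > 17 or rec[
            "logp"
        ] > 6.5
        rec["incubation_min"] = 120.0 if slow else 30.0
        if rng.random() < config.logbb_fraction:
            # BBB permeation tracks the *observed* call: measured inhibition
            # requires the compound to have reached the lysosome, so observed
            # actives never carry a negative logBB
            if rec["residual_activity"] <= ACTIVITY_THRESHOLD:
                rec["logbb"] = float(max(rng.normal(0.7, 0.4), 0.0))
            else:
                rec["logbb"] = float(rng.normal(-0.2, 0.6))
        rec["smiles"] = smiles
        records.append(CompoundRecord(**rec))
        structures[cid] = Chem.MolFromSmiles(smiles)
        truth_rows.append(
            {"id": cid, "category": category, "score": score,
             "utility": utility, "p_active": p_active, "active": active}
        )
    table = CompoundTable(records, provenance=f"synthetic-experimental(seed={config.seed})")
    ids = [r.id for r in records]
    noise_rng = generator(config.seed, "noise")
    noise = pd.DataFrame(
        noise_rng.standard_normal((len(ids), config.n_noise_descriptors)),
        index=ids,
        columns=[f"noise_{j + 1:02d}" for j in range(config.n_noise_descriptors)],
    )
    truth = {
        "coefficients": {
            "lipo": config.mech_coef_lipo,
            "base": config.mech_coef_base,
            "acid": config.mech_coef_acid,
            "polar": -config.mech_coef_polar,
        },
        "compounds": truth_rows,
        "n_active_generated": sum(r["active"] for r in truth_rows),
    }
    return SyntheticExperiment(table, structures, noise, truth)


@dataclass
class SyntheticLibrary:
    """Generated screening library with group labels and truth record."""

    table: CompoundTable
    structures: dict[str, Chem.Mol]
    groups: dict[str, list[str]]
    truth: dict


def generate_library(
    config: GeneratorConfig | None = None, kind: str = "drug_like"
) -> SyntheticLibrary:
    """Generate a screening library.

    ``drug_like``: licensed-drug-like mix, roughly 7 % of compounds from the
    active-mechanism region, group labels with a few planted enriched groups
    carrying most of the actives. ``natural_like``: natural-product-like mix
    (acid/polyphenol-heavy, low lipophilicity/basicity, well under 1 %
    active), plus configured counts of descriptor-incalculable entries,
    quaternary-nitrogen compounds and exact duplicates.
    """
    config = config or GeneratorConfig()
    if kind not in ("drug_like", "natural_like"):
        raise ConfigurationError(f"unknown library kind {kind!r}")
    rng = generator(config.seed, f"library:{kind}")
    if kind == "drug_like":
        n = config.library_n
        mix = {"acid": 18, "monobase": 38, "zwitter": 12, "bibase": 7, "none": 25}
        shift = {"logp": -1.2, "pka_base1": -1.3}
        n_quat, n_dup, n_incalc = 0, 0, 0
    else:
        n = config.natural_n
        mix = {"acid": 30, "monobase": 12, "zwitter": 8, "bibase": 2, "none": 48}
        shift = {"logp": -2.2, "pka_base1": -3.2}
        n_quat = config.n_quaternary
        n_dup = config.n_duplicates
        n_incalc = config.n_incalculable
    lib_cfg = replace(config, category_counts=mix)
    n_fresh = n - n_quat - n_dup
    if n_fresh < 1:
        raise ConfigurationError("library size too small for the requested special entries")
    factory = _StructureFactory()
    categories = _sample_categories(lib_cfg, n_fresh, rng)
    records, structures, truth_rows = [], {}, []
    prefix = "D" if kind == "drug_like" else "N"
    for i, category in enumerate(categories):
        cid = f"{prefix}{i + 1:05d}"
        rec, smiles = _draw_compound(cid, category, lib_cfg, rng, factory)
        rec["logp"] = float(np.clip(rec["logp"] + shift["logp"], -3.0, 9.0))
        if rec.get("pka_base1") is not None:
            rec["pka_base1"] = float(
                np.clip(rec["pka_base1"] + shift["pka_base1"], 0.5, 11.5)
            )
            if rec.get("pka_base2") is not None:
                rec["pka_base2"] = float(min(rec["pka_base2"], rec["pka_base1"]))
        score = _mechanism_score(rec, lib_cfg)
        p_active = float(1.0 / (1.0 + np.exp(-score / config.mech_scale)))
        active = bool(rng.random() < p_active)
        rec["smiles"] = smiles
        records.append(CompoundRecord(**rec))
        structures[cid] = Chem.MolFromSmiles(smiles)
        truth_rows.append({"id": cid, "category": category, "active": active})
    # quaternary-nitrogen entries (screening filters must drop these)
    for j in range(n_quat):
        cid = f"{prefix}Q{j + 1:03d}"
        smiles = factory.make("quaternary", templates=(_QUAT_TEMPLATE,))
        rec = {"id": cid, "name": f"synthetic-{cid}", "mw": 200.0, "logp": -1.0,
               "vsa_pol": 20.0, "hbd": 0, "hba": 1, "smiles": smiles}
        records.append(CompoundRecord(**rec))
        structures[cid] = Chem.MolFromSmiles(smiles)
        truth_rows.append({"id": cid, "category": "quaternary", "active": False})
    # exact duplicates of already-generated fresh entries
    dup_sources = rng.choice(n_fresh, size=n_dup, replace=False) if n_dup else []
    for j, src in enumerate(dup_sources):
        cid = f"{prefix}DUP{j + 1:03d}"
        source = records[src]
        rec = {f: getattr(source, f) for f in (
            "mw", "logp", "pka_base1", "pka_base2", "pka_acid",
            "vsa_pol", "hbd", "hba", "k", "smiles")}
        rec.update({"id": cid, "name": f"duplicate-of-{source.id}"})
        records.append(CompoundRecord(**rec))
        structures[cid] = Chem.MolFromSmiles(source.smiles)
        truth_rows.append({"id": cid, "category": "duplicate", "active": False})
    # knock out descriptor inputs for the incalculable entries
    if n_incalc:
        fresh_ids = list(range(n_fresh))
        chosen = rng.choice(
            [i for i in fresh_ids if i not in set(dup_sources)],
            size=n_incalc, replace=False,
        )
        for i in chosen:
            records[i].logp = None
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    table = CompoundTable(records, provenance=f"synthetic-{kind}(seed={config.seed})")

    # group labels (ATC-second-level-like): actives pile into the enriched groups
    group_names = [f"G{i + 1:02d}" for i in range(config.n_groups)]
    plain = [g for g in group_names if g not in config.enriched_groups]
    active_ids = {r["id"] for r in truth_rows if r["active"]}
    groups: dict[str, list[str]] = {}
    for rec in records:
        weights = np.array(
            [
                config.enrichment_odds
                if (g in config.enriched_groups and rec.id in active_ids)
                else 1.0
                for g in group_names
            ]
        )
        n_memberships = 1 + int(rng.random() < 0.15)
        idx = rng.choice(len(group_names), size=n_memberships, replace=False,
                         p=weights / weights.sum())
        groups[rec.id] = [group_names[i] for i in idx]
    truth = {
        "kind": kind,
        "n_active_generated": len(active_ids),
        "compounds": truth_rows,
        "enriched_groups": list(config.enriched_groups),
    }
    return SyntheticLibrary(table, structures, groups, truth)
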