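"""Activity calls, bimodality analysis, virtual screening and enrichment.

A compound is called *active* (a functional ASM inhibitor) when its residual
ASM activity is <= 50.0 % of the solvent control; calls within one replicate
standard deviation (default 16 percentage points) of the threshold carry a
low-reliability flag.

The distribution of residual activities over a compound panel is strongly
bimodal -- active and inactive compounds form two separate modes -- which is
what justifies dichotomising the continuous readout. ``bimodality_analysis``
quantifies this: a Kolmogorov-Smirnov test of the pooled sample against a
single normal, plus a two-component Gaussian mixture fit (EM, initialised by
splitting at 50 %) with per-component normality tests.

``virtual_screen`` applies a trained model to a compound library after the
standard exclusions, in fixed order: compounds whose model descriptors are
incalculable, compounds with a quaternary nitrogen (no passive membrane
permeation, hence outside the model's applicability domain), and duplicate
structures. ``group_enrichment`` tests whether predicted actives concentrate
in particular drug groups (one-sided Fisher exact tests with
Benjamini-Hochberg correction), and ``rof_association`` cross-tabulates
activity against Rule-of-Five violation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy import stats
from sklearn.mixture import GaussianMixture
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .errors import PipelineError, ValidationError
from .io import CompoundTable
from .descriptors import compute_descriptors
from .learner import ModelArtifact

logger = logging.getLogger(__name__)

ACTIVITY_THRESHOLD = 50.0
REPLICATE_SD = 16.0


@dataclass
class ActivityCall:
    """Binary activity call for one residual-activity measurement."""

    residual_activity: float
    label: int
    low_reliability: bool

    @property
    def active(self) -> bool:
        return self.label == 1


def classify_activity(residual: float, sd: float = REPLICATE_SD) -> ActivityCall:
    """Threshold a residual ASM activity at <= 50.0 % (inclusive).

    Calls within ``sd`` percentage points of the threshold are flagged
    low-reliability (experimental error could flip them).
    """
    if residual < 0:
        raise ValidationError(f"residual activity must be >= 0, got {residual}")
    label = 1 if residual <= ACTIVITY_THRESHOLD else 0
    return ActivityCall(
        residual_activity=residual,
        label=label,
        low_reliability=abs(residual - ACTIVITY_THRESHOLD) < sd,
    )


# --- bimodality --------------------------------------------------------------

@dataclass
class MixtureComponent:
    mean: float
    sd: float
    weight: float
    ks_p: float | None  # normality within the component (None if too few points)
    n: int


@dataclass
class BimodalityReport:
    """Pooled-normality test plus a two-component Gaussian mixture fit."""

    n: int
    pooled_ks_p: float
    pooled_lilliefors_p: float
    components: list[MixtureComponent]
    converged: bool

    @property
    def component_means(self) -> tuple[float, ...]:
        return tuple(c.mean for c in self.components)


def bimodality_analysis(residuals: Sequence[float], min_component: int = 5) -> BimodalityReport:
    """Test a pooled residual-activity sample for deviation from normality
    and fit a two-component Gaussian mixture by EM.

    The pooled KS test uses the sample mean and SD as the reference normal's
    parameters (the Lilliefors-corrected p is reported alongside). The EM is
    initialised from the empirical split at the 50 % activity threshold; if
    either side of the split is empty or EM fails, a single-Gaussian
    fallback is reported with ``converged=False``.
    """
    x = np.asarray(residuals, dtype=float)
    if x.size < 20:
        raise ValidationError("bimodality analysis requires n >= 20")
    if np.ptp(x) == 0:
        raise ValidationError("degenerate input: all residual activities identical")
    mu, sd = x.mean(), x.std(ddof=1)
    pooled_p = stats.kstest(x, "norm", args=(mu, sd)).pvalue
    lf_p = lilliefors(x, dist="norm")[1]

    lo = x[x <= ACTIVITY_THRESHOLD]
    hi = x[x > ACTIVITY_THRESHOLD]
    converged = False
    components: list[MixtureComponent]
    if lo.size >= 2 and hi.size >= 2:
        gm = GaussianMixture(
            n_components=2,
            means_init=[[lo.mean()], [hi.mean()]],
            weights_init=[lo.size / x.size, hi.size / x.size],
            precisions_init=[[[1.0 / max(lo.var(), 1e-6)]], [[1.0 / max(hi.var(), 1e-6)]]],
            max_iter=500,
            random_state=0,
        )
        gm.fit(x.reshape(-1, 1))
        converged = bool(gm.converged_)
    if converged:
        resp = gm.predict(x.reshape(-1, 1))
        components = []
        for k in range(2):
            xk = x[resp == k]
            ks_p = None
            if xk.size >= min_component and xk.std(ddof=1) > 0:
                ks_p = float(stats.kstest(xk, "norm", args=(xk.mean(), xk.std(ddof=1))).pvalue)
            components.append(
                MixtureComponent(
                    mean=float(gm.means_[k, 0]),
                    sd=float(np.sqrt(gm.covariances_[k, 0, 0])),
                    weight=float(gm.weights_[k]),
                    ks_p=ks_p,
                    n=int(xk.size),
                )
            )
        components.sort(key=lambda c: c.mean)
    else:
        logger.warning("mixture fit did not converge; single-Gaussian fallback")
        components = [MixtureComponent(mean=float(mu), sd=float(sd), weight=1.0,
                                       ks_p=float(pooled_p), n=int(x.size))]
    return BimodalityReport(
        n=int(x.size),
        pooled_ks_p=float(pooled_p),
        pooled_lilliefors_p=float(lf_p),
        components=components,
        converged=converged,
    )


# --- virtual screening -------------------------------------------------------

_QUAT_N = Chem.MolFromSmarts("[N+;X4;H0]")


def _canonical_parent(mol: Chem.Mol) -> str:
    """Canonical SMILES of the largest fragment (salt-stripped duplicate key)."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    parent = max(frags, key=lambda f: f.GetNumHeavyAtoms())
    return Chem.MolToSmiles(parent)


@dataclass
class EnrichmentRow:
    group: str
    in_active: int
    in_inactive: int
    out_active: int
    out_inactive: int
    fisher_p: float
    adjusted_p: float | None = None
    enriched: bool = False


@dataclass
class ScreenResult:
    """Per-library screening outcome with reconciling exclusion counts."""

    library: str
    n_input: int
    n_excluded_incalculable: int
    n_excluded_quaternary: int
    n_excluded_duplicates: int
    n_screened: int
    n_predicted_active: int
    predictions: pd.DataFrame  # index id, columns: predicted, excluded_reason
    enrichment: list[EnrichmentRow] = field(default_factory=list)
    global_p: float | None = None

    def __post_init__(self) -> None:
        total = (
            self.n_screened
            + self.n_excluded_incalculable
            + self.n_excluded_quaternary
            + self.n_excluded_duplicates
        )
        if total != self.n_input:
            raise ValidationError("screening counts do not reconcile with n_input")

    @property
    def predicted_active_fraction(self) -> float:
        return self.n_predicted_active / self.n_screened if self.n_screened else 0.0


def virtual_screen(
    table: CompoundTable,
    model: ModelArtifact,
    structures: Mapping[str, Chem.Mol] | None = None,
    library_tag: str = "",
) -> ScreenResult:
    """Screen a compound library with a trained model.

    Exclusions are applied in fixed order: (1) compounds whose model
    descriptors are incalculable (missing inputs), (2) compounds with a
    quaternary nitrogen, (3) duplicate structures (canonical salt-stripped
    SMILES; the first occurrence is kept). The remaining compounds are
    classified; all counts reconcile with the input size.
    """
    matrix, _ = compute_descriptors(table, structures=structures)
    reason = pd.Series("", index=matrix.index, dtype=object)

    calculable = ~matrix[model.descriptor_names].isna().any(axis=1)
    reason[~calculable] = "incalculable"

    if structures:
        for cid in matrix.index[calculable]:
            mol = structures.get(cid)
            if mol is not None and mol.HasSubstructMatch(_QUAT_N):
                reason[cid] = "quaternary_nitrogen"

    seen: dict[str, str] = {}
    for cid in matrix.index:
        if reason[cid]:
            continue
        mol = structures.get(cid) if structures else None
        if mol is None:
            continue
        key = _canonical_parent(mol)
        if key in seen:
            reason[cid] = "duplicate"
        else:
            seen[key] = cid

    keep = reason == ""
    if not keep.any():
        raise PipelineError("no compounds left to screen after exclusions")
    predicted = pd.Series(np.nan, index=matrix.index)
    predicted[keep] = model.predict(matrix[keep])
    predictions = pd.DataFrame({"predicted": predicted, "excluded_reason": reason})
    result = ScreenResult(
        library=library_tag or table.provenance,
        n_input=len(table),
        n_excluded_incalculable=int((reason == "incalculable").sum()),
        n_excluded_quaternary=int((reason == "quaternary_nitrogen").sum()),
        n_excluded_duplicates=int((reason == "duplicate").sum()),
        n_screened=int(keep.sum()),
        n_predicted_active=int((predicted == 1).sum()),
        predictions=predictions,
    )
    logger.info(
        "%s: %d in, %d incalculable, %d quaternary, %d duplicates, %d screened, %d active",
        result.library, result.n_input, result.n_excluded_incalculable,
        result.n_excluded_quaternary, result.n_excluded_duplicates,
        result.n_screened, result.n_predicted_active,
    )
    return result


# --- enrichment --------------------------------------------------------------

#: character count of an ATC code prefix per classification level
_ATC_LEVEL_CHARS = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}


def groups_from_atc(table: CompoundTable, level: int = 2) -> dict[str, list[str]]:
    """Group memberships from ATC codes truncated to a classification level.

    Level 2 (the default) is the therapeutic main group, e.g. ``N05`` from
    ``N05AB02``. Compounds without ATC codes are omitted.
    """
    if level not in _ATC_LEVEL_CHARS:
        raise ValidationError(f"ATC level must be 1..5, got {level}")
    n_chars = _ATC_LEVEL_CHARS[level]
    out: dict[str, list[str]] = {}
    for rec in table:
        codes = sorted({c[:n_chars] for c in rec.atc_codes if len(c) >= n_chars})
        if codes:
            out[rec.id] = codes
    return out


def group_enrichment(
    calls: Mapping[str, int],
    groups: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
) -> tuple[list[EnrichmentRow], float]:
    """Per-group enrichment of predicted actives (one-sided Fisher + BH).

    ``calls`` maps compound id to 0/1; ``groups`` maps compound id to its
    group memberships (a compound in several groups is counted once per
    group). For each group a 2x2 table (in-group vs rest x active vs
    inactive) is tested one-sided for over-representation via the
    hypergeometric tail; p-values are Benjamini-Hochberg adjusted across
    groups. The returned global p comes from a chi-square contingency test
    over the group x class table (an approximation to a global exact test).
    """
    by_group: dict[str, list[str]] = {}
    for cid, gs in groups.items():
        if cid not in calls:
            continue
        for g in set(gs):
            by_group.setdefault(g, []).append(cid)
    by_group = {g: ms for g, ms in by_group.items() if ms}
    if len(by_group) < 2:
        raise ValidationError("enrichment requires >= 2 non-empty groups")
    total_active = sum(calls[c] for g in by_group.values() for c in g)
    total = sum(len(g) for g in by_group.values())
    rows = []
    for g in sorted(by_group):
        members = by_group[g]
        in_active = sum(calls[c] for c in members)
        in_total = len(members)
        out_active = total_active - in_active
        out_total = total - in_total
        # one-sided (over-representation): P[X >= in_active], X ~ Hypergeom
        p = float(stats.hypergeom.sf(in_active - 1, total, total_active, in_total))
        rows.append(
            EnrichmentRow(
                group=g,
                in_active=in_active,
                in_inactive=in_total - in_active,
                out_active=out_active,
                out_inactive=out_total - out_active,
                fisher_p=p,
            )
        )
    reject, adjusted, _, _ = multipletests([r.fisher_p for r in rows], alpha=alpha, method="fdr_bh")
    for row, adj, rej in zip(rows, adjusted, reject):
        row.adjusted_p = float(adj)
        row.enriched = bool(rej)
    counts = np.array([[r.in_active, r.in_inactive] for r in rows])
    counts = counts[counts.sum(axis=1) > 0]
    if counts.shape[0] >= 2 and counts.sum(axis=0).min() > 0:
        global_p = float(stats.chi2_contingency(counts)[1])
    else:
        global_p = float("nan")
    return rows, global_p


# --- Rule-of-Five / logBB associations --------------------------------------

@dataclass
class RofAssociation:
    table: np.ndarray  # rows: violation no/yes; cols: class 0/1
    chi_square: float
    p: float
    violation_pct_active: float
    violation_pct_inactive: float


def rof_association(
    labels: Sequence[int], violated: Sequence[bool], correction: bool = False
) -> RofAssociation:
    """Chi-square association between activity class and Rule-of-Five
    violation, with per-class violation percentages.

    ``correction=False`` (default) is the plain Pearson statistic; set True
    for the Yates continuity-corrected variant."""
    y = np.asarray(labels).astype(int)
    v = np.asarray(violated).astype(bool)
    if y.size != v.size:
        raise ValidationError("labels and violations must align")
    table = np.array(
        [
            [int(((~v) & (y == 0)).sum()), int(((~v) & (y == 1)).sum())],
            [int((v & (y == 0)).sum()), int((v & (y == 1)).sum())],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("rof_association: zero margin in contingency table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return RofAssociation(
        table=table,
        chi_square=float(chi2),
        p=float(p),
        violation_pct_active=100.0 * table[1, 1] / table[:, 1].sum(),
        violation_pct_inactive=100.0 * table[1, 0] / table[:, 0].sum(),
    )


@dataclass
class LogBBAssociation:
    crosstab: np.ndarray  # rows: logBB < 0 / >= 0; cols: class 0/1
    n: int
    violations: list[str]  # active compounds with logBB < 0


def logbb_association(
    labels: Mapping[str, int], logbb: Mapping[str, float]
) -> LogBBAssociation:
    """Cross-tabulate activity against blood-brain-barrier permeation.

    Functional ASM inhibition is expected only for compounds that cross the
    BBB (logBB >= 0); any active compound with logBB < 0 is listed as a
    violation of that observation (reported, not fatal).
    """
    common = [c for c in labels if c in logbb]
    if not common:
        logger.warning("logbb_association: no compounds with logBB data")
        return LogBBAssociation(crosstab=np.zeros((2, 2), dtype=int), n=0, violations=[])
    tab = np.zeros((2, 2), dtype=int)
    violations = []
    for cid in common:
        row = 1 if logbb[cid] >= 0 else 0
        col = labels[cid]
        tab[row, col] += 1
        if col == 1 and logbb[cid] < 0:
            violations.append(cid)
    if violations:
        logger.warning("active compounds with logBB < 0: %s", violations)
    return LogBBAssociation(crosstab=tab, n=len(common), violations=sorted(violations))
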