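"""Structural diversity via typed-triangle 2D pharmacophore fingerprints.

Each heavy atom is assigned zero or more pharmacophore types (donor,
acceptor, cation, anion, aromatic, hydrophobe) by SMARTS rules documented
below. Every triple of typed atoms yields a triangle key: the three types
together with the pairwise topological (bond-path) distances binned into
{1, 2, 3, 4-5, 6-8, 9+}. Keys are canonicalized over vertex orderings, so
the fingerprint is invariant to atom numbering. Molecules with fewer than
three typed atoms fall back to pair and single-type keys.

Similarity between fingerprints is the Tanimoto coefficient on key sets;
compound sets are clustered by hierarchical complete-linkage agglomeration
on 1 - Tanimoto, cut at a similarity threshold (default 0.85). Complete
linkage guarantees that every within-cluster pair meets the threshold.
The *relative structural diversity* of a set is the number of clusters at
the cutoff divided by the number of compounds: 1/N for N copies of one
scaffold, 1.0 when every compound is its own cluster.

The triangle-key dialect here is an open reimplementation; absolute
diversity values are comparable only within one dialect, so analyses
should compare div_rel across sets, not against values produced by other
fingerprint software.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem

from .errors import ValidationError

SCHEME = "tgt-open-1"

#: topological distance bins: upper bounds, last bin open-ended
_BIN_EDGES = (1, 2, 3, 5, 8)

_TYPE_SMARTS = {
    "D": "[$([#7;!H0;+0]),$([#8;H1;+0]),$([#16;H1;+0])]",  # H-bond donor
    "A": "[$([#8;+0]),$([#7;+0;!$([#7][#6,#16]=[O,S])])]",  # H-bond acceptor
    "P": "[$([#7;+]),$([NX3;+0;!a;!$([N][C,S]=[O,S,N])])]",  # cation / protonizable N
    "N": "[$([O,S;-]),$([OX2H1][CX3]=O),$([OX2H1]S(=O)=O)]",  # anion / acidic O
    "R": "[a]",  # aromatic
    "H": "[$([C;!$(C~[N,O,S])]),F,Cl,Br,I]",  # hydrophobe
}
_TYPE_PATTERNS = {t: Chem.MolFromSmarts(s) for t, s in _TYPE_SMARTS.items()}


def _dist_bin(d: int) -> int:
    for i, edge in enumerate(_BIN_EDGES):
        if d <= edge:
            return i
    return len(_BIN_EDGES)


@dataclass(frozen=True)
class Fingerprint:
    """Hashed triangle-key set for one compound."""

    id: str
    keys: frozenset
    scheme: str = SCHEME

    def __len__(self) -> int:
        return len(self.keys)


def _typed_atoms(mol: Chem.Mol) -> list[tuple[int, str]]:
    typed = []
    for tname, patt in _TYPE_PATTERNS.items():
        for match in mol.GetSubstructMatches(patt, uniquify=True):
            typed.append((match[0], tname))
    return sorted(set(typed))


def _canonical_triangle(v: Sequence[tuple[str, int]]) -> tuple:
    # v = [(type_i, opposite_edge_bin_i)]; minimise over rotations+reflections
    perms = [
        (v[0], v[1], v[2]), (v[1], v[2], v[0]), (v[2], v[0], v[1]),
        (v[0], v[2], v[1]), (v[2], v[1], v[0]), (v[1], v[0], v[2]),
    ]
    return min(perms)


def triangle_fingerprint(mol: Chem.Mol, id: str = "") -> Fingerprint:
    """Typed-triangle fingerprint of a sanitized molecular graph.

    Degenerate graphs (< 3 typed atoms) contribute pair keys
    ``("pair", t1, t2, bin)`` and single keys ``("single", t)`` instead of
    triangles, so every non-empty molecule has a non-empty fingerprint.
    """
    if mol is None:
        raise ValidationError("triangle_fingerprint requires a molecule")
    if mol.GetNumAtoms() == 0:
        raise ValidationError("empty molecular graph")
    typed = _typed_atoms(mol)
    keys: set = set()
    if len(typed) >= 3:
        dmat = Chem.GetDistanceMatrix(mol)
        for (a1, t1), (a2, t2), (a3, t3) in combinations(typed, 3):
            d12 = _dist_bin(int(dmat[a1][a2])) if a1 != a2 else -1
            d13 = _dist_bin(int(dmat[a1][a3])) if a1 != a3 else -1
            d23 = _dist_bin(int(dmat[a2][a3])) if a2 != a3 else -1
            keys.add(("tri",) + _canonical_triangle(((t1, d23), (t2, d13), (t3, d12))))
    if not keys and len(typed) >= 2:
        dmat = Chem.GetDistanceMatrix(mol)
        for (a1, t1), (a2, t2) in combinations(typed, 2):
            d = _dist_bin(int(dmat[a1][a2])) if a1 != a2 else -1
            keys.add(("pair",) + tuple(sorted((t1, t2))) + (d,))
    if not keys:
        for _, t in typed:
            keys.add(("single", t))
    if not keys:
        keys.add(("single", "untyped"))
    return Fingerprint(id=id, keys=frozenset(keys))


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto set similarity |A∩B| / |A∪B| in [0, 1].

    Two empty fingerprints are defined as identical (similarity 1).
    """
    if a.scheme != b.scheme:
        raise ValidationError(f"fingerprint scheme mismatch: {a.scheme} vs {b.scheme}")
    union = len(a.keys | b.keys)
    if union == 0:
        return 1.0
    return len(a.keys & b.keys) / union


@dataclass
class ClusterSolution:
    """Hard cluster assignment at a similarity cutoff."""

    assignment: dict[str, int]
    n_clusters: int
    similarity_cutoff: float


def cluster_at(
    fingerprints: Sequence[Fingerprint],
    similarity_cutoff: float = 0.85,
    linkage: str = "complete",
) -> ClusterSolution:
    """Hierarchical agglomeration on 1 - Tanimoto, cut at the cutoff.

    With the default complete linkage, merging stops once the closest pair
    of clusters is farther apart than ``1 - similarity_cutoff``, so all
    within-cluster pairwise similarities are >= the cutoff (this is the
    guarantee the "clusters at a similarity" reading needs). ``single`` and
    ``average`` linkage are available for comparison; they do not carry
    that guarantee. Merge ties are broken deterministically by the smallest
    lexicographic member id, making the solution invariant to the input
    order.
    """
    if linkage not in ("complete", "single", "average"):
        raise ValidationError(f"unknown linkage {linkage!r}")
    if not fingerprints:
        raise ValidationError("cluster_at requires at least one fingerprint")
    order = sorted(range(len(fingerprints)), key=lambda i: fingerprints[i].id)
    fps = [fingerprints[i] for i in order]
    n = len(fps)
    dist = np.ones((n, n))
    for i in range(n):
        dist[i, i] = 0.0
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = 1.0 - tanimoto(fps[i], fps[j])
    threshold = 1.0 - similarity_cutoff
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    d = dist.copy()
    np.fill_diagonal(d, np.inf)
    active = sorted(clusters)
    while len(active) > 1:
        sub = d[np.ix_(active, active)]
        mval = sub.min()
        if mval > threshold:
            break
        ties = np.argwhere(np.isclose(sub, mval))
        # deterministic tie-break: smallest lexicographic member id of the pair
        def pair_key(pair):
            i, j = active[pair[0]], active[pair[1]]
            ids = sorted(fps[k].id for k in clusters[i] + clusters[j])
            return ids
        pi, pj = min((tuple(t) for t in ties if t[0] < t[1]), key=pair_key)
        ci, cj = active[pi], active[pj]
        ni, nj = len(clusters[ci]), len(clusters[cj])
        clusters[ci].extend(clusters.pop(cj))
        if linkage == "complete":
            d[ci, :] = np.maximum(d[ci, :], d[cj, :])
        elif linkage == "single":
            d[ci, :] = np.minimum(d[ci, :], d[cj, :])
        else:  # size-weighted average linkage
            finite = np.isfinite(d[ci, :]) & np.isfinite(d[cj, :])
            d[ci, finite] = (ni * d[ci, finite] + nj * d[cj, finite]) / (ni + nj)
        d[:, ci] = d[ci, :]
        d[ci, ci] = np.inf
        d[cj, :] = np.inf
        d[:, cj] = np.inf
        active = sorted(clusters)
    assignment = {}
    for label, (_, members) in enumerate(sorted(clusters.items())):
        for m in members:
            assignment[fps[m].id] = label
    return ClusterSolution(assignment, len(clusters), similarity_cutoff)


def div_rel(solution: ClusterSolution, n_compounds: int) -> float:
    """Relative structural diversity: clusters at the cutoff / compounds."""
    if n_compounds < 1:
        raise ValidationError("n_compounds must be >= 1")
    return solution.n_clusters / n_compounds


def diversity_of(
    molecules: Mapping[str, Chem.Mol], similarity_cutoff: float = 0.85
) -> tuple[float, ClusterSolution]:
    """Convenience: fingerprints -> clustering -> div_rel for a compound set."""
    fps = [triangle_fingerprint(mol, id=key) for key, mol in molecules.items()]
    solution = cluster_at(fps, similarity_cutoff)
    return div_rel(solution, len(fps)), solution


def save_fingerprints(fingerprints: Sequence[Fingerprint], path) -> None:
    """Cache fingerprints as a sorted plain-text key-set file (one line per
    compound: id, tab, comma-separated repr keys)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#scheme={SCHEME}\n")
        for f in sorted(fingerprints, key=lambda f: f.id):
            keys = ";".join(sorted(repr(k) for k in f.keys))
            fh.write(f"{f.id}\t{keys}\n")


def load_fingerprints(path) -> list[Fingerprint]:
    from ast import literal_eval

    out = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        scheme = header.removeprefix("#scheme=") if header.startswith("#scheme=") else SCHEME
        for line in fh:
            cid, _, raw = line.rstrip("\n").partition("\t")
            keys = frozenset(literal_eval(k) for k in raw.split(";") if k)
            out.append(Fingerprint(id=cid, keys=keys, scheme=scheme))
    return out
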