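"""Chemical redundancy filtering.

Morgan (hashed circular, radius 2) fingerprints, pairwise Tanimoto
similarity, Ward agglomerative clustering cut at a minimum similarity, per
cluster representative selection by composite score, and structural
comparison of candidates against clinical-trial drugs.

Ward linkage is applied to the 1 - Tanimoto distance matrix even though that
distance is not Euclidean, mirroring the common chemoinformatics practice;
the dendrogram is cut at height 1 - min_similarity on the merge-height
(cophenetic) scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


@dataclass
class CompoundRecord:
    id: str
    smiles: str
    fingerprint: Optional[np.ndarray] = None
    score: Optional[float] = None
    is_trial_drug: bool = False


def canonical_smiles(smiles: str) -> str:
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def fingerprint(smiles: str, n_bits: int = 2048, radius: int = 2) -> np.ndarray:
    """Hashed circular (Morgan) substructure fingerprint as a 0/1 vector."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return np.asarray(gen.GetFingerprintAsNumPy(mol), dtype=np.uint8)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a AND b| / |a OR b|; defined as 1 when both vectors are all-zero."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return np.count_nonzero(a & b) / union


def similarity_matrix(fingerprints: Sequence[np.ndarray]) -> np.ndarray:
    n = len(fingerprints)
    sim = np.ones((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = tanimoto(fingerprints[i], fingerprints[j])
    return sim


def validate_similarity(sim: np.ndarray) -> np.ndarray:
    sim = np.asarray(sim, dtype=float)
    if sim.ndim != 2 or sim.shape[0] != sim.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(sim, sim.T, atol=1e-12):
        raise ValueError("similarity matrix must be symmetric")
    if not np.allclose(np.diag(sim), 1.0, atol=1e-12):
        raise ValueError("similarity matrix diagonal must be 1")
    if sim.min() < -1e-12 or sim.max() > 1 + 1e-12:
        raise ValueError("similarities must lie in [0, 1]")
    return sim


@dataclass
class ClusterAssignment:
    """Flat clusters over a compound set.

    Cluster ids are 1-based and ordered by each cluster's lexicographically
    smallest member id, making the assignment invariant to input order.
    """

    labels: Dict[str, int]
    representatives: Dict[int, str] = field(default_factory=dict)
    contains_trial_drug: Dict[int, bool] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def members(self, cluster: int) -> List[str]:
        return sorted(c for c, k in self.labels.items() if k == cluster)

    def clusters(self) -> List[List[str]]:
        return [self.members(k) for k in sorted(set(self.labels.values()))]


def _canonical_labels(ids: Sequence[str], raw: np.ndarray) -> Dict[str, int]:
    # order clusters by their lexicographically smallest member
    groups: Dict[int, List[str]] = {}
    for cid, raw_label in zip(ids, raw):
        groups.setdefault(int(raw_label), []).append(cid)
    ordered = sorted(groups.values(), key=lambda g: min(g))
    labels: Dict[str, int] = {}
    for new_label, group in enumerate(ordered, start=1):
        for cid in group:
            labels[cid] = new_label
    return labels


def ward_cluster(
    sim: np.ndarray,
    ids: Sequence[str],
    min_similarity: float = 0.80,
) -> ClusterAssignment:
    """Ward agglomeration on d = 1 - similarity, cut at d = 1 - min_similarity."""
    sim = validate_similarity(sim)
    n = sim.shape[0]
    if n == 0:
        raise ValueError("cannot cluster zero compounds")
    if len(ids) != n:
        raise ValueError("ids length must match similarity matrix")
    if not 0.0 < min_similarity < 1.0:
        raise ValueError("min_similarity must lie strictly inside (0, 1)")
    if n == 1:
        return ClusterAssignment({str(ids[0]): 1})
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="ward")
    raw = fcluster(Z, t=1.0 - min_similarity, criterion="distance")
    return ClusterAssignment(_canonical_labels([str(i) for i in ids], raw))


def select_representatives(
    assignment: ClusterAssignment, scores: Mapping[str, float]
) -> ClusterAssignment:
    """Per cluster, the highest-scoring member; missing scores count as -inf.

    Ties break to the lexicographically smallest compound id.
    """
    reps: Dict[int, str] = {}
    for k in sorted(set(assignment.labels.values())):
        members = assignment.members(k)
        reps[k] = max(
            members,
            key=lambda c: (scores.get(c, float("-inf")), _NegStr(c)),
        )
    assignment.representatives = reps
    return assignment


class _NegStr(str):
    """Reverses string comparison so max() prefers the smallest id on ties."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def annotate_trial_overlap(
    candidates: Sequence[CompoundRecord],
    trial_drugs: Sequence[CompoundRecord],
    min_similarity: float = 0.80,
    n_bits: int = 2048,
) -> pd.DataFrame:
    """Joint clustering of candidates with clinical-trial drugs.

    status per candidate: ``in_trial`` if a trial drug with identical
    canonical structure exists, ``trial_similar`` if its cluster contains at
    least one trial drug, else ``structurally_specific``.
    """
    records = list(candidates) + list(trial_drugs)
    if len({r.id for r in records}) != len(records):
        raise ValueError("compound ids must be unique across candidates and trials")
    for r in records:
        if r.fingerprint is None:
            r.fingerprint = fingerprint(r.smiles, n_bits=n_bits)
    sim = similarity_matrix([r.fingerprint for r in records])
    assignment = ward_cluster(sim, [r.id for r in records], min_similarity)
    trial_canon = {canonical_smiles(t.smiles) for t in trial_drugs}
    trial_ids = {t.id for t in trial_drugs}
    cluster_has_trial = {
        k: any(m in trial_ids for m in assignment.members(k))
        for k in sorted(set(assignment.labels.values()))
    }
    assignment.contains_trial_drug = cluster_has_trial
    rows = []
    for c in candidates:
        k = assignment.labels[c.id]
        if canonical_smiles(c.smiles) in trial_canon:
            status = "in_trial"
        elif cluster_has_trial[k]:
            status = "trial_similar"
        else:
            status = "structurally_specific"
        rows.append((c.id, k, status))
    return pd.DataFrame(rows, columns=["id", "cluster", "status"])
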