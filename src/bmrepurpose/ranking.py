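"""Consensus ranking and composite (CoDReS-style) scoring.

Multiple signature-reversal sources each contribute an ordered drug list
(best reverser first).  The lists are truncated to a common cutoff, merged
into a consensus prior that weights the occurrence fraction and the average
rank, and the prior is combined with functional and structural components
into a weighted composite score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .signatures import SignedGeneSet


@dataclass(frozen=True)
class SourceRanking:
    """One source's ordered drug list: ranks are exactly 1..n, drugs unique."""

    source: str
    entries: Tuple[Tuple[str, int], ...]

    def __post_init__(self) -> None:
        drugs = [d for d, _ in self.entries]
        if len(set(drugs)) != len(drugs):
            raise ValueError(f"source {self.source!r}: duplicate drugs")
        ranks = sorted(r for _, r in self.entries)
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError(
                f"source {self.source!r}: ranks must be exactly 1..n "
                f"with no gaps or duplicates (got {ranks})"
            )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def drugs(self) -> List[str]:
        return [d for d, _ in sorted(self.entries, key=lambda e: e[1])]


def truncate_ranking(r: SourceRanking, cutoff: int) -> SourceRanking:
    """Keep entries with rank <= cutoff; ranks are left unchanged."""
    kept = tuple((d, k) for d, k in r.entries if k <= cutoff)
    return SourceRanking(r.source, kept)


def consensus_prior(
    rankings: Sequence[SourceRanking], cutoff: int = 50
) -> pd.DataFrame:
    """Aggregate source rankings into a prior score.

    prior(drug) = (k / K) * (1 - (mean_rank - 1) / cutoff) where k is the
    number of sources listing the drug and mean_rank the average of its ranks
    there.  A drug ranked first in every source attains prior = 1.  Output is
    sorted by prior descending, ties broken lexicographically by drug id.
    """
    if len(rankings) == 0:
        raise ValueError("need at least one source ranking")
    K = len(rankings)
    ranks: Dict[str, List[int]] = {}
    for r in rankings:
        for drug, rank in r.entries:
            if rank > cutoff:
                raise ValueError(
                    f"source {r.source!r}: rank {rank} exceeds cutoff {cutoff}; "
                    "truncate first"
                )
            ranks.setdefault(drug, []).append(rank)
    rows = []
    for drug in sorted(ranks):
        k = len(ranks[drug])
        mean_rank = sum(ranks[drug]) / k
        prior = (k / K) * (1.0 - (mean_rank - 1.0) / cutoff)
        rows.append((drug, k, mean_rank, prior))
    frame = pd.DataFrame(rows, columns=["drug", "k", "mean_rank", "prior"])
    frame = frame.sort_values(
        ["prior", "drug"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return frame


def functional_score(drug_genes: Set[str], disease: SignedGeneSet) -> float:
    """Target-overlap precision: |targets in disease set| / |targets|."""
    if len(drug_genes) == 0:
        raise ValueError("drug gene set is empty")
    return len(drug_genes & disease.genes) / len(drug_genes)


def structural_score(smiles: str) -> float:
    """Druglikeness rule fraction over the four Lipinski criteria.

    Counts satisfied rules among MW <= 500, logP <= 5, H-bond donors <= 5,
    H-bond acceptors <= 10, divided by 4.
    """
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors, Lipinski

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    rules = (
        Descriptors.MolWt(mol) <= 500,
        Crippen.MolLogP(mol) <= 5,
        Lipinski.NumHDonors(mol) <= 5,
        Lipinski.NumHAcceptors(mol) <= 10,
    )
    return sum(rules) / 4.0


def codres_score(
    a_s: float,
    f_s: float,
    st_s: float,
    weights: Tuple[float, float, float] = (0.45, 0.45, 0.1),
) -> float:
    """Weighted composite: w_aS * aS + w_FS * FS + w_StS * StS."""
    for name, v in (("aS", a_s), ("FS", f_s), ("StS", st_s)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} component must lie in [0, 1], got {v}")
    w_as, w_fs, w_sts = weights
    if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError(f"weights must be non-negative and sum to 1: {weights}")
    return w_as * a_s + w_fs * f_s + w_sts * st_s


def score_drugs(
    prior: pd.DataFrame,
    drug_genes: Optional[Mapping[str, Set[str]]] = None,
    disease: Optional[SignedGeneSet] = None,
    smiles: Optional[Mapping[str, str]] = None,
    weights: Tuple[float, float, float] = (0.45, 0.45, 0.1),
) -> pd.DataFrame:
    """Compose the scored drug table (aS, FS, StS, composite).

    aS is the consensus prior.  FS falls back to 0 for drugs without a target
    set, StS to 0 for drugs without a structure; both are stated components,
    pluggable by supplying the corresponding mapping.
    """
    rows = []
    for rec in prior.itertuples(index=False):
        a_s = float(rec.prior)
        f_s = 0.0
        if drug_genes is not None and disease is not None and rec.drug in drug_genes:
            f_s = functional_score(drug_genes[rec.drug], disease)
        st_s = 0.0
        if smiles is not None and rec.drug in smiles:
            st_s = structural_score(smiles[rec.drug])
        rows.append(
            (rec.drug, rec.k, rec.mean_rank, a_s, f_s, st_s,
             codres_score(a_s, f_s, st_s, weights))
        )
    frame = pd.DataFrame(
        rows, columns=["drug", "k", "mean_rank", "aS", "FS", "StS", "composite"]
    )
    return frame.sort_values(
        ["composite", "drug"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
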