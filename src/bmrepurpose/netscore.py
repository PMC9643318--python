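"""Network criticality scoring of compounds against signed disease gene sets.

Each compound carries a signed perturbation signature (the direction it
drives each of its target genes).  Against a reference signed gene set
(the bone-metastasis DEG signature S_BM or the GSEA-derived M2 macrophage
set S_GSEA) every shared gene contributes one bipartite edge, labeled
``reverse`` when the compound drives the gene opposite to the disease and
``mimic`` when it drives it the same way.  The raw criticality of a compound
is (Degree_reverse - Degree_mimic) / |S_i intersect S_ref|; raw scores are
normalized into [-1, 1] by dividing by the absolute maximum, and the final
score combines both references:

    DR_i = omega_bm * Score_BM_i + omega_m2 * Score_M2_i
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import pandas as pd

from .signatures import SignedGeneSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PerturbationSignature:
    """Per-compound regulated genes with the direction the compound drives."""

    compound: str
    regulated: Mapping[str, int]

    def __post_init__(self) -> None:
        bad = {g: d for g, d in self.regulated.items() if d not in (1, -1)}
        if bad:
            raise ValueError(f"{self.compound}: directions must be +1/-1: {bad}")

    def flipped(self) -> "PerturbationSignature":
        return PerturbationSignature(
            self.compound, {g: -d for g, d in self.regulated.items()}
        )


def build_bipartite(
    signatures: Sequence[PerturbationSignature], reference: SignedGeneSet
) -> pd.DataFrame:
    """Edge list (compound, interaction, gene) over S_i intersect S_ref."""
    if len(reference) == 0:
        raise ValueError("reference gene set is empty")
    rows = []
    for sig in signatures:
        for gene in sorted(sig.regulated):
            if gene not in reference:
                continue
            kind = (
                "reverse"
                if sig.regulated[gene] == -reference.directions[gene]
                else "mimic"
            )
            rows.append((sig.compound, kind, gene))
    return pd.DataFrame(rows, columns=["compound", "interaction", "gene"])


def degree_split(
    sig: PerturbationSignature, reference: SignedGeneSet
) -> Tuple[int, int]:
    """(Degree_reverse, Degree_mimic) over the shared gene set."""
    rev = mim = 0
    for gene, d in sig.regulated.items():
        if gene not in reference:
            continue
        if d == -reference.directions[gene]:
            rev += 1
        else:
            mim += 1
    return rev, mim


def raw_score(sig: PerturbationSignature, reference: SignedGeneSet) -> float:
    """(Degree_reverse - Degree_mimic) / |shared genes|; 0 on empty overlap."""
    rev, mim = degree_split(sig, reference)
    shared = rev + mim
    if shared == 0:
        logger.warning(
            "compound %s shares no genes with reference %s; raw score 0",
            sig.compound,
            reference.label or "<unlabeled>",
        )
        return 0.0
    return (rev - mim) / shared


def normalize_scores(raw: Mapping[str, float]) -> Dict[str, float]:
    """Divide by the absolute maximum so scores span [-1, 1]; all-zero stays 0."""
    if len(raw) == 0:
        raise ValueError("no compounds to normalize")
    m = max(abs(v) for v in raw.values())
    if m == 0:
        return {c: 0.0 for c in raw}
    return {c: v / m for c, v in raw.items()}


def dr_score(
    score_bm: float, score_m2: float, omega_bm: float = 0.3, omega_m2: float = 0.7
) -> float:
    if abs(omega_bm + omega_m2 - 1.0) > 1e-9:
        raise ValueError("omega_bm + omega_m2 must equal 1")
    return omega_bm * score_bm + omega_m2 * score_m2


def score_compounds(
    signatures: Sequence[PerturbationSignature],
    bm: SignedGeneSet,
    m2: SignedGeneSet,
    omega_bm: float = 0.3,
    omega_m2: float = 0.7,
    m2_norm_by_bm: bool = False,
) -> pd.DataFrame:
    """Full per-compound score table, sorted by DR descending.

    ``m2_norm_by_bm`` switches the M2 normalization denominator from its own
    max |raw| to the BM one.
    """
    if len({s.compound for s in signatures}) != len(signatures):
        raise ValueError("compound ids must be unique")
    rows = {}
    for sig in signatures:
        rev_bm, mim_bm = degree_split(sig, bm)
        rev_m2, mim_m2 = degree_split(sig, m2)
        rows[sig.compound] = {
            "deg_rev_bm": rev_bm,
            "deg_mim_bm": mim_bm,
            "raw_bm": raw_score(sig, bm),
            "deg_rev_m2": rev_m2,
            "deg_mim_m2": mim_m2,
            "raw_m2": raw_score(sig, m2),
        }
    score_bm = normalize_scores({c: r["raw_bm"] for c, r in rows.items()})
    raw_m2 = {c: r["raw_m2"] for c, r in rows.items()}
    if m2_norm_by_bm:
        denom = max(abs(r["raw_bm"]) for r in rows.values())
        score_m2 = (
            {c: v / denom for c, v in raw_m2.items()}
            if denom > 0
            else {c: 0.0 for c in raw_m2}
        )
    else:
        score_m2 = normalize_scores(raw_m2)
    records = []
    for c in sorted(rows):
        r = rows[c]
        dr = dr_score(score_bm[c], score_m2[c], omega_bm, omega_m2)
        records.append(
            (c, r["deg_rev_bm"], r["deg_mim_bm"], r["raw_bm"], score_bm[c],
             r["deg_rev_m2"], r["deg_mim_m2"], r["raw_m2"], score_m2[c], dr)
        )
    frame = pd.DataFrame(
        records,
        columns=[
            "compound", "deg_rev_bm", "deg_mim_bm", "raw_bm", "score_bm",
            "deg_rev_m2", "deg_mim_m2", "raw_m2", "score_m2", "dr",
        ],
    )
    return frame.sort_values(
        ["dr", "compound"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
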