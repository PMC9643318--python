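"""Disease signature selection.

Defines the signed disease gene sets that feed the scoring stages: the
differential-expression filter (adjusted p and |log2FC| thresholds, both
strict), the gene/cell-type-abundance Pearson screen, and the multi-method
consensus intersection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

DEG_COLUMNS = ("gene", "log2fc", "adj_p")


def validate_deg_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the DEG-table contract: unique genes, adj_p in [0, 1]."""
    missing = [c for c in DEG_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"DEG table missing columns: {', '.join(missing)}")
    dup = table["gene"][table["gene"].duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate genes in DEG table: {', '.join(map(str, dup))}")
    bad = table[(table["adj_p"] < 0) | (table["adj_p"] > 1)]
    if len(bad):
        raise ValueError(
            f"adj_p outside [0, 1] for genes: {', '.join(bad['gene'].astype(str))}"
        )
    return table


@dataclass
class SignedGeneSet:
    """A gene set with per-gene direction (+1 up, -1 down in the condition).

    Carries the disease (bone-metastasis) signature, the GSEA-derived M2
    macrophage set, or a compound perturbation target set.
    """

    directions: Dict[str, int]
    magnitudes: Optional[Dict[str, float]] = None
    label: str = ""

    def __post_init__(self) -> None:
        bad = {g: d for g, d in self.directions.items() if d not in (1, -1)}
        if bad:
            raise ValueError(f"directions must be +1/-1, got {bad}")

    def __len__(self) -> int:
        return len(self.directions)

    def __contains__(self, gene: str) -> bool:
        return gene in self.directions

    @property
    def genes(self) -> Set[str]:
        return set(self.directions)

    @property
    def counts(self) -> Tuple[int, int, int]:
        """(total, up, down)."""
        up = sum(1 for d in self.directions.values() if d == 1)
        return len(self.directions), up, len(self.directions) - up

    def flipped(self) -> "SignedGeneSet":
        return SignedGeneSet(
            {g: -d for g, d in self.directions.items()},
            magnitudes=dict(self.magnitudes) if self.magnitudes else None,
            label=self.label,
        )

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.directions)
        frame = pd.DataFrame(
            {
                "gene": genes,
                "direction": [self.directions[g] for g in genes],
            }
        )
        if self.magnitudes is not None:
            frame["log2fc"] = [self.magnitudes.get(g, np.nan) for g in genes]
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label: str = "") -> "SignedGeneSet":
        directions = {
            str(g): int(d) for g, d in zip(frame["gene"], frame["direction"])
        }
        magnitudes = None
        if "log2fc" in frame.columns:
            magnitudes = {
                str(g): float(v)
                for g, v in zip(frame["gene"], frame["log2fc"])
                if np.isfinite(v)
            }
        return cls(directions, magnitudes=magnitudes, label=label)


def filter_degs(
    table: pd.DataFrame,
    p_thr: float = 0.05,
    lfc_thr: float = 1.0,
    label: str = "BM",
) -> SignedGeneSet:
    """Keep genes with adj_p < p_thr and |log2fc| > lfc_thr (both strict).

    Direction is sign(log2fc).  Counts (total, up, down) are available on the
    returned set via :attr:`SignedGeneSet.counts`.
    """
    validate_deg_table(table)
    keep = table[(table["adj_p"] < p_thr) & (table["log2fc"].abs() > lfc_thr)]
    directions = {
        str(g): (1 if fc > 0 else -1) for g, fc in zip(keep["gene"], keep["log2fc"])
    }
    magnitudes = {str(g): float(fc) for g, fc in zip(keep["gene"], keep["log2fc"])}
    return SignedGeneSet(directions, magnitudes=magnitudes, label=label)


def correlate_gene_abundance(
    expr: Sequence[float], abundance: Sequence[float]
) -> Tuple[float, float]:
    """Pearson r between per-sample expression and cell-type abundance.

    p is the two-sided t-transform of r with n-2 degrees of freedom.  Zero
    variance in either vector is an error, never a silent NaN.
    """
    x = np.asarray(expr, dtype=float)
    y = np.asarray(abundance, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("expr and abundance must be 1-D and the same length")
    if x.size < 3:
        raise ValueError("need at least 3 paired samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: Pearson correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def select_associated_genes(
    genes: Iterable[str],
    correlations: Mapping[str, Tuple[float, float]],
    r_thr: float = 0.3,
    p_thr: float = 0.05,
    mode: str = "signed",
) -> Set[str]:
    """Keep genes whose abundance correlation clears the screen.

    mode="signed" (default) keeps r > r_thr; mode="absolute" keeps
    |r| > r_thr.  Both require p < p_thr.  All inequalities strict.
    """
    if mode not in ("signed", "absolute"):
        raise ValueError(f"mode must be 'signed' or 'absolute', got {mode!r}")
    out: Set[str] = set()
    for gene in genes:
        if gene not in correlations:
            raise KeyError(f"no correlation record for gene {gene!r}")
        r, p = correlations[gene]
        stat = abs(r) if mode == "absolute" else r
        if stat > r_thr and p < p_thr:
            out.add(gene)
    return out


def consensus_intersect(
    sets: Sequence[Set[str]], min_support: Optional[int] = None
) -> Set[str]:
    """Genes present in at least ``min_support`` of the sets (default: all)."""
    if len(sets) == 0:
        raise ValueError("need at least one gene set")
    if min_support is None:
        min_support = len(sets)
    if not 1 <= min_support <= len(sets):
        raise ValueError("min_support must be between 1 and the number of sets")
    support: Dict[str, int] = {}
    for s in sets:
        for g in s:
            support[g] = support.get(g, 0) + 1
    return {g for g, n in support.items() if n >= min_support}
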