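"""Seeded synthetic-data generators.

Every downstream stage of the pipeline is exercised on data produced here:
DEG tables with a planted differential fraction, partially overlapping
ranked drug lists drawn around a latent efficacy ordering, compound
perturbation signatures with planted reversers, a SMILES library enumerated
from a packaged fragment grammar (with recorded near-duplicate pairs),
IC50 response matrices with planted sensitive drugs and missing-at-random
entries, and particle trajectories with planted correlated/anti-correlated
blocks.

All generators are pure functions of (spec, seed): randomness comes from an
explicitly seeded ``numpy.random.Generator`` (PCG64), never global state,
and each generator returns machine-readable ground truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .chem import CompoundRecord
from .netscore import PerturbationSignature
from .ranking import SourceRanking, truncate_ranking
from .signatures import SignedGeneSet


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for the synthetic workspace.

    Defaults mirror the shape of the study inputs at desk scale: a few
    thousand genes with ~10% differential, three 50-drug source lists,
    a small natural-compound signature panel, a GDSC-style response matrix,
    and a short two-block trajectory.
    """

    n_genes: int = 2000
    frac_de: float = 0.1
    lfc_effect: float = 2.0
    n_sources: int = 3
    n_drugs: int = 120
    source_overlap: float = 0.6
    rank_noise_sd: float = 0.5
    n_compounds: int = 10
    reversal_strength: Union[float, Tuple[float, ...]] = 0.8
    n_shared_genes: int = 50
    n_cell_lines: int = 60
    frac_sensitive: float = 0.2
    na_fraction: float = 0.05
    n_high_na_drugs: int = 0
    n_frames: int = 100
    n_particles: int = 20
    block_spec: Optional[Tuple[Tuple[Tuple[int, ...], int], ...]] = None
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_de", "source_overlap", "na_fraction", "frac_sensitive"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "n_genes", "n_sources", "n_drugs", "n_compounds",
            "n_cell_lines", "n_frames", "n_particles", "n_shared_genes",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        strengths = self.reversal_strength
        if isinstance(strengths, (tuple, list)):
            if len(strengths) != self.n_compounds:
                raise ValueError("per-compound reversal_strength length mismatch")
            bad = [s for s in strengths if not 0.0 <= s <= 1.0]
        else:
            bad = [] if 0.0 <= strengths <= 1.0 else [strengths]
        if bad:
            raise ValueError(f"reversal_strength must lie in [0, 1]: {bad}")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


def _gene_names(n: int) -> List[str]:
    return [f"G{i:05d}" for i in range(n)]


def gen_deg_table(spec: SimulationSpec) -> Tuple[pd.DataFrame, Set[str]]:
    """DEG table with a planted differential fraction.

    Planted genes draw |log2FC| >= lfc_effect and adjusted p strictly below
    0.05; non-planted genes draw adjusted p uniformly on [0.05, 1] so the
    standard filter (p < 0.05, |log2FC| > 1) recovers the truth set exactly.
    """
    n_de = int(round(spec.frac_de * spec.n_genes))
    if spec.frac_de > 0 and n_de < 1:
        raise ValueError("frac_de * n_genes must be >= 1 when frac_de > 0")
    if spec.frac_de > 0 and spec.lfc_effect <= 1.0:
        raise ValueError("lfc_effect must exceed 1 for planted genes to pass")
    rng = spec.rng(salt=1)
    genes = _gene_names(spec.n_genes)
    planted = sorted(rng.choice(spec.n_genes, size=n_de, replace=False).tolist())
    planted_set = {genes[i] for i in planted}
    lfc = np.zeros(spec.n_genes)
    adj_p = np.zeros(spec.n_genes)
    is_de = np.zeros(spec.n_genes, dtype=bool)
    is_de[planted] = True
    # planted: |lfc| >= effect, p < 0.05
    signs = rng.choice([-1.0, 1.0], size=n_de)
    lfc[planted] = signs * (spec.lfc_effect + rng.exponential(0.5, size=n_de))
    adj_p[planted] = 0.05 * rng.uniform(0.0, 1.0, size=n_de)
    # background: p uniform on [0.05, 1], small fold changes
    n_bg = spec.n_genes - n_de
    lfc[~is_de] = rng.normal(0.0, 0.4, size=n_bg)
    adj_p[~is_de] = rng.uniform(0.05, 1.0, size=n_bg)
    table = pd.DataFrame({"gene": genes, "log2fc": lfc, "adj_p": adj_p})
    return table, planted_set


def _drug_names(n: int) -> List[str]:
    return [f"drug{i:04d}" for i in range(n)]


def gen_rankings(
    spec: SimulationSpec, cutoff: int = 50
) -> Tuple[List[SourceRanking], List[str]]:
    """K partially overlapping ranked lists around a latent efficacy order.

    A latent efficacy score is drawn per drug; a core fraction
    (``source_overlap``) of the most efficacious drugs is shared by all
    sources and each source pads its list with its own draw from the rest.
    Sources rank by latent score plus Gaussian noise (``rank_noise_sd``) and
    truncate to ``cutoff``.  Truth is the latent ordering (best first).
    """
    rng = spec.rng(salt=2)
    drugs = _drug_names(spec.n_drugs)
    latent = rng.normal(0.0, 1.0, size=spec.n_drugs)
    order = np.argsort(-latent, kind="stable")
    truth = [drugs[i] for i in order]
    per_source = min(spec.n_drugs, cutoff)
    n_core = int(round(spec.source_overlap * per_source))
    core = list(order[:n_core])
    rest = [i for i in range(spec.n_drugs) if i not in set(core)]
    rankings = []
    for s in range(spec.n_sources):
        n_fill = per_source - n_core
        fill = (
            list(rng.choice(rest, size=n_fill, replace=False)) if n_fill else []
        )
        members = core + fill
        noisy = latent[members] + rng.normal(0.0, spec.rank_noise_sd, len(members))
        ranked = [members[i] for i in np.argsort(-noisy, kind="stable")]
        entries = tuple(
            (drugs[d], rank) for rank, d in enumerate(ranked, start=1)
        )
        rankings.append(truncate_ranking(SourceRanking(f"source{s + 1}", entries), cutoff))
    return rankings, truth


def gen_signatures(
    spec: SimulationSpec,
    disease: SignedGeneSet,
    strengths: Optional[Sequence[float]] = None,
) -> Tuple[List[PerturbationSignature], Dict[str, float]]:
    """Compound signatures with planted reversal strengths.

    Each compound targets ``n_shared_genes`` genes sampled from the disease
    set plus an equal number of off-set distractor genes.  On each shared
    gene the compound opposes the disease direction with probability equal
    to its reversal strength (recorded in the returned truth map).
    """
    if len(disease) == 0:
        raise ValueError("disease gene set is empty")
    rng = spec.rng(salt=3)
    if strengths is None:
        if isinstance(spec.reversal_strength, (tuple, list)):
            strengths = list(spec.reversal_strength)
        else:
            strengths = [float(spec.reversal_strength)] * spec.n_compounds
    if len(strengths) != spec.n_compounds:
        raise ValueError("strengths length must equal n_compounds")
    disease_genes = sorted(disease.directions)
    n_shared = min(spec.n_shared_genes, len(disease_genes))
    sigs = []
    truth: Dict[str, float] = {}
    for c in range(spec.n_compounds):
        name = f"compound{c + 1:03d}"
        shared = rng.choice(len(disease_genes), size=n_shared, replace=False)
        regulated: Dict[str, int] = {}
        for gi in shared:
            gene = disease_genes[gi]
            opposes = rng.uniform() < strengths[c]
            regulated[gene] = (
                -disease.directions[gene] if opposes else disease.directions[gene]
            )
        for d in range(n_shared):  # distractors outside the disease set
            regulated[f"OFF{c:03d}_{d:03d}"] = int(rng.choice([-1, 1]))
        sigs.append(PerturbationSignature(name, regulated))
        truth[name] = float(strengths[c])
    return sigs, truth


# Fragment grammar for SMILES enumeration.  Each scaffold carries a long
# alkyl run plus an internal connector slot {0} (divalent-safe fragments
# only) and a terminal substituent slot {1}.  Near-duplicate pairs are
# planted by chain homologation (one extra CH2 in the alkyl run), which
# leaves the set of circular substructure environments - and hence the
# binary Morgan fingerprint - essentially unchanged, while unrelated
# scaffolds (alkyl vs aromatic vs fused-ring) stay well below the 0.8
# redundancy threshold.
_SCAFFOLDS = [
    "CCCCCCCCCCCCCCCC{0}C1CCC(CC1){1}",
    "CCCCCCCCCCCCCCCCCC{0}c1ccc(cc1){1}",
    "CCCCCCCCCCCCCCCCCCCC{0}{1}",
    "CC(C)CCCCCCCCCCCCCC{0}C1CCCCC1CCCC{1}",
    "CCCCCCCCCCCCCCc1cc2ccccc2cc1{0}{1}",
]
_CONNECTORS = ["C", "O", "N", "CC", "CO", "OCC"]
_TERMINALS = ["C", "O", "N", "OC", "C(C)C", "CO", "CC", "CCO", "F", "Cl"]
_CHAIN = "CCCCCCCCCC"  # every scaffold contains this run; homolog adds one C


def gen_smiles_library(
    n: int, seed: int = 0
) -> Tuple[List[CompoundRecord], Dict[str, object]]:
    """Enumerated SMILES library with recorded near-duplicate pairs.

    Structures come from a packaged fragment grammar (long-chain scaffolds
    with connector and terminal substituents).  Roughly one in ten records is
    followed by its planted chain homolog; truth records the near-duplicate
    pairs and each record's scaffold index.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    from rdkit import Chem

    rng = np.random.default_rng((seed, 4))
    combos = [
        (si, ai, bi)
        for si in range(len(_SCAFFOLDS))
        for ai in range(len(_CONNECTORS))
        for bi in range(len(_TERMINALS))
    ]
    order = rng.permutation(len(combos))
    records: List[CompoundRecord] = []
    pairs: List[Tuple[str, str]] = []
    scaffold_of: Dict[str, int] = {}
    used = set()
    i = 0
    while len(records) < n and i < len(combos):
        si, ai, bi = combos[order[i]]
        i += 1
        smiles = _SCAFFOLDS[si].format(_CONNECTORS[ai], _TERMINALS[bi])
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:  # pragma: no cover - grammar only emits valid SMILES
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in used:
            continue
        used.add(canon)
        cid = f"cmpd{len(records) + 1:04d}"
        records.append(CompoundRecord(id=cid, smiles=canon))
        scaffold_of[cid] = si
        # plant a near duplicate: the chain homolog (one extra CH2)
        if len(records) < n and len(pairs) < max(1, n // 10):
            twin = smiles.replace(_CHAIN, _CHAIN + "C", 1)
            tmol = Chem.MolFromSmiles(twin)
            if tmol is not None:
                tcanon = Chem.MolToSmiles(tmol)
                if tcanon not in used:
                    used.add(tcanon)
                    tid = f"cmpd{len(records) + 1:04d}"
                    records.append(CompoundRecord(id=tid, smiles=tcanon))
                    scaffold_of[tid] = si
                    pairs.append((cid, tid))
    if len(records) < n:
        raise ValueError(f"grammar exhausted at {len(records)} < {n} structures")
    return records, {"pairs": pairs, "scaffold": scaffold_of}


def gen_response_matrix(
    spec: SimulationSpec,
) -> Tuple[pd.DataFrame, Set[str]]:
    """IC50 matrix with planted sensitive drugs and MCAR missingness.

    Planted sensitive drugs have IC50 < 10 uM in every line; the rest sit at
    or above 10 uM.  A fraction ``na_fraction`` of entries is masked at
    random, and ``n_high_na_drugs`` additional drugs are masked in > 20% of
    lines (to exercise the discard rule).
    """
    rng = spec.rng(salt=5)
    lines = [f"line{i:03d}" for i in range(spec.n_cell_lines)]
    drugs = _drug_names(spec.n_drugs)
    n_sens = int(round(spec.frac_sensitive * spec.n_drugs))
    sens_idx = set(rng.choice(spec.n_drugs, size=n_sens, replace=False).tolist())
    values = np.empty((spec.n_cell_lines, spec.n_drugs))
    for j in range(spec.n_drugs):
        if j in sens_idx:
            values[:, j] = rng.uniform(0.05, 9.0, size=spec.n_cell_lines)
        else:
            values[:, j] = rng.uniform(10.0, 200.0, size=spec.n_cell_lines)
    mask = rng.uniform(size=values.shape) < spec.na_fraction
    # keep at least one observation per drug so imputation stays defined
    for j in range(spec.n_drugs):
        if mask[:, j].all():
            mask[rng.integers(spec.n_cell_lines), j] = False
    high_na = rng.choice(
        [j for j in range(spec.n_drugs) if j not in sens_idx],
        size=min(spec.n_high_na_drugs, spec.n_drugs - n_sens),
        replace=False,
    )
    for j in high_na:
        n_mask = int(np.ceil(0.20 * spec.n_cell_lines)) + 1
        rows = rng.choice(spec.n_cell_lines, size=min(n_mask, spec.n_cell_lines), replace=False)
        mask[rows, j] = True
    values[mask] = np.nan
    frame = pd.DataFrame(values, index=lines, columns=drugs)
    truth = {drugs[j] for j in sorted(sens_idx)}
    return frame, truth


def gen_trajectory(
    spec: SimulationSpec,
) -> Tuple[np.ndarray, List[str], List[Tuple[List[int], int]]]:
    """Trajectory with planted coherently moving particle blocks.

    Particles in a block share a sinusoidal displacement along a common unit
    vector, scaled by the block's motion direction (+1/-1), on top of static
    base positions and isotropic Gaussian noise of width ``noise_sd`` (nm).
    Default block_spec splits the particles into two anti-phase halves.
    """
    rng = spec.rng(salt=6)
    n, f = spec.n_particles, spec.n_frames
    if spec.block_spec is None:
        half = n // 2
        blocks = [
            (list(range(half)), 1),
            (list(range(half, n)), -1),
        ]
    else:
        blocks = [(list(p), int(d)) for p, d in spec.block_spec]
    assigned = [i for p, _ in blocks for i in p]
    if sorted(assigned) != sorted(set(assigned)) or any(
        i < 0 or i >= n for i in assigned
    ):
        raise ValueError("block_spec particle indices must be unique and in range")
    base = rng.uniform(-5.0, 5.0, size=(n, 3))
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    t = np.arange(f)
    signal = np.sin(2.0 * np.pi * t / max(f / 4.0, 2.0))  # amplitude 1 nm
    traj = np.tile(base, (f, 1, 1))
    for particles, direction in blocks:
        disp = direction * signal[:, None] * axis[None, :]
        for i in particles:
            traj[:, i, :] += disp
    traj += rng.normal(0.0, spec.noise_sd, size=traj.shape)
    ids = [f"P{i:03d}" for i in range(n)]
    return traj, ids, blocks


def make_disease_set(spec: SimulationSpec) -> SignedGeneSet:
    """Convenience: planted disease signature via gen_deg_table + the filter."""
    from .signatures import filter_degs

    table, _ = gen_deg_table(spec)
    return filter_degs(table, 0.05, 1.0, label="BM")
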