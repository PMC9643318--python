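"""Readers and writers for every external format the pipeline touches.

All tables travel as TSV.  Structures travel as "SMILES<tab>id" lines,
trajectories as multi-frame XYZ-style text (particle-count header, then one
"id x y z" line per particle, coordinates in nm), and the bipartite network
as a SIF-style edge list.  Every reader/writer pair is a lossless round trip
on valid data, and all writers emit deterministic row and column order.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import CompoundRecord, canonical_smiles
from .netscore import PerturbationSignature
from .ranking import SourceRanking
from .signatures import SignedGeneSet, validate_deg_table

logger = logging.getLogger(__name__)

_DIRECTION_TOKENS = {"1": 1, "+1": 1, "up": 1, "-1": -1, "down": -1}


def read_deg_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns gene, log2fc, adj_p; genes unique, adj_p in [0, 1]."""
    table = pd.read_csv(path, sep="\t", dtype={"gene": str})
    return validate_deg_table(table)


def write_deg_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_deg_table(table)
    table.loc[:, ["gene", "log2fc", "adj_p"]].to_csv(path, sep="\t", index=False)


def read_rankings(path: str | Path) -> List[SourceRanking]:
    """TSV with columns source, drug, rank; per source ranks are exactly 1..n."""
    frame = pd.read_csv(path, sep="\t", dtype={"source": str, "drug": str})
    out = []
    for source in frame["source"].drop_duplicates():
        sub = frame[frame["source"] == source]
        try:
            out.append(
                SourceRanking(
                    str(source),
                    tuple((str(d), int(r)) for d, r in zip(sub["drug"], sub["rank"])),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    return out


def write_rankings(rankings: Sequence[SourceRanking], path: str | Path) -> None:
    rows = [
        (r.source, drug, rank)
        for r in rankings
        for drug, rank in sorted(r.entries, key=lambda e: e[1])
    ]
    pd.DataFrame(rows, columns=["source", "drug", "rank"]).to_csv(
        path, sep="\t", index=False
    )


def read_smiles(path: str | Path, strict: bool = True) -> List[CompoundRecord]:
    """One "SMILES<tab>id" per line; structures are canonicalized on read.

    Invalid lines raise with their line number in strict mode (default) and
    are skipped with a logged warning in lenient mode.
    """
    records: List[CompoundRecord] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            msg = f"{path}: line {lineno}: expected 'SMILES<tab>id'"
            if strict:
                raise ValueError(msg)
            logger.warning("%s (skipped)", msg)
            continue
        smiles, cid = parts[0].strip(), parts[1].strip()
        try:
            smiles = canonical_smiles(smiles)
        except ValueError:
            msg = f"{path}: line {lineno}: unparsable SMILES {parts[0]!r}"
            if strict:
                raise ValueError(msg) from None
            logger.warning("%s (skipped)", msg)
            continue
        records.append(CompoundRecord(id=cid, smiles=smiles))
    return records


def write_smiles(records: Sequence[CompoundRecord], path: str | Path) -> None:
    lines = [f"{r.smiles}\t{r.id}" for r in records]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_signatures(path: str | Path) -> List[PerturbationSignature]:
    """TSV compound, gene, direction with direction in {+1, -1, up, down}."""
    frame = pd.read_csv(
        path, sep="\t", dtype={"compound": str, "gene": str, "direction": str}
    )
    sigs: Dict[str, Dict[str, int]] = {}
    order: List[str] = []
    for row in frame.itertuples(index=False):
        token = str(row.direction).strip().lower()
        if token not in _DIRECTION_TOKENS:
            raise ValueError(
                f"{path}: unknown direction token {row.direction!r} "
                f"for ({row.compound}, {row.gene})"
            )
        if row.compound not in sigs:
            sigs[row.compound] = {}
            order.append(row.compound)
        sigs[row.compound][row.gene] = _DIRECTION_TOKENS[token]
    return [PerturbationSignature(c, sigs[c]) for c in order]


def write_signatures(
    signatures: Sequence[PerturbationSignature], path: str | Path
) -> None:
    rows = [
        (s.compound, g, s.regulated[g])
        for s in signatures
        for g in sorted(s.regulated)
    ]
    pd.DataFrame(rows, columns=["compound", "gene", "direction"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_set(path: str | Path, label: str = "") -> SignedGeneSet:
    """TSV gene, direction (+ optional log2fc) -> signed gene set."""
    frame = pd.read_csv(path, sep="\t", dtype={"gene": str})
    frame["direction"] = [
        _parse_direction(t, path) for t in frame["direction"].astype(str)
    ]
    return SignedGeneSet.from_frame(frame, label=label)


def _parse_direction(token: str, path) -> int:
    t = token.strip().lower()
    if t not in _DIRECTION_TOKENS:
        raise ValueError(f"{path}: unknown direction token {token!r}")
    return _DIRECTION_TOKENS[t]


def write_gene_set(gene_set: SignedGeneSet, path: str | Path) -> None:
    gene_set.to_frame().to_csv(path, sep="\t", index=False)


def read_response_matrix(path: str | Path) -> pd.DataFrame:
    """Wide TSV: first column cell_line, remaining columns drugs (IC50, uM)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    return frame


def write_response_matrix(m: pd.DataFrame, path: str | Path) -> None:
    m.to_csv(path, sep="\t", index_label="cell_line")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Wide TSV: first column gene, remaining columns samples."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    if frame.isna().any().any():
        raise ValueError(f"{path}: expression matrix must be complete")
    return frame


def write_expression(m: pd.DataFrame, path: str | Path) -> None:
    m.to_csv(path, sep="\t", index_label="gene")


def read_trajectory(path: str | Path) -> Tuple[np.ndarray, List[str]]:
    """Multi-frame XYZ-style text -> (frames x particles x 3 array, ids).

    Each frame is a particle-count line followed by that many
    "id x y z" lines; coordinates in nm.  The particle set (ids and order)
    must be constant across frames.
    """
    lines = [l for l in Path(path).read_text().splitlines()]
    frames: List[np.ndarray] = []
    ids: Optional[List[str]] = None
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError as exc:
            raise ValueError(
                f"{path}: line {pos + 1}: expected particle count"
            ) from exc
        block = lines[pos + 1 : pos + 1 + n]
        if len(block) < n:
            raise ValueError(f"{path}: truncated frame at line {pos + 1}")
        frame_ids, coords = [], []
        for off, row in enumerate(block):
            parts = row.split()
            if len(parts) != 4:
                raise ValueError(
                    f"{path}: line {pos + 2 + off}: expected 'id x y z'"
                )
            frame_ids.append(parts[0])
            coords.append([float(v) for v in parts[1:]])
        if ids is None:
            ids = frame_ids
        elif frame_ids != ids:
            raise ValueError(f"{path}: particle ids differ between frames")
        frames.append(np.asarray(coords))
        pos += 1 + n
    if not frames:
        raise ValueError(f"{path}: empty trajectory")
    return np.stack(frames), list(ids or [])


def write_trajectory(
    t: np.ndarray, ids: Sequence[str], path: str | Path
) -> None:
    t = np.asarray(t, dtype=float)
    if t.ndim != 3 or t.shape[2] != 3 or t.shape[1] != len(ids):
        raise ValueError("trajectory must be (frames, len(ids), 3)")
    out = []
    for frame in t:
        out.append(str(len(ids)))
        for pid, (x, y, z) in zip(ids, frame):
            out.append(f"{pid} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(out) + "\n")


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Generic deterministic TSV writer (column order as given, rows as given)."""
    frame.to_csv(path, sep="\t", index=False)


def write_sif(edges: pd.DataFrame, path: str | Path) -> None:
    """SIF-style edge list: "compound<tab>mimic|reverse<tab>gene" lines."""
    lines = [
        f"{r.compound}\t{r.interaction}\t{r.gene}"
        for r in edges.itertuples(index=False)
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
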