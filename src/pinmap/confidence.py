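"""Confidence-based post-processing of predicted models.

Two operations are provided: pruning of low-confidence residues before any
geometric interpretation (residues below a pLDDT threshold are removed
whole — confidence is a per-residue quantity), and rectangular block
summaries of the predicted-aligned-error matrix, which is how the relative
placement of two domains is judged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structio import Chain, PAEMatrix, SelectionSpec, StructureModel

__all__ = [
    "PlddtProfile",
    "PaeBlockSummary",
    "prune_low_confidence",
    "plddt_profile",
    "pae_block",
]


@dataclass(frozen=True)
class PlddtProfile:
    """Ordered per-residue confidence values, one entry per residue."""

    entries: tuple[tuple[str, int, float], ...]  # (chain_id, res_seq, plddt)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.entries),
                            columns=["chain_id", "res_seq", "plddt"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def mean(self, chain_id: str | None = None,
             res_range: tuple[int, int] | None = None) -> float:
        vals = [p for c, r, p in self.entries
                if (chain_id is None or c == chain_id)
                and (res_range is None or res_range[0] <= r <= res_range[1])]
        if not vals:
            raise ValueError("no residues match the requested region")
        return float(np.mean(vals))


@dataclass(frozen=True)
class PaeBlockSummary:
    """Summary of one rectangular PAE block (rows -> cols direction) plus
    the symmetrized mean over both directions, which is the headline
    statistic since PAE is asymmetric."""

    rows: SelectionSpec
    cols: SelectionSpec
    mean: float
    min: float
    max: float
    n_cells: int
    symmetric_mean: float

    def __post_init__(self) -> None:
        if not (self.min <= self.mean <= self.max):
            raise ValueError("block summary violates min <= mean <= max")


def _check_plddt(model: StructureModel) -> None:
    values = [res.plddt for _, res in model.iter_residues()]
    if not values or any(v is None for v in values):
        raise ValueError(
            "model carries no per-residue confidence; predicted models store "
            "pLDDT in the B-factor column — check the B-factor source")
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0) or np.any(arr > 100):
        raise ValueError(
            "B-factors outside [0, 100]; they do not look like pLDDT values "
            "— check the B-factor source")


def prune_low_confidence(model: StructureModel, threshold: float = 50.0) -> StructureModel:
    """Remove every residue with pLDDT strictly below ``threshold``.

    Residues exactly at the threshold are retained.  Chains emptied
    entirely are dropped.  Pruning is idempotent and monotone in the
    threshold.
    """
    if model.n_residues == 0:
        return model.copy()
    _check_plddt(model)
    chains = []
    for chain in model.chains:
        kept = [r.copy() for r in chain.residues if r.plddt >= threshold]
        if kept:
            chains.append(Chain(chain.chain_id, kept))
    return StructureModel(model.model_id, chains, model.source)


def plddt_profile(model: StructureModel) -> PlddtProfile:
    """One confidence entry per residue, in chain/residue file order."""
    _check_plddt(model)
    entries = tuple((chain.chain_id, res.res_seq, float(res.plddt))
                    for chain, res in model.iter_residues())
    return PlddtProfile(entries=entries)


def _resolve(pae: PAEMatrix, spec: SelectionSpec) -> np.ndarray:
    idx = [i for i, (chain_id, res_seq) in enumerate(pae.residue_index)
           if spec.matches_chain(chain_id)
           and (spec.res_range is None
                or spec.res_range[0] <= res_seq <= spec.res_range[1])]
    return np.asarray(idx, dtype=int)


def pae_block(pae: PAEMatrix, rows: SelectionSpec, cols: SelectionSpec) -> PaeBlockSummary:
    """Arithmetic summary of the PAE block rows x cols.

    ``mean`` is directional (error of the row residues when aligned on the
    column residues); ``symmetric_mean`` averages both directions.
    """
    ri = _resolve(pae, rows)
    ci = _resolve(pae, cols)
    if ri.size == 0 or ci.size == 0:
        raise ValueError("empty row or column selection for PAE block")
    block = pae.values[np.ix_(ri, ci)]
    block_t = pae.values[np.ix_(ci, ri)]
    return PaeBlockSummary(
        rows=rows,
        cols=cols,
        mean=float(block.mean()),
        min=float(block.min()),
        max=float(block.max()),
        n_cells=int(block.size),
        symmetric_mean=float((block.mean() + block_t.mean()) / 2.0),
    )
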