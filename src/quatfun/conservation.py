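"""Interface-conservation delta from per-residue conservation scores.

Scores follow the ConSurf convention (lower = more conserved), so
delta = mean(surface) - mean(interface) is positive when the interface is
more conserved than the solvent-accessible surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .structure_annotation import ResidueKey

logger = logging.getLogger(__name__)


@dataclass
class ConservationProfile:
    scores: dict[ResidueKey, float]

    def subset(self, keys) -> np.ndarray:
        return np.array(
            [self.scores[k] for k in sorted(keys) if k in self.scores]
        )


@dataclass
class ConservationDelta:
    delta: float
    p_value: float
    n_surface: int
    n_interface: int


def read_conservation(
    source: str | Path | pd.DataFrame,
    structure_residues: set | frozenset,
) -> ConservationProfile:
    """Load a (chain, resnum, score) table and map it onto the structure.

    Rows that do not match any structure residue (including insertion-code
    mismatches) are dropped with a warning count.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=None, engine="python")
    cols = {c.lower().strip(): c for c in df.columns}
    if "resnum" not in cols or "score" not in cols:
        raise ValueError(
            f"conservation table needs resnum and score columns; got "
            f"{list(df.columns)}"
        )
    if df.empty:
        raise ValueError("empty conservation table")
    chain_col = cols.get("chain")
    lookup = {key: key for key in structure_residues}

    scores: dict[ResidueKey, float] = {}
    dropped = 0
    for _, row in df.iterrows():
        resnum = int(row[cols["resnum"]])
        chains = [str(row[chain_col])] if chain_col else sorted(
            {k.chain for k in structure_residues}
        )
        matched = False
        for chain in chains:
            key = ResidueKey(chain, resnum, "")
            if key in lookup:
                scores[key] = float(row[cols["score"]])
                matched = True
        if not matched:
            dropped += 1
    if dropped:
        logger.warning("dropped %d conservation rows with no structure match",
                       dropped)
    if not scores:
        raise ValueError("conservation table has no overlap with structure")
    return ConservationProfile(scores)


def conservation_delta(
    profile: ConservationProfile,
    surface: set | frozenset,
    interface: set | frozenset,
    alternative: str = "two-sided",
) -> ConservationDelta:
    """delta = mean(surface scores) - mean(interface scores), rank-sum p."""
    surf = profile.subset(surface)
    intf = profile.subset(interface)
    if surf.size < 3 or intf.size < 3:
        raise ValueError(
            f"need >= 3 scored residues per set (got {surf.size} surface, "
            f"{intf.size} interface)"
        )
    delta = float(surf.mean() - intf.mean())
    p = float(mannwhitneyu(surf, intf, alternative=alternative,
                           method="asymptotic").pvalue)
    return ConservationDelta(delta=delta, p_value=p,
                             n_surface=int(surf.size),
                             n_interface=int(intf.size))
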