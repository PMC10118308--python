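"""Amino-acid composition of regions vs missense-variant alternate alleles."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .structure_annotation import AMINO_ACIDS


class VariantRecord(NamedTuple):
    position: int          # 1-based protein position
    ref: str
    alt: str


def read_variants(source: str | Path | pd.DataFrame) -> list[VariantRecord]:
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    out = []
    for _, row in df.iterrows():
        rec = VariantRecord(int(row[cols["position"]]),
                            str(row[cols["ref"]]), str(row[cols["alt"]]))
        if rec.ref == rec.alt:
            raise ValueError(f"variant at {rec.position}: ref == alt")
        if rec.ref not in AMINO_ACIDS or rec.alt not in AMINO_ACIDS:
            raise ValueError(f"non-canonical amino acid in variant {rec}")
        out.append(rec)
    return out


def map_variants(
    variants: Sequence[VariantRecord],
    regions: dict[str, set[int]],
    sequence_length: int,
) -> dict[str, list[VariantRecord]]:
    """Partition variants by the region of their position; positions in no
    region go to 'neither'.  Out-of-range positions raise."""
    bad = [v for v in variants if not (1 <= v.position <= sequence_length)]
    if bad:
        raise ValueError(f"variants outside 1..{sequence_length}: {bad}")
    out: dict[str, list[VariantRecord]] = {name: [] for name in regions}
    out["neither"] = []
    for v in variants:
        hit = False
        for name, positions in regions.items():
            if v.position in positions:
                out[name].append(v)
                hit = True
        if not hit:
            out["neither"].append(v)
    return out


@dataclass
class CompositionTable:
    region_freq: pd.Series       # 20 amino-acid frequencies of the region
    variant_alt_freq: pd.Series  # frequencies of variant alternate alleles
    n_residues: int
    n_variants: int


def composition(
    region_sequence: Sequence[str],
    region_variants: Sequence[VariantRecord],
) -> CompositionTable:
    """Amino-acid frequencies of a region and of its variants' alt alleles."""
    seq = list(region_sequence)
    if not seq:
        raise ValueError("empty region")
    res_counts = pd.Series(0, index=AMINO_ACIDS, dtype=float)
    for aa in seq:
        if aa in res_counts.index:
            res_counts[aa] += 1
    alt_counts = pd.Series(0, index=AMINO_ACIDS, dtype=float)
    for v in region_variants:
        alt_counts[v.alt] += 1
    region_freq = res_counts / res_counts.sum()
    n_var = len(region_variants)
    variant_freq = alt_counts / n_var if n_var else alt_counts
    return CompositionTable(region_freq=region_freq,
                            variant_alt_freq=variant_freq,
                            n_residues=len(seq), n_variants=n_var)


@dataclass
class SlopeTest:
    slope: float
    intercept: float
    f_statistic: float
    p_value: float
    n: int


def slope_vs_one_test(
    x: pd.Series | np.ndarray,
    y: pd.Series | np.ndarray,
    exclusions: set[str] = frozenset(),
) -> SlopeTest:
    """OLS of y on x over amino acids, F test of H0: slope = 1."""
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        keep = [aa for aa in x.index if aa not in exclusions]
        xv = x.loc[keep].to_numpy(dtype=float)
        yv = y.loc[keep].to_numpy(dtype=float)
    else:
        xv = np.asarray(x, dtype=float)
        yv = np.asarray(y, dtype=float)
    if xv.size < 5:
        raise ValueError("need >= 5 points after exclusions")
    if np.ptp(xv) == 0:
        raise ValueError("zero-variance x")
    n = xv.size
    xm, ym = xv.mean(), yv.mean()
    sxx = float(((xv - xm) ** 2).sum())
    slope = float(((xv - xm) * (yv - ym)).sum() / sxx)
    intercept = ym - slope * xm
    resid = yv - (intercept + slope * xv)
    dof = n - 2
    mse = float((resid ** 2).sum()) / dof
    if mse == 0:
        f_stat = 0.0 if slope == 1.0 else np.inf
        p = 1.0 if slope == 1.0 else 0.0
    else:
        se2 = mse / sxx
        f_stat = (slope - 1.0) ** 2 / se2
        p = float(f_dist.sf(f_stat, 1, dof))
    return SlopeTest(slope=slope, intercept=float(intercept),
                     f_statistic=float(f_stat), p_value=p, n=n)


def enrichment_ratio(
    aa: str,
    variant_freq: pd.Series,
    region_freq: pd.Series,
) -> float:
    """Variant alt-allele frequency of ``aa`` divided by its region
    frequency."""
    denom = float(region_freq[aa])
    if denom == 0:
        raise ValueError(f"region frequency of {aa!r} is zero")
    return float(variant_freq[aa]) / denom
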