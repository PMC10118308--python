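"""Evolutionary-coupling Z statistics for homodimer interfaces.

Coupling scores are computed on one chain's sequence, so both chains of a
homodimer map onto the same alignment columns.  Three standardized
statistics are provided:

* interface Z — cross-interface couplings vs couplings of interface
  residues with the non-interface residues they contact;
* ligand–interface Z — LBR x interface couplings vs LBR x surface;
* LBR–LBR Z — couplings within the binding site vs LBR x surface.

Each Z is (mean_focus - mean_reference) / sd_reference (sample SD, ddof 1)
with a two-sided Mann–Whitney rank-sum p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import mannwhitneyu

from .structure_annotation import ContactMap, ResidueKey, StructureModel

logger = logging.getLogger(__name__)


@dataclass
class TransformSpec:
    lam: float
    applied: bool


@dataclass
class CouplingMatrix:
    """Symmetric residue-pair score matrix plus alignment statistics."""

    scores: np.ndarray          # L x L, NaN diagonal
    neff: float
    position_map: dict[ResidueKey, int]   # structure residue -> column

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def column(self, key: ResidueKey) -> int | None:
        return self.position_map.get(key)

    def pair_scores(self, pairs) -> np.ndarray:
        """Scores of mapped, deduplicated unordered column pairs.

        Pairs whose two residues map to the same column (homodimer mirror
        pairs) are dropped.
        """
        cols = set()
        dropped = 0
        for a, b in pairs:
            ca, cb = self.column(a), self.column(b)
            if ca is None or cb is None:
                dropped += 1
                continue
            if ca == cb:
                dropped += 1
                continue
            cols.add((min(ca, cb), max(ca, cb)))
        if dropped:
            logger.debug("dropped %d unmapped/diagonal pairs", dropped)
        if not cols:
            return np.empty(0)
        idx = np.array(sorted(cols))
        return self.scores[idx[:, 0], idx[:, 1]]


@dataclass
class ZScoreResult:
    z: float
    mean_focus: float
    mean_reference: float
    sd_reference: float
    n_focus: int
    n_reference: int
    p_value: float
    transform: TransformSpec = field(
        default_factory=lambda: TransformSpec(1.0, False)
    )


def homodimer_position_map(s: StructureModel) -> dict[ResidueKey, int]:
    """Map every chain's residue (chain, n, icode) to 0-based column n-1."""
    return {key: key.resnum - 1 for key in s.residue_keys() if not key.icode}


def read_coupling_scores(
    source: str | Path | pd.DataFrame,
    position_map: dict[ResidueKey, int],
    length: int,
    neff: float,
) -> CouplingMatrix:
    """Load an (i, j, cn) coupling CSV into a symmetric matrix.

    Positions are 1-based in the file.  Conflicting duplicate entries raise.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)
    cols = {c.lower().strip(): c for c in df.columns}
    try:
        i_col, j_col = cols["i"], cols["j"]
        s_col = cols.get("cn") or cols.get("score")
        assert s_col is not None
    except (KeyError, AssertionError):
        raise ValueError(
            f"coupling table needs columns i, j, cn/score; got {list(df.columns)}"
        ) from None

    scores = np.full((length, length), np.nan)
    dropped = 0
    for i, j, val in zip(df[i_col], df[j_col], df[s_col]):
        a, b = int(i) - 1, int(j) - 1
        if a == b:
            raise ValueError(f"self-pair ({i},{j}) in coupling table")
        if not (0 <= a < length and 0 <= b < length):
            dropped += 1
            continue
        existing = scores[a, b]
        if not np.isnan(existing) and not np.isclose(existing, val):
            raise ValueError(
                f"conflicting duplicate entry for pair ({i},{j}): "
                f"{existing} vs {val}"
            )
        scores[a, b] = scores[b, a] = val
    if dropped:
        logger.info("dropped %d coupling rows outside 1..%d", dropped, length)
    return CouplingMatrix(scores=scores, neff=float(neff),
                          position_map=dict(position_map))


def neff_filter(cm: CouplingMatrix) -> bool:
    """Analyzable iff Neff / L >= 1."""
    return cm.neff / cm.length >= 1.0


def yeo_johnson(x, lam: float):
    """Four-branch Yeo–Johnson power transform (vectorized, total)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    if lam != 0:
        out[pos] = ((x[pos] + 1.0) ** lam - 1.0) / lam
    else:
        out[pos] = np.log1p(x[pos])
    neg = ~pos
    if lam != 2:
        out[neg] = -(((1.0 - x[neg]) ** (2.0 - lam)) - 1.0) / (2.0 - lam)
    else:
        out[neg] = -np.log1p(-x[neg])
    if out.ndim == 0:
        return float(out)
    return out


def _yj_profile_loglik(x: np.ndarray, lam: float) -> float:
    # Gaussian profile log-likelihood including the Jacobian term
    # sum (lam-1) * sign(x) * log(|x|+1).
    t = yeo_johnson(x, lam)
    n = x.size
    var = t.var()
    if var <= 0:
        return -np.inf
    jac = (lam - 1.0) * np.sum(np.sign(x) * np.log1p(np.abs(x)))
    return -0.5 * n * np.log(var) + jac


def select_lambda(reference, bounds: tuple[float, float] = (-5.0, 5.0)) -> float:
    """Lambda maximizing normality (profile log-likelihood) of the sample."""
    x = np.asarray(reference, dtype=float)
    if x.size < 8:
        raise ValueError("need >= 8 reference values to fit lambda")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: no transform can normalize it")
    res = minimize_scalar(
        lambda lam: -_yj_profile_loglik(x, lam),
        bounds=bounds, method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def _z_from_samples(
    focus: np.ndarray,
    reference: np.ndarray,
    transform: bool = False,
) -> ZScoreResult:
    focus = np.asarray(focus, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if focus.size < 2 or reference.size < 2:
        raise ValueError(
            f"need >= 2 values per class (got {focus.size} focus, "
            f"{reference.size} reference)"
        )
    spec = TransformSpec(1.0, False)
    if transform:
        lam = select_lambda(reference)
        spec = TransformSpec(lam, True)
        focus = yeo_johnson(focus, lam)
        reference = yeo_johnson(reference, lam)
    sd = reference.std(ddof=1)
    if sd == 0:
        raise ValueError("reference distribution has zero spread")
    z = (focus.mean() - reference.mean()) / sd
    p = float(mannwhitneyu(focus, reference, alternative="two-sided",
                           method="asymptotic").pvalue)
    return ZScoreResult(
        z=float(z),
        mean_focus=float(focus.mean()),
        mean_reference=float(reference.mean()),
        sd_reference=float(sd),
        n_focus=int(focus.size),
        n_reference=int(reference.size),
        p_value=p,
        transform=spec,
    )


def _interface_pair_classes(interface: set, contacts: ContactMap,
                            all_pairs: bool = False,
                            non_interface: set | None = None):
    focus, reference = [], []
    for pair in contacts.residue_pairs:
        a, b = tuple(pair)
        a_in, b_in = a in interface, b in interface
        if a_in and b_in and a.chain != b.chain:
            focus.append((a, b))
        elif a_in != b_in:
            reference.append((a, b))
    if all_pairs:
        if non_interface is None:
            raise ValueError("all_pairs mode needs the non-interface set")
        reference = [(a, b) for a in interface for b in non_interface]
    return focus, reference


def interface_z(
    cm: CouplingMatrix,
    interface: set | frozenset,
    contacts: ContactMap,
    transform: bool = True,
    all_pairs: bool = False,
    non_interface: set | None = None,
) -> ZScoreResult:
    """Cross-interface couplings vs interface/non-interface contact couplings.

    The reference distribution (interface residues with the non-interface
    residues they contact) is also the sample the Yeo–Johnson lambda is
    fitted on when ``transform`` is set.
    """
    focus_pairs, ref_pairs = _interface_pair_classes(
        set(interface), contacts, all_pairs, non_interface
    )
    focus = cm.pair_scores(focus_pairs)
    reference = cm.pair_scores(ref_pairs)
    return _z_from_samples(focus, reference, transform=transform)


def _cross_set_scores(cm: CouplingMatrix, set_a, set_b) -> np.ndarray:
    return cm.pair_scores([(a, b) for a in set_a for b in set_b])


def _drop_lbr_columns(cm: CouplingMatrix, surface, lbr_set):
    """Surface residues whose sequence position is an LBR position on the
    other chain would contaminate the reference distribution with
    binding-site couplings; drop them."""
    lbr_cols = {cm.column(k) for k in lbr_set} - {None}
    return [k for k in sorted(surface) if cm.column(k) not in lbr_cols]


def ligand_interface_z(
    cm: CouplingMatrix,
    lbr_set: set | frozenset,
    interface: set | frozenset,
    surface: set | frozenset,
) -> ZScoreResult:
    """LBR x interface couplings vs LBR x surface couplings (untransformed)."""
    if not (lbr_set and interface and surface):
        raise ValueError("LBR, interface and surface sets must be nonempty")
    focus = _cross_set_scores(cm, sorted(lbr_set), sorted(interface))
    reference = _cross_set_scores(
        cm, sorted(lbr_set), _drop_lbr_columns(cm, surface, lbr_set)
    )
    return _z_from_samples(focus, reference, transform=False)


def lbr_coevolution_z(
    cm: CouplingMatrix,
    lbr_set: set | frozenset,
    surface: set | frozenset,
) -> ZScoreResult:
    """LBR–LBR couplings vs LBR x surface couplings (untransformed)."""
    lbrs = sorted(lbr_set)
    if len(lbrs) < 2:
        raise ValueError("need >= 2 ligand-binding residues")
    focus = cm.pair_scores(
        [(a, b) for i, a in enumerate(lbrs) for b in lbrs[i + 1:]]
    )
    reference = _cross_set_scores(
        cm, lbrs, _drop_lbr_columns(cm, surface, lbr_set)
    )
    return _z_from_samples(focus, reference, transform=False)


def select_best_ligand(
    per_ligand: dict[str, float],
    site_types: dict[str, str] | None = None,
    complex_class: str | None = None,
) -> str:
    """Argmax ligand by statistic; in MBS complexes only MBS ligands are
    candidates; ties break to the lexicographically smaller ligand id."""
    candidates = dict(per_ligand)
    if complex_class == "MBS" and site_types is not None:
        candidates = {
            lid: v for lid, v in candidates.items()
            if site_types.get(lid) == "MBS"
        }
    if not candidates:
        raise ValueError("no candidate ligands")
    return min(candidates, key=lambda lid: (-candidates[lid], lid))
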