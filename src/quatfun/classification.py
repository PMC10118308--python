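"""Cohort-level classification: scorecards, non-functionality flags,
Venn overlaps with simulated random expectations, ANCOVA, proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

INTERFACE_MINIMUM = 40
STRATUM_BOUNDARY = 100
ALPHA = 0.05

METHODS = ("Z", "R2", "CONS")


@dataclass
class ComplexScoreCard:
    complex_id: str
    complex_class: str | None = None       # "MBS" | "SBS"
    n_mbs_sites: int = 0
    interface_size: int = 0
    structure_size: int = 0
    ligand_distance: float | None = None
    neff: float | None = None
    analyzable: bool = True                # Neff/L gate for coupling stats
    z_interface: float | None = None
    p_z_interface: float | None = None
    z_ligand: float | None = None
    p_z_ligand: float | None = None
    z_lbr: float | None = None
    p_z_lbr: float | None = None
    conservation_delta: float | None = None
    p_conservation: float | None = None
    r2: float | None = None
    r2_correlation: float | None = None
    p_r2: float | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def excluded(self) -> bool:
        return self.interface_size < INTERFACE_MINIMUM

    @property
    def stratum(self) -> str:
        return "lt100" if self.interface_size < STRATUM_BOUNDARY else "ge100"


@dataclass
class MethodFlags:
    complex_id: str
    nonfunctional_by: frozenset
    stratum: str
    gated: bool                           # passed the z_lbr gate


def assemble_scorecard(complex_id: str, **fields_) -> ComplexScoreCard:
    """Build a scorecard; unknown statistics stay None and are logged in
    ``notes``."""
    card = ComplexScoreCard(complex_id=complex_id)
    for name, value in fields_.items():
        if not hasattr(card, name):
            raise TypeError(f"unknown scorecard field {name!r}")
        setattr(card, name, value)
    for stat in ("z_ligand", "conservation_delta", "r2"):
        if getattr(card, stat) is None:
            card.notes.append(f"missing:{stat}")
    if card.excluded:
        card.notes.append(f"excluded:interface_size<{INTERFACE_MINIMUM}")
    if not card.analyzable:
        card.notes.append("excluded:neff_over_L<1")
    return card


def apply_bh(p_values: Sequence[float], alpha: float = ALPHA):
    """Benjamini–Hochberg step-up; returns (q_values, reject)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def flag_cohort(
    cards: Sequence[ComplexScoreCard], alpha: float = ALPHA
) -> dict[str, MethodFlags]:
    """Apply the z_lbr gate and per-method non-functionality flags.

    Each method's p-values are BH-corrected across the gated cohort; a
    method flags a complex iff its statistic is non-positive or its q-value
    exceeds alpha.  Complexes with interface_size < 40, failing the Neff/L
    filter, or failing the gate are not flagged.
    """
    usable = [
        c for c in cards
        if not c.excluded and c.analyzable and c.p_z_lbr is not None
    ]
    if not usable:
        return {}
    q_gate, _ = apply_bh([c.p_z_lbr for c in usable], alpha)
    gated = [
        c for c, q in zip(usable, q_gate)
        if c.z_lbr is not None and c.z_lbr > 0 and q <= alpha
    ]

    flags: dict[str, MethodFlags] = {}
    for c in usable:
        flags[c.complex_id] = MethodFlags(
            complex_id=c.complex_id, nonfunctional_by=frozenset(),
            stratum=c.stratum, gated=False,
        )
    if not gated:
        return flags

    def _method_flags(stat: str, p_attr: str, positive) -> dict[str, bool]:
        have = [c for c in gated if getattr(c, p_attr) is not None
                and getattr(c, stat) is not None]
        out: dict[str, bool] = {}
        if not have:
            return out
        q, _ = apply_bh([getattr(c, p_attr) for c in have], alpha)
        for c, qv in zip(have, q):
            out[c.complex_id] = (not positive(c)) or (qv > alpha)
        return out

    z_flags = _method_flags("z_ligand", "p_z_ligand",
                            lambda c: c.z_ligand > 0)
    r2_flags = _method_flags(
        "r2", "p_r2",
        lambda c: (c.r2_correlation if c.r2_correlation is not None
                   else c.r2) > 0,
    )
    cons_flags = _method_flags("conservation_delta", "p_conservation",
                               lambda c: c.conservation_delta > 0)

    for c in gated:
        by = set()
        if z_flags.get(c.complex_id):
            by.add("Z")
        if r2_flags.get(c.complex_id):
            by.add("R2")
        if cons_flags.get(c.complex_id):
            by.add("CONS")
        flags[c.complex_id] = MethodFlags(
            complex_id=c.complex_id, nonfunctional_by=frozenset(by),
            stratum=c.stratum, gated=True,
        )
    return flags


@dataclass
class VennCounts:
    n_universe: int
    regions: dict[str, int]        # keys '100','010','001','110','101','011','111'
    percentages: dict[str, float]
    triple_percent: float
    at_least_two_percent: float


def venn_counts(set_a: set, set_b: set, set_c: set, n_universe: int) -> VennCounts:
    """All 7 Venn regions of three flag sets, as counts and percentages of
    the stratum size."""
    if n_universe < 1:
        raise ValueError("empty stratum")
    a, b, c = set(set_a), set(set_b), set(set_c)
    regions = {
        "111": len(a & b & c),
        "110": len((a & b) - c),
        "101": len((a & c) - b),
        "011": len((b & c) - a),
        "100": len(a - b - c),
        "010": len(b - a - c),
        "001": len(c - a - b),
    }
    if len(a | b | c) > n_universe:
        raise ValueError("flag sets exceed the stratum size")
    pct = {k: 100.0 * v / n_universe for k, v in regions.items()}
    triple = pct["111"]
    at_least_two = pct["111"] + pct["110"] + pct["101"] + pct["011"]
    return VennCounts(
        n_universe=n_universe, regions=regions, percentages=pct,
        triple_percent=triple, at_least_two_percent=at_least_two,
    )


@dataclass
class OverlapSummary:
    sizes: tuple[int, ...]
    n_universe: int
    n_reps: int
    seed: int
    triple_mean: float
    triple_sd: float
    at_least_two_mean: float
    at_least_two_sd: float
    pairwise_mean: dict[str, float]
    pairwise_sd: dict[str, float]
    triple_analytic: float


def random_overlap_expectation(
    sizes: Sequence[int],
    n_universe: int,
    n_reps: int = 1000,
    seed: int = 0,
) -> OverlapSummary:
    """Random expectation (mean ± SD) of set overlaps at fixed set sizes.

    Per replicate, three uniform subsets are drawn without replacement and
    the triple, ≥2-of-3 and pairwise overlap percentages recorded.  The
    analytic triple expectation 100·∏(size/N) is reported alongside.
    """
    sizes = tuple(int(s) for s in sizes)
    if len(sizes) != 3:
        raise ValueError("expected exactly three set sizes")
    if any(s > n_universe or s < 0 for s in sizes):
        raise ValueError("set sizes must lie in [0, universe size]")
    rng = np.random.default_rng(seed)
    triple = np.empty(n_reps)
    atleast2 = np.empty(n_reps)
    pair_keys = ("ab", "ac", "bc")
    pairwise = {k: np.empty(n_reps) for k in pair_keys}
    for rep in range(n_reps):
        member = np.zeros((3, n_universe), dtype=bool)
        for k, size in enumerate(sizes):
            member[k, rng.permutation(n_universe)[:size]] = True
        counts = member.sum(axis=0)
        triple[rep] = 100.0 * np.mean(counts == 3)
        atleast2[rep] = 100.0 * np.mean(counts >= 2)
        pairwise["ab"][rep] = 100.0 * np.mean(member[0] & member[1])
        pairwise["ac"][rep] = 100.0 * np.mean(member[0] & member[2])
        pairwise["bc"][rep] = 100.0 * np.mean(member[1] & member[2])
    analytic = 100.0 * np.prod([s / n_universe for s in sizes])
    return OverlapSummary(
        sizes=sizes, n_universe=n_universe, n_reps=n_reps, seed=seed,
        triple_mean=float(triple.mean()), triple_sd=float(triple.std(ddof=1)),
        at_least_two_mean=float(atleast2.mean()),
        at_least_two_sd=float(atleast2.std(ddof=1)),
        pairwise_mean={k: float(v.mean()) for k, v in pairwise.items()},
        pairwise_sd={k: float(v.std(ddof=1)) for k, v in pairwise.items()},
        triple_analytic=float(analytic),
    )


def ancova_effect(
    data: pd.DataFrame,
    response: str,
    covariates: Sequence[str],
    factor: str,
    alpha: float = ALPHA,
    log_covariates: bool = True,
) -> pd.DataFrame:
    """Type-III ANCOVA of ``response`` on a two-level factor with
    log-transformed covariates and backwards elimination.

    The least significant covariate with p > alpha is removed iteratively;
    the factor is never removed.  Returns the final ANOVA table with a
    ``retained`` covariate list in ``DataFrame.attrs``.
    """
    if len(data) < 10:
        raise ValueError("need >= 10 complexes for ANCOVA")
    df = data.copy()
    covariates = list(covariates)
    for cov in covariates:
        if log_covariates:
            if (df[cov] <= 0).any():
                raise ValueError(f"covariate {cov!r} must be positive for log")
            df[f"log_{cov}"] = np.log(df[cov])
        else:
            df[f"log_{cov}"] = df[cov]

    terms = [f"log_{c}" for c in covariates]
    design = df[terms]
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(df)), design]))
    if rank < len(terms) + 1:
        corr = design.corr().abs()
        np.fill_diagonal(corr.values, 0)
        pairs = corr.stack().sort_values(ascending=False).head(3)
        raise ValueError(f"collinear design; strongest aliases: {pairs.to_dict()}")

    while True:
        formula = f"{response} ~ C({factor}, Sum)"
        if terms:
            formula += " + " + " + ".join(terms)
        model = ols(formula, data=df).fit()
        table = anova_lm(model, typ=3)
        cov_p = {
            t: float(table.loc[t, "PR(>F)"]) for t in terms if t in table.index
        }
        if not cov_p:
            break
        worst = max(cov_p, key=cov_p.get)
        if cov_p[worst] > alpha:
            terms.remove(worst)
        else:
            break
    table = table.copy()
    table.attrs["retained"] = [t.removeprefix("log_") for t in terms]
    table.attrs["factor_p"] = float(table.loc[f"C({factor}, Sum)", "PR(>F)"])
    table.attrs["model"] = model
    return table


def proportion_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided two-sample test of proportions (chi-square with continuity
    correction); returns the p-value."""
    if n1 == 0 or n2 == 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        return 1.0
    _, p, _, _ = chi2_contingency(table, correction=True)
    return float(p)
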