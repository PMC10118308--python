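"""Synthetic inputs with planted ground truth.

Toy dimers are two grids of residues (Cα plus one sidechain pseudo-atom on
a 3.8 Å lattice).  Row 0 of each chain faces the other chain across an 8 Å
gap, with sidechain atoms reaching inward so that exactly the row-0
residues are in inter-chain contact; chain B's columns are mirrored so the
interface is antiparallel and cross-interface contacts pair *distinct*
sequence positions.  MBS ligands sit in the gap (occluding row-0 sidechains
of both chains); SBS ligands sit on chain A's outer face at a configurable
row offset, so MBS ligands are closer to the interface by construction.

Coupling tables are i.i.d. lognormal baselines with designated pair classes
shifted by effect sizes expressed in baseline-SD units; conservation scores
are standard normal with a planted interface shift; variant tables draw
alternate alleles from a spectrum with a configurable cysteine excess.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .structure_annotation import AA_1TO3, AMINO_ACIDS, write_pdb
from .structure_annotation.sasa import shrake_rupley

DX = 3.8            # lattice spacing, Å (Cα–Cα contact at probe >= 0.2)
GAP = 8.0           # inter-chain Cα plane separation, Å
CB_REACH = 2.3      # sidechain pseudo-atom offset from Cα, Å
LIG_Z_MBS = GAP / 2.0
LIG_Z_SBS = -4.0


@dataclass(frozen=True)
class DimerSpec:
    n_residues: int = 60            # per chain
    interface_width: int = 20       # residues per chain in the interface row
    ligand_mode: str = "SBS"        # "MBS" | "SBS"
    n_mbs_sites: int = 1
    site_width: int = 5             # LBR columns per binding site
    ligand_offset: float = 7.6      # SBS ligand row offset from interface, Å
    seed: int = 0

    @property
    def n_rows(self) -> int:
        return -(-self.n_residues // self.interface_width)


@dataclass(frozen=True)
class SignalSpec:
    baseline_meanlog: float = -1.0
    baseline_sdlog: float = 0.5
    cross_interface: float = 0.0    # effect sizes in baseline-SD units
    lbr_interface: float = 0.0
    lbr_lbr: float = 0.0
    conservation_shift: float = 0.0
    cysteine_factor: float = 1.0
    motion_align: bool = True
    spatial_decay: float = 10.0     # Å, for the motion-coupling gradient
    neff_over_l: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for name in ("cross_interface", "lbr_interface", "lbr_lbr",
                     "conservation_shift"):
            if getattr(self, name) < 0:
                raise ValueError(f"effect {name} must be >= 0")

    @property
    def baseline_sd(self) -> float:
        s2 = self.baseline_sdlog ** 2
        return float(
            np.sqrt(np.expm1(s2)) * np.exp(self.baseline_meanlog + s2 / 2)
        )


EFFECT_PRESETS: dict[str, SignalSpec] = {
    "null": SignalSpec(lbr_lbr=3.0),
    "strong": SignalSpec(cross_interface=2.0, lbr_interface=3.0,
                         lbr_lbr=3.0, conservation_shift=1.0,
                         cysteine_factor=4.0),
}


def _grid_position(index: int, width: int) -> tuple[int, int]:
    return index // width, index % width


def residue_ca(index: int, width: int, chain: str) -> np.ndarray:
    """Cα coordinate of residue ``index`` (0-based) on chain A or B."""
    row, col = _grid_position(index, width)
    if chain == "B":
        col = width - 1 - col
        return np.array([col * DX, row * DX, GAP])
    return np.array([col * DX, row * DX, 0.0])


def _residue_atoms(index: int, width: int, chain: str):
    row, _ = _grid_position(index, width)
    ca = residue_ca(index, width, chain)
    sign = 1.0 if chain == "A" else -1.0
    inward = row == 0
    cb_z = ca[2] + (sign * CB_REACH if inward else -sign * CB_REACH)
    cb = np.array([ca[0], ca[1], cb_z])
    return [("CA", "C", ca), ("CB", "C", cb)]


def _site_columns(spec: DimerSpec) -> list[list[int]]:
    w, sw = spec.interface_width, spec.site_width
    if sw > w:
        raise ValueError("site width exceeds interface width")
    if spec.ligand_mode == "MBS" and spec.n_mbs_sites == 2:
        if 2 * sw + 2 > w:
            raise ValueError("two binding sites do not fit the interface")
        return [list(range(1, 1 + sw)),
                list(range(w - 1 - sw, w - 1))]
    center = (w - sw) // 2
    return [list(range(center, center + sw))]


@lru_cache(maxsize=8)
def toy_rsa_reference(probe_radius: float = 0.21,
                      n_points: int = 960) -> float:
    """SASA of one isolated toy residue (Cα + sidechain pseudo-atom)."""
    coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, CB_REACH]])
    radii = np.array([1.7, 1.7])
    return float(shrake_rupley(coords, radii, probe_radius, n_points).sum())


def generate_dimer(spec: DimerSpec) -> tuple[str, dict]:
    """PDB text plus a ground-truth sidecar for one planted dimer."""
    n, w = spec.n_residues, spec.interface_width
    if w > n:
        raise ValueError("interface width exceeds chain length")
    if spec.ligand_mode not in ("MBS", "SBS"):
        raise ValueError(f"unknown ligand mode {spec.ligand_mode!r}")
    rng = np.random.default_rng(spec.seed)
    sequence = "".join(rng.choice(AMINO_ACIDS, size=n))

    chains = {}
    for chain in ("A", "B"):
        chains[chain] = [
            (i + 1, AA_1TO3[sequence[i]], _residue_atoms(i, w, chain))
            for i in range(n)
        ]

    sites = _site_columns(spec)
    ligands = []
    truth_ligands = {}
    lig_columns: set[int] = set()
    if spec.ligand_mode == "SBS":
        r_lig = int(round(spec.ligand_offset / DX))
        if r_lig < 1 or r_lig > spec.n_rows - 1:
            raise ValueError(
                f"ligand offset {spec.ligand_offset} Å infeasible for "
                f"{spec.n_rows} rows"
            )
    for s_idx, cols in enumerate(sites):
        resnum = 900 + s_idx
        if spec.ligand_mode == "MBS":
            atoms = [("C1", "C", np.array([c * DX, 0.0, LIG_Z_MBS]))
                     for c in cols]
            lbrs_a = [c + 1 for c in cols]
            lbrs_b = [w - c for c in cols]   # mirrored column -> residue num
            lbr_cols = sorted({c for c in cols} | {w - 1 - c for c in cols})
            site_type = "MBS"
            truth_lbrs = {"A": sorted(lbrs_a), "B": sorted(lbrs_b)}
        else:
            atoms = [("C1", "C",
                      np.array([c * DX, r_lig * DX, LIG_Z_SBS]))
                     for c in cols]
            idx = [r_lig * w + c for c in cols]
            if any(i >= n for i in idx):
                raise ValueError("SBS binding site falls outside the chain")
            site_type = "SBS"
            truth_lbrs = {"A": sorted(i + 1 for i in idx), "B": []}
            lbr_cols = sorted(idx)
        ligands.append(("LIG", "L", resnum, atoms))
        truth_ligands[f"LIG_L{resnum}"] = {
            "site_type": site_type,
            "lbrs": truth_lbrs,
            "columns": sorted(lbr_cols),
        }
        lig_columns |= set(lbr_cols)

    pdb_text = write_pdb(chains, ligands)
    interface_resnums = list(range(1, w + 1))
    lbr_resnums = {
        chain: sorted({r for lig in truth_ligands.values()
                       for r in lig["lbrs"][chain]})
        for chain in ("A", "B")
    }
    surface = {
        chain: [i + 1 for i in range(w, n)
                if i + 1 not in lbr_resnums[chain]]
        for chain in ("A", "B")
    }
    truth = {
        "spec": {
            "n_residues": n, "interface_width": w,
            "ligand_mode": spec.ligand_mode,
            "n_mbs_sites": spec.n_mbs_sites if spec.ligand_mode == "MBS" else 0,
            "site_width": spec.site_width,
            "ligand_offset": spec.ligand_offset, "seed": spec.seed,
        },
        "sequence": sequence,
        "interface": {"A": interface_resnums, "B": interface_resnums},
        "interface_columns": list(range(w)),
        "ligands": truth_ligands,
        "lbr_columns": sorted(lig_columns),
        "surface": surface,
        "complex_class": "MBS" if spec.ligand_mode == "MBS" else "SBS",
        "rsa_reference": dict.fromkeys(AMINO_ACIDS, toy_rsa_reference()),
    }
    return pdb_text, truth


def _pair_index(truth: dict) -> dict[str, list[tuple[int, int]]]:
    """0-based column pair classes used for planting effects."""
    w = truth["spec"]["interface_width"]
    interface = truth["interface_columns"]
    lbr = truth["lbr_columns"]
    cross = sorted(
        {(min(c, w - 1 - c), max(c, w - 1 - c))
         for c in range(w) if c != w - 1 - c}
    )
    lbr_interface = sorted(
        {(min(l, i), max(l, i)) for l in lbr for i in interface if l != i}
    )
    lbr_lbr = sorted(
        {(min(a, b), max(a, b)) for a in lbr for b in lbr if a != b}
    )
    return {"cross": cross, "lbr_interface": lbr_interface,
            "lbr_lbr": lbr_lbr}


def generate_couplings(
    signal: SignalSpec, truth: dict
) -> tuple[pd.DataFrame, dict]:
    """Coupling table (columns i, j, cn; 1-based) plus alignment stats."""
    n = truth["spec"]["n_residues"]
    rng = np.random.default_rng(signal.seed)
    iu, ju = np.triu_indices(n, k=1)
    scores = rng.lognormal(signal.baseline_meanlog, signal.baseline_sdlog,
                           size=iu.size)
    mat = np.zeros((n, n))
    mat[iu, ju] = scores
    sd = signal.baseline_sd
    classes = _pair_index(truth)

    if signal.cross_interface > 0:
        for a, b in classes["cross"]:
            mat[a, b] += signal.cross_interface * sd

    if signal.lbr_interface > 0:
        weights = _interface_weights(signal, truth)
        for a, b in classes["lbr_interface"]:
            i_col = a if a in weights else b
            mat[min(a, b), max(a, b)] += (
                signal.lbr_interface * sd * weights.get(i_col, 1.0)
            )

    if signal.lbr_lbr > 0:
        for a, b in classes["lbr_lbr"]:
            mat[a, b] += signal.lbr_lbr * sd

    df = pd.DataFrame({"i": iu + 1, "j": ju + 1, "cn": mat[iu, ju]})
    stats = {"neff": signal.neff_over_l * n, "L": n}
    return df, stats


def _interface_weights(signal: SignalSpec, truth: dict) -> dict[int, float]:
    """Per-interface-column weights (mean 1) decaying with distance to the
    binding-site centroid; flat when motion alignment is off."""
    interface = truth["interface_columns"]
    if not signal.motion_align:
        return {c: 1.0 for c in interface}
    w = truth["spec"]["interface_width"]
    lbr_coords = np.array([
        residue_ca(c, w, "A") for c in truth["lbr_columns"]
    ])
    centroid = lbr_coords.mean(axis=0)
    d = np.array([
        np.linalg.norm(residue_ca(c, w, "A") - centroid) for c in interface
    ])
    raw = np.exp(-d / signal.spatial_decay)
    raw /= raw.mean()
    return dict(zip(interface, raw))


def generate_conservation(signal: SignalSpec, truth: dict) -> pd.DataFrame:
    """Per-residue scores: N(0,1), interface shifted down (more conserved)."""
    rng = np.random.default_rng(signal.seed + 1)
    n = truth["spec"]["n_residues"]
    interface = {r for r in truth["interface"]["A"]}
    rows = []
    for chain in ("A", "B"):
        for resnum in range(1, n + 1):
            score = rng.normal()
            if resnum in interface:
                score -= signal.conservation_shift
            rows.append({"chain": chain, "resnum": resnum, "score": score})
    return pd.DataFrame(rows)


def variant_spectrum(cysteine_factor: float = 1.0) -> pd.Series:
    """Alt-allele spectrum: p(C) = factor/20, the rest sharing the
    remainder, so the cysteine enrichment over a uniform region is exactly
    ``cysteine_factor``."""
    if not 0 < cysteine_factor < 20:
        raise ValueError("cysteine factor must lie in (0, 20)")
    p_cys = cysteine_factor / 20.0
    spectrum = pd.Series((1.0 - p_cys) / 19.0, index=AMINO_ACIDS)
    spectrum["C"] = p_cys
    return spectrum


def generate_variants(
    signal: SignalSpec, truth: dict, n_variants: int
) -> pd.DataFrame:
    """Uniform positions on chain A; alt alleles from the spectrum."""
    if n_variants < 1:
        raise ValueError("need n >= 1 variants")
    rng = np.random.default_rng(signal.seed + 2)
    seq = truth["sequence"]
    spectrum = variant_spectrum(signal.cysteine_factor)
    rows = []
    for _ in range(n_variants):
        pos = int(rng.integers(1, len(seq) + 1))
        ref = seq[pos - 1]
        probs = spectrum.drop(ref)
        probs = probs / probs.sum()
        alt = str(rng.choice(probs.index, p=probs.to_numpy()))
        rows.append({"position": pos, "ref": ref, "alt": alt})
    return pd.DataFrame(rows)


def generate_network(redundant: bool) -> dict:
    """Linear uptake→conversion→sink chain; optionally a parallel isoenzyme
    branch under a different gene."""
    reactions = [
        {"id": "SRC", "stoichiometry": {"A": 1.0},
         "lower_bound": 0.0, "upper_bound": 10.0, "gpr": ""},
        {"id": "CONV1", "stoichiometry": {"A": -1.0, "B": 1.0},
         "lower_bound": 0.0, "upper_bound": 10.0, "gpr": "g_main"},
        {"id": "SNK", "stoichiometry": {"B": -1.0},
         "lower_bound": 0.0, "upper_bound": 10.0, "gpr": ""},
    ]
    if redundant:
        reactions.insert(2, {
            "id": "CONV2", "stoichiometry": {"A": -1.0, "B": 1.0},
            "lower_bound": 0.0, "upper_bound": 10.0, "gpr": "g_iso",
        })
    return {
        "metabolites": [{"id": "A", "boundary": False},
                        {"id": "B", "boundary": False}],
        "reactions": reactions,
    }


@dataclass
class CohortMember:
    complex_id: str
    complex_class: str
    functional: bool
    directory: Path


def generate_cohort(
    n_mbs: int,
    n_sbs: int,
    functional_fraction: float,
    effects: SignalSpec | str = "strong",
    seed: int = 0,
    out_dir: str | Path = ".",
    dimer_spec: DimerSpec | None = None,
    n_variants: int = 50,
) -> tuple[list[CohortMember], pd.DataFrame]:
    """Write a full per-complex input bundle plus a truth table.

    Planted-functional complexes get the requested effect profile;
    planted-gratuitous complexes have the three functionality effects zeroed
    (the LBR–LBR effect is kept so the flagging gate passes).
    """
    if isinstance(effects, str):
        effects = EFFECT_PRESETS[effects]
    base_spec = dimer_spec or DimerSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    members = []
    rows = []
    plan = [("MBS", k) for k in range(n_mbs)] + [
        ("SBS", k) for k in range(n_sbs)
    ]
    for idx, (cls, k) in enumerate(plan):
        n_class = n_mbs if cls == "MBS" else n_sbs
        functional = k < round(functional_fraction * n_class)
        complex_id = f"{cls.lower()}_{k:03d}"
        cdir = out_dir / complex_id
        cdir.mkdir(exist_ok=True)
        dspec = replace(
            base_spec, ligand_mode=cls,
            n_mbs_sites=base_spec.n_mbs_sites if cls == "MBS" else 1,
            seed=seed * 100003 + idx,
        )
        sig = replace(
            effects,
            cross_interface=effects.cross_interface if functional else 0.0,
            lbr_interface=effects.lbr_interface if functional else 0.0,
            conservation_shift=(effects.conservation_shift
                                if functional else 0.0),
            seed=seed * 200003 + idx,
        )
        pdb_text, truth = generate_dimer(dspec)
        couplings, stats = generate_couplings(sig, truth)
        conservation = generate_conservation(sig, truth)
        variants = generate_variants(sig, truth, n_variants)
        (cdir / "structure.pdb").write_text(pdb_text)
        (cdir / "truth.json").write_text(json.dumps(truth, indent=1))
        (cdir / "rsa_reference.json").write_text(
            json.dumps(truth["rsa_reference"])
        )
        couplings.to_csv(cdir / "couplings.csv", index=False)
        (cdir / "alignment_stats.json").write_text(json.dumps(stats))
        conservation.to_csv(cdir / "conservation.tsv", sep="\t", index=False)
        variants.to_csv(cdir / "variants.tsv", sep="\t", index=False)
        members.append(CohortMember(complex_id, cls, functional, cdir))
        rows.append({"complex_id": complex_id, "complex_class": cls,
                     "functional": functional})
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "truth_table.tsv", sep="\t", index=False)
    return members, table
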