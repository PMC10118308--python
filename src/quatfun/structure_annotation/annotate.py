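"""Residue-level annotation of homodimer biounits.

Interface residues are inter-chain contacts under a probe-augmented van der
Waals criterion; ligand-binding residues (LBRs) are residues whose SASA
changes when a ligand is removed; surface residues are the unannotated
residues with relative solvent accessibility above 0.2.  Binding sites are
classified as multichain (MBS) or single-chain (SBS) by the chains their
LBRs touch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .pdb import LigandRecord, ResidueKey, StructureModel
from .radii import HYDROPHOBIC_SET
from .sasa import shrake_rupley

DEFAULT_CONTACT_PROBE = 0.25
DEFAULT_SASA_PROBE = 0.21
LBR_SASA_TOLERANCE = 1e-3
RSA_SURFACE_THRESHOLD = 0.2


@dataclass
class ContactMap:
    """Residue-pair contacts plus residue→ligand contacts."""

    residue_pairs: set[frozenset]
    ligand_contacts: dict[str, set[ResidueKey]]
    probe_radius: float

    def partners(self, key: ResidueKey) -> set[ResidueKey]:
        out = set()
        for pair in self.residue_pairs:
            if key in pair:
                (other,) = pair - {key}
                out.add(other)
        return out


@dataclass
class BindingSiteProfile:
    ligand_id: str
    lbr_set: frozenset
    chains_touched: frozenset
    site_type: str  # "MBS" | "SBS"
    distance_to_interface: float | None = None


@dataclass
class ComplexTopology:
    interface_residues: dict[str, list[ResidueKey]]
    interface_size: int
    n_mbs_sites: int = 0
    complex_class: str | None = None


@dataclass
class ResidueAnnotation:
    residue: ResidueKey
    aa: str
    is_interface: bool = False
    is_surface: bool = False
    lbr_of: set = field(default_factory=set)
    sasa: float = float("nan")
    rsa: float = float("nan")

    @property
    def is_lbr(self) -> bool:
        return bool(self.lbr_of)


def compute_contacts(
    s: StructureModel, probe_radius: float = DEFAULT_CONTACT_PROBE
) -> ContactMap:
    """Atoms i,j contact iff dist <= r_i + r_j + 2*probe; residue pairs
    contact iff any atom pair does."""
    if not s.atoms:
        raise ValueError("empty structure")
    coords = s.coords()
    radii = s.radii()
    res_keys = [a.residue for a in s.atoms]
    tree = cKDTree(coords)
    max_r = float(radii.max())
    cutoff = 2.0 * max_r + 2.0 * probe_radius

    pairs: set[frozenset] = set()
    for i, j in tree.query_pairs(cutoff):
        if res_keys[i] == res_keys[j]:
            continue
        thresh = radii[i] + radii[j] + 2.0 * probe_radius
        if np.linalg.norm(coords[i] - coords[j]) <= thresh:
            pairs.add(frozenset((res_keys[i], res_keys[j])))

    ligand_contacts: dict[str, set[ResidueKey]] = {}
    for lig in s.ligands:
        touched: set[ResidueKey] = set()
        for atom in lig.atoms:
            lr = atom.vdw_radius
            idx = tree.query_ball_point(atom.coord, lr + max_r + 2 * probe_radius)
            for i in idx:
                thresh = radii[i] + lr + 2.0 * probe_radius
                if np.linalg.norm(coords[i] - np.array(atom.coord)) <= thresh:
                    touched.add(res_keys[i])
        ligand_contacts[lig.ligand_id] = touched
    return ContactMap(pairs, ligand_contacts, probe_radius)


def identify_interface(s: StructureModel, contacts: ContactMap) -> ComplexTopology:
    """Interface = residues in direct inter-chain protein contact.

    Ligand-only contacts never qualify (the contact map here contains only
    protein-protein residue pairs, so the exclusion is structural).
    """
    if len(s.chains) < 2:
        raise ValueError("interface analysis requires >= 2 protein chains")
    per_chain: dict[str, set[ResidueKey]] = {c: set() for c in s.chains}
    for pair in contacts.residue_pairs:
        a, b = tuple(pair)
        if a.chain != b.chain:
            per_chain[a.chain].add(a)
            per_chain[b.chain].add(b)
    size = sum(len(v) for v in per_chain.values())
    if size == 0:
        warnings.warn("no inter-chain contacts: empty interface", stacklevel=2)
    ordered = {c: sorted(per_chain[c]) for c in s.chains}
    return ComplexTopology(interface_residues=ordered, interface_size=size)


def compute_sasa(
    s: StructureModel,
    probe_radius: float = DEFAULT_SASA_PROBE,
    include_ligands: bool = False,
    exclude_ligand: str | None = None,
    n_points: int = 960,
) -> tuple[np.ndarray, dict[ResidueKey, float]]:
    """Per-atom and per-residue SASA of the protein.

    With ``include_ligands`` the (non-water) ligand atoms occlude solvent;
    ``exclude_ligand`` removes one ligand from the occluder set.
    """
    occ_coords = None
    occ_radii = None
    if include_ligands:
        keep = [
            lig for lig in s.ligands if lig.ligand_id != exclude_ligand
        ]
        if keep:
            occ_coords = np.vstack([lig.coords for lig in keep])
            occ_radii = np.concatenate([lig.radii for lig in keep])
    atom_areas = shrake_rupley(
        s.coords(), s.radii(), probe_radius, n_points,
        occluder_coords=occ_coords, occluder_radii=occ_radii,
    )
    per_residue: dict[ResidueKey, float] = {}
    for atom, area in zip(s.atoms, atom_areas):
        per_residue[atom.residue] = per_residue.get(atom.residue, 0.0) + area
    return atom_areas, per_residue


def identify_ligand_binding_residues(
    s: StructureModel,
    ligand: LigandRecord | str,
    probe_radius: float = DEFAULT_SASA_PROBE,
    tol: float = LBR_SASA_TOLERANCE,
    n_points: int = 960,
) -> frozenset:
    """Residues whose SASA changes by more than ``tol`` when ``ligand`` is
    removed (all other relevant ligands stay as occluders)."""
    if isinstance(ligand, str):
        ligand = s.get_ligand(ligand)
    if ligand.is_metal:
        raise ValueError(
            f"metal ligand {ligand.ligand_id!r}: metal ligands are excluded"
        )
    _, with_lig = compute_sasa(s, probe_radius, include_ligands=True,
                               n_points=n_points)
    _, without_lig = compute_sasa(
        s, probe_radius, include_ligands=True,
        exclude_ligand=ligand.ligand_id, n_points=n_points,
    )
    return frozenset(
        key for key in with_lig
        if abs(without_lig[key] - with_lig[key]) > tol
    )


def classify_binding_site(
    lbr_set: frozenset, ligand_id: str = ""
) -> BindingSiteProfile:
    """MBS iff the LBRs span >= 2 chains, else SBS."""
    if not lbr_set:
        raise ValueError("empty ligand-binding residue set")
    chains = frozenset(key.chain for key in lbr_set)
    site_type = "MBS" if len(chains) >= 2 else "SBS"
    return BindingSiteProfile(
        ligand_id=ligand_id,
        lbr_set=frozenset(lbr_set),
        chains_touched=chains,
        site_type=site_type,
    )


def identify_surface(
    s: StructureModel,
    residue_sasa: dict[ResidueKey, float],
    rsa_reference: dict[str, float],
    interface: set | frozenset = frozenset(),
    lbrs: set | frozenset = frozenset(),
    threshold: float = RSA_SURFACE_THRESHOLD,
) -> tuple[frozenset, dict[ResidueKey, float]]:
    """Surface = RSA > threshold and neither interface nor LBR.

    Returns the surface set and the per-residue RSA map.  ``rsa_reference``
    maps one-letter amino acid to its reference (Gly-X-Gly) SASA.
    """
    rsa: dict[ResidueKey, float] = {}
    surface = set()
    for key, area in residue_sasa.items():
        aa = s.sequence1(key)
        if aa not in rsa_reference:
            raise KeyError(
                f"amino acid {aa!r} (residue {key}) missing from RSA reference"
            )
        rsa[key] = area / rsa_reference[aa]
        if rsa[key] > threshold and key not in interface and key not in lbrs:
            surface.add(key)
    return frozenset(surface), rsa


def ligand_interface_distance(
    s: StructureModel,
    interface: set | frozenset,
    lbr_set: set | frozenset,
    policy: str = "nearest-lbr",
) -> float:
    """Average distance (Å) of the interface from the ligand-binding site.

    ``nearest-lbr``: mean over interface residues of the distance to their
    closest LBR.  ``all-pairs``: mean over every interface × LBR pair.
    Residue–residue distance is the minimum heavy-atom distance.
    """
    if not interface or not lbr_set:
        raise ValueError("interface and LBR sets must both be nonempty")
    residues = s.residues()

    def heavy_coords(key: ResidueKey) -> np.ndarray:
        return np.array(
            [a.coord for a in residues[key] if a.element != "H"], dtype=float
        )

    lbr_coords = [heavy_coords(k) for k in sorted(lbr_set) if k in residues]
    if not lbr_coords:
        raise ValueError("no LBR residues found in structure")
    dists = []
    for key in sorted(interface):
        if key not in residues:
            continue
        ic = heavy_coords(key)
        per_lbr = [
            float(np.sqrt(
                ((ic[:, None, :] - lc[None, :, :]) ** 2).sum(-1)
            ).min())
            for lc in lbr_coords
        ]
        if policy == "nearest-lbr":
            dists.append(min(per_lbr))
        elif policy == "all-pairs":
            dists.extend(per_lbr)
        else:
            raise ValueError(f"unknown distance policy {policy!r}")
    if not dists:
        raise ValueError("no interface residues found in structure")
    return float(np.mean(dists))


def hydrophobic_fraction(aa_sequence) -> float:
    """Fraction of residues in the C/F/I/L/M/V/Y hydrophobic set."""
    seq = list(aa_sequence)
    if not seq:
        raise ValueError("empty residue set")
    return sum(1 for aa in seq if aa in HYDROPHOBIC_SET) / len(seq)


def annotate_structure(
    s: StructureModel,
    contact_probe: float = DEFAULT_CONTACT_PROBE,
    sasa_probe: float = DEFAULT_SASA_PROBE,
    rsa_reference: dict[str, float] | None = None,
    n_points: int = 960,
    distance_policy: str = "nearest-lbr",
):
    """Run the full annotation pipeline on one structure.

    Returns (topology, annotations, binding_sites, contacts).
    """
    from .radii import MAX_SASA_GXG

    rsa_reference = rsa_reference if rsa_reference is not None else MAX_SASA_GXG
    contacts = compute_contacts(s, contact_probe)
    topology = identify_interface(s, contacts)
    interface_all = {
        key for keys in topology.interface_residues.values() for key in keys
    }

    sites: list[BindingSiteProfile] = []
    all_lbrs: set[ResidueKey] = set()
    for lig in s.ligands:
        if lig.is_metal or not lig.is_biologically_relevant:
            continue
        lbrs = identify_ligand_binding_residues(
            s, lig, probe_radius=sasa_probe, n_points=n_points
        )
        if not lbrs:
            continue
        profile = classify_binding_site(lbrs, lig.ligand_id)
        if interface_all:
            profile.distance_to_interface = ligand_interface_distance(
                s, interface_all, lbrs, policy=distance_policy
            )
        sites.append(profile)
        all_lbrs |= lbrs

    topology.n_mbs_sites = sum(1 for p in sites if p.site_type == "MBS")
    topology.complex_class = "MBS" if topology.n_mbs_sites >= 1 else "SBS"

    _, residue_sasa = compute_sasa(
        s, sasa_probe, include_ligands=False, n_points=n_points
    )
    surface, rsa = identify_surface(
        s, residue_sasa, rsa_reference, interface=interface_all, lbrs=all_lbrs
    )

    annotations: dict[ResidueKey, ResidueAnnotation] = {}
    for key in s.residue_keys():
        ann = ResidueAnnotation(
            residue=key,
            aa=s.sequence1(key),
            is_interface=key in interface_all,
            is_surface=key in surface,
            sasa=residue_sasa.get(key, float("nan")),
            rsa=rsa.get(key, float("nan")),
        )
        for profile in sites:
            if key in profile.lbr_set:
                ann.lbr_of.add(profile.ligand_id)
        annotations[key] = ann
    return topology, annotations, sites, contacts
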