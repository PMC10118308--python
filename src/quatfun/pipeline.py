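"""End-to-end orchestration over a directory of complex bundles.

Each complex directory holds ``structure.pdb``, ``couplings.csv``,
``alignment_stats.json``, ``conservation.tsv`` and optionally
``rsa_reference.json`` / ``variants.tsv`` (the layout written by
:mod:`quatfun.synthetic_data`).  Per-complex failures are isolated and
logged; outputs are TSV/JSON with the config hash and seed embedded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import classification, conservation, coevolution, dynamics
from .classification import ComplexScoreCard, assemble_scorecard
from .structure_annotation import annotate_structure, parse_structure

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    contact_probe: float = 0.25
    sasa_probe: float = 0.21
    sasa_points: int = 960
    interface_minimum: int = 40
    stratum_boundary: int = 100
    alpha: float = 0.05
    overlap_reps: int = 1000
    seed: int = 0
    transform: bool = True
    exclude_direct: bool = False
    distance_policy: str = "nearest-lbr"
    enm_cutoff: float = 15.0
    fva_mode: str = "max_abs"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def analyze_complex(directory: str | Path,
                    config: RunConfig = RunConfig()) -> ComplexScoreCard:
    """Annotate one complex bundle and compute all five statistics."""
    directory = Path(directory)
    complex_id = directory.name
    s = parse_structure((directory / "structure.pdb").read_text(),
                        structure_id=complex_id)

    rsa_reference = None
    ref_file = directory / "rsa_reference.json"
    if ref_file.exists():
        rsa_reference = json.loads(ref_file.read_text())

    topology, annotations, sites, contacts = annotate_structure(
        s,
        contact_probe=config.contact_probe,
        sasa_probe=config.sasa_probe,
        rsa_reference=rsa_reference,
        n_points=config.sasa_points,
        distance_policy=config.distance_policy,
    )
    interface = {k for keys in topology.interface_residues.values()
                 for k in keys}
    surface = {k for k, a in annotations.items() if a.is_surface}
    non_interface = {k for k in annotations if k not in interface}

    stats = json.loads((directory / "alignment_stats.json").read_text())
    pos_map = coevolution.homodimer_position_map(s)
    cm = coevolution.read_coupling_scores(
        directory / "couplings.csv", pos_map,
        length=int(stats["L"]), neff=float(stats["neff"]),
    )
    analyzable = coevolution.neff_filter(cm)

    fields: dict = dict(
        complex_class=topology.complex_class,
        n_mbs_sites=topology.n_mbs_sites,
        interface_size=topology.interface_size,
        structure_size=len(annotations),
        neff=cm.neff,
        analyzable=analyzable,
    )

    site_types = {p.ligand_id: p.site_type for p in sites}
    best_profile = None
    if analyzable and sites:
        zi = coevolution.interface_z(
            cm, interface, contacts, transform=config.transform,
            non_interface=non_interface,
        )
        fields.update(z_interface=zi.z, p_z_interface=zi.p_value)

        per_ligand: dict[str, coevolution.ZScoreResult] = {}
        for profile in sites:
            try:
                per_ligand[profile.ligand_id] = coevolution.ligand_interface_z(
                    cm, profile.lbr_set, interface, surface
                )
            except ValueError as exc:
                logger.info("%s: ligand %s skipped (%s)", complex_id,
                            profile.ligand_id, exc)
        if per_ligand:
            best_id = coevolution.select_best_ligand(
                {lid: r.z for lid, r in per_ligand.items()},
                site_types=site_types,
                complex_class=topology.complex_class,
            )
            best = per_ligand[best_id]
            best_profile = next(
                p for p in sites if p.ligand_id == best_id
            )
            fields.update(
                z_ligand=best.z, p_z_ligand=best.p_value,
                ligand_distance=best_profile.distance_to_interface,
            )
            zl = coevolution.lbr_coevolution_z(
                cm, best_profile.lbr_set, surface
            )
            fields.update(z_lbr=zl.z, p_z_lbr=zl.p_value)

    cons_file = directory / "conservation.tsv"
    if cons_file.exists():
        profile = conservation.read_conservation(
            cons_file, set(annotations)
        )
        cd = conservation.conservation_delta(profile, surface, interface)
        fields.update(conservation_delta=cd.delta, p_conservation=cd.p_value)

    if best_profile is not None:
        enm = dynamics.build_enm(s, cutoff=config.enm_cutoff)
        dccm = dynamics.compute_dccm(enm)
        r2 = dynamics.coupling_dynamics_r2(
            cm, dccm, interface, best_profile.lbr_set,
            exclude_direct=config.exclude_direct, contacts=contacts,
        )
        fields.update(r2=r2.r2, r2_correlation=r2.correlation,
                      p_r2=r2.p_value)

    return assemble_scorecard(complex_id, **fields)


def scorecards_frame(cards) -> pd.DataFrame:
    rows = []
    for card in cards:
        row = dataclasses.asdict(card)
        row["notes"] = ";".join(row["notes"])
        row["stratum"] = card.stratum
        row["excluded"] = card.excluded
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(in_dir: str | Path,
                 out_dir: str | Path,
                 config: RunConfig = RunConfig()) -> dict:
    """Run every complex bundle under ``in_dir``; write reports to
    ``out_dir``.  Returns the report dict."""
    in_dir = Path(in_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundles = sorted(
        d for d in in_dir.iterdir()
        if d.is_dir() and (d / "structure.pdb").exists()
    )
    if not bundles:
        raise ValueError(f"no complex bundles under {in_dir}")

    cards: list[ComplexScoreCard] = []
    failures: dict[str, str] = {}
    for bundle in bundles:
        try:
            cards.append(analyze_complex(bundle, config))
        except Exception as exc:   # isolate per-complex failures
            logger.warning("%s failed: %s", bundle.name, exc)
            failures[bundle.name] = str(exc)

    flags = classification.flag_cohort(cards, alpha=config.alpha)
    cards_df = scorecards_frame(cards)
    cards_df.to_csv(out_dir / "scorecards.tsv", sep="\t", index=False)

    flag_rows = [
        {
            "complex_id": f.complex_id,
            "gated": f.gated,
            "stratum": f.stratum,
            "flag_Z": "Z" in f.nonfunctional_by,
            "flag_R2": "R2" in f.nonfunctional_by,
            "flag_CONS": "CONS" in f.nonfunctional_by,
            "n_flags": len(f.nonfunctional_by),
        }
        for f in flags.values()
    ]
    flags_df = pd.DataFrame(flag_rows)
    flags_df.to_csv(out_dir / "flags.tsv", sep="\t", index=False)

    overlap_report = {}
    by_card = {c.complex_id: c for c in cards}
    for cls in ("MBS", "SBS"):
        for stratum in ("lt100", "ge100"):
            members = [
                f for f in flags.values()
                if f.gated and f.stratum == stratum
                and by_card[f.complex_id].complex_class == cls
            ]
            if not members:
                continue
            sets = {
                m: {f.complex_id for f in members
                    if m in f.nonfunctional_by}
                for m in classification.METHODS
            }
            n = len(members)
            venn = classification.venn_counts(
                sets["Z"], sets["R2"], sets["CONS"], n
            )
            expectation = classification.random_overlap_expectation(
                [len(sets[m]) for m in classification.METHODS], n,
                n_reps=config.overlap_reps, seed=config.seed,
            )
            overlap_report[f"{cls}_{stratum}"] = {
                "n": n,
                "regions": venn.regions,
                "triple_percent": venn.triple_percent,
                "at_least_two_percent": venn.at_least_two_percent,
                "random_triple": [expectation.triple_mean,
                                  expectation.triple_sd],
                "random_at_least_two": [expectation.at_least_two_mean,
                                        expectation.at_least_two_sd],
            }

    exclusions = {
        c.complex_id: [n for n in c.notes if n.startswith("excluded")]
        for c in cards if c.excluded or not c.analyzable
    }
    report = {
        "config": json.loads(config.to_json()),
        "config_hash": config.hash,
        "seed": config.seed,
        "n_complexes": len(cards),
        "failures": failures,
        "exclusions": exclusions,
        "overlaps": overlap_report,
    }
    (out_dir / "overlap.json").write_text(json.dumps(report, indent=1))
    return report
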