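"""End-to-end orchestration: ingest → renumber → filter → score → rank,
plus the single-residue environment report that joins contacts,
conservation and variant annotations.

All outputs are plain TSV/JSON, deterministic under a fixed config, and
stamped with the hash of the config that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import conservation as cons
from . import variants as var
from .curation_rank import (
    ScoringWeights,
    StructureScore,
    collect_metadata,
    rank_table,
    read_remark_table,
    score_structure,
)
from .interactions import GeometryConfig, residue_environment_report
from .io_structures import (
    Method,
    StructureModel,
    classify_entities,
    read_ligand_dict,
    read_structure,
)
from .reference_map import (
    AlignmentError,
    FilterConfig,
    FilterDecision,
    ReferenceSequence,
    RenumberedChain,
    align_chain_to_reference,
    apply_structure_filters,
    mapping_table,
    read_reference_fasta,
    renumber_chain,
)

log = logging.getLogger("strucmap")

CONFIG_SCHEMA_VERSION = 1


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    structures_dir: str
    reference_fasta: str
    output_dir: str = "strucmap_out"
    msa_path: Optional[str] = None
    msa_format: str = "aligned-fasta"
    variant_table: Optional[str] = None
    ligand_dict: Optional[str] = None
    remark_table: Optional[str] = None
    peptide_max_len: int = 30
    #: chains to map to the reference (curator annotation); None = any chain
    #: whose alignment clears the identity floor
    target_chain_ids: Optional[list[str]] = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    weights: ScoringWeights = field(default_factory=ScoringWeights)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    log_level: str = "INFO"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["filters"]["allow_override"] = sorted(self.filters.allow_override)
        d["weights"]["method_prior"] = {
            (k.value if isinstance(k, Method) else str(k)): v
            for k, v in self.weights.method_prior.items()
        }
        d["schema_version"] = CONFIG_SCHEMA_VERSION
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d.pop("schema_version", None)
        if "filters" in d and isinstance(d["filters"], dict):
            f = dict(d["filters"])
            f["allow_override"] = frozenset(f.get("allow_override", ()))
            d["filters"] = FilterConfig(**f)
        if "weights" in d and isinstance(d["weights"], dict):
            w = dict(d["weights"])
            if "method_prior" in w:
                w["method_prior"] = {Method(k): v for k, v in w["method_prior"].items()}
            d["weights"] = ScoringWeights(**w)
        if "geometry" in d and isinstance(d["geometry"], dict):
            d["geometry"] = GeometryConfig(**d["geometry"])
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def validate_paths(self, need_structures: bool = True) -> None:
        if need_structures and not os.path.isdir(self.structures_dir):
            raise ConfigError(f"structures dir not found: {self.structures_dir}")
        for name in ("reference_fasta", "msa_path", "variant_table",
                     "ligand_dict", "remark_table"):
            p = getattr(self, name)
            if name == "reference_fasta" and not os.path.isfile(p):
                raise ConfigError(f"reference FASTA not found: {p}")
            if name != "reference_fasta" and p is not None and not os.path.isfile(p):
                raise ConfigError(f"{name} not found: {p}")


@dataclass
class StructureReport:
    entry_id: str
    path: str
    decision: FilterDecision
    renumbered: list[RenumberedChain]
    model: StructureModel
    score: Optional[StructureScore] = None


@dataclass
class CurationResult:
    config_hash: str
    reports: list[StructureReport]
    ranked: "object"  # pandas DataFrame

    @property
    def kept(self) -> list[StructureReport]:
        return [r for r in self.reports if r.decision.keep]

    @property
    def filtered(self) -> list[StructureReport]:
        return [r for r in self.reports if not r.decision.keep]


def _pick_reference(refs: list[ReferenceSequence]) -> ReferenceSequence:
    if not refs:
        raise ConfigError("reference FASTA holds no sequences")
    return refs[0]  # one reference per gene


def curate_structure(
    model: StructureModel,
    ref: ReferenceSequence,
    cfg: FilterConfig,
    peptide_max_len: int = 30,
    ligand_dict=None,
    target_chain_ids: Optional[list[str]] = None,
) -> tuple[list[RenumberedChain], FilterDecision]:
    """Renumber every alignable chain of one structure and apply the filters.

    ``target_chain_ids`` restricts reference mapping to annotated chains;
    otherwise every chain clearing the identity floor is mapped.
    """
    renumbered: list[RenumberedChain] = []
    for chain in model.chains:
        if target_chain_ids is not None and chain.chain_id not in target_chain_ids:
            continue
        try:
            aln = align_chain_to_reference(chain, ref, cfg.min_identity)
        except AlignmentError:
            continue  # partner chain / peptide: no confident mapping
        renumbered.append(renumber_chain(chain, aln, cfg, model.header, ref))
    classify_entities(model, ligand_dict, peptide_max_len,
                      mapped_chain_ids={rc.chain_id for rc in renumbered})
    decision = apply_structure_filters(model, renumbered, cfg)
    return renumbered, decision


def cmd_curate(config: RunConfig) -> CurationResult:
    """Run the full curation pipeline over a directory of structures.

    Every structure appears in the result — kept ones in the ranked table,
    filtered ones with explicit reasons.  Outputs are written under
    ``config.output_dir`` and are byte-identical across reruns of the same
    config.
    """
    config.validate_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    refs = read_reference_fasta(config.reference_fasta)
    ref = _pick_reference(refs)
    ligand_dict = read_ligand_dict(config.ligand_dict) if config.ligand_dict else {}
    remarks = read_remark_table(config.remark_table) if config.remark_table else {}

    paths = sorted(
        p for p in Path(config.structures_dir).iterdir()
        if p.suffix.lower() in (".pdb", ".ent", ".cif", ".mmcif")
    )
    if not paths:
        log.warning("no structure files in %s (no experimental structure available)",
                    config.structures_dir)
    reports: list[StructureReport] = []
    scores: list[StructureScore] = []
    for path in paths:
        model = read_structure(path)
        renumbered, decision = curate_structure(
            model, ref, config.filters, config.peptide_max_len, ligand_dict,
            config.target_chain_ids)
        rep = StructureReport(model.header.entry_id, str(path), decision,
                              renumbered, model)
        if decision.keep:
            meta = collect_metadata(model, renumbered, remarks)
            rep.score = score_structure(meta, config.weights)
            scores.append(rep.score)
        reports.append(rep)

    ranked = rank_table(scores)
    # outputs
    with open(out / "ranked.tsv", "w") as fh:
        fh.write(f"# config_hash: {chash}\n")
        ranked.to_csv(fh, sep="\t", index=False)
    report_doc = {
        "config_hash": chash,
        "reference": ref.accession,
        "n_structures": len(reports),
        "n_kept": sum(r.decision.keep for r in reports),
        "structures": [
            {
                "entry_id": r.entry_id,
                "path": os.path.basename(r.path),
                "kept": r.decision.keep,
                "reasons": r.decision.reasons,
                "override_used": r.decision.override_used,
                "n_mutations": r.decision.n_mutations,
                "chains": [
                    {
                        "chain_id": rc.chain_id,
                        "ref_span": list(rc.ref_span),
                        "missing_fraction": round(rc.missing_fraction, 4),
                        "kept": rc.kept,
                        "discrepancies": rc.discrepancies.summary(),
                    }
                    for rc in r.renumbered
                ],
            }
            for r in reports
        ],
    }
    with open(out / "curation_report.json", "w") as fh:
        json.dump(report_doc, fh, indent=1, sort_keys=True)
    for r in reports:
        for rc in r.renumbered:
            rows = mapping_table(rc)
            with open(out / f"{r.entry_id}_{rc.chain_id}_mapping.tsv", "w") as fh:
                fh.write(f"# config_hash: {chash}\n")
                fh.write("chain\tauthor_seq\ticode\tref_pos\tstatus\n")
                for row in rows:
                    fh.write("\t".join(str(row[c]) for c in
                                       ("chain", "author_seq", "icode", "ref_pos", "status"))
                             + "\n")
    return CurationResult(config_hash=chash, reports=reports, ranked=ranked)


def cmd_residue(
    config: RunConfig,
    entry_id: str,
    ref_pos: int,
    chain_id: Optional[str] = None,
) -> dict:
    """Single-residue report joining 3D contacts, ortholog conservation and
    vicinity variants — the command-line analogue of the linked panels.

    If the residue is unresolved in the chosen structure the contacts
    section says so but conservation and variant data are still returned.
    """
    config.validate_paths()
    refs = read_reference_fasta(config.reference_fasta)
    ref = _pick_reference(refs)
    if not (1 <= ref_pos <= len(ref)):
        raise ValueError(f"position {ref_pos} outside reference 1..{len(ref)}")

    candidates = [
        p for p in sorted(Path(config.structures_dir).iterdir())
        if p.stem.upper() == entry_id.upper()
        and p.suffix.lower() in (".pdb", ".ent", ".cif", ".mmcif")
    ]
    if not candidates:
        raise ConfigError(f"no structure file for entry {entry_id!r}")
    model = read_structure(candidates[0])
    ligand_dict = read_ligand_dict(config.ligand_dict) if config.ligand_dict else {}
    renumbered, _decision = curate_structure(
        model, ref, config.filters, config.peptide_max_len, ligand_dict,
        config.target_chain_ids)

    records = []
    if config.variant_table:
        records, _rejects = var.read_variant_table(config.variant_table)
    by_pos = var.variants_by_position(records)

    report: dict = {
        "entry_id": model.header.entry_id,
        "ref_accession": ref.accession,
        "ref_pos": ref_pos,
        "ref_aa": ref.at(ref_pos),
        "config_hash": config.config_hash(),
    }

    target = None
    for rc in renumbered:
        if chain_id is not None and rc.chain_id != chain_id:
            continue
        key = rc.author_key_of(ref_pos)
        if key is not None:
            target = (rc, key)
            break
    if target is None:
        report["structure"] = {"status": "absent",
                               "note": "residue not resolved in this structure"}
    else:
        rc, key = target
        env = residue_environment_report(
            model, key, config.geometry,
            variants_by_position=by_pos, renumbered=renumbered,
            include_other_chains=True,
        )
        env["status"] = "resolved"
        env["chain_id"] = rc.chain_id
        report["structure"] = env

    if config.msa_path:
        aln = cons.read_alignment(config.msa_path, config.msa_format,
                                  human_accession=ref.accession)
        profile = cons.conservation_profile(aln)
        if ref_pos <= len(profile):
            p = profile.at(ref_pos)
            f = p.identity_fraction
            report["conservation"] = {
                "identity_fraction": ("undefined" if f is None else round(f, 4)),
                "n_nongap": p.n_nongap,
                "gap_count": p.gap_count,
                "members": profile.member_labels,
            }
    if config.variant_table:
        report["variants_at_position"] = [
            {"variant": v.canonical(), "type": v.type, "effect": v.effect, "ptm": v.ptm}
            for v in by_pos.get(ref_pos, [])
        ]
    return report
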