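"""Score and rank curated structures by relevance.

Each structure gets a metadata vector (experimental method and quality,
reference coverage, bound drugs, partner chains, mutation load, curator
remarks) combined into a transparent additive score.  Higher scores mean a
more informative structure; a tier threshold splits the list into the
``high``/``low`` relevance display levels.  Every weight is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import pandas as pd

from .io_structures import (
    EntityKind,
    LigandCategory,
    Method,
    StructureModel,
)
from .reference_map import RenumberedChain


@dataclass
class ScoringWeights:
    """Additive relevance-scoring weights (all points, all configurable).

    Coverage contributes ``coverage * coverage_weight``; the resolution bonus
    scales linearly from 0 points at ``resolution_floor`` (4.0 Å) to
    ``resolution_weight`` points at ``resolution_ceiling`` (1.0 Å), clamped.
    """

    coverage_weight: float = 40.0
    resolution_weight: float = 20.0
    resolution_floor: float = 4.0     # Å, bonus = 0 at/beyond this
    resolution_ceiling: float = 1.0   # Å, full bonus at/below this
    method_prior: dict = field(default_factory=lambda: {
        Method.XRAY: 10.0,
        Method.NEUTRON: 10.0,
        Method.CRYOEM: 8.0,
        Method.NMR: 6.0,
        Method.FIBER: 4.0,
        Method.MODEL: 2.0,
        Method.UNKNOWN: 0.0,
    })
    approved_drug_bonus: float = 15.0
    investigational_bonus: float = 8.0
    partner_chain_bonus: float = 8.0
    mutation_penalty: float = 3.0     # subtracted per mutation
    high_tier_cutoff: float = 50.0


@dataclass
class StructureScore:
    entry_id: str
    method: Method = Method.UNKNOWN
    resolution: Optional[float] = None
    r_free: Optional[float] = None
    coverage_fraction: float = 0.0
    n_mutations: int = 0
    has_approved_drug: bool = False
    has_investigational: bool = False
    has_partner_chain: bool = False
    domain_tags: list[str] = field(default_factory=list)
    state_tag: str = "unknown"  # active | inactive | unknown
    resolved_span: tuple[int, int] = (0, 0)
    ligand_names: list[str] = field(default_factory=list)
    score: Optional[float] = None
    tier: Optional[str] = None  # high | low

    def to_row(self) -> dict:
        d = asdict(self)
        d["method"] = self.method.value
        d["domain_tags"] = ";".join(self.domain_tags)
        d["ligand_names"] = ";".join(self.ligand_names)
        d["resolved_span"] = f"{self.resolved_span[0]}-{self.resolved_span[1]}"
        return d


def read_remark_table(path) -> dict[str, dict]:
    """Curator remark TSV: ``entry_id, domain_tags(;-sep), state_tag, notes``."""
    out: dict[str, dict] = {}
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None and parts[0] == "entry_id":
                header = parts
                continue
            row = dict(zip(["entry_id", "domain_tags", "state_tag", "notes"], parts))
            out[row["entry_id"]] = {
                "domain_tags": [t for t in row.get("domain_tags", "").split(";") if t],
                "state_tag": row.get("state_tag", "unknown") or "unknown",
                "notes": row.get("notes", ""),
            }
    return out


def collect_metadata(
    model: StructureModel,
    renumbered: list[RenumberedChain],
    annotations: Optional[dict[str, dict]] = None,
) -> StructureScore:
    """Gather the metadata vector for one structure (score left unset).

    ``coverage_fraction`` is ``(span length - missing) / reference length``
    for the best kept chain; the partner flag is true when at least one
    polymer chain is not mapped to the reference (a bound protein or domain).
    """
    header = model.header
    kept = [rc for rc in renumbered if rc.kept]
    pool = kept or renumbered
    coverage = 0.0
    span = (0, 0)
    if pool:
        def chain_cov(rc: RenumberedChain) -> float:
            n_resolved = rc.ref_span_len_resolved()
            return n_resolved / rc.ref_length
        best = max(pool, key=chain_cov)
        coverage = chain_cov(best)
        span = best.ref_span
    mapped_ids = {rc.chain_id for rc in renumbered}
    has_partner = any(
        c.chain_id not in mapped_ids and c.entity_kind != EntityKind.PEPTIDE
        for c in model.chains
    )
    n_mut = sum(len(rc.discrepancies.mutated) for rc in renumbered)
    cats = {l.category for l in model.ligands}
    ann = (annotations or {}).get(header.entry_id, {})
    return StructureScore(
        entry_id=header.entry_id,
        method=header.method,
        resolution=header.resolution,
        r_free=header.r_free,
        coverage_fraction=coverage,
        n_mutations=n_mut,
        has_approved_drug=LigandCategory.APPROVED_DRUG in cats,
        has_investigational=LigandCategory.INVESTIGATIONAL in cats,
        has_partner_chain=has_partner,
        domain_tags=list(ann.get("domain_tags", [])),
        state_tag=ann.get("state_tag", "unknown"),
        resolved_span=span,
        ligand_names=sorted({l.comp_id for l in model.ligands
                             if l.category not in (LigandCategory.WATER,)}),
    )


def resolution_bonus(resolution: Optional[float], w: ScoringWeights) -> float:
    """Linear resolution bonus, clamped to [0, resolution_weight].

    Methods without a resolution (e.g. solution NMR) get no bonus.
    """
    if resolution is None:
        return 0.0
    lo, hi = w.resolution_ceiling, w.resolution_floor
    frac = (hi - resolution) / (hi - lo)
    return w.resolution_weight * min(1.0, max(0.0, frac))


def score_structure(meta: StructureScore, w: ScoringWeights = ScoringWeights()) -> StructureScore:
    """Fill in ``score`` and ``tier`` from the metadata vector."""
    score = meta.coverage_fraction * w.coverage_weight
    score += resolution_bonus(meta.resolution, w)
    score += w.method_prior.get(meta.method, 0.0)
    if meta.has_approved_drug:
        score += w.approved_drug_bonus
    if meta.has_investigational:
        score += w.investigational_bonus
    if meta.has_partner_chain:
        score += w.partner_chain_bonus
    score -= w.mutation_penalty * meta.n_mutations
    meta.score = score
    meta.tier = "high" if score >= w.high_tier_cutoff else "low"
    return meta


def rank_structures(scores: list[StructureScore]) -> list[StructureScore]:
    """Order structures from most to least relevant.

    Descending score; ties broken by better (smaller) resolution, then by
    lexicographic entry id.  Deterministic; an empty input gives an empty
    list (the case of a gene with no experimental structure at all).
    """
    def sort_key(s: StructureScore):
        res = s.resolution if s.resolution is not None else float("inf")
        return (-(s.score if s.score is not None else float("-inf")), res, s.entry_id)

    return sorted(scores, key=sort_key)


RANK_TABLE_COLUMNS = [
    "entry_id", "domain_tags", "ligand_names", "resolved_span", "n_mutations",
    "method", "resolution", "r_free", "coverage_fraction", "score", "tier",
]


def rank_table(scores: list[StructureScore]) -> pd.DataFrame:
    """Ranked structure-list table mirroring the selection-panel columns."""
    rows = [s.to_row() for s in rank_structures(scores)]
    df = pd.DataFrame(rows, columns=RANK_TABLE_COLUMNS) if rows else pd.DataFrame(
        columns=RANK_TABLE_COLUMNS
    )
    return df
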