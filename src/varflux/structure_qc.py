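"""Structure quality control and pharmacogenomic target triage.

Ranks candidate protein structures per gene by a composite quality score
(sequence coverage, sequence identity, crystallographic resolution,
interior completeness), assigns the best structure of each gene to one of
three QC groups (usable as-is, needs point modification, needs a homology
model), and sorts candidate targets into four pharmacogenomic classes by
the availability of structure, drug-binding and variant-effect evidence,
and network importance.

The score is a convex combination of four terms, each in [0, 1]:

    score = w_cov * coverage
          + w_id  * identity
          + w_res * max(0, 1 - (resolution - 1 A) / 4 A)
          + w_miss * exp(-missing_interior / 10)

Homology models have no resolution; they receive the resolution term's
neutral midpoint (0.5). Default weights put coverage and identity first
(0.35 each), then resolution (0.20), then completeness (0.10); the exact
weighting is a package choice and is configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

DEFAULT_WEIGHTS: dict[str, float] = {
    "coverage": 0.35,
    "identity": 0.35,
    "resolution": 0.20,
    "completeness": 0.10,
}

#: Coverage above which a structure may avoid homology modelling.
COVERAGE_HI = 0.80
#: Identity above which only point modifications are needed.
IDENTITY_LO = 0.95


class QcGroup(Enum):
    NO_MODIFICATION = "no_modification"
    MINIMAL_MODIFICATION = "minimal_modification"
    NEEDS_HOMOLOGY_MODEL = "needs_homology_model"


class TargetClass(Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    UNCLASSIFIED = "unclassified"


@dataclass
class StructureRecord:
    gene: str
    structure_id: str
    is_experimental: bool
    seq_identity: float
    seq_coverage: float
    resolution: float | None = None
    missing_interior_residues: int = 0
    quality_score_external: float | None = None

    def __post_init__(self):
        if not 0 <= self.seq_identity <= 1:
            raise ValueError("seq_identity must be in [0, 1]")
        if not 0 <= self.seq_coverage <= 1:
            raise ValueError("seq_coverage must be in [0, 1]")
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError("resolution must be > 0 when present")
        if self.missing_interior_residues < 0:
            raise ValueError("missing_interior_residues must be >= 0")


@dataclass
class TargetDossier:
    gene: str
    has_structure: bool
    has_drug_binding_info: bool
    has_snp_drug_association: bool
    has_variant_with_effect_data: bool
    is_network_important: bool


@dataclass
class RankedGene:
    gene: str
    ranking: list[tuple[StructureRecord, float]]
    best_group: QcGroup


def _resolution_term(record: StructureRecord) -> float:
    if record.resolution is None or not record.is_experimental:
        return 0.5  # neutral midpoint for homology models
    return max(0.0, 1.0 - (record.resolution - 1.0) / 4.0)


def score_structure(
    record: StructureRecord, weights: Mapping[str, float] | None = None
) -> float:
    """Composite quality score in [0, 1]; higher is better."""
    w = dict(DEFAULT_WEIGHTS if weights is None else weights)
    missing = set(DEFAULT_WEIGHTS) - set(w)
    if missing:
        raise ValueError(f"weights missing terms: {sorted(missing)}")
    if any(v < 0 for v in w.values()):
        raise ValueError("weights must be nonnegative")
    total = sum(w[k] for k in DEFAULT_WEIGHTS)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1 (got {total})")
    return (
        w["coverage"] * record.seq_coverage
        + w["identity"] * record.seq_identity
        + w["resolution"] * _resolution_term(record)
        + w["completeness"] * math.exp(-record.missing_interior_residues / 10.0)
    )


def qc_group(
    record: StructureRecord,
    coverage_hi: float = COVERAGE_HI,
    identity_lo: float = IDENTITY_LO,
) -> QcGroup:
    """Assign the QC group for a (best-ranked) structure.

    Usable as-is requires perfect identity, high coverage and no interior
    gaps; point substitutions alone (identity just below 1 at high
    coverage) call for minimal modification; anything else needs a
    homology model.
    """
    if (
        record.seq_identity == 1.0
        and record.seq_coverage >= coverage_hi
        and record.missing_interior_residues == 0
    ):
        return QcGroup.NO_MODIFICATION
    if record.seq_identity >= identity_lo and record.seq_coverage >= coverage_hi:
        return QcGroup.MINIMAL_MODIFICATION
    return QcGroup.NEEDS_HOMOLOGY_MODEL


def rank_structures(
    records: Iterable[StructureRecord],
    weights: Mapping[str, float] | None = None,
    genes: Iterable[str] | None = None,
    coverage_hi: float = COVERAGE_HI,
    identity_lo: float = IDENTITY_LO,
) -> tuple[dict[str, RankedGene], list[str]]:
    """Rank structures per gene and tag each gene's best with its QC group.

    Returns ``(per_gene, no_structure)`` where ``no_structure`` lists genes
    from ``genes`` that have no candidate record. Within a gene, records are
    sorted by descending score with ties broken lexicographically by
    structure id, so the ranking is a total order independent of input order.
    """
    by_gene: dict[str, list[StructureRecord]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene, []).append(rec)

    per_gene: dict[str, RankedGene] = {}
    for gene, recs in by_gene.items():
        scored = [(r, score_structure(r, weights)) for r in recs]
        scored.sort(key=lambda rs: (-rs[1], rs[0].structure_id))
        per_gene[gene] = RankedGene(
            gene=gene,
            ranking=scored,
            best_group=qc_group(scored[0][0], coverage_hi, identity_lo),
        )
    no_structure = (
        sorted(set(genes) - set(by_gene)) if genes is not None else []
    )
    return per_gene, no_structure


def classify_target(dossier: TargetDossier) -> TargetClass:
    """Four-way pharmacogenomic triage; first matching rule wins (I -> IV).

    Class I: structure + known variant-drug association + drug binding
    information (the best-characterized targets). Class II: structure and
    variant-effect data but no variant-drug association (candidates for
    prospective prediction). Class III: network-important with a structure
    but neither pharmacogenomic flag. Class IV: network-important only.
    """
    d = dossier
    if d.has_structure and d.has_snp_drug_association and d.has_drug_binding_info:
        return TargetClass.I
    if d.has_structure and d.has_variant_with_effect_data and not d.has_snp_drug_association:
        return TargetClass.II
    if (
        d.is_network_important
        and d.has_structure
        and not d.has_snp_drug_association
        and not d.has_drug_binding_info
    ):
        return TargetClass.III
    if (
        d.is_network_important
        and not d.has_structure
        and not d.has_snp_drug_association
        and not d.has_drug_binding_info
    ):
        return TargetClass.IV
    return TargetClass.UNCLASSIFIED


# -- table adapters ---------------------------------------------------------

def structures_from_table(df: pd.DataFrame) -> list[StructureRecord]:
    out = []
    for _, row in df.iterrows():
        res = row.get("resolution")
        out.append(
            StructureRecord(
                gene=row["gene"],
                structure_id=row["structure_id"],
                is_experimental=bool(row["experimental"]),
                seq_identity=float(row["identity"]),
                seq_coverage=float(row["coverage"]),
                resolution=None if pd.isna(res) else float(res),
                missing_interior_residues=int(row.get("missing_interior", 0)),
            )
        )
    return out


def ranking_to_table(per_gene: Mapping[str, RankedGene]) -> pd.DataFrame:
    rows = []
    for gene in sorted(per_gene):
        rg = per_gene[gene]
        for rank, (rec, score) in enumerate(rg.ranking, start=1):
            rows.append(
                {
                    "gene": gene,
                    "rank": rank,
                    "structure_id": rec.structure_id,
                    "score": score,
                    "qc_group": rg.best_group.value if rank == 1 else "",
                }
            )
    return pd.DataFrame(rows)


def dossiers_from_table(df: pd.DataFrame) -> list[TargetDossier]:
    flags = (
        "has_structure",
        "has_drug_binding_info",
        "has_snp_drug_association",
        "has_variant_with_effect_data",
        "is_network_important",
    )
    return [
        TargetDossier(gene=row["gene"], **{f: bool(row[f]) for f in flags})
        for _, row in df.iterrows()
    ]
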