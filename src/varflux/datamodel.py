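"""Core data structures and file I/O.

Holds the constraint-based model container (stoichiometry, bounds,
gene-protein-reaction rules, exchanges), variant bookkeeping records, the
shared analysis configuration, and readers/writers for the model JSON
dialect, an SBML (Level 3 + fbc) subset, and tab-separated result tables.

Sign conventions: exchange fluxes are positive for secretion and negative
for uptake. Flux units are mmol·gDW⁻¹·h⁻¹ by convention but the code is
unit-agnostic. All tables are tab-separated (chemical names contain commas).
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("varflux")

#: Gas constant in kcal·mol⁻¹·K⁻¹.
R_KCAL = 1.987204e-3

#: Standard temperature (K) used for free-energy / Km interconversion.
T_STANDARD = 298.15

THREE_LETTER_AA = {
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
}

_PROTEIN_CHANGE_RE = re.compile(r"^([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")


class ModelValidationError(ValueError):
    """Raised when a metabolic model violates a structural invariant."""


class ModelParseError(ValueError):
    """Raised when a model document cannot be parsed; names the offending element."""


# ---------------------------------------------------------------------------
# GPR boolean expressions
# ---------------------------------------------------------------------------

class GPRSyntaxError(ValueError):
    pass


def _tokenize_gpr(expr: str) -> list[str]:
    tokens = []
    i, n = 0, len(expr)
    while i < n:
        c = expr[i]
        if c.isspace():
            i += 1
        elif c in "()":
            tokens.append(c)
            i += 1
        else:
            j = i
            while j < n and not expr[j].isspace() and expr[j] not in "()":
                j += 1
            tokens.append(expr[i:j])
            i = j
    return tokens


def _parse_gpr(tokens: list[str], pos: int = 0):
    """Recursive-descent parser for infix AND/OR with parentheses.

    Grammar: or_expr := and_expr (OR and_expr)* ; and_expr := atom (AND atom)* ;
    atom := gene | '(' or_expr ')'. AND binds tighter than OR; operators are
    case-insensitive; gene ids may contain dots (isoforms such as ``Aldoa.1``).
    Returns an AST of nested tuples ('and'|'or', [children]) or ('gene', id).
    """

    def parse_or(p):
        node, p = parse_and(p)
        children = [node]
        while p < len(tokens) and tokens[p].lower() == "or":
            nxt, p = parse_and(p + 1)
            children.append(nxt)
        return (("or", children) if len(children) > 1 else children[0]), p

    def parse_and(p):
        node, p = parse_atom(p)
        children = [node]
        while p < len(tokens) and tokens[p].lower() == "and":
            nxt, p = parse_atom(p + 1)
            children.append(nxt)
        return (("and", children) if len(children) > 1 else children[0]), p

    def parse_atom(p):
        if p >= len(tokens):
            raise GPRSyntaxError("unexpected end of GPR expression")
        tok = tokens[p]
        if tok == "(":
            node, p = parse_or(p + 1)
            if p >= len(tokens) or tokens[p] != ")":
                raise GPRSyntaxError("unbalanced parentheses in GPR")
            return node, p + 1
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRSyntaxError(f"unexpected token {tok!r} in GPR")
        return ("gene", tok), p + 1

    node, p = parse_or(pos)
    if p != len(tokens):
        raise GPRSyntaxError(f"trailing tokens in GPR: {tokens[p:]}")
    return node


def parse_gpr(expr: str):
    """Parse a GPR rule string into an AST; empty/blank rules parse to None."""
    if expr is None or not expr.strip():
        return None
    return _parse_gpr(_tokenize_gpr(expr))


def gpr_genes(expr: str) -> set[str]:
    """The set of gene ids referenced by a GPR rule."""
    ast = parse_gpr(expr)
    out: set[str] = set()

    def walk(node):
        if node is None:
            return
        if node[0] == "gene":
            out.add(node[1])
        else:
            for child in node[1]:
                walk(child)

    walk(ast)
    return out


def evaluate_gpr(expr: str, gene_states: Mapping[str, bool]) -> bool:
    """Evaluate a GPR rule; genes absent from ``gene_states`` count as present.

    A reaction with an empty rule is always available.
    """
    ast = parse_gpr(expr)
    if ast is None:
        return True

    def ev(node) -> bool:
        kind = node[0]
        if kind == "gene":
            return bool(gene_states.get(node[1], True))
        if kind == "and":
            return all(ev(c) for c in node[1])
        return any(ev(c) for c in node[1])

    return ev(ast)


# ---------------------------------------------------------------------------
# Metabolic model
# ---------------------------------------------------------------------------

@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    gpr: str = ""
    is_exchange: bool = False
    name: str = ""

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class MetabolicModel:
    """A constraint-based metabolic network.

    The steady-state flux space is ``{v : S v = 0, lb <= v <= ub}`` where the
    stoichiometric matrix S is (metabolites x reactions). Exchange reactions
    touch exactly one metabolite and carry the secretion-positive convention.
    """

    model_id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    genes: list[str] = field(default_factory=list)
    #: genes knocked out so far; successive knockouts accumulate
    disabled_genes: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.validate()

    # -- lookups ------------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def exchange_ids(self) -> list[str]:
        return [r.id for r in self.reactions if r.is_exchange]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"unknown reaction {rid!r}")

    def validate(self) -> None:
        met_ids = self.metabolite_ids
        if len(set(met_ids)) != len(met_ids):
            raise ModelValidationError("duplicate metabolite ids")
        rxn_ids = self.reaction_ids
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelValidationError("duplicate reaction ids")
        met_set = set(met_ids)
        missing = [
            (r.id, m)
            for r in self.reactions
            for m in r.stoichiometry
            if m not in met_set
        ]
        if missing:
            raise ModelValidationError(
                f"reactions reference unknown metabolites: {missing}"
            )
        inverted = [r.id for r in self.reactions if r.lower_bound > r.upper_bound]
        if inverted:
            raise ModelValidationError(
                f"lower_bound > upper_bound for reactions: {inverted}"
            )
        bad_ex = [
            r.id
            for r in self.reactions
            if r.is_exchange and len([c for c in r.stoichiometry.values() if c != 0]) != 1
        ]
        if bad_ex:
            raise ModelValidationError(
                f"exchange reactions must touch exactly one metabolite: {bad_ex}"
            )
        if not self.genes:
            self.genes = sorted({g for r in self.reactions for g in gpr_genes(r.gpr)})

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S with shape (n_metabolites, n_reactions)."""
        met_index = {m: i for i, m in enumerate(self.metabolite_ids)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met, coef in r.stoichiometry.items():
                S[met_index[met], j] = coef
        return S

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            model_id=self.model_id,
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            genes=list(self.genes),
            disabled_genes=set(self.disabled_genes),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        return (
            self.model_id == other.model_id
            and self.metabolites == other.metabolites
            and self.reactions == other.reactions
            and sorted(self.genes) == sorted(other.genes)
            and self.disabled_genes == other.disabled_genes
        )


# ---------------------------------------------------------------------------
# Variant records and configuration
# ---------------------------------------------------------------------------

@dataclass
class VariantRecord:
    """A protein sequence variant (e.g. ``Val108Met``) with its annotations."""

    gene: str
    protein_change: str
    dbsnp_id: str | None = None
    disease_flag: str = "unknown"  # disease / benign / unknown
    drug_associations: list[str] = field(default_factory=list)

    def __post_init__(self):
        m = _PROTEIN_CHANGE_RE.match(self.protein_change)
        if not m:
            raise ValueError(
                f"protein_change {self.protein_change!r} does not match "
                "<Aaa><pos><Aaa>"
            )
        ref, pos, alt = m.groups()
        if ref not in THREE_LETTER_AA or alt not in THREE_LETTER_AA:
            raise ValueError(
                f"protein_change {self.protein_change!r} uses an invalid "
                "three-letter amino-acid code"
            )
        if int(pos) < 1:
            raise ValueError("variant position must be >= 1")
        if self.disease_flag not in ("disease", "benign", "unknown"):
            raise ValueError(f"invalid disease_flag {self.disease_flag!r}")


@dataclass
class AnalysisConfig:
    """Shared knobs for the constraint-based and kinetic analyses.

    alpha is the significance level for flux-distribution shifts;
    span_fraction_threshold is the fraction of the wild-type flux span below
    which a mutant span counts as a significant magnitude change.
    """

    alpha: float = 0.05
    span_fraction_threshold: float = 0.40
    zero_flux_tol: float = 1e-6
    steady_state_tol: float = 1e-8
    temperature: float = T_STANDARD
    gas_constant: float = R_KCAL
    rng_seed: int = 0
    extinction_threshold: float = 1e-9
    t_max: float = 2e3
    concentration_ceiling: float = 1e3

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.span_fraction_threshold < 1:
            raise ValueError("span_fraction_threshold must be in (0, 1)")
        for name in ("zero_flux_tol", "steady_state_tol", "temperature",
                     "gas_constant", "extinction_threshold", "t_max",
                     "concentration_ceiling"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load from YAML or JSON (sniffed by extension)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "alpha", "span_fraction_threshold", "zero_flux_tol",
                "steady_state_tol", "temperature", "gas_constant", "rng_seed",
                "extinction_threshold", "t_max", "concentration_ceiling",
            )
        }


# ---------------------------------------------------------------------------
# Model JSON dialect
# ---------------------------------------------------------------------------

def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.model_id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(r.stoichiometry),
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "gpr": r.gpr,
                "exchange": r.is_exchange,
            }
            for r in model.reactions
        ],
        "genes": sorted(model.genes),
    }


def _model_from_dict(data: dict) -> MetabolicModel:
    if "id" not in data:
        raise ModelParseError("model document lacks an 'id' field")
    mets = []
    for entry in data.get("metabolites", []):
        if "id" not in entry:
            raise ModelParseError(f"metabolite entry without id: {entry!r}")
        mets.append(
            Metabolite(
                id=entry["id"],
                name=entry.get("name", ""),
                compartment=entry.get("compartment", ""),
            )
        )
    rxns = []
    for entry in data.get("reactions", []):
        if "id" not in entry:
            raise ModelParseError(f"reaction entry without id: {entry!r}")
        rid = entry["id"]
        if "stoichiometry" not in entry or not isinstance(entry["stoichiometry"], dict):
            raise ModelParseError(f"reaction {rid!r} lacks a stoichiometry map")
        try:
            lb = float(entry["lb"])
            ub = float(entry["ub"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ModelParseError(f"reaction {rid!r} has invalid bounds") from exc
        stoich = {m: float(c) for m, c in entry["stoichiometry"].items()}
        nonzero = [m for m, c in stoich.items() if c != 0]
        is_exchange = bool(entry.get("exchange", len(nonzero) == 1))
        rxns.append(
            Reaction(
                id=rid,
                name=entry.get("name", ""),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=entry.get("gpr", "") or "",
                is_exchange=is_exchange,
            )
        )
    return MetabolicModel(
        model_id=data["id"],
        metabolites=mets,
        reactions=rxns,
        genes=list(data.get("genes", [])),
    )


def load_model(source: str | Path | dict) -> MetabolicModel:
    """Load a metabolic model from JSON (native dialect) or an SBML subset.

    ``source`` may be a path, a JSON string, or an already-parsed dict.
    Exchange reactions are auto-detected as single-metabolite reactions when
    the explicit flag is absent. Bound inversions and dangling metabolite
    references raise :class:`ModelValidationError` naming the culprits.
    """
    if isinstance(source, dict):
        return _model_from_dict(source)
    text: str | None = None
    path: Path | None = None
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        path = Path(source)
        text = path.read_text()
    else:
        text = str(source)
    stripped = text.lstrip()
    if stripped.startswith("<"):
        return _load_sbml(text)
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelParseError(f"not valid model JSON: {exc}") from exc
    return _model_from_dict(data)


def write_model(model: MetabolicModel, dest: str | Path) -> None:
    Path(dest).write_text(json.dumps(model_to_dict(model), indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# SBML (Level 3 + fbc) subset import
# ---------------------------------------------------------------------------

def _load_sbml(text: str) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromString(text)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(f"SBML parse error: {err.getMessage()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelParseError("SBML document contains no model element")

    unsupported = []
    for attr, label in (
        ("getNumRules", "rules"),
        ("getNumEvents", "events"),
        ("getNumConstraints", "constraints"),
    ):
        n = getattr(sbml_model, attr)()
        if n:
            unsupported.append(f"{n} {label}")
    if unsupported:
        warnings.warn(
            "SBML constructs not supported and ignored: " + ", ".join(unsupported),
            stacklevel=3,
        )

    def _clip(sid: str, prefix: str) -> str:
        # conventional SBML id prefixes ("M_", "R_") are presentation only
        return sid[len(prefix):] if sid.startswith(prefix) else sid

    params = {
        p.getId(): p.getValue() for p in sbml_model.getListOfParameters()
    }
    mets = [
        Metabolite(
            id=_clip(s.getId(), "M_"),
            name=s.getName() or "",
            compartment=s.getCompartment() or "",
        )
        for s in sbml_model.getListOfSpecies()
        if not s.getBoundaryCondition()
    ]
    met_ids = {m.id for m in mets}

    rxns = []
    for rxn in sbml_model.getListOfReactions():
        stoich: dict[str, float] = {}
        for ref in rxn.getListOfReactants():
            sid = _clip(ref.getSpecies(), "M_")
            if sid in met_ids:
                stoich[sid] = stoich.get(sid, 0.0) - ref.getStoichiometry()
        for ref in rxn.getListOfProducts():
            sid = _clip(ref.getSpecies(), "M_")
            if sid in met_ids:
                stoich[sid] = stoich.get(sid, 0.0) + ref.getStoichiometry()
        fbc = rxn.getPlugin("fbc")
        lb, ub = -1000.0, 1000.0
        gpr = ""
        if fbc is not None:
            lb_id, ub_id = fbc.getLowerFluxBound(), fbc.getUpperFluxBound()
            if lb_id in params:
                lb = params[lb_id]
            if ub_id in params:
                ub = params[ub_id]
            gpa = fbc.getGeneProductAssociation()
            if gpa is not None:
                gpr = _sbml_gpa_to_infix(gpa.getAssociation(), sbml_model)
        elif not rxn.getReversible():
            lb = 0.0
        nonzero = [m for m, c in stoich.items() if c != 0]
        rxns.append(
            Reaction(
                id=_clip(rxn.getId(), "R_"),
                name=rxn.getName() or "",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                is_exchange=len(nonzero) == 1,
            )
        )
    return MetabolicModel(
        model_id=sbml_model.getId() or "sbml_model",
        metabolites=mets,
        reactions=rxns,
    )


def _sbml_gpa_to_infix(assoc, sbml_model) -> str:
    import libsbml

    if assoc is None:
        return ""
    fbc_model = sbml_model.getPlugin("fbc")

    def label(gp_ref):
        gp = fbc_model.getGeneProduct(gp_ref.getGeneProduct())
        raw = gp_ref.getGeneProduct()
        if gp is not None:
            raw = gp.getLabel() or gp.getId()
        return raw[2:] if raw.startswith("G_") else raw

    if isinstance(assoc, libsbml.GeneProductRef):
        return label(assoc)
    if isinstance(assoc, libsbml.FbcAnd):
        parts = [_sbml_gpa_to_infix(assoc.getAssociation(i), sbml_model)
                 for i in range(assoc.getNumAssociations())]
        return "(" + " and ".join(parts) + ")"
    if isinstance(assoc, libsbml.FbcOr):
        parts = [_sbml_gpa_to_infix(assoc.getAssociation(i), sbml_model)
                 for i in range(assoc.getNumAssociations())]
        return "(" + " or ".join(parts) + ")"
    warnings.warn(f"unsupported GPR association node {type(assoc).__name__}; dropped")
    return ""


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_result_table(
    records: Sequence[Mapping], dest: str | Path, columns: Sequence[str] | None = None
) -> None:
    """Write result rows to a deterministic TSV.

    All records must share one header schema. Rows are sorted by the first
    key column; floats are rendered at six significant digits; encoding is
    UTF-8. An empty record list writes a header-only file (``columns`` gives
    the header when no record can supply it).
    """
    records = list(records)
    if not records:
        header = "\t".join(columns) + "\n" if columns else ""
        Path(dest).write_text(header, encoding="utf-8")
        return
    keys = list(columns) if columns else list(records[0].keys())
    for rec in records[1:]:
        if list(rec.keys()) != keys:
            raise ValueError(
                f"heterogeneous record schemas: {list(rec.keys())} != {keys}"
            )
    df = pd.DataFrame.from_records(records, columns=keys)
    df = df.sort_values(keys[0], kind="mergesort").reset_index(drop=True)
    df.to_csv(dest, sep="\t", index=False, float_format="%.6g", encoding="utf-8")


def write_table(df: pd.DataFrame, dest: str | Path, sort_by: str | None = None) -> None:
    """Write a DataFrame as a deterministic TSV (6 significant digits)."""
    out = df.copy()
    if sort_by is None and len(out.columns):
        sort_by = out.columns[0]
    if sort_by is not None and sort_by in out.columns:
        out = out.sort_values(sort_by, kind="mergesort").reset_index(drop=True)
    out.to_csv(dest, sep="\t", index=False, float_format="%.6g", encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def variants_from_table(df: pd.DataFrame) -> list[VariantRecord]:
    out = []
    for _, row in df.iterrows():
        drugs = row.get("drug_associations", "")
        drug_list = (
            [d for d in str(drugs).split(";") if d and d != "nan"]
            if pd.notna(drugs)
            else []
        )
        out.append(
            VariantRecord(
                gene=row["gene"],
                protein_change=row["protein_change"],
                dbsnp_id=(row.get("dbsnp_id") if pd.notna(row.get("dbsnp_id")) else None),
                disease_flag=row.get("disease_flag", "unknown"),
                drug_associations=drug_list,
            )
        )
    return out
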