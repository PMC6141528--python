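"""Reaction-model generation from interaction, domain and abundance data.

A :class:`ReactionModel` holds molecular species (proteins, RNAs, drugs)
and domain-level binding rules.  Rules are derived from a PPI network
constrained by domain–domain interactions (DDI): a protein pair can bind
only through a compatible domain pair.  When an interacting protein pair
has no DDI-compatible domains but shares a GO function term, the pair is
given a fresh *fictitious* domain pair private to that edge, so the
interaction remains realizable; pairs with neither DDI support nor a
shared term are dropped and counted.

Binding and unbinding propensities default to a single uniform (kon,
koff) for all rules; per-rule kon can be supplied as the weight column of
the DDI table.
"""

from __future__ import annotations

import copy as _copy
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .iofmt import (
    DEFAULT_COMPARTMENT,
    DIFFUSION_RATE_DEFAULT,
    MAX_PARTNERS_DEFAULT,
    InteractionTable,
    SpeciesAttributeTable,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "MolecularSpecies",
    "BindingRule",
    "BuildReport",
    "ReactionModel",
    "build_model",
    "scale_abundances",
    "add_species",
]

KON_DEFAULT = 1.0
KOFF_DEFAULT = 0.1


@dataclass
class ModelConfig:
    """Tunable model-generation parameters (YAML-overridable)."""

    kon_default: float = KON_DEFAULT
    koff_default: float = KOFF_DEFAULT
    abundance_mode: str = "identity"  # identity | sqrt | factor
    abundance_factor: float = 1.0
    abundance_unit: str = "copies"  # copies | molecules_per_million
    cell_volume_factor: float = 1000.0
    max_partners_default: int = MAX_PARTNERS_DEFAULT
    diffusion_rate_default: float = DIFFUSION_RATE_DEFAULT
    use_go: bool = True


@dataclass
class MolecularSpecies:
    id: str
    kind: str = "protein"
    domains: list[tuple[str, int]] = field(default_factory=list)
    abundance: int = 0
    compartments: set[str] = field(default_factory=lambda: {DEFAULT_COMPARTMENT})
    diffusion_rate: float = DIFFUSION_RATE_DEFAULT
    max_partners: int = MAX_PARTNERS_DEFAULT
    go_terms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.max_partners < 1:
            raise ValueError(f"species {self.id!r}: max_partners must be >= 1")
        if self.abundance < 0:
            raise ValueError(f"species {self.id!r}: abundance must be >= 0")

    @property
    def n_sites(self) -> int:
        return sum(n for _, n in self.domains)


@dataclass
class BindingRule:
    species_a: str
    species_b: str
    domain_a: str
    domain_b: str
    kon: float = KON_DEFAULT
    koff: float = KOFF_DEFAULT
    fictitious: bool = False

    def __post_init__(self) -> None:
        if self.kon <= 0 or self.koff <= 0:
            raise ValueError("kon and koff must be positive")

    def key(self) -> tuple:
        a = (self.species_a, self.domain_a)
        b = (self.species_b, self.domain_b)
        return (a, b) if a <= b else (b, a)


@dataclass
class BuildReport:
    n_ppi_edges: int = 0
    n_edges_direct: int = 0
    n_edges_fictitious: int = 0
    n_edges_dropped_no_shared_go: int = 0
    n_edges_dropped_missing_species: int = 0
    fictitious_proteins: set[str] = field(default_factory=set)


@dataclass
class ReactionModel:
    species: list[MolecularSpecies] = field(default_factory=list)
    rules: list[BindingRule] = field(default_factory=list)
    config: ModelConfig = field(default_factory=ModelConfig)
    build_report: BuildReport | None = None

    def species_by_id(self) -> dict[str, MolecularSpecies]:
        return {s.id: s for s in self.species}

    def abundances(self) -> dict[str, int]:
        return {s.id: s.abundance for s in self.species}

    def validate(self) -> None:
        by_id = self.species_by_id()
        for rule in self.rules:
            for sid, dom in ((rule.species_a, rule.domain_a), (rule.species_b, rule.domain_b)):
                if sid not in by_id:
                    raise ValueError(f"rule references unknown species {sid!r}")
                if dom not in {d for d, _ in by_id[sid].domains}:
                    raise ValueError(f"rule references unknown domain {dom!r} on {sid!r}")

    # -- JSON round trip (used by the CLI to chain subcommands) -------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "species": [
                {**asdict(s), "compartments": sorted(s.compartments),
                 "go_terms": sorted(s.go_terms),
                 "domains": [list(d) for d in s.domains]}
                for s in self.species
            ],
            "rules": [asdict(r) for r in self.rules],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReactionModel":
        payload = json.loads(Path(path).read_text())
        config = ModelConfig(**payload["config"])
        species = [
            MolecularSpecies(
                id=s["id"], kind=s["kind"],
                domains=[tuple(d) for d in s["domains"]],
                abundance=s["abundance"],
                compartments=set(s["compartments"]),
                diffusion_rate=s["diffusion_rate"],
                max_partners=s["max_partners"],
                go_terms=set(s["go_terms"]),
            )
            for s in payload["species"]
        ]
        rules = [BindingRule(**r) for r in payload["rules"]]
        return cls(species=species, rules=rules, config=config)


def _fictitious_domains(a: str, b: str) -> tuple[str, str]:
    """Fictitious domain pair private to the unordered edge (a, b)."""
    x, y = sorted((a, b))
    return (f"fict[{x}~{y}]@{a}", f"fict[{x}~{y}]@{b}")


def _scaled_abundance(raw: float, config: ModelConfig) -> int:
    if config.abundance_unit == "molecules_per_million":
        raw = raw / config.cell_volume_factor
    n = round(raw)
    return n


def build_model(
    ppi: InteractionTable,
    ddi: InteractionTable,
    domain_annot: InteractionTable | None,
    attrs: SpeciesAttributeTable,
    config: ModelConfig | None = None,
) -> ReactionModel:
    """Build a reaction model from PPI/DDI/domain/GO/abundance inputs.

    For each PPI edge (a, b) one binding rule is emitted per
    DDI-compatible domain pair.  Edges without any compatible pair get a
    single fictitious rule iff the two proteins share a GO term (and
    ``config.use_go``); otherwise the edge is dropped and counted in the
    build report.
    """
    config = config or ModelConfig()
    report = BuildReport(n_ppi_edges=len(ppi.pairs))

    # species table: attrs plus domain annotations merged in
    species: dict[str, MolecularSpecies] = {}
    for sid, a in attrs.items():
        species[sid] = MolecularSpecies(
            id=sid,
            kind=a.kind,
            domains=list(a.domains),
            abundance=_scaled_abundance(a.abundance, config),
            compartments=set(a.compartments),
            diffusion_rate=a.diffusion_rate,
            max_partners=a.max_partners,
            go_terms=set(a.go_terms),
        )
    if domain_annot is not None:
        for sid, dom in domain_annot.pairs:
            if sid not in species:
                logger.warning("domain annotation for unknown species %r ignored", sid)
                continue
            copies = int(domain_annot.weights.get((sid, dom) if sid <= dom else (dom, sid), 1))
            existing = {d for d, _ in species[sid].domains}
            if dom not in existing:
                species[sid].domains.append((dom, max(1, copies)))

    ddi_pairs = {frozenset(p) for p in ddi.pairs}
    # DDI weight column, when present, supplies a per-rule kon
    ddi_kon: dict[frozenset, float] = {}
    for (x, y), w in ddi.weights.items():
        ddi_kon[frozenset((x, y))] = w

    rules: list[BindingRule] = []
    seen_rules: set[tuple] = set()
    for a, b in ppi.pairs:
        if a not in species or b not in species:
            report.n_edges_dropped_missing_species += 1
            logger.warning("PPI edge (%s, %s) dropped: endpoint missing from attributes", a, b)
            continue
        sa, sb = species[a], species[b]
        compatible = []
        for da, _ in sa.domains:
            for db, _ in sb.domains:
                if frozenset((da, db)) in ddi_pairs:
                    compatible.append((da, db))
        if compatible:
            report.n_edges_direct += 1
            for da, db in compatible:
                rule = BindingRule(
                    species_a=a, species_b=b, domain_a=da, domain_b=db,
                    kon=ddi_kon.get(frozenset((da, db)), config.kon_default),
                    koff=config.koff_default, fictitious=False,
                )
                if rule.key() not in seen_rules:
                    seen_rules.add(rule.key())
                    rules.append(rule)
        elif config.use_go and (sa.go_terms & sb.go_terms):
            report.n_edges_fictitious += 1
            report.fictitious_proteins.update((a, b))
            fa, fb = _fictitious_domains(a, b)
            sa.domains.append((fa, 1))
            sb.domains.append((fb, 1))
            rules.append(
                BindingRule(
                    species_a=a, species_b=b, domain_a=fa, domain_b=fb,
                    kon=config.kon_default, koff=config.koff_default,
                    fictitious=True,
                )
            )
        else:
            report.n_edges_dropped_no_shared_go += 1

    if not rules:
        raise ValueError("model has no binding rules: no PPI edge is DDI- or GO-supported")

    model = ReactionModel(
        species=list(species.values()), rules=rules, config=config, build_report=report,
    )
    if config.abundance_mode != "identity":
        model = scale_abundances(model, config.abundance_mode, config.abundance_factor)
    model.validate()
    logger.info(
        "model: %d species, %d rules (%d direct, %d fictitious edges; %d dropped)",
        len(model.species), len(model.rules), report.n_edges_direct,
        report.n_edges_fictitious,
        report.n_edges_dropped_no_shared_go + report.n_edges_dropped_missing_species,
    )
    return model


def scale_abundances(model: ReactionModel, mode: str, k: float | None = None) -> ReactionModel:
    """Transform species abundances (identity, sqrt, or multiply by a factor).

    Scaled abundances are rounded to integers; any species that started
    with at least one copy keeps at least one copy.
    """
    if mode == "identity":
        return model
    if mode == "sqrt":
        transform = math.sqrt
    elif mode == "factor":
        if k is None or k <= 0:
            raise ValueError("factor mode requires k > 0")
        transform = lambda x: x * k  # noqa: E731
    else:
        raise ValueError(f"unknown abundance mode {mode!r}")
    out = _copy.deepcopy(model)
    for s in out.species:
        if s.abundance >= 1:
            s.abundance = max(1, round(transform(s.abundance)))
    return out


def add_species(
    model: ReactionModel,
    species: MolecularSpecies,
    partners: list[tuple[str, tuple[str, str] | None]],
) -> ReactionModel:
    """Add an extra molecular species (drug, rRNA, ...) with its binding rules.

    ``partners`` lists (partner id, optional (domain-on-new, domain-on-
    partner)); when no domain pair is supplied a fictitious pair private
    to the edge is created.  Existing species and rules are untouched.
    """
    by_id = model.species_by_id()
    if species.id in by_id:
        raise ValueError(f"species id {species.id!r} already present in model")
    for pid, _ in partners:
        if pid not in by_id:
            raise ValueError(f"partner {pid!r} not present in model")

    out = _copy.deepcopy(model)
    new = _copy.deepcopy(species)
    out_by_id = out.species_by_id()
    for pid, domain_pair in partners:
        partner = out_by_id[pid]
        if domain_pair is not None:
            d_new, d_partner = domain_pair
            if d_new not in {d for d, _ in new.domains}:
                new.domains.append((d_new, 1))
            if d_partner not in {d for d, _ in partner.domains}:
                partner.domains.append((d_partner, 1))
            fict = False
        else:
            d_new, d_partner = _fictitious_domains(new.id, pid)
            new.domains.append((d_new, 1))
            partner.domains.append((d_partner, 1))
            fict = True
        out.rules.append(
            BindingRule(
                species_a=new.id, species_b=pid, domain_a=d_new, domain_b=d_partner,
                kon=out.config.kon_default, koff=out.config.koff_default,
                fictitious=fict,
            )
        )
    out.species.append(new)
    out.validate()
    return out
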