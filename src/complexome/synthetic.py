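"""Synthetic proteomes with planted ground-truth complexes.

The generator emits every input the pipeline consumes — PPI, DDI, domain
annotations, species attributes, and a reference catalog equal to the
planted truth — for a toy proteome in which the true complexes are
known.  Planted complexes are disjoint cliques by default; each within-
complex edge is realized either by a dedicated domain pair present in
the DDI table or (for a configurable fraction of edges) by a shared GO
term only, which exercises the fictitious-domain rule of the model
builder.  Every planted complex carries one unique GO term shared by all
its members, so spurious between-complex noise edges have neither DDI
support nor a shared term and are dropped during model generation.

Because each within-complex edge uses its own single-copy domain pair, a
molecule can hold at most one bond per planted partner; fully assembled
complexes have no free sites and are inert, which makes the planted
member sets the absorbing states of the binding dynamics at low koff.

Everything is reproducible: the same seed yields byte-identical files.
"""

from __future__ import annotations

import copy as _copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .iofmt import (
    InteractionTable,
    ReferenceComplex,
    ReferenceComplexSet,
    SpeciesAttributeTable,
    SpeciesAttributes,
)
from .model import ModelConfig, MolecularSpecies, ReactionModel, build_model

__all__ = [
    "PlantedComplexTruth",
    "PlantedScenario",
    "generate_scenario",
    "generate_two_condition_pair",
]


@dataclass
class PlantedComplexTruth:
    id: str
    members: list[str]
    abundance: int
    compartment: str = "cell"


@dataclass
class PlantedScenario:
    complexes: list[PlantedComplexTruth]
    ppi: InteractionTable
    ddi: InteractionTable
    domain_annot: InteractionTable
    attrs: SpeciesAttributeTable
    reference: ReferenceComplexSet
    seed: int
    params: dict = field(default_factory=dict)
    compartment_scheme: str = "single"
    extra_species: list[tuple[MolecularSpecies, list]] = field(default_factory=list)
    perturbation: dict = field(default_factory=dict)

    def truth_abundances(self) -> dict[str, int]:
        return {c.id: c.abundance for c in self.complexes}

    def build_model(self, config: ModelConfig | None = None) -> ReactionModel:
        from .model import add_species

        model = build_model(self.ppi, self.ddi, self.domain_annot, self.attrs, config)
        for species, partners in self.extra_species:
            model = add_species(model, species, partners)
        return model

    # -- persistence in the standard TSV dialect ----------------------------

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "ppi.tsv", "w") as fh:
            fh.write("id_a\tid_b\n")
            for a, b in self.ppi.pairs:
                fh.write(f"{a}\t{b}\n")
        with open(outdir / "ddi.tsv", "w") as fh:
            fh.write("domain_a\tdomain_b\n")
            for a, b in self.ddi.pairs:
                fh.write(f"{a}\t{b}\n")
        with open(outdir / "domains.tsv", "w") as fh:
            fh.write("id\tdomain\tcopies\n")
            for sid, dom in self.domain_annot.pairs:
                key = (sid, dom) if sid <= dom else (dom, sid)
                copies = int(self.domain_annot.weights.get(key, 1))
                fh.write(f"{sid}\t{dom}\t{copies}\n")
        with open(outdir / "attributes.tsv", "w") as fh:
            fh.write("id\tabundance\tkind\tcompartments\tgo_terms\tdiffusion_rate\tmax_partners\n")
            for sid in sorted(self.attrs):
                a = self.attrs[sid]
                fh.write(
                    f"{sid}\t{a.abundance:g}\t{a.kind}\t{';'.join(sorted(a.compartments))}\t"
                    f"{';'.join(sorted(a.go_terms))}\t{a.diffusion_rate:g}\t{a.max_partners}\n"
                )
        with open(outdir / "reference.tsv", "w") as fh:
            fh.write("complex_id\tmember\n")
            for c in self.reference:
                for m in sorted(c.members):
                    fh.write(f"{c.id}\t{m}\n")
        manifest = {
            "seed": self.seed,
            "params": self.params,
            "compartment_scheme": self.compartment_scheme,
            "perturbation": self.perturbation,
            "complexes": [
                {
                    "id": c.id,
                    "members": list(c.members),
                    "abundance": c.abundance,
                    "compartment": c.compartment,
                }
                for c in self.complexes
            ],
            "extra_species": [
                {"id": sp.id, "kind": sp.kind, "abundance": sp.abundance,
                 "partners": [p for p, _ in partners]}
                for sp, partners in self.extra_species
            ],
        }
        (outdir / "truth.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return outdir


def generate_scenario(
    n_complexes: int = 10,
    size_range: tuple[int, int] = (3, 6),
    abundance_levels: tuple[int, ...] = (20, 40, 80),
    noise_edge_rate: float = 0.0,
    fictitious_fraction: float = 0.2,
    compartment_scheme: str = "single",
    seed: int = 0,
    excess_free: int = 0,
    overlap_proteins: int = 0,
) -> PlantedScenario:
    """Generate a toy proteome with planted, disjoint ground-truth complexes.

    Every within-complex protein pair is a PPI edge; a fraction
    ``fictitious_fraction`` of these edges has no DDI support and relies
    on the complex's shared GO term.  ``noise_edge_rate`` adds that
    fraction (relative to the number of within-complex edges) of spurious
    between-complex edges with neither DDI nor shared GO terms.  Protein
    abundance equals its complex's planted abundance level (cycled from
    ``abundance_levels``) plus ``excess_free`` unassembled copies.
    ``overlap_proteins`` shared subunits can be introduced between
    consecutive complexes to stress the split/merge logic.
    """
    if n_complexes < 1:
        raise ValueError("need at least one planted complex")
    lo, hi = size_range
    if lo < 2:
        raise ValueError("complex sizes must be >= 2")
    if compartment_scheme not in ("single", "two"):
        raise ValueError(f"unknown compartment scheme {compartment_scheme!r}")
    rng = np.random.default_rng(seed)

    complexes: list[PlantedComplexTruth] = []
    members_of: dict[str, list[str]] = {}
    for c in range(n_complexes):
        cid = f"c{c + 1:02d}"
        size = int(rng.integers(lo, hi + 1))
        members = [f"{cid.upper()}P{k + 1}" for k in range(size)]
        compartment = "cell" if compartment_scheme == "single" else ("n" if c % 2 == 0 else "c")
        complexes.append(
            PlantedComplexTruth(
                id=cid,
                members=members,
                abundance=int(abundance_levels[c % len(abundance_levels)]),
                compartment=compartment,
            )
        )
        members_of[cid] = members

    # shared subunits between consecutive complexes (optional stress mode)
    for k in range(overlap_proteins):
        c = k % max(1, n_complexes - 1)
        donor, host = complexes[c], complexes[c + 1]
        shared = donor.members[0]
        if shared not in host.members:
            host.members.append(shared)

    ppi = InteractionTable(kind="ppi")
    ddi = InteractionTable(kind="ddi")
    annot = InteractionTable(kind="species_domain")
    attrs = SpeciesAttributeTable()

    for c in complexes:
        go_term = f"GO:{c.id}"
        for p in c.members:
            if p not in attrs:
                attrs[p] = SpeciesAttributes(
                    id=p,
                    abundance=c.abundance + excess_free,
                    compartments={c.compartment},
                    go_terms={go_term},
                )
            else:  # shared subunit: allowed in both compartments, both GO terms
                attrs[p].compartments.add(c.compartment)
                attrs[p].go_terms.add(go_term)
        members = c.members
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                if (a, b) in ppi.pairs or (b, a) in ppi.pairs:
                    continue
                ppi.pairs.append((a, b))
                if rng.random() < fictitious_fraction:
                    continue  # realized through the shared GO term only
                da = f"d[{c.id}:{a}-{b}]@{a}"
                db = f"d[{c.id}:{a}-{b}]@{b}"
                annot.pairs.append((a, da))
                annot.pairs.append((b, db))
                ddi.pairs.append((da, db))

    n_within = len(ppi.pairs)
    n_noise = int(round(noise_edge_rate * n_within))
    all_proteins = sorted(attrs)
    complex_of = {p: c.id for c in complexes for p in c.members}
    existing = {frozenset(p) for p in ppi.pairs}
    attempts = 0
    added = 0
    while added < n_noise and attempts < 100 * max(1, n_noise):
        attempts += 1
        a, b = (all_proteins[int(k)] for k in rng.integers(len(all_proteins), size=2))
        if a == b or complex_of[a] == complex_of[b] or frozenset((a, b)) in existing:
            continue
        ppi.pairs.append((a, b))
        existing.add(frozenset((a, b)))
        added += 1

    ppi.n_read = len(ppi.pairs)
    ddi.n_read = len(ddi.pairs)
    annot.n_read = len(annot.pairs)

    reference = ReferenceComplexSet(
        [ReferenceComplex(id=c.id, members=frozenset(c.members)) for c in complexes]
    )
    return PlantedScenario(
        complexes=complexes,
        ppi=ppi,
        ddi=ddi,
        domain_annot=annot,
        attrs=attrs,
        reference=reference,
        seed=seed,
        compartment_scheme=compartment_scheme,
        params={
            "n_complexes": n_complexes,
            "size_range": list(size_range),
            "abundance_levels": list(abundance_levels),
            "noise_edge_rate": noise_edge_rate,
            "fictitious_fraction": fictitious_fraction,
            "excess_free": excess_free,
            "overlap_proteins": overlap_proteins,
        },
    )


def generate_two_condition_pair(
    base: PlantedScenario, perturbation: dict
) -> tuple[PlantedScenario, PlantedScenario]:
    """Derive a (baseline, perturbed) scenario pair differing only as stated.

    Supported perturbations:

    * ``{"kind": "identity"}`` — B is an exact copy of A;
    * ``{"kind": "scale_complex", "complex_id": ..., "factor": f}`` —
      the members of one planted complex change abundance by ``f``;
    * ``{"kind": "add_drug", "id": ..., "partners": [...], "abundance": n}``
      — a drug species with fictitious bindings to the listed partner
      proteins is added to the model of B.
    """
    a = base
    b = _copy.deepcopy(base)
    b.perturbation = dict(perturbation)
    kind = perturbation.get("kind", "identity")
    if kind == "identity":
        pass
    elif kind == "scale_complex":
        cid = perturbation["complex_id"]
        factor = float(perturbation["factor"])
        truth = {c.id: c for c in b.complexes}
        if cid not in truth:
            raise ValueError(f"unknown planted complex {cid!r}")
        target = truth[cid]
        target.abundance = int(round(target.abundance * factor))
        for p in target.members:
            b.attrs[p].abundance = round(b.attrs[p].abundance * factor)
    elif kind == "add_drug":
        partners = list(perturbation["partners"])
        unknown = [p for p in partners if p not in b.attrs]
        if unknown:
            raise ValueError(f"drug partners not in scenario: {unknown}")
        drug = MolecularSpecies(
            id=perturbation.get("id", "drug1"),
            kind="drug",
            abundance=int(perturbation.get("abundance", 50)),
            compartments=set().union(*(b.attrs[p].compartments for p in partners)),
        )
        b.extra_species.append((drug, [(p, None) for p in partners]))
    else:
        raise ValueError(f"unknown perturbation kind {kind!r}")
    return a, b
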