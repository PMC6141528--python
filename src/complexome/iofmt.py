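"""Readers and writers for every table the tool touches.

All inputs are headered, tab-separated text files; multi-valued cells use
";" as the inner separator and identifiers are case-sensitive strings.
The formats are:

``ppi`` / ``ddi`` / ``extra_species``
    two identifier columns (plus an optional numeric weight column);
``species_domain``
    species identifier, domain identifier, optional copy count;
attributes
    one row per species with at least ``id`` and ``abundance``; optional
    columns ``compartments``, ``go_terms``, ``domains`` (``dom:copies``
    items), ``diffusion_rate``, ``max_partners``, ``kind``;
reference complexes
    two columns (complex id, member protein), CYC2008/CORUM style.

Outputs are a per-complex CSV report, a raw simulated-complex table, and
a Cytoscape-importable SIF edge file with a node attribute table.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionTable",
    "SpeciesAttributes",
    "SpeciesAttributeTable",
    "ReferenceComplex",
    "ReferenceComplexSet",
    "read_interaction_table",
    "read_species_attributes",
    "read_reference_complexes",
    "read_compartment_map",
    "export_complex_report",
    "read_complex_report",
    "export_network",
    "write_sc_table",
    "read_sc_table",
]

MAX_PARTNERS_DEFAULT = 10
DIFFUSION_RATE_DEFAULT = 1.0
DEFAULT_COMPARTMENT = "cell"

_INTERACTION_KINDS = ("ppi", "ddi", "species_domain", "extra_species")


@dataclass
class InteractionTable:
    """Deduplicated unordered pair list with optional weights."""

    kind: str
    pairs: list[tuple[str, str]] = field(default_factory=list)
    weights: dict[tuple[str, str], float] = field(default_factory=dict)
    n_read: int = 0
    n_dropped_self: int = 0
    n_dropped_duplicate: int = 0

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def degree(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for a, b in self.pairs:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        return deg


@dataclass
class SpeciesAttributes:
    id: str
    abundance: float
    kind: str = "protein"
    compartments: set[str] = field(default_factory=lambda: {DEFAULT_COMPARTMENT})
    go_terms: set[str] = field(default_factory=set)
    domains: list[tuple[str, int]] = field(default_factory=list)
    diffusion_rate: float = DIFFUSION_RATE_DEFAULT
    max_partners: int = MAX_PARTNERS_DEFAULT


class SpeciesAttributeTable(dict):
    """Mapping species id -> :class:`SpeciesAttributes`."""

    def compartment_map(self) -> dict[str, set[str]]:
        return {sid: set(a.compartments) for sid, a in self.items()}


@dataclass
class ReferenceComplex:
    id: str
    members: frozenset[str]
    name: str = ""

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ReferenceComplexSet:
    complexes: list[ReferenceComplex]

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)

    def member_sets(self) -> list[frozenset[str]]:
        return [c.members for c in self.complexes]

    def ids(self) -> list[str]:
        return [c.id for c in self.complexes]


def _split_multi(cell: str) -> list[str]:
    return [x.strip() for x in str(cell).split(";") if x.strip()]


def read_interaction_table(path: str | Path, kind: str = "ppi") -> InteractionTable:
    """Read a two-column pair table; drop self-pairs, deduplicate unordered pairs."""
    if kind not in _INTERACTION_KINDS:
        raise ValueError(f"unknown interaction kind {kind!r}; expected one of {_INTERACTION_KINDS}")
    path = Path(path)
    table = InteractionTable(kind=kind)
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    for lineno, line in enumerate(lines[1:], start=2):  # line 1 is the header
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) < 2 or not cells[0].strip() or not cells[1].strip():
            raise ValueError(f"{path}:{lineno}: malformed row (need >= 2 tab-separated columns)")
        a, b = cells[0].strip(), cells[1].strip()
        weight = None
        if len(cells) > 2 and cells[2].strip():
            try:
                weight = float(cells[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric weight {cells[2]!r}") from exc
        table.n_read += 1
        if a == b:
            table.n_dropped_self += 1
            continue
        key = (a, b) if a <= b else (b, a)
        if key in seen:
            table.n_dropped_duplicate += 1
            continue
        seen.add(key)
        table.pairs.append((a, b))
        if weight is not None:
            table.weights[key] = weight
    if table.n_dropped_self:
        logger.warning("%s: dropped %d self-pair(s)", path, table.n_dropped_self)
    logger.info(
        "%s [%s]: %d rows read, %d kept (%d self, %d duplicate dropped)",
        path, kind, table.n_read, len(table.pairs),
        table.n_dropped_self, table.n_dropped_duplicate,
    )
    return table


_KNOWN_ATTR_COLUMNS = {
    "id", "abundance", "kind", "compartments", "go_terms", "domains",
    "diffusion_rate", "max_partners",
}


def read_species_attributes(path: str | Path) -> SpeciesAttributeTable:
    """Read the per-species attribute table, filling documented defaults."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    df.columns = [c.strip() for c in df.columns]
    for required in ("id", "abundance"):
        if required not in df.columns:
            raise ValueError(f"{path}: missing required column {required!r}")
    for col in df.columns:
        if col not in _KNOWN_ATTR_COLUMNS:
            logger.warning("%s: ignoring unknown column %r", path, col)

    out = SpeciesAttributeTable()
    for row in df.itertuples(index=False):
        rec = row._asdict()
        sid = str(rec["id"]).strip()
        abundance = float(rec["abundance"])
        if abundance < 0:
            raise ValueError(f"{path}: species {sid!r} has negative abundance {abundance}")
        attrs = SpeciesAttributes(id=sid, abundance=abundance)
        if rec.get("kind", "").strip():
            attrs.kind = rec["kind"].strip()
        if rec.get("compartments", "").strip():
            attrs.compartments = set(_split_multi(rec["compartments"]))
        if rec.get("go_terms", "").strip():
            attrs.go_terms = set(_split_multi(rec["go_terms"]))
        if rec.get("domains", "").strip():
            domains = []
            for item in _split_multi(rec["domains"]):
                dom, _, copies = item.partition(":")
                n = int(copies) if copies else 1
                if n < 1:
                    raise ValueError(f"{path}: species {sid!r} domain {dom!r} has copy count {n} < 1")
                domains.append((dom, n))
            attrs.domains = domains
        if rec.get("diffusion_rate", "").strip():
            attrs.diffusion_rate = float(rec["diffusion_rate"])
            if attrs.diffusion_rate < 0:
                raise ValueError(f"{path}: species {sid!r} has negative diffusion rate")
        if rec.get("max_partners", "").strip():
            attrs.max_partners = int(rec["max_partners"])
            if attrs.max_partners < 1:
                raise ValueError(f"{path}: species {sid!r} has max_partners < 1")
        out[sid] = attrs
    return out


def read_reference_complexes(path: str | Path) -> ReferenceComplexSet:
    """Read a two-column (complex id, member) catalog; complexes need >= 2 members."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 columns (complex id, member)")
    cid_col, member_col = df.columns[0], df.columns[1]
    name_col = df.columns[2] if df.shape[1] > 2 else None
    complexes = []
    for cid, group in df.groupby(cid_col, sort=False):
        members = frozenset(str(m).strip() for m in group[member_col] if str(m).strip())
        if len(members) < 2:
            logger.warning("%s: complex %r has < 2 members, dropped", path, cid)
            continue
        name = str(group[name_col].iloc[0]) if name_col else ""
        complexes.append(ReferenceComplex(id=str(cid), members=members, name=name))
    if not complexes:
        raise ValueError(f"{path}: no reference complex with >= 2 members")
    return ReferenceComplexSet(complexes)


def read_compartment_map(path: str | Path) -> list[list[str]]:
    """Read a text grid of single-character compartment labels (one row per line)."""
    rows = [list(line) for line in Path(path).read_text().splitlines() if line]
    if not rows:
        raise ValueError(f"{path}: empty compartment map")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError(f"{path}: ragged compartment map (rows of unequal width)")
    return rows


# ---------------------------------------------------------------------------
# reports and exports


def export_complex_report(
    rcs,
    path: str | Path,
    reference: ReferenceComplexSet | None = None,
) -> None:
    """Write one CSV row per refined complex (id, size, members, abundance, best match)."""
    rcs = list(rcs)
    if not rcs:
        raise ValueError("refusing to write an empty complex report")
    from .metrics import overlap_score  # local import keeps module deps one-way

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "size", "members", "abundance", "best_reference", "best_overlap"])
        for rc in rcs:
            best_id, best_o = "", ""
            if reference is not None:
                scored = [(overlap_score(rc.members, r.members), r.id) for r in reference]
                if scored:
                    o, rid = max(scored)
                    best_id, best_o = rid, f"{o:.6g}"
            writer.writerow([
                rc.id,
                len(rc.members),
                ";".join(sorted(rc.members)),
                rc.abundance,
                best_id,
                best_o,
            ])


def read_complex_report(path: str | Path):
    """Read a complex report back into :class:`~complexome.refine.RefinedComplex` objects."""
    from .refine import RefinedComplex

    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                RefinedComplex(
                    id=row["id"],
                    members=frozenset(_split_multi(row["members"])),
                    abundance=float(row["abundance"]),
                )
            )
    return out


def export_network(
    rcs,
    scs,
    species_abundances: Mapping[str, float],
    path_prefix: str | Path,
) -> tuple[Path, Path]:
    """Export refined complexes as a SIF edge file plus a node attribute table.

    The edge file has one ``protein  bond  protein`` line per distinct
    intra-complex bond type observed in the simulated complexes assigned
    to each refined complex.  The attribute table is keyed (protein,
    complex) and carries the per-complex protein abundance ``A_i^c`` and
    the specificity ``S_i^c = A_i^c / A_i``.
    """
    path_prefix = Path(path_prefix)
    sif_path = path_prefix.with_suffix(".sif")
    attr_path = path_prefix.with_suffix(".attrs.tsv")
    sc_by_id = {sc.id: sc for sc in scs}

    with open(sif_path, "w") as fh:
        for rc in rcs:
            edges: set[tuple[str, str]] = set()
            for scid in rc.assigned_sc_ids:
                sc = sc_by_id[scid]
                for i, j in sc.bonds:
                    a, b = sc.members[i], sc.members[j]
                    edges.add((a, b) if a <= b else (b, a))
            for a, b in sorted(edges):
                fh.write(f"{a}\tbond\t{b}\n")

    with open(attr_path, "w") as fh:
        fh.write("protein\tcomplex\tabundance_in_complex\ttotal_abundance\tspecificity\n")
        for rc in rcs:
            counts: dict[str, float] = {}
            for scid in rc.assigned_sc_ids:
                for m in sc_by_id[scid].members:
                    counts[m] = counts.get(m, 0.0) + 1.0
            for prot in sorted(counts):
                total = float(species_abundances.get(prot, 0.0))
                spec = counts[prot] / total if total > 0 else ""
                fh.write(f"{prot}\t{rc.id}\t{counts[prot]:g}\t{total:g}\t"
                         f"{spec if spec == '' else format(spec, '.6g')}\n")
    return sif_path, attr_path


def write_sc_table(scs: Iterable, path: str | Path) -> None:
    """Write the raw simulated-complex table (run, sample, members, bonds)."""
    with open(path, "w") as fh:
        fh.write("id\trun\tsample\tmembers\tbonds\n")
        for sc in scs:
            bonds = ";".join(f"{i}-{j}" for i, j in sc.bonds)
            fh.write(f"{sc.id}\t{sc.run}\t{sc.sample}\t{';'.join(sc.members)}\t{bonds}\n")


def read_sc_table(path: str | Path):
    """Read a raw simulated-complex table back into ``SimulatedComplex`` objects."""
    from .simulator import SimulatedComplex

    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty simulated-complex table")
        for line in fh:
            if not line.strip():
                continue
            scid, run, sample, members, bonds = line.rstrip("\n").split("\t")
            bond_list = []
            for item in _split_multi(bonds):
                i, _, j = item.partition("-")
                bond_list.append((int(i), int(j)))
            out.append(
                SimulatedComplex(
                    id=scid,
                    members=_split_multi(members),
                    bonds=bond_list,
                    run=int(run),
                    sample=int(sample),
                )
            )
    return out
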