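"""Protein-protein interface characterization.

Implements the quantities used to describe a binding interface between two
molecules of a complex: solvent-accessible surface area (SASA) by the
Shrake-Rupley sphere-sampling construction, buried surface area per
molecule, interface residue lists and spans, typed cross-molecule contacts
(salt bridges, hydrogen bonds, hydrophobic), hydrophobic clusters, and
"pin" residues — single residues whose sidechain inserts deeply into a
hydrophobic pocket of the partner molecule.

The molecule partition is explicit: a pair of selections, e.g. the two
chains of a homodimer as one molecule and the bound domain as the other.

All geometric cutoffs are parameters with field-standard defaults; none of
them is fitted to data.  Hydrogens are excluded everywhere (predicted
models have none); hydrogen bonds are therefore distance-only, without
donor-acceptor angle terms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structio import (Atom, Chain, Residue, SelectionSpec, StructureModel,
                       select)

__all__ = [
    "VDW_RADII",
    "SasaResult",
    "Contact",
    "ResAtomRef",
    "HydrophobicCluster",
    "InterfaceReport",
    "shrake_rupley_sasa",
    "buried_surface_area",
    "interface_residues",
    "classify_contacts",
    "hydrophobic_clusters",
    "pin_residues",
    "interface_report",
]

#: Van der Waals radii (Angstrom).  A compact field-standard table; other
#: elements require an explicit override.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "H": 1.20,
    "D": 1.20,
}

_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

#: Residues whose sidechains count as hydrophobic for contact typing.
HYDROPHOBIC_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP",
                        "TYR", "PRO"}

#: Sidechain nitrogen atoms of basic residues (salt-bridge donors).
_BASIC_SIDECHAIN_N = {
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"},
}

#: Sidechain carboxylate oxygens of acidic residues (salt-bridge acceptors).
_ACIDIC_CARBOXYLATE_O = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}

ResKey = tuple[str, int, str]  # (chain_id, res_seq, icode)


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA
# ---------------------------------------------------------------------------

def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit sphere points (Fibonacci lattice)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class SasaResult:
    """Per-atom and per-residue solvent-accessible surface areas (A^2)."""

    per_atom: dict[tuple[ResKey, str], float]
    per_residue: dict[ResKey, float]
    total: float
    probe_radius: float
    n_points: int

    def residue_area(self, chain_id: str, res_seq: int, icode: str = "") -> float:
        return self.per_residue.get((chain_id, res_seq, icode), 0.0)

    def sidechain_area(self, chain_id: str, res_seq: int, icode: str = "") -> float:
        key = (chain_id, res_seq, icode)
        return sum(area for (rkey, name), area in self.per_atom.items()
                   if rkey == key and name not in _BACKBONE_ATOMS)


def _heavy_atom_arrays(model: StructureModel,
                       radii: dict[str, float]) -> tuple[list, np.ndarray, np.ndarray]:
    atoms: list[tuple[ResKey, str]] = []
    coords: list[np.ndarray] = []
    rads: list[float] = []
    for chain, res, atom in model.iter_atoms():
        if atom.is_hydrogen:
            continue
        radius = radii.get(atom.element)
        if radius is None:
            raise ValueError(
                f"no van der Waals radius for element {atom.element!r}; "
                "supply a radius override")
        atoms.append(((chain.chain_id, res.res_seq, res.icode), atom.name))
        coords.append(atom.coords)
        rads.append(radius)
    if not atoms:
        raise ValueError("model has no heavy atoms")
    return atoms, np.asarray(coords), np.asarray(rads)


def shrake_rupley_sasa(
    model: StructureModel,
    probe: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
) -> SasaResult:
    """Shrake-Rupley SASA over the heavy atoms of ``model``.

    Each atom is given a sphere of radius (vdW + probe) sampled with a
    deterministic golden-spiral point set; a point is accessible when it
    lies outside every neighbouring expanded sphere.  There is no
    randomness: identical inputs give identical areas.
    """
    table = dict(VDW_RADII)
    if radii:
        table.update({k.upper(): v for k, v in radii.items()})
    keys, coords, rads = _heavy_atom_arrays(model, table)
    n_atoms = coords.shape[0]
    expanded = rads + probe
    sphere = _golden_spiral(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()

    per_atom: dict[tuple[ResKey, str], float] = {}
    per_residue: dict[ResKey, float] = {}
    neighbor_lists = tree.query_ball_point(coords, max_reach)
    for i in range(n_atoms):
        ri = expanded[i]
        pts = coords[i] + ri * sphere
        nbrs = [j for j in neighbor_lists[i] if j != i]
        if nbrs:
            nbrs = np.asarray(nbrs)
            # keep only neighbours whose expanded sphere can reach ours
            d = np.linalg.norm(coords[nbrs] - coords[i], axis=1)
            close = nbrs[d < ri + expanded[nbrs]]
        else:
            close = np.empty(0, dtype=int)
        if close.size:
            diff = pts[:, None, :] - coords[close][None, :, :]
            dist2 = np.einsum("pnk,pnk->pn", diff, diff)
            buried = np.any(dist2 < (expanded[close] ** 2)[None, :], axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        area = 4.0 * math.pi * ri * ri * frac
        per_atom[keys[i]] = area
        rkey = keys[i][0]
        per_residue[rkey] = per_residue.get(rkey, 0.0) + area
    return SasaResult(
        per_atom=per_atom,
        per_residue=per_residue,
        total=float(sum(per_atom.values())),
        probe_radius=probe,
        n_points=n_points,
    )


# ---------------------------------------------------------------------------
# Partition handling
# ---------------------------------------------------------------------------

Partition = tuple[SelectionSpec, SelectionSpec]


def partition_from_chains(group1: Iterable[str], group2: Iterable[str]) -> Partition:
    return (SelectionSpec(chain_id=tuple(group1)),
            SelectionSpec(chain_id=tuple(group2)))


def _split(model: StructureModel, partition: Partition
           ) -> tuple[StructureModel, StructureModel]:
    g1 = select(model, partition[0])
    g2 = select(model, partition[1])
    if not g1.chains or not g2.chains:
        raise ValueError("both partition groups must select at least one atom")
    keys1 = {(c.chain_id, r.res_seq, r.icode, a.name) for c, r, a in g1.iter_atoms()}
    keys2 = {(c.chain_id, r.res_seq, r.icode, a.name) for c, r, a in g2.iter_atoms()}
    if keys1 & keys2:
        raise ValueError("partition groups overlap")
    return g1, g2


def _union_model(g1: StructureModel, g2: StructureModel) -> StructureModel:
    chains = [c.copy() for c in g1.chains] + [c.copy() for c in g2.chains]
    return StructureModel(g1.model_id, chains, g1.source)


# ---------------------------------------------------------------------------
# Buried surface area
# ---------------------------------------------------------------------------

def buried_surface_area(
    complex_model: StructureModel,
    partition: Partition,
    probe: float = 1.4,
    n_points: int = 960,
) -> tuple[float, float]:
    """Surface area (A^2) each molecule buries on complex formation.

    BSA of a group is its isolated SASA minus its SASA contribution within
    the complex, so that bsa1 + bsa2 = SASA1 + SASA2 - SASA12 exactly.
    Values are clamped at zero for reporting.
    """
    g1, g2 = _split(complex_model, partition)
    both = _union_model(g1, g2)
    sasa1 = shrake_rupley_sasa(g1, probe, n_points)
    sasa2 = shrake_rupley_sasa(g2, probe, n_points)
    sasa12 = shrake_rupley_sasa(both, probe, n_points)

    def group_in_complex(group: StructureModel) -> float:
        keys = {(c.chain_id, r.res_seq, r.icode) for c, r in group.iter_residues()}
        return sum(area for rkey, area in sasa12.per_residue.items() if rkey in keys)

    bsa1 = sasa1.total - group_in_complex(g1)
    bsa2 = sasa2.total - group_in_complex(g2)
    return (max(bsa1, 0.0), max(bsa2, 0.0))


# ---------------------------------------------------------------------------
# Interface residues
# ---------------------------------------------------------------------------

def _cross_contact_residues(g1: StructureModel, g2: StructureModel,
                            contact_dist: float) -> tuple[set[ResKey], set[ResKey]]:
    keys1, coords1, _ = _heavy_atom_arrays(g1, VDW_RADII)
    keys2, coords2, _ = _heavy_atom_arrays(g2, VDW_RADII)
    tree2 = cKDTree(coords2)
    pairs = tree2.query_ball_point(coords1, contact_dist)
    res1: set[ResKey] = set()
    res2: set[ResKey] = set()
    for i, hits in enumerate(pairs):
        if hits:
            res1.add(keys1[i][0])
            for j in hits:
                res2.add(keys2[j][0])
    return res1, res2


def interface_residues(
    complex_model: StructureModel,
    partition: Partition,
    dsasa_min: float = 0.1,
    contact_dist: float = 5.0,
    probe: float = 1.4,
    n_points: int = 960,
) -> dict[str, dict]:
    """Interfacial residues per chain, with (min, max) author-number spans.

    A residue is interfacial when its per-residue SASA drops by more than
    ``dsasa_min`` on complex formation, or when any of its heavy atoms lies
    within ``contact_dist`` of the partner molecule.
    """
    g1, g2 = _split(complex_model, partition)
    both = _union_model(g1, g2)
    sasa12 = shrake_rupley_sasa(both, probe, n_points)
    members: set[ResKey] = set()
    for group in (g1, g2):
        iso = shrake_rupley_sasa(group, probe, n_points)
        for rkey, area in iso.per_residue.items():
            if area - sasa12.per_residue.get(rkey, 0.0) > dsasa_min:
                members.add(rkey)
    near1, near2 = _cross_contact_residues(g1, g2, contact_dist)
    members |= near1 | near2

    out: dict[str, dict] = {}
    for chain_id in sorted({k[0] for k in members}):
        res_list = sorted(k[1] for k in members if k[0] == chain_id)
        out[chain_id] = {"residues": res_list,
                         "span": (res_list[0], res_list[-1])}
    return out


# ---------------------------------------------------------------------------
# Typed contacts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResAtomRef:
    chain_id: str
    res_seq: int
    icode: str
    res_name: str
    atom_name: str

    @property
    def res_key(self) -> ResKey:
        return (self.chain_id, self.res_seq, self.icode)


@dataclass(frozen=True)
class Contact:
    """One cross-molecule atom pair under its highest-priority type."""

    kind: str  # salt_bridge | hydrogen_bond | hydrophobic
    atom_a: ResAtomRef
    atom_b: ResAtomRef
    distance: float


_KIND_CUTOFFS = {"salt_bridge": 4.0, "hydrogen_bond": 3.5, "hydrophobic": 4.5}


def _is_salt_bridge(ref_x: ResAtomRef, ref_y: ResAtomRef) -> bool:
    def basic_n(r: ResAtomRef) -> bool:
        return r.atom_name in _BASIC_SIDECHAIN_N.get(r.res_name, ())

    def acidic_o(r: ResAtomRef) -> bool:
        return r.atom_name in _ACIDIC_CARBOXYLATE_O.get(r.res_name, ())

    return (basic_n(ref_x) and acidic_o(ref_y)) or (basic_n(ref_y) and acidic_o(ref_x))


def classify_contacts(
    complex_model: StructureModel,
    partition: Partition,
    salt_bridge_dist: float = 4.0,
    hbond_dist: float = 3.5,
    hydrophobic_dist: float = 4.5,
) -> list[Contact]:
    """Cross-molecule heavy-atom contacts, typed by priority.

    * salt_bridge: sidechain N of Lys/Arg/His against a sidechain
      carboxylate O of Asp/Glu within ``salt_bridge_dist``;
    * hydrogen_bond: any remaining N/O pair within ``hbond_dist``
      (distance-only — predicted models carry no hydrogens);
    * hydrophobic: sidechain carbon pair within ``hydrophobic_dist`` where
      both residues are apolar.

    Each atom pair is reported once, under the highest-priority kind it
    satisfies (salt_bridge > hydrogen_bond > hydrophobic).
    """
    g1, g2 = _split(complex_model, partition)

    def refs_and_coords(group: StructureModel):
        refs, coords = [], []
        for chain, res, atom in group.iter_atoms():
            if atom.is_hydrogen:
                continue
            refs.append(ResAtomRef(chain.chain_id, res.res_seq, res.icode,
                                   res.res_name, atom.name))
            coords.append(atom.coords)
        return refs, np.asarray(coords)

    refs1, coords1 = refs_and_coords(g1)
    refs2, coords2 = refs_and_coords(g2)
    max_cut = max(salt_bridge_dist, hbond_dist, hydrophobic_dist)
    tree2 = cKDTree(coords2)
    hits = cKDTree(coords1).query_ball_tree(tree2, max_cut)

    contacts: list[Contact] = []
    for i, row in enumerate(hits):
        ra = refs1[i]
        for j in row:
            rb = refs2[j]
            dist = float(np.linalg.norm(coords1[i] - coords2[j]))
            kind = None
            if dist <= salt_bridge_dist and _is_salt_bridge(ra, rb):
                kind = "salt_bridge"
            elif (dist <= hbond_dist
                  and ra.atom_name[0] in "NO" and rb.atom_name[0] in "NO"):
                kind = "hydrogen_bond"
            elif (dist <= hydrophobic_dist
                  and ra.res_name in HYDROPHOBIC_RESIDUES
                  and rb.res_name in HYDROPHOBIC_RESIDUES
                  and ra.atom_name.startswith("C") and ra.atom_name not in _BACKBONE_ATOMS
                  and rb.atom_name.startswith("C") and rb.atom_name not in _BACKBONE_ATOMS):
                kind = "hydrophobic"
            if kind is not None:
                contacts.append(Contact(kind, ra, rb, dist))
    contacts.sort(key=lambda c: (c.atom_a.res_key, c.atom_b.res_key,
                                 c.atom_a.atom_name, c.atom_b.atom_name))
    for c in contacts:
        assert c.distance <= _KIND_CUTOFFS[c.kind] + 1e-9
    return contacts


def residue_pair_contacts(contacts: list[Contact]) -> set[tuple[ResKey, ResKey, str]]:
    """Collapse atom-level contacts to (residue_a, residue_b, kind) triples."""
    return {(c.atom_a.res_key, c.atom_b.res_key, c.kind) for c in contacts}


# ---------------------------------------------------------------------------
# Hydrophobic clusters and pins
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HydrophobicCluster:
    """Connected patch of hydrophobic interface residues on one molecule,
    with the partner residues ("pins") that contact at least half of it."""

    members: frozenset[ResKey]
    partner_pins: tuple[ResKey, ...]


def hydrophobic_clusters(
    contacts: list[Contact],
    side: str = "b",
    neighbor_sep: int = 4,
) -> list[HydrophobicCluster]:
    """Group one molecule's hydrophobic interface residues into clusters.

    Nodes are the residues of the chosen side ("a" = partition group 1,
    "b" = group 2) that make cross-molecule hydrophobic contacts.  Two
    nodes are joined when they share a common contact partner, or when
    they are sequence neighbours (same chain, residue numbers within
    ``neighbor_sep``).  Clusters are the connected components.
    """
    import networkx as nx

    if side not in ("a", "b"):
        raise ValueError("side must be 'a' or 'b'")
    partners: dict[ResKey, set[ResKey]] = {}
    for c in contacts:
        if c.kind != "hydrophobic":
            continue
        mine = c.atom_a.res_key if side == "a" else c.atom_b.res_key
        other = c.atom_b.res_key if side == "a" else c.atom_a.res_key
        partners.setdefault(mine, set()).add(other)
    graph = nx.Graph()
    graph.add_nodes_from(partners)
    nodes = sorted(partners)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            if partners[u] & partners[v]:
                graph.add_edge(u, v)
            elif u[0] == v[0] and abs(u[1] - v[1]) <= neighbor_sep:
                graph.add_edge(u, v)
    clusters = []
    for comp in nx.connected_components(graph):
        members = frozenset(comp)
        counts: dict[ResKey, int] = {}
        for node in members:
            for p in partners[node]:
                counts[p] = counts.get(p, 0) + 1
        pins = tuple(sorted(p for p, n in counts.items()
                            if n >= len(members) / 2.0))
        clusters.append(HydrophobicCluster(members=members, partner_pins=pins))
    clusters.sort(key=lambda c: min(c.members))
    return clusters


@dataclass(frozen=True)
class PinResidue:
    residue: ResKey
    res_name: str
    pocket: tuple[ResKey, ...]
    buried_fraction: float
    n_partners: int


def pin_residues(
    complex_model: StructureModel,
    partition: Partition,
    contacts: list[Contact] | None = None,
    burial_min: float = 0.75,
    partner_min: int = 4,
    probe: float = 1.4,
    n_points: int = 960,
) -> list[PinResidue]:
    """Residues whose sidechain is a "pin": buried by the partner molecule
    (sidechain dSASA / isolated sidechain SASA >= ``burial_min``) while
    making hydrophobic contacts with at least ``partner_min`` distinct
    partner residues.  The thresholds are heuristics, documented as such.
    """
    g1, g2 = _split(complex_model, partition)
    if contacts is None:
        contacts = classify_contacts(complex_model, partition)
    both = _union_model(g1, g2)
    sasa12 = shrake_rupley_sasa(both, probe, n_points)
    sasa_iso = {id(g): shrake_rupley_sasa(g, probe, n_points) for g in (g1, g2)}

    partner_map: dict[ResKey, set[ResKey]] = {}
    name_map: dict[ResKey, str] = {}
    for c in contacts:
        if c.kind != "hydrophobic":
            continue
        partner_map.setdefault(c.atom_a.res_key, set()).add(c.atom_b.res_key)
        partner_map.setdefault(c.atom_b.res_key, set()).add(c.atom_a.res_key)
        name_map[c.atom_a.res_key] = c.atom_a.res_name
        name_map[c.atom_b.res_key] = c.atom_b.res_name

    pins: list[PinResidue] = []
    for group in (g1, g2):
        iso = sasa_iso[id(group)]
        group_keys = {(c.chain_id, r.res_seq, r.icode)
                      for c, r in group.iter_residues()}
        for rkey in sorted(group_keys & set(partner_map)):
            partners = partner_map[rkey]
            if len(partners) < partner_min:
                continue
            iso_sc = iso.sidechain_area(*rkey)
            cpx_sc = sasa12.sidechain_area(*rkey)
            if iso_sc <= 1e-9:
                continue
            frac = (iso_sc - cpx_sc) / iso_sc
            if frac >= burial_min:
                pins.append(PinResidue(
                    residue=rkey,
                    res_name=name_map.get(rkey, "UNK"),
                    pocket=tuple(sorted(partners)),
                    buried_fraction=float(frac),
                    n_partners=len(partners),
                ))
    pins.sort(key=lambda p: p.residue)
    return pins


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class InterfaceReport:
    """Full interface description for one molecule partition."""

    bsa_group1: float
    bsa_group2: float
    bsa_per_chain: dict[str, float]
    interface: dict[str, dict]
    contacts: list[Contact]
    clusters: list[HydrophobicCluster]
    pins: list[PinResidue]
    asymmetric: bool
    options: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "bsa_group1_A2": round(self.bsa_group1, 2),
            "bsa_group2_A2": round(self.bsa_group2, 2),
            "bsa_per_chain_A2": {k: round(v, 2)
                                 for k, v in self.bsa_per_chain.items()},
            "interface_residues": {
                chain: {"residues": info["residues"],
                        "span": list(info["span"])}
                for chain, info in self.interface.items()},
            "contacts": [
                {"kind": c.kind,
                 "a": [c.atom_a.chain_id, c.atom_a.res_seq, c.atom_a.res_name,
                       c.atom_a.atom_name],
                 "b": [c.atom_b.chain_id, c.atom_b.res_seq, c.atom_b.res_name,
                       c.atom_b.atom_name],
                 "distance_A": round(c.distance, 3)}
                for c in self.contacts],
            "clusters": [
                {"members": sorted([list(m) for m in cl.members]),
                 "partner_pins": [list(p) for p in cl.partner_pins]}
                for cl in self.clusters],
            "pins": [
                {"residue": list(p.residue), "res_name": p.res_name,
                 "pocket": [list(q) for q in p.pocket],
                 "buried_fraction": round(p.buried_fraction, 4),
                 "n_partners": p.n_partners}
                for p in self.pins],
            "asymmetric": self.asymmetric,
            "options": self.options,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def contacts_frame(self) -> pd.DataFrame:
        rows = [{
            "kind": c.kind,
            "chain_a": c.atom_a.chain_id, "res_a": c.atom_a.res_seq,
            "resname_a": c.atom_a.res_name, "atom_a": c.atom_a.atom_name,
            "chain_b": c.atom_b.chain_id, "res_b": c.atom_b.res_seq,
            "resname_b": c.atom_b.res_name, "atom_b": c.atom_b.atom_name,
            "distance_A": round(c.distance, 3),
        } for c in self.contacts]
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.contacts_frame().to_csv(path, sep="\t", index=False)


def interface_report(
    complex_model: StructureModel,
    partition: Partition,
    dsasa_min: float = 0.1,
    contact_dist: float = 5.0,
    salt_bridge_dist: float = 4.0,
    hbond_dist: float = 3.5,
    hydrophobic_dist: float = 4.5,
    burial_min: float = 0.75,
    partner_min: int = 4,
    cluster_side: str = "b",
    probe: float = 1.4,
    n_points: int = 960,
) -> InterfaceReport:
    """Run the full interface analysis for one molecule partition.

    The asymmetry flag is set when the per-chain interface spans differ
    between the chains of a multi-chain group (a domain binding across the
    two-fold axis of a homodimer gives unequal spans on the two chains).
    """
    g1, g2 = _split(complex_model, partition)
    bsa1, bsa2 = buried_surface_area(complex_model, partition, probe, n_points)
    interface = interface_residues(complex_model, partition, dsasa_min,
                                   contact_dist, probe, n_points)
    contacts = classify_contacts(complex_model, partition, salt_bridge_dist,
                                 hbond_dist, hydrophobic_dist)
    clusters = hydrophobic_clusters(contacts, side=cluster_side)
    pins = pin_residues(complex_model, partition, contacts, burial_min,
                        partner_min, probe, n_points)

    # per-chain BSA breakdown of group 1 (each chain against group 2)
    bsa_per_chain: dict[str, float] = {}
    for chain in g1.chains:
        sub = partition_from_chains([chain.chain_id],
                                    [c.chain_id for c in g2.chains])
        sub_model = _union_model(
            StructureModel(complex_model.model_id, [chain.copy()]),
            g2)
        b1, _ = buried_surface_area(sub_model, sub, probe, n_points)
        bsa_per_chain[chain.chain_id] = b1

    spans = [tuple(interface[c.chain_id]["span"]) for c in g1.chains
             if c.chain_id in interface]
    asymmetric = len(g1.chains) >= 2 and len(set(spans)) > 1

    return InterfaceReport(
        bsa_group1=bsa1,
        bsa_group2=bsa2,
        bsa_per_chain=bsa_per_chain,
        interface=interface,
        contacts=contacts,
        clusters=clusters,
        pins=pins,
        asymmetric=asymmetric,
        options={
            "dsasa_min": dsasa_min, "contact_dist": contact_dist,
            "salt_bridge_dist": salt_bridge_dist, "hbond_dist": hbond_dist,
            "hydrophobic_dist": hydrophobic_dist, "burial_min": burial_min,
            "partner_min": partner_min, "probe": probe, "n_points": n_points,
        },
    )
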