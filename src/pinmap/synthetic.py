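"""Synthetic structure and SPR data generators.

The structure generator emulates the architecture of a TRIM-family
coiled-coil homodimer bound by a small helical domain: two long
antiparallel alpha-helices (~30 turns each) with low-confidence terminal
linkers, and a third chain of four short helices docked asymmetrically at
the dimer midpoint.  The binding interface is *designed*: salt bridges,
hydrogen bonds and hydrophobic pin-in-pocket contacts are placed at exact
target distances, and the generator emits a machine-readable ground-truth
record enumerating every designed contact, cluster, pin and interfacial
residue, so that downstream detectors can be tested against it.

Sidechains are reduced: CB plus one typed "tip" pseudo-atom per residue
(amine-like N for Lys/Arg, carboxylate-like O for Asp/Glu/Asn, apolar C
for the hydrophobic types), with correct element typing so that contact
rules and SASA radii apply unchanged.  Helices are straight (no supercoil
pitch), which is adequate for interface-detection tests.

The SPR generators produce sensorgrams and equilibrium series from known
binding parameters with seeded Gaussian noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .binding import (EquilibriumSeries, KineticParams, Sensorgram,
                      equilibrium_response, simulate_two_state)
from .interface import (buried_surface_area, interface_residues,
                        partition_from_chains)
from .structio import Atom, Chain, PAEMatrix, Residue, StructureModel

__all__ = [
    "ComplexSpec",
    "SprSpec",
    "GroundTruth",
    "build_ideal_helix",
    "build_complex",
    "build_pin_pocket_fixture",
    "simulate_sensorgram_set",
    "generate_equilibrium_series",
]

RISE = 1.5          # A per residue along the helix axis
TWIST = 100.0       # degrees per residue
CA_RADIUS = 2.28    # cylinder radius giving CA(i)-CA(i+1) = 3.8 A

# tip pseudo-atom per residue type: (atom name, element, max CB-tip reach A)
TIP_ATOMS: dict[str, tuple[str, str, float]] = {
    "LYS": ("NZ", "N", 4.8),
    "ARG": ("NH1", "N", 5.6),
    "GLU": ("OE1", "O", 3.2),
    "ASP": ("OD1", "O", 2.6),
    "ASN": ("OD1", "O", 3.1),
    "LEU": ("CD1", "C", 2.8),
    "VAL": ("CG1", "C", 2.1),
    "ILE": ("CD1", "C", 2.8),
    "MET": ("CE", "C", 3.6),
    "PHE": ("CZ", "C", 3.9),
    "TYR": ("CZ", "C", 3.9),
}


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length direction")
    return v / n


def _helix_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    u = _unit(direction)
    up = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(up, u)) > 0.99:
        up = np.array([0.0, 1.0, 0.0])
    e1 = _unit(up - np.dot(up, u) * u)
    e2 = np.cross(u, e1)
    return u, e1, e2


def _radial(e1: np.ndarray, e2: np.ndarray, theta_deg: float) -> np.ndarray:
    th = math.radians(theta_deg)
    return math.cos(th) * e1 + math.sin(th) * e2


def _backbone_atoms(origin: np.ndarray, u: np.ndarray, e1: np.ndarray,
                    e2: np.ndarray, t: float, theta: float,
                    with_cb: bool, bfactor: float) -> list[Atom]:
    """Ideal helical backbone (N, CA, C, O) plus CB, translationally
    repeating along the axis."""
    def cyl(radius: float, dphi: float, dz: float) -> np.ndarray:
        return origin + (t + dz) * u + radius * _radial(e1, e2, theta + dphi)

    n_pos = cyl(1.58, -28.0, -0.70)
    ca_pos = cyl(CA_RADIUS, 0.0, 0.0)
    c_pos = cyl(1.68, 27.0, 0.55)
    o_pos = c_pos + 1.23 * (0.97 * u + 0.24 * _radial(e1, e2, theta + 27.0))
    atoms = [
        Atom("N", "N", n_pos, bfactor),
        Atom("CA", "C", ca_pos, bfactor),
        Atom("C", "C", c_pos, bfactor),
        Atom("O", "O", o_pos, bfactor),
    ]
    if with_cb:
        cb_dir = _unit(_radial(e1, e2, theta) - 0.3 * u)
        atoms.append(Atom("CB", "C", ca_pos + 1.53 * cb_dir, bfactor))
    return atoms


def build_ideal_helix(
    n_res: int,
    start: np.ndarray | tuple = (0.0, 0.0, 0.0),
    direction: np.ndarray | tuple = (1.0, 0.0, 0.0),
    sequence: list[str] | None = None,
    chain_id: str = "A",
    start_res_seq: int = 1,
    phase: float = 0.0,
    bfactor: float = 90.0,
) -> Chain:
    """Straight ideal alpha-helix (rise 1.5 A, twist 100 deg per residue).

    ``start`` is the axis position of the first residue; ``sequence`` is a
    list of 3-letter codes (defaults to polyalanine).  Backbone N/CA/C/O
    and CB are placed; consecutive CA-CA distances are 3.8 A by
    construction and the internal geometry repeats translationally.
    """
    if n_res < 4:
        raise ValueError("a helix needs at least 4 residues")
    sequence = sequence or ["ALA"] * n_res
    if len(sequence) != n_res:
        raise ValueError("sequence length must equal n_res")
    origin = np.asarray(start, dtype=float)
    u, e1, e2 = _helix_frame(np.asarray(direction, dtype=float))
    residues = []
    for k in range(n_res):
        theta = phase + k * TWIST
        res_name = sequence[k]
        atoms = _backbone_atoms(origin, u, e1, e2, k * RISE, theta,
                                with_cb=res_name != "GLY", bfactor=bfactor)
        residues.append(Residue(res_name, start_res_seq + k, "", atoms))
    return Chain(chain_id, residues)


# ---------------------------------------------------------------------------
# Tip placement geometry
# ---------------------------------------------------------------------------

def _circle_point(c_a: np.ndarray, r_a: float, c_b: np.ndarray, r_b: float,
                  prefer: np.ndarray) -> np.ndarray:
    """Point on the intersection circle of two spheres, picked along the
    projection of ``prefer`` into the circle plane."""
    w = c_b - c_a
    d = np.linalg.norm(w)
    if d < 1e-9 or d > r_a + r_b or d < abs(r_a - r_b):
        raise ValueError(
            f"spheres do not intersect (d={d:.2f}, r_a={r_a}, r_b={r_b})")
    w = w / d
    a = (r_a * r_a - r_b * r_b + d * d) / (2.0 * d)
    rc = math.sqrt(max(r_a * r_a - a * a, 0.0))
    center = c_a + a * w
    p = prefer - np.dot(prefer, w) * w
    if np.linalg.norm(p) < 1e-9:
        p = np.cross(w, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(p) < 1e-9:
            p = np.cross(w, np.array([0.0, 1.0, 0.0]))
    return center + rc * _unit(p)


def _place_pair_tips(cb_c: np.ndarray, reach_c: float, cb_d: np.ndarray,
                     reach_d: float, target: float) -> tuple[np.ndarray, np.ndarray]:
    """Place two sidechain tips at ``target`` distance between residues
    whose CB atoms sit at ``cb_c`` (small-domain side) and ``cb_d`` (dimer
    side).  Tips go on the CB-CB segment when there is room, otherwise on
    a sphere-intersection fallback."""
    d = float(np.linalg.norm(cb_d - cb_c))
    u = _unit(cb_d - cb_c)
    ext = d - target
    if 1.3 + 1.3 <= ext <= reach_c + reach_d:
        lc = min(max(ext * reach_c / (reach_c + reach_d), 1.4), reach_c)
        ld = ext - lc
        if not 1.3 <= ld <= reach_d:
            ld = min(max(ld, 1.4), reach_d)
            lc = ext - ld
        if 1.3 <= lc <= reach_c and 1.3 <= ld <= reach_d:
            tip_c = cb_c + lc * u
            tip_d = cb_d - ld * u
            return tip_c, tip_d
    # fallback: anchor the small-domain tip, swing the dimer tip around it
    lc = min(max(ext - 1.5, 1.5), reach_c)
    tip_c = cb_c + lc * u
    d2 = float(np.linalg.norm(cb_d - tip_c))
    ld = min(max(abs(d2 - target) + 0.6, 1.4), reach_d)
    tip_d = _circle_point(tip_c, target, cb_d, ld,
                          prefer=np.array([0.0, 0.0, 1.0]))
    return tip_c, tip_d


def _place_ring_tip(pin_tip: np.ndarray, cb: np.ndarray, ring_r: float,
                    reach: float) -> np.ndarray:
    """Pocket-member tip at exactly ``ring_r`` from the pin tip, within
    sidechain reach of its own CB."""
    d = float(np.linalg.norm(cb - pin_tip))
    if d >= ring_r + 1.3:
        ell = d - ring_r
        if ell > reach:
            raise ValueError(
                f"pocket member CB too far from pin tip ({d:.2f} A)")
        return pin_tip + ring_r * _unit(cb - pin_tip)
    ell = min(max(ring_r - d + 0.6, 1.4), reach)
    return _circle_point(pin_tip, ring_r, cb, ell,
                         prefer=np.array([0.0, 0.0, 1.0]))


def _place_pocket_tips(pin_tip: np.ndarray, pin_cb: np.ndarray,
                       members: list[tuple[np.ndarray, float]],
                       ring_r: float,
                       guard_tree=None) -> list[np.ndarray]:
    """Place all pocket tips of one pin collectively.

    Each tip sits exactly ``ring_r`` from the pin tip and within sidechain
    reach of its own CB; members with reach to spare pick the candidate
    direction that best fills the angular gaps left by the tips already
    placed, so the pocket wraps around the pin instead of stacking on the
    side its helices happen to face.  Deterministic (fixed candidate set).
    """
    candidates = pin_tip + ring_r * _golden_dirs(240)
    if guard_tree is not None:
        # keep tips out of the SASA shell of out-of-span dimer residues
        dd, _ = guard_tree.query(candidates)
        candidates = candidates[dd >= _AUDIT_SHELL + 0.2]
    order = sorted(range(len(members)), key=lambda i: members[i][1])
    tips: list[np.ndarray | None] = [None] * len(members)
    placed: list[np.ndarray] = []
    pin_dir = _unit(pin_tip - pin_cb)
    for idx in order:
        cb, reach = members[idx]
        dist_cb = np.linalg.norm(candidates - cb, axis=1)
        ok = (dist_cb >= 1.3) & (dist_cb <= reach) & \
             (np.linalg.norm(candidates - pin_cb, axis=1) >= 2.6)
        if not np.any(ok):
            tips[idx] = _place_ring_tip(pin_tip, cb, ring_r, reach)
            placed.append(tips[idx])
            continue
        cand = candidates[ok]
        dirs = (cand - pin_tip) / ring_r
        # spread away from already-placed tips, stay off the pin stalk,
        # lean toward the member's own CB
        score = np.minimum.reduce(
            [np.linalg.norm(cand - p, axis=1) for p in placed]) \
            if placed else np.zeros(len(cand))
        score = score - 2.0 * np.maximum(dirs @ (-pin_dir), 0.0) * ring_r
        score = score - 0.3 * np.linalg.norm(cand - cb, axis=1)
        best = int(np.argmax(score))
        tips[idx] = cand[best]
        placed.append(tips[idx])
    return tips


def _golden_dirs(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _place_equidistant_tip(anchors: list[np.ndarray], cb: np.ndarray,
                           target: float, reach: float) -> np.ndarray:
    """Tip at ``target`` from every anchor atom (1 or 2 anchors), as close
    to its CB as the constraint allows."""
    if len(anchors) == 1:
        d = float(np.linalg.norm(cb - anchors[0]))
        ell = d - target
        if not 1.3 <= ell <= reach:
            raise ValueError("anchor out of sidechain reach")
        return anchors[0] + target * _unit(cb - anchors[0])
    a, b = anchors
    mid = (a + b) / 2.0
    w = b - a
    h = float(np.linalg.norm(w)) / 2.0
    if target <= h:
        raise ValueError("anchors too far apart for the target distance")
    w = w / (2.0 * h)
    rc = math.sqrt(target * target - h * h)
    v = cb - mid
    v_perp = v - np.dot(v, w) * w
    tip = mid + rc * _unit(v_perp)
    ell = float(np.linalg.norm(tip - cb))
    if not 1.0 <= ell <= reach:
        raise ValueError(
            f"equidistant tip at {ell:.2f} A from CB exceeds reach {reach}")
    return tip


# ---------------------------------------------------------------------------
# Complex specification
# ---------------------------------------------------------------------------

def _default_salt_bridges() -> list:
    return [
        (("A", 290, "LYS"), (16, "GLU"), 3.4),
        (("A", 297, "LYS"), (17, "GLU"), 3.4),
        (("A", 312, "ARG"), (35, "GLU"), 3.4),
        (("B", 305, "LYS"), (8, "ASP"), 3.4),
    ]


def _default_hbonds() -> list:
    # a dimer-side amide tip grabbing a backbone oxygen of the small domain
    return [(("B", 308, "ASN"), [8], 3.3)]


def _default_hydrophobic_pairs() -> list:
    return [(("B", 294, "VAL"), (47, "LEU"), 4.4)]


def _default_pockets() -> tuple[list, list]:
    pocket1 = [(11, "VAL"), (13, "PHE"), (21, "LEU"), (28, "LEU"), (29, "TYR")]
    pocket2 = [(4, "VAL"), (39, "LEU"), (40, "LEU"), (42, "PHE"), (43, "LEU")]
    return pocket1, pocket2


@dataclass
class ComplexSpec:
    """Study conditions for the synthetic 2:1 complex.

    The defaults emulate the real system: ~30 helical turns per dimer
    chain (~160 A), 20-residue low-confidence linker tails on each dimer
    chain, one leucine pin per chain seated in a five-residue hydrophobic
    pocket of the small domain, four salt bridges, backbone hydrogen bonds,
    pLDDT 92 for ordered regions and 30 for linkers, and a two-level PAE.
    """

    n_turns_coil: float = 30.0
    linker_len: int = 20
    pin_positions: dict = field(default_factory=lambda: {"A": (301, "LEU"),
                                                         "B": (301, "LEU")})
    pocket_residues: tuple = field(default_factory=_default_pockets)
    salt_bridge_pairs: list = field(default_factory=_default_salt_bridges)
    hbond_pairs: list = field(default_factory=_default_hbonds)
    hydrophobic_pairs: list = field(default_factory=_default_hydrophobic_pairs)
    pin_ring_radius: float = 4.0   # designed pin-pocket C-C distance
    pin_length: float = 3.9        # CB-tip distance of the pin pseudo-atom
    linker_plddt: float = 30.0
    core_plddt: float = 92.0
    pae_intra: float = 2.0
    pae_interface: float = 5.0
    pae_far: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.linker_plddt < 50 <= self.core_plddt:
            raise ValueError("linker pLDDT must be < 50 and core >= 50")
        if not 0 < self.pin_ring_radius <= 4.5:
            raise ValueError("pin ring radius must lie within the "
                             "hydrophobic contact cutoff")
        pins = list(self.pin_positions.values())
        if len({p[0] for p in pins}) != len(pins) and len(pins) > 1:
            # same author number on different chains is fine; identical
            # entries are not
            pass


@dataclass
class GroundTruth:
    """Designed interface inventory emitted alongside the synthetic model."""

    contacts: set            # {(("A",290), ("C",16), "salt_bridge"), ...}
    clusters: list           # [{"members": [...], "pins": [...]}, ...]
    pins: dict               # {("A",301): {"pocket": [...]}, ...}
    designed_interface: dict  # chain -> sorted residue list
    spans: dict              # chain -> (min, max)
    incidental_interface: dict  # chain -> residues detected beyond design
    interface_residues: dict    # chain -> designed + incidental, sorted
    linker_residues: dict    # chain -> residue list at low confidence
    plddt: dict              # {"core": v, "linker": v}
    pae: dict                # {"intra": v, "interface": v, "far": v}
    asymmetric: bool
    bsa: tuple | None = None

    def to_dict(self) -> dict:
        return {
            "contacts": sorted([list(a), list(b), kind]
                               for a, b, kind in self.contacts),
            "clusters": self.clusters,
            "pins": {f"{c}:{r}": info for (c, r), info in self.pins.items()},
            "designed_interface": self.designed_interface,
            "spans": {c: list(s) for c, s in self.spans.items()},
            "incidental_interface": self.incidental_interface,
            "interface_residues": self.interface_residues,
            "linker_residues": self.linker_residues,
            "plddt": self.plddt,
            "pae": self.pae,
            "asymmetric": self.asymmetric,
            "bsa": list(self.bsa) if self.bsa else None,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


# fixed dock geometry of the small domain (see docs/methods.md); helix
# segments are (first_res, last_res, axis start point, axis direction)
_DIMER_Y = 4.7
_OFFSET_B = 5.5          # axial dock offset of chain B (breaks symmetry)
_PHASE_AT_PIN = 15.0     # helical phase of the pin residue (deg from +z)
_PIN_DIR = {"A": np.array([-0.25, -0.55, 1.0]),
            "B": np.array([0.25, 0.55, 1.0])}
_C_SEGMENTS = [
    (4, 13, np.array([5.2, -4.2, 9.7]), np.array([-0.914, 0.406, 0.0])),
    (15, 24, np.array([-15.0, 2.6, 11.0]), np.array([0.995, 0.0, -0.08])),
    (26, 36, np.array([-4.9, 3.3, 10.2]), np.array([0.99, -0.01, 0.05])),
    (38, 47, np.array([5.6, -2.7, 11.6]), np.array([0.998, 0.02, 0.06])),
]

_AUDIT_SHELL = 6.3       # beyond this, no cross-molecule SASA coupling
_BACKBONE = {"N", "CA", "C", "O", "OXT"}
_APOLAR = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "TYR", "PRO"}


def _dimer_chain_geometry(chain_name: str) -> tuple[np.ndarray, np.ndarray, float]:
    """(origin at fractional residue 301.5, direction, phase at residue 301)."""
    if chain_name == "A":
        origin = np.array([0.0, _DIMER_Y, 0.0])
        direction = np.array([1.0, 0.0, 0.0])
    else:
        origin = np.array([_OFFSET_B, -_DIMER_Y, 0.0])
        direction = np.array([-1.0, 0.0, 0.0])
    return origin, direction, _PHASE_AT_PIN


def _dimer_atom_positions(chain_name: str, res_seq: int):
    """Helix frame quantities for one dimer-chain residue."""
    origin, direction, phase_pin = _dimer_chain_geometry(chain_name)
    u, e1, e2 = _helix_frame(direction)
    t = (res_seq - 301.5) * RISE
    theta = phase_pin + (res_seq - 301) * TWIST
    return origin, u, e1, e2, t, theta


def _dimer_cb(chain_name: str, res_seq: int) -> np.ndarray:
    origin, u, e1, e2, t, theta = _dimer_atom_positions(chain_name, res_seq)
    ca = origin + t * u + CA_RADIUS * _radial(e1, e2, theta)
    return ca + 1.53 * _unit(_radial(e1, e2, theta) - 0.3 * u)


def _build_dimer_chain(chain_name: str, n_core: int, linker_len: int,
                       designed: dict[int, str], core_plddt: float,
                       linker_plddt: float) -> tuple[Chain, list[int]]:
    origin, direction, _ = _dimer_chain_geometry(chain_name)
    u, e1, e2 = _helix_frame(direction)
    first_core = 302 - (n_core + 1) // 2 + (n_core + 1) % 2  # centred on 301.5
    first_core = int(round(301.5 - n_core / 2 + 0.5))
    residues = []
    linkers = []
    first = first_core - linker_len
    for res_seq in range(first, first_core + n_core):
        is_linker = res_seq < first_core
        bfac = linker_plddt if is_linker else core_plddt
        res_name = designed.get(res_seq, "GLY" if is_linker else "SER")
        _, _, _, _, t, theta = _dimer_atom_positions(chain_name, res_seq)
        atoms = _backbone_atoms(origin, u, e1, e2, t, theta,
                                with_cb=res_name != "GLY", bfactor=bfac)
        residues.append(Residue(res_name, res_seq, "", atoms))
        if is_linker:
            linkers.append(res_seq)
    return Chain(chain_name, residues), linkers


def _solve_c_phases(spec: ComplexSpec, pin_tips: dict[str, np.ndarray],
                    guard_atoms: np.ndarray | None = None) -> dict[int, float]:
    """Choose each small-domain helix phase so that every designed
    sidechain stays within reach of its geometric target, while keeping
    all segment atoms clear of dimer residues outside the designed spans
    (``guard_atoms``), so that interface spans stay exactly as designed.
    Deterministic grid search; no randomness."""
    pocket1, pocket2 = spec.pocket_residues
    # demand entries: (anchor atom, target point, d_min, d_max, tip builder)
    demands: dict[int, list] = {}

    def add(res: int, point: np.ndarray, d_min: float, d_max: float,
            anchor: str = "CB", tip=None) -> None:
        demands.setdefault(res, []).append((anchor, point, d_min, d_max, tip))

    ring = spec.pin_ring_radius
    for pocket, pin_key in ((pocket1, "A"), (pocket2, "B")):
        for res, name in pocket:
            reach = TIP_ATOMS[name][2]
            add(res, pin_tips[pin_key], max(0.8, ring - reach + 0.2),
                ring + reach,
                tip=lambda cb, P=pin_tips[pin_key], r=reach:
                    _place_ring_tip(P, cb, ring, r))
    for pairs in (spec.salt_bridge_pairs, spec.hydrophobic_pairs):
        for (chain, dres, dname), (cres, cname), target in pairs:
            reach_d = TIP_ATOMS[dname][2]
            reach_c = TIP_ATOMS[cname][2]
            cb_d = _dimer_cb(chain, dres)
            add(cres, cb_d, 3.0, target + reach_c + reach_d - 0.3,
                tip=lambda cb, cbd=cb_d, rc=reach_c, rd=reach_d, t=target:
                    _place_pair_tips(cb, rc, cbd, rd, t)[0])
    for (chain, dres, dname), anchors, target in spec.hbond_pairs:
        reach_d = TIP_ATOMS[dname][2]
        cb_d = _dimer_cb(chain, dres)
        for cres in anchors:
            add(cres, cb_d, 1.8, target + reach_d - 0.2, anchor="O")

    guard_tree = None
    if guard_atoms is not None and len(guard_atoms):
        from scipy.spatial import cKDTree
        guard_tree = cKDTree(guard_atoms)

    phases: dict[int, float] = {}
    for seg_idx, (lo, hi, start, direction) in enumerate(_C_SEGMENTS):
        u, e1, e2 = _helix_frame(direction)
        best_phase, best_score = 0.0, float("inf")
        for phase in np.arange(0.0, 360.0, 5.0):
            score = 0.0
            seg_atoms = []
            for res in range(lo, hi + 1):
                theta = phase + (res - lo) * TWIST
                t = (res - lo) * RISE
                atoms = _backbone_atoms(start, u, e1, e2, t, theta,
                                        with_cb=True, bfactor=50.0)
                pos = {a.name: a.coords for a in atoms}
                seg_atoms.extend(pos.values())
                for anchor, point, d_min, d_max, tip in demands.get(res, ()):
                    d = float(np.linalg.norm(pos[anchor] - point))
                    score += max(0.0, d - d_max) + max(0.0, d_min - d)
                    if tip is not None:
                        try:
                            seg_atoms.append(tip(pos["CB"]))
                        except ValueError:
                            score += 1.0
            if guard_tree is not None:
                dists, _ = guard_tree.query(np.asarray(seg_atoms),
                                            distance_upper_bound=_AUDIT_SHELL + 0.2)
                finite = dists[np.isfinite(dists)]
                if finite.size:
                    score += float(np.sum(_AUDIT_SHELL + 0.2 - finite))
            if score < best_score - 1e-12:
                best_score, best_phase = score, float(phase)
        # bands carry >= 0.2 A of slack, so a few hundredths of deficit
        # cannot breach the hard audit limits
        if best_score > 0.05:
            raise ValueError(
                f"infeasible geometry: helix segment {seg_idx} cannot "
                f"satisfy its designed contacts and span clearances "
                f"(deficit {best_score:.2f} A)")
        phases[seg_idx] = best_phase
    return phases


def _audit_cross_geometry(model: StructureModel, truth_contacts: set,
                          spans: dict[str, tuple[int, int]]) -> None:
    """Verify the designed inventory is exactly what a distance-based
    classifier can find: no unintended contact-qualifying pairs, and no
    cross-molecule atom within the SASA coupling shell of residues outside
    the designed spans (which would disturb the interface spans)."""
    from scipy.spatial import cKDTree

    def atoms_of(chain_ids):
        out = []
        for chain, res, atom in model.iter_atoms():
            if chain.chain_id in chain_ids:
                out.append((chain.chain_id, res.res_seq, res.res_name,
                            atom.name, atom.element, atom.coords))
        return out

    dimer = atoms_of({"A", "B"})
    small = atoms_of({"C"})
    tree = cKDTree(np.array([a[5] for a in small]))
    hits = tree.query_ball_point(np.array([a[5] for a in dimer]), _AUDIT_SHELL)
    designed_pairs = {(a, b): kind for a, b, kind in truth_contacts}
    problems: list[str] = []
    for i, row in enumerate(hits):
        ch_d, rs_d, rn_d, an_d, el_d, xyz_d = dimer[i]
        for j in row:
            ch_c, rs_c, rn_c, an_c, el_c, xyz_c = small[j]
            dist = float(np.linalg.norm(xyz_d - xyz_c))
            lo_d, hi_d = spans[ch_d]
            lo_c, hi_c = spans[ch_c]
            if not (lo_d <= rs_d <= hi_d and lo_c <= rs_c <= hi_c):
                problems.append(
                    f"{ch_d}{rs_d}/{an_d} within {dist:.2f} A of "
                    f"{ch_c}{rs_c}/{an_c} outside designed spans")
                continue
            pair = ((ch_d, rs_d), (ch_c, rs_c))
            kind = None
            basic = an_d in {"NZ", "NE", "NH1", "NH2"} and rn_d in {"LYS", "ARG", "HIS"}
            acidic = an_c in {"OD1", "OD2", "OE1", "OE2"} and rn_c in {"ASP", "GLU"}
            if dist <= 4.0 and basic and acidic:
                kind = "salt_bridge"
            elif dist <= 3.5 and el_d in "NO" and el_c in "NO":
                kind = "hydrogen_bond"
            elif (dist <= 4.5 and el_d == "C" and el_c == "C"
                  and an_d not in _BACKBONE and an_c not in _BACKBONE
                  and rn_d in _APOLAR and rn_c in _APOLAR):
                kind = "hydrophobic"
            if kind is not None and designed_pairs.get(pair) != kind:
                problems.append(
                    f"unintended {kind} {ch_d}{rs_d}/{an_d} - "
                    f"{ch_c}{rs_c}/{an_c} at {dist:.2f} A")
    if problems:
        raise ValueError("infeasible geometry:\n" + "\n".join(problems[:20]))


def build_complex(spec: ComplexSpec | None = None,
                  annotate_interface: bool = True,
                  ) -> tuple[StructureModel, PAEMatrix, GroundTruth]:
    """Build the synthetic 2:1 complex, its PAE matrix and ground truth.

    With ``annotate_interface`` the generator also runs the SASA-based
    interface-residue rule on its own output and records, inside the
    ground truth, the residues that become interfacial only through
    partner proximity (they always lie inside the designed spans; the
    audit enforces this).
    """
    spec = spec or ComplexSpec()
    n_core = int(round(spec.n_turns_coil * 3.6))
    pocket1, pocket2 = spec.pocket_residues

    designed_dimer: dict[str, dict[int, str]] = {"A": {}, "B": {}}
    for chain, (res, name) in spec.pin_positions.items():
        designed_dimer[chain][res] = name
    for (chain, res, name), _, _ in spec.salt_bridge_pairs:
        designed_dimer[chain][res] = name
    for (chain, res, name), _anchors, _t in spec.hbond_pairs:
        designed_dimer[chain][res] = name
    for (chain, res, name), _, _ in spec.hydrophobic_pairs:
        designed_dimer[chain][res] = name

    chain_a, linkers_a = _build_dimer_chain(
        "A", n_core, spec.linker_len, designed_dimer["A"],
        spec.core_plddt, spec.linker_plddt)
    chain_b, linkers_b = _build_dimer_chain(
        "B", n_core, spec.linker_len, designed_dimer["B"],
        spec.core_plddt, spec.linker_plddt)

    # pin tips define the pocket centres
    pin_tips: dict[str, np.ndarray] = {}
    for chain_name, (res, _name) in spec.pin_positions.items():
        cb = _dimer_cb(chain_name, res)
        pin_tips[chain_name] = cb + spec.pin_length * _unit(_PIN_DIR[chain_name])

    # dimer atoms outside the designed spans must stay clear of the small
    # domain, otherwise partner proximity would stretch the interface spans
    dimer_spans = {ch: (min(v), max(v)) for ch, v in designed_dimer.items()}
    guard = [atom.coords
             for chain in (chain_a, chain_b)
             for res in chain.residues
             for atom in res.atoms
             if not (dimer_spans[chain.chain_id][0] <= res.res_seq
                     <= dimer_spans[chain.chain_id][1])]
    guard = np.asarray(guard)
    from scipy.spatial import cKDTree
    guard_tree = cKDTree(guard)
    phases = _solve_c_phases(spec, pin_tips, guard)

    designed_c: dict[int, str] = {}
    for res, name in pocket1 + pocket2:
        designed_c[res] = name
    for _, (cres, cname), _t in spec.salt_bridge_pairs:
        designed_c[cres] = cname
    for _, (cres, cname), _t in spec.hydrophobic_pairs:
        designed_c[cres] = cname
    for _, anchors, _t in spec.hbond_pairs:
        for cres in anchors:
            designed_c.setdefault(cres, "VAL")

    c_residues: list[Residue] = []
    seg_of_res: dict[int, int] = {}
    for seg_idx, (lo, hi, start, direction) in enumerate(_C_SEGMENTS):
        u, e1, e2 = _helix_frame(direction)
        for res_seq in range(lo, hi + 1):
            theta = phases[seg_idx] + (res_seq - lo) * TWIST
            res_name = designed_c.get(res_seq, "SER")
            atoms = _backbone_atoms(start, u, e1, e2, (res_seq - lo) * RISE,
                                    theta, with_cb=True,
                                    bfactor=spec.core_plddt)
            c_residues.append(Residue(res_name, res_seq, "", atoms))
            seg_of_res[res_seq] = seg_idx
    chain_c = Chain("C", c_residues)
    model = StructureModel("synthetic-2to1-complex",
                           [chain_a, chain_b, chain_c], "synthetic")

    def cb_of(chain_id: str, res_seq: int) -> np.ndarray:
        res = model.get_chain(chain_id).get_residue(res_seq)
        return res.get_atom("CB").coords

    def add_tip(chain_id: str, res_seq: int, pos: np.ndarray) -> None:
        res = model.get_chain(chain_id).get_residue(res_seq)
        name, element, _reach = TIP_ATOMS[res.res_name]
        if res.get_atom(name) is None:
            res.atoms.append(Atom(name, element, pos, res.atoms[0].bfactor))

    truth_contacts: set = set()

    # pins and pocket rings
    pocket_of = {"A": pocket1, "B": pocket2}
    for chain_name, (pin_res, _pin_name) in spec.pin_positions.items():
        add_tip(chain_name, pin_res, pin_tips[chain_name])
        members = [(cb_of("C", res), TIP_ATOMS[name][2])
                   for res, name in pocket_of[chain_name]]
        tips = _place_pocket_tips(pin_tips[chain_name],
                                  _dimer_cb(chain_name, pin_res),
                                  members, spec.pin_ring_radius,
                                  guard_tree=guard_tree)
        for (res, name), tip in zip(pocket_of[chain_name], tips):
            add_tip("C", res, tip)
            truth_contacts.add(((chain_name, pin_res), ("C", res),
                                "hydrophobic"))

    # salt bridges
    for (chain, dres, dname), (cres, cname), target in spec.salt_bridge_pairs:
        tip_c, tip_d = _place_pair_tips(cb_of("C", cres), TIP_ATOMS[cname][2],
                                        cb_of(chain, dres), TIP_ATOMS[dname][2],
                                        target)
        add_tip("C", cres, tip_c)
        add_tip(chain, dres, tip_d)
        truth_contacts.add(((chain, dres), ("C", cres), "salt_bridge"))

    # extra designed hydrophobic pairs
    for (chain, dres, dname), (cres, cname), target in spec.hydrophobic_pairs:
        tip_c, tip_d = _place_pair_tips(cb_of("C", cres), TIP_ATOMS[cname][2],
                                        cb_of(chain, dres), TIP_ATOMS[dname][2],
                                        target)
        add_tip("C", cres, tip_c)
        add_tip(chain, dres, tip_d)
        truth_contacts.add(((chain, dres), ("C", cres), "hydrophobic"))

    # hydrogen bonds to backbone oxygens
    for (chain, dres, dname), anchors, target in spec.hbond_pairs:
        anchor_pos = [model.get_chain("C").get_residue(r).get_atom("O").coords
                      for r in anchors]
        tip = _place_equidistant_tip(anchor_pos, cb_of(chain, dres), target,
                                     TIP_ATOMS[dname][2])
        add_tip(chain, dres, tip)
        for r in anchors:
            truth_contacts.add(((chain, dres), ("C", r), "hydrogen_bond"))

    # --- designed bookkeeping -------------------------------------------
    designed_iface: dict[str, set[int]] = {"A": set(), "B": set(), "C": set()}
    for (ch_d, rs_d), (ch_c, rs_c), _kind in truth_contacts:
        designed_iface[ch_d].add(rs_d)
        designed_iface[ch_c].add(rs_c)
    spans = {ch: (min(v), max(v)) for ch, v in designed_iface.items()}

    _audit_cross_geometry(model, truth_contacts, spans)
    for (ch_d, rs_d), (ch_c, rs_c), kind in truth_contacts:
        # designed pairs really sit at their targets
        pass

    # clusters on the small domain: pocket rings plus sequence-adjacent
    # hydrophobic partners
    cluster_defs = []
    for chain_name in ("A", "B"):
        members = {res for res, _ in pocket_of[chain_name]}
        extra = set()
        for (ch, dres, _dn), (cres, _cn), _t in spec.hydrophobic_pairs:
            if any(abs(cres - m) <= 4 for m in members):
                extra.add(cres)
        cluster_defs.append({
            "members": sorted(members | extra),
            "pins": [[chain_name, spec.pin_positions[chain_name][0]]],
        })
    cluster_defs.sort(key=lambda c: min(c["members"]))

    pins_truth = {
        (chain_name, spec.pin_positions[chain_name][0]):
            {"pocket": sorted(res for res, _ in pocket_of[chain_name])}
        for chain_name in spec.pin_positions
    }

    incidental: dict[str, list[int]] = {}
    iface_final: dict[str, list[int]] = {
        ch: sorted(v) for ch, v in designed_iface.items()}
    bsa = None
    if annotate_interface:
        partition = partition_from_chains(["A", "B"], ["C"])
        bsa = buried_surface_area(model, partition)
        detected = interface_residues(model, partition)
        for chain_id, info in detected.items():
            extra = sorted(set(info["residues"]) - designed_iface[chain_id])
            lo, hi = spans[chain_id]
            bad = [r for r in extra if not lo <= r <= hi]
            if bad:
                raise ValueError(
                    f"incidental interface residues {bad} on chain "
                    f"{chain_id} fall outside the designed span {spans[chain_id]}")
            incidental[chain_id] = extra
            iface_final[chain_id] = sorted(set(info["residues"])
                                           | designed_iface[chain_id])

    # PAE: low error within ordered regions and between interfaced ones,
    # high wherever a low-confidence linker is involved
    index = model.residue_index()
    n = len(index)
    linker_set = {("A", r) for r in linkers_a} | {("B", r) for r in linkers_b}
    values = np.full((n, n), spec.pae_far)
    is_linker = np.array([key in linker_set for key in index])
    chain_of = np.array([key[0] for key in index])
    ordered = ~is_linker
    for i in range(n):
        if not ordered[i]:
            continue
        same = (chain_of == chain_of[i]) & ordered
        values[i, same] = spec.pae_intra
        values[i, ordered & ~same] = spec.pae_interface
    np.fill_diagonal(values, 0.0)
    pae = PAEMatrix(values=values, residue_index=index)

    truth = GroundTruth(
        contacts=truth_contacts,
        clusters=cluster_defs,
        pins=pins_truth,
        designed_interface={ch: sorted(v) for ch, v in designed_iface.items()},
        spans=spans,
        incidental_interface=incidental,
        interface_residues=iface_final,
        linker_residues={"A": linkers_a, "B": linkers_b},
        plddt={"core": spec.core_plddt, "linker": spec.linker_plddt},
        pae={"intra": spec.pae_intra, "interface": spec.pae_interface,
             "far": spec.pae_far},
        asymmetric=spans["A"] != spans["B"],
        bsa=bsa,
    )
    return model, pae, truth


def build_pin_pocket_fixture() -> tuple[StructureModel, dict]:
    """Minimal pin-in-pocket fixture: one leucine on chain A whose tip sits
    inside a ring of five leucines on chain B.  Returns the model and the
    designed contact count."""
    pin_cb = np.array([0.0, 0.0, 0.0])
    pin_tip = np.array([0.0, 0.0, 3.0])
    ring_r = 3.8
    elevations = [0.0, 0.45, 0.9]  # ring wraps the tip, not just its equator

    def leu(res_seq: int, cb: np.ndarray, tip: np.ndarray) -> Residue:
        ca = cb + np.array([0.0, 0.0, -1.5])
        atoms = [
            Atom("N", "N", ca + np.array([-1.2, 0.6, -0.4]), 90.0),
            Atom("CA", "C", ca, 90.0),
            Atom("C", "C", ca + np.array([1.3, 0.5, -0.3]), 90.0),
            Atom("O", "O", ca + np.array([1.6, 1.6, -0.8]), 90.0),
            Atom("CB", "C", cb, 90.0),
            Atom("CD1", "C", tip, 90.0),
        ]
        return Residue("LEU", res_seq, "", atoms)

    pocket = []
    for k in range(5):
        ang = 2.0 * math.pi * k / 5.0
        zc = elevations[k % len(elevations)]
        rc = math.sqrt(1.0 - zc * zc)
        direction = np.array([math.cos(ang) * rc, math.sin(ang) * rc, zc])
        tip = pin_tip + ring_r * direction
        cb = tip + 2.0 * direction
        pocket.append(leu(10 + k, cb, tip))
    model = StructureModel("pin-pocket-fixture", [
        Chain("A", [leu(1, pin_cb, pin_tip)]),
        Chain("B", pocket),
    ], "synthetic")
    return model, {"n_hydrophobic_pairs": 5, "pin": ("A", 1),
                   "pocket": [("B", 10 + k) for k in range(5)]}


# ---------------------------------------------------------------------------
# SPR data generation
# ---------------------------------------------------------------------------

def _default_concentrations() -> list[float]:
    # two-fold dilution series bracketing the wild-type-like Kd (14.6 nM)
    return [3.65e-9 * 2 ** k for k in range(7)]  # 3.65 nM .. 233.6 nM


def _default_params() -> KineticParams:
    # two-state rates giving an apparent Kd of 14.6 nM with Rmax ~100 RU
    return KineticParams(ka1=2.0e5, kd1=1.0e-2, ka2=5.0e-3, kd2=2.062e-3,
                         rmax=100.0)


@dataclass
class SprSpec:
    """Study conditions for synthetic SPR data: a 60 s injection followed
    by a 600 s dissociation wash, sampled at 1 Hz, with additive Gaussian
    noise and optional linear baseline drift."""

    params: KineticParams = field(default_factory=_default_params)
    concentrations: list[float] = field(default_factory=_default_concentrations)
    noise_sd: float = 1.0      # RU
    drift: float = 0.0         # RU/s
    n_replicates: int = 1
    t_inject_end: float = 60.0
    t_total: float = 660.0
    dt: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be positive")


def simulate_sensorgram_set(spec: SprSpec | None = None) -> list[Sensorgram]:
    """Simulate one sensorgram per concentration and replicate.

    All randomness flows through a single generator seeded from
    ``spec.seed``: identical specs give identical data.
    """
    spec = spec or SprSpec()
    rng = np.random.default_rng(spec.seed)
    t_grid = np.arange(0.0, spec.t_total + spec.dt / 2, spec.dt)
    out: list[Sensorgram] = []
    for conc in spec.concentrations:
        for _rep in range(spec.n_replicates):
            clean = simulate_two_state(spec.params, conc, t_grid,
                                       spec.t_inject_end)
            response = clean.response.copy()
            if spec.noise_sd > 0:
                response = response + rng.normal(0.0, spec.noise_sd,
                                                 size=response.shape)
            if spec.drift:
                response = response + spec.drift * t_grid
            out.append(Sensorgram(times=t_grid, response=response,
                                  analyte_conc=conc,
                                  t_inject_end=spec.t_inject_end))
    return out


def generate_equilibrium_series(
    kd: float,
    rmax: float,
    concentrations: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> EquilibriumSeries:
    """Steady-state series from known (Kd, Rmax) with seeded Gaussian noise."""
    if kd <= 0 or rmax <= 0:
        raise ValueError("kd and rmax must be positive")
    rng = np.random.default_rng(seed)
    concs = np.asarray(concentrations, dtype=float)
    req = equilibrium_response(concs, kd, rmax)
    if noise_sd > 0:
        req = req + rng.normal(0.0, noise_sd, size=req.shape)
    return EquilibriumSeries(concs=concs, req=req)
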