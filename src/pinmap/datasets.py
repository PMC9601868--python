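"""Reference affinity data for the Trim28 coiled-coil / KRAB-domain system.

Published SPR dissociation constants for murine Trim28 RBCC coiled-coil
mutants binding the immobilized ZFP932 KRAB domain, as printed (mean of
three runs; the uncertainty column is omitted here).  The wild-type
affinity is 14.6 nM.  Entries are (name, Kd in molar or None for
binding-deficient mutants, stated integer fold-decrease or None).

Some stated fold-decreases were evidently computed from unrounded Kd
estimates and differ by a few counts from the ratio of the printed,
rounded values; ``pinmap.binding.fold_change_table`` flags those rows.
"""

from __future__ import annotations

#: Wild-type Trim28 RBCC / ZFP932 KRAB dissociation constant (M).
WILD_TYPE_KD = 14.6e-9

#: Multi-residue turn/face alanine mutants of the coiled-coil.
TURN_FACE_MUTANTS: list[tuple[str, float | None, int | None]] = [
    ("Turns 1-2", 2.7e-6, 185),
    ("Turns 3-4", 1.1e-6, 77),
    ("Turns 5-6", 14.0e-6, 962),
    ("Turns 7-8", 61.5e-9, 4),
    ("Top Face 2", 613.4e-9, 42),
    ("Top Face 6", None, None),        # binding-deficient
    ("Bottom Face 2", 34.5e-9, 2),
    ("Bottom Face 6", 52.9e-9, 4),
]

#: Single-residue interface mutants (alanine, serine and glutamate scans).
POINT_MUTANTS: list[tuple[str, float | None, int | None]] = [
    ("K290A", 37.3e-9, 3),
    ("V294A", 113.3e-9, 8),
    ("K297A", 54.1e-9, 4),
    ("M298A", 323.7e-9, 22),
    ("I300A", 26.3e-9, 2),
    ("L301A", 6.5e-6, 445),
    ("M304A", 24.2e-9, 2),
    ("K305A", 31.1e-9, 2),
    ("R312A", 27.8e-9, 2),
    ("K290E", 132.3e-9, 9),
    ("V294S", 319.0e-9, 22),
    ("K297E", None, None),             # binding-deficient
    ("M298S", 670.6e-9, 46),
    ("I300S", 35.8e-9, 2),
    ("L301S", 30.8e-6, 2112),
    ("M304S", 20.3e-9, 2),
    ("K305E", 15.9e-6, 1071),
    ("R312E", 212.1e-9, 15),
]
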