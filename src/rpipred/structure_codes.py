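"""Structural alphabets: protein blocks and RNA secondary-structure elements.

Two 1D structural codes feed the pair encoder:

* **Protein blocks (PBs)** — a 16-letter structural alphabet (``a``-``p``)
  of canonical five-residue backbone fragments. Each fragment is defined by
  eight dihedral angles (psi(i-2), phi(i-1), psi(i-1), phi(i), psi(i),
  phi(i+1), psi(i+1), phi(i+2)); a residue is assigned the prototype letter
  whose dihedral vector is nearest in angular RMSD. ``Z`` marks unassignable
  positions (chain termini, missing dihedrals).

* **RNA secondary-structure elements (RSS)** — a five-class per-nucleotide
  annotation derived from a nested (pseudo-knot-free) base-pair set:
  Stem (S, paired), Hairpin (H), Bulge (B, unpaired on one side between
  consecutive stems), Internal loop (I, unpaired on both sides), and
  Loop (L, multibranch interiors and exterior unpaired nucleotides).
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

__all__ = [
    "PB_ALPHABET",
    "RSS_ALPHABET",
    "PB_DIHEDRAL_PROTOTYPES",
    "parse_dot_bracket",
    "classify_rss",
    "assign_pb_from_backbone",
    "validate_pb_string",
    "validate_rss_string",
    "read_structure_strings",
]

PB_ALPHABET = "abcdefghijklmnop"
RSS_ALPHABET = "SHLBI"

# Canonical dihedral prototypes of the 16 protein blocks, eight angles per
# block: psi(i-2), phi(i-1), psi(i-1), phi(i), psi(i), phi(i+1), psi(i+1),
# phi(i+2), degrees. Values from the original structural-alphabet derivation
# ('m' is the core alpha-helix block, 'd' the core beta-strand block).
PB_DIHEDRAL_PROTOTYPES: dict[str, tuple[float, ...]] = {
    "a": (41.14, 75.53, 13.92, -99.80, 131.88, -96.27, 122.08, -99.68),
    "b": (108.24, -90.12, 119.54, -92.21, -18.06, -128.93, 147.04, -99.90),
    "c": (-11.61, -105.66, 94.81, -106.09, 133.56, -106.93, 135.97, -100.63),
    "d": (141.98, -112.79, 132.20, -114.79, 140.11, -111.05, 139.54, -103.16),
    "e": (133.25, -112.37, 137.64, -108.13, 133.00, -87.30, 120.54, 77.40),
    "f": (116.40, -105.53, 129.32, -96.68, 140.72, -74.19, -26.65, -94.51),
    "g": (0.40, -81.83, 4.91, -100.59, 85.50, -71.65, 130.78, 84.98),
    "h": (119.14, -102.58, 130.83, -67.91, 121.55, 76.25, -2.95, -90.88),
    "i": (130.68, -56.92, 119.26, 77.85, 10.42, -99.43, 141.40, -98.01),
    "j": (114.32, -121.47, 118.14, 82.88, -150.05, -83.81, 23.35, -85.82),
    "k": (117.16, -95.41, 140.40, -59.35, -29.23, -72.39, -25.08, -76.16),
    "l": (139.20, -55.96, -32.70, -68.51, -26.09, -74.44, -22.60, -71.74),
    "m": (-39.62, -64.73, -39.50, -65.54, -38.88, -66.89, -37.76, -70.19),
    "n": (-35.34, -65.03, -38.12, -66.34, -29.51, -89.10, -2.91, 77.90),
    "o": (-45.29, -67.44, -27.72, -87.27, 5.13, 77.49, 30.71, -93.23),
    "p": (-27.09, -86.14, 0.30, 59.85, 21.51, -96.30, 132.67, -92.91),
}

assert set(PB_DIHEDRAL_PROTOTYPES) == set(PB_ALPHABET)


class DotBracketError(ValueError):
    """Malformed or unsupported dot-bracket input."""


def parse_dot_bracket(db: str) -> list[tuple[int, int]]:
    """Parse a Vienna dot-bracket string into a nested base-pair list.

    Only ``.``, ``(`` and ``)`` are accepted; pseudo-knot bracket alphabets
    (``[ ] { } < >``) are rejected since crossing topologies are outside the
    model. Returns 0-based (i, j) pairs with i < j, nested by construction.
    """
    pairs: list[tuple[int, int]] = []
    stack: list[int] = []
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise DotBracketError(f"unbalanced ')' at position {i}")
            pairs.append((stack.pop(), i))
        elif ch == ".":
            continue
        elif ch in "[]{}<>" or ch.isalpha():
            raise DotBracketError(
                f"pseudo-knot bracket {ch!r} at position {i} is not supported"
            )
        else:
            raise DotBracketError(f"illegal character {ch!r} at position {i}")
    if stack:
        raise DotBracketError(f"unbalanced '(' at position {stack[-1]}")
    return sorted(pairs)


def classify_rss(db: str) -> str:
    """Per-nucleotide five-class element annotation of a dot-bracket string.

    Paired positions are S. Unpaired positions are classified by the loop
    that owns them in the nesting tree: hairpin interiors H; single-sided
    runs between two consecutive nested stems B; double-sided runs I; and
    everything else (multibranch interiors, exterior) L.
    """
    pairs = parse_dot_bracket(db)
    n = len(db)
    out = ["L"] * n
    for i, j in pairs:
        out[i] = out[j] = "S"

    pair_set = set(pairs)

    def children(i: int, j: int) -> list[tuple[int, int]]:
        """Base pairs directly enclosed by (i, j) (or by the root)."""
        kids = []
        k = i + 1
        while k < j:
            if out[k] == "S":
                # k opens some pair (k, l) nested inside (i, j)
                l = _partner(pairs, k)
                if l is None or l < k:
                    k += 1
                    continue
                kids.append((k, l))
                k = l + 1
            else:
                k += 1
        return kids

    def _partner(prs, k):
        for a, b in prs:
            if a == k:
                return b
            if b == k:
                return a
        return None

    def visit(i: int, j: int) -> None:
        kids = children(i, j)
        if not kids:
            for k in range(i + 1, j):
                out[k] = "H"
        elif len(kids) == 1:
            (k, l) = kids[0]
            left = k - i - 1
            right = j - l - 1
            if left and right:
                cls = "I"
            elif left or right:
                cls = "B"
            else:
                cls = None  # stacked helix, no unpaired run
            if cls:
                for p in range(i + 1, k):
                    out[p] = cls
                for p in range(l + 1, j):
                    out[p] = cls
        # multibranch interiors stay L
        for k, l in kids:
            visit(k, l)

    # exterior: treat the whole string as the root loop; root unpaired = L
    for k, l in children(-1, n):
        visit(k, l)

    assert out.count("S") == 2 * len(pair_set)
    return "".join(out)


def _angular_rmsd(window: np.ndarray, proto: np.ndarray) -> float:
    d = np.abs(window - proto) % 360.0
    d = np.minimum(d, 360.0 - d)
    return math.sqrt(float(np.mean(d**2)))


def assign_pb_from_backbone(phi_psi: list[tuple[float | None, float | None]]) -> str:
    """Assign protein-block letters from a per-residue (phi, psi) series.

    Each residue i is described by the eight dihedrals of the window
    i-2..i+2; the nearest prototype in angular RMSD wins. The first and last
    two residues, and any window touching a missing dihedral, get ``Z``.
    """
    n = len(phi_psi)
    if n < 5:
        import warnings

        warnings.warn("chain shorter than 5 residues: all positions unassigned")
        return "Z" * n
    letters = list(PB_DIHEDRAL_PROTOTYPES)
    protos = np.array([PB_DIHEDRAL_PROTOTYPES[c] for c in letters])
    out = []
    for i in range(n):
        if i < 2 or i > n - 3:
            out.append("Z")
            continue
        angles = [
            phi_psi[i - 2][1], phi_psi[i - 1][0], phi_psi[i - 1][1],
            phi_psi[i][0], phi_psi[i][1],
            phi_psi[i + 1][0], phi_psi[i + 1][1], phi_psi[i + 2][0],
        ]
        if any(a is None for a in angles):
            out.append("Z")
            continue
        w = np.asarray(angles, dtype=float)
        scores = [_angular_rmsd(w, p) for p in protos]
        out.append(letters[int(np.argmin(scores))])
    return "".join(out)


def validate_pb_string(s: str) -> str:
    for i, ch in enumerate(s):
        if ch not in PB_ALPHABET and ch != "Z":
            raise ValueError(f"illegal protein-block code {ch!r} at position {i + 1}")
    return s


def validate_rss_string(s: str) -> str:
    for i, ch in enumerate(s):
        if ch not in RSS_ALPHABET:
            raise ValueError(f"illegal RSS code {ch!r} at position {i + 1}")
    return s


def read_structure_strings(path: str | Path, alphabet: str = "pb") -> dict[str, str]:
    """Read FASTA-like files of per-residue code strings.

    ``alphabet`` selects validation: ``pb`` for protein blocks, ``rss`` for
    secondary-structure element classes. Lets users supply externally
    predicted structure strings (structure-prediction tools are consumed,
    not reimplemented).
    """
    validate = {"pb": validate_pb_string, "rss": validate_rss_string}[alphabet]
    records: dict[str, str] = {}
    name = None
    buf: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records[name] = validate("".join(buf))
                name = line[1:].split()[0]
                buf = []
            else:
                buf.append(line)
    if name is not None:
        records[name] = validate("".join(buf))
    return records
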