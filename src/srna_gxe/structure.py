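"""Secondary-structure folding and hairpin evaluation for miRNA precursors.

The primary engine is the ViennaRNA thermodynamic folder (``RNA`` python
bindings).  A self-contained base-pair-maximization engine (Nussinov dynamic
programming with per-pair pseudo-energies) is provided as ``builtin``; it is
selected explicitly or used when ViennaRNA is not importable.

Precursor acceptance follows the canonical plant-miRNA criteria: the mature
must sit entirely on one arm of a single stem-loop, pair with a contiguous
star region on the opposite arm, carry at most ``max_unpaired`` unpaired
positions and no asymmetric bulge longer than ``max_bulge`` inside the
mature/star duplex, and the precursor folding energy must not exceed
``max_energy`` kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

try:  # thermodynamic engine
    import RNA as _vienna
except ImportError:  # pragma: no cover - exercised only without ViennaRNA
    _vienna = None

_PAIR_ENERGY = {"GC": -3.0, "CG": -3.0, "AT": -2.0, "TA": -2.0, "GT": -1.0, "TG": -1.0}
_MIN_LOOP = 3


def available_engines() -> list[str]:
    return (["vienna"] if _vienna is not None else []) + ["builtin"]


@lru_cache(maxsize=65536)
def fold(seq: str, engine: str = "auto") -> tuple[str, float]:
    """Fold a DNA/RNA sequence; returns (dot-bracket, energy).

    Energies from the builtin engine are pseudo-energies (pair-sum), not
    kcal/mol; they share the sign convention so the same thresholds apply to
    well-formed stems.
    """
    seq = seq.upper().replace("U", "T")
    if engine == "auto":
        engine = "vienna" if _vienna is not None else "builtin"
    if engine == "vienna":
        if _vienna is None:
            raise RuntimeError(
                "ViennaRNA python bindings not installed; install viennarna or "
                "run with --structure-engine builtin"
            )
        structure, mfe = _vienna.fold(seq.replace("T", "U"))
        return structure, float(mfe)
    if engine == "builtin":
        return _nussinov(seq)
    raise ValueError(f"unknown structure engine {engine!r}")


def _nussinov(seq: str) -> tuple[str, float]:
    """Base-pair maximization by pseudo-energy minimization (O(n^3) DP)."""
    n = len(seq)
    if n == 0:
        return "", 0.0
    NEG = 0.0
    E = [[0.0] * n for _ in range(n)]
    for span in range(_MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = E[i + 1][j]  # i unpaired
            pair = _PAIR_ENERGY.get(seq[i] + seq[j], NEG)
            if pair < 0:
                cand = pair + (E[i + 1][j - 1] if j - 1 >= i + 1 else 0.0)
                if cand < best:
                    best = cand
            for k in range(i + 1, j):  # i pairs with k < j
                pk = _PAIR_ENERGY.get(seq[i] + seq[k], NEG)
                if pk < 0:
                    cand = pk + (E[i + 1][k - 1] if k - 1 >= i + 1 else 0.0) + (
                        E[k + 1][j] if k + 1 <= j else 0.0
                    )
                    if cand < best:
                        best = cand
            E[i][j] = best
    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or E[i][j] == 0.0:
            continue
        if E[i][j] == E[i + 1][j]:
            stack.append((i + 1, j))
            continue
        matched = False
        for k in range(i + _MIN_LOOP + 1, j + 1):
            pk = _PAIR_ENERGY.get(seq[i] + seq[k], NEG)
            if pk < 0:
                inner = E[i + 1][k - 1] if k - 1 >= i + 1 else 0.0
                outer = E[k + 1][j] if k + 1 <= j else 0.0
                if abs(E[i][j] - (pk + inner + outer)) < 1e-9:
                    structure[i], structure[k] = "(", ")"
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    matched = True
                    break
        if not matched:
            stack.append((i + 1, j))
    return "".join(structure), E[0][n - 1]


def pair_table(structure: str) -> list[int]:
    """Partner index per position (-1 when unpaired)."""
    pt = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket")
            j = stack.pop()
            pt[i], pt[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return pt


@dataclass
class HairpinCriteria:
    max_unpaired: int = 5
    max_bulge: int = 3
    max_energy: float = -18.0


@dataclass
class HairpinEvaluation:
    passed: bool
    reasons: list[str] = field(default_factory=list)
    structure: str = ""
    energy: float = 0.0
    mature_arm: str = ""  # "5p" or "3p"
    star_span: tuple[int, int] | None = None  # 0-based half-open, candidate coords
    unpaired_mature: int = 0


def evaluate_hairpin(
    seq: str,
    mature_start: int,
    mature_end: int,
    criteria: HairpinCriteria | None = None,
    engine: str = "auto",
) -> HairpinEvaluation:
    """Fold a precursor candidate and test the mature placement against the
    stem-loop criteria.  ``mature_start``/``mature_end`` are 0-based half-open
    coordinates of the mature within ``seq`` (sense orientation)."""
    criteria = criteria or HairpinCriteria()
    if not (0 <= mature_start < mature_end <= len(seq)):
        raise ValueError("mature span outside candidate")
    structure, energy = fold(seq, engine)
    ev = HairpinEvaluation(passed=True, structure=structure, energy=energy)
    pt = pair_table(structure)
    mature = range(mature_start, mature_end)

    partners = [pt[i] for i in mature if pt[i] >= 0]
    ev.unpaired_mature = sum(1 for i in mature if pt[i] < 0)
    if ev.unpaired_mature > criteria.max_unpaired:
        ev.reasons.append("unpaired")
    if not partners:
        ev.reasons.append("loop_overlap")  # mature entirely unpaired = in loop
        ev.passed = False
        return ev

    lo, hi = min(partners), max(partners)
    if all(p >= mature_end for p in partners):
        ev.mature_arm = "5p"
    elif all(p < mature_start for p in partners):
        ev.mature_arm = "3p"
    else:
        ev.reasons.append("loop_overlap")  # pairs on both sides: mature spans the apex
    if ev.mature_arm:
        ev.star_span = (lo, hi + 1)
        # asymmetric internal loops / bulges inside the mature-star duplex
        paired = [i for i in mature if pt[i] >= 0]
        for a, b in zip(paired, paired[1:]):
            if (pt[b] - pt[a]) * (b - a) > 0:
                ev.reasons.append("crossing_duplex")
                break
            gap_m = b - a - 1
            gap_s = abs(pt[a] - pt[b]) - 1
            if abs(gap_m - gap_s) > criteria.max_bulge:
                ev.reasons.append("bulge")
                break
    if energy > criteria.max_energy:
        ev.reasons.append("energy")
    ev.passed = not ev.reasons
    return ev
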