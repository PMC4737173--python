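"""Reactivity-constrained secondary structure prediction.

Reactivities enter thermodynamic folding through the standard per-
nucleotide pseudo-free-energy term

    dG_i = m * ln(rho_i + 1) + b        [kcal/mol]

with defaults m = 1.1, b = -0.3, so reactive (flexible) positions pay an
energetic penalty for base pairing.  Folding itself is delegated to the
ViennaRNA Turner nearest-neighbour engine via its SHAPE-restraint
mechanism (per-stack application of the term above); the engine name and
version are recorded on every structure so configurations are auditable.
Missing reactivities contribute no pseudo energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

try:
    import RNA

    _ENGINE = f"ViennaRNA {RNA.__version__}"
except ImportError:  # pragma: no cover - engine is a hard runtime dependency
    RNA = None
    _ENGINE = None

from .reactivity import MISSING, RhoProfile
from .targets import TargetRNA, as_rna


def _require_engine() -> None:
    if RNA is None:
        raise RuntimeError(
            "no thermodynamic folding engine available: install the ViennaRNA "
            "python bindings (package 'ViennaRNA') to enable fold_mfe"
        )


@dataclass(frozen=True)
class PseudoEnergyParams:
    """Slope/intercept of the reactivity pseudo-free-energy term, kcal/mol."""

    m: float = 1.1
    b: float = -0.3

    def __post_init__(self) -> None:
        if not (math.isfinite(self.m) and math.isfinite(self.b)):
            raise ValueError("pseudo-energy parameters must be finite")


@dataclass
class StructureModel:
    """A secondary structure model: sequence, dot-bracket, free energy."""

    sequence: str
    dotbracket: str
    free_energy: float  # kcal/mol
    constrained: bool = False
    engine: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.dotbracket):
            raise ValueError("sequence and dot-bracket lengths differ")
        base_pairs(self.dotbracket)  # validates balance

    @property
    def pairs(self) -> set[tuple[int, int]]:
        return base_pairs(self.dotbracket)


def base_pairs(dotbracket: str) -> set[tuple[int, int]]:
    """1-based (i, j) pairs of a balanced dot-bracket string."""
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for i, c in enumerate(dotbracket, start=1):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced dot-bracket at position {i}")
            pairs.add((stack.pop(), i))
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket: unclosed '('")
    return pairs


def pseudo_energy_terms(rho: RhoProfile | np.ndarray,
                        params: PseudoEnergyParams = PseudoEnergyParams()) -> np.ndarray:
    """Per-nucleotide pseudo energies m*ln(rho+1)+b; 0 at missing positions."""
    if isinstance(rho, RhoProfile):
        values, observed = rho.rho, rho.observed
    else:
        values = np.asarray(rho, dtype=float)
        observed = ~np.isnan(values)
        values = np.where(observed, values, 0.0)
    if (values[observed] < 0).any():
        raise ValueError("rho must be non-negative at observed positions")
    terms = np.zeros_like(values, dtype=float)
    terms[observed] = params.m * np.log1p(values[observed]) + params.b
    return terms


# ---------------------------------------------------------------------------
# SHAPE constraint file I/O (1-based "index value" lines, -999 = missing)


def write_shape_file(rho: RhoProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, (value, obs) in enumerate(zip(rho.rho, rho.observed), start=1):
            fh.write(f"{i} {value:g}\n" if obs else f"{i} {MISSING:g}\n")


def read_shape_file(path: str | Path, target: str = "") -> RhoProfile:
    indices, values = [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            idx, val = line.split()
            indices.append(int(idx))
            values.append(float(val))
    n = max(indices, default=0)
    rho = np.zeros(n)
    observed = np.zeros(n, dtype=bool)
    for i, v in zip(indices, values):
        if v != MISSING:
            rho[i - 1] = v
            observed[i - 1] = True
    return RhoProfile(target, rho, observed=observed)


# ---------------------------------------------------------------------------
# folding


def fold_mfe(sequence: str, rho: RhoProfile | None = None,
             params: PseudoEnergyParams = PseudoEnergyParams()) -> StructureModel:
    """Minimum-free-energy structure, optionally reactivity-constrained.

    With ``rho`` given, the per-nucleotide pseudo-energy terms are applied
    through the engine's SHAPE-restraint mechanism (missing positions are
    passed as -999 and ignored).
    """
    _require_engine()
    seq = as_rna(sequence)
    if len(seq) < 4:
        raise ValueError("sequence too short to fold (need >= 4 nt)")
    if set(seq) - set("ACGU"):
        raise ValueError("sequence contains non-ACGU characters")
    fc = RNA.fold_compound(seq)
    constrained = rho is not None
    if constrained:
        if rho.n != len(seq):
            raise ValueError(
                f"reactivity profile length {rho.n} != sequence length {len(seq)}"
            )
        # engine expects a 1-based array (leading dummy); negatives ignored
        shape = [MISSING] + [
            float(v) if obs else MISSING for v, obs in zip(rho.rho, rho.observed)
        ]
        fc.sc_add_SHAPE_deigan(shape, params.m, params.b)
    structure, energy = fc.mfe()
    return StructureModel(seq, structure, round(float(energy), 2),
                          constrained=constrained, engine=_ENGINE)


def subsequence_mfe_energy(target: TargetRNA | str, start: int, end: int) -> float:
    """MFE free energy (kcal/mol) of a 1-based inclusive subsequence folded
    in isolation (flanking sequence does not enter)."""
    if isinstance(target, TargetRNA):
        sub = target.subsequence(start, end)
    else:
        seq = as_rna(target)
        if not 1 <= start <= end <= len(seq):
            raise ValueError(f"interval [{start}, {end}] out of range or reversed")
        sub = seq[start - 1 : end]
    return fold_mfe(sub).free_energy


def structure_agreement(a: StructureModel, b: StructureModel) -> tuple[int, float]:
    """(base-pair distance, paired/unpaired agreement fraction).

    Base-pair distance is the size of the symmetric difference of the two
    pair sets; agreement is the fraction of positions with identical
    paired/unpaired status.
    """
    if len(a.dotbracket) != len(b.dotbracket):
        raise ValueError("structures must have equal length")
    distance = len(a.pairs ^ b.pairs)
    same = sum(
        (ca != ".") == (cb != ".") for ca, cb in zip(a.dotbracket, b.dotbracket)
    )
    return distance, same / len(a.dotbracket)


# ---------------------------------------------------------------------------
# dot-bracket / CT interoperability


def write_dotbracket(model: StructureModel, path: str | Path, name: str = "structure") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n{model.sequence}\n{model.dotbracket} ({model.free_energy:.2f})\n")


def read_dotbracket(path: str | Path) -> StructureModel:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    seq, struct_line = lines[0], lines[1]
    parts = struct_line.split()
    energy = 0.0
    if len(parts) > 1:
        energy = float(parts[-1].strip("()"))
    return StructureModel(as_rna(seq), parts[0], energy)


def read_ct(path: str | Path) -> StructureModel:
    """Read a connectivity-table (CT) file into a StructureModel."""
    with open(path) as fh:
        header = fh.readline().split()
        n = int(header[0])
        energy = 0.0
        for tok in header:
            try:
                energy = float(tok)
            except ValueError:
                continue
            else:
                if tok != header[0]:
                    break
        seq = [""] * n
        partner = [0] * n
        for line in fh:
            parts = line.split()
            if len(parts) < 6:
                continue
            i = int(parts[0])
            seq[i - 1] = parts[1]
            partner[i - 1] = int(parts[4])
    db = ["."] * n
    for i, j in enumerate(partner, start=1):
        if j > i:
            db[i - 1] = "("
            db[j - 1] = ")"
    return StructureModel(as_rna("".join(seq)), "".join(db), energy)
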