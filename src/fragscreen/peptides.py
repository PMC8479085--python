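"""Peptide fragments and sequence-derived electrostatic properties.

Amyloid-beta (Aβ) screening studies work with short windows cut from the
42-residue parent peptide.  This module represents those fragments and
computes their Henderson--Hasselbalch net charge and theoretical
isoelectric point (pI) with the Bjellqvist pKₐ convention used by the
ExPASy ProtParam tool, so that printed pI values for fragments can be
reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "AB42_SEQUENCE",
    "FRAGMENT_WINDOWS",
    "Peptide",
    "PkaTable",
    "BJELLQVIST",
    "fragment_windows",
    "standard_fragments",
    "net_charge",
    "isoelectric_point",
    "NoIsoelectricPointError",
]

#: Human amyloid-beta 1-42 in single-letter code.
AB42_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"

#: The seven overlapping fragment windows P1..P7 (1-based, inclusive).
FRAGMENT_WINDOWS: dict[str, tuple[int, int]] = {
    "P1": (1, 10),
    "P2": (6, 15),
    "P3": (11, 20),
    "P4": (16, 25),
    "P5": (21, 30),
    "P6": (26, 36),
    "P7": (31, 42),
}

_STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Peptide:
    """A named peptide with optional terminal modifications.

    Parameters
    ----------
    name : str
        Short label, e.g. ``"P3"``.
    sequence : str
        Single-letter residue codes; only the 20 standard residues are
        accepted (non-standard codes are rejected rather than skipped,
        because silently dropping residues corrupts charge sums).
    n_acetylated, c_amidated : bool
        Whether the termini carry acetyl/amide caps that remove the
        terminal charges.
    parent_range : tuple[int, int] or None
        1-based inclusive interval in the parent sequence this fragment
        was cut from, if any.
    """

    name: str
    sequence: str
    n_acetylated: bool = False
    c_amidated: bool = False
    parent_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"peptide {self.name!r}: empty sequence")
        bad = sorted(set(self.sequence) - _STANDARD_RESIDUES)
        if bad:
            raise ValueError(
                f"peptide {self.name!r}: non-standard residue codes {bad!r}"
            )
        if self.parent_range is not None:
            lo, hi = self.parent_range
            if hi - lo + 1 != len(self.sequence):
                raise ValueError(
                    f"peptide {self.name!r}: parent_range {self.parent_range} "
                    f"length {hi - lo + 1} != sequence length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PkaTable:
    """Side-chain and terminal pKₐ values for charge calculations.

    ``nterm_by_residue`` / ``cterm_by_residue`` hold the residue-specific
    terminal pKₐ variants of the Bjellqvist set (the N-terminal pKₐ
    depends on the first residue, the C-terminal one on the last).
    """

    acidic: dict[str, float]
    basic: dict[str, float]
    nterm_default: float
    cterm_default: float
    nterm_by_residue: dict[str, float] = field(default_factory=dict)
    cterm_by_residue: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for group in (
            self.acidic,
            self.basic,
            {"Nterm": self.nterm_default, "Cterm": self.cterm_default},
            self.nterm_by_residue,
            self.cterm_by_residue,
        ):
            for site, pka in group.items():
                if not 0.0 < pka < 14.0:
                    raise ValueError(f"pKa for {site!r} out of (0, 14): {pka}")

    def nterm_pka(self, first_residue: str) -> float:
        return self.nterm_by_residue.get(first_residue, self.nterm_default)

    def cterm_pka(self, last_residue: str) -> float:
        return self.cterm_by_residue.get(last_residue, self.cterm_default)


#: The Bjellqvist pKa set as used by ExPASy ProtParam.
BJELLQVIST = PkaTable(
    acidic={"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
    basic={"H": 5.98, "K": 10.0, "R": 12.0},
    nterm_default=7.5,
    cterm_default=3.55,
    nterm_by_residue={
        "A": 7.59,
        "M": 7.0,
        "S": 6.93,
        "P": 8.36,
        "T": 6.82,
        "V": 7.44,
        "E": 7.7,
    },
    cterm_by_residue={"D": 4.55, "E": 4.75},
)


class NoIsoelectricPointError(ValueError):
    """Raised when net charge has no zero crossing on pH 0..14."""


def fragment_windows(
    parent: Peptide, ranges: Sequence[tuple[int, int]], names: Sequence[str] | None = None
) -> list[Peptide]:
    """Cut overlapping windows out of a parent peptide.

    Each interval is 1-based and inclusive.  The returned fragments are
    flagged as N-terminally acetylated and C-terminally amidated, the way
    synthesized screening fragments are capped.

    Raises
    ------
    ValueError
        If an interval falls outside the parent sequence.
    """
    if names is None:
        names = [f"{parent.name}_{lo}-{hi}" for lo, hi in ranges]
    if len(names) != len(ranges):
        raise ValueError("names and ranges must have equal length")
    out = []
    n = len(parent.sequence)
    for name, (lo, hi) in zip(names, ranges):
        if not (1 <= lo <= hi <= n):
            raise ValueError(
                f"interval ({lo}, {hi}) out of bounds for parent of length {n}"
            )
        out.append(
            Peptide(
                name=name,
                sequence=parent.sequence[lo - 1 : hi],
                n_acetylated=True,
                c_amidated=True,
                parent_range=(lo, hi),
            )
        )
    return out


def standard_fragments() -> list[Peptide]:
    """The seven standard overlapping Aβ1-42 screening fragments P1..P7."""
    parent = Peptide("Abeta42", AB42_SEQUENCE)
    return fragment_windows(
        parent, list(FRAGMENT_WINDOWS.values()), names=list(FRAGMENT_WINDOWS)
    )


def net_charge(
    p: Peptide,
    pH: float,
    table: PkaTable = BJELLQVIST,
    free_termini: bool = True,
) -> float:
    """Henderson--Hasselbalch net charge at a given pH.

    Each basic site contributes ``1 / (1 + 10**(pH - pKa))`` and each
    acidic site ``-1 / (1 + 10**(pKa - pH))``.  Terminal amine/carboxyl
    charges are included only when ``free_termini`` is true; capped
    synthetic fragments should pass ``free_termini=False`` for the
    chemically accurate charge.
    """
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH {pH} outside [0, 14]")
    charge = 0.0
    for res in p.sequence:
        if res in table.basic:
            charge += 1.0 / (1.0 + 10.0 ** (pH - table.basic[res]))
        elif res in table.acidic:
            charge -= 1.0 / (1.0 + 10.0 ** (table.acidic[res] - pH))
    if free_termini:
        charge += 1.0 / (1.0 + 10.0 ** (pH - table.nterm_pka(p.sequence[0])))
        charge -= 1.0 / (1.0 + 10.0 ** (table.cterm_pka(p.sequence[-1]) - pH))
    return charge


def isoelectric_point(
    p: Peptide,
    table: PkaTable = BJELLQVIST,
    free_termini: bool = True,
    tol: float = 1e-3,
    decimals: int | None = 2,
) -> float:
    """pH of zero net charge, by bisection on [0, 14].

    Printed theoretical pI values for capped fragments are conventionally
    computed with free termini (the ProtParam convention), so that is the
    default even for acetylated/amidated peptides.

    Parameters
    ----------
    tol : float
        Bisection half-width in pH units before rounding.
    decimals : int or None
        Rounding applied to the result (2 matches conventional
        reporting); ``None`` disables rounding.

    Raises
    ------
    NoIsoelectricPointError
        If the net charge does not change sign on [0, 14] (possible only
        with fixed termini and a one-signed composition).
    """
    lo, hi = 0.0, 14.0
    c_lo = net_charge(p, lo, table, free_termini)
    c_hi = net_charge(p, hi, table, free_termini)
    if c_lo < 0.0 or c_hi > 0.0 or (c_lo == 0.0 and c_hi == 0.0):
        raise NoIsoelectricPointError(
            f"peptide {p.name!r}: no isoelectric point on pH [0, 14] "
            f"(charge {c_lo:+.3f} at pH 0, {c_hi:+.3f} at pH 14)"
        )
    # net_charge is strictly decreasing in pH, so bisection converges to
    # the unique zero crossing.
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(p, mid, table, free_termini) > 0.0:
            lo = mid
        else:
            hi = mid
    pi = 0.5 * (lo + hi)
    return round(pi, decimals) if decimals is not None else pi
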