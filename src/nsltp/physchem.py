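"""Molecular weight and isoelectric point of mature proteins.

Molecular weight uses average (not monoisotopic) residue masses, matching
conventional protein-parameter tools. The isoelectric point solves
``charge(pH) = 0`` by bisection on [0, 14], where the net charge is the sum
of Henderson-Hasselbalch terms over ionizable side chains and the termini;
cysteines are treated as free (disulphides ignored). Both tables ship as
editable TSV data files and can be overridden per call.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources


@dataclass(frozen=True)
class MassTable:
    residue_mass: dict[str, float]
    water: float = 18.01524

    def __post_init__(self):
        if any(m <= 0 for m in self.residue_mass.values()) or self.water <= 0:
            raise ValueError("masses must be positive")


@dataclass(frozen=True)
class PkaSet:
    """pKa per ionizable group plus its charge sign ('+' or '-')."""

    pka: dict[str, float]
    sign: dict[str, str]

    def __post_init__(self):
        for g, v in self.pka.items():
            if not 0 < v < 14:
                raise ValueError(f"pKa for {g} outside (0,14)")


def _read_table(name: str) -> list[list[str]]:
    text = resources.files("nsltp.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        if line.strip() and not line.startswith("#"):
            rows.append(line.split("\t"))
    return rows


def load_mass_table(path=None) -> MassTable:
    rows = (
        [l.split("\t") for l in open(path) if l.strip() and not l.startswith("#")]
        if path else _read_table("residue_masses.tsv")
    )
    return MassTable({r[0]: float(r[1]) for r in rows})


def load_pka_set(path=None) -> PkaSet:
    rows = (
        [l.split("\t") for l in open(path) if l.strip() and not l.startswith("#")]
        if path else _read_table("pka_emboss.tsv")
    )
    return PkaSet(
        {r[0]: float(r[1]) for r in rows},
        {r[0]: r[2].strip() for r in rows},
    )


DEFAULT_MASSES = load_mass_table()
DEFAULT_PKA = load_pka_set()


def molecular_weight(sequence: str, table: MassTable = DEFAULT_MASSES) -> float:
    """Average molecular weight in Da: sum of residue masses plus one water."""
    bad = [i for i, r in enumerate(sequence) if r not in table.residue_mass]
    if bad:
        raise ValueError(f"non-standard residues at positions {bad}")
    return sum(table.residue_mass[r] for r in sequence) + table.water


def net_charge(sequence: str, ph: float, pka: PkaSet = DEFAULT_PKA) -> float:
    """Henderson-Hasselbalch net charge of a peptide at a given pH."""
    counts = {"Nterm": 1, "Cterm": 1}
    for r in sequence:
        if r in pka.pka:
            counts[r] = counts.get(r, 0) + 1
    charge = 0.0
    for group, n in counts.items():
        k = pka.pka[group]
        if pka.sign[group] == "+":
            charge += n / (1 + 10 ** (ph - k))
        else:
            charge -= n / (1 + 10 ** (k - ph))
    return charge


def isoelectric_point(
    sequence: str, pka: PkaSet = DEFAULT_PKA, tol: float = 1e-4
) -> float:
    """pH at which the net charge crosses zero (bisection on [0, 14]).

    The charge is strictly decreasing in pH and positive at pH 0, negative
    at pH 14, so the root always exists and bisection converges.
    """
    if not sequence:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if net_charge(sequence, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2
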