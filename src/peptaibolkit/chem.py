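"""Elemental-formula arithmetic and the noncanonical peptaibol residue alphabet.

Peptaibols are linear fungal nonribosomal peptides (typically 5-20 residues)
built from an acetylated N-terminus, a run of amino-acid residues rich in
alpha-aminoisobutyric acid (Aib), and a C-terminal amino alcohol in place of
the usual carboxylate. Several residues are isobaric at MS resolution and are
therefore handled as ambiguity classes: ``Vxx`` (Val/Iva), ``Lxx`` (Leu/Ile),
``Lxxol`` (leucinol/isoleucinol).

All masses in this package are monoisotopic and flow through the element
table defined here; the nominal (integer mass-number) scale used in classic
b-ion ladder bookkeeping (Aib = 85 u, Gln = 128 u, ...) is carried alongside.

Protonated species use the hydrogen-atom convention: ``[M+H]+ = M + m(H)``
with the electron mass neglected. This matches the convention of the
instrument software the reference measurements were reduced with.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterator, Mapping

__all__ = [
    "FormulaError",
    "AlphabetError",
    "ElementalFormula",
    "ResidueDef",
    "AminoAlcoholDef",
    "Alphabet",
    "PeptaibolSequence",
    "parse_formula",
    "monoisotopic_mass",
    "nominal_mass",
    "protonated_mz",
    "ppm_error",
    "sequence_formula",
    "HYDROGEN",
    "ACETYL",
    "WATER",
]

#: Monoisotopic atomic masses (Da) of the supported elements.
MONOISOTOPIC: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

#: Integer mass numbers of the most abundant isotopes (nominal-mass scale).
NOMINAL: dict[str, int] = {"C": 12, "H": 1, "N": 14, "O": 16, "S": 32}

#: Mass added on protonation (hydrogen-atom convention, electron neglected).
HYDROGEN: float = MONOISOTOPIC["H"]


class FormulaError(ValueError):
    """Malformed or unsupported elemental formula."""


class AlphabetError(KeyError):
    """Residue or amino-alcohol code missing from the alphabet."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Immutable element -> count map with monoisotopic/nominal mass semantics.

    Instances are hashable and additive; ``parse`` accepts both the plain
    dialect (``C63H111N17O18``) and the underscore dialect sometimes used in
    print (``C_63_H_111_N_17_O_18``). Serialization is canonical Hill order
    (C, H, then alphabetical).
    """

    counts: tuple[tuple[str, int], ...]

    def __init__(self, counts: Mapping[str, int]):
        clean: dict[str, int] = {}
        for element, n in counts.items():
            if element not in MONOISOTOPIC:
                raise FormulaError(f"unsupported element symbol: {element!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"count for {element} must be a non-negative integer, got {n!r}")
            if n:
                clean[element] = n
        object.__setattr__(self, "counts", tuple(sorted(clean.items())))

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        return parse_formula(text)

    def __getitem__(self, element: str) -> int:
        return dict(self.counts).get(element, 0)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for element, n in other.counts:
            merged[element] = merged.get(element, 0) + n
        return ElementalFormula(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for element, n in other.counts:
            merged[element] = merged.get(element, 0) - n
            if merged[element] < 0:
                raise FormulaError(
                    f"subtraction would make {element} count negative ({self} - {other})"
                )
        return ElementalFormula(merged)

    def __mul__(self, k: int) -> "ElementalFormula":
        if not isinstance(k, int) or k < 0:
            raise FormulaError(f"formula multiplier must be a non-negative integer, got {k!r}")
        return ElementalFormula({e: n * k for e, n in self.counts})

    __rmul__ = __mul__

    @property
    def monoisotopic_mass(self) -> float:
        return sum(n * MONOISOTOPIC[e] for e, n in self.counts)

    @property
    def nominal_mass(self) -> int:
        return sum(n * NOMINAL[e] for e, n in self.counts)

    def hill(self) -> str:
        """Canonical Hill-order string (count 1 written explicitly omitted)."""
        order = [e for e in ("C", "H") if self[e]] + sorted(
            e for e, _ in self.counts if e not in ("C", "H")
        )
        return "".join(f"{e}{self[e] if self[e] != 1 else ''}" for e in order)

    def __str__(self) -> str:
        return self.hill()


def parse_formula(text: str) -> ElementalFormula:
    """Parse ``C63H111N17O18`` or the underscore dialect ``C_63_H_111_N_17_O_18``."""
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    stripped = text.strip().replace("_", "")
    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN.finditer(stripped):
        if match.start() != pos:
            raise FormulaError(
                f"malformed formula {text!r}: unexpected token {stripped[pos:match.start()]!r}"
            )
        element, digits = match.group(1), match.group(2)
        if element not in MONOISOTOPIC:
            raise FormulaError(f"unknown element symbol {element!r} in {text!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(stripped):
        raise FormulaError(f"malformed formula {text!r}: trailing {stripped[pos:]!r}")
    return ElementalFormula(counts)


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Sum of count x monoisotopic atomic mass, in Da."""
    return f.monoisotopic_mass


def nominal_mass(f: ElementalFormula) -> int:
    """Sum of count x integer mass number (C=12, H=1, N=14, O=16)."""
    return f.nominal_mass


def protonated_mz(f: ElementalFormula) -> float:
    """[M+H]+ m/z of a neutral formula (hydrogen-atom convention)."""
    return f.monoisotopic_mass + HYDROGEN


def ppm_error(theoretical: float, observed: float) -> float:
    """Relative mass deviation, (observed - theoretical) / theoretical x 1e6."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return (observed - theoretical) / theoretical * 1e6


#: Mass delta of N-terminal acetylation (CH3CO- replacing an H).
ACETYL = ElementalFormula({"C": 2, "H": 2, "O": 1})
WATER = ElementalFormula({"H": 2, "O": 1})


@dataclass(frozen=True)
class ResidueDef:
    """An amino-acid residue (NH-CHR-CO composition) of the peptaibol alphabet.

    ``ambiguity_class`` lists the concrete amino acids an MS-level code stands
    for, e.g. Vxx = {Val, Iva}: isobaric at residue level, indistinguishable
    by fragment mass alone.
    """

    code: str
    formula: ElementalFormula
    ambiguity_class: frozenset[str] = field(default_factory=frozenset)

    @property
    def monoisotopic_mass(self) -> float:
        return self.formula.monoisotopic_mass

    @property
    def nominal_mass(self) -> int:
        return self.formula.nominal_mass


@dataclass(frozen=True)
class AminoAlcoholDef:
    """A C-terminal amino alcohol (reduced residue terminating the peptaibol).

    ``neutral_loss_mass`` is the mass of the free amino alcohol molecule,
    which is lost from [M+H]+ to give the b(n-1) ion — the diagnostic
    C-terminal loss (117 u for leucinol/isoleucinol, 151 u for
    phenylalaninol).
    """

    code: str
    free_formula: ElementalFormula
    ambiguity_class: frozenset[str] = field(default_factory=frozenset)

    @property
    def neutral_loss_mass(self) -> float:
        return self.free_formula.monoisotopic_mass

    @property
    def nominal_loss(self) -> int:
        return self.free_formula.nominal_mass


class Alphabet:
    """Residue + amino-alcohol alphabet, loadable from a TSV table.

    The packaged default covers the codes seen in Trichoderma peptaibols
    (Gly, Ala, Aib, Ser, Pro, Vxx, Lxx, Gln, Glu; Lxxol, Pheol, Vxxol) and can
    be overridden with a user table of the same three-column layout
    (kind, code, formula, members).
    """

    def __init__(self, residues: dict[str, ResidueDef], amino_alcohols: dict[str, AminoAlcoholDef]):
        self.residues = dict(residues)
        self.amino_alcohols = dict(amino_alcohols)

    def residue(self, code: str) -> ResidueDef:
        try:
            return self.residues[code]
        except KeyError:
            raise AlphabetError(f"unknown residue code {code!r}") from None

    def amino_alcohol(self, code: str) -> AminoAlcoholDef:
        try:
            return self.amino_alcohols[code]
        except KeyError:
            raise AlphabetError(f"unknown amino-alcohol code {code!r}") from None

    @classmethod
    def from_table(cls, path) -> "Alphabet":
        residues: dict[str, ResidueDef] = {}
        alcohols: dict[str, AminoAlcoholDef] = {}
        with open(path, encoding="utf-8") as handle:
            header = handle.readline().rstrip("\n").split("\t")
            for line in handle:
                if not line.strip() or line.startswith("#"):
                    continue
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                members = frozenset(m for m in row.get("members", "").split(",") if m)
                formula = parse_formula(row["formula"])
                if row["kind"] == "residue":
                    residues[row["code"]] = ResidueDef(row["code"], formula, members)
                elif row["kind"] == "amino_alcohol":
                    alcohols[row["code"]] = AminoAlcoholDef(row["code"], formula, members)
                else:
                    raise FormulaError(f"unknown alphabet entry kind {row['kind']!r}")
        return cls(residues, alcohols)

    @classmethod
    def default(cls) -> "Alphabet":
        return _default_alphabet()


@lru_cache(maxsize=1)
def _default_alphabet() -> Alphabet:
    ref = resources.files("peptaibolkit.data").joinpath("residues.tsv")
    with resources.as_file(ref) as path:
        return Alphabet.from_table(path)


@dataclass(frozen=True)
class PeptaibolSequence:
    """Acetyl cap + ordered residue codes + C-terminal amino alcohol.

    ``residues`` excludes the amino alcohol; a 15-residue peptaibol therefore
    has 14 entries plus ``c_term``.
    """

    residues: tuple[str, ...]
    c_term: str
    name: str = ""
    n_term_acetyl: bool = True

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValueError("a peptaibol needs at least one residue before the amino alcohol")
        object.__setattr__(self, "residues", tuple(self.residues))

    @property
    def n_positions(self) -> int:
        """Total positions including the C-terminal amino alcohol."""
        return len(self.residues) + 1

    def formula(self, alphabet: Alphabet | None = None) -> ElementalFormula:
        return sequence_formula(self, alphabet)

    def monoisotopic_mass(self, alphabet: Alphabet | None = None) -> float:
        return self.formula(alphabet).monoisotopic_mass

    def protonated_mz(self, alphabet: Alphabet | None = None) -> float:
        return protonated_mz(self.formula(alphabet))

    def __str__(self) -> str:
        cap = "Ac-" if self.n_term_acetyl else "H-"
        return cap + "-".join(self.residues) + "-" + self.c_term

    @classmethod
    def from_string(cls, text: str, name: str = "") -> "PeptaibolSequence":
        """Parse ``Ac-Aib-Ala-...-Lxxol`` notation."""
        parts = text.strip().split("-")
        if len(parts) < 3:
            raise ValueError(f"cannot parse sequence string {text!r}")
        acetyl = parts[0] == "Ac"
        if parts[0] not in ("Ac", "H"):
            raise ValueError(f"sequence must start with 'Ac' or 'H', got {parts[0]!r}")
        return cls(residues=tuple(parts[1:-1]), c_term=parts[-1], name=name, n_term_acetyl=acetyl)


def sequence_formula(s: PeptaibolSequence, alphabet: Alphabet | None = None) -> ElementalFormula:
    """Molecular formula: acetyl delta + sum of residues + free amino alcohol.

    Ambiguity classes map to the class's shared composition (all members are
    isomers), so Vxx contributes C5H9NO regardless of Val vs Iva.
    """
    alphabet = alphabet or Alphabet.default()
    total = ACETYL if s.n_term_acetyl else ElementalFormula({})
    for code in s.residues:
        total = total + alphabet.residue(code).formula
    return total + alphabet.amino_alcohol(s.c_term).free_formula
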