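"""Theoretical fragment generation for N-acetylated, amino-alcohol peptaibols.

Under low-energy CID, peptaibols fragment almost exclusively into b-series
ions: the acylium ladder b2..b(n-1) whose successive differences are residue
masses, plus a precursor family of [M+H]+, the water loss, and the
diagnostic loss of the free C-terminal amino alcohol (which coincides with
b(n-1)). y-type ions can be generated on request but are off by default, as
they are rarely informative for these compounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import (
    ACETYL,
    HYDROGEN,
    WATER,
    Alphabet,
    ElementalFormula,
    PeptaibolSequence,
    sequence_formula,
)
from .spectra import Spectrum

__all__ = [
    "FragmentIon",
    "TheoreticalSpectrum",
    "b_ion_formula",
    "b_ion_mz",
    "precursor_losses",
    "theoretical_spectrum",
]


@dataclass(frozen=True)
class FragmentIon:
    """A single predicted ion: kind, b index (if applicable), m/z, composition."""

    kind: str  # 'b', 'y', 'precursor', 'precursor_minus_water', 'precursor_minus_aminol'
    index: int | None
    mz: float
    nominal_mz: int
    composition: ElementalFormula


def b_ion_formula(s: PeptaibolSequence, i: int, alphabet: Alphabet | None = None) -> ElementalFormula:
    """Neutral composition of the b_i fragment (acetyl + first i residues)."""
    n_res = len(s.residues)
    if not 1 <= i <= n_res:
        raise IndexError(f"b index {i} out of range [1, {n_res}] for {s.name or s}")
    alphabet = alphabet or Alphabet.default()
    total = ACETYL
    for code in s.residues[:i]:
        total = total + alphabet.residue(code).formula
    return total


def b_ion_mz(s: PeptaibolSequence, i: int, alphabet: Alphabet | None = None) -> float:
    """m/z of the singly charged b_i ion: acetyl + residues(1..i) + H."""
    return b_ion_formula(s, i, alphabet).monoisotopic_mass + HYDROGEN


def _ion(kind: str, index: int | None, composition: ElementalFormula) -> FragmentIon:
    return FragmentIon(
        kind=kind,
        index=index,
        mz=composition.monoisotopic_mass + HYDROGEN,
        nominal_mz=composition.nominal_mass + 1,
        composition=composition,
    )


def precursor_losses(s: PeptaibolSequence, alphabet: Alphabet | None = None) -> list[FragmentIon]:
    """[M+H]+, [M+H-H2O]+ and [M+H-amino alcohol]+ for a sequence.

    The amino-alcohol loss equals b(n-1): losing the free amino alcohol from
    the protonated molecule leaves exactly the acylium b(n-1) fragment.
    """
    alphabet = alphabet or Alphabet.default()
    full = sequence_formula(s, alphabet)
    aminol = alphabet.amino_alcohol(s.c_term)
    return [
        _ion("precursor", None, full),
        _ion("precursor_minus_water", None, full - WATER),
        _ion("precursor_minus_aminol", None, full - aminol.free_formula),
    ]


@dataclass(frozen=True)
class TheoreticalSpectrum:
    """Predicted ion list for a sequence, convertible to a peak list."""

    sequence: PeptaibolSequence
    ions: tuple[FragmentIon, ...]
    intensity_model: str = "uniform"

    def peak_list(self) -> list[tuple[float, float]]:
        """(m/z, intensity) pairs, duplicates within 1e-6 Da merged (max intensity)."""
        weights = _intensities(self.sequence, self.ions, self.intensity_model)
        pairs = sorted(zip((ion.mz for ion in self.ions), weights))
        merged: list[tuple[float, float]] = []
        for mz, w in pairs:
            if merged and abs(mz - merged[-1][0]) <= 1e-6:
                merged[-1] = (merged[-1][0], max(merged[-1][1], w))
            else:
                merged.append((mz, w))
        return merged

    def to_spectrum(self, id: str = "") -> Spectrum:
        peaks = self.peak_list()
        precursor = next(ion.mz for ion in self.ions if ion.kind == "precursor")
        return Spectrum(
            precursor_mz=precursor,
            mz=np.array([p[0] for p in peaks]),
            intensity=np.array([p[1] for p in peaks]),
            id=id or self.sequence.name,
        )


def _intensities(s: PeptaibolSequence, ions, model: str) -> list[float]:
    """Invented intensity models; 'uniform' is all-ones, 'triangular' peaks mid-ladder."""
    if model == "uniform":
        return [1.0 for _ in ions]
    if model == "triangular":
        n = len(s.residues)
        mid = (n + 1) / 2.0
        out = []
        for ion in ions:
            if ion.kind == "b":
                out.append(max(0.2, 1.0 - abs(ion.index - mid) / mid))
            else:
                out.append(0.5)
        return out
    raise ValueError(f"unknown intensity model {model!r}")


def theoretical_spectrum(
    s: PeptaibolSequence,
    *,
    suppress_b1_b2: bool = False,
    include_y: bool = False,
    intensity_model: str = "uniform",
    charge: int = 1,
    alphabet: Alphabet | None = None,
) -> TheoreticalSpectrum:
    """Assemble the default ion set: b ions (2..n-1) plus the precursor family.

    ``suppress_b1_b2`` mimics real peptaibol spectra, where the short
    N-terminal acylium ions are not observed; downstream sequencing never
    relies on them.
    """
    if charge != 1:
        raise ValueError(f"only charge 1 is supported, got {charge}")
    alphabet = alphabet or Alphabet.default()
    n_res = len(s.residues)
    ions: list[FragmentIon] = []
    first_b = 3 if suppress_b1_b2 else 2
    for i in range(first_b, n_res + 1):
        ions.append(_ion("b", i, b_ion_formula(s, i, alphabet)))
    if include_y:
        # y_k: last k residues + amino alcohol, protonated free amine.
        alcohol = alphabet.amino_alcohol(s.c_term).free_formula
        for k in range(1, n_res):
            comp = alcohol
            for code in s.residues[n_res - k:]:
                comp = comp + alphabet.residue(code).formula
            ions.append(
                FragmentIon(
                    kind="y",
                    index=k,
                    mz=comp.monoisotopic_mass + HYDROGEN,
                    nominal_mz=comp.nominal_mass + 1,
                    composition=comp,
                )
            )
    ions.extend(precursor_losses(s, alphabet))
    ions.sort(key=lambda ion: (ion.mz, ion.kind))
    return TheoreticalSpectrum(sequence=s, ions=tuple(ions), intensity_model=intensity_model)
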