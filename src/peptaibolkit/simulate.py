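"""Synthetic peptaibol MS/MS spectra and the packaged endophytin table.

Real peptaibol product-ion spectra are dominated by the b3..b(n-1) ladder
plus the precursor, its water loss, and the amino-alcohol loss. The
generator emulates exactly that, with controlled imperfections: ppm-scale
Gaussian m/z jitter, independent per-b-ion dropout, and uniform random noise
peaks — all reproducible under a seed — so every pipeline stage can be
exercised without instrument data.

The packaged fixture covers the 21 endophytins (A1-A13, B1-B8), all
instances of the template

    Ac-Aib-Ala-Aib-Ala-AA1-Gln-AA2-AA3-Aib-Ala-Aib-Aib-AA4-AA5-AA6ol

with six variable positions. Each record carries the values as printed in
the source table (experimental m/z, ppm, formula) alongside the formula and
theoretical m/z derived here from the sequence, plus consistency flags:
several printed rows disagree with their own sequences and are flagged
rather than silently corrected. The row printed with the bare name
"Endophytin" (compound 11) is stored as A7, the only A-series index
otherwise unused.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from .chem import (
    Alphabet,
    PeptaibolSequence,
    parse_formula,
    ppm_error,
    protonated_mz,
    sequence_formula,
)
from .fragments import _intensities, theoretical_spectrum
from .spectra import Spectrum, read_mgf, write_mgf  # noqa: F401  (re-exported I/O)

__all__ = [
    "GeneratorParams",
    "EndophytinRecord",
    "generate_spectrum",
    "endophytin_table",
    "fixture_spectra",
    "random_sequence",
    "read_mgf",
    "write_mgf",
]

#: Variable template positions (1-based) filled by aa1..aa5; aa6 is the C-terminus.
TEMPLATE = ("Aib", "Ala", "Aib", "Ala", None, "Gln", None, None, "Aib", "Ala", "Aib", "Aib", None, None)


@dataclass(frozen=True)
class GeneratorParams:
    """Noise model for synthetic spectra; defaults are noiseless."""

    mz_jitter_ppm: float = 0.0
    dropout_prob: float = 0.0
    n_noise_peaks: int = 0
    intensity_model: str = "uniform"
    suppress_b1_b2: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.mz_jitter_ppm < 0:
            raise ValueError("mz_jitter_ppm must be >= 0")
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout_prob must be in [0, 1]")
        if self.n_noise_peaks < 0:
            raise ValueError("n_noise_peaks must be >= 0")


def generate_spectrum(
    s: PeptaibolSequence,
    p: GeneratorParams = GeneratorParams(),
    alphabet: Alphabet | None = None,
) -> Spectrum:
    """Simulate one product-ion spectrum of a sequence under a noise model.

    Pipeline: predicted ions (b ladder + precursor family) -> independent
    b-ion dropout -> merge of coincident ions (the amino-alcohol loss equals
    b(n-1)) -> Gaussian m/z jitter (sigma = mz_jitter_ppm) -> uniform noise
    peaks in [200, precursor] with intensities in (0, 0.3 x max]. Identical
    params and seed give identical output.
    """
    rng = np.random.default_rng(p.seed)
    theo = theoretical_spectrum(
        s,
        suppress_b1_b2=p.suppress_b1_b2,
        intensity_model=p.intensity_model,
        alphabet=alphabet,
    )
    weights = _intensities(s, theo.ions, p.intensity_model)
    kept: list[tuple[float, float]] = []
    for ion, w in zip(theo.ions, weights):
        if ion.kind == "b" and rng.random() < p.dropout_prob:
            continue
        kept.append((ion.mz, w))

    kept.sort()
    merged: list[tuple[float, float]] = []
    for mz, w in kept:
        if merged and abs(mz - merged[-1][0]) <= 1e-6:
            merged[-1] = (merged[-1][0], max(merged[-1][1], w))
        else:
            merged.append((mz, w))

    mzs = np.array([m for m, _ in merged])
    intensities = np.array([w for _, w in merged])
    precursor = protonated_mz(sequence_formula(s, alphabet))
    if p.mz_jitter_ppm > 0:
        mzs = mzs * (1.0 + rng.normal(0.0, p.mz_jitter_ppm * 1e-6, size=mzs.size))
    if p.n_noise_peaks > 0:
        noise_mz = rng.uniform(200.0, precursor, size=p.n_noise_peaks)
        top = intensities.max() if intensities.size else 1.0
        noise_int = rng.uniform(0.0, 0.3 * top, size=p.n_noise_peaks)
        mzs = np.concatenate([mzs, noise_mz])
        intensities = np.concatenate([intensities, noise_int])
    return Spectrum(precursor_mz=precursor, mz=mzs, intensity=intensities, id=s.name or str(s))


@dataclass(frozen=True)
class EndophytinRecord:
    """One fixture row: printed values, sequence-derived values, and flags."""

    name: str
    compound_number: int
    sequence: PeptaibolSequence
    printed_mz: float
    printed_ppm: float
    printed_formula: str
    derived_formula: str = ""
    theoretical_mz: float = 0.0
    formula_matches: bool = False
    mz_within_5ppm: bool = False

    @property
    def consistent(self) -> bool:
        """Printed formula matches the sequence AND printed m/z agrees within 5 ppm."""
        return self.formula_matches and self.mz_within_5ppm


@lru_cache(maxsize=1)
def endophytin_table() -> tuple[EndophytinRecord, ...]:
    """The 21 endophytin records, with consistency flags computed on load."""
    alphabet = Alphabet.default()
    ref = resources.files("peptaibolkit.data").joinpath("endophytins.tsv")
    rows: list[EndophytinRecord] = []
    with ref.open(encoding="utf-8") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            residues = list(TEMPLATE)
            residues[4] = row["aa1"]
            residues[6] = row["aa2"]
            residues[7] = row["aa3"]
            residues[12] = row["aa4"]
            residues[13] = row["aa5"]
            seq = PeptaibolSequence(
                residues=tuple(residues), c_term=row["aa6"], name=row["name"]
            )
            derived = sequence_formula(seq, alphabet)
            theo_mz = protonated_mz(derived)
            printed_mz = float(row["printed_mz"])
            printed_formula = row["printed_formula"]
            formula_matches = derived.hill() == parse_formula(printed_formula).hill()
            rows.append(
                EndophytinRecord(
                    name=row["name"],
                    compound_number=int(row["compound_number"]),
                    sequence=seq,
                    printed_mz=printed_mz,
                    printed_ppm=float(row["printed_ppm"]),
                    printed_formula=printed_formula,
                    derived_formula=derived.hill(),
                    theoretical_mz=theo_mz,
                    formula_matches=formula_matches,
                    mz_within_5ppm=abs(ppm_error(theo_mz, printed_mz)) <= 5.0,
                )
            )
    assert len(rows) == 21, "fixture must hold exactly 21 endophytins"
    return tuple(rows)


def fixture_spectra(params: GeneratorParams = GeneratorParams()) -> list[Spectrum]:
    """Synthetic spectra for all 21 endophytins; per-row seeds derive from params.seed."""
    out = []
    for i, rec in enumerate(endophytin_table()):
        row_params = GeneratorParams(
            mz_jitter_ppm=params.mz_jitter_ppm,
            dropout_prob=params.dropout_prob,
            n_noise_peaks=params.n_noise_peaks,
            intensity_model=params.intensity_model,
            suppress_b1_b2=params.suppress_b1_b2,
            seed=(params.seed * 1000 + i) % (2**31),
        )
        out.append(generate_spectrum(rec.sequence, row_params))
    return out


def random_sequence(rng: np.random.Generator, length: int, alphabet: Alphabet | None = None) -> PeptaibolSequence:
    """A random peptaibol-like sequence (used for decoys and property tests)."""
    alphabet = alphabet or Alphabet.default()
    codes = sorted(alphabet.residues)
    alcohols = sorted(alphabet.amino_alcohols)
    residues = tuple(str(rng.choice(codes)) for _ in range(length - 1))
    return PeptaibolSequence(
        residues=residues, c_term=str(rng.choice(alcohols)), name=f"decoy_{rng.integers(1e6)}"
    )
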