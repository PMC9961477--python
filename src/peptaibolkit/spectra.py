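"""Centroided MS/MS spectrum container and MGF input/output.

A :class:`Spectrum` is the unit every pipeline stage consumes: a singly
protonated precursor m/z plus a centroided peak list. All file exchange goes
through the Mascot Generic Format (MGF), read and written with pyteomics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mgf as _mgf

__all__ = ["Spectrum", "MGFError", "read_mgf", "write_mgf"]


class MGFError(ValueError):
    """Malformed MGF content."""


@dataclass
class Spectrum:
    """A centroided product-ion spectrum of a singly charged precursor.

    Peaks are kept sorted ascending by m/z. Only charge 1+ is supported: the
    peptaibols this package targets ionize as monocharged [M+H]+ species.
    """

    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray
    charge: int = 1
    id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.charge != 1:
            raise ValueError(f"only singly charged spectra are supported, got charge {self.charge}")
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(self.intensity < 0):
            raise ValueError("peak intensities must be non-negative")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if self.mz.size and self.mz[-1] > self.precursor_mz + 1.0:
            raise ValueError(
                f"peak at m/z {self.mz[-1]:.4f} exceeds precursor {self.precursor_mz:.4f} + 1.0"
            )

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    @classmethod
    def from_peaks(
        cls,
        precursor_mz: float,
        peaks: Sequence[tuple[float, float]],
        *,
        charge: int = 1,
        id: str = "",
    ) -> "Spectrum":
        mz = [p[0] for p in peaks]
        intensity = [p[1] for p in peaks]
        return cls(precursor_mz=precursor_mz, mz=np.array(mz), intensity=np.array(intensity), charge=charge, id=id)


def read_mgf(path) -> list[Spectrum]:
    """Read all spectra from an MGF file.

    Raises :class:`MGFError` naming the offending block when a spectrum lacks
    PEPMASS or carries a charge other than 1+. An empty file yields an empty
    list.
    """
    path = Path(path)
    spectra: list[Spectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry.get("params", {})
            title = str(params.get("title", f"spectrum_{i}"))
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                raise MGFError(f"{path.name}: block {i + 1} ({title!r}) is missing PEPMASS")
            charges = params.get("charge")
            charge = int(charges[0]) if charges else 1
            try:
                spectra.append(
                    Spectrum(
                        precursor_mz=float(pepmass[0]),
                        mz=entry["m/z array"],
                        intensity=entry["intensity array"],
                        charge=charge,
                        id=title,
                    )
                )
            except ValueError as exc:
                raise MGFError(f"{path.name}: block {i + 1} ({title!r}): {exc}") from exc
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path) -> None:
    """Write spectra to MGF (BEGIN IONS / TITLE / PEPMASS / CHARGE=1+ / peaks)."""
    entries = []
    for s in spectra:
        entries.append(
            {
                "params": {"title": s.id, "pepmass": round(s.precursor_mz, 5), "charge": [s.charge]},
                "m/z array": s.mz,
                "intensity array": s.intensity,
            }
        )
    _mgf.write(entries, str(path), file_mode="w")
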