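"""De novo peptaibol sequencing from b-ion ladders.

The strategy mirrors how peptaibol MS/MS spectra are read by hand:

1. *C-terminal anchor* — the neutral loss of the free amino alcohol from
   [M+H]+ (117 u for leucinol/isoleucinol, 151 u for phenylalaninol)
   identifies the C-terminus and lands on the b(n-1) ion.
2. *Ladder reading* — walking from b(n-1) toward the N-terminus, successive
   peak differences are matched against residue masses (Gln 128, Ala 71,
   Aib 85, Vxx 99, Lxx 113, ...), one residue per step.
3. *Prefix completion* — b1/b2 are never observed, so the remaining
   N-terminal mass (everything below the last ladder peak, minus the acetyl
   cap) is completed combinatorially into residue multisets.
4. *Ordering* — multiset orderings that survive NRPS module-collinearity
   constraints become ranked sequence candidates.

All matching is done on monoisotopic masses with a configurable tolerance
(Da or ppm); the default 0.02 Da suits QTOF-class accuracy.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

from .chem import (
    ACETYL,
    HYDROGEN,
    Alphabet,
    PeptaibolSequence,
    ppm_error,
    protonated_mz,
    sequence_formula,
)
from .spectra import Spectrum

__all__ = [
    "Tolerance",
    "CTermCall",
    "LadderSegment",
    "LadderReading",
    "SequenceCandidate",
    "resolve_cterm",
    "read_ladder",
    "complete_prefix",
    "sequence_candidates",
]


@dataclass(frozen=True)
class Tolerance:
    """A mass-match tolerance in Da or ppm."""

    value: float
    unit: str = "da"

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("tolerance must be positive")
        if self.unit not in ("da", "ppm"):
            raise ValueError(f"tolerance unit must be 'da' or 'ppm', got {self.unit!r}")

    def window(self, reference_mz: float) -> float:
        """Absolute half-window in Da around a reference mass."""
        if self.unit == "da":
            return self.value
        return abs(reference_mz) * self.value * 1e-6

    def matches(self, theoretical: float, observed: float) -> bool:
        return abs(observed - theoretical) <= self.window(theoretical)


def _as_tol(tol) -> Tolerance:
    return tol if isinstance(tol, Tolerance) else Tolerance(float(tol), "da")


@dataclass(frozen=True)
class CTermCall:
    """An amino-alcohol assignment anchored on the b(n-1) peak."""

    code: str
    anchor_mz: float
    ppm: float


def resolve_cterm(spec: Spectrum, tol=0.02, alphabet: Alphabet | None = None) -> list[CTermCall]:
    """Identify the C-terminal amino alcohol from the [M+H - aminol]+ loss.

    For each amino alcohol in the alphabet, looks for a peak at
    ``precursor - neutral_loss`` within ``tol``; that peak doubles as the
    b(n-1) anchor for ladder reading. Calls are ranked by |ppm|; an empty
    list means no diagnostic loss was found.
    """
    tol = _as_tol(tol)
    alphabet = alphabet or Alphabet.default()
    calls: list[CTermCall] = []
    for code, aminol in sorted(alphabet.amino_alcohols.items()):
        target = spec.precursor_mz - aminol.neutral_loss_mass
        best = None
        for mz in spec.mz:
            if abs(mz - target) <= tol.window(target):
                dev = ppm_error(target, mz)
                if best is None or abs(dev) < abs(best[1]):
                    best = (float(mz), dev)
        if best is not None:
            calls.append(CTermCall(code=code, anchor_mz=best[0], ppm=best[1]))
    calls.sort(key=lambda c: (abs(c.ppm), c.code))
    return calls


@dataclass(frozen=True)
class LadderSegment:
    """One downward step of the ladder: a peak-pair difference explained by residues.

    ``options`` holds the alternative residue multisets (tuples, sorted) that
    explain the mass difference; a normal step has one single-residue option,
    a bridged step (one missing peak) carries two-residue multisets, which may
    be isobaric alternatives (e.g. {Ala,Ala} vs {Gly,Aib}).
    """

    upper_mz: float
    lower_mz: float
    options: tuple[tuple[str, ...], ...]
    ppm: float

    @property
    def n_residues(self) -> int:
        return len(self.options[0])


@dataclass(frozen=True)
class LadderReading:
    """Result of walking a b-ion ladder downward from an anchor peak.

    Segments are ordered from the anchor (C-terminal side) toward the
    N-terminus. ``prefix_gap_mass`` is the residue mass still unexplained
    below the last matched peak, after removing the acetyl cap and the
    charge proton.
    """

    anchor_mz: float
    segments: tuple[LadderSegment, ...]
    terminal_mz: float
    prefix_gap_mass: float

    @property
    def n_matched_b(self) -> int:
        """Number of b-ion peaks on the path, anchor included."""
        return len(self.segments) + 1

    @property
    def n_residues_called(self) -> int:
        return sum(seg.n_residues for seg in self.segments)

    @property
    def residue_calls(self) -> list[tuple[str, float]]:
        """(code, ppm) for unambiguous single-residue steps, C- to N-terminal order."""
        out = []
        for seg in self.segments:
            if len(seg.options) == 1 and len(seg.options[0]) == 1:
                out.append((seg.options[0][0], seg.ppm))
        return out


def read_ladder(
    spec: Spectrum,
    anchor_mz: float,
    *,
    tol=0.02,
    alphabet: Alphabet | None = None,
    bridge_missing_peaks: bool = False,
) -> LadderReading:
    """Trace the longest residue-difference path downward from an anchor peak.

    Builds a spectrum graph over peaks at or below the anchor: a directed
    edge joins two peaks whose m/z difference matches one residue mass (or,
    with ``bridge_missing_peaks``, the sum of two) within ``tol``. Returns
    the path from the anchor explaining the most residues; ties prefer fewer
    bridges, then lower cumulative |ppm|, then lexicographic residue labels.
    """
    tol = _as_tol(tol)
    alphabet = alphabet or Alphabet.default()
    window = tol.window(anchor_mz)
    if not any(abs(m - anchor_mz) <= 1e-9 for m in spec.mz):
        raise ValueError(f"anchor peak {anchor_mz:.4f} not present in spectrum {spec.id!r}")

    peaks = sorted({float(m) for m in spec.mz if m <= anchor_mz + window}, reverse=True)
    residues = sorted(alphabet.residues.items())
    singles = [(code, r.monoisotopic_mass) for code, r in residues]
    pair_masses: dict[tuple[str, ...], float] = {}
    if bridge_missing_peaks:
        for (c1, m1), (c2, m2) in itertools.combinations_with_replacement(singles, 2):
            pair_masses[tuple(sorted((c1, c2)))] = m1 + m2

    # edges[u] -> list of (v, segment); grouped so isobaric explanations of the
    # same peak pair become alternatives of a single segment.
    edges: dict[float, list[tuple[float, LadderSegment]]] = {p: [] for p in peaks}
    for i, upper in enumerate(peaks):
        for lower in peaks[i + 1:]:
            diff = upper - lower
            opts_1 = [
                (code, ppm_error(mass, diff))
                for code, mass in singles
                if abs(diff - mass) <= tol.window(mass)
            ]
            if opts_1:
                seg = LadderSegment(
                    upper_mz=upper,
                    lower_mz=lower,
                    options=tuple(sorted((c,) for c, _ in opts_1)),
                    ppm=min((p for _, p in opts_1), key=abs),
                )
                edges[upper].append((lower, seg))
            elif bridge_missing_peaks:
                opts_2 = [
                    (pair, ppm_error(mass, diff))
                    for pair, mass in pair_masses.items()
                    if abs(diff - mass) <= tol.window(mass)
                ]
                if opts_2:
                    seg = LadderSegment(
                        upper_mz=upper,
                        lower_mz=lower,
                        options=tuple(sorted(pair for pair, _ in opts_2)),
                        ppm=min((p for _, p in opts_2), key=abs),
                    )
                    edges[upper].append((lower, seg))

    # Longest-path DP over the (acyclic, descending-mz) spectrum graph.
    # Cost is minimized: (-residues, bridges, cum |ppm|, label tuple).
    best: dict[float, tuple[tuple, tuple[LadderSegment, ...]]] = {}
    anchor = min(peaks, key=lambda p: abs(p - anchor_mz))
    best[anchor] = ((0, 0, 0.0, ()), ())
    for u in peaks:
        if u not in best:
            continue
        (neg_res, n_bridge, cum, labels), path = best[u]
        for v, seg in edges[u]:
            cand_cost = (
                neg_res - seg.n_residues,
                n_bridge + (1 if seg.n_residues > 1 else 0),
                cum + abs(seg.ppm),
                labels + (seg.options[0],),
            )
            if v not in best or cand_cost < best[v][0]:
                best[v] = (cand_cost, path + (seg,))

    terminal, (cost, path) = min(best.items(), key=lambda kv: (kv[1][0], kv[0]))
    prefix_gap = terminal - ACETYL.monoisotopic_mass - HYDROGEN
    return LadderReading(
        anchor_mz=anchor, segments=path, terminal_mz=terminal, prefix_gap_mass=prefix_gap
    )


def complete_prefix(
    gap_mass: float,
    k_max: int = 6,
    alphabet: Alphabet | None = None,
    tol=Tolerance(10, "ppm"),
) -> list[tuple[str, ...]]:
    """Enumerate residue multisets (size <= k_max) whose masses sum to the gap.

    This is the combinatorial step that replaces the unobservable b1/b2 ions:
    exhaustive enumeration over the alphabet, returned as sorted code tuples
    ordered by |ppm| then lexicographically. Isobaric compositions (e.g.
    2 Aib + Ala vs Gly + Aib + Vxx, both C11H19N3O3) are all reported;
    collinearity constraints downstream arbitrate between them.
    """
    if gap_mass <= 0:
        raise ValueError(f"gap mass must be positive, got {gap_mass}")
    if k_max > 6:
        raise ValueError("k_max above 6 is combinatorially unsupported")
    tol = _as_tol(tol)
    alphabet = alphabet or Alphabet.default()
    codes = sorted(alphabet.residues)
    hits: list[tuple[float, tuple[str, ...]]] = []
    for k in range(1, k_max + 1):
        for combo in itertools.combinations_with_replacement(codes, k):
            total = sum(alphabet.residues[c].monoisotopic_mass for c in combo)
            if abs(gap_mass - total) <= tol.window(total):
                hits.append((abs(ppm_error(total, gap_mass)), combo))
    hits.sort(key=lambda h: (h[0], h[1]))
    return [combo for _, combo in hits]


@dataclass(frozen=True)
class SequenceCandidate:
    """A ranked full-sequence hypothesis for one spectrum."""

    sequence: PeptaibolSequence
    score: float
    matched_b_count: int
    mean_abs_ppm: float
    prefix_resolved_by: str = "unresolved"  # unique_composition | module_constraint | unresolved
    precursor_ppm: float = 0.0


def _score(matched_b: int, n_positions: int, mean_abs_ppm: float) -> float:
    """Artifact-defined score: ladder coverage damped by mass accuracy."""
    denom = max(n_positions - 2, 1)
    return (matched_b / denom) * math.exp(-mean_abs_ppm / 20.0)


def sequence_candidates(
    spec: Spectrum,
    constraints=None,
    *,
    tol_frag=0.02,
    tol_precursor=Tolerance(10, "ppm"),
    alphabet: Alphabet | None = None,
    k_max: int = 6,
    bridge_missing_peaks: bool = False,
) -> list[SequenceCandidate]:
    """Full de novo pipeline: anchor -> ladder -> prefix completion -> constraints.

    Returns candidates ranked by constraint consistency and score; never
    raises on an uninterpretable spectrum (returns an empty list). With a
    constraint set whose hard positions pin the prefix (the usual case for
    peptaibol synthetases, where modules 1-2 are phylogenetically
    unambiguous), a single candidate survives and is flagged
    ``module_constraint``; a prefix whose composition admits only one
    ordering is ``unique_composition``; remaining ties are ``unresolved``.
    """
    from .constraints import resolve_ambiguity  # local import to avoid a cycle

    tol_frag = _as_tol(tol_frag)
    tol_precursor = _as_tol(tol_precursor)
    alphabet = alphabet or Alphabet.default()
    raw: dict[str, tuple[SequenceCandidate, int]] = {}

    for cterm in resolve_cterm(spec, tol_frag, alphabet):
        reading = read_ladder(
            spec, cterm.anchor_mz, tol=tol_frag, alphabet=alphabet,
            bridge_missing_peaks=bridge_missing_peaks,
        )
        gap = reading.prefix_gap_mass
        ppms = [abs(cterm.ppm)] + [abs(seg.ppm) for seg in reading.segments]
        min_residue = min(r.monoisotopic_mass for r in alphabet.residues.values())

        if abs(gap) <= tol_frag.window(max(reading.terminal_mz, 1.0)):
            completions: list[tuple[str, ...]] = [()]
        elif gap < min_residue - tol_frag.window(min_residue):
            continue
        else:
            completions = complete_prefix(gap, k_max, alphabet, tol_frag)

        # Expand: prefix orderings x bridge-segment orderings (C->N segments reversed).
        for multiset in completions:
            prefix_orderings = sorted(set(itertools.permutations(multiset)))
            n_orderings = len(prefix_orderings)
            seg_choices = []
            for seg in reversed(reading.segments):
                alts = sorted({perm for opt in seg.options for perm in itertools.permutations(opt)})
                seg_choices.append(alts)
            for prefix in prefix_orderings:
                for picked in itertools.product(*seg_choices):
                    # picked segments run N->C after reversal; each is a residue tuple
                    body: list[str] = []
                    for chunk in picked:
                        body.extend(chunk)
                    residues = tuple(prefix) + tuple(body)
                    if not residues:
                        continue
                    seq = PeptaibolSequence(residues=residues, c_term=cterm.code, name=spec.id)
                    theo = protonated_mz(sequence_formula(seq, alphabet))
                    dev = ppm_error(theo, spec.precursor_mz)
                    if not tol_precursor.matches(theo, spec.precursor_mz):
                        continue
                    mean_ppm = sum(ppms) / len(ppms) if ppms else 0.0
                    cand = SequenceCandidate(
                        sequence=seq,
                        score=_score(reading.n_matched_b, seq.n_positions, mean_ppm),
                        matched_b_count=reading.n_matched_b,
                        mean_abs_ppm=mean_ppm,
                        prefix_resolved_by="unresolved",
                        precursor_ppm=dev,
                    )
                    key = str(seq)
                    if key not in raw or cand.score > raw[key][0].score:
                        raw[key] = (cand, n_orderings)

    ordered = sorted(raw.values(), key=lambda cr: (-cr[0].score, str(cr[0].sequence)))
    candidates = [c for c, _ in ordered]
    orderings = {str(c.sequence): n for c, n in ordered}

    final = resolve_ambiguity(candidates, constraints, alphabet=alphabet)

    has_constraints = constraints is not None and getattr(constraints, "modules", ())
    if len(final) == 1:
        only = final[0]
        if orderings.get(str(only.sequence), 2) == 1 and len(candidates) == 1:
            flag = "unique_composition"
        elif has_constraints:
            flag = "module_constraint"
        else:
            flag = "unresolved"
        final = [replace(only, prefix_resolved_by=flag)]
    return final
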