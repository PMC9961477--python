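"""End-to-end annotation: de novo + constraints + networking, tabulated.

Produces one record per input spectrum in the layout of a peptaibol
characterization table: experimental and theoretical m/z, ppm, molecular
formula, the per-position sequence of the best candidate, how its N-terminal
prefix was resolved, and the molecular-network component it belongs to.
Spectra that yield no constraint-consistent candidate still get a record,
annotated with the violations of the best unconstrained interpretation.
"""

from __future__ import annotations

import pandas as pd

from .chem import Alphabet, ppm_error, protonated_mz, sequence_formula
from .constraints import ConstraintError, ModuleConstraintSet, check_collinearity
from .denovo import sequence_candidates
from .network import NetworkParams, build_network, components
from .spectra import Spectrum, read_mgf

__all__ = ["annotate", "annotate_spectra", "write_report"]

REPORT_COLUMNS = [
    "spectrum_id",
    "experimental_mz",
    "sequence",
    "theoretical_mz",
    "ppm",
    "formula",
    "score",
    "matched_b",
    "prefix_resolved_by",
    "constraint_violations",
    "network_component",
]


def annotate_spectra(
    spectra: list[Spectrum],
    constraints: ModuleConstraintSet | None = None,
    *,
    tol_frag=0.02,
    net_params: NetworkParams = NetworkParams(),
    alphabet: Alphabet | None = None,
) -> pd.DataFrame:
    """Annotate a batch of spectra; one row per spectrum, always."""
    alphabet = alphabet or Alphabet.default()
    comp_of: dict[str, int] = {}
    if spectra:
        net = build_network(spectra, net_params)
        for idx, comp in enumerate(components(net), start=1):
            for node in comp:
                comp_of[node] = idx

    rows = []
    for spec in spectra:
        row = {col: "" for col in REPORT_COLUMNS}
        row["spectrum_id"] = spec.id
        row["experimental_mz"] = round(spec.precursor_mz, 4)
        row["network_component"] = comp_of.get(spec.id, "")

        cands = sequence_candidates(
            spec, constraints, tol_frag=tol_frag, alphabet=alphabet
        )
        violations = ""
        if not cands and constraints is not None:
            # Nothing survives the constraints: report the best unconstrained
            # reading with its violation tally instead of an empty record.
            cands = sequence_candidates(spec, None, tol_frag=tol_frag, alphabet=alphabet)
            if cands:
                try:
                    rep = check_collinearity(cands[0].sequence, constraints)
                    violations = f"hard:{rep.n_hard},soft:{rep.n_soft}"
                except ConstraintError:
                    violations = "length_mismatch"
        if cands:
            best = cands[0]
            formula = sequence_formula(best.sequence, alphabet)
            theo = protonated_mz(formula)
            row.update(
                sequence=str(best.sequence),
                theoretical_mz=round(theo, 4),
                ppm=round(ppm_error(theo, spec.precursor_mz), 2),
                formula=formula.hill(),
                score=round(best.score, 4),
                matched_b=best.matched_b_count,
                prefix_resolved_by=best.prefix_resolved_by,
                constraint_violations=violations,
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def annotate(
    mgf_path,
    constraints: ModuleConstraintSet | None = None,
    *,
    tol_frag=0.02,
    net_params: NetworkParams = NetworkParams(),
) -> pd.DataFrame:
    """Read an MGF file and annotate every spectrum in it."""
    return annotate_spectra(
        read_mgf(mgf_path), constraints, tol_frag=tol_frag, net_params=net_params
    )


def write_report(df: pd.DataFrame, path) -> None:
    """TSV output (tab-separated so sequence strings may contain anything)."""
    df.to_csv(path, sep="\t", index=False)
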