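"""NRPS module-collinearity constraints for peptaibol sequence resolution.

Nonribosomal peptide synthetases are assembly lines: module order dictates
residue order (collinearity), and phylogenetic placement of each module's
adenylation domain predicts its substrate set. Those predictions enter this
package as *constraint sets* — one allowed-residue set per module, marked
hard (high bootstrap support, binding) or soft (promiscuous, advisory) —
and are used to discard or re-rank de novo sequence candidates whose
fragment evidence alone is ambiguous.

Peptaibols shorter than the module count are handled through *module
skipping*: a monotone assignment of sequence positions to modules that
minimizes hard violations, then the number of contiguous skipped runs.

Constraint sets are plain INI-style text files ([synthetase] header plus one
[module N] section per position); two presets covering the Trichoderma
15-module (endophytin-type) and 14-module (harzianin-type) synthetases are
packaged.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .chem import Alphabet, PeptaibolSequence

__all__ = [
    "ModuleConstraint",
    "ModuleConstraintSet",
    "CollinearityReport",
    "ConstraintError",
    "load_constraints",
    "builtin_constraints",
    "check_collinearity",
    "resolve_ambiguity",
    "BUILTIN_CONSTRAINT_SETS",
]

BUILTIN_CONSTRAINT_SETS = ("endophytin_15mod", "harzianin_14mod")


class ConstraintError(ValueError):
    """Invalid constraint configuration."""


@dataclass(frozen=True)
class ModuleConstraint:
    """Allowed substrate set for one NRPS module (1-based position)."""

    position: int
    allowed: frozenset[str]
    hard: bool = False
    note: str = ""


@dataclass(frozen=True)
class ModuleConstraintSet:
    """Ordered module constraints for one synthetase, with a skip policy."""

    synthetase_name: str
    modules: tuple[ModuleConstraint, ...]
    allow_skipping: bool = False
    max_skipped_run: int = 0

    def __post_init__(self):
        positions = [m.position for m in self.modules]
        if positions != list(range(1, len(self.modules) + 1)):
            raise ConstraintError(
                f"{self.synthetase_name}: module positions must be contiguous 1..m, got {positions}"
            )
        for m in self.modules:
            if not m.allowed:
                raise ConstraintError(f"{self.synthetase_name}: module {m.position} allows nothing")

    def validate_against(self, alphabet: Alphabet) -> None:
        """Check codes resolve and the terminal module holds only amino alcohols."""
        if not self.modules:
            raise ConstraintError(f"{self.synthetase_name}: no modules defined")
        *body, terminal = self.modules
        for m in body:
            unknown = m.allowed - set(alphabet.residues)
            if unknown:
                raise ConstraintError(
                    f"{self.synthetase_name}: module {m.position} has non-residue codes {sorted(unknown)}"
                )
        if not terminal.allowed <= set(alphabet.amino_alcohols):
            raise ConstraintError(
                f"{self.synthetase_name}: terminal module {terminal.position} must allow only "
                f"amino-alcohol codes, got {sorted(terminal.allowed)}"
            )

    def __len__(self) -> int:
        return len(self.modules)


def load_constraints(path, alphabet: Alphabet | None = None) -> ModuleConstraintSet:
    """Load and validate a constraint set from an INI-style config file.

    Layout::

        [synthetase]
        name = endophytin_15mod
        allow_skipping = false
        max_skipped_run = 0

        [module 1]
        allowed = Aib
        hard = true
        note = Aib clade, 100% bootstrap
    """
    parser = configparser.ConfigParser(interpolation=None)
    read = parser.read(str(path))
    if not read:
        raise ConstraintError(f"cannot read constraint config {path}")
    if "synthetase" not in parser:
        raise ConstraintError(f"{path}: missing [synthetase] section")
    head = parser["synthetase"]
    name = head.get("name", Path(str(path)).stem)
    allow_skipping = head.getboolean("allow_skipping", fallback=False)
    max_skipped_run = head.getint("max_skipped_run", fallback=0)

    modules: dict[int, ModuleConstraint] = {}
    for section in parser.sections():
        if not section.startswith("module"):
            continue
        try:
            position = int(section.split()[1])
        except (IndexError, ValueError):
            raise ConstraintError(f"{path}: bad module section name [{section}]") from None
        allowed = frozenset(
            code.strip() for code in parser[section].get("allowed", "").split(",") if code.strip()
        )
        modules[position] = ModuleConstraint(
            position=position,
            allowed=allowed,
            hard=parser[section].getboolean("hard", fallback=False),
            note=parser[section].get("note", ""),
        )
    ordered = tuple(modules[p] for p in sorted(modules))
    missing = set(range(1, (max(modules) if modules else 0) + 1)) - set(modules)
    if missing:
        raise ConstraintError(f"{path}: missing module positions {sorted(missing)}")
    cset = ModuleConstraintSet(
        synthetase_name=name,
        modules=ordered,
        allow_skipping=allow_skipping,
        max_skipped_run=max_skipped_run,
    )
    cset.validate_against(alphabet or Alphabet.default())
    return cset


def builtin_constraints(name: str, alphabet: Alphabet | None = None) -> ModuleConstraintSet:
    """Load one of the packaged presets ('endophytin_15mod', 'harzianin_14mod')."""
    if name not in BUILTIN_CONSTRAINT_SETS:
        raise ConstraintError(f"unknown builtin constraint set {name!r}; have {BUILTIN_CONSTRAINT_SETS}")
    ref = resources.files("peptaibolkit.data").joinpath(f"constraints/{name}.cfg")
    with resources.as_file(ref) as path:
        return load_constraints(path, alphabet)


@dataclass(frozen=True)
class CollinearityReport:
    """Position-wise outcome of aligning a sequence against a module set."""

    statuses: tuple[str, ...]  # per sequence position: consistent | soft | hard
    module_mapping: tuple[int, ...]  # module position assigned to each sequence position
    skipped_modules: tuple[int, ...]
    n_hard: int
    n_soft: int
    n_skipped_runs: int

    @property
    def consistent(self) -> bool:
        return self.n_hard == 0


def _positions(s: PeptaibolSequence) -> list[str]:
    return list(s.residues) + [s.c_term]


def _status(code: str, module: ModuleConstraint) -> str:
    if code in module.allowed:
        return "consistent"
    return "hard" if module.hard else "soft"


def check_collinearity(s: PeptaibolSequence, c: ModuleConstraintSet) -> CollinearityReport:
    """Align sequence positions to modules and tally constraint violations.

    Equal lengths give a direct position-wise comparison. A shorter sequence
    (module skipping) is aligned by dynamic programming over monotone
    assignments, minimizing (hard violations, skipped runs, soft violations)
    with lexicographically smallest mapping on ties; ``max_skipped_run``
    (0 = unlimited) caps the length of each contiguous skipped block.
    """
    seq = _positions(s)
    n, m = len(seq), len(c.modules)
    if n > m:
        raise ConstraintError(
            f"sequence has {n} positions but {c.synthetase_name} has only {m} modules"
        )
    if n < m and not c.allow_skipping:
        raise ConstraintError(
            f"sequence has {n} positions for {m} modules and {c.synthetase_name} forbids skipping"
        )

    if n == m:
        statuses = tuple(_status(code, mod) for code, mod in zip(seq, c.modules))
        return CollinearityReport(
            statuses=statuses,
            module_mapping=tuple(range(1, m + 1)),
            skipped_modules=(),
            n_hard=statuses.count("hard"),
            n_soft=statuses.count("soft"),
            n_skipped_runs=0,
        )

    max_run = c.max_skipped_run if c.max_skipped_run > 0 else m
    # DP state: (residues placed, current skipped-run length) after each module.
    # Value: ((hard, runs, soft, mapping) ...) minimized lexicographically.
    start = {(0, 0): (0, 0, 0, ())}
    for j, module in enumerate(c.modules):
        nxt: dict[tuple[int, int], tuple] = {}

        def offer(state, value):
            if state not in nxt or value < nxt[state]:
                nxt[state] = value

        for (i, run), (hard, runs, soft, mapping) in start.items():
            # skip module j+1
            if run + 1 <= max_run:
                offer((i, run + 1), (hard, runs + (1 if run == 0 else 0), soft, mapping))
            # assign sequence position i to module j+1
            if i < n:
                st = _status(seq[i], module)
                offer(
                    (i + 1, 0),
                    (
                        hard + (st == "hard"),
                        runs,
                        soft + (st == "soft"),
                        mapping + (j + 1,),
                    ),
                )
        start = nxt

    finals = [v for (i, _run), v in start.items() if i == n]
    if not finals:
        raise ConstraintError(
            f"no feasible alignment of {n} positions onto {m} modules with max run {max_run}"
        )
    hard, runs, soft, mapping = min(finals)
    assigned = set(mapping)
    skipped = tuple(p for p in range(1, m + 1) if p not in assigned)
    statuses = tuple(_status(code, c.modules[mp - 1]) for code, mp in zip(seq, mapping))
    return CollinearityReport(
        statuses=statuses,
        module_mapping=mapping,
        skipped_modules=skipped,
        n_hard=hard,
        n_soft=soft,
        n_skipped_runs=runs,
    )


def resolve_ambiguity(candidates, c: ModuleConstraintSet | None, alphabet: Alphabet | None = None):
    """Filter and re-rank sequence candidates by collinearity.

    Candidates with hard violations (or that cannot be aligned at all) are
    dropped; survivors are stably re-ranked by fewest soft violations,
    preserving the incoming (score) order among ties. With no constraint set
    the input is returned unchanged.
    """
    if c is None or not c.modules:
        return list(candidates)
    kept: list[tuple[int, object]] = []
    for cand in candidates:
        try:
            report = check_collinearity(cand.sequence, c)
        except ConstraintError:
            continue
        if report.n_hard:
            continue
        kept.append((report.n_soft, cand))
    kept.sort(key=lambda pair: pair[0])  # stable: ties keep input order
    return [cand for _, cand in kept]
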