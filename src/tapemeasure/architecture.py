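"""Reference layout of a tape-measure protein and the per-repeat length solver.

The TP901-1-like tape measure protein (TMP) studied here is 937 residues
long.  Its annotated landmarks, in 1-based inclusive coordinates throughout:

* an N-terminal essential region (1-154),
* a first hydrophobic region I390-Y460 with three membrane-spanning
  sub-spans (Tm1-Tm3),
* a second hydrophobic region F591-V679 with three sub-spans (Tm4-Tm6),
* a cytoplasmic loop between the two hydrophobic regions (461-590),
* a region of 29 tandem aromatic-anchored repeats, each 11 or 18 residues
  long, totalling 347 residues and starting immediately after the first
  hydrophobic region (461-807); the second hydrophobic region overlaps it,
* a C-terminal essential region covering the last 60 residues (878-937).

The individual repeat lengths are never stated directly; they are pinned
down by the sizes of an incremental deletion series (numbers of residues
removed when repeats 1-2, 1-3, ... 1-29 and various internal windows are
deleted).  :func:`solve_repeat_lengths` recovers every assignment of
``{11, 18}`` to the 29 repeats consistent with such a table, and
:func:`build_reference_architecture` selects one deterministically.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

import pandas as pd

from .grammar import RepeatRange, parse_spec_text

__all__ = [
    "RepeatAssignment",
    "DeletionConstraint",
    "HydrophobicRegion",
    "TMPArchitecture",
    "UNCONSTRAINED",
    "Unconstrained",
    "solve_repeat_lengths",
    "select_reference_assignment",
    "reference_constraints",
    "build_reference_architecture",
    "REFERENCE_TOTAL_LENGTH",
]

#: Reference layout constants (see module docstring for provenance).
REFERENCE_TOTAL_LENGTH = 937
REFERENCE_NTERM = (1, 154)
REFERENCE_CTERM = (878, 937)
REFERENCE_HR1 = (390, 460)
REFERENCE_HR1_TM = ((390, 417), (418, 441), (442, 460))
REFERENCE_HR2 = (591, 679)
#: Tm4 ends at 613 (fixed by its deletion size of 23 aa); the 614-679 split
#: between Tm5 and Tm6 is not constrained by any deletion row and the even
#: split is an explicit convention.
REFERENCE_HR2_TM = ((591, 613), (614, 646), (647, 679))
REFERENCE_LOOP = (461, 590)
REFERENCE_REPEAT_REGION_START = 461
N_REPEATS = 29
ALLOWED_REPEAT_LENGTHS = (11, 18)


@dataclass(frozen=True)
class RepeatAssignment:
    """An ordered assignment of lengths to the tandem repeats.

    ``anchor_rule`` maps a repeat length to the aromatic residue(s) that may
    open a repeat of that length: 18-mers always start with Trp, 11-mers with
    Trp or Phe.
    """

    lengths: tuple[int, ...]
    anchor_rule: dict[int, str] = field(
        default_factory=lambda: {18: "W", 11: "WF"}, compare=False
    )

    def __post_init__(self) -> None:
        bad = [x for x in self.lengths if x not in ALLOWED_REPEAT_LENGTHS]
        if bad:
            raise ValueError(f"repeat lengths must be 11 or 18, got {sorted(set(bad))}")

    @property
    def n_repeats(self) -> int:
        return len(self.lengths)

    @property
    def total(self) -> int:
        return sum(self.lengths)

    def count(self, length: int) -> int:
        return self.lengths.count(length)

    def span_sum(self, from_idx: int, to_idx: int) -> int:
        """Sum of repeat lengths over 1-based inclusive repeat indices."""
        if not (1 <= from_idx <= to_idx <= self.n_repeats):
            raise ValueError(f"repeat indices {from_idx}..{to_idx} out of range")
        return sum(self.lengths[from_idx - 1 : to_idx])


@dataclass(frozen=True)
class DeletionConstraint:
    """One row of the deletion-size table, as a constraint on repeat lengths.

    Deleting repeats ``repeat_from..repeat_to`` entirely, plus either the
    first ``extra_residues`` residues of repeat ``repeat_to + 1`` or (if
    ``half``) the first ``floor(len/2)`` residues of it, removed
    ``observed_size`` residues in total.
    """

    repeat_from: int
    repeat_to: int
    observed_size: int
    extra_residues: int = 0
    half: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.repeat_from <= self.repeat_to):
            raise ValueError(f"invalid repeat range {self.repeat_from}..{self.repeat_to}")
        if self.observed_size <= 0:
            raise ValueError("observed_size must be positive")
        if self.extra_residues < 0 or (self.extra_residues and self.half):
            raise ValueError("use either extra_residues or half, not both")

    @property
    def max_index(self) -> int:
        """Largest 1-based repeat index the constraint touches."""
        return self.repeat_to + (1 if (self.half or self.extra_residues) else 0)


class Unconstrained:
    """Sentinel: every assignment is admissible (empty constraint list)."""

    def __repr__(self) -> str:  # pragma: no cover
        return "UNCONSTRAINED"


UNCONSTRAINED = Unconstrained()


def solve_repeat_lengths(
    constraints,
    n_repeats: int = N_REPEATS,
    allowed_lengths: tuple[int, ...] = ALLOWED_REPEAT_LENGTHS,
    max_solutions: int = 1_000_000,
):
    """Enumerate all repeat-length assignments satisfying the constraints.

    Returns a tuple of :class:`RepeatAssignment` in lexicographic order of
    their length tuples (deterministic); an empty tuple signals an
    inconsistent constraint set.  An *empty* constraint list returns the
    :data:`UNCONSTRAINED` sentinel instead of enumerating ``2**n`` tuples.

    A branch-and-bound search assigns repeats left to right; each constraint
    is checked as soon as every repeat it touches is assigned, and partial
    sums are bounded by the extreme admissible lengths to prune early.
    """
    constraints = list(constraints)
    if not constraints:
        return UNCONSTRAINED
    for c in constraints:
        if c.max_index > n_repeats:
            raise ValueError(
                f"constraint {c.name or c} references repeat {c.max_index} > {n_repeats}"
            )
    lo, hi = min(allowed_lengths), max(allowed_lengths)
    order = sorted(allowed_lengths)

    def value(c: DeletionConstraint, assign: list[int]) -> int:
        total = sum(assign[c.repeat_from - 1 : c.repeat_to])
        if c.half:
            total += assign[c.repeat_to] // 2
        elif c.extra_residues:
            total += c.extra_residues
        return total

    # Static feasibility of "+k" against the largest admissible repeat length.
    for c in constraints:
        if c.extra_residues > hi:
            return ()

    by_close_index: dict[int, list[DeletionConstraint]] = {}
    for c in constraints:
        by_close_index.setdefault(c.max_index - 1, []).append(c)

    solutions: list[RepeatAssignment] = []
    assign: list[int] = []

    def bounds_ok(depth: int) -> bool:
        # depth = number of assigned repeats; prune on every open constraint
        for c in constraints:
            if c.max_index - 1 < depth:
                continue
            a, b = c.repeat_from - 1, c.repeat_to  # half-open over full repeats
            done = sum(assign[a:depth] if a < depth else [])
            n_open = max(0, b - max(a, depth))
            lo_sum = done + n_open * lo
            hi_sum = done + n_open * hi
            if c.half:
                if c.repeat_to < depth:
                    lo_sum += assign[c.repeat_to] // 2
                    hi_sum += assign[c.repeat_to] // 2
                else:
                    lo_sum += lo // 2
                    hi_sum += hi // 2
            elif c.extra_residues:
                lo_sum += c.extra_residues
                hi_sum += c.extra_residues
                if c.repeat_to < depth and c.extra_residues > assign[c.repeat_to]:
                    return False
            if not (lo_sum <= c.observed_size <= hi_sum):
                return False
        return True

    def closed_ok(depth: int) -> bool:
        for c in by_close_index.get(depth - 1, []):
            if value(c, assign) != c.observed_size:
                return False
            if c.extra_residues and c.extra_residues > assign[c.repeat_to]:
                return False
        return True

    def recurse() -> None:
        depth = len(assign)
        if depth == n_repeats:
            solutions.append(RepeatAssignment(tuple(assign)))
            if len(solutions) > max_solutions:
                raise RuntimeError(f"more than {max_solutions} admissible assignments")
            return
        for length in order:
            assign.append(length)
            if closed_ok(depth + 1) and bounds_ok(depth + 1):
                recurse()
            assign.pop()

    recurse()
    return tuple(solutions)


def select_reference_assignment(solutions) -> RepeatAssignment:
    """Deterministic tie-break: place the 18-mers as early as the constraints
    allow (lexicographically smallest list of 18-mer indices)."""
    if solutions is UNCONSTRAINED or not solutions:
        raise ValueError("no assignment to select from")
    def key(a: RepeatAssignment):
        return tuple(i for i, x in enumerate(a.lengths) if x == 18)
    return min(solutions, key=key)


@lru_cache(maxsize=None)
def _fixture_frame(name: str) -> pd.DataFrame:
    path = importlib.resources.files("tapemeasure.data") / name
    with importlib.resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", dtype={"name": str, "spec": str}, keep_default_na=False)


def reference_constraints(exclude: tuple[str, ...] = ()) -> tuple[DeletionConstraint, ...]:
    """The packaged deletion-size constraints from the two mutant tables.

    Only rows whose specification is a single repeat range (possibly with a
    ``+k``/``+half`` suffix) constrain the solver directly; combination rows
    (e.g. repeats 1-9 plus 20-26) are checked downstream via mutant
    accounting instead.  ``exclude`` drops rows by mutant name.
    """
    out = []
    for table in ("table1.tsv", "table2.tsv"):
        df = _fixture_frame(table)
        for _, row in df.iterrows():
            if row["name"] in exclude:
                continue
            comps = parse_spec_text(row["spec"])
            if len(comps) != 1 or not isinstance(comps[0], RepeatRange):
                continue
            if row["aa_deleted"] in ("", "NA"):
                continue
            c = comps[0]
            out.append(
                DeletionConstraint(
                    repeat_from=c.from_idx,
                    repeat_to=c.to_idx,
                    observed_size=int(row["aa_deleted"]),
                    extra_residues=c.extra,
                    half=c.half,
                    name=row["name"],
                )
            )
    return tuple(out)


@dataclass(frozen=True)
class HydrophobicRegion:
    """A hydrophobic region and its membrane-spanning sub-spans, all in
    1-based inclusive coordinates; sub-spans tile the region contiguously."""

    start: int
    end: int
    tm_spans: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must not exceed end")
        expected = self.start
        for s, e in self.tm_spans:
            if s != expected or e < s:
                raise ValueError("Tm sub-spans must tile the region contiguously")
            expected = e + 1
        if expected != self.end + 1:
            raise ValueError("Tm sub-spans must cover the region exactly")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TMPArchitecture:
    """Full positional layout of a TMP-like protein.

    Note that the repeat region deliberately overlaps the second hydrophobic
    region: the repeats run without interruption from the end of the first
    hydrophobic region to the start of the C-terminal deletions, straight
    through the second hydrophobic stretch.
    """

    total_length: int
    nterm_essential: tuple[int, int]
    hydrophobic_region_1: HydrophobicRegion
    hydrophobic_region_2: HydrophobicRegion
    cytoplasmic_loop: tuple[int, int]
    repeat_region: tuple[int, int]
    repeats: RepeatAssignment
    cterm_essential: tuple[int, int]

    def __post_init__(self) -> None:
        spans = [
            self.nterm_essential,
            (self.hydrophobic_region_1.start, self.hydrophobic_region_1.end),
            (self.hydrophobic_region_2.start, self.hydrophobic_region_2.end),
            self.cytoplasmic_loop,
            self.repeat_region,
            self.cterm_essential,
        ]
        for s, e in spans:
            if not (1 <= s <= e <= self.total_length):
                raise ValueError(f"span {s}-{e} outside [1, {self.total_length}]")
        if self.hydrophobic_region_1.end >= self.hydrophobic_region_2.start:
            raise ValueError("hydrophobic regions must be ordered and disjoint")
        region_len = self.repeat_region[1] - self.repeat_region[0] + 1
        if self.repeats.total != region_len:
            raise ValueError(
                f"repeat lengths sum to {self.repeats.total}, "
                f"but the repeat region holds {region_len} residues"
            )

    @property
    def n_repeats(self) -> int:
        return self.repeats.n_repeats

    def repeat_spans(self) -> tuple[tuple[int, int], ...]:
        """1-based inclusive span of every repeat, tiling the repeat region."""
        spans = []
        pos = self.repeat_region[0]
        for length in self.repeats.lengths:
            spans.append((pos, pos + length - 1))
            pos += length
        return tuple(spans)

    def tm_spans(self) -> tuple[tuple[int, int], ...]:
        """All membrane-spanning sub-spans, numbered 1..6 across both regions."""
        return self.hydrophobic_region_1.tm_spans + self.hydrophobic_region_2.tm_spans

    def repeat_anchor_positions(self) -> tuple[int, ...]:
        return tuple(s for s, _ in self.repeat_spans())


def build_reference_architecture(
    assignment: RepeatAssignment | None = None,
    repeat_region_start: int = REFERENCE_REPEAT_REGION_START,
) -> TMPArchitecture:
    """The TP901-1-like reference layout.

    If no assignment is given, the packaged deletion tables are solved and
    the reference assignment selected (18-mers as early as allowed).  The
    repeat-region start is exposed because the source data never prints
    repeat coordinates; 461 follows from the repeats starting immediately
    after the first hydrophobic region.
    """
    if assignment is None:
        assignment = select_reference_assignment(
            solve_repeat_lengths(reference_constraints())
        )
    region = (repeat_region_start, repeat_region_start + assignment.total - 1)
    return TMPArchitecture(
        total_length=REFERENCE_TOTAL_LENGTH,
        nterm_essential=REFERENCE_NTERM,
        hydrophobic_region_1=HydrophobicRegion(*REFERENCE_HR1, REFERENCE_HR1_TM),
        hydrophobic_region_2=HydrophobicRegion(*REFERENCE_HR2, REFERENCE_HR2_TM),
        cytoplasmic_loop=REFERENCE_LOOP,
        repeat_region=region,
        repeats=assignment,
        cterm_essential=REFERENCE_CTERM,
    )
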