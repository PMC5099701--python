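"""Construction and accounting of in-frame TMP deletion/replacement mutants.

A mutant is specified in the text grammar of :mod:`tapemeasure.grammar`
(repeat ranges, residue ranges, membrane-span ranges, whole-repeat
replacements), resolved against a concrete architecture into edit
intervals, and can then be applied to a sequence (with coordinate liftover
of the annotation), accounted (residues removed net of insertions), and
realised as a recombineering oligonucleotide on a back-translated CDS.

The packaged phenotype tables (efficiency of plaquing, lysogeny frequency,
electron-microscopy tail lengths) load into :class:`MutantRecord` rows;
``<=`` bounds in the source tables are kept as censored values, never
converted to point estimates.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .architecture import TMPArchitecture
from .grammar import (
    Component,
    Replacement,
    RepeatRange,
    ResidueRange,
    TmRange,
    parse_spec_text,
)
from .io import Feature, SequenceAnnotation

__all__ = [
    "Edit",
    "MutantSpec",
    "MutantRecord",
    "OligoParams",
    "OligoDesign",
    "MutantApplication",
    "EssentialAudit",
    "parse_mutant",
    "aa_deleted",
    "apply_mutant",
    "back_translate",
    "design_recombineering_oligo",
    "load_mutant_table",
    "load_packaged_table",
    "verify_table_accounting",
    "audit_essential_elements",
]


@dataclass(frozen=True)
class Edit:
    """One resolved edit: delete the inclusive interval, insert
    ``replacement`` (empty for a pure deletion)."""

    start: int
    end: int
    replacement: str = ""

    @property
    def net_removed(self) -> int:
        return (self.end - self.start + 1) - len(self.replacement)


@dataclass(frozen=True)
class MutantSpec:
    """A named mutant, fully resolved against an architecture."""

    name: str
    components: tuple[Component, ...]
    edits: tuple[Edit, ...]

    @property
    def is_identity(self) -> bool:
        return not self.edits


def _resolve_repeat_range(c: RepeatRange, arch: TMPArchitecture) -> Edit:
    spans = arch.repeat_spans()
    if c.to_idx > len(spans):
        raise ValueError(f"repeat index {c.to_idx} exceeds {len(spans)} repeats")
    start = spans[c.from_idx - 1][0]
    end = spans[c.to_idx - 1][1]
    if c.half or c.extra:
        if c.to_idx + 1 > len(spans):
            raise ValueError(
                f"repeat range {c.from_idx}..{c.to_idx} extends into repeat "
                f"{c.to_idx + 1}, which does not exist"
            )
        next_len = arch.repeats.lengths[c.to_idx]
        extra = next_len // 2 if c.half else c.extra
        if extra > next_len:
            raise ValueError(
                f"+{extra} exceeds the {next_len}-residue repeat {c.to_idx + 1}"
            )
        end += extra
    return Edit(start, end)


def _resolve_tm_range(c: TmRange, arch: TMPArchitecture) -> list[Edit]:
    spans = arch.tm_spans()
    if c.to_tm > len(spans):
        raise ValueError(f"tm index {c.to_tm} exceeds {len(spans)} membrane spans")
    # Union of the named sub-span intervals, merging abutting ones.  The two
    # hydrophobic regions are disjoint, so e.g. tm1..6 yields two intervals
    # (the table's 160 aa = 71 + 89, not the 290-residue bounding interval).
    edits: list[Edit] = []
    for s, e in spans[c.from_tm - 1 : c.to_tm]:
        if edits and s == edits[-1].end + 1:
            edits[-1] = Edit(edits[-1].start, e)
        else:
            edits.append(Edit(s, e))
    return edits


def parse_mutant(
    spec, arch: TMPArchitecture, name: str = ""
) -> MutantSpec:
    """Resolve a specification (grammar text or pre-parsed components)
    against an architecture.

    Components must not overlap on the reference coordinate map; an empty
    specification is the identity mutant.
    """
    components = parse_spec_text(spec) if isinstance(spec, str) else tuple(spec)
    edits: list[Edit] = []
    for c in components:
        if isinstance(c, RepeatRange):
            edits.append(_resolve_repeat_range(c, arch))
        elif isinstance(c, ResidueRange):
            if c.end > arch.total_length:
                raise ValueError(f"residue {c.end} exceeds length {arch.total_length}")
            edits.append(Edit(c.start, c.end))
        elif isinstance(c, TmRange):
            edits.extend(_resolve_tm_range(c, arch))
        elif isinstance(c, Replacement):
            spans = arch.repeat_spans()
            if c.repeat_idx > len(spans):
                raise ValueError(f"repeat index {c.repeat_idx} out of range")
            s, e = spans[c.repeat_idx - 1]
            edits.append(Edit(s, e, c.insert_residues))
        else:  # pragma: no cover
            raise TypeError(f"unknown component {c!r}")
    edits.sort(key=lambda ed: ed.start)
    for a, b in zip(edits, edits[1:]):
        if b.start <= a.end:
            raise ValueError(
                f"overlapping components: {a.start}-{a.end} and {b.start}-{b.end}"
            )
    return MutantSpec(name=name, components=components, edits=tuple(edits))


def aa_deleted(spec: MutantSpec, arch: TMPArchitecture | None = None) -> int:
    """Net residues removed (insertions subtracted)."""
    return sum(e.net_removed for e in spec.edits)


@dataclass
class MutantApplication:
    """Result of applying a mutant: edited sequence plus lifted annotation.

    Features fully removed by the edits are dropped from the annotation and
    listed in ``destroyed``; partially removed features are truncated to
    their surviving residues and listed in ``truncated``."""

    sequence: str
    annotation: SequenceAnnotation
    destroyed: list[str]
    truncated: list[str]


def apply_mutant(
    sequence: str, annotation: SequenceAnnotation, spec: MutantSpec
) -> MutantApplication:
    """Apply the resolved edits to a sequence and lift the annotation."""
    n = len(sequence)
    if spec.edits and spec.edits[0].start == 1:
        raise ValueError("edits may not remove the initiator residue at position 1")
    if spec.edits and spec.edits[-1].end > n:
        raise ValueError(f"edit beyond sequence end ({spec.edits[-1].end} > {n})")

    pieces: list[str] = []
    cursor = 1
    for e in spec.edits:
        pieces.append(sequence[cursor - 1 : e.start - 1])
        pieces.append(e.replacement)
        cursor = e.end + 1
    pieces.append(sequence[cursor - 1 :])
    new_seq = "".join(pieces)

    def lift(p: int) -> int | None:
        """New 1-based coordinate of original position p (None if removed)."""
        offset = 0
        for e in spec.edits:
            if p < e.start:
                break
            if p <= e.end:
                return None
            offset += len(e.replacement) - (e.end - e.start + 1)
        return p + offset

    destroyed: list[str] = []
    truncated: list[str] = []
    lifted: list[Feature] = []
    for f in annotation.features:
        retained = [p for p in (lift(q) for q in range(f.start, f.end + 1))
                    if p is not None]
        if not retained:
            destroyed.append(f.feature_id)
            continue
        status = "intact" if len(retained) == f.length else "truncated"
        if status == "truncated":
            truncated.append(f.feature_id)
        lifted.append(
            Feature(f.type, retained[0], retained[-1], f.feature_id,
                    {**f.attributes, "status": status})
        )
    new_annotation = SequenceAnnotation(
        sequence_id=annotation.sequence_id + (f"|{spec.name}" if spec.name else "|mutant"),
        length=len(new_seq),
        features=lifted,
    )
    return MutantApplication(new_seq, new_annotation, destroyed, truncated)


# One fixed codon per residue for back-translation (common Escherichia coli
# codons); oligo design needs a deterministic CDS, not a codon-usage model.
CODON_TABLE = {
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "TCT", "T": "ACC", "V": "GTT", "W": "TGG", "Y": "TAT",
}


def back_translate(protein: str) -> str:
    """Deterministic CDS for a protein (one documented codon per residue)."""
    try:
        return "".join(CODON_TABLE[aa.upper()] for aa in protein)
    except KeyError as exc:
        raise ValueError(f"cannot back-translate residue {exc.args[0]!r}") from None


@dataclass(frozen=True)
class OligoParams:
    """Recombineering-oligo design parameters.

    Homology arms of 40-45 nt flank the deletion; the oligo is written on
    the coding strand by fixed convention.  Set ``validate=False`` to allow
    arm lengths outside the standard window.
    """

    arm_length: int = 45
    strand: str = "coding"
    validate: bool = True

    def __post_init__(self) -> None:
        if self.validate and not (40 <= self.arm_length <= 45):
            raise ValueError("arm_length outside the standard 40-45 nt window")
        if self.arm_length < 1:
            raise ValueError("arm_length must be positive")


@dataclass(frozen=True)
class OligoDesign:
    oligo: str
    left_arm: str
    right_arm: str
    deleted_nt: tuple[int, int]
    left_truncated: bool
    right_truncated: bool


def design_recombineering_oligo(
    cds: str, spec: MutantSpec, params: OligoParams | None = None
) -> OligoDesign:
    """Oligo deleting (or replacing) the spec's single contiguous interval.

    The protein interval maps to codons ``3*(start-1)+1 .. 3*end`` of the
    CDS; the oligo concatenates the homology arm immediately 5' of the
    deletion, any back-translated replacement, and the arm immediately 3'.
    Arms hitting a CDS end are truncated with a warning.
    """
    params = params or OligoParams()
    if len(spec.edits) != 1:
        raise ValueError(
            f"oligo design needs one contiguous interval; {spec.name or 'spec'} "
            f"resolves to {len(spec.edits)} intervals"
        )
    edit = spec.edits[0]
    d_start, d_end = 3 * (edit.start - 1) + 1, 3 * edit.end
    if d_end > len(cds):
        raise ValueError("deletion extends past the CDS end")
    left_from = d_start - 1 - params.arm_length
    left = cds[max(0, left_from) : d_start - 1]
    right = cds[d_end : d_end + params.arm_length]
    left_short = len(left) < params.arm_length
    right_short = len(right) < params.arm_length
    if left_short or right_short:
        warnings.warn(
            f"deletion {d_start}-{d_end} too close to a CDS end: "
            f"arms {len(left)}/{len(right)} nt", stacklevel=2,
        )
    insert = back_translate(edit.replacement) if edit.replacement else ""
    return OligoDesign(
        oligo=left + insert + right,
        left_arm=left,
        right_arm=right,
        deleted_nt=(d_start, d_end),
        left_truncated=left_short,
        right_truncated=right_short,
    )


@dataclass(frozen=True)
class MutantRecord:
    """One phenotype-table row.  ``None`` marks cells the source leaves
    empty; ``*_censored`` marks values printed as upper bounds (<=)."""

    name: str
    spec_text: str
    aa_deleted: int | None = None
    tail_length_nm: float | None = None
    tail_note: str = ""
    eop: float | None = None
    eop_censored: bool = False
    plaque_morphology: str = ""
    lysogeny_frequency: float | None = None
    lysogeny_censored: bool = False
    fl_with_tails: float | None = None
    morphology: str = ""
    reduced_plaque: bool = False
    convention_note: str = ""

    def __post_init__(self) -> None:
        if self.aa_deleted is not None and self.aa_deleted < 0:
            raise ValueError("aa_deleted must be >= 0")
        for label, value in (("lysogeny_frequency", self.lysogeny_frequency),
                             ("fl_with_tails", self.fl_with_tails)):
            if value is not None and not (0 <= value <= 1):
                raise ValueError(f"{label} must lie in [0, 1]")

    @property
    def residue_count(self) -> int | None:
        """Mutant TMP size given the 937-residue reference (net of edits)."""
        from .architecture import REFERENCE_TOTAL_LENGTH

        if self.aa_deleted is None:
            return None
        return REFERENCE_TOTAL_LENGTH - self.aa_deleted


def _cell(row, column: str, caster, label: str):
    raw = str(row.get(column, "")).strip()
    if raw in ("", "NA", "ND", "nan"):
        return None
    try:
        return caster(raw)
    except ValueError:
        raise ValueError(f"malformed value {raw!r} in column {column} of row {label}")


def load_mutant_table(path) -> list[MutantRecord]:
    """Load a phenotype TSV (either packaged table schema) into records."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    required = {"name", "spec", "aa_deleted"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        label = row["name"]
        records.append(
            MutantRecord(
                name=label,
                spec_text=row["spec"],
                aa_deleted=_cell(row, "aa_deleted", int, label),
                tail_length_nm=_cell(row, "tail_length_nm", float, label),
                tail_note=str(row.get("tail_note", "") or ""),
                eop=_cell(row, "eop", float, label),
                eop_censored=str(row.get("eop_censored", "")).strip() == "True",
                plaque_morphology=str(row.get("plaque_morphology", "") or ""),
                lysogeny_frequency=_cell(row, "lysogeny_frequency", float, label),
                lysogeny_censored=str(row.get("lysogeny_censored", "")).strip() == "True",
                fl_with_tails=_cell(row, "fl_with_tails", float, label),
                morphology=str(row.get("phage_morphology", "") or ""),
                reduced_plaque=str(row.get("reduced_plaque", "")).strip() == "True",
                convention_note=str(row.get("convention_note", "") or ""),
            )
        )
    return records


def load_packaged_table(which: int) -> list[MutantRecord]:
    """Load packaged phenotype table 1 or 2."""
    name = {1: "table1.tsv", 2: "table2.tsv"}[which]
    path = importlib.resources.files("tapemeasure.data") / name
    with importlib.resources.as_file(path) as p:
        return load_mutant_table(p)


def verify_table_accounting(
    records: list[MutantRecord], arch: TMPArchitecture
) -> pd.DataFrame:
    """Recompute residues removed for every record and compare with the
    printed value.

    Rows carrying a convention note (the two ranges whose printed size is
    one short of the inclusive count, i.e. whose first named residue is
    retained at the junction) are flagged, never silently corrected.
    """
    rows = []
    for r in records:
        spec = parse_mutant(r.spec_text, arch, name=r.name)
        computed = aa_deleted(spec)
        rows.append({
            "name": r.name,
            "printed": r.aa_deleted,
            "computed": computed,
            "matches": r.aa_deleted is not None and computed == r.aa_deleted,
            "convention_note": r.convention_note,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EssentialAudit:
    """Descriptive audit of the minimal infectivity requirements: which
    essential elements a mutant keeps intact.  No phenotype is predicted."""

    name: str
    nterm_intact: bool
    cterm_intact: bool
    hydrophobic_region_1_intact: bool
    repeats_lost: tuple[int, ...]
    repeats_truncated: tuple[int, ...]


def audit_essential_elements(spec: MutantSpec, arch: TMPArchitecture) -> EssentialAudit:
    def disturbed(span: tuple[int, int]) -> bool:
        s, e = span
        return any(ed.start <= e and ed.end >= s for ed in spec.edits)

    lost, cut = [], []
    for i, span in enumerate(arch.repeat_spans(), 1):
        covered = sum(
            max(0, min(ed.end, span[1]) - max(ed.start, span[0]) + 1)
            for ed in spec.edits
        )
        if covered == span[1] - span[0] + 1:
            lost.append(i)
        elif covered:
            cut.append(i)
    hr1 = arch.hydrophobic_region_1
    return EssentialAudit(
        name=spec.name,
        nterm_intact=not disturbed(arch.nterm_essential),
        cterm_intact=not disturbed(arch.cterm_essential),
        hydrophobic_region_1_intact=not disturbed((hr1.start, hr1.end)),
        repeats_lost=tuple(lost),
        repeats_truncated=tuple(cut),
    )
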