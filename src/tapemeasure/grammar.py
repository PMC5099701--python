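"""Text grammar for mutant specifications.

A mutant specification is a ``;``-separated list of components:

``R<a>..<b>``            delete repeats *a* through *b* (1-based, inclusive)
``R<a>..<b>+<k>``        additionally delete the first *k* residues of repeat *b*+1
``R<a>..<b>+half``       additionally delete the first ``floor(len/2)`` residues
                         of repeat *b*+1
``res<start>..<end>``    delete the inclusive residue range
``tm<a>..<b>``           delete membrane-spanning sub-spans *a* through *b*
                         (resolved as the union of their intervals)
``R<i>::<residues>``     replace repeat *i* with the given residues

The empty string is the identity (wild-type) specification.  Parsing is
purely syntactic; resolution against a concrete architecture happens in
:mod:`tapemeasure.mutants`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Union

__all__ = [
    "RepeatRange",
    "ResidueRange",
    "TmRange",
    "Replacement",
    "Component",
    "parse_spec_text",
    "format_components",
]


@dataclass(frozen=True)
class RepeatRange:
    """Deletion of whole repeats ``from_idx..to_idx`` plus an optional prefix
    of the following repeat (``extra`` residues, or half of it)."""

    from_idx: int
    to_idx: int
    extra: int = 0
    half: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.from_idx <= self.to_idx):
            raise ValueError(f"invalid repeat range {self.from_idx}..{self.to_idx}")
        if self.extra < 0:
            raise ValueError("extra residues must be non-negative")
        if self.extra and self.half:
            raise ValueError("a repeat range takes either +k or +half, not both")


@dataclass(frozen=True)
class ResidueRange:
    """Deletion of an inclusive residue interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid residue range {self.start}..{self.end}")


@dataclass(frozen=True)
class TmRange:
    """Deletion of membrane-spanning sub-spans (global numbering across both
    hydrophobic regions)."""

    from_tm: int
    to_tm: int

    def __post_init__(self) -> None:
        if not (1 <= self.from_tm <= self.to_tm):
            raise ValueError(f"invalid tm range {self.from_tm}..{self.to_tm}")


@dataclass(frozen=True)
class Replacement:
    """Replacement of one whole repeat by an arbitrary residue string."""

    repeat_idx: int
    insert_residues: str

    def __post_init__(self) -> None:
        if self.repeat_idx < 1:
            raise ValueError("repeat index must be >= 1")
        if not re.fullmatch(r"[ACDEFGHIKLMNPQRSTVWY]+", self.insert_residues):
            raise ValueError(f"invalid insert residues {self.insert_residues!r}")


Component = Union[RepeatRange, ResidueRange, TmRange, Replacement]

_REPEAT_RE = re.compile(r"R(\d+)\.\.(\d+)(?:\+(half|\d+))?$")
_RES_RE = re.compile(r"res(\d+)\.\.(\d+)$")
_TM_RE = re.compile(r"tm(\d+)\.\.(\d+)$")
_REPL_RE = re.compile(r"R(\d+)::([A-Z]+)$")


def _parse_component(text: str) -> Component:
    if m := _REPEAT_RE.match(text):
        a, b, suffix = m.group(1), m.group(2), m.group(3)
        if suffix is None:
            return RepeatRange(int(a), int(b))
        if suffix == "half":
            return RepeatRange(int(a), int(b), half=True)
        return RepeatRange(int(a), int(b), extra=int(suffix))
    if m := _RES_RE.match(text):
        return ResidueRange(int(m.group(1)), int(m.group(2)))
    if m := _TM_RE.match(text):
        return TmRange(int(m.group(1)), int(m.group(2)))
    if m := _REPL_RE.match(text):
        return Replacement(int(m.group(1)), m.group(2))
    if re.match(r"R\d+\.\.\d+\.", text):
        raise ValueError(
            f"ambiguous fractional repeat range {text!r}: write 'R<a>..<b>+<k>' "
            "for k extra residues or 'R<a>..<b>+half' for half of the next repeat"
        )
    raise ValueError(f"cannot parse mutant component {text!r}")


def parse_spec_text(text: str) -> tuple[Component, ...]:
    """Parse a specification string into its ordered components.

    An empty or whitespace-only string yields the identity (no components).
    """
    text = text.strip()
    if not text:
        return ()
    return tuple(_parse_component(part.strip()) for part in text.split(";"))


def format_components(components: tuple[Component, ...]) -> str:
    """Inverse of :func:`parse_spec_text` (round-trips exactly)."""
    out = []
    for c in components:
        if isinstance(c, RepeatRange):
            s = f"R{c.from_idx}..{c.to_idx}"
            if c.half:
                s += "+half"
            elif c.extra:
                s += f"+{c.extra}"
            out.append(s)
        elif isinstance(c, ResidueRange):
            out.append(f"res{c.start}..{c.end}")
        elif isinstance(c, TmRange):
            out.append(f"tm{c.from_tm}..{c.to_tm}")
        elif isinstance(c, Replacement):
            out.append(f"R{c.repeat_idx}::{c.insert_residues}")
        else:  # pragma: no cover
            raise TypeError(f"unknown component {c!r}")
    return ";".join(out)
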