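"""Hydropathy profiling and hydrophobic-region calling.

A transparent Kyte-Doolittle sliding-window scanner: the smoothed profile
is thresholded into candidate membrane-spanning runs, short runs are
discarded, and nearby runs are grouped into hydrophobic regions.  This is
a deliberately simple, fully inspectable caller - it makes no claim of
reproducing HMM-based topology predictors, only of recovering hydrophobic
architecture of the kind the synthetic generator plants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

__all__ = [
    "HydropathyParams",
    "HydropathyRegion",
    "HydropathyCall",
    "hydropathy_profile",
    "call_spans",
    "group_regions",
    "call_hydropathy",
    "KYTE_DOOLITTLE",
]


@dataclass(frozen=True)
class HydropathyParams:
    """Scanner parameters.

    window
        Odd smoothing-window width in residues (default 19, the classic
        choice for membrane-span detection).
    span_threshold
        Mean windowed score at or above which a position counts as
        membrane-like (default 1.6).
    min_span
        Shortest run reported as a membrane span (default 15 residues).
    region_gap
        Runs separated by at most this many residues are grouped into one
        hydrophobic region (default 30: wide enough to bridge the short
        polar connectors between helices of one region, far narrower than
        the cytoplasmic loop separating the two reference regions).
    """

    scale: dict[str, float] = field(
        default_factory=lambda: dict(KYTE_DOOLITTLE), compare=False
    )
    window: int = 19
    span_threshold: float = 1.6
    min_span: int = 15
    region_gap: int = 30

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.min_span < 1:
            raise ValueError("min_span must be >= 1")
        if self.region_gap < 0:
            raise ValueError("region_gap must be >= 0")


@dataclass(frozen=True)
class HydropathyRegion:
    """A group of membrane spans: indices into the span list plus the
    bounding interval (min start, max end)."""

    span_indices: tuple[int, ...]
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def n_spans(self) -> int:
        return len(self.span_indices)


@dataclass
class HydropathyCall:
    """Profile plus called spans and regions for one sequence."""

    profile: np.ndarray
    spans: list[tuple[int, int]]
    regions: list[HydropathyRegion]


def hydropathy_profile(sequence: str, params: HydropathyParams | None = None) -> np.ndarray:
    """Centred moving average of per-residue hydropathy.

    Terminal positions, where the window would overhang the sequence, use
    the truncated window so the profile keeps the sequence length.  The
    result is invariant under sequence reversal (up to index reversal).
    """
    params = params or HydropathyParams()
    n = len(sequence)
    if n < params.window:
        raise ValueError(f"sequence length {n} shorter than window {params.window}")
    try:
        scores = np.array([params.scale[aa.upper()] for aa in sequence], dtype=float)
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} missing from hydropathy scale") from None
    half = params.window // 2
    csum = np.concatenate([[0.0], np.cumsum(scores)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def call_spans(
    profile: np.ndarray, params: HydropathyParams | None = None
) -> list[tuple[int, int]]:
    """Maximal runs of profile >= threshold, at least ``min_span`` long,
    as 1-based inclusive intervals."""
    params = params or HydropathyParams()
    above = np.asarray(profile) >= params.span_threshold
    spans: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= params.min_span:
                spans.append((start + 1, i))
            start = None
    if start is not None and len(above) - start >= params.min_span:
        spans.append((start + 1, len(above)))
    return spans


def group_regions(
    spans: list[tuple[int, int]], params: HydropathyParams | None = None
) -> list[HydropathyRegion]:
    """Merge spans whose gaps are at most ``region_gap`` into regions."""
    params = params or HydropathyParams()
    if any(b[0] <= a[1] for a, b in zip(spans, spans[1:])):
        raise ValueError("spans must be sorted and non-overlapping")
    regions: list[HydropathyRegion] = []
    group: list[int] = []
    for i, (s, _e) in enumerate(spans):
        if group and s - spans[group[-1]][1] - 1 > params.region_gap:
            regions.append(HydropathyRegion(tuple(group), spans[group[0]][0],
                                            spans[group[-1]][1]))
            group = []
        group.append(i)
    if group:
        regions.append(HydropathyRegion(tuple(group), spans[group[0]][0],
                                        spans[group[-1]][1]))
    return regions


def call_hydropathy(sequence: str, params: HydropathyParams | None = None) -> HydropathyCall:
    """Profile, spans and regions in one call."""
    params = params or HydropathyParams()
    profile = hydropathy_profile(sequence, params)
    spans = call_spans(profile, params)
    return HydropathyCall(profile, spans, group_regions(spans, params))
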