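"""Classify inparalog pairs by physical distance and percent similarity.

Recent duplicates have not had time to move or diverge, so the joint
distribution of pair distance and similarity profiles the duplication
mechanisms at work: tandem duplication leaves copies within tens of kbp,
while retrotransposition and duplicative (drift) transposition place copies
far away or on other chromosomes.

Distance classes (boundary configurable, default 50 kbp):

* ``near``     — same chromosome, gap < 50 kbp (tandem-like)
* ``far``      — same chromosome, gap >= 50 kbp
* ``unlinked`` — different chromosomes
* ``unknown``  — either gene lacks coordinates

Similarity classes: four bins from three ascending percent boundaries.
Only the top boundary (95%, "recent" pairs) is biologically anchored; the
defaults 85/90/95 for the lower two are this package's choice and freely
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .graph_io import ConfigError, Gene, InputError
from .inparalogs import InparalogCall

UNLINKED = "unlinked"
UNKNOWN = "unknown"

DISTANCE_CLASSES = ("near", "far", UNLINKED)

DEFAULT_DISTANCE_BOUNDARY = 50_000
DEFAULT_SIMILARITY_BOUNDARIES = (85.0, 90.0, 95.0)


def physical_distance(
    a: Gene, b: Gene, midpoint: bool = False
) -> Union[int, str]:
    """Distance in bp between two genes, or ``"unlinked"`` / ``"unknown"``.

    The default measure is the gap between the two gene intervals
    (0 when they overlap); ``midpoint=True`` uses the distance between
    interval midpoints instead.
    """
    if (
        a.chromosome is None
        or b.chromosome is None
        or a.start is None
        or a.end is None
        or b.start is None
        or b.end is None
    ):
        if a.chromosome is not None and b.chromosome is not None and a.chromosome != b.chromosome:
            return UNLINKED
        return UNKNOWN
    if a.chromosome != b.chromosome:
        return UNLINKED
    if midpoint:
        return abs((a.start + a.end) - (b.start + b.end)) // 2
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def distance_class(
    a: Gene,
    b: Gene,
    boundary: int = DEFAULT_DISTANCE_BOUNDARY,
    midpoint: bool = False,
) -> str:
    """``near`` (< boundary), ``far`` (>= boundary, same chromosome),
    ``unlinked``, or ``unknown``.  A gap of exactly the boundary is far."""
    d = physical_distance(a, b, midpoint=midpoint)
    if isinstance(d, str):
        return d
    return "near" if d < boundary else "far"


def similarity_bins(boundaries: Sequence[float]) -> list[str]:
    """Human-readable labels for the four similarity classes."""
    b1, b2, b3 = boundaries
    return [f"<={b1:g}", f"({b1:g},{b2:g}]", f"({b2:g},{b3:g}]", f">{b3:g}"]


def _check_boundaries(boundaries: Sequence[float]) -> tuple[float, float, float]:
    if len(boundaries) != 3:
        raise ConfigError(
            f"exactly 3 similarity boundaries required, got {len(boundaries)}"
        )
    b = tuple(float(x) for x in boundaries)
    if not (0.0 < b[0] < b[1] < b[2] < 100.0):
        raise ConfigError(
            f"similarity boundaries must be strictly ascending within (0, 100), got {b}"
        )
    return b


def similarity_class(
    similarity: float,
    boundaries: Sequence[float] = DEFAULT_SIMILARITY_BOUNDARIES,
) -> int:
    """Bin index 0..3; bins are right-closed so that a pair *above* the top
    boundary falls in the "recent" bin 3."""
    b = _check_boundaries(boundaries)
    for i, edge in enumerate(b):
        if similarity <= edge:
            return i
    return 3


@dataclass(frozen=True)
class PairClassification:
    call: InparalogCall
    distance_class: str
    similarity_class: int


def classify_call(
    call: InparalogCall,
    genes: Mapping[str, Gene],
    distance_boundary: int = DEFAULT_DISTANCE_BOUNDARY,
    similarity_boundaries: Sequence[float] = DEFAULT_SIMILARITY_BOUNDARIES,
    midpoint: bool = False,
) -> PairClassification:
    for gid in (call.gene_a, call.gene_b):
        if gid not in genes:
            raise InputError(f"call references unknown gene {gid!r}")
    return PairClassification(
        call=call,
        distance_class=distance_class(
            genes[call.gene_a], genes[call.gene_b], distance_boundary, midpoint
        ),
        similarity_class=similarity_class(call.similarity, similarity_boundaries),
    )


def classify_pairs(
    calls: Iterable[InparalogCall],
    genes: Mapping[str, Gene],
    distance_boundary: int = DEFAULT_DISTANCE_BOUNDARY,
    similarity_boundaries: Sequence[float] = DEFAULT_SIMILARITY_BOUNDARIES,
    midpoint: bool = False,
) -> pd.DataFrame:
    """Tabulate calls per genome into (distance class x similarity class)
    cells.

    Returns a long-format frame with columns ``genome``, ``distance_class``,
    ``similarity_class`` (bin label), ``count`` and ``proportion``.  For
    every genome present all 3 x 4 = 12 known-distance cells are emitted
    (zeros included); proportions are over the genome's known-distance
    calls and sum to 1 wherever any exist.  Unknown-distance calls appear
    as extra ``distance_class == "unknown"`` rows with ``proportion`` NA.
    """
    boundaries = _check_boundaries(similarity_boundaries)
    labels = similarity_bins(boundaries)
    classified = [
        classify_call(c, genes, distance_boundary, boundaries, midpoint)
        for c in calls
    ]

    rows = []
    genomes = sorted({pc.call.genome for pc in classified})
    for genome in genomes:
        mine = [pc for pc in classified if pc.call.genome == genome]
        known = [pc for pc in mine if pc.distance_class != UNKNOWN]
        n_known = len(known)
        for dclass in DISTANCE_CLASSES:
            for sclass, label in enumerate(labels):
                count = sum(
                    1
                    for pc in known
                    if pc.distance_class == dclass and pc.similarity_class == sclass
                )
                rows.append(
                    {
                        "genome": genome,
                        "distance_class": dclass,
                        "similarity_class": label,
                        "count": count,
                        "proportion": count / n_known if n_known else 0.0,
                    }
                )
        for sclass, label in enumerate(labels):
            count = sum(
                1
                for pc in mine
                if pc.distance_class == UNKNOWN and pc.similarity_class == sclass
            )
            if count:
                rows.append(
                    {
                        "genome": genome,
                        "distance_class": UNKNOWN,
                        "similarity_class": label,
                        "count": count,
                        "proportion": float("nan"),
                    }
                )
    columns = ["genome", "distance_class", "similarity_class", "count", "proportion"]
    return pd.DataFrame(rows, columns=columns)


def to_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long classification table to a stacked-bar-ready wide
    layout: one row per (genome, distance_class), similarity bins as
    columns."""
    if table.empty:
        return pd.DataFrame()
    return table.pivot_table(
        index=["genome", "distance_class"],
        columns="similarity_class",
        values="count",
        aggfunc="sum",
        fill_value=0,
    )
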