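"""Reproducibility filtering and four-set Venn region algebra.

A site is *reproducible* for a (condition, label) when it is detected with
that label in at least ``min_replicates`` of the replicates (default 2 of 3).
Each reproducible site key (accession, position) then has a *redox pattern*:
the subset of {oxidized, reduced} it reproducibly shows under each of the two
conditions.  With two labels and two conditions there are 4x4 = 16 subset
pairs of which 15 are realizable (both-empty means the site was never
reproducible), and each pattern is one region of the four-set Venn diagram.

Region letters: the three cold-reactive patterns are fixed by their published
definitions (L: reduced at RT -> oxidized in cold; M: both at RT -> oxidized
in cold; N: reduced at RT -> both in cold); condition-exclusive blocks are
A-C (RT only) and I-K (cold only).  The remaining letters follow a documented
canonical order -- class membership (dynamic / reactive / exclusive / stable),
not lettering, carries the scientific meaning.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from cysredox.psm_io import OXIDIZED, REDUCED
from cysredox.redox_classify import CysteineSiteObservation

OX = frozenset({OXIDIZED})
RED = frozenset({REDUCED})
BOTH = frozenset({OXIDIZED, REDUCED})
EMPTY: frozenset = frozenset()


@dataclass(frozen=True)
class RedoxPattern:
    """Reproducible label subsets under the two conditions (RT, then cold)."""

    rt_labels: frozenset
    cold_labels: frozenset

    def __post_init__(self) -> None:
        if not self.rt_labels and not self.cold_labels:
            raise ValueError("pattern with both label sets empty is not realizable")


# Canonical letter order.  L, M, N are fixed by the published legend; A-C are
# the RT-exclusive patterns, I-K the cold analogues; D, F, H stable; E, G, O
# the reduction-direction dynamic patterns.
_PATTERN_BY_LETTER: dict[str, tuple[frozenset, frozenset]] = {
    "A": (OX, EMPTY),
    "B": (BOTH, EMPTY),
    "C": (RED, EMPTY),
    "D": (OX, OX),
    "E": (OX, RED),
    "F": (RED, RED),
    "G": (BOTH, RED),
    "H": (BOTH, BOTH),
    "I": (EMPTY, OX),
    "J": (EMPTY, BOTH),
    "K": (EMPTY, RED),
    "L": (RED, OX),
    "M": (BOTH, OX),
    "N": (RED, BOTH),
    "O": (OX, BOTH),
}

REGION_LETTERS: tuple[str, ...] = tuple(sorted(_PATTERN_BY_LETTER))
ALL_PATTERNS: tuple[RedoxPattern, ...] = tuple(
    RedoxPattern(rt, cold) for rt, cold in _PATTERN_BY_LETTER.values()
)
_LETTER_BY_PATTERN = {
    (rt, cold): letter for letter, (rt, cold) in _PATTERN_BY_LETTER.items()
}

REACTIVE_LETTERS = ("L", "M", "N")


@dataclass(frozen=True)
class ReproducibleSite:
    accession: str
    position: int
    condition: str
    label: str
    n_replicates_detected: int


@dataclass(frozen=True)
class RegionAssignment:
    accession: str
    position: int
    pattern: RedoxPattern
    region: str
    classes: frozenset


def reproducible_sites(
    observations: Iterable[CysteineSiteObservation],
    min_replicates: int = 2,
    n_replicates: int = 3,
) -> list[ReproducibleSite]:
    """Apply the replicate-reproducibility rule per (site, condition, label).

    Unlabeled observations never produce reproducible entries; the redoxome
    is defined over tagged cysteines only.
    """
    if min_replicates > n_replicates:
        raise ValueError(
            f"min_replicates={min_replicates} exceeds n_replicates={n_replicates}"
        )
    reps: dict[tuple[str, int, str, str], set[int]] = {}
    for o in observations:
        if o.label not in (OXIDIZED, REDUCED):
            continue
        key = (o.accession, o.position, o.condition, o.label)
        reps.setdefault(key, set()).add(o.replicate)
    out = []
    for (acc, pos, cond, label), r in reps.items():
        if len(r) >= min_replicates:
            out.append(ReproducibleSite(acc, pos, cond, label, len(r)))
    return sorted(out, key=lambda s: (s.accession, s.position, s.condition, s.label))


def pattern_classes(pattern: RedoxPattern) -> frozenset:
    """Class memberships of a pattern.

    dynamic: detected under both conditions with differing label sets;
    reactive: the three cold-oxidation-shifted dynamic patterns (L, M, N);
    rt_exclusive / cold_exclusive: absent from the other condition;
    stable: identical non-empty label sets under both conditions.
    """
    rt, cold = pattern.rt_labels, pattern.cold_labels
    classes = set()
    if rt and cold and rt != cold:
        classes.add("dynamic")
    if (rt, cold) in {(RED, OX), (BOTH, OX), (RED, BOTH)}:
        classes.add("reactive")
    if not cold:
        classes.add("rt_exclusive")
    if not rt:
        classes.add("cold_exclusive")
    if rt and rt == cold:
        classes.add("stable")
    return frozenset(classes)


def assign_region(pattern: RedoxPattern) -> tuple[str, frozenset]:
    """Map a realizable pattern to its region letter and classes."""
    letter = _LETTER_BY_PATTERN[(pattern.rt_labels, pattern.cold_labels)]
    return letter, pattern_classes(pattern)


def assign_regions(
    sites: Iterable[ReproducibleSite],
    rt_condition: str = "RT",
    cold_condition: str = "Cold",
) -> list[RegionAssignment]:
    """Collapse reproducible (site, condition, label) entries to one region per site."""
    rt_sets: dict[tuple[str, int], set[str]] = {}
    cold_sets: dict[tuple[str, int], set[str]] = {}
    keys = set()
    for s in sites:
        key = (s.accession, s.position)
        keys.add(key)
        if s.condition == rt_condition:
            rt_sets.setdefault(key, set()).add(s.label)
        elif s.condition == cold_condition:
            cold_sets.setdefault(key, set()).add(s.label)
        else:
            raise ValueError(f"unknown condition {s.condition!r}")
    out = []
    for acc, pos in sorted(keys):
        pattern = RedoxPattern(
            frozenset(rt_sets.get((acc, pos), ())),
            frozenset(cold_sets.get((acc, pos), ())),
        )
        letter, classes = assign_region(pattern)
        out.append(RegionAssignment(acc, pos, pattern, letter, classes))
    return out


CLASS_NAMES = ("dynamic", "reactive", "rt_exclusive", "cold_exclusive", "stable")


def venn_counts(assignments: Sequence[RegionAssignment]) -> dict:
    """Site- and protein-level counts per region letter and per class.

    Site counts partition the reproducible site keys (they sum to the total);
    protein counts deduplicate by accession within each region/class, so a
    protein with several sites in the same category counts once there.
    """
    sites_by_region = {letter: 0 for letter in REGION_LETTERS}
    proteins_by_region = {letter: set() for letter in REGION_LETTERS}
    sites_by_class = {c: 0 for c in CLASS_NAMES}
    proteins_by_class = {c: set() for c in CLASS_NAMES}
    for a in assignments:
        sites_by_region[a.region] += 1
        proteins_by_region[a.region].add(a.accession)
        for c in a.classes:
            sites_by_class[c] += 1
            proteins_by_class[c].add(a.accession)
    return {
        "n_sites": len(assignments),
        "sites_by_region": sites_by_region,
        "proteins_by_region": {k: len(v) for k, v in proteins_by_region.items()},
        "sites_by_class": sites_by_class,
        "proteins_by_class": {k: len(v) for k, v in proteins_by_class.items()},
    }


def select_reactive(assignments: Iterable[RegionAssignment]) -> list[RegionAssignment]:
    """Sites shifted toward oxidation in the cold (regions L, M, N)."""
    return [a for a in assignments if "reactive" in a.classes]


def load_reactive_site_table() -> pd.DataFrame:
    """Load the packaged table of published cold-reactive cysteine sites.

    Columns: accession, gene, protein_name, position, region, localization.
    """
    with resources.files("cysredox.data").joinpath("reactive_sites.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def assignments_from_region_table(df: pd.DataFrame) -> list[RegionAssignment]:
    """Rebuild RegionAssignments from a (accession, position, region) table.

    Each region letter is expanded back to its redox pattern, so downstream
    selectors run on the same algebra as pipeline-derived assignments.
    """
    out = []
    for row in df.itertuples(index=False):
        rt, cold = _PATTERN_BY_LETTER[row.region]
        pattern = RedoxPattern(rt, cold)
        letter, classes = assign_region(pattern)
        out.append(
            RegionAssignment(row.accession, int(row.position), pattern, letter, classes)
        )
    return out


def assignments_to_frame(assignments: Sequence[RegionAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "accession": a.accession,
                "position": a.position,
                "rt_labels": ",".join(sorted(a.pattern.rt_labels)),
                "cold_labels": ",".join(sorted(a.pattern.cold_labels)),
                "region": a.region,
                "classes": ",".join(sorted(a.classes)),
            }
            for a in assignments
        ],
        columns=["accession", "position", "rt_labels", "cold_labels", "region", "classes"],
    )
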