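"""Site-level redox classification and per-group percentage summaries.

Each peptide cysteine becomes one observation labeled ``oxidized`` (BPM tag,
+548.28 Da), ``reduced`` (NEM tag, +125.05 Da) or ``unlabeled`` (no tag).
The counting unit throughout is the distinct (protein, position, label)
site observation within a replicate, not the PSM: the same site seen in many
PSMs of one replicate counts once, but a site seen with both tags in one
replicate (different PSMs) legitimately yields one observation per label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from cysredox.psm_io import (
    OXIDIZED,
    REDUCED,
    UNLABELED,
    ModificationMap,
    PeptideMappingError,
    PsmRecord,
    map_peptide_to_protein,
)

logger = logging.getLogger(__name__)

LABELS = (OXIDIZED, REDUCED, UNLABELED)


@dataclass(frozen=True, order=True)
class CysteineSiteObservation:
    """One redox call for one cysteine in one replicate."""

    accession: str
    position: int
    label: str
    condition: str
    replicate: int


def classify_sites(
    psms: Iterable[PsmRecord],
    db: dict[str, str],
    mod_map: ModificationMap | None = None,
    include_ambiguous: bool = False,
) -> list[CysteineSiteObservation]:
    """Classify every mappable peptide cysteine by its tag.

    A cysteine carrying both an oxidized-class and a reduced-class token in
    the same PSM is contradictory and is dropped (logged).  Peptides that
    match their protein at several offsets are excluded unless
    ``include_ambiguous`` is set.  Duplicate observations collapse to one.
    """
    if mod_map is None:
        mod_map = ModificationMap.default()
    seen: set[CysteineSiteObservation] = set()
    for psm in psms:
        try:
            mappings = map_peptide_to_protein(psm, db)
        except PeptideMappingError as exc:
            logger.warning("skipping PSM: %s", exc)
            continue
        labels_by_pep_idx: dict[int, set[str]] = {}
        for idx, name in psm.modifications:
            label = mod_map.label_for(name)
            if label is not None:
                labels_by_pep_idx.setdefault(idx, set()).add(label)
        for m in mappings:
            if m.ambiguous and not include_ambiguous:
                continue
            labels = labels_by_pep_idx.get(m.peptide_index, set())
            if len(labels) > 1:
                logger.warning(
                    "conflicting redox tags on %s position %d (replicate %s/%d); dropped",
                    m.accession,
                    m.position,
                    psm.condition,
                    psm.replicate,
                )
                continue
            label = next(iter(labels)) if labels else UNLABELED
            seen.add(
                CysteineSiteObservation(
                    accession=m.accession,
                    position=m.position,
                    label=label,
                    condition=psm.condition,
                    replicate=psm.replicate,
                )
            )
    return sorted(seen)


def _replicate_percentages(
    observations: Sequence[CysteineSiteObservation], condition: str
) -> dict[int, dict[str, float]]:
    by_rep: dict[int, set[tuple[str, int, str]]] = {}
    for o in observations:
        if o.condition != condition:
            continue
        by_rep.setdefault(o.replicate, set()).add((o.accession, o.position, o.label))
    out: dict[int, dict[str, float]] = {}
    for rep in sorted(by_rep):
        sites = by_rep[rep]
        total = len(sites)
        if total == 0:
            logger.warning("replicate %d of %s has no cysteines; excluded", rep, condition)
            continue
        counts = {label: sum(1 for s in sites if s[2] == label) for label in LABELS}
        out[rep] = {label: 100.0 * counts[label] / total for label in LABELS}
    return out


def percent_redox(
    observations: Sequence[CysteineSiteObservation],
    conditions: tuple[str, str] = ("RT", "Cold"),
) -> dict:
    """Percentages of oxidized/reduced/unlabeled sites per replicate and group.

    Per replicate the denominator is that replicate's distinct
    (accession, position, label) observations, so the three percentages sum
    to 100.  Group summaries are mean +/- SEM over replicates, compared
    between the two conditions with an equal-variance two-tailed t test.
    """
    result: dict = {"conditions": {}, "tests": {}}
    per_cond: dict[str, dict[int, dict[str, float]]] = {}
    for cond in conditions:
        reps = _replicate_percentages(observations, cond)
        per_cond[cond] = reps
        summary: dict[str, dict] = {}
        for label in LABELS:
            vals = np.array([reps[r][label] for r in sorted(reps)])
            summary[label] = {
                "per_replicate": vals.tolist(),
                "mean": float(vals.mean()) if vals.size else float("nan"),
                "sem": float(stats.sem(vals, ddof=1)) if vals.size > 1 else float("nan"),
            }
        result["conditions"][cond] = summary
    a, b = conditions
    for label in LABELS:
        x = [per_cond[a][r][label] for r in sorted(per_cond[a])]
        y = [per_cond[b][r][label] for r in sorted(per_cond[b])]
        if len(x) > 1 and len(y) > 1:
            t, p = stats.ttest_ind(x, y, equal_var=True)
            result["tests"][label] = {"t": float(t), "p": float(p)}
        else:
            result["tests"][label] = {"t": float("nan"), "p": float("nan")}
    return result
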