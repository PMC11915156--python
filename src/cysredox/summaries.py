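"""Subcellular-compartment joins and per-compartment redox percentages.

Sites on multi-localized proteins are counted once per compartment, matching
the convention that every annotated localization of a protein contributes to
quantification.  Compartment percentages consider tagged (oxidized/reduced)
sites only, so %oxidized + %reduced = 100 within a compartment-condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cysredox.psm_io import OXIDIZED, REDUCED
from cysredox.redox_classify import CysteineSiteObservation

logger = logging.getLogger(__name__)

#: Controlled compartment vocabulary.
COMPARTMENTS = (
    "nucleus",
    "mitochondrion",
    "cytosol",
    "endoplasmic reticulum",
    "golgi apparatus",
    "plasma membrane",
    "extracellular space",
)

#: UniProt-style term variants folded onto the controlled vocabulary.
COMPARTMENT_ALIASES = {
    "mitochondria": "mitochondrion",
    "mitochondrial": "mitochondrion",
    "nuclear": "nucleus",
    "cytoplasm": "cytosol",
    "er": "endoplasmic reticulum",
    "golgi": "golgi apparatus",
    "plasm membrane": "plasma membrane",
    "cell membrane": "plasma membrane",
    "extracellular": "extracellular space",
    "secreted": "extracellular space",
}


def normalize_compartment(name: str) -> str:
    key = name.strip().lower()
    return COMPARTMENT_ALIASES.get(key, key)


def read_localization_table(path: str | Path) -> dict[str, list[str]]:
    """Read ``accession<TAB>compartment1;compartment2`` into a mapping."""
    table: dict[str, list[str]] = {}
    df = pd.read_csv(path, sep="\t", header=None, names=["accession", "compartments"])
    for row in df.itertuples(index=False):
        comps = [
            normalize_compartment(c)
            for c in str(row.compartments).split(";")
            if c.strip()
        ]
        table[str(row.accession)] = comps
    return table


@dataclass(frozen=True)
class LocalizedSite:
    accession: str
    position: int
    label: str
    condition: str
    replicate: int
    compartment: str


def join_localization(
    sites: Iterable[CysteineSiteObservation],
    table: dict[str, list[str]],
) -> tuple[list[LocalizedSite], list[str]]:
    """Expand each site to one record per annotated compartment.

    Returns (records, unannotated accessions).  A protein with m compartments
    contributes m records per site; proteins without annotation contribute
    none and are reported.
    """
    records: list[LocalizedSite] = []
    missing: set[str] = set()
    for s in sites:
        comps = table.get(s.accession)
        if not comps:
            missing.add(s.accession)
            continue
        for c in comps:
            records.append(
                LocalizedSite(s.accession, s.position, s.label, s.condition, s.replicate, c)
            )
    for acc in sorted(missing):
        logger.warning("no subcellular annotation for %s", acc)
    return records, sorted(missing)


def compartment_percentages(
    localized: Sequence[LocalizedSite],
    conditions: tuple[str, str] = ("RT", "Cold"),
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-compartment oxidized/reduced percentages with group statistics.

    Default mode computes %oxidized = n_ox / (n_ox + n_red) x 100 per
    replicate and reports mean +/- SEM per condition plus an equal-variance
    two-tailed t test between conditions; ``pooled`` collapses replicates
    before taking the percentage.  Unlabeled sites never enter denominators.
    """
    tagged = [s for s in localized if s.label in (OXIDIZED, REDUCED)]
    compartments = sorted({s.compartment for s in tagged})
    rows = []
    for comp in compartments:
        row: dict = {"compartment": comp}
        per_cond_pcts: dict[str, list[float]] = {}
        for cond in conditions:
            subset = [s for s in tagged if s.compartment == comp and s.condition == cond]
            if not subset:
                continue
            if pooled:
                sites = {(s.accession, s.position, s.label) for s in subset}
                n_ox = sum(1 for s in sites if s[2] == OXIDIZED)
                n_red = len(sites) - n_ox
                pcts = [100.0 * n_ox / (n_ox + n_red)]
            else:
                pcts = []
                n_ox = n_red = 0
                for rep in sorted({s.replicate for s in subset}):
                    sites = {
                        (s.accession, s.position, s.label)
                        for s in subset
                        if s.replicate == rep
                    }
                    ox = sum(1 for s in sites if s[2] == OXIDIZED)
                    red = len(sites) - ox
                    n_ox += ox
                    n_red += red
                    if ox + red:
                        pcts.append(100.0 * ox / (ox + red))
            per_cond_pcts[cond] = pcts
            arr = np.asarray(pcts)
            row[f"n_oxidized_{cond}"] = n_ox
            row[f"n_reduced_{cond}"] = n_red
            row[f"pct_oxidized_{cond}"] = float(arr.mean())
            row[f"pct_reduced_{cond}"] = 100.0 - float(arr.mean())
            row[f"sem_oxidized_{cond}"] = (
                float(stats.sem(arr, ddof=1)) if arr.size > 1 else float("nan")
            )
        a, b = conditions
        if a in per_cond_pcts and b in per_cond_pcts:
            row["delta_pct_oxidized"] = row[f"pct_oxidized_{b}"] - row[f"pct_oxidized_{a}"]
            x, y = per_cond_pcts[a], per_cond_pcts[b]
            if len(x) > 1 and len(y) > 1:
                t, p = stats.ttest_ind(x, y, equal_var=True)
                row["t"] = float(t)
                row["p"] = float(p)
        rows.append(row)
    return pd.DataFrame(rows)
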