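"""Input/output for PSM tables, protein FASTA, and site tables.

The PSM table is a generic TSV distilled from a search-engine export
(e.g. Proteome Discoverer): columns ``peptide``, ``accession``,
``modifications`` and optionally ``abundance``.  Modification cells hold
semicolon-separated tokens ``C<idx>(<name>)`` where ``idx`` is the 1-based
residue index within the peptide and ``<name>`` is a modification name or a
delta mass in Da (e.g. ``C2(NEM)``, ``C5(+548.28)``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from pyteomics import mass as _ptmass

logger = logging.getLogger(__name__)

#: Monoisotopic mass increment of the N-ethylmaleimide adduct (C6H7NO2),
#: the tag carried by cysteines that were free thiols (reduced) in vivo.
NEM_DELTA_MASS: float = float(_ptmass.calculate_mass(formula="C6H7NO2"))

#: Monoisotopic mass increment of the biotin-PEAC5-maleimide adduct, the tag
#: carried by cysteines that were reversibly oxidized in vivo.
BPM_DELTA_MASS: float = 548.28

OXIDIZED = "oxidized"
REDUCED = "reduced"
UNLABELED = "unlabeled"

_MOD_TOKEN_RE = re.compile(r"^C(\d+)\(([^()]+)\)$")
_MASS_RE = re.compile(r"^[+-]?\d+(\.\d+)?$")


class PsmIoError(ValueError):
    """Raised on unrecoverable table/FASTA format problems."""


@dataclass
class PsmRecord:
    """One identified peptide in one replicate of one condition."""

    peptide_sequence: str
    accession: str
    modifications: list[tuple[int, str]] = field(default_factory=list)
    condition: str = ""
    replicate: int = 1
    abundance: float | None = None

    def __post_init__(self) -> None:
        if not self.peptide_sequence:
            raise PsmIoError("peptide_sequence must be non-empty")
        self.peptide_sequence = self.peptide_sequence.upper()
        for idx, _name in self.modifications:
            if not 1 <= idx <= len(self.peptide_sequence):
                raise PsmIoError(
                    f"modification index {idx} outside peptide "
                    f"{self.peptide_sequence!r}"
                )
        if self.abundance is not None and self.abundance < 0:
            raise PsmIoError("abundance must be non-negative")


class ModificationMap:
    """Resolve modification names or delta masses to redox labels.

    Names are matched case-insensitively; numeric tokens are matched against
    registered delta masses within ``mass_tolerance`` Da.
    """

    def __init__(self, mass_tolerance: float = 0.02) -> None:
        self.mass_tolerance = mass_tolerance
        self._by_name: dict[str, str] = {}
        self._by_mass: list[tuple[float, str]] = []

    @classmethod
    def default(cls) -> "ModificationMap":
        m = cls()
        m.add("NEM", REDUCED, delta_mass=NEM_DELTA_MASS)
        m.add("N-ethylmaleimide", REDUCED)
        m.add("Cysteine N-ethylmaleimide", REDUCED)
        m.add("BPM", OXIDIZED, delta_mass=BPM_DELTA_MASS)
        m.add("Biotin-Peac5-maleimide", OXIDIZED)
        m.add("Cysteine Biotin-Peac5-maleimide", OXIDIZED)
        return m

    def add(self, name: str, label: str, delta_mass: float | None = None) -> None:
        if label not in (OXIDIZED, REDUCED):
            raise PsmIoError(f"unknown redox label {label!r}")
        key = name.strip().lower()
        if key in self._by_name and self._by_name[key] != label:
            raise PsmIoError(f"modification {name!r} already mapped to another label")
        self._by_name[key] = label
        if delta_mass is not None:
            self._by_mass.append((float(delta_mass), label))

    def label_for(self, token: str) -> str | None:
        """Return the redox label for a modification token, or None."""
        key = token.strip().lower()
        if key in self._by_name:
            return self._by_name[key]
        if _MASS_RE.match(key):
            value = float(key)
            for m, label in self._by_mass:
                if abs(value - m) <= self.mass_tolerance:
                    return label
        return None


def parse_modification_cell(cell: str) -> tuple[list[tuple[int, str]], list[str]]:
    """Parse a semicolon-separated modification cell.

    Returns (mods, bad_tokens); malformed tokens are collected rather than
    raised so one bad cell does not discard the whole row.
    """
    mods: list[tuple[int, str]] = []
    bad: list[str] = []
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return mods, bad
    for token in str(cell).split(";"):
        token = token.strip()
        if not token:
            continue
        m = _MOD_TOKEN_RE.match(token)
        if m is None:
            bad.append(token)
            continue
        mods.append((int(m.group(1)), m.group(2)))
    return mods, bad


_REQUIRED_COLUMNS = ("peptide", "accession", "modifications")


def read_psm_table(
    path: str | Path,
    condition: str,
    replicate: int,
    warnings: list[str] | None = None,
) -> list[PsmRecord]:
    """Read one replicate's PSM TSV into records.

    Malformed modification tokens are appended to ``warnings`` (if given)
    and logged; the row itself is kept with its parseable tokens.
    """
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "accession": str})
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise PsmIoError(f"PSM table {path} missing required column {col!r}")
    if df.empty:
        logger.warning("PSM table %s is empty", path)
        return []
    records: list[PsmRecord] = []
    for row in df.itertuples(index=False):
        mods, bad = parse_modification_cell(getattr(row, "modifications"))
        for token in bad:
            msg = f"{path}: unparseable modification token {token!r} in peptide {row.peptide}"
            logger.warning(msg)
            if warnings is not None:
                warnings.append(msg)
        abundance = getattr(row, "abundance", None)
        if abundance is not None and pd.isna(abundance):
            abundance = None
        records.append(
            PsmRecord(
                peptide_sequence=str(row.peptide),
                accession=str(row.accession),
                modifications=mods,
                condition=condition,
                replicate=replicate,
                abundance=None if abundance is None else float(abundance),
            )
        )
    return records


def write_psm_table(records: Iterable[PsmRecord], path: str | Path) -> None:
    """Write records back to the TSV schema read by :func:`read_psm_table`."""
    rows = []
    for r in records:
        cell = ";".join(f"C{idx}({name})" for idx, name in r.modifications)
        rows.append(
            {
                "peptide": r.peptide_sequence,
                "accession": r.accession,
                "modifications": cell,
                "abundance": "" if r.abundance is None else r.abundance,
            }
        )
    pd.DataFrame(rows, columns=["peptide", "accession", "modifications", "abundance"]).to_csv(
        path, sep="\t", index=False
    )


def _clean_accession(header_token: str) -> str:
    # UniProt dialect "sp|P001|NAME" -> "P001"
    parts = header_token.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1]
    return header_token


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a protein FASTA into an accession -> sequence mapping."""
    db: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = _clean_accession(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise PsmIoError(f"empty sequence for {acc} in {path}")
        if acc in db:
            raise PsmIoError(f"duplicate accession {acc} in {path}")
        db[acc] = seq
    return db


def write_fasta(db: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for acc, seq in db.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


@dataclass(frozen=True)
class CysMapping:
    """A peptide cysteine placed on protein coordinates (1-based)."""

    accession: str
    position: int
    peptide_index: int
    ambiguous: bool = False


class PeptideMappingError(ValueError):
    """Peptide is not a substring of its stated protein."""


def map_peptide_to_protein(record: PsmRecord, db: dict[str, str]) -> list[CysMapping]:
    """Map every cysteine of a peptide to 1-based protein coordinates.

    All occurrences of the peptide in the protein are enumerated; if there is
    more than one offset every resulting coordinate is flagged ambiguous.
    """
    if record.accession not in db:
        raise PeptideMappingError(f"accession {record.accession} not in FASTA")
    protein = db[record.accession]
    peptide = record.peptide_sequence
    offsets = []
    start = protein.find(peptide)
    while start != -1:
        offsets.append(start)
        start = protein.find(peptide, start + 1)
    if not offsets:
        raise PeptideMappingError(
            f"peptide {peptide} not found in protein {record.accession}"
        )
    ambiguous = len(offsets) > 1
    out: list[CysMapping] = []
    for off in offsets:
        for i, aa in enumerate(peptide):
            if aa == "C":
                out.append(
                    CysMapping(
                        accession=record.accession,
                        position=off + i + 1,
                        peptide_index=i + 1,
                        ambiguous=ambiguous,
                    )
                )
    return out


SITE_TABLE_COLUMNS = ["accession", "position", "label", "condition", "replicate"]


def write_site_table(sites: Sequence, path: str | Path) -> None:
    """Write site observations to TSV (columns fixed by SITE_TABLE_COLUMNS)."""
    df = pd.DataFrame(
        [
            {
                "accession": s.accession,
                "position": s.position,
                "label": s.label,
                "condition": s.condition,
                "replicate": s.replicate,
            }
            for s in sites
        ],
        columns=SITE_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_site_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SITE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise PsmIoError(f"site table {path} missing columns {missing}")
    return df
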