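"""Truth-annotated synthetic inputs for the whole pipeline.

The generator emulates a two-condition (room temperature vs acute cold),
three-replicate differential-alkylation experiment: a proteome FASTA with
i.i.d. mouse-like residue composition, planted cysteine sites with known
redox patterns across the fifteen Venn regions, tryptic-like peptides emitted
into per-replicate PSM tables with NEM/BPM modification tokens, a
subcellular-localization table, and a log-normal protein-abundance matrix
with planted differential proteins.  Every planted fact is recorded in a
machine-readable truth table so recovery can be checked exactly.

Default site counts are a roughly quarter-scale rendition of the study
design's reproducible-site marginals (about 50 oxidized / 240 reduced sites
at room temperature, with a minority of dynamic sites concentrated in the
stable-reduced region), sized so the full pipeline runs in seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from cysredox import psm_io
from cysredox.psm_io import PsmRecord, write_fasta, write_psm_table
from cysredox.repro_regions import (
    REGION_LETTERS,
    RedoxPattern,
    _PATTERN_BY_LETTER,
    assign_region,
)
from cysredox.summaries import COMPARTMENTS

# Mouse-proteome-like residue composition (mole fractions, normalized below).
MOUSE_LIKE_COMPOSITION = {
    "A": 6.9, "R": 5.6, "N": 3.6, "D": 4.8, "C": 2.3, "E": 7.0, "Q": 4.8,
    "G": 6.3, "H": 2.6, "I": 4.4, "L": 10.0, "K": 5.7, "M": 2.2, "F": 3.7,
    "P": 6.1, "S": 8.4, "T": 5.5, "W": 1.2, "Y": 2.7, "V": 6.1,
}

DEFAULT_SITES_PER_PATTERN = {
    "A": 10, "B": 6, "C": 90,     # RT-exclusive
    "D": 12, "F": 120, "H": 10,   # stable
    "I": 6, "J": 3, "K": 40,      # cold-exclusive
    "E": 2, "G": 1, "O": 1,       # dynamic, reduction-shifted
    "L": 4, "M": 8, "N": 5,       # dynamic, oxidation-shifted (reactive)
}

#: Motif plants: site-class -> list of (residue, flank position, fraction).
#: Reactive sites carry the positively charged lysine at -1 that favors the
#: thiolate state; exclusively reduced sites carry an acidic residue at +1.
DEFAULT_MOTIF_PLANTS = {
    "reactive": [("K", -1, 0.6)],
    "exclusive_reduced": [("D", 1, 0.5)],
}

_CLASS_REGIONS = {
    "reactive": ("L", "M", "N"),
    "exclusive_reduced": ("C", "K"),
}

CONDITIONS = ("RT", "Cold")
N_REPLICATES = 3


@dataclass
class SimulationConfig:
    n_proteins: int = 200
    length_range: tuple[int, int] = (250, 450)
    sites_per_pattern: dict = field(default_factory=lambda: dict(DEFAULT_SITES_PER_PATTERN))
    n_unlabeled_sites: int = 30
    detection_probability: float = 0.9
    motif_plants: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_MOTIF_PLANTS.items()})
    background_frequencies: dict = field(default_factory=lambda: dict(MOUSE_LIKE_COMPOSITION))
    n_differential_proteins: int = 20
    abundance_log2fc: float = 1.0
    abundance_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.detection_probability <= 1.0:
            raise ValueError("detection_probability must be in (0, 1]")
        for plants in self.motif_plants.values():
            for _res, _pos, frac in plants:
                if not 0.0 <= frac <= 1.0:
                    raise ValueError(f"motif plant fraction {frac} outside [0, 1]")
        for letter in self.sites_per_pattern:
            if letter not in REGION_LETTERS:
                raise ValueError(f"unknown region letter {letter!r}")


@dataclass
class PlantedSite:
    accession: str
    position: int        # 1-based protein coordinate
    region: str | None   # None for unlabeled filler sites
    peptide: str
    peptide_cys_index: int  # 1-based index of the cysteine in the peptide
    motif_planted: list = field(default_factory=list)


@dataclass
class SimulatedBundle:
    config: SimulationConfig
    proteome: dict[str, str]
    psm_tables: dict[tuple[str, int], list[PsmRecord]]
    localization: dict[str, list[str]]
    abundance: pd.DataFrame
    sample_conditions: dict[str, str]
    sites: list[PlantedSite]
    protein_log2fc: dict[str, float]

    def truth_records(self) -> list[dict]:
        out = []
        for s in self.sites:
            if s.region is None:
                region, classes = None, []
            else:
                rt, cold = _PATTERN_BY_LETTER[s.region]
                region, cls = assign_region(RedoxPattern(rt, cold))
                classes = sorted(cls)
            out.append(
                {
                    "accession": s.accession,
                    "position": s.position,
                    "region": region,
                    "classes": classes,
                    "motif_planted": s.motif_planted,
                }
            )
        return out

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Write all pipeline inputs plus the truth table; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, str] = {}
        fasta = outdir / "proteome.fasta"
        write_fasta(self.proteome, fasta)
        paths["fasta"] = str(fasta)
        for (cond, rep), records in self.psm_tables.items():
            p = outdir / f"psm_{cond}_{rep}.tsv"
            write_psm_table(records, p)
            paths[f"psm_{cond}_{rep}"] = str(p)
        loc = outdir / "localization.tsv"
        with open(loc, "w") as fh:
            for acc, comps in self.localization.items():
                fh.write(f"{acc}\t{';'.join(comps)}\n")
        paths["localization"] = str(loc)
        ab = outdir / "abundance.tsv"
        self.abundance.to_csv(ab, sep="\t")
        paths["abundance"] = str(ab)
        sheet = outdir / "sample_sheet.tsv"
        pd.DataFrame(
            [
                {"sample": s, "condition": c, "replicate": int(s.rsplit("_", 1)[1])}
                for s, c in self.sample_conditions.items()
            ]
        ).to_csv(sheet, sep="\t", index=False)
        paths["sample_sheet"] = str(sheet)
        truth = outdir / "truth.json"
        with open(truth, "w") as fh:
            json.dump(
                {
                    "config": {**asdict(self.config), "length_range": list(self.config.length_range)},
                    "sites": self.truth_records(),
                    "protein_log2fc": self.protein_log2fc,
                    "localization": self.localization,
                },
                fh,
                indent=1,
            )
        paths["truth"] = str(truth)
        return paths


def _draw_sequence(rng: np.random.Generator, length: int, freqs: dict[str, float]) -> list[str]:
    residues = list(freqs)
    p = np.array([freqs[r] for r in residues], dtype=float)
    p /= p.sum()
    return list(rng.choice(residues, size=length, p=p))


def _nonspecial_residue(rng: np.random.Generator, freqs: dict[str, float]) -> str:
    # filler residue that neither cleaves (K/R) nor adds a cysteine
    residues = [r for r in freqs if r not in ("K", "R", "C")]
    p = np.array([freqs[r] for r in residues], dtype=float)
    p /= p.sum()
    return str(rng.choice(residues, p=p))


def _tryptic_fragment(seq: str, pos0: int) -> tuple[str, int]:
    """Fully tryptic fragment (cut after K/R) containing 0-based ``pos0``.

    Returns (peptide, 0-based start offset in the protein).
    """
    start = 0
    for i in range(pos0 - 1, -1, -1):
        if seq[i] in "KR":
            start = i + 1
            break
    end = len(seq)
    for i in range(pos0, len(seq)):
        if seq[i] in "KR":
            end = i + 1
            break
    return seq[start:end], start


def _site_classes(region: str) -> list[str]:
    return [cls for cls, letters in _CLASS_REGIONS.items() if region in letters]


def generate(config: SimulationConfig) -> SimulatedBundle:
    """Generate a full consistent input bundle from one seed."""
    rng = np.random.default_rng(config.seed)
    freqs = dict(config.background_frequencies)

    lengths = rng.integers(config.length_range[0], config.length_range[1] + 1, size=config.n_proteins)
    accessions = [f"SYN{i:04d}" for i in range(config.n_proteins)]
    seqs = {acc: _draw_sequence(rng, int(n), freqs) for acc, n in zip(accessions, lengths)}

    # candidate site slots: positions spaced >= 40 apart, 15 aa clear of termini
    slots: list[tuple[str, int]] = []
    for acc in accessions:
        n = len(seqs[acc])
        pos0 = 15
        while pos0 < n - 15:
            slots.append((acc, pos0))
            pos0 += 40
    site_specs: list[str | None] = []
    for letter in sorted(config.sites_per_pattern):
        site_specs.extend([letter] * int(config.sites_per_pattern[letter]))
    site_specs.extend([None] * config.n_unlabeled_sites)
    if len(site_specs) > len(slots):
        raise ValueError(
            f"requested {len(site_specs)} sites but the proteome only hosts {len(slots)}"
        )
    order = rng.permutation(len(slots))[: len(site_specs)]

    sites: list[PlantedSite] = []
    for region, slot_idx in zip(site_specs, order):
        acc, pos0 = slots[int(slot_idx)]
        seq = seqs[acc]
        seq[pos0] = "C"
        # sanitize the neighbourhood: no stray C within the window, and
        # cleavage sites only where we put them
        for j in range(pos0 - 13, pos0 + 14):
            if 0 <= j < len(seq) and j != pos0 and seq[j] in "KRC":
                seq[j] = _nonspecial_residue(rng, freqs)
        left = int(rng.integers(8, 13))
        right = int(rng.integers(6, 13))
        seq[pos0 - left] = str(rng.choice(["K", "R"]))
        seq[pos0 + right] = str(rng.choice(["K", "R"]))
        planted: list = []
        if region is not None:
            for cls in _site_classes(region):
                for res, flank_pos, frac in config.motif_plants.get(cls, []):
                    if rng.random() < frac:
                        seq[pos0 + flank_pos] = res
                        planted.append([res, flank_pos])
        sites.append(PlantedSite(acc, pos0 + 1, region, "", 0, planted))

    proteome = {acc: "".join(seq) for acc, seq in seqs.items()}

    # derive each site's tryptic peptide; resolve rare ambiguous matches by
    # swapping in a tryptophan away from the planted positions
    for s in sites:
        seq = proteome[s.accession]
        pos0 = s.position - 1
        for _ in range(5):
            peptide, start = _tryptic_fragment(seq, pos0)
            if seq.count(peptide) == 1:
                break
            forbidden = {pos0} | {pos0 + fp for _res, fp in s.motif_planted}
            for j in range(start + 1, start + len(peptide) - 1):
                if j not in forbidden and seq[j] not in "KRCW":
                    seq = seq[:j] + "W" + seq[j + 1 :]
                    break
            proteome[s.accession] = seq
        else:
            raise RuntimeError(f"could not make a unique peptide for {s.accession}:{s.position}")
        s.peptide = peptide
        s.peptide_cys_index = pos0 - start + 1

    # per-replicate PSM emission with the configured detection probability
    tag_for = {psm_io.REDUCED: "NEM", psm_io.OXIDIZED: "BPM"}
    psm_tables: dict[tuple[str, int], list[PsmRecord]] = {
        (cond, rep): [] for cond in CONDITIONS for rep in range(1, N_REPLICATES + 1)
    }
    for s in sites:
        if s.region is None:
            label_sets = {cond: [None] for cond in CONDITIONS}
        else:
            rt, cold = _PATTERN_BY_LETTER[s.region]
            label_sets = {"RT": sorted(rt), "Cold": sorted(cold)}
        for cond in CONDITIONS:
            for label in label_sets[cond]:
                for rep in range(1, N_REPLICATES + 1):
                    if rng.random() > config.detection_probability:
                        continue
                    mods = [] if label is None else [(s.peptide_cys_index, tag_for[label])]
                    psm_tables[(cond, rep)].append(
                        PsmRecord(
                            peptide_sequence=s.peptide,
                            accession=s.accession,
                            modifications=mods,
                            condition=cond,
                            replicate=rep,
                            abundance=float(np.exp(rng.normal(18, 1))),
                        )
                    )

    localization = {
        acc: sorted(
            rng.choice(COMPARTMENTS, size=int(rng.integers(1, 4)), replace=False).tolist()
        )
        for acc in accessions
    }

    # log-normal abundance matrix with planted cold-shifted proteins
    samples = [f"{cond}_{rep}" for cond in CONDITIONS for rep in range(1, N_REPLICATES + 1)]
    sample_conditions = {s: s.split("_")[0] for s in samples}
    diff = rng.choice(config.n_proteins, size=config.n_differential_proteins, replace=False)
    protein_log2fc = {acc: 0.0 for acc in accessions}
    for i in diff:
        protein_log2fc[accessions[int(i)]] = config.abundance_log2fc
    base = rng.uniform(15, 25, size=config.n_proteins)
    data = np.empty((config.n_proteins, len(samples)))
    for col, sample in enumerate(samples):
        shift = np.array(
            [
                protein_log2fc[acc] if sample_conditions[sample] == "Cold" else 0.0
                for acc in accessions
            ]
        )
        data[:, col] = 2.0 ** (base + shift + rng.normal(0, config.abundance_sigma, size=config.n_proteins))
    abundance = pd.DataFrame(data, index=accessions, columns=samples)
    abundance.index.name = "accession"

    bundle = SimulatedBundle(
        config=config,
        proteome=proteome,
        psm_tables=psm_tables,
        localization=localization,
        abundance=abundance,
        sample_conditions=sample_conditions,
        sites=sites,
        protein_log2fc=protein_log2fc,
    )
    audit(bundle)
    return bundle


def audit(bundle: SimulatedBundle) -> None:
    """Internal consistency pass: emitted files must match the truth table."""
    for s in bundle.sites:
        seq = bundle.proteome[s.accession]
        if seq[s.position - 1] != "C":
            raise AssertionError(f"{s.accession}:{s.position} is not a cysteine")
        if seq.count(s.peptide) != 1:
            raise AssertionError(f"peptide for {s.accession}:{s.position} is not unique")
        if s.peptide[s.peptide_cys_index - 1] != "C":
            raise AssertionError(f"peptide cysteine index wrong for {s.accession}:{s.position}")
        for res, fp in s.motif_planted:
            if seq[s.position - 1 + fp] != res:
                raise AssertionError(f"motif plant missing at {s.accession}:{s.position}{fp:+d}")
    for records in bundle.psm_tables.values():
        for r in records:
            if r.peptide_sequence not in bundle.proteome[r.accession]:
                raise AssertionError(f"emitted peptide not in protein {r.accession}")
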