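"""End-to-end orchestration of the redoxome analysis stages.

``run_all`` executes classification -> percentages -> reproducibility ->
Venn regions -> motif scoring -> compartment summaries -> volcano in
dependency order, writing every table plus a manifest with row counts into
the output directory.  It is deterministic for a given config: rerunning
produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import yaml

from cysredox import abundance as ab
from cysredox import motif as mo
from cysredox import psm_io, summaries
from cysredox.redox_classify import classify_sites, percent_redox, CysteineSiteObservation
from cysredox.repro_regions import (
    assignments_to_frame,
    assign_regions,
    reproducible_sites,
    select_reactive,
    venn_counts,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclasses.dataclass
class RunConfig:
    fasta: str
    psm_tables: list[dict]  # each: {path, condition, replicate}
    localization: str | None = None
    abundance: str | None = None
    sample_sheet: str | None = None
    min_replicates: int = 2
    n_replicates: int = 3
    include_ambiguous: bool = False
    motif_alpha: float = 0.05
    motif_foreground: str = "dynamic"  # or "reactive"
    motif_threshold: float | None = None
    conditions: tuple[str, str] = ("RT", "Cold")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not Path(self.fasta).exists():
            raise FileNotFoundError(f"FASTA not found: {self.fasta}")
        if not self.psm_tables:
            raise ValueError("no PSM tables configured")
        for entry in self.psm_tables:
            for key in ("path", "condition", "replicate"):
                if key not in entry:
                    raise ValueError(f"psm_tables entry missing {key!r}: {entry}")
            if not Path(entry["path"]).exists():
                raise FileNotFoundError(f"PSM table not found: {entry['path']}")
        for attr in ("localization", "abundance", "sample_sheet"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr} file not found: {p}")
        if self.min_replicates > self.n_replicates:
            raise ValueError("min_replicates exceeds n_replicates")


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage; returns the manifest (also written to disk)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logging.getLogger("cysredox").addHandler(log_handler)
    manifest: dict = {"outputs": {}, "stages": []}

    def _write(name: str, path: Path, n_rows: int) -> None:
        manifest["outputs"][name] = {"path": str(path), "rows": int(n_rows)}

    try:
        cfg_dict = dataclasses.asdict(config)
        cfg_dict["conditions"] = list(config.conditions)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg_dict, fh)

        stage = "classify"
        db = psm_io.read_fasta(config.fasta)
        psms = []
        for entry in config.psm_tables:
            psms.extend(
                psm_io.read_psm_table(entry["path"], entry["condition"], int(entry["replicate"]))
            )
        observations = classify_sites(psms, db, include_ambiguous=config.include_ambiguous)
        site_path = outdir / "site_table.tsv"
        psm_io.write_site_table(observations, site_path)
        _write("site_table", site_path, len(observations))
        manifest["stages"].append(stage)

        stage = "percentages"
        pct = percent_redox(observations, config.conditions)
        pct_path = outdir / "group_summary.json"
        with open(pct_path, "w") as fh:
            json.dump(pct, fh, indent=1)
        _write("group_summary", pct_path, len(pct["conditions"]))
        manifest["stages"].append(stage)

        stage = "regions"
        repro = reproducible_sites(
            observations, min_replicates=config.min_replicates, n_replicates=config.n_replicates
        )
        assignments = assign_regions(repro, *config.conditions)
        regions_df = assignments_to_frame(assignments)
        regions_path = outdir / "regions.tsv"
        regions_df.to_csv(regions_path, sep="\t", index=False)
        _write("regions", regions_path, len(regions_df))
        counts = venn_counts(assignments)
        venn_path = outdir / "venn_counts.json"
        with open(venn_path, "w") as fh:
            json.dump(counts, fh, indent=1)
        _write("venn_counts", venn_path, counts["n_sites"])
        reactive = select_reactive(assignments)
        reactive_path = outdir / "reactive_sites.tsv"
        assignments_to_frame(reactive).to_csv(reactive_path, sep="\t", index=False)
        _write("reactive_sites", reactive_path, len(reactive))
        manifest["stages"].append(stage)

        stage = "motif"
        wanted = "reactive" if config.motif_foreground == "reactive" else "dynamic"
        foreground_sites = [a for a in assignments if wanted in a.classes]
        if foreground_sites:
            fg = [mo.extract_window(db, a.accession, a.position) for a in foreground_sites]
            bg = mo.background_frequencies(mo.all_cysteine_windows(db))
            threshold = config.motif_threshold
            if threshold is None:
                threshold = mo.significance_threshold(config.motif_alpha)
            pwm = mo.build_pwm(fg, bg, threshold=threshold)
            pwm_path = outdir / "pwm_scores.tsv"
            pwm.to_frame().to_csv(pwm_path, sep="\t", index=False)
            _write("pwm_scores", pwm_path, 20 * 14)
            heat_path = outdir / "pwm_heatmap.tsv"
            mo.pwm_heatmap_matrix(pwm).to_csv(heat_path, sep="\t")
            _write("pwm_heatmap", heat_path, 20)
        else:
            logger.warning("no %s sites; motif stage skipped", wanted)
        manifest["stages"].append(stage)

        stage = "summarize"
        if config.localization:
            table = summaries.read_localization_table(config.localization)
            localized, missing = summaries.join_localization(observations, table)
            comp = summaries.compartment_percentages(localized, config.conditions)
            comp_path = outdir / "compartments.tsv"
            comp.to_csv(comp_path, sep="\t", index=False)
            _write("compartments", comp_path, len(comp))
            manifest["unannotated_proteins"] = len(missing)
        manifest["stages"].append(stage)

        stage = "volcano"
        if config.abundance and config.sample_sheet:
            matrix = ab.read_abundance_matrix(config.abundance)
            sheet = ab.read_sample_sheet(config.sample_sheet)
            sample_conditions = dict(zip(sheet["sample"].astype(str), sheet["condition"].astype(str)))
            normalized = ab.total_sum_normalize(matrix)
            vol = ab.volcano(normalized, sample_conditions, config.conditions)
            vol_path = outdir / "volcano.tsv"
            vol.to_csv(vol_path, sep="\t", index=False)
            _write("volcano", vol_path, len(vol))
        manifest["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001 - rewrap with the failing stage
        raise StageError(stage, exc) from exc
    finally:
        logging.getLogger("cysredox").removeHandler(log_handler)
        log_handler.close()

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
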