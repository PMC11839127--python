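"""End-to-end orchestration with deterministic seeding and a run manifest.

Stages run in a fixed order: simulate (or load counts) -> QC -> activity
-> differential activity -> allelic -> interaction -> repeat annotation
-> motif scanning and disruption -> enrichment -> gene linking and
concordance -> regional regression.  A single seed is expanded into
per-stage substreams so any stage can be re-run reproducibly; the
manifest records the configuration, per-filter attrition and the SHA-256
of every output file, and two runs with the same seed produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import activity as act
from . import allelic as allelic_mod
from . import linking, motifs, qc, repeats, simulate
from .stats import dedup_variants, enrich_features

log = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "qc", "activity", "diff_activity", "allelic",
               "interaction", "annotate", "motifs", "enrich", "link",
               "regional")
FLOAT_FORMAT = "%.6g"


@dataclass
class PipelineConfig:
    outdir: str = "mprakit_run"
    seed: int = 0
    counts_path: str | None = None      # precomputed counts TSV; else simulate
    library_path: str | None = None
    sim: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig)
    qc: qc.QCConfig = field(default_factory=qc.QCConfig)
    fdr_threshold: float = 0.1
    moderation: bool = True
    stages: dict = field(default_factory=dict)  # stage -> bool toggles

    def enabled(self, stage: str) -> bool:
        return self.stages.get(stage, True)

    def validate(self) -> None:
        if self.fdr_threshold <= 0:
            raise ValueError("fdr_threshold must be positive")
        # gating dependencies between stages
        deps = {"allelic": "activity", "interaction": "allelic",
                "diff_activity": "activity", "enrich": "activity"}
        for stage, needs in deps.items():
            if self.enabled(stage) and not self.enabled(needs):
                raise ValueError(
                    f"stage '{stage}' requires stage '{needs}' to be enabled")
        if self.counts_path is not None:
            for p in (self.counts_path, self.library_path):
                if p is None or not Path(p).exists():
                    raise ValueError(f"input path missing or absent: {p}")


def _substream(seed: int, stage: str) -> np.random.Generator:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:4], "big"))


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT,
              lineterminator="\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages; return the manifest (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "attrition": {},
                      "outputs": {}}

    # --- simulate or load --------------------------------------------------
    sim_cfg = dataclasses.replace(config.sim, rng_seed=config.seed)
    if config.counts_path is None:
        rng_lib = _substream(config.seed, "library")
        library, truth = simulate.generate_library(sim_cfg, rng_lib)
        rng_counts = _substream(config.seed, "counts")
        barcode_map = simulate.assign_barcodes(library, sim_cfg, rng_counts)
        counts = simulate.generate_counts(library, truth, sim_cfg, rng_counts,
                                          barcode_map)
        ann = simulate.generate_annotations(
            library, sim_cfg, _substream(config.seed, "annotations"),
            truth=truth)
        _write(library, outdir / "library.tsv")
        _write(truth, outdir / "truth.tsv")
        _write(barcode_map, outdir / "barcode_map.tsv")
        _write(counts, outdir / "counts.tsv")
        simulate.write_library_fasta(library, outdir / "library.fasta")
        simulate.write_repeats_bed(ann.repeats, outdir / "repeats.bed")
        manifest["stages"].append("simulate")
    else:
        counts = pd.read_csv(config.counts_path, sep="\t")
        library = pd.read_csv(config.library_path, sep="\t")
        truth = None
        ann = None

    # --- qc ----------------------------------------------------------------
    summaries, qc_report = qc.run_qc(counts, config.qc)
    manifest["attrition"] = qc_report
    _write(summaries, outdir / "element_summaries.tsv")
    manifest["stages"].append("qc")

    negatives = library.loc[library["category"] == "negative_control",
                            "element_id"]

    # --- activity ----------------------------------------------------------
    results = variant_activity = diff = None
    if config.enabled("activity"):
        alphas = act.estimate_alpha(summaries, config.qc.pseudocount)
        tested = act.mad_test(alphas, negatives)
        results, variant_activity = act.call_active(
            tested, library, config.fdr_threshold)
        _write(results, outdir / "activity.tsv")
        _write(variant_activity, outdir / "variant_activity.tsv")
        manifest["stages"].append("activity")
        if config.enabled("diff_activity"):
            diff = act.differential_activity(summaries, results,
                                             config.fdr_threshold)
            _write(diff, outdir / "differential_activity.tsv")
            manifest["stages"].append("diff_activity")

    # --- allelic + interaction ---------------------------------------------
    emvars = None
    if config.enabled("allelic") and results is not None:
        per_cond = []
        for cond in sorted(summaries["condition"].unique()):
            per_cond.append(allelic_mod.test_allelic(
                summaries, library, variant_activity, cond,
                config.moderation, config.fdr_threshold))
        emvars = pd.concat(per_cond, ignore_index=True)
        _write(emvars, outdir / "allelic.tsv")
        manifest["stages"].append("allelic")
        if config.enabled("interaction") and len(emvars):
            inter = allelic_mod.test_interaction(
                summaries, library, emvars, config.fdr_threshold)
            _write(inter, outdir / "interaction.tsv")
            manifest["stages"].append("interaction")

    # --- repeats -----------------------------------------------------------
    alu_context = None
    if config.enabled("annotate") and ann is not None:
        alu_context = repeats.annotate_alu_context(library, ann.repeats)
        _write(alu_context, outdir / "alu_context.tsv")
        manifest["stages"].append("annotate")

    # --- motifs ------------------------------------------------------------
    disruptions = None
    if config.enabled("motifs") and ann is not None:
        pwm_list = [motifs.PWM(mid, mat) for mid, mat in ann.pwms.items()]
        hits = motifs.scan_elements(library, pwm_list,
                                    fdr_threshold=config.fdr_threshold)
        _write(hits, outdir / "motif_hits.tsv")
        disruptions = motifs.disruption_table(library, pwm_list)
        _write(disruptions, outdir / "motif_disruption.tsv")
        if emvars is not None and len(emvars):
            pooled = motifs.correlate_disruption(
                disruptions[disruptions["delta"] != 0],
                emvars[emvars["condition"] == "vehicle"])
            _write(pooled, outdir / "disruption_correlation.tsv")
        manifest["stages"].append("motifs")

    # --- enrichment --------------------------------------------------------
    if (config.enabled("enrich") and results is not None
            and alu_context is not None):
        merged = results.merge(
            library[["element_id", "variant_id", "allele", "category"]],
            on="element_id")
        veh = merged[(merged["condition"] == "vehicle")
                     & (merged["category"].isin(["gwas", "caqtl"]))]
        best = dedup_variants(veh)
        both_tested = veh.groupby("variant_id")["element_id"].nunique() == 2
        inactive_ok = ~veh.groupby("variant_id")["active"].any()
        units = best.copy()
        units["group"] = np.where(
            units["active"], "target",
            np.where(units["variant_id"].map(both_tested & inactive_ok),
                     "background", ""))
        units = units[units["group"] != ""]
        alu_ids = set(alu_context["element_id"])
        sine_ids = set(alu_context["element_id"])  # all Alus are SINEs here
        units["alu_overlap"] = units["element_id"].isin(alu_ids)
        units["sine_overlap"] = units["element_id"].isin(sine_ids)
        enr = enrich_features(units, ["sine_overlap", "alu_overlap"],
                              fdr_threshold=config.fdr_threshold)
        _write(enr, outdir / "enrichment.tsv")
        manifest["stages"].append("enrich")

    # --- linking + concordance --------------------------------------------
    if config.enabled("link") and ann is not None:
        prom = linking.link_promoters(library, ann.genes)
        loop = linking.link_loops(library, ann.loops, ann.genes)
        links = pd.concat([prom, loop], ignore_index=True)
        _write(links, outdir / "gene_links.tsv")
        if diff is not None and len(diff) and ann.de_table is not None:
            conc = linking.concordance_test(diff, ann.de_table, links)
            (outdir / "concordance.json").write_text(
                json.dumps(conc, indent=2, default=float) + "\n")
        manifest["stages"].append("link")

    # --- regional ----------------------------------------------------------
    if config.enabled("regional") and ann is not None:
        reg = linking.regional_regression(ann.expression, ann.gwas_regional)
        _write(reg, outdir / "regional_regression.tsv")
        manifest["stages"].append("regional")

    for f in sorted(outdir.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return manifest
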