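"""End-to-end emulated-study pipeline and the printed-table report.

``run_pipeline`` drives the full synthetic study: cohort generation ->
oracle prediction -> three-source adjudication -> rollup to the display
lattice -> stratified metrics -> paired reader study -> missed-slide Venn
analysis -> report bundle. Every intermediate is written to disk as plain
text, stamped with a hash of the configuration, and the whole run is
reproducible from (config, seed) alone. ``fixture_report`` computes the
same metric battery directly from the published contingency-count
fixtures, with no simulation.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fileio, fixtures
from .cohort import SlideRecord
from .gridding import AREA_THRESHOLD_UM2, GridLabelMap, rollup_display
from .ground_truth import adjudicate
from .metrics import (DEFAULT_Z, likelihood_ratios, metrics_table,
                      round_half_up, sens_spec, stratify)
from .reader_study import (RevisionTable, classify_revisions, mcnemar_test,
                           missed_slides, paired_performance, venn_overlap)
from .synthetic_data import (CohortConfig, OracleConfig, ReaderProfile,
                             default_reader_profiles, generate_cohort,
                             simulate_oracle, simulate_reader)

log = logging.getLogger("slidegrid")


@dataclass
class StudyConfig:
    """Everything needed to reproduce one emulated-study run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    oracle: OracleConfig = field(default_factory=OracleConfig)
    reader_profiles: list[ReaderProfile] | None = None  # None -> defaults
    #: error rates of the two ground-truth annotators in the adjudication
    annotator_sensitivity: float = 0.98
    annotator_specificity: float = 0.999
    z: float = DEFAULT_Z
    mcnemar_variant: str = "auto"
    rollup_rule: str = "any"
    area_threshold_um2: float = AREA_THRESHOLD_UM2
    run_readers: bool = True
    seed: int = 0

    def profiles(self) -> list[ReaderProfile]:
        return (self.reader_profiles
                if self.reader_profiles is not None
                else default_reader_profiles(self.oracle))

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        if self.reader_profiles is not None:
            doc["reader_profiles"] = [dataclasses.asdict(p)
                                      for p in self.reader_profiles]
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "StudyConfig":
        doc = dict(doc)
        if "cohort" in doc:
            c = dict(doc["cohort"])
            if "slide_size_grids" in c:
                rr, cc = c["slide_size_grids"]
                c["slide_size_grids"] = (tuple(rr), tuple(cc))
            if isinstance(c.get("lesion_area_mm2"), list):
                c["lesion_area_mm2"] = tuple(c["lesion_area_mm2"])
            doc["cohort"] = CohortConfig(**c)
        if "oracle" in doc:
            o = dict(doc["oracle"])
            for k in ("score_beta_positive", "score_beta_negative"):
                if isinstance(o.get(k), list):
                    o[k] = tuple(o[k])
            doc["oracle"] = OracleConfig(**o)
        if doc.get("reader_profiles") is not None:
            doc["reader_profiles"] = [ReaderProfile(**p)
                                      for p in doc["reader_profiles"]]
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _noisy_observer(truth: GridLabelMap, sens: float, spec: float,
                    rng: np.random.Generator, source: str) -> GridLabelMap:
    hit = np.where(truth.labels, sens, 1.0 - spec)
    return GridLabelMap(layout=truth.layout,
                        labels=rng.random(truth.labels.shape) < hit,
                        level=truth.level, source=source)


def run_pipeline(config: StudyConfig, outdir: str | Path) -> dict:
    """Run the emulated study end to end; returns result objects and paths.

    Stage order: simulate -> grid predictions -> adjudicate -> evaluate ->
    reader study -> Venn -> report. Any stage error aborts with the stage
    name and offending slide id in the exception message.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = fileio.config_hash(config.to_dict())
    header = {"config_hash": chash, "seed": str(config.seed)}
    config.to_yaml(outdir / "config.yaml")
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(6)

    log.info("stage=simulate n_slides=%d seed=%d",
             config.cohort.n_slides, config.seed)
    records = generate_cohort(config.cohort, seed=int(seeds[0]))
    fileio.write_manifest(outdir / "manifest.yaml", records,
                          extra={"config_hash": chash})

    profiles = config.profiles()
    adj_logs = []
    rng_ann = np.random.default_rng(int(seeds[2]))
    reader_pairs = []
    truths_display: dict[str, GridLabelMap] = {}
    records_display: list[SlideRecord] = []
    for i, rec in enumerate(records):
        stage = "grid"
        try:
            rec.prediction = simulate_oracle(
                rec.truth, config.oracle,
                seed=int((seeds[1] + i) % (2 ** 31)))
            stage = "adjudicate"
            ann_a = _noisy_observer(rec.truth, config.annotator_sensitivity,
                                    config.annotator_specificity, rng_ann,
                                    "annotator_a")
            ann_b = _noisy_observer(rec.truth, config.annotator_sensitivity,
                                    config.annotator_specificity, rng_ann,
                                    "annotator_b")
            adj_truth, adj_log = adjudicate(ann_a, ann_b, rec.prediction,
                                            chief=rec.truth, log="disputed")
            adj_log.insert(0, "slide_id", rec.slide_id)
            adj_logs.append(adj_log)
            rec.truth = adj_truth
            stage = "rollup"
            truth_disp = rollup_display(rec.truth, config.rollup_rule,
                                        config.area_threshold_um2)
            pred_disp = rollup_display(rec.prediction, config.rollup_rule,
                                       config.area_threshold_um2)
            truths_display[rec.slide_id] = truth_disp
            records_display.append(SlideRecord(
                slide_id=rec.slide_id, procedure=rec.procedure,
                truth=truth_disp, prediction=pred_disp))
            if config.run_readers:
                # readers annotate the prediction lattice: their revision
                # probabilities are conditioned on the AI's per-grid error
                # rates, which hold at the scale the oracle runs at
                stage = "readers"
                for j, prof in enumerate(profiles):
                    pair = simulate_reader(
                        rec.truth, rec.prediction, prof,
                        slide_id=rec.slide_id,
                        seed=int((seeds[3] + 1000 * j + i) % (2 ** 31)))
                    reader_pairs.append(pair)
                    rec.readers.setdefault(prof.reader_id, {}).update(
                        no_ai=pair.before, with_ai=pair.after)
        except Exception as exc:
            raise type(exc)(
                f"pipeline stage '{stage}' failed on slide "
                f"{rec.slide_id}: {exc}") from exc

    fileio.write_grid_table(outdir / "truth_fine.csv",
                            {r.slide_id: r.truth for r in records}, header)
    fileio.write_grid_table(outdir / "pred_fine.csv",
                            {r.slide_id: r.prediction for r in records},
                            header)
    fileio._write_csv(outdir / "adjudication_log.csv",
                      pd.concat(adj_logs, ignore_index=True), header)

    log.info("stage=evaluate")
    strata: dict = {}
    for key in ("all", "procedure", "cancer_area_le_50mm2"):
        strata.update(stratify(records, key))  # fine-level grid counts
    table_fine = metrics_table(strata, config.z)
    table_fine.insert(0, "level", "fine_0.25mm")
    strata_disp: dict = {}
    for key in ("all", "procedure"):
        strata_disp.update(stratify(records_display, key))
    table_disp = metrics_table(strata_disp, config.z)
    table_disp.insert(0, "level", "display_0.5mm")
    report_table = pd.concat([table_fine, table_disp], ignore_index=True)
    fileio._write_csv(outdir / "metrics.csv", report_table, header)
    fileio.write_json(outdir / "metrics.json",
                      {"rows": report_table.to_dict(orient="records")},
                      header)

    results: dict = {"config_hash": chash, "records": records,
                     "metrics": report_table, "outdir": outdir}

    if config.run_readers:
        log.info("stage=readers n_pairs=%d", len(reader_pairs))
        truths_fine = {r.slide_id: r.truth for r in records}
        perf = paired_performance(reader_pairs, truths_fine, config.z)
        fileio._write_csv(outdir / "reader_performance.csv", perf, header)
        revisions: dict[str, RevisionTable] = {}
        for pair in reader_pairs:
            tab = classify_revisions(pair, truths_fine[pair.slide_id])
            revisions[pair.reader_id] = (
                revisions.get(pair.reader_id,
                              RevisionTable(pair.reader_id)) + tab)
        rev_rows = []
        for rid in sorted(revisions):
            tab = revisions[rid].with_pvalues(config.mcnemar_variant)
            rev_rows.append({
                "reader_id": rid, "fn_to_tp": tab.fn_to_tp,
                "tp_to_fn": tab.tp_to_fn, "fp_to_tn": tab.fp_to_tn,
                "tn_to_fp": tab.tn_to_fp,
                "p_positive": tab.mcnemar_positive.pvalue,
                "p_negative": tab.mcnemar_negative.pvalue,
                "method_positive": tab.mcnemar_positive.method,
                "method_negative": tab.mcnemar_negative.method})
        rev_table = pd.DataFrame(rev_rows)
        fileio._write_csv(outdir / "revisions.csv", rev_table, header)
        fileio.write_reader_table(outdir / "reader_annotations.csv",
                                  reader_pairs, header)

        log.info("stage=venn")
        miss_sets = []
        by_reader: dict[str, dict[str, GridLabelMap]] = {}
        for pair in reader_pairs:
            by_reader.setdefault(pair.reader_id, {})[pair.slide_id] = \
                pair.before
        for rid in sorted(by_reader):
            miss_sets.append(missed_slides(rid, by_reader[rid],
                                           truths_fine))
        ai_maps = {r.slide_id: r.prediction for r in records}
        miss_sets.append(missed_slides("AI", ai_maps, truths_fine))
        venn = venn_overlap(miss_sets)
        fileio.write_json(outdir / "venn.json", venn, header)
        results.update(reader_performance=perf, revisions=rev_table,
                       venn=venn)

    _write_markdown_report(outdir, config, results, header)
    results["report"] = outdir / "report.md"
    return results


def _write_markdown_report(outdir: Path, config: StudyConfig, results: dict,
                           header: dict) -> None:
    lines = ["# slidegrid emulated-study report", ""]
    lines += [f"- config_hash: {header['config_hash']}",
              f"- seed: {config.seed}",
              f"- slides: {len(results['records'])}", ""]
    lines += ["## Metrics", "",
              results["metrics"].to_markdown(index=False), ""]
    if "revisions" in results:
        lines += ["## Reader revisions", "",
                  results["revisions"].to_markdown(index=False), ""]
    if "venn" in results:
        lines += ["## Missed-slide Venn", "",
                  f"union of miss sets: {results['venn']['union']}", ""]
    (outdir / "report.md").write_text("\n".join(lines))


def fixture_report(z: float = DEFAULT_Z) -> pd.DataFrame:
    """Metric battery computed from the published contingency fixtures.

    One row per (table, stratum) with percent-scale estimates and Wald
    bounds (half-up rounded to two decimals, as printed) and the
    likelihood ratios from the unrounded estimates.
    """
    rows = []
    for table, by_stratum in (("grid", fixtures.TABLE2A),
                              ("slide", fixtures.TABLE2B)):
        for stratum, counts in by_stratum.items():
            sens, spec = sens_spec(counts, z)
            lrs = likelihood_ratios(sens.estimate, spec.estimate)
            s_pct, s_lo, s_hi = sens.as_percent()
            p_pct, p_lo, p_hi = spec.as_percent()
            rows.append({
                "granularity": table, "stratum": stratum,
                "tp": counts.tp, "fn": counts.fn, "tn": counts.tn,
                "fp": counts.fp,
                "sensitivity_pct": s_pct, "sens_ci_low_pct": s_lo,
                "sens_ci_high_pct": s_hi,
                "specificity_pct": p_pct, "spec_ci_low_pct": p_lo,
                "spec_ci_high_pct": p_hi,
                "lr_positive": round_half_up(lrs.lr_positive, 2)
                if math.isfinite(lrs.lr_positive) else math.inf,
                "lr_negative": round_half_up(lrs.lr_negative, 3)})
    return pd.DataFrame(rows)


def fixture_revision_report(variant: str = "auto") -> pd.DataFrame:
    """Published reader revision counts with recomputed McNemar p-values."""
    rows = []
    for rid, d in fixtures.TABLE3.items():
        p_pos = mcnemar_test(d["fn_to_tp"], d["tp_to_fn"], variant)
        p_neg = mcnemar_test(d["fp_to_tn"], d["tn_to_fp"], variant)
        rows.append({"reader_id": rid, **d,
                     "p_positive": p_pos.pvalue, "method_positive":
                     p_pos.method,
                     "p_negative": p_neg.pvalue, "method_negative":
                     p_neg.method})
    return pd.DataFrame(rows)
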