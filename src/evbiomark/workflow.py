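"""End-to-end pipeline orchestration and report generation.

Runs quantification (when alignments are given), biotype composition,
both differential-expression contrasts, the tumor-origin intersection
filter, the diagnostic panel, and clinical-status association, writing
TSV/JSON outputs plus a run manifest and a human-readable markdown
summary.  Every output is a pure function of (inputs, config, seed), so a
re-run with the same config is byte-identical.
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
import yaml

from . import __version__
from .alignments import load_alignments
from .annotation import load_annotations
from .clinical import ClinicalError, associate_markers, dichotomize, receptor_status_model
from .composition import biotype_fractions, compare_fractions
from .countmatrix import CountMatrix, SampleTable
from .diffexpr import DesignSpec, call_significant, normalize_within_biotype, run_de
from .discovery import annotate_candidates, intersect_candidates
from .panelmodel import build_panel, marker_design
from .quantify import count_matrix_from_alignments
from .simdata import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Inputs and parameters of a full pipeline run.

    Exactly one input route must be configured: a counts TSV (plus sample
    sheet), alignments (plus annotation and sample sheet), or
    ``simulate=True`` to drive the run from the synthetic generator.
    """

    outdir: str = "evbiomark_out"
    counts: str | None = None
    sample_sheet: str | None = None
    annotation: list[str] = field(default_factory=list)
    alignments: dict[str, str] = field(default_factory=dict)  # sample -> path
    simulate: bool = False
    sim_overrides: dict = field(default_factory=dict)
    alpha: float = 0.05
    min_abs_lfc: float = 1.0
    prior_df: float = 10.0
    prior_count: float = 2.0
    detection_threshold: int = 1
    paired: bool = True
    bh_per_biotype: bool = True
    her2_rule: str = "3"
    criterion: str = "aic"
    clinical_variables: list[str] = field(default_factory=lambda: ["ER", "HER2_IHC"])
    seed: int = 0

    def validate(self) -> None:
        routes = sum([self.counts is not None, bool(self.alignments), self.simulate])
        if routes != 1:
            raise PipelineError(
                "configure exactly one input route: counts, alignments, or simulate"
            )
        if not 0 < self.alpha < 1:
            raise PipelineError("alpha must be in (0, 1)")
        if self.min_abs_lfc < 0:
            raise PipelineError("min_abs_lfc must be >= 0")
        for p in [self.counts, self.sample_sheet, *self.annotation, *self.alignments.values()]:
            if p is not None and not Path(p).exists():
                raise PipelineError(f"input file not found: {p}")

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (excludes outdir, so
        the same analysis written to two locations hashes identically)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the in-memory outputs bundle."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict = {"config": config}

    # --- stage: input -----------------------------------------------------
    stage = "input"
    try:
        if config.simulate:
            sim = SimulationConfig(seed=config.seed, **config.sim_overrides)
            cm, samples, truth = simulate_dataset(sim)
            truth.to_json(outdir / "ground_truth.json")
            outputs["ground_truth"] = truth
            logger.info("simulated dataset: %d features x %d samples", *cm.counts.shape)
        elif config.counts is not None:
            cm = CountMatrix.from_tsv(config.counts)
            samples = SampleTable.from_tsv(config.sample_sheet)
            logger.info("quantify stage skipped: counts supplied directly")
            outputs["quantify_skipped"] = True
        else:
            stage = "quantify"
            ann = load_annotations(config.annotation)
            aln = {s: load_alignments(p) for s, p in sorted(config.alignments.items())}
            cm, unassigned = count_matrix_from_alignments(aln, ann)
            samples = SampleTable.from_tsv(config.sample_sheet)
            _write_tsv(unassigned.to_frame("unassigned_reads"), outdir / "unassigned.tsv")
        cm.to_tsv(outdir / "counts.tsv")
        samples.to_tsv(outdir / "samples.tsv")
        outputs["counts"] = cm
        outputs["samples"] = samples
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: composition ----------------------------------------------
    try:
        fractions = biotype_fractions(cm)
        _write_tsv(fractions, outdir / "biotype_fractions.tsv")
        comp = compare_fractions(fractions, samples, "PreOp", "HC", alpha=config.alpha)
        _write_tsv(comp, outdir / "composition_preop_vs_hc.tsv")
        outputs["fractions"] = fractions
        outputs["composition_preop_vs_hc"] = comp
        if samples.samples_in_group("PostOp"):
            comp_post = compare_fractions(
                fractions, samples, "PreOp", "PostOp", paired=True, alpha=config.alpha
            )
            _write_tsv(comp_post, outdir / "composition_preop_vs_postop.tsv")
            outputs["composition_preop_vs_postop"] = comp_post
    except Exception as exc:
        raise PipelineError(f"stage 'composition' failed: {exc}") from exc

    # --- stage: differential expression -----------------------------------
    try:
        de_hc = run_de(
            cm,
            samples,
            DesignSpec("PreOp_vs_HC", paired=False),
            prior_df=config.prior_df,
            prior_count=config.prior_count,
            bh_per_biotype=config.bh_per_biotype,
        )
        de_post = run_de(
            cm,
            samples,
            DesignSpec("PreOp_vs_PostOp", paired=config.paired),
            prior_df=config.prior_df,
            prior_count=config.prior_count,
            bh_per_biotype=config.bh_per_biotype,
        )
        _write_tsv(de_hc, outdir / "de_preop_vs_hc.tsv")
        _write_tsv(de_post, outdir / "de_preop_vs_postop.tsv")
        outputs["de_preop_vs_hc"] = de_hc
        outputs["de_preop_vs_postop"] = de_post
    except Exception as exc:
        raise PipelineError(f"stage 'diffexpr' failed: {exc}") from exc

    # --- stage: discovery --------------------------------------------------
    try:
        sig_hc = call_significant(de_hc, alpha=config.alpha, min_abs_lfc=config.min_abs_lfc)
        sig_post = call_significant(de_post, alpha=config.alpha, min_abs_lfc=config.min_abs_lfc)
        up_hc = sig_hc[sig_hc["direction"] == "up"]
        down_post = sig_post[sig_post["direction"] == "up"]  # higher PreOp = drops PostOp
        candidates = intersect_candidates(up_hc, down_post)
        candidates = annotate_candidates(
            candidates, cm, samples, detection_threshold=config.detection_threshold
        )
        _write_tsv(candidates, outdir / "candidates.tsv")
        outputs["candidates"] = candidates
    except Exception as exc:
        raise PipelineError(f"stage 'discovery' failed: {exc}") from exc

    # --- stage: panel model -------------------------------------------------
    try:
        if len(candidates) > 0:
            normalized, _ = normalize_within_biotype(cm)
            ids = samples.samples_in_group("HC") + samples.samples_in_group("PreOp")
            y = np.array(
                [1 if g == "PreOp" else 0 for g in samples.table.set_index("sample_id").loc[ids, "group"]]
            )
            X = marker_design(normalized, candidates.index, ids)
            keep = [c for c in X.columns if X[c].nunique() > 1]
            panel = build_panel(X[keep], y, criterion=config.criterion)
            with open(outdir / "panel_model.json", "w") as fh:
                json.dump(panel.to_dict(), fh, indent=2, sort_keys=True)
            outputs["panel"] = panel
        else:
            logger.info("no biomarker candidates; panel stage skipped")
    except Exception as exc:
        raise PipelineError(f"stage 'panelmodel' failed: {exc}") from exc

    # --- stage: clinical ----------------------------------------------------
    try:
        clin_table = samples.clinical()
        assoc_all = {}
        models = {}
        if len(clin_table.columns) and len(candidates) > 0:
            for var in config.clinical_variables:
                try:
                    labels = dichotomize(clin_table, var, her2_rule=config.her2_rule)
                    assoc = associate_markers(cm, samples, labels, feature_ids=candidates.index)
                    _write_tsv(assoc, outdir / f"association_{var}.tsv")
                    assoc_all[var] = assoc
                    model = receptor_status_model(
                        cm, samples, labels, candidates.index, criterion=config.criterion
                    )
                    with open(outdir / f"status_model_{var}.json", "w") as fh:
                        json.dump(model.to_dict(), fh, indent=2, sort_keys=True)
                    models[var] = model
                except ClinicalError as exc:
                    logger.warning("clinical variable %s skipped: %s", var, exc)
        outputs["associations"] = assoc_all
        outputs["status_models"] = models
    except Exception as exc:
        raise PipelineError(f"stage 'clinical' failed: {exc}") from exc

    # --- manifest and report -------------------------------------------------
    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_features": int(cm.counts.shape[0]),
        "n_samples": int(cm.counts.shape[1]),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    outputs["manifest"] = manifest
    write_report(outputs, outdir / "report.md")
    return outputs


def _fmt_roc(s) -> str:
    return (
        f"AUC {s.auc:.3f} (95% CI {s.ci_low:.3f}-{s.ci_high:.3f}, p = {s.p:.3g}), "
        f"sensitivity {s.sensitivity:.2f}, specificity {s.specificity:.2f}"
    )


def write_report(outputs: dict, path: str | Path) -> None:
    """Render the outputs bundle as a markdown summary.

    Missing stages are reported as absent rather than failing, so a report
    can always be produced from partial outputs.  Regeneration from the
    same bundle is idempotent.
    """
    lines = ["# EV RNA biomarker pipeline report", ""]
    manifest = outputs.get("manifest")
    if manifest:
        lines += [
            f"Package version {manifest['package_version']}, "
            f"seed {manifest['seed']}, config hash `{manifest['config_hash']}`.",
            "",
        ]

    lines.append("## Biotype composition")
    if "fractions" in outputs:
        mean_frac = outputs["fractions"].mean(axis=1)
        lines.append("")
        lines.append("| biotype | mean fraction |")
        lines.append("|---|---|")
        for b, v in mean_frac.items():
            lines.append(f"| {b} | {v:.4f} |")
        comp = outputs.get("composition_preop_vs_hc")
        if comp is not None:
            sig = comp[comp["significant"]]
            lines.append("")
            lines.append(
                "Significant PreOp-vs-HC composition shifts (adj. p < 0.05): "
                + (
                    ", ".join(
                        f"{b} ({'up' if comp.loc[b, 'delta'] > 0 else 'down'})"
                        for b in sig.index
                    )
                    if len(sig)
                    else "none"
                )
            )
    else:
        lines.append("_Section absent._")
    lines.append("")

    lines.append("## Differential expression")
    any_de = False
    for key, label in [
        ("de_preop_vs_hc", "PreOp vs HC"),
        ("de_preop_vs_postop", "PreOp vs PostOp"),
    ]:
        de = outputs.get(key)
        if de is None or len(de) == 0:
            continue
        any_de = True
        sig = de[(de["adj_p"] <= 0.05) & (de["log2FC"].abs() > 1.0)]
        per_biotype = sig.groupby("biotype").size()
        lines.append(
            f"- {label}: {len(sig)} significant features of {len(de)} tested"
            + (
                " ("
                + ", ".join(f"{b}: {n}" for b, n in per_biotype.items())
                + ")"
                if len(per_biotype)
                else ""
            )
        )
    if not any_de:
        lines.append("_Section absent._")
    lines.append("")

    lines.append("## Biomarker candidates")
    cand = outputs.get("candidates")
    if cand is None:
        lines.append("_Section absent._")
    elif len(cand) == 0:
        lines.append("Zero candidates passed the intersection filter.")
    else:
        lines.append("")
        lines.append(
            "| feature | biotype | log2FC (vs HC) | adj. p (vs HC) | sensitivity | specificity | AUC |"
        )
        lines.append("|---|---|---|---|---|---|---|")
        for fid, row in cand.iterrows():
            lines.append(
                f"| {fid} | {row['biotype']} | {row['log2FC_preop_vs_hc']:.2f} | "
                f"{row['adj_p_preop_vs_hc']:.2g} | {row['sensitivity']:.2f} | "
                f"{row['specificity']:.2f} | {row['auc']:.2f} |"
            )
    lines.append("")

    lines.append("## Diagnostic panel")
    panel = outputs.get("panel")
    if panel is None:
        lines.append("_Section absent._")
    else:
        lines.append(f"Markers: {', '.join(panel.marker_ids)}")
        lines.append("")
        lines.append(f"- Training: {_fmt_roc(panel.training)}")
        lines.append(f"- LOOCV: {_fmt_roc(panel.loocv)}")
    lines.append("")

    lines.append("## Clinical associations")
    assoc_all = outputs.get("associations") or {}
    models = outputs.get("status_models") or {}
    if not assoc_all and not models:
        lines.append("_Section absent._")
    for var, assoc in assoc_all.items():
        n_sig = int((assoc["adj_p"] < 0.05).sum())
        lines.append(f"- {var}: {n_sig} of {len(assoc)} candidate markers associated (adj. p < 0.05)")
    for var, model in models.items():
        lines.append(f"- {var} status panel ({', '.join(model.marker_ids)}): LOOCV {_fmt_roc(model.loocv)}")
    lines.append("")

    with open(path, "w") as fh:
        fh.write("\n".join(lines))
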