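"""Config-driven orchestration of the full clonotype-tracking analysis.

Stages run in analysis order — QC/normalization, clonotype calling,
repertoire summaries, longitudinal classification (with tumor matching and
viral annotation), cluster flux, NE-vs-PE differential expression, memory
signature derivation (from a paired precursor dataset), clonotype score
timecourse with its random-signature control — and emit delimited tables
plus a JSON summary and a run manifest into the output directory. Reruns
with the same configuration and seed produce identical outputs.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from . import clonotypes as ctmod
from . import dynamics as dyn
from . import signature as sig
from . import simulate as sim
from . import stats as rstats
from . import viral as vir
from .io import ExpressionMatrix, normalize, qc_filter_cells

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All analysis thresholds, with the study defaults.

    Either ``input_dir`` (a cohort directory in the generator's layout) or
    ``simulate`` must be provided; when both are absent, a cohort is
    simulated from the default :class:`~tcrtrace.simulate.SimConfig` at
    ``seed``.
    """

    out_dir: str = "tcrtrace_out"
    input_dir: str | None = None
    simulate: sim.SimConfig | None = None
    seed: int = 0
    # QC / normalization
    mito_prefix: str = "MT-"
    blood_max_mito: float = 0.20
    tumor_max_mito: float = 0.30
    scale_total: float = 1e4
    # repertoire stats
    hyper_threshold: int = 10
    # dynamics
    min_expanded_cells: int = 2
    ne_denominator: str = "post_clonotypes"
    flux_mode: str = "incidence"
    # signature
    lfc_min: float = 0.25
    antilog_base: float = 2.0
    p_adj_max: float = 0.05
    min_cells: int = 2
    n_random_genes: int = 40
    precursor_cells_per_group: int = 500
    precursor_lfc: float = 0.6
    # viral
    drop_viral: bool = False
    require_v_gene: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if raw.get("simulate") is not None:
            raw["simulate"] = sim.SimConfig(**raw["simulate"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def _load_inputs(config: PipelineConfig):
    if config.input_dir is not None:
        files = sim.read_cohort(config.input_dir)
        return files.cells, files.chains, files.expr, files.db, files.truth_clones
    sc = config.simulate if config.simulate is not None else sim.SimConfig(seed=config.seed)
    cohort = sim.simulate_cohort(sc)
    return (
        cohort.cells,
        cohort.chains,
        cohort.expr,
        cohort.db,
        sim.truth_table(cohort),
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the report directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    summary: dict = {}

    cells, chains, expr, db, truth = _stage("load")(_load_inputs)(config)
    log.info("loaded %d cells, %d chains", len(cells), len(chains))

    if expr is not None:
        @_stage("qc")
        def _qc():
            return qc_filter_cells(
                expr, cells, mito_prefix=config.mito_prefix,
                blood_max_mito=config.blood_max_mito,
                tumor_max_mito=config.tumor_max_mito,
            )
        expr_qc, cells_qc = _qc()
        expr_qc = _stage("normalize")(normalize)(expr_qc, config.scale_total)
        summary["n_cells_pre_qc"] = len(cells)
        summary["n_cells_post_qc"] = len(cells_qc)
    else:
        expr_qc, cells_qc = None, list(cells)

    clonos = _stage("clonotyping")(ctmod.call_clonotypes)(chains, cells_qc)
    ctmod.write_clonotype_table(clonos, out / "clonotypes.tsv")
    by_key = ctmod.clonotypes_by_key(clonos)
    clusters = {c.barcode: c.cluster for c in cells_qc}
    patients = sorted({c.patient for c in cells_qc})
    summary["n_clonotypes"] = len(clonos)

    @_stage("repertoire_summary")
    def _summaries():
        sums = []
        samples = sorted({c.sample for c in cells_qc})
        for patient, tp, comp in samples:
            s = rstats.summarize_repertoire(clonos, patient, tp, comp,
                                            config.hyper_threshold)
            if s.n_clonotypes:
                sums.append(s)
        return sums
    summaries = _summaries()
    rstats.write_summary_table(summaries, out / "repertoire_summary.tsv")
    gini_pre = [s.gini for s in summaries if s.timepoint == "pre" and s.compartment == "blood"]
    gini_post = [s.gini for s in summaries if s.timepoint == "post" and s.compartment == "blood"]
    summary["gini_pre_blood_mean"] = float(np.mean(gini_pre)) if gini_pre else None
    summary["gini_post_blood_mean"] = float(np.mean(gini_post)) if gini_post else None

    @_stage("dynamics")
    def _dynamics():
        all_records: list[dyn.DynamicsRecord] = []
        rates = []
        for patient in patients:
            pre = [c for c in clonos if c.size_in(patient, "pre", "blood") > 0]
            post = [c for c in clonos if c.size_in(patient, "post", "blood") > 0]
            if not pre or not post:
                log.info("patient %s lacks a paired blood sample; skipped", patient)
                continue
            records = dyn.classify_dynamics(
                pre, post, patient, min_expanded_cells=config.min_expanded_cells
            )
            tumor = [c for c in clonos if c.size_in(patient, "pre", "tumor") > 0]
            blood = sorted({c.key for c in pre} | {c.key for c in post})
            if tumor:
                matched = ctmod.annotate_tumor_matched(
                    [by_key[k] for k in blood], tumor
                )
                for r in records:
                    r.tumor_matched = r.key in matched
            if db is not None and len(db):
                ann = {a.key: a.viral for a in vir.annotate_viral(
                    [by_key[k] for k in blood if k in by_key], db,
                    require_v_gene=config.require_v_gene)}
                for r in records:
                    r.viral = ann.get(r.key, False)
            all_records += records
            row = {"patient": patient}
            for den in dyn.NE_DENOMINATORS:
                row[f"ne_rate_{den}"] = dyn.ne_rate(records, den)
            rates.append(row)
        return all_records, pd.DataFrame(rates)
    records, rates = _dynamics()
    dyn.write_dynamics_table(records, out / "dynamics.tsv")
    rates.to_csv(out / "ne_rates.tsv", sep="\t", index=False)
    expanded = [r for r in records if r.treatment_expanded]
    summary["n_treatment_expanded"] = len(expanded)
    summary["n_novel_expanded"] = sum(1 for r in expanded if r.origin == "novel")
    summary["ne_rate_mean"] = (
        float(rates["ne_rate_post_clonotypes"].mean()) if len(rates) else None
    )
    if expanded:
        summary["tumor_matched_fraction_of_expanded"] = float(
            np.mean([r.tumor_matched for r in expanded])
        )

    @_stage("flux")
    def _flux():
        for patient in patients:
            recs = [r for r in records if r.patient == patient]
            if not recs or any(clusters.get(b) is None for b in clusters):
                continue
            table = dyn.flux_table(recs, by_key, clusters, mode=config.flux_mode)
            dyn.write_flux_table(table, out / f"flux_{patient}.tsv")
    _flux()

    if db is not None and len(db):
        @_stage("viral_annotation")
        def _viral():
            anns = vir.annotate_viral(clonos, db, require_v_gene=config.require_v_gene)
            vir.write_annotation_table(anns, out / "viral_annotations.tsv")
            return anns
        annotations = _viral()
        summary["viral_fraction"] = vir.viral_fraction(annotations)

    if expr_qc is not None:
        @_stage("de_ne_vs_pe")
        def _de():
            ne_cells = [
                b for r in expanded if r.origin == "novel"
                for b in by_key[r.key].cells_in(r.patient, "post", "blood")
            ]
            pe_cells = [
                b for r in expanded if r.origin == "pre_existing"
                for b in by_key[r.key].cells_in(r.patient, "post", "blood")
            ]
            present = set(expr_qc.barcodes)
            ne_cells = [b for b in ne_cells if b in present]
            pe_cells = [b for b in pe_cells if b in present]
            if len(ne_cells) < 3 or len(pe_cells) < 3:
                log.info("too few NE/PE cells for differential expression; skipped")
                return None
            de = sig.rank_sum_de(expr_qc, ne_cells, pe_cells)
            sig.write_de_table(de, out / "de_ne_vs_pe.tsv")
            ranked = de.sort_values("lfc", ascending=False)
            top = [str(g) for g in ranked.index[:20]]
            bottom = [str(g) for g in ranked.index[-20:]]
            totals = pd.DataFrame({
                "top20_total": sig.signature_set_expression(expr_qc, ne_cells, top),
                "bottom20_total": sig.signature_set_expression(expr_qc, ne_cells, bottom),
            })
            totals.to_csv(out / "ne_marker_set_expression.tsv", sep="\t")
            return de
        _de()

        @_stage("signature")
        def _signature():
            sc = config.simulate if config.simulate is not None else sim.SimConfig(seed=config.seed)
            prec = sim.simulate_precursor_dataset(
                sc, seed=(config.seed + 10007) % (2**31),
                n_cells_per_group=config.precursor_cells_per_group,
                lfc=config.precursor_lfc,
            )
            des = {}
            for tp, (mat, groups) in (
                ("pre", (prec.expr_pre, prec.groups_pre)),
                ("post", (prec.expr_post, prec.groups_post)),
            ):
                mat_n = normalize(mat, config.scale_total)
                g1 = [b for b, g in groups.items() if g == "5M"]
                g2 = [b for b, g in groups.items() if g == "5E"]
                des[tp] = sig.rank_sum_de(mat_n, g1, g2)
            derived = sig.derive_signature(
                des["pre"], des["post"], lfc_min=config.lfc_min,
                antilog_base=config.antilog_base, p_adj_max=config.p_adj_max,
            )
            sig.write_signature(derived, out / "signature.tsv")
            return derived, prec
        memory_sig, prec = _signature()
        summary["n_signature_genes"] = len(memory_sig.genes)
        summary["signature_recovered_planted"] = len(
            set(memory_sig.genes) & set(prec.memory_genes)
        )
        summary["signature_false_positives"] = len(
            set(memory_sig.genes) - set(prec.memory_genes)
        )

        @_stage("score_timecourse")
        def _scores():
            blood_pre = [c.barcode for c in cells_qc
                         if c.compartment == "blood" and c.timepoint == "pre"]
            blood_post = [c.barcode for c in cells_qc
                          if c.compartment == "blood" and c.timepoint == "post"]
            present = set(expr_qc.barcodes)
            blood_pre = [b for b in blood_pre if b in present]
            blood_post = [b for b in blood_post if b in present]
            results = {}
            for name, signature in (("memory", memory_sig),
                                    ("random", sig.random_signature(
                                        expr_qc, config.n_random_genes, config.seed))):
                usable = [g for g in signature.genes if g in set(expr_qc.genes)]
                weights = np.array([w for g, w in zip(signature.genes, signature.weights)
                                    if g in set(expr_qc.genes)])
                use_sig = sig.GeneSignature(genes=usable, weights=weights,
                                            provenance=signature.provenance,
                                            antilog_base=signature.antilog_base)
                z = sig.gene_zscores(expr_qc, use_sig.genes)
                res = sig.score_timecourse(
                    clonos, records, z[blood_pre], z[blood_post], use_sig,
                    min_cells=config.min_cells, drop_viral=config.drop_viral,
                )
                sig.write_score_table(res.records, out / f"scores_{name}.tsv")
                results[name] = res
            return results
        score_results = _scores()
        for name, res in score_results.items():
            summary[f"fraction_increasing_{name}"] = res.fraction_increasing
            summary[f"signed_rank_p_{name}"] = res.signed_rank_p
            summary[f"n_scored_clonotypes_{name}"] = len(res.records)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    manifest = {
        "tcrtrace": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "stages": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
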