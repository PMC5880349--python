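"""End-to-end orchestration of the synthetic study.

``run_all`` executes the full analysis order — synthetic data, counting,
differential transcription and clustering, accessibility-based TRE
refinement, motif enrichment, and RET-ligand outlier scoring — from a
single validated config, writing every table plus a manifest (input
checksums, seed, package version).  Re-running with the same config is
bit-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .diffexpr import classify_tres, correlation_cluster, nb_test
from .ligandscore import RetLigandScoreModel, ligand_high_fraction
from .motifs import MarkovBackground, MotifModel, enrichment_scan, gc_content
from .refine import (
    AccessibilityImputer,
    PeakCallParams,
    call_peaks,
    divergent_center,
    impute_signal,
    match_peaks,
    tune_parameters,
)
from .synthdata import (
    SimParams,
    background_windows,
    child_rng,
    gen_accessibility_truth,
    gen_count_table,
    gen_expression_cohort,
    gen_genome,
    gen_proseq_tracks,
    gen_tre_sequences,
    write_genome_beds,
)
from .tracks import count_gene_body, count_window, rpkm, write_track

logger = logging.getLogger("retpoise")

__all__ = ["RunConfig", "run_all", "end_to_end_refinement", "load_config"]


class SimBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    chrom_length: int = 400_000
    n_genes: int = 20
    n_tres: int = 12
    pause_height: float = 2.0
    body_density: float = 0.05
    enhancer_height: float = 1.0
    nb_dispersion: float = 0.02
    planted_fc: float = 2.0
    diff_fraction: float = 0.2
    ligand_tail_fraction: float = 0.13
    responder_shift: float = 0.5
    n_cohort_samples: int = 925


class RefineBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    fdr_target: float = 0.10
    n_decoys: int = 20
    max_train: int = 800


class MotifBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tre_seq_length: int = 300
    n_motif_set: int = 10  # Bonferroni denominator for the demo motif set
    background_n_min: int = 50  # desk-scale background size (study scale: 1500)
    planted_consensus: str = "TGACGTCATG"
    plant_fraction: float = 0.5


class ScoreBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ligand_genes: list[str] = Field(
        default_factory=lambda: ["GDNF", "NRTN", "ARTN", "PSPN"]
    )
    er_positive_only: bool = True

    @field_validator("ligand_genes")
    @classmethod
    def _four_ligands(cls, v: list[str]) -> list[str]:
        if len(v) != 4:
            raise ValueError("exactly 4 ligand genes are required")
        return v


class RunConfig(BaseModel):
    """Schema-validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    outdir: str = "run"
    sim: SimBlock = Field(default_factory=SimBlock)
    refine: RefineBlock = Field(default_factory=RefineBlock)
    motifs: MotifBlock = Field(default_factory=MotifBlock)
    score: ScoreBlock = Field(default_factory=ScoreBlock)

    def sim_params(self) -> SimParams:
        return SimParams(seed=self.seed, **self.sim.model_dump())


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def end_to_end_refinement(train_seed: int, test_seed: int,
                          sim_overrides: dict | None = None,
                          fdr_target: float = 0.10,
                          n_decoys: int = 20,
                          max_train: int = 2000) -> dict:
    """Train, tune and evaluate the refinement pipeline on fresh genomes.

    The imputer is trained and its two peak-calling parameters tuned on a
    genome built from ``train_seed``; sensitivity and FDR are then measured
    on a freshly generated genome from ``test_seed`` whose candidate set
    mixes true TREs with signal-free decoy windows.
    """
    overrides = dict(sim_overrides or {})
    p_train = SimParams(seed=train_seed, **overrides)
    genome = gen_genome(p_train)
    tracks = gen_proseq_tracks(genome, "A", p_train)
    target = gen_accessibility_truth(genome, p_train)
    rng = child_rng(train_seed, "refine-train")
    tres = genome.tre_intervals()
    decoys = background_windows(genome, n_decoys, 300, rng)
    imputer = AccessibilityImputer(max_train=max_train)
    model = imputer.fit(tracks, tres, target, rng, background_regions=decoys)
    signal = impute_signal(model, tracks, tres + decoys)
    params, diag = tune_parameters(signal, tres, fdr_target=fdr_target)
    if params is None:
        return {"params": None, "diagnostics": diag, "model": model}

    p_test = SimParams(seed=test_seed, **overrides)
    genome2 = gen_genome(p_test)
    tracks2 = gen_proseq_tracks(genome2, "A", p_test)
    rng2 = child_rng(test_seed, "refine-test")
    tres2 = genome2.tre_intervals()
    decoys2 = background_windows(genome2, n_decoys, 300, rng2)
    signal2 = impute_signal(model, tracks2, tres2 + decoys2)
    called = [iv for iv, _ in call_peaks(signal2, params)]
    sens, fdr = match_peaks(called, tres2)
    return {
        "params": params, "diagnostics": diag, "model": model,
        "sensitivity": sens, "fdr": fdr, "n_called": len(called),
        "val_r": model.val_r,
    }


def run_all(config: RunConfig, outdir: str | Path | None = None) -> Path:
    """Execute every stage in order and write a manifest; returns the run dir."""
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.sim_params()
    manifest: dict = {
        "seed": config.seed,
        "config": config.model_dump(),
        "sim_params": asdict(params),
        "versions": {"retpoise": __version__, "python": platform.python_version(),
                     "numpy": np.__version__, "pandas": pd.__version__},
        "stages": {},
        "warnings": [],
    }
    written: list[Path] = []
    current_stage = "setup"

    def stage(name):
        nonlocal current_stage
        current_stage = name
        logger.info("stage %s (seed=%d)", name, config.seed)

    def emit(path: Path):
        written.append(path)

    try:
        # ---- stage 1: synthetic data ------------------------------------
        stage("synthdata")
        genome = gen_genome(params)
        tracks = {}
        for cond in ("A", "B"):
            for rep in (0, 1, 2):
                tracks[(cond, rep)] = gen_proseq_tracks(genome, cond, params,
                                                        replicate=rep)
                for strand in ("plus", "minus"):
                    p = out / f"proseq_{cond}{rep}_{strand}.bedGraph"
                    write_track(getattr(tracks[(cond, rep)], strand), p)
                    emit(p)
        target = gen_accessibility_truth(genome, params)
        write_genome_beds(genome, out / "genes.bed", out / "tres.bed")
        emit(out / "genes.bed")
        emit(out / "tres.bed")
        truth_df = pd.DataFrame(
            [{"feature_id": k, "true_log2fc": v}
             for k, v in sorted(genome.differential_truth.items())]
        )
        truth_df.to_csv(out / "differential_truth.tsv", sep="\t", index=False)
        emit(out / "differential_truth.tsv")

        # ---- stage 2: counting ------------------------------------------
        stage("counting")
        rows = []
        for gene in genome.genes:
            row = {"feature_id": gene.id, "kind": "gene",
                   "length": gene.length - 1000}
            for (cond, rep), tr in tracks.items():
                c = count_gene_body(tr, gene)
                row[f"count_{cond}{rep}"] = c
                row[f"rpkm_{cond}{rep}"] = (
                    np.nan if c is None else rpkm(c, gene.length - 1000,
                                                  tr.total_mapped)
                )
            rows.append(row)
        for t in genome.true_tres:
            iv = t["interval"]
            row = {"feature_id": iv.id, "kind": t["class"], "length": iv.length}
            for (cond, rep), tr in tracks.items():
                c = count_window(tr, iv)
                row[f"count_{cond}{rep}"] = c
                row[f"rpkm_{cond}{rep}"] = rpkm(c, iv.length, tr.total_mapped)
            rows.append(row)
        counts_df = pd.DataFrame(rows).set_index("feature_id")
        counts_df.to_csv(out / "counts.tsv", sep="\t")
        emit(out / "counts.tsv")

        # ---- stage 3: differential transcription + clustering -----------
        stage("diffexpr")
        count_cols = [c for c in counts_df.columns if c.startswith("count_")]
        mat = counts_df[count_cols].dropna().astype(int)
        mat.columns = [c.removeprefix("count_") for c in count_cols]
        groups = [c[0] for c in mat.columns]
        results = nb_test(mat, groups)
        results.to_tsv(out / "differential.tsv")
        emit(out / "differential.tsv")
        parts = classify_tres(results)
        rho, order, _ = correlation_cluster(mat)
        rho.to_csv(out / "sample_correlation.tsv", sep="\t")
        emit(out / "sample_correlation.tsv")
        manifest["stages"]["diffexpr"] = {
            "n_changed": results.n_changed,
            "cluster_order": order,
            "n_unchanged": len(parts["unchanged"]),
        }

        # ---- stage 4: TRE refinement ------------------------------------
        stage("refine")
        rng = child_rng(config.seed, "pipeline-refine")
        tres = genome.tre_intervals()
        decoys = background_windows(genome, config.refine.n_decoys, 300, rng)
        imputer = AccessibilityImputer(max_train=config.refine.max_train)
        model = imputer.fit(tracks[("A", 0)], tres, target, rng,
                            background_regions=decoys)
        signal = impute_signal(model, tracks[("A", 0)], tres + decoys)
        tuned, diag = tune_parameters(signal, tres,
                                      fdr_target=config.refine.fdr_target)
        diag.to_csv(out / "refine_grid.tsv", sep="\t", index=False)
        emit(out / "refine_grid.tsv")
        if tuned is None:
            raise RuntimeError("refine: no grid point met the FDR target")
        peaks = call_peaks(signal, tuned)
        n_unrefined = 0
        chrom_len = genome.chrom_sizes["chr1"]
        with open(out / "peaks.bed", "w") as fh:
            for iv, height in peaks:
                # search for the divergent pause pair on a TRE-scale window
                from .tracks import Interval as _Iv

                window = _Iv(iv.chrom, max(0, iv.center - 200),
                             min(chrom_len, iv.center + 200), iv.id)
                refined_iv, ok = divergent_center(tracks[("A", 0)], window)
                n_unrefined += int(not ok)
                fh.write(f"{refined_iv.chrom}\t{refined_iv.start}"
                         f"\t{refined_iv.end}\t{refined_iv.id}"
                         f"\t{height:.3f}\t.\n")
        emit(out / "peaks.bed")
        sens, fdr = match_peaks([iv for iv, _ in peaks], tres)
        manifest["stages"]["refine"] = {
            "params": asdict(tuned), "sensitivity": sens, "fdr": fdr,
            "imputer_val_r": model.val_r, "n_unrefined": n_unrefined,
        }
        if n_unrefined:
            manifest["warnings"].append(
                f"refine: {n_unrefined} peaks lacked divergent geometry"
            )

        # ---- stage 5: motif enrichment ----------------------------------
        stage("motifs")
        mrng = child_rng(config.seed, "pipeline-motifs")
        changed_ids = set(parts["changed"])
        tre_ids = [t["interval"].id for t in genome.true_tres]
        n_changed = sum(1 for i in tre_ids if i in changed_ids)
        mb = config.motifs
        changed_seqs, _ = gen_tre_sequences(
            max(n_changed, 10), mb.tre_seq_length, mrng,
            motif_consensus=mb.planted_consensus,
            plant_fraction=mb.plant_fraction,
        )
        pool_n = max(4 * mb.background_n_min, 200)
        unchanged_seqs, _ = gen_tre_sequences(pool_n, mb.tre_seq_length, mrng)
        background = MarkovBackground(order=3).fit(changed_seqs + unchanged_seqs)
        consensus_counts = np.zeros((len(mb.planted_consensus), 4))
        for i, b in enumerate(mb.planted_consensus):
            consensus_counts[i, "ACGT".index(b)] = 1.0
        motif_set = [MotifModel.from_counts("planted", consensus_counts, background)]
        srng = child_rng(config.seed, "pipeline-motif-decoys")
        for k in range(mb.n_motif_set - 1):
            rand_counts = np.zeros((8, 4))
            for i in range(8):
                rand_counts[i, srng.integers(0, 4)] = 1.0
            motif_set.append(
                MotifModel.from_counts(f"decoy{k:02d}", rand_counts, background)
            )
        from .motifs import matched_background

        changed_gc = [gc_content(s) for s in changed_seqs]
        unchanged_gc = [gc_content(s) for s in unchanged_seqs]
        bg_idx = matched_background(changed_gc, unchanged_gc, mrng,
                                    n_min=mb.background_n_min)
        bg_seqs = [unchanged_seqs[i] for i in bg_idx]
        enr = enrichment_scan(changed_seqs, bg_seqs, motif_set)
        enr.to_csv(out / "motif_enrichment.tsv", sep="\t", index=False)
        emit(out / "motif_enrichment.tsv")
        manifest["stages"]["motifs"] = {
            "top_motif": str(enr.iloc[0]["motif_id"]),
            "top_p_bonferroni": float(enr.iloc[0]["p_bonferroni"]),
        }

        # ---- stage 6: RET-ligand outlier score --------------------------
        stage("ligandscore")
        tcga, tcga_truth = gen_expression_cohort(params, style="tcga")
        tcga.to_tsv(out / "cohort_tcga.tsv")
        emit(out / "cohort_tcga.tsv")
        tcga_truth.to_csv(out / "cohort_tcga_truth.tsv", sep="\t",
                          index_label="sample_id")
        emit(out / "cohort_tcga_truth.tsv")
        frac = ligand_high_fraction(tcga,
                                    er_positive_only=config.score.er_positive_only)
        letro, letro_truth = gen_expression_cohort(params, style="letrozole",
                                                   n_timepoints=3)
        letro.to_tsv(out / "cohort_letrozole.tsv")
        emit(out / "cohort_letrozole.tsv")
        score_res = RetLigandScoreModel(letro).fit()
        score_res.to_frame().to_csv(out / "outlier_scores.tsv", sep="\t",
                                    index_label="sample_id")
        emit(out / "outlier_scores.tsv")
        summary = {
            "tcga": {
                "fraction_any_high": frac["fraction"],
                "n_any_high": frac["n_any_high"],
                "n_samples": frac["n_samples"],
                "per_ligand_high": frac["per_ligand_high"],
                "thresholds": frac["thresholds"],
            },
            "letrozole": {
                "responder_p": score_res.group_p,
                "n_samples": len(score_res.scores),
            },
        }
        with open(out / "score_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        emit(out / "score_summary.json")
        manifest["stages"]["ligandscore"] = summary
    except Exception as exc:
        raise RuntimeError(
            f"pipeline halted at stage {current_stage!r}: {exc}"
        ) from exc

    manifest["outputs"] = {
        str(p.relative_to(out)): {"sha256": _sha256(p), "bytes": p.stat().st_size}
        for p in written
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    logger.info("run complete: %d outputs in %s", len(written), out)
    return out
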