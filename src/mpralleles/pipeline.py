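"""End-to-end orchestration of the allelic-enhancer discovery pipeline.

The stages mirror the analysis workflow: synthetic (or user) inputs ->
barcode counting -> enhancer-activity calling -> allelic-skew testing ->
peak-set enrichment -> allelic ChIP-seq filtering -> motif classification ->
gene annotation -> summary report.  All randomness derives from a single
seed; re-running with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activity import MPRAActivity, oligo_variant
from .allelic import AllelicSkew
from .annotation import annotate_variants
from .barcodes import count_barcodes
from .chip_allelic import (
    apply_consistency_filters,
    call_allelic_table,
    calls_to_frame,
    summarize_allelic_profile,
)
from .enrichment import reli_batch
from .motifs import (
    adjacent_motif_enrichment,
    best_hit,
    classify_tfs,
    detect_altering_events,
    hit_position_distribution,
    overlapping_family_enrichment,
)
from .oligo import design_library, write_design_fasta, write_design_manifest
from .simulate import (
    gen_allelic_reads,
    gen_annotation_tables,
    gen_mpra_counts,
    gen_peaksets,
    gen_pwms,
    gen_reference_and_variants,
    write_genome_fasta,
)

DEFAULT_THRESHOLDS = {
    "padj": 0.05,
    "enhancer_fold": 1.5,
    "allelic_fold": 1.25,
    "negative_fold": 1.10,
    "reli_iterations": 2000,
    "ars_threshold": 0.4,
    "strong_score": 70.0,
    "weak_score": 40.0,
    "pad": 25,
    "min_barcodes": 30,
    "min_events": 3,
    "min_sites": 5,
}

DEFAULT_SIMULATION = {
    "n_variants": 40,
    "n_loci": 8,
    "frac_enhancer": 0.3,
    "frac_allelic": 0.5,  # fraction of planted enhancers that are also allelic
    "enhancer_fold": 2.0,
    "allelic_log2": 1.0,
    "n_peak_datasets": 6,
    "peak_p_target": 0.5,
    "peak_p_background": 0.1,
    "n_pwms": 6,
    "allelic_read_ratio": 0.8,
    "barcode_median": 729.0,
    "n_replicates": 3,
    "dispersion": 0.05,
}


def default_config(seed: int = 1, out_dir: str = "mpra_run") -> dict:
    return {
        "seed": seed,
        "out_dir": out_dir,
        "thresholds": dict(DEFAULT_THRESHOLDS),
        "simulation": dict(DEFAULT_SIMULATION),
    }


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    base = default_config()
    base.update({k: v for k, v in cfg.items() if k not in ("thresholds", "simulation")})
    base["thresholds"].update(cfg.get("thresholds", {}))
    base["simulation"].update(cfg.get("simulation", {}))
    return base


def _padded_allele_seqs(variant, genome, pad):
    left = genome[variant.chrom][variant.start - pad : variant.start]
    right = genome[variant.chrom][variant.end : variant.end + pad]
    return {
        a: (left + a + right, (pad, pad + len(a))) for a in variant.alleles
    }


def run_pipeline(config: Mapping | str | Path) -> dict:
    """Execute every stage on a seeded synthetic dataset; returns the report.

    ``config`` is a mapping (see :func:`default_config`) or a YAML path.
    Output tables, the truth tables, a log and a JSON report are written to
    ``config["out_dir"]``.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    cfg = default_config()
    cfg.update({k: v for k, v in config.items() if k not in ("thresholds", "simulation")})
    cfg["thresholds"].update(dict(config.get("thresholds", {})))
    cfg["simulation"].update(dict(config.get("simulation", {})))
    thr = cfg["thresholds"]
    sim = cfg["simulation"]
    seed = int(cfg["seed"])
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"mpralleles {__version__}", f"seed: {seed}"]
    log_lines += [f"threshold {k}: {v}" for k, v in sorted(thr.items())]

    # --- stage 0: synthetic inputs with planted truth -----------------------
    ss = np.random.SeedSequence(seed)
    (s_pick, s_ref, s_counts, s_peaks, s_reads, s_motifs) = ss.spawn(6)
    rng = np.random.default_rng(s_pick)
    n_var = int(sim["n_variants"])
    n_enh = int(round(sim["frac_enhancer"] * n_var))
    enh_idx = sorted(rng.choice(n_var, size=n_enh, replace=False).tolist())
    n_all = int(round(sim["frac_allelic"] * n_enh))
    all_idx = sorted(rng.choice(enh_idx, size=n_all, replace=False).tolist())

    pwms = gen_pwms(int(sim["n_pwms"]), np.random.default_rng(s_motifs))
    planted_overlapping = {}
    planted_adjacent = {}
    for j, idx in enumerate(all_idx):
        pwm = pwms[j % len(pwms)]
        if j % 2 == 0:
            planted_overlapping[idx] = pwm
        else:
            planted_adjacent[idx] = pwm

    simvar = gen_reference_and_variants(
        n_var,
        np.random.default_rng(s_ref),
        n_loci=int(sim["n_loci"]),
        planted_overlapping=planted_overlapping,
        planted_adjacent=planted_adjacent,
    )
    variants = simvar.variants
    by_id = {v.id: v for v in variants}
    enh_ids = [variants[i].id for i in enh_idx]
    allelic_ids = [variants[i].id for i in all_idx]
    write_genome_fasta(simvar.genome, out / "genome.fa")
    simvar.truth.to_csv(out / "truth_variants.tsv", sep="\t", index=False)

    # --- stage 1: oligo design ---------------------------------------------
    oligos = design_library(variants, simvar.genome)
    write_design_fasta(oligos, out / "design.fa")
    write_design_manifest(oligos, out / "design_manifest.tsv")

    # --- stage 2: barcode counts -> count matrix ---------------------------
    mpra = gen_mpra_counts(
        variants,
        np.random.default_rng(s_counts),
        n_replicates=int(sim["n_replicates"]),
        barcode_median=float(sim["barcode_median"]),
        dispersion=float(sim["dispersion"]),
        enhancer_folds={vid: float(sim["enhancer_fold"]) for vid in enh_ids},
        allelic_log2={vid: float(sim["allelic_log2"]) for vid in allelic_ids},
    )
    mpra.truth.to_csv(out / "truth_mpra.tsv", sep="\t", index=False)
    cm = count_barcodes(
        mpra.barcode_counts, mpra.barcode_map, mpra.samples,
        min_barcodes=int(thr["min_barcodes"]),
    )
    cm.to_tsv(out / "count_matrix.tsv")

    # --- stage 3: enhancer-activity calling --------------------------------
    activity = MPRAActivity.from_count_matrix(cm).fit()
    calls = activity.call_enhancers(
        fc_threshold=float(thr["enhancer_fold"]),
        padj_threshold=float(thr["padj"]),
        negative_fc=float(thr["negative_fold"]),
    )
    activity.to_tsv(out / "activity_results.tsv")
    pd.DataFrame({"variant_id": sorted(calls.en_vars)}).to_csv(
        out / "envars.tsv", sep="\t", index=False
    )

    # --- stage 4: allelic skew ---------------------------------------------
    skew = AllelicSkew(
        mpra.barcode_counts, mpra.samples, calls.en_vars,
        allele_order={v.id: v.alleles for v in variants},
    ).fit(
        fc_threshold=float(thr["allelic_fold"]),
        padj_threshold=float(thr["padj"]),
    )
    skew.to_tsv(out / "allelic_results.tsv")
    dependence = skew.genotype_dependence(activity)
    dependence.to_csv(out / "genotype_dependence.tsv", sep="\t", index=False)
    allelic_envars = sorted(skew.allelic_en_vars)

    # --- stage 5: peak-set enrichment (enVars vs non-enVars) ---------------
    peak_sets, peak_truth = gen_peaksets(
        variants,
        np.random.default_rng(s_peaks),
        n_datasets=int(sim["n_peak_datasets"]),
        p_target=float(sim["peak_p_target"]),
        p_background=float(sim["peak_p_background"]),
        target_ids=frozenset(enh_ids),
    )
    peak_truth.to_csv(out / "truth_peaks.tsv", sep="\t", index=False)
    peaks_dir = out / "peaks"
    peaks_dir.mkdir(exist_ok=True)
    manifest_rows = []
    for ps in peak_sets:
        bed = peaks_dir / f"{ps.name}.bed"
        with open(bed, "w") as fh:
            for chrom, (starts, ends) in sorted(ps._merged.items()):
                for s, e in zip(starts, ends):
                    fh.write(f"{chrom}\t{s}\t{e}\n")
        manifest_rows.append({"dataset": ps.name, "path": str(bed.name)})
    pd.DataFrame(manifest_rows).to_csv(
        peaks_dir / "manifest.tsv", sep="\t", index=False
    )
    input_regions = [by_id[vid] for vid in sorted(calls.en_vars)]
    negative_regions = [by_id[vid] for vid in sorted(calls.non_en_vars)]
    for fname, regions in (
        ("envars_regions.bed", input_regions),
        ("background_regions.bed", negative_regions),
    ):
        with open(out / fname, "w") as fh:
            for v in regions:
                fh.write(f"{v.chrom}\t{v.start}\t{v.end}\t{v.id}\n")
    if input_regions and len(negative_regions) >= len(input_regions):
        enrich = reli_batch(
            input_regions, negative_regions, peak_sets,
            n_iter=int(thr["reli_iterations"]), seed=seed,
        )
    else:
        enrich = pd.DataFrame()
    enrich.to_csv(out / "reli_enrichment.tsv", sep="\t", index=False)

    # --- stage 6: allelic ChIP-seq binding ---------------------------------
    planted_binding_ids = {
        variants[i].id for i in (*planted_overlapping, *planted_adjacent)
    }
    proteins_of: dict[str, str] = {}
    for idx, pwm in {**planted_overlapping, **planted_adjacent}.items():
        proteins_of[variants[idx].id] = pwm.tf_name
    reads, read_truth = gen_allelic_reads(
        variants,
        np.random.default_rng(s_reads),
        proteins=sorted({p.tf_name for p in pwms}),
        ratios={vid: float(sim["allelic_read_ratio"]) for vid in planted_binding_ids},
    )
    read_truth.to_csv(out / "truth_allelic_reads.tsv", sep="\t", index=False)
    reads.to_csv(out / "allelic_reads.tsv", sep="\t", index=False)
    calls_chip = call_allelic_table(
        reads, ars_threshold=float(thr["ars_threshold"])
    ) if len(reads) else []
    calls_to_frame(calls_chip).to_csv(
        out / "allelic_binding_calls.tsv", sep="\t", index=False
    )
    events_chip = apply_consistency_filters(calls_chip)
    profile = summarize_allelic_profile(events_chip)
    profile.to_csv(out / "allelic_binding_profile.tsv", sep="\t", index=False)

    # --- stage 7: motif classification -------------------------------------
    pad = int(thr["pad"])
    non_allelic_envars = sorted(set(calls.en_vars) - set(allelic_envars))
    events_fg, events_bg = [], []
    for vid in allelic_envars:
        events_fg += detect_altering_events(
            vid, _padded_allele_seqs(by_id[vid], simvar.genome, pad), pwms,
            strong=float(thr["strong_score"]), weak=float(thr["weak_score"]),
        )
    for vid in non_allelic_envars:
        events_bg += detect_altering_events(
            vid, _padded_allele_seqs(by_id[vid], simvar.genome, pad), pwms,
            strong=float(thr["strong_score"]), weak=float(thr["weak_score"]),
        )
    fam_overlap = overlapping_family_enrichment(
        events_fg, max(len(allelic_envars), 1),
        events_bg, max(len(non_allelic_envars), 1),
        min_events=int(thr["min_events"]),
    )
    fam_overlap.to_csv(out / "family_overlapping.tsv", sep="\t", index=False)

    core_by_variant = {
        o.variant_id: o.core_seq
        for o in oligos
        if o.orientation == "forward" and o.allele == by_id[o.variant_id].ref
    }
    fg_seqs = {vid: core_by_variant[vid] for vid in allelic_envars}
    fam_adjacent = (
        adjacent_motif_enrichment(
            fg_seqs, pwms, seed=np.random.default_rng(s_motifs.spawn(1)[0]),
            hit_threshold=float(thr["strong_score"]),
            min_sites=int(thr["min_sites"]),
        )
        if fg_seqs
        else pd.DataFrame()
    )
    fam_adjacent.to_csv(out / "family_adjacent.tsv", sep="\t", index=False)

    allelic_proteins_by_variant: dict[str, set] = {}
    for e in events_chip:
        allelic_proteins_by_variant.setdefault(e.variant_id, set()).add(e.protein)
    class_frames, position_frames = [], []
    pwm_by_tf = {p.tf_name: p for p in pwms}
    for vid in allelic_envars:
        proteins = allelic_proteins_by_variant.get(vid, set())
        if not proteins:
            continue
        ev = [e for e in events_fg if e.variant_id == vid]
        classification = classify_tfs(vid, proteins, ev, pwms)
        class_frames.append(classification)
        core = core_by_variant[vid]
        hits = {
            tf: best_hit(pwm_by_tf[tf], core, vid)
            for tf in proteins
            if tf in pwm_by_tf
        }
        position_frames.append(
            hit_position_distribution(classification, hits, len(core) / 2.0)
        )
    classification = (
        pd.concat(class_frames, ignore_index=True)
        if class_frames
        else pd.DataFrame(columns=["variant_id", "tf", "classification", "has_motif"])
    )
    classification.to_csv(out / "tf_classification.tsv", sep="\t", index=False)
    positions = (
        pd.concat(position_frames, ignore_index=True)
        if position_frames
        else pd.DataFrame(columns=["tf", "classification", "center_offset"])
    )
    positions.to_csv(out / "tf_hit_positions.tsv", sep="\t", index=False)

    # --- stage 8: gene annotation ------------------------------------------
    tier_spec = {v.id: (i % 4) + 1 for i, v in enumerate(variants)}
    loops, eqtls, genes = gen_annotation_tables(variants, tier_spec)
    annotation = annotate_variants(variants, loops, eqtls, genes)
    annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)

    # --- report -------------------------------------------------------------
    loci = {v.id: v.locus_id for v in variants}
    allelic_loci = sorted({loci[vid] for vid in allelic_envars})
    per_locus = pd.Series([loci[v.id] for v in variants]).value_counts()
    report = {
        "seed": seed,
        "version": __version__,
        "thresholds": {k: thr[k] for k in sorted(thr)},
        "n_variants": len(variants),
        "n_oligos": len(oligos),
        "n_oligos_retained": int(len(cm.counts)),
        "n_enAlleles": len(calls.en_alleles),
        "n_enVars": len(calls.en_vars),
        "n_non_enVars": len(calls.non_en_vars),
        "n_allelic_enVars": len(allelic_envars),
        "n_loci": int(per_locus.size),
        "n_loci_with_allelic_enVar": len(allelic_loci),
        "mean_variants_per_locus": float(per_locus.mean()),
        "mean_allelic_enVars_per_allelic_locus": (
            float(len(allelic_envars) / len(allelic_loci)) if allelic_loci else 0.0
        ),
        "n_altering_events_allelic": len(events_fg),
        "n_tf_classifications": int(len(classification)),
        "outputs": sorted(
            str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
            if p.name != "report.json"
        ),
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    log_lines.append(f"enVars: {len(calls.en_vars)}")
    log_lines.append(f"allelic enVars: {len(allelic_envars)}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return report
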