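"""End-to-end orchestration of the virome case-control analysis.

:func:`run_all` executes the stages in method order — simulate -> triage
(+ BUSCO filter) -> vOTU dereplication -> taxonomy/host annotation ->
abundance profiling -> community statistics -> correlation network ->
random-forest classification — under one :class:`PipelineConfig` and one
global seed, writes every artifact as TSV/FASTA/JSON, and returns a
:class:`RunReport` whose stage counts obey conservation laws (vOTU member
counts sum to the retained contig count; significant features are a
subset of tested features).  Two runs with identical config and seed
produce byte-identical outputs.

The synthetic study layout (:class:`SyntheticSpec`) defaults to the
16-case / 31-control design with moderate detector noise and the planted
effect sizes documented in the generator.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, classify, derep, profiling, stats
from .triage import triage_pool
from .config import PipelineConfig
from .io import (
    write_decisions_tsv,
    write_design_tsv,
    write_evidence_tsv,
    write_fasta,
)
from .synthetic import (
    EvidenceNoise,
    StudyDesign,
    generate_abundance_study,
    generate_contig_pool,
    generate_genomes,
    generate_protein_hits,
    ViralGenome,
)


@dataclass
class SyntheticSpec:
    """Study conditions for a fully synthetic run."""

    n_case: int = 16
    n_control: int = 31
    n_viral: int = 8
    n_host: int = 4
    prophage_rate: float = 0.5
    spacer_count: int = 3
    noise_level: float = 0.5
    n_contigs_per_sample: int = 8
    contig_length_range: tuple[int, int] = (2000, 6000)
    n_votus: int = 120
    n_genera: int = 40
    n_differential: int = 16
    effect_log2: float = 2.0
    n_corr_pairs: int = 6
    rho_target: float = 0.9
    subset_k_grid: tuple[int, ...] = (
        1, 2, 3, 4, 5, 6, 8, 10, 12, 16, 20, 26, 32, 40, 50, 64, 80, 100, 120,
    )


@dataclass
class RunReport:
    counts: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    config_hash: str = ""
    warnings: list[str] = field(default_factory=list)

    def check_conservation(self) -> None:
        c = self.counts
        for mode in ("bulk", "vlp"):
            if c[f"viral_retained_{mode}"] > c[f"contigs_in_{mode}"]:
                raise AssertionError(f"retained > input for {mode}")
        if c["votu_member_total"] != c["viral_retained_bulk"] + c["viral_retained_vlp"]:
            raise AssertionError("vOTU member counts do not sum to retained contigs")
        if c["significant_votus"] > c["tested_votus"]:
            raise AssertionError("significant features exceed tested features")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _protein_coords(length: int) -> tuple[tuple[int, int], ...]:
    # fixed 1 kb tiling for representative contigs (gene calls are upstream)
    coords = []
    pos = 0
    while pos + 500 <= length:
        end = min(pos + 1000, length)
        coords.append((pos, end))
        pos = end
    return tuple(coords) if coords else ((0, length),)


def run_all(
    config: PipelineConfig,
    out_dir: str | Path,
    synthetic: SyntheticSpec | None = None,
) -> RunReport:
    """Run every stage on a synthetic study and write all artifacts."""
    config.require_valid()
    spec = synthetic or SyntheticSpec()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())

    report = RunReport(config_hash=config.config_hash())
    report.seeds = {stage: config.stage_seed(stage) for stage in
                    ("simulate", "triage", "derep", "annotate", "profile",
                     "stats", "network", "classify")}

    # ------------------------------------------------------------------ simulate
    design = StudyDesign.balanced(spec.n_case, spec.n_control)
    write_design_tsv(design, out / "design.tsv")
    s_sim = report.seeds["simulate"]
    genomes = generate_genomes(
        spec.n_viral, spec.n_host,
        prophage_rate=spec.prophage_rate,
        spacer_count=spec.spacer_count,
        seed=s_sim,
    )
    write_fasta({v.id: v.sequence for v in genomes.viral_genomes},
                out / "genomes_viral.fasta")
    write_fasta({h.id: h.sequence for h in genomes.host_genomes},
                out / "genomes_host.fasta")

    pools = {}
    noise = EvidenceNoise(spec.noise_level)
    for offset, mode in ((1, "bulk"), (2, "vlp")):
        contigs, evidence, truth = generate_contig_pool(
            genomes, design, mode, noise=noise,
            n_contigs_per_sample=spec.n_contigs_per_sample,
            length_range=spec.contig_length_range,
            seed=(s_sim + offset) % 2**31,
        )
        pools[mode] = (contigs, evidence, truth)
        write_fasta({c.id: c.sequence for c in contigs}, out / f"contigs_{mode}.fasta")
        write_evidence_tsv(evidence, out / f"evidence_{mode}.tsv")
        report.counts[f"contigs_in_{mode}"] = len(contigs)

    # ------------------------------------------------------------------- triage
    retained_seqs: dict[str, str] = {}
    correct = total = 0
    for mode in ("bulk", "vlp"):
        contigs, evidence, truth = pools[mode]
        ev_map = {e.contig_id: e for e in evidence}
        decisions, retained = triage_pool(
            contigs, ev_map,
            dvf_p=config.dvf_p, dvf_score=config.dvf_score,
            busco_ratio=config.busco_ratio,
        )
        write_decisions_tsv(decisions, out / f"decisions_{mode}.tsv")
        seq_map = {c.id: c.sequence for c in contigs}
        write_fasta({cid: seq_map[cid] for cid in retained},
                    out / f"retained_{mode}.fasta")
        retained_seqs.update({cid: seq_map[cid] for cid in retained})
        report.counts[f"viral_retained_{mode}"] = len(retained)
        for d in decisions:
            total += 1
            correct += int(d.verdict == truth.viral_labels[d.contig_id])
    report.metrics["triage_accuracy_pct"] = round(100.0 * correct / total, 3)

    # -------------------------------------------------------------------- derep
    clusters = derep.cluster_votus(
        retained_seqs,
        identity_threshold=config.identity,
        coverage_threshold=config.coverage,
        coverage_denominator=config.coverage_denominator,
        word_size=config.word_size,
    )
    pd.DataFrame(
        derep.membership_table(clusters),
        columns=["votu_id", "member_id", "identity", "coverage"],
    ).to_csv(out / "votus.tsv", sep="\t", index=False, float_format="%.4f")
    reps = {cl.representative_id: retained_seqs[cl.representative_id]
            for cl in clusters}
    write_fasta(reps, out / "representatives.fasta")
    report.counts["n_votus"] = len(clusters)
    report.counts["votu_member_total"] = sum(len(c.member_ids) for c in clusters)

    # ----------------------------------------------------------------- annotate
    sources = {}
    for mode in ("bulk", "vlp"):
        sources.update(pools[mode][2].contig_sources)
    viral_families = {v.id: v.family for v in genomes.viral_genomes}
    rep_genomes = []
    for cl in clusters:
        src = sources[cl.representative_id]
        family = viral_families.get(src)
        if family is None:
            continue  # host-derived contamination has no viral family
        seq = retained_seqs[cl.representative_id]
        rep_genomes.append(
            ViralGenome(cl.representative_id, seq, family, _protein_coords(len(seq)))
        )
    hits = generate_protein_hits(rep_genomes, seed=report.seeds["annotate"])
    hits_by_virus: dict[str, list] = {}
    for h in hits:
        hits_by_virus.setdefault(h.virus_id, []).append(h)
    taxonomy_rows = []
    rep_to_votu = {cl.representative_id: cl.votu_id for cl in clusters}
    rep_families = {g.id: g for g in rep_genomes}
    for cl in clusters:
        rid = cl.representative_id
        if rid in rep_families:
            family = annotate.assign_family(
                hits_by_virus.get(rid, []),
                len(rep_families[rid].protein_coords),
                vote_fraction=config.vote_fraction,
                min_identity=config.hit_min_identity,
                min_query_cover=config.hit_min_query_cover,
                min_subject_cover=config.hit_min_subject_cover,
                min_bitscore=config.hit_min_bitscore,
            )
        else:
            family = annotate.UNCLASSIFIED
        taxonomy_rows.append((cl.votu_id, family))
    taxonomy = pd.DataFrame(taxonomy_rows, columns=["votu_id", "family"])
    taxonomy.to_csv(out / "taxonomy.tsv", sep="\t", index=False)
    report.counts["classified_families"] = int(
        (taxonomy["family"] != annotate.UNCLASSIFIED).sum()
    )

    host_tax = genomes.host_taxonomy()
    arrays = []
    for h in genomes.host_genomes:
        arrays.extend(
            annotate.detect_crispr_arrays(
                h.sequence, min_repeats=config.crispr_min_repeats, genome_id=h.id
            )
        )
    assignments = []
    for cl in clusters:
        seq = retained_seqs[cl.representative_id]
        votu = rep_to_votu[cl.representative_id]
        found = annotate.match_spacers(
            arrays, votu, seq, host_tax, bit_threshold=config.spacer_bitscore
        ) + annotate.predict_host_prophage(
            votu, seq, genomes.host_genomes, host_tax,
            id_threshold=config.prophage_identity,
            cov_threshold=config.prophage_coverage,
            word_size=config.word_size,
        )
        assignments.extend(found)
    pd.DataFrame(
        [(a.virus_id, a.host_id, a.host_genus, a.host_phylum, a.evidence,
          round(a.score, 2)) for a in assignments],
        columns=["votu_id", "host_id", "genus", "phylum", "evidence", "score"],
    ).to_csv(out / "hosts.tsv", sep="\t", index=False)
    report.counts["hosts_assigned"] = len({a.virus_id for a in assignments})
    report.metrics["host_census"] = (
        annotate.host_census(assignments, host_tax) if assignments else {}
    )

    # ------------------------------------------------------------------ profile
    virome, bacteriome, ab_truth = generate_abundance_study(
        design,
        n_votus=spec.n_votus,
        n_genera=spec.n_genera,
        n_differential=spec.n_differential,
        effect_log2=spec.effect_log2,
        n_corr_pairs=spec.n_corr_pairs,
        rho_target=spec.rho_target,
        seed=report.seeds["profile"],
    )
    virome.to_tsv(out / "profile_virome.tsv")
    bacteriome.to_tsv(out / "profile_bacteriome.tsv")

    # -------------------------------------------------------------------- stats
    s_stats = report.seeds["stats"]
    diversity = stats.alpha_diversity(virome)
    diversity.to_csv(out / "diversity.tsv", sep="\t", float_format="%.6f")
    rare = stats.rarefaction_over_samples(
        virome.data > 0, design.labels,
        n_reps=config.rarefaction_reps, seed=s_stats,
    )
    rare.to_csv(out / "rarefaction.tsv", sep="\t", index=False, float_format="%.2f")
    dist = stats.bray_curtis(virome)
    dist.to_csv(out / "distance_virome.tsv", sep="\t", float_format="%.8f")
    perm = stats.permanova(
        dist, design.labels, n_permutations=config.n_permutations, seed=s_stats
    )
    (out / "permanova.json").write_text(json.dumps({
        "pseudo_F": perm.pseudo_F, "R2": perm.R2, "p_value": perm.p_value,
        "n_permutations": perm.n_permutations,
    }, indent=2, sort_keys=True))
    ordination = stats.dbrda(dist, design.labels)
    ordination.site_scores.to_csv(out / "dbrda_scores.tsv", sep="\t",
                                  float_format="%.6f")
    report.metrics["permanova_R2_pct"] = round(100.0 * perm.R2, 3)
    report.metrics["permanova_p"] = perm.p_value
    report.metrics["dbrda_constrained_pct"] = round(
        100.0 * ordination.constrained_fraction, 3
    )

    diff = stats.differential_abundance(virome, design, alpha=config.alpha)
    diff.to_csv(out / "differential_votu.tsv", sep="\t", float_format="%.6g")
    report.counts["tested_votus"] = len(diff)
    report.counts["significant_votus"] = int((diff["q_value"] < config.alpha).sum())
    planted = {f for f, _, _ in ab_truth.differential_features}
    detected = set(diff.index[diff["q_value"] < config.alpha])
    report.metrics["differential_recall_pct"] = round(
        100.0 * len(planted & detected) / len(planted), 3
    ) if planted else 100.0

    family_profile = profiling.aggregate_taxa(virome, "family")
    panel = stats.family_fold_panel(family_profile, design, alpha=config.alpha)
    panel.to_csv(out / "family_panel.tsv", sep="\t", float_format="%.6g")
    report.counts["significant_families"] = int(
        (panel["q_value"] < config.alpha).sum()
    )

    effects = stats.feature_effect_sizes(
        bacteriome, dist, n_permutations=config.n_permutations, seed=s_stats
    )
    effects.to_csv(out / "effect_sizes_genus_on_virome.tsv", sep="\t",
                   float_format="%.6g")

    # ------------------------------------------------------------------ network
    assoc = sorted(detected) if len(detected) >= 1 else list(virome.features)
    edges = stats.correlation_network(
        virome.data[assoc], bacteriome,
        rho_threshold=config.rho_threshold, alpha=config.alpha,
    )
    cyto = edges.rename(columns={"votu": "source", "genus": "target"})
    cyto["interaction"] = cyto["sign"]
    cyto[["source", "interaction", "target", "rho", "q_value"]].to_csv(
        out / "network_edges.tsv", sep="\t", index=False, float_format="%.4f"
    )
    report.counts["network_edges"] = len(edges)
    planted_pairs = {(v, g) for v, g, _ in ab_truth.correlated_pairs}
    found_pairs = set(zip(edges["votu"], edges["genus"]))
    # recall over every planted pair: a pair whose vOTU never reached the
    # study-associated set counts as missed
    report.metrics["network_recall_pct"] = (
        round(100.0 * len(planted_pairs & found_pairs) / len(planted_pairs), 3)
        if planted_pairs else 100.0
    )

    # ----------------------------------------------------------------- classify
    s_cls = report.seeds["classify"]
    roc_oob, importance = classify.train_rf(
        virome, design, n_trees=config.n_trees, seed=s_cls, evaluation="oob"
    )
    roc_resub, _ = classify.train_rf(
        virome, design, n_trees=config.n_trees, seed=s_cls, evaluation="resub",
        n_bootstrap=0,
    )
    roc_oob.curve.to_csv(out / "roc_points.tsv", sep="\t", index=False,
                         float_format="%.6f")
    importance.rename("importance").to_csv(out / "importance.tsv", sep="\t",
                                           float_format="%.8f")
    grid = [k for k in spec.subset_k_grid if k <= len(virome.features)]
    curve = classify.feature_subset_curve(
        virome, design, k_grid=grid, n_trees=config.n_trees, seed=s_cls,
        evaluation=config.rf_evaluation,
    )
    pd.DataFrame({"k": curve.k_values, "auc": curve.auc_values}).to_csv(
        out / "subset_curve.tsv", sep="\t", index=False, float_format="%.6f"
    )
    report.metrics["rf_oob_auc"] = round(roc_oob.auc, 4)
    report.metrics["rf_oob_ci"] = [round(roc_oob.ci_low, 4),
                                   round(roc_oob.ci_high, 4)]
    report.metrics["rf_resub_auc"] = round(roc_resub.auc, 4)
    report.counts["best_k"] = curve.best_k
    report.metrics["best_k_auc"] = round(curve.best_auc, 4)

    report.check_conservation()
    (out / "report.json").write_text(report.to_json())
    return report
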