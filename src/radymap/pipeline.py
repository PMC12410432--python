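"""End-to-end orchestration on simulated data.

Runs the full discovery-to-homology chain: simulate a study, call candidate
Y-linked loci from the adult coverage matrix, filter the family VCF and
append presence/absence pseudo-SNPs, build the linkage map, and assign
linkage-group/chromosome homology against the simulated reference.

The pseudo-SNP markers carry a known assay error — a carrier whose marker
dropped out is miscalled absent, a non-carrier can be contaminated — so the
mapping stage is given their derived per-call error rate
(dropout + contamination) / 2 (each affects half the offspring under 1:1
Y transmission); SNP markers get error rate 0.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genofilter import FamilyGenotypes, FilterConfig, append_pseudosnps, \
    filter_snps, thin_per_locus
from .linkage import LinkageMap, MapConfig, build_linkage_map, locate_y_region
from .sexassoc import CoverageMatrix, SexAssocConfig, build_candidate_table
from .simulate import FamilyData, SimConfig, SimTruth, emit_sequences, \
    simulate_adult_coverage, simulate_family, simulate_truth
from .synteny import AlignConfig, assign_homology, magnitude_filter, search

__all__ = ["PipelineResult", "run_pipeline", "discovery_replicates"]


@dataclass
class PipelineResult:
    truth: SimTruth
    coverage: CoverageMatrix
    candidates: pd.DataFrame
    family: FamilyData
    filter_report: dict
    linkage_map: LinkageMap
    y_report: pd.DataFrame
    homology: pd.DataFrame
    oxford: pd.DataFrame
    metrics: dict = field(default_factory=dict)


def _discovery_metrics(candidates, truth) -> dict:
    found = set(candidates.index)
    true_y = set(truth.y_locus_ids())
    recall = len(found & true_y) / len(true_y) if true_y else 1.0
    false_pos = len(found - true_y)
    return {"candidate_recall": recall, "autosomal_false_positives": false_pos,
            "n_candidates": len(found)}


def run_pipeline(config: SimConfig | None = None, outdir=None,
                 sex_cfg: SexAssocConfig | None = None,
                 filt_cfg: FilterConfig | None = None,
                 map_cfg: MapConfig | None = None,
                 align_cfg: AlignConfig | None = None) -> PipelineResult:
    """Simulate one study and run every analysis stage on it."""
    config = config or SimConfig()
    sex_cfg = sex_cfg or SexAssocConfig()
    map_cfg = map_cfg or MapConfig()
    align_cfg = align_cfg or AlignConfig()

    truth = simulate_truth(config)
    catalog = dict(zip(truth.loci["locus_id"], truth.loci["sequence"]))

    # stage 1: candidate discovery in the sexed adults
    coverage = simulate_adult_coverage(truth, config)
    candidates = build_candidate_table(coverage, catalog, sex_cfg)

    # stage 2: family genotypes -> filtered testcross markers + pseudo-SNPs
    family = simulate_family(truth, config)
    filtered, report = filter_snps(family.genotypes, filt_cfg)
    filtered = filtered.subset(filtered.paternal_testcross_mask())
    thinned = thin_per_locus(filtered)
    assayable = [c for c in candidates.index if c in family.y_presence.columns]
    geno = append_pseudosnps(thinned, family.y_presence[assayable])

    # stage 3: linkage map (pseudo-SNPs carry their derived assay error)
    n_snp = len(thinned.variants)
    pseudo_err = (config.dropout_rate + config.contamination_rate) / 2.0
    error_rates = np.concatenate([
        np.zeros(n_snp), np.full(len(assayable), pseudo_err)
    ])
    y_flags = np.concatenate([
        np.zeros(n_snp, bool), np.ones(len(assayable), bool)
    ])
    lmap = build_linkage_map(
        geno.offspring_calls(), geno.variants["marker_id"], y_flags,
        error_rates, map_cfg,
    )
    y_report = locate_y_region(lmap)

    # stage 4: synteny against the simulated reference
    if outdir is None:
        tmp = tempfile.TemporaryDirectory()
        outdir = Path(tmp.name)
    else:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
    emit_sequences(truth, config, outdir / "catalog.fa", outdir / "reference.fa")
    from .io import read_fasta

    reference = read_fasta(outdir / "reference.fa")
    marker_to_locus = dict(zip(geno.variants["marker_id"], geno.variants["locus_id"]))
    queries = {
        m: catalog[marker_to_locus[m]]
        for m in lmap.table["marker"]
        if marker_to_locus.get(m) in catalog
    }
    hits = search(queries, reference, align_cfg)
    accepted = magnitude_filter(hits, align_cfg.magnitude_factor)
    homology, oxford = assign_homology(lmap, accepted)

    metrics = _discovery_metrics(candidates, truth)
    metrics.update({
        "n_linkage_groups": lmap.n_groups,
        "n_mapped_markers": len(lmap.table),
        "total_map_cM": lmap.total_length_cM(),
        "n_unplaced": len(lmap.unplaced),
        "n_accepted_hits": len(accepted),
    })
    # homology recovery vs planted bijection
    true_map = {}
    chrom_of = dict(zip(truth.loci["locus_id"], truth.loci["chromosome"]))
    for gid in homology["group"]:
        markers = lmap.group_markers_list(gid)
        chroms = pd.Series([chrom_of[marker_to_locus[m]] for m in markers
                            if marker_to_locus.get(m) in chrom_of])
        true_map[gid] = truth.homology[chroms.mode().iloc[0]]
    hom_ok = homology.dropna(subset=["chrom"])
    metrics["homology_correct"] = int(
        sum(hom_ok.set_index("group")["chrom"].get(g) == true_map[g]
            for g in true_map)
    )
    metrics["homology_reciprocal"] = int(homology["reciprocal"].sum())
    # Y placement vs planted truth
    ytab = lmap.table[lmap.table["y_flag"]]
    if len(ytab):
        y_groups = sorted(ytab["group"].unique())
        sex_chrom = config.sex_chromosome
        in_true = [
            g for g in y_groups
            if true_map.get(g) == truth.homology[sex_chrom]
        ]
        metrics["y_single_group"] = len(y_groups) == 1
        metrics["y_in_true_sex_group"] = (
            len(y_groups) == 1 and y_groups[0] in in_true
        )
        g = y_groups[0]
        full = lmap.table[lmap.table["group"] == g]
        end = full["cm"].max()
        dist_to_end = np.minimum(ytab.loc[ytab["group"] == g, "cm"],
                                 end - ytab.loc[ytab["group"] == g, "cm"])
        metrics["y_span_cm"] = float(
            ytab.loc[ytab["group"] == g, "cm"].max()
            - ytab.loc[ytab["group"] == g, "cm"].min()
        )
        metrics["y_max_dist_from_group_end_cm"] = float(dist_to_end.max())
        metrics["y_within_terminal_region"] = bool(
            (dist_to_end <= config.y_region_span_cM).all()
        )
        yhits = accepted[accepted["query"].isin(ytab["marker"])]
        metrics["y_hits_on_true_ref_chrom"] = int(
            (yhits["chrom"] == truth.homology[sex_chrom]).sum()
        )
        metrics["y_hits_total"] = int(len(yhits))
    return PipelineResult(
        truth=truth, coverage=coverage, candidates=candidates, family=family,
        filter_report=report, linkage_map=lmap, y_report=y_report,
        homology=homology, oxford=oxford, metrics=metrics,
    )


def discovery_replicates(config: SimConfig | None = None, n_replicates: int = 100,
                         base_seed: int = 0,
                         sex_cfg: SexAssocConfig | None = None) -> pd.DataFrame:
    """Candidate-discovery stage only, replicated across seeds.

    Returns one row per replicate with the Y-locus recall and the count of
    autosomal false positives (paralog screening skipped: it affects ranks,
    not membership).
    """
    config = config or SimConfig()
    sex_cfg = sex_cfg or SexAssocConfig()
    rows = []
    for i in range(n_replicates):
        import dataclasses

        cfg = dataclasses.replace(config, seed=base_seed + i)
        truth = simulate_truth(cfg)
        cov = simulate_adult_coverage(truth, cfg)
        cand = build_candidate_table(cov, catalog=None, cfg=sex_cfg)
        m = _discovery_metrics(cand, truth)
        rows.append((cfg.seed, m["candidate_recall"], m["autosomal_false_positives"]))
    return pd.DataFrame(rows, columns=["seed", "recall", "false_positives"])
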