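"""One-shot characterisation run producing a report bundle.

The bundle mirrors the classic mitogenome-paper table set: a feature table
with intergenic spacings, a composition TSV per region, codon-usage and
codon-bias TSVs, repeat/motif hit TSVs, a control-region annotation JSON and —
when an alignment is supplied — a variant TSV, a diversity JSON, a distance
matrix TSV and a Newick tree. A manifest records the package version, all
parameters and the seed, so a rerun with the same config is byte-identical
(timestamps are deliberately not written).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .codon_bias import (
    classify_start_stop,
    codon_usage,
    extract_cds,
    per_gene_bias_table,
    rscu,
)
from .composition import find_cpg_islands, molecular_weight, partition_profiles
from .control_region import annotate_control_region, load_motif_library
from .errors import PipelineError
from .phylo import bootstrap_support, distance_matrix, nj_tree, overall_mean_distance, write_newick
from .repeats import (
    find_inverted_repeats,
    find_palindromes,
    find_ssrs,
    find_tandem_repeats,
)
from .seq_io import intergenic_and_overlaps, read_alignment, read_genome
from .variation import call_variants, classify_coding_effect, diversity_stats, haplotype_partition


@dataclass
class RunConfig:
    genome_fasta: str | None = None
    features: str | None = None
    alignment_fasta: str | None = None
    reference_id: str | None = None
    out_dir: str = "mitoprofile_run"
    seed: int = 0
    # stage toggles
    do_composition: bool = True
    do_codon: bool = True
    do_repeats: bool = True
    do_control_region: bool = True
    do_variants: bool = True
    do_tree: bool = True
    # scan parameters (defaults follow the documented scan settings)
    ssr_unit_min: int = 1
    ssr_unit_max: int = 10
    ssr_min_copies: int = 3
    ssr_min_length: int = 6
    trf_min_score: int = 50
    trf_max_period: int = 500
    sir_arm_min: int = 6
    sir_arm_max: int = 50
    sir_gap_max: int = 20
    palindrome_min: int = 6
    palindrome_max: int = 30
    cpg_window: int = 100
    cpg_min_length: int = 200
    cpg_min_gc: float = 50.0
    cpg_min_obs_exp: float = 0.6
    tree_model: str = "TN93"
    bootstrap: int = 0
    motif_library: str | None = None
    quiet: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _hit_rows(hits) -> list[str]:
    rows = ["kind\tstart\tend\tunit_or_motif\tperiod\tcopies\tpercent_matches\tscore\tgap"]
    for h in hits:
        rows.append(
            f"{h.kind}\t{h.start}\t{h.end}\t{h.unit_or_motif}\t"
            f"{h.period if h.period is not None else '.'}\t"
            f"{h.copy_number if h.copy_number is not None else '.'}\t"
            f"{round(h.percent_matches, 1) if h.percent_matches is not None else '.'}\t"
            f"{h.score if h.score is not None else '.'}\t"
            f"{h.gap if h.gap is not None else '.'}"
        )
    return rows


def run_characterization(config: RunConfig) -> dict:
    """Run every enabled stage; returns the summary dict written to the bundle.

    Any stage failure aborts with :class:`PipelineError` naming the stage;
    outputs written so far stay on disk next to a FAILED marker.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}
    stage = "setup"
    try:
        genome = None
        if config.genome_fasta:
            stage = "read_genome"
            genome = read_genome(config.genome_fasta, config.features)
            summary["genome_id"] = genome.id
            summary["genome_length_bp"] = genome.length

            stage = "features"
            spacing = intergenic_and_overlaps(genome.features, genome.length)
            with open(out / "features.tsv", "w") as fh:
                fh.write("name\tkind\tstart\tend\tsize\tstrand\tspacing_to_next\n")
                sp = {pair[0]: s for pair, s in spacing}
                for f in sorted(genome.features, key=lambda f: f.start):
                    fh.write(
                        f"{f.name}\t{f.kind}\t{f.start}\t{f.end}\t{f.size}\t"
                        f"{f.strand}\t{sp.get(f.name, '.')}\n"
                    )

            if config.do_composition:
                stage = "composition"
                profiles = partition_profiles(genome)
                with open(out / "composition.tsv", "w") as fh:
                    fh.write(
                        "region_label\tA\tC\tG\tT\tN\tAT_percent\tGC_percent\t"
                        "AT_skew\tGC_skew\n"
                    )
                    for p in profiles:
                        r = p.rounded()
                        fh.write(
                            "\t".join(
                                str(r[k]) if r[k] is not None else "NA"
                                for k in (
                                    "region_label", "A", "C", "G", "T", "N",
                                    "AT_percent", "GC_percent", "AT_skew", "GC_skew",
                                )
                            )
                            + "\n"
                        )
                islands = find_cpg_islands(
                    genome.sequence,
                    window=config.cpg_window,
                    min_length=config.cpg_min_length,
                    min_gc=config.cpg_min_gc,
                    min_obs_exp=config.cpg_min_obs_exp,
                )
                summary["n_cpg_islands"] = len(islands)
                summary["molecular_weight_kDa"] = (
                    round(molecular_weight(genome.sequence), 2)
                    if "N" not in genome.sequence
                    else None
                )
                whole = profiles[0]
                summary["at_percent"] = round(whole.at_percent, 2)
                summary["at_skew"] = round(whole.at_skew, 3)
                summary["gc_skew"] = round(whole.gc_skew, 3)

            if config.do_codon:
                stage = "codon_usage"
                pcgs = [f for f in genome.features if f.kind == "PCG"]
                cds_list = [extract_cds(genome, f) for f in pcgs]
                usage = codon_usage(cds_list)
                with open(out / "codon_usage.tsv", "w") as fh:
                    fh.write("codon\tamino_acid\tcount\tpercent\trscu\n")
                    r = rscu(usage)
                    pct = usage.percent
                    from .codon_bias import CODON_TO_AA

                    for codon in sorted(usage.counts):
                        aa = CODON_TO_AA.get(codon, "*")
                        rs = r.get(codon)
                        fh.write(
                            f"{codon}\t{aa}\t{usage.counts[codon]}\t"
                            f"{pct[codon]:.2f}\t{rs if rs is None else round(rs, 3)}\n"
                        )
                with open(out / "codon_bias.tsv", "w") as fh:
                    fh.write("gene\tENc\tCBI\tGC3s\n")
                    for row in per_gene_bias_table(genome):
                        fh.write(
                            f"{row['gene']}\t{row['enc']:.3f}\t{row['cbi']:.3f}\t"
                            f"{row['gc3s']:.3f}\n"
                        )
                summary["total_codons"] = int(usage.total_codons)
                summary["coded_amino_acids"] = int(usage.total_sense)
                summary["start_stop_classes"] = {
                    cds.gene: classify_start_stop(cds) for cds in cds_list
                }

            if config.do_repeats:
                stage = "repeats"
                hits = []
                hits += find_ssrs(
                    genome.sequence,
                    unit_min=config.ssr_unit_min,
                    unit_max=config.ssr_unit_max,
                    min_copies=config.ssr_min_copies,
                    min_length=config.ssr_min_length,
                    circular=genome.circular,
                )
                hits += find_tandem_repeats(
                    genome.sequence,
                    min_score=config.trf_min_score,
                    max_period=config.trf_max_period,
                )
                hits += find_inverted_repeats(
                    genome.sequence,
                    arm_min=config.sir_arm_min,
                    arm_max=config.sir_arm_max,
                    gap_max=config.sir_gap_max,
                )
                hits += find_palindromes(
                    genome.sequence,
                    len_min=config.palindrome_min,
                    len_max=config.palindrome_max,
                )
                with open(out / "repeat_hits.tsv", "w") as fh:
                    fh.write("\n".join(_hit_rows(hits)) + "\n")
                summary["n_repeat_hits"] = {
                    kind: sum(1 for h in hits if h.kind == kind)
                    for kind in ("SSR", "tandem", "inverted", "palindrome")
                }

            if config.do_control_region:
                stage = "control_region"
                cr = next(
                    (f for f in genome.features if f.kind == "control_region"), None
                )
                if cr is not None:
                    lib = (
                        load_motif_library(config.motif_library)
                        if config.motif_library
                        else None
                    )
                    ann = annotate_control_region(
                        genome.slice_h(cr.start, cr.end), offset=cr.start,
                        motif_library=lib,
                    )
                    with open(out / "control_region.json", "w") as fh:
                        json.dump(
                            {
                                "cr": [ann.cr_start, ann.cr_end],
                                "domains": ann.domains,
                                "elements": [dataclasses.asdict(e) for e in ann.elements],
                                "missing": ann.missing,
                            },
                            fh,
                            indent=1,
                        )
                    summary["cr_elements_located"] = len(ann.elements)
                    summary["cr_elements_missing"] = len(ann.missing)

        if config.alignment_fasta:
            stage = "read_alignment"
            aln = read_alignment(config.alignment_fasta, config.reference_id)

            if config.do_variants:
                stage = "variants"
                feats = genome.features if genome is not None else None
                calls = call_variants(aln, features=feats)
                if genome is not None:
                    for v in calls:
                        v.coding_effect = classify_coding_effect(v, genome, genome.features)
                with open(out / "variants.tsv", "w") as fh:
                    fh.write(
                        "ref_position\taln_column\tkind\tref\talt\tcarriers\t"
                        "region\tcoding_effect\n"
                    )
                    for v in calls:
                        fh.write(
                            f"{v.ref_position}\t{v.aln_column}\t{v.kind}\t"
                            f"{v.ref_allele}\t{','.join(v.alt_alleles)}\t"
                            f"{','.join(v.carriers)}\t{v.region}\t{v.coding_effect}\n"
                        )
                stats = diversity_stats(aln)
                partition = haplotype_partition(aln)
                with open(out / "diversity.json", "w") as fh:
                    json.dump(
                        {
                            **dataclasses.asdict(stats),
                            "haplotypes": {
                                str(h): m for h, m in partition.items()
                            },
                        },
                        fh,
                        indent=1,
                    )
                summary["n_variants"] = len(calls)
                summary["variant_kinds"] = {
                    kind: sum(1 for v in calls if v.kind == kind)
                    for kind in ("transition", "transversion", "indel")
                }
                summary["n_haplotypes"] = stats.n_haplotypes
                summary["pi"] = round(stats.pi, 4)
                summary["hd"] = round(stats.hd, 4)

            if config.do_tree and aln.n_rows >= 3:
                stage = "tree"
                dm = distance_matrix(aln, model=config.tree_model)
                with open(out / "distances.tsv", "w") as fh:
                    fh.write("id\t" + "\t".join(dm.ids) + "\n")
                    for i, rid in enumerate(dm.ids):
                        fh.write(
                            rid + "\t"
                            + "\t".join(f"{dm.values[i, j]:.4f}" for j in range(len(dm.ids)))
                            + "\n"
                        )
                summary["overall_mean_distance"] = round(overall_mean_distance(dm), 4)
                if config.bootstrap > 0 and aln.n_rows >= 4:
                    tree = bootstrap_support(
                        aln, model=config.tree_model, B=config.bootstrap,
                        seed=config.seed,
                    )
                else:
                    tree = nj_tree(dm)
                write_newick(out / "tree.nwk", tree)

        stage = "manifest"
        manifest = {
            "package": "mitoprofile",
            "version": __version__,
            "config": dataclasses.asdict(config),
            "summary": summary,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        return summary
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
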