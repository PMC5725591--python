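"""Report rendering and the end-to-end pipeline driver."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import relationships as rel
from .chimera import ChimeraModelConfig, infer_all_loci
from .clonal_panel import group_profiles, greedy_discriminating_subset, minimal_discriminating_subsets
from .core_io import GenotypeCategory, read_genome, read_gff3_genes, read_region_mask, read_vcf_multisample
from .effects import annotate_cohort, summarize_effects
from .filtering import FilterParams, filter_cohort, write_rejected_tsv
from .partition import PartitionSummary, classify_site, tabulate_partition, write_labels_tsv
from .synthetic_data import (
    ChimeraSimConfig,
    CohortSimConfig,
    PanelSimConfig,
    generate_chimera_assays,
    generate_cohort,
    generate_panel,
    reference_panel_profile,
)

logger = logging.getLogger("clonotyper")


def render_partition_report(summary: PartitionSummary) -> tuple[str, dict]:
    """Text table mirroring the three-clone tally layout, plus a JSON twin
    with exact integers (percentages are display-rounded to one decimal in
    the text; the JSON keeps full precision)."""
    payload = summary.as_dict()
    clones = payload["clones"]
    header = ["Genotype"] + [f"clone-specific {c}" for c in clones] + ["varietal", "total"]
    lines = ["\t".join(header)]
    for row_name in ("HOM_REF", "HOM_ALT", "HET"):
        row = payload["rows"][row_name]
        lines.append(
            "\t".join(
                [row_name]
                + [f"{row[c]:,}" for c in clones]
                + [f"{row['varietal']:,}", f"{row['total']:,}"]
            )
        )
    lines.append("\t".join(["Excluded"] + ["-"] * len(clones) + ["-", f"{payload['excluded']:,}"]))
    totals = payload["totals"]
    lines.append(
        "\t".join(
            ["TOTAL"]
            + [f"{totals[c]:,}" for c in clones]
            + [f"{totals['varietal']:,}", f"{totals['total']:,}"]
        )
    )
    frac = payload["varietal_fraction"]
    percent = "n/a" if frac is None else f"{100 * frac:.1f}%"
    lines.append(f"Varietal fraction: {percent}")
    return "\n".join(lines), payload


@dataclass
class RunConfig:
    """Driver configuration; with no input paths, the synthetic generators
    supply every input."""

    out_dir: str
    seed: int = 0
    vcf: str | None = None
    mask: str | None = None
    gff3: str | None = None
    fasta: str | None = None
    panel_csv: str | None = None
    assays_csv: str | None = None
    clone_names: tuple[str, ...] | None = None
    filter_params: FilterParams = field(default_factory=FilterParams)
    chimera_config: ChimeraModelConfig = field(default_factory=ChimeraModelConfig)
    cohort_sim: CohortSimConfig | None = None
    panel_sim: PanelSimConfig | None = None
    chimera_sim: ChimeraSimConfig | None = None
    bootstrap_reps: int = 1000


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """simulate? -> filter -> partition -> annotate -> chimera -> classify ->
    tree -> network; returns the artifact manifest (paths + checksums)."""
    os.makedirs(config.out_dir, exist_ok=True)
    artifacts: dict[str, str] = {}
    stage = "setup"
    try:
        if config.vcf is None:
            stage = "simulate"
            sim_dir = os.path.join(config.out_dir, "simulated")
            cohort_cfg = config.cohort_sim or CohortSimConfig(seed=config.seed)
            cohort = generate_cohort(cohort_cfg, out_dir=sim_dir)
            config.vcf = cohort.paths["vcf"]
            config.mask = cohort.paths["repeats"]
            config.gff3 = cohort.paths["genes"]
            config.fasta = cohort.paths["genome"]
            config.clone_names = cohort_cfg.clone_names
            artifacts.update({f"sim_{k}": v for k, v in cohort.paths.items()})
            panel_cfg = config.panel_sim or PanelSimConfig(seed=config.seed)
            panel_data = generate_panel(panel_cfg, out_dir=sim_dir)
            config.panel_csv = panel_data.paths["panel"]
            artifacts["sim_panel"] = panel_data.paths["panel"]
            chimera_cfg = config.chimera_sim or ChimeraSimConfig(seed=config.seed)
            chimera_data = generate_chimera_assays(chimera_cfg, out_dir=sim_dir)
            config.assays_csv = chimera_data.paths["assays"]
            artifacts["sim_assays"] = chimera_data.paths["assays"]

        stage = "filter"
        for required in ("vcf", "mask"):
            path = getattr(config, required)
            if path is None or not os.path.exists(path):
                raise FileNotFoundError(f"missing input for filter stage: {required}={path}")
        from .core_io import read_samples

        clone_names = list(config.clone_names or read_samples(config.vcf))
        records = read_vcf_multisample(config.vcf, clone_names)
        mask = read_region_mask(config.mask)
        passing, rejected, summary = filter_cohort(records, mask, config.filter_params)
        logger.info("filter: %d in, %d passed, %d rejected", summary.n_input, summary.n_passed, summary.n_rejected)
        rejected_path = os.path.join(config.out_dir, "rejected.tsv")
        write_rejected_tsv(rejected, rejected_path)
        filter_json = os.path.join(config.out_dir, "filter_summary.json")
        with open(filter_json, "w") as fh:
            json.dump(summary.as_dict(), fh, indent=2)
        artifacts["rejected"] = rejected_path
        artifacts["filter_summary"] = filter_json

        stage = "partition"
        labels = [classify_site(r.calls) for r in passing]
        part_summary = tabulate_partition(labels, clone_names)
        labels_path = os.path.join(config.out_dir, "labels.tsv")
        write_labels_tsv(passing, labels, labels_path)
        text, payload = render_partition_report(part_summary)
        table1_path = os.path.join(config.out_dir, "partition_summary.json")
        with open(table1_path, "w") as fh:
            json.dump(payload, fh, indent=2)
        with open(os.path.join(config.out_dir, "partition_summary.txt"), "w") as fh:
            fh.write(text + "\n")
        artifacts["labels"] = labels_path
        artifacts["partition_summary"] = table1_path

        stage = "annotate"
        genome = read_genome(config.fasta)
        genes = read_gff3_genes(config.gff3)
        from .partition import PartitionKind

        site_category = {}
        varietal_records = []
        for record, label in zip(passing, labels):
            if label.kind is PartitionKind.VARIETAL:
                site_category[(record.chrom, record.pos)] = label.reported_category
                varietal_records.append(record)
        effects = annotate_cohort(varietal_records, genes, genome)
        effect_summary = summarize_effects(effects, site_category)
        effects_json = os.path.join(config.out_dir, "effect_summary.json")
        with open(effects_json, "w") as fh:
            json.dump(effect_summary.as_dict(), fh, indent=2)
        artifacts["effect_summary"] = effects_json

        stage = "chimera"
        assays_df = pd.read_csv(config.assays_csv)
        from .chimera import LayerAssay

        assays = [
            LayerAssay(row.locus, row.tissue, float(row.alt_fraction))
            for row in assays_df.itertuples(index=False)
        ]
        inferences = infer_all_loci(assays, config.chimera_config)
        chim_path = os.path.join(config.out_dir, "chimera_inferences.csv")
        pd.DataFrame(
            [
                {
                    "locus": inf.locus,
                    "l1_state": inf.l1_state,
                    "l2_state": inf.l2_state,
                    "is_chimera": inf.is_chimera,
                    "residual": inf.residual,
                    "note": inf.note,
                }
                for inf in inferences
            ]
        ).to_csv(chim_path, index=False)
        artifacts["chimera_inferences"] = chim_path

        stage = "classify"
        from .clonal_panel import read_panel_csv

        panel = read_panel_csv(config.panel_csv)
        grouping = group_profiles(panel)
        classes_path = os.path.join(config.out_dir, "classes.csv")
        pd.DataFrame(
            [
                {"class": c.label, "n_members": len(c.members), "profile": "/".join(c.profile)}
                for c in grouping.classes
            ]
        ).to_csv(classes_path, index=False)
        subsets = minimal_discriminating_subsets(grouping.classes, panel.markers)
        subsets_path = os.path.join(config.out_dir, "subsets.json")
        with open(subsets_path, "w") as fh:
            json.dump(
                {
                    "size": subsets.size,
                    "subsets": [list(s) for s in subsets.subsets],
                    "greedy": list(greedy_discriminating_subset(grouping.classes, panel.markers)),
                },
                fh,
                indent=2,
            )
        artifacts["classes"] = classes_path
        artifacts["subsets"] = subsets_path

        stage = "tree"
        profiles = {c.label: c.profile for c in grouping.classes}
        freqs = {c.label: len(c.members) for c in grouping.classes}
        ref_profile = reference_panel_profile() if len(next(iter(profiles.values()))) == len(reference_panel_profile()) else None
        dm = rel.profiles_distance_matrix(profiles, ref_profile)
        tree = rel.upgma_tree(dm)
        supports = rel.bootstrap_support(profiles, n_reps=config.bootstrap_reps, seed=config.seed,
                                         reference_profile=ref_profile)
        rel.attach_supports(tree, supports)
        tree_path = os.path.join(config.out_dir, "tree.nwk")
        with open(tree_path, "w") as fh:
            fh.write(tree.to_newick() + ";\n")
        artifacts["tree"] = tree_path

        stage = "network"
        network = rel.median_joining_network(profiles, freqs)
        net_path = os.path.join(config.out_dir, "network.gml")
        rel.write_gml(network, net_path, marker_names=list(panel.markers))
        artifacts["network"] = net_path
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "artifacts": {name: {"path": path, "sha256": _checksum(path)} for name, path in artifacts.items()},
    }
    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
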