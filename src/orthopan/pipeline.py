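"""Project setup and the end-to-end pipeline driver.

``project_init`` ingests the configured genomes, applies identical-paralog
filtering and writes the project manifests; ``run_pipeline`` chains
align → store → orthologs → pan/core/singletons → similarity matrices,
logging survivor counts at every stage. Both are thin compositions of the
library modules and are what the CLI subcommands call.
"""

from __future__ import annotations

import logging
from pathlib import Path

from . import align_driver, distances, genesets, genome_model, hitstore, orthology
from .config import MIN_PROJECT_GENOMES, ProjectConfig

logger = logging.getLogger("orthopan")


def project_init(config: ProjectConfig | str | Path) -> genome_model.Project:
    """Ingest all configured genomes and write the project manifests."""
    if not isinstance(config, ProjectConfig):
        config = ProjectConfig.load(config)
    if len(config.genomes) < MIN_PROJECT_GENOMES:
        raise ValueError(
            f"project requires at least {MIN_PROJECT_GENOMES} genomes "
            f"(got {len(config.genomes)})")
    project = genome_model.Project(name=config.name)
    for entry in config.genomes:
        path = Path(entry["path"])
        name = entry.get("name", path.stem)
        fmt = entry.get("format") or ("genbank" if path.suffix.lower() in
                                      (".gb", ".gbk", ".gbff", ".genbank") else "fasta")
        if fmt == "genbank":
            genome_model.ingest_genbank(path, name, project)
        else:
            genome_model.ingest_fasta_pair(path, entry["contig_map"], name, project)
        gid = project.genome_by_name(name).genome_id
        before = len(project.active_genes(gid))
        genome_model.filter_identical_paralogs(project, gid)
        after = len(project.active_genes(gid))
        logger.info("genome %s: %d genes, %d after paralog filtering", name, before, after)
    project.validate()
    genome_model.write_manifests(project, config.manifest_dir)
    logger.info("project %s: %d genomes, %d genes (%d aliased paralogs)",
                config.name, len(project.genomes), len(project.genes),
                len(project.paralog_aliases))
    return project


def build_store(config: ProjectConfig, project: genome_model.Project) -> hitstore.HitStore:
    """Run the configured alignment backend and write the hit store."""
    if config.backend in ("table", "synthetic"):
        if not config.hits_table:
            raise ValueError("table/synthetic backend needs 'hits_table' in the config")
        cls = (align_driver.SyntheticBackend if config.backend == "synthetic"
               else align_driver.TableBackend)
        backend = cls(table=config.hits_table)
    elif config.backend == "external":
        if not config.cmd_template:
            raise ValueError("external backend needs 'cmd_template' in the config")
        backend = align_driver.ExternalBackend(cmd_template=config.cmd_template)
    else:
        raise ValueError(f"unknown backend {config.backend!r}")
    hits = align_driver.run_all_vs_all(project, backend,
                                       workers=config.workers,
                                       chunk_size=config.chunk_size)
    logger.info("alignment produced %d hits", len(hits))
    Path(config.outdir).mkdir(parents=True, exist_ok=True)
    hitstore.write_store(hits, project, config.store_prefix,
                         compression=config.compression)
    return hitstore.HitStore(config.store_prefix)


def open_project(config: ProjectConfig) -> genome_model.Project:
    if not (config.manifest_dir / "genes.tsv").exists():
        raise FileNotFoundError(
            f"no project manifests under {config.manifest_dir}; run 'init' first")
    return genome_model.read_manifests(config.manifest_dir)


def open_store(config: ProjectConfig) -> hitstore.HitStore:
    if not (Path(str(config.store_prefix) + ".ehx")).exists():
        raise FileNotFoundError(
            f"no hit store at {config.store_prefix}; run 'align' first")
    return hitstore.HitStore(config.store_prefix)


def run_pipeline(config: ProjectConfig | str | Path) -> dict:
    """Full run; returns a summary dict and writes all standard outputs."""
    if not isinstance(config, ProjectConfig):
        config = ProjectConfig.load(config)
    outdir = Path(config.outdir)
    project = project_init(config)
    store = build_store(config, project)
    genome_ids = [g.genome_id for g in project.genomes]
    criteria = config.orthology_criteria

    ortho = orthology.orthologs_pairwise(project, store, genome_ids,
                                         criteria, config.workers)
    orthology.ortholog_table(ortho, project).to_csv(
        outdir / "orthologs.tsv", sep="\t", index=False)

    pm = genesets.pan_genome(project, genome_ids, genome_ids[0],
                             criteria, ortho=ortho)
    pm.to_frame(project).to_csv(outdir / "pan_matrix.tsv", sep="\t", index=False)
    pm.to_triplets().to_csv(outdir / "pan_matrix_triplets.tsv", sep="\t", index=False)
    singles = genesets.singletons(project, genome_ids, criteria, ortho=ortho)
    curves = genesets.development_curves(project, genome_ids, criteria,
                                         ortho=ortho, seed=config.seed)
    curves.to_csv(outdir / "development_curves.tsv", sep="\t", index=False)
    genesets.upset_table(pm).to_frame(project).to_csv(
        outdir / "upset.tsv", sep="\t", index=False)

    aai_m = distances.similarity_matrix(project, store, genome_ids, "aai",
                                        criteria, workers=config.workers)
    aai_m.to_tsv(project, outdir / "aai.tsv")
    pocp_m = distances.similarity_matrix(
        project, store, genome_ids,
        "pocp_rbh" if config.pocp_variant == "rbh" else "pocp_strict",
        criteria, workers=config.workers)
    pocp_m.to_tsv(project, outdir / "pocp.tsv")

    summary = {
        "genomes": len(genome_ids),
        "genes": len(project.genes),
        "active_genes": len(project.all_active_genes()),
        "stored_hits": store.total_hits(),
        "ortholog_pairs": sum(len(o.pairs) for o in ortho.values()),
        "pan": pm.pan_size,
        "core": pm.core_size,
        "singletons": {project.genomes[g].name: len(v) for g, v in singles.items()},
    }
    logger.info("pipeline summary: %s", summary)
    return summary
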