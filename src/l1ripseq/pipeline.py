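"""End-to-end orchestration: simulate -> classify -> quantify -> enrich ->
compare, with a run manifest.

Stages communicate through files in the output directory using standard
formats (FASTA/FASTQ/SAM/BED/GTF/TSV/JSON), so each stage can also be
run alone from the CLI on externally produced inputs. Stage seeds are
derived from the master seed by fixed offsets, making every stage
independently reproducible; the manifest records a config hash, per-file
checksums and wall times, and reruns with the same config and seed must
produce identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, em, enrichment, granules, simulate


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def config_from_dict(d: dict, seed: int | None = None) -> simulate.SimulationConfig:
    known = {f.name for f in dataclasses.fields(simulate.SimulationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    cfg = dict(d)
    if seed is not None:
        cfg["seed"] = seed
    for tup_key in ("class_proportions",):
        if tup_key in cfg:
            cfg[tup_key] = tuple(cfg[tup_key])
    return simulate.SimulationConfig(**cfg)


def _category_annotations(genome: simulate.SimulatedGenome) -> pd.DataFrame:
    rows = []
    for _, g in genome.genes.iterrows():
        if g["category"] == "rRNA":
            rows.append((genome.chrom, g["start"], g["end"], "rRNA"))
        rows.append((genome.chrom, g["start"], g["end"], "exon"))
    for _, locus in genome.loci.iterrows():
        rows.append((genome.chrom, locus["start"], locus["end"], "L1"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "category"])


def _fragment_positions(
    hits: simulate.FragmentHits, genome: simulate.SimulatedGenome
) -> pd.DataFrame:
    """Primary-alignment genomic position of every fragment (unmapped: -1)."""
    g = simulate.hits_to_genomic(hits, genome)
    g = g.assign(nm=g["nm1"] + g["nm2"]).sort_values(
        ["read_id", "nm", "feature_id"], kind="stable"
    )
    best = g.drop_duplicates("read_id", keep="first")
    unmapped = pd.DataFrame(
        {
            "read_id": hits.unmapped,
            "chrom": genome.chrom,
            "g_start": -1,
            "g_end": -1,
            "feature_id": "*",
        }
    )
    out = pd.concat(
        [best[["read_id", "chrom", "g_start", "g_end", "feature_id"]], unmapped],
        ignore_index=True,
    )
    return out.rename(columns={"g_start": "start", "g_end": "end"})


def _build_count_table(
    genome: simulate.SimulatedGenome,
    calls: pd.DataFrame,
    hits: dict[str, simulate.FragmentHits],
    reads: dict[str, simulate.ReadSet],
    estimates: dict[str, em.AbundanceEstimate],
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-feature counts for input and IP.

    Host genes and circRNA features are counted from primary alignments;
    LINE-1 intactness classes get the EM expected counts summed over
    member loci (the locus-level resolution is what the EM is for); all
    back-splice junction reads are pooled into one circRNA feature.
    """
    gene_ids = list(genome.genes["gene_id"])
    circ_ids = [f"circ|{g}" for g in genome.genes.loc[genome.genes["circ_start"] >= 0, "gene_id"]]
    class_feats = [f"L1:{c}" for c in simulate.CLASSES]
    features = gene_ids + circ_ids + ["circRNA_pooled"] + class_feats
    cols = {}
    for lib in ("input", "ip"):
        best = (
            hits[lib]
            .hits.assign(nm=lambda d: d["nm1"] + d["nm2"])
            .sort_values(["read_id", "nm", "feature_id"], kind="stable")
            .drop_duplicates("read_id", keep="first")
        )
        counts = best["feature_id"].value_counts()
        agg = em.aggregate_by_class(estimates[lib], calls).set_index("intact_class")
        junction_by_gene = (
            reads[lib]
            .origin_table()
            .query("junction")
            .groupby("feature_id")["read_id"]
            .count()
        )
        vec = []
        for f in features:
            if f.startswith("L1:"):
                cls = f[3:]
                vec.append(
                    float(agg.loc[cls, "expected_count"]) if cls in agg.index else 0.0
                )
            elif f == "circRNA_pooled":
                vec.append(float(enrichment.pool_circ_reads(junction_by_gene.to_list())))
            else:
                vec.append(float(counts.get(f, 0)))
        cols[lib] = vec
    table = pd.DataFrame(cols, index=pd.Index(features, name="feature_id"))
    cat = {}
    for _, g in genome.genes.iterrows():
        cat[g["gene_id"]] = g["category"]
    for f in circ_ids:
        cat[f] = "circRNA"
    cat["circRNA_pooled"] = "circRNA_pooled"
    for c in simulate.CLASSES:
        cat[f"L1:{c}"] = f"L1_{c}"
    return table, pd.Series(cat).reindex(table.index)


def run_all(
    config: simulate.SimulationConfig,
    outdir: Path,
    max_mismatches: int = 5,
    normalize_to: str = "all",
) -> dict:
    """Execute the whole pipeline on one simulated experiment.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
        "warnings": [],
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True, default=str).encode()
    ).hexdigest()

    def stage(name):
        t0 = time.perf_counter()

        def done(**extra):
            manifest["stages"][name] = {
                "wall_s": round(time.perf_counter() - t0, 3),
                **extra,
            }

        return done

    # ---- simulate -------------------------------------------------------
    done = stage("simulate")
    genome, truth, reads, hits = simulate.simulate_all(config, outdir)
    done(n_loci=len(genome.loci), n_genes=len(genome.genes))

    # ---- classify-orfs --------------------------------------------------
    done = stage("classify_orfs")
    locus_seqs = {lid: simulate.decode(genome.transcripts[lid]) for lid in genome.loci["locus_id"]}
    calls = annotate.classify_panel(
        locus_seqs, genome.orf1_protein, genome.orf2_protein
    )
    calls.to_csv(outdir / "intactness_calls.tsv", sep="\t", index=False)
    done(n_loci=len(calls))

    # ---- quantify-l1 ----------------------------------------------------
    done = stage("quantify_l1")
    estimates = {}
    em_report = {}
    for lib in ("input", "ip"):
        C = em.compatibility_from_hits(
            hits[lib].hits,
            genome.loci["locus_id"].to_numpy(),
            config.sequencing_error_rate,
            config.read_length,
            n_unmapped=len(hits[lib].unmapped),
        )
        est = em.em_quantify(C)
        estimates[lib] = est
        est.to_frame().to_csv(outdir / f"l1_theta_{lib}.tsv", sep="\t", index=False)
        em_report[lib] = {
            "iterations": est.iterations,
            "converged": est.converged,
            "n_fragments": est.n_fragments,
            "n_dropped": est.n_dropped,
            "logL_first": est.log_likelihood[0],
            "logL_last": est.log_likelihood[-1],
        }
    with open(outdir / "em_report.json", "w") as fh:
        json.dump(em_report, fh, indent=2)
    done(**{k: v["iterations"] for k, v in em_report.items()})

    # ---- enrich ---------------------------------------------------------
    done = stage("enrich")
    table, categories = _build_count_table(genome, calls, hits, reads, estimates)
    table.to_csv(outdir / "counts.tsv", sep="\t")
    if normalize_to == "all":
        norm = enrichment.total_count_factors(table)
    elif normalize_to == "exon":
        exonic = categories[
            ~categories.isin(["rRNA"]) & ~categories.str.startswith(("L1_", "circRNA"))
        ].index
        norm = enrichment.total_count_factors(table, exonic)
    elif normalize_to == "median":
        norm = enrichment.size_factors(table)
    else:
        raise ValueError(f"unknown normalize_to mode: {normalize_to}")
    enr = enrichment.fold_enrichment(
        table, ip_samples=["ip"], input_samples=["input"],
        normalization=norm, categories=categories,
    )
    enr.to_csv(outdir / "enrichment.tsv", sep="\t")
    fractions = {}
    annotations = _category_annotations(genome)
    for lib in ("input", "ip"):
        pos = _fragment_positions(hits[lib], genome)
        fractions[lib] = enrichment.count_read_categories(pos, annotations).to_dict()
    summaries = {}
    for cat in sorted(categories.dropna().unique()):
        try:
            summaries[cat] = enrichment.category_summary(enr.reset_index(), cat)
        except ValueError:
            continue
    with open(outdir / "enrichment_summary.json", "w") as fh:
        json.dump(
            {
                "size_factors": norm.factors.to_dict(),
                "read_fractions": fractions,
                "category_summaries": summaries,
            },
            fh,
            indent=2,
            default=float,
        )
    done(n_features=len(enr))

    # ---- compare-granules -----------------------------------------------
    done = stage("compare_granules")
    external = simulate.simulate_external_tables(truth, config)
    for name, tab in external.items():
        tab.to_csv(outdir / f"external_{name}.tsv", sep="\t", index=False)
    gene_enr = enr[enr.index.isin(set(external["pbody"]["gene_id"]))]
    comp_pbody = granules.join_and_compare(gene_enr, external["pbody"])
    comp_sg = granules.join_and_compare(
        gene_enr, external["sg"], external2=external["pbody"]
    )
    comparison = {"pbody": comp_pbody.to_dict(), "sg": comp_sg.to_dict()}
    with open(outdir / "granule_comparison.json", "w") as fh:
        json.dump(comparison, fh, indent=2, default=float)
    done(n_joined=comp_pbody.n_joined)

    # ---- manifest -------------------------------------------------------
    manifest["files"] = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest
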