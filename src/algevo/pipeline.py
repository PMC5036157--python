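"""Configuration-driven orchestration of the full analysis.

A run reads a flat YAML config (sections: inputs, params, seed, outdir),
executes the stages whose inputs are present — domain screening,
subfamily delineation, reconciliation, genomic context, ecophysiology —
and writes CSV/JSON outputs plus a parameter-echo run log. Outputs are
deterministic under fixed seeds (stable sort orders, fixed float
formatting, no timestamps), so re-running a config reproduces files
byte-for-byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import domain_screen, ecophys, genome_context, subfamily, synthetic_data
from . import reconcile as rec_mod
from .treeio import TaxonMap, as_dated, read_newick_file

FLOAT_FMT = "%.10g"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    cfg.setdefault("inputs", {})
    cfg.setdefault("params", {})
    cfg.setdefault("seed", 0)
    paths = []
    for p in cfg["inputs"].values():
        paths.extend(p if isinstance(p, list) else [p])
    missing = [str(p) for p in paths if p and not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"config references missing inputs: {missing}")
    return cfg


def _write(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, float_format=FLOAT_FMT, index=False, **kwargs)


def run(config: dict, outdir) -> dict:
    """Execute all stages whose inputs are configured; return a report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = config.get("inputs", {})
    params = config.get("params", {})
    seed = int(config.get("seed", 0))
    report: dict = {"stages": {}, "parameters": params, "seed": seed}
    log_lines = [f"algevo run | seed={seed}"]
    for k, v in sorted(params.items()):
        log_lines.append(f"param {k} = {v}")

    taxa = TaxonMap.from_csv(inputs["taxa"]) if inputs.get("taxa") else None

    # ---- domain screening
    if inputs.get("hits"):
        try:
            hits = pd.read_csv(inputs["hits"])
            filt = domain_screen.filter_hits(
                hits,
                e_max=float(params.get("e_max", domain_screen.E_MAX_DEFAULT)),
                cov_min=float(params.get("cov_min", domain_screen.COV_MIN_DEFAULT)),
                best_per_orf=True,
            )
            _write(filt, outdir / "filtered_hits.csv")
            if taxa is not None:
                cm = domain_screen.copy_numbers(filt, taxa)
                cm.to_csv(outdir / "copies_genome.csv",
                          outdir / "copies_population.csv")
            report["stages"]["screen"] = dict(done=True, n_hits=int(len(filt)))
            log_lines.append(f"screen: {len(hits)} hits -> {len(filt)} retained")
        except Exception as exc:
            raise StageError("screen", exc) from exc
    else:
        report["stages"]["screen"] = dict(done=False, reason="no hits input")
        log_lines.append("screen: skipped (no hits input)")

    # ---- subfamilies
    if inputs.get("gene_tree") and taxa is not None:
        try:
            gt = read_newick_file(inputs["gene_tree"])[0]
            aln = None
            if inputs.get("alignment"):
                aln = _read_fasta(inputs["alignment"])
            merge = params.get("merge_candidates")
            sfs = subfamily.delineate(
                gt, taxa,
                bootstrap_threshold=float(params.get("bootstrap_threshold", 70)),
                merge_candidates=merge,
                alignment=aln,
                cutoff=params.get("distance_cutoff"),
                alpha=float(params.get("au_alpha", 0.05)),
                replicates=int(params.get("au_replicates", 2000)),
                seed=seed,
            )
            _write(subfamily.subfamilies_to_frame(sfs), outdir / "subfamilies.csv")
            report["stages"]["subfamilies"] = dict(done=True, n=len(sfs))
            log_lines.append(f"subfamilies: {len(sfs)} delineated")
        except Exception as exc:
            raise StageError("subfamilies", exc) from exc
    else:
        report["stages"]["subfamilies"] = dict(done=False, reason="no gene tree/taxa")
        log_lines.append("subfamilies: skipped")

    # ---- reconciliation
    if inputs.get("species_tree") and inputs.get("family_trees"):
        try:
            sp = as_dated(read_newick_file(inputs["species_tree"])[0])
            sliced = rec_mod.SlicedTree(
                sp, slices_per_interval=int(params.get("slices_per_interval", 4))
            )
            costs = rec_mod.CostScheme(
                loss=float(params.get("loss_cost", 1.0)),
                duplication=float(params.get("duplication_cost", 2.0)),
                transfer=float(params.get("transfer_cost", 3.0)),
            )
            recs, ev_frames = [], []
            fam_paths = inputs["family_trees"]
            if isinstance(fam_paths, str):
                fam_paths = [fam_paths]
            names = []
            for path in fam_paths:
                for i, gt in enumerate(read_newick_file(path)):
                    name = f"{Path(path).stem}_{i+1}"
                    r = rec_mod.reconcile(gt, sliced, taxa, costs)
                    recs.append(r)
                    fr = r.to_frame()
                    fr.insert(0, "family", name)
                    ev_frames.append(fr)
                    names.append((name, r.total_cost))
            _write(pd.concat(ev_frames, ignore_index=True), outdir / "events.csv")
            clades = {"all": set(sliced.bid.values())}
            crown = params.get("crown_populations")
            if crown and taxa is not None:
                leaves = [
                    g for p in crown for g in {
                        taxa.genome(l) for l in taxa.populations().get(p, [])
                    }
                ]
                if leaves:
                    clades["crown"] = rec_mod.clade_branches(sliced, leaves)
            summary = rec_mod.summarize(recs, sliced, clades, taxa)
            _write(summary.to_frame(), outdir / "acquisitions.csv")
            summary.per_branch.to_csv(outdir / "events_per_branch.csv",
                                      float_format=FLOAT_FMT)
            costs_df = pd.DataFrame(names, columns=["family", "total_cost"])
            _write(costs_df, outdir / "reconciliation_costs.csv")
            report["stages"]["reconcile"] = dict(done=True, n_families=len(recs))
            log_lines.append(
                f"reconcile: {len(recs)} families, costs "
                + ",".join(f"{c:g}" for _, c in names)
            )
        except Exception as exc:
            raise StageError("reconcile", exc) from exc
    else:
        report["stages"]["reconcile"] = dict(done=False, reason="no trees")
        log_lines.append("reconcile: skipped")

    # ---- genomic context
    if inputs.get("genes"):
        try:
            genes = pd.read_csv(inputs["genes"])
            lyases = genes[genes["category"].str.startswith("lyase")]
            gap = int(params.get("chain_gap", 5000))
            regions = genome_context.chain_regions(lyases, gap=gap)
            _write(genome_context.regions_to_frame(regions), outdir / "regions.csv")
            enr = genome_context.region_enrichment(regions, genes)
            _write(enr, outdir / "region_enrichment.csv")
            if inputs.get("gc_windows"):
                gc = pd.read_csv(inputs["gc_windows"])
                dep = genome_context.gc_depletion(regions, gc_windows=gc)
                _write(dep, outdir / "gc_depletion.csv")
            report["stages"]["context"] = dict(done=True, n_regions=len(regions))
            log_lines.append(f"context: {len(regions)} regions (gap={gap})")
        except Exception as exc:
            raise StageError("context", exc) from exc
    else:
        report["stages"]["context"] = dict(done=False, reason="no gene table")
        log_lines.append("context: skipped")

    # ---- ecophysiology
    if inputs.get("growth"):
        try:
            growth = pd.read_csv(inputs["growth"])
            per_rep, mean = ecophys.fit_growth_table(growth)
            _write(per_rep, outdir / "growth_fits.csv")
            calls = ecophys.classify_growth(
                mean,
                r_min=float(params.get("r_min", 0.05)),
                delta_od_min=float(params.get("delta_od_min", 0.05)),
            )
            _write(calls, outdir / "growth_calls.csv")
            assoc = None
            if (outdir / "copies_genome.csv").exists():
                cn = pd.read_csv(outdir / "copies_genome.csv", index_col=0)
                table = ecophys.build_pheno_geno_table(cn, calls)
                assoc = {}
                for col in [c for c in table.columns if c.startswith("grows_")]:
                    try:
                        orr, p, tab = ecophys.genotype_phenotype_test(
                            table, "has_oal", col
                        )
                        assoc[col] = dict(odds_ratio=orr, p=p,
                                          table=tab.tolist())
                    except ValueError:
                        continue
                with open(outdir / "association.json", "w") as fh:
                    json.dump(assoc, fh, indent=2, sort_keys=True)
            report["stages"]["ecophys"] = dict(done=True,
                                               n_fits=int(len(per_rep)))
            log_lines.append(f"ecophys: {len(per_rep)} replicate fits")
        except Exception as exc:
            raise StageError("ecophys", exc) from exc
    else:
        report["stages"]["ecophys"] = dict(done=False, reason="no growth input")
        log_lines.append("ecophys: skipped (no growth input)")

    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(outdir / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return report


def _read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# bundled synthetic dataset


def simulate_dataset(
    outdir,
    seed: int = 0,
    n_species: int = 8,
    n_families: int = 3,
) -> dict:
    """Generate a complete synthetic input bundle plus its config file.

    Writes: species tree and per-family gene trees (Newick), taxon map,
    domain-hit table consistent with the simulated copy numbers, a
    focal/outgroup gene tree with alignment for subfamily delineation,
    an annotated genome with planted islands, growth curves, and
    truth.json recording every planted quantity.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sp = synthetic_data.sim_species_tree(n_species, seed=seed)
    (out / "species.nwk").write_text(sp.to_newick() + "\n")

    species = sorted(sp.leaf_labels())
    pops = {s: f"P{(i // 2) + 1}" for i, s in enumerate(species)}
    with open(out / "taxa.csv", "w") as fh:
        fh.write("leaf,genome,population,focal\n")
        for s in species:
            fh.write(f"{s},{s},{pops[s]},1\n")
    taxa = TaxonMap.from_csv(out / "taxa.csv")

    families = [f"PL{k}" for k in (6, 7, 15, 17)][:n_families]
    truth: dict = {"families": {}, "seed": seed}
    tree_paths = []
    hit_rows = []
    for fi, fam in enumerate(families):
        forest, log = synthetic_data.sim_gene_family(
            sp, dup_rate=0.2, transfer_rate=0.2, loss_rate=0.3,
            seed=seed * 101 + fi, root_copies=1,
        )
        path = out / f"family_{fam}.nwk"
        with open(path, "w") as fh:
            for t in forest:
                fh.write(t.to_newick() + "\n")
        tree_paths.append(str(path))
        truth["families"][fam] = {
            "events": {k: log.count(k) for k in
                       ("duplication", "transfer", "loss", "acquisition")},
            "copy_numbers": log.final_counts,
        }
        for s, n in log.final_counts.items():
            for i in range(n):
                hit_rows.append(
                    dict(orf=f"{s}|{fam}_{i+1}", genome=s, family=fam,
                         evalue=10.0 ** -float(rng.uniform(30, 80)),
                         coverage=float(rng.uniform(0.85, 1.0)),
                         bitscore=float(rng.uniform(100, 400)))
                )
    pd.DataFrame(hit_rows).to_csv(out / "hits.csv", index=False,
                                  float_format=FLOAT_FMT)

    # focal/outgroup gene tree + alignment for subfamily delineation
    gt, gt_taxa, members = synthetic_data.sim_two_origin_family(sp, seed=seed + 7)
    (out / "gene_tree.nwk").write_text(gt.to_newick() + "\n")
    merged_taxa = dict(taxa.entries)
    merged_taxa.update(gt_taxa.entries)
    TaxonMap(merged_taxa).to_csv(out / "taxa.csv")
    aln = synthetic_data.sim_alignment(gt, 1000, seed=seed + 11)
    synthetic_data.write_fasta(aln, out / "gene_alignment.fasta")
    truth["subfamily_origins"] = [sorted(m) for m in members]

    genes, gc, gtruth = synthetic_data.sim_genome(
        synthetic_data.GenomeLayout(), seed=seed + 13
    )
    genes.to_csv(out / "genes.csv", index=False)
    gc.to_csv(out / "gc_windows.csv", index=False)
    truth["islands"] = gtruth

    # growth phenotypes follow the simulated pathway content: polymer
    # growth needs at least one Aly and one Oal family, oligomer growth
    # needs an Oal, glucose is the universal control
    def count(fam_set, s):
        return sum(
            truth["families"].get(f, {}).get("copy_numbers", {}).get(s, 0)
            for f in fam_set
        )

    rows = []
    for s in species:
        has_aly = count({"PL6", "PL7"}, s) > 0
        has_oal = count({"PL15", "PL17"}, s) > 0
        for sub, grows in (
            ("Dp>50", has_aly and has_oal),
            ("Dp~3-4", has_oal),
            ("glucose", True),
        ):
            rows.append(
                dict(strain=s, substrate=sub, fraction="unfractionated",
                     r=float(rng.uniform(0.2, 0.7)) if grows else 0.0,
                     K=float(rng.uniform(0.5, 1.2)), n0=0.01,
                     lag=float(rng.uniform(0.0, 24.0)) if grows else 0.0)
            )
    prm = pd.DataFrame(rows)
    growth = synthetic_data.sim_growth(prm, seed=seed + 17)
    growth.to_csv(out / "growth.csv", index=False, float_format=FLOAT_FMT)
    truth["growth_params"] = prm.to_dict("records")

    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)

    config = dict(
        seed=seed,
        inputs=dict(
            taxa=str(out / "taxa.csv"),
            hits=str(out / "hits.csv"),
            gene_tree=str(out / "gene_tree.nwk"),
            alignment=str(out / "gene_alignment.fasta"),
            species_tree=str(out / "species.nwk"),
            family_trees=tree_paths,
            genes=str(out / "genes.csv"),
            gc_windows=str(out / "gc_windows.csv"),
            growth=str(out / "growth.csv"),
        ),
        params=dict(
            merge_candidates=[[0, 1]],
            au_replicates=500,
            bootstrap_threshold=70,
            distance_cutoff=0.66,
        ),
    )
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return config
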