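"""CAZyme domain-hit filtering, copy-number matrices and marker selection.

Input is the per-domain table of a profile-HMM search (hmmsearch
``--domtblout`` dialect, parsed with Biopython) or an equivalent CSV with
columns orf, genome, family, evalue, coverage, bitscore. Alignment coverage
follows the dbCAN convention: aligned HMM positions divided by model
length. Read-level validation hits arrive as 12-column BLAST/UBLAST
tabular files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SearchIO
from scipy import stats

HIT_COLUMNS = ["orf", "genome", "family", "evalue", "coverage", "bitscore"]

#: default thresholds: strict e-value < 1e-23 and model coverage > 0.8,
#: deliberately more stringent than the dbCAN recommendations
E_MAX_DEFAULT = 1e-23
COV_MIN_DEFAULT = 0.8


def read_domtblout(path, orf_delimiter: str = "|") -> pd.DataFrame:
    """Parse hmmsearch --domtblout into a DomainHit table.

    The HMM (query) name is the family; the target is the ORF. Genome ids
    are taken from the ORF id prefix before ``orf_delimiter``.
    """
    rows = []
    for qresult in SearchIO.parse(str(path), "hmmsearch3-domtab"):
        family = qresult.id
        qlen = qresult.seq_len
        for hit in qresult:
            for hsp in hit:
                cov = (hsp.query_end - hsp.query_start) / qlen
                rows.append(
                    dict(
                        orf=hit.id,
                        genome=hit.id.split(orf_delimiter)[0],
                        family=family,
                        evalue=hsp.evalue,
                        coverage=cov,
                        bitscore=hsp.bitscore,
                        env_from=hsp.env_start + 1,
                        env_to=hsp.env_end,
                    )
                )
    df = pd.DataFrame(rows, columns=HIT_COLUMNS + ["env_from", "env_to"])
    return validate_hits(df)


def validate_hits(hits: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in HIT_COLUMNS if c not in hits.columns]
    if missing:
        raise ValueError(f"hit table missing columns: {missing}")
    if len(hits) and ((hits["coverage"] < 0) | (hits["coverage"] > 1)).any():
        raise ValueError("coverage must lie in [0, 1]")
    if len(hits) and (hits["evalue"] <= 0).any():
        raise ValueError("e-values must be positive")
    return hits


def filter_hits(
    hits: pd.DataFrame,
    e_max: float = E_MAX_DEFAULT,
    cov_min: float = COV_MIN_DEFAULT,
    best_per_orf: bool = False,
) -> pd.DataFrame:
    """Retain hits with e-value < e_max AND coverage > cov_min (both strict).

    With ``best_per_orf``, keep at most one hit per (orf, family): lowest
    e-value, ties by highest bit score, then lexicographic orf id.
    Idempotent, and invariant to input row order.
    """
    validate_hits(hits)
    out = hits[(hits["evalue"] < e_max) & (hits["coverage"] > cov_min)]
    if best_per_orf and len(out):
        out = out.sort_values(
            ["orf", "family", "evalue", "bitscore"],
            ascending=[True, True, True, False],
            kind="mergesort",
        ).drop_duplicates(["orf", "family"], keep="first")
    return out.sort_values(["genome", "family", "orf"], kind="mergesort").reset_index(
        drop=True
    )


class CopyNumberMatrix:
    """Genome x family counts with population maxima (the Fig-1b-style view)."""

    def __init__(
        self,
        per_genome: pd.DataFrame,
        per_population: pd.DataFrame,
        genome_population: dict[str, str],
    ):
        self.per_genome = per_genome
        self.per_population = per_population
        self.genome_population = genome_population

    def to_csv(self, genome_path, population_path) -> None:
        self.per_genome.rename_axis("genome").to_csv(genome_path)
        self.per_population.rename_axis("population").to_csv(population_path)


def copy_numbers(hits: pd.DataFrame, taxa) -> CopyNumberMatrix:
    """Per-genome and per-population-maximum family copy counts.

    A genome's count for a family is the number of *distinct* ORFs with at
    least one retained hit (an ORF carrying two domains of one family
    counts once). Populations report the maximum over member genomes;
    absent families are reported as 0.
    """
    validate_hits(hits)
    genome_pop = {e.genome: e.population for e in taxa.entries.values()}
    unmapped = sorted(set(hits["genome"]) - set(genome_pop))
    if unmapped:
        raise KeyError(f"genomes absent from taxon map: {unmapped}")
    families = sorted(hits["family"].unique())
    genomes = sorted(genome_pop)
    per_genome = pd.DataFrame(0, index=genomes, columns=families, dtype=int)
    if len(hits):
        counts = (
            hits.drop_duplicates(["genome", "family", "orf"])
            .groupby(["genome", "family"])
            .size()
        )
        for (g, f), c in counts.items():
            per_genome.loc[g, f] = c
    pops = sorted(set(genome_pop.values()))
    per_pop = pd.DataFrame(0, index=pops, columns=families, dtype=int)
    for g in genomes:
        p = genome_pop[g]
        per_pop.loc[p] = np.maximum(per_pop.loc[p], per_genome.loc[g])
    return CopyNumberMatrix(per_genome, per_pop, genome_pop)


def select_markers(
    hits: pd.DataFrame,
    e_exclusion: float = 1e-10,
    min_presence: float = 0.5,
    drop_paralogs: bool = True,
    genomes: list[str] | None = None,
) -> list[str]:
    """Select single-copy marker genes for the reference phylogeny.

    Hits with e-value *greater than* ``e_exclusion`` are excluded (a hit at
    exactly the threshold is kept). Markers with more than one retained
    copy in any genome are dropped as paralogous; markers present in at
    least ``min_presence`` of all genomes (boundary inclusive) are
    retained. ``hits`` needs columns marker, genome, orf, evalue.
    """
    required = {"marker", "genome", "orf", "evalue"}
    if not required.issubset(hits.columns):
        raise ValueError(f"marker hit table needs columns {sorted(required)}")
    if genomes is None:
        genomes = sorted(hits["genome"].unique())
    n_genomes = len(genomes)
    if n_genomes == 0:
        raise ValueError("no genomes")
    kept = hits[hits["evalue"] <= e_exclusion]
    selected = []
    for marker, sub in kept.groupby("marker"):
        per_genome_copies = sub.groupby("genome")["orf"].nunique()
        if drop_paralogs and (per_genome_copies > 1).any():
            continue
        presence = (per_genome_copies >= 1).sum() / n_genomes
        if presence >= min_presence:
            selected.append(marker)
    if not selected:
        raise ValueError("no markers survive filtering")
    return sorted(selected)


# ---------------------------------------------------------------------------
# read-based copy-number validation


def read_blast_tab(path) -> pd.DataFrame:
    """12-column BLAST/UBLAST tabular read-hit table."""
    cols = [
        "read", "subject", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    return pd.read_csv(path, sep="\t", comment="#", names=cols)


def read_hit_fraction(read_hits: pd.DataFrame, read_lengths: pd.Series) -> float:
    """Percent of sequenced bases on reads with at least one domain hit.

    A read's *full* length counts once it has any hit (read-granularity
    interpretation of base-level hit accounting).
    """
    total = float(read_lengths.sum())
    if total <= 0:
        raise ValueError("zero total read bases")
    hit_reads = set(read_hits["read"]) if len(read_hits) else set()
    unknown = hit_reads - set(read_lengths.index)
    if unknown:
        raise KeyError(f"hit reads without lengths: {sorted(unknown)[:5]}")
    hit_bases = float(read_lengths.loc[sorted(hit_reads)].sum()) if hit_reads else 0.0
    return 100.0 * hit_bases / total


def copy_number_read_correlation(
    hit_fractions: pd.Series, assembled_copies: pd.Series
) -> tuple[float, float]:
    """Pearson correlation of the read statistic with assembled copy number."""
    common = hit_fractions.index.intersection(assembled_copies.index)
    if len(common) < 3:
        raise ValueError("need at least 3 strains")
    r, p = stats.pearsonr(hit_fractions.loc[common], assembled_copies.loc[common])
    return float(r), float(p)
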