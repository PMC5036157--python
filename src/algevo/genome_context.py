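"""Lyase-containing genomic regions: chaining, enrichment, GC depletion.

Coordinates are 0-based half-open internally; GFF3 input (1-based
inclusive) is converted on read and BED output is emitted natively.
Regions are single-linkage chains of lyase genes no farther than a gap
threshold apart (nearest interval ends, inclusive). Mobile-element
enrichment inside regions and region GC depletion are tested with exact
hypergeometric tails, computed in log space so extreme depletion does not
underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

GENE_COLUMNS = ["genome", "replicon", "start", "end", "strand", "category"]

MOBILE_CATEGORIES = frozenset({"mobile_element", "integrase", "transposase"})


def validate_genes(genes: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    if len(genes) and (genes["start"] >= genes["end"]).any():
        raise ValueError("gene records must satisfy start < end (0-based half-open)")
    return genes


def read_gff3(path, genome: str, category_attribute: str = "product") -> pd.DataFrame:
    """Minimal GFF3 gene reader (1-based inclusive -> half-open)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] not in ("gene", "CDS"):
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            rows.append(
                dict(
                    genome=genome,
                    replicon=parts[0],
                    start=int(parts[3]) - 1,
                    end=int(parts[4]),
                    strand=parts[6],
                    category=attrs.get(category_attribute, "other"),
                )
            )
    return validate_genes(pd.DataFrame(rows, columns=GENE_COLUMNS))


@dataclass
class Region:
    replicon: str
    start: int  # min start over member lyases
    end: int  # max end over member lyases
    members: list[int] = field(default_factory=list)  # row indices of lyases

    @property
    def span(self) -> int:
        return self.end - self.start


def chain_regions(lyases: pd.DataFrame, gap: int = 5000) -> list[Region]:
    """Single-linkage chaining of lyase genes within each replicon.

    Two lyases join one region iff the distance between their nearest
    interval ends is <= gap (inclusive: 5,000 bp apart chains at the
    default threshold; 5,001 splits). Regions never span replicons;
    singleton lyases form singleton regions. Output is invariant to input
    row order.
    """
    validate_genes(lyases)
    if gap < 0:
        raise ValueError("gap must be non-negative")
    regions: list[Region] = []
    for replicon, sub in lyases.groupby("replicon", sort=True):
        sub = sub.sort_values(["start", "end"], kind="mergesort")
        current: Region | None = None
        reach = 0  # rightmost end of the current chain
        for row in sub.itertuples():
            if current is not None and row.start - reach <= gap:
                current.end = max(current.end, row.end)
                current.members.append(row.Index)
                reach = max(reach, row.end)
            else:
                current = Region(replicon, row.start, row.end, [row.Index])
                regions.append(current)
                reach = row.end
    for r in regions:
        assert all(lyases.loc[m, "replicon"] == r.replicon for m in r.members)
    return regions


def regions_to_frame(regions: list[Region]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(replicon=r.replicon, start=r.start, end=r.end,
                 n_lyases=len(r.members))
            for r in regions
        ],
        columns=["replicon", "start", "end", "n_lyases"],
    )


def write_bed(regions: list[Region], path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            fh.write(f"{r.replicon}\t{r.start}\t{r.end}\tregion{i+1}\n")


def _overlaps(gene_start, gene_end, regions_by_replicon, replicon) -> bool:
    for r in regions_by_replicon.get(replicon, []):
        if gene_start < r.end and gene_end > r.start:  # >=1 bp overlap
            return True
    return False


def region_enrichment(
    regions: list[Region],
    genes: pd.DataFrame,
    categories: frozenset[str] = MOBILE_CATEGORIES,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of gene categories in regions.

    Per genome: population N = all genes, successes K = genes in the
    named categories, sample n = genes overlapping any region by >=1 bp,
    observed k = category genes in regions; p = P(X >= k).
    """
    validate_genes(genes)
    by_rep: dict[str, list[Region]] = {}
    for r in regions:
        by_rep.setdefault(r.replicon, []).append(r)
    missing = set(by_rep) - set(genes["replicon"])
    if missing:
        raise ValueError(f"regions on replicons absent from gene table: {missing}")
    rows = []
    for genome, sub in genes.groupby("genome", sort=True):
        in_cat = sub["category"].isin(categories)
        in_reg = sub.apply(
            lambda g: _overlaps(g["start"], g["end"], by_rep, g["replicon"]), axis=1
        )
        N, K = len(sub), int(in_cat.sum())
        n, k = int(in_reg.sum()), int((in_cat & in_reg).sum())
        if k > min(K, n):
            raise ValueError(f"impossible counts: k={k} > min(K={K}, n={n})")
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(dict(genome=genome, N=N, K=K, n=n, k=k, p_enrichment=p))
    return pd.DataFrame(rows, columns=["genome", "N", "K", "n", "k", "p_enrichment"])


def hypergeom_upper_pit(k: int, N: int, K: int, n: int, u: float) -> float:
    """Randomized probability-integral transform of the upper-tail test.

    ``P(X > k) + u * P(X = k)`` with ``u ~ Uniform(0,1)`` is exactly
    uniform under the hypergeometric null. The plain tail p-value of a
    discrete test is super-uniform (conservative), so this is the
    statistic to use when checking calibration of the tail computation.
    """
    return float(hypergeom.sf(k, N, K, n) + u * hypergeom.pmf(k, N, K, n))


# ---------------------------------------------------------------------------
# GC depletion


def gc_from_fasta(path) -> dict[str, tuple[int, int]]:
    """Replicon id -> (GC count, length) from a FASTA of replicon sequences."""
    from Bio import SeqIO

    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        out[rec.id] = (s.count("G") + s.count("C"), len(s))
    return out


def _window_gc(windows: pd.DataFrame, replicon: str, start: int, end: int) -> int:
    sub = windows[
        (windows["replicon"] == replicon)
        & (windows["end"] > start)
        & (windows["start"] < end)
    ]
    total = 0.0
    for w in sub.itertuples():
        ov = min(w.end, end) - max(w.start, start)
        total += w.gc_count * ov / (w.end - w.start)
    return int(round(total))


def gc_depletion(
    regions: list[Region],
    replicon_gc: dict[str, tuple[int, int]] | None = None,
    gc_windows: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Lower-tail hypergeometric test of region GC against its replicon.

    Base-level sampling model: population = replicon bases, successes =
    replicon G+C bases, sample = region span, observed = region G+C.
    Each region is compared only against the chromosome or element that
    hosts it. Reports the depletion p-value and its natural logarithm
    (the latter remains finite for extreme tails).
    """
    if replicon_gc is None and gc_windows is None:
        raise ValueError("need replicon sequences/GC totals or a GC window table")
    if replicon_gc is None:
        replicon_gc = {}
        for rep, sub in gc_windows.groupby("replicon"):
            replicon_gc[rep] = (int(sub["gc_count"].sum()), int(sub["length"].sum()))
    rows = []
    for i, r in enumerate(regions):
        if r.replicon not in replicon_gc:
            raise KeyError(f"no GC data for replicon {r.replicon!r}")
        K, N = replicon_gc[r.replicon]
        n = r.span
        if n > N:
            raise ValueError(
                f"region span {n} exceeds replicon length {N} ({r.replicon})"
            )
        if gc_windows is not None:
            k = _window_gc(gc_windows, r.replicon, r.start, r.end)
        else:
            raise ValueError(
                "per-region GC requires gc_windows (or supply sequences and "
                "precompute region counts)"
            )
        logp = float(hypergeom.logcdf(k, N, K, n))
        rows.append(
            dict(
                region=f"region{i+1}",
                replicon=r.replicon,
                start=r.start,
                end=r.end,
                gc_region=k / n if n else np.nan,
                gc_replicon=K / N,
                p_depletion=float(np.exp(logp)),
                log_p_depletion=logp,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["region", "replicon", "start", "end", "gc_region",
                 "gc_replicon", "p_depletion", "log_p_depletion"],
    )


def gc_depletion_from_sequences(
    regions: list[Region], sequences: dict[str, str]
) -> pd.DataFrame:
    """GC depletion directly from replicon sequence strings."""
    rep_gc = {}
    windows = []
    for rep, seq in sequences.items():
        s = seq.upper()
        rep_gc[rep] = (s.count("G") + s.count("C"), len(s))
        arr = np.frompyfunc(lambda ch: ch in "GC", 1, 1)(np.array(list(s)))
        cum = np.concatenate([[0], np.cumsum(arr.astype(int))])
        windows.append((rep, cum))
    cums = dict(windows)
    rows = []
    for i, r in enumerate(regions):
        K, N = rep_gc[r.replicon]
        if r.span > N:
            raise ValueError("region span exceeds replicon length")
        cum = cums[r.replicon]
        k = int(cum[min(r.end, N)] - cum[r.start])
        logp = float(hypergeom.logcdf(k, N, K, r.span))
        rows.append(
            dict(
                region=f"region{i+1}", replicon=r.replicon, start=r.start,
                end=r.end, gc_region=k / r.span, gc_replicon=K / N,
                p_depletion=float(np.exp(logp)), log_p_depletion=logp,
            )
        )
    return pd.DataFrame(rows)
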