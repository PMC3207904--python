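"""Transcription-factor (Smad1) binding-site calling and gene assignment.

Site calling slides a fixed window (default 300 bp, step window/3) over
each chromosome and flags windows whose read count is both at least
``min_reads`` and Poisson-improbable (upper tail p < ``p_cutoff``) under the
genome-wide uniform background rate lambda = total stored reads x window /
genome length.  Overlapping or nearly-adjacent significant windows merge
into one site whose summit is the center of its highest-count window
(leftmost on ties).  All five knobs are configuration-exposed; the caller is
intentionally simple (no control-track subtraction, no local lambda).

Assignment follows two distance rules: a site lies "near a gene" when its
summit is within a halo (default 10 kb) of the gene span, and it marks a
gene as a target when the summit is within a radius (default 5 kb) of that
gene's TSS.  One site within the TSS radius of several genes marks all of
them (one-to-many).  Signed summit-to-TSS distances are positive downstream
in transcription direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GeneAnnotation, MappedReadSet


@dataclass(frozen=True)
class SiteCallerParams:
    window: int = 300
    p_cutoff: float = 1e-5
    min_reads: int = 8
    merge_gap: int = 100
    mode: str = "5prime"

    @property
    def step(self) -> int:
        return max(self.window // 3, 1)


def call_sites(readset: MappedReadSet, genome: dict[str, int],
               params: SiteCallerParams = SiteCallerParams()) -> pd.DataFrame:
    """Call binding sites; returns a frame with chrom, start, end, site_id,
    summit, score (summit-window RPM), n_reads."""
    genome_length = sum(genome.values())
    if genome_length <= 0:
        raise ValueError("zero genome length")
    if len(readset) == 0:
        raise ValueError("empty read set")
    index = readset.five_prime(params.mode)
    lam = len(readset) * params.window / genome_length
    # count threshold: smallest c with P(X >= c) < p_cutoff, also >= min_reads
    c_min = int(sps.poisson.isf(params.p_cutoff, lam)) + 1
    threshold = max(c_min, params.min_reads)

    sites = []
    for chrom in sorted(genome):
        length = genome[chrom]
        pos = index.get(chrom)
        if pos is None or pos.size == 0:
            continue
        starts = np.arange(0, max(length - params.window, 0) + 1, params.step,
                           dtype=np.int64)
        counts = (np.searchsorted(pos, starts + params.window, "left")
                  - np.searchsorted(pos, starts, "left"))
        sig = counts >= threshold
        if not sig.any():
            continue
        idx = np.flatnonzero(sig)
        # merge significant windows separated by <= merge_gap
        breaks = np.flatnonzero(
            starts[idx[1:]] - (starts[idx[:-1]] + params.window)
            > params.merge_gap)
        groups = np.split(idx, breaks + 1)
        for g in groups:
            s = int(starts[g[0]])
            e = int(starts[g[-1]]) + params.window
            best = g[int(np.argmax(counts[g]))]  # argmax is leftmost on ties
            summit = int(starts[best]) + params.window // 2
            n_reads = int(np.searchsorted(pos, e, "left")
                          - np.searchsorted(pos, s, "left"))
            score = 1e6 * counts[best] / readset.total_mapped
            sites.append((chrom, s, e, summit, float(score), n_reads))
    df = pd.DataFrame(sites, columns=["chrom", "start", "end", "summit",
                                      "score", "n_reads"])
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    df.insert(3, "site_id", [f"site{i:05d}" for i in range(len(df))])
    return df


def assign_sites(sites: pd.DataFrame, annotation: GeneAnnotation,
                 tss_radius: int = 5000, gene_halo: int = 10000
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign sites to genes by distance rules.

    Returns (site_table, gene_table): the site table adds nearest_gene,
    distance (signed, transcription direction), within_5kb_tss and
    within_10kb_gene flags; the gene table has a boolean is_target per gene
    (any site summit within tss_radius of its TSS).
    """
    if len(annotation) == 0:
        raise ValueError("empty annotation")
    genes = annotation.genes
    site_rows = []
    target_genes: set[str] = set()
    by_chrom = {c: g for c, g in genes.groupby("chrom", sort=False)}
    for row in sites.itertuples(index=False):
        g = by_chrom.get(row.chrom)
        if g is None:
            site_rows.append((row.site_id, "", np.nan, False, False))
            continue
        tss = g["tss"].to_numpy(np.int64)
        absd = np.abs(row.summit - tss)
        near = absd <= tss_radius
        in_halo = ((row.summit >= g["start"].to_numpy(np.int64) - gene_halo)
                   & (row.summit < g["end"].to_numpy(np.int64) + gene_halo))
        # nearest gene by |summit - tss|, ties to smaller gene_id
        order = np.lexsort((g["gene_id"].to_numpy(), absd))
        best = order[0]
        sign = 1 if g["strand"].iloc[best] == "+" else -1
        dist = int(sign * (row.summit - tss[best]))
        site_rows.append((row.site_id, g["gene_id"].iloc[best], dist,
                          bool(near.any()), bool(in_halo.any())))
        target_genes |= set(g["gene_id"].to_numpy()[near])
    site_table = sites.merge(
        pd.DataFrame(site_rows, columns=["site_id", "nearest_gene", "distance",
                                         "within_5kb_tss", "within_10kb_gene"]),
        on="site_id")
    gene_table = pd.DataFrame({
        "gene_id": genes["gene_id"],
        "is_target": genes["gene_id"].isin(sorted(target_genes)),
    })
    return site_table, gene_table


def proximity_fractions(site_table: pd.DataFrame) -> tuple[float, float]:
    """(fraction within gene halo, fraction within TSS radius) of all sites."""
    n = len(site_table)
    if n == 0:
        raise ValueError("no sites")
    return (float(site_table["within_10kb_gene"].mean()),
            float(site_table["within_5kb_tss"].mean()))


def target_enrichment(targets: set[str], active: set[str], universe: set[str],
                      ranked_active: pd.DataFrame):
    """Fisher test of target status against activity, and KS enrichment of
    targets within the active genes ranked by stimulation fold change.

    Returns (fisher_p or None, EnrichmentResult or None); None marks an
    untestable combination (degenerate margins or subset).
    """
    from .stats import ContingencyTable, EnrichmentResult, fisher_exact, \
        ks_rank_enrichment

    targets = targets & universe
    active = active & universe
    a = len(targets & active)
    b = len(targets - active)
    c = len(active - targets)
    d = len(universe - targets - active)
    try:
        fisher_p = fisher_exact(ContingencyTable(a, b, c, d), sided="greater")
    except ValueError:
        fisher_p = None
    sub = targets & set(ranked_active.index)
    try:
        # directional: targets predicted upward among stimulation-induced genes
        ks = ks_rank_enrichment(ranked_active, sub, sided="greater",
                                label="targets_in_active")
    except ValueError:
        ks = None
    return fisher_p, ks


def stratify_targets_by_delta_k27(targets: set[str], delta_class: pd.Series,
                                  ranked_targets: pd.DataFrame) -> pd.DataFrame:
    """KS enrichment of each ΔK27 stratum (increase/none/decrease at the 0.4
    RPM cutoff) within all target genes ranked by senescence fold change."""
    from .stats import ks_rank_enrichment

    rows = []
    bg = ranked_targets.loc[ranked_targets.index.isin(targets)].copy()
    bg = bg.sort_values("rank", kind="mergesort")
    bg["rank"] = range(1, len(bg) + 1)
    # predicted tails: repressive-mark gain -> repression (downward), loss or
    # no gain -> upregulation (upward)
    tails = {"increase": "less", "none": "greater", "decrease": "greater"}
    for stratum in ("increase", "none", "decrease"):
        sub = set(delta_class.index[(delta_class == stratum)]) & set(bg.index)
        if len(sub) == 0 or len(sub) >= len(bg):
            rows.append((stratum, len(sub), len(bg), np.nan, np.nan, "", True))
            continue
        res = ks_rank_enrichment(bg, sub, sided=tails[stratum],
                                 label=f"delta_k27_{stratum}")
        rows.append((stratum, res.n_subset, res.n_background, res.statistic,
                     res.p_value, res.direction, False))
    return pd.DataFrame(rows, columns=["stratum", "n_subset", "n_background",
                                       "D", "p", "direction", "untestable"])
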