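"""Detection of regions of consanguinity (ROCs) from parental read counts.

A ROC is a genomic region where the two parents share both haplotypes, which
makes the identity of the transmitted haplotype ambiguous; phasing accuracy
is therefore reported outside ROCs. Inside a ROC the parents have identical
genotypes, so sites with strong opposite-homozygote evidence (one parent
with >= 2 alt reads and no ref reads, the other with >= 2 ref reads and no
alt reads) occur only through binomial sampling of shared heterozygotes and
are roughly an order of magnitude rarer than elsewhere in the genome.

The detector segments this per-site discordance indicator with a 2-state
HMM whose state rates are tied to the observed genome-wide rate (the
absolute rate depends strongly on parental depth, so no fixed cutoff is
used), takes the Viterbi path, and then extends each boundary outward past
a small number of discordant sites. The extension makes the reported
intervals deliberately conservative: inside a true ROC discordant sites are
sparse, so an interval that Viterbi cut short keeps growing until it meets
genuinely discordant flanking sequence, while in non-ROC sequence the
extension stops within a few hundred kb. When the genome-wide discordance
rate is too low to discriminate at all (e.g. unsequenced parents) the scan
is reported as indeterminate rather than as ROC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import hmm
from .data import ModelParams, Pedigree, SiteTable

logger = logging.getLogger(__name__)


@dataclass
class RocSet:
    """Detected ROC intervals (1-based inclusive) plus per-site flags."""

    intervals: pd.DataFrame = field(repr=False)  # chrom, start, end
    site_flags: np.ndarray = field(repr=False)   # aligned to the scanned table
    indeterminate: bool = False
    genome_rate: float = float("nan")

    def flags_for(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Boolean ROC membership for arbitrary (chrom, pos) arrays."""
        chrom = np.asarray(chrom)
        pos = np.asarray(pos)
        out = np.zeros(len(pos), dtype=bool)
        for _, iv in self.intervals.iterrows():
            out |= (chrom == iv["chrom"]) & (pos >= iv["start"]) & (pos <= iv["end"])
        return out

    def total_length(self) -> int:
        if len(self.intervals) == 0:
            return 0
        return int((self.intervals["end"] - self.intervals["start"] + 1).sum())

    def to_bed(self, path):
        df = self.intervals.copy()
        df["start"] = df["start"] - 1  # BED half-open
        df.to_csv(path, sep="\t", index=False, header=False)


def _discordant_mask(table: SiteTable, pedigree: Pedigree) -> np.ndarray:
    m = table.counts_for(pedigree.mother_id)
    f = table.counts_for(pedigree.father_id)
    rm, am = m[:, 0], m[:, 1]
    rf, af = f[:, 0], f[:, 1]
    return ((am >= 2) & (rm == 0) & (rf >= 2) & (af == 0)) | (
        (rm >= 2) & (am == 0) & (af >= 2) & (rf == 0)
    )


def _extend_boundary(disc: np.ndarray, start_idx: int, step: int, n_hits: int) -> int:
    """Move outward from a Viterbi boundary past ``n_hits`` discordant sites.

    Returns the index of the last site before the ``n_hits``-th discordant
    site in the given direction (the conservative interval edge).
    """
    i = start_idx
    hits = 0
    last = start_idx
    while 0 <= i < len(disc):
        if disc[i]:
            hits += 1
            if hits >= n_hits:
                return last
        last = i
        i += step
    return last


def detect_roc(table: SiteTable, pedigree: Pedigree, params: ModelParams | None = None) -> RocSet:
    """Scan for ROC intervals from the parents' read counts alone."""
    params = params or ModelParams()
    disc = _discordant_mask(table, pedigree)
    genome_rate = float(disc.mean()) if table.n_sites else 0.0

    if genome_rate < params.roc_min_genome_rate:
        logger.warning(
            "genome-wide discordance rate %.4g below %.4g: ROC detection indeterminate",
            genome_rate, params.roc_min_genome_rate,
        )
        return RocSet(
            intervals=pd.DataFrame(columns=["chrom", "start", "end"]),
            site_flags=np.zeros(table.n_sites, dtype=bool),
            indeterminate=True,
            genome_rate=genome_rate,
        )

    p_roc = params.roc_rate_ratio * genome_rate
    p_null = genome_rate
    intervals = []
    for chrom, sl in table.chrom_slices().items():
        pos = table.sites["pos"].to_numpy()[sl]
        d = disc[sl].astype(int)
        if len(pos) < 2:
            continue
        # emissions: state 0 = non-ROC, state 1 = ROC
        em = np.empty((len(pos), 2))
        em[:, 0] = np.where(d, p_null, 1.0 - p_null)
        em[:, 1] = np.where(d, p_roc, 1.0 - p_roc)
        r = 1.0 - np.exp(-np.diff(pos).astype(float) * params.roc_switch_per_bp)
        trans = np.empty((len(pos) - 1, 2, 2))
        trans[:, 0, 0] = trans[:, 1, 1] = 1.0 - r
        trans[:, 0, 1] = trans[:, 1, 0] = r
        path = hmm.viterbi(em, trans, initial=np.array([0.9, 0.1]))
        # runs of state 1 -> candidate intervals with conservative edges
        in_roc = path == 1
        if not in_roc.any():
            continue
        edges = np.flatnonzero(np.diff(in_roc.astype(int)))
        starts = [0] if in_roc[0] else []
        starts += [int(e) + 1 for e in edges if not in_roc[e]]
        ends = [int(e) for e in edges if in_roc[e]]
        if in_roc[-1]:
            ends.append(len(pos) - 1)
        for s_idx, e_idx in zip(starts, ends):
            s_idx = _extend_boundary(disc[sl], s_idx, -1, params.roc_edge_pad_hits)
            e_idx = _extend_boundary(disc[sl], e_idx, +1, params.roc_edge_pad_hits)
            start, end = int(pos[s_idx]), int(pos[e_idx])
            if end - start + 1 >= params.roc_min_len:
                intervals.append({"chrom": chrom, "start": start, "end": end})

    ivdf = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
    roc = RocSet(intervals=ivdf, site_flags=np.zeros(table.n_sites, dtype=bool),
                 genome_rate=genome_rate)
    roc.site_flags = roc.flags_for(
        table.sites["chrom"].to_numpy(), table.sites["pos"].to_numpy()
    )
    logger.info(
        "detect_roc: %d intervals covering %.3g Mb (genome discordance rate %.4g)",
        len(ivdf), roc.total_length() / 1e6, genome_rate,
    )
    return roc


def mask_roc(tracks, roc: RocSet):
    """Annotate phasing tracks with a per-site ``roc`` flag (pure annotation).

    Returns new tracks; marginals, predictions and pass flags are unchanged.
    """
    from .phasing import PhasingTrack

    out = []
    for t in tracks:
        df = t.data.copy()
        df["roc"] = roc.flags_for(df["chrom"].to_numpy(), df["pos"].to_numpy())
        out.append(PhasingTrack(embryo=t.embryo, side=t.side, data=df))
    return out
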