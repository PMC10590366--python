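"""Core data containers for family-based phasing.

The package operates on biallelic SNV sites with per-individual ref/alt read
counts (the output of an allele-counting step on aligned low-pass sequencing
data), a pedigree describing sample roles, and a small set of model
parameters. Coordinates are 1-based inclusive throughout (VCF convention);
BED output converts to 0-based half-open at the boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "alt_freq"]
SIDES = ("maternal", "paternal")

_CHRX_ALIASES = {"x", "chrx"}


def is_chrx(chrom: str) -> bool:
    """True if ``chrom`` names the X chromosome (case-insensitive)."""
    return str(chrom).lower() in _CHRX_ALIASES


def chrom_sort_key(chrom: str):
    """Natural chromosome ordering: numbered autosomes first, then others."""
    m = re.fullmatch(r"(?:chr)?(\d+)", str(chrom), flags=re.IGNORECASE)
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, str(chrom).lower())


class ReadCounts(NamedTuple):
    """Reads supporting the ref and alt allele at one site in one sample."""

    n_ref: int
    n_alt: int


@dataclass(frozen=True)
class ModelParams:
    """Tunable model parameters.

    eps
        Per-read substitution error probability (symmetric ref<->alt).
    ado
        Allele-dropout probability per heterozygous site in whole-genome
        amplified embryo material.
    cm_per_mb
        Recombination rate used as a physical-distance proxy for the genetic
        map (centiMorgan per megabase).
    conf_hi
        High-confidence ("pass") threshold on the marginal posterior; a site
        passes when the marginal is > conf_hi or < 1 - conf_hi.
    min_cnv_len
        Minimum length (bp) of a reportable copy-number gain/loss.
    subtel_len
        Subtelomeric window length (bp) measured from telomeres and
        acrocentric centromeres.
    """

    eps: float = 0.002
    ado: float = 0.1
    cm_per_mb: float = 1.0
    conf_hi: float = 0.99
    min_cnv_len: int = 5_000_000
    subtel_len: int = 5_000_000
    min_alt_reads: int = 2
    cnv_bin_width: int = 1_000_000
    cnv_switch_prob: float = 1e-4
    cnv_min_sigma: float = 0.02
    roc_min_len: int = 3_000_000
    roc_rate_ratio: float = 0.15
    roc_switch_per_bp: float = 1e-7
    roc_edge_pad_hits: int = 2
    roc_min_genome_rate: float = 0.003

    def __post_init__(self):
        if not 0.0 <= self.eps < 0.5:
            raise ValueError(f"eps must be in [0, 0.5), got {self.eps}")
        if not 0.0 <= self.ado < 1.0:
            raise ValueError(f"ado must be in [0, 1), got {self.ado}")
        if self.cm_per_mb <= 0:
            raise ValueError("cm_per_mb must be positive")
        if not 0.5 < self.conf_hi < 1.0:
            raise ValueError("conf_hi must be in (0.5, 1)")
        if self.min_cnv_len < 0 or self.subtel_len < 0:
            raise ValueError("lengths must be non-negative")

    @property
    def conf_lo(self) -> float:
        return 1.0 - self.conf_hi


@dataclass
class Pedigree:
    """Sample roles within one family.

    ``reference_mode`` selects the phasing reference: ``"child"`` (an already
    born sibling of the embryos, given by ``reference_child_id``) or
    ``"grandparent"`` (1-2 sequenced grandparents per parental side, listed in
    ``grandparents``; list order defines grandparent_1 vs grandparent_2).
    ``sex`` optionally maps sample id -> "female"/"male"; it only matters on
    chrX.
    """

    mother_id: str
    father_id: str
    embryos: list[str]
    reference_mode: str = "child"
    reference_child_id: str | None = None
    grandparents: dict[str, list[str]] = field(default_factory=dict)
    sex: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.reference_mode not in ("child", "grandparent"):
            raise ValueError(f"unknown reference_mode {self.reference_mode!r}")
        if not self.embryos:
            raise ValueError("pedigree must list at least one embryo")
        if self.reference_mode == "child":
            if not self.reference_child_id:
                raise ValueError("reference_mode='child' requires reference_child_id")
        else:
            sides = [s for s, ids in self.grandparents.items() if ids]
            if not sides:
                raise ValueError(
                    "reference_mode='grandparent' requires >=1 grandparent on "
                    "at least one parental side"
                )
            for side in self.grandparents:
                if side not in SIDES:
                    raise ValueError(f"unknown parental side {side!r}")
                if len(self.grandparents[side]) > 2:
                    raise ValueError("at most two grandparents per side")

    def phaseable_sides(self) -> list[str]:
        if self.reference_mode == "child":
            return list(SIDES)
        return [s for s in SIDES if self.grandparents.get(s)]

    def reference_ids(self) -> list[str]:
        if self.reference_mode == "child":
            return [self.reference_child_id]
        return [g for s in SIDES for g in self.grandparents.get(s, [])]

    def samples(self) -> list[str]:
        return [self.mother_id, self.father_id, *self.reference_ids(), *self.embryos]


class SiteTable:
    """Ordered biallelic SNV sites with per-sample ref/alt read counts.

    ``sites`` is a DataFrame with columns chrom, pos, ref, alt, alt_freq;
    ``counts`` maps sample id -> int array of shape (n_sites, 2) holding
    (n_ref, n_alt). Rows are sorted by (chrom, pos) with natural chromosome
    order; (chrom, pos) pairs are unique.
    """

    def __init__(self, sites: pd.DataFrame, counts: Mapping[str, np.ndarray]):
        sites = sites.reset_index(drop=True).copy()
        missing = [c for c in SITE_COLUMNS if c not in sites.columns]
        if missing:
            raise ValueError(f"sites table missing columns {missing}")
        sites["pos"] = sites["pos"].astype(np.int64)
        sites["alt_freq"] = sites["alt_freq"].astype(float)
        if (sites["pos"] < 1).any():
            raise ValueError("positions must be >= 1")
        if (sites["ref"] == sites["alt"]).any():
            raise ValueError("ref and alt alleles must differ")
        af = sites["alt_freq"].to_numpy()
        if ((af < 0) | (af > 1)).any():
            raise ValueError("alt_freq must lie in [0, 1]")

        counts = {s: np.ascontiguousarray(np.asarray(c, dtype=np.int64)) for s, c in counts.items()}
        n = len(sites)
        for s, c in counts.items():
            if c.shape != (n, 2):
                raise ValueError(f"counts for {s!r} have shape {c.shape}, expected {(n, 2)}")
            if (c < 0).any():
                raise ValueError(f"negative read counts for sample {s!r}")

        order = sorted(range(n), key=lambda i: (chrom_sort_key(sites["chrom"].iat[i]), sites["pos"].iat[i]))
        if order != list(range(n)):
            logger.warning("site table not sorted by (chrom, pos); sorting")
            idx = np.asarray(order)
            sites = sites.iloc[idx].reset_index(drop=True)
            counts = {s: c[idx] for s, c in counts.items()}
        if sites.duplicated(subset=["chrom", "pos"]).any():
            dup = sites[sites.duplicated(subset=["chrom", "pos"], keep=False)]
            raise ValueError(f"duplicate (chrom, pos) entries:\n{dup.head()}")

        self.sites = sites
        self.counts = counts

    # -- basic queries ------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def samples(self) -> list[str]:
        return list(self.counts)

    def counts_for(self, sample: str) -> np.ndarray:
        try:
            return self.counts[sample]
        except KeyError:
            raise KeyError(f"sample {sample!r} not present in table") from None

    def coverage(self, sample: str) -> np.ndarray:
        return self.counts_for(sample).sum(axis=1)

    def chromosomes(self) -> list[str]:
        seen: list[str] = []
        for ch in self.sites["chrom"]:
            if not seen or seen[-1] != ch:
                seen.append(ch)
        return seen

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous row slice per chromosome, in table order."""
        out: dict[str, slice] = {}
        chroms = self.sites["chrom"].to_numpy()
        if len(chroms) == 0:
            return out
        boundaries = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [len(chroms)]])
        for s, e in zip(starts, ends):
            out[chroms[s]] = slice(int(s), int(e))
        return out

    def subset(self, mask: np.ndarray) -> "SiteTable":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        sites = self.sites.iloc[idx].reset_index(drop=True)
        counts = {s: c[idx] for s, c in self.counts.items()}
        return SiteTable(sites, counts)

    def equals(self, other: "SiteTable") -> bool:
        if set(self.counts) != set(other.counts):
            return False
        if not self.sites.reset_index(drop=True).equals(other.sites.reset_index(drop=True)):
            return False
        return all(np.array_equal(self.counts[s], other.counts[s]) for s in self.counts)


def genetic_distance(pos_a: int, pos_b: int, params: ModelParams) -> float:
    """Genetic distance in Morgans between two positions on one chromosome.

    Uses the constant-rate physical proxy ``cm_per_mb``:
    d = (pos_b - pos_a) * cm_per_mb / 1e8 Morgans.
    """
    if pos_b < pos_a:
        raise ValueError("pos_b must be >= pos_a")
    return (pos_b - pos_a) * params.cm_per_mb / 1e8
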