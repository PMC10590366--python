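"""Genotype-conditional read likelihoods, genotype priors and site filtering.

Genotypes are encoded as the alt-allele count: 0 (hom ref), 1 (het),
2 (hom alt). Read likelihoods are binomial in the number of alt-supporting
reads, with per-read alt probability eps / 0.5 / 1-eps for the three
genotypes. Embryo (whole-genome amplified) material additionally allows
allele dropout at heterozygous sites, modelled as a three-component mixture:
with probability 1-ado both alleles amplify (p=0.5), otherwise one of the two
alleles is lost (p=eps or p=1-eps, each with probability ado/2).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.stats import binom

from .data import ModelParams, Pedigree, SiteTable

logger = logging.getLogger(__name__)

GENOTYPES = (0, 1, 2)


def _alt_read_prob(g: int, eps: float) -> float:
    return (eps, 0.5, 1.0 - eps)[g]


def read_likelihood(counts, g: int, eps: float) -> float:
    """P(observed reads | genotype g) for bulk (non-amplified) DNA.

    ``counts`` is a (n_ref, n_alt) pair. Returns 1 when no reads were
    observed (flat likelihood), so the function is total.
    """
    n_ref, n_alt = counts
    n = n_ref + n_alt
    if n == 0:
        return 1.0
    return float(binom.pmf(n_alt, n, _alt_read_prob(g, eps)))


def embryo_read_likelihood(counts, g: int, eps: float, ado: float) -> float:
    """P(observed reads | genotype g) for WGA embryo material with dropout."""
    if g != 1:
        return read_likelihood(counts, g, eps)
    return (
        (1.0 - ado) * read_likelihood(counts, 1, eps)
        + 0.5 * ado * read_likelihood(counts, 0, eps)
        + 0.5 * ado * read_likelihood(counts, 2, eps)
    )


def genotype_prior(g: int, alt_freq: float) -> float:
    """Hardy-Weinberg genotype prior at population alt-allele frequency q."""
    if not 0.0 <= alt_freq <= 1.0:
        raise ValueError("alt_freq must lie in [0, 1]")
    q = alt_freq
    return ((1 - q) ** 2, 2 * q * (1 - q), q * q)[g]


# -- vectorised forms ------------------------------------------------------

def read_likelihood_table(counts: np.ndarray, eps: float) -> np.ndarray:
    """(n_sites, 3) array of P(reads | g) for g = 0, 1, 2."""
    counts = np.asarray(counts)
    n_alt = counts[:, 1]
    n_tot = counts.sum(axis=1)
    out = np.empty((len(counts), 3))
    for g in GENOTYPES:
        out[:, g] = binom.pmf(n_alt, n_tot, _alt_read_prob(g, eps))
    out[n_tot == 0] = 1.0
    return out


def embryo_read_likelihood_table(counts: np.ndarray, eps: float, ado: float) -> np.ndarray:
    """Like :func:`read_likelihood_table` with the het-dropout mixture."""
    out = read_likelihood_table(counts, eps)
    out[:, 1] = (1.0 - ado) * out[:, 1] + 0.5 * ado * (out[:, 0] + out[:, 2])
    return out


def hemizygous_likelihood_table(counts: np.ndarray, eps: float) -> np.ndarray:
    """(n_sites, 2) likelihoods for a hemizygous locus (alleles R, A)."""
    return read_likelihood_table(counts, eps)[:, [0, 2]]


def genotype_prior_table(alt_freq: np.ndarray) -> np.ndarray:
    """(n_sites, 3) Hardy-Weinberg priors."""
    q = np.asarray(alt_freq, dtype=float)
    return np.stack([(1 - q) ** 2, 2 * q * (1 - q), q * q], axis=1)


def hemizygous_prior_table(alt_freq: np.ndarray) -> np.ndarray:
    """(n_sites, 2) allele priors for a hemizygous locus."""
    q = np.asarray(alt_freq, dtype=float)
    return np.stack([1 - q, q], axis=1)


def filter_informative_sites(
    table: SiteTable, pedigree: Pedigree, min_alt_reads: int | None = None,
    params: ModelParams | None = None,
) -> SiteTable:
    """Keep sites where an alternate allele was seen in a parent or reference.

    A site is retained when at least one of mother, father, or the reference
    individual(s) has >= ``min_alt_reads`` alt-supporting reads. Embryo reads
    never qualify a site. Order is preserved; kept/dropped counts are logged.
    """
    if min_alt_reads is None:
        min_alt_reads = (params or ModelParams()).min_alt_reads
    if min_alt_reads < 1:
        raise ValueError("min_alt_reads must be >= 1")
    informative = [pedigree.mother_id, pedigree.father_id, *pedigree.reference_ids()]
    mask = np.zeros(table.n_sites, dtype=bool)
    for sample in informative:
        mask |= table.counts_for(sample)[:, 1] >= min_alt_reads
    kept = int(mask.sum())
    logger.info(
        "filter_informative_sites: kept %d / %d sites (min_alt_reads=%d)",
        kept, table.n_sites, min_alt_reads,
    )
    if kept == 0:
        logger.warning("no informative sites retained")
    return table.subset(mask)
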