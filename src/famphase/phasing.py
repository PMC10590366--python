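"""Transmitted-haplotype inference for embryos from family read counts.

The hidden state tracks, per parental side, the identity of the haplotype an
embryo inherited: in child-reference mode, whether it is identical (by
descent) to the haplotype the reference sibling inherited from the same
parent; in grandparent-reference mode, which grandparent of the focal parent
it originates from. Child mode runs a joint 4-state chain per embryo (the
embryo's reads couple the maternal and paternal sides); grandparent mode runs
an independent 2-state chain per phaseable side.

Emissions marginalise over all unobserved genotypes: parental genotypes carry
Hardy-Weinberg priors at the site's population alt-allele frequency and are
weighted by the parents' own read likelihoods; transmitted alleles are
uniform over a heterozygous parent's two alleles; embryo reads use the
allele-dropout mixture. Sites with no reads in an individual contribute a
flat factor, so missing data degrades gracefully.

Transition probabilities follow Haldane's map function on physical distance
scaled by ``cm_per_mb``. The number of meioses entering the switch rate is
determined by the state definition: the sibling-match indicator flips at
crossovers of either the reference child's or the embryo's gamete (two
independent meioses), whereas the grandparent-identity state flips only at
the parent-to-embryo meiosis - crossovers in the grandparent-to-parent
meiosis move between haplotypes of the *same* grandparent and leave the
origin label unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import hmm
from .data import SIDES, ModelParams, Pedigree, SiteTable, is_chrx
from .likelihoods import (
    embryo_read_likelihood_table,
    genotype_prior_table,
    hemizygous_likelihood_table,
    hemizygous_prior_table,
    read_likelihood_table,
)

logger = logging.getLogger(__name__)

#: meioses separating the two gametes whose IBD state the chain tracks
CHILD_MODE_MEIOSES = 2
#: meioses across which the grandparent-origin label can flip
GRANDPARENT_MODE_MEIOSES = 1

# child-mode joint state order: (maternal, paternal) with 0 = same-as-reference
CHILD_STATES = ((0, 0), (0, 1), (1, 0), (1, 1))

# transmission options per genotype: (allele, probability)
_TRANSMIT = {0: ((0, 1.0),), 1: ((0, 0.5), (1, 0.5)), 2: ((1, 1.0),)}


def transition_matrix(d: float, n_meioses: int) -> np.ndarray:
    """2x2 per-side transition matrix for genetic distance ``d`` (Morgans)."""
    if d < 0:
        raise ValueError("genetic distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d * n_meioses))
    return np.array([[1.0 - r, r], [r, 1.0 - r]])


def switch_probs(positions: np.ndarray, params: ModelParams, n_meioses: int) -> np.ndarray:
    """Per-gap recombination switch probabilities (Haldane)."""
    d = np.diff(np.asarray(positions, dtype=float)) * params.cm_per_mb / 1e8
    return 0.5 * (1.0 - np.exp(-2.0 * d * n_meioses))


def _two_state_stack(r: np.ndarray) -> np.ndarray:
    out = np.empty((len(r), 2, 2))
    out[:, 0, 0] = out[:, 1, 1] = 1.0 - r
    out[:, 0, 1] = out[:, 1, 0] = r
    return out


def _joint_stack(r_m: np.ndarray, r_f: np.ndarray) -> np.ndarray:
    """Per-gap 4x4 matrices: tensor product of maternal and paternal 2x2."""
    tm = _two_state_stack(r_m)
    tf = _two_state_stack(r_f)
    return np.einsum("kij,klm->kiljm", tm, tf).reshape(len(r_m), 4, 4)


# -- emissions -------------------------------------------------------------

def child_emissions(L_m, L_f, L_c, L_e, prior) -> np.ndarray:
    """(n_sites, 4) joint-state emission likelihoods, child-reference mode.

    Arguments are per-site likelihood tables: mother/father/reference-child
    (n, 3) bulk likelihoods, embryo (n, 3) dropout-mixture likelihoods, and
    the (n, 3) Hardy-Weinberg prior used for both parents.
    """
    n = len(L_m)
    E = np.zeros((n, 4))
    for gm in (0, 1, 2):
        for gf in (0, 1, 2):
            base = prior[:, gm] * prior[:, gf] * L_m[:, gm] * L_f[:, gf]
            for tm, wm in _TRANSMIT[gm]:
                om = gm - tm  # the mother's other allele
                for tf, wf in _TRANSMIT[gf]:
                    of = gf - tf
                    w = base * (wm * wf) * L_c[:, tm + tf]
                    for s, (im, ip) in enumerate(CHILD_STATES):
                        e_m = tm if im == 0 else om
                        e_f = tf if ip == 0 else of
                        E[:, s] += w * L_e[:, e_m + e_f]
    return E


def transmit_weights(L, prior) -> np.ndarray:
    """(n, 2) marginal weight that an individual transmits allele 0 / 1.

    Sums the individual's genotype posterior factors (prior x read
    likelihood) times the Mendelian transmission probability.
    """
    F0 = prior[:, 0] * L[:, 0] + 0.5 * prior[:, 1] * L[:, 1]
    F1 = 0.5 * prior[:, 1] * L[:, 1] + prior[:, 2] * L[:, 2]
    return np.stack([F0, F1], axis=1)


def grandparent_emissions(A1, A2, L_par, L_e, F_other) -> np.ndarray:
    """(n_sites, 2) emission likelihoods for one grandparent-phased side.

    ``A1``/``A2`` are (n, 2) transmitted-allele weights for grandparent 1/2
    (use :func:`transmit_weights`; an unsequenced grandparent contributes its
    prior only). ``L_par`` is the focal parent's (n, 3) likelihood table,
    ``F_other`` the other parent's (n, 2) transmitted-allele weights, and
    ``L_e`` the embryo's (n, 3) dropout-mixture table. State 0 means the
    embryo's allele on this side originates from grandparent 1.
    """
    n = len(L_par)
    # G[:, e] = sum_t F_other[:, t] * L_e[:, e + t]
    G = np.stack(
        [
            F_other[:, 0] * L_e[:, 0] + F_other[:, 1] * L_e[:, 1],
            F_other[:, 0] * L_e[:, 1] + F_other[:, 1] * L_e[:, 2],
        ],
        axis=1,
    )
    E = np.zeros((n, 2))
    for a1 in (0, 1):
        for a2 in (0, 1):
            base = A1[:, a1] * A2[:, a2] * L_par[:, a1 + a2]
            E[:, 0] += base * G[:, a1]
            E[:, 1] += base * G[:, a2]
    return E


def child_emissions_chrx(
    L_m, L_f_hemi, L_c_dip, L_c_hemi, L_e_dip, L_e_hemi,
    prior, prior_hemi, child_sex: str, embryo_sex: str,
) -> np.ndarray:
    """(n, 2) maternal-side emissions on chrX, child-reference mode.

    The father is hemizygous; a male child/embryo carries only the maternal
    X (hemizygous likelihood), a female carries the maternal allele plus the
    father's X allele.
    """
    n = len(L_m)
    E = np.zeros((n, 2))
    for gm in (0, 1, 2):
        for xf in (0, 1):
            base = prior[:, gm] * L_m[:, gm] * prior_hemi[:, xf] * L_f_hemi[:, xf]
            for tm, wm in _TRANSMIT[gm]:
                om = gm - tm
                if child_sex == "male":
                    w = base * wm * L_c_hemi[:, tm]
                else:
                    w = base * wm * L_c_dip[:, tm + xf]
                for s, allele in ((0, tm), (1, om)):
                    if embryo_sex == "male":
                        E[:, s] += w * L_e_hemi[:, allele]
                    else:
                        E[:, s] += w * L_e_dip[:, allele + xf]
    return E


# -- track containers ------------------------------------------------------

TRACK_COLUMNS = ["chrom", "pos", "marginal", "prediction", "pass", "embryo_covered"]


@dataclass
class PhasingTrack:
    """Per-site phasing output for one embryo on one parental side.

    ``data`` columns: chrom, pos, marginal (posterior of the
    reference-match / grandparent_1-origin state), prediction (Viterbi,
    1 = match / grandparent_1), pass (marginal outside [conf_lo, conf_hi]),
    embryo_covered (>= 1 embryo read at the site). An optional ``roc`` column
    is added by :func:`famphase.roc.mask_roc`.
    """

    embryo: str
    side: str
    data: pd.DataFrame = field(repr=False)

    @property
    def marginal(self) -> np.ndarray:
        return self.data["marginal"].to_numpy()

    @property
    def prediction(self) -> np.ndarray:
        return self.data["prediction"].to_numpy()

    @property
    def passed(self) -> np.ndarray:
        return self.data["pass"].to_numpy()

    def to_tsv(self, path):
        df = self.data.copy()
        df.insert(2, "side", self.side)
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _make_track(embryo, side, sites, marginal, prediction, covered, params) -> PhasingTrack:
    marginal = np.clip(marginal, 0.0, 1.0)
    passed = (marginal > params.conf_hi) | (marginal < params.conf_lo)
    df = pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "marginal": marginal,
            "prediction": prediction.astype(np.int64),
            "pass": passed,
            "embryo_covered": covered,
        }
    )
    return PhasingTrack(embryo=embryo, side=side, data=df)


# -- main driver -----------------------------------------------------------

def _sample_sex(pedigree: Pedigree, sample: str, override: dict | None, context: str) -> str:
    if override and sample in override:
        return override[sample]
    if sample in pedigree.sex:
        return pedigree.sex[sample]
    logger.warning("sex of %s unknown on chrX (%s); assuming diploid female model", sample, context)
    return "female"


def run_phasing(
    table: SiteTable,
    pedigree: Pedigree,
    params: ModelParams | None = None,
    embryo_sex: dict[str, str] | None = None,
) -> list[PhasingTrack]:
    """Infer transmitted-haplotype tracks for every embryo and phaseable side.

    Returns one :class:`PhasingTrack` per embryo per phaseable side; chrX
    sites appear only in maternal tracks. ``embryo_sex`` (sample id ->
    "female"/"male") overrides the pedigree's sex assignments, e.g. with
    output of :func:`famphase.cnv.infer_sex`.
    """
    params = params or ModelParams()
    sides = pedigree.phaseable_sides()
    if not sides:
        raise ValueError("pedigree has no phaseable side")
    if table.n_sites == 0:
        raise ValueError("empty site table")

    q = table.sites["alt_freq"].to_numpy()
    prior = genotype_prior_table(q)
    prior_hemi = hemizygous_prior_table(q)
    eps = params.eps

    L = {
        pedigree.mother_id: read_likelihood_table(table.counts_for(pedigree.mother_id), eps),
        pedigree.father_id: read_likelihood_table(table.counts_for(pedigree.father_id), eps),
    }
    for ref in pedigree.reference_ids():
        L[ref] = read_likelihood_table(table.counts_for(ref), eps)

    slices = table.chrom_slices()
    tracks: list[PhasingTrack] = []

    for embryo in pedigree.embryos:
        counts_e = table.counts_for(embryo)
        if counts_e.sum() == 0:
            logger.warning("embryo %s has no reads at any site; marginals will be flat", embryo)
        L_e = embryo_read_likelihood_table(counts_e, eps, params.ado)
        covered = counts_e.sum(axis=1) >= 1

        if pedigree.reference_mode == "child":
            tracks.extend(
                _phase_child_mode(
                    table, pedigree, params, embryo, L, L_e, prior, prior_hemi,
                    covered, slices, embryo_sex,
                )
            )
        else:
            tracks.extend(
                _phase_grandparent_mode(
                    table, pedigree, params, embryo, L, L_e, prior, prior_hemi,
                    covered, slices, sides, embryo_sex,
                )
            )
    return tracks


def _phase_child_mode(
    table, pedigree, params, embryo, L, L_e, prior, prior_hemi, covered, slices, embryo_sex,
):
    child = pedigree.reference_child_id
    parts = {side: [] for side in SIDES}
    for chrom, sl in slices.items():
        pos = table.sites["pos"].to_numpy()[sl]
        if is_chrx(chrom):
            c_sex = _sample_sex(pedigree, child, None, f"reference child, {chrom}")
            e_sex = _sample_sex(pedigree, embryo, embryo_sex, f"embryo, {chrom}")
            counts_f = table.counts_for(pedigree.father_id)[sl]
            counts_c = table.counts_for(child)[sl]
            counts_e = table.counts_for(embryo)[sl]
            E = child_emissions_chrx(
                L[pedigree.mother_id][sl],
                hemizygous_likelihood_table(counts_f, params.eps),
                L[child][sl],
                hemizygous_likelihood_table(counts_c, params.eps),
                L_e[sl],
                hemizygous_likelihood_table(counts_e, params.eps),
                prior[sl], prior_hemi[sl], c_sex, e_sex,
            )
            r = switch_probs(pos, params, CHILD_MODE_MEIOSES)
            post, _ = hmm.forward_backward(E, _two_state_stack(r))
            path = hmm.viterbi(E, _two_state_stack(r))
            parts["maternal"].append(
                (sl, post[:, 0], (path == 0).astype(np.int64))
            )
        else:
            E = child_emissions(
                L[pedigree.mother_id][sl],
                L[pedigree.father_id][sl],
                L[child][sl],
                L_e[sl],
                prior[sl],
            )
            r = switch_probs(pos, params, CHILD_MODE_MEIOSES)
            trans = _joint_stack(r, r)
            post, _ = hmm.forward_backward(E, trans)
            path = hmm.viterbi(E, trans)
            parts["maternal"].append((sl, post[:, 0] + post[:, 1], (path < 2).astype(np.int64)))
            parts["paternal"].append((sl, post[:, 0] + post[:, 2], (path % 2 == 0).astype(np.int64)))

    out = []
    for side in SIDES:
        if not parts[side]:
            continue
        idx = np.concatenate([np.arange(sl.start, sl.stop) for sl, _, _ in parts[side]])
        marg = np.concatenate([m for _, m, _ in parts[side]])
        pred = np.concatenate([p for _, _, p in parts[side]])
        out.append(
            _make_track(embryo, side, table.sites.iloc[idx], marg, pred, covered[idx], params)
        )
    return out


def _phase_grandparent_mode(
    table, pedigree, params, embryo, L, L_e, prior, prior_hemi, covered, slices, sides, embryo_sex,
):
    out = []
    for side in sides:
        gps = pedigree.grandparents.get(side, [])
        if not gps:
            raise ValueError(f"side {side!r} has no grandparents and cannot be phased")
        parent = pedigree.mother_id if side == "maternal" else pedigree.father_id
        other = pedigree.father_id if side == "maternal" else pedigree.mother_id
        chunks = []
        for chrom, sl in slices.items():
            xchrom = is_chrx(chrom)
            if xchrom and side == "paternal":
                continue  # embryo X comes from the mother
            pos = table.sites["pos"].to_numpy()[sl]
            A = []
            for k in range(2):
                if k < len(gps):
                    gp = gps[k]
                    if xchrom and _sample_sex(pedigree, gp, None, f"grandparent, {chrom}") == "male":
                        counts_gp = table.counts_for(gp)[sl]
                        Ak = prior_hemi[sl] * hemizygous_likelihood_table(counts_gp, params.eps)
                    else:
                        Ak = transmit_weights(L[gp][sl], prior[sl])
                else:
                    # unsequenced grandparent: prior-only transmission weights
                    ones = np.ones((sl.stop - sl.start, 3))
                    Ak = transmit_weights(ones, prior[sl])
                A.append(Ak)
            if xchrom:
                e_sex = _sample_sex(pedigree, embryo, embryo_sex, f"embryo, {chrom}")
                counts_o = table.counts_for(other)[sl]
                F_other = prior_hemi[sl] * hemizygous_likelihood_table(counts_o, params.eps)
                if e_sex == "male":
                    counts_e = table.counts_for(embryo)[sl]
                    L_e_hemi = hemizygous_likelihood_table(counts_e, params.eps)
                    # no paternal contribution: embed hemizygous likelihood
                    F_other = np.stack([np.ones(sl.stop - sl.start), np.zeros(sl.stop - sl.start)], 1)
                    L_e_use = np.stack(
                        [L_e_hemi[:, 0], L_e_hemi[:, 1], np.zeros(sl.stop - sl.start)], 1
                    )
                else:
                    L_e_use = L_e[sl]
            else:
                F_other = transmit_weights(L[other][sl], prior[sl])
                L_e_use = L_e[sl]
            E = grandparent_emissions(A[0], A[1], L[parent][sl], L_e_use, F_other)
            r = switch_probs(pos, params, GRANDPARENT_MODE_MEIOSES)
            trans = _two_state_stack(r)
            post, _ = hmm.forward_backward(E, trans)
            path = hmm.viterbi(E, trans)
            chunks.append((sl, post[:, 0], (path == 0).astype(np.int64)))
        idx = np.concatenate([np.arange(sl.start, sl.stop) for sl, _, _ in chunks])
        marg = np.concatenate([m for _, m, _ in chunks])
        pred = np.concatenate([p for _, _, p in chunks])
        out.append(
            _make_track(embryo, side, table.sites.iloc[idx], marg, pred, covered[idx], params)
        )
    return out


# -- single-site convenience wrappers (useful for testing and inspection) --

def emission_child_mode(counts_by_sample, alt_freq, pedigree, embryo, params) -> np.ndarray:
    """Joint 4-state emission likelihoods at a single autosomal site."""
    eps, ado = params.eps, params.ado

    def tab(sample, embryo_like=False):
        c = np.asarray([counts_by_sample.get(sample, (0, 0))])
        if embryo_like:
            return embryo_read_likelihood_table(c, eps, ado)
        return read_likelihood_table(c, eps)

    prior = genotype_prior_table(np.asarray([alt_freq]))
    E = child_emissions(
        tab(pedigree.mother_id),
        tab(pedigree.father_id),
        tab(pedigree.reference_child_id),
        tab(embryo, embryo_like=True),
        prior,
    )
    return E[0]


def emission_grandparent_mode(counts_by_sample, side, alt_freq, pedigree, embryo, params) -> np.ndarray:
    """2-state emission likelihoods at a single autosomal site for ``side``."""
    gps = pedigree.grandparents.get(side, [])
    if not gps:
        raise ValueError(f"side {side!r} has no grandparents and cannot be phased")
    eps, ado = params.eps, params.ado
    prior = genotype_prior_table(np.asarray([alt_freq]))

    def tab(sample):
        return read_likelihood_table(np.asarray([counts_by_sample.get(sample, (0, 0))]), eps)

    A = []
    for k in range(2):
        if k < len(gps):
            A.append(transmit_weights(tab(gps[k]), prior))
        else:
            A.append(transmit_weights(np.ones((1, 3)), prior))
    parent = pedigree.mother_id if side == "maternal" else pedigree.father_id
    other = pedigree.father_id if side == "maternal" else pedigree.mother_id
    L_e = embryo_read_likelihood_table(
        np.asarray([counts_by_sample.get(embryo, (0, 0))]), eps, ado
    )
    E = grandparent_emissions(A[0], A[1], tab(parent), L_e, transmit_weights(tab(other), prior))
    return E[0]


# -- model / results objects -----------------------------------------------

class FamilyPhasingModel:
    """Family phasing model over a :class:`SiteTable` and :class:`Pedigree`.

    ``fit`` filters phase-informative sites (unless disabled) and runs the
    per-embryo HMMs, returning a :class:`PhasingResults`.
    """

    def __init__(self, table, pedigree, params=None, embryo_sex=None):
        self.table = table
        self.pedigree = pedigree
        self.params = params or ModelParams()
        self.embryo_sex = embryo_sex

    @classmethod
    def from_files(cls, counts_path, pedigree_path, params=None, embryo_sex=None):
        from .io import load_allele_counts, load_pedigree, load_vcf

        pedigree = load_pedigree(pedigree_path)
        path = str(counts_path)
        if path.endswith((".vcf", ".vcf.gz")):
            table = load_vcf(path, pedigree)
        else:
            table = load_allele_counts(path, pedigree)
        return cls(table, pedigree, params=params, embryo_sex=embryo_sex)

    def fit(self, filter_sites: bool = True, min_alt_reads: int | None = None) -> "PhasingResults":
        from .likelihoods import filter_informative_sites

        table = self.table
        if filter_sites:
            table = filter_informative_sites(
                table, self.pedigree, min_alt_reads=min_alt_reads, params=self.params
            )
        tracks = run_phasing(table, self.pedigree, self.params, embryo_sex=self.embryo_sex)
        return PhasingResults(self, table, tracks)


class PhasingResults:
    """Fitted phasing tracks plus simple per-track summaries."""

    def __init__(self, model: FamilyPhasingModel, table: SiteTable, tracks: list[PhasingTrack]):
        self.model = model
        self.table = table
        self.tracks = tracks

    def track(self, embryo: str, side: str) -> PhasingTrack:
        for t in self.tracks:
            if t.embryo == embryo and t.side == side:
                return t
        raise KeyError(f"no track for embryo {embryo!r}, side {side!r}")

    def summary(self) -> pd.DataFrame:
        rows = []
        for t in self.tracks:
            m = t.marginal
            rows.append(
                {
                    "embryo": t.embryo,
                    "side": t.side,
                    "n_sites": len(m),
                    "n_embryo_covered": int(t.data["embryo_covered"].sum()),
                    "prop_pass": float(t.passed.mean()) if len(m) else np.nan,
                    "prop_match": float((t.prediction == 1).mean()) if len(m) else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def to_dir(self, outdir):
        import os

        os.makedirs(outdir, exist_ok=True)
        for t in self.tracks:
            t.to_tsv(os.path.join(outdir, f"track_{t.embryo}_{t.side}.tsv"))
        self.summary().to_csv(os.path.join(outdir, "summary.tsv"), sep="\t", index=False)
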