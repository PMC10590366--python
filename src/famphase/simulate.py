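"""Synthetic family-sequencing generator.

Simulates the study design the phasing engine targets: founder haplotypes
drawn site-wise from population allele frequencies, meioses with
Haldane-model crossovers (Poisson along the genetic map), optional
consanguinity (one parent's haplotype pair copied into the other over
contiguous segments), embryo copy-number events, and read-count sampling at
role-specific depths (reads per site ~ Poisson(depth), allele choice uniform
over the carried alleles, per-read error eps, and per-het-site allele
dropout ado in embryos). Returns the observable :class:`SiteTable` together
with a :class:`TruthSet` carrying the transmitted-haplotype origin of every
embryo allele, crossover positions, true ROC intervals and true CNVs.

Defaults mirror the designs the engine is validated on: five 50 Mb
chromosomes with 10,000 SNVs each, parents and reference at 2x, embryos at
0.3x, eps = 0.002, ado = 0.1, 1 cM/Mb.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import Pedigree, SiteTable, is_chrx

_ALLELES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CnvSpec:
    """A simulated embryo copy-number event (1-based inclusive coords)."""

    chrom: str
    start: int
    end: int
    copy: int  # 0, 1, 3 (2 = no event)


@dataclass
class SimConfig:
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 50_000_000 for i in range(1, 6)}
    )
    n_sites_per_chrom: int = 10_000
    alt_freq_range: tuple[float, float] = (0.05, 0.95)
    depth_mother: float = 2.0
    depth_father: float = 2.0
    depth_reference: float = 2.0
    depth_embryo: float = 0.3
    depth_overrides: dict[str, float] = field(default_factory=dict)
    eps: float = 0.002
    ado: float = 0.1
    cm_per_mb: float = 1.0
    n_embryos: int = 3
    reference_mode: str = "child"
    grandparents: dict[str, int] = field(default_factory=dict)  # side -> 1 or 2 sequenced
    consanguinity_fraction: float = 0.0
    consanguinity_segment_bp: int = 10_000_000
    embryo_cnvs: dict[str, list[CnvSpec]] = field(default_factory=dict)
    include_chrx: bool = False
    chrx_length: int = 155_000_000
    child_sex: str = "female"
    embryo_sexes: list[str] | None = None
    depth_cv: float = 0.0  # per-site Gamma depth multiplier (0 = off)
    seed: int = 0

    def __post_init__(self):
        for d in (self.depth_mother, self.depth_father, self.depth_reference, self.depth_embryo):
            if d < 0:
                raise ValueError("depths must be non-negative")
        if not 0.0 <= self.consanguinity_fraction <= 1.0:
            raise ValueError("consanguinity_fraction must lie in [0, 1]")
        if self.reference_mode == "child" and self.grandparents:
            raise ValueError("grandparents cannot be requested in child reference mode")
        if self.reference_mode == "grandparent" and not self.grandparents:
            raise ValueError("grandparent mode requires at least one grandparent side")
        for side, k in self.grandparents.items():
            if side not in ("maternal", "paternal") or not 1 <= k <= 2:
                raise ValueError(f"invalid grandparent spec {side}={k}")


@dataclass
class TruthSet:
    """Ground truth for a simulated family."""

    sites: pd.DataFrame = field(repr=False)  # chrom, pos
    origins: dict = field(repr=False)        # (embryo, side) -> int8 array (hap slot)
    labels_: dict = field(repr=False)        # (embryo, side) -> bool array
    site_index: dict = field(repr=False)     # (embryo, side) -> row indices into sites
    crossovers: dict = field(default_factory=dict, repr=False)
    haplotypes: dict = field(default_factory=dict, repr=False)  # individual -> chrom -> (copies, n)
    roc_intervals: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end"]), repr=False)
    cnvs: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["embryo", "chrom", "start", "end", "copy"]), repr=False)
    sexes: dict = field(default_factory=dict)

    def labels(self, embryo: str, side: str) -> pd.DataFrame:
        """(chrom, pos, label) for an embryo/side; label is True when the
        embryo's haplotype matches the reference child's (child mode) or
        originates from grandparent 1 (grandparent mode)."""
        idx = self.site_index[(embryo, side)]
        df = self.sites.iloc[idx][["chrom", "pos"]].reset_index(drop=True)
        df["label"] = self.labels_[(embryo, side)]
        return df

    def label_frame(self) -> pd.DataFrame:
        rows = []
        for (embryo, side) in self.labels_:
            df = self.labels(embryo, side)
            df.insert(0, "side", side)
            df.insert(0, "embryo", embryo)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


@dataclass
class SimFamily:
    table: SiteTable
    pedigree: Pedigree
    truth: TruthSet

    def __iter__(self):
        return iter((self.table, self.pedigree, self.truth))


# -- internals -------------------------------------------------------------

def _meiosis(haps: np.ndarray, pos: np.ndarray, length: int, cm_per_mb: float, rng):
    """One gamete from a diploid haplotype pair.

    Returns (gamete alleles, per-site origin slot in {0,1}, crossover bp).
    """
    morgans = length * cm_per_mb / 1e8
    n_x = rng.poisson(morgans)
    xpos = np.sort(rng.uniform(0, length, size=n_x))
    start = int(rng.integers(2))
    origin = (start + np.searchsorted(xpos, pos)) % 2
    gamete = haps[origin, np.arange(len(pos))]
    return gamete.astype(np.int8), origin.astype(np.int8), xpos


def _founder(q: np.ndarray, rng) -> np.ndarray:
    return (rng.random((2, len(q))) < q[None, :]).astype(np.int8)


def _place_segments(chrom_lengths: Mapping[str, int], target_bp: int, seg_len: int, rng):
    """Non-overlapping segments of ~seg_len distributed over chromosomes."""
    chroms = [c for c in chrom_lengths if not is_chrx(c)]
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    total = 0
    attempts = 0
    ci = 0
    while total < target_bp and attempts < 10_000:
        chrom = chroms[ci % len(chroms)]
        ci += 1
        attempts += 1
        length = min(seg_len, target_bp - total)  # last segment truncated
        L = chrom_lengths[chrom]
        if length >= L:
            continue
        s = int(rng.integers(1, L - length + 1))
        e = s + length - 1
        if any(not (e < a or s > b) for a, b in placed[chrom]):
            continue
        placed[chrom].append((s, e))
        total += length
    rows = [
        {"chrom": c, "start": s, "end": e}
        for c in chroms
        for s, e in sorted(placed[c])
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _sample_counts(f_alt: np.ndarray, depth: float, eps: float, rng, depth_cv: float = 0.0,
                   depth_mult: np.ndarray | None = None) -> np.ndarray:
    lam = np.full(len(f_alt), float(depth))
    if depth_mult is not None:
        lam = lam * depth_mult
    if depth_cv > 0:
        k = 1.0 / depth_cv**2
        lam = lam * rng.gamma(k, 1.0 / k, size=len(f_alt))
    n_tot = rng.poisson(lam)
    p = f_alt * (1.0 - eps) + (1.0 - f_alt) * eps
    n_alt = rng.binomial(n_tot, p)
    return np.stack([n_tot - n_alt, n_alt], axis=1).astype(np.int64)


def simulate_family(config: SimConfig) -> SimFamily:
    """Generate one family: observable counts, pedigree and ground truth."""
    rng = np.random.default_rng(config.seed)
    chroms = dict(config.chrom_lengths)
    if config.include_chrx:
        chroms["chrX"] = config.chrx_length

    # sites ---------------------------------------------------------------
    site_rows = []
    q_by_chrom = {}
    pos_by_chrom = {}
    lo, hi = config.alt_freq_range
    for chrom, length in chroms.items():
        n = config.n_sites_per_chrom
        pos = np.unique(rng.integers(1, length + 1, size=int(n * 1.05) + 8))
        if len(pos) > n:
            pos = np.sort(rng.choice(pos, size=n, replace=False))
        q = rng.uniform(lo, hi, size=len(pos))
        ra = _ALLELES[rng.integers(0, 4, size=len(pos))]
        shift = rng.integers(1, 4, size=len(pos))
        aa = _ALLELES[(np.searchsorted(_ALLELES, ra) + shift) % 4]
        site_rows.append(pd.DataFrame({"chrom": chrom, "pos": pos, "ref": ra, "alt": aa, "alt_freq": q}))
        q_by_chrom[chrom] = q
        pos_by_chrom[chrom] = pos
    sites = pd.concat(site_rows, ignore_index=True)

    # pedigree ------------------------------------------------------------
    embryo_ids = [f"embryo{i+1}" for i in range(config.n_embryos)]
    sexes: dict[str, str] = {}
    if config.include_chrx:
        e_sexes = config.embryo_sexes or ["female"] * config.n_embryos
        sexes.update(dict(zip(embryo_ids, e_sexes)))
        sexes["mother"] = "female"
        sexes["father"] = "male"

    gp_ids: dict[str, list[str]] = {}
    if config.reference_mode == "grandparent":
        for side, k in config.grandparents.items():
            ids = [f"{side}_gp{j+1}" for j in range(k)]
            gp_ids[side] = ids
            for j, gid in enumerate(ids):
                sexes[gid] = "female" if j == 0 else "male"
        pedigree = Pedigree(
            mother_id="mother", father_id="father", embryos=embryo_ids,
            reference_mode="grandparent", grandparents=gp_ids, sex=sexes,
        )
    else:
        if config.include_chrx:
            sexes["child"] = config.child_sex
        pedigree = Pedigree(
            mother_id="mother", father_id="father", embryos=embryo_ids,
            reference_mode="child", reference_child_id="child", sex=sexes,
        )

    # founder haplotypes and parental meioses ------------------------------
    # haps[individual][chrom] -> (n_copies, n_sites_chrom) int8
    haps: dict[str, dict[str, np.ndarray]] = {}
    crossovers: dict[str, list] = {}

    def new_individual(name):
        haps[name] = {}

    for name in ("mother", "father"):
        new_individual(name)

    # which grandparents exist genetically (both, on any side with a reference)
    gp_sides = set(config.grandparents) if config.reference_mode == "grandparent" else set()
    for side in gp_sides:
        for j in (0, 1):
            new_individual(f"{side}_gp{j+1}__full")

    for chrom, length in chroms.items():
        q = q_by_chrom[chrom]
        pos = pos_by_chrom[chrom]
        xchrom = is_chrx(chrom)
        for side, parent in (("maternal", "mother"), ("paternal", "father")):
            if side in gp_sides:
                g1 = f"{side}_gp1__full"
                g2 = f"{side}_gp2__full"
                haps[g1][chrom] = _founder(q, rng)
                if xchrom:
                    haps[g2][chrom] = _founder(q, rng)[:1]  # grandfather: single X
                else:
                    haps[g2][chrom] = _founder(q, rng)
                # parent haplotype slot k descends wholly from grandparent k+1
                h1, _, x1 = _meiosis(haps[g1][chrom], pos, length, config.cm_per_mb, rng)
                if xchrom:
                    h2 = haps[g2][chrom][0].copy()
                    x2 = np.array([])
                else:
                    h2, _, x2 = _meiosis(haps[g2][chrom], pos, length, config.cm_per_mb, rng)
                crossovers.setdefault(f"{side}_gp1->{parent}", []).append((chrom, x1))
                crossovers.setdefault(f"{side}_gp2->{parent}", []).append((chrom, x2))
                pair = np.stack([h1, h2])
            else:
                pair = _founder(q, rng)
            if xchrom and parent == "father":
                pair = pair[:1]  # father carries a single X
            haps[parent][chrom] = pair

    # consanguinity: copy the mother's haplotype pair into the father -------
    roc_intervals = pd.DataFrame(columns=["chrom", "start", "end"])
    if config.consanguinity_fraction > 0:
        total_bp = sum(L for c, L in chroms.items() if not is_chrx(c))
        roc_intervals = _place_segments(
            chroms, int(config.consanguinity_fraction * total_bp),
            config.consanguinity_segment_bp, rng,
        )
        for _, iv in roc_intervals.iterrows():
            chrom = iv["chrom"]
            pos = pos_by_chrom[chrom]
            mask = (pos >= iv["start"]) & (pos <= iv["end"])
            haps["father"][chrom][:, mask] = haps["mother"][chrom][:2, mask]

    # meioses to reference child and embryos --------------------------------
    offspring = ([("child", config.child_sex)] if config.reference_mode == "child" else []) + [
        (e, sexes.get(e, "female")) for e in embryo_ids
    ]
    origins: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for name, sex in offspring:
        new_individual(name)
        for chrom, length in chroms.items():
            pos = pos_by_chrom[chrom]
            xchrom = is_chrx(chrom)
            hm, om, xm = _meiosis(haps["mother"][chrom], pos, length, config.cm_per_mb, rng)
            crossovers.setdefault(f"mother->{name}", []).append((chrom, xm))
            origins.setdefault((name, "maternal"), {})[chrom] = om
            if xchrom:
                if sex == "male":
                    haps[name][chrom] = hm[None, :]
                else:
                    haps[name][chrom] = np.stack([hm, haps["father"][chrom][0]])
            else:
                hp, op, xp = _meiosis(haps["father"][chrom], pos, length, config.cm_per_mb, rng)
                crossovers.setdefault(f"father->{name}", []).append((chrom, xp))
                origins.setdefault((name, "paternal"), {})[chrom] = op
                haps[name][chrom] = np.stack([hm, hp])

    # truth labels ----------------------------------------------------------
    chrom_order = list(chroms)
    chrom_row0 = {}
    off = 0
    for chrom in chrom_order:
        chrom_row0[chrom] = off
        off += len(pos_by_chrom[chrom])

    labels_: dict = {}
    origins_flat: dict = {}
    site_index: dict = {}
    for e in embryo_ids:
        for side in pedigree.phaseable_sides():
            rows = []
            orig = []
            lab = []
            for chrom in chrom_order:
                if is_chrx(chrom) and side == "paternal":
                    continue
                o = origins[(e, side)][chrom]
                rows.append(np.arange(chrom_row0[chrom], chrom_row0[chrom] + len(o)))
                orig.append(o)
                if config.reference_mode == "child":
                    lab.append(o == origins[("child", side)][chrom])
                else:
                    lab.append(o == 0)  # slot 0 descends from grandparent 1
            site_index[(e, side)] = np.concatenate(rows)
            origins_flat[(e, side)] = np.concatenate(orig)
            labels_[(e, side)] = np.concatenate(lab)

    # read counts ------------------------------------------------------------
    depths = {
        "mother": config.depth_mother,
        "father": config.depth_father,
    }
    if config.reference_mode == "child":
        depths["child"] = config.depth_reference
    else:
        for side, ids in gp_ids.items():
            for gid in ids:
                depths[gid] = config.depth_reference
    for e in embryo_ids:
        depths[e] = config.depth_embryo
    depths.update(config.depth_overrides)

    cnv_rows = []
    counts: dict[str, np.ndarray] = {}
    for sample, depth in depths.items():
        hap_source = sample[:-6] if sample.endswith("__full") else sample
        if sample not in haps and f"{sample}__full" in haps:
            hap_source = f"{sample}__full"
        sample_haps = haps[hap_source]
        blocks = []
        is_embryo = sample in embryo_ids
        for chrom in chrom_order:
            pair = sample_haps[chrom]
            n = pair.shape[1]
            pools = pair.astype(float)
            f_alt = pools.mean(axis=0)
            depth_mult = np.ones(n)
            if is_embryo:
                # allele dropout at heterozygous sites
                if config.ado > 0 and pair.shape[0] == 2:
                    het = pair[0] != pair[1]
                    drop = het & (rng.random(n) < config.ado)
                    keep = rng.integers(2, size=n)
                    f_alt = np.where(drop, pair[keep, np.arange(n)], f_alt)
                for spec in config.embryo_cnvs.get(sample, []):
                    if spec.chrom != chrom:
                        continue
                    pos = pos_by_chrom[chrom]
                    mask = (pos >= spec.start) & (pos <= spec.end)
                    depth_mult = np.where(mask, spec.copy / 2.0, depth_mult)
                    if spec.copy == 1 and pair.shape[0] == 2:
                        lost = int(rng.integers(2))
                        f_alt = np.where(mask, pair[1 - lost], f_alt)
                    elif spec.copy >= 3 and pair.shape[0] == 2:
                        dup = int(rng.integers(2))
                        f_alt = np.where(mask, (pair.sum(axis=0) + pair[dup]) / 3.0, f_alt)
                    elif spec.copy == 0:
                        f_alt = np.where(mask, 0.0, f_alt)
            blocks.append(
                _sample_counts(f_alt, depth, config.eps, rng,
                               depth_cv=config.depth_cv, depth_mult=depth_mult)
            )
        counts[sample] = np.concatenate(blocks, axis=0)

    for e, specs in config.embryo_cnvs.items():
        for spec in specs:
            cnv_rows.append({"embryo": e, "chrom": spec.chrom, "start": spec.start,
                             "end": spec.end, "copy": spec.copy})

    table = SiteTable(sites, counts)
    truth = TruthSet(
        sites=sites[["chrom", "pos"]].copy(),
        origins=origins_flat,
        labels_=labels_,
        site_index=site_index,
        crossovers=crossovers,
        haplotypes=haps,
        roc_intervals=roc_intervals,
        cnvs=pd.DataFrame(cnv_rows, columns=["embryo", "chrom", "start", "end", "copy"]),
        sexes=sexes,
    )
    return SimFamily(table=table, pedigree=pedigree, truth=truth)


def simulate_binned_counts(
    chrom_lengths: Mapping[str, int],
    depth: float,
    cnvs: Sequence[CnvSpec] = (),
    bin_width: int = 1_000_000,
    read_length: int = 150,
    seed: int | np.random.Generator = 0,
    sex: str = "female",
) -> dict[str, np.ndarray]:
    """Per-bin read counts for one embryo at a given sequencing depth.

    Expected reads per full bin are depth * bin_width / read_length, scaled
    by copy/2 within CNV intervals (male embryos carry one X: copy 1 on
    chrX). Counts are Poisson.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean_full = depth * bin_width / read_length
    out = {}
    for chrom, length in chrom_lengths.items():
        n_bins = int(np.ceil(length / bin_width))
        starts = np.arange(n_bins, dtype=np.int64) * bin_width
        ends = np.minimum(starts + bin_width, length)
        frac = (ends - starts) / bin_width
        copy = np.full(n_bins, 1.0 if (is_chrx(chrom) and sex == "male") else 2.0)
        for spec in cnvs:
            if spec.chrom != chrom:
                continue
            ov = np.minimum(ends, spec.end) - np.maximum(starts, spec.start - 1)
            ov = np.clip(ov, 0, None) / np.maximum(ends - starts, 1)
            copy = copy + (spec.copy - 2.0) * ov
        out[chrom] = rng.poisson(mean_full * frac * copy / 2.0)
    return out


def write_fixture(sim: SimFamily, out_dir) -> dict[str, str]:
    """Write TSV + VCF counts, pedigree config and truth files; returns paths."""
    import os

    from .io import write_allele_counts, write_pedigree, write_vcf

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "counts_tsv": os.path.join(out_dir, "counts.tsv"),
        "counts_vcf": os.path.join(out_dir, "counts.vcf"),
        "pedigree": os.path.join(out_dir, "pedigree.yaml"),
        "truth_labels": os.path.join(out_dir, "truth_labels.tsv"),
        "truth_roc": os.path.join(out_dir, "truth_roc.bed"),
        "truth_cnv": os.path.join(out_dir, "truth_cnv.tsv"),
    }
    write_allele_counts(sim.table, paths["counts_tsv"])
    write_vcf(sim.table, paths["counts_vcf"])
    write_pedigree(sim.pedigree, paths["pedigree"])
    sim.truth.label_frame().to_csv(paths["truth_labels"], sep="\t", index=False)
    roc = sim.truth.roc_intervals.copy()
    if len(roc):
        roc["start"] = roc["start"] - 1
    roc.to_csv(paths["truth_roc"], sep="\t", index=False, header=False)
    sim.truth.cnvs.to_csv(paths["truth_cnv"], sep="\t", index=False)
    return paths
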