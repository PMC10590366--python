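"""Readers and writers: allele-count TSV, VCF (AD-based), pedigree config.

The allele-count TSV dialect has the header
``chrom pos ref alt alt_freq <sample>_ref <sample>_alt ...`` (tab-separated,
one row per site). VCF input is standard VCF 4.x with a per-sample
allelic-depth (AD) FORMAT field; non-biallelic records and indels are
skipped (with a logged count). Pedigree configuration is a small YAML file
mapping roles to sample ids.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import yaml

from .data import SITE_COLUMNS, Pedigree, SiteTable

logger = logging.getLogger(__name__)

DEFAULT_ALT_FREQ = 0.5  # symmetric prior when no population frequency is given


def load_allele_counts(path, pedigree: Pedigree) -> SiteTable:
    """Read the allele-count TSV into a :class:`SiteTable`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"allele-count file missing columns {missing}")
    for sample in pedigree.samples():
        for suffix in ("_ref", "_alt"):
            if f"{sample}{suffix}" not in df.columns:
                raise ValueError(f"missing column {sample}{suffix} for pedigree sample {sample!r}")

    count_cols = [c for c in df.columns if c.endswith(("_ref", "_alt")) and c not in SITE_COLUMNS]
    bad_rows = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = row._asdict()
        try:
            pos = int(rec["pos"])
            af = float(rec["alt_freq"])
            ok = pos >= 1 and 0 <= af <= 1 and rec["ref"] != rec["alt"]
            ok = ok and all(int(rec[c]) >= 0 for c in count_cols)
        except (TypeError, ValueError):
            ok = False
        if not ok:
            bad_rows.append(i + 2)  # 1-based file line, counting the header
    if bad_rows:
        raise ValueError(f"malformed rows at file lines {bad_rows[:20]}")

    samples = sorted({c[:-4] for c in count_cols})
    counts = {
        s: np.stack([df[f"{s}_ref"].to_numpy(np.int64), df[f"{s}_alt"].to_numpy(np.int64)], axis=1)
        for s in samples
    }
    return SiteTable(df[SITE_COLUMNS], counts)


def write_allele_counts(table: SiteTable, path):
    df = table.sites.copy()
    for s in table.samples:
        c = table.counts_for(s)
        df[f"{s}_ref"] = c[:, 0]
        df[f"{s}_alt"] = c[:, 1]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def load_vcf(path, pedigree: Pedigree, alt_freq_default: float = DEFAULT_ALT_FREQ) -> SiteTable:
    """Read per-sample allelic depths from a VCF into a :class:`SiteTable`.

    Only biallelic SNVs are kept (skipped records are counted and logged).
    Population alt-allele frequency is taken from INFO/AF when present,
    otherwise ``alt_freq_default``. A sample with missing AD at a site gets
    (0, 0) counts.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for s in pedigree.samples():
        if s not in samples:
            raise ValueError(f"pedigree sample {s!r} not in VCF")

    rows = []
    counts_rows = []
    n_skipped = 0
    saw_ad = False
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            counts_rows.append(np.zeros((len(samples), 2), dtype=np.int64))
        else:
            saw_ad = True
            ad = np.asarray(ad, dtype=np.int64)[:, :2]
            ad[ad < 0] = 0
            counts_rows.append(ad)
        af = var.INFO.get("AF")
        if af is None:
            af = alt_freq_default
        else:
            if isinstance(af, tuple):
                af = af[0]
            # VCF Float is 32-bit; recover the shortest decimal it encodes
            af = float(np.format_float_positional(np.float32(af), unique=True))
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0], float(af)))
    if rows and not saw_ad:
        raise ValueError("VCF has no allelic-depth (AD) annotation in any record")
    if n_skipped:
        logger.info("load_vcf: skipped %d non-biallelic-SNV records", n_skipped)

    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    stacked = (
        np.stack(counts_rows, axis=0) if counts_rows else np.zeros((0, len(samples), 2), np.int64)
    )
    counts = {s: stacked[:, i, :] for i, s in enumerate(samples)}
    return SiteTable(sites, counts)


def write_vcf(table: SiteTable, path):
    """Write the table as a minimal VCF 4.2 with AF info and AD genotypes."""
    samples = table.samples
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        for chrom in table.chromosomes():
            sl = table.chrom_slices()[chrom]
            fh.write(f"##contig=<ID={chrom},length={int(table.sites['pos'].iloc[sl.stop - 1]) + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        counts = [table.counts_for(s) for s in samples]
        for i, row in enumerate(table.sites.itertuples(index=False)):
            fields = [
                str(row.chrom), str(row.pos), ".", row.ref, row.alt, ".", "PASS",
                f"AF={row.alt_freq:.6g}", "GT:AD",
            ]
            for c in counts:
                fields.append(f"./.:{c[i, 0]},{c[i, 1]}")
            fh.write("\t".join(fields) + "\n")


def load_pedigree(path) -> Pedigree:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return Pedigree(
        mother_id=cfg["mother"],
        father_id=cfg["father"],
        embryos=list(cfg["embryos"]),
        reference_mode=cfg.get("reference_mode", "child"),
        reference_child_id=cfg.get("reference_child"),
        grandparents={k: list(v) for k, v in (cfg.get("grandparents") or {}).items()},
        sex=dict(cfg.get("sex") or {}),
    )


def write_pedigree(pedigree: Pedigree, path):
    cfg = {
        "mother": pedigree.mother_id,
        "father": pedigree.father_id,
        "embryos": list(pedigree.embryos),
        "reference_mode": pedigree.reference_mode,
    }
    if pedigree.reference_child_id:
        cfg["reference_child"] = pedigree.reference_child_id
    if pedigree.grandparents:
        cfg["grandparents"] = {k: list(v) for k, v in pedigree.grandparents.items()}
    if pedigree.sex:
        cfg["sex"] = dict(pedigree.sex)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def apply_include_mask(table: SiteTable, bed_path) -> SiteTable:
    """Restrict a table to sites inside a BED include-mask (0-based half-open)."""
    bed = pd.read_csv(bed_path, sep="\t", header=None, usecols=[0, 1, 2],
                      names=["chrom", "start", "end"], dtype={"chrom": str})
    chrom = table.sites["chrom"].to_numpy()
    pos = table.sites["pos"].to_numpy()
    mask = np.zeros(table.n_sites, dtype=bool)
    for _, iv in bed.iterrows():
        mask |= (chrom == iv["chrom"]) & (pos > iv["start"]) & (pos <= iv["end"])
    return table.subset(mask)


def load_track_tsv(path):
    """Read a phasing-track TSV written by :meth:`PhasingTrack.to_tsv`."""
    from .phasing import PhasingTrack

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    side = df.pop("side").iloc[0] if "side" in df.columns and len(df) else "maternal"
    import os

    name = os.path.basename(str(path))
    embryo = name[len("track_"):].rsplit("_", 1)[0] if name.startswith("track_") else name
    return PhasingTrack(embryo=embryo, side=side, data=df)
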