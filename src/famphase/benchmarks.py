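"""Standard simulation designs used to validate the phasing and CNV engines.

The child-reference design mirrors a two-parent family with one born child
as phasing reference and three embryo biopsies: five 50 Mb chromosomes with
10,000 SNVs each (200 SNVs/Mb), parents and reference sequenced at a chosen
low-pass depth, embryos at 0.3x, per-read error 0.002, allele dropout 0.1,
and a 1 cM/Mb genetic map. The grandparent-reference design replaces the
born child with one or two sequenced maternal grandparents. The CNV design
places a whole-chromosome trisomy and monosomy, a 10 Mb deletion, and a
3 Mb deletion (below the 5 Mb reporting length) on separate chromosomes at
0.3x embryo depth.

Each runner simulates a family, runs the corresponding model on the
simulated counts, and scores the results against the simulator's truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cnv import bin_and_normalize, call_cnv
from .data import ModelParams
from .evaluate import evaluate_family, reciprocal_overlap
from .phasing import run_phasing
from .roc import detect_roc
from .simulate import CnvSpec, SimConfig, simulate_binned_counts, simulate_family


def child_reference_config(depth: float, seed: int, consanguinity: float = 0.0,
                           n_embryos: int = 3) -> SimConfig:
    return SimConfig(
        depth_mother=depth, depth_father=depth, depth_reference=depth,
        consanguinity_fraction=consanguinity, n_embryos=n_embryos, seed=seed,
    )


def grandparent_reference_config(depth: float, seed: int, n_grandparents: int = 2,
                                 n_embryos: int = 8) -> SimConfig:
    return SimConfig(
        depth_mother=depth, depth_father=depth, depth_reference=depth,
        reference_mode="grandparent", grandparents={"maternal": n_grandparents},
        n_embryos=n_embryos, seed=seed,
    )


def run_child_reference(depth: float, seed: int, consanguinity: float = 0.0,
                        params: ModelParams | None = None) -> pd.DataFrame:
    """Simulate, phase and score one child-reference family.

    With consanguinity, ROC intervals are detected from the parental counts
    and a ``non-ROC`` stratum is added to the report.
    """
    sim = simulate_family(child_reference_config(depth, seed, consanguinity))
    roc = detect_roc(sim.table, sim.pedigree, params) if consanguinity > 0 else None
    tracks = run_phasing(sim.table, sim.pedigree, params)
    rep = evaluate_family(tracks, sim.truth, roc=roc, params=params)
    rep.insert(0, "depth", depth)
    rep.insert(1, "seed", seed)
    return rep


def run_grandparent_reference(depth: float, seed: int, n_grandparents: int = 2,
                              n_embryos: int = 8,
                              params: ModelParams | None = None) -> pd.DataFrame:
    sim = simulate_family(
        grandparent_reference_config(depth, seed, n_grandparents, n_embryos)
    )
    tracks = run_phasing(sim.table, sim.pedigree, params)
    rep = evaluate_family(tracks, sim.truth, params=params)
    rep.insert(0, "depth", depth)
    rep.insert(1, "seed", seed)
    return rep


CNV_CHROMS = {f"chr{i}": 80_000_000 for i in range(1, 6)}
CNV_EVENTS = [
    ("trisomy", CnvSpec("chr1", 1, 80_000_000, 3), "gain"),
    ("monosomy", CnvSpec("chr2", 1, 80_000_000, 1), "loss"),
    ("del_10mb", CnvSpec("chr3", 30_000_001, 40_000_000, 1), "loss"),
    ("del_3mb", CnvSpec("chr4", 50_000_001, 53_000_000, 1), "loss"),
]


def run_cnv_trial(seed: int, depth: float = 0.3,
                  params: ModelParams | None = None) -> dict[str, float]:
    """One CNV-detection trial: best reciprocal overlap per simulated event."""
    specs = [spec for _, spec, _ in CNV_EVENTS]
    counts = simulate_binned_counts(CNV_CHROMS, depth, specs, seed=seed)
    segments = call_cnv(bin_and_normalize(counts, chrom_lengths=CNV_CHROMS), params).segments
    out = {}
    for name, spec, state in CNV_EVENTS:
        hits = segments[
            (segments["chrom"] == spec.chrom)
            & (segments["state"] == state)
        ]
        best = max(
            (reciprocal_overlap(spec.start - 1, spec.end, r["start"], r["end"])
             for _, r in hits.iterrows()),
            default=0.0,
        )
        out[name] = best
    out["n_nonneutral_chr4"] = int(
        (segments[segments["chrom"] == "chr4"]["state"] != "neutral").sum()
    )
    return out
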