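"""Embryo-only copy-number calling from binned sequencing depth.

Runs on each embryo's ultra-low-pass data alone: read counts are binned into
fixed-width windows (1 Mb default), normalised by the autosomal median, and
segmented by a 3-state HMM with expected depth ratios 0.5 / 1.0 / 1.5 for
single-copy loss / neutral / single-copy gain. Gaussian emissions use a
dispersion estimated robustly (MAD) from the autosomal ratios. Non-neutral
segments shorter than ``min_cnv_len`` (5 Mb default) are relabelled neutral
rather than reported. Also provides embryo sex inference from the mean chrX
depth ratio, consumed by the phasing model on chrX.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import hmm
from .data import ModelParams, is_chrx

logger = logging.getLogger(__name__)

CNV_STATES = ("loss", "neutral", "gain")
STATE_RATIOS = np.array([0.5, 1.0, 1.5])


@dataclass
class BinnedDepth:
    """Per-bin read counts and autosomal-median-normalised depth ratios.

    ``bins`` columns: chrom, start, end (0-based half-open), count, ratio.
    """

    bins: pd.DataFrame = field(repr=False)
    bin_width: int = 1_000_000

    def autosomal(self) -> pd.DataFrame:
        mask = ~self.bins["chrom"].map(is_chrx)
        return self.bins[mask]

    def chrx(self) -> pd.DataFrame:
        return self.bins[self.bins["chrom"].map(is_chrx)]


@dataclass
class CnvSegmentSet:
    """Sorted, non-overlapping copy-number segments per chromosome.

    ``segments`` columns: chrom, start, end (0-based half-open),
    state in {loss, neutral, gain}, mean_ratio.
    """

    segments: pd.DataFrame = field(repr=False)

    def non_neutral(self) -> pd.DataFrame:
        return self.segments[self.segments["state"] != "neutral"].reset_index(drop=True)

    def to_bed(self, path):
        self.segments.to_csv(path, sep="\t", index=False, header=False,
                             float_format="%.4f",
                             columns=["chrom", "start", "end", "state", "mean_ratio"])


def bin_reads(positions_by_chrom: Mapping[str, np.ndarray],
              chrom_lengths: Mapping[str, int], bin_width: int) -> dict[str, np.ndarray]:
    """Histogram read positions (1-based) into fixed-width bins."""
    out = {}
    for chrom, length in chrom_lengths.items():
        n_bins = int(np.ceil(length / bin_width))
        pos = np.asarray(positions_by_chrom.get(chrom, []), dtype=np.int64)
        out[chrom] = np.bincount((pos - 1) // bin_width, minlength=n_bins)[:n_bins]
    return out


def bin_and_normalize(
    counts_by_chrom: Mapping[str, np.ndarray],
    bin_width: int = 1_000_000,
    chrom_lengths: Mapping[str, int] | None = None,
) -> BinnedDepth:
    """Normalise per-bin counts so the autosomal median ratio is 1.

    ``counts_by_chrom`` maps chromosome -> per-bin read counts (bins of
    ``bin_width`` from the chromosome start; the final bin may be partial if
    ``chrom_lengths`` is given). Raises on zero total reads.
    """
    rows = []
    for chrom, counts in counts_by_chrom.items():
        counts = np.asarray(counts, dtype=np.int64)
        starts = np.arange(len(counts), dtype=np.int64) * bin_width
        ends = starts + bin_width
        if chrom_lengths and chrom in chrom_lengths:
            ends = np.minimum(ends, chrom_lengths[chrom])
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "count": counts}))
    bins = pd.concat(rows, ignore_index=True)
    if bins["count"].sum() == 0:
        raise ValueError("no reads: cannot normalise binned depth")
    auto = bins.loc[~bins["chrom"].map(is_chrx), "count"]
    med = float(np.median(auto if len(auto) else bins["count"]))
    if med <= 0:
        raise ValueError("autosomal median bin count is zero; depth too low for binning")
    bins["ratio"] = bins["count"] / med
    return BinnedDepth(bins=bins, bin_width=bin_width)


def _segments_from_path(chrom, starts, ends, ratios, path) -> list[dict]:
    segs = []
    s = 0
    for i in range(1, len(path) + 1):
        if i == len(path) or path[i] != path[s]:
            segs.append(
                {
                    "chrom": chrom,
                    "start": int(starts[s]),
                    "end": int(ends[i - 1]),
                    "state": CNV_STATES[path[s]],
                    "mean_ratio": float(np.mean(ratios[s:i])),
                }
            )
            s = i
    return segs


def _merge_short(segs: list[dict], min_len: int) -> list[dict]:
    for seg in segs:
        if seg["state"] != "neutral" and seg["end"] - seg["start"] < min_len:
            seg["state"] = "neutral"
    merged: list[dict] = []
    for seg in segs:
        if merged and merged[-1]["state"] == seg["state"]:
            prev = merged[-1]
            w_prev = prev["end"] - prev["start"]
            w_cur = seg["end"] - seg["start"]
            prev["mean_ratio"] = (prev["mean_ratio"] * w_prev + seg["mean_ratio"] * w_cur) / (
                w_prev + w_cur
            )
            prev["end"] = seg["end"]
        else:
            merged.append(dict(seg))
    return merged


def call_cnv(depth: BinnedDepth, params: ModelParams | None = None) -> CnvSegmentSet:
    """Segment normalised bin ratios into loss/neutral/gain segments."""
    params = params or ModelParams()
    auto_ratios = depth.autosomal()["ratio"].to_numpy()
    if len(auto_ratios) == 0:
        auto_ratios = depth.bins["ratio"].to_numpy()
    med = np.median(auto_ratios)
    sigma = 1.4826 * np.median(np.abs(auto_ratios - med))
    sigma = max(float(sigma), params.cnv_min_sigma)

    p = params.cnv_switch_prob
    trans = np.full((3, 3), p)
    np.fill_diagonal(trans, 1.0 - 2.0 * p)

    all_segs = []
    for chrom, grp in depth.bins.groupby("chrom", sort=False):
        ratios = grp["ratio"].to_numpy()
        em = norm.pdf(ratios[:, None], loc=STATE_RATIOS[None, :], scale=sigma)
        em = np.maximum(em, 1e-300)
        path = hmm.viterbi(em, np.broadcast_to(trans, (len(ratios) - 1, 3, 3)))
        segs = _segments_from_path(chrom, grp["start"].to_numpy(), grp["end"].to_numpy(), ratios, path)
        all_segs.extend(_merge_short(segs, params.min_cnv_len))
    return CnvSegmentSet(segments=pd.DataFrame(all_segs))


def infer_sex(depth: BinnedDepth, male_threshold: float = 0.75) -> str | None:
    """Embryo sex from the mean chrX depth ratio; None if chrX absent."""
    x = depth.chrx()["ratio"]
    if len(x) == 0:
        return None
    return "male" if float(x.mean()) < male_threshold else "female"


class EmbryoCnvModel:
    """Copy-number model over one embryo's binned depth."""

    def __init__(self, depth: BinnedDepth, params: ModelParams | None = None):
        self.depth = depth
        self.params = params or ModelParams()

    def fit(self) -> "CnvResults":
        segments = call_cnv(self.depth, self.params)
        return CnvResults(self, segments)


class CnvResults:
    def __init__(self, model: EmbryoCnvModel, segments: CnvSegmentSet):
        self.model = model
        self.segments = segments
        self.sex = infer_sex(model.depth)

    def summary(self) -> pd.DataFrame:
        return self.segments.segments.copy()
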