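"""Accuracy surfaces: high-confidence yield, pass-site concordance,
non-ROC stratification and subtelomeric summaries.

Marginal posteriors are dichotomised by rounding to 0/1 (the 0.5 cut; pass
sites are by construction far from it). Concordance restricts to pass sites
(intersected with a comparator's pass sites when comparing two tracks) and
is reported as the fraction agreeing with the truth or comparator labels;
it is undefined (None) when no site qualifies.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import ModelParams
from .phasing import PhasingTrack

logger = logging.getLogger(__name__)


def dichotomize(marginal: np.ndarray) -> np.ndarray:
    """Round marginal posteriors to binary haplotype labels."""
    return np.asarray(marginal) >= 0.5


def _aligned_labels(track: PhasingTrack, labels: pd.DataFrame) -> np.ndarray:
    merged = track.data.merge(labels, on=["chrom", "pos"], how="left", validate="one_to_one")
    if merged["label"].isna().any():
        n = int(merged["label"].isna().sum())
        raise ValueError(f"{n} track sites missing from the label table (misaligned inputs)")
    return merged["label"].to_numpy(dtype=bool)


def concordance(
    track: PhasingTrack,
    labels: pd.DataFrame,
    mask: np.ndarray | None = None,
    comparator: PhasingTrack | None = None,
) -> dict:
    """Pass-site concordance of one track with truth/comparator labels.

    ``labels`` must hold columns (chrom, pos, label) covering every track
    site. ``mask`` optionally restricts the considered sites (boolean,
    aligned to the track). When ``comparator`` is given, only sites passing
    in both tracks are considered.
    """
    truth = _aligned_labels(track, labels)
    consider = track.passed.copy()
    if comparator is not None:
        if len(comparator.data) != len(track.data) or not np.array_equal(
            comparator.data["pos"].to_numpy(), track.data["pos"].to_numpy()
        ):
            raise ValueError("comparator track sites misaligned with track")
        consider &= comparator.passed
    if mask is not None:
        consider &= np.asarray(mask, dtype=bool)
    n = int(consider.sum())
    if n == 0:
        conc = None
    else:
        conc = float((dichotomize(track.marginal[consider]) == truth[consider]).mean())
    return {
        "embryo": track.embryo,
        "side": track.side,
        "n_considered": n,
        "concordance": conc,
    }


def highconf_proportion(track: PhasingTrack, mask: np.ndarray | None = None) -> float | None:
    """Fraction of considered sites with a high-confidence ("pass") call."""
    passed = track.passed
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() == 0:
            return None
        passed = passed[mask]
    if len(passed) == 0:
        return None
    return float(passed.mean())


def subtelomeric_windows(
    chrom_lengths: dict[str, int],
    acrocentric_centromeres: dict[str, int] | None = None,
    params: ModelParams | None = None,
) -> pd.DataFrame:
    """Subtelomeric windows: within ``subtel_len`` of a telomere, or extending
    ``subtel_len`` into the long arm from an acrocentric centromere.

    Boundaries are closed: a site exactly ``subtel_len`` bp from a telomere
    is inside the window.
    """
    params = params or ModelParams()
    w = params.subtel_len
    acro = acrocentric_centromeres or {}
    rows = []
    for chrom, L in chrom_lengths.items():
        rows.append({"chrom": chrom, "window": "p_ter", "start": 1, "end": min(w, L)})
        rows.append({"chrom": chrom, "window": "q_ter", "start": max(L - w, 1), "end": L})
        if chrom in acro:
            cen = acro[chrom]
            rows.append({"chrom": chrom, "window": "acro_cen", "start": cen, "end": min(cen + w, L)})
    return pd.DataFrame(rows)


def subtelomere_summary(
    track: PhasingTrack,
    chrom_lengths: dict[str, int],
    acrocentric_centromeres: dict[str, int] | None = None,
    params: ModelParams | None = None,
) -> pd.DataFrame:
    """Per-window counts of sites with predictions and, among sites sequenced
    in the embryo (the track's ``embryo_covered`` flag, i.e. >= 1 read), the
    pass proportion."""
    windows = subtelomeric_windows(chrom_lengths, acrocentric_centromeres, params)
    chrom = track.data["chrom"].to_numpy()
    pos = track.data["pos"].to_numpy()
    covered = track.data["embryo_covered"].to_numpy()
    passed = track.passed
    rows = []
    for _, win in windows.iterrows():
        inside = (chrom == win["chrom"]) & (pos >= win["start"]) & (pos <= win["end"])
        seq = inside & covered
        n_seq = int(seq.sum())
        rows.append(
            {
                "embryo": track.embryo,
                "side": track.side,
                "chrom": win["chrom"],
                "window": win["window"],
                "n_sites": int(inside.sum()),
                "n_sequenced": n_seq,
                "prop_pass_sequenced": float(passed[seq].mean()) if n_seq else np.nan,
            }
        )
    return pd.DataFrame(rows)


def reciprocal_overlap(a_start, a_end, b_start, b_end) -> float:
    """Reciprocal overlap of two intervals (min of the two overlap fractions)."""
    ov = min(a_end, b_end) - max(a_start, b_start)
    if ov <= 0:
        return 0.0
    return min(ov / (a_end - a_start), ov / (b_end - b_start))


def evaluate_family(tracks, truth, roc=None, params: ModelParams | None = None) -> pd.DataFrame:
    """Concordance and yield for every track of a simulated family.

    ``truth`` is a :class:`famphase.simulate.TruthSet`; ``roc`` an optional
    :class:`famphase.roc.RocSet` whose intervals define a non-ROC stratum.
    Returns one row per track per stratum.
    """
    rows = []
    for t in tracks:
        labels = truth.labels(t.embryo, t.side)
        strata = {"all": None}
        if roc is not None:
            strata["non-ROC"] = ~roc.flags_for(t.data["chrom"].to_numpy(), t.data["pos"].to_numpy())
        for name, mask in strata.items():
            row = concordance(t, labels, mask=mask)
            row["stratum"] = name
            row["prop_pass"] = highconf_proportion(t, mask=mask)
            rows.append(row)
    return pd.DataFrame(rows)
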