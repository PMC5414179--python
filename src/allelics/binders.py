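"""Allele-preferential binder calling from label-swap DNA-pulldown proteomics.

A pulldown experiment incubates nuclear extract with allele-specific DNA
baits (here: the C and G alleles of a regulatory SNP) and quantifies bound
proteins by isotope-labelled mass spectrometry.  Channel artefacts are
cancelled by performing the experiment twice with the isotope labels
swapped: a genuine allele-preferential binder shows a consistent
allele-oriented log2(C/G) enrichment in both the forward and the reverse
run, while a label artefact flips sign.

The caller mirrors the classic two-panel scatter analysis: per run, log2
ratios are median-centred and proteins beyond the Tukey fences
(Q3 + k*IQR / Q1 - k*IQR, default k = 1.5) are flagged as outliers; a
protein is called C-preferential only if it is an upper outlier (toward C)
in BOTH runs, G-preferential only if a lower outlier in both, and
non-differential otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PulldownRun",
    "compute_log_ratios",
    "normalize_ratios",
    "call_outliers",
    "classify_binders",
    "call_binders",
    "DEFAULT_IQR_K",
]

# outlier fence multiplier: values beyond quartile +/- 1.5 IQR are flagged
DEFAULT_IQR_K = 1.5

ORIENTATIONS = ("forward", "reverse")


@dataclass
class PulldownRun:
    """One label orientation of a pulldown: per-protein allele intensities.

    ``table`` has columns ``protein_id, intensity_c, intensity_g`` (raw,
    non-negative).  ``orientation`` records which physical labelling the run
    used ('forward': heavy channel carried the C bait; 'reverse': swapped);
    intensities are stored already allele-resolved, so downstream arithmetic
    is orientation-agnostic.  ``competitor`` carries the competitor-DNA
    condition as metadata and can be used to partition runs into separate
    analyses.
    """

    run_id: str
    orientation: str
    table: pd.DataFrame
    competitor: str = "poly-dAdT"

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        required = {"protein_id", "intensity_c", "intensity_g"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"run table missing columns: {sorted(missing)}")
        if self.table["protein_id"].duplicated().any():
            raise ValueError("protein ids must be unique within a run")
        ints = self.table[["intensity_c", "intensity_g"]].to_numpy(float)
        if (ints < 0).any() or np.isnan(ints).any():
            raise ValueError("intensities must be non-negative and finite")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_channels(
        cls,
        run_id: str,
        orientation: str,
        protein_ids: Sequence[str],
        intensity_heavy: np.ndarray,
        intensity_light: np.ndarray,
        competitor: str = "poly-dAdT",
    ) -> "PulldownRun":
        """Build a run from physical isotope channels plus orientation.

        In the forward orientation the heavy channel carried the C-allele
        bait; in the reverse orientation the labels were swapped.
        """
        if orientation == "forward":
            c, g = intensity_heavy, intensity_light
        elif orientation == "reverse":
            c, g = intensity_light, intensity_heavy
        else:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        table = pd.DataFrame(
            {"protein_id": list(protein_ids),
             "intensity_c": np.asarray(c, float),
             "intensity_g": np.asarray(g, float)}
        )
        return cls(run_id=run_id, orientation=orientation, table=table,
                   competitor=competitor)


def compute_log_ratios(run: PulldownRun, floor: Optional[float] = None):
    """Allele-oriented log2(C/G) per protein; positive means C preference.

    Zero intensities in one channel are floor-imputed (default: half the
    smallest positive intensity in the run); proteins with zero in both
    channels are dropped.  Returns ``(ratios, dropped)`` where ``ratios`` is
    a Series indexed by protein id and ``dropped`` a DataFrame logging the
    removed proteins.
    """
    tbl = run.table
    c = tbl["intensity_c"].to_numpy(float)
    g = tbl["intensity_g"].to_numpy(float)
    both_zero = (c == 0) & (g == 0)
    dropped = pd.DataFrame(
        {"protein_id": tbl.loc[both_zero, "protein_id"],
         "reason": "zero intensity in both channels"}
    ).reset_index(drop=True)
    c, g = c[~both_zero], g[~both_zero]
    ids = tbl.loc[~both_zero, "protein_id"]
    if floor is None:
        positive = np.concatenate([c[c > 0], g[g > 0]])
        floor = positive.min() / 2.0 if positive.size else 1.0
    ratios = np.log2(np.where(c == 0, floor, c) / np.where(g == 0, floor, g))
    return pd.Series(ratios, index=pd.Index(ids, name="protein_id"), name="log2_c_over_g"), dropped


def normalize_ratios(ratios: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Median-centre log ratios (shift-invariant; output median is 0)."""
    values = np.asarray(ratios, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two ratios to normalize")
    centred = values - np.median(values)
    if isinstance(ratios, pd.Series):
        return pd.Series(centred, index=ratios.index, name=ratios.name)
    return centred


@dataclass(frozen=True)
class Fences:
    q1: float
    q3: float
    iqr: float
    lower: float
    upper: float


def call_outliers(ratios: pd.Series | np.ndarray, k: float = DEFAULT_IQR_K):
    """Flag ratios beyond the Tukey fences Q1 - k*IQR / Q3 + k*IQR.

    Quartiles use linear interpolation of order statistics (position
    (n-1)p + 1); exceedance is strict, so values exactly on a fence (and
    everything, when the IQR collapses to zero) are not flagged.  Returns
    ``(flags, fences)`` with flags in {'upper', 'lower', 'none'}.
    """
    values = np.asarray(ratios, dtype=float)
    if values.size < 4:
        raise ValueError("need at least four ratios to call outliers")
    q1, q3 = np.quantile(values, [0.25, 0.75])  # linear interpolation
    iqr = q3 - q1
    fences = Fences(float(q1), float(q3), float(iqr),
                    float(q1 - k * iqr), float(q3 + k * iqr))
    flags = np.where(values > fences.upper, "upper",
                     np.where(values < fences.lower, "lower", "none"))
    if isinstance(ratios, pd.Series):
        flags = pd.Series(flags, index=ratios.index, name="outlier")
    return flags, fences


def classify_binders(
    fwd_ratios: pd.Series,
    fwd_flags: pd.Series,
    rev_ratios: pd.Series,
    rev_flags: pd.Series,
    fences: Optional[tuple[Fences, Fences]] = None,
) -> pd.DataFrame:
    """Concordance classification over the two label-swap runs.

    A protein is C-preferential iff flagged 'upper' (toward C) in both runs,
    G-preferential iff 'lower' in both, otherwise non-differential.  The
    protein universe is the intersection of the runs; proteins present in
    only one run are appended as non-differential with a 'single-run' note.
    Output is sorted by mean |log2 ratio| descending.
    """
    common = fwd_ratios.index.intersection(rev_ratios.index)
    if len(common) == 0:
        raise ValueError("no overlapping proteins between the two runs")
    fr, rr = fwd_ratios.loc[common], rev_ratios.loc[common]
    ff, rf = fwd_flags.loc[common], rev_flags.loc[common]
    cls = np.where((ff == "upper") & (rf == "upper"), "C-preferential",
                   np.where((ff == "lower") & (rf == "lower"), "G-preferential",
                            "non-differential"))
    out = pd.DataFrame(
        {
            "protein_id": common,
            "log2_ratio_fwd": fr.to_numpy(),
            "log2_ratio_rev": rr.to_numpy(),
            "outlier_fwd": ff.to_numpy(),
            "outlier_rev": rf.to_numpy(),
            "classification": cls,
            "note": "",
        }
    )
    singles = []
    for ratios, flags, col in ((fwd_ratios, fwd_flags, "log2_ratio_fwd"),
                               (rev_ratios, rev_flags, "log2_ratio_rev")):
        only = ratios.index.difference(common)
        for pid in only:
            row = {"protein_id": pid, "log2_ratio_fwd": np.nan,
                   "log2_ratio_rev": np.nan, "outlier_fwd": "none",
                   "outlier_rev": "none", "classification": "non-differential",
                   "note": "single-run"}
            row[col] = float(ratios.loc[pid])
            singles.append(row)
    if singles:
        out = pd.concat([out, pd.DataFrame(singles)], ignore_index=True)
    strength = np.nanmean(
        np.abs(out[["log2_ratio_fwd", "log2_ratio_rev"]].to_numpy(float)), axis=1
    )
    out = out.assign(_strength=strength).sort_values(
        "_strength", ascending=False, kind="mergesort"
    ).drop(columns="_strength").reset_index(drop=True)
    if fences is not None:
        out.attrs["fences_fwd"] = fences[0]
        out.attrs["fences_rev"] = fences[1]
    return out


def call_binders(
    fwd: PulldownRun,
    rev: PulldownRun,
    k: float = DEFAULT_IQR_K,
    normalize: bool = True,
) -> pd.DataFrame:
    """Full pipeline: ratios -> median centring -> IQR outliers -> concordance."""
    if {fwd.orientation, rev.orientation} != set(ORIENTATIONS):
        raise ValueError("need one forward and one reverse run")
    ratios = {}
    flags = {}
    fences = {}
    for run in (fwd, rev):
        r, _ = compute_log_ratios(run)
        if normalize:
            r = normalize_ratios(r)
        f, fen = call_outliers(r, k=k)
        ratios[run.orientation], flags[run.orientation], fences[run.orientation] = r, f, fen
    return classify_binders(
        ratios["forward"], flags["forward"], ratios["reverse"], flags["reverse"],
        fences=(fences["forward"], fences["reverse"]),
    )
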