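"""Relative-quantification qPCR arithmetic and the associated statistics.

All arithmetic assumes perfectly efficient TaqMan-style amplification (one
threshold cycle per doubling of template), so a template amount T maps to
Ct = offset - log2 T and relative quantities are powers of two of Ct
differences:

* ddCt expression:  dCt = Ct(target) - Ct(reference gene);
  ddCt = dCt(condition) - dCt(calibrator);  fold = 2^-ddCt.
* allelic discrimination:  expression ratio C/G = 2^-(Ct_C - Ct_G) on cDNA
  (the reference-gene terms cancel within a sample), with a genomic-DNA
  ratio from the same assay dividing out copy-number imbalance.
* per-allele knockdown: 100 x (1 - fold_treated / fold_scrambled) per
  allele, alleles compared by a two-sided t-test (paired across
  experiments by default).
* ChIP-qPCR: percent input 100 x 2^-(Ct_antibody - Ct_input_adjusted),
  enrichment = percent-input(IP) / percent-input(control antibody).
* reporter assays: firefly/renilla per well, scaled to the empty-vector
  mean, allele contrast by t-test.

Replicate Cts are averaged within a group before differencing; standard
errors are propagated to the fold scale by the delta method
(SE(fold) = ln 2 * fold * SE(ddCt)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ddct_expression",
    "allelic_expression",
    "copy_number_adjust",
    "allelic_knockdown",
    "sirna_specificity_test",
    "chip_enrichment",
    "chip_allelic_test",
    "reporter_activity",
    "paired_ttest",
    "welch_ttest",
]

LN2 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# small statistical helpers (degenerate cases handled explicitly)
# ---------------------------------------------------------------------------

def paired_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test; returns (t, p).

    Zero-variance differences are resolved exactly: all-zero differences
    give p = 1, constant non-zero differences give p -> 0.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 2:
        raise ValueError("paired t-test needs at least two pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return float(np.inf) * np.sign(d.mean()), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def welch_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test; returns (t, p)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("t-test needs at least two replicates per group")
    if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
        if np.allclose(a.mean(), b.mean()):
            return 0.0, 1.0
        return float(np.inf) * np.sign(a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# ddCt expression
# ---------------------------------------------------------------------------

def _group_ct(table: pd.DataFrame, **filters) -> pd.DataFrame:
    sub = table
    for col, val in filters.items():
        if val is None:
            sub = sub[sub[col].isna()]
        else:
            sub = sub[sub[col] == val]
    return sub


def _mean_se(ct: np.ndarray) -> tuple[float, float, int]:
    n = ct.size
    se = float(np.std(ct, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return float(np.mean(ct)), se, n


def ddct_expression(
    table: pd.DataFrame,
    target: str,
    reference_gene: str,
    calibrator_condition: str,
    template: str = "cDNA",
) -> pd.DataFrame:
    """ddCt relative expression per (sample, condition) versus a calibrator.

    The input is a long Ct table (columns sample, target, allele, condition,
    replicate, ct, template).  Replicate Cts are averaged within each
    (sample, target, condition) group before differencing.  Returns one row
    per (sample, condition) with dct, ddct, fold (2^-ddct) and a delta-method
    SEM of the fold.
    """
    tbl = table[table["template"] == template] if "template" in table else table
    out = []
    for sample, sample_tbl in tbl.groupby("sample", sort=False):
        conditions = sample_tbl["condition"].unique().tolist()
        if calibrator_condition not in conditions:
            raise ValueError(
                f"calibrator condition {calibrator_condition!r} missing for sample {sample!r}"
            )
        stats_by_cond = {}
        for condition in conditions:
            t_ct = _group_ct(sample_tbl, target=target, condition=condition)["ct"].to_numpy(float)
            r_ct = _group_ct(sample_tbl, target=reference_gene, condition=condition)["ct"].to_numpy(float)
            if t_ct.size == 0:
                raise ValueError(f"no {target!r} wells for ({sample!r}, {condition!r})")
            if r_ct.size == 0:
                raise ValueError(
                    f"no reference-gene ({reference_gene!r}) wells for ({sample!r}, {condition!r})"
                )
            mt, set_, nt = _mean_se(t_ct)
            mr, ser, nr = _mean_se(r_ct)
            dct = mt - mr
            se_dct = float(np.sqrt(set_**2 + ser**2))
            stats_by_cond[condition] = (dct, se_dct, nt, nr)
        dct_cal, se_cal, _, _ = stats_by_cond[calibrator_condition]
        for condition, (dct, se_dct, nt, nr) in stats_by_cond.items():
            if condition == calibrator_condition:
                ddct, se_ddct = 0.0, se_dct
            else:
                ddct = dct - dct_cal
                se_ddct = float(np.sqrt(se_dct**2 + se_cal**2))
            fold = float(2.0 ** (-ddct))
            out.append(
                dict(sample=sample, condition=condition, target=target,
                     dct=dct, ddct=ddct, fold=fold,
                     fold_sem=LN2 * fold * se_ddct,
                     n_target=nt, n_reference=nr)
            )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# allelic discrimination
# ---------------------------------------------------------------------------

def allelic_expression(
    table: pd.DataFrame,
    allelic_assay_target: str,
    reference_gene: Optional[str] = None,
    template: str = "cDNA",
    alleles: tuple[str, str] = ("C", "G"),
) -> pd.DataFrame:
    """Per-sample (and condition) C/G expression ratio from an allelic assay.

    ratio = 2^-(Ct_C - Ct_G); each allele's reference normalisation cancels
    within a sample, but when a reference gene is supplied its wells are
    required and per-allele reference-normalised levels are reported for
    cross-sample comparability.
    """
    tbl = table[table["template"] == template] if "template" in table else table
    a_c, a_g = alleles
    out = []
    for (sample, condition), grp in tbl.groupby(["sample", "condition"], sort=False):
        ct_c = _group_ct(grp, target=allelic_assay_target, allele=a_c)["ct"].to_numpy(float)
        ct_g = _group_ct(grp, target=allelic_assay_target, allele=a_g)["ct"].to_numpy(float)
        if ct_c.size == 0 or ct_g.size == 0:
            raise ValueError(
                f"allele channel missing for ({sample!r}, {condition!r}): "
                f"need both {a_c!r} and {a_g!r} wells"
            )
        mc, sec, _ = _mean_se(ct_c)
        mg, seg, _ = _mean_se(ct_g)
        row = dict(sample=sample, condition=condition)
        dct = mc - mg
        ratio = float(2.0 ** (-dct))
        row.update(ct_c=mc, ct_g=mg,
                   ratio_c_over_g=ratio,
                   ratio_sem=LN2 * ratio * float(np.sqrt(sec**2 + seg**2)))
        if reference_gene is not None:
            ct_r = _group_ct(grp, target=reference_gene)["ct"].to_numpy(float)
            if ct_r.size == 0:
                raise ValueError(
                    f"reference gene {reference_gene!r} missing for ({sample!r}, {condition!r})"
                )
            mr = float(np.mean(ct_r))
            row.update(level_c=float(2.0 ** (-(mc - mr))),
                       level_g=float(2.0 ** (-(mg - mr))))
        out.append(row)
    return pd.DataFrame(out)


def copy_number_adjust(expression_ratio, genomic_dna_ratio):
    """Divide an allelic expression ratio by the genomic-DNA (copy-number) ratio."""
    e = np.asarray(expression_ratio, dtype=float)
    g = np.asarray(genomic_dna_ratio, dtype=float)
    if (e <= 0).any() or (g <= 0).any():
        raise ValueError("ratios must be positive")
    adjusted = e / g
    if np.ndim(expression_ratio) == 0 and np.ndim(genomic_dna_ratio) == 0:
        return float(adjusted)
    return adjusted


# ---------------------------------------------------------------------------
# allele-specific knockdown
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KnockdownResult:
    """Per-allele knockdown percentages with an allele-contrast t-test."""

    knockdown_c: np.ndarray
    knockdown_g: np.ndarray
    mean_c: float
    mean_g: float
    difference: float
    t_stat: float
    p_value: float
    paired: bool


def allelic_knockdown(
    treated_c: np.ndarray,
    treated_g: np.ndarray,
    scrambled_c: np.ndarray,
    scrambled_g: np.ndarray,
    paired: bool = True,
) -> KnockdownResult:
    """Per-allele knockdown relative to a scrambled-siRNA control.

    Inputs are per-experiment expression levels (linear scale) for each
    allele under the targeting siRNA and the scrambled control; indices pair
    experiments.  knockdown% = 100 x (1 - treated / scrambled), and the two
    alleles' knockdown vectors are compared with a two-sided t-test (paired
    across experiments by default, Welch otherwise).
    """
    tc, tg = np.asarray(treated_c, float), np.asarray(treated_g, float)
    sc, sg = np.asarray(scrambled_c, float), np.asarray(scrambled_g, float)
    if not (tc.shape == tg.shape == sc.shape == sg.shape):
        raise ValueError("all four replicate vectors must have the same length")
    if tc.size < 2:
        raise ValueError("need at least two experiments per allele")
    if (sc <= 0).any() or (sg <= 0).any():
        raise ValueError("scrambled-control expression must be positive")
    kd_c = 100.0 * (1.0 - tc / sc)
    kd_g = 100.0 * (1.0 - tg / sg)
    if paired:
        t, p = paired_ttest(kd_c, kd_g)
    else:
        t, p = welch_ttest(kd_c, kd_g)
    return KnockdownResult(
        knockdown_c=kd_c, knockdown_g=kd_g,
        mean_c=float(kd_c.mean()), mean_g=float(kd_g.mean()),
        difference=float(kd_c.mean() - kd_g.mean()),
        t_stat=t, p_value=p, paired=paired,
    )


# ---------------------------------------------------------------------------
# siRNA specificity
# ---------------------------------------------------------------------------

def sirna_specificity_test(
    hits_target: int, n_target: int, hits_controls: int, n_controls: int
) -> float:
    """Two-sided Fisher's exact p for target-vs-control siRNA hit counts.

    The 2x2 table is [[hits_target, misses_target], [hits_controls,
    misses_controls]]; the two-sided p sums, over all tables with the same
    margins, the probabilities no larger than the observed table's.
    """
    for v in (hits_target, n_target, hits_controls, n_controls):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if hits_target > n_target or hits_controls > n_controls:
        raise ValueError("hits cannot exceed trials")
    table = [[hits_target, n_target - hits_target],
             [hits_controls, n_controls - hits_controls]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# ChIP-qPCR
# ---------------------------------------------------------------------------

def chip_enrichment(
    ip_table: pd.DataFrame,
    control_antibody_table: pd.DataFrame,
    input_table: pd.DataFrame,
    amplicons: Optional[Sequence[str]] = None,
    input_dilution_factor: float = 1.0,
) -> pd.DataFrame:
    """Per-amplicon fold enrichment of the IP over a nonspecific antibody.

    Each table is long-format with columns ``target`` (amplicon), ``replicate``
    and ``ct``; at least two replicates per amplicon are required in the
    antibody tables.  percent input = 100 x 2^-(Ct_antibody - Ct_input_adj)
    with Ct_input_adj = mean Ct_input - log2(dilution factor); enrichment is
    the ratio of the two percent-input values, with a delta-method SD from
    replicate scatter.
    """
    if input_dilution_factor <= 0:
        raise ValueError("input dilution factor must be positive")
    if amplicons is None:
        amplicons = list(pd.unique(ip_table["target"]))
    rows = []
    for amp in amplicons:
        inp = input_table.loc[input_table["target"] == amp, "ct"].to_numpy(float)
        if inp.size == 0:
            raise ValueError(f"no input wells for amplicon {amp!r}")
        ct_in_adj = float(np.mean(inp)) - np.log2(input_dilution_factor)
        se_in = float(np.std(inp, ddof=1) / np.sqrt(inp.size)) if inp.size > 1 else 0.0
        pct = {}
        se = {}
        for name, tbl in (("ip", ip_table), ("control", control_antibody_table)):
            ct = tbl.loc[tbl["target"] == amp, "ct"].to_numpy(float)
            if ct.size < 2:
                raise ValueError(f"need >= 2 {name} replicates for amplicon {amp!r}")
            m, s, _ = _mean_se(ct)
            pct[name] = 100.0 * 2.0 ** (-(m - ct_in_adj))
            se[name] = float(np.sqrt(s**2 + se_in**2))
        enrichment = pct["ip"] / pct["control"]
        sd = LN2 * enrichment * float(np.sqrt(se["ip"] ** 2 + se["control"] ** 2))
        rows.append(
            dict(target=amp, pct_input_ip=pct["ip"], pct_input_control=pct["control"],
                 enrichment=enrichment, enrichment_sd=sd)
        )
    return pd.DataFrame(rows)


def chip_allelic_test(
    c_signals: np.ndarray, g_signals: np.ndarray, paired: bool = True
) -> tuple[float, float, float]:
    """Allelic ChIP contrast: fold = mean(C)/mean(G) plus a two-sided t-test.

    Signals are input-normalised per-replicate allele quantities (equal
    length, paired by experiment).  Returns (fold, t, p).
    """
    c = np.asarray(c_signals, float)
    g = np.asarray(g_signals, float)
    if c.shape != g.shape:
        raise ValueError("C and G signal vectors must have equal length")
    if c.size < 2:
        raise ValueError("need at least two paired replicates")
    fold = float(c.mean() / g.mean())
    if paired:
        t, p = paired_ttest(c, g)
    else:
        t, p = welch_ttest(c, g)
    return fold, t, p


# ---------------------------------------------------------------------------
# reporter assays
# ---------------------------------------------------------------------------

def reporter_activity(
    table: pd.DataFrame,
    empty_construct: str = "empty",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalised luciferase activity per well and allele contrasts.

    ``table`` has one row per well with columns ``construct, orientation,
    allele, firefly, renilla`` (allele/orientation may be missing for the
    empty vector).  Activity = (firefly/renilla) / mean(firefly/renilla of
    the empty vector).  Returns ``(well_table, contrasts)`` where contrasts
    hold the C/G fold and a two-sided Welch t-test per orientation.
    """
    tbl = table.copy()
    ren = tbl["renilla"].to_numpy(float)
    if (ren <= 0).any():
        raise ValueError("renilla activity must be positive in every well")
    tbl["fr"] = tbl["firefly"].to_numpy(float) / ren
    empty = tbl[tbl["construct"] == empty_construct]
    if len(empty) == 0:
        raise ValueError(f"no wells for the empty vector ({empty_construct!r})")
    scale = empty["fr"].mean()
    tbl["activity"] = tbl["fr"] / scale
    contrasts = []
    non_empty = tbl[tbl["construct"] != empty_construct]
    for orientation, grp in non_empty.groupby("orientation", sort=False, dropna=True):
        c = grp.loc[grp["allele"] == "C", "activity"].to_numpy(float)
        g = grp.loc[grp["allele"] == "G", "activity"].to_numpy(float)
        if c.size == 0 or g.size == 0:
            continue
        t, p = welch_ttest(c, g)
        contrasts.append(
            dict(orientation=orientation, mean_c=float(c.mean()), mean_g=float(g.mean()),
                 fold_c_over_g=float(c.mean() / g.mean()), t_stat=t, p_value=p,
                 n_c=int(c.size), n_g=int(g.size))
        )
    return tbl.drop(columns="fr"), pd.DataFrame(contrasts)
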