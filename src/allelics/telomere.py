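"""Relative telomere length from telomere-repeat vs single-copy-gene qPCR.

Average telomere length is proportional to the ratio of telomere-repeat
qPCR signal (T) to that of a single-copy gene (S, e.g. RPLP0) in the same
genomic DNA sample.  Under perfectly efficient amplification,

    T/S = 2^-(Ct_T - Ct_S),

and relative length is the sample's T/S divided by the T/S of a calibrator
condition (e.g. the scrambled-siRNA control in a knockdown time course);
the calibrator's own relative length is exactly 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .qpcr import LN2, _group_ct, _mean_se

__all__ = ["ts_ratio"]


def ts_ratio(
    table: pd.DataFrame,
    calibrator_condition: str,
    tel_target: str = "TEL",
    scg_target: str = "SCG",
) -> pd.DataFrame:
    """Per (sample, condition) T/S ratio and relative telomere length.

    ``table`` is the long Ct format (sample, target, condition, replicate,
    ct); both the telomere and single-copy-gene targets must be measured in
    every (sample, condition), and the calibrator condition must be present
    for every sample.  Replicate Cts are averaged before differencing; the
    SEM of the relative length is propagated by the delta method.
    """
    out = []
    for sample, sample_tbl in table.groupby("sample", sort=False):
        conditions = sample_tbl["condition"].unique().tolist()
        if calibrator_condition not in conditions:
            raise ValueError(
                f"calibrator condition {calibrator_condition!r} missing for sample {sample!r}"
            )
        per_cond = {}
        for condition in conditions:
            t_ct = _group_ct(sample_tbl, target=tel_target, condition=condition)["ct"].to_numpy(float)
            s_ct = _group_ct(sample_tbl, target=scg_target, condition=condition)["ct"].to_numpy(float)
            if t_ct.size == 0:
                raise ValueError(f"no telomere ({tel_target!r}) wells for ({sample!r}, {condition!r})")
            if s_ct.size == 0:
                raise ValueError(f"no single-copy-gene ({scg_target!r}) wells for ({sample!r}, {condition!r})")
            mt, se_t, _ = _mean_se(t_ct)
            ms, se_s, _ = _mean_se(s_ct)
            dct = mt - ms
            per_cond[condition] = (float(2.0 ** (-dct)), float(np.sqrt(se_t**2 + se_s**2)))
        ts_cal, se_cal = per_cond[calibrator_condition]
        for condition, (ts, se_dct) in per_cond.items():
            if condition == calibrator_condition:
                rel, se_rel_dct = 1.0, se_dct
            else:
                rel = ts / ts_cal
                se_rel_dct = float(np.sqrt(se_dct**2 + se_cal**2))
            out.append(
                dict(sample=sample, condition=condition, ts_ratio=ts,
                     relative_length=rel, relative_length_sem=LN2 * rel * se_rel_dct)
            )
    return pd.DataFrame(out)
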