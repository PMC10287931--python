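"""Reporter and qPCR quantification arithmetic.

Dual-luciferase reporters: the firefly/Renilla ratio of a test reporter is
normalized to the matched control reporter — the CAA sense-codon reporter
for stop-codon readthrough (UAA/UAG/UGA), the frame-0 reporter for the -1
and +1 programmed-frameshift constructs — and expressed as a percentage.
Normalization is per replicate, then summarized as mean +/- sem.

qPCR: primer amplification factors come from a dilution-series slope
(efficiency% = (10^(-1/slope) - 1) * 100); relative amounts use the
efficiency-corrected delta-delta-Ct form against a constant spike-in,
E_target^(-Cq_target) / E_spike^(-Cq_spike), which reduces to 2^(-ddCt)
when both factors are 2.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

STOP_REPORTERS = ("UAA", "UAG", "UGA")
FRAMESHIFT_REPORTERS = ("fs_minus1", "fs_plus1")


def primer_efficiency(slope: float) -> tuple[float, float]:
    """(efficiency %, amplification factor) from a log10-dilution slope.

    A perfect doubling assay has slope -1/log10(2) ~ -3.3219 -> 100%, 2.0.
    """
    if slope >= 0:
        raise ValueError("dilution-series slope must be negative")
    factor = 10.0 ** (-1.0 / slope)
    return (factor - 1.0) * 100.0, factor


def relative_amount(
    cq_target: float,
    cq_spike: float,
    eff_target: float,
    eff_spike: float,
) -> float:
    """Efficiency-corrected relative amount against the spike-in control."""
    if not (eff_target > 1.0 and eff_spike > 1.0):
        raise ValueError("amplification factors must exceed 1")
    return eff_target ** (-cq_target) / eff_spike ** (-cq_spike)


def fraction_distribution(amounts: Sequence[float]) -> np.ndarray:
    """Percent of total per fraction; requires at least one positive amount."""
    arr = np.asarray(amounts, dtype=float)
    total = np.nansum(arr)
    if not total > 0:
        raise ValueError("all-zero fraction amounts")
    return np.where(np.isnan(arr), np.nan, arr) / total * 100.0


def qpcr_fraction_table(cq_table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene % RNA per fraction from a Cq table.

    Expects columns target, fraction, cq, spike_cq, efficiency,
    spike_efficiency; a ``replicate`` column, if present, is summarized as
    mean +/- sem per fraction.
    """
    rows = []
    group_cols = ["target"] + (["replicate"] if "replicate" in cq_table.columns else [])
    for keys, block in cq_table.groupby(group_cols, sort=True):
        amounts = [
            0.0
            if np.isnan(r.cq)
            else relative_amount(r.cq, r.spike_cq, r.efficiency, r.spike_efficiency)
            for r in block.itertuples(index=False)
        ]
        pct = fraction_distribution(amounts)
        keys = keys if isinstance(keys, tuple) else (keys,)
        for frac, p in zip(block["fraction"], pct):
            rows.append((*keys, frac, p))
    out = pd.DataFrame(rows, columns=group_cols + ["fraction", "percent"])
    if "replicate" in out.columns:
        summary = (
            out.groupby(["target", "fraction"], sort=True)["percent"]
            .agg(mean="mean", sem=lambda x: x.sem() if len(x) > 1 else 0.0, n="count")
            .reset_index()
        )
        return summary
    return out


def _ratio_table(dlr: pd.DataFrame) -> pd.DataFrame:
    if (dlr["rluc"] <= 0).any():
        raise ValueError("rluc must be > 0 for usable measurements")
    out = dlr.copy()
    out["ratio"] = out["fluc"] / out["rluc"]
    return out


def _normalized_percent(
    dlr: pd.DataFrame,
    test_reporters: Sequence[str],
    control_reporter: str,
    paired: bool = True,
) -> pd.DataFrame:
    """Per-replicate 100 * test/control Fluc/Rluc ratios, then mean/sem.

    ``paired`` matches each test replicate to the control measurement of the
    same replicate id; unpaired divides by the pooled mean control ratio.
    """
    ratios = _ratio_table(dlr)
    rows = []
    for (strain, condition), block in ratios.groupby(["strain", "condition"], sort=True):
        control = block[block["reporter"] == control_reporter]
        if len(control) == 0 or (control["ratio"] == 0).any():
            raise ValueError(f"missing or zero {control_reporter} control for {strain}/{condition}")
        pooled_control = control["ratio"].mean()
        for reporter in test_reporters:
            test = block[block["reporter"] == reporter]
            if len(test) == 0:
                continue
            if paired:
                ctrl_by_rep = control.set_index("replicate")["ratio"]
                pct = [
                    100.0 * r.ratio / ctrl_by_rep[r.replicate]
                    for r in test.itertuples(index=False)
                ]
            else:
                pct = list(100.0 * test["ratio"] / pooled_control)
            pct = pd.Series(pct, dtype=float)
            rows.append(
                (
                    strain,
                    condition,
                    reporter,
                    float(pct.mean()),
                    float(pct.sem()) if len(pct) > 1 else 0.0,
                    len(pct),
                )
            )
    return pd.DataFrame(rows, columns=["strain", "condition", "reporter", "percent", "sem", "n"])


def readthrough_percent(dlr: pd.DataFrame, paired: bool = True) -> pd.DataFrame:
    """%readthrough of each stop-codon reporter, normalized to CAA."""
    return _normalized_percent(dlr, STOP_REPORTERS, "CAA", paired)


def frameshift_percent(dlr: pd.DataFrame, paired: bool = True) -> pd.DataFrame:
    """%frameshift of the -1/+1 reporters, normalized to the frame-0 reporter."""
    return _normalized_percent(dlr, FRAMESHIFT_REPORTERS, "frame0", paired)


def anova_two_way(
    df: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
) -> pd.DataFrame:
    """Convenience two-way ANOVA with interaction (delegated to statsmodels)."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    model = ols(f"{response} ~ C({factor_a}) * C({factor_b})", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)


def tukey_posthoc(df: pd.DataFrame, response: str, group: str):
    """Tukey HSD pairwise comparisons (delegated to statsmodels)."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    return pairwise_tukeyhsd(df[response], df[group])
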