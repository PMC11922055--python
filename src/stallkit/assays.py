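"""Closed-form assay computations.

Sanger trace misincorporation percentage, periodate-protection qPCR charged
fraction (ΔΔCt), 2^-ΔΔCt relative expression, Pearson chi-square and Fisher
exact breeding-ratio statistics, and densitometry normalization.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def sanger_percent_misinc(treated: pd.DataFrame, control: pd.DataFrame,
                          position: int) -> float:
    """Net percent misincorporation at a Sanger trace position.

    Per trace, raw = 100 * T / (C + T) on peak heights; the water-control
    raw value is subtracted and the result clamped at 0 (background can
    exceed signal by chance).
    """

    def raw(tbl: pd.DataFrame) -> float:
        at = tbl[tbl["position"] == position]
        heights = {b: float(at[at["base"] == b]["height"].sum()) for b in ("C", "T")}
        denom = heights["C"] + heights["T"]
        if denom <= 0:
            raise ValueError(f"no C/T peaks at position {position}")
        return 100.0 * heights["T"] / denom

    return max(0.0, raw(treated) - raw(control))


def charged_fraction(ct: pd.DataFrame, target: str, spike_target: str) -> float:
    """Charged tRNA fraction from periodate-protection qPCR.

    ΔΔCt = (mean Ct_target - mean Ct_spike) in the oxidized reaction minus
    the same difference in the control reaction; the charged fraction is
    2^-ΔΔCt (replicate means per target and treatment).  Values above 1 are
    reported with a warning, not capped.
    """
    means = {}
    for treatment in ("oxidized", "control"):
        for t in (target, spike_target):
            sub = ct[(ct["target"] == t) & (ct["treatment"] == treatment)]
            if sub.empty:
                raise ValueError(f"missing Ct values for {t} under {treatment}")
            means[(t, treatment)] = float(sub["ct"].mean())
    ddct = (means[(target, "oxidized")] - means[(spike_target, "oxidized")]) - (
        means[(target, "control")] - means[(spike_target, "control")]
    )
    frac = 2.0 ** (-ddct)
    if frac > 1:
        warnings.warn(f"charged fraction {frac:.3f} exceeds 1 (Ct noise)", stacklevel=2)
    return frac


def ddct_expression(ct: pd.DataFrame, target: str,
                    reference_gene: str | None,
                    calibrator_sample: str) -> pd.Series:
    """Relative expression per sample by 2^-ΔΔCt, normalized so the
    calibrator sample maps to 1.

    With a reference gene, ΔCt = Ct_target - Ct_reference per sample and
    ΔΔCt is taken against the calibrator's ΔCt; without one, ΔΔCt is simply
    Ct_sample - Ct_calibrator for the target.
    """
    sub = ct[ct["target"] == target]
    ct_t = sub.groupby("sample")["ct"].mean()
    if calibrator_sample not in ct_t.index:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not found")
    if reference_gene is not None:
        ref = ct[ct["target"] == reference_gene].groupby("sample")["ct"].mean()
        dct = ct_t - ref.reindex(ct_t.index)
    else:
        dct = ct_t
    ddct = dct - dct[calibrator_sample]
    return (2.0 ** (-ddct)).rename("relative_abundance")


def mendelian_test(observed: pd.Series | dict, expected: pd.Series | dict) -> dict:
    """Pearson chi-square goodness of fit of genotype counts against expected
    proportions (df = categories - 1)."""
    obs = pd.Series(observed, dtype=float)
    exp = pd.Series(expected, dtype=float).reindex(obs.index)
    if exp.isna().any():
        raise ValueError("expected proportions missing for some categories")
    if not np.isclose(exp.sum(), 1.0):
        raise ValueError("expected proportions must sum to 1")
    total = obs.sum()
    if total <= 0:
        raise ValueError("total count must be > 0")
    if ((exp == 0) & (obs > 0)).any():
        raise ValueError("nonzero count in a category with zero expected probability")
    keep = exp > 0
    chi2, p = stats.chisquare(obs[keep], f_exp=exp[keep] * total)
    return {"chi2": float(chi2), "df": int(keep.sum() - 1), "p": float(p)}


def genotype_counts_by_locus(tbl: pd.DataFrame, locus: str) -> pd.Series:
    """Marginal genotype counts (+/+, +/-, -/-) for one locus of a
    GenotypeTable."""
    return tbl.groupby(locus)["count"].sum().reindex(["+/+", "+/-", "-/-"], fill_value=0)


def compare_proportions(tbl: pd.DataFrame) -> dict:
    """Thumpd1-/- proportion in Gcn2-/- offspring versus offspring carrying
    a functional Gcn2 allele, with a two-sided Fisher exact test on the
    collapsed 2x2 table (-/- vs not).  The full 3x3 table is returned too."""
    functional = tbl[tbl["gcn2"].isin(["+/+", "+/-"])]
    ko = tbl[tbl["gcn2"] == "-/-"]
    n_func = functional["count"].sum()
    n_ko = ko["count"].sum()
    if n_func == 0 or n_ko == 0:
        raise ValueError("both Gcn2 strata must be nonempty")
    ko_func = functional.loc[functional["thumpd1"] == "-/-", "count"].sum()
    ko_ko = ko.loc[ko["thumpd1"] == "-/-", "count"].sum()
    table22 = np.array([[ko_func, n_func - ko_func], [ko_ko, n_ko - ko_ko]])
    _, p = stats.fisher_exact(table22, alternative="two-sided")
    full = tbl.pivot_table(index="thumpd1", columns="gcn2", values="count",
                           aggfunc="sum", fill_value=0)
    return {
        "proportion_gcn2_functional": ko_func / n_func,
        "proportion_gcn2_ko": ko_ko / n_ko,
        "p_fisher": float(p),
        "table_2x2": table22,
        "table_3x3": full,
    }


def densitometry_normalize(signal: float, loading: float) -> float:
    """Loading-control normalization of a densitometry value:
    100 * signal / loading."""
    if loading <= 0:
        raise ValueError("loading control must be > 0")
    if signal < 0:
        raise ValueError("signal must be >= 0")
    return 100.0 * signal / loading
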