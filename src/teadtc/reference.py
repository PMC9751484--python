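"""Published reference measurements bundled for worked examples and validation.

A published greenhouse drought–rehydration study of ten tea cultivars reports,
per cultivar and sampling occasion (drought days 1, 5, 9, 13, 17; rehydration
days 4, 8), the mean of three technical replicates of malondialdehyde (MDA,
nmol/g), soluble sugar (SS, mg/g) and total polyphenol (TP, mg/g), together
with the per-cultivar counts of individual samples lying beyond the overall
composite-score references among 280 individuals.  The per-sample raw data are
not deposited; these per-cell summaries are the densest obtainable subset and
drive the package's worked-arithmetic checks.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = [
    "VARIETIES",
    "STAGES",
    "physiology_stage_means",
    "dtc_proportion_counts",
    "REPORTED_INFO_CONTENT",
    "REPORTED_SHARES_PCT",
    "REPORTED_DTC_MEAN",
    "REPORTED_DTC_MEDIAN",
    "REPORTED_TOLERANCE_ORDER",
]

VARIETIES = ["SCZ", "ZC108", "MS9", "QN1", "QN21", "QN36", "QN38", "JGY", "JX", "XY10"]
STAGES = ["d1", "d5", "d9", "d13", "d17", "r4", "r8"]

# indicator, variety, then one column per occasion (means of 3 replicates)
_MEANS_CSV = """\
indicator,variety,d1,d5,d9,d13,d17,r4,r8
mda,SCZ,8.23,12.52,11.51,18.93,17.98,11.69,8.99
mda,ZC108,8.54,11.45,11.38,15.03,17.13,13.18,8.48
mda,MS9,8.97,11.56,11.92,12.56,16.56,11.94,10.16
mda,QN1,8.83,8.61,11.87,13.53,17.09,10.83,10.21
mda,QN21,9.44,10.07,10.98,15.25,16.64,13.43,9.82
mda,QN36,8.58,9.26,10.72,13.72,16.97,10.65,10.41
mda,QN38,7.77,9.31,9.59,15.33,18.07,12.62,11.54
mda,JGY,10.65,8.98,12.24,14.77,15.40,14.49,13.51
mda,JX,9.07,9.83,13.95,19.18,14.74,13.14,12.01
mda,XY10,8.50,15.87,10.11,13.72,13.22,11.83,11.79
ss,SCZ,17.21,10.32,12.58,21.02,35.12,24.07,15.76
ss,ZC108,17.81,14.77,24.59,28.99,29.60,22.38,20.34
ss,MS9,18.51,21.534,23.95,35.93,29.01,28.79,23.76
ss,QN1,16.54,25.68,25.07,32.11,28.63,22.73,24.97
ss,QN21,18.11,22.47,18.43,36.58,29.92,22.38,21.04
ss,QN36,14.85,23.91,21.66,32.99,32.99,25.29,21.36
ss,QN38,13.44,25.38,16.86,31.70,35.20,21.04,23.39
ss,JGY,10.96,18.45,18.08,33.04,34.61,17.21,16.41
ss,JX,11.28,19.81,18.98,30.84,38.11,19.58,14.91
ss,XY10,8.27,23.784,22.08,32.94,40.51,19.47,21.74
tp,SCZ,5.48,4.94,4.14,3.99,3.86,4.69,6.59
tp,ZC108,7.95,7.02,5.07,3.42,2.15,6.23,6.58
tp,MS9,5.13,4.04,2.12,3.34,2.62,6.44,7.37
tp,QN1,4.13,1.96,5.81,3.86,5.01,4.31,6.81
tp,QN21,6.25,3.69,2.08,3.38,2.75,3.92,4.57
tp,QN36,6.18,5.01,4.76,4.69,4.12,4.78,7.59
tp,QN38,6.95,4.35,2.94,2.53,3.06,3.95,4.13
tp,JGY,8.57,8.09,4.79,3.51,2.83,5.72,5.37
tp,JX,3.76,5.11,4.97,2.96,2.22,4.67,6.11
tp,XY10,5.91,4.85,4.44,4.01,3.91,5.59,6.89
"""

# per-cultivar counts of samples beyond the overall composite-score references
# (mean 0.4487, median 0.4344) among 280 tested individuals
_PROPORTIONS_CSV = """\
variety,n_vs_mean,n_vs_median
SCZ,18,18
ZC108,19,17
MS9,12,11
QN1,14,12
QN21,9,8
QN36,19,18
QN38,13,9
JGY,17,16
JX,18,16
XY10,16,15
"""

#: Reported replicate-level CRITIC information contents (MDA, SS, TP) and weight shares (%).
REPORTED_INFO_CONTENT = {"mda": 0.21, "ss": 0.209, "tp": 0.227}
REPORTED_SHARES_PCT = {"mda": 32.57, "ss": 32.32, "tp": 35.11}
REPORTED_DTC_MEAN = 0.4487
REPORTED_DTC_MEDIAN = 0.4344
#: Reported comprehensive drought tolerance, strongest first.
REPORTED_TOLERANCE_ORDER = [
    "QN36", "SCZ", "ZC108", "JX", "JGY", "XY10", "QN1", "MS9", "QN38", "QN21",
]


def physiology_stage_means(long: bool = False) -> pd.DataFrame:
    """The published per-(cultivar, occasion) indicator means.

    Wide form (default): one row per (indicator, variety), occasion columns.
    Long form: columns (variety, stage, mda, ss, tp), one row per cell — the
    same schema a per-sample physiology table uses, with cell means as values.
    """
    wide = pd.read_csv(io.StringIO(_MEANS_CSV))
    if not long:
        return wide
    melted = wide.melt(
        id_vars=["indicator", "variety"], var_name="stage", value_name="value"
    )
    out = melted.pivot_table(
        index=["variety", "stage"], columns="indicator", values="value"
    ).reset_index()
    out.columns.name = None
    # preserve experiment ordering
    out["variety"] = pd.Categorical(out["variety"], VARIETIES, ordered=True)
    out["stage"] = pd.Categorical(out["stage"], STAGES, ordered=True)
    return out.sort_values(["variety", "stage"]).reset_index(drop=True)


def dtc_proportion_counts() -> pd.DataFrame:
    """Published per-cultivar counts beyond the overall DTC mean/median (n=280)."""
    return pd.read_csv(io.StringIO(_PROPORTIONS_CSV))
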