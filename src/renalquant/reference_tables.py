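"""Published cohort summary statistics for multi-parametric renal MRI.

These tables are the group-level summary values reported by a two-observer
reproducibility study of renal MRI in healthy volunteers (HV), patients with
heart failure (HF) and renal transplant recipients (Tx): per-group means and
between-subject SDs for kidney volume and for T1, pCASL perfusion and ADC in
six regions of interest, the mean within-ROI SD per sequence, and the
reported interobserver CoV/ICC.  They serve two purposes here:

* worked-example inputs — ratio, group-difference and SD-fraction arithmetic
  can be recomputed from them and checked against the study's printed values;
* generator conditions — the synthetic cohort draws each subject's tissue
  parameters and kidney size from these group distributions.

Values are stored exactly as printed (units: T1 ms, pCASL ml/min/100 g,
ADC 1e-6 mm^2/s, volume ml).
"""

from __future__ import annotations

import pandas as pd

GROUPS = ("All", "HV", "HF", "Tx")

#: number of participants per group (All, HV, HF, Tx)
GROUP_N = {"All": 40, "HV": 10, "HF": 10, "Tx": 20}

ROI_ORDER = ("WK", "Cx", "repCx", "supCx", "infCx", "Med")

SEQUENCE_UNITS = {
    "T1": "ms",
    "pCASL": "ml/100 g/min",
    "ADC": "1e-6 mm^2/s",
    "volume": "ml",
}

# (sequence, roi) -> {group: (mean, sd)}
_GROUP_STATS = {
    ("volume", "alternate"): {
        "All": (195.8, 56.8), "HV": (147.8, 30.9), "HF": (170.6, 45.3), "Tx": (230.1, 49.2)},
    ("volume", "every"): {
        "All": (197.5, 57.4), "HV": (149.0, 31.3), "HF": (170.8, 44.9), "Tx": (232.6, 49.3)},
    ("T1", "WK"): {
        "All": (1772.8, 131.4), "HV": (1702.4, 76.7), "HF": (1696.5, 85.7), "Tx": (1842.6, 134.4)},
    ("T1", "Cx"): {
        "All": (1630.2, 102.0), "HV": (1557.7, 104.1), "HF": (1595.5, 80.1), "Tx": (1680.1, 86.3)},
    ("T1", "repCx"): {
        "All": (1606.1, 114.4), "HV": (1545.4, 113.2), "HF": (1543.8, 71.1), "Tx": (1664.6, 105.0)},
    ("T1", "supCx"): {
        "All": (1655.6, 119.5), "HV": (1606.8, 149.8), "HF": (1600.0, 93.4), "Tx": (1705.3, 98.1)},
    ("T1", "infCx"): {
        "All": (1639.0, 103.7), "HV": (1587.0, 94.3), "HF": (1590.0, 113.3), "Tx": (1687.0, 82.0)},
    ("T1", "Med"): {
        "All": (1975.8, 74.9), "HV": (1899.0, 80.5), "HF": (1940.2, 71.3), "Tx": (2028.1, 74.2)},
    ("pCASL", "WK"): {
        "All": (181.7, 56.6), "HV": (187.5, 58.4), "HF": (161.6, 47.1), "Tx": (190.2, 60.7)},
    ("pCASL", "Cx"): {
        "All": (221.0, 80.0), "HV": (235.1, 79.3), "HF": (175.7, 59.5), "Tx": (239.3, 84.3)},
    ("pCASL", "repCx"): {
        "All": (260.8, 91.4), "HV": (271.8, 93.5), "HF": (228.4, 92.3), "Tx": (273.3, 90.4)},
    ("pCASL", "supCx"): {
        "All": (196.4, 75.9), "HV": (230.5, 77.9), "HF": (160.4, 54.2), "Tx": (197.4, 79.6)},
    ("pCASL", "infCx"): {
        "All": (225.2, 105.2), "HV": (213.8, 91.1), "HF": (161.8, 84.4), "Tx": (269.2, 107.5)},
    ("pCASL", "Med"): {
        "All": (95.8, 41.8), "HV": (108.8, 45.1), "HF": (121.5, 31.5), "Tx": (73.0, 45.9)},
    # ADC was not acquired in the HF cohort
    ("ADC", "WK"): {
        "All": (1687.6, 115.6), "HV": (1687.2, 97.4), "Tx": (1687.7, 125.8)},
    ("ADC", "Cx"): {
        "All": (1678.1, 111.4), "HV": (1704.0, 96.8), "Tx": (1665.8, 118.1)},
    ("ADC", "repCx"): {
        "All": (1696.9, 117.7), "HV": (1719.9, 158.6), "Tx": (1686.0, 96.1)},
    ("ADC", "supCx"): {
        "All": (1686.3, 144.2), "HV": (1720.4, 120.6), "Tx": (1670.1, 154.5)},
    ("ADC", "infCx"): {
        "All": (1696.4, 115.2), "HV": (1700.5, 111.8), "Tx": (1694.4, 119.7)},
    ("ADC", "Med"): {
        "All": (1671.9, 82.5), "HV": (1726.3, 93.9), "Tx": (1646.1, 77.2)},
}

# cortex:medulla ratios as printed, per group
REPORTED_RATIOS = {
    "T1": {"All": 0.83, "HV": 0.82, "HF": 0.82, "Tx": 0.83},
    "pCASL": {"All": 2.3, "HV": 2.2, "HF": 1.4, "Tx": 3.3},
    "ADC": {"All": 1.0, "HV": 1.0, "Tx": 1.0},
}

# sequence -> roi -> (mean within-ROI SD, SD as % of the cohort mean value)
_WITHIN_ROI_SD = {
    "T1": {
        "WK": (354.1, 20.0), "Cx": (125.7, 7.7), "repCx": (49.6, 3.1),
        "supCx": (71.4, 4.3), "infCx": (69.8, 4.3), "Med": (74.9, 3.8)},
    "pCASL": {
        "WK": (100.7, 55.4), "Cx": (85.1, 38.5), "repCx": (41.2, 15.8),
        "supCx": (48.0, 24.5), "infCx": (53.2, 23.6), "Med": (41.8, 43.6)},
    "ADC": {
        "WK": (289.5, 17.2), "Cx": (169.6, 10.1), "repCx": (71.5, 4.2),
        "supCx": (105.8, 6.3), "infCx": (85.9, 5.1), "Med": (84.7, 5.1)},
}

# sequence -> roi (or volumetry mode) -> (interobserver CoV %, ICC(2,k))
_REPORTED_REPRO = {
    "volume": {"alternate": (6.5, 0.97), "every": (6.7, 0.96)},
    "T1": {
        "WK": (1.0, 0.97), "Cx": (1.2, 0.97), "repCx": (2.0, 0.95),
        "supCx": (3.2, 0.96), "infCx": (2.5, 0.86), "Med": (2.6, 0.87)},
    "pCASL": {
        "WK": (7.0, 0.90), "Cx": (10.3, 0.93), "repCx": (14.2, 0.86),
        "supCx": (19.1, 0.69), "infCx": (14.6, 0.92), "Med": (29.6, 0.73)},
    "ADC": {
        "WK": (2.0, 0.90), "Cx": (2.6, 0.85), "repCx": (3.7, 0.76),
        "supCx": (5.0, 0.64), "infCx": (3.8, 0.62), "Med": (5.5, 0.50)},
}


def group_summary() -> pd.DataFrame:
    """Tidy per-group summary: sequence, roi, group, mean, sd, units."""
    rows = []
    for (sequence, roi), per_group in _GROUP_STATS.items():
        for group, (mean, sd) in per_group.items():
            rows.append({
                "sequence": sequence, "roi": roi, "group": group,
                "mean": mean, "sd": sd, "units": SEQUENCE_UNITS[sequence],
            })
    return pd.DataFrame(rows)


def group_mean(sequence: str, roi: str, group: str) -> float:
    return _GROUP_STATS[(sequence, roi)][group][0]


def group_sd(sequence: str, roi: str, group: str) -> float:
    return _GROUP_STATS[(sequence, roi)][group][1]


def within_roi_sd() -> pd.DataFrame:
    """Mean within-ROI SD and its printed percentage of the cohort mean."""
    rows = []
    for sequence, per_roi in _WITHIN_ROI_SD.items():
        for roi, (sd_mean, pct) in per_roi.items():
            rows.append({
                "sequence": sequence, "roi": roi,
                "roi_sd_mean": sd_mean, "roi_sd_pct_of_mean": pct,
                "units": SEQUENCE_UNITS[sequence],
            })
    return pd.DataFrame(rows)


def reported_reproducibility() -> pd.DataFrame:
    """Reported interobserver CoV (%) and ICC by sequence and ROI."""
    rows = []
    for sequence, per_roi in _REPORTED_REPRO.items():
        for roi, (cov, icc) in per_roi.items():
            rows.append({"sequence": sequence, "roi": roi,
                         "cov_percent": cov, "icc": icc})
    return pd.DataFrame(rows)
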