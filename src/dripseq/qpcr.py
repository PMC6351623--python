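"""Efficiency-corrected relative qPCR quantification (Pfaffl method).

The amplification efficiency of each primer set is derived from the
slope of its standard curve, E = 10^(-1/slope) (a perfect doubling per
cycle gives E = 2 at slope ~ -3.32). The relative expression ratio of a
target transcript in a sample versus a control condition, normalized to
a reference gene, is

    ratio = E_target^dCt_target / E_ref^dCt_ref

with dCt = Ct(control) - Ct(sample) for each assay. With both
efficiencies equal to 2 this reduces to the familiar 2^-ddCt form.
Technical replicates are averaged on the Ct scale before dCt; each
biological replicate yields its own ratio, and groups of per-replicate
ratios are compared with a two-sided two-sample t test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class QpcrAssay:
    """One primer set: its standard-curve slope and per-sample Ct values.

    ``ct`` maps sample name to a list of technical-replicate Ct values.
    ``primer_type`` distinguishes primer sets amplifying the spliced
    junction from those amplifying the unspliced (intron-containing)
    transcript.
    """

    target: str
    slope: float
    ct: dict[str, list[float]] = field(default_factory=dict)
    primer_type: str = "spliced"  # or 'unspliced'

    @property
    def efficiency(self) -> float:
        return efficiency_from_slope(self.slope)

    def mean_ct(self, sample: str) -> float:
        values = self.ct[sample]
        if any(v <= 0 for v in values):
            raise ValueError(f"non-positive Ct for sample {sample!r}")
        return float(np.mean(values))


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency E = 10^(-1/slope); requires slope < 0."""
    if slope >= 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope}")
    return float(10.0 ** (-1.0 / slope))


def pfaffl_ratio(
    e_target: float, dct_target: float, e_ref: float, dct_ref: float
) -> float:
    """Relative expression ratio E_target^dCt_target / E_ref^dCt_ref.

    dCt is Ct(control) - Ct(sample) for the respective assay.
    """
    for e in (e_target, e_ref):
        if not (1.0 < e <= 10.0):
            raise ValueError(f"efficiency {e} outside (1, 10]")
    return float(e_target**dct_target / e_ref**dct_ref)


def sample_ratios(
    target: QpcrAssay,
    reference: QpcrAssay,
    control_sample: str,
    samples: list[str],
) -> pd.Series:
    """Pfaffl ratio of each sample versus the control sample.

    Technical replicates are averaged per sample before the dCt.
    """
    e_t = target.efficiency
    e_r = reference.efficiency
    ct_t0 = target.mean_ct(control_sample)
    ct_r0 = reference.mean_ct(control_sample)
    out = {}
    for s in samples:
        dct_t = ct_t0 - target.mean_ct(s)
        dct_r = ct_r0 - reference.mean_ct(s)
        out[s] = pfaffl_ratio(e_t, dct_t, e_r, dct_r)
    return pd.Series(out, name=target.target)


def group_compare(group_a: list[float], group_b: list[float]) -> tuple[float, float]:
    """Two-sided two-sample t test of per-replicate ratios.

    Returns (t statistic, p value); identical degenerate groups return
    (0, 1) by convention. At least two replicates per group required.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two replicates per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf), 0.0
    t, p = stats.ttest_ind(a, b)
    return float(t), float(p)


def read_ct_table(path) -> pd.DataFrame:
    """Ct table TSV with columns assay, sample, group, ct (one row per
    technical replicate)."""
    df = pd.read_csv(path, sep="\t", dtype={"assay": str, "sample": str,
                                            "group": str})
    required = {"assay", "sample", "group", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return df
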