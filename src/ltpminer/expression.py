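"""Relative qPCR expression by the 2^-ddCt method.

Target-gene Ct values are normalised to a reference gene (dCt) in both
the sample of interest and a calibrator sample; the fold change is
2^-(dCt_sample - dCt_calibrator).  Technical replicates are averaged on
the Ct scale (arithmetic mean) before any delta is taken; the replicate
SD is carried along for plotting but not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .core_io import LtpMinerError


@dataclass(frozen=True)
class CtRecord:
    sample: str
    gene: str
    ct: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if not self.ct > 0:
            raise LtpMinerError(f"Ct must be positive ({self.sample}/{self.gene})")


def relative_expression(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Fold change 2^-ddCt of the target gene, sample vs calibrator."""
    for ct in (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator):
        if not math.isfinite(ct):
            raise LtpMinerError("all four Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator
    )
    return 2.0 ** (-ddct)


def fold_change_table(
    ct_table: pd.DataFrame,
    reference_gene: str,
    calibrator_sample: str,
) -> pd.DataFrame:
    """Per-gene, per-sample fold changes from a long-format Ct table.

    ``ct_table`` needs columns sample, gene, ct (and optionally
    replicate); technical replicates are averaged first.  The reference
    gene must be measured in every sample.
    """
    required = {"sample", "gene", "ct"}
    if not required <= set(ct_table.columns):
        raise LtpMinerError(f"Ct table needs columns {sorted(required)}")
    means = ct_table.groupby(["sample", "gene"])["ct"].agg(["mean", "std"]).reset_index()
    ref = means[means["gene"] == reference_gene].set_index("sample")["mean"]
    if calibrator_sample not in set(means["sample"]):
        raise LtpMinerError(f"calibrator sample {calibrator_sample!r} not in table")
    rows = []
    for row in means[means["gene"] != reference_gene].itertuples(index=False):
        if row.sample not in ref.index:
            raise LtpMinerError(f"reference gene missing in sample {row.sample!r}")
        cal = means[(means["gene"] == row.gene) & (means["sample"] == calibrator_sample)]
        if cal.empty:
            raise LtpMinerError(f"gene {row.gene!r} missing in calibrator sample")
        fold = relative_expression(
            row.mean,
            float(ref[row.sample]),
            float(cal["mean"].iloc[0]),
            float(ref[calibrator_sample]),
        )
        rows.append(
            {
                "gene": row.gene,
                "sample": row.sample,
                "fold_change": fold,
                "ct_sd": row.std,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "sample", "fold_change", "ct_sd"])
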