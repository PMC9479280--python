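"""TBV-proportion and T-score normalization of ROI volumes.

The analysis model operates on ROI volumes expressed first as proportions
of each participant's total brain volume (removing overall head-size
differences) and then T-scored across participants per column (removing
scale differences between regions).  The T convention is the standard
psychometric one: mean 50, SD 10, sample (n-1) standard deviation.  Any
affine convention gives the same Manhattan-distance geometry up to a
global scale, which every downstream MDMR statistic is invariant to.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["to_proportions", "to_tscores", "T_MEAN", "T_SD"]

T_MEAN = 50.0
T_SD = 10.0


def to_proportions(volumes: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """ROI volumes (mm^3) as fractions of each participant's TBV (cm^3).

    The cm^3 -> mm^3 conversion (x1000) happens here and only here.
    """
    tbv = cohort.set_index("participant_id")["tbv_cm3"]
    missing = [i for i in volumes.index if i not in tbv.index]
    if missing:
        raise ValueError(f"no TBV for participants {missing[:5]}")
    tbv_mm3 = tbv.loc[volumes.index].to_numpy(dtype=float) * 1000.0
    if (tbv_mm3 <= 0).any():
        raise ValueError("non-positive TBV")
    props = volumes.div(tbv_mm3, axis=0)
    over = props.gt(1.0)
    if over.any().any():
        bad = props.index[over.any(axis=1)].tolist()
        raise ValueError(f"ROI volume exceeds TBV for participants {bad[:5]}")
    return props


def to_tscores(props: pd.DataFrame) -> pd.DataFrame:
    """Standardize each column to mean 50, SD 10 across participants.

    Uses the analyzed sample only, with the n-1 sample SD.  A
    zero-variance column cannot be standardized and raises, naming the
    column.
    """
    if len(props) < 2:
        raise ValueError("T-scoring requires at least 2 participants")
    x = props.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [props.columns[j] for j in dead]
        raise ValueError(f"zero-variance column(s): {names}")
    t = T_MEAN + T_SD * (x - x.mean(axis=0)) / sd
    return pd.DataFrame(t, index=props.index, columns=props.columns)
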