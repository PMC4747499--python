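"""Bundled small example tables used by docs, tests and the acceptance script."""

from __future__ import annotations

import numpy as np
import pandas as pd

# Per-gene posterior probabilities of the alternative hypothesis for the
# three standard comparisons of a child/adult stratified case-control qPCR
# panel (p_child / p_adult: CD vs control within stratum; p_diff: CD children
# vs CD adults). NaN means the posterior fell below the reporting threshold.
_EXAMPLE_ROWS = [
    # gene, p_child, p_adult, p_diff
    ("C1orf106", 0.57, 0.51, 0.52),
    ("C2orf74", 0.58, 0.73, None),
    ("CCR4", 0.58, 0.79, 0.72),
    ("CCR6", 0.68, 0.62, None),
    ("CD28", None, 0.55, None),
    ("FASLG", 0.72, 0.63, None),
    ("ICOSLG", 0.59, None, 0.57),
    ("IL18RAP", 0.54, 0.60, 0.51),
    ("IL1RL1", None, 0.72, 0.70),
    ("IL23A", 0.70, 0.69, None),
    ("IL6", 0.50, 0.63, 0.91),
    ("JAK2", 0.65, 0.65, None),
    ("PLEK", 0.52, 0.61, 0.51),
    ("STAT3", None, 0.56, None),
    ("TAGAP", 0.56, 0.52, None),
    ("TMEM187", None, 0.62, None),
    ("TNFSF18", 0.73, None, 0.54),
    ("UBE2L3", 0.52, 0.77, None),
    ("VAMP3", None, 0.55, None),
    ("ZFP36L1", None, 0.57, None),
]


def example_posterior_summaries() -> pd.DataFrame:
    """20-gene example of per-comparison posterior alternative probabilities."""
    df = pd.DataFrame(
        _EXAMPLE_ROWS, columns=["gene", "p_child", "p_adult", "p_diff"]
    ).set_index("gene")
    return df.astype(float).replace({None: np.nan})
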