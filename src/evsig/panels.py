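"""Reference marker panels shipped with the package.

``discovery_panel`` is the published 26-protein plasma tdEV signature
(breast cancer vs healthy controls) with each marker's reported p-value and
linear-scale fold change; it serves as a worked example for the differential
expression rule and as the source of the planted-marker effect sizes used by
the synthetic cohort generator.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["discovery_panel", "dep_rule"]


def discovery_panel() -> pd.DataFrame:
    """The 26-marker discovery signature: gene, uniprot, protein_name,
    p_value, fold_change (linear scale, direction-free)."""
    with resources.files("evsig.data").joinpath("discovery_panel.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def dep_rule(
    p_values, fold_changes, p_thresh: float = 0.05, fc_thresh: float = 2.0
) -> np.ndarray:
    """The differential-expression call on reported statistics: p strictly
    below ``p_thresh`` and linear fold change strictly above ``fc_thresh``."""
    p = np.asarray(p_values, dtype=float)
    fc = np.asarray(fold_changes, dtype=float)
    if p.shape != fc.shape:
        raise ValueError("p_values and fold_changes must align")
    return (p < p_thresh) & (fc > fc_thresh)
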