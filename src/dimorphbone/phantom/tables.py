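"""Synthetic qPCR Ct tables with known fold-change ground truth."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CtTableSpec", "generate_ct_table"]


@dataclass
class CtTableSpec:
    """Ct tables for target genes vs a reference gene across two groups.

    ``true_folds`` maps gene name -> expression fold of the test group over
    the calibrator group; the generated Ct values satisfy
    fold = 2^(-ddCt) exactly in expectation (sd adds measurement noise).
    """

    true_folds: dict = field(default_factory=lambda: {"Gene1": 2.0})
    n_per_group: int = 6
    reference_gene: str = "GAPDH"
    reference_ct_mean: float = 18.0
    target_ct_mean: float = 24.0
    ct_sd: float = 0.15
    seed: int = 0


def generate_ct_table(spec: CtTableSpec) -> pd.DataFrame:
    """Long-format Ct table: sample_id, group, gene, ct."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group in ("calibrator", "test"):
        for i in range(spec.n_per_group):
            sid = f"{group}_{i + 1}"
            rows.append({"sample_id": sid, "group": group,
                         "gene": spec.reference_gene,
                         "ct": spec.reference_ct_mean
                         + rng.normal(0.0, spec.ct_sd)})
            for gene, fold in spec.true_folds.items():
                shift = -np.log2(fold) if group == "test" else 0.0
                rows.append({"sample_id": sid, "group": group, "gene": gene,
                             "ct": spec.target_ct_mean + shift
                             + rng.normal(0.0, spec.ct_sd)})
    return pd.DataFrame(rows)
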