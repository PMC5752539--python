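"""Bundled reference tables for the worked examples and checks.

Small published summary tables from a pan-cancer TCGA analysis of
prognosis-related miRNA-target interactions, carried as package data so
the association tests and summary arithmetic can be demonstrated without
external downloads.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "gbm_literature_tables",
    "pan_cancer_interaction_counts",
]


def gbm_literature_tables() -> dict[str, pd.DataFrame]:
    """Literature-support 2x2 tables for GBM miRNAs.

    ``risk``: key miRNAs (42 of 51 literature-supported as GBM
    risk-associated) against other disease-associated miRNAs (45 of 80).
    ``metastasis``: the same comparison for metastasis association
    (34 of 51 vs 32 of 80).  Rows: miRNA group; columns: supported or not.
    """
    idx = pd.Index(["key_mirnas", "other_disease_mirnas"], name="group")
    cols = pd.Index(["supported", "not_supported"], name="literature")
    return {
        "risk": pd.DataFrame([[42, 9], [45, 35]], index=idx, columns=cols),
        "metastasis": pd.DataFrame([[34, 17], [32, 48]], index=idx, columns=cols),
    }


def pan_cancer_interaction_counts() -> pd.Series:
    """Published per-cancer-type counts of key miRNA-target interactions
    across 16 TCGA cancer types."""
    counts = {
        "BLCA": 203,
        "BRCA": 93,
        "CESC": 31,
        "COAD": 4,
        "ESCA": 12,
        "GBM": 528,
        "HNSC": 115,
        "KIRC": 580,
        "KIRP": 181,
        "LIHC": 71,
        "LUAD": 51,
        "LUSC": 6,
        "OV": 84,
        "PAAD": 3,
        "STAD": 7,
        "THCA": 10,
    }
    return pd.Series(counts, name="key_interactions")
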