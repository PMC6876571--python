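"""Shared builders for hand-crafted record tables and libraries."""

import numpy as np
import pandas as pd

from incprint import Status, make_library
from incprint.screen import RECORD_COLUMNS


def make_records(
    lum_pairs,
    elisa_pairs=None,
    rna_id="RNA_X",
    status=Status.ANALYZED,
    protein_ids=None,
):
    """Record table with given replicate pairs; means left unset."""
    n = len(lum_pairs)
    if protein_ids is None:
        protein_ids = [f"P{i:04d}" for i in range(1, n + 1)]
    if elisa_pairs is None:
        elisa_pairs = [(1000.0, 1000.0)] * n
    df = pd.DataFrame(
        {
            "protein_id": protein_ids,
            "rna_id": rna_id,
            "lum_1": [float(a) for a, _ in lum_pairs],
            "lum_2": [float(b) for _, b in lum_pairs],
            "elisa_1": [float(a) for a, _ in elisa_pairs],
            "elisa_2": [float(b) for _, b in elisa_pairs],
            "status": int(status),
            "mean_lum": np.nan,
            "mean_elisa": np.nan,
            "normalized_score": np.nan,
        }
    )
    df["is_interactor"] = pd.array([pd.NA] * n, dtype="boolean")
    return df[list(RECORD_COLUMNS)]


def make_called_records(entries, rna_id):
    """Minimal called table: entries = [(protein_id, status, score, is_hit)]."""
    df = pd.DataFrame(
        entries, columns=["protein_id", "status", "normalized_score", "is_interactor"]
    )
    df["rna_id"] = rna_id
    df["status"] = df["status"].astype(int)
    df["is_interactor"] = df["is_interactor"].astype("boolean")
    return df


def make_domain_library(domain_map):
    """Library table from {protein_id: iterable of pfam ids}."""
    return make_library(
        pd.DataFrame(
            {
                "protein_id": list(domain_map),
                "symbol": list(domain_map),
                "category": "RBP",
                "pfam_domains": [";".join(v) for v in domain_map.values()],
            }
        )
    )
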