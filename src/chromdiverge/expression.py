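"""Expression quantification and expression-derived gene classes."""

from __future__ import annotations

import numpy as np
import pandas as pd

#: RPKM-like scale constant: reads / (gene kb * million mapped reads).
RPKM_SCALE = 1e9


def quantify_expression(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    pseudocount: float = 1.0,
    scale: float = RPKM_SCALE,
) -> pd.Series:
    """log2 length- and depth-normalized expression, averaged over replicates.

    ``counts`` is genes x replicates.  Per replicate,
    value = count / (length * total mapped) * scale, then log2(+pseudocount);
    the final value is the mean over replicates.  Invariant to uniform
    library scaling (count doubling with total doubling) and gene order.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = counts.index[lengths.isna()][:5].tolist()
        raise ValueError(f"missing gene lengths for {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    logs = []
    for col in counts.columns:
        total = counts[col].sum()
        if total <= 0:
            raise ValueError(f"replicate {col!r} has zero total reads")
        rpkm = counts[col] / (lengths * total) * scale
        logs.append(np.log2(rpkm + pseudocount))
    return pd.concat(logs, axis=1).mean(axis=1).rename("expression")


def responsiveness_classes(compendium: pd.DataFrame, n: int = 1000) -> pd.DataFrame:
    """Classify genes by expression SD across a condition compendium.

    The ``n`` genes with the highest SD over conditions become
    ``responsive``, the ``n`` lowest become ``non_responsive``.  Ties break
    by gene id.  ``compendium`` is conditions x genes, assumed log scale.
    """
    if len(compendium) < 2:
        raise ValueError("need at least 2 conditions")
    n_genes = compendium.shape[1]
    if n > n_genes // 2:
        raise ValueError(f"n={n} exceeds half the gene count ({n_genes})")
    sd = compendium.std(axis=0, ddof=1)
    order = sd.sort_index().sort_values(kind="stable")  # id tie-break, then sd
    responsive = order.index[-n:]
    non_responsive = order.index[:n]
    rows = [(g, "responsive") for g in responsive]
    rows += [(g, "non_responsive") for g in non_responsive]
    return pd.DataFrame(rows, columns=["gene_id", "class_name"])


def top_k_class(scores: pd.Series, k: int = 800, name: str = "periodic") -> pd.DataFrame:
    """Top-k genes by score as a class table; ties break by gene id."""
    if k > len(scores):
        raise ValueError(f"k={k} exceeds number of genes ({len(scores)})")
    order = scores.sort_index().sort_values(kind="stable")
    top = order.index[-k:] if k else order.index[:0]
    return pd.DataFrame({"gene_id": list(top), "class_name": name})
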