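"""Single-replicate fold-change expression screen.

With one RNA-seq replicate per population no test statistic is available;
the screen is the classical filter-and-threshold procedure: keep genes with
expression above a floor (RPKM strictly greater than 1 in at least one
sample), compute the log2 fold-change between the two samples, call genes
with |log2FC| strictly above log2(2) differential, split by direction, and
rank by |log2FC| to select the top N per direction.  A per-gene Z-score
profile across stromal subsets supports downstream heat-map style
comparisons.

Fold-changes on RPKM use a pseudocount (0.1 by default) so zero values stay
finite; with a pseudocount of 0 both values must be positive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError, UndefinedStatisticError

__all__ = [
    "rpkm_filter",
    "log2_fold_change",
    "de_screen",
    "zscore_profile",
    "DEFAULT_PSEUDOCOUNT",
]

DEFAULT_PSEUDOCOUNT = 0.1


def _check_table(table: pd.DataFrame) -> None:
    if table.index.has_duplicates:
        raise InputError("gene identifiers must be unique")
    if (table.to_numpy() < 0).any():
        raise InputError("RPKM values must be >= 0")


def rpkm_filter(
    table: pd.DataFrame, min_rpkm: float = 1.0, min_samples: int = 1
) -> pd.DataFrame:
    """Drop lowly expressed genes.

    Keeps genes with RPKM strictly greater than ``min_rpkm`` in at least
    ``min_samples`` samples; row order is preserved and the operation is
    idempotent.
    """
    _check_table(table)
    if min_samples > table.shape[1]:
        raise ConfigError("min_samples exceeds the number of samples")
    keep = (table > min_rpkm).sum(axis=1) >= min_samples
    return table.loc[keep]


def log2_fold_change(
    a: float | np.ndarray, b: float | np.ndarray, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float | np.ndarray:
    """``log2((a + eps) / (b + eps))``; positive when ``a`` exceeds ``b``."""
    if pseudocount < 0:
        raise ConfigError("pseudocount must be >= 0")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if pseudocount == 0 and (np.any(a <= 0) or np.any(b <= 0)):
        raise UndefinedStatisticError("zero RPKM with pseudocount 0: fold-change undefined")
    out = np.log2(a + pseudocount) - np.log2(b + pseudocount)
    return float(out) if out.ndim == 0 else out


def de_screen(
    table: pd.DataFrame,
    fc_threshold: float = 2.0,
    top_n: int = 500,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Fold-change screen between exactly two samples.

    Returns a per-gene frame (same order as the input) with columns
    ``log2fc`` (first sample over second), ``direction`` (up/down),
    ``passes_threshold`` (|log2FC| strictly above log2(fc_threshold)),
    ``rank`` (1 = largest |log2FC|; ties broken by gene identifier) and
    ``top`` (among the ``top_n`` passing genes of its direction).
    """
    _check_table(table)
    if table.shape[1] != 2:
        raise InputError(f"need exactly two samples, got {table.shape[1]}")
    if fc_threshold <= 0:
        raise ConfigError("fc_threshold must be > 0")
    a, b = table.iloc[:, 0], table.iloc[:, 1]
    log2fc = log2_fold_change(a.to_numpy(), b.to_numpy(), pseudocount)
    result = pd.DataFrame(
        {
            "log2fc": log2fc,
            "direction": np.where(log2fc >= 0, "up", "down"),
            "passes_threshold": np.abs(log2fc) > np.log2(fc_threshold),
        },
        index=table.index,
    )
    order = result.assign(_abs=np.abs(result["log2fc"]), _gene=result.index).sort_values(
        ["_abs", "_gene"], ascending=[False, True], kind="mergesort"
    )
    rank = pd.Series(np.arange(1, len(result) + 1), index=order.index)
    result["rank"] = rank.reindex(result.index)
    top = np.zeros(len(result), dtype=bool)
    for direction in ("up", "down"):
        candidates = order.index[
            (order["direction"] == direction) & order["passes_threshold"]
        ][:top_n]
        top |= result.index.isin(candidates)
    result["top"] = top
    return result


def screen_summary(result: pd.DataFrame) -> dict:
    """Counts of passing genes and the down-regulated fraction among them."""
    passing = result[result["passes_threshold"]]
    n_pass = int(len(passing))
    n_down = int((passing["direction"] == "down").sum())
    return {
        "n_genes": int(len(result)),
        "n_pass": n_pass,
        "n_down": n_down,
        "n_up": n_pass - n_down,
        "down_fraction": n_down / n_pass if n_pass else float("nan"),
    }


def zscore_profile(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Row-wise Z-scores of a genes x subsets matrix.

    Each row is centered on its mean and scaled by its sample standard
    deviation (n-1).  Zero-variance rows come back as all zeros and are
    flagged in the returned boolean series.
    """
    if matrix.shape[1] < 2:
        raise InputError("need at least 2 subsets per gene")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (values - mean) / safe_sd
    z[flat, :] = 0.0
    return (
        pd.DataFrame(z, index=matrix.index, columns=matrix.columns),
        pd.Series(flat, index=matrix.index, name="zero_variance"),
    )
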