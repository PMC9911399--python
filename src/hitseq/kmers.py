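"""Projection of 7-mer affinities onto 5-mer space and flanking-base effects.

Each 7-mer contains three 5-mer registers (offsets 0, 1, 2).  A 5-mer's
"contexts" are the distinct 7-mers that contain it at one of those offsets —
48 for a 5-mer that cannot overlap itself (3 offsets x 16 flank pairs), fewer
for self-overlapping 5-mers like AAAAA.  5-mer summaries use box-plot
semantics: median (default) or mean, quartiles, and min/max whiskers over the
context values.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .affinity import AffinityTable
from .sequences import RNA_BASES, all_kmers, validate_sequence


def kmer_contexts(kmer5: str) -> list[str]:
    """All distinct 7-mers containing ``kmer5`` at offsets 0-2 (sorted)."""
    if len(kmer5) != 5:
        raise ValueError(f"expected a 5-mer, got {kmer5!r} (length {len(kmer5)})")
    validate_sequence(kmer5, what="5-mer")
    contexts = set()
    for a in RNA_BASES:
        for b in RNA_BASES:
            contexts.add(kmer5 + a + b)  # offset 0
            contexts.add(a + kmer5 + b)  # offset 1
            contexts.add(a + b + kmer5)  # offset 2
    return sorted(contexts)


def _ka_series(table: AffinityTable | pd.Series) -> pd.Series:
    return table if isinstance(table, pd.Series) else table.ka


def aggregate_5mer(
    table: AffinityTable | pd.Series, stat: str = "median"
) -> pd.DataFrame:
    """Summarise K_A,rel over every 5-mer's 7-mer contexts.

    Returns a 1,024-row table indexed by 5-mer with columns ``value`` (the
    chosen statistic), ``context_count``, quartiles and min/max whiskers.
    Missing 7-mers silently reduce a 5-mer's context set; the ``incomplete``
    flag marks those rows.
    """
    if stat not in ("median", "mean"):
        raise ValueError(f"unknown statistic {stat!r}; use 'median' or 'mean'")
    ka = _ka_series(table)
    rows = []
    missing_any = False
    for kmer5 in all_kmers(5):
        contexts = kmer_contexts(kmer5)
        values = ka.reindex(contexts).dropna().to_numpy()
        incomplete = len(values) < len(contexts)
        missing_any |= incomplete
        if len(values) == 0:
            rows.append((kmer5, np.nan, 0, np.nan, np.nan, np.nan, np.nan, True))
            continue
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        value = med if stat == "median" else float(values.mean())
        rows.append(
            (kmer5, value, len(values), q1, q3, values.min(), values.max(), incomplete)
        )
    if missing_any:
        warnings.warn("some 5-mers had missing 7-mer contexts; summaries reduced")
    out = pd.DataFrame(
        rows,
        columns=[
            "kmer5", "value", "context_count", "q1", "q3",
            "whisker_low", "whisker_high", "incomplete",
        ],
    ).set_index("kmer5")
    return out


def flanking_effect(table: AffinityTable | pd.Series, core5: str) -> dict:
    """Effect of the 5' and 3' flanking base around a centred 5-mer core.

    Considers the 16 7-mers N-core5-N (the unambiguous centred register),
    groups them by each flank, and reports group medians plus pairwise
    ln-ratio matrices between flank choices (positive: row base gives higher
    affinity than column base).
    """
    if len(core5) != 5:
        raise ValueError(f"core must be a 5-mer, got {core5!r}")
    validate_sequence(core5, what="core 5-mer")
    ka = _ka_series(table)
    values = pd.DataFrame(
        [
            (five, three, ka.get(five + core5 + three, np.nan))
            for five in RNA_BASES
            for three in RNA_BASES
        ],
        columns=["five_prime", "three_prime", "ka_rel"],
    )
    grid = values.pivot(index="five_prime", columns="three_prime", values="ka_rel")
    by5 = grid.median(axis=1)
    by3 = grid.median(axis=0)

    def log_ratio(medians: pd.Series) -> pd.DataFrame:
        m = medians.to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            lr = np.log(m[:, None] / m[None, :])
        return pd.DataFrame(lr, index=medians.index, columns=medians.index)

    return {
        "values": grid,
        "by_five_prime": by5,
        "by_three_prime": by3,
        "log_ratio_five_prime": log_ratio(by5),
        "log_ratio_three_prime": log_ratio(by3),
    }


def context_multiplicity_total(k_long: int = 7, k_short: int = 5) -> int:
    """Total register count: each long k-mer contributes one per offset."""
    n_offsets = k_long - k_short + 1
    return n_offsets * 4**k_long
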