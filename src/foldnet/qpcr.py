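"""Comparative-CT relative quantification with multi-reference normalization.

delta CT = mean CT of the gene minus the geometric mean of the reference-gene
CTs in the same sample (replicate CTs are averaged arithmetically first).
delta-delta CT = delta CT(sample) - delta CT(control); relative expression is
``2**-ddct`` (amplification efficiency 2 implicit, no efficiency correction).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["geometric_mean", "delta_ct", "fold_change", "quantify"]


def geometric_mean(values: Sequence[float]) -> float:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of empty sequence")
    if (arr <= 0).any():
        raise ValueError("geometric mean requires positive values")
    return float(np.exp(np.mean(np.log(arr))))


def _mean_ct(table: pd.DataFrame, sample: str, gene: str) -> float:
    sub = table[(table["sample"] == sample) & (table["gene"] == gene)]
    if sub.empty:
        raise ValueError(f"no CT measurements for gene {gene!r} in sample {sample!r}")
    return float(sub["ct"].mean())


def delta_ct(table: pd.DataFrame, sample: str, gene: str,
             references: Sequence[str]) -> float:
    """Normalized CT of ``gene`` in ``sample`` (cycles).

    Raises if the gene or any reference is missing from the sample; the error
    names the offending gene.
    """
    if len(references) < 1:
        raise ValueError("at least one reference gene required")
    gene_ct = _mean_ct(table, sample, gene)
    ref_cts = []
    for ref in references:
        try:
            ref_cts.append(_mean_ct(table, sample, ref))
        except ValueError:
            raise ValueError(
                f"reference gene {ref!r} missing from sample {sample!r}") from None
    return gene_ct - geometric_mean(ref_cts)


def fold_change(delta_ct_sample: float, delta_ct_control: float) -> float:
    """Relative expression ``2**-(dCT_sample - dCT_control)``."""
    return float(2.0 ** -(delta_ct_sample - delta_ct_control))


def quantify(table: pd.DataFrame, references: Sequence[str], control_sample: str,
             genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Gene-by-sample fold changes relative to ``control_sample``.

    Returns columns ``gene, sample, delta_ct, ddct, fold_change, ct_sd``
    (``ct_sd`` is the replicate SD of the raw gene CTs, for QC).
    """
    samples = [s for s in dict.fromkeys(table["sample"]) if s != control_sample]
    if control_sample not in set(table["sample"]):
        raise ValueError(f"control sample {control_sample!r} not in CT table")
    if genes is None:
        genes = [g for g in dict.fromkeys(table["gene"]) if g not in set(references)]
    rows = []
    for gene in genes:
        dct_control = delta_ct(table, control_sample, gene, references)
        for sample in samples:
            dct = delta_ct(table, sample, gene, references)
            ddct = dct - dct_control
            sub = table[(table["sample"] == sample) & (table["gene"] == gene)]
            sd = float(sub["ct"].std(ddof=1)) if len(sub) > 1 else 0.0
            rows.append((gene, sample, dct, ddct, fold_change(dct, dct_control), sd))
    return pd.DataFrame(
        rows, columns=["gene", "sample", "delta_ct", "ddct", "fold_change", "ct_sd"])
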