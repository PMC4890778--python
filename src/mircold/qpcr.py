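"""Relative expression from Ct tables by the 2^-ddCt method.

Technical replicates are averaged on the Ct scale; each gene is
normalized against a reference gene within the same sample (dCt), then
against a calibrator sample (ddCt), and RQ = 2^-ddCt assuming one
doubling per cycle. The standard error of ddCt propagates the four
technical-replicate standard errors in quadrature and is carried to the
RQ scale by the delta method. Direction calls (up / down / no-change)
use |log2 RQ| > 0.5 by default, mirroring the sequencing-side fold-change
threshold; the boundary itself is no-change.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "RelExpr",
    "read_ct_table",
    "mean_ct",
    "ddct",
    "direction_call",
    "relative_expression_table",
    "correlation_table",
]

DIRECTION_THRESHOLD_LOG2 = 0.5


@dataclass
class RelExpr:
    """Relative expression of one gene in one sample vs a calibrator."""

    gene_id: str
    sample: str
    calibrator: str
    delta_ct: float
    delta_delta_ct: float
    rq: float
    se: float          # standard error of RQ (delta method)
    call: str          # up | down | no-change


def read_ct_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Load a delimited Ct table with columns sample, gene, replicate, ct."""
    df = pd.read_csv(path, sep=sep)
    required = {"sample", "gene", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return df


def mean_ct(cts: Sequence[float]) -> tuple[float, float]:
    """Mean and sample sd of one sample-gene's technical replicates.

    A single replicate yields sd 0 by convention (flagged with a warning).
    """
    cts = list(cts)
    if not cts:
        raise ValueError("no Ct replicates")
    n = len(cts)
    mean = sum(cts) / n
    if n == 1:
        warnings.warn("single Ct replicate: sd set to 0")
        return mean, 0.0
    var = sum((c - mean) ** 2 for c in cts) / (n - 1)
    return mean, math.sqrt(var)


def _cell(ct_table: pd.DataFrame, sample: str, gene: str) -> tuple[float, float, int]:
    sub = ct_table[(ct_table["sample"] == sample) & (ct_table["gene"] == gene)]
    if sub.empty:
        raise KeyError(f"Ct table has no rows for sample={sample!r}, gene={gene!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m, sd = mean_ct(sub["ct"].tolist())
    return m, sd, len(sub)


def ddct(gene: str, reference_gene: str, sample: str, calibrator: str,
         ct_table: pd.DataFrame,
         threshold_log2: float = DIRECTION_THRESHOLD_LOG2) -> RelExpr:
    """2^-ddCt relative expression of ``gene`` in ``sample`` vs ``calibrator``.

    dCt = Ct(gene) - Ct(reference) within each sample; ddCt is the sample
    dCt minus the calibrator dCt. All four (sample/calibrator x
    gene/reference) Ct means must be present.
    """
    mg_s, sd_g_s, n_g_s = _cell(ct_table, sample, gene)
    mr_s, sd_r_s, n_r_s = _cell(ct_table, sample, reference_gene)
    mg_c, sd_g_c, n_g_c = _cell(ct_table, calibrator, gene)
    mr_c, sd_r_c, n_r_c = _cell(ct_table, calibrator, reference_gene)

    dct_sample = mg_s - mr_s
    dct_cal = mg_c - mr_c
    dd = dct_sample - dct_cal
    rq = 2.0 ** (-dd)
    se_dd = math.sqrt(
        sd_g_s**2 / n_g_s + sd_r_s**2 / n_r_s + sd_g_c**2 / n_g_c + sd_r_c**2 / n_r_c
    )
    se_rq = math.log(2.0) * rq * se_dd
    return RelExpr(
        gene_id=gene, sample=sample, calibrator=calibrator,
        delta_ct=dct_sample, delta_delta_ct=dd, rq=rq, se=se_rq,
        call=direction_call(rq, threshold_log2),
    )


def direction_call(rq: float, threshold_log2: float = DIRECTION_THRESHOLD_LOG2) -> str:
    """up if log2(rq) > threshold, down if < -threshold, else no-change."""
    if rq <= 0:
        raise ValueError("RQ must be positive")
    l2 = math.log2(rq)
    if l2 > threshold_log2:
        return "up"
    if l2 < -threshold_log2:
        return "down"
    return "no-change"


def relative_expression_table(ct_table: pd.DataFrame, genes: Sequence[str],
                              reference_gene: str,
                              sample_calibrators: Mapping[str, str],
                              threshold_log2: float = DIRECTION_THRESHOLD_LOG2
                              ) -> pd.DataFrame:
    """RelExpr rows for each gene x (sample -> calibrator) pair."""
    rows = []
    for sample, calibrator in sample_calibrators.items():
        for gene in genes:
            r = ddct(gene, reference_gene, sample, calibrator, ct_table, threshold_log2)
            rows.append({
                "gene": r.gene_id, "sample": r.sample, "calibrator": r.calibrator,
                "delta_ct": r.delta_ct, "delta_delta_ct": r.delta_delta_ct,
                "rq": r.rq, "se": r.se, "call": r.call,
            })
    return pd.DataFrame(rows)


def correlation_table(mirna_rel: pd.DataFrame, target_rel: pd.DataFrame,
                      pairing: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """miRNA/target direction-correlation matrix.

    For each miRNA -> target pair and each sample present in both tables,
    reports both calls and whether they are negatively correlated
    (one up while the other is down). Pairs whose target is missing from
    the target table are skipped with a warning.
    """
    rows = []
    mi = mirna_rel.set_index(["gene", "sample"])
    tg = target_rel.set_index(["gene", "sample"])
    for mirna, targets_ in pairing.items():
        for target in targets_:
            for (g, sample) in mi.index:
                if g != mirna:
                    continue
                if (target, sample) not in tg.index:
                    warnings.warn(f"no target Ct data for {target!r} in sample {sample!r}; skipped")
                    continue
                mc = mi.loc[(mirna, sample), "call"]
                tc = tg.loc[(target, sample), "call"]
                rows.append({
                    "mirna": mirna, "target": target, "sample": sample,
                    "mirna_call": mc, "target_call": tc,
                    "negative_correlation": {mc, tc} == {"up", "down"},
                })
    return pd.DataFrame(rows)
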