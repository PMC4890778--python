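"""Replicate-free differential expression between two sRNA libraries.

Expression is normalized to tags per million clean reads,

    TPM = count / total_clean_reads * 1e6,

with zero counts replaced by a TPM of 0.01 so that log fold changes stay
finite. Significance comes from the Audic-Claverie exact test, which
conditions on the count observed in the first library and asks how
surprising the second library's count is given the two sequencing depths:

    P(y | x) = (N2/N1)^y * (x+y)! / (x! * y! * (1 + N2/N1)^(x+y+1)).

Equivalently, y | x follows a negative binomial with x+1 successes and
success probability N1/(N1+N2). The two-sided p-value doubles the smaller
tail (capped at 1). A miRNA is called up when log2(TPM_treat/TPM_control)
> 0.5 with p < 0.05, down when < -0.5 with p < 0.05, otherwise ns;
boundary values are ns (strict inequalities). No multiple-testing
correction is applied by default (an optional Benjamini-Hochberg column
can be requested).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "ContrastResult",
    "normalize",
    "log2fc",
    "ac_test",
    "classify",
    "contrast_table",
]

ZERO_TPM = 0.01
LOG2FC_THRESHOLD = 0.5
P_THRESHOLD = 0.05


@dataclass
class ContrastResult:
    entity_id: str
    contrast: str
    tpm_treat: float
    tpm_control: float
    log2fc: float
    pvalue: float
    call: str  # up | down | ns


def normalize(x: int, n_total: int) -> float:
    """Tags-per-million with the zero -> 0.01 substitution."""
    if n_total <= 0:
        raise ValueError("total clean reads must be positive")
    if x < 0:
        raise ValueError("count must be non-negative")
    if x == 0:
        return ZERO_TPM
    return x / n_total * 1e6


def log2fc(tpm_treat: float, tpm_control: float) -> float:
    """log2 ratio treat/control; inputs must be positive (zero-replaced)."""
    return math.log2(tpm_treat / tpm_control)


def _ac_logpmf(k: np.ndarray, x: int, log_r: float) -> np.ndarray:
    """log P(k | x) for the Audic-Claverie conditional, r = N2/N1."""
    k = np.asarray(k, dtype=float)
    return (
        k * log_r
        + gammaln(x + k + 1)
        - gammaln(x + 1)
        - gammaln(k + 1)
        - (x + k + 1) * np.log1p(np.exp(log_r))
    )


def _ac_upper_tail(y: int, x: int, log_r: float) -> float:
    """Sum_{k >= y} P(k | x), summed directly in log space.

    The conditional is negative binomial, so terms decay geometrically
    past the mode; summation proceeds in chunks until the running total
    stops changing at double precision.
    """
    mode = (x + 1) * math.exp(log_r)  # ~ mean of the NB
    chunk = max(64, int(4 * math.sqrt(mode + 1)))
    parts: list[float] = []
    k0 = y
    total = -math.inf
    while True:
        ks = np.arange(k0, k0 + chunk)
        part = logsumexp(_ac_logpmf(ks, x, log_r))
        parts.append(part)
        new_total = logsumexp(parts)
        if k0 > mode and (new_total - total) < 1e-13:
            total = new_total
            break
        total = new_total
        k0 += chunk
    return float(math.exp(total))


def ac_test(x: int, n1: int, y: int, n2: int) -> float:
    """Two-sided Audic-Claverie exact p-value, computed in log space.

    p = min(1, 2 * min(P(K <= y | x), P(K >= y | x))) under the
    conditional distribution with depth ratio r = N2/N1. The conditioning
    side is canonicalized — the test conditions on the library whose
    (count, depth) pair sorts first — so the result is exactly symmetric
    in its two library arguments (the raw conditional definition is not).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if (y, n2) < (x, n1):
        x, n1, y, n2 = y, n2, x, n1
    log_r = math.log(n2) - math.log(n1)
    lower = float(math.exp(logsumexp(_ac_logpmf(np.arange(0, y + 1), x, log_r))))
    # upper tail: complement is accurate unless the tail is vanishing
    upper = 1.0 - (lower - float(math.exp(_ac_logpmf(np.array([y]), x, log_r)[0])))
    if upper < 1e-6:
        upper = _ac_upper_tail(y, x, log_r)
    return min(1.0, 2.0 * min(lower, upper))


def classify(lfc: float, p: float, lfc_threshold: float = LOG2FC_THRESHOLD,
             p_threshold: float = P_THRESHOLD) -> str:
    """up / down / ns call; thresholds are strict, boundaries fall to ns."""
    if not (math.isfinite(lfc) and math.isfinite(p)):
        raise ValueError("log2fc and p must be finite")
    if p < p_threshold and lfc > lfc_threshold:
        return "up"
    if p < p_threshold and lfc < -lfc_threshold:
        return "down"
    return "ns"


def contrast_table(counts: pd.DataFrame, totals: Mapping[str, int],
                   contrasts: Sequence[tuple[str, str, str]],
                   test: Callable[[int, int, int, int], float] = ac_test,
                   adjust: bool = False) -> pd.DataFrame:
    """Per-entity DE results for each (name, treat_lib, control_lib) contrast.

    ``counts`` is an entity x library integer matrix; ``totals`` the
    total-clean-reads denominators. Returns one row per entity per
    contrast with TPMs, log2FC, p-value and call; with ``adjust`` an extra
    Benjamini-Hochberg column ``p_adj`` is included (calls still use the
    raw p, matching the stated thresholds).
    """
    rows = []
    for name, treat, control in contrasts:
        for lib in (treat, control):
            if lib not in counts.columns or lib not in totals:
                raise KeyError(f"contrast {name!r} references unknown library {lib!r}")
        for entity, row in counts.iterrows():
            x_c = int(row[control])
            x_t = int(row[treat])
            tpm_c = normalize(x_c, totals[control])
            tpm_t = normalize(x_t, totals[treat])
            lfc = log2fc(tpm_t, tpm_c)
            p = test(x_c, totals[control], x_t, totals[treat])
            rows.append({
                "entity_id": entity, "contrast": name,
                "tpm_treat": tpm_t, "tpm_control": tpm_c,
                "log2fc": lfc, "pvalue": p, "call": classify(lfc, p),
            })
    df = pd.DataFrame(rows)
    if adjust and len(df):
        from scipy.stats import false_discovery_control

        df["p_adj"] = df.groupby("contrast")["pvalue"].transform(
            lambda s: false_discovery_control(s, method="bh"))
    return df


def summarize_calls(results: pd.DataFrame) -> dict[str, dict[str, int]]:
    """Per-contrast tallies of up/down/ns calls."""
    out: dict[str, dict[str, int]] = {}
    for contrast, sub in results.groupby("contrast"):
        vc = sub["call"].value_counts()
        out[contrast] = {c: int(vc.get(c, 0)) for c in ("up", "down", "ns")}
    return out
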