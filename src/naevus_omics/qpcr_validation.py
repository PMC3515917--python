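"""Relative qPCR quantification by the comparative Ct (ddCt) method.

For each patient and target gene the DNMC/MC expression ratio is

    dCt(cond)  = mean Ct(target, cond) - mean Ct(reference, cond)
    ddCt       = dCt(DNMC) - dCt(MC)
    ratio      = efficiency ** (-ddCt)

with replicate Ct values averaged first and the amplification efficiency
fixed at 2 (the classic assumption of perfect doubling per cycle; it can be
varied for sensitivity analysis). A ratio below 1 means the target is
expressed at a lower level in the lesional (DNMC) sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import CtTable

DEFAULT_REFERENCE = "RPS11"


@dataclass
class RatioResult:
    patient_id: str
    gene: str
    ratio: float
    replicate_ct_means: dict  # {(condition, role): mean Ct}

    def __post_init__(self) -> None:
        if not self.ratio > 0:
            raise ValueError("expression ratio must be positive")


def ddct_ratio(
    table: CtTable,
    patient_id,
    target: str,
    reference: str = DEFAULT_REFERENCE,
    efficiency: float = 2.0,
) -> RatioResult:
    """DNMC/MC expression ratio of `target` in one patient via ddCt."""
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    means = {}
    for cond in ("MC", "DNMC"):
        for role, gene in (("target", target), ("reference", reference)):
            means[(cond, role)] = table.mean_ct(patient_id, cond, gene)
    dct_mc = means[("MC", "target")] - means[("MC", "reference")]
    dct_dn = means[("DNMC", "target")] - means[("DNMC", "reference")]
    ddct = dct_dn - dct_mc
    return RatioResult(
        patient_id=patient_id,
        gene=target,
        ratio=float(efficiency ** (-ddct)),
        replicate_ct_means=means,
    )


def ddct_all(
    table: CtTable,
    reference: str = DEFAULT_REFERENCE,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Per-patient DNMC/MC ratios for every non-reference gene in the table."""
    rows = []
    for patient in table.patients:
        for gene in table.genes:
            if gene == reference:
                continue
            res = ddct_ratio(table, patient, gene, reference, efficiency)
            rows.append(
                {"patient_id": patient, "gene": gene, "ratio": res.ratio}
            )
    return pd.DataFrame(rows)
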