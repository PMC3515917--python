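"""Synthetic data with the statistical structure of the paired study design.

No public data accompanies the study design this pipeline addresses, so
every downstream stage is exercised on generated data that reproduces its
assumed structure:

* **Expression** — 18 patient-paired sample sets; per-gene precisions drawn
  from the Gamma(a, scale=b) prior the RVM test assumes (so the prior fit is
  a genuine parameter-recovery problem); a strong additive patient effect
  shared by both members of a pair (autologous samples cluster together,
  and pairing cancels it); a configurable fraction of genes carrying a
  signed log2 condition shift, half up and half down.
* **Gene sets** — random same-size-range subsets of the gene universe, with
  a configurable number of "enriched" sets built predominantly from genes
  carrying a condition effect.
* **DIGE spot tables** — log-normal spot volumes with per-gel-channel scale
  factors (removed by within-gel normalization), a Bernoulli presence mask,
  planted fold changes, and a dye-swap subset with optional dye bias
  (default 0, i.e. no label effect).
* **Ct tables** — a stable reference gene and per-target true DNMC/MC
  ratios encoded as Ct shifts of -log2(ratio), two replicates per cell.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CtTable, ExpressionMatrix, GeneSet, GeneSetCollection, SpotTable


@dataclass
class SimulationConfig:
    """Parameters of the paired-design expression simulation.

    Defaults mirror the study conditions: 18 patient pairs, a genome-scale
    gene count kept desk-sized at 5000, an inverse-gamma variance prior with
    shape a=3 and scale b=1, 10% of genes with a +-1 log2-unit condition
    shift, and a patient effect of SD 0.5 log2 units.
    """

    n_pairs: int = 18
    n_genes: int = 5000
    rvm_a: float = 3.0
    rvm_b: float = 1.0
    de_fraction: float = 0.1
    effect_size: float = 1.0
    sigma_patient: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    n_sets: int = 50
    set_size_range: tuple = (5, 100)
    n_enriched_sets: int = 3
    enriched_de_proportion: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be at least 2")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.rvm_a <= 0 or self.rvm_b <= 0:
            raise ValueError("variance-prior parameters must be positive")
        lo, hi = self.set_size_range
        if not (1 <= lo <= hi):
            raise ValueError("set_size_range must satisfy 1 <= lo <= hi")
        if hi > self.n_genes:
            raise ValueError("set sizes cannot exceed the gene count")
        if not 0 <= self.enriched_de_proportion <= 1:
            raise ValueError("enriched_de_proportion must lie in [0, 1]")


@dataclass
class TruthLabels:
    """Ground truth attached to generated data, for power/calibration tests."""

    gene_is_de: pd.Series | None = None      # bool per gene
    gene_delta: pd.Series | None = None      # true log2 shift per gene
    set_is_enriched: pd.Series | None = None  # bool per term
    spot_is_de: pd.Series | None = None      # bool per spot
    spot_fold: pd.Series | None = None       # true DNMC/MC fold per spot
    ct_true_ratios: pd.Series | None = None  # true ratio per target gene
    extras: dict = field(default_factory=dict)


def _mc_dnmc_ids(n_pairs: int) -> tuple[list, list, list]:
    patients = [f"P{i + 1:02d}" for i in range(n_pairs)]
    mc = [f"{p}_MC" for p in patients]
    dn = [f"{p}_DNMC" for p in patients]
    return patients, mc, dn


def gen_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, TruthLabels]:
    """Generate a paired log2 expression matrix under the RVM data model.

    Per gene g: precision tau_g ~ Gamma(a, scale=b), baseline mu_g; both
    samples of patient p share an additive effect ~ Normal(0, sigma_patient^2);
    the DNMC sample adds the gene's true shift delta_g; measurement noise is
    Normal(0, 1/tau_g) per sample.
    """
    rng = np.random.default_rng(config.seed)
    G, n = config.n_genes, config.n_pairs
    genes = [f"G{i + 1:05d}" for i in range(G)]
    patients, mc_ids, dn_ids = _mc_dnmc_ids(n)

    tau = rng.gamma(shape=config.rvm_a, scale=config.rvm_b, size=G)
    sigma = 1.0 / np.sqrt(tau)
    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=G)

    n_de = int(round(config.de_fraction * G))
    is_de = np.zeros(G, dtype=bool)
    de_idx = rng.choice(G, size=n_de, replace=False)
    is_de[de_idx] = True
    delta = np.zeros(G)
    # signed effects: half up, half down
    signs = np.ones(n_de)
    signs[1::2] = -1.0
    delta[de_idx] = config.effect_size * rng.permutation(signs)

    patient_eff = rng.normal(0.0, config.sigma_patient, size=(G, n))
    eps_mc = rng.normal(0.0, 1.0, size=(G, n)) * sigma[:, None]
    eps_dn = rng.normal(0.0, 1.0, size=(G, n)) * sigma[:, None]
    mc_vals = mu[:, None] + patient_eff + eps_mc
    dn_vals = mu[:, None] + patient_eff + delta[:, None] + eps_dn

    values = pd.DataFrame(
        np.concatenate([mc_vals, dn_vals], axis=1),
        index=genes,
        columns=mc_ids + dn_ids,
    )
    sheet = pd.DataFrame(
        {
            "patient_id": patients + patients,
            "condition": ["MC"] * n + ["DNMC"] * n,
        },
        index=pd.Index(mc_ids + dn_ids, name="sample_id"),
    )
    matrix = ExpressionMatrix(values=values, sample_sheet=sheet)
    truth = TruthLabels(
        gene_is_de=pd.Series(is_de, index=genes),
        gene_delta=pd.Series(delta, index=genes),
        extras={"tau": pd.Series(tau, index=genes)},
    )
    return matrix, truth


def gen_gene_sets(config: SimulationConfig, labels: TruthLabels) -> GeneSetCollection:
    """Generate gene sets over the simulated universe, some enriched for DE.

    Enriched sets draw `enriched_de_proportion` of their members from the
    genes with a true condition effect; the remaining sets are uniform
    subsets of the universe. Namespaces cycle through BP/MF/CC.
    """
    if labels.gene_is_de is None:
        raise ValueError("labels must carry per-gene DE flags")
    rng = np.random.default_rng(config.seed + 1)
    genes = np.array(labels.gene_is_de.index)
    is_de = labels.gene_is_de.to_numpy()
    de_pool = genes[is_de]
    bg_pool = genes[~is_de]
    lo, hi = config.set_size_range
    namespaces = ("BP", "MF", "CC")

    sets: dict[str, GeneSet] = {}
    enriched_flags = {}
    for s in range(config.n_sets):
        term = f"SET{s + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        enriched = s < config.n_enriched_sets
        if enriched:
            n_from_de = min(int(round(config.enriched_de_proportion * size)),
                            de_pool.size)
            members = list(rng.choice(de_pool, size=n_from_de, replace=False))
            members += list(rng.choice(bg_pool, size=size - n_from_de, replace=False))
        else:
            members = list(rng.choice(genes, size=size, replace=False))
        sets[term] = GeneSet(
            term_id=term,
            name=f"synthetic class {s + 1}",
            namespace=namespaces[s % 3],
            genes=frozenset(members),
        )
        enriched_flags[term] = enriched
    labels.set_is_enriched = pd.Series(enriched_flags)
    return GeneSetCollection(sets=sets, universe=frozenset(genes))


def gen_spot_table(
    n_spots: int = 200,
    n_gel_sets: int = 18,
    de_spots: int = 0,
    fold: float = 2.0,
    missing_rate: float = 0.1,
    sd_log: float = 0.4,
    gel_scale_sd: float = 0.3,
    n_dye_swap: int | None = None,
    dye_bias: float = 0.0,
    seed: int | None = None,
) -> tuple[SpotTable, TruthLabels]:
    """Generate a paired 2D-DIGE spot-volume table with planted fold changes.

    Log volumes are baseline + gel-channel scale factor + half the log fold
    (+ for DNMC, - for MC on planted spots) + Normal(0, sd_log) noise, then
    exponentiated. Presence is Bernoulli(1 - missing_rate) per (spot, gel
    set). The first `n_dye_swap` gel sets are flagged as dye-swapped; with
    `dye_bias` > 0 the Cy5-labelled channel gains that additive log bias
    (DNMC normally, MC on swapped gels), so bias 0 means no label effect.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    if de_spots > n_spots:
        raise ValueError("de_spots cannot exceed n_spots")
    rng = np.random.default_rng(seed)
    if n_dye_swap is None:
        n_dye_swap = n_gel_sets // 2
    spot_ids = [f"spot{i + 1:04d}" for i in range(n_spots)]
    gel_ids = [f"gel{j + 1:02d}" for j in range(n_gel_sets)]

    base = rng.normal(10.0, 1.0, size=n_spots)  # log-normal spot abundance
    gel_fac = rng.normal(0.0, gel_scale_sd, size=(n_gel_sets, 2))
    is_de = np.zeros(n_spots, dtype=bool)
    is_de[:de_spots] = True
    half_shift = 0.5 * np.log(fold) * is_de

    logv = (
        base[:, None, None]
        + gel_fac[None, :, :]
        + rng.normal(0.0, sd_log, size=(n_spots, n_gel_sets, 2))
    )
    logv[:, :, 1] += half_shift[:, None]  # DNMC up on planted spots
    logv[:, :, 0] -= half_shift[:, None]  # MC down

    dye_swap = np.zeros(n_gel_sets, dtype=bool)
    dye_swap[:n_dye_swap] = True
    if dye_bias != 0.0:
        # Cy5 labels DNMC on standard gels, MC on swapped gels
        cy5_channel = np.where(dye_swap, 0, 1)
        for j in range(n_gel_sets):
            logv[:, j, cy5_channel[j]] += dye_bias

    present = rng.random((n_spots, n_gel_sets)) >= missing_rate
    volumes = np.exp(logv)
    volumes[~np.repeat(present[:, :, None], 2, axis=2)] = np.nan
    table = SpotTable(spot_ids, gel_ids, volumes, present, dye_swap)
    truth = TruthLabels(
        spot_is_de=pd.Series(is_de, index=spot_ids),
        spot_fold=pd.Series(np.where(is_de, fold, 1.0), index=spot_ids),
    )
    return table, truth


def gen_ct_table(
    n_patients: int = 18,
    n_targets: int = 5,
    true_ratios=None,
    sd_ct: float = 0.1,
    seed: int | None = None,
    reference_gene: str = "RPS11",
    n_replicates: int = 2,
) -> tuple[CtTable, TruthLabels]:
    """Generate a duplicate-well qPCR Ct table with a stable reference gene.

    Target Ct in the DNMC sample is offset by -log2(true ratio); the
    reference gene's Ct is constant across conditions in expectation.
    `true_ratios` maps target gene names to DNMC/MC ratios (default: a small
    panel spanning down-, non- and up-regulation).
    """
    if sd_ct < 0:
        raise ValueError("sd_ct must be non-negative")
    rng = np.random.default_rng(seed)
    if true_ratios is None:
        defaults = [0.5, 0.8, 1.0, 1.25, 2.0]
        true_ratios = {
            f"TGT{i + 1}": defaults[i % len(defaults)] for i in range(n_targets)
        }
    if any(r <= 0 for r in true_ratios.values()):
        raise ValueError("true ratios must be positive")

    patients = [f"P{i + 1:02d}" for i in range(n_patients)]
    target_base = {g: rng.normal(24.0, 1.0) for g in true_ratios}
    ref_base = 18.0
    rows = []
    for patient in patients:
        shift = rng.normal(0.0, 0.5)  # per-patient cDNA input offset
        for cond in ("MC", "DNMC"):
            genes = {reference_gene: ref_base}
            for g, ratio in true_ratios.items():
                ct = target_base[g]
                if cond == "DNMC":
                    ct -= np.log2(ratio)
                genes[g] = ct
            for gene, ct0 in genes.items():
                for rep in range(1, n_replicates + 1):
                    noise = rng.normal(0.0, sd_ct) if sd_ct > 0 else 0.0
                    rows.append(
                        {
                            "patient_id": patient,
                            "sample": cond,
                            "gene": gene,
                            "replicate": rep,
                            "ct": ct0 + shift + noise,
                        }
                    )
    table = CtTable(data=pd.DataFrame(rows))
    truth = TruthLabels(ct_true_ratios=pd.Series(true_ratios))
    return table, truth
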