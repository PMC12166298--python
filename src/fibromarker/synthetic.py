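"""Synthetic cohorts with the statistical structure the pipeline assumes.

Emulates the study design: nine patients each contributing matched samples
from an ileal stricture and the non-strictured proximal and distal margins,
with a desk-scale transcriptome (~2,000 genes). Expression is multivariate
log-normal on the log2 scale: a gene-specific baseline, a per-patient random
intercept (matched-sample pairing), exchangeable correlation within
contiguous gene blocks, and a +/- effect_log2fc mean shift in the stricture
site for a configurable set of injected differentially expressed genes
(default 81: 64 up, 17 down). A paired qPCR generator produces target and
housekeeping Ct values for the ddCt stage.

All randomness flows from one seed: ``numpy.random.SeedSequence(seed)`` is
spawned into independent child streams, stream 0 for expression and stream 1
for qPCR, so either table can be regenerated without the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import SITES, STRICTURE, ExpressionMatrix


@dataclass
class CohortDesign:
    """Parameters of the simulated matched three-site cohort.

    Defaults mirror the study conditions: 9 patients x 3 sites, ~2,000
    genes, 64 up- and 17 down-regulated injected DEGs with a 1.5 log2-unit
    shift, per-sample log2 noise SD 1.0, per-patient intercept SD 0.5, and
    exchangeable correlation 0.6 within contiguous 50-gene blocks.
    """

    n_patients: int = 9
    sites: tuple = SITES
    n_genes: int = 2000
    n_deg_up: int = 64
    n_deg_down: int = 17
    effect_log2fc: float = 1.5
    block_size: int = 50
    within_block_corr: float = 0.6
    noise_sd_log2: float = 1.0
    patient_sd_log2: float = 0.5
    baseline_log2_range: tuple = (0.0, 10.0)
    # Signature genes are well-expressed (qPCR-quantifiable) transcripts, so
    # their baseline stays above the <1-transformed-count exclusion rule.
    deg_baseline_log2_min: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if tuple(self.sites) != SITES:
            raise ValueError(f"sites must be exactly {SITES}, got {tuple(self.sites)}")
        if self.n_deg_up + self.n_deg_down > self.n_genes:
            raise ValueError("n_deg_up + n_deg_down exceeds n_genes")
        if not 0.0 <= self.within_block_corr < 1.0:
            raise ValueError("within_block_corr must lie in [0, 1)")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be non-negative")
        if self.noise_sd_log2 <= 0:
            raise ValueError("noise_sd_log2 must be positive")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")


@dataclass
class QpcrTruth:
    """Ground truth for the qPCR generator: per-site mean dCt shifts.

    ``shifts`` maps each site to the mean shift (in cycles) of the target
    gene's dCt relative to the calibrator site, whose shift must be 0. A
    negative shift means higher expression (fewer cycles to threshold).
    """

    gene: str
    shifts: Mapping[str, float] = field(default_factory=lambda: {s: 0.0 for s in SITES})
    ct_noise_sd: float = 0.25
    calibrator_site: str = "proximal"
    target_baseline_ct: float = 25.0
    housekeeping_ct: float = 18.0

    def validate(self, sites=SITES) -> None:
        unknown = sorted(set(self.shifts) - set(sites))
        if unknown:
            raise ValueError(f"unknown site label in shifts: {unknown}")
        missing = sorted(set(sites) - set(self.shifts))
        if missing:
            raise ValueError(f"shifts missing for sites: {missing}")
        if abs(self.shifts[self.calibrator_site]) > 1e-12:
            raise ValueError("shift for the calibrator site must be 0")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be non-negative")


def _streams(seed: int, n: int = 4):
    """Split one master seed into independent child bit-generator seeds."""
    return np.random.SeedSequence(seed).spawn(n)


def generate_cohort(design: CohortDesign) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate a matched three-site cohort.

    Returns
    -------
    (matrix, metadata, truth)
        ``matrix`` is TPM-scale (2**log2-values), genes x samples;
        ``metadata`` has columns sample_id, patient_id, site; ``truth`` has
        one row per gene with is_deg, direction and injected_log2fc.
    """
    design.validate()
    rng = np.random.default_rng(_streams(design.seed)[0])

    g, p = design.n_genes, design.n_patients
    genes = [f"G{i + 1:05d}" for i in range(g)]
    patients = [f"P{i + 1:02d}" for i in range(p)]

    # --- truth ----------------------------------------------------------
    n_deg = design.n_deg_up + design.n_deg_down
    deg_idx = rng.choice(g, size=n_deg, replace=False) if n_deg else np.array([], dtype=int)
    up_idx = deg_idx[: design.n_deg_up]
    down_idx = deg_idx[design.n_deg_up:]
    injected = np.zeros(g)
    injected[up_idx] = design.effect_log2fc
    injected[down_idx] = -design.effect_log2fc
    direction = np.full(g, "null", dtype=object)
    direction[up_idx] = "up"
    direction[down_idx] = "down"
    truth = pd.DataFrame(
        {
            "gene": genes,
            "is_deg": direction != "null",
            "direction": direction,
            "injected_log2fc": injected,
        }
    )

    # --- baselines ------------------------------------------------------
    lo, hi = design.baseline_log2_range
    baseline = rng.uniform(lo, hi, size=g)
    if n_deg:
        baseline[deg_idx] = rng.uniform(max(lo, design.deg_baseline_log2_min), hi, size=n_deg)

    # --- samples --------------------------------------------------------
    site_order = list(design.sites)
    sample_ids, patient_col, site_col = [], [], []
    for pat in patients:
        for site in site_order:
            sample_ids.append(f"{pat}_{site}")
            patient_col.append(pat)
            site_col.append(site)
    meta = pd.DataFrame({"sample_id": sample_ids, "patient_id": patient_col, "site": site_col})
    n_samples = len(sample_ids)

    intercept = rng.normal(0.0, design.patient_sd_log2, size=p)
    sample_intercept = np.repeat(intercept, len(site_order))
    is_stricture = np.array([s == STRICTURE for s in site_col], dtype=float)

    # Exchangeable within-block noise: shared block factor + gene residual.
    rho = design.within_block_corr
    block_of = np.arange(g) // design.block_size
    n_blocks = block_of.max() + 1
    eta = rng.normal(size=(n_blocks, n_samples))          # block factors
    eps = rng.normal(size=(g, n_samples))                 # gene residuals
    noise = design.noise_sd_log2 * (np.sqrt(rho) * eta[block_of] + np.sqrt(1.0 - rho) * eps)

    log2 = baseline[:, None] + sample_intercept[None, :] + injected[:, None] * is_stricture[None, :] + noise
    tpm = np.exp2(log2)
    matrix = ExpressionMatrix(pd.DataFrame(tpm, index=genes, columns=sample_ids), scale="tpm")
    return matrix, meta, truth


def generate_qpcr(design: CohortDesign, truth: QpcrTruth) -> pd.DataFrame:
    """Simulate a paired Ct table (target + housekeeping per sample).

    Per sample: housekeeping Ct = its fixed baseline + noise; target Ct =
    target baseline + the site's mean dCt shift + noise. Noise is Gaussian
    on the cycle scale with SD ``truth.ct_noise_sd``; seeded from the
    design's qPCR stream (stream 1).
    """
    design.validate()
    truth.validate(design.sites)
    rng = np.random.default_rng(_streams(design.seed)[1])

    rows = []
    for i in range(design.n_patients):
        pat = f"P{i + 1:02d}"
        for site in design.sites:
            ct_hk = truth.housekeeping_ct + rng.normal(0.0, truth.ct_noise_sd)
            ct_t = truth.target_baseline_ct + truth.shifts[site] + rng.normal(0.0, truth.ct_noise_sd)
            rows.append(
                {
                    "sample_id": f"{pat}_{site}",
                    "patient_id": pat,
                    "site": site,
                    "gene": truth.gene,
                    "ct_target": ct_t,
                    "ct_housekeeping": ct_hk,
                }
            )
    table = pd.DataFrame(rows)
    bad = table[(table[["ct_target", "ct_housekeeping"]] <= 0).any(axis=1)
                | (table[["ct_target", "ct_housekeeping"]] > 45).any(axis=1)]
    if len(bad):
        warnings.warn(f"{len(bad)} simulated Ct values fall outside (0, 45]", stacklevel=2)
    return table
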