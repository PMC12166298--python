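"""Relative qPCR quantification by the 2^-ddCt method.

Per sample, dCt = Ct(target) - Ct(housekeeping); ddCt subtracts the same
patient's calibrator-site dCt (proximal margin by default, so the matched
design cancels patient effects); relative quantity rq = 2^-ddCt, equal to 1
for calibrator samples by construction. Site groups are compared by the
Kruskal-Wallis rank test (tie-corrected H, chi-square on k-1 df) and
summarised as medians with percentile-bootstrap confidence intervals.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ddct", "kruskal_wallis", "median_ci"]

_CT_COLUMNS = ("sample_id", "patient_id", "site", "gene", "ct_target", "ct_housekeeping")


def _validate_ct(ct: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    vals = ct[["ct_target", "ct_housekeeping"]].to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)) or np.any(vals <= 0) or np.any(vals > 45):
        raise ValueError("Ct values must lie in (0, 45]")
    return ct


def ddct(ct: pd.DataFrame, calibrator_site: str = "proximal") -> pd.DataFrame:
    """Relative expression per sample and gene by 2^-ddCt.

    Technical replicates (duplicate sample/gene rows) are averaged on the
    Ct scale first. Samples of a patient lacking a calibrator-site sample
    for a gene are excluded with a warning.
    """
    ct = _validate_ct(ct)
    # average technical replicates on the Ct scale
    ct = (
        ct.groupby(["sample_id", "patient_id", "site", "gene"], as_index=False, sort=False)[
            ["ct_target", "ct_housekeeping"]
        ].mean()
    )
    ct = ct.assign(delta_ct=ct["ct_target"] - ct["ct_housekeeping"])

    out = []
    for gene, sub in ct.groupby("gene", sort=False):
        cal = sub[sub["site"] == calibrator_site].set_index("patient_id")["delta_ct"]
        if cal.index.has_duplicates:
            raise ValueError(f"multiple calibrator-site samples per patient for {gene}")
        has_cal = sub["patient_id"].isin(cal.index)
        if (~has_cal).any():
            dropped = sorted(sub.loc[~has_cal, "patient_id"].unique())
            warnings.warn(
                f"{gene}: no {calibrator_site} calibrator for patients {dropped}; "
                "their samples are excluded", stacklevel=2,
            )
        sub = sub[has_cal].copy()
        sub["delta_delta_ct"] = sub["delta_ct"] - cal.loc[sub["patient_id"]].to_numpy()
        out.append(sub)
    res = pd.concat(out, ignore_index=True)
    res["rq"] = np.exp2(-res["delta_delta_ct"])
    return res


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square P on k-1 df.

    ``groups`` is a sequence of value vectors (one per site) or a mapping
    site -> values. All-identical values give (0, 1) by convention.
    """
    if isinstance(groups, dict):
        groups = list(groups.values())
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need at least 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def median_ci(values, n_boot: int = 2000, level: float = 0.95, seed=None):
    """Sample median with a seeded percentile-bootstrap confidence interval."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("median_ci needs at least 3 values")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    meds = np.median(
        rng.choice(values, size=(n_boot, values.size), replace=True), axis=1
    )
    lo, hi = np.quantile(meds, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(np.median(values)), float(lo), float(hi)
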