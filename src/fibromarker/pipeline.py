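"""End-to-end pipeline driver: preprocess -> DEG -> overlap -> PLS-DA ->
panel AUC -> power curves, with a reproducibility manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import STRICTURE, align_metadata
from .differential import ContrastSpec, fit_eb_prior, moderated_t, overlap_deg
from .io import read_expression_tsv, read_metadata_tsv, write_expression_tsv
from .panel import PanelSpec, rf_panel_auc
from .plsda import PLSDA, cross_validate, select_genes
from .power import DEFAULT_GRID, EffectSpec, cohens_d, fit_lognormal, power_curve, required_n
from .preprocess import filter_genes, log_transform

CONTRASTS = (
    ContrastSpec("stricture_vs_proximal", "stricture", "proximal"),
    ContrastSpec("stricture_vs_distal", "stricture", "distal"),
    ContrastSpec("proximal_vs_distal", "proximal", "distal"),
)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""


@dataclass
class PipelineConfig:
    expression_tsv: str
    metadata_tsv: str
    out_dir: str
    input_scale: str = "tpm"
    alpha: float = 0.05
    fc_threshold: float = 2.0
    variance_quantile: float = 0.10
    paired: bool = True
    n_components: int = 2
    vip_threshold: float = 1.0
    panel_size: int = 8
    rf_trees: int = 500
    rf_scheme: str = "cv"
    power_grid: tuple = DEFAULT_GRID
    power_reps: int = 1000
    power_genes: int = 3
    qpcr_calibrator: str = "proximal"
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if not 0 <= self.variance_quantile < 1:
            raise ValueError("variance_quantile must lie in [0, 1)")
        if self.vip_threshold < 0:
            raise ValueError("vip_threshold must be non-negative")
        if self.input_scale not in ("tpm", "log"):
            raise ValueError("input_scale must be 'tpm' or 'log'")
        if self.rf_scheme not in ("cv", "oob", "resub"):
            raise ValueError("rf_scheme must be 'cv', 'oob' or 'resub'")
        if list(self.power_grid) != sorted(set(int(n) for n in self.power_grid)):
            raise ValueError("power_grid must be strictly increasing")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; writes outputs plus a run manifest, returns it."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31 - 1))
        for name, s in zip(
            ("classify", "power"), np.random.SeedSequence(config.seed).spawn(2)
        )
    }
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "software_version": __version__,
        "stage_seeds": stage_seeds,
        "input_checksums": {
            "expression": _sha256(config.expression_tsv),
            "metadata": _sha256(config.metadata_tsv),
        },
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # re-tag with the stage name
                raise PipelineError(f"[{name}] {exc}") from exc
        return wrap

    # preprocess -------------------------------------------------------
    def _preprocess():
        m = read_expression_tsv(config.expression_tsv, scale=config.input_scale)
        meta = read_metadata_tsv(config.metadata_tsv)
        meta = align_metadata(m, meta)
        if m.scale == "tpm":
            m = log_transform(m)
        filtered, report = filter_genes(m, variance_quantile=config.variance_quantile)
        write_expression_tsv(filtered, out / "filtered_log2.tsv")
        manifest["stages"]["preprocess"] = {
            "n_input_genes": report.n_input_genes,
            "n_removed_low_count": report.n_removed_low_count,
            "n_removed_low_variance": report.n_removed_low_variance,
            "n_retained": len(report.retained_genes),
        }
        return filtered, meta
    filtered, meta = stage("preprocess")(_preprocess)

    # differential expression ------------------------------------------
    def _deg():
        pairing = "paired" if config.paired else "unpaired"
        results = {}
        for spec in CONTRASTS:
            spec = ContrastSpec(spec.name, spec.group_a, spec.group_b, pairing)
            res = moderated_t(spec, filtered, meta,
                              alpha=config.alpha, fc_threshold=config.fc_threshold)
            res.to_csv(out / f"deg_{spec.name}.tsv", sep="\t")
            results[spec.name] = res
        ov = overlap_deg(results["stricture_vs_proximal"], results["stricture_vs_distal"])
        ov.genes.to_csv(out / "deg_overlap.tsv", sep="\t")
        manifest["stages"]["deg"] = {
            "per_contrast_deg": {k: int(v["is_deg"].sum()) for k, v in results.items()},
            "overlap": {"n_up": ov.n_up, "n_down": ov.n_down, "n_overlap": ov.n_overlap},
        }
        return results, ov
    deg_results, overlap = stage("deg")(_deg)

    # PLS-DA / VIP selection -------------------------------------------
    def _select():
        X = filtered.to_samples_by_genes()
        y = (meta["site"] == STRICTURE).astype(int).to_numpy()
        model = PLSDA(n_components=config.n_components).fit(X, y)
        cv = cross_validate(X, y, n_components=config.n_components)
        sel = select_genes(model, threshold=config.vip_threshold)
        ranked = pd.DataFrame(
            {"vip": model.vip_, "selected": model.vip_ > config.vip_threshold},
            index=model.genes_,
        ).sort_values("vip", ascending=False)
        ranked.to_csv(out / "vip_ranked.tsv", sep="\t")
        summary = {
            "r2_cum": cv["r2"].tolist(),
            "q2_cum": cv["q2"].tolist(),
            "recommended_components": cv.attrs["recommended"],
            "n_selected": len(sel.genes),
            "vip_threshold": config.vip_threshold,
        }
        (out / "plsda_summary.json").write_text(json.dumps(summary, indent=2))
        manifest["stages"]["select"] = summary
        return model, sel, ranked
    model, selection, ranked = stage("select")(_select)

    # panel AUC ---------------------------------------------------------
    def _classify():
        panel_genes = ranked.index[: config.panel_size].tolist()
        y = (meta["site"] == STRICTURE).to_numpy()
        res = rf_panel_auc(
            filtered, y, PanelSpec("top_vip_panel", panel_genes),
            n_trees=config.rf_trees, scheme=config.rf_scheme,
            seed=stage_seeds["classify"],
        )
        res.scores.to_csv(out / "panel_scores.tsv", sep="\t")
        payload = {
            "panel": res.panel, "genes": panel_genes, "auc": res.auc,
            "ci_low": res.ci_low, "ci_high": res.ci_high,
            "n_pos": res.n_pos, "n_neg": res.n_neg, "scheme": res.scheme,
        }
        (out / "panel_auc.json").write_text(json.dumps(payload, indent=2))
        manifest["stages"]["classify"] = {"auc": res.auc, "genes": panel_genes}
        return res
    stage("classify")(_classify)

    # power curves ------------------------------------------------------
    def _power():
        y = (meta["site"] == STRICTURE).to_numpy()
        X = filtered.to_samples_by_genes()
        genes = ranked.index[: config.power_genes].tolist()
        rows, info = [], {}
        for k, gene in enumerate(genes):
            vals = X[gene].to_numpy()
            d = cohens_d(vals[y], vals[~y])
            mdl = fit_lognormal(filtered, [gene])
            curve = power_curve(
                mdl, EffectSpec(gene, d=abs(d)), n_grid=config.power_grid,
                n_reps=config.power_reps, alpha=config.alpha,
                seed=stage_seeds["power"] + k,
            )
            frame = curve.to_frame().assign(gene=gene, d=d)
            rows.append(frame)
            info[gene] = {"d": d, "required_n_75": required_n(curve, 0.75)}
        pd.concat(rows, ignore_index=True).to_csv(out / "power_curves.tsv", sep="\t", index=False)
        (out / "power_summary.json").write_text(json.dumps(info, indent=2))
        manifest["stages"]["power"] = info
    stage("power")(_power)

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
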