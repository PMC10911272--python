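"""End-to-end pipeline: simulate -> score -> test -> embed -> quantify.

Every run is driven by a :class:`RunConfig` (one YAML file or keyword
overrides) and a single root seed; all randomness flows through named
substreams of that seed so stages can be re-run independently yet
reproducibly.  Outputs are plain TSV tables plus a JSON manifest holding
the config, its hash and per-stage row counts — identical config and seed
give byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .catalog import SiteCatalog, default_catalog, load_site_catalog
from .design import StudyDesign, default_design
from .scoring import (
    EndCountProfile,
    RMSScoreTable,
    ScoreParams,
    compute_rms_scores,
    merge_technical_replicates,
    read_end_counts,
    write_end_counts,
)
from .simulate import (
    FragmentationParams,
    build_truth,
    donor_dominant_preset,
    growth_arrest_preset,
    simulate_band_intensities,
    simulate_end_counts,
    simulate_snoRNA_expression,
)
from .stats import (
    bh_adjust,
    classify_sites,
    eliminate_factor,
    embed_samples,
    fit_blocked_anova,
    results_to_frame,
    tukey_pairwise,
)
from .quant import correlate_expression_methylation, processing_ratios

__all__ = ["RunConfig", "simulate_run", "run_full_pipeline", "GROWTH_ARREST_BAND_MEANS"]

PRESETS = {
    "growth_arrest": growth_arrest_preset,
    "donor_dominant": donor_dominant_preset,
}

#: default per-state mean band intensities for the simulated northern blot:
#: arrested states shift toward processing pathway B (higher 30S:41S) and
#: senescent cells lose late SSU intermediates (lower 21S, 18S-E).
GROWTH_ARREST_BAND_MEANS: dict[str, dict[str, float]] = {
    "P": {"47S": 100.0, "45S": 80.0, "41S": 60.0, "30S": 30.0, "21S": 50.0,
          "18S-E": 40.0, "32S": 70.0, "12S": 20.0, "28S": 200.0},
    "Q": {"47S": 100.0, "45S": 80.0, "41S": 60.0, "30S": 45.0, "21S": 50.0,
          "18S-E": 40.0, "32S": 70.0, "12S": 20.0, "28S": 200.0},
    "SIPS": {"47S": 100.0, "45S": 80.0, "41S": 60.0, "30S": 45.0, "21S": 35.0,
             "18S-E": 28.0, "32S": 70.0, "12S": 20.0, "28S": 200.0},
}


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    preset: str = "growth_arrest"
    catalog_path: str | None = None  # None -> bundled 104-site catalog
    counts_dir: str | None = None  # None -> <out_dir>/counts
    design_path: str | None = None  # None -> <out_dir>/design.tsv
    # scoring
    window: int = 2
    min_flank_mean: float = 10.0
    # statistics
    q_cutoff: float = 0.1
    high_cutoff: float = 0.9
    alpha: float = 0.05
    # embedding
    perplexity: float = 3.0
    embed_method: str = "tsne"
    # simulation
    depth_per_bond: float = 3000.0
    protection: float = 1.0
    coupling: float = 0.9
    expr_noise_sd: float = 0.01
    band_noise_cv: float = 0.05

    def __post_init__(self) -> None:
        for name in ("q_cutoff", "high_cutoff", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {list(PRESETS)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    def load_catalog(self) -> SiteCatalog:
        if self.catalog_path is None:
            return default_catalog()
        return load_site_catalog(self.catalog_path)

    def score_params(self) -> ScoreParams:
        return ScoreParams(window=self.window, min_flank_mean=self.min_flank_mean)


def _write_manifest(out: Path, config: RunConfig, stages: dict, complete: bool) -> None:
    manifest = {
        "package": "ribomethdiff",
        "version": __version__,
        "config": config.to_dict(),
        "config_sha256": config.sha256(),
        "seed": config.seed,
        "stages": stages,
        "complete": complete,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def simulate_run(config: RunConfig) -> Path:
    """Generate a ground-truthed dataset under ``config.out_dir``.

    Writes design.tsv, truth.tsv, counts/<library>.tsv, expression.tsv and
    bands.tsv, plus a manifest."""
    out = Path(config.out_dir)
    (out / "counts").mkdir(parents=True, exist_ok=True)
    catalog = config.load_catalog()
    design = default_design()
    truth = build_truth(catalog, design, seed=config.seed, **PRESETS[config.preset]())
    params = FragmentationParams(
        depth_per_bond=config.depth_per_bond,
        protection=config.protection,
        seed=config.seed,
    )
    profiles = simulate_end_counts(truth, params, catalog)
    design.write(out / "design.tsv")
    truth.write(out / "truth.tsv")
    for prof in profiles:
        write_end_counts(prof, out / "counts" / f"{prof.sample_id}.tsv")
    expr = simulate_snoRNA_expression(
        truth, catalog, coupling=config.coupling,
        noise_sd=config.expr_noise_sd, seed=config.seed,
    )
    expr.to_csv(out / "expression.tsv", sep="\t", index_label="target", float_format="%.6g")
    bands = simulate_band_intensities(
        GROWTH_ARREST_BAND_MEANS, config.band_noise_cv, design, seed=config.seed
    )
    bands.to_csv(out / "bands.tsv", sep="\t", index_label="species", float_format="%.6g")
    _write_manifest(
        out,
        config,
        {"simulate": {"status": "ok", "libraries": len(profiles), "sites": len(catalog)}},
        complete=True,
    )
    return out


def _load_profiles(config: RunConfig, catalog: SiteCatalog, design: StudyDesign):
    counts_dir = Path(config.counts_dir or Path(config.out_dir) / "counts")
    profiles = []
    for sample in design:
        path = counts_dir / f"{sample.sample_id}.tsv"
        if not path.exists():
            raise FileNotFoundError(
                f"stage score: no count file for design sample {sample.sample_id!r} "
                f"(expected {path})"
            )
        profiles.append(read_end_counts(path, catalog.reference_lengths,
                                        sample_id=sample.sample_id))
    return profiles


def score_stage(config: RunConfig) -> RMSScoreTable:
    out = Path(config.out_dir)
    catalog = config.load_catalog()
    design = StudyDesign.read(config.design_path or out / "design.tsv")
    profiles = _load_profiles(config, catalog, design)
    merged = merge_technical_replicates(profiles, design)
    table = compute_rms_scores(merged, catalog, config.score_params())
    table.write(out / "scores.tsv")
    return table


def diff_stage(config: RunConfig, scores: RMSScoreTable | None = None):
    out = Path(config.out_dir)
    design = StudyDesign.read(config.design_path or out / "design.tsv")
    if scores is None:
        scores = RMSScoreTable.read(out / "scores.tsv")
    results = fit_blocked_anova(scores, design)
    p = [r.p_state if not r.skipped else float("nan") for r in results]
    q = bh_adjust(p)
    for r, qv in zip(results, q):
        r.q_state = float(qv)
    for r in results:
        if not r.skipped:
            r.tukey_p = tukey_pairwise(scores, design, r.site)
    classify_sites(results, scores, config.high_cutoff, config.q_cutoff)
    results_to_frame(results).to_csv(out / "results.tsv", sep="\t", float_format="%.6g")
    raw = embed_samples(scores, seed=config.seed, method=config.embed_method,
                        perplexity=config.perplexity)
    raw.write(out / "embedding_raw.tsv")
    adjusted = eliminate_factor(scores, design, "donor")
    adj = embed_samples(adjusted, seed=config.seed, method=config.embed_method,
                        perplexity=config.perplexity, eliminated_factor="donor")
    adj.write(out / "embedding_donor_eliminated.tsv")
    return results, raw, adj


def correlate_stage(config: RunConfig, scores: RMSScoreTable | None = None):
    out = Path(config.out_dir)
    expr_path = out / "expression.tsv"
    if not expr_path.exists():
        return None
    if scores is None:
        scores = RMSScoreTable.read(out / "scores.tsv")
    catalog = config.load_catalog()
    expr = pd.read_csv(expr_path, sep="\t", index_col="target")
    records = correlate_expression_methylation(scores, expr, catalog)
    df = pd.DataFrame(
        [
            {"site": r.site, "guide": r.guide, "n": r.n, "pearson_r": r.pearson_r,
             "spearman_r": r.spearman_r, "status": r.status}
            for r in records
        ]
    )
    df.to_csv(out / "correlations.tsv", sep="\t", index=False, float_format="%.6g")
    return records


def ratios_stage(config: RunConfig):
    out = Path(config.out_dir)
    bands_path = out / "bands.tsv"
    if not bands_path.exists():
        return None
    design = StudyDesign.read(config.design_path or out / "design.tsv")
    bands = pd.read_csv(bands_path, sep="\t", index_col="species")
    results = processing_ratios(bands, design)
    rows = []
    for r in results:
        for sid, v in r.normalized.items():
            rows.append({"ratio": r.name, "sample": sid, "normalized": v})
        for state, tt in r.state_tests.items():
            rows.append({"ratio": r.name, "sample": f"t-test:{state}",
                         "normalized": float("nan"), "t": tt.t, "p": tt.p, "df": tt.df})
    pd.DataFrame(rows).to_csv(out / "ratios.tsv", sep="\t", index=False,
                              float_format="%.6g")
    return results


def run_full_pipeline(config: RunConfig, simulate: bool = True) -> Path:
    """Run every stage under ``config.out_dir``; abort names the failing stage."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}
    try:
        if simulate:
            stage = "simulate"
            simulate_run(config)
            stages[stage] = {"status": "ok"}
        stage = "score"
        scores = score_stage(config)
        stages[stage] = {"status": "ok", "sites": int(scores.scores.shape[0]),
                         "samples": int(scores.scores.shape[1])}
        stage = "diff"
        results, _, _ = diff_stage(config, scores)
        n_var = sum(1 for r in results if r.classification == "variable")
        stages[stage] = {"status": "ok", "sites_tested": len(results),
                         "variable_sites": n_var}
        stage = "correlate"
        recs = correlate_stage(config, scores)
        stages[stage] = {"status": "ok", "records": len(recs) if recs else 0}
        stage = "ratios"
        rres = ratios_stage(config)
        stages[stage] = {"status": "ok", "ratios": len(rres) if rres else 0}
    except Exception as exc:
        stages[stage] = {"status": "failed", "error": str(exc)}
        _write_manifest(out, config, stages, complete=False)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    _write_manifest(out, config, stages, complete=True)
    return out
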