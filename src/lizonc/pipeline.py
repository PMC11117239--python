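"""End-to-end analysis pipeline: simulate/load -> validate -> fit ->
permutation test -> survival -> summaries, with a reproducibility manifest.

Every stage writes inspectable CSV/JSON artifacts to the output directory;
the manifest records the seed, a hash of the configuration, and a checksum
per output file, so two runs with the same configuration are verifiably
identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from . import boosting, datasets, permutation, summaries, survival, synthetic
from .cohort import (
    Cohort,
    MODEL_VARIABLES,
    encode_outcomes,
    read_cohort,
    subset_by_indices,
    write_cohort,
)

log = logging.getLogger("lizonc")

STAGES = ("simulate", "validate", "fit", "permtest", "survival", "summarize")


@dataclass
class RunConfig:
    """Pipeline settings; defaults reproduce the published analysis
    settings where stated (B=2000 permutations, alpha=0.05, a minimum of
    two individuals per assessed level, the eight predictor variables)."""

    input_path: str | None = None          # cohort CSV; None -> simulate
    synthetic_n: int = 274
    variables: Sequence[str] = MODEL_VARIABLES
    mstop: int = 100
    nu: float = 0.1
    df: float = 4.0
    B: int = 2000
    alpha: float = 0.05
    min_n: int = 2
    seed: int = 0
    outdir: str = "lizonc_run"
    tail_rule: str = "absolute"            # or "percentile"
    unknown_death: str = "non_neoplastic"  # or "exclude"

    def hyperparams(self) -> boosting.BoostHyperparams:
        return boosting.BoostHyperparams(mstop=self.mstop, nu=self.nu, df=self.df)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["variables"] = list(d["variables"])
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns the manifest (also written to
    ``manifest.json`` in the output directory)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "stages": [],
        "outputs": {},
    }
    outputs: list[Path] = []

    def stage(name):
        log.info("stage %s", name)
        manifest["stages"].append(name)

    try:
        stage("simulate")
        if config.input_path is not None:
            cohort = read_cohort(config.input_path)
        else:
            syn = synthetic.default_config(n_records=config.synthetic_n,
                                           seed=config.seed)
            cohort = synthetic.generate_cohort(syn)
        cohort_path = outdir / "cohort.csv"
        write_cohort(cohort, cohort_path)
        outputs.append(cohort_path)

        stage("validate")
        from .cohort import validate_cohort
        report = validate_cohort(cohort)
        vpath = outdir / "validation.csv"
        report.to_frame().to_csv(vpath, index=False)
        outputs.append(vpath)
        vocab_path = outdir / "vocabularies.json"
        vocab_path.write_text(json.dumps(cohort.vocabularies, indent=2))
        outputs.append(vocab_path)

        stage("fit")
        hp = config.hyperparams()
        log.info("hyperparameters: mstop=%d nu=%g df=%g tail_rule=%s "
                 "unknown_death=%s", hp.mstop, hp.nu, hp.df,
                 config.tail_rule, config.unknown_death)
        y, included = encode_outcomes(cohort, unknown_death=config.unknown_death)
        modeled = subset_by_indices(cohort, included)
        blocks = boosting.build_design(modeled, config.variables)
        fit = boosting.fit_boost(blocks, y.to_numpy(), hp)
        effects = boosting.extract_effects(fit, blocks)
        epath = outdir / "effects.csv"
        effects.to_csv(epath, index=False)
        outputs.append(epath)

        stage("permtest")
        if config.B <= 0:
            raise ValueError("permtest requires B >= 1 permutations")
        nulls = permutation.null_distributions(
            blocks, y.to_numpy(), config.B, hp, seed=config.seed
        )
        sig = permutation.significance_table(
            effects, nulls, alpha=config.alpha, min_n=config.min_n,
            tail_rule=config.tail_rule,
        )
        spath = outdir / "significance.csv"
        sig.to_csv(spath, index=False)
        outputs.append(spath)

        stage("survival")
        grouped = survival.group_survival(cohort)
        for (malig, status), curve in grouped.curves.items():
            cpath = outdir / f"km_{malig}_{status}.csv"
            curve.to_frame().to_csv(cpath, index=False)
            outputs.append(cpath)
        plot_path = outdir / "km_curves.png"
        survival.plot_km(grouped.curves, plot_path)

        stage("summarize")
        for var in ("species_scientific", "diagnosis", "treatment", "outcome"):
            t = summaries.frequency_table(cohort, var)
            fpath = outdir / f"freq_{var}.csv"
            t.to_csv(fpath, index=False)
            outputs.append(fpath)
        surv_sum = summaries.survival_time_summary(cohort, by_source=True)
        sspath = outdir / "survival_summary.json"
        sspath.write_text(json.dumps(
            {src: dataclasses.asdict(s) for src, s in surv_sum.items()}, indent=2
        ))
        outputs.append(sspath)
        dpath = outdir / "discrepancies.json"
        datasets.export_discrepancies(dpath)
        outputs.append(dpath)
    except Exception as exc:
        failed_stage = manifest["stages"][-1] if manifest["stages"] else "setup"
        manifest["failed_stage"] = failed_stage
        manifest["partial_outputs"] = [str(p) for p in outputs]
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {failed_stage!r} failed: {exc}") from exc

    manifest["outputs"] = {p.name: _sha256(p) for p in outputs}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
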