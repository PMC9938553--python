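"""One-shot end-to-end run on synthetic data, with a reproducibility manifest.

Stage order: simulate (beta matrix, stool plate, tissue plate, roster) →
screen → call → split → fit → cut-off → classify validation → evaluate.
A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence(global_seed).generate_state(...)``, so each stage
is individually reproducible; every output file's SHA-256 goes into the
manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import io as cio
from .model import SplitConfig, classify, fit_model, roc_auc, select_cutoff, stratified_split
from .qmsp import CallThresholds, process_plate
from .screening import ScreenConfig, run_screen
from .synth import (
    BetaSimConfig,
    QmspSimConfig,
    generate_beta_matrix,
    generate_paired_tissue_plate,
    generate_plate,
    generate_roster,
)

STAGES = ("beta", "stool_plate", "tissue_plate", "roster", "split", "screen")


def stage_seeds(global_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds derived from one global seed."""
    state = np.random.SeedSequence(global_seed).generate_state(len(STAGES))
    return {name: int(s % (2**31)) for name, s in zip(STAGES, state)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_end_to_end(out_dir, seed: int = 0) -> dict:
    """Simulate, screen, call, split, fit and evaluate; write all reports.

    Returns the run manifest (also written to ``manifest.json``): seeds,
    per-stage summary numbers, and SHA-256 hashes of every output file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(seed)
    manifest: dict = {"global_seed": seed, "stage_seeds": seeds, "stages": {}}

    # --- simulate + screen the discovery beta matrix
    bcfg = BetaSimConfig(seed=seeds["beta"])
    matrix, truth = generate_beta_matrix(bcfg)
    cio.write_beta_matrix(matrix, out / "beta.tsv", out / "beta_samples.tsv")
    cio.write_annotation(truth, out / "annotation.tsv")
    truth.to_csv(out / "beta_truth.tsv", sep="\t", index=False)
    scfg = ScreenConfig(seed=seeds["screen"])
    report = run_screen(matrix, scfg, annotation=truth.set_index("site_id")["gene"])
    report.site_table.rename_axis("site_id").to_csv(out / "screen_sites.tsv", sep="\t")
    (out / "screen_summary.json").write_text(json.dumps(report.summary(), indent=2))
    manifest["stages"]["screen"] = report.summary()

    # --- simulate + call the stool plate
    qcfg = QmspSimConfig(
        group_sizes={"NED": 36, "AA": 14, "CRC_I_II": 28, "CRC_III_IV": 20, "interfering": 6},
        matrix="stool",
        seed=seeds["stool_plate"],
    )
    plate, samples = generate_plate(qcfg)
    cio.write_plate(plate, out / "stool_plate.csv")
    samples.to_csv(out / "stool_samples.tsv", sep="\t", index=False)
    thresholds = CallThresholds()
    result = process_plate(plate, thresholds, samples.set_index("sample_id")["group"])
    result.calls.to_csv(out / "stool_calls.tsv", sep="\t", index=False)
    result.invalid.to_csv(out / "stool_invalid.tsv", sep="\t", index=False)
    manifest["stages"]["call"] = {
        "n_called": int(result.calls["sample_id"].nunique()),
        "n_invalid": int(len(result.invalid)),
    }

    # --- tissue plate: paired delta-Ct comparison
    tplate, tsamples = generate_paired_tissue_plate(n_pairs=40, seed=seeds["tissue_plate"])
    cio.write_plate(tplate, out / "tissue_plate.csv")
    tres = process_plate(tplate, thresholds, tsamples.set_index("sample_id")["group"])
    tres.delta_ct.to_csv(out / "tissue_delta_ct.tsv", sep="\t", index=False)
    paired = {}
    dct = tres.delta_ct.merge(tsamples[["sample_id", "pair_id"]], on="sample_id")
    for marker, sub in dct.groupby("target"):
        wide = sub.pivot(index="pair_id", columns="group", values="delta_ct").dropna()
        paired[marker] = ev.paired_tissue_comparison(wide["tumor"], wide["normal"])
    manifest["stages"]["tissue"] = paired

    # --- split / fit / cut-off / validate on the stool calls
    wide = result.calls.pivot_table(index="sample_id", columns="marker", values="mean_ct")
    meta = result.calls.drop_duplicates("sample_id").set_index("sample_id")["group"]
    main = meta[meta != "interfering"]
    labels = (main != "NED").astype(int)
    train_ids, val_ids = stratified_split(main, SplitConfig(seed=seeds["split"]))
    fitted = fit_model(wide.loc[train_ids], labels.loc[train_ids])
    (out / "model.json").write_text(fitted.to_json())
    train_scores = np.asarray(fitted.score(wide.loc[train_ids]))
    cutoff = select_cutoff(train_scores, labels.loc[train_ids])
    val_calls = classify(fitted, cutoff, wide.loc[val_ids])
    val_scores = np.asarray(fitted.score(wide.loc[val_ids]))
    roc = roc_auc(val_scores, labels.loc[val_ids])
    sens, spec = ev.performance(val_calls, labels.loc[val_ids], group="validation")
    interfering = meta[meta == "interfering"].index
    neg = ev.negative_rate(
        classify(fitted, cutoff, wide.loc[interfering]).to_numpy(),
        ["interfering"] * len(interfering),
    ) if len(interfering) else None
    perf = pd.DataFrame(
        [
            ("validation", "sensitivity", sens.numerator, sens.n, sens.estimate, sens.ci_low, sens.ci_high),
            ("validation", "specificity", spec.numerator, spec.n, spec.estimate, spec.ci_low, spec.ci_high),
        ],
        columns=["set", "kind", "numerator", "n", "estimate_pct", "ci_low", "ci_high"],
    )
    perf.to_csv(out / "performance.tsv", sep="\t", index=False)
    manifest["stages"]["model"] = {
        "cutoff": cutoff,
        "validation_auc": roc.auc,
        "sensitivity_pct": sens.estimate,
        "specificity_pct": spec.estimate,
        "n_train": len(train_ids),
        "n_validation": len(val_ids),
        "interfering_pooled_negative_pct": None if neg is None else float(neg.iloc[-1]["rate_pct"]),
    }

    # --- roster accounting
    roster = generate_roster(
        515,
        {"incomplete_pathology": 12, "failed_collection": 25, "insufficient_reference": 32},
        n_interfering=24,
        seed=seeds["roster"],
    )
    cio.write_roster(roster, out / "roster.tsv")
    manifest["stages"]["flow"] = ev.account_samples(roster)

    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
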