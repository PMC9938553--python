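"""Candidate CpG-site screening on 450K-style beta-value matrices.

The screening cascade mirrors common practice in methylation biomarker
discovery: a tumor-vs-normal differential filter (effect size, significance
and absolute tumor methylation), a rescreen against peripheral-blood
methylation of non-tumor donors (so that background blood signal cannot
swamp a stool or plasma assay), ranking by effect size, optional restriction
to genes of prior interest, and a final random-forest importance selection
favouring sites that are unmethylated in normal tissue.

Each stage is a pure set filter over per-site statistics; ``run_screen``
composes them and records survivor counts per stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .errors import ConfigError, InputError

GROUPS = ("tumor", "normal", "blood")

#: per-site statistics columns produced by :func:`compute_site_stats`
STAT_COLUMNS = [
    "gene",
    "mean_beta_tumor",
    "mean_beta_normal",
    "mean_beta_blood",
    "delta_beta",
    "p_value",
]


@dataclass
class BetaMatrix:
    """CpG-site x sample methylation fractions with group annotations.

    Parameters
    ----------
    values
        DataFrame indexed by CpG site id with one column per sample;
        entries are beta values in [0, 1] (NaN allowed for missing).
    sample_groups
        Series mapping sample id -> arm, one of ``tumor``/``normal``/``blood``.
    """

    values: pd.DataFrame
    sample_groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise InputError("duplicate CpG site ids in beta matrix")
        missing = set(self.values.columns) - set(self.sample_groups.index)
        if missing:
            raise InputError(f"samples without group annotation: {sorted(missing)[:5]}")
        bad = set(self.sample_groups.loc[list(self.values.columns)]) - set(GROUPS)
        if bad:
            raise InputError(f"unknown sample groups: {sorted(bad)}")
        v = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(v) < 0 or np.nanmax(v) > 1:
                raise InputError("beta values must lie in [0, 1]")

    @property
    def site_ids(self) -> pd.Index:
        return self.values.index

    def arm(self, group: str) -> pd.DataFrame:
        """Sub-matrix of the samples belonging to one arm."""
        cols = [s for s in self.values.columns if self.sample_groups[s] == group]
        if not cols:
            raise InputError(f"beta matrix has no '{group}' samples")
        return self.values[cols]


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and knobs of the screening cascade.

    delta_min : minimum tumor-minus-normal mean beta difference (default 0.2)
    p_max : rank-sum significance threshold, uncorrected (default 0.01)
    beta_tumor_min : minimum mean tumor beta (default 0.2)
    blood_margin_min : minimum tumor-minus-blood mean beta margin (default 0.25)
    blood_rule : 'margin' (default) filters on tumor-minus-blood difference;
        'absolute' excludes sites whose mean blood beta >= blood_beta_max
    gene_whitelist : optional gene symbols to restrict candidates to
    n_select : size of the final marker panel (default 2)
    rf_trees : trees in the random forest used for final selection
    summary : 'mean' (default) or 'median' arm summaries
    p_adjust : None (default, raw P as stated) or 'fdr_bh'
    seed : random-forest seed
    """

    delta_min: float = 0.2
    p_max: float = 0.01
    beta_tumor_min: float = 0.2
    blood_margin_min: float = 0.25
    blood_rule: str = "margin"
    blood_beta_max: float = 0.25
    gene_whitelist: tuple[str, ...] | None = None
    n_select: int = 2
    rf_trees: int = 500
    summary: str = "mean"
    p_adjust: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("delta_min", "p_max", "beta_tumor_min", "blood_margin_min", "blood_beta_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.n_select < 1:
            raise ConfigError("n_select must be >= 1")
        if self.blood_rule not in ("margin", "absolute"):
            raise ConfigError(f"unknown blood_rule {self.blood_rule!r}")
        if self.summary not in ("mean", "median"):
            raise ConfigError(f"unknown summary {self.summary!r}")


@dataclass
class ScreenReport:
    """Result of the full cascade: per-site table, stage counts, final picks."""

    site_table: pd.DataFrame
    stage_counts: dict[str, int]
    selected: list[str]
    config: ScreenConfig

    def summary(self) -> dict:
        return {"stage_counts": self.stage_counts, "selected": self.selected}


# ---------------------------------------------------------------------------
# per-site testing


def site_rank_sum_test(tumor_betas: Sequence[float], normal_betas: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) P for one CpG site.

    Exact enumeration when both arms have <= 8 untied values, otherwise the
    normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(tumor_betas, dtype=float)
    y = np.asarray(normal_betas, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise InputError("rank-sum test requires at least one finite value per arm")
    pooled = np.concatenate([x, y])
    exact = x.size <= 8 and y.size <= 8 and np.unique(pooled).size == pooled.size
    method = "exact" if exact else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def _rank_sum_by_site(tumor: pd.DataFrame, normal: pd.DataFrame) -> np.ndarray:
    """Vectorised per-site rank-sum P; falls back to row loop if NaN present."""
    tx, ny = tumor.to_numpy(dtype=float), normal.to_numpy(dtype=float)
    n1, n2 = tx.shape[1], ny.shape[1]
    if n1 > 8 and n2 > 8 and np.isfinite(tx).all() and np.isfinite(ny).all():
        res = stats.mannwhitneyu(tx, ny, alternative="two-sided", method="asymptotic", axis=1)
        return np.asarray(res.pvalue, dtype=float)
    return np.array(
        [site_rank_sum_test(tx[i], ny[i]) for i in range(tx.shape[0])], dtype=float
    )


def compute_site_stats(
    m: BetaMatrix,
    cfg: ScreenConfig | None = None,
    annotation: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-site arm summaries, delta-beta and rank-sum P for every site.

    ``annotation`` maps site id -> gene symbol; sites without annotation get
    an empty gene. Returns a DataFrame indexed by site id with
    :data:`STAT_COLUMNS`.
    """
    cfg = cfg or ScreenConfig()
    summarise = np.nanmean if cfg.summary == "mean" else np.nanmedian
    tumor, normal, blood = m.arm("tumor"), m.arm("normal"), m.arm("blood")
    out = pd.DataFrame(index=m.site_ids)
    out["gene"] = "" if annotation is None else annotation.reindex(m.site_ids).fillna("")
    out["mean_beta_tumor"] = summarise(tumor.to_numpy(dtype=float), axis=1)
    out["mean_beta_normal"] = summarise(normal.to_numpy(dtype=float), axis=1)
    out["mean_beta_blood"] = summarise(blood.to_numpy(dtype=float), axis=1)
    out["delta_beta"] = out["mean_beta_tumor"] - out["mean_beta_normal"]
    out["p_value"] = _rank_sum_by_site(tumor, normal)
    if cfg.p_adjust == "fdr_bh":
        from statsmodels.stats.multitest import multipletests

        out["p_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# cascade stages (each returns a subset of its input candidate table)


def stage1_differential_filter(m: BetaMatrix, cfg: ScreenConfig,
                               stats_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tumor-vs-normal differential filter.

    Retains sites with delta_beta >= delta_min, rank-sum P < p_max and mean
    tumor beta >= beta_tumor_min. All three statistics are recorded for every
    input site (the returned frame is a row subset of the full stats table).
    """
    t = compute_site_stats(m, cfg) if stats_table is None else stats_table
    keep = (
        (t["delta_beta"] >= cfg.delta_min)
        & (t["p_value"] < cfg.p_max)
        & (t["mean_beta_tumor"] >= cfg.beta_tumor_min)
    )
    return t[keep]


def stage2_blood_filter(candidates: pd.DataFrame, cfg: ScreenConfig) -> pd.DataFrame:
    """Blood rescreen: drop sites with high background in non-tumor blood.

    Default rule keeps sites whose tumor-minus-blood mean beta margin is at
    least ``blood_margin_min``; the 'absolute' rule instead excludes sites
    whose mean blood beta is >= ``blood_beta_max``.
    """
    if "mean_beta_blood" not in candidates or candidates["mean_beta_blood"].isna().any():
        raise InputError("blood-arm means missing; run compute_site_stats on a matrix with a blood arm")
    if cfg.blood_rule == "margin":
        keep = (candidates["mean_beta_tumor"] - candidates["mean_beta_blood"]) >= cfg.blood_margin_min
    else:
        keep = candidates["mean_beta_blood"] < cfg.blood_beta_max
    return candidates[keep]


def rank_sites(candidates: pd.DataFrame) -> pd.DataFrame:
    """Order descending by delta_beta; ties by ascending P then site id."""
    t = candidates.copy()
    t["_site"] = t.index
    t = t.sort_values(["delta_beta", "p_value", "_site"], ascending=[False, True, True])
    return t.drop(columns="_site")


def restrict_to_genes(candidates: pd.DataFrame, gene_whitelist: Iterable[str]) -> pd.DataFrame:
    """Keep candidates whose annotated gene is in the whitelist."""
    if "gene" not in candidates.columns or (candidates["gene"] == "").all():
        raise InputError("no gene annotation available for gene restriction")
    wanted = set(gene_whitelist)
    return candidates[candidates["gene"].isin(wanted)]


def rf_select(candidates: pd.DataFrame, m: BetaMatrix, cfg: ScreenConfig) -> pd.DataFrame:
    """Final selection by random-forest importance, preferring sites with
    low methylation in normal tissue.

    A tumor-vs-normal forest is trained on the candidate-site betas;
    candidates are ranked by impurity importance, then within the top
    ``2 * n_select`` the tie among similarly important sites is resolved
    toward lower mean normal beta. Exactly ``n_select`` sites are returned,
    with importances recorded.
    """
    if len(candidates) < cfg.n_select:
        raise InputError(
            f"{len(candidates)} candidates < n_select={cfg.n_select}"
        )
    tumor, normal = m.arm("tumor"), m.arm("normal")
    sites = list(candidates.index)
    X = np.vstack([
        tumor.loc[sites].to_numpy(dtype=float).T,
        normal.loc[sites].to_numpy(dtype=float).T,
    ])
    y = np.r_[np.ones(tumor.shape[1], int), np.zeros(normal.shape[1], int)]
    X = np.nan_to_num(X, nan=0.5)
    forest = RandomForestClassifier(n_estimators=cfg.rf_trees, random_state=cfg.seed)
    forest.fit(X, y)
    t = candidates.copy()
    t["importance"] = forest.feature_importances_
    t["_site"] = t.index
    pool = t.sort_values(["importance", "_site"], ascending=[False, True]).head(2 * cfg.n_select)
    final = pool.sort_values(["mean_beta_normal", "_site"], ascending=[True, True]).head(cfg.n_select)
    final = final.sort_values(["importance", "_site"], ascending=[False, True])
    return final.drop(columns="_site")


def run_screen(
    m: BetaMatrix,
    cfg: ScreenConfig | None = None,
    annotation: pd.Series | None = None,
) -> ScreenReport:
    """Run the full cascade and report per-stage survivor counts.

    Stages: differential filter -> blood rescreen -> rank -> optional gene
    restriction -> random-forest selection of the final panel.
    """
    cfg = cfg or ScreenConfig()
    table = compute_site_stats(m, cfg, annotation)
    counts = {"input": len(table)}
    s1 = stage1_differential_filter(m, cfg, stats_table=table)
    counts["stage1_differential"] = len(s1)
    s2 = stage2_blood_filter(s1, cfg)
    counts["stage2_blood"] = len(s2)
    ranked = rank_sites(s2)
    if cfg.gene_whitelist is not None:
        ranked = restrict_to_genes(ranked, cfg.gene_whitelist)
    counts["gene_restricted"] = len(ranked)
    final = rf_select(ranked, m, cfg)
    counts["selected"] = len(final)

    table = table.copy()
    table["importance"] = np.nan
    table.loc[final.index, "importance"] = final["importance"]
    for name, surv in (
        ("pass_stage1", s1.index),
        ("pass_stage2", s2.index),
        ("pass_genes", ranked.index),
        ("selected", final.index),
    ):
        table[name] = table.index.isin(surv)
    return ScreenReport(table, counts, list(final.index), cfg)
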