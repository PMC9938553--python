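"""Synthetic data generators for the methylation biomarker pipeline.

Three generators emulate the study's data structure end to end:

* a 450K-style beta matrix with tumor / adjacent-normal / peripheral-blood
  arms and a configurable number of spiked CRC-hypermethylated sites;
* qMSP plate data — triplicate-well Ct values for the marker targets and
  the ACTB reference across tissue / stool / blood samples and clinical
  groups, with well dropout and reference-QC failures;
* a participant roster with exclusion flags and an interfering-disease arm.

Background beta values are drawn from a Beta distribution and Ct values
from a truncated Normal: the simplest families matching the support of each
quantity. Undetected wells are an explicit sentinel (missing Ct), never a
number, so downstream imputation stays observable. Truth labels (spiked
sites, group assignments) travel in sidecar tables, never inside the data
files the pipeline reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .screening import BetaMatrix

MARKERS = ("cg13096260", "cg12993163")
REFERENCE = "ACTB"

#: gene pool for spiked sites; background sites get GENE#### symbols
SPIKE_GENES = ("SDC2", "SHOX2", "SEPT9", "NDRG4", "BMP3")

MAX_CT = 40.0  # qPCR run length in cycles; no Ct beyond this is observable


# ---------------------------------------------------------------------------
# beta matrices


@dataclass(frozen=True)
class BetaSimConfig:
    """Conditions for the simulated 450K-style beta matrix.

    n_sites : number of CpG sites
    n_tumor, n_normal, n_blood : samples per arm
    n_differential : number of spiked CRC-hypermethylated sites
    delta_spike : target mean tumor-minus-normal beta difference at spiked
        sites (fraction)
    base_beta_params : (a, b) of the background Beta distribution; the
        default (2, 8) gives background mean beta 0.2 with realistic spread
    seed : RNG seed
    """

    n_sites: int = 1000
    n_tumor: int = 40
    n_normal: int = 40
    n_blood: int = 40
    n_differential: int = 50
    delta_spike: float = 0.4
    base_beta_params: tuple[float, float] = (2.0, 8.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sites", "n_tumor", "n_normal", "n_blood"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_differential < 0 or self.n_differential > self.n_sites:
            raise ConfigError("n_differential must lie in [0, n_sites]")
        if not 0 < self.delta_spike < 1:
            raise ConfigError("delta_spike must lie in (0, 1)")
        a, b = self.base_beta_params
        if a <= 0 or b <= 0:
            raise ConfigError("base_beta_params must be positive")


def _beta_draw(rng: np.random.Generator, mean: float, conc: float, size) -> np.ndarray:
    """Beta variates with the given mean and concentration (a+b)."""
    mean = float(np.clip(mean, 1e-3, 1 - 1e-3))
    return rng.beta(mean * conc, (1 - mean) * conc, size=size)


def generate_beta_matrix(cfg: BetaSimConfig) -> tuple[BetaMatrix, pd.DataFrame]:
    """Simulate a beta matrix plus a sidecar truth table.

    Background sites are iid Beta(a, b) in every arm. Spiked sites keep the
    background distribution in the normal and blood arms but have their
    tumor-arm mean raised by ``delta_spike`` (at matched concentration), the
    signature of CRC-hypermethylated CpG sites with low background in blood.

    Returns the matrix and a truth DataFrame with columns
    ``site_id``, ``spiked``, ``gene`` (spiked sites draw symbols from known
    CRC methylation genes; background sites get synthetic GENE#### symbols).
    """
    rng = np.random.default_rng(cfg.seed)
    a, b = cfg.base_beta_params
    mu0 = a / (a + b)
    conc = a + b
    n_samp = cfg.n_tumor + cfg.n_normal + cfg.n_blood

    values = rng.beta(a, b, size=(cfg.n_sites, n_samp))
    spiked_idx = rng.choice(cfg.n_sites, size=cfg.n_differential, replace=False)
    tumor_cols = slice(0, cfg.n_tumor)
    if cfg.n_differential:
        values[spiked_idx, tumor_cols] = _beta_draw(
            rng, mu0 + cfg.delta_spike, conc, (cfg.n_differential, cfg.n_tumor)
        )

    site_ids = [f"cg{i:08d}" for i in range(cfg.n_sites)]
    sample_ids = (
        [f"T{i:03d}" for i in range(cfg.n_tumor)]
        + [f"N{i:03d}" for i in range(cfg.n_normal)]
        + [f"B{i:03d}" for i in range(cfg.n_blood)]
    )
    groups = pd.Series(
        ["tumor"] * cfg.n_tumor + ["normal"] * cfg.n_normal + ["blood"] * cfg.n_blood,
        index=sample_ids,
        name="group",
    )
    matrix = BetaMatrix(pd.DataFrame(values, index=site_ids, columns=sample_ids), groups)

    spiked = np.zeros(cfg.n_sites, dtype=bool)
    spiked[spiked_idx] = True
    genes = np.array([f"GENE{i:04d}" for i in range(cfg.n_sites)], dtype=object)
    genes[spiked_idx] = [SPIKE_GENES[k % len(SPIKE_GENES)] for k in range(cfg.n_differential)]
    truth = pd.DataFrame({"site_id": site_ids, "spiked": spiked, "gene": genes})
    return matrix, truth


# ---------------------------------------------------------------------------
# qMSP plates


@dataclass(frozen=True)
class QmspSimConfig:
    """Conditions for a simulated qMSP plate.

    group_sizes : clinical group -> number of samples
    matrix : sample matrix for every sample on the plate (tissue/stool/blood)
    marker_ct_means : (group, target) -> mean Ct for this plate's matrix;
        targets include the markers and the ACTB reference
    ct_sd : within-sample replicate-well Ct noise (cycles)
    sample_sd : between-sample biological spread of the true Ct around the
        group mean (cycles); real cohorts overlap across groups, so this is
        what keeps simulated assays imperfect
    marker_rho : correlation of the two markers' sample-level deviations;
        both markers ride on the same tumor-DNA fraction in a sample, so
        their deviations are strongly shared (default 0.8)
    p_well_dropout : probability any single well is undetected
    p_actb_fail : probability a sample's reference gene fails QC (its ACTB
        wells are shifted above the QC bound)
    seed : RNG seed
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"NED": 30, "AA": 12, "CRC_I_II": 20, "CRC_III_IV": 14}
    )
    matrix: str = "stool"
    marker_ct_means: dict[tuple[str, str], float] | None = None
    ct_sd: float = 0.5
    sample_sd: float = 2.0
    marker_rho: float = 0.8
    p_well_dropout: float = 0.03
    p_actb_fail: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_well_dropout", "p_actb_fail"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if any(v < 0 for v in self.group_sizes.values()):
            raise ConfigError("group sizes must be >= 0")
        if self.matrix not in ("tissue", "stool", "blood"):
            raise ConfigError(f"unknown sample matrix {self.matrix!r}")
        if self.ct_sd <= 0:
            raise ConfigError("ct_sd must be positive")
        if self.sample_sd < 0:
            raise ConfigError("sample_sd must be >= 0")
        if not 0 <= self.marker_rho <= 1:
            raise ConfigError("marker_rho must lie in [0, 1]")
        for (g, t), m in (self.marker_ct_means or {}).items():
            if not 0 < m < MAX_CT:
                raise ConfigError(f"Ct mean for ({g}, {t}) outside (0, 40)")


def default_stool_ct_means() -> dict[tuple[str, str], float]:
    """Plate means emulating a stool cohort.

    With the default between-sample spread (2 cycles) and the stool
    positivity bounds (31/32), diseased groups land mostly below the bound
    and NED mostly above it, so threshold calling shows the high-but-
    imperfect sensitivity/specificity typical of stool methylation assays;
    late NED draws past the 40-cycle run come back undetected and are
    imputed at Ct 33."""
    means: dict[tuple[str, str], float] = {}
    for g, m1, m2 in [
        ("NED", 34.5, 35.5),
        ("AA", 30.0, 29.5),
        ("CRC_I_II", 28.0, 29.0),
        ("CRC_III_IV", 27.0, 28.0),
        ("interfering", 34.0, 35.0),
    ]:
        means[(g, MARKERS[0])] = m1
        means[(g, MARKERS[1])] = m2
        means[(g, REFERENCE)] = 26.0
    return means


def default_blood_ct_means() -> dict[tuple[str, str], float]:
    """Plasma cohort: ctDNA is dilute, so the positivity bound is 25 cycles;
    diseased samples centre around 23, NED around 30 (valid but negative)."""
    means: dict[tuple[str, str], float] = {}
    for g, m1, m2 in [
        ("NED", 27.5, 27.5),
        ("AA", 24.0, 23.5),
        ("CRC_I_II", 23.5, 23.0),
        ("CRC_III_IV", 22.5, 22.5),
        ("interfering", 27.0, 27.0),
    ]:
        means[(g, MARKERS[0])] = m1
        means[(g, MARKERS[1])] = m2
        means[(g, REFERENCE)] = 26.0
    return means


def default_tissue_ct_means() -> dict[tuple[str, str], float]:
    """Paired tissue plate: tumor samples ~5 cycles earlier than normals."""
    means: dict[tuple[str, str], float] = {}
    for g, m in [("tumor", 27.0), ("normal", 32.0)]:
        means[(g, MARKERS[0])] = m
        means[(g, MARKERS[1])] = m + 0.5
        means[(g, REFERENCE)] = 24.0
    return means


def generate_plate(cfg: QmspSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate triplicate-well qMSP records plus a sample truth table.

    Returns
    -------
    plate : long DataFrame with columns ``sample_id, matrix, target, well, ct``
        (ct is NaN for undetected wells — draws past the 40-cycle run or
        random dropout).
    samples : truth table with ``sample_id, matrix, group``.
    """
    rng = np.random.default_rng(cfg.seed)
    means = cfg.marker_ct_means
    if means is None:
        means = {
            "tissue": default_tissue_ct_means,
            "stool": default_stool_ct_means,
            "blood": default_blood_ct_means,
        }[cfg.matrix]()

    targets = list(MARKERS) + [REFERENCE]
    rows, meta = [], []
    i = 0
    for group, n in cfg.group_sizes.items():
        for _ in range(n):
            sid = f"S{i:04d}"
            i += 1
            actb_fails = rng.random() < cfg.p_actb_fail
            # markers share a tumor-DNA-load effect; the rest is marker-specific
            shared = rng.normal(0.0, cfg.sample_sd * np.sqrt(cfg.marker_rho))
            indep_sd = cfg.sample_sd * np.sqrt(1.0 - cfg.marker_rho)
            for target in targets:
                try:
                    mu = means[(group, target)]
                except KeyError as e:
                    raise ConfigError(f"no Ct mean for (group={group}, target={target})") from e
                if target == REFERENCE:
                    sample_mu = 36.0 if actb_fails else rng.normal(mu, cfg.ct_sd)
                else:
                    sample_mu = mu + shared + rng.normal(0.0, indep_sd)
                for well in (1, 2, 3):
                    ct = rng.normal(sample_mu, cfg.ct_sd)
                    undetected = ct >= MAX_CT or rng.random() < cfg.p_well_dropout
                    ct = max(ct, 1e-6)  # truncate at the low end, Ct > 0
                    rows.append((sid, cfg.matrix, target, well, np.nan if undetected else ct))
            meta.append((sid, cfg.matrix, group))
    plate = pd.DataFrame(rows, columns=["sample_id", "matrix", "target", "well", "ct"])
    samples = pd.DataFrame(meta, columns=["sample_id", "matrix", "group"])
    return plate, samples


def generate_paired_tissue_plate(
    n_pairs: int = 76,
    tumor_shift: float = -5.0,
    ct_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired tumor / adjacent-normal tissue plate for the delta-Ct analysis.

    Tumor samples amplify ``tumor_shift`` cycles relative to their paired
    normals (negative = earlier = more methylated). Pair identity is encoded
    in the sample ids (``P0001_T`` / ``P0001_N``).
    """
    rng = np.random.default_rng(seed)
    base = default_tissue_ct_means()
    rows, meta = [], []
    for i in range(n_pairs):
        pair_effect = rng.normal(0.0, 0.5)  # shared per-pair input-amount shift
        for arm, tag in (("normal", "N"), ("tumor", "T")):
            sid = f"P{i:04d}_{tag}"
            for target in list(MARKERS) + [REFERENCE]:
                mu = base[("normal", target)] + pair_effect
                if arm == "tumor" and target != REFERENCE:
                    mu += tumor_shift
                for well in (1, 2, 3):
                    ct = max(rng.normal(mu, ct_sd), 1e-6)
                    rows.append((sid, "tissue", target, well, np.nan if ct >= MAX_CT else ct))
            meta.append((sid, "tissue", arm, f"P{i:04d}"))
    plate = pd.DataFrame(rows, columns=["sample_id", "matrix", "target", "well", "ct"])
    samples = pd.DataFrame(meta, columns=["sample_id", "matrix", "group", "pair_id"])
    return plate, samples


# ---------------------------------------------------------------------------
# participant rosters


def generate_roster(
    n_enrolled: int,
    exclusion_counts: dict[str, int] | None = None,
    n_interfering: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Participant roster with per-person exclusion flags.

    Participants are assigned exactly the requested number of each exclusion
    flag and of interfering-disease status; everyone else lands in the main
    analysis arm with a clinical group drawn from CRC/AA/NED. The derived
    ``analysis_arm`` is ``excluded`` if any exclusion flag is set,
    ``interfering`` for the interfering-disease arm, else ``main``.
    """
    exclusion_counts = dict(exclusion_counts or {})
    n_excl = sum(exclusion_counts.values())
    if any(v < 0 for v in exclusion_counts.values()) or n_interfering < 0:
        raise ConfigError("counts must be >= 0")
    if n_excl + n_interfering > n_enrolled:
        raise ConfigError(
            f"exclusions ({n_excl}) + interfering ({n_interfering}) exceed enrollment ({n_enrolled})"
        )
    rng = np.random.default_rng(seed)
    ids = [f"PT{i:04d}" for i in range(n_enrolled)]
    order = rng.permutation(n_enrolled)

    roster = pd.DataFrame({"participant_id": ids})
    for reason in exclusion_counts:
        roster[reason] = False
    roster["interfering"] = False
    pos = 0
    for reason, k in exclusion_counts.items():
        roster.loc[order[pos : pos + k], reason] = True
        pos += k
    roster.loc[order[pos : pos + n_interfering], "interfering"] = True
    pos += n_interfering

    flag_cols = list(exclusion_counts)
    excluded = roster[flag_cols].any(axis=1) if flag_cols else pd.Series(False, index=roster.index)
    roster["analysis_arm"] = np.where(
        excluded, "excluded", np.where(roster["interfering"], "interfering", "main")
    )
    groups = np.full(n_enrolled, "", dtype=object)
    main_idx = np.flatnonzero((roster["analysis_arm"] == "main").to_numpy())
    groups[main_idx] = rng.choice(["CRC", "AA", "NED"], size=main_idx.size, p=[0.5, 0.12, 0.38])
    groups[(roster["analysis_arm"] == "interfering").to_numpy()] = "interfering"
    roster["group"] = groups
    return roster
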